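"""Constrained DDM variants compared by the analysis.

Six nested variants differ in which parameters may vary over the three probe
conditions and in how the starting point is treated:

* Model 1 — drift rate and its intertrial variability vary by condition;
  boundary, starting-point range, nondecision time and its range shared;
  unbiased start (z = a/2).  10 free parameters.
* Model 2 — Model 1 plus boundary separation and starting-point range per
  condition.  14 free parameters.
* Model 3 — Model 2 plus nondecision time and its range per condition.
  18 free parameters.
* Models 4–6 — as 1–3 but with the starting point estimated (one z shared
  across conditions, free to differ from a/2).  11 / 15 / 19 free parameters.

For the unbiased models the upper boundary codes the *correct* response
("accuracy coding").  For the biased models the upper boundary codes the
*"positive"* response and drifts are stimulus-coded (positive trials drift
+v, negative trials −v), so a starting point above a/2 means a bias toward
responding "positive".
"""

from __future__ import annotations

from dataclasses import dataclass

from .params import CONDITIONS


@dataclass(frozen=True)
class ModelSpec:
    """Declarative constraint map for one model variant."""

    id: int
    a_by_condition: bool
    ter_by_condition: bool
    bias: str  # "unbiased" (z = a/2) or "estimated" (z free, shared)

    def __post_init__(self) -> None:
        if self.bias not in ("unbiased", "estimated"):
            raise ValueError(f"bias must be 'unbiased' or 'estimated', got {self.bias!r}")

    @property
    def coding(self) -> str:
        """Boundary coding: 'accuracy' (upper = correct) or 'stimulus' (upper = positive)."""
        return "accuracy" if self.bias == "unbiased" else "stimulus"

    @property
    def n_free_parameters(self) -> int:
        k = 2 * len(CONDITIONS)  # v, eta always per condition
        k += 2 * len(CONDITIONS) if self.a_by_condition else 2  # a, sz
        k += 2 * len(CONDITIONS) if self.ter_by_condition else 2  # ter, st
        if self.bias == "estimated":
            k += 1  # shared z
        return k

    def describe(self) -> str:
        free = ["v", "eta"]
        if self.a_by_condition:
            free += ["a", "sz"]
        if self.ter_by_condition:
            free += ["ter", "st"]
        start = "z = a/2" if self.bias == "unbiased" else "z estimated (shared)"
        return (
            f"Model {self.id}: per-condition {{{', '.join(free)}}}; {start}; "
            f"{self.n_free_parameters} free parameters"
        )


MODEL_SPECS: dict[int, ModelSpec] = {
    1: ModelSpec(1, a_by_condition=False, ter_by_condition=False, bias="unbiased"),
    2: ModelSpec(2, a_by_condition=True, ter_by_condition=False, bias="unbiased"),
    3: ModelSpec(3, a_by_condition=True, ter_by_condition=True, bias="unbiased"),
    4: ModelSpec(4, a_by_condition=False, ter_by_condition=False, bias="estimated"),
    5: ModelSpec(5, a_by_condition=True, ter_by_condition=False, bias="estimated"),
    6: ModelSpec(6, a_by_condition=True, ter_by_condition=True, bias="estimated"),
}


def get_model(model_id: int) -> ModelSpec:
    try:
        return MODEL_SPECS[int(model_id)]
    except (KeyError, ValueError):
        raise ValueError(f"unknown model id {model_id!r}; expected 1-6") from None
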