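"""Core parameter containers for the diffusion decision model (DDM).

The DDM describes two-choice decisions as a noisy accumulation of evidence
between two absorbing boundaries.  Its main parameters are the drift rate
``v`` (mean evidence per second, signed toward the correct / "positive"
boundary), the boundary separation ``a`` (response caution), the starting
point ``z`` (predecision bias) and the nondecision time ``ter`` (encoding +
motor latency, seconds).  Across trials the drift is Normal(v, eta), the
starting point Uniform(z ± sz/2) and the nondecision time Uniform(ter ± st/2).
The diffusion constant ``s`` is a scaling parameter fixed to 0.1, with all
times in seconds.

Parameters that the constrained model variants allow to differ between task
conditions (positive, non-recent negative, recent negative probes) are stored
per condition; scalars given to the constructor are broadcast.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

#: Canonical condition order used throughout the package.
CONDITIONS: tuple[str, ...] = ("positive", "nonrecent_negative", "recent_negative")

#: Conditions requiring a "negative" (probe not in target set) response.
NEGATIVE_CONDITIONS: frozenset[str] = frozenset(
    {"nonrecent_negative", "recent_negative"}
)

#: Default diffusion constant (evidence units per sqrt second).
DIFFUSION_CONSTANT: float = 0.1

#: Default intertrial variabilities used when no value is supplied.
DEFAULT_ETA: float = 0.10
DEFAULT_SZ: float = 0.02
DEFAULT_ST: float = 0.10

#: Quantile probabilities used in quantile-probability summaries.
QUANTILE_PROBS: tuple[float, ...] = (0.1, 0.3, 0.5, 0.7, 0.9)


def _as_condition_map(
    value: float | Mapping[str, float] | Sequence[float],
    name: str,
) -> dict[str, float]:
    """Broadcast a scalar, mapping, or length-3 sequence to a condition map."""
    if isinstance(value, Mapping):
        missing = set(CONDITIONS) - set(value)
        if missing:
            raise ValueError(f"{name} missing conditions: {sorted(missing)}")
        return {c: float(value[c]) for c in CONDITIONS}
    if np.isscalar(value):
        return {c: float(value) for c in CONDITIONS}
    seq = list(value)
    if len(seq) != len(CONDITIONS):
        raise ValueError(f"{name} must be scalar, mapping, or length-3 sequence")
    return {c: float(x) for c, x in zip(CONDITIONS, seq)}


@dataclass
class DDMParameterSet:
    """Full DDM parameter vector, stored per condition.

    All fields except ``s`` are condition maps; the constructor broadcasts
    scalars.  ``z`` defaults to ``a / 2`` (unbiased start).

    Invariants enforced by :meth:`validate`: ``a > 0``; ``0 < z < a`` with the
    whole starting-point range inside the boundaries (``z - sz/2 > 0`` and
    ``z + sz/2 < a``); ``ter - st/2 >= 0``; ``eta >= 0``.
    """

    v: Mapping[str, float] | float
    eta: Mapping[str, float] | float = DEFAULT_ETA
    a: Mapping[str, float] | float = 0.1
    z: Mapping[str, float] | float | None = None
    sz: Mapping[str, float] | float = DEFAULT_SZ
    ter: Mapping[str, float] | float = 0.3
    st: Mapping[str, float] | float = DEFAULT_ST
    s: float = DIFFUSION_CONSTANT

    def __post_init__(self) -> None:
        self.v = _as_condition_map(self.v, "v")
        self.eta = _as_condition_map(self.eta, "eta")
        self.a = _as_condition_map(self.a, "a")
        if self.z is None:
            self.z = {c: self.a[c] / 2.0 for c in CONDITIONS}
        else:
            self.z = _as_condition_map(self.z, "z")
        self.sz = _as_condition_map(self.sz, "sz")
        self.ter = _as_condition_map(self.ter, "ter")
        self.st = _as_condition_map(self.st, "st")
        self.s = float(self.s)
        self.validate()

    def validate(self) -> None:
        if not self.s > 0:
            raise ValueError(f"diffusion constant must be positive, got {self.s}")
        for c in CONDITIONS:
            a, z, sz = self.a[c], self.z[c], self.sz[c]
            ter, st, eta = self.ter[c], self.st[c], self.eta[c]
            if not a > 0:
                raise ValueError(f"a must be positive ({c}: {a})")
            if not (0.0 < z < a):
                raise ValueError(f"z must lie strictly inside (0, a) ({c}: z={z}, a={a})")
            if sz < 0 or z - sz / 2.0 <= 0 or z + sz / 2.0 >= a:
                raise ValueError(
                    f"starting-point range must stay inside boundaries "
                    f"({c}: z={z}, sz={sz}, a={a})"
                )
            if st < 0 or ter - st / 2.0 < 0:
                raise ValueError(f"nondecision range must be nonnegative ({c}: ter={ter}, st={st})")
            if eta < 0:
                raise ValueError(f"eta must be nonnegative ({c}: {eta})")

    # -- convenience ------------------------------------------------------

    def arrays(self) -> dict[str, np.ndarray]:
        """Per-condition parameter arrays in canonical condition order."""
        return {
            name: np.array([getattr(self, name)[c] for c in CONDITIONS], dtype=float)
            for name in ("v", "eta", "a", "z", "sz", "ter", "st")
        }

    def for_condition(self, condition: str) -> dict[str, float]:
        if condition not in CONDITIONS:
            raise ValueError(f"unknown condition {condition!r}")
        return {
            "v": self.v[condition],
            "eta": self.eta[condition],
            "a": self.a[condition],
            "z": self.z[condition],
            "sz": self.sz[condition],
            "ter": self.ter[condition],
            "st": self.st[condition],
            "s": self.s,
        }

    def replace(self, **updates) -> "DDMParameterSet":
        """Return a copy with the given fields replaced (broadcast as usual)."""
        kwargs = {
            "v": dict(self.v),
            "eta": dict(self.eta),
            "a": dict(self.a),
            "z": dict(self.z),
            "sz": dict(self.sz),
            "ter": dict(self.ter),
            "st": dict(self.st),
            "s": self.s,
        }
        kwargs.update(updates)
        return DDMParameterSet(**kwargs)

    def to_dict(self) -> dict:
        return {
            "v": dict(self.v),
            "eta": dict(self.eta),
            "a": dict(self.a),
            "z": dict(self.z),
            "sz": dict(self.sz),
            "ter": dict(self.ter),
            "st": dict(self.st),
            "s": self.s,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "DDMParameterSet":
        return cls(**d)


@dataclass
class QuantileSummary:
    """Response proportions and RT quantiles per (condition, response) cell.

    ``proportion[(condition, response)]`` with response in {"correct",
    "error"}; ``quantiles[(condition, response)]`` holds RTs (seconds) at
    :data:`QUANTILE_PROBS`.  Cells whose response probability or trial count
    is too small for stable quantiles are listed in ``unreliable`` instead of
    being fabricated (their quantiles are NaN).
    """

    probs: tuple[float, ...] = QUANTILE_PROBS
    proportion: dict = field(default_factory=dict)
    quantiles: dict = field(default_factory=dict)
    unreliable: set = field(default_factory=set)

    def conditions(self) -> list[str]:
        return sorted({c for (c, _r) in self.proportion}, key=CONDITIONS.index)

    def check(self, atol: float = 1e-8) -> None:
        """Verify quantiles are nondecreasing and proportions sum to 1."""
        for cond in self.conditions():
            total = sum(
                self.proportion.get((cond, r), 0.0) for r in ("correct", "error")
            )
            if abs(total - 1.0) > atol:
                raise ValueError(f"proportions for {cond} sum to {total}, not 1")
        for key, q in self.quantiles.items():
            q = np.asarray(q, dtype=float)
            if key in self.unreliable or np.isnan(q).any():
                continue
            if np.any(np.diff(q) < -atol):
                raise ValueError(f"quantiles for {key} are not nondecreasing: {q}")
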