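"""Trial-level stochastic simulator of the full DDM.

Serves both as the data-generating engine behind synthetic cohorts and as the
ground-truth Monte-Carlo oracle against which the analytic densities are
tested.  Each trial draws its drift from Normal(v, eta), its starting point
from Uniform(z ± sz/2) and its nondecision time from Uniform(ter ± st/2),
then runs an Euler–Maruyama walk with diffusion constant ``s`` until a
boundary is crossed.

Simulation is always in the stimulus frame: the upper boundary is the
"positive" response, so on negative-probe trials the (correct-pointing)
drift enters with a minus sign.  For unbiased parameter sets (z = a/2) this
is distributionally identical to accuracy coding.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit

from .params import CONDITIONS, NEGATIVE_CONDITIONS, DDMParameterSet

#: Trials still unabsorbed at max_t are redrawn; above this rate we warn.
MAX_REDRAW_RATE: float = 1e-3


@dataclass
class SimOptions:
    """Euler–Maruyama settings: step ``dt`` (s), absorption cap ``max_t`` (s)."""

    dt: float = 1e-4
    max_t: float = 10.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (self.dt > 0 and self.max_t > 0):
            raise ValueError("dt and max_t must be positive")


@njit(cache=True)
def _euler_kernel(
    drift: np.ndarray,
    start: np.ndarray,
    a: float,
    s: float,
    dt: float,
    max_steps: int,
    seed: int,
):
    """Simulate first-passage for each trial; returns (decision time, hit-upper, redraws)."""
    np.random.seed(seed)
    n = drift.shape[0]
    rt = np.empty(n)
    hit = np.empty(n, np.bool_)
    redraws = 0
    sq = s * math.sqrt(dt)
    for i in range(n):
        attempts = 0
        while True:
            x = start[i]
            absorbed = False
            for step in range(1, max_steps + 1):
                x += drift[i] * dt + sq * np.random.normal(0.0, 1.0)
                if x >= a:
                    rt[i] = step * dt
                    hit[i] = True
                    absorbed = True
                    break
                if x <= 0.0:
                    rt[i] = step * dt
                    hit[i] = False
                    absorbed = True
                    break
            if absorbed:
                break
            redraws += 1
            attempts += 1
            if attempts >= 100:  # pathological parameters; take sign of position
                rt[i] = max_steps * dt
                hit[i] = x >= a / 2.0
                break
    return rt, hit, redraws


def simulate_condition(
    params: DDMParameterSet,
    condition: str,
    n: int,
    rng: np.random.Generator,
    options: SimOptions | None = None,
):
    """Simulate ``n`` trials of one condition.

    Returns ``(rt_s, response, accuracy, n_redrawn)`` where ``response`` is an
    array of ``"positive"`` / ``"negative"`` strings.
    """
    options = options or SimOptions()
    p = params.for_condition(condition)
    sign = -1.0 if condition in NEGATIVE_CONDITIONS else 1.0
    drift = rng.normal(sign * p["v"], p["eta"], n) if p["eta"] > 0 else np.full(n, sign * p["v"])
    start = p["z"] + p["sz"] * (rng.random(n) - 0.5)
    ndt = p["ter"] + p["st"] * (rng.random(n) - 0.5)
    kernel_seed = int(rng.integers(0, 2**31 - 1))
    max_steps = int(round(options.max_t / options.dt))
    dec, hit_upper, redraws = _euler_kernel(
        drift, start, p["a"], p["s"], options.dt, max_steps, kernel_seed
    )
    if n > 0 and redraws / n > MAX_REDRAW_RATE:
        warnings.warn(
            f"{redraws}/{n} trials unabsorbed by max_t={options.max_t}s and redrawn "
            f"({condition}); consider raising max_t",
            stacklevel=2,
        )
    response = np.where(hit_upper, "positive", "negative")
    correct = "negative" if condition in NEGATIVE_CONDITIONS else "positive"
    accuracy = (response == correct).astype(int)
    return dec + ndt, response, accuracy, redraws


def simulate_trial(
    params: DDMParameterSet,
    condition: str,
    rng: np.random.Generator,
    options: SimOptions | None = None,
) -> tuple[float, str]:
    """Simulate a single trial; returns ``(rt_s, response)``."""
    rt, response, _acc, _n = simulate_condition(params, condition, 1, rng, options)
    return float(rt[0]), str(response[0])


def simulate_dataset(
    params: DDMParameterSet,
    trials,
    options: SimOptions | None = None,
) -> pd.DataFrame:
    """Simulate one behavioral record per trial specification.

    ``trials`` is either a DataFrame with a ``condition`` column (``block``
    and ``trial`` optional) or a sequence of objects with ``condition`` /
    ``block`` / ``index`` attributes (:class:`~piddm.task.TrialSpec`).
    Reproducible given ``options.seed``; trials are simulated grouped by
    condition with the output restored to presentation order.
    """
    options = options or SimOptions()
    if isinstance(trials, pd.DataFrame):
        spec_df = trials[["condition"]].copy()
        spec_df["block"] = trials["block"] if "block" in trials else 1
        spec_df["trial"] = trials["trial"] if "trial" in trials else np.arange(len(trials))
    else:
        spec_df = pd.DataFrame(
            {
                "condition": [t.condition for t in trials],
                "block": [getattr(t, "block", 1) for t in trials],
                "trial": [getattr(t, "index", i) for i, t in enumerate(trials)],
            }
        )
    bad = set(spec_df["condition"]) - set(CONDITIONS)
    if bad:
        raise ValueError(f"unknown conditions in trial list: {sorted(bad)}")
    rng = np.random.default_rng(options.seed)
    n = len(spec_df)
    rt = np.empty(n)
    response = np.empty(n, dtype=object)
    accuracy = np.empty(n, dtype=int)
    total_redraws = 0
    for condition in CONDITIONS:  # fixed order keeps the RNG stream stable
        mask = (spec_df["condition"] == condition).to_numpy()
        if not mask.any():
            continue
        r, resp, acc, redraws = simulate_condition(
            params, condition, int(mask.sum()), rng, options
        )
        rt[mask], response[mask], accuracy[mask] = r, resp, acc
        total_redraws += redraws
    out = pd.DataFrame(
        {
            "block": spec_df["block"].to_numpy(),
            "trial": spec_df["trial"].to_numpy(),
            "condition": spec_df["condition"].to_numpy(),
            "response": response,
            "rt_s": rt,
            "accuracy": accuracy,
        }
    )
    out.attrs["n_redrawn"] = total_redraws
    return out
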