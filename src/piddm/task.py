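"""Recent-probes task design and synthetic cohorts.

The recent-probes task probes short-term recognition: each trial presents a
target set of four lowercase consonants, then a single probe.  Half of the
probes are *positive* (in the current target set).  Negative probes split
into *recent negatives* — absent from the current set but present in the
immediately preceding trial's set, which induces proactive interference —
and *non-recent negatives*, absent from the current and the two preceding
sets.  A session is three blocks of 160 trials (240 / 120 / 120 per
condition).

Because no behavioral data from the original study are available, this
module also synthesizes full cohorts: participant-level DDM parameters are
drawn around the published group means (young and older adults) and driven
through the trial simulator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .params import (
    CONDITIONS,
    DEFAULT_ETA,
    DEFAULT_ST,
    DEFAULT_SZ,
    DDMParameterSet,
)
from .simulate import SimOptions, simulate_dataset

#: All twenty lowercase consonants.
CONSONANT_POOL: tuple[str, ...] = tuple("bcdfghjklmnpqrstvwxz")

#: Trials at the start of a session that cannot satisfy the recency
#: look-back and are therefore restricted to positive / non-recent probes.
BURN_IN_TRIALS: int = 2

BEHAVIOR_COLUMNS = [
    "participant_id",
    "group",
    "block",
    "trial",
    "condition",
    "response",
    "rt_s",
    "accuracy",
]


# ---------------------------------------------------------------------------
# session design
# ---------------------------------------------------------------------------


@dataclass
class SessionDesign:
    """Structural description of one testing session."""

    n_blocks: int = 3
    trials_per_block: int = 160
    n_targets_per_set: int = 4
    stimulus_pool: tuple[str, ...] = CONSONANT_POOL
    proportions: Mapping[str, float] = field(
        default_factory=lambda: {
            "positive": 0.5,
            "nonrecent_negative": 0.25,
            "recent_negative": 0.25,
        }
    )
    # presentation timing (ms); recorded for completeness, not simulated
    fixation_ms: int = 500
    target_ms: int = 1500
    delay_ms: int = 3000
    intertrial_ms: int = 1000

    def __post_init__(self) -> None:
        self.proportions = {c: float(self.proportions.get(c, 0.0)) for c in CONDITIONS}
        if abs(sum(self.proportions.values()) - 1.0) > 1e-9:
            raise ValueError(f"condition proportions must sum to 1: {self.proportions}")
        if any(p < 0 for p in self.proportions.values()):
            raise ValueError("condition proportions must be nonnegative")
        if len(set(self.stimulus_pool)) != len(self.stimulus_pool):
            raise ValueError("stimulus pool contains duplicates")
        if self.n_blocks < 1 or self.trials_per_block < 1 or self.n_targets_per_set < 1:
            raise ValueError("design counts must be positive")

    @property
    def n_trials(self) -> int:
        return self.n_blocks * self.trials_per_block

    def condition_counts(self) -> dict[str, int]:
        """Exact per-session counts (largest-remainder rounding of proportions)."""
        raw = {c: self.proportions[c] * self.n_trials for c in CONDITIONS}
        counts = {c: int(math.floor(x)) for c, x in raw.items()}
        short = self.n_trials - sum(counts.values())
        for c in sorted(CONDITIONS, key=lambda c: raw[c] - counts[c], reverse=True)[:short]:
            counts[c] += 1
        return counts


@dataclass(frozen=True)
class TrialSpec:
    """One planned trial: target set, probe, and its condition."""

    index: int
    block: int
    target_set: tuple[str, ...]
    probe: str
    condition: str

    @property
    def correct_response(self) -> str:
        return "positive" if self.condition == "positive" else "negative"


class InfeasibleDesignError(ValueError):
    """Raised when a session design cannot satisfy its recency constraints."""


def generate_session(design: SessionDesign, seed: int) -> list[TrialSpec]:
    """Generate one session honoring exact condition counts and recency rules.

    The first two trials are restricted to positive / non-recent conditions
    (no look-back exists for them); counts are balanced over the rest so the
    session totals are exact.  Raises :class:`InfeasibleDesignError` naming
    the violated constraint when the stimulus pool is too small or the
    condition mix leaves no room for the burn-in.
    """
    pool = list(design.stimulus_pool)
    if len(pool) < max(12, 3 * design.n_targets_per_set):
        raise InfeasibleDesignError(
            f"stimulus pool of {len(pool)} cannot satisfy the recency constraints "
            f"(need at least {max(12, 3 * design.n_targets_per_set)} symbols)"
        )
    rng = np.random.default_rng(seed)
    counts = design.condition_counts()
    sequence = [c for c in CONDITIONS for _ in range(counts[c])]
    rng.shuffle(sequence)
    # burn-in: move recent-negative trials out of the first two slots
    n_burn = min(BURN_IN_TRIALS, len(sequence))
    for i in range(n_burn):
        if sequence[i] == "recent_negative":
            swap = next(
                (j for j in range(n_burn, len(sequence)) if sequence[j] != "recent_negative"),
                None,
            )
            if swap is None:
                raise InfeasibleDesignError(
                    "first trials cannot be recent negatives: no preceding target set "
                    "exists and every later trial is already recent negative"
                )
            sequence[i], sequence[swap] = sequence[swap], sequence[i]

    trials: list[TrialSpec] = []
    prev_sets: list[frozenset[str]] = []
    pool_set = frozenset(pool)
    for idx, condition in enumerate(sequence):
        for _attempt in range(1000):
            target = frozenset(rng.choice(pool, size=design.n_targets_per_set, replace=False))
            if condition == "positive":
                candidates = target
            elif condition == "recent_negative":
                candidates = prev_sets[-1] - target
            else:
                recent_union = frozenset().union(*prev_sets[-2:]) if prev_sets else frozenset()
                candidates = pool_set - target - recent_union
            if candidates:
                break
        else:
            raise InfeasibleDesignError(
                f"no admissible probe for condition {condition!r} at trial {idx}"
            )
        probe = str(rng.choice(sorted(candidates)))
        trials.append(
            TrialSpec(
                index=idx,
                block=idx // design.trials_per_block + 1,
                target_set=tuple(sorted(target)),
                probe=probe,
                condition=condition,
            )
        )
        prev_sets.append(target)
    return trials


# ---------------------------------------------------------------------------
# sequence validation
# ---------------------------------------------------------------------------


@dataclass
class ViolationReport:
    """Per-trial recency-constraint audit of a trial sequence."""

    n_trials: int
    condition_counts: dict[str, int]
    violations: list[tuple[int, str]]

    @property
    def n_violations(self) -> int:
        return len(self.violations)

    @property
    def ok(self) -> bool:
        return not self.violations


def validate_sequence(trials: Sequence[TrialSpec]) -> ViolationReport:
    """Re-check every trial against the two preceding target sets.

    Reports, never mutates: positive probes must be in the current set;
    recent negatives must come from the immediately preceding set (and not
    the current one); non-recent negatives must avoid the current and the
    two preceding sets.
    """
    if not trials:
        raise ValueError("cannot validate an empty trial list")
    violations: list[tuple[int, str]] = []
    counts = {c: 0 for c in CONDITIONS}
    for i, t in enumerate(trials):
        counts[t.condition] = counts.get(t.condition, 0) + 1
        current = set(t.target_set)
        prev1 = set(trials[i - 1].target_set) if i >= 1 else None
        prev2 = set(trials[i - 2].target_set) if i >= 2 else None
        if t.condition == "positive":
            if t.probe not in current:
                violations.append((i, "positive probe not in current target set"))
        elif t.condition == "recent_negative":
            if t.probe in current:
                violations.append((i, "recent negative probe in current target set"))
            if prev1 is None:
                violations.append((i, "recent negative trial has no preceding target set"))
            elif t.probe not in prev1:
                violations.append((i, "recent negative probe not in preceding target set"))
        elif t.condition == "nonrecent_negative":
            if t.probe in current:
                violations.append((i, "non-recent negative probe in current target set"))
            for lag, prev in ((1, prev1), (2, prev2)):
                if prev is not None and t.probe in prev:
                    violations.append(
                        (i, f"non-recent negative probe in target set {lag} back")
                    )
        else:
            violations.append((i, f"unknown condition {t.condition!r}"))
    return ViolationReport(
        n_trials=len(trials), condition_counts=counts, violations=violations
    )


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

#: Group-level DDM parameter estimates (means and standard errors) for the
#: best-fitting model: drift per condition, boundary separation, nondecision
#: time.  Used as the centers of the synthetic cohorts.
GROUP_ESTIMATES: dict[str, dict] = {
    "young": {
        "n": 25,
        "v": {"positive": 0.366, "nonrecent_negative": 0.290, "recent_negative": 0.230},
        "v_se": {"positive": 0.025, "nonrecent_negative": 0.017, "recent_negative": 0.014},
        "a": 0.176,
        "a_se": 0.010,
        "ter": 0.304,
        "ter_se": 0.011,
    },
    "older": {
        "n": 38,
        "v": {"positive": 0.304, "nonrecent_negative": 0.255, "recent_negative": 0.196},
        "v_se": {"positive": 0.020, "nonrecent_negative": 0.014, "recent_negative": 0.011},
        "a": 0.229,
        "a_se": 0.007,
        "ter": 0.455,
        "ter_se": 0.023,
    },
}

#: Lower truncation bounds used when sampling participant parameters.
PARAM_BOUNDS = {"v": 0.02, "a": 0.06, "ter": 0.10}


@dataclass
class GroupSpec:
    """One age group: mean parameters and between-subject SDs."""

    label: str
    n_participants: int
    means: dict
    sds: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_participants <= 0:
            raise ValueError(f"group {self.label!r}: n_participants must be positive")
        for key, val in self.sds.items():
            vals = val.values() if isinstance(val, Mapping) else [val]
            if any(x < 0 for x in vals):
                raise ValueError(f"group {self.label!r}: SD for {key} must be >= 0")


@dataclass
class CohortSpec:
    groups: list[GroupSpec]
    seed: int = 0


@dataclass
class Participant:
    participant_id: str
    group: str
    params: DDMParameterSet


def group_spec_from_estimates(
    label: str,
    estimates: Mapping | None = None,
    n_participants: int | None = None,
    sd_from_se: bool = True,
) -> GroupSpec:
    """Build a :class:`GroupSpec` centered on the published group estimates.

    Between-subject SDs default to SE·sqrt(n) of the printed standard errors
    (``sd_from_se=True``); the unprinted variabilities start at the package
    defaults (eta=0.10, sz=0.02 evidence units, st=0.10 s) with zero SD.
    """
    est = estimates or GROUP_ESTIMATES[label]
    n = n_participants if n_participants is not None else est["n"]
    means = {
        "v": dict(est["v"]),
        "eta": DEFAULT_ETA,
        "a": est["a"],
        "sz": DEFAULT_SZ,
        "ter": est["ter"],
        "st": DEFAULT_ST,
    }
    if sd_from_se:
        root_n = math.sqrt(est["n"])
        sds = {
            "v": {c: est["v_se"][c] * root_n for c in CONDITIONS},
            "a": est["a_se"] * root_n,
            "ter": est["ter_se"] * root_n,
        }
    else:
        sds = {}
    return GroupSpec(label=label, n_participants=n, means=means, sds=sds)


def default_cohort_spec(seed: int = 0) -> CohortSpec:
    """The default synthetic cohort: 25 young and 38 older adults."""
    return CohortSpec(
        groups=[group_spec_from_estimates("young"), group_spec_from_estimates("older")],
        seed=seed,
    )


def _sample_value(rng, mean, sd, lo, hi, max_tries: int = 1000) -> float:
    if sd == 0:
        if not (lo <= mean <= hi):
            raise ValueError(f"mean {mean} outside bounds [{lo}, {hi}]")
        return float(mean)
    for _ in range(max_tries):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)
    return float(min(max(mean, lo), hi))


def _get(mapping: Mapping, key: str, cond: str, default: float) -> float:
    val = mapping.get(key, default)
    if isinstance(val, Mapping):
        return float(val.get(cond, default))
    return float(val)


def sample_cohort(spec: CohortSpec) -> dict[str, Participant]:
    """Draw participant-level parameter sets, truncated at parameter bounds.

    Deterministic given ``spec.seed``.  Means or SDs that violate parameter
    bounds raise before any sampling.
    """
    for g in spec.groups:
        for c in CONDITIONS:
            if _get(g.means, "v", c, 0.0) < PARAM_BOUNDS["v"]:
                raise ValueError(f"group {g.label!r}: mean drift below bound in {c}")
        for key in ("a", "ter"):
            if _get(g.means, key, CONDITIONS[0], 0.0) < PARAM_BOUNDS[key]:
                raise ValueError(f"group {g.label!r}: mean {key} below bound")
    rng = np.random.default_rng(spec.seed)
    cohort: dict[str, Participant] = {}
    for g in spec.groups:
        for i in range(g.n_participants):
            pid = f"{g.label}_{i + 1:03d}"
            v = {
                c: _sample_value(
                    rng,
                    _get(g.means, "v", c, 0.25),
                    _get(g.sds, "v", c, 0.0),
                    PARAM_BOUNDS["v"],
                    np.inf,
                )
                for c in CONDITIONS
            }
            eta = {
                c: _sample_value(
                    rng, _get(g.means, "eta", c, DEFAULT_ETA), _get(g.sds, "eta", c, 0.0), 0.0, 0.5
                )
                for c in CONDITIONS
            }
            a = _sample_value(
                rng, _get(g.means, "a", "", 0.15), _get(g.sds, "a", "", 0.0),
                PARAM_BOUNDS["a"], np.inf,
            )
            ter = _sample_value(
                rng, _get(g.means, "ter", "", 0.3), _get(g.sds, "ter", "", 0.0),
                PARAM_BOUNDS["ter"], np.inf,
            )
            sz = _sample_value(
                rng, _get(g.means, "sz", "", DEFAULT_SZ), _get(g.sds, "sz", "", 0.0),
                0.0, 0.9 * a,
            )
            st = _sample_value(
                rng, _get(g.means, "st", "", DEFAULT_ST), _get(g.sds, "st", "", 0.0),
                0.0, 2.0 * ter,
            )
            cohort[pid] = Participant(
                pid,
                g.label,
                DDMParameterSet(v=v, eta=eta, a=a, sz=sz, ter=ter, st=st),
            )
    return cohort


# ---------------------------------------------------------------------------
# dataset synthesis
# ---------------------------------------------------------------------------


def synthesize_dataset(
    cohort: Mapping[str, Participant],
    design: SessionDesign | None = None,
    seed: int = 0,
    sim_options: SimOptions | None = None,
) -> pd.DataFrame:
    """Simulate a full behavioral table: one record per trial per participant.

    Each participant gets an independent trial sequence and noise stream
    derived from ``seed`` and their position in the cohort, so any one
    participant's data do not depend on who else is in the cohort.
    """
    design = design or SessionDesign()
    base_options = sim_options or SimOptions()
    frames = []
    for idx, (pid, participant) in enumerate(cohort.items()):
        ss = np.random.SeedSequence([int(seed), idx])
        session_seed, sim_seed = [int(s) for s in ss.generate_state(2) % (2**31 - 1)]
        trials = generate_session(design, session_seed)
        opts = SimOptions(dt=base_options.dt, max_t=base_options.max_t, seed=sim_seed)
        df = simulate_dataset(participant.params, trials, opts)
        df.insert(0, "participant_id", pid)
        df.insert(1, "group", participant.group)
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    return out[BEHAVIOR_COLUMNS]


def write_behavior_csv(df: pd.DataFrame, path) -> None:
    df[BEHAVIOR_COLUMNS].to_csv(path, index=False)


def read_behavior_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(BEHAVIOR_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"behavioral CSV missing columns: {sorted(missing)}")
    return df
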