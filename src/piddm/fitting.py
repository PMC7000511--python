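"""Per-participant maximum-likelihood estimation of the six DDM variants.

Fitting happens in three layers:

1. ``pack_parameters`` / ``unpack_parameters`` map between a full
   :class:`~piddm.params.DDMParameterSet` and the minimal free-parameter
   vector implied by a :class:`~piddm.models.ModelSpec`.
2. The free vector is mapped to an unconstrained space for the optimizer
   (log for positive scales, scaled logistic for the bounded variabilities
   and the relative starting point), so no proposal can violate the
   parameter invariants: z stays strictly inside (0, a), the starting-point
   range inside the boundaries, and st <= 2*ter.
3. Nelder–Mead simplex search (the optimizer used for this analysis) from a
   moment-based start (EZ-style closed forms mapping accuracy and RT moments
   to v, a, ter), with jittered restarts because the simplex is a local
   search in 10–19 dimensions.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, logit

from . import wfpt
from .models import ModelSpec, get_model
from .params import (
    CONDITIONS,
    DEFAULT_ETA,
    DEFAULT_ST,
    DEFAULT_SZ,
    DIFFUSION_CONSTANT,
    NEGATIVE_CONDITIONS,
    DDMParameterSet,
)
from .selection import bic

#: RT cutoffs (seconds) applied before fitting.
RT_CUTOFF_LOW: float = 0.200
RT_CUTOFF_HIGH: float = 7.000

#: Upper bound on the intertrial drift SD (weakly identified; bounding
#: prevents boundary drift during optimization).
ETA_MAX: float = 0.5

#: The starting-point range may span at most this fraction of the distance
#: from z to the nearer boundary (times two).
SZ_FRACTION: float = 0.9

_TINY = 1e-9


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------


def apply_rt_cutoffs(
    data: pd.DataFrame,
    low_s: float = RT_CUTOFF_LOW,
    high_s: float = RT_CUTOFF_HIGH,
) -> tuple[pd.DataFrame, float]:
    """Drop trials with RTs outside [low_s, high_s]; report the excluded fraction.

    Raises if any participant present in the input loses all trials.
    """
    if len(data) == 0:
        raise ValueError("empty behavioral table")
    keep = (data["rt_s"] >= low_s) & (data["rt_s"] <= high_s)
    excluded = 1.0 - keep.mean()
    out = data.loc[keep].reset_index(drop=True)
    if "participant_id" in data.columns:
        lost = set(data["participant_id"].unique()) - set(out["participant_id"].unique())
        if lost:
            raise ValueError(
                f"RT cutoffs removed every trial for participant(s): {sorted(lost)}"
            )
    elif len(out) == 0:
        raise ValueError("RT cutoffs removed every trial")
    return out, float(excluded)


# ---------------------------------------------------------------------------
# packing / unpacking
# ---------------------------------------------------------------------------


def _n_slots(by_condition: bool) -> int:
    return len(CONDITIONS) if by_condition else 1


def pack_parameters(spec: ModelSpec, params: DDMParameterSet) -> np.ndarray:
    """Flatten a parameter set to the model's free vector (natural scale).

    Order: v per condition, eta per condition, a, sz, ter, st (each one slot
    or three depending on the model), then z for the biased models.
    """
    out = [params.v[c] for c in CONDITIONS]
    out += [params.eta[c] for c in CONDITIONS]
    for name, by_cond in (
        ("a", spec.a_by_condition),
        ("sz", spec.a_by_condition),
        ("ter", spec.ter_by_condition),
        ("st", spec.ter_by_condition),
    ):
        vals = getattr(params, name)
        if by_cond:
            out += [vals[c] for c in CONDITIONS]
        else:
            out.append(vals[CONDITIONS[0]])
    if spec.bias == "estimated":
        out.append(params.z[CONDITIONS[0]])
    vec = np.array(out, dtype=float)
    assert vec.size == spec.n_free_parameters
    return vec


def unpack_parameters(spec: ModelSpec, vector: Sequence[float]) -> DDMParameterSet:
    """Inverse of :func:`pack_parameters`."""
    vec = np.asarray(vector, dtype=float)
    if vec.size != spec.n_free_parameters:
        raise ValueError(
            f"model {spec.id} expects {spec.n_free_parameters} parameters, got {vec.size}"
        )
    pos = 0

    def take(k: int) -> np.ndarray:
        nonlocal pos
        out = vec[pos : pos + k]
        pos += k
        return out

    v = dict(zip(CONDITIONS, take(3)))
    eta = dict(zip(CONDITIONS, take(3)))
    fields: dict[str, dict] = {}
    for name, by_cond in (
        ("a", spec.a_by_condition),
        ("sz", spec.a_by_condition),
        ("ter", spec.ter_by_condition),
        ("st", spec.ter_by_condition),
    ):
        vals = take(_n_slots(by_cond))
        fields[name] = (
            dict(zip(CONDITIONS, vals))
            if by_cond
            else {c: float(vals[0]) for c in CONDITIONS}
        )
    if spec.bias == "estimated":
        zval = float(take(1)[0])
        z = {c: zval for c in CONDITIONS}
    else:
        z = {c: fields["a"][c] / 2.0 for c in CONDITIONS}
    return DDMParameterSet(
        v=v, eta=eta, a=fields["a"], z=z, sz=fields["sz"], ter=fields["ter"], st=fields["st"]
    )


# ---------------------------------------------------------------------------
# unconstrained transform
# ---------------------------------------------------------------------------


def to_unconstrained(spec: ModelSpec, vector: Sequence[float]) -> np.ndarray:
    """Map a natural-scale free vector to the optimizer's unconstrained space."""
    p = unpack_parameters(spec, vector)  # validates invariants
    x = [p.v[c] for c in CONDITIONS]
    x += [
        logit(np.clip(p.eta[c] / ETA_MAX, _TINY, 1 - _TINY)) for c in CONDITIONS
    ]
    a_slots = CONDITIONS if spec.a_by_condition else CONDITIONS[:1]
    t_slots = CONDITIONS if spec.ter_by_condition else CONDITIONS[:1]
    x += [math.log(p.a[c]) for c in a_slots]
    for c in a_slots:
        cap = SZ_FRACTION * 2.0 * min(p.z[c], p.a[c] - p.z[c])
        x.append(logit(np.clip(p.sz[c] / cap, _TINY, 1 - _TINY)))
    x += [math.log(p.ter[c]) for c in t_slots]
    x += [
        logit(np.clip(p.st[c] / (2.0 * p.ter[c]), _TINY, 1 - _TINY)) for c in t_slots
    ]
    if spec.bias == "estimated":
        a_min = min(p.a[c] for c in CONDITIONS)
        x.append(logit(np.clip(p.z[CONDITIONS[0]] / a_min, _TINY, 1 - _TINY)))
    return np.array(x, dtype=float)


def from_unconstrained(spec: ModelSpec, x: Sequence[float]) -> DDMParameterSet:
    """Inverse of :func:`to_unconstrained`; always yields a valid parameter set."""
    x = np.asarray(x, dtype=float)
    if x.size != spec.n_free_parameters:
        raise ValueError("transformed vector has wrong length")
    pos = 0

    def take(k: int) -> np.ndarray:
        nonlocal pos
        out = x[pos : pos + k]
        pos += k
        return out

    v = dict(zip(CONDITIONS, take(3)))
    eta = {c: ETA_MAX * expit(val) for c, val in zip(CONDITIONS, take(3))}
    na, nt = _n_slots(spec.a_by_condition), _n_slots(spec.ter_by_condition)
    a_raw = np.exp(take(na))
    sz_raw = expit(take(na))
    ter_raw = np.exp(take(nt))
    st_raw = expit(take(nt))
    a = dict(zip(CONDITIONS, a_raw)) if na == 3 else {c: float(a_raw[0]) for c in CONDITIONS}
    ter = dict(zip(CONDITIONS, ter_raw)) if nt == 3 else {c: float(ter_raw[0]) for c in CONDITIONS}
    st = {
        c: 2.0 * ter[c] * (st_raw[i] if nt == 3 else st_raw[0])
        for i, c in enumerate(CONDITIONS)
    }
    if spec.bias == "estimated":
        z_frac = expit(x[-1])
        a_min = min(a.values())
        z = {c: z_frac * a_min for c in CONDITIONS}
    else:
        z = {c: a[c] / 2.0 for c in CONDITIONS}
    sz = {
        c: SZ_FRACTION
        * 2.0
        * min(z[c], a[c] - z[c])
        * (sz_raw[i] if na == 3 else sz_raw[0])
        for i, c in enumerate(CONDITIONS)
    }
    return DDMParameterSet(v=v, eta=eta, a=a, z=z, sz=sz, ter=ter, st=st)


# ---------------------------------------------------------------------------
# initialization
# ---------------------------------------------------------------------------


def _ez_moments(acc: float, mrt: float, vrt: float, n: int, s: float):
    """Closed-form moment estimates of (v, a, ter) from accuracy and RT moments."""
    edge = 1.0 / (2.0 * max(n, 2))
    acc = min(max(acc, 0.5 + edge), 1.0 - edge)
    vrt = max(vrt, 1e-4)
    y = math.log(acc / (1.0 - acc))
    x = y * (acc * acc * y - acc * y + acc - 0.5) / vrt
    v = s * x**0.25
    a = s * s * y / v
    ratio = v * a / (s * s)
    mdt = (a / (2.0 * v)) * (1.0 - math.exp(-ratio)) / (1.0 + math.exp(-ratio))
    return v, a, mrt - mdt


def initialize_parameters(data: pd.DataFrame, spec: ModelSpec) -> DDMParameterSet:
    """Moment-based starting values, always inside the parameter bounds.

    Per condition, accuracy and correct-RT mean/variance give EZ-style
    estimates of v, a and ter, which are then averaged where the model shares
    a parameter across conditions.  Variabilities start at the package
    defaults.  Warns when a condition has fewer than 40 trials.
    """
    v, a_c, ter_c = {}, {}, {}
    min_rt = float(data["rt_s"].min())
    for c in CONDITIONS:
        sub = data[data["condition"] == c]
        if len(sub) == 0:
            raise ValueError(f"no trials in condition {c!r}")
        if len(sub) < 40:
            warnings.warn(f"only {len(sub)} trials in condition {c!r}; fits may be unstable")
        acc = float(sub["accuracy"].mean())
        correct_rts = sub.loc[sub["accuracy"] == 1, "rt_s"]
        mrt = float(correct_rts.mean()) if len(correct_rts) else float(sub["rt_s"].mean())
        vrt = float(correct_rts.var(ddof=1)) if len(correct_rts) > 1 else 0.05
        vi, ai, ti = _ez_moments(acc, mrt, vrt, len(sub), DIFFUSION_CONSTANT)
        v[c] = float(np.clip(vi, 0.02, 1.0))
        a_c[c] = float(np.clip(ai, 0.08, 0.6))
        ter_c[c] = ti
    if not spec.a_by_condition:
        a_c = {c: float(np.mean(list(a_c.values()))) for c in CONDITIONS}
    st0 = DEFAULT_ST
    # keep the start of the nondecision-time support below the fastest trial
    ter_hi = min_rt - 0.01 + st0 / 2.0
    ter = {
        c: float(np.clip(t, st0 / 2.0 + 0.01, max(ter_hi, st0 / 2.0 + 0.02)))
        for c, t in ter_c.items()
    }
    if not spec.ter_by_condition:
        ter = {c: float(np.mean(list(ter.values()))) for c in CONDITIONS}
    z = {c: a_c[c] / 2.0 for c in CONDITIONS}
    sz = {c: min(DEFAULT_SZ, SZ_FRACTION * a_c[c] / 2.0) for c in CONDITIONS}
    return DDMParameterSet(
        v=v, eta=DEFAULT_ETA, a=a_c, z=z, sz=sz, ter=ter, st=st0
    )


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


@dataclass
class FitOptions:
    """Optimizer settings.

    Each restart runs a coarse-to-fine pair of simplex searches: a cheap
    exploration stage using ``n_nodes_coarse`` quadrature nodes, then a
    polishing stage at the full ``n_nodes`` resolution and ``tolerance``.
    """

    n_restarts: int = 5
    seed: int | None = None
    tolerance: float = 1e-6
    n_nodes: int = wfpt.N_QUAD
    n_nodes_coarse: int = 5
    n_nodes_search: int = 7
    jitter: float = 0.25
    maxiter_per_dim: int = 400
    max_polish_rounds: int = 3
    #: two consecutive polish rounds improving the log-likelihood by less
    #: than this count as converged (far below the ~0.5 change that one
    #: standard error in any parameter produces)
    stagnation_tol: float = 1e-4


@dataclass
class FitResult:
    participant_id: str
    model_id: int
    parameters: DDMParameterSet
    log_likelihood: float
    n_trials_used: int
    bic: float
    n_restarts: int
    converged: bool
    best_restart_seed: int

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in self.__dataclass_fields__}
        d["parameters"] = self.parameters.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "FitResult":
        d = dict(d)
        d["parameters"] = DDMParameterSet.from_dict(d["parameters"])
        return cls(**d)


class _TrialData:
    """Precomputed per-trial arrays so the likelihood kernel is called directly."""

    def __init__(self, data: pd.DataFrame, coding: str, n_nodes: int):
        self.rt = np.ascontiguousarray(data["rt_s"].to_numpy(dtype=float))
        self.cond = np.array(
            [CONDITIONS.index(c) for c in data["condition"]], dtype=np.int64
        )
        acc = data["accuracy"].to_numpy(dtype=np.int64)
        neg = np.array([c in NEGATIVE_CONDITIONS for c in data["condition"]])
        if coding == "accuracy":
            self.upper = acc == 1
            self.sign = np.ones(self.rt.size)
        else:
            self.upper = np.where(neg, acc == 0, acc == 1)
            self.sign = np.where(neg, -1.0, 1.0)
        self.upper = np.ascontiguousarray(self.upper.astype(np.bool_))
        self.sign = np.ascontiguousarray(self.sign)
        self.zn, self.zw = wfpt._gl_nodes(n_nodes, 1.0)
        self.tn, self.tw = wfpt._gl_nodes(n_nodes, 1.0)

    def loglik(self, params: DDMParameterSet) -> float:
        arr = params.arrays()
        return float(
            wfpt._loglik_kernel(
                self.rt, self.upper, self.cond, self.sign,
                arr["v"], arr["eta"], arr["a"], arr["z"], arr["sz"],
                arr["ter"], arr["st"], params.s,
                self.zn, self.zw, self.tn, self.tw,
                wfpt.EPS_SERIES, wfpt.DENSITY_FLOOR,
            )
        )


def fit_participant(
    data: pd.DataFrame,
    spec: ModelSpec | int,
    options: FitOptions | None = None,
) -> FitResult:
    """Maximum-likelihood fit of one model to one participant's filtered trials.

    Runs ``n_restarts`` Nelder–Mead searches (the first from the moment-based
    start, the rest jittered) and returns the best.  Deterministic given
    ``options.seed``.
    """
    if isinstance(spec, int):
        spec = get_model(spec)
    options = options or FitOptions()
    if "participant_id" in data.columns:
        pids = data["participant_id"].unique()
        if len(pids) > 1:
            raise ValueError("fit_participant expects a single participant's data")
        pid = str(pids[0])
    else:
        pid = "participant"
    n = len(data)
    final_data = _TrialData(data, spec.coding, options.n_nodes)
    coarse_data = _TrialData(data, spec.coding, options.n_nodes_coarse)
    search_data = _TrialData(data, spec.coding, options.n_nodes_search)
    init = initialize_parameters(data, spec)
    x0 = to_unconstrained(spec, pack_parameters(spec, init))
    dim = x0.size
    rng = np.random.default_rng(options.seed)

    def make_objective(trial_data: _TrialData):
        def objective(x: np.ndarray) -> float:
            try:
                params = from_unconstrained(spec, x)
            except (ValueError, OverflowError):
                return 1e12
            ll = trial_data.loglik(params)
            return -ll if np.isfinite(ll) else 1e12

        return objective

    obj_coarse = make_objective(coarse_data)
    obj_search = make_objective(search_data)
    nm_opts = {"adaptive": True}
    best_x = None
    best_f = np.inf
    best_restart = 0
    any_converged = False
    for r in range(max(1, options.n_restarts)):
        xstart = x0 if r == 0 else x0 + options.jitter * rng.standard_normal(dim)
        coarse = minimize(
            obj_coarse,
            xstart,
            method="Nelder-Mead",
            options={
                **nm_opts,
                "maxiter": options.maxiter_per_dim * dim,
                "xatol": 1e-2,
                "fatol": 1e-3,
            },
        )
        # polish rounds: fresh, shrinking simplexes around the incumbent
        # until the simplex collapses or the objective stagnates
        xcur, fprev, converged = coarse.x, np.inf, False
        for round_, step in zip(range(options.max_polish_rounds), (0.03, 0.01, 0.005)):
            simplex = np.vstack([xcur, xcur + step * np.eye(dim)])
            res = minimize(
                obj_search,
                xcur,
                method="Nelder-Mead",
                options={
                    **nm_opts,
                    "maxiter": 200 * dim,
                    "xatol": 1e-3,
                    "fatol": options.tolerance,
                    "initial_simplex": simplex,
                },
            )
            improved = fprev - res.fun
            xcur, fprev = res.x, res.fun
            if res.success or (round_ > 0 and improved < options.stagnation_tol):
                converged = True
                break
        any_converged = any_converged or converged
        if fprev < best_f:
            best_x, best_f = xcur, fprev
            best_restart = r
    params = from_unconstrained(spec, best_x)
    # final likelihood (and BIC) at the full quadrature resolution
    ll = final_data.loglik(params)
    return FitResult(
        participant_id=pid,
        model_id=spec.id,
        parameters=params,
        log_likelihood=ll,
        n_trials_used=n,
        bic=bic(ll, spec.n_free_parameters, n),
        n_restarts=max(1, options.n_restarts),
        converged=any_converged,
        best_restart_seed=best_restart,
    )


def fit_cohort(
    data: pd.DataFrame,
    model_ids: Sequence[int] = (1, 2, 3, 4, 5, 6),
    options: FitOptions | None = None,
) -> list[FitResult]:
    """Fit each requested model to each participant in a behavioral table."""
    options = options or FitOptions()
    fits = []
    for i, (pid, sub) in enumerate(data.groupby("participant_id", sort=True)):
        for mid in model_ids:
            opts = replace(
                options,
                seed=None if options.seed is None else int(options.seed) + 1000 * i + mid,
            )
            fits.append(fit_participant(sub.reset_index(drop=True), get_model(mid), opts))
    return fits


def save_fits(fits: Sequence[FitResult], path) -> None:
    with open(path, "w") as fh:
        json.dump([f.to_dict() for f in fits], fh, indent=1)


def load_fits(path) -> list[FitResult]:
    with open(path) as fh:
        return [FitResult.from_dict(d) for d in json.load(fh)]
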