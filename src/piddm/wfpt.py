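"""Wiener first-passage-time (WFPT) densities and the DDM likelihood.

The density of absorption at one boundary of a drift-diffusion process is a
*defective* density: it integrates to that boundary's choice probability.
Writing ``w = z/a`` for the relative start and rescaling evidence units by the
diffusion constant ``s`` (so ``v/s``, ``a/s`` enter the formulas), the
lower-boundary density is

    f_lower(t | v, a, w) = f0(t / a^2, w) / a^2 * exp(-v a w - v^2 t / 2)

where ``f0`` is the density for a unit-boundary, zero-drift process.  ``f0``
has two classical series representations — one converging quickly for small
normalized times, one for large — and we evaluate whichever needs fewer terms
for a truncation error below ``eps`` (default 1e-10).

Gaussian intertrial drift variability integrates analytically: with drift
Normal(v, eta) the exponential factor becomes

    exp( (eta^2 a^2 w^2 - 2 v a w - v^2 t) / (2 (1 + eta^2 t)) )
        / sqrt(1 + eta^2 t).

Uniform starting-point (range sz) and nondecision-time (range st) variability
are integrated by fixed-order Gauss–Legendre quadrature (11 nodes each by
default).  The upper-boundary density follows from reflection:
``f_upper(t | v, a, w) = f_lower(t | -v, a, 1 - w)``.

Scalar kernels are JIT-compiled with numba; the public functions accept
arrays and :class:`~piddm.params.DDMParameterSet` objects.
"""

from __future__ import annotations

import math
from typing import Iterable

import numpy as np
from numba import njit

from .models import ModelSpec
from .params import (
    CONDITIONS,
    NEGATIVE_CONDITIONS,
    QUANTILE_PROBS,
    DDMParameterSet,
    QuantileSummary,
)

#: Default series truncation tolerance.
EPS_SERIES: float = 1e-10

#: Default Gauss–Legendre order for the sz and st integrals.
N_QUAD: int = 11

#: Floor applied to per-trial densities inside the log-likelihood so that a
#: single outlying trial cannot drive the objective to -inf.
DENSITY_FLOOR: float = 1e-10


# ---------------------------------------------------------------------------
# scalar kernels
# ---------------------------------------------------------------------------


@njit(cache=True, fastmath=True)
def _f0(tau: float, w: float, eps: float) -> float:
    """Normalized (a=1, v=0) lower-boundary FPT density at scaled time tau."""
    if tau <= 0.0:
        return 0.0
    # number of terms needed by each expansion (Navarro & Fuss style bounds)
    if 2.0 * math.sqrt(2.0 * math.pi * tau) * eps < 1.0:
        ks = 2.0 + math.sqrt(-2.0 * tau * math.log(2.0 * eps * math.sqrt(2.0 * math.pi * tau)))
        if ks < math.sqrt(tau) + 1.0:
            ks = math.sqrt(tau) + 1.0
    else:
        ks = 2.0
    if math.pi * tau * eps < 1.0:
        kl = math.sqrt(-2.0 * math.log(math.pi * tau * eps) / (math.pi * math.pi * tau))
        if kl < 1.0 / (math.pi * math.sqrt(tau)):
            kl = 1.0 / (math.pi * math.sqrt(tau))
    else:
        kl = 1.0 / (math.pi * math.sqrt(tau))

    if ks < kl:  # small-time expansion
        K = int(math.ceil(ks))
        lo = -((K - 1) // 2)
        hi = (K - 1) // 2 + (K - 1) % 2
        p = 0.0
        for k in range(lo, hi + 1):
            arg = w + 2.0 * k
            p += arg * math.exp(-arg * arg / (2.0 * tau))
        return p / math.sqrt(2.0 * math.pi * tau * tau * tau)
    else:  # large-time expansion
        K = int(math.ceil(kl))
        p = 0.0
        for k in range(1, K + 1):
            p += k * math.exp(-k * k * math.pi * math.pi * tau / 2.0) * math.sin(
                k * math.pi * w
            )
        return p * math.pi


@njit(cache=True, fastmath=True)
def _flower(td: float, v: float, a: float, w: float, eta: float, eps: float) -> float:
    """Lower-boundary defective density at decision time td (unit diffusion)."""
    if td <= 0.0:
        return 0.0
    g = _f0(td / (a * a), w, eps)
    if g <= 0.0:
        return 0.0 if g == 0.0 else g
    if eta > 0.0:
        lam = 1.0 + eta * eta * td
        num = eta * eta * a * a * w * w - 2.0 * v * a * w - v * v * td
        fac = math.exp(num / (2.0 * lam)) / math.sqrt(lam)
    else:
        fac = math.exp(-v * a * w - 0.5 * v * v * td)
    return g * fac / (a * a)


@njit(cache=True, fastmath=True)
def _cell_density(
    t: float,
    upper: bool,
    v: float,
    eta: float,
    a: float,
    z: float,
    sz: float,
    ter: float,
    st: float,
    s: float,
    zn: np.ndarray,
    zw: np.ndarray,
    tn: np.ndarray,
    tw: np.ndarray,
    eps: float,
) -> float:
    """Full defective density at observed RT t for one boundary.

    zn/zw and tn/tw are Gauss–Legendre nodes and weights on [-1, 1] for the
    starting-point and nondecision-time integrals (weights sum to 2; the 0.5
    factors convert sums to uniform averages).
    """
    vs = v / s
    av = a / s
    zv = z / s
    szv = sz / s
    etas = eta / s
    acc = 0.0
    for i in range(tn.shape[0]):
        td = t - (ter + 0.5 * st * tn[i])
        if td <= 0.0:
            continue
        inner = 0.0
        for j in range(zn.shape[0]):
            w = (zv + 0.5 * szv * zn[j]) / av
            if upper:
                d = _flower(td, -vs, av, 1.0 - w, etas, eps)
            else:
                d = _flower(td, vs, av, w, etas, eps)
            inner += zw[j] * d
        acc += tw[i] * inner * 0.5
    return acc * 0.5


@njit(cache=True, fastmath=True)
def _loglik_kernel(
    rt: np.ndarray,
    upper: np.ndarray,
    cond: np.ndarray,
    sign: np.ndarray,
    v: np.ndarray,
    eta: np.ndarray,
    a: np.ndarray,
    z: np.ndarray,
    sz: np.ndarray,
    ter: np.ndarray,
    st: np.ndarray,
    s: float,
    zn: np.ndarray,
    zw: np.ndarray,
    tn: np.ndarray,
    tw: np.ndarray,
    eps: float,
    floor: float,
) -> float:
    total = 0.0
    for i in range(rt.shape[0]):
        c = cond[i]
        d = _cell_density(
            rt[i],
            upper[i],
            sign[i] * v[c],
            eta[c],
            a[c],
            z[c],
            sz[c],
            ter[c],
            st[c],
            s,
            zn,
            zw,
            tn,
            tw,
            eps,
        )
        if d < floor:
            d = floor
        total += math.log(d)
    return total


# ---------------------------------------------------------------------------
# quadrature node helpers
# ---------------------------------------------------------------------------


def _gl_nodes(order: int, width: float) -> tuple[np.ndarray, np.ndarray]:
    """Gauss–Legendre nodes/weights on [-1, 1]; a point mass if width == 0."""
    if width <= 0.0 or order <= 1:
        return np.zeros(1), np.full(1, 2.0)
    x, w = np.polynomial.legendre.leggauss(order)
    return x, w


# ---------------------------------------------------------------------------
# public densities
# ---------------------------------------------------------------------------


def _check_basic(v: float, a: float, z: float, s: float) -> None:
    if not (a > 0 and 0 < z < a and s > 0):
        raise ValueError(f"invalid DDM parameters: v={v}, a={a}, z={z}, s={s}")


def wfpt_density(t, boundary: str, v: float, a: float, z: float, s: float = 0.1):
    """Defective FPT density (1/s) at decision time ``t`` for one boundary.

    No intertrial variabilities; ``t`` is the decision time (nondecision time
    already removed).  ``boundary`` is ``"upper"`` or ``"lower"``; drift ``v``
    points toward the upper boundary.
    """
    if boundary not in ("upper", "lower"):
        raise ValueError(f"boundary must be 'upper' or 'lower', got {boundary!r}")
    _check_basic(v, a, z, s)
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr <= 0):
        raise ValueError("decision times must be positive")
    vs, av, w = v / s, a / s, z / a
    out = np.empty(t_arr.shape, dtype=float)
    flat = t_arr.ravel()
    res = out.ravel()
    for i, td in enumerate(flat):
        if boundary == "upper":
            res[i] = _flower(td, -vs, av, 1.0 - w, 0.0, EPS_SERIES)
        else:
            res[i] = _flower(td, vs, av, w, 0.0, EPS_SERIES)
    return out if t_arr.shape else float(res[0])


def _boundary_and_sign(response: str, condition: str, coding: str) -> tuple[bool, float]:
    """Map (response in {correct,error}, condition, coding) to (upper?, drift sign).

    Accuracy coding: the upper boundary is the correct response and drift +v
    points toward it.  Stimulus coding: the upper boundary is the "positive"
    response; on negative-probe trials the (correct-pointing) drift is -v in
    this frame and the correct response is the lower boundary.
    """
    if response not in ("correct", "error"):
        raise ValueError(f"response must be 'correct' or 'error', got {response!r}")
    if coding == "accuracy" or condition not in NEGATIVE_CONDITIONS:
        return (response == "correct", 1.0)
    if coding == "stimulus":
        return (response == "error", -1.0)
    raise ValueError(f"coding must be 'accuracy' or 'stimulus', got {coding!r}")


def full_density(
    t,
    response: str,
    params: DDMParameterSet,
    condition: str,
    coding: str = "accuracy",
    n_nodes: int = N_QUAD,
):
    """Defective density of the observed RT ``t`` (seconds) for one response.

    Integrates Gaussian drift variability analytically and uniform
    starting-point / nondecision-time variability by Gauss–Legendre
    quadrature.  Reduces exactly to :func:`wfpt_density` at ``t - ter`` when
    all variabilities are zero.
    """
    p = params.for_condition(condition)
    upper, sign = _boundary_and_sign(response, condition, coding)
    zn, zw = _gl_nodes(n_nodes, p["sz"])
    tn, tw = _gl_nodes(n_nodes, p["st"])
    t_arr = np.asarray(t, dtype=float)
    out = np.empty(t_arr.shape, dtype=float)
    flat, res = t_arr.ravel(), out.ravel()
    for i, ti in enumerate(flat):
        res[i] = _cell_density(
            ti,
            upper,
            sign * p["v"],
            p["eta"],
            p["a"],
            p["z"],
            p["sz"],
            p["ter"],
            p["st"],
            p["s"],
            zn,
            zw,
            tn,
            tw,
            EPS_SERIES,
        )
    return out if t_arr.shape else float(res[0])


# ---------------------------------------------------------------------------
# choice probabilities
# ---------------------------------------------------------------------------


def prob_upper(v: float, a: float, z: float, s: float = 0.1) -> float:
    """Closed-form probability of absorption at the upper boundary.

    ``(1 - exp(-2 v z / s^2)) / (1 - exp(-2 v a / s^2))``, evaluated stably;
    equals ``z / a`` at zero drift.
    """
    _check_basic(v, a, z, s)
    x = 2.0 * v / (s * s)
    if abs(x) * a < 1e-12:
        return z / a
    if v < 0:  # reflect for numerical stability
        return 1.0 - prob_upper(-v, a, a - z, s)
    return math.expm1(-x * z) / math.expm1(-x * a)


def choice_probability(
    params: DDMParameterSet,
    condition: str,
    coding: str = "accuracy",
    n_nodes: int = N_QUAD,
    n_hermite: int = 41,
) -> float:
    """P(correct) under the full model (drift and start variability matter;
    nondecision variability does not affect which boundary is reached)."""
    p = params.for_condition(condition)
    upper, sign = _boundary_and_sign("correct", condition, coding)
    zn, zw = _gl_nodes(n_nodes, p["sz"])
    if p["eta"] > 0:
        hx, hw = np.polynomial.hermite_e.hermegauss(n_hermite)
        drifts = sign * p["v"] + p["eta"] * hx
        dw = hw / math.sqrt(2.0 * math.pi)
    else:
        drifts = np.array([sign * p["v"]])
        dw = np.array([1.0])
    total = 0.0
    for mu, wmu in zip(drifts, dw):
        for xj, wj in zip(zn, zw):
            zj = p["z"] + 0.5 * p["sz"] * xj
            pu = prob_upper(mu, p["a"], zj, p["s"])
            total += wmu * (wj / 2.0) * (pu if upper else 1.0 - pu)
    return float(total)


# ---------------------------------------------------------------------------
# predicted quantiles
# ---------------------------------------------------------------------------


def _defective_cdf_grid(
    params: DDMParameterSet,
    condition: str,
    response: str,
    coding: str,
    t_max: float = 12.0,
    n_grid: int = 4000,
) -> tuple[np.ndarray, np.ndarray]:
    p = params.for_condition(condition)
    t0 = max(p["ter"] - p["st"] / 2.0, 0.0)
    t = np.linspace(t0, t0 + t_max, n_grid)
    dens = full_density(t, response, params, condition, coding=coding)
    cdf = np.concatenate([[0.0], np.cumsum((dens[1:] + dens[:-1]) / 2.0 * np.diff(t))])
    return t, cdf


def predicted_quantiles(
    params: DDMParameterSet,
    condition: str,
    coding: str = "accuracy",
    probs: Iterable[float] = QUANTILE_PROBS,
    min_probability: float = 1e-3,
) -> QuantileSummary:
    """Model-predicted response proportions and RT quantiles for a condition.

    Quantiles invert the defective CDF per response (the q-quantile of the
    correct-RT distribution solves ``CDF(t) = q * P(correct)``).  Responses
    with probability below ``min_probability`` are flagged unreliable and
    given NaN quantiles rather than fabricated values.
    """
    probs = tuple(probs)
    summary = QuantileSummary(probs=probs)
    for response in ("correct", "error"):
        t, cdf = _defective_cdf_grid(params, condition, response, coding)
        p_resp = float(cdf[-1])
        summary.proportion[(condition, response)] = p_resp
        if p_resp < min_probability:
            summary.quantiles[(condition, response)] = np.full(len(probs), np.nan)
            summary.unreliable.add((condition, response))
            continue
        targets = np.asarray(probs) * p_resp
        # cdf is nondecreasing; interpolate t as a function of mass
        summary.quantiles[(condition, response)] = np.interp(targets, cdf, t)
    # renormalize tiny numerical-integration defect
    total = sum(summary.proportion[(condition, r)] for r in ("correct", "error"))
    if total > 0:
        for r in ("correct", "error"):
            summary.proportion[(condition, r)] /= total
    summary.check()
    return summary


# ---------------------------------------------------------------------------
# log-likelihood
# ---------------------------------------------------------------------------


def log_likelihood(
    data,
    params: DDMParameterSet,
    spec: ModelSpec | str = "accuracy",
    n_nodes: int = N_QUAD,
    floor: float = DENSITY_FLOOR,
) -> float:
    """Joint log-likelihood of a participant's trials.

    ``data`` is a behavioral table with columns ``condition``, ``rt_s`` and
    ``accuracy`` (``response`` is required for stimulus coding).  ``spec`` may
    be a :class:`ModelSpec` (its boundary coding is used) or the coding string
    itself.  Densities below ``floor`` are floored so that single outlier
    trials keep the objective finite.
    """
    coding = spec if isinstance(spec, str) else spec.coding
    if coding not in ("accuracy", "stimulus"):
        raise ValueError(f"unknown coding {coding!r}")
    rt = np.ascontiguousarray(data["rt_s"].to_numpy(dtype=float))
    if rt.size == 0:
        raise ValueError("empty dataset")
    cond_idx = np.array(
        [CONDITIONS.index(c) for c in data["condition"]], dtype=np.int64
    )
    acc = data["accuracy"].to_numpy(dtype=np.int64)
    neg = np.array([c in NEGATIVE_CONDITIONS for c in data["condition"]])
    if coding == "accuracy":
        upper = acc == 1
        sign = np.ones(rt.size)
    else:
        upper = np.where(neg, acc == 0, acc == 1)
        sign = np.where(neg, -1.0, 1.0)
    arr = params.arrays()
    zn, zw = _gl_nodes(n_nodes, float(np.max(arr["sz"])))
    tn, tw = _gl_nodes(n_nodes, float(np.max(arr["st"])))
    return float(
        _loglik_kernel(
            rt,
            upper.astype(np.bool_),
            cond_idx,
            np.ascontiguousarray(sign),
            arr["v"],
            arr["eta"],
            arr["a"],
            arr["z"],
            arr["sz"],
            arr["ter"],
            arr["st"],
            params.s,
            zn,
            zw,
            tn,
            tw,
            EPS_SERIES,
            floor,
        )
    )
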