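"""Group-level inferential statistics on behavior and fitted parameters.

The analysis compares young and older adults with a mixed-design ANOVA
(condition as the within-subject factor, age group between subjects) run
separately on error rates, correct-trial mean RTs, and fitted drift rates;
planned comparisons target the proactive-interference (PI) effect — the
recent-negative minus non-recent-negative difference — and its interaction
with age; boundary separation and nondecision time are compared with
pooled-variance independent-samples t-tests (df = n1 + n2 - 2).

The classical (uncorrected) degrees of freedom are reported by default;
Greenhouse–Geisser epsilon is returned alongside for reference.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

PI_MINUEND = "recent_negative"
PI_SUBTRAHEND = "nonrecent_negative"


@dataclass
class ContrastResult:
    """A planned single-df comparison (simple effect or difference of differences)."""

    label: str
    estimate: float
    t: float
    F: float
    df: tuple
    p: float


@dataclass
class TTestResult:
    t: float
    df: int
    p: float
    mean_difference: float


# ---------------------------------------------------------------------------
# behavioral summaries
# ---------------------------------------------------------------------------


def summarize_behavior(data: pd.DataFrame) -> pd.DataFrame:
    """Per participant x condition: mean correct RT (s) and error rate (%).

    Expects RT cutoffs to have been applied.  Cells with zero correct trials
    get NaN mean RT and are logged rather than silently dropped.
    """
    rows = []
    for (pid, cond), sub in data.groupby(["participant_id", "condition"], sort=True):
        correct = sub[sub["accuracy"] == 1]
        if len(correct) == 0:
            logger.warning("participant %s, condition %s: no correct trials", pid, cond)
            mean_rt = np.nan
        else:
            mean_rt = float(correct["rt_s"].mean())
        rows.append(
            {
                "participant_id": pid,
                "group": sub["group"].iloc[0] if "group" in sub else "all",
                "condition": cond,
                "mean_correct_rt_s": mean_rt,
                "error_rate_pct": 100.0 * (1.0 - float(sub["accuracy"].mean())),
                "n_trials": len(sub),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# mixed ANOVA
# ---------------------------------------------------------------------------


def mixed_anova(
    data: pd.DataFrame,
    dv: str,
    subject: str = "participant_id",
    within: str = "condition",
    between: str = "group",
) -> pd.DataFrame:
    """Classical mixed-design ANOVA (one within, one between factor).

    Returns a table with one row per effect (between, within, interaction):
    F, numerator/denominator df, uncorrected p, partial eta squared, and
    Greenhouse–Geisser epsilon for the within effects.  Participants with
    incomplete cells are dropped listwise (logged).
    """
    import pingouin as pg  # deferred: heavy import

    wide = data.pivot_table(index=subject, columns=within, values=dv, aggfunc="mean")
    complete = wide.dropna().index
    dropped = set(wide.index) - set(complete)
    if dropped:
        logger.warning("listwise deletion of %d participant(s): %s", len(dropped), sorted(dropped))
    use = data[data[subject].isin(complete)]
    n_per_group = use.groupby(between)[subject].nunique()
    if (n_per_group < 2).any():
        raise ValueError(f"need >= 2 participants per group, got {n_per_group.to_dict()}")
    table = pg.mixed_anova(
        data=use, dv=dv, within=within, subject=subject, between=between, effsize="np2"
    )
    out = table.rename(
        columns={"Source": "effect", "DF1": "df1", "DF2": "df2", "p_unc": "p", "p-unc": "p"}
    )[["effect", "F", "df1", "df2", "p", "np2"] + (["eps"] if "eps" in table else [])]
    out["effect"] = out["effect"].replace({between: "group", within: "condition", "Interaction": "condition * group"})
    return out


# ---------------------------------------------------------------------------
# planned PI contrasts
# ---------------------------------------------------------------------------


def pi_differences(
    data: pd.DataFrame,
    dv: str,
    subject: str = "participant_id",
    within: str = "condition",
    between: str = "group",
) -> pd.DataFrame:
    """Per-participant PI effect: dv(recent negative) - dv(non-recent negative)."""
    wide = data.pivot_table(index=[subject, between], columns=within, values=dv, aggfunc="mean")
    for cond in (PI_MINUEND, PI_SUBTRAHEND):
        if cond not in wide.columns:
            raise ValueError(f"condition {cond!r} missing from data")
    out = wide.reset_index()
    out["pi"] = out[PI_MINUEND] - out[PI_SUBTRAHEND]
    return out[[subject, between, "pi"]].dropna()


def planned_pi_contrast(
    data: pd.DataFrame,
    dv: str,
    subject: str = "participant_id",
    within: str = "condition",
    between: str = "group",
) -> dict[str, ContrastResult]:
    """The PI effect and the PI x Age interaction as planned comparisons.

    The PI effect is a one-sample t-test of the per-participant differences
    against zero; the interaction is a pooled two-sample t-test of those
    differences between groups (reported also as F = t^2 with 1 numerator df,
    matching the single-df planned-contrast form).
    """
    diffs = pi_differences(data, dv, subject, within, between)
    pi = diffs["pi"].to_numpy(dtype=float)
    n = pi.size
    t_pi, p_pi = sps.ttest_1samp(pi, 0.0)
    results = {
        "pi_effect": ContrastResult(
            label=f"PI effect on {dv}",
            estimate=float(pi.mean()),
            t=float(t_pi),
            F=float(t_pi**2),
            df=(1, n - 1),
            p=float(p_pi),
        )
    }
    groups = diffs[between].unique()
    if len(groups) == 2:
        g1 = diffs.loc[diffs[between] == groups[0], "pi"].to_numpy(dtype=float)
        g2 = diffs.loc[diffs[between] == groups[1], "pi"].to_numpy(dtype=float)
        t_int, p_int = sps.ttest_ind(g1, g2, equal_var=True)
        results["pi_by_age"] = ContrastResult(
            label=f"PI x age interaction on {dv}",
            estimate=float(g1.mean() - g2.mean()),
            t=float(t_int),
            F=float(t_int**2),
            df=(1, g1.size + g2.size - 2),
            p=float(p_int),
        )
    return results


# ---------------------------------------------------------------------------
# independent-samples t-test
# ---------------------------------------------------------------------------


def independent_t(values, groups) -> TTestResult:
    """Pooled-variance two-sample t-test, df = n1 + n2 - 2."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    if len(labels) != 2:
        raise ValueError(f"need exactly two groups, got {list(labels)}")
    g1, g2 = (values[groups == lab] for lab in labels)
    if len(g1) < 2 or len(g2) < 2:
        raise ValueError("need at least two observations per group")
    pooled = ((len(g1) - 1) * g1.var(ddof=1) + (len(g2) - 1) * g2.var(ddof=1)) / (
        len(g1) + len(g2) - 2
    )
    if pooled == 0:
        raise ValueError("zero pooled variance")
    se = math.sqrt(pooled * (1.0 / len(g1) + 1.0 / len(g2)))
    t = (g1.mean() - g2.mean()) / se
    df = len(g1) + len(g2) - 2
    p = 2.0 * sps.t.sf(abs(t), df)
    return TTestResult(t=float(t), df=int(df), p=float(p), mean_difference=float(g1.mean() - g2.mean()))
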