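"""Quantile-probability summaries and plots.

A quantile-probability plot shows, per condition and response (correct /
error), the response proportion on the x-axis against five RT quantiles
(0.1, 0.3, 0.5, 0.7, 0.9) on the y-axis.  Comparing observed (crosses) with
model-predicted (circles) points summarizes how well a fitted model captures
both accuracy and the full RT distributions at once.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import matplotlib

matplotlib.use("Agg", force=False)
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .params import CONDITIONS, QUANTILE_PROBS, DDMParameterSet, QuantileSummary
from .wfpt import predicted_quantiles

#: Cells with fewer RTs than this are flagged unreliable.
MIN_CELL_TRIALS: int = 5


def observed_quantiles(
    data: pd.DataFrame,
    probs: Sequence[float] = QUANTILE_PROBS,
) -> QuantileSummary:
    """Empirical response proportions and RT quantiles per condition x response.

    Quantiles use linear interpolation (the type-7 convention).  Cells with
    fewer than :data:`MIN_CELL_TRIALS` RTs — error cells are often sparse —
    are flagged unreliable and given NaN quantiles, never fabricated values.
    """
    probs = tuple(probs)
    summary = QuantileSummary(probs=probs)
    for condition in CONDITIONS:
        sub = data[data["condition"] == condition]
        if len(sub) == 0:
            continue
        for response, mask in (
            ("correct", sub["accuracy"] == 1),
            ("error", sub["accuracy"] == 0),
        ):
            rts = sub.loc[mask, "rt_s"].to_numpy(dtype=float)
            summary.proportion[(condition, response)] = len(rts) / len(sub)
            if len(rts) < MIN_CELL_TRIALS:
                summary.quantiles[(condition, response)] = np.full(len(probs), np.nan)
                summary.unreliable.add((condition, response))
            else:
                summary.quantiles[(condition, response)] = np.quantile(
                    rts, probs, method="linear"
                )
    summary.check()
    return summary


def average_summaries(summaries: Iterable[QuantileSummary]) -> QuantileSummary:
    """Average proportions and quantiles over participants (NaN-aware).

    This is the participant-averaged display convention: quantiles are
    predicted (or observed) per participant and then averaged, cell by cell.
    """
    summaries = list(summaries)
    if not summaries:
        raise ValueError("no summaries to average")
    probs = summaries[0].probs
    out = QuantileSummary(probs=probs)
    keys = sorted({k for s in summaries for k in s.proportion}, key=str)
    for key in keys:
        props = [s.proportion[key] for s in summaries if key in s.proportion]
        out.proportion[key] = float(np.mean(props))
        qs = np.array(
            [s.quantiles[key] for s in summaries if key in s.quantiles], dtype=float
        )
        good = ~np.isnan(qs).any(axis=1)
        if good.any():
            out.quantiles[key] = qs[good].mean(axis=0)
        else:
            out.quantiles[key] = np.full(len(probs), np.nan)
            out.unreliable.add(key)
    return out


def predicted_summary_for_participant(
    params: DDMParameterSet, coding: str = "accuracy"
) -> QuantileSummary:
    """Model-predicted quantile summary across all three conditions."""
    merged = QuantileSummary()
    for condition in CONDITIONS:
        s = predicted_quantiles(params, condition, coding=coding)
        merged.proportion.update(s.proportion)
        merged.quantiles.update(s.quantiles)
        merged.unreliable |= s.unreliable
    return merged


def qpp_figure(
    observed: QuantileSummary | Mapping[str, QuantileSummary],
    predicted: QuantileSummary | Mapping[str, QuantileSummary],
    out_path: str,
    formats: Sequence[str] = ("svg", "png"),
) -> list[str]:
    """Quantile-probability panels: one per condition x group.

    ``observed`` and ``predicted`` are either single summaries or mappings
    from group label to summary (young / older rows).  Observed points are
    crosses, predictions circles.  Output is deterministic for fixed inputs.
    Raises if the two sides cover different condition sets.
    """
    if not isinstance(observed, Mapping):
        observed = {"all": observed}
    if not isinstance(predicted, Mapping):
        predicted = {"all": predicted}
    if set(observed) != set(predicted):
        raise ValueError(
            f"group mismatch: observed {sorted(observed)} vs predicted {sorted(predicted)}"
        )
    groups = list(observed)
    for g in groups:
        obs_conds, pred_conds = set(observed[g].conditions()), set(predicted[g].conditions())
        if obs_conds != pred_conds:
            raise ValueError(
                f"condition mismatch in group {g!r}: observed-only "
                f"{sorted(obs_conds - pred_conds)}, predicted-only {sorted(pred_conds - obs_conds)}"
            )
    conditions = observed[groups[0]].conditions()
    plt.rcParams["svg.hashsalt"] = "piddm"
    fig, axes = plt.subplots(
        len(groups),
        len(conditions),
        figsize=(4 * len(conditions), 3.2 * len(groups)),
        squeeze=False,
        sharey="row",
    )
    for gi, g in enumerate(groups):
        for ci, cond in enumerate(conditions):
            ax = axes[gi][ci]
            for summary, marker, label in (
                (observed[g], "x", "observed"),
                (predicted[g], "o", "predicted"),
            ):
                for response in ("error", "correct"):
                    key = (cond, response)
                    if key not in summary.proportion:
                        continue
                    q = np.asarray(summary.quantiles[key], dtype=float)
                    if np.isnan(q).all():
                        continue
                    x = np.full(q.size, summary.proportion[key])
                    ax.plot(
                        x,
                        q,
                        marker,
                        mfc="none",
                        color="k",
                        ms=5,
                        label=label if (response == "correct" and cond == conditions[0]) else None,
                    )
            ax.set_xlim(-0.05, 1.05)
            ax.set_title(f"{g}: {cond.replace('_', ' ')}", fontsize=9)
            if ci == 0:
                ax.set_ylabel("RT quantile (s)")
            if gi == len(groups) - 1:
                ax.set_xlabel("response proportion")
    axes[0][0].legend(fontsize=8, loc="upper left")
    fig.tight_layout()
    written = []
    for fmt in formats:
        path = f"{out_path}.{fmt}"
        fig.savefig(path, format=fmt, metadata={"Date": None} if fmt == "svg" else None)
        written.append(path)
    plt.close(fig)
    return written
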