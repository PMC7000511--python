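"""BIC model selection and cohort-level ranking.

Each participant is fitted by all candidate models; the winner minimizes the
Bayesian information criterion BIC = -2 ln L + k ln n, which penalizes the
extra free parameters of the more complex variants.  The cohort ranking
counts, per model, how many participants it won.
"""

from __future__ import annotations

import logging
import math
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .models import get_model

logger = logging.getLogger(__name__)


def bic(log_likelihood: float, k: int, n: int) -> float:
    """Bayesian information criterion: ``-2 ln L + k ln n`` (lower is better)."""
    if n <= 0 or k <= 0:
        raise ValueError(f"need n > 0 and k > 0, got n={n}, k={k}")
    return -2.0 * log_likelihood + k * math.log(n)


def select_best(fits: Sequence) -> int:
    """Winning model id for one participant's fits (argmin BIC).

    Non-converged fits are excluded from the comparison.  Exact BIC ties are
    broken toward fewer free parameters, then toward the lower model id; a
    tie-break is logged whenever invoked.
    """
    usable = [f for f in fits if f.converged]
    if len(usable) < 2:
        raise ValueError("need at least two converged fits to select a model")
    pids = {f.participant_id for f in usable}
    if len(pids) > 1:
        raise ValueError(f"fits belong to several participants: {sorted(pids)}")

    def key(f):
        return (f.bic, get_model(f.model_id).n_free_parameters, f.model_id)

    ranked = sorted(usable, key=key)
    winner = ranked[0]
    ties = [f for f in usable if f.bic == winner.bic and f.model_id != winner.model_id]
    if ties:
        logger.info(
            "participant %s: BIC tie between models %s; choosing model %d by parsimony",
            winner.participant_id,
            sorted(f.model_id for f in [winner, *ties]),
            winner.model_id,
        )
    return winner.model_id


def winners_by_participant(fits: Iterable) -> dict[str, int]:
    """Map participant id to winning model id; participants for whom fewer
    than two fits converged are excluded with a logged reason."""
    by_pid: dict[str, list] = {}
    for f in fits:
        by_pid.setdefault(f.participant_id, []).append(f)
    winners: dict[str, int] = {}
    for pid, pfits in by_pid.items():
        try:
            winners[pid] = select_best(pfits)
        except ValueError as err:
            logger.warning("participant %s excluded from ranking: %s", pid, err)
    return winners


def ranking_table(fits_or_winners) -> pd.DataFrame:
    """Cohort ranking: per model, the number and percentage of participants
    it fitted best, ranked by wins (rank 1 = most wins).

    Accepts either an iterable of fit results or a precomputed
    ``{participant_id: model_id}`` mapping.  Percentages sum to 100.
    """
    if isinstance(fits_or_winners, Mapping):
        winners = dict(fits_or_winners)
    else:
        winners = winners_by_participant(fits_or_winners)
    if not winners:
        raise ValueError("no participants with a selectable model")
    n_total = len(winners)
    rows = []
    for mid in range(1, 7):
        n_best = sum(1 for w in winners.values() if w == mid)
        rows.append(
            {"model": mid, "n_best": n_best, "percentage": 100.0 * n_best / n_total}
        )
    table = pd.DataFrame(rows)
    table["rank"] = (
        table["n_best"].rank(method="min", ascending=False).astype(int)
    )
    return table
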