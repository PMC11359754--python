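"""NASA-TLX weighted workload scoring with reliability/validity statistics.

The instrument rates six dimensions (mental, physical and temporal
demand, performance, effort, frustration) on 0-10 and weights each by
the number of times it wins one of the 15 pairwise comparisons, so the
overall score is

    F = sum_i M_i * P_i / 15,       0 <= F <= 10.

Group-level checks: Cronbach's alpha for internal consistency of the six
ratings and the Kaiser-Meyer-Olkin (KMO) sampling-adequacy measure as
the validity companion ("K" in the workload literature is interpreted
here as KMO; this is a labelled interpretation, not a standard symbol).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import PreconditionError

logger = logging.getLogger(__name__)

DIMENSIONS: tuple[str, ...] = (
    "mental", "physical", "temporal", "performance", "effort", "frustration",
)
N_PAIRS = 15  # C(6, 2)

#: The 15 unordered dimension pairs in canonical listing order.
PAIRS: tuple[tuple[str, str], ...] = tuple(itertools.combinations(DIMENSIONS, 2))


@dataclass
class TLXResponse:
    """One subject x phase questionnaire record."""

    subject: str
    phase: str
    ratings: np.ndarray      # (6,) M_i on 0-10
    weights: np.ndarray      # (6,) P_i pairwise win counts, sum 15

    def __post_init__(self) -> None:
        self.ratings = np.asarray(self.ratings, dtype=float)
        self.weights = np.asarray(self.weights, dtype=int)
        if self.ratings.shape != (6,) or self.weights.shape != (6,):
            raise PreconditionError("ratings and weights must have 6 entries each")
        if np.any(self.ratings < 0) or np.any(self.ratings > 10):
            raise PreconditionError(
                f"subject {self.subject!r}: ratings must lie in [0, 10]"
            )
        if np.any(self.weights < 0) or self.weights.sum() != N_PAIRS:
            raise PreconditionError(
                f"subject {self.subject!r}: pairwise wins must be >= 0 and sum to {N_PAIRS}"
            )


def tlx_score(resp: TLXResponse) -> float:
    """Overall weighted workload F = sum M_i P_i / 15."""
    return float((resp.ratings * resp.weights).sum() / N_PAIRS)


def pairwise_to_weights(
    comparisons: dict[tuple[str, str], str] | list[tuple[tuple[str, str], str]],
) -> np.ndarray:
    """Win counts P_i from the 15 pairwise choices.

    ``comparisons`` maps each unordered dimension pair to the winning
    dimension; every one of the 15 pairs must appear exactly once and the
    winner must belong to its pair (ties are not allowed).
    """
    if not isinstance(comparisons, dict):
        comparisons = dict(comparisons)
    normalized: dict[frozenset, str] = {}
    for (a, b), winner in comparisons.items():
        key = frozenset((a, b))
        if len(key) != 2 or not key.issubset(DIMENSIONS):
            raise PreconditionError(f"unknown dimension pair {(a, b)!r}")
        if key in normalized:
            raise PreconditionError(f"duplicate pair {(a, b)!r}")
        if winner not in key:
            raise PreconditionError(f"winner {winner!r} not in pair {(a, b)!r}")
        normalized[key] = winner
    if len(normalized) != N_PAIRS:
        raise PreconditionError(
            f"expected all {N_PAIRS} pairs, got {len(normalized)}"
        )
    wins = {d: 0 for d in DIMENSIONS}
    for winner in normalized.values():
        wins[winner] += 1
    return np.array([wins[d] for d in DIMENSIONS], dtype=int)


def reliability_alpha(ratings: np.ndarray) -> float:
    """Cronbach's alpha: (k/(k-1)) * (1 - sum(item variances)/var(total)).

    ``ratings`` is subjects x items; variances are sample variances
    (ddof=1) as in the conventional formula.
    """
    X = np.asarray(ratings, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 2:
        raise PreconditionError("need >= 2 subjects and >= 2 items")
    k = X.shape[1]
    item_var = X.var(axis=0, ddof=1)
    if np.any(item_var <= 0):
        raise PreconditionError("every item needs positive variance")
    total_var = X.sum(axis=1).var(ddof=1)
    if total_var <= 0:
        raise PreconditionError("total-score variance is zero")
    return float(k / (k - 1) * (1.0 - item_var.sum() / total_var))


def validity_kmo(ratings: np.ndarray) -> float:
    """Kaiser-Meyer-Olkin sampling adequacy in [0, 1]; NaN if singular.

    KMO = sum of squared off-diagonal correlations over that sum plus the
    squared off-diagonal partial correlations (from the inverse
    correlation matrix).
    """
    X = np.asarray(ratings, dtype=float)
    if X.ndim != 2 or X.shape[0] < X.shape[1] + 1:
        raise PreconditionError("need at least items + 1 subjects")
    R = np.corrcoef(X, rowvar=False)
    if not np.all(np.isfinite(R)):
        logger.warning("constant item: correlation matrix undefined; KMO is NaN")
        return float("nan")
    sign, logdet = np.linalg.slogdet(R)
    if sign <= 0 or logdet < -50:
        logger.warning("singular correlation matrix; KMO is NaN")
        return float("nan")
    Rinv = np.linalg.inv(R)
    d = np.sqrt(np.outer(np.diag(Rinv), np.diag(Rinv)))
    partial = -Rinv / d
    off = ~np.eye(R.shape[0], dtype=bool)
    r2 = (R[off] ** 2).sum()
    p2 = (partial[off] ** 2).sum()
    return float(r2 / (r2 + p2))


# ---------------------------------------------------------------------------
# CSV interface: one row per subject x phase; 6 rating columns
# rating_<dim>, and 15 comparison columns cmp_<dimA>_<dimB> holding the
# winning dimension name.
# ---------------------------------------------------------------------------

def _cmp_col(a: str, b: str) -> str:
    return f"cmp_{a}_{b}"


def read_responses(path: str | Path) -> list[TLXResponse]:
    df = pd.read_csv(path)
    rating_cols = [f"rating_{d}" for d in DIMENSIONS]
    cmp_cols = [_cmp_col(a, b) for a, b in PAIRS]
    missing = [c for c in ["subject", "phase", *rating_cols, *cmp_cols]
               if c not in df.columns]
    if missing:
        raise PreconditionError(f"TLX CSV missing columns: {missing}")
    responses = []
    for row in df.itertuples():
        comparisons = {
            pair: str(getattr(row, _cmp_col(*pair))) for pair in PAIRS
        }
        responses.append(
            TLXResponse(
                subject=str(row.subject),
                phase=str(row.phase),
                ratings=np.array([getattr(row, c) for c in rating_cols]),
                weights=pairwise_to_weights(comparisons),
            )
        )
    return responses


def score_responses(responses: list[TLXResponse]) -> pd.DataFrame:
    """Per-response F plus group alpha/KMO and per-phase means.

    Returns a frame with one row per response; group statistics are
    attached as frame attrs ``alpha``, ``kmo`` and ``phase_means``.
    """
    if not responses:
        raise PreconditionError("no responses to score")
    out = pd.DataFrame(
        {
            "subject": [r.subject for r in responses],
            "phase": [r.phase for r in responses],
            "score": [tlx_score(r) for r in responses],
        }
    )
    ratings = np.stack([r.ratings for r in responses])
    out.attrs["alpha"] = (
        reliability_alpha(ratings) if len(responses) >= 2
        and np.all(ratings.var(axis=0, ddof=1) > 0) else float("nan")
    )
    out.attrs["kmo"] = (
        validity_kmo(ratings) if len(responses) >= 7 else float("nan")
    )
    out.attrs["phase_means"] = out.groupby("phase")["score"].mean().to_dict()
    return out
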