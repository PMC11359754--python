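"""Shannon entropy and sample entropy of epoch signals.

Shannon entropy is computed on an equal-width amplitude histogram and
reported in log10 units (dits), so its ceiling is log10(B) for B bins.
Sample entropy follows the Richman–Moorman convention: Chebyshev distance
between delay-embedded templates, self-matches excluded, tolerance
r = r_frac * SD(x), and SampEn = -ln(A/B) where B counts matching
m-length template pairs and A matching (m+1)-length pairs.  A zero count
makes the statistic undefined (NaN), which downstream tables flag and
exclude rather than correct.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import PreconditionError
from .signal_io import EpochSet

logger = logging.getLogger(__name__)

DEFAULT_BINS = 100
DEFAULT_M = 2
DEFAULT_R_FRAC = 0.2


def shannon_entropy(x: np.ndarray, bins: int = DEFAULT_BINS) -> float:
    """Histogram Shannon entropy in dits (log base 10).

    Probabilities come from an equal-width histogram over [min(x), max(x)];
    empty bins contribute nothing (0 * log 0 = 0).  A constant signal
    occupies a single bin and has zero entropy.
    """
    x = np.asarray(x, dtype=float).ravel()
    if x.size < 2:
        raise PreconditionError("need at least 2 samples for an entropy estimate")
    if bins < 2:
        raise PreconditionError("need at least 2 histogram bins")
    if np.ptp(x) == 0:
        return 0.0
    counts, _ = np.histogram(x, bins=bins, range=(x.min(), x.max()))
    p = counts[counts > 0] / x.size
    return float(-(p * np.log10(p)).sum())


def _pair_count(d: np.ndarray, k: int, r: float) -> int:
    """Matched pairs (i < j) among the first k templates of distance matrix d."""
    iu = np.triu_indices(k, k=1)
    return int(np.count_nonzero(d[:k, :k][iu] <= r))


def sample_entropy_counts(
    x: np.ndarray, m: int = DEFAULT_M, r_frac: float = DEFAULT_R_FRAC
) -> tuple[int, int]:
    """Return (A, B): matched (m+1)- and m-length template pair counts.

    Both counts run over the same N - m template start positions so every
    m-template has a corresponding (m+1)-template.  The Chebyshev
    template distance is built incrementally: the m-template distance is
    the running maximum of m diagonal shifts of the scalar distance
    matrix, which keeps the cost at O(m N^2) with no embedding copies.
    """
    x = np.asarray(x, dtype=float).ravel()
    n = x.size
    if n <= m + 1:
        raise PreconditionError(f"series of {n} samples too short for m={m}")
    r = r_frac * float(np.std(x))
    d1 = np.abs(x[:, None] - x[None, :])
    dm = d1
    for k in range(1, m):
        dm = np.maximum(dm[:-1, :-1], d1[k:, k:])
    n_templates = n - m          # same start range for both lengths
    b = _pair_count(dm, n_templates, r)
    dm1 = np.maximum(dm[:-1, :-1], d1[m:, m:])
    a = _pair_count(dm1, n_templates, r)
    return a, b


def sample_entropy(
    x: np.ndarray, m: int = DEFAULT_M, r_frac: float = DEFAULT_R_FRAC
) -> float:
    """SampEn(m, r, N) = -ln(A/B); NaN when either count is zero.

    Scale- and offset-invariant because the tolerance is proportional to
    the series SD.  A constant series gives r = 0 with all distances 0,
    hence A = B and SampEn = 0 (perfect regularity).
    """
    a, b = sample_entropy_counts(x, m, r_frac)
    if a == 0 or b == 0:
        return float("nan")
    return float(-np.log(a / b)) + 0.0   # +0.0 normalizes -0.0 when A == B


@dataclass
class EntropyResult:
    """Per-epoch x channel entropy tables with their parameters."""

    shannon: np.ndarray          # (n_epochs, n_channels), dits
    sampen: np.ndarray           # (n_epochs, n_channels), NaN = undefined
    a_counts: np.ndarray         # matched (m+1)-template pairs
    b_counts: np.ndarray         # matched m-template pairs
    labels: np.ndarray
    channels: list[str]
    bins: int
    m: int
    r_frac: float

    @property
    def n_undefined(self) -> int:
        return int(np.isnan(self.sampen).sum())


def entropy_table(
    epochs: EpochSet,
    bins: int = DEFAULT_BINS,
    m: int = DEFAULT_M,
    r_frac: float = DEFAULT_R_FRAC,
    channels: list[str] | None = None,
) -> EntropyResult:
    """Both entropies for every epoch x channel (optionally a channel subset).

    Epochs whose sample entropy is undefined are flagged NaN and should be
    excluded from downstream means; the count is logged.
    """
    if channels is None:
        ch_idx = list(range(len(epochs.channels)))
        ch_names = list(epochs.channels)
    else:
        ch_idx = [epochs.channels.index(c) for c in channels]
        ch_names = list(channels)
    n_ep = epochs.n_epochs
    shan = np.empty((n_ep, len(ch_idx)))
    samp = np.empty((n_ep, len(ch_idx)))
    a_cnt = np.zeros((n_ep, len(ch_idx)), dtype=int)
    b_cnt = np.zeros((n_ep, len(ch_idx)), dtype=int)
    for i in range(n_ep):
        for j, c in enumerate(ch_idx):
            x = epochs.epochs[i, c]
            shan[i, j] = shannon_entropy(x, bins)
            a, b = sample_entropy_counts(x, m, r_frac)
            a_cnt[i, j], b_cnt[i, j] = a, b
            samp[i, j] = (-np.log(a / b) + 0.0) if a > 0 and b > 0 else np.nan
    n_undef = int(np.isnan(samp).sum())
    if n_undef:
        logger.warning("%d epoch x channel entries have undefined SampEn", n_undef)
    return EntropyResult(
        shannon=shan, sampen=samp, a_counts=a_cnt, b_counts=b_cnt,
        labels=epochs.labels.copy(), channels=ch_names,
        bins=bins, m=m, r_frac=r_frac,
    )
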