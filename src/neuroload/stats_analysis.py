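"""Pearson correlation analyses and normality screening.

Channel correlation follows the analysis design: per epoch a 14x14
Pearson matrix of the (optionally beta-band-filtered) channel series,
averaged across epochs through the Fisher z-transform, then summarized
per channel as the mean |r| to all other channels.  Feature correlations
reproduce the entropy-by-energy-ratio table layout, and normality is
screened per feature and phase with Shapiro-Wilk (pass = p > 0.05); the
screen is reported, never used to gate the pipeline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .band_features import BandMap
from .errors import EmptySelectionError, PreconditionError
from .preprocess import bandpass_array
from .signal_io import EpochSet

logger = logging.getLogger(__name__)

SHAPIRO_MAX_N = 5000
NORMALITY_ALPHA = 0.05

ENTROPY_FEATURES = ("shannon", "sampen")
RATIO_FEATURES = ("delta_ratio", "theta_ratio", "alpha_ratio", "beta_ratio",
                  "beta_theta_alpha")


def pearson_r(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson product-moment correlation; NaN for constant input."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise PreconditionError(f"length mismatch: {x.size} vs {y.size}")
    if x.size < 3:
        raise PreconditionError("need at least 3 paired observations")
    xd = x - x.mean()
    yd = y - y.mean()
    denom = np.sqrt((xd ** 2).sum() * (yd ** 2).sum())
    if denom == 0:
        logger.warning("constant input: correlation undefined")
        return float("nan")
    return float(np.clip((xd * yd).sum() / denom, -1.0, 1.0))


@dataclass
class CorrelationMatrix:
    """Symmetric unit-diagonal correlation matrix with labels."""

    labels: list[str]
    r: np.ndarray
    n: int                     # epochs (or rows) behind each cell

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        if self.r.shape != (len(self.labels), len(self.labels)):
            raise PreconditionError("matrix shape must match labels")

    def mean_abs(self) -> pd.Series:
        """Per-channel mean |r| to all other channels."""
        k = len(self.labels)
        off = np.abs(self.r) * (1 - np.eye(k))
        return pd.Series(off.sum(axis=1) / (k - 1), index=self.labels)

    @property
    def argmax_channel(self) -> str:
        return str(self.mean_abs().idxmax())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.r, index=self.labels, columns=self.labels)


def _fisher_mean(rs: np.ndarray, axis: int = 0) -> np.ndarray:
    z = np.arctanh(np.clip(rs, -1 + 1e-12, 1 - 1e-12))
    return np.tanh(np.nanmean(z, axis=axis))


def channel_correlation(
    epochs: EpochSet,
    phase: str,
    band: tuple[float, float] | str | None = None,
    band_map: BandMap | None = None,
) -> CorrelationMatrix:
    """Cross-channel Pearson matrix for one phase, Fisher-z averaged.

    ``band`` may be a band name from ``band_map`` (default rhythm bands),
    an explicit (low, high) Hz pair, or None for broadband series.
    """
    mask = epochs.select(phase)
    if not mask.any():
        raise EmptySelectionError(f"no epochs labelled {phase!r}")
    data = epochs.epochs[mask]                      # (n, ch, s)
    if band is not None:
        if isinstance(band, str):
            band = (band_map or BandMap()).bands[band]
        lo, hi = band
        data = bandpass_array(data, epochs.fs, lo, hi)
    n_ep, n_ch, _ = data.shape
    rs = np.empty((n_ep, n_ch, n_ch))
    for i in range(n_ep):
        with np.errstate(invalid="ignore", divide="ignore"):
            rs[i] = np.corrcoef(data[i])
    r_mean = _fisher_mean(rs, axis=0)
    np.fill_diagonal(r_mean, 1.0)
    r_mean = (r_mean + r_mean.T) / 2
    return CorrelationMatrix(labels=list(epochs.channels), r=r_mean, n=n_ep)


def feature_correlations(
    features: pd.DataFrame,
    entropy_cols: tuple[str, ...] = ENTROPY_FEATURES,
    ratio_cols: tuple[str, ...] = RATIO_FEATURES,
) -> pd.DataFrame:
    """Entropy-by-energy-ratio Pearson table, one row per entropy x phase.

    ``features`` needs a ``phase`` column plus the entropy and ratio
    columns (one row per epoch, or per epoch x channel).  Rows with NaN in
    a pair are dropped pairwise.
    """
    if "phase" not in features.columns:
        raise PreconditionError("features must carry a 'phase' column")
    rows = []
    for ent in entropy_cols:
        for phase, grp in features.groupby("phase", sort=True):
            if len(grp) < 3:
                raise PreconditionError(
                    f"fewer than 3 rows for phase {phase!r}"
                )
            row: dict[str, object] = {"entropy": ent, "phase": phase}
            for rc in ratio_cols:
                pair = grp[[ent, rc]].dropna()
                row[rc] = (
                    pearson_r(pair[ent].to_numpy(), pair[rc].to_numpy())
                    if len(pair) >= 3
                    else np.nan
                )
            rows.append(row)
    return pd.DataFrame(rows).set_index(["entropy", "phase"])


def normality_check(
    features: pd.DataFrame,
    columns: tuple[str, ...] | None = None,
    by_phase: bool = True,
) -> pd.DataFrame:
    """Shapiro-Wilk screen per feature (and phase); pass = p > 0.05.

    Requires n >= 8 per group.  Groups beyond the test's reliable size are
    subsampled deterministically to 5000.  Results are informational: the
    pipeline never gates on them.
    """
    if columns is None:
        columns = tuple(
            c for c in features.columns
            if c in ENTROPY_FEATURES + RATIO_FEATURES
        )
    groups = features.groupby("phase", sort=True) if by_phase else [("all", features)]
    rows = []
    for phase, grp in groups:
        for col in columns:
            x = grp[col].dropna().to_numpy(dtype=float)
            if x.size < 8:
                raise PreconditionError(
                    f"normality check needs n >= 8 for {col!r}/{phase!r}, got {x.size}"
                )
            if x.size > SHAPIRO_MAX_N:
                idx = np.random.default_rng(0).choice(x.size, SHAPIRO_MAX_N, replace=False)
                x = x[idx]
            stat, p = stats.shapiro(x)
            rows.append(
                {"phase": phase, "feature": col, "statistic": float(stat),
                 "p": float(p), "normal": bool(p > NORMALITY_ALPHA)}
            )
    out = pd.DataFrame(rows)
    logger.info("normality screen: %d/%d feature groups pass", out["normal"].sum(), len(out))
    return out
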