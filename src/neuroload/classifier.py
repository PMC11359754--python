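"""Feature normalization, train/test split, SVM training and evaluation.

Workload states are binary: epochs from turning phases are ``high``,
cruise epochs ``low``.  Features default to the (beta energy ratio,
Shannon entropy) pair — the combination with the strongest mutual
correlation — averaged over a configurable channel subset (the temporal
electrodes T7/T8 by default, where the turning beta surge lives).

Min-max normalization uses extrema fitted on the training rows only;
test rows may fall outside [0, 1] and are deliberately not clipped.  The
SVM itself is a standard maximum-margin dual solve (radial-basis kernel
by default, linear selectable — the two kernel conventions that appear
for this detector); the package's contribution is the feature pipeline
and the reporting around it, so the quadratic program is delegated to
scikit-learn's SVC.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.svm import SVC

from .band_features import BandEnergySummary
from .entropy_features import EntropyResult
from .errors import PreconditionError

logger = logging.getLogger(__name__)

LABEL_HIGH = "high"
LABEL_LOW = "low"
PHASE_TO_LABEL = {"cruise": LABEL_LOW, "turn_left": LABEL_HIGH, "turn_right": LABEL_HIGH}

DEFAULT_FEATURES = ("beta_ratio", "shannon", "sampen")
DEFAULT_FEATURE_CHANNELS = ("T7", "T8")


@dataclass
class FeatureMatrix:
    """Epoch-level feature rows with binary workload labels."""

    X: np.ndarray                       # (n_rows, n_features)
    labels: np.ndarray                  # (n_rows,) in {high, low}
    feature_names: list[str]
    x_min: np.ndarray | None = None     # fit-row extrema once normalized
    x_max: np.ndarray | None = None
    fit_rows: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.labels = np.asarray(self.labels, dtype=object)
        if self.X.ndim != 2 or self.X.shape[0] != len(self.labels):
            raise PreconditionError("X must be 2-D with one label per row")
        if self.X.shape[1] != len(self.feature_names):
            raise PreconditionError("one name per feature column required")
        bad = set(self.labels) - {LABEL_HIGH, LABEL_LOW}
        if bad:
            raise PreconditionError(f"labels must be binary high/low, got {bad}")

    @property
    def n_rows(self) -> int:
        return self.X.shape[0]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=self.feature_names)
        df["label"] = self.labels
        return df


def build_feature_matrix(
    band_summary: BandEnergySummary,
    entropies: EntropyResult | None = None,
    features: tuple[str, ...] = DEFAULT_FEATURES,
    channels: tuple[str, ...] = DEFAULT_FEATURE_CHANNELS,
    entropy_channels: tuple[str, ...] | None = None,
    pool_turns: bool = True,
) -> FeatureMatrix:
    """Assemble per-epoch feature columns matched to their spatial footprint.

    Band features (``<band>_ratio``, ``beta_theta_alpha``) get one column
    per channel in ``channels`` — the beta surge is lateralized to single
    temporal electrodes, so averaging across hemispheres would dilute it.
    Entropy features (``shannon``, ``sampen``) measure a broadband
    irregularity change common to all channels, so each becomes a single
    column averaged over ``entropy_channels`` (default: every channel in
    the EntropyResult).

    Rows containing NaN (degenerate epochs, undefined SampEn) are dropped
    with a logged count.  With ``pool_turns`` both turn directions
    collapse into the ``high`` class; otherwise ``turn_right`` epochs are
    excluded so classes stay binary.
    """
    ch_idx = [band_summary.channels.index(c) for c in channels]

    columns: list[np.ndarray] = []
    names: list[str] = []
    for name in features:
        if name.endswith("_ratio") or name == "beta_theta_alpha":
            table = (
                band_summary.beta_theta_alpha if name == "beta_theta_alpha"
                else band_summary.ratios[name[:-6]]
            )
            for c, ch in zip(ch_idx, channels):
                columns.append(table[:, c])
                names.append(f"{name}_{ch}")
        elif name in ("shannon", "sampen"):
            if entropies is None:
                raise PreconditionError(f"feature {name!r} needs an EntropyResult")
            e_idx = (
                [entropies.channels.index(c) for c in entropy_channels]
                if entropy_channels is not None
                else list(range(len(entropies.channels)))
            )
            table = entropies.shannon if name == "shannon" else entropies.sampen
            columns.append(table[:, e_idx].mean(axis=1))
            names.append(name)
        else:
            raise PreconditionError(f"unknown feature {name!r}")

    X = np.column_stack(columns)
    phases = band_summary.labels
    labels = np.array([PHASE_TO_LABEL[p] for p in phases], dtype=object)
    keep = ~np.isnan(X).any(axis=1)
    if not pool_turns:
        keep &= phases != "turn_right"
    dropped = int((~keep).sum())
    if dropped:
        logger.warning("dropped %d rows (NaN features or excluded phase)", dropped)
    return FeatureMatrix(X=X[keep], labels=labels[keep], feature_names=names)


def normalize(fm: FeatureMatrix, fit_rows: np.ndarray) -> FeatureMatrix:
    """Min-max normalize against extrema of the fit (training) rows.

    Non-fit rows may land outside [0, 1] and are not clipped.  A feature
    constant on the fit rows is dropped with a warning.
    """
    fit_rows = np.asarray(fit_rows)
    x_min = fm.X[fit_rows].min(axis=0)
    x_max = fm.X[fit_rows].max(axis=0)
    keep = x_max > x_min
    if not keep.all():
        dropped = [n for n, k in zip(fm.feature_names, keep) if not k]
        logger.warning("dropping constant feature(s) on fit rows: %s", dropped)
    if not keep.any():
        raise PreconditionError("all features constant on the fit rows")
    Xn = (fm.X[:, keep] - x_min[keep]) / (x_max[keep] - x_min[keep])
    return FeatureMatrix(
        X=Xn,
        labels=fm.labels.copy(),
        feature_names=[n for n, k in zip(fm.feature_names, keep) if k],
        x_min=x_min[keep],
        x_max=x_max[keep],
        fit_rows=fit_rows,
    )


def split(
    fm: FeatureMatrix, n_train: int, stratify: bool = True, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Random (stratified) train/test row indices, deterministic per seed."""
    n = fm.n_rows
    if not 0 < n_train < n:
        raise PreconditionError(f"n_train must be in (0, {n}), got {n_train}")
    rng = np.random.default_rng(seed)
    if not stratify:
        perm = rng.permutation(n)
        return np.sort(perm[:n_train]), np.sort(perm[n_train:])
    classes, counts = np.unique(fm.labels.astype(str), return_counts=True)
    takes = {}
    acc = 0
    for cls, cnt in zip(classes, counts):
        t = int(round(n_train * cnt / n))
        takes[cls] = t
        acc += t
    takes[classes[np.argmax(counts)]] += n_train - acc   # fix rounding drift
    train_idx: list[np.ndarray] = []
    for cls, cnt in zip(classes, counts):
        rows = np.flatnonzero(fm.labels.astype(str) == cls)
        t = takes[cls]
        if not 0 < t < cnt:
            raise PreconditionError(
                f"class {cls!r} too small to stratify ({cnt} rows, need {t} train)"
            )
        train_idx.append(rng.permutation(rows)[:t])
    train = np.sort(np.concatenate(train_idx))
    test = np.setdiff1d(np.arange(n), train)
    logger.info("split: %d train / %d test rows", len(train), len(test))
    return train, test


def train_svm(
    fm: FeatureMatrix,
    rows: np.ndarray | None = None,
    kernel: str = "rbf",
    C: float = 1.0,
    gamma: str | float = "scale",
) -> SVC:
    """Fit the maximum-margin classifier on the given rows."""
    if kernel not in ("rbf", "linear"):
        raise PreconditionError("kernel must be 'rbf' or 'linear'")
    rows = np.arange(fm.n_rows) if rows is None else np.asarray(rows)
    y = fm.labels[rows].astype(str)
    if len(np.unique(y)) < 2:
        raise PreconditionError("training rows must contain both classes")
    model = SVC(kernel=kernel, C=C, gamma=gamma)
    model.fit(fm.X[rows], y)
    return model


@dataclass
class ClassifierReport:
    """Trained-model evaluation record, JSON-serializable."""

    kernel: str
    params: dict
    n_support: int
    train_accuracy_pct: float
    test_accuracy_pct: float
    confusion: dict                     # {true -> {pred -> count}}
    split: dict = field(default_factory=dict)

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(
            self.__dict__, indent=2,
            default=lambda o: o.item() if hasattr(o, "item") else str(o),
        )
        if path is not None:
            Path(path).write_text(text)
        return text


def evaluate(
    model: SVC,
    fm: FeatureMatrix,
    train_rows: np.ndarray,
    test_rows: np.ndarray,
    seed: int | None = None,
) -> ClassifierReport:
    """Accuracy and confusion matrix on the held-out rows."""
    if fm.X.shape[1] != model.n_features_in_:
        raise PreconditionError("feature-set mismatch with the trained model")

    def accuracy(rows: np.ndarray) -> float:
        pred = model.predict(fm.X[rows])
        return float((pred == fm.labels[rows].astype(str)).mean() * 100.0)

    pred_test = model.predict(fm.X[test_rows])
    true_test = fm.labels[test_rows].astype(str)
    classes = sorted(set(true_test) | set(pred_test))
    confusion = {
        t: {p: int(((true_test == t) & (pred_test == p)).sum()) for p in classes}
        for t in classes
    }
    return ClassifierReport(
        kernel=model.kernel,
        params={"C": model.C, "gamma": model._gamma if hasattr(model, "_gamma")
                else model.gamma},
        n_support=int(model.n_support_.sum()),
        train_accuracy_pct=accuracy(train_rows),
        test_accuracy_pct=accuracy(test_rows),
        confusion=confusion,
        split={
            "n_train": int(len(train_rows)),
            "n_test": int(len(test_rows)),
            "seed": seed,
        },
    )


def classify_features(
    fm: FeatureMatrix,
    n_train: int,
    kernel: str = "rbf",
    C: float = 1.0,
    gamma: str | float = "scale",
    seed: int = 0,
) -> ClassifierReport:
    """Normalize on training extrema, fit, and report — the one-call path."""
    train, test = split(fm, n_train, stratify=True, seed=seed)
    norm = normalize(fm, train)
    model = train_svm(norm, train, kernel=kernel, C=C, gamma=gamma)
    return evaluate(model, norm, train, test, seed=seed)
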