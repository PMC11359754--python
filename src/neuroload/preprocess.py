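"""Preprocessing: FIR band-pass, ICA artifact rejection, time-locked averaging.

The filter is a linear-phase windowed-sinc band-pass (Hamming) applied
forward with group-delay compensation, so the output stays on the input
timebase and the operation is literally a finite impulse response.  ICA
uses FastICA (deflation, tanh contrast) and flags ocular components by
correlation with a blink reference — or, without one, by frontal mixing
dominance plus low-frequency spectral concentration — and muscular
components by their high-frequency spectral fraction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from sklearn.decomposition import FastICA

from .errors import (
    EmptySelectionError,
    InputTooShortError,
    PreconditionError,
)
from .signal_io import EpochSet, Recording

logger = logging.getLogger(__name__)

#: Hamming-window approximate transition-width constant (normalized).
_HAMMING_TBW = 3.3

#: Cap on FIR length so the 0.1 Hz edge stays practical on short records.
MAX_FIR_TAPS = 4097

#: Default artifact-detection thresholds (overridable per call).
EOG_CORR_THRESHOLD = 0.7
EOG_LOWFREQ_HZ = 4.0
EOG_LOWFREQ_FRACTION = 0.5   # blink trains are sparse pulses: energy is
                             # concentrated but not confined below 4 Hz
EOG_FRONTAL_DOMINANCE = 2.0
EMG_HIGHFREQ_HZ = 20.0
EMG_HIGHFREQ_FRACTION = 0.6
FRONTAL_CHANNELS = ("AF3", "AF4")


@dataclass
class FilterSpec:
    """Band-pass design parameters.

    ``transition_hz`` sets the nominal transition width used to size the
    filter; the low edge is narrower than most transitions, so the design
    uses ``min(transition_hz, 2 * low_hz)`` and caps the tap count at
    :data:`MAX_FIR_TAPS` (the achieved figures are logged).
    """

    low_hz: float = 0.1
    high_hz: float = 40.0
    transition_hz: float = 0.5
    window: str = "hamming"

    def validate(self, fs: float) -> None:
        if not 0 < self.low_hz < self.high_hz < fs / 2:
            raise PreconditionError(
                f"need 0 < low ({self.low_hz}) < high ({self.high_hz}) < fs/2 ({fs / 2})"
            )


def design_fir(spec: FilterSpec, fs: float, max_taps: int = MAX_FIR_TAPS) -> np.ndarray:
    """Design the linear-phase band-pass taps for ``spec`` at rate ``fs``."""
    spec.validate(fs)
    transition = min(spec.transition_hz, 2.0 * spec.low_hz)
    numtaps = int(np.ceil(_HAMMING_TBW * fs / transition))
    numtaps = min(numtaps, max_taps)
    if numtaps % 2 == 0:
        numtaps -= 1  # odd length -> type I, integer group delay
    logger.debug(
        "FIR band-pass %.3g-%.3g Hz, %d taps (transition %.3g Hz)",
        spec.low_hz, spec.high_hz, numtaps, transition,
    )
    return sps.firwin(
        numtaps,
        [spec.low_hz, spec.high_hz],
        pass_zero=False,
        window=spec.window,
        fs=fs,
    )


def _filter_aligned(data: np.ndarray, taps: np.ndarray) -> np.ndarray:
    """Apply FIR taps along the last axis with group-delay compensation.

    The signal is reflect-padded by half the filter length on both ends so
    the output has the input's length and timebase.
    """
    n = data.shape[-1]
    half = (len(taps) - 1) // 2
    if len(taps) > n:
        raise InputTooShortError(
            f"signal of {n} samples shorter than the {len(taps)}-tap filter"
        )
    pad = min(half, n - 1)
    padded = np.concatenate(
        [data[..., 1:pad + 1][..., ::-1], data, data[..., -pad - 1:-1][..., ::-1]],
        axis=-1,
    )
    if half > pad:  # very short signal: extend with edge values
        extra = half - pad
        padded = np.concatenate(
            [
                np.repeat(padded[..., :1], extra, axis=-1),
                padded,
                np.repeat(padded[..., -1:], extra, axis=-1),
            ],
            axis=-1,
        )
    taps = taps.reshape((1,) * (padded.ndim - 1) + (len(taps),))
    out = sps.oaconvolve(padded, taps, mode="valid", axes=-1)
    return out[..., :n] if out.shape[-1] != n else out


def bandpass_fir(rec: Recording, spec: FilterSpec | None = None) -> Recording:
    """Band-pass filter a recording (default 0.1–40 Hz)."""
    spec = spec or FilterSpec()
    taps = design_fir(spec, rec.fs)
    if len(taps) > rec.n_samples:
        raise InputTooShortError(
            f"recording of {rec.n_samples} samples cannot support the "
            f"{len(taps)}-tap filter"
        )
    return rec.copy_with(_filter_aligned(rec.data, taps))


def bandpass_array(
    data: np.ndarray, fs: float, low_hz: float, high_hz: float,
    transition_hz: float = 2.0,
) -> np.ndarray:
    """Band-pass a raw array along its last axis (helper for sub-band work).

    ``low_hz = 0`` degrades to a low-pass at ``high_hz``.
    """
    n = data.shape[-1]
    numtaps = min(int(np.ceil(_HAMMING_TBW * fs / transition_hz)), MAX_FIR_TAPS, n)
    if numtaps % 2 == 0:
        numtaps -= 1
    if low_hz <= 0:
        taps = sps.firwin(numtaps, high_hz, pass_zero=True, window="hamming", fs=fs)
    else:
        taps = sps.firwin(
            numtaps, [low_hz, high_hz], pass_zero=False, window="hamming", fs=fs
        )
    return _filter_aligned(data, taps)


# ---------------------------------------------------------------------------
# ICA
# ---------------------------------------------------------------------------

@dataclass
class ICADecomposition:
    """An unmixed recording plus per-component artifact flags."""

    mixing: np.ndarray            # (n_channels, n_components)
    sources: np.ndarray           # (n_components, n_samples)
    mean: np.ndarray              # (n_channels,) removed channel means
    channels: list[str]
    fs: float
    flags: dict[int, str] = field(default_factory=dict)   # index -> reason

    @property
    def n_components(self) -> int:
        return self.sources.shape[0]

    def reconstruct(self, drop_flagged: bool = False) -> np.ndarray:
        src = self.sources
        if drop_flagged and self.flags:
            src = src.copy()
            src[list(self.flags), :] = 0.0
        return self.mixing @ src + self.mean[:, None]


def ica_decompose(
    rec: Recording,
    seed: int,
    n_components: int | None = None,
    fit_samples: int = 40_000,
) -> ICADecomposition:
    """FastICA unmixing with variance-ordered components.

    Deterministic for a fixed seed; components are sorted by the channel
    variance they explain.  Rank-deficient input yields fewer components
    (logged), single-channel input is rejected.  Recordings longer than
    ``fit_samples`` are fitted on an evenly strided subsample and the
    learned unmixing is applied to the full series; with a full-rank
    decomposition the mixing matrix inverts the unmixing exactly, so the
    reconstruction identity is unaffected.
    """
    if rec.n_channels < 2:
        raise PreconditionError("ICA needs at least 2 channels")
    if rec.n_samples < 4 * rec.n_channels:
        raise PreconditionError("ICA needs far more samples than channels")
    X = rec.data.T  # samples x channels
    rank = int(np.linalg.matrix_rank(X - X.mean(0)))
    k = n_components or rec.n_channels
    if rank < k:
        logger.warning("rank-deficient input: %d components instead of %d", rank, k)
        k = rank
    ica = FastICA(
        n_components=k,
        algorithm="deflation",
        fun="logcosh",            # tanh contrast
        whiten="unit-variance",
        random_state=seed,
        max_iter=1000,
    )
    if rec.n_samples > fit_samples:
        stride = int(np.ceil(rec.n_samples / fit_samples))
        logger.info("fitting ICA on every %d-th of %d samples", stride, rec.n_samples)
        ica.fit(X[::stride])
        sources = ica.transform(X).T          # components x samples
    else:
        sources = ica.fit_transform(X).T
    mixing = ica.mixing_                      # channels x components
    mean = ica.mean_
    explained = (mixing ** 2).sum(axis=0) * sources.var(axis=1)
    order = np.argsort(explained)[::-1]
    return ICADecomposition(
        mixing=mixing[:, order],
        sources=sources[order],
        mean=mean,
        channels=list(rec.channels),
        fs=rec.fs,
    )


def _spectral_fraction(source: np.ndarray, fs: float, f_lo: float, f_hi: float) -> float:
    freqs, psd = sps.welch(source, fs=fs, nperseg=min(len(source), 1024))
    total = psd.sum()
    if total <= 0:
        return 0.0
    band = psd[(freqs >= f_lo) & (freqs < f_hi)].sum()
    return float(band / total)


def flag_artifact_components(
    ica: ICADecomposition,
    rec: Recording | None = None,
    reference: np.ndarray | None = None,
    corr_threshold: float = EOG_CORR_THRESHOLD,
    emg_fraction: float = EMG_HIGHFREQ_FRACTION,
    lowfreq_fraction: float = EOG_LOWFREQ_FRACTION,
    frontal_dominance: float = EOG_FRONTAL_DOMINANCE,
) -> ICADecomposition:
    """Flag EOG and EMG components; zero flags is a valid outcome.

    EOG: |corr(source, reference)| > ``corr_threshold`` when a blink
    reference channel is given, otherwise frontal (AF3/AF4) mixing-weight
    dominance together with < 4 Hz spectral concentration.  EMG: > 20 Hz
    spectral fraction above ``emg_fraction``.
    """
    flags: dict[int, str] = {}
    frontal_idx = [
        ica.channels.index(ch) for ch in FRONTAL_CHANNELS if ch in ica.channels
    ]
    other_idx = [i for i in range(len(ica.channels)) if i not in frontal_idx]
    nyq = ica.fs / 2

    for i, src in enumerate(ica.sources):
        if reference is not None:
            if len(reference) != src.shape[0]:
                raise PreconditionError("reference length must match the sources")
            r = np.corrcoef(src, reference)[0, 1]
            if np.abs(r) > corr_threshold:
                flags[i] = f"EOG (|corr|={abs(r):.2f} with reference)"
                continue
        elif frontal_idx and other_idx:
            w = np.abs(ica.mixing[:, i])
            dominance = w[frontal_idx].mean() / max(w[other_idx].mean(), 1e-12)
            low = _spectral_fraction(src, ica.fs, 0.0, EOG_LOWFREQ_HZ)
            if dominance > frontal_dominance and low > lowfreq_fraction:
                flags[i] = (
                    f"EOG (frontal dominance {dominance:.1f}, "
                    f"<4 Hz fraction {low:.2f})"
                )
                continue
        if nyq > EMG_HIGHFREQ_HZ:
            high = _spectral_fraction(src, ica.fs, EMG_HIGHFREQ_HZ, nyq)
            if high > emg_fraction:
                flags[i] = f"EMG (>20 Hz fraction {high:.2f})"

    out = ICADecomposition(
        mixing=ica.mixing, sources=ica.sources, mean=ica.mean,
        channels=list(ica.channels), fs=ica.fs, flags=flags,
    )
    logger.info("flagged %d/%d components: %s", len(flags), ica.n_components,
                list(flags.values()) or "none")
    return out


def remove_components(ica: ICADecomposition) -> Recording:
    """Reconstruct the recording with flagged sources zeroed."""
    if len(ica.flags) == ica.n_components:
        raise PreconditionError(
            "all components flagged; removing them would leave a zero signal"
        )
    return Recording(
        fs=ica.fs,
        channels=list(ica.channels),
        data=ica.reconstruct(drop_flagged=True),
    )


def superimposed_average(epochs: EpochSet, phase: str) -> np.ndarray:
    """Time-locked (pointwise) average of all epochs of one phase.

    With n epochs of identical signal plus iid noise, residual noise
    variance drops as 1/n.
    """
    mask = epochs.select(phase)
    if not mask.any():
        raise EmptySelectionError(f"no epochs labelled {phase!r}")
    return epochs.epochs[mask].mean(axis=0)
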