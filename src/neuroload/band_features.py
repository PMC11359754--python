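"""Wavelet-packet rhythm-band energies, ratios and electrode maps.

Each epoch is decomposed with an orthogonal wavelet packet (db4 by
default) down to uniform sub-bands of ~2 Hz, the terminal nodes are
re-ordered into ascending frequency via the binary-reflected Gray code
(the high-pass branch of each split flips the spectrum, so the natural
tree order is *not* the frequency order), and node energies are summed
into the classic EEG rhythm bands:

    delta [0, 4) Hz,  theta [4, 8) Hz,  alpha [8, 12) Hz,  beta [12, 30) Hz.

Decomposition uses periodized extension so the transform is orthonormal
and conserves energy exactly (sum of node energies equals the epoch's sum
of squares); nodes above 30 Hz are computed but excluded from the ratio
denominators, which are restricted to the 0-30 Hz analysis range.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pywt

from .errors import ConfigError, EmptySelectionError, PreconditionError
from .signal_io import EpochSet

logger = logging.getLogger(__name__)

#: Rhythm-band edges in Hz, half-open intervals.  The beta band follows the
#: 12-30 Hz computational definition (an alternative 14-30 Hz convention
#: exists in descriptive tables; pass a custom BandMap to use it).
DEFAULT_BANDS: dict[str, tuple[float, float]] = {
    "delta": (0.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 12.0),
    "beta": (12.0, 30.0),
}

#: Approximate 2-D projection of the 14 electrode positions (10-20 layout),
#: x toward the right ear, y toward the nasion, unit head radius.
ELECTRODE_COORDS: dict[str, tuple[float, float]] = {
    "AF3": (-0.32, 0.82), "AF4": (0.32, 0.82),
    "F7": (-0.72, 0.45), "F3": (-0.42, 0.50),
    "F4": (0.42, 0.50), "F8": (0.72, 0.45),
    "FC5": (-0.65, 0.22), "FC6": (0.65, 0.22),
    "T7": (-0.85, 0.00), "T8": (0.85, 0.00),
    "P7": (-0.72, -0.45), "P8": (0.72, -0.45),
    "O1": (-0.32, -0.82), "O2": (0.32, -0.82),
}


@dataclass
class BandMap:
    """Named, non-overlapping frequency bands with half-open edges."""

    bands: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BANDS)
    )

    def __post_init__(self) -> None:
        edges = sorted(self.bands.values())
        for (lo, hi) in edges:
            if not lo < hi:
                raise ConfigError(f"band edges must satisfy low < high, got [{lo}, {hi})")
        for (_, hi1), (lo2, _) in zip(edges, edges[1:]):
            if lo2 < hi1:
                raise ConfigError("bands must not overlap")

    def __iter__(self):
        return iter(self.bands.items())

    @property
    def names(self) -> list[str]:
        return list(self.bands)


@dataclass
class WPDecomposition:
    """Frequency-ordered terminal nodes of a wavelet-packet transform.

    ``coeffs[k]`` holds the coefficients of the k-th node in ascending
    frequency; leading array dimensions (epochs, channels) pass through.
    """

    wavelet: str
    level: int
    fs: float
    coeffs: list[np.ndarray]
    node_hz: list[tuple[float, float]]

    @property
    def bandwidth_hz(self) -> float:
        return self.fs / 2 ** (self.level + 1)

    def node_energies(self) -> np.ndarray:
        """Per-node sum of squared coefficients, stacked on a last axis."""
        return np.stack([np.sum(c ** 2, axis=-1) for c in self.coeffs], axis=-1)


def _gray(n: int) -> int:
    return n ^ (n >> 1)


def wp_decompose(
    signal: np.ndarray,
    fs: float,
    wavelet: str = "db4",
    target_bandwidth_hz: float = 2.0,
) -> WPDecomposition:
    """Uniform wavelet-packet decomposition with frequency-ordered nodes.

    The level J is chosen so the terminal-node bandwidth fs / 2**(J+1)
    matches ``target_bandwidth_hz`` (J = 5 at fs = 128); when fs is not a
    power-of-two multiple of the target the nearest achievable bandwidth
    is used and logged.  Works on any array whose last axis is time.
    """
    x = np.asarray(signal, dtype=float)
    ratio = fs / (2.0 * target_bandwidth_hz)
    level = max(int(round(np.log2(ratio))), 1)
    achieved = fs / 2 ** (level + 1)
    if abs(achieved - target_bandwidth_hz) > 1e-9:
        logger.warning(
            "fs=%g is not a power-of-two multiple of %g Hz; using %g Hz nodes",
            fs, target_bandwidth_hz, achieved,
        )
    if x.shape[-1] < 2 ** level:
        raise PreconditionError(
            f"epoch of {x.shape[-1]} samples too short for a level-{level} decomposition"
        )

    nodes = [x]
    for _ in range(level):
        nxt: list[np.ndarray] = []
        for nd in nodes:
            a, d = pywt.dwt(nd, wavelet, mode="periodization", axis=-1)
            nxt.append(a)
            nxt.append(d)
        nodes = nxt

    # natural (Paley) -> frequency order: node at frequency rank f sits at
    # natural position gray(f)
    order = [_gray(f) for f in range(2 ** level)]
    coeffs = [nodes[i] for i in order]
    bw = achieved
    node_hz = [(k * bw, (k + 1) * bw) for k in range(2 ** level)]
    return WPDecomposition(
        wavelet=wavelet, level=level, fs=fs, coeffs=coeffs, node_hz=node_hz
    )


def band_energies(
    wp: WPDecomposition, bands: BandMap | None = None
) -> dict[str, np.ndarray]:
    """Aggregate node energies into rhythm bands.

    Every band edge must fall on the terminal-node grid; a node contributes
    to the band whose interval contains it, so band energies are additive
    and sum (with out-of-band nodes) to the total signal energy.
    """
    bands = bands or BandMap()
    bw = wp.bandwidth_hz
    for name, (lo, hi) in bands:
        for edge in (lo, hi):
            if abs(edge / bw - round(edge / bw)) > 1e-9:
                raise ConfigError(
                    f"band {name!r} edge {edge} Hz is not on the {bw} Hz node grid"
                )
    energies = wp.node_energies()
    out: dict[str, np.ndarray] = {}
    for name, (lo, hi) in bands:
        idx = [
            k for k, (nlo, nhi) in enumerate(wp.node_hz)
            if nlo >= lo - 1e-9 and nhi <= hi + 1e-9
        ]
        out[name] = energies[..., idx].sum(axis=-1)
    return out


def energy_ratios(
    energies: dict[str, np.ndarray]
) -> tuple[dict[str, np.ndarray], np.ndarray]:
    """Band ratios over the in-range total, and the beta/(theta+alpha) index.

    Degenerate (all-zero-energy) entries yield NaN ratios; a zero
    theta+alpha denominator flags beta/(theta+alpha) as NaN (undefined)
    without failing.
    """
    names = list(energies)
    stack = np.stack([np.asarray(energies[n], dtype=float) for n in names], axis=-1)
    total = stack.sum(axis=-1)
    degenerate = total <= 0
    if np.any(degenerate):
        logger.warning("%d degenerate (zero-energy) entries flagged", degenerate.sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        ratios = {
            n: np.where(degenerate, np.nan, stack[..., i] / np.where(total > 0, total, 1.0))
            for i, n in enumerate(names)
        }
        denom = energies.get("theta", 0) + energies.get("alpha", 0)
        denom = np.asarray(denom, dtype=float)
        bta = np.where(
            (denom > 0) & ~degenerate,
            np.asarray(energies.get("beta", np.nan), dtype=float)
            / np.where(denom > 0, denom, 1.0),
            np.nan,
        )
    return ratios, bta


@dataclass
class BandEnergySummary:
    """Per-epoch, per-channel band energies, ratios and labels."""

    energies: dict[str, np.ndarray]      # band -> (n_epochs, n_channels)
    ratios: dict[str, np.ndarray]
    beta_theta_alpha: np.ndarray         # (n_epochs, n_channels), NaN = undefined
    labels: np.ndarray                   # (n_epochs,)
    channels: list[str]
    bands: BandMap

    @property
    def n_epochs(self) -> int:
        return len(self.labels)


def band_energy_table(
    epochs: EpochSet,
    bands: BandMap | None = None,
    wavelet: str = "db4",
    target_bandwidth_hz: float = 2.0,
) -> BandEnergySummary:
    """Decompose every epoch x channel and tabulate band energies/ratios."""
    bands = bands or BandMap()
    wp = wp_decompose(epochs.epochs, epochs.fs, wavelet, target_bandwidth_hz)
    E = band_energies(wp, bands)
    ratios, bta = energy_ratios(E)
    return BandEnergySummary(
        energies=E, ratios=ratios, beta_theta_alpha=bta,
        labels=epochs.labels.copy(), channels=list(epochs.channels), bands=bands,
    )


@dataclass
class ElectrodeMap:
    """Per-electrode phase-mean band values plus an optional 2-D grid."""

    band: str
    phase: str
    values: dict[str, float]
    argmax: str
    grid: np.ndarray | None = None       # (res, res), NaN outside the head disk
    grid_x: np.ndarray | None = None
    grid_y: np.ndarray | None = None


def electrode_map(
    summary: BandEnergySummary,
    phase: str,
    band: str = "beta",
    use_ratio: bool = False,
    interpolate: bool = False,
    resolution: int = 32,
    idw_power: float = 2.0,
) -> ElectrodeMap:
    """Mean band energy (or ratio) per electrode across one phase's epochs.

    The argmax electrode is reported with ties broken by channel order;
    with ``interpolate=True`` an inverse-distance-weighted grid over the
    projected head disk is attached for plotting.
    """
    for ch in summary.channels:
        if ch not in ELECTRODE_COORDS:
            raise ConfigError(f"unknown electrode label {ch!r}")
    mask = summary.labels == phase
    if not mask.any():
        raise EmptySelectionError(f"no epochs labelled {phase!r}")
    table = summary.ratios[band] if use_ratio else summary.energies[band]
    per_channel = np.nanmean(table[mask], axis=0)
    values = {ch: float(v) for ch, v in zip(summary.channels, per_channel)}
    argmax = summary.channels[int(np.argmax(per_channel))]

    grid = gx = gy = None
    if interpolate:
        pts = np.array([ELECTRODE_COORDS[ch] for ch in summary.channels])
        vals = per_channel
        axis = np.linspace(-1, 1, resolution)
        gx, gy = np.meshgrid(axis, axis)
        d2 = (gx[..., None] - pts[:, 0]) ** 2 + (gy[..., None] - pts[:, 1]) ** 2
        w = 1.0 / np.maximum(d2 ** (idw_power / 2), 1e-12)
        grid = (w * vals).sum(-1) / w.sum(-1)
        grid[gx ** 2 + gy ** 2 > 1.0] = np.nan

    return ElectrodeMap(
        band=band, phase=phase, values=values, argmax=argmax,
        grid=grid, grid_x=gx, grid_y=gy,
    )
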