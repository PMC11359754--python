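"""Synthetic 14-channel EEG with the statistical structure the analysis assumes.

Each channel is a 1/f (pink) background plus band-limited Gaussian
oscillations in the four rhythm bands, all drawn from one seeded
generator.  Two planted effects mirror what the analysis is built to
detect during turning maneuvers:

* a multiplicative beta-amplitude boost at T7 during left turns and at
  T8 during right turns (the lateralized temporal beta surge), and
* a broadband white-noise "complexity" increment on every channel during
  any turn (raising signal irregularity, hence both entropies).

Eye blinks (smooth high-amplitude pulses on AF3/AF4) and EMG bursts
(high-frequency packets on temporal/frontal-temporal channels) provide
artifacts for the ICA stage to find.  Output is bit-reproducible for a
fixed config and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .band_features import DEFAULT_BANDS
from .errors import PreconditionError
from .preprocess import bandpass_array
from .signal_io import CANONICAL_CHANNELS, Event, EventTable, Recording

#: Default phase schedule: cruise/turn blocks honouring a >= 10 s cruise
#: separation between consecutive turns.
DEFAULT_SCHEDULE: tuple[tuple[str, float], ...] = (
    ("cruise", 60.0),
    ("turn_left", 20.0),
    ("cruise", 60.0),
    ("turn_right", 20.0),
    ("cruise", 60.0),
)

#: Baseline per-band RMS amplitudes in microvolts (delta > alpha > theta >
#: beta ordering consistent with descriptive EEG amplitude tables).
DEFAULT_BAND_AMPLITUDES: dict[str, float] = {
    "delta": 8.0, "theta": 6.0, "alpha": 10.0, "beta": 4.0,
}

EMG_CHANNELS = ("T7", "T8", "F7", "F8")
EMG_BURST_S = 0.3


@dataclass
class SyntheticConfig:
    """Generator parameters; defaults are the package's study conditions."""

    fs: float = 128.0
    schedule: tuple[tuple[str, float], ...] = DEFAULT_SCHEDULE
    band_amplitudes: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BAND_AMPLITUDES)
    )
    beta_boost: float = 2.0          # T7 amplitude factor in turn_left, T8 in turn_right
    complexity_boost: float = 2.0    # broadband white RMS (uV) added during turns
    pink_amplitude: float = 10.0     # 1/f background RMS (uV)
    blink_rate_per_min: float = 4.0
    blink_amplitude: float = 150.0
    blink_width_s: float = 0.4
    emg_rate_per_min: float = 2.0
    emg_amplitude: float = 20.0
    seed: int = 0

    def validate(self) -> None:
        if self.fs <= 0:
            raise PreconditionError("fs must be positive")
        if self.beta_boost < 1:
            raise PreconditionError("beta_boost must be >= 1")
        if self.complexity_boost < 0 or self.pink_amplitude < 0:
            raise PreconditionError("amplitudes must be >= 0")
        if any(a < 0 for a in self.band_amplitudes.values()):
            raise PreconditionError("band amplitudes must be >= 0")
        if not self.schedule or any(d <= 0 for _, d in self.schedule):
            raise PreconditionError("schedule durations must be positive")


def balanced_schedule(
    epochs_per_class: int = 1500, window_s: float = 2.0, overlap_frac: float = 0.5
) -> tuple[tuple[str, float], ...]:
    """A long alternating cruise/turn schedule yielding a balanced epoch pool.

    Block lengths are chosen so sliding windows (default 2 s, 50% overlap)
    cut exactly ``epochs_per_class`` cruise and turn epochs, turn direction
    alternating left/right, with cruise separations well above 10 s.
    """
    hop = window_s * (1.0 - overlap_frac)
    per_block = 20                                  # epochs per block
    block_s = window_s + hop * (per_block - 1)      # 21 s at the defaults
    n_blocks, rem = divmod(epochs_per_class, per_block)
    sched: list[tuple[str, float]] = []
    for i in range(n_blocks):
        turn = "turn_left" if i % 2 == 0 else "turn_right"
        sched.append(("cruise", block_s))
        sched.append((turn, block_s))
    if rem:
        sched.append(("cruise", window_s + hop * (rem - 1)))
        sched.append(
            ("turn_left" if n_blocks % 2 == 0 else "turn_right",
             window_s + hop * (rem - 1))
        )
    return tuple(sched)


def blink_template(width_s: float, amplitude: float, fs: float) -> np.ndarray:
    """Smooth unimodal eye-blink pulse: a squared half-sine.

    Peak equals ``amplitude`` exactly (the sample count is forced odd so
    the midpoint is hit); support is ~``width_s`` seconds.
    """
    if width_s <= 0:
        raise PreconditionError("blink width must be positive")
    n = max(int(round(width_s * fs)), 3)
    if n % 2 == 0:
        n += 1
    t = np.arange(n) / (n - 1)
    return amplitude * np.sin(np.pi * t) ** 2


def _pink_noise(rng: np.random.Generator, n: int, fs: float, rms: float) -> np.ndarray:
    """1/f-amplitude-spectrum Gaussian noise, scaled to the requested RMS."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    shaping = np.zeros_like(freqs)
    nonzero = freqs > 0
    shaping[nonzero] = 1.0 / np.sqrt(freqs[nonzero])
    x = np.fft.irfft(spec * shaping, n)
    sd = x.std()
    return x * (rms / sd) if sd > 0 else x


def _band_noise(
    rng: np.random.Generator, n: int, fs: float, lo: float, hi: float
) -> np.ndarray:
    """Unit-RMS Gaussian noise band-limited by the package's FIR band-pass."""
    x = bandpass_array(rng.standard_normal(n), fs, lo, hi)
    sd = x.std()
    return x / sd if sd > 0 else x


def _phase_masks(
    schedule: tuple[tuple[str, float], ...], fs: float
) -> tuple[int, dict[str, np.ndarray], EventTable]:
    """Total samples, per-phase boolean masks, and the mirroring event table."""
    events = []
    onset = 0.0
    for phase, dur in schedule:
        events.append(Event(onset, dur, phase))
        onset += dur
    n = int(round(onset * fs))
    masks = {p: np.zeros(n, dtype=bool) for p in ("cruise", "turn_left", "turn_right")}
    for ev in events:
        s0 = int(round(ev.onset_s * fs))
        s1 = int(round((ev.onset_s + ev.duration_s) * fs))
        masks[ev.phase][s0:s1] = True
    return n, masks, EventTable(events)


def generate(config: SyntheticConfig | None = None, **overrides) -> tuple[Recording, EventTable]:
    """Generate a 14-channel recording and its event table.

    Keyword overrides are applied on top of ``config`` (or the defaults),
    e.g. ``generate(seed=7, beta_boost=1.0)``.
    """
    config = replace(config or SyntheticConfig(), **overrides)
    config.validate()
    rng = np.random.default_rng(config.seed)
    fs = config.fs
    n, masks, events = _phase_masks(config.schedule, fs)
    turn_mask = masks["turn_left"] | masks["turn_right"]

    data = np.zeros((len(CANONICAL_CHANNELS), n))
    bands = {name: DEFAULT_BANDS[name] for name in config.band_amplitudes}

    for ci, ch in enumerate(CANONICAL_CHANNELS):
        sig = _pink_noise(rng, n, fs, config.pink_amplitude)
        for name, (lo, hi) in bands.items():
            comp = _band_noise(rng, n, fs, lo, hi) * config.band_amplitudes[name]
            if name == "beta":
                if ch == "T7":
                    comp = comp * (1.0 + (config.beta_boost - 1.0) * masks["turn_left"])
                elif ch == "T8":
                    comp = comp * (1.0 + (config.beta_boost - 1.0) * masks["turn_right"])
            sig += comp
        if config.complexity_boost > 0:
            sig += config.complexity_boost * rng.standard_normal(n) * turn_mask
        data[ci] = sig

    _add_blinks(rng, data, config, n)
    _add_emg(rng, data, config, n)

    return Recording(fs=fs, channels=list(CANONICAL_CHANNELS), data=data), events


def _add_blinks(
    rng: np.random.Generator, data: np.ndarray, config: SyntheticConfig, n: int
) -> None:
    if config.blink_rate_per_min <= 0 or config.blink_amplitude <= 0:
        return
    fs = config.fs
    template = blink_template(config.blink_width_s, config.blink_amplitude, fs)
    minutes = n / fs / 60.0
    count = rng.poisson(config.blink_rate_per_min * minutes)
    starts = np.sort(rng.integers(0, max(n - len(template), 1), size=count))
    rows = [CANONICAL_CHANNELS.index("AF3"), CANONICAL_CHANNELS.index("AF4")]
    for s0 in starts:
        seg = slice(s0, s0 + len(template))
        for r in rows:                      # shared VEOG source, same polarity
            data[r, seg] += template[: data.shape[1] - s0]


def _add_emg(
    rng: np.random.Generator, data: np.ndarray, config: SyntheticConfig, n: int
) -> None:
    if config.emg_rate_per_min <= 0 or config.emg_amplitude <= 0:
        return
    fs = config.fs
    burst_len = max(int(round(EMG_BURST_S * fs)), 4)
    window = np.hanning(burst_len)
    minutes = n / fs / 60.0
    hi = min(45.0, fs / 2 - 1.0)
    for ch in EMG_CHANNELS:
        r = CANONICAL_CHANNELS.index(ch)
        count = rng.poisson(config.emg_rate_per_min * minutes)
        starts = rng.integers(0, max(n - burst_len, 1), size=count)
        for s0 in starts:
            burst = bandpass_array(
                rng.standard_normal(burst_len), fs, 20.0, hi, transition_hz=4.0
            )
            sd = burst.std()
            if sd > 0:
                burst = burst / sd * config.emg_amplitude
            data[r, s0:s0 + burst_len] += (burst * window)[: n - s0]
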