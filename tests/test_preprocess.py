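"""FIR filtering, ICA artifact rejection and superimposed averaging."""

import numpy as np
import pytest

import neuroload as nl
from neuroload.errors import (
    EmptySelectionError,
    InputTooShortError,
    PreconditionError,
)
from neuroload.preprocess import (
    FilterSpec,
    bandpass_fir,
    design_fir,
    flag_artifact_components,
    ica_decompose,
    remove_components,
    superimposed_average,
)
from neuroload.signal_io import EpochSet, Recording


def tone(freq, fs=128.0, dur=60.0, amp=1.0):
    t = np.arange(int(fs * dur)) / fs
    return amp * np.sin(2 * np.pi * freq * t)


def rms(x):
    return np.sqrt(np.mean(x**2))


def steady_state_gain_db(freq, fs=128.0):
    """Filter gain on a long tone, excluding start/end transients."""
    x = tone(freq, fs)
    rec = Recording(fs, ["A"], x[None, :])
    out = bandpass_fir(rec).data[0]
    taps = design_fir(FilterSpec(), fs)
    core = slice(len(taps), len(x) - len(taps))
    return 20 * np.log10(rms(out[core]) / rms(x[core]))


class TestBandpass:
    def test_passband_10hz_within_1db(self):
        assert abs(steady_state_gain_db(10.0)) < 1.0

    def test_stopband_50hz_attenuated_40db(self):
        assert steady_state_gain_db(50.0) < -40.0

    def test_dc_removed(self):
        rec = Recording(128.0, ["A"], np.full((1, 4000), 5.0))
        out = bandpass_fir(rec)
        assert np.abs(out.data).max() < 0.1  # 5 uV DC -> ~0

    def test_linearity(self, rng):
        x = rng.standard_normal(4096)
        y = rng.standard_normal(4096)
        spec = FilterSpec()
        fa = bandpass_fir(Recording(128.0, ["A"], x[None]), spec).data
        fb = bandpass_fir(Recording(128.0, ["A"], y[None]), spec).data
        fab = bandpass_fir(Recording(128.0, ["A"], (3 * x - 2 * y)[None]), spec).data
        np.testing.assert_allclose(fab, 3 * fa - 2 * fb, atol=1e-9)

    def test_invalid_band_rejected(self):
        with pytest.raises(PreconditionError):
            design_fir(FilterSpec(low_hz=50.0, high_hz=40.0), fs=128.0)

    def test_too_short_signal_rejected(self):
        rec = Recording(128.0, ["A"], np.zeros((1, 16)))
        with pytest.raises(InputTooShortError):
            bandpass_fir(rec, FilterSpec(low_hz=1.0, high_hz=40.0, transition_hz=0.5))


class TestICA:
    def test_recovers_independent_sources(self, rng):
        n = 5000
        s1 = np.sign(np.sin(2 * np.pi * 3 * np.arange(n) / 128))  # square
        s2 = rng.uniform(-1, 1, n)                                # uniform noise
        A = np.array([[1.0, 0.6], [0.4, 1.0]])
        X = A @ np.vstack([s1, s2])
        rec = Recording(128.0, ["A", "B"], X)
        ica = ica_decompose(rec, seed=0)
        corr = np.abs(np.corrcoef(np.vstack([ica.sources, [s1, s2]]))[:2, 2:])
        # each true source matched by some component up to sign/permutation
        assert corr.max(axis=0).min() > 0.95

    def test_deterministic_for_fixed_seed(self, rng):
        X = rng.standard_normal((3, 2000))
        rec = Recording(128.0, ["A", "B", "C"], X)
        m1 = ica_decompose(rec, seed=4).mixing
        m2 = ica_decompose(rec, seed=4).mixing
        np.testing.assert_array_equal(m1, m2)

    def test_single_channel_rejected(self):
        rec = Recording(128.0, ["A"], np.random.default_rng(0).standard_normal((1, 512)))
        with pytest.raises(PreconditionError):
            ica_decompose(rec, seed=0)

    def test_reconstruction_identity_when_nothing_flagged(self, rng):
        X = rng.standard_normal((4, 3000))
        rec = Recording(128.0, ["A", "B", "C", "D"], X)
        ica = ica_decompose(rec, seed=1)
        np.testing.assert_allclose(ica.reconstruct(), X, atol=1e-8)
        out = remove_components(ica)          # no flags -> identity
        np.testing.assert_allclose(out.data, X, atol=1e-8)

    def test_reference_self_correlation_flags(self, rng):
        X = rng.standard_normal((3, 4000))
        rec = Recording(128.0, ["A", "B", "C"], X)
        ica = ica_decompose(rec, seed=2)
        flagged = flag_artifact_components(ica, rec, reference=ica.sources[1])
        assert any("EOG" in reason for reason in flagged.flags.values())

    def test_all_flagged_refused(self, rng):
        X = rng.standard_normal((2, 1000))
        rec = Recording(128.0, ["A", "B"], X)
        ica = ica_decompose(rec, seed=0)
        ica.flags = {0: "EOG", 1: "EMG"}
        with pytest.raises(PreconditionError):
            remove_components(ica)


class TestBlinkCleaning:
    def test_planted_blinks_flagged_and_removed(self):
        rec, _ = nl.generate(seed=5)
        rec0, _ = nl.generate(seed=5, blink_amplitude=0.0)
        i = rec.channels.index("AF3")
        blink_train = rec.data[i] - rec0.data[i]
        filt = bandpass_fir(rec)
        ica = flag_artifact_components(ica_decompose(filt, seed=0), filt)
        assert any("EOG" in r for r in ica.flags.values())
        clean = remove_components(ica)
        pre = abs(np.corrcoef(filt.data[i], blink_train)[0, 1])
        post = abs(np.corrcoef(clean.data[i], blink_train)[0, 1])
        assert pre > 0.5          # blinks dominate the frontal channel
        assert post < 0.1

    def test_artifact_free_recording_yields_no_flags(self):
        rec, _ = nl.generate(
            seed=6, blink_rate_per_min=0.0, emg_rate_per_min=0.0,
            schedule=(("cruise", 60.0),),
        )
        filt = bandpass_fir(rec)
        ica = flag_artifact_components(ica_decompose(filt, seed=0), filt)
        assert ica.flags == {}


class TestSuperimposedAverage:
    def _epochs(self, arrays, labels, fs=128.0):
        return EpochSet(np.stack(arrays), np.array(labels, dtype=object),
                        fs, arrays[0].shape[-1] / fs, ["A"])

    def test_single_epoch_identity(self, rng):
        x = rng.standard_normal((1, 64))
        eps = self._epochs([x], ["cruise"])
        np.testing.assert_array_equal(superimposed_average(eps, "cruise"), x)

    def test_antisymmetric_pair_cancels(self, rng):
        x = rng.standard_normal((1, 64))
        eps = self._epochs([x, -x], ["cruise", "cruise"])
        np.testing.assert_allclose(superimposed_average(eps, "cruise"), 0, atol=1e-12)

    def test_noise_shrinks_as_sqrt_n(self, rng):
        template = np.sin(2 * np.pi * 5 * np.arange(128) / 128.0)[None, :]
        sigma = 1.0
        n = 100
        eps = self._epochs(
            [template + sigma * rng.standard_normal(template.shape) for _ in range(n)],
            ["cruise"] * n,
        )
        err = superimposed_average(eps, "cruise") - template
        expected = sigma / np.sqrt(n)
        assert np.sqrt(np.mean(err**2)) == pytest.approx(expected, rel=0.35)

    def test_empty_phase_selection_rejected(self, rng):
        eps = self._epochs([rng.standard_normal((1, 32))], ["cruise"])
        with pytest.raises(EmptySelectionError):
            superimposed_average(eps, "turn_left")
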