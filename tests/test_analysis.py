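"""Analysis-layer tests on constructed signals."""

import numpy as np
import pytest
from fractions import Fraction

from twomass import analysis
from twomass.fixtures_io import FixtureSpec, synth_signal

FS = 40000.0


def sig(components, duration=1.0, noise=0.0, seed=0):
    return synth_signal(FixtureSpec(components=tuple(components), noise_rms=noise,
                                    fs=FS, duration=duration, seed=seed))


class TestEstimateF0:
    def test_pure_tone(self):
        f0 = analysis.estimate_f0(sig([(180.0, 1.0, 0.0)]), FS)
        assert f0 == pytest.approx(180.0, abs=0.1)

    def test_strong_subharmonic_halves_f0(self):
        """A 0.3-amplitude component at 90 Hz makes the true period 1/90 s."""
        f0 = analysis.estimate_f0(sig([(180.0, 1.0, 0.0), (90.0, 0.3, 0.4)]), FS)
        assert f0 == pytest.approx(90.0, rel=0.01)

    def test_weak_subharmonic_does_not_halve_f0(self):
        f0 = analysis.estimate_f0(sig([(180.0, 1.0, 0.0), (90.0, 0.05, 0.4)]), FS)
        assert f0 == pytest.approx(180.0, rel=0.01)

    def test_constant_series_has_no_f0(self):
        assert analysis.estimate_f0(np.full(8000, 1.23), FS) is None

    def test_noise_has_no_f0(self):
        rng = np.random.default_rng(0)
        assert analysis.estimate_f0(rng.standard_normal(40000), FS) is None


class TestSpl:
    def test_reference_pressure_is_zero_db(self):
        x = sig([(100.0, 20e-6 * np.sqrt(2.0), 0.0)])
        assert analysis.spl(x, FS) == pytest.approx(0.0, abs=0.01)

    def test_one_pascal_rms(self):
        x = sig([(100.0, np.sqrt(2.0), 0.0)])
        assert analysis.spl(x, FS) == pytest.approx(93.98, abs=0.01)

    def test_tenfold_amplitude_adds_20_db(self):
        a = analysis.spl(sig([(150.0, 0.2, 0.0)]), FS)
        b = analysis.spl(sig([(150.0, 2.0, 0.0)]), FS)
        assert b - a == pytest.approx(20.0, abs=1e-9)

    def test_zero_window_is_minus_infinity(self):
        assert analysis.spl(np.zeros(4000), FS) == -np.inf

    def test_short_window_rejected(self):
        with pytest.raises(ValueError):
            analysis.spl(np.ones(100), FS)


class TestSpectrum:
    def test_single_tone_peak_location(self):
        spec = analysis.spectrum(sig([(450.0, 1.0, 0.0)]), FS)
        assert spec.resolution <= 10.0
        peak = spec.frequency_hz[np.argmax(spec.magnitude_db)]
        assert abs(peak - 450.0) <= spec.resolution / 2 + 1e-9

    def test_subharmonic_comb_shows_90_hz_spacing(self):
        comps = [(90.0 * k, 1.0, 0.1 * k) for k in range(1, 6)]
        spec = analysis.spectrum(sig(comps), FS)
        for k in range(1, 6):
            i = int(round(90.0 * k / spec.resolution))
            local = spec.magnitude_db[i - 1 : i + 2].max()
            floor = np.median(spec.magnitude_db)
            assert local > floor + 20.0

    def test_white_noise_is_flat_across_a_decade(self):
        rng = np.random.default_rng(42)
        spec = analysis.spectrum(rng.standard_normal(int(4 * FS)), FS)
        f = spec.frequency_hz
        bands = [(100 * 10 ** (i / 4), 100 * 10 ** ((i + 1) / 4)) for i in range(4)]
        levels = [
            10 * np.log10(spec.power[(f >= lo) & (f < hi)].mean()) for lo, hi in bands
        ]
        assert max(levels) - min(levels) < 3.0

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            analysis.spectrum(np.zeros(100), FS, nfft=8192)


class TestSubharmonicIndex:
    def test_pure_harmonic_comb_is_near_zero(self):
        comps = [(180.0 * k, 1.0 / k, 0.0) for k in range(1, 5)]
        spec = analysis.spectrum(sig(comps), FS)
        assert analysis.subharmonic_index(spec, 180.0) < 0.02

    def test_equal_power_half_harmonics_near_one(self):
        spec = analysis.spectrum(sig([(90.0, 1.0, 0.0), (180.0, 1.0, 0.3)]), FS)
        assert analysis.subharmonic_index(spec, 180.0) == pytest.approx(1.0, abs=0.1)

    def test_gain_invariance(self):
        x = sig([(90.0, 0.4, 0.0), (180.0, 1.0, 0.0), (270.0, 0.2, 0.0)])
        a = analysis.subharmonic_index(analysis.spectrum(x, FS), 180.0)
        b = analysis.subharmonic_index(analysis.spectrum(100.0 * x, FS), 180.0)
        assert a == pytest.approx(b, rel=1e-9)

    def test_f0_below_resolution_rejected(self):
        spec = analysis.spectrum(sig([(180.0, 1.0, 0.0)]), FS)
        with pytest.raises(ValueError):
            analysis.subharmonic_index(spec, 0.5 * spec.resolution)


class TestEntrainmentRatio:
    def test_published_lock_is_two_to_five(self):
        """180 Hz against a 450 Hz resonance: 2:5 with a 90 Hz difference tone."""
        ratio, residual, diff = analysis.entrainment_ratio(180.0, 450.0, max_order=8)
        assert ratio == Fraction(2, 5)
        assert residual == 0.0
        assert diff == pytest.approx(90.0)

    def test_unison(self):
        ratio, residual, _ = analysis.entrainment_ratio(450.0, 450.0)
        assert ratio == Fraction(1, 1)
        assert residual == 0.0

    def test_robust_to_slight_detuning(self):
        ratio, residual, _ = analysis.entrainment_ratio(181.0, 450.0, max_order=8)
        assert ratio == Fraction(2, 5)
        assert 0 < residual < 0.01

    def test_reciprocal_symmetry(self):
        r_ab, _, _ = analysis.entrainment_ratio(180.0, 450.0)
        r_ba, _, _ = analysis.entrainment_ratio(450.0, 180.0)
        assert r_ab * r_ba == 1

    def test_input_validation(self):
        with pytest.raises(ValueError):
            analysis.entrainment_ratio(-1.0, 450.0)
        with pytest.raises(ValueError):
            analysis.entrainment_ratio(180.0, 450.0, max_order=0)


def pair(f1, f2=None, am=None, duration=2.0, phase=0.7):
    """Two correlated series for the regime classifier."""
    t = np.arange(int(duration * FS)) / FS
    y1 = np.sin(2 * np.pi * f1 * t)
    y2 = 0.8 * np.sin(2 * np.pi * f1 * t + phase)
    if f2 is not None:
        y1 = y1 + 0.5 * np.sin(2 * np.pi * f2 * t + 0.3)
        y2 = y2 + 0.4 * np.sin(2 * np.pi * f2 * t + 1.1)
    if am is not None:
        mod = 1.0 + am * np.sign(np.sin(2 * np.pi * (f1 / 2) * t + 1e-6))
        y1, y2 = y1 * mod, y2 * mod
    return y1, y2


class TestClassifyRegime:
    def test_sinusoid_pair_is_limit_cycle(self):
        y1, y2 = pair(180.0)
        lab = analysis.classify_regime(y1, y2, FS, 180.0)
        assert lab.label == "limit_cycle"
        assert lab.n_clusters == 1

    def test_quasiperiodic_pair_is_torus(self):
        y1, y2 = pair(180.0, f2=171.0)
        lab = analysis.classify_regime(y1, y2, FS, 180.0)
        assert lab.label == "torus_or_subharmonic"

    def test_period_two_has_two_clusters(self):
        y1, y2 = pair(180.0, am=0.3)
        lab = analysis.classify_regime(y1, y2, FS, 180.0)
        assert lab.label == "torus_or_subharmonic"
        assert lab.n_clusters == 2

    def test_silence_detected(self):
        z = np.zeros(int(FS))
        lab = analysis.classify_regime(z, z, FS, None)
        assert lab.label == "silent"

    def test_invariance_to_gain_and_shift(self):
        y1, y2 = pair(180.0, f2=171.0)
        a = analysis.classify_regime(y1, y2, FS, 180.0)
        k = 1234
        b = analysis.classify_regime(50.0 * y1[k:], 50.0 * y2[k:], FS, 180.0)
        assert a.label == b.label


class TestDisplacementMetrics:
    def test_sine_amplitude_recovered(self):
        x = sig([(180.0, 2.5e-3, 0.0)])
        assert analysis.displacement_metrics(x) == pytest.approx(2.5e-3, rel=1e-3)

    def test_constant_offset_is_zero(self):
        assert analysis.displacement_metrics(np.full(4000, 0.7)) == 0.0

    def test_amplitude_modulated_sine_averages_cycles(self):
        t = np.arange(int(FS)) / FS
        x = (1.0 + 0.25 * np.sin(2 * np.pi * 5.0 * t)) * np.sin(2 * np.pi * 180.0 * t)
        m = analysis.displacement_metrics(x)
        assert m == pytest.approx(1.0, abs=0.03)  # mean of per-cycle amplitudes
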