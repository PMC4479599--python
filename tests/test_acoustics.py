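import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lombardlab import acoustics, call_synth, stimuli
from lombardlab.acoustics import MeasurementError, NoiseStats
from lombardlab.audio_io import AudioClip, CallAnnotation, Syllable, P_REF
from lombardlab.call_synth import SyllableSpec


def tone(freq=2000.0, duration=1.0, rate=48000, level_db=70.0):
    return call_synth.synth_syllable(
        SyllableSpec("whistle", duration, freq, freq, [1.0], level_db), rate)


class TestLevels:
    def test_rms_of_unit_sine(self):
        t = np.arange(48000) / 48000
        clip = AudioClip(np.sin(2 * np.pi * 1000 * t), 48000)
        assert acoustics.rms(clip) == pytest.approx(1 / np.sqrt(2), rel=1e-4)

    @pytest.mark.parametrize("pa,db", [(20e-6, 0.0), (0.02, 60.0), (2.0, 100.0)])
    def test_db_conversion(self, pa, db):
        assert acoustics.to_db_spl(pa) == pytest.approx(db, abs=1e-9)

    def test_nonpositive_pressure_rejected(self):
        with pytest.raises(MeasurementError):
            acoustics.to_db_spl(0.0)

    def test_noise_subtraction_arithmetic(self):
        clip = AudioClip(np.full(100, np.sqrt(5e-6)), 48000)
        p, reliable = acoustics.noise_subtracted_rms(clip, 1e-6)
        assert p == pytest.approx(2e-3, rel=1e-9)
        assert reliable

    def test_zero_noise_is_identity(self):
        clip = tone()
        p, _ = acoustics.noise_subtracted_rms(clip, 0.0)
        assert p == pytest.approx(acoustics.rms(clip), rel=1e-12)

    def test_over_subtraction_flagged_not_raised(self):
        clip = AudioClip(np.full(100, 1e-4), 48000)
        p, reliable = acoustics.noise_subtracted_rms(clip, 1.0)
        assert not reliable
        assert p > 0

    def test_trial_source_level_linear_mean(self):
        # mean(0.01, 0.03) = 0.02 Pa -> 60 dB
        assert acoustics.trial_source_level([0.01, 0.03]) == pytest.approx(60.0, abs=1e-9)

    def test_identical_levels_pass_through(self):
        assert acoustics.trial_source_level([0.02, 0.02]) == pytest.approx(60.0, abs=1e-9)

    def test_linear_mean_dominates_db_mean(self):
        rng = np.random.default_rng(0)
        pas = rng.uniform(0.001, 0.1, size=20)
        linear = acoustics.trial_source_level(list(pas))
        db_domain = np.mean([acoustics.to_db_spl(p) for p in pas])
        assert linear >= db_domain  # Jensen

    def test_empty_trial_rejected(self):
        with pytest.raises(MeasurementError):
            acoustics.trial_source_level([])


class TestTrialNoiseLevel:
    def test_recovers_set_level(self):
        bed = stimuli.band_limited_noise(stimuli.get_treatment("A"), 8.0, seed=2)
        level, stats = acoustics.trial_noise_level(bed, [])
        assert level == pytest.approx(64.0, abs=0.25)
        assert stats.mean_square > 0

    def test_window_overlapping_call_skipped(self):
        rng = np.random.default_rng(0)
        clip = AudioClip(rng.normal(0, 1e-3, 12 * 48000), 48000)
        clip.samples[: 3 * 48000] *= 100.0  # loud region under the call
        ann = CallAnnotation("c", "chirp", 0.0, 3.0, [])
        level, _ = acoustics.trial_noise_level(clip, [ann])
        quiet_db = acoustics.to_db_spl(1e-3)
        assert level == pytest.approx(quiet_db, abs=0.5)

    def test_short_trial_rejected(self):
        clip = AudioClip(np.random.default_rng(0).normal(size=48000), 48000)
        with pytest.raises(MeasurementError, match="shorter"):
            acoustics.trial_noise_level(clip, [])

    def test_fully_occupied_trial_rejected(self):
        clip = AudioClip(np.random.default_rng(0).normal(size=6 * 48000), 48000)
        ann = CallAnnotation("c", "CLC", 0.0, 6.0, [])
        with pytest.raises(MeasurementError, match="free"):
            acoustics.trial_noise_level(clip, [ann])


class TestAveragedPsd:
    def test_bin_spacing_matches_analysis_parameters(self):
        psd = acoustics.averaged_psd(tone())
        assert psd.bin_hz == pytest.approx(48000 / 4096, abs=1e-9)
        assert psd.bin_hz == pytest.approx(11.72, abs=0.005)

    def test_tone_argmax(self):
        psd = acoustics.averaged_psd(tone(2000.0))
        assert abs(psd.freqs[np.argmax(psd.power)] - 2000.0) <= psd.bin_hz

    def test_short_clip_single_segment_with_warning(self):
        clip = AudioClip(np.sin(2 * np.pi * 2000 * np.arange(500) / 48000), 48000)
        with pytest.warns(UserWarning, match="shorter"):
            psd = acoustics.averaged_psd(clip)
        assert psd.freqs[np.argmax(psd.power)] == pytest.approx(2000.0, abs=5 * psd.bin_hz)


class TestSubtractPsd:
    def test_zero_noise_identity(self):
        psd = acoustics.averaged_psd(tone())
        zero = acoustics.Psd(psd.freqs, np.zeros_like(psd.power),
                             psd.window_len, psd.overlap, psd.dft_len)
        out = acoustics.subtract_psd(psd, zero)
        assert np.allclose(out.power, psd.power)

    def test_self_subtraction_floors(self):
        psd = acoustics.averaged_psd(tone())
        out = acoustics.subtract_psd(psd, psd)
        assert np.all(out.power <= 1e-12 * psd.power.max() + 1e-30)

    def test_grid_mismatch_rejected(self):
        psd = acoustics.averaged_psd(tone())
        other = acoustics.Psd(psd.freqs + 1.0, psd.power,
                              psd.window_len, psd.overlap, psd.dft_len)
        with pytest.raises(MeasurementError):
            acoustics.subtract_psd(psd, other)

    def test_tone_in_noise_recovered_within_10pct(self):
        bed = stimuli.band_limited_noise(stimuli.get_treatment("D"), 4.0, seed=3)
        sig = tone(3000.0, 4.0, level_db=70.0)
        clean = acoustics.averaged_psd(sig)
        mixed = AudioClip(bed.samples + sig.samples, 48000)
        noise_psd = acoustics.averaged_psd(bed)
        sub = acoustics.subtract_psd(acoustics.averaged_psd(mixed), noise_psd)
        i = np.argmax(clean.power)
        assert sub.power[i] == pytest.approx(clean.power[i], rel=0.10)


class TestHarmonicPeaks:
    def test_stack_of_three(self):
        spec = SyllableSpec("whistle", 1.0, 1500.0, 1500.0, [1.0, 1.0, 1.0], 70.0)
        psd = acoustics.averaged_psd(call_synth.synth_syllable(spec))
        peaks = acoustics.harmonic_peaks(psd, 1500.0, 3)
        assert [p.k for p in peaks] == [1, 2, 3]
        for p, f in zip(peaks, (1500.0, 3000.0, 4500.0)):
            assert abs(p.freq_hz - f) <= psd.bin_hz

    def test_pure_tone_yields_only_fundamental(self):
        psd = acoustics.averaged_psd(tone(2000.0))
        peaks = acoustics.harmonic_peaks(psd, 2000.0, 3)
        assert [p.k for p in peaks] == [1]

    def test_tolerant_to_10pct_f0_error(self):
        spec = SyllableSpec("whistle", 1.0, 1500.0, 1500.0, [1.0, 1.0, 1.0], 70.0)
        psd = acoustics.averaged_psd(call_synth.synth_syllable(spec))
        a = acoustics.harmonic_peaks(psd, 1500.0, 3)
        b = acoustics.harmonic_peaks(psd, 1650.0, 3)
        assert [(p.k, p.freq_hz) for p in a] == [(p.k, p.freq_hz) for p in b]

    def test_silence_has_no_fundamental(self):
        rng = np.random.default_rng(0)
        psd = acoustics.averaged_psd(AudioClip(rng.normal(0, 1e-6, 48000), 48000))
        with pytest.raises(MeasurementError, match="fundamental"):
            acoustics.harmonic_peaks(psd, 2000.0, 3)

    def test_tilt_ratio_equal_densities(self):
        peaks = [acoustics.HarmonicPeak(1, 1500.0, 2.0), acoustics.HarmonicPeak(2, 3000.0, 2.0)]
        assert acoustics.tilt_ratio(peaks, 2) == 1.0

    def test_tilt_ratio_missing_harmonic_is_none(self):
        peaks = [acoustics.HarmonicPeak(1, 1500.0, 2.0)]
        assert acoustics.tilt_ratio(peaks, 3) is None


class TestSpectrumExtrema:
    def test_pure_tone_degenerate(self):
        psd = acoustics.averaged_psd(tone(2000.0))
        fmin, fpk, fmax = acoustics.spectrum_extrema(psd)
        assert fmin <= fpk <= fmax
        assert abs(fpk - 2000.0) <= 2 * psd.bin_hz
        assert fmax - fmin < 200.0

    def test_two_tones_span(self):
        clip = AudioClip(tone(2000.0).samples + tone(6000.0).samples, 48000)
        psd = acoustics.averaged_psd(clip)
        fmin, _, fmax = acoustics.spectrum_extrema(psd)
        assert fmin == pytest.approx(2000.0, abs=150.0)
        assert fmax == pytest.approx(6000.0, abs=150.0)

    def test_widening_monotone_in_edge_db(self):
        psd = acoustics.averaged_psd(tone(3000.0))
        spans = []
        for edge in (12.0, 24.0, 36.0):
            fmin, _, fmax = acoustics.spectrum_extrema(psd, edge_db=edge)
            spans.append(fmax - fmin)
        assert spans == sorted(spans)

    def test_flat_spectrum_rejected(self):
        psd = acoustics.Psd(np.arange(10.0), np.ones(10), 1024, 0.75, 4096)
        with pytest.raises(MeasurementError):
            acoustics.spectrum_extrema(psd)


class TestF0Measures:
    def test_constant_fundamental(self):
        clip = tone(1600.0, 1.0)
        ann = CallAnnotation("c", "CLC", 0.0, 1.0, [Syllable("whistle", 0.0, 1.0)])
        f0 = acoustics.f0_measures(clip, ann)
        bin_hz = 48000 / 4096
        assert f0.f0_peak_hz == pytest.approx(1600.0, abs=2 * bin_hz)
        assert f0.f0_min_hz == pytest.approx(1600.0, abs=2 * bin_hz)

    def test_sweep_contour_endpoints(self):
        spec = SyllableSpec("whistle", 1.0, 1500.0, 2500.0, [1.0], 70.0)
        clip = call_synth.synth_syllable(spec)
        ann = CallAnnotation("c", "CLC", 0.0, 1.0, [Syllable("whistle", 0.0, 1.0)])
        f0 = acoustics.f0_measures(clip, ann, search_band=(1000.0, 3000.0))
        bin_hz = 48000 / 4096
        truth = 1500.0 + 1000.0 * f0.contour_times_s
        assert abs(f0.contour_hz[0] - truth[0]) <= 2 * bin_hz
        assert abs(f0.contour_hz[-1] - truth[-1]) <= 2 * bin_hz

    def test_silent_clip_missing_values(self):
        clip = AudioClip(np.zeros(48000) + 1e-12, 48000)
        ann = CallAnnotation("c", "CLC", 0.0, 1.0, [Syllable("whistle", 0.0, 1.0)])
        f0 = acoustics.f0_measures(clip, ann)
        assert f0.f0_peak_hz is None or f0.contour_hz.size == 0


@given(st.lists(st.tuples(st.floats(0.02, 0.5), st.floats(0.0, 0.3)),
                min_size=1, max_size=6))
@settings(max_examples=50, deadline=None, derandomize=True)
def test_pause_identity_holds_for_any_layout(layout):
    """whole-call duration minus syllable durations equals the pause sum."""
    t, sylls, pause_total = 0.0, [], 0.0
    for dur, gap in layout:
        sylls.append(Syllable("whistle", t, t + dur))
        t += dur + gap
        pause_total += gap
    pause_total -= layout[-1][1]
    ann = CallAnnotation("c", "CLC", 0.0, sylls[-1].offset_s, sylls)
    whole, per = acoustics.durations(ann)
    assert whole - sum(per) == pytest.approx(pause_total, abs=1e-9)


class TestDurations:
    def test_example_arithmetic(self):
        ann = CallAnnotation("c", "CLC", 0.0, 0.25,
                             [Syllable("whistle", 0.0, 0.1), Syllable("whistle", 0.15, 0.25)])
        whole, per = acoustics.durations(ann)
        assert whole == pytest.approx(0.25)
        assert per == pytest.approx([0.1, 0.1])
        assert whole - sum(per) == pytest.approx(0.05)

    def test_chirp_milliseconds(self):
        ann = CallAnnotation("c", "chirp", 1.0, 1.0537, [Syllable("chirp", 1.0, 1.0537)])
        whole, _ = acoustics.durations(ann)
        assert whole == pytest.approx(0.0537, abs=1e-12)


class TestMeasureCall:
    def test_tilt_harmonic_by_call_type(self, rendered_clc, rendered_chirp):
        assert rendered_clc[2].tilt_harmonic == 3
        assert rendered_chirp[2].tilt_harmonic == 2

    def test_extrema_ordering(self, rendered_clc, rendered_chirp):
        for _, _, m in (rendered_clc, rendered_chirp):
            assert m.min_freq_hz <= m.peak_freq_hz <= m.max_freq_hz

    def test_clc_reports_whistle_measures(self, rendered_clc):
        m = rendered_clc[2]
        assert m.whistle_level_db is not None
        assert m.whistle_peak_hz is not None
        assert len(m.whistle_durations_s) == 4
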