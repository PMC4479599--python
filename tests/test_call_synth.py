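import copy

import numpy as np
import pytest

from lombardlab import acoustics, call_synth, stats
from lombardlab.call_synth import CallSpec, ResponseModel, SyllableSpec


class TestSynthSyllable:
    def test_pure_tone_peak_frequency(self):
        spec = SyllableSpec("whistle", 1.0, 2000.0, 2000.0, [1.0], 70.0)
        psd = acoustics.averaged_psd(call_synth.synth_syllable(spec))
        peak = psd.freqs[np.argmax(psd.power)]
        assert abs(peak - 2000.0) <= psd.bin_hz

    def test_power_weights_set_density_ratio(self):
        spec = SyllableSpec("whistle", 1.0, 2000.0, 2000.0, [1.0, 2.5], 70.0)
        psd = acoustics.averaged_psd(call_synth.synth_syllable(spec))
        peaks = acoustics.harmonic_peaks(psd, 2000.0, 2)
        assert acoustics.tilt_ratio(peaks, 2) == pytest.approx(2.5, rel=0.10)

    def test_duration_sample_count(self):
        # 53.7 ms at 48 kHz, the baseline control chirp duration
        spec = SyllableSpec("chirp", 0.0537, 8000.0, 11000.0, [1.0], 70.0)
        clip = call_synth.synth_syllable(spec, rate=48000)
        assert abs(clip.samples.size - 2578) <= 1

    def test_aliased_harmonics_dropped_with_warning(self, caplog):
        spec = SyllableSpec("whistle", 0.5, 20000.0, 20000.0, [1.0, 1.0], 70.0)
        with caplog.at_level("WARNING", logger="lombardlab.call_synth"):
            clip = call_synth.synth_syllable(spec, rate=48000)
        assert "aliased" in caplog.text
        psd = acoustics.averaged_psd(clip)
        assert psd.freqs[np.argmax(psd.power)] == pytest.approx(20000.0, abs=2 * psd.bin_hz)

    def test_level_is_exact(self):
        spec = SyllableSpec("whistle", 0.5, 1600.0, 1600.0, [1.0, 2.0], 73.0)
        clip = call_synth.synth_syllable(spec)
        assert acoustics.to_db_spl(acoustics.rms(clip)) == pytest.approx(73.0, abs=1e-9)


class TestSynthCall:
    def test_default_clc_has_five_syllables(self, clc_spec, rendered_clc):
        _, ann, _ = rendered_clc
        assert len(ann.syllables) == 5
        assert [s.type for s in ann.syllables] == ["chirp"] + ["whistle"] * 4

    def test_annotation_matches_rendered_extent(self, rendered_clc):
        clip, ann, _ = rendered_clc
        assert ann.onset_s == 0.0
        assert ann.offset_s == pytest.approx(clip.duration_s, abs=1e-12)

    def test_zero_pauses_duration_is_syllable_sum(self):
        syl = SyllableSpec("whistle", 0.3, 1600.0, 1600.0, [1.0], 70.0)
        spec = CallSpec("CLC", [syl, copy.deepcopy(syl)], [0.0])
        _, ann = call_synth.synth_call(spec)
        assert ann.duration_s == pytest.approx(0.6, abs=1e-9)

    def test_pause_identity(self, clc_spec, rendered_clc):
        _, ann, _ = rendered_clc
        whole, per_syl = acoustics.durations(ann)
        assert whole - sum(per_syl) == pytest.approx(sum(clc_spec.pauses_s), abs=1e-6)


class TestApplyResponse:
    def test_zero_delta_is_identity(self, clc_spec):
        out = call_synth.apply_response(clc_spec, 0.0, "broad", call_synth.CLC_RESPONSE)
        assert out == clc_spec

    def test_lombard_arithmetic(self, clc_spec):
        model = ResponseModel(lombard_slope=0.5)
        out = call_synth.apply_response(clc_spec, 22.0, "narrow", model)
        for before, after in zip(clc_spec.syllables, out.syllables):
            assert after.level_db - before.level_db == pytest.approx(11.0)

    def test_broadband_interaction_adds_slope(self, clc_spec):
        model = ResponseModel(lombard_slope=0.5, lombard_bw_interaction=0.1)
        out = call_synth.apply_response(clc_spec, 10.0, "broad", model)
        assert out.syllables[0].level_db - clc_spec.syllables[0].level_db == pytest.approx(6.0)

    def test_tilt_change_measured_end_to_end(self):
        # programmed third-harmonic ratio rises 2.5 -> 6 at delta = 22 dB
        syl = SyllableSpec("whistle", 0.9, 1600.0, 1600.0, [1.0, 0.5, 2.5], 76.0)
        base = CallSpec("CLC", [syl], [])
        model = ResponseModel(tilt_slope_per_db=(6.0 - 2.5) / 22.0)
        treated = call_synth.apply_response(base, 22.0, "narrow", model)
        assert call_synth.expected_tilt_ratio(treated) == pytest.approx(6.0, rel=1e-6)
        clip, ann = call_synth.synth_call(treated)
        m = acoustics.measure_call(clip, ann, acoustics.NoiseStats.silent())
        assert m.tilt_ratio == pytest.approx(6.0, rel=0.15)

    def test_negative_weights_clip_at_zero(self, caplog):
        syl = SyllableSpec("whistle", 0.5, 1600.0, 1600.0, [1.0, 1.0, 0.5], 70.0)
        base = CallSpec("CLC", [syl], [])
        model = ResponseModel(tilt_slope_per_db=-1.0)
        with caplog.at_level("WARNING", logger="lombardlab.call_synth"):
            out = call_synth.apply_response(base, 10.0, "narrow", model)
        assert out.syllables[0].harmonic_weights[2] == 0.0
        assert "clipping" in caplog.text

    def test_min_f0_shift_sign_by_bandwidth(self, clc_spec):
        model = call_synth.CLC_RESPONSE
        broad = call_synth.apply_response(clc_spec, 12.0, "broad", model)
        narrow = call_synth.apply_response(clc_spec, 12.0, "narrow", model)
        assert call_synth.true_f0_min(broad) < call_synth.true_f0_min(clc_spec)
        assert call_synth.true_f0_min(narrow) >= call_synth.true_f0_min(clc_spec)

    def test_negative_delta_rejected(self, clc_spec):
        with pytest.raises(ValueError):
            call_synth.apply_response(clc_spec, -1.0, "broad", call_synth.CLC_RESPONSE)


class TestSimulateTruth:
    def test_design_counts(self):
        cfg = call_synth.make_default_config(3, seed=0)
        truth = call_synth.simulate_truth(cfg)
        assert truth["trial_id"].nunique() == 36
        assert truth.groupby("subject")["trial_id"].nunique().eq(12).all()
        per_trial = truth.groupby(["trial_id", "call_type"]).size()
        assert per_trial.loc[:, "CLC"].eq(4).all()
        assert per_trial.loc[:, "chirp"].eq(6).all()

    def test_same_seed_identical(self):
        a = call_synth.simulate_truth(call_synth.make_default_config(2, seed=9))
        b = call_synth.simulate_truth(call_synth.make_default_config(2, seed=9))
        assert a.equals(b)

    def test_lombard_slope_monotone_in_treatment_level(self):
        levels = {}
        for slope in (0.2, 0.6):
            cfg = call_synth.make_default_config(3, seed=4)
            cfg.clc_model = ResponseModel(lombard_slope=slope)
            truth = call_synth.simulate_truth(cfg)
            sel = (truth.call_type == "CLC") & (truth.trial_type == "treatment")
            levels[slope] = truth.loc[sel, "level_db"].mean()
        assert levels[0.6] > levels[0.2]


@pytest.fixture(scope="module")
def small_experiment(tmp_path_factory):
    cfg = call_synth.make_default_config(1, seed=13, trial_s=30.0)
    cfg.subjects[0].clcs_per_trial = 2
    cfg.subjects[0].chirps_per_trial = 2
    out = tmp_path_factory.mktemp("exp")
    return cfg, call_synth.simulate_experiment(cfg, out)


class TestSimulateExperiment:
    def test_outputs_on_disk(self, small_experiment):
        cfg, exp = small_experiment
        wavs = sorted(p.name for p in exp["dir"].glob("*.wav"))
        assert len(wavs) == 12
        assert len(exp["manifest"]) == 12
        assert (exp["dir"] / "manifest.csv").exists()
        assert (exp["dir"] / "annotations.csv").exists()
        assert len(exp["truth"]) == 12 * 4

    def test_annotations_within_trials(self, small_experiment):
        cfg, exp = small_experiment
        for wav, anns in exp["annotations"].items():
            ends = sorted((a.onset_s, a.offset_s) for a in anns)
            assert all(b[0] >= a[1] for a, b in zip(ends, ends[1:]))  # non-overlapping
            assert ends[0][0] >= cfg.preroll_s  # call-free lead-in preserved
            assert ends[-1][1] <= cfg.trial_s

    def test_same_seed_byte_identical_truth(self, small_experiment, tmp_path):
        cfg, exp = small_experiment
        cfg2 = copy.deepcopy(cfg)
        call_synth.simulate_experiment(cfg2, tmp_path / "again")
        assert (tmp_path / "again" / "truth.csv").read_bytes() == \
               (exp["dir"] / "truth.csv").read_bytes()

    def test_overdense_trial_rejected(self, tmp_path):
        cfg = call_synth.make_default_config(1, seed=0, trial_s=15.0)
        cfg.subjects[0].clcs_per_trial = 10
        with pytest.raises(ValueError, match="density"):
            call_synth.simulate_experiment(cfg, tmp_path / "dense")
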