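"""Prosody synthesis, measurement and attenuation."""
import numpy as np
import pytest

from emonirs import dsp, stimuli
from emonirs.audio import AudioSignal

from conftest import flat_spec, glide_spec

BANK_REF = 0.3


class TestSynthesis:
    def test_constant_contour_tracks_at_synthesis_frequency(self):
        sig = stimuli.synth_sentence(flat_spec(220.0))
        track = dsp.track_f0(sig.samples, sig.rate_hz)
        assert abs(np.mean(track.voiced_f0()) - 220.0) < 2.0

    def test_same_seed_is_bit_identical(self):
        a = stimuli.synth_sentence(glide_spec(seed=9))
        b = stimuli.synth_sentence(glide_spec(seed=9))
        assert np.array_equal(a.samples, b.samples)

    def test_doubling_gains_doubles_rms(self):
        spec = flat_spec()
        loud = stimuli.SentenceSpec(
            n_syllables=spec.n_syllables,
            syllable_durations_s=spec.syllable_durations_s,
            gap_durations_s=spec.gap_durations_s,
            f0_contour_hz=spec.f0_contour_hz,
            syllable_gains=tuple(0.4 * g for g in spec.syllable_gains),
            seed=spec.seed)
        quiet = stimuli.SentenceSpec(
            n_syllables=spec.n_syllables,
            syllable_durations_s=spec.syllable_durations_s,
            gap_durations_s=spec.gap_durations_s,
            f0_contour_hz=spec.f0_contour_hz,
            syllable_gains=tuple(0.2 * g for g in spec.syllable_gains),
            seed=spec.seed)
        ratio = (stimuli.synth_sentence(loud).rms()
                 / stimuli.synth_sentence(quiet).rms())
        assert ratio == pytest.approx(2.0, rel=1e-6)

    def test_contour_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            stimuli.SentenceSpec(
                n_syllables=1, syllable_durations_s=(0.2,),
                gap_durations_s=(), f0_contour_hz=(40.0, 40.0),
                syllable_gains=(1.0,))


class TestF0Tracker:
    def test_pure_harmonic_complex(self):
        rate = 48_000
        t = np.arange(int(1.0 * rate)) / rate
        x = sum(np.sin(2 * np.pi * 220 * k * t) / k for k in range(1, 6))
        track = dsp.track_f0(np.asarray(x), rate)
        voiced = track.voiced_f0()
        assert len(voiced) > 50
        assert np.all(np.abs(voiced - 220.0) < 2.0)

    def test_white_noise_mostly_unvoiced(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 0.3, 48_000)
        track = dsp.track_f0(x, 48_000)
        assert np.mean(~track.voiced) >= 0.90

    def test_glide_follows_synthesis_contour(self, glide_sentence):
        spec = glide_spec()
        track = dsp.track_f0(glide_sentence.samples, glide_sentence.rate_hz)
        tt = np.linspace(0, glide_sentence.duration_s,
                         len(spec.f0_contour_hz))
        truth = np.interp(track.times_s[track.voiced], tt,
                          np.asarray(spec.f0_contour_hz))
        err = track.voiced_f0() - truth
        assert abs(np.median(err)) < 5.0

    def test_empty_signal_rejected(self):
        with pytest.raises(ValueError):
            dsp.track_f0(np.array([]), 48_000)


class TestMeasureProfile:
    def test_angry_table_mean_f0(self):
        """A sentence synthesised at the angry mean F0 measures back at
        that value."""
        rng = np.random.default_rng(5)
        specs = [stimuli.random_sentence_spec("angry", rng)
                 for _ in range(5)]
        shift = 241.47 - np.mean(
            [np.mean(sp.f0_contour_hz) for sp in specs])
        measured = []
        for sp in specs:
            from dataclasses import replace
            sp = replace(sp, f0_contour_hz=tuple(
                np.asarray(sp.f0_contour_hz) + shift))
            sig = stimuli.synth_sentence(sp)
            prof = stimuli.measure_profile(sig, 6, BANK_REF)
            measured.append(prof.f0_mean_hz)
        assert abs(np.mean(measured) - 241.47) < 3.0

    def test_rate_is_count_over_duration(self):
        sig = AudioSignal(np.zeros(int(1.2 * 48_000)) + 1e-6)
        prof = stimuli.measure_profile(sig, 6, 1.0)
        assert prof.rate_syl_per_s == pytest.approx(5.0, rel=1e-6)

    def test_own_rms_reference_gives_zero_db(self, flat_sentence):
        prof = stimuli.measure_profile(flat_sentence, 6,
                                       flat_sentence.rms())
        assert abs(prof.intensity_db) < 1e-9


class TestAttenuateF0:
    def test_glide_flattens_to_target(self, glide_sentence):
        flat = stimuli.attenuate_f0(glide_sentence, 217.0)
        track = dsp.track_f0(flat.samples, flat.rate_hz)
        assert abs(np.mean(track.voiced_f0()) - 217.0) < 3.0
        assert abs(np.median(track.voiced_f0()) - 217.0) < 3.0

    def test_duration_preserved(self, glide_sentence):
        flat = stimuli.attenuate_f0(glide_sentence, 217.0)
        assert flat.n_samples == glide_sentence.n_samples

    def test_identity_on_signal_already_at_target(self, flat_sentence):
        out = stimuli.attenuate_f0(flat_sentence, 217.0)
        lsd = dsp.band_spectral_distance(flat_sentence.samples, out.samples,
                                         flat_sentence.rate_hz)
        assert lsd < 2.0

    def test_target_outside_tracker_range_rejected(self, glide_sentence):
        with pytest.raises(ValueError):
            stimuli.attenuate_f0(glide_sentence, 500.0)


class TestAttenuateIntensity:
    def test_active_frames_reach_target(self, glide_sentence):
        out = stimuli.attenuate_intensity(glide_sentence, -11.19, BANK_REF)
        levels = stimuli.active_frame_levels(out, BANK_REF)
        assert len(levels) > 10
        assert np.all(np.abs(levels + 11.19) < 0.5)
        assert abs(levels.mean() + 11.19) < 0.2

    def test_identity_on_uniform_signal_at_target(self):
        rate = 48_000
        t = np.arange(int(1.5 * rate)) / rate
        tone = np.sin(2 * np.pi * 220.0 * t)
        tone *= (BANK_REF * 10 ** (-11.19 / 20)) / np.sqrt(
            np.mean(tone ** 2))
        sig = AudioSignal(tone)
        out = stimuli.attenuate_intensity(sig, -11.19, BANK_REF)
        mid = slice(24_000, 48_000)
        gain = out.samples[mid] / sig.samples[mid]
        assert np.abs(gain - 1.0).max() < 0.01

    def test_doubling_reference_shifts_level_6db(self, glide_sentence):
        out = stimuli.attenuate_intensity(glide_sentence, -11.19,
                                          2 * BANK_REF)
        levels = stimuli.active_frame_levels(out, BANK_REF)
        assert abs(levels.mean() - (-11.19 + 20 * np.log10(2))) < 0.25

    def test_all_silent_returned_unchanged(self):
        sig = AudioSignal(np.full(48_000, 1e-6))
        out = stimuli.attenuate_intensity(sig, -11.19, 1.0)
        assert np.array_equal(out.samples, sig.samples)


class TestAttenuateRate:
    def test_duration_matches_target_rate(self):
        spec = stimuli.SentenceSpec(
            n_syllables=6, syllable_durations_s=(0.19,) * 6,
            gap_durations_s=(0.072,) * 5,
            f0_contour_hz=tuple(np.linspace(180, 260, 64)),
            syllable_gains=(1.0,) * 6, seed=2)
        sig = stimuli.synth_sentence(spec)       # 1.5 s -> 4.0 syl/s
        assert sig.duration_s == pytest.approx(1.5, abs=1e-3)
        out = stimuli.attenuate_rate(sig, 4.82, 6)
        assert out.duration_s == pytest.approx(6 / 4.82, rel=0.01)

    def test_identity_when_already_at_target(self, glide_sentence):
        rate_now = 6 / glide_sentence.duration_s
        out = stimuli.attenuate_rate(glide_sentence, rate_now, 6)
        assert abs(out.duration_s / glide_sentence.duration_s - 1) < 0.01

    def test_pitch_preserved(self, glide_sentence):
        before = dsp.track_f0(glide_sentence.samples,
                              glide_sentence.rate_hz)
        out = stimuli.attenuate_rate(glide_sentence, 4.82, 6)
        after = dsp.track_f0(out.samples, out.rate_hz)
        assert abs(np.mean(after.voiced_f0())
                   - np.mean(before.voiced_f0())) < 3.0

    def test_extreme_scale_factor_rejected(self, glide_sentence):
        with pytest.raises(ValueError):
            stimuli.attenuate_rate(glide_sentence, 30.0, 6)


class TestApplyCondition:
    TARGETS = stimuli.ManipulationTargets()

    def test_natural_returns_input(self, glide_sentence):
        out = stimuli.apply_condition(glide_sentence, "natural",
                                      self.TARGETS, BANK_REF)
        assert np.array_equal(out.samples, glide_sentence.samples)

    def test_rate_plus_f0(self, glide_sentence):
        out = stimuli.apply_condition(glide_sentence, "rate+F0",
                                      self.TARGETS, BANK_REF)
        track = dsp.track_f0(out.samples, out.rate_hz)
        assert abs(np.mean(track.voiced_f0()) - 217.0) < 3.0
        assert out.duration_s == pytest.approx(6 / 4.82, rel=0.01)

    def test_intensity_plus_f0_keeps_duration(self, glide_sentence):
        out = stimuli.apply_condition(glide_sentence, "intensity+F0",
                                      self.TARGETS, BANK_REF)
        assert out.n_samples == glide_sentence.n_samples
        track = dsp.track_f0(out.samples, out.rate_hz)
        assert abs(np.median(track.voiced_f0()) - 217.0) < 3.0
        levels = stimuli.active_frame_levels(out, BANK_REF)
        assert abs(levels.mean() + 11.19) < 0.3

    def test_unknown_condition_rejected(self, glide_sentence):
        with pytest.raises(ValueError):
            stimuli.apply_condition(glide_sentence, "loudness",
                                    self.TARGETS, BANK_REF)


class TestStimulusBank:
    def test_same_seed_identical(self):
        a, ref_a = stimuli.make_stimulus_bank(
            n_sentences_per_emotion=1, conditions=("natural",), seed=4)
        b, ref_b = stimuli.make_stimulus_bank(
            n_sentences_per_emotion=1, conditions=("natural",), seed=4)
        assert ref_a == ref_b
        for x, y in zip(a, b):
            assert np.array_equal(x["signal"].samples, y["signal"].samples)

    def test_grand_mean_f0_calibrated(self):
        bank, ref = stimuli.make_stimulus_bank(
            n_sentences_per_emotion=5, conditions=("natural",), seed=21)
        per_emotion = {}
        for item in bank:
            prof = stimuli.measure_profile(item["signal"], 6, ref)
            per_emotion.setdefault(item["emotion"], []).append(
                prof.f0_mean_hz)
        grand = np.mean([np.mean(v) for v in per_emotion.values()])
        assert abs(grand - 216.95) < 2.0

    def test_attenuated_members_satisfy_feature_oracles(self):
        bank, ref = stimuli.make_stimulus_bank(
            n_sentences_per_emotion=1, conditions=("F0", "rate+F0"),
            seed=8)
        for item in bank:
            track = dsp.track_f0(item["signal"].samples,
                                 item["signal"].rate_hz)
            assert abs(np.median(track.voiced_f0()) - 217.0) < 3.0
            if "rate" in item["condition"]:
                assert item["signal"].duration_s == pytest.approx(
                    6 / 4.82, rel=0.01)

    def test_no_clipping(self, small_bank):
        bank, _ = small_bank
        for item in bank:
            assert np.abs(item["signal"].samples).max() <= 1.0


class TestConcatBlock:
    def test_duration_is_sum_of_parts(self):
        parts = [AudioSignal(np.zeros(int(1.25 * 48_000)) + 1e-6)
                 for _ in range(5)]
        block = stimuli.concat_block(parts, gap_s=0.2)
        assert block.duration_s == pytest.approx(5 * 1.25 + 4 * 0.2,
                                                 abs=1e-6)

    def test_tone_present_only_in_its_span(self):
        rate = 48_000
        base = AudioSignal(np.zeros(int(3.0 * rate)) + 1e-9, rate)
        block = stimuli.concat_block([base], tone=(400.0, 0.5, 1.0))
        f, t = np.fft.rfftfreq(int(0.5 * rate), 1 / rate), None
        seg_in = block.samples[int(1.0 * rate):int(1.5 * rate)]
        seg_out = block.samples[int(2.0 * rate):int(2.5 * rate)]
        spec_in = np.abs(np.fft.rfft(seg_in))
        spec_out = np.abs(np.fft.rfft(seg_out))
        bin400 = np.argmin(np.abs(f - 400.0))
        assert spec_in[bin400] > 100 * spec_out[bin400]

    def test_single_sentence_no_gap_is_identity(self, flat_sentence):
        block = stimuli.concat_block([flat_sentence])
        assert np.array_equal(block.samples, flat_sentence.samples)

    def test_tone_past_end_rejected(self, flat_sentence):
        with pytest.raises(ValueError):
            stimuli.concat_block([flat_sentence],
                                 tone=(400.0, 0.5,
                                       flat_sentence.duration_s - 0.1))


class TestProperties:
    def test_attenuation_idempotent(self, glide_sentence):
        once = stimuli.attenuate_intensity(glide_sentence, -11.19, BANK_REF)
        twice = stimuli.attenuate_intensity(once, -11.19, BANK_REF)
        l1 = stimuli.active_frame_levels(once, BANK_REF)
        l2 = stimuli.active_frame_levels(twice, BANK_REF)
        assert abs(l1.mean() - l2.mean()) < 0.1

    def test_rate_duration_depends_only_on_targets(self, glide_sentence):
        t = stimuli.ManipulationTargets()
        for cond in ("rate+F0", "intensity+rate"):
            out = stimuli.apply_condition(glide_sentence, cond, t, BANK_REF)
            assert out.duration_s == pytest.approx(6 / 4.82, rel=0.01)

    def test_profile_recovery_across_random_specs(self):
        """measure_profile recovers the synthesis parameters."""
        rng = np.random.default_rng(17)
        for _ in range(10):
            emotion = rng.choice(list(stimuli.EMOTIONS))
            spec = stimuli.random_sentence_spec(str(emotion), rng)
            sig = stimuli.synth_sentence(spec)
            prof = stimuli.measure_profile(sig, 6, sig.rms())
            assert abs(prof.f0_mean_hz
                       - np.mean(spec.f0_contour_hz)) < 2.0
            assert prof.rate_syl_per_s == pytest.approx(
                6 / spec.duration_s, rel=0.02)
            assert abs(prof.intensity_db) < 0.2
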