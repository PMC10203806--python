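"""Attenuate the prosodic cues of a synthetic pseudo-sentence.

Builds a six-syllable harmonic sentence whose F0 glides 150-300 Hz, then
flattens each cue to its grand-mean target: F0 to 217 Hz, short-time
level to -11.19 dB re the bank's loudest sentence, speech rate to
4.82 syllables/s. The printed numbers are the measured prosodic profile
before and after each stage — after manipulation the tracked F0 sits at
the constant target, the active-frame level at the dB target, and the
syllable rate at the rate target.
"""
import numpy as np

from emonirs import dsp, stimuli

spec = stimuli.SentenceSpec(
    n_syllables=6,
    syllable_durations_s=(0.22,) * 6,
    gap_durations_s=(0.06,) * 5,
    f0_contour_hz=tuple(np.linspace(150.0, 300.0, 64)),
    syllable_gains=(1.0, 0.5, 0.9, 0.7, 1.0, 0.8),
    seed=3,
)
sentence = stimuli.synth_sentence(spec)
ref_rms = 0.3                     # stand-in for the bank's max RMS
targets = stimuli.ManipulationTargets()

prof = stimuli.measure_profile(sentence, 6, ref_rms)
print(f"natural:        F0 {prof.f0_mean_hz:6.1f} Hz "
      f"(sd {prof.f0_sd_hz:5.1f}), level {prof.intensity_db:6.2f} dB, "
      f"rate {prof.rate_syl_per_s:.2f} syl/s")

flat = stimuli.attenuate_f0(sentence, targets.f0_target_hz)
track = dsp.track_f0(flat.samples, flat.rate_hz)
print(f"F0 flattened:   F0 {np.mean(track.voiced_f0()):6.1f} Hz "
      f"(sd {np.std(track.voiced_f0()):5.1f})  <- target "
      f"{targets.f0_target_hz} Hz")

level = stimuli.attenuate_intensity(sentence,
                                    targets.intensity_target_db, ref_rms)
levels = stimuli.active_frame_levels(level, ref_rms)
print(f"level flattened: active frames {levels.mean():6.2f} dB "
      f"(range {levels.min():.2f} to {levels.max():.2f})  <- target "
      f"{targets.intensity_target_db} dB")

scaled = stimuli.attenuate_rate(sentence, targets.rate_target_syl_per_s, 6)
print(f"rate scaled:    {6 / scaled.duration_s:.3f} syl/s "
      f"(duration {scaled.duration_s:.3f} s)  <- target "
      f"{targets.rate_target_syl_per_s} syl/s")

combo = stimuli.apply_condition(sentence, "rate+F0", targets, ref_rms)
track2 = dsp.track_f0(combo.samples, combo.rate_hz)
print(f"rate+F0:        F0 {np.mean(track2.voiced_f0()):6.1f} Hz, "
      f"rate {6 / combo.duration_s:.3f} syl/s (both cues attenuated, "
      f"intensity contour untouched)")
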