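"""Pseudo-sentence stimuli: synthesis, prosodic profiling, and cue
attenuation.

The experimental material consists of six-syllable pseudo-sentences spoken
with angry, happy, sad or unemotional prosody. This module provides an
acoustic surrogate: harmonic-complex "syllables" with a controllable F0
contour, per-syllable gains and speech rate. Three prosodic cues can be
attenuated to fixed grand-mean targets —

* F0 variation flattened to a constant 217 Hz,
* intensity variation flattened to −11.19 dB relative to the loudest
  sentence (maximum overall RMS) in the stimulus bank,
* speech rate scaled to 4.82 syllables/s,

giving five conditions named for the attenuated features: natural,
intensity+rate, F0, intensity+F0 and rate+F0. When several features are
attenuated the order is fixed: F0 first, then rate, then intensity.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .audio import AudioSignal, DEFAULT_RATE_HZ
from . import dsp

log = logging.getLogger(__name__)

EMOTIONS = ("angry", "happy", "sad", "unemotional")
CONDITIONS = ("natural", "intensity+rate", "F0", "intensity+F0", "rate+F0")

#: Per-emotion prosody statistics of the recorded material: mean F0 (Hz),
#: between-sentence F0 SD (Hz), level (dB re bank max RMS), rate (syl/s).
EMOTION_PROFILES: dict[str, dict[str, float]] = {
    "angry": {"f0_mean_hz": 241.47, "f0_sd_hz": 6.14,
              "level_db": -0.99, "rate_syl_per_s": 4.50},
    "happy": {"f0_mean_hz": 243.31, "f0_sd_hz": 10.29,
              "level_db": -10.97, "rate_syl_per_s": 5.57},
    "sad": {"f0_mean_hz": 215.97, "f0_sd_hz": 11.44,
            "level_db": -17.76, "rate_syl_per_s": 4.70},
    "unemotional": {"f0_mean_hz": 167.04, "f0_sd_hz": 8.37,
                    "level_db": -15.04, "rate_syl_per_s": 4.68},
}

F0_CONTOUR_MIN_HZ = 50.0
F0_CONTOUR_MAX_HZ = 500.0


@dataclass(frozen=True)
class ManipulationTargets:
    """Grand-mean attenuation targets for the three prosodic cues."""

    f0_target_hz: float = 217.0
    intensity_target_db: float = -11.19
    rate_target_syl_per_s: float = 4.82


@dataclass(frozen=True)
class Condition:
    """A stimulus condition, named for the attenuated features."""

    name: str

    _FEATURES = {
        "natural": frozenset(),
        "intensity+rate": frozenset({"intensity", "rate"}),
        "F0": frozenset({"F0"}),
        "intensity+F0": frozenset({"intensity", "F0"}),
        "rate+F0": frozenset({"rate", "F0"}),
    }

    def __post_init__(self) -> None:
        if self.name not in self._FEATURES:
            raise ValueError(f"unknown condition {self.name!r}")

    @property
    def attenuated_features(self) -> frozenset[str]:
        return self._FEATURES[self.name]


@dataclass(frozen=True)
class SentenceSpec:
    """Parameters of one synthetic pseudo-sentence.

    ``f0_contour`` gives the F0 (Hz) on a uniform grid spanning the whole
    utterance; it is read only within voiced syllables. ``syllable_gains``
    are linear amplitudes; gaps are silent.
    """

    n_syllables: int
    syllable_durations_s: tuple[float, ...]
    gap_durations_s: tuple[float, ...]
    f0_contour_hz: tuple[float, ...]
    syllable_gains: tuple[float, ...]
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_syllables < 1:
            raise ValueError("need at least one syllable")
        if len(self.syllable_durations_s) != self.n_syllables:
            raise ValueError("one duration per syllable required")
        if len(self.gap_durations_s) != self.n_syllables - 1:
            raise ValueError("need n_syllables - 1 gap durations")
        if len(self.syllable_gains) != self.n_syllables:
            raise ValueError("one gain per syllable required")
        if any(d <= 0 for d in self.syllable_durations_s):
            raise ValueError("syllable durations must be positive")
        if any(d < 0 for d in self.gap_durations_s):
            raise ValueError("gap durations must be non-negative")
        contour = np.asarray(self.f0_contour_hz, float)
        if contour.size < 2:
            raise ValueError("f0 contour needs at least two points")
        if contour.min() < F0_CONTOUR_MIN_HZ or contour.max() > F0_CONTOUR_MAX_HZ:
            raise ValueError(
                f"f0 contour must stay within [{F0_CONTOUR_MIN_HZ}, "
                f"{F0_CONTOUR_MAX_HZ}] Hz")

    @property
    def duration_s(self) -> float:
        return float(sum(self.syllable_durations_s) + sum(self.gap_durations_s))


@dataclass(frozen=True)
class ProsodyProfile:
    """Measured prosodic statistics of one utterance."""

    f0_mean_hz: float
    f0_sd_hz: float
    f0_range_hz: tuple[float, float]
    intensity_db: float
    rate_syl_per_s: float


def synth_sentence(
    spec: SentenceSpec,
    rate_hz: float = DEFAULT_RATE_HZ,
    n_harmonics: int = 12,
    ramp_s: float = 0.015,
) -> AudioSignal:
    """Render a sentence spec as a harmonic-complex waveform.

    Each syllable is a sum of harmonics (1/k amplitude roll-off) whose
    instantaneous frequency follows the spec's F0 contour, shaped by onset
    and offset cosine ramps and scaled by the syllable gain. Deterministic
    given the spec (harmonic phases come from ``spec.seed``).
    """
    rng = np.random.default_rng(spec.seed)
    total = spec.duration_s
    n_total = int(round(total * rate_hz))
    out = np.zeros(n_total)
    contour_t = np.linspace(0.0, total, len(spec.f0_contour_hz))
    contour = np.asarray(spec.f0_contour_hz, float)
    phases = rng.uniform(0, 2 * np.pi, size=n_harmonics)

    t_cursor = 0.0
    for i in range(spec.n_syllables):
        dur = spec.syllable_durations_s[i]
        n = int(round(dur * rate_hz))
        s0 = int(round(t_cursor * rate_hz))
        tt = t_cursor + np.arange(n) / rate_hz
        f0 = np.interp(tt, contour_t, contour)
        phase = 2 * np.pi * np.cumsum(f0) / rate_hz
        fmax = f0.max()
        wave = np.zeros(n)
        norm = 0.0
        for k in range(1, n_harmonics + 1):
            if k * fmax >= rate_hz / 2 * 0.9:
                break
            wave += np.sin(k * phase + phases[k - 1]) / k
            norm += 1.0 / k
        if norm > 0:
            wave /= norm
        env = np.ones(n)
        n_ramp = min(int(ramp_s * rate_hz), n // 2)
        if n_ramp > 0:
            ramp = 0.5 * (1 - np.cos(np.pi * np.arange(n_ramp) / n_ramp))
            env[:n_ramp] = ramp
            env[-n_ramp:] = ramp[::-1]
        seg = wave * env * spec.syllable_gains[i]
        out[s0:s0 + n] = seg[:max(0, min(n, n_total - s0))]
        t_cursor += dur
        if i < spec.n_syllables - 1:
            t_cursor += spec.gap_durations_s[i]

    peak = np.abs(out).max()
    if peak > 1.0:
        log.warning("synthesised sentence clipped (peak %.3f); rescaling", peak)
        out /= peak
    return AudioSignal(samples=out, rate_hz=rate_hz)


def measure_profile(
    signal: AudioSignal,
    n_syllables: int,
    ref_rms: float,
) -> ProsodyProfile:
    """Measure F0 statistics, overall level and syllable rate.

    F0 statistics are computed over voiced frames of the autocorrelation
    track; intensity is 20·log10(overall RMS / ref_rms); rate is
    ``n_syllables`` divided by the total duration.
    """
    if ref_rms <= 0:
        raise ValueError("ref_rms must be positive")
    track = dsp.track_f0(signal.samples, signal.rate_hz)
    voiced = track.voiced_f0()
    if voiced.size:
        f0_mean = float(np.mean(voiced))
        f0_sd = float(np.std(voiced, ddof=1)) if voiced.size > 1 else 0.0
        f0_range = (float(voiced.min()), float(voiced.max()))
    else:
        f0_mean = f0_sd = float("nan")
        f0_range = (float("nan"), float("nan"))
    intensity_db = 20.0 * np.log10(signal.rms() / ref_rms)
    rate = n_syllables / signal.duration_s
    return ProsodyProfile(
        f0_mean_hz=f0_mean,
        f0_sd_hz=f0_sd,
        f0_range_hz=f0_range,
        intensity_db=float(intensity_db),
        rate_syl_per_s=float(rate),
    )


def attenuate_f0(signal: AudioSignal, target_hz: float) -> AudioSignal:
    """Flatten F0 variation to a constant target (PSOLA resynthesis).

    Voiced spans are resynthesised at the target period; unvoiced and silent
    spans, and the total duration, are untouched.
    """
    out = dsp.flatten_pitch(signal.samples, signal.rate_hz, target_hz)
    return signal.with_samples(out)


def attenuate_intensity(
    signal: AudioSignal,
    target_db: float,
    ref_rms: float,
    frame_s: float = 0.050,
    silence_floor_db: float = -40.0,
    n_passes: int = 3,
) -> AudioSignal:
    """Flatten short-time level to ``target_db`` re ``ref_rms``.

    The level being equalised is the 50 ms short-time RMS (``frame_s``).
    Internally the gain is tracked at twice that resolution — a sliding RMS
    envelope over ``frame_s / 2`` — and every speech-active sample (envelope
    above the silence floor re ``ref_rms``) is scaled by
    ``target / envelope``; silent samples keep unit gain. The gain curve is
    smoothed over 5 ms so active/silent transitions are click-free, and the
    measure-correct cycle runs ``n_passes`` times so the achieved level
    converges. If the result would clip, the whole waveform is rescaled
    globally and a warning logged.
    """
    if ref_rms <= 0:
        raise ValueError("ref_rms must be positive")
    target_rms = ref_rms * 10.0 ** (target_db / 20.0)
    floor_rms = ref_rms * 10.0 ** (silence_floor_db / 20.0)
    out = signal.samples.copy()
    env0 = dsp.sliding_rms(out, signal.rate_hz, frame_s)
    if np.all(env0 <= floor_rms):
        log.warning("attenuate_intensity: signal entirely below the silence "
                    "floor; returning it unchanged")
        return signal
    n_smooth = max(3, int(round(0.005 * signal.rate_hz)))
    smooth = np.hanning(n_smooth)
    smooth /= smooth.sum()
    for _ in range(n_passes):
        env = dsp.sliding_rms(out, signal.rate_hz, frame_s / 2)
        gain = np.ones_like(env)
        active = env > floor_rms
        gain[active] = target_rms / env[active]
        gain = np.convolve(gain, smooth, mode="same")
        out = out * gain
    peak = np.abs(out).max()
    if peak > 1.0:
        log.warning("attenuate_intensity: output clipped (peak %.3f); "
                    "rescaling globally", peak)
        out /= peak
    return signal.with_samples(out)


def active_frame_levels(
    signal: AudioSignal,
    ref_rms: float,
    frame_s: float = 0.050,
    silence_floor_db: float = -40.0,
) -> np.ndarray:
    """Short-time levels (dB re ``ref_rms``) of speech-active frames.

    A frame counts as speech-active when all of its samples lie inside an
    active region (sliding-RMS envelope above the silence floor), so frames
    straddling speech/silence boundaries — whose RMS necessarily includes
    forced silence — are not reported.
    """
    floor_rms = ref_rms * 10.0 ** (silence_floor_db / 20.0)
    env = dsp.sliding_rms(signal.samples, signal.rate_hz, frame_s)
    active = env > floor_rms
    # erode by half an envelope window: nearer the boundary the envelope
    # estimate itself is contaminated by the adjacent silence
    margin = max(1, int(round(frame_s * signal.rate_hz / 2)))
    eroded = active.copy()
    edges = np.flatnonzero(np.diff(active.astype(int)))
    for e in edges:
        lo, hi = max(0, e - margin), min(len(eroded), e + margin + 1)
        eroded[lo:hi] = False
    active = eroded
    centres, rms = dsp.frame_rms(signal.samples, signal.rate_hz, frame_s)
    n_frame = int(round(frame_s * signal.rate_hz))
    levels = []
    for c, r in zip(centres, rms):
        lo = max(0, c - n_frame // 2)
        hi = min(len(active), c + n_frame // 2)
        if active[lo:hi].all() and r > 0:
            levels.append(20.0 * np.log10(r / ref_rms))
    return np.asarray(levels)


def attenuate_rate(
    signal: AudioSignal,
    target_syl_per_s: float,
    n_syllables: int,
) -> AudioSignal:
    """Scale speech rate uniformly to the target (WSOLA, pitch preserved).

    The output duration is exactly ``n_syllables / target_syl_per_s``
    (rounded to one sample).
    """
    if n_syllables < 1:
        raise ValueError("need at least one syllable")
    new_duration = n_syllables / target_syl_per_s
    ratio = new_duration / signal.duration_s
    out = dsp.time_stretch(signal.samples, signal.rate_hz, ratio)
    return signal.with_samples(out)


def apply_condition(
    signal: AudioSignal,
    condition: Condition | str,
    targets: ManipulationTargets,
    bank_ref_rms: float,
    n_syllables: int = 6,
) -> AudioSignal:
    """Attenuate the condition's features, in the fixed order
    F0 → rate → intensity. The natural condition returns the input."""
    if isinstance(condition, str):
        condition = Condition(condition)
    feats = condition.attenuated_features
    out = signal
    if "F0" in feats:
        out = attenuate_f0(out, targets.f0_target_hz)
    if "rate" in feats:
        out = attenuate_rate(out, targets.rate_target_syl_per_s, n_syllables)
    if "intensity" in feats:
        out = attenuate_intensity(out, targets.intensity_target_db,
                                  bank_ref_rms)
    return out


def random_sentence_spec(
    emotion: str,
    rng: np.random.Generator,
    n_syllables: int = 6,
    gap_s: float = 0.06,
    profiles: dict[str, dict[str, float]] | None = None,
) -> SentenceSpec:
    """Draw a sentence spec whose prosody matches an emotion profile.

    The sentence-mean F0 is drawn from the emotion's (mean, SD); within the
    sentence a gentle declination plus per-syllable excursions provide the
    natural F0 variation. Rate jitters around the emotion's rate; syllable
    gains vary mildly around unity (absolute level is set at bank assembly).
    """
    if profiles is None:
        profiles = EMOTION_PROFILES
    p = profiles[emotion]
    sentence_f0 = rng.normal(p["f0_mean_hz"], p["f0_sd_hz"])
    sentence_f0 = float(np.clip(sentence_f0, 90.0, 380.0))
    rate = max(2.0, rng.normal(p["rate_syl_per_s"], 0.15))
    total = n_syllables / rate
    gap = min(gap_s, total / (4 * n_syllables))
    syl = (total - (n_syllables - 1) * gap) / n_syllables
    n_points = 64
    x = np.linspace(0, 1, n_points)
    declination = -12.0 * (x - 0.5)                       # Hz, falling
    wiggle = (14.0 * np.sin(2 * np.pi * rng.uniform(1.0, 2.5) * x
                            + rng.uniform(0, 2 * np.pi)))
    contour = sentence_f0 + declination + wiggle
    contour += sentence_f0 - contour.mean()               # recentre exactly
    contour = np.clip(contour, F0_CONTOUR_MIN_HZ + 10, F0_CONTOUR_MAX_HZ - 10)
    gains = np.clip(rng.normal(1.0, 0.25, size=n_syllables), 0.4, 1.6)
    return SentenceSpec(
        n_syllables=n_syllables,
        syllable_durations_s=tuple([syl] * n_syllables),
        gap_durations_s=tuple([gap] * (n_syllables - 1)),
        f0_contour_hz=tuple(contour),
        syllable_gains=tuple(gains),
        seed=int(rng.integers(0, 2**31 - 1)),
    )


def make_stimulus_bank(
    emotion_profiles: dict[str, dict[str, float]] | None = None,
    n_sentences_per_emotion: int = 5,
    conditions: tuple[str, ...] = CONDITIONS,
    seed: int = 0,
    targets: ManipulationTargets | None = None,
    rate_hz: float = DEFAULT_RATE_HZ,
    peak_level: float = 0.45,
):
    """Build the seeded stimulus bank: sentences × emotions × conditions.

    Natural sentences are synthesised first and scaled so that each
    emotion's overall level (dB re the loudest sentence) matches its
    profile; the loudest sentence's RMS defines the bank's 0 dB reference.
    Every non-natural condition is then derived from its natural parent.

    Returns ``(stimuli, bank_ref_rms)`` where ``stimuli`` is a list of dicts
    with keys ``emotion, condition, sentence, signal, spec``.
    """
    if emotion_profiles is None:
        emotion_profiles = EMOTION_PROFILES
    if targets is None:
        targets = ManipulationTargets()
    rng = np.random.default_rng(seed)

    naturals = []
    for emotion in emotion_profiles:
        specs = [random_sentence_spec(emotion, rng, profiles=emotion_profiles)
                 for _ in range(n_sentences_per_emotion)]
        # calibrate: the emotion's mean F0 is a measured property of the
        # bank, so recentre the sentence means onto it while keeping the
        # between-sentence spread
        means = np.array([np.mean(sp.f0_contour_hz) for sp in specs])
        shift = emotion_profiles[emotion]["f0_mean_hz"] - means.mean()
        for s, sp in enumerate(specs):
            contour = np.asarray(sp.f0_contour_hz) + shift
            contour = np.clip(contour, F0_CONTOUR_MIN_HZ + 5,
                              F0_CONTOUR_MAX_HZ - 5)
            sp = replace(sp, f0_contour_hz=tuple(contour))
            sig = synth_sentence(sp, rate_hz=rate_hz)
            naturals.append({"emotion": emotion, "sentence": s,
                             "spec": sp, "signal": sig})

    # set per-emotion levels relative to the loudest emotion profile
    max_level = max(p["level_db"] for p in emotion_profiles.values())
    ref0 = max(item["signal"].rms() for item in naturals)
    for item in naturals:
        lvl = emotion_profiles[item["emotion"]]["level_db"] - max_level
        want_rms = ref0 * 10.0 ** (lvl / 20.0)
        gain = want_rms / item["signal"].rms()
        scaled = item["signal"].samples * gain
        peak = np.abs(scaled).max()
        if peak > peak_level:
            scaled *= peak_level / peak
        item["signal"] = item["signal"].with_samples(scaled)

    bank_ref_rms = max(item["signal"].rms() for item in naturals)

    stimuli = []
    for item in naturals:
        for condition in conditions:
            if condition == "natural":
                sig = item["signal"]
            else:
                sig = apply_condition(item["signal"], condition, targets,
                                      bank_ref_rms,
                                      n_syllables=item["spec"].n_syllables)
            stimuli.append({
                "emotion": item["emotion"],
                "condition": condition,
                "sentence": item["sentence"],
                "spec": item["spec"],
                "signal": sig,
            })
    return stimuli, bank_ref_rms


def concat_block(
    sentences: list[AudioSignal],
    gap_s: float = 0.0,
    tone: tuple[float, float, float] | None = None,
    tone_level: float = 0.1,
) -> AudioSignal:
    """Concatenate sentences (with silent gaps) into one stimulus block.

    ``tone`` optionally overlays an attention tone as ``(freq_hz, dur_s,
    onset_s)``; the 400 Hz, 500 ms probe used in the listening task is the
    intended use. The tone must fit inside the block.
    """
    if not sentences:
        raise ValueError("need at least one sentence")
    rate = sentences[0].rate_hz
    if any(s.rate_hz != rate for s in sentences):
        raise ValueError("all sentences must share a sampling rate")
    gap = np.zeros(int(round(gap_s * rate)))
    parts = []
    for i, s in enumerate(sentences):
        parts.append(s.samples)
        if i < len(sentences) - 1:
            parts.append(gap)
    out = np.concatenate(parts) if len(parts) > 1 else parts[0].copy()
    if tone is not None:
        freq, dur, onset = tone
        i0 = int(round(onset * rate))
        n = int(round(dur * rate))
        if i0 < 0 or i0 + n > len(out):
            raise ValueError("tone extends past the block end")
        t = np.arange(n) / rate
        out = out.copy()
        out[i0:i0 + n] += tone_level * np.sin(2 * np.pi * freq * t)
    return AudioSignal(samples=np.clip(out, -1.0, 1.0), rate_hz=rate)
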