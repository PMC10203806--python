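import numpy as np
import pytest

from emonirs import stimuli


def glide_spec(seed: int = 3) -> stimuli.SentenceSpec:
    """Six-syllable sentence whose F0 glides 150 -> 300 Hz, with unequal
    syllable gains."""
    return stimuli.SentenceSpec(
        n_syllables=6,
        syllable_durations_s=(0.22,) * 6,
        gap_durations_s=(0.06,) * 5,
        f0_contour_hz=tuple(np.linspace(150.0, 300.0, 64)),
        syllable_gains=(1.0, 0.5, 0.9, 0.7, 1.0, 0.8),
        seed=seed,
    )


def flat_spec(f0_hz: float = 217.0, seed: int = 1) -> stimuli.SentenceSpec:
    """Six-syllable sentence with a constant F0 contour and unit gains."""
    return stimuli.SentenceSpec(
        n_syllables=6,
        syllable_durations_s=(0.22,) * 6,
        gap_durations_s=(0.06,) * 5,
        f0_contour_hz=(f0_hz,) * 64,
        syllable_gains=(1.0,) * 6,
        seed=seed,
    )


@pytest.fixture(scope="session")
def glide_sentence():
    return stimuli.synth_sentence(glide_spec())


@pytest.fixture(scope="session")
def flat_sentence():
    return stimuli.synth_sentence(flat_spec())


@pytest.fixture(scope="session")
def small_bank():
    """Two sentences per emotion, natural condition only (fast)."""
    return stimuli.make_stimulus_bank(
        n_sentences_per_emotion=2, conditions=("natural",), seed=11)
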