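"""Trial lists and block-design schedules.

Two session types are generated here:

* the 4-AFC emotion-recognition assessment — a handful of practice trials
  followed by one test trial per emotion × condition × sentence, in seeded
  random order (4 emotions × 5 conditions × 5 sentences = 100 test trials
  in the full assessment);
* the fNIRS block-design listening session — four familiarisation trials,
  then experimental speech/silence blocks (each condition repeated 20
  times) randomly interleaved with attention blocks (5 tone-carrying
  stimuli × 2), separated by inter-stimulus intervals drawn uniformly from
  13–23 s: 4 + 100 + 10 = 114 trials in the default session.

Schedules serialise to BIDS-style events tables (onset, duration,
trial_type) via :func:`write_events` / :func:`read_events`.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

DEFAULT_ISI_RANGE_S = (13.0, 23.0)
DEFAULT_BLOCK_DUR_S = 7.25


@dataclass(frozen=True)
class Trial:
    index: int
    kind: str                   # familiarization | experimental | attention
    label: str                  # condition or emotion label
    stimulus: str
    onset_s: float
    duration_s: float
    isi_s: float


@dataclass(frozen=True)
class TrialSchedule:
    trials: tuple[Trial, ...]
    seed: int
    session: str

    def __len__(self) -> int:
        return len(self.trials)

    def of_kind(self, kind: str) -> list[Trial]:
        return [t for t in self.trials if t.kind == kind]

    @property
    def total_duration_s(self) -> float:
        return float(sum(t.duration_s + t.isi_s for t in self.trials))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "onset": [t.onset_s for t in self.trials],
            "duration": [t.duration_s for t in self.trials],
            "trial_type": [t.label for t in self.trials],
            "kind": [t.kind for t in self.trials],
            "stimulus": [t.stimulus for t in self.trials],
        })


@dataclass(frozen=True)
class AfcResponse:
    """One 4-AFC response row."""

    participant: int
    trial: int
    emotion: str
    condition: str
    response: str
    time: str = "single"        # pre | post | single
    sentence: int = 0

    @property
    def correct(self) -> bool:
        return self.response == self.emotion


def make_afc_schedule(
    emotions: tuple[str, ...],
    conditions: tuple[str, ...],
    sentences_per_cell: int = 5,
    n_practice: int = 4,
    seed: int = 0,
    trial_dur_s: float = 1.5,
    isi_s: float = 2.0,
) -> TrialSchedule:
    """Build a 4-AFC assessment: practice first, then every emotion ×
    condition × sentence exactly once in seeded random order."""
    if sentences_per_cell < 1 or not emotions or not conditions:
        raise ValueError("counts must be at least 1")
    rng = np.random.default_rng(seed)
    cells = [(e, c, s)
             for e in emotions for c in conditions
             for s in range(sentences_per_cell)]
    order = rng.permutation(len(cells))

    trials = []
    onset = 0.0
    idx = 0
    practice_emotions = list(emotions)
    for p in range(n_practice):
        e = practice_emotions[p % len(practice_emotions)]
        trials.append(Trial(idx, "familiarization", f"{e}/natural",
                            f"practice_{e}", onset, trial_dur_s, isi_s))
        onset += trial_dur_s + isi_s
        idx += 1
    for k in order:
        e, c, s = cells[k]
        trials.append(Trial(idx, "experimental", f"{e}/{c}",
                            f"{e}_{c}_s{s}", onset, trial_dur_s, isi_s))
        onset += trial_dur_s + isi_s
        idx += 1
    return TrialSchedule(tuple(trials), seed, "afc")


def make_block_schedule(
    experimental_conditions: tuple[str, ...],
    reps: int = 20,
    attention_stimuli: tuple[str, ...] = ("attn_1", "attn_2", "attn_3",
                                          "attn_4", "attn_5"),
    attention_reps: int = 2,
    n_familiarization: int = 4,
    isi_range_s: tuple[float, float] = DEFAULT_ISI_RANGE_S,
    block_dur_s: float = DEFAULT_BLOCK_DUR_S,
    seed: int = 0,
) -> TrialSchedule:
    """Build an fNIRS listening session.

    Familiarisation trials come first; experimental blocks (every condition
    ``reps`` times) and attention blocks are then randomly interleaved.
    ISIs are uniform on ``isi_range_s``. Defaults give the 114-trial
    session: 4 + 5×20 + 5×2.
    """
    lo, hi = isi_range_s
    if not lo < hi:
        raise ValueError("isi_range_s must be (low, high) with low < high")
    rng = np.random.default_rng(seed)

    main = ([(c, "experimental") for c in experimental_conditions
             for _ in range(reps)] +
            [(a, "attention") for a in attention_stimuli
             for _ in range(attention_reps)])
    order = rng.permutation(len(main))

    trials = []
    onset = 0.0
    idx = 0
    fam_labels = (list(experimental_conditions) or ["familiarization"])
    for f in range(n_familiarization):
        label = fam_labels[f % len(fam_labels)]
        isi = float(rng.uniform(lo, hi))
        trials.append(Trial(idx, "familiarization", label,
                            f"fam_{f}", onset, block_dur_s, isi))
        onset += block_dur_s + isi
        idx += 1
    for k in order:
        label, kind = main[k]
        isi = float(rng.uniform(lo, hi))
        trials.append(Trial(idx, kind, label, f"{label}_{idx}",
                            onset, block_dur_s, isi))
        onset += block_dur_s + isi
        idx += 1
    return TrialSchedule(tuple(trials), seed, "nirs")


def write_events(schedule: TrialSchedule, path: str | Path) -> None:
    """Write a BIDS-style events TSV (onset, duration, trial_type, ...)."""
    schedule.to_frame().to_csv(path, sep="\t", index=False)


def read_events(path: str | Path) -> pd.DataFrame:
    """Read an events TSV back into a DataFrame."""
    df = pd.read_csv(path, sep="\t")
    required = {"onset", "duration", "trial_type"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"events table missing columns: {sorted(missing)}")
    return df


def experimental_events(schedule: TrialSchedule) -> pd.DataFrame:
    """Events frame restricted to experimental trials (the analysis path
    drops familiarisation and attention trials)."""
    df = schedule.to_frame()
    return df[df["kind"] == "experimental"].reset_index(drop=True)
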