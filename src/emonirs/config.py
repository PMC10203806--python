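"""Run configuration: one plain-text (YAML) file drives the end-to-end
pipeline.

Every default that has a stated value in the study protocol equals that
value: 2.6 Hz acquisition downsampled to 0.6 Hz for analysis, partial
pathlength factor 0.1, 3 s boxcar, drift regressors up to 0.01 Hz,
channel-distance bounds 20-40 mm, 20 repetitions per condition with ISIs
uniform on 13-23 s, F0/intensity/rate targets 217 Hz, -11.19 dB and
4.82 syl/s. Unknown keys in a config file are errors.
"""
from __future__ import annotations

from dataclasses import dataclass, field, fields, asdict
from pathlib import Path

import yaml

from .stimuli import ManipulationTargets
from .synth import NoiseConfig


@dataclass(frozen=True)
class ScheduleConfig:
    conditions: tuple[str, ...] = ("happy", "sad", "F0_happy", "F0_sad",
                                   "control")
    reps: int = 20
    attention_reps: int = 2
    n_familiarization: int = 4
    isi_range_s: tuple[float, float] = (13.0, 23.0)
    block_dur_s: float = 7.25


@dataclass(frozen=True)
class AnalysisConfig:
    analysis_rate_hz: float = 0.6
    ppf: float = 0.1
    boxcar_s: float = 3.0
    drift_cutoff_hz: float = 0.01
    channel_min_mm: float = 20.0
    channel_max_mm: float = 40.0
    roi_weight: str = "inverse_se"
    use_short_regression: bool = True
    cooks_threshold: float | None = None      # None -> 4/N


@dataclass(frozen=True)
class RunConfig:
    seed: int = 0
    n_participants: int = 22
    targets: ManipulationTargets = field(default_factory=ManipulationTargets)
    schedule: ScheduleConfig = field(default_factory=ScheduleConfig)
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    n_sentences_per_emotion: int = 5
    run_stimuli: bool = True

    def validate(self) -> None:
        if self.n_participants < 1:
            raise ValueError("n_participants must be at least 1")
        if self.seed < 0 or self.seed >= 2 ** 31:
            raise ValueError("seed must be in [0, 2^31)")

    def parameter_log(self) -> list[str]:
        """Human-readable log of every analysis default in effect."""
        a, s, t = self.analysis, self.schedule, self.targets
        return [
            f"acquisition rate: 2.6 Hz; analysis rate: "
            f"{a.analysis_rate_hz} Hz",
            f"partial pathlength factor (DPF/PVC): {a.ppf}",
            f"boxcar duration: {a.boxcar_s} s",
            f"drift cutoff: {a.drift_cutoff_hz} Hz",
            f"channel distance bounds: {a.channel_min_mm}/"
            f"{a.channel_max_mm} mm",
            f"repetitions per condition: {s.reps}; "
            f"ISI range: {s.isi_range_s[0]}-{s.isi_range_s[1]} s",
            f"F0 target: {t.f0_target_hz} Hz; intensity target: "
            f"{t.intensity_target_db} dB re bank max RMS; rate target: "
            f"{t.rate_target_syl_per_s} syl/s",
        ]


def _build(cls, data: dict):
    allowed = {f.name: f for f in fields(cls)}
    unknown = set(data) - set(allowed)
    if unknown:
        raise ValueError(
            f"unknown config keys for {cls.__name__}: {sorted(unknown)}")
    kwargs = {}
    for name, value in data.items():
        ftype = allowed[name].type
        if isinstance(value, dict):
            sub = {"targets": ManipulationTargets,
                   "schedule": ScheduleConfig,
                   "noise": NoiseConfig,
                   "analysis": AnalysisConfig}.get(name)
            if sub is None:
                raise ValueError(f"unexpected mapping for key {name!r}")
            kwargs[name] = _build(sub, value)
        elif isinstance(value, list):
            kwargs[name] = tuple(value)
        else:
            kwargs[name] = value
    return cls(**kwargs)


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    with open(path) as f:
        data = yaml.safe_load(f) or {}
    cfg = _build(RunConfig, data)
    cfg.validate()
    return cfg


def save_config(cfg: RunConfig, path: str | Path) -> None:
    with open(path, "w") as f:
        yaml.safe_dump(asdict(cfg), f, sort_keys=False)
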