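"""Sampled-waveform container and WAV round-trip.

All prosody operations act on :class:`AudioSignal`, a thin immutable wrapper
around a float array in [-1, 1] plus its sampling rate. Stimuli default to
48 kHz mono, the rate of the original studio recordings the synthetic
sentences stand in for.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.io import wavfile

DEFAULT_RATE_HZ = 48_000


@dataclass(frozen=True)
class AudioSignal:
    """A mono waveform with its sampling rate.

    Parameters
    ----------
    samples
        Dimensionless amplitudes, expected within [-1, 1].
    rate_hz
        Sampling rate in Hz, strictly positive.
    """

    samples: np.ndarray
    rate_hz: float = DEFAULT_RATE_HZ

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        if samples.ndim != 1:
            raise ValueError("AudioSignal requires a 1-D (mono) sample array")
        if not np.all(np.isfinite(samples)):
            raise ValueError("AudioSignal samples must be finite")
        if not self.rate_hz > 0:
            raise ValueError("rate_hz must be positive")
        object.__setattr__(self, "samples", samples)

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.rate_hz

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def rms(self) -> float:
        """Overall root-mean-square amplitude."""
        return float(np.sqrt(np.mean(np.square(self.samples))))

    def times(self) -> np.ndarray:
        return np.arange(len(self.samples)) / self.rate_hz

    def with_samples(self, samples: np.ndarray) -> "AudioSignal":
        return AudioSignal(samples=samples, rate_hz=self.rate_hz)


def write_wav(path: str | Path, signal: AudioSignal) -> None:
    """Write a mono float32 WAV file."""
    wavfile.write(str(path), int(round(signal.rate_hz)),
                  signal.samples.astype(np.float32))


def read_wav(path: str | Path) -> AudioSignal:
    """Read a WAV file to an :class:`AudioSignal`, normalising PCM to float."""
    rate, data = wavfile.read(str(path))
    data = np.asarray(data)
    if data.ndim > 1:
        raise ValueError("only mono WAV files are supported")
    if np.issubdtype(data.dtype, np.integer):
        scale = float(np.iinfo(data.dtype).max)
        data = data.astype(np.float64) / scale
    else:
        data = data.astype(np.float64)
    return AudioSignal(samples=data, rate_hz=float(rate))
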