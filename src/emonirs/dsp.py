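"""Low-level speech DSP: F0 tracking, PSOLA pitch flattening, WSOLA
time-scale modification, and short-time level measurement.

These primitives back the prosody-attenuation stages. The F0 tracker is a
normalised-autocorrelation tracker (40 ms frames, 10 ms hop, 75-400 Hz
search range by default, covering the full F0 range of the emotional speech
material). Pitch flattening is time-domain pitch-synchronous overlap-add;
rate change is waveform-similarity overlap-add, which preserves pitch.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

# Tracker defaults: 40 ms analysis frames every 10 ms, 75-400 Hz.
FRAME_S = 0.040
HOP_S = 0.010
FMIN_HZ = 75.0
FMAX_HZ = 400.0
# A frame is voiced when its normalised autocorrelation peak exceeds this
# and it carries appreciable energy relative to the utterance.
VOICING_THRESHOLD = 0.5
ENERGY_FLOOR_REL = 1e-3


@dataclass(frozen=True)
class F0Track:
    """Per-frame F0 estimates; ``f0_hz`` is NaN on unvoiced frames."""

    times_s: np.ndarray
    f0_hz: np.ndarray

    @property
    def voiced(self) -> np.ndarray:
        return np.isfinite(self.f0_hz)

    def voiced_f0(self) -> np.ndarray:
        return self.f0_hz[self.voiced]


def _parabolic_refine(values: np.ndarray, i: int) -> float:
    """Sub-sample peak position via parabolic interpolation around bin i."""
    if i <= 0 or i >= len(values) - 1:
        return float(i)
    a, b, c = values[i - 1], values[i], values[i + 1]
    denom = a - 2.0 * b + c
    if denom == 0:
        return float(i)
    return i + 0.5 * (a - c) / denom


def track_f0(
    samples: np.ndarray,
    rate_hz: float,
    frame_s: float = FRAME_S,
    hop_s: float = HOP_S,
    fmin_hz: float = FMIN_HZ,
    fmax_hz: float = FMAX_HZ,
    voicing_threshold: float = VOICING_THRESHOLD,
) -> F0Track:
    """Autocorrelation F0 tracker.

    Frames whose normalised autocorrelation peak in the candidate lag range
    falls below ``voicing_threshold``, or whose RMS is negligible relative to
    the loudest frame, are flagged unvoiced (NaN).
    """
    samples = np.asarray(samples, dtype=np.float64)
    if len(samples) == 0:
        raise ValueError("cannot track F0 of an empty signal")
    if not (0 < fmin_hz < fmax_hz < rate_hz / 2):
        raise ValueError("need 0 < fmin < fmax < Nyquist")

    n_frame = int(round(frame_s * rate_hz))
    hop = int(round(hop_s * rate_hz))
    lag_min = int(np.floor(rate_hz / fmax_hz))
    lag_max = int(np.ceil(rate_hz / fmin_hz))
    if lag_max >= n_frame:
        raise ValueError("frame too short for the requested fmin")

    starts = np.arange(0, max(1, len(samples) - n_frame + 1), hop)
    times = (starts + n_frame / 2) / rate_hz
    f0 = np.full(len(starts), np.nan)

    frame_rms = np.array([
        np.sqrt(np.mean(samples[s:s + n_frame] ** 2)) for s in starts
    ])
    rms_floor = ENERGY_FLOOR_REL * (frame_rms.max() if frame_rms.size else 0.0)

    for k, s in enumerate(starts):
        if frame_rms[k] <= rms_floor:
            continue
        frame = samples[s:s + n_frame]
        frame = frame - frame.mean()
        denom = np.dot(frame, frame)
        if denom <= 0:
            continue
        ac = np.correlate(frame, frame, mode="full")[n_frame - 1:]
        ac = ac / denom
        window = ac[lag_min:lag_max + 1]
        i = int(np.argmax(window))
        if window[i] < voicing_threshold:
            continue
        lag = _parabolic_refine(ac, lag_min + i)
        if lag > 0:
            f0[k] = rate_hz / lag

    return F0Track(times_s=times, f0_hz=f0)


def _voiced_spans(track: F0Track, rate_hz: float, min_span_s: float = 0.05):
    """Contiguous voiced regions as (start_sample, end_sample, interpolator).

    Single-frame unvoiced dropouts inside a span are bridged by
    interpolation; spans shorter than ``min_span_s`` are ignored.
    """
    voiced = track.voiced.astype(int)
    # bridge isolated dropouts
    for i in range(1, len(voiced) - 1):
        if voiced[i] == 0 and voiced[i - 1] == 1 and voiced[i + 1] == 1:
            voiced[i] = 1
    spans = []
    i = 0
    while i < len(voiced):
        if voiced[i]:
            j = i
            while j + 1 < len(voiced) and voiced[j + 1]:
                j += 1
            t0, t1 = track.times_s[i], track.times_s[j]
            if t1 - t0 >= min_span_s:
                idx = np.arange(i, j + 1)
                tt = track.times_s[idx]
                ff = track.f0_hz[idx]
                ok = np.isfinite(ff)
                spans.append((
                    int(t0 * rate_hz), int(t1 * rate_hz),
                    (tt[ok], ff[ok]),
                ))
            i = j + 1
        else:
            i += 1
    return spans


def flatten_pitch(
    samples: np.ndarray,
    rate_hz: float,
    target_hz: float,
    fmin_hz: float = FMIN_HZ,
    fmax_hz: float = FMAX_HZ,
) -> np.ndarray:
    """Flatten voiced-span F0 to ``target_hz`` by TD-PSOLA.

    Analysis pitch marks are laid down at the local period from the tracked
    contour; synthesis marks at the constant target period. Each synthesis
    mark receives the Hann-windowed two-period grain of the nearest analysis
    mark, and the overlap-added span is normalised by the accumulated window
    envelope. Unvoiced and silent regions are returned unchanged, so the
    output duration equals the input duration exactly.
    """
    if not (fmin_hz <= target_hz <= fmax_hz):
        raise ValueError(
            f"target {target_hz} Hz outside tracker range "
            f"[{fmin_hz}, {fmax_hz}] Hz")
    samples = np.asarray(samples, dtype=np.float64)
    track = track_f0(samples, rate_hz, fmin_hz=fmin_hz, fmax_hz=fmax_hz)
    if not track.voiced.any():
        raise ValueError("signal contains no voiced spans")

    out = samples.copy()
    for s0, s1, (tt, ff) in _voiced_spans(track, rate_hz):
        def f0_at(t: float) -> float:
            return float(np.interp(t, tt, ff))

        # analysis marks at the local period
        marks = []
        t = s0 / rate_hz
        while t < s1 / rate_hz:
            marks.append(t)
            t += 1.0 / f0_at(t)
        if len(marks) < 2:
            continue
        marks = np.asarray(marks)

        period_new = 1.0 / target_hz
        acc = np.zeros(s1 - s0)
        wsum = np.zeros(s1 - s0)
        t = s0 / rate_hz
        while t < s1 / rate_hz:
            a = marks[int(np.argmin(np.abs(marks - t)))]
            half = int(round(rate_hz / f0_at(a)))  # one local period
            centre = int(round(a * rate_hz))
            lo, hi = centre - half, centre + half
            if lo < 0 or hi > len(samples):
                t += period_new
                continue
            grain = samples[lo:hi]
            win = np.hanning(len(grain))
            c_out = int(round(t * rate_hz)) - s0
            olo, ohi = c_out - half, c_out + half
            glo = max(0, -olo)
            ghi = len(grain) - max(0, ohi - (s1 - s0))
            olo, ohi = max(0, olo), min(s1 - s0, ohi)
            if ghi > glo:
                acc[olo:ohi] += grain[glo:ghi] * win[glo:ghi]
                wsum[olo:ohi] += win[glo:ghi]
            t += period_new
        nz = wsum > 1e-6
        span = out[s0:s1]
        span[nz] = acc[nz] / wsum[nz]
        out[s0:s1] = span
    return out


def time_stretch(
    samples: np.ndarray,
    rate_hz: float,
    ratio: float,
    frame_s: float = 0.045,
    search_s: float = 0.010,
) -> np.ndarray:
    """Pitch-preserving uniform time-scale modification by WSOLA.

    ``ratio`` is output duration / input duration. Segments are copied
    verbatim (so pitch is untouched) at a synthesis hop of half the frame,
    with the analysis read position advanced at ``hop/ratio`` and refined
    within ±``search_s`` by cross-correlation against the naturally
    continuing waveform.
    """
    if not (0.25 <= ratio <= 4.0):
        raise ValueError(f"scale factor {ratio} outside [0.25, 4]")
    samples = np.asarray(samples, dtype=np.float64)
    n_out = int(round(len(samples) * ratio))
    if ratio == 1.0 or len(samples) < int(frame_s * rate_hz) * 2:
        y = samples.copy()
        return _fit_length(y, n_out)

    n_frame = int(round(frame_s * rate_hz))
    if n_frame % 2:
        n_frame += 1
    hop_syn = n_frame // 2
    search = int(round(search_s * rate_hz))
    win = np.hanning(n_frame)

    out = np.zeros(n_out + n_frame)
    wsum = np.zeros(n_out + n_frame)

    pos_syn = 0
    # natural continuation of the previously copied segment
    prev_end = None  # samples following the last analysis segment
    while pos_syn < n_out:
        lo = int(round(pos_syn / ratio))
        if prev_end is None:
            best = min(max(lo, 0), len(samples) - n_frame)
        else:
            cand_lo = max(0, lo - search)
            cand_hi = min(len(samples) - n_frame, lo + search)
            if cand_hi <= cand_lo:
                best = min(max(lo, 0), max(0, len(samples) - n_frame))
            else:
                target = prev_end
                best, best_score = cand_lo, -np.inf
                seg_len = len(target)
                for cand in range(cand_lo, cand_hi + 1):
                    seg = samples[cand:cand + seg_len]
                    score = np.dot(seg, target)
                    norm = np.sqrt(np.dot(seg, seg)) + 1e-12
                    score = score / norm
                    if score > best_score:
                        best_score, best = score, cand
        seg = samples[best:best + n_frame]
        if len(seg) < n_frame:
            seg = np.pad(seg, (0, n_frame - len(seg)))
        out[pos_syn:pos_syn + n_frame] += seg * win
        wsum[pos_syn:pos_syn + n_frame] += win
        nxt = samples[best + hop_syn:best + hop_syn + hop_syn]
        prev_end = nxt if len(nxt) == hop_syn else None
        pos_syn += hop_syn

    nz = wsum > 1e-6
    out[nz] /= wsum[nz]
    return _fit_length(out[:n_out], n_out)


def _fit_length(y: np.ndarray, n: int) -> np.ndarray:
    if len(y) >= n:
        return y[:n]
    return np.pad(y, (0, n - len(y)))


def sliding_rms(
    samples: np.ndarray,
    rate_hz: float,
    window_s: float = 0.050,
) -> np.ndarray:
    """Per-sample RMS envelope over a centred sliding Hann window."""
    samples = np.asarray(samples, dtype=np.float64)
    n_win = max(3, int(round(window_s * rate_hz)))
    win = np.hanning(n_win)
    win /= win.sum()
    power = np.convolve(samples ** 2, win, mode="same")
    return np.sqrt(np.maximum(power, 0.0))


def band_spectral_distance(
    a: np.ndarray,
    b: np.ndarray,
    rate_hz: float,
    fmin_hz: float = 100.0,
    fmax_hz: float = 8000.0,
    n_bands: int = 24,
    floor_db: float = -40.0,
) -> float:
    """RMS log-spectral distance (dB) over log-spaced bands carrying energy.

    Band energies are compared only where the reference signal ``a`` has
    energy within ``floor_db`` of its loudest band; empty bands would
    otherwise be dominated by numerical noise and synthesis artifacts far
    below audibility.
    """
    n = min(len(a), len(b))
    A = np.abs(np.fft.rfft(a[:n])) ** 2
    B = np.abs(np.fft.rfft(b[:n])) ** 2
    freqs = np.fft.rfftfreq(n, 1.0 / rate_hz)
    edges = np.geomspace(fmin_hz, fmax_hz, n_bands + 1)
    la, lb = [], []
    for i in range(n_bands):
        m = (freqs >= edges[i]) & (freqs < edges[i + 1])
        if not m.any():
            continue
        la.append(A[m].sum())
        lb.append(B[m].sum())
    la = 10.0 * np.log10(np.asarray(la) + 1e-300)
    lb = 10.0 * np.log10(np.asarray(lb) + 1e-300)
    keep = la >= la.max() + floor_db
    return float(np.sqrt(np.mean((la[keep] - lb[keep]) ** 2)))


def frame_rms(
    samples: np.ndarray,
    rate_hz: float,
    frame_s: float = 0.050,
) -> tuple[np.ndarray, np.ndarray]:
    """Short-time RMS on non-overlapping-centred frames (50% overlap hop).

    Returns (frame centre samples, RMS per frame).
    """
    samples = np.asarray(samples, dtype=np.float64)
    n_frame = int(round(frame_s * rate_hz))
    hop = max(1, n_frame // 2)
    starts = np.arange(0, max(1, len(samples) - n_frame + 1), hop)
    rms = np.array([
        np.sqrt(np.mean(samples[s:s + n_frame] ** 2)) for s in starts
    ])
    centres = starts + n_frame // 2
    return centres, rms


def apply_frame_gains(
    samples: np.ndarray,
    centres: np.ndarray,
    gains: np.ndarray,
) -> np.ndarray:
    """Apply per-frame gains, linearly interpolated to every sample."""
    idx = np.arange(len(samples))
    g = np.interp(idx, centres, gains)
    return samples * g
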