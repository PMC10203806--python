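"""Forward simulation of dual-wavelength fNIRS recordings.

The simulator produces raw 760/850 nm intensities at the acquisition rate
of 2.6 Hz from known ground-truth condition amplitudes, so the whole
analysis chain can be validated by parameter recovery. Long channels carry

    sum_cond beta[cond, roi, chromophore] * (3 s boxcar (x) canonical HRF)

plus shared systemic oscillations (Mayer-wave-like ~0.1 Hz, respiratory
~0.25 Hz, cardiac ~1.1 Hz) with channel-specific coupling weights, slow
drift, and AR(1) sensor noise. Short-separation channels (8 mm) carry only
the non-neural components, which is what makes them usable as nuisance
regressors downstream. Concentrations map to raw intensities through the
same modified Beer-Lambert model the analysis inverts.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import glm, optics

ROIS = ("LSTG", "RSTG", "LIFG", "RIFG", "LMFG", "RMFG")

DEFAULT_LONG_COUNTS = {roi: 10 for roi in ROIS}
DEFAULT_SHORT_COUNTS = {"LSTG": 2, "RSTG": 2, "LIFG": 1, "RIFG": 1,
                        "LMFG": 1, "RMFG": 1}
LONG_DISTANCE_MM = 30.0
SHORT_DISTANCE_MM = 8.0
HBR_RATIO_DEFAULT = -1.0 / 3.0


def make_montage(
    per_roi_long_counts: dict[str, int] | None = None,
    per_roi_short_counts: dict[str, int] | None = None,
    long_distance_mm: float = LONG_DISTANCE_MM,
    short_distance_mm: float = SHORT_DISTANCE_MM,
) -> pd.DataFrame:
    """Build a channel table.

    Defaults mirror the recording montage: 60 long channels (~30 mm) over
    bilateral STG, IFG and MFG plus 8 short channels (8 mm), two per STG
    and one per IFG/MFG.
    """
    import logging
    if per_roi_long_counts is None:
        per_roi_long_counts = DEFAULT_LONG_COUNTS
    if per_roi_short_counts is None:
        per_roi_short_counts = DEFAULT_SHORT_COUNTS
    rows = []
    src = det = 0
    for roi, n in per_roi_long_counts.items():
        if n > 0 and per_roi_short_counts.get(roi, 0) == 0:
            logging.getLogger(__name__).warning(
                "ROI %s has long channels but no short channel; "
                "short-channel regression will be degraded there", roi)
        for _ in range(n):
            src += 1
            det += 1
            rows.append({"channel": f"S{src}_D{det}", "source": src,
                         "detector": det, "distance_mm": long_distance_mm,
                         "roi": roi, "is_short": False})
    for roi, n in per_roi_short_counts.items():
        for _ in range(n):
            src += 1
            det += 1
            rows.append({"channel": f"S{src}_D{det}s", "source": src,
                         "detector": det, "distance_mm": short_distance_mm,
                         "roi": roi, "is_short": True})
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class GroundTruth:
    """True neural amplitudes for one simulated participant.

    ``beta_hbo`` maps (condition, roi) -> HbO response amplitude in uM;
    the HbR amplitude is ``hbr_ratio`` times the HbO amplitude (negative:
    activation raises HbO and lowers HbR).
    """

    beta_hbo: dict[tuple[str, str], float]
    hbr_ratio: float = HBR_RATIO_DEFAULT

    def __post_init__(self) -> None:
        if not self.hbr_ratio < 0:
            raise ValueError("hbr_ratio must be negative")
        if not all(np.isfinite(list(self.beta_hbo.values()))):
            raise ValueError("betas must be finite")

    def beta(self, condition: str, roi: str, chromophore: str) -> float:
        b = self.beta_hbo.get((condition, roi), 0.0)
        return b if chromophore == "hbo" else b * self.hbr_ratio


@dataclass(frozen=True)
class NoiseConfig:
    """Amplitudes (uM) and frequencies (Hz) of the non-neural components.

    Systemic oscillations are shared latent sinusoids with channel-specific
    coupling weights (mean 1, sd ``coupling_sd``, clipped at 0), emulating
    location-dependent heterogeneity of the extracerebral signal. Drift is
    a sum of slow random cosines below the analysis drift cutoff. Sensor
    noise is AR(1).
    """

    mayer_amp: float = 0.8
    mayer_freq_hz: float = 0.1
    resp_amp: float = 0.5
    resp_freq_hz: float = 0.25
    cardiac_amp: float = 0.4
    cardiac_freq_hz: float = 1.1
    drift_amp: float = 1.5
    n_drift_cosines: int = 3
    white_sd: float = 0.4
    ar1_rho: float = 0.3
    coupling_sd: float = 0.3
    systemic_hbr_scale: float = 0.3

    def __post_init__(self) -> None:
        for name in ("mayer_amp", "resp_amp", "cardiac_amp", "drift_amp",
                     "white_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass(frozen=True)
class NirsRecording:
    """Raw dual-wavelength intensities plus montage, events and (when
    simulated) the ground truth."""

    intensity: np.ndarray            # (n_channels, 2 wavelengths, T)
    rate_hz: float
    wavelengths_nm: tuple[float, float]
    montage: pd.DataFrame
    events: pd.DataFrame
    ground_truth: GroundTruth | None = None

    def __post_init__(self) -> None:
        if np.any(self.intensity <= 0):
            raise ValueError("raw intensities must be strictly positive")

    @property
    def duration_s(self) -> float:
        return self.intensity.shape[-1] / self.rate_hz


def simulate_concentrations(
    montage: pd.DataFrame,
    events: pd.DataFrame,
    truth: GroundTruth,
    noise: NoiseConfig | None = None,
    rate_hz: float = glm.ACQUISITION_RATE_HZ,
    duration_s: float | None = None,
    boxcar_s: float = glm.BOXCAR_S,
    seed: int = 0,
) -> np.ndarray:
    """Simulate HbO/HbR time courses (uM): (n_channels, 2, T).

    Long channels receive the event-locked neural response for their ROI;
    short channels receive only systemic + drift + sensor noise.
    """
    if noise is None:
        noise = NoiseConfig()
    rng = np.random.default_rng(seed)
    exp_events = events[events["kind"] == "experimental"] \
        if "kind" in events.columns else events
    if duration_s is None:
        duration_s = float((events["onset"] + events["duration"]).max() + 40.0)
    n = int(round(duration_s * rate_hz))
    t = np.arange(n) / rate_hz

    regs = glm.condition_regressors(exp_events, rate_hz, n, boxcar_s)

    n_ch = len(montage)
    conc = np.zeros((n_ch, 2, n))

    # shared systemic latents
    latents = []
    for amp, freq in ((noise.mayer_amp, noise.mayer_freq_hz),
                      (noise.resp_amp, noise.resp_freq_hz),
                      (noise.cardiac_amp, noise.cardiac_freq_hz)):
        phase = rng.uniform(0, 2 * np.pi)
        jitter = rng.normal(0, 0.02)
        latents.append(amp * np.sin(2 * np.pi * (freq + jitter) * t + phase))

    for i, row in enumerate(montage.itertuples(index=False)):
        coupling = np.clip(
            rng.normal(1.0, noise.coupling_sd, size=len(latents)), 0.0, None)
        systemic = sum(w * lat for w, lat in zip(coupling, latents))
        for c, chrom in enumerate(glm.CHROMOPHORES):
            scale = 1.0 if chrom == "hbo" else noise.systemic_hbr_scale
            x = scale * systemic.copy()
            # slow drift below the analysis cutoff
            for _ in range(noise.n_drift_cosines):
                f = rng.uniform(0.0005, 0.008)
                ph = rng.uniform(0, 2 * np.pi)
                x += (noise.drift_amp / noise.n_drift_cosines
                      * np.cos(2 * np.pi * f * t + ph)) * scale
            # AR(1) sensor noise
            if noise.white_sd > 0:
                innov_sd = noise.white_sd * np.sqrt(1 - noise.ar1_rho ** 2)
                e = rng.normal(0, innov_sd, size=n)
                ar = np.empty(n)
                ar[0] = rng.normal(0, noise.white_sd)
                for k in range(1, n):
                    ar[k] = noise.ar1_rho * ar[k - 1] + e[k]
                x += ar
            if not row.is_short:
                for cond in regs.columns:
                    x += truth.beta(cond, row.roi, chrom) \
                        * regs[cond].to_numpy()
            conc[i, c] = x
    return conc


def concentrations_to_raw(
    conc: np.ndarray,
    montage: pd.DataFrame,
    events: pd.DataFrame,
    rate_hz: float = glm.ACQUISITION_RATE_HZ,
    ppf: float = optics.DEFAULT_PPF,
    baseline_intensity: float = 1.0,
    truth: GroundTruth | None = None,
) -> NirsRecording:
    """Map concentrations to raw intensities via the forward MBLL.

    ``I_wl(t) = I0 * exp(-(eps_hbo*HbO + eps_hbr*HbR) * d * ppf)`` — always
    strictly positive.
    """
    conc = np.asarray(conc, float)
    if not np.all(np.isfinite(conc)):
        raise ValueError("concentrations contain non-finite values")
    n_ch = conc.shape[0]
    intensity = np.empty_like(conc)
    d = montage["distance_mm"].to_numpy(float)
    for i in range(n_ch):
        od = optics.concentration_to_od(conc[i], d[i], ppf)
        intensity[i] = optics.od_to_intensity(od, baseline_intensity)
    return NirsRecording(
        intensity=intensity,
        rate_hz=rate_hz,
        wavelengths_nm=optics.WAVELENGTHS_NM,
        montage=montage.reset_index(drop=True),
        events=events.reset_index(drop=True),
        ground_truth=truth,
    )


def simulate_session(
    montage: pd.DataFrame,
    events: pd.DataFrame,
    truth: GroundTruth,
    noise: NoiseConfig | None = None,
    seed: int = 0,
    rate_hz: float = glm.ACQUISITION_RATE_HZ,
    ppf: float = optics.DEFAULT_PPF,
) -> NirsRecording:
    """Simulate one participant's raw recording for a schedule."""
    conc = simulate_concentrations(montage, events, truth, noise,
                                   rate_hz=rate_hz, seed=seed)
    return concentrations_to_raw(conc, montage, events, rate_hz=rate_hz,
                                 ppf=ppf, truth=truth)


def default_ground_truth(
    conditions: tuple[str, ...],
    rng: np.random.Generator,
    group_means: dict[tuple[str, str], float] | None = None,
    participant_sd: float = 0.3,
    hbr_ratio: float = HBR_RATIO_DEFAULT,
) -> GroundTruth:
    """Draw one participant's ground truth around group-level means.

    Without explicit ``group_means``, speech conditions activate STG
    bilaterally (right larger than left: 2.5 vs 2.0 uM HbO) and weakly
    activate IFG (0.5 uM); the silence control and the frontal MFG carry no
    event-locked response.
    """
    if group_means is None:
        group_means = {}
        for cond in conditions:
            if cond == "control":
                continue
            for roi, amp in (("LSTG", 2.0), ("RSTG", 2.5),
                             ("LIFG", 0.5), ("RIFG", 0.5)):
                group_means[(cond, roi)] = amp
    beta = {key: float(m + rng.normal(0, participant_sd))
            for key, m in group_means.items()}
    return GroundTruth(beta_hbo=beta, hbr_ratio=hbr_ratio)
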