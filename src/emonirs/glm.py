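"""First-level fNIRS GLM.

The analysis chain for one recording session:

1. resample the raw 2.6 Hz signal to 0.6 Hz (polyphase, rational 3/13);
2. convert raw intensities to optical density (absolute intensities,
   per-channel temporal mean as reference);
3. convert OD to HbO/HbR concentration via the modified Beer-Lambert law
   (PPF 0.1);
4. keep long channels only (source-detector distance within 20-40 mm,
   bounds inclusive);
5. build the design matrix: one regressor per condition — a 3 s boxcar at
   each onset convolved with the canonical haemodynamic response — plus a
   discrete-cosine drift basis up to 0.01 Hz, a constant, and all
   principal components of the short-separation channels (per
   chromophore);
6. fit each long channel with an AR(1)-prewhitened GLM;
7. average channel betas within each region of interest, weighted by the
   inverse standard error.

Epoch-averaged grand waveforms (for visual inspection of the block
response) are produced by :func:`epoch_average`.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy import special

from . import optics

ANALYSIS_RATE_HZ = 0.6
ACQUISITION_RATE_HZ = 2.6
BOXCAR_S = 3.0
DRIFT_CUTOFF_HZ = 0.01
CHANNEL_MIN_MM = 20.0
CHANNEL_MAX_MM = 40.0

CHROMOPHORES = ("hbo", "hbr")


# ---------------------------------------------------------------------------
# signal conditioning

def resample(data: np.ndarray, rate_hz: float, target_rate_hz: float,
             axis: int = -1) -> np.ndarray:
    """Anti-aliased polyphase resampling along ``axis``.

    The 2.6 -> 0.6 Hz reduction is the rational ratio 3/13; other rational
    ratios are derived from the rates' integer representation.
    """
    if target_rate_hz >= rate_hz:
        raise ValueError("target rate must be below the original rate")
    from fractions import Fraction
    frac = Fraction(target_rate_hz / rate_hz).limit_denominator(1000)
    # mean padding: raw intensities sit on a non-zero baseline, and zero
    # padding would ring a large step through the anti-aliasing filter
    return sps.resample_poly(data, frac.numerator, frac.denominator,
                             axis=axis, padtype="mean")


def to_optical_density(intensity: np.ndarray) -> np.ndarray:
    """Raw intensity -> OD; see :func:`emonirs.optics.intensity_to_od`."""
    return optics.intensity_to_od(intensity)


def beer_lambert(
    od: np.ndarray,
    distances_mm: np.ndarray,
    ppf: float = optics.DEFAULT_PPF,
) -> np.ndarray:
    """OD (n_channels, 2 wavelengths, T) -> conc (n_channels, 2, T) in uM.

    Output chromophore order is (HbO, HbR).
    """
    od = np.asarray(od, float)
    out = np.empty_like(od)
    for i in range(od.shape[0]):
        out[i] = optics.od_to_concentration(od[i], distances_mm[i], ppf)
    return out


def select_long_channels(
    montage: pd.DataFrame,
    min_mm: float = CHANNEL_MIN_MM,
    max_mm: float = CHANNEL_MAX_MM,
) -> pd.DataFrame:
    """Long-channel subset: min <= distance <= max (bounds inclusive)."""
    sel = montage[(montage["distance_mm"] >= min_mm)
                  & (montage["distance_mm"] <= max_mm)]
    if sel.empty:
        raise ValueError("no channels within the distance bounds")
    return sel


# ---------------------------------------------------------------------------
# design matrix

def hrf_canonical(t_s: np.ndarray) -> np.ndarray:
    """Canonical haemodynamic response: difference of gamma densities
    peaking at 6 s (response) and 16 s (undershoot), undershoot ratio 1/6,
    peak-normalised to 1. Zero for t < 0 and at t = 0."""
    t = np.asarray(t_s, float)
    out = np.zeros_like(t)
    pos = t > 0

    def gamma_peak(tt, peak, scale=1.0):
        shape = peak / scale + 1.0
        return (tt ** (shape - 1) * np.exp(-tt / scale)
                / (scale ** shape * special.gamma(shape)))

    h = gamma_peak(t[pos], 6.0) - gamma_peak(t[pos], 16.0) / 6.0
    out[pos] = h
    # normalise peak to 1 on a dense grid
    tt = np.linspace(0, 32, 3201)[1:]
    peak = (gamma_peak(tt, 6.0) - gamma_peak(tt, 16.0) / 6.0).max()
    return out / peak


def block_response_kernel(
    boxcar_s: float = BOXCAR_S,
    internal_rate_hz: float = 10.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Continuous-time single-block response: boxcar (x) canonical HRF,
    peak-normalised to 1. Returned as (times_s, values) on a fine grid so
    regressors at any sampling rate are samples of the same function."""
    t = np.arange(0.0, 33.0 + boxcar_s, 1.0 / internal_rate_hz)
    hrf = hrf_canonical(t)
    n_box = max(1, int(round(boxcar_s * internal_rate_hz)))
    kernel = np.convolve(np.ones(n_box), hrf) / internal_rate_hz
    kernel = kernel[:len(t)]
    return t, kernel / kernel.max()


def condition_regressors(
    events: pd.DataFrame,
    rate_hz: float,
    n_samples: int,
    boxcar_s: float = BOXCAR_S,
) -> pd.DataFrame:
    """One boxcar-convolved-HRF regressor per condition label.

    A ``boxcar_s`` boxcar placed at each onset of the condition is
    convolved with the canonical HRF; the single-block kernel is evaluated
    at the exact onset offsets (no quantisation to the sample grid) and has
    unit peak, so a fitted beta reads as the peak response amplitude.
    """
    if (events["onset"] > n_samples / rate_hz).any():
        raise ValueError("event beyond the end of the recording")
    tk, kernel = block_response_kernel(boxcar_s)
    t = np.arange(n_samples) / rate_hz
    cols = {}
    for cond in pd.unique(events["trial_type"]):
        x = np.zeros(n_samples)
        for onset in events.loc[events["trial_type"] == cond, "onset"]:
            x += np.interp(t - onset, tk, kernel, left=0.0, right=0.0)
        cols[str(cond)] = x
    return pd.DataFrame(cols)


def dct_drift_basis(
    n_samples: int,
    rate_hz: float,
    cutoff_hz: float = DRIFT_CUTOFF_HZ,
) -> pd.DataFrame:
    """Discrete-cosine drift regressors with frequencies <= cutoff, plus a
    constant. Order K = floor(2 * duration * cutoff)."""
    duration = n_samples / rate_hz
    order = int(np.floor(2.0 * duration * cutoff_hz))
    n = np.arange(n_samples)
    cols = {"constant": np.ones(n_samples)}
    for k in range(1, order + 1):
        cols[f"drift_{k}"] = np.cos(np.pi * k * (2 * n + 1) / (2 * n_samples))
    return pd.DataFrame(cols)


def short_channel_components(short_conc: np.ndarray) -> np.ndarray:
    """All principal components of the centred short-channel matrix.

    ``short_conc`` is (n_short, T); returns (n_components, T), each
    unit-variance. Degenerate directions (zero singular value) are dropped.
    """
    X = np.asarray(short_conc, float)
    if X.ndim != 2 or X.shape[0] < 1:
        raise ValueError("need at least one short channel")
    Xc = X - X.mean(axis=1, keepdims=True)
    # PCA via SVD on (T, n_short)
    U, s, Vt = np.linalg.svd(Xc.T, full_matrices=False)
    keep = s > 1e-10 * max(1.0, s.max())
    comps = U[:, keep].T                      # orthonormal scores
    sd = comps.std(axis=1, ddof=0)
    return comps / sd[:, None]


def build_design(
    events: pd.DataFrame,
    rate_hz: float,
    n_samples: int,
    boxcar_s: float = BOXCAR_S,
    drift_cutoff_hz: float = DRIFT_CUTOFF_HZ,
    short_components: np.ndarray | None = None,
) -> pd.DataFrame:
    """Assemble the full first-level design matrix."""
    parts = [condition_regressors(events, rate_hz, n_samples, boxcar_s),
             dct_drift_basis(n_samples, rate_hz, drift_cutoff_hz)]
    if short_components is not None and len(short_components):
        sc = pd.DataFrame(
            {f"short_pc_{i + 1}": comp
             for i, comp in enumerate(np.atleast_2d(short_components))})
        parts.append(sc)
    X = pd.concat(parts, axis=1)
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        import logging
        logging.getLogger(__name__).warning(
            "design matrix is rank deficient (%d < %d)", rank, X.shape[1])
    return X


# ---------------------------------------------------------------------------
# AR(1)-whitened GLM

@dataclass
class ChannelFit:
    """GLM result for one channel x chromophore."""

    beta: pd.Series
    se: pd.Series
    rho: float
    dof: int
    resid_white: np.ndarray | None = None


def fit_ar1_glm(
    y: np.ndarray,
    X: pd.DataFrame,
    rho: float | None = None,
    tol: float = 1e-3,
    max_iter: int = 10,
) -> ChannelFit:
    """GLM with a lag-1 autoregressive noise model.

    Iterative prewhitening: OLS fit, estimate rho from the lag-1
    autocorrelation of the residuals, apply the Prais-Winsten transform to
    y and X, refit; repeated until |delta rho| < tol. Passing ``rho``
    fixes the coefficient (rho=0 reproduces OLS exactly).
    """
    y = np.asarray(y, float)
    Xv = X.to_numpy(float)
    n, p = Xv.shape
    if len(y) != n:
        raise ValueError("y and X row counts differ")
    if np.linalg.matrix_rank(Xv) < p:
        # identify (approximately) collinear columns for the error message
        _, r = np.linalg.qr(Xv)
        bad = [X.columns[j] for j in range(p) if abs(r[j, j]) < 1e-8]
        raise ValueError(f"design is rank deficient; suspect columns: {bad}")

    def whiten(arr, r):
        out = arr.copy().astype(float)
        out[1:] = arr[1:] - r * arr[:-1]
        out[0] = arr[0] * np.sqrt(1.0 - r ** 2)
        return out

    fixed_rho = rho is not None
    rho_hat = rho if fixed_rho else 0.0
    beta = None
    for _ in range(max_iter):
        yw = whiten(y, rho_hat)
        Xw = whiten(Xv, rho_hat)
        beta, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
        resid = y - Xv @ beta
        if fixed_rho:
            break
        denom = float(resid @ resid)
        # near-perfect fits leave only rounding error; its autocorrelation
        # is meaningless, so treat the noise as white
        scale = float(y @ y)
        if denom <= 0 or (scale > 0 and denom < 1e-20 * scale):
            rho_hat = 0.0
            break
        new_rho = float(resid[1:] @ resid[:-1] / denom)
        new_rho = float(np.clip(new_rho, -0.99, 0.99))
        if abs(new_rho - rho_hat) < tol:
            rho_hat = new_rho
            break
        rho_hat = new_rho

    yw = whiten(y, rho_hat)
    Xw = whiten(Xv, rho_hat)
    beta, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
    resid_w = yw - Xw @ beta
    dof = n - p
    s2 = float(resid_w @ resid_w) / dof
    cov = s2 * np.linalg.inv(Xw.T @ Xw)
    se = np.sqrt(np.diag(cov))
    return ChannelFit(
        beta=pd.Series(beta, index=X.columns),
        se=pd.Series(se, index=X.columns),
        rho=float(rho_hat),
        dof=dof,
        resid_white=resid_w,
    )


def roi_aggregate(
    channel_results: pd.DataFrame,
    weight: str = "inverse_se",
    residual_corr: dict[str, pd.DataFrame] | None = None,
) -> pd.DataFrame:
    """SE-weighted ROI averaging of channel betas.

    ``channel_results`` columns: channel, roi, chromophore, condition,
    beta, se. Weights are 1/se (default) or 1/se^2; the ROI standard error
    is the propagated error of the weighted mean. Channel estimates within
    a session are not independent — every channel is fitted against the
    same design, including the shared short-channel components — so when
    ``residual_corr`` provides the whitened-residual correlation matrix
    per chromophore (channel x channel), the propagation uses the full
    covariance ``sum_ij w_i w_j se_i se_j rho_ij``; without it the
    channels are treated as independent.
    """
    if weight not in ("inverse_se", "inverse_variance"):
        raise ValueError("weight must be 'inverse_se' or 'inverse_variance'")
    rows = []
    for (roi, chrom, cond), g in channel_results.groupby(
            ["roi", "chromophore", "condition"], sort=False):
        se = np.maximum(g["se"].to_numpy(float), 1e-12)  # degenerate fits
        beta = g["beta"].to_numpy(float)
        w = 1.0 / se if weight == "inverse_se" else 1.0 / se ** 2
        theta = float(np.sum(w * beta) / np.sum(w))
        if residual_corr is not None and chrom in residual_corr:
            R = residual_corr[chrom].loc[g["channel"], g["channel"]] \
                .to_numpy(float)
            var = float(w @ (np.outer(se, se) * R) @ w)
        else:
            var = float(np.sum(w ** 2 * se ** 2))
        se_roi = float(np.sqrt(max(var, 0.0)) / np.sum(w))
        rows.append({"roi": roi, "chromophore": chrom, "condition": cond,
                     "theta": theta, "se": se_roi, "n_channels": len(g)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# orchestration

def first_level(
    recording,
    ppf: float = optics.DEFAULT_PPF,
    analysis_rate_hz: float = ANALYSIS_RATE_HZ,
    boxcar_s: float = BOXCAR_S,
    drift_cutoff_hz: float = DRIFT_CUTOFF_HZ,
    use_short_regression: bool = True,
    weight: str = "inverse_se",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the full first-level chain on one recording.

    ``recording`` is an :class:`emonirs.synth.NirsRecording` (or anything
    with ``intensity``, ``rate_hz``, ``montage``, ``events`` attributes).
    Returns ``(channel_results, roi_estimates)`` DataFrames. Only
    experimental trials enter the design.
    """
    montage = recording.montage
    events = recording.events
    if "kind" in events.columns:
        events = events[events["kind"] == "experimental"]

    data = resample(recording.intensity, recording.rate_hz, analysis_rate_hz)
    od = to_optical_density(data)
    conc = beer_lambert(od, montage["distance_mm"].to_numpy(float), ppf)
    n_samples = conc.shape[-1]

    long_idx = select_long_channels(montage).index.to_numpy()
    short_idx = montage.index[montage["is_short"]].to_numpy()

    chan_rows = []
    residual_corr: dict[str, pd.DataFrame] = {}
    for c, chrom in enumerate(CHROMOPHORES):
        short_comps = None
        if use_short_regression and len(short_idx):
            short_comps = short_channel_components(conc[short_idx, c, :])
        X = build_design(events, analysis_rate_hz, n_samples,
                         boxcar_s, drift_cutoff_hz, short_comps)
        cond_names = [str(t) for t in pd.unique(events["trial_type"])]
        resids = []
        for i in long_idx:
            fit = fit_ar1_glm(conc[i, c, :], X)
            resids.append(fit.resid_white)
            for cond in cond_names:
                chan_rows.append({
                    "channel": montage.loc[i, "channel"],
                    "roi": montage.loc[i, "roi"],
                    "chromophore": chrom,
                    "condition": cond,
                    "beta": float(fit.beta[cond]),
                    "se": float(fit.se[cond]),
                    "rho": fit.rho,
                    "dof": fit.dof,
                })
        R = np.atleast_2d(np.corrcoef(np.vstack(resids)))
        R = np.nan_to_num(R, nan=0.0)
        np.fill_diagonal(R, 1.0)
        names = montage.loc[long_idx, "channel"]
        residual_corr[chrom] = pd.DataFrame(R, index=names, columns=names)
    channel_results = pd.DataFrame(chan_rows)
    roi_estimates = roi_aggregate(channel_results, weight=weight,
                                  residual_corr=residual_corr)
    return channel_results, roi_estimates


def epoch_average(
    conc: np.ndarray,
    rate_hz: float,
    events: pd.DataFrame,
    montage: pd.DataFrame,
    window_s: tuple[float, float] = (-5.0, 30.0),
) -> pd.DataFrame:
    """Grand-average waveforms per condition x ROI x chromophore.

    Epochs are cut around each experimental onset, baseline-corrected by
    the pre-onset mean, and averaged over trials and the ROI's long
    channels with a t-based 95% CI.

    Returns a long DataFrame: condition, roi, chromophore, time_s, mean,
    ci_lo, ci_hi.
    """
    from scipy import stats as sstats
    if "kind" in events.columns:
        events = events[events["kind"] == "experimental"]
    i_lo = int(round(window_s[0] * rate_hz))
    i_hi = int(round(window_s[1] * rate_hz))
    times = np.arange(i_lo, i_hi) / rate_hz
    long_mont = select_long_channels(montage)
    rows = []
    for cond in pd.unique(events["trial_type"]):
        onsets = events.loc[events["trial_type"] == cond, "onset"]
        for roi, g in long_mont.groupby("roi", sort=False):
            idx = g.index.to_numpy()
            for c, chrom in enumerate(CHROMOPHORES):
                epochs = []
                for onset in onsets:
                    i0 = int(round(onset * rate_hz))
                    lo, hi = i0 + i_lo, i0 + i_hi
                    if lo < 0 or hi > conc.shape[-1]:
                        raise ValueError("epoch window outside recording")
                    seg = conc[idx, c, lo:hi]
                    base = seg[:, :(-i_lo)].mean(axis=1, keepdims=True) \
                        if i_lo < 0 else 0.0
                    epochs.append(seg - base)
                stack = np.concatenate(epochs, axis=0)
                mean = stack.mean(axis=0)
                n = stack.shape[0]
                if n > 1:
                    sem = stack.std(axis=0, ddof=1) / np.sqrt(n)
                    tcrit = sstats.t.ppf(0.975, n - 1)
                else:
                    sem = np.zeros_like(mean)
                    tcrit = 0.0
                for k, t in enumerate(times):
                    rows.append({
                        "condition": cond, "roi": roi, "chromophore": chrom,
                        "time_s": float(t), "mean": float(mean[k]),
                        "ci_lo": float(mean[k] - tcrit * sem[k]),
                        "ci_hi": float(mean[k] + tcrit * sem[k]),
                    })
    return pd.DataFrame(rows)
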