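"""Group-level statistics.

Second level of the haemodynamic analysis and the shared statistical
machinery:

* linear mixed cell-means models of ROI response amplitudes (suppressed
  intercept, so every ROI x condition cell is estimated against zero),
  with participant random intercepts and random condition effects;
* Cook's-distance screening of influential rows before the mixed fit;
* planned contrasts between cell estimates with Benjamini-Hochberg FDR
  correction across each contrast family;
* sliding-difference and treatment contrast codings for the behavioural
  models;
* Nakagawa marginal/conditional R-squared;
* the brain-behaviour model: response amplitude against emotion-recognition
  accuracy per ROI, with participant random intercepts;
* the unsigned HbO-HbR difference metric.

Mixed models are fitted by REML via :mod:`statsmodels` (``MixedLM``); the
codings, contrasts, FDR, Cook's distance and R-squared computations are
implemented here.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# contrast codings

@dataclass(frozen=True)
class ContrastCoding:
    """A factor coding: levels and the (k x k-1) coding matrix."""

    kind: str
    levels: tuple[str, ...]
    matrix: np.ndarray

    @property
    def column_names(self) -> list[str]:
        if self.kind == "sliding_difference":
            return [f"{self.levels[j + 1]}-{self.levels[j]}"
                    for j in range(len(self.levels) - 1)]
        return [f"{lvl}-{self.levels[0]}" for lvl in self.levels[1:]]

    def encode(self, values) -> np.ndarray:
        """Map a sequence of level labels to rows of the coding matrix."""
        index = {lvl: i for i, lvl in enumerate(self.levels)}
        rows = np.array([index[v] for v in values])
        return self.matrix[rows]


def sliding_diff_coding(levels: tuple[str, ...]) -> ContrastCoding:
    """Sliding-difference (successive differences) coding.

    The j-th regression coefficient estimates mu[j+1] - mu[j] for
    consecutive factor levels. Closed form for k levels: entry (i, j) is
    -(k - j)/k for i <= j else j/k (1-indexed).
    """
    k = len(levels)
    if k < 2:
        raise ValueError("need at least two levels")
    M = np.empty((k, k - 1))
    for i in range(1, k + 1):
        for j in range(1, k):
            M[i - 1, j - 1] = -(k - j) / k if i <= j else j / k
    return ContrastCoding("sliding_difference", tuple(levels), M)


def treatment_coding(levels: tuple[str, ...]) -> ContrastCoding:
    """Treatment (dummy) coding against the first level."""
    k = len(levels)
    if k < 2:
        raise ValueError("need at least two levels")
    M = np.zeros((k, k - 1))
    for j in range(1, k):
        M[j, j - 1] = 1.0
    return ContrastCoding("treatment", tuple(levels), M)


def difference_matrix(k: int) -> np.ndarray:
    """(k-1) x k matrix whose rows are the consecutive differences
    mu[i+1] - mu[i]; ``difference_matrix(k) @ sliding coding = identity``."""
    D = np.zeros((k - 1, k))
    for i in range(k - 1):
        D[i, i] = -1.0
        D[i, i + 1] = 1.0
    return D


# ---------------------------------------------------------------------------
# multiple testing and influence

def fdr_bh(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    ``p_adj[(i)] = min_{j >= i} ( m * p[(j)] / j )`` over the ascending
    order statistics, clipped at 1.
    """
    p = np.asarray(p_values, float)
    m = len(p)
    order = np.argsort(p)
    ranked = p[order] * m / np.arange(1, m + 1)
    # enforce monotonicity from the largest p downwards
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.clip(adj, 0, 1)
    return out


def cooks_distance(y: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Cook's distance of every row of an OLS regression.

    ``D_i = r_i^2 h_ii / (p s^2 (1 - h_ii)^2)`` with hat matrix leverages
    h_ii and the usual residual variance estimate s^2.
    """
    y = np.asarray(y, float)
    X = np.atleast_2d(np.asarray(X, float))
    n, p = X.shape
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    XtX_inv = np.linalg.pinv(X.T @ X)
    h = np.einsum("ij,jk,ik->i", X, XtX_inv, X)
    s2 = float(resid @ resid) / (n - p)
    return resid ** 2 * h / (p * s2 * (1 - h) ** 2)


def cooks_exclude(
    y: np.ndarray,
    X: np.ndarray,
    threshold: float | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Flag influential rows: Cook's D above ``threshold`` (default 4/N).

    Returns (retained indices, excluded indices, distances).
    """
    y = np.asarray(y, float)
    D = cooks_distance(y, X)
    if threshold is None:
        threshold = 4.0 / len(y)
    excluded = np.flatnonzero(D > threshold)
    retained = np.flatnonzero(D <= threshold)
    if len(excluded):
        log.info("Cook's distance excluded %d of %d rows (threshold %.3g)",
                 len(excluded), len(y), threshold)
    return retained, excluded, D


# ---------------------------------------------------------------------------
# second-level mixed model

def _cell_design(df: pd.DataFrame) -> tuple[np.ndarray, list[tuple[str, str]]]:
    """Suppressed-intercept cell-means design: one column per ROI x
    condition cell."""
    cells = sorted({(r, c) for r, c in zip(df["roi"], df["condition"])})
    index = {cell: k for k, cell in enumerate(cells)}
    X = np.zeros((len(df), len(cells)))
    for i, (r, c) in enumerate(zip(df["roi"], df["condition"])):
        X[i, index[(r, c)]] = 1.0
    return X, cells


@dataclass
class CellModelResult:
    """Second-level fit for one chromophore."""

    cells: pd.DataFrame              # roi, condition, estimate, se, ci, t, p
    cov: np.ndarray                  # covariance of the cell estimates
    excluded: np.ndarray             # row indices dropped by Cook's screen
    random_structure: str            # structure actually fitted
    variance_components: dict[str, float]
    model_result: object = None


def fit_cellmeans_model(
    roi_estimates: pd.DataFrame,
    chromophore: str = "hbo",
    cooks_threshold: float | None = None,
    random_condition_effects: bool = True,
) -> CellModelResult:
    """Cell-means linear mixed model of ROI response amplitudes.

    ``theta ~ 0 + ROI:Condition`` with participant random intercepts and
    (by default) uncorrelated random condition effects per participant,
    fitted by REML. The intercept is suppressed so each ROI x condition
    estimate is tested against zero. Rows flagged by Cook's distance on
    the fixed-effects regression (D > 4/N) are excluded before the mixed
    fit. If the requested random structure fails or is singular, the model
    is refitted with random intercepts only.
    """
    df = roi_estimates[roi_estimates["chromophore"] == chromophore].copy()
    if df.empty:
        raise ValueError(f"no rows for chromophore {chromophore!r}")
    if df["participant"].nunique() < 2:
        raise ValueError("need at least two participants")

    X, cells = _cell_design(df)
    y = df["theta"].to_numpy(float)
    retained, excluded, _ = cooks_exclude(y, X, cooks_threshold)
    df = df.iloc[retained].reset_index(drop=True)
    X, cells = _cell_design(df)
    y = df["theta"].to_numpy(float)
    groups = df["participant"].to_numpy()

    exog_names = [f"{r}:{c}" for r, c in cells]

    # formula API keeps the variance-component bookkeeping simple
    import statsmodels.formula.api as smf
    frame = df.copy()
    frame["y"] = y
    for k, name in enumerate(exog_names):
        frame[f"_cell_{k}"] = X[:, k]
    fixed = "y ~ 0 + " + " + ".join(f"_cell_{k}" for k in range(len(cells)))

    structure = "intercept+condition" if random_condition_effects \
        else "intercept"
    result = None
    while result is None:
        try:
            if structure == "intercept+condition":
                md = smf.mixedlm(fixed, frame, groups=frame["participant"],
                                 vc_formula={"condition": "0 + C(condition)"})
            else:
                md = smf.mixedlm(fixed, frame, groups=frame["participant"])
            with np.errstate(all="ignore"):
                import warnings
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    result = md.fit(reml=True)
            bad = (not np.all(np.isfinite(result.fe_params))
                   or not np.all(np.isfinite(np.diag(result.cov_params())
                                             [:len(cells)])))
            if bad:
                raise np.linalg.LinAlgError("non-finite mixed fit")
        except Exception:
            if structure == "intercept":
                raise
            log.warning("random condition effects dropped "
                        "(singular or failed fit); refitting with random "
                        "intercepts only")
            structure = "intercept"
            result = None

    fe = result.fe_params[:len(cells)]
    cov = np.asarray(result.cov_params())[:len(cells), :len(cells)]
    se = np.sqrt(np.diag(cov))
    z = fe / se
    p = 2 * sstats.norm.sf(np.abs(z))
    ci = 1.959963984540054 * se
    cells_df = pd.DataFrame({
        "roi": [r for r, _ in cells],
        "condition": [c for _, c in cells],
        "chromophore": chromophore,
        "estimate": np.asarray(fe),
        "se": se,
        "ci_lo": np.asarray(fe) - ci,
        "ci_hi": np.asarray(fe) + ci,
        "t": z,
        "p": p,
    })
    vc = {"participant_intercept": float(result.cov_re.iloc[0, 0])
          if result.cov_re.size else 0.0,
          "residual": float(result.scale)}
    if structure == "intercept+condition" and result.vcomp.size:
        vc["condition_effects"] = float(result.vcomp[0])
    return CellModelResult(cells=cells_df, cov=cov, excluded=excluded,
                           random_structure=structure,
                           variance_components=vc, model_result=result)


# ---------------------------------------------------------------------------
# contrasts

@dataclass(frozen=True)
class ContrastResult:
    name: str
    estimate: float
    se: float
    ci_lo: float
    ci_hi: float
    t: float
    p_raw: float
    p_fdr: float = float("nan")


def contrast(
    cell_result: CellModelResult,
    weights: dict[tuple[str, str], float],
    name: str = "",
) -> ContrastResult:
    """A linear combination of cell estimates.

    ``weights`` maps (roi, condition) to its weight; unmentioned cells get
    zero. Inference uses the normal approximation on the cell covariance.
    """
    cells = cell_result.cells
    w = np.zeros(len(cells))
    keys = list(zip(cells["roi"], cells["condition"]))
    for key, val in weights.items():
        if key not in keys:
            raise KeyError(f"cell {key} not in the model")
        w[keys.index(key)] = val
    est = float(w @ cells["estimate"].to_numpy())
    se = float(np.sqrt(w @ cell_result.cov @ w))
    z = est / se if se > 0 else 0.0
    p = 2 * sstats.norm.sf(abs(z))
    ci = 1.959963984540054 * se
    return ContrastResult(name=name, estimate=est, se=se,
                          ci_lo=est - ci, ci_hi=est + ci, t=z, p_raw=p)


def adjust_family(results: list[ContrastResult]) -> list[ContrastResult]:
    """BH-FDR adjust a family of contrasts; returns new results with
    ``p_fdr`` filled in."""
    p_adj = fdr_bh([r.p_raw for r in results])
    return [ContrastResult(r.name, r.estimate, r.se, r.ci_lo, r.ci_hi,
                           r.t, r.p_raw, float(q))
            for r, q in zip(results, p_adj)]


def speech_vs_control_weights(
    rois, speech_conditions, control: str = "control",
) -> dict[str, dict[tuple[str, str], float]]:
    """Per-ROI weights for the aggregated speech-minus-silence contrast."""
    out = {}
    k = len(speech_conditions)
    for roi in rois:
        w = {(roi, c): 1.0 / k for c in speech_conditions}
        w[(roi, control)] = -1.0
        out[roi] = w
    return out


def lateralization_weights(
    conditions, left: str = "LSTG", right: str = "RSTG",
) -> dict[tuple[str, str], float]:
    """Right-minus-left STG weights aggregated over ``conditions``."""
    k = len(conditions)
    w = {}
    for c in conditions:
        w[(right, c)] = 1.0 / k
        w[(left, c)] = -1.0 / k
    return w


# ---------------------------------------------------------------------------
# R-squared

def nakagawa_r2_components(
    var_fixed: float,
    var_random: float,
    var_resid: float,
) -> tuple[float, float]:
    """Marginal and conditional R-squared from variance components."""
    total = var_fixed + var_random + var_resid
    return var_fixed / total, (var_fixed + var_random) / total


def nakagawa_r2(result, logistic: bool = False) -> tuple[float, float]:
    """Nakagawa marginal/conditional R-squared of a fitted mixed model.

    ``result`` is a statsmodels ``MixedLMResults``. The fixed-effects
    variance is the population variance of the fixed linear predictor; the
    random variance sums all random-effect variance components; the
    residual variance is the model scale, or pi^2/3 on the latent logit
    scale for logistic models.
    """
    fe = np.asarray(result.fe_params)
    X = result.model.exog
    var_f = float(np.var(X @ fe))
    var_r = float(np.trace(np.atleast_2d(result.cov_re)))
    if getattr(result, "vcomp", None) is not None:
        var_r += float(np.sum(result.vcomp))
    var_e = float(np.pi ** 2 / 3) if logistic else float(result.scale)
    return nakagawa_r2_components(var_f, var_r, var_e)


# ---------------------------------------------------------------------------
# brain-behaviour

def brain_behavior_model(
    roi_estimates: pd.DataFrame,
    accuracy: pd.DataFrame,
    chromophore: str = "hbo",
) -> pd.DataFrame:
    """Response amplitude against recognition accuracy, per ROI.

    ``roi_estimates`` rows (participant, roi, condition, chromophore,
    theta) are merged with one accuracy value per participant and fitted
    with ``theta ~ 0 + ROI + ROI:accuracy`` fixed effects and participant
    random intercepts (REML). Returns one row per ROI: slope, se, t, p.
    """
    import statsmodels.formula.api as smf

    acc = accuracy[["participant", "accuracy"]]
    if acc["accuracy"].nunique() <= 1:
        raise ValueError("accuracy is constant across participants; "
                         "slopes are undefined")
    df = roi_estimates[roi_estimates["chromophore"] == chromophore].merge(
        acc, on="participant")
    if df.empty:
        raise ValueError("no matching rows after the accuracy merge")
    import warnings
    formula = "theta ~ 0 + C(roi) + C(roi):accuracy"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        md = smf.mixedlm(formula, df, groups=df["participant"])
        res = md.fit(reml=True)
        bse = np.asarray(res.bse[:len(res.fe_params)])
        scale = max(1.0, float(np.abs(res.fe_params).max()))
        if not np.all(np.isfinite(bse)) or bse.max() > 1e4 * scale:
            # degenerate mixed fit (tiny cohorts); fall back to OLS
            log.warning("brain_behavior_model: singular mixed fit; "
                        "refitting without random intercepts")
            res = smf.ols(formula, df).fit()
    rows = []
    params = getattr(res, "fe_params", None)
    if params is None:
        params = res.params
    for name, est in params.items():
        if ":accuracy" not in name:
            continue
        roi = name.split("[")[1].split("]")[0].replace("T.", "")
        se = float(res.bse[name])
        z = est / se
        rows.append({"roi": roi, "chromophore": chromophore,
                     "slope": float(est), "se": se, "t": float(z),
                     "p": float(2 * sstats.norm.sf(abs(z)))})
    return pd.DataFrame(rows).sort_values("roi").reset_index(drop=True)


def hbo_hbr_difference(theta_hbo: float, theta_hbr: float
                       ) -> tuple[float, str]:
    """Unsigned HbO-HbR difference magnitude and the pair's sign class.

    Pairs with opposite signs ("negatively correlated") are the pattern of
    a true haemodynamic response; same-sign pairs are classed positively
    correlated; a zero member makes the pair degenerate.
    """
    magnitude = abs(theta_hbo - theta_hbr)
    if theta_hbo == 0 or theta_hbr == 0:
        cls = "degenerate"
    elif np.sign(theta_hbo) != np.sign(theta_hbr):
        cls = "negatively-correlated"
    else:
        cls = "positively-correlated"
    return float(magnitude), cls


def hbo_hbr_difference_table(roi_estimates: pd.DataFrame) -> pd.DataFrame:
    """Pair HbO and HbR rows and compute the difference metric for each
    (participant, roi, condition) present in both chromophores."""
    keys = ["participant", "roi", "condition"] \
        if "participant" in roi_estimates.columns else ["roi", "condition"]
    hbo = roi_estimates[roi_estimates["chromophore"] == "hbo"]
    hbr = roi_estimates[roi_estimates["chromophore"] == "hbr"]
    merged = hbo.merge(hbr, on=keys, suffixes=("_hbo", "_hbr"),
                       how="inner")
    dropped = len(hbo) - len(merged)
    if dropped:
        log.info("hbo_hbr_difference: %d unpaired rows skipped", dropped)
    value_col = "theta" if "theta" in roi_estimates.columns else "estimate"
    rows = []
    for _, r in merged.iterrows():
        mag, cls = hbo_hbr_difference(r[f"{value_col}_hbo"],
                                      r[f"{value_col}_hbr"])
        rows.append({**{k: r[k] for k in keys},
                     "magnitude": mag, "pair_class": cls})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# group-level simulation scaffolding (for validation by recovery)

def simulate_roi_estimates(
    cell_means: dict[tuple[str, str], float],
    n_participants: int,
    chromophore: str = "hbo",
    participant_sd: float = 0.5,
    condition_sd: float = 0.3,
    resid_sd: float = 0.5,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw participant-level ROI estimates around known cell means.

    Participant intercepts, participant-by-condition effects and residual
    noise are independent Gaussians — the generative model matched by the
    second-level mixed model.
    """
    rng = np.random.default_rng(seed)
    conditions = sorted({c for _, c in cell_means})
    rows = []
    for p in range(n_participants):
        b0 = rng.normal(0, participant_sd)
        bc = {c: rng.normal(0, condition_sd) for c in conditions}
        for (roi, cond), mu in cell_means.items():
            rows.append({
                "participant": p, "roi": roi, "condition": cond,
                "chromophore": chromophore,
                "theta": mu + b0 + bc[cond] + rng.normal(0, resid_sd),
                "se": resid_sd,
            })
    return pd.DataFrame(rows)


def simulate_accuracy_coupling(
    rois,
    n_participants: int = 22,
    coupled_roi: str = "RSTG",
    slope: float = -6.0,
    base: float = 2.0,
    accuracy_mean: float = 0.6,
    accuracy_sd: float = 0.15,
    participant_sd: float = 1.0,
    resid_sd: float = 0.8,
    chromophore: str = "hbo",
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate ROI amplitudes whose coupling to recognition accuracy is
    confined to one ROI (negative slope there, zero elsewhere).

    Returns (roi_estimates, accuracy) frames suitable for
    :func:`brain_behavior_model`.
    """
    rng = np.random.default_rng(seed)
    acc = np.clip(rng.normal(accuracy_mean, accuracy_sd, n_participants),
                  0.05, 0.95)
    rows = []
    for p in range(n_participants):
        b0 = rng.normal(0, participant_sd)
        for roi in rois:
            mu = base + (slope * acc[p] if roi == coupled_roi else 0.0)
            rows.append({
                "participant": p, "roi": roi, "condition": "F0",
                "chromophore": chromophore,
                "theta": mu + b0 + rng.normal(0, resid_sd),
                "se": resid_sd,
            })
    est = pd.DataFrame(rows)
    accuracy = pd.DataFrame({"participant": np.arange(n_participants),
                             "accuracy": acc})
    return est, accuracy
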