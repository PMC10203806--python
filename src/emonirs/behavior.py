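"""Behavioural 4-AFC emotion recognition: simulation and analysis.

The choice model is a cue-weighting softmax. On each trial the presented
emotion's response alternative gains log-odds from every prosodic cue that
is still informative (F0 carries most weight, then intensity, then rate);
attenuating a cue removes its contribution. When F0 variation is
attenuated the "unemotional" alternative additionally gains a bias term —
listeners deprived of melodic variation tend to hear speech as
unemotional. Participant proficiency varies through a random intercept on
the correct-response log-odds.

Analysis mirrors the assessment pipeline: per-condition confusion
matrices, and logistic mixed models (GLMMs) of trial correctness with
sliding-difference or treatment contrast codings as fixed effects and
participant/sentence random intercepts.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .stats import ContrastCoding, nakagawa_r2_components

log = logging.getLogger(__name__)

EMOTIONS = ("angry", "happy", "sad", "unemotional")

CONDITION_ATTENUATES = {
    "natural": frozenset(),
    "intensity+rate": frozenset({"intensity", "rate"}),
    "F0": frozenset({"F0"}),
    "intensity+F0": frozenset({"intensity", "F0"}),
    "rate+F0": frozenset({"rate", "F0"}),
}


@dataclass(frozen=True)
class CueWeightModel:
    """Softmax cue-weighting model of 4-AFC responses.

    ``w_base`` is the log-odds advantage of the presented emotion with no
    informative cues at all; each informative cue adds its weight. When F0
    is attenuated, ``unemotional_bias`` is added to the "unemotional"
    alternative (unless it is the presented emotion, where the bias and
    correctness coincide). ``participant_sd`` scales a per-participant
    intercept on the correct alternative.
    """

    w_base: float = 0.4
    w_f0: float = 2.2
    w_intensity: float = 0.35
    w_rate: float = 0.25
    unemotional_bias: float = 1.2
    participant_sd: float = 0.5

    def correct_logit(self, condition: str, participant_effect: float = 0.0
                      ) -> float:
        attenuated = CONDITION_ATTENUATES[condition]
        w = self.w_base + participant_effect
        if "F0" not in attenuated:
            w += self.w_f0
        if "intensity" not in attenuated:
            w += self.w_intensity
        if "rate" not in attenuated:
            w += self.w_rate
        return w

    def response_probabilities(
        self, emotion: str, condition: str, participant_effect: float = 0.0,
    ) -> np.ndarray:
        """Probability over the four response alternatives."""
        attenuated = CONDITION_ATTENUATES[condition]
        logits = np.zeros(len(EMOTIONS))
        logits[EMOTIONS.index(emotion)] = self.correct_logit(
            condition, participant_effect)
        if "F0" in attenuated:
            logits[EMOTIONS.index("unemotional")] += self.unemotional_bias \
                if emotion != "unemotional" else 0.0
        ex = np.exp(logits - logits.max())
        return ex / ex.sum()


def simulate_behavior(
    trials: pd.DataFrame,
    model: CueWeightModel,
    n_participants: int,
    seed: int = 0,
    time_label: str = "single",
) -> pd.DataFrame:
    """Draw 4-AFC responses for every participant on a trial table.

    ``trials`` needs ``emotion`` and ``condition`` columns (a ``sentence``
    column is carried through when present). Returns one row per
    participant x trial with the multinomial response and correctness.
    """
    rng = np.random.default_rng(seed)
    intercepts = rng.normal(0, model.participant_sd, size=n_participants)
    rows = []
    for p in range(n_participants):
        for i, tr in trials.iterrows():
            probs = model.response_probabilities(
                tr["emotion"], tr["condition"], intercepts[p])
            resp = EMOTIONS[rng.choice(len(EMOTIONS), p=probs)]
            rows.append({
                "participant": p,
                "trial": i,
                "emotion": tr["emotion"],
                "condition": tr["condition"],
                "sentence": tr.get("sentence", 0),
                "response": resp,
                "correct": int(resp == tr["emotion"]),
                "time": time_label,
            })
    return pd.DataFrame(rows)


def afc_trial_table(
    emotions=EMOTIONS,
    conditions=tuple(CONDITION_ATTENUATES),
    sentences_per_cell: int = 5,
) -> pd.DataFrame:
    """The test-trial table of the 4-AFC assessment (one row per
    emotion x condition x sentence)."""
    rows = [{"emotion": e, "condition": c, "sentence": s}
            for e in emotions for c in conditions
            for s in range(sentences_per_cell)]
    return pd.DataFrame(rows)


def confusion_matrix(responses: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Per-condition confusion matrices (rows: presented emotion,
    columns: response; each row sums to 1)."""
    if responses.empty:
        raise ValueError("no responses")
    out = {}
    for cond, g in responses.groupby("condition", sort=False):
        mat = pd.crosstab(g["emotion"], g["response"], normalize="index")
        mat = mat.reindex(index=list(EMOTIONS), columns=list(EMOTIONS),
                          fill_value=0.0)
        out[str(cond)] = mat
    return out


# ---------------------------------------------------------------------------
# logistic mixed models

@dataclass
class GlmmResult:
    """Coefficient table and variance components of a correctness GLMM."""

    coefficients: pd.DataFrame       # term, estimate, se, z, p
    random_sd: dict[str, float]
    converged: bool
    r2_marginal: float
    r2_conditional: float
    backend: str


def _glm_fit(y: np.ndarray, X: pd.DataFrame) -> pd.DataFrame:
    import statsmodels.api as sm
    res = sm.GLM(y, X, family=sm.families.Binomial()).fit()
    return pd.DataFrame({
        "term": X.columns,
        "estimate": res.params.to_numpy(),
        "se": res.bse.to_numpy(),
        "z": (res.params / res.bse).to_numpy(),
        "p": res.pvalues.to_numpy(),
    })


def fit_accuracy_glmm(
    responses: pd.DataFrame,
    coding: ContrastCoding,
    random_spec: tuple[str, ...] = ("participant", "sentence"),
    min_random_sd: float = 0.01,
) -> GlmmResult:
    """Logistic mixed model of trial correctness.

    Fixed effects are an intercept plus the contrast-coded condition
    columns; random intercepts are included per grouping factor in
    ``random_spec``. Following the usual simplification policy, random
    terms whose fitted standard deviation falls below ``min_random_sd``
    are removed and the model refitted. With an empty ``random_spec`` the
    model reduces to an ordinary logistic GLM (exact cell-logit solution
    on saturated designs).

    The mixed fit uses the variational Bayes approximation of
    :class:`statsmodels` ``BinomialBayesMixedGLM``; coefficients are
    posterior means with posterior-sd-based normal inference.
    """
    df = responses.copy()
    X = pd.DataFrame(coding.encode(df["condition"]),
                     columns=coding.column_names, index=df.index)
    X.insert(0, "intercept", 1.0)
    y = df["correct"].to_numpy(float)

    if not random_spec:
        coefs = _glm_fit(y, X)
        var_f = float(np.var(X.to_numpy() @ coefs["estimate"].to_numpy()))
        r2m, r2c = nakagawa_r2_components(var_f, 0.0, np.pi ** 2 / 3)
        return GlmmResult(coefs, {}, True, r2m, r2c, "glm")

    from statsmodels.genmod.bayes_mixed_glm import BinomialBayesMixedGLM

    spec = list(random_spec)
    while True:
        vc_formulas = {g: f"0 + C({g})" for g in spec}
        model_df = df[["correct", "condition"] + spec].copy()
        for name in coding.column_names:
            model_df[name] = X[name].to_numpy()
        fixed = "correct ~ " + " + ".join(f"Q('{n}')"
                                          for n in coding.column_names)
        md = BinomialBayesMixedGLM.from_formula(fixed, vc_formulas, model_df)
        res = md.fit_vb()
        sds = dict(zip(spec, np.exp(res.vcp_mean)))
        weak = [g for g, sd in sds.items() if sd < min_random_sd]
        if not weak or len(spec) == len(weak) == 0:
            break
        if weak:
            log.info("dropping weak random terms (sd < %.2g): %s",
                     min_random_sd, weak)
            spec = [g for g in spec if g not in weak]
            if not spec:
                coefs = _glm_fit(y, X)
                var_f = float(np.var(
                    X.to_numpy() @ coefs["estimate"].to_numpy()))
                r2m, r2c = nakagawa_r2_components(var_f, 0.0,
                                                  np.pi ** 2 / 3)
                return GlmmResult(coefs, {}, True, r2m, r2c, "glm")
        else:
            break

    k_fe = len(coding.column_names) + 1
    fe_mean = np.asarray(res.fe_mean[:k_fe])
    fe_sd = np.asarray(res.fe_sd[:k_fe])
    names = ["intercept"] + list(coding.column_names)
    z = fe_mean / fe_sd
    coefs = pd.DataFrame({
        "term": names,
        "estimate": fe_mean,
        "se": fe_sd,
        "z": z,
        "p": 2 * sstats.norm.sf(np.abs(z)),
    })
    var_f = float(np.var(X.to_numpy() @ fe_mean))
    var_r = float(sum(sd ** 2 for sd in sds.values()))
    r2m, r2c = nakagawa_r2_components(var_f, var_r, np.pi ** 2 / 3)
    return GlmmResult(coefs, {g: float(s) for g, s in sds.items()},
                      True, r2m, r2c, "vb")


def accuracy_by_condition(responses: pd.DataFrame) -> pd.Series:
    """Proportion correct per condition."""
    return responses.groupby("condition")["correct"].mean()


def participant_accuracy(
    responses: pd.DataFrame,
    condition: str | None = None,
) -> pd.DataFrame:
    """One accuracy value per participant (optionally for one condition),
    as used by the brain-behaviour model."""
    df = responses
    if condition is not None:
        df = df[df["condition"] == condition]
    out = df.groupby("participant")["correct"].mean().rename("accuracy")
    return out.reset_index()
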