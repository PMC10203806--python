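"""End-to-end orchestration: stimuli -> schedules -> simulated recordings
-> first-level GLM -> group statistics -> brain-behaviour model.

Everything is driven by one :class:`~emonirs.config.RunConfig` and one
root seed; per-stage seeds are spawned from it, so two runs with the same
configuration produce identical outputs. The run writes CSV artefacts and
returns them in a report bundle, including a recovery report comparing
recovered ROI amplitudes with the simulated ground truth.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import behavior, design, glm, stats, stimuli, synth
from .config import RunConfig

log = logging.getLogger(__name__)


@dataclass
class RunReport:
    roi_estimates: pd.DataFrame
    recovery: pd.DataFrame
    cells: pd.DataFrame
    contrasts: pd.DataFrame
    behaviour: pd.DataFrame
    confusion: dict[str, pd.DataFrame]
    slopes: pd.DataFrame
    stimulus_metadata: pd.DataFrame | None
    parameter_log: list[str]


def _spawn_seeds(root: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(root)
    return [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(n)]


def run_end_to_end(cfg: RunConfig, out_dir: str | Path | None = None
                   ) -> RunReport:
    """Run the whole pipeline on one configuration."""
    cfg.validate()
    seeds = _spawn_seeds(cfg.seed, 6)
    seed_bank, seed_sched, seed_truth, seed_rec, seed_behav, seed_acc = seeds
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    # --- stimuli ----------------------------------------------------------
    stim_meta = None
    if cfg.run_stimuli:
        bank, bank_ref = stimuli.make_stimulus_bank(
            n_sentences_per_emotion=cfg.n_sentences_per_emotion,
            seed=seed_bank, targets=cfg.targets)
        rows = []
        for item in bank:
            prof = stimuli.measure_profile(item["signal"], 6, bank_ref)
            rows.append({
                "emotion": item["emotion"], "condition": item["condition"],
                "sentence": item["sentence"],
                "f0_mean_hz": prof.f0_mean_hz,
                "intensity_db": prof.intensity_db,
                "rate_syl_per_s": prof.rate_syl_per_s,
            })
        stim_meta = pd.DataFrame(rows)
        if out is not None:
            stim_meta.to_csv(out / "stimulus_metadata.csv", index=False)

    # --- behaviour (pre-session assessment) -------------------------------
    trials = behavior.afc_trial_table(
        conditions=("natural", "F0"), sentences_per_cell=5)
    cue_model = behavior.CueWeightModel()
    responses = behavior.simulate_behavior(
        trials, cue_model, cfg.n_participants, seed=seed_behav,
        time_label="pre")
    confusion = behavior.confusion_matrix(responses)
    acc = behavior.participant_accuracy(responses, condition="F0")

    # --- schedules and recordings -----------------------------------------
    montage = synth.make_montage()
    rng_truth = np.random.default_rng(seed_truth)
    sched_seeds = _spawn_seeds(seed_sched, cfg.n_participants)
    rec_seeds = _spawn_seeds(seed_rec, cfg.n_participants)

    # couple each participant's F0-condition amplitudes to their measured
    # recognition accuracy (lower accuracy -> larger response)
    acc_values = acc.set_index("participant")["accuracy"]
    coupling_slope = -6.0
    group_means = {}
    speech_conds = [c for c in cfg.schedule.conditions if c != "control"]
    for cond in speech_conds:
        for roi, amp in (("LSTG", 2.0), ("RSTG", 2.5),
                         ("LIFG", 0.5), ("RIFG", 0.5)):
            group_means[(cond, roi)] = amp

    all_roi = []
    all_truth = []
    for p in range(cfg.n_participants):
        sched = design.make_block_schedule(
            cfg.schedule.conditions, reps=cfg.schedule.reps,
            attention_reps=cfg.schedule.attention_reps,
            n_familiarization=cfg.schedule.n_familiarization,
            isi_range_s=cfg.schedule.isi_range_s,
            block_dur_s=cfg.schedule.block_dur_s,
            seed=sched_seeds[p])
        beta = {}
        acc_dev = float(acc_values.get(p, acc_values.mean())
                        - acc_values.mean())
        for (cond, roi), mu in group_means.items():
            b = mu + rng_truth.normal(0, 0.3)
            if cond.startswith("F0_") and roi == "RSTG":
                b += coupling_slope * acc_dev
            beta[(cond, roi)] = float(b)
        truth = synth.GroundTruth(beta_hbo=beta)
        rec = synth.simulate_session(montage, sched.to_frame(), truth,
                                     noise=cfg.noise, seed=rec_seeds[p])
        _, roi_est = glm.first_level(
            rec, ppf=cfg.analysis.ppf,
            analysis_rate_hz=cfg.analysis.analysis_rate_hz,
            boxcar_s=cfg.analysis.boxcar_s,
            drift_cutoff_hz=cfg.analysis.drift_cutoff_hz,
            use_short_regression=cfg.analysis.use_short_regression,
            weight=cfg.analysis.roi_weight)
        roi_est.insert(0, "participant", p)
        all_roi.append(roi_est)
        for (cond, roi), b in beta.items():
            for chrom in glm.CHROMOPHORES:
                all_truth.append({
                    "participant": p, "condition": cond, "roi": roi,
                    "chromophore": chrom,
                    "beta_true": truth.beta(cond, roi, chrom)})
    roi_estimates = pd.concat(all_roi, ignore_index=True)
    truth_df = pd.DataFrame(all_truth)

    recovery = roi_estimates.merge(
        truth_df, on=["participant", "condition", "roi", "chromophore"],
        how="inner")
    recovery["error"] = recovery["theta"] - recovery["beta_true"]
    rec_summary = (recovery.groupby(["condition", "roi", "chromophore"])
                   .agg(beta_true=("beta_true", "mean"),
                        theta=("theta", "mean"),
                        bias=("error", "mean"),
                        rmse=("error", lambda e: float(np.sqrt(
                            np.mean(np.square(e))))))
                   .reset_index())

    # --- group statistics --------------------------------------------------
    cells_frames = []
    contrast_rows = []
    cell_results = {}
    for chrom in glm.CHROMOPHORES:
        res = stats.fit_cellmeans_model(
            roi_estimates, chromophore=chrom,
            cooks_threshold=cfg.analysis.cooks_threshold)
        cell_results[chrom] = res
        cells_frames.append(res.cells)
        family = []
        for roi, w in stats.speech_vs_control_weights(
                synth.ROIS, speech_conds).items():
            family.append(stats.contrast(res, w,
                                         f"speech-vs-control {roi}"))
        family.append(stats.contrast(
            res, stats.lateralization_weights(speech_conds),
            "RSTG-vs-LSTG speech"))
        family = stats.adjust_family(family)
        for r in family:
            contrast_rows.append({
                "chromophore": chrom, "contrast": r.name,
                "estimate": r.estimate, "se": r.se,
                "ci_lo": r.ci_lo, "ci_hi": r.ci_hi,
                "t": r.t, "p": r.p_raw, "p_fdr": r.p_fdr})
    cells = pd.concat(cells_frames, ignore_index=True)
    contrasts = pd.DataFrame(contrast_rows)

    # --- brain-behaviour ---------------------------------------------------
    f0_conds = [c for c in speech_conds if c.startswith("F0_")]
    slopes_frames = []
    if f0_conds and acc["accuracy"].nunique() > 1:
        sub = roi_estimates[roi_estimates["condition"].isin(f0_conds)]
        for chrom in glm.CHROMOPHORES:
            slopes_frames.append(
                stats.brain_behavior_model(sub, acc, chromophore=chrom))
    slopes = pd.concat(slopes_frames, ignore_index=True) \
        if slopes_frames else pd.DataFrame()

    report = RunReport(
        roi_estimates=roi_estimates,
        recovery=rec_summary,
        cells=cells,
        contrasts=contrasts,
        behaviour=responses,
        confusion=confusion,
        slopes=slopes,
        stimulus_metadata=stim_meta,
        parameter_log=cfg.parameter_log(),
    )

    if out is not None:
        roi_estimates.to_csv(out / "roi_estimates.csv", index=False)
        rec_summary.to_csv(out / "recovery.csv", index=False)
        cells.to_csv(out / "cell_estimates.csv", index=False)
        contrasts.to_csv(out / "contrasts.csv", index=False)
        responses.to_csv(out / "behaviour.csv", index=False)
        if len(slopes):
            slopes.to_csv(out / "accuracy_slopes.csv", index=False)
        with open(out / "parameters.log", "w") as f:
            f.write("\n".join(report.parameter_log) + "\n")
        for cond, mat in confusion.items():
            mat.to_csv(out / f"confusion_{cond.replace('+', '_')}.csv")
    return report
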