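"""End-to-end pipeline driver.

Runs the stages in order on a synthetic cohort (or on amplitudes extracted
from simulated raw EEG for a subset of subjects): simulate -> (preprocess ->
extract) -> retention rules -> extended horseshoe fit -> reliability ->
final fixed-effects fit on retained subjects -> behavioral reduced-rank
regression -> descriptive report.  Every output file gets a JSON sidecar with
the config hash and seed; reruns with the same config are reproducible.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import erp, io, reliability as rel, stats
from .behavior import derive_outcomes, fit_reduced_rank
from .config import MCMCSettings, PipelineConfig, config_hash
from .model import HorseshoeSpec, build_design_matrix, diagnose_and_summarize, fit_mcmc
from .preprocessing import preprocess
from .synthetic import EEGSimParams, SimConfig, simulate_cohort, simulate_raw_eeg, simulate_trial_amplitudes

__all__ = ["run_pipeline"]


def run_pipeline(
    config: PipelineConfig,
    sim: SimConfig | None = None,
    truth=None,
    n_eeg_subjects: int = 0,
    eeg_params: EEGSimParams | None = None,
) -> dict:
    """Execute the full synthetic pipeline and write a run directory.

    With ``n_eeg_subjects > 0``, raw EEG is simulated for that many subjects
    and single-trial amplitudes are extracted from it; otherwise the
    model-simulated amplitudes are analyzed directly (fast path).  Returns a
    dict of key results and output paths; raises on stage failure after
    writing a machine-readable ``status.json``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config_hash(config)
    config.to_yaml(out / "config.yaml")
    status: dict = {"config_hash": chash, "seed": config.seed, "stages": []}

    def _fail(stage: str, exc: Exception) -> None:
        status["failed_stage"] = stage
        status["error"] = str(exc)
        (out / "status.json").write_text(json.dumps(status, indent=1))

    results: dict = {"out_dir": str(out), "config_hash": chash}
    try:
        stage = "simulate"
        sim = sim or SimConfig(seed=config.seed)
        trials, traits, default_truth = simulate_cohort(sim)
        truth = truth if truth is not None else default_truth
        io.write_table(trials, out / "trials.tsv")
        io.write_table(traits, out / "traits.tsv")
        io.write_ground_truth(truth, out / "ground_truth.json")
        io.write_sidecar(out / "trials.tsv", chash, config.seed)
        amps = simulate_trial_amplitudes(trials, traits, truth, seed=config.seed + 1)
        status["stages"].append(stage)

        if n_eeg_subjects > 0:
            stage = "extract"
            eeg_params = eeg_params or EEGSimParams()
            subjects = sorted(trials.subject.unique())[:n_eeg_subjects]
            trials = trials[trials.subject.isin(subjects)].reset_index(drop=True)
            traits = traits[traits.subject.isin(subjects)].reset_index(drop=True)
            amps = amps[amps.subject.isin(subjects)].reset_index(drop=True)
            recordings = {}
            for j in subjects:
                rec = simulate_raw_eeg(
                    trials[trials.subject == j], amps[amps.subject == j], eeg_params, seed=config.seed + 100 + j
                )
                rec, _ = preprocess(rec, config.filters, config.segments)
                recordings[j] = rec
            amps, window, rejections = erp.single_trial_amplitudes(recordings, trials, "CRN", config.epochs)
            results["component_window_ms"] = (window.start_ms, window.end_ms)
            (out / "rejections.json").write_text(json.dumps(rejections, indent=1))
            status["stages"].append(stage)

        stage = "criteria"
        amps, exclusions = erp.apply_trial_criteria(amps, trials, "CRN", config.epochs)
        (out / "exclusions.json").write_text(json.dumps(exclusions, indent=1, default=str))
        io.write_table(amps, out / "amplitude_table.csv")
        io.write_sidecar(out / "amplitude_table.csv", chash, config.seed)
        status["stages"].append(stage)

        stage = "fit"
        conditions = tuple(c for c in sim.conditions if c in set(amps.condition))
        design = build_design_matrix(amps, traits, conditions=conditions)
        spec = HorseshoeSpec.from_config(config.model)
        settings = MCMCSettings(
            chains=config.model.mcmc.chains,
            warmup=config.model.mcmc.warmup,
            samples=config.model.mcmc.samples,
            seed=config.seed,
        )
        fit_ext = fit_mcmc(design, spec=spec, settings=settings, extended=True)
        status["stages"].append(stage)

        stage = "reliability"
        report = rel.reliability_report(
            fit_ext, design, s_grid=config.reliability.s_grid, threshold=config.reliability.phi_threshold
        )
        (out / "reliability.json").write_text(json.dumps(report.to_json_dict(), indent=1, default=float))
        report.subject_table.to_csv(out / "reliability_subjects.csv", index=False)
        report.group_table.to_csv(out / "reliability_groups.csv", index=False)
        retained = report.meta["retained"]
        results["n_retained"] = len(retained)
        results["n_excluded_phi"] = len(report.meta["excluded"])
        if len(retained) < 3:
            raise RuntimeError(
                f"only {len(retained)} subjects pass the internal-consistency threshold "
                f"{config.reliability.phi_threshold}; too few for the fixed-effects model"
            )
        status["stages"].append(stage)

        stage = "final_fit"
        amps_final = amps[amps.subject.isin(retained)].reset_index(drop=True)
        design_final = build_design_matrix(amps_final, traits, conditions=conditions)
        fit_final = fit_mcmc(design_final, spec=spec, settings=settings, extended=False)
        summary = diagnose_and_summarize(fit_final)
        summary.to_csv(out / "posterior_summary.csv", index=False)
        io.write_sidecar(out / "posterior_summary.csv", chash, config.seed)
        coef = fit_final.coefficient_summary()
        coef.to_csv(out / "coefficients.csv", index=False)
        results["coefficients"] = coef
        results["diagnostics_ok"] = bool(summary.attrs["all_rhat_ok"] and summary.attrs["all_ess_ok"])
        status["stages"].append(stage)

        stage = "behavior"
        outcomes = derive_outcomes(trials, traits)
        io.write_table(outcomes, out / "behavioral_outcomes.csv")
        rrr = fit_reduced_rank(outcomes, traits, rank=1, seed=config.seed)
        rrr.summary().to_csv(out / "rrr_summary.csv", index=False)
        status["stages"].append(stage)

        stage = "report"
        _, rt_summary = stats.rt_crn_correlations(amps)
        rt_summary.to_csv(out / "rt_crn_correlations.csv", index=False)
        binned = stats.binned_behavior_summary(trials, reps=2000, seed=config.seed)
        binned.to_csv(out / "binned_behavior.csv", index=False)
        prom_items = traits[[c for c in traits.columns if c.startswith("prom_item_")]].to_numpy()
        prev_items = traits[[c for c in traits.columns if c.startswith("prev_item_")]].to_numpy()
        alpha_prom, ci_prom = stats.cronbach_alpha_bootstrap(prom_items, reps=2000, seed=config.seed)
        alpha_prev, ci_prev = stats.cronbach_alpha_bootstrap(prev_items, reps=2000, seed=config.seed + 1)
        report_json = {
            "alpha_promotion": {"alpha": alpha_prom, "ci": ci_prom},
            "alpha_prevention": {"alpha": alpha_prev, "ci": ci_prev},
            "rt_crn_correlations": rt_summary.to_dict(orient="records"),
        }
        (out / "report.json").write_text(json.dumps(report_json, indent=1, default=float))
        results["alpha_promotion"] = alpha_prom
        results["alpha_prevention"] = alpha_prev
        status["stages"].append(stage)
    except Exception as exc:
        _fail(stage, exc)
        raise

    status["ok"] = True
    (out / "status.json").write_text(json.dumps(status, indent=1))
    return results
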