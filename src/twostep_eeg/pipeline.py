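"""End-to-end synthetic study: agents -> model fits -> RPEs -> EEG ->
features -> group statistics.

Composes the package's pieces into the full analysis chain: simulate a
cohort of hybrid agents on the task, fit each subject's parameters by MAP
and derive trial-wise RPEs from the *fitted* (not generating) parameters,
generate synthetic feedback-locked EEG whose ground truth follows the
component model, quantify single-trial FRN/P3/theta/delta, and run the
cell-mean ANOVAs and RPE-coupling analyses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .agent import AgentParams, REFERENCE_PARAMS, simulate_agent
from .coupling import group_inference, rpe_regression
from .eeg_sim import EEGGenConfig, generate_epochs, perturb_config
from .features import (baseline_correct, cell_anova, reject_artifacts,
                       trial_features)
from .fitting import derive_rpes, fit_subject, to_constrained, \
    to_unconstrained
from .task import TaskConfig

COMPONENTS = ("frn", "p3", "theta", "delta")


@dataclass
class StudyResult:
    features: pd.DataFrame           # pooled single-trial features
    fitted_params: pd.DataFrame      # per-subject MAP estimates
    anovas: dict                     # component -> ANOVA table
    coupling: dict                   # component -> group_inference output


def run_synthetic_study(n_subjects: int = 29, n_blocks: int = 4,
                        seed: int = 0,
                        group_params: AgentParams = REFERENCE_PARAMS,
                        subject_param_sd: float = 0.2,
                        eeg_cfg: EEGGenConfig | None = None,
                        eeg_subject_sd: float = 0.3,
                        fit_params: bool = True) -> StudyResult:
    """Run one full synthetic study.

    Subject-level agent parameters scatter around ``group_params`` on the
    unconstrained scale (sd ``subject_param_sd``); EEG effect coefficients
    scatter per subject by ``eeg_subject_sd`` (relative).  With
    ``fit_params`` the RPEs entering the EEG analyses come from each
    subject's MAP fit, mirroring the model-informed analysis chain.
    """
    task_cfg = TaskConfig(n_blocks=n_blocks)
    base_eeg = eeg_cfg or EEGGenConfig()
    ss = np.random.SeedSequence(seed)
    subj_seeds = ss.generate_state(3 * n_subjects) % (2**31)
    rng = np.random.default_rng(ss.spawn(1)[0])

    x0 = to_unconstrained(group_params)
    all_feats = []
    fit_rows = []
    for s in range(n_subjects):
        params = to_constrained(
            x0 + rng.normal(0.0, subject_param_sd, size=5))
        trials, _ = simulate_agent(params, task_cfg,
                                   seed=int(subj_seeds[3 * s]), subject=s)
        if fit_params:
            fr = fit_subject(trials, method="map", n_restarts=3,
                             seed=int(subj_seeds[3 * s + 1]))
            use = fr.params
        else:
            use = params
        fit_rows.append({"subject": s, **use.to_dict()})
        recs = derive_rpes(use, trials)
        trials = trials.sort_values(["block", "trial"]).reset_index(
            drop=True)
        trials["rpe"] = [r.rpe for r in recs]
        trials["abs_rpe"] = [r.abs_rpe for r in recs]

        cfg_s = perturb_config(base_eeg, rng, sd=eeg_subject_sd)
        epochs, _ = generate_epochs(trials, cfg_s,
                                    seed=int(subj_seeds[3 * s + 2]))
        epochs = baseline_correct(reject_artifacts(epochs))
        all_feats.append(trial_features(epochs))

    features = pd.concat(all_feats, ignore_index=True)
    anovas = {c: cell_anova(features, col)
              for c, col in (("frn", "frn_p2p"), ("p3", "p3_mean"),
                             ("theta", "theta_db"), ("delta", "delta_db"))}
    coupling = {c: group_inference(rpe_regression(features, c))
                for c in COMPONENTS}
    return StudyResult(features=features,
                       fitted_params=pd.DataFrame(fit_rows),
                       anovas=anovas, coupling=coupling)


def dissociation_summary(result: StudyResult,
                         alpha: float = 0.05) -> dict:
    """Boolean summary of the target dissociation pattern.

    Fronto-central measures (FRN, theta) should couple to |RPE| and show
    expectancy effects independent of condition; centro-parietal measures
    (P3, delta) should show expectancy effects and RPE coupling only under
    the predictable internal model.
    """
    out = {}
    for c in COMPONENTS:
        an = result.anovas[c].set_index("effect")
        out[f"{c}_condition_x_expectancy_p"] = float(
            an.loc["condition x expectancy", "p"])
        t = result.coupling[c]["t_tests"].set_index("scope")
        av = result.coupling[c]["anova"].set_index("effect")
        out[f"{c}_slope_condition_p"] = float(av.loc["condition", "p"])
        out[f"{c}_slope_pred_p"] = float(
            t.loc["condition:predictable", "p"])
        out[f"{c}_slope_rand_p"] = float(t.loc["condition:random", "p"])
        out[f"{c}_slope_pred_mean"] = float(
            t.loc["condition:predictable", "mean_slope"])
    out["pattern"] = {
        "p3_expectancy_interaction": out["p3_condition_x_expectancy_p"]
        < alpha,
        "frn_no_expectancy_interaction":
            out["frn_condition_x_expectancy_p"] >= alpha,
        "p3_slope_condition_effect": out["p3_slope_condition_p"] < alpha,
        "p3_slope_predictable_only": (out["p3_slope_pred_p"] < alpha)
        and (out["p3_slope_rand_p"] >= alpha),
        "frn_slope_condition_blind": out["frn_slope_condition_p"] >= alpha,
        "theta_slope_condition_blind":
            out["theta_slope_condition_p"] >= alpha,
    }
    return out
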