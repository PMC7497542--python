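"""Single-trial coupling between model RPEs and EEG component amplitudes.

Because the sign of an RPE is confounded with feedback valence, separate
regressions are run for positive-RPE and negative-RPE trials using the
*absolute* RPE as predictor.  If a component tracks an unsigned RPE, the
regression slopes share the same sign in both partitions; a signed-RPE
component flips sign with valence.

Per subject x condition x RPE sign, the component amplitude is regressed
on |RPE| with both variables z-scored within the regression sample, so the
slope is a standardized regression weight (equal to the Pearson
correlation).  Group inference: one-sample t-tests of the mean slope
against zero, and a 2x2 within-subject ANOVA over RPE sign x condition.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .features import _rm_anova_sums

#: regression cells with fewer trials are dropped (flagged) per subject
MIN_TRIALS = 8

COMPONENT_COLUMNS = {"frn": "frn_p2p", "p3": "p3_mean",
                     "theta": "theta_db", "delta": "delta_db"}


def rpe_regression(features: pd.DataFrame, component: str,
                   min_trials: int = MIN_TRIALS) -> pd.DataFrame:
    """Standardized slope of component amplitude on |RPE| per subject x
    condition x RPE sign.

    ``features`` is a trial-feature table (see
    :func:`twostep_eeg.features.trial_features`) carrying ``rpe`` and the
    component column.  Cells below ``min_trials`` are omitted with a flag
    row (slope NaN).
    """
    col = COMPONENT_COLUMNS.get(component, component)
    if col not in features.columns:
        raise ValueError(f"unknown component column {col!r}")
    df = features.dropna(subset=[col, "rpe"])
    rows = []
    for (subj, cond), grp in df.groupby(["subject", "condition"],
                                        observed=True):
        for sign_label, m in (("positive", grp["rpe"] > 0),
                              ("negative", grp["rpe"] < 0)):
            cell = grp[m]
            n = len(cell)
            if n < min_trials:
                rows.append({"subject": subj, "component": component,
                             "condition": cond, "rpe_sign": sign_label,
                             "slope": np.nan, "n_trials": n,
                             "flag": "too_few_trials"})
                continue
            x = np.abs(cell["rpe"].to_numpy(float))
            y = cell[col].to_numpy(float)
            sx, sy = x.std(ddof=0), y.std(ddof=0)
            if sx == 0 or sy == 0:
                slope = 0.0
            else:
                slope = float(np.mean((x - x.mean()) * (y - y.mean()))
                              / (sx * sy))
            rows.append({"subject": subj, "component": component,
                         "condition": cond, "rpe_sign": sign_label,
                         "slope": slope, "n_trials": n, "flag": ""})
    return pd.DataFrame(rows)


def _one_sample_t(values: np.ndarray) -> tuple[float, float]:
    """t statistic and two-sided p; degenerate zero-variance samples give
    an infinite t (p = 0) unless the mean is also 0."""
    values = values[np.isfinite(values)]
    n = len(values)
    if n < 2:
        return np.nan, np.nan
    m = values.mean()
    sd = values.std(ddof=1)
    if sd <= 1e-12 * max(1.0, abs(m)):
        if m == 0:
            return 0.0, 1.0
        return float(np.inf * np.sign(m)), 0.0
    t = m / (sd / np.sqrt(n))
    return float(t), float(2 * stats.t.sf(abs(t), n - 1))


def group_inference(slopes: pd.DataFrame) -> dict:
    """Group-level tests of the RPE-coupling slopes for one component.

    Returns one-sample t-tests (overall, per condition and per cell) and
    the 2x2 within-subject ANOVA (rpe_sign x condition).  Subjects with
    incomplete cells are excluded from the ANOVA; zero-variance cells are
    flagged through the degenerate t/F conventions (infinite t, F = 0).
    """
    ok = slopes.dropna(subset=["slope"])
    if ok["subject"].nunique() < 3:
        raise ValueError("group inference requires >= 3 subjects")

    ttests = []
    overall = ok.groupby("subject")["slope"].mean().to_numpy()
    t, p = _one_sample_t(overall)
    ttests.append({"scope": "overall", "mean_slope": overall.mean(),
                   "t": t, "p": p, "n": len(overall)})
    for cond, grp in ok.groupby("condition", observed=True):
        vals = grp.groupby("subject")["slope"].mean().to_numpy()
        t, p = _one_sample_t(vals)
        ttests.append({"scope": f"condition:{cond}",
                       "mean_slope": vals.mean(), "t": t, "p": p,
                       "n": len(vals)})
    for (cond, sign), grp in ok.groupby(["condition", "rpe_sign"],
                                        observed=True):
        vals = grp["slope"].to_numpy()
        t, p = _one_sample_t(vals)
        ttests.append({"scope": f"{cond}/{sign}",
                       "mean_slope": vals.mean(), "t": t, "p": p,
                       "n": len(vals)})

    conds = sorted(ok["condition"].unique())
    signs = sorted(ok["rpe_sign"].unique())
    wide = ok.pivot_table(index="subject", columns=["rpe_sign", "condition"],
                          values="slope")
    order = [(s, c) for s in signs for c in conds]
    wide = wide.reindex(columns=pd.MultiIndex.from_tuples(order)).dropna()
    anova = None
    if len(wide) >= 2 and len(conds) == 2 and len(signs) == 2:
        res = _rm_anova_sums(wide.to_numpy(), (2, 2))
        names = {(0,): "rpe_sign", (1,): "condition",
                 (0, 1): "rpe_sign x condition"}
        anova = pd.DataFrame(
            [{"effect": names[r["effect"]], "F": r["F"],
              "df_num": r["df"], "df_den": r["df_err"], "p": r["p"]}
             for r in res])
    return {"t_tests": pd.DataFrame(ttests), "anova": anova,
            "n_anova_subjects": int(len(wide))}
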