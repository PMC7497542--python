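"""Stay/switch analysis, performance metrics and block-validity filtering.

Stay behavior links every trial to the *preceding trial of the same
condition* (not necessarily the preceding trial in the experiment, since
conditions are interleaved).  Predictors are coded exactly as in the
regression design: previous reward win/loss as +1/-1, previous transition
common/rare as +1/-1, stay as 1 and switch as 0.  The predictable
condition's model includes intercept, reward, transition and their
interaction; the random condition omits the transition terms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._mcmc import hierarchical_mcmc
from .task import TaskConfig, expected_random_payoff

PREDICTABLE_TERMS = ("intercept", "reward", "transition",
                     "reward_x_transition")
RANDOM_TERMS = ("intercept", "reward")


def build_stay_table(trials: pd.DataFrame) -> pd.DataFrame:
    """One row per trial that has a same-condition predecessor in the same
    block.

    Columns: subject, condition, stay (0/1), prev_reward (+1/-1),
    prev_transition (+1/-1, NaN in the random condition).
    """
    rows = []
    group_cols = ["subject", "block"] if "subject" in trials.columns \
        else ["block"]
    for _, blk in trials.groupby(group_cols, sort=True):
        blk = blk.sort_values("trial", kind="stable")
        for cond, sub in blk.groupby("condition", sort=False):
            sub = sub.reset_index(drop=True)
            for i in range(1, len(sub)):
                prev, cur = sub.iloc[i - 1], sub.iloc[i]
                rec = {
                    "subject": cur.get("subject", 0),
                    "condition": cond,
                    "stay": int(cur["action_idx"] == prev["action_idx"]),
                    "prev_reward": 1 if prev["valence"] == "win" else -1,
                    "prev_transition": np.nan,
                }
                if cond == "predictable":
                    rec["prev_transition"] = \
                        1 if prev["transition"] == "common" else -1
                rows.append(rec)
    return pd.DataFrame(rows)


def _design(records: pd.DataFrame, condition: str):
    sub = records[records["condition"] == condition]
    y = sub["stay"].to_numpy(float)
    r = sub["prev_reward"].to_numpy(float)
    if condition == "predictable":
        t = sub["prev_transition"].to_numpy(float)
        X = np.column_stack([np.ones_like(r), r, t, r * t])
        terms = PREDICTABLE_TERMS
    else:
        X = np.column_stack([np.ones_like(r), r])
        terms = RANDOM_TERMS
    return sub, X, y, terms


@dataclass
class StayRegressionResult:
    condition: str
    mode: str
    table: pd.DataFrame          # term, estimate, stat, p, flag
    per_subject: pd.DataFrame | None = None


def _logistic_nll(beta, X, y):
    z = X @ beta
    # -sum log sigmoid(z_i * (2y_i - 1)), numerically safe
    s = z * (2 * y - 1)
    return float(np.sum(np.logaddexp(0.0, -s)))


def fit_stay_regression(records: pd.DataFrame, condition: str,
                        mode: str = "per_subject", seed: int = 0,
                        chains: int = 4, iterations: int = 1500,
                        warmup: int = 750) -> StayRegressionResult:
    """Group-level logistic regression of stay behavior.

    ``per_subject``: maximum-likelihood logistic fit per subject, then a
    one-sample t-test on each coefficient across subjects (two-stage
    summary-statistics approach).  ``hierarchical``: random coefficients
    per subject with Gaussian group distributions, sampled by the package's
    MCMC machinery; the group-level test is the posterior z of the group
    mean.  Degenerate/separated subject fits are flagged, not fatal.
    """
    if mode not in ("per_subject", "hierarchical"):
        raise ValueError("mode must be 'per_subject' or 'hierarchical'")
    sub, X, y, terms = _design(records, condition)
    subjects = np.sort(sub["subject"].unique())

    if mode == "per_subject":
        import statsmodels.api as sm
        coefs, flags = [], []
        for s in subjects:
            m = sub["subject"].to_numpy() == s
            try:
                with np.errstate(all="ignore"):
                    fit = sm.Logit(y[m], X[m]).fit(disp=0, maxiter=200)
                b = fit.params
                flag = "" if np.all(np.abs(b) < 15) else "separation"
            except Exception:
                b = np.full(X.shape[1], np.nan)
                flag = "failed"
            coefs.append(b)
            flags.append(flag)
        coefs = np.asarray(coefs)
        per_subject = pd.DataFrame(coefs, columns=terms)
        per_subject.insert(0, "subject", subjects)
        per_subject["flag"] = flags
        ok = ~np.isnan(coefs).any(axis=1) & \
            (np.abs(coefs) < 15).all(axis=1)
        rows = []
        for j, term in enumerate(terms):
            vals = coefs[ok, j]
            t, p = stats.ttest_1samp(vals, 0.0)
            rows.append({"term": term, "estimate": vals.mean(),
                         "stat": float(t), "p": float(p),
                         "flag": "" if ok.all() else
                         f"{int((~ok).sum())} subjects dropped"})
        return StayRegressionResult(condition=condition, mode=mode,
                                    table=pd.DataFrame(rows),
                                    per_subject=per_subject)

    if mode == "hierarchical":
        nlls = []
        for s in subjects:
            m = sub["subject"].to_numpy() == s
            Xs, ys = X[m], y[m]
            nlls.append(lambda b, Xs=Xs, ys=ys: _logistic_nll(b, Xs, ys))
        draws = hierarchical_mcmc(nlls, dim=X.shape[1], chains=chains,
                                  iterations=iterations, warmup=warmup,
                                  seed=seed, prior_loc_sd=2.5,
                                  inner_sweeps=8)
        mu = draws.mu.reshape(-1, X.shape[1])
        rows = []
        for j, term in enumerate(terms):
            est = mu[:, j].mean()
            sd = mu[:, j].std(ddof=1)
            z = est / sd if sd > 0 else np.inf * np.sign(est)
            p = 2 * stats.norm.sf(abs(z))
            rows.append({"term": term, "estimate": float(est),
                         "stat": float(z), "p": float(p), "flag": ""})
        return StayRegressionResult(condition=condition, mode=mode,
                                    table=pd.DataFrame(rows))

    raise ValueError("mode must be 'per_subject' or 'hierarchical'")


def performance_metrics(trials: pd.DataFrame,
                        config: TaskConfig | None = None) -> dict:
    """Bonus per condition per block (EUR) and the predictable condition's
    subblock learning curve.

    The 50 predictable trials of each block are split into ten consecutive
    subblocks of 5 trials; 'correct' is choosing the first-stage action
    whose common transition leads to the high-reward picture.  Correctness
    is undefined for the random condition.
    """
    bonus = (trials.groupby(["condition", "block"])["payoff"].sum() / 100.0)
    pred = trials[trials["condition"] == "predictable"]
    n_sub = 10
    curves = []
    group_cols = ["subject", "block"] if "subject" in trials.columns \
        else ["block"]
    for _, blk in pred.groupby(group_cols, sort=True):
        blk = blk.sort_values("trial", kind="stable")
        correct = blk["correct"].to_numpy(float)
        k = len(correct) // n_sub
        if k == 0:
            continue
        curves.append([np.nanmean(correct[i * k:(i + 1) * k])
                       for i in range(n_sub)])
    curve = np.mean(curves, axis=0) if curves else np.full(n_sub, np.nan)
    return {
        "bonus_eur": bonus,
        "subblock_correct": np.asarray(curve),
        "chance_payoff_random_ct": expected_random_payoff(
            config or TaskConfig()),
    }


def filter_valid_blocks(trials: pd.DataFrame,
                        judgments: pd.DataFrame | dict) -> \
        tuple[pd.DataFrame, float]:
    """Drop all trials of blocks where the predictable set was misjudged.

    ``judgments`` maps (subject, block) -> bool (True = correctly
    identified); as a DataFrame it needs columns subject, block, correct.
    Returns (filtered table, excluded fraction).  A block present in the
    trial table but missing from the judgments is an error.
    """
    if isinstance(judgments, dict):
        lookup = dict(judgments)
    else:
        lookup = {(r.subject, r.block): bool(r.correct)
                  for r in judgments.itertuples()}
    subj = trials["subject"] if "subject" in trials.columns \
        else pd.Series(0, index=trials.index)
    keys = list(zip(subj, trials["block"]))
    missing = {k for k in keys if k not in lookup}
    if missing:
        raise ValueError(f"missing judgments for blocks {sorted(missing)[:5]}")
    keep = np.array([lookup[k] for k in keys])
    excluded = 1.0 - keep.mean()
    return trials[keep].reset_index(drop=True), float(excluded)
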