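"""Likelihood evaluation, parameter fitting, WAIC, and RPE derivation.

Choice data enter as trial tables produced by (or shaped like)
:func:`twostep_eeg.agent.simulate_agent`.  The likelihood replays the
deterministic state recursion over the observed choices and outcomes and
scores each first-stage choice under the softmax rule; the second stage
involves no choice and contributes no likelihood term.

Bounded parameters are optimized/sampled on an unconstrained scale:
logit for alpha, lambda and omega, log for beta, identity for rho.  MAP
estimation and MCMC place a weakly-informative Normal(0, 1.5) prior on each
transformed coordinate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, logit

from . import _core
from ._mcmc import HierarchicalDraws, hierarchical_mcmc, \
    sample_subject_posterior
from .agent import AgentParams, RPERecord

PARAM_NAMES = ("alpha", "lam", "beta", "omega", "rho")
PRIOR_SD = 1.5
_EPS = 1e-9


def to_unconstrained(params: AgentParams) -> np.ndarray:
    """Map (alpha, lam, beta, omega, rho) to R^5."""
    a = np.clip(params.alpha, _EPS, 1 - _EPS)
    l = np.clip(params.lam, _EPS, 1 - _EPS)
    w = np.clip(params.omega, _EPS, 1 - _EPS)
    b = max(params.beta, _EPS)
    return np.array([logit(a), logit(l), np.log(b), logit(w), params.rho])


def to_constrained(x: np.ndarray) -> AgentParams:
    """Inverse of :func:`to_unconstrained`."""
    return AgentParams(alpha=float(expit(x[0])), lam=float(expit(x[1])),
                       beta=float(np.exp(x[2])), omega=float(expit(x[3])),
                       rho=float(x[4]))


def constrain_draws(x: np.ndarray) -> np.ndarray:
    """Vectorized transform of draws (..., 5) to the natural scale."""
    out = np.empty_like(x, dtype=float)
    out[..., 0] = expit(x[..., 0])
    out[..., 1] = expit(x[..., 1])
    out[..., 2] = np.exp(x[..., 2])
    out[..., 3] = expit(x[..., 3])
    out[..., 4] = x[..., 4]
    return out


@dataclass
class PackedTrials:
    """Trial table flattened to the arrays the compiled replay consumes."""

    block_starts: np.ndarray
    set_seq: np.ndarray
    actions: np.ndarray
    pics: np.ndarray
    rewards: np.ndarray

    @property
    def n_trials(self) -> int:
        return int(self.set_seq.shape[0])


def pack_trials(trials: pd.DataFrame) -> PackedTrials:
    """Flatten a single subject's trial table (presentation order)."""
    required = {"block", "trial", "set_id", "action_idx", "stage2_idx",
                "reward"}
    missing = required - set(trials.columns)
    if missing:
        raise ValueError(f"trial table missing columns {sorted(missing)}")
    df = trials.sort_values(["block", "trial"], kind="stable")
    blocks = df["block"].to_numpy()
    starts = np.flatnonzero(np.r_[True, blocks[1:] != blocks[:-1]])
    return PackedTrials(
        block_starts=np.r_[starts, len(df)].astype(np.int64),
        set_seq=df["set_id"].to_numpy(np.int64),
        actions=df["action_idx"].to_numpy(np.int64),
        pics=df["stage2_idx"].to_numpy(np.int64),
        rewards=df["reward"].to_numpy(np.float64),
    )


def negative_log_likelihood(params: AgentParams,
                            trials: pd.DataFrame | PackedTrials) -> float:
    """Summed -log P(observed first-stage choice) over all trials."""
    p = trials if isinstance(trials, PackedTrials) else pack_trials(trials)
    return float(_core.nll_session(p.block_starts, p.set_seq, p.actions,
                                   p.pics, p.rewards, *params.as_tuple()))


def replay_choice_probabilities(params: AgentParams,
                                trials: pd.DataFrame | PackedTrials
                                ) -> np.ndarray:
    """Per-trial probability of the observed choice under ``params``."""
    p = trials if isinstance(trials, PackedTrials) else pack_trials(trials)
    probs, _ = _core.replay_session(p.block_starts, p.set_seq, p.actions,
                                    p.pics, p.rewards, *params.as_tuple())
    return probs


def pointwise_loglik(x_unconstrained: np.ndarray,
                     packed: PackedTrials) -> np.ndarray:
    """Per-trial log-likelihood at one unconstrained parameter vector."""
    p = to_constrained(x_unconstrained)
    return _core.loglik_pointwise(packed.block_starts, packed.set_seq,
                                  packed.actions, packed.pics,
                                  packed.rewards, *p.as_tuple())


def derive_rpes(params: AgentParams,
                trials: pd.DataFrame | PackedTrials) -> list[RPERecord]:
    """Deterministic replay emitting r(t) - Q_MF|S2(p_x, t) per trial.

    Feeding fitted parameters back through the same state recursion used
    for fitting yields the model's trial-wise RPE estimates.
    """
    p = trials if isinstance(trials, PackedTrials) else pack_trials(trials)
    _, rpe = _core.replay_session(p.block_starts, p.set_seq, p.actions,
                                  p.pics, p.rewards, *params.as_tuple())
    return [RPERecord(trial=i, rpe=float(r), abs_rpe=float(abs(r)))
            for i, r in enumerate(rpe)]


class FitError(RuntimeError):
    pass


@dataclass
class FitResult:
    params: AgentParams
    nll: float
    method: str
    diagnostics: dict | None = None


def _make_objective(packed: PackedTrials, penalized: bool,
                    fixed: dict | None):
    """Objective over the free unconstrained coordinates.

    ``fixed`` maps natural-scale parameter names to pinned values,
    shrinking the search space (used for reduced/ablated model variants).
    """
    fixed = fixed or {}
    free_idx = [i for i, n in enumerate(PARAM_NAMES) if n not in fixed]
    base = np.zeros(5)
    for name, val in fixed.items():
        i = PARAM_NAMES.index(name)
        kw = {n: (val if n == name else 0.5) for n in PARAM_NAMES}
        kw["beta"] = val if name == "beta" else 1.0
        kw["rho"] = val if name == "rho" else 0.0
        base[i] = to_unconstrained(AgentParams(**kw))[i]

    def unpack(z):
        x = base.copy()
        x[free_idx] = z
        return x

    def objective(z):
        x = unpack(z)
        p = to_constrained(x)
        val = _core.nll_session(packed.block_starts, packed.set_seq,
                                packed.actions, packed.pics, packed.rewards,
                                *p.as_tuple())
        if penalized:
            val += 0.5 * np.sum(z**2) / PRIOR_SD**2
        return val

    return objective, unpack, len(free_idx)


def fit_subject(trials: pd.DataFrame | PackedTrials, method: str = "map",
                n_restarts: int = 5, seed: int = 0,
                fixed: dict | None = None) -> FitResult:
    """Point estimate of the hybrid model for one subject.

    Best of ``n_restarts`` L-BFGS-B runs from random unconstrained starts;
    ``method='map'`` adds the Normal(0, 1.5) prior penalty, ``'mle'`` does
    not.  Deterministic under ``seed``.
    """
    if method not in ("map", "mle"):
        raise ValueError("method must be 'map' or 'mle'")
    packed = trials if isinstance(trials, PackedTrials) else \
        pack_trials(trials)
    objective, unpack, n_free = _make_objective(packed, method == "map",
                                                fixed)
    rng = np.random.default_rng(seed)
    best = None
    n_fail = 0
    for _ in range(n_restarts):
        z0 = rng.normal(0.0, 1.0, size=n_free)
        res = minimize(objective, z0, method="L-BFGS-B")
        if not res.success and not np.isfinite(res.fun):
            n_fail += 1
            continue
        if best is None or res.fun < best.fun:
            best = res
    if best is None:
        raise FitError(f"all {n_restarts} restarts failed to converge")
    params = to_constrained(unpack(best.x))
    nll = negative_log_likelihood(params, packed)
    return FitResult(params=params, nll=float(nll), method=method,
                     diagnostics={"n_failed_restarts": n_fail,
                                  "objective": float(best.fun)})


@dataclass
class Posterior:
    """Hierarchical posterior over subject-level and group-level parameters.

    ``draws`` holds unconstrained-scale samples (see
    :class:`twostep_eeg._mcmc.HierarchicalDraws`); subject/group point
    estimates are posterior means on the natural scale.
    """

    draws: HierarchicalDraws
    param_names: tuple = PARAM_NAMES
    rhat: dict | None = None
    ess: dict | None = None

    def subject_means(self) -> pd.DataFrame:
        nat = constrain_draws(self.draws.theta)  # (chains, draws, S, 5)
        means = nat.reshape(-1, *nat.shape[2:]).mean(axis=0)
        return pd.DataFrame(means, columns=self.param_names)

    def group_means(self) -> pd.Series:
        nat = constrain_draws(self.draws.mu)
        return pd.Series(nat.reshape(-1, 5).mean(axis=0),
                         index=self.param_names)

    def max_rhat(self) -> float:
        return max(float(np.nanmax(v)) for v in self.rhat.values())


def _compute_diagnostics(draws: HierarchicalDraws) -> tuple[dict, dict]:
    import arviz as az
    data = az.from_dict(posterior=draws.to_arviz_dict())
    rhat_ds = az.rhat(data)
    ess_ds = az.ess(data)
    rhat = {k: np.asarray(v) for k, v in rhat_ds.data_vars.items()}
    ess = {k: np.asarray(v) for k, v in ess_ds.data_vars.items()}
    return rhat, ess


def _laplace_init(packs, seed):
    """Per-subject MAP modes and inverse-Hessian covariances used to seed
    the chains and the MH proposal shapes."""
    init_theta = np.empty((len(packs), 5))
    init_cov = np.empty((len(packs), 5, 5))
    for s, pk in enumerate(packs):
        fr = fit_subject(pk, method="map", n_restarts=4, seed=seed + s)
        x0 = to_unconstrained(fr.params)
        init_theta[s] = x0
        objective, _, _ = _make_objective(pk, penalized=True, fixed=None)
        h = 1e-3
        hess = np.empty((5, 5))
        f0 = objective(x0)
        for i in range(5):
            for j in range(i, 5):
                ei = np.zeros(5); ei[i] = h
                ej = np.zeros(5); ej[j] = h
                val = (objective(x0 + ei + ej) - objective(x0 + ei)
                       - objective(x0 + ej) + f0) / h**2
                hess[i, j] = hess[j, i] = val
        # regularize to a valid covariance
        w, v = np.linalg.eigh(hess)
        w = np.clip(w, 0.1, None)
        init_cov[s] = v @ np.diag(1.0 / w) @ v.T
    return init_theta, init_cov


def fit_hierarchical(datasets, chains: int = 4, iterations: int = 2000,
                     warmup: int = 1000, seed: int = 0,
                     inner_sweeps: int = 36) -> Posterior:
    """Hierarchical Bayesian fit across subjects.

    ``datasets`` is a sequence of per-subject trial tables (or
    :class:`PackedTrials`).  Subject-level parameter vectors are drawn from
    per-coordinate Gaussian group distributions on the unconstrained scale;
    split-Rhat and effective sample size are reported per parameter, and
    point estimates are posterior means.  Chains are started overdispersed
    around per-subject MAP modes with Laplace proposal covariances.
    """
    packs = [t if isinstance(t, PackedTrials) else pack_trials(t)
             for t in datasets]
    if len(packs) < 2:
        raise ValueError("hierarchical fit requires >= 2 subjects")

    def make_nll(pk: PackedTrials):
        def nll(x):
            p = to_constrained(x)
            return _core.nll_session(pk.block_starts, pk.set_seq, pk.actions,
                                     pk.pics, pk.rewards, *p.as_tuple())
        return nll

    init_theta, init_cov = _laplace_init(packs, seed)
    draws = hierarchical_mcmc([make_nll(pk) for pk in packs], dim=5,
                              chains=chains, iterations=iterations,
                              warmup=warmup, seed=seed,
                              prior_loc_sd=PRIOR_SD,
                              inner_sweeps=inner_sweeps,
                              init_theta=init_theta, init_cov=init_cov)
    rhat, ess = _compute_diagnostics(draws)
    return Posterior(draws=draws, rhat=rhat, ess=ess)


def sample_subject(trials: pd.DataFrame | PackedTrials, draws: int = 1000,
                   warmup: int = 1000, seed: int = 0,
                   fixed: dict | None = None) -> np.ndarray:
    """Posterior draws (draws, 5 unconstrained) for one subject under the
    fixed Normal(0, 1.5) prior; pinned coordinates stay at their fixed
    values."""
    packed = trials if isinstance(trials, PackedTrials) else \
        pack_trials(trials)
    objective, unpack, n_free = _make_objective(packed, penalized=False,
                                                fixed=fixed)
    out = sample_subject_posterior(objective, n_free, draws=draws,
                                   warmup=warmup, seed=seed,
                                   prior_sd=PRIOR_SD)
    return np.stack([unpack(z) for z in out])


def loglik_draws(samples: np.ndarray,
                 trials: pd.DataFrame | PackedTrials) -> np.ndarray:
    """Pointwise log-likelihood matrix (draws, trials) for WAIC."""
    packed = trials if isinstance(trials, PackedTrials) else \
        pack_trials(trials)
    return np.stack([pointwise_loglik(x, packed) for x in samples])


def waic(loglik_draws: np.ndarray) -> tuple[float, float]:
    """WAIC on the deviance scale with the variance-based penalty (pWAIC2).

    WAIC = -2 * sum_i [ log mean_d exp(ll_di) - var_d(ll_di) ]; lower is
    better.  Returns (waic, standard error).
    """
    ll = np.asarray(loglik_draws, dtype=float)
    if ll.ndim != 2 or ll.shape[0] < 2:
        raise ValueError("need a (draws >= 2, trials) log-likelihood matrix")
    n_draws, n_trials = ll.shape
    from scipy.special import logsumexp
    lppd_i = logsumexp(ll, axis=0) - np.log(n_draws)
    p_i = ll.var(axis=0, ddof=1)
    elpd_i = lppd_i - p_i
    value = -2.0 * elpd_i.sum()
    se = 2.0 * np.sqrt(n_trials * elpd_i.var(ddof=1))
    return float(value), float(se)
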