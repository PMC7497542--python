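"""Generic hierarchical MCMC machinery (adaptive Metropolis-within-Gibbs).

Model: per-subject parameter vectors theta_s (on an unconstrained scale)
drawn from independent Gaussian group distributions per coordinate,
theta_s[j] ~ Normal(mu[j], sigma[j]).  Hyperpriors: mu[j] ~ Normal(0,
prior_loc_sd^2), sigma[j]^2 ~ InvGamma(sigma_a0, sigma_b0).  Subject-level
likelihoods enter through arbitrary callables nll(theta_s) -> float.

Sampling scheme per iteration:
  * `inner_sweeps` joint random-walk Metropolis proposals per subject,
    using a proposal covariance adapted during warmup (Haario-style
    empirical covariance, scaled 2.38^2/d, with a per-subject step-size
    adapted towards a 0.3 acceptance rate);
  * conjugate Gibbs draws of mu and sigma^2.

Adaptation stops at the end of warmup, so the kept draws come from a valid
(fixed-kernel) Markov chain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class HierarchicalDraws:
    """Posterior draws: theta (chains, draws, subjects, dim), mu and sigma
    (chains, draws, dim), plus mean subject-level acceptance rates."""

    theta: np.ndarray
    mu: np.ndarray
    sigma: np.ndarray
    accept_rate: np.ndarray

    def to_arviz_dict(self) -> dict:
        return {"theta": self.theta, "mu": self.mu, "sigma": self.sigma}


def _run_chain(nlls, dim, iterations, warmup, rng, prior_loc_sd,
               sigma_a0, sigma_b0, inner_sweeps, init_scale,
               init_theta=None, init_cov=None):
    n_subj = len(nlls)
    if init_theta is None:
        theta = rng.normal(0.0, init_scale, size=(n_subj, dim))
    else:
        # overdispersed starts around the supplied mode
        theta = init_theta + rng.normal(0.0, init_scale,
                                        size=(n_subj, dim))
    cur_nll = np.array([nlls[s](theta[s]) for s in range(n_subj)])
    mu = theta.mean(axis=0)
    sigma = np.ones(dim)

    # adaptation state
    step = np.full(n_subj, 0.3)
    run_mean = theta.copy()
    if init_cov is None:
        run_cov = np.tile(np.eye(dim) * 0.1, (n_subj, 1, 1))
    else:
        run_cov = init_cov.copy()
    scale = 2.38**2 / dim
    chol = np.linalg.cholesky(scale * run_cov + 1e-8 * np.eye(dim))
    n_adapt = 1

    kept = iterations - warmup
    out_theta = np.empty((kept, n_subj, dim))
    out_mu = np.empty((kept, dim))
    out_sigma = np.empty((kept, dim))
    n_acc = np.zeros(n_subj)
    n_prop = np.zeros(n_subj)

    for it in range(iterations):
        for _ in range(inner_sweeps):
            z = rng.standard_normal((n_subj, dim))
            log_u = np.log(rng.random(n_subj))
            for s in range(n_subj):
                prop = theta[s] + step[s] * (chol[s] @ z[s])
                prop_nll = nlls[s](prop)
                d_prior = 0.5 * np.sum(
                    ((theta[s] - mu) ** 2 - (prop - mu) ** 2) / sigma**2)
                log_alpha = (cur_nll[s] - prop_nll) + d_prior
                accept = log_u[s] < log_alpha
                if accept:
                    theta[s] = prop
                    cur_nll[s] = prop_nll
                if it < warmup:
                    # Robbins-Monro step-size adaptation towards 0.3
                    step[s] *= np.exp(
                        (1.0 if accept else 0.0) - 0.3) ** (5.0 / (n_adapt + 20))
                else:
                    n_acc[s] += accept
                    n_prop[s] += 1
        if it < warmup:
            n_adapt += 1
            w = 1.0 / (n_adapt + 1)
            delta = theta - run_mean
            run_mean += w * delta
            for s in range(n_subj):
                run_cov[s] = (1 - w) * run_cov[s] \
                    + w * np.outer(delta[s], delta[s])
            if it % 25 == 24 or it == warmup - 1:
                for s in range(n_subj):
                    chol[s] = np.linalg.cholesky(
                        scale * run_cov[s] + 1e-8 * np.eye(dim))

        # conjugate Gibbs updates of the group-level parameters
        prec = n_subj / sigma**2 + 1.0 / prior_loc_sd**2
        mean = (theta.sum(axis=0) / sigma**2) / prec
        mu = rng.normal(mean, 1.0 / np.sqrt(prec))
        a_post = sigma_a0 + 0.5 * n_subj
        b_post = sigma_b0 + 0.5 * np.sum((theta - mu) ** 2, axis=0)
        sigma = np.sqrt(b_post / rng.gamma(a_post, 1.0, size=dim))

        if it >= warmup:
            k = it - warmup
            out_theta[k] = theta
            out_mu[k] = mu
            out_sigma[k] = sigma

    acc = np.where(n_prop > 0, n_acc / np.maximum(n_prop, 1), np.nan)
    return out_theta, out_mu, out_sigma, acc


def hierarchical_mcmc(nlls, dim, chains=4, iterations=2000, warmup=1000,
                      seed=0, prior_loc_sd=1.5, sigma_a0=2.0, sigma_b0=0.5,
                      inner_sweeps=6, init_scale=0.5, init_theta=None,
                      init_cov=None) -> HierarchicalDraws:
    """Sample the hierarchical posterior; see module docstring.

    ``nlls`` is a sequence of per-subject negative log-likelihood callables
    over the unconstrained parameter vector.  ``init_theta`` (subjects, dim)
    and ``init_cov`` (subjects, dim, dim) optionally seed the chains and
    proposal covariances (e.g., from per-subject MAP/Laplace fits); chains
    start overdispersed around ``init_theta``.  Returns post-warmup draws
    for all chains.
    """
    if iterations <= warmup:
        raise ValueError("iterations must exceed warmup")
    if len(nlls) < 2:
        raise ValueError("hierarchical fit requires >= 2 subjects")
    rngs = [np.random.default_rng(c)
            for c in np.random.SeedSequence(seed).spawn(chains)]
    thetas, mus, sigmas, accs = [], [], [], []
    for rng in rngs:
        t, m, s, a = _run_chain(nlls, dim, iterations, warmup, rng,
                                prior_loc_sd, sigma_a0, sigma_b0,
                                inner_sweeps, init_scale,
                                init_theta=init_theta, init_cov=init_cov)
        thetas.append(t)
        mus.append(m)
        sigmas.append(s)
        accs.append(a)
    return HierarchicalDraws(theta=np.stack(thetas), mu=np.stack(mus),
                             sigma=np.stack(sigmas), accept_rate=np.stack(accs))


def sample_subject_posterior(nll, dim, draws=1000, warmup=1000, seed=0,
                             prior_sd=1.5, inner_sweeps=4,
                             init_scale=0.5) -> np.ndarray:
    """Single-subject adaptive random-walk Metropolis under a fixed
    Normal(0, prior_sd) prior on each unconstrained coordinate.

    Returns (draws, dim) post-warmup samples (one chain).  Used for
    pointwise log-likelihood draws in WAIC model comparisons.
    """
    rng = np.random.default_rng(seed)
    theta = rng.normal(0.0, init_scale, size=dim)
    cur = nll(theta) + 0.5 * np.sum(theta**2) / prior_sd**2

    step = 0.3
    run_mean = theta.copy()
    run_cov = np.eye(dim) * 0.1
    chol = np.linalg.cholesky(run_cov)
    scale = 2.38**2 / dim
    out = np.empty((draws, dim))
    n_adapt = 1
    total = warmup + draws
    for it in range(total):
        for _ in range(inner_sweeps):
            prop = theta + step * (chol @ rng.standard_normal(dim))
            val = nll(prop) + 0.5 * np.sum(prop**2) / prior_sd**2
            accept = np.log(rng.random()) < cur - val
            if accept:
                theta, cur = prop, val
            if it < warmup:
                step *= np.exp(
                    (1.0 if accept else 0.0) - 0.3) ** (5.0 / (n_adapt + 20))
        if it < warmup:
            n_adapt += 1
            w = 1.0 / (n_adapt + 1)
            delta = theta - run_mean
            run_mean += w * delta
            run_cov = (1 - w) * run_cov + w * np.outer(delta, delta)
            if it % 25 == 24 or it == warmup - 1:
                chol = np.linalg.cholesky(scale * run_cov
                                          + 1e-8 * np.eye(dim))
        else:
            out[it - warmup] = theta
    return out
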