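"""Thin wrapper around the emcee ensemble sampler.

All Bayesian fits in the package share this entry point: a vectorised
log-posterior over a flat parameter vector is sampled with several
independent affine-invariant/differential-evolution ensembles, burn-in is
discarded, and the retained ensembles are flattened to a fixed number of
draws.

Convergence is judged with split-R̂ computed across the independent
ensembles (walkers within one ensemble interact through the
differential-evolution proposals, so they are not valid chains for R̂;
separately seeded ensembles are). Effective sample size comes from the
integrated autocorrelation time of each ensemble.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

import emcee


@dataclass
class EnsembleResult:
    draws: np.ndarray  # (n_draws, ndim)
    rhat: np.ndarray  # (ndim,)
    ess: np.ndarray  # (ndim,)
    converged: bool


RHAT_THRESHOLD = 1.05


def run_ensemble(
    log_prob,
    init_center: np.ndarray,
    *,
    init_scale: np.ndarray | float = 1e-2,
    nwalkers: int | None = None,
    nsteps: int = 2000,
    burn: int | None = None,
    n_chains: int = 4,
    n_draws: int = 5000,
    seed: int = 0,
    vectorized: bool = True,
) -> EnsembleResult:
    """Sample ``log_prob`` and return ``n_draws`` flattened posterior draws.

    ``log_prob`` maps a (nwalkers, ndim) array to (nwalkers,) log densities
    when ``vectorized`` (the default); -inf marks out-of-support points.
    ``nsteps`` is the length of each of the ``n_chains`` ensembles; ``burn``
    defaults to half of it.
    """
    init_center = np.atleast_1d(np.asarray(init_center, dtype=float))
    ndim = init_center.size
    inner = log_prob

    def log_prob(theta, _inner=inner):  # NaN-safe: degenerate corners -> -inf
        with np.errstate(all="ignore"):
            lp = np.asarray(_inner(theta), dtype=float)
        return np.where(np.isnan(lp), -np.inf, lp)

    if nwalkers is None:
        nwalkers = max(2 * ndim + 2, 16)
    if burn is None:
        burn = nsteps // 2
    scale = np.broadcast_to(np.asarray(init_scale, dtype=float), (ndim,))
    # DE moves handle the correlated, partly funnel-shaped posteriors of the
    # hierarchical fits far better than stretch moves alone.
    moves = [(emcee.moves.DEMove(), 0.8), (emcee.moves.DESnookerMove(), 0.2)]

    chains = []
    for c in range(n_chains):
        rng = np.random.default_rng([seed, c])
        p0 = init_center + scale * rng.standard_normal((nwalkers, ndim))
        lp0 = log_prob(p0) if vectorized else np.array([log_prob(p) for p in p0])
        bad = ~np.isfinite(lp0)
        tries = 0
        while bad.any() and tries < 50:
            p0[bad] = init_center + 0.1 * scale * rng.standard_normal(
                (int(bad.sum()), ndim)
            )
            lp0 = log_prob(p0) if vectorized else np.array([log_prob(p) for p in p0])
            bad = ~np.isfinite(lp0)
            tries += 1
        if bad.any():
            raise RuntimeError("could not initialise all walkers at finite log density")
        sampler = emcee.EnsembleSampler(
            nwalkers, ndim, log_prob, vectorize=vectorized, moves=moves
        )
        # emcee expects a legacy RandomState *state tuple* here (it silently
        # ignores anything else, leaving the sampler entropy-seeded)
        sampler.random_state = np.random.RandomState(
            int(np.random.SeedSequence([seed, c]).generate_state(1)[0])
        ).get_state()
        sampler.run_mcmc(p0, nsteps, progress=False)
        kept = sampler.get_chain(discard=burn)  # (steps, walkers, ndim)
        chains.append(kept.reshape(-1, ndim))  # step-major flattening

    stacked = np.stack(chains)  # (n_chains, samples, ndim)
    rhat = _split_rhat(stacked)
    converged = bool(np.all(rhat < RHAT_THRESHOLD))

    flat = stacked.reshape(-1, ndim)
    if flat.shape[0] >= n_draws:
        idx = np.linspace(0, flat.shape[0] - 1, n_draws).round().astype(int)
        draws = flat[idx]
    else:  # pragma: no cover - only with very short runs
        draws = flat
    # summaries are computed from the retained draws, which keep mild
    # autocorrelation and ensemble-level disagreement after thinning; measure
    # their effective size on the retained sequence, split by source ensemble
    # so between-ensemble variance deflates it
    ess = _retained_ess(draws, n_chains)
    return EnsembleResult(draws=draws, rhat=rhat, ess=ess, converged=converged)


def _retained_ess(draws: np.ndarray, n_chains: int) -> np.ndarray:
    """Bulk ESS of the retained draws per dimension (via arviz).

    The retained sequence is chain-major, so reshaping to (n_chains, ·)
    recovers the source-ensemble structure; arviz's multi-chain ESS then
    accounts for both residual autocorrelation and ensemble disagreement.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        import arviz as az

        n, ndim = draws.shape
        per = n // n_chains
        shaped = draws[: per * n_chains].reshape(n_chains, per, ndim)
        out = np.empty(ndim)
        for j in range(ndim):
            out[j] = float(np.clip(az.ess(shaped[:, :, j]), 1.0, n))
    return out


def _split_rhat(stacked: np.ndarray) -> np.ndarray:
    """Split-R̂ per dimension, ensembles as chains (via arviz)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        import arviz as az

        ndim = stacked.shape[-1]
        return np.array(
            [float(az.rhat(stacked[:, :, j])) for j in range(ndim)]
        )


def mc_standard_error(draws: np.ndarray, ess: float) -> float:
    """Monte-Carlo standard error of the posterior mean given an ESS."""
    return float(np.std(draws, ddof=1) / np.sqrt(max(ess, 1.0)))
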