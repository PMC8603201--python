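"""Shared affine-invariant ensemble MCMC harness.

All Bayesian models in this package expose a vectorized log-posterior over
unconstrained parameters and are sampled with an emcee ensemble using a
mixture of differential-evolution and snooker moves, which mix far better
than the default stretch move on the correlated hierarchical posteriors
fitted here.
Multiple independent ensembles ("chains") with distinct seeds are run so
that rank-normalized R-hat across chains is meaningful. Draws within a
chain pool all walkers after burn-in; walker autocorrelation is accounted
for by reporting arviz effective sample sizes, which treat the pooled walker
draws conservatively.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    import arviz as az

import emcee

_MOD31 = 2**31 - 1


@dataclass
class SamplerSettings:
    """Ensemble-sampler configuration shared by every model fit.

    ``chains`` independent ensembles of ``walkers`` walkers each run for
    ``steps`` iterations; the first ``burn`` (default steps//2) are
    discarded and the rest pooled. ``seed`` drives walker initialization
    and all proposal randomness.
    """

    chains: int = 2
    walkers: int = 0       # 0 -> max(2*dim + 2, 32), rounded up to even
    steps: int = 800
    burn: int = 0          # 0 -> steps // 2
    seed: int = 0

    def resolved(self, dim: int) -> "SamplerSettings":
        w = self.walkers or max(2 * dim + 2, 32)
        if w % 2:
            w += 1
        b = self.burn or self.steps // 2
        if self.chains < 2:
            raise ValueError("at least 2 chains are required for diagnostics")
        if self.steps - b < 1:
            raise ValueError("no post-burn-in steps left")
        return SamplerSettings(self.chains, w, self.steps, b, self.seed)


def run_ensemble(log_prob, x0: np.ndarray, jitter: np.ndarray,
                 settings: SamplerSettings) -> np.ndarray:
    """Sample ``log_prob`` (vectorized over rows) around center ``x0``.

    Returns draws of shape (chains, (steps - burn) * walkers, dim).
    Walkers are initialized at ``x0 + jitter * normal`` and re-drawn (up to
    200 tries) until their log-probability is finite.
    """
    x0 = np.asarray(x0, dtype=float)
    dim = x0.size
    s = settings.resolved(dim)
    jitter = np.broadcast_to(np.asarray(jitter, dtype=float), (dim,))
    out = []
    for c in range(s.chains):
        cseed = (s.seed * 1000003 + 7919 * c + 1) % _MOD31
        rng = np.random.default_rng(cseed)
        p0 = x0[None, :] + jitter[None, :] * rng.standard_normal((s.walkers, dim))
        lp = np.asarray(log_prob(p0))
        for _ in range(200):
            bad = ~np.isfinite(lp)
            if not bad.any():
                break
            p0[bad] = x0[None, :] + jitter[None, :] * rng.standard_normal(
                (int(bad.sum()), dim))
            lp = np.asarray(log_prob(p0))
        else:
            raise RuntimeError("could not initialize walkers at finite log-probability")
        sampler = emcee.EnsembleSampler(
            s.walkers, dim, log_prob, vectorize=True,
            moves=[(emcee.moves.DEMove(), 0.8),
                   (emcee.moves.DESnookerMove(), 0.2)])
        sampler._random = np.random.RandomState(cseed)
        sampler.run_mcmc(p0, s.steps, progress=False, skip_initial_state_check=True)
        chain = sampler.get_chain(discard=s.burn)       # (kept, walkers, dim)
        out.append(chain.reshape(-1, dim))
    return np.stack(out)                                # (chains, draws, dim)


def rhat_ess(chains: np.ndarray):
    """Rank-normalized R-hat and bulk ESS per parameter.

    ``chains`` has shape (chains, draws, dim); returns two (dim,) arrays.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        data = az.from_dict(posterior={"x": chains})
        r = az.rhat(data)["x"].to_numpy()
        e = az.ess(data)["x"].to_numpy()
    return np.atleast_1d(r), np.atleast_1d(e)


def rhat_scalar(per_chain_draws: np.ndarray) -> float:
    """R-hat for a single derived quantity, shape (chains, draws)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(az.rhat(az.from_dict(posterior={"x": per_chain_draws}))["x"])


def ess_scalar(per_chain_draws: np.ndarray) -> float:
    """Bulk effective sample size for a single derived quantity."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(az.ess(az.from_dict(posterior={"x": per_chain_draws}))["x"])
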