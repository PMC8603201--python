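"""Hierarchical Bayesian model of gamma-H2A.X focus-count dynamics.

For one cell line, the observed focus count of nucleus ``i`` (area ``A_i``
unit areas of 0.1*Pixel^2, time ``t(i)``, replicate ``r(i)``) is modeled as

    k_i       ~ Binomial(A_i, p_{r(i), t(i)})
    p_{r,t}   ~ Beta(mean = p_t, variance = v_t)
    v_t       ~ chi-square(k_t), truncated to the unimodal-beta range
                (0, p_t(1-p_t) * m/(1+m)) with m = min(p_t, 1-p_t)
    p_t       ~ Uniform(0, 1)
    k_t       ~ chi-square(2)     (prior on the top-level positive scale)

i.e. a binomial count per nucleus, a beta across replicates, and a
replicate-overarching success probability per unit area ``p_t`` whose beta
variance is itself given a chi-square model with (continuous) degrees of
freedom ``k_t`` per time. Two aspects of the truncation matter. First, it
guarantees a valid beta everywhere in the parameter space. Second, the
upper bound keeps both beta shape parameters above 1 (a unimodal beta):
U-shaped replicate distributions would place replicate probabilities at the
boundaries of (0, 1), contradicting the unit-area construction chosen
precisely so that probabilities lie safely inside the interval, and they
make the joint density unbounded as a replicate probability approaches 0,
leaving the mean p_t unidentified for near-zero counts. Because the
admissible variance range is far below the chi-square scale, the truncated
density behaves as v^(k/2 - 1). ``k_t`` may optionally be shared across
times (``kt_shared=True``). A variant with an additional free scale,
``v_t = sigma2 * X_t / k_t``, ``sigma2 ~ chi-square(2)``
(``variance_model="scaled_chi2"``), is retained for comparison.

Two simpler competitors are provided for predictive comparison by
PSIS-LOO: a replicate-pooled beta-binomial (``model="betabinom"``) and a
fully pooled binomial (``model="pooled"``).

Sampling uses the shared ensemble-MCMC harness in unconstrained
coordinates (logit for probabilities and for the variance fraction
``w_t = v_t / (p_t(1-p_t))``, log for positive scales).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.special import betaln, expit, gammainc, gammaln, log_expit

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    import arviz as az

from ._mcmc import SamplerSettings, rhat_ess, run_ensemble
from .metabolic_glm import hdi

log = logging.getLogger(__name__)

_LN2 = math.log(2.0)


# -------------------------------------------------- marginal (beta-binomial)

def marginal_foci_logpmf(k, n, p, phi):
    """Replicate-integrated log-likelihood of one (area, count) pair.

    Integrating Binomial(k | n, q) over q ~ Beta(phi*p, phi*(1-p)) gives the
    beta-binomial pmf with alpha = phi*p, beta = phi*(1-p):

        C(n, k) * B(k + a, n - k + b) / B(a, b)
    """
    k = np.asarray(k, dtype=float)
    n = np.asarray(n, dtype=float)
    a = np.asarray(phi, dtype=float) * np.asarray(p, dtype=float)
    b = np.asarray(phi, dtype=float) * (1.0 - np.asarray(p, dtype=float))
    return (gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)
            + betaln(k + a, n - k + b) - betaln(a, b))


# ------------------------------------------------------------------ the fits

@dataclass
class FociModelPosterior:
    """Posterior draws and diagnostics for one cell line's foci model."""

    cell_line: str
    model: str
    times: np.ndarray
    replicates: np.ndarray
    p_t: np.ndarray                 # (draws, T)
    p_t_chains: np.ndarray          # (chains, draws_per_chain, T)
    log_lik: np.ndarray             # (thinned draws, n_obs)
    obs: pd.DataFrame               # records in model order
    p_rt: Optional[np.ndarray] = None      # (draws, R, T)
    v_t: Optional[np.ndarray] = None       # (draws, T)
    k_t: Optional[np.ndarray] = None       # (draws, T)
    sigma2: Optional[np.ndarray] = None    # (draws,)
    phi_t: Optional[np.ndarray] = None     # (draws, T), betabinom model
    rhat: Optional[np.ndarray] = None      # per p_t
    ess: Optional[np.ndarray] = None
    valid: bool = True

    @property
    def n_draws(self) -> int:
        return self.p_t.shape[0]


def _layout(records: pd.DataFrame):
    cells = records["cell_line"].unique()
    if len(cells) != 1:
        raise ValueError(f"fit one cell line at a time; got {sorted(cells)}")
    times = np.array(sorted(records["time_h"].unique()), dtype=float)
    reps = np.array(sorted(records["replicate"].unique()))
    if len(times) < 2:
        raise ValueError("need >= 2 time points")
    t_idx = records["time_h"].map({t: i for i, t in enumerate(times)}).to_numpy()
    r_idx = records["replicate"].map({r: i for i, r in enumerate(reps)}).to_numpy()
    A = records["area_units"].to_numpy(dtype=float)
    k = records["foci_count"].to_numpy(dtype=float)
    if np.any(k > A):
        raise ValueError("foci_count exceeds area_units")
    R, T = len(reps), len(times)
    K = np.zeros((R, T))
    M = np.zeros((R, T))
    np.add.at(K, (r_idx, t_idx), k)
    np.add.at(M, (r_idx, t_idx), A - k)
    return cells[0], times, reps, t_idx, r_idx, A, k, K, M


def _logit(p):
    return np.log(p) - np.log1p(-p)


def _chi2_logpdf(x, df):
    h = df / 2.0
    return (h - 1.0) * np.log(x) - x / 2.0 - gammaln(h) - h * _LN2


def _fit_hierarchical(records, settings, kt_shared, variance_model="chi2"):
    cell, times, reps, t_idx, r_idx, A, kk, K, M = _layout(records)
    R, T = len(reps), len(times)
    if R < 2:
        raise ValueError(
            "hierarchical replicate variance is unidentified with a single "
            "replicate; use model='betabinom' or model='pooled' instead")
    if variance_model not in ("chi2", "scaled_chi2"):
        raise ValueError(f"unknown variance_model {variance_model!r}")
    scaled = variance_model == "scaled_chi2"
    nk = 1 if kt_shared else T
    dim = T + R * T + T + nk + (1 if scaled else 0)

    def unpack(th):
        i = 0
        pt = expit(th[:, i:i + T]); th_pt = th[:, i:i + T]; i += T
        th_prt = th[:, i:i + R * T].reshape(-1, R, T); i += R * T
        th_w = th[:, i:i + T]; i += T
        kdf = np.exp(th[:, i:i + nk]); i += nk
        s2 = np.exp(th[:, i]) if scaled else None
        return pt, th_pt, th_prt, th_w, kdf, s2

    def log_prob(th):
        th = np.atleast_2d(th)
        with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
            return _log_prob_inner(th)

    def _log_prob_inner(th):
        pt, th_pt, th_prt, th_w, kdf, s2 = unpack(th)
        w = expit(th_w)
        kb = np.broadcast_to(kdf, (th.shape[0], T))
        # binomial level via per-(r,t) sufficient statistics
        lp = np.sum(K[None] * log_expit(th_prt) + M[None] * log_expit(-th_prt),
                    axis=(1, 2))
        # beta level: mean p_t, variance v = w * b; concentration
        # nu = (1 - v/c) / (v/c) with v/c = w * m/(1+m)
        m = np.minimum(pt, 1.0 - pt)
        wc = w * m / (1.0 + m)
        nu = (1.0 - wc) / wc
        alpha = pt * nu
        beta = (1.0 - pt) * nu
        lp += np.sum((alpha[:, None, :] - 1.0) * log_expit(th_prt)
                     + (beta[:, None, :] - 1.0) * log_expit(-th_prt), axis=(1, 2))
        lp -= R * np.sum(betaln(alpha, beta), axis=1)
        # truncated chi-square model for v_t = w_t * b_t, where b_t is the
        # largest variance keeping the replicate beta unimodal
        c = pt * (1.0 - pt)
        b = c * m / (1.0 + m)
        v = w * b
        if scaled:
            x = v * kb / s2[:, None]
            bound = b * kb / s2[:, None]
            extra = np.log(kb) - np.log(s2)[:, None]
        else:
            x = v
            bound = b
            extra = 0.0
        cdf = np.maximum(gammainc(kb / 2.0, bound / 2.0), 1e-300)
        lp += np.sum(_chi2_logpdf(x, kb) + extra - np.log(cdf) + np.log(b),
                     axis=1)
        # top-level chi-square(2) priors on positive scales; uniform on p_t
        lp += np.sum(-kdf / 2.0 - _LN2, axis=1)
        if scaled:
            lp += -s2 / 2.0 - _LN2
        # jacobians: logit for p_t, p_rt, w_t; log for k_t (and sigma2)
        lp += np.sum(log_expit(th_pt) + log_expit(-th_pt), axis=1)
        lp += np.sum(log_expit(th_prt) + log_expit(-th_prt), axis=(1, 2))
        lp += np.sum(log_expit(th_w) + log_expit(-th_w), axis=1)
        lp += np.sum(np.log(kdf), axis=1)
        if scaled:
            lp += np.log(s2)
        return np.where(np.isfinite(lp), lp, -np.inf)

    # initialization at empirical densities
    tot = K + M
    p_rt0 = np.clip(K / np.maximum(tot, 1.0), 1e-6, 1 - 1e-6)
    p_t0 = np.clip(K.sum(0) / np.maximum(tot.sum(0), 1.0), 1e-6, 1 - 1e-6)
    m0 = np.minimum(p_t0, 1 - p_t0)
    b0 = p_t0 * (1 - p_t0) * m0 / (1 + m0)
    w0 = np.clip(p_rt0.var(axis=0) / b0, 1e-4, 0.5)
    x0 = np.concatenate([
        _logit(p_t0), _logit(p_rt0).ravel(), _logit(w0),
        np.full(nk, math.log(2.0)),
    ] + ([[math.log(max(float(np.mean(w0 * b0)), 1e-6))]] if scaled else []))
    jitter = np.concatenate([
        np.full(T, 0.15), np.full(R * T, 0.15), np.full(T, 0.5),
        np.full(nk, 0.5),
    ] + ([[0.5]] if scaled else []))
    chains = run_ensemble(log_prob, x0, jitter, settings)

    nchain, ndr, _ = chains.shape
    flat = chains.reshape(-1, dim)
    pt, th_pt, th_prt, th_w, kdf, s2 = unpack(flat)
    prt = expit(th_prt)
    w = expit(th_w)
    mm = np.minimum(pt, 1 - pt)
    v = w * pt * (1 - pt) * mm / (1 + mm)
    p_t_chains = expit(chains[:, :, :T])
    rh, es = rhat_ess(p_t_chains)
    valid = bool(np.all(np.isfinite(rh)) and np.all(rh < 1.05))
    if not valid:
        log.warning("%s: R-hat for p_t = %s (threshold 1.05); flagged invalid",
                    cell, np.round(rh, 3))

    ll = _pointwise_loglik_prt(flat, prt, A, kk, r_idx, t_idx)
    obs = records.reset_index(drop=True)
    return FociModelPosterior(
        cell_line=cell, model="hierarchical", times=times, replicates=reps,
        p_t=pt, p_t_chains=p_t_chains, log_lik=ll, obs=obs, p_rt=prt,
        v_t=v, k_t=np.broadcast_to(kdf, (flat.shape[0], T)).copy(),
        sigma2=s2, rhat=rh, ess=es, valid=valid)


_N_LOGLIK_DRAWS = 2000


def _thin_idx(n, target=_N_LOGLIK_DRAWS):
    if n <= target:
        return np.arange(n)
    return np.linspace(0, n - 1, target).astype(int)


def _pointwise_loglik_prt(flat, prt, A, kk, r_idx, t_idx):
    idx = _thin_idx(flat.shape[0])
    const = gammaln(A + 1) - gammaln(kk + 1) - gammaln(A - kk + 1)
    p = prt[idx][:, r_idx, t_idx]                     # (S, N)
    return const[None, :] + kk[None, :] * np.log(p) + (A - kk)[None, :] * np.log1p(-p)


def _fit_pooled(records, settings):
    cell, times, reps, t_idx, r_idx, A, kk, K, M = _layout(records)
    T = len(times)
    Kt, Mt = K.sum(0), M.sum(0)

    def log_prob(th):
        th = np.atleast_2d(th)
        lp = np.sum(Kt[None] * log_expit(th) + Mt[None] * log_expit(-th), axis=1)
        lp += np.sum(log_expit(th) + log_expit(-th), axis=1)  # uniform + jacobian
        return lp

    p_t0 = np.clip(Kt / np.maximum(Kt + Mt, 1.0), 1e-6, 1 - 1e-6)
    chains = run_ensemble(log_prob, _logit(p_t0), np.full(T, 0.2), settings)
    flat = chains.reshape(-1, T)
    pt = expit(flat)
    p_t_chains = expit(chains)
    rh, es = rhat_ess(p_t_chains)
    idx = _thin_idx(flat.shape[0])
    const = gammaln(A + 1) - gammaln(kk + 1) - gammaln(A - kk + 1)
    p = pt[idx][:, t_idx]
    ll = const[None] + kk[None] * np.log(p) + (A - kk)[None] * np.log1p(-p)
    return FociModelPosterior(
        cell_line=cell, model="pooled", times=times, replicates=reps,
        p_t=pt, p_t_chains=p_t_chains, log_lik=ll,
        obs=records.reset_index(drop=True),
        rhat=rh, ess=es, valid=bool(np.all(rh < 1.05)))


def _fit_betabinom(records, settings):
    cell, times, reps, t_idx, r_idx, A, kk, K, M = _layout(records)
    T = len(times)
    by_time = [(np.flatnonzero(t_idx == j)) for j in range(T)]
    const = gammaln(A + 1) - gammaln(kk + 1) - gammaln(A - kk + 1)

    def log_prob(th):
        th = np.atleast_2d(th)
        with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
            return _log_prob_inner(th)

    def _log_prob_inner(th):
        W = th.shape[0]
        pt = expit(th[:, :T])
        phi = np.exp(th[:, T:])
        lp = np.zeros(W)
        a = phi * pt
        b = phi * (1 - pt)
        for j, rows in enumerate(by_time):
            aj = a[:, j:j + 1]
            bj = b[:, j:j + 1]
            lp += np.sum(const[None, rows]
                         + betaln(kk[None, rows] + aj, (A - kk)[None, rows] + bj)
                         - betaln(aj, bj), axis=1)
        # uniform(0,1) on p_t + logit jacobian; lognormal(log 100, 2) on phi
        lp += np.sum(log_expit(th[:, :T]) + log_expit(-th[:, :T]), axis=1)
        lp += np.sum(-0.5 * ((th[:, T:] - math.log(100.0)) / 2.0) ** 2, axis=1)
        return np.where(np.isfinite(lp), lp, -np.inf)

    p_t0 = np.clip(K.sum(0) / np.maximum((K + M).sum(0), 1.0), 1e-6, 1 - 1e-6)
    x0 = np.concatenate([_logit(p_t0), np.full(T, math.log(100.0))])
    chains = run_ensemble(log_prob, x0, np.full(2 * T, 0.3), settings)
    flat = chains.reshape(-1, 2 * T)
    pt = expit(flat[:, :T])
    phi = np.exp(flat[:, T:])
    p_t_chains = expit(chains[:, :, :T])
    rh, es = rhat_ess(p_t_chains)
    idx = _thin_idx(flat.shape[0])
    ll = marginal_foci_logpmf(kk[None, :], A[None, :],
                              pt[idx][:, t_idx], phi[idx][:, t_idx])
    return FociModelPosterior(
        cell_line=cell, model="betabinom", times=times, replicates=reps,
        p_t=pt, p_t_chains=p_t_chains, log_lik=ll,
        obs=records.reset_index(drop=True), phi_t=phi,
        rhat=rh, ess=es, valid=bool(np.all(rh < 1.05)))


def fit_foci_model(records: pd.DataFrame, settings: Optional[SamplerSettings] = None,
                   model: str = "hierarchical", kt_shared: bool = False,
                   variance_model: str = "chi2") -> FociModelPosterior:
    """Fit a foci-dynamics model to one cell line's records.

    ``records`` is a validated foci table restricted to one cell line with
    at least two time points (and, for the hierarchical model, at least two
    replicates). Returns posterior draws, per-time convergence diagnostics
    and the pointwise log-likelihood matrix needed for LOO.
    """
    settings = settings or SamplerSettings(steps=1500)
    if model == "hierarchical":
        return _fit_hierarchical(records, settings, kt_shared, variance_model)
    if model == "pooled":
        return _fit_pooled(records, settings)
    if model == "betabinom":
        return _fit_betabinom(records, settings)
    raise ValueError(f"unknown model {model!r}")


# ------------------------------------------------------------------ summaries

def expected_foci(post: FociModelPosterior, area_units: float) -> pd.DataFrame:
    """Expected focus count per nucleus of the given area, per time point.

    E[k | t] = area_units * p_t, summarized by the posterior median and 95%
    highest-density credible interval.
    """
    rows = []
    for j, t in enumerate(post.times):
        d = area_units * post.p_t[:, j]
        lo, hi = hdi(d, 0.95)
        rows.append({"time_h": float(t), "median": float(np.median(d)),
                     "cri95_lo": lo, "cri95_hi": hi})
    return pd.DataFrame(rows)


def ppc_foci(post: FociModelPosterior, records: Optional[pd.DataFrame] = None,
             n_rep: int = 200, seed: int = 0) -> pd.DataFrame:
    """Posterior predictive check for the foci model.

    Replicates count tables from the posterior (using replicate-level
    probabilities when present) and compares per-time mean counts, per-time
    variance/mean ratios and the maximum count against the observed data.
    Tail probability is Pr(T_rep >= T_obs).
    """
    obs = post.obs if records is None else records.reset_index(drop=True)
    A = obs["area_units"].to_numpy(dtype=float)
    kk = obs["foci_count"].to_numpy(dtype=float)
    t_idx = obs["time_h"].map(
        {t: i for i, t in enumerate(post.times)}).to_numpy()
    r_idx = obs["replicate"].map(
        {r: i for i, r in enumerate(post.replicates)}).to_numpy()
    rng = np.random.default_rng(seed)
    take = rng.choice(post.n_draws, size=min(n_rep, post.n_draws), replace=False)
    if post.p_rt is not None:
        p = post.p_rt[take][:, r_idx, t_idx]
    else:
        p = post.p_t[take][:, t_idx]
    k_rep = rng.binomial(A.astype(int)[None, :], p)

    rows = []

    def add(name, f):
        t_obs = float(f(kk[None, :])[0])
        t_rep = f(k_rep)
        rows.append({"statistic": name, "observed": t_obs,
                     "rep_mean": float(np.mean(t_rep)),
                     "tail_prob": float(np.mean(t_rep >= t_obs))})

    for j, t in enumerate(post.times):
        mask = t_idx == j
        add(f"mean_count[t={t}]", lambda v, m=mask: v[:, m].mean(axis=1))
        mu = kk[mask].mean()
        if mu > 0:
            add(f"var_mean_ratio[t={t}]",
                lambda v, m=mask: v[:, m].var(axis=1, ddof=1)
                / np.maximum(v[:, m].mean(axis=1), 1e-12))
    add("max_count", lambda v: v.max(axis=1))
    return pd.DataFrame(rows)


# ------------------------------------------------------------------------ LOO

def importance_ratios(log_lik: np.ndarray) -> np.ndarray:
    """Raw (unsmoothed) leave-one-out importance ratios.

    For observation i and posterior draw s the ratio is 1 / p(y_i | theta_s),
    normalized over draws. Input (draws, n_obs); output (n_obs, draws).
    """
    lw = -np.asarray(log_lik, dtype=float).T
    lw = lw - lw.max(axis=1, keepdims=True)
    w = np.exp(lw)
    return w / w.sum(axis=1, keepdims=True)


@dataclass
class LooComparison:
    model_a: str
    model_b: str
    elpd_a: float
    elpd_b: float
    elpd_diff: float            # a - b
    se_diff: float
    preferred: Optional[str]
    pareto_k_max: float
    frac_high_k: float
    warn: bool = False
    loo_i_a: np.ndarray = field(default=None, repr=False)
    loo_i_b: np.ndarray = field(default=None, repr=False)


def _loo_pointwise(post: FociModelPosterior):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        S = post.log_lik.shape[0]
        idata = az.from_dict(
            posterior={"p_t": post.p_t[_thin_idx(post.n_draws, S)][None]},
            log_likelihood={"y": post.log_lik[None]})
        res = az.loo(idata, pointwise=True)
    return (float(res.elpd_loo), res.loo_i.to_numpy(),
            np.asarray(res.pareto_k))


def loo_compare(fit_a: FociModelPosterior, fit_b: FociModelPosterior) -> LooComparison:
    """Compare two fits on the same records by PSIS-LOO expected log
    predictive density.

    A model is declared preferred only when |elpd difference| exceeds twice
    its standard error. More than 10% of Pareto-k diagnostics above 0.7
    sets the warning flag.
    """
    for col in ("area_units", "foci_count", "time_h", "replicate"):
        if not np.array_equal(fit_a.obs[col].to_numpy(), fit_b.obs[col].to_numpy()):
            raise ValueError("fits were not computed on identical records")
    elpd_a, li_a, k_a = _loo_pointwise(fit_a)
    elpd_b, li_b, k_b = _loo_pointwise(fit_b)
    diff_i = li_a - li_b
    n = diff_i.size
    elpd_diff = float(np.sum(diff_i))
    se = float(math.sqrt(n * np.var(diff_i, ddof=1))) if n > 1 else 0.0
    preferred = None
    if abs(elpd_diff) > 2.0 * se and elpd_diff != 0.0:
        preferred = fit_a.model if elpd_diff > 0 else fit_b.model
    ks = np.concatenate([k_a.ravel(), k_b.ravel()])
    frac = float(np.mean(ks > 0.7))
    cmp = LooComparison(
        model_a=fit_a.model, model_b=fit_b.model, elpd_a=elpd_a, elpd_b=elpd_b,
        elpd_diff=elpd_diff, se_diff=se, preferred=preferred,
        pareto_k_max=float(ks.max()), frac_high_k=frac, warn=frac > 0.10,
        loo_i_a=li_a, loo_i_b=li_b)
    if cmp.warn:
        log.warning("more than 10%% of Pareto-k diagnostics above 0.7 "
                    "(max %.2f): LOO estimates unreliable", cmp.pareto_k_max)
    return cmp


# ------------------------------------------------- simulation-based checking

def sample_variance_prior(rng, p_t, k_t):
    """Draw v_t from the truncated chi-square prior by inverse-CDF sampling.

    The support is the unimodal-beta variance range
    (0, p_t(1-p_t) * m/(1+m)), m = min(p_t, 1-p_t), matching the fit.
    """
    from scipy.stats import chi2

    m = min(p_t, 1.0 - p_t)
    b = p_t * (1.0 - p_t) * m / (1.0 + m)
    mass = chi2.cdf(b, k_t)
    u = rng.uniform(0.0, mass)
    v = float(chi2.ppf(u, k_t))
    return min(max(v, 1e-12 * b), b * (1 - 1e-12))


def sbc_ranks(n_iter: int, n_replicates: int = 2, nuclei: int = 15,
              n_times: int = 2, settings: Optional[SamplerSettings] = None,
              seed: int = 0, n_rank_draws: int = 63,
              area_median: float = 400.0) -> np.ndarray:
    """Simulation-based calibration ranks for p_t.

    Repeatedly draws hyperparameters and data from the model's own prior,
    refits, and records the rank of each true p_t among thinned posterior
    draws. Under a correctly implemented sampler the ranks are uniform on
    {0, ..., n_rank_draws}. Returns an (n_iter, n_times) integer array.
    """
    settings = settings or SamplerSettings(steps=400, walkers=32)
    times = np.linspace(0.5, 24.0, n_times)
    ranks = np.zeros((n_iter, n_times), dtype=int)
    for it in range(n_iter):
        rng = np.random.default_rng([seed, it])
        rows = []
        truth = np.zeros(n_times)
        for j, t in enumerate(times):
            p_t = rng.uniform(0.005, 0.6)   # away from hard boundaries
            k_t = max(rng.chisquare(2.0), 0.2)
            v = sample_variance_prior(rng, p_t, k_t)
            nu = p_t * (1 - p_t) / v - 1.0
            truth[j] = p_t
            for r in range(1, n_replicates + 1):
                p_rt = rng.beta(p_t * nu, (1 - p_t) * nu)
                areas = np.maximum(1, np.rint(np.exp(
                    math.log(area_median) + 0.35 * rng.standard_normal(nuclei)))
                    .astype(int))
                counts = rng.binomial(areas, p_rt)
                for i in range(nuclei):
                    rows.append(("sbc", r, t, f"n{i}", int(areas[i]), int(counts[i])))
        df = pd.DataFrame(rows, columns=[
            "cell_line", "replicate", "time_h", "nucleus_id", "area_units",
            "foci_count"])
        s = SamplerSettings(settings.chains, settings.walkers, settings.steps,
                            settings.burn, (seed * 7919 + it) % (2**31 - 1))
        post = fit_foci_model(df, s, model="hierarchical")
        take = np.linspace(0, post.n_draws - 1, n_rank_draws).astype(int)
        for j in range(n_times):
            ranks[it, j] = int(np.sum(post.p_t[take, j] < truth[j]))
    return ranks
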