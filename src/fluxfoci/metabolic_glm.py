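"""Multilevel Bayesian model of log-metabolic parameters.

The response (the log of a flux parameter such as basal respiration) is
modeled with normal distributions at all levels:

    y_i ~ Normal(mu + a_{c(i)} + d_{t(i)} + b_{g(i)}, sigma)
    a_c ~ Normal(0, tau_cell)         cell-line deflections
    d_t ~ Normal(0, tau_time)         time deflections (time-course variant)
    b_g ~ Normal(0, tau_rep)          replicate deflections, nested in cell line

with weakly informative priors: mu ~ Normal(mean(y), 10*sd(y)); each
group-level scale and the residual sigma ~ HalfNormal(prior_scale*sd(y)).
Deflections are reported relative to the grand mean via a sum-to-zero
adjustment applied at summary time, and summarized by the posterior median,
50%/95% highest density intervals (HDIs) and P-minus, the posterior
probability that a deflection is negative (i.e. that the cell line's log
value lies below the average over all cell lines).

If no cell line has two replicates the nested replicate level is
unidentified and the model degrades to cell-line-only deflections (logged).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd

from ._mcmc import SamplerSettings, ess_scalar, rhat_scalar, run_ensemble

log = logging.getLogger(__name__)

_LOG2PI = math.log(2.0 * math.pi)


# ------------------------------------------------------------- posterior sums

def hdi(draws, mass: float) -> Tuple[float, float]:
    """Highest density interval by sliding window on sorted draws.

    The narrowest contiguous window containing ceil(mass * n) sorted draws;
    ties are broken toward the lower start. Assumes a unimodal posterior.
    Requires at least 100 draws for a stable estimate. ``mass = 1`` is the
    degenerate full-support case spanning min..max.
    """
    if not 0.0 < mass <= 1.0:
        raise ValueError(f"mass must be in (0, 1], got {mass}")
    x = np.sort(np.asarray(draws, dtype=float).ravel())
    n = x.size
    if n < 100:
        raise ValueError(f"hdi needs >= 100 draws, got {n}")
    w = int(math.ceil(mass * n))
    widths = x[w - 1:] - x[: n - w + 1]
    i = int(np.argmin(widths))  # argmin returns the first minimum: lower start
    return float(x[i]), float(x[i + w - 1])


def p_minus(draws) -> float:
    """Posterior probability that a deflection is negative."""
    x = np.asarray(draws, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("p_minus needs at least one draw")
    return float(np.mean(x < 0.0))


@dataclass
class GLMSpec:
    """What to fit: response column, prior scale and sampler settings."""

    response: str = "value"
    prior_scale: float = 2.5
    sampler: SamplerSettings = field(default_factory=lambda: SamplerSettings(steps=800))


@dataclass
class EffectPosterior:
    """One deflection from the grand mean, with posterior summaries."""

    response: str
    level: str
    draws: np.ndarray
    median: float
    hdi50: Tuple[float, float]
    hdi95: Tuple[float, float]
    p_minus: float
    rhat: float
    ess: float
    valid: bool = True

    @property
    def mcse(self) -> float:
        """Monte Carlo standard error of the posterior mean."""
        return float(np.std(self.draws, ddof=1) / math.sqrt(max(self.ess, 1.0)))

    def to_row(self) -> dict:
        return {
            "response": self.response, "level": self.level, "median": self.median,
            "hdi50_lo": self.hdi50[0], "hdi50_hi": self.hdi50[1],
            "hdi95_lo": self.hdi95[0], "hdi95_hi": self.hdi95[1],
            "p_minus": self.p_minus, "rhat": self.rhat, "ess": self.ess,
            "mcse": self.mcse, "valid": self.valid,
        }


def _summarize(response: str, level: str, per_chain: np.ndarray,
               valid: bool) -> EffectPosterior:
    flat = per_chain.reshape(-1)
    r = rhat_scalar(per_chain)
    ess = ess_scalar(per_chain)
    return EffectPosterior(
        response=response, level=level, draws=flat,
        median=float(np.median(flat)), hdi50=hdi(flat, 0.50), hdi95=hdi(flat, 0.95),
        p_minus=p_minus(flat), rhat=r, ess=float(ess), valid=valid,
    )


# -------------------------------------------------------------------- the fit

class GLMFit:
    """Posterior of the multilevel model; iterable over its EffectPosteriors."""

    def __init__(self, spec, data, effects, chains, layout, warn):
        self.spec = spec
        self.data = data
        self.effects: List[EffectPosterior] = effects
        self.chains = chains          # (chains, draws, dim) unconstrained
        self.layout = layout          # dict of slices / index arrays
        self.warn = warn

    def __iter__(self):
        return iter(self.effects)

    def __len__(self):
        return len(self.effects)


def _prepare(df: pd.DataFrame, response: str, with_time: bool):
    y = df[response].to_numpy(dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError(f"non-finite values in response {response!r}")
    cells = sorted(df["cell_line"].unique())
    if len(cells) < 2:
        raise ValueError("need >= 2 cell lines")
    cell_idx = df["cell_line"].map({c: i for i, c in enumerate(cells)}).to_numpy()
    times: list = []
    time_idx = np.zeros(len(df), dtype=int)
    if with_time:
        times = sorted(df["time_h"].unique())
        time_idx = df["time_h"].map({t: i for i, t in enumerate(times)}).to_numpy()

    nested = df.groupby("cell_line")["replicate"].nunique().max() >= 2
    if not nested:
        log.warning("no cell line has >= 2 replicates: replicate variance is "
                    "unidentified; fitting cell-line-only deflections")
    if nested:
        pairs = sorted(set(zip(df["cell_line"], df["replicate"])))
        pair_map = {p: i for i, p in enumerate(pairs)}
        rep_idx = np.array([pair_map[p] for p in zip(df["cell_line"], df["replicate"])])
    else:
        pairs, rep_idx = [], np.zeros(len(df), dtype=int)

    # sufficient statistics per (cell, time, replicate-group) design cell
    key = (cell_idx.astype(np.int64) * (len(times) or 1) + time_idx) * (
        len(pairs) or 1) + rep_idx
    order = np.argsort(key, kind="stable")
    uniq, start = np.unique(key[order], return_index=True)
    g_n, g_sum, g_ssq, g_cell, g_time, g_rep = [], [], [], [], [], []
    for s, e in zip(start, list(start[1:]) + [len(key)]):
        rows = order[s:e]
        g_n.append(len(rows))
        g_sum.append(float(y[rows].sum()))
        g_ssq.append(float((y[rows] ** 2).sum()))
        g_cell.append(int(cell_idx[rows[0]]))
        g_time.append(int(time_idx[rows[0]]))
        g_rep.append(int(rep_idx[rows[0]]))
    layout = {
        "cells": cells, "times": times, "pairs": pairs, "nested": nested,
        "g_n": np.array(g_n, float), "g_sum": np.array(g_sum),
        "g_ssq": np.array(g_ssq), "g_cell": np.array(g_cell),
        "g_time": np.array(g_time), "g_rep": np.array(g_rep),
        "obs_cell": cell_idx, "obs_time": time_idx, "obs_rep": rep_idx,
        "y": y,
    }
    return layout


def _make_logprob(layout, prior_scale: float, with_time: bool):
    y = layout["y"]
    sd = max(float(np.std(y, ddof=1)) if y.size > 1 else 1.0, 1e-8)
    ybar = float(np.mean(y))
    C, T, G = len(layout["cells"]), len(layout["times"]), len(layout["pairs"])
    nested = layout["nested"]
    n_g = layout["g_n"]; s_g = layout["g_sum"]; ss_g = layout["g_ssq"]
    ic, it, ir = layout["g_cell"], layout["g_time"], layout["g_rep"]
    hn_scale = prior_scale * sd

    # parameter packing: mu | a(C) | d(T)? | b(G)? | log_tau_cell |
    #                    log_tau_time? | log_tau_rep? | log_sigma
    pos = {"mu": 0}
    k = 1
    pos["a"] = slice(k, k + C); k += C
    if with_time:
        pos["d"] = slice(k, k + T); k += T
    if nested:
        pos["b"] = slice(k, k + G); k += G
    pos["lt_cell"] = k; k += 1
    if with_time:
        pos["lt_time"] = k; k += 1
    if nested:
        pos["lt_rep"] = k; k += 1
    pos["ls"] = k; k += 1
    dim = k

    def log_prob(theta: np.ndarray) -> np.ndarray:
        theta = np.atleast_2d(theta)
        mu = theta[:, 0]
        a = theta[:, pos["a"]]
        tau_c = np.exp(theta[:, pos["lt_cell"]])
        sigma = np.exp(theta[:, pos["ls"]])
        m = mu[:, None] + a[:, ic]
        lp = np.zeros(theta.shape[0])
        # group-level normals + half-normal hyperpriors (with log-jacobians)
        lp += -0.5 * ((mu - ybar) / (10 * sd)) ** 2
        lp += (-C * np.log(tau_c) - 0.5 * np.sum(a**2, axis=1) / tau_c**2
               - 0.5 * (tau_c / hn_scale) ** 2 + np.log(tau_c))
        if with_time:
            d = theta[:, pos["d"]]
            tau_t = np.exp(theta[:, pos["lt_time"]])
            m = m + d[:, it]
            lp += (-T * np.log(tau_t) - 0.5 * np.sum(d**2, axis=1) / tau_t**2
                   - 0.5 * (tau_t / hn_scale) ** 2 + np.log(tau_t))
        if nested:
            b = theta[:, pos["b"]]
            tau_r = np.exp(theta[:, pos["lt_rep"]])
            m = m + b[:, ir]
            lp += (-G * np.log(tau_r) - 0.5 * np.sum(b**2, axis=1) / tau_r**2
                   - 0.5 * (tau_r / hn_scale) ** 2 + np.log(tau_r))
        lp += -0.5 * (sigma / hn_scale) ** 2 + np.log(sigma)
        # normal likelihood via per-group sufficient statistics
        quad = ss_g[None, :] - 2.0 * m * s_g[None, :] + n_g[None, :] * m**2
        lp += np.sum(-n_g[None, :] * (np.log(sigma)[:, None] + 0.5 * _LOG2PI)
                     - 0.5 * quad / sigma[:, None] ** 2, axis=1)
        return lp

    # data-informed initialization
    x0 = np.zeros(dim)
    x0[0] = ybar
    cell_means = np.array([
        s_g[ic == c].sum() / n_g[ic == c].sum() for c in range(C)])
    x0[pos["a"]] = cell_means - ybar
    if with_time:
        tmeans = np.array([s_g[it == t].sum() / n_g[it == t].sum() for t in range(T)])
        x0[pos["d"]] = tmeans - ybar
        x0[pos["lt_time"]] = math.log(max(np.std(tmeans - ybar), 0.1 * sd))
    if nested:
        gmeans = np.array([s_g[ir == g].sum() / n_g[ir == g].sum() for g in range(G)])
        x0[pos["b"]] = gmeans - cell_means[np.array(
            [ic[ir == g][0] for g in range(G)])] - (tmeans[np.array(
                [it[ir == g][0] for g in range(G)])] - ybar if with_time else 0.0)
        x0[pos["lt_rep"]] = math.log(0.3 * sd)
    x0[pos["lt_cell"]] = math.log(max(np.std(cell_means - ybar), 0.1 * sd))
    x0[pos["ls"]] = math.log(0.5 * sd)
    jitter = np.full(dim, 0.1 * sd)
    for name in ("lt_cell", "lt_time", "lt_rep", "ls"):
        if name in pos:
            jitter[pos[name]] = 0.3
    return log_prob, x0, jitter, pos, dim


def _fit(df: pd.DataFrame, spec: GLMSpec, with_time: bool) -> GLMFit:
    layout = _prepare(df, spec.response, with_time)
    log_prob, x0, jitter, pos, dim = _make_logprob(layout, spec.prior_scale, with_time)
    chains = run_ensemble(log_prob, x0, jitter, spec.sampler)
    n_chain_draws = chains.shape[1]
    if chains.shape[0] * n_chain_draws < 500:
        log.warning("fewer than 500 posterior draws; summaries will be noisy")

    a = chains[:, :, pos["a"]]                       # (chains, draws, C)
    dev_c = a - a.mean(axis=2, keepdims=True)        # sum-to-zero at summary
    effects: List[EffectPosterior] = []
    warn = False
    if with_time:
        d = chains[:, :, pos["d"]]
        dev_t = d - d.mean(axis=2, keepdims=True)
        for i, cell in enumerate(layout["cells"]):
            for j, t in enumerate(layout["times"]):
                eff = _summarize(spec.response, f"{cell}@{t}h",
                                 dev_c[:, :, i] + dev_t[:, :, j], True)
                effects.append(eff)
    else:
        for i, cell in enumerate(layout["cells"]):
            effects.append(_summarize(spec.response, cell, dev_c[:, :, i], True))
    for eff in effects:
        if not np.isfinite(eff.rhat) or eff.rhat > 1.05:
            eff.valid = False
            warn = True
    if warn:
        log.warning("R-hat > 1.05 for some deflections; summaries flagged invalid")
    layout["pos"] = pos
    return GLMFit(spec, df, effects, chains, layout, warn)


def fit_metabolic_glm(df: pd.DataFrame, spec: Optional[GLMSpec] = None) -> GLMFit:
    """Fit the cell-line/replicate multilevel model to log values.

    ``df`` needs columns ``cell_line``, ``replicate`` and the response
    column named by ``spec.response`` (already on the log scale).
    """
    return _fit(df, spec or GLMSpec(), with_time=False)


def fit_time_course_glm(df: pd.DataFrame, spec: Optional[GLMSpec] = None) -> GLMFit:
    """Time-course variant: additive time deflections, one effect per
    (cell line, time)."""
    return _fit(df, spec or GLMSpec(), with_time=True)


# ------------------------------------------------------------------------ PPC

def _obs_means(fit: GLMFit, theta: np.ndarray) -> np.ndarray:
    """Per-observation posterior means for a batch of draws (S, dim)."""
    lay, pos = fit.layout, fit.layout["pos"]
    m = theta[:, [0]] + theta[:, pos["a"]][:, lay["obs_cell"]]
    if "d" in pos:
        m = m + theta[:, pos["d"]][:, lay["obs_time"]]
    if "b" in pos:
        m = m + theta[:, pos["b"]][:, lay["obs_rep"]]
    return m


def posterior_predictive_check(fit: GLMFit, df: Optional[pd.DataFrame] = None,
                               n_rep: int = 200, seed: int = 0) -> pd.DataFrame:
    """Compare replicated datasets from the posterior with the observed data.

    Statistics: overall mean and sd, and per-cell-line means. The reported
    tail probability is Pr(T_rep >= T_obs); values near 0 or 1 indicate
    misfit for that statistic.
    """
    data = fit.data if df is None else df
    y = data[fit.spec.response].to_numpy(dtype=float)
    lay = fit.layout
    flat = fit.chains.reshape(-1, fit.chains.shape[-1])
    rng = np.random.default_rng(seed)
    take = rng.choice(flat.shape[0], size=min(n_rep, flat.shape[0]), replace=False)
    theta = flat[take]
    m = _obs_means(fit, theta)
    sigma = np.exp(theta[:, lay["pos"]["ls"]])
    y_rep = m + sigma[:, None] * rng.standard_normal(m.shape)

    stats = {"mean": lambda v: v.mean(axis=-1), "sd": lambda v: v.std(axis=-1, ddof=1)}
    for i, cell in enumerate(lay["cells"]):
        mask = lay["obs_cell"] == i
        stats[f"mean[{cell}]"] = lambda v, mask=mask: v[..., mask].mean(axis=-1)
    rows = []
    for name, f in stats.items():
        t_obs = float(f(y))
        t_rep = f(y_rep)
        rows.append({"statistic": name, "observed": t_obs,
                     "rep_mean": float(t_rep.mean()),
                     "tail_prob": float(np.mean(t_rep >= t_obs))})
    return pd.DataFrame(rows)
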