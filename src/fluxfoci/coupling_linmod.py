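"""Linear coupling of repair kinetics to metabolic recovery.

Foci probabilities per unit area are first interpolated from the repair
time grid (0, 0.5, 2, 6, 24 h) to the metabolic grid (0, 1, 6, 24 h): the
1 h value is linearly interpolated in time between 0.5 h and 2 h (weight
1/3 toward the 2 h value), the other grid points pass through. For each
cell line and metabolic parameter, a Bayesian simple linear regression of
foci probability (response) on the log-metabolic parameter (predictor) is
fitted on the four paired points, alongside the ordinary least-squares fit
used for plotting. Four points give weak inference by construction, so
slope signs are called by whether the 95% HDI excludes zero, not by point
estimates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from ._mcmc import SamplerSettings, rhat_scalar, run_ensemble
from .metabolic_glm import hdi, p_minus

REPAIR_TIMES = (0.0, 0.5, 2.0, 6.0, 24.0)
METAB_TIMES = (0.0, 1.0, 6.0, 24.0)


def interpolate_foci_to_metab_grid(q: Sequence[float],
                                   scale: str = "linear") -> np.ndarray:
    """Map the five-point repair vector onto the metabolic time grid.

    ``q`` holds p at t = (0, 0.5, 2, 6, 24) h; returns p at (0, 1, 6, 24) h.
    With ``scale="linear"`` the 1 h value is p(0.5) + (1-0.5)/(2-0.5) *
    (p(2) - p(0.5)); ``scale="log_time"`` interpolates linearly in log-time
    instead. All inputs must lie in the open interval (0, 1).
    """
    q = np.asarray(q, dtype=float)
    if q.shape != (5,):
        raise ValueError("expected the five-point repair vector")
    if np.any(q <= 0.0) or np.any(q >= 1.0):
        raise ValueError(f"foci probabilities must lie in (0, 1); got {q.tolist()}")
    p0, p05, p2, p6, p24 = q
    if scale == "linear":
        w = (1.0 - 0.5) / (2.0 - 0.5)
    elif scale == "log_time":
        w = (math.log(1.0) - math.log(0.5)) / (math.log(2.0) - math.log(0.5))
    else:
        raise ValueError(f"unknown interpolation scale {scale!r}")
    p1 = p05 + w * (p2 - p05)
    return np.array([p0, p1, p6, p24])


@dataclass
class CouplingFit:
    """Bayesian and least-squares linear relation for one (cell line,
    metabolic parameter) pair."""

    cell_line: str
    metabolic_parameter: str
    slope_draws: np.ndarray
    intercept_draws: np.ndarray
    slope_median: float
    slope_hdi95: Tuple[float, float]
    intercept_median: float
    intercept_hdi95: Tuple[float, float]
    ls_slope: float
    ls_intercept: float
    rhat_slope: float
    n_points: int = 4

    @property
    def pr_slope_negative(self) -> float:
        return p_minus(self.slope_draws)

    @property
    def sign(self) -> str:
        lo, hi = self.slope_hdi95
        if hi < 0:
            return "negative"
        if lo > 0:
            return "positive"
        return "indeterminate"


def least_squares_line(x: np.ndarray, y: np.ndarray) -> Tuple[float, float]:
    """Closed-form simple-regression solution (slope, intercept)."""
    X = np.column_stack([x, np.ones_like(x)])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return float(beta[0]), float(beta[1])


def fit_coupling(foci_p: Sequence[float], log_metab: Sequence[float],
                 settings: Optional[SamplerSettings] = None,
                 cell_line: str = "", metabolic_parameter: str = "",
                 prior_scale: float = 10.0) -> CouplingFit:
    """Bayesian linear regression of foci probability on a log-metabolic
    parameter at the four shared time points.

    Normal likelihood, weakly informative priors: slope ~ Normal(0,
    prior_scale * sd(y)/sd(x)), intercept ~ Normal(mean(y), prior_scale *
    sd(y)), log sigma ~ Normal(log(0.5 * sd(y)), 3). The ordinary
    least-squares slope/intercept are computed alongside.
    """
    y = np.asarray(foci_p, dtype=float)
    x = np.asarray(log_metab, dtype=float)
    if y.shape != x.shape or y.ndim != 1:
        raise ValueError("foci_p and log_metab must be equal-length vectors")
    if len(set(zip(x, y))) < 3:
        raise ValueError("need at least 3 distinct points")
    sx = float(np.std(x, ddof=1))
    if sx == 0.0:
        raise ValueError("slope unidentifiable: constant predictor")
    sy = max(float(np.std(y, ddof=1)), 1e-9)
    ls_slope, ls_intercept = least_squares_line(x, y)
    n = y.size

    s_slope = prior_scale * sy / sx
    s_int = prior_scale * sy
    ybar = float(np.mean(y))
    resid = y - (ls_intercept + ls_slope * x)
    s0 = max(float(np.sqrt(np.sum(resid**2) / max(n - 2, 1))), 1e-7 * sy)

    def log_prob(th):
        th = np.atleast_2d(th)
        slope, intercept, ls = th[:, 0], th[:, 1], th[:, 2]
        with np.errstate(divide="ignore", over="ignore"):
            sigma2 = np.exp(2.0 * ls)
            r = y[None, :] - intercept[:, None] - slope[:, None] * x[None, :]
            lp = -n * ls - 0.5 * np.sum(r**2, axis=1) / sigma2
        lp += -0.5 * (slope / s_slope) ** 2
        lp += -0.5 * ((intercept - ybar) / s_int) ** 2
        lp += -0.5 * ((ls - math.log(0.5 * sy)) / 3.0) ** 2
        return lp

    settings = settings or SamplerSettings(steps=2500, walkers=32)
    x0 = np.array([ls_slope, ls_intercept, math.log(s0)])
    jitter = np.array([0.1 * s_slope + 1e-12, 0.1 * s_int + 1e-12, 0.5])
    chains = run_ensemble(log_prob, x0, jitter, settings)
    slope_d = chains[:, :, 0].reshape(-1)
    inter_d = chains[:, :, 1].reshape(-1)
    return CouplingFit(
        cell_line=cell_line, metabolic_parameter=metabolic_parameter,
        slope_draws=slope_d, intercept_draws=inter_d,
        slope_median=float(np.median(slope_d)), slope_hdi95=hdi(slope_d, 0.95),
        intercept_median=float(np.median(inter_d)),
        intercept_hdi95=hdi(inter_d, 0.95),
        ls_slope=ls_slope, ls_intercept=ls_intercept,
        rhat_slope=rhat_scalar(chains[:, :, 0]), n_points=int(n))


def coupling_panel(fits: Mapping[Tuple[str, str], CouplingFit] | Sequence[CouplingFit]
                   ) -> pd.DataFrame:
    """Tabulate slopes across cell lines and metabolic parameters.

    One row per fit with the posterior summary, the least-squares values,
    and a sign flag (negative / positive / indeterminate) from whether the
    95% HDI of the slope excludes zero.
    """
    items = fits.values() if isinstance(fits, Mapping) else fits
    rows = []
    for f in items:
        rows.append({
            "cell_line": f.cell_line, "metabolic_parameter": f.metabolic_parameter,
            "slope_median": f.slope_median,
            "slope_hdi95_lo": f.slope_hdi95[0], "slope_hdi95_hi": f.slope_hdi95[1],
            "pr_slope_negative": f.pr_slope_negative,
            "intercept_median": f.intercept_median,
            "ls_slope": f.ls_slope, "ls_intercept": f.ls_intercept,
            "sign": f.sign, "rhat_slope": f.rhat_slope,
        })
    return pd.DataFrame(rows)
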