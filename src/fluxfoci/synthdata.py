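"""Seeded generators for foci tables and extracellular-flux plates.

The generators emulate the data structure of a radiation-response study:

* Foci tables: per-nucleus gamma-H2A.X focus counts at times 0 (unirradiated
  baseline), 0.5, 2, 6 and 24 h after irradiation, for several cell lines and
  N independent biological replicates. Counts follow the hierarchy the
  downstream model assumes: a replicate-level focus probability per unit area
  ``p_{r,t}`` is drawn from a beta distribution with mean ``p_t`` and
  concentration ``phi``; each nucleus draws an integer area ``A`` (in
  0.1*Pixel^2 unit areas) and a count ``k ~ Binomial(A, p_{r,t})``.
  Marginally across replicates the counts are beta-binomially overdispersed.

* Flux plates: per-well OCR/ECAR traces for the Mito Stress Test (basal ->
  oligomycin -> FCCP -> rotenone/antimycin A) and the Glycolysis Stress Test
  (baseline -> glucose -> oligomycin -> 2-deoxy-glucose), several measurement
  cycles per phase, with per-well nuclear-stain fluorescence (RFU) for
  cell-number normalization. Irradiation acts multiplicatively on the whole
  trace: a strong mitochondrial shutdown at 1 h with slow incomplete recovery
  by 24 h, and a milder glycolytic dip with fast recovery by 6 h.

Randomness is split into one independent stream per (cell line, replicate,
time) or per (condition, well) using numpy seed sequences, so enlarging one
part of a study never perturbs the draws of another.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Dict, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd

from .dataio import FOCI_COLUMNS, FLUX_COLUMNS, PHASES_BY_ASSAY

DEFAULT_TIMES: Tuple[float, ...] = (0.0, 0.5, 2.0, 6.0, 24.0)

#: default repair curves (probability of a focus per 0.1*Pixel^2 unit area):
#: low baseline damage, a strong peak 30 min after 3 Gy, then clearance.
DEFAULT_P_CURVES: Dict[str, Tuple[float, ...]] = {
    "fastrepair": (0.002, 0.030, 0.015, 0.005, 0.002),
    "slowrepair": (0.002, 0.030, 0.022, 0.012, 0.006),
}


class ConfigError(ValueError):
    """A simulation configuration violates its invariants."""


@dataclass
class FociSimConfig:
    """Configuration of the foci-table generator.

    ``p_curves`` maps each cell line to its true per-time focus probability
    per unit area ``p_t`` (one value per entry of ``times``). ``phi`` is the
    beta concentration across replicates: ``p_{r,t} ~ Beta(phi*p_t,
    phi*(1-p_t))``, so the replicate-level variance is
    ``p_t(1-p_t)/(phi+1) < p_t(1-p_t)``. ``phi = inf`` collapses the
    replicate level to a point mass at ``p_t``.

    Nuclear areas are drawn from a discretized log-normal (median
    ``area_median`` unit areas, log-sd ``area_log_sigma``), floored at 1.
    The area distribution of real nuclei is instrument- and cell-line-
    specific; these defaults are placeholders and fully configurable.
    """

    p_curves: Mapping[str, Sequence[float]] = field(
        default_factory=lambda: dict(DEFAULT_P_CURVES))
    times: Tuple[float, ...] = DEFAULT_TIMES
    n_replicates: int = 3
    nuclei_per_replicate: int = 80
    area_median: float = 400.0
    area_log_sigma: float = 0.35
    phi: float = 2000.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_replicates < 1:
            raise ConfigError("n_replicates must be >= 1")
        if self.nuclei_per_replicate < 1:
            raise ConfigError("nuclei_per_replicate must be >= 1")
        if not (self.phi > 0):
            raise ConfigError(f"dispersion phi must be > 0, got phi={self.phi}")
        if self.area_median < 1 or self.area_log_sigma < 0:
            raise ConfigError("invalid nuclear-area distribution parameters")
        for cl, curve in self.p_curves.items():
            if len(curve) != len(self.times):
                raise ConfigError(
                    f"cell line {cl!r}: p curve length {len(curve)} != "
                    f"{len(self.times)} time points")
            for p in curve:
                # p == 0 is allowed as an explicit degenerate boundary: the
                # beta draw is bypassed and p_{r,t} := 0.
                if not (0.0 <= p < 1.0):
                    raise ConfigError(
                        f"invalid beta mean/concentration combination "
                        f"(p_t={p}, phi={self.phi}) for cell line {cl!r}")


@dataclass
class FluxSimConfig:
    """Configuration of the flux-plate generator.

    ``baselines`` maps each cell line to ``(ocr, ecar)``: the basal-phase OCR
    level of the mito assay (pmol O2/min) and the glucose-free baseline ECAR
    of the glyco assay (mpH/min). Phase multipliers scale those levels per
    injection phase. ``mito_response`` / ``glyco_response`` give the
    multiplicative irradiation factor (shutdown fraction at 1 h, recovery
    fractions at 6 and 24 h) applied to OCR and ECAR respectively.
    Measurement noise is multiplicative log-normal with coefficient of
    variation ``cv``; RFU is log-normal per well. Wells are split across
    ``n_experiments`` independent experiments which receive a small
    multiplicative batch offset with coefficient of variation ``exp_cv``.
    """

    baselines: Mapping[str, Tuple[float, float]] = field(
        default_factory=lambda: {"fastrepair": (95.0, 11.0), "slowrepair": (70.0, 14.0)})
    mito_ocr_mult: Mapping[str, float] = field(
        default_factory=lambda: {"basal": 1.0, "oligo": 0.35, "fccp": 1.6, "rot_aa": 0.12})
    mito_ecar_mult: Mapping[str, float] = field(
        default_factory=lambda: {"basal": 3.0, "oligo": 3.8, "fccp": 3.6, "rot_aa": 3.2})
    glyco_ecar_mult: Mapping[str, float] = field(
        default_factory=lambda: {"baseline": 1.0, "glucose": 4.0, "oligo": 7.0, "2dg": 1.2})
    glyco_ocr_mult: Mapping[str, float] = field(
        default_factory=lambda: {"baseline": 0.8, "glucose": 0.8, "oligo": 0.3, "2dg": 0.3})
    mito_response: Mapping[float, float] = field(
        default_factory=lambda: {1.0: 0.40, 6.0: 0.70, 24.0: 0.85})
    glyco_response: Mapping[float, float] = field(
        default_factory=lambda: {1.0: 0.50, 6.0: 0.95, 24.0: 1.05})
    cv: float = 0.08
    wells_per_condition: int = 12
    n_experiments: int = 2
    exp_cv: float = 0.05
    rfu_mean: float = 5000.0
    rfu_cv: float = 0.10
    cycles_per_phase: int = 3
    seed: int = 0

    def validate(self) -> None:
        for cl, (ocr, ecar) in self.baselines.items():
            if ocr <= 0 or ecar <= 0:
                raise ConfigError(f"cell line {cl!r}: baselines must be > 0")
        for name, resp in (("mito", self.mito_response), ("glyco", self.glyco_response)):
            for t, f in resp.items():
                if not (0.0 < f <= 1.5):
                    raise ConfigError(
                        f"{name} response fraction at {t} h must be in (0, 1.5], got {f}")
        if self.cv < 0 or self.rfu_cv < 0 or self.exp_cv < 0:
            raise ConfigError("coefficients of variation must be >= 0")
        if self.cycles_per_phase < 1:
            raise ConfigError("cycles_per_phase must be >= 1")
        if self.wells_per_condition < 1 or self.n_experiments < 1:
            raise ConfigError("wells_per_condition and n_experiments must be >= 1")
        if self.rfu_mean <= 0:
            raise ConfigError("rfu_mean must be > 0")


def _lognormal_factor(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Multiplicative noise with unit mean and coefficient of variation cv."""
    if cv == 0:
        return np.ones(size)
    sigma = math.sqrt(math.log1p(cv * cv))
    return np.exp(rng.standard_normal(size) * sigma - 0.5 * sigma * sigma)


# ----------------------------------------------------------------- foci table

def simulate_foci_dataset(cfg: FociSimConfig) -> pd.DataFrame:
    """Generate a foci table with beta-binomial overdispersion across replicates.

    Returns a DataFrame with the dataio foci-table columns. Reproducible
    under a fixed ``cfg.seed``; each (cell line, replicate, time) triple has
    its own random stream.
    """
    cfg.validate()
    rows = []
    for ci, (cell, curve) in enumerate(sorted(cfg.p_curves.items())):
        for r in range(1, cfg.n_replicates + 1):
            for ti, t in enumerate(cfg.times):
                p_t = float(curve[ti])
                rng = np.random.default_rng([cfg.seed, ci, r, ti])
                if p_t == 0.0:
                    p_rt = 0.0
                elif math.isinf(cfg.phi):
                    p_rt = p_t
                else:
                    p_rt = rng.beta(cfg.phi * p_t, cfg.phi * (1.0 - p_t))
                n = cfg.nuclei_per_replicate
                areas = np.maximum(
                    1, np.rint(np.exp(
                        math.log(cfg.area_median)
                        + cfg.area_log_sigma * rng.standard_normal(n))).astype(int))
                counts = rng.binomial(areas, p_rt)
                for j in range(n):
                    rows.append((cell, r, t, f"{cell}_r{r}_t{ti}_n{j:03d}",
                                 int(areas[j]), int(counts[j])))
    return pd.DataFrame(rows, columns=FOCI_COLUMNS)


# ----------------------------------------------------------------- flux plate

_ASSAY_CODE = {"mito": 1, "glyco": 2}


def _response_factor(cfg: FluxSimConfig, arm: str, timepoint_h: float,
                     irradiated: bool) -> float:
    if not irradiated or timepoint_h == 0.0:
        return 1.0
    resp = cfg.mito_response if arm == "mito" else cfg.glyco_response
    if timepoint_h not in resp:
        raise ConfigError(
            f"no {arm} irradiation response configured at {timepoint_h} h "
            f"(have {sorted(resp)})")
    return float(resp[timepoint_h])


def simulate_flux_plate(cfg: FluxSimConfig, assay: str, timepoint_h: float,
                        irradiated: bool) -> pd.DataFrame:
    """Generate one plate: all cell lines x wells for one (assay, time, arm).

    Each well's trace is baseline x phase multiplier x irradiation factor x
    experiment batch factor x log-normal measurement noise; OCR and ECAR are
    generated in parallel with the mitochondrial and glycolytic response
    schedules respectively.
    """
    cfg.validate()
    if assay not in PHASES_BY_ASSAY:
        raise ConfigError(f"unknown assay {assay!r}; expected one of "
                          f"{sorted(PHASES_BY_ASSAY)}")
    phases = PHASES_BY_ASSAY[assay]
    ocr_mult = cfg.mito_ocr_mult if assay == "mito" else cfg.glyco_ocr_mult
    ecar_mult = cfg.mito_ecar_mult if assay == "mito" else cfg.glyco_ecar_mult
    f_ocr = _response_factor(cfg, "mito", timepoint_h, irradiated)
    f_ecar = _response_factor(cfg, "glyco", timepoint_h, irradiated)
    treatment = "IR" if irradiated else "control"
    tcode = int(round(timepoint_h * 10))
    acode = _ASSAY_CODE[assay]
    n_cycles = cfg.cycles_per_phase

    rows = []
    for ci, (cell, (ocr_base, ecar_base)) in enumerate(sorted(cfg.baselines.items())):
        for j in range(cfg.wells_per_condition):
            exp = 1 + (j * cfg.n_experiments) // cfg.wells_per_condition
            rng = np.random.default_rng(
                [cfg.seed, acode, tcode, int(irradiated), ci, j])
            batch_rng = np.random.default_rng([cfg.seed, 9090, ci, exp])
            batch = float(_lognormal_factor(batch_rng, cfg.exp_cv, ()))
            rfu = float(cfg.rfu_mean * _lognormal_factor(rng, cfg.rfu_cv, ()))
            well = f"{cell}_{assay}_{tcode}_{treatment}_e{exp}_w{j:02d}"
            for phase in phases:
                noise_o = _lognormal_factor(rng, cfg.cv, n_cycles)
                noise_e = _lognormal_factor(rng, cfg.cv, n_cycles)
                ocr = ocr_base * ocr_mult[phase] * f_ocr * batch * noise_o
                ecar = ecar_base * ecar_mult[phase] * f_ecar * batch * noise_e
                for c in range(n_cycles):
                    rows.append((well, cell, treatment, timepoint_h, assay,
                                 c + 1, phase, float(ocr[c]), float(ecar[c]), rfu))
    return pd.DataFrame(rows, columns=FLUX_COLUMNS)


def simulate_flux_study(cfg: FluxSimConfig, assay: str,
                        timepoints: Sequence[float] = (1.0, 6.0, 24.0)) -> pd.DataFrame:
    """Irradiated plates at each timepoint plus matched unirradiated controls."""
    plates = [simulate_flux_plate(cfg, assay, 0.0, irradiated=False)]
    for t in timepoints:
        plates.append(simulate_flux_plate(cfg, assay, t, irradiated=False))
        plates.append(simulate_flux_plate(cfg, assay, t, irradiated=True))
    return pd.concat(plates, ignore_index=True)


# -------------------------------------------------------------- coupled study

METAB_TIMES: Tuple[float, ...] = (0.0, 1.0, 6.0, 24.0)


@dataclass
class CoupledStudy:
    foci: pd.DataFrame
    flux: pd.DataFrame
    metadata: dict

    def write_metadata(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.metadata, fh, indent=2, sort_keys=True)


def simulate_coupled_study(foci_cfg: FociSimConfig, flux_cfg: FluxSimConfig,
                           coupling_slope: float, seed: int,
                           p_center: float = 0.015) -> CoupledStudy:
    """Jointly generate foci and flux data with a known linear coupling.

    A shared latent recovery trajectory (the irradiation response schedule of
    basal mitochondrial respiration) drives both arms: at the metabolic time
    grid t = (0, 1, 6, 24) h the true focus probability per unit area is
    ``p(t) = a + coupling_slope * log(basal_t / RFU)`` with the intercept
    ``a`` chosen so the probabilities center at ``p_center``. The 0.5 h and
    2 h foci time points are placed on the local linear-in-time segment
    through p(1 h), so linear interpolation back to 1 h is exact. True
    slopes, intercepts and both four-point vectors are recorded in metadata.
    """
    if not math.isfinite(coupling_slope):
        raise ConfigError("coupling_slope must be finite")
    flux_cfg.validate()
    basal_frac = 1.0 - flux_cfg.mito_ocr_mult["rot_aa"]

    p_curves: Dict[str, list] = {}
    meta_lines: Dict[str, dict] = {}
    for cell, (ocr_base, _) in sorted(flux_cfg.baselines.items()):
        factors = [1.0] + [_response_factor(flux_cfg, "mito", t, True)
                           for t in METAB_TIMES[1:]]
        logm = np.log(np.array(factors) * ocr_base * basal_frac / flux_cfg.rfu_mean)
        a = p_center - coupling_slope * float(np.mean(logm))
        p4 = a + coupling_slope * logm
        if np.any(p4 <= 0) or np.any(p4 >= 1):
            raise ConfigError(
                f"cell line {cell!r}: coupled p values {p4.round(4).tolist()} "
                "leave (0,1); reduce |coupling_slope| or adjust p_center")
        p0, p1, p6, p24 = (float(x) for x in p4)
        s = (p6 - p1) / (METAB_TIMES[2] - METAB_TIMES[1])  # local per-hour slope
        p05, p2 = p1 - 0.5 * s, p1 + 1.0 * s
        if not (0 < p05 < 1 and 0 < p2 < 1):
            raise ConfigError(f"cell line {cell!r}: interpolation anchors leave (0,1)")
        p_curves[cell] = [p0, p05, p2, p6, p24]
        meta_lines[cell] = {
            "p5": p_curves[cell],
            "p4": [float(x) for x in p4],
            "logm4": [float(x) for x in logm],
            "intercept": float(a),
        }

    foci_cfg = FociSimConfig(**{**asdict(foci_cfg), "p_curves": p_curves, "seed": seed})
    flux_cfg = FluxSimConfig(**{**asdict(flux_cfg), "seed": seed})
    foci = simulate_foci_dataset(foci_cfg)
    flux = simulate_flux_study(flux_cfg, "mito", timepoints=METAB_TIMES[1:])
    metadata = {
        "coupling_slope": float(coupling_slope),
        "metab_parameter": "basal",
        "metab_times_h": list(METAB_TIMES),
        "foci_times_h": list(foci_cfg.times),
        "seed": int(seed),
        "cell_lines": meta_lines,
    }
    return CoupledStudy(foci=foci, flux=flux, metadata=metadata)
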