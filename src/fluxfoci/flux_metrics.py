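"""Mito and Glycolysis Stress Test parameters from per-well flux traces.

Parameter definitions follow the standard kit conventions:

Mito Stress Test (OCR, pmol O2/min)
    non-mitochondrial respiration = min OCR over rotenone/antimycin-A cycles
    basal respiration             = last basal-phase OCR - non-mito
    ATP production                = last basal-phase OCR - min oligomycin OCR
    proton leak                   = min oligomycin OCR - non-mito
    maximal respiration           = max FCCP OCR - non-mito
    spare capacity                = maximal - basal

Glycolysis Stress Test (ECAR, mpH/min)
    non-glycolytic acidification  = last glucose-free baseline ECAR
    glycolysis                    = max glucose-phase ECAR - non-glycolytic
    glycolytic capacity           = max oligomycin ECAR - non-glycolytic
    glycolytic reserve            = capacity - glycolysis

Whether the instrument software uses the last cycle or the phase mean for
the reference cycle is vendor-version dependent; ``cycle_stat="mean"``
switches every min/max/last above to the per-phase mean. Parameters are
normalized per well by Hoechst fluorescence (RFU) for cell number, and group
contrasts are reported as log2 of the ratio of group means.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, fields, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .dataio import GLYCO_PHASES, MITO_PHASES, ValidationError

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class MitoParams:
    non_mito: float
    basal: float
    atp_production: float
    proton_leak: float
    maximal: float
    spare_capacity: float


@dataclass(frozen=True)
class GlycoParams:
    non_glycolytic: float
    glycolysis: float
    glycolytic_capacity: float
    glycolytic_reserve: float


@dataclass(frozen=True)
class FoldChange:
    parameter: str
    cell_line: str
    treatment: str
    timepoint_h: float
    log2_fc: float
    n_treated: int
    n_control: int


def _phase_values(trace: pd.DataFrame, phase: str, column: str) -> np.ndarray:
    vals = trace.loc[trace["phase"] == phase, column].to_numpy(dtype=float)
    if vals.size == 0:
        raise ValidationError(f"trace is missing phase {phase!r}")
    return vals


def compute_mito_params(trace: pd.DataFrame, cycle_stat: str = "kit") -> MitoParams:
    """Derive Mito Stress Test parameters from one well's cycles.

    ``trace`` holds one well's rows (columns ``phase`` and ``ocr`` required),
    cycles in measurement order. Negative derived parameters are retained
    (they are numerically valid) but logged as biologically degenerate.
    """
    if cycle_stat not in ("kit", "mean"):
        raise ValueError(f"cycle_stat must be 'kit' or 'mean', got {cycle_stat!r}")
    vals = {ph: _phase_values(trace, ph, "ocr") for ph in MITO_PHASES}
    if cycle_stat == "kit":
        last_basal = vals["basal"][-1]
        min_oligo = vals["oligo"].min()
        max_fccp = vals["fccp"].max()
        non_mito = vals["rot_aa"].min()
    else:
        last_basal = vals["basal"].mean()
        min_oligo = vals["oligo"].mean()
        max_fccp = vals["fccp"].mean()
        non_mito = vals["rot_aa"].mean()
    p = MitoParams(
        non_mito=float(non_mito),
        basal=float(last_basal - non_mito),
        atp_production=float(last_basal - min_oligo),
        proton_leak=float(min_oligo - non_mito),
        maximal=float(max_fccp - non_mito),
        spare_capacity=float(max_fccp - last_basal),
    )
    if p.basal < 0 or p.atp_production < 0 or p.proton_leak < 0:
        log.warning("negative derived mito parameter (biologically degenerate): %s", p)
    return p


def compute_glyco_params(trace: pd.DataFrame, cycle_stat: str = "kit") -> GlycoParams:
    """Derive Glycolysis Stress Test parameters from one well's cycles."""
    if cycle_stat not in ("kit", "mean"):
        raise ValueError(f"cycle_stat must be 'kit' or 'mean', got {cycle_stat!r}")
    vals = {ph: _phase_values(trace, ph, "ecar") for ph in GLYCO_PHASES}
    if cycle_stat == "kit":
        non_glyc = vals["baseline"][-1]
        max_glucose = vals["glucose"].max()
        max_oligo = vals["oligo"].max()
    else:
        non_glyc = vals["baseline"].mean()
        max_glucose = vals["glucose"].mean()
        max_oligo = vals["oligo"].mean()
    p = GlycoParams(
        non_glycolytic=float(non_glyc),
        glycolysis=float(max_glucose - non_glyc),
        glycolytic_capacity=float(max_oligo - non_glyc),
        glycolytic_reserve=float(max_oligo - max_glucose),
    )
    if p.glycolysis < 0 or p.glycolytic_capacity < 0:
        log.warning("negative derived glyco parameter (biologically degenerate): %s", p)
    return p


def normalize_params(params, rfu: float):
    """Divide every parameter field by the well's RFU (cell-number proxy)."""
    if not rfu > 0:
        raise ValidationError(f"rfu must be > 0, got {rfu}")
    return replace(params, **{f.name: getattr(params, f.name) / rfu
                              for f in fields(params)})


PARAM_FIELDS = {
    "mito": [f.name for f in fields(MitoParams)],
    "glyco": [f.name for f in fields(GlycoParams)],
}


def compute_params_table(plate: pd.DataFrame, assay: str, normalize: bool = True,
                         cycle_stat: str = "kit") -> pd.DataFrame:
    """Per-well parameter table for a whole plate.

    Returns one row per well with metadata columns (cell_line, treatment,
    timepoint_h, experiment replicate inferred from the well grouping when
    present) and one column per derived parameter, RFU-normalized by default.
    """
    if assay not in PARAM_FIELDS:
        raise ValidationError(f"unknown assay {assay!r}")
    compute = compute_mito_params if assay == "mito" else compute_glyco_params
    rows = []
    sub = plate[plate["assay"] == assay]
    for well, trace in sub.groupby("well", sort=False):
        params = compute(trace, cycle_stat=cycle_stat)
        rfu = float(trace["rfu"].iloc[0])
        if normalize:
            params = normalize_params(params, rfu)
        row = {
            "well": well,
            "cell_line": trace["cell_line"].iloc[0],
            "treatment": trace["treatment"].iloc[0],
            "timepoint_h": float(trace["timepoint_h"].iloc[0]),
            "rfu": rfu,
        }
        row.update({f: getattr(params, f) for f in PARAM_FIELDS[assay]})
        rows.append(row)
    return pd.DataFrame(rows)


def energy_map_table(plate: pd.DataFrame, normalize: bool = True) -> pd.DataFrame:
    """Per-well basal OCR vs basal ECAR scatter export (the "energy map").

    Uses the mean of the first-phase cycles of each well of a mito-assay
    plate; optionally RFU-normalized. Plotting is left to the caller.
    """
    rows = []
    sub = plate[plate["assay"] == "mito"]
    for well, trace in sub.groupby("well", sort=False):
        basal = trace[trace["phase"] == "basal"]
        rfu = float(trace["rfu"].iloc[0]) if normalize else 1.0
        rows.append({
            "well": well, "cell_line": trace["cell_line"].iloc[0],
            "treatment": trace["treatment"].iloc[0],
            "timepoint_h": float(trace["timepoint_h"].iloc[0]),
            "ocr_basal": float(basal["ocr"].mean()) / rfu,
            "ecar_basal": float(basal["ecar"].mean()) / rfu,
        })
    return pd.DataFrame(rows)


def log2_fold_change(treated: Iterable[float], control: Iterable[float],
                     parameter: str, cell_line: str = "", treatment: str = "IR",
                     timepoint_h: float = float("nan")) -> FoldChange:
    """log2 of (mean treated / mean control) for one parameter.

    Uses the ratio of group means (not the mean of per-well ratios), matching
    the presentation of group means over n wells per condition.
    """
    treated = np.asarray(list(treated), dtype=float)
    control = np.asarray(list(control), dtype=float)
    if treated.size == 0 or control.size == 0:
        raise ValidationError("fold change needs >= 1 well in each group")
    mc = control.mean()
    mt = treated.mean()
    if not mc > 0:
        raise ValidationError(f"control mean must be > 0, got {mc}")
    if not mt > 0:
        raise ValidationError(f"treated mean must be > 0, got {mt}")
    return FoldChange(
        parameter=parameter, cell_line=cell_line, treatment=treatment,
        timepoint_h=timepoint_h, log2_fc=float(np.log2(mt / mc)),
        n_treated=int(treated.size), n_control=int(control.size),
    )


def fold_change_table(params: pd.DataFrame, parameter: str,
                      control_label: str = "control",
                      timepoints: Sequence[float] | None = None) -> pd.DataFrame:
    """Per (cell line, timepoint) log2 fold change vs matched unirradiated wells.

    Controls are the ``control_label`` wells measured at the same timepoint
    when present, otherwise the timepoint-0 controls.
    """
    out = []
    ctl = params[params["treatment"] == control_label]
    if ctl.empty:
        raise ValidationError(f"no wells with treatment == {control_label!r}")
    trt = params[params["treatment"] != control_label]
    tps = sorted(trt["timepoint_h"].unique()) if timepoints is None else timepoints
    for cell in sorted(params["cell_line"].unique()):
        base = ctl[(ctl["cell_line"] == cell) & (ctl["timepoint_h"] == 0.0)]
        for t in tps:
            tt = trt[(trt["cell_line"] == cell) & (trt["timepoint_h"] == t)]
            same = ctl[(ctl["cell_line"] == cell) & (ctl["timepoint_h"] == t)]
            cc = same if not same.empty else base
            if tt.empty or cc.empty:
                continue
            fc = log2_fold_change(
                tt[parameter], cc[parameter], parameter, cell_line=cell,
                treatment=tt["treatment"].iloc[0], timepoint_h=float(t))
            out.append(fc.__dict__)
    return pd.DataFrame(out)
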