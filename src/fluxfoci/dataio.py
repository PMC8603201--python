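"""Readers and writers for the pipeline's tabular artifacts.

All artifacts are delimited text (TSV by default, CSV accepted by file
extension), UTF-8, '.' decimal separator. Reals are serialized with 17
significant digits so that write -> read round-trips exactly.

Column contracts
----------------
Foci table (one row per nucleus at one time point):
    cell_line, replicate, time_h, nucleus_id, area_units, foci_count
    ``area_units`` is the nuclear area expressed as a count of 0.1*Pixel^2
    unit areas; ``foci_count`` is the number of gamma-H2A.X foci, a
    binomial success count with ``area_units`` trials.

Flux plate (one row per well per measurement cycle):
    well, cell_line, treatment, timepoint_h, assay, cycle_index, phase,
    ocr, ecar, rfu
    ``ocr`` in pmol O2/min, ``ecar`` in mpH/min, ``rfu`` the per-well
    Hoechst nuclear-stain fluorescence used for cell-number normalization.
    Phases must appear in canonical injection order within each well.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

FOCI_COLUMNS = ["cell_line", "replicate", "time_h", "nucleus_id", "area_units", "foci_count"]
FLUX_COLUMNS = [
    "well", "cell_line", "treatment", "timepoint_h", "assay",
    "cycle_index", "phase", "ocr", "ecar", "rfu",
]
MITO_PHASES = ("basal", "oligo", "fccp", "rot_aa")
GLYCO_PHASES = ("baseline", "glucose", "oligo", "2dg")
PHASES_BY_ASSAY = {"mito": MITO_PHASES, "glyco": GLYCO_PHASES}

SUMMARY_COLUMNS = [
    "response", "level", "median", "hdi50_lo", "hdi50_hi",
    "hdi95_lo", "hdi95_hi", "p_minus", "rhat", "ess", "mcse", "valid",
]

FLOAT_FMT = "%.17g"


class SchemaError(ValueError):
    """A file's header does not match the documented column contract."""


class ValidationError(ValueError):
    """A file parses but violates a row-level invariant."""


def _sep_for(path) -> str:
    return "," if str(path).endswith(".csv") else "\t"


def _require_columns(df: pd.DataFrame, columns, what: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{what}: missing required column(s) {missing}")


# ---------------------------------------------------------------- foci tables

def validate_foci_table(df: pd.DataFrame, time_grid=None) -> None:
    """Check foci-table invariants, raising ValidationError with row indices."""
    _require_columns(df, FOCI_COLUMNS, "foci table")
    area = df["area_units"].to_numpy()
    count = df["foci_count"].to_numpy()
    rep = df["replicate"].to_numpy()
    time = df["time_h"].to_numpy()

    bad = np.flatnonzero(area < 1)
    if bad.size:
        raise ValidationError(f"area_units must be >= 1; offending row(s) {bad[:5].tolist()}")
    bad = np.flatnonzero(count < 0)
    if bad.size:
        raise ValidationError(f"foci_count must be >= 0; offending row(s) {bad[:5].tolist()}")
    bad = np.flatnonzero(count > area)
    if bad.size:
        raise ValidationError(
            f"foci_count exceeds area_units at row(s) {bad[:5].tolist()}"
        )
    bad = np.flatnonzero(rep < 1)
    if bad.size:
        raise ValidationError(f"replicate must be a positive integer; row(s) {bad[:5].tolist()}")
    bad = np.flatnonzero(time < 0)
    if bad.size:
        raise ValidationError(f"time_h must be non-negative; row(s) {bad[:5].tolist()}")
    if time_grid is not None:
        grid = np.asarray(sorted(time_grid), dtype=float)
        ok = np.isin(time.astype(float), grid)
        bad = np.flatnonzero(~ok)
        if bad.size:
            raise ValidationError(
                f"time_h outside declared grid {grid.tolist()} at row(s) {bad[:5].tolist()}"
            )


def read_foci_table(path, time_grid=None) -> pd.DataFrame:
    df = pd.read_csv(path, sep=_sep_for(path))
    _require_columns(df, FOCI_COLUMNS, f"foci table {path}")
    df = df[FOCI_COLUMNS].copy()
    df["time_h"] = df["time_h"].astype(float)
    validate_foci_table(df, time_grid=time_grid)
    return df


def write_foci_table(df: pd.DataFrame, path) -> None:
    validate_foci_table(df)
    df[FOCI_COLUMNS].to_csv(path, sep=_sep_for(path), index=False, float_format=FLOAT_FMT)


# ---------------------------------------------------------------- flux plates

def validate_flux_plate(df: pd.DataFrame) -> None:
    """Check flux-plate invariants: canonical phase order, RFU constant per well."""
    _require_columns(df, FLUX_COLUMNS, "flux plate")
    bad_assay = set(df["assay"].unique()) - set(PHASES_BY_ASSAY)
    if bad_assay:
        raise ValidationError(f"unknown assay label(s) {sorted(bad_assay)}")
    if (df["ocr"].to_numpy() < 0).any() or (df["ecar"].to_numpy() < 0).any():
        raise ValidationError("ocr/ecar must be non-negative")
    if (df["rfu"].to_numpy() <= 0).any():
        raise ValidationError("rfu must be positive")

    for well, sub in df.groupby("well", sort=False):
        assays = sub["assay"].unique()
        if len(assays) != 1:
            raise ValidationError(f"well {well!r}: mixed assay labels {assays.tolist()}")
        canonical = PHASES_BY_ASSAY[assays[0]]
        phases = sub["phase"].tolist()
        # collapse consecutive repeats: cycles within a phase
        seq = [p for i, p in enumerate(phases) if i == 0 or p != phases[i - 1]]
        if tuple(seq) != canonical:
            raise ValidationError(
                f"well {well!r}: phases {seq} out of canonical order {list(canonical)}"
            )
        if sub["rfu"].nunique() != 1:
            raise ValidationError(f"well {well!r}: rfu not constant within well")


def read_flux_plate(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep=_sep_for(path))
    _require_columns(df, FLUX_COLUMNS, f"flux plate {path}")
    df = df[FLUX_COLUMNS].copy()
    for col in ("timepoint_h", "ocr", "ecar", "rfu"):
        df[col] = df[col].astype(float)
    validate_flux_plate(df)
    return df


def write_flux_plate(df: pd.DataFrame, path) -> None:
    validate_flux_plate(df)
    df[FLUX_COLUMNS].to_csv(path, sep=_sep_for(path), index=False, float_format=FLOAT_FMT)


# ------------------------------------------------------- summaries & matrices

def write_posterior_summary(summaries, path) -> None:
    """Write effect summaries as TSV with a fixed column order.

    ``summaries`` may be a DataFrame with (a subset of) SUMMARY_COLUMNS or an
    iterable of mappings / objects exposing ``to_row()``. An empty input
    produces a header-only file.
    """
    if isinstance(summaries, pd.DataFrame):
        df = summaries.copy()
    else:
        rows = []
        for s in summaries:
            rows.append(s.to_row() if hasattr(s, "to_row") else dict(s))
        df = pd.DataFrame(rows, columns=SUMMARY_COLUMNS)
    cols = [c for c in SUMMARY_COLUMNS if c in df.columns] + [
        c for c in df.columns if c not in SUMMARY_COLUMNS
    ]
    df[cols].to_csv(path, sep=_sep_for(path), index=False, float_format=FLOAT_FMT)


def read_posterior_summary(path) -> pd.DataFrame:
    return pd.read_csv(path, sep=_sep_for(path))


def write_distance_matrix(labels, d, path, atol: float = 0.0) -> None:
    """Write a labelled symmetric distance matrix; asymmetric input is refused."""
    d = np.asarray(d, dtype=float)
    labels = list(labels)
    if d.ndim != 2 or d.shape[0] != d.shape[1] or d.shape[0] != len(labels):
        raise ValidationError("distance matrix must be square and match labels")
    if not np.allclose(d, d.T, atol=atol, rtol=0.0):
        raise ValidationError("refusing to write a non-symmetric distance matrix")
    out = pd.DataFrame(d, index=labels, columns=labels)
    out.to_csv(path, sep=_sep_for(path), index=True, index_label="cell_line",
               float_format=FLOAT_FMT)


def read_distance_matrix(path):
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    return list(df.index), df.to_numpy(dtype=float)
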