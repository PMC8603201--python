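import numpy as np
import pandas as pd
import pytest

from fluxfoci import FociSimConfig, simulate_foci_dataset
from fluxfoci._mcmc import SamplerSettings
from fluxfoci.dataio import FLUX_COLUMNS


@pytest.fixture(scope="session")
def fast_sampler():
    return SamplerSettings(chains=2, steps=800, seed=11)


@pytest.fixture(scope="session")
def clean_foci_table():
    """A clean single-cell-line repair time course at study scale."""
    cfg = FociSimConfig(
        p_curves={"lineA": (0.002, 0.030, 0.015, 0.005, 0.002)}, seed=7)
    return simulate_foci_dataset(cfg)


@pytest.fixture(scope="session")
def clean_fit(clean_foci_table):
    from fluxfoci import fit_foci_model
    return fit_foci_model(clean_foci_table,
                          SamplerSettings(chains=2, steps=1500, seed=13))


def make_well(well="w1", assay="mito", phase_values=None, cell="A",
              treatment="control", timepoint=0.0, rfu=1000.0, cycles=3):
    """Build one well's flux rows with constant per-phase OCR==ECAR values."""
    rows = []
    i = 0
    for phase, val in phase_values.items():
        for c in range(cycles):
            rows.append((well, cell, treatment, timepoint, assay, c + 1,
                         phase, val, val, rfu))
            i += 1
    return pd.DataFrame(rows, columns=FLUX_COLUMNS)


@pytest.fixture
def mito_well():
    return make_well(phase_values={"basal": 100.0, "oligo": 40.0,
                                   "fccp": 150.0, "rot_aa": 20.0})


@pytest.fixture
def glyco_well():
    return make_well(assay="glyco",
                     phase_values={"baseline": 10.0, "glucose": 40.0,
                                   "oligo": 70.0, "2dg": 12.0})


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
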