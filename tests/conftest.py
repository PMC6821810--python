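import numpy as np
import pandas as pd
import pytest

from spikecount import (
    CalibrationParams,
    GrowthDesign,
    MixingDesign,
    MixtureContext,
    NoiseModel,
    SpikeInLocus,
)
from spikecount.core import CalibrationSource


@pytest.fixture
def wide_calib():
    """Well-separated calibration typical of a clean assay."""
    return CalibrationParams(0.02, 0.98, CalibrationSource.FITTED)


@pytest.fixture
def simple_ctx(wide_calib):
    """Mixture context with a round copy number for hand arithmetic."""
    return MixtureContext(1e6, wide_calib, ploidy=2)


@pytest.fixture
def unit_locus():
    """Locus whose copy number is exactly 1e6 (mass/MW chosen for that)."""
    from spikecount.core import AVOGADRO

    return SpikeInLocus(
        "UNIT", "cg_unit", mass_ug=1.0, molar_weight_g_per_mol=AVOGADRO * 1e-6 / 1e6,
        correction_factor=1.0,
    )


@pytest.fixture
def noiseless_series(unit_locus, wide_calib):
    """Exact (infinite-depth) mixing series over 5 decades of cell numbers."""
    from spikecount import EXACT, simulate_mixing_series

    design = MixingDesign(
        true_cell_numbers=tuple(np.geomspace(1e3, 1e7, 6)),
        locus=unit_locus,
        calib=wide_calib,
        noise=EXACT,
        replicates_per_point=1,
        seed=0,
    )
    return simulate_mixing_series(design)


@pytest.fixture
def estimates_table():
    """Hand-built estimates table: one condition, 3 lines, 2 days."""
    rows = []
    for line, scale in (("L1", 900.0), ("L2", 1000.0), ("L3", 1100.0)):
        for day, factor in ((0, 1.0), (7, 4.0)):
            rows.append(
                {
                    "condition": "TCP",
                    "line": line,
                    "day": day,
                    "cells": scale * factor,
                    "status": "ok",
                }
            )
    return pd.DataFrame(rows)
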