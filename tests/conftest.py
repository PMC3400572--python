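"""Shared fixtures: the calibrated cell and the expensive simulated maps.

Session scope keeps each heavy simulation to a single run; the peak cache
in the summation module additionally shares single-site ramps with grid
rows and columns.
"""

from __future__ import annotations

import numpy as np
import pytest

from dendsum.cell import CellModel, CellSpec, default_cell
from dendsum.summation import (
    TwoInputMap,
    between_branch_comparison,
    map_two_input,
    ramp_single_site,
)
from dendsum.two_compartment import (
    TwoCompParams,
    fit_output_scale,
    response_surface,
)

RAMP_COUNTS = np.arange(2, 42, 2)


@pytest.fixture(scope="session")
def cell() -> CellModel:
    return default_cell()


@pytest.fixture(scope="session")
def passive_cell() -> CellModel:
    return CellModel(CellSpec(with_axon=False, channels=None))


@pytest.fixture(scope="session")
def ramps(cell):
    """Single-pulse synapse-count ramps at 70/160 um, control and NMDA block."""
    out = {}
    for loc in (70.0, 160.0):
        for scale, cond in ((1.0, "control"), (0.0, "block")):
            out[(loc, cond)] = ramp_single_site(cell, loc, RAMP_COUNTS,
                                                nmda_scale=scale)
    return out


@pytest.fixture(scope="session")
def two_input_map(cell) -> TwoInputMap:
    """The canonical (90, 150) um double-pulse map, 21 x 21."""
    return map_two_input(cell, 90.0, 150.0, n_max=40, step=2)


@pytest.fixture(scope="session")
def branch_comparison(cell) -> dict:
    return between_branch_comparison(cell)


@pytest.fixture(scope="session")
def twocomp_surface() -> np.ndarray:
    """41 x 41 steady-state surface of the printed circuit parameters."""
    return response_surface(TwoCompParams())


@pytest.fixture(scope="session")
def canonical_map_2c() -> TwoInputMap:
    """Coarse 2-compartment surface dressed as a two-input map (for synth)."""
    counts = np.arange(0, 41, 4)
    surf = response_surface(TwoCompParams(), counts, counts)
    surf = surf * fit_output_scale(surf, 15.2)
    return TwoInputMap(90.0, 150.0, counts, counts, surf)


@pytest.fixture(scope="session")
def epsp_table():
    from dendsum.epsp import distance_sweep

    return distance_sweep(n_sets=4, seed=11)
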