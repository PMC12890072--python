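"""Shared fixtures: synthetic ensembles with analytically known answers.

The three session-scoped solvation fixtures (ideal gas, hard wall,
square well) are the workhorses of the MDDF/KBI checks.  Their sizes
were set by an a-priori variance budget (see docs/methods.md) so the
statistical error of each analytic comparison is several times smaller
than the tolerance asserted on it; seeds are fixed constants.
"""

from __future__ import annotations

import numpy as np
import pytest

from solvkb.mddf import compute_mddf
from solvkb.model import AnalysisConfig, SimulationBox
from solvkb.synth import SyntheticModel, gen_solvent_ensemble


def brute_force_min_distance(solute: np.ndarray, molecule: np.ndarray,
                             lengths: np.ndarray):
    """Exhaustive all-pairs, all-27-images minimum distance oracle.

    Returns (dmin, solute_idx, solvent_atom_idx) with ties broken by
    lowest (solute index, solvent atom index).
    """
    best = (np.inf, -1, -1)
    shifts = [-1.0, 0.0, 1.0]
    for si, s in enumerate(solute):
        for ai, a in enumerate(molecule):
            delta = s - a
            for kx in shifts:
                for ky in shifts:
                    for kz in shifts:
                        shift = np.array([kx, ky, kz]) * lengths
                        d = np.sqrt(np.sum((delta - shift) ** 2))
                        if d < best[0]:
                            best = (d, si, ai)
    return best


@pytest.fixture(scope="session")
def ideal_gas_setup():
    """Point solute in an interaction-free solvent: g == 1, G == 0."""
    box = SimulationBox.cubic(30.0)
    solute = np.array([[15.0, 15.0, 15.0]])
    model = SyntheticModel("ideal_gas", density=1000 / box.volume, seed=101)
    system = gen_solvent_ensemble(solute, box, model, n_frames=100)
    config = AnalysisConfig(bin_width=0.1, r_max=15.0, bulk_shell=(10.0, 15.0),
                            reference_oversampling=5, seed=7)
    return system, config, model


@pytest.fixture(scope="session")
def ideal_gas_mddf(ideal_gas_setup):
    system, config, _ = ideal_gas_setup
    return compute_mddf(system, "water", config)


@pytest.fixture(scope="session")
def hard_wall_setup():
    """Point solute with a 3 Å hard wall: G -> -(4/3) pi d^3."""
    box = SimulationBox.cubic(20.0)
    solute = np.array([[10.0, 10.0, 10.0]])
    model = SyntheticModel("hard_wall", density=0.05, wall_distance=3.0, seed=11)
    system = gen_solvent_ensemble(solute, box, model, n_frames=12000)
    config = AnalysisConfig(bin_width=0.1, r_max=10.0, bulk_shell=(6.0, 9.0),
                            reference_oversampling=3, seed=5)
    return system, config, model


@pytest.fixture(scope="session")
def hard_wall_mddf(hard_wall_setup):
    system, config, _ = hard_wall_setup
    return compute_mddf(system, "water", config)


@pytest.fixture(scope="session")
def square_well_setup():
    """Point solute with a unit-kT square well over [3, 4] Å:
    g = e in the well, G -> (e - 1) V_well - V_core."""
    box = SimulationBox.cubic(24.0)
    solute = np.array([[12.0, 12.0, 12.0]])
    model = SyntheticModel("square_well", density=0.05, wall_distance=3.0,
                           well_depth=1.0, well_width=1.0, seed=13)
    system = gen_solvent_ensemble(solute, box, model, n_frames=6000)
    config = AnalysisConfig(bin_width=0.1, r_max=10.0, bulk_shell=(6.0, 9.0),
                            reference_oversampling=3, seed=5)
    return system, config, model


@pytest.fixture(scope="session")
def square_well_mddf(square_well_setup):
    system, config, _ = square_well_setup
    return compute_mddf(system, "water", config)
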