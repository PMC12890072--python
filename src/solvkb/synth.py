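"""Synthetic solute-solvent ensembles with analytically known structure.

The generator places rigid solvent molecules independently around a
fixed solute, one molecule at a time, according to one of three radial
models of the solute-solvent interaction expressed in terms of the
molecule's minimum distance ``r`` to the solute:

``ideal_gas``
    No interaction: uniform positions and orientations.  The MDDF is
    identically 1 and all KBIs vanish.
``hard_wall``
    Excluded region below ``d``: molecules never approach closer than
    ``d``.  The KBI converges to minus the excluded volume.
``square_well``
    Hard core below ``d`` plus an attractive well of depth ``eps``
    (in units of kT) over ``[d, d + w]``.  Because molecules are placed
    independently (no solvent-solvent correlations), the MDDF has the
    closed form ``exp(eps)`` inside the well and 1 outside, and the KBI
    converges to ``(exp(eps) - 1) * V_well - V_core``.

Sampling is exact rejection sampling against the uniform envelope, so
generated ensembles follow the stated Boltzmann weights without
Markov-chain burn-in, and seeded runs are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import molecule_min_distances, place_rigid
from .model import (
    AtomRecord,
    Frame,
    PolarityClass,
    Role,
    SimulationBox,
    SolvationSystem,
    SolventSpecies,
)

_MIN_ACCEPTANCE = 1e-3


@dataclass(frozen=True)
class SyntheticModel:
    """Radial placement model for one solvent species.

    Parameters
    ----------
    kind : {"ideal_gas", "hard_wall", "square_well"}
    wall_distance : float
        Hard-core distance ``d`` in Å (ignored for ``ideal_gas``).
    well_depth : float
        Well depth ``eps`` in units of kT (square well only).
    well_width : float
        Width ``w`` of the attractive well in Å (square well only).
    density : float
        Number density in molecules/Å^3; the generated molecule count is
        ``round(density * V_box)`` exactly.
    seed : int
        Seed of the generator's random stream.
    """

    kind: str
    density: float
    wall_distance: float = 0.0
    well_depth: float = 0.0
    well_width: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("ideal_gas", "hard_wall", "square_well"):
            raise ValueError(f"unknown model kind {self.kind!r}")
        if self.density <= 0:
            raise ValueError("density must be positive")
        if self.wall_distance < 0:
            raise ValueError("wall_distance must be >= 0")
        if self.kind == "square_well" and self.well_width <= 0:
            raise ValueError("square_well needs well_width > 0")

    def log_weight(self, dmin: np.ndarray) -> np.ndarray:
        """Log of the (unnormalised) placement weight at minimum distance dmin."""
        if self.kind == "ideal_gas":
            return np.zeros_like(dmin)
        logw = np.where(dmin < self.wall_distance, -np.inf, 0.0)
        if self.kind == "square_well":
            in_well = (dmin >= self.wall_distance) & (
                dmin < self.wall_distance + self.well_width
            )
            logw = np.where(in_well, self.well_depth, logw)
        return logw


def point_species(name: str = "water", n_molecules: int = 0) -> SolventSpecies:
    """A one-atom solvent species (idealised water oxygen)."""
    rec = AtomRecord("O", "O", 1, name.upper()[:3] or "SOL", Role.SOLVENT)
    return SolventSpecies(name=name, atom_records=[rec], n_molecules=n_molecules)


#: Rigid geometry of the 3-atom toy cosolvent: a protruding hydroxyl-like
#: hydrogen (HO), a carbon, and a fluorine-like atom.  Distances in Å.
TOY_COSOLVENT_TEMPLATE = np.array(
    [
        [0.0, 0.0, 0.0],  # HO
        [1.0, 0.0, 0.0],  # C
        [1.8, 1.0, 0.0],  # F
    ]
)


def toy_cosolvent_species(name: str = "cosolvent", n_molecules: int = 0) -> SolventSpecies:
    """Three-atom rigid toy cosolvent used to exercise decomposition."""
    records = [
        AtomRecord("HO", "H", 1, "TFE", Role.SOLVENT),
        AtomRecord("C", "C", 1, "TFE", Role.SOLVENT),
        AtomRecord("F", "F", 1, "TFE", Role.SOLVENT),
    ]
    return SolventSpecies(name=name, atom_records=records, n_molecules=n_molecules)


def species_template(species: SolventSpecies) -> np.ndarray:
    """Rigid template coordinates for a species (by name convention)."""
    if species.atoms_per_molecule == 1:
        return np.zeros((1, 3))
    if species.atoms_per_molecule == 3:
        return TOY_COSOLVENT_TEMPLATE.copy()
    raise ValueError(
        f"no built-in template for a {species.atoms_per_molecule}-atom species"
    )


def _sample_frame(
    solute: np.ndarray,
    box: SimulationBox,
    model: SyntheticModel,
    template: np.ndarray,
    n_molecules: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw one frame of independently placed molecules by rejection sampling."""
    # envelope constant: max weight is exp(eps) for the square well, 1 otherwise
    log_envelope = model.well_depth if model.kind == "square_well" else 0.0
    accepted: list[np.ndarray] = []
    n_accepted = 0
    n_proposed = 0
    while n_accepted < n_molecules:
        batch = max(n_molecules - n_accepted, 256)
        cand = place_rigid(template, batch, box, rng)
        if model.kind == "ideal_gas":
            keep = np.ones(batch, dtype=bool)
        else:
            dmin = molecule_min_distances(solute, cand, box)
            accept_p = np.exp(model.log_weight(dmin) - log_envelope)
            keep = rng.uniform(size=batch) < accept_p
        n_proposed += batch
        n_accepted += int(keep.sum())
        accepted.append(cand[keep])
        if n_proposed >= 10_000 and n_accepted / n_proposed < _MIN_ACCEPTANCE:
            raise RuntimeError(
                "placement acceptance rate below 1e-3; "
                "lower the density, the well depth, or the wall distance"
            )
    return np.concatenate(accepted, axis=0)[:n_molecules]


def gen_solvent_ensemble(
    solute_coords: np.ndarray,
    box: SimulationBox,
    model: SyntheticModel,
    n_frames: int,
    species: SolventSpecies | None = None,
    solute_atoms: list[AtomRecord] | None = None,
) -> SolvationSystem:
    """Generate a single-species ensemble around a fixed solute.

    The molecule count is ``round(model.density * box.volume)``; the
    species' ``n_molecules`` field is overwritten accordingly.
    """
    solute_coords = np.asarray(solute_coords, dtype=float)
    if solute_coords.ndim != 2 or solute_coords.shape[1] != 3:
        raise ValueError("solute_coords must have shape (n_atoms, 3)")
    if np.any(solute_coords < -box.lengths) or np.any(solute_coords > 2 * box.lengths):
        raise ValueError("solute does not fit in the box")
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    if species is None:
        species = point_species()
    n_molecules = int(round(model.density * box.volume))
    if n_molecules < 1:
        raise ValueError("density * volume rounds to zero molecules")
    species = SolventSpecies(species.name, species.atom_records, n_molecules)
    template = species_template(species)
    if solute_atoms is None:
        solute_atoms = [
            AtomRecord(f"S{i + 1}", "C", 1, "LIG", Role.SIDECHAIN,
                       PolarityClass.NONPOLAR)
            for i in range(solute_coords.shape[0])
        ]

    rng = np.random.default_rng(model.seed)
    frames = [
        Frame(
            solute=solute_coords.copy(),
            solvent={species.name: _sample_frame(solute_coords, box, model,
                                                 template, n_molecules, rng)},
            box=box,
        )
        for _ in range(n_frames)
    ]
    return SolvationSystem(
        solute_atoms=list(solute_atoms),
        species={species.name: species},
        frames=frames,
    )


def gen_binary_solvent(
    solute_coords: np.ndarray,
    box: SimulationBox,
    models: dict[str, SyntheticModel],
    n_frames: int,
    species: dict[str, SolventSpecies] | None = None,
    solute_atoms: list[AtomRecord] | None = None,
) -> SolvationSystem:
    """Generate a two-species ensemble; each species follows its own model.

    The canonical use is a square-well "cosolvent" plus an ideal-gas
    "water", which by construction must yield a positive preferential
    interaction parameter for the cosolvent.
    """
    if len(models) != 2:
        raise ValueError("gen_binary_solvent needs exactly two species models")
    if species is None:
        names = list(models)
        species = {names[0]: point_species(names[0]),
                   names[1]: point_species(names[1])}
    single = {
        name: gen_solvent_ensemble(
            solute_coords, box, models[name], n_frames,
            species=species[name], solute_atoms=solute_atoms,
        )
        for name in models
    }
    first = next(iter(single.values()))
    merged_species = {name: sys.species[name] for name, sys in single.items()}
    frames = []
    for i in range(n_frames):
        solvent = {}
        for name, sys in single.items():
            solvent[name] = sys.frames[i].solvent[name]
        frames.append(Frame(solute=first.frames[i].solute, solvent=solvent, box=box))
    return SolvationSystem(
        solute_atoms=first.solute_atoms,
        species=merged_species,
        frames=frames,
    )
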