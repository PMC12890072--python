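"""Core domain types: boxes, atoms, solvent species and multi-frame systems.

A :class:`SolvationSystem` is the substrate of every analysis in this
package: a solute (list of :class:`AtomRecord` plus per-frame coordinates)
surrounded by one or more solvent species whose molecules are stored as
``(n_molecules, atoms_per_molecule, 3)`` arrays per frame, all inside an
orthorhombic periodic box.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np


class Role(str, enum.Enum):
    """Structural role of an atom."""

    BACKBONE = "backbone"
    SIDECHAIN = "sidechain"
    SOLVENT = "solvent"


class PolarityClass(str, enum.Enum):
    """Coarse polarity classification of the parent residue/side chain."""

    POLAR_CHARGED = "polar_charged"
    POLAR_UNCHARGED = "polar_uncharged"
    NONPOLAR = "nonpolar"
    NA = "n/a"


@dataclass(frozen=True)
class SimulationBox:
    """Orthorhombic periodic box with edge lengths in Å."""

    lengths: np.ndarray

    def __post_init__(self) -> None:
        lengths = np.asarray(self.lengths, dtype=float).reshape(3)
        if not np.all(np.isfinite(lengths)) or np.any(lengths <= 0):
            raise ValueError(f"box lengths must be positive and finite, got {lengths}")
        object.__setattr__(self, "lengths", lengths)

    @property
    def volume(self) -> float:
        return float(np.prod(self.lengths))

    @classmethod
    def cubic(cls, length: float) -> "SimulationBox":
        return cls(np.full(3, float(length)))


@dataclass(frozen=True)
class AtomRecord:
    """One atom of the solute or of a solvent molecule template."""

    atom_name: str
    element: str
    residue_index: int  # 1-based, preserved from the input file
    residue_name: str
    role: Role
    polarity_class: PolarityClass = PolarityClass.NA

    def __post_init__(self) -> None:
        if self.residue_index < 1:
            raise ValueError("residue_index is 1-based and must be >= 1")


@dataclass
class SolventSpecies:
    """A solvent species: a rigid molecule template replicated n_molecules times."""

    name: str
    atom_records: list[AtomRecord]
    n_molecules: int

    def __post_init__(self) -> None:
        if not self.atom_records:
            raise ValueError("a solvent species needs at least one atom")
        if self.n_molecules < 0:
            raise ValueError("n_molecules must be non-negative")
        for rec in self.atom_records:
            if rec.role is not Role.SOLVENT:
                raise ValueError("solvent species atoms must have role=solvent")

    @property
    def atoms_per_molecule(self) -> int:
        return len(self.atom_records)


@dataclass
class Frame:
    """A single snapshot: solute coordinates, per-species solvent coordinates, box."""

    solute: np.ndarray  # (n_solute_atoms, 3) Å
    solvent: dict[str, np.ndarray]  # name -> (n_molecules, atoms_per_molecule, 3) Å
    box: SimulationBox

    def __post_init__(self) -> None:
        self.solute = np.asarray(self.solute, dtype=float)
        if self.solute.ndim != 2 or self.solute.shape[1] != 3:
            raise ValueError("solute coordinates must have shape (n_atoms, 3)")
        if not np.all(np.isfinite(self.solute)):
            raise ValueError("non-finite solute coordinates")
        clean: dict[str, np.ndarray] = {}
        for name, coords in self.solvent.items():
            coords = np.asarray(coords, dtype=float)
            if coords.ndim != 3 or coords.shape[2] != 3:
                raise ValueError(
                    f"solvent coordinates for {name!r} must have shape "
                    f"(n_molecules, atoms_per_molecule, 3)"
                )
            if not np.all(np.isfinite(coords)):
                raise ValueError(f"non-finite solvent coordinates for {name!r}")
            clean[name] = coords
        self.solvent = clean


@dataclass
class SolvationSystem:
    """A solute plus grouped solvent molecules over one or more frames."""

    solute_atoms: list[AtomRecord]
    species: dict[str, SolventSpecies]
    frames: list[Frame]

    def __post_init__(self) -> None:
        if not self.frames:
            raise ValueError("a SolvationSystem needs at least one frame")
        n_solute = len(self.solute_atoms)
        for i, frame in enumerate(self.frames):
            if frame.solute.shape[0] != n_solute:
                raise ValueError(
                    f"frame {i}: {frame.solute.shape[0]} solute atoms, "
                    f"expected {n_solute}"
                )
            for name, sp in self.species.items():
                coords = frame.solvent.get(name)
                if coords is None:
                    raise ValueError(f"frame {i}: missing species {name!r}")
                if coords.shape[:2] != (sp.n_molecules, sp.atoms_per_molecule):
                    raise ValueError(
                        f"frame {i}: species {name!r} has shape {coords.shape[:2]}, "
                        f"expected {(sp.n_molecules, sp.atoms_per_molecule)}"
                    )

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def n_solute_atoms(self) -> int:
        return len(self.solute_atoms)

    def residue_indices(self) -> np.ndarray:
        """1-based residue index of each solute atom."""
        return np.array([a.residue_index for a in self.solute_atoms], dtype=int)

    def residue_labels(self) -> list[str]:
        """Ordered unique ``NAME###`` labels of the solute residues."""
        seen: dict[int, str] = {}
        for a in self.solute_atoms:
            seen.setdefault(a.residue_index, f"{a.residue_name}{a.residue_index}")
        return [seen[i] for i in sorted(seen)]


@dataclass(frozen=True)
class AnalysisConfig:
    """Binning and reference-sampling parameters shared by MDDF and KBI.

    Parameters
    ----------
    bin_width : float
        Histogram bin width in Å.
    r_max : float
        Upper limit R of the distance histograms and KBI profiles, Å.
    bulk_shell : tuple of float
        Minimum-distance interval, in Å from the solute surface, whose
        occupancy defines the bulk solvent density.
    reference_oversampling : int
        Number of ideal-gas reference insertions per real solvent
        molecule (variance reduction; expectation is unchanged).
    seed : int
        Seed for the reference-insertion random stream.
    include_solute_hydrogens : bool
        Whether solute hydrogens participate in minimum distances.
    """

    bin_width: float = 0.1
    r_max: float = 15.0
    bulk_shell: tuple[float, float] = (10.0, 15.0)
    reference_oversampling: int = 5
    seed: int = 0
    include_solute_hydrogens: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.bin_width < self.r_max:
            raise ValueError("need 0 < bin_width < r_max")
        lo, hi = self.bulk_shell
        if not (0 < lo < hi <= self.r_max):
            raise ValueError("bulk_shell must satisfy 0 < lo < hi <= r_max")
        if self.reference_oversampling < 1:
            raise ValueError("reference_oversampling must be >= 1")

    @property
    def n_bins(self) -> int:
        return int(round(self.r_max / self.bin_width))

    def bin_edges(self) -> np.ndarray:
        """Half-open bin edges [0, r_max] with width ``bin_width``."""
        return np.linspace(0.0, self.n_bins * self.bin_width, self.n_bins + 1)
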