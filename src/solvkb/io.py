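"""Structure/trajectory readers and writers (MDAnalysis-backed).

Supported formats: PDB and GRO for structures, XYZ, DCD and XTC for
trajectories, YAML for manifests/configs.  Reading returns the domain
types of :mod:`solvkb.model`; the split of a flat atom list into solute
plus solvent species is driven by residue names.

Atom ordering convention for written systems: solute atoms first, then
each species (sorted by name) with its molecules consecutive.  The
manifest written next to a fixture records this layout so trajectories
can be re-split without heuristics.
"""

from __future__ import annotations

import pathlib
import warnings
from dataclasses import dataclass

import numpy as np
import yaml

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    import MDAnalysis as mda

from .chemistry import WATER_RESIDUES, classify_atom
from .model import (
    AtomRecord,
    Frame,
    Role,
    SimulationBox,
    SolvationSystem,
    SolventSpecies,
)

STRUCTURE_FORMATS = ("PDB", "GRO")
TRAJECTORY_FORMATS = ("XYZ", "DCD", "XTC")


class StructureParseError(ValueError):
    """Malformed structure file; the message names the offending line."""


class TrajectoryError(ValueError):
    """Trajectory inconsistent with the structure; names the frame."""


@dataclass
class Structure:
    """A flat structure file: atoms, first-frame coordinates, optional box."""

    atoms: list[AtomRecord]
    coords: np.ndarray
    box: SimulationBox | None
    resnames: np.ndarray  # per-atom residue name
    resids: np.ndarray  # per-atom residue id (file numbering)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)


def _infer_format(path: str | pathlib.Path, formats: tuple[str, ...]) -> str:
    suffix = pathlib.Path(path).suffix.lstrip(".").upper()
    if suffix not in formats:
        raise ValueError(f"cannot infer format from {path!s}; expected {formats}")
    return suffix


def _prevalidate_pdb(path: pathlib.Path) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.startswith(("ATOM", "HETATM")):
                continue
            if len(line.rstrip("\n")) < 54:
                raise StructureParseError(
                    f"{path.name} line {lineno}: truncated ATOM record"
                )
            for lo, hi, what in ((30, 38, "x"), (38, 46, "y"), (46, 54, "z")):
                try:
                    float(line[lo:hi])
                except ValueError:
                    raise StructureParseError(
                        f"{path.name} line {lineno}: malformed {what} coordinate "
                        f"field {line[lo:hi]!r}"
                    ) from None


def _prevalidate_gro(path: pathlib.Path) -> None:
    lines = open(path).read().splitlines()
    if len(lines) < 3:
        raise StructureParseError(f"{path.name}: too short for a GRO file")
    try:
        n_atoms = int(lines[1].strip())
    except ValueError:
        raise StructureParseError(
            f"{path.name} line 2: expected atom count, got {lines[1]!r}"
        ) from None
    if len(lines) < n_atoms + 3:
        raise StructureParseError(
            f"{path.name}: declares {n_atoms} atoms but has "
            f"{len(lines) - 3} atom lines"
        )
    for i in range(n_atoms):
        lineno = i + 3
        line = lines[lineno - 1]
        if len(line) < 44:
            raise StructureParseError(
                f"{path.name} line {lineno}: truncated coordinate fields"
            )
        for lo, hi in ((20, 28), (28, 36), (36, 44)):
            try:
                float(line[lo:hi])
            except ValueError:
                raise StructureParseError(
                    f"{path.name} line {lineno}: malformed coordinate "
                    f"field {line[lo:hi]!r}"
                ) from None


def read_structure(
    path: str | pathlib.Path,
    format: str | None = None,
    solvent_resnames: set[str] | None = None,
    his_charged: bool = False,
) -> Structure:
    """Read a PDB or GRO structure into atom records plus coordinates.

    Roles and polarity classes are assigned from the residue tables in
    :mod:`solvkb.chemistry`; atoms of residues named in
    ``solvent_resnames`` (waters by default) get role=solvent.  Residue
    indexing is 1-based and preserved from the file.
    """
    path = pathlib.Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = (format or _infer_format(path, STRUCTURE_FORMATS)).upper()
    if fmt not in STRUCTURE_FORMATS:
        raise ValueError(f"unsupported structure format {fmt!r}")
    if fmt == "PDB":
        _prevalidate_pdb(path)
    else:
        _prevalidate_gro(path)
    solvent_resnames = {r.upper() for r in (solvent_resnames or set())} | WATER_RESIDUES

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        universe = mda.Universe(str(path), format=fmt)
    names = universe.atoms.names
    resnames = universe.atoms.resnames
    resids = universe.atoms.resids
    atoms = [
        classify_atom(
            atom_name=str(names[i]),
            residue_name=str(resnames[i]),
            residue_index=int(resids[i]),
            is_solvent=str(resnames[i]).upper() in solvent_resnames,
            his_charged=his_charged,
        )
        for i in range(len(names))
    ]
    dims = universe.dimensions
    box = None
    if dims is not None and np.all(dims[:3] > 0):
        box = SimulationBox(np.asarray(dims[:3], dtype=float))
    return Structure(
        atoms=atoms,
        coords=np.asarray(universe.atoms.positions, dtype=float),
        box=box,
        resnames=np.asarray(resnames, dtype=object),
        resids=np.asarray(resids, dtype=int),
    )


@dataclass
class SystemLayout:
    """How a flat atom array splits into solute and solvent species."""

    solute_index: np.ndarray  # indices into the flat atom order
    species_order: list[str]
    species_index: dict[str, np.ndarray]  # name -> (n_mol, apm) index matrix


def layout_from_structure(
    structure: Structure, species_resnames: dict[str, str]
) -> SystemLayout:
    """Split a structure into solute + species by residue name.

    ``species_resnames`` maps species names (e.g. ``water``) to the
    residue name used in the file (e.g. ``SOL``).  Molecules are the
    residues of that name; every molecule of a species must have the
    same atom count.
    """
    resnames = np.array([r.upper() for r in structure.resnames])
    used = np.zeros(structure.n_atoms, dtype=bool)
    species_index: dict[str, np.ndarray] = {}
    order = sorted(species_resnames)
    for name in order:
        resname = species_resnames[name].upper()
        mask = resnames == resname
        if not mask.any():
            raise ValueError(f"no atoms with residue name {resname!r} for species {name!r}")
        idx = np.flatnonzero(mask)
        rid = structure.resids[idx]
        # group consecutive atoms by residue id
        breaks = np.flatnonzero(np.diff(rid) != 0) + 1
        groups = np.split(idx, breaks)
        sizes = {len(g) for g in groups}
        if len(sizes) != 1:
            raise ValueError(
                f"species {name!r}: molecules have differing atom counts {sorted(sizes)}"
            )
        species_index[name] = np.vstack(groups)
        used[idx] = True
    return SystemLayout(
        solute_index=np.flatnonzero(~used),
        species_order=order,
        species_index=species_index,
    )


def _iter_frames(universe: "mda.Universe"):
    for ts in universe.trajectory:
        yield ts


def read_trajectory(
    path: str | pathlib.Path,
    structure: Structure,
    species_resnames: dict[str, str],
    format: str | None = None,
    box: SimulationBox | None = None,
    structure_path: str | pathlib.Path | None = None,
) -> SolvationSystem:
    """Read a trajectory against a structure into a SolvationSystem.

    Frames keep file order.  The box is taken per frame when the format
    carries one (DCD/XTC), otherwise from ``box`` or the structure.
    """
    path = pathlib.Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = (format or _infer_format(path, TRAJECTORY_FORMATS)).upper()
    if fmt not in TRAJECTORY_FORMATS:
        raise ValueError(f"unsupported trajectory format {fmt!r}")
    layout = layout_from_structure(structure, species_resnames)

    n_expected = structure.n_atoms
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            universe = mda.Universe.empty(n_expected, trajectory=False)
            universe.load_new(str(path), format=fmt)
    except (ValueError, OSError, EOFError) as exc:
        raise TrajectoryError(
            f"frame 0: cannot read {path.name} against a {n_expected}-atom "
            f"structure ({exc})"
        ) from exc

    solute_atoms = [structure.atoms[i] for i in layout.solute_index]
    species: dict[str, SolventSpecies] = {}
    for name in layout.species_order:
        idx = layout.species_index[name]
        records = [structure.atoms[i] for i in idx[0]]
        species[name] = SolventSpecies(
            name=name, atom_records=records, n_molecules=idx.shape[0]
        )

    frames: list[Frame] = []
    for f, ts in enumerate(_iter_frames(universe)):
        if ts.positions.shape[0] != n_expected:
            raise TrajectoryError(
                f"frame {f}: {ts.positions.shape[0]} atoms, expected {n_expected}"
            )
        coords = np.asarray(ts.positions, dtype=float)
        if ts.dimensions is not None and np.all(ts.dimensions[:3] > 0):
            frame_box = SimulationBox(np.asarray(ts.dimensions[:3], dtype=float))
        elif box is not None:
            frame_box = box
        elif structure.box is not None:
            frame_box = structure.box
        else:
            raise TrajectoryError(
                f"frame {f}: no box in file and none supplied"
            )
        solvent = {
            name: coords[layout.species_index[name]]
            for name in layout.species_order
        }
        frames.append(Frame(solute=coords[layout.solute_index],
                            solvent=solvent, box=frame_box))
    return SolvationSystem(solute_atoms=solute_atoms, species=species,
                           frames=frames)


# ---------------------------------------------------------------------------
# writing


def _flat_arrays(system: SolvationSystem, frame: Frame):
    """Flatten one frame to (names, resnames, resids, coords) in the
    canonical solute-first order."""
    names: list[str] = []
    resnames: list[str] = []
    resids: list[int] = []
    blocks: list[np.ndarray] = [frame.solute]
    for a in system.solute_atoms:
        names.append(a.atom_name)
        resnames.append(a.residue_name)
        resids.append(a.residue_index)
    next_resid = (max(resids) if resids else 0) + 1
    for sp_name in sorted(system.species):
        sp = system.species[sp_name]
        coords = frame.solvent[sp_name]
        blocks.append(coords.reshape(-1, 3))
        for mol in range(sp.n_molecules):
            for a in sp.atom_records:
                names.append(a.atom_name)
                resnames.append(a.residue_name)
                resids.append(next_resid)
            next_resid += 1
    return names, resnames, resids, np.concatenate(blocks, axis=0)


def _universe_for(system: SolvationSystem) -> "mda.Universe":
    names, resnames, resids, coords = _flat_arrays(system, system.frames[0])
    n_atoms = coords.shape[0]
    # one residue per distinct resid, in order of appearance
    resid_arr = np.array(resids)
    _, res_first = np.unique(resid_arr, return_index=True)
    res_order = resid_arr[np.sort(res_first)]
    res_pos = {r: i for i, r in enumerate(res_order)}
    atom_resindex = np.array([res_pos[r] for r in resid_arr])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        universe = mda.Universe.empty(
            n_atoms, n_residues=len(res_order), atom_resindex=atom_resindex,
            trajectory=True,
        )
        universe.add_TopologyAttr("names", names)
        universe.add_TopologyAttr("resids", res_order)
        universe.add_TopologyAttr(
            "resnames",
            [resnames[resid_arr.tolist().index(r)] for r in res_order],
        )
    universe.atoms.positions = coords.astype(np.float32)
    lengths = system.frames[0].box.lengths
    universe.dimensions = [*lengths, 90.0, 90.0, 90.0]
    return universe


def write_structure(system: SolvationSystem, path: str | pathlib.Path) -> None:
    """Write the first frame as PDB or GRO (by extension)."""
    universe = _universe_for(system)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        universe.atoms.write(str(path))


def write_trajectory(system: SolvationSystem, path: str | pathlib.Path) -> None:
    """Write all frames as XYZ, DCD or XTC (by extension)."""
    universe = _universe_for(system)
    fmt = _infer_format(path, TRAJECTORY_FORMATS)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.Writer(str(path), n_atoms=universe.atoms.n_atoms, format=fmt) as w:
            for frame in system.frames:
                _, _, _, coords = _flat_arrays(system, frame)
                universe.atoms.positions = coords.astype(np.float32)
                universe.dimensions = [*frame.box.lengths, 90.0, 90.0, 90.0]
                w.write(universe.atoms)


def write_fixture(
    system: SolvationSystem,
    outdir: str | pathlib.Path,
    trajectory_format: str = "XYZ",
) -> pathlib.Path:
    """Write structure (PDB) + trajectory + YAML manifest into a directory."""
    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    structure_path = outdir / "structure.pdb"
    traj_path = outdir / f"trajectory.{trajectory_format.lower()}"
    write_structure(system, structure_path)
    write_trajectory(system, traj_path)
    manifest = {
        "structure": structure_path.name,
        "trajectory": traj_path.name,
        "box_lengths": [float(x) for x in system.frames[0].box.lengths],
        "n_frames": system.n_frames,
        "n_solute_atoms": system.n_solute_atoms,
        "species": {
            name: {
                "residue_name": sp.atom_records[0].residue_name,
                "n_molecules": sp.n_molecules,
                "atoms_per_molecule": sp.atoms_per_molecule,
            }
            for name, sp in system.species.items()
        },
    }
    manifest_path = outdir / "manifest.yaml"
    with open(manifest_path, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return manifest_path


def read_fixture(manifest_path: str | pathlib.Path) -> SolvationSystem:
    """Round-trip loader for fixtures written by :func:`write_fixture`."""
    manifest_path = pathlib.Path(manifest_path)
    manifest = yaml.safe_load(open(manifest_path))
    base = manifest_path.parent
    box = SimulationBox(np.array(manifest["box_lengths"], dtype=float))
    structure = read_structure(
        base / manifest["structure"],
        solvent_resnames={s["residue_name"] for s in manifest["species"].values()},
    )
    species_resnames = {
        name: spec["residue_name"] for name, spec in manifest["species"].items()
    }
    return read_trajectory(
        base / manifest["trajectory"], structure, species_resnames, box=box
    )
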