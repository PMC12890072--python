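"""Residue/atom classification tables.

The tables below drive the assignment of :class:`~solvkb.model.Role` and
:class:`~solvkb.model.PolarityClass` when structures are read.  They are
deliberately plain module-level data so that callers can pass overriding
tables: the grouping of residues into charged / polar-uncharged /
nonpolar classes is a convention, not a physical constant.

Histidine is classified as polar-uncharged by default; the explicitly
protonated variants (HIP/HSP) are charged.  ``his_charged=True`` moves
all histidine variants to the charged class.
"""

from __future__ import annotations

import warnings

from .model import AtomRecord, PolarityClass, Role

#: Backbone atom names of a protein residue (PDB v3 naming).
BACKBONE_ATOMS = {
    "N", "CA", "C", "O", "H", "HN", "HA", "HA2", "HA3",
    "OXT", "OT1", "OT2", "H1", "H2", "H3",
}

#: Residue names recognised as water.
WATER_RESIDUES = {"HOH", "SOL", "WAT", "TIP3", "TIP4", "TIP5", "SPC", "T3P", "T4P"}

#: Charged side chains (His only when protonated, see module docstring).
CHARGED_RESIDUES = {"ASP", "GLU", "LYS", "ARG", "HIP", "HSP"}

#: Polar but uncharged side chains.
POLAR_UNCHARGED_RESIDUES = {
    "SER", "THR", "ASN", "GLN", "TYR", "CYS",
    "HIS", "HID", "HIE", "HSD", "HSE",
}

#: Nonpolar side chains.
NONPOLAR_RESIDUES = {
    "ALA", "VAL", "LEU", "ILE", "MET", "PHE", "TRP", "PRO", "GLY",
}

_HIS_VARIANTS = {"HIS", "HID", "HIE", "HSD", "HSE", "HIP", "HSP"}

STANDARD_RESIDUES = CHARGED_RESIDUES | POLAR_UNCHARGED_RESIDUES | NONPOLAR_RESIDUES


def residue_polarity(residue_name: str, his_charged: bool = False) -> PolarityClass:
    """Polarity class of a residue by name; NA (with a warning) if unknown."""
    name = residue_name.upper()
    if his_charged and name in _HIS_VARIANTS:
        return PolarityClass.POLAR_CHARGED
    if name in CHARGED_RESIDUES:
        return PolarityClass.POLAR_CHARGED
    if name in POLAR_UNCHARGED_RESIDUES:
        return PolarityClass.POLAR_UNCHARGED
    if name in NONPOLAR_RESIDUES:
        return PolarityClass.NONPOLAR
    warnings.warn(
        f"unknown residue {residue_name!r}: polarity_class set to n/a",
        stacklevel=2,
    )
    return PolarityClass.NA


def guess_element(atom_name: str) -> str:
    """Guess the element from a PDB-style atom name."""
    stripped = atom_name.strip()
    if not stripped:
        return "X"
    if stripped[0].isdigit():  # e.g. 1H, 2HB
        stripped = stripped.lstrip("0123456789")
    two = stripped[:2].upper()
    if two in {"CL", "BR", "NA", "MG", "ZN", "FE", "CA"} and len(stripped) == 2:
        return two.capitalize()
    return stripped[0].upper()


def classify_atom(
    atom_name: str,
    residue_name: str,
    residue_index: int,
    is_solvent: bool,
    his_charged: bool = False,
    element: str | None = None,
) -> AtomRecord:
    """Build an :class:`AtomRecord` with role and polarity assigned from tables."""
    name = atom_name.strip()
    if is_solvent:
        role = Role.SOLVENT
        polarity = PolarityClass.NA
    else:
        role = Role.BACKBONE if name.upper() in BACKBONE_ATOMS else Role.SIDECHAIN
        polarity = residue_polarity(residue_name, his_charged=his_charged)
    return AtomRecord(
        atom_name=name,
        element=element or guess_element(name),
        residue_index=int(residue_index),
        residue_name=residue_name.strip(),
        role=role,
        polarity_class=polarity,
    )
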