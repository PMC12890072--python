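"""Toy polyalanine backbone builder at ideal dihedral angles.

Builds N, H, CA, C, O backbone atoms with standard bond lengths and
angles via internal-coordinate (NeRF) placement.  Two conformations are
supported: an ideal alpha helix (phi = -57 deg, psi = -47 deg) and a
fully extended chain (phi = psi = 180 deg).  The construction is the
fixture for secondary-structure assignment: in the helix every
O(i)...H(i+4) pair sits at hydrogen-bonding distance, in the extended
chain none does.
"""

from __future__ import annotations

import numpy as np

from .model import AtomRecord, PolarityClass, Role

# standard backbone geometry (Engh-Huber-like values), Å and degrees
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.229
BOND_N_H = 1.00
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.8
OMEGA = 180.0

CONFORMATIONS = {
    "alpha_helix": (-57.0, -47.0),
    "extended": (180.0, 180.0),
}


def _place(a: np.ndarray, b: np.ndarray, c: np.ndarray,
           bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Place atom D given A-B-C with bond |CD|, angle BCD and torsion ABCD."""
    ang = np.radians(angle_deg)
    tor = np.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array(
        [-bond * np.cos(ang), bond * np.sin(ang) * np.cos(tor),
         bond * np.sin(ang) * np.sin(tor)]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def gen_toy_peptide(
    n_residues: int, conformation: str = "alpha_helix"
) -> tuple[list[AtomRecord], np.ndarray]:
    """Polyalanine backbone (N, H, CA, C, O per residue) at ideal dihedrals.

    Returns the atom records (1-based residue numbering) and an
    ``(5 * n_residues, 3)`` coordinate array in Å.

    Raises
    ------
    ValueError
        If ``n_residues < 5`` — no i -> i+4 hydrogen bond is possible,
        so no helix could ever be assigned.
    """
    if n_residues < 5:
        raise ValueError(
            "need at least 5 residues for an i -> i+4 hydrogen bond"
        )
    if conformation not in CONFORMATIONS:
        raise ValueError(f"unknown conformation {conformation!r}")
    phi, psi = CONFORMATIONS[conformation]

    N = np.zeros((n_residues, 3))
    CA = np.zeros((n_residues, 3))
    C = np.zeros((n_residues, 3))

    N[0] = (0.0, 0.0, 0.0)
    CA[0] = (BOND_N_CA, 0.0, 0.0)
    theta = np.radians(ANGLE_N_CA_C)
    CA_to_N = np.array([-1.0, 0.0, 0.0])
    direction = np.cos(theta) * CA_to_N + np.sin(theta) * np.array([0.0, 1.0, 0.0])
    C[0] = CA[0] + BOND_CA_C * direction

    for i in range(1, n_residues):
        N[i] = _place(N[i - 1], CA[i - 1], C[i - 1], BOND_C_N, ANGLE_CA_C_N, psi)
        CA[i] = _place(CA[i - 1], C[i - 1], N[i], BOND_N_CA, ANGLE_C_N_CA, OMEGA)
        C[i] = _place(C[i - 1], N[i], CA[i], BOND_CA_C, ANGLE_N_CA_C, phi)

    O = np.zeros((n_residues, 3))
    H = np.zeros((n_residues, 3))
    for i in range(n_residues):
        O[i] = _place(N[i], CA[i], C[i], BOND_C_O, ANGLE_CA_C_O, psi + 180.0)
        if i == 0:
            # no preceding carbonyl: point H away from CA and C
            u = N[i] - CA[i]
            v = N[i] - C[i]
            h_dir = u / np.linalg.norm(u) + v / np.linalg.norm(v)
        else:
            # in-plane, opposite the bisector of C(i-1)-N-CA
            u = N[i] - C[i - 1]
            v = N[i] - CA[i]
            h_dir = u / np.linalg.norm(u) + v / np.linalg.norm(v)
        H[i] = N[i] + BOND_N_H * h_dir / np.linalg.norm(h_dir)

    atoms: list[AtomRecord] = []
    coords: list[np.ndarray] = []
    for i in range(n_residues):
        for name, xyz in (("N", N[i]), ("H", H[i]), ("CA", CA[i]),
                          ("C", C[i]), ("O", O[i])):
            atoms.append(
                AtomRecord(name, "H" if name == "H" else name[0], i + 1, "ALA",
                           Role.BACKBONE, PolarityClass.NONPOLAR)
            )
            coords.append(xyz)
    return atoms, np.array(coords)
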