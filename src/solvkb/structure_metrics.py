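"""Helix assignment, hydrogen-bond counting and convergence diagnostics.

Secondary structure is assigned with the Kabsch-Sander electrostatic
hydrogen-bond model restricted to the alpha-helix class: a backbone
hydrogen bond between the carbonyl of residue i and the amide of
residue j exists when

    E = 0.084 * 332 * (1/r_ON + 1/r_CH - 1/r_OH - 1/r_CN)  kcal/mol

is below -0.5 kcal/mol; residue r is alpha-helical when it lies in the
span of two consecutive i -> i+4 turns (the minimal-helix rule).  3-10
and pi helices and strands are deliberately reported as "not alpha".

Convergence of ensemble averages over correlated series is assessed by
block averaging: the standard error of block means grows with block
size until blocks exceed the correlation time, and the plateau value
estimates the true standard error of the mean.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .geometry import min_image_displacement, min_image_distance
from .model import AtomRecord, Frame, SimulationBox, SolvationSystem

KS_COUPLING = 0.084 * 332.0  # kcal/mol * Å, Kabsch-Sander q1*q2*f
KS_CUTOFF = -0.5  # kcal/mol


@dataclass(frozen=True)
class HBondCriterion:
    """Geometric hydrogen-bond criterion (defaults are a common convention)."""

    max_da_distance: float = 3.5  # donor-acceptor, Å
    min_dha_angle: float = 150.0  # donor-hydrogen-acceptor, degrees

    def __post_init__(self) -> None:
        if self.max_da_distance <= 0:
            raise ValueError("max_da_distance must be positive")
        if not 0 < self.min_dha_angle <= 180:
            raise ValueError("min_dha_angle must lie in (0, 180]")


@dataclass
class HelixProfile:
    """Per-frame and per-residue alpha-helix statistics."""

    assignment: np.ndarray  # (n_frames, n_residues) bool
    assignable: np.ndarray  # (n_residues,) bool
    per_frame_fraction: np.ndarray  # (n_frames,)
    per_residue_fraction: np.ndarray  # (n_residues,)
    residue_labels: list[str]

    def fraction_histogram(self, bins: int = 20) -> tuple[np.ndarray, np.ndarray]:
        return np.histogram(self.per_frame_fraction, bins=bins, range=(0.0, 1.0))


@dataclass
class BlockAverageResult:
    """Standard error of the mean versus block size, with plateau estimate."""

    block_sizes: np.ndarray
    se: np.ndarray
    naive_se: float
    plateau_se: float
    plateau_block: int
    statistical_inefficiency: float  # (plateau_se / naive_se)^2


def _backbone_map(atoms: list[AtomRecord]) -> dict[int, dict[str, int]]:
    out: dict[int, dict[str, int]] = {}
    for i, a in enumerate(atoms):
        out.setdefault(a.residue_index, {})[a.atom_name.upper()] = i
    return out


def _reconstruct_amide_h(n: np.ndarray, ca: np.ndarray, c_prev: np.ndarray) -> np.ndarray:
    """Amide H along the bisector opposite C(i-1)-N-CA, 1.0 Å from N."""
    u = n - c_prev
    v = n - ca
    u /= np.linalg.norm(u)
    v /= np.linalg.norm(v)
    h = u + v
    return n + h / np.linalg.norm(h)


def ks_hbond_energy(o: np.ndarray, c: np.ndarray, n: np.ndarray, h: np.ndarray) -> float:
    """Kabsch-Sander electrostatic energy (kcal/mol) of one C=O...H-N contact."""
    r_on = np.linalg.norm(o - n)
    r_ch = np.linalg.norm(c - h)
    r_oh = np.linalg.norm(o - h)
    r_cn = np.linalg.norm(c - n)
    if min(r_on, r_ch, r_oh, r_cn) < 1e-3:
        return -np.inf
    return KS_COUPLING * (1.0 / r_on + 1.0 / r_ch - 1.0 / r_oh - 1.0 / r_cn)


def assign_helix(
    coords: np.ndarray,
    solute_atoms: list[AtomRecord],
) -> tuple[np.ndarray, np.ndarray]:
    """Alpha-helix assignment of each residue for one frame.

    Returns ``(is_helix, assignable)`` boolean arrays over the sorted
    residue indices.  A residue lacking N/CA/C/O backbone atoms is
    unassignable; a missing amide H is reconstructed from N, CA and the
    preceding carbonyl C.
    """
    coords = np.asarray(coords, dtype=float)
    bb = _backbone_map(solute_atoms)
    residues = sorted(bb)
    n_res = len(residues)
    pos = {r: i for i, r in enumerate(residues)}

    assignable = np.zeros(n_res, dtype=bool)
    N = np.full((n_res, 3), np.nan)
    CA = np.full((n_res, 3), np.nan)
    C = np.full((n_res, 3), np.nan)
    O = np.full((n_res, 3), np.nan)
    H = np.full((n_res, 3), np.nan)
    for r in residues:
        i = pos[r]
        names = bb[r]
        if not {"N", "CA", "C", "O"} <= names.keys():
            continue
        assignable[i] = True
        N[i] = coords[names["N"]]
        CA[i] = coords[names["CA"]]
        C[i] = coords[names["C"]]
        O[i] = coords[names["O"]]
        if "H" in names:
            H[i] = coords[names["H"]]
        elif "HN" in names:
            H[i] = coords[names["HN"]]
    for i in range(1, n_res):
        if assignable[i] and assignable[i - 1] and np.isnan(H[i]).any():
            H[i] = _reconstruct_amide_h(N[i], CA[i], C[i - 1])

    # i -> i+4 turns: C=O of residue at slot i bonded to N-H of slot i+4
    turn = np.zeros(n_res, dtype=bool)
    for i in range(n_res - 4):
        j = i + 4
        if not (assignable[i] and assignable[j]) or np.isnan(H[j]).any():
            continue
        if residues[j] - residues[i] != 4:  # chain break in numbering
            continue
        turn[i] = ks_hbond_energy(O[i], C[i], N[j], H[j]) < KS_CUTOFF

    is_helix = np.zeros(n_res, dtype=bool)
    for i in range(1, n_res - 4):
        if turn[i - 1] and turn[i]:
            is_helix[i:i + 4] = True
    return is_helix, assignable


def helix_content(system: SolvationSystem) -> HelixProfile:
    """Helix assignment over all frames plus per-frame/per-residue fractions.

    Fractions are over assignable residues, so the mean per-frame
    fraction equals the assignable-residue-weighted mean of the
    per-residue fractions exactly.
    """
    first, assignable = assign_helix(system.frames[0].solute, system.solute_atoms)
    n_res = first.size
    matrix = np.zeros((system.n_frames, n_res), dtype=bool)
    matrix[0] = first
    for f in range(1, system.n_frames):
        matrix[f], _ = assign_helix(system.frames[f].solute, system.solute_atoms)
    n_assignable = max(int(assignable.sum()), 1)
    per_frame = matrix.sum(axis=1) / n_assignable
    per_residue = matrix.mean(axis=0)
    return HelixProfile(
        assignment=matrix,
        assignable=assignable,
        per_frame_fraction=per_frame,
        per_residue_fraction=per_residue,
        residue_labels=system.residue_labels(),
    )


def _attached_hydrogens(
    coords: np.ndarray,
    atoms: list[AtomRecord],
    donors: np.ndarray,
    box: SimulationBox,
    max_bond: float = 1.25,
) -> dict[int, list[int]]:
    h_idx = np.array([i for i, a in enumerate(atoms) if a.element.upper() == "H"],
                     dtype=int)
    out: dict[int, list[int]] = {}
    for d in donors:
        if h_idx.size == 0:
            out[int(d)] = []
            continue
        dists = min_image_distance(coords[d], coords[h_idx], box)
        out[int(d)] = [int(h) for h, r in zip(h_idx, dists) if r <= max_bond]
    return out


def count_hbonds(
    system: SolvationSystem,
    donor_selection: str,
    acceptor_selection: str,
    criterion: HBondCriterion | None = None,
) -> tuple[np.ndarray, float, float]:
    """Hydrogen bonds per frame between donor and acceptor solute atoms.

    Donors are heavy atoms; their hydrogens are located by covalent
    distance (<= 1.25 Å) in each frame.  Donors without any hydrogen are
    excluded with a warning.  Returns the per-frame integer counts, the
    mean and a block-averaged standard error of the mean.
    """
    from .selection import select_atoms

    criterion = criterion or HBondCriterion()
    donors = np.array(select_atoms(system.solute_atoms, donor_selection), dtype=int)
    acceptors = np.array(select_atoms(system.solute_atoms, acceptor_selection),
                         dtype=int)
    if donors.size == 0 or acceptors.size == 0:
        raise ValueError("empty donor or acceptor selection")
    heavy = [d for d in donors if system.solute_atoms[d].element.upper() != "H"]
    donors = np.array(heavy, dtype=int)

    counts = np.zeros(system.n_frames, dtype=int)
    warned: set[int] = set()
    cos_min = np.cos(np.radians(criterion.min_dha_angle))
    for f, frame in enumerate(system.frames):
        coords = frame.solute
        h_of = _attached_hydrogens(coords, system.solute_atoms, donors, frame.box)
        n = 0
        for d in donors:
            hs = h_of[int(d)]
            if not hs:
                if int(d) not in warned:
                    warnings.warn(
                        f"donor atom {int(d)} has no attached hydrogen; excluded",
                        stacklevel=2,
                    )
                    warned.add(int(d))
                continue
            for a in acceptors:
                if a == d or a in hs:
                    continue
                r_da = float(min_image_distance(coords[d], coords[a], frame.box))
                if r_da > criterion.max_da_distance:
                    continue
                for h in hs:
                    dh = min_image_displacement(coords[h] - coords[d],
                                                frame.box.lengths)
                    ha = min_image_displacement(coords[a] - coords[h],
                                                frame.box.lengths)
                    # angle D-H...A: 180 deg when collinear
                    cos_dha = -float(
                        np.dot(dh, ha) / (np.linalg.norm(dh) * np.linalg.norm(ha))
                    )
                    # bond if angle >= min_dha_angle, i.e. cos(angle) <= cos_min
                    if cos_dha <= cos_min:
                        n += 1
                        break
        counts[f] = n
    mean = float(counts.mean())
    if counts.size >= 16:
        se = block_average(counts.astype(float)).plateau_se
    else:
        se = float(counts.std(ddof=1) / np.sqrt(counts.size)) if counts.size > 1 else 0.0
    return counts, mean, se


def statistical_inefficiency(series: np.ndarray, c: float = 5.0) -> float:
    """Statistical inefficiency g = 1 + 2 sum_k rho(k) by self-consistent window.

    The autocorrelation sum is truncated at the smallest lag W >= c * g/2
    (Sokal's windowing rule), trading a small truncation bias against
    the noise of summing the ACF tail.  Returns at least 1.
    """
    series = np.asarray(series, dtype=float)
    n = series.size
    if n < 4 or series.std() == 0:
        return 1.0
    rho = autocorrelation(series, min(n // 2 - 1, 4000))
    g = 1.0
    for w in range(1, rho.size):
        g = 1.0 + 2.0 * float(rho[1:w + 1].sum())
        if w >= c * max(g, 1.0) / 2.0:
            break
    return max(g, 1.0)


def block_average(series: np.ndarray) -> BlockAverageResult:
    """Standard error of the mean of a correlated series by block averaging.

    The SE of block means is tabulated for dyadic block sizes while at
    least 16 blocks remain.  Individual block estimates at large block
    sizes are noisy (few blocks), so the plateau is located through the
    statistical inefficiency g estimated from the autocorrelation
    function: the plateau SE is naive_se * sqrt(g), and plateau_block is
    the smallest tabulated block size exceeding ~2.5 g (blocks longer
    than the correlation time), at which the tabulated SE agrees with
    the plateau up to block-count noise.
    """
    series = np.asarray(series, dtype=float)
    if series.ndim != 1:
        raise ValueError("series must be one-dimensional")
    n = series.size
    if n < 16:
        raise ValueError("series must contain at least 16 points")
    naive = float(series.std(ddof=1) / np.sqrt(n))

    sizes: list[int] = []
    ses: list[float] = []
    b = 1
    while n // b >= 16:
        k = n // b
        blocks = series[: k * b].reshape(k, b).mean(axis=1)
        sizes.append(b)
        ses.append(float(blocks.std(ddof=1) / np.sqrt(k)))
        b *= 2
    sizes_arr = np.array(sizes)
    se_arr = np.array(ses)

    g = statistical_inefficiency(series)
    plateau = naive * float(np.sqrt(g))
    above = sizes_arr[sizes_arr >= 2.5 * g]
    plateau_block = int(above[0]) if above.size else int(sizes_arr[-1])
    return BlockAverageResult(
        block_sizes=sizes_arr,
        se=se_arr,
        naive_se=naive,
        plateau_se=plateau,
        plateau_block=plateau_block,
        statistical_inefficiency=float(g),
    )


def autocorrelation(series: np.ndarray, max_lag: int) -> np.ndarray:
    """Normalised autocorrelation function, biased (1/n) estimator.

    ``acf[0] == 1``; requires ``max_lag < n / 2``.
    """
    series = np.asarray(series, dtype=float)
    n = series.size
    if max_lag >= n // 2:
        raise ValueError("max_lag must be below half the series length")
    x = series - series.mean()
    var = float(np.dot(x, x) / n)
    if var == 0:
        out = np.zeros(max_lag + 1)
        out[0] = 1.0
        return out
    # FFT-based full autocovariance, biased normalisation
    size = 1 << (2 * n - 1).bit_length()
    fx = np.fft.rfft(x, size)
    acov = np.fft.irfft(fx * np.conj(fx), size)[: max_lag + 1] / n
    return acov / var
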