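"""Minimum-distance distribution functions (MDDFs) and their decomposition.

The MDDF g(r) of a solvent species around a solute is the ratio between
the observed number of solvent molecules whose *minimum* distance to the
solute falls in each distance bin, and the same count for an ideal-gas
reference in which the species is randomly re-inserted (uniform position
and orientation, internal geometry preserved) into the same box:

    g(r) = n(r) / n*(r)

Here r is the minimum distance between any solute atom and any atom of
the solvent molecule, so a single distribution captures solvation of an
arbitrarily shaped solute without an orientational average.  Counts are
accumulated in half-open bins [left, right) of constant width over
[0, r_max]; events at or beyond r_max are discarded.

Because each per-molecule event is realized by a specific (solute atom,
solvent atom) pair, the observed histogram decomposes exactly into
contributions of atom groups: a group's contribution collects the events
whose realizing atom belongs to it, so any exhaustive partition of
either side sums bin-by-bin to the total.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import molecule_min_distances, place_rigid
from .model import AnalysisConfig, Frame, SolvationSystem
from .selection import select_atoms
from .synth import species_template


@dataclass
class MDDFResult:
    """Binned observed/reference minimum-distance counts and their ratio."""

    species: str
    bin_edges: np.ndarray  # (n_bins + 1,)
    observed_counts: np.ndarray  # mean counts per frame per bin
    reference_counts: np.ndarray  # mean ideal counts per frame per bin
    g: np.ndarray  # observed / reference, NaN where undefined
    undefined: np.ndarray  # bool mask: reference bin empty
    n_frames: int
    config: AnalysisConfig
    solute_indices: tuple[int, ...]
    # per-frame histograms, kept for KBI cumulative sums and error bars
    obs_frames: np.ndarray = field(repr=False, default=None)  # (F, n_bins)
    ref_frames: np.ndarray = field(repr=False, default=None)  # (F, n_bins)

    @property
    def r_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def mean_g(self, r_lo: float, r_hi: float) -> float:
        """Mean of g over the defined bins whose centers lie in [r_lo, r_hi]."""
        r = self.r_centers
        mask = (r >= r_lo) & (r <= r_hi) & ~self.undefined
        if not mask.any():
            raise ValueError("no defined bins in the requested range")
        return float(np.mean(self.g[mask]))


@dataclass
class ContributionSet:
    """Per-group shares of the observed minimum-distance counts."""

    species: str
    side: str  # "solute" or "solvent"
    bin_edges: np.ndarray
    contributions: dict[str, np.ndarray]  # group -> mean counts per frame per bin
    total: np.ndarray  # observed_counts of the parent MDDF
    reference_counts: np.ndarray
    overlapping: bool = False

    def g_contribution(self, group: str) -> np.ndarray:
        """Group contribution on the g scale (share of counts / reference)."""
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(
                self.reference_counts > 0,
                self.contributions[group] / self.reference_counts,
                np.nan,
            )


@dataclass
class ResidueDensityMap:
    """Residues x distance matrix of solvent density relative to bulk."""

    species: str
    residue_labels: list[str]
    bin_edges: np.ndarray
    density: np.ndarray  # (n_residues, n_bins), g-like scale
    counts: np.ndarray  # (n_residues, n_bins), mean observed counts per frame


def _template_for(system: SolvationSystem, species: str) -> np.ndarray:
    """Rigid re-insertion template: built-in toy geometry, else the first
    molecule of the first frame (assumed whole, i.e. not PBC-broken)."""
    try:
        return species_template(system.species[species])
    except ValueError:
        mol = system.frames[0].solvent[species][0]
        return mol - mol.mean(axis=0)


def _solute_indices(system: SolvationSystem, config: AnalysisConfig,
                    solute_selection: str | None) -> tuple[int, ...]:
    if solute_selection is not None:
        idx = select_atoms(system.solute_atoms, solute_selection)
    else:
        idx = tuple(range(len(system.solute_atoms)))
    if not config.include_solute_hydrogens:
        idx = tuple(i for i in idx if system.solute_atoms[i].element.upper() != "H")
    if not idx:
        raise ValueError("empty solute selection")
    return idx


def min_distances(
    frame: Frame,
    species: str,
    solute_selection: np.ndarray | tuple[int, ...] | None = None,
):
    """Per-molecule minimum distance and realizing atom pair for one frame.

    Returns ``(dmin, solute_atom_idx, solvent_atom_idx)``; solute indices
    refer to the original solute atom numbering even under a selection.
    Ties are broken by lowest (solute index, solvent atom index).
    """
    if species not in frame.solvent:
        raise KeyError(f"species {species!r} not present in frame")
    coords = frame.solvent[species]
    if coords.shape[0] == 0:
        raise ValueError(f"species {species!r} has zero molecules")
    if solute_selection is None:
        solute = frame.solute
        back = None
    else:
        sel = np.asarray(solute_selection, dtype=int)
        if sel.size == 0:
            raise ValueError("empty solute selection")
        solute = frame.solute[sel]
        back = sel
    dmin, s_idx, a_idx = molecule_min_distances(solute, coords, frame.box,
                                                return_pairs=True)
    if back is not None:
        s_idx = back[s_idx]
    return dmin, s_idx, a_idx


def reference_counts(
    frame: Frame,
    species_name: str,
    template: np.ndarray,
    config: AnalysisConfig,
    solute_indices: tuple[int, ...],
    rng: np.random.Generator,
) -> np.ndarray:
    """Ideal-gas reference histogram for one frame.

    ``nu * n_molecules`` rigid random re-insertions of the species into
    the frame's box, minimum distances binned and scaled by ``1 / nu``,
    so the expectation matches a single ideal-gas realisation of the
    same molecule count while the variance is reduced ``nu``-fold.
    """
    n_mol = frame.solvent[species_name].shape[0]
    nu = config.reference_oversampling
    placed = place_rigid(template, nu * n_mol, frame.box, rng)
    solute = frame.solute[np.asarray(solute_indices, dtype=int)]
    dmin = molecule_min_distances(solute, placed, frame.box)
    hist, _ = np.histogram(dmin, bins=config.bin_edges())
    return hist / nu


def compute_mddf(
    system: SolvationSystem,
    species: str,
    config: AnalysisConfig | None = None,
    solute_selection: str | None = None,
) -> MDDFResult:
    """Accumulate observed and reference histograms over all frames.

    Bins where the reference histogram is empty are flagged undefined
    (g = NaN there), never reported as zero.
    """
    config = config or AnalysisConfig()
    if species not in system.species:
        raise KeyError(f"unknown species {species!r}")
    if system.species[species].n_molecules == 0:
        raise ValueError(f"species {species!r} has zero molecules")
    sol_idx = _solute_indices(system, config, solute_selection)
    template = _template_for(system, species)
    edges = config.bin_edges()
    n_bins = config.n_bins
    n_frames = system.n_frames

    obs = np.zeros((n_frames, n_bins))
    ref = np.zeros((n_frames, n_bins))
    sel = np.asarray(sol_idx, dtype=int)
    for f, frame in enumerate(system.frames):
        dmin, _, _ = min_distances(frame, species, sel)
        obs[f], _ = np.histogram(dmin, bins=edges)
        rng = np.random.default_rng([config.seed & 0x7FFFFFFF, f])
        ref[f] = reference_counts(frame, species, template, config, sol_idx, rng)

    obs_mean = obs.mean(axis=0)
    ref_mean = ref.mean(axis=0)
    undefined = ref_mean <= 0
    with np.errstate(divide="ignore", invalid="ignore"):
        g = np.where(undefined, np.nan, obs_mean / ref_mean)
    return MDDFResult(
        species=species,
        bin_edges=edges,
        observed_counts=obs_mean,
        reference_counts=ref_mean,
        g=g,
        undefined=undefined,
        n_frames=n_frames,
        config=config,
        solute_indices=sol_idx,
        obs_frames=obs,
        ref_frames=ref,
    )


def decompose(
    mddf_result: MDDFResult,
    system: SolvationSystem,
    groups: dict[str, str],
    side: str = "solute",
    allow_overlap: bool = False,
) -> ContributionSet:
    """Attribute each minimum-distance event to the group of its realizing atom.

    ``groups`` maps labels to selection expressions over the solute atoms
    (``side="solute"``) or over the species' per-molecule atom records
    (``side="solvent"``).  With an exhaustive partition the per-bin sums
    of the contributions reproduce the total observed counts exactly.
    Overlapping groups raise unless ``allow_overlap`` (sums may then
    exceed the total; the result is flagged).
    """
    if side not in ("solute", "solvent"):
        raise ValueError("side must be 'solute' or 'solvent'")
    species = mddf_result.species
    config = mddf_result.config
    if side == "solute":
        atom_pool = system.solute_atoms
    else:
        atom_pool = system.species[species].atom_records
    group_indices = {name: set(select_atoms(atom_pool, sel))
                     for name, sel in groups.items()}
    names = list(group_indices)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            common = group_indices[a] & group_indices[b]
            if common and not allow_overlap:
                raise ValueError(
                    f"groups {a!r} and {b!r} overlap on atoms {sorted(common)[:5]}"
                )
    overlapping = any(
        group_indices[a] & group_indices[b]
        for i, a in enumerate(names) for b in names[i + 1:]
    )

    edges = mddf_result.bin_edges
    sel = np.asarray(mddf_result.solute_indices, dtype=int)
    contrib = {name: np.zeros(config.n_bins) for name in groups}
    for frame in system.frames:
        dmin, s_idx, a_idx = min_distances(frame, species, sel)
        realizing = s_idx if side == "solute" else a_idx
        for name, idx_set in group_indices.items():
            if not idx_set:
                continue
            mask = np.isin(realizing, list(idx_set))
            hist, _ = np.histogram(dmin[mask], bins=edges)
            contrib[name] += hist
    for name in contrib:
        contrib[name] /= system.n_frames
    return ContributionSet(
        species=species,
        side=side,
        bin_edges=edges,
        contributions=contrib,
        total=mddf_result.observed_counts,
        reference_counts=mddf_result.reference_counts,
        overlapping=overlapping,
    )


def residue_density_map(
    system: SolvationSystem,
    species: str,
    config: AnalysisConfig | None = None,
    mddf_result: MDDFResult | None = None,
) -> ResidueDensityMap:
    """Solvent density around each solute residue versus minimum distance.

    Each minimum-distance event is attributed to the solute residue of
    its realizing atom.  Rows are normalised by the total ideal-gas
    reference scaled by a uniform per-residue share, so a residue
    contacted at the ensemble-average rate of an interaction-free system
    would show a density of about 1 at every distance.
    """
    config = config or AnalysisConfig()
    if mddf_result is None:
        mddf_result = compute_mddf(system, species, config)
    res_of_atom = system.residue_indices()
    unique_res = np.array(sorted(set(res_of_atom.tolist())))
    n_res = unique_res.size
    row_of = {r: i for i, r in enumerate(unique_res.tolist())}

    counts = np.zeros((n_res, config.n_bins))
    edges = mddf_result.bin_edges
    sel = np.asarray(mddf_result.solute_indices, dtype=int)
    for frame in system.frames:
        dmin, s_idx, _ = min_distances(frame, species, sel)
        rows = np.array([row_of[r] for r in res_of_atom[s_idx]])
        for row in range(n_res):
            mask = rows == row
            if mask.any():
                hist, _ = np.histogram(dmin[mask], bins=edges)
                counts[row] += hist
    counts /= system.n_frames

    share = mddf_result.reference_counts / n_res
    with np.errstate(divide="ignore", invalid="ignore"):
        density = np.where(share > 0, counts / share, 0.0)
    return ResidueDensityMap(
        species=species,
        residue_labels=system.residue_labels(),
        bin_edges=edges,
        density=density,
        counts=counts,
    )
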