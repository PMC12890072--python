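"""Minimum-distance kernels, MDDF normalisation, decomposition, maps."""

import numpy as np
import pytest

from conftest import brute_force_min_distance
from solvkb.mddf import (
    compute_mddf,
    decompose,
    min_distances,
    reference_counts,
    residue_density_map,
)
from solvkb.model import (
    AnalysisConfig,
    AtomRecord,
    Frame,
    PolarityClass,
    Role,
    SimulationBox,
    SolvationSystem,
)
from solvkb.peptide import gen_toy_peptide
from solvkb.synth import (
    SyntheticModel,
    gen_solvent_ensemble,
    point_species,
    toy_cosolvent_species,
)


def _frame(solute, solvent, box_length=20.0):
    return Frame(solute=np.asarray(solute, float),
                 solvent={"water": np.asarray(solvent, float)},
                 box=SimulationBox.cubic(box_length))


class TestMinDistances:
    def test_hand_geometry_diatomic(self):
        frame = _frame([[0.0, 0.0, 0.0]],
                       [[[5.0, 0.0, 0.0], [6.0, 0.0, 0.0]]])
        d, s, a = min_distances(frame, "water")
        assert d[0] == pytest.approx(5.0, abs=1e-12)
        assert (s[0], a[0]) == (0, 0)

    def test_minimum_image_wraps_through_the_boundary(self):
        # 19 ≡ -1 in a 20 Å box: the far atom is the close one
        frame = _frame([[0.0, 0.0, 0.0]],
                       [[[18.0, 0.0, 0.0], [19.0, 0.0, 0.0]]])
        d, s, a = min_distances(frame, "water")
        assert d[0] == pytest.approx(1.0, abs=1e-12)
        assert (s[0], a[0]) == (0, 1)

    def test_matches_all_images_brute_force_on_random_systems(self):
        rng = np.random.default_rng(17)
        for _ in range(50):
            n_solute = rng.integers(1, 6)
            n_mol = rng.integers(1, 9)
            n_atoms = rng.integers(1, 4)
            length = rng.uniform(5.0, 15.0)
            solute = rng.uniform(0, length, (n_solute, 3))
            solvent = rng.uniform(0, length, (n_mol, n_atoms, 3))
            frame = _frame(solute, solvent, box_length=length)
            d, s, a = min_distances(frame, "water")
            for m in range(n_mol):
                bd, bs, ba = brute_force_min_distance(
                    solute, solvent[m], frame.box.lengths
                )
                assert d[m] == pytest.approx(bd, rel=1e-12)
                assert (s[m], a[m]) == (bs, ba)

    def test_empty_selection_rejected(self):
        frame = _frame([[0.0, 0.0, 0.0]], [[[5.0, 0.0, 0.0]]])
        with pytest.raises(ValueError):
            min_distances(frame, "water", solute_selection=np.array([], dtype=int))


class TestReferenceCounts:
    def test_ideal_shell_scaling_for_point_solute(self):
        # n*(r) proportional to 4 pi r^2 rho dr well inside the box
        box = SimulationBox.cubic(40.0)
        model = SyntheticModel("ideal_gas", density=0.02, seed=51)
        system = gen_solvent_ensemble(np.array([[20.0, 20.0, 20.0]]), box,
                                      model, n_frames=1)
        config = AnalysisConfig(bin_width=0.5, r_max=15.0, bulk_shell=(10, 15),
                                reference_oversampling=100, seed=3)
        rng = np.random.default_rng(12)
        counts = reference_counts(system.frames[0], "water", np.zeros((1, 3)),
                                  config, (0,), rng)
        edges = config.bin_edges()
        centers = 0.5 * (edges[:-1] + edges[1:])
        n_mol = system.species["water"].n_molecules
        expected = n_mol * 4 * np.pi * centers**2 * config.bin_width / box.volume
        sel = (centers > 4) & (centers < 12)
        rel = counts[sel] / expected[sel]
        assert abs(rel.mean() - 1) < 0.03
        # per-bin deviation bounded by 5 sigma of the oversampled counts
        sigma = 1.0 / np.sqrt(config.reference_oversampling * expected[sel])
        assert np.all(np.abs(rel - 1) < 5 * sigma + 0.01)

    def test_oversampling_preserves_expectation_and_cuts_variance(self):
        box = SimulationBox.cubic(20.0)
        model = SyntheticModel("ideal_gas", density=0.01, seed=52)
        system = gen_solvent_ensemble(np.array([[10.0, 10.0, 10.0]]), box,
                                      model, n_frames=1)
        edges_sel = slice(20, 60)  # bins within [2, 6] Å

        def total(nu, seed):
            config = AnalysisConfig(bin_width=0.1, r_max=10.0,
                                    bulk_shell=(6, 9),
                                    reference_oversampling=nu, seed=3)
            rng = np.random.default_rng(seed)
            c = reference_counts(system.frames[0], "water", np.zeros((1, 3)),
                                 config, (0,), rng)
            return c[edges_sel].sum()

        lo = np.array([total(1, s) for s in range(40)])
        hi = np.array([total(10, s) for s in range(40)])
        assert abs(lo.mean() - hi.mean()) < 3 * np.hypot(
            lo.std() / np.sqrt(40), hi.std() / np.sqrt(40)
        ) + 1e-9
        assert hi.std() < lo.std()


class TestComputeMddf:
    def test_ideal_gas_mddf_is_unity(self, ideal_gas_mddf):
        mean_g = ideal_gas_mddf.mean_g(2.0, 10.0)
        assert 0.97 < mean_g < 1.03

    def test_hard_wall_mddf_vanishes_inside_the_wall(self, hard_wall_mddf):
        r = hard_wall_mddf.r_centers
        inside = (r < 3.0) & ~hard_wall_mddf.undefined
        assert np.all(hard_wall_mddf.g[inside] == 0)

    def test_square_well_mddf_matches_boltzmann_oracle(self, square_well_mddf):
        assert square_well_mddf.mean_g(3.05, 3.95) == pytest.approx(np.e, rel=0.05)
        assert square_well_mddf.mean_g(5.0, 9.0) == pytest.approx(1.0, rel=0.03)

    def test_zero_reference_bins_flagged_not_zero(self):
        # a sparse single-frame system leaves the innermost bins without
        # any reference insertion: they must be NaN-flagged, never 0
        box = SimulationBox.cubic(30.0)
        model = SyntheticModel("ideal_gas", density=10 / box.volume, seed=55)
        system = gen_solvent_ensemble(np.array([[15.0, 15.0, 15.0]]), box,
                                      model, n_frames=1)
        config = AnalysisConfig(bin_width=0.1, r_max=10.0, bulk_shell=(6, 9),
                                reference_oversampling=1, seed=3)
        res = compute_mddf(system, "water", config)
        empty = res.reference_counts == 0
        assert empty.any()
        assert np.array_equal(res.undefined, empty)
        assert np.all(np.isnan(res.g[empty]))

    def test_invariant_under_rigid_motion_of_every_frame(self):
        from scipy.spatial.transform import Rotation

        box = SimulationBox.cubic(20.0)
        model = SyntheticModel("square_well", density=0.02, wall_distance=3.0,
                               well_depth=1.0, well_width=1.0, seed=61)
        system = gen_solvent_ensemble(np.array([[10.0, 10.0, 10.0]]), box,
                                      model, n_frames=10)
        config = AnalysisConfig(bin_width=0.2, r_max=9.0, bulk_shell=(6, 8.5),
                                reference_oversampling=2, seed=3)
        base = compute_mddf(system, "water", config)

        rot = Rotation.from_euler("z", 90, degrees=True)
        shift = np.array([3.0, -2.0, 5.0])
        moved_frames = []
        for frame in system.frames:
            moved_frames.append(Frame(
                solute=rot.apply(frame.solute) + shift,
                solvent={"water": rot.apply(
                    frame.solvent["water"].reshape(-1, 3)
                ).reshape(frame.solvent["water"].shape) + shift},
                box=box,
            ))
        moved = SolvationSystem(solute_atoms=system.solute_atoms,
                                species=system.species, frames=moved_frames)
        got = compute_mddf(moved, "water", config)
        # observed histograms identical (90-degree rotation + shift keeps
        # minimum-image distances exactly); references share the seed
        assert np.array_equal(base.obs_frames, got.obs_frames)

    def test_zero_molecule_species_rejected(self):
        atoms, xyz = gen_toy_peptide(5, "extended")
        box = SimulationBox.cubic(60.0)
        sp = point_species("water", n_molecules=0)
        system = SolvationSystem(
            solute_atoms=atoms, species={"water": sp},
            frames=[Frame(solute=xyz + 20.0,
                          solvent={"water": np.zeros((0, 1, 3))}, box=box)],
        )
        with pytest.raises(ValueError, match="zero molecules"):
            compute_mddf(system, "water")


@pytest.fixture(scope="module")
def cosolvent_system():
    """Two-residue solute, 3-atom cosolvent, short-range well."""
    atoms = [
        AtomRecord("C1", "C", 1, "LIG", Role.SIDECHAIN, PolarityClass.NONPOLAR),
        AtomRecord("C2", "C", 2, "LIG", Role.SIDECHAIN, PolarityClass.NONPOLAR),
    ]
    solute = np.array([[8.0, 10.0, 10.0], [12.0, 10.0, 10.0]])
    box = SimulationBox.cubic(20.0)
    model = SyntheticModel("square_well", density=0.02, wall_distance=2.5,
                           well_depth=1.5, well_width=1.0, seed=71)
    return gen_solvent_ensemble(solute, box, model, n_frames=150,
                                species=toy_cosolvent_species(),
                                solute_atoms=atoms)


class TestDecompose:
    CONFIG = AnalysisConfig(bin_width=0.1, r_max=9.0, bulk_shell=(6.0, 8.5),
                            reference_oversampling=2, seed=3)

    def test_exhaustive_partition_sums_to_total_exactly(self, cosolvent_system):
        res = compute_mddf(cosolvent_system, "cosolvent", self.CONFIG)
        contrib = decompose(
            res, cosolvent_system,
            groups={"res1": "residue_index=1", "res2": "residue_index=2"},
            side="solute",
        )
        total = sum(contrib.contributions.values())
        np.testing.assert_array_almost_equal(total, res.observed_counts, decimal=10)
        # integer identity before frame averaging
        n = cosolvent_system.n_frames
        assert np.array_equal(np.round(total * n), np.round(res.observed_counts * n))

    def test_solvent_side_partition_also_conserves(self, cosolvent_system):
        res = compute_mddf(cosolvent_system, "cosolvent", self.CONFIG)
        contrib = decompose(
            res, cosolvent_system,
            groups={"hydroxyl": "atom_name=HO", "rest": "atom_name!=HO"},
            side="solvent",
        )
        total = sum(contrib.contributions.values())
        np.testing.assert_allclose(total, res.observed_counts, atol=1e-10)

    def test_single_group_of_all_atoms_reproduces_total(self, cosolvent_system):
        res = compute_mddf(cosolvent_system, "cosolvent", self.CONFIG)
        contrib = decompose(res, cosolvent_system,
                            groups={"all": "residue_index=1:2"}, side="solute")
        np.testing.assert_allclose(contrib.contributions["all"],
                                   res.observed_counts, atol=1e-10)

    def test_overlapping_groups_rejected_unless_allowed(self, cosolvent_system):
        res = compute_mddf(cosolvent_system, "cosolvent", self.CONFIG)
        groups = {"a": "residue_index=1", "both": "residue_index=1:2"}
        with pytest.raises(ValueError, match="overlap"):
            decompose(res, cosolvent_system, groups, side="solute")
        contrib = decompose(res, cosolvent_system, groups, side="solute",
                            allow_overlap=True)
        assert contrib.overlapping


class TestResidueDensityMap:
    def test_asymmetric_well_lights_up_only_the_attractive_residue(self):
        # residue 1 carries a square well, residue 2 is invisible to the
        # solvent beyond its hard core: row 1 must dominate in the well
        atoms = [
            AtomRecord("C1", "C", 1, "LIG", Role.SIDECHAIN, PolarityClass.NONPOLAR),
            AtomRecord("C2", "C", 2, "LIG", Role.SIDECHAIN, PolarityClass.NONPOLAR),
        ]
        box = SimulationBox.cubic(24.0)
        solute = np.array([[6.0, 12.0, 12.0], [18.0, 12.0, 12.0]])
        rng = np.random.default_rng(81)
        config = AnalysisConfig(bin_width=0.1, r_max=8.0, bulk_shell=(5.0, 7.5),
                                reference_oversampling=3, seed=3)
        # hand-built frames: molecules placed in the well of residue 1
        # plus a uniform background
        frames = []
        n_shell, n_bg = 40, 200
        for _ in range(30):
            u = rng.normal(size=(n_shell, 3))
            u /= np.linalg.norm(u, axis=1, keepdims=True)
            shell = solute[0] + u * rng.uniform(2.5, 3.5, (n_shell, 1))
            background = rng.uniform(0, 24.0, (n_bg, 3))
            coords = np.concatenate([shell, background])[:, None, :]
            frames.append(Frame(solute=solute, solvent={"water": coords},
                                box=box))
        system = SolvationSystem(
            solute_atoms=atoms,
            species={"water": point_species("water", n_molecules=n_shell + n_bg)},
            frames=frames,
        )
        rmap = residue_density_map(system, "water", config)
        r = 0.5 * (rmap.bin_edges[:-1] + rmap.bin_edges[1:])
        well = (r >= 2.5) & (r <= 3.5)
        assert rmap.density[0, well].mean() > 5 * rmap.density[1, well].mean()

    def test_row_counts_sum_to_total_observed(self, cosolvent_system):
        config = TestDecompose.CONFIG
        res = compute_mddf(cosolvent_system, "cosolvent", config)
        rmap = residue_density_map(cosolvent_system, "cosolvent", config,
                                   mddf_result=res)
        np.testing.assert_allclose(rmap.counts.sum(axis=0),
                                   res.observed_counts, atol=1e-10)

    def test_relabeling_residues_permutes_rows(self, cosolvent_system):
        config = TestDecompose.CONFIG
        rmap = residue_density_map(cosolvent_system, "cosolvent", config)
        swapped_atoms = [
            AtomRecord(a.atom_name, a.element, 3 - a.residue_index,
                       a.residue_name, a.role, a.polarity_class)
            for a in cosolvent_system.solute_atoms
        ]
        swapped = SolvationSystem(
            solute_atoms=swapped_atoms,
            species=cosolvent_system.species,
            frames=cosolvent_system.frames,
        )
        rmap_swapped = residue_density_map(swapped, "cosolvent", config)
        np.testing.assert_allclose(rmap_swapped.counts, rmap.counts[::-1],
                                   atol=1e-12)

    def test_map_covers_the_contact_range(self, cosolvent_system):
        rmap = residue_density_map(cosolvent_system, "cosolvent",
                                   TestDecompose.CONFIG)
        assert rmap.bin_edges[0] <= 1.5
        assert rmap.bin_edges[-1] >= 3.5


class TestHydroxylFirstPeak:
    def test_protruding_hydroxyl_dominates_contact_distances(self):
        """Frames built with the hydroxyl-like atom pointing at the solute:
        the argmin atom of every short event is known by construction."""
        atoms = [AtomRecord("C1", "C", 1, "LIG", Role.SIDECHAIN,
                            PolarityClass.NONPOLAR)]
        solute = np.array([[10.0, 10.0, 10.0]])
        box = SimulationBox.cubic(20.0)
        rng = np.random.default_rng(91)
        from solvkb.synth import TOY_COSOLVENT_TEMPLATE

        template = TOY_COSOLVENT_TEMPLATE
        frames = []
        n_close, n_far = 25, 80
        for _ in range(40):
            mols = []
            for _ in range(n_close):
                u = rng.normal(size=3)
                u /= np.linalg.norm(u)
                # hydroxyl at 1.8-2.2 Å from the solute, C and F strung
                # out radially behind it
                ho = solute[0] + u * rng.uniform(1.8, 2.2)
                mols.append(np.vstack([ho, ho + u * 1.0, ho + u * 2.0]))
            for _ in range(n_far):
                pos = rng.uniform(0, 20.0, 3)
                mols.append(pos + template - template.mean(axis=0))
            frames.append(Frame(solute=solute,
                                solvent={"cosolvent": np.array(mols)},
                                box=box))
        system = SolvationSystem(
            solute_atoms=atoms,
            species={"cosolvent": toy_cosolvent_species(
                n_molecules=n_close + n_far)},
            frames=frames,
        )
        config = AnalysisConfig(bin_width=0.1, r_max=9.0, bulk_shell=(6, 8.5),
                                reference_oversampling=2, seed=3)
        res = compute_mddf(system, "cosolvent", config)
        contrib = decompose(
            res, system,
            groups={"hydroxyl": "atom_name=HO", "rest": "atom_name!=HO"},
            side="solvent",
        )
        r = res.r_centers
        peak = (r >= 1.7) & (r <= 2.3)
        hydroxyl = contrib.contributions["hydroxyl"][peak].sum()
        rest = contrib.contributions["rest"][peak].sum()
        assert hydroxyl > 10 * max(rest, 1e-12)
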