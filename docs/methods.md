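# Methods

This note documents the models, estimators and numerical choices behind
`solvkb`, in the spirit of a package methods appendix: what is computed,
under which assumptions, and what the synthetic validation does and does
not demonstrate.

## Minimum-distance distribution functions

The MDDF of a solvent species around a solute is the histogram ratio
`g(r) = n(r)/n*(r)`, where `r` is the minimum over all (solute atom,
solvent atom) minimum-image distances for one solvent molecule, `n(r)`
the mean observed count per frame in half-open bins `[left, right)` of
width `bin_width` (default 0.1 Å) over `[0, r_max]` (default 15 Å), and
`n*(r)` the same count for an ideal-gas reference.  Events at or beyond
`r_max` are discarded from the histograms.

**Reference.** The ideal-gas reference is generated by rigid random
re-insertion of the species into the same box: uniform position, uniform
orientation (quaternion sampling), internal geometry preserved.  Each
frame receives `nu × n_molecules` insertions binned with weight `1/nu`
(`reference_oversampling`, default 5): the expectation equals a single
ideal realisation of the same molecule count, the variance is `nu`-fold
smaller.  The reference is recomputed per frame with a seed derived from
`(config.seed, frame_index)`, so results are reproducible and
independent of frame order.  Bins whose reference is empty are flagged
undefined (`g = NaN`), never reported as 0.

**Decomposition.** Each per-molecule event is realized by one atom
pair; ties are broken deterministically by lowest (solute atom index,
solvent atom index).  A group's contribution collects the events whose
realizing atom (solute-side or solvent-side, per call) belongs to the
group, so an exhaustive partition reproduces the total bin-by-bin as an
integer identity before frame averaging.  Overlapping groups are
rejected unless explicitly allowed (sums may then exceed the total and
the result is flagged).  The per-residue density map is the solute-side
decomposition by residue, with each row normalised by the total
reference scaled by a uniform per-residue share; rows of residues the
solvent never contacts are ~0.

**Kernels.** All distances use the minimum-image convention in
orthorhombic boxes (triclinic cells are out of scope).  The
minimum-distance kernel is chunked, vectorised numpy over
(molecule, solute atom, solvent atom) blocks; at the package's intended
problem sizes (≤ a few thousand molecules, ≤ tens of solute atoms) this
is faster in wall-clock terms than a cell list would make it, and its
contract — exact agreement with an exhaustive all-pairs, all-27-images
brute force — is enforced by a property test rather than assumed.

## Kirkwood–Buff integrals and preferential solvation

`G(R) = (1/rho)[N(R) − N*(R)]` from cumulative observed and reference
counts, reported in L/mol with concentrations in mol/L.  The single
unit conversion, 1 mol/L = 6.02214076e−4 molecules/Å³, lives in
`solvkb.constants`.

**Bulk density.** `rho` is the mean molecule count whose minimum
distance falls in the bulk shell (default 10–15 Å from the solute
surface) divided by the shell's effective volume, estimated by
Monte-Carlo insertion of the species template (the fraction of random
rigid placements whose minimum distance lands in the shell, times the
box volume).  Using insertions rather than point sampling keeps the
numerator and denominator geometrically consistent for multi-atom
solvents; for a one-atom species around a point solute it converges to
the analytic spherical-shell volume.

**Reference-density matching.** The re-insertion reference is built
with the per-box molecule count, not the bulk density, and in a fixed-N
ensemble the raw integral of `g − 1` over the whole box vanishes
identically (closure).  The reference histogram is therefore rescaled
so its implied density in the bulk shell equals the estimated bulk
density before the difference `N − N*` is taken.  On the synthetic
fixtures this normalisation recovers the grand-canonical closed forms
exactly in expectation.

**Preferential parameters.** `Gamma_pc = rho_c (G_pc − G_pw)` and
`Gamma_pw = rho_w (G_pw − G_pc)` at a common radius `R_used`: the
largest converged radius of the two profiles when both converge, else
`r_max` with a warning.  The identity
`Gamma_pw = −(rho_w/rho_c) Gamma_pc` is exact by construction and
asserted to 1e−10 in the tests.  Positive `Gamma_pc` means cosolvent
accumulation in the solute domain (effective dehydration of the
solute).

**Convergence.** `converged_R` is the smallest grid radius whose G
stays within a tolerance over a trailing window (defaults: 0.05 L/mol
over 3 Å, matched to protein-scale KBIs of order 1–10 L/mol).  On toy
point-solute fixtures, where the entire KBI is ~0.07–0.17 L/mol, tests
pass a proportionally tighter tolerance (0.002–0.01 L/mol); the
tolerance is an analysis parameter that must scale with the magnitude
of G.

**Cross-formula check.** An independent shell-integral route —
`sum_b (g_b − 1) ΔV_b` with per-bin volumes `ΔV_b` estimated by
Monte-Carlo insertion (the minimum-distance iso-surface area times dr)
— agrees with the counting route within Monte-Carlo error; it is a
consistency test, not the estimator.

## Synthetic ensembles (what they do and do not emulate)

The generator places rigid solvent molecules independently around a
fixed solute by exact rejection sampling against the uniform envelope,
under one of three radial models of the molecule-solute interaction in
terms of the minimum distance:

- `ideal_gas`: no interaction; `g ≡ 1`, `G ≡ 0`.
- `hard_wall(d)`: excluded region below `d`; `G = −V_excl`, and for a
  point solute `V_excl = (4/3)πd³` exactly.
- `square_well(d, w, eps)`: hard core plus a well of depth `eps` (kT
  units) over `[d, d+w]`; because placements are independent,
  `g = exp(eps)` in the well and 1 outside in closed form, and
  `G = (e^eps − 1) V_well − V_core`.

Molecule counts are `round(density × V_box)` exactly; seeded runs are
bit-reproducible.  A 3-atom rigid toy cosolvent (a protruding
hydroxyl-like hydrogen, a carbon, a fluorine-like atom) exercises
solvent-side decomposition; `gen_binary_solvent` combines an attractive
cosolvent with an inert water so the sign of `Gamma_pc` is known by
construction.

These ensembles deliberately omit solvent-solvent correlations,
molecular flexibility, electrostatics and real solvation-shell
structure.  Passing the oracle tests therefore demonstrates the
*estimators* (binning, reference normalisation, bulk-density matching,
cumulative integration, decomposition bookkeeping) are correct — not
that any particular force field or real mixture behaves a given way.

**Fixture sizes** were fixed by an a-priori variance budget so each
statistical check sits several standard errors inside its tolerance:
ideal-gas null 1000 molecules × 100 frames (SE of the mean g over
2–10 Å ≈ 1.2% against a ±3% band); hard-wall 20 Å box at
0.05 molecules/Å³ × 12000 frames (SE(G) ≈ 0.6% against a 2% band);
square-well 24 Å box × 6000 frames (SE(G) ≈ 1%, fixed-N closure bias
of the raw-reference g ≈ 1%, against 5% bands).  The whole suite runs
in about half a minute on one CPU.

## Toy peptide and helix assignment

`gen_toy_peptide` builds a polyalanine backbone (N, H, CA, C, O) by
internal-coordinate placement with standard bond lengths/angles at
ideal dihedrals: alpha helix (phi, psi) = (−57°, −47°), extended
(180°, 180°).  The construction yields O(i)···H(i+4) = 2.12 Å in the
helix and > 12 Å extended, so the assignment fixtures are unambiguous.
Chains shorter than 5 residues are rejected (no i→i+4 bond exists).

Helix assignment reimplements the Kabsch–Sander electrostatic model:
a backbone H-bond exists when
`E = 0.084·332·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN) < −0.5 kcal/mol`,
and a residue is alpha-helical when it lies in the span of two
consecutive i→i+4 turns (minimal-helix rule).  3₁₀/π helices and
strands are reported as "not alpha" by design.  A missing amide H is
reconstructed 1.0 Å from N along the bisector opposite C(i−1)–N–CA.
One consequence of the 4-residue span of each turn pair: a single
broken i→i+4 bond in the middle of a long helix does not unassign any
residue (the neighbouring pairs bridge it); at least two consecutive
turns must fail before the assignment changes.

Hydrogen bonds elsewhere use a geometric criterion (donor-acceptor
≤ 3.5 Å and donor-H···acceptor angle ≥ 150°, both configurable — the
cutoffs are a common convention, not a universal constant), with donor
hydrogens located by covalent distance (≤ 1.25 Å) per frame and
minimum-image geometry throughout.

## Block averaging and autocorrelation

`block_average` tabulates the SE of block means for dyadic block sizes
while ≥ 16 blocks remain, and reports the naive SE (`sd/√n`) alongside.
Plateau detection by thresholding successive block estimates is noisy —
at the block sizes where correlated series level off only 16–64 blocks
remain, giving 12–18% relative noise per estimate — so the plateau is
located through the statistical inefficiency
`g = 1 + 2·sum_k rho(k)` estimated from the FFT autocorrelation
function with Sokal's self-consistent truncation window (`W ≥ 5 g/2`):
`plateau_se = naive_se · sqrt(g)`, and `plateau_block` is the smallest
tabulated block size exceeding ~2.5 g.  For positively correlated
series `plateau_se ≥ naive_se` by construction; a constant series
yields zero at every block size.  The ACF uses the biased (1/n)
estimator for stability, `acf(0) = 1`.

## REST2 arithmetic

All replicas share one physical temperature T0; replica m sees
`E_m = lambda_m E_pp + sqrt(lambda_m) E_ps + E_ss` with
`lambda_m = beta_m/beta_0` descending from 1.  (Printed forms of the
scaled potential sometimes show both solute terms scaled by lambda; the
square-root scaling of the solute-solvent cross term is the standard
REST2 prescription and is what this module implements.)  Ladders have
exact endpoints `lambda_0 = 1`, `lambda_{M−1} = lambda_min`; geometric
spacing (constant ratio) is the default, as in common replica-exchange
practice, with linear spacing available for comparison — the spacing
between stated endpoints is otherwise a free choice.  Swap acceptance
is `min(1, exp(−Delta))` with
`Delta = beta_0[(E_i(λ_j) + E_j(λ_i)) − (E_i(λ_i) + E_j(λ_j))]`,
antisymmetric under exchanging replica labels.  No molecular dynamics
is run; emergent observables of real REST2 simulations (e.g. the
realised exchange rate) are out of scope.

## Degenerate inputs and numerical conventions

- Coordinates in Å, energies in kJ/mol, `k_B = 8.31446…e−3 kJ/mol/K`.
- Orthorhombic boxes only; no unwrapping of PBC-broken molecules beyond
  minimum-image distance evaluation (inputs are assumed whole).
- Histidine is polar-uncharged by default; `his_charged=True` moves all
  His variants to the charged class.  Solute hydrogens participate in
  minimum distances by default (`include_solute_hydrogens=False` to
  exclude).  Both are config choices because upstream conventions vary.
- Unknown residues are kept with polarity class `n/a` and a warning.
- Generator rejection sampling aborts with a diagnostic when the
  acceptance rate falls below 1e−3 (e.g. wall distance close to the
  half-box diagonal).
- Zero-molecule species, empty selections, empty bulk shells, and
  mismatched KBI grids raise immediately with the failing quantity
  named.

## Known limitations

- The shell-rescaled reference corrects the fixed-N closure in
  expectation but not finite-size corrections beyond it (no
  compressibility-route or pressure-route KBIs).
- Minimum-distance shell volumes are Monte-Carlo estimates; their noise
  enters G multiplicatively through the bulk density (controlled by
  `n_mc_points`).
- The DSSP reimplementation covers only the alpha class; per-residue
  assignments at chain termini depend on amide-H availability.
- XTC trajectories store fixed-point 0.001 nm coordinates; round-trip
  comparisons are only meaningful to ~0.01 Å.
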