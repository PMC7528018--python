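# Methods

This note documents the models and numerical choices behind `stainfit`:
what each stage computes, which parameters matter, what the synthetic
benchmark does and does not emulate, and where the design was genuinely
open.

## Density model and map simulation

A `DensityMap` is a scalar field on a regular grid, stored `(nz, ny, nx)`
with per-axis voxel spacing (Å) and the physical position of the center of
voxel `(0,0,0)` as the origin. MRC2014 I/O goes through gemmi; on read, the
origin is taken from the ORIGIN header words when any is nonzero, otherwise
from the start-voxel words times the voxel size, and axis order is
normalized to section/row/column = z/y/x (files that cannot be brought to
that order are rejected with the order named).

Maps are simulated from coordinates by Gaussian blurring: each atom
contributes an isotropic Gaussian of width `σ = sigma_factor × resolution`
with peak amplitude equal to its weight (atomic mass for real structures;
1.0 for Cα-only toys — at 30 Å the weighting is immaterial to fit ranking).
`sigma_factor` defaults to 0.225, the convention of the Chimera-family
fitting tools; the kernel that produced any given experimental simulated
map is rarely published, so this is a configurable convention, not a fact.
Gaussians are truncated on a 4σ sphere (99.9% of the 3D mass) and the
default grid pads the model bounding box by the same 4σ. The *radial*
cutoff makes a single atom's grid sum independent of where it sits relative
to the voxel lattice, so sums over well-separated atoms are additive and
the total integrates to `Σ w · (2πσ²)^{3/2}` to 0.1%.

Stain maps carry no absolute intensity scale. All thresholds are therefore
defined on a max-normalized `[0,1]` map with negative values (reconstruction
noise) clamped to zero; the canonical envelope threshold is 0.06 on that
scale.

### Envelope extraction

`binarize` is the raw primitive (strictly-greater threshold). The pipeline
extracts envelopes through `extract_envelope`, which additionally

1. low-pass filters the normalized map with a 1-voxel Gaussian and
   re-normalizes before thresholding — voxel-scale intensity fluctuations
   cannot represent signal at a ~30 Å map's resolution, but they dimple a
   raw threshold contour and dominate surface-based scores; and
2. keeps only the largest 6-connected component — shot noise above the
   threshold otherwise contributes isolated speck voxels whose surfaces
   swamp the Chamfer distance.

The identical extraction is applied to experimental and simulated maps
wherever envelopes are compared, so a noiseless self-fit still attains
Chamfer 0 and Dice 1 at the truth pose. Both steps are configurable
(`prefilter_vox=0`, `clean_envelope=False` restore raw thresholding).

## Global fitting

`global_fit` runs: random placements → local optimization → coverage filter
→ greedy clustering → four-metric scoring, fully deterministic for a fixed
seed. Desk defaults are 2,000 placements and 100 optimization steps (the
production-scale analog of this procedure used 100,000 and 100); the
coverage minimum is 0.30.

The optimizer climbs the overlap score only. Because the model density is a
sum of Gaussians, `Σ_v ρ_exp · ρ_model,T` equals `Σ_atoms w_a (ρ_exp ∗
G_σ)(T x_a)`: the experimental map is convolved with the simulation kernel
once, and every trial pose costs one trilinear interpolation per atom. The
ascent itself is a central-finite-difference gradient on the six rigid
parameters (rotation about the current centroid scaled by the gyration
radius so all six are in Å-equivalents; difference step 0.25 Å, initial
line-search step 2 Å with up to 8 halvings), accepting only improving
steps, so the score sequence is non-decreasing and a placement whose line
search fails has converged. All placements are advanced together through
batched grid interpolation; the batched and the one-at-a-time code paths
follow the same rule and are tested against each other.

Coverage is the fraction of the *placed* body's own envelope voxel centers
(simulated at the placement, extracted at the experimental threshold) that
fall inside the experimental envelope; at truth on a noiseless self-map it
is exactly 1.

Clustering is greedy in descending score order: a fit joins a
representative within both `cluster_rot_deg` (geodesic rotation angle) and
`cluster_trans` (centroid displacement), else founds a new cluster. The
tight regime (3°, 2 Å, the default) corresponds to the fine clustering used
for single-body fitting runs; the loose regime used before two-body
combination is 10°/5 Å (`LOW_CLUSTERING`). The loose values are a choice:
coarse enough to keep the pairwise product tractable, fine enough that
orientation variants of a basin — which the union scoring must
discriminate — survive as distinct representatives.

## The four metrics

- **overlap** — voxel sum of experimental × simulated model density, the
  optimization score. Computed with the *raw* (not per-placement
  normalized) model density, so on a self-simulated map no placement can
  outscore the truth (Cauchy–Schwarz with a placement-independent model
  norm). Unbounded above for union models, where densities can pile.
- **ccc** — about-zero normalized cross-correlation inside the experimental
  envelope. About-zero rather than about-mean because clamped stain maps
  are non-negative and mostly empty; the about-mean variant is dominated by
  background.
- **Chamfer distance** — symmetrized mean nearest-neighbor distance between
  the two envelopes' surface voxels (face-adjacency surface, grid boundary
  counts as outside). Surfaces only, never filled volumes: the stain map is
  a surface approximation.
- **envelope score** — Dice coefficient of the binary masks. The name
  "envelope score" does not pin down a formula in the literature this
  pipeline descends from; Dice is this package's deliberate realization of
  the surface-agreement intent: bounded, symmetric, exactly testable.

Chamfer enters all rankings negated so every metric is higher-is-better.
Cross-metric aggregation is by mean rank, never mean score — the four live
on incommensurable scales.

## Handedness decision

Both mirror maps are fitted with every body. A mirror is chosen only if

1. its best fit beats the other mirror's under **all four** metrics for
   every body;
2. within it, the same top fit wins regardless of metric — where "same"
   means the poses differ by less than the kernel width σ in Cα RMSD,
   since the map cannot resolve poses below its kernel; and
3. the overlap margin exceeds 3× the pipeline's replicate sampling jitter,
   measured by re-fitting with a shifted placement seed.

Anything weaker is *ambiguous*. The jitter guard exists because the mirror
map carries the same noise realization, reflected: for an achiral body the
noise cancels in the cross-mirror margin, leaving multi-start sampling
scatter as the null scale — and because overlap/ccc and Chamfer/Dice are
two, not four, independent evidence channels, sign-unanimity alone
false-fires on roughly a third of achiral controls. With the guard, the
benchmark tallies are 9/10 correct on chiral cases and 9/10 ambiguous on
planar achiral controls (one chiral case is honestly ambiguous — the
weakest-chirality body at the benchmark noise level; helices blur to rods
at 30 Å, so map-level chirality is carried by the global fold, not the
helical hand).

## Two-body combination

Pairs from the Cartesian product of two loosely-clustered ensembles are
filtered sterically and scored as **union models**: one density simulated
from both placed bodies jointly (additive), never an average of per-body
scores. On a noiseless benchmark the truth pair attains the exact optima
of the three bounded metrics (ccc 1, Chamfer 0, Dice 1).

The clash criterion is the fraction of body-A Cα atoms within 4.0 Å of any
body-B Cα, with retention at ≤ 0.05 — but measured after a *relieved*
clash computation: the fraction is minimized over a rigid push-out of B
along the inter-centroid axis of up to σ (1 Å steps). Independent overlap
fitting biases each body into the shared density by up to about the kernel
width at a contact interface, so region-correct pairs read as apparent
clashes at atomic radii; a sub-resolution push-out relieves contact bias
but cannot relieve gross interpenetration, which is what the filter must
remove. Both the relieved and the raw fraction are recorded.

Ranking is by mean rank across the four metrics; when a crosslink set is
supplied, candidates inside the top decile (configurable) are reordered by
descending crosslink satisfaction, with ties broken stably by pair index
so the ranking is permutation-invariant. Crosslinks reorder but never veto:
a violated link in a flexible complex is information, not disproof.

## Crosslink validation

xQuest-style tables (TSV or CSV; flexible column spellings) are filtered at
ld ≥ 40 *inclusive*. A link is mappable iff both residues have Cα atoms in
the assembly under the user-supplied protein→chain table (never guessed);
with multiple chain copies the minimum Cα–Cα distance is used and flagged.
Violation means distance > 35 Å, the standard bound for a DSS crosslinker
Cα–Cα; both thresholds are configurable. Monolinks pass the confidence
filter but carry no distance. The totals obey
`n_violated ≤ n_mapped ≤ n_pass_filter ≤ n_input` on every input, and
unmappable links are reported with reasons, never silently dropped.

## Surface areas

SASA is Shrake–Rupley with a 256-point golden-spiral quadrature per atom
(≤0.5% error on an isolated sphere), probe radius 1.4 Å, hydrogens ignored,
Bondi van der Waals radii (fallback 1.70 Å). Buried interface area is
`SASA(A) + SASA(B) − SASA(A∪B)` with all atoms outside the two selections
removed. Published interface areas depend a few percent on the radii set
and quadrature of the tool that produced them, so reproduction of literature
values should be expected at the ~10% level, not exactly.

## The synthetic benchmark

`make_two_body_case` emulates the inputs of a stain-map fitting study: two
bodies fitted independently into one shared ~30 Å map of the whole complex,
the map's x-mirror, and a DSS-style crosslink table. Defaults (chosen once
as realistic desk-scale study conditions): bodies of 72 and 48 residues
(unequal, as real subcomplexes are), helical_fraction 0.5, consecutive
Cα–Cα exactly 3.8 Å, right-handed helix (rise 1.5 Å, 100°/residue) plus a
self-avoiding random walk, a docked interface with minimum inter-body Cα
distance between 5 and 8 Å, 4 Å voxels, noiseless map; 21 satisfied + 4
violated confident links (satisfied planted at ≤ 30 Å, violated at > 40 Å —
a 5 Å margin on both sides of the 35 Å bound), 6 sub-threshold decoys and
3 monolinks. Handedness benchmark cases use a single 60-residue body at
helical_fraction 0.8 with i.i.d. Gaussian voxel noise at 5% of the map
maximum.

What this does **not** emulate: stain flattening, uneven stain, missing
tails, atomic side chains, or spatially correlated reconstruction noise.
Passing benchmarks therefore demonstrate the correctness and internal
consistency of the pipeline at these conditions — not performance on real
micrograph-derived maps. Two desk-scale effects deserve naming: (i) at
30 Å, independent fitting of a small touching body is biased into its
partner's density by up to ~σ, which is why the combination stage, not the
single-body fit, resolves the assembly; (ii) orientation degeneracy (a
48-residue body flipped end-for-end scores nearly identically), which is
why the closest-to-truth combined pair is expected near, not invariably at,
the top of the ranking.

Every case is byte-reproducible from its parameters and seed, including the
files written by `SyntheticCase.save` and the CLI.

## Degenerate inputs and edge rules

Empty models, empty envelopes and zero-norm maps raise; a placement with no
density inside the experimental envelope scores ccc 0 (uncorrelated, not an
error); all placements failing the coverage filter yield an empty ensemble
with a warning; fit significance requires ≥ 3 representatives and reports
z=0, p=0.5 when all scores are equal, and a machine-precision floor when
the top stands alone above a zero-variance rest. Alternate locations
resolve to the highest-occupancy conformer; insertion-code residues are
kept distinct, and crosslink tables (which carry plain numbers) match the
blank insertion code only. Problem sizes throughout (2,000 placements,
400-placement handedness runs, 1,000-placement combination runs) are the
package's desk-scale defaults; every stage scales to larger runs through
`FitConfig`.
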