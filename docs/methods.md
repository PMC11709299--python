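# Methods

## Reconstruction model

A gene's 3D expression pattern is modeled as a nonnegative array
R ∈ ℝ^(lx×ly×lz) supported on a binary mask M of the sample shape, whose
axis marginals equal the gene's three preprocessed tomo-seq profiles.
Iterative proportional fitting (IPF) solves this marginal-matching
problem by cyclic multiplicative slice scaling. Properties that follow
directly from the update rule, and that the test suite checks:

- **Support preservation.** R(0) = M and updates are multiplicative, so
  R(t) = 0 wherever M = 0, for every t.
- **Exactness per step.** After fitting an axis, that axis's marginal
  equals its target on every slice with a positive denominator.
- **Feasibility ⇒ convergence.** If any supported volume with the given
  marginals exists (always true for simulated data, where profiles are
  computed from a truth volume), the loss — the sum of squared marginal
  residuals over the three axes — decays to numerical zero; on random
  feasible instances up to 5×5×5 it is below 1e-6·T² after 100 sets.
- **Non-uniqueness.** Marginals under-determine a 3D array; IPF returns
  the fit reachable from the mask initialization, which spreads mass as
  evenly as the constraints allow. This, not lack of convergence, is why
  reconstructions of compact patterns are smoothed versions of the truth.

Axis order is fixed at x → y → z; after the final z step the z-marginal
is exact and the total mass equals T. Exactly m sets are run (default
m = 100, no early stopping), so runs are deterministic and reproducible
bit for bit.

### Degenerate inputs

- A mask slice with no voxels but a positive marginal target cannot
  absorb mass: the step leaves the slice at zero and records the amount
  as an `unassignable_mass` warning (from the final iteration set) on the
  reconstruction, rather than aborting — real masks imperfectly match
  section data and a completed run with an auditable report is more
  useful than an error.
- Slice-sum denominators are compared against an epsilon of exactly 0:
  all values are nonnegative, so a slice sum is either exactly zero or
  usable. The threshold is configurable (`IPFConfig.epsilon_denominator`).
- A gene whose profile is all-zero along any axis is flagged
  non-reconstructable and skipped in batch runs.

## Preprocessing

Inter-section normalization divides each count by its section's total
over all genes and multiplies by the section's mask voxel count, making
sections comparable in depth and material volume. Consequences used as
test oracles: normalized column totals equal the mask marginals wherever
raw totals were positive, and the stage is invariant to a global
rescaling of all counts. A section with zero total expression carries no
allocable signal; it maps to zero with a warning.

The common total T is computed from the **raw** matrices (grand totals
averaged over the three axes), then each gene's normalized vectors are
rescaled to sum to T. Whether T should come from raw or normalized
matrices is ambiguous in principle; this package follows the raw
definition. The choice only moves the global scale of every
reconstruction by a shared constant, so correlation-based evaluation is
unaffected. With normalization off, the inter-section stage is skipped
but common scaling is still applied: IPF requires the three marginal
totals to agree, so total-mass agreement is forced in both modes.

The pipeline records applied stages on the dataset and refuses to apply
inter-section normalization twice (it is not idempotent).

## Simulated data

The generator reproduces a standard evaluation design: a solid ellipsoid
voxelized at 50×50×50 (default radii 24, 18, 14 voxels along the
anterior–posterior, ventral–dorsal and left–right axes; 25,368 mask
voxels), five spatial genes, and 1,997 or 4,997 background genes;
profiles are exact marginal sums of each gene's truth volume; 10
replicates per setting.

Spatial gene geometry (voxel units; all defaults in `PatternSpec` /
`default_patterns`):

| gene  | pattern | strong region | floor |
|-------|---------|---------------|-------|
| Gene1 | centered blob | ellipsoid at 40% of mask radii | 0 |
| Gene2 | blob + ubiquitous background | same as Gene1 | 40% of high |
| Gene3 | anterior spot | radius-4 sphere, 70% toward the anterior pole | 0 |
| Gene4 | mirrored spot pair | two radius-4 spots at ±8 voxels across the LR mid-plane, anterior | 0 |
| Gene5 | off-axis spot | radius-4 sphere offset +8 voxels from both the LR and DV mid-planes | 0 |

The high level is 100 (arbitrary units; correlation-based scoring is
scale-free). The published design describes these patterns only
verbally, so the region sizes and offsets above are this package's
calibration: they were fixed once, by checking that the resulting
per-gene mean PCCs land near the reference values (0.85/0.64/0.91/0.97/
0.86) with the ordering Gene4 > Gene3 > Gene1 ≈ Gene5 > Gene2. The only
parameter adjusted during that calibration was Gene2's floor (10% → 40%
of the high level); at 40% the mean PCC is ≈ 0.64. Spatial truths are
deterministic — replicate-to-replicate variability in accuracy enters
through the background genes via the normalization denominators, which
matches the very small reported standard deviations for the blob genes.

Background genes are spatially unstructured by construction: each gene
draws a mean from a log-normal (log-mean 1.0, log-sd 1.0) and per-voxel
counts inside the mask from a negative binomial with that mean and size
(dispersion) 0.5 — variance μ + μ²/0.5, i.e. strongly overdispersed
RNA-seq-like counts, with the Poisson limit as the size parameter grows.
This is an explicit stand-in for a semi-parametric RNA-seq simulator:
only the absence of spatial structure and a realistic count marginal
matter here, and tests verify Moran's I of background volumes is ≈ 0.
All parameters are user-overridable via `BackgroundModel`.

Seeding is counter-based: `SeedSequence(entropy=seed,
spawn_key=(replicate, gene_index))`, so (seed, replicate) fully
determines a dataset and adding genes or replicates never reshuffles
existing draws. The marginal-only fast path used for large gene counts
draws from the identical streams as the full-volume path and is tested
to agree with it exactly.

**What the simulation does not emulate:** real tomo-seq dropout and
section-loss artifacts, axis misalignment, gene–gene correlation in the
background, and library-construction biases beyond per-section depth.
Passing accuracy tests therefore demonstrates correctness of the
algorithmic pipeline under feasible, well-registered inputs, not
robustness to all real-data pathologies (no imputation or smoothing of
dropout zeros is attempted).

## Evaluation statistics

- **Masked PCC.** Pearson correlation over mask voxels only. It is
  invariant to positive affine transforms of either argument, so scoring
  against raw truth or depth-rescaled (reads-per-million) truth is
  identical; the raw truth volume is used.
- **Permutation null.** Reconstruction values are permuted across mask
  voxels (1,000 permutations by default; voxels outside the mask take no
  part), preserving the value multiset. The empirical p-value uses the
  add-one convention (1 + #{null ≥ observed}) / (n_perm + 1), so it is
  never zero; the smallest attainable value is 1/1001.
- **KS comparison.** Observed per-replicate PCCs versus the null pooled
  across replicates, two-sample Kolmogorov–Smirnov with the asymptotic
  p-value (the null pool is large, so exact small-sample computation is
  unnecessary).
- **Moran's I.** Weights are 6-connected (face-adjacent) neighbors
  within the mask, row-standardized; neighbor relations never wrap
  around the grid. The classical null expectation −1/(N−1) and the value
  −1 for two adjacent voxels serve as test oracles. The weight scheme is
  explicit in `SpatialWeights` because "Moran's I" alone does not pin
  one down.
- **Target-gene screen.** Masked PCC of every reconstruction against a
  target gene's volume, sorted descending with lexicographic
  tie-breaking; the target is excluded from its own ranking.

## Problem sizes and defaults

Accuracy benchmarks (tests and `scripts/acceptance.py`) use the full
published design — 10 replicates × (5 spatial + 1,997 background) genes,
plus 10 replicates at 4,997 background genes for the robustness check,
100 IPF sets on the 50³ grid, 1,000 permutations per gene and replicate —
chosen because the whole computation runs in minutes on one CPU.
Unit and property tests use 3³–6³ grids where brute-force oracles
(triple-loop marginals, covariance-formula PCC, hand-computed Moran's I)
are cheap and exact.

## File formats

Tomo-seq matrices are CSV (header row, gene IDs in column 1, sections in
anatomical order; comma separator, "." decimal, UTF-8). Column order is
taken as anatomical order; flipping an axis is the user's
responsibility, since section orientation metadata is not standardized.
Masks and reconstructions are NRRD volumes (attached header, raw
little-endian or ascii encodings; the first `sizes` axis varies fastest
per the NRRD convention), with a slice-CSV directory + `meta.json` as a
human-editable mask alternative and a JSON sidecar carrying
reconstruction metadata (loss trace, warnings). Reading coerces any
nonzero mask value to 1 with a warning. Arrays are 0-based internally;
section labels in reports and file names are 1-based, matching wet-lab
numbering. Point clouds are ASCII PLY with voxel-center coordinates.

## Known limitations

- Exactly three orthogonal axes; no support for more axes or oblique
  sectioning geometries.
- No alternative objectives (entropy / I-divergence raking, spatial
  smoothness priors) and no dropout imputation.
- The reconstruction inherits IPF's under-determination: fine structure
  not visible in any marginal (e.g. patterns symmetric in all three
  axes' shadows) cannot be recovered, only smoothed approximations.
- Moran's I p-values are not computed (only the statistic, used for
  ranking); the permutation machinery applies only to the accuracy PCC.
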