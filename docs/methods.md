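# Methods

## The model

`gradmap` estimates the low-dimensional organization of a seed region's
resting-state functional connectivity. The data model is: group BOLD time
courses, already preprocessed (motion/nuisance regression, band-pass
filtering, spatial normalization are upstream of this package), z-scored
per voxel and concatenated across subjects. For seed voxel *i* and brain
voxel *j* outside the seed, connectivity is the Fisher-z Pearson
correlation `z_ij = atanh(r_ij)`; correlations are clipped to
±(1 − 1e−7) before `atanh` so degenerate identical series stay finite.

Each connectivity row is thresholded to its top fraction (default 10%,
with 20%/30% as sensitivity settings): `k = round(fraction × n_targets)`,
at least 1, ranked on signed values with ties broken toward the lower
target index. Ranking on z equals ranking on r because `atanh` is
monotone. If `k` exceeds the number of positive entries, negative
correlations survive the cut and a warning is emitted — the affinity step
then clips any resulting negative similarities to zero.

Pairwise cosine similarity of the sparsified rows gives the affinity
matrix `W` (symmetric, entries in [0, 1], unit diagonal). The diffusion
map is computed exactly as the dense linear algebra says: `W' = D^-α W
D^-α` with `D = diag(W·1)` and α = 0.5 (α trades off the influence of
sampling density; 0.5 is the standard choice for connectivity data);
`P = D'^-1 W'` is the Markov operator; its non-trivial right eigenvectors
(unit norm), ordered by descending eigenvalue λ and scaled by
`λ/(1−λ)` ("automatic" multi-scale diffusion time; a fixed time t uses
`λ^t` instead), are the gradient coordinates. Internally the symmetric
conjugate `D'^-1/2 W' D'^-1/2` is eigendecomposed (dense below 500 seed
voxels, Lanczos with a fixed deterministic start vector above), which is
numerically better behaved and verified against a brute-force
nonsymmetric eigendecomposition of `P` to 1e−8.

Eigenvector signs are arbitrary; the package fixes each gradient's sign so
the voxel with the largest-magnitude coordinate is positive. This makes
runs comparable but carries no meaning — analyses that need a direction
(e.g. a planned positive morphology association) should orient the
gradient against ground truth or a reference topography first.

**Variance explained** is defined as `λ_g / Σ_h λ_h` over the retained
non-trivial spectrum (40 components by default); negative eigenvalues,
possible when clipping makes `W` slightly non-PSD, contribute zero. An
eigenvalue-squared variant is available via
`DiffusionConfig(variance_definition="squared")`. Shares therefore sum to
1 over what is retained — they are relative, not absolute, variance
fractions.

## Surrogate-map inference

Cross-voxel correlations between smooth brain maps cannot be tested
against naive permutations: spatial autocorrelation makes the null far
wider than exchangeability implies. The package builds
autocorrelation-matched surrogates of the x-map: permute its values,
smooth the permuted field with an anisotropic Gaussian distance kernel,
then re-impose the observed value multiset by rank matching. The kernel's
three per-axis bandwidths (multiples {0.3, 1.5, 2.5, 5, 16} of the grid
spacing, plus a no-smoothing candidate) are selected by generating 20
trial surrogates per candidate and minimizing the squared error between
mean trial variogram and observed variogram.

Two design points deserve emphasis:

- *Anisotropy.* Gradient maps on a grid are near-constant along some axes
  and steep along others; an isotropic kernel cannot reproduce such
  autocorrelation (its per-bin variogram error saturates at 40%+ no
  matter the bandwidth), while fitted per-axis bandwidths bring the mean
  surrogate variogram within ~10–15% of the observed one on the first
  half of distance bins. The no-smoothing candidate makes the generator
  exact for maps without spatial structure: surrogates degenerate to pure
  permutations and the test is exactly exchangeable.
- *Rank matching.* Every surrogate holds exactly the observed multiset of
  values, so the null varies topography only. The cost is a resolution
  floor: for maps whose value distribution is strongly gapped (e.g. a
  saturated two-level ramp) no multiset-preserving surrogate can match
  the short-lag variogram better than ~25–30%.

The **empirical variogram** is `γ(h) = mean of 0.5 (v_i − v_j)²` over
voxel pairs binned by distance: 25 quantile bins of the pairwise
distances up to the median distance (long-range bins are noise-dominated
in small regions); bins emptied by tied grid distances are dropped.

The **permutation p** follows the count convention `p = #(null r >
r_obs)/n` for an upper-tail test, mirrored for a lower tail, with n =
5000 surrogates by default, so the smallest reportable nonzero p is 1/n
(p = 0 prints as "< 1/n"). The tail should be fixed by the planned
hypothesis ("greater" for the morphology association, "less" for the
distance dependence); the "auto" convenience mode follows the observed
sign and accordingly doubles the effective type-I rate of a nominally
one-sided test — measured at ~10% vs the fixed tail's calibrated 5%.

**Geometry.** For each gradient, the Euclidean distance (mm, world
coordinates) from every seed voxel to the gradient's peak voxel is
correlated with the gradient itself, independently per hemisphere (each
hemisphere gets its own peak). Peak ties go to the lowest linear voxel
index with a warning. The hemisphere boundary on a synthetic grid is the
mid-plane of the first axis.

**Winner-take-all parcellation** correlates each seed voxel's time course
with the mean time course of each canonical network, computed over target
voxels only (the seed region is excluded — mirroring the connectivity
target set and avoiding self-correlation bias), and assigns the argmax;
ties go to the lowest network id with a warning. Networks that win no
voxel are reported absent rather than as empty groups. Gradient-value
distributions per present subdivision are reported in ascending-median
order.

**Decoding** splits a gradient map into ten percentile bins (stable sort,
lower index first on ties, bin sizes within one voxel of each other —
invariant to monotone transforms of the map), takes the mean term
z-statistic per bin over seed voxels, zeroes cells not strictly above
1.645 (one-sided p < 0.05), and drops terms with no surviving cell. Term
means are taken over seed voxels only.

## The synthetic generator

The generator emulates the statistical structure the pipeline assumes,
with known ground truth:

- Target voxels are partitioned into K angular territories (K = 4 by
  default), each with an independent unit-variance latent time course.
  Each target voxel's signal blends its own territory's latent with
  angular neighbors (Gaussian blend, width 0.8 of a wedge) plus a fixed
  per-voxel mixture jitter (sd 0.1). Both features mimic real
  connectivity's smooth transitions and voxel-level heterogeneity, and
  both are necessary: with piecewise-constant territory profiles the
  top-10% rows of opposite ramp ends share no support and the affinity
  graph disconnects.
- Seed voxels mix the network latents with weights following logistic
  ramps (scale 0.15 of the seed extent) along two orthogonal axes: the
  primary ramp contrasts networks 1 vs 2 with 60% of the signal, the
  secondary networks 3 vs 4 with 40%. The ramp values are the planted
  gradients; they are exactly uncorrelated by the separable block
  geometry. The 60/40 split makes the first gradient dominate without
  pushing the second below the first axis's harmonic (at 70/30 the
  embedding's second component is the harmonic, not the planted axis).
- Per subject, fresh latents and Gaussian noise (sd 0.5 against
  unit-variance signal) are drawn; each subject's voxel time courses are
  z-scored before concatenation (z-scoring the concatenated series
  instead is available as an option).
- The morphology map is `0.5 + 0.1 (ρ z₁ + sqrt(1−ρ²) ε)` with ε
  orthogonalized against the standardized planted axis z₁, so the
  realized spatial correlation equals the requested ρ exactly (default
  0.22, a typical magnitude for gradient–morphology associations).
- The planted network affiliation of a seed voxel is the network whose
  aggregate territory signal its clean signal most resembles — the
  argmax of the population correlation computed from the mixture weights
  alone. With blended territories this is the correct ground truth for
  what winner-take-all estimates; noiseless runs recover it exactly.
  Only the primary-pair networks ever win, so configurations with K ≥ 5
  exercise absent-network reporting.
- Term maps put amplitude ~3 (z scale) on one network's territory and,
  within the seed, grade the amplitude by the rank of the voxel's
  coupling to that network, rising monotonically toward the matching
  gradient extreme; background noise sd is 0.3.

Reference conditions: a 12×12×12 grid of 3 mm voxels (a central 144-voxel
seed block, 1584 targets), 10 subjects × 180 timepoints. These sizes were
chosen as the smallest configuration at which the embedding, surrogate,
and parcellation analyses are all well-conditioned; recovery at these
conditions is |r| ≈ 0.96 for the planted primary axis and ≈ 0.89 for the
secondary at the default noise level (≈ 0.98/0.94 noise-free).

What the generator does **not** emulate: hemodynamic response shape and
temporal autocorrelation, head motion and scanner artifacts, inter-subject
anatomical variability, surface geometry, and realistic network
topographies. Passing tests therefore demonstrate correctness of the
computations and their contracts on data satisfying the model's
assumptions — not robustness to the full messiness of empirical fMRI.

## Numerical choices and degenerate inputs

- Correlation clipping at ±(1 − 1e−7); affinity negatives clipped to 0;
  affinity symmetrized and diagonal pinned to 1.
- Disconnected affinity graphs raise (component sizes are listed) rather
  than silently embedding per-component.
- `n_components` is clamped to n_seed − 1.
- Re-sparsifying at the same fraction returns the input unchanged; the
  recorded fraction on the matrix makes this well-defined even when
  negative values were retained.
- Constant maps: variogram warns and returns zeros; correlation raises.
- All randomness flows through explicit integer seeds
  (`numpy.random.default_rng`); identical configuration and seed give
  bit-identical datasets and byte-identical NIfTI files.

## Known limitations

- Surrogate generation materializes the voxel-pair distance and kernel
  matrices (O(n²) memory); comfortable to a few thousand seed voxels,
  not beyond.
- No Procrustes alignment across datasets: gradients from different
  datasets are comparable by topography, not by coordinates.
- Group-level only; individual-level gradients are out of scope.
- The variance-explained definition is a convention (eigenvalue shares of
  the retained spectrum); comparisons against other toolboxes must match
  conventions before comparing numbers.
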