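# gradmap

Functional gradients describe how a brain region's connectivity profile
changes smoothly across space: instead of cutting a region into discrete
parcels, the region's voxel-to-brain resting-state functional connectivity
(rsFC) is embedded into a few continuous axes, each one a spatial
"gradient" along which connectivity reorganizes. `gradmap` implements this
analysis for an arbitrary seed region — the workflow used to map the
hierarchical organization of structures such as the precuneus — together
with the statistics that give the gradients meaning, and a synthetic-data
generator that plants known gradient structure so the whole pipeline can
be validated end to end without any imaging download.

The pipeline:

1. **Connectivity.** Group BOLD time courses (z-scored, concatenated
   across subjects) give a seed-voxel × brain-voxel Pearson correlation
   matrix, Fisher z-transformed: `z_ij = atanh(r_ij)`.
2. **Sparsification.** Per row, only the top 10% of connections are kept
   (20%/30% as sensitivity settings).
3. **Affinity.** Cosine similarity between sparsified rows yields a
   positive, symmetric seed-voxel pair affinity matrix `W`.
4. **Diffusion-map embedding.** With degree matrix `D`, the
   density-normalized operator `W' = D^-α W D^-α` (α = 0.5) is
   row-normalized into a Markov matrix `P`; the non-trivial eigenvectors
   of `P`, scaled by `λ/(1-λ)` and ordered by descending eigenvalue, are
   the gradients G1, G2, …, with variance-explained shares `λ_g / Σ λ`.
5. **Gradient-level statistics.** Association of a gradient with a
   morphology map is tested by cross-voxel Pearson correlation against
   5000 spatially-autocorrelated surrogate maps (permute → variogram-fitted
   smoothing → re-rank, so every surrogate keeps the observed value
   multiset exactly); geometry is probed by correlating each gradient with
   Euclidean distance from its peak voxel, per hemisphere; network
   correspondence by winner-take-all assignment of seed voxels to
   canonical networks; behavioral relevance by ten-percentile binning of
   the gradient against term-activation maps, keeping mean z > 1.645.

It is intended for neuroimaging researchers who want a tested, scriptable
version of this workflow operating on NIfTI volumes, and for method
developers who need a planted-truth testbed for gradient analyses.

## Worked example

```python
import numpy as np
import gradmap as gm

# a synthetic group dataset with two planted, orthogonal gradients
ds = gm.generate_dataset(gm.SyntheticConfig(seed=1))
res = gm.GradientModel.from_dataset(ds).fit()
print(res.summary(5))
print("G1 recovers planted axis, |r| =",
      round(abs(np.corrcoef(res.gradients.gradient(1), ds.planted_g1)[0, 1]), 3))

gmv = ds.seed_values(ds.gmv_map)
perm = res.correlate_with(gmv, gradient=1, n_surrogates=5000, seed=1)
print(f"G1-morphology r = {perm.r_observed:.2f}, p_perm = {perm.format_p()}")
print(res.distance_dependence(1, n_surrogates=0))
```

prints

```
            Functional Gradient Decomposition
==========================================================
Seed voxels: 144      Targets: 1584     Timepoints: 1800
Sparsity: 0.10        alpha: 0.50       components: 40
----------------------------------------------------------
 component     eigenvalue     variance explained
         1       0.942120                 30.6%
         2       0.584963                 19.0%
         3       0.449892                 14.6%
         4       0.277791                  9.0%
         5       0.167168                  5.4%
==========================================================
G1 recovers planted axis, |r| = 0.963
G1-morphology r = 0.23, p_perm = 0.005
   gradient hemisphere         r  p_perm
0         1          L -0.859297     NaN
1         1          R -0.860965     NaN
```

The first gradient dominates the variance spectrum and tracks the planted
primary axis almost perfectly; the morphology correlation (0.23 here; the
eigenvector sign is arbitrary, so orient against ground truth or a
reference map before interpreting a sign) is tested against
autocorrelation-preserving nulls; and both hemispheres show the strong
negative correlation between gradient value and distance from the peak
voxel that smooth monotone topographies imply.

The same analyses run from the shell on NIfTI inputs:

```bash
gradmap simulate --config sim.yaml --out data/
gradmap run --data data/ --out results/ --sparsity 0.10 --sparsity 0.20
gradmap stats corr --x results/sparsity-0.10/gradient_1.nii.gz \
    --y data/gmv.nii.gz --mask data/seed_mask.nii.gz --n-surrogates 5000 --seed 1
```

See `docs/methods.md` for the model, its assumptions, and the synthetic
generator's design.

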