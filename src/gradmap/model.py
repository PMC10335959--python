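"""Model/Results interface to the gradient pipeline.

`GradientModel` wraps group BOLD data plus seed/target masks and the
analysis settings; `fit()` runs connectivity -> sparsification -> affinity
-> diffusion embedding and returns a `GradientResults` object carrying the
gradients, their variance-explained shares, and methods for the downstream
analyses (morphology association with surrogate permutation nulls,
geometric distance dependence, winner-take-all network correspondence, and
percentile-bin behavioral decoding).
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from . import connectivity as conn
from . import decoding as dec
from . import embedding as emb
from . import parcellation as parc
from . import spatial_stats as sps
from .synthetic import SyntheticDataset, hemisphere_labels

__all__ = ["GradientModel", "GradientResults"]


class GradientModel:
    """Seed-region functional gradient model.

    Parameters
    ----------
    bold : BoldGroupMatrix
        Standardized group time courses covering seed and target voxels.
    seed_mask, brain_mask : 3D boolean arrays
        The seed region and the (disjoint) target set.
    sparsity : float
        Fraction of connections retained per connectivity row (default
        0.10; 0.20/0.30 are the conventional sensitivity settings).
    alpha : float
        Diffusion-embedding density-normalization exponent (default 0.5).
    n_components : int
        Number of gradients retained (default 40).
    diffusion_time : "automatic" or non-negative float
        Eigenvalue scaling rule of the embedding coordinates.
    affine : (4, 4) array, optional
        Voxel-to-world transform used for mm distances; identity when
        omitted.
    """

    def __init__(
        self,
        bold: conn.BoldGroupMatrix,
        seed_mask: np.ndarray,
        brain_mask: np.ndarray,
        *,
        sparsity: float = 0.10,
        alpha: float = 0.5,
        n_components: int = 40,
        diffusion_time: float | str = "automatic",
        affine: np.ndarray | None = None,
    ):
        self.bold = bold
        self.seed_mask = np.asarray(seed_mask, dtype=bool)
        self.brain_mask = np.asarray(brain_mask, dtype=bool)
        self.sparsity = float(sparsity)
        self.diffusion = emb.DiffusionConfig(
            alpha=alpha, n_components=n_components, diffusion_time=diffusion_time
        )
        self.affine = np.eye(4) if affine is None else np.asarray(affine, dtype=float)

    @classmethod
    def from_dataset(cls, dataset: SyntheticDataset, **kwargs) -> "GradientModel":
        """Build a model from a synthetic dataset (affine included)."""
        kwargs.setdefault("affine", dataset.affine)
        return cls(dataset.bold, dataset.seed_mask, dataset.brain_mask, **kwargs)

    # -- geometry helpers -------------------------------------------------
    @property
    def grid_shape(self) -> tuple:
        return self.bold.grid_shape

    @property
    def seed_index(self) -> np.ndarray:
        return np.argwhere(self.seed_mask)

    def seed_coords_mm(self) -> np.ndarray:
        idx = self.seed_index
        return idx @ self.affine[:3, :3].T + self.affine[:3, 3]

    def fit(self) -> "GradientResults":
        """Run the pipeline and return the fitted results."""
        fc = conn.compute_fc(self.bold, self.seed_mask, self.brain_mask)
        fc_sparse = conn.sparsify_rows(fc, self.sparsity)
        affinity = conn.cosine_affinity(fc_sparse)
        gradients = emb.diffusion_embedding(affinity, self.diffusion)
        return GradientResults(self, fc_sparse, affinity, gradients)


class GradientResults:
    """Fitted gradients with their spectrum and downstream analyses."""

    def __init__(self, model: GradientModel, fc_sparse, affinity, gradients):
        self.model = model
        self.fc_sparse = fc_sparse
        self.affinity = affinity
        self.gradients = gradients

    # -- estimates --------------------------------------------------------
    @property
    def coordinates(self) -> np.ndarray:
        return self.gradients.coordinates

    @property
    def eigenvalues(self) -> np.ndarray:
        return self.gradients.eigenvalues

    @property
    def variance_explained(self) -> np.ndarray:
        return self.gradients.variance_explained

    def seed_map(self, gradient: int = 1) -> sps.SeedMap:
        """Gradient ``g`` as a SeedMap with world coordinates and hemisphere tags."""
        return sps.SeedMap(
            values=self.gradients.gradient(gradient),
            coords_mm=self.model.seed_coords_mm(),
            hemisphere=hemisphere_labels(self.model.seed_index, self.model.grid_shape),
        )

    def as_seed_map(self, values: np.ndarray) -> sps.SeedMap:
        """Wrap an arbitrary per-seed-voxel vector on this model's geometry."""
        return self.seed_map(1).with_values(np.asarray(values, dtype=float))

    def gradient_map(self, gradient: int = 1, background: float = np.nan):
        """Gradient ``g`` written into a NIfTI volume."""
        return emb.gradient_map(
            self.gradients, gradient, self.model.grid_shape, self.model.affine, background
        )

    def spectrum_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "component": np.arange(1, self.eigenvalues.size + 1),
                "eigenvalue": self.eigenvalues,
                "variance_explained": self.variance_explained,
            }
        )

    # -- downstream analyses ----------------------------------------------
    def correlate_with(
        self,
        other,
        gradient: int = 1,
        n_surrogates: int = 5000,
        seed: int | None = None,
        tail: str = "auto",
    ) -> sps.PermutationResult:
        """Cross-voxel correlation of a gradient with another seed map,
        tested against autocorrelation-matched surrogates of the gradient.
        Fix ``tail`` ("greater"/"less") for a planned one-sided hypothesis.
        """
        g = self.seed_map(gradient)
        y = other if isinstance(other, sps.SeedMap) else self.as_seed_map(other)
        surr = sps.generate_surrogates(g, n=n_surrogates, seed=seed)
        return sps.permutation_pvalue(g, y, surr, tail=tail)

    def distance_dependence(
        self,
        gradient: int = 1,
        per_hemisphere: bool = True,
        n_surrogates: int = 5000,
        seed: int | None = None,
    ) -> pd.DataFrame:
        """Correlation of a gradient with distance from its peak voxel.

        Each hemisphere is analyzed independently with its own peak (set
        ``per_hemisphere=False`` for a joint analysis). ``n_surrogates=0``
        skips the permutation test.
        """
        g = self.seed_map(gradient)

        def analyze(sub: sps.SeedMap):
            dist = sps.euclidean_distance_map(sub)
            r = sps.crossvoxel_correlation(sub, dist)
            p = np.nan
            if n_surrogates:
                surr = sps.generate_surrogates(sub, n=n_surrogates, seed=seed)
                # the planned hypothesis is a negative distance dependence
                p = sps.permutation_pvalue(sub, dist, surr, tail="less").p_perm
            return r, p

        rows = []
        if per_hemisphere:
            for h, (r, p) in sps.per_hemisphere(analyze, g).items():
                rows.append({"gradient": gradient, "hemisphere": h, "r": r, "p_perm": p})
        else:
            r, p = analyze(g)
            rows.append({"gradient": gradient, "hemisphere": "both", "r": r, "p_perm": p})
        return pd.DataFrame(rows)

    def parcellate(self, atlas: parc.NetworkAtlas) -> parc.SeedParcellation:
        """Winner-take-all assignment of seed voxels to networks."""
        return parc.winner_take_all(self.model.bold, self.model.seed_mask, atlas)

    def subdivision_profiles(self, parcellation: parc.SeedParcellation, which=(1, 2)) -> pd.DataFrame:
        return parc.subdivision_profiles(parcellation, self.gradients, which=which)

    def decode(
        self,
        terms: dec.TermMapSet,
        gradient: int = 1,
        n_bins: int = 10,
        z_threshold: float = 1.645,
    ) -> dec.BinTermProfile:
        """Percentile-bin behavioral decoding of a gradient."""
        masks = dec.percentile_bins(self.seed_map(gradient), n_bins=n_bins)
        profile = dec.bin_term_profile(masks, terms)
        return dec.filter_terms(profile, z_threshold=z_threshold)

    # -- reporting ---------------------------------------------------------
    def summary(self, n_show: int = 10) -> str:
        """Text summary of the decomposition, statsmodels-style."""
        m = self.model
        lines = []
        w = 58
        lines.append("Functional Gradient Decomposition".center(w))
        lines.append("=" * w)
        lines.append(
            f"Seed voxels: {self.affinity.n_seed:<8d} Targets: {self.fc_sparse.n_targets:<8d} "
            f"Timepoints: {m.bold.n_timepoints}"
        )
        lines.append(
            f"Sparsity: {m.sparsity:<11.2f} alpha: {m.diffusion.alpha:<10.2f} "
            f"components: {self.gradients.n_components}"
        )
        lines.append("-" * w)
        lines.append(f"{'component':>10} {'eigenvalue':>14} {'variance explained':>22}")
        for i in range(min(n_show, self.eigenvalues.size)):
            lines.append(
                f"{i + 1:>10d} {self.eigenvalues[i]:>14.6f} {self.variance_explained[i]:>21.1%}"
            )
        lines.append("=" * w)
        return "\n".join(lines)

    # -- plotting ----------------------------------------------------------
    def plot_variance(self, ax=None, n_show: int = 40):
        from .plotting import plot_variance_explained

        return plot_variance_explained(self, ax=ax, n_show=n_show)

    def plot_scatter(self, gx: int = 1, gy: int = 2, ax=None):
        from .plotting import plot_gradient_scatter

        return plot_gradient_scatter(self, gx=gx, gy=gy, ax=ax)
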