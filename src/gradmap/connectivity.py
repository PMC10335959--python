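"""Seed-to-brain functional connectivity.

Builds the voxel-wise seed-to-target correlation matrix (Fisher-z scale),
sparsifies it row-wise to the strongest connections, and converts the
sparsified rows into a voxel-pair cosine affinity matrix — the input to
diffusion-map embedding.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

#: correlations are clipped to +/-(1 - ATANH_EPS) before the Fisher transform
#: so that degenerate identical series map to a finite (large) z.
ATANH_EPS = 1e-7

__all__ = [
    "BoldGroupMatrix",
    "ConnectivityMatrix",
    "AffinityMatrix",
    "compute_fc",
    "sparsify_rows",
    "cosine_affinity",
]


@dataclass
class BoldGroupMatrix:
    """Group-level BOLD time courses on a voxel grid.

    Parameters
    ----------
    data : ndarray, shape (n_timepoints, n_voxels)
        Concatenated group time courses, one column per voxel.
    voxel_index : ndarray, shape (n_voxels, 3)
        0-based grid coordinate of each column.
    standardized : bool
        Whether each column has been z-scored (mean 0, sd 1). Checked at
        construction time with tolerance 1e-6.
    grid_shape : tuple of int, optional
        Shape of the enclosing 3D grid; inferred from ``voxel_index`` when
        omitted.
    """

    data: np.ndarray
    voxel_index: np.ndarray
    standardized: bool = False
    grid_shape: tuple | None = None
    _lookup: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.voxel_index = np.asarray(self.voxel_index, dtype=int)
        if self.data.ndim != 2:
            raise ValueError("data must be a (time x voxel) matrix")
        if self.voxel_index.shape != (self.data.shape[1], 3):
            raise ValueError("voxel_index must have one 3D coordinate per column")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("BOLD matrix contains non-finite values")
        if self.grid_shape is None:
            self.grid_shape = tuple(int(m) + 1 for m in self.voxel_index.max(axis=0))
        else:
            self.grid_shape = tuple(int(s) for s in self.grid_shape)
        if self.standardized:
            mu = self.data.mean(axis=0)
            sd = self.data.std(axis=0)
            if np.abs(mu).max() > 1e-6 or np.abs(sd - 1.0).max() > 1e-6:
                raise ValueError(
                    "standardized=True but columns are not z-scored "
                    f"(max |mean| = {np.abs(mu).max():.2e}, "
                    f"max |sd - 1| = {np.abs(sd - 1.0).max():.2e})"
                )

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.data.shape[1]

    def _index_volume(self) -> np.ndarray:
        if self._lookup is None:
            vol = np.full(self.grid_shape, -1, dtype=int)
            vol[tuple(self.voxel_index.T)] = np.arange(self.n_voxels)
            self._lookup = vol
        return self._lookup

    def columns_for(self, mask: np.ndarray) -> np.ndarray:
        """Column indices of the voxels selected by a boolean 3D mask.

        Columns are returned in the C-scan order of the mask.
        """
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != self.grid_shape:
            raise ValueError(f"mask shape {mask.shape} != grid shape {self.grid_shape}")
        cols = self._index_volume()[mask]
        if np.any(cols < 0):
            missing = np.argwhere(mask)[cols < 0][:3]
            raise ValueError(f"mask selects voxels with no time course, e.g. {missing.tolist()}")
        return cols


@dataclass
class ConnectivityMatrix:
    """Seed-voxel x target-voxel connectivity on the Fisher-z scale."""

    values: np.ndarray
    seed_index: np.ndarray
    target_index: np.ndarray
    sparsified_fraction: float | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.seed_index = np.asarray(self.seed_index, dtype=int)
        self.target_index = np.asarray(self.target_index, dtype=int)
        if self.values.shape != (len(self.seed_index), len(self.target_index)):
            raise ValueError("values shape inconsistent with voxel index lists")

    @property
    def n_seed(self) -> int:
        return self.values.shape[0]

    @property
    def n_targets(self) -> int:
        return self.values.shape[1]


@dataclass
class AffinityMatrix:
    """Symmetric non-negative seed-voxel pair affinity, entries in [0, 1]."""

    values: np.ndarray
    seed_index: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.seed_index = np.asarray(self.seed_index, dtype=int)
        self.validate()

    def validate(self) -> None:
        a = self.values
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("affinity must be square")
        if np.abs(a - a.T).max() > 1e-12:
            raise ValueError("affinity is not symmetric within 1e-12")
        if a.min() < 0:
            raise ValueError("affinity has negative entries")
        if np.abs(np.diag(a) - 1.0).max() > 1e-12:
            raise ValueError("affinity diagonal is not 1")

    @property
    def n_seed(self) -> int:
        return self.values.shape[0]


def compute_fc(bold: BoldGroupMatrix, seed_mask: np.ndarray, brain_mask: np.ndarray) -> ConnectivityMatrix:
    """Pearson correlation of every seed voxel with every target voxel,
    Fisher z-transformed.

    ``brain_mask`` defines the target set and must not overlap the seed
    region (targets exclude the seed, as in seed-to-rest-of-brain
    connectivity). Correlations are clipped to +/-(1 - 1e-7) before
    ``atanh`` so identical series yield a finite z.
    """
    seed_mask = np.asarray(seed_mask, dtype=bool)
    brain_mask = np.asarray(brain_mask, dtype=bool)
    if np.any(seed_mask & brain_mask):
        n_ov = int(np.sum(seed_mask & brain_mask))
        raise ValueError(f"seed and target masks overlap in {n_ov} voxels; targets must exclude the seed")
    if bold.n_timepoints < 3:
        raise ValueError("need at least 3 timepoints for correlation")

    seed_cols = bold.columns_for(seed_mask)
    targ_cols = bold.columns_for(brain_mask)
    X = bold.data[:, seed_cols]
    Y = bold.data[:, targ_cols]

    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    nx = np.linalg.norm(Xc, axis=0)
    ny = np.linalg.norm(Yc, axis=0)
    for norms, mask, kind in ((nx, seed_mask, "seed"), (ny, brain_mask, "target")):
        if np.any(norms == 0):
            bad = np.argwhere(mask)[norms == 0][0]
            raise ValueError(f"zero-variance {kind} voxel at grid index {tuple(bad)}")

    r = (Xc.T @ Yc) / np.outer(nx, ny)
    z = np.arctanh(np.clip(r, -1.0 + ATANH_EPS, 1.0 - ATANH_EPS))
    return ConnectivityMatrix(
        values=z,
        seed_index=np.argwhere(seed_mask),
        target_index=np.argwhere(brain_mask),
    )


def sparsify_rows(fc: ConnectivityMatrix, fraction: float, absolute: bool = False) -> ConnectivityMatrix:
    """Retain the top ``fraction`` of connections per row, zero the rest.

    Ranking is by signed value by default (``absolute=True`` ranks by
    magnitude instead). k = round(fraction * n_targets), at least 1. Ties at
    the cutoff are broken toward the lower target-voxel index so the
    operation is deterministic. Because ``atanh`` is monotone, ranking
    Fisher-z values is equivalent to ranking raw correlations.

    Re-applying the same fraction to an already-sparsified matrix returns an
    unchanged copy: the operation is idempotent. (For rows whose retained
    values are all positive this follows from the ranking itself; when
    negative values survive the cut — possible when k exceeds the number of
    positive entries, in which case a warning is emitted — literal
    re-ranking would prefer the introduced zeros, so the recorded
    ``sparsified_fraction`` short-circuits.)
    """
    if not (0.0 < fraction <= 1.0):
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    if fc.sparsified_fraction is not None and math.isclose(fc.sparsified_fraction, fraction):
        return ConnectivityMatrix(fc.values.copy(), fc.seed_index, fc.target_index, fc.sparsified_fraction)

    n = fc.n_targets
    k = max(1, int(math.floor(fraction * n + 0.5)))
    key = np.abs(fc.values) if absolute else fc.values
    order = np.argsort(-key, axis=1, kind="stable")  # stable: ties keep lower index first
    keep = np.zeros_like(fc.values, dtype=bool)
    np.put_along_axis(keep, order[:, :k], True, axis=1)
    out = np.where(keep, fc.values, 0.0)
    if not absolute and np.any(out[keep] < 0):
        warnings.warn(
            "negative correlations survive the top-fraction cut in some rows "
            "(fraction exceeds the share of positive connections)",
            stacklevel=2,
        )
    return ConnectivityMatrix(out, fc.seed_index, fc.target_index, sparsified_fraction=fraction)


def cosine_affinity(fc_sparse: ConnectivityMatrix) -> AffinityMatrix:
    """Cosine similarity between all pairs of (sparsified) connectivity rows.

    For rows that are non-negative after thresholding the result lies in
    [0, 1]; tiny float negatives are clipped to 0, larger negatives (only
    possible when negative connections survived sparsification) are clipped
    with a warning. Diagonal is set to exactly 1.
    """
    V = fc_sparse.values
    norms = np.linalg.norm(V, axis=1)
    if np.any(norms == 0):
        bad = fc_sparse.seed_index[norms == 0][0]
        raise ValueError(f"all-zero connectivity row for seed voxel at grid index {tuple(bad)}")
    Vn = V / norms[:, None]
    A = Vn @ Vn.T
    A = 0.5 * (A + A.T)
    if A.min() < -1e-6:
        warnings.warn(
            f"negative profile similarities down to {A.min():.3g} clipped to 0",
            stacklevel=2,
        )
    np.clip(A, 0.0, 1.0, out=A)
    np.fill_diagonal(A, 1.0)
    return AffinityMatrix(values=A, seed_index=fc_sparse.seed_index)
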