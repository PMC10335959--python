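"""Diffusion-map embedding of a voxel-pair affinity matrix into gradients.

The affinity matrix W is density-normalized with exponent alpha
(W' = D^-a W D^-a), row-normalized into a Markov transition matrix P, and
eigendecomposed. The non-trivial eigenvectors, ordered by descending
eigenvalue and scaled by an eigenvalue term, are the functional gradients;
the eigenvalue spectrum yields per-gradient variance-explained shares.

alpha controls the influence of sampling density on the manifold geometry
(0 = maximal, 1 = none); 0.5 is the conventional choice for functional
connectivity data.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
import scipy.sparse
import scipy.sparse.csgraph
import scipy.sparse.linalg

from .connectivity import AffinityMatrix

__all__ = [
    "DiffusionConfig",
    "GradientSet",
    "diffusion_embedding",
    "variance_explained",
    "gradient_map",
    "extract_gradient",
]

#: below this matrix size the dense symmetric eigensolver is used; above it,
#: an iterative Lanczos solver with a fixed deterministic start vector.
DENSE_LIMIT = 500


@dataclass(frozen=True)
class DiffusionConfig:
    """Settings of the diffusion embedding.

    alpha : anisotropic-normalization exponent in [0, 1].
    n_components : number of gradients to retain (clamped to n_seed - 1).
    diffusion_time : "automatic" uses the multi-scale lambda/(1-lambda)
        scaling; a non-negative number t uses lambda**t.
    variance_definition : "eigenvalue" (shares proportional to lambda) or
        "squared" (proportional to lambda**2).
    """

    alpha: float = 0.5
    n_components: int = 40
    diffusion_time: float | str = "automatic"
    variance_definition: str = "eigenvalue"

    def __post_init__(self):
        if not (0.0 <= self.alpha <= 1.0):
            raise ValueError(f"alpha must be in [0, 1], got {self.alpha}")
        if self.n_components < 1:
            raise ValueError("n_components must be positive")
        if isinstance(self.diffusion_time, str):
            if self.diffusion_time != "automatic":
                raise ValueError("diffusion_time must be a number or 'automatic'")
        elif self.diffusion_time < 0:
            raise ValueError("diffusion_time must be non-negative")
        if self.variance_definition not in ("eigenvalue", "squared"):
            raise ValueError("variance_definition must be 'eigenvalue' or 'squared'")


@dataclass
class GradientSet:
    """Embedding coordinates and spectrum of a diffusion-map decomposition.

    coordinates : (n_seed, k) matrix; column g-1 is gradient g.
    eigenvectors : the unit-norm non-trivial eigenvectors of P (unscaled).
    eigenvalues : descending, trivial unit eigenvalue excluded.
    variance_explained : per-gradient share of the retained spectrum.
    seed_index : (n_seed, 3) grid coordinates of the seed voxels.
    """

    coordinates: np.ndarray
    eigenvectors: np.ndarray
    eigenvalues: np.ndarray
    variance_explained: np.ndarray
    seed_index: np.ndarray

    def __post_init__(self):
        ev = self.eigenvalues
        if np.any(ev > 1.0 + 1e-9):
            raise ValueError("non-trivial eigenvalues must be < 1")
        if np.any(np.diff(ev) > 1e-12):
            raise ValueError("eigenvalues must be sorted descending")

    @property
    def n_components(self) -> int:
        return self.coordinates.shape[1]

    def gradient(self, g: int) -> np.ndarray:
        """Coordinates of gradient ``g`` (1-based)."""
        if not (1 <= g <= self.n_components):
            raise IndexError(f"gradient index {g} out of range 1..{self.n_components}")
        return self.coordinates[:, g - 1]


def _markov_spectrum_dense(W: np.ndarray, alpha: float, k: int):
    d = W.sum(axis=1)
    da = d ** alpha
    W1 = W / np.outer(da, da)
    d1 = W1.sum(axis=1)
    s = np.sqrt(d1)
    M = W1 / np.outer(s, s)  # symmetric matrix similar to the Markov matrix P
    n = W.shape[0]
    if n <= DENSE_LIMIT:
        evals, evecs = scipy.linalg.eigh(M)
        evals = evals[::-1][: k + 1]
        evecs = evecs[:, ::-1][:, : k + 1]
    else:
        v0 = np.full(n, 1.0 / np.sqrt(n))
        evals, evecs = scipy.sparse.linalg.eigsh(M, k=k + 1, which="LA", v0=v0)
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
    # right eigenvectors of P = D1^-1 W1, normalized to unit Euclidean norm
    V = evecs / s[:, None]
    V /= np.linalg.norm(V, axis=0)
    return evals, V


def _fix_signs(V: np.ndarray) -> np.ndarray:
    """Make the entry of largest magnitude in each column positive."""
    idx = np.argmax(np.abs(V), axis=0)
    signs = np.sign(V[idx, np.arange(V.shape[1])])
    signs[signs == 0] = 1.0
    return V * signs


def diffusion_embedding(affinity: AffinityMatrix, config: DiffusionConfig | None = None) -> GradientSet:
    """Diffusion-map embedding of an affinity matrix.

    Raises if the affinity graph is disconnected (the Markov chain would
    not have a unique stationary distribution, and gradients across
    components are meaningless).

    Deterministic given the input; eigenvector sign is fixed so that the
    seed voxel with the largest-magnitude coordinate on each gradient is
    positive.
    """
    if config is None:
        config = DiffusionConfig()
    W = affinity.values
    n = W.shape[0]

    ncomp, labels = scipy.sparse.csgraph.connected_components(
        scipy.sparse.csr_matrix(W > 0), directed=False
    )
    if ncomp > 1:
        sizes = np.bincount(labels).tolist()
        raise ValueError(f"affinity graph is disconnected: {ncomp} components with sizes {sizes}")

    k = min(config.n_components, n - 1)
    evals, V = _markov_spectrum_dense(W, config.alpha, k)

    if abs(evals[0] - 1.0) > 1e-6:
        raise ValueError(f"leading eigenvalue {evals[0]:.6f} != 1; eigensolver did not converge")
    lam = np.clip(evals[1:], None, 1.0 - 1e-12)
    vecs = _fix_signs(V[:, 1:])

    if config.diffusion_time == "automatic":
        scale = lam / (1.0 - lam)
    else:
        scale = lam ** float(config.diffusion_time)
    coords = vecs * scale

    return GradientSet(
        coordinates=coords,
        eigenvectors=vecs,
        eigenvalues=lam,
        variance_explained=variance_explained(lam, definition=config.variance_definition),
        seed_index=np.asarray(affinity.seed_index, dtype=int),
    )


def variance_explained(eigenvalues: np.ndarray, definition: str = "eigenvalue") -> np.ndarray:
    """Per-gradient variance-explained shares from the non-trivial spectrum.

    share_g = lambda_g / sum(lambda) over the retained components (or
    lambda^2-proportional with ``definition="squared"``). Shares sum to 1
    over the retained spectrum and inherit the descending order. Negative
    eigenvalues (possible when the affinity is not positive semidefinite)
    contribute zero variance.
    """
    lam = np.asarray(eigenvalues, dtype=float)
    if lam.size == 0:
        raise ValueError("empty eigenvalue spectrum")
    if np.any(np.diff(lam) > 1e-12):
        raise ValueError("eigenvalues must be sorted descending")
    w = lam ** 2 if definition == "squared" else np.clip(lam, 0.0, None)
    total = w.sum()
    if total <= 0:
        raise ValueError(f"spectrum sums to {total}; variance shares undefined")
    return w / total


def gradient_map(
    gradients: GradientSet,
    g: int,
    grid_shape: tuple,
    affine: np.ndarray | None = None,
    background: float = np.nan,
):
    """Write gradient ``g`` into the seed voxels of a NIfTI volume.

    Background voxels are NaN by default (pass ``background=0.0`` for
    viewers that dislike NaN). The operation is invertible: see
    :func:`extract_gradient`.
    """
    import nibabel as nib

    vals = gradients.gradient(g)
    vol = np.full(tuple(grid_shape), background, dtype=float)
    vol[tuple(gradients.seed_index.T)] = vals
    if affine is None:
        affine = np.eye(4)
    return nib.Nifti1Image(vol, affine)


def extract_gradient(img_or_volume, seed_index: np.ndarray) -> np.ndarray:
    """Read gradient values back out of a volume at the given seed voxels."""
    vol = np.asanyarray(img_or_volume.dataobj) if hasattr(img_or_volume, "dataobj") else np.asarray(img_or_volume)
    return np.asarray(vol[tuple(np.asarray(seed_index, dtype=int).T)], dtype=float)
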