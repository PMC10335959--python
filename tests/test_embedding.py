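"""Diffusion embedding against a brute-force dense oracle, plus map I/O."""
import numpy as np
import pytest
import scipy.linalg

import gradmap as gm
from gradmap.connectivity import AffinityMatrix
from gradmap.embedding import DiffusionConfig, extract_gradient, gradient_map


def random_affinity(n, rng):
    """A random symmetric positive affinity with unit diagonal."""
    X = rng.random((n, n))
    A = 0.5 * (X + X.T)
    np.fill_diagonal(A, 1.0)
    idx = np.stack([np.arange(n), np.zeros(n, int), np.zeros(n, int)], 1)
    return AffinityMatrix(A, idx)


def dense_oracle(W, alpha, n_components, diffusion_time="automatic"):
    """Brute-force reference: explicit alpha-normalization, explicit Markov
    matrix, full non-symmetric eigendecomposition of P."""
    d = W.sum(axis=1)
    W1 = W / np.outer(d**alpha, d**alpha)
    P = W1 / W1.sum(axis=1)[:, None]
    evals, evecs = scipy.linalg.eig(P)
    evals, evecs = np.real(evals), np.real(evecs)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    lam = evals[1 : n_components + 1]
    V = evecs[:, 1 : n_components + 1]
    V = V / np.linalg.norm(V, axis=0)
    scale = lam / (1 - lam) if diffusion_time == "automatic" else lam ** diffusion_time
    return V * scale, lam


def align_signs(A, B):
    """Flip columns of B to the sign that best matches A."""
    signs = np.sign(np.sum(A * B, axis=0))
    signs[signs == 0] = 1
    return B * signs


@pytest.mark.parametrize("alpha", [0.0, 0.5, 1.0])
def test_embedding_matches_dense_oracle(alpha):
    rng = np.random.default_rng(42)
    for _ in range(10):
        n = int(rng.integers(10, 51))
        aff = random_affinity(n, rng)
        g = gm.diffusion_embedding(aff, DiffusionConfig(alpha=alpha, n_components=5))
        ref, lam = dense_oracle(aff.values, alpha, 5)
        assert np.allclose(g.eigenvalues, lam, atol=1e-10)
        assert np.max(np.abs(g.coordinates - align_signs(g.coordinates, ref))) < 1e-8


def test_fixed_diffusion_time_scaling():
    rng = np.random.default_rng(3)
    aff = random_affinity(20, rng)
    g = gm.diffusion_embedding(aff, DiffusionConfig(n_components=4, diffusion_time=2.0))
    ref, _ = dense_oracle(aff.values, 0.5, 4, diffusion_time=2.0)
    assert np.max(np.abs(g.coordinates - align_signs(g.coordinates, ref))) < 1e-8


def test_two_block_affinity_separates_blocks():
    n = 16
    W = np.full((n, n), 1e-3)
    W[:8, :8] = 1.0
    W[8:, 8:] = 1.0
    np.fill_diagonal(W, 1.0)
    idx = np.stack([np.arange(n), np.zeros(n, int), np.zeros(n, int)], 1)
    g = gm.diffusion_embedding(AffinityMatrix(W, idx), DiffusionConfig(n_components=3))
    g1 = g.gradient(1)
    assert len(set(np.sign(g1[:8]))) == 1
    assert len(set(np.sign(g1[8:]))) == 1
    assert np.sign(g1[0]) != np.sign(g1[-1])


def test_permutation_equivariance():
    rng = np.random.default_rng(7)
    aff = random_affinity(25, rng)
    perm = rng.permutation(25)
    aff_p = AffinityMatrix(aff.values[np.ix_(perm, perm)], aff.seed_index[perm])
    a = gm.diffusion_embedding(aff, DiffusionConfig(n_components=4))
    b = gm.diffusion_embedding(aff_p, DiffusionConfig(n_components=4))
    assert np.max(np.abs(b.coordinates - align_signs(b.coordinates, a.coordinates[perm]))) < 1e-8


def test_sign_convention_largest_magnitude_positive(ref_results):
    C = ref_results.coordinates
    peak = np.argmax(np.abs(C), axis=0)
    assert np.all(C[peak, np.arange(C.shape[1])] > 0)


def test_disconnected_graph_raises():
    W = np.eye(10)
    W[:5, :5] = 1.0
    W[5:, 5:] = 1.0
    idx = np.stack([np.arange(10), np.zeros(10, int), np.zeros(10, int)], 1)
    with pytest.raises(ValueError, match="disconnected.*sizes"):
        gm.diffusion_embedding(AffinityMatrix(W, idx))


def test_variance_explained_shares():
    shares = gm.variance_explained(np.array([0.5, 0.25, 0.25]))
    assert np.allclose(shares, [0.5, 0.25, 0.25])
    # scale invariance
    assert np.allclose(gm.variance_explained(np.array([4.0, 2.0, 2.0]) * 0.13), [0.5, 0.25, 0.25])
    with pytest.raises(ValueError):
        gm.variance_explained(np.array([]))
    with pytest.raises(ValueError):
        gm.variance_explained(np.array([-1.0, -2.0]))
    with pytest.raises(ValueError, match="descending"):
        gm.variance_explained(np.array([0.1, 0.5]))


def test_variance_shares_descending_on_reference(ref_results):
    ve = ref_results.variance_explained
    assert ve[0] > ve[1] > ve[2]
    assert np.all(np.diff(ve) <= 1e-12)
    assert ve.sum() == pytest.approx(1.0)


def test_gradient_map_roundtrip(ref_results, ref_dataset):
    img = ref_results.gradient_map(1)
    vol = np.asanyarray(img.dataobj)
    # support equals the seed mask exactly
    assert np.array_equal(~np.isnan(vol), ref_dataset.seed_mask)
    back = extract_gradient(img, ref_results.gradients.seed_index)
    assert np.array_equal(back, ref_results.gradients.gradient(1))
    with pytest.raises(IndexError):
        ref_results.gradients.gradient(0)
    with pytest.raises(IndexError):
        ref_results.gradients.gradient(10_000)


def test_gradient_map_monotone_along_planted_axis(noiseless_results, noiseless_dataset):
    from scipy.stats import spearmanr

    g1 = noiseless_results.gradients.gradient(1)
    proj = noiseless_dataset.seed_coords_mm @ np.asarray(noiseless_dataset.config.gradient_axes[0])
    rho = spearmanr(g1, proj).statistic
    assert abs(rho) > 0.9


def test_stability_to_pruning_small_affinities(ref_results):
    W = ref_results.affinity.values.copy()
    off = W[np.triu_indices_from(W, k=1)]
    cut = np.quantile(off[off > 0], 0.01)
    W2 = np.where(W <= cut, 0.0, W)
    np.fill_diagonal(W2, 1.0)
    g2 = gm.diffusion_embedding(
        AffinityMatrix(0.5 * (W2 + W2.T), ref_results.affinity.seed_index),
        DiffusionConfig(n_components=5),
    )
    r = np.corrcoef(g2.gradient(1), ref_results.gradients.gradient(1))[0, 1]
    assert abs(r) > 0.99
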