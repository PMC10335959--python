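"""Connectivity, sparsification and affinity contracts."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import gradmap as gm
from gradmap.connectivity import ATANH_EPS, BoldGroupMatrix, ConnectivityMatrix


def _tiny_bold(series):
    """Time courses on a 1D row of voxels; seed is voxel 0, targets the rest."""
    data = np.asarray(series, dtype=float).T
    n = data.shape[1]
    idx = np.stack([np.arange(n), np.zeros(n, int), np.zeros(n, int)], axis=1)
    bold = BoldGroupMatrix(data, idx, standardized=False, grid_shape=(n, 1, 1))
    seed = np.zeros((n, 1, 1), bool)
    seed[0] = True
    brain = ~seed
    return bold, seed, brain


def test_fc_matches_hand_pearson():
    # x = (1,2,3,4), y = (2,1,4,3): r = 0.6 by the covariance formula
    bold, seed, brain = _tiny_bold([[1, 2, 3, 4], [2, 1, 4, 3], [4, 3, 2, 1]])
    fc = gm.compute_fc(bold, seed, brain)
    assert fc.values.shape == (1, 2)
    assert fc.values[0, 0] == pytest.approx(np.arctanh(0.6), abs=1e-12)
    assert fc.values[0, 1] == pytest.approx(np.arctanh(-1 + ATANH_EPS), abs=1e-9)


def test_identical_series_give_finite_large_z():
    bold, seed, brain = _tiny_bold([[1, 2, 3, 4], [1, 2, 3, 4]])
    fc = gm.compute_fc(bold, seed, brain)
    assert np.isfinite(fc.values[0, 0])
    assert fc.values[0, 0] == pytest.approx(np.arctanh(1 - ATANH_EPS))


def test_fc_scale_invariance():
    rng = np.random.default_rng(0)
    series = rng.standard_normal((5, 12))
    bold, seed, brain = _tiny_bold(series)
    bold2, _, _ = _tiny_bold(3.7 * series)
    a = gm.compute_fc(bold, seed, brain)
    b = gm.compute_fc(bold2, seed, brain)
    assert np.allclose(a.values, b.values, atol=1e-12)


def test_fc_errors():
    bold, seed, brain = _tiny_bold([[1, 2, 3, 4], [5, 5, 5, 5]])
    with pytest.raises(ValueError, match="zero-variance"):
        gm.compute_fc(bold, seed, brain)
    with pytest.raises(ValueError, match="overlap"):
        gm.compute_fc(bold, seed, np.ones_like(brain))
    short, seed2, brain2 = _tiny_bold([[1, 2], [2, 1]])
    with pytest.raises(ValueError, match="timepoints"):
        gm.compute_fc(short, seed2, brain2)


def test_fc_shape_matches_masks(small_dataset):
    # the shape contract: (n seed voxels) x (n target voxels)
    fc = gm.compute_fc(small_dataset.bold, small_dataset.seed_mask, small_dataset.brain_mask)
    assert fc.values.shape == (
        int(small_dataset.seed_mask.sum()),
        int(small_dataset.brain_mask.sum()),
    )


def _row_matrix(rows):
    rows = np.atleast_2d(np.asarray(rows, dtype=float))
    ns, nt = rows.shape
    seed_idx = np.stack([np.arange(ns), np.zeros(ns, int), np.zeros(ns, int)], 1)
    targ_idx = np.stack([np.arange(nt), np.ones(nt, int), np.zeros(nt, int)], 1)
    return ConnectivityMatrix(rows, seed_idx, targ_idx)


def test_sparsify_example_row():
    fc = _row_matrix([[5, 4, 3, 2, 1, 0, -1, -2, -3, -4]])
    out = gm.sparsify_rows(fc, 0.2)
    expected = np.zeros(10)
    expected[:2] = [5, 4]
    assert np.array_equal(out.values[0], expected)


def test_sparsify_tie_rule_keeps_lowest_indices():
    fc = _row_matrix([np.ones(10)])
    out = gm.sparsify_rows(fc, 0.3)
    assert np.array_equal(np.flatnonzero(out.values[0]), [0, 1, 2])


@settings(deadline=None, derandomize=True, max_examples=30)
@given(st.integers(0, 10_000))
def test_sparsify_matches_sort_oracle_and_nests(seed):
    rng = np.random.default_rng(seed)
    rows = rng.standard_normal((4, 37))
    fc = _row_matrix(rows)
    prev_support = None
    for frac in (0.10, 0.20, 0.30):
        out = gm.sparsify_rows(fc, frac)
        k = int(np.floor(frac * 37 + 0.5))
        support = out.values != 0
        assert np.all(support.sum(axis=1) == k)
        for i in range(rows.shape[0]):
            # brute-force oracle: k largest by (value desc, index asc)
            order = sorted(range(37), key=lambda j: (-rows[i, j], j))
            assert set(np.flatnonzero(support[i])) == set(order[:k])
            # every retained value >= every zeroed value
            assert rows[i][support[i]].min() >= rows[i][~support[i]].max()
        if prev_support is not None:
            assert np.all(support[prev_support])  # nesting across fractions
        prev_support = support


def test_sparsify_idempotent():
    rng = np.random.default_rng(1)
    fc = _row_matrix(np.abs(rng.standard_normal((3, 20))))
    once = gm.sparsify_rows(fc, 0.2)
    twice = gm.sparsify_rows(once, 0.2)
    assert np.array_equal(once.values, twice.values)


def test_sparsify_invalid_fraction():
    fc = _row_matrix([[1.0, 2.0]])
    for frac in (0.0, -0.1, 1.2):
        with pytest.raises(ValueError):
            gm.sparsify_rows(fc, frac)


def test_sparsify_warns_when_negatives_survive():
    fc = _row_matrix([[-1.0, -2.0, -3.0, -4.0]])
    with pytest.warns(UserWarning, match="negative"):
        gm.sparsify_rows(fc, 0.5)


def test_cosine_affinity_examples():
    fc = _row_matrix([[1, 1, 0], [1, 0, 1], [0, 2, 0], [2, 2, 0]])
    aff = gm.cosine_affinity(fc)
    assert aff.values[0, 1] == pytest.approx(0.5)  # (1,1,0) . (1,0,1) / (sqrt2*sqrt2)
    assert aff.values[1, 2] == pytest.approx(0.0)  # disjoint support
    assert aff.values[0, 3] == pytest.approx(1.0)  # proportional rows
    assert np.all(np.diag(aff.values) == 1.0)


def test_cosine_affinity_zero_row_error():
    fc = _row_matrix([[1, 2, 3], [0, 0, 0]])
    with pytest.raises(ValueError, match="all-zero"):
        gm.cosine_affinity(fc)


def test_pipeline_affinity_invariants(ref_results):
    a = ref_results.affinity.values
    assert np.abs(a - a.T).max() <= 1e-12
    assert a.min() >= 0.0
    assert a.max() <= 1.0
    assert np.all(np.diag(a) == 1.0)
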