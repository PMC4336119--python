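import math

import numpy as np
import pytest
import scipy.linalg
import scipy.sparse as sp

from thynseg import (
    AffinityGraph,
    AffinityParams,
    build_weight_matrix,
    discretize_fiedler,
    ncut_value,
    recursive_ncut,
    solve_fiedler,
)
from thynseg.ncut import best_spectral_split, solve_smallest


def exhaustive_min_ncut(graph):
    """Brute-force minimum over all 2^(n-1)-1 bipartitions."""
    n = graph.n_nodes
    best = math.inf
    best_mask = None
    for bits in range(1, 2 ** (n - 1)):
        mask = np.array([(bits >> i) & 1 for i in range(n)], dtype=bool)
        val = ncut_value(graph, mask)
        if val < best:
            best, best_mask = val, mask
    return best, best_mask


def barbell_graph():
    """Two tight pairs joined by a weak bridge; unit self-loops."""
    W = np.eye(4)
    W[0, 1] = W[1, 0] = 1.0
    W[2, 3] = W[3, 2] = 1.0
    W[1, 2] = W[2, 1] = 0.01
    return AffinityGraph.from_matrix(W)


def random_graph(rng, n, density=0.6):
    W = rng.random((n, n)) * (rng.random((n, n)) < density)
    W = np.triu(W, 1)
    W = W + W.T + np.eye(n)
    for i in range(n):  # weak ring guarantees connectivity
        j = (i + 1) % n
        if W[i, j] == 0:
            W[i, j] = W[j, i] = 0.05
    return AffinityGraph.from_matrix(W)


class TestBuildWeightMatrix:
    def test_adjacent_identical_pixels_weight(self):
        img = np.full((8, 128), 0.5)
        g = build_weight_matrix(img, AffinityParams())
        expected = math.exp(-((1 / 128) ** 2) / 0.1**2)
        assert g.weights[0, 1] == pytest.approx(expected, abs=1e-9)
        assert expected == pytest.approx(0.99391, abs=1e-5)

    def test_zero_beyond_radius_and_unit_selfloops(self, rng):
        img = rng.random((10, 10))
        g = build_weight_matrix(img, AffinityParams(radius=2.0))
        W = g.weights.toarray()
        np.testing.assert_array_equal(np.diag(W), 1.0)
        idx = np.arange(100)
        rr, cc = idx // 10, idx % 10
        dist = np.hypot(rr[:, None] - rr[None, :], cc[:, None] - cc[None, :])
        assert np.all(W[dist > 2.0] == 0.0)
        assert np.all(W[dist <= 2.0] > 0.0)

    def test_symmetry_and_bounds(self, rng):
        g = build_weight_matrix(rng.random((12, 12)), AffinityParams(radius=3))
        W = g.weights
        assert abs(W - W.T).max() < 1e-12
        assert W.data.min() > 0.0 and W.data.max() <= 1.0

    def test_cap_enforced(self, rng):
        with pytest.raises(ValueError, match="cap"):
            build_weight_matrix(rng.random((130, 130)), AffinityParams())


class TestNcutValue:
    def test_disconnected_split_is_zero(self):
        W = np.eye(4)
        W[0, 1] = W[1, 0] = 0.8
        W[2, 3] = W[3, 2] = 0.5
        g = AffinityGraph.from_matrix(W)
        mask = np.array([True, True, False, False])
        assert ncut_value(g, mask) == pytest.approx(0.0, abs=1e-15)

    def test_two_node_closed_form(self):
        w = 0.37
        W = np.array([[1.0, w], [w, 1.0]])
        g = AffinityGraph.from_matrix(W)
        expected = 2 * w / (w + 1)
        assert ncut_value(g, np.array([True, False])) == pytest.approx(expected)

    def test_barbell_value_and_optimality(self):
        g = barbell_graph()
        mask = np.array([True, True, False, False])
        val = ncut_value(g, mask)
        # assoc includes self-loops: assoc({0,1}, V) = 1 + 1 + 1 + 1.01
        assert val == pytest.approx(2 * 0.01 / 4.01, rel=1e-12)
        best, best_mask = exhaustive_min_ncut(g)
        assert best == pytest.approx(val)
        assert np.array_equal(best_mask, mask) or np.array_equal(
            best_mask, ~mask
        )

    def test_symmetry_and_range(self, rng):
        g = random_graph(rng, 8)
        for _ in range(20):
            mask = rng.random(8) < 0.5
            if mask.all() or not mask.any():
                continue
            a = ncut_value(g, mask)
            assert a == pytest.approx(ncut_value(g, ~mask), rel=1e-12)
            assert 0.0 <= a <= 2.0

    def test_empty_side_rejected(self):
        g = barbell_graph()
        with pytest.raises(ValueError):
            ncut_value(g, np.zeros(4, dtype=bool))


class TestFiedler:
    def test_disconnected_components_kernel_vector(self):
        W = np.eye(6)
        W[0, 1] = W[1, 0] = W[1, 2] = W[2, 1] = 0.9
        W[3, 4] = W[4, 3] = W[4, 5] = W[5, 4] = 0.7
        g = AffinityGraph.from_matrix(W)
        y = solve_fiedler(g)
        # lambda_2 = 0: the vector lies in the Laplacian kernel, constant
        # on each component, and thresholding recovers the components
        assert np.ptp(y[:3]) < 1e-8 and np.ptp(y[3:]) < 1e-8
        assert abs(y[0] - y[3]) > 1e-8
        mask = discretize_fiedler(y, g)
        assert ncut_value(g, mask) == pytest.approx(0.0, abs=1e-12)
        assert set(np.flatnonzero(mask)) in ({0, 1, 2}, {3, 4, 5})

    def test_complete_graph_k3_lambda(self):
        W = np.ones((3, 3)) - np.eye(3)
        g = AffinityGraph.from_matrix(W)
        y = solve_fiedler(g)
        L = np.diag(g.degrees) - W
        lam = (y @ L @ y) / (y @ np.diag(g.degrees) @ y)
        assert lam == pytest.approx(1.5, abs=1e-10)

    def test_matches_dense_generalized_oracle(self, rng):
        for _ in range(5):
            g = random_graph(rng, 10)
            y = solve_fiedler(g)
            W = g.weights.toarray()
            L = np.diag(g.degrees) - W
            vals, vecs = scipy.linalg.eigh(L, np.diag(g.degrees))
            ref = vecs[:, 1]
            ref = ref / np.linalg.norm(ref)
            yn = y / np.linalg.norm(y)
            if np.dot(ref, yn) < 0:
                ref = -ref
            assert np.abs(yn - ref).max() < 1e-8

    def test_sparse_path_matches_dense_oracle(self, rng):
        # a graph large enough to exercise the Lanczos branch
        img = rng.random((40, 40))
        g = build_weight_matrix(img, AffinityParams(radius=2.5))
        y = solve_fiedler(g)
        W = g.weights.toarray()
        L = np.diag(g.degrees) - W
        vals, vecs = scipy.linalg.eigh(L, np.diag(g.degrees))
        ref = vecs[:, 1] / np.linalg.norm(vecs[:, 1])
        yn = y / np.linalg.norm(y)
        if np.dot(ref, yn) < 0:
            ref = -ref
        assert np.abs(yn - ref).max() < 1e-7

    def test_sign_convention_first_nonzero_positive(self, rng):
        g = random_graph(rng, 9)
        y = solve_fiedler(g)
        nz = y[np.abs(y) > 1e-12 * np.abs(y).max()]
        assert nz[0] > 0


class TestDiscretize:
    def test_two_component_graph_recovered_exactly(self):
        W = np.eye(7)
        W[np.ix_([0, 1, 2], [0, 1, 2])] = 1.0
        W[np.ix_([3, 4, 5, 6], [3, 4, 5, 6])] = 0.8
        np.fill_diagonal(W, 1.0)
        g = AffinityGraph.from_matrix(W)
        y = solve_fiedler(g)
        mask = discretize_fiedler(y, g)
        assert ncut_value(g, mask) == pytest.approx(0.0, abs=1e-12)
        assert set(np.flatnonzero(mask)) in ({0, 1, 2}, {3, 4, 5, 6})

    def test_barbell_optimum_recovered(self):
        g = barbell_graph()
        mask = discretize_fiedler(solve_fiedler(g), g)
        assert set(np.flatnonzero(mask)) in ({0, 1}, {2, 3})

    def test_monotone_vector_on_path_matches_exhaustive_thresholds(self):
        n = 10
        W = np.eye(n)
        for i in range(n - 1):
            W[i, i + 1] = W[i + 1, i] = 0.5
        g = AffinityGraph.from_matrix(W)
        y = np.linspace(-1.0, 1.0, n)
        mask = discretize_fiedler(y, g)
        vals = [
            ncut_value(g, y > 0.5 * (y[i] + y[i + 1])) for i in range(n - 1)
        ]
        assert ncut_value(g, mask) == pytest.approx(min(vals), rel=1e-12)

    def test_degenerate_vector_rejected(self):
        g = barbell_graph()
        with pytest.raises(ValueError):
            discretize_fiedler(np.zeros(4), g)


class TestSpectralQuality:
    def test_first_split_near_exhaustive_optimum(self):
        rng = np.random.default_rng(12345)
        for _ in range(30):
            n = int(rng.integers(6, 13))
            g = random_graph(rng, n)
            opt, _ = exhaustive_min_ncut(g)
            mask, val = best_spectral_split(g)
            assert val >= opt - 1e-12
            assert val <= 1.25 * opt + 1e-12


class TestRecursive:
    def test_uniform_image_single_region(self):
        img = np.full((24, 24), 0.5)
        seg = recursive_ncut(img, AffinityParams(radius=5.0))
        assert seg.n_regions == 1
        assert seg.split_ncuts == []
        assert len(seg.rejected_ncuts) == 1

    def test_two_level_image_two_regions(self):
        img = np.full((24, 24), 0.1)
        img[:, 12:] = 0.9
        seg = recursive_ncut(img, AffinityParams(radius=5.0))
        assert seg.n_regions == 2
        left = seg.labels[:, :12]
        right = seg.labels[:, 12:]
        assert np.ptp(left) == 0 and np.ptp(right) == 0
        assert left[0, 0] != right[0, 0]

    def test_labels_form_partition(self):
        img = np.full((20, 20), 0.2)
        img[5:15, 5:15] = 0.8
        seg = recursive_ncut(img, AffinityParams(radius=4.0))
        labels = seg.labels
        assert labels.shape == img.shape
        assert labels.min() == 0
        assert set(np.unique(labels)) == set(range(seg.n_regions))

    def test_accepted_splits_below_threshold(self):
        img = np.full((24, 24), 0.1)
        img[:, 12:] = 0.9
        thr = 0.065
        seg = recursive_ncut(img, AffinityParams(radius=5.0), threshold=thr)
        assert all(v < thr for v in seg.split_ncuts)

    def test_max_regions_respected(self):
        img = np.zeros((24, 24))
        img[:, 8:16] = 0.5
        img[:, 16:] = 1.0
        seg = recursive_ncut(img, AffinityParams(radius=5.0), max_regions=2)
        assert seg.n_regions <= 2
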