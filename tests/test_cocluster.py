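import numpy as np
import pandas as pd
import pytest

from crossclust import cocluster
from crossclust.cocluster import (
    DegeneracyError,
    calinski_harabasz,
    fit_cocluster,
    reorder_blockdiagonal,
    scale_normalize,
    select_k,
    silhouette_score,
)
from crossclust.simulate import adjusted_rand_index
from crossclust.tables import ValidationError

from conftest import block_diagonal


class TestScaleNormalize:
    def test_all_ones_hand_value(self):
        An, d1, d2 = scale_normalize(np.ones((2, 3)), shift="none")
        assert np.allclose(An, 1.0 / np.sqrt(6.0))
        assert np.allclose(d1, 3.0) and np.allclose(d2, 2.0)

    def test_identity_fixed_point(self):
        An, _, _ = scale_normalize(np.eye(3), shift="none")
        assert np.allclose(An, np.eye(3))

    def test_half_shift_maps_correlations_to_unit_interval(self):
        A = np.array([[-1.0, 0.0], [0.5, 1.0]])
        An, d1, d2 = scale_normalize(A, shift="half")
        expected = (A + 1) / 2
        assert np.allclose(An * np.sqrt(d1)[:, None] * np.sqrt(d2)[None, :], expected)

    def test_negative_row_without_shift_is_degenerate(self):
        A = np.array([[-0.5, -0.4], [0.3, 0.2]])
        with pytest.raises(DegeneracyError):
            scale_normalize(A, shift="none")


class TestFitCocluster:
    def test_exact_recovery_small_blockdiag(self):
        A = block_diagonal((2, 3), (2, 3))
        model = fit_cocluster(A, k=2, seed=0, shift="none")
        assert adjusted_rand_index([0, 0, 1, 1, 1], model.row_labels) == 1.0
        assert adjusted_rand_index([0, 0, 1, 1, 1], model.col_labels) == 1.0

    @pytest.mark.parametrize("k,sizes_r,sizes_c", [
        (2, (2, 3), (3, 2)),
        (3, (5, 4, 3), (6, 5, 4)),
        (5, (8, 8, 8, 7, 7), (14, 14, 14, 12, 12)),
    ])
    def test_exact_recovery_constant_blocks(self, k, sizes_r, sizes_c):
        A = block_diagonal(sizes_r, sizes_c)
        model = fit_cocluster(A, k=k, seed=0, shift="none")
        assert adjusted_rand_index(np.repeat(range(k), sizes_r), model.row_labels) == 1.0
        assert adjusted_rand_index(np.repeat(range(k), sizes_c), model.col_labels) == 1.0

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(7)
        A = block_diagonal((4, 5, 3), (5, 4, 6), constants=[1.0, 2.0, 3.0])
        pr, pc = rng.permutation(A.shape[0]), rng.permutation(A.shape[1])
        base = fit_cocluster(A, k=3, seed=0, shift="none")
        perm = fit_cocluster(A[np.ix_(pr, pc)], k=3, seed=0, shift="none")
        assert adjusted_rand_index(np.asarray(base.row_labels)[pr], perm.row_labels) == 1.0
        assert adjusted_rand_index(np.asarray(base.col_labels)[pc], perm.col_labels) == 1.0

    def test_determinism(self):
        rng = np.random.default_rng(8)
        A = rng.normal(size=(12, 15))
        m1 = fit_cocluster(A, k=3, seed=42)
        m2 = fit_cocluster(A, k=3, seed=42)
        assert np.array_equal(m1.row_labels, m2.row_labels)
        assert np.array_equal(m1.col_labels, m2.col_labels)

    def test_k_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            fit_cocluster(np.ones((4, 4)), k=5)

    def test_agrees_with_sklearn_spectral_coclustering(self):
        # independent oracle on a noisy positive block matrix
        from sklearn.cluster import SpectralCoclustering

        rng = np.random.default_rng(9)
        A = block_diagonal((6, 6, 6), (8, 8, 8), constants=[5.0, 5.0, 5.0])
        A = A + rng.uniform(0.01, 0.2, A.shape)
        mine = fit_cocluster(A, k=3, seed=0, shift="none")
        oracle = SpectralCoclustering(n_clusters=3, random_state=0).fit(A)
        assert adjusted_rand_index(mine.row_labels, oracle.row_labels_) == 1.0
        assert adjusted_rand_index(mine.col_labels, oracle.column_labels_) == 1.0


class TestScores:
    def test_silhouette_hand_computed(self):
        pts = np.array([[0.0], [0.1], [10.0], [10.1]])
        s = silhouette_score(pts, [0, 0, 1, 1])
        assert s == pytest.approx(0.990, abs=5e-4)

    def test_silhouette_coincident_clusters_zero(self):
        pts = np.array([[1.0], [1.0], [1.0], [1.0]])
        assert silhouette_score(pts, [0, 0, 1, 1]) == pytest.approx(0.0)

    def test_silhouette_all_singletons_zero_by_convention(self):
        pts = np.arange(4.0).reshape(-1, 1)
        assert silhouette_score(pts, [0, 1, 2, 3]) == 0.0

    def test_silhouette_single_cluster_is_error(self):
        with pytest.raises(ValidationError):
            silhouette_score(np.arange(4.0).reshape(-1, 1), [0, 0, 0, 0])

    def test_calinski_hand_computed(self):
        pts = np.array([[0.0], [1.0], [10.0], [11.0]])
        assert calinski_harabasz(pts, [0, 0, 1, 1]) == pytest.approx(200.0)

    def test_calinski_scale_invariance(self):
        rng = np.random.default_rng(10)
        pts = rng.normal(size=(30, 2))
        labels = rng.integers(0, 3, 30)
        a = calinski_harabasz(pts, labels)
        b = calinski_harabasz(pts * 10.0, labels)
        assert a == pytest.approx(b)

    def test_calinski_null_centered_near_one(self):
        rng = np.random.default_rng(11)
        vals = [
            calinski_harabasz(rng.normal(size=(200, 1)), rng.integers(0, 2, 200))
            for _ in range(100)
        ]
        assert 0.2 < np.mean(vals) < 5.0

    def test_calinski_zero_within_dispersion_is_inf(self):
        pts = np.array([[0.0], [0.0], [5.0], [5.0]])
        with pytest.warns(UserWarning):
            assert calinski_harabasz(pts, [0, 0, 1, 1]) == np.inf


class TestSelectK:
    def test_three_strong_blocks_recovered(self):
        rng = np.random.default_rng(12)
        A = block_diagonal((6, 7, 5), (7, 8, 9), constants=[1.0, 1.2, 0.9])
        A = A + rng.normal(0.0, 0.01, A.shape)
        trace = select_k(A, k_grid=range(2, 9), seed=0)
        assert trace.chosen_k == 3

    def test_single_k_grid_returns_that_k(self):
        A = block_diagonal((4, 4), (4, 4))
        assert select_k(A, k_grid=[3], seed=0).chosen_k == 3

    def test_grid_truncated_to_matrix_size(self):
        A = block_diagonal((3, 3), (3, 3))
        trace = select_k(A, k_grid=range(2, 20), seed=0)
        assert max(trace.k_grid) <= 6


class TestReorder:
    def test_block_ordered_input_identity_permutation(self):
        A = block_diagonal((2, 3), (3, 2))
        model = fit_cocluster(A, k=2, seed=0, shift="none")
        permuted, row_order, col_order, rb, cb = reorder_blockdiagonal(A, model)
        assert sorted(row_order.tolist()) == list(range(5))
        # labels are canonical (first-appearance), so ordering is identity
        assert np.array_equal(permuted.to_numpy(), A)
        assert rb == [2] and cb == [3]

    def test_reversed_input_restores_blocks(self):
        A = block_diagonal((2, 3), (3, 2))
        rev = A[::-1, ::-1]
        model = fit_cocluster(rev, k=2, seed=0, shift="none")
        permuted, *_ = reorder_blockdiagonal(rev, model)
        within = permuted.to_numpy()
        # block structure restored: mean within first block = 1
        assert within[:3, :2].mean() == pytest.approx(1.0)

    def test_within_block_mass_exceeds_cross_block(self, sim_dataset):
        from crossclust.correlation import cross_correlation
        from crossclust.preprocess import (
            FilterSpec,
            add_pseudocount,
            clr_transform,
            prevalence_filter,
        )

        counts, mets, design, bio, truth = sim_dataset
        filtered, _ = prevalence_filter(counts, FilterSpec(), "genera")
        shifted, _ = add_pseudocount(filtered)
        corr = cross_correlation(mets, clr_transform(shifted))
        model = fit_cocluster(corr, k=5, seed=0)
        rho = corr.rho.to_numpy()
        within = [
            rho[np.ix_(model.row_labels == b, model.col_labels == b)].mean()
            for b in range(5)
        ]
        cross = [
            rho[np.ix_(model.row_labels == b, model.col_labels != b)].mean()
            for b in range(5)
        ]
        assert np.mean(within) > np.mean(cross)
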