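import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from dkbcgs import (
    ExpressionDataset,
    GeneWeights,
    KernelParams,
    compute_centers,
    generate,
    objective,
    per_gene_dissimilarity,
    run,
    update_delta_dkbcgs,
    update_delta_kbcgs,
    update_weights,
    zscore_normalize,
)
from dkbcgs.simulate import SyntheticSpec

d_vectors = st.lists(
    st.floats(min_value=0, max_value=20), min_size=2, max_size=10
).map(np.array)


class TestCenters:
    def test_hand_fixture_means(self, tiny_ds):
        cc = compute_centers(tiny_ds)
        assert cc.class_order == ["tumor", "normal"]
        assert cc.class_sizes == [2, 2]
        np.testing.assert_allclose(cc.centers[0], [2.0, 3.0, 0.0], atol=1e-12)
        np.testing.assert_allclose(cc.centers[1], [1.0, 7.0, 2.0], atol=1e-12)

    def test_singleton_class_center_is_the_sample(self):
        ds = ExpressionDataset(
            np.array([[1.0, 2.0], [5.0, 9.0], [7.0, 1.0]]),
            ["a", "b", "c"], ["g1", "g2"], ["x", "y", "y"],
        )
        cc = compute_centers(ds)
        np.testing.assert_array_equal(cc.centers[0], [1.0, 2.0])

    def test_midpoint_of_two_values(self):
        ds = ExpressionDataset(
            np.array([[0.0], [2.0], [5.0], [5.0]]),
            list("abcd"), ["g"], ["x", "x", "y", "y"],
        )
        assert compute_centers(ds).centers[0, 0] == 1.0

    def test_single_class_rejected(self):
        ds = ExpressionDataset(
            np.array([[1.0], [2.0]]), ["a", "b"], ["g"], ["x", "x"]
        )
        with pytest.raises(ValueError, match="2 classes"):
            compute_centers(ds)


class TestDissimilarity:
    def test_samples_equal_centers_give_zero(self):
        ds = ExpressionDataset(
            np.array([[1.0, 2.0], [1.0, 2.0], [4.0, 0.0], [4.0, 0.0]]),
            list("abcd"), ["g1", "g2"], ["x", "x", "y", "y"],
        )
        D = per_gene_dissimilarity(ds, compute_centers(ds), KernelParams())
        np.testing.assert_allclose(D, 0.0, atol=1e-14)

    def test_brute_force_double_loop_oracle(self, tiny_ds):
        """D matches a direct sum of 2(1 - e^{-(x-v)^2}) over all samples."""
        params = KernelParams(gamma1=1.0, gamma2=1.0, c=1.0)  # single RBF
        cc = compute_centers(tiny_ds)
        D = per_gene_dissimilarity(tiny_ds, cc, params)
        for k in range(tiny_ds.l):
            expected = 0.0
            for i, lab in enumerate(cc.class_order):
                for j in np.flatnonzero(tiny_ds.labels == lab):
                    diff = tiny_ds.values[j, k] - cc.centers[i, k]
                    expected += 2.0 * (1.0 - math.exp(-(diff**2)))
            assert D[k] == pytest.approx(expected, abs=1e-12)

    def test_strictly_below_twice_sample_count(self, tiny_ds):
        D = per_gene_dissimilarity(
            tiny_ds, compute_centers(tiny_ds), KernelParams(10.0, 5.0, 0.5)
        )
        assert np.all(D >= 0) and np.all(D < 2 * tiny_ds.n)

    def test_dimension_mismatch_rejected(self, tiny_ds):
        cc = compute_centers(tiny_ds)
        cc.centers = cc.centers[:, :2]
        with pytest.raises(ValueError, match="does not match"):
            per_gene_dissimilarity(tiny_ds, cc, KernelParams())


class TestUpdateWeights:
    def test_equal_dissimilarities_give_uniform_weights(self):
        gw = update_weights(np.full(5, 3.2), delta=0.7)
        np.testing.assert_allclose(gw.w, 0.2, atol=1e-14)

    def test_hand_example_two_genes(self):
        gw = update_weights(np.array([0.0, 2.0]), delta=1.0)
        np.testing.assert_allclose(gw.w, [1.0, 0.0], atol=1e-14)

    def test_clipping_renormalizes_onto_simplex(self):
        gw = update_weights(np.array([0.0, 1.0, 10.0]), delta=0.5)
        np.testing.assert_allclose(gw.w, [4 / 7, 3 / 7, 0.0], atol=1e-12)

    @given(D=d_vectors, delta=st.floats(min_value=1e-3, max_value=1e3))
    def test_simplex_and_anti_monotonicity(self, D, delta):
        gw = update_weights(D, delta)
        assert np.all(gw.w >= 0)
        assert gw.w.sum() == pytest.approx(1.0, abs=1e-10)
        order = np.argsort(D, kind="stable")
        assert np.all(np.diff(gw.w[order]) <= 1e-12)  # smaller D -> larger w

    def test_matches_simplex_grid_minimizer_without_clipping(self):
        """With delta at the schedule scale, the closed form is the simplex
        minimizer of J; checked against a dense grid for l = 3."""
        rng = np.random.default_rng(7)
        h = 1e-3
        w1, w2 = np.meshgrid(np.arange(0, 1 + h, h), np.arange(0, 1 + h, h))
        keep = w1 + w2 <= 1 + 1e-12
        W = np.stack([w1[keep], w2[keep], 1 - w1[keep] - w2[keep]], axis=1)
        for _ in range(5):
            D = rng.uniform(0, 20, size=3)
            delta = D.sum() * rng.uniform(1, 3)
            gw = update_weights(D, delta)
            J = W @ D + delta * (W**2).sum(axis=1)
            w_grid = W[np.argmin(J)]
            np.testing.assert_allclose(gw.w, w_grid, atol=2.5e-3)

    def test_invalid_delta_rejected(self):
        with pytest.raises(ValueError, match="delta"):
            update_weights(np.array([1.0, 2.0]), 0.0)


class TestDeltaSchedules:
    @given(D=d_vectors)
    def test_uniform_weights_give_sum_of_d(self, D):
        if D.sum() == 0:
            return
        w = np.full(D.size, 1.0 / D.size)
        assert update_delta_dkbcgs(D, w) == pytest.approx(D.sum(), rel=1e-10)
        assert update_delta_kbcgs(D, w, alpha=0.05) == pytest.approx(
            0.05 * D.sum(), rel=1e-10
        )

    def test_hand_example(self):
        delta = update_delta_dkbcgs(np.array([1.0, 3.0]), np.array([0.5, 0.5]))
        assert delta == pytest.approx(4.0, abs=1e-12)
        assert update_delta_kbcgs(
            np.array([1.0, 3.0]), np.array([0.5, 0.5]), alpha=0.05
        ) == pytest.approx(0.2, abs=1e-12)

    def test_one_hot_weights_return_that_gene(self):
        assert update_delta_dkbcgs(
            np.array([2.5, 9.0]), np.array([1.0, 0.0])
        ) == pytest.approx(2.5, abs=1e-12)

    @given(D=d_vectors, alpha=st.floats(min_value=0.01, max_value=10))
    def test_alpha_scales_linearly(self, D, alpha):
        if D.sum() == 0:
            return
        w = np.full(D.size, 1.0 / D.size)
        base = update_delta_kbcgs(D, w, alpha)
        assert update_delta_kbcgs(D, w, 2 * alpha) == pytest.approx(2 * base, rel=1e-12)
        assert update_delta_kbcgs(D, w, 1.0) == pytest.approx(
            update_delta_dkbcgs(D, w), rel=1e-12
        )

    def test_vanishing_weighted_dissimilarity_is_degenerate(self):
        with pytest.raises(ValueError, match="vanish"):
            update_delta_dkbcgs(np.zeros(3), np.full(3, 1 / 3))


class TestObjective:
    def test_uniform_weights_with_schedule_delta(self):
        D = np.array([1.0, 2.0, 3.0])
        w = np.full(3, 1 / 3)
        J = objective(D, w, delta=D.sum())
        assert J == pytest.approx(2 * D.sum() / 3, abs=1e-12)

    def test_one_hot_vertex(self):
        D = np.array([0.5, 4.0])
        assert objective(D, np.array([1.0, 0.0]), delta=2.0) == pytest.approx(2.5)

    def test_zero_dissimilarity_leaves_penalty_only(self):
        w = np.array([0.5, 0.25, 0.25])
        assert objective(np.zeros(3), w, delta=2.0) == pytest.approx(2.0 * (w @ w))


class TestRun:
    def test_single_gene_trivially_converges(self):
        ds = ExpressionDataset(
            np.array([[1.0], [2.0], [5.0], [9.0]]),
            list("abcd"), ["g"], ["x", "x", "y", "y"],
        )
        gw, state = run(ds)
        assert gw.w.tolist() == [1.0]
        assert state.converged

    def test_identical_gene_columns_get_equal_weights(self, tiny_ds):
        values = np.column_stack([tiny_ds.values, tiny_ds.values[:, 0]])
        ds = ExpressionDataset(
            values, tiny_ds.sample_ids, ["gA", "gB", "gC", "gA2"], tiny_ds.labels
        )
        gw, _ = run(ds)
        assert abs(gw.w[0] - gw.w[3]) < 1e-10

    def test_gene_permutation_equivariance(self, tiny_ds):
        gw, _ = run(tiny_ds)
        perm = [2, 0, 1]
        ds_p = ExpressionDataset(
            tiny_ds.values[:, perm],
            tiny_ds.sample_ids,
            [tiny_ds.gene_ids[i] for i in perm],
            tiny_ds.labels,
        )
        gw_p, _ = run(ds_p)
        # mean(D) sums in a different order under permutation: last-bit slack
        np.testing.assert_allclose(gw_p.w, gw.w[perm], rtol=0, atol=1e-12)
        assert [ds_p.gene_ids[i] for i in gw_p.order] == [
            tiny_ds.gene_ids[i] for i in gw.order
        ]

    def test_sample_order_invariance(self, tiny_ds):
        gw, _ = run(tiny_ds)
        shuf = [3, 1, 0, 2]
        ds_s = ExpressionDataset(
            tiny_ds.values[shuf],
            [tiny_ds.sample_ids[i] for i in shuf],
            tiny_ds.gene_ids,
            tiny_ds.labels[shuf],
        )
        gw_s, _ = run(ds_s)
        np.testing.assert_allclose(gw_s.w, gw.w, atol=1e-12)

    def test_converges_within_cap_on_synthetic_data(self):
        ds, _ = generate(SyntheticSpec(n_samples=30, n_genes=200, seed=5))
        gw, state = run(ds)
        assert state.converged and state.t <= 100
        assert abs(state.objective_trace[-1] - state.objective_trace[-2]) < 1e-6
        assert gw.w.sum() == pytest.approx(1.0, abs=1e-10)

    def test_kbcgs_with_unit_alpha_matches_dkbcgs(self, tiny_ds):
        _, s1 = run(tiny_ds, variant="dkbcgs")
        _, s2 = run(tiny_ds, variant="kbcgs", alpha=1.0)
        np.testing.assert_array_equal(s1.objective_trace, s2.objective_trace)

    def test_ranking_follows_ascending_dissimilarity(self):
        ds, _ = generate(SyntheticSpec(n_samples=24, n_genes=60, seed=9))
        params = KernelParams()
        gw, _ = run(ds, params)
        norm, _ = zscore_normalize(ds)
        D = per_gene_dissimilarity(norm, compute_centers(norm), params)
        np.testing.assert_array_equal(gw.order, np.argsort(D, kind="stable"))

    def test_unknown_variant_rejected(self, tiny_ds):
        with pytest.raises(ValueError, match="variant"):
            run(tiny_ds, variant="other")


def test_gene_weights_ranking_tie_rule():
    gw = GeneWeights(np.array([0.25, 0.5, 0.25]))
    assert gw.order.tolist() == [1, 0, 2]
    assert gw.ranks.tolist() == [2, 1, 3]
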