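"""Quantile / smooth quantile normalization against hand oracles,
degenerate-limit equalities, and the RMSE diagnostic."""

import numpy as np
import pytest

from tissuenorm import (
    normalize_tissue_aware,
    qsmooth_normalize,
    quantile_normalize,
    quantile_normalize_per_group,
    reference_rmse,
    simulate_experiment,
)


def qsmooth_oracle_window1(matrix, groups):
    """Literal per-rank transcription of the smooth-quantile rule
    (no smoothing), kept deliberately loop-based and independent of the
    vectorized implementation."""
    matrix = np.asarray(matrix, float)
    n_genes, n_samples = matrix.shape
    labels = sorted(set(groups))
    Q = np.sort(matrix, axis=0)
    out = np.empty_like(matrix)
    qbar = [np.mean([Q[k, j] for j in range(n_samples)]) for k in range(n_genes)]
    qbar_g = {
        g: [
            np.mean([Q[k, j] for j in range(n_samples) if groups[j] == g])
            for k in range(n_genes)
        ]
        for g in labels
    }
    w = []
    for k in range(n_genes):
        sst = sum((Q[k, j] - qbar[k]) ** 2 for j in range(n_samples))
        ssb = sum(
            sum(1 for j in range(n_samples) if groups[j] == g)
            * (qbar_g[g][k] - qbar[k]) ** 2
            for g in labels
        )
        w.append(1.0 if sst == 0 else min(max(1.0 - ssb / sst, 0.0), 1.0))
    for j in range(n_samples):
        g = groups[j]
        target = [
            w[k] * qbar[k] + (1 - w[k]) * qbar_g[g][k] for k in range(n_genes)
        ]
        assert target == sorted(target), "oracle toy must have a monotone target"
        order = np.argsort(matrix[:, j], kind="mergesort")
        col = np.empty(n_genes)
        col[order] = target
        out[:, j] = col
    return out


class TestQuantileNormalize:
    def test_identical_samples_are_a_fixed_point(self):
        m = np.tile([[4.0], [1.0], [9.0]], (1, 5))
        np.testing.assert_allclose(quantile_normalize(m).normalized, m)

    def test_printed_two_sample_toy(self):
        m = np.array([[1.0, 4.0], [2.0, 6.0], [3.0, 8.0]])
        expected = np.array([[2.5, 2.5], [4.0, 4.0], [5.5, 5.5]])
        np.testing.assert_allclose(quantile_normalize(m).normalized, expected)

    def test_ties_get_mean_of_tied_reference_values(self):
        # sample 0 has a two-way tie at its two smallest ranks
        m = np.array([[5.0, 1.0], [5.0, 2.0], [9.0, 30.0]])
        res = quantile_normalize(m)
        ref = np.sort(m, axis=0).mean(axis=1)
        out = res.normalized
        assert out[0, 0] == out[1, 0] == pytest.approx(ref[:2].mean())
        # total mass of the sample is preserved relative to the reference
        assert out[:, 0].sum() == pytest.approx(ref.sum())

    def test_tie_free_samples_share_sorted_values(self):
        rng = np.random.default_rng(20)
        m = rng.uniform(size=(30, 6))  # continuous => tie-free a.s.
        out = quantile_normalize(m).normalized
        base = np.sort(out[:, 0])
        for j in range(1, 6):
            np.testing.assert_allclose(np.sort(out[:, j]), base, atol=1e-10)

    def test_single_sample_is_identity_with_warning(self):
        m = np.array([[3.0], [1.0]])
        with pytest.warns(UserWarning):
            res = quantile_normalize(m)
        np.testing.assert_array_equal(res.normalized, m)


class TestQsmooth:
    def test_single_group_equals_global_quantile_normalization(self):
        rng = np.random.default_rng(21)
        m = rng.integers(0, 50, size=(25, 6)).astype(float)
        res = qsmooth_normalize(m, ["t"] * 6)
        np.testing.assert_allclose(
            res.normalized, quantile_normalize(m).normalized, atol=1e-12
        )

    def test_identical_group_distributions_give_unit_weights(self):
        # two groups that are column permutations of each other: the
        # per-group sorted means coincide, so SSB is 0 at every rank
        rng = np.random.default_rng(22)
        block = rng.integers(0, 100, size=(20, 3)).astype(float)
        m = np.hstack([block, block[:, ::-1]])
        res = qsmooth_normalize(m, ["a"] * 3 + ["b"] * 3)
        np.testing.assert_allclose(res.weights, 1.0)
        np.testing.assert_allclose(
            res.normalized, quantile_normalize(m).normalized, atol=1e-12
        )

    def test_matches_literal_oracle_on_two_group_toy(self):
        # 4 genes x 4 samples, 2 groups, planted group shift, window 1
        m = np.array(
            [
                [2.0, 3.0, 40.0, 44.0],
                [1.0, 2.0, 20.0, 26.0],
                [5.0, 4.0, 60.0, 70.0],
                [7.0, 9.0, 90.0, 96.0],
            ]
        )
        groups = ["a", "a", "b", "b"]
        res = qsmooth_normalize(m, groups, window_fraction=0.0)
        expected = qsmooth_oracle_window1(m, groups)
        np.testing.assert_allclose(res.normalized, expected, atol=1e-10)

    def test_weight_zero_reduces_to_per_group_normalization(self):
        rng = np.random.default_rng(23)
        m = rng.integers(0, 80, size=(30, 8)).astype(float)
        groups = ["a"] * 4 + ["b"] * 4
        forced = qsmooth_normalize(m, groups, weight_override=0.0)
        np.testing.assert_allclose(
            forced.normalized,
            quantile_normalize_per_group(m, groups).normalized,
            atol=1e-12,
        )

    def test_weight_one_reduces_to_global_normalization(self):
        rng = np.random.default_rng(24)
        m = rng.integers(0, 80, size=(30, 8)).astype(float)
        forced = qsmooth_normalize(
            m, ["a"] * 4 + ["b"] * 4, weight_override=1.0
        )
        np.testing.assert_allclose(
            forced.normalized, quantile_normalize(m).normalized, atol=1e-12
        )

    def test_preserves_within_sample_rank_order(self):
        rng = np.random.default_rng(25)
        m = rng.negative_binomial(2, 0.2, size=(60, 10)).astype(float)
        res = qsmooth_normalize(m, ["a"] * 3 + ["b"] * 3 + ["c"] * 4)
        for j in range(10):
            order = np.argsort(m[:, j], kind="mergesort")
            assert np.all(np.diff(res.normalized[order, j]) >= -1e-12)

    def test_weights_lie_in_unit_interval(self):
        rng = np.random.default_rng(26)
        m = rng.integers(0, 200, size=(50, 9)).astype(float)
        res = qsmooth_normalize(m, ["a"] * 3 + ["b"] * 3 + ["c"] * 3)
        assert np.all(res.weights >= 0) and np.all(res.weights <= 1)
        assert len(res.weights) == 50

    def test_sample_permutation_equivariance(self):
        rng = np.random.default_rng(27)
        m = rng.integers(0, 60, size=(40, 8)).astype(float)
        groups = np.array(["a"] * 4 + ["b"] * 4)
        perm = rng.permutation(8)
        res = qsmooth_normalize(m, groups)
        res_p = qsmooth_normalize(m[:, perm], groups[perm])
        np.testing.assert_allclose(
            res.normalized[:, perm], res_p.normalized, atol=1e-12
        )

    def test_missing_group_label_raises(self):
        with pytest.raises(ValueError):
            qsmooth_normalize(np.ones((4, 2)), ["a", None])


class TestPerGroupNormalization:
    def test_blockwise_equals_independent_normalizations(self):
        rng = np.random.default_rng(28)
        a = rng.integers(0, 90, size=(20, 4)).astype(float)
        b = rng.integers(0, 90, size=(20, 3)).astype(float)
        m = np.hstack([a, b])
        res = quantile_normalize_per_group(m, ["a"] * 4 + ["b"] * 3)
        np.testing.assert_allclose(
            res.normalized[:, :4], quantile_normalize(a).normalized
        )
        np.testing.assert_allclose(
            res.normalized[:, 4:], quantile_normalize(b).normalized
        )

    def test_singleton_group_left_unchanged_with_warning(self):
        rng = np.random.default_rng(29)
        m = rng.integers(0, 50, size=(10, 3)).astype(float)
        with pytest.warns(UserWarning, match="single sample"):
            res = quantile_normalize_per_group(m, ["a", "a", "lonely"])
        np.testing.assert_array_equal(res.normalized[:, 2], m[:, 2])


class TestNormalizeTissueAware:
    def test_single_group_qsmooth_equals_global(self):
        expr, _ = simulate_experiment(
            n_groups=1, samples_per_group=6, n_genes=80, seed=30
        )
        expr.sample_table["merged_group"] = "only"
        out = normalize_tissue_aware(expr, method="qsmooth")
        np.testing.assert_allclose(
            out.assays["normalized"],
            quantile_normalize(expr.counts).normalized,
            atol=1e-12,
        )

    def test_methods_differ_when_group_distributions_differ(self):
        expr, _ = simulate_experiment(
            n_groups=2, samples_per_group=5, n_genes=120,
            tissue_specific_fraction=0.3, seed=31,
        )
        expr.sample_table["merged_group"] = expr.sample_table["sub_site"]
        a = normalize_tissue_aware(expr, method="qsmooth")
        b = normalize_tissue_aware(expr, method="quantile_per_group")
        assert not np.allclose(a.assays["normalized"], b.assays["normalized"])

    def test_rerun_is_idempotent_and_preserves_raw_counts(self):
        expr, _ = simulate_experiment(
            n_groups=2, samples_per_group=4, n_genes=60, seed=32
        )
        expr.sample_table["merged_group"] = expr.sample_table["sub_site"]
        once = normalize_tissue_aware(expr, method="qsmooth")
        twice = normalize_tissue_aware(once, method="qsmooth")
        np.testing.assert_array_equal(once.counts, expr.counts)
        np.testing.assert_allclose(
            once.assays["normalized"], twice.assays["normalized"]
        )


class TestReferenceRmse:
    def test_identical_samples_have_zero_rmse(self):
        m = np.tile([[4.0], [9.0], [1.0]], (1, 3))
        np.testing.assert_allclose(reference_rmse(m), 0.0, atol=1e-12)

    def test_group_reference_fits_heterogeneous_groups_better(self):
        better = 0
        for seed in range(20):
            expr, _ = simulate_experiment(
                n_groups=3, samples_per_group=6, n_genes=300,
                tissue_specific_fraction=0.2, seed=seed,
            )
            groups = expr.sample_table["sub_site"].to_numpy()
            g = reference_rmse(expr.counts, groups, "group").mean()
            glob = reference_rmse(expr.counts, None, "global").mean()
            better += g < glob
        assert better >= 19

    def test_group_scope_requires_groups(self):
        with pytest.raises(ValueError):
            reference_rmse(np.ones((3, 2)), None, "group")
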