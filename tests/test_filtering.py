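"""Gene filters against brute-force oracles and their invariants."""

import numpy as np
import pytest

from tissuenorm import (
    biotype_summary,
    cpm,
    filter_genes_by_chromosome,
    filter_low_genes,
    filter_missing_genes,
    make_experiment,
    min_samples_tissue_aware,
)


def _brute_force_low_filter(counts, min_samples, cpm_threshold=1.0):
    """Per-gene loop over samples: the oracle the vectorized filter must match."""
    libsize = [sum(counts[i][j] for i in range(len(counts)))
               for j in range(len(counts[0]))]
    retained = []
    for i in range(len(counts)):
        passes = sum(
            1
            for j in range(len(counts[0]))
            if counts[i][j] / libsize[j] * 1e6 >= cpm_threshold
        )
        if passes >= min_samples:
            retained.append(i)
    return retained


def _experiment(counts, groups=None, chromosomes=None, biotypes=None):
    n, m = np.asarray(counts).shape
    return make_experiment(
        counts,
        [f"g{i}" for i in range(n)],
        [f"s{j}" for j in range(m)],
        chromosomes=chromosomes,
        biotypes=biotypes,
        sub_site=groups,
    )


class TestCpm:
    def test_definition(self):
        counts = np.zeros((2, 1))
        counts[0, 0] = 100
        counts[1, 0] = 999_900
        assert cpm(counts)[0, 0] == pytest.approx(100.0)

    def test_all_zero_gene_row_is_zero(self):
        counts = np.array([[0, 0], [10, 20]], float)
        np.testing.assert_array_equal(cpm(counts)[0], [0.0, 0.0])

    def test_matches_brute_force(self):
        rng = np.random.default_rng(9)
        counts = rng.integers(0, 100, size=(4, 3)).astype(float)
        out = cpm(counts)
        for i in range(4):
            for j in range(3):
                assert out[i, j] == pytest.approx(
                    counts[i, j] / counts[:, j].sum() * 1e6
                )

    def test_zero_library_size_names_sample(self):
        with pytest.raises(ValueError, match=r"\[1\]"):
            cpm(np.array([[1.0, 0.0], [2.0, 0.0]]))


class TestMinSamplesTissueAware:
    def test_half_of_smallest_group(self):
        assert min_samples_tissue_aware({"a": 10, "b": 4}) == 2.0

    def test_fractional_result_not_rounded(self):
        assert min_samples_tissue_aware({"only": 7}) == 3.5

    def test_empty_map_raises(self):
        with pytest.raises(ValueError):
            min_samples_tissue_aware({})


class TestFilterLowGenes:
    def test_boundary_cases_in_two_groups_of_three(self):
        # min_samples = 3/2: a gene passing in 2 samples stays, in 1 goes
        counts = np.full((10, 6), 1000.0)
        counts[0] = [5000, 5000, 0, 0, 0, 0]  # CPM >= 1 in 2 samples
        counts[1] = [5000, 0, 0, 0, 0, 0]  # CPM >= 1 in 1 sample
        expr = _experiment(counts, groups=["a"] * 3 + ["b"] * 3)
        filtered, result = filter_low_genes(expr, group_column="sub_site")
        assert result.min_samples == 1.5
        assert "g0" in result.retained_ids
        assert "g1" in result.removed_ids

    def test_gene_above_threshold_everywhere_is_retained(self):
        counts = np.full((3, 4), 50.0)
        filtered, result = filter_low_genes(_experiment(counts))
        assert result.retained_ids == ["g0", "g1", "g2"]

    def test_all_zero_gene_always_removed(self):
        counts = np.full((3, 4), 50.0)
        counts[2] = 0
        _, result = filter_low_genes(_experiment(counts))
        assert "g2" in result.removed_ids

    def test_agnostic_boundary_half_of_cohort(self):
        counts = np.zeros((2, 10))
        counts[0] = [10_000] * 5 + [0] * 5  # present in exactly half
        counts[1] = 100.0
        _, result = filter_low_genes(_experiment(counts), group_column=None)
        assert "g0" in result.retained_ids

    @pytest.mark.parametrize("mode", ["aware", "agnostic"])
    def test_matches_brute_force_on_random_matrices(self, mode):
        rng = np.random.default_rng(10)
        groups = ["a"] * 10 + ["b"] * 8 + ["c"] * 12
        for _ in range(30):
            counts = rng.integers(0, 30, size=(50, 30)).astype(float)
            counts[0] = 1.0  # guarantees every library size is positive
            expr = _experiment(counts, groups=groups)
            col = "sub_site" if mode == "aware" else None
            _, result = filter_low_genes(expr, group_column=col)
            expected = _brute_force_low_filter(
                counts.tolist(), result.min_samples
            )
            assert result.retained_ids == [f"g{i}" for i in expected]

    def test_tissue_aware_superset_of_agnostic(self):
        rng = np.random.default_rng(11)
        counts = rng.negative_binomial(2, 0.1, size=(80, 24)).astype(float)
        groups = ["a"] * 4 + ["b"] * 20  # smallest group 4 < 24/2
        expr = _experiment(counts, groups=groups)
        _, aware = filter_low_genes(expr, group_column="sub_site")
        _, agnostic = filter_low_genes(expr, group_column=None)
        assert set(agnostic.retained_ids) <= set(aware.retained_ids)

    def test_planted_tissue_specific_gene_survives_only_tissue_aware(self):
        # one group of 6 in a cohort of 26: a gene expressed only there
        # passes tissue-aware (6 >= 3) but not agnostic (6 < 13)
        counts = np.full((20, 26), 40.0)
        counts[0] = 0.0
        counts[0, :6] = 5000.0
        groups = ["small"] * 6 + ["big"] * 20
        expr = _experiment(counts, groups=groups)
        _, aware = filter_low_genes(expr, group_column="sub_site")
        _, agnostic = filter_low_genes(expr, group_column=None)
        assert "g0" in aware.retained_ids
        assert "g0" in agnostic.removed_ids

    def test_sample_permutation_changes_nothing(self):
        rng = np.random.default_rng(12)
        counts = rng.integers(0, 40, size=(30, 12)).astype(float) + 1
        groups = ["a"] * 5 + ["b"] * 7
        expr = _experiment(counts, groups=groups)
        perm = rng.permutation(12)
        permuted = _experiment(
            counts[:, perm], groups=[groups[j] for j in perm]
        )
        _, r1 = filter_low_genes(expr, group_column="sub_site")
        _, r2 = filter_low_genes(permuted, group_column="sub_site")
        assert r1.retained_ids == r2.retained_ids

    def test_retained_pass_counts_meet_threshold(self):
        rng = np.random.default_rng(13)
        counts = rng.integers(0, 20, size=(40, 10)).astype(float) + 1
        expr = _experiment(counts, groups=["a"] * 3 + ["b"] * 7)
        _, result = filter_low_genes(expr, group_column="sub_site")
        assert set(result.retained_ids) | set(result.removed_ids) == set(
            expr.gene_ids
        )
        assert not set(result.retained_ids) & set(result.removed_ids)
        for g in result.retained_ids:
            assert result.per_gene_pass_count[g] >= result.min_samples


class TestChromosomeAndMissingFilters:
    def _mixed(self):
        counts = np.ones((10, 4))
        return _experiment(
            counts,
            chromosomes=["X", "X", "Y", "Y", "MT", "MT", "1", "2", "3", "4"],
        )

    def test_remove_sex_and_mito_leaves_autosomes(self):
        expr, result = filter_genes_by_chromosome(
            self._mixed(), {"X", "Y", "MT"}, mode="remove"
        )
        assert expr.n_genes == 4
        assert set(expr.gene_table["chromosome"]) == {"1", "2", "3", "4"}

    def test_keep_y_returns_exactly_y_genes(self):
        expr, _ = filter_genes_by_chromosome(self._mixed(), {"Y"}, mode="keep")
        assert list(expr.gene_ids) == ["g2", "g3"]

    def test_m_alias_matches_mt(self):
        expr, _ = filter_genes_by_chromosome(self._mixed(), {"M"}, mode="keep")
        assert expr.n_genes == 2

    def test_remove_empty_set_is_identity(self):
        expr, result = filter_genes_by_chromosome(self._mixed(), set(), "remove")
        assert expr.n_genes == 10 and result.removed_ids == []

    def test_missing_filter_removes_exactly_zero_total_genes(self):
        rng = np.random.default_rng(14)
        counts = rng.integers(1, 10, size=(20, 5)).astype(float)
        counts[[3, 11, 17]] = 0.0
        expr, result = filter_missing_genes(_experiment(counts))
        assert sorted(result.removed_ids) == ["g11", "g17", "g3"]
        assert expr.n_genes == 17

    def test_single_count_gene_is_retained(self):
        counts = np.zeros((2, 3))
        counts[0, 1] = 1
        counts[1] = 5
        expr, _ = filter_missing_genes(_experiment(counts))
        assert "g0" in expr.gene_ids


class TestBiotypeSummary:
    def test_counts_and_fractions(self):
        expr = _experiment(
            np.ones((10, 2)),
            biotypes=["protein_coding"] * 6 + ["pseudogene"] + ["other"] * 3,
        )
        summary = biotype_summary(expr)
        assert summary["protein_coding"] == (6, 0.6)
        assert summary["pseudogene"] == (1, 0.1)
        assert summary["other"] == (3, 0.3)
        assert sum(f for _, f in summary.values()) == pytest.approx(1.0)

    def test_all_unknown(self):
        expr = _experiment(np.ones((4, 2)))
        assert biotype_summary(expr) == {"unknown": (4, 1.0)}
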