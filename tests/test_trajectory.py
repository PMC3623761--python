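import numpy as np
import pandas as pd
import pytest

from epitraject.intervals import GenomicInterval
from epitraject.quantify import DensityMatrix
from epitraject.trajectory import (TrajectoryCallConfig, assign_age_groups,
                                   classify_up_down,
                                   filter_and_normalize_for_clustering,
                                   geneset_mean_expression, kmeans_profiles,
                                   label_cluster_trend, mean_profile)


def _dm(values, lengths=None, chroms=None):
    values = np.asarray(values, dtype=float)
    n = values.shape[0]
    lengths = lengths if lengths is not None else [1200] * n
    chroms = chroms if chroms is not None else ["chr1"] * n
    regions = [GenomicInterval(c, i * 100_000, i * 100_000 + l)
               for i, (c, l) in enumerate(zip(chroms, lengths))]
    return DensityMatrix(regions, [f"s{j}" for j in range(values.shape[1])],
                         values, np.ones(values.shape[1]))


def _welch_p_oracle(a, b):
    """Welch two-sided t-test p by the textbook formulas."""
    from scipy import stats

    a, b = np.asarray(a, float), np.asarray(b, float)
    va, vb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
    t = (a.mean() - b.mean()) / np.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (a.size - 1) + vb**2 / (b.size - 1))
    return 2 * stats.t.sf(abs(t), df)


class TestAgeGroups:
    def test_partition_rules(self):
        ages = [-0.11, -0.02, 0.0, 0.5, 0.99, 1.0, 5.0]
        out = assign_age_groups(ages).tolist()
        assert out == ["prenatal", "prenatal", "prenatal", "infant",
                       "infant", "older", "older"]


class TestClassifyUpDown:
    def _ages(self):
        return np.array([-0.11, -0.02, 0.0] + [2.0 + i for i in range(25)])

    def test_down_call_with_welch_oracle(self, rng):
        pren = np.array([0.039, 0.040, 0.041])
        older = 0.010 + rng.normal(0, 0.001, 25)
        row = np.concatenate([pren, older])
        calls = classify_up_down(_dm([row]), self._ages())
        assert calls["klass"][0] == "down"
        assert calls["p_value"][0] == pytest.approx(
            _welch_p_oracle(pren, older), rel=1e-9
        )
        assert calls["fold_older_vs_prenatal"][0] < 0.5

    def test_up_is_reciprocal(self, rng):
        row = np.concatenate([[0.010, 0.011, 0.010],
                              0.040 + rng.normal(0, 0.002, 25)])
        calls = classify_up_down(_dm([row]), self._ages())
        assert calls["klass"][0] == "up"

    def test_floor_gate(self):
        row = np.concatenate([[0.005, 0.005, 0.005], np.full(25, 0.001)])
        calls = classify_up_down(_dm([row]), self._ages())
        assert calls["klass"][0] == "none"  # both means below the floor

    def test_fold_gate_blocks_significant_small_changes(self, rng):
        row = np.concatenate([0.030 + rng.normal(0, 1e-4, 3),
                              0.020 + rng.normal(0, 1e-4, 25)])
        calls = classify_up_down(_dm([row]), self._ages())
        assert calls["p_value"][0] < 1e-3  # clearly significant ...
        assert calls["klass"][0] == "none"  # ... but fold 1.5 < 2

    def test_length_gate(self, rng):
        row = np.concatenate([[0.04, 0.041, 0.042],
                              0.010 + rng.normal(0, 0.001, 25)])
        calls = classify_up_down(_dm([row], lengths=[800]), self._ages())
        assert calls["klass"][0] == "none"

    def test_zero_variance_flagged_none(self):
        row = np.concatenate([np.full(3, 0.04), np.full(25, 0.01)])
        calls = classify_up_down(_dm([row]), self._ages())
        assert calls["klass"][0] == "none"
        assert not np.isfinite(calls["p_value"][0])

    def test_infants_do_not_enter_the_test(self, rng):
        base = np.concatenate([[0.04, 0.041, 0.042],
                               0.010 + rng.normal(0, 0.001, 25)])
        ages = self._ages()
        with_infants = np.concatenate([base, [0.9, 0.9]])
        ages_i = np.concatenate([ages, [0.3, 0.6]])
        c0 = classify_up_down(_dm([base]), ages)
        c1 = classify_up_down(_dm([with_infants]), ages_i)
        assert c1["p_value"][0] == pytest.approx(c0["p_value"][0])

    def test_age_reversal_swaps_up_and_down(self, rng):
        """Mirroring the age axis turns every up call into a down call
        and vice versa."""
        X = rng.uniform(0.0, 0.06, size=(50, 10))
        ages = np.array([-0.1, -0.05] + list(range(2, 10)))
        # swap the group roles: prenatal samples become older and vice
        # versa (no infants involved)
        rev = np.where(ages <= 0, 5.0, -0.05)
        c_fwd = classify_up_down(_dm(X), ages)
        c_rev = classify_up_down(_dm(X), rev)
        swap = {"up": "down", "down": "up", "none": "none"}
        assert [swap[k] for k in c_fwd["klass"]] == list(c_rev["klass"])

    def test_group_size_requirement(self):
        with pytest.raises(ValueError):
            classify_up_down(_dm([[0.1, 0.2, 0.3]]), np.array([-0.1, 2.0, 3.0]))

    def test_recovers_planted_classes(self, default_cohort, default_density,
                                      default_ages):
        """Headline parameter recovery on the default synthetic cohort."""
        calls = classify_up_down(default_density, default_ages)
        truth = default_cohort.planted_classes
        called = calls["klass"].isin(["up", "down"]).to_numpy()
        hits = (calls["klass"].to_numpy() == truth) & called
        sensitivity = hits.sum() / (truth != "flat").sum()
        fdp = (called & ~hits).sum() / max(called.sum(), 1)
        assert sensitivity >= 0.90
        assert fdp <= 0.10


class TestMeanProfile:
    def test_single_region_is_its_own_row(self):
        dm = _dm([[0.1, 0.2, 0.3], [0.4, 0.5, 0.6]])
        assert mean_profile(dm, [1]).tolist() == [0.4, 0.5, 0.6]

    def test_duplicate_regions_equal_single(self):
        dm = _dm([[0.1, 0.2, 0.3], [0.1, 0.2, 0.3]])
        assert mean_profile(dm, [0, 1]).tolist() == mean_profile(dm, [0]).tolist()

    def test_matches_column_mean_oracle(self, rng):
        X = rng.random((30, 6))
        idx = rng.choice(30, 10, replace=False)
        assert np.allclose(mean_profile(_dm(X), idx), X[idx].mean(axis=0))

    def test_empty_subset_rejected(self):
        with pytest.raises(ValueError):
            mean_profile(_dm([[0.1, 0.2]]), [])


class TestFilterAndNormalize:
    def _ages(self):
        return np.array([-0.1, -0.05, 2.0, 3.0])

    def test_max_normalization(self):
        X = [[0.02, 0.02, 0.04, 0.04]]
        norm, idx = filter_and_normalize_for_clustering(_dm(X), self._ages())
        assert norm[0].tolist() == [0.5, 0.5, 1.0, 1.0]
        assert norm.max(axis=1).tolist() == [1.0]

    def test_short_region_excluded(self):
        X = [[0.05, 0.05, 0.05, 0.05]]
        _, idx = filter_and_normalize_for_clustering(
            _dm(X, lengths=[800]), self._ages()
        )
        assert idx.size == 0

    def test_chrY_excluded(self):
        X = [[0.05] * 4, [0.05] * 4]
        norm, idx = filter_and_normalize_for_clustering(
            _dm(X, chroms=["chrY", "chr1"]), self._ages()
        )
        assert idx.tolist() == [1]

    def test_matches_predicate_oracle(self, default_cohort, default_density,
                                      default_ages):
        cfg = TrajectoryCallConfig()
        norm, idx = filter_and_normalize_for_clustering(
            default_density, default_ages, cfg
        )
        groups = assign_age_groups(default_ages)
        X = default_density.values
        expected = []
        for i, r in enumerate(default_density.regions):
            if len(r) < cfg.min_length or r.chrom == "chrY":
                continue
            pa = X[i, groups == "prenatal"].mean()
            pb = X[i, groups == "older"].mean()
            if (pa >= cfg.density_floor or pb >= cfg.density_floor) and X[i].max() > 0:
                expected.append(i)
        assert idx.tolist() == expected
        assert norm.min() >= 0 and np.allclose(norm.max(axis=1), 1.0)


class TestKmeansProfiles:
    def test_recovers_noiseless_archetypes(self):
        ages = np.arange(6, dtype=float)
        up = np.linspace(0.2, 1.0, 6)
        down = np.linspace(1.0, 0.2, 6)
        flat = np.full(6, 1.0)
        X = np.vstack([np.tile(up, (10, 1)), np.tile(down, (10, 1)),
                       np.tile(flat, (10, 1))])
        res = kmeans_profiles(X, np.arange(30), ages, k=3, seed=0)
        from sklearn.metrics import adjusted_rand_score

        planted = np.repeat([0, 1, 2], 10)
        assert adjusted_rand_score(planted, res.assignments) == 1.0
        assert sorted(res.trends) == ["down", "flat", "up"]

    def test_identical_profiles_zero_within_ss(self):
        X = np.tile(np.linspace(0, 1, 5), (8, 1))
        res = kmeans_profiles(X, np.arange(8), np.arange(5), k=2, seed=0)
        ss = sum(
            ((X[res.assignments == c] - res.centroids[c]) ** 2).sum()
            for c in range(2)
        )
        assert ss == pytest.approx(0.0)

    def test_seeded_determinism(self, rng):
        X = rng.random((40, 7))
        a = kmeans_profiles(X, np.arange(40), np.arange(7), k=4, seed=9)
        b = kmeans_profiles(X, np.arange(40), np.arange(7), k=4, seed=9)
        assert np.array_equal(a.assignments, b.assignments)

    def test_k_larger_than_regions_rejected(self):
        with pytest.raises(ValueError):
            kmeans_profiles(np.ones((3, 4)), np.arange(3), np.arange(4), k=5)


class TestLabelClusterTrend:
    def test_monotone_and_constant(self):
        ages = np.arange(8, dtype=float)
        assert label_cluster_trend(np.linspace(0, 1, 8), ages) == "up"
        assert label_cluster_trend(np.full(8, 0.3), ages) == "flat"

    def test_noisy_decreasing_matches_spearman_oracle(self, rng):
        from scipy import stats

        ages = np.arange(12, dtype=float)
        centroid = np.linspace(1, 0, 12) + rng.normal(0, 0.15, 12)
        rho = stats.spearmanr(centroid, ages).statistic
        expected = "down" if rho <= -0.5 else ("up" if rho >= 0.5 else "flat")
        assert label_cluster_trend(centroid, ages) == expected

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            label_cluster_trend([1.0, 2.0], [0.0, 1.0, 2.0])


class TestGenesetMeanExpression:
    def _expr(self):
        return pd.DataFrame(
            [[1.0, 2.0, 3.0], [5.0, 6.0, 7.0]],
            index=pd.Index(["gA", "gB"], name="gene_id"),
            columns=["s0", "s1", "s2"],
        )

    def test_singleton_set_is_the_gene_row(self):
        assert geneset_mean_expression(self._expr(), ["gB"]).tolist() == [5, 6, 7]

    def test_disjoint_set_is_error(self):
        with pytest.raises(ValueError, match="none of the 2 genes"):
            geneset_mean_expression(self._expr(), ["gX", "gY"])

    def test_missing_genes_dropped(self):
        out = geneset_mean_expression(self._expr(), ["gA", "gMissing"])
        assert out.tolist() == [1.0, 2.0, 3.0]

    def test_up_gene_set_rises_with_age(self, default_cohort, default_ages):
        expr = default_cohort.expression
        up = [m.gene_id for m in default_cohort.models if m.klass == "up"]
        prof = geneset_mean_expression(expr, up)
        groups = assign_age_groups(default_ages)
        assert prof[groups == "older"].mean() > prof[groups == "prenatal"].mean()
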