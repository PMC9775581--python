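import itertools

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score, silhouette_samples

from omnifuse import (
    SurvivalTable,
    adjusted_rand_index,
    km_logrank,
    rand_index,
    silhouette,
    single_domain_assessment,
)
from omnifuse.evaluation import pair_counts

from conftest import make_partition


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def pair_count_oracle(l1, l2):
    """Explicit O(n^2) enumeration of sample pairs."""
    n = len(l1)
    a = b = c = d = 0
    for i, j in itertools.combinations(range(n), 2):
        same1 = l1[i] == l1[j]
        same2 = l2[i] == l2[j]
        if same1 and same2:
            a += 1
        elif not same1 and not same2:
            b += 1
        elif same1:
            c += 1
        else:
            d += 1
    return a, b, c, d


def ari_oracle(l1, l2):
    a, b, c, d = pair_count_oracle(l1, l2)
    n11, n00, n10, n01 = a, b, c, d
    num = 2.0 * (n11 * n00 - n10 * n01)
    den = (n11 + n10) * (n10 + n00) + (n11 + n01) * (n01 + n00)
    if den == 0:
        return 1.0
    return num / den


def all_partitions(n):
    """Every set partition of range(n), as a label vector."""
    if n == 0:
        yield []
        return
    for part in all_partitions(n - 1):
        k = max(part, default=0)
        for c in range(1, k + 2):
            yield part + [c]


# ---------------------------------------------------------------------------
# Rand / adjusted Rand
# ---------------------------------------------------------------------------

class TestRandIndices:
    def test_identical_partitions(self):
        p = make_partition([1, 2, 2, 3, 1])
        assert rand_index(p, p) == pytest.approx(1.0)
        assert adjusted_rand_index(p, p) == pytest.approx(1.0)

    def test_worked_five_element_example(self):
        # P1 = {{1,2,3},{4,5}}, P2 = {{1,2},{3,4,5}}
        p1 = make_partition([1, 1, 1, 2, 2])
        p2 = make_partition([1, 1, 2, 2, 2])
        assert rand_index(p1, p2) == pytest.approx(0.6)
        assert adjusted_rand_index(p1, p2) == pytest.approx(1.0 / 6.0)

    def test_single_cluster_vs_singletons(self):
        p1 = make_partition([1, 1, 1, 1])
        p2 = make_partition([1, 2, 3, 4])
        assert rand_index(p1, p2) == pytest.approx(0.0)

    def test_contingency_equals_pair_count_oracle_exhaustive_small_n(self):
        parts = [list(p) for p in all_partitions(5)]
        for l1 in parts:
            p1 = make_partition(l1)
            for l2 in parts:
                p2 = make_partition(l2)
                pc = pair_counts(p1, p2)
                assert (pc.a, pc.b, pc.c, pc.d) == pair_count_oracle(l1, l2)
                assert adjusted_rand_index(p1, p2) == pytest.approx(ari_oracle(l1, l2))

    @pytest.mark.parametrize("n", [6, 7, 8])
    def test_contingency_equals_pair_count_oracle_sampled(self, n):
        parts = [list(p) for p in all_partitions(n)]
        rng = np.random.default_rng(n)
        for _ in range(300):
            l1 = parts[rng.integers(len(parts))]
            l2 = parts[rng.integers(len(parts))]
            p1, p2 = make_partition(l1), make_partition(l2)
            assert adjusted_rand_index(p1, p2) == pytest.approx(ari_oracle(l1, l2))

    def test_matches_scikit_learn_on_random_labelings(self, rng):
        for _ in range(50):
            l1 = rng.integers(1, 5, size=40)
            l2 = rng.integers(1, 4, size=40)
            p1 = make_partition(_compact(l1))
            p2 = make_partition(_compact(l2))
            assert adjusted_rand_index(p1, p2) == pytest.approx(
                adjusted_rand_score(l1, l2), abs=1e-12
            )

    def test_relabeling_invariance(self, rng):
        l1 = _compact(rng.integers(1, 5, size=30))
        l2 = _compact(rng.integers(1, 4, size=30))
        p1, p2 = make_partition(l1), make_partition(l2)
        # permute the label names of p2
        perm = rng.permutation(p2.k) + 1
        p2_relab = make_partition(_compact(perm[np.asarray(l2) - 1]))
        assert adjusted_rand_index(p1, p2) == pytest.approx(adjusted_rand_index(p1, p2_relab))

    def test_permutation_null_is_centered(self):
        rng = np.random.default_rng(0)
        base = np.repeat([1, 2, 3], [40, 30, 30])
        fixed = make_partition(base)
        vals = []
        for _ in range(1000):
            perm = make_partition(base[rng.permutation(100)])
            vals.append(adjusted_rand_index(fixed, perm))
        assert abs(np.mean(vals)) < 0.02

    def test_mismatched_samples_error(self):
        p1 = make_partition([1, 2])
        p2 = make_partition([1, 2, 1])
        with pytest.raises(ValueError):
            rand_index(p1, p2)


def _compact(labels):
    _, inv = np.unique(labels, return_inverse=True)
    return inv + 1


# ---------------------------------------------------------------------------
# silhouette
# ---------------------------------------------------------------------------

class TestSilhouette:
    def test_coincident_far_clusters_score_one(self):
        X = np.array([[0.0], [0.0], [10.0], [10.0]])
        part = make_partition([1, 1, 2, 2])
        per_sample, per_cluster = silhouette(X, part)
        np.testing.assert_allclose(per_sample, 1.0)
        np.testing.assert_allclose(per_cluster, 1.0)

    def test_four_point_hand_computed_values(self):
        # 1-D points 0,1 (cluster A) and 10,11 (cluster B):
        # for x=0: a=1, b=(10+11)/2=10.5, SI=(10.5-1)/10.5
        X = np.array([[0.0], [1.0], [10.0], [11.0]])
        part = make_partition([1, 1, 2, 2])
        per_sample, _ = silhouette(X, part)
        expected = [(10.5 - 1) / 10.5, (9.5 - 1) / 9.5, (9.5 - 1) / 9.5, (10.5 - 1) / 10.5]
        np.testing.assert_allclose(per_sample, expected)

    def test_per_cluster_output_length_is_k(self, rng):
        X = rng.standard_normal((30, 3))
        part = make_partition(np.repeat([1, 2, 3], 10))
        _, per_cluster = silhouette(X, part)
        assert per_cluster.shape == (3,)

    def test_matches_scikit_learn(self, rng):
        X = rng.standard_normal((40, 4))
        labels = _compact(rng.integers(1, 4, size=40))
        part = make_partition(labels)
        per_sample, _ = silhouette(X, part)
        np.testing.assert_allclose(per_sample, silhouette_samples(X, labels), atol=1e-10)

    def test_singleton_cluster_scores_zero(self):
        X = np.array([[0.0], [0.1], [5.0]])
        part = make_partition([1, 1, 2])
        per_sample, _ = silhouette(X, part)
        assert per_sample[2] == 0.0

    def test_single_cluster_error(self, rng):
        X = rng.standard_normal((5, 2))
        with pytest.raises(ValueError):
            silhouette(X, make_partition([1] * 5))


# ---------------------------------------------------------------------------
# single-domain assessment
# ---------------------------------------------------------------------------

class TestSingleDomainAssessment:
    def test_mirroring_one_reference_shows_in_row(self, rng):
        base = np.repeat([1, 2, 3], 20)
        fused = make_partition(base)
        ref1 = make_partition(base)  # identical
        ref2 = make_partition(_compact(rng.integers(1, 4, size=60)))  # independent
        table = single_domain_assessment(fused, {"domain1": ref1, "domain2": ref2})
        row = table.table.loc["fused"]
        assert row["domain1"] == pytest.approx(1.0)
        assert abs(row["domain2"]) < 0.15

    def test_multiple_method_rows(self, rng):
        base = np.repeat([1, 2], 20)
        refs = {"r": make_partition(base)}
        methods = {
            "jsvd": make_partition(base),
            "snf": make_partition(_compact(rng.integers(1, 3, size=40))),
        }
        table = single_domain_assessment(methods, refs)
        assert list(table.table.index) == ["jsvd", "snf"]
        assert table.table.loc["jsvd", "r"] == pytest.approx(1.0)

    def test_cells_are_symmetric_in_arguments(self, rng):
        l1 = _compact(rng.integers(1, 4, size=30))
        l2 = _compact(rng.integers(1, 3, size=30))
        p1, p2 = make_partition(l1), make_partition(l2)
        assert adjusted_rand_index(p1, p2) == pytest.approx(adjusted_rand_index(p2, p1))


# ---------------------------------------------------------------------------
# Kaplan-Meier + log-rank
# ---------------------------------------------------------------------------

class TestKmLogrank:
    def test_identical_event_times_give_null_result(self):
        ids = [f"s{i:03d}" for i in range(20)]
        part = make_partition([1] * 10 + [2] * 10)
        surv = SurvivalTable(ids, np.tile(np.arange(1.0, 11.0), 2), np.ones(20, dtype=int))
        res = km_logrank(part, surv)
        assert res.chi2 == pytest.approx(0.0, abs=1e-10)
        assert res.p_value == pytest.approx(1.0, abs=1e-10)

    def test_hand_computed_four_event_logrank(self):
        # A events at t=1,2; B events at t=3,4; no censoring.
        # Hypergeometric table: O_A - E_A = 2 - (2/4 + 1/3) = 7/6,
        # Var = 1/4 + 2/9; chi2 = (7/6)^2 / (1/4 + 2/9)
        part = make_partition([1, 1, 2, 2])
        surv = SurvivalTable(part.sample_ids, [1.0, 2.0, 3.0, 4.0], [1, 1, 1, 1])
        res = km_logrank(part, surv)
        expected_chi2 = (7.0 / 6.0) ** 2 / (1.0 / 4.0 + 2.0 / 9.0)
        assert res.chi2 == pytest.approx(expected_chi2, rel=1e-10)

    def test_km_without_censoring_is_empirical_survival(self):
        part = make_partition([1, 1, 1, 1, 2, 2, 2, 2])
        times = np.array([1.0, 2, 3, 4, 1, 2, 3, 4])
        surv = SurvivalTable(part.sample_ids, times, np.ones(8, dtype=int))
        res = km_logrank(part, surv)
        curve = res.curves[1]
        surv_at = dict(zip(curve["time"], curve["survival"]))
        np.testing.assert_allclose([surv_at[t] for t in [1.0, 2.0, 3.0, 4.0]],
                                   [0.75, 0.5, 0.25, 0.0])

    def test_missing_survival_rows_are_counted(self):
        part = make_partition([1] * 6 + [2] * 6)
        # only 4 of 6 class-1 and 5 of 6 class-2 samples have survival data
        keep = part.sample_ids[:4] + part.sample_ids[6:11]
        rng = np.random.default_rng(1)
        surv = SurvivalTable(keep, rng.exponential(100, len(keep)), np.ones(len(keep), dtype=int))
        res = km_logrank(part, surv)
        assert res.n_used == {1: 4, 2: 5}
        assert res.n_labeled == {1: 6, 2: 6}

    def test_pairwise_excludes_third_group(self):
        rng = np.random.default_rng(2)
        part = make_partition(np.repeat([1, 2, 3], 15))
        times = np.concatenate([
            rng.exponential(50, 15), rng.exponential(500, 15), rng.exponential(50, 15)
        ])
        surv = SurvivalTable(part.sample_ids, times, np.ones(45, dtype=int))
        res = km_logrank(part, surv)
        assert set(res.pairwise_p) == {(1, 2), (1, 3), (2, 3)}
        # clusters 1 and 3 share a hazard; 2 differs strongly
        assert res.pairwise_p[(1, 2)] < 0.05
        assert res.pairwise_p[(2, 3)] < 0.05
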