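import itertools

import numpy as np
import pytest
from scipy.stats import hypergeom

from omnifuse import (
    GeneSetCollection,
    aggregate_gene_methylation,
    cross_domain_feature_view,
    ora_test,
    sam_differential,
)

from conftest import make_matrix, make_partition


class TestSamDifferential:
    def planted(self, seed=1, n=120, m=600, n_planted=40, shift=3.0):
        rng = np.random.default_rng(seed)
        X = rng.standard_normal((n, m))
        X[: n // 3, :n_planted] += shift
        mat = make_matrix(X)
        part = make_partition(np.repeat([1, 2, 3], n // 3))
        return mat, part, mat.feature_ids[:n_planted]

    def test_global_null_calls_nothing(self):
        medians = []
        for seed in range(5):
            rng = np.random.default_rng(100 + seed)
            mat = make_matrix(rng.standard_normal((60, 500)))
            part = make_partition(np.repeat([1, 2], 30))
            res = sam_differential(mat, part, (1, 2), n_perm=100, seed=seed)
            medians.append(len(res.called))
        assert np.median(medians) == 0

    def test_planted_features_recovered(self):
        mat, part, planted = self.planted()
        res = sam_differential(mat, part, (1, "rest"), n_perm=200, seed=0)
        called = set(res.called)
        recall = len(called & set(planted)) / len(planted)
        false = len(called - set(planted))
        assert recall >= 0.9
        assert false <= 5

    def test_d_sign_matches_mean_difference(self):
        mat, part, _ = self.planted(seed=2)
        res = sam_differential(mat, part, (1, "rest"), n_perm=50, seed=0)
        in_A = part.labels == 1
        diff = mat.values[in_A].mean(axis=0) - mat.values[~in_A].mean(axis=0)
        assert np.all(np.sign(res.d[diff != 0]) == np.sign(diff[diff != 0]))

    def test_called_set_shrinks_with_delta(self):
        mat, part, _ = self.planted(seed=3, shift=1.5)
        res = sam_differential(mat, part, (1, "rest"), n_perm=100, seed=0)
        sets = [set(res.called_at(delta)) for delta in (0.5, 1.0, 2.0, 4.0)]
        for smaller_delta, larger_delta in itertools.pairwise(sets):
            assert larger_delta <= smaller_delta

    def test_one_vs_one_contrast(self):
        mat, part, planted = self.planted(seed=4)
        res = sam_differential(mat, part, (1, 2), n_perm=100, seed=0)
        assert set(res.called) >= set(planted[:10])  # strong signal survives

    def test_small_class_error(self):
        mat = make_matrix(np.random.default_rng(0).standard_normal((5, 10)))
        part = make_partition([1, 1, 2, 2, 2])
        with pytest.raises(ValueError, match="at least 3"):
            sam_differential(mat, part, (1, 2))

    def test_deterministic_given_seed(self):
        mat, part, _ = self.planted(seed=5)
        r1 = sam_differential(mat, part, (1, "rest"), n_perm=50, seed=9)
        r2 = sam_differential(mat, part, (1, "rest"), n_perm=50, seed=9)
        assert r1.called == r2.called
        np.testing.assert_array_equal(r1.d, r2.d)


class TestAggregateGeneMethylation:
    def test_mean_of_two_probes(self):
        m = make_matrix(np.array([[0.2, 0.4], [0.6, 0.8]]))
        out = aggregate_gene_methylation(m, {"f0000": "geneA", "f0001": "geneA"})
        assert out.feature_ids == ["geneA"]
        np.testing.assert_allclose(out.values[:, 0], [0.3, 0.7])

    def test_unmapped_probes_ignored_and_single_probe_passthrough(self):
        m = make_matrix(np.array([[0.2, 0.4, 0.9], [0.6, 0.8, 0.1]]))
        out = aggregate_gene_methylation(m, {"f0002": "geneB"})
        assert out.feature_ids == ["geneB"]
        np.testing.assert_allclose(out.values[:, 0], [0.9, 0.1])

    def test_commutes_with_sample_subsetting(self, rng):
        m = make_matrix(rng.uniform(0, 1, size=(6, 8)))
        mapping = {f"f{j:04d}": f"g{j % 3}" for j in range(8)}
        full = aggregate_gene_methylation(m, mapping)
        sub_ids = m.sample_ids[1:4]
        sub = aggregate_gene_methylation(m.subset_samples(sub_ids), mapping)
        np.testing.assert_allclose(sub.values, full.subset_samples(sub_ids).values)

    def test_empty_map_error(self, rng):
        with pytest.raises(ValueError):
            aggregate_gene_methylation(make_matrix(rng.uniform(size=(2, 2))), {})


class TestOra:
    def test_query_equal_universe_gives_p_one(self):
        universe = [f"g{i}" for i in range(20)]
        sets = GeneSetCollection(sets={"s1": universe[:5], "s2": universe[5:9]})
        df = ora_test(universe, universe, sets)
        assert np.allclose(df["p"], 1.0)
        assert list(df["overlap"]) == list(df["set_size"])

    def test_exact_hit_closed_form(self):
        universe = [f"g{i}" for i in range(100)]
        target = universe[:5]
        sets = GeneSetCollection(sets={"hit": target})
        df = ora_test(target, universe, sets)
        from math import comb

        assert df.loc[0, "p"] == pytest.approx(1.0 / comb(100, 5))

    def test_matches_enumeration_oracle_small_universe(self):
        # exhaustively count query draws with >= observed overlap
        universe = [f"g{i}" for i in range(12)]
        gene_set = universe[:5]
        query = universe[2:7]  # overlap 3
        sets = GeneSetCollection(sets={"s": gene_set})
        df = ora_test(query, universe, sets)
        hits = 0
        total = 0
        for draw in itertools.combinations(universe, len(query)):
            total += 1
            if len(set(draw) & set(gene_set)) >= 3:
                hits += 1
        assert df.loc[0, "p"] == pytest.approx(hits / total)

    def test_q_values_dominate_p_values(self, rng):
        universe = [f"g{i}" for i in range(50)]
        sets = GeneSetCollection(sets={
            f"s{j}": list(rng.choice(universe, size=8, replace=False)) for j in range(6)
        })
        df = ora_test(universe[:10], universe, sets)
        assert np.all(df["q"].to_numpy() >= df["p"].to_numpy() - 1e-12)

    def test_query_outside_universe_error(self):
        sets = GeneSetCollection(sets={"s": ["g1"]})
        with pytest.raises(ValueError, match="not in universe"):
            ora_test(["gX"], ["g1", "g2"], sets)


class TestCrossDomainView:
    def build(self, coupled, seed=0):
        rng = np.random.default_rng(seed)
        n = 90
        part = make_partition(np.repeat([1, 2, 3], 30))
        genes = [f"gene{j:03d}" for j in range(300)]
        X = rng.standard_normal((n, 300))
        X[part.labels == 2, :40] += 3.0  # up in cluster 2
        rna = make_matrix(X)
        rna.feature_ids = genes
        meth = rng.uniform(0.3, 0.7, size=(n, 300))
        if coupled:
            meth[np.ix_(part.labels == 2, range(40))] -= 0.25
        gene_meth = make_matrix(meth)
        gene_meth.feature_ids = list(genes)
        res = sam_differential(rna, part, (2, "rest"), n_perm=100, seed=seed)
        return res, gene_meth, part

    def test_coupled_construction_gives_fraction_near_one(self):
        res, gene_meth, part = self.build(coupled=True)
        df, frac = cross_domain_feature_view(res, gene_meth, part, (2, "rest"))
        assert frac >= 0.95
        up_with_meth = sum(1 for g in res.called if res.direction[g] == "up")
        assert len(df) == up_with_meth

    def test_uncoupled_methylation_gives_fraction_near_half(self):
        res, gene_meth, part = self.build(coupled=False, seed=1)
        _, frac = cross_domain_feature_view(res, gene_meth, part, (2, "rest"))
        assert 0.3 <= frac <= 0.7
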