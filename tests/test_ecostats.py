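"""Diversity, dissimilarity, PERMANOVA, clustering and correlation."""

import itertools

import numpy as np
import pandas as pd
import pytest

from pyrosom.ecostats import (
    AbundanceTable,
    _pseudo_f,
    bray_curtis,
    bray_curtis_matrix,
    class_relative_abundance,
    diversity_table,
    hclust_profiles,
    pearson_profiles,
    permanova,
    shannon,
    simpson,
)
from pyrosom.errors import ParameterError, UndefinedSimilarityError


class TestClassRelativeAbundance:
    def test_two_class_shares(self):
        t = class_relative_abundance({"s1": [("lignin", 300.0),
                                             ("phenols", 100.0)]})
        assert t.values.loc["s1", "lignin"] == pytest.approx(0.75)
        assert t.values.loc["s1", "phenols"] == pytest.approx(0.25)

    def test_single_class_share_is_one(self):
        t = class_relative_abundance({"s1": [("MAH", 5.0), ("MAH", 7.0)]})
        assert t.values.loc["s1", "MAH"] == pytest.approx(1.0)

    def test_rows_sum_to_one(self, rng):
        feats = {
            f"s{i}": [(f"c{j}", float(h))
                      for j, h in enumerate(rng.uniform(0.1, 10, size=6))]
            for i in range(4)
        }
        t = class_relative_abundance(feats)
        assert np.allclose(t.values.sum(axis=1), 1.0, atol=1e-12)

    def test_zero_abundance_sample_excluded_with_warning(self):
        with pytest.warns(RuntimeWarning, match="s2"):
            t = class_relative_abundance({"s1": [("MAH", 1.0)],
                                          "s2": [("MAH", 0.0)]})
        assert list(t.values.index) == ["s1"]


class TestDiversity:
    def test_shannon_uniform_is_log_richness(self):
        assert shannon([0.25] * 4) == pytest.approx(np.log(4))

    def test_shannon_single_compound_zero(self):
        assert shannon([1.0]) == 0.0

    def test_shannon_direct_summation_oracle(self):
        p = (0.5, 0.25, 0.25)
        expected = -sum(pi * np.log(pi) for pi in p)
        assert shannon(p) == pytest.approx(expected)
        assert shannon(p) == pytest.approx(1.0397, abs=1e-4)

    def test_simpson_values(self):
        assert simpson([1.0]) == 0.0
        assert simpson([0.25] * 4) == pytest.approx(0.75)
        assert simpson([0.5, 0.25, 0.25]) == pytest.approx(0.625)

    def test_renormalization_warns(self):
        with pytest.warns(RuntimeWarning):
            h = shannon([2.0, 2.0])
        assert h == pytest.approx(np.log(2))

    def test_empty_vector_rejected(self):
        with pytest.raises(ParameterError):
            shannon([])

    def test_analytic_bounds(self, rng):
        for _ in range(50):
            n = int(rng.integers(2, 30))
            p = rng.dirichlet(np.ones(n))
            assert 0.0 <= shannon(p) <= np.log(n) + 1e-9
            assert 0.0 <= simpson(p) <= 1.0 - 1.0 / n + 1e-9


class TestBrayCurtis:
    def test_identical_is_zero(self):
        assert bray_curtis([1, 2, 3], [1, 2, 3]) == 0.0

    def test_disjoint_supports_is_one(self):
        assert bray_curtis([1, 0, 2], [0, 3, 0]) == 1.0

    def test_direct_formula_oracle(self):
        assert bray_curtis([1, 2], [2, 1]) == pytest.approx(1 / 3)

    def test_symmetric_and_bounded(self, rng):
        for _ in range(25):
            x = rng.uniform(0, 5, size=8)
            y = rng.uniform(0, 5, size=8)
            d = bray_curtis(x, y)
            assert d == pytest.approx(bray_curtis(y, x))
            assert 0.0 <= d <= 1.0

    def test_all_zero_pair_undefined(self):
        with pytest.raises(UndefinedSimilarityError):
            bray_curtis([0, 0], [0, 0])


class TestPermanova:
    def _toy(self, seed=1, shift=3.0, n=6):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(n, 4))
        X[n // 2:] += shift
        D = np.linalg.norm(X[:, None] - X[None, :], axis=-1)
        return D, ["a"] * (n // 2) + ["b"] * (n - n // 2)

    def test_pseudo_f_matches_exhaustive_enumeration(self):
        D, groups = self._toy()
        codes = np.array([0, 0, 0, 1, 1, 1])
        f_obs, _ = _pseudo_f(D * D, codes)
        perms = {p for p in itertools.permutations(codes)}
        fs = [_pseudo_f(D * D, np.array(p))[0] for p in perms]
        p_exact = sum(f >= f_obs for f in fs) / len(fs)
        res = permanova(D, groups, n_perm=9999, seed=3)
        assert res.pseudo_f == pytest.approx(f_obs)
        assert res.p_value == pytest.approx(p_exact, abs=0.02)

    def test_matches_skbio_statistic(self):
        from skbio.stats.distance import DistanceMatrix
        from skbio.stats.distance import permanova as skbio_permanova

        D, groups = self._toy(seed=7, n=10)
        ours = permanova(D, groups, n_perm=99, seed=0)
        ref = skbio_permanova(DistanceMatrix(D), grouping=groups,
                              permutations=99)
        assert ours.pseudo_f == pytest.approx(float(ref["test statistic"]))

    def test_strong_separation_r2_near_one_p_at_floor(self):
        D, groups = self._toy(seed=2, shift=100.0, n=12)
        res = permanova(D, groups, n_perm=199, seed=0)
        assert res.r2 > 0.97
        # permutation floor: only permutations preserving the split reach F
        assert res.p_value <= 0.02

    def test_insufficient_dof_rejected(self):
        D = np.array([[0.0, 1.0], [1.0, 0.0]])
        with pytest.raises(ParameterError):
            permanova(D, ["a", "b"], n_perm=9)

    def test_asymmetric_matrix_rejected(self):
        D = np.array([[0, 1, 2], [1, 0, 1], [0.5, 1, 0]], dtype=float)
        with pytest.raises(ParameterError):
            permanova(D, ["a", "a", "b"])

    def test_seed_reproducibility(self):
        D, groups = self._toy(n=8)
        r1 = permanova(D, groups, n_perm=99, seed=5)
        r2 = permanova(D, groups, n_perm=99, seed=5)
        assert r1.p_value == r2.p_value


def brute_force_average_linkage(D):
    """Step-by-step agglomeration oracle returning the cophenetic matrix."""
    n = D.shape[0]
    active = {i: [i] for i in range(n)}
    coph = np.zeros((n, n))
    dist = {(i, j): D[i, j] for i in range(n) for j in range(i + 1, n)}
    next_id = n
    while len(active) > 1:
        (a, b), d = min(dist.items(), key=lambda kv: (kv[1], kv[0]))
        for i in active[a]:
            for j in active[b]:
                coph[i, j] = coph[j, i] = d
        merged = active[a] + active[b]
        na, nb = len(active[a]), len(active[b])
        del active[a], active[b]
        new_dist = {}
        for (i, j), v in dist.items():
            if a in (i, j) or b in (i, j):
                continue
            new_dist[(i, j)] = v
        for c in list(active):
            da = dist.get((min(a, c), max(a, c)))
            db = dist.get((min(b, c), max(b, c)))
            new_dist[(min(c, next_id), max(c, next_id))] = (
                (na * da + nb * db) / (na + nb)
            )
        active[next_id] = merged
        dist = new_dist
        next_id += 1
    return coph


class TestHclust:
    def test_duplicate_samples_merge_first_at_zero(self):
        df = pd.DataFrame([[1.0, 2.0], [1.0, 2.0], [5.0, 0.0]],
                          index=["a", "b", "c"], columns=["x", "y"])
        dendro = hclust_profiles(AbundanceTable(df))
        assert dendro.linkage[0, 2] == pytest.approx(0.0)
        coph = dendro.cophenetic_matrix()
        assert coph.loc["a", "b"] == pytest.approx(0.0)

    def test_disjoint_blocks_split_at_top(self):
        df = pd.DataFrame(
            [[3.0, 1.0, 0, 0], [2.0, 2.0, 0, 0],
             [0, 0, 4.0, 1.0], [0, 0, 1.0, 3.0]],
            index=["a1", "a2", "b1", "b2"], columns=list("wxyz"))
        dendro = hclust_profiles(AbundanceTable(df))
        coph = dendro.cophenetic_matrix()
        within = max(coph.loc["a1", "a2"], coph.loc["b1", "b2"])
        across = coph.loc["a1", "b1"]
        assert across > within
        assert across == pytest.approx(1.0)  # disjoint -> Bray-Curtis 1

    def test_cophenetic_matches_brute_force_oracle(self, rng):
        df = pd.DataFrame(rng.uniform(0, 5, size=(6, 8)),
                          index=[f"s{i}" for i in range(6)],
                          columns=[f"c{j}" for j in range(8)])
        table = AbundanceTable(df)
        dendro = hclust_profiles(table)
        logged = np.log1p(df.to_numpy())
        n = 6
        D = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                D[i, j] = D[j, i] = bray_curtis(logged[i], logged[j])
        oracle = brute_force_average_linkage(D)
        assert np.allclose(dendro.cophenetic_matrix().to_numpy(), oracle,
                           atol=1e-10)

    def test_newick_export_parses(self):
        import dendropy
        df = pd.DataFrame(np.eye(3) + 0.1, index=list("abc"),
                          columns=list("xyz"))
        nwk = hclust_profiles(AbundanceTable(df)).to_newick()
        tree = dendropy.Tree.get(data=nwk, schema="newick")
        assert {leaf.taxon.label for leaf in tree.leaf_node_iter()} == \
            {"a", "b", "c"}

    def test_single_sample_rejected(self):
        df = pd.DataFrame([[1.0]], index=["a"], columns=["x"])
        with pytest.raises(ParameterError):
            hclust_profiles(AbundanceTable(df))


class TestPearson:
    def test_proportional_profiles_r_one(self):
        r, p = pearson_profiles([1, 2, 3, 4], [2, 4, 6, 8])
        assert r == pytest.approx(1.0)

    def test_orthogonal_to_centered_r_zero(self):
        r, _ = pearson_profiles([1.0, 2.0, 3.0], [1.0, 3.0, 1.0])
        assert r == pytest.approx(0.0, abs=1e-12)

    def test_five_point_covariance_oracle(self, rng):
        x = rng.uniform(0, 10, 5)
        y = rng.uniform(0, 10, 5)
        r, _ = pearson_profiles(x, y)
        expected = (np.sum((x - x.mean()) * (y - y.mean()))
                    / np.sqrt(np.sum((x - x.mean()) ** 2)
                              * np.sum((y - y.mean()) ** 2)))
        assert r == pytest.approx(expected)

    def test_union_of_compounds_with_absent_as_zero(self):
        x = {"a": 1.0, "b": 2.0, "c": 3.0}
        y = {"b": 2.0, "c": 3.0, "d": 4.0}
        r, _ = pearson_profiles(x, y)
        rx = np.array([1.0, 2.0, 3.0, 0.0])
        ry = np.array([0.0, 2.0, 3.0, 4.0])
        expected, _ = pearson_profiles(rx, ry)
        assert r == pytest.approx(expected)

    def test_zero_variance_undefined(self):
        with pytest.raises(UndefinedSimilarityError):
            pearson_profiles([1, 1, 1], [1, 2, 3])


class TestTables:
    def test_replicate_averaging(self):
        df = pd.DataFrame([[2.0, 0.0], [4.0, 2.0], [1.0, 1.0]],
                          index=["g1_r1", "g1_r2", "g2_r1"],
                          columns=["c1", "c2"])
        t = AbundanceTable(df, {"g1_r1": "g1", "g1_r2": "g1", "g2_r1": "g2"})
        avg = t.replicate_averaged()
        assert avg.values.loc["g1", "c1"] == pytest.approx(3.0)
        assert avg.values.loc["g1", "c2"] == pytest.approx(1.0)

    def test_bray_curtis_matrix_symmetric_zero_diag(self, rng):
        df = pd.DataFrame(rng.uniform(0, 5, size=(4, 6)),
                          index=list("abcd"))
        d = bray_curtis_matrix(AbundanceTable(df))
        assert np.allclose(d, d.T)
        assert np.allclose(np.diag(d), 0.0)

    def test_diversity_table_columns(self, rng):
        df = pd.DataFrame(rng.uniform(0, 5, size=(3, 10)),
                          index=list("abc"))
        div = diversity_table(AbundanceTable(df))
        assert set(div.columns) == {"sample", "shannon", "simpson",
                                    "richness"}
        assert len(div) == 3
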