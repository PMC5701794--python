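"""Accumulation curves, Chao1, Jaccard / Chao-Jaccard, usage distances, UPGMA."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from tcrarep.diversity import (
    accumulation_curve,
    chao1,
    chao_jaccard,
    estimate_richness,
    euclidean_usage_distance,
    hierarchical_order,
    jaccard,
    usage_distance_matrix,
)
from tcrarep.keys import KeyScheme

from conftest import make_repertoire


def _cdr3_rep(sample_id, counts):
    return make_repertoire(sample_id, counts, key_scheme=KeyScheme.CDR3_ONLY)


class TestAccumulation:
    def test_single_clonotype_curve_is_constant_one(self):
        rep = _cdr3_rep("s1", {"CAAF": 100})
        curve = accumulation_curve(rep, permutations=5, seed=1)
        assert all(m == 1.0 for m in curve.mean_unique)
        assert all(s == 0.0 for s in curve.sd_unique)

    def test_all_distinct_reads_track_the_depth(self):
        rep = _cdr3_rep("s1", {f"CA{a}{b}F": 1 for a in "ARND" for b in "GHKL"})
        curve = accumulation_curve(rep, depths=[1, 4, 16], permutations=5, seed=1)
        assert curve.mean_unique == (1.0, 4.0, 16.0)

    def test_final_point_equals_observed_richness_exactly(self):
        rep = _cdr3_rep("s1", {"CAAF": 5, "CARF": 3, "CASF": 1})
        curve = accumulation_curve(rep, permutations=20, seed=3)
        assert curve.mean_unique[-1] == rep.n_clonotypes
        assert curve.sd_unique[-1] == 0.0

    def test_two_equal_clonotypes_match_hypergeometric_expectation(self):
        # closed form: E[unique at depth d] = sum_i (1 - C(N-n_i,d)/C(N,d));
        # here 2 * (1 - C(5,2)/C(10,2)) = 14/9
        rep = _cdr3_rep("s1", {"CAAF": 5, "CARF": 5})
        perms = 2000
        curve = accumulation_curve(rep, depths=[2], permutations=perms, seed=7)
        expected = 2 * (1 - math.comb(5, 2) / math.comb(10, 2))
        assert expected == pytest.approx(14.0 / 9.0)
        mc_sd = curve.sd_unique[0] / math.sqrt(perms)
        assert abs(curve.mean_unique[0] - expected) <= 3 * max(mc_sd, 1e-9)

    def test_depth_beyond_total_is_an_error(self):
        rep = _cdr3_rep("s1", {"CAAF": 3})
        with pytest.raises(ValueError, match="depths"):
            accumulation_curve(rep, depths=[4], permutations=2, seed=1)

    def test_seed_determines_the_curve(self):
        rep = _cdr3_rep("s1", {"CAAF": 4, "CARF": 2, "CASF": 1})
        a = accumulation_curve(rep, permutations=10, seed=9)
        b = accumulation_curve(rep, permutations=10, seed=9)
        assert a == b


class TestChao1:
    def test_no_rare_clonotypes_returns_observed(self):
        assert chao1([5, 4, 3]) == 3.0

    def test_standard_formula(self):
        # S_obs 10, f1 4, f2 2 -> 10 + 16/4 = 14
        counts = [1, 1, 1, 1, 2, 2, 3, 4, 5, 6]
        assert chao1(counts) == 14.0

    def test_bias_corrected_branch_without_doubletons(self):
        # S_obs 5, f1 3, f2 0 -> 5 + 3*2/2 = 8
        counts = [1, 1, 1, 3, 4]
        assert chao1(counts) == 8.0

    def test_estimate_richness_reads_the_table(self):
        rep = _cdr3_rep("s1", {"CAAF": 1, "CARF": 1, "CASF": 2, "CATF": 5})
        assert estimate_richness(rep) == 4 + 4 / 2


class TestJaccard:
    def test_identical_key_sets(self):
        a = _cdr3_rep("a", {"CAAF": 3, "CARF": 1})
        b = _cdr3_rep("b", {"CAAF": 9, "CARF": 2})
        assert jaccard(a, b).value == 1.0

    def test_disjoint_key_sets(self):
        a = _cdr3_rep("a", {"CAAF": 3})
        b = _cdr3_rep("b", {"CARF": 3})
        assert jaccard(a, b).value == 0.0

    def test_half_overlap(self):
        a = _cdr3_rep("a", {"CAAF": 1, "CARF": 1, "CASF": 1})
        b = _cdr3_rep("b", {"CARF": 1, "CASF": 1, "CATF": 1})
        assert jaccard(a, b).value == 0.5

    def test_both_empty_flagged_undefined(self):
        a, b = _cdr3_rep("a", {}), _cdr3_rep("b", {})
        res = jaccard(a, b)
        assert not res.defined and math.isnan(res.value)

    def test_symmetry(self):
        a = _cdr3_rep("a", {"CAAF": 2, "CARF": 5})
        b = _cdr3_rep("b", {"CARF": 1, "CATF": 4})
        assert jaccard(a, b).value == jaccard(b, a).value


def brute_force_chao_jaccard(counts_a: dict, counts_b: dict) -> float:
    """Independent literal transcription of the abundance-based index."""
    n, m = sum(counts_a.values()), sum(counts_b.values())
    shared = set(counts_a) & set(counts_b)
    if not shared:
        return 0.0

    def u_hat(mine, other, n_mine, m_other):
        term1 = sum(mine[s] / n_mine for s in shared)
        f1 = sum(1 for s in shared if other[s] == 1)
        f2 = sum(1 for s in shared if other[s] == 2)
        rare = sum(mine[s] / n_mine for s in shared if other[s] == 1)
        denom = f2 if f2 > 0 else 1
        return min(term1 + ((m_other - 1) / m_other) * (f1 / (2 * denom)) * rare, 1.0)

    u = u_hat(counts_a, counts_b, n, m)
    v = u_hat(counts_b, counts_a, m, n)
    if u == 0 or v == 0:
        return 0.0
    return u * v / (u + v - u * v)


class TestChaoJaccard:
    def test_identical_abundant_samples_reach_one(self):
        a = _cdr3_rep("a", {"CAAF": 50, "CARF": 50})
        b = _cdr3_rep("b", {"CAAF": 50, "CARF": 50})
        assert chao_jaccard(a, b).value == 1.0

    def test_disjoint_supports_give_zero(self):
        a = _cdr3_rep("a", {"CAAF": 5})
        b = _cdr3_rep("b", {"CARF": 5})
        assert chao_jaccard(a, b).value == 0.0

    def test_hand_worked_half_shared_example(self):
        # A={X:5,Y:5}, B={X:5,Z:5}: U=V=1/2, index = (1/4)/(3/4) = 1/3
        a = _cdr3_rep("a", {"CAXF": 5, "CAYF": 5})
        b = _cdr3_rep("b", {"CAXF": 5, "CAZF": 5})
        assert chao_jaccard(a, b).value == pytest.approx(1.0 / 3.0, abs=1e-12)

    def test_bounded_and_symmetric_on_random_tables(self):
        rng = np.random.default_rng(21)
        species = [f"CA{a}{b}F" for a in "ARNDCQ" for b in "GHKL"]
        for _ in range(50):
            ka = rng.choice(species, size=rng.integers(2, 12), replace=False)
            kb = rng.choice(species, size=rng.integers(2, 12), replace=False)
            a = _cdr3_rep("a", {k: int(rng.integers(1, 30)) for k in ka})
            b = _cdr3_rep("b", {k: int(rng.integers(1, 30)) for k in kb})
            ab, ba = chao_jaccard(a, b).value, chao_jaccard(b, a).value
            assert ab == pytest.approx(ba, abs=1e-12)
            assert 0.0 <= ab <= 1.0
            expected = brute_force_chao_jaccard(
                {k[0]: v for k, v in a.counts().items()},
                {k[0]: v for k, v in b.counts().items()},
            )
            assert ab == pytest.approx(expected, abs=1e-12)

    def test_exceeds_plain_jaccard_when_shared_clonotypes_dominate(self):
        # abundant shared clonotypes, rare private ones
        a = _cdr3_rep("a", {"CAAF": 40, "CARF": 40, "CAPF": 1, "CAQF": 1})
        b = _cdr3_rep("b", {"CAAF": 40, "CARF": 40, "CAVF": 1, "CAWF": 1})
        assert chao_jaccard(a, b).value > jaccard(a, b).value


class TestUsageDistance:
    def test_identical_profiles_at_zero(self):
        s = pd.Series({"TRAV01-1A": 40, "TRAV02-1A": 60})
        assert euclidean_usage_distance(s, s) == 0.0

    def test_one_hot_closed_form(self):
        a = pd.Series({"x": 10_000.0, "y": 0.0})
        b = pd.Series({"x": 0.0, "y": 10_000.0})
        expected = math.sqrt(2) * math.log2(10_001)
        assert euclidean_usage_distance(a, b, pseudocount=1.0) == pytest.approx(expected)

    def test_metric_properties_on_a_triple(self):
        rng = np.random.default_rng(8)
        profiles = [
            pd.Series(rng.integers(0, 200, size=5).astype(float), index=list("abcde"))
            for _ in range(3)
        ]
        d = {
            (i, j): euclidean_usage_distance(profiles[i], profiles[j])
            for i, j in itertools.permutations(range(3), 2)
        }
        for i, j in itertools.combinations(range(3), 2):
            assert d[i, j] == pytest.approx(d[j, i])
        for i, j, k in itertools.permutations(range(3)):
            assert d[i, j] <= d[i, k] + d[k, j] + 1e-12

    def test_label_mismatch_is_a_hard_error(self):
        a = pd.Series({"x": 1.0})
        b = pd.Series({"y": 1.0})
        with pytest.raises(ValueError, match="label"):
            euclidean_usage_distance(a, b)


class TestHierarchicalOrder:
    def _block_matrix(self):
        labels = ["a1", "a2", "b1", "b2"]
        mat = pd.DataFrame(10.0, index=labels, columns=labels)
        for x, y in [("a1", "a2"), ("b1", "b2")]:
            mat.loc[x, y] = mat.loc[y, x] = 0.1
        np.fill_diagonal(mat.values, 0.0)
        return mat

    def test_two_clear_blocks_form_clades(self):
        order, _z, newick = hierarchical_order(self._block_matrix())
        assert {tuple(sorted(order[:2])), tuple(sorted(order[2:]))} == {
            ("a1", "a2"),
            ("b1", "b2"),
        }
        assert newick.endswith(";")

    def test_single_sample_is_a_single_leaf(self):
        mat = pd.DataFrame([[0.0]], index=["only"], columns=["only"])
        order, z, newick = hierarchical_order(mat)
        assert order == ["only"] and newick == "only;"

    def test_permuting_inputs_gives_isomorphic_trees(self):
        mat = self._block_matrix()
        base_order, base_z, _ = hierarchical_order(mat)
        perm = ["b2", "a1", "b1", "a2"]
        shuffled = mat.loc[perm, perm]
        order, z, _ = hierarchical_order(shuffled)
        # same merge heights and same clade partition
        assert np.allclose(sorted(base_z[:, 2]), sorted(z[:, 2]))
        assert {tuple(sorted(order[:2])), tuple(sorted(order[2:]))} == {
            tuple(sorted(base_order[:2])),
            tuple(sorted(base_order[2:])),
        }

    def test_asymmetric_matrix_rejected(self):
        mat = self._block_matrix()
        mat.iloc[0, 1] = 5.0
        with pytest.raises(ValueError, match="symmetric"):
            hierarchical_order(mat)

    def test_usage_distance_matrix_harmonises_labels(self):
        mats = usage_distance_matrix(
            {
                "s1": pd.Series({"TRAV01-1A": 10.0, "TRAV02-1A": 5.0}),
                "s2": pd.Series({"TRAV02-1A": 5.0, "TRAV03-1A": 10.0}),
            }
        )
        assert mats.loc["s1", "s2"] > 0
        assert mats.loc["s1", "s1"] == 0.0
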