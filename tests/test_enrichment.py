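"""Enrichment statistics against independent oracles.

Exhaustive oracles: the permutation GSEA p is checked against full
enumeration of hit-set placements on tiny universes; Fisher's exact p
against direct hypergeometric enumeration over every table up to N = 12;
the rank-sum example against enumeration of all rank assignments.
"""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from puvote.enrichment import (
    fisher_enrichment,
    group_compare,
    gsea_es,
    jaccard,
    permutation_enrichment,
    proportion_curve,
    similarity_profile,
    voted_status_association,
)
from puvote.io import AnnotationTable


def _series(values):
    return pd.Series(
        dict(zip((f"g{i}" for i in range(len(values))), map(float, values)))
    )


def _brute_es(hit_positions, n):
    """Independent running-sum oracle at weight exponent 0."""
    n_hits = len(hit_positions)
    total, best = 0.0, 0.0
    for i in range(n):
        if i in hit_positions:
            total += 1.0 / n_hits
        else:
            total -= 1.0 / (n - n_hits)
        if abs(total) > abs(best):
            best = total
    return best


class TestRunningSum:
    def test_hits_at_top(self):
        s = _series([5, 4, 3, 2, 1])
        res = gsea_es(s, {"g0", "g1"})
        assert res.es == pytest.approx(1.0)
        assert res.hits == 2 and res.misses == 3
        assert set(res.leading_edge) == {"g0", "g1"}

    def test_single_hit_at_bottom(self):
        s = _series([5, 4, 3, 2, 1])
        res = gsea_es(s, {"g4"})
        assert res.es == pytest.approx(-1.0)

    def test_all_genes_hit(self):
        s = _series([5, 4, 3])
        res = gsea_es(s, {"g0", "g1", "g2"})
        assert res.es == pytest.approx(1.0)
        assert res.running_sum[-1] == pytest.approx(1.0)

    def test_empty_intersection_rejected(self):
        with pytest.raises(ValueError):
            gsea_es(_series([3, 2, 1]), {"absent"})

    @settings(max_examples=60, deadline=None)
    @given(
        n=st.integers(min_value=3, max_value=10),
        data=st.data(),
    )
    def test_matches_brute_force_oracle(self, n, data):
        k = data.draw(st.integers(min_value=1, max_value=n - 1))
        hits = set(data.draw(st.permutations(range(n)))[:k])
        s = _series(range(n, 0, -1))
        res = gsea_es(s, {f"g{i}" for i in hits})
        assert res.es == pytest.approx(_brute_es(hits, n))

    @settings(max_examples=30, deadline=None)
    @given(
        scores=st.lists(
            st.integers(min_value=-50, max_value=50), min_size=4, max_size=10,
            unique=True,
        )
    )
    def test_invariant_under_monotone_transform(self, scores):
        """At exponent 0 the ES depends only on the ranking."""
        s = _series(scores)
        hit = {s.index[0], s.index[-1]}
        res1 = gsea_es(s, hit)
        res2 = gsea_es(np.exp(s / 25.0), hit)
        assert res1.es == pytest.approx(res2.es)


def _exact_perm_p(scores, hit_size, observed_abs_es):
    """Enumerate every hit-set placement (the exhaustive permutation null)."""
    n = len(scores)
    null = []
    for combo in itertools.combinations(range(n), hit_size):
        null.append(_brute_es(set(combo), n))
    k = sum(1 for e in null if abs(e) >= observed_abs_es - 1e-12)
    return k / len(null), null


class TestPermutation:
    def test_matches_exhaustive_enumeration(self):
        s = _series([6, 5, 4, 3, 2, 1])
        hit = {"g0", "g1"}
        n_perm = 4000
        res = permutation_enrichment(s, hit, n_perm=n_perm, seed=1)
        exact_p, _ = _exact_perm_p(s.to_numpy(), 2, abs(res.es))
        assert abs(res.p - exact_p) <= 2 / math.sqrt(n_perm)

    def test_top_hits_significant(self):
        s = _series(range(60, 0, -1))
        hit = {f"g{i}" for i in range(6)}
        res = permutation_enrichment(s, hit, n_perm=1000, seed=0)
        assert res.p <= 0.05
        assert res.z > 0

    def test_tied_scores_give_null_result(self):
        s = _series([1] * 30)
        hit = {f"g{i}" for i in range(5)}
        res = permutation_enrichment(s, hit, n_perm=500, seed=0)
        assert res.p > 0.5

    def test_p_never_zero(self):
        s = _series(range(40, 0, -1))
        hit = {f"g{i}" for i in range(10)}
        res = permutation_enrichment(s, hit, n_perm=200, seed=0)
        assert res.p >= 1 / 201

    def test_schemes_agree(self):
        s = _series(range(30, 0, -1))
        hit = {f"g{i}" for i in range(4)}
        r1 = permutation_enrichment(s, hit, n_perm=500, seed=3, scheme="scores")
        r2 = permutation_enrichment(s, hit, n_perm=500, seed=3, scheme="labels")
        assert r1.p == r2.p and r1.z == r2.z

    def test_too_few_permutations_rejected(self):
        with pytest.raises(ValueError):
            permutation_enrichment(_series([2, 1]), {"g0"}, n_perm=10)


def _exact_fisher_p(a, b, c, d):
    """Two-sided Fisher p by direct hypergeometric enumeration."""
    n = a + b + c + d
    row1, col1 = a + b, a + c

    def prob(x):
        return (
            math.comb(row1, x)
            * math.comb(n - row1, col1 - x)
            / math.comb(n, col1)
        )

    lo = max(0, col1 - (n - row1))
    hi = min(row1, col1)
    p_obs = prob(a)
    return sum(prob(x) for x in range(lo, hi + 1) if prob(x) <= p_obs * (1 + 1e-9))


class TestFisher:
    def test_diagonal_table(self):
        odds, p = fisher_enrichment(2, 0, 0, 2)
        assert p == pytest.approx(1 / 3)

    def test_flat_table(self):
        odds, p = fisher_enrichment(5, 5, 5, 5)
        assert odds == pytest.approx(1.0)
        assert p == pytest.approx(1.0)

    def test_anti_diagonal_table(self):
        odds, p = fisher_enrichment(0, 10, 10, 0)
        assert odds == 0.0
        assert p == pytest.approx(_exact_fisher_p(0, 10, 10, 0))

    def test_zero_margin(self):
        odds, p = fisher_enrichment(0, 0, 3, 5)
        assert odds is None
        assert p == 1.0

    def test_negative_entries_rejected(self):
        with pytest.raises(ValueError):
            fisher_enrichment(-1, 2, 3, 4)

    def test_matches_enumeration_for_all_small_tables(self):
        """Every 2x2 table with N <= 12 agrees with the hypergeometric
        enumeration oracle."""
        for n in range(2, 13):
            for a in range(n + 1):
                for b in range(n + 1 - a):
                    for c in range(n + 1 - a - b):
                        d = n - a - b - c
                        if min(a + b, c + d, a + c, b + d) == 0:
                            continue
                        _, p = fisher_enrichment(a, b, c, d)
                        assert p == pytest.approx(
                            _exact_fisher_p(a, b, c, d), abs=1e-9
                        ), (a, b, c, d)


class TestProportionCurve:
    def test_reference_is_top_half(self):
        scores = _series(range(20, 0, -1))
        ref = set(scores.index[:10])
        curve = proportion_curve(scores, ref, thresholds=[1, 5, 11, 16])
        props = curve.proportions()
        assert (props.diff().dropna() >= 0).all()
        assert props.iloc[-1] == 1.0

    def test_zero_threshold_gives_global_fraction(self):
        scores = _series([3, 2, 1, 0])
        curve = proportion_curve(scores, {"g0", "g1"}, thresholds=[0])
        assert curve.proportions().iloc[0] == 0.5

    def test_empty_subset_dropped(self, caplog):
        scores = _series([1, 2])
        with caplog.at_level("WARNING"):
            curve = proportion_curve(scores, {"g0"}, thresholds=[1, 99])
        assert list(curve.table["threshold"]) == [1]

    def test_no_thresholds_rejected(self):
        with pytest.raises(ValueError):
            proportion_curve(_series([1]), {"g0"}, thresholds=[])


class TestJaccard:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            ({"a", "b", "c"}, {"b", "c", "d"}, 0.5),
            ({"a"}, {"a"}, 1.0),
            ({"a"}, {"b"}, 0.0),
            (set(), set(), 0.0),
        ],
    )
    def test_cases(self, a, b, expected):
        assert jaccard(a, b) == expected

    @settings(max_examples=100, deadline=None)
    @given(
        a=st.frozensets(st.integers(0, 20), max_size=10),
        b=st.frozensets(st.integers(0, 20), max_size=10),
    )
    def test_symmetry_bounds_identity(self, a, b):
        j = jaccard(a, b)
        assert 0.0 <= j <= 1.0
        assert j == jaccard(b, a)
        if a:
            assert jaccard(a, a) == 1.0


class TestSimilarityProfile:
    def _table(self, rows):
        return AnnotationTable(
            records=pd.DataFrame(
                rows, columns=["gene", "term_id", "term_name", "evidence"]
            )
        )

    def test_shared_terms_give_unit_similarity(self):
        tbl = self._table(
            [
                ["CORE", "T1", "t", "IDA"], ["CORE", "T2", "t", "IDA"],
                ["G", "T1", "t", "IMP"], ["G", "T2", "t", "IMP"],
                ["H", "T1", "t", "IDA"],
            ]
        )
        prof = similarity_profile(tbl, ["G", "H"], ["CORE"])
        assert prof.similarity.loc["G", "CORE"] == 1.0
        assert prof.similarity.loc["H", "CORE"] == 0.5

    def test_unannotated_gene_excluded_from_ranking(self):
        tbl = self._table(
            [["CORE", "T1", "t", "IDA"], ["G", "T1", "t", "IDA"]]
        )
        prof = similarity_profile(tbl, ["G", "NOTERMS"], ["CORE"])
        ranking = prof.ranking("CORE")
        assert "NOTERMS" not in ranking.index
        assert "G" in ranking.index

    def test_unannotated_core_gene_rejected(self):
        tbl = self._table([["G", "T1", "t", "IDA"]])
        with pytest.raises(ValueError, match="CORE"):
            similarity_profile(tbl, ["G"], ["CORE"])

    def test_candidates_enriched_near_core(self, bundle):
        """Hidden members share experimental terms with the core genes, so
        they enrich at the high-similarity end of each core ranking."""
        genes = [g for g in bundle.gene_ids if g not in bundle.seed_genes]
        prof = similarity_profile(
            bundle.annotations, genes, list(bundle.core_genes)
        )
        core = bundle.core_genes[0]
        ranking = prof.ranking(core)
        hits = set(ranking.index) & bundle.hidden_genes
        res = permutation_enrichment(ranking, hits, n_perm=500, seed=0)
        assert res.z > 0


class TestGroupCompare:
    def test_identical_groups(self):
        p, d = group_compare([1, 2, 3, 4], [1, 2, 3, 4])
        assert 0.4 <= p <= 0.6
        assert d == 0.0

    def test_shifted_groups(self):
        rng = np.random.default_rng(0)
        b = rng.normal(0, 1, 200)
        a = b + 1.0
        p, d = group_compare(a, b)
        assert p < 0.01
        assert d == pytest.approx(1.0 / b.std(ddof=1), rel=0.05)

    def test_exact_enumeration_oracle(self):
        """A entirely below B: enumerate all C(6,3)=20 rank assignments."""
        a, b = [1, 2, 3], [4, 5, 6]
        p, _ = group_compare(a, b)
        # oracle: rank-sum of A is minimal, so P(U >= observed) over all
        # assignments is 20/20 = 1
        pooled = a + b
        u_obs = sum(1 for x in a for y in b if x > y)
        count = 0
        total = 0
        for combo in itertools.combinations(range(6), 3):
            grp_a = [pooled[i] for i in combo]
            grp_b = [pooled[i] for i in range(6) if i not in combo]
            u = sum(1 for x in grp_a for y in grp_b if x > y)
            total += 1
            if u >= u_obs:
                count += 1
        assert p == pytest.approx(count / total)

    def test_zero_spread_gives_missing_d(self):
        p, d = group_compare([1, 1, 1], [1, 1, 1])
        assert d is None

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            group_compare([1], [2, 3])


class TestVotedAssociation:
    def test_null_covariate_small_z(self):
        rng = np.random.default_rng(5)
        n = 2000
        voted = pd.Series(rng.integers(0, 2, n))
        cov = pd.Series(rng.normal(size=n))
        z, p, sep = voted_status_association(cov, voted)
        assert not sep
        assert abs(z) < 3

    def test_shifted_covariate_strong_z(self):
        rng = np.random.default_rng(5)
        n = 2000
        voted = pd.Series(rng.integers(0, 2, n))
        cov = pd.Series(rng.normal(size=n) + voted)
        z, p, sep = voted_status_association(cov, voted)
        assert not sep
        assert z > 5
        assert p < 1e-6

    def test_complete_separation_flagged(self):
        rng = np.random.default_rng(0)
        n = 200
        voted = pd.Series(np.r_[np.ones(100), np.zeros(100)].astype(int))
        cov = pd.Series(voted + rng.normal(0, 1e-4, n))
        z, p, sep = voted_status_association(cov, voted)
        assert sep
        assert z is None

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            voted_status_association(
                pd.Series([1.0, 2.0]), pd.Series([1, 1])
            )
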