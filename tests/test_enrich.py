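"""Hypergeometric enrichment, FDR, miRIS and ranking."""

import math
import warnings

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from mirrorkit.enrich import (
    Direction,
    EnrichmentParams,
    bh_fdr,
    enrich_direction,
    hypergeom_tail,
    miris,
    rank_and_filter,
)
from mirrorkit.mdb import MDBTable, QuerySet

from conftest import enumeration_tail, make_mdb, stepup_fdr


class TestHypergeomTail:
    @pytest.mark.parametrize(
        "k,n,K,N,expected",
        [
            (0, 3, 4, 10, 1.0),          # tail from zero is certain
            (2, 3, 4, 10, 1.0 / 3.0),    # 40 of the 120 possible draws
            (3, 3, 5, 5, 1.0),           # whole population is a success
            (3, 3, 4, 10, 4.0 / 120.0),  # all three hits among 4 partners
        ],
    )
    def test_frozen_enumeration_values(self, k, n, K, N, expected):
        assert hypergeom_tail(k, n, K, N) == pytest.approx(expected, abs=1e-12)

    def test_bound_violation_raises(self):
        with pytest.raises(ValueError):
            hypergeom_tail(5, 3, 4, 10)
        with pytest.raises(ValueError):
            hypergeom_tail(1, 4, 11, 10)

    @given(
        st.integers(min_value=1, max_value=9).flatmap(
            lambda N: st.tuples(
                st.just(N),
                st.integers(min_value=1, max_value=N),
                st.integers(min_value=0, max_value=N),
            )
        )
    )
    def test_matches_exhaustive_enumeration(self, nnk):
        N, n, K = nnk
        for k in range(0, min(n, K) + 1):
            assert hypergeom_tail(k, n, K, N) == pytest.approx(
                enumeration_tail(k, n, K, N), abs=1e-12
            )


class TestBhFdr:
    @pytest.mark.parametrize(
        "p,expected",
        [
            ([0.04], [0.04]),
            ([0.005, 0.5], [0.01, 0.5]),
            ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
        ],
    )
    def test_frozen_stepup_values(self, p, expected):
        assert bh_fdr(p) == pytest.approx(expected, abs=1e-12)

    def test_empty_list(self):
        assert bh_fdr([]) == []

    @given(
        st.lists(
            st.floats(min_value=1e-6, max_value=1.0, allow_nan=False),
            min_size=1,
            max_size=20,
        )
    )
    def test_matches_brute_force_stepup(self, p):
        got = bh_fdr(p)
        want = stepup_fdr(p)
        assert got == pytest.approx(want, abs=1e-12)
        assert all(q <= 1.0 + 1e-12 for q in got)
        # monotone non-decreasing when sorted by p
        order = np.argsort(p)
        assert all(np.diff(np.asarray(got)[order]) >= -1e-12)


class TestMiris:
    def test_minimum_with_two_of_ten_mdbs_exceeds_point_one(self):
        for input_size in (2, 10, 100, 10000):
            assert miris(2, 10, 2, input_size) > 0.1

    def test_maximum_is_one(self):
        assert miris(5, 5, 7, 7) == 1.0

    def test_equal_weight_arithmetic(self):
        assert miris(2, 10, 2, 20) == pytest.approx(0.15)

    def test_bound_violations(self):
        with pytest.raises(ValueError):
            miris(0, 10, 2, 20)
        with pytest.raises(ValueError):
            miris(2, 10, 0, 20)
        with pytest.raises(ValueError):
            miris(11, 10, 2, 20)

    @given(
        st.integers(1, 10), st.integers(1, 10),
        st.integers(1, 50), st.integers(1, 50),
    )
    def test_monotone_and_bounded(self, s, nsel, h, inp):
        if s > nsel or h > inp:
            return
        v = miris(s, nsel, h, inp)
        assert 0.0 < v <= 1.0
        if s + 1 <= nsel:
            assert miris(s + 1, nsel, h, inp) >= v
        if h + 1 <= inp:
            assert miris(s, nsel, h + 1, inp) >= v


class TestEnrichDirection:
    def test_single_mdb_candidate_probability(self, toy_mdb):
        """mA targets g1..g4 in a 10-gene MDB; query {g1,g2,g3} hits all three."""
        query = QuerySet.from_ids(["g1", "g2", "g3"])
        params = EnrichmentParams(min_mdbs=1, min_hits=2)
        results = enrich_direction(query, [toy_mdb], params, Direction.GENE2MIR)
        by_id = {r.candidate_id: r for r in results}
        assert "mA" in by_id
        stat = by_id["mA"].per_mdb[0]
        assert (stat.k, stat.n, stat.K, stat.N) == (3, 3, 4, 10)
        assert stat.p_value == pytest.approx(4.0 / 120.0)

    def test_default_min_mdbs_drops_single_support(self, toy_mdb):
        query = QuerySet.from_ids(["g1", "g2", "g3"])
        results = enrich_direction(
            query, [toy_mdb], EnrichmentParams(), Direction.GENE2MIR
        )
        assert results == []  # only one MDB can support anything

    def test_min_hits_drops_single_hit_candidates(self):
        mdb1 = make_mdb("a", [("mA", "g1"), ("mA", "g9"), ("mB", "g2")]
                        + [("mC", f"g{i}") for i in range(1, 9)])
        query = QuerySet.from_ids(["g1", "g2"])
        params = EnrichmentParams(min_mdbs=1, min_hits=2, p_threshold=1.0)
        results = enrich_direction(query, [mdb1], params, Direction.GENE2MIR)
        assert all(len(r.hit_union) >= 2 for r in results)
        assert "mA" not in {r.candidate_id for r in results}  # k=1 only

    def test_no_overlap_warns_and_returns_empty(self, toy_mdb):
        query = QuerySet.from_ids(["absent1", "absent2"])
        with pytest.warns(UserWarning):
            out = enrich_direction(
                query, [toy_mdb], EnrichmentParams(), Direction.GENE2MIR
            )
        assert out == []

    def test_direction_symmetry_on_transposed_table(self, toy_mdb):
        """miR2Gene on the transposed graph mirrors Gene2miR statistics."""
        transposed = MDBTable.from_edges(
            "toyT",
            toy_mdb.edges.rename(columns={"mirna": "gene", "gene": "mirna"}),
        )
        query = QuerySet.from_ids(["g1", "g2", "g3"])
        params = EnrichmentParams(min_mdbs=1, min_hits=1, p_threshold=1.0)
        fwd = enrich_direction(query, [toy_mdb], params, Direction.GENE2MIR)
        rev = enrich_direction(query, [transposed], params, Direction.MIR2GENE)
        fwd_stats = {
            r.candidate_id: (s.k, s.n, s.K, s.N, s.p_value)
            for r in fwd for s in r.per_mdb
        }
        rev_stats = {
            r.candidate_id: (s.k, s.n, s.K, s.N, s.p_value)
            for r in rev for s in r.per_mdb
        }
        assert fwd_stats == rev_stats

    def test_nestedness_across_p_thresholds(self):
        """Stricter thresholds select subsets of looser ones."""
        from mirrorkit.synth import SyntheticConfig, generate_mdbs

        cfg = SyntheticConfig(p_signal=0.5, mdb_agreement=0.8, rng_seed=7)
        tables, truth = generate_mdbs(cfg)
        query = QuerySet.from_ids(truth.planted_genes)
        sets = {}
        for p in (0.01, 0.02, 0.05):
            res = enrich_direction(
                query, tables, EnrichmentParams(p_threshold=p), Direction.GENE2MIR
            )
            sets[p] = {r.candidate_id for r in res}
        assert sets[0.01] <= sets[0.02] <= sets[0.05]


class TestRankAndFilter:
    def _fake(self, cid, score, best_p):
        from mirrorkit.enrich import EnrichmentResult

        return EnrichmentResult(
            candidate_id=cid, direction=Direction.GENE2MIR, per_mdb=(),
            supporting_mdbs=("a", "b"), hit_union=frozenset({"g1", "g2"}),
            best_p=best_p, miris=score,
        )

    def test_min_miris_threshold(self):
        results = [self._fake("x", 0.7, 0.01), self._fake("y", 0.65, 0.01),
                   self._fake("z", 0.3, 0.01)]
        kept = rank_and_filter(results, EnrichmentParams(min_miris=0.6))
        assert [r.candidate_id for r in kept] == ["x", "y"]

    def test_all_below_threshold_empty(self):
        kept = rank_and_filter(
            [self._fake("x", 0.2, 0.01)], EnrichmentParams(min_miris=0.6)
        )
        assert kept == []

    def test_tie_breaks_by_best_p_then_id(self):
        results = [self._fake("b", 0.5, 0.02), self._fake("a", 0.5, 0.01),
                   self._fake("c", 0.5, 0.01)]
        kept = rank_and_filter(results, EnrichmentParams())
        assert [r.candidate_id for r in kept] == ["a", "c", "b"]
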