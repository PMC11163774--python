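import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from occmeth import (GeneSetCollection, GseaThresholds, RankedList,
                     consensus_leading_edge, consensus_sets, enrichment_score,
                     leading_edge, preranked_gsea, read_gmt, write_gmt)
from occmeth.gsea import GseaResult


def _ranked(scores: dict) -> RankedList:
    return RankedList.from_scores("meth_log2fc", scores)


def brute_force_es(ranked: RankedList, members, weight=1.0):
    """Independent oracle: exhaustive prefix-deviation scan.

    Returns (max deviation, min deviation); the ES is whichever has the
    larger magnitude, with the sign undefined on an exact magnitude tie.
    """
    members = set(members)
    genes = list(ranked.genes)
    scores = ranked.scores.to_numpy()
    n_hit = sum(g in members for g in genes)
    total_w = sum(abs(scores[i]) ** weight if weight else 1.0
                  for i, g in enumerate(genes) if g in members)
    top, bottom, p_hit, p_miss = 0.0, 0.0, 0.0, 0.0
    for i, g in enumerate(genes):
        if g in members:
            w = abs(scores[i]) ** weight if weight else 1.0
            p_hit += (w / total_w) if total_w else 1.0 / n_hit
        else:
            p_miss += 1.0 / (len(genes) - n_hit)
        dev = p_hit - p_miss
        top = max(top, dev)
        bottom = min(bottom, dev)
    return top, bottom


def assert_matches_oracle(es, ranked, members, weight=1.0, tol=1e-9):
    top, bottom = brute_force_es(ranked, members, weight)
    if abs(top) > -bottom + tol:
        assert es == pytest.approx(top, abs=tol)
    elif -bottom > abs(top) + tol:
        assert es == pytest.approx(bottom, abs=tol)
    else:  # magnitude tie: sign is an implementation tie-break
        assert abs(es) == pytest.approx(top, abs=tol)


class TestEnrichmentScore:
    def test_singleton_extremes(self):
        ranked = _ranked({"a": 4.0, "b": 2.0, "c": 1.0, "d": -3.0})
        es_top, _, _ = enrichment_score(ranked, ["a"])
        es_bottom, _, _ = enrichment_score(ranked, ["d"])
        assert es_top == pytest.approx(1.0)
        assert es_bottom == pytest.approx(-1.0)

    def test_matches_prefix_scan_oracle_on_random_lists(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            genes = [f"g{i}" for i in range(10)]
            ranked = _ranked(dict(zip(genes, rng.normal(size=10))))
            members = rng.choice(genes, size=3, replace=False)
            es, _, _ = enrichment_score(ranked, members)
            assert_matches_oracle(es, ranked, members)

    def test_weight_zero_is_classical_ks_and_monotone_invariant(self):
        rng = np.random.default_rng(1)
        genes = [f"g{i}" for i in range(30)]
        scores = rng.normal(size=30)
        ranked = _ranked(dict(zip(genes, scores)))
        members = list(rng.choice(genes, size=8, replace=False))
        es0, _, _ = enrichment_score(ranked, members, weight=0.0)
        assert_matches_oracle(es0, ranked, members, weight=0.0)
        # any strictly increasing transform preserves the ranking, hence the ES
        transformed = _ranked(dict(zip(genes, np.exp(scores / 3.0))))
        es0t, _, _ = enrichment_score(transformed, members, weight=0.0)
        assert es0t == pytest.approx(es0, abs=1e-12)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=50, deadline=None)
    def test_es_bounded_by_one(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 40))
        k = int(rng.integers(1, n))
        genes = [f"g{i}" for i in range(n)]
        ranked = _ranked(dict(zip(genes, rng.normal(size=n))))
        es, _, _ = enrichment_score(ranked, genes[:k] if k < n else genes[:-1])
        assert abs(es) <= 1.0 + 1e-12

    def test_disjoint_set_rejected(self):
        ranked = _ranked({"a": 1.0, "b": 0.5})
        with pytest.raises(ValueError, match="disjoint"):
            enrichment_score(ranked, ["zzz"])


class TestLeadingEdge:
    def test_set_at_top_is_entirely_leading_edge(self):
        ranked = _ranked({"a": 5.0, "b": 4.0, "c": 1.0, "d": 0.5, "e": 0.1})
        es, running, peak = enrichment_score(ranked, ["a", "b"])
        assert leading_edge(ranked, ["a", "b"], running, peak) == ["a", "b"]

    def test_member_after_positive_peak_excluded(self):
        ranked = _ranked({"a": 5.0, "b": 4.0, "c": 3.0, "d": 2.0, "e": 1.0,
                          "f": 0.9, "g": 0.8, "h": -4.0})
        es, running, peak = enrichment_score(ranked, ["a", "b", "h"])
        le = leading_edge(ranked, ["a", "b", "h"], running, peak)
        assert es > 0
        assert "h" not in le

    def test_matches_membership_scan_on_random_fixtures(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            genes = [f"g{i}" for i in range(15)]
            ranked = _ranked(dict(zip(genes, rng.normal(size=15))))
            members = list(rng.choice(genes, size=4, replace=False))
            es, running, peak = enrichment_score(ranked, members)
            le = leading_edge(ranked, members, running, peak)
            ordered = list(ranked.genes)
            if es >= 0:
                expected = [g for g in ordered[: peak + 1] if g in members]
            else:
                expected = [g for g in ordered[peak:] if g in members]
            assert le == expected


class TestPrerankedGsea:
    def _toy(self, seed=0, n=60, k=8, signal=True):
        rng = np.random.default_rng(seed)
        genes = [f"g{i}" for i in range(n)]
        scores = dict(zip(genes, rng.normal(size=n)))
        if signal:  # push the member genes to the top
            for g in genes[:k]:
                scores[g] = abs(scores[g]) + 3.0
        ranked = _ranked(scores)
        coll = GeneSetCollection({"SET": genes[:k],
                                  "DECOY": list(rng.choice(genes, size=k,
                                                           replace=False))})
        return ranked, coll

    def test_identical_seed_identical_results(self):
        ranked, coll = self._toy()
        r1 = preranked_gsea(ranked, coll, n_perm=200, seed=11)
        r2 = preranked_gsea(ranked, coll, n_perm=200, seed=11)
        for a, b in zip(r1, r2):
            assert (a.es, a.nes, a.p, a.q) == (b.es, b.nes, b.p, b.q)
            assert a.leading_edge == b.leading_edge

    def test_result_independent_of_collection_order(self):
        ranked, coll = self._toy()
        rev = GeneSetCollection(dict(reversed(list(coll.sets.items()))))
        r1 = {r.name: r for r in preranked_gsea(ranked, coll, n_perm=200, seed=3)}
        r2 = {r.name: r for r in preranked_gsea(ranked, rev, n_perm=200, seed=3)}
        assert r1.keys() == r2.keys()
        for name in r1:
            assert r1[name].nes == r2[name].nes
            assert r1[name].q == r2[name].q

    def test_planted_signal_set_significant(self):
        # a set at the extreme of a long list clears the study's cutoffs
        ranked, coll = self._toy(signal=True, n=200, k=10)
        res = {r.name: r for r in preranked_gsea(ranked, coll, n_perm=500, seed=1)}
        assert res["SET"].p < 0.05
        assert res["SET"].nes > 2
        assert res["SET"].q <= 0.25
        assert np.sign(res["SET"].nes) == np.sign(res["SET"].es)

    def test_small_n_perm_records_warning(self):
        ranked, coll = self._toy()
        res = preranked_gsea(ranked, coll, n_perm=50, seed=0)
        assert all("n_perm" in (r.warning or "") for r in res)

    def test_size_filter_applied_after_universe_intersection(self):
        ranked, _ = self._toy()
        coll = GeneSetCollection({"TINY": ["g0", "g1"],
                                  "OK": [f"g{i}" for i in range(10)],
                                  "ALIEN": ["x1", "x2", "x3", "x4", "x5"]})
        with pytest.raises(ValueError, match="disjoint"):
            # a set entirely outside the universe fails enrichment_score; the
            # runner never sees it because the intersection empties it first
            enrichment_score(ranked, ["x1"])
        names = [r.name for r in preranked_gsea(ranked, coll, n_perm=100, seed=0)]
        assert names == ["OK"]

    def test_q_threshold_nesting(self):
        ranked, coll = self._toy()
        res = preranked_gsea(ranked, coll, n_perm=500, seed=5)
        at_10 = {r.name for r in res if r.q <= 0.10}
        at_25 = {r.name for r in res if r.q <= 0.25}
        assert at_10 <= at_25


def _fake_result(name, metric, nes, q, le):
    return GseaResult(name=name, metric=metric, es=np.sign(nes), nes=nes, p=0.01,
                      q=q, leading_edge=le, size=len(le), n_perm=1000, seed=0)


class TestConsensus:
    def test_set_significant_in_two_of_three_excluded(self):
        results = {
            "m1": [_fake_result("S", "m1", 2.5, 0.01, ["a"])],
            "m2": [_fake_result("S", "m2", -2.5, 0.01, ["a"])],
            "m3": [_fake_result("S", "m3", 1.2, 0.01, ["a"])],  # |NES| < 2
        }
        assert consensus_sets(results).empty
        assert consensus_leading_edge(results) == []

    def test_sign_pattern_reported(self):
        results = {
            "meth": [_fake_result("S", "meth", -2.2, 0.01, ["a", "b"])],
            "expr": [_fake_result("S", "expr", 2.4, 0.01, ["a", "c"])],
            "rho": [_fake_result("S", "rho", -2.1, 0.01, ["a", "b", "c"])],
        }
        out = consensus_sets(results)
        assert list(out.index) == ["S"]
        assert out.loc["S", "nes_meth"] < 0 < out.loc["S", "nes_expr"]
        assert consensus_leading_edge(results) == ["a"]

    def test_leading_edge_intersection_over_set_unions(self):
        results = {
            "m1": [_fake_result("A", "m1", 2.5, 0.01, ["x", "y"]),
                   _fake_result("B", "m1", -2.5, 0.01, ["z"])],
            "m2": [_fake_result("A", "m2", 2.5, 0.01, ["y", "z"])],
        }
        # union per metric: m1 -> {x,y,z}; m2 -> {y,z}; intersection {y,z}
        assert consensus_leading_edge(results) == ["y", "z"]


class TestGmtIO:
    def test_round_trip_identity(self, tmp_path):
        coll = GeneSetCollection({"S1": ["a", "b", "c"], "S2": ["d", "e"]},
                                 {"S1": "first", "S2": "second"})
        path = tmp_path / "sets.gmt"
        write_gmt(coll, path)
        back = read_gmt(path)
        assert back.sets == coll.sets
        assert back.descriptions == coll.descriptions

    def test_short_line_names_line_number(self, tmp_path):
        path = tmp_path / "bad.gmt"
        path.write_text("GOOD\tdesc\tg1\tg2\nBAD\tonly-desc\n")
        with pytest.raises(ValueError, match="line 2"):
            read_gmt(path)

    def test_duplicate_members_collapsed_with_warning(self, tmp_path):
        path = tmp_path / "dup.gmt"
        path.write_text("S\tdesc\tg1\tg2\tg1\n")
        with pytest.warns(UserWarning, match="duplicate"):
            coll = read_gmt(path)
        assert coll["S"] == ["g1", "g2"]
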