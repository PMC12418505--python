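"""Hypergeometric term enrichment, BH adjustment, domain folds, factors."""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest
from statsmodels.stats.multitest import multipletests

from phosphocons import (
    PhosphoSite,
    ProteinRecord,
    bh_adjust,
    domain_fold_enrichment,
    enrichment_factor,
    hypergeom_enrich,
    map_sites_to_domains,
)
from phosphocons.io_formats import DomainSpan


def enumerate_tail(N, K, n, k):
    """P(X >= k) by exhaustive enumeration of all C(N, n) draws."""
    annotated = set(range(K))
    total = hits = 0
    for draw in itertools.combinations(range(N), n):
        total += 1
        if len(annotated & set(draw)) >= k:
            hits += 1
    return hits / total


class TestHypergeom:
    def test_worked_example(self):
        """N=10, K=5, n=4, k=4 -> 5/210."""
        background = {f"p{i}" for i in range(10)}
        cluster = {f"p{i}" for i in range(4)}
        annotation = {"GO:X": {f"p{i}" for i in range(5)}}  # covers the cluster
        (res,) = hypergeom_enrich(cluster, background, annotation)
        assert res.k == 4 and res.K == 5
        assert res.p == pytest.approx(5 / 210)
        assert res.p == pytest.approx(enumerate_tail(10, 5, 4, 4))

    def test_zero_overlap_gives_p_one(self):
        background = {f"p{i}" for i in range(8)}
        cluster = {"p0", "p1"}
        annotation = {"GO:X": {"p5", "p6"}}
        (res,) = hypergeom_enrich(cluster, background, annotation)
        assert res.k == 0 and res.p == 1.0

    def test_cluster_equals_background_saturates(self):
        background = {f"p{i}" for i in range(6)}
        annotation = {"GO:X": {"p0", "p1", "p2"}}
        (res,) = hypergeom_enrich(background, background, annotation)
        assert res.k == res.K and res.p == pytest.approx(1.0)

    def test_cluster_outside_background_rejected(self):
        with pytest.raises(ValueError):
            hypergeom_enrich({"zz"}, {"p0"}, {"t": {"p0"}})

    def test_small_terms_skipped(self):
        background = {f"p{i}" for i in range(6)}
        annotation = {"tiny": {"p0"}, "ok": {"p0", "p1"}}
        results = hypergeom_enrich({"p0", "p1"}, background, annotation, min_term_size=2)
        assert [r.term for r in results] == ["ok"]

    def test_matches_enumeration_on_small_universes(self):
        """Exhaustive agreement for a sweep of (N, K, n, k) with N <= 9."""
        for N in (5, 7, 9):
            background = {f"p{i}" for i in range(N)}
            for K in range(N + 1):
                annotation = {"t": {f"p{i}" for i in range(K)}}
                for n in range(1, N + 1):
                    # cluster with maximal overlap min(n, K)
                    cluster = {f"p{i}" for i in range(n)}
                    results = hypergeom_enrich(
                        cluster, background, annotation, min_term_size=0
                    )
                    k = len(cluster & annotation["t"])
                    assert results[0].p == pytest.approx(
                        enumerate_tail(N, K, n, k), abs=1e-12
                    )


class TestBhAdjust:
    def test_closed_form_example(self):
        assert bh_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.42]) == [pytest.approx(0.42)]

    def test_order_preserved(self):
        p = [0.5, 0.001, 0.2]
        adj = bh_adjust(p)
        assert adj[1] == min(adj)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    def test_matches_statsmodels_on_random_vectors(self):
        rng = np.random.default_rng(77)
        for _ in range(200):
            m = int(rng.integers(1, 40))
            p = rng.uniform(0, 1, size=m)
            expected = multipletests(p, method="fdr_bh")[1]
            assert bh_adjust(list(p)) == pytest.approx(list(expected), abs=1e-12)

    def test_invariants(self):
        rng = np.random.default_rng(78)
        p = list(rng.uniform(0, 1, size=25))
        adj = bh_adjust(p)
        assert all(a >= raw - 1e-15 for a, raw in zip(adj, p))
        assert all(a <= 1.0 for a in adj)
        order = np.argsort(p)
        ranked = [adj[i] for i in order]
        assert ranked == sorted(ranked)


class TestSiteDomainMapping:
    def _spans(self):
        return [
            DomainSpan("P1", 100, 200, "IPR_A", 1),
            DomainSpan("P1", 140, 160, "IPR_B", 2),
        ]

    def test_first_match_rule(self):
        site = PhosphoSite("P1", "S", 150, 9)
        assert map_sites_to_domains([site], self._spans())[site] == "IPR_A"

    @pytest.mark.parametrize("pos,expected", [(99, None), (100, "IPR_A"), (200, "IPR_A"), (201, None)])
    def test_inclusive_boundaries(self, pos, expected):
        site = PhosphoSite("P1", "S", pos, 9)
        assert map_sites_to_domains([site], self._spans())[site] == expected

    def test_rank_beats_coordinate_order(self):
        spans = [
            DomainSpan("P1", 140, 160, "IPR_B", 1),
            DomainSpan("P1", 100, 200, "IPR_A", 2),
        ]
        site = PhosphoSite("P1", "S", 150, 9)
        assert map_sites_to_domains([site], spans)[site] == "IPR_B"


class TestDomainFold:
    def _fixture(self):
        sites = [PhosphoSite("P1", "S", i, 9) for i in (10, 20, 30, 40, 50)]
        sites += [PhosphoSite("P2", "S", i, 9) for i in (10, 20, 30, 40, 50)]
        mapping = {}
        for i, s in enumerate(sites):
            mapping[s] = "IPR_A" if i % 2 == 0 else "IPR_B"
        return sites, mapping

    def test_direct_substitution(self):
        """a=2, b=4, A=5, B=20 -> fold 2, log2 1."""
        background = [PhosphoSite("P", "S", i, 9) for i in range(1, 21)]
        mapping = {s: ("IPR_X" if s.position <= 5 else "IPR_Y") for s in background}
        pattern = background[:2] + background[10:12]  # a=2 in IPR_X, b=4
        results = domain_fold_enrichment(pattern, background, mapping, min_domain_sites=2)
        by_id = {r.interpro_id: r for r in results}
        r = by_id["IPR_X"]
        assert (r.a, r.b, r.A, r.B) == (2, 4, 5, 20)
        assert r.fold == pytest.approx(2.0) and r.log2_fold == pytest.approx(1.0)
        assert r.percent_mapped == pytest.approx(50.0)

    def test_pattern_equals_background_gives_fold_one(self):
        sites, mapping = self._fixture()
        for r in domain_fold_enrichment(sites, sites, mapping):
            assert r.fold == pytest.approx(1.0)

    def test_sparse_domains_excluded(self):
        sites, mapping = self._fixture()
        lone = PhosphoSite("P3", "S", 5, 9)
        mapping[lone] = "IPR_RARE"  # A=1
        results = domain_fold_enrichment(sites + [lone], sites + [lone], mapping)
        assert "IPR_RARE" not in {r.interpro_id for r in results}

    def test_weighted_mean_fold_is_one_at_identity(self):
        sites, mapping = self._fixture()
        results = domain_fold_enrichment(sites, sites, mapping)
        weighted = sum(r.fold * r.A for r in results) / sum(r.A for r in results)
        assert weighted == pytest.approx(1.0)

    def test_unmapped_pattern_rejected(self):
        with pytest.raises(ValueError):
            domain_fold_enrichment([], [], {})


class TestEnrichmentFactor:
    def _proteome(self, n=20, stretch="STYAAAA"):
        return [ProteinRecord(f"p{i}", "sp", stretch * 5) for i in range(n)]

    def test_predictions_subset_of_sparse_evidence(self):
        proteome = self._proteome()
        # evidence on 10% of the S/T/Y residues
        sty = [
            (rec.accession, i + 1)
            for rec in proteome
            for i, c in enumerate(rec.sequence)
            if c in "STY"
        ]
        evidence = set(sty[:: 10])
        predictions = set(list(evidence)[:5])
        ef = enrichment_factor(predictions, evidence, proteome)
        assert ef.observed_rate == 1.0
        assert ef.factor == pytest.approx(1.0 / ef.background_rate)

    def test_saturated_evidence_gives_factor_one(self):
        proteome = self._proteome()
        sty = {
            (rec.accession, i + 1)
            for rec in proteome
            for i, c in enumerate(rec.sequence)
            if c in "STY"
        }
        predictions = set(list(sty)[:7])
        ef = enrichment_factor(predictions, sty, proteome)
        assert ef.factor == pytest.approx(1.0)

    def test_duplicating_fixture_leaves_factor_unchanged(self):
        proteome = self._proteome(10)
        sty = [
            (rec.accession, i + 1)
            for rec in proteome
            for i, c in enumerate(rec.sequence)
            if c in "STY"
        ]
        evidence = set(sty[::5])
        predictions = set(sty[::7])
        ef = enrichment_factor(predictions, evidence, proteome)
        doubled_proteome = proteome + [
            ProteinRecord(f"dup_{r.accession}", r.species_id, r.sequence) for r in proteome
        ]
        doubled_evidence = evidence | {(f"dup_{a}", p) for a, p in evidence}
        ef2 = enrichment_factor(predictions, doubled_evidence, doubled_proteome)
        assert ef2.factor == pytest.approx(ef.factor)

    def test_empty_predictions_rejected(self):
        with pytest.raises(ValueError):
            enrichment_factor(set(), {("p", 1)}, self._proteome())
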