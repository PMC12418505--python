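"""Over-representation statistics for clusters, domains and predictions.

Three statistics live here:

* Term enrichment of a protein cluster against the background of all
  analysed proteins — upper-tail hypergeometric test per term, with
  Benjamini–Hochberg adjustment across terms and a significance cut of
  adjusted p < 0.1.
* Domain fold enrichment of phosphosites with a given conservation
  pattern against all domain-mapped phosphosites:
  fold = (a/b) / (A/B), reported with log2(fold) and the percentage of
  pattern sites mapped; domains with fewer than two mapped background
  sites are dropped.  Site-to-domain mapping follows the first-match
  rule: a site maps to the first domain span (file order) covering it.
* The validation enrichment factor for propagated phosphosites:
  observed evidence rate among predictions divided by the evidence rate
  of random S/T/Y residue choice in the target proteome.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .io_formats import DomainSpan, PhosphoSite, ProteinRecord

__all__ = [
    "TermResult",
    "DomainEnrichment",
    "EnrichmentFactor",
    "hypergeom_enrich",
    "bh_adjust",
    "map_sites_to_domains",
    "domain_fold_enrichment",
    "enrichment_factor",
]

DEFAULT_ALPHA = 0.1
MIN_TERM_SIZE = 2
MIN_DOMAIN_SITES = 2


@dataclass(frozen=True)
class TermResult:
    """Hypergeometric over-representation of one term in a cluster."""

    term: str
    k: int  # cluster proteins annotated with the term
    n: int  # cluster size
    K: int  # background proteins annotated
    N: int  # background size
    p: float
    p_adj: float

    @property
    def significant(self) -> bool:
        return self.p_adj < DEFAULT_ALPHA


@dataclass(frozen=True)
class DomainEnrichment:
    """Fold enrichment of pattern sites in one domain: (a/b)/(A/B)."""

    interpro_id: str
    a: int  # pattern sites in the domain
    b: int  # all pattern sites (domain-mapped)
    A: int  # background sites in the domain
    B: int  # all background sites (domain-mapped)
    fold: float
    log2_fold: float
    percent_mapped: float


@dataclass(frozen=True)
class EnrichmentFactor:
    """Observed evidence rate among predictions over the random-chance rate."""

    observed_rate: float
    background_rate: float
    factor: float
    n_predictions: int
    n_with_evidence: int


def bh_adjust(p_values: Sequence[float]) -> list[float]:
    """Benjamini–Hochberg step-up adjustment, order-preserving.

    Each adjusted p is ``min_{j>=rank} p_(j) * m / j`` clamped at 1, so
    outputs are >= the raw p values and monotone in rank.
    """
    m = len(p_values)
    if m == 0:
        return []
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p values must lie in [0, 1]")
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    # enforce monotonicity from the largest rank down
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return [float(x) for x in out]


def hypergeom_enrich(
    cluster: Iterable[str],
    background: Iterable[str],
    annotation: Mapping[str, Iterable[str]],
    min_term_size: int = MIN_TERM_SIZE,
    alpha: float = DEFAULT_ALPHA,
) -> list[TermResult]:
    """Upper-tail hypergeometric enrichment of each term in a cluster.

    For a term annotating K of the N background proteins, the p value is
    P(X >= k) where k counts annotated proteins among the n cluster
    members.  BH adjustment runs across all tested terms; terms
    annotating fewer than ``min_term_size`` background proteins are not
    tested.  The cluster must be a subset of the background.
    """
    cluster_set = frozenset(cluster)
    background_set = frozenset(background)
    if not cluster_set <= background_set:
        raise ValueError("cluster is not a subset of the background")
    N, n = len(background_set), len(cluster_set)
    rows: list[tuple[str, int, int, float]] = []
    for term in annotation:
        annotated = frozenset(annotation[term]) & background_set
        K = len(annotated)
        if K < min_term_size:
            continue
        k = len(annotated & cluster_set)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append((term, k, K, min(p, 1.0)))
    adjusted = bh_adjust([r[3] for r in rows])
    results = [
        TermResult(term=t, k=k, n=n, K=K, N=N, p=p, p_adj=p_adj)
        for (t, k, K, p), p_adj in zip(rows, adjusted)
    ]
    results.sort(key=lambda r: (r.p, r.term))
    return results


def map_sites_to_domains(
    sites: Sequence[PhosphoSite], spans: Sequence[DomainSpan]
) -> dict[PhosphoSite, str | None]:
    """Map each site to the first-listed domain span covering it.

    When overlapping spans cover a site, the span with the lowest
    ``file_rank`` wins; sites covered by no span map to None.
    Coordinates are 1-based inclusive on both ends.
    """
    by_protein: dict[str, list[DomainSpan]] = {}
    for span in sorted(spans, key=lambda s: s.file_rank):
        by_protein.setdefault(span.accession, []).append(span)
    mapping: dict[PhosphoSite, str | None] = {}
    for site in sites:
        mapping[site] = None
        for span in by_protein.get(site.accession, ()):
            if span.start <= site.position <= span.stop:
                mapping[site] = span.interpro_id
                break
    return mapping


def domain_fold_enrichment(
    pattern_sites: Iterable[PhosphoSite],
    background_sites: Iterable[PhosphoSite],
    site_domain_map: Mapping[PhosphoSite, str | None],
    min_domain_sites: int = MIN_DOMAIN_SITES,
) -> list[DomainEnrichment]:
    """Fold enrichment (a/b)/(A/B) per domain, pattern vs background.

    Only sites mapped to some domain enter the counts; domains with
    fewer than ``min_domain_sites`` mapped background sites are
    excluded.  Results are sorted by percent of pattern sites mapped
    (descending) so the head of the list is the "top domains" report.
    """
    pattern = {s for s in pattern_sites if site_domain_map.get(s) is not None}
    background = {s for s in background_sites if site_domain_map.get(s) is not None}
    if not pattern <= background:
        raise ValueError("pattern sites are not a subset of the background sites")
    b, B = len(pattern), len(background)
    if b == 0 or B == 0:
        raise ValueError("no domain-mapped sites in pattern or background")
    per_domain_bg: dict[str, int] = {}
    for s in background:
        dom = site_domain_map[s]
        per_domain_bg[dom] = per_domain_bg.get(dom, 0) + 1
    per_domain_pat: dict[str, int] = {}
    for s in pattern:
        dom = site_domain_map[s]
        per_domain_pat[dom] = per_domain_pat.get(dom, 0) + 1
    results = []
    for dom, A in per_domain_bg.items():
        if A < min_domain_sites:
            continue
        a = per_domain_pat.get(dom, 0)
        fold = (a / b) / (A / B)
        results.append(
            DomainEnrichment(
                interpro_id=dom,
                a=a,
                b=b,
                A=A,
                B=B,
                fold=fold,
                log2_fold=math.log2(fold) if fold > 0 else -math.inf,
                percent_mapped=100.0 * a / b,
            )
        )
    results.sort(key=lambda r: (-r.percent_mapped, r.interpro_id))
    return results


def enrichment_factor(
    predictions: Iterable[tuple[str, int]],
    evidence: Iterable[tuple[str, int]],
    proteome: Sequence[ProteinRecord],
    residues: str = "STY",
) -> EnrichmentFactor:
    """How much more often predictions carry evidence than random residues.

    ``observed_rate`` is the fraction of predictions found in the
    evidence set; ``background_rate`` is the fraction of the proteome's
    residues (of the stated types) carrying evidence.  The factor is
    their ratio — 1.0 means no better than picking residues at random.
    """
    pred = set(predictions)
    if not pred:
        raise ValueError("no predictions to evaluate")
    evid = set(evidence)
    residue_set = frozenset(residues.upper())
    total_residues = sum(
        sum(1 for c in rec.sequence if c in residue_set) for rec in proteome
    )
    if total_residues == 0:
        raise ValueError("proteome has no residues of the stated types")
    hits = len(pred & evid)
    observed = hits / len(pred)
    background = len(evid) / total_residues
    if background == 0:
        raise ValueError("evidence set is empty: background rate undefined")
    return EnrichmentFactor(
        observed_rate=observed,
        background_rate=background,
        factor=observed / background,
        n_predictions=len(pred),
        n_with_evidence=hits,
    )
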