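"""Kinase assignment and kinase-vs-site conservation comparison.

Each Ser/Thr site gets its most likely kinase(s) from a site -> kinase
score table (all kinases sharing the maximum score are kept).  Kinase
conservation is read off orthologue-group membership: a kinase counts
as conserved in a panel species when that species appears in the
kinase's orthologue group; species outside the registry are ignored,
and whole groups (e.g. birds, whose signal is weak) can be excluded.
Site and kinase conservation are then compared by ordinary least
squares, summarised by R^2.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .io_formats import PhosphoSite, SpeciesRegistry

__all__ = [
    "KinaseMatch",
    "KinaseConservationProfile",
    "RegressionResult",
    "top_kinases",
    "kinase_conservation",
    "regress_conservation",
]


@dataclass(frozen=True)
class KinaseMatch:
    """The top-scoring kinase(s) for one site; ties share the maximum."""

    site: PhosphoSite
    kinases: frozenset[str]
    score: float


@dataclass(frozen=True)
class KinaseConservationProfile:
    """Per-group conservation of one kinase from orthologue membership."""

    kinase: str
    orthodb_group: str
    species_present: frozenset[str]
    group_percent: Mapping[str, float]

    def overall_percent(self, registry: SpeciesRegistry) -> float:
        ids = registry.species_ids
        return 100.0 * len(self.species_present & ids) / len(ids)


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    n: int


def top_kinases(site: PhosphoSite, site_scores: Mapping[str, float]) -> KinaseMatch:
    """All kinases attaining the maximum likelihood score for the site."""
    if not site_scores:
        raise ValueError("empty kinase score map")
    best = max(site_scores.values())
    winners = frozenset(k for k, v in site_scores.items() if v == best)
    return KinaseMatch(site=site, kinases=winners, score=best)


def kinase_conservation(
    kinase: str,
    orthodb_group: str,
    group_members: Iterable[str],
    registry: SpeciesRegistry,
    excluded_groups: Iterable[str] = (),
) -> KinaseConservationProfile:
    """Score a kinase's conservation per registry group.

    ``group_members`` is the orthologue group's species list; species
    not in the registry are ignored.  Groups named in
    ``excluded_groups`` are omitted from the output entirely.
    """
    excluded = set(excluded_groups)
    present = frozenset(group_members) & registry.species_ids
    percents = {
        name: 100.0 * len(present & members) / len(members)
        for name, members in registry.groups.items()
        if name not in excluded and members
    }
    return KinaseConservationProfile(
        kinase=kinase,
        orthodb_group=orthodb_group,
        species_present=present,
        group_percent=percents,
    )


def regress_conservation(
    pairs: Sequence[tuple[float, float]],
) -> RegressionResult:
    """OLS of kinase conservation on site conservation, with R^2.

    Requires at least three pairs and nonzero variance in the predictor
    (two points always fit exactly and say nothing).
    """
    if len(pairs) < 3:
        raise ValueError(f"need >= 3 pairs, got {len(pairs)}")
    x = np.array([p[0] for p in pairs], dtype=float)
    y = np.array([p[1] for p in pairs], dtype=float)
    if np.allclose(x, x[0]):
        raise ValueError("zero variance in predictor: R^2 undefined")
    fit = stats.linregress(x, y)
    return RegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        n=len(pairs),
    )
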