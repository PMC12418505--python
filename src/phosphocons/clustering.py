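"""Conservation-pattern clustering and descriptive labeling.

Proteins (or individual sites, or kinases — anything with a vector of
group conservation percentages) are grouped by agglomerative
hierarchical clustering on Euclidean distances between raw percentage
vectors, and the tree is cut into exactly k clusters.  Each cluster is
then given a descriptive label ("High in all species", "High in
primates", ...) drawn from an explicit template catalog: a template
constrains some groups to High (>= 75% conserved) or Medium (>= 50%),
and a cluster takes the best-matching template when at least half of
its members satisfy it, otherwise it is labeled "mixed".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from .conservation import ProteinConservationProfile

__all__ = [
    "HIGH_THRESHOLD",
    "MEDIUM_THRESHOLD",
    "LabelTemplate",
    "ClusterAssignment",
    "default_templates",
    "cluster_profiles",
    "match_template",
    "label_clusters",
]

HIGH_THRESHOLD = 75.0
MEDIUM_THRESHOLD = 50.0
MIXED_LABEL = "mixed"

#: Canonical order in which group percentages are vectorised.
DEFAULT_GROUP_ORDER = [
    "primates",
    "other-mammals",
    "birds",
    "fish",
    "reptiles",
    "amphibians",
    "insects-invertebrates",
    "fungi",
    "plants",
    "protists",
]


@dataclass(frozen=True)
class LabelTemplate:
    """A named conservation pattern: constrained groups and their levels.

    ``requirements`` maps group name -> "High" or "Medium"; unlisted
    groups are unconstrained.  High means >= 75% conserved, Medium
    >= 50% (both inclusive).
    """

    name: str
    requirements: Mapping[str, str]

    def __post_init__(self) -> None:
        if not self.requirements:
            raise ValueError(f"template {self.name!r} constrains no group")
        bad = {v for v in self.requirements.values()} - {"High", "Medium"}
        if bad:
            raise ValueError(f"template {self.name!r}: unknown levels {sorted(bad)}")

    def threshold(self, group: str) -> float:
        return HIGH_THRESHOLD if self.requirements[group] == "High" else MEDIUM_THRESHOLD


@dataclass
class ClusterAssignment:
    """Cluster ids (1..k) per accession, plus labels and label support."""

    assignments: dict[str, int]
    labels: dict[int, str] = field(default_factory=dict)
    support: dict[int, float] = field(default_factory=dict)

    @property
    def k(self) -> int:
        return max(self.assignments.values(), default=0)

    def members(self, cluster_id: int) -> list[str]:
        return [a for a, c in self.assignments.items() if c == cluster_id]


def default_templates(base_groups: Sequence[str] = tuple(DEFAULT_GROUP_ORDER)) -> list[LabelTemplate]:
    """The built-in label catalog, most-specific (most groups constrained) first.

    Mirrors the descriptive labels used for the ten-cluster heatmaps:
    conservation High/Medium in all species, in animals, in vertebrates
    (with or without fish), in mammals, or in primates only.
    """
    base = list(base_groups)
    animals = [g for g in base if g not in ("fungi", "plants", "protists")]
    vertebrates = [g for g in animals if g != "insects-invertebrates"]
    vertebrates_no_fish = [g for g in vertebrates if g != "fish"]
    mammals = ["primates", "other-mammals"]

    def make(name: str, groups: Sequence[str], level: str) -> LabelTemplate:
        return LabelTemplate(name, {g: level for g in groups})

    return [
        make("High in all species", base, "High"),
        make("Medium in all species", base, "Medium"),
        make("High in animals", animals, "High"),
        make("Medium in animals", animals, "Medium"),
        make("High in vertebrates", vertebrates, "High"),
        make("Medium in vertebrates", vertebrates, "Medium"),
        make("High in vertebrates except fish", vertebrates_no_fish, "High"),
        make("Medium in vertebrates except fish", vertebrates_no_fish, "Medium"),
        make("High in mammals", mammals, "High"),
        make("Medium in mammals", mammals, "Medium"),
        make("High in primates", ["primates"], "High"),
        make("Medium in primates", ["primates"], "Medium"),
    ]


def _vectorise(
    profiles: Sequence[ProteinConservationProfile],
    group_order: Sequence[str] | None,
) -> tuple[list[str], np.ndarray, list[str]]:
    if group_order is None:
        groups = [g for g in DEFAULT_GROUP_ORDER if g in profiles[0].group_percent]
        if not groups:
            groups = sorted(profiles[0].group_percent)
    else:
        groups = list(group_order)
    accessions = [p.accession for p in profiles]
    try:
        matrix = np.array(
            [[p.group_percent[g] for g in groups] for p in profiles], dtype=float
        )
    except KeyError as exc:
        raise ValueError(f"profile missing group {exc}") from None
    return accessions, matrix, groups


def cluster_profiles(
    profiles: Sequence[ProteinConservationProfile],
    k: int,
    linkage_method: str = "complete",
    group_order: Sequence[str] | None = None,
    standardize: bool = False,
) -> ClusterAssignment:
    """Hierarchically cluster group-percentage vectors and cut into k clusters.

    Distances are Euclidean on raw percentages (optionally standardized
    per group with ``standardize=True``); the default linkage is
    "complete".  Cluster ids are 1..k.
    """
    if k < 1 or k > len(profiles):
        raise ValueError(f"k must be in 1..{len(profiles)}, got {k}")
    accessions, matrix, _ = _vectorise(profiles, group_order)
    if standardize:
        sd = matrix.std(axis=0)
        sd[sd == 0] = 1.0
        matrix = (matrix - matrix.mean(axis=0)) / sd
    if len(profiles) == 1:
        return ClusterAssignment(assignments={accessions[0]: 1})
    tree = linkage(pdist(matrix, metric="euclidean"), method=linkage_method)
    raw = fcluster(tree, t=k, criterion="maxclust")
    # Renumber so cluster ids follow first appearance, making assignments
    # deterministic for equivalent inputs.
    remap: dict[int, int] = {}
    assignments: dict[str, int] = {}
    for acc, cid in zip(accessions, raw):
        if cid not in remap:
            remap[cid] = len(remap) + 1
        assignments[acc] = remap[cid]
    return ClusterAssignment(assignments=assignments)


def match_template(
    profile: ProteinConservationProfile, template: LabelTemplate
) -> bool:
    """Does the profile meet every constrained group's threshold (inclusive)?"""
    for group, _level in template.requirements.items():
        if group not in profile.group_percent:
            raise ValueError(
                f"template {template.name!r} constrains unknown group {group!r}"
            )
        if profile.group_percent[group] < template.threshold(group):
            return False
    return True


def label_clusters(
    assignment: ClusterAssignment,
    profiles: Sequence[ProteinConservationProfile],
    templates: Sequence[LabelTemplate],
) -> ClusterAssignment:
    """Label each cluster with its best-matching template.

    The template matched by the largest fraction of members wins and is
    assigned when that fraction is >= 0.5; otherwise the cluster is
    "mixed".  Ties go to the earlier template in the catalog (catalogs
    list most-specific templates first).
    """
    if not templates:
        raise ValueError("empty template catalog")
    by_acc = {p.accession: p for p in profiles}
    labels: dict[int, str] = {}
    support: dict[int, float] = {}
    for cid in sorted(set(assignment.assignments.values())):
        members = [by_acc[a] for a in assignment.members(cid)]
        best_name, best_frac = MIXED_LABEL, -1.0
        for tmpl in templates:
            frac = sum(match_template(m, tmpl) for m in members) / len(members)
            if frac > best_frac:  # strict: earlier template wins ties
                best_name, best_frac = tmpl.name, frac
        if best_frac >= 0.5:
            labels[cid] = best_name
            support[cid] = best_frac
        else:
            labels[cid] = MIXED_LABEL
            support[cid] = max(best_frac, 0.0)
    return ClusterAssignment(
        assignments=dict(assignment.assignments), labels=labels, support=support
    )
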