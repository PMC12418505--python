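"""Per-site, per-group and per-protein phosphosite conservation.

A reference site is conserved in a species when the residue aligned to
it equals the reference residue, with one substitution tolerated: a Thr
aligned to a reference Ser counts as conserved and vice versa (never for
Tyr, and never involving other residues).  Gaps, ambiguity codes (``X``)
and species missing from the alignment all count as "not conserved",
and group percentages always divide by the full group size, keeping
scores comparable across proteins.

The +1 residue (immediately C-terminal to the site — the position read
by proline-directed kinases) is scored the same way against the
reference's next residue; S/T equivalence applies there only when that
reference residue is itself S or T.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .io_formats import GAP, Msa, PhosphoSite, SpeciesRegistry
from .homology_msa import map_reference_positions

__all__ = [
    "SiteConservationProfile",
    "ProteinConservationProfile",
    "BoxStats",
    "residues_equivalent",
    "site_conserved",
    "profile_site",
    "profile_protein",
    "classify_disorder",
    "tukey_box_stats",
    "compare_groups",
]

_ST = frozenset("ST")


@dataclass(frozen=True)
class SiteConservationProfile:
    """Conservation flags and group percentages for one phosphosite."""

    site: PhosphoSite
    flags: Mapping[str, bool]
    plus1_flags: Mapping[str, bool] | None  # None: site is reference C-terminal
    group_percent: Mapping[str, float]

    def overall_percent(self, registry: SpeciesRegistry) -> float:
        """Percentage conserved over every registry species."""
        ids = registry.species_ids
        return 100.0 * sum(self.flags.get(s, False) for s in ids) / len(ids)


@dataclass(frozen=True)
class ProteinConservationProfile:
    """Unweighted mean of a protein's site percentages, per residue class."""

    accession: str
    residue_class: str  # "ST" or "Y"
    group_percent: Mapping[str, float]
    n_sites: int = 0


@dataclass(frozen=True)
class BoxStats:
    """Tukey boxplot statistics: box = quartiles, whiskers = farthest
    points within 1.5x IQR of the box, remaining points are outliers."""

    q1: float
    median: float
    q3: float
    whisker_low: float
    whisker_high: float
    outliers: tuple[float, ...]


def residues_equivalent(ref: str, other: str, st_equivalent: bool) -> bool:
    """Conservation rule for one aligned residue pair.

    True iff ``other`` equals ``ref``, or S/T substitution applies
    (``st_equivalent`` and both residues in {S, T}).  Gaps and ``X``
    never match anything, including themselves.
    """
    if ref == GAP or other == GAP or ref == "X" or other == "X":
        return False
    if other == ref:
        return True
    return st_equivalent and ref in _ST and other in _ST


def site_conserved(
    msa: Msa,
    position: int,
    species_row: str,
    st_equivalent: bool,
    _position_map: Mapping[int, int] | None = None,
) -> bool:
    """Is the reference residue at ``position`` conserved in ``species_row``?"""
    pos_map = map_reference_positions(msa) if _position_map is None else _position_map
    if position not in pos_map:
        raise ValueError(
            f"position {position} beyond reference length {len(pos_map)}"
        )
    col = pos_map[position] - 1
    ref_char = msa.reference_row[col]
    other_char = msa.rows[species_row][col]
    return residues_equivalent(ref_char, other_char, st_equivalent)


def _group_percents(
    flags: Mapping[str, bool], registry: SpeciesRegistry
) -> dict[str, float]:
    return {
        name: 100.0 * sum(flags.get(s, False) for s in members) / len(members)
        for name, members in registry.groups.items()
        if members
    }


def profile_site(
    msa: Msa,
    site: PhosphoSite,
    registry: SpeciesRegistry,
    row_species: Mapping[str, str] | None = None,
) -> SiteConservationProfile:
    """Score one site (and its +1 residue) against every registry species.

    ``row_species`` maps MSA row ids to species ids; by default each
    non-reference row id is taken as a species id directly.  Registry
    species absent from the MSA get flag False but stay in every
    denominator.  S/T equivalence applies when the compared reference
    residue is S or T — for the site that means Ser/Thr sites only, and
    for the +1 position it depends on the reference +1 residue.
    """
    pos_map = map_reference_positions(msa)
    if site.position not in pos_map:
        raise ValueError(
            f"site {site.accession}/{site.residue}{site.position} beyond reference"
        )
    ref_seq = msa.reference_sequence
    if ref_seq[site.position - 1] != site.residue:
        raise ValueError(
            f"reference residue at {site.position} is {ref_seq[site.position - 1]!r},"
            f" expected {site.residue!r}"
        )
    if row_species is None:
        row_species = {
            rid: rid for rid in msa.rows if rid != msa.reference_id
        }
    st_site = site.residue in _ST
    has_plus1 = site.position + 1 <= len(ref_seq)
    st_plus1 = has_plus1 and ref_seq[site.position] in _ST

    flags = {s: False for s in registry.species_ids}
    plus1 = {s: False for s in registry.species_ids} if has_plus1 else None
    for rid, species_id in row_species.items():
        if species_id not in flags:
            continue
        flags[species_id] = site_conserved(
            msa, site.position, rid, st_site, _position_map=pos_map
        )
        if plus1 is not None:
            plus1[species_id] = site_conserved(
                msa, site.position + 1, rid, st_plus1, _position_map=pos_map
            )
    return SiteConservationProfile(
        site=site,
        flags=flags,
        plus1_flags=plus1,
        group_percent=_group_percents(flags, registry),
    )


def profile_protein(
    profiles: Sequence[SiteConservationProfile],
    residue_class: str,
) -> ProteinConservationProfile | None:
    """Average site percentages over a protein's sites of one residue class.

    Returns None when the protein has no site of the class (caller skips
    the protein for that class).
    """
    if residue_class not in ("ST", "Y"):
        raise ValueError(f"residue_class must be 'ST' or 'Y', got {residue_class!r}")
    selected = [p for p in profiles if p.site.residue_class == residue_class]
    if not selected:
        return None
    accessions = {p.site.accession for p in selected}
    if len(accessions) > 1:
        raise ValueError(f"profiles span multiple proteins: {sorted(accessions)}")
    groups = selected[0].group_percent.keys()
    means = {
        g: float(np.mean([p.group_percent[g] for p in selected])) for g in groups
    }
    return ProteinConservationProfile(
        accession=accessions.pop(),
        residue_class=residue_class,
        group_percent=means,
        n_sites=len(selected),
    )


def classify_disorder(score: float) -> str:
    """Classify a disorder predictor score: disordered iff score > 0.5 (strict)."""
    if not 0.0 <= score <= 1.0:
        raise ValueError(f"disorder score must be in [0, 1], got {score}")
    return "disordered" if score > 0.5 else "ordered"


def tukey_box_stats(values: Sequence[float]) -> BoxStats:
    """Tukey boxplot statistics with 1.5x IQR whiskers."""
    if len(values) == 0:
        raise ValueError("no data for box statistics")
    arr = np.asarray(values, dtype=float)
    q1, med, q3 = np.percentile(arr, [25, 50, 75])
    iqr = q3 - q1
    low_fence, high_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = arr[(arr >= low_fence) & (arr <= high_fence)]
    outliers = arr[(arr < low_fence) | (arr > high_fence)]
    return BoxStats(
        q1=float(q1),
        median=float(med),
        q3=float(q3),
        whisker_low=float(inside.min()),
        whisker_high=float(inside.max()),
        outliers=tuple(sorted(float(x) for x in outliers)),
    )


def compare_groups(
    values_a: Sequence[float], values_b: Sequence[float]
) -> tuple[BoxStats, BoxStats, float, float]:
    """Box statistics per arm plus a Welch two-sample t test.

    With fewer than two values in either arm (or zero variance in both)
    the test statistic and p value are NaN; the boxes are still returned.
    """
    box_a = tukey_box_stats(values_a)
    box_b = tukey_box_stats(values_b)
    if len(values_a) < 2 or len(values_b) < 2:
        return box_a, box_b, math.nan, math.nan
    if list(values_a) == list(values_b):
        # identical samples: no difference by definition
        return box_a, box_b, 0.0, 1.0
    t_stat, p_value = stats.ttest_ind(values_a, values_b, equal_var=False)
    return box_a, box_b, float(t_stat), float(p_value)
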