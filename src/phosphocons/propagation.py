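"""Propagating reference phosphosites to other species, with validation.

A reference site is propagated to a species when both the residue
aligned with the site and the residue at the reference +1 position are
conserved (Ser/Thr substitutions tolerated where the reference residue
is S or T).  The predicted site is reported in target-protein
coordinates, obtained by ungapping the species row up to the matched
column, so predictions can annotate target proteomes directly.

Reference C-terminal sites have no +1 residue to compare, so they are
skipped and counted in a skipped-sites report rather than propagated
unconditionally.  By default the target's +1 residue is read at the
reference-anchored +1 column; the alternative "next residue in the
target sequence" behaviour is available via ``plus1_mode="adjacent"``.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .io_formats import GAP, Msa, PhosphoSite, SpeciesRegistry
from .conservation import residues_equivalent
from .homology_msa import map_reference_positions

__all__ = [
    "PredictedSite",
    "ValidationSummary",
    "propagate_sites",
    "validate_predictions",
    "summarize_by_group",
]

_ST = frozenset("ST")


@dataclass(frozen=True)
class PredictedSite:
    """A propagated phosphosite in a target species, traced to its source."""

    species_id: str
    accession: str
    position: int  # 1-based in the ungapped target sequence
    residue: str
    plus1_residue: str
    source: PhosphoSite

    @property
    def residue_class(self) -> str:
        return "ST" if self.residue in _ST else "Y"


@dataclass(frozen=True)
class ValidationSummary:
    """Evidence coverage of predictions, per residue class.

    ``any_evidence_percent[c]`` is the share of class-c predictions with
    any evidence; ``strong_percent[c]`` the share of *evidenced*
    class-c predictions whose evidence count reaches ``min_strong``.
    """

    n_predictions: Mapping[str, int]
    any_evidence_percent: Mapping[str, float]
    strong_percent: Mapping[str, float]
    min_strong: int


def propagate_sites(
    msa: Msa,
    sites: Sequence[PhosphoSite],
    registry: SpeciesRegistry | None = None,
    row_species: Mapping[str, tuple[str, str]] | None = None,
    plus1_mode: str = "column",
) -> tuple[list[PredictedSite], list[PhosphoSite]]:
    """Predict phosphosites in every species row of one alignment.

    ``row_species`` maps MSA row id -> (species_id, target accession);
    by default each non-reference row id serves as both.  When a
    registry is given, rows for species outside it are ignored.

    Returns (predictions, skipped_sites); skipped sites are those with
    no +1 residue on the reference (C-terminal), which the rule cannot
    evaluate.
    """
    if plus1_mode not in ("column", "adjacent"):
        raise ValueError(f"plus1_mode must be 'column' or 'adjacent', got {plus1_mode!r}")
    pos_map = map_reference_positions(msa)
    ref_seq = msa.reference_sequence
    if row_species is None:
        row_species = {
            rid: (rid, rid) for rid in msa.rows if rid != msa.reference_id
        }
    if registry is not None:
        row_species = {
            rid: sp for rid, sp in row_species.items() if sp[0] in registry.species_ids
        }
    predictions: list[PredictedSite] = []
    skipped: list[PhosphoSite] = []
    # Precompute, per row, cumulative ungapped positions per column.
    for site in sites:
        if site.position not in pos_map:
            raise ValueError(f"site position {site.position} beyond reference")
        if ref_seq[site.position - 1] != site.residue:
            raise ValueError(
                f"reference residue mismatch at {site.accession}:{site.position}"
            )
        if site.position + 1 > len(ref_seq):
            skipped.append(site)
            continue
        site_col = pos_map[site.position] - 1
        plus1_col = pos_map[site.position + 1] - 1
        ref_plus1 = ref_seq[site.position]
        st_site = site.residue in _ST
        st_plus1 = ref_plus1 in _ST
        for rid, (species_id, target_acc) in row_species.items():
            row = msa.rows[rid]
            target_char = row[site_col]
            if not residues_equivalent(site.residue, target_char, st_site):
                continue
            if plus1_mode == "column":
                plus1_char = row[plus1_col]
            else:
                # next residue in the target sequence after the site column
                rest = row[site_col + 1 :].replace(GAP, "")
                plus1_char = rest[0] if rest else GAP
            if not residues_equivalent(ref_plus1, plus1_char, st_plus1):
                continue
            target_pos = len(row[: site_col + 1].replace(GAP, ""))
            predictions.append(
                PredictedSite(
                    species_id=species_id,
                    accession=target_acc,
                    position=target_pos,
                    residue=target_char,
                    plus1_residue=plus1_char,
                    source=site,
                )
            )
    return predictions, skipped


def validate_predictions(
    predictions: Sequence[PredictedSite],
    evidence: Mapping[tuple[str, int], int],
    min_strong: int = 5,
) -> ValidationSummary:
    """Evidence coverage of predictions, split by residue class (ST / Y)."""
    if not predictions:
        raise ValueError("no predictions to validate")
    n: dict[str, int] = {"ST": 0, "Y": 0}
    evidenced: dict[str, int] = {"ST": 0, "Y": 0}
    strong: dict[str, int] = {"ST": 0, "Y": 0}
    for p in predictions:
        cls = p.residue_class
        n[cls] += 1
        count = evidence.get((p.accession, p.position))
        if count is not None:
            evidenced[cls] += 1
            if count >= min_strong:
                strong[cls] += 1
    any_pct = {
        cls: (100.0 * evidenced[cls] / n[cls]) if n[cls] else float("nan")
        for cls in n
    }
    strong_pct = {
        cls: (100.0 * strong[cls] / evidenced[cls]) if evidenced[cls] else float("nan")
        for cls in n
    }
    return ValidationSummary(
        n_predictions=n,
        any_evidence_percent=any_pct,
        strong_percent=strong_pct,
        min_strong=min_strong,
    )


def summarize_by_group(
    predictions: Iterable[PredictedSite],
    registry: SpeciesRegistry,
) -> tuple[dict[str, Counter], dict[str, Counter]]:
    """Counts of predicted Ser/Thr/Tyr per species and per registry group.

    Returns (per_species, per_group) where each value is a Counter over
    residues S, T, Y.  Group counts sum the group's species counts, so a
    species in several (nested) groups contributes to each.
    """
    per_species: dict[str, Counter] = {}
    for p in predictions:
        per_species.setdefault(p.species_id, Counter())[p.residue] += 1
    per_group: dict[str, Counter] = {}
    for name, members in registry.groups.items():
        total: Counter = Counter()
        for sid in members:
            total.update(per_species.get(sid, Counter()))
        per_group[name] = total
    return per_species, per_group
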