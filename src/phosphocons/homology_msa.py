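"""Top-hit selection and reference-anchored star alignments.

For each reference protein, one significant homolog per species is kept
(minimum E-value, ties broken by maximum bit score, then input order;
hits above the E-value threshold are discarded).  Alignments are built
as reference-anchored star alignments: each subject is globally aligned
to the reference (BLOSUM62, affine gaps) and the pairwise alignments are
merged through shared reference coordinates.  Conservation is only ever
read at reference-anchored columns, so inter-subject alignment quality
is immaterial; externally produced MSAs remain loadable for exact
reproduction of alignment-dependent results.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from Bio import Align
from Bio.Align import substitution_matrices

from .io_formats import GAP, HomologyHit, Msa, ProteinRecord

__all__ = [
    "DEFAULT_EVALUE_THRESHOLD",
    "AlignmentParams",
    "TopHitMap",
    "select_top_hits",
    "build_star_msa",
    "map_reference_positions",
]

#: Significance threshold for keeping a homology hit.
DEFAULT_EVALUE_THRESHOLD = 1e-5


@dataclass(frozen=True)
class AlignmentParams:
    """Pairwise global alignment scoring (stand-in for external aligner defaults)."""

    matrix: str = "BLOSUM62"
    gap_open: float = 11.0
    gap_extend: float = 1.0

    def __post_init__(self) -> None:
        if self.gap_open < 0 or self.gap_extend < 0:
            raise ValueError("gap penalties must be nonnegative")


@dataclass(frozen=True)
class TopHitMap:
    """At most one significant hit per species for a single query."""

    query_accession: str
    hits: Mapping[str, HomologyHit]


def select_top_hits(
    hits: Sequence[HomologyHit],
    threshold: float = DEFAULT_EVALUE_THRESHOLD,
) -> TopHitMap:
    """Keep the top significant hit (E-value <= threshold) per species.

    Per species the hit with minimal E-value wins; ties go to the larger
    bit score, then to the earlier input row.  Species whose best hit
    exceeds the threshold are absent from the map.  All hits must share
    one query accession.
    """
    if not hits:
        raise ValueError("select_top_hits needs at least one hit")
    queries = {h.query_accession for h in hits}
    if len(queries) > 1:
        raise ValueError(f"hits mix multiple queries: {sorted(queries)}")
    best: dict[str, tuple[float, float, int]] = {}
    chosen: dict[str, HomologyHit] = {}
    for idx, h in enumerate(hits):
        if h.e_value > threshold:
            continue
        key = (h.e_value, -h.bit_score, idx)
        if h.species_id not in best or key < best[h.species_id]:
            best[h.species_id] = key
            chosen[h.species_id] = h
    return TopHitMap(query_accession=queries.pop(), hits=chosen)


def _make_aligner(params: AlignmentParams) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load(params.matrix)
    aligner.mode = "global"
    aligner.open_gap_score = -params.gap_open
    aligner.extend_gap_score = -params.gap_extend
    # End gaps free: homology hits are often partial relative to the query.
    aligner.target_end_gap_score = 0.0
    aligner.query_end_gap_score = 0.0
    return aligner


def _pairwise(
    aligner: Align.PairwiseAligner, reference: str, subject: str
) -> tuple[str, str]:
    alignment = next(iter(aligner.align(reference, subject)))
    ref_aln, sub_aln = str(alignment[0]), str(alignment[1])
    return ref_aln, sub_aln


def build_star_msa(
    reference: ProteinRecord,
    subjects: Sequence[ProteinRecord],
    params: AlignmentParams = AlignmentParams(),
) -> Msa:
    """Align every subject to the reference and merge on reference columns.

    Each pairwise alignment contributes, per reference residue, the
    subject residue aligned to it plus any insertion run that precedes
    it.  Merged columns interleave: for each reference position, first
    the maximal insertion run over all subjects (gap-padded), then the
    anchored column itself.  The reference row ungaps to the reference
    sequence by construction.
    """
    if not subjects:
        raise ValueError("build_star_msa needs at least one subject")
    aligner = _make_aligner(params)
    ref_seq = reference.sequence
    n = len(ref_seq)
    # Per subject: inserts[i] = run inserted before reference position i+1
    # (index n = run after the last residue); matched[i] = residue or gap
    # aligned to reference position i+1.
    all_inserts: list[list[str]] = []
    all_matched: list[list[str]] = []
    for subj in subjects:
        ref_aln, sub_aln = _pairwise(aligner, ref_seq, subj.sequence)
        inserts = [""] * (n + 1)
        matched = [GAP] * n
        ref_pos = 0
        for rc, sc in zip(ref_aln, sub_aln):
            if rc == GAP:
                inserts[ref_pos] += sc
            else:
                matched[ref_pos] = sc
                ref_pos += 1
        all_inserts.append(inserts)
        all_matched.append(matched)

    insert_widths = [
        max(len(ins[i]) for ins in all_inserts) for i in range(n + 1)
    ]
    rows: dict[str, str] = {}
    ref_chunks: list[str] = []
    for i in range(n + 1):
        ref_chunks.append(GAP * insert_widths[i])
        if i < n:
            ref_chunks.append(ref_seq[i])
    rows[reference.accession] = "".join(ref_chunks)
    for subj, inserts, matched in zip(subjects, all_inserts, all_matched):
        chunks: list[str] = []
        for i in range(n + 1):
            chunks.append(inserts[i].ljust(insert_widths[i], GAP))
            if i < n:
                chunks.append(matched[i])
        row_id = subj.accession
        while row_id in rows:  # e.g. a subject sharing the reference accession
            row_id += "~"
        rows[row_id] = "".join(chunks)
    return Msa(rows, reference_id=reference.accession)


def map_reference_positions(msa: Msa) -> dict[int, int]:
    """Map each 1-based reference residue position to its 1-based MSA column."""
    mapping: dict[int, int] = {}
    pos = 0
    for col, char in enumerate(msa.reference_row, start=1):
        if char != GAP:
            pos += 1
            mapping[pos] = col
    return mapping
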