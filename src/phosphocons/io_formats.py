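"""Readers and writers for every file dialect the pipeline touches.

All coordinates are 1-based inclusive (protein residues, domain spans and
MSA columns alike), matching UniProtKB/InterProScan conventions.  Residue
letters are uppercased on read; ``X`` and other ambiguity codes never count
as conserved matches downstream.

Dialects
--------
* FASTA proteomes / aligned FASTA MSAs (via Biopython).
* Phosphosite tables: TSV with header ``accession  residue  position
  evidence_count``.
* Homology hits: the classic 12-column tabular alignment format
  (query, subject, %id, length, mismatches, gapopens, qstart, qend,
  sstart, send, evalue, bitscore), with the species encoded in the
  subject field as ``species|accession``.
* InterProScan TSV (columns 1, 7, 8, 12 used; rows without an InterPro
  id are skipped).
* Two-column term-annotation maps, kinase-score tables, orthologue-group
  membership tables, disorder-score tables and evidence tables — all
  plain TSV with headers.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "FormatError",
    "ProteinRecord",
    "PhosphoSite",
    "SpeciesRegistry",
    "HomologyHit",
    "Msa",
    "DomainSpan",
    "default_registry",
    "read_fasta",
    "write_fasta",
    "read_msa",
    "write_msa",
    "read_site_table",
    "write_site_table",
    "read_hit_table",
    "write_hit_table",
    "read_interpro_tsv",
    "read_registry",
    "write_registry",
    "read_annotation_map",
    "write_annotation_map",
    "read_kinase_scores",
    "read_orthogroups",
    "read_disorder_scores",
    "read_evidence_table",
    "write_evidence_table",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"
PHOSPHO_RESIDUES = frozenset("STY")

#: Default per-base-group species counts, totalling 100 eukaryotes.
DEFAULT_GROUP_SIZES = {
    "primates": 18,
    "other-mammals": 32,
    "birds": 12,
    "fish": 5,
    "reptiles": 4,
    "amphibians": 2,
    "insects-invertebrates": 11,
    "fungi": 4,
    "plants": 7,
    "protists": 5,
}

#: Broader groups as unions of base groups.
BROAD_GROUPS = {
    "mammals": ("primates", "other-mammals"),
    "vertebrates": ("primates", "other-mammals", "birds", "fish", "reptiles", "amphibians"),
    "animals": (
        "primates",
        "other-mammals",
        "birds",
        "fish",
        "reptiles",
        "amphibians",
        "insects-invertebrates",
    ),
}


class FormatError(ValueError):
    """Raised when an input file violates its dialect contract."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ProteinRecord:
    """One protein sequence from a proteome."""

    accession: str
    species_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise FormatError(f"empty sequence for {self.accession!r}")
        object.__setattr__(self, "sequence", self.sequence.upper())


@dataclass(frozen=True, order=True)
class PhosphoSite:
    """A phosphorylatable Ser/Thr/Tyr residue on a reference protein.

    Gold-standard membership requires ``evidence_count >= 5``.
    """

    accession: str
    residue: str
    position: int
    evidence_count: int = 0

    def __post_init__(self) -> None:
        if self.residue not in PHOSPHO_RESIDUES:
            raise FormatError(
                f"phosphosite residue must be S, T or Y, got {self.residue!r}"
            )
        if self.position < 1:
            raise FormatError(f"positions are 1-based, got {self.position}")
        if self.evidence_count < 0:
            raise FormatError("evidence_count must be nonnegative")

    @property
    def residue_class(self) -> str:
        """``"ST"`` for Ser/Thr sites, ``"Y"`` for Tyr sites."""
        return "ST" if self.residue in "ST" else "Y"


@dataclass(frozen=True)
class HomologyHit:
    """One pairwise homology search hit."""

    query_accession: str
    subject_accession: str
    species_id: str
    e_value: float
    bit_score: float

    def __post_init__(self) -> None:
        if self.e_value < 0:
            raise FormatError("e_value must be nonnegative")


@dataclass(frozen=True)
class DomainSpan:
    """An InterPro domain annotation on a protein, 1-based inclusive."""

    accession: str
    start: int
    stop: int
    interpro_id: str
    file_rank: int

    def __post_init__(self) -> None:
        if self.start > self.stop:
            raise FormatError(
                f"domain span start {self.start} > stop {self.stop} "
                f"({self.accession}/{self.interpro_id})"
            )


class SpeciesRegistry:
    """The species panel and its (overlapping) taxon groups.

    Base groups partition the species; broader groups (mammals,
    vertebrates, animals) are unions of base groups.  Percentage
    denominators always use the full group size, so species without a
    homolog count as "not conserved".
    """

    def __init__(
        self,
        species: Sequence[tuple[str, str, str]],
        groups: Mapping[str, frozenset[str] | set[str]],
    ) -> None:
        self.species = list(species)
        self.groups: dict[str, frozenset[str]] = {
            name: frozenset(members) for name, members in groups.items()
        }
        known = self.species_ids
        for name, members in self.groups.items():
            unknown = members - known
            if unknown:
                raise FormatError(
                    f"group {name!r} references unknown species {sorted(unknown)}"
                )
        self._validate_unions()

    @property
    def species_ids(self) -> frozenset[str]:
        return frozenset(s[0] for s in self.species)

    @property
    def base_groups(self) -> list[str]:
        return [g for g in self.groups if g not in BROAD_GROUPS]

    @property
    def group_names(self) -> list[str]:
        return list(self.groups)

    def group(self, name: str) -> frozenset[str]:
        try:
            return self.groups[name]
        except KeyError:
            raise KeyError(f"unknown species group {name!r}") from None

    def base_group_of(self, species_id: str) -> str:
        for name in self.base_groups:
            if species_id in self.groups[name]:
                return name
        raise KeyError(f"species {species_id!r} in no base group")

    def _validate_unions(self) -> None:
        for broad, parts in BROAD_GROUPS.items():
            if broad not in self.groups:
                continue
            expected = frozenset().union(*(self.groups[p] for p in parts if p in self.groups))
            if self.groups[broad] != expected:
                raise FormatError(
                    f"broad group {broad!r} is not the union of its base groups"
                )

    def __repr__(self) -> str:  # pragma: no cover - debug aid
        return (
            f"SpeciesRegistry({len(self.species)} species, "
            f"{len(self.groups)} groups)"
        )


def default_registry(
    group_sizes: Mapping[str, int] | None = None,
) -> SpeciesRegistry:
    """Build the default registry: synthetic species ids per base group.

    Sizes default to the 100-eukaryote panel (primates 18, other mammals
    32, birds 12, fish 5, reptiles 4, amphibians 2, insects/invertebrates
    11, fungi 4, plants 7, protists 5); broader groups are derived.
    """
    sizes = dict(DEFAULT_GROUP_SIZES if group_sizes is None else group_sizes)
    species: list[tuple[str, str, str]] = []
    groups: dict[str, set[str]] = {}
    for gname, n in sizes.items():
        members = set()
        for i in range(1, n + 1):
            sid = f"{gname}_{i:02d}"
            species.append((sid, f"{gname} species {i}", f"UP{gname[:3].upper()}{i:04d}"))
            members.add(sid)
        groups[gname] = members
    for broad, parts in BROAD_GROUPS.items():
        groups[broad] = set().union(*(groups[p] for p in parts if p in groups))
    return SpeciesRegistry(species, groups)


class Msa:
    """A reference-anchored multiple sequence alignment.

    ``rows`` is an ordered mapping row id -> aligned string (amino acids
    plus ``-``), all of equal length; ``reference_id`` names the
    reference (human) row, by default the first record in the file.
    """

    def __init__(self, rows: Mapping[str, str], reference_id: str | None = None) -> None:
        if not rows:
            raise FormatError("MSA has no rows")
        self.rows: dict[str, str] = {k: v.upper() for k, v in rows.items()}
        lengths = {len(v) for v in self.rows.values()}
        if len(lengths) != 1:
            bad = next(
                k for k, v in self.rows.items() if len(v) != len(next(iter(self.rows.values())))
            )
            raise FormatError(f"aligned rows have unequal lengths (e.g. record {bad!r})")
        self.length = lengths.pop()
        first = next(iter(self.rows))
        self.reference_id = reference_id if reference_id is not None else first
        if self.reference_id not in self.rows:
            raise FormatError(f"reference row {self.reference_id!r} not in MSA")

    @property
    def reference_row(self) -> str:
        return self.rows[self.reference_id]

    @property
    def reference_sequence(self) -> str:
        """The ungapped reference sequence."""
        return self.reference_row.replace(GAP, "")

    def ungapped(self, row_id: str) -> str:
        return self.rows[row_id].replace(GAP, "")

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    def __repr__(self) -> str:  # pragma: no cover - debug aid
        return f"Msa({self.n_rows} rows x {self.length} cols, ref={self.reference_id!r})"


# ---------------------------------------------------------------------------
# FASTA / aligned FASTA
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path, species_id: str = "") -> list[ProteinRecord]:
    """Read a proteome FASTA; the first whitespace-delimited token is the accession."""
    records = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        acc = rec.id
        if acc in seen:
            raise FormatError(f"duplicate accession {acc!r} in {path}")
        seen.add(acc)
        records.append(ProteinRecord(acc, species_id, str(rec.seq)))
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    seqs = [SeqRecord(Seq(r.sequence), id=r.accession, description="") for r in records]
    SeqIO.write(seqs, str(path), "fasta-2line")


def read_msa(path: str | Path, reference_id: str | None = None) -> Msa:
    """Read an aligned FASTA file.

    The reference row is the first record unless ``reference_id`` names
    another row explicitly.  Unequal row lengths or an empty file raise
    :class:`FormatError`.
    """
    rows: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in rows:
            raise FormatError(f"duplicate row id {rec.id!r} in {path}")
        rows[rec.id] = str(rec.seq)
    if not rows:
        raise FormatError(f"no alignment records in {path}")
    if len(rows) < 2:
        raise FormatError(f"alignment in {path} has fewer than 2 records")
    return Msa(rows, reference_id=reference_id)


def write_msa(msa: Msa, path: str | Path) -> None:
    """Write an MSA as two-line aligned FASTA (round-trips with read_msa)."""
    with open(path, "w") as fh:
        for rid, row in msa.rows.items():
            fh.write(f">{rid}\n{row}\n")


# ---------------------------------------------------------------------------
# Phosphosite tables
# ---------------------------------------------------------------------------

_SITE_COLUMNS = ["accession", "residue", "position", "evidence_count"]


def read_site_table(path: str | Path, min_evidence: int = 5) -> list[PhosphoSite]:
    """Read a phosphosite TSV, keeping rows with evidence >= ``min_evidence``.

    The default threshold of 5 selects the gold-standard set.
    """
    sites: list[PhosphoSite] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        missing = set(_SITE_COLUMNS) - set(reader.fieldnames or [])
        if missing:
            raise FormatError(f"site table missing columns {sorted(missing)}")
        for i, row in enumerate(reader, start=2):
            try:
                position = int(row["position"])
                evidence = int(row["evidence_count"])
            except ValueError as exc:
                raise FormatError(f"{path} line {i}: non-integer field ({exc})") from None
            try:
                site = PhosphoSite(row["accession"], row["residue"].upper(), position, evidence)
            except FormatError as exc:
                raise FormatError(f"{path} line {i}: {exc}") from None
            if site.evidence_count >= min_evidence:
                sites.append(site)
    return sites


def write_site_table(sites: Iterable[PhosphoSite], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(_SITE_COLUMNS)
        for s in sites:
            w.writerow([s.accession, s.residue, s.position, s.evidence_count])


# ---------------------------------------------------------------------------
# Homology hit tables (12-column tabular dialect)
# ---------------------------------------------------------------------------


def read_hit_table(path: str | Path) -> list[HomologyHit]:
    """Read 12-column tabular hits; species parsed from ``species|accession`` subjects."""
    hits: list[HomologyHit] = []
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 12:
                raise FormatError(f"{path} line {i}: expected 12 columns, got {len(parts)}")
            query, subject = parts[0], parts[1]
            if "|" not in subject:
                raise FormatError(
                    f"{path} line {i}: subject {subject!r} lacks 'species|accession' form"
                )
            species_id, subj_acc = subject.split("|", 1)
            try:
                e_value = float(parts[10])
                bit_score = float(parts[11])
            except ValueError as exc:
                raise FormatError(f"{path} line {i}: bad numeric field ({exc})") from None
            hits.append(HomologyHit(query, subj_acc, species_id, e_value, bit_score))
    return hits


def write_hit_table(hits: Iterable[HomologyHit], path: str | Path) -> None:
    """Write hits in the 12-column dialect (unused columns zero-filled)."""
    with open(path, "w") as fh:
        for h in hits:
            fields = [
                h.query_accession,
                f"{h.species_id}|{h.subject_accession}",
                "0", "0", "0", "0", "0", "0", "0", "0",
                repr(h.e_value),
                repr(h.bit_score),
            ]
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# InterProScan TSV
# ---------------------------------------------------------------------------


def read_interpro_tsv(path: str | Path) -> list[DomainSpan]:
    """Read InterProScan TSV output into domain spans.

    Uses columns 1 (accession), 7 (start), 8 (stop) and 12 (InterPro id);
    rows without an InterPro id are skipped.  ``file_rank`` records the
    order of appearance, which drives the first-match site-to-domain rule.
    """
    spans: list[DomainSpan] = []
    rank = 0
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 12 or not parts[11].strip() or parts[11].strip() == "-":
                continue
            try:
                start = int(parts[6])
                stop = int(parts[7])
            except ValueError:
                raise FormatError(f"{path} line {i}: non-integer coordinates") from None
            rank += 1
            try:
                spans.append(DomainSpan(parts[0], start, stop, parts[11].strip(), rank))
            except FormatError as exc:
                raise FormatError(f"{path} line {i}: {exc}") from None
    return spans


# ---------------------------------------------------------------------------
# Species registry TSV
# ---------------------------------------------------------------------------


def read_registry(path: str | Path) -> SpeciesRegistry:
    """Read a registry TSV: species_id, display_name, proteome_id, base_group."""
    species: list[tuple[str, str, str]] = []
    groups: dict[str, set[str]] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"species_id", "display_name", "proteome_id", "base_group"}
        missing = required - set(reader.fieldnames or [])
        if missing:
            raise FormatError(f"registry missing columns {sorted(missing)}")
        for row in reader:
            species.append((row["species_id"], row["display_name"], row["proteome_id"]))
            groups.setdefault(row["base_group"], set()).add(row["species_id"])
    for broad, parts in BROAD_GROUPS.items():
        members = set().union(*(groups.get(p, set()) for p in parts))
        if members:
            groups[broad] = members
    return SpeciesRegistry(species, groups)


def write_registry(registry: SpeciesRegistry, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["species_id", "display_name", "proteome_id", "base_group"])
        for sid, name, pid in registry.species:
            w.writerow([sid, name, pid, registry.base_group_of(sid)])


# ---------------------------------------------------------------------------
# Small auxiliary tables
# ---------------------------------------------------------------------------


def read_annotation_map(path: str | Path) -> dict[str, frozenset[str]]:
    """Read a two-column TSV (term, accession) into term -> accession sets."""
    out: dict[str, set[str]] = {}
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header is None:
            raise FormatError(f"empty annotation map {path}")
        for row in reader:
            if len(row) < 2:
                continue
            out.setdefault(row[0], set()).add(row[1])
    return {k: frozenset(v) for k, v in out.items()}


def write_annotation_map(annotation: Mapping[str, Iterable[str]], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["term", "accession"])
        for term in annotation:
            for acc in sorted(annotation[term]):
                w.writerow([term, acc])


def read_kinase_scores(path: str | Path) -> dict[tuple[str, int], dict[str, float]]:
    """Read a kinase-score TSV (accession, position, kinase, score) keyed by site."""
    out: dict[tuple[str, int], dict[str, float]] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"accession", "position", "kinase", "score"}
        missing = required - set(reader.fieldnames or [])
        if missing:
            raise FormatError(f"kinase score table missing columns {sorted(missing)}")
        for row in reader:
            key = (row["accession"], int(row["position"]))
            out.setdefault(key, {})[row["kinase"]] = float(row["score"])
    return out


def read_orthogroups(path: str | Path) -> dict[str, frozenset[str]]:
    """Read an orthologue-group TSV (group_id, species_id) into group -> species sets."""
    out: dict[str, set[str]] = {}
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header is None:
            raise FormatError(f"empty orthogroup table {path}")
        for row in reader:
            if len(row) < 2:
                continue
            out.setdefault(row[0], set()).add(row[1])
    return {k: frozenset(v) for k, v in out.items()}


def read_disorder_scores(path: str | Path) -> dict[tuple[str, int], float]:
    """Read per-residue disorder scores (accession, position, score)."""
    out: dict[tuple[str, int], float] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"accession", "position", "score"}
        missing = required - set(reader.fieldnames or [])
        if missing:
            raise FormatError(f"disorder table missing columns {sorted(missing)}")
        for row in reader:
            out[(row["accession"], int(row["position"]))] = float(row["score"])
    return out


def read_evidence_table(path: str | Path) -> dict[tuple[str, int], int]:
    """Read an evidence TSV (accession, position, evidence_count)."""
    out: dict[tuple[str, int], int] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"accession", "position", "evidence_count"}
        missing = required - set(reader.fieldnames or [])
        if missing:
            raise FormatError(f"evidence table missing columns {sorted(missing)}")
        for row in reader:
            out[(row["accession"], int(row["position"]))] = int(row["evidence_count"])
    return out


def write_evidence_table(evidence: Mapping[tuple[str, int], int], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["accession", "position", "evidence_count"])
        for (acc, pos), count in evidence.items():
            w.writerow([acc, pos, count])
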