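"""Synthetic fixtures with the statistical structure the pipeline assumes.

Two generators are provided:

* :func:`simulate_profiles` plants conservation *percentage vectors*
  directly: each archetype (a label template) sets a target percentage
  per species group and proteins scatter around it by a uniform noise
  amplitude in percentage points.  This isolates the clustering and
  labeling stages.
* :func:`simulate_study` builds a full study from sequences up: a
  reference proteome with phosphosites, per-species orthologues whose
  site and +1 columns are knocked out with group-specific
  probabilities (S<->T swaps emitted at a configurable rate to
  exercise the substitution-tolerance rule), decoy species with
  unrelated sequences, homology hit tables, reference-anchored MSAs,
  annotation maps with planted term enrichments, domain spans, kinase
  score/orthologue-group tables, disorder scores and evidence tables
  for validation.  Planted truth (archetype per protein, conservation
  flag per site x species) is returned alongside, consistent with the
  generated sequences by construction.

Determinism: a single integer seed drives everything; per-protein
substreams are derived by stable hashing (CRC-32) of the accession, so
adding proteins does not perturb existing ones.

What the generator does *not* emulate: phylogenetic substitution
models (no trees or rate matrices — species are conditionally
independent given the archetype), indel evolution, and correlated
evidence biases.  Conclusions from passing tests therefore concern the
pipeline's correctness, not the biology of any real proteome.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .io_formats import (
    AMINO_ACIDS,
    DomainSpan,
    HomologyHit,
    Msa,
    PhosphoSite,
    ProteinRecord,
    SpeciesRegistry,
    default_registry,
    write_annotation_map,
    write_evidence_table,
    write_fasta,
    write_hit_table,
    write_msa,
    write_registry,
    write_site_table,
)
from .clustering import LabelTemplate, default_templates

__all__ = [
    "ArchetypeSpec",
    "SimulationConfig",
    "TruthBundle",
    "simulate_profiles",
    "simulate_ortholog_set",
    "simulate_study",
    "write_bundle",
]

_ST = frozenset("ST")
_NON_ST = "".join(c for c in AMINO_ACIDS if c not in "ST")

#: Archetype target percentages for the profile-level generator; chosen so
#: that +-10-point noise keeps High in [80, 100], Medium in [52, 72] and
#: unconstrained groups in [0, 18], i.e. each protein still matches its
#: planted template and no stricter one.
PROFILE_TARGETS = {"High": 90.0, "Medium": 62.0, None: 8.0}


@dataclass(frozen=True)
class ArchetypeSpec:
    """One planted conservation archetype.

    ``template`` names the pattern; groups it constrains are conserved
    with probability ``conserved_prob`` per level (High/Medium), all
    other base groups with ``background_conserved_prob``.
    """

    template: LabelTemplate
    n_proteins: int
    conserved_prob: Mapping[str, float] = field(
        default_factory=lambda: {"High": 0.99, "Medium": 0.68}
    )
    background_conserved_prob: float = 0.02
    jitter: float = 0.01  # per-protein uniform jitter on the probabilities

    def site_keep_prob(self, base_group: str) -> float:
        level = self.template.requirements.get(base_group)
        if level is None:
            return self.background_conserved_prob
        return self.conserved_prob[level]


def _default_archetypes() -> tuple[ArchetypeSpec, ...]:
    catalog = {t.name: t for t in default_templates()}
    names = [
        "High in all species",
        "High in animals",
        "High in vertebrates",
        "High in primates",
    ]
    return tuple(ArchetypeSpec(template=catalog[n], n_proteins=50) for n in names)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the sequence-level generator."""

    seed: int = 0
    group_sizes: Mapping[str, int] | None = None  # None: the 100-species panel
    archetypes: tuple[ArchetypeSpec, ...] = field(default_factory=_default_archetypes)
    sites_per_protein: tuple[int, int] = (5, 10)
    protein_length: tuple[int, int] = (100, 160)
    residue_probs: Mapping[str, float] = field(
        default_factory=lambda: {"S": 0.82, "T": 0.13, "Y": 0.05}
    )
    st_swap_rate: float = 0.3  # conserved S/T sites written as the partner residue
    background_sub_prob: float = 0.02  # off-site substitution rate in orthologues
    decoy_species_fraction: float = 0.0
    evidence_coverage: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "other-mammals_01": (0.82, 0.75),  # (ST, Y) any-evidence coverage
            "plants_01": (0.35, 0.35),
        }
    )
    strong_evidence_fraction: float = 0.61  # of evidenced true sites, >=5 pieces
    background_evidence_rate: float = 0.058  # evidence rate on random S/T/Y residues
    background_strong_fraction: float = 0.2
    validation_padding: int = 12000  # extra non-orthologous proteins per validation species
    planted_term_fold: float = 4.0
    planted_terms_per_archetype: int = 2
    planted_term_size: int = 20
    null_terms: int = 8
    null_term_size: int = 20
    n_kinases: int = 30
    orthodb_missing_species: int = 8  # registry species absent from every orthologue group
    min_evidence: int = 5

    def __post_init__(self) -> None:
        for name, spec in [("sites_per_protein", self.sites_per_protein),
                           ("protein_length", self.protein_length)]:
            if spec[0] < 1 or spec[0] > spec[1]:
                raise ValueError(f"invalid range for {name}: {spec}")
        if not 0 <= self.decoy_species_fraction <= 1:
            raise ValueError("decoy_species_fraction must be in [0, 1]")
        for a in self.archetypes:
            if a.n_proteins < 1:
                raise ValueError("archetype protein counts must be positive")


@dataclass
class TruthBundle:
    """A generated study plus its planted ground truth."""

    config: SimulationConfig
    registry: SpeciesRegistry
    reference_records: list[ProteinRecord]
    sites: list[PhosphoSite]
    archetype_of: dict[str, str]  # accession -> template name
    site_flags: dict[tuple[str, int], dict[str, bool]]  # (acc, pos) -> species -> conserved
    plus1_flags: dict[tuple[str, int], dict[str, bool]]
    msas: dict[str, Msa]  # accession -> MSA (rows keyed by species id)
    hits: dict[str, list[HomologyHit]]
    decoy_species: dict[str, frozenset[str]]  # accession -> species with decoy sequences
    annotation: dict[str, frozenset[str]]
    planted_terms: dict[str, str]  # term -> archetype name (null terms absent)
    domain_spans: list[DomainSpan]
    kinase_scores: dict[tuple[str, int], dict[str, float]]
    orthogroups: dict[str, frozenset[str]]
    kinase_group: dict[str, str]
    disorder: dict[tuple[str, int], float]
    evidence: dict[str, dict[tuple[str, int], int]]  # species -> (target acc, pos) -> count
    target_proteomes: dict[str, list[ProteinRecord]]

    def sites_of(self, accession: str) -> list[PhosphoSite]:
        return [s for s in self.sites if s.accession == accession]


def _substream(seed: int, *tokens: str) -> np.random.Generator:
    """Deterministic per-object generator: root seed + CRC-32 of the tokens."""
    crcs = [zlib.crc32(t.encode()) for t in tokens]
    return np.random.default_rng([seed % 2**31, *crcs])


# ---------------------------------------------------------------------------
# Profile-level generator
# ---------------------------------------------------------------------------


def simulate_profiles(
    archetypes: Sequence[tuple[LabelTemplate, int]],
    noise_points: float = 10.0,
    seed: int = 0,
    base_groups: Sequence[str] | None = None,
    residue_class: str = "ST",
):
    """Plant archetype percentage vectors with uniform +-noise (in points).

    Returns ``(profiles, truth)`` where ``truth`` maps accession ->
    planted template name.  Constrained groups sit at 90 (High) or 62
    (Medium) and unconstrained groups at 8, so with noise up to +-10
    points every protein still matches exactly its planted template.
    """
    from .conservation import ProteinConservationProfile

    registry = default_registry()
    groups = list(base_groups) if base_groups is not None else registry.base_groups
    rng = np.random.default_rng([seed % 2**31, 0xC0FFEE])
    profiles: list[ProteinConservationProfile] = []
    truth: dict[str, str] = {}
    for ai, (template, count) in enumerate(archetypes):
        for j in range(count):
            acc = f"SYN{ai}_{j:03d}"
            percents = {}
            for g in groups:
                target = PROFILE_TARGETS[template.requirements.get(g)]
                val = target + rng.uniform(-noise_points, noise_points)
                percents[g] = float(np.clip(val, 0.0, 100.0))
            profiles.append(
                ProteinConservationProfile(
                    accession=acc,
                    residue_class=residue_class,
                    group_percent=percents,
                    n_sites=1,
                )
            )
            truth[acc] = template.name
    return profiles, truth


# ---------------------------------------------------------------------------
# Sequence-level generator
# ---------------------------------------------------------------------------


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


def _non_conserving(rng: np.random.Generator, ref: str) -> str:
    """A residue that never counts as conserved against ``ref``.

    For S/T references both S and T are excluded (an S<->T swap would be
    conserving under the substitution rule); otherwise only the residue
    itself is excluded.
    """
    pool = _NON_ST if ref in _ST else "".join(c for c in AMINO_ACIDS if c != ref)
    return str(rng.choice(list(pool)))


def _plant_reference(
    rng: np.random.Generator, config: SimulationConfig, accession: str
) -> tuple[ProteinRecord, list[PhosphoSite]]:
    length = int(rng.integers(config.protein_length[0], config.protein_length[1] + 1))
    seq = list(_random_sequence(rng, length))
    n_sites = int(
        rng.integers(config.sites_per_protein[0], config.sites_per_protein[1] + 1)
    )
    # sites spaced >= 3 apart and never at the C-terminus, so every site
    # has a +1 residue and site/+1 columns never collide
    candidates = list(range(1, length - 1))
    positions: list[int] = []
    rng.shuffle(candidates)
    for pos in candidates:
        if all(abs(pos - p) >= 3 for p in positions):
            positions.append(pos)
        if len(positions) == n_sites:
            break
    positions.sort()
    residues = list(config.residue_probs)
    probs = np.array([config.residue_probs[r] for r in residues], dtype=float)
    probs /= probs.sum()
    sites: list[PhosphoSite] = []
    for idx, pos in enumerate(positions):
        residue = str(rng.choice(residues, p=probs))
        if idx == 0:
            residue = "S" if residue == "Y" else residue  # >=1 Ser/Thr site per protein
        seq[pos - 1] = residue
        # keep the +1 residue outside {S, T, Y} so it is never itself a site
        # and the S/T-equivalence branch at +1 is exercised via dedicated tests
        plus1 = str(rng.choice(list("ACDEFGHIKLMNPQRVW")))
        seq[pos] = plus1
        evidence = int(rng.integers(config.min_evidence, 61))
        sites.append(PhosphoSite(accession, residue, pos, evidence))
    record = ProteinRecord(accession, "reference", "".join(seq))
    return record, sites


def simulate_ortholog_set(
    reference: ProteinRecord,
    sites: Sequence[PhosphoSite],
    config: SimulationConfig,
    archetype: ArchetypeSpec,
    registry: SpeciesRegistry,
) -> tuple[dict[str, str], dict[tuple[str, int], dict[str, bool]],
           dict[tuple[str, int], dict[str, bool]], frozenset[str]]:
    """Generate one orthologue per species plus planted conservation flags.

    Returns ``(sequences, site_flags, plus1_flags, decoy_species)``:
    ``sequences`` maps species id -> orthologue sequence (decoy species
    get unrelated random sequences); flags record the planted truth,
    with decoy species always False.
    """
    for g in registry.base_groups:
        # fail early if the probability table cannot cover a group
        archetype.site_keep_prob(g)
    rng = _substream(config.seed, "ortho", reference.accession)
    keep_prob = {
        g: float(
            np.clip(
                archetype.site_keep_prob(g) + rng.uniform(-archetype.jitter, archetype.jitter),
                0.0,
                1.0,
            )
        )
        for g in registry.base_groups
    }
    ref_seq = reference.sequence
    site_positions = {s.position for s in sites}
    plus1_positions = {s.position + 1 for s in sites}
    special = site_positions | plus1_positions

    species_ids = [s[0] for s in registry.species]
    n_decoys = int(round(config.decoy_species_fraction * len(species_ids)))
    decoy_idx = rng.choice(len(species_ids), size=n_decoys, replace=False) if n_decoys else []
    decoys = frozenset(species_ids[i] for i in decoy_idx)

    sequences: dict[str, str] = {}
    site_flags: dict[tuple[str, int], dict[str, bool]] = {
        (s.accession, s.position): {} for s in sites
    }
    plus1_flags: dict[tuple[str, int], dict[str, bool]] = {
        (s.accession, s.position): {} for s in sites
    }
    for sid in species_ids:
        if sid in decoys:
            sequences[sid] = _random_sequence(rng, len(ref_seq))
            for s in sites:
                site_flags[(s.accession, s.position)][sid] = False
                plus1_flags[(s.accession, s.position)][sid] = False
            continue
        group = registry.base_group_of(sid)
        p_keep = keep_prob[group]
        seq = list(ref_seq)
        for pos in range(1, len(ref_seq) + 1):
            if pos in special:
                continue
            if rng.random() < config.background_sub_prob:
                seq[pos - 1] = _non_conserving(rng, ref_seq[pos - 1])
        for s in sites:
            key = (s.accession, s.position)
            conserved = rng.random() < p_keep
            site_flags[key][sid] = conserved
            if conserved:
                if s.residue in _ST and rng.random() < config.st_swap_rate:
                    seq[s.position - 1] = "T" if s.residue == "S" else "S"
            else:
                seq[s.position - 1] = _non_conserving(rng, s.residue)
            ref_plus1 = ref_seq[s.position]
            plus1_ok = rng.random() < p_keep
            plus1_flags[key][sid] = plus1_ok
            if not plus1_ok:
                seq[s.position] = _non_conserving(rng, ref_plus1)
        sequences[sid] = "".join(seq)
    return sequences, site_flags, plus1_flags, decoys


def _build_msa_from_orthologs(
    reference: ProteinRecord, sequences: Mapping[str, str], decoys: frozenset[str]
) -> Msa:
    """Stack equal-length substitution-only orthologues under the reference.

    The generator introduces no indels, so the reference-anchored star
    alignment of these sequences is the gapless stack; building it
    directly keeps large simulations cheap.  Decoy species are excluded,
    mirroring their failure to produce a significant homology hit.
    """
    rows = {reference.accession: reference.sequence}
    for sid, seq in sequences.items():
        if sid not in decoys:
            rows[sid] = seq
    return Msa(rows, reference_id=reference.accession)


def _plant_annotation(
    rng: np.random.Generator,
    config: SimulationConfig,
    accessions_by_archetype: Mapping[str, list[str]],
) -> tuple[dict[str, frozenset[str]], dict[str, str]]:
    all_accessions = [a for accs in accessions_by_archetype.values() for a in accs]
    N = len(all_accessions)
    annotation: dict[str, frozenset[str]] = {}
    planted: dict[str, str] = {}
    term_no = 0
    for arch_name, members in accessions_by_archetype.items():
        n_a = len(members)
        for _ in range(config.planted_terms_per_archetype):
            K = config.planted_term_size
            k = int(round(config.planted_term_fold * K * n_a / N))
            if k > min(K, n_a):
                raise ValueError(
                    f"planted fold {config.planted_term_fold} infeasible for "
                    f"archetype {arch_name!r} (needs {k} of {min(K, n_a)} proteins)"
                )
            inside = list(rng.choice(members, size=k, replace=False))
            outside_pool = [a for a in all_accessions if a not in members]
            outside = list(rng.choice(outside_pool, size=K - k, replace=False))
            term_no += 1
            term = f"TERM{term_no:04d}"
            annotation[term] = frozenset(inside + outside)
            planted[term] = arch_name
    for _ in range(config.null_terms):
        term_no += 1
        term = f"TERM{term_no:04d}"
        members = rng.choice(all_accessions, size=config.null_term_size, replace=False)
        annotation[term] = frozenset(members)
    return annotation, planted


def _plant_domains(
    rng: np.random.Generator,
    references: Sequence[ProteinRecord],
    sites_by_acc: Mapping[str, list[PhosphoSite]],
) -> list[DomainSpan]:
    """Domain spans covering roughly half of each protein's sites."""
    spans: list[DomainSpan] = []
    rank = 0
    domain_pool = [f"IPR{n:06d}" for n in range(1, 41)]
    for rec in references:
        if rng.random() < 0.2:
            continue  # some proteins carry no annotated domain
        length = len(rec.sequence)
        n_domains = int(rng.integers(1, 3))
        for _ in range(n_domains):
            width = int(rng.integers(length // 4, max(length // 2, length // 4 + 1)))
            start = int(rng.integers(1, max(length - width, 2)))
            rank += 1
            spans.append(
                DomainSpan(
                    accession=rec.accession,
                    start=start,
                    stop=min(start + width - 1, length),
                    interpro_id=str(rng.choice(domain_pool)),
                    file_rank=rank,
                )
            )
    return spans


def _plant_kinases(
    rng: np.random.Generator,
    config: SimulationConfig,
    sites: Sequence[PhosphoSite],
    registry: SpeciesRegistry,
) -> tuple[dict[tuple[str, int], dict[str, float]], dict[str, frozenset[str]], dict[str, str]]:
    """Kinase scores per Ser/Thr site plus orthologue groups per kinase.

    Kinase conservation is drawn independently of site conservation, so
    the site-vs-kinase regression has no real signal.  A fixed set of
    registry species is absent from every group, emulating incomplete
    orthologue-database coverage.
    """
    kinases = [f"KIN{n:03d}" for n in range(1, config.n_kinases + 1)]
    species_ids = [s[0] for s in registry.species]
    missing = set(
        rng.choice(species_ids, size=config.orthodb_missing_species, replace=False)
    )
    orthogroups: dict[str, frozenset[str]] = {}
    kinase_group: dict[str, str] = {}
    for i, kin in enumerate(kinases, start=1):
        gid = f"OG{i:04d}"
        presence = rng.uniform(0.2, 0.95)
        members = {
            sid for sid in species_ids
            if sid not in missing and rng.random() < presence
        }
        orthogroups[gid] = frozenset(members)
        kinase_group[kin] = gid
    scores: dict[tuple[str, int], dict[str, float]] = {}
    for s in sites:
        if s.residue_class != "ST":
            continue
        chosen = rng.choice(kinases, size=5, replace=False)
        vals = np.round(rng.uniform(0.1, 0.9, size=5), 3)
        table = {str(k): float(v) for k, v in zip(chosen, vals)}
        if rng.random() < 0.03:  # occasional exact ties at the top
            top = max(table.values())
            other = str(rng.choice([k for k in table if table[k] != top] or list(table)))
            table[other] = top
        scores[(s.accession, s.position)] = table
    return scores, orthogroups, kinase_group


def _plant_evidence(
    rng: np.random.Generator,
    config: SimulationConfig,
    species_id: str,
    coverage: tuple[float, float],
    bundle_sites: Sequence[PhosphoSite],
    site_flags: Mapping[tuple[str, int], Mapping[str, bool]],
    plus1_flags: Mapping[tuple[str, int], Mapping[str, bool]],
    target_proteome: Sequence[ProteinRecord],
) -> dict[tuple[str, int], int]:
    """Evidence for one validation species.

    True propagated positions (site and +1 planted conserved) carry
    evidence at the class coverage rate, with a configured fraction
    reaching the strong (>= min_evidence) level; every other S/T/Y
    residue of the target proteome carries background evidence at a low
    rate, emulating the density of known phosphosites in a real
    database.
    """
    cov_st, cov_y = coverage
    evidence: dict[tuple[str, int], int] = {}
    true_positions: set[tuple[str, int]] = set()
    for s in bundle_sites:
        key = (s.accession, s.position)
        if site_flags[key].get(species_id) and plus1_flags[key].get(species_id):
            target_acc = f"{s.accession}@{species_id}"
            true_positions.add((target_acc, s.position))
            cov = cov_st if s.residue_class == "ST" else cov_y
            if rng.random() < cov:
                strong = rng.random() < config.strong_evidence_fraction
                count = int(rng.integers(config.min_evidence, 40)) if strong else int(
                    rng.integers(1, config.min_evidence)
                )
                evidence[(target_acc, s.position)] = count
    for rec in target_proteome:
        arr = np.frombuffer(rec.sequence.encode(), dtype=np.uint8)
        sty = np.nonzero((arr == ord("S")) | (arr == ord("T")) | (arr == ord("Y")))[0]
        if sty.size == 0:
            continue
        picked = sty[rng.random(sty.size) < config.background_evidence_rate] + 1
        strong_mask = rng.random(picked.size) < config.background_strong_fraction
        counts = np.where(
            strong_mask,
            rng.integers(config.min_evidence, 40, size=picked.size),
            rng.integers(1, config.min_evidence, size=picked.size),
        )
        for pos, count in zip(picked, counts):
            key = (rec.accession, int(pos))
            if key not in true_positions:
                evidence[key] = int(count)
    return evidence


def simulate_study(config: SimulationConfig = SimulationConfig()) -> TruthBundle:
    """Generate a complete multi-archetype study with planted ground truth."""
    registry = default_registry(config.group_sizes)
    reference_records: list[ProteinRecord] = []
    sites: list[PhosphoSite] = []
    archetype_of: dict[str, str] = {}
    site_flags: dict[tuple[str, int], dict[str, bool]] = {}
    plus1_flags: dict[tuple[str, int], dict[str, bool]] = {}
    msas: dict[str, Msa] = {}
    hits: dict[str, list[HomologyHit]] = {}
    decoy_species: dict[str, frozenset[str]] = {}
    target_sequences: dict[str, dict[str, str]] = {}  # accession -> species -> seq
    accessions_by_archetype: dict[str, list[str]] = {}

    idx = 0
    for archetype in config.archetypes:
        members: list[str] = []
        for _ in range(archetype.n_proteins):
            idx += 1
            acc = f"P{idx:05d}"
            rng = _substream(config.seed, "ref", acc)
            record, prot_sites = _plant_reference(rng, config, acc)
            reference_records.append(record)
            sites.extend(prot_sites)
            archetype_of[acc] = archetype.template.name
            members.append(acc)
            sequences, sf, pf, decoys = simulate_ortholog_set(
                record, prot_sites, config, archetype, registry
            )
            site_flags.update(sf)
            plus1_flags.update(pf)
            decoy_species[acc] = decoys
            target_sequences[acc] = sequences
            msas[acc] = _build_msa_from_orthologs(record, sequences, decoys)
            hit_rng = _substream(config.seed, "hits", acc)
            prot_hits = []
            for sid in sequences:
                if sid in decoys:
                    e_value, bit = 10.0 ** hit_rng.uniform(-3, 1), 25.0
                else:
                    e_value, bit = 10.0 ** hit_rng.uniform(-120, -20), float(
                        np.round(hit_rng.uniform(150, 900), 1)
                    )
                prot_hits.append(
                    HomologyHit(acc, f"{acc}@{sid}", sid, e_value, bit)
                )
            hits[acc] = prot_hits
        accessions_by_archetype[archetype.template.name] = members

    ann_rng = _substream(config.seed, "annotation")
    annotation, planted_terms = _plant_annotation(ann_rng, config, accessions_by_archetype)
    dom_rng = _substream(config.seed, "domains")
    sites_by_acc: dict[str, list[PhosphoSite]] = {}
    for s in sites:
        sites_by_acc.setdefault(s.accession, []).append(s)
    domain_spans = _plant_domains(dom_rng, reference_records, sites_by_acc)
    kin_rng = _substream(config.seed, "kinases")
    kinase_scores, orthogroups, kinase_group = _plant_kinases(
        kin_rng, config, sites, registry
    )
    dis_rng = _substream(config.seed, "disorder")
    # ~83% of sites land in disordered regions (score > 0.5)
    disorder = {
        (s.accession, s.position): float(
            np.round(
                dis_rng.uniform(0.55, 1.0) if dis_rng.random() < 0.83 else dis_rng.uniform(0.0, 0.5),
                4,
            )
        )
        for s in sites
    }

    # Target proteomes: orthologues under target accessions; validation
    # species additionally get non-orthologous padding proteins so that
    # predictions are a small fraction of the proteome, as in real data.
    target_proteomes: dict[str, list[ProteinRecord]] = {}
    evidence: dict[str, dict[tuple[str, int], int]] = {}
    for species_id, coverage in config.evidence_coverage.items():
        if species_id not in registry.species_ids:
            raise ValueError(f"evidence species {species_id!r} not in registry")
        proteome = [
            ProteinRecord(f"{acc}@{species_id}", species_id, seqs[species_id])
            for acc, seqs in target_sequences.items()
            if species_id in seqs and species_id not in decoy_species[acc]
        ]
        pad_rng = _substream(config.seed, "padding", species_id)
        lengths = pad_rng.integers(
            config.protein_length[0], config.protein_length[1], size=config.validation_padding
        )
        letters = pad_rng.choice(list(AMINO_ACIDS), size=int(lengths.sum()))
        offset = 0
        for j, length in enumerate(lengths):
            seq = "".join(letters[offset : offset + int(length)])
            offset += int(length)
            proteome.append(ProteinRecord(f"PAD{j:05d}@{species_id}", species_id, seq))
        target_proteomes[species_id] = proteome
        ev_rng = _substream(config.seed, "evidence", species_id)
        evidence[species_id] = _plant_evidence(
            ev_rng, config, species_id, coverage, sites, site_flags, plus1_flags, proteome
        )

    return TruthBundle(
        config=config,
        registry=registry,
        reference_records=reference_records,
        sites=sites,
        archetype_of=archetype_of,
        site_flags=site_flags,
        plus1_flags=plus1_flags,
        msas=msas,
        hits=hits,
        decoy_species=decoy_species,
        annotation=annotation,
        planted_terms=planted_terms,
        domain_spans=domain_spans,
        kinase_scores=kinase_scores,
        orthogroups=orthogroups,
        kinase_group=kinase_group,
        disorder=disorder,
        evidence=evidence,
        target_proteomes=target_proteomes,
    )


def write_bundle(bundle: TruthBundle, out_dir: str | Path) -> None:
    """Dump a bundle as the pipeline's on-disk input dialects."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_fasta(bundle.reference_records, out / "reference.fasta")
    write_site_table(bundle.sites, out / "sites.tsv")
    write_registry(bundle.registry, out / "registry.tsv")
    write_annotation_map(bundle.annotation, out / "annotation.tsv")
    msa_dir = out / "msas"
    msa_dir.mkdir(exist_ok=True)
    for acc, msa in bundle.msas.items():
        write_msa(msa, msa_dir / f"{acc}.afa")
    all_hits = [h for hs in bundle.hits.values() for h in hs]
    write_hit_table(all_hits, out / "hits.tsv")
    with open(out / "interpro.tsv", "w") as fh:
        for span in sorted(bundle.domain_spans, key=lambda s: s.file_rank):
            row = [span.accession, "md5", "0", "Pfam", "PFX", "desc",
                   str(span.start), str(span.stop), "0.0", "T", "date", span.interpro_id]
            fh.write("\t".join(row) + "\n")
    with open(out / "kinase_scores.tsv", "w") as fh:
        fh.write("accession\tposition\tkinase\tscore\n")
        for (acc, pos), table in bundle.kinase_scores.items():
            for kin, score in table.items():
                fh.write(f"{acc}\t{pos}\t{kin}\t{score}\n")
    with open(out / "orthogroups.tsv", "w") as fh:
        fh.write("group_id\tspecies_id\n")
        for gid, members in bundle.orthogroups.items():
            for sid in sorted(members):
                fh.write(f"{gid}\t{sid}\n")
    with open(out / "kinase_groups.tsv", "w") as fh:
        fh.write("kinase\tgroup_id\n")
        for kin, gid in bundle.kinase_group.items():
            fh.write(f"{kin}\t{gid}\n")
    with open(out / "disorder.tsv", "w") as fh:
        fh.write("accession\tposition\tscore\n")
        for (acc, pos), score in bundle.disorder.items():
            fh.write(f"{acc}\t{pos}\t{score}\n")
    for species_id, ev in bundle.evidence.items():
        write_evidence_table(ev, out / f"evidence_{species_id}.tsv")
        write_fasta(bundle.target_proteomes[species_id], out / f"proteome_{species_id}.fasta")
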