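"""End-to-end orchestration of the conservation and propagation studies.

``run_conservation_study`` goes from alignments + site table to site
and protein conservation tables, conservation-pattern clusters with
labels, term enrichment, domain fold enrichment, the kinase
conservation comparison and the ordered/disordered comparison.
``run_propagation_study`` goes from the same alignments to propagated
phosphosite predictions, per-species/per-group summaries and
evidence-based validation.  Every run writes a manifest recording the
resolved configuration and SHA-256 checksums of all inputs, and stage
logging reports counts in/out of each filter.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import yaml

from . import clustering, conservation, enrichment, kinase_evolution, propagation
from .io_formats import (
    Msa,
    PhosphoSite,
    SpeciesRegistry,
    read_annotation_map,
    read_disorder_scores,
    read_evidence_table,
    read_fasta,
    read_interpro_tsv,
    read_kinase_scores,
    read_msa,
    read_orthogroups,
    read_registry,
    read_site_table,
)

__all__ = ["RunConfig", "InputError", "run_conservation_study", "run_propagation_study"]

logger = logging.getLogger("phosphocons")


class InputError(FileNotFoundError):
    """A required pipeline input is missing or unreadable."""


@dataclass
class RunConfig:
    """Declarative configuration for a study run.

    Optional stages (enrichment, domains, kinases, disorder,
    validation) activate when their inputs are supplied.
    """

    msa_dir: str
    sites_path: str
    registry_path: str
    annotation_path: str | None = None
    interpro_path: str | None = None
    kinase_scores_path: str | None = None
    orthogroups_path: str | None = None
    kinase_groups_path: str | None = None
    disorder_path: str | None = None
    # species_id -> {"evidence": path, "proteome": optional path}
    validation: dict[str, dict[str, str]] = field(default_factory=dict)

    e_value_threshold: float = 1e-5
    min_evidence: int = 5
    k_clusters: int = 10
    alpha: float = 0.1
    min_strong: int = 5
    excluded_groups: tuple[str, ...] = ("birds",)
    linkage: str = "complete"
    standardize: bool = False
    st_equivalent: bool = True
    plus1_mode: str = "column"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "excluded_groups" in raw:
            raw["excluded_groups"] = tuple(raw["excluded_groups"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["excluded_groups"] = list(self.excluded_groups)
        return d


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _require(path: str | Path | None, what: str) -> Path:
    if path is None:
        raise InputError(f"missing required input: {what}")
    p = Path(path)
    if not p.exists():
        raise InputError(f"{what} not found: {p}")
    return p


def _load_msas(msa_dir: Path) -> dict[str, Msa]:
    msas: dict[str, Msa] = {}
    for path in sorted(msa_dir.glob("*.afa")) + sorted(msa_dir.glob("*.fasta")):
        msas[path.stem] = read_msa(path)
    if not msas:
        raise InputError(f"no alignments (*.afa / *.fasta) in {msa_dir}")
    return msas


def _write_tsv(path: Path, header: Sequence[str], rows: Sequence[Sequence]) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


def _profile_all_sites(
    msas: Mapping[str, Msa],
    sites: Sequence[PhosphoSite],
    registry: SpeciesRegistry,
) -> dict[str, list[conservation.SiteConservationProfile]]:
    """Site profiles grouped by accession; sites without an MSA are skipped."""
    by_acc: dict[str, list[PhosphoSite]] = {}
    for s in sites:
        by_acc.setdefault(s.accession, []).append(s)
    profiles: dict[str, list[conservation.SiteConservationProfile]] = {}
    n_skipped = 0
    for acc, acc_sites in by_acc.items():
        msa = msas.get(acc)
        if msa is None:
            n_skipped += len(acc_sites)
            continue
        profiles[acc] = [
            conservation.profile_site(msa, s, registry) for s in acc_sites
        ]
    logger.info(
        "profiled %d proteins; %d sites skipped (no alignment)",
        len(profiles),
        n_skipped,
    )
    return profiles


def run_conservation_study(config: RunConfig, out_dir: str | Path) -> Path:
    """Run the conservation stages and write all output tables.

    Outputs: site_conservation.tsv, protein_profiles.tsv, clusters.tsv,
    terms.tsv / domains.tsv / kinase_conservation.tsv /
    disorder_comparison.tsv when their inputs are configured, and
    manifest.json.  Fails fast (removing partial outputs) when an input
    is missing.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    created: list[Path] = []
    try:
        return _run_conservation(config, out, created)
    except Exception:
        for p in created:
            p.unlink(missing_ok=True)
        raise


def _run_conservation(config: RunConfig, out: Path, created: list[Path]) -> Path:
    msa_dir = _require(config.msa_dir, "MSA directory")
    sites_path = _require(config.sites_path, "site table")
    registry_path = _require(config.registry_path, "species registry")
    inputs = {"msa_dir": str(msa_dir), "sites": str(sites_path), "registry": str(registry_path)}

    registry = read_registry(registry_path)
    sites = read_site_table(sites_path, min_evidence=config.min_evidence)
    logger.info("loaded %d gold-standard sites (min_evidence=%d)", len(sites), config.min_evidence)
    msas = _load_msas(msa_dir)
    profiles_by_acc = _profile_all_sites(msas, sites, registry)

    group_names = registry.group_names
    rows = []
    for acc, profs in profiles_by_acc.items():
        for p in profs:
            n_cons = sum(p.flags.values())
            rows.append(
                [acc, p.site.residue, p.site.position, n_cons,
                 f"{p.overall_percent(registry):.2f}"]
                + [f"{p.group_percent[g]:.2f}" for g in group_names]
            )
    path = out / "site_conservation.tsv"
    _write_tsv(path, ["accession", "residue", "position", "n_conserved", "overall_percent"] + group_names, rows)
    created.append(path)

    protein_profiles: dict[str, list[conservation.ProteinConservationProfile]] = {"ST": [], "Y": []}
    rows = []
    for acc, profs in profiles_by_acc.items():
        for cls in ("ST", "Y"):
            prof = conservation.profile_protein(profs, cls)
            if prof is None:
                continue
            protein_profiles[cls].append(prof)
            rows.append(
                [acc, cls, prof.n_sites]
                + [f"{prof.group_percent[g]:.2f}" for g in group_names]
            )
    path = out / "protein_profiles.tsv"
    _write_tsv(path, ["accession", "residue_class", "n_sites"] + group_names, rows)
    created.append(path)

    templates = clustering.default_templates()
    assignments: dict[str, clustering.ClusterAssignment] = {}
    rows = []
    for cls in ("ST", "Y"):
        profs = protein_profiles[cls]
        if len(profs) < 2:
            continue
        k = min(config.k_clusters, len(profs))
        assignment = clustering.cluster_profiles(
            profs, k=k, linkage_method=config.linkage, standardize=config.standardize
        )
        assignment = clustering.label_clusters(assignment, profs, templates)
        assignments[cls] = assignment
        for p in profs:
            cid = assignment.assignments[p.accession]
            rows.append(
                [p.accession, cls, cid, assignment.labels[cid],
                 f"{assignment.support[cid]:.3f}"]
            )
    path = out / "clusters.tsv"
    _write_tsv(path, ["accession", "residue_class", "cluster", "label", "support"], rows)
    created.append(path)

    if config.annotation_path is not None:
        annotation = read_annotation_map(_require(config.annotation_path, "annotation map"))
        inputs["annotation"] = str(config.annotation_path)
        rows = []
        for cls, assignment in assignments.items():
            background = {p.accession for p in protein_profiles[cls]}
            for cid in sorted(set(assignment.assignments.values())):
                cluster = set(assignment.members(cid))
                for r in enrichment.hypergeom_enrich(cluster, background, annotation):
                    rows.append(
                        [cls, cid, assignment.labels[cid], r.term, r.k, r.n, r.K, r.N,
                         f"{r.p:.4g}", f"{r.p_adj:.4g}",
                         int(r.p_adj < config.alpha)]
                    )
        path = out / "terms.tsv"
        _write_tsv(
            path,
            ["residue_class", "cluster", "label", "term", "k", "n", "K", "N", "p", "p_adj", "significant"],
            rows,
        )
        created.append(path)

    if config.interpro_path is not None:
        spans = read_interpro_tsv(_require(config.interpro_path, "InterProScan TSV"))
        inputs["interpro"] = str(config.interpro_path)
        all_sites = [s for profs in profiles_by_acc.values() for p in profs for s in [p.site]]
        site_domain = enrichment.map_sites_to_domains(all_sites, spans)
        rows = []
        for cls, assignment in assignments.items():
            for cid in sorted(set(assignment.assignments.values())):
                members = set(assignment.members(cid))
                pattern = [
                    s for s in all_sites
                    if s.accession in members and s.residue_class == cls
                ]
                background = [s for s in all_sites if s.residue_class == cls]
                mapped_pattern = [s for s in pattern if site_domain.get(s)]
                if not mapped_pattern:
                    continue
                for r in enrichment.domain_fold_enrichment(pattern, background, site_domain):
                    rows.append(
                        [cls, cid, assignment.labels[cid], r.interpro_id, r.a, r.b, r.A, r.B,
                         f"{r.fold:.4f}", f"{r.log2_fold:.4f}", f"{r.percent_mapped:.2f}"]
                    )
        path = out / "domains.tsv"
        _write_tsv(
            path,
            ["residue_class", "cluster", "label", "interpro_id", "a", "b", "A", "B",
             "fold", "log2_fold", "percent_mapped"],
            rows,
        )
        created.append(path)

    regression_summary = None
    if config.kinase_scores_path is not None:
        scores = read_kinase_scores(_require(config.kinase_scores_path, "kinase score table"))
        groups_table = read_orthogroups(_require(config.orthogroups_path, "orthologue groups"))
        inputs["kinase_scores"] = str(config.kinase_scores_path)
        inputs["orthogroups"] = str(config.orthogroups_path)
        kinase_group: dict[str, str] = {}
        if config.kinase_groups_path is not None:
            with open(_require(config.kinase_groups_path, "kinase-group map")) as fh:
                next(fh)
                for line in fh:
                    kin, gid = line.rstrip("\n").split("\t")[:2]
                    kinase_group[kin] = gid
        site_lookup = {(s.accession, s.position): s for s in sites}
        matches = []
        for key, table in scores.items():
            site = site_lookup.get(key)
            if site is None or site.residue_class != "ST":
                continue
            matches.append(kinase_evolution.top_kinases(site, table))
        kin_profiles: dict[str, kinase_evolution.KinaseConservationProfile] = {}
        for m in matches:
            for kin in m.kinases:
                if kin in kin_profiles or kin not in kinase_group:
                    continue
                gid = kinase_group[kin]
                if gid not in groups_table:
                    continue
                kin_profiles[kin] = kinase_evolution.kinase_conservation(
                    kin, gid, groups_table[gid], registry, config.excluded_groups
                )
        rows = []
        kept_groups = [g for g in group_names if g not in config.excluded_groups]
        for kin, prof in sorted(kin_profiles.items()):
            rows.append(
                [kin, prof.orthodb_group, len(prof.species_present),
                 f"{prof.overall_percent(registry):.2f}"]
                + [f"{prof.group_percent[g]:.2f}" for g in kept_groups]
            )
        path = out / "kinase_conservation.tsv"
        _write_tsv(
            path,
            ["kinase", "orthodb_group", "n_species", "overall_percent"] + kept_groups,
            rows,
        )
        created.append(path)
        # site-vs-kinase regression: one pair per site x tied kinase
        pairs = []
        site_profiles = {
            (p.site.accession, p.site.position): p
            for profs in profiles_by_acc.values()
            for p in profs
        }
        for m in matches:
            sp = site_profiles.get((m.site.accession, m.site.position))
            if sp is None:
                continue
            for kin in m.kinases:
                if kin in kin_profiles:
                    pairs.append(
                        (sp.overall_percent(registry), kin_profiles[kin].overall_percent(registry))
                    )
        if len(pairs) >= 3:
            fit = kinase_evolution.regress_conservation(pairs)
            regression_summary = {
                "slope": fit.slope,
                "intercept": fit.intercept,
                "r_squared": fit.r_squared,
                "n_pairs": fit.n,
            }

    if config.disorder_path is not None:
        disorder = read_disorder_scores(_require(config.disorder_path, "disorder table"))
        inputs["disorder"] = str(config.disorder_path)
        rows = []
        for cls in ("S", "T", "Y"):
            ordered_vals, disordered_vals = [], []
            for profs in profiles_by_acc.values():
                for p in profs:
                    if p.site.residue != cls:
                        continue
                    score = disorder.get((p.site.accession, p.site.position))
                    if score is None:
                        continue
                    target = (
                        disordered_vals
                        if conservation.classify_disorder(score) == "disordered"
                        else ordered_vals
                    )
                    target.append(p.overall_percent(registry))
            if not ordered_vals or not disordered_vals:
                continue
            box_o, box_d, t_stat, p_val = conservation.compare_groups(ordered_vals, disordered_vals)
            rows.append(
                [cls, len(ordered_vals), len(disordered_vals),
                 f"{box_o.median:.2f}", f"{box_d.median:.2f}",
                 f"{t_stat:.4f}" if not math.isnan(t_stat) else "NA",
                 f"{p_val:.4g}" if not math.isnan(p_val) else "NA"]
            )
        path = out / "disorder_comparison.tsv"
        _write_tsv(
            path,
            ["residue", "n_ordered", "n_disordered", "median_ordered",
             "median_disordered", "t_statistic", "p_value"],
            rows,
        )
        created.append(path)

    manifest = {
        "stage": "conservation",
        "config": config.to_dict(),
        "inputs": {k: _sha256(v) if Path(v).is_file() else "dir" for k, v in inputs.items()},
        "n_sites": len(sites),
        "n_proteins": len(profiles_by_acc),
        "regression": regression_summary,
    }
    path = out / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    created.append(path)
    return out


def run_propagation_study(config: RunConfig, out_dir: str | Path) -> Path:
    """Propagate reference sites through every alignment and validate.

    Outputs: predictions.tsv, skipped_sites.tsv, prediction_summary.tsv
    (per species and group), validation.tsv when evidence tables are
    configured, and manifest.json.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    created: list[Path] = []
    try:
        return _run_propagation(config, out, created)
    except Exception:
        for p in created:
            p.unlink(missing_ok=True)
        raise


def _run_propagation(config: RunConfig, out: Path, created: list[Path]) -> Path:
    msa_dir = _require(config.msa_dir, "MSA directory")
    sites_path = _require(config.sites_path, "site table")
    registry_path = _require(config.registry_path, "species registry")
    registry = read_registry(registry_path)
    sites = read_site_table(sites_path, min_evidence=config.min_evidence)
    msas = _load_msas(msa_dir)

    by_acc: dict[str, list[PhosphoSite]] = {}
    for s in sites:
        by_acc.setdefault(s.accession, []).append(s)

    predictions: list[propagation.PredictedSite] = []
    skipped: list[PhosphoSite] = []
    for acc, acc_sites in by_acc.items():
        msa = msas.get(acc)
        if msa is None:
            continue
        row_species = {
            rid: (rid, f"{acc}@{rid}") for rid in msa.rows if rid != msa.reference_id
        }
        preds, skip = propagation.propagate_sites(
            msa, acc_sites, registry, row_species=row_species, plus1_mode=config.plus1_mode
        )
        predictions.extend(preds)
        skipped.extend(skip)
    logger.info("%d predictions, %d C-terminal sites skipped", len(predictions), len(skipped))

    path = out / "predictions.tsv"
    _write_tsv(
        path,
        ["species_id", "group", "accession", "position", "residue", "plus1",
         "source_accession", "source_position", "source_residue"],
        [
            [p.species_id, registry.base_group_of(p.species_id), p.accession, p.position,
             p.residue, p.plus1_residue, p.source.accession, p.source.position, p.source.residue]
            for p in predictions
        ],
    )
    created.append(path)

    path = out / "skipped_sites.tsv"
    _write_tsv(
        path,
        ["accession", "residue", "position", "reason"],
        [[s.accession, s.residue, s.position, "no +1 residue (C-terminal)"] for s in skipped],
    )
    created.append(path)

    per_species, per_group = propagation.summarize_by_group(predictions, registry)
    rows = [
        ["species", sid, counts.get("S", 0), counts.get("T", 0), counts.get("Y", 0)]
        for sid, counts in sorted(per_species.items())
    ] + [
        ["group", g, counts.get("S", 0), counts.get("T", 0), counts.get("Y", 0)]
        for g, counts in per_group.items()
    ]
    path = out / "prediction_summary.tsv"
    _write_tsv(path, ["level", "name", "ser", "thr", "tyr"], rows)
    created.append(path)

    validation_rows = []
    for species_id, spec_paths in config.validation.items():
        evidence = read_evidence_table(_require(spec_paths["evidence"], f"evidence for {species_id}"))
        species_preds = [p for p in predictions if p.species_id == species_id]
        if not species_preds:
            logger.warning("no predictions for validation species %s", species_id)
            continue
        summary = propagation.validate_predictions(species_preds, evidence, config.min_strong)
        factor_any = factor_strong = None
        if "proteome" in spec_paths:
            proteome = read_fasta(_require(spec_paths["proteome"], f"proteome for {species_id}"), species_id)
            pred_keys = {(p.accession, p.position) for p in species_preds}
            ef = enrichment.enrichment_factor(pred_keys, set(evidence), proteome)
            factor_any = ef.factor
            strong_evidence = {k for k, v in evidence.items() if v >= config.min_strong}
            ef_strong = enrichment.enrichment_factor(pred_keys, strong_evidence, proteome)
            factor_strong = ef_strong.factor
        for cls in ("ST", "Y"):
            validation_rows.append(
                [species_id, cls, summary.n_predictions[cls],
                 f"{summary.any_evidence_percent[cls]:.2f}",
                 f"{summary.strong_percent[cls]:.2f}",
                 f"{factor_any:.2f}" if factor_any is not None else "NA",
                 f"{factor_strong:.2f}" if factor_strong is not None else "NA"]
            )
    if config.validation:
        path = out / "validation.tsv"
        _write_tsv(
            path,
            ["species_id", "residue_class", "n_predictions", "any_evidence_percent",
             "strong_percent", "enrichment_factor_any", "enrichment_factor_strong"],
            validation_rows,
        )
        created.append(path)
    else:
        logger.info("no evidence tables supplied; validation skipped")

    manifest = {
        "stage": "propagation",
        "config": config.to_dict(),
        "n_predictions": len(predictions),
        "n_skipped_sites": len(skipped),
    }
    path = out / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    created.append(path)
    return out
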