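"""The synthetic-study generator: determinism, planted structure, truth."""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest
from scipy import stats

from phosphocons import (
    ArchetypeSpec,
    SimulationConfig,
    default_registry,
    profile_site,
    simulate_ortholog_set,
    simulate_study,
)
from phosphocons.clustering import default_templates
from phosphocons.io_formats import Msa, PhosphoSite, ProteinRecord
from phosphocons.synthetic_data import _plant_reference, _substream


def archetype(name="High in all species", **kwargs):
    by_name = {t.name: t for t in default_templates()}
    return ArchetypeSpec(template=by_name[name], n_proteins=1, **kwargs)


def make_reference(seed=3, config=None):
    config = config or SimulationConfig(seed=seed)
    rng = _substream(config.seed, "ref", "PX")
    return _plant_reference(rng, config, "PX")


class TestOrthologSet:
    def test_zero_substitution_gives_full_conservation(self):
        config = SimulationConfig(seed=1)
        record, sites = make_reference(config=config)
        registry = default_registry()
        arch = archetype(conserved_prob={"High": 1.0, "Medium": 1.0}, jitter=0.0,
                         background_conserved_prob=1.0)
        seqs, sf, pf, decoys = simulate_ortholog_set(record, sites, config, arch, registry)
        assert decoys == frozenset()
        for flags in sf.values():
            assert all(flags.values())
        for flags in pf.values():
            assert all(flags.values())

    def test_deterministic_planting_per_group(self):
        """Probability 1 loss in fish only: fish flags all false, others all true."""
        config = SimulationConfig(seed=2)
        record, sites = make_reference(config=config)
        registry = default_registry()
        by_name = {t.name: t for t in default_templates()}
        # constrain every group High at prob 1 except fish at background prob 0
        arch = ArchetypeSpec(
            template=by_name["High in vertebrates"],  # fish constrained too; override below
            n_proteins=1,
            conserved_prob={"High": 1.0, "Medium": 1.0},
            background_conserved_prob=0.0,
            jitter=0.0,
        )
        seqs, sf, pf, _ = simulate_ortholog_set(record, sites, config, arch, registry)
        for flags in sf.values():
            for sid, ok in flags.items():
                in_vertebrates = sid in registry.group("vertebrates")
                assert ok == in_vertebrates

    def test_conserved_count_within_binomial_bounds(self):
        """p=0.25 in a 32-species group: counts inside the 99.9% binomial band."""
        registry = default_registry()
        config = SimulationConfig(seed=5)
        arch = archetype(
            conserved_prob={"High": 0.25, "Medium": 0.25},
            background_conserved_prob=0.25,
            jitter=0.0,
        )
        total = conserved = 0
        for i in range(20):
            rng = _substream(config.seed, "ref", f"P{i}")
            record, sites = _plant_reference(rng, config, f"P{i}")
            _, sf, _, _ = simulate_ortholog_set(record, sites, config, arch, registry)
            for flags in sf.values():
                for sid in registry.group("other-mammals"):
                    total += 1
                    conserved += flags[sid]
        lo, hi = stats.binom.interval(0.999, total, 0.25)
        assert lo <= conserved <= hi

    def test_st_swaps_remain_conserving(self):
        """Conserved S/T sites written as the partner residue still flag True."""
        config = SimulationConfig(seed=7, st_swap_rate=1.0)
        record, sites = make_reference(config=config)
        registry = default_registry()
        arch = archetype(conserved_prob={"High": 1.0, "Medium": 1.0}, jitter=0.0,
                         background_conserved_prob=1.0)
        seqs, sf, _, _ = simulate_ortholog_set(record, sites, config, arch, registry)
        st_sites = [s for s in sites if s.residue in "ST"]
        assert st_sites
        sid = next(iter(seqs))
        for s in st_sites:
            swapped = seqs[sid][s.position - 1]
            assert swapped == ("T" if s.residue == "S" else "S")
            assert sf[(s.accession, s.position)][sid] is True

    def test_decoy_species_never_conserved(self):
        config = SimulationConfig(seed=8, decoy_species_fraction=0.2)
        record, sites = make_reference(config=config)
        registry = default_registry()
        arch = archetype(conserved_prob={"High": 1.0, "Medium": 1.0}, jitter=0.0)
        seqs, sf, pf, decoys = simulate_ortholog_set(record, sites, config, arch, registry)
        assert len(decoys) == 20
        for flags in sf.values():
            assert not any(flags[d] for d in decoys)


class TestStudyBundle:
    def test_same_seed_reproduces_bundle(self, small_bundle):
        again = simulate_study(small_bundle.config)
        assert again.reference_records == small_bundle.reference_records
        assert again.sites == small_bundle.sites
        assert again.annotation == small_bundle.annotation
        assert again.evidence == small_bundle.evidence
        assert {a: m.rows for a, m in again.msas.items()} == {
            a: m.rows for a, m in small_bundle.msas.items()
        }

    def test_planted_flags_consistent_with_sequences(self, small_bundle):
        """The recorded truth matches what the conservation module computes."""
        b = small_bundle
        for rec in b.reference_records[:8]:
            msa = b.msas[rec.accession]
            for site in b.sites_of(rec.accession):
                prof = profile_site(msa, site, b.registry)
                key = (site.accession, site.position)
                for sid in b.registry.species_ids:
                    assert prof.flags[sid] == b.site_flags[key][sid]
                    if prof.plus1_flags is not None:
                        assert prof.plus1_flags[sid] == b.plus1_flags[key][sid]

    def test_gold_standard_sites_meet_evidence_floor(self, small_bundle):
        assert all(s.evidence_count >= 5 for s in small_bundle.sites)

    def test_every_protein_has_st_site(self, small_bundle):
        by_acc = {}
        for s in small_bundle.sites:
            by_acc.setdefault(s.accession, []).append(s)
        for rec in small_bundle.reference_records:
            assert any(s.residue in "ST" for s in by_acc[rec.accession])

    def test_evidence_coverage_near_planted_rate(self, small_bundle):
        """True propagated ST sites carry evidence at about the planted 82%."""
        b = small_bundle
        species = "other-mammals_01"
        covered = total = 0
        for s in b.sites:
            if s.residue_class != "ST":
                continue
            key = (s.accession, s.position)
            if b.site_flags[key][species] and b.plus1_flags[key][species]:
                total += 1
                covered += (f"{s.accession}@{species}", s.position) in b.evidence[species]
        assert total > 50
        lo, hi = stats.binom.interval(0.999, total, 0.82)
        assert lo <= covered <= hi

    def test_planted_term_members_drawn_from_archetype(self, small_bundle):
        b = small_bundle
        for term, arch_name in b.planted_terms.items():
            members = b.annotation[term]
            inside = sum(b.archetype_of[a] == arch_name for a in members)
            n_arch = sum(v == arch_name for v in b.archetype_of.values())
            N = len(b.archetype_of)
            fold = (inside / len(members)) / (n_arch / N)
            assert fold >= b.config.planted_term_fold * 0.9

    def test_infeasible_fold_rejected(self):
        base = SimulationConfig()
        config = dataclasses.replace(
            base,
            archetypes=tuple(
                dataclasses.replace(a, n_proteins=4) for a in base.archetypes
            ),
            planted_term_size=20,
            validation_padding=10,
        )
        with pytest.raises(ValueError):
            simulate_study(config)
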