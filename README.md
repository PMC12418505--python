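# phosphocons

Cross-species conservation analysis and propagation of protein
phosphorylation sites.

Experimental phosphosite catalogs are deep for human but thin for most
other organisms.  `phosphocons` is for proteomics and molecular-
evolution researchers who want to leverage that asymmetry: it scores
how well each reference (human) Ser/Thr/Tyr phosphosite is conserved
across a panel of eukaryotic proteomes, clusters and labels the
conservation patterns, attaches functional context, and propagates
sites to other species as candidate phosphosite annotations.

## The model in brief

For a phosphosite at position *i* of a reference protein, and each
species' top homology hit (E ≤ 1e-5) aligned to the reference, the
site is **conserved** in species *s* when the aligned residue equals
the reference residue — tolerating Thr↔Ser substitutions (never Tyr).
Gaps, `X`, and species without a significant homolog count as not
conserved.  Per species group *g*:

    percent(g) = 100 · #conserved species in g / |g|

The default panel is 100 eukaryotes in ten base groups (primates 18,
other mammals 32, birds 12, fish 5, reptiles 4, amphibians 2,
insects/invertebrates 11, fungi 4, plants 7, protists 5) plus the
unions mammals/vertebrates/animals.  Protein profiles (mean over
sites, per Ser/Thr and Tyr class) are clustered on Euclidean distance
and labeled High (≥75 %) / Medium (≥50 %) per group when ≥50 % of the
cluster matches.  Enrichment uses the hypergeometric upper tail with
Benjamini–Hochberg adjustment (significant at adjusted p < 0.1) for
terms, and fold = (a/b)/(A/B) for domains.  A site **propagates** to a
species when both the site and its +1 residue are conserved; the
validation enrichment factor is the evidence rate among predictions
over the evidence rate of random S/T/Y residues.

See `docs/methods.md` for the full model, parameter defaults, and the
synthetic-data generator's assumptions.

## Worked example

Simulate a study with planted conservation archetypes, then run the
conservation and propagation stages:

```bash
phosphocons simulate --seed 1 --out-dir fixtures/
```

```python
from phosphocons import (
    SimulationConfig, simulate_study, profile_site, profile_protein,
    cluster_profiles, label_clusters,
)
from phosphocons.clustering import default_templates

bundle = simulate_study(SimulationConfig(seed=1))
profiles = []
for rec in bundle.reference_records:
    site_profiles = [
        profile_site(bundle.msas[rec.accession], s, bundle.registry)
        for s in bundle.sites_of(rec.accession)
    ]
    prof = profile_protein(site_profiles, "ST")
    if prof is not None:
        profiles.append(prof)

assignment = label_clusters(
    cluster_profiles(profiles, k=4), profiles, default_templates()
)
for cid in sorted(assignment.labels):
    members = assignment.members(cid)
    print(cid, assignment.labels[cid], len(members), assignment.support[cid])
```

Output:

```
1 High in all species 50 1.0
2 High in animals 50 1.0
3 High in vertebrates 50 1.0
4 High in primates 50 1.0
```

Each line is one cluster: its id, the conservation-pattern label it
earned (every constrained group at ≥75 % conservation for "High"
labels), the number of member proteins, and the fraction of members
matching the label — here all four planted archetypes are recovered
with full support.

The same stages run from files via the CLI
(`phosphocons conserve`, `phosphocons propagate`,
`phosphocons run --config study.yaml`), writing TSV tables
(site/protein conservation, clusters, term and domain enrichment,
kinase conservation, predictions, validation) plus a manifest with
the resolved configuration and input checksums.

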