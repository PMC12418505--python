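# Methods

## The problem

Protein phosphorylation on Ser, Thr and Tyr residues is the most
common regulatory post-translational modification, but experimental
phosphosite catalogs exist for only a handful of organisms.  If a
human phosphosite is conserved in another species — same residue (or
its functional Ser/Thr partner) at the aligned position — that is
evidence both of the site's functional importance and of its likely
phosphorylation in the other species.  `phosphocons` turns this idea
into a pipeline: score conservation of a reference ("gold standard")
phosphosite set across a panel of eukaryotic proteomes, cluster the
resulting conservation patterns, attach functional and structural
context (term enrichment, domain enrichment, kinase conservation,
disorder), and propagate sites to other species with evidence-based
validation.

## Conservation model

For each reference protein with phosphosites, homologs are collected
as the top significant hit per species (E-value ≤ 1e-5; ties broken by
bit score, then input order) and aligned to the reference.  A site at
1-based position *i* is **conserved** in a species when the residue in
the MSA column anchored to *i* equals the reference residue, with one
tolerated substitution: Thr aligned to a reference Ser counts as
conserved and vice versa.  The rule is never extended to Tyr, and it
applies at any compared position only when the *reference* residue
there is S or T.  Gaps, ambiguity codes (`X`) and species with no
significant homolog all count as *not conserved*, and the group
percentage always divides by the full group size:

    percent(g) = 100 · |{s ∈ g : conserved(s)}| / |g|

This keeps percentages comparable across proteins regardless of how
many homologs were found.  The +1 residue (immediately C-terminal,
the position read by proline-directed kinases) is scored the same way
against the reference's next residue.

The species panel defaults to 100 eukaryotes in ten base groups —
primates (18), other mammals (32), birds (12), fish (5), reptiles (4),
amphibians (2), insects/invertebrates (11), fungi (4), plants (7),
protists (5) — plus the derived unions mammals (50), vertebrates (73)
and animals (84).  Group sizes are configurable; the broader groups
are always unions of base groups, so a broad-group percentage is the
species-count-weighted mean of its constituents.

Protein-level profiles are the unweighted mean of the protein's site
percentages, separately for the Ser/Thr and Tyr classes.

## Alignment stand-in

Conservation is only ever read at reference-anchored columns, so the
package builds *reference-anchored star alignments*: each subject is
globally aligned to the reference (BLOSUM62, affine gaps, open 11 /
extend 1, terminal gaps free because homology hits are often partial)
and the pairwise alignments are merged through shared reference
coordinates.  Inter-subject alignment quality is immaterial to every
downstream statistic.  Externally produced MSAs in aligned-FASTA form
load directly (reference row = first record by default), so results
from a full external-aligner run can be reproduced exactly.

## Clustering and labels

Proteins (or sites, or kinases — anything with a group-percentage
vector) are clustered by agglomerative hierarchical clustering on
Euclidean distances between raw percentage vectors (complete linkage
by default; a `standardize` flag is available but off, since the
coordinates share one scale) and the tree is cut into exactly *k*
clusters (default 10 per residue class).  Labels come from an
explicit template catalog: a template constrains some groups to High
(≥ 75 % conserved, inclusive) or Medium (≥ 50 %).  A cluster takes the
template matched by the largest fraction of its members when that
fraction is ≥ 0.5, else `mixed`; exact ties go to the earlier catalog
entry, and the built-in catalog lists templates with more constrained
groups first, so among equally supported descriptions the most
specific wins.

## Enrichment statistics

*Term enrichment* of a cluster against the background of all analysed
proteins is the upper-tail hypergeometric probability P(X ≥ k) of
seeing k annotated proteins among n cluster members when K of N
background proteins are annotated, BH-adjusted across terms, with
significance at adjusted p < 0.1.  Terms annotating fewer than two
background proteins are not tested.

*Domain fold enrichment* for a conservation pattern is
(a/b)/(A/B): pattern sites in the domain over all pattern sites,
relative to the same ratio in the background of all domain-mapped
sites.  A site overlapping several domain spans takes the first span
in InterProScan file order; domains with fewer than two mapped
background sites are dropped; reports carry log2(fold) and the
percentage of pattern sites mapped, sorted so the head of the table is
the "top domains" view.

*The validation enrichment factor* for propagated predictions is the
observed evidence rate among predictions divided by the evidence rate
of all S/T/Y residues in the target proteome — the factor by which the
method beats picking residues at random.

## Kinases

Each Ser/Thr site takes its top-scoring kinase(s) from a site→kinase
score table, keeping all kinases tied at the maximum.  Kinase
conservation is read from orthologue-group membership: conserved in a
panel species iff that species occurs in the kinase's group; species
outside the panel are ignored and whole groups can be excluded from
the percentages (birds by default, whose orthologue signal is weak).
Site vs kinase conservation is compared by OLS on (site overall %,
kinase overall %) pairs — "overall" meaning the percentage over all
non-excluded panel species — with one pair per tied kinase; both
choices are configurable.

## Propagation

A site propagates to a species when the aligned residue **and** the
residue at the reference +1 position are both conserved (S/T
substitutions tolerated where the reference residue is S or T).
Predicted positions are reported in ungapped target-protein
coordinates.  Two deliberate choices:

* Reference C-terminal sites have no +1 residue, so the rule cannot
  evaluate them; they are skipped and counted in a skipped-sites
  report rather than propagated unconditionally.
* The target's +1 residue is read at the reference-anchored +1 column
  by default; when the target has an insertion between site and +1, an
  alternative `plus1_mode="adjacent"` reads the target's
  sequence-adjacent residue instead.

Validation splits predictions by residue class and reports the
fraction with any evidence and, among evidenced predictions, the
fraction with ≥ 5 pieces of evidence ("strong", matching the
gold-standard floor).

## Synthetic data: what it emulates and what it does not

The sequence-level generator plants conservation archetypes: each
archetype is a label template, and sites (and their +1 residues) in a
constrained group survive with probability 0.99 (High) or 0.68
(Medium), versus 0.02 in unconstrained groups, with ±0.01 per-protein
jitter; off-site positions mutate at 2 %.  Non-conserving mutations
never produce S↔T at S/T sites (that would be conserving by the
substitution rule); conversely, conserved S/T sites are written as the
partner residue 30 % of the time, so the S/T rule is genuinely
exercised.  Default study: four High archetypes (all species, animals,
vertebrates, primates) × 50 proteins, 5–10 sites per protein spaced
≥ 3 apart, protein lengths 100–160.  Sites-per-protein is set a little
above real gold-standard density so that small groups (amphibians,
n = 2) average over enough site×species draws for group percentages
to be stable.

Evidence tables for the validation species mirror reported real-data
rates: true propagated Ser/Thr (Tyr) sites carry evidence with
probability 0.82 (0.75) in the mouse-like species and 0.35 in the
plant-like species; 61 % of evidenced true sites reach the strong
level; background S/T/Y residues carry evidence at 5.8 % (20 % of it
strong), roughly the density of catalogued phosphosites among all
S/T/Y residues in a well-studied proteome.  Validation species get
12,000 padding proteins so predictions are a small fraction of the
proteome, as in real data.  Kinase orthologue groups are drawn
independently of site conservation, so the site-vs-kinase regression
has no true signal and its R² is expected ≈ 0.

A separate profile-level generator plants percentage *vectors*
directly (High → 90, Medium → 62, unconstrained → 8, uniform ±10-point
noise), isolating the clustering/labeling stages from sampling noise.

Determinism: one root seed; per-protein substreams derive from the
CRC-32 of the accession, so adding proteins leaves existing ones
unchanged.

Not emulated: phylogenetic structure (species are conditionally
independent given the archetype — no trees, rate matrices or
covarion effects), indels within orthologues, annotation biases
correlated with conservation, and real motif-level kinase
specificity.  Passing tests therefore demonstrate pipeline
correctness and statistical calibration, not biological conclusions
about any real proteome.

## Numerical choices and degenerate inputs

* Quartiles use linear interpolation (NumPy default); Tukey whiskers
  are the farthest data points within 1.5×IQR of the box.
* The two-sample test is Welch's t (unequal variances); identical
  samples return t = 0, p = 1; arms with < 2 values return NaN for the
  test while box statistics are still produced.
* Disorder classification is strict: disordered iff score > 0.5.
* BH adjustment is the standard step-up with monotonicity enforcement
  and clamping at 1, order-preserving.
* Cluster ids are renumbered by first appearance so equal inputs give
  byte-identical outputs; a single profile or k = n degenerate cuts
  are handled explicitly.
* Zero-variance predictors and < 3 points are rejected by the
  regression rather than returning a misleading R².
* Empty site tables propagate to empty (but valid) outputs; missing
  input files fail fast with the offending path and partial outputs
  are removed.

## Problem sizes

Tests and the acceptance script run the default study (200 proteins ×
100 species, ≈ 1,500 sites, ≈ 100,000 predictions) plus
enumeration-exact checks at small N (hypergeometric universes N ≤ 12,
200 randomized MSAs of ≤ 10 species × ≤ 60 columns, 10,000-draw factor
calibration).  These sizes exercise every code path at full panel
width while keeping a complete run in seconds; the same code paths
scale to full proteome studies by pointing the pipeline at larger
input directories.

## Known limitations

* Ser+Thr totals in public gold-standard tables are occasionally
  internally inconsistent; loaders report their own counts and do not
  reconcile source tallies.
* The labeling rule ("largest matching fraction, ties to the more
  specific template") can prefer a more general description when
  sampling noise makes a few cluster members fail a small constrained
  group; this mirrors the ambiguity of manual labels.
* Whether percentage vectors should be standardized before Euclidean
  clustering is genuinely open; raw percentages are the default and a
  flag exposes the alternative.
* The built-in aligner is a stand-in: per-species pairwise alignment
  can differ from a joint multiple alignment in low-identity regions.
  Externally produced MSAs should be used when exact reproduction of
  an external aligner's columns matters.
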