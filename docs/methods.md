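# Methods

`mobilome` implements an integrated comparative-genomics workflow for
bacterial species complexes: delimiting subspecies-level sublineages from
whole-genome relatedness, synteny, and pangenome structure; discovering and
reconstructing integrated and episomal mobile genetic elements (MGEs) from
draft assemblies using seed queries plus contextual evidence; and tracking
insertion-sequence (IS) transposition across serial-passage resequencing.
This note records the models, the parameters that matter, and the design
choices made where the design was genuinely open.

## Synthetic species complexes (`mobilome.forge`)

The forge produces ground-truthed data so that every downstream stage can be
scored offline against `TruthRecord`s.

**Divergence model.** A random ancestral chromosome (default 50 kb,
GC 0.585 — the GC range typical of acidophilic iron-oxidizing
chemolithotrophs) carries non-overlapping protein-coding genes
(mean 900 bp ± 20% jitter, 50–200-bp intergenic spacers, random strand,
stop-free ORFs) and four tRNA genes that serve as island integration sites.
Two sublineage ancestors diverge from the root by
(between − within)/2 substitutions/site and each strain from its group
ancestor by within/2, so the *realized* pairwise difference is `within`
inside a group and `between` across groups (defaults 0.005 / 0.03, giving
ANI ≈ 99.5% within and ≈ 97% between — bracketing the 96% species threshold
from above, the configuration under which sublineage delimitation is a
non-trivial but solvable problem). Divergence is substitution-only, which
keeps Hamming-style identity oracles exact; indels occur only inside planted
cargo. Default 4 strains per group (8 total). All coordinates are 0-based
half-open in memory and 1-based inclusive in GFF3.

**Element planting.** `plant_element` inserts GC-shifted cargo immediately
downstream of its integration site, duplicating the `dr_length` bp that
follow the insertion point so identical direct repeats flank the cargo
(attL/attR); excising the element plus one repeat copy restores the original
chromosome byte-for-byte. Plasmid specs instead add a separate circular
replicon. The cargo's outermost bases are adjusted so they cannot
coincidentally extend the duplicated target site — this keeps the planted
repeat *maximal* and the DR-recovery oracle well defined. Planting the same
spec with the same seed and base GC into several strains yields
byte-identical cargo, i.e. a genuinely orthologous shared element.
The standard study complex plants an ICE (9 genes, 48-bp DR, tRNA-Ala),
a high-GC genomic island (6 genes, 48-bp DR, tRNA-Arg), a transposon
(3 genes, 8-bp target-site duplication — the short TSD scale typical of
Tn7/ISL3-family elements, deliberately below the 12-bp DR detection floor)
and a 6-gene plasmid into every group-A strain.

**Drafts.** `make_draft` breaks the chromosome only at intergenic midpoints
(annotations survive remapping); random breaks avoid planted elements, and an
optional forced break splits one element across two contigs, updating its
truth record to two per-contig segments.

**Resequencing.** `simulate_reseq` emits a per-base Poisson depth track
(plasmid contigs scaled by `plasmid_fold`) and single-end SAM-convention
reads around each IS insertion. Reads are drawn from the mutant haplotype
(reference + IS + target-site duplication) at rate `depth × allele_fraction`
and from the wild haplotype at the complementary rate; reads crossing a new
junction carry soft-clipped IS tails (min clip 8 bp). Read starts are
sampled so that interior positions see the nominal depth regardless of
window width — this is what makes the downstream allele-fraction estimator
unbiased. No sequencing-error model is applied (a stated non-goal);
consequences for real data are discussed under Limitations.

## Genome relatedness (`mobilome.relatedness`)

**ANIb.** The query is chopped into 1020-bp fragments; each fragment is
placed in the subject and retained when identity ≥ 30% over ≥ 70% fragment
coverage; ANIb is the mean identity of retained fragments, averaged over
both directions. The alignment backend is pluggable; the default uses edlib
semi-global alignment with two BLAST-emulating refinements: (i) a fragment
must share an exact 16-bp word with the subject before it can produce a hit
(edit-distance alignment otherwise "aligns" anything, letting non-homologous
sequence corrupt the average), and (ii) the alignment is trimmed to its
maximum-scoring local window (match +2, mismatch −3, gap −4), so a fragment
whose flank has no homolog loses *coverage* rather than identity — the
behavior of a true local aligner's HSP. The shared word also localizes the
alignment, keeping all-vs-all runs fast.

**dDDH-style index.** The distance d = 1 − (Σ identities / Σ HSP length)
over retained fragments is mapped to a hybridization percentage through a
logistic curve, `100 / (1 + exp(−(a + b·d)))`. The published regression
coefficients for this transform are not restated here; the defaults
(a = 6.9068, b = −157.39) are calibrated to the two canonical anchors —
identical genomes ≈ 100% and 70% at the species-boundary distance
d = 0.0385 — and live in `DdhModel`, overridable per run. Identical genomes
give d = 0 exactly.

**Delimitation.** Species are connected components of the ≥ 96% ANI graph;
within the largest species, sublineages come from the single-linkage
dendrogram cut at its largest merge-height jump, accepted only when the jump
exceeds the configured gap (default 0.5 ANI points). A strain whose best
cross-group ANI comes within the gap of its worst within-group ANI is
flagged ambiguous rather than silently assigned.

## Synteny (`mobilome.synteny`)

Anchors are unique reciprocal-best protein hits (paralog-free). A block is a
maximal run of anchors colinear on both genomes, with at most `delta`
intervening genes between consecutive anchors on either genome and a
consistent orientation; blocks need ≥ 2 anchors. Coverage(delta) = anchored
genes inside blocks / gene count, averaged over both genomes (a
reference-directed mode is provided since published synteny fractions are
sometimes computed against a fixed reference), reported for delta 2..10 and
summarized by the mean of the nine values. Coverage is monotone
non-decreasing in delta by construction.

## Pangenome (`mobilome.pangenome`)

All-vs-all protein comparison (4-mer candidate prefilter, edlib global
identity, BLOSUM62 Karlin–Altschul e-values with λ = 0.267, K = 0.041);
edges kept at ≥ 75% length-ratio coverage, e-value ≤ 1e-5, identity ≥ 50%;
families are connected components. Compartments: core (all strains),
exclusive (one strain), soft-core (≥ 95% but not all; folded into flexible
for census-style counting), flexible (otherwise). A family is
group-exclusive for a sublineage when present in > 90% of its strains and
absent from all others; whether "> 90%" tolerates one absent member is a
function of group size and is exposed via the `group_majority` parameter.

## Seed census and boundaries (`mobilome.census`, `mobilome.boundaries`)

Seed-element proteins are searched against each target proteome (retained at
e-value < 0.001; a stricter 1e-10 display cut-off is available for
clustering figures), confirmed by reciprocal best hit into the seed's source
proteome, and summarized as percent-of-seed-proteins coverage per strain
(occurrence call at ≥ 95%; protein-wise, not bp-wise). Strains are clustered
on coverage profiles (average linkage, Euclidean) with name tie-breaking,
and the dendrogram is exported as Newick.

Boundary inference integrates per-gene evidence: GC deviation as a z-score
against the **core-gene** GC distribution (median/MAD; horizontally acquired
genes are the outliers being flagged, so they must not widen the reference
spread), read-depth z-score against the chromosome median, pangenome
compartment, and mobility-signature keywords (integrase, transposase, virB,
relaxase, par, toxin/antitoxin, rep, ...). Hits of one seed element within
10 genes cluster together; candidates extend outward over consecutive
flexible/exclusive genes, absorb runs of at most one core gene (islands
capture host genes), and stop at two consecutive core genes. Contigs that
are entirely flexible/exclusive and seed-bearing are absorbed whole.
Same-contig candidates with overlapping spans merge; cross-contig segments
merge into one element when they cover disjoint portions of the same seed at
≥ 50% combined coverage — the rule a draft-genome island split by assembly
fragmentation satisfies. Single-gene candidates are reported but flagged
low-confidence.

**att sites.** The terminal windows of a single-contig candidate
(1000 bp outward, 250 bp inward of each terminus) are scanned for their best
shared repeat: exact 8-mer seeds extended bidirectionally with a shared
mismatch budget (default ≤ 1). Two choices here are deliberate: mismatches
are only admitted in repeats ≥ 2×`min_dr` (a near-minimum-length repeat with
a mismatch is indistinguishable from chance in ~kb windows), and exact
repeats outrank longer mismatched extensions (greedy bridging otherwise
shadows the true repeat behind a spuriously extended one). attB is
reconstructed by excising the element plus one repeat copy; attP joins the
element termini across the repeat; the nearest tRNA/integrase feature is
recorded as the integration association. Elements whose planted repeat is
shorter than `min_dr` (e.g. the 8-bp transposon TSD) are correctly reported
as having no detectable att site.

**In-silico PCR.** Opposing-orientation primer matches within 6 kb;
amplicon length is the distance between outer 5′ ends, inclusive; circular
templates are searched across the origin; > 100 sites per primer raises an
ambiguity error. The validation designs reproduce the published geometry:
a 954-bp wild-type amplicon grows to 2,264 bp when a 1,302-bp IS with an
8-bp target-site duplication lands inside it (2,264 − 954 = IS + TSD).

## Typing and plasmid utilities (`mobilome.classify`)

Module detection is label-driven (product names / provided functional tags);
DnaA boxes (TTATCCACA, ≤ 1 mismatch, both strands) and IHF motifs
(WATCAANNNNTTR, IUPAC) are scanned within 500 bp of each replication gene.
Typing is a pure function of inventory × context: rep + circular (or rep +
oriV evidence on a stand-alone contig) → plasmid; integrated + integrase +
(≥ 5 distinct virB components or relaxase + coupling protein) → ICE;
integrase without conjugation → GI; transposase-bounded without
integrase/tRNA att → Tn; otherwise fragment. The ≥ 5-virB completeness
threshold reflects component loss in fragmented drafts and is configurable.
`circularize_contig` trims the longest terminal self-overlap
(≥ 50 bp exact by default); conflicting non-periodic overlap candidates
raise an ambiguity error. `digest` cuts at IUPAC-specified sites (G^GATCC
offset convention); circular molecules with n sites give n fragments summing
to the length, linear ones n + 1.

## IS dynamics (`mobilome.isdyn`)

`scan_is_copies` inventories copies by iterative best-placement and masking
(both strands), counting placements at ≥ 90% similarity over 100% of the IS
length by default; overlapping hits merge, and counts are monotone
non-increasing in the similarity threshold. `detect_insertions` clusters
soft-clipped reads (≥ 8-bp clips) whose tails continue into an IS terminus
(≤ 10% edit tolerance, both orientations), pairs left/right junction
clusters within 15 bp (the upper bound of ISL3-family target-site
duplications), and reports the insertion position (right-junction
coordinate), the TSD length (left − right offset), and the overlapped gene.
Both junctions require `min_support` (default 5) reads. Insertions inside
known reference copies of the same IS are suppressed.

The allele-fraction estimator is mutant-junction reads /
(mutant-junction + 2 × wild-spanning reads), where the margin demanded of a
spanning read shrinks with the TSD so the genomic windows producing
countable mutant and wild reads have equal width — without this the
estimator is biased by the ratio of window widths. Detection per passage
requires `min_support` total mutant junction reads; loss is called at the
first undetected passage after a detected one. `replicon_depth_fold` is the
ratio of median depths.

## Cargo census (`mobilome.cargo`)

A family is MGE-associated when any member lies in a reconstructed candidate
element and the family is flexible/exclusive (soft-core included). Each gets
an occurrence pattern — exclusive (one strain), intra-lineage, inter-lineage
— and a caller-provided functional category (COG-style letters a–u;
out-of-vocabulary labels coerce to "unknown" with a warning; no live
database lookups, by design). The mobilome fraction is MGE-associated
families / all families.

## Orchestration

`RunConfig` (YAML, unknown keys rejected, echoed into every report) drives
stages in dependency order; reports are JSON plus per-stage TSV/GFF3/Newick.
Reruns with identical config and inputs are byte-identical. The `mobilome`
CLI exposes forge / relate / synteny / pangenome / census / reconstruct /
classify / isdyn / report / run.

## Problem sizes and determinism

Validation sweeps use 20 independently forged complexes (8 strains × ~50 kb,
3 integrated elements + plasmid, one element split across draft contigs),
100 allele-fraction simulations, 20 transposition simulations at 30×, and
100 random digests — sizes at which the full validation completes in a few
minutes on one CPU while leaving every statistical check adequately powered.
Every operation takes one integer seed; internal streams split via
`numpy.random.SeedSequence.spawn`, so identical seeds give byte-identical
outputs.

## What the forge does and does not emulate

It emulates: two-sublineage clonal structure at tunable divergence, shared
vs strain-exclusive gene content, GC-shifted mobile cargo with target-site
duplications at tRNA/gene sites, multi-copy circular plasmids, draft
fragmentation that splits elements, and junction/depth read evidence for
transposition. It does not emulate: indel/rearrangement divergence of the
backbone, sequencing error, paired-end information, repeat-induced
misassembly, paralogous gene families, or annotation error. Passing tests
therefore demonstrate the correctness of the algorithms under clean
homology and exact annotations; on real drafts, performance will degrade
with annotation quality and repeat content, and ANI/dDDH absolute values
depend on the alignment backend (as they do between published ANI tools).

## Known limitations

- The dDDH transform is a calibrated logistic, not the published regression;
  comparisons across tools should use the distance d, which is exact.
- Element typing is only as good as the functional labels provided;
  unlabeled cargo can demote an ICE to GI.
- The transposition caller consumes alignment records; it does not map
  reads (the bundled simulator emits pre-aligned records), so real data
  must be aligned externally first.
- Excision is modeled only as attP/attB junction prediction and
  loss-of-detection; excision rates are out of scope.
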