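# Methods

## Consensus gene calling

Gene callers disagree mostly on translation starts and on marginal genes.
The identity rule therefore keys each predicted ORF on its *stop anchor* —
the forward-strand coordinate of the 3′-terminal base — together with the
strand, and ignores the predicted start.  Two predictions with the same
(strand, stop anchor) are one ORF; the longest predicted extent is kept,
on the rationale that a too-long ORF still contains the true protein while
a too-short one truncates it.  On circular-permuted genomes a gene spanning
the contig origin is stored with `end = start + len − 1 > L` and its anchor
reduced modulo the genome length, so both unwrapped representations merge.

Ties between equally long variants with the same anchor cannot differ in
extent on the same strand; when two callers emit the identical extent the
variant of the caller earliest in the configured order is recorded first
(pure determinism, no biological content).

Agreement is summarized as exact Venn cells: for k callers, the count of
consensus ORFs supported by exactly each of the 2^k − 1 non-empty caller
subsets.  A caller is flagged as an outlier when the fraction of its
predictions unique to it exceeds 25 % (configurable); flagging is advisory
— exclusion is an explicit configuration choice, because dropping a caller
changes the union.  The keep policy is union-keep over the trusted callers:
conservative on purpose, since small real genes (anti-CRISPR, immunity,
anti-restriction proteins, 50–120 aa) are exactly the ones single callers
miss.  No minimum ORF length filter is applied by default for the same
reason.

Reported percentages are rounded half-up to one decimal, matching the
convention of the aggregate tables this reproduces.

## Functional annotation transfer

Hits are HH-suite-style profile–profile comparisons (probability in
percent, E-value, alignment coverage as a fraction of the query).  The best
hit per query ranks by probability first, then E-value, then subject id;
probability-first is the HH-suite convention and is a deliberate choice
where the upstream procedure is ambiguous.

Family affiliation uses the rejection region "probability < 80 % or
E-value > 10⁻⁴": acceptance is therefore *inclusive* (≥ 80, ≤ 10⁻⁴).
The structure fallback is stated as an acceptance region ("greater than
80 %", "less than 10⁻³") and is encoded *strict*.  The asymmetry is kept
exactly as the source procedures state it; in practice no real hit sits on
a boundary.  The fallback additionally requires alignment coverage ≥ 0.5
of the query (default; the underlying manual check has no published
number) to avoid transferring a whole-protein name from a single-domain
structural match.  Whether upstream coverage was measured on query or
subject is not recoverable from hit tables; query coverage is assumed and
documented on the reader.

The re-annotation overlay is a packaged 24-family table (family →
product, category) applied to every member of a listed family, making the
renaming database-consistent; the operation is idempotent.

## Curation of overlapping ORFs

"Highly overlapping" is quantified as ≥ 50 % of the shorter feature
(configurable).  The published procedure gives no number; 0.5 matches
"almost entirely overlap" while sparing the few-bp overlaps normal in
compact phage genomes.  Conflicts are maximal cliques of mutually
overlapping ORFs, so a chain A–B–C where A and C do not overlap is two
pairwise conflicts, not one trio.

Resolution per conflict: with at least one strong member (probability
≥ 70 % and E-value ≤ 10⁻⁴), every weak member without a passing structure
hit is discarded; all-strong conflicts keep everything (no basis to
choose); all-weak conflicts keep-and-flag for review rather than discard —
the procedure modeled here only discards against a strong competitor.  An
ORF completely containing (or contained in) a same-strand tRNA is
discarded when its affiliation is weak or absent; the tRNA, predicted by a
dedicated tool upstream, always wins.  Opposite-strand containment
("overprinting", a real phenomenon in phage genomes) is never
auto-discarded.  The weak threshold (70 %) is deliberately distinct from
the affiliation threshold (80 %): both exist in the modeled procedure and
both are configurable.

Decisions are order-independent and exhaustive (one per input ORF), and
discarded ORFs stay in the audit export with the rule and metrics used.

## Genome layout

Terminal-repeat detection is exact-match only (the assembler artifact is
an exact duplication of one k-mer length, 77 bp in the assemblies this
models); the search range 20–1000 bp is configurable because the repeat
length is assembler-version-dependent.  The right-most copy is removed and
the contig treated as circular downstream.  Orientation
reverse-complements (if needed) and rotates so the terminase small subunit
gene starts at base 1 on the forward strand; all features are remapped by
the same transformation, which preserves lengths and is idempotent.  When
several ORFs annotate as terminase small subunit, the strongest family
probability anchors the numbering.

## Lifestyle and taxonomy

Temperate requires an integrase (default family phrog_216) plus at least
one co-marker: RDF/excisionase (phrog_66), CI-like repressor (phrog_6201),
CII-like regulator (phrog_725) or CIII anti-termination (phrog_550).  One
co-marker is required — the modeled procedure says "together with other
functions" without a count, and one is the weakest reading that still
blocks the known confounder of an orphan RDF in strictly virulent genera
(flagged in the rationale, never flipping the call).  An Ant-type
antirepressor (phrog_130) is tracked as temperate-associated but is not a
co-marker.  Detection is by family id, with an optional case-insensitive
product-keyword fallback for assignments from other databases.

Clustering is single-linkage (connected components at similarity ≥
threshold) at 95 % / 70 % for species / genus.  Single-linkage is the
natural reading of a pure threshold rule and guarantees that the species
partition refines the genus partition (asserted anyway).  A species
cluster containing no reference genome is a new species.

## Anti-CRISPR screen

Retention is disjunctive over the two predictor scores (strictly > 0.5,
strictly > −5): the published candidate table retains a row with the
AcRanker-style score at −5.17 on the strength of its PaCRISPR-style 0.77,
so a conjunctive rule contradicts the printed data.  Length (> 200 aa) and
homolog query cover (< 40 %) exclusions apply before scores and are never
rescued.  Genus rescue retains a score-failing candidate whose family
passes in ≥ 2 other genomes of the same genus — families conserved across
a genus with good scores elsewhere are unlikely to be noise in one member.
The context check flags candidates strictly between a portal-protein gene
and a head-scaffolding gene (either order, each within 3 intervening genes
by default), the genomic neighborhood of the validated AcrIE3 locus.

## Synthetic data

The generators emulate the statistical structure of the real inputs, not
their content:

* `make_genome` plants in-frame genes (genetic code 11; starts ATG/GTG/TTG,
  stops TAA/TAG/TGA — standard for enterobacterial phages) in a random
  background at a set GC, one labeled terminase small subunit, with an
  optional exact terminal repeat.  Realized GC concentrates within ±0.02
  of the target at 50 kb.
* `make_caller_outputs` gives each caller a sensitivity, a false-positive
  rate per kb and an in-frame start-jitter probability, reproducing the
  observed disagreement structure (starts differ, stops agree; one caller
  can be an outlier).  The demo defaults (sensitivities 0.72–0.98, fp
  0.02–0.35/kb, jitter 0.3) were chosen to produce the qualitative pattern
  seen in real five-caller comparisons: a phage-tuned caller that
  over-predicts and one bacterial caller that disagrees with the ensemble.
* `build_agreement_fixture` realizes an exact Venn-cell specification as
  caller prediction sets, validated by an independent recount oracle.  The
  packaged cell assignment reproduces the case-study aggregates (union
  290, five-way 90, outlier caller 144/47 unique, four-caller union 243
  with 186 shared, 34 unique to the phage-specific caller); cells not
  fixed by those aggregates were distributed once over plausible subsets
  and are not tuned.
* `make_similarity_matrix` draws within-species similarities from
  96–99.9 %, within-genus 75–90 % and between-genus 20–50 %, cleanly
  separated from the 95/70 thresholds as real genus-level data are.

What the synthetic fixtures do *not* model: sequencing error, assembly
chimeras, caller-specific start-codon biases, similarity values near the
clustering thresholds, and real protein sequences behind the hit tables.
Passing tests therefore demonstrate the correctness of the decision rules
and bookkeeping, not caller or predictor accuracy on real genomes.

Packaged static fixtures (all small TSVs) carry the published worked
examples: the 28-row candidate table (with synthetic query-cover values,
labeled as such, since covers were not printed), the 24-family overlay,
the per-genome lifestyle markers, and the three curation scenarios whose
affiliation metrics are transcribed and whose coordinates are synthetic
geometry realizing the described overlaps.

## Problem sizes and numerics

The demo genome is 40 kb (≈ 50 genes), the property suites use 1000
3 kb genomes for repeat recovery, 1500 random predictions for the merge
oracle, and 20 seeded 18-genome matrices for partition recovery — sizes at
which every oracle is exhaustive.  All randomness flows through
`numpy.random.default_rng(seed)` or `random.Random(seed)`; percentages use
decimal half-up rounding; E-values are plain floats (well inside double
range for profile comparisons).

## Known limitations

* Caller-native output formats are not parsed; ingestion is GFF3 or a
  normalized TSV.
* tRNA prediction, profile searches, similarity computation and the Acr
  predictors are consumed as inputs, never computed.
* The flat-file annotation export is a human-readable feature table, not a
  submission-grade GenBank/ENA file.
* Lifestyle calling is marker-based only; a temperate phage with a novel
  integrase family outside the marker set (or keyword list) is missed.
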