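# phagepipe

Consensus annotation and genetic mining of bacteriophage genomes.

Newly assembled phage genomes are hard to annotate well: gene callers
disagree on start codons and marginal genes, half of the predicted proteome
typically has no known function, false-positive ORFs overlap real genes, and
downstream decisions — is this phage temperate? does it carry anti-CRISPR
genes? — depend on getting all of that right.  `phagepipe` implements the
full desk-side pipeline as a tested, reusable library with a CLI, for
researchers characterizing phage isolates (e.g. for phage-therapy cocktail
design).

## What it does

* **Consensus gene calling.**  Predictions from several gene callers
  (AMIGene, Glimmer, MetaGeneAnnotator, Phanotate, Prodigal, ...) are merged
  under the *stop-anchor rule*: two predictions are the same ORF iff they
  share the stop codon position and strand, regardless of start.  The
  longest start variant is kept.  Venn-style agreement statistics identify
  outlier callers (flagged when > 25 % of a caller's predictions are unique
  to it), and a union-keep policy retains every ORF supported by any
  trusted caller.
* **Functional annotation transfer.**  Per-protein best hits against a
  PHROG-style orthologous-family database are accepted when probability
  ≥ 80 % and E-value ≤ 10⁻⁴; anything weaker is a *singleton* of unknown
  function.  Proteins still unannotated can take a product from a pdb70
  structure hit (probability > 80 %, E-value < 10⁻³, alignment covering
  ≥ 50 % of the query), and a curated 24-family re-annotation overlay
  renames families database-wide.
* **Automated curation.**  Highly overlapping ORFs (≥ 50 % of the shorter)
  are resolved: weak members (probability < 70 % or E-value > 10⁻⁴) without
  structure rescue are discarded when a strong competitor exists; all-strong
  groups are kept; ORFs swallowing a reliably predicted tRNA are discarded.
  Every decision lands in an audit table.
* **Genome layout.**  Exact terminal repeats left by the assembler on
  circularly permuted contigs are trimmed; the genome is rotated/flipped so
  the terminase small subunit gene is `GP_001` at position 1 on the forward
  strand; locus tags follow the `<prefix>_GP_001` / `<prefix>_tRNA1`
  convention.
* **Lifestyle and taxonomy.**  Temperate iff an integrase co-occurs with a
  lysogeny marker (RDF/excisionase, CI-, CII-, CIII-like); single-linkage
  clustering of an intergenomic-similarity matrix at 95 % (species) and
  70 % (genus).
* **Anti-CRISPR screen.**  Candidates pass when either predictor score is
  meaningful (PaCRISPR-style > 0.5 or AcRanker-style > −5), unless overlong
  (> 200 aa) or weakly homologous to validated Acr (query cover < 40 %);
  score-failing candidates are rescued when their family passes in ≥ 2
  other genomes of the same genus, and a context check flags candidates
  between the portal and head-scaffolding genes.

A synthetic-data module generates every input the pipeline consumes
(genomes with planted genes and terminal repeats, per-caller prediction
sets with exact Venn structure, hit tables, similarity matrices with
planted taxon blocks), so the whole pipeline runs self-contained.

## Worked example

```sh
phagepipe --seed 1 --out out run-all
```

runs the demo configuration — a 40 kb synthetic genome with a 77 bp
terminal repeat, five emulated callers, a synthetic hit table, the packaged
marker/candidate fixtures — and writes seven tables plus a manifest:

```
wrote 7 outputs to out
```

`out/summary.tsv` then reads (seed 1):

```
genome_id	n_orfs	pct_unknown_function	pct_singleton
synthetic_1	48	56.3	37.5
```

48 ORFs survived consensus and curation; 56.3 % remain of unknown function
and 37.5 % are singletons — the typical "dark matter" share of a fresh
phage isolate.  `out/lifestyle.tsv` calls one genome temperate (integrase +
CI/CII/CIII markers) and nine virulent; `out/clusters.tsv` recovers the
planted 4-genus / 10-species partition; `out/acr.tsv` retains 28 of 32
screened Acr candidates, rejecting all four distractors.

The same stages are available individually (`phagepipe consensus`,
`curate`, `acr`, ...) and as library functions (`phagepipe.consensus`,
`phagepipe.curation`, ...).

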