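# Methods

## The detection model

`defenscan` treats defence-system identification as a two-stage inference:
per-gene homology evidence, then per-locus rule evaluation.

**Homology evidence.** Every protein-coding gene (plus every pseudogene
whose inferred product has been substituted in) is scored against a set of
profile HMMs. Each HMM evidences exactly one protein family, but a family
may be evidenced by several HMMs (e.g. distinct clades of one protein); the
metadata table maps accession → family and may carry per-HMM thresholds.
For each (protein, HMM) pair only the best-scoring domain is kept (lowest
independent E-value, ties broken by bit score, then accession), and a hit
survives filtering iff

* full-sequence E-value ≤ ceiling **and** best-domain independent E-value ≤
  ceiling (default `1e-5`), and
* alignment coverage of the target ≥ floor **and** of the HMM ≥ floor
  (default `0.4` each),

with all comparisons inclusive and per-HMM metadata overriding the
defaults. Applying the ceiling to *both* E-values is the stricter of the
possible readings and is fixed here for reproducibility. Coverage is
computed from the best domain's alignment bounds, not its envelope. These
defaults live in configuration (`defenscan.config`), not in code paths, and
can be overridden globally from the CLI.

**Locus evaluation.** A system-definition model declares core, accessory
and prohibited families, a quorum (`minimum_core` distinct core families,
`minimum_total` distinct member families) and a colocalization limit
(`maximum_separation`). Along each contig, maximal runs of genes carrying
any of the model's families are assembled, allowing at most
`maximum_separation` intervening unrelated genes between consecutive
members. Separation is counted in annotated genes (including merged
non-coding features), not base pairs: gene-rank distance is robust to
intergenic-length variation and matches how operon insertions fragment a
locus. A run containing any prohibited-family gene is rejected outright
(prohibition scope is the run, not the genome); otherwise quorum is
checked on *distinct* families, so tandem duplications are reported as
members but never inflate the count. Within one model a gene contributes
exactly one family — its best-scoring among the model's member families —
preventing a single multi-domain gene from satisfying two slots at once.
Across models no exclusivity is imposed: overlapping classifications
(e.g. shared ATPase domains between Septu PtuA, retron proteins and Old
nucleases) are reported side by side for the user to resolve, since
silently picking one would discard information.

**Relaxed `_other` models.** Catch-all definitions (recognised by the
`_other` name suffix) run alongside the canonical ones with low quorum
(typically two co-localized components) to catch systems split across
contigs, fragmented by insertions, or containing pseudogenes. An `_other`
call is suppressed only when its member set is a subset of an accepted
canonical call of the same system family; cross-family overlaps are never
suppressed.

**Non-coding components.** ncRNA hits from a covariance-model search are
retained at the inclusion threshold E ≤ 0.01 (inclusive — "passing the
threshold" is read as ≤), and CRISPR arrays are ingested from an array
finder's GFF. Both are spliced into the gene order as features carrying
fixed family tokens (`ncRNA`, `CRISPR_array`) that models may list like any
protein family; they bypass HMM filtering entirely. The wrapper
configuration records the array finder's parameters verbatim
(`array_quality_score_cutoff 2.5, minimum_word_repeatation 3, word_length
11, minimum_no_of_repeats 3, repeat_length_cutoff 11,
max_gap_between_crisprs 250`) and the cmsearch search-space settings
(`Z 10, FZ 500`).

**Pseudogene rescue.** Pseudogenes arrive without protein sequences; when
the annotation names the full-length protein used to infer the product
(parsed from the `inference` attribute's "similar to AA sequence"
clause, falling back to `protein_id`), substitution attaches that sequence
so the gene can carry HMM evidence. Substitution never changes
coordinates, strand or gene order, is idempotent, and marks members with
the `pseudo_sub_` output prefix. Hits naming an unsubstituted pseudogene
are ignored during labelling, since a protein-less gene can have no real
search evidence.

## Parameters that matter

| parameter | default | unit | rationale |
|---|---|---|---|
| `evalue_max` | 1e-5 | E-value | conventional HMM screening ceiling; overridable per HMM |
| `target_cov_min`, `hmm_cov_min` | 0.4 | fraction | rejects single-domain matches to multi-domain families |
| `maximum_separation` | 4 | genes | tolerates small insertions without fusing neighbouring loci; per-model override |
| ncRNA `evalue_max` | 0.01 | E-value | covariance-model inclusion threshold, inclusive |
| gene-caller mode switch | 100 000 | nt | shorter inputs use anonymous/metagenomic calling |

Quorum defaults when a model file omits them: all listed core families
required, total = core — a missing core gene is a rejection unless the
model explicitly relaxes it.

## Coordinates and determinism

Coordinates are 1-based inclusive (GFF3 convention) everywhere, preserved
verbatim from input to output. Multi-interval (joined) genes collapse to
their outer span and are ranked by span start; ties break by end, then
locus tag. Circular contigs are treated as linear — a system spanning the
origin is seen as two fragments (a documented limitation; the `_other`
models usually still flag it). Model loading sorts by name, call numbering
sorts by (contig order, span start, model name), and CSV numeric formatting
is fixed (E-values at three significant digits, coverages at three
decimals), so identical inputs yield byte-identical outputs.

## The synthetic test bed

The fixture generator emulates exactly what the pipeline consumes: a demo
database (nine system models over 18 protein families, one toy HMM per
family — two for the RT family — built from ten 5%-mutated copies of a
fixed random seed protein) and planted genomes written in every input
format. Planted member proteins are 5%-mutated copies of the family seeds,
so the real HMM engine scores them strongly but not identically; a
fabricated per-domain table is emitted in parallel with E-values drawn
log-uniformly from a strong band (10⁻⁶⁰–10⁻²⁰) for planted genes and a
sub-threshold weak band (10⁻⁴–10⁰, low coverage) for decoy noise, so the
pipeline is testable without running any search engine. The two
methyltransferase families are modelled as ~18%-diverged paralogs whose
hits cross-match, reproducing the real shared-domain ambiguity that lets a
DISARM locus satisfy either subtype's methyltransferase slot.

What the toy bed does *not* emulate: realistic amino-acid composition,
genuine domain architecture, partial-coverage homology, or the
sensitivity/specificity trade-offs of a curated production database.
Passing tests therefore demonstrate the correctness of the filtering,
clustering and rule logic on unambiguous evidence — not detection
performance on real genomes, which is a property of the model database a
user supplies.

Problem sizes are deliberately small — contigs of ~10–20 genes, ≤ 30
features in the randomized engine-versus-oracle suites (200 seeded cases),
ten-sequence alignments behind each toy HMM — chosen so the whole suite
exercises every code path in seconds while the brute-force oracles remain
exhaustive.

## Open design choices made here

* Model files are flat YAML (keys `core`, `accessory`, `prohibited`,
  `minimum_core`, `minimum_total`, `maximum_separation`), one model per
  file, named by file stem; `_other` status is derived from the name
  suffix rather than a flag field, matching the naming convention.
* Per-model score thresholds beyond the per-HMM ones are not supported:
  thresholds attach to evidence (HMMs), rules attach to models.
* Gap counting is in genes; a base-pair alternative was rejected because
  annotation density varies and the rule should be invariant to intergenic
  drift. Both the default and per-model values are configurable.
* An ncRNA overlapping a CDS is kept as a separate ordered feature
  (least destructive choice).
* When two canonical models of one family both accept a run, both calls
  are reported; no precedence is invented.

## Known limitations

* No wraparound clusters on circular replicons.
* The CRISPR array finder and covariance-model search are consumed as
  files, not executed; only the gene caller (Prodigal) is wrapped.
* Single-gene systems inherit the precision limits of their single HMM;
  the demo database ships a stricter per-HMM threshold for its single-gene
  model for exactly this reason.
* Protein FASTA identifiers must match one of `protein_id`, `Name`,
  `locus_tag` or `ID` from the GFF; exotic header schemes need
  pre-processing.
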