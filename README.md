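# defenscan

Most bacteria and archaea carry arsenals of antiviral defence systems —
restriction–modification, CRISPR–Cas, DISARM, Wadjet, retrons and dozens of
other families — that protect them against phages and mobile genetic
elements. `defenscan` locates such systems in annotated prokaryotic genomes.
It is aimed at microbiologists screening isolate genomes, plasmids or
metagenomic contigs for defence loci, and at developers who need a tested,
scriptable detection engine.

## How detection works

1. **Evidence.** Every protein in the genome is searched against a database
   of profile HMMs (in process, or by ingesting a precomputed HMMER3
   per-domain table). Each (protein, HMM) pair is reduced to its best
   domain and filtered with inclusive thresholds: both the full-sequence
   E-value and the best domain's independent E-value must be ≤ the ceiling
   (default 10⁻⁵), and the alignment must cover ≥ 40% of both the target
   protein and the HMM. Per-HMM thresholds in the metadata table override
   these defaults.
2. **Non-coding components.** CRISPR arrays (from an external array
   finder's GFF) and retron msr-msd ncRNAs (from Infernal `cmsearch`
   output, filtered at the inclusion threshold E ≤ 0.01) are spliced into
   the gene order as non-protein "genes" carrying the fixed family tokens
   `CRISPR_array` and `ncRNA`.
3. **System models.** Each candidate system type is a declarative model:
   core, accessory and prohibited gene families, a quorum (minimum distinct
   core and total families), and a colocalization limit (maximum number of
   intervening unrelated genes, default 4). Maximal runs of labelled genes
   are built along each contig; a run containing a prohibited family is
   rejected, a run below quorum is rejected, anything else is reported as a
   system call. Relaxed `[system]_other` models (typically requiring only
   two co-localized components) run alongside the canonical definitions to
   catch fragmented, truncated or divergent systems; an `_other` call is
   suppressed only when it is a subset of an accepted canonical call of the
   same family.
4. **Pseudogene rescue.** Annotation pipelines flag frameshifted or
   truncated genes as pseudogenes and omit their proteins. When the
   annotation records the accession of the protein used to infer the
   pseudogene's product, `defenscan` can substitute that full-length
   protein so broken systems are still found; rescued members are prefixed
   `pseudo_sub_` in the output.

Inputs: GFF3 + protein FASTA (RefSeq- or Prodigal-style), GenBank flat
files (including RASTtk exports), or bare nucleotide FASTA (genes called
with Prodigal, switching to anonymous mode for inputs ≤ 100 kb). Outputs:
a per-gene CSV, a systems GFF3, a per-genome summary of **diversity**
(distinct system types) and **abundance** (total systems), and a JSON run
log with the complete effective configuration.

## Worked example

The package ships a deterministic fixture generator (a small demo model
database plus genomes with planted systems), so a complete run needs no
downloads:

```bash
defenscan fixtures --out fx --seed 1
defenscan run \
  --gff fx/genomes/disarm_reclass/disarm_reclass.gff \
  --faa fx/genomes/disarm_reclass/disarm_reclass.faa \
  --data fx/db \
  --domtbl fx/genomes/disarm_reclass/disarm_reclass.domtbl \
  --out out
# 2 system(s) detected (diversity 2, abundance 2); outputs in out
```

This genome carries a DISARM locus with *drmA–drmD*, a methyltransferase
and *drmE*. Because *drmE* is prohibited for DISARM type I, the locus is
not reported as type I but matches the type II definition; the surrounding
locus is additionally flagged by the relaxed `DISARM_other` model. The
first lines of `out/systems.csv` (one gene per row):

```
system.number,seqid,system,target.name,hmm.accession,hmm.name,protein.name,full.seq.E.value,domain.iE.value,target.coverage,hmm.coverage,start,end,strand,target.description
1,ctgA,DISARM_II,ctgA_0006,PLDC00004,DrmA_seed,DrmA,9.00e-34,4.30e-33,1.000,1.000,4249,5151,-,DrmA
1,ctgA,DISARM_II,ctgA_0007,PLDC00005,DrmB_seed,DrmB,1.20e-27,1.70e-27,1.000,1.000,5272,6114,+,DrmB
1,ctgA,DISARM_II,ctgA_0008,PLDC00006,DrmC_seed,DrmC,1.30e-53,9.80e-53,1.000,1.000,6247,6849,+,DrmC
1,ctgA,DISARM_II,ctgA_0010,PLDC00009,DrmMII_seed,DrmMII,1.00e-15,1.00e-14,1.000,1.000,8217,8969,+,DrmMI
1,ctgA,DISARM_II,ctgA_0011,PLDC00008,DrmE_seed,DrmE,5.90e-27,5.20e-26,1.000,1.000,9116,9778,+,DrmE
```

`full.seq.E.value` / `domain.iE.value` are the HMMER full-sequence and
best-domain independent E-values; `target.coverage` / `hmm.coverage` are
the alignment fractions of the protein and the HMM — the four numbers to
inspect when judging the confidence of a hit. `out/summary.tsv` tabulates
diversity and abundance per genome:

```
assembly.id	abundance	diversity	per.type.counts
disarm_reclass	2	2	DISARM=1;DISARM_II=1
```

The same pipeline is available as a library:

```python
from defenscan import run_pipeline
result = run_pipeline(["genome.gff", "genome.faa"], db_dir="fx/db", out_dir="out")
for call in result.calls:
    print(call.model_name, [m.feature.locus_tag for m in call.members])
```

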