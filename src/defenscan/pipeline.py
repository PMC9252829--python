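"""End-to-end detection: wire annotation input, hits, non-coding features,
the engine and the writers into one reproducible run."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import annotation_io, hmm_search, noncoding, output
from .annotation_io import Genome
from .config import DEFAULT_MAX_SEPARATION, FilterThresholds, NCRNA_EVALUE_MAX, RunConfig
from .engine import SystemCall, detect_systems
from .model_db import ModelDatabase

log = logging.getLogger(__name__)


@dataclass
class RunResult:
    genome: Genome
    calls: list[SystemCall]
    summary: output.GenomeSummary
    outputs: dict[str, Path] = field(default_factory=dict)


def load_genome(
    inputs: list[Path],
    dialect: str | None = None,
    fix_prodigal: bool = False,
    workdir: Path | None = None,
) -> Genome:
    """Dispatch one or two input files to the right parser."""
    inputs = [Path(p) for p in inputs]
    dialect = dialect or annotation_io.detect_dialect(inputs)
    if fix_prodigal:
        dialect = "prodigal_gff_faa"
    if dialect in {"genbank", "rast_genbank"}:
        return annotation_io.parse_genbank(inputs[0], dialect=dialect)
    if dialect == "nucleotide_fasta":
        genome, mode = annotation_io.call_genes(
            inputs[0], workdir or inputs[0].parent / "gene_calls"
        )
        log.info("gene caller ran in %s mode", mode)
        return genome
    # GFF + FASTA pair, in either order
    a, b = inputs
    if annotation_io._sniff(a) == "gff":
        gff, faa = a, b
    else:
        gff, faa = b, a
    return annotation_io.parse_gff_faa(gff, faa, dialect=dialect)


def run_pipeline(
    inputs: list[Path],
    db_dir: Path,
    out_dir: Path,
    domtbl: Path | None = None,
    crispr: Path | None = None,
    ncrna: Path | None = None,
    pseudo_proteins: Path | None = None,
    dialect: str | None = None,
    fix_prodigal: bool = False,
    thresholds: FilterThresholds | None = None,
    max_separation: int | None = None,
    ncrna_evalue_max: float = NCRNA_EVALUE_MAX,
) -> RunResult:
    """One full detection run; writes systems.csv, systems.gff, summary.tsv
    and a JSON run log with the effective configuration."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    thresholds = thresholds or FilterThresholds()
    sep = max_separation if max_separation is not None else DEFAULT_MAX_SEPARATION

    db = ModelDatabase.load(db_dir)
    for warning in db.validate():
        log.warning("%s", warning)

    genome = load_genome(inputs, dialect=dialect, fix_prodigal=fix_prodigal,
                         workdir=out_dir / "gene_calls")

    if pseudo_proteins is not None:
        from Bio import SeqIO

        lookup = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(pseudo_proteins), "fasta")}
        genome = annotation_io.substitute_pseudogenes(genome, lookup)

    ncrnas = noncoding.parse_cmsearch(ncrna, evalue_max=ncrna_evalue_max) if ncrna else []
    arrays = noncoding.parse_crispr_gff(crispr) if crispr else []
    genome = noncoding.merge_noncoding(genome, ncrnas, arrays)

    if domtbl is not None:
        hits = hmm_search.parse_domtbl(domtbl)
    else:
        hits = hmm_search.search_proteins(genome, db.hmm_path)
    hits = hmm_search.filter_hits(hits, db.meta, thresholds)

    calls = detect_systems(genome, hits, db.models, db.meta, max_separation_default=sep)

    outputs = {
        "csv": out_dir / "systems.csv",
        "gff": out_dir / "systems.gff",
        "summary": out_dir / "summary.tsv",
        "log": out_dir / "run_log.json",
    }
    output.write_csv(calls, genome, outputs["csv"])
    output.write_gff(calls, genome, outputs["gff"])
    summaries = output.summarize({genome.assembly_id: calls})
    output.write_summary(summaries, outputs["summary"])

    config = RunConfig(
        db_dir=str(db_dir), thresholds=thresholds, max_separation=sep,
        ncrna_evalue_max=ncrna_evalue_max, fix_prodigal=fix_prodigal,
    )
    outputs["log"].write_text(
        json.dumps(
            {
                "inputs": [str(p) for p in inputs],
                "effective_config": config.describe(),
                "n_models": len(db.models),
                "n_hmm_meta": len(db.meta),
                "n_features": len(genome.features),
                "n_filtered_hits": len(hits),
                "n_calls": len(calls),
            },
            indent=2,
        )
        + "\n"
    )
    return RunResult(genome=genome, calls=calls, summary=summaries[0], outputs=outputs)
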