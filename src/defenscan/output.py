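"""Result serialization and per-genome summaries.

The main output is a CSV with one gene per row for every accepted system
call, carrying the identity of the system and member, the HMM evidence
(full-sequence and best-domain independent E-values, target and HMM
coverages) and the member's coordinates exactly as annotated.  A systems
GFF3 mirrors the calls as parent/child features, and per-genome summaries
tabulate diversity (distinct system types) and abundance (total systems).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .annotation_io import Genome
from .engine import SystemCall

#: Column order of the per-gene CSV.
CSV_COLUMNS = [
    "system.number",
    "seqid",
    "system",
    "target.name",
    "hmm.accession",
    "hmm.name",
    "protein.name",
    "full.seq.E.value",
    "domain.iE.value",
    "target.coverage",
    "hmm.coverage",
    "start",
    "end",
    "strand",
    "target.description",
]


def _rows(calls: list[SystemCall]) -> list[dict[str, object]]:
    rows = []
    for call in calls:
        for m in sorted(call.members, key=lambda m: (m.feature.start, m.feature.locus_tag)):
            f = m.feature
            if m.hit is not None:
                evidence = {
                    "hmm.accession": m.hit.hmm_accession,
                    "hmm.name": m.hit.hmm_name,
                    # fixed formatting so reruns are byte-identical
                    "full.seq.E.value": f"{m.hit.full_seq_evalue:.2e}",
                    "domain.iE.value": f"{m.hit.domain_ievalue:.2e}",
                    "target.coverage": f"{m.hit.target_coverage:.3f}",
                    "hmm.coverage": f"{m.hit.hmm_coverage:.3f}",
                }
            else:  # non-coding member: no HMM scores
                evidence = {
                    "hmm.accession": "",
                    "hmm.name": "",
                    "full.seq.E.value": "",
                    "domain.iE.value": "",
                    "target.coverage": "",
                    "hmm.coverage": "",
                }
            rows.append(
                {
                    "system.number": call.system_number,
                    "seqid": call.contig,
                    "system": call.model_name,
                    "target.name": f.display_name,
                    "protein.name": m.family,
                    "start": f.start,
                    "end": f.end,
                    "strand": f.strand,
                    "target.description": f.description,
                    **evidence,
                }
            )
    return rows


def write_csv(calls: list[SystemCall], genome: Genome, path: Path) -> int:
    """Write the per-gene CSV; returns the number of data rows written."""
    df = pd.DataFrame(_rows(calls), columns=CSV_COLUMNS)
    df.to_csv(path, index=False)
    return len(df)


def write_gff(calls: list[SystemCall], genome: Genome, path: Path) -> int:
    """Write calls as GFF3: one parent row per system, one child per member.

    Member coordinates are identical to the input annotation.  Returns the
    total number of feature rows written.
    """
    lines = ["##gff-version 3"]
    for contig, length in genome.contigs.items():
        if length:
            lines.append(f"##sequence-region {contig} 1 {length}")
    n = 0
    for call in calls:
        sys_id = f"system_{call.system_number}"
        lo, hi = call.span
        lines.append(
            "\t".join(
                [
                    call.contig, "defenscan", "sequence_feature",
                    str(lo), str(hi), ".", ".", ".",
                    f"ID={sys_id};Name={call.model_name};system_number={call.system_number}",
                ]
            )
        )
        n += 1
        for m in sorted(call.members, key=lambda m: (m.feature.start, m.feature.locus_tag)):
            f = m.feature
            lines.append(
                "\t".join(
                    [
                        call.contig, "defenscan", "gene",
                        str(f.start), str(f.end), ".", f.strand, ".",
                        f"ID={sys_id}.{f.locus_tag};Parent={sys_id};"
                        f"family={m.family};role={m.role};target={f.display_name}",
                    ]
                )
            )
            n += 1
    Path(path).write_text("\n".join(lines) + "\n")
    return n


@dataclass
class GenomeSummary:
    """Per-genome defence diversity and abundance.

    Diversity is the number of distinct system types in the genome;
    abundance the total number of systems.  An ``_other`` call counts toward
    abundance, but its type — for diversity — is its system family: the
    ``_other`` suffix marks reduced confidence, not a distinct type.
    """

    assembly_id: str
    abundance: int = 0
    diversity: int = 0
    per_type_counts: dict[str, int] = field(default_factory=dict)


def call_type(call: SystemCall) -> str:
    return call.family if call.is_other else call.model_name


def summarize(calls_by_genome: dict[str, list[SystemCall]]) -> list[GenomeSummary]:
    """Tabulate diversity and abundance per genome (call-order invariant)."""
    out = []
    for assembly_id in sorted(calls_by_genome):
        calls = calls_by_genome[assembly_id]
        counts: dict[str, int] = {}
        for call in calls:
            t = call_type(call)
            counts[t] = counts.get(t, 0) + 1
        out.append(
            GenomeSummary(
                assembly_id=assembly_id,
                abundance=len(calls),
                diversity=len(counts),
                per_type_counts=dict(sorted(counts.items())),
            )
        )
    return out


def write_summary(summaries: list[GenomeSummary], path: Path) -> None:
    rows = [
        {
            "assembly.id": s.assembly_id,
            "abundance": s.abundance,
            "diversity": s.diversity,
            "per.type.counts": ";".join(f"{t}={n}" for t, n in s.per_type_counts.items()),
        }
        for s in summaries
    ]
    pd.DataFrame(
        rows, columns=["assembly.id", "abundance", "diversity", "per.type.counts"]
    ).to_csv(path, sep="\t", index=False)
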