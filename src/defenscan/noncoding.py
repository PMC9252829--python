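"""Non-coding system components: retron ncRNAs and CRISPR arrays.

Some defence systems include non-protein components — the msr-msd ncRNA of
retrons, or a CRISPR array.  These are detected by external tools (a
covariance-model search for ncRNAs, a repeat finder for arrays) whose
tabular/GFF outputs are ingested here, filtered, and spliced into the
genome's ordered feature table as first-class "genes".  Once merged they
carry a fixed family token (``ncRNA`` / ``CRISPR_array``), bypass HMM
filtering entirely, and count toward system quorums exactly like protein
members.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

from Bio import SearchIO
from gffutils.iterators import DataIterator

from .annotation_io import GeneFeature, Genome, order_features
from .config import NCRNA_EVALUE_MAX

log = logging.getLogger(__name__)

#: GFF feature types accepted as CRISPR arrays.
_ARRAY_TYPES = {"repeat_region", "CRISPR"}
_REPEAT_UNIT_TYPES = {"direct_repeat", "repeat_unit"}


@dataclass(frozen=True)
class NcrnaHit:
    """One covariance-model hit passing the inclusion threshold."""

    contig: str
    start: int  # 1-based inclusive
    end: int
    strand: str
    cm_name: str
    evalue: float
    family_token: str = "ncRNA"

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"ncRNA hit on {self.contig}: start > end")


@dataclass(frozen=True)
class CrisprArray:
    """One CRISPR repeat-spacer array from the external array finder."""

    contig: str
    start: int
    end: int
    repeat_count: int
    family_token: str = "CRISPR_array"


def parse_cmsearch(path: Path, evalue_max: float = NCRNA_EVALUE_MAX) -> list[NcrnaHit]:
    """Parse Infernal cmsearch tabular output, keeping hits with E ≤ threshold.

    The default threshold is the inclusion threshold E = 0.01; the comparison
    is inclusive, so a hit at exactly 0.01 is retained.  Coordinates are
    returned 1-based inclusive with start ≤ end regardless of strand.
    """
    path = Path(path)
    _prevalidate_cmsearch(path)
    hits: list[NcrnaHit] = []
    try:
        qresults = list(SearchIO.parse(str(path), "infernal-tab"))
    except ValueError as exc:
        if "likely incorrect" in str(exc):  # header-only / empty output
            return []
        raise
    for qresult in qresults:
        for hit in qresult:
            for hsp in hit:
                ev = float(hsp.evalue)
                if ev > evalue_max:
                    continue
                lo, hi = sorted((int(hsp.hit_start), int(hsp.hit_end)))
                hits.append(
                    NcrnaHit(
                        contig=hit.id,
                        start=lo,
                        end=hi,
                        strand="-" if hsp.hit_strand == -1 else "+",
                        cm_name=qresult.id,
                        evalue=ev,
                    )
                )
    hits.sort(key=lambda h: (h.contig, h.start, h.end, h.cm_name))
    return hits


def _prevalidate_cmsearch(path: Path) -> None:
    for lineno, ln in enumerate(path.read_text().splitlines(), start=1):
        if not ln.strip() or ln.startswith("#"):
            continue
        n = len(ln.split())
        if n < 18:
            raise ValueError(
                f"{path}, line {lineno}: expected >= 18 cmsearch tabular columns, found {n}"
            )


def parse_crispr_gff(path: Path) -> list[CrisprArray]:
    """Parse a CRISPR-finder GFF into arrays (repeat_region / CRISPR rows).

    The repeat count comes from a numeric attribute whose key mentions
    "repeat" when present; otherwise child repeat-unit rows referencing the
    array via ``Parent`` are counted.  Rows of any other type are skipped
    (with a debug note); nothing here is fatal.
    """
    path = Path(path)
    arrays: list[dict] = []
    unit_parents: list[str] = []
    for feat in DataIterator(str(path)):
        if feat.featuretype in _ARRAY_TYPES:
            count = None
            for key, vals in feat.attributes.items():
                if "repeat" in key.lower() and vals:
                    try:
                        count = int(vals[0])
                        break
                    except ValueError:
                        continue
            arrays.append(
                {
                    "contig": feat.seqid,
                    "start": feat.start,
                    "end": feat.end,
                    "id": (feat.attributes.get("ID") or [None])[0],
                    "count": count,
                }
            )
        elif feat.featuretype in _REPEAT_UNIT_TYPES:
            parent = (feat.attributes.get("Parent") or [None])[0]
            if parent:
                unit_parents.append(parent)
        else:
            log.debug("skipping %s row in %s", feat.featuretype, path.name)
    out: list[CrisprArray] = []
    for a in arrays:
        count = a["count"]
        if count is None and a["id"]:
            count = sum(1 for p in unit_parents if p == a["id"]) or None
        out.append(
            CrisprArray(
                contig=a["contig"], start=a["start"], end=a["end"], repeat_count=count or 0
            )
        )
    out.sort(key=lambda c: (c.contig, c.start, c.end))
    return out


def merge_noncoding(
    genome: Genome,
    ncrnas: list[NcrnaHit] | None = None,
    arrays: list[CrisprArray] | None = None,
) -> Genome:
    """Splice ncRNA hits and CRISPR arrays into the ordered feature table.

    Each becomes a :class:`GeneFeature` of kind ``ncRNA`` / ``CRISPR_array``
    in coordinate order; ranks are recomputed so separation counting sees
    them like any other gene.  Referencing an unknown contig is an error.
    """
    extras: list[GeneFeature] = []
    counters: dict[str, int] = {}
    for item in list(ncrnas or []) + list(arrays or []):
        if item.contig not in genome.contigs:
            raise ValueError(
                f"non-coding feature on unknown contig {item.contig!r} "
                f"(genome has {sorted(genome.contigs)})"
            )
        kind = item.family_token  # "ncRNA" or "CRISPR_array"
        n = counters.get(kind, 0) + 1
        counters[kind] = n
        extras.append(
            GeneFeature(
                contig=item.contig,
                locus_tag=f"{item.contig}_{kind.lower()}_{n}",
                start=item.start,
                end=item.end,
                strand=getattr(item, "strand", "+"),
                kind=kind,
                description=getattr(item, "cm_name", "") or f"CRISPR array",
            )
        )
    if not extras:
        return genome
    return order_features(
        genome.assembly_id,
        dict(genome.contigs),
        [*(genome.features), *extras],
        dict(genome.nt_seqs),
    )
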