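"""Genome annotation input: dialect detection, parsing, pseudogene substitution.

Accepted inputs are a GFF3 + amino-acid FASTA pair (RefSeq-style or
Prodigal-style identifiers), a GenBank flat file (including RASTtk exports),
or a bare nucleotide FASTA handed to an external gene caller.  Whatever the
source, the result is a :class:`Genome`: an ordered table of
:class:`GeneFeature` records with 1-based inclusive coordinates exactly as
annotated, ranked along each contig.

Pseudogenes are carried through without a protein sequence.  When the
annotation records the accession of the full-length protein that was used to
infer the pseudogene's product, :func:`substitute_pseudogenes` can attach
that protein so that broken genes still contribute HMM evidence downstream;
such features are flagged ``pseudo_substituted`` and their output rows carry
the ``pseudo_sub_`` prefix.
"""

from __future__ import annotations

import logging
import re
import shutil
import subprocess
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterable, Mapping

from Bio import SeqIO
from gffutils.iterators import DataIterator

from .config import GENE_CALLER_SINGLE_MODE_MIN_LENGTH

log = logging.getLogger(__name__)

FEATURE_KINDS = ("CDS", "pseudogene", "ncRNA", "CRISPR_array")

#: Prefix applied to the target name of substituted pseudogenes in outputs.
PSEUDO_SUB_PREFIX = "pseudo_sub_"


class AnnotationError(ValueError):
    """Input annotation could not be parsed or reconciled."""


@dataclass
class GeneFeature:
    """One ordered coding or non-coding feature on a contig.

    Coordinates are 1-based inclusive (GFF3 convention) and are preserved
    verbatim from input to output.  ``order_index`` is the rank of the
    feature along its contig, the unit in which cluster separation is
    counted.
    """

    contig: str
    locus_tag: str
    start: int
    end: int
    strand: str
    kind: str = "CDS"
    order_index: int = -1
    protein_seq: str | None = None
    pseudo_substituted: bool = False
    inference_accession: str | None = None
    description: str = ""

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise AnnotationError(
                f"feature {self.locus_tag!r}: start {self.start} > end {self.end}"
            )
        if self.strand not in {"+", "-"}:
            raise AnnotationError(
                f"feature {self.locus_tag!r}: strand must be '+' or '-', got {self.strand!r}"
            )
        if self.kind not in FEATURE_KINDS:
            raise AnnotationError(f"feature {self.locus_tag!r}: unknown kind {self.kind!r}")

    @property
    def searchable(self) -> bool:
        """True when the feature has a protein sequence to search with HMMs."""
        return self.protein_seq is not None

    @property
    def display_name(self) -> str:
        return (PSEUDO_SUB_PREFIX + self.locus_tag) if self.pseudo_substituted else self.locus_tag


@dataclass
class Genome:
    """An annotated genome: ordered contigs and their ordered features."""

    assembly_id: str
    contigs: dict[str, int] = field(default_factory=dict)  # name -> length (nt)
    features: list[GeneFeature] = field(default_factory=list)
    nt_seqs: dict[str, str] = field(default_factory=dict)  # optional, GenBank/FASTA path

    def __post_init__(self) -> None:
        self._validate()

    def _validate(self) -> None:
        seen: set[str] = set()
        for f in self.features:
            if f.contig not in self.contigs:
                raise AnnotationError(
                    f"feature {f.locus_tag!r} references unknown contig {f.contig!r}"
                )
            if f.locus_tag in seen:
                raise AnnotationError(f"duplicate locus_tag {f.locus_tag!r}")
            seen.add(f.locus_tag)

    def by_locus(self) -> dict[str, GeneFeature]:
        return {f.locus_tag: f for f in self.features}

    def features_on(self, contig: str) -> list[GeneFeature]:
        return [f for f in self.features if f.contig == contig]


def order_features(
    assembly_id: str,
    contigs: dict[str, int],
    features: Iterable[GeneFeature],
    nt_seqs: dict[str, str] | None = None,
) -> Genome:
    """Assemble a :class:`Genome`, sorting features and assigning order ranks.

    Features are ordered by start, ties broken by end then locus_tag; ranks
    restart at 0 on each contig.  Contigs keep their input order.
    """
    ordered: list[GeneFeature] = []
    feats = list(features)
    for contig in contigs:
        on_contig = sorted(
            (f for f in feats if f.contig == contig),
            key=lambda f: (f.start, f.end, f.locus_tag),
        )
        # copy so that re-ranking never mutates features owned by another Genome
        ordered.extend(replace(f, order_index=rank) for rank, f in enumerate(on_contig))
    return Genome(
        assembly_id=assembly_id,
        contigs=dict(contigs),
        features=ordered,
        nt_seqs=nt_seqs or {},
    )


# ---------------------------------------------------------------------------
# dialect detection

DIALECTS = (
    "refseq_gff_faa",
    "prodigal_gff_faa",
    "rast_genbank",
    "genbank",
    "nucleotide_fasta",
)

_NT_CHARS = set("ACGTUNacgtun")


def _sniff(path: Path, nbytes: int = 65536) -> str:
    text = Path(path).read_text(errors="replace")[:nbytes]
    first = next((ln for ln in text.splitlines() if ln.strip()), "")
    if first.startswith("LOCUS"):
        return "genbank"
    if first.startswith("##gff-version") or first.startswith("#!"):
        return "gff"
    if first.startswith(">"):
        seq = "".join(
            ln.strip() for ln in text.splitlines()[1:] if ln and not ln.startswith(">")
        )[:2000]
        if seq and sum(c in _NT_CHARS for c in seq) / len(seq) > 0.9:
            return "fasta_nt"
        return "fasta_aa"
    for ln in text.splitlines():
        if ln.strip() and not ln.startswith("#"):
            if len(ln.split("\t")) == 9:
                return "gff"
            break
    return "unknown"


def detect_dialect(paths: list[Path]) -> str:
    """Classify one or two input files into a supported dialect (content-based).

    A single file may be GenBank (RASTtk exports are recognised by the string
    ``rasttk`` in the file), or a nucleotide FASTA destined for gene calling.
    A pair must be GFF3 + protein FASTA; Prodigal output is recognised by the
    string ``Prodigal`` in the GFF header.
    """
    kinds = {p: _sniff(Path(p)) for p in paths}
    if len(paths) == 1:
        (path,), (kind,) = zip(*kinds.items())
        if kind == "genbank":
            return "rast_genbank" if "rasttk" in Path(path).read_text(errors="replace") else "genbank"
        if kind == "fasta_nt":
            return "nucleotide_fasta"
    elif len(paths) == 2:
        by_kind = {v: k for k, v in kinds.items()}
        if "gff" in by_kind and ("fasta_aa" in by_kind or "fasta_nt" in by_kind):
            gff_head = Path(by_kind["gff"]).read_text(errors="replace")[:65536]
            return "prodigal_gff_faa" if "Prodigal" in gff_head else "refseq_gff_faa"
    raise AnnotationError(
        "unsupported input format; accepted: GFF3 + amino-acid FASTA pair "
        "(RefSeq or Prodigal formatting), GenBank flat file (incl. RASTtk), "
        f"or nucleotide FASTA (got {', '.join(sorted(set(kinds.values())))})"
    )


# ---------------------------------------------------------------------------
# GFF3 + FASTA

_INFERENCE_RE = re.compile(r"similar to AA sequence[:\s]+(?:[^:,\s]+:)?([A-Za-z0-9_.]+)")


def _prevalidate_gff(path: Path) -> None:
    """Cheap structural scan so parse errors can name the offending line."""
    for lineno, ln in enumerate(Path(path).read_text().splitlines(), start=1):
        if not ln.strip() or ln.startswith("#"):
            continue
        if ln.startswith(">"):  # trailing ##FASTA section
            return
        n = len(ln.split("\t"))
        if n != 9:
            raise AnnotationError(
                f"{path}, line {lineno}: expected 9 tab-separated GFF columns, found {n}"
            )


def _attr(feature, *keys: str) -> str | None:
    for key in keys:
        vals = feature.attributes.get(key)
        if vals:
            return vals[0]
    return None


def _sequence_regions(path: Path) -> dict[str, int]:
    regions: dict[str, int] = {}
    for ln in Path(path).read_text().splitlines():
        if ln.startswith("##sequence-region"):
            parts = ln.split()
            if len(parts) >= 4:
                regions[parts[1]] = int(parts[3])
        elif ln.strip() and not ln.startswith("#"):
            break
    return regions


def parse_gff_faa(
    gff: Path,
    faa: Path,
    dialect: str = "refseq_gff_faa",
    assembly_id: str | None = None,
) -> Genome:
    """Parse a GFF3 + protein FASTA pair into an ordered :class:`Genome`.

    CDS rows sharing one ID (multi-interval genes) collapse to their outer
    span.  Rows typed ``pseudogene`` or flagged ``pseudo=true`` become
    pseudogene features without a protein; their inference accession is
    pulled from the ``inference`` attribute ("similar to AA sequence...")
    with ``protein_id`` as fallback.  With the Prodigal dialect, GFF IDs of
    the form ``<k>_<n>`` are rewritten to the FASTA convention
    ``<contig>_<n>`` so the pair reconciles.

    Every CDS must find its protein in the FASTA and vice versa; offenders
    are listed in the raised error.
    """
    gff, faa = Path(gff), Path(faa)
    _prevalidate_gff(gff)
    proteins = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(faa), "fasta")}

    rows: dict[str, dict] = {}
    order: list[str] = []
    for feat in DataIterator(str(gff)):
        if feat.featuretype not in {"CDS", "pseudogene"}:
            continue
        pseudo = feat.featuretype == "pseudogene" or (
            (_attr(feat, "pseudo") or "").lower() == "true"
        )
        raw_id = _attr(feat, "ID") or _attr(feat, "locus_tag") or f"{feat.seqid}:{feat.start}"
        if dialect == "prodigal_gff_faa":
            # Prodigal GFF IDs are "<seqnum>_<genenum>"; FASTA ids are "<contig>_<genenum>"
            locus = f"{feat.seqid}_{raw_id.rsplit('_', 1)[-1]}"
        else:
            locus = _attr(feat, "locus_tag") or raw_id
        key = f"{feat.seqid}\t{raw_id}\t{pseudo}"
        row = rows.get(key)
        if row is None:
            rows[key] = {
                "contig": feat.seqid,
                "locus": locus,
                "start": feat.start,
                "end": feat.end,
                "strand": feat.strand if feat.strand in "+-" else "+",
                "pseudo": pseudo,
                "protein_keys": [],
                "inference": _attr(feat, "inference"),
                "protein_id": _attr(feat, "protein_id"),
                "name": _attr(feat, "Name"),
                "description": _attr(feat, "product") or "",
            }
            order.append(key)
            row = rows[key]
        else:  # additional interval of a joined CDS: collapse to outer span
            row["start"] = min(row["start"], feat.start)
            row["end"] = max(row["end"], feat.end)

    features: list[GeneFeature] = []
    unmatched_cds: list[str] = []
    used_proteins: set[str] = set()
    for key in order:
        row = rows[key]
        inference_acc = None
        if row["inference"]:
            m = _INFERENCE_RE.search(row["inference"])
            if m:
                inference_acc = m.group(1)
        if inference_acc is None and row["pseudo"]:
            inference_acc = row["protein_id"]

        protein = None
        if not row["pseudo"]:
            for cand in (row["protein_id"], row["name"], row["locus"], key.split("\t")[1]):
                if cand and cand in proteins:
                    protein = proteins[cand]
                    used_proteins.add(cand)
                    break
            if protein is None:
                unmatched_cds.append(row["locus"])
        features.append(
            GeneFeature(
                contig=row["contig"],
                locus_tag=row["locus"],
                start=row["start"],
                end=row["end"],
                strand=row["strand"],
                kind="pseudogene" if row["pseudo"] else "CDS",
                protein_seq=protein,
                inference_accession=inference_acc,
                description=row["description"],
            )
        )

    unmatched_faa = sorted(set(proteins) - used_proteins)
    if unmatched_cds or unmatched_faa:
        raise AnnotationError(
            f"could not reconcile {gff.name} with {faa.name}: "
            f"CDS without protein: {unmatched_cds or 'none'}; "
            f"protein without CDS: {unmatched_faa or 'none'}"
        )

    contigs = _sequence_regions(gff)
    for f in features:
        if f.contig not in contigs:
            contigs[f.contig] = 0
    for f in features:  # fall back to max coordinate when no ##sequence-region
        if contigs[f.contig] < f.end:
            contigs[f.contig] = f.end
    return order_features(assembly_id or gff.stem, contigs, features)


# ---------------------------------------------------------------------------
# GenBank

def parse_genbank(gbk: Path, dialect: str = "genbank", assembly_id: str | None = None) -> Genome:
    """Parse a GenBank flat file into the same :class:`Genome` as the GFF path.

    Translations are taken from the CDS qualifiers; ``pseudo``-flagged CDS
    become pseudogene features without a protein.  Joined (multi-interval)
    CDS collapse to their outer span.  For RASTtk exports the ``db_xref``
    qualifier stands in for missing locus tags.  The nucleotide sequence of
    each record is retained for downstream ncRNA searches.
    """
    gbk = Path(gbk)
    contigs: dict[str, int] = {}
    nt_seqs: dict[str, str] = {}
    features: list[GeneFeature] = []
    counter = 0
    for rec in SeqIO.parse(str(gbk), "genbank"):
        contig = rec.id if rec.id and rec.id != "unknown" else rec.name
        contigs[contig] = len(rec.seq)
        try:
            nt_seqs[contig] = str(rec.seq)
        except Exception:  # contigless records (CONTIG join placeholders)
            pass
        for feat in rec.features:
            if feat.type != "CDS":
                continue
            counter += 1
            quals = feat.qualifiers
            pseudo = "pseudo" in quals or "pseudogene" in quals
            locus = None
            if dialect == "rast_genbank" and "db_xref" in quals:
                # RASTtk identifiers live in db_xref; remap to locus_tag
                locus = quals["db_xref"][0].split(":", 1)[-1]
            locus = locus or (quals.get("locus_tag") or quals.get("protein_id") or [None])[0]
            locus = locus or f"{contig}_cds_{counter}"
            translation = (quals.get("translation") or [None])[0]
            if not pseudo and translation is None:
                if contig in nt_seqs:
                    translation = str(feat.extract(rec.seq).translate(to_stop=True))
                else:
                    log.warning(
                        "skipping CDS %s: no translation and no nucleotide sequence", locus
                    )
                    continue
            inference_acc = None
            for inf in quals.get("inference", []):
                m = _INFERENCE_RE.search(inf)
                if m:
                    inference_acc = m.group(1)
                    break
            if pseudo and inference_acc is None:
                inference_acc = (quals.get("protein_id") or [None])[0]
            features.append(
                GeneFeature(
                    contig=contig,
                    locus_tag=locus,
                    # outer span of possibly compound locations, back to 1-based
                    start=int(feat.location.start) + 1,
                    end=int(feat.location.end),
                    strand="-" if feat.location.strand == -1 else "+",
                    kind="pseudogene" if pseudo else "CDS",
                    protein_seq=None if pseudo else translation,
                    inference_accession=inference_acc,
                    description=(quals.get("product") or [""])[0],
                )
            )
    if not contigs:
        raise AnnotationError(f"{gbk}: no GenBank records found")
    return order_features(assembly_id or gbk.stem, contigs, features, nt_seqs)


# ---------------------------------------------------------------------------
# pseudogene product substitution

def substitute_pseudogenes(genome: Genome, protein_lookup: Mapping[str, str]) -> Genome:
    """Attach inferred full-length proteins to pseudogenes (best effort, idempotent).

    Each pseudogene whose ``inference_accession`` resolves in the lookup gains
    that protein sequence and is flagged ``pseudo_substituted``; coordinates,
    strand and order are untouched.  Pseudogenes that do not resolve stay as
    they are (and remain excluded from HMM search).
    """
    new_features = []
    for f in genome.features:
        if (
            f.kind == "pseudogene"
            and f.inference_accession
            and f.inference_accession in protein_lookup
        ):
            f = replace(
                f,
                protein_seq=protein_lookup[f.inference_accession],
                pseudo_substituted=True,
            )
        new_features.append(f)
    return Genome(
        assembly_id=genome.assembly_id,
        contigs=dict(genome.contigs),
        features=new_features,
        nt_seqs=dict(genome.nt_seqs),
    )


# ---------------------------------------------------------------------------
# gene calling on bare nucleotide input

GeneCaller = Callable[[Path, str, Path, Path], None]


def _prodigal_caller(fna: Path, mode: str, out_gff: Path, out_faa: Path) -> None:
    exe = shutil.which("prodigal")
    if exe is None:
        raise AnnotationError(
            "no gene caller available on PATH (prodigal); provide a pre-annotated "
            "GFF3 + protein FASTA pair or a GenBank file instead"
        )
    cmd = [exe, "-i", str(fna), "-f", "gff", "-o", str(out_gff), "-a", str(out_faa)]
    if mode == "meta":
        cmd += ["-p", "meta"]
    subprocess.run(cmd, check=True, capture_output=True)


def call_genes(
    fna: Path,
    workdir: Path,
    caller: GeneCaller | None = None,
    assembly_id: str | None = None,
) -> tuple[Genome, str]:
    """Run an external gene caller on a nucleotide FASTA and parse the result.

    Inputs longer than 100 kb in total are called in single-genome mode;
    shorter sequences (plasmids, contig bins) use the short/metagenomic mode,
    where the caller's species-specific training would otherwise mislead.
    Returns the parsed genome and the mode used.
    """
    fna, workdir = Path(fna), Path(workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    total = sum(len(rec.seq) for rec in SeqIO.parse(str(fna), "fasta"))
    mode = "single" if total > GENE_CALLER_SINGLE_MODE_MIN_LENGTH else "meta"
    out_gff, out_faa = workdir / f"{fna.stem}.gff", workdir / f"{fna.stem}.faa"
    (caller or _prodigal_caller)(fna, mode, out_gff, out_faa)
    genome = parse_gff_faa(
        out_gff, out_faa, dialect="prodigal_gff_faa", assembly_id=assembly_id or fna.stem
    )
    genome.nt_seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(fna), "fasta")}
    return genome, mode
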