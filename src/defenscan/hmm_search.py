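"""Profile-HMM search and hit filtering.

Candidate defence genes are found by searching every protein in the genome
(CDS and substituted pseudogenes) against the database's profile HMMs, either
in process (pyhmmer) or by ingesting a pre-computed HMMER3 per-domain table.
Each (protein, HMM) pair is reduced to its best domain, annotated with the
full-sequence E-value, the domain's independent E-value, and the fractions of
the target protein and of the HMM covered by the domain alignment.  Hits are
then filtered against inclusive thresholds — an E-value ceiling applied to
both E-values and floors on both coverages — with per-HMM thresholds from the
metadata table overriding the global defaults.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable

import pyhmmer
from Bio import SearchIO

from .annotation_io import Genome
from .config import FilterThresholds
from .model_db import HmmMeta

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class HmmHit:
    """Best-domain summary of one HMM-vs-protein match."""

    target_name: str
    hmm_accession: str
    hmm_name: str
    full_seq_evalue: float
    domain_ievalue: float
    bit_score: float
    target_len: int
    hmm_len: int
    ali_target_from: int  # 1-based inclusive alignment bounds
    ali_target_to: int
    ali_hmm_from: int
    ali_hmm_to: int
    protein_family: str | None = None  # joined from HmmMeta during filtering

    def __post_init__(self) -> None:
        if not (1 <= self.ali_target_from <= self.ali_target_to <= self.target_len):
            raise ValueError(
                f"hit {self.target_name}/{self.hmm_accession}: target alignment bounds "
                f"{self.ali_target_from}..{self.ali_target_to} outside 1..{self.target_len}"
            )
        if not (1 <= self.ali_hmm_from <= self.ali_hmm_to <= self.hmm_len):
            raise ValueError(
                f"hit {self.target_name}/{self.hmm_accession}: HMM alignment bounds "
                f"{self.ali_hmm_from}..{self.ali_hmm_to} outside 1..{self.hmm_len}"
            )
        if self.full_seq_evalue < 0 or self.domain_ievalue < 0:
            raise ValueError("E-values must be non-negative")

    @property
    def target_coverage(self) -> float:
        return (self.ali_target_to - self.ali_target_from + 1) / self.target_len

    @property
    def hmm_coverage(self) -> float:
        return (self.ali_hmm_to - self.ali_hmm_from + 1) / self.hmm_len


def _best_per_pair(hits: Iterable[HmmHit]) -> list[HmmHit]:
    """Reduce to one hit per (target, HMM): best domain by i-E-value, then bit score."""
    best: dict[tuple[str, str], HmmHit] = {}
    for h in hits:
        key = (h.target_name, h.hmm_accession)
        cur = best.get(key)
        if cur is None or (h.domain_ievalue, -h.bit_score) < (cur.domain_ievalue, -cur.bit_score):
            best[key] = h
    return sorted(best.values(), key=lambda h: (h.target_name, h.hmm_accession))


def search_proteins(genome: Genome, hmm_path: Path, cpus: int = 1) -> list[HmmHit]:
    """Search every searchable protein against the profile set, in process.

    Only features carrying a protein sequence are searched (CDS, plus
    pseudogenes after product substitution).  Returns best-domain hits in
    deterministic (target, accession) order; an empty protein set yields an
    empty list.
    """
    alphabet = pyhmmer.easel.Alphabet.amino()
    targets = [
        pyhmmer.easel.TextSequence(name=f.locus_tag.encode(), sequence=f.protein_seq).digitize(
            alphabet
        )
        for f in genome.features
        if f.searchable
    ]
    if not targets:
        return []
    with pyhmmer.plan7.HMMFile(str(hmm_path)) as hmm_file:
        hmms = list(hmm_file)
    hits: list[HmmHit] = []
    def _text(value: bytes | str | None) -> str | None:
        return value.decode() if isinstance(value, bytes) else value

    for top_hits in pyhmmer.hmmsearch(hmms, targets, cpus=cpus):
        query = top_hits.query
        accession = _text(query.accession) or _text(query.name)
        hmm_name = _text(query.name)
        for hit in top_hits:
            for dom in hit.domains.reported:
                ali = dom.alignment
                hits.append(
                    HmmHit(
                        target_name=_text(hit.name),
                        hmm_accession=accession,
                        hmm_name=hmm_name,
                        full_seq_evalue=hit.evalue,
                        domain_ievalue=dom.i_evalue,
                        bit_score=dom.score,
                        target_len=ali.target_length,
                        hmm_len=ali.hmm_length,
                        ali_target_from=ali.target_from,
                        ali_target_to=ali.target_to,
                        ali_hmm_from=ali.hmm_from,
                        ali_hmm_to=ali.hmm_to,
                    )
                )
    return _best_per_pair(hits)


def parse_domtbl(path: Path) -> list[HmmHit]:
    """Parse HMMER3 per-domain tabular output (``--domtblout``) into hits.

    Comment lines are tolerated; each (target, HMM) pair is reduced to its
    best domain.  Malformed rows raise an error naming the line.
    """
    path = Path(path)
    _prevalidate_domtbl(path)
    hits: list[HmmHit] = []
    for qresult in SearchIO.parse(str(path), "hmmsearch3-domtab"):
        accession = qresult.accession if qresult.accession not in (None, "-") else qresult.id
        for hit in qresult:
            for hsp in hit:
                hits.append(
                    HmmHit(
                        target_name=hit.id,
                        hmm_accession=accession,
                        hmm_name=qresult.id,
                        full_seq_evalue=float(hit.evalue),
                        domain_ievalue=float(hsp.evalue),
                        bit_score=float(hsp.bitscore),
                        target_len=int(hit.seq_len),
                        hmm_len=int(qresult.seq_len),
                        # SearchIO uses 0-based half-open; back to 1-based inclusive
                        ali_target_from=int(hsp.hit_start) + 1,
                        ali_target_to=int(hsp.hit_end),
                        ali_hmm_from=int(hsp.query_start) + 1,
                        ali_hmm_to=int(hsp.query_end),
                    )
                )
    return _best_per_pair(hits)


def _prevalidate_domtbl(path: Path) -> None:
    for lineno, ln in enumerate(path.read_text().splitlines(), start=1):
        if not ln.strip() or ln.startswith("#"):
            continue
        fields = ln.split()
        if len(fields) < 23:
            raise ValueError(
                f"{path}, line {lineno}: expected >= 23 whitespace-separated "
                f"per-domain columns, found {len(fields)}"
            )


def effective_thresholds(
    accession: str, meta: dict[str, HmmMeta], defaults: FilterThresholds
) -> FilterThresholds:
    """Thresholds in force for one HMM: per-HMM metadata overrides the defaults."""
    m = meta.get(accession)
    if m is None:
        return defaults
    return FilterThresholds(
        evalue_max=m.evalue_max if m.evalue_max is not None else defaults.evalue_max,
        target_cov_min=(
            m.target_cov_min if m.target_cov_min is not None else defaults.target_cov_min
        ),
        hmm_cov_min=m.hmm_cov_min if m.hmm_cov_min is not None else defaults.hmm_cov_min,
    )


def passes(hit: HmmHit, thresholds: FilterThresholds) -> bool:
    """The retention predicate: both E-values under the ceiling, both coverages
    over the floor (all comparisons inclusive)."""
    return (
        hit.full_seq_evalue <= thresholds.evalue_max
        and hit.domain_ievalue <= thresholds.evalue_max
        and hit.target_coverage >= thresholds.target_cov_min
        and hit.hmm_coverage >= thresholds.hmm_cov_min
    )


def filter_hits(
    hits: list[HmmHit],
    meta: dict[str, HmmMeta],
    defaults: FilterThresholds | None = None,
) -> list[HmmHit]:
    """Drop low-confidence hits and join each survivor to its protein family.

    Hits whose accession is absent from the metadata table cannot be mapped
    to a family and are dropped with a warning.  The output is a subset of
    the input, order preserved, with ``protein_family`` filled in.
    """
    defaults = defaults or FilterThresholds()
    kept: list[HmmHit] = []
    for hit in hits:
        m = meta.get(hit.hmm_accession)
        if m is None:
            log.warning(
                "dropping hit %s/%s: accession not in HMM metadata",
                hit.target_name,
                hit.hmm_accession,
            )
            continue
        if passes(hit, effective_thresholds(hit.hmm_accession, meta, defaults)):
            kept.append(replace(hit, protein_family=m.protein_family))
    return kept
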