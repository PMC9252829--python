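"""The detection core: family labelling, candidate clusters, quorum rules.

Filtered HMM hits label genome features with the protein families they
evidence (one best hit per feature per family); non-coding features carry
their fixed token.  For each system-definition model, maximal runs of
features carrying any of the model's families are built along each contig,
allowing up to ``maximum_separation`` intervening unrelated genes between
consecutive members, and each run is judged:

* a run containing any prohibited family is rejected outright;
* a run with fewer distinct core families than ``minimum_core``, or fewer
  distinct member families than ``minimum_total``, fails quorum;
* otherwise the run is reported as a system call.

Relaxed ``_other`` models are evaluated alongside the canonical definitions;
an ``_other`` call is suppressed only when its members are a subset of an
accepted canonical call of the same system family, so fragmented or divergent
systems stay visible without duplicating clean canonical calls.  Overlapping
calls across different families are always reported side by side — resolving
those ambiguities is deliberately left to the user.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .annotation_io import GeneFeature, Genome
from .config import DEFAULT_MAX_SEPARATION
from .hmm_search import HmmHit
from .model_db import NONPROTEIN_TOKENS, HmmMeta, SystemModel

log = logging.getLogger(__name__)


@dataclass
class LabelledFeature:
    """A genome feature with the family labels the evidence supports.

    ``labels`` maps family token → best :class:`HmmHit` for protein
    families, or ``None`` for non-coding provenance (ncRNA / CRISPR array
    features, which need no HMM evidence).
    """

    feature: GeneFeature
    labels: dict[str, HmmHit | None] = field(default_factory=dict)

    @property
    def families(self) -> set[str]:
        return set(self.labels)


@dataclass(frozen=True)
class SystemMember:
    """One gene inside an accepted system call."""

    feature: GeneFeature
    family: str
    role: str  # "core" or "accessory"
    hit: HmmHit | None  # None for non-coding members


@dataclass
class SystemCall:
    """One accepted system instance."""

    system_number: int
    model_name: str
    family: str
    contig: str
    members: list[SystemMember]
    is_other: bool = False

    @property
    def span(self) -> tuple[int, int]:
        return (
            min(m.feature.start for m in self.members),
            max(m.feature.end for m in self.members),
        )

    @property
    def member_loci(self) -> frozenset[str]:
        return frozenset(m.feature.locus_tag for m in self.members)


@dataclass(frozen=True)
class Rejection:
    """A candidate run that failed a model, with the reason."""

    model_name: str
    contig: str
    reason: str  # "prohibited" or "quorum"
    loci: tuple[str, ...]


def assign_labels(
    genome: Genome, hits: Sequence[HmmHit], meta: dict[str, HmmMeta] | None = None
) -> list[LabelledFeature]:
    """Turn filtered hits into per-feature family labels.

    Every genome feature is carried through (unlabelled features are needed
    for gap counting).  Per (feature, family) only the best hit is kept:
    lowest domain i-E-value, ties by bit score descending, then accession.
    Hits naming an unknown locus tag are an error; hits on features without
    a protein sequence (unsubstituted pseudogenes are never searched, so any
    such hit is stale evidence) are ignored.
    """
    by_locus = {f.locus_tag: f for f in genome.features}
    labelled = {f.locus_tag: LabelledFeature(feature=f) for f in genome.features}
    for lf in labelled.values():
        if lf.feature.kind in NONPROTEIN_TOKENS:
            lf.labels[lf.feature.kind] = None
    for hit in hits:
        feature = by_locus.get(hit.target_name)
        if feature is None:
            raise ValueError(f"hit references unknown locus_tag {hit.target_name!r}")
        if not feature.searchable:
            log.debug("ignoring hit on protein-less feature %s", feature.locus_tag)
            continue
        family = hit.protein_family
        if family is None:
            raise ValueError(
                f"hit {hit.target_name}/{hit.hmm_accession} has no protein_family; "
                "filter_hits must run first"
            )
        cur = labelled[hit.target_name].labels.get(family)
        if cur is None or _hit_rank(hit) < _hit_rank(cur):
            labelled[hit.target_name].labels[family] = hit
    return [labelled[f.locus_tag] for f in genome.features]


def _hit_rank(hit: HmmHit) -> tuple[float, float, str]:
    return (hit.domain_ievalue, -hit.bit_score, hit.hmm_accession)


def find_runs(
    labelled: Sequence[LabelledFeature],
    model: SystemModel,
    max_separation_default: int = DEFAULT_MAX_SEPARATION,
) -> list[list[LabelledFeature]]:
    """Maximal colocalized runs of features relevant to one model.

    A feature is relevant when it carries any of the model's core, accessory
    or prohibited families.  Consecutive run members may be separated by at
    most the model's maximum separation in irrelevant features; runs never
    span contigs.  Separation is counted in annotated genes (including
    merged non-coding features), not base pairs.
    """
    sep = model.separation(max_separation_default)
    relevant = model.relevant_families
    runs: list[list[LabelledFeature]] = []
    by_contig: dict[str, list[LabelledFeature]] = {}
    for lf in labelled:
        by_contig.setdefault(lf.feature.contig, []).append(lf)
    for contig_feats in by_contig.values():
        contig_feats.sort(key=lambda lf: lf.feature.order_index)
        current: list[LabelledFeature] = []
        for lf in contig_feats:
            if not (lf.families & relevant):
                continue
            if current and (
                lf.feature.order_index - current[-1].feature.order_index - 1 > sep
            ):
                runs.append(current)
                current = []
            current.append(lf)
        if current:
            runs.append(current)
    return runs


def evaluate_run(
    run: Sequence[LabelledFeature], model: SystemModel
) -> SystemCall | Rejection:
    """Judge one candidate run against one model.

    Prohibition is checked first, over the whole run; then quorum.  Within a
    model each feature contributes exactly one family — its best-scoring
    among the model's member families — so duplicated genes never double
    count toward quorum.
    """
    loci = tuple(lf.feature.locus_tag for lf in run)
    prohibited = set(model.prohibited_families)
    if any(lf.families & prohibited for lf in run):
        return Rejection(model.name, run[0].feature.contig, "prohibited", loci)

    members: list[SystemMember] = []
    core = set(model.core_families)
    member_fams = model.member_families
    for lf in run:
        candidates = [
            (fam, hit) for fam, hit in lf.labels.items() if fam in member_fams
        ]
        if not candidates:
            continue
        # best-scoring family for this feature under this model; non-coding
        # tokens carry no score and win only when they are the sole candidate
        fam, hit = min(
            candidates,
            key=lambda fh: _hit_rank(fh[1]) if fh[1] is not None else (float("inf"), 0.0, ""),
        )
        members.append(
            SystemMember(
                feature=lf.feature,
                family=fam,
                role="core" if fam in core else "accessory",
                hit=hit,
            )
        )
    distinct_core = {m.family for m in members if m.role == "core"}
    distinct_all = {m.family for m in members}
    if len(distinct_core) < model.minimum_core or len(distinct_all) < model.minimum_total:
        return Rejection(model.name, run[0].feature.contig, "quorum", loci)
    return SystemCall(
        system_number=-1,
        model_name=model.name,
        family=model.family,
        contig=run[0].feature.contig,
        members=members,
        is_other=model.is_other,
    )


def detect_systems(
    genome: Genome,
    hits: Sequence[HmmHit],
    models: Iterable[SystemModel],
    meta: dict[str, HmmMeta] | None = None,
    max_separation_default: int = DEFAULT_MAX_SEPARATION,
    collect_rejections: list[Rejection] | None = None,
) -> list[SystemCall]:
    """Run every model against the genome and number the accepted calls.

    ``_other`` calls whose member set is a subset of an accepted canonical
    call of the same family are suppressed; everything else — including
    overlapping calls from different families — is reported.  Calls are
    numbered in (contig order, span start, model name) order, so identical
    inputs always yield an identical call list.
    """
    labelled = assign_labels(genome, hits, meta)
    accepted: list[SystemCall] = []
    for model in sorted(models, key=lambda m: m.name):
        for run in find_runs(labelled, model, max_separation_default):
            verdict = evaluate_run(run, model)
            if isinstance(verdict, SystemCall):
                accepted.append(verdict)
            elif collect_rejections is not None:
                collect_rejections.append(verdict)

    canonical = [c for c in accepted if not c.is_other]
    kept: list[SystemCall] = []
    for call in accepted:
        if call.is_other and any(
            c.family == call.family
            and c.contig == call.contig
            and call.member_loci <= c.member_loci
            for c in canonical
        ):
            continue
        kept.append(call)

    contig_rank = {name: i for i, name in enumerate(genome.contigs)}
    kept.sort(key=lambda c: (contig_rank.get(c.contig, 0), c.span[0], c.model_name))
    for i, call in enumerate(kept, start=1):
        call.system_number = i
    return kept
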