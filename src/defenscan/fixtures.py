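"""Deterministic toy model database and synthetic genomes with planted systems.

Nothing here aims at biologically realistic sequence composition; the goal
is a fully self-contained test bed.  The demo database holds nine
system-definition models transcribed from well-characterised defence
systems (DISARM types I/II and its relaxed catch-all, Wadjet, a retron with
its msr-msd ncRNA, a single-gene nuclease, a phosphorothioation catch-all,
and a CRISPR-adaptation catch-all referencing a CRISPR array), with one toy
profile HMM per protein family built from mutated copies of a fixed random
seed sequence.

Planted genomes are described by a :class:`GenomePlan` — operons (optionally
with omissions or extra genes), pseudogene fragments carrying an inference
accession, ncRNA elements, CRISPR arrays and decoy genes — and are written
out in every format the pipeline reads: GFF3 + protein FASTA + nucleotide
FASTA, a fabricated HMMER3 per-domain table (so the pipeline is testable
without a search engine), a cmsearch table, a CRISPR GFF, an
inferred-protein lookup FASTA, and a truth table of the calls the plan
expects.  Identical (plan, seed) always yields byte-identical files.

Planted proteins are point-mutated copies of the family seed (default 5%
substitution rate) so that the real HMM engine scores them strongly but not
identically; fabricated E-values are drawn log-uniformly from a strong band
for planted genes and a weak, sub-threshold band for decoy noise.
"""

from __future__ import annotations

import datetime
import random
from dataclasses import dataclass, field
from pathlib import Path

import pyhmmer

AA = "ACDEFGHIKLMNPQRSTVWY"

#: Protein length (residues) per toy family.
FAMILY_LENGTHS: dict[str, int] = {
    "DrmA": 300, "DrmB": 280, "DrmC": 200, "DrmD": 320, "DrmMI": 250,
    "DrmMII": 250, "DrmE": 220,
    "JetA": 260, "JetB": 180, "JetC": 340, "JetD": 200,
    "RT": 280, "NucA": 230, "Cas1": 210,
    "DndC": 190, "DndD": 210, "PbeA": 160, "PbeB": 150,
}

#: Demo system definitions: name -> (family, core, accessory, prohibited,
#: minimum_core, minimum_total).  -1 means "use the schema default".
MODEL_DEFS: dict[str, tuple[str, list[str], list[str], list[str], int, int]] = {
    "DISARM_I": ("DISARM", ["DrmA", "DrmB", "DrmC", "DrmD", "DrmMI"], [], ["DrmE"], 5, 5),
    "DISARM_II": ("DISARM", ["DrmA", "DrmB", "DrmC", "DrmE", "DrmMII"], [], [], 5, 5),
    "DISARM_other": (
        "DISARM",
        ["DrmA", "DrmB", "DrmC", "DrmD", "DrmMI", "DrmE", "DrmMII"],
        [], [], 2, 2,
    ),
    "wadjet_I": ("wadjet", ["JetA", "JetB", "JetC", "JetD"], [], [], 4, 4),
    "wadjet_other": ("wadjet", ["JetA", "JetB", "JetC", "JetD"], [], [], 2, 2),
    "retron": ("retron", ["RT", "ncRNA"], [], [], 2, 2),
    "nuc_single": ("nuc_single", ["NucA"], [], [], 1, 1),
    "PT_other": ("PT", ["DndC", "DndD", "PbeA", "PbeB"], [], [], 2, 2),
    "cas_adaptation_other": ("cas_adaptation", ["Cas1", "CRISPR_array"], [], [], 2, 2),
}

#: HMMs shipped with the demo DB: (hmm_name, family). RT gets two clades to
#: exercise families evidenced by several HMMs.
HMM_DEFS: list[tuple[str, str]] = sorted(
    [(f"{fam}_seed", fam) for fam in FAMILY_LENGTHS if fam != "RT"]
    + [("RT_clade1", "RT"), ("RT_clade2", "RT")]
)

#: Stricter per-HMM thresholds for the single-gene system (single-gene
#: detection trades sensitivity for specificity).
PER_HMM_THRESHOLDS: dict[str, tuple[float, float, float]] = {
    "NucA_seed": (1e-10, 0.8, 0.8),
}


def mutate(seq: str, rate: float, rng: random.Random) -> str:
    return "".join(rng.choice(AA) if rng.random() < rate else c for c in seq)


def family_seed(family: str) -> str:
    """Fixed seed protein for a family (stable across runs and machines)."""
    if family == "DrmMII":
        # paralogous methyltransferases: DrmMII diverges ~18% from DrmMI, so
        # their HMMs cross-match, mirroring real shared-domain ambiguity
        rng = random.Random("defenscan::DrmMII::paralog")
        return mutate(family_seed("DrmMI"), 0.18, rng)
    rng = random.Random(f"defenscan::{family}")
    return "".join(rng.choice(AA) for _ in range(FAMILY_LENGTHS[family]))


def hmm_accessions() -> dict[str, str]:
    """hmm_name -> PLDC accession, assigned in sorted name order."""
    return {name: f"PLDC{i + 1:05d}" for i, (name, _) in enumerate(HMM_DEFS)}


# ---------------------------------------------------------------------------
# toy database

def _model_yaml(name: str) -> str:
    family, core, acc, proh, min_core, min_total = MODEL_DEFS[name]
    lines = [f"family: {family}", "core: [" + ", ".join(core) + "]"]
    if acc:
        lines.append("accessory: [" + ", ".join(acc) + "]")
    if proh:
        lines.append("prohibited: [" + ", ".join(proh) + "]")
    if min_core >= 0:
        lines.append(f"minimum_core: {min_core}")
    if min_total >= 0:
        lines.append(f"minimum_total: {min_total}")
    return "\n".join(lines) + "\n"


def make_toy_db(db_dir: Path, n_align: int = 10, mutation_rate: float = 0.05) -> tuple[int, int]:
    """Write the demo model database; returns (model count, HMM count).

    Each toy HMM is built from ``n_align`` point-mutated copies of the
    family seed sequence.  Regeneration is byte-identical.
    """
    db_dir = Path(db_dir)
    (db_dir / "sys").mkdir(parents=True, exist_ok=True)
    (db_dir / "hmm").mkdir(parents=True, exist_ok=True)
    for name in MODEL_DEFS:
        (db_dir / "sys" / f"{name}.yaml").write_text(_model_yaml(name))

    accs = hmm_accessions()
    alphabet = pyhmmer.easel.Alphabet.amino()
    builder = pyhmmer.plan7.Builder(alphabet)
    background = pyhmmer.plan7.Background(alphabet)
    with open(db_dir / "hmm" / "profiles.hmm", "wb") as handle:
        for hmm_name, fam in HMM_DEFS:
            rng = random.Random(f"defenscan::msa::{hmm_name}")
            seed = family_seed(fam)
            if hmm_name == "RT_clade2":  # second clade: a diverged copy
                seed = mutate(seed, 0.15, rng)
            seqs = [
                pyhmmer.easel.TextSequence(
                    name=f"{hmm_name}_{i}".encode(), sequence=mutate(seed, mutation_rate, rng)
                )
                for i in range(n_align)
            ]
            msa = pyhmmer.easel.TextMSA(name=hmm_name.encode(), sequences=seqs)
            hmm, _, _ = builder.build_msa(msa.digitize(alphabet), background)
            hmm.accession = accs[hmm_name].encode()
            # pin the DATE header line so regeneration is byte-identical
            hmm.creation_time = datetime.datetime(2024, 1, 1, 0, 0, 0)
            hmm.write(handle)

    rows = ["\t".join(
        ["accession", "original.name", "protein.family", "e.val.threshold",
         "target.coverage.threshold", "hmm.coverage.threshold", "citation"]
    )]
    for hmm_name, fam in HMM_DEFS:
        ev, tc, hc = PER_HMM_THRESHOLDS.get(hmm_name, (None, None, None))
        rows.append("\t".join([
            accs[hmm_name], hmm_name, fam,
            "" if ev is None else f"{ev:g}",
            "" if tc is None else f"{tc:g}",
            "" if hc is None else f"{hc:g}",
            "synthetic demo profile",
        ]))
    (db_dir / "hmm_meta.txt").write_text("\n".join(rows) + "\n")
    return len(MODEL_DEFS), len(HMM_DEFS)


# ---------------------------------------------------------------------------
# genome plans

@dataclass(frozen=True)
class Gene:
    family: str


@dataclass(frozen=True)
class Operon:
    model: str
    omit: tuple[str, ...] = ()
    extra: tuple[str, ...] = ()

    def families(self) -> list[str]:
        core = MODEL_DEFS[self.model][1]
        fams = [f for f in core if f not in self.omit and f != "ncRNA"]
        return fams + list(self.extra)


@dataclass(frozen=True)
class Pseudo:
    """A pseudogene (optionally split into pieces) with an inference accession."""

    family: str
    accession: str
    pieces: int = 2


@dataclass(frozen=True)
class Ncrna:
    cm_name: str = "msr_msd_1"
    evalue: float = 1e-6


@dataclass(frozen=True)
class Crispr:
    repeats: int = 5


@dataclass(frozen=True)
class Decoys:
    n: int


PlanElement = Gene | Operon | Pseudo | Ncrna | Crispr | Decoys


@dataclass(frozen=True)
class ContigPlan:
    name: str
    elements: tuple[PlanElement, ...]


@dataclass(frozen=True)
class TruthRow:
    phase: str  # "default" or "pre_substitution"
    contig: str
    model: str
    n_members: int


@dataclass(frozen=True)
class GenomePlan:
    assembly_id: str
    seed: int
    contigs: tuple[ContigPlan, ...]
    truth: tuple[TruthRow, ...] = ()


@dataclass
class FixtureSet:
    """Paths of everything one plan wrote, plus its truth table."""

    plan: GenomePlan
    gff: Path
    faa: Path
    fna: Path
    domtbl: Path
    cmsearch: Path
    crispr_gff: Path
    protein_lookup: Path
    truth_csv: Path


# internal record of one planted feature during generation
@dataclass
class _Planted:
    contig: str
    locus: str
    start: int
    end: int
    strand: str
    family: str | None  # None for decoys
    protein: str | None
    pseudo: bool = False
    inference: str | None = None
    substituted_protein: str | None = None  # full protein behind a pseudogene


def _fabricate_strong(rng: random.Random) -> tuple[float, float, float]:
    full = 10.0 ** -rng.uniform(20.0, 60.0)
    ie = full * (10.0 ** rng.uniform(0.0, 1.0))
    bits = rng.uniform(100.0, 500.0)
    return full, ie, bits


def _fabricate_weak(rng: random.Random) -> tuple[float, float, float]:
    full = 10.0 ** rng.uniform(-4.0, 0.0)
    ie = min(1.0, full * (10.0 ** rng.uniform(0.0, 1.0)))
    bits = rng.uniform(5.0, 15.0)
    return full, ie, bits


def make_genome(plan: GenomePlan, outdir: Path) -> FixtureSet:
    """Write every input file for one plan (deterministic in (plan, seed))."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    names = [c.name for c in plan.contigs]
    if len(set(names)) != len(names):
        raise ValueError(f"plan {plan.assembly_id!r}: duplicate contig names {names}")
    rng = random.Random(plan.seed)
    planted: list[_Planted] = []
    ncrna_rows: list[tuple[str, int, int, str, float]] = []
    crispr_rows: list[tuple[str, int, int, int]] = []
    contig_lengths: dict[str, int] = {}
    lookup: dict[str, str] = {}

    for contig in plan.contigs:
        pos = 501
        idx = 0

        def _next_locus() -> str:
            nonlocal idx
            idx += 1
            return f"{contig.name}_{idx:04d}"

        def _plant_protein_gene(family: str | None) -> None:
            nonlocal pos
            if family is None:
                length = rng.randint(120, 300)
                protein = "".join(rng.choice(AA) for _ in range(length))
            else:
                protein = mutate(family_seed(family), 0.05, rng)
                length = len(protein)
            start, end = pos, pos + 3 * length + 2
            planted.append(
                _Planted(
                    contig=contig.name, locus=_next_locus(), start=start, end=end,
                    strand=rng.choice("++-"), family=family, protein=protein,
                )
            )
            pos = end + rng.randint(80, 250)

        for element in contig.elements:
            if isinstance(element, Gene):
                _plant_protein_gene(element.family)
            elif isinstance(element, Operon):
                for fam in element.families():
                    _plant_protein_gene(fam)
            elif isinstance(element, Decoys):
                for _ in range(element.n):
                    _plant_protein_gene(None)
            elif isinstance(element, Pseudo):
                protein = mutate(family_seed(element.family), 0.05, rng)
                lookup[element.accession] = protein
                total_nt = 3 * len(protein) + 2
                piece_nt = total_nt // element.pieces
                for p in range(element.pieces):
                    start = pos + p * (piece_nt + 50)
                    end = start + piece_nt - 1
                    planted.append(
                        _Planted(
                            contig=contig.name, locus=_next_locus(), start=start, end=end,
                            strand="+", family=element.family, protein=None, pseudo=True,
                            inference=element.accession, substituted_protein=protein,
                        )
                    )
                pos = planted[-1].end + rng.randint(80, 250)
            elif isinstance(element, Ncrna):
                start, end = pos, pos + 159
                ncrna_rows.append((contig.name, start, end, element.cm_name, element.evalue))
                pos = end + rng.randint(80, 250)
            elif isinstance(element, Crispr):
                start, end = pos, pos + 299
                crispr_rows.append((contig.name, start, end, element.repeats))
                pos = end + rng.randint(80, 250)
            else:  # pragma: no cover
                raise ValueError(f"unknown plan element {element!r}")
        contig_lengths[contig.name] = pos + 500

    paths = FixtureSet(
        plan=plan,
        gff=outdir / f"{plan.assembly_id}.gff",
        faa=outdir / f"{plan.assembly_id}.faa",
        fna=outdir / f"{plan.assembly_id}.fna",
        domtbl=outdir / f"{plan.assembly_id}.domtbl",
        cmsearch=outdir / f"{plan.assembly_id}_cmsearch.tbl",
        crispr_gff=outdir / f"{plan.assembly_id}_crispr.gff",
        protein_lookup=outdir / f"{plan.assembly_id}_inferred.faa",
        truth_csv=outdir / f"{plan.assembly_id}_truth.csv",
    )
    _write_gff(paths.gff, plan.assembly_id, contig_lengths, planted)
    _write_faa(paths.faa, planted)
    _write_fna(paths.fna, contig_lengths, random.Random(plan.seed ^ 0x5EED))
    _write_domtbl(paths.domtbl, planted, random.Random(plan.seed ^ 0xD0B))
    _write_cmsearch(paths.cmsearch, ncrna_rows)
    _write_crispr_gff(paths.crispr_gff, crispr_rows)
    _write_lookup(paths.protein_lookup, lookup)
    _write_truth(paths.truth_csv, plan.truth)
    return paths


def _write_gff(path: Path, assembly: str, lengths: dict[str, int], planted: list[_Planted]) -> None:
    lines = ["##gff-version 3"]
    for contig, length in lengths.items():
        lines.append(f"##sequence-region {contig} 1 {length}")
    for g in planted:
        if g.pseudo:
            ftype = "pseudogene"
            attrs = (
                f"ID={g.locus};locus_tag={g.locus};pseudo=true;"
                f"inference=COORDINATES: similar to AA sequence:RefSeq:{g.inference};"
                f"product=putative {g.family} pseudogene"
            )
        else:
            desc = g.family or "hypothetical protein"
            attrs = f"ID={g.locus};locus_tag={g.locus};product={desc}"
            ftype = "CDS"
        lines.append(
            "\t".join(
                [g.contig, "defenscan_fixture", ftype, str(g.start), str(g.end),
                 ".", g.strand, "0", attrs]
            )
        )
    path.write_text("\n".join(lines) + "\n")


def _write_faa(path: Path, planted: list[_Planted]) -> None:
    lines = []
    for g in planted:
        if g.protein is None:
            continue  # pseudogene products are absent from the protein FASTA
        lines.append(f">{g.locus} {g.family or 'hypothetical protein'}")
        for i in range(0, len(g.protein), 60):
            lines.append(g.protein[i : i + 60])
    path.write_text("\n".join(lines) + "\n")


def _write_fna(path: Path, lengths: dict[str, int], rng: random.Random) -> None:
    lines = []
    for contig, length in lengths.items():
        lines.append(f">{contig}")
        seq = "".join(rng.choice("ACGT") for _ in range(length))
        for i in range(0, length, 70):
            lines.append(seq[i : i + 70])
    path.write_text("\n".join(lines) + "\n")


_DOMTBL_HEADER = (
    "#                                                                            "
    "--- full sequence --- -------------- this domain -------------   hmm coord   "
    "ali coord   env coord\n"
    "# target name        accession   tlen query name           accession   qlen"
    "   E-value  score  bias   #  of  c-Evalue  i-Evalue  score  bias  from    to"
    "  from    to  from    to  acc description of target\n"
    "#------------------- ---------- ----- -------------------- ---------- -----"
    " --------- ------ ----- --- --- --------- --------- ------ ----- ----- -----"
    " ----- ----- ----- ----- ---- ---------------------\n"
)


def _domtbl_row(
    target: str, tlen: int, hmm_name: str, acc: str, qlen: int,
    full_e: float, ie: float, bits: float,
    ali_from: int, ali_to: int, hmm_from: int, hmm_to: int,
) -> str:
    return (
        f"{target:<20} {'-':<10} {tlen:5d} {hmm_name:<20} {acc:<10} {qlen:5d} "
        f"{full_e:9.2g} {bits:6.1f} {0.0:5.1f} {1:3d} {1:3d} {ie:9.2g} {ie:9.2g} "
        f"{bits:6.1f} {0.0:5.1f} {hmm_from:5d} {hmm_to:5d} {ali_from:5d} {ali_to:5d} "
        f"{ali_from:5d} {ali_to:5d} 0.99 -"
    )


def _write_domtbl(path: Path, planted: list[_Planted], rng: random.Random) -> None:
    accs = hmm_accessions()
    by_family: dict[str, list[tuple[str, str]]] = {}
    for hmm_name, fam in HMM_DEFS:
        by_family.setdefault(fam, []).append((hmm_name, accs[hmm_name]))
    #: fabricated cross-hits between the paralogous methyltransferase families
    cross = {"DrmMI": "DrmMII", "DrmMII": "DrmMI"}

    rows: list[str] = []
    for g in planted:
        protein = g.protein or g.substituted_protein
        if g.family is None:
            # decoy noise: an occasional weak, low-coverage hit that must
            # fail filtering
            if protein is not None and rng.random() < 0.3:
                hmm_name, fam = rng.choice(HMM_DEFS)
                acc = accs[hmm_name]
                qlen = FAMILY_LENGTHS[fam]
                full_e, ie, bits = _fabricate_weak(rng)
                span = max(10, int(0.25 * len(protein)))
                rows.append(
                    _domtbl_row(
                        g.locus, len(protein), hmm_name, acc, qlen, full_e, ie, bits,
                        1, span, 1, max(10, int(0.25 * qlen)),
                    )
                )
            continue
        if protein is None:
            continue
        fams = [g.family] + ([cross[g.family]] if g.family in cross else [])
        for k, fam in enumerate(fams):
            for hmm_name, acc in by_family[fam]:
                qlen = FAMILY_LENGTHS[fam]
                full_e, ie, bits = _fabricate_strong(rng)
                if k > 0:  # cross-hit: clearly weaker, still confidently passing
                    full_e, ie = max(full_e, 1e-15), max(ie, 1e-14)
                    bits /= 2.0
                rows.append(
                    _domtbl_row(
                        g.locus, len(protein), hmm_name, acc, qlen, full_e, ie, bits,
                        1, len(protein), 1, qlen,
                    )
                )
    path.write_text(_DOMTBL_HEADER + "\n".join(rows) + ("\n" if rows else "") + "#\n")


_CMSEARCH_HEADER = (
    "#target name         accession query name           accession mdl mdl from"
    "   mdl to seq from   seq to strand trunc pass   gc  bias  score   E-value inc"
    " description of target\n"
    "#------------------- --------- -------------------- --------- --- --------"
    " -------- -------- -------- ------ ----- ---- ---- ----- ------ --------- ---"
    " ---------------------\n"
)


def _write_cmsearch(path: Path, rows: list[tuple[str, int, int, str, float]]) -> None:
    lines = []
    for contig, start, end, cm_name, evalue in rows:
        lines.append(
            f"{contig:<20} {'-':<9} {cm_name:<20} {'-':<9} {'cm':<3} {1:8d} "
            f"{end - start + 1:8d} {start:8d} {end:8d} {'+':>6} {'no':>5} {1:4d} "
            f"{0.5:4.2f} {0.0:5.1f} {55.2:6.1f} {evalue:9.3g} {'!':>3} -"
        )
    path.write_text(_CMSEARCH_HEADER + "\n".join(lines) + ("\n" if lines else "") + "#\n")


def _write_crispr_gff(path: Path, rows: list[tuple[str, int, int, int]]) -> None:
    lines = ["##gff-version 3"]
    for i, (contig, start, end, repeats) in enumerate(rows, start=1):
        lines.append(
            "\t".join(
                [contig, "crispr_finder", "repeat_region", str(start), str(end),
                 ".", "+", ".", f"ID=array_{i};repeats={repeats};name=CRISPR array"]
            )
        )
    path.write_text("\n".join(lines) + "\n")


def _write_lookup(path: Path, lookup: dict[str, str]) -> None:
    lines = []
    for acc in sorted(lookup):
        lines.append(f">{acc}")
        seq = lookup[acc]
        for i in range(0, len(seq), 60):
            lines.append(seq[i : i + 60])
    path.write_text("\n".join(lines) + ("\n" if lines else ""))


def _write_truth(path: Path, truth: tuple[TruthRow, ...]) -> None:
    lines = ["phase,contig,model,n.members"]
    for row in truth:
        lines.append(f"{row.phase},{row.contig},{row.model},{row.n_members}")
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# shipped plans

def shipped_plans(seed: int = 1) -> dict[str, GenomePlan]:
    """The standard fixture plans, with per-plan seeds derived from ``seed``."""

    def s(i: int) -> int:
        return (seed * 1_000_003 + i) % (2**31)

    plans = {
        "disarm_type_i": GenomePlan(
            assembly_id="disarm_type_i", seed=s(1),
            contigs=(ContigPlan("ctgA", (Decoys(6), Operon("DISARM_I"), Decoys(6))),),
            truth=(TruthRow("default", "ctgA", "DISARM_I", 5),),
        ),
        "disarm_reclass": GenomePlan(
            assembly_id="disarm_reclass", seed=s(2),
            contigs=(
                ContigPlan("ctgA", (Decoys(5), Operon("DISARM_I", extra=("DrmE",)), Decoys(5))),
            ),
            truth=(
                TruthRow("default", "ctgA", "DISARM_II", 5),
                TruthRow("default", "ctgA", "DISARM_other", 6),
            ),
        ),
        "disarm_quorum": GenomePlan(
            assembly_id="disarm_quorum", seed=s(3),
            contigs=(
                ContigPlan("ctgA", (Decoys(5), Operon("DISARM_I", omit=("DrmD",)), Decoys(5))),
            ),
            truth=(TruthRow("default", "ctgA", "DISARM_other", 4),),
        ),
        "wadjet": GenomePlan(
            assembly_id="wadjet", seed=s(4),
            contigs=(ContigPlan("ctgA", (Decoys(5), Operon("wadjet_I"), Decoys(5))),),
            truth=(TruthRow("default", "ctgA", "wadjet_I", 4),),
        ),
        "wadjet_pseudo": GenomePlan(
            assembly_id="wadjet_pseudo", seed=s(5),
            contigs=(
                ContigPlan(
                    "ctgA",
                    (Decoys(4), Gene("JetA"), Gene("JetB"),
                     Pseudo("JetC", "WP_JETC001.1", pieces=2), Gene("JetD"), Decoys(4)),
                ),
            ),
            truth=(
                TruthRow("default", "ctgA", "wadjet_I", 5),
                TruthRow("pre_substitution", "ctgA", "wadjet_other", 3),
            ),
        ),
        "retron": GenomePlan(
            assembly_id="retron", seed=s(6),
            contigs=(ContigPlan("ctgA", (Decoys(4), Gene("RT"), Ncrna(), Decoys(4))),),
            truth=(TruthRow("default", "ctgA", "retron", 2),),
        ),
        "split_contig": GenomePlan(
            assembly_id="split_contig", seed=s(7),
            contigs=(
                ContigPlan("ctgA", (Decoys(4), Gene("JetA"), Gene("JetB"))),
                ContigPlan("ctgB", (Gene("JetC"), Gene("JetD"), Decoys(4))),
            ),
            truth=(
                TruthRow("default", "ctgA", "wadjet_other", 2),
                TruthRow("default", "ctgB", "wadjet_other", 2),
            ),
        ),
        "crispr_cas": GenomePlan(
            assembly_id="crispr_cas", seed=s(8),
            contigs=(ContigPlan("ctgA", (Decoys(4), Gene("Cas1"), Crispr(5), Decoys(4))),),
            truth=(TruthRow("default", "ctgA", "cas_adaptation_other", 2),),
        ),
        "single_gene": GenomePlan(
            assembly_id="single_gene", seed=s(9),
            contigs=(ContigPlan("ctgA", (Decoys(5), Gene("NucA"), Decoys(5))),),
            truth=(TruthRow("default", "ctgA", "nuc_single", 1),),
        ),
        "pt_fragment": GenomePlan(
            assembly_id="pt_fragment", seed=s(10),
            contigs=(ContigPlan("ctgA", (Decoys(4), Gene("DndC"), Gene("DndD"), Decoys(4))),),
            truth=(TruthRow("default", "ctgA", "PT_other", 2),),
        ),
        "decoy_only": GenomePlan(
            assembly_id="decoy_only", seed=s(11),
            contigs=(ContigPlan("ctgA", (Decoys(25),)),),
            truth=(),
        ),
    }
    return plans


def make_all(outdir: Path, seed: int = 1) -> tuple[Path, dict[str, FixtureSet]]:
    """Write the toy DB plus every shipped plan under ``outdir``."""
    outdir = Path(outdir)
    db_dir = outdir / "db"
    make_toy_db(db_dir)
    fixture_sets = {
        name: make_genome(plan, outdir / "genomes" / name)
        for name, plan in shipped_plans(seed).items()
    }
    return db_dir, fixture_sets
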