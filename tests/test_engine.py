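"""Engine unit tests plus the brute-force-oracle equivalence suite."""

import random

import pytest

from defenscan.annotation_io import GeneFeature, order_features
from defenscan.engine import (
    Rejection,
    SystemCall,
    assign_labels,
    detect_systems,
    evaluate_run,
    find_runs,
)
from defenscan.hmm_search import HmmHit
from defenscan.model_db import SystemModel


def mk_hit(target, family, acc="PLDC09999", ie=1e-20, bits=200.0):
    return HmmHit(
        target_name=target, hmm_accession=acc, hmm_name=acc, full_seq_evalue=ie,
        domain_ievalue=ie, bit_score=bits, target_len=100, hmm_len=100,
        ali_target_from=1, ali_target_to=100, ali_hmm_from=1, ali_hmm_to=100,
        protein_family=family,
    )


def genome_with(families, contig="c1", kinds=None):
    """One gene per entry; entry None → unlabelled decoy."""
    feats = []
    for i, fam in enumerate(families):
        kind = (kinds or {}).get(i, "CDS")
        feats.append(
            GeneFeature(
                contig=contig, locus_tag=f"{contig}_g{i}", start=1000 * (i + 1),
                end=1000 * (i + 1) + 500, strand="+", kind=kind,
                protein_seq=None if kind != "CDS" else "M" * 100,
            )
        )
    genome = order_features("t", {contig: 1000 * (len(families) + 2)}, feats)
    hits = [
        mk_hit(f"{contig}_g{i}", fam)
        for i, fam in enumerate(families)
        if fam is not None and (kinds or {}).get(i, "CDS") == "CDS"
    ]
    return genome, hits


DISARM_I = SystemModel(
    name="DISARM_I", family="DISARM",
    core_families=("DrmA", "DrmB", "DrmC", "DrmD", "DrmMI"),
    prohibited_families=("DrmE",), minimum_core=5, minimum_total=5,
)


def test_best_label_per_family_is_order_independent():
    genome, _ = genome_with(["DrmA"])
    strong = mk_hit("c1_g0", "DrmA", acc="PLDC00001", ie=1e-9)
    weak = mk_hit("c1_g0", "DrmA", acc="PLDC00002", ie=1e-4)
    for order in ([strong, weak], [weak, strong]):
        (lf,) = assign_labels(genome, order)
        assert lf.labels["DrmA"].domain_ievalue == pytest.approx(1e-9)


def test_feature_may_carry_labels_for_several_families():
    genome, _ = genome_with(["x"])
    hits = [mk_hit("c1_g0", "DrmC"), mk_hit("c1_g0", "PtuA", acc="PLDC09998")]
    (lf,) = assign_labels(genome, hits)
    assert lf.families == {"DrmC", "PtuA"}


def test_unknown_locus_tag_is_error():
    genome, _ = genome_with(["DrmA"])
    with pytest.raises(ValueError, match="ghost"):
        assign_labels(genome, [mk_hit("ghost", "DrmA")])


def test_hits_on_proteinless_pseudogene_ignored():
    genome, _ = genome_with(["DrmA", None])
    pseudo = GeneFeature(contig="c1", locus_tag="c1_p", start=5000, end=5500,
                         strand="+", kind="pseudogene")
    genome = order_features("t", genome.contigs, [*genome.features, pseudo])
    labelled = assign_labels(genome, [mk_hit("c1_p", "DrmB")])
    assert all("DrmB" not in lf.families for lf in labelled)


def test_runs_split_by_separation():
    model = SystemModel(name="m", family="m", core_families=("A", "B"),
                        minimum_core=1, minimum_total=1, maximum_separation=3)
    # relevant at ranks 0 and 5: gap of 4 unlabelled genes > 3 → two runs
    genome, hits = genome_with(["A", None, None, None, None, "B"])
    runs = find_runs(assign_labels(genome, hits), model)
    assert [[lf.feature.locus_tag for lf in r] for r in runs] == [["c1_g0"], ["c1_g5"]]
    # gap of exactly 3 → one run
    genome, hits = genome_with(["A", None, None, None, "B"])
    runs = find_runs(assign_labels(genome, hits), model)
    assert len(runs) == 1 and len(runs[0]) == 2


def test_runs_never_span_contigs():
    model = SystemModel(name="m", family="m", core_families=("A",),
                        minimum_core=1, maximum_separation=10)
    g1, h1 = genome_with(["A"], contig="c1")
    g2, h2 = genome_with(["A"], contig="c2")
    genome = order_features("t", {**g1.contigs, **g2.contigs},
                            [*g1.features, *g2.features])
    runs = find_runs(assign_labels(genome, h1 + h2), model)
    assert len(runs) == 2


def test_disarm_acceptance_prohibition_and_quorum():
    complete, hits = genome_with(["DrmA", "DrmB", "DrmC", "DrmD", "DrmMI"])
    (run,) = find_runs(assign_labels(complete, hits), DISARM_I)
    verdict = evaluate_run(run, DISARM_I)
    assert isinstance(verdict, SystemCall) and len(verdict.members) == 5

    with_e, hits_e = genome_with(["DrmA", "DrmB", "DrmC", "DrmD", "DrmMI", "DrmE"])
    (run,) = find_runs(assign_labels(with_e, hits_e), DISARM_I)
    verdict = evaluate_run(run, DISARM_I)
    assert isinstance(verdict, Rejection) and verdict.reason == "prohibited"

    missing, hits_m = genome_with(["DrmA", "DrmB", "DrmC", "DrmMI"])
    (run,) = find_runs(assign_labels(missing, hits_m), DISARM_I)
    verdict = evaluate_run(run, DISARM_I)
    assert isinstance(verdict, Rejection) and verdict.reason == "quorum"


def test_quorum_counts_distinct_families_not_copies():
    model = SystemModel(name="m", family="m", core_families=("A", "B"),
                        minimum_core=2, minimum_total=2)
    genome, hits = genome_with(["A", "A", "A"])
    (run,) = find_runs(assign_labels(genome, hits), model)
    assert isinstance(evaluate_run(run, model), Rejection)
    genome, hits = genome_with(["A", "A", "B"])
    (run,) = find_runs(assign_labels(genome, hits), model)
    call = evaluate_run(run, model)
    assert isinstance(call, SystemCall)
    assert len(call.members) == 3  # duplicated copies reported, counted once


def test_other_call_suppressed_only_when_subset_of_same_family():
    canonical = SystemModel(name="wadjet_I", family="wadjet",
                            core_families=("JetA", "JetB", "JetC", "JetD"))
    other = SystemModel(name="wadjet_other", family="wadjet",
                        core_families=("JetA", "JetB", "JetC", "JetD"),
                        minimum_core=2, minimum_total=2)
    cross = SystemModel(name="mok_other", family="mok",
                        core_families=("JetA", "JetB"), minimum_core=2, minimum_total=2)
    genome, hits = genome_with(["JetA", "JetB", "JetC", "JetD"])
    calls = detect_systems(genome, hits, [canonical, other, cross])
    assert sorted(c.model_name for c in calls) == ["mok_other", "wadjet_I"]


def test_calls_numbered_deterministically():
    m1 = SystemModel(name="s1", family="s1", core_families=("A",), minimum_core=1)
    m2 = SystemModel(name="s2", family="s2", core_families=("B",), minimum_core=1)
    genome, hits = genome_with(["B", None, None, None, None, None, "A"])
    calls = detect_systems(genome, hits, [m1, m2])
    assert [(c.system_number, c.model_name) for c in calls] == [(1, "s2"), (2, "s1")]
    again = detect_systems(genome, hits, [m2, m1])
    assert [(c.system_number, c.model_name, c.member_loci) for c in calls] == [
        (c.system_number, c.model_name, c.member_loci) for c in again
    ]


def test_locality_appending_far_features_changes_nothing():
    genome, hits = genome_with(["DrmA", "DrmB", "DrmC", "DrmD", "DrmMI"])
    base = detect_systems(genome, hits, [DISARM_I])
    extended, extra_hits = genome_with(
        ["DrmA", "DrmB", "DrmC", "DrmD", "DrmMI"] + [None] * 10 + ["DrmE"]
    )
    after = detect_systems(extended, extra_hits, [DISARM_I])
    assert [(c.model_name, c.member_loci) for c in base] == [
        (c.model_name, c.member_loci) for c in after
    ]


def test_monotone_rejection_on_core_deletion():
    genome, hits = genome_with(["DrmA", "DrmB", "DrmC", "DrmD", "DrmMI"])
    assert len(detect_systems(genome, hits, [DISARM_I])) == 1
    for drop in range(5):
        pruned = [h for h in hits if h.target_name != f"c1_g{drop}"]
        assert detect_systems(genome, pruned, [DISARM_I]) == []


# ---------------------------------------------------------------------------
# brute-force oracle equivalence

def oracle_calls(labelled, model, sep_default=4):
    """Independent re-derivation of the engine's call set.

    Enumerates every maximal run directly from the definition — for each
    pair of relevant ranks, check chain gaps and non-extendability — then
    applies the prohibition and quorum predicates verbatim.
    """
    sep = model.separation(sep_default)
    by_contig = {}
    for lf in labelled:
        by_contig.setdefault(lf.feature.contig, []).append(lf)
    accepted = []
    for feats in by_contig.values():
        feats = sorted(feats, key=lambda lf: lf.feature.order_index)
        rel = [lf for lf in feats if lf.families & model.relevant_families]
        n = len(rel)
        for i in range(n):
            for j in range(i, n):
                chain = rel[i : j + 1]
                ok = all(
                    chain[k + 1].feature.order_index - chain[k].feature.order_index - 1 <= sep
                    for k in range(len(chain) - 1)
                )
                if not ok:
                    continue
                if i > 0 and chain[0].feature.order_index - rel[i - 1].feature.order_index - 1 <= sep:
                    continue  # extendable left → not maximal
                if j < n - 1 and rel[j + 1].feature.order_index - chain[-1].feature.order_index - 1 <= sep:
                    continue  # extendable right → not maximal
                if any(lf.families & set(model.prohibited_families) for lf in chain):
                    continue
                member_fams = model.member_families
                chosen = []
                for lf in chain:
                    fams = [f for f in lf.families if f in member_fams]
                    if fams:
                        best = min(
                            fams,
                            key=lambda f: (
                                (lf.labels[f].domain_ievalue, -lf.labels[f].bit_score,
                                 lf.labels[f].hmm_accession)
                                if lf.labels[f] is not None
                                else (float("inf"), 0.0, "")
                            ),
                        )
                        chosen.append((lf.feature.locus_tag, best))
                core = {f for _, f in chosen if f in set(model.core_families)}
                allf = {f for _, f in chosen}
                if len(core) >= model.minimum_core and len(allf) >= model.minimum_total:
                    accepted.append(frozenset(l for l, _ in chosen))
    return sorted(accepted, key=sorted)


def _random_case(rng):
    families = ["A", "B", "C", "D", "E", "P"]
    n = rng.randint(1, 30)
    assignment = [rng.choice(families + [None, None, None]) for _ in range(n)]
    genome, hits = genome_with(assignment)
    core = tuple(rng.sample(["A", "B", "C", "D"], rng.randint(1, 4)))
    accessory = ("E",) if rng.random() < 0.5 else ()
    prohibited = ("P",) if rng.random() < 0.5 else ()
    min_core = rng.randint(1, len(core))
    model = SystemModel(
        name="rnd", family="rnd", core_families=core, accessory_families=accessory,
        prohibited_families=prohibited, minimum_core=min_core,
        minimum_total=rng.randint(min_core, min_core + len(accessory)),
        maximum_separation=rng.randint(0, 5),
    )
    return genome, hits, model


def test_engine_matches_bruteforce_oracle_on_random_contigs():
    """200 seeded random ≤30-feature contigs: engine call set == oracle call set."""
    rng = random.Random(20260922)
    for _ in range(200):
        genome, hits, model = _random_case(rng)
        labelled = assign_labels(genome, hits)
        engine = sorted(
            (frozenset(c.member_loci) for run in find_runs(labelled, model)
             if isinstance((c := evaluate_run(run, model)), SystemCall)),
            key=sorted,
        )
        assert engine == oracle_calls(labelled, model), (
            f"divergence for model {model} on "
            f"{[sorted(lf.families) for lf in labelled]}"
        )


def test_accepted_calls_satisfy_model_invariants_independently():
    rng = random.Random(5)
    for _ in range(50):
        genome, hits, model = _random_case(rng)
        for call in detect_systems(genome, hits, [model]):
            core = {m.family for m in call.members if m.role == "core"}
            assert len(core) >= model.minimum_core
            assert len({m.family for m in call.members}) >= model.minimum_total
            ranks = sorted(m.feature.order_index for m in call.members)
            assert all(b - a - 1 <= model.separation(4) for a, b in zip(ranks, ranks[1:]))
            assert not any(
                set(model.prohibited_families) & {m.family for m in call.members}
            )
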