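from pathlib import Path

import pytest
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

from defenscan.annotation_io import (
    AnnotationError,
    call_genes,
    detect_dialect,
    parse_genbank,
    parse_gff_faa,
    substitute_pseudogenes,
)

GFF = """##gff-version 3
##sequence-region chr1 1 10000
chr1\tsrc\tCDS\t100\t399\t.\t+\t0\tID=g1;locus_tag=g1;product=alpha
chr1\tsrc\tCDS\t500\t799\t.\t-\t0\tID=g2;locus_tag=g2;product=beta
chr1\tsrc\tCDS\t900\t1199\t.\t+\t0\tID=g3;locus_tag=g3;product=gamma
"""
FAA = ">g1\nMAAAA\n>g2\nMCCCC\n>g3\nMDDDD\n"


def _pair(tmp_path, gff=GFF, faa=FAA):
    g, f = tmp_path / "a.gff", tmp_path / "a.faa"
    g.write_text(gff)
    f.write_text(faa)
    return g, f


def test_refseq_pair_parses_in_order(tmp_path):
    g, f = _pair(tmp_path)
    genome = parse_gff_faa(g, f)
    assert [x.locus_tag for x in genome.features] == ["g1", "g2", "g3"]
    assert [x.order_index for x in genome.features] == [0, 1, 2]
    assert genome.features[0].protein_seq == "MAAAA"
    assert genome.features[1].strand == "-"
    assert genome.contigs["chr1"] == 10000
    # round-trip: coordinates preserved exactly, 1-based inclusive
    assert (genome.features[0].start, genome.features[0].end) == (100, 399)


def test_unreconciled_protein_listed(tmp_path):
    g, f = _pair(tmp_path, faa=FAA + ">orphan\nMEEEE\n")
    with pytest.raises(AnnotationError, match="orphan"):
        parse_gff_faa(g, f)


def test_cds_without_protein_listed(tmp_path):
    g, f = _pair(tmp_path, faa=">g1\nMAAAA\n>g2\nMCCCC\n")
    with pytest.raises(AnnotationError, match="g3"):
        parse_gff_faa(g, f)


def test_truncated_gff_names_line(tmp_path):
    bad = GFF + "chr1\tsrc\tCDS\t1300\n"
    g, f = _pair(tmp_path, gff=bad)
    with pytest.raises(AnnotationError, match="line 6"):
        parse_gff_faa(g, f)


def test_prodigal_identifiers_reconciled(tmp_path):
    gff = (
        "##gff-version 3\n"
        "# Model Data: Prodigal.v2.6.3\n"
        'ctg\tProdigal_v2.6.3\tCDS\t10\t309\t.\t+\t0\tID=1_1;partial=00\n'
        'ctg\tProdigal_v2.6.3\tCDS\t400\t699\t.\t+\t0\tID=1_2;partial=00\n'
    )
    faa = ">ctg_1 # 10 # 309 # 1\nMAAAA\n>ctg_2 # 400 # 699 # 1\nMCCCC\n"
    g, f = _pair(tmp_path, gff=gff, faa=faa)
    genome = parse_gff_faa(g, f, dialect="prodigal_gff_faa")
    assert [x.locus_tag for x in genome.features] == ["ctg_1", "ctg_2"]
    assert all(x.protein_seq for x in genome.features)


def test_joined_cds_collapses_to_outer_span(tmp_path):
    gff = GFF + (
        "chr1\tsrc\tCDS\t2000\t2200\t.\t+\t0\tID=g4;locus_tag=g4\n"
        "chr1\tsrc\tCDS\t2400\t2600\t.\t+\t0\tID=g4;locus_tag=g4\n"
    )
    g, f = _pair(tmp_path, gff=gff, faa=FAA + ">g4\nMFFFF\n")
    genome = parse_gff_faa(g, f)
    g4 = genome.by_locus()["g4"]
    assert (g4.start, g4.end) == (2000, 2600)


def test_pseudogene_inference_accession_parsed(tmp_path):
    gff = GFF + (
        "chr1\tsrc\tpseudogene\t3000\t3200\t.\t+\t0\t"
        "ID=p1;locus_tag=p1;pseudo=true;"
        "inference=COORDINATES: similar to AA sequence:RefSeq:WP_010649895.1\n"
    )
    g, f = _pair(tmp_path, gff=gff)
    genome = parse_gff_faa(g, f)
    p1 = genome.by_locus()["p1"]
    assert p1.kind == "pseudogene"
    assert p1.protein_seq is None
    assert p1.inference_accession == "WP_010649895.1"


def _toy_genbank(tmp_path, rast=False, pseudo=False, joined=False):
    seq = Seq("ATG" + "GCT" * 99 + "TAA" + "A" * 700)
    rec = SeqRecord(seq, id="ctg1", name="ctg1", description="toy",
                    annotations={"molecule_type": "DNA"})
    q1 = {"translation": ["M" + "A" * 99], "product": ["alpha"]}
    if rast:
        q1["db_xref"] = ["SEED:fig|1.1.peg.1"]
    else:
        q1["locus_tag"] = ["t1"]
    rec.features.append(SeqFeature(SimpleLocation(0, 303, strand=1), type="CDS", qualifiers=q1))
    q2 = {"locus_tag": ["t2"], "translation": ["M" + "C" * 50], "product": ["beta"]}
    if pseudo:
        q2["pseudo"] = [""]
        q2["protein_id"] = ["WP_000001.1"]
    loc = (
        CompoundLocation([SimpleLocation(400, 500, strand=1), SimpleLocation(550, 650, strand=1)])
        if joined
        else SimpleLocation(400, 553, strand=1)
    )
    rec.features.append(SeqFeature(loc, type="CDS", qualifiers=q2))
    path = tmp_path / "toy.gbk"
    SeqIO.write([rec], str(path), "genbank")
    if rast:
        text = path.read_text().replace("toy", "toy rasttk annotation")
        path.write_text(text)
    return path


def test_genbank_two_gene_toy(tmp_path):
    genome = parse_genbank(_toy_genbank(tmp_path))
    assert [f.locus_tag for f in genome.features] == ["t1", "t2"]
    assert genome.features[0].start == 1 and genome.features[0].end == 303
    assert genome.features[0].protein_seq.startswith("MA")
    assert "ctg1" in genome.nt_seqs


def test_genbank_pseudo_cds_has_no_protein(tmp_path):
    genome = parse_genbank(_toy_genbank(tmp_path, pseudo=True))
    t2 = genome.by_locus()["t2"]
    assert t2.kind == "pseudogene"
    assert t2.protein_seq is None
    assert t2.inference_accession == "WP_000001.1"


def test_genbank_joined_cds_outer_span(tmp_path):
    genome = parse_genbank(_toy_genbank(tmp_path, joined=True))
    t2 = genome.by_locus()["t2"]
    assert (t2.start, t2.end) == (401, 650)  # min(start)..max(end), 1-based


def test_genbank_gff_paths_equivalent(tmp_path):
    """The two annotated-input paths normalize to field-identical features."""
    gb = parse_genbank(_toy_genbank(tmp_path))
    gff = (
        "##gff-version 3\n"
        "ctg1\tsrc\tCDS\t1\t303\t.\t+\t0\tID=t1;locus_tag=t1;product=alpha\n"
        "ctg1\tsrc\tCDS\t401\t553\t.\t+\t0\tID=t2;locus_tag=t2;product=beta\n"
    )
    faa = f">t1\n{'M' + 'A' * 99}\n>t2\n{'M' + 'C' * 50}\n"
    g, f = tmp_path / "eq.gff", tmp_path / "eq.faa"
    g.write_text(gff)
    f.write_text(faa)
    gf = parse_gff_faa(g, f)
    for a, b in zip(gb.features, gf.features):
        for attr in ("contig", "locus_tag", "start", "end", "strand", "kind",
                     "protein_seq", "order_index", "description"):
            assert getattr(a, attr) == getattr(b, attr), attr


def test_dialect_detection(tmp_path):
    gbk = _toy_genbank(tmp_path)
    assert detect_dialect([gbk]) == "genbank"
    rast = _toy_genbank(tmp_path / "r", rast=True) if (tmp_path / "r").mkdir() is None else None
    assert detect_dialect([rast]) == "rast_genbank"
    fna = tmp_path / "x.fna"
    fna.write_text(">c1\nACGTACGTACGTACGT\n")
    assert detect_dialect([fna]) == "nucleotide_fasta"
    g, f = _pair(tmp_path)
    assert detect_dialect([g, f]) == "refseq_gff_faa"
    pg = tmp_path / "p.gff"
    pg.write_text("##gff-version 3\n# Prodigal.v2.6.3\nctg\tx\tCDS\t1\t9\t.\t+\t0\tID=1_1\n")
    assert detect_dialect([pg, f]) == "prodigal_gff_faa"
    junk = tmp_path / "junk.txt"
    junk.write_text("hello world\n")
    with pytest.raises(AnnotationError, match="unsupported"):
        detect_dialect([junk])


def test_rast_db_xref_becomes_locus_tag(tmp_path):
    genome = parse_genbank(_toy_genbank(tmp_path, rast=True), dialect="rast_genbank")
    assert genome.features[0].locus_tag == "fig|1.1.peg.1"


def test_substitution_attaches_protein_and_is_idempotent(tmp_path):
    gff = GFF + (
        "chr1\tsrc\tpseudogene\t3000\t3200\t.\t+\t0\tID=p1;pseudo=true;"
        "inference=COORDINATES: similar to AA sequence:RefSeq:WP_1.1\n"
        "chr1\tsrc\tpseudogene\t3500\t3700\t.\t+\t0\tID=p2;pseudo=true\n"
    )
    g, f = _pair(tmp_path, gff=gff)
    genome = parse_gff_faa(g, f)
    sub = substitute_pseudogenes(genome, {"WP_1.1": "MHHHH"})
    p1, p2 = sub.by_locus()["p1"], sub.by_locus()["p2"]
    assert p1.protein_seq == "MHHHH" and p1.pseudo_substituted
    assert p1.display_name == "pseudo_sub_p1"
    assert p2.protein_seq is None and not p2.pseudo_substituted
    assert (p1.start, p1.end, p1.strand) == (3000, 3200, "+")
    again = substitute_pseudogenes(sub, {"WP_1.1": "MHHHH"})
    assert again == sub
    # empty lookup and no pseudogenes are both identity
    assert substitute_pseudogenes(genome, {}) == genome


def test_call_genes_mode_switch_and_stub(tmp_path):
    """>100 kb total → single-genome mode; short input → meta mode."""
    recorded = {}

    def stub(fna, mode, out_gff, out_faa):
        recorded["mode"] = mode
        Path(out_gff).write_text(
            "##gff-version 3\n# Prodigal stub\n"
            + "".join(
                f"c1\tstub\tCDS\t{i * 1000 + 1}\t{i * 1000 + 300}\t.\t+\t0\tID=1_{i + 1}\n"
                for i in range(5)
            )
        )
        Path(out_faa).write_text("".join(f">c1_{i + 1}\nMAAA\n" for i in range(5)))

    long_fna = tmp_path / "long.fna"
    long_fna.write_text(">c1\n" + "ACGT" * 40000 + "\n")
    genome, mode = call_genes(long_fna, tmp_path / "w1", caller=stub)
    assert mode == "single"
    assert len(genome.features) == 5

    short_fna = tmp_path / "short.fna"
    short_fna.write_text(">c1\n" + "ACGT" * 5000 + "\n")
    _, mode = call_genes(short_fna, tmp_path / "w2", caller=stub)
    assert mode == "meta"
    assert recorded["mode"] == "meta"
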