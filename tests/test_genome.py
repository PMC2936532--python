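"""Region partitioning and GFF3/FASTA round-trips."""
import numpy as np
import pytest

from p1bslink.genome import (
    GeneModel,
    REGIONS,
    partition_regions,
    read_annotation,
    write_partitions_bed,
)
from p1bslink.synthetic import SyntheticConfig, generate_genome, write_fasta, write_gff3

from oracles import minus_partition_via_mirror


def _example_gene():
    # tss=5000, ATG at 5200, stop at 7000, tes=7300, one intron 5600-5900
    return GeneModel(
        gene_id="gx",
        chrom="chr1",
        strand="+",
        start=5000,
        end=7300,
        cds_start=5200,
        cds_end=7000,
        exons=((5000, 5600), (5900, 7300)),
    )


def test_plus_strand_partition_worked_example():
    part = partition_regions(_example_gene(), 100_000)
    r = part.regions
    assert r["prox_prom"] == [(4000, 5000)]
    assert r["distal_prom"] == [(2000, 4000)]
    assert r["utr5"] == [(5000, 5200)]
    assert r["intron"] == [(5600, 5900)]
    assert r["cds"] == [(5200, 5600), (5900, 7000)]
    assert r["utr3"] == [(7000, 7300)]
    assert r["downs1"] == [(7300, 8300)]
    assert r["downs2"] == [(8300, 10300)]
    # the transcribed parts tile the transcribed span
    transcribed = sorted(r["utr5"] + r["cds"] + r["intron"] + r["utr3"])
    total = sum(e - s for s, e in transcribed)
    assert total == 7300 - 5000


def test_partition_is_deterministic_and_idempotent():
    g = _example_gene()
    assert partition_regions(g, 100_000).regions == partition_regions(g, 100_000).regions


def test_chromosome_edge_clipping():
    g = GeneModel("ge", "chr1", "+", 500, 1500, None, None, ((500, 1500),))
    part = partition_regions(g, 2000)
    assert part.regions["prox_prom"] == [(0, 500)]
    assert part.regions["distal_prom"] == []  # fully clipped away
    assert part.regions["downs1"] == [(1500, 2000)]
    assert part.regions["downs2"] == []  # starts beyond the chromosome end
    up_len = part.length("distal_prom") + part.length("prox_prom")
    assert up_len == min(3000, g.start)


def test_intronless_fully_coding_gene_has_empty_utrs():
    g = GeneModel("gi", "chr1", "+", 1000, 1900, 1000, 1900, ((1000, 1900),))
    part = partition_regions(g, 10_000)
    assert part.regions["utr5"] == []
    assert part.regions["utr3"] == []
    assert part.regions["intron"] == []
    assert part.regions["cds"] == [(1000, 1900)]


def test_noncoding_gene_transcript_is_all_utr5():
    g = GeneModel("gn", "chr1", "+", 1000, 1900, None, None, ((1000, 1900),))
    part = partition_regions(g, 10_000)
    assert part.regions["utr5"] == [(1000, 1900)]
    assert part.regions["cds"] == []


def test_atg_anchor_moves_promoter_windows():
    part = partition_regions(_example_gene(), 100_000, anchor="atg")
    assert part.regions["prox_prom"] == [(4200, 5200)]
    with pytest.raises(ValueError, match="anchor"):
        partition_regions(_example_gene(), 100_000, anchor="cds")


def test_minus_strand_partition_matches_reverse_complement_oracle():
    """For 100 random synthetic genes on the minus strand, the partition
    must equal the one obtained by mirroring the chromosome, partitioning
    on the plus strand, and mapping coordinates back."""
    cfg = SyntheticConfig(seed=5, n_genes=200, minus_strand_half=True)
    _, genes, _ = generate_genome(cfg)
    L = cfg.required_length()
    minus = [g for g in genes if g.strand == "-"][:100]
    assert len(minus) == 100
    for g in minus:
        part = partition_regions(g, L)
        expected = minus_partition_via_mirror(
            g, L, lambda m, n: partition_regions(m, n), GeneModel
        )
        got = {r: sorted(part.regions[r]) for r in REGIONS}
        assert got == expected


def test_partition_regions_are_disjoint(study):
    part = study.parts[0]
    ivs = part.span()
    assert all(a[1] <= b[0] for a, b in zip(ivs, ivs[1:]))


def test_annotation_round_trip(tmp_path):
    cfg = SyntheticConfig(seed=3, n_genes=25, minus_strand_half=True)
    sequences, genes, _ = generate_genome(cfg)
    fasta = tmp_path / "g.fa"
    gff = tmp_path / "g.gff3"
    write_fasta(sequences, fasta)
    write_gff3(genes, gff)
    ann = read_annotation(str(gff), str(fasta))
    assert len(ann.genes) == 25
    assert ann.rejected == []
    by_id = {g.gene_id: g for g in ann.genes}
    for g in genes:
        got = by_id[g.gene_id]
        assert (got.start, got.end, got.strand) == (g.start, g.end, g.strand)
        assert (got.cds_start, got.cds_end) == (g.cds_start, g.cds_end)
        assert got.exons == g.exons


def test_gene_with_cds_outside_exons_is_rejected(tmp_path):
    fasta = tmp_path / "g.fa"
    write_fasta({"chr1": "ACGT" * 3000}, fasta)
    gff = tmp_path / "bad.gff3"
    gff.write_text(
        "##gff-version 3\n"
        "chr1\tx\tgene\t1001\t2000\t.\t+\t.\tID=gok\n"
        "chr1\tx\tmRNA\t1001\t2000\t.\t+\t.\tID=gok.1;Parent=gok\n"
        "chr1\tx\texon\t1001\t2000\t.\t+\t.\tID=gok.1.e1;Parent=gok.1\n"
        "chr1\tx\tCDS\t1101\t1900\t.\t+\t0\tID=gok.1.c1;Parent=gok.1\n"
        "chr1\tx\tgene\t3001\t4000\t.\t+\t.\tID=gbad\n"
        "chr1\tx\tmRNA\t3001\t4000\t.\t+\t.\tID=gbad.1;Parent=gbad\n"
        "chr1\tx\texon\t3001\t3500\t.\t+\t.\tID=gbad.1.e1;Parent=gbad.1\n"
        "chr1\tx\tCDS\t3101\t3900\t.\t+\t0\tID=gbad.1.c1;Parent=gbad.1\n"
    )
    ann = read_annotation(str(gff), str(fasta))
    assert [g.gene_id for g in ann.genes] == ["gok"]
    assert ann.rejected == ["gbad"]


def test_missing_chromosome_is_hard_error(tmp_path):
    fasta = tmp_path / "g.fa"
    write_fasta({"chr1": "ACGT" * 100}, fasta)
    gff = tmp_path / "g.gff3"
    gff.write_text(
        "##gff-version 3\n"
        "chr9\tx\tgene\t1\t100\t.\t+\t.\tID=g1\n"
    )
    with pytest.raises(ValueError, match="chr9"):
        read_annotation(str(gff), str(fasta))


def test_bed_export_is_half_open(tmp_path):
    part = partition_regions(_example_gene(), 100_000)
    path = tmp_path / "parts.bed"
    write_partitions_bed([part], str(path))
    lines = [l.split("\t") for l in path.read_text().splitlines()]
    assert all(len(l) == 6 for l in lines)
    prox = [l for l in lines if l[3] == "gx:prox_prom"]
    assert prox == [["chr1", "4000", "5000", "gx:prox_prom", "0", "+"]]
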