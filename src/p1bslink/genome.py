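"""Gene models and region partitioning.

Each gene's neighbourhood is split into eight analysis regions: two promoter
windows upstream of the transcription start (distal, 3-1 kb; proximal, 1 kb),
the transcribed parts (5'UTR, CDS, intron, 3'UTR) and two downstream windows
past the transcript end (proximal, 1 kb; distal, 1-3 kb).  All coordinates
are 0-based half-open internally; GFF3 I/O converts from/to 1-based
inclusive.  Partitioning is strand-aware: for a minus-strand gene "upstream"
means larger genomic coordinates.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pyfaidx

logger = logging.getLogger(__name__)

#: canonical ordering of the eight analysis regions (5' to 3')
REGIONS = (
    "distal_prom",
    "prox_prom",
    "utr5",
    "cds",
    "intron",
    "utr3",
    "downs1",
    "downs2",
)

Interval = tuple[int, int]


@dataclass(frozen=True)
class GeneModel:
    """A single (canonical-transcript) gene model.

    ``start``/``end`` delimit the transcribed span, half-open on the forward
    genomic strand regardless of gene strand.  ``cds_start``/``cds_end`` are
    genomic bounds of the coding span; both ``None`` for non-coding genes.
    ``exons`` are non-overlapping, sorted by genomic coordinate.
    """

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    cds_start: int | None
    cds_end: int | None
    exons: tuple[Interval, ...]

    @property
    def tss(self) -> int:
        """Genomic coordinate anchoring the transcription start.

        For a plus-strand gene this is ``start``; for a minus-strand gene it
        is ``end`` (the half-open bound just 5' of the first transcribed
        base), so ``[tss - k, tss)`` / ``[tss, tss + k)`` are the upstream
        windows on + / - strands respectively.
        """
        return self.start if self.strand == "+" else self.end

    @property
    def tes(self) -> int:
        return self.end if self.strand == "+" else self.start

    def validate(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: bad strand {self.strand!r}")
        if self.end <= self.start:
            raise ValueError(f"{self.gene_id}: end <= start")
        if not self.exons:
            raise ValueError(f"{self.gene_id}: no exons")
        prev_end = None
        for s, e in self.exons:
            if e <= s:
                raise ValueError(f"{self.gene_id}: malformed exon [{s},{e})")
            if prev_end is not None and s < prev_end:
                raise ValueError(f"{self.gene_id}: overlapping/unsorted exons")
            prev_end = e
        if self.exons[0][0] != self.start or self.exons[-1][1] != self.end:
            raise ValueError(f"{self.gene_id}: exons do not span transcript")
        if (self.cds_start is None) != (self.cds_end is None):
            raise ValueError(f"{self.gene_id}: half-specified CDS")
        if self.cds_start is not None:
            if self.cds_end <= self.cds_start:
                raise ValueError(f"{self.gene_id}: CDS end <= start")
            # both CDS bounds must fall inside exons of this transcript
            if not (
                _in_exons(self.cds_start, self.exons)
                and _in_exons(self.cds_end - 1, self.exons)
            ):
                raise ValueError(f"{self.gene_id}: CDS outside exon union")


def _in_exons(pos: int, exons: tuple[Interval, ...]) -> bool:
    return any(s <= pos < e for s, e in exons)


@dataclass(frozen=True)
class RegionPartition:
    """The eight labelled region interval lists for one gene (genomic,
    half-open, clipped to the chromosome)."""

    gene_id: str
    chrom: str
    strand: str
    regions: dict[str, list[Interval]] = field(default_factory=dict)

    def length(self, region: str) -> int:
        return sum(e - s for s, e in self.regions[region])

    def span(self) -> list[Interval]:
        """Union of all region intervals (they are mutually disjoint)."""
        ivs = sorted(iv for lst in self.regions.values() for iv in lst)
        return ivs


def _clip(intervals: list[Interval], lo: int, hi: int) -> list[Interval]:
    out = []
    for s, e in intervals:
        s2, e2 = max(s, lo), min(e, hi)
        if e2 > s2:
            out.append((s2, e2))
    return out


def _subtract(span: Interval, holes: list[Interval]) -> list[Interval]:
    """Intervals of ``span`` not covered by the sorted disjoint ``holes``."""
    out = []
    cur = span[0]
    for hs, he in holes:
        if hs > cur:
            out.append((cur, min(hs, span[1])))
        cur = max(cur, he)
        if cur >= span[1]:
            break
    if cur < span[1]:
        out.append((cur, span[1]))
    return [iv for iv in out if iv[1] > iv[0]]


def _intersect(intervals: list[Interval], window: Interval) -> list[Interval]:
    out = []
    for s, e in intervals:
        s2, e2 = max(s, window[0]), min(e, window[1])
        if e2 > s2:
            out.append((s2, e2))
    return out


def partition_regions(
    gene: GeneModel,
    chrom_length: int,
    anchor: str = "tss",
    distal: int = 3000,
    proximal: int = 1000,
) -> RegionPartition:
    """Partition a gene's +/- 3 kb neighbourhood into the eight regions.

    ``anchor`` selects the promoter anchor point: ``"tss"`` (default) anchors
    the promoter windows at the annotated transcription start, ``"atg"`` at
    the translation start.  Degenerate regions (intronless genes, CDS-less
    genes, chromosome-edge clipping) come back as empty interval lists.
    """
    if anchor not in ("tss", "atg"):
        raise ValueError(f"anchor must be 'tss' or 'atg', got {anchor!r}")
    exons = list(gene.exons)
    transcribed = (gene.start, gene.end)
    introns = _subtract(transcribed, exons)

    if gene.cds_start is None:
        # non-coding gene: whole transcript treated as 5'UTR
        utr5, cds, utr3 = exons[:], [], []
        atg_anchor = gene.tss
    elif gene.strand == "+":
        utr5 = _intersect(exons, (gene.start, gene.cds_start))
        cds = _intersect(exons, (gene.cds_start, gene.cds_end))
        utr3 = _intersect(exons, (gene.cds_end, gene.end))
        atg_anchor = gene.cds_start
    else:
        utr5 = _intersect(exons, (gene.cds_end, gene.end))
        cds = _intersect(exons, (gene.cds_start, gene.cds_end))
        utr3 = _intersect(exons, (gene.start, gene.cds_start))
        atg_anchor = gene.cds_end

    up_anchor = gene.tss if anchor == "tss" else atg_anchor
    if gene.strand == "+":
        prox_prom = [(up_anchor - proximal, up_anchor)]
        distal_prom = [(up_anchor - distal, up_anchor - proximal)]
        downs1 = [(gene.end, gene.end + proximal)]
        downs2 = [(gene.end + proximal, gene.end + distal)]
    else:
        prox_prom = [(up_anchor, up_anchor + proximal)]
        distal_prom = [(up_anchor + proximal, up_anchor + distal)]
        downs1 = [(gene.start - proximal, gene.start)]
        downs2 = [(gene.start - distal, gene.start - proximal)]

    regions = {
        "distal_prom": distal_prom,
        "prox_prom": prox_prom,
        "utr5": utr5,
        "cds": cds,
        "intron": introns,
        "utr3": utr3,
        "downs1": downs1,
        "downs2": downs2,
    }
    regions = {k: _clip(v, 0, chrom_length) for k, v in regions.items()}
    return RegionPartition(gene.gene_id, gene.chrom, gene.strand, regions)


@dataclass
class AnnotationSet:
    """Validated gene models plus the ids rejected during parsing."""

    genes: list[GeneModel]
    rejected: list[str]
    chrom_lengths: dict[str, int]


def _canonical_transcript(transcripts):
    """Longest CDS, tie-break longest transcript, then smallest id."""

    def key(t):
        tid, span, cds_len = t
        return (-cds_len, -(span[1] - span[0]), tid)

    return sorted(transcripts, key=key)[0][0]


def read_annotation(gff3_path: str, fasta_path: str) -> AnnotationSet:
    """Read gene models from GFF3 with sequence access via an indexed FASTA.

    One canonical mRNA is chosen per gene (longest CDS; ties broken by
    transcript length then lexicographic id).  Genes failing validation are
    skipped with a logged warning and reported in ``rejected``.  A GFF3
    chromosome missing from the FASTA is a hard error.
    """
    import gffutils

    fasta = pyfaidx.Fasta(fasta_path)
    chrom_lengths = {name: len(fasta[name]) for name in fasta.keys()}
    db = gffutils.create_db(
        gff3_path, ":memory:", keep_order=True, merge_strategy="create_unique"
    )
    genes: list[GeneModel] = []
    rejected: list[str] = []
    for g in db.features_of_type("gene"):
        gid = g.id
        if g.seqid not in chrom_lengths:
            raise ValueError(
                f"chromosome {g.seqid!r} of gene {gid} missing from FASTA"
            )
        mrnas = list(db.children(g, featuretype="mRNA"))
        if not mrnas:
            mrnas = [g]
        choices = []
        for m in mrnas:
            cds_len = sum(
                c.end - c.start + 1 for c in db.children(m, featuretype="CDS")
            )
            choices.append((m.id, (m.start - 1, m.end), cds_len))
        chosen_id = _canonical_transcript(choices)
        mrna = next(m for m in mrnas if m.id == chosen_id)
        exons = sorted(
            (e.start - 1, e.end) for e in db.children(mrna, featuretype="exon")
        )
        if not exons:
            exons = [(mrna.start - 1, mrna.end)]
        cds = sorted(
            (c.start - 1, c.end) for c in db.children(mrna, featuretype="CDS")
        )
        cds_start = cds[0][0] if cds else None
        cds_end = cds[-1][1] if cds else None
        model = GeneModel(
            gene_id=gid,
            chrom=g.seqid,
            strand=g.strand,
            start=exons[0][0],
            end=exons[-1][1],
            cds_start=cds_start,
            cds_end=cds_end,
            exons=tuple(exons),
        )
        try:
            model.validate()
        except ValueError as err:
            logger.warning("rejecting gene %s: %s", gid, err)
            rejected.append(gid)
            continue
        genes.append(model)
    return AnnotationSet(genes=genes, rejected=rejected, chrom_lengths=chrom_lengths)


def load_sequences(fasta_path: str) -> dict[str, str]:
    """Full chromosome sequences as upper-case strings."""
    fasta = pyfaidx.Fasta(fasta_path)
    return {name: str(fasta[name][:]).upper() for name in fasta.keys()}


def write_partitions_bed(partitions: list[RegionPartition], path: str) -> None:
    """BED6 export (0-based half-open) of all region intervals."""
    with open(path, "w") as fh:
        for part in partitions:
            for region in REGIONS:
                for s, e in part.regions[region]:
                    fh.write(
                        f"{part.chrom}\t{s}\t{e}\t{part.gene_id}:{region}\t0\t{part.strand}\n"
                    )
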