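"""Degenerate IUPAC motif scanning and per-gene, per-region hit counting.

The motifs of interest are fixed consensus strings over the IUPAC alphabet —
the PHR1 binding sequence P1BS (``GNATATNC``, an imperfect palindrome equal
to its own reverse complement) and the cooperating promoter element motif B
(``GAWGATNC``).  Scanning is exhaustive: every window satisfying the pattern
is reported, overlapping matches included.  With both-strand scanning a
window matching the reverse complement of the pattern is reported once on
strand '-'; a window matching on both strands at the same start is reported
once with strand '+'.  An ambiguous reference base (N) matches only an N
pattern position.
"""
from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import REGIONS, RegionPartition

IUPAC: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_COMPLEMENT = {
    "A": "T", "C": "G", "G": "C", "T": "A",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
}

#: the two consensus elements the pipeline is built around
P1BS = None  # populated below once MotifPattern exists
MOTIF_B = None


@dataclass(frozen=True)
class MotifPattern:
    """A named degenerate consensus motif."""

    name: str
    iupac: str

    def __post_init__(self):
        pat = self.iupac.upper()
        if len(pat) < 4:
            raise ValueError(f"motif {self.name}: length must be >= 4")
        bad = sorted(set(pat) - set(IUPAC))
        if bad:
            raise ValueError(f"motif {self.name}: invalid IUPAC codes {bad}")
        object.__setattr__(self, "iupac", pat)

    def __len__(self) -> int:
        return len(self.iupac)

    def reverse_complement(self) -> "MotifPattern":
        rc = "".join(_COMPLEMENT[c] for c in reversed(self.iupac))
        return MotifPattern(self.name, rc)

    @property
    def is_palindromic(self) -> bool:
        return self.iupac == self.reverse_complement().iupac


P1BS = MotifPattern("P1BS", "GNATATNC")
MOTIF_B = MotifPattern("motifB", "GAWGATNC")


@dataclass(frozen=True)
class MotifHit:
    chrom: str
    start: int
    strand: str
    pattern: str


def _char_class(code: str) -> str:
    # sequence N matches only a pattern N position
    chars = sorted(IUPAC[code]) + (["N"] if code == "N" else [])
    return "[" + "".join(chars) + "]"


def _compile(iupac: str) -> re.Pattern:
    # lookahead so overlapping matches are all found
    return re.compile("(?=" + "".join(_char_class(c) for c in iupac) + ")")


def scan(
    sequence: str,
    pattern: MotifPattern,
    both_strands: bool = True,
    chrom: str = "",
) -> list[MotifHit]:
    """All starts where ``pattern`` matches ``sequence``.

    Returns hits sorted by start.  With ``both_strands`` the reverse
    complement of the pattern is also matched against the forward sequence;
    a start matching both ways is reported once on '+'.
    """
    seq = sequence.upper()
    fwd = {m.start() for m in _compile(pattern.iupac).finditer(seq)}
    if both_strands:
        rc = pattern.reverse_complement().iupac
        rev = {m.start() for m in _compile(rc).finditer(seq)}
    else:
        rev = set()
    hits = [
        MotifHit(chrom, s, "+" if s in fwd else "-", pattern.name)
        for s in sorted(fwd | rev)
    ]
    return hits


def scan_sequences(
    sequences: dict[str, str],
    patterns: list[MotifPattern],
    both_strands: bool = True,
) -> pd.DataFrame:
    """Scan whole chromosomes; tidy frame (chrom, start, strand, pattern)."""
    rows = []
    for chrom, seq in sequences.items():
        for pat in patterns:
            rows.extend(scan(seq, pat, both_strands=both_strands, chrom=chrom))
    return pd.DataFrame(
        [(h.chrom, h.start, h.strand, h.pattern) for h in rows],
        columns=["chrom", "start", "strand", "pattern"],
    )


def count_by_region(
    hits: pd.DataFrame,
    partitions: list[RegionPartition],
    pattern: str | None = None,
) -> pd.DataFrame:
    """Per-gene x per-region hit counts, plus an ``any`` column.

    A hit is assigned to region R of gene g iff its start lies in an
    interval of R (start-containment; half-open intervals resolve boundary
    ties).  A hit may land in regions of several genes when neighbourhoods
    overlap.  Counts are per distinct start position: same-start matches on
    both strands were already merged by the scanner.  The eight regions of
    one gene are mutually disjoint and tile the -3 kb..+3 kb neighbourhood,
    so ``any`` is their row sum.
    """
    if pattern is not None:
        hits = hits[hits["pattern"] == pattern]
    starts_by_chrom = {
        chrom: np.sort(sub["start"].unique())
        for chrom, sub in hits.groupby("chrom")
    }
    empty = np.array([], dtype=int)
    data = np.zeros((len(partitions), len(REGIONS)), dtype=int)
    gene_ids = []
    for i, part in enumerate(partitions):
        starts = starts_by_chrom.get(part.chrom, empty)
        gene_ids.append(part.gene_id)
        for j, region in enumerate(REGIONS):
            n = 0
            for s, e in part.regions[region]:
                n += int(
                    np.searchsorted(starts, e, side="left")
                    - np.searchsorted(starts, s, side="left")
                )
            data[i, j] = n
    out = pd.DataFrame(data, index=pd.Index(gene_ids, name="gene_id"), columns=REGIONS)
    out["any"] = out.sum(axis=1)
    return out


def write_hits_bed(hits: pd.DataFrame, path: str, lengths: dict[str, int]) -> None:
    """BED6 export of hits (name=pattern, score=0); ``lengths`` maps pattern
    name to motif length so the full match interval is written."""
    with open(path, "w") as fh:
        for row in hits.itertuples(index=False):
            end = row.start + lengths[row.pattern]
            fh.write(f"{row.chrom}\t{row.start}\t{end}\t{row.pattern}\t0\t{row.strand}\n")
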