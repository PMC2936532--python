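"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own implementations: the scanner
oracle checks every window character-by-character, the BH oracle applies the
step-up definition directly, the hypergeometric oracle enumerates all
equally likely draws, and the partition oracle recomputes minus-strand
partitions by reverse-complement coordinate mirroring.
"""
from __future__ import annotations

import itertools
import math

import numpy as np

IUPAC = {
    "A": set("A"), "C": set("C"), "G": set("G"), "T": set("T"),
    "R": set("AG"), "Y": set("CT"), "S": set("CG"), "W": set("AT"),
    "K": set("GT"), "M": set("AC"), "B": set("CGT"), "D": set("AGT"),
    "H": set("ACT"), "V": set("ACG"), "N": set("ACGTN"),
}
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N",
         "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
         "B": "V", "V": "B", "D": "H", "H": "D"}


def revcomp(s: str) -> str:
    return "".join(_COMP[c] for c in reversed(s))


def window_matches(window: str, iupac: str) -> bool:
    return len(window) == len(iupac) and all(
        c in IUPAC[p] for c, p in zip(window, iupac)
    )


def window_scan(sequence: str, iupac: str, both_strands: bool = True):
    """(start, strand) pairs by checking every window; both-strand matches
    at one start collapse to '+', as the scanner contract specifies."""
    seq = sequence.upper()
    rc = revcomp(iupac)
    out = []
    for i in range(len(seq) - len(iupac) + 1):
        w = seq[i : i + len(iupac)]
        fwd = window_matches(w, iupac)
        rev = both_strands and window_matches(w, rc)
        if fwd:
            out.append((i, "+"))
        elif rev:
            out.append((i, "-"))
    return out


def bh_stepup(p):
    """Benjamini-Hochberg adjusted p by the step-up definition:
    q(i) = min_{j >= i} p(j) * m / j over the sorted p-values."""
    p = list(map(float, p))
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        q[i] = running
    return q


def hypergeom_upper_tail(N: int, labels_a: set, labels_b: set, universe: list) -> float:
    """P(|A ∩ B'| >= |A ∩ B|) by enumerating every |B|-subset B' of the
    universe as equally likely.  Feasible for N <= 12."""
    k_obs = len(labels_a & labels_b)
    nb = len(labels_b)
    total = 0
    hits = 0
    for combo in itertools.combinations(universe, nb):
        total += 1
        if len(labels_a & set(combo)) >= k_obs:
            hits += 1
    return hits / total


def mirror_intervals(intervals, L):
    return sorted((L - e, L - s) for s, e in intervals)


def minus_partition_via_mirror(gene, chrom_length, partition_fn, gene_cls):
    """Partition a minus-strand gene by reverse-complementing the chromosome
    coordinate system, partitioning the mirrored plus-strand gene, and
    mapping the intervals back."""
    L = chrom_length
    mirrored = gene_cls(
        gene_id=gene.gene_id,
        chrom=gene.chrom,
        strand="+",
        start=L - gene.end,
        end=L - gene.start,
        cds_start=None if gene.cds_start is None else L - gene.cds_end,
        cds_end=None if gene.cds_end is None else L - gene.cds_start,
        exons=tuple(mirror_intervals(gene.exons, L)),
    )
    part = partition_fn(mirrored, L)
    return {
        region: mirror_intervals(ivs, L) for region, ivs in part.regions.items()
    }


def mc_linked_probability(
    L, len_a, len_b, cap, n_draws=1_000_000, seed=0, distance="gap"
):
    """Monte-Carlo P(two uniform motifs in a region of length L fall within
    the distance cap), the oracle for the exact analytic placement count."""
    rng = np.random.default_rng(seed)
    a = rng.integers(0, L - len_a + 1, size=n_draws)
    b = rng.integers(0, L - len_b + 1, size=n_draws)
    if distance == "start":
        d = np.abs(a - b)
    else:
        d = np.maximum(np.maximum(b - (a + len_a), a - (b + len_b)), 0)
    hit = d <= cap
    p = hit.mean()
    se = math.sqrt(p * (1 - p) / n_draws)
    return p, se
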