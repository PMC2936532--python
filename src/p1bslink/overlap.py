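"""Gene-set overlap statistics: hypergeometric enrichment between responsive
sets, flag (e.g. transcription-factor) representation in shared sets, and
the general-stress-response cross-tabulation."""
from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from scipy import stats

from .diffexpr import GeneSet


@dataclass(frozen=True)
class OverlapResult:
    set_a: str
    set_b: str
    universe_size: int
    n_a: int
    n_b: int
    n_overlap: int
    expected: float
    p: float  # one-sided (enrichment) hypergeometric upper tail


def overlap_test(a: GeneSet, b: GeneSet, universe: GeneSet) -> OverlapResult:
    """Exact hypergeometric upper-tail test of |A ∩ B| given the universe."""
    if len(universe) == 0:
        raise ValueError("empty universe")
    if not (a.members <= universe.members and b.members <= universe.members):
        raise ValueError("sets must be contained in the universe")
    n = len(universe)
    k = len(a.members & b.members)
    expected = len(a) * len(b) / n
    p = float(stats.hypergeom.sf(k - 1, n, len(a), len(b)))
    return OverlapResult(a.name, b.name, n, len(a), len(b), k, expected, p)


def overlap_matrix(
    focal: GeneSet, others: dict[str, GeneSet], universe: GeneSet
) -> pd.DataFrame:
    """Focal set against each other set; raw p plus a BH column as
    convenience (no correction is applied to the reported raw p)."""
    from .diffexpr import bh_adjust

    rows = []
    for name, other in others.items():
        r = overlap_test(focal, other, universe)
        rows.append(
            dict(
                set_b=name,
                n_a=r.n_a,
                n_b=r.n_b,
                n_overlap=r.n_overlap,
                expected=r.expected,
                p=r.p,
            )
        )
    out = pd.DataFrame(rows).set_index("set_b")
    out["p_bh"] = bh_adjust(out["p"].to_numpy())
    return out


def flag_representation(
    shared: GeneSet, parent: GeneSet, flags: pd.Series
) -> tuple[float, float, pd.DataFrame]:
    """Representation ratio of a boolean gene flag in ``shared`` vs its
    ``parent`` set, with a two-sided Fisher exact test.

    ratio = (flagged fraction in shared) / (flagged fraction in parent);
    undefined (NaN) when the parent has no flagged gene.
    """
    if not shared.members <= parent.members:
        raise ValueError("shared set must be contained in the parent set")
    flags = flags.astype(bool)
    in_shared = pd.Index(sorted(shared.members))
    in_parent = pd.Index(sorted(parent.members))
    f_shared = int(flags.reindex(in_shared).fillna(False).sum())
    f_parent = int(flags.reindex(in_parent).fillna(False).sum())
    n_shared, n_parent = len(in_shared), len(in_parent)
    if f_parent == 0 or n_shared == 0:
        ratio = float("nan")
    else:
        ratio = (f_shared / n_shared) / (f_parent / n_parent)
    # flag x membership (shared vs parent-only)
    table = pd.DataFrame(
        {
            "shared": [f_shared, n_shared - f_shared],
            "parent_only": [f_parent - f_shared, (n_parent - n_shared) - (f_parent - f_shared)],
        },
        index=["flagged", "unflagged"],
    )
    _, p = stats.fisher_exact(table.to_numpy(), alternative="two-sided")
    return ratio, float(p), table


def gsr_crosstab(
    gsr_sets: dict[str, GeneSet], pi_up: GeneSet, affected: GeneSet
) -> pd.DataFrame:
    """Per general-stress-response source: set size, number induced by the
    focal stress (the PSI-GSR column), and % of those also in the
    mutant-affected (down in the double mutant at 1.5x, FDR<0.1) set.
    Empty PSI-GSR intersections give NaN percentages."""
    rows = []
    for name, gsr in gsr_sets.items():
        psi = gsr.members & pi_up.members
        aff = psi & affected.members
        pct = 100.0 * len(aff) / len(psi) if psi else float("nan")
        rows.append(
            dict(source=name, n_gsr=len(gsr), n_psi_gsr=len(psi), pct_affected=pct)
        )
    return pd.DataFrame(rows).set_index("source")
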