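"""Motif dosage vs induction strength and vs cross-stress specificity.

The dose curve ranks the induced genes by log2 fold induction (descending,
gene-id tie-break) and slides a window of 30 genes at one-gene steps,
emitting the window's mean motif count against its mean induction.  A rising
curve for the proximal promoter, flat for other regions, is the expected
signature of promoter-dosage-driven activation.

Specificity asks the complementary question: genes with more promoter
copies of the element should not be broadly stress-induced.  Each induced
gene gets a specificity score = the number of other stress conditions
(typically 28) in which it is also induced; genes are binned by promoter
motif count class {0, 1, >1} and the score distributions are compared by an
r x c chi-square on score bins {0, 1, 2, >=3}.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


def dose_curve(
    log2fc: pd.Series,
    counts: pd.Series,
    window: int = 30,
    step: int = 1,
) -> pd.DataFrame:
    """Sliding-window mean motif count vs mean log2 fold induction.

    ``log2fc`` and ``counts`` are indexed by gene id over the induced set.
    Windows cover ranks [w, w+window); windows that would overrun the list
    are not emitted, so ``n - window + 1`` rows come back for step 1.
    """
    genes = log2fc.index
    if len(genes) < window:
        raise ValueError(
            f"{len(genes)} genes < window {window}; use a smaller window"
        )
    order = sorted(genes, key=lambda g: (-log2fc[g], g))
    fc = log2fc.reindex(order).to_numpy(float)
    ct = counts.reindex(order).to_numpy(float)
    rows = []
    for w, lo in enumerate(range(0, len(order) - window + 1, step)):
        rows.append(
            dict(
                window=w,
                mean_count=float(ct[lo : lo + window].mean()),
                mean_log2fc=float(fc[lo : lo + window].mean()),
            )
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class SpecificityResult:
    bins: pd.DataFrame  # per count class: n genes, mean score, sd
    statistic: float
    p: float
    contingency: pd.DataFrame


def _count_class(c: int) -> str:
    return "0" if c == 0 else ("1" if c == 1 else ">1")


def specificity_by_count(
    counts: pd.Series,
    other_calls: pd.DataFrame,
    score_bins: tuple[int, ...] = (0, 1, 2),
) -> SpecificityResult:
    """Mean number of other inducing stresses per motif-count class.

    ``other_calls`` is a genes x conditions boolean frame of induction calls
    in the other (non-focal) conditions; its row sums are the specificity
    scores.  The between-class test is a chi-square on the contingency of
    count class x binned score (bins 0, 1, 2, >=3 by default).  Degenerate
    tables (fewer than two non-empty rows or columns, e.g. when no gene is
    induced elsewhere) report statistic 0 and p = 1.
    """
    genes = counts.index
    scores = other_calls.reindex(genes).fillna(False).astype(int).sum(axis=1)
    classes = counts.map(_count_class)
    order = ["0", "1", ">1"]
    rows = []
    for cls in order:
        sub = scores[classes == cls]
        rows.append(
            dict(
                count_class=cls,
                n_genes=int(len(sub)),
                mean_other=float(sub.mean()) if len(sub) else float("nan"),
                sd_other=float(sub.std(ddof=1)) if len(sub) > 1 else float("nan"),
            )
        )
    bins = pd.DataFrame(rows).set_index("count_class")

    # score bins: one per listed value plus an open top bin (default 0,1,2,>=3)
    binned = pd.cut(
        scores,
        bins=[-0.5] + [b + 0.5 for b in score_bins] + [np.inf],
        labels=[str(b) for b in score_bins] + [f">={score_bins[-1] + 1}"],
    )
    table = pd.crosstab(classes, binned)
    table = table.loc[table.sum(axis=1) > 0, table.sum(axis=0) > 0]
    if table.shape[0] < 2 or table.shape[1] < 2:
        return SpecificityResult(bins, 0.0, 1.0, table)
    stat, p, _, _ = stats.chi2_contingency(table.to_numpy())
    return SpecificityResult(bins, float(stat), float(p), table)
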