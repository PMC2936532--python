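"""Genome-average-normalised motif content per region and the fraction of
genes lacking the motif anywhere in the -3 kb..+3 kb neighbourhood.

"Content per gene" is the arithmetic mean of hit counts per region (not a
per-bp density); the universe mean defines 1.0 so the focal set's relative
content reads as a fold enrichment over the average gene.  Significance is a
1-df chi-square comparing the focal set's total hits against the
universe-rate expectation; an exact binomial alternative is available for
small counts.  A ``per_kb`` switch additionally reports length-normalised
densities.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import GeneSet
from .genome import REGIONS, RegionPartition


def _chi2_focal(obs: float, total: float, frac: float) -> tuple[float, float]:
    """Chi-square (1 df) for ``obs`` of ``total`` hits falling in the focal
    gene fraction ``frac``; two cells (focal / non-focal)."""
    exp_in = total * frac
    exp_out = total - exp_in
    if exp_in <= 0 or exp_out <= 0:
        return float("nan"), float("nan")
    stat = (obs - exp_in) ** 2 / exp_in + ((total - obs) - exp_out) ** 2 / exp_out
    return float(stat), float(stats.chi2.sf(stat, df=1))


def _binom_focal(obs: int, total: int, frac: float) -> float:
    if total == 0:
        return float("nan")
    return float(stats.binomtest(int(obs), int(total), frac).pvalue)


def relative_content(
    counts: pd.DataFrame,
    focal: GeneSet,
    universe: GeneSet,
    regions: tuple[str, ...] = REGIONS,
    test: str = "chi2",
    partitions: list[RegionPartition] | None = None,
    per_kb: bool = False,
) -> pd.DataFrame:
    """Per-region relative motif content of ``focal`` vs ``universe``.

    ``focal`` must be a subset of ``universe``; the universe mean content is
    the 1.0 reference.  Rows carry focal/universe means, the ratio, the test
    statistic and p.  Regions with zero universe content get NaN ratio and a
    ``defined`` = False flag.  With ``per_kb`` (requires ``partitions``)
    additional columns report hits per kb in both sets.
    """
    if not focal.members <= universe.members:
        raise ValueError("focal set must be contained in the universe")
    if test not in ("chi2", "binomial"):
        raise ValueError(f"unknown test {test!r}")
    uni = sorted(universe.members)
    foc = sorted(focal.members)
    cu = counts.loc[uni]
    cf = counts.loc[foc]
    frac = len(foc) / len(uni)
    if per_kb and partitions is None:
        raise ValueError("per_kb requires partitions")
    lengths = None
    if per_kb:
        lengths = pd.DataFrame(
            {r: [p.length(r) for p in partitions] for r in regions},
            index=[p.gene_id for p in partitions],
        )
    rows = []
    for region in regions:
        u_mean = float(cu[region].mean())
        f_mean = float(cf[region].mean())
        total = int(cu[region].sum())
        obs = int(cf[region].sum())
        defined = u_mean > 0
        ratio = f_mean / u_mean if defined else float("nan")
        if test == "chi2":
            stat, p = _chi2_focal(obs, total, frac)
        else:
            stat, p = float("nan"), _binom_focal(obs, total, frac)
        row = dict(
            region=region,
            focal_mean=f_mean,
            universe_mean=u_mean,
            ratio=ratio,
            statistic=stat,
            p=p,
            defined=defined,
        )
        if per_kb:
            lu = lengths.loc[uni, region].sum() / 1000.0
            lf = lengths.loc[foc, region].sum() / 1000.0
            row["focal_per_kb"] = obs / lf if lf > 0 else float("nan")
            row["universe_per_kb"] = total / lu if lu > 0 else float("nan")
        rows.append(row)
    return pd.DataFrame(rows).set_index("region")


def lacking_fraction(counts: pd.DataFrame, gene_set: GeneSet) -> float:
    """Fraction of the set's genes with zero hits anywhere in -3 kb..+3 kb."""
    if len(gene_set) == 0:
        raise ValueError(f"gene set {gene_set.name!r} is empty; fraction undefined")
    sub = counts.loc[sorted(gene_set.members), "any"]
    return float((sub == 0).mean())
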