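"""Per-contrast differential expression, tiered responsiveness calls, the
mutant-effect cross-tabulation and direct-target calling.

Expression values are on the log2 scale throughout.  The per-gene statistic
is a two-sample unequal-variance (Welch) t-test with Benjamini-Hochberg
step-up FDR adjustment over all genes in the matrix; externally computed
contrast tables (gene_id, log2fc, p, fdr) can be dropped in anywhere a
contrast result is accepted, so a moderated-statistics table from a
dedicated microarray/RNA-seq package is a valid substitute.

The tiered calls mirror the fold-change/FDR cut-offs used for the
phosphate-starvation sets: 4x and 2x at FDR<0.05 for the responsive sets,
1.5x at FDR<0.1 as the relaxed mutant-effect cut-off.  Direct targets are
the genes up-regulated upon posttranslational activation of the transcription
factor in the presence of a translation inhibitor (the GR-fusion + DEX + CHX
design), compared against the responsive sets.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass(frozen=True)
class GeneSet:
    name: str
    members: frozenset
    provenance: str = ""

    def __len__(self):
        return len(self.members)

    def __contains__(self, g):
        return g in self.members


def select_samples(samples: pd.DataFrame, spec: dict) -> list[str]:
    """Sample names matching every factor in ``spec``
    (e.g. ``{"genotype": "wt", "condition": "minusPi", "tissue": "shoot"}``).
    """
    mask = np.ones(len(samples), dtype=bool)
    for key, val in spec.items():
        mask &= (samples[key] == val).to_numpy()
    return samples.loc[mask, "sample"].tolist()


def contrast(
    expr: pd.DataFrame,
    samples: pd.DataFrame,
    group_a: dict,
    group_b: dict,
    name: str = "",
    moderate_var: float | None = 20.0,
) -> pd.DataFrame:
    """Two-sample contrast of group A vs group B.

    Returns a frame indexed by gene_id with columns log2fc (mean A - mean B),
    p and fdr (BH over all genes in the matrix).  Requires >= 2 replicates
    per group.

    With few replicates a per-gene test is dominated by the noise of the
    per-gene variance estimate (4 residual df at 3+3 replicates), so by
    default the pooled per-gene variance is shrunk toward the across-gene
    mean variance with ``moderate_var`` pseudo-degrees of freedom and the
    t reference gains those df (the classic Cyber-T-style stabilisation;
    Baldi & Long 2001).  ``moderate_var=None`` gives the plain per-gene
    Welch test.  Zero-variance degenerate cases are resolved exactly: equal
    constant groups get p = 1, unequal constant groups p = 0.
    """
    cols_a = select_samples(samples, group_a)
    cols_b = select_samples(samples, group_b)
    for label, cols in (("A", cols_a), ("B", cols_b)):
        if len(cols) < 2:
            raise ValueError(
                f"contrast {name or '(unnamed)'}: group {label} {group_a if label == 'A' else group_b} "
                f"has {len(cols)} replicate(s); need >= 2"
            )
    a = expr[cols_a].to_numpy(float)
    b = expr[cols_b].to_numpy(float)
    na, nb = a.shape[1], b.shape[1]
    log2fc = a.mean(axis=1) - b.mean(axis=1)
    if moderate_var is None:
        with np.errstate(divide="ignore", invalid="ignore"):
            _, p = stats.ttest_ind(a, b, axis=1, equal_var=False)
        p = np.asarray(p, dtype=float)
    else:
        d_g = na + nb - 2
        s2 = (a.var(axis=1, ddof=1) * (na - 1) + b.var(axis=1, ddof=1) * (nb - 1)) / d_g
        s0 = float(s2.mean())
        s2_shrunk = (moderate_var * s0 + d_g * s2) / (moderate_var + d_g)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = log2fc / np.sqrt(s2_shrunk * (1.0 / na + 1.0 / nb))
        p = 2.0 * stats.t.sf(np.abs(t), df=d_g + moderate_var)
    degenerate = np.isnan(p)
    p[degenerate] = np.where(np.isclose(log2fc[degenerate], 0.0), 1.0, 0.0)
    fdr = multipletests(p, method="fdr_bh")[1]
    return pd.DataFrame(
        {"log2fc": log2fc, "p": p, "fdr": fdr},
        index=expr.index.rename("gene_id"),
    )


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    return multipletests(np.asarray(p, float), method="fdr_bh")[1]


def call_responsive(cr: pd.DataFrame, fold: float = 2.0, fdr: float = 0.05) -> pd.Series:
    """Direction call per gene: 'up', 'down' or 'none' at the given cut-off."""
    if fold <= 1:
        raise ValueError("fold cut-off must exceed 1")
    thr = np.log2(fold)
    sig = cr["fdr"] < fdr
    direction = np.where(
        sig & (cr["log2fc"] >= thr),
        "up",
        np.where(sig & (cr["log2fc"] <= -thr), "down", "none"),
    )
    return pd.Series(direction, index=cr.index, name="direction")


def responsive_set(
    cr: pd.DataFrame,
    direction: str,
    fold: float = 2.0,
    fdr: float = 0.05,
    name: str | None = None,
) -> GeneSet:
    calls = call_responsive(cr, fold=fold, fdr=fdr)
    members = frozenset(calls.index[calls == direction])
    label = name or f"{direction}_{fold}x_fdr{fdr}"
    return GeneSet(label, members, provenance=f"fold={fold}, fdr={fdr}, direction={direction}")


def mutant_effect_table(
    wt_contrast: pd.DataFrame,
    mutant_contrasts: dict[str, pd.DataFrame],
    wt_tiers: tuple[float, ...] = (2.0, 4.0),
    wt_fdr: float = 0.05,
    mutant_cutoffs: tuple[tuple[float, float], ...] = ((2.0, 0.05), (1.5, 0.1)),
) -> pd.DataFrame:
    """Percentage of wt-responsive genes with reduced/increased expression in
    each mutant-vs-wt contrast, per wt tier x direction x mutant cut-off.

    'reduced' means called down in the mutant-vs-wt contrast, 'increased'
    means called up, regardless of the wt direction.  Empty wt cells yield
    NaN percentages (undefined, not zero).
    """
    rows = []
    for direction in ("up", "down"):
        for tier in wt_tiers:
            wt_calls = call_responsive(wt_contrast, fold=tier, fdr=wt_fdr)
            wt_genes = wt_calls.index[wt_calls == direction]
            n_wt = len(wt_genes)
            for mutant, mc in mutant_contrasts.items():
                for fold, q in mutant_cutoffs:
                    mut_calls = call_responsive(mc, fold=fold, fdr=q)
                    if n_wt:
                        sub = mut_calls.reindex(wt_genes).fillna("none")
                        reduced = 100.0 * (sub == "down").sum() / n_wt
                        increased = 100.0 * (sub == "up").sum() / n_wt
                    else:
                        reduced = increased = float("nan")
                    rows.append(
                        dict(
                            wt_direction=direction,
                            wt_fold=tier,
                            n_wt=n_wt,
                            mutant=mutant,
                            mut_fold=fold,
                            mut_fdr=q,
                            reduced_pct=reduced,
                            increased_pct=increased,
                        )
                    )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class DirectTargetResult:
    """Set algebra of the GR-fusion induction experiment: counts of ox-up /
    ox-down genes and their overlaps with the starvation up/down sets."""

    ox_up: GeneSet
    ox_down: GeneSet
    direct_targets: GeneSet
    table: pd.DataFrame  # rows ox direction, columns pi_up/pi_down overlap


def call_direct_targets(
    ox_contrast: pd.DataFrame,
    pi_up: GeneSet,
    pi_down: GeneSet,
    fold: float = 2.0,
    fdr: float = 0.05,
) -> DirectTargetResult:
    calls = call_responsive(ox_contrast, fold=fold, fdr=fdr)
    up = frozenset(calls.index[calls == "up"])
    down = frozenset(calls.index[calls == "down"])
    table = pd.DataFrame(
        {
            "n": [len(up), len(down)],
            "pi_up_overlap": [len(up & pi_up.members), len(down & pi_up.members)],
            "pi_down_overlap": [len(up & pi_down.members), len(down & pi_down.members)],
        },
        index=pd.Index(["up", "down"], name="ox_direction"),
    )
    prov = f"ox contrast at {fold}x, FDR<{fdr}"
    return DirectTargetResult(
        ox_up=GeneSet("ox_up", up, prov),
        ox_down=GeneSet("ox_down", down, prov),
        direct_targets=GeneSet("direct_targets", up, prov),
        table=table,
    )


def read_contrast_table(path: str) -> pd.DataFrame:
    """TSV with columns gene_id, log2fc, p, fdr (externally computed DE)."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "log2fc", "p", "fdr"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"contrast table {path} missing columns {sorted(missing)}")
    return df.set_index("gene_id")


def write_gene_set(gs: GeneSet, path: str) -> None:
    with open(path, "w") as fh:
        for g in sorted(gs.members):
            fh.write(f"{g}\n")


def read_gene_set(path: str, name: str | None = None) -> GeneSet:
    with open(path) as fh:
        members = frozenset(line.strip() for line in fh if line.strip())
    return GeneSet(name or path, members, provenance=f"file:{path}")
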