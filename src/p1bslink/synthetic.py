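"""Synthetic genome + expression generator with planted regulatory truth.

The generator emulates the statistical structure of a replicated two-
condition (+Pi / -Pi), multi-genotype (wild type, single mutant, double
mutant, GR-fusion overexpressor), two-tissue microarray design around a
phosphate-starvation response controlled by a promoter cis-element:

* a toy single-chromosome genome of non-overlapping gene neighbourhoods,
  each gene carrying a fixed exon/intron layout inside a +/- 3 kb window of
  i.i.d. background sequence at a configurable GC content;
* "direct target" genes get 1..k exact instantiations of the P1BS consensus
  (``GNATATNC``; N positions drawn uniformly) planted at non-overlapping
  offsets in the proximal 1 kb promoter, and a configurable fraction of them
  additionally get one motif-B instantiation within a <= 25 bp edge gap of a
  planted P1BS;
* log2 expression = per-gene baseline + condition effect + genotype-
  attenuated element-driven induction + i.i.d. replicate noise. Direct
  targets are induced by ``base + beta * copies``; indirect induced and
  repressed genes carry effects not tied to planted copies, attenuated in
  the mutants when flagged as regulator-dependent; a DEX+CHX pseudo-
  genotype contrast expresses only the direct (element-driven) component.

Everything is driven by one integer seed; the same seed yields byte-
identical FASTA/GFF3/TSV artifacts.  A truth table records every planted
position, per-gene class and the exact per-genotype/tissue effects, for
parameter-recovery tests downstream.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .genome import GeneModel
from .motifs import IUPAC, MOTIF_B, P1BS

GENOTYPES = ("wt", "phr1", "phr1_phl1")
TISSUES = ("shoot", "root")
CLASSES = ("direct_up", "indirect_up", "repressed", "nonresponsive")


@dataclass
class SyntheticConfig:
    """Free parameters of the generator; defaults are the study conditions
    exercised by the recovery tests (see docs/methods.md for rationale)."""

    seed: int = 0
    n_genes: int = 2000
    promoter_len: int = 3000
    downstream_len: int = 3000
    gc_content: float = 0.36  # Arabidopsis-like genomic GC
    # class fractions
    frac_direct: float = 0.15
    frac_indirect_up: float = 0.15
    frac_repressed: float = 0.10
    frac_indirect_dependent: float = 0.5  # regulator-dependent share of indirect_up
    # planted dosage model
    lambda_copies: float = 1.5  # Poisson mean, clipped to >= 1 copy
    beta_per_copy: float = 0.5  # log2FC increment per proximal-promoter copy
    base_induction_log2: float = 1.5
    frac_B_linked: float = 0.5
    b_link_cap: int = 25  # max planted edge-to-edge gap, bp
    # effect sizes for the non-dosage classes (log2, uniform ranges)
    indirect_effect_range: tuple[float, float] = (1.5, 3.0)
    repressed_effect_range: tuple[float, float] = (1.0, 2.5)
    # expression design
    noise_sd_log2: float = 0.25
    n_reps: int = 3
    genotype_attenuation: dict = field(
        default_factory=lambda: {"wt": 1.0, "phr1": 0.3, "phr1_phl1": 0.05}
    )
    ox_attenuation: float = 1.0  # element-driven multiplier in the GR-fusion line
    baseline_mean: float = 8.0
    baseline_sd: float = 1.0
    tissue_fracs: dict = field(
        default_factory=lambda: {"both": 0.7, "shoot": 0.15, "root": 0.15}
    )
    # auxiliary flags
    n_other_conditions: int = 28
    other_mean_direct: float = 2.0
    other_mean_nondirect: float = 5.0
    frac_TF: float = 0.06
    frac_GSR: float = 0.12
    # gene layout (bp)
    utr5_len: int = 150
    cds_len: int = 900
    intron_len: int = 200
    utr3_len: int = 250
    spacer: int = 100
    minus_strand_half: bool = False  # place every other gene on the - strand
    chrom_length: int | None = None  # optional explicit length (checked)

    @property
    def transcript_len(self) -> int:
        return self.utr5_len + self.cds_len + self.intron_len + self.utr3_len

    @property
    def margin(self) -> int:
        return max(self.promoter_len, self.downstream_len)

    @property
    def slot(self) -> int:
        return 2 * self.margin + self.transcript_len + self.spacer

    def required_length(self) -> int:
        return self.n_genes * self.slot

    def validate(self) -> None:
        fracs = {
            "frac_direct": self.frac_direct,
            "frac_indirect_up": self.frac_indirect_up,
            "frac_repressed": self.frac_repressed,
            "frac_indirect_dependent": self.frac_indirect_dependent,
            "frac_B_linked": self.frac_B_linked,
            "frac_TF": self.frac_TF,
            "frac_GSR": self.frac_GSR,
        }
        for name, v in fracs.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.frac_direct + self.frac_indirect_up + self.frac_repressed > 1.0:
            raise ValueError("class fractions sum beyond 1")
        if not 0.0 < self.gc_content < 1.0:
            raise ValueError("gc_content must be in (0, 1)")
        if self.n_reps < 2:
            raise ValueError("n_reps must be >= 2")
        if abs(sum(self.tissue_fracs.values()) - 1.0) > 1e-9:
            raise ValueError("tissue_fracs must sum to 1")
        if self.chrom_length is not None and self.chrom_length < self.required_length():
            raise ValueError(
                f"chrom_length={self.chrom_length} cannot hold {self.n_genes} genes "
                f"with non-overlapping +/-{self.margin} bp neighbourhoods "
                f"(need >= {self.required_length()} bp)"
            )

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown synthetic config keys: {sorted(unknown)}")
        cfg = cls(**{k: v for k, v in d.items() if k in known})
        for key in ("indirect_effect_range", "repressed_effect_range"):
            val = getattr(cfg, key)
            if isinstance(val, list):
                setattr(cfg, key, tuple(val))
        return cfg


def _rngs(config: SyntheticConfig) -> tuple[np.random.Generator, np.random.Generator]:
    children = np.random.SeedSequence(config.seed).spawn(2)
    return np.random.default_rng(children[0]), np.random.default_rng(children[1])


def _instantiate(iupac: str, rng: np.random.Generator) -> str:
    """Concrete site: each degenerate position drawn uniformly from its set."""
    return "".join(
        c if len(IUPAC[c]) == 1 else rng.choice(sorted(IUPAC[c])) for c in iupac
    )


_COMP = str.maketrans("ACGT", "TGCA")


def _revcomp(s: str) -> str:
    return s.translate(_COMP)[::-1]


def _exact_counts(n: int, fracs: dict[str, float]) -> dict[str, int]:
    """Deterministic integer allocation of n items to labelled fractions."""
    counts = {k: int(round(v * n)) for k, v in fracs.items()}
    return counts


def _build_gene(cfg: SyntheticConfig, i: int, strand: str) -> GeneModel:
    t0 = i * cfg.slot + cfg.margin
    half1 = cfg.cds_len // 2
    if strand == "+":
        left_flank = cfg.utr5_len
    else:
        left_flank = cfg.utr3_len
    exon1 = (t0, t0 + left_flank + half1)
    intron = (exon1[1], exon1[1] + cfg.intron_len)
    exon2 = (intron[1], t0 + cfg.transcript_len)
    cds_start = t0 + left_flank
    cds_end = cds_start + cfg.cds_len + cfg.intron_len
    return GeneModel(
        gene_id=f"g{i:05d}",
        chrom="chr1",
        strand=strand,
        start=t0,
        end=t0 + cfg.transcript_len,
        cds_start=cds_start,
        cds_end=cds_end,
        exons=(exon1, exon2),
    )


def _prox_prom_interval(gene: GeneModel, prox: int = 1000) -> tuple[int, int]:
    if gene.strand == "+":
        return (gene.tss - prox, gene.tss)
    return (gene.tss, gene.tss + prox)


def generate_genome(
    config: SyntheticConfig,
) -> tuple[dict[str, str], list[GeneModel], pd.DataFrame]:
    """Toy genome: sequences, gene models and the ground-truth table.

    Genes occupy non-overlapping slots so their +/- 3 kb neighbourhoods never
    collide.  For every direct-target gene the configured number of exact
    P1BS instantiations is planted at non-overlapping uniform offsets in the
    proximal promoter; a fraction of those genes additionally receive one
    motif-B instantiation with a start-to-start distance drawn uniformly in
    [9, 25 + motif length], i.e. an edge gap of 1..25 bp.  The truth table
    records every planted position (genomic starts), per-gene class,
    regulator dependence, effect sizes and auxiliary flags.
    """
    config.validate()
    rng, _ = _rngs(config)
    n = config.n_genes
    chrom_len = config.chrom_length or config.required_length()
    g = config.gc_content
    base_probs = [(1 - g) / 2, g / 2, g / 2, (1 - g) / 2]
    alphabet = np.frombuffer(b"ACGT", dtype="S1")
    seq = rng.choice(alphabet, size=chrom_len, p=base_probs)

    # deterministic class assignment with exact counts
    counts = _exact_counts(
        n,
        {
            "direct_up": config.frac_direct,
            "indirect_up": config.frac_indirect_up,
            "repressed": config.frac_repressed,
        },
    )
    order = rng.permutation(n)
    classes = np.full(n, "nonresponsive", dtype=object)
    pos = 0
    for cls in ("direct_up", "indirect_up", "repressed"):
        classes[order[pos : pos + counts[cls]]] = cls
        pos += counts[cls]

    strands = [
        "-" if (config.minus_strand_half and i % 2 == 1) else "+" for i in range(n)
    ]
    genes = [_build_gene(config, i, strands[i]) for i in range(n)]

    # tissue profiles, exact counts, shuffled independently of class
    tissue_profile = np.full(n, "both", dtype=object)
    tcounts = _exact_counts(n, config.tissue_fracs)
    torder = rng.permutation(n)
    tpos = 0
    for prof in ("both", "shoot", "root"):
        tissue_profile[torder[tpos : tpos + tcounts.get(prof, 0)]] = prof
        tpos += tcounts.get(prof, 0)

    # regulator dependence: direct and repressed genes are always dependent;
    # an exact fraction of the indirect_up genes is dependent
    dependent = np.zeros(n, dtype=bool)
    dependent[classes == "direct_up"] = True
    dependent[classes == "repressed"] = True
    ind_idx = np.flatnonzero(classes == "indirect_up")
    n_dep = int(round(config.frac_indirect_dependent * ind_idx.size))
    dependent[rng.choice(ind_idx, size=n_dep, replace=False)] = True

    # plant P1BS copies (and linked motif B) in direct-target promoters
    len_a, len_b = len(P1BS), len(MOTIF_B)
    copies = np.zeros(n, dtype=int)
    p1bs_starts: list[list[int]] = [[] for _ in range(n)]
    b_start = np.full(n, -1, dtype=int)
    direct_idx = np.flatnonzero(classes == "direct_up")
    for i in direct_idx:
        copies[i] = max(1, int(rng.poisson(config.lambda_copies)))
    b_linked_idx = rng.choice(
        direct_idx,
        size=int(round(config.frac_B_linked * direct_idx.size)),
        replace=False,
    )
    b_linked = np.zeros(n, dtype=bool)
    b_linked[b_linked_idx] = True

    prox = 1000
    for i in direct_idx:
        lo, hi = _prox_prom_interval(genes[i], prox)
        occupied: list[tuple[int, int]] = []

        def _free(s: int, length: int) -> bool:
            return all(s + length <= os or s >= oe for os, oe in occupied)

        for _ in range(copies[i]):
            for _attempt in range(1000):
                off = int(rng.integers(0, prox - len_a + 1))
                if _free(lo + off, len_a):
                    break
            else:  # pragma: no cover - promoter is never that crowded
                raise RuntimeError("could not place non-overlapping motif copies")
            start = lo + off
            occupied.append((start, start + len_a))
            site = _instantiate(P1BS.iupac, rng)
            if genes[i].strand == "-":
                site = _revcomp(site)
            seq[start : start + len_a] = np.frombuffer(site.encode(), dtype="S1")
            p1bs_starts[i].append(start)
        if b_linked[i]:
            for _attempt in range(1000):
                anchor = int(rng.choice(p1bs_starts[i]))
                dist = int(rng.integers(9, config.b_link_cap + len_a + 1))
                side = 1 if rng.random() < 0.5 else -1
                start = anchor + side * dist
                if lo <= start and start + len_b <= hi and _free(start, len_b):
                    break
            else:  # pragma: no cover
                raise RuntimeError("could not place linked motif B")
            occupied.append((start, start + len_b))
            site = _instantiate(MOTIF_B.iupac, rng)
            if genes[i].strand == "-":
                site = _revcomp(site)
            seq[start : start + len_b] = np.frombuffer(site.encode(), dtype="S1")
            b_start[i] = start

    # effect sizes
    direct_effect = np.where(
        classes == "direct_up",
        config.base_induction_log2 + config.beta_per_copy * copies,
        0.0,
    )
    other_effect = np.zeros(n)
    ind_lo, ind_hi = config.indirect_effect_range
    rep_lo, rep_hi = config.repressed_effect_range
    for i in range(n):
        if classes[i] == "indirect_up":
            other_effect[i] = rng.uniform(ind_lo, ind_hi)
        elif classes[i] == "repressed":
            other_effect[i] = -rng.uniform(rep_lo, rep_hi)

    # auxiliary flags: exact-count random subsets
    tf_flag = np.zeros(n, dtype=bool)
    tf_flag[rng.choice(n, size=int(round(config.frac_TF * n)), replace=False)] = True
    gsr_flag = np.zeros(n, dtype=bool)
    gsr_flag[rng.choice(n, size=int(round(config.frac_GSR * n)), replace=False)] = True

    # induction flags in the other (non-focal) stress conditions: direct
    # targets are more starvation-specific (fewer other inductions)
    n_other = config.n_other_conditions
    other_flags = np.zeros((n, n_other), dtype=int)
    for i in range(n):
        mean = (
            config.other_mean_direct
            if classes[i] == "direct_up"
            else config.other_mean_nondirect
        )
        k = min(int(rng.poisson(mean)), n_other)
        if k:
            other_flags[i, rng.choice(n_other, size=k, replace=False)] = 1

    truth = pd.DataFrame(
        {
            "gene_id": [gm.gene_id for gm in genes],
            "class": classes,
            "strand": strands,
            "tissue_profile": tissue_profile,
            "dependent": dependent,
            "copies": copies,
            "b_linked": b_linked,
            "p1bs_starts": [",".join(map(str, s)) for s in p1bs_starts],
            "b_start": b_start,
            "direct_effect": direct_effect,
            "other_effect": other_effect,
            "tf_flag": tf_flag,
            "gsr_flag": gsr_flag,
        }
    ).set_index("gene_id")
    for g_name, atten in config.genotype_attenuation.items():
        for tissue in TISSUES:
            truth[f"true_log2fc_{g_name}_{tissue}"] = [
                _true_log2fc(config, classes[i], dependent[i], tissue_profile[i],
                             direct_effect[i], other_effect[i], atten, tissue)
                for i in range(n)
            ]
    truth["true_log2fc_ox"] = (
        config.ox_attenuation - config.genotype_attenuation["phr1"]
    ) * direct_effect
    for c in range(n_other):
        truth[f"cond_{c + 1:02d}"] = other_flags[:, c]
    sequences = {"chr1": seq.tobytes().decode("ascii")}
    return sequences, genes, truth


def _true_log2fc(
    config, klass, dependent, profile, direct_effect, other_effect, atten, tissue
) -> float:
    active = profile in ("both", tissue)
    if not active or klass == "nonresponsive":
        return 0.0
    if klass == "direct_up":
        return atten * direct_effect
    mult = atten if dependent else 1.0
    return mult * other_effect


def generate_expression(
    config: SyntheticConfig, truth: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Replicated log2 expression matrix plus the sample sheet.

    Samples cover genotype x (+Pi / -Pi) x tissue for the starvation design,
    plus a DEX+CHX contrast pair (GR-fusion overexpressor vs its mutant
    background, whole plants) in which only the direct, element-driven
    component is expressed.
    """
    config.validate()
    _, rng = _rngs(config)
    n = len(truth)
    rows = []
    for genotype in GENOTYPES:
        for condition in ("plusPi", "minusPi"):
            for tissue in TISSUES:
                for rep in range(1, config.n_reps + 1):
                    rows.append((genotype, condition, tissue, rep))
    for genotype in ("OxGR_PHR1", "phr1"):
        for rep in range(1, config.n_reps + 1):
            rows.append((genotype, "dex_chx", "whole", rep))
    samples = pd.DataFrame(rows, columns=["genotype", "condition", "tissue", "replicate"])
    samples.insert(
        0,
        "sample",
        [
            f"{g}_{c}_{t}_r{r}"
            for g, c, t, r in zip(
                samples.genotype, samples.condition, samples.tissue, samples.replicate
            )
        ],
    )

    baseline = rng.normal(config.baseline_mean, config.baseline_sd, size=n)
    direct_effect = truth["direct_effect"].to_numpy(float)
    data = np.empty((n, len(samples)))
    for j, s in enumerate(samples.itertuples(index=False)):
        if s.condition == "plusPi":
            delta = np.zeros(n)
        elif s.condition == "minusPi":
            delta = truth[f"true_log2fc_{s.genotype}_{s.tissue}"].to_numpy(float)
        else:  # dex_chx: only the element-driven (direct) component
            atten = (
                config.ox_attenuation
                if s.genotype == "OxGR_PHR1"
                else config.genotype_attenuation["phr1"]
            )
            delta = atten * direct_effect
        noise = (
            rng.normal(0.0, config.noise_sd_log2, size=n)
            if config.noise_sd_log2 > 0
            else np.zeros(n)
        )
        data[:, j] = baseline + delta + noise
    expr = pd.DataFrame(data, index=truth.index.copy(), columns=samples["sample"])
    return expr, samples


@dataclass
class SyntheticDataset:
    config: SyntheticConfig
    sequences: dict[str, str]
    genes: list[GeneModel]
    truth: pd.DataFrame
    expr: pd.DataFrame
    samples: pd.DataFrame

    def write(self, outdir: str | Path) -> dict[str, Path]:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "fasta": out / "genome.fa",
            "gff3": out / "genes.gff3",
            "truth": out / "truth.tsv",
            "expression": out / "expression.tsv",
            "samples": out / "samples.tsv",
            "config": out / "synthetic_config.yaml",
        }
        write_fasta(self.sequences, paths["fasta"])
        write_gff3(self.genes, paths["gff3"])
        self.truth.to_csv(paths["truth"], sep="\t")
        self.expr.to_csv(paths["expression"], sep="\t")
        self.samples.to_csv(paths["samples"], sep="\t", index=False)
        self.config.to_yaml(paths["config"])
        return paths


def generate(config: SyntheticConfig) -> SyntheticDataset:
    sequences, genes, truth = generate_genome(config)
    expr, samples = generate_expression(config, truth)
    return SyntheticDataset(config, sequences, genes, truth, expr, samples)


def write_fasta(sequences: dict[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_gff3(genes: list[GeneModel], path: str | Path) -> None:
    """GFF3 (1-based inclusive) with gene/mRNA/exon/CDS features."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            attrs = f"ID={g.gene_id}"
            fh.write(
                f"{g.chrom}\tsynthetic\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )
            mid = f"{g.gene_id}.1"
            fh.write(
                f"{g.chrom}\tsynthetic\tmRNA\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={mid};Parent={g.gene_id}\n"
            )
            for k, (s, e) in enumerate(g.exons, 1):
                fh.write(
                    f"{g.chrom}\tsynthetic\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t"
                    f"ID={mid}.exon{k};Parent={mid}\n"
                )
            if g.cds_start is not None:
                pieces = []
                for s, e in g.exons:
                    lo, hi = max(s, g.cds_start), min(e, g.cds_end)
                    if hi > lo:
                        pieces.append((lo, hi))
                ordered = pieces if g.strand == "+" else pieces[::-1]
                cum = 0
                phases = {}
                for s, e in ordered:
                    phases[(s, e)] = (3 - cum % 3) % 3
                    cum += e - s
                for k, (s, e) in enumerate(pieces, 1):
                    fh.write(
                        f"{g.chrom}\tsynthetic\tCDS\t{s + 1}\t{e}\t.\t{g.strand}\t"
                        f"{phases[(s, e)]}\tID={mid}.cds{k};Parent={mid}\n"
                    )
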