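"""End-to-end orchestration: generate -> scan -> de -> enrich -> dose ->
specificity -> cooccur -> overlap, under one YAML config, with per-stage
TSV outputs and a machine-readable JSON report.

Every stage writes its outputs into the shared output directory and every
stage can reload its inputs from the files written by earlier stages, so
any downstream stage can be resumed without recomputation.  Reports are
deterministic: rerunning with the same config and seed is bit-identical.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats as _sstats

from . import __version__
from .cooccurrence import cooccurrence_test, hits_in_region
from .diffexpr import (
    GeneSet,
    call_direct_targets,
    contrast,
    mutant_effect_table,
    read_gene_set,
    responsive_set,
    write_gene_set,
)
from .enrichment import lacking_fraction, relative_content
from .genome import partition_regions, read_annotation, write_partitions_bed
from .inducibility import dose_curve, specificity_by_count
from .motifs import REGIONS, MotifPattern, count_by_region, scan_sequences, write_hits_bed
from .overlap import flag_representation, gsr_crosstab, overlap_matrix
from .synthetic import SyntheticConfig, generate

logger = logging.getLogger("p1bslink.pipeline")


@dataclass
class PipelineConfig:
    outdir: str = "p1bslink_out"
    seed: int = 0
    synthetic: SyntheticConfig | None = None
    paths: dict | None = None  # fasta, gff3, expression, samples, flags
    motif_a: dict = field(default_factory=lambda: {"name": "P1BS", "iupac": "GNATATNC"})
    motif_b: dict = field(default_factory=lambda: {"name": "motifB", "iupac": "GAWGATNC"})
    anchor: str = "tss"
    tissue: str = "shoot"
    up_fold: float = 2.0
    up_fdr: float = 0.05
    relaxed_fold: float = 1.5
    relaxed_fdr: float = 0.1
    dose_window: int = 30
    cooccur_cap: int = 25
    cooccur_region: str = "prox_prom"
    cooccur_null: str = "permutation"
    cooccur_n_perm: int = 1999
    cooccur_distance: str = "gap"
    n_overlap_conditions: int = 5  # other-condition sets tested for overlap
    wt_genotype: str = "wt"
    mutants: tuple[str, ...] = ("phr1", "phr1_phl1")
    ox_genotype: str = "OxGR_PHR1"
    ox_reference: str = "phr1"
    starved: str = "minusPi"
    replete: str = "plusPi"
    ox_condition: str = "dex_chx"

    def validate(self) -> None:
        if (self.synthetic is None) == (self.paths is None):
            raise ValueError("config must provide exactly one of 'synthetic' or 'paths'")

    @classmethod
    def from_yaml(cls, path: str | Path, seed: int | None = None) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        syn = raw.pop("synthetic", None)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown pipeline config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        if syn is not None:
            cfg.synthetic = SyntheticConfig.from_dict(syn)
        if seed is not None:
            cfg.seed = seed
            if cfg.synthetic is not None:
                cfg.synthetic.seed = seed
        if isinstance(cfg.mutants, list):
            cfg.mutants = tuple(cfg.mutants)
        cfg.validate()
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def sha256(self) -> str:
        canon = yaml.safe_dump(_plain(self.to_dict()), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()


def _plain(obj):
    """Recursively convert numpy/pandas scalars for YAML/JSON emission."""
    if isinstance(obj, dict):
        return {str(k): _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, float) and (np.isnan(obj) or np.isinf(obj)):
        return None
    return obj


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


class Pipeline:
    """Runs the stages against one output directory; each stage persists its
    outputs so later stages (or separate CLI invocations) can resume."""

    STAGES = (
        "generate",
        "scan",
        "de",
        "enrich",
        "dose",
        "specificity",
        "cooccur",
        "overlap",
    )

    def __init__(self, config: PipelineConfig):
        config.validate()
        self.cfg = config
        self.out = Path(config.outdir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.report: dict = {}
        self._cache: dict = {}
        self.pattern_a = MotifPattern(config.motif_a["name"], config.motif_a["iupac"])
        self.pattern_b = MotifPattern(config.motif_b["name"], config.motif_b["iupac"])

    # ---------------------------------------------------------------- inputs
    def _path(self, key: str, default_name: str) -> Path:
        if self.cfg.paths and key in self.cfg.paths:
            return Path(self.cfg.paths[key])
        return self.out / default_name

    def _annotation(self):
        if "annotation" not in self._cache:
            ann = read_annotation(
                str(self._path("gff3", "genes.gff3")), str(self._path("fasta", "genome.fa"))
            )
            from .genome import load_sequences

            sequences = load_sequences(str(self._path("fasta", "genome.fa")))
            parts = [
                partition_regions(
                    g, ann.chrom_lengths[g.chrom], anchor=self.cfg.anchor
                )
                for g in ann.genes
            ]
            self._cache["annotation"] = (sequences, ann, parts)
        return self._cache["annotation"]

    def _expression(self):
        if "expression" not in self._cache:
            expr = pd.read_csv(
                self._path("expression", "expression.tsv"), sep="\t", index_col=0
            )
            samples = pd.read_csv(self._path("samples", "samples.tsv"), sep="\t")
            self._cache["expression"] = (expr, samples)
        return self._cache["expression"]

    def _flags(self) -> pd.DataFrame:
        if "flags" not in self._cache:
            self._cache["flags"] = pd.read_csv(
                self._path("flags", "truth.tsv"), sep="\t", index_col=0
            )
        return self._cache["flags"]

    def _counts(self, pattern: str) -> pd.DataFrame:
        key = f"counts_{pattern}"
        if key not in self._cache:
            path = self.out / f"counts_{pattern}.tsv"
            self._cache[key] = pd.read_csv(path, sep="\t", index_col=0)
        return self._cache[key]

    def _hits(self) -> pd.DataFrame:
        if "hits" not in self._cache:
            self._cache["hits"] = pd.read_csv(self.out / "hits.tsv", sep="\t")
        return self._cache["hits"]

    def _gene_set(self, name: str) -> GeneSet:
        return read_gene_set(str(self.out / f"set_{name}.txt"), name=name)

    def _contrast(self, name: str) -> pd.DataFrame:
        return pd.read_csv(self.out / f"contrast_{name}.tsv", sep="\t", index_col=0)

    # ---------------------------------------------------------------- stages
    def stage_generate(self) -> dict:
        if self.cfg.synthetic is None:
            section = {"mode": "paths", "paths": _plain(dict(self.cfg.paths))}
            self.report["generate"] = section
            return section
        ds = generate(self.cfg.synthetic)
        ds.write(self.out)
        self._cache.pop("annotation", None)  # invalidate any stale load
        section = {
            "mode": "synthetic",
            "n_genes": len(ds.genes),
            "chrom_length": len(ds.sequences["chr1"]),
            "class_counts": _plain(ds.truth["class"].value_counts().to_dict()),
            "planted_p1bs_total": int(ds.truth["copies"].sum()),
            "planted_b_linked": int(ds.truth["b_linked"].sum()),
        }
        self.report["generate"] = section
        return section

    def stage_scan(self) -> dict:
        sequences, ann, parts = self._annotation()
        hits = scan_sequences(sequences, [self.pattern_a, self.pattern_b])
        hits.to_csv(self.out / "hits.tsv", sep="\t", index=False)
        lengths = {
            self.pattern_a.name: len(self.pattern_a),
            self.pattern_b.name: len(self.pattern_b),
        }
        write_hits_bed(hits, str(self.out / "hits.bed"), lengths)
        write_partitions_bed(parts, str(self.out / "partitions.bed"))
        section = {"n_rejected_genes": len(ann.rejected)}
        for pat in (self.pattern_a, self.pattern_b):
            counts = count_by_region(hits, parts, pattern=pat.name)
            counts.to_csv(self.out / f"counts_{pat.name}.tsv", sep="\t")
            self._cache[f"counts_{pat.name}"] = counts
            section[pat.name] = {
                "n_hits": int((hits["pattern"] == pat.name).sum()),
                "mean_per_gene_any": float(counts["any"].mean()),
            }
        self._cache["hits"] = hits
        self.report["scan"] = section
        return section

    def _tissues(self, samples: pd.DataFrame) -> list[str]:
        mask = samples["condition"].isin([self.cfg.starved, self.cfg.replete])
        return sorted(samples.loc[mask, "tissue"].unique())

    def stage_de(self) -> dict:
        cfg = self.cfg
        expr, samples = self._expression()
        section: dict = {}
        pi_up_union: set = set()
        pi_down_union: set = set()
        for tissue in self._tissues(samples):
            wt = contrast(
                expr,
                samples,
                {"genotype": cfg.wt_genotype, "condition": cfg.starved, "tissue": tissue},
                {"genotype": cfg.wt_genotype, "condition": cfg.replete, "tissue": tissue},
                name=f"wt_{tissue}",
            )
            wt.to_csv(self.out / f"contrast_wt_{tissue}.tsv", sep="\t")
            mut_contrasts = {}
            for mutant in cfg.mutants:
                mc = contrast(
                    expr,
                    samples,
                    {"genotype": mutant, "condition": cfg.starved, "tissue": tissue},
                    {"genotype": cfg.wt_genotype, "condition": cfg.starved, "tissue": tissue},
                    name=f"{mutant}_vs_wt_{tissue}",
                )
                mc.to_csv(self.out / f"contrast_{mutant}_vs_wt_{tissue}.tsv", sep="\t")
                mut_contrasts[mutant] = mc
            table = mutant_effect_table(wt, mut_contrasts)
            table.to_csv(self.out / f"mutant_effect_{tissue}.tsv", sep="\t", index=False)
            up = responsive_set(wt, "up", cfg.up_fold, cfg.up_fdr, name=f"pi_up_{tissue}")
            down = responsive_set(
                wt, "down", cfg.up_fold, cfg.up_fdr, name=f"pi_down_{tissue}"
            )
            write_gene_set(up, str(self.out / f"set_pi_up_{tissue}.txt"))
            write_gene_set(down, str(self.out / f"set_pi_down_{tissue}.txt"))
            pi_up_union |= up.members
            pi_down_union |= down.members
            affected = responsive_set(
                mut_contrasts[cfg.mutants[-1]],
                "down",
                cfg.relaxed_fold,
                cfg.relaxed_fdr,
                name=f"affected_{tissue}",
            )
            write_gene_set(affected, str(self.out / f"set_affected_{tissue}.txt"))
            section[tissue] = {
                "n_up": len(up),
                "n_down": len(down),
                "n_affected": len(affected),
                "mutant_effect": _plain(table.to_dict(orient="records")),
            }
        ox = contrast(
            expr,
            samples,
            {"genotype": cfg.ox_genotype, "condition": cfg.ox_condition},
            {"genotype": cfg.ox_reference, "condition": cfg.ox_condition},
            name="ox",
        )
        ox.to_csv(self.out / "contrast_ox.tsv", sep="\t")
        dt = call_direct_targets(
            ox,
            GeneSet("pi_up_union", frozenset(pi_up_union)),
            GeneSet("pi_down_union", frozenset(pi_down_union)),
            fold=cfg.up_fold,
            fdr=cfg.up_fdr,
        )
        write_gene_set(dt.direct_targets, str(self.out / "set_direct_targets.txt"))
        section["direct_targets"] = {
            "n_ox_up": len(dt.ox_up),
            "n_ox_down": len(dt.ox_down),
            "table": _plain(dt.table.reset_index().to_dict(orient="records")),
        }
        self.report["de"] = section
        return section

    def stage_enrich(self) -> dict:
        counts = self._counts(self.pattern_a.name)
        universe = GeneSet("universe", frozenset(counts.index))
        focal = self._gene_set("direct_targets")
        focal = GeneSet(focal.name, focal.members & universe.members)
        section: dict = {}
        if len(focal) == 0:
            section["note"] = "empty direct-target set; enrichment skipped"
        else:
            table = relative_content(counts, focal, universe)
            table.to_csv(self.out / "enrichment.tsv", sep="\t")
            section["relative_content"] = _plain(
                table.reset_index().to_dict(orient="records")
            )
            section["lacking_fraction_focal"] = lacking_fraction(counts, focal)
        section["lacking_fraction_universe"] = lacking_fraction(counts, universe)
        self.report["enrich"] = section
        return section

    def stage_dose(self) -> dict:
        cfg = self.cfg
        counts = self._counts(self.pattern_a.name)
        wt = self._contrast(f"wt_{cfg.tissue}")
        up = self._gene_set(f"pi_up_{cfg.tissue}")
        genes = sorted(up.members & set(counts.index))
        section: dict = {"n_induced": len(genes), "tissue": cfg.tissue}
        if len(genes) < cfg.dose_window:
            section["note"] = "induced set smaller than window; dose curve skipped"
            self.report["dose"] = section
            return section
        log2fc = wt.loc[genes, "log2fc"]
        rho = {}
        for region in REGIONS:
            curve = dose_curve(log2fc, counts.loc[genes, region], window=cfg.dose_window)
            if region == cfg.cooccur_region:
                curve.to_csv(self.out / f"dose_curve_{region}.tsv", sep="\t", index=False)
            r = _sstats.spearmanr(curve["mean_count"], curve["mean_log2fc"])
            rho[region] = float(r.statistic) if curve["mean_count"].nunique() > 1 else 0.0
        section["spearman_rho"] = _plain(rho)
        self.report["dose"] = section
        return section

    def stage_specificity(self) -> dict:
        cfg = self.cfg
        counts = self._counts(self.pattern_a.name)
        flags = self._flags()
        up = self._gene_set(f"pi_up_{cfg.tissue}")
        genes = sorted(up.members & set(counts.index))
        cond_cols = [c for c in flags.columns if c.startswith("cond_")]
        other = flags.loc[flags.index.intersection(genes), cond_cols].astype(bool)
        res = specificity_by_count(counts.loc[genes, cfg.cooccur_region], other)
        res.bins.to_csv(self.out / "specificity_bins.tsv", sep="\t")
        section = {
            "bins": _plain(res.bins.reset_index().to_dict(orient="records")),
            "statistic": _plain(res.statistic),
            "p": _plain(res.p),
            "n_conditions": len(cond_cols),
        }
        self.report["specificity"] = section
        return section

    def stage_cooccur(self) -> dict:
        cfg = self.cfg
        _, ann, parts = self._annotation()
        up = self._gene_set(f"pi_up_{cfg.tissue}")
        parts_up = [p for p in parts if p.gene_id in up.members]
        hits = self._hits()
        a_hits, lengths = hits_in_region(
            hits, parts_up, cfg.cooccur_region, pattern=self.pattern_a.name
        )
        b_hits, _ = hits_in_region(
            hits, parts_up, cfg.cooccur_region, pattern=self.pattern_b.name
        )
        res = cooccurrence_test(
            a_hits,
            b_hits,
            lengths,
            len(self.pattern_a),
            len(self.pattern_b),
            cap=cfg.cooccur_cap,
            null=cfg.cooccur_null,
            n_perm=cfg.cooccur_n_perm,
            seed=cfg.seed,
            distance=cfg.cooccur_distance,
        )
        section = _plain(dataclasses.asdict(res))
        pd.DataFrame([section]).to_csv(self.out / "cooccurrence.tsv", sep="\t", index=False)
        self.report["cooccur"] = section
        return section

    def stage_overlap(self) -> dict:
        cfg = self.cfg
        flags = self._flags()
        expr, _ = self._expression()
        universe = GeneSet("universe", frozenset(expr.index))
        up = self._gene_set(f"pi_up_{cfg.tissue}")
        up = GeneSet(up.name, up.members & universe.members)
        cond_cols = [c for c in flags.columns if c.startswith("cond_")]
        others = {
            c: GeneSet(c, frozenset(flags.index[flags[c].astype(bool)]) & universe.members)
            for c in cond_cols[: cfg.n_overlap_conditions]
        }
        section: dict = {}
        if others and len(up):
            matrix = overlap_matrix(up, others, universe)
            matrix.to_csv(self.out / "overlaps.tsv", sep="\t")
            section["overlaps"] = _plain(matrix.reset_index().to_dict(orient="records"))
            first = next(iter(others.values()))
            shared = GeneSet("shared", up.members & first.members)
            if len(shared) and "tf_flag" in flags.columns:
                ratio, p, _tab = flag_representation(
                    shared, up, flags["tf_flag"].astype(bool)
                )
                section["tf_representation"] = {"ratio": _plain(ratio), "p": _plain(p)}
        if "gsr_flag" in flags.columns and len(up):
            gsr = GeneSet(
                "synthetic_gsr", frozenset(flags.index[flags["gsr_flag"].astype(bool)])
            )
            affected = self._gene_set(f"affected_{cfg.tissue}")
            tab = gsr_crosstab({"synthetic_gsr": gsr}, up, affected)
            tab.to_csv(self.out / "gsr_crosstab.tsv", sep="\t")
            section["gsr"] = _plain(tab.reset_index().to_dict(orient="records"))
        self.report["overlap"] = section
        return section

    # ------------------------------------------------------------------ run
    def run(self) -> dict:
        for stage in self.STAGES:
            t0 = time.perf_counter()
            try:
                getattr(self, f"stage_{stage}")()
            except Exception as err:
                self._write_report()  # retain partial outputs
                raise PipelineError(stage, err) from err
            logger.info("stage %-12s %6.2fs", stage, time.perf_counter() - t0)
        self.report["provenance"] = {
            "package": "p1bslink",
            "version": __version__,
            "seed": self.cfg.seed,
            "config_sha256": self.cfg.sha256(),
        }
        self._write_report()
        return self.report

    def _write_report(self) -> None:
        with open(self.out / "report.json", "w") as fh:
            json.dump(_plain(self.report), fh, indent=2, sort_keys=True)
            fh.write("\n")


def run_pipeline(config: PipelineConfig) -> dict:
    return Pipeline(config).run()
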