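from types import SimpleNamespace

import pytest

from p1bslink.diffexpr import contrast, responsive_set
from p1bslink.genome import partition_regions
from p1bslink.motifs import MOTIF_B, P1BS, count_by_region, scan_sequences
from p1bslink.synthetic import SyntheticConfig, generate

STUDY_SEED = 1


@pytest.fixture(scope="session")
def study():
    """One full synthetic study at the default conditions (2000 genes,
    15% direct targets, Poisson(1.5) planted copies clipped to >= 1,
    0.5 log2 per copy on a 1.5 log2 base, noise sd 0.25, 3 replicates),
    scanned and contrasted once and shared across tests."""
    cfg = SyntheticConfig(seed=STUDY_SEED)
    ds = generate(cfg)
    chrom_len = len(ds.sequences["chr1"])
    parts = [partition_regions(g, chrom_len) for g in ds.genes]
    hits = scan_sequences(ds.sequences, [P1BS, MOTIF_B])
    counts_p1bs = count_by_region(hits, parts, pattern="P1BS")
    wt_shoot = contrast(
        ds.expr,
        ds.samples,
        {"genotype": "wt", "condition": "minusPi", "tissue": "shoot"},
        {"genotype": "wt", "condition": "plusPi", "tissue": "shoot"},
        name="wt_shoot",
    )
    mutants_shoot = {
        m: contrast(
            ds.expr,
            ds.samples,
            {"genotype": m, "condition": "minusPi", "tissue": "shoot"},
            {"genotype": "wt", "condition": "minusPi", "tissue": "shoot"},
            name=f"{m}_shoot",
        )
        for m in ("phr1", "phr1_phl1")
    }
    ox = contrast(
        ds.expr,
        ds.samples,
        {"genotype": "OxGR_PHR1", "condition": "dex_chx"},
        {"genotype": "phr1", "condition": "dex_chx"},
        name="ox",
    )
    pi_up = responsive_set(wt_shoot, "up", 2.0, 0.05, name="pi_up_shoot")
    pi_down = responsive_set(wt_shoot, "down", 2.0, 0.05, name="pi_down_shoot")
    return SimpleNamespace(
        cfg=cfg,
        ds=ds,
        chrom_len=chrom_len,
        parts=parts,
        hits=hits,
        counts_p1bs=counts_p1bs,
        wt_shoot=wt_shoot,
        mutants_shoot=mutants_shoot,
        ox=ox,
        pi_up=pi_up,
        pi_down=pi_down,
    )


@pytest.fixture(scope="session")
def small_dataset():
    """A small, fast dataset for unit-level checks (deterministic)."""
    cfg = SyntheticConfig(seed=11, n_genes=120, frac_B_linked=1.0)
    return generate(cfg)
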