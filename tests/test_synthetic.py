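"""Generator contracts: determinism, planted-truth recovery, background
motif rates, and the expression noise model."""
import numpy as np
import pandas as pd
import pytest

from p1bslink.cooccurrence import hits_in_region, linked_genes
from p1bslink.genome import partition_regions
from p1bslink.motifs import MOTIF_B, P1BS, scan_sequences
from p1bslink.synthetic import SyntheticConfig, generate, generate_genome


def test_same_seed_is_byte_identical(tmp_path):
    cfg = SyntheticConfig(seed=7, n_genes=40)
    a = generate(cfg)
    b = generate(SyntheticConfig(seed=7, n_genes=40))
    assert a.sequences == b.sequences
    pd.testing.assert_frame_equal(a.truth, b.truth)
    pd.testing.assert_frame_equal(a.expr, b.expr)
    pa = a.write(tmp_path / "a")
    pb = b.write(tmp_path / "b")
    for key in pa:
        assert pa[key].read_bytes() == pb[key].read_bytes()


def test_different_seed_differs():
    a = generate(SyntheticConfig(seed=1, n_genes=30))
    b = generate(SyntheticConfig(seed=2, n_genes=30))
    assert a.sequences != b.sequences


def test_scanner_recovers_every_planted_site(small_dataset):
    ds = small_dataset
    hits = scan_sequences(ds.sequences, [P1BS, MOTIF_B])
    p1bs_starts = set(hits.loc[hits.pattern == "P1BS", "start"])
    b_starts = set(hits.loc[hits.pattern == "motifB", "start"])
    for gene_id, row in ds.truth[ds.truth["class"] == "direct_up"].iterrows():
        planted = [int(x) for x in row.p1bs_starts.split(",") if x]
        assert len(planted) == row.copies
        assert set(planted) <= p1bs_starts
        if row.b_linked:
            assert row.b_start in b_starts


def test_planted_b_sites_are_linked_within_cap(small_dataset):
    """With frac_B_linked=1, every direct gene has a motif-B hit within a
    25 bp edge gap of a P1BS hit in its proximal promoter."""
    ds = small_dataset
    chrom_len = len(ds.sequences["chr1"])
    parts = [partition_regions(g, chrom_len) for g in ds.genes]
    hits = scan_sequences(ds.sequences, [P1BS, MOTIF_B])
    a_hits, lengths = hits_in_region(hits, parts, "prox_prom", pattern="P1BS")
    b_hits, _ = hits_in_region(hits, parts, "prox_prom", pattern="motifB")
    linked = linked_genes(a_hits, b_hits, len(P1BS), len(MOTIF_B), cap=25)
    direct = ds.truth.index[ds.truth["class"] == "direct_up"]
    assert ds.truth.loc[direct, "b_linked"].all()
    assert linked.reindex(direct).all()


@pytest.mark.parametrize("gc", [0.5, 0.36])
def test_background_motif_rate_matches_closed_form(gc):
    """With no planting, genome-wide P1BS hits match the analytic window
    probability (g/2)^2 * ((1-g)/2)^4 — which is (1/4)^6 at uniform GC,
    with forward-only = both-strand because the pattern is palindromic —
    within 3 Monte-Carlo standard errors."""
    cfg = SyntheticConfig(
        seed=23, n_genes=250, frac_direct=0.0, frac_indirect_up=0.0,
        frac_repressed=0.0, gc_content=gc,
    )
    sequences, _, truth = generate_genome(cfg)
    assert (truth["class"] == "nonresponsive").all()
    hits = scan_sequences(sequences, [P1BS])
    L = len(sequences["chr1"]) - len(P1BS) + 1
    p = (gc / 2) ** 2 * ((1 - gc) / 2) ** 4
    if gc == 0.5:
        assert np.isclose(p, 0.25**6)
    expected = L * p
    se = np.sqrt(L * p * (1 - p))
    assert abs(len(hits) - expected) < 3 * se


def test_noise_free_log2fc_is_exact_arithmetic():
    """With zero noise the empirical log2FC equals the planted effect
    exactly: base + beta * copies in wt, attenuated by the genotype
    multiplier in the double mutant."""
    cfg = SyntheticConfig(
        seed=4, n_genes=60, noise_sd_log2=0.0, base_induction_log2=1.0,
        beta_per_copy=0.5,
        tissue_fracs={"both": 1.0, "shoot": 0.0, "root": 0.0},
    )
    ds = generate(cfg)

    def emp(genotype, condition, tissue="shoot"):
        cols = ds.samples.loc[
            (ds.samples.genotype == genotype)
            & (ds.samples.condition == condition)
            & (ds.samples.tissue == tissue),
            "sample",
        ]
        return ds.expr[cols].mean(axis=1)

    fc_wt = emp("wt", "minusPi") - emp("wt", "plusPi")
    fc_mut = emp("phr1_phl1", "minusPi") - emp("phr1_phl1", "plusPi")
    direct = ds.truth[ds.truth["class"] == "direct_up"]
    expected_wt = 1.0 + 0.5 * direct.copies
    assert np.allclose(fc_wt[direct.index], expected_wt, atol=1e-9)
    assert np.allclose(fc_mut[direct.index], 0.05 * expected_wt, atol=1e-9)
    # two-copy gene: the worked example 1.0 + 0.5*2 = 2.0, and 0.1 at 0.05x
    two = direct[direct.copies == 2]
    if len(two):
        g = two.index[0]
        assert np.isclose(fc_wt[g], 2.0) and np.isclose(fc_mut[g], 0.1)
    nonresp = ds.truth[ds.truth["class"] == "nonresponsive"].index
    assert np.allclose(fc_wt[nonresp], 0.0, atol=1e-9)


def test_estimated_log2fc_error_matches_sampling_theory(study):
    """MAE of estimated vs true log2FC over 2000 genes: the estimate is the
    difference of two 3-replicate means, sd = noise * sqrt(2/3), and the
    mean absolute deviation of a centred normal is sd * sqrt(2/pi)."""
    ds = study.ds
    est = study.wt_shoot["log2fc"]
    true = ds.truth["true_log2fc_wt_shoot"]
    mae = (est - true).abs().mean()
    expected = 0.25 * np.sqrt(2 / 3) * np.sqrt(2 / np.pi)
    assert abs(mae - expected) / expected < 0.06


def test_truth_invariants(study):
    tr = study.ds.truth
    direct = tr[tr["class"] == "direct_up"]
    assert (direct.copies >= 1).all()
    nonresp = tr[tr["class"] == "nonresponsive"]
    fc_cols = [c for c in tr.columns if c.startswith("true_log2fc")]
    assert (nonresp[fc_cols] == 0).all().all()
    # exact class fractions (rounded counts, not Bernoulli draws)
    assert (tr["class"] == "direct_up").sum() == 300
    assert (tr["class"] == "indirect_up").sum() == 300
    assert (tr["class"] == "repressed").sum() == 200


def test_config_validation_errors():
    with pytest.raises(ValueError, match="frac_direct"):
        SyntheticConfig(frac_direct=1.2).validate()
    with pytest.raises(ValueError, match="n_reps"):
        SyntheticConfig(n_reps=1).validate()
    with pytest.raises(ValueError, match="non-overlapping"):
        SyntheticConfig(n_genes=100, chrom_length=1000).validate()


def test_minus_strand_flag_places_half_the_genes():
    cfg = SyntheticConfig(seed=9, n_genes=20, minus_strand_half=True)
    _, genes, _ = generate_genome(cfg)
    assert sum(g.strand == "-" for g in genes) == 10
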