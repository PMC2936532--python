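"""Contrasts, BH adjustment, tiered calls, mutant table and direct targets."""
import numpy as np
import pandas as pd
import pytest

from p1bslink.diffexpr import (
    GeneSet,
    bh_adjust,
    call_direct_targets,
    call_responsive,
    contrast,
    mutant_effect_table,
    read_contrast_table,
)

from oracles import bh_stepup


def _toy_design(values: dict[str, list[float]], groups: dict[str, dict]):
    """Tiny expression matrix + sample sheet from per-group replicate lists."""
    cols, meta = [], []
    for gname, spec in groups.items():
        for r in range(len(next(iter(values.values()))[gname])):
            cols.append(f"{gname}_r{r}")
            meta.append({"sample": f"{gname}_r{r}", **spec})
    expr = pd.DataFrame(
        {
            f"{gname}_r{r}": [values[g][gname][r] for g in values]
            for gname, spec in groups.items()
            for r in range(len(next(iter(values.values()))[gname]))
        },
        index=pd.Index(list(values), name="gene_id"),
    )
    return expr, pd.DataFrame(meta)


def test_bh_adjustment_matches_stepup_oracle():
    rng = np.random.default_rng(0)
    # the worked example first: all adjusted values collapse to 0.04
    assert np.allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)
    for _ in range(100):
        m = int(rng.integers(1, 50))
        p = rng.uniform(0, 1, size=m)
        assert np.allclose(bh_adjust(p), bh_stepup(p))


def test_identical_groups_zero_noise():
    values = {"g1": {"a": [5.0, 5.0, 5.0], "b": [5.0, 5.0, 5.0]},
              "g2": {"a": [7.0, 7.0, 7.0], "b": [7.0, 7.0, 7.0]}}
    expr, samples = _toy_design(values, {"a": {"grp": "A"}, "b": {"grp": "B"}})
    cr = contrast(expr, samples, {"grp": "A"}, {"grp": "B"})
    assert np.allclose(cr["log2fc"], 0.0)
    assert np.allclose(cr["p"], 1.0)


def test_constant_unequal_groups_are_certain():
    values = {"g1": {"a": [6.0, 6.0], "b": [5.0, 5.0]}}
    expr, samples = _toy_design(values, {"a": {"grp": "A"}, "b": {"grp": "B"}})
    cr = contrast(expr, samples, {"grp": "A"}, {"grp": "B"})
    assert cr.loc["g1", "log2fc"] == 1.0
    assert cr.loc["g1", "p"] == 0.0


def test_contrast_requires_two_replicates():
    values = {"g1": {"a": [6.0, 6.0], "b": [5.0, 5.0]}}
    expr, samples = _toy_design(values, {"a": {"grp": "A"}, "b": {"grp": "B"}})
    with pytest.raises(ValueError, match="group B"):
        contrast(expr, samples.iloc[:3], {"grp": "A"}, {"grp": "B"}, name="t")


def test_welch_fallback_path():
    rng = np.random.default_rng(1)
    values = {
        f"g{i}": {"a": list(5 + rng.normal(0, 0.3, 3)), "b": list(5 + rng.normal(0, 0.3, 3))}
        for i in range(10)
    }
    expr, samples = _toy_design(values, {"a": {"grp": "A"}, "b": {"grp": "B"}})
    cr = contrast(expr, samples, {"grp": "A"}, {"grp": "B"}, moderate_var=None)
    assert ((cr["p"] >= 0) & (cr["p"] <= 1)).all()


@pytest.mark.parametrize(
    "log2fc,fdr_val,fold,fdr,expected",
    [
        (1.2, 0.01, 2.0, 0.05, "up"),
        (0.9, 0.01, 2.0, 0.05, "none"),  # 0.9 < log2(2)
        (-2.1, 0.06, 2.0, 0.05, "none"),  # FDR fails
        (-1.1, 0.01, 2.0, 0.05, "down"),
    ],
)
def test_responsiveness_call_cases(log2fc, fdr_val, fold, fdr, expected):
    cr = pd.DataFrame({"log2fc": [log2fc], "p": [0.001], "fdr": [fdr_val]},
                      index=pd.Index(["g"], name="gene_id"))
    assert call_responsive(cr, fold=fold, fdr=fdr)["g"] == expected


def test_tier_nesting_on_study_contrast(study):
    cr = study.wt_shoot
    for direction in ("up", "down"):
        t4 = set(cr.index[call_responsive(cr, 4.0, 0.05) == direction])
        t2 = set(cr.index[call_responsive(cr, 2.0, 0.05) == direction])
        t15 = set(cr.index[call_responsive(cr, 1.5, 0.1) == direction])
        assert t4 <= t2 <= t15


def test_mutant_table_full_attenuation_and_null_case():
    genes = [f"g{i}" for i in range(5)]
    wt = pd.DataFrame(
        {"log2fc": [2.0] * 5, "p": [1e-6] * 5, "fdr": [1e-6] * 5},
        index=pd.Index(genes, name="gene_id"),
    )
    fully_reduced = pd.DataFrame(
        {"log2fc": [-2.0] * 5, "p": [1e-6] * 5, "fdr": [1e-6] * 5},
        index=wt.index,
    )
    unchanged = pd.DataFrame(
        {"log2fc": [0.0] * 5, "p": [1.0] * 5, "fdr": [1.0] * 5},
        index=wt.index,
    )
    table = mutant_effect_table(wt, {"mut": fully_reduced, "same": unchanged})
    up2 = table[(table.wt_direction == "up") & (table.wt_fold == 2.0)]
    assert (up2[up2.mutant == "mut"].reduced_pct == 100.0).all()
    assert (up2[up2.mutant == "mut"].increased_pct == 0.0).all()
    assert (up2[up2.mutant == "same"].reduced_pct == 0.0).all()
    # empty wt cells are undefined, not zero
    down = table[table.wt_direction == "down"]
    assert down.reduced_pct.isna().all()


def test_mutant_table_percentage_invariants(study):
    table = mutant_effect_table(study.wt_shoot, study.mutants_shoot)
    filled = table.dropna(subset=["reduced_pct"])
    assert ((filled.reduced_pct >= 0) & (filled.reduced_pct <= 100)).all()
    assert ((filled.increased_pct >= 0) & (filled.increased_pct <= 100)).all()
    assert (filled.reduced_pct + filled.increased_pct <= 100).all()


def test_direct_target_overlap_counts():
    genes = ["g1", "g2", "g3", "g4", "g5"]
    ox = pd.DataFrame(
        {
            "log2fc": [2.0, 2.0, 2.0, -2.0, 0.0],
            "p": [1e-6] * 4 + [0.9],
            "fdr": [1e-6] * 4 + [0.9],
        },
        index=pd.Index(genes, name="gene_id"),
    )
    pi_up = GeneSet("pi_up", frozenset({"g2", "g3", "g4"}))
    pi_down = GeneSet("pi_down", frozenset({"g5"}))
    res = call_direct_targets(ox, pi_up, pi_down)
    assert res.table.loc["up", "n"] == 3
    assert res.table.loc["up", "pi_up_overlap"] == 2
    assert res.table.loc["down", "pi_down_overlap"] == 0
    assert res.direct_targets.members == {"g1", "g2", "g3"}


def test_contrast_table_round_trip(tmp_path, study):
    path = tmp_path / "wt.tsv"
    study.wt_shoot.to_csv(path, sep="\t")
    back = read_contrast_table(str(path))
    pd.testing.assert_frame_equal(back, study.wt_shoot)
    bad = tmp_path / "bad.tsv"
    bad.write_text("gene_id\tlog2fc\n g1\t1.0\n")
    with pytest.raises(ValueError, match="missing columns"):
        read_contrast_table(str(bad))
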