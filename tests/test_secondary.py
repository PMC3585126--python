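"""Secondary-assay rules: ddCT arithmetic, conjunctive calls, recovery."""

import numpy as np
import pandas as pd
import pytest

from lipidscreen.secondary_assays import (
    classify_transfection,
    ddct_fold_change,
    enzymatic_call,
    huh7_fc_call,
    ldlr_mrna_call,
    ldlr_protein_call,
    normalize_densitometry,
    overexpression_fc_effect,
    secondary_call_matrix,
)
from lipidscreen.synth import SecondaryDesign, simulate_secondary_tables
from lipidscreen.synth.secondary import OverexpressionConstruct, SecondarySirna, mock_gfp_p97


def design_with(sirnas=(), constructs=(), **kw):
    return SecondaryDesign(sirnas=list(sirnas), constructs=list(constructs), **kw)


# ------------------------------------------------------------- 2^-ddCT


def test_ddct_closed_forms():
    """ddCT of 0 gives fold 1; ddCT of 1 gives fold 0.5."""
    rows = []
    for sample, role, shift in [("cal", "untreated", 0.0), ("s_null", "candidate", 0.0),
                                ("s_half", "candidate", 1.0)]:
        for rep in (1, 2):
            for tech in (1, 2, 3):
                rows.append((sample, role, rep, tech, "LDLR", 24.0 + shift))
                rows.append((sample, role, rep, tech, "GAPDH", 18.0))
    qpcr = pd.DataFrame(rows, columns=["sample_id", "role", "replicate", "tech_rep", "gene", "ct"])
    fc = ddct_fold_change(qpcr, "GAPDH").groupby("sample_id")["fold_change"].mean()
    assert fc["s_null"] == pytest.approx(1.0)
    assert fc["s_half"] == pytest.approx(0.5)


def test_ddct_inverts_noise_free_generator_exactly():
    design = design_with([SecondarySirna("sX", "GX", ldlr_mrna_fold=0.25)], qpcr_ct_sd=0.0)
    tables = simulate_secondary_tables(design, seed=0)
    for hk in ("GAPDH", "ACTB"):
        fc = ddct_fold_change(tables["qpcr"], hk)
        got = fc[fc["sample_id"] == "sX"]["fold_change"]
        np.testing.assert_allclose(got, 0.25, rtol=1e-12)


def test_ddct_invariant_to_per_sample_ct_offset():
    design = design_with([SecondarySirna("sX", "GX", ldlr_mrna_fold=0.5)])
    qpcr = simulate_secondary_tables(design, seed=1)["qpcr"]
    base = ddct_fold_change(qpcr, "GAPDH")
    shifted = qpcr.copy()
    # a plate offset adds the same constant to every CT of a sample
    offsets = {s: o for s, o in zip(shifted["sample_id"].unique(),
                                    np.linspace(-2, 2, shifted["sample_id"].nunique()))}
    shifted["ct"] = shifted["ct"] + shifted["sample_id"].map(offsets)
    out = ddct_fold_change(shifted, "GAPDH")
    np.testing.assert_allclose(out["fold_change"], base["fold_change"], rtol=1e-10)


def test_ddct_missing_housekeeper_errors():
    design = design_with([SecondarySirna("sX", "GX")])
    qpcr = simulate_secondary_tables(design, seed=2)["qpcr"]
    with pytest.raises(ValueError, match="missing CT"):
        ddct_fold_change(qpcr[qpcr["gene"] != "GAPDH"], "GAPDH")


def test_mrna_call_rules():
    design = design_with(
        [SecondarySirna("s_down", "GD", ldlr_mrna_fold=1 / 3),
         SecondarySirna("s_null", "GN", ldlr_mrna_fold=1.0)],
        qpcr_ct_sd=0.05,
    )
    qpcr = simulate_secondary_tables(design, seed=3)["qpcr"]
    folds = {hk: ddct_fold_change(qpcr, hk) for hk in ("GAPDH", "ACTB")}
    down = ldlr_mrna_call(folds, "s_down")
    null = ldlr_mrna_call(folds, "s_null")
    assert down.direction == "-"
    assert null.direction == "n.s."
    missing = ldlr_mrna_call({"GAPDH": folds["GAPDH"]}, "s_down")
    assert missing.direction == "untestable"


def test_mrna_recovery_rate_over_seeds():
    hits = 0
    for seed in range(20):
        design = design_with([SecondarySirna("sX", "GX", ldlr_mrna_fold=1 / 3)], qpcr_ct_sd=0.08)
        qpcr = simulate_secondary_tables(design, seed=100 + seed)["qpcr"]
        folds = {hk: ddct_fold_change(qpcr, hk) for hk in ("GAPDH", "ACTB")}
        hits += ldlr_mrna_call(folds, "sX").direction == "-"
    assert hits >= 18  # >= 90% of 20 seeds


# ------------------------------------------------------------ enzymatic


def test_enzymatic_equal_means_not_significant():
    rng = np.random.default_rng(0)
    ctrl, mock = rng.normal(100, 2, 6), rng.normal(100, 2, 6)
    out = enzymatic_call(rng.normal(100, 2, 6), ctrl, mock, "s")
    assert out.direction == "n.s."
    with pytest.raises(ValueError):
        enzymatic_call([1.0], [], mock)


def test_enzymatic_conjunction_requires_both_tests():
    rng = np.random.default_rng(1)
    ctrl = rng.normal(100, 1, 6)
    noisy_mock = rng.normal(100, 40, 6)  # wide mock defeats its t-test
    x = rng.normal(106, 1, 6)  # > 2 pooled sd away, t-test vs ctrl passes
    out = enzymatic_call(x, ctrl, noisy_mock, "s")
    assert out.direction == "n.s."


def test_enzymatic_recovery_of_planted_shift():
    called = 0
    for seed in range(20):
        design = design_with([SecondarySirna("sX", "GX", cholesterol_fold=0.7)])
        table = simulate_secondary_tables(design, seed=200 + seed)["enzymatic"]
        x = table[table["sirna_id"] == "sX"]["reading"]
        ctrl = table[table["role"] == "control_sirna"]["reading"]
        mock = table[table["role"] == "mock"]["reading"]
        call = enzymatic_call(x, ctrl, mock, "sX")
        called += call.direction == "-"
    assert called >= 18


# ------------------------------------------------------------- HuH7 FC


def test_huh7_untestable_below_cell_count():
    rng = np.random.default_rng(2)
    reps = [rng.normal(size=40) for _ in range(3)]
    ctrl = [rng.normal(size=200) for _ in range(3)]
    assert huh7_fc_call(reps, ctrl).direction == "untestable"


def test_huh7_null_and_planted_calls():
    rng = np.random.default_rng(3)
    null_sig = 0
    for _ in range(30):
        reps = [rng.normal(0, 1, 200) for _ in range(3)]
        ctrl = [rng.normal(0, 1, 200) for _ in range(3)]
        null_sig += huh7_fc_call(reps, ctrl).significant
    assert null_sig / 30 <= 0.05

    strong = [rng.normal(2.0, 1, 200) for _ in range(3)]
    ctrl = [rng.normal(0, 1, 200) for _ in range(3)]
    out = huh7_fc_call(strong, ctrl)
    assert out.direction == "+"


# ---------------------------------------------------------- densitometry


def test_densitometry_normalization_and_rescale_invariance():
    design = design_with([SecondarySirna("sX", "GX", ldlr_protein_fold=0.5)], western_cv=0.03)
    west = simulate_secondary_tables(design, seed=4)["western"]
    norm = normalize_densitometry(west)
    ctrl = norm[norm["role"].isin(["untreated", "control_sirna"])]
    assert ctrl["ldlr_norm"].mean() == pytest.approx(1.0, abs=0.05)

    # rescaling all lanes of one gel cancels out
    scaled = west.copy()
    gel = scaled["gel_id"] == "gel01"
    scaled.loc[gel, ["ldlr_density", "tubulin_density"]] *= 7.3
    norm2 = normalize_densitometry(scaled)
    np.testing.assert_allclose(norm2["ldlr_norm"], norm["ldlr_norm"], rtol=1e-10)


def test_protein_call_rules_and_recovery():
    called = 0
    for seed in range(20):
        design = design_with([SecondarySirna("sX", "GX", ldlr_protein_fold=0.5)],
                             western_cv=0.05, lane_cv=0.05)
        west = simulate_secondary_tables(design, seed=300 + seed)["western"]
        norm = normalize_densitometry(west)
        called += ldlr_protein_call(norm, "sX").direction == "-"
    assert called >= 18

    null_design = design_with([SecondarySirna("sN", "GN")], western_cv=0.05, lane_cv=0.05)
    norm = normalize_densitometry(simulate_secondary_tables(null_design, seed=5)["western"])
    assert ldlr_protein_call(norm, "sN").direction == "n.s."
    assert ldlr_protein_call(norm, "missing").direction == "untestable"


# ------------------------------------------------------- overexpression


def test_transfection_classification_rules():
    rng = np.random.default_rng(6)
    mock = pd.DataFrame({"gfp_total": rng.lognormal(np.log(100), 0.5, 500)})
    t = np.percentile(mock["gfp_total"], 97)
    cells = pd.DataFrame({"gfp_total": [5 * t, 0.5 * t, 2 * t], "dish": 1})
    out = classify_transfection(cells, mock)
    assert list(out["transfection_class"]) == ["transfected", "untransfected", "intermediate"]
    with pytest.raises(ValueError):
        classify_transfection(cells, mock.head(10))


def test_transfected_fraction_recovered():
    design = design_with(
        constructs=[OverexpressionConstruct("GX", gfp_multiplier=10, transfected_fraction=0.3)]
    )
    tables = simulate_secondary_tables(design, seed=7)["overexpression"]
    mock = tables[tables["construct"] == "mock"]
    cells = tables[tables["construct"] == "GX"]
    out = classify_transfection(cells, mock)
    frac = (out["transfection_class"] == "transfected").mean()
    assert frac == pytest.approx(0.30, abs=0.02)


def test_overexpression_null_and_doubling():
    design = design_with(
        constructs=[
            OverexpressionConstruct("G_null", filipin_ratio=1.0),
            OverexpressionConstruct("G_double", filipin_ratio=2.0),
        ],
        filipin_cv=0.2,
    )
    tables = simulate_secondary_tables(design, seed=8)["overexpression"]
    mock = tables[tables["construct"] == "mock"]
    for gene, expect_ratio, expect_sig in [("G_null", 1.0, "n.s."), ("G_double", 2.0, "***")]:
        cells = classify_transfection(tables[tables["construct"] == gene], mock)
        out = overexpression_fc_effect(cells, mock, construct=gene)
        assert out["ratio_vs_untransfected"] == pytest.approx(expect_ratio, rel=0.1)
        assert out["significance"] == expect_sig


def test_concentration_dependent_effect_gives_positive_trend():
    pos = 0
    for seed in range(10):
        design = design_with(
            constructs=[OverexpressionConstruct("GX", filipin_ratio=2.0, gfp_coupling=True)]
        )
        tables = simulate_secondary_tables(design, seed=400 + seed)["overexpression"]
        mock = tables[tables["construct"] == "mock"]
        cells = classify_transfection(tables[tables["construct"] == "GX"], mock)
        out = overexpression_fc_effect(cells, mock, construct="GX")
        pos += out["trend_slope_sign"] > 0
    assert pos >= 9


# ----------------------------------------------------- summary matrix


def test_secondary_call_matrix_symbols():
    from lipidscreen.secondary_assays import SecondaryCall

    calls = [
        SecondaryCall("s1", "enzymatic", "+"),
        SecondaryCall("s2", "enzymatic", "+"),
        SecondaryCall("s3", "qpcr", "-"),
        SecondaryCall("s4", "qpcr", "n.s."),
        SecondaryCall("s5", "western", "+"),
        SecondaryCall("s6", "western", "-"),
    ]
    gene_map = {"s1": "A", "s2": "A", "s3": "B", "s4": "B", "s5": "C", "s6": "C"}
    m = secondary_call_matrix(calls, gene_map)
    assert m.loc["A", "enzymatic"] == "+"
    assert m.loc["B", "qpcr"] == "(-)"
    assert m.loc["C", "western"] == "-/+"
    assert m.loc["A", "qpcr"] == "n.d."


def test_null_calibration_call_rate_small():
    """Effect-free tables rarely produce calls in any assay."""
    n_calls = n_tests = 0
    for seed in range(15):
        design = design_with([SecondarySirna("sN", "GN")])
        tables = simulate_secondary_tables(design, seed=500 + seed)
        folds = {hk: ddct_fold_change(tables["qpcr"], hk) for hk in ("GAPDH", "ACTB")}
        n_calls += ldlr_mrna_call(folds, "sN").significant
        norm = normalize_densitometry(tables["western"])
        n_calls += ldlr_protein_call(norm, "sN").significant
        enz = tables["enzymatic"]
        n_calls += enzymatic_call(
            enz[enz["sirna_id"] == "sN"]["reading"],
            enz[enz["role"] == "control_sirna"]["reading"],
            enz[enz["role"] == "mock"]["reading"],
        ).significant
        n_tests += 3
    assert n_calls / n_tests <= 0.05
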