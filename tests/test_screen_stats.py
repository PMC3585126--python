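"""Deviation-value statistics, thresholds, effector and hit calling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lipidscreen.screen_stats import (
    DegenerateControlsError,
    DeviationTable,
    ThresholdSet,
    PUBLISHED_THRESHOLDS,
    aggregate_deviations,
    call_effector_sirnas,
    call_hit_genes,
    compute_deviations,
    control_error,
    control_normality_check,
    deviation_value,
    effector_thresholds,
    empirical_fdr,
    parameter_correlations,
    summarize_replicates,
    validation_rate,
)
from lipidscreen.synth import EffectSpec, SceneSpec, simulate_screen


def make_dev_table(rows):
    per_rep = pd.DataFrame(
        rows, columns=["position_id", "sirna_id", "role", "parameter", "replicate", "deviation"]
    )
    return DeviationTable(per_replicate=per_rep, means=aggregate_deviations(per_rep))


# ------------------------------------------------------ deviation value


def test_deviation_value_hand_example():
    """Controls {1, 3}: mean 2, mean absolute deviation 1 -> (6-2)/2 = 2."""
    assert deviation_value(6.0, [1.0, 3.0]) == pytest.approx(2.0)
    assert deviation_value(2.0, [1.0, 3.0]) == 0.0


def test_deviation_value_is_odd_about_control_mean():
    ctrl = [4.0, 5.5, 6.5, 8.0]
    center = np.mean(ctrl)
    for x in (0.3, 1.7, 9.2):
        assert deviation_value(center + x, ctrl) == pytest.approx(
            -deviation_value(center - x, ctrl)
        )


def test_deviation_value_scale_invariance_with_mad():
    ctrl = [2.0, 3.0, 7.0, 8.5]
    base = deviation_value(11.0, ctrl)
    for c in (0.1, 3.0, 250.0):
        scaled = deviation_value(11.0 * c, [v * c for v in ctrl])
        assert scaled == pytest.approx(base, rel=1e-12)


def test_degenerate_controls_raise():
    with pytest.raises(DegenerateControlsError):
        deviation_value(1.0, [2.0, 2.0, 2.0])
    with pytest.raises(ValueError):
        deviation_value(1.0, [2.0])


def test_error_estimators():
    x = np.array([1.0, 3.0])
    assert control_error(x, "mad") == 1.0
    assert control_error(x, "sd") == pytest.approx(np.sqrt(2))
    assert control_error(x, "sem") == pytest.approx(1.0)


@given(st.lists(st.floats(-50, 50), min_size=3, max_size=12), st.floats(-50, 50))
@settings(max_examples=50, deadline=None)
def test_deviation_monotone_in_sirna_mean(ctrl, x):
    ctrl = np.asarray(ctrl)
    if np.abs(ctrl - ctrl.mean()).mean() < 1e-6:
        return
    assert deviation_value(x + 1.0, ctrl) > deviation_value(x, ctrl)


# ----------------------------------------------------------- aggregation


def test_aggregate_mean_examples_and_oracle():
    rows = [("p1", "s1", "candidate", "total", r, d) for r, d in enumerate([-1.0, 0.0, 1.0])]
    rows += [("p2", "s2", "candidate", "total", 0, 0.7)]
    table = make_dev_table(rows)
    m = table.means.set_index("sirna_id")["mean_deviation"]
    assert m["s1"] == 0.0
    assert m["s2"] == 0.7

    rng = np.random.default_rng(0)
    for _ in range(20):
        vals = rng.normal(size=rng.integers(1, 8))
        rows = [("p", "s", "candidate", "total", r, v) for r, v in enumerate(vals)]
        got = make_dev_table(rows).means["mean_deviation"].iloc[0]
        assert got == pytest.approx(vals.mean(), rel=1e-12)


def test_control_centering_is_exact(null_screen_fc):
    """Negative-control deviations average to zero within each replicate."""
    res = null_screen_fc
    summaries = summarize_replicates(res.cells, res.layout)
    table = compute_deviations(summaries, assay=res.assay)
    neg = table.per_replicate[table.per_replicate["role"] == "negative_control"]
    for (_, _), grp in neg.groupby(["parameter", "replicate"]):
        assert abs(grp["deviation"].mean()) < 1e-10


def test_replicate_summary_averages_images_then_replicates():
    cells = pd.DataFrame(
        {
            "position_id": ["A01"] * 4,
            "replicate": [1, 1, 1, 1],
            "image": [0, 0, 1, 1],
            "cell_id": [0, 1, 0, 1],
            "assay": "free_cholesterol",
            "total": [3.0, 5.0, 5.0, 7.0],  # image means 4 and 6 -> replicate mean 5
            "concentration": 1.0,
            "structures": 1,
            "area": 1.0,
            "cell_area": 10.0,
            "nucleus_area": 2.0,
        }
    )
    from lipidscreen.synth import ControlSpec, make_plate_layout

    layout = make_plate_layout("plate_96", [("sX", "GX")], ControlSpec(mock=3), seed=0)
    layout.positions.loc[0, "position_id"] = "A01"  # place the candidate at A01
    layout.positions.loc[0, ["sirna_id", "gene", "role"]] = ["sX", "GX", "candidate"]
    summ = summarize_replicates(cells, layout)
    row = summ[(summ["position_id"] == "A01") & (summ["parameter"] == "total")]
    assert row["mean_value"].iloc[0] == 5.0
    assert row["n_images"].iloc[0] == 2

    # excluding one failed image leaves the mean of the remaining one
    summ2 = summarize_replicates(cells, layout, failed_images={("A01", 1, 0)})
    row2 = summ2[(summ2["position_id"] == "A01") & (summ2["parameter"] == "total")]
    assert row2["mean_value"].iloc[0] == 6.0


# ------------------------------------------------------------ thresholds


def test_threshold_formula_on_constructed_controls():
    """Two controls with means -0.2/0.1 and overall value sd 0.3 over nine
    replicates give SEM 0.1 and bounds [-0.5, 0.4]."""
    x = 0.375 / np.sqrt(2)  # alternating offsets with zero sum
    a_off = np.array([x, -x] * 4 + [0.0])
    target_ss = 17 * 0.09 - 18 * 0.0225  # required sum of squared offsets
    scale = np.sqrt(target_ss / (2 * (a_off**2).sum()))
    a_vals = -0.2 + a_off * scale
    b_vals = 0.1 + a_off * scale
    allv = np.concatenate([a_vals, b_vals])
    assert np.std(allv, ddof=1) == pytest.approx(0.3)

    rows = [("pA", "neg", "negative_control", "total", r, v) for r, v in enumerate(a_vals)]
    rows += [("pB", "neg", "negative_control", "total", r, v) for r, v in enumerate(b_vals)]
    table = make_dev_table(rows)
    thr = effector_thresholds(table, "total", n_replicates=9)
    assert thr.lower == pytest.approx(-0.5)
    assert thr.upper == pytest.approx(0.4)


def test_thresholds_symmetric_for_centered_controls():
    rng = np.random.default_rng(1)
    vals = rng.normal(0, 0.3, size=12)
    rows = []
    for i in range(4):
        sub = vals[i * 3:(i + 1) * 3] - vals[i * 3:(i + 1) * 3].mean()  # mean 0 per control
        rows += [(f"p{i}", "neg", "negative_control", "total", r, v) for r, v in enumerate(sub)]
    table = make_dev_table(rows)
    thr = effector_thresholds(table, "total", n_replicates=3)
    sem = table.per_replicate["deviation"].std(ddof=1) / np.sqrt(3)
    assert thr.upper == pytest.approx(3 * sem)
    assert thr.lower == pytest.approx(-3 * sem)


def test_published_threshold_classification():
    thr = PUBLISHED_THRESHOLDS[("ldl_uptake", "GWAS2")]
    assert (thr.lower, thr.upper) == (-0.55, 1.02)
    assert thr.classify(-1.47) == "decrease"  # LDLR siRNA s224006
    assert thr.classify(1.32) == "increase"  # TBL2 siRNA s226084
    assert thr.classify(1.02) == "none"  # boundary equality is not a call
    assert thr.classify(-0.55) == "none"
    assert thr.classify(np.nan) == "none"


def test_region_normalization_removes_edge_artifact(layout_96):
    scene = SceneSpec(assay="free_cholesterol", seed=4)
    res = simulate_screen(layout_96, {}, 3, scene, seed=33)
    summaries = summarize_replicates(res.cells, res.layout)
    raw = compute_deviations(summaries, assay=res.assay, region_normalize=False)
    norm = compute_deviations(summaries, assay=res.assay, region_normalize=True)

    def region1_mean(table):
        m = table.means.merge(
            res.layout.positions[["position_id", "region"]], on="position_id"
        )
        sub = m[(m["role"] == "candidate") & (m["parameter"] == "total") & (m["region"] == 1)]
        return sub["mean_deviation"].mean()

    assert region1_mean(raw) < -0.5  # edge factor 0.85 depresses edge wells
    assert abs(region1_mean(norm)) < 0.5


def test_uniform_plate_region_and_plate_normalization_agree(layout_96):
    scene = SceneSpec(assay="free_cholesterol", seed=4, edge_factors=(1.0, 1.0, 1.0))
    res = simulate_screen(layout_96, {}, 3, scene, seed=35)
    summaries = summarize_replicates(res.cells, res.layout)
    raw = compute_deviations(summaries, assay=res.assay, region_normalize=False)
    norm = compute_deviations(summaries, assay=res.assay, region_normalize=True)
    merged = raw.means.merge(
        norm.means, on=["position_id", "sirna_id", "role", "parameter"], suffixes=("_r", "_n")
    )
    cand = merged[(merged["role"] == "candidate") & (merged["parameter"] == "total")]
    # same underlying data; differences reflect the smaller control pool only
    assert (cand["mean_deviation_r"] - cand["mean_deviation_n"]).abs().mean() < 0.6


# ---------------------------------------------------- normality checks


def test_normality_check_calibration_and_power():
    rng = np.random.default_rng(7)
    normal_ps = [
        control_normality_check(rng.normal(size=100))["p_value"] for _ in range(40)
    ]
    assert np.mean(np.array(normal_ps) > 0.01) >= 0.95
    lognormal_ps = [
        control_normality_check(rng.lognormal(0, 1, size=100))["p_value"] for _ in range(40)
    ]
    assert np.mean(np.array(lognormal_ps) < 0.01) >= 0.95
    with pytest.raises(DegenerateControlsError):
        control_normality_check([1.0, 1.0, 1.0])
    with pytest.raises(ValueError):
        control_normality_check([1.0, 2.0])


# ------------------------------------------------------------ hit calls


def test_two_sirna_rule_gene_calls():
    thr = ThresholdSet("ldl_uptake", "total", -0.55, 1.02)
    rows = []
    devs = {
        "s224006": -1.47, "s224007": -0.9, "s6": -0.7,  # LDLR: three effectors
        "sA_1": 1.5, "sA_2": 0.0, "sA_3": 0.2, "sA_4": 0.1,  # one of four
        "sB_1": 0.3,  # single-siRNA gene: untestable by rule
    }
    for i, (sid, d) in enumerate(devs.items()):
        rows.append((f"p{i}", sid, "candidate", "total", 0, d))
    table = make_dev_table(rows)
    calls = call_effector_sirnas(table, thr)
    gene_map = {"s224006": "LDLR", "s224007": "LDLR", "s6": "LDLR",
                "sA_1": "A", "sA_2": "A", "sA_3": "A", "sA_4": "A", "sB_1": "B"}
    genes = call_hit_genes(calls, gene_map).set_index("gene")
    assert genes.loc["LDLR", "is_hit"]
    assert set(genes.loc["LDLR", "supporting_sirnas"].split(",")) == {"s224006", "s224007", "s6"}
    assert genes.loc["LDLR", "direction_consistent"]
    assert not genes.loc["A", "is_hit"]
    assert not genes.loc["B", "is_hit"] and genes.loc["B", "untestable"]


def test_validation_rate_examples():
    s1 = {f"s{i}" for i in range(63)}
    s2 = {f"s{i}" for i in range(30)}
    out = validation_rate(s1, s2)
    assert out == {"n_effectors_s1": 63, "n_validated": 30, "rate_percent": 48}
    assert validation_rate(s1, s1)["rate_percent"] == 100
    assert validation_rate(s1, set())["rate_percent"] == 0
    assert validation_rate(set(), s2)["rate_percent"] is None


# --------------------------------------------------------- correlations


def test_parameter_correlations_identities_and_oracle():
    rng = np.random.default_rng(3)
    for _ in range(10):
        wide = pd.DataFrame(rng.normal(size=(30, 4)), columns=list("abcd"))
        corr = parameter_correlations(wide)
        assert np.allclose(np.diag(corr), 1.0)
        for i in "abcd":
            for j in "abcd":
                x, y = wide[i].to_numpy(), wide[j].to_numpy()
                manual = ((x - x.mean()) * (y - y.mean())).sum() / np.sqrt(
                    ((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()
                )
                assert corr.loc[i, j] == pytest.approx(manual, abs=1e-12)
    wide["e"] = -wide["a"]
    assert parameter_correlations(wide).loc["a", "e"] == pytest.approx(-1.0)
    wide["f"] = 2.5
    assert np.isnan(parameter_correlations(wide).loc["f", "a"])


# -------------------------------------------------------- empirical FDR


def test_empirical_p_values_add_one_rule():
    ctrl = np.linspace(-1, 1, 100)
    out = empirical_fdr(np.array([0.0, 5.0, -5.0]), ctrl)
    assert out["p_value"].iloc[0] > 0.9  # at the control median
    assert out["p_value"].iloc[1] == pytest.approx(2 / 101)
    assert out["p_value"].iloc[2] == pytest.approx(2 / 101)
    with pytest.raises(ValueError):
        empirical_fdr(np.array([0.0]), ctrl[:5])


def test_bh_adjustment_matches_stepup_oracle():
    rng = np.random.default_rng(11)
    ctrl = rng.normal(size=200)
    for _ in range(10):
        devs = rng.normal(0, 2, size=25)
        out = empirical_fdr(devs, ctrl)
        p = out["p_value"].to_numpy()
        m = len(p)
        order = np.argsort(p)
        adj = np.empty(m)
        running = 1.0
        for rank in range(m, 0, -1):
            i = order[rank - 1]
            running = min(running, p[i] * m / rank)
            adj[i] = running
        np.testing.assert_allclose(out["fdr"].to_numpy(), adj, atol=1e-12)


# --------------------------------------------------- screen-level checks


def test_planted_screen_recovery(planted_screen_fc, layout_384):
    res, effects = planted_screen_fc
    summaries = summarize_replicates(res.cells, res.layout)
    table = compute_deviations(summaries, assay=res.assay, region_normalize=True)
    thr = effector_thresholds(table, "total", n_replicates=3)
    calls = call_effector_sirnas(table, thr)

    ctrl = calls[calls["role"].isin(["negative_control", "mock"])]
    assert (ctrl["direction"] != "none").sum() == 0  # control self-exclusion

    cand = layout_384.by_role("candidate")
    genes = call_hit_genes(calls, dict(zip(cand["sirna_id"], cand["gene"])))
    true_genes = {g for g in (e.sirna_id.split("_")[0][1:] for e in effects.values())}
    hits = set(genes[genes["is_hit"]]["gene"])
    sens = len(hits & true_genes) / len(true_genes)
    false = len(hits - true_genes)
    assert sens >= 0.8
    assert false <= 2
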