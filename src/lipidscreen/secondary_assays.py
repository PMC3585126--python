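"""Secondary-assay decision rules.

Each rule is deliberately conjunctive — an effect-size criterion against
control spread AND explicit t-tests — so dropping any sub-criterion can
only increase the number of calls:

* enzymatic cholesterol: mean beyond 2 sd of the pooled negative controls
  and p < 0.05 vs both control-siRNA and mock groups;
* HuH7 free cholesterol: >= 50 quantified cells per replica, mean
  deviation outside the controls' mean +/- 2 SEM band, and p < 0.05 in at
  least two replicas;
* LDLR mRNA (2^-ddCT): beyond 2 sd on both housekeeper normalizations
  (published control sd 0.21 for GAPDH, 0.20 for ACTB) and four t-tests
  (untreated/mock x both housekeepers) at p < 0.01;
* LDLR protein (densitometry): per-gel normalization, 2 sd on both the
  absolute (sd 0.13) and tubulin-normalized (sd 0.18) scales, four
  t-tests at p < 0.01;
* GFP overexpression: per-cell transfection classes from the mock GFP
  97th percentile, filipin ratios of transfected vs mock/untransfected
  cells, significance stars from per-replica t-tests at p < 0.01.

Student's t-tests use the Welch (unequal-variance) form by default; a
flag restores the pooled-variance form.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

#: published control standard deviations accepted as defaults
MRNA_CONTROL_SD = {"GAPDH": 0.21, "ACTB": 0.20}
PROTEIN_CONTROL_SD = {"ldlr": 0.13, "ldlr_tub": 0.18}


@dataclass
class SecondaryCall:
    """Verdict of one secondary assay for one siRNA or gene."""

    target: str
    assay: str
    direction: str  # "+", "-", "n.s." or "untestable"
    p_values: list[float] = field(default_factory=list)
    effect: float | None = None
    detail: dict = field(default_factory=dict)

    @property
    def significant(self) -> bool:
        return self.direction in ("+", "-")


def _ttest(a, b, equal_var: bool = False) -> float:
    return float(stats.ttest_ind(a, b, equal_var=equal_var).pvalue)


# ---------------------------------------------------------------------------
# enzymatic cholesterol
# ---------------------------------------------------------------------------

def enzymatic_call(
    readings: pd.Series | np.ndarray,
    control_sirna_readings,
    mock_readings,
    sirna_id: str = "",
    equal_var: bool = False,
) -> SecondaryCall:
    """Call one siRNA from plate-reader cholesterol readings.

    Requires the replicate mean to deviate > 2 sd from the pooled negative
    controls AND p < 0.05 in t-tests against both control groups.
    """
    x = np.asarray(readings, dtype=float)
    ctrl = np.asarray(control_sirna_readings, dtype=float)
    mock = np.asarray(mock_readings, dtype=float)
    if len(ctrl) == 0 or len(mock) == 0:
        raise ValueError("both control groups are required")
    pooled = np.concatenate([ctrl, mock])
    delta = x.mean() - pooled.mean()
    p1, p2 = _ttest(x, ctrl, equal_var), _ttest(x, mock, equal_var)
    passed = abs(delta) > 2 * pooled.std(ddof=1) and p1 < 0.05 and p2 < 0.05
    return SecondaryCall(
        target=sirna_id,
        assay="enzymatic",
        direction=("+" if delta > 0 else "-") if passed else "n.s.",
        p_values=[p1, p2],
        effect=float(x.mean() / pooled.mean()),
    )


# ---------------------------------------------------------------------------
# HuH7 free-cholesterol validation
# ---------------------------------------------------------------------------

def huh7_fc_call(
    replica_cells: list[np.ndarray],
    control_replica_cells: list[np.ndarray],
    sirna_id: str = "",
    min_cells: int = 50,
    equal_var: bool = False,
) -> SecondaryCall:
    """Validate one siRNA on per-cell FC values from HuH7 liver cells.

    ``replica_cells[i]`` holds the quantified per-cell values of replica
    ``i``; replicas under ``min_cells`` cells are excluded.  The call needs
    the replicate-mean deviation outside the controls' mean +/- 2 SEM band
    and p < 0.05 in at least two usable replicas.
    """
    usable = [
        (np.asarray(x, float), np.asarray(c, float))
        for x, c in zip(replica_cells, control_replica_cells)
        if len(x) >= min_cells
    ]
    if not usable:
        return SecondaryCall(target=sirna_id, assay="huh7_fc", direction="untestable")
    rep_means = np.array([x.mean() for x, _ in usable])
    ctrl_means = np.array([c.mean() for _, c in usable])
    sem = ctrl_means.std(ddof=1) / np.sqrt(len(ctrl_means)) if len(ctrl_means) > 1 else 0.0
    delta = rep_means.mean() - ctrl_means.mean()
    outside = abs(delta) > 2 * sem and sem > 0
    pvals = [_ttest(x, c, equal_var) for x, c in usable]
    n_sig = sum(p < 0.05 for p in pvals)
    passed = outside and n_sig >= 2
    return SecondaryCall(
        target=sirna_id,
        assay="huh7_fc",
        direction=("+" if delta > 0 else "-") if passed else "n.s.",
        p_values=pvals,
        effect=float(rep_means.mean() / ctrl_means.mean()),
        detail={"n_replicas": len(usable), "n_significant": n_sig},
    )


# ---------------------------------------------------------------------------
# LDLR mRNA: 2^-ddCT
# ---------------------------------------------------------------------------

def ddct_fold_change(
    qpcr_records: pd.DataFrame,
    housekeeper: str,
    calibrator_roles: tuple[str, ...] = ("untreated", "mock"),
    target_gene: str = "LDLR",
) -> pd.DataFrame:
    """Per-sample 2^-ddCT fold changes of *target_gene* vs *housekeeper*.

    Technical replicates are averaged on the CT scale; dCT = CT_target -
    CT_housekeeper per (sample, biological replicate); ddCT subtracts the
    mean calibrator dCT.  Returns sample_id, role, replicate, fold_change.
    """
    ct = (
        qpcr_records.groupby(["sample_id", "role", "replicate", "gene"])["ct"]
        .mean()
        .unstack("gene")
    )
    for gene in (target_gene, housekeeper):
        if gene not in ct.columns or ct[gene].isna().any():
            raise ValueError(f"missing CT values for {gene}")
    dct = (ct[target_gene] - ct[housekeeper]).rename("dct").reset_index()
    calib = dct[dct["role"].isin(calibrator_roles)]["dct"]
    if calib.empty:
        raise ValueError("no calibrator samples")
    dct["fold_change"] = 2.0 ** -(dct["dct"] - calib.mean())
    return dct[["sample_id", "role", "replicate", "fold_change"]]


def ldlr_mrna_call(
    fold_changes: dict[str, pd.DataFrame],
    sirna_id: str,
    control_sd: dict[str, float] | None = None,
    equal_var: bool = False,
    alpha: float = 0.01,
) -> SecondaryCall:
    """Call one siRNA from 2^-ddCT fold changes of both housekeepers.

    ``fold_changes`` maps housekeeper name to the table from
    :func:`ddct_fold_change`.  The 2 sd criterion (published control sd by
    default) must hold on both normalizations, and all four t-tests (vs
    untreated and mock, per housekeeper) must reach p < 0.01.
    """
    control_sd = control_sd or MRNA_CONTROL_SD
    if set(fold_changes) != set(control_sd):
        return SecondaryCall(target=sirna_id, assay="ldlr_mrna", direction="untestable")
    pvals, deltas, sd_ok = [], [], []
    for hk, table in fold_changes.items():
        x = table[table["sample_id"] == sirna_id]["fold_change"].to_numpy()
        if len(x) == 0:
            return SecondaryCall(target=sirna_id, assay="ldlr_mrna", direction="untestable")
        ctrl = table[table["role"].isin(("untreated", "mock"))]["fold_change"]
        delta = x.mean() - ctrl.mean()
        deltas.append(delta)
        sd_ok.append(abs(delta) > 2 * control_sd[hk])
        for role in ("untreated", "mock"):
            grp = table[table["role"] == role]["fold_change"].to_numpy()
            pvals.append(_ttest(x, grp, equal_var))
    passed = all(sd_ok) and all(p < alpha for p in pvals) and len(pvals) == 4
    direction = ("+" if np.mean(deltas) > 0 else "-") if passed else "n.s."
    return SecondaryCall(
        target=sirna_id,
        assay="ldlr_mrna",
        direction=direction,
        p_values=pvals,
        effect=float(np.mean(deltas) + 1.0),
    )


# ---------------------------------------------------------------------------
# LDLR protein: Western densitometry
# ---------------------------------------------------------------------------

def normalize_densitometry(records: pd.DataFrame) -> pd.DataFrame:
    """Normalize band densities to the control-lane average of each gel.

    Adds ``ldlr_norm`` (absolute LDLR scale) and ``ldlr_tub_norm``
    (LDLR/tubulin scale); flagged lanes are dropped; a gel without control
    lanes leaves its candidate lanes untestable (NaN).
    """
    recs = records[~records["flagged"].astype(bool)].copy()
    recs["ldlr_tub"] = recs["ldlr_density"] / recs["tubulin_density"]
    out = []
    for _gel, grp in recs.groupby("gel_id"):
        ctrl = grp[grp["role"].isin(("untreated", "control_sirna"))]
        g = grp.copy()
        if ctrl.empty:
            g["ldlr_norm"] = np.nan
            g["ldlr_tub_norm"] = np.nan
        else:
            g["ldlr_norm"] = g["ldlr_density"] / ctrl["ldlr_density"].mean()
            g["ldlr_tub_norm"] = g["ldlr_tub"] / ctrl["ldlr_tub"].mean()
        out.append(g)
    return pd.concat(out, ignore_index=True)


def ldlr_protein_call(
    normalized: pd.DataFrame,
    sirna_id: str,
    control_sd: dict[str, float] | None = None,
    equal_var: bool = False,
    alpha: float = 0.01,
) -> SecondaryCall:
    """Call one siRNA from gel-normalized densitometry.

    Requires the 2 sd criterion on both the absolute-LDLR and LDLR/tubulin
    scales and four t-tests (vs untreated and control-siRNA lanes, per
    scale) at p < 0.01.
    """
    control_sd = control_sd or PROTEIN_CONTROL_SD
    x = normalized[normalized["sirna_id"] == sirna_id]
    if x.empty or x["ldlr_norm"].isna().all():
        return SecondaryCall(target=sirna_id, assay="ldlr_protein", direction="untestable")
    pvals, deltas, sd_ok = [], [], []
    for scale, col in (("ldlr", "ldlr_norm"), ("ldlr_tub", "ldlr_tub_norm")):
        ctrl = normalized[normalized["role"].isin(("untreated", "control_sirna"))][col]
        delta = x[col].mean() - ctrl.mean()
        deltas.append(delta)
        sd_ok.append(abs(delta) > 2 * control_sd[scale])
        for role in ("untreated", "control_sirna"):
            grp = normalized[normalized["role"] == role][col].to_numpy()
            pvals.append(_ttest(x[col].to_numpy(), grp, equal_var))
    passed = all(sd_ok) and all(p < alpha for p in pvals) and len(pvals) == 4
    return SecondaryCall(
        target=sirna_id,
        assay="ldlr_protein",
        direction=("+" if np.mean(deltas) > 0 else "-") if passed else "n.s.",
        p_values=pvals,
        effect=float(x["ldlr_norm"].mean()),
    )


# ---------------------------------------------------------------------------
# GFP overexpression
# ---------------------------------------------------------------------------

def classify_transfection(
    cells: pd.DataFrame,
    mock_cells: pd.DataFrame,
    min_mock_cells: int = 50,
) -> pd.DataFrame:
    """Classify cells as untransfected / intermediate / transfected.

    The untransfected threshold T is the 97th percentile of mock GFP
    totals; transfected cells show GFP > 4 x T; cells in between are
    intermediate and excluded from ratio statistics.
    """
    if len(mock_cells) < min_mock_cells:
        raise ValueError(f"need >= {min_mock_cells} mock cells")
    t = float(np.percentile(mock_cells["gfp_total"], 97))
    out = cells.copy()
    gfp = out["gfp_total"].to_numpy(dtype=float)
    cls = np.where(gfp > 4 * t, "transfected", np.where(gfp < t, "untransfected", "intermediate"))
    out["transfection_class"] = cls
    out.attrs["untransfected_threshold"] = t
    return out


def overexpression_fc_effect(
    classified: pd.DataFrame,
    mock_cells: pd.DataFrame,
    construct: str = "",
    equal_var: bool = False,
    alpha: float = 0.01,
) -> dict:
    """Filipin effect of one GFP construct across replica dishes.

    Per usable dish (both classes present): filipin ratio of transfected
    vs untransfected cells in the same dish and vs mock cells of the same
    dish index; significance stars from the count of dishes with
    transfected-vs-untransfected p < 0.01 ('*' at 2, '***' at 3-4).  Also
    reports the sign of the per-cell filipin-vs-GFP trend.
    """
    ratios_un, ratios_mock, pvals = [], [], []
    for dish, grp in classified.groupby("dish"):
        tr = grp[grp["transfection_class"] == "transfected"]["filipin_total"]
        un = grp[grp["transfection_class"] == "untransfected"]["filipin_total"]
        if len(tr) < 2 or len(un) < 2:
            continue
        ratios_un.append(tr.mean() / un.mean())
        mock = mock_cells[mock_cells["dish"] == dish]["filipin_total"]
        if len(mock):
            ratios_mock.append(tr.mean() / mock.mean())
        pvals.append(_ttest(tr, un, equal_var))
    if len(ratios_un) < 2:
        return {
            "construct": construct, "ratio_vs_untransfected": None,
            "ratio_vs_mock": None, "significance": "untestable",
            "trend_slope_sign": 0, "p_values": pvals,
        }
    n_sig = sum(p < alpha for p in pvals)
    stars = "***" if n_sig >= 3 else "*" if n_sig == 2 else "n.s."
    slope = stats.linregress(
        classified["gfp_total"].astype(float), classified["filipin_total"].astype(float)
    ).slope
    return {
        "construct": construct,
        "ratio_vs_untransfected": float(np.mean(ratios_un)),
        "ratio_vs_mock": float(np.mean(ratios_mock)) if ratios_mock else None,
        "significance": stars,
        "n_significant_replicas": n_sig,
        "n_replicas": len(ratios_un),
        "trend_slope_sign": int(np.sign(slope)),
        "p_values": pvals,
    }


# ---------------------------------------------------------------------------
# Table-2-style summary
# ---------------------------------------------------------------------------

def secondary_call_matrix(calls: list[SecondaryCall], sirna_gene_map: dict[str, str]) -> pd.DataFrame:
    """Gene x assay matrix of symbols: +/- (two siRNAs), (+)/(-) (one
    siRNA), -/+ (two siRNAs, discordant), n.s., n.d. (not determined)."""
    rows: dict[tuple[str, str], list[str]] = {}
    for call in calls:
        gene = sirna_gene_map.get(call.target, call.target)
        rows.setdefault((gene, call.assay), []).append(call.direction)
    genes = sorted({g for g, _ in rows})
    assays = sorted({a for _, a in rows})
    matrix = pd.DataFrame("n.d.", index=genes, columns=assays)
    for (gene, assay), dirs in rows.items():
        sig = [d for d in dirs if d in ("+", "-")]
        if not sig:
            matrix.loc[gene, assay] = "n.s." if any(d == "n.s." for d in dirs) else "n.d."
        elif len(set(sig)) == 2:
            matrix.loc[gene, assay] = "-/+"
        elif len(sig) >= 2:
            matrix.loc[gene, assay] = sig[0]
        else:
            matrix.loc[gene, assay] = f"({sig[0]})"
    return matrix
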