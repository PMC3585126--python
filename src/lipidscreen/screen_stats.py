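"""Control-anchored screen statistics: deviation values, thresholds, hits.

The screen's core statistic is the per-siRNA, per-replicate *deviation
value*:

    deviation = (siRNA replicate mean - mean of negative-control means)
                / (2 x error of the negative-control means)

a z-like score in which the error term defaults to the mean absolute
deviation of the 16 negative-control replicate means about their mean
("twice the absolute error"), with standard-deviation and SEM estimators
available behind a flag.  Deviations from all biological replicates are
averaged into the siRNA's mean deviation (dimensionless "deviation
units").

Effector thresholds are derived from the controls themselves: the extreme
negative-control/mock mean deviation plus/minus three standard errors of
the mean (SEM = sd of all control deviation values / sqrt(replicates)).
An siRNA is an effector when its mean deviation on parameter "total"
falls strictly outside these bounds; a gene is a hit when at least two
independent siRNAs are effectors in one assay.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from lipidscreen.params import NULL_CONTROL_ROLES, Role
from lipidscreen.synth.layout import PlateLayout

SIGNAL_PARAMETERS = ("total", "concentration", "structures", "area")
EXTRA_PARAMETERS = ("n_cells", "cell_area")


class DegenerateControlsError(ValueError):
    """Controls carry no spread; deviation values are undefined."""


# ---------------------------------------------------------------------------
# replicate summaries
# ---------------------------------------------------------------------------

def summarize_replicates(
    cell_records: pd.DataFrame,
    layout: PlateLayout,
    failed_images: set[tuple[str, int, int]] | None = None,
) -> pd.DataFrame:
    """Average cells per image, then images per biological replicate.

    ``failed_images`` lists (position_id, replicate, image) triples flagged
    by QC; their cells are excluded.  Returns a long table with one row per
    (position, replicate, parameter), including the per-image cell count
    and cell-area QC parameters.
    """
    cells = cell_records
    if failed_images:
        key = list(zip(cells["position_id"], cells["replicate"], cells["image"]))
        cells = cells[[k not in failed_images for k in key]]
    params = [p for p in SIGNAL_PARAMETERS if p in cells.columns and cells[p].notna().any()]
    params += [p for p in ("cell_area",) if p in cells.columns]

    per_image = (
        cells.groupby(["position_id", "replicate", "image"], sort=True)
        .agg(**{p: (p, "mean") for p in params}, n_cells=("cell_id", "size"))
        .reset_index()
    )
    per_rep = (
        per_image.groupby(["position_id", "replicate"], sort=True)
        .agg(
            **{p: (p, "mean") for p in params},
            n_cells=("n_cells", "mean"),
            n_images=("image", "size"),
        )
        .reset_index()
    )
    long = per_rep.melt(
        id_vars=["position_id", "replicate", "n_images"],
        value_vars=params + ["n_cells"],
        var_name="parameter",
        value_name="mean_value",
    )
    meta = layout.positions[["position_id", "sirna_id", "role", "region"]]
    out = long.merge(meta, on="position_id", how="left")
    counts = per_rep.set_index(["position_id", "replicate"])["n_cells"]
    out["n_cells"] = out.set_index(["position_id", "replicate"]).index.map(counts).astype(float)
    return out[
        ["position_id", "sirna_id", "role", "region", "replicate",
         "parameter", "mean_value", "n_cells", "n_images"]
    ]


# ---------------------------------------------------------------------------
# deviation values
# ---------------------------------------------------------------------------

def control_error(control_means: np.ndarray, estimator: str = "mad") -> float:
    """Spread of the negative-control means: 'mad' (mean absolute
    deviation about the mean, the default), 'sd' or 'sem'."""
    x = np.asarray(control_means, dtype=float)
    center = x.mean()
    if estimator == "mad":
        return float(np.abs(x - center).mean())
    if estimator == "sd":
        return float(x.std(ddof=1))
    if estimator == "sem":
        return float(x.std(ddof=1) / np.sqrt(len(x)))
    raise ValueError(f"unknown estimator {estimator!r}")


def deviation_value(
    sirna_mean: float, control_means, estimator: str = "mad"
) -> float:
    """Deviation of one replicate mean from the negative controls."""
    x = np.asarray(control_means, dtype=float)
    if len(x) < 2:
        raise ValueError("need >= 2 control means")
    err = control_error(x, estimator)
    if err == 0:
        raise DegenerateControlsError("all control means identical")
    return (float(sirna_mean) - x.mean()) / (2.0 * err)


@dataclass
class DeviationTable:
    """Per-replicate and replicate-averaged deviation values.

    ``per_replicate``: position_id, sirna_id, role, parameter, replicate,
    deviation.  ``means``: position_id, sirna_id, role, parameter,
    mean_deviation, n_replicates.
    """

    per_replicate: pd.DataFrame
    means: pd.DataFrame
    assay: str = ""
    estimator: str = "mad"
    region_normalized: bool = False

    def mean_of(self, sirna_id: str, parameter: str = "total") -> float:
        m = self.means
        rows = m[(m["sirna_id"] == sirna_id) & (m["parameter"] == parameter)]
        return float(rows["mean_deviation"].mean())


def aggregate_deviations(per_replicate: pd.DataFrame) -> pd.DataFrame:
    """Average per-replicate deviations (arithmetic mean over replicates)."""
    means = (
        per_replicate.dropna(subset=["deviation"])
        .groupby(["position_id", "sirna_id", "role", "parameter"], dropna=False, sort=True)
        .agg(mean_deviation=("deviation", "mean"), n_replicates=("deviation", "size"))
        .reset_index()
    )
    return means


def compute_deviations(
    summaries: pd.DataFrame,
    assay: str = "",
    estimator: str = "mad",
    region_normalize: bool = False,
    min_region_controls: int = 2,
    region_fallback: bool = True,
) -> DeviationTable:
    """Deviation values for every position x parameter x replicate.

    Centering uses the negative-control positions of the identical
    replicate (same plate region when ``region_normalize`` is on; plate-wide
    fallback when a region holds fewer than ``min_region_controls``
    controls and fallback is allowed).
    """
    rows = []
    for (param, rep), grp in summaries.groupby(["parameter", "replicate"], sort=True):
        neg_all = grp[grp["role"] == Role.NEGATIVE_CONTROL.value]["mean_value"].dropna()
        for region, sub in (grp.groupby("region") if region_normalize else [(None, grp)]):
            if region_normalize:
                neg = sub[sub["role"] == Role.NEGATIVE_CONTROL.value]["mean_value"].dropna()
                if len(neg) < min_region_controls:
                    if not region_fallback:
                        raise DegenerateControlsError(
                            f"region {region} has {len(neg)} negative controls"
                        )
                    neg = neg_all
            else:
                neg = neg_all
            if len(neg) < 2:
                raise DegenerateControlsError("need >= 2 negative-control positions")
            err = control_error(neg.to_numpy(), estimator)
            if err == 0:
                raise DegenerateControlsError("degenerate controls")
            center = neg.mean()
            dev = (sub["mean_value"] - center) / (2.0 * err)
            out = sub[["position_id", "sirna_id", "role"]].copy()
            out["parameter"] = param
            out["replicate"] = rep
            out["deviation"] = dev
            rows.append(out)
    per_replicate = pd.concat(rows, ignore_index=True)
    return DeviationTable(
        per_replicate=per_replicate,
        means=aggregate_deviations(per_replicate),
        assay=assay,
        estimator=estimator,
        region_normalized=region_normalize,
    )


def control_normality_check(control_deviations, parameter: str = "") -> dict:
    """Shapiro-Wilk test plus Q-Q points for control deviation values."""
    x = np.sort(np.asarray(control_deviations, dtype=float))
    if len(x) < 3:
        raise ValueError("need >= 3 control deviation values")
    if np.ptp(x) == 0:
        raise DegenerateControlsError("constant control deviations")
    stat, p = stats.shapiro(x)
    theo = stats.norm.ppf((np.arange(1, len(x) + 1) - 0.5) / len(x))
    return {
        "parameter": parameter,
        "statistic": float(stat),
        "p_value": float(p),
        "qq_points": list(zip(theo.tolist(), x.tolist())),
    }


# ---------------------------------------------------------------------------
# thresholds and calls
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ThresholdSet:
    """Control-derived effector bounds for one assay/parameter."""

    assay: str
    parameter: str
    lower: float
    upper: float
    control_n: int = 0

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise ValueError("lower must be < upper")

    def classify(self, mean_deviation: float) -> str:
        """Three-way call with strict inequalities (boundary -> 'none')."""
        if np.isnan(mean_deviation):
            return "none"
        if mean_deviation > self.upper:
            return "increase"
        if mean_deviation < self.lower:
            return "decrease"
        return "none"


#: thresholds on parameter "total" published for the four original screens
PUBLISHED_THRESHOLDS = {
    ("ldl_uptake", "GWAS1"): ThresholdSet("ldl_uptake", "total", -0.50, 0.81),
    ("ldl_uptake", "GWAS2"): ThresholdSet("ldl_uptake", "total", -0.55, 1.02),
    ("free_cholesterol", "GWAS1"): ThresholdSet("free_cholesterol", "total", -1.11, 1.70),
    ("free_cholesterol", "GWAS2"): ThresholdSet("free_cholesterol", "total", -1.06, 1.05),
}


def effector_thresholds(
    deviations: DeviationTable,
    parameter: str = "total",
    n_replicates: int | None = None,
    mode: str = "extreme",
) -> ThresholdSet:
    """Derive effector bounds from negative-control and mock positions.

    ``upper = max(control mean deviations) + 3*SEM`` and ``lower =
    min - 3*SEM`` with SEM = sd(all control deviation values)/sqrt(n
    replicates) ("extreme" reading: a call must clear the bound of every
    control).  ``mode='nearest'`` instead anchors at the innermost control.
    """
    ctrl_roles = {r.value for r in NULL_CONTROL_ROLES}
    means = deviations.means
    ctrl_means = means[
        (means["role"].isin(ctrl_roles)) & (means["parameter"] == parameter)
    ]["mean_deviation"].dropna()
    per_rep = deviations.per_replicate
    ctrl_values = per_rep[
        (per_rep["role"].isin(ctrl_roles)) & (per_rep["parameter"] == parameter)
    ]["deviation"].dropna()
    if len(ctrl_means) < 2 or ctrl_values.std(ddof=1) == 0:
        raise DegenerateControlsError("not enough control spread for thresholds")
    if n_replicates is None:
        n_replicates = int(
            per_rep[per_rep["role"].isin(ctrl_roles)]["replicate"].nunique()
        )
    sem = float(ctrl_values.std(ddof=1) / np.sqrt(n_replicates))
    if mode == "extreme":
        lo, hi = float(ctrl_means.min()), float(ctrl_means.max())
    elif mode == "nearest":
        lo, hi = float(ctrl_means.max()), float(ctrl_means.min())
        if lo - 3 * sem >= hi + 3 * sem:
            lo, hi = hi, lo  # keep the interval well-formed
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return ThresholdSet(
        assay=deviations.assay,
        parameter=parameter,
        lower=lo - 3 * sem,
        upper=hi + 3 * sem,
        control_n=len(ctrl_means),
    )


def call_effector_sirnas(
    deviations: DeviationTable | pd.DataFrame,
    thresholds: ThresholdSet,
    parameter: str = "total",
) -> pd.DataFrame:
    """Classify every scored position on *parameter* against *thresholds*.

    Rows with a missing mean deviation are called 'none' and flagged
    ``missing=True``.
    """
    means = deviations.means if isinstance(deviations, DeviationTable) else deviations
    sub = means[means["parameter"] == parameter].copy()
    sub["direction"] = [thresholds.classify(v) for v in sub["mean_deviation"]]
    sub["missing"] = sub["mean_deviation"].isna()
    sub["assay"] = thresholds.assay
    return sub[
        ["position_id", "sirna_id", "role", "assay", "parameter",
         "mean_deviation", "n_replicates", "direction", "missing"]
    ].reset_index(drop=True)


def call_hit_genes(
    effector_calls: pd.DataFrame,
    sirna_gene_map: dict[str, str | None],
    min_sirnas: int = 2,
) -> pd.DataFrame:
    """Gene-level hit calls: >= ``min_sirnas`` distinct effector siRNAs.

    Only candidate positions enter; genes with fewer than ``min_sirnas``
    siRNAs tested are flagged untestable-by-rule.  Multi-assay call tables
    may be concatenated first — a gene is then a hit if the rule holds in
    at least one assay.
    """
    cand = effector_calls[effector_calls["role"] == Role.CANDIDATE.value].copy()
    cand["gene"] = cand["sirna_id"].map(sirna_gene_map)
    cand = cand.dropna(subset=["gene"])
    rows = []
    for gene, grp in cand.groupby("gene", sort=True):
        n_tested = grp["sirna_id"].nunique()
        best = []
        hit_assay = None
        for assay, agrp in grp.groupby("assay"):
            eff = agrp[agrp["direction"] != "none"]
            support = sorted(eff["sirna_id"].unique())
            if len(support) >= min_sirnas and len(support) > len(best):
                best, hit_assay = support, assay
        eff_all = grp[grp["direction"] != "none"]
        dirs = set(eff_all[eff_all["sirna_id"].isin(best)]["direction"]) if best else set()
        rows.append(
            {
                "gene": gene,
                "is_hit": bool(best),
                "assay": hit_assay,
                "supporting_sirnas": ",".join(best),
                "n_supporting": len(best),
                "n_sirnas_tested": n_tested,
                "direction_consistent": len(dirs) == 1 if best else False,
                "untestable": n_tested < min_sirnas,
            }
        )
    return pd.DataFrame(rows)


def validation_rate(
    effectors_screen1: set[str],
    effectors_screen2: set[str],
    shared_sirnas: set[str] | None = None,
) -> dict:
    """Fraction of screen-1 effectors confirmed in screen 2.

    Only siRNAs present in both screens count; the rate is reported as a
    percentage rounded to the nearest integer (missing when screen 1 has
    no effectors among the shared set).
    """
    s1 = set(effectors_screen1)
    if shared_sirnas is not None:
        s1 &= set(shared_sirnas)
    validated = s1 & set(effectors_screen2)
    rate = round(100.0 * len(validated) / len(s1)) if s1 else None
    return {"n_effectors_s1": len(s1), "n_validated": len(validated), "rate_percent": rate}


# ---------------------------------------------------------------------------
# correlations and empirical FDR
# ---------------------------------------------------------------------------

def parameter_correlations(
    wide: pd.DataFrame, pairwise_complete: bool = True, min_rows: int = 3
) -> pd.DataFrame:
    """Pairwise Pearson correlations between parameter columns.

    ``wide`` holds one row per siRNA and one column per parameter.
    Constant columns yield NaN against every other column.
    """
    if len(wide) < min_rows:
        raise ValueError(f"need >= {min_rows} rows")
    data = wide.astype(float)
    if not pairwise_complete:
        data = data.dropna()
    corr = data.corr(method="pearson", min_periods=2)
    for col in data.columns:
        if data[col].nunique(dropna=True) <= 1:
            corr.loc[col, :] = np.nan
            corr.loc[:, col] = np.nan
        else:
            corr.loc[col, col] = 1.0
    return corr


def empirical_fdr(
    mean_deviations: pd.Series | np.ndarray,
    control_deviation_values,
    min_controls: int = 10,
) -> pd.DataFrame:
    """Two-sided empirical p-values against the control distribution + BH.

    p = 2 * min(P(ctrl <= d), P(ctrl >= d)) with add-one smoothing, capped
    at 1; Benjamini-Hochberg adjusted across the scored siRNAs.
    """
    ctrl = np.asarray(control_deviation_values, dtype=float)
    ctrl = ctrl[~np.isnan(ctrl)]
    if len(ctrl) < min_controls:
        raise ValueError(f"need >= {min_controls} control values")
    d = np.asarray(mean_deviations, dtype=float)
    n = len(ctrl)
    p = np.empty(len(d))
    for i, v in enumerate(d):
        if np.isnan(v):
            p[i] = np.nan
            continue
        ge = (1 + np.sum(ctrl >= v)) / (n + 1)
        le = (1 + np.sum(ctrl <= v)) / (n + 1)
        p[i] = min(1.0, 2.0 * min(ge, le))
    ok = ~np.isnan(p)
    fdr = np.full(len(d), np.nan)
    if ok.any():
        fdr[ok] = multipletests(p[ok], method="fdr_bh")[1]
    idx = mean_deviations.index if isinstance(mean_deviations, pd.Series) else None
    return pd.DataFrame({"p_value": p, "fdr": fdr}, index=idx)
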