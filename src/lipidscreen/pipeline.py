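"""End-to-end pipeline: simulate/load -> score -> call -> profile -> report.

A single :class:`RunConfig` drives every stage; all randomness flows from
one top-level seed split per stage, so identical configurations produce
byte-identical outputs.  Intermediates (cell tables, deviation tables,
thresholds, calls) are persisted as CSV/JSON when an output directory is
configured.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

import lipidscreen.io as lio
from lipidscreen import __version__
from lipidscreen.params import Assay, Role, assay_parameters
from lipidscreen.profiling import build_fingerprint, classify_functional_group, locus_summary
from lipidscreen.reporting import hit_rate
from lipidscreen.screen_stats import (
    DeviationTable,
    ThresholdSet,
    call_effector_sirnas,
    call_hit_genes,
    compute_deviations,
    control_normality_check,
    effector_thresholds,
    empirical_fdr,
    summarize_replicates,
)
from lipidscreen.synth import (
    ControlSpec,
    EffectSpec,
    SceneSpec,
    make_plate_layout,
    simulate_screen,
)


class ConfigError(ValueError):
    """Invalid run configuration."""


def _check_keys(section: str, given: dict, allowed: set[str]) -> None:
    unknown = set(given) - allowed
    if unknown:
        raise ConfigError(f"unknown keys in {section}: {sorted(unknown)}")


@dataclass
class RunConfig:
    """Validated pipeline configuration (unknown keys are rejected)."""

    seed: int = 0
    output_dir: str | None = None
    mode: str = "simulate"  # or "load"
    format: str = "plate_384"
    n_genes: int = 50
    sirnas_per_gene: int = 3
    n_replicates: int = 3
    images_per_position: int = 4
    tables_only: bool = True
    gene_effects: dict = field(default_factory=dict)  # gene -> {param: shift}
    penetrance: float = 1.0
    scene: dict = field(default_factory=dict)  # SceneSpec overrides
    layout_path: str | None = None
    cells_paths: dict = field(default_factory=dict)  # assay -> csv (load mode)
    annotation_path: str | None = None
    estimator: str = "mad"
    threshold_mode: str = "extreme"
    region_normalize_fc: bool = True
    published_thresholds: dict = field(default_factory=dict)  # assay -> [lo, hi]

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        _check_keys("config", raw, {f.name for f in dataclasses.fields(cls)})
        cfg = cls(**raw)
        if cfg.mode not in ("simulate", "load"):
            raise ConfigError(f"mode must be simulate|load, got {cfg.mode!r}")
        if cfg.mode == "load":
            if not cfg.layout_path or not cfg.cells_paths:
                raise ConfigError("load mode requires layout_path and cells_paths")
            for p in [cfg.layout_path, *cfg.cells_paths.values()]:
                if not Path(p).exists():
                    raise ConfigError(f"input path does not exist: {p}")
        if cfg.estimator not in ("mad", "sd", "sem"):
            raise ConfigError(f"unknown estimator {cfg.estimator!r}")
        try:
            SceneSpec(**cfg.scene)
        except TypeError as exc:
            raise ConfigError(f"invalid scene override: {exc}") from exc
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ConfigError("config file must hold a mapping")
        return cls.from_dict(raw)

    def digest(self) -> str:
        """Hash of the analysis-relevant configuration (output location
        excluded, so re-running elsewhere reproduces the same digest)."""
        payload = dataclasses.asdict(self)
        payload.pop("output_dir", None)
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def candidate_set(n_genes: int, sirnas_per_gene: int) -> list[tuple[str, str]]:
    """Deterministic candidate siRNA/gene naming: gene G007 -> sG007_2."""
    out = []
    for g in range(1, n_genes + 1):
        gene = f"G{g:03d}"
        for s in range(1, sirnas_per_gene + 1):
            out.append((f"s{gene}_{s}", gene))
    return out


def effects_from_config(config: RunConfig) -> dict[str, EffectSpec]:
    """Expand per-gene shift maps into per-siRNA EffectSpecs."""
    effects: dict[str, EffectSpec] = {}
    for gene, shifts in config.gene_effects.items():
        for s in range(1, config.sirnas_per_gene + 1):
            sid = f"s{gene}_{s}"
            effects[sid] = EffectSpec(
                sirna_id=sid, shifts=dict(shifts),
                knockdown_penetrance=config.penetrance,
            )
    return effects


@dataclass
class ScreenReport:
    """All result tables of one pipeline run plus provenance."""

    deviations: dict[str, DeviationTable]
    thresholds: dict[str, ThresholdSet]
    effector_calls: pd.DataFrame
    gene_calls: pd.DataFrame
    fingerprints: list
    functional_groups: pd.Series
    locus_summaries: list
    control_stats: dict
    headline: dict
    provenance: dict


def _score_assay(
    cells: pd.DataFrame,
    layout,
    assay: Assay,
    config: RunConfig,
) -> tuple[DeviationTable, dict[str, ThresholdSet]]:
    summaries = summarize_replicates(cells, layout)
    region = assay is Assay.FREE_CHOLESTEROL and config.region_normalize_fc and (
        layout.format == "plate_384"
    )
    table = compute_deviations(
        summaries, assay=assay.value, estimator=config.estimator,
        region_normalize=region,
    )
    thresholds: dict[str, ThresholdSet] = {}
    for param in assay_parameters(assay):
        key = f"{assay.short}_{param}"
        thresholds[key] = effector_thresholds(
            table, parameter=param, n_replicates=config.n_replicates,
            mode=config.threshold_mode,
        )
    override = config.published_thresholds.get(assay.value)
    if override:
        thresholds[f"{assay.short}_total"] = ThresholdSet(
            assay=assay.value, parameter="total",
            lower=float(override[0]), upper=float(override[1]),
        )
    return table, thresholds


def run_pipeline(config: RunConfig) -> ScreenReport:
    """Execute simulate/load -> quantify -> score -> call -> profile."""
    rng_root = np.random.SeedSequence(config.seed)
    stage_seeds = rng_root.spawn(4)

    if config.mode == "simulate":
        candidates = candidate_set(config.n_genes, config.sirnas_per_gene)
        layout = make_plate_layout(
            config.format, candidates, ControlSpec(),
            seed=int(np.random.default_rng(stage_seeds[0]).integers(2**31)),
        )
        effects = effects_from_config(config)
        cells_by_assay = {}
        for i, assay in enumerate([Assay.LDL_UPTAKE, Assay.FREE_CHOLESTEROL]):
            scene = SceneSpec(**{**config.scene, "assay": assay.value})
            res = simulate_screen(
                layout, effects, config.n_replicates, scene,
                seed=int(np.random.default_rng(stage_seeds[1 + i]).integers(2**31)),
                images_per_position=config.images_per_position,
                tables_only=True,
            )
            cells_by_assay[assay.value] = res.cells
    else:
        layout = lio.read_layout(config.layout_path)
        cells_by_assay = {a: lio.read_cells(p) for a, p in config.cells_paths.items()}

    deviations: dict[str, DeviationTable] = {}
    thresholds: dict[str, ThresholdSet] = {}
    calls = []
    control_stats: dict = {}
    for assay_name, cells in cells_by_assay.items():
        assay = Assay(assay_name)
        table, thr = _score_assay(cells, layout, assay, config)
        deviations[assay.value] = table
        thresholds.update(thr)
        total_thr = thr[f"{assay.short}_total"]
        assay_calls = call_effector_sirnas(table, total_thr, parameter="total")
        ctrl_roles = {Role.NEGATIVE_CONTROL.value, Role.MOCK.value}
        ctrl_vals = table.per_replicate[
            (table.per_replicate["role"].isin(ctrl_roles))
            & (table.per_replicate["parameter"] == "total")
        ]["deviation"].dropna()
        fdr = empirical_fdr(assay_calls["mean_deviation"], ctrl_vals)
        assay_calls["empirical_fdr"] = fdr["fdr"].to_numpy()
        calls.append(assay_calls)
        control_stats[assay.value] = {
            "normality": control_normality_check(ctrl_vals, parameter="total"),
            "threshold": {"lower": total_thr.lower, "upper": total_thr.upper},
            "n_control_values": int(len(ctrl_vals)),
        }
    effector_calls = pd.concat(calls, ignore_index=True)

    cand = layout.by_role(Role.CANDIDATE)
    cand_gene_map = dict(zip(cand["sirna_id"], cand["gene"]))
    gene_calls = call_hit_genes(effector_calls, cand_gene_map)

    fingerprints = []
    groups = {}
    genes = sorted(set(cand_gene_map.values()))
    gene_sirnas: dict[str, list[str]] = {}
    for sid, gene in cand_gene_map.items():
        gene_sirnas.setdefault(gene, []).append(sid)
    for gene in genes:
        fp = build_fingerprint(gene, sorted(gene_sirnas[gene]), deviations, thresholds)
        fingerprints.append(fp)
        groups[gene] = classify_functional_group(fp)
    functional_groups = pd.Series(groups, name="functional_group")

    locus_summaries = []
    if config.annotation_path:
        annotation = lio.read_annotation(config.annotation_path)
        locus_summaries = locus_summary(gene_calls, annotation)

    n_genes_tested = int(gene_calls["gene"].nunique()) if len(gene_calls) else 0
    n_hits = int(gene_calls["is_hit"].sum()) if len(gene_calls) else 0
    headline = {
        "n_genes_tested": n_genes_tested,
        "n_hit_genes": n_hits,
        "hit_rate_percent": hit_rate(n_hits, n_genes_tested) if n_genes_tested else None,
        "functional_groups": functional_groups.value_counts().to_dict(),
    }
    provenance = {
        "seed": config.seed,
        "config_digest": config.digest(),
        "version": __version__,
    }
    report = ScreenReport(
        deviations=deviations,
        thresholds=thresholds,
        effector_calls=effector_calls,
        gene_calls=gene_calls,
        fingerprints=fingerprints,
        functional_groups=functional_groups,
        locus_summaries=locus_summaries,
        control_stats=control_stats,
        headline=headline,
        provenance=provenance,
    )
    if config.output_dir:
        _persist(report, layout, cells_by_assay, config)
    return report


def _persist(report: ScreenReport, layout, cells_by_assay, config: RunConfig) -> None:
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    lio.write_layout(layout, out / "layout.csv")
    for assay, cells in cells_by_assay.items():
        lio.write_cells(cells, out / f"cells_{Assay(assay).short}.csv")
    for assay, table in report.deviations.items():
        lio.write_deviations(table, out / f"deviations_{Assay(assay).short}.csv")
    lio.write_thresholds(report.thresholds, out / "thresholds.json")
    report.effector_calls.to_csv(out / "effector_calls.csv", index=False)
    report.gene_calls.to_csv(out / "gene_calls.csv", index=False)
    report.functional_groups.rename_axis("gene").to_csv(out / "functional_groups.csv")
    if report.fingerprints:
        rows = []
        for fp in report.fingerprints:
            for sirna in fp.sirnas:
                row = {"gene": fp.gene, "sirna_id": sirna}
                row.update(fp.matrix.loc[sirna].to_dict())
                rows.append(row)
        pd.DataFrame(rows).to_csv(out / "fingerprints.csv", index=False)
    if report.locus_summaries:
        pd.DataFrame(
            [
                {
                    "locus": ls.locus,
                    "lead_snps": ";".join(ls.lead_snps),
                    "n_genes_tested": len(ls.genes_tested),
                    "n_effector_genes": ls.n_effector_genes,
                    "multi_effector": ls.multi_effector,
                }
                for ls in report.locus_summaries
            ]
        ).to_csv(out / "locus_summary.csv", index=False)
    payload = {
        "headline": report.headline,
        "control_stats": {
            a: {
                "threshold": s["threshold"],
                "n_control_values": s["n_control_values"],
                "shapiro_p": s["normality"]["p_value"],
            }
            for a, s in report.control_stats.items()
        },
        "provenance": report.provenance,
    }
    (out / "report.json").write_text(json.dumps(payload, indent=2, sort_keys=True))
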