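"""Synthetic secondary-assay tables with known ground truth.

Emulates the four follow-up experiments used to validate screen hits:

* qPCR of LDLR mRNA (CT values for LDLR, GAPDH, ACTB; technical
  triplicates nested in biological replicates) — CTs are generated as
  ``CT = baseline - log2(expression) + noise`` so the 2^-ddCT analysis
  can be inverted exactly when noise is zero;
* Western-blot densitometry (LDLR and tubulin band densities with
  per-lane loading factors, grouped by gel);
* enzymatic (Amplex-Red-style) total-cholesterol plate-reader readings;
* GFP-cDNA overexpression: per-cell GFP and filipin totals for mock and
  construct-transfected dishes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: CT baselines at unit expression (cycles)
CT_BASELINES = {"LDLR": 24.0, "GAPDH": 18.0, "ACTB": 17.0}

#: lognormal parameters of the mock GFP distribution (camera units)
MOCK_GFP_MEDIAN = 100.0
MOCK_GFP_SIGMA = 0.5


@dataclass(frozen=True)
class SecondarySirna:
    """True fold changes planted for one siRNA across secondary assays."""

    sirna_id: str
    gene: str
    ldlr_mrna_fold: float = 1.0
    ldlr_protein_fold: float = 1.0
    cholesterol_fold: float = 1.0


@dataclass(frozen=True)
class OverexpressionConstruct:
    """One GFP-cDNA construct: transfection strength and filipin effect."""

    gene: str
    gfp_multiplier: float = 10.0  # transfected GFP relative to mock 97th percentile
    transfected_fraction: float = 0.3
    filipin_ratio: float = 1.0  # filipin in transfected relative to untransfected
    gfp_coupling: bool = False  # filipin effect proportional to GFP level


@dataclass
class SecondaryDesign:
    """Sample sizes and noise levels of the synthetic secondary assays."""

    sirnas: list[SecondarySirna] = field(default_factory=list)
    constructs: list[OverexpressionConstruct] = field(default_factory=list)
    n_bio_replicates: int = 4
    n_tech_replicates: int = 3
    n_untreated: int = 8
    n_mock: int = 8
    qpcr_ct_sd: float = 0.12
    western_cv: float = 0.06
    lane_cv: float = 0.10
    n_gels: int = 3
    enzymatic_replicas: int = 6
    enzymatic_cv: float = 0.05
    n_dishes: int = 4
    cells_per_dish: int = 500
    filipin_cv: float = 0.30


def mock_gfp_p97() -> float:
    """Theoretical 97th percentile of the mock GFP distribution."""
    from scipy.stats import norm

    return MOCK_GFP_MEDIAN * float(np.exp(MOCK_GFP_SIGMA * norm.ppf(0.97)))


def _qpcr(design: SecondaryDesign, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    samples = [("untreated", f"untreated_{i:02d}") for i in range(design.n_untreated)]
    samples += [("mock", f"mock_{i:02d}") for i in range(design.n_mock)]
    fold = 1.0
    for role, sample_id in samples:
        for rep in range(1, design.n_bio_replicates + 1):
            bio = rng.normal(0, design.qpcr_ct_sd)
            for gene, base in CT_BASELINES.items():
                for tech in range(1, design.n_tech_replicates + 1):
                    ct = base - np.log2(fold if gene == "LDLR" else 1.0)
                    ct += bio + rng.normal(0, design.qpcr_ct_sd / 2)
                    rows.append((sample_id, None, role, rep, tech, gene, ct))
    for s in design.sirnas:
        for rep in range(1, design.n_bio_replicates + 1):
            bio = rng.normal(0, design.qpcr_ct_sd)
            for gene, base in CT_BASELINES.items():
                for tech in range(1, design.n_tech_replicates + 1):
                    ct = base - np.log2(s.ldlr_mrna_fold if gene == "LDLR" else 1.0)
                    ct += bio + rng.normal(0, design.qpcr_ct_sd / 2)
                    rows.append((s.sirna_id, s.sirna_id, "candidate", rep, tech, gene, ct))
    return pd.DataFrame(
        rows,
        columns=["sample_id", "sirna_id", "role", "replicate", "tech_rep", "gene", "ct"],
    )


def _western(design: SecondaryDesign, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    per_gel = int(np.ceil(len(design.sirnas) / design.n_gels)) if design.sirnas else 0
    for g in range(design.n_gels):
        gel = f"gel{g + 1:02d}"
        lane = 0
        for role in ("untreated", "untreated", "control_sirna", "control_sirna"):
            lane += 1
            lf = np.exp(rng.normal(0, design.lane_cv))
            ldlr = 1000.0 * lf * np.exp(rng.normal(0, design.western_cv))
            tub = 800.0 * lf * np.exp(rng.normal(0, design.western_cv))
            rows.append((gel, f"{gel}_lane{lane:02d}", None, role, ldlr, tub, False))
        for s in design.sirnas[g * per_gel:(g + 1) * per_gel]:
            for _rep in range(3):
                lane += 1
                lf = np.exp(rng.normal(0, design.lane_cv))
                ldlr = 1000.0 * s.ldlr_protein_fold * lf * np.exp(rng.normal(0, design.western_cv))
                tub = 800.0 * lf * np.exp(rng.normal(0, design.western_cv))
                rows.append((gel, f"{gel}_lane{lane:02d}", s.sirna_id, "candidate", ldlr, tub, False))
    return pd.DataFrame(
        rows,
        columns=["gel_id", "lane_id", "sirna_id", "role", "ldlr_density",
                 "tubulin_density", "flagged"],
    )


def _enzymatic(design: SecondaryDesign, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    for role in ("control_sirna", "mock"):
        for rep in range(1, design.enzymatic_replicas + 1):
            rows.append((role, role, rep, 100.0 * np.exp(rng.normal(0, design.enzymatic_cv))))
    for s in design.sirnas:
        for rep in range(1, design.enzymatic_replicas + 1):
            reading = 100.0 * s.cholesterol_fold * np.exp(rng.normal(0, design.enzymatic_cv))
            rows.append((s.sirna_id, "candidate", rep, reading))
    return pd.DataFrame(rows, columns=["sirna_id", "role", "replicate", "reading"])


def _overexpression(design: SecondaryDesign, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    t_ref = mock_gfp_p97()
    base_filipin = 1000.0

    def mock_gfp(n):
        return MOCK_GFP_MEDIAN * np.exp(rng.normal(0, MOCK_GFP_SIGMA, size=n))

    for dish in range(1, design.n_dishes + 1):
        gfp = mock_gfp(design.cells_per_dish)
        fil = base_filipin * np.exp(rng.normal(0, design.filipin_cv, size=design.cells_per_dish))
        for i in range(design.cells_per_dish):
            rows.append(("mock", dish, i, gfp[i], fil[i]))

    for c in design.constructs:
        for dish in range(1, design.n_dishes + 1):
            n = design.cells_per_dish
            transfected = rng.random(n) < c.transfected_fraction
            gfp = mock_gfp(n)
            gfp[transfected] = (
                c.gfp_multiplier * t_ref * np.exp(rng.normal(0, 0.25, size=int(transfected.sum())))
            )
            fil = base_filipin * np.exp(rng.normal(0, design.filipin_cv, size=n))
            if c.gfp_coupling:
                mean_t = c.gfp_multiplier * t_ref
                mult = 1.0 + (c.filipin_ratio - 1.0) * (gfp / mean_t)
                fil[transfected] *= np.maximum(mult[transfected], 0.05)
            else:
                fil[transfected] *= c.filipin_ratio
            for i in range(n):
                rows.append((c.gene, dish, i, gfp[i], fil[i]))
    return pd.DataFrame(rows, columns=["construct", "dish", "cell_id", "gfp_total", "filipin_total"])


def simulate_secondary_tables(design: SecondaryDesign, seed: int = 0) -> dict[str, pd.DataFrame]:
    """Generate all four secondary-assay tables from one seed."""
    root = np.random.SeedSequence(seed).spawn(4)
    return {
        "qpcr": _qpcr(design, np.random.default_rng(root[0])),
        "western": _western(design, np.random.default_rng(root[1])),
        "enzymatic": _enzymatic(design, np.random.default_rng(root[2])),
        "overexpression": _overexpression(design, np.random.default_rng(root[3])),
    }
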