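"""Multiparametric phenotypic fingerprints and locus-level aggregation.

A gene's fingerprint is the 2 x 7 matrix of mean deviation values of its
two strongest effector siRNAs (ranked by |mean deviation| on parameter
"total", max over the two assays) across the seven phenotypic parameters:
LDL total/concentration/structures and FC total/concentration/area/
structures.  Entries beyond the control-derived thresholds are flagged
significant.  Genes are classified into direction-pattern groups from the
signed "total" calls of the two siRNAs, and effector calls are aggregated
per GWAS locus (candidate genes within +/-50 kb of the lead SNP).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

from lipidscreen.params import ALL_PARAMETERS, Assay, fingerprint_column
from lipidscreen.screen_stats import DeviationTable, ThresholdSet

FUNCTIONAL_GROUPS = ("cocorrelated", "fc_only", "inverse", "ldl_only", "unclassified")


@dataclass
class Fingerprint:
    """Two-siRNA seven-parameter deviation matrix for one gene."""

    gene: str
    sirnas: list[str]
    matrix: pd.DataFrame = field(repr=False)  # index: sirna, columns: ALL_PARAMETERS
    flags: pd.DataFrame = field(repr=False)  # same shape, bool

    def __post_init__(self) -> None:
        if list(self.matrix.columns) != list(ALL_PARAMETERS):
            raise ValueError("fingerprint must carry exactly the seven parameter columns")


def select_strongest_sirnas(
    gene_sirnas: list[str],
    deviations: dict[str, DeviationTable],
    k: int = 2,
) -> list[str]:
    """Rank a gene's siRNAs by |mean deviation| on "total" (max over assays).

    Deterministic: ties break on the lexicographically smaller siRNA id.
    Returns all siRNAs (with a warning) when fewer than ``k`` are scored.
    """
    strengths = {}
    for sirna in gene_sirnas:
        best = 0.0
        for table in deviations.values():
            m = table.means
            rows = m[(m["sirna_id"] == sirna) & (m["parameter"] == "total")]
            if len(rows):
                val = float(rows["mean_deviation"].abs().max())
                if not np.isnan(val):
                    best = max(best, val)
        strengths[sirna] = best
    ranked = sorted(strengths, key=lambda s: (-strengths[s], s))
    if len(ranked) < k:
        warnings.warn(f"only {len(ranked)} scored siRNAs (requested {k})", stacklevel=2)
    return ranked[:k]


def build_fingerprint(
    gene: str,
    gene_sirnas: list[str],
    deviations: dict[str, DeviationTable],
    thresholds: dict[str, ThresholdSet],
    k: int = 2,
) -> Fingerprint:
    """Assemble the fingerprint of *gene* from per-assay deviation tables.

    ``deviations`` maps assay name to its :class:`DeviationTable`;
    ``thresholds`` maps a fingerprint column (e.g. ``"fc_total"``) to the
    :class:`ThresholdSet` of that assay/parameter.  Missing entries stay
    NaN and are never flagged.
    """
    if not gene_sirnas:
        raise ValueError(f"no scored siRNAs for gene {gene}")
    chosen = select_strongest_sirnas(gene_sirnas, deviations, k=k)
    matrix = pd.DataFrame(np.nan, index=chosen, columns=list(ALL_PARAMETERS))
    flags = pd.DataFrame(False, index=chosen, columns=list(ALL_PARAMETERS))
    for assay_name, table in deviations.items():
        assay = Assay(assay_name)
        m = table.means
        for sirna in chosen:
            sub = m[m["sirna_id"] == sirna]
            for _, row in sub.iterrows():
                try:
                    col = fingerprint_column(assay, row["parameter"])
                except ValueError:
                    continue  # QC parameters are not part of the fingerprint
                matrix.loc[sirna, col] = row["mean_deviation"]
                thr = thresholds.get(col)
                if thr is not None:
                    flags.loc[sirna, col] = thr.classify(row["mean_deviation"]) != "none"
    return Fingerprint(gene=gene, sirnas=chosen, matrix=matrix, flags=flags)


def _assay_direction(fp: Fingerprint, column: str) -> int:
    """Signed consensus on a "total" column: sign of the strongest flagged
    siRNA entry, 0 when nothing is flagged."""
    flagged = [
        (abs(fp.matrix.loc[s, column]), np.sign(fp.matrix.loc[s, column]))
        for s in fp.sirnas
        if fp.flags.loc[s, column]
    ]
    if not flagged:
        return 0
    return int(max(flagged)[1])


def classify_functional_group(fingerprint: Fingerprint) -> str:
    """Direction-pattern group from the signed "total" calls of both assays.

    Same sign in both assays -> 'cocorrelated'; opposite signs ->
    'inverse'; significant in only one assay -> 'fc_only'/'ldl_only';
    nothing significant -> 'unclassified'.
    """
    s_ldl = _assay_direction(fingerprint, "ldl_total")
    s_fc = _assay_direction(fingerprint, "fc_total")
    if s_ldl and s_fc:
        return "cocorrelated" if s_ldl == s_fc else "inverse"
    if s_fc:
        return "fc_only"
    if s_ldl:
        return "ldl_only"
    return "unclassified"


def cluster_fingerprints(fingerprints: list[Fingerprint], n_clusters: int = 5) -> pd.Series:
    """Exploratory alternative to the rule-based groups: hierarchical
    clustering (Euclidean, complete linkage) of flattened fingerprints."""
    genes = [fp.gene for fp in fingerprints]
    mat = np.vstack([np.nan_to_num(fp.matrix.to_numpy().ravel()) for fp in fingerprints])
    labels = fcluster(linkage(mat, method="complete"), t=n_clusters, criterion="maxclust")
    return pd.Series(labels, index=genes, name="cluster")


@dataclass
class LocusSummary:
    """Per-locus tally of tested and effector genes."""

    locus: str
    lead_snps: list[str]
    genes_tested: list[str]
    effector_genes: list[str]

    @property
    def n_effector_genes(self) -> int:
        return len(self.effector_genes)

    @property
    def multi_effector(self) -> bool:
        return self.n_effector_genes > 1

    @property
    def single_prominent_effector(self) -> bool:
        return self.n_effector_genes == 1 and len(self.genes_tested) > 1


def locus_summary(
    gene_calls: pd.DataFrame, annotation: pd.DataFrame
) -> list[LocusSummary]:
    """Aggregate gene-level hit calls per GWAS locus.

    ``annotation`` columns: gene, locus, lead_snp (others pass through).
    Genes called but absent from the annotation are excluded with a
    warning; loci without tested genes are dropped.
    """
    known = set(annotation["gene"])
    missing = sorted(set(gene_calls["gene"]) - known)
    if missing:
        warnings.warn(f"genes missing from annotation, excluded: {missing}", stacklevel=2)
    calls = gene_calls[gene_calls["gene"].isin(known)]
    merged = calls.merge(annotation[["gene", "locus", "lead_snp"]].drop_duplicates("gene"),
                         on="gene", how="left")
    out = []
    for locus, grp in merged.groupby("locus", sort=True):
        out.append(
            LocusSummary(
                locus=str(locus),
                lead_snps=sorted(set(grp["lead_snp"].dropna())),
                genes_tested=sorted(grp["gene"].unique()),
                effector_genes=sorted(grp[grp["is_hit"]]["gene"].unique()),
            )
        )
    return out
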