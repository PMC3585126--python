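"""Headline screen statistics assembled from counts.

The screen's summary numbers are simple ratios of counts — hit genes over
genes tested, validated effector siRNAs over re-screened effectors, images
retained after QC — reported as integer-rounded percentages.
"""

from __future__ import annotations


def percent(numerator: int, denominator: int) -> int:
    """``round(100 * n / d)`` with a zero-denominator guard."""
    if denominator == 0:
        raise ZeroDivisionError("denominator is 0")
    return round(100.0 * numerator / denominator)


def hit_rate(n_hit_genes: int, n_genes_tested: int) -> int:
    """Percentage of tested genes called as hits."""
    return percent(n_hit_genes, n_genes_tested)


def qc_retention(n_passed: int, n_total: int) -> int:
    """Percentage of images retained after quality control."""
    return percent(n_passed, n_total)


def confirmation_rate(n_confirmed: int, n_tested: int) -> int:
    """Percentage of effector siRNAs confirmed in a follow-up assay."""
    return percent(n_confirmed, n_tested)
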