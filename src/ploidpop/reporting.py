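"""Genotyping-rate and filter-attrition summaries.

Small reporting helpers that turn raw counts into the percentages quoted
in a GBS results section: fraction of reads passing filters, fraction of
SNPs genotyped in at least k samples, singleton rates, subsampling rates,
and step-by-step filter attrition tables.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .genotyping import MISSING, AlleleCountMatrix, DiploidGenotypeMatrix


def percentage(numerator: float, denominator: float, digits: int = 1) -> float:
    """100 * numerator / denominator, rounded to ``digits`` decimals."""
    if denominator == 0:
        raise ValueError("zero denominator")
    return round(100.0 * numerator / denominator, digits)


def genotyped_sample_counts(matrix) -> np.ndarray:
    """Per-SNP number of samples with a non-missing call (or any read)."""
    if isinstance(matrix, AlleleCountMatrix):
        return (matrix.total() > 0).sum(axis=0)
    if isinstance(matrix, DiploidGenotypeMatrix):
        return (matrix.calls != MISSING).sum(axis=0)
    return (matrix.calls >= 0).sum(axis=0)  # pseudo-haploid


def snp_genotyping_summary(matrix, thresholds: Sequence[int] = (1,)) -> pd.DataFrame:
    """SNP counts and percentages genotyped in >= each threshold of samples."""
    counts = genotyped_sample_counts(matrix)
    n_snps = counts.size
    rows = [
        {
            "min_samples": t,
            "n_snps": int((counts >= t).sum()),
            "pct_snps": percentage((counts >= t).sum(), n_snps),
        }
        for t in thresholds
    ]
    return pd.DataFrame(rows)


def singleton_summary(counts: AlleleCountMatrix) -> dict[str, object]:
    """SNPs whose minor allele is observed in exactly one sample."""
    a, b = counts.counts_a, counts.counts_b
    minor_is_a = a.sum(axis=0) < b.sum(axis=0)
    m = np.where(minor_is_a[None, :], a, b)
    carriers = (m > 0).sum(axis=0)
    n_singleton = int((carriers == 1).sum())
    per_sample = ((m > 0) & (carriers == 1)[None, :]).sum(axis=1)
    return {
        "n_singleton_snps": n_singleton,
        "pct_singleton_snps": percentage(n_singleton, counts.n_snps),
        "singletons_per_sample": dict(zip(counts.sample_ids, per_sample.tolist())),
    }


def attrition_table(steps: Sequence[tuple[str, int]]) -> pd.DataFrame:
    """Item counts per pipeline step with percentages of the first step."""
    if not steps:
        raise ValueError("no steps given")
    base = steps[0][1]
    return pd.DataFrame(
        [
            {"step": name, "n": n, "pct_of_input": percentage(n, base)}
            for name, n in steps
        ]
    )
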