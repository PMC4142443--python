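"""Heterozygosity and nucleotide-diversity estimation.

Per-sample heterozygosity is the number of heterozygous diploid calls
divided by the number of full diploid calls (HET + HOM); partial and
missing calls are excluded from the denominator.

Nucleotide diversity per group is estimated as the average pairwise
pseudo-haploid genetic distance among its members.  Each pseudo-haploid
genotype is one sampled genome copy, so the expected pairwise difference
per SNP within a random-mating pool with allele frequency p is 2p(1-p) —
the heterozygosity of the pool — making the average pairwise distance a
direct diversity estimate that is comparable across ploidy levels.

Distances are raw proportions of differing calls (p-distance) with
pairwise deletion of missing data; substitution-model corrections are not
meaningful on an ascertained SNP panel (a JC69 transform is available for
sensitivity checks).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

from .genotyping import (
    HET,
    HOM_A,
    HOM_B,
    PH_A,
    PH_B,
    DiploidGenotypeMatrix,
    PseudoHaploidMatrix,
)

logger = logging.getLogger(__name__)


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distances with per-pair completeness counts.

    ``values[i, j]`` is NaN where fewer than the required number of SNPs
    were genotyped in both samples (``n_shared`` keeps the raw counts).
    """

    values: np.ndarray
    sample_ids: list[str]
    n_shared: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.sample_ids)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix shape does not match sample ids")
        if not np.allclose(np.nan_to_num(self.values), np.nan_to_num(self.values.T)):
            raise ValueError("distance matrix must be symmetric")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.sample_ids)

    def select_samples(self, keep: Iterable[str]) -> "DistanceMatrix":
        keep = set(keep)
        idx = [i for i, s in enumerate(self.sample_ids) if s in keep]
        shared = self.n_shared[np.ix_(idx, idx)] if self.n_shared is not None else None
        return DistanceMatrix(
            self.values[np.ix_(idx, idx)], [self.sample_ids[i] for i in idx], shared
        )


@dataclass
class DiversitySummary:
    per_sample_het: pd.Series
    per_group_diversity: pd.Series
    group_sizes: pd.Series


def heterozygosity(diploid: DiploidGenotypeMatrix) -> pd.Series:
    """Per-sample #HET / #(HET + HOM_A + HOM_B); NaN if no full calls."""
    c = diploid.calls
    het = (c == HET).sum(axis=1)
    full = het + (c == HOM_A).sum(axis=1) + (c == HOM_B).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        h = np.where(full > 0, het / np.maximum(full, 1), np.nan)
    if (full == 0).any():
        logger.warning(
            "%d samples with zero full diploid calls: heterozygosity undefined",
            int((full == 0).sum()),
        )
    return pd.Series(h, index=diploid.sample_ids, name="heterozygosity")


def het_calls_vector(calls_row: np.ndarray) -> float:
    """Heterozygosity of a single diploid call vector (helper)."""
    het = int((calls_row == HET).sum())
    full = het + int((calls_row == HOM_A).sum()) + int((calls_row == HOM_B).sum())
    return het / full if full else float("nan")


def pairwise_distance(
    ph: PseudoHaploidMatrix, min_shared: int = 100, model: str = "raw"
) -> DistanceMatrix:
    """Proportion of differing pseudo-haploid calls per sample pair.

    Missing calls are dropped pairwise; pairs sharing fewer than
    ``min_shared`` genotyped SNPs are masked (NaN) rather than estimated.
    ``model='jc69'`` applies the Jukes-Cantor two-state correction
    -0.5 ln(1 - 2d) for sensitivity analyses.
    """
    if len(ph.sample_ids) < 2:
        raise ValueError("need at least two samples")
    x = (ph.calls == PH_A).astype(np.float64)
    y = (ph.calls == PH_B).astype(np.float64)
    shared = x @ x.T + x @ y.T + y @ x.T + y @ y.T
    diffs = x @ y.T + y @ x.T
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(shared > 0, diffs / np.maximum(shared, 1), np.nan)
    low = shared < min_shared
    np.fill_diagonal(low, False)
    if low.any():
        logger.warning(
            "%d sample pairs share fewer than %d SNPs and are masked",
            int(low.sum() // 2), min_shared,
        )
        d[low] = np.nan
    np.fill_diagonal(d, 0.0)
    if model == "jc69":
        with np.errstate(invalid="ignore", divide="ignore"):
            d = np.where(np.isnan(d), np.nan, -0.5 * np.log(np.maximum(1 - 2 * d, 1e-12)))
        np.fill_diagonal(d, 0.0)
    elif model != "raw":
        raise ValueError(f"unknown distance model {model!r}")
    return DistanceMatrix(d, list(ph.sample_ids), shared.astype(np.int64))


def group_diversity(
    dist: DistanceMatrix,
    grouping: Mapping[str, str],
    gene_pool: Optional[Mapping[str, str]] = None,
    exclude: Iterable[str] = (),
) -> pd.Series:
    """Mean within-group pairwise distance per group.

    Groups (typically sampling populations) whose members span multiple
    gene pools are split into per-pool subgroups named ``group|pool``
    before averaging, so each estimate reflects within-pool diversity.
    Admixed samples are removed via the explicit ``exclude`` list.
    Singleton groups are skipped with a log message.
    """
    excluded = set(exclude)
    members: dict[str, list[int]] = {}
    for i, s in enumerate(dist.sample_ids):
        if s in excluded or s not in grouping:
            continue
        key = grouping[s]
        if gene_pool is not None:
            pools = {gene_pool[t] for t in grouping if grouping[t] == key and t in gene_pool}
            if len(pools) > 1 and s in gene_pool:
                key = f"{key}|{gene_pool[s]}"
        members.setdefault(key, []).append(i)
    out = {}
    for g, idx in sorted(members.items()):
        if len(idx) < 2:
            logger.info("group %s has a single sample: skipped", g)
            continue
        sub = dist.values[np.ix_(idx, idx)]
        iu = np.triu_indices(len(idx), 1)
        vals = sub[iu]
        out[g] = float(np.nanmean(vals))
    return pd.Series(out, name="diversity", dtype=float)


def summarize_diversity(
    diploid: DiploidGenotypeMatrix,
    dist: DistanceMatrix,
    grouping: Mapping[str, str],
    gene_pool: Optional[Mapping[str, str]] = None,
    exclude: Iterable[str] = (),
) -> DiversitySummary:
    """Bundle per-sample heterozygosity with per-group diversity."""
    het = heterozygosity(diploid)
    div = group_diversity(dist, grouping, gene_pool, exclude)
    sizes = pd.Series(
        {g: sum(1 for s in grouping if grouping[s] == g.split("|")[0]) for g in div.index},
        dtype=int,
    )
    return DiversitySummary(het, div, sizes)
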