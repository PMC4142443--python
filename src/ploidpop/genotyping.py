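"""Genotype calling from GBS allele read counts, and SNP/locus/sample filters.

Genotyping-by-sequencing yields, for each sample at each biallelic SNP, a
pair of read counts (allele A, allele B).  Two callers convert these counts
into genotypes:

* **pseudo-haploid** — sample one read per cell and call its allele.  The
  resulting single-copy genotypes are comparable across ploidy levels and
  underlie all genetic-distance analyses.
* **diploid** — a deterministic truth table producing six call states
  (HOM_A, HOM_B, HET, PARTIAL_A, PARTIAL_B, MISSING).  Heterozygotes
  require at least one read of each allele; homozygotes require >=6 reads
  of one allele and none of the other; 1-5 reads of a single allele give a
  partial call.  Valid for disomic tetraploids; octoploids are analysed
  with the understanding that their heterozygosity is inflated.

The filters mirror a standard GBS quality pipeline: drop low-read samples,
drop loci whose SNP spacing suggests indels, drop SNPs far from the
restriction site, and keep only SNPs whose per-sample allele counts vary
more than a monomorphic-locus + sequencing-error null allows (chi-squared).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

# Diploid call codes (int8).
MISSING = 0
HOM_A = 1
HOM_B = 2
HET = 3
PARTIAL_A = 4
PARTIAL_B = 5

DIPLOID_LABELS = {
    MISSING: "NA",
    HOM_A: "AA",
    HOM_B: "BB",
    HET: "AB",
    PARTIAL_A: "A:NA",
    PARTIAL_B: "B:NA",
}
DIPLOID_CODES = {v: k for k, v in DIPLOID_LABELS.items()}

# Pseudo-haploid call codes.
PH_MISSING = -1
PH_A = 0
PH_B = 1

PH_LABELS = {PH_MISSING: "NA", PH_A: "A", PH_B: "B"}
PH_CODES = {v: k for k, v in PH_LABELS.items()}


def locus_of(snp_id: str) -> str:
    """Locus component of a ``locus:offset`` SNP identifier."""
    return snp_id.rsplit(":", 1)[0]


def _check_ids(ids: Sequence[str], what: str) -> list[str]:
    ids = list(ids)
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate {what} identifiers")
    return ids


@dataclass
class AlleleCountMatrix:
    """Per-(sample, SNP) read counts for the two alleles of biallelic SNPs.

    ``snp_ids`` follow the ``locus:offset`` convention so that every SNP
    carries its GBS locus and its 0-based position within the tag.
    """

    counts_a: np.ndarray
    counts_b: np.ndarray
    sample_ids: list[str]
    snp_ids: list[str]

    def __post_init__(self) -> None:
        self.counts_a = np.asarray(self.counts_a)
        self.counts_b = np.asarray(self.counts_b)
        if self.counts_a.shape != self.counts_b.shape:
            raise ValueError("counts_a and counts_b shapes differ")
        for c in (self.counts_a, self.counts_b):
            if not np.issubdtype(c.dtype, np.integer):
                raise ValueError("allele counts must be integers")
            if (c < 0).any():
                raise ValueError("allele counts must be non-negative")
        self.sample_ids = _check_ids(self.sample_ids, "sample")
        self.snp_ids = _check_ids(self.snp_ids, "SNP")
        if self.counts_a.shape != (len(self.sample_ids), len(self.snp_ids)):
            raise ValueError("counts shape does not match id lists")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def total(self) -> np.ndarray:
        return self.counts_a + self.counts_b

    def read_totals(self) -> dict[str, int]:
        """Total read count per sample (over both alleles and all SNPs)."""
        tot = self.total().sum(axis=1)
        return {s: int(t) for s, t in zip(self.sample_ids, tot)}

    def locus_ids(self) -> list[str]:
        return [locus_of(s) for s in self.snp_ids]

    def select_snps(self, keep: Iterable[str]) -> "AlleleCountMatrix":
        keep = set(keep)
        idx = [j for j, s in enumerate(self.snp_ids) if s in keep]
        return AlleleCountMatrix(
            self.counts_a[:, idx], self.counts_b[:, idx],
            list(self.sample_ids), [self.snp_ids[j] for j in idx],
        )

    def select_samples(self, keep: Iterable[str]) -> "AlleleCountMatrix":
        keep = set(keep)
        idx = [i for i, s in enumerate(self.sample_ids) if s in keep]
        return AlleleCountMatrix(
            self.counts_a[idx], self.counts_b[idx],
            [self.sample_ids[i] for i in idx], list(self.snp_ids),
        )


@dataclass
class PseudoHaploidMatrix:
    """Single-allele calls in {A, B, missing}; one sampled read per cell."""

    calls: np.ndarray  # int8, PH_* codes
    sample_ids: list[str]
    snp_ids: list[str]
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.sample_ids), len(self.snp_ids)):
            raise ValueError("calls shape does not match id lists")

    def select_snps(self, keep: Iterable[str]) -> "PseudoHaploidMatrix":
        keep = set(keep)
        idx = [j for j, s in enumerate(self.snp_ids) if s in keep]
        return PseudoHaploidMatrix(
            self.calls[:, idx], list(self.sample_ids),
            [self.snp_ids[j] for j in idx], self.seed,
        )

    def select_samples(self, keep: Iterable[str]) -> "PseudoHaploidMatrix":
        keep = set(keep)
        idx = [i for i, s in enumerate(self.sample_ids) if s in keep]
        return PseudoHaploidMatrix(
            self.calls[idx], [self.sample_ids[i] for i in idx],
            list(self.snp_ids), self.seed,
        )

    def subsample_snps(self, fraction: float, seed: int) -> "PseudoHaploidMatrix":
        """Random SNP subset (the optional panel-thinning step), seeded."""
        rng = np.random.default_rng(seed)
        keep = rng.random(len(self.snp_ids)) < fraction
        idx = np.flatnonzero(keep)
        return PseudoHaploidMatrix(
            self.calls[:, idx], list(self.sample_ids),
            [self.snp_ids[j] for j in idx], self.seed,
        )


@dataclass
class DiploidGenotypeMatrix:
    """Six-state diploid calls; see module docstring for the truth table."""

    calls: np.ndarray  # int8, diploid codes
    sample_ids: list[str]
    snp_ids: list[str]

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.sample_ids), len(self.snp_ids)):
            raise ValueError("calls shape does not match id lists")

    def sample_index(self, sample: str) -> int:
        try:
            return self.sample_ids.index(sample)
        except ValueError:
            raise KeyError(f"unknown sample {sample!r}") from None

    def select_snps(self, keep: Iterable[str]) -> "DiploidGenotypeMatrix":
        keep = set(keep)
        idx = [j for j, s in enumerate(self.snp_ids) if s in keep]
        return DiploidGenotypeMatrix(
            self.calls[:, idx], list(self.sample_ids),
            [self.snp_ids[j] for j in idx],
        )

    def select_samples(self, keep: Iterable[str]) -> "DiploidGenotypeMatrix":
        keep = set(keep)
        idx = [i for i, s in enumerate(self.sample_ids) if s in keep]
        return DiploidGenotypeMatrix(
            self.calls[idx], [self.sample_ids[i] for i in idx], list(self.snp_ids),
        )


@dataclass(frozen=True)
class LocusAnnotation:
    """Per-locus SNP layout: tag offsets, restriction-site distances, mapping.

    ``mapped_interval`` is an optional (chrom, start, end) in 0-based
    half-open BED convention.
    """

    locus_id: str
    snp_offsets: tuple[int, ...]
    distance_to_restriction_site: tuple[int, ...] = field(default=())
    mapped_interval: Optional[tuple[str, int, int]] = None

    def __post_init__(self) -> None:
        if any(o < 0 for o in self.snp_offsets):
            raise ValueError("SNP offsets must be non-negative")
        if list(self.snp_offsets) != sorted(self.snp_offsets):
            raise ValueError("SNP offsets must be sorted")
        if self.distance_to_restriction_site and len(
            self.distance_to_restriction_site
        ) != len(self.snp_offsets):
            raise ValueError("one restriction-site distance per SNP required")
        if self.mapped_interval is not None:
            _, start, end = self.mapped_interval
            if not start < end:
                raise ValueError("mapped interval must satisfy start < end")

    def snp_ids(self) -> list[str]:
        return [f"{self.locus_id}:{o}" for o in self.snp_offsets]


def call_pseudo_haploid(counts: AlleleCountMatrix, seed: int) -> PseudoHaploidMatrix:
    """Sample one read per cell and call its allele.

    Cells with no reads are MISSING.  A Philox counter-based generator keyed
    on ``seed`` supplies one uniform per cell at a fixed row-major stream
    position, so each cell's draw depends only on (seed, sample index, SNP
    index) and results are bit-identical across runs.
    """
    rng = np.random.Generator(np.random.Philox(key=seed))
    u = rng.random(counts.counts_a.shape)
    total = counts.total()
    with np.errstate(divide="ignore", invalid="ignore"):
        p_a = np.where(total > 0, counts.counts_a / np.maximum(total, 1), 0.0)
    calls = np.where(u < p_a, PH_A, PH_B).astype(np.int8)
    calls[total == 0] = PH_MISSING
    return PseudoHaploidMatrix(calls, list(counts.sample_ids), list(counts.snp_ids), seed)


def call_diploid(
    counts: AlleleCountMatrix, min_hom_reads: int = 6
) -> DiploidGenotypeMatrix:
    """Deterministic six-state diploid calls from allele counts.

    HET needs >=1 read of each allele; HOM_X needs >=``min_hom_reads`` reads
    of X with none of the other; 1..(min_hom_reads-1) reads of a single
    allele give PARTIAL_X; no reads give MISSING.
    """
    a, b = counts.counts_a, counts.counts_b
    calls = np.full(a.shape, MISSING, dtype=np.int8)
    calls[(a > 0) & (b > 0)] = HET
    calls[(a >= min_hom_reads) & (b == 0)] = HOM_A
    calls[(b >= min_hom_reads) & (a == 0)] = HOM_B
    calls[(a > 0) & (a < min_hom_reads) & (b == 0)] = PARTIAL_A
    calls[(b > 0) & (b < min_hom_reads) & (a == 0)] = PARTIAL_B
    return DiploidGenotypeMatrix(calls, list(counts.sample_ids), list(counts.snp_ids))


def filter_samples_by_reads(
    read_totals: Mapping[str, int], threshold: int = 310_000
) -> list[str]:
    """Samples with at least ``threshold`` total reads, order preserved.

    The default mirrors the read-count cut-off below which GBS genotype
    matrices become missing-data dominated.
    """
    if any(t < 0 for t in read_totals.values()):
        raise ValueError("read totals must be non-negative")
    kept = [s for s, t in read_totals.items() if t >= threshold]
    logger.info("read filter: %d/%d samples retained", len(kept), len(read_totals))
    if not kept:
        raise ValueError(f"no sample reaches {threshold} reads")
    return kept


def filter_indel_loci(annotations: Iterable[LocusAnnotation]) -> list[str]:
    """Drop loci with SNPs at >=3 consecutive tag positions (likely indels)."""
    kept = []
    n = 0
    for ann in annotations:
        n += 1
        off = np.asarray(ann.snp_offsets)
        run = np.diff(off) == 1
        has_triplet = len(off) >= 3 and bool((run[:-1] & run[1:]).any())
        if not has_triplet:
            kept.append(ann.locus_id)
    logger.info("indel filter: %d/%d loci retained", len(kept), n)
    return kept


def filter_far_snps(
    annotations: Iterable[LocusAnnotation], max_dist: int = 50
) -> list[str]:
    """Keep SNPs within ``max_dist`` bp of the restriction site.

    "More than 50 bp" is read strictly: distance 50 is retained, 51 removed.
    Read quality degrades toward tag ends, so distant SNPs are suspect.
    """
    kept, n = [], 0
    for ann in annotations:
        if not ann.distance_to_restriction_site:
            raise ValueError(f"locus {ann.locus_id} lacks restriction-site distances")
        for sid, d in zip(ann.snp_ids(), ann.distance_to_restriction_site):
            n += 1
            if d <= max_dist:
                kept.append(sid)
    logger.info("restriction-distance filter: %d/%d SNPs retained", len(kept), n)
    return kept


def chi_square_snp_filter(
    counts: AlleleCountMatrix,
    error_rate: float = 0.01,
    alpha: float = 0.05,
    min_reads_per_sample: int = 2,
) -> list[str]:
    """Keep SNPs whose per-sample allele counts reject a monomorphic null.

    Null model: the locus is monomorphic and minor-allele reads arise from
    symmetric sequencing error at ``error_rate``, so per-sample minor counts
    are Binomial(n_i, error_rate).  Each sample with at least
    ``min_reads_per_sample`` reads contributes the upper-tail binomial
    probability of its minor count; samples below the read floor are pooled
    into a single cell.  The tail probabilities are combined with Fisher's
    method, giving a chi-squared statistic with two degrees of freedom per
    cell (the combined statistic is conservative under the binomial's
    discreteness, which keeps the false-retention rate at or below alpha
    even for the near-empty cells typical of GBS depth).  A SNP is retained
    iff the null is rejected at ``alpha``.  Zero-read SNPs are excluded
    with a warning.
    """
    if not 0.0 < error_rate < 0.5:
        raise ValueError("error_rate must be in (0, 0.5)")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    a, b = counts.counts_a.astype(np.int64), counts.counts_b.astype(np.int64)
    n = a + b
    tot_a, tot_b = a.sum(axis=0), b.sum(axis=0)
    minor_is_a = tot_a < tot_b
    m = np.where(minor_is_a[None, :], a, b)

    e = error_rate
    big = n >= min_reads_per_sample
    # P(Bin(n_i, e) >= m_i); sf(m-1) is the inclusive upper tail
    tail = stats.binom.sf(m - 1, np.maximum(n, 1), e)
    tail[n == 0] = 1.0
    with np.errstate(divide="ignore"):
        logs = np.log(np.clip(tail, 1e-300, 1.0))
    stat = -2.0 * np.where(big, logs, 0.0).sum(axis=0)

    small = ~big
    pool_n = np.where(small, n, 0).sum(axis=0)
    pool_m = np.where(small, m, 0).sum(axis=0)
    has_pool = pool_n > 0
    pool_tail = stats.binom.sf(pool_m - 1, np.maximum(pool_n, 1), e)
    with np.errstate(divide="ignore"):
        pool_logs = np.log(np.clip(pool_tail, 1e-300, 1.0))
    stat = stat + np.where(has_pool, -2.0 * pool_logs, 0.0)
    df = 2 * (big.sum(axis=0) + has_pool.astype(int))

    zero = n.sum(axis=0) == 0
    if zero.any():
        logger.warning("%d SNPs with zero total reads excluded", int(zero.sum()))
    pval = np.ones(counts.n_snps)
    ok = (df > 0) & ~zero
    pval[ok] = stats.chi2.sf(stat[ok], df[ok])
    kept = [s for s, p, z in zip(counts.snp_ids, pval, zero) if (p < alpha and not z)]
    logger.info("chi-squared filter: %d/%d SNPs retained", len(kept), counts.n_snps)
    return kept
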