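"""Synthetic GBS datasets with the structure the analysis assumes.

The generator emulates a range-wide collection of a mixed-ploidy,
outcrossing grass: two ecotypes, each containing three regional gene
pools, with hierarchical Balding-Nichols divergence (ecotype divergence
F_e over ancestral frequencies, pool divergence F_p nested within
ecotypes).  Tetraploids are disomic and drawn Binomial(2, p); octoploids
are formed by combining two tetraploid lineage draws (by default from two
different pools of the same ecotype, emulating allopolyploid origin by
admixture); dihaploid controls are haploid draws doubled, hence fully
homozygous; F1 hybrids carry one haplotype from each ecotype.  A fraction
of loci are planted "coassembled homeologs" whose read counts merge two
independent loci.  Per-cell read depth is negative binomial and reads
carry a symmetric sequencing error.

Every draw flows from one master seed, and truth tables (genotype calls,
homeolog flags, ancestries) are emitted alongside the read counts so
every pipeline stage can be scored against known truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .genotyping import (
    HET,
    HOM_A,
    HOM_B,
    AlleleCountMatrix,
    LocusAnnotation,
)

TAG_LENGTH = 80  # usable bp of a GBS tag downstream of the restriction site
N_CHROMOSOMES = 9
LOCUS_SPACING = 5_000  # bp between simulated locus starts on a chromosome


@dataclass
class SimConfig:
    """Study-design parameters of the synthetic cohort.

    Defaults describe the emulated design: 2 ecotypes x 3 pools x 8
    samples, ~2000 loci of 1-3 SNPs, ecotype divergence well above pool
    divergence, negative-binomial depth around 8 reads, two dihaploid
    controls from the first lowland pool, three planted inter-ecotype
    hybrids, and 5% coassembled-homeolog loci.
    """

    n_pools_per_ecotype: int = 3
    samples_per_pool: int = 8
    pool_ploidies: tuple[tuple[int, ...], ...] = ((4, 4, 8), (4, 8, 8))
    minority_cytotype_fraction: float = 0.125
    n_loci: int = 2000
    max_snps_per_locus: int = 3
    f_ecotype: float = 0.35
    f_pool: float = 0.12
    ancestral_freq_range: tuple[float, float] = (0.1, 0.9)
    depth_mean: float = 8.0
    depth_dispersion: float = 2.0  # NB shape; variance = mu + mu^2/k
    error_rate: float = 0.005
    homeolog_fraction: float = 0.05
    n_dihaploids: int = 2
    n_hybrids: int = 3
    octoploids_admixed: bool = True
    depth_scales_with_ploidy: bool = False  # library normalization equalizes depth
    within_pool_scatter_deg: float = 0.5
    pool_centroids: Optional[tuple[tuple[float, float], ...]] = None
    seed: int = 0

    def __post_init__(self) -> None:
        for frac in (
            self.minority_cytotype_fraction,
            self.homeolog_fraction,
            self.error_rate,
        ):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")
        if self.depth_mean <= 0:
            raise ValueError("depth_mean must be positive")
        if len(self.pool_ploidies) != 2 or any(
            len(p) != self.n_pools_per_ecotype for p in self.pool_ploidies
        ):
            raise ValueError("pool_ploidies must give one ploidy per pool per ecotype")

    def centroids(self) -> list[tuple[float, float]]:
        """(lat, lon) per global pool; default grid spans the emulated range."""
        if self.pool_centroids is not None:
            return list(self.pool_centroids)
        lons = np.linspace(-98.0, -78.0, self.n_pools_per_ecotype)
        out = [(30.0, float(lon)) for lon in lons]  # ecotype 0 (lowland), south
        out += [(43.0, float(lon)) for lon in lons]  # ecotype 1 (upland), north
        return out


ECOTYPE_NAMES = ("lowland", "upland")


@dataclass
class FrequencyTable:
    ancestral: np.ndarray  # (n_snps,)
    ecotype: np.ndarray  # (2, n_snps)
    pool: np.ndarray  # (n_pools_total, n_snps)
    pool_names: list[str]
    pool_ecotype: list[int]  # ecotype index per pool
    snp_ids: list[str]
    shadow: Optional["FrequencyTable"] = None  # homeolog partner-locus frequencies


@dataclass
class SimTruth:
    truth_calls: np.ndarray  # diploid-code truth genotypes (primary locus)
    shadow_truth_calls: np.ndarray  # meaningful only at homeolog SNPs
    homeolog_snp: np.ndarray  # bool per SNP
    octoploid_parent_pools: dict[str, tuple[str, str]]
    hybrid_ancestry: dict[str, tuple[str, str]]


@dataclass
class SyntheticDataset:
    counts: AlleleCountMatrix
    metadata: pd.DataFrame  # indexed by sample id
    truth: SimTruth
    annotations: list[LocusAnnotation]
    frequencies: FrequencyTable
    config: SimConfig

    def bed_frame(self) -> pd.DataFrame:
        rows = [
            {
                "chrom": ann.mapped_interval[0],
                "start": ann.mapped_interval[1],
                "end": ann.mapped_interval[2],
                "name": ann.locus_id,
            }
            for ann in self.annotations
            if ann.mapped_interval is not None
        ]
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])


def _balding_nichols(p: np.ndarray, f: float, rng: np.random.Generator) -> np.ndarray:
    """One Balding-Nichols draw around ancestral frequencies p with FST f."""
    if f <= 1e-9:
        return p.copy()
    if f >= 1 - 1e-9:
        return (rng.random(p.shape) < p).astype(float)
    scale = (1 - f) / f
    out = p.copy()
    seg = (p > 0) & (p < 1)
    out[seg] = rng.beta(p[seg] * scale, (1 - p[seg]) * scale)
    return out


def _snp_layout(config: SimConfig, rng: np.random.Generator):
    """Locus annotations plus the flat SNP id list."""
    annotations = []
    snp_ids: list[str] = []
    loci_per_chrom = int(np.ceil(config.n_loci / N_CHROMOSOMES))
    for i in range(config.n_loci):
        n_snps = int(rng.integers(1, config.max_snps_per_locus + 1))
        offsets = tuple(
            sorted(rng.choice(TAG_LENGTH, size=n_snps, replace=False).tolist())
        )
        chrom = f"Chr{i // loci_per_chrom + 1:02d}"
        start = (i % loci_per_chrom) * LOCUS_SPACING
        ann = LocusAnnotation(
            locus_id=f"L{i:05d}",
            snp_offsets=offsets,
            distance_to_restriction_site=offsets,
            mapped_interval=(chrom, start, start + TAG_LENGTH),
        )
        annotations.append(ann)
        snp_ids.extend(ann.snp_ids())
    return annotations, snp_ids


def simulate_frequencies(
    config: SimConfig, rng: Optional[np.random.Generator] = None
) -> FrequencyTable:
    """Hierarchical island-model allele frequencies (plus homeolog shadows).

    Ancestral frequencies are uniform on ``ancestral_freq_range``; ecotype
    frequencies are Balding-Nichols draws at ``f_ecotype``; pool
    frequencies are nested draws at ``f_pool`` around their ecotype.  The
    shadow table gives the independent partner-locus frequencies used at
    planted homeolog loci.
    """
    own_rng = rng is None
    if own_rng:
        rng = np.random.default_rng(config.seed)
    annotations, snp_ids = _snp_layout(config, rng)
    n_snps = len(snp_ids)
    lo, hi = config.ancestral_freq_range

    def hierarchy(r: np.random.Generator) -> FrequencyTable:
        anc = r.uniform(lo, hi, n_snps)
        eco = np.stack([_balding_nichols(anc, config.f_ecotype, r) for _ in range(2)])
        pools, names, pool_eco = [], [], []
        for e in range(2):
            for p in range(config.n_pools_per_ecotype):
                pools.append(_balding_nichols(eco[e], config.f_pool, r))
                names.append(f"{ECOTYPE_NAMES[e]}_P{p + 1}")
                pool_eco.append(e)
        return FrequencyTable(anc, eco, np.stack(pools), names, pool_eco, list(snp_ids))

    table = hierarchy(rng)
    table.shadow = hierarchy(rng)
    table.annotations = annotations  # type: ignore[attr-defined]
    return table


def _truth_from_fraction(f: np.ndarray) -> np.ndarray:
    calls = np.full(f.shape, HET, dtype=np.int8)
    calls[f == 0.0] = HOM_A
    calls[f == 1.0] = HOM_B
    return calls


def _sample_fraction(
    kind: str,
    pool_idx: int,
    partner_idx: int,
    freqs: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """True B-allele fraction of one sample's genome at every SNP."""
    p = freqs[pool_idx]
    if kind == "tetraploid":
        return rng.binomial(2, p) / 2.0
    if kind == "octoploid":
        g1 = rng.binomial(2, p)
        g2 = rng.binomial(2, freqs[partner_idx])
        return (g1 + g2) / 4.0
    if kind == "dihaploid":
        return (rng.random(p.shape) < p).astype(float)
    raise ValueError(kind)


def _reads(
    frac: np.ndarray,
    shadow_frac: np.ndarray,
    homeolog: np.ndarray,
    depth_mean: float,
    config: SimConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """NB-depth reads with symmetric error; homeolog SNPs merge two loci."""
    k = config.depth_dispersion
    p_nb = k / (k + depth_mean)
    e = config.error_rate

    d1 = rng.negative_binomial(k, p_nb, frac.shape)
    b = rng.binomial(d1, frac * (1 - e) + (1 - frac) * e)
    a = d1 - b
    d2 = rng.negative_binomial(k, p_nb, frac.shape)
    b2 = rng.binomial(d2, shadow_frac * (1 - e) + (1 - shadow_frac) * e)
    b = np.where(homeolog, b + b2, b)
    a = np.where(homeolog, a + d2 - b2, a)
    return a.astype(np.int64), b.astype(np.int64)


def simulate_genotypes_and_reads(
    freqs: FrequencyTable, config: SimConfig, rng: np.random.Generator
) -> tuple[AlleleCountMatrix, SimTruth, pd.DataFrame]:
    """Cohort genotypes and read counts (pools + dihaploids, no hybrids)."""
    n_snps = len(freqs.snp_ids)
    locus_index = np.asarray(
        [int(s.rsplit(":", 1)[0][1:]) for s in freqs.snp_ids]
    )
    n_homeolog_loci = int(round(config.homeolog_fraction * config.n_loci))
    homeolog_loci = rng.choice(config.n_loci, size=n_homeolog_loci, replace=False)
    homeolog_snp = np.isin(locus_index, homeolog_loci)

    centroids = config.centroids()
    scatter = config.within_pool_scatter_deg
    n_pools = len(freqs.pool_names)

    rows_a, rows_b, truth_rows, shadow_rows, meta = [], [], [], [], []
    oct_parents: dict[str, tuple[str, str]] = {}

    for g in range(n_pools):
        e = freqs.pool_ecotype[g]
        pool_name = freqs.pool_names[g]
        primary_ploidy = config.pool_ploidies[e][g % config.n_pools_per_ecotype]
        n_minor = int(round(config.minority_cytotype_fraction * config.samples_per_pool))
        lat0, lon0 = centroids[g]
        pop_centers = [
            (lat0 + rng.normal(0, scatter), lon0 + rng.normal(0, scatter))
            for _ in range(2)
        ]
        same_eco = [
            h for h in range(n_pools) if freqs.pool_ecotype[h] == e and h != g
        ]
        for k in range(config.samples_per_pool):
            ploidy = primary_ploidy if k >= n_minor else (12 - primary_ploidy)
            sample = f"{pool_name}_s{k:02d}"
            if ploidy == 8:
                partner = int(rng.choice(same_eco)) if config.octoploids_admixed else g
                kind = "octoploid"
                oct_parents[sample] = (pool_name, freqs.pool_names[partner])
            else:
                partner, kind = g, "tetraploid"
            frac = _sample_fraction(kind, g, partner, freqs.pool, rng)
            sh_frac = _sample_fraction(kind, g, partner, freqs.shadow.pool, rng)
            depth = config.depth_mean * (
                ploidy / 4.0 if config.depth_scales_with_ploidy else 1.0
            )
            a, b = _reads(frac, sh_frac, homeolog_snp, depth, config, rng)
            rows_a.append(a)
            rows_b.append(b)
            truth_rows.append(_truth_from_fraction(frac))
            shadow_rows.append(_truth_from_fraction(sh_frac))
            plat, plon = pop_centers[k % 2]
            meta.append(
                {
                    "sample": sample,
                    "ecotype": ECOTYPE_NAMES[e],
                    "gene_pool": pool_name,
                    "population": f"{pool_name}_pop{k % 2 + 1}",
                    "ploidy": ploidy,
                    "dihaploid": False,
                    "hybrid": False,
                    "latitude": plat + rng.normal(0, scatter / 2),
                    "longitude": plon + rng.normal(0, scatter / 2),
                }
            )

    # Dihaploid controls: haploid draws from the first pool, doubled.
    di_pool = 0
    lat0, lon0 = centroids[di_pool]
    for k in range(config.n_dihaploids):
        sample = f"dihaploid_s{k:02d}"
        frac = _sample_fraction("dihaploid", di_pool, di_pool, freqs.pool, rng)
        sh_frac = _sample_fraction("dihaploid", di_pool, di_pool, freqs.shadow.pool, rng)
        a, b = _reads(frac, sh_frac, homeolog_snp, config.depth_mean, config, rng)
        rows_a.append(a)
        rows_b.append(b)
        truth_rows.append(_truth_from_fraction(frac))
        shadow_rows.append(_truth_from_fraction(sh_frac))
        meta.append(
            {
                "sample": sample,
                "ecotype": ECOTYPE_NAMES[freqs.pool_ecotype[di_pool]],
                "gene_pool": freqs.pool_names[di_pool],
                "population": f"{freqs.pool_names[di_pool]}_dihaploid",
                "ploidy": 2,
                "dihaploid": True,
                "hybrid": False,
                "latitude": lat0 + rng.normal(0, scatter),
                "longitude": lon0 + rng.normal(0, scatter),
            }
        )

    metadata = pd.DataFrame(meta).set_index("sample")
    counts = AlleleCountMatrix(
        np.vstack(rows_a), np.vstack(rows_b), list(metadata.index), list(freqs.snp_ids)
    )
    truth = SimTruth(
        truth_calls=np.vstack(truth_rows),
        shadow_truth_calls=np.vstack(shadow_rows),
        homeolog_snp=homeolog_snp,
        octoploid_parent_pools=oct_parents,
        hybrid_ancestry={},
    )
    return counts, truth, metadata


def plant_hybrids(
    freqs: FrequencyTable,
    config: SimConfig,
    rng: np.random.Generator,
    homeolog_snp: Optional[np.ndarray] = None,
) -> tuple[AlleleCountMatrix, SimTruth, pd.DataFrame]:
    """F1 hybrids: one haplotype drawn from a pool of each ecotype.

    ``homeolog_snp`` should carry the cohort's planted-homeolog mask so the
    hybrids' reads merge the same locus pairs; standalone use may omit it.
    """
    pools_by_eco = {
        e: [i for i, pe in enumerate(freqs.pool_ecotype) if pe == e] for e in (0, 1)
    }
    if homeolog_snp is None:
        homeolog_snp = np.zeros(len(freqs.snp_ids), dtype=bool)

    rows_a, rows_b, truth_rows, meta = [], [], [], {}
    ancestry = {}
    records = []
    centroids = config.centroids()
    for k in range(config.n_hybrids):
        g_low = int(rng.choice(pools_by_eco[0]))
        g_up = int(rng.choice(pools_by_eco[1]))
        hap_l = (rng.random(len(freqs.snp_ids)) < freqs.pool[g_low]).astype(int)
        hap_u = (rng.random(len(freqs.snp_ids)) < freqs.pool[g_up]).astype(int)
        frac = (hap_l + hap_u) / 2.0
        sh_l = (rng.random(len(freqs.snp_ids)) < freqs.shadow.pool[g_low]).astype(int)
        sh_u = (rng.random(len(freqs.snp_ids)) < freqs.shadow.pool[g_up]).astype(int)
        sh_frac = (sh_l + sh_u) / 2.0
        a, b = _reads(frac, sh_frac, homeolog_snp, config.depth_mean, config, rng)
        sample = f"hybrid_s{k:02d}"
        rows_a.append(a)
        rows_b.append(b)
        truth_rows.append(_truth_from_fraction(frac))
        ancestry[sample] = (freqs.pool_names[g_low], freqs.pool_names[g_up])
        lat = (centroids[g_low][0] + centroids[g_up][0]) / 2 + rng.normal(0, 1)
        lon = (centroids[g_low][1] + centroids[g_up][1]) / 2 + rng.normal(0, 1)
        records.append(
            {
                "sample": sample,
                "ecotype": "hybrid",
                "gene_pool": "hybrid",
                "population": "hybrid",
                "ploidy": 4,
                "dihaploid": False,
                "hybrid": True,
                "latitude": lat,
                "longitude": lon,
            }
        )
    metadata = pd.DataFrame(
        records,
        columns=[
            "sample", "ecotype", "gene_pool", "population", "ploidy",
            "dihaploid", "hybrid", "latitude", "longitude",
        ],
    ).set_index("sample")
    counts = AlleleCountMatrix(
        np.vstack(rows_a) if rows_a else np.zeros((0, len(freqs.snp_ids)), dtype=np.int64),
        np.vstack(rows_b) if rows_b else np.zeros((0, len(freqs.snp_ids)), dtype=np.int64),
        list(metadata.index),
        list(freqs.snp_ids),
    )
    truth = SimTruth(
        truth_calls=(
            np.vstack(truth_rows)
            if truth_rows
            else np.zeros((0, len(freqs.snp_ids)), dtype=np.int8)
        ),
        shadow_truth_calls=np.zeros_like(
            np.vstack(truth_rows)
            if truth_rows
            else np.zeros((0, len(freqs.snp_ids)), dtype=np.int8)
        ),
        homeolog_snp=homeolog_snp,
        octoploid_parent_pools={},
        hybrid_ancestry=ancestry,
    )
    return counts, truth, metadata


def simulate_dataset(config: SimConfig) -> SyntheticDataset:
    """Full synthetic dataset: pools, dihaploids and hybrids, with truth."""
    rng = np.random.default_rng(config.seed)
    freqs = simulate_frequencies(config, rng)
    counts, truth, metadata = simulate_genotypes_and_reads(freqs, config, rng)
    if config.n_hybrids > 0:
        hc, ht, hm = plant_hybrids(freqs, config, rng, truth.homeolog_snp)
        counts = AlleleCountMatrix(
            np.vstack([counts.counts_a, hc.counts_a]),
            np.vstack([counts.counts_b, hc.counts_b]),
            counts.sample_ids + hc.sample_ids,
            list(counts.snp_ids),
        )
        truth = SimTruth(
            truth_calls=np.vstack([truth.truth_calls, ht.truth_calls]),
            shadow_truth_calls=np.vstack(
                [truth.shadow_truth_calls, ht.shadow_truth_calls]
            ),
            homeolog_snp=truth.homeolog_snp,
            octoploid_parent_pools=truth.octoploid_parent_pools,
            hybrid_ancestry=ht.hybrid_ancestry,
        )
        metadata = pd.concat([metadata, hm])
    return SyntheticDataset(
        counts=counts,
        metadata=metadata,
        truth=truth,
        annotations=freqs.annotations,  # type: ignore[attr-defined]
        frequencies=freqs,
        config=config,
    )
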