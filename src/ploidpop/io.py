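"""Readers and writers for the pipeline's tabular formats.

Allele counts travel as a TSV matrix pair (``counts_a.tsv`` +
``counts_b.tsv``; sample-major, header row of SNP ids) or come from a VCF
with per-sample allele depths (``AD``).  Genotype matrices, metadata,
locus annotations, distance matrices (square TSV and PHYLIP) and BED
intervals round-trip through plain text.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Optional, Union

import numpy as np
import pandas as pd

from .diversity import DistanceMatrix
from .genotyping import (
    DIPLOID_CODES,
    DIPLOID_LABELS,
    PH_CODES,
    PH_LABELS,
    AlleleCountMatrix,
    DiploidGenotypeMatrix,
    LocusAnnotation,
    PseudoHaploidMatrix,
)

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]


def write_counts(counts: AlleleCountMatrix, path_a: PathLike, path_b: PathLike) -> None:
    for mat, path in ((counts.counts_a, path_a), (counts.counts_b, path_b)):
        pd.DataFrame(mat, index=counts.sample_ids, columns=counts.snp_ids).to_csv(
            path, sep="\t", index_label="sample"
        )


def read_counts(path_a: PathLike, path_b: PathLike) -> AlleleCountMatrix:
    a = pd.read_csv(path_a, sep="\t", index_col="sample")
    b = pd.read_csv(path_b, sep="\t", index_col="sample")
    if list(a.index) != list(b.index) or list(a.columns) != list(b.columns):
        raise ValueError("counts_a and counts_b files disagree on samples or SNPs")
    logger.info("read counts: %d samples x %d SNPs", a.shape[0], a.shape[1])
    return AlleleCountMatrix(
        a.to_numpy(np.int64), b.to_numpy(np.int64), list(a.index), list(a.columns)
    )


def read_vcf_counts(path: PathLike) -> AlleleCountMatrix:
    """Biallelic allele counts from the AD field of a VCF.

    The first ALT is allele B; records with more than one ALT are skipped
    with a logged count, as are records without usable AD.
    """
    from cyvcf2 import VCF  # optional dependency

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows_a, rows_b, ids = [], [], []
    n_multi = n_no_ad = 0
    for var in vcf:
        if len(var.ALT) != 1:
            n_multi += 1
            continue
        ad = var.format("AD")
        if ad is None:
            n_no_ad += 1
            continue
        ad = np.asarray(ad)
        ad[ad < 0] = 0  # missing AD encodes as negative
        rows_a.append(ad[:, 0])
        rows_b.append(ad[:, 1])
        ids.append(f"{var.CHROM}_{var.POS}:{0}")
    if n_multi or n_no_ad:
        logger.info(
            "VCF: skipped %d multi-allelic and %d AD-less records", n_multi, n_no_ad
        )
    a = np.column_stack(rows_a).astype(np.int64)
    b = np.column_stack(rows_b).astype(np.int64)
    return AlleleCountMatrix(a, b, samples, ids)


def write_diploid(matrix: DiploidGenotypeMatrix, path: PathLike) -> None:
    labels = np.vectorize(DIPLOID_LABELS.get)(matrix.calls)
    pd.DataFrame(labels, index=matrix.sample_ids, columns=matrix.snp_ids).to_csv(
        path, sep="\t", index_label="sample"
    )


def read_diploid(path: PathLike) -> DiploidGenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col="sample", dtype=str, keep_default_na=False)
    calls = np.vectorize(DIPLOID_CODES.get)(df.to_numpy())
    return DiploidGenotypeMatrix(calls.astype(np.int8), list(df.index), list(df.columns))


def write_pseudo_haploid(matrix: PseudoHaploidMatrix, path: PathLike) -> None:
    labels = np.vectorize(PH_LABELS.get)(matrix.calls)
    pd.DataFrame(labels, index=matrix.sample_ids, columns=matrix.snp_ids).to_csv(
        path, sep="\t", index_label="sample"
    )


def read_pseudo_haploid(path: PathLike, seed: Optional[int] = None) -> PseudoHaploidMatrix:
    df = pd.read_csv(path, sep="\t", index_col="sample", dtype=str, keep_default_na=False)
    calls = np.vectorize(PH_CODES.get)(df.to_numpy())
    return PseudoHaploidMatrix(
        calls.astype(np.int8), list(df.index), list(df.columns), seed
    )


def write_locus_annotations(annotations: Iterable[LocusAnnotation], path: PathLike) -> None:
    rows = []
    for ann in annotations:
        dists = ann.distance_to_restriction_site or ann.snp_offsets
        for off, d in zip(ann.snp_offsets, dists):
            chrom, start, end = ann.mapped_interval or ("", -1, -1)
            rows.append(
                {
                    "locus_id": ann.locus_id, "offset": off, "rs_distance": d,
                    "chrom": chrom, "start": start, "end": end,
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_locus_annotations(path: PathLike) -> list[LocusAnnotation]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str}, keep_default_na=False)
    out = []
    for locus_id, grp in df.groupby("locus_id", sort=False):
        grp = grp.sort_values("offset")
        chrom = str(grp["chrom"].iloc[0])
        interval = None
        if chrom and int(grp["start"].iloc[0]) >= 0:
            interval = (chrom, int(grp["start"].iloc[0]), int(grp["end"].iloc[0]))
        out.append(
            LocusAnnotation(
                locus_id=str(locus_id),
                snp_offsets=tuple(int(o) for o in grp["offset"]),
                distance_to_restriction_site=tuple(int(d) for d in grp["rs_distance"]),
                mapped_interval=interval,
            )
        )
    return out


def write_metadata(meta: pd.DataFrame, path: PathLike) -> None:
    meta.to_csv(path, sep="\t", index_label="sample")


def read_metadata(path: PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="sample")


def write_distance_tsv(dist: DistanceMatrix, path: PathLike) -> None:
    dist.to_dataframe().to_csv(path, sep="\t", index_label="sample")


def read_distance_tsv(path: PathLike) -> DistanceMatrix:
    df = pd.read_csv(path, sep="\t", index_col="sample")
    return DistanceMatrix(df.to_numpy(float), list(df.index))


def write_phylip_distance(dist: DistanceMatrix, path: PathLike) -> None:
    """Square PHYLIP distance file (relaxed names) for external tree tools."""
    if np.isnan(dist.values).any():
        raise ValueError("PHYLIP output requires a complete distance matrix")
    with open(path, "w") as fh:
        fh.write(f"{len(dist.sample_ids)}\n")
        for name, row in zip(dist.sample_ids, dist.values):
            fh.write(name + "  " + " ".join(f"{v:.6f}" for v in row) + "\n")


def write_bed(bed: pd.DataFrame, path: PathLike) -> None:
    bed[["chrom", "start", "end", "name"]].to_csv(
        path, sep="\t", header=False, index=False
    )
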