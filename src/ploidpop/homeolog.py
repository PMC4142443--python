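"""Coassembled-homeolog detection using dihaploid control samples.

In an allopolyploid, reads from the two subgenomic copies of a locus
(homeologs) can be coassembled into a single GBS tag; fixed differences
between the copies then masquerade as heterozygous SNPs.  Dihaploid plants
carry one chromosome copy per subgenome and must be homozygous genome-wide,
so any heterozygous diploid call in a dihaploid marks a coassembled
homeolog rather than a true allele pair.

Detection is limited by the dihaploids' origin: dihaploids from one gene
pool cannot flag homeologs whose copies differ only in other pools.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .genotyping import HET, DiploidGenotypeMatrix

logger = logging.getLogger(__name__)


@dataclass
class HomeologReport:
    flagged_snps: list[str]
    n_candidates: int
    per_dihaploid_het_counts: dict[str, int]

    @property
    def fraction_flagged(self) -> float:
        return len(self.flagged_snps) / self.n_candidates if self.n_candidates else 0.0


def detect_homeologs(
    diploid: DiploidGenotypeMatrix,
    dihaploid_samples: Iterable[str],
    min_dihaploids: int = 1,
) -> HomeologReport:
    """Flag SNPs heterozygous in at least ``min_dihaploids`` dihaploids.

    Every SNP in the matrix is a candidate.  The default of a single
    heterozygous dihaploid sufficing to flag a SNP reflects that dihaploids
    admit no true heterozygosity at all.
    """
    dihaploids = list(dihaploid_samples)
    if not dihaploids:
        raise ValueError("at least one dihaploid control sample is required")
    rows = [diploid.sample_index(s) for s in dihaploids]
    het = diploid.calls[rows] == HET
    flagged_mask = het.sum(axis=0) >= min_dihaploids
    flagged = [s for s, f in zip(diploid.snp_ids, flagged_mask) if f]
    per_counts = {s: int(het[i].sum()) for i, s in enumerate(dihaploids)}
    logger.info(
        "homeolog detection: %d/%d SNPs flagged (%.1f%%)",
        len(flagged), len(diploid.snp_ids), 100 * len(flagged) / max(len(diploid.snp_ids), 1),
    )
    return HomeologReport(flagged, len(diploid.snp_ids), per_counts)


def apply_homeolog_policy(
    matrices: Sequence, report: HomeologReport, policy: str = "retain"
):
    """Apply the retain/remove policy for flagged homeolog SNPs.

    ``retain`` keeps all SNPs (flagged homeologs carry real variation and
    removing them biases diversity against the gene pool the dihaploids
    came from) and returns an annotation mask; ``remove`` drops flagged
    SNPs from every matrix.

    Returns ``(matrices, annotation)`` where ``annotation`` maps SNP id to
    a homeolog flag for the surviving SNP set.
    """
    if policy not in {"retain", "remove"}:
        raise ValueError(f"unknown policy {policy!r}")
    flagged = set(report.flagged_snps)
    if policy == "retain":
        annotation = {s: (s in flagged) for s in matrices[0].snp_ids}
        return list(matrices), annotation
    keep = [s for s in matrices[0].snp_ids if s not in flagged]
    out = [m.select_snps(keep) for m in matrices]
    annotation = {s: False for s in keep}
    logger.info("homeolog removal: %d SNPs dropped", len(flagged))
    return out, annotation
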