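"""Ecotype-private alleles and genome-wide hybrid ancestry tracks.

An allele is private to an ecotype when it is seen there and demonstrably
absent from the other: the SNP must be genotyped in at least ``min_n``
individuals of the focal ecotype with the allele observed, and either the
SNP is entirely ungenotyped in the other ecotype or it is genotyped in at
least ``min_n`` individuals there without the allele ever appearing.

Laying the private alleles a hybrid sample carries along reference-genome
coordinates visualizes its mosaic of ecotype ancestries.  Because one
ecotype is usually sampled more densely and so contributes more private
alleles, its entries are randomly thinned (default 25%) before plotting.
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
    MISSING,
    PARTIAL_A,
    PARTIAL_B,
    DiploidGenotypeMatrix,
    LocusAnnotation,
    locus_of,
)

logger = logging.getLogger(__name__)


@dataclass
class PrivateAlleleSet:
    entries: pd.DataFrame  # snp_id, allele, ecotype, n_genotyped_focal, n_genotyped_other
    per_ecotype_totals: dict[str, int]


def _observes(calls: np.ndarray, allele: str, count_partial: bool) -> np.ndarray:
    if allele == "A":
        obs = (calls == HOM_A) | (calls == HET)
        if count_partial:
            obs |= calls == PARTIAL_A
    else:
        obs = (calls == HOM_B) | (calls == HET)
        if count_partial:
            obs |= calls == PARTIAL_B
    return obs


def find_private_alleles(
    diploid: DiploidGenotypeMatrix,
    ecotype: Mapping[str, str],
    min_n: int = 10,
    count_partial: bool = True,
) -> PrivateAlleleSet:
    """Alleles private to one of two ecotypes under the >=min_n rule.

    ``count_partial`` controls whether partial calls count both as
    "genotyped" and as observations of their allele (default on; the rule
    is switchable because single-allele support is weaker evidence).
    """
    groups = sorted(set(ecotype.values()))
    if len(groups) != 2:
        raise ValueError(f"exactly two ecotypes required, got {groups}")
    idx = {
        g: [i for i, s in enumerate(diploid.sample_ids) if ecotype.get(s) == g]
        for g in groups
    }
    for g, rows in idx.items():
        if len(rows) < min_n:
            raise ValueError(f"ecotype {g!r} has {len(rows)} samples (< min_n={min_n})")

    genotyped_states = (
        lambda c: c != MISSING
        if count_partial
        else (c == HOM_A) | (c == HOM_B) | (c == HET)
    )
    stats = {}
    for g, rows in idx.items():
        c = diploid.calls[rows]
        stats[g] = {
            "n_gt": genotyped_states(c).sum(axis=0),
            "obs_A": _observes(c, "A", count_partial).any(axis=0),
            "obs_B": _observes(c, "B", count_partial).any(axis=0),
        }

    records = []
    totals = {g: 0 for g in groups}
    snp_ids = np.asarray(diploid.snp_ids)
    for focal, other in ((groups[0], groups[1]), (groups[1], groups[0])):
        f, o = stats[focal], stats[other]
        for allele in ("A", "B"):
            seen_f = f[f"obs_{allele}"] & (f["n_gt"] >= min_n)
            absent_o = (o["n_gt"] == 0) | ((o["n_gt"] >= min_n) & ~o[f"obs_{allele}"])
            priv = seen_f & absent_o
            for j in np.flatnonzero(priv):
                records.append(
                    {
                        "snp_id": snp_ids[j],
                        "allele": allele,
                        "ecotype": focal,
                        "n_genotyped_focal": int(f["n_gt"][j]),
                        "n_genotyped_other": int(o["n_gt"][j]),
                    }
                )
                totals[focal] += 1
    entries = pd.DataFrame(
        records,
        columns=["snp_id", "allele", "ecotype", "n_genotyped_focal", "n_genotyped_other"],
    )
    logger.info(
        "private alleles: %s", ", ".join(f"{g}={totals[g]}" for g in groups)
    )
    return PrivateAlleleSet(entries, totals)


def layout_hybrid_ancestry(
    private: PrivateAlleleSet,
    diploid: DiploidGenotypeMatrix,
    samples: Iterable[str],
    mapping: Mapping[str, tuple[str, int, int]],
    subsample_ecotype: Optional[str] = None,
    subsample_fraction: float = 0.25,
    seed: int = 0,
    count_partial: bool = True,
) -> dict[str, pd.DataFrame]:
    """Ordered (chrom, pos, ecotype) ancestry track per focal sample.

    ``mapping`` gives each GBS locus a unique (chrom, start, end) interval
    in 0-based half-open BED convention; output positions are 1-based
    (interval start + SNP tag offset + 1).  Loci without a mapping are
    dropped with a logged count.  Entries of ``subsample_ecotype`` are
    thinned to ``subsample_fraction`` by a per-entry uniform draw keyed on
    the seed, so the fraction-1.0 track is a superset of any thinner track
    under the same seed.
    """
    if private.entries.empty:
        raise ValueError("no private alleles to lay out")
    ent = private.entries.copy()
    ent["locus"] = ent["snp_id"].map(locus_of)
    mapped = ent["locus"].isin(mapping.keys())
    n_drop = int((~mapped).sum())
    if n_drop:
        logger.info("%d private-allele entries on unmapped loci dropped", n_drop)
    ent = ent[mapped]
    if ent.empty:
        raise ValueError("no private-allele locus overlaps the mapping")

    snp_pos = {}
    for sid, loc in zip(ent["snp_id"], ent["locus"]):
        chrom, start, _ = mapping[loc]
        offset = int(sid.rsplit(":", 1)[1])
        snp_pos[sid] = (chrom, start + offset + 1)

    col = {s: j for j, s in enumerate(diploid.snp_ids)}
    out: dict[str, pd.DataFrame] = {}
    for si, sample in enumerate(samples):
        row = diploid.calls[diploid.sample_index(sample)]
        recs = []
        for sid, allele, eco in zip(ent["snp_id"], ent["allele"], ent["ecotype"]):
            j = col.get(sid)
            if j is None:
                continue
            call = row[j : j + 1]
            if _observes(call, allele, count_partial)[0]:
                chrom, pos = snp_pos[sid]
                recs.append({"chrom": chrom, "pos": pos, "ecotype": eco, "snp_id": sid})
        track = pd.DataFrame(recs, columns=["chrom", "pos", "ecotype", "snp_id"])
        if subsample_ecotype is not None and not track.empty:
            rng = np.random.default_rng([seed, si])
            u = rng.random(len(track))
            keep = (track["ecotype"].to_numpy() != subsample_ecotype) | (
                u < subsample_fraction
            )
            track = track[keep]
        out[sample] = track.sort_values(["chrom", "pos"]).reset_index(drop=True)
    return out


def plot_ancestry_tracks(tracks: Mapping[str, pd.DataFrame], path) -> None:
    """Per-sample chromosome tracks of private-allele positions.

    One row per sample; each point is a private allele the sample carries,
    colored by the ecotype it is private to.  Requires matplotlib.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    chroms = sorted(
        {c for t in tracks.values() for c in t["chrom"].unique()}
    )
    ecotypes = sorted(
        {e for t in tracks.values() for e in t["ecotype"].unique()}
    )
    colors = dict(zip(ecotypes, ["tab:red", "tab:blue", "tab:green"]))
    fig, axes = plt.subplots(
        len(tracks), 1, figsize=(8, 0.8 * len(tracks) + 1), sharex=True,
        squeeze=False,
    )
    offset = {c: i for i, c in enumerate(chroms)}
    for ax, (sample, t) in zip(axes[:, 0], tracks.items()):
        for eco in ecotypes:
            sub = t[t["ecotype"] == eco]
            x = sub["pos"] + sub["chrom"].map(offset) * 1.1 * max(
                (t["pos"].max() for t in tracks.values() if len(t)), default=1
            )
            ax.scatter(x, np.zeros(len(sub)), s=4, c=colors[eco], label=eco)
        ax.set_yticks([])
        ax.set_ylabel(sample, rotation=0, ha="right", fontsize=7)
    axes[0, 0].legend(frameon=False, fontsize=7, ncol=len(ecotypes))
    axes[-1, 0].set_xlabel("concatenated chromosome position")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def read_bed_mapping(path) -> dict[str, tuple[str, int, int]]:
    """Locus -> (chrom, start, end) from a BED file (name in column 4).

    The input contract mirrors the upstream alignment step: intervals are
    assumed to be unique best hits per locus; duplicate names raise.
    """
    bed = pd.read_csv(
        path, sep="\t", header=None, usecols=[0, 1, 2, 3],
        names=["chrom", "start", "end", "name"], dtype={"chrom": str, "name": str},
    )
    if bed["name"].duplicated().any():
        raise ValueError("BED mapping contains non-unique locus names")
    return {
        r.name: (r.chrom, int(r.start), int(r.end))
        for r in bed.itertuples(index=False)
    }


def annotations_to_mapping(
    annotations: Iterable[LocusAnnotation],
) -> dict[str, tuple[str, int, int]]:
    """Extract the mapped intervals carried on locus annotations."""
    out = {}
    for ann in annotations:
        if ann.mapped_interval is not None:
            out[ann.locus_id] = ann.mapped_interval
    return out
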