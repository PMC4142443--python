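"""Simulated octoploids: combine pairs of tetraploid diploid genotypes.

Whether octoploid lineages owe their elevated heterozygosity to ploidy
alone or to admixture can be tested by constructing synthetic octoploid
genotypes from pairs of tetraploid samples: pairs drawn within one gene
pool emulate a single-lineage genome doubling, pairs drawn across gene
pools emulate allopolyploid formation by admixture.  Comparing the
heterozygosity distributions of the two simulant classes against real
octoploids distinguishes the hypotheses.

Combination rules per SNP (calls from the six-state diploid alphabet):

1. the combined genotype is heterozygous if both alleles are found in
   either sample;
2. it is homozygous if both samples are homozygous or partial for the
   same allele;
3. it is partial if one sample is partial and the other has no genotype.

The rules leave some ordered pairs uncovered — a homozygous call paired
with a missing one carries allele information but matches none of the
three.  Completion here: such pairs yield MISSING, and the full 36-cell
table plus an ``UNCOVERED`` mask ship with the module so the choice can be
audited (see also the combined-call annotation emitted per simulant).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations, product
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .genotyping import (
    DIPLOID_LABELS,
    HET,
    HOM_A,
    HOM_B,
    MISSING,
    PARTIAL_A,
    PARTIAL_B,
    DiploidGenotypeMatrix,
)

_ALLELES = {
    MISSING: frozenset(),
    HOM_A: frozenset("A"),
    HOM_B: frozenset("B"),
    HET: frozenset("AB"),
    PARTIAL_A: frozenset("A"),
    PARTIAL_B: frozenset("B"),
}
_STATES = (MISSING, HOM_A, HOM_B, HET, PARTIAL_A, PARTIAL_B)


def _build_tables() -> tuple[np.ndarray, np.ndarray]:
    table = np.full((6, 6), MISSING, dtype=np.int8)
    uncovered = np.zeros((6, 6), dtype=bool)
    for g1, g2 in product(_STATES, repeat=2):
        union = _ALLELES[g1] | _ALLELES[g2]
        if union == frozenset("AB"):
            call = HET
        elif g1 in (HOM_A, PARTIAL_A) and g2 in (HOM_A, PARTIAL_A):
            call = HOM_A
        elif g1 in (HOM_B, PARTIAL_B) and g2 in (HOM_B, PARTIAL_B):
            call = HOM_B
        elif {g1, g2} == {PARTIAL_A, MISSING}:
            call = PARTIAL_A
        elif {g1, g2} == {PARTIAL_B, MISSING}:
            call = PARTIAL_B
        elif g1 == MISSING and g2 == MISSING:
            call = MISSING
        else:
            # HOM paired with MISSING: information present but no rule applies.
            call = MISSING
            uncovered[g1, g2] = True
        table[g1, g2] = call
    return table, uncovered


COMBINE_TABLE, UNCOVERED = _build_tables()


def combine_genotypes(g1: int, g2: int) -> int:
    """Combined octoploid-style call for one pair of diploid calls."""
    return int(COMBINE_TABLE[g1, g2])


def combine_table_frame() -> pd.DataFrame:
    """The full 36-cell combination table, labeled, for docs and audit."""
    labels = [DIPLOID_LABELS[s] for s in _STATES]
    data = [
        [DIPLOID_LABELS[int(COMBINE_TABLE[i, j])] for j in _STATES] for i in _STATES
    ]
    return pd.DataFrame(data, index=labels, columns=labels)


@dataclass
class SimulatedOctoploid:
    name: str
    parent_pair: tuple[str, str]
    pair_class: str  # "within_pool" | "cross_pool"
    source_pools: tuple[str, str]
    calls: np.ndarray
    n_uncovered: int  # cells resolved by the completion rule


def simulate_octoploid_cohort(
    diploid: DiploidGenotypeMatrix,
    pools: Mapping[str, str],
    mode: str,
    pool_filter: Optional[Sequence[str]] = None,
    max_pairs: Optional[int] = None,
    seed: Optional[int] = None,
) -> list[SimulatedOctoploid]:
    """All unordered same-mode pairings of tetraploid samples, combined.

    ``mode='within_pool'`` pairs samples inside each gene pool;
    ``mode='cross_pool'`` pairs samples from different pools.  Samples
    absent from ``pools`` are ignored; ``pool_filter`` restricts to the
    named pools.  ``max_pairs`` caps the cohort by seeded subsampling.
    """
    if mode not in {"within_pool", "cross_pool"}:
        raise ValueError(f"unknown mode {mode!r}")
    samples = [s for s in diploid.sample_ids if s in pools]
    if pool_filter is not None:
        allowed = set(pool_filter)
        samples = [s for s in samples if pools[s] in allowed]
    by_pool: dict[str, list[str]] = {}
    for s in samples:
        by_pool.setdefault(pools[s], []).append(s)

    if mode == "within_pool":
        bad = sorted(p for p, mem in by_pool.items() if len(mem) < 2)
        if bad:
            raise ValueError(f"pools with fewer than 2 samples: {', '.join(bad)}")
        pairs = [
            (s1, s2) for mem in by_pool.values() for s1, s2 in combinations(mem, 2)
        ]
    else:
        if len(by_pool) < 2:
            raise ValueError("cross_pool mode requires samples from >=2 pools")
        pairs = [
            (s1, s2)
            for s1, s2 in combinations(samples, 2)
            if pools[s1] != pools[s2]
        ]

    if max_pairs is not None and len(pairs) > max_pairs:
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(pairs), size=max_pairs, replace=False)
        pairs = [pairs[i] for i in sorted(idx)]

    out = []
    for s1, s2 in pairs:
        c1 = diploid.calls[diploid.sample_index(s1)]
        c2 = diploid.calls[diploid.sample_index(s2)]
        calls = COMBINE_TABLE[c1, c2]
        n_unc = int(UNCOVERED[c1, c2].sum())
        out.append(
            SimulatedOctoploid(
                name=f"sim8x_{s1}+{s2}",
                parent_pair=(s1, s2),
                pair_class=mode,
                source_pools=(pools[s1], pools[s2]),
                calls=calls,
                n_uncovered=n_unc,
            )
        )
    return out


def cohort_heterozygosity(cohort: Sequence[SimulatedOctoploid]) -> pd.Series:
    """Heterozygosity (HET over full calls) of each simulated octoploid."""
    vals = {}
    for sim in cohort:
        het = int((sim.calls == HET).sum())
        full = het + int((sim.calls == HOM_A).sum()) + int((sim.calls == HOM_B).sum())
        vals[sim.name] = het / full if full else float("nan")
    return pd.Series(vals, name="heterozygosity")


def compare_het_distributions(
    real_octoploid_het: Sequence[float],
    sim_within_het: Sequence[float],
    sim_cross_het: Sequence[float],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Group means/spreads and pairwise mean differences.

    The comparison is descriptive (no hypothesis test): groups of size one
    report their value as the mean with spread NaN.
    """
    groups = {
        "real_octoploid": np.asarray(real_octoploid_het, dtype=float),
        "sim_within_pool": np.asarray(sim_within_het, dtype=float),
        "sim_cross_pool": np.asarray(sim_cross_het, dtype=float),
    }
    rows = []
    for name, v in groups.items():
        if v.size == 0:
            raise ValueError(f"group {name} is empty")
        rows.append(
            {
                "group": name,
                "n": v.size,
                "mean": float(np.nanmean(v)),
                "sd": float(np.nanstd(v, ddof=1)) if v.size > 1 else float("nan"),
            }
        )
    summary = pd.DataFrame(rows).set_index("group")
    names = list(groups)
    diffs = pd.DataFrame(
        [
            [summary.loc[a, "mean"] - summary.loc[b, "mean"] for b in names]
            for a in names
        ],
        index=names,
        columns=names,
    )
    return summary, diffs
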