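"""Population structure and isolation by distance.

PCoA (classical metric scaling), BIONJ neighbour-joining trees, haversine
geographic distances, and full/partial correlations of genetic distance
with log geographic distance (isolation by distance, IBD) with percentile
bootstrap confidence limits.

Partial correlations residualize both distance variables on a pair-level
covariate design in which each covariate (ecotype, regional gene pool,
ploidy) enters as a binary same/different indicator per sample pair — the
standard partial-Mantel encoding.  The bootstrap resamples *samples* (not
pairs, which are non-independent) and rebuilds the pair set per replicate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .diversity import DistanceMatrix

logger = logging.getLogger(__name__)

EARTH_RADIUS_KM = 6371.0


# ---------------------------------------------------------------------------
# PCoA

@dataclass
class PCoAResult:
    coordinates: pd.DataFrame  # samples x axes
    eigenvalues: np.ndarray  # all eigenvalues, non-increasing (incl. negative)
    proportion_explained: np.ndarray  # over positive eigenvalues, per kept axis


def pcoa(dist: DistanceMatrix, n_axes: Optional[int] = None) -> PCoAResult:
    """Classical metric scaling of a distance matrix.

    Double-centers -D²/2, eigendecomposes, and scales eigenvectors by the
    square root of their eigenvalues.  Negative eigenvalues (non-Euclidean
    input) are reported but their axes dropped.  Masked (NaN) pairs are not
    allowed: impute or remove samples first.
    """
    d = dist.values
    if np.isnan(d).any():
        raise ValueError(
            "distance matrix contains masked pairs; impute or drop samples before PCoA"
        )
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d ** 2) @ j
    evals, evecs = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    tol = max(1e-10, 1e-10 * abs(evals[0])) if n else 0.0
    pos = evals > tol
    coords = evecs[:, pos] * np.sqrt(evals[pos])
    prop = evals[pos] / evals[pos].sum() if pos.any() else np.array([])
    if n_axes is not None:
        coords = coords[:, :n_axes]
        prop = prop[:n_axes]
    cols = [f"PCo{k + 1}" for k in range(coords.shape[1])]
    return PCoAResult(
        coordinates=pd.DataFrame(coords, index=dist.sample_ids, columns=cols),
        eigenvalues=evals,
        proportion_explained=prop,
    )


# ---------------------------------------------------------------------------
# BIONJ

def nj_tree(dist: DistanceMatrix) -> str:
    """Unrooted BIONJ tree in newick format.

    BIONJ is neighbour joining with variance-weighted distance updates:
    when nodes i and j are joined into u, the new distances are
    ``d_uk = w d_ik + (1-w) d_jk - w L_i - (1-w) L_j`` with the weight w
    chosen to minimize the variance of the reduced matrix (variances are
    initialized to the distances and updated alongside).  Pair selection
    and branch lengths follow the classical NJ criterion, so on perfectly
    additive input the true tree is recovered exactly.
    """
    d0 = dist.values
    if np.isnan(d0).any():
        raise ValueError("distance matrix contains masked pairs")
    names = list(dist.sample_ids)
    n = len(names)
    if n < 3:
        raise ValueError("need at least 3 samples for a tree")
    d = d0.astype(float).copy()
    v = d.copy()

    def label(x: str) -> str:
        # quote labels so underscores survive newick round-trips
        if x.isalnum():
            return x
        return "'" + str(x).replace("'", "''") + "'"

    nodes = [label(str(x)) for x in names]

    def fmt(x: float) -> str:
        return f"{x:.10g}"

    while len(nodes) > 3:
        m = len(nodes)
        r = d.sum(axis=1)
        q = (m - 2) * d - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        i, j = np.unravel_index(np.argmin(q), q.shape)
        if i > j:
            i, j = j, i
        li = d[i, j] / 2 + (r[i] - r[j]) / (2 * (m - 2))
        lj = d[i, j] - li
        # variance-optimal weight (plain NJ uses w = 1/2)
        if v[i, j] > 0:
            others = [k for k in range(m) if k not in (i, j)]
            w = 0.5 + float(np.sum(v[j, others] - v[i, others])) / (
                2 * (m - 2) * v[i, j]
            )
            w = min(1.0, max(0.0, w))
        else:
            w = 0.5
        du = w * (d[i] - li) + (1 - w) * (d[j] - lj)
        vu = w * v[i] + (1 - w) * v[j] - w * (1 - w) * v[i, j]
        new_node = f"({nodes[i]}:{fmt(li)},{nodes[j]}:{fmt(lj)})"
        keep = [k for k in range(m) if k not in (i, j)]
        d = np.vstack([d[keep][:, keep], du[keep]])
        d = np.hstack([d, np.append(du[keep], 0.0)[:, None]])
        v = np.vstack([v[keep][:, keep], vu[keep]])
        v = np.hstack([v, np.append(vu[keep], 0.0)[:, None]])
        nodes = [nodes[k] for k in keep] + [new_node]

    (a, b, c) = (0, 1, 2)
    la = (d[a, b] + d[a, c] - d[b, c]) / 2
    lb = (d[a, b] + d[b, c] - d[a, c]) / 2
    lc = (d[a, c] + d[b, c] - d[a, b]) / 2
    return f"({nodes[a]}:{fmt(la)},{nodes[b]}:{fmt(lb)},{nodes[c]}:{fmt(lc)});"


# ---------------------------------------------------------------------------
# Geographic distance

def geo_distance(meta: pd.DataFrame) -> DistanceMatrix:
    """Great-circle (haversine) distances in km from latitude/longitude.

    ``meta`` is indexed by sample with ``latitude``/``longitude`` columns
    in decimal degrees; samples with missing coordinates are excluded.
    """
    ok = meta[["latitude", "longitude"]].notna().all(axis=1)
    if (~ok).any():
        logger.info("%d samples without coordinates excluded", int((~ok).sum()))
    sub = meta.loc[ok]
    lat = np.radians(sub["latitude"].to_numpy(float))
    lon = np.radians(sub["longitude"].to_numpy(float))
    dlat = lat[:, None] - lat[None, :]
    dlon = lon[:, None] - lon[None, :]
    h = np.sin(dlat / 2) ** 2 + np.cos(lat)[:, None] * np.cos(lat)[None, :] * np.sin(dlon / 2) ** 2
    km = 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))
    np.fill_diagonal(km, 0.0)
    km = (km + km.T) / 2
    return DistanceMatrix(km, list(sub.index))


# ---------------------------------------------------------------------------
# Isolation by distance

@dataclass
class IBDResult:
    r: float
    ci_low: float
    ci_high: float
    covariates: tuple[str, ...]
    n_pairs: int
    n_boot: int
    p_value: Optional[float] = None  # Mantel permutation p, if requested


def _pair_design(
    labels: dict[str, np.ndarray], pos_pairs: tuple[np.ndarray, np.ndarray]
) -> np.ndarray:
    """Same/different binary indicator per pair per covariate, plus intercept."""
    p, q = pos_pairs
    cols = [np.ones(p.size)]
    for lab in labels.values():
        cols.append((lab[p] == lab[q]).astype(float))
    return np.column_stack(cols)


def _residual_corr(x: np.ndarray, y: np.ndarray, z: Optional[np.ndarray]) -> float:
    if z is not None and z.shape[1] > 1:
        bx, *_ = np.linalg.lstsq(z, x, rcond=None)
        by, *_ = np.linalg.lstsq(z, y, rcond=None)
        x = x - z @ bx
        y = y - z @ by
    else:
        x = x - x.mean()
        y = y - y.mean()
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        raise ValueError("degenerate variance in IBD correlation")
    return float(np.dot(x, y) / (x.size * sx * sy))


def ibd_correlation(
    gen_dist: DistanceMatrix,
    geo_dist: DistanceMatrix,
    covariates: Optional[Mapping[str, Mapping[str, object]]] = None,
    n_boot: int = 500,
    seed: int = 0,
    geo_floor_km: float = 1.0,
    mantel_permutations: int = 0,
) -> IBDResult:
    """Full or partial correlation of genetic vs log geographic distance.

    ``covariates`` maps covariate name (e.g. ``ecotype``, ``gene_pool``,
    ``ploidy``) to a per-sample label mapping; each becomes a same/different
    pair indicator that both distance variables are residualized on.  The
    percentile bootstrap resamples samples with the given seed.  Geographic
    distances below ``geo_floor_km`` (co-located samples) are floored
    before the log transform.  ``mantel_permutations > 0`` adds a Mantel
    permutation p-value (off by default).
    """
    common = [s for s in gen_dist.sample_ids if s in set(geo_dist.sample_ids)]
    if len(common) < 3:
        raise ValueError("need at least 3 samples present in both matrices")
    gd = gen_dist.select_samples(common)
    xd = geo_dist.select_samples(common)
    # align ordering
    order = [xd.sample_ids.index(s) for s in gd.sample_ids]
    geo = xd.values[np.ix_(order, order)]
    gen = gd.values
    n = len(common)
    labels = {
        name: np.asarray([mapping[s] for s in gd.sample_ids])
        for name, mapping in (covariates or {}).items()
    }

    n_floored = int((geo[np.triu_indices(n, 1)] < geo_floor_km).sum())
    if n_floored:
        logger.info("%d pairs floored to %.3g km before log", n_floored, geo_floor_km)
    loggeo = np.log(np.maximum(geo, geo_floor_km))

    def corr_for(idx: np.ndarray) -> float:
        p, q = np.triu_indices(idx.size, 1)
        ii, jj = idx[p], idx[q]
        distinct = ii != jj
        p, q, ii, jj = p[distinct], q[distinct], ii[distinct], jj[distinct]
        y = gen[ii, jj]
        x = loggeo[ii, jj]
        ok = ~np.isnan(y)
        y, x, ii2, jj2 = y[ok], x[ok], ii[ok], jj[ok]
        z = _pair_design(labels, (ii2, jj2)) if labels else None
        return _residual_corr(x, y, z)

    base_idx = np.arange(n)
    r = corr_for(base_idx)
    p_pairs, q_pairs = np.triu_indices(n, 1)
    n_pairs = int((~np.isnan(gen[p_pairs, q_pairs])).sum())

    rng = np.random.default_rng(seed)
    boot = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n, n)
        try:
            boot[b] = corr_for(idx)
        except ValueError:
            boot[b] = np.nan
    ci_low, ci_high = np.nanpercentile(boot, [2.5, 97.5])

    p_value = None
    if mantel_permutations > 0:
        null = np.empty(mantel_permutations)
        for b in range(mantel_permutations):
            perm = rng.permutation(n)
            y = gen[np.ix_(perm, perm)][p_pairs, q_pairs]
            x = loggeo[p_pairs, q_pairs]
            ok = ~np.isnan(y)
            z = _pair_design(labels, (p_pairs[ok], q_pairs[ok])) if labels else None
            null[b] = _residual_corr(x[ok], y[ok], z)
        p_value = float((np.sum(np.abs(null) >= abs(r)) + 1) / (mantel_permutations + 1))

    return IBDResult(
        r=r,
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        covariates=tuple((covariates or {}).keys()),
        n_pairs=n_pairs,
        n_boot=n_boot,
        p_value=p_value,
    )


def ibd_table(
    gen_dist: DistanceMatrix,
    geo_dist: DistanceMatrix,
    covariate_sets: Sequence[Mapping[str, Mapping[str, object]]],
    n_boot: int = 500,
    seed: int = 0,
) -> pd.DataFrame:
    """IBD correlations for several covariate combinations, as one table."""
    rows = []
    for cov in covariate_sets:
        res = ibd_correlation(gen_dist, geo_dist, cov, n_boot=n_boot, seed=seed)
        rows.append(
            {
                "r": res.r,
                "ci_low": res.ci_low,
                "ci_high": res.ci_high,
                "covariates": "+".join(res.covariates) or "(none)",
                "n_pairs": res.n_pairs,
            }
        )
    return pd.DataFrame(rows)


def plot_ibd_scatter(
    gen_dist: DistanceMatrix,
    geo_dist: DistanceMatrix,
    ecotype: Mapping[str, str],
    path,
    geo_floor_km: float = 1.0,
):
    """Scatter of pairwise genetic vs log geographic distance.

    Grey points are between-ecotype pairs, black within-ecotype, with the
    two OLS regression lines overlaid.  Requires matplotlib.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    common = [s for s in gen_dist.sample_ids if s in set(geo_dist.sample_ids)]
    gd = gen_dist.select_samples(common)
    xd = geo_dist.select_samples(common)
    order = [xd.sample_ids.index(s) for s in gd.sample_ids]
    geo = xd.values[np.ix_(order, order)]
    lab = np.asarray([ecotype[s] for s in gd.sample_ids])
    p, q = np.triu_indices(len(common), 1)
    x = np.log(np.maximum(geo[p, q], geo_floor_km))
    y = gd.values[p, q]
    same = lab[p] == lab[q]
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(x[~same], y[~same], s=6, c="0.6", label="between ecotypes")
    ax.scatter(x[same], y[same], s=6, c="k", label="within ecotype")
    slopes = ecotype_regression_slopes(gen_dist, geo_dist, ecotype, geo_floor_km)
    grid = np.linspace(np.nanmin(x), np.nanmax(x), 50)
    for name, mask, style in (("between", ~same, "-"), ("within", same, "--")):
        if slopes[name] is None:
            continue
        b = np.polyfit(x[mask], y[mask], 1)
        ax.plot(grid, np.polyval(b, grid), "k" + style, lw=1)
    ax.set_xlabel("log geographic distance (km)")
    ax.set_ylabel("genetic distance")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def ecotype_regression_slopes(
    gen_dist: DistanceMatrix,
    geo_dist: DistanceMatrix,
    ecotype: Mapping[str, str],
    geo_floor_km: float = 1.0,
    min_pairs: int = 3,
) -> dict[str, Optional[float]]:
    """OLS slopes of genetic on log geographic distance, within vs between ecotypes.

    Shallower between-ecotype than within-ecotype slopes indicate that
    ecotype boundaries, not geography, dominate between-ecotype divergence.
    Classes with fewer than ``min_pairs`` pairs are omitted (None).
    """
    common = [s for s in gen_dist.sample_ids if s in set(geo_dist.sample_ids)]
    gd = gen_dist.select_samples(common)
    xd = geo_dist.select_samples(common)
    order = [xd.sample_ids.index(s) for s in gd.sample_ids]
    geo = xd.values[np.ix_(order, order)]
    lab = np.asarray([ecotype[s] for s in gd.sample_ids])
    p, q = np.triu_indices(len(common), 1)
    y = gd.values[p, q]
    x = np.log(np.maximum(geo[p, q], geo_floor_km))
    same = lab[p] == lab[q]
    out: dict[str, Optional[float]] = {}
    for name, mask in (("within", same), ("between", ~same)):
        ok = mask & ~np.isnan(y)
        if ok.sum() < min_pairs:
            out[name] = None
            continue
        slope = np.polyfit(x[ok], y[ok], 1)[0]
        out[name] = float(slope)
    return out
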