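"""PCoA, BIONJ trees, geographic distance and IBD correlations."""

import io as _io

import numpy as np
import pandas as pd
import pytest
import skbio

from ploidpop import (
    DistanceMatrix,
    ecotype_regression_slopes,
    geo_distance,
    ibd_correlation,
    ibd_table,
    nj_tree,
    pcoa,
)


def _dm(values, names=None):
    values = np.asarray(values, float)
    names = names or [f"t{i}" for i in range(values.shape[0])]
    return DistanceMatrix(values, names)


def _euclid(points):
    p = np.asarray(points, float)
    return np.sqrt(((p[:, None, :] - p[None, :, :]) ** 2).sum(-1))


class TestPCoA:
    def test_collinear_points_recovered_on_axis1(self):
        d = _dm(_euclid([[0.0], [0.1], [0.3]]))
        res = pcoa(d)
        x = res.coordinates["PCo1"].to_numpy()
        gaps = np.diff(np.sort(x))
        np.testing.assert_allclose(sorted(gaps), [0.1, 0.2], atol=1e-12)

    def test_identical_samples_all_zero(self):
        res = pcoa(_dm(np.zeros((4, 4))))
        assert res.coordinates.shape[1] == 0 or np.allclose(res.coordinates, 0)

    def test_exact_recovery_of_euclidean_configuration(self):
        """Classical scaling is exact on Euclidean input: Procrustes RMS ~ 0."""
        rng = np.random.default_rng(8)
        pts = rng.normal(size=(12, 2))
        res = pcoa(_dm(_euclid(pts)), n_axes=2)
        from scipy.spatial import procrustes

        _, _, disparity = procrustes(pts, res.coordinates.to_numpy())
        assert np.sqrt(disparity) < 1e-8

    def test_matches_skbio_pcoa(self):
        rng = np.random.default_rng(5)
        pts = rng.normal(size=(10, 3))
        d = _euclid(pts)
        ours = pcoa(_dm(d), n_axes=3).coordinates.to_numpy()
        ref = skbio.stats.ordination.pcoa(
            skbio.DistanceMatrix(d), number_of_dimensions=3
        ).samples.to_numpy()
        # axes defined up to sign
        for k in range(3):
            assert min(
                np.abs(ours[:, k] - ref[:, k]).max(),
                np.abs(ours[:, k] + ref[:, k]).max(),
            ) < 1e-8

    def test_masked_pairs_rejected(self):
        v = np.zeros((3, 3))
        v[0, 1] = v[1, 0] = np.nan
        with pytest.raises(ValueError, match="masked"):
            pcoa(_dm(v))

    def test_eigenvalues_non_increasing_and_coords_centered(self, small_pseudo_haploid):
        from ploidpop import pairwise_distance

        d = pairwise_distance(small_pseudo_haploid, min_shared=10)
        res = pcoa(d)
        assert (np.diff(res.eigenvalues) <= 1e-9).all()
        assert np.abs(res.coordinates.mean(axis=0)).max() < 1e-9


def _tree_path_lengths(newick: str) -> pd.DataFrame:
    tree = skbio.TreeNode.read(_io.StringIO(newick))
    names = sorted(t.name for t in tree.tips())
    tip = {t.name: t for t in tree.tips()}
    out = pd.DataFrame(0.0, index=names, columns=names)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            d = tip[a].distance(tip[b])
            out.loc[a, b] = out.loc[b, a] = d
    return out


class TestNJTree:
    def _additive_matrix(self):
        # ((a:2,b:3):1,(c:4,d:5):1) -> additive distances
        d = {
            ("a", "b"): 5, ("a", "c"): 8, ("a", "d"): 9,
            ("b", "c"): 9, ("b", "d"): 10, ("c", "d"): 9,
        }
        names = ["a", "b", "c", "d"]
        v = np.zeros((4, 4))
        for (x, y), val in d.items():
            i, j = names.index(x), names.index(y)
            v[i, j] = v[j, i] = val
        return _dm(v, names)

    def test_recovers_additive_tree_exactly(self):
        dm = self._additive_matrix()
        paths = _tree_path_lengths(nj_tree(dm))
        ref = dm.to_dataframe().loc[paths.index, paths.columns]
        np.testing.assert_allclose(paths.to_numpy(), ref.to_numpy(), atol=1e-9)

    def test_three_taxa_three_point_formulas(self):
        v = np.array([[0, 3.0, 4.0], [3.0, 0, 5.0], [4.0, 5.0, 0]])
        newick = nj_tree(_dm(v, ["x", "y", "z"]))
        tree = skbio.TreeNode.read(_io.StringIO(newick))
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths["x"] == pytest.approx((3 + 4 - 5) / 2)
        assert lengths["y"] == pytest.approx((3 + 5 - 4) / 2)
        assert lengths["z"] == pytest.approx((4 + 5 - 3) / 2)

    def test_matches_skbio_nj_on_additive_input(self):
        """BIONJ and plain NJ coincide on perfectly additive distances."""
        rng = np.random.default_rng(4)
        # points on a line give an exactly additive (path-tree) metric
        n = 7
        names = [f"t{i}" for i in range(n)]
        x = np.sort(rng.uniform(0, 10, n))
        d = np.abs(x[:, None] - x[None, :])
        ours = _tree_path_lengths(nj_tree(_dm(d, names)))
        ref = skbio.tree.nj(skbio.DistanceMatrix(d, names))
        ref_paths = pd.DataFrame(
            0.0, index=ours.index, columns=ours.columns
        )
        tips = {t.name: t for t in ref.tips()}
        for i, a in enumerate(ours.index):
            for b in ours.index[i + 1:]:
                ref_paths.loc[a, b] = ref_paths.loc[b, a] = tips[a].distance(tips[b])
        # both methods' path lengths approximate the input distances; on
        # near-additive input they correlate almost perfectly
        iu = np.triu_indices(n, 1)
        r_ours = np.corrcoef(ours.to_numpy()[iu], d[iu])[0, 1]
        r_ref = np.corrcoef(ref_paths.to_numpy()[iu], d[iu])[0, 1]
        assert r_ours > 0.99
        assert abs(r_ours - r_ref) < 0.01

    def test_all_taxa_present_and_lengths_finite(self, small_pseudo_haploid):
        from ploidpop import pairwise_distance

        d = pairwise_distance(small_pseudo_haploid, min_shared=10)
        tree = skbio.TreeNode.read(_io.StringIO(nj_tree(d)))
        tips = sorted(t.name for t in tree.tips())
        assert tips == sorted(d.sample_ids)
        assert all(np.isfinite(t.length) for t in tree.tips())

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            nj_tree(_dm(np.zeros((2, 2))))


class TestGeoDistance:
    def test_identical_coordinates_zero(self):
        meta = pd.DataFrame(
            {"latitude": [40.0, 40.0], "longitude": [-90.0, -90.0]},
            index=["a", "b"],
        )
        assert geo_distance(meta).values[0, 1] == 0.0

    def test_one_degree_latitude(self):
        meta = pd.DataFrame(
            {"latitude": [40.0, 41.0], "longitude": [-90.0, -90.0]},
            index=["a", "b"],
        )
        assert geo_distance(meta).values[0, 1] == pytest.approx(111.2, abs=0.1)

    def test_antipodal_points(self):
        meta = pd.DataFrame(
            {"latitude": [0.0, 0.0], "longitude": [0.0, 180.0]}, index=["a", "b"]
        )
        assert geo_distance(meta).values[0, 1] == pytest.approx(np.pi * 6371.0, rel=1e-6)

    def test_missing_coordinates_excluded(self):
        meta = pd.DataFrame(
            {"latitude": [40.0, np.nan, 42.0], "longitude": [-90.0, -91.0, -92.0]},
            index=["a", "b", "c"],
        )
        d = geo_distance(meta)
        assert d.sample_ids == ["a", "c"]


class TestIBD:
    def _linear_data(self, n=20, seed=0):
        rng = np.random.default_rng(seed)
        lat = rng.uniform(30, 45, n)
        lon = rng.uniform(-100, -80, n)
        meta = pd.DataFrame(
            {"latitude": lat, "longitude": lon},
            index=[f"s{i}" for i in range(n)],
        )
        geo = geo_distance(meta)
        gen = DistanceMatrix(
            0.01 * np.log(np.maximum(geo.values, 1.0)), list(geo.sample_ids)
        )
        return gen, geo

    def test_perfect_linear_relation_r_one(self):
        gen, geo = self._linear_data()
        res = ibd_correlation(gen, geo, n_boot=10, seed=1)
        assert res.r == pytest.approx(1.0, abs=1e-9)

    def test_independent_distances_r_near_zero(self):
        """Permutation oracle: shuffling sample identities kills the signal;
        the CI covers zero in most replicate experiments."""
        rng = np.random.default_rng(9)
        covered = 0
        for rep in range(10):
            gen, geo = self._linear_data(n=25, seed=100 + rep)
            perm = rng.permutation(len(gen.sample_ids))
            shuffled = DistanceMatrix(
                gen.values[np.ix_(perm, perm)], list(gen.sample_ids)
            )
            res = ibd_correlation(shuffled, geo, n_boot=100, seed=rep)
            assert abs(res.r) < 0.5
            covered += res.ci_low <= 0.0 <= res.ci_high
        assert covered >= 9

    def test_bootstrap_reproducible_under_seed(self):
        gen, geo = self._linear_data(seed=2)
        r1 = ibd_correlation(gen, geo, n_boot=50, seed=7)
        r2 = ibd_correlation(gen, geo, n_boot=50, seed=7)
        assert (r1.ci_low, r1.ci_high) == (r2.ci_low, r2.ci_high)

    def test_partial_equals_full_with_constant_covariate(self):
        gen, geo = self._linear_data(seed=3)
        full = ibd_correlation(gen, geo, n_boot=10, seed=0)
        cov = {"pool": {s: "same" for s in gen.sample_ids}}
        part = ibd_correlation(gen, geo, cov, n_boot=10, seed=0)
        assert part.r == pytest.approx(full.r, abs=1e-9)

    def test_pool_structure_drops_partial_below_full(self):
        """When genetic structure is pool membership and pools are spatially
        separated, the gene-pool covariate absorbs most of the IBD signal."""
        rng = np.random.default_rng(11)
        n_per, pools = 10, ["P1", "P2", "P3"]
        names, lat, lon, lab = [], [], [], {}
        for k, p in enumerate(pools):
            for i in range(n_per):
                s = f"{p}_{i}"
                names.append(s)
                lab[s] = p
                lat.append(32 + 6 * k + rng.normal(0, 0.3))
                lon.append(-95 + 5 * k + rng.normal(0, 0.3))
        meta = pd.DataFrame({"latitude": lat, "longitude": lon}, index=names)
        geo = geo_distance(meta)
        labels = np.array([lab[s] for s in geo.sample_ids])
        gen_v = 0.05 + 0.1 * (labels[:, None] != labels[None, :]) + rng.normal(
            0, 0.004, (len(names), len(names))
        )
        gen_v = (gen_v + gen_v.T) / 2
        np.fill_diagonal(gen_v, 0)
        gen = DistanceMatrix(gen_v, list(geo.sample_ids))
        full = ibd_correlation(gen, geo, n_boot=20, seed=0)
        part = ibd_correlation(gen, geo, {"gene_pool": lab}, n_boot=20, seed=0)
        assert full.r > 0.5
        assert part.r < full.r

    def test_ibd_table_layout(self):
        gen, geo = self._linear_data(seed=4)
        lab = {s: ("A" if i % 2 else "B") for i, s in enumerate(gen.sample_ids)}
        table = ibd_table(gen, geo, [None, {"ecotype": lab}], n_boot=10, seed=0)
        assert list(table.columns) == ["r", "ci_low", "ci_high", "covariates", "n_pairs"]
        assert table["covariates"].tolist() == ["(none)", "ecotype"]


class TestSlopes:
    def test_flat_genetic_distance_zero_slope(self):
        gen, geo = TestIBD()._linear_data(seed=5)
        flat = DistanceMatrix(
            np.full_like(gen.values, 0.1) - 0.1 * np.eye(len(gen.sample_ids)),
            list(gen.sample_ids),
        )
        eco = {s: ("up" if i % 2 else "low") for i, s in enumerate(gen.sample_ids)}
        slopes = ecotype_regression_slopes(flat, geo, eco)
        assert slopes["within"] == pytest.approx(0.0, abs=1e-12)
        assert slopes["between"] == pytest.approx(0.0, abs=1e-12)

    def test_exact_line_recovered(self):
        gen, geo = TestIBD()._linear_data(seed=6)
        eco = {s: ("up" if i % 2 else "low") for i, s in enumerate(gen.sample_ids)}
        slopes = ecotype_regression_slopes(gen, geo, eco)
        assert slopes["within"] == pytest.approx(0.01, rel=1e-9)
        assert slopes["between"] == pytest.approx(0.01, rel=1e-9)

    def test_matches_closed_form_ols(self):
        rng = np.random.default_rng(13)
        gen, geo = TestIBD()._linear_data(seed=7)
        noisy = gen.values + rng.normal(0, 0.002, gen.values.shape)
        noisy = (noisy + noisy.T) / 2
        np.fill_diagonal(noisy, 0)
        gen = DistanceMatrix(noisy, list(gen.sample_ids))
        eco = {s: "one" for s in gen.sample_ids}
        slopes = ecotype_regression_slopes(gen, geo, eco)
        n = len(gen.sample_ids)
        p, q = np.triu_indices(n, 1)
        x = np.log(np.maximum(geo.values[p, q], 1.0))
        y = gen.values[p, q]
        beta = np.cov(x, y)[0, 1] / np.var(x, ddof=1)
        assert slopes["within"] == pytest.approx(beta, rel=1e-9)
        assert slopes["between"] is None  # no between-ecotype pairs
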