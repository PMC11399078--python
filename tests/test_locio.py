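import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lequant.errors import DataError, FormatError, ParameterError
from lequant.locio import (
    ROI,
    LocalizationTable,
    MoleculeSet,
    binder_density,
    cluster_localizations,
    molecules_from_clusters,
    read_localizations,
    weighted_center,
    write_localizations,
)

from .conftest import make_locs


class TestReadWrite:
    def test_csv_pixel_to_nm_conversion(self, tmp_path):
        # 130 nm effective pixel size: x=1 px -> 130 nm, y=2 px -> 260 nm
        path = tmp_path / "locs.csv"
        path.write_text("frame,x,y,photons,lpx,lpy\n0,1,2,1000,0.1,0.1\n")
        table = read_localizations(path, format="csv", pixel_size_nm=130.0)
        assert table.x[0] == pytest.approx(130.0)
        assert table.y[0] == pytest.approx(260.0)
        assert table.lpx[0] == pytest.approx(13.0)

    def test_empty_table_no_error(self, tmp_path):
        path = tmp_path / "empty.csv"
        path.write_text("frame,x,y,photons,lpx,lpy\n")
        table = read_localizations(path, format="csv", pixel_size_nm=130.0)
        assert len(table) == 0

    @pytest.mark.parametrize("fmt,suffix", [("hdf5", ".h5"), ("csv", ".csv")])
    def test_round_trip(self, tmp_path, rng, fmt, suffix):
        n = 100
        table = make_locs(
            rng.uniform(0, 5000, n),
            rng.uniform(0, 5000, n),
            lpx=rng.uniform(2, 10, n),
            lpy=rng.uniform(2, 10, n),
            frame=rng.integers(0, 1000, n),
            photons=rng.uniform(100, 5000, n),
        )
        path = tmp_path / f"rt{suffix}"
        write_localizations(table, path, format=fmt, pixel_size_nm=130.0)
        back = read_localizations(path, format=fmt, pixel_size_nm=130.0)
        np.testing.assert_allclose(back.x, table.x, rtol=1e-12)
        np.testing.assert_allclose(back.y, table.y, rtol=1e-12)
        np.testing.assert_allclose(back.lpx, table.lpx, rtol=1e-12)
        np.testing.assert_array_equal(back.frame, table.frame)

    def test_hdf5_writes_yaml_sidecar(self, tmp_path):
        table = make_locs([100.0], [200.0])
        path = tmp_path / "locs.h5"
        write_localizations(table, path, pixel_size_nm=130.0)
        assert (tmp_path / "locs.yaml").exists()

    def test_missing_field_names_it(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("frame,x,y,photons,lpx\n0,1,2,1000,0.1\n")
        with pytest.raises(FormatError, match="lpy"):
            read_localizations(path, format="csv")

    def test_nonpositive_pixel_size(self, tmp_path):
        path = tmp_path / "locs.csv"
        path.write_text("frame,x,y,photons,lpx,lpy\n")
        with pytest.raises(ParameterError):
            read_localizations(path, format="csv", pixel_size_nm=0.0)

    def test_missing_file(self):
        with pytest.raises(FileNotFoundError):
            read_localizations("/nonexistent/locs.h5")


class TestLocalizationTable:
    def test_nonpositive_precision_rejected(self):
        with pytest.raises(DataError):
            make_locs([1.0], [1.0], lpx=[0.0])

    def test_nonfinite_coordinates_rejected(self):
        with pytest.raises(DataError):
            make_locs([np.nan], [1.0])


class TestROI:
    def test_rectangle_area(self):
        roi = ROI.rectangle(0, 0, 10_000, 10_000)
        assert roi.area_um2 == pytest.approx(100.0)

    def test_polygon_area(self):
        # right triangle, legs 2 µm
        roi = ROI.polygon([(0, 0), (2000, 0), (0, 2000)])
        assert roi.area_um2 == pytest.approx(2.0)

    def test_self_intersecting_polygon_rejected(self):
        with pytest.raises(ParameterError):
            ROI.polygon([(0, 0), (1000, 1000), (1000, 0), (0, 1000)])

    def test_zero_area_rejected(self):
        with pytest.raises(ParameterError):
            ROI.rectangle(0, 0, 0, 1000)

    def test_contains_includes_boundary(self):
        roi = ROI.rectangle(0, 0, 1000, 1000)
        assert roi.contains(np.array([0.0, 500.0, 1001.0]), np.array([0.0, 500.0, 500.0])).tolist() == [True, True, False]


class TestClustering:
    def test_two_separated_clouds(self, cloud_table):
        locs, _ = cloud_table
        labels = cluster_localizations(locs, radius=50.0, min_locs=5)
        assert set(labels) == {0, 1}
        # each cloud's 20 rows share one label
        assert len(set(labels[:20])) == 1
        assert len(set(labels[20:])) == 1

    def test_below_min_locs_all_noise(self):
        locs = make_locs([0.0, 1.0, 2.0], [0.0, 1.0, 2.0])
        labels = cluster_localizations(locs, radius=50.0, min_locs=5)
        assert (labels == -1).all()

    def test_empty_input(self):
        locs = make_locs([], [])
        assert len(cluster_localizations(locs, radius=10.0)) == 0

    def test_invalid_params(self, cloud_table):
        locs, _ = cloud_table
        with pytest.raises(ParameterError):
            cluster_localizations(locs, radius=0.0)
        with pytest.raises(ParameterError):
            cluster_localizations(locs, radius=10.0, min_locs=0)

    def test_members_within_radius_of_seed(self, rng):
        pts = rng.uniform(0, 2000, (400, 2))
        locs = make_locs(pts[:, 0], pts[:, 1])
        labels = cluster_localizations(locs, radius=100.0, min_locs=2)
        for cid in set(labels) - {-1}:
            members = pts[labels == cid]
            # all members lie within 2*radius of each other (within radius of a common seed)
            d = np.linalg.norm(members[:, None] - members[None, :], axis=-1)
            assert d.max() <= 200.0 + 1e-9

    def test_permutation_invariance(self, rng):
        centers = rng.uniform(200, 4800, (30, 2))
        pts = np.vstack([c + rng.normal(0, 5, (15, 2)) for c in centers])
        locs = make_locs(pts[:, 0], pts[:, 1])
        perm = rng.permutation(len(pts))
        shuffled = locs.subset(perm)
        mols_a = molecules_from_clusters(locs, cluster_localizations(locs, 25.0, 5))
        mols_b = molecules_from_clusters(shuffled, cluster_localizations(shuffled, 25.0, 5))
        assert len(mols_a) == len(mols_b)
        order_a = np.lexsort((mols_a.yc, mols_a.xc))
        order_b = np.lexsort((mols_b.yc, mols_b.xc))
        np.testing.assert_allclose(mols_a.xc[order_a], mols_b.xc[order_b], rtol=1e-12)
        np.testing.assert_allclose(mols_a.yc[order_a], mols_b.yc[order_b], rtol=1e-12)

    def test_frame_spread_check_discards_transient_cluster(self, rng):
        # persistent cluster: frames across the acquisition; transient: narrow burst
        persistent = rng.normal([500, 500], 5, (30, 2))
        transient = rng.normal([1500, 500], 5, (30, 2))
        pts = np.vstack([persistent, transient])
        frames = np.concatenate([rng.integers(0, 10_000, 30), rng.integers(100, 150, 30)])
        locs = make_locs(pts[:, 0], pts[:, 1], frame=frames)
        labels_off = cluster_localizations(locs, 50.0, 5, frame_spread_check=False)
        labels_on = cluster_localizations(locs, 50.0, 5, frame_spread_check=True)
        assert len(set(labels_off) - {-1}) == 2
        assert len(set(labels_on) - {-1}) == 1
        assert (labels_on[30:] == -1).all()


class TestWeightedCenter:
    def test_equal_precisions_is_centroid(self, rng):
        x = rng.uniform(0, 100, 20)
        y = rng.uniform(0, 100, 20)
        xc, yc, _ = weighted_center(make_locs(x, y))
        assert xc == pytest.approx(np.mean(x))
        assert yc == pytest.approx(np.mean(y))

    def test_hand_computed_two_point_example(self):
        # x = (0, 10), lpx = (1, 2): xc = (0*1 + 10*0.25)/1.25 = 2.0
        locs = make_locs([0.0, 10.0], [0.0, 0.0], lpx=[1.0, 2.0], lpy=[1.0, 1.0])
        xc, _, _ = weighted_center(locs)
        assert xc == pytest.approx(2.0)

    def test_single_localization_identity(self):
        locs = make_locs([3.5], [7.2], lpx=[2.0], lpy=[3.0])
        xc, yc, unc = weighted_center(locs)
        assert (xc, yc) == (3.5, 7.2)
        assert unc == pytest.approx(np.sqrt(0.5 * (4.0 + 9.0)))

    def test_empty_cluster_error(self):
        with pytest.raises(DataError):
            weighted_center(make_locs([], []))

    @given(st.integers(2, 30), st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_center_inside_convex_hull_bounds(self, n, seed):
        r = np.random.default_rng(seed)
        locs = make_locs(r.uniform(0, 100, n), r.uniform(0, 100, n), lpx=r.uniform(1, 10, n), lpy=r.uniform(1, 10, n))
        xc, yc, unc = weighted_center(locs)
        assert locs.x.min() <= xc <= locs.x.max()
        assert locs.y.min() <= yc <= locs.y.max()
        assert unc > 0


class TestMoleculesFromClusters:
    def test_vectorized_centers_match_scalar_op(self, rng):
        centers = rng.uniform(500, 4500, (10, 2))
        pts = np.vstack([c + rng.normal(0, 5, (12, 2)) for c in centers])
        locs = make_locs(pts[:, 0], pts[:, 1], lpx=rng.uniform(2, 8, 120), lpy=rng.uniform(2, 8, 120))
        labels = cluster_localizations(locs, 25.0, 5)
        mols = molecules_from_clusters(locs, labels)
        for cid in np.unique(labels[labels >= 0]):
            xc, yc, unc = weighted_center(locs.subset(labels == cid))
            j = np.argmin(np.hypot(mols.xc - xc, mols.yc - yc))
            assert mols.xc[j] == pytest.approx(xc)
            assert mols.center_uncertainty[j] == pytest.approx(unc)

    def test_roi_masking(self, cloud_table):
        locs, centers = cloud_table
        labels = cluster_localizations(locs, 50.0, 5)
        roi_both = ROI.rectangle(0, 0, 1000, 1000)
        roi_one = ROI.rectangle(0, 0, 600, 1000)  # excludes cloud at x=700
        assert len(molecules_from_clusters(locs, labels, roi_both)) == 2
        mols = molecules_from_clusters(locs, labels, roi_one)
        assert len(mols) == 1
        assert abs(mols.xc[0] - 500.0) < 20.0

    def test_ids_dense(self, cloud_table):
        locs, _ = cloud_table
        mols = molecules_from_clusters(locs, cluster_localizations(locs, 50.0, 5))
        np.testing.assert_array_equal(mols.molecule_id, [0, 1])

    def test_count_matches_unique_cluster_ids(self, rng):
        centers = rng.uniform(200, 9800, (50, 2))
        pts = np.vstack([c + rng.normal(0, 5, (15, 2)) for c in centers])
        locs = make_locs(pts[:, 0], pts[:, 1])
        labels = cluster_localizations(locs, 25.0, 5)
        roi = ROI.rectangle(0, 0, 10_000, 10_000)
        assert len(molecules_from_clusters(locs, labels, roi)) == len(np.unique(labels[labels >= 0]))


class TestMoleculeSetIO:
    def test_csv_round_trip(self, tmp_path, rng):
        roi = ROI.rectangle(0, 0, 10_000, 10_000)
        n = 40
        mols = MoleculeSet(
            molecule_id=np.arange(n),
            xc=rng.uniform(0, 10_000, n),
            yc=rng.uniform(0, 10_000, n),
            n_locs=rng.integers(10, 50, n),
            center_uncertainty=rng.uniform(0.5, 3.0, n),
            roi=roi,
        )
        path = tmp_path / "mols.csv"
        mols.to_csv(path)
        back = MoleculeSet.from_csv(path, roi=roi)
        np.testing.assert_allclose(back.xc, mols.xc)
        np.testing.assert_array_equal(back.n_locs, mols.n_locs)

    def test_missing_column(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("molecule_id,xc_nm\n0,1.0\n")
        with pytest.raises(FormatError):
            MoleculeSet.from_csv(path)


class TestBinderDensity:
    def test_direct_division(self, rng):
        roi = ROI.rectangle(0, 0, 10_000, 10_000)  # 100 µm²
        n = 100
        mols = MoleculeSet(np.arange(n), rng.uniform(0, 10_000, n), rng.uniform(0, 10_000, n),
                           np.full(n, 10), np.ones(n), roi)
        assert binder_density(mols) == pytest.approx(1.0)

    def test_empty_set(self):
        roi = ROI.rectangle(0, 0, 10_000, 10_000)
        mols = MoleculeSet(np.empty(0, int), np.empty(0), np.empty(0), np.empty(0, int), np.empty(0), roi)
        assert binder_density(mols) == 0.0

    def test_matches_independent_arithmetic(self, rng):
        roi = ROI.rectangle(0, 0, 7_000, 3_000)
        n = int(rng.integers(5, 200))
        mols = MoleculeSet(np.arange(n), rng.uniform(0, 7_000, n), rng.uniform(0, 3_000, n),
                           np.full(n, 10), np.ones(n), roi)
        assert binder_density(mols) == pytest.approx(n / (7.0 * 3.0))
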