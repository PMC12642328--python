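from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from glandscape.glands import (BandShape, CurveFitError, GlandRecord,
                               OrderingError, assign_cells_to_glands,
                               build_gland_records, classify_gland,
                               classify_glands, expand_band,
                               filter_glands_by_ratio, fit_principal_curve,
                               mst_order, mst_total_weight)
from glandscape.io_qc import GlandMask
from glandscape.pipeline import PipelineConfig, classify_core
from glandscape.synthetic import SimCoreConfig, simulate_core

from conftest import make_cell_table


def brute_force_mst_weight(pts: np.ndarray) -> float:
    """Minimum total weight over all spanning trees by exhaustive search
    (all edge subsets of size n-1 that connect the graph)."""
    n = len(pts)
    edges = list(combinations(range(n), 2))
    w = {e: float(np.linalg.norm(pts[e[0]] - pts[e[1]])) for e in edges}
    best = np.inf
    for subset in combinations(edges, n - 1):
        parent = list(range(n))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        ok = True
        for a, b in subset:
            ra, rb = find(a), find(b)
            if ra == rb:
                ok = False
                break
            parent[ra] = rb
        if ok:
            best = min(best, sum(w[e] for e in subset))
    return best


class TestAssignCells:
    def test_cell_in_labeled_block(self):
        mask = np.zeros((10, 10), dtype=np.int32)
        mask[2:5, 2:5] = 7
        table = make_cell_table(2)
        table.df.loc[0, ["x", "y"]] = [3.0, 3.0]   # inside block
        table.df.loc[1, ["x", "y"]] = [8.0, 8.0]   # background
        gid = assign_cells_to_glands(table, GlandMask(mask))
        np.testing.assert_array_equal(gid, [7, 0])

    def test_out_of_bounds_warns_and_zero(self):
        table = make_cell_table(1)
        table.df.loc[0, ["x", "y"]] = [50.0, 50.0]
        with pytest.warns(UserWarning, match="outside"):
            gid = assign_cells_to_glands(table, GlandMask(np.ones((5, 5), np.int32)))
        assert gid[0] == 0

    def test_synthetic_assignments_match_truth(self, small_core):
        # every cell interior to a truth gland polygon (clear of the
        # rasterized boundary) maps to that gland's label
        import shapely.geometry as sg
        table, mask, truth = small_core
        gid = assign_cells_to_glands(table, mask)
        pts = table.df[["x", "y"]].to_numpy()
        checked = 0
        for g, poly in truth.gland_polygons.items():
            inner = poly.buffer(-1.5)
            sel = np.array([inner.covers(sg.Point(p)) for p in pts])
            assert (gid[sel] == g).all()
            checked += int(sel.sum())
        assert checked > 0


class TestRatioFilter:
    @pytest.mark.parametrize("area,n_nce,eligible", [
        (100_000, 2, False),   # ratio 50,000 > 25,000
        (100_000, 10, True),   # ratio 10,000 <= 25,000
        (100_000, 4, True),    # ratio exactly 25,000: kept (<= threshold)
        (50_000, 0, False),    # no points to fit
    ])
    def test_threshold(self, area, n_nce, eligible):
        rec = GlandRecord(gland_id=1, area_px=area, n_nce_cells=n_nce)
        out = filter_glands_by_ratio([rec])[0]
        assert out.eligible == eligible


class TestMstOrder:
    def test_collinear_points_ordered(self):
        pts = np.array([[3.0, 0.0], [0.0, 0.0], [2.0, 0.0], [1.0, 0.0]])
        order = mst_order(pts)
        xs = pts[order, 0]
        assert (xs == sorted(xs)).all() or (xs == sorted(xs, reverse=True)).all()

    def test_two_points(self):
        order = mst_order(np.array([[0.0, 0.0], [1.0, 1.0]]))
        assert sorted(order) == [0, 1]

    def test_single_point_error(self):
        with pytest.raises(OrderingError):
            mst_order(np.array([[0.0, 0.0]]))

    def test_output_is_permutation(self):
        rng = np.random.default_rng(0)
        pts = rng.uniform(0, 100, (20, 2))
        order = mst_order(pts)
        assert sorted(order) == list(range(20))

    def test_mst_weight_matches_bruteforce(self):
        """MST total weight equals the exhaustive minimum over all spanning
        trees on random 5-point instances."""
        rng = np.random.default_rng(1)
        for _ in range(10):
            pts = rng.uniform(0, 50, (5, 2))
            assert np.isclose(mst_total_weight(pts), brute_force_mst_weight(pts))

    def test_mst_weight_six_points(self):
        rng = np.random.default_rng(2)
        pts = rng.uniform(0, 50, (6, 2))
        assert np.isclose(mst_total_weight(pts), brute_force_mst_weight(pts))


class TestPrincipalCurve:
    def test_straight_line_exact(self):
        t = np.linspace(0, 100, 30)
        pts = np.column_stack([t, 0.5 * t + 3.0])
        curve = fit_principal_curve(pts)
        assert curve.residual < 1e-6
        # endpoints within 1 px of the extreme points
        assert np.linalg.norm(curve.polyline[0] - pts[0]) < 1.0
        assert np.linalg.norm(curve.polyline[-1] - pts[-1]) < 1.0

    def test_noisy_three_quarter_circle(self):
        rng = np.random.default_rng(0)
        theta = np.linspace(0, 1.5 * np.pi, 200)
        pts = 100.0 * np.column_stack([np.cos(theta), np.sin(theta)])
        pts += rng.normal(0, 2.0, pts.shape)
        order = mst_order(pts)
        curve = fit_principal_curve(pts[order])
        assert np.sqrt(curve.residual) <= 3.0  # mean projection distance

    def test_residual_monotone_in_df(self):
        # lower df = stiffer curve = residual cannot decrease
        rng = np.random.default_rng(3)
        theta = np.linspace(0, 1.5 * np.pi, 200)
        pts = 100.0 * np.column_stack([np.cos(theta), np.sin(theta)])
        pts += rng.normal(0, 2.0, pts.shape)
        order = mst_order(pts)
        residuals = [fit_principal_curve(pts[order], df=df).residual
                     for df in (8, 5, 3, 2)]
        assert all(np.diff(residuals) >= -1e-9)

    def test_residual_trace_nonincreasing(self):
        rng = np.random.default_rng(4)
        theta = np.linspace(0, np.pi, 120)
        pts = 80.0 * np.column_stack([np.cos(theta), np.sin(theta)])
        pts += rng.normal(0, 3.0, pts.shape)
        curve = fit_principal_curve(pts[mst_order(pts)])
        assert all(np.diff(curve.residual_trace) <= 1e-12)

    def test_identical_points_error(self):
        with pytest.raises(CurveFitError):
            fit_principal_curve(np.ones((10, 2)))

    def test_small_n_lowers_df_with_warning(self):
        pts = np.array([[0.0, 0.0], [1.0, 0.2], [2.0, -0.1], [3.0, 0.05],
                        [4.0, 0.0]])
        with pytest.warns(UserWarning, match="lowering curve df"):
            curve = fit_principal_curve(pts, df=8)
        assert curve.df == 4


class TestExpandBand:
    def _line_band(self, half_width=10.0):
        poly = np.column_stack([np.linspace(0, 100, 50), np.zeros(50)])
        curve = fit_principal_curve(poly)
        return expand_band(curve, half_width)

    def test_point_on_curve_is_member(self):
        band = self._line_band()
        assert band.contains_points(np.array([[50.0, 0.0]]))[0]

    def test_boundary_inclusive_at_10px(self):
        band = self._line_band(10.0)
        assert band.contains_points(np.array([[50.0, 10.0]]))[0]
        assert not band.contains_points(np.array([[50.0, 10.5]]))[0]

    def test_membership_matches_bruteforce(self):
        """Band membership equals brute-force point-to-segment min distance
        on a random 50-vertex polyline."""
        rng = np.random.default_rng(7)
        steps = rng.normal(0, 5, (50, 2))
        polyline = np.cumsum(steps, axis=0) + 100.0
        band = BandShape(polygon=None, polyline=polyline, half_width=10.0)
        pts = rng.uniform(polyline.min() - 20, polyline.max() + 20, (1000, 2))

        def seg_dist(p, a, b):
            ab = b - a
            tt = np.clip(np.dot(p - a, ab) / np.dot(ab, ab), 0, 1)
            return np.linalg.norm(p - (a + tt * ab))

        brute = np.array([min(seg_dist(p, polyline[i], polyline[i + 1])
                              for i in range(len(polyline) - 1))
                          for p in pts])
        np.testing.assert_array_equal(band.contains_points(pts),
                                      brute <= 10.0 + 1e-9)

    def test_rigid_invariance(self):
        rng = np.random.default_rng(8)
        polyline = np.cumsum(rng.normal(0, 5, (30, 2)), axis=0)
        pts = rng.uniform(-30, 30, (200, 2)) + polyline.mean(axis=0)
        band = BandShape(polygon=None, polyline=polyline, half_width=10.0)
        before = band.contains_points(pts)
        ang = 0.7
        R = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
        shift = np.array([123.4, -56.7])
        band2 = BandShape(polygon=None, polyline=polyline @ R.T + shift,
                          half_width=10.0)
        after = band2.contains_points(pts @ R.T + shift)
        np.testing.assert_array_equal(before, after)


class TestClassifyGland:
    def _cells(self, xy, labels, compartment="epithelial"):
        df = pd.DataFrame({
            "cell_id": [f"c{i}" for i in range(len(xy))],
            "x": xy[:, 0], "y": xy[:, 1],
            "compartment": compartment, "cell_label": labels})
        return df

    def test_ineligible_gland_becomes_ce(self):
        # large gland, 2 scattered basal-positive cells: all relabeled CE
        xy = np.array([[10.0, 10.0], [40.0, 40.0]])
        cells = self._cells(xy, ["N-CE", "N-CE"])
        rec = GlandRecord(gland_id=1, area_px=100_000, n_nce_cells=2)
        rec = filter_glands_by_ratio([rec])[0]
        rec, labels = classify_gland(rec, None, cells)
        assert rec.gland_label == "CE"
        assert (labels == "CE").all()

    def test_empty_gland_excluded(self):
        cells = self._cells(np.empty((0, 2)), [])
        rec = GlandRecord(gland_id=1, area_px=500, n_nce_cells=0)
        rec, _ = classify_gland(rec, None, cells)
        assert rec.gland_label == "excluded"

    def test_stroma_only_gland_excluded(self):
        xy = np.array([[1.0, 1.0]])
        cells = self._cells(xy, ["stroma"], compartment="stromal")
        rec = GlandRecord(gland_id=1, area_px=500, n_nce_cells=0)
        rec, labels = classify_gland(rec, None, cells)
        assert rec.gland_label == "excluded"
        assert labels.iloc[0] == "stroma"

    def test_band_relabels_epithelial_cells(self):
        # straight rim of N-CE cells; one GMM-mislabeled cell on the rim is
        # rescued into N-CE, one far-off epithelial cell becomes CE
        xs = np.linspace(0, 100, 12)
        rim = np.column_stack([xs, np.zeros(12)])
        far = np.array([[50.0, 40.0]])
        xy = np.vstack([rim, far])
        labels = ["N-CE"] * 11 + ["CE", "N-CE"]  # one rim cell miscalled CE
        cells = self._cells(xy, labels)
        curve = fit_principal_curve(rim)
        band = expand_band(curve, 10.0)
        rec = GlandRecord(gland_id=1, area_px=5000, n_nce_cells=12,
                          eligible=True)
        rec, final = classify_gland(rec, band, cells)
        assert rec.gland_label == "N-CE"
        assert (final.iloc[:12] == "N-CE").all()
        assert final.iloc[12] == "CE"


class TestGlandStageEndToEnd:
    def test_synthetic_gland_labels_match_truth(self):
        """Gland-level calls match ground truth on well-separated cores."""
        correct = total = 0
        for seed in (0, 1, 2):
            table, mask, truth = simulate_core(SimCoreConfig(seed=seed))
            final, gland_df, _ = classify_core(table, mask, PipelineConfig())
            pred = dict(zip(gland_df["gland_id"], gland_df["gland_label"]))
            for g, t in truth.gland_types.items():
                correct += pred[g] == t
                total += 1
        assert correct / total >= 0.95

    def test_ring_gland_rim_in_band(self, small_core):
        table, mask, truth = small_core
        final, gland_df, _ = classify_core(table, mask, PipelineConfig())
        nce_glands = gland_df.loc[gland_df["gland_label"] == "N-CE", "gland_id"]
        # every true basal cell of an N-CE gland is labeled N-CE at the end
        tt = truth.cell_types
        for g in nce_glands:
            sel = final.df["gland_id"] == g
            truth_sel = tt.loc[final.df.loc[sel, "cell_id"]] == "N-CE"
            labels = final.df.loc[sel, "cell_label"][truth_sel.to_numpy()]
            assert (labels == "N-CE").mean() > 0.9
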