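"""Gland-level modeling: cell-to-gland assignment, eligibility filtering,
MST ordering, principal-curve fitting, band expansion and gland calls.

A benign prostate gland retains a basal cell rim (p63+/CK5+, i.e. N-CE
cells); carcinoma loses it. The latent backbone of a gland's basal rim is
recovered as a principal curve: the smooth 1-D curve gamma(t) minimizing the
mean squared orthogonal distance (1/N) sum_i ||x_i - gamma(t_i)||^2 to the
gland's N-CE cell coordinates. A minimum spanning tree over the cells'
pairwise Euclidean distances supplies the initial spatial ordering so the
curve follows the gland contour continuously. The fitted curve is dilated
into a fixed half-width band; epithelial cells inside the band are the
gland's basal compartment (N-CE), those inside the gland but outside the
band are CE.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
import networkx as nx
from scipy.interpolate import LSQUnivariateSpline
from shapely.geometry import LineString, Point, Polygon
import shapely

from .io_qc import CellTable, GlandMask

#: a gland is eligible for curve fitting when area_px / n_nce <= this ratio
DEFAULT_RATIO_THRESHOLD = 25_000.0
#: half-width (px) of the perpendicular band around the fitted curve
DEFAULT_BAND_HALF_WIDTH = 10.0
#: smoothing-spline degrees of freedom (number of cubic B-spline coefficients)
DEFAULT_CURVE_DF = 8


class OrderingError(ValueError):
    """Too few points to order."""


class CurveFitError(ValueError):
    """Degenerate geometry prevents a principal-curve fit."""


@dataclass
class GlandRecord:
    gland_id: int
    area_px: int
    member_cells: list[str] = field(default_factory=list)
    n_nce_cells: int = 0
    eligible: bool = False
    gland_label: str = "excluded"  # CE | N-CE | excluded
    exclusion_reason: str | None = None
    residual: float | None = None


@dataclass
class PrincipalCurve:
    """An ordered polyline gamma(t) with per-point arclength projections."""

    t: np.ndarray            # projection parameter per input point (arclength)
    polyline: np.ndarray     # (m, 2) ordered curve samples
    df: int
    residual: float          # mean squared projection distance
    residual_trace: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        assert self.polyline.shape[0] >= 2
        assert self.residual >= 0


@dataclass
class BandShape:
    """The curve polyline dilated by ``half_width`` (round caps)."""

    polygon: Polygon
    polyline: np.ndarray
    half_width: float

    def contains_points(self, points: np.ndarray) -> np.ndarray:
        """Membership = Euclidean distance to the polyline <= half_width."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        line = LineString(self.polyline)
        d = shapely.distance(line, shapely.points(pts))
        return d <= self.half_width + 1e-9


# ---------------------------------------------------------------------------
# Cell-to-gland assignment and eligibility
# ---------------------------------------------------------------------------

def assign_cells_to_glands(table: CellTable, mask: GlandMask) -> np.ndarray:
    """Gland id per cell = mask label at the cell's rounded pixel position
    (x = column, y = row); cells outside the mask bounds get 0 with a
    warning."""
    h, w = mask.labels.shape
    cols = np.rint(table.df["x"].to_numpy(dtype=float)).astype(int)
    rows = np.rint(table.df["y"].to_numpy(dtype=float)).astype(int)
    inside = (rows >= 0) & (rows < h) & (cols >= 0) & (cols < w)
    if not inside.all():
        warnings.warn(f"{int((~inside).sum())} cells fall outside the mask "
                      "bounds; assigned gland_id 0")
    gid = np.zeros(len(table.df), dtype=np.int32)
    gid[inside] = mask.labels[rows[inside], cols[inside]]
    return gid


def build_gland_records(table: CellTable, mask: GlandMask,
                        gland_ids: np.ndarray | None = None) -> list[GlandRecord]:
    """One record per mask label with area, member cells and N-CE count.

    ``gland_ids`` is the per-cell assignment (computed when omitted); the
    cell table must already carry mixture-model ``cell_label`` values.
    """
    if gland_ids is None:
        gland_ids = assign_cells_to_glands(table, mask)
    df = table.df
    records = []
    counts = np.bincount(mask.labels.ravel())
    for g in mask.gland_ids:
        member = gland_ids == g
        cells = df.loc[member, "cell_id"].tolist()
        n_nce = int(((df["cell_label"] == "N-CE") & member).sum()) \
            if "cell_label" in df.columns else 0
        records.append(GlandRecord(gland_id=int(g), area_px=int(counts[g]),
                                   member_cells=cells, n_nce_cells=n_nce))
    return records


def filter_glands_by_ratio(records: list[GlandRecord],
                           threshold: float = DEFAULT_RATIO_THRESHOLD
                           ) -> list[GlandRecord]:
    """Mark glands eligible for curve fitting.

    Eligibility requires at least one N-CE cell and area/N-CE-count <=
    ``threshold`` px per cell; a gland too large for its N-CE count is more
    plausibly a CE-dominated gland with a few scattered basal-positive cells
    than a true benign gland, so it is excluded from curve fitting.
    """
    for rec in records:
        if rec.n_nce_cells < 1:
            rec.eligible = False
            rec.exclusion_reason = "no N-CE cells"
        elif rec.area_px / rec.n_nce_cells > threshold:
            rec.eligible = False
            rec.exclusion_reason = (
                f"area/N-CE ratio {rec.area_px / rec.n_nce_cells:.0f} px/cell "
                f"> {threshold:.0f}")
        else:
            rec.eligible = True
            rec.exclusion_reason = None
    return records


# ---------------------------------------------------------------------------
# MST ordering
# ---------------------------------------------------------------------------

def mst_total_weight(points: np.ndarray) -> float:
    """Total edge weight of the Euclidean MST (for cross-checks)."""
    pts = np.asarray(points, dtype=float)
    tree = _euclidean_mst(pts)
    return float(sum(d for _, _, d in tree.edges(data="weight")))


def _euclidean_mst(pts: np.ndarray) -> nx.Graph:
    n = len(pts)
    g = nx.Graph()
    g.add_nodes_from(range(n))
    for i, j in combinations(range(n), 2):
        g.add_edge(i, j, weight=float(np.hypot(*(pts[i] - pts[j]))))
    return nx.minimum_spanning_tree(g)


def mst_order(points: np.ndarray) -> np.ndarray:
    """Order points along the MST's longest simple path (tree diameter).

    The diameter endpoints are found by double traversal (farthest node from
    an arbitrary node, then farthest from that). Points not on the diameter
    path are inserted immediately after their nearest path vertex, keeping
    the output a permutation of the input. Returns the index permutation.
    """
    pts = np.asarray(points, dtype=float)
    if len(pts) < 2:
        raise OrderingError("need at least 2 points to order")
    if len(pts) == 2:
        return np.array([0, 1])

    tree = _euclidean_mst(pts)

    def farthest_from(src: int) -> int:
        dist = nx.single_source_dijkstra_path_length(tree, src)
        # deterministic tie-break on node index
        return min(dist, key=lambda k: (-dist[k], k))

    a = farthest_from(0)
    b = farthest_from(a)
    path = nx.dijkstra_path(tree, a, b)

    order = list(path)
    on_path = set(path)
    off = sorted(set(range(len(pts))) - on_path)
    for node in off:
        # nearest vertex of the current ordering, by Euclidean distance
        d = np.linalg.norm(pts[order] - pts[node], axis=1)
        k = int(np.argmin(d))
        order.insert(k + 1, node)
    return np.asarray(order)


# ---------------------------------------------------------------------------
# Principal curve
# ---------------------------------------------------------------------------

def _arclength_param(poly: np.ndarray) -> np.ndarray:
    seg = np.linalg.norm(np.diff(poly, axis=0), axis=1)
    return np.concatenate([[0.0], np.cumsum(seg)])


def _project_to_polyline(pts: np.ndarray, poly: np.ndarray
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Foot-of-perpendicular projection of each point onto a polyline.

    Returns (arclength parameter of the projection, squared distance).
    Fully vectorized over points x segments.
    """
    a = poly[:-1]                      # (m,2) segment starts
    ab = poly[1:] - a                  # (m,2)
    ab2 = (ab ** 2).sum(axis=1)        # (m,)
    ab2 = np.where(ab2 == 0, 1.0, ab2)
    ap = pts[:, None, :] - a[None, :, :]          # (n,m,2)
    s = np.clip((ap * ab[None, :, :]).sum(axis=2) / ab2[None, :], 0.0, 1.0)
    foot = a[None, :, :] + s[:, :, None] * ab[None, :, :]
    d2 = ((pts[:, None, :] - foot) ** 2).sum(axis=2)
    j = np.argmin(d2, axis=1)
    n = np.arange(len(pts))
    cum = _arclength_param(poly)
    seg_len = np.sqrt((ab ** 2).sum(axis=1))
    t = cum[j] + s[n, j] * seg_len[j]
    return t, d2[n, j]


def _smooth_spline(t: np.ndarray, y: np.ndarray, df: int) -> LSQUnivariateSpline:
    """Least-squares regression spline with ``df`` coefficients.

    Cubic (k=3) with df - 4 interior knots at uniform quantiles of t; the
    order drops below cubic when df < 4 (tiny point sets).
    """
    k = min(3, df - 1)
    n_interior = max(df - (k + 1), 0)
    if n_interior > 0:
        qs = np.linspace(0, 1, n_interior + 2)[1:-1]
        knots = np.quantile(t, qs)
        # interior knots must be strictly inside (t[0], t[-1]) and increasing
        knots = np.unique(knots[(knots > t[0]) & (knots < t[-1])])
    else:
        knots = np.array([])
    return LSQUnivariateSpline(t, y, knots, k=k)


def fit_principal_curve(ordered_points: np.ndarray, df: int = DEFAULT_CURVE_DF,
                        max_iter: int = 30, tol: float = 1e-4,
                        n_samples: int | None = None) -> PrincipalCurve:
    """Fit a principal curve to points given in a spatial ordering.

    Alternates (i) smoothing x(t) and y(t) against the current projection
    parameters t_i with cubic regression splines at ``df`` degrees of
    freedom, and (ii) re-projecting the points onto the densely sampled
    curve to update t_i. Stops when the mean squared projection distance
    improves by less than ``tol`` (relative), increases, or ``max_iter`` is
    hit; the reported residual trace is non-increasing because the best
    curve so far is kept. ``df`` is lowered to n-1 (minimum 4) with a
    warning when fewer than df+1 points are given.
    """
    pts = np.asarray(ordered_points, dtype=float)
    if len(pts) < 2 or np.allclose(pts, pts[0]):
        raise CurveFitError("degenerate geometry: need >= 2 distinct points")
    n = len(pts)
    if n == 2:
        # two points define a segment: the principal curve is exact
        t = _arclength_param(pts)
        return PrincipalCurve(t=t, polyline=pts.copy(), df=1, residual=0.0,
                              residual_trace=[0.0])
    if n < df + 1:
        new_df = max(min(df, n - 1), 2)
        warnings.warn(f"only {n} points: lowering curve df from {df} to {new_df}")
        df = new_df
    if n_samples is None:
        n_samples = max(20 * n, 200)

    # initial parameter: cumulative chord length along the given ordering
    t = _arclength_param(pts)
    if t[-1] == 0:
        raise CurveFitError("degenerate geometry: zero total chord length")

    best_poly = None
    best_t = t
    best_res = np.inf
    trace: list[float] = []
    for _ in range(max_iter):
        # strictly increasing t is required by the spline fit
        order = np.argsort(t, kind="stable")
        ts = t[order]
        ts = ts + np.arange(n) * 1e-9 * max(ts[-1], 1.0)  # break exact ties
        try:
            sx = _smooth_spline(ts, pts[order, 0], df)
            sy = _smooth_spline(ts, pts[order, 1], df)
        except Exception as exc:  # singular design from collapsed parameters
            if best_poly is not None:
                break
            raise CurveFitError(f"spline fit failed: {exc}") from exc
        grid = np.linspace(ts[0], ts[-1], n_samples)
        poly = np.column_stack([sx(grid), sy(grid)])

        t_new, d2 = _project_to_polyline(pts, poly)
        res = float(d2.mean())
        if res < best_res - 1e-15:
            improved = best_res - res
            best_poly, best_t, best_res = poly, t_new, res
            trace.append(res)
            if np.isfinite(improved) and improved < tol * max(best_res, 1e-12):
                break
        else:
            break  # no improvement: keep the best curve
        t = t_new

    assert best_poly is not None
    return PrincipalCurve(t=best_t, polyline=best_poly, df=df,
                          residual=best_res, residual_trace=trace)


def expand_band(curve: PrincipalCurve,
                half_width: float = DEFAULT_BAND_HALF_WIDTH) -> BandShape:
    """Dilate the fitted curve into a perpendicular band of the given
    half-width (round caps, so the band has uniform Euclidean half-width
    with no wedge gaps at polyline vertices)."""
    line = LineString(curve.polyline)
    polygon = line.buffer(half_width, quad_segs=32)
    return BandShape(polygon=polygon, polyline=curve.polyline,
                     half_width=half_width)


# ---------------------------------------------------------------------------
# Gland classification
# ---------------------------------------------------------------------------

def classify_gland(rec: GlandRecord, band: BandShape | None,
                   cells: pd.DataFrame) -> tuple[GlandRecord, pd.Series]:
    """Final gland call and per-cell label overrides for one gland.

    An eligible gland with a fitted curve is N-CE: epithelial member cells
    inside the band are (re)labeled N-CE, those inside the gland but outside
    the band are CE. An ineligible gland containing at least one epithelial
    cell is a CE gland and all its epithelial cells are labeled CE. A gland
    with no epithelial cells is excluded.

    ``cells`` holds this gland's member cells with x, y, compartment and the
    mixture-model cell_label; the returned Series gives the final label per
    cell (indexed like ``cells``).
    """
    labels = cells["cell_label"].copy()
    epi = cells["compartment"] == "epithelial"
    if not epi.any():
        rec.gland_label = "excluded"
        rec.exclusion_reason = rec.exclusion_reason or "no epithelial cells"
        return rec, labels
    if rec.eligible and band is not None:
        rec.gland_label = "N-CE"
        pts = cells[["x", "y"]].to_numpy(dtype=float)
        inside = band.contains_points(pts)
        labels[epi & inside] = "N-CE"
        labels[epi & ~inside] = "CE"
    else:
        rec.gland_label = "CE"
        labels[epi] = "CE"
    return rec, labels


def classify_glands(table: CellTable, mask: GlandMask, *,
                    ratio_threshold: float = DEFAULT_RATIO_THRESHOLD,
                    band_half_width: float = DEFAULT_BAND_HALF_WIDTH,
                    curve_df: int = DEFAULT_CURVE_DF
                    ) -> tuple[CellTable, pd.DataFrame,
                               dict[int, PrincipalCurve], dict[int, BandShape]]:
    """Run the whole gland stage on a labeled core.

    Returns the table with a ``gland_id`` column and final ``cell_label``
    values, a per-gland summary frame, and the fitted curves and bands by
    gland id. Cells outside every gland keep their mixture-model labels.
    """
    if "cell_label" not in table.df.columns:
        raise ValueError("run the cell classifier before the gland stage")
    out = table.copy()
    gid = assign_cells_to_glands(out, mask)
    out.df["gland_id"] = gid
    records = filter_glands_by_ratio(build_gland_records(out, mask, gid),
                                     ratio_threshold)
    curves: dict[int, PrincipalCurve] = {}
    bands: dict[int, BandShape] = {}
    for rec in records:
        member = out.df["gland_id"] == rec.gland_id
        cells = out.df.loc[member]
        band = None
        if rec.eligible:
            nce = cells[(cells["cell_label"] == "N-CE")
                        & (cells["compartment"] == "epithelial")]
            pts = nce[["x", "y"]].to_numpy(dtype=float)
            try:
                order = mst_order(pts)
                curve = fit_principal_curve(pts[order], df=curve_df)
                band = expand_band(curve, band_half_width)
                curves[rec.gland_id] = curve
                bands[rec.gland_id] = band
                rec.residual = curve.residual
            except (OrderingError, CurveFitError) as exc:
                rec.eligible = False
                rec.exclusion_reason = f"curve fit failed: {exc}"
        rec, labels = classify_gland(rec, band, cells)
        out.df.loc[member, "cell_label"] = labels

    gland_df = pd.DataFrame([{
        "gland_id": r.gland_id, "area_px": r.area_px, "n_nce": r.n_nce_cells,
        "eligible": r.eligible, "gland_label": r.gland_label,
        "residual": r.residual if r.residual is not None else np.nan,
        "exclusion_reason": r.exclusion_reason or "",
    } for r in records])
    return out, gland_df, curves, bands
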