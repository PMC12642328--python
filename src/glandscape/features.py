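"""Spatial immune-geometry features and patient-level summaries.

Three feature families relate immune cells to cancerous (CE) glands:

* cell-centric (point view): shortest Euclidean distance from each T cell
  (T_reg, T_H) to the centroid of the nearest CE gland, in micrometres;
* region-centric (shape view): shortest boundary-to-boundary distance
  between macrophage-dense (MD) regions — alpha-shape polygons around
  spatial clusters of CD68+ cells — and CE gland boundaries, with distance
  defined as 0 when a region overlaps a gland (an infiltration event);
* patient summaries: T-cell distances by median, MD-region areas by log
  mean, and infiltration events tallied per patient over usable cores.

All geometry is computed in pixels; micrometre conversion (default
0.325 um/px: a 6.5 um camera pixel through a 20x objective) is applied at
output only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import Delaunay, cKDTree
from shapely.geometry import Polygon
from shapely.ops import unary_union
import shapely
from skimage import measure
from sklearn.cluster import DBSCAN

from .io_qc import DEFAULT_UM_PER_PX, GlandMask


@dataclass
class UnitScale:
    um_per_px: float = DEFAULT_UM_PER_PX

    def __post_init__(self) -> None:
        if self.um_per_px <= 0:
            raise ValueError("um_per_px must be positive")


@dataclass
class MDRegion:
    """A macrophage-dense region: alpha-shape polygon around a CD68+ cluster."""

    region_id: int
    member_ids: list[str]
    polygon: Polygon
    area_px: float
    distance_um: float | None = None
    infiltrating: bool = False

    @property
    def log_area(self) -> float:
        return float(np.log(self.area_px))


@dataclass
class PatientFeatures:
    patient_id: str
    median_treg_distance_um: float = np.nan
    median_th_distance_um: float = np.nan
    log_mean_md_area: float = np.nan
    infiltration_count: int = 0
    n_usable_cores: int = 0


class GeometryError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Cell-centric distances
# ---------------------------------------------------------------------------

def cell_to_gland_distance(t_cells: np.ndarray, ce_gland_centroids: np.ndarray,
                           scale: UnitScale | None = None) -> np.ndarray:
    """Distance (um) from each T cell to the nearest CE-gland centroid.

    Returns an empty array for zero T cells and an all-NaN array when there
    is no CE gland (the feature is undefined, recorded as missing).
    """
    scale = scale or UnitScale()
    pts = np.atleast_2d(np.asarray(t_cells, dtype=float))
    if pts.size == 0:
        return np.empty(0)
    cents = np.atleast_2d(np.asarray(ce_gland_centroids, dtype=float))
    if cents.size == 0:
        return np.full(len(pts), np.nan)
    d, _ = cKDTree(cents).query(pts)
    return d * scale.um_per_px


def gland_centroids(mask: GlandMask, gland_ids=None) -> dict[int, np.ndarray]:
    """Centroid (x, y) of each gland = unweighted mean of its pixel coords."""
    ids = mask.gland_ids if gland_ids is None else np.asarray(gland_ids)
    out = {}
    for g in ids:
        rows, cols = np.nonzero(mask.labels == g)
        if len(rows):
            out[int(g)] = np.array([cols.mean(), rows.mean()])
    return out


def gland_boundary_polygon(mask: GlandMask, gland_id: int) -> Polygon:
    """Polygonized mask contour of one gland label, in (x, y) pixel coords.

    The longest closed contour of the binary label image is used; this works
    for CE glands that never received a fitted curve.
    """
    binary = (mask.labels == gland_id).astype(float)
    contours = measure.find_contours(binary, 0.5)
    if not contours:
        raise GeometryError(f"gland {gland_id} has no boundary contour")
    contour = max(contours, key=len)  # (row, col) -> (x, y)
    poly = Polygon(np.column_stack([contour[:, 1], contour[:, 0]]))
    if not poly.is_valid:
        poly = poly.buffer(0)
    return poly


# ---------------------------------------------------------------------------
# Macrophage-dense regions (alpha shapes)
# ---------------------------------------------------------------------------

def alpha_shape(points: np.ndarray, alpha: float) -> Polygon | None:
    """Alpha shape (concave hull) of a 2-D point set.

    Classic construction: keep every Delaunay triangle whose circumradius is
    at most ``alpha`` and take the union. As alpha grows the shape converges
    to the convex hull. Returns None when the points are degenerate or no
    triangle survives.
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    pts = np.asarray(points, dtype=float)
    if len(pts) < 3:
        return None
    try:
        tri = Delaunay(pts)
    except Exception:
        return None  # collinear / duplicate degeneracy
    a = pts[tri.simplices[:, 0]]
    b = pts[tri.simplices[:, 1]]
    c = pts[tri.simplices[:, 2]]
    la = np.linalg.norm(b - c, axis=1)
    lb = np.linalg.norm(a - c, axis=1)
    lc = np.linalg.norm(a - b, axis=1)
    s = (la + lb + lc) / 2.0
    area = np.sqrt(np.maximum(s * (s - la) * (s - lb) * (s - lc), 0.0))
    with np.errstate(divide="ignore"):
        circumradius = np.where(area > 0, la * lb * lc / (4.0 * area), np.inf)
    keep = circumradius <= alpha
    if not keep.any():
        return None
    triangles = [Polygon(t) for t in pts[tri.simplices[keep]]]
    merged = unary_union(triangles)
    if merged.is_empty or merged.area == 0:
        return None
    if merged.geom_type == "MultiPolygon":
        merged = max(merged.geoms, key=lambda p: p.area)
    return merged


def build_md_regions(cd68_points: np.ndarray, alpha: float = 30.0,
                     min_points: int = 5,
                     member_ids: list[str] | None = None) -> list[MDRegion]:
    """Cluster CD68+ cells and wrap each cluster in an alpha-shape polygon.

    Clustering is density-based (DBSCAN with eps = ``alpha`` and
    ``min_points`` minimum samples), so the neighborhood radius that links
    macrophages into one dense region is the same scale that controls the
    concavity of its polygon. Clusters whose alpha shape is degenerate
    (fewer than 3 non-collinear points) yield no region. Polygon area is the
    shoelace value of the boundary.
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    pts = np.atleast_2d(np.asarray(cd68_points, dtype=float))
    if pts.size == 0 or len(pts) < min_points:
        return []
    if member_ids is None:
        member_ids = [str(i) for i in range(len(pts))]
    labels = DBSCAN(eps=alpha, min_samples=min_points).fit_predict(pts)
    regions: list[MDRegion] = []
    for lab in sorted(set(labels) - {-1}):
        sel = labels == lab
        poly = alpha_shape(pts[sel], alpha)
        if poly is None:
            continue
        regions.append(MDRegion(
            region_id=len(regions),
            member_ids=[member_ids[i] for i in np.nonzero(sel)[0]],
            polygon=poly, area_px=float(poly.area)))
    return regions


def region_to_gland_distance(region_polygon: Polygon, gland_polygon: Polygon,
                             scale: UnitScale | None = None
                             ) -> tuple[float, bool]:
    """Shortest boundary-to-boundary distance (um) and infiltration flag.

    Distance is 0 — an infiltration event — when the polygons intersect or
    one contains the other (fully or partially overlapping regions);
    otherwise the minimum distance between the two boundaries.
    """
    scale = scale or UnitScale()
    for poly, name in ((region_polygon, "region"), (gland_polygon, "gland")):
        if poly is None or poly.is_empty or len(poly.exterior.coords) < 4:
            raise GeometryError(f"degenerate {name} polygon")
    # two independent predicates: edge intersection OR containment
    overlapping = (region_polygon.intersects(gland_polygon)
                   or region_polygon.contains(gland_polygon)
                   or gland_polygon.contains(region_polygon))
    if overlapping:
        return 0.0, True
    d = region_polygon.distance(gland_polygon)
    return float(d) * scale.um_per_px, False


# ---------------------------------------------------------------------------
# Per-core feature extraction and patient summaries
# ---------------------------------------------------------------------------

@dataclass
class CoreFeatures:
    """Per-core raw features prior to patient-level aggregation."""

    core_id: str
    patient_id: str
    usable: bool
    treg_distances_um: np.ndarray = field(default_factory=lambda: np.empty(0))
    th_distances_um: np.ndarray = field(default_factory=lambda: np.empty(0))
    md_regions: list[MDRegion] = field(default_factory=list)


def extract_core_features(table, mask: GlandMask, gland_df: pd.DataFrame, *,
                          alpha: float = 30.0, min_points: int = 5,
                          scale: UnitScale | None = None) -> CoreFeatures:
    """Compute all three feature families for one classified core.

    Requires the gland stage's outputs: final ``cell_label`` values, a
    ``phenotype`` column for immune cells, and the per-gland summary frame.
    A core with no CE gland is flagged unusable (its distance features are
    undefined).
    """
    scale = scale or UnitScale(mask.pixel_size_um)
    df = table.df
    ce_ids = gland_df.loc[gland_df["gland_label"] == "CE", "gland_id"].to_numpy()
    usable = len(ce_ids) > 0
    feats = CoreFeatures(core_id=table.core_id, patient_id=table.patient_id,
                         usable=usable)
    if not usable:
        return feats

    cents = gland_centroids(mask, ce_ids)
    cent_arr = np.array(list(cents.values()))
    phen = df["phenotype"] if "phenotype" in df.columns else pd.Series(
        "other", index=df.index)
    for name, attr in (("T_reg", "treg_distances_um"), ("T_H", "th_distances_um")):
        pts = df.loc[phen == name, ["x", "y"]].to_numpy(dtype=float)
        setattr(feats, attr, cell_to_gland_distance(pts, cent_arr, scale))

    mac = df.loc[phen == "macrophage"]
    regions = build_md_regions(mac[["x", "y"]].to_numpy(dtype=float),
                               alpha=alpha, min_points=min_points,
                               member_ids=mac["cell_id"].tolist())
    gland_polys = []
    for g in ce_ids:
        try:
            gland_polys.append(gland_boundary_polygon(mask, int(g)))
        except GeometryError:
            continue
    for reg in regions:
        dists, flags = [], []
        for gp in gland_polys:
            d, infl = region_to_gland_distance(reg.polygon, gp, scale)
            dists.append(d)
            flags.append(infl)
        if dists:
            k = int(np.argmin(dists))
            reg.distance_um, reg.infiltrating = dists[k], flags[k]
    feats.md_regions = regions
    return feats


def summarize_patient(core_features: list[CoreFeatures],
                      clinical_row: pd.Series | None = None) -> PatientFeatures | None:
    """Aggregate one patient's usable cores into patient-level features.

    Medians pool all T cells across the patient's usable cores; the MD-area
    summary is the mean of natural-log region areas; the infiltration count
    is the number of regions at distance 0. Returns None (with a warning)
    when the patient has no usable core.
    """
    usable = [c for c in core_features if c.usable]
    pid = core_features[0].patient_id if core_features else "?"
    if not usable:
        warnings.warn(f"patient {pid!r} has no usable core; dropped")
        return None
    treg = np.concatenate([c.treg_distances_um for c in usable]) \
        if usable else np.empty(0)
    th = np.concatenate([c.th_distances_um for c in usable])
    areas = np.array([r.area_px for c in usable for r in c.md_regions])
    infl = sum(r.infiltrating for c in usable for r in c.md_regions)

    def _median(v: np.ndarray) -> float:
        v = v[np.isfinite(v)]
        return float(np.median(v)) if len(v) else np.nan

    return PatientFeatures(
        patient_id=pid,
        median_treg_distance_um=_median(treg),
        median_th_distance_um=_median(th),
        log_mean_md_area=float(np.log(areas).mean()) if len(areas) else np.nan,
        infiltration_count=int(infl),
        n_usable_cores=len(usable))


def patient_feature_table(all_core_features: list[CoreFeatures]) -> pd.DataFrame:
    """Patient feature frame from per-core features (patients with no usable
    core are dropped)."""
    by_patient: dict[str, list[CoreFeatures]] = {}
    for c in all_core_features:
        by_patient.setdefault(c.patient_id, []).append(c)
    rows = []
    for pid, cores in sorted(by_patient.items()):
        pf = summarize_patient(cores)
        if pf is not None:
            rows.append(vars(pf))
    return pd.DataFrame(rows)
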