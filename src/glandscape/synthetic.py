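"""Synthetic tissue cores and cohorts with known ground truth.

Real multiplexed prostate TMA data are access-restricted, so every pipeline
stage is exercised on simulated cores that reproduce the data-generating
structure the method assumes: benign (N-CE) glands are rings of basal cells
(p63/CK5 drawn from the bright foreground mixture component) around a
cell-free lumen; cancerous (CE) glands are lumenless and filled with
epithelial cells that are basal-negative but AMACR-bright; stromal and
immune cells are scattered in the inter-gland space, the immune cells at a
configurable distance from gland boundaries; and per-patient biochemical
recurrence times are exponential with a hazard that depends on a chosen
spatial feature.

Marker intensities are two-component Gaussians in log2 space — the same
generative family the mixture-model classifier assumes — stored on the
linear scale as 2**x - 1 so that the standard log2(v + 1) transform recovers
the generated values exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from shapely.geometry import Polygon
from skimage.draw import polygon as draw_polygon

from .io_qc import (ALL_MARKERS, BASAL_MARKERS, CANCER_MARKER, IMMUNE_MARKERS,
                    CellTable, GlandMask, DEFAULT_UM_PER_PX)


@dataclass
class MarkerModel:
    """Two-component Gaussian intensity model in log2 space.

    Defaults put foreground and background ~6 pooled standard deviations
    apart: basal and immune lineage markers in multiplexed IF are close to
    on/off, with the two log-intensity modes far clearer than the 4-sd
    floor of the classifier's well-separated regime.
    """

    bg_mean: float = 2.0
    bg_sd: float = 0.8
    fg_mean: float = 7.0
    fg_sd: float = 0.8

    def sample(self, rng: np.random.Generator, n: int, foreground: bool) -> np.ndarray:
        mu, sd = (self.fg_mean, self.fg_sd) if foreground else (self.bg_mean, self.bg_sd)
        return rng.normal(mu, sd, size=n)


@dataclass
class SimCoreConfig:
    """Everything that defines one simulated core.

    Gland geometry is a circle with a sinusoidal boundary perturbation,
    chosen so the basal rim forms a smooth closed contour that a principal
    curve can recover. Defaults give a ~0.5 mm field at 0.325 um/px with
    glands of 120-200 px (40-65 um) radius — the scale of real prostate
    acini, so the 25,000 px-per-cell gland eligibility ratio behaves as it
    does on tissue — a basal rim sitting within the 10 px curve band, and
    marker components 4 pooled standard deviations apart (the
    well-separated regime the classifier assumes). T cells are scattered
    individually at a configurable distance from gland boundaries;
    macrophages are placed in a few dense clusters so macrophage-dense
    regions exist to detect.
    """

    image_size: tuple[int, int] = (1536, 1536)   # (rows, cols)
    n_glands: int = 5
    gland_radius_range: tuple[float, float] = (120.0, 200.0)
    rim_width: float = 6.0
    ce_fraction: float = 0.5
    boundary_wobble: float = 0.06      # relative sinusoidal radius perturbation
    basal_spacing_px: float = 9.0      # angular spacing of rim cells along the ring
    ce_cell_density: float = 0.004     # CE cells per gland-interior pixel
    n_stromal: int = 400
    immune_density: dict[str, int] = field(default_factory=lambda: {
        "T_H": 40, "T_reg": 15, "macrophage": 60})
    immune_distance_mean_px: float = 60.0   # mean gap from gland boundary
    immune_distance_sd_px: float = 30.0
    macrophage_clusters: int = 4            # dense CD68+ clusters per core
    macrophage_cluster_sd_px: float = 12.0
    markers: dict[str, MarkerModel] = field(default_factory=lambda: {
        m: MarkerModel() for m in ALL_MARKERS})
    pixel_size_um: float = DEFAULT_UM_PER_PX
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.ce_fraction <= 1.0:
            raise ValueError("ce_fraction must be in [0, 1]")
        if self.gland_radius_range[0] <= self.rim_width:
            raise ValueError("gland radii must exceed the rim width")


@dataclass
class SimTruth:
    """Ground truth for one simulated core."""

    cell_types: pd.Series                 # cell_id -> CE | N-CE | stroma | phenotype
    gland_types: dict[int, str]           # gland_id -> CE | N-CE
    gland_polygons: dict[int, Polygon]    # gland_id -> boundary polygon


class PlacementError(RuntimeError):
    pass


def _gland_boundary(cx: float, cy: float, r0: float, wobble: float,
                    phase: float, lobes: int, n_vert: int = 180) -> np.ndarray:
    theta = np.linspace(0, 2 * np.pi, n_vert, endpoint=False)
    r = r0 * (1.0 + wobble * np.sin(lobes * theta + phase))
    return np.column_stack([cx + r * np.cos(theta), cy + r * np.sin(theta)])


def _place_glands(cfg: SimCoreConfig, rng: np.random.Generator
                  ) -> list[dict]:
    """Rejection-sample non-overlapping perturbed-circle glands."""
    h, w = cfg.image_size
    placed: list[dict] = []
    margin = 10.0
    for _ in range(cfg.n_glands):
        ok = False
        for _attempt in range(200):
            r0 = rng.uniform(*cfg.gland_radius_range)
            rmax = r0 * (1 + cfg.boundary_wobble)
            cx = rng.uniform(rmax + margin, w - rmax - margin)
            cy = rng.uniform(rmax + margin, h - rmax - margin)
            if all(np.hypot(cx - g["cx"], cy - g["cy"]) >
                   rmax + g["r0"] * (1 + cfg.boundary_wobble) + 8.0
                   for g in placed):
                placed.append({"cx": cx, "cy": cy, "r0": r0,
                               "phase": rng.uniform(0, 2 * np.pi),
                               "lobes": int(rng.integers(3, 7))})
                ok = True
                break
        if not ok:
            raise PlacementError(
                f"could not place {cfg.n_glands} non-overlapping glands in a "
                f"{w}x{h} image; use fewer or smaller glands")
    return placed


def _marker_matrix(cfg: SimCoreConfig, rng: np.random.Generator, n: int,
                   positive: set[str]) -> dict[str, np.ndarray]:
    """Linear-scale intensities for n cells; markers in ``positive`` draw
    from the foreground component, all others from background."""
    out = {}
    for m, model in cfg.markers.items():
        x = model.sample(rng, n, foreground=m in positive)
        out[m] = np.maximum(2.0 ** x - 1.0, 0.0)
    return out


def _qc_fields(rng: np.random.Generator, n: int, compartment: str) -> dict:
    """QC quantities drawn comfortably inside the retention bounds."""
    if compartment == "epithelial":
        return {
            "nucleus_count": rng.integers(1, 3, size=n),
            "nucleus_area": rng.uniform(40, 400, size=n),
            "membrane_area": rng.uniform(40, 400, size=n),
            "cytoplasm_area": rng.uniform(40, 800, size=n),
            "cell_area": rng.uniform(120, 1600, size=n),
            "quality_score": rng.uniform(0.90, 1.0, size=n),
            "qc_p63": np.ones(n, dtype=bool),
            "qc_CK5": np.ones(n, dtype=bool),
        }
    return {
        "nucleus_count": rng.integers(1, 2, size=n),
        "nucleus_area": rng.uniform(30, 200, size=n),
        "membrane_area": rng.uniform(30, 200, size=n),
        "cytoplasm_area": rng.uniform(30, 300, size=n),
        "cell_area": rng.uniform(60, 900, size=n),
        "quality_score": rng.uniform(0.90, 1.0, size=n),
        "qc_p63": np.ones(n, dtype=bool),
        "qc_CK5": np.ones(n, dtype=bool),
    }


def simulate_core(cfg: SimCoreConfig, *, core_id: str = "core0",
                  patient_id: str = "p0", grade_group: int | None = None
                  ) -> tuple[CellTable, GlandMask, SimTruth]:
    """Simulate one core: cell table (raw intensities), gland label mask,
    and ground truth. Fully reproducible from ``cfg.seed``.

    Each sub-step (geometry, each cell population, intensities) consumes a
    named child of one seed sequence, so enlarging one population does not
    perturb the coordinates drawn for another.
    """
    root = np.random.SeedSequence(cfg.seed)
    streams = {name: np.random.default_rng(s) for name, s in zip(
        ("geometry", "basal", "ce", "stroma", "immune", "qc"),
        root.spawn(6))}

    h, w = cfg.image_size
    mask = np.zeros((h, w), dtype=np.int32)
    glands = _place_glands(cfg, streams["geometry"]) if cfg.n_glands else []
    n_ce_glands = int(round(cfg.ce_fraction * len(glands)))
    # deterministic assignment: first n_ce_glands (placement order is random)
    gland_types = {i + 1: ("CE" if i < n_ce_glands else "N-CE")
                   for i in range(len(glands))}

    gland_polys: dict[int, Polygon] = {}
    rows_list: list[pd.DataFrame] = []
    truth_types: list[pd.Series] = []
    cell_counter = 0

    def _make_cells(xy: np.ndarray, compartment: str, positive: set[str],
                    true_type: str, rng_key: str) -> None:
        nonlocal cell_counter
        n = len(xy)
        if n == 0:
            return
        ids = [f"c{cell_counter + i:06d}" for i in range(n)]
        cell_counter += n
        cols = {"cell_id": ids, "x": xy[:, 0], "y": xy[:, 1],
                "compartment": compartment}
        cols.update(_qc_fields(streams["qc"], n, compartment))
        cols.update(_marker_matrix(cfg, streams[rng_key], n, positive))
        rows_list.append(pd.DataFrame(cols))
        truth_types.append(pd.Series(true_type, index=ids))

    for idx, g in enumerate(glands):
        gid = idx + 1
        boundary = _gland_boundary(g["cx"], g["cy"], g["r0"],
                                   cfg.boundary_wobble, g["phase"], g["lobes"])
        gland_polys[gid] = Polygon(boundary)
        rr, cc = draw_polygon(boundary[:, 1], boundary[:, 0], shape=(h, w))
        mask[rr, cc] = gid

        if gland_types[gid] == "N-CE":
            # basal rim: cells on the ring just inside the boundary
            circumference = 2 * np.pi * g["r0"]
            n_basal = max(int(circumference / cfg.basal_spacing_px), 8)
            theta = np.linspace(0, 2 * np.pi, n_basal, endpoint=False)
            theta = theta + streams["basal"].uniform(0, 2 * np.pi / n_basal)
            r = (g["r0"] * (1 + cfg.boundary_wobble * np.sin(g["lobes"] * theta + g["phase"]))
                 - cfg.rim_width / 2.0)
            jitter = streams["basal"].normal(0, cfg.rim_width / 4.0, size=(n_basal, 2))
            xy = np.column_stack([g["cx"] + r * np.cos(theta),
                                  g["cy"] + r * np.sin(theta)]) + jitter
            _make_cells(xy, "epithelial", set(BASAL_MARKERS), "N-CE", "basal")
        else:
            # CE gland: filled with basal-negative, AMACR-positive cells
            area = np.pi * g["r0"] ** 2
            n_ce = max(int(cfg.ce_cell_density * area), 12)
            rad = g["r0"] * 0.92 * np.sqrt(streams["ce"].uniform(0, 1, n_ce))
            ang = streams["ce"].uniform(0, 2 * np.pi, n_ce)
            xy = np.column_stack([g["cx"] + rad * np.cos(ang),
                                  g["cy"] + rad * np.sin(ang)])
            _make_cells(xy, "epithelial", {CANCER_MARKER}, "CE", "ce")

    # stromal cells: uniform over the image, rejected from gland interiors
    rng = streams["stroma"]
    target = cfg.n_stromal
    placed_xy = []
    while target > 0:
        cand = np.column_stack([rng.uniform(0, w - 1, 4 * target),
                                rng.uniform(0, h - 1, 4 * target)])
        cc = np.rint(cand).astype(int)
        free = mask[cc[:, 1], cc[:, 0]] == 0
        take = cand[free][:target]
        placed_xy.append(take)
        target -= len(take)
        if not free.any():
            break
    if placed_xy:
        _make_cells(np.vstack(placed_xy), "stromal", set(), "stroma", "stroma")

    # immune cells: placed at a configurable distance outside gland boundaries
    rng = streams["immune"]
    phen_pos = {"T_H": {"CD3", "CD4"},
                "T_reg": {"CD3", "CD4", "FOXP3"},
                "macrophage": {"CD68"}}
    def _near_gland_points(n: int) -> np.ndarray:
        """Points at the configured distance distribution outside a random
        gland boundary (uniform over the image when there are no glands)."""
        if not glands:
            return np.column_stack([rng.uniform(0, w - 1, n),
                                    rng.uniform(0, h - 1, n)])
        picks = rng.integers(0, len(glands), size=n)
        theta = rng.uniform(0, 2 * np.pi, n)
        gap = np.abs(rng.normal(cfg.immune_distance_mean_px,
                                cfg.immune_distance_sd_px, n))
        pts = []
        for k in range(n):
            g = glands[picks[k]]
            r_b = g["r0"] * (1 + cfg.boundary_wobble
                             * np.sin(g["lobes"] * theta[k] + g["phase"]))
            x = g["cx"] + (r_b + gap[k]) * np.cos(theta[k])
            y = g["cy"] + (r_b + gap[k]) * np.sin(theta[k])
            pts.append((np.clip(x, 0, w - 1), np.clip(y, 0, h - 1)))
        return np.asarray(pts)

    for phen, n_cells in cfg.immune_density.items():
        if n_cells == 0:
            continue
        if phen == "macrophage" and cfg.macrophage_clusters > 0:
            # dense clusters: centers follow the distance distribution, cells
            # scatter around them
            centers = _near_gland_points(cfg.macrophage_clusters)
            which = rng.integers(0, len(centers), size=n_cells)
            xy = centers[which] + rng.normal(
                0, cfg.macrophage_cluster_sd_px, size=(n_cells, 2))
            xy[:, 0] = np.clip(xy[:, 0], 0, w - 1)
            xy[:, 1] = np.clip(xy[:, 1], 0, h - 1)
        else:
            xy = _near_gland_points(n_cells)
        _make_cells(xy, "stromal", phen_pos[phen], phen, "immune")

    if rows_list:
        df = pd.concat(rows_list, ignore_index=True)
    else:
        df = pd.DataFrame(columns=["cell_id", "x", "y", "compartment"])
    truth = SimTruth(
        cell_types=pd.concat(truth_types) if truth_types else pd.Series(dtype=object),
        gland_types=gland_types, gland_polygons=gland_polys)
    table = CellTable(df=df, core_id=core_id, patient_id=patient_id,
                      grade_group=grade_group)
    return table, GlandMask(labels=mask, pixel_size_um=cfg.pixel_size_um), truth


# ---------------------------------------------------------------------------
# Cohort simulation with outcome
# ---------------------------------------------------------------------------

def simulate_cohort(n_patients: int, cores_per_patient: int = 1, *,
                    hazard_link: Callable[[float], float] | None = None,
                    baseline_hazard: float = 0.02,
                    censor_horizon_months: float = 60.0,
                    grade_proportions: tuple[float, float, float] = (0.4, 0.4, 0.2),
                    feature_range: tuple[float, float] = (20.0, 100.0),
                    core_config: SimCoreConfig | None = None,
                    seed: int = 0
                    ) -> tuple[list[tuple[CellTable, GlandMask]],
                               pd.DataFrame, list[SimTruth]]:
    """Simulate a patient cohort with recurrence outcomes.

    Each patient gets a latent spatial feature (the mean immune-to-gland
    placement distance, px) drawn uniformly over ``feature_range``;
    ``hazard_link`` maps that feature to a hazard multiplier (default:
    constant 1, i.e. no association). Recurrence times are exponential with
    rate baseline_hazard * multiplier (per month) and administratively
    censored at ``censor_horizon_months``. With ``cores_per_patient`` = 0 no
    imaging cores are generated (fast path for outcome-only studies).

    Returns ([(CellTable, GlandMask), ...] across all cores, the clinical
    table with one row per patient, [SimTruth, ...] matching the cores).
    """
    if n_patients < 2:
        raise ValueError("need at least 2 patients")
    if baseline_hazard <= 0:
        raise ValueError("baseline hazard must be positive")
    hazard_link = hazard_link or (lambda f: 1.0)
    root = np.random.SeedSequence(seed)
    rng = np.random.default_rng(root.spawn(1)[0])

    features = rng.uniform(*feature_range, size=n_patients)
    grades = rng.choice([1, 2, 3], size=n_patients, p=grade_proportions)
    mult = np.array([hazard_link(f) for f in features], dtype=float)
    if (mult <= 0).any():
        raise ValueError("hazard_link must return positive multipliers")
    times = rng.exponential(1.0 / (baseline_hazard * mult))
    event = times <= censor_horizon_months
    obs = np.minimum(times, censor_horizon_months)

    clinical = pd.DataFrame({
        "patient_id": [f"pt{i:04d}" for i in range(n_patients)],
        "grade_group": grades,
        "bcr_event": event,
        "bcr_time_months": obs,
        "true_feature": features,
    })

    cores: list[tuple[CellTable, GlandMask]] = []
    truths: list[SimTruth] = []
    if cores_per_patient > 0:
        base = core_config or SimCoreConfig()
        core_seeds = root.spawn(n_patients * cores_per_patient)
        k = 0
        for i in range(n_patients):
            for j in range(cores_per_patient):
                cfg = SimCoreConfig(
                    **{**base.__dict__,
                       "immune_distance_mean_px": float(features[i]),
                       "seed": int(core_seeds[k].generate_state(1)[0] % (2**31))})
                table, mask, truth = simulate_core(
                    cfg, core_id=f"pt{i:04d}_core{j}", patient_id=f"pt{i:04d}",
                    grade_group=int(grades[i]))
                cores.append((table, mask))
                truths.append(truth)
                k += 1
    return cores, clinical, truths
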