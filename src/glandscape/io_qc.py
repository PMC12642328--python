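"""Cell-table, gland-mask and clinical-table IO plus cell-level QC and normalization.

The cell table is the pipeline's spine: one row per segmented cell carrying
its ID, pixel coordinates, tissue compartment (epithelial/stromal), raw
per-marker intensities, and the segmentation/registration QC quantities used
to filter unreliable cells before classification.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import tifffile
import imageio.v3 as iio

# Canonical markers used by the classification and immune phenotyping stages.
BASAL_MARKERS = ("p63", "CK5")
IMMUNE_MARKERS = ("CD3", "CD4", "CD8", "CD68", "FOXP3")
CANCER_MARKER = "AMACR"
ALL_MARKERS = BASAL_MARKERS + (CANCER_MARKER,) + IMMUNE_MARKERS

#: physical pixel size: 6.5 um camera pixel imaged through a 20x objective.
DEFAULT_UM_PER_PX = 6.5 / 20.0

# Canonical (non-marker) columns of a cell table.
CORE_COLUMNS = [
    "cell_id", "x", "y", "compartment",
    "nucleus_count", "nucleus_area", "membrane_area", "cytoplasm_area",
    "cell_area", "quality_score",
]


class SchemaError(ValueError):
    """A mandatory column is missing or mis-mapped in an input file."""


class FormatError(ValueError):
    """An input image is not a single-channel integer label image."""


@dataclass
class CellTable:
    """Ordered collection of per-cell records for one tissue core.

    ``df`` holds one row per cell with the canonical columns plus one column
    per marker (raw or log2 intensity) and optional ``qc_<marker>`` boolean
    columns for marker-specific registration QC.
    """

    df: pd.DataFrame
    core_id: str = "core"
    patient_id: str = "patient"
    grade_group: int | None = None
    markers: tuple[str, ...] = ALL_MARKERS

    def __post_init__(self) -> None:
        if self.df["cell_id"].duplicated().any():
            raise ValueError(f"duplicate cell_id within core {self.core_id!r}")

    def __len__(self) -> int:
        return len(self.df)

    def copy(self) -> "CellTable":
        return replace(self, df=self.df.copy())

    @property
    def epithelial(self) -> pd.DataFrame:
        return self.df[self.df["compartment"] == "epithelial"]

    @property
    def stromal(self) -> pd.DataFrame:
        return self.df[self.df["compartment"] == "stromal"]


@dataclass
class GlandMask:
    """Integer label image: 0 = background, k > 0 = gland k."""

    labels: np.ndarray
    pixel_size_um: float = DEFAULT_UM_PER_PX

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if labels.ndim != 2:
            raise FormatError("gland mask must be a single-channel 2-D image")
        if not np.issubdtype(labels.dtype, np.integer):
            raise FormatError("gland mask must have an integer dtype")
        if labels.min() < 0:
            raise FormatError("gland mask labels must be nonnegative")
        self.labels = labels

    @property
    def gland_ids(self) -> np.ndarray:
        ids = np.unique(self.labels)
        return ids[ids > 0]

    def area_px(self, gland_id: int) -> int:
        return int(np.count_nonzero(self.labels == gland_id))


@dataclass
class QCConfig:
    """Cell-level quality-control thresholds.

    Epithelial cells must contain one clearly segmented nucleus but no more
    than two; each epithelial sub-compartment (nucleus, membrane, cytoplasm)
    must cover more than 10 but not more than 1500 pixels; whole-cell area is
    bounded per compartment; the cyclic-registration quality score (0 = no
    registration, 1 = perfect) must exceed 0.85; and epithelial cells failing
    registration QC for either basal marker are dropped before
    classification.
    """

    nucleus_count_bounds: tuple[int, int] = (1, 2)
    subcompartment_area_bounds: tuple[float, float] = (10.0, 1500.0)  # (lo, hi]
    epithelial_cell_area_bounds: tuple[float, float] = (50.0, 3500.0)  # [lo, hi]
    stromal_cell_area_bounds: tuple[float, float] = (30.0, 1500.0)  # [lo, hi]
    quality_score_min: float = 0.85  # strict >
    marker_qc_markers: tuple[str, ...] = BASAL_MARKERS

    def __post_init__(self) -> None:
        for lo, hi in (self.nucleus_count_bounds, self.subcompartment_area_bounds,
                       self.epithelial_cell_area_bounds, self.stromal_cell_area_bounds):
            if not lo < hi:
                raise ValueError("QC bounds must satisfy lower < upper")


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_cell_table(path, schema: dict[str, str] | None = None, *,
                    core_id: str = "core", patient_id: str = "patient",
                    grade_group: int | None = None,
                    markers: tuple[str, ...] = ALL_MARKERS) -> CellTable:
    """Read a per-cell CSV into a :class:`CellTable`.

    ``schema`` maps canonical field names (``cell_id``, ``x``, ``y``,
    marker names, ...) to the column names actually present in the file.
    Rows whose coordinates cannot be parsed as finite numbers are rejected
    with their row indices reported in a warning.
    """
    raw = pd.read_csv(path)
    schema = schema or {}
    rename = {v: k for k, v in schema.items() if v in raw.columns}
    raw = raw.rename(columns=rename)

    mandatory = ["cell_id", "x", "y", "compartment"]
    for col in mandatory + list(markers):
        if col not in raw.columns:
            raise SchemaError(f"cell table is missing mandatory column {col!r}")

    xy = raw[["x", "y"]].apply(pd.to_numeric, errors="coerce")
    bad = ~np.isfinite(xy).all(axis=1)
    if bad.any():
        warnings.warn(
            f"rejected {int(bad.sum())} rows with unparseable coordinates "
            f"(row indices {list(raw.index[bad])})")
        raw = raw[~bad].copy()
    raw[["x", "y"]] = xy[~bad]

    raw["cell_id"] = raw["cell_id"].astype(str)
    raw["compartment"] = raw["compartment"].astype(str)
    for col in CORE_COLUMNS:
        if col in raw.columns and col not in ("cell_id", "compartment"):
            raw[col] = pd.to_numeric(raw[col], errors="coerce")
    for m in markers:
        raw[m] = pd.to_numeric(raw[m], errors="coerce")

    keep = [c for c in CORE_COLUMNS if c in raw.columns]
    keep += list(markers)
    keep += [c for c in raw.columns if c.startswith("qc_") or c.startswith("call_")
             or c in ("cell_label", "gland_id", "true_type", "true_gland")]
    df = raw[keep].reset_index(drop=True)
    return CellTable(df=df, core_id=core_id, patient_id=patient_id,
                     grade_group=grade_group, markers=tuple(markers))


def write_cell_table(table: CellTable, path) -> None:
    """Write a cell table to CSV (repeatable byte-for-byte for a given table).

    Boolean columns are written as 0/1 so they survive the round trip.
    """
    df = table.df.copy()
    for col in df.columns:
        if df[col].dtype == bool:
            df[col] = df[col].astype(np.int8)
    df.to_csv(path, index=False, float_format="%.10g", lineterminator="\n")


def read_gland_mask(path, pixel_size_um: float = DEFAULT_UM_PER_PX) -> GlandMask:
    """Read a single-channel integer label image (TIFF or PNG)."""
    path = str(path)
    if path.lower().endswith((".tif", ".tiff")):
        arr = tifffile.imread(path)
    else:
        arr = iio.imread(path)
    arr = np.asarray(arr)
    if arr.ndim != 2:
        raise FormatError(f"expected single-channel label image, got shape {arr.shape}")
    if not np.issubdtype(arr.dtype, np.integer):
        raise FormatError(f"expected integer labels, got dtype {arr.dtype}")
    return GlandMask(labels=arr.astype(np.int32), pixel_size_um=pixel_size_um)


def write_gland_mask(mask: GlandMask, path) -> None:
    """Write a label image as 16-bit (or 32-bit when needed) TIFF/PNG."""
    labels = mask.labels
    dtype = np.uint16 if labels.max() <= np.iinfo(np.uint16).max else np.int32
    path = str(path)
    if path.lower().endswith((".tif", ".tiff")):
        tifffile.imwrite(path, labels.astype(dtype))
    else:
        iio.imwrite(path, labels.astype(dtype))


def read_clinical_table(path) -> pd.DataFrame:
    """Read the per-patient clinical CSV.

    Columns: ``patient_id``, ``grade_group``, ``bcr_event`` (biochemical
    recurrence flag), ``bcr_time_months`` (event or censoring time).
    """
    df = pd.read_csv(path)
    for col in ("patient_id", "grade_group", "bcr_event", "bcr_time_months"):
        if col not in df.columns:
            raise SchemaError(f"clinical table is missing column {col!r}")
    df["patient_id"] = df["patient_id"].astype(str)
    df["bcr_event"] = df["bcr_event"].astype(bool)
    if (df["bcr_time_months"] < 0).any():
        raise ValueError("follow-up times must be nonnegative")
    return df


def write_clinical_table(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out["bcr_event"] = out["bcr_event"].astype(int)
    out.to_csv(path, index=False, float_format="%.10g", lineterminator="\n")


# ---------------------------------------------------------------------------
# QC and normalization
# ---------------------------------------------------------------------------

@dataclass
class QCReport:
    """Per-rule removal counts; a cell failing several rules counts once per
    rule, and ``n_removed`` is the number of distinct removed cells."""

    removed_per_rule: dict[str, int] = field(default_factory=dict)
    n_input: int = 0
    n_removed: int = 0

    def to_frame(self) -> pd.DataFrame:
        rows = [{"rule": k, "removed": v} for k, v in self.removed_per_rule.items()]
        rows.append({"rule": "total_removed", "removed": self.n_removed})
        return pd.DataFrame(rows)


def apply_qc(table: CellTable, cfg: QCConfig | None = None) -> tuple[CellTable, QCReport]:
    """Apply cell-level QC; return the filtered table and per-rule counts.

    All rules are conjunctive: a retained cell satisfies every applicable
    rule. Marker-registration QC (``qc_<marker>`` columns, when present)
    applies to epithelial cells only, removing them before classification.
    """
    cfg = cfg or QCConfig()
    df = table.df
    epi = (df["compartment"] == "epithelial").to_numpy()
    fail = {}

    if "quality_score" in df.columns:
        fail["quality_score"] = ~(df["quality_score"].to_numpy() > cfg.quality_score_min)
    if "nucleus_count" in df.columns:
        lo, hi = cfg.nucleus_count_bounds
        nc = df["nucleus_count"].to_numpy()
        fail["nucleus_count"] = epi & ~((nc >= lo) & (nc <= hi))
    sub_lo, sub_hi = cfg.subcompartment_area_bounds
    for comp_col in ("nucleus_area", "membrane_area", "cytoplasm_area"):
        if comp_col in df.columns:
            a = df[comp_col].to_numpy()
            fail[f"subcompartment_area:{comp_col}"] = epi & ~((a > sub_lo) & (a <= sub_hi))
    if "cell_area" in df.columns:
        a = df["cell_area"].to_numpy()
        elo, ehi = cfg.epithelial_cell_area_bounds
        slo, shi = cfg.stromal_cell_area_bounds
        fail["cell_area"] = np.where(epi, ~((a >= elo) & (a <= ehi)),
                                     ~((a >= slo) & (a <= shi)))
    for m in cfg.marker_qc_markers:
        col = f"qc_{m}"
        if col in df.columns:
            fail[f"marker_qc:{m}"] = epi & ~df[col].astype(bool).to_numpy()

    any_fail = np.zeros(len(df), dtype=bool)
    report = QCReport(n_input=len(df))
    for rule, mask in fail.items():
        report.removed_per_rule[rule] = int(mask.sum())
        any_fail |= mask
    report.n_removed = int(any_fail.sum())

    out = replace(table, df=df[~any_fail].reset_index(drop=True))
    if len(out) == 0:
        warnings.warn(f"QC removed every cell of core {table.core_id!r}")
    return out, report


def normalize_log2(table: CellTable, pseudocount: float = 1.0, *,
                   median_center: bool = True,
                   cap_quantile: float | None = None) -> CellTable:
    """log2-transform marker intensities, then per-core median-center.

    Each raw intensity v becomes ``log2(v + pseudocount)``; the log2
    transform tames the right-skew of raw fluorescence. Median-centering
    per core and marker (subtracting the core's marker median) is a minimal
    batch correction; both steps are monotone, so within-core intensity
    ranks are preserved (capping only introduces ties at the cap). Set
    ``median_center=False`` to disable the centering step.

    ``cap_quantile`` (e.g. 0.999), when given, winsorizes each marker at
    that per-core quantile before the transform — an automated stand-in for
    manual review of artifactual intensity outliers; off by default.
    """
    df = table.df.copy()
    for m in table.markers:
        v = df[m].to_numpy(dtype=float)
        if np.nanmin(v) < 0:
            bad = df["cell_id"][v < 0].iloc[0]
            raise ValueError(
                f"negative intensity for marker {m!r} at cell {bad!r}; "
                "intensities must be nonnegative before log transform")
        if cap_quantile is not None:
            v = np.minimum(v, np.nanquantile(v, cap_quantile))
        logged = np.log2(v + pseudocount)
        if median_center:
            logged = logged - np.nanmedian(logged)
        df[m] = logged
    return replace(table, df=df)
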