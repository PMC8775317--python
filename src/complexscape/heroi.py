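"""Per-ROI, per-band complexity extraction and reporting.

Given a multiband integer raster and a polygon layer of regions of interest
(ROIs), this module selects the pixels of each band that overlap each ROI,
computes descriptive statistics (count, min, max, mean, population standard
deviation) and the full set of entropy/complexity metrics, and assembles one
results row per (ROI, band) pair — the tabular product a landscape analyst
exports to CSV and turns into cross-band "complexity signatures".

Two pixel-selection rules are offered. ``"center"`` (default) keeps a pixel
when its center lies inside the polygon (centers exactly on the boundary are
included); ``"all_touched"`` keeps any pixel whose square cell intersects the
polygon. The center rule is the usual rasterization convention and avoids
double counting along shared boundaries.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import box, mapping, shape
from shapely.geometry.base import BaseGeometry
from shapely.validation import make_valid

from .entropy_core import NoValidPixelsError, build_histogram, compute_all
from .raster import MultibandRaster

__all__ = [
    "ROILayer",
    "BandStats",
    "EmptyROIError",
    "CRSMismatchError",
    "RESULT_COLUMNS",
    "read_roi_layer",
    "write_roi_layer",
    "extract_roi_pixels",
    "describe",
    "analyze_rois",
    "write_results_csv",
    "read_results_csv",
    "complexity_signature",
    "write_signature_csv",
]

#: Column order of the results table; fixed so CSVs are directly comparable.
RESULT_COLUMNS = [
    "roi_id", "band", "count", "min", "max", "mean", "sd",
    "N", "Hmax", "He", "He_Hmax", "D", "SDL", "LMC",
]

_METRIC_FIELD = {
    "He": "h_e",
    "He_Hmax": "variability",
    "SDL": "sdl",
    "LMC": "lmc",
}


class EmptyROIError(ValueError):
    """A polygon selects no valid (non-nodata) pixels."""


class CRSMismatchError(ValueError):
    """Raster and ROI layer declare different coordinate reference systems."""


@dataclass
class ROILayer:
    """Polygon features with unique identifiers drawn from ``id_field``."""

    features: List[Tuple[object, BaseGeometry]]
    id_field: str = "id"
    crs_epsg: Optional[int] = None

    def __post_init__(self) -> None:
        ids = [fid for fid, _ in self.features]
        if len(ids) != len(set(ids)):
            raise ValueError("ROI identifiers must be unique")
        repaired = []
        for fid, geom in self.features:
            if geom.is_empty:
                raise ValueError(f"ROI {fid!r} has an empty geometry")
            if not geom.is_valid:
                geom = make_valid(geom)
            repaired.append((fid, geom))
        self.features = repaired


@dataclass(frozen=True)
class BandStats:
    """Descriptive statistics of one ROI's pixel values in one band."""

    count: int
    min: float
    max: float
    mean: float
    sd: float  # population standard deviation (divide by n)


def read_roi_layer(path, id_field: str) -> ROILayer:
    """Load a polygon GeoJSON FeatureCollection as an ROI layer.

    ``id_field`` names the feature property used as the ROI identifier; a
    missing property raises a KeyError naming the field.
    """
    with open(path) as fh:
        gj = json.load(fh)
    feats = []
    for feat in gj.get("features", []):
        props = feat.get("properties") or {}
        if id_field not in props:
            raise KeyError(
                f"id field {id_field!r} missing from feature properties "
                f"(available: {sorted(props)})"
            )
        feats.append((props[id_field], shape(feat["geometry"])))
    epsg = None
    crs = gj.get("crs")
    if isinstance(crs, dict):
        name = str(crs.get("properties", {}).get("name", ""))
        if "EPSG" in name.upper():
            epsg = int(name.upper().split("EPSG")[-1].strip(":/ "))
    return ROILayer(features=feats, id_field=id_field, crs_epsg=epsg)


def write_roi_layer(layer: ROILayer, path) -> None:
    """Write an ROI layer as GeoJSON (EPSG recorded in a ``crs`` member)."""
    gj = {
        "type": "FeatureCollection",
        "features": [
            {
                "type": "Feature",
                "properties": {layer.id_field: fid},
                "geometry": mapping(geom),
            }
            for fid, geom in layer.features
        ],
    }
    if layer.crs_epsg is not None:
        gj["crs"] = {
            "type": "name",
            "properties": {"name": f"urn:ogc:def:crs:EPSG::{layer.crs_epsg}"},
        }
    with open(path, "w") as fh:
        json.dump(gj, fh)


def _candidate_window(raster: MultibandRaster, polygon: BaseGeometry):
    """Row/col ranges of pixels whose cells could intersect the polygon."""
    h, w = raster.shape
    t = raster.transform
    xmin, ymin, xmax, ymax = polygon.bounds
    rows = sorted(t.rowcol(0.0, np.array([ymin, ymax]))[0])
    cols = sorted(t.rowcol(np.array([xmin, xmax]), 0.0)[1])
    r0 = max(int(np.floor(rows[0])), 0)
    r1 = min(int(np.ceil(rows[1])), h)
    c0 = max(int(np.floor(cols[0])), 0)
    c1 = min(int(np.ceil(cols[1])), w)
    return r0, r1, c0, c1


def roi_pixel_mask(
    raster: MultibandRaster, polygon: BaseGeometry, overlap_rule: str = "center"
) -> np.ndarray:
    """Boolean mask (rows, cols) of pixels selected by the overlap rule."""
    if overlap_rule not in ("center", "all_touched"):
        raise ValueError(f"unknown overlap rule: {overlap_rule!r}")
    h, w = raster.shape
    mask = np.zeros((h, w), dtype=bool)
    r0, r1, c0, c1 = _candidate_window(raster, polygon)
    if r0 >= r1 or c0 >= c1:
        return mask
    rows, cols = np.meshgrid(np.arange(r0, r1), np.arange(c0, c1), indexing="ij")
    t = raster.transform
    if overlap_rule == "center":
        xs, ys = t.xy(rows.ravel(), cols.ravel(), center=True)
        sel = shapely.intersects_xy(polygon, xs, ys)
    else:
        x_lo, y_lo = t.xy(rows.ravel(), cols.ravel(), center=False)
        x_hi, y_hi = t.xy(rows.ravel() + 1, cols.ravel() + 1, center=False)
        cells = shapely.box(
            np.minimum(x_lo, x_hi), np.minimum(y_lo, y_hi),
            np.maximum(x_lo, x_hi), np.maximum(y_lo, y_hi),
        )
        sel = shapely.intersects(cells, polygon)
    mask[rows.ravel()[sel], cols.ravel()[sel]] = True
    return mask


def extract_roi_pixels(
    raster: MultibandRaster,
    band_index: int,
    polygon: BaseGeometry,
    overlap_rule: str = "center",
) -> np.ndarray:
    """DN multiset of the selected, non-nodata pixels of one band.

    Raises :class:`EmptyROIError` if the polygon selects no valid pixel.
    """
    mask = roi_pixel_mask(raster, polygon, overlap_rule)
    values = raster.band(band_index)[mask]
    if raster.nodata is not None:
        values = values[values != raster.nodata]
    if values.size == 0:
        raise EmptyROIError("polygon selects no valid pixels")
    return values


def describe(values: Sequence[int] | np.ndarray) -> BandStats:
    """Count, min, max, mean and population standard deviation."""
    arr = np.asarray(values, dtype=np.float64).ravel()
    if arr.size == 0:
        raise EmptyROIError("cannot describe an empty pixel set")
    return BandStats(
        count=int(arr.size),
        min=float(arr.min()),
        max=float(arr.max()),
        mean=float(arr.mean()),
        sd=float(arr.std(ddof=0)),
    )


def analyze_rois(
    raster: MultibandRaster,
    rois: ROILayer,
    overlap_rule: str = "center",
    hmax_mode: str = "log2",
) -> pd.DataFrame:
    """Compute stats + complexity metrics for every (band, ROI) pair.

    Rows are ordered band-major then by feature order. ROIs that select no
    valid pixels produce a flagged row (count 0, NaN statistics and metrics)
    rather than aborting the run.
    """
    if raster.n_bands < 1 or not rois.features:
        raise ValueError("need at least one band and one ROI feature")
    if (
        raster.crs_epsg is not None
        and rois.crs_epsg is not None
        and raster.crs_epsg != rois.crs_epsg
    ):
        raise CRSMismatchError(
            f"raster EPSG:{raster.crs_epsg} != ROI layer EPSG:{rois.crs_epsg}"
        )
    masks = {
        fid: roi_pixel_mask(raster, geom, overlap_rule) for fid, geom in rois.features
    }
    rows = []
    for b, label in enumerate(raster.band_labels):
        band = raster.band(b)
        for fid, _ in rois.features:
            values = band[masks[fid]]
            if raster.nodata is not None:
                values = values[values != raster.nodata]
            if values.size == 0:
                rows.append([fid, label, 0] + [np.nan] * (len(RESULT_COLUMNS) - 3))
                continue
            st = describe(values)
            m = compute_all(build_histogram(values), hmax_mode=hmax_mode)
            rows.append(
                [
                    fid, label, st.count, st.min, st.max, st.mean, st.sd,
                    m.n_states, m.h_max, m.h_e, m.variability,
                    m.disequilibrium, m.sdl, m.lmc,
                ]
            )
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def write_results_csv(table: pd.DataFrame, path) -> None:
    """Write the results table to CSV with full float precision."""
    if table.empty:
        raise ValueError("results table is empty")
    table.to_csv(path, index=False, float_format="%.12g")


def read_results_csv(path) -> pd.DataFrame:
    """Read a results CSV back, preserving band labels as strings."""
    return pd.read_csv(path, dtype={"band": str, "roi_id": str})


def complexity_signature(
    table: pd.DataFrame, roi_id, metric_name: str
) -> pd.Series:
    """One metric's values across bands for one ROI, in band order.

    This is the cross-band "complexity signature" of a region: bands on the
    x axis, the selected measure on the y axis.
    """
    if metric_name not in _METRIC_FIELD:
        raise KeyError(
            f"unknown metric {metric_name!r}; choose from {sorted(_METRIC_FIELD)}"
        )
    sub = table[table["roi_id"].astype(str) == str(roi_id)]
    if sub.empty:
        raise KeyError(f"roi_id {roi_id!r} not present in results table")
    series = pd.Series(
        sub[metric_name].to_numpy(), index=sub["band"].astype(str).to_numpy(),
        name=metric_name,
    )
    series.index.name = "band"
    return series


def write_signature_csv(table: pd.DataFrame, roi_id, metric_name: str, path) -> None:
    """Persist one signature as ``roi_id,metric,band,value`` rows."""
    sig = complexity_signature(table, roi_id, metric_name)
    out = pd.DataFrame(
        {
            "roi_id": [roi_id] * len(sig),
            "metric": [metric_name] * len(sig),
            "band": sig.index,
            "value": sig.to_numpy(),
        }
    )
    out.to_csv(path, index=False, float_format="%.12g")
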