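"""Moving-window complexity mapping.

A k x k kernel (k odd) slides over a single integer band; for each position
the chosen entropy/complexity measure of the window's DN histogram is written
to the central pixel of an output float raster — a *complexity map*. Patch
interiors (locally homogeneous or locally equiprobable neighborhoods) map to
zero under the convex measures, while patch boundaries and transition zones
light up as a positive band roughly k-1 pixels wide, so the maps delineate
the limits between landscape units.

Border policy: no padding. The margin of width (k-1)/2, where the full window
does not fit inside the grid, is marked invalid — padding would fabricate DN
values and bias the system extension. Nodata pixels inside a window are
dropped from its histogram; a window is valid as long as one valid pixel
remains (a single valid pixel gives N = 1 and metric 0, consistent with the
single-state convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .entropy_core import (
    METRIC_NAMES,
    disequilibrium_of_distribution,
    entropy_of_distribution,
    lmc,
    max_entropy,
    sdl,
    variability,
)
from .raster import GridTransform, MultibandRaster, read_geotiff, write_geotiff

__all__ = [
    "WindowSpec",
    "ComplexityMap",
    "NODATA_SENTINEL",
    "map_window_metric",
    "map_all",
    "write_map",
    "read_map",
]

NODATA_SENTINEL = -9999.0


@dataclass(frozen=True)
class WindowSpec:
    """Kernel size (odd, >= 3) and the metric to map."""

    size: int
    metric: str

    def __post_init__(self) -> None:
        if self.size < 3 or self.size % 2 == 0:
            raise ValueError(f"window size must be an odd integer >= 3, got {self.size}")
        if self.metric not in METRIC_NAMES:
            raise ValueError(
                f"metric must be one of {METRIC_NAMES}, got {self.metric!r}"
            )


@dataclass
class ComplexityMap:
    """Single-band float complexity map with validity mask and provenance."""

    grid: np.ndarray  # float32, NODATA_SENTINEL where invalid
    valid_mask: np.ndarray  # bool
    transform: GridTransform
    crs_epsg: Optional[int] = None
    metric: str = "SDL"
    window: int = 3
    band_label: str = "1"
    nodata: float = field(default=NODATA_SENTINEL)


def _window_metric_value(values: np.ndarray, metric: str, hmax_mode: str) -> float:
    """Metric of one window's DN multiset (values already nodata-free)."""
    _, counts = np.unique(values, return_counts=True)
    p = counts / counts.sum()
    h_e = entropy_of_distribution(p)
    h_max = max_entropy(len(counts), hmax_mode)
    v = variability(min(h_e, h_max), h_max)
    if metric == "He":
        return h_e
    if metric == "He_Hmax":
        return v
    if metric == "SDL":
        return sdl(v)
    return lmc(v, disequilibrium_of_distribution(p))


def map_window_metric(
    band: np.ndarray,
    spec: WindowSpec,
    nodata: Optional[int] = None,
    transform: Optional[GridTransform] = None,
    crs_epsg: Optional[int] = None,
    band_label: str = "1",
    hmax_mode: str = "log2",
) -> ComplexityMap:
    """Slide the window over one band and map the chosen metric.

    Every pixel whose full k x k neighborhood lies inside the grid receives
    the metric of the histogram of its non-nodata neighborhood values; the
    (k-1)/2 border margin and all-nodata neighborhoods are invalid.
    """
    arr = np.asarray(band)
    if arr.ndim != 2:
        raise ValueError("band must be a 2-D grid")
    k = spec.size
    h, w = arr.shape
    if h < k or w < k:
        raise ValueError(f"grid {arr.shape} smaller than {k}x{k} window")
    half = k // 2
    grid = np.full((h, w), NODATA_SENTINEL, dtype=np.float32)
    valid = np.zeros((h, w), dtype=bool)
    windows = sliding_window_view(arr, (k, k))
    for i in range(windows.shape[0]):
        for j in range(windows.shape[1]):
            values = windows[i, j].ravel()
            if nodata is not None:
                values = values[values != nodata]
                if values.size == 0:
                    continue
            grid[i + half, j + half] = _window_metric_value(
                values, spec.metric, hmax_mode
            )
            valid[i + half, j + half] = True
    if transform is None:
        transform = GridTransform(0.0, 0.0, 1.0, -1.0)
    return ComplexityMap(
        grid=grid,
        valid_mask=valid,
        transform=transform,
        crs_epsg=crs_epsg,
        metric=spec.metric,
        window=k,
        band_label=band_label,
    )


def map_all(
    raster: MultibandRaster,
    spec: WindowSpec,
    band_selection: Optional[Sequence[int]] = None,
    hmax_mode: str = "log2",
):
    """One independent complexity map per selected band (0-based indices)."""
    indices = list(range(raster.n_bands)) if band_selection is None else list(band_selection)
    if not indices:
        raise ValueError("band selection is empty")
    for b in indices:
        if not 0 <= b < raster.n_bands:
            raise IndexError(f"band index {b} out of range (0..{raster.n_bands - 1})")
    return [
        map_window_metric(
            raster.band(b),
            spec,
            nodata=raster.nodata,
            transform=raster.transform,
            crs_epsg=raster.crs_epsg,
            band_label=raster.band_labels[b],
            hmax_mode=hmax_mode,
        )
        for b in indices
    ]


def write_map(cmap: ComplexityMap, path) -> None:
    """Persist a complexity map as a single-band float32 GeoTIFF.

    The nodata sentinel, metric name, window size and source band label are
    recorded in the file so maps are self-describing.
    """
    write_geotiff(
        path,
        cmap.grid.astype(np.float32),
        cmap.transform,
        crs_epsg=cmap.crs_epsg,
        nodata=cmap.nodata,
        metadata={
            "metric": cmap.metric,
            "window": cmap.window,
            "band_label": cmap.band_label,
        },
    )


def read_map(path) -> ComplexityMap:
    """Read back a complexity map written by :func:`write_map`."""
    arr, transform, epsg, nodata, desc = read_geotiff(path)
    grid = arr[0].astype(np.float32)
    nod = float(nodata) if nodata is not None else NODATA_SENTINEL
    return ComplexityMap(
        grid=grid,
        valid_mask=grid != nod,
        transform=transform,
        crs_epsg=epsg,
        metric=desc.get("metric", "SDL"),
        window=int(desc.get("window", 3)),
        band_label=str(desc.get("band_label", "1")),
        nodata=nod,
    )
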