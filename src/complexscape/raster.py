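"""Georeferenced raster container and GeoTIFF input/output.

Rasters are held as a ``(bands, rows, cols)`` integer array plus a north-up
affine transform (no rotation/shear terms), an optional EPSG code, an optional
integer nodata value, and per-band labels. Files are read and written through
:mod:`tifffile`, emitting the GeoTIFF georeferencing tags directly
(ModelPixelScale, ModelTiepoint, a minimal GeoKey directory for the EPSG code,
and the GDAL-style ASCII nodata tag), which keeps outputs loadable by GDAL,
QGIS and rasterio.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import tifffile

__all__ = ["GridTransform", "MultibandRaster", "read_geotiff", "write_geotiff"]

# GeoTIFF / GDAL tag codes
_TAG_PIXELSCALE = 33550
_TAG_TIEPOINT = 33922
_TAG_GEOKEYS = 34735
_TAG_GDAL_METADATA = 42112
_TAG_GDAL_NODATA = 42113


@dataclass(frozen=True)
class GridTransform:
    """North-up affine transform: map coordinates of the raster grid.

    ``(x0, y0)`` is the outer corner of the top-left pixel; ``dx > 0`` and
    ``dy < 0`` are the pixel sizes along columns and rows.
    """

    x0: float
    y0: float
    dx: float
    dy: float

    def xy(self, row, col, center: bool = True):
        """Map coordinates of a pixel (center by default; corner otherwise)."""
        off = 0.5 if center else 0.0
        return (
            self.x0 + (np.asarray(col) + off) * self.dx,
            self.y0 + (np.asarray(row) + off) * self.dy,
        )

    def rowcol(self, x, y):
        """Fractional (row, col) grid indices of map coordinates."""
        return (np.asarray(y) - self.y0) / self.dy, (np.asarray(x) - self.x0) / self.dx

    def bounds(self, height: int, width: int):
        """(xmin, ymin, xmax, ymax) of the full grid in map coordinates."""
        xs = sorted((self.x0, self.x0 + width * self.dx))
        ys = sorted((self.y0, self.y0 + height * self.dy))
        return xs[0], ys[0], xs[1], ys[1]

    def shifted(self, drow: int, dcol: int) -> "GridTransform":
        """Transform for the same grid translated by whole pixels."""
        return replace(self, x0=self.x0 + dcol * self.dx, y0=self.y0 + drow * self.dy)


@dataclass
class MultibandRaster:
    """Stack of integer bands sharing dimensions and georeferencing."""

    bands: np.ndarray  # (k, rows, cols), integer dtype
    transform: GridTransform
    crs_epsg: Optional[int] = None
    nodata: Optional[int] = None
    band_labels: Sequence[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.bands = np.asarray(self.bands)
        if self.bands.ndim == 2:
            self.bands = self.bands[None, ...]
        if self.bands.ndim != 3:
            raise ValueError("bands must be a (k, rows, cols) array")
        if not np.issubdtype(self.bands.dtype, np.integer):
            raise ValueError("raster pixels must be integer-valued DNs")
        if not self.band_labels:
            self.band_labels = [str(i + 1) for i in range(self.bands.shape[0])]
        if len(self.band_labels) != self.bands.shape[0]:
            raise ValueError("one label per band required")

    @property
    def n_bands(self) -> int:
        return self.bands.shape[0]

    @property
    def shape(self):
        return self.bands.shape[1:]

    def band(self, index: int) -> np.ndarray:
        return self.bands[index]


def _geo_extratags(transform: GridTransform, crs_epsg, nodata, metadata):
    tags = [
        (_TAG_PIXELSCALE, "d", 3, (abs(transform.dx), abs(transform.dy), 0.0)),
        (_TAG_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, transform.x0, transform.y0, 0.0)),
    ]
    # Minimal GeoKey directory: model type projected + the EPSG code.
    keys = [(1024, 0, 1, 1), (1025, 0, 1, 1)]
    if crs_epsg is not None:
        keys.append((3072, 0, 1, int(crs_epsg)))
    directory = (1, 1, 0, len(keys)) + tuple(v for k in keys for v in k)
    tags.append((_TAG_GEOKEYS, "H", len(directory), directory))
    if nodata is not None:
        s = str(nodata) + "\x00"
        tags.append((_TAG_GDAL_NODATA, "s", len(s), s))
    if metadata:
        xml = "<GDALMetadata>\n"
        for k, v in metadata.items():
            xml += f'  <Item name="{k}">{v}</Item>\n'
        xml += "</GDALMetadata>\x00"
        tags.append((_TAG_GDAL_METADATA, "s", len(xml), xml))
    return tags


def write_geotiff(
    path,
    data: np.ndarray,
    transform: GridTransform,
    crs_epsg: Optional[int] = None,
    nodata=None,
    band_labels: Optional[Sequence[str]] = None,
    metadata: Optional[dict] = None,
) -> None:
    """Write a (k, rows, cols) or (rows, cols) array as a tagged GeoTIFF.

    Band labels and any extra provenance go into the image description as
    JSON; georeferencing and nodata go into standard GeoTIFF/GDAL tags.
    """
    arr = np.asarray(data)
    if arr.ndim == 2:
        arr = arr[None, ...]
    desc = dict(metadata or {})
    if band_labels is not None:
        desc["band_labels"] = list(band_labels)
    tifffile.imwrite(
        str(path),
        arr,
        photometric="minisblack",
        metadata=None,
        description=json.dumps(desc),
        extratags=_geo_extratags(transform, crs_epsg, nodata, None),
    )


def _parse_geotags(page):
    tags = page.tags
    transform = None
    if _TAG_PIXELSCALE in tags and _TAG_TIEPOINT in tags:
        sx, sy, _ = tags[_TAG_PIXELSCALE].value[:3]
        i, j, _, x, y, _ = tags[_TAG_TIEPOINT].value[:6]
        transform = GridTransform(x0=x - j * sx, y0=y + i * sy, dx=sx, dy=-sy)
    epsg = None
    if _TAG_GEOKEYS in tags:
        d = tags[_TAG_GEOKEYS].value
        nkeys = d[3]
        for k in range(nkeys):
            key_id, loc, _cnt, val = d[4 + 4 * k : 8 + 4 * k]
            if key_id == 3072 and loc == 0:
                epsg = int(val)
    nodata = None
    if _TAG_GDAL_NODATA in tags:
        raw = tags[_TAG_GDAL_NODATA].value.strip("\x00 ")
        nodata = float(raw)
        if nodata == int(nodata):
            nodata = int(nodata)
    return transform, epsg, nodata


def read_geotiff(path):
    """Read a GeoTIFF written by :func:`write_geotiff` (or a compatible one).

    Returns ``(array, transform, crs_epsg, nodata, description_dict)`` with
    the array shaped ``(bands, rows, cols)``.
    """
    with tifffile.TiffFile(str(path)) as tf:
        arr = tf.asarray()
        page = tf.pages[0]
        transform, epsg, nodata = _parse_geotags(page)
        desc = {}
        if page.description:
            try:
                desc = json.loads(page.description)
            except (json.JSONDecodeError, TypeError):
                desc = {}
    if arr.ndim == 2:
        arr = arr[None, ...]
    if transform is None:
        transform = GridTransform(0.0, 0.0, 1.0, -1.0)
    return arr, transform, epsg, nodata, desc


def read_multiband(path) -> MultibandRaster:
    """Read a multiband integer GeoTIFF into a :class:`MultibandRaster`."""
    arr, transform, epsg, nodata, desc = read_geotiff(path)
    labels = desc.get("band_labels") or [str(i + 1) for i in range(arr.shape[0])]
    if nodata is not None:
        nodata = int(nodata)
    return MultibandRaster(
        bands=arr, transform=transform, crs_epsg=epsg, nodata=nodata, band_labels=labels
    )


def write_multiband(path, raster: MultibandRaster, metadata: Optional[dict] = None) -> None:
    """Write a :class:`MultibandRaster` to GeoTIFF."""
    write_geotiff(
        path,
        raster.bands,
        raster.transform,
        crs_epsg=raster.crs_epsg,
        nodata=raster.nodata,
        band_labels=raster.band_labels,
        metadata=metadata,
    )


__all__ += ["read_multiband", "write_multiband"]
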