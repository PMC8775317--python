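"""Deterministic synthetic scenes with analytically known complexity regimes.

Real complexity studies run on multispectral satellite scenes with hand-drawn
land-use polygons. This module generates small stand-in rasters whose patches
sit at known points of the order-disorder gradient, so every other module can
be exercised end to end with closed-form expectations:

* **constant patches** — one DN everywhere: the perfectly ordered extreme
  (N = 1, all metrics 0);
* **equiprobable patches** — n distinct DNs, each occurring exactly
  pixel_count / n times, spatially shuffled: the perfectly disordered extreme
  (He/Hmax = 1, D = 0, SDL = LMC = 0);
* **mixture strips** — exact target proportions of a few DNs, emulating the
  transition areas where land uses mix and convex complexity peaks.

Patches are exact-count shuffled multisets, not i.i.d. draws, so expected
metrics follow in closed form from the stated proportions rather than being
stochastic. All shuffling uses numpy's PCG64 generator seeded explicitly;
the same seed reproduces a scene bit-exactly. DNs stay within 0-255 to mimic
8-bit sensor quantization.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from shapely.geometry import box

from .entropy_core import build_histogram, compute_all
from .heroi import RESULT_COLUMNS, ROILayer, write_results_csv, write_roi_layer
from .raster import GridTransform, MultibandRaster, write_multiband

__all__ = [
    "SyntheticScene",
    "make_constant_patch",
    "make_equiprobable_patch",
    "make_mixture_strip",
    "build_scene",
    "canonical_layout",
    "write_scene",
]

_DEFAULT_TRANSFORM = GridTransform(x0=500000.0, y0=7500000.0, dx=20.0, dy=-20.0)
_DEFAULT_EPSG = 32723  # a southern-hemisphere UTM zone; any projected CRS works


@dataclass
class SyntheticScene:
    """Generated raster + ROI polygons + per-(ROI, band) expected metrics."""

    raster: MultibandRaster
    rois: ROILayer
    truth: pd.DataFrame  # same schema as the heroi results table
    seed: int


def make_constant_patch(shape: Tuple[int, int], value: int) -> np.ndarray:
    """A patch holding a single DN everywhere — the ordered extreme."""
    if shape[0] < 1 or shape[1] < 1:
        raise ValueError("patch shape must be positive")
    return np.full(shape, value, dtype=np.uint8)


def make_equiprobable_patch(
    shape: Tuple[int, int], n_values: int, seed: int, dn_start: int = 0
) -> np.ndarray:
    """A patch where ``n_values`` DNs each occur equally often, shuffled.

    The pixel count must be divisible by ``n_values`` so equiprobability is
    exact, which pins He/Hmax at exactly 1 and D at exactly 0.
    """
    npix = shape[0] * shape[1]
    if npix % n_values:
        raise ValueError(
            f"pixel count {npix} not divisible by n_values={n_values}"
        )
    if dn_start + n_values > 256:
        raise ValueError("DN alphabet must stay within 0-255")
    values = np.repeat(np.arange(dn_start, dn_start + n_values, dtype=np.uint8),
                       npix // n_values)
    rng = np.random.default_rng(seed)
    return rng.permutation(values).reshape(shape)


def make_mixture_strip(
    shape: Tuple[int, int], dn_proportions: Mapping[int, float], seed: int
) -> np.ndarray:
    """A patch with exact DN proportions, shuffled — a transition regime.

    Proportions must sum to 1 and each must allocate a whole number of
    pixels, so the expected metrics are exactly the closed-form values of
    the stated distribution.
    """
    npix = shape[0] * shape[1]
    props = dict(dn_proportions)
    if abs(sum(props.values()) - 1.0) > 1e-12:
        raise ValueError("proportions must sum to 1")
    counts: Dict[int, int] = {}
    for dn, p in props.items():
        c = p * npix
        if abs(c - round(c)) > 1e-9:
            raise ValueError(
                f"proportion {p} of {npix} pixels is not a whole count"
            )
        counts[dn] = int(round(c))
    values = np.concatenate(
        [np.full(c, dn, dtype=np.uint8) for dn, c in counts.items()]
    )
    rng = np.random.default_rng(seed)
    return rng.permutation(values).reshape(shape)


def canonical_layout(patch_shape: Tuple[int, int] = (20, 20)):
    """The default three-regime, four-band layout.

    Three side-by-side patches — ordered / disordered / transition — with
    per-band parameters that vary so each ROI acquires a band-dependent
    complexity signature. The transition strip runs from a strongly skewed
    90/10 two-DN mix in the first band to an even 50/50 mix in the last, so
    its SDL rises toward 0.25 and its LMC falls toward 0 across bands.
    """
    return {
        "patch_shape": patch_shape,
        "patches": [
            {"roi_id": "ordered", "kind": "constant",
             "value": [40, 45, 50, 55]},
            {"roi_id": "disordered", "kind": "equiprobable",
             "n_values": [4, 8, 16, 20], "dn_start": [100, 100, 100, 100]},
            {"roi_id": "transition", "kind": "mixture",
             "proportions": [
                 {200: 0.9, 210: 0.1},
                 {200: 0.75, 210: 0.25},
                 {200: 0.6, 210: 0.4},
                 {200: 0.5, 210: 0.5},
             ]},
        ],
    }


def build_scene(
    layout: Optional[dict] = None,
    n_bands: int = 4,
    seed: int = 0,
    transform: GridTransform = _DEFAULT_TRANSFORM,
    crs_epsg: int = _DEFAULT_EPSG,
) -> SyntheticScene:
    """Assemble a multiband raster, matching ROI polygons, and a truth table.

    Patches are placed left to right on a single row; each ROI polygon is the
    exact map-coordinate footprint of its patch, so center-rule extraction
    recovers precisely the generated pixel multiset. The truth table holds
    the metrics recomputed from each patch's pixels at generation time.
    """
    layout = layout or canonical_layout()
    ph, pw = layout["patch_shape"]
    patches = layout["patches"]
    height, width = ph, pw * len(patches)
    bands = np.zeros((n_bands, height, width), dtype=np.uint8)
    features = []
    rows = []
    for pi, patch in enumerate(patches):
        c0 = pi * pw
        for b in range(n_bands):
            sub_seed = (seed * 1009 + pi * 101 + b) % (2**31)
            kind = patch["kind"]
            if kind == "constant":
                grid = make_constant_patch((ph, pw), _per_band(patch["value"], b))
            elif kind == "equiprobable":
                grid = make_equiprobable_patch(
                    (ph, pw),
                    _per_band(patch["n_values"], b),
                    seed=sub_seed,
                    dn_start=_per_band(patch["dn_start"], b),
                )
            elif kind == "mixture":
                grid = make_mixture_strip(
                    (ph, pw), _per_band(patch["proportions"], b), seed=sub_seed
                )
            else:
                raise ValueError(f"unknown patch kind {kind!r}")
            bands[b, :, c0 : c0 + pw] = grid
        x0, _ = transform.xy(0, c0, center=False)
        x1, _ = transform.xy(0, c0 + pw, center=False)
        _, y0 = transform.xy(0, 0, center=False)
        _, y1 = transform.xy(ph, 0, center=False)
        features.append(
            (patch["roi_id"], box(min(x0, x1), min(y0, y1), max(x0, x1), max(y0, y1)))
        )
    _check_disjoint(patches)
    raster = MultibandRaster(
        bands=bands, transform=transform, crs_epsg=crs_epsg,
        band_labels=[str(i + 1) for i in range(n_bands)],
    )
    rois = ROILayer(features=features, id_field="roi_id", crs_epsg=crs_epsg)
    for b in range(n_bands):
        for pi, patch in enumerate(patches):
            values = bands[b, :, pi * pw : (pi + 1) * pw].ravel()
            m = compute_all(build_histogram(values))
            rows.append(
                [
                    patch["roi_id"], str(b + 1), values.size,
                    float(values.min()), float(values.max()),
                    float(values.mean()), float(values.std(ddof=0)),
                    m.n_states, m.h_max, m.h_e, m.variability,
                    m.disequilibrium, m.sdl, m.lmc,
                ]
            )
    truth = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    return SyntheticScene(raster=raster, rois=rois, truth=truth, seed=seed)


def _per_band(value, b):
    """A layout entry may be a single value or one value per band."""
    if isinstance(value, (list, tuple)):
        return value[b]
    return value


def _check_disjoint(patches) -> None:
    ids = [p["roi_id"] for p in patches]
    if len(ids) != len(set(ids)):
        raise ValueError("patch ROI ids overlap")


def write_scene(scene: SyntheticScene, out_dir) -> Dict[str, str]:
    """Write raster (GeoTIFF), ROIs (GeoJSON) and truth table (CSV).

    Returns the paths written, keyed ``raster`` / ``rois`` / ``truth``.
    """
    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "raster": os.path.join(out_dir, "scene.tif"),
        "rois": os.path.join(out_dir, "rois.geojson"),
        "truth": os.path.join(out_dir, "truth.csv"),
    }
    write_multiband(paths["raster"], scene.raster, metadata={"seed": scene.seed})
    write_roi_layer(scene.rois, paths["rois"])
    write_results_csv(scene.truth, paths["truth"])
    return paths
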