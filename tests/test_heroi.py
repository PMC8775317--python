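"""Zonal extraction, descriptive statistics and results-table tests."""

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import box

from complexscape.heroi import (
    CRSMismatchError,
    EmptyROIError,
    RESULT_COLUMNS,
    ROILayer,
    analyze_rois,
    complexity_signature,
    describe,
    extract_roi_pixels,
    read_results_csv,
    read_roi_layer,
    write_results_csv,
    write_roi_layer,
    write_signature_csv,
)
from complexscape.raster import GridTransform, MultibandRaster
from complexscape.synthetic_scenes import build_scene

from _oracle import oracle_metrics

ATOL = 1e-9


def _simple_raster(values, nodata=None, origin=(0.0, 0.0)):
    """Unit-pixel raster with top-left corner at origin (dy = -1)."""
    arr = np.asarray(values, dtype=np.int32)
    t = GridTransform(x0=origin[0], y0=origin[1], dx=1.0, dy=-1.0)
    return MultibandRaster(bands=arr, transform=t, nodata=nodata)


class TestExtractRoiPixels:
    def test_rectangle_over_2x2_block_centers(self):
        raster = _simple_raster(np.arange(16).reshape(4, 4))
        # pixel centers of rows 1-2, cols 1-2 are (1.5,-1.5)...(2.5,-2.5)
        poly = box(1.2, -2.8, 2.8, -1.2)
        values = sorted(extract_roi_pixels(raster, 0, poly))
        assert values == [5, 6, 9, 10]

    def test_polygon_outside_raster_is_empty(self):
        raster = _simple_raster(np.zeros((4, 4), dtype=int))
        with pytest.raises(EmptyROIError):
            extract_roi_pixels(raster, 0, box(100, 100, 110, 110))

    def test_single_center_in_constant_band(self):
        raster = _simple_raster(np.full((3, 3), 5))
        values = extract_roi_pixels(raster, 0, box(1.4, -1.6, 1.6, -1.4))
        assert list(values) == [5]

    def test_all_touched_includes_cell_intersections(self):
        raster = _simple_raster(np.arange(9).reshape(3, 3))
        tiny = box(0.9, -1.1, 1.1, -0.9)  # straddles four cell corners
        assert len(extract_roi_pixels(raster, 0, tiny, overlap_rule="all_touched")) == 4
        with pytest.raises(EmptyROIError):
            extract_roi_pixels(raster, 0, tiny, overlap_rule="center")

    def test_nodata_removed_before_metrics(self):
        band = np.array([[1, 1], [255, 2]])
        raster = _simple_raster(band, nodata=255)
        values = sorted(extract_roi_pixels(raster, 0, box(0, -2, 2, 0)))
        assert values == [1, 1, 2]


class TestDescribe:
    @pytest.mark.parametrize(
        "values,count,vmin,vmax,mean,sd",
        [
            ([2, 2, 4], 3, 2, 4, 8 / 3, 0.9428090415820634),
            ([9, 9, 9], 3, 9, 9, 9.0, 0.0),
            ([0, 10], 2, 0, 10, 5.0, 5.0),
        ],
    )
    def test_population_statistics(self, values, count, vmin, vmax, mean, sd):
        st = describe(values)
        assert st.count == count
        assert st.min == vmin and st.max == vmax
        assert st.mean == pytest.approx(mean, abs=ATOL)
        assert st.sd == pytest.approx(sd, abs=ATOL)

    def test_empty_rejected(self):
        with pytest.raises(EmptyROIError):
            describe([])


class TestAnalyzeRois:
    def test_zonal_oracle_on_canonical_scene(self, canonical_scene):
        """Every (ROI, band) row equals the brute-force oracle on the
        independently enumerated pixel multiset."""
        scene = canonical_scene
        table = analyze_rois(scene.raster, scene.rois)
        assert list(table.columns) == RESULT_COLUMNS
        assert len(table) == scene.raster.n_bands * len(scene.rois.features)
        for _, row in table.iterrows():
            fid = row["roi_id"]
            geom = dict(scene.rois.features)[fid]
            b = scene.raster.band_labels.index(row["band"])
            values = extract_roi_pixels(scene.raster, b, geom)
            ref = oracle_metrics(values)
            for col, key in [
                ("N", "N"), ("Hmax", "Hmax"), ("He", "He"),
                ("He_Hmax", "He_Hmax"), ("D", "D"), ("SDL", "SDL"), ("LMC", "LMC"),
            ]:
                assert row[col] == pytest.approx(ref[key], abs=ATOL)

    def test_rows_are_band_major(self, canonical_scene):
        table = analyze_rois(canonical_scene.raster, canonical_scene.rois)
        bands = table["band"].tolist()
        assert bands == sorted(bands, key=bands.index)  # grouped contiguously
        assert bands[:3] == ["1", "1", "1"]

    def test_regime_rows(self, canonical_scene):
        table = analyze_rois(canonical_scene.raster, canonical_scene.rois)
        b1 = table[table["band"] == "1"].set_index("roi_id")
        assert b1.loc["ordered", ["He", "He_Hmax", "SDL", "LMC"]].eq(0).all()
        assert b1.loc["disordered", "He_Hmax"] == pytest.approx(1.0, abs=ATOL)
        assert b1.loc["disordered", "SDL"] == pytest.approx(0.0, abs=ATOL)
        assert b1.loc["transition", "He"] == pytest.approx(0.4689955935892812, abs=ATOL)
        assert b1.loc["transition", "LMC"] == pytest.approx(0.15007858994857, abs=ATOL)

    def test_geometry_invariance_under_translation(self, canonical_scene):
        """Shifting raster and ROIs by the same map offset changes nothing."""
        scene = canonical_scene
        base = analyze_rois(scene.raster, scene.rois)
        dx, dy = 1234.0, -987.0
        t = scene.raster.transform
        moved_raster = MultibandRaster(
            bands=scene.raster.bands.copy(),
            transform=GridTransform(t.x0 + dx, t.y0 + dy, t.dx, t.dy),
            crs_epsg=scene.raster.crs_epsg,
            band_labels=list(scene.raster.band_labels),
        )
        from shapely.affinity import translate

        moved_rois = ROILayer(
            features=[(fid, translate(g, dx, dy)) for fid, g in scene.rois.features],
            id_field=scene.rois.id_field,
            crs_epsg=scene.rois.crs_epsg,
        )
        moved = analyze_rois(moved_raster, moved_rois)
        pd.testing.assert_frame_equal(base, moved)

    def test_subadditivity_of_extension(self):
        """For disjoint ROIs, max(N_A, N_B) <= N_AuB <= N_A + N_B."""
        rng = np.random.default_rng(7)
        raster = _simple_raster(rng.integers(0, 30, size=(10, 10)))
        a, b = box(0, -10, 5, 0), box(5, -10, 10, 0)
        union = box(0, -10, 10, 0)
        layer = ROILayer(
            features=[("A", a), ("B", b), ("AB", union)], id_field="id"
        )
        t = analyze_rois(raster, layer).set_index("roi_id")
        n_a, n_b, n_ab = t.loc["A", "N"], t.loc["B", "N"], t.loc["AB", "N"]
        assert max(n_a, n_b) <= n_ab <= n_a + n_b
        assert t.loc["A", "count"] + t.loc["B", "count"] == t.loc["AB", "count"]

    def test_empty_roi_is_flagged_not_dropped(self):
        band = np.full((4, 4), 255)
        band[0, 0] = 3
        raster = _simple_raster(band, nodata=255)
        layer = ROILayer(
            features=[("good", box(0, -1, 1, 0)), ("dead", box(2, -4, 4, -2))],
            id_field="id",
        )
        table = analyze_rois(raster, layer)
        assert len(table) == 2
        dead = table[table["roi_id"] == "dead"].iloc[0]
        assert dead["count"] == 0
        assert np.isnan(dead["He"]) and np.isnan(dead["SDL"])

    def test_crs_mismatch_raises(self, canonical_scene):
        scene = canonical_scene
        other = ROILayer(
            features=list(scene.rois.features),
            id_field=scene.rois.id_field,
            crs_epsg=4326,
        )
        with pytest.raises(CRSMismatchError):
            analyze_rois(scene.raster, other)


class TestResultsCsv:
    def test_round_trip_and_row_count(self, canonical_scene, tmp_path):
        table = analyze_rois(canonical_scene.raster, canonical_scene.rois)
        path = tmp_path / "results.csv"
        write_results_csv(table, path)
        header = path.read_text().splitlines()[0]
        assert header == ",".join(RESULT_COLUMNS)
        assert len(path.read_text().splitlines()) == len(table) + 1
        back = read_results_csv(path)
        for col in RESULT_COLUMNS[2:]:
            np.testing.assert_allclose(back[col], table[col].astype(float), atol=ATOL)

    def test_empty_table_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            write_results_csv(pd.DataFrame(columns=RESULT_COLUMNS), tmp_path / "x.csv")


class TestSignature:
    def test_signature_values_and_length(self, canonical_scene):
        table = analyze_rois(canonical_scene.raster, canonical_scene.rois)
        sig = complexity_signature(table, "transition", "SDL")
        assert len(sig) == canonical_scene.raster.n_bands
        assert list(sig.index) == ["1", "2", "3", "4"]
        # SDL follows v(1-v) applied bandwise to the variability signature
        v = complexity_signature(table, "transition", "He_Hmax")
        np.testing.assert_allclose(sig.to_numpy(), v * (1 - v), atol=ATOL)

    def test_constant_roi_signature_is_zero(self, canonical_scene):
        table = analyze_rois(canonical_scene.raster, canonical_scene.rois)
        sig = complexity_signature(table, "ordered", "SDL")
        assert (sig == 0).all()

    def test_unknown_roi_or_metric(self, canonical_scene):
        table = analyze_rois(canonical_scene.raster, canonical_scene.rois)
        with pytest.raises(KeyError):
            complexity_signature(table, "nope", "SDL")
        with pytest.raises(KeyError):
            complexity_signature(table, "ordered", "Renyi")

    def test_signature_csv_schema(self, canonical_scene, tmp_path):
        table = analyze_rois(canonical_scene.raster, canonical_scene.rois)
        out = tmp_path / "sig.csv"
        write_signature_csv(table, "transition", "LMC", out)
        back = pd.read_csv(out, dtype={"band": str})
        assert list(back.columns) == ["roi_id", "metric", "band", "value"]
        assert len(back) == 4 and set(back["metric"]) == {"LMC"}


class TestRoiLayerIO:
    def test_geojson_round_trip(self, canonical_scene, tmp_path):
        path = tmp_path / "rois.geojson"
        write_roi_layer(canonical_scene.rois, path)
        back = read_roi_layer(path, "roi_id")
        assert [fid for fid, _ in back.features] == [
            fid for fid, _ in canonical_scene.rois.features
        ]
        assert back.crs_epsg == canonical_scene.rois.crs_epsg
        for (_, g1), (_, g2) in zip(back.features, canonical_scene.rois.features):
            assert g1.equals(g2)

    def test_missing_id_field_names_it(self, canonical_scene, tmp_path):
        path = tmp_path / "rois.geojson"
        write_roi_layer(canonical_scene.rois, path)
        with pytest.raises(KeyError, match="wrong_field"):
            read_roi_layer(path, "wrong_field")

    def test_duplicate_ids_rejected(self):
        sq = box(0, 0, 1, 1)
        with pytest.raises(ValueError):
            ROILayer(features=[("a", sq), ("a", sq)], id_field="id")
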