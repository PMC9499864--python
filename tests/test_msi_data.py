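"""Pixel-matrix I/O, TIC normalization, hotspot clipping, rendering."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from spacetrace.errors import FormatError, ValidationError
from spacetrace.msi_data import (
    PixelMatrix,
    hotspot_clip,
    read_imzml,
    read_pixel_matrix,
    render_pseudoimage,
    save_pseudoimage,
    tic_normalize,
    write_pixel_matrix,
)


class TestPixelMatrix:
    def test_parses_simple_tsv(self, tmp_path):
        p = tmp_path / "pm.tsv"
        p.write_text(
            "section_id\tx\ty\tf1\tf2\n"
            "s\t0\t0\t1.0\t2.0\n"
            "s\t1\t0\t3.0\t4.0\n"
            "s\t0\t1\t5.0\t6.0\n"
        )
        pm = read_pixel_matrix(p)
        assert pm.n_pixels == 3 and pm.n_features == 2
        assert pm.feature_ids == ["f1", "f2"]
        np.testing.assert_array_equal(pm.coords[1], [1, 0])

    def test_duplicate_coords_rejected(self):
        with pytest.raises(ValidationError, match=r"duplicate coordinate \(0, 0\)"):
            PixelMatrix(
                section_id="s",
                coords=[[0, 0], [0, 0]],
                intensities=[[1.0], [2.0]],
                feature_ids=["f"],
            )

    def test_negative_intensity_names_cell(self):
        with pytest.raises(ValidationError, match="lipB"):
            PixelMatrix(
                section_id="s",
                coords=[[0, 0], [1, 0]],
                intensities=[[1.0, 2.0], [1.0, -3.0]],
                feature_ids=["lipA", "lipB"],
            )

    def test_missing_coordinate_column_is_format_error(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("section_id\tx\tf1\ns\t0\t1.0\n")
        with pytest.raises(FormatError, match="y"):
            read_pixel_matrix(p)

    def test_roundtrip_identity(self, tmp_path, tiny_pm):
        p = tmp_path / "rt.tsv"
        write_pixel_matrix(tiny_pm, p)
        back = read_pixel_matrix(p)
        np.testing.assert_array_equal(back.coords, tiny_pm.coords)
        np.testing.assert_allclose(back.intensities, tiny_pm.intensities)
        assert back.feature_ids == tiny_pm.feature_ids
        assert back.section_id == tiny_pm.section_id


class TestTicNormalize:
    def test_rows_sum_to_one(self, tiny_pm):
        out = tic_normalize(tiny_pm)
        np.testing.assert_allclose(out.intensities.sum(axis=1), 1.0, atol=1e-9)
        np.testing.assert_allclose(
            out.intensities[0], [0.2, 0.3, 0.5]
        )

    def test_idempotent(self, tiny_pm):
        once = tic_normalize(tiny_pm)
        twice = tic_normalize(once)
        np.testing.assert_allclose(once.intensities, twice.intensities)

    def test_zero_tic_pixel_reports_coords(self, tiny_pm):
        tiny_pm.intensities[2] = 0.0
        pm = PixelMatrix(
            section_id="s",
            coords=tiny_pm.coords,
            intensities=tiny_pm.intensities,
            feature_ids=tiny_pm.feature_ids,
        )
        with pytest.raises(ValidationError, match=r"\(2, 0\)"):
            tic_normalize(pm)


class TestHotspotClip:
    def test_quantile_by_linear_interpolation(self):
        values = np.arange(101, dtype=float)  # 0..100, q99 -> 99.0
        out = hotspot_clip(values, q=0.99)
        assert out.max() == pytest.approx(99.0)
        np.testing.assert_array_equal(out[:-1], values[:-1])

    def test_all_equal_unchanged(self):
        out = hotspot_clip(np.full(10, 7.0), q=0.99)
        np.testing.assert_array_equal(out, np.full(10, 7.0))

    def test_q1_is_identity(self):
        rng = np.random.default_rng(0)
        v = rng.exponential(size=50)
        np.testing.assert_array_equal(hotspot_clip(v, q=1.0), v)

    def test_empty_input_errors(self):
        with pytest.raises(ValidationError):
            hotspot_clip(np.array([]))

    @settings(deadline=None, max_examples=50)
    @given(
        hst.lists(
            hst.floats(min_value=-1e6, max_value=1e6), min_size=2, max_size=40
        ),
        hst.floats(min_value=0.1, max_value=1.0),
    )
    def test_monotone(self, values, q):
        v = np.asarray(values)
        out = hotspot_clip(v, q)
        # monotone: order of any two elements is preserved (weakly)
        i, j = 0, len(v) - 1
        if v[i] <= v[j]:
            assert out[i] <= out[j]
        assert (out <= v).all()

    def test_idempotent_when_quantile_hits_order_statistic(self):
        # 101 values at q = 0.99: the cap is the 99th order statistic, so
        # clipping again changes nothing
        rng = np.random.default_rng(2)
        v = rng.exponential(size=101)
        out = hotspot_clip(v, q=0.99)
        np.testing.assert_allclose(hotspot_clip(out, q=0.99), out, rtol=1e-12)


class TestRenderPseudoimage:
    def test_full_grid_roundtrips(self):
        coords = np.array([[0, 0], [1, 0], [0, 1], [1, 1]])
        values = np.array([1.0, 2.0, 3.0, 4.0])
        img = render_pseudoimage(values, coords)
        np.testing.assert_array_equal(img.raster, [[1.0, 2.0], [3.0, 4.0]])

    def test_missing_pixel_is_background(self):
        coords = np.array([[0, 0], [1, 0], [0, 1]])
        img = render_pseudoimage(np.array([1.0, 2.0, 3.0]), coords)
        assert np.isnan(img.raster[1, 1])

    def test_rgb_preserves_channel_order(self):
        coords = np.array([[0, 0], [1, 0]])
        rgb = np.array([[10.0, 20.0, 30.0], [1.0, 2.0, 3.0]])
        img = render_pseudoimage(rgb, coords)
        np.testing.assert_array_equal(img.raster[0, 0], [10.0, 20.0, 30.0])
        np.testing.assert_array_equal(img.raster[0, 1], [1.0, 2.0, 3.0])

    def test_out_of_extent_coordinate_errors(self):
        with pytest.raises(ValidationError, match="extent"):
            render_pseudoimage(
                np.array([1.0]), np.array([[5, 5]]), extent=(0, 3, 0, 3)
            )

    def test_png_written(self, tmp_path):
        coords = np.array([[0, 0], [1, 0], [0, 1], [1, 1]])
        img = render_pseudoimage(np.array([0.0, 1.0, 2.0, 3.0]), coords)
        out = tmp_path / "img.png"
        save_pseudoimage(img, out)
        assert out.stat().st_size > 0


class TestImzml:
    def test_imzml_roundtrip_matches_tsv_reader(self, tmp_path, tiny_pm):
        writer_mod = pytest.importorskip("pyimzml.ImzMLWriter")
        mzs = np.array([400.0, 500.0, 600.0])
        path = tmp_path / "tiny.imzML"
        with writer_mod.ImzMLWriter(str(path)) as w:
            for i in range(tiny_pm.n_pixels):
                x, y = tiny_pm.coords[i]
                w.addSpectrum(
                    mzs, tiny_pm.intensities[i], (int(x) + 1, int(y) + 1)
                )
        pm = read_imzml(
            path, mzs, feature_ids=tiny_pm.feature_ids, tol_ppm=5.0
        )
        order = np.lexsort((pm.coords[:, 0], pm.coords[:, 1]))
        ref_order = np.lexsort((tiny_pm.coords[:, 0], tiny_pm.coords[:, 1]))
        np.testing.assert_array_equal(
            pm.coords[order], tiny_pm.coords[ref_order]
        )
        np.testing.assert_allclose(
            pm.intensities[order], tiny_pm.intensities[ref_order], rtol=1e-6
        )
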