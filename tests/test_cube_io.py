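import numpy as np
import pytest

from tuberhsi.cube_io import (
    CubeKind,
    ReferencePair,
    build_wavelength_axis,
    calibrate_reflectance,
    fold,
    mean_spectrum,
    read_envi,
    trim_leading_bands,
    unfold,
    write_envi,
)
from tuberhsi.errors import (
    DegenerateReferenceError,
    EmptySelectionError,
    FormatError,
    InvalidAxisError,
)

from conftest import make_cube


class TestWavelengthAxis:
    @pytest.mark.parametrize(
        "start,end,n,spacing",
        [
            (900.0, 1700.0, 256, 800.0 / 255.0),  # instrument grid, 3.14 nm to 2 dp
            (0.0, 10.0, 11, 1.0),
            (900.0, 1700.0, 2, 800.0),
        ],
    )
    def test_endpoints_and_spacing(self, start, end, n, spacing):
        ax = build_wavelength_axis(start, end, n)
        assert ax.values[0] == start and ax.values[-1] == end
        assert ax.n_bands == n
        assert ax.spacing_nm == pytest.approx(spacing)

    def test_instrument_spacing_rounds_to_3_14(self):
        ax = build_wavelength_axis(900, 1700, 256)
        assert round(ax.spacing_nm, 2) == 3.14

    @pytest.mark.parametrize("args", [(1700, 900, 10), (900, 900, 10), (900, 1700, 1)])
    def test_invalid_axis(self, args):
        with pytest.raises(InvalidAxisError):
            build_wavelength_axis(*args)


class TestTrimLeadingBands:
    def test_drop_30_of_256_leaves_226_starting_994(self):
        cube = make_cube(np.zeros((2, 2, 256)), build_wavelength_axis(900, 1700, 256))
        trimmed = trim_leading_bands(cube, 30)
        assert trimmed.n_bands == 226
        assert trimmed.axis.start_nm == pytest.approx(900 + 30 * 800 / 255)
        assert round(trimmed.axis.start_nm, 2) == 994.12
        assert trimmed.axis.end_nm == 1700.0

    def test_zero_drop_is_identity(self, rng):
        cube = make_cube(rng.normal(size=(3, 4, 8)))
        trimmed = trim_leading_bands(cube, 0)
        np.testing.assert_array_equal(trimmed.data, cube.data)
        np.testing.assert_array_equal(trimmed.axis.values, cube.axis.values)

    def test_dropping_all_bands_errors(self):
        cube = make_cube(np.zeros((2, 2, 8)))
        with pytest.raises(EmptySelectionError):
            trim_leading_bands(cube, 8)


class TestCalibrateReflectance:
    def _refs(self, cols, bands, white=100.0, dark=20.0):
        return ReferencePair(
            np.full((cols, bands), white), np.full((cols, bands), dark)
        )

    def test_white_dark_and_midpoint_identities(self):
        refs = self._refs(3, 4)
        for value, expected in [(100.0, 1.0), (20.0, 0.0), (60.0, 0.5)]:
            raw = make_cube(np.full((2, 3, 4), value), kind=CubeKind.RAW)
            out = calibrate_reflectance(raw, refs)
            assert out.kind is CubeKind.REFLECTANCE
            np.testing.assert_allclose(out.data, expected)

    def test_affine_invariance_in_intensity_scale(self, rng):
        raw = rng.uniform(30, 90, size=(4, 3, 5))
        white = rng.uniform(95, 105, size=(3, 5))
        dark = rng.uniform(5, 15, size=(3, 5))
        a, b = 2.7, 13.0
        r1 = calibrate_reflectance(
            make_cube(raw, kind=CubeKind.RAW), ReferencePair(white, dark)
        )
        r2 = calibrate_reflectance(
            make_cube(a * raw + b, kind=CubeKind.RAW),
            ReferencePair(a * white + b, a * dark + b),
        )
        np.testing.assert_allclose(r1.data, r2.data, atol=1e-12)

    def test_monotone_in_intensity(self):
        refs = self._refs(2, 3)
        lo = calibrate_reflectance(make_cube(np.full((1, 2, 3), 40.0), kind=CubeKind.RAW), refs)
        hi = calibrate_reflectance(make_cube(np.full((1, 2, 3), 41.0), kind=CubeKind.RAW), refs)
        assert np.all(hi.data > lo.data)

    def test_scan_averaged_references(self):
        # 3-D reference stacks are averaged over the scan direction first
        white = np.stack([np.full((3, 4), 90.0), np.full((3, 4), 110.0)])
        dark = np.stack([np.full((3, 4), 15.0), np.full((3, 4), 25.0)])
        raw = make_cube(np.full((2, 3, 4), 60.0), kind=CubeKind.RAW)
        out = calibrate_reflectance(raw, ReferencePair(white, dark))
        np.testing.assert_allclose(out.data, 0.5)

    def test_degenerate_reference_names_position(self):
        white2 = np.full((3, 4), 100.0)
        dark2 = np.full((3, 4), 20.0)
        dark2[1, 2] = 100.0
        raw = make_cube(np.zeros((2, 3, 4)), kind=CubeKind.RAW)
        with pytest.raises(DegenerateReferenceError, match="x=1.*band 2"):
            calibrate_reflectance(raw, ReferencePair(white2, dark2))

    def test_clipping(self):
        refs = self._refs(2, 2)
        raw = make_cube(np.full((1, 2, 2), 500.0), kind=CubeKind.RAW)
        clipped = calibrate_reflectance(raw, refs, clip=True, clip_max=2.0)
        assert clipped.data.max() == 2.0
        unclipped = calibrate_reflectance(raw, refs)
        assert unclipped.data.max() > 2.0


class TestEnviRoundTrip:
    @pytest.mark.parametrize("interleave", ["bil", "bsq", "bip"])
    def test_write_read_identity(self, tmp_path, rng, interleave):
        cube = make_cube(rng.normal(size=(5, 7, 11)))
        hdr = write_envi(cube, tmp_path / "cube", interleave=interleave)
        back = read_envi(hdr)
        np.testing.assert_array_equal(back.data, cube.data)
        np.testing.assert_allclose(back.axis.values, cube.axis.values)
        assert back.kind is cube.kind

    def test_interleaves_agree_in_memory(self, tmp_path, rng):
        cube = make_cube(rng.normal(size=(4, 6, 3)))
        a = read_envi(write_envi(cube, tmp_path / "a", "bil"))
        b = read_envi(write_envi(cube, tmp_path / "b", "bsq"))
        np.testing.assert_array_equal(a.data, b.data)

    def test_wavelength_axis_full_precision(self, tmp_path):
        cube = make_cube(np.zeros((1, 1, 256)), build_wavelength_axis(900, 1700, 256))
        back = read_envi(write_envi(cube, tmp_path / "c"))
        np.testing.assert_array_equal(back.axis.values, cube.axis.values)
        assert back.axis.n_bands == 256

    def test_band_count_mismatch_raises(self, tmp_path, rng):
        cube = make_cube(rng.normal(size=(2, 2, 8)))
        hdr = write_envi(cube, tmp_path / "c")
        text = hdr.read_text().replace("bands = 8", "bands = 9")
        hdr.write_text(text)
        with pytest.raises(FormatError):
            read_envi(hdr)

    def test_missing_mandatory_field_raises(self, tmp_path, rng):
        cube = make_cube(rng.normal(size=(2, 2, 4)))
        hdr = write_envi(cube, tmp_path / "c")
        text = "\n".join(
            l for l in hdr.read_text().splitlines() if not l.startswith("samples")
        )
        hdr.write_text(text)
        with pytest.raises(FormatError, match="samples"):
            read_envi(hdr)

    def test_metadata_round_trip(self, tmp_path):
        cube = make_cube(np.zeros((1, 2, 3)))
        cube.sample_id, cube.class_label = "Agria_01", "frying"
        back = read_envi(write_envi(cube, tmp_path / "c"))
        assert back.sample_id == "Agria_01"
        assert back.class_label == "frying"


class TestUnfoldFold:
    def test_full_unfold_shape_and_order(self, rng):
        cube = make_cube(rng.normal(size=(2, 2, 3)))
        pm = unfold(cube, np.ones((2, 2), dtype=bool))
        assert pm.spectra.shape == (4, 3)
        np.testing.assert_array_equal(
            pm.coords, [[0, 0], [0, 1], [1, 0], [1, 1]]
        )  # row-major

    def test_single_pixel(self, rng):
        cube = make_cube(rng.normal(size=(2, 3, 4)))
        mask = np.zeros((2, 3), dtype=bool)
        mask[0, 1] = True
        pm = unfold(cube, mask)
        assert pm.spectra.shape == (1, 4)
        np.testing.assert_array_equal(pm.coords, [[0, 1]])
        np.testing.assert_array_equal(pm.spectra[0], cube.data[0, 1])

    def test_fold_unfold_round_trip_any_mask(self, rng):
        cube = make_cube(rng.normal(size=(6, 5, 4)))
        mask = rng.random((6, 5)) > 0.4
        mask[0, 0] = True
        pm = unfold(cube, mask)
        for band in range(4):
            img = fold(pm.spectra[:, band], pm.coords, pm.source_shape, np.nan)
            np.testing.assert_array_equal(img[mask], cube.data[:, :, band][mask])
            assert np.isnan(img[~mask]).all()

    def test_empty_mask_errors(self, rng):
        cube = make_cube(rng.normal(size=(2, 2, 3)))
        with pytest.raises(EmptySelectionError):
            unfold(cube, np.zeros((2, 2), dtype=bool))

    def test_fold_examples_and_order_invariance(self, rng):
        img = fold(np.array([1]), np.array([[0, 0]]), (2, 2), 0)
        np.testing.assert_array_equal(img, [[1, 0], [0, 0]])
        img = fold(np.array([]), np.zeros((0, 2)), (2, 3), 7)
        np.testing.assert_array_equal(img, np.full((2, 3), 7))
        values = np.array([1, 2, 3])
        coords = np.array([[0, 0], [1, 1], [2, 0]])
        perm = rng.permutation(3)
        np.testing.assert_array_equal(
            fold(values, coords, (3, 2), 0), fold(values[perm], coords[perm], (3, 2), 0)
        )

    def test_fold_out_of_bounds(self):
        with pytest.raises(IndexError):
            fold(np.array([1]), np.array([[2, 0]]), (2, 2), 0)


class TestMeanSpectrum:
    def test_uniform_and_two_pixel_mean(self, rng):
        cube = make_cube(np.full((2, 2, 3), 0.7))
        np.testing.assert_allclose(mean_spectrum(cube, np.ones((2, 2), bool)), 0.7)
        cube2 = make_cube(rng.normal(size=(1, 2, 3)))
        mask = np.ones((1, 2), bool)
        np.testing.assert_allclose(
            mean_spectrum(cube2, mask), (cube2.data[0, 0] + cube2.data[0, 1]) / 2
        )

    def test_consistent_with_unfold(self, rng):
        cube = make_cube(rng.normal(size=(5, 4, 6)))
        mask = rng.random((5, 4)) > 0.5
        mask[2, 2] = True
        np.testing.assert_allclose(
            mean_spectrum(cube, mask), unfold(cube, mask).spectra.mean(axis=0)
        )
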