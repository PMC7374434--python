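"""Cube container, ENVI round-trips, calibration, and band lookup."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from leafdist.cube import (
    ReferenceSet,
    SpectralCube,
    band_index,
    calibrate,
    read_envi_cube,
    write_envi_cube,
)


def make_cube(values, wavelengths=None, **kw):
    values = np.asarray(values)
    if wavelengths is None:
        wavelengths = np.linspace(500.0, 800.0, values.shape[2])
    return SpectralCube(values, wavelengths, **kw)


class TestContainer:
    def test_wavelength_count_mismatch_rejected(self):
        with pytest.raises(ValueError, match="wavelength count mismatch"):
            SpectralCube(np.zeros((2, 2, 4)), np.linspace(500, 700, 5))

    def test_non_increasing_wavelengths_rejected(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            make_cube(np.zeros((2, 2, 3)), [500.0, 500.0, 600.0])

    def test_empty_cube_rejected(self):
        with pytest.raises(ValueError, match="empty cube"):
            SpectralCube(np.zeros((0, 4, 3)), np.linspace(500, 700, 3))

    def test_wavelengths_outside_sensor_range_rejected(self):
        with pytest.raises(ValueError, match="sensor range"):
            make_cube(np.zeros((2, 2, 3)), [400.0, 600.0, 800.0])

    def test_calibrated_cube_must_be_finite(self):
        values = np.full((2, 2, 3), np.nan)
        with pytest.raises(ValueError, match="non-finite"):
            make_cube(values, calibrated=True)


class TestEnviIO:
    @pytest.mark.parametrize("interleave", ["bil", "bip", "bsq"])
    @pytest.mark.parametrize("dtype", [np.float32, np.float64, np.uint16])
    def test_roundtrip_identity(self, tmp_path, rng, interleave, dtype):
        values = rng.uniform(0, 1, size=(4, 6, 5))
        if np.dtype(dtype).kind == "u":
            values = (values * 1000).astype(dtype)
        cube = make_cube(values.astype(dtype))
        hdr = write_envi_cube(cube, tmp_path / "cube.hdr", interleave=interleave, dtype=dtype)
        back = read_envi_cube(hdr)
        assert back.values.dtype == np.dtype(dtype)
        assert np.array_equal(back.values, cube.values.astype(dtype))
        np.testing.assert_allclose(back.wavelengths, cube.wavelengths)

    def test_float32_truncation_on_write(self, tmp_path):
        cube = make_cube(np.full((1, 1, 2), 0.123456789))
        hdr = write_envi_cube(cube, tmp_path / "c.hdr", dtype=np.float32)
        assert read_envi_cube(hdr).values[0, 0, 0] == np.float32(0.123456789)

    def test_independent_encoders_agree(self, tmp_path, rng):
        """Hand-encoded BIL and BSQ files of one array read back identically."""
        arr = rng.uniform(0, 1, size=(3, 4, 5)).astype(np.float32)
        wl = np.linspace(500, 700, 5)
        wl_text = ", ".join(str(w) for w in wl)
        header = (
            "ENVI\nsamples = 4\nlines = 3\nbands = 5\nheader offset = 0\n"
            "data type = 4\ninterleave = {interleave}\nbyte order = 0\n"
            "wavelength = {{ " + wl_text + " }}\n"
        )
        # independent encoding: explicit loops over the ENVI disk layouts
        bil = np.empty((3, 5, 4), np.float32)
        bsq = np.empty((5, 3, 4), np.float32)
        for y in range(3):
            for x in range(4):
                for b in range(5):
                    bil[y, b, x] = arr[y, x, b]
                    bsq[b, y, x] = arr[y, x, b]
        for name, disk in (("a.bil", bil), ("b.bsq", bsq)):
            disk.tofile(tmp_path / name)
            (tmp_path / name).with_suffix(".hdr").write_text(
                header.format(interleave=name.split(".")[1])
            )
        cube_bil = read_envi_cube(tmp_path / "a.hdr")
        cube_bsq = read_envi_cube(tmp_path / "b.hdr")
        assert cube_bil == cube_bsq
        assert np.array_equal(cube_bil.values, arr)

    def test_header_wavelength_mismatch(self, tmp_path):
        cube = make_cube(np.zeros((2, 2, 4)))
        hdr = write_envi_cube(cube, tmp_path / "c.hdr")
        text = hdr.read_text().replace("bands = 4", "bands = 5")
        hdr.write_text(text)
        with pytest.raises(ValueError, match="wavelength count mismatch"):
            read_envi_cube(hdr)

    def test_missing_binary(self, tmp_path):
        cube = make_cube(np.zeros((2, 2, 4)))
        hdr = write_envi_cube(cube, tmp_path / "c.hdr")
        hdr.with_suffix(".bil").unlink()
        with pytest.raises(FileNotFoundError, match="missing binary"):
            read_envi_cube(hdr)

    def test_unsupported_interleave(self, tmp_path):
        cube = make_cube(np.zeros((2, 2, 4)))
        hdr = write_envi_cube(cube, tmp_path / "c.hdr")
        hdr.write_text(hdr.read_text().replace("interleave = bil", "interleave = xyz"))
        with pytest.raises(ValueError, match="interleave"):
            read_envi_cube(hdr)


class TestCalibration:
    def test_single_value_arithmetic(self):
        raw = make_cube(np.full((1, 1, 1), 0.6), [650.0], calibrated=False)
        refs = ReferenceSet(dark=np.full((1, 1), 0.1), white=np.full((1, 1), 0.9))
        out = calibrate(raw, refs)
        assert out.values[0, 0, 0] == pytest.approx(0.5, abs=1e-15)
        assert out.calibrated

    def test_raw_equal_dark_gives_zero(self, rng):
        dark = rng.uniform(0.05, 0.1, size=(3, 4))
        raw = make_cube(np.broadcast_to(dark[:, None, :], (3, 2, 4)).copy())
        refs = ReferenceSet(dark=dark, white=np.full((3, 4), 0.8))
        assert np.all(calibrate(raw, refs).values == 0)

    @pytest.mark.parametrize("denominator", ["white_plus_dark", "white_minus_dark"])
    def test_matches_scalar_loop_oracle(self, rng, denominator):
        raw = make_cube(rng.uniform(0.1, 0.9, size=(3, 3, 4)))
        dark = rng.uniform(0.01, 0.05, size=(3, 4))
        white = rng.uniform(0.7, 0.9, size=(3, 4))
        out = calibrate(raw, ReferenceSet(dark, white), denominator)
        for y in range(3):
            for x in range(3):
                for b in range(4):
                    den = (white[y, b] + dark[y, b] if denominator == "white_plus_dark"
                           else white[y, b] - dark[y, b])
                    expected = (raw.values[y, x, b] - dark[y, b]) / den
                    assert out.values[y, x, b] == pytest.approx(expected, abs=1e-12)

    def test_linearity_in_raw_with_zero_dark(self, rng):
        wl = np.linspace(500, 800, 4)
        X = rng.uniform(0.1, 0.9, size=(3, 3, 4))
        Y = rng.uniform(0.1, 0.9, size=(3, 3, 4))
        refs = ReferenceSet(dark=np.zeros((3, 4)), white=rng.uniform(0.7, 0.9, (3, 4)))
        lhs = calibrate(SpectralCube(2 * X + 3 * Y, wl), refs).values
        rhs = (2 * calibrate(SpectralCube(X, wl), refs).values
               + 3 * calibrate(SpectralCube(Y, wl), refs).values)
        np.testing.assert_allclose(lhs, rhs, atol=1e-12)

    def test_reference_cube_averaged_over_scan_axis(self, rng):
        raw = make_cube(rng.uniform(0.1, 0.9, size=(3, 5, 4)))
        dark_cube = SpectralCube(rng.uniform(0.01, 0.05, size=(3, 7, 4)),
                                 raw.wavelengths)
        white = np.full((3, 4), 0.8)
        out = calibrate(raw, ReferenceSet(dark_cube, white))
        dark_frame = dark_cube.values.mean(axis=1)
        expected = calibrate(raw, ReferenceSet(dark_frame, white))
        np.testing.assert_allclose(out.values, expected.values)

    def test_zero_denominator_rejected(self):
        raw = make_cube(np.full((1, 1, 1), 0.6), [650.0])
        refs = ReferenceSet(dark=np.full((1, 1), 0.1), white=np.full((1, 1), -0.1))
        with pytest.raises(ValueError, match="zero denominator"):
            calibrate(raw, refs)

    def test_shape_mismatch_rejected(self):
        raw = make_cube(np.zeros((2, 2, 4)))
        refs = ReferenceSet(dark=np.zeros((3, 4)), white=np.full((3, 4), 0.8))
        with pytest.raises(ValueError, match="incompatible"):
            calibrate(raw, refs)


class TestBandIndex:
    def test_nearest_band(self):
        cube = make_cube(np.zeros((1, 1, 3)), [648.9, 649.6, 650.4])
        assert band_index(cube, 650.0) == 1

    def test_exact_center(self):
        cube = make_cube(np.zeros((1, 1, 3)), [600.0, 650.0, 700.0])
        assert band_index(cube, 650.0) == 1

    def test_equidistant_tie_takes_lower_index(self):
        cube = make_cube(np.zeros((1, 1, 2)), [640.0, 660.0])
        assert band_index(cube, 650.0) == 0

    def test_outside_range_rejected(self):
        cube = make_cube(np.zeros((1, 1, 2)), [640.0, 660.0])
        with pytest.raises(ValueError, match="outside"):
            band_index(cube, 900.0)

    @settings(deadline=None, max_examples=25)
    @given(st.integers(min_value=2, max_value=40), st.integers(min_value=0, max_value=39))
    def test_band_center_maps_to_itself(self, n_bands, i):
        cube = make_cube(np.zeros((1, 1, n_bands)), np.linspace(460, 890, n_bands))
        i = i % n_bands
        assert band_index(cube, float(cube.wavelengths[i])) == i
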