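"""Cube I/O, white/dark calibration, ROI means, and band trimming."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hypernitro import (
    FormatError,
    Hypercube,
    SpectraTable,
    calibrate,
    mean_roi_spectrum,
    read_envi,
    trim_bands,
    write_envi,
)


def _cube(rng, rows=8, cols=6, bands=5, dtype=np.float64, interleave="bil"):
    data = rng.uniform(0, 1, size=(rows, cols, bands)).astype(dtype)
    wl = np.linspace(400, 800, bands)
    return Hypercube(data=data, wavelengths=wl, interleave=interleave)


class TestEnviRoundTrip:
    @pytest.mark.parametrize("interleave", ["bsq", "bil", "bip"])
    @pytest.mark.parametrize("dtype", [np.float32, np.float64, np.uint16])
    def test_lossless(self, tmp_path, rng, interleave, dtype):
        cube = _cube(rng, dtype=dtype, interleave=interleave)
        if np.issubdtype(dtype, np.integer):
            cube.data = (cube.data * 1000).astype(dtype)
        write_envi(cube, tmp_path / "c.dat", tmp_path / "c.hdr")
        back = read_envi(tmp_path / "c.dat", tmp_path / "c.hdr")
        assert back.data.dtype == np.dtype(dtype)
        np.testing.assert_array_equal(back.data, cube.data)
        np.testing.assert_array_equal(back.wavelengths, cube.wavelengths)

    def test_cross_interleave_consistency(self, tmp_path, rng):
        """The same cube written BSQ and BIL reads back identically."""
        cube = _cube(rng)
        for il in ("bsq", "bil"):
            c = Hypercube(cube.data, cube.wavelengths, interleave=il)
            write_envi(c, tmp_path / f"{il}.dat", tmp_path / f"{il}.hdr")
        a = read_envi(tmp_path / "bsq.dat", tmp_path / "bsq.hdr")
        b = read_envi(tmp_path / "bil.dat", tmp_path / "bil.hdr")
        np.testing.assert_array_equal(a.data, b.data)

    def test_band_count_mismatch_rejected(self, tmp_path, rng):
        cube = _cube(rng)
        write_envi(cube, tmp_path / "c.dat", tmp_path / "c.hdr")
        hdr = (tmp_path / "c.hdr").read_text().replace("bands = 5", "bands = 4")
        (tmp_path / "c.hdr").write_text(hdr)
        with pytest.raises(FormatError):
            read_envi(tmp_path / "c.dat", tmp_path / "c.hdr")

    def test_missing_header_field_rejected(self, tmp_path, rng):
        cube = _cube(rng)
        write_envi(cube, tmp_path / "c.dat", tmp_path / "c.hdr")
        hdr = "\n".join(l for l in (tmp_path / "c.hdr").read_text().splitlines()
                        if not l.startswith("samples"))
        (tmp_path / "c.hdr").write_text(hdr)
        with pytest.raises(FormatError, match="samples"):
            read_envi(tmp_path / "c.dat", tmp_path / "c.hdr")

    def test_file_size_mismatch_rejected(self, tmp_path, rng):
        cube = _cube(rng)
        write_envi(cube, tmp_path / "c.dat", tmp_path / "c.hdr")
        with open(tmp_path / "c.dat", "ab") as fh:
            fh.write(b"\x00" * 8)
        with pytest.raises(FormatError, match="size"):
            read_envi(tmp_path / "c.dat", tmp_path / "c.hdr")


class TestCalibration:
    def test_white_dark_midpoint_anchors(self, rng):
        """raw=white -> 1, raw=dark -> 0, raw=midpoint -> 0.5 everywhere."""
        wl = np.linspace(400, 800, 4)
        dark = Hypercube(np.full((5, 4, 4), 100.0), wl)
        white = Hypercube(rng.uniform(1000, 4000, (5, 4, 4)) , wl)
        mid = Hypercube((white.data + dark.data) / 2, wl)
        for raw, expected in ((white, 1.0), (dark, 0.0), (mid, 0.5)):
            out = calibrate(raw, white, dark)
            assert out.is_reflectance
            np.testing.assert_allclose(out.data, expected, atol=1e-12)

    def test_zero_denominator_marks_invalid(self):
        wl = np.array([500.0, 600.0])
        white = Hypercube(np.full((3, 3, 2), 200.0), wl)
        dark = Hypercube(np.full((3, 3, 2), 100.0), wl)
        white.data[1, 1, 0] = 100.0          # dead pixel-band
        raw = Hypercube(np.full((3, 3, 2), 150.0), wl)
        out = calibrate(raw, white, dark)
        assert np.isnan(out.data[1, 1, 0])
        assert np.isfinite(out.data[0, 0, :]).all()

    def test_shape_mismatch_rejected(self, rng):
        a = _cube(rng, rows=4)
        b = _cube(rng, rows=5)
        with pytest.raises(ValueError, match="shape"):
            calibrate(a, b, b)


class TestMeanRoiSpectrum:
    def test_constant_and_two_pixel_cases(self):
        wl = np.linspace(400, 700, 3)
        cube = Hypercube(np.full((4, 4, 3), 0.7), wl)
        mask = np.zeros((4, 4), bool)
        mask[0, 0] = True
        np.testing.assert_allclose(mean_roi_spectrum(cube, mask), 0.7)
        cube.data[0, 0] = [0.2, 0.4, 0.6]
        cube.data[1, 1] = [0.4, 0.8, 1.0]
        mask[1, 1] = True
        np.testing.assert_allclose(mean_roi_spectrum(cube, mask),
                                   [0.3, 0.6, 0.8])

    def test_matches_loop_oracle(self, rng):
        cube = _cube(rng, rows=6, cols=6, bands=4)
        mask = rng.uniform(size=(6, 6)) < 0.3
        mask[2, 2] = True
        got = mean_roi_spectrum(cube, mask)
        # brute force: per-band loop over masked pixels
        for b in range(4):
            vals = [cube.data[i, j, b] for i in range(6) for j in range(6)
                    if mask[i, j]]
            assert got[b] == pytest.approx(np.mean(vals), rel=1e-12)

    def test_excludes_invalid_pixels(self):
        wl = np.array([500.0])
        data = np.full((2, 2, 1), 0.5)
        data[0, 0, 0] = np.nan
        cube = Hypercube(data, wl)
        mask = np.ones((2, 2), bool)
        np.testing.assert_allclose(mean_roi_spectrum(cube, mask), 0.5)

    def test_empty_mask_rejected(self, rng):
        cube = _cube(rng)
        with pytest.raises(ValueError, match="no pixels"):
            mean_roi_spectrum(cube, np.zeros(cube.shape[:2], bool))


class TestTrimBands:
    def test_closed_interval_membership(self):
        wl = np.array([400.0, 500.0, 600.0])
        t = SpectraTable(X=np.ones((2, 3)), y=np.array([1.0, 2.0]),
                         wavelengths=wl)
        out = trim_bands(t, 450, 650)
        np.testing.assert_array_equal(out.wavelengths, [500.0, 600.0])

    def test_identity_and_idempotence(self, small_table):
        full = trim_bands(small_table, small_table.wavelengths[0],
                          small_table.wavelengths[-1])
        np.testing.assert_array_equal(full.X, small_table.X)
        twice = trim_bands(trim_bands(small_table, 500, 900), 500, 900)
        once = trim_bands(small_table, 500, 900)
        np.testing.assert_array_equal(twice.X, once.X)

    def test_no_surviving_band_rejected(self, small_table):
        with pytest.raises(ValueError, match="no band"):
            trim_bands(small_table, 1, 2)

    @given(low=st.floats(min_value=400, max_value=600),
           width=st.floats(min_value=50, max_value=400))
    @settings(max_examples=25, deadline=None)
    def test_output_strictly_increasing(self, low, width):
        wl = np.linspace(380, 1030, 64)
        cube = Hypercube(np.ones((2, 2, 64)), wl)
        out = trim_bands(cube, low, low + width)
        assert np.all(np.diff(out.wavelengths) > 0)
        # never reordered: a subsequence of the original grid
        assert np.isin(out.wavelengths, wl).all()


class TestSpectraTableCsv:
    def test_round_trip_lossless(self, tmp_path, small_table):
        path = tmp_path / "spectra.csv"
        small_table.to_csv(path)
        back = SpectraTable.from_csv(path)
        np.testing.assert_array_equal(back.X, small_table.X)
        np.testing.assert_array_equal(back.y, small_table.y)
        np.testing.assert_array_equal(back.wavelengths, small_table.wavelengths)
        assert list(back.organs) == list(small_table.organs)
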