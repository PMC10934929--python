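"""Cube types, band arithmetic, ROI segmentation, mean-spectrum extraction."""

import numpy as np
import pytest

from candlepls.hypercube import (EggMask, Hypercube, SpectrumSet,
                                 band_wavelength, extract_spectra,
                                 mean_spectrum, segment_eggs)


def make_cube(data, lo=900.0, hi=1700.0):
    return Hypercube(data=data, wavelengths=np.linspace(lo, hi, data.shape[2]))


class TestBandWavelength:
    def test_endpoints(self):
        assert band_wavelength(1, 167) == 900.0
        assert band_wavelength(167, 167) == 1700.0

    def test_segmentation_band_sits_near_1078nm(self):
        # linear convention: 900 + 37 * 800/166
        assert band_wavelength(38, 167) == pytest.approx(900 + 37 * 800 / 166)
        assert band_wavelength(38, 167) == pytest.approx(1078.31, abs=0.01)

    def test_out_of_range_index(self):
        with pytest.raises(IndexError):
            band_wavelength(0, 167)
        with pytest.raises(IndexError):
            band_wavelength(168, 167)


class TestHypercubeValidation:
    def test_rejects_negative_and_nonfinite(self):
        with pytest.raises(ValueError, match="negative"):
            make_cube(-np.ones((2, 2, 3)))
        with pytest.raises(ValueError, match="non-finite"):
            make_cube(np.full((2, 2, 3), np.nan))

    def test_rejects_mismatched_or_unsorted_axis(self):
        data = np.ones((2, 2, 3))
        with pytest.raises(ValueError):
            Hypercube(data=data, wavelengths=[900, 1000])
        with pytest.raises(ValueError, match="increasing"):
            Hypercube(data=data, wavelengths=[900, 1700, 1000])


class TestMeanSpectrum:
    def test_constant_cube_gives_constant_spectrum(self):
        cube = make_cube(np.full((4, 4, 5), 7.5))
        mask = EggMask(grid=np.eye(4, dtype=bool), egg_id="e")
        assert np.array_equal(mean_spectrum(cube, mask), np.full(5, 7.5))

    def test_hand_computed_three_pixel_mean(self):
        data = np.arange(8, dtype=float).reshape(2, 2, 2)
        cube = make_cube(data)
        grid = np.array([[True, True], [True, False]])
        # band 0 pixels: 0, 2, 4 -> 2.0 ; band 1 pixels: 1, 3, 5 -> 3.0
        assert mean_spectrum(cube, EggMask(grid=grid, egg_id="e")).tolist() == [2.0, 3.0]

    def test_linearity_in_intensities(self, rng):
        data = rng.uniform(0, 1, size=(5, 5, 4))
        cube1, cube3 = make_cube(data), make_cube(3 * data)
        grid = rng.random((5, 5)) < 0.4
        grid[0, 0] = True
        mask = EggMask(grid=grid, egg_id="e")
        assert np.allclose(mean_spectrum(cube3, mask),
                           3 * mean_spectrum(cube1, mask))

    def test_shape_mismatch_rejected(self):
        cube = make_cube(np.ones((4, 4, 3)))
        mask = EggMask(grid=np.ones((3, 3), dtype=bool), egg_id="e")
        with pytest.raises(ValueError, match="shape"):
            mean_spectrum(cube, mask)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            EggMask(grid=np.zeros((2, 2), dtype=bool), egg_id="e")


def ellipse_frame(centers, axes=(5, 7), shape=(40, 60), value=1.0):
    rr, cc = np.mgrid[0:shape[0], 0:shape[1]]
    slice_ = np.zeros(shape)
    masks = []
    for r0, c0 in centers:
        m = ((rr - r0) / axes[0]) ** 2 + ((cc - c0) / axes[1]) ** 2 <= 1
        slice_[m] = value
        masks.append(m)
    return slice_, masks


class TestSegmentEggs:
    def test_four_ellipses_recovered_exactly(self):
        centers = [(10, 12), (10, 45), (29, 12), (29, 45)]
        slice_, truth = ellipse_frame(centers)
        cube = make_cube(np.repeat(slice_[:, :, None], 3, axis=2))
        masks = segment_eggs(cube, band_index=1, min_area=10)
        assert len(masks) == 4
        union = np.zeros_like(slice_, dtype=bool)
        for m in masks:
            match = max(truth, key=lambda t: (t & m.grid).sum())
            assert np.array_equal(m.grid, match)
            assert not (union & m.grid).any()  # pairwise disjoint
            union |= m.grid

    def test_uniform_slice_yields_empty_list_with_warning(self):
        cube = make_cube(np.ones((10, 10, 2)))
        with pytest.warns(UserWarning, match="blank frame"):
            assert segment_eggs(cube, band_index=1, min_area=1) == []

    def test_min_area_filters_small_specks(self):
        slice_, _ = ellipse_frame([(20, 30)], axes=(6, 8))
        slice_[0, 0] = 1.0  # single-pixel speck
        cube = make_cube(np.repeat(slice_[:, :, None], 2, axis=2))
        masks = segment_eggs(cube, band_index=1, min_area=5)
        assert len(masks) == 1
        assert all(m.pixel_count >= 5 for m in masks)

    def test_ordering_by_area_then_position(self):
        slice_ = np.zeros((20, 20))
        slice_[2:4, 2:6] = 1    # area 8, top-left first
        slice_[10:14, 10:14] = 1  # area 16, largest
        slice_[2:4, 12:16] = 1  # area 8, later in row-major order
        cube = make_cube(np.repeat(slice_[:, :, None], 2, axis=2))
        masks = segment_eggs(cube, band_index=1, min_area=1, max_eggs=10)
        areas = [m.pixel_count for m in masks]
        assert areas == [16, 8, 8]
        assert masks[1].grid[2, 2] and masks[2].grid[2, 12]

    def test_max_eggs_caps_output(self):
        centers = [(10, 12), (10, 45), (29, 12), (29, 45)]
        slice_, _ = ellipse_frame(centers)
        cube = make_cube(np.repeat(slice_[:, :, None], 2, axis=2))
        assert len(segment_eggs(cube, band_index=1, min_area=5, max_eggs=2)) == 2

    def test_punch_through_band_independence(self, rng):
        """One mask derived at the segmentation band applies verbatim to all
        bands: extraction never re-thresholds per band."""
        centers = [(10, 12)]
        slice_, truth = ellipse_frame(centers, axes=(6, 8))
        data = np.repeat(slice_[:, :, None], 4, axis=2)
        data[:, :, 2] *= 0.1  # a dim band would segment differently
        cube = make_cube(data)
        masks = segment_eggs(cube, band_index=1, min_area=5)
        spec = mean_spectrum(cube, masks[0])
        npix = truth[0].sum()
        assert spec[2] == pytest.approx(0.1 * data[truth[0], 0].sum() / npix)


class TestSpectrumSet:
    def test_round_trip_csv(self, tmp_path, small_spectra):
        path = tmp_path / "spectra.csv"
        small_spectra.to_csv(path)
        back = SpectrumSet.from_csv(path)
        assert np.allclose(back.X, small_spectra.X)
        assert back.y.tolist() == small_spectra.y.tolist()
        assert back.day == small_spectra.day

    def test_missing_columns_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("a,b\n1,2\n")
        with pytest.raises(ValueError, match="missing column"):
            SpectrumSet.from_csv(path)

    def test_extract_spectra_uses_cube_metadata_labels(self, rng):
        slice_, truth = ellipse_frame([(10, 12), (29, 45)], axes=(5, 7))
        data = np.repeat(slice_[:, :, None], 3, axis=2)
        cube = make_cube(data)
        cube.meta["egg_classes"] = ["fertile", "non-fertile"]
        masks = segment_eggs(cube, band_index=1, min_area=5)
        spectra = extract_spectra(cube, masks, day=1)
        assert spectra.n == 2
        assert set(spectra.y) == {"fertile", "non-fertile"}


def test_mask_run_length_round_trip():
    grid = np.zeros((5, 6), dtype=bool)
    grid[1, 1:4] = True
    grid[3, 0] = True
    grid[3, 5] = True
    mask = EggMask(grid=grid, egg_id="egg-1")
    rle = mask.to_rle()
    rebuilt = np.zeros_like(grid)
    for _, row in rle.iterrows():
        rebuilt[row["row"], row["col_start"]:row["col_end"] + 1] = True
    assert np.array_equal(rebuilt, grid)
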