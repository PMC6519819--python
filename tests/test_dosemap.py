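import json

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from estreamlab.dosemap import (
    DoseMap,
    DoseMapFormatError,
    drx_profile,
    isodose_area,
    isodose_areas,
    max_point,
    mean_dose_in_circle,
    read_dosemap,
    rebin,
    write_dosemap,
)
from conftest import gaussian_spot_map


def brute_circle_mean(dmap, center, radius_cm):
    """Independent double-loop pixel-center-in-circle oracle."""
    px = dmap.pixel_size / 10.0
    total, count = 0.0, 0
    for i in range(dmap.shape[0]):
        for j in range(dmap.shape[1]):
            d2 = ((i - center[0]) ** 2 + (j - center[1]) ** 2) * px * px
            if d2 <= radius_cm**2 + 1e-12:
                total += dmap.values[i, j]
                count += 1
    return total / count


class TestIO:
    def test_round_trip_is_bit_identical(self, tmp_path):
        rng = np.random.default_rng(5)
        dmap = DoseMap(rng.uniform(0, 200, (17, 23)), 0.75, (1.25, -3.5), "x")
        path = tmp_path / "map.txt"
        write_dosemap(dmap, path)
        back = read_dosemap(path)
        assert np.array_equal(back.values, dmap.values)
        assert back.pixel_size == dmap.pixel_size
        assert back.origin == dmap.origin

    def test_negative_value_rejected(self, tmp_path):
        path = tmp_path / "bad.txt"
        path.write_text(
            "pixel_size_mm=1.0\norigin_cm=0,0\nunits=cGy\n1 2\n-3 4\n"
        )
        with pytest.raises(DoseMapFormatError):
            read_dosemap(path)

    def test_missing_header_field_named(self, tmp_path):
        path = tmp_path / "bad.txt"
        path.write_text("pixel_size_mm=1.0\nunits=cGy\n1 2\n3 4\n")
        with pytest.raises(DoseMapFormatError, match="origin_cm"):
            read_dosemap(path)

    def test_image_import_75dpi_sidecar(self, tmp_path):
        import imageio.v3 as iio

        img = (np.arange(64, dtype=np.uint8).reshape(8, 8)) * 3
        path = tmp_path / "scan.png"
        iio.imwrite(path, img)
        (tmp_path / "scan.png.json").write_text(
            json.dumps({"dpi": 75, "cgy_per_level": 0.5})
        )
        dmap = read_dosemap(path, "image")
        assert dmap.pixel_size == pytest.approx(25.4 / 75, abs=1e-3)
        assert dmap.pixel_size == pytest.approx(0.3387, abs=1e-3)
        assert dmap.values.max() == pytest.approx(63 * 3 * 0.5)

    def test_image_without_sidecar_rejected(self, tmp_path):
        import imageio.v3 as iio

        path = tmp_path / "scan.png"
        iio.imwrite(path, np.zeros((4, 4), dtype=np.uint8))
        with pytest.raises(DoseMapFormatError, match="sidecar"):
            read_dosemap(path, "image")


class TestRebin:
    def test_constant_map_stays_constant(self):
        dmap = DoseMap(np.full((12, 12), 7.5), 1.0)
        out = rebin(dmap, 3.0)
        assert np.allclose(out.values, 7.5)
        assert out.pixel_size == 3.0

    def test_checkerboard_two_to_one(self):
        board = np.indices((8, 8)).sum(axis=0) % 2 * 100.0
        out = rebin(DoseMap(board, 1.0), 2.0)
        assert np.allclose(out.values, 50.0)

    def test_upsampling_rejected(self):
        with pytest.raises(ValueError):
            rebin(DoseMap(np.ones((4, 4)), 2.0), 1.0)

    @given(seed=st.integers(0, 100), factor=st.integers(2, 5))
    @settings(deadline=None, max_examples=25)
    def test_mean_preserved_over_covered_region(self, seed, factor):
        rng = np.random.default_rng(seed)
        n = factor * 6
        dmap = DoseMap(rng.uniform(0, 300, (n, n)), 1.0)
        out = rebin(dmap, float(factor))
        assert out.values.mean() == pytest.approx(dmap.values.mean(), rel=1e-6)

    def test_drx_stable_under_rebinning_of_smooth_map(self):
        fine = gaussian_spot_map(n=240, pixel_size=0.68)
        for new_px in (1.36, 2.0):
            coarse = rebin(fine, new_px)
            d_fine = drx_profile(fine).values
            d_coarse = drx_profile(coarse).values
            for a, b in zip(d_fine, d_coarse):
                assert b == pytest.approx(a, rel=0.02)


class TestMaxPoint:
    def test_single_hot_pixel(self):
        v = np.zeros((5, 5))
        v[3, 1] = 10.0
        assert max_point(DoseMap(v, 1.0)) == (3, 1)

    def test_tie_takes_first_row_major(self):
        v = np.zeros((4, 4))
        v[1, 2] = 5.0
        v[2, 0] = 5.0
        assert max_point(DoseMap(v, 1.0)) == (1, 2)

    def test_gaussian_spot_center_recovered(self, spot_map):
        assert max_point(spot_map) == (60, 55)


class TestCircleMean:
    def test_constant_map_any_radius(self):
        dmap = DoseMap(np.full((20, 20), 42.0), 1.36)
        for r in (0.5, 1.0, 3.0):
            assert mean_dose_in_circle(dmap, (10, 10), r) == pytest.approx(42.0)

    def test_delta_map_equals_dose_over_pixel_count(self):
        v = np.zeros((31, 31))
        v[15, 15] = 200.0
        dmap = DoseMap(v, 1.0)
        for r in (0.25, 0.3, 0.5):
            n_pix = sum(
                1
                for i in range(31)
                for j in range(31)
                if ((i - 15) ** 2 + (j - 15) ** 2) * 0.01 <= r**2 + 1e-12
            )
            assert mean_dose_in_circle(dmap, (15, 15), r) == pytest.approx(
                200.0 / n_pix
            )

    @given(seed=st.integers(0, 200))
    @settings(deadline=None, max_examples=20)
    def test_matches_double_loop_oracle_exactly(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(8, 40))
        dmap = DoseMap(rng.uniform(0, 300, (n, n)), float(rng.uniform(0.5, 2.0)))
        center = (int(rng.integers(0, n)), int(rng.integers(0, n)))
        radius = float(rng.uniform(0.2, 3.0))
        # identical pixel selection; the averages agree to float round-off
        assert mean_dose_in_circle(dmap, center, radius) == pytest.approx(
            brute_circle_mean(dmap, center, radius), rel=1e-12
        )

    def test_truncated_circle_uses_in_map_pixels_only(self):
        dmap = DoseMap(np.full((10, 10), 9.0), 1.0)
        assert mean_dose_in_circle(dmap, (0, 0), 2.0) == pytest.approx(9.0)


class TestDrxProfile:
    def test_constant_map_flat_profile(self):
        dmap = DoseMap(np.full((80, 80), 33.0), 1.36)
        prof = drx_profile(dmap)
        assert prof.radii == (1.0, 2.0, 3.0, 4.0)
        assert all(v == pytest.approx(33.0) for v in prof.values)

    def test_single_spot_profile_monotone_nonincreasing(self, spot_map):
        prof = drx_profile(spot_map)
        assert all(a >= b for a, b in zip(prof.values, prof.values[1:]))

    def test_single_radius_equals_circle_mean(self, spot_map):
        prof = drx_profile(spot_map, radii=(1.0,))
        assert prof.values[0] == pytest.approx(
            mean_dose_in_circle(spot_map, max_point(spot_map), 1.0)
        )

    def test_non_increasing_radii_rejected(self, spot_map):
        with pytest.raises(ValueError):
            drx_profile(spot_map, radii=(2.0, 1.0))


class TestIsodose:
    def test_constant_map_full_area(self):
        dmap = DoseMap(np.full((10, 10), 100.0), 1.36)
        assert isodose_area(dmap, 90.0) == pytest.approx(100 * 0.136**2)

    def test_threshold_above_max_gives_zero(self, spot_map):
        assert isodose_area(spot_map, 1e4) == 0.0

    def test_pixel_count_oracle_500_pixels(self):
        v = np.zeros((40, 40))
        v.ravel()[:500] = 120.0
        dmap = DoseMap(v, 1.36)
        assert isodose_area(dmap, 100.0) == pytest.approx(500 * 0.018496)
        assert isodose_area(dmap, 100.0) == pytest.approx(9.248, abs=1e-3)

    def test_two_level_step_map_by_hand(self):
        v = np.zeros((10, 10))
        v[:5, :] = 200.0  # 50 pixels
        v[5:, :5] = 120.0  # 25 pixels
        dmap = DoseMap(v, 2.0)
        px_area = 0.04
        assert isodose_area(dmap, 150.0) == pytest.approx(50 * px_area)
        assert isodose_area(dmap, 100.0) == pytest.approx(75 * px_area)

    def test_levels_non_increasing_on_any_map(self, spot_map):
        iso = isodose_areas(spot_map, 300.0)
        assert all(a >= b for a, b in zip(iso.areas, iso.areas[1:]))

    def test_bad_levels_rejected(self, spot_map):
        with pytest.raises(ValueError):
            isodose_areas(spot_map, 300.0, levels=(0.0, 0.5))


class TestTranspositionInvariance:
    def test_metrics_invariant_under_transpose(self):
        dmap = gaussian_spot_map(n=90, center_px=(40.0, 62.0))
        t = DoseMap(dmap.values.T.copy(), dmap.pixel_size)
        c = max_point(dmap)
        ct = max_point(t)
        assert ct == (c[1], c[0])
        for r in (1.0, 2.5):
            assert mean_dose_in_circle(dmap, c, r) == pytest.approx(
                mean_dose_in_circle(t, ct, r)
            )
        assert isodose_area(dmap, 50.0) == isodose_area(t, 50.0)
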