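"""Calibration, speckle filtering and masking."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from woodychange import Raster, apply_masks, calibrate_dn, enhanced_lee_filter
from woodychange.preprocessing import db_to_linear, linear_to_db


def make_raster(data, **kw):
    return Raster(np.asarray(data, dtype=float), **kw)


class TestCalibration:
    def test_known_dn_value(self):
        # Hand arithmetic: gamma0_dB = 20*log10(5000) - 83 = -9.0206 dB.
        expected_db = 20 * np.log10(5000.0) - 83.0
        expected_lin = 10 ** (expected_db / 10)
        img = calibrate_dn(make_raster([[5000.0]]))
        assert img.data[0, 0] == pytest.approx(expected_lin, rel=1e-9)
        assert img.data[0, 0] == pytest.approx(0.1253, rel=1e-3)
        assert expected_db == pytest.approx(-9.0206, abs=1e-4)

    def test_zero_dn_becomes_nodata(self):
        img = calibrate_dn(make_raster([[0.0, 100.0]]))
        assert np.isnan(img.data[0, 0]) and np.isfinite(img.data[0, 1])

    def test_zero_db_is_unit_linear(self):
        assert db_to_linear(0.0) == pytest.approx(1.0)

    def test_negative_dn_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            calibrate_dn(make_raster([[-5.0]]))

    def test_all_nodata_flagged_not_silent(self, caplog):
        with caplog.at_level("WARNING"):
            img = calibrate_dn(make_raster([[0.0, 0.0]]))
        assert img.n_valid == 0
        assert any("all-nodata" in r.message for r in caplog.records)

    @given(st.floats(min_value=1.0, max_value=1e5), st.floats(min_value=1.0, max_value=1e5))
    @settings(derandomize=True, max_examples=50)
    def test_calibration_monotone(self, dn1, dn2):
        g = calibrate_dn(make_raster([[dn1, dn2]])).data[0]
        if dn1 < dn2:
            assert g[0] < g[1]
        elif dn1 > dn2:
            assert g[0] > g[1]

    @given(st.floats(min_value=-40.0, max_value=10.0))
    @settings(derandomize=True, max_examples=50)
    def test_db_linear_roundtrip(self, db):
        assert linear_to_db(db_to_linear(db)) == pytest.approx(db, rel=1e-9, abs=1e-9)


class TestLeeFilter:
    def test_constant_image_unchanged(self):
        img = make_raster(np.full((11, 11), 0.05))
        out = enhanced_lee_filter(img, window=5, enl=60.0)
        np.testing.assert_allclose(out.data, 0.05, rtol=1e-12)

    def test_impulse_pulled_toward_window_mean(self):
        # Brute-force 5x5 window statistics at the impulse pixel.
        data = np.full((11, 11), 0.05)
        data[5, 5] = 0.12
        img = make_raster(data)
        out = enhanced_lee_filter(img, window=5, enl=60.0, damping=1.0)
        win = data[3:8, 3:8]
        m, sd = win.mean(), win.std()
        ci = sd / m
        cu = 1 / np.sqrt(60.0)
        cmax = np.sqrt(1 + 2 / 60.0)
        assert cu < ci < cmax  # a mild impulse sits in the blending regime
        w = np.exp(-1.0 * (ci - cu) / (cmax - ci))
        expected = m + w * (0.12 - m)
        assert out.data[5, 5] == pytest.approx(expected, rel=1e-9)
        assert 0.05 < out.data[5, 5] < 0.12

    def test_strong_point_target_preserved(self):
        # Above the upper coefficient-of-variation bound the enhanced
        # filter treats the pixel as a real point scatterer and keeps it.
        data = np.full((11, 11), 0.05)
        data[5, 5] = 0.5
        out = enhanced_lee_filter(make_raster(data), window=5, enl=60.0)
        assert out.data[5, 5] == pytest.approx(0.5)

    def test_variance_reduced_on_speckle_field(self, rng, sm):
        k, theta = 60.0, 0.05 / 60.0
        img = make_raster(rng.gamma(k, theta, (60, 60)))
        out = enhanced_lee_filter(img, window=5, enl=k)
        assert np.nanvar(out.data) < np.nanvar(img.data)

    def test_homogeneous_mean_preserved_within_1pct(self, rng):
        img = make_raster(rng.gamma(60.0, 0.05 / 60.0, (80, 80)))
        out = enhanced_lee_filter(img, window=5, enl=60.0)
        assert abs(np.nanmean(out.data) - np.nanmean(img.data)) / np.nanmean(img.data) < 0.01

    def test_nodata_excluded_and_propagated(self, rng):
        data = rng.gamma(60.0, 0.05 / 60.0, (20, 20))
        data[4, 4] = np.nan
        out = enhanced_lee_filter(make_raster(data), window=5, enl=60.0)
        assert np.isnan(out.data[4, 4])          # nodata stays nodata
        assert np.isfinite(out.data[4, 5])       # neighbours survive
        assert np.isfinite(out.data).sum() == np.isfinite(data).sum()

    @pytest.mark.parametrize("window", [4, 2])
    def test_even_window_rejected(self, window):
        with pytest.raises(ValueError, match="odd"):
            enhanced_lee_filter(make_raster(np.ones((9, 9))), window=window, enl=10)

    def test_window_larger_than_image_rejected(self):
        with pytest.raises(ValueError, match="larger"):
            enhanced_lee_filter(make_raster(np.ones((3, 3))), window=5, enl=10)


class TestMasks:
    def test_empty_mask_list_identity(self):
        img = make_raster(np.ones((4, 4)))
        out, n = apply_masks(img, [])
        np.testing.assert_array_equal(out.data, img.data)
        assert n == 0

    def test_all_true_mask_warns(self, caplog):
        img = make_raster(np.ones((4, 4)))
        with caplog.at_level("WARNING"):
            out, n = apply_masks(img, [np.ones((4, 4), dtype=bool)])
        assert out.n_valid == 0 and n == 16
        assert any("every valid pixel" in r.message for r in caplog.records)

    def test_overlapping_masks_union(self):
        # 10 and 12 pixels sharing 4 -> 18 newly invalid (set union).
        img = make_raster(np.ones((5, 10)))
        m1 = np.zeros((5, 10), dtype=bool)
        m2 = np.zeros((5, 10), dtype=bool)
        m1.ravel()[:10] = True
        m2.ravel()[6:18] = True
        assert (m1 & m2).sum() == 4
        out, n = apply_masks(img, [m1, m2])
        assert n == 18
        assert out.n_valid == 50 - 18

    def test_masking_never_unmasks(self, rng):
        data = rng.random((6, 6))
        data[0, 0] = np.nan
        img = make_raster(data)
        out, _ = apply_masks(img, [rng.random((6, 6)) > 0.5])
        assert np.all(out.valid <= img.valid)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            apply_masks(make_raster(np.ones((4, 4))), [np.ones((3, 3), dtype=bool)])


class TestAsciiIO:
    def test_roundtrip_preserves_values_and_nodata(self, tmp_path, rng):
        data = rng.random((7, 5))
        data[2, 3] = np.nan
        img = Raster(data, pixel_size=25.0, origin=(100.0, 200.0))
        path = tmp_path / "g.asc"
        img.write_ascii(path)
        back = Raster.read_ascii(path)
        np.testing.assert_allclose(back.data, img.data, rtol=1e-6, equal_nan=True)
        assert back.pixel_size == 25.0
        assert back.origin == (100.0, 200.0)
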