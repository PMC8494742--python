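"""Congestion detector: gamma correction, vessel extraction, calibers, rules."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from octaquant import (CongestionParams, EnFaceAngiogram, FULL_SCALE_16,
                       RegionMask, detect_congestion, estimate_calibers,
                       extract_vessels, gamma_correct, load_mask, save_mask)
from scipy import ndimage as ndi


def _angio(px, layer="DCP"):
    return EnFaceAngiogram(np.asarray(px, dtype=np.uint16), layer=layer)


def _mask(name, px):
    return RegionMask(name, np.asarray(px, dtype=bool))


class TestGammaCorrect:
    def test_endpoints_preserved_for_any_gamma(self):
        img = np.array([[0, FULL_SCALE_16]], dtype=np.uint16)
        for gamma in (0.5, 1.0, 3.0, 10.0):
            out = gamma_correct(img, gamma)
            assert out[0, 0] == 0 and out[0, 1] == FULL_SCALE_16

    def test_midpoint_closed_form(self):
        out = gamma_correct(np.array([[32768]], dtype=np.uint16), 3.0)
        assert out[0, 0] == round(FULL_SCALE_16 * (32768 / FULL_SCALE_16) ** (1 / 3))

    def test_gamma_one_is_identity(self):
        rng = np.random.default_rng(0)
        img = rng.integers(0, FULL_SCALE_16 + 1, (32, 32)).astype(np.uint16)
        assert np.array_equal(gamma_correct(img, 1.0), img)

    def test_invalid_gamma_rejected(self):
        with pytest.raises(ValueError):
            gamma_correct(np.zeros((2, 2), np.uint16), 0.0)

    @given(st.integers(0, FULL_SCALE_16), st.integers(0, FULL_SCALE_16),
           st.floats(0.1, 10.0))
    def test_monotone_in_input(self, a, b, gamma):
        lo, hi = sorted((a, b))
        out = gamma_correct(np.array([[lo, hi]], dtype=np.uint16), gamma)
        assert out[0, 0] <= out[0, 1]


class TestExtractVessels:
    def test_zero_image_gives_empty_mask_with_warning(self):
        with pytest.warns(UserWarning, match="empty"):
            mask = extract_vessels(_angio(np.zeros((32, 32))))
        assert not mask.any()

    def test_zero_threshold_keeps_everything(self):
        mask = extract_vessels(_angio(np.zeros((16, 16))),
                               CongestionParams(vessel_threshold=0))
        assert mask.all()

    def test_phantom_network_recovered(self, phantom_case):
        vessels = extract_vessels(phantom_case.dcp)
        truth = phantom_case.truth.vessel_raster_dcp
        iou = (vessels & truth).sum() / (vessels | truth).sum()
        assert iou >= 0.9


class TestEstimateCalibers:
    def test_ribbon_width_five(self):
        px = np.zeros((30, 120), bool)
        px[10:15, 10:110] = True
        cal = estimate_calibers(px)
        interior = cal[:, 30:90]
        vals = interior[np.isfinite(interior)]
        assert vals.size
        assert np.all(np.abs(vals - 5.0) <= 0.5)

    def test_single_pixel_line(self):
        px = np.zeros((20, 60), bool)
        px[10, 5:55] = True
        cal = estimate_calibers(px)
        vals = cal[np.isfinite(cal)]
        assert np.all((vals >= 0.9) & (vals <= 2.0))

    def test_disc_maximum_is_diameter(self):
        r = 12
        yy, xx = np.mgrid[-20:21, -20:21]
        px = yy ** 2 + xx ** 2 <= r ** 2
        cal = estimate_calibers(px)
        assert np.nanmax(cal) == pytest.approx(2 * r, abs=1.5)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            estimate_calibers(np.zeros((8, 8), bool))


def _corridor_image(g=120, bright=0.8, width=5, deep=False):
    """Tiny synthetic: abnormal left half, one thick bright vessel.

    The vessel sits at the abnormal/normal interface, or deep inside the
    abnormal region when ``deep``.
    """
    img = np.zeros((g, g))
    abnormal = np.zeros((g, g), bool)
    abnormal[:, :g // 2] = True
    col = g // 2 - 8 if not deep else 8
    vessel = np.zeros((g, g), bool)
    vessel[10:g - 10, col - width // 2:col + width // 2 + 1] = True
    img[vessel] = bright
    faz = np.zeros((g, g), bool)
    return (_angio(np.round(img * FULL_SCALE_16)), _mask("DCP-A", abnormal),
            _mask("DCP-FAZ", faz), vessel)


class TestDetectCongestion:
    def test_dim_thin_network_yields_empty_mask(self):
        # 1-px dim lines: no criterion satisfiable
        g = 80
        img = np.zeros((g, g))
        for row in range(10, 70, 12):
            img[row, 5:75] = 0.08  # gamma-corrected ~43% < bright threshold
        abnormal = np.zeros((g, g), bool)
        abnormal[:, :40] = True
        out = detect_congestion(
            _angio(np.round(img * FULL_SCALE_16)),
            _mask("DCP-A", abnormal), _mask("DCP-FAZ", np.zeros((g, g), bool)),
            CongestionParams(vessel_threshold=20000))
        assert out.count() == 0

    def test_bright_corridor_at_interface_detected(self):
        img, abnormal, faz, vessel = _corridor_image()
        out = detect_congestion(img, abnormal, faz)
        iou = (out.pixels & vessel).sum() / (out.pixels | vessel).sum()
        assert iou >= 0.8

    def test_corridor_deep_inside_npa_excluded_with_tight_band(self):
        img, abnormal, faz, _ = _corridor_image(deep=True)
        out = detect_congestion(img, abnormal, faz,
                                CongestionParams(boundary_band_px=0))
        assert out.count() == 0

    def test_phantom_iou(self, phantom_case):
        truth = phantom_case.truth.masks
        out = detect_congestion(phantom_case.dcp, truth["DCP-A"],
                                truth["DCP-FAZ"])
        gt = truth["DCP-C"].pixels
        iou = (out.pixels & gt).sum() / (out.pixels | gt).sum()
        assert iou >= 0.8

    def test_never_in_faz_and_inside_vessel_dilation(self, phantom_case):
        truth = phantom_case.truth.masks
        out = detect_congestion(phantom_case.dcp, truth["DCP-A"],
                                truth["DCP-FAZ"])
        assert not (out.pixels & truth["DCP-FAZ"].pixels).any()
        vessels = extract_vessels(phantom_case.dcp)
        dilated = ndi.binary_dilation(vessels, np.ones((3, 3)))
        assert (out.pixels <= dilated).all()

    def test_anti_monotone_in_bright_threshold(self, phantom_case):
        truth = phantom_case.truth.masks
        low = detect_congestion(phantom_case.dcp, truth["DCP-A"],
                                truth["DCP-FAZ"],
                                CongestionParams(bright_threshold=30000))
        high = detect_congestion(phantom_case.dcp, truth["DCP-A"],
                                 truth["DCP-FAZ"],
                                 CongestionParams(bright_threshold=60000))
        assert (high.pixels <= low.pixels).all()

    def test_grid_mismatch_rejected(self):
        from octaquant import GridMismatchError
        with pytest.raises(GridMismatchError):
            detect_congestion(_angio(np.zeros((16, 16))),
                              _mask("DCP-A", np.zeros((8, 8), bool)),
                              _mask("DCP-FAZ", np.zeros((16, 16), bool)))


class TestMaskIO:
    def test_random_round_trip(self, tmp_path):
        rng = np.random.default_rng(8)
        mask = _mask("SCP-C", rng.random((64, 64)) < 0.5)
        save_mask(mask, tmp_path / "m.png")
        back = load_mask(tmp_path / "m.png", "SCP-C")
        assert np.array_equal(back.pixels, mask.pixels)

    def test_all_false_round_trip(self, tmp_path):
        mask = _mask("SCP-FAZ", np.zeros((16, 16)))
        save_mask(mask, tmp_path / "z.png")
        assert not load_mask(tmp_path / "z.png", "SCP-FAZ").pixels.any()

    def test_255_reads_true(self, tmp_path):
        import imageio.v3 as iio
        arr = np.zeros((8, 8), np.uint8)
        arr[2, 3] = 255
        arr[5, 5] = 7  # any nonzero pixel reads TRUE
        iio.imwrite(tmp_path / "raw.png", arr)
        back = load_mask(tmp_path / "raw.png", "DCP-C")
        expected = arr != 0
        assert np.array_equal(back.pixels, expected)

    def test_wrong_shape_rejected(self, tmp_path):
        from octaquant import GridMismatchError
        mask = _mask("TZ", np.zeros((8, 8)))
        save_mask(mask, tmp_path / "m.png")
        with pytest.raises(GridMismatchError):
            load_mask(tmp_path / "m.png", "TZ", expected_shape=(16, 16))
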