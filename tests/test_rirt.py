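"""RIRT mapping: ratio field, ME territory, apexes, recurrence rule."""

import math

import numpy as np
import pytest

from octaquant import (RegionMask, RirtError, ScalarMap, classify_recurrence,
                       compute_rirt, locate_apexes, me_territory,
                       rirt_summary)


def _smap(vals):
    return ScalarMap(np.asarray(vals, dtype=float), units="um")


def _mask(name, px):
    return RegionMask(name, np.asarray(px, dtype=bool))


def _blob_field(g=200, center=(100, 100), peak=1.5, radius=60.0):
    jj, ii = np.meshgrid(np.arange(g), np.arange(g))
    r = np.hypot(ii - center[0], jj - center[1])
    field = np.ones((g, g))
    inside = r <= radius
    field[inside] = 1 + (peak - 1) * 0.5 * (1 + np.cos(math.pi * r[inside] / radius))
    return field, r


class TestComputeRirt:
    def test_identical_maps_give_unity(self):
        vals = np.full((16, 16), 250.0)
        rirt, valid = compute_rirt(_smap(vals), _smap(vals))
        assert valid.all()
        np.testing.assert_allclose(rirt, 1.0)

    def test_constant_ratio(self):
        rirt, _ = compute_rirt(_smap(np.full((8, 8), 200.0)),
                               _smap(np.full((8, 8), 300.0)))
        np.testing.assert_allclose(rirt, 1.5)

    def test_matches_elementwise_division_loop(self):
        rng = np.random.default_rng(6)
        base = rng.uniform(150, 350, (16, 16))
        follow = rng.uniform(150, 450, (16, 16))
        rirt, _ = compute_rirt(_smap(base), _smap(follow))
        for i in range(16):
            for j in range(16):
                assert rirt[i, j] == follow[i, j] / base[i, j]

    def test_too_many_zero_baseline_pixels_raises(self):
        base = np.full((10, 10), 250.0)
        base[:2] = 0.0  # 20% of overlap
        with pytest.raises(RirtError):
            compute_rirt(_smap(base), _smap(np.full((10, 10), 300.0)))

    def test_few_zero_pixels_excluded_with_warning(self):
        base = np.full((10, 10), 250.0)
        base[0, 0] = 0.0
        with pytest.warns(UserWarning, match="zero-baseline"):
            rirt, valid = compute_rirt(_smap(base),
                                       _smap(np.full((10, 10), 300.0)))
        assert not valid[0, 0] and np.isnan(rirt[0, 0])


class TestMeTerritory:
    def test_unity_field_gives_empty_territory(self):
        rirt = np.ones((16, 16))
        territory, contours = me_territory(rirt, np.ones((16, 16), bool))
        assert not territory.any() and contours == []

    def test_exact_threshold_pixel_excluded(self):
        rirt = np.ones((8, 8))
        rirt[4, 4] = 1.1  # exactly at the cut: strict >
        territory, _ = me_territory(rirt, np.ones((8, 8), bool), threshold=1.1)
        assert not territory.any()

    def test_blob_matches_analytic_superlevel_disc(self):
        """Raised-cosine blob: territory = closed-form disc ± 1-px band."""
        peak, radius = 1.5, 60.0
        field, r = _blob_field(peak=peak, radius=radius)
        territory, contours = me_territory(field, np.ones(field.shape, bool))
        # closed form: ratio > 1.1  <=>  r < R·acos(2·0.1/(peak−1) − 1)/π
        r_star = radius * math.acos(2 * 0.1 / (peak - 1) - 1) / math.pi
        analytic = r < r_star
        boundary_band = np.abs(r - r_star) <= 1.0
        assert not ((territory ^ analytic) & ~boundary_band).any()
        assert len(contours) == 1

    def test_monotone_nesting_in_threshold(self):
        field, _ = _blob_field()
        valid = np.ones(field.shape, bool)
        t_low, _ = me_territory(field, valid, threshold=1.1)
        t_high, _ = me_territory(field, valid, threshold=1.3)
        assert (t_high <= t_low).all()

    def test_threshold_must_exceed_one(self):
        with pytest.raises(ValueError):
            me_territory(np.ones((4, 4)), np.ones((4, 4), bool), threshold=0.9)


class TestLocateApexes:
    def test_blob_in_faz_labeled_faz_at_center(self):
        field, r = _blob_field(center=(100, 100))
        valid = np.ones(field.shape, bool)
        territory, _ = me_territory(field, valid)
        faz = _mask("DCP-FAZ", r <= 30)
        abnormal = _mask("DCP-A", np.zeros_like(valid))
        apexes = locate_apexes(field, valid, territory, faz, abnormal)
        assert len(apexes) == 1
        apex = apexes[0]
        assert apex.label == "FAZ"
        assert abs(apex.row - 100) <= 1 and abs(apex.col - 100) <= 1

    def test_two_equal_blobs_ordered_by_raster_position(self):
        g = 220
        f1, _ = _blob_field(g, center=(60, 60), peak=1.4, radius=40)
        f2, _ = _blob_field(g, center=(160, 160), peak=1.4, radius=40)
        field = np.maximum(f1, f2)
        valid = np.ones((g, g), bool)
        territory, _ = me_territory(field, valid)
        zeros = np.zeros((g, g), bool)
        apexes = locate_apexes(field, valid, territory, _mask("DCP-FAZ", zeros),
                               _mask("DCP-A", zeros))
        assert len(apexes) == 2
        assert (apexes[0].row, apexes[0].col) == (60, 60)
        assert all(a.label == "other" for a in apexes)

    def test_blob_in_abnormal_region_labeled_npa(self):
        field, r = _blob_field(center=(100, 100))
        valid = np.ones(field.shape, bool)
        territory, _ = me_territory(field, valid)
        abnormal = np.zeros_like(valid)
        abnormal[80:120, 80:120] = True
        apexes = locate_apexes(field, valid, territory,
                               _mask("DCP-FAZ", np.zeros_like(valid)),
                               _mask("DCP-A", abnormal))
        assert apexes[0].label == "NPA"

    def test_empty_territory_gives_no_apexes(self):
        valid = np.ones((16, 16), bool)
        out = locate_apexes(np.ones((16, 16)), valid,
                            np.zeros((16, 16), bool),
                            _mask("DCP-FAZ", np.zeros((16, 16))),
                            _mask("DCP-A", np.zeros((16, 16))))
        assert out == []


class TestRirtSummary:
    def test_constant_field(self):
        rirt = np.full((16, 16), 1.25)
        valid = np.ones((16, 16), bool)
        territory = np.ones((16, 16), bool)
        dcp_c = _mask("DCP-C", np.ones((16, 16)))
        s = rirt_summary(rirt, valid, territory, dcp_c)
        assert (s.mean_territory, s.max_territory) == (1.25, 1.25)
        assert (s.mean_dcp_c, s.max_dcp_c) == (1.25, 1.25)

    def test_empty_dcp_c_flagged_undefined(self):
        rirt = np.full((8, 8), 1.2)
        s = rirt_summary(rirt, np.ones((8, 8), bool), np.ones((8, 8), bool),
                         _mask("DCP-C", np.zeros((8, 8))))
        assert math.isnan(s.mean_dcp_c) and math.isnan(s.max_dcp_c)

    def test_territory_max_dominates_any_subset(self):
        rng = np.random.default_rng(2)
        rirt = 1.0 + rng.random((32, 32))
        valid = np.ones((32, 32), bool)
        territory = rirt > 1.1
        subset = territory & (rng.random((32, 32)) < 0.5)
        if subset.any():
            s_t = rirt_summary(rirt, valid, territory,
                               _mask("DCP-C", subset))
            assert s_t.max_territory >= s_t.max_dcp_c


class TestClassifyRecurrence:
    @pytest.mark.parametrize("base,follow,expected", [
        (300.0, 330.0, True),    # exact 10% boundary is inclusive
        (226.4, 362.2, True),
        (250.0, 250.0, False),
        (250.0, 274.9, False),
        (200.0, 220.0, True),
    ])
    def test_rule(self, base, follow, expected):
        assert classify_recurrence(base, follow) is expected

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            classify_recurrence(0.0, 300.0)


def test_phantom_territory_matches_generator_truth(identity_motion_case):
    """End-to-end ratio → territory reproduces the generating edema field."""
    case = identity_motion_case
    rirt, valid = compute_rirt(case.thickness_baseline,
                               case.thickness_followup)
    territory, _ = me_territory(rirt, valid)
    truth = case.truth.true_edema_territory
    cfg = case.config
    r_star = cfg.edema.territory_radius_px(1.1, cfg.pixel_pitch_um)
    g = cfg.grid_size
    jj, ii = np.meshgrid(np.arange(g), np.arange(g))
    c = (g - 1) / 2.0
    r = np.hypot(ii - c, jj - c)
    band = np.abs(r - r_star) <= 1.0
    assert not ((territory ^ truth) & ~band).any()
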