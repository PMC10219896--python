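"""ROI-mean two-point relaxometry estimators and per-slice markers."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import mrnquant as mq
from mrnquant.errors import (EmptyROIError, IncompleteCoverageError,
                             InvalidParameterError)

from conftest import homogeneous_volume


class TestRoiMeanSignals:
    def test_homogeneous_roi(self):
        vol, mask = homogeneous_volume(100.0, 50.0)
        assert mq.roi_mean_signals(vol, mask, 0) == (100.0, 50.0)

    def test_two_pixel_roi_mean(self):
        vol, mask = homogeneous_volume(0.0, 0.0, shape=(2, 1, 1))
        vol.image_te1[:, 0, 0] = [80.0, 120.0]
        vol.image_te2[:, 0, 0] = [40.0, 60.0]
        si1, si2 = mq.roi_mean_signals(vol, mask, 0)
        assert si1 == 100.0 and si2 == 50.0

    def test_empty_mask_slice_names_slice(self):
        vol, mask = homogeneous_volume()
        mask.mask[:, :, 1] = False
        with pytest.raises(EmptyROIError, match="slice 1"):
            mq.roi_mean_signals(vol, mask, 1)

    def test_forward_generated_slice_means(self, small_protocol):
        import dataclasses
        params = dataclasses.replace(mq.CASE_PARAMS.zero_sd(),
                                     t2_thigh=60.0, rho_thigh=400.0)
        cfg = dataclasses.replace(
            mq.CohortConfig(n_case=1, n_control=1), case=params).noise_free()
        part = mq.generate_participant(small_protocol, cfg, "case", seed=0)
        si1, si2 = mq.roi_mean_signals(part.volumes[0], part.masks[0], 0)
        assert si1 == pytest.approx(400 * math.exp(-14 / 60), rel=1e-12)
        assert si2 == pytest.approx(400 * math.exp(-86 / 60), rel=1e-12)


class TestT2FromSignals:
    def test_log_ratio_of_e_gives_te_difference(self):
        assert mq.t2app_from_signals(100 * math.e, 100, 14, 86) == \
            pytest.approx(72.0, rel=1e-12)

    def test_equal_signals_flagged_undefined(self):
        assert math.isnan(mq.t2app_from_signals(100.0, 100.0, 14, 86))
        assert math.isnan(mq.t2app_from_signals(90.0, 100.0, 14, 86))

    def test_nonpositive_signals_raise(self):
        with pytest.raises(InvalidParameterError):
            mq.t2app_from_signals(0.0, 50.0, 14, 86)
        with pytest.raises(InvalidParameterError):
            mq.t2app_from_signals(100.0, -1.0, 14, 86)

    def test_round_trip_at_reported_group_mean(self):
        t2 = 66.1
        s1 = mq.predict_signal(473.2, t2, 14)
        s2 = mq.predict_signal(473.2, t2, 86)
        assert mq.t2app_from_signals(s1, s2, 14, 86) == pytest.approx(
            t2, rel=1e-12)

    @given(si2=st.floats(1.0, 99.0))
    def test_strictly_increasing_in_si2(self, si2):
        t2a = mq.t2app_from_signals(100.0, si2, 14, 86)
        t2b = mq.t2app_from_signals(100.0, si2 + 0.5, 14, 86)
        assert t2b > t2a


class TestRhoFromSignals:
    def test_infinite_t2_limit_is_uncorrected_signal(self):
        assert mq.rho_from_signals(100.0, 1e12, 14.0) == pytest.approx(
            100.0, rel=1e-9)

    def test_direct_evaluation(self):
        assert mq.rho_from_signals(100.0, 72.0, 14.0) == pytest.approx(
            100 * math.exp(14 / 72), rel=1e-12)  # ~121.466

    def test_round_trip_at_reported_group_mean(self):
        rho = 473.2
        s1 = mq.predict_signal(rho, 66.1, 14)
        s2 = mq.predict_signal(rho, 66.1, 86)
        t2 = mq.t2app_from_signals(s1, s2, 14, 86)
        assert mq.rho_from_signals(s1, t2, 14) == pytest.approx(rho, rel=1e-12)

    def test_undefined_t2_propagates(self):
        assert math.isnan(mq.rho_from_signals(100.0, math.nan, 14.0))


class TestT2wAndCsa:
    def test_t2w_is_long_echo_roi_mean(self):
        vol, mask = homogeneous_volume(200.0, 111.3)
        assert mq.t2w_signal(vol, mask, 0) == pytest.approx(111.3, rel=1e-14)

    def test_single_pixel_mask(self):
        vol, mask = homogeneous_volume(200.0, 0.0)
        vol.image_te2[3, 4, 0] = 77.0
        mask.mask[:] = False
        mask.mask[3, 4, 0] = True
        assert mq.t2w_signal(vol, mask, 0) == 77.0

    def test_csa_pixel_count_times_spacing_squared(self):
        _, mask = homogeneous_volume(shape=(5, 4, 1))
        mask.mask[:] = False
        mask.mask[:2, :, 0] = True  # 8 px
        mask.mask[2, :2, 0] = True  # +2 px
        assert mq.csa(mask, 0, pixel_spacing=1.0) == 10.0
        assert mq.csa(mask, 0, pixel_spacing=170 / 512) * 10 == pytest.approx(
            11.0245, abs=5e-5)  # 100 px at the study spacing

    def test_synthetic_disc_area_close_to_circle(self):
        # rasterized disc area tracks pi*r^2 up to lattice (Gauss-circle)
        # error, a few pixels at this radius
        sp = 170 / 512
        r, count = mq.disc_radius_for_area(17.3, sp, (85.0, 85.1), 512)
        assert count * sp ** 2 == pytest.approx(math.pi * r ** 2,
                                                abs=3 * sp ** 2)


class TestSliceAndProfile:
    def test_scale_equivariance(self):
        vol, mask = homogeneous_volume(120.0, 60.0)
        base = mq.measure_slice(vol, mask, 0)
        c = 3.7
        vol2, mask2 = homogeneous_volume(120.0 * c, 60.0 * c)
        scaled = mq.measure_slice(vol2, mask2, 0)
        assert scaled.t2_app == pytest.approx(base.t2_app, rel=1e-12)
        assert scaled.rho == pytest.approx(base.rho * c, rel=1e-12)
        assert scaled.t2w_signal == pytest.approx(base.t2w_signal * c,
                                                  rel=1e-12)

    def test_roi_first_equals_pixelwise_on_homogeneous_roi(self):
        vol, mask = homogeneous_volume(150.0, 40.0)
        roi = mq.measure_slice(vol, mask, 0, pixelwise=False)
        px = mq.measure_slice(vol, mask, 0, pixelwise=True)
        assert px.t2_app == pytest.approx(roi.t2_app, rel=1e-12)
        assert px.rho == pytest.approx(roi.rho, rel=1e-12)

    def test_nonphysical_slice_flagged_not_dropped(self):
        vol, mask = homogeneous_volume(50.0, 80.0)  # "rising" signal
        m = mq.measure_slice(vol, mask, 0)
        assert not m.valid and math.isnan(m.t2_app) and math.isnan(m.rho)
        assert m.csa > 0 and m.t2w_signal == 80.0

    def test_formula_round_trip_thousand_random_pairs(self):
        rng = np.random.default_rng(123)
        rho = rng.uniform(50, 1000, size=1000)
        t2 = rng.uniform(20, 150, size=1000)
        s1 = mq.predict_signal(rho, t2, 14.0)
        s2 = mq.predict_signal(rho, t2, 86.0)
        t2_hat = 72.0 / np.log(s1 / s2)
        rho_hat = s1 * np.exp(14.0 / t2_hat)
        assert np.max(np.abs(t2_hat - t2) / t2) < 1e-10
        assert np.max(np.abs(rho_hat - rho) / rho) < 1e-10

    def test_profile_flag_conservation_and_ordering(self, noise_free_frames):
        slices = noise_free_frames["slices"]
        profiles = mq.profiles_from_frame(slices)
        for p in profiles:
            assert p.n_valid + p.n_flagged == len(p.measurements)
            left = [m.slice_index for m in p.side("left")]
            assert left == sorted(left)

    def test_missing_slab_raises(self, small_protocol):
        cfg = mq.CohortConfig(n_case=1, n_control=1).noise_free()
        part = mq.generate_participant(small_protocol, cfg, "case", seed=0)
        with pytest.raises(IncompleteCoverageError, match=r"\[3\]"):
            mq.compute_profile(part.volumes[:2], part.masks[:2], "p",
                               expected_left_slabs=[1, 2, 3])
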