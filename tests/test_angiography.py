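"""En-face workflow: projection, registration, binarization, FAZ, density."""

import numpy as np
import pytest

from octa_compare import angiography as ang
from octa_compare.datamodel import (EnFaceAngiogram, LayerMask,
                                    ScanPatternConfig, ScanVolume)
from octa_compare.errors import (DegenerateInputError, RegistrationError,
                                 ValidationError)
from octa_compare.synth import build_vascular_pattern, render_angiogram


def _volume(data):
    data = np.asarray(data, dtype=float)
    cfg = ScanPatternConfig(device="SS", pattern_name="3x3mm",
                            n_fast=data.shape[0], n_slow=data.shape[1],
                            lateral_spacing=3000.0 / data.shape[0], repeats=4,
                            n_depth=data.shape[2])
    return ScanVolume(intensities=data, config=cfg)


def _angio(image, spacing, device):
    return EnFaceAngiogram(image=image, lateral_spacing=spacing,
                           device=device, layer_name="retina")


@pytest.fixture(scope="module")
def pattern():
    return build_vascular_pattern(seed=11, field_width_mm=3.0, spacing_um=4.0)


@pytest.fixture(scope="module")
def paired_angiograms(pattern):
    cfg_sd = ScanPatternConfig(device="SD", pattern_name="3x3mm", n_fast=245,
                               n_slow=245, lateral_spacing=12.2, repeats=4)
    cfg_ss = ScanPatternConfig(device="SS", pattern_name="3x3mm", n_fast=300,
                               n_slow=300, lateral_spacing=10.0, repeats=4)
    return (render_angiogram(pattern, cfg_sd, seed=1, noise_sd=0.03),
            render_angiogram(pattern, cfg_ss, seed=2, noise_sd=0.03))


class TestMaxIntensityProjection:
    def test_single_bright_voxel_per_column(self, rng):
        data = np.zeros((4, 4, 8))
        for i in range(4):
            for j in range(4):
                data[i, j, rng.integers(0, 8)] = 7.0
        mask = LayerMask(mask=np.ones((4, 4, 8), dtype=bool),
                         layer_name="superficial_retina")
        out = ang.max_intensity_projection(_volume(data), mask)
        np.testing.assert_allclose(out.image, 7.0)

    def test_unmasked_column_projects_to_zero(self):
        data = np.full((3, 3, 4), 2.0)
        mask = np.ones((3, 3, 4), dtype=bool)
        mask[1, 1, :] = False
        out = ang.max_intensity_projection(
            _volume(data), LayerMask(mask=mask, layer_name="deep_retina"))
        assert out.image[1, 1] == 0.0
        assert out.image[0, 0] == 2.0

    def test_matches_per_column_brute_force(self, rng):
        data = rng.random((4, 4, 8))
        mask = rng.random((4, 4, 8)) < 0.5
        mask[0, 0, 3] = True
        out = ang.max_intensity_projection(
            _volume(data), LayerMask(mask=mask, layer_name="deep_retina"))
        for i in range(4):
            for j in range(4):
                masked = [data[i, j, k] for k in range(8) if mask[i, j, k]]
                expected = max(masked) if masked else 0.0
                assert out.image[i, j] == pytest.approx(expected)

    def test_empty_mask_rejected(self):
        mask = LayerMask(mask=np.zeros((3, 3, 4), dtype=bool),
                         layer_name="deep_retina")
        with pytest.raises(DegenerateInputError):
            ang.max_intensity_projection(_volume(np.ones((3, 3, 4))), mask)


class TestRegistration:
    def test_self_registration_is_identity(self, paired_angiograms):
        _, a_ss = paired_angiograms
        twin = _angio(a_ss.image.copy(), a_ss.lateral_spacing, "SD")
        roi = ang.register_angiograms(twin, a_ss)
        half_px = a_ss.lateral_spacing / 2000.0
        assert abs(roi.shift_mm[0]) <= half_px
        assert abs(roi.shift_mm[1]) <= half_px
        assert roi.correlation > 0.99
        assert roi.radius_mm > 1.0

    def test_known_pixel_shift_recovered(self, paired_angiograms):
        _, a_ss = paired_angiograms
        shifted = np.roll(np.roll(a_ss.image, 5, axis=0), 3, axis=1)
        moved = _angio(shifted, a_ss.lateral_spacing, "SD")
        roi = ang.register_angiograms(moved, a_ss)
        px = a_ss.lateral_spacing / 1000.0
        assert roi.shift_mm[0] == pytest.approx(-5 * px, abs=px)
        assert roi.shift_mm[1] == pytest.approx(-3 * px, abs=px)

    def test_unrelated_noise_fails(self, rng):
        a = _angio(rng.random((200, 200)), 10.0, "SD")
        b = _angio(rng.random((200, 200)), 10.0, "SS")
        with pytest.raises(RegistrationError):
            ang.register_angiograms(a, b)

    def test_cross_device_registration_of_same_pattern(self,
                                                       paired_angiograms):
        a_sd, a_ss = paired_angiograms
        roi = ang.register_angiograms(a_sd, a_ss)
        assert roi.correlation > 0.5
        assert abs(roi.shift_mm[0]) < 0.05 and abs(roi.shift_mm[1]) < 0.05
        assert 1.0 < roi.radius_mm <= 1.5


class TestBinarization:
    @staticmethod
    def _roi(radius=1.0):
        return ang.CommonCircularROI(center_sd_mm=(0, 0), center_ss_mm=(0, 0),
                                     radius_mm=radius, shift_mm=(0, 0),
                                     correlation=1.0)

    def test_separable_classes_recovered_exactly(self, rng):
        truth = rng.random((100, 100)) < 0.4
        a = _angio(truth.astype(float), 20.0, "SS")
        b = ang.binarize_vessels(a, self._roi())
        np.testing.assert_array_equal(b.vessel_map,
                                      truth & b.roi_mask)

    def test_constant_roi_rejected(self):
        a = _angio(np.full((50, 50), 3.0), 20.0, "SS")
        with pytest.raises(DegenerateInputError):
            ang.binarize_vessels(a, self._roi(radius=0.4))

    def test_gaussian_classes_misclassified_below_one_percent(self, rng):
        truth = rng.random((200, 200)) < 0.45
        image = np.where(truth, rng.normal(0.8, 0.05, truth.shape),
                         rng.normal(0.2, 0.05, truth.shape))
        a = _angio(np.clip(image, 0, None), 10.0, "SS")
        b = ang.binarize_vessels(a, self._roi())
        inside = b.roi_mask
        err = (b.vessel_map[inside] != truth[inside]).mean()
        assert err < 0.01

    def test_affine_rescaling_leaves_result_invariant(self, rng):
        truth = rng.random((120, 120)) < 0.45
        image = np.where(truth, rng.normal(0.8, 0.05, truth.shape),
                         rng.normal(0.2, 0.05, truth.shape))
        image = np.clip(image, 0.0, None)
        a1 = _angio(image, 15.0, "SS")
        a2 = _angio(3.5 * image + 10.0, 15.0, "SS")
        b1 = ang.binarize_vessels(a1, self._roi())
        b2 = ang.binarize_vessels(a2, self._roi())
        np.testing.assert_array_equal(b1.vessel_map, b2.vessel_map)


class TestFazAndDensity:
    @staticmethod
    def _roi(radius=1.4):
        return ang.CommonCircularROI(center_sd_mm=(0, 0), center_ss_mm=(0, 0),
                                     radius_mm=radius, shift_mm=(0, 0),
                                     correlation=1.0)

    def test_faz_area_close_to_disk_area(self, paired_angiograms):
        _, a_ss = paired_angiograms
        roi = self._roi()
        b = ang.binarize_vessels(a_ss, roi)
        faz = ang.exclude_faz(b, roi, a_ss)
        assert not faz.fallback_used
        assert faz.area_mm2 == pytest.approx(np.pi * 0.25 ** 2, rel=0.10)

    def test_faz_never_overlaps_vessels(self, paired_angiograms):
        a_sd, _ = paired_angiograms
        roi = self._roi()
        b = ang.binarize_vessels(a_sd, roi)
        faz = ang.exclude_faz(b, roi, a_sd)
        assert not (faz.mask & b.vessel_map).any()

    def test_vessel_at_center_triggers_fallback(self, rng):
        image = np.ones((150, 150)) * 0.9  # vessel everywhere
        image[95:105, 95:105] = 0.05       # off-centre background patch
        a = _angio(image, 20.0, "SS")
        roi = self._roi(radius=1.2)
        b = ang.binarize_vessels(a, roi)
        faz = ang.exclude_faz(b, roi, a)
        assert faz.fallback_used

    def test_all_vessel_roi_without_faz_is_saturated(self):
        n = 100
        a = _angio(np.ones((n, n)), 20.0, "SS")
        roi = self._roi(radius=0.8)
        roi_mask = roi.pixel_mask(a)
        b = ang.VesselBinarization(vessel_map=roi_mask.copy(),
                                   roi_mask=roi_mask, threshold=0.5,
                                   method="otsu", device="SS")
        faz = ang.FAZMask(mask=np.zeros_like(roi_mask), area_mm2=0.0,
                          fallback_used=False)
        result = ang.vessel_density(b, roi, faz)
        assert result.density_percent == 100.0

    def test_half_vessel_roi_is_fifty_percent(self):
        n = 100
        a = _angio(np.ones((n, n)), 20.0, "SS")
        roi = self._roi(radius=0.8)
        roi_mask = roi.pixel_mask(a)
        vessel = roi_mask.copy()
        vessel[n // 2:, :] = False  # half-plane through the centre
        b = ang.VesselBinarization(vessel_map=vessel, roi_mask=roi_mask,
                                   threshold=0.5, method="otsu", device="SS")
        faz = ang.FAZMask(mask=np.zeros_like(roi_mask), area_mm2=0.0,
                          fallback_used=False)
        result = ang.vessel_density(b, roi, faz)
        assert result.density_percent == pytest.approx(50.0, abs=1.0)

    def test_roi_swallowed_by_faz_rejected(self):
        n = 60
        a = _angio(np.ones((n, n)), 20.0, "SS")
        roi = self._roi(radius=0.5)
        roi_mask = roi.pixel_mask(a)
        b = ang.VesselBinarization(vessel_map=np.zeros_like(roi_mask),
                                   roi_mask=roi_mask, threshold=0.5,
                                   method="otsu", device="SS")
        faz = ang.FAZMask(mask=roi_mask.copy(), area_mm2=1.0,
                          fallback_used=False)
        with pytest.raises(DegenerateInputError):
            ang.vessel_density(b, roi, faz)
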