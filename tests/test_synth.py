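"""The synthetic-acquisition generator: geometry, forward model, vascular
patterns and cohorts."""

import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from octa_compare.datamodel import SURFACE_NAMES, ScanPatternConfig
from octa_compare.errors import ValidationError
from octa_compare.metrics import layer_signal_strength, normalize_volume
from octa_compare.segmentation import csr_mask, measure_csv, slab_mask
from octa_compare.synth import (BASE_DEPTHS_UM, DeviceModel, GeometryParams,
                                RetinaGeometry, VascularPattern,
                                build_geometry, build_vascular_pattern,
                                default_device_models, generate_cohort,
                                render_angiogram, render_volume,
                                resample_pattern)

NO_JITTER = dict(thickness_jitter_sd_um=0.0, elevation_jitter_sd_um=0.0,
                 reflectivity_jitter_sd=0.0)


def _uniform_geometry(value=0.5, dome=(0, 0, 0)):
    a, b, c = dome
    return RetinaGeometry(
        depths_um=dict(BASE_DEPTHS_UM),
        reflectivity={k: value for k in
                      ("vitreous", "superficial", "deep", "outer", "fluid",
                       "rpe_band", "sattler", "haller", "sclera")},
        dome_a_mm=a, dome_b_mm=b, dome_c_mm=c, dome_center_mm=(0.0, 0.0))


def _device(rolloff=0.0, tissue=0.0, fluid=0.0, noise=0.0, device="SS"):
    return DeviceModel(device=device, rolloff_rate=rolloff,
                       tissue_attenuation=tissue,
                       fluid_excess_attenuation=fluid, noise_sd=noise)


class TestGeometry:
    def test_flat_dome_has_zero_gap_and_empty_csr(self, cfg_ss3):
        params = GeometryParams(dome_a_mm=0.5, dome_b_mm=0.5, dome_c_mm=0.0,
                                **NO_JITTER)
        geometry, surfaces = build_geometry(params, seed=0, config=cfg_ss3)
        np.testing.assert_array_equal(surfaces["ISOS"], surfaces["RPE"])
        assert csr_mask(surfaces, cfg_ss3).voxel_count == 0

    def test_analytic_volume_closed_form(self):
        params = GeometryParams(dome_a_mm=0.5, dome_b_mm=0.5, dome_c_mm=0.2,
                                **NO_JITTER)
        geometry, _ = build_geometry(params, seed=0)
        assert geometry.analytic_csv_mm3 == pytest.approx(
            (2.0 / 3.0) * math.pi * 0.5 * 0.5 * 0.2)
        assert geometry.analytic_csv_mm3 == pytest.approx(0.10472, abs=5e-6)

    @settings(max_examples=25, deadline=None)
    @given(a=st.one_of(st.just(0.0), st.floats(0.05, 1.3)),
           c=st.one_of(st.just(0.0), st.floats(0.005, 0.3)),
           seed=st.integers(0, 2**16))
    def test_surfaces_always_ordered(self, a, c, seed):
        cfg = ScanPatternConfig(device="SS", pattern_name="3x3mm", n_fast=30,
                                n_slow=30, lateral_spacing=100.0, repeats=4,
                                n_depth=120)
        params = GeometryParams(dome_a_mm=a, dome_b_mm=a, dome_c_mm=c)
        geometry, surfaces = build_geometry(params, seed=seed, config=cfg)
        stack = surfaces.as_array()
        assert (np.diff(stack, axis=0) >= -1e-9).all()
        # gap equals dome height at the apex (within sampling of the apex)
        gap = (surfaces["RPE"] - surfaces["ISOS"]).max()
        if c > 0:
            assert gap <= 1000 * c + 1e-6
        if a > 0.4 and c > 0:  # apex resolved by the 100 µm test grid
            assert gap >= 1000 * c * 0.95

    def test_dome_outside_field_rejected_unless_truncation_allowed(self):
        params = GeometryParams(dome_a_mm=4.0, dome_b_mm=1.0, dome_c_mm=0.1,
                                **NO_JITTER)
        with pytest.raises(ValidationError):
            build_geometry(params, seed=0)
        ok = dataclasses.replace(params, allow_truncation=True)
        geometry, _ = build_geometry(ok, seed=0)
        assert geometry.allow_truncation

    def test_negative_dome_axes_rejected(self):
        with pytest.raises(ValidationError):
            GeometryParams(dome_a_mm=-0.1)


class TestRenderVolume:
    def test_identity_limit_is_constant(self, cfg_sd3):
        vol = render_volume(_uniform_geometry(0.5), _device(device="SD"),
                            cfg_sd3, seed=0)
        np.testing.assert_allclose(vol.intensities, 0.5, rtol=1e-6)

    def test_rolloff_only_decreases_strictly_with_depth(self, cfg_sd3):
        vol = render_volume(_uniform_geometry(1.0),
                            _device(rolloff=0.5, device="SD"), cfg_sd3, seed=0)
        column = vol.intensities[3, 4, :].astype(np.float64)
        assert (np.diff(column) < 0).all()
        # matches the closed-form exponential at each sample
        z_mm = cfg_sd3.depth_coords_um() / 1000.0
        np.testing.assert_allclose(column, np.exp(-0.5 * z_mm), rtol=1e-5)

    def test_same_seed_reproduces_bitwise(self, cfg_ss3, flat_geometry):
        dm = default_device_models()["SS"]
        a = render_volume(flat_geometry, dm, cfg_ss3, seed=42)
        b = render_volume(flat_geometry, dm, cfg_ss3, seed=42)
        np.testing.assert_array_equal(a.intensities, b.intensities)
        c = render_volume(flat_geometry, dm, cfg_ss3, seed=43)
        assert (a.intensities != c.intensities).any()

    def test_zero_attenuation_devices_agree_up_to_grid(self, flat_geometry,
                                                       small_configs):
        """With no roll-off/attenuation/noise the devices differ only by the
        sampling grid: same-grid renders are identical, and per-voxel layer
        means scale exactly with the voxel count."""
        sd = _device(device="SD")
        ss = _device(device="SS")
        cfg_sd = small_configs[("SD", "3x3mm")]
        cfg_ss = small_configs[("SS", "3x3mm")]
        same_grid_sd = render_volume(flat_geometry, sd, cfg_ss, seed=0)
        same_grid_ss = render_volume(flat_geometry, ss, cfg_ss, seed=0)
        np.testing.assert_array_equal(same_grid_sd.intensities,
                                      same_grid_ss.intensities)
        strengths = {}
        for cfg, model in ((cfg_sd, sd), (cfg_ss, ss)):
            nv = normalize_volume(render_volume(flat_geometry, model, cfg,
                                                seed=0))
            mask = slab_mask(flat_geometry.surfaces_on_grid(cfg),
                             "sattler", cfg)
            strengths[cfg.device] = layer_signal_strength(nv, mask).value
        n_ratio = (cfg_ss.n_fast * cfg_ss.n_slow) / (cfg_sd.n_fast
                                                     * cfg_sd.n_slow)
        assert strengths["SD"] / strengths["SS"] == pytest.approx(n_ratio,
                                                                  rel=0.01)

    def test_sub_dome_delta_s_monotone_in_dome_height(self, small_configs):
        """The fluid-differential mechanism: with SD attenuated more per mm
        of fluid, the Sattler-layer ΔS rises monotonically with dome
        height in a deterministic cohort."""
        models = {k: dataclasses.replace(v, noise_sd=0.0)
                  for k, v in default_device_models().items()}
        deltas = []
        for c in (0.04, 0.08, 0.12, 0.16):
            params = GeometryParams(dome_a_mm=1.0, dome_b_mm=1.0,
                                    dome_c_mm=c, **NO_JITTER)
            geometry, _ = build_geometry(params, seed=0)
            values = {}
            for device in ("SD", "SS"):
                cfg = small_configs[(device, "3x3mm")]
                nv = normalize_volume(render_volume(
                    geometry, models[device], cfg, seed=0))
                mask = slab_mask(geometry.surfaces_on_grid(cfg), "sattler",
                                 cfg)
                values[device] = layer_signal_strength(nv, mask).value
            deltas.append(values["SS"] - values["SD"])
        assert (np.diff(deltas) > 0).all()


class TestVascularPattern:
    @pytest.fixture(scope="class")
    def pattern(self):
        return build_vascular_pattern(seed=3, field_width_mm=3.0,
                                      spacing_um=4.0)

    def test_faz_is_vessel_free(self, pattern):
        r = pattern._radius_map_mm()
        assert not pattern.grid[r <= pattern.faz_radius_mm].any()

    def test_true_fraction_in_unit_range(self, pattern):
        assert 0.0 < pattern.true_vessel_fraction < 1.0

    def test_noiseless_angiogram_recovers_resampled_map(self, pattern,
                                                        cfg_ss3):
        angio = render_angiogram(pattern, cfg_ss3, seed=0,
                                 vessel_intensity=1.0,
                                 background_intensity=0.0, noise_sd=0.0)
        recovered = angio.image > 0.5
        np.testing.assert_array_equal(recovered,
                                      resample_pattern(pattern, cfg_ss3))

    def test_device_grid_preserves_vessel_fraction(self, pattern):
        """Area fraction on the 10 µm swept-source grid stays within two
        percentage points of the reference-grid truth."""
        cfg = ScanPatternConfig(device="SS", pattern_name="3x3mm", n_fast=300,
                                n_slow=300, lateral_spacing=10.0, repeats=4)
        resampled = resample_pattern(pattern, cfg)
        c = cfg.lateral_coords_um(300) / 1000.0
        r = np.hypot(c[:, None], c[None, :])
        sel = (r <= 1.4) & (r > pattern.faz_radius_mm)
        measured = resampled[sel].mean()
        truth = pattern.vessel_fraction(1.4)
        assert abs(measured - truth) * 100 < 2.0

    def test_pattern_must_cover_the_field(self, pattern):
        cfg6 = ScanPatternConfig(device="SS", pattern_name="6x6mm",
                                 n_fast=150, n_slow=150, lateral_spacing=40.0,
                                 repeats=2)
        with pytest.raises(ValidationError):
            render_angiogram(pattern, cfg6, seed=0)


class TestCohort:
    def test_counts_and_scan_index(self, small_configs):
        cohort = generate_cohort(2, 2, seed=9, configs=small_configs,
                                 build_vascular=False)
        assert len(cohort.subjects) == 4
        assert len(cohort.scan_index) == 16
        truth = cohort.ground_truth()
        assert len(truth) == 4
        assert (truth.group == "csr").sum() == 2

    def test_same_master_seed_is_bit_identical(self, small_configs):
        key = ("SD", "3x3mm")
        runs = []
        for _ in range(2):
            cohort = generate_cohort(1, 1, seed=77, configs=small_configs,
                                     build_vascular=False)
            subject = cohort.subjects[1]
            vol = subject.render_volume(small_configs[key],
                                        cohort.device_models)
            runs.append((vol.intensities,
                         subject.geometry.analytic_csv_mm3,
                         subject.measured_surfaces(small_configs[key])))
        np.testing.assert_array_equal(runs[0][0], runs[1][0])
        assert runs[0][1] == runs[1][1]
        for name in SURFACE_NAMES:
            np.testing.assert_array_equal(runs[0][2][name], runs[1][2][name])

    def test_csr_analytic_volumes_strictly_increase(self, small_configs):
        cohort = generate_cohort(0, 6, seed=5, configs=small_configs,
                                 build_vascular=False)
        volumes = [s.geometry.analytic_csv_mm3 for s in cohort.subjects]
        assert (np.diff(volumes) > 0).all()

    def test_measured_surfaces_keep_fluid_boundaries_exact(self,
                                                           small_configs):
        cohort = generate_cohort(0, 1, seed=3, configs=small_configs,
                                 build_vascular=False)
        subject = cohort.subjects[0]
        cfg = small_configs[("SD", "3x3mm")]
        true = subject.surfaces(cfg)
        measured = subject.measured_surfaces(cfg)
        for name in ("ISOS", "RPE", "BM"):
            np.testing.assert_array_equal(measured[name], true[name])
        assert (measured["IPL"] != true["IPL"]).any()

    def test_truncated_subject_spills_over_the_3mm_field(self, small_configs):
        cohort = generate_cohort(0, 1, seed=3, configs=small_configs,
                                 n_truncated_csr=1, build_vascular=False)
        truncated = cohort.subjects[-1]
        assert not truncated.geometry.dome_contained(3.0)
        assert truncated.geometry.dome_contained(6.0)
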