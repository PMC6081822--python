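"""Synthetic paired SD/SS acquisitions with analytically known ground truth.

The generator emulates the study conditions of a dual-device comparison on
normal and central-serous-retinopathy (CSR) eyes:

* a layered retina/choroid reflectivity model sampled on each device's scan
  grid (the four commercial protocols in
  :func:`octa_compare.datamodel.builtin_scan_configs`);
* a serous detachment modelled as a half-ellipsoid fluid dome between the
  photoreceptor IS/OS band and the RPE, chosen because its volume has the
  closed form ``(2/3)·π·a·b·c`` and therefore provides exact volumetric
  ground truth;
* a phenomenological device model: exponential sensitivity roll-off with
  depth (faster for the spectral-domain device), exponential attenuation per
  mm of traversed tissue, an *excess* attenuation per mm of traversed serous
  fluid that is larger for SD than SS — the hypothesised mechanism by which
  a large detachment degrades sub-lesion imaging more on SD — and additive
  Gaussian noise;
* a seeded vascular map on a fine reference grid — a bifurcating
  arteriolar tree over a capillary mesh — with a vessel-free foveal
  avascular zone (FAZ) bounded by a perifoveal ring, so the true vessel
  area fraction is exactly pixel-countable;
* per-scan variability: additive noise and a sub-voxel segmentation error
  on the inner retinal boundaries (the crisp IS/OS, RPE and BM are exact).

No speckle, interferometric or flow-decorrelation physics is simulated;
angiograms are rendered directly from the vessel map.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from skimage.draw import disk as draw_disk
from skimage.draw import polygon as draw_polygon

from .datamodel import (BoundarySurfaces, EnFaceAngiogram, ScanPatternConfig,
                        ScanVolume, builtin_scan_configs)
from .errors import ValidationError

# ---------------------------------------------------------------------------
# Device models
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DeviceModel:
    """Phenomenological signal model of one OCT device.

    Rates are per mm.  ``rolloff_rate`` is the depth-dependent sensitivity
    decay of Fourier-domain detection; ``tissue_attenuation`` the decay per
    mm of traversed tissue; ``fluid_excess_attenuation`` the extra decay per
    mm of traversed serous fluid; ``noise_sd`` the additive noise standard
    deviation relative to the mean reflectivity of the scene.
    """

    device: str
    rolloff_rate: float
    tissue_attenuation: float
    fluid_excess_attenuation: float
    noise_sd: float

    def __post_init__(self) -> None:
        for name in ("rolloff_rate", "tissue_attenuation",
                     "fluid_excess_attenuation", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")


def default_device_models() -> dict[str, DeviceModel]:
    """Default SD/SS device models.

    The values are synthetic conventions chosen to reproduce the qualitative
    ordering of the two technologies (slower roll-off and weaker fluid
    sensitivity loss for the swept source), not measured instrument
    constants.
    """
    return {
        "SD": DeviceModel(device="SD", rolloff_rate=0.6,
                          tissue_attenuation=1.0,
                          fluid_excess_attenuation=1.5, noise_sd=0.02),
        "SS": DeviceModel(device="SS", rolloff_rate=0.2,
                          tissue_attenuation=1.0,
                          fluid_excess_attenuation=0.5, noise_sd=0.02),
    }


# ---------------------------------------------------------------------------
# Retinal geometry
# ---------------------------------------------------------------------------

#: Baseline boundary depths in µm from the top of the 2 mm window.  Flat
#: boundaries are placed halfway between axial samples (x.5 multiples of the
#: 5 µm pitch) so that whole-voxel volumetry is unbiased: a boundary that
#: coincides with a sample centre would systematically over-count by half a
#: voxel per column.
BASE_DEPTHS_UM = {
    "ILM": 132.5,
    "IPL": 232.5,
    "OPL": 302.5,
    "ISOS": 482.5,   # apposed to the RPE in the normal eye: zero gap
    "RPE": 482.5,
    "BM": 497.5,
}

#: Mean linear reflectivities of the model tissue slabs (arbitrary units).
#: The plexiform/nerve-fibre layers are bright, the outer nuclear layer dark,
#: the RPE band brightest, and the choroid/sclera dim — the familiar en-depth
#: contrast of a macular B-scan.
BASE_REFLECTIVITY = {
    "vitreous": 0.05,
    "superficial": 1.0,
    "deep": 0.35,
    "outer": 0.10,
    "fluid": 0.05,
    "rpe_band": 0.3,
    "sattler": 0.07,
    "haller": 0.06,
    "sclera": 0.01,
}


@dataclass(frozen=True)
class GeometryParams:
    """Inputs to :func:`build_geometry`.

    The dome is a half-ellipsoid of lateral semi-axes ``(a, b)`` mm and
    height ``c`` mm centred at ``center_mm`` in the en-face frame (fovea at
    the origin).  Per-subject biological variability is emulated by seeded
    jitter of the retinal layer thicknesses (sd in µm), of the overall
    retinal elevation, and of the slab reflectivities (log-normal sd).
    """

    dome_a_mm: float = 0.0
    dome_b_mm: float = 0.0
    dome_c_mm: float = 0.0
    dome_center_mm: tuple[float, float] = (0.0, 0.0)
    allow_truncation: bool = False
    thickness_jitter_sd_um: float = 0.5
    elevation_jitter_sd_um: float = 0.7
    reflectivity_jitter_sd: float = 0.004
    field_width_mm: float = 6.0

    def __post_init__(self) -> None:
        if min(self.dome_a_mm, self.dome_b_mm, self.dome_c_mm) < 0:
            raise ValidationError("dome semi-axes must be >= 0")


@dataclass(frozen=True)
class RetinaGeometry:
    """A subject's layered anatomy plus fluid dome, grid independent."""

    depths_um: dict[str, float]
    reflectivity: dict[str, float]
    dome_a_mm: float
    dome_b_mm: float
    dome_c_mm: float
    dome_center_mm: tuple[float, float]
    allow_truncation: bool = False
    sattler_thickness_um: float = 100.0
    haller_thickness_um: float = 200.0

    @property
    def analytic_csv_mm3(self) -> float:
        """Closed-form dome volume ``(2/3)·π·a·b·c`` in mm³."""
        return (2.0 / 3.0) * math.pi * self.dome_a_mm * self.dome_b_mm \
            * self.dome_c_mm

    def dome_height_um(self, x_mm: np.ndarray, y_mm: np.ndarray) -> np.ndarray:
        """Fluid dome height in µm at en-face coordinates (mm)."""
        if self.dome_c_mm == 0 or self.dome_a_mm == 0 or self.dome_b_mm == 0:
            return np.zeros(np.broadcast_shapes(x_mm.shape, y_mm.shape))
        x0, y0 = self.dome_center_mm
        r2 = (((x_mm - x0) / self.dome_a_mm) ** 2
              + ((y_mm - y0) / self.dome_b_mm) ** 2)
        return 1000.0 * self.dome_c_mm * np.sqrt(np.clip(1.0 - r2, 0.0, None))

    def dome_contained(self, field_width_mm: float) -> bool:
        half = field_width_mm / 2.0
        x0, y0 = self.dome_center_mm
        return (abs(x0) + self.dome_a_mm <= half
                and abs(y0) + self.dome_b_mm <= half)

    def surfaces_on_grid(self, config: ScanPatternConfig) -> BoundarySurfaces:
        """Sample the boundary surfaces on a device grid.

        The photoreceptor IS/OS surface is displaced anteriorly by the dome
        height while the RPE and Bruch's membrane stay at baseline, so the
        IS/OS-RPE gap equals the dome height everywhere over the footprint.
        The outer nuclear layer absorbs the displacement; where a tall dome
        exceeds its baseline thickness the inner boundaries are pushed up
        just enough to preserve ordering (a synthetic convention — the inner
        retina stays put wherever the dome allows, so retinal-layer metrics
        are insensitive to the dome).  Raises :class:`ValidationError` when
        the dome extends outside the scan field, unless the geometry was
        built with ``allow_truncation`` (the field-of-view truncation
        scenario).
        """
        if (self.dome_c_mm > 0 and not self.allow_truncation
                and not self.dome_contained(config.field_width_um / 1000.0)):
            raise ValidationError(
                "fluid dome extends outside the scan field; build the "
                "geometry with allow_truncation=True to model FOV truncation")
        x = config.lateral_coords_um(config.n_fast)[:, None] / 1000.0
        y = config.lateral_coords_um(config.n_slow)[None, :] / 1000.0
        h = self.dome_height_um(x, y)
        shape = (config.n_fast, config.n_slow)
        surfaces = {}
        isos = np.maximum(np.full(shape, self.depths_um["ISOS"]) - h, 0.0)
        surfaces["ISOS"] = isos
        prev = isos
        for name in ("OPL", "IPL", "ILM"):
            prev = np.minimum(np.full(shape, self.depths_um[name]), prev)
            surfaces[name] = prev
        for name in ("RPE", "BM"):
            surfaces[name] = np.full(shape, self.depths_um[name])
        return BoundarySurfaces(surfaces=surfaces)


def build_geometry(params: GeometryParams, seed: int = 0,
                   config: ScanPatternConfig | None = None,
                   ) -> tuple[RetinaGeometry, BoundarySurfaces]:
    """Construct a subject's geometry and its surfaces on a reference grid.

    ``seed`` drives the per-subject anatomical jitter only; the dome is
    placed exactly as requested.  A dome that would leave the scan field
    raises unless ``params.allow_truncation``.
    """
    rng = np.random.default_rng(seed)
    depths = dict(BASE_DEPTHS_UM)
    # Retinal elevation and per-layer thickness variability.  The RPE/BM
    # complex is the fixed reference: CSV ground truth depends only on the
    # dome, never on jitter.
    elev = rng.normal(0.0, params.elevation_jitter_sd_um)
    t_sup = depths["IPL"] - depths["ILM"] \
        + rng.normal(0.0, params.thickness_jitter_sd_um)
    t_deep = depths["OPL"] - depths["IPL"] \
        + rng.normal(0.0, params.thickness_jitter_sd_um)
    t_outer = depths["ISOS"] - depths["OPL"] \
        + rng.normal(0.0, params.thickness_jitter_sd_um)
    t_sup, t_deep, t_outer = (max(20.0, t) for t in (t_sup, t_deep, t_outer))
    depths["ISOS"] = depths["RPE"]
    depths["OPL"] = depths["ISOS"] - t_outer
    depths["IPL"] = depths["OPL"] - t_deep
    depths["ILM"] = max(10.0, depths["IPL"] - t_sup + elev)
    if depths["ILM"] > depths["IPL"]:
        depths["ILM"] = depths["IPL"]
    refl = {k: v * float(np.exp(rng.normal(0.0, params.reflectivity_jitter_sd)))
            for k, v in BASE_REFLECTIVITY.items()}
    geometry = RetinaGeometry(
        depths_um=depths, reflectivity=refl,
        dome_a_mm=params.dome_a_mm, dome_b_mm=params.dome_b_mm,
        dome_c_mm=params.dome_c_mm, dome_center_mm=params.dome_center_mm,
        allow_truncation=params.allow_truncation)
    if (params.dome_c_mm > 0 and not params.allow_truncation
            and not geometry.dome_contained(params.field_width_mm)):
        raise ValidationError("fluid dome extends outside the scan field")
    if config is None:
        config = builtin_scan_configs()[("SS", "3x3mm")]
    return geometry, geometry.surfaces_on_grid(config)


# ---------------------------------------------------------------------------
# Volume rendering
# ---------------------------------------------------------------------------

def render_volume(geometry: RetinaGeometry, device_model: DeviceModel,
                  config: ScanPatternConfig, seed: int = 0,
                  subject_id: str = "", eye_label: str = "OD") -> ScanVolume:
    """Render a structural OCT volume of a geometry through a device model.

    Each voxel is::

        refl(x,y,z) * exp(-mu_t*T - mu_f*F - r*z) + noise, clipped at 0

    where ``T`` and ``F`` are the tissue and serous-fluid path lengths (mm)
    traversed above the voxel and ``r`` the sensitivity roll-off rate.
    Deterministic given (geometry, device model, config, seed).
    """
    surfaces = geometry.surfaces_on_grid(config)
    nz = config.n_depth
    z_um = config.depth_coords_um().astype(np.float32)[None, None, :]
    z_mm = z_um / 1000.0

    bounds = [surfaces["ILM"], surfaces["IPL"], surfaces["OPL"],
              surfaces["ISOS"], surfaces["RPE"], surfaces["BM"],
              surfaces["BM"] + geometry.sattler_thickness_um,
              surfaces["BM"] + geometry.sattler_thickness_um
              + geometry.haller_thickness_um]
    names = ["vitreous", "superficial", "deep", "outer", "fluid", "rpe_band",
             "sattler", "haller", "sclera"]
    # reflectivity built additively: vitreous + per-boundary steps, written
    # in place to keep peak memory at ~two volume-sized float32 arrays
    values = [np.float32(geometry.reflectivity[n]) for n in names]
    refl = np.full((config.n_fast, config.n_slow, nz), values[0],
                   dtype=np.float32)
    for k, top in enumerate(bounds):
        step = values[k + 1] - values[k]
        np.add(refl, step, out=refl,
               where=z_um > top[:, :, None].astype(np.float32))

    isos = surfaces["ISOS"][:, :, None].astype(np.float32) / 1000.0
    rpe = surfaces["RPE"][:, :, None].astype(np.float32) / 1000.0
    ilm = surfaces["ILM"][:, :, None].astype(np.float32) / 1000.0

    fluid = np.minimum(z_mm, rpe)
    fluid -= isos
    np.clip(fluid, 0.0, None, out=fluid)
    expo = np.subtract(z_mm, ilm)  # tissue path before fluid subtraction
    np.clip(expo, 0.0, None, out=expo)
    expo -= fluid
    expo *= -np.float32(device_model.tissue_attenuation)
    fluid *= -np.float32(device_model.fluid_excess_attenuation)
    expo += fluid
    del fluid
    expo -= np.float32(device_model.rolloff_rate) * z_mm
    np.exp(expo, out=expo)

    out = refl
    out *= expo
    del expo
    if device_model.noise_sd > 0:
        rng = np.random.default_rng(seed)
        scale = np.float32(device_model.noise_sd
                           * float(np.mean(list(geometry.reflectivity.values()))))
        noise = rng.standard_normal(out.shape, dtype=np.float32)
        noise *= scale
        out += noise
    np.clip(out, 0.0, None, out=out)
    return ScanVolume(intensities=out, config=config,
                      subject_id=subject_id, eye_label=eye_label)


# ---------------------------------------------------------------------------
# Vascular patterns and angiograms
# ---------------------------------------------------------------------------


@dataclass
class VascularPattern:
    """Ground-truth binary vessel map on a fine reference grid.

    ``grid`` is indexed ``(x, y)`` like the en-face plane of a volume, with
    pixel centres at ``(i - (n - 1)/2) * spacing_um``.  Pixels within
    ``faz_radius_mm`` of the centre are guaranteed vessel free.
    """

    grid: np.ndarray
    spacing_um: float
    faz_radius_mm: float
    true_vessel_fraction: float = 0.0

    def _radius_map_mm(self) -> np.ndarray:
        n = self.grid.shape[0]
        c = (np.arange(n) - (n - 1) / 2.0) * self.spacing_um / 1000.0
        return np.hypot(c[:, None], c[None, :])

    def vessel_fraction(self, radius_mm: float,
                        faz_exclusion_mm: float | None = None) -> float:
        """Vessel area fraction inside a centred circle, excluding the FAZ
        from both numerator and denominator."""
        if faz_exclusion_mm is None:
            faz_exclusion_mm = self.faz_radius_mm
        r = self._radius_map_mm()
        sel = (r <= radius_mm) & (r > faz_exclusion_mm)
        if not sel.any():
            raise ValidationError("empty analysis region")
        return float(self.grid[sel].mean())

    @property
    def field_width_mm(self) -> float:
        return self.grid.shape[0] * self.spacing_um / 1000.0


def build_vascular_pattern(seed: int = 0, field_width_mm: float = 6.0,
                           faz_radius_mm: float = 0.25,
                           spacing_um: float = 2.0,
                           n_trunks: int = 6,
                           generations: int = 6,
                           trunk_width_um: float = 35.0,
                           mesh_scale_um: float = 40.0,
                           mesh_level: float = 0.5) -> VascularPattern:
    """Deterministic vascular map: branching arteriolar tree over a
    capillary mesh, with a central avascular zone.

    The tree's trunks enter near the field edge and bifurcate inward with
    seeded angular jitter, shrinking in calibre each generation and
    terminating before the perifoveal region.  The intervening capillary
    bed — which carries most of the ~40-50 % area density seen in en-face
    angiograms and which a pure bifurcating tree cannot supply at
    resolvable calibres — is the sub-level band ``|F| < mesh_level·sd`` of a
    Gaussian-smoothed noise field ``F`` with correlation scale
    ``mesh_scale_um``, giving a connected web of ~30 µm channels whose area
    fraction is set by the level.  A perifoveal capillary ring encircles the
    FAZ (as the real parafoveal arcade does) and the FAZ disk itself is
    cleared, so the avascular zone is exactly a disk of the requested
    radius.
    """
    from scipy.ndimage import gaussian_filter

    rng = np.random.default_rng(seed)
    n = int(round(field_width_mm * 1000.0 / spacing_um))
    half_px = (n - 1) / 2.0

    # capillary mesh
    fieldmap = gaussian_filter(
        rng.standard_normal((n, n)), mesh_scale_um / spacing_um)
    canvas = np.abs(fieldmap) < mesh_level * float(fieldmap.std())
    del fieldmap

    def to_px(x_mm: float) -> float:
        return x_mm * 1000.0 / spacing_um + half_px

    def draw_segment(x0, y0, x1, y1, w_mm):
        hw = max(w_mm * 1000.0 / spacing_um / 2.0, 0.5)
        p0 = np.array([to_px(x0), to_px(y0)])
        p1 = np.array([to_px(x1), to_px(y1)])
        d = p1 - p0
        norm = np.hypot(*d)
        if norm < 1e-9:
            return
        perp = np.array([-d[1], d[0]]) / norm * hw
        corners = np.array([p0 + perp, p1 + perp, p1 - perp, p0 - perp])
        rr, cc = draw_polygon(corners[:, 0], corners[:, 1], shape=canvas.shape)
        canvas[rr, cc] = True
        rr, cc = draw_disk((p1[0], p1[1]), hw, shape=canvas.shape)
        canvas[rr, cc] = True

    half_field = field_width_mm / 2.0
    stack = []
    r0 = 0.93 * half_field
    for k in range(n_trunks):
        ang = 2 * math.pi * (k + 0.5) / n_trunks + rng.uniform(-0.2, 0.2)
        x, y = r0 * math.cos(ang), r0 * math.sin(ang)
        heading = ang + math.pi + rng.uniform(-0.3, 0.3)
        stack.append((x, y, heading, 0))
    seg_len0 = 0.14 * field_width_mm
    while stack:
        x, y, heading, gen = stack.pop()
        if gen >= generations:
            continue
        length = seg_len0 * 0.82 ** gen * rng.uniform(0.85, 1.15)
        width_mm = trunk_width_um / 1000.0 * 0.8 ** gen
        x1 = x + length * math.cos(heading)
        y1 = y + length * math.sin(heading)
        if max(abs(x1), abs(y1)) > half_field:
            continue
        if math.hypot(x1, y1) < 0.45:  # arterioles stop short of the fovea
            continue
        draw_segment(x, y, x1, y1, width_mm)
        spread = 0.42 + rng.uniform(-0.12, 0.12)
        for sign in (+1.0, -1.0):
            stack.append((x1, y1, heading + sign * spread
                          + rng.uniform(-0.1, 0.1), gen + 1))

    # perifoveal capillary ring bounding the FAZ
    center = (half_px, half_px)
    ring_outer_px = (faz_radius_mm + 0.025) * 1000.0 / spacing_um
    rr, cc = draw_disk(center, ring_outer_px, shape=canvas.shape)
    canvas[rr, cc] = True
    # clear the FAZ disk itself (also removes any capillary that strayed in)
    faz_px = faz_radius_mm * 1000.0 / spacing_um
    rr, cc = draw_disk(center, faz_px, shape=canvas.shape)
    canvas[rr, cc] = False

    pattern = VascularPattern(grid=canvas, spacing_um=spacing_um,
                              faz_radius_mm=faz_radius_mm)
    pattern.true_vessel_fraction = pattern.vessel_fraction(
        radius_mm=half_field - 0.05)
    return pattern


def _box_edges(n_out: int, pitch_um: float, n_ref: int,
               spacing_um: float) -> np.ndarray:
    """Reference-grid indices of device-pixel box edges along one axis."""
    centers = (np.arange(n_out) - (n_out - 1) / 2.0) * pitch_um
    left = centers - pitch_um / 2.0
    ref_origin = -(n_ref - 1) / 2.0 * spacing_um - spacing_um / 2.0
    edges = np.rint((np.append(left, centers[-1] + pitch_um / 2.0)
                     - ref_origin) / spacing_um).astype(int)
    return np.clip(edges, 0, n_ref)


def _box_downsample(grid: np.ndarray, spacing_um: float,
                    n_out: int, pitch_um: float) -> np.ndarray:
    """Area-average a reference grid onto an ``n_out`` × ``n_out`` device
    grid sharing the same physical centre (summed-area box filter)."""
    ex = _box_edges(n_out, pitch_um, grid.shape[0], spacing_um)
    ey = _box_edges(n_out, pitch_um, grid.shape[1], spacing_um)
    g = grid.astype(np.float64)
    cs = np.zeros((g.shape[0] + 1, g.shape[1]))
    np.cumsum(g, axis=0, out=cs[1:])
    rows = cs[ex[1:]] - cs[ex[:-1]]
    cs2 = np.zeros((rows.shape[0], rows.shape[1] + 1))
    np.cumsum(rows, axis=1, out=cs2[:, 1:])
    both = cs2[:, ey[1:]] - cs2[:, ey[:-1]]
    counts = np.outer(np.diff(ex), np.diff(ey)).astype(np.float64)
    counts[counts == 0] = 1.0
    return both / counts


def resample_pattern(pattern: VascularPattern,
                     config: ScanPatternConfig) -> np.ndarray:
    """Ground-truth vessel map on a device grid: a device pixel is vessel
    when more than half its footprint is covered on the reference grid."""
    cov = _box_downsample(pattern.grid, pattern.spacing_um,
                          config.n_fast, config.lateral_spacing)
    return cov > 0.5


def render_angiogram(pattern: VascularPattern, config: ScanPatternConfig,
                     seed: int = 0, vessel_intensity: float = 1.0,
                     background_intensity: float = 0.05,
                     noise_sd: float = 0.03) -> EnFaceAngiogram:
    """Render a device en-face angiogram from a ground-truth vessel map.

    The vessel map is area-averaged onto the device grid (partial-volume
    coverage), scaled between background and vessel intensity, and additive
    Gaussian noise is applied.  The FAZ stays background.
    """
    if pattern.field_width_mm * 1000.0 < config.field_width_um - 1e-6:
        raise ValidationError("pattern does not cover the scan field")
    cov = _box_downsample(pattern.grid, pattern.spacing_um,
                          config.n_fast, config.lateral_spacing)
    image = background_intensity + (vessel_intensity - background_intensity) * cov
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        image = image + rng.normal(0.0, noise_sd, size=image.shape)
    return EnFaceAngiogram(image=np.clip(image, 0.0, None),
                           lateral_spacing=config.lateral_spacing,
                           device=config.device, layer_name="retina")


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------


@dataclass
class CohortSubject:
    """One synthetic eye: geometry, vasculature and per-scan seeds.

    Volumes are rendered on demand (four scans of the largest grid would
    not fit comfortably in memory for a whole cohort) but every render is
    deterministic from the stored seeds.
    """

    subject_id: str
    group: str  # "normal" or "csr"
    geometry: RetinaGeometry
    vascular: VascularPattern
    scan_seeds: dict[tuple[str, str], int]
    seg_error_sd_um: float = 4.0

    def surfaces(self, config: ScanPatternConfig) -> BoundarySurfaces:
        return self.geometry.surfaces_on_grid(config)

    def measured_surfaces(self, config: ScanPatternConfig) -> BoundarySurfaces:
        """Boundary surfaces as a segmentation step would deliver them.

        Each scan's retinal boundaries (ILM, IPL, OPL) carry an independent
        sub-voxel placement error — segmentation of the low-contrast inner
        boundaries is not perfectly reproducible between devices — while the
        bright, crisp IS/OS, RPE and Bruch's membrane are returned exactly,
        so fluid volumetry and the BM-anchored choroid slabs are unaffected.
        """
        true = self.geometry.surfaces_on_grid(config)
        if self.seg_error_sd_um <= 0:
            return true
        rng = np.random.default_rng([self.scan_seeds[config.key()], 905])
        surfaces = {k: v.copy() for k, v in true.surfaces.items()}
        for name in ("ILM", "IPL", "OPL"):
            surfaces[name] = surfaces[name] + rng.normal(
                0.0, self.seg_error_sd_um)
        surfaces["OPL"] = np.minimum(surfaces["OPL"], surfaces["ISOS"])
        surfaces["IPL"] = np.minimum(surfaces["IPL"], surfaces["OPL"])
        surfaces["ILM"] = np.clip(
            np.minimum(surfaces["ILM"], surfaces["IPL"]), 0.0, None)
        return BoundarySurfaces(surfaces=surfaces)

    def render_volume(self, config: ScanPatternConfig,
                      device_models: dict[str, DeviceModel]) -> ScanVolume:
        return render_volume(self.geometry, device_models[config.device],
                             config, seed=self.scan_seeds[config.key()],
                             subject_id=self.subject_id)

    def render_angiogram(self, config: ScanPatternConfig,
                         noise_sd: float = 0.03) -> EnFaceAngiogram:
        return render_angiogram(self.vascular, config,
                                seed=self.scan_seeds[config.key()],
                                noise_sd=noise_sd)


@dataclass
class Cohort:
    """A paired synthetic dataset: every subject imaged under all four
    device × pattern configurations, with ground-truth records."""

    subjects: list[CohortSubject]
    configs: dict[tuple[str, str], ScanPatternConfig]
    device_models: dict[str, DeviceModel]
    seed: int

    @property
    def scan_index(self) -> list[tuple[str, str, str]]:
        return [(s.subject_id, device, pattern)
                for s in self.subjects
                for (device, pattern) in sorted(self.configs)]

    def ground_truth(self):
        import pandas as pd
        rows = []
        for s in self.subjects:
            rows.append({
                "subject_id": s.subject_id,
                "group": s.group,
                "dome_a_mm": s.geometry.dome_a_mm,
                "dome_b_mm": s.geometry.dome_b_mm,
                "dome_c_mm": s.geometry.dome_c_mm,
                "analytic_csv_mm3": s.geometry.analytic_csv_mm3,
                "true_vessel_fraction": s.vascular.true_vessel_fraction,
                "fov_truncated_3x3": not s.geometry.dome_contained(3.0)
                if s.geometry.dome_c_mm > 0 else False,
            })
        return pd.DataFrame(rows)


#: Dome parameter range of the default CSR cohort: heights span 60-120 µm and
#: lateral semi-axes 0.7-1.3 mm, giving analytic volumes from roughly 0.06 to
#: 0.42 mm³ — shallow-to-moderate macular serous detachments that fit the
#: 3×3 mm field.
CSR_HEIGHT_RANGE_MM = (0.06, 0.17)
CSR_SEMIAXIS_RANGE_MM = (0.7, 1.35)


def generate_cohort(n_normal: int, n_csr: int, seed: int = 0,
                    configs: dict | None = None,
                    device_models: dict[str, DeviceModel] | None = None,
                    n_truncated_csr: int = 0,
                    anatomical_jitter: bool = True,
                    seg_error_sd_um: float = 4.0,
                    build_vascular: bool = True) -> Cohort:
    """Generate a paired SD/SS cohort with known ground truth.

    CSR subjects receive dome heights and semi-axes spanning the stated
    ranges (both increasing together, so analytic CSV is strictly increasing
    across the CSR subjects in order).  ``n_truncated_csr`` appends extra
    CSR subjects whose dome (semi-axis 2 mm) exceeds the 3×3 mm field of
    view, the truncation scenario.  All randomness derives from the master
    seed through per-subject spawned seed sequences.
    """
    if n_normal < 0 or n_csr < 0:
        raise ValidationError("cohort sizes must be >= 0")
    configs = configs or builtin_scan_configs()
    device_models = device_models or default_device_models()
    total = n_normal + n_csr + n_truncated_csr
    master = np.random.SeedSequence(seed)
    children = master.spawn(total) if total else []
    jit = dict() if anatomical_jitter else dict(
        thickness_jitter_sd_um=0.0, elevation_jitter_sd_um=0.0,
        reflectivity_jitter_sd=0.0)
    if not anatomical_jitter:
        seg_error_sd_um = 0.0

    subjects = []
    for i, child in enumerate(children):
        state = child.generate_state(8) & 0x7FFFFFFF
        sub_seed = int(state[0])
        rng = np.random.default_rng(child)
        if i < n_normal:
            group, params = "normal", GeometryParams(**jit)
        elif i < n_normal + n_csr:
            j = i - n_normal
            frac = j / max(n_csr - 1, 1)
            c = CSR_HEIGHT_RANGE_MM[0] + frac * (CSR_HEIGHT_RANGE_MM[1]
                                                 - CSR_HEIGHT_RANGE_MM[0])
            ab = CSR_SEMIAXIS_RANGE_MM[0] + frac * (CSR_SEMIAXIS_RANGE_MM[1]
                                                    - CSR_SEMIAXIS_RANGE_MM[0])
            center = tuple(rng.uniform(-0.1, 0.1, size=2))
            group, params = "csr", GeometryParams(
                dome_a_mm=ab, dome_b_mm=ab, dome_c_mm=c,
                dome_center_mm=center, **jit)
        else:
            group, params = "csr", GeometryParams(
                dome_a_mm=2.0, dome_b_mm=1.8, dome_c_mm=0.11,
                dome_center_mm=(0.25, 0.1), allow_truncation=True, **jit)
        geometry, _ = build_geometry(params, seed=sub_seed)
        if build_vascular:
            pattern = build_vascular_pattern(seed=int(state[1]))
        else:  # structural-only studies skip the (costly) vessel map
            pattern = VascularPattern(grid=np.zeros((2, 2), dtype=bool),
                                      spacing_um=3000.0, faz_radius_mm=0.0)
        scan_seeds = {key: int(state[2 + k])
                      for k, key in enumerate(sorted(configs))}
        subjects.append(CohortSubject(
            subject_id=f"{group}{i:03d}", group=group, geometry=geometry,
            vascular=pattern, scan_seeds=scan_seeds,
            seg_error_sd_um=seg_error_sd_um))
    return Cohort(subjects=subjects, configs=configs,
                  device_models=device_models, seed=seed)
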