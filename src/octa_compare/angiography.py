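"""En-face angiogram analysis: projection, cross-device registration,
vessel binarization, FAZ exclusion and vessel density.

The cross-device workflow mirrors how paired angiograms are compared in
practice: the two images are brought into a common physical frame (known
pixel-pitch ratio plus a residual translation estimated by normalized
cross-correlation), the largest circle covering the same fundus area in both
images is centred on the fovea, vessels are binarized inside that circle
with a between-class-variance (Otsu) threshold on contrast-normalized
intensities, the foveal avascular zone is excluded, and vessel density is
the vessel-pixel fraction of the remaining region.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.feature import match_template
from skimage.filters import threshold_otsu
from skimage.morphology import closing as _gray_closing, disk
from skimage.transform import resize

from .datamodel import EnFaceAngiogram, LayerMask, ScanVolume
from .errors import DegenerateInputError, RegistrationError, ValidationError


def max_intensity_projection(volume: ScanVolume | np.ndarray,
                             mask: LayerMask,
                             lateral_spacing: float | None = None,
                             device: str = "",
                             ) -> EnFaceAngiogram:
    """Maximum-intensity projection of a volume through a slab mask.

    Each en-face pixel is the maximum voxel value within the mask along its
    A-line; columns with no masked voxel are set to 0.
    """
    if isinstance(volume, ScanVolume):
        values = volume.intensities
        lateral_spacing = volume.config.lateral_spacing
        device = device or volume.config.device
    else:
        values = np.asarray(volume)
        if lateral_spacing is None:
            raise ValidationError("lateral_spacing required for bare arrays")
    if values.shape != mask.mask.shape:
        raise ValidationError(
            f"mask shape {mask.mask.shape} != volume shape {values.shape}")
    if not mask.mask.any():
        raise DegenerateInputError("projection mask is empty")
    lowered = np.where(mask.mask, values, -np.inf)
    image = lowered.max(axis=2)
    image[~mask.mask.any(axis=2)] = 0.0
    return EnFaceAngiogram(image=image, lateral_spacing=lateral_spacing,
                           device=device, layer_name=mask.layer_name)


# ---------------------------------------------------------------------------
# Registration and the common circular ROI
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CommonCircularROI:
    """The largest circle covering the same fundus area in both images.

    Centres are in mm in each image's own physical frame (origin at the
    image centre); ``shift_mm`` is the residual translation taking SD-frame
    coordinates into the SS frame, on top of the pixel-pitch rescaling.
    """

    center_sd_mm: tuple[float, float]
    center_ss_mm: tuple[float, float]
    radius_mm: float
    shift_mm: tuple[float, float]
    correlation: float

    def __post_init__(self) -> None:
        if self.radius_mm <= 0:
            raise ValidationError("ROI radius must be positive")

    def center_for(self, device: str) -> tuple[float, float]:
        if device == "SD":
            return self.center_sd_mm
        if device == "SS":
            return self.center_ss_mm
        raise ValidationError(f"unknown device {device!r}")

    def pixel_mask(self, angio: EnFaceAngiogram) -> np.ndarray:
        """Boolean mask of pixels inside the circle for one image."""
        cx, cy = self.center_for(angio.device)
        n0, n1 = angio.image.shape
        x = (np.arange(n0) - (n0 - 1) / 2.0) * angio.lateral_spacing / 1000.0
        y = (np.arange(n1) - (n1 - 1) / 2.0) * angio.lateral_spacing / 1000.0
        r = np.hypot(x[:, None] - cx, y[None, :] - cy)
        return r <= self.radius_mm


def _resample_to_spacing(angio: EnFaceAngiogram, spacing_um: float) -> np.ndarray:
    """Bilinear resampling onto a grid of the requested pitch, same physical
    extent and centre."""
    n0, n1 = angio.image.shape
    m0 = max(int(round(n0 * angio.lateral_spacing / spacing_um)), 1)
    m1 = max(int(round(n1 * angio.lateral_spacing / spacing_um)), 1)
    if (m0, m1) == (n0, n1):
        return np.asarray(angio.image, dtype=np.float64)
    return resize(np.asarray(angio.image, dtype=np.float64), (m0, m1),
                  order=1, mode="edge", anti_aliasing=False,
                  preserve_range=True)


def _central_crop(img: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    r0 = (img.shape[0] - shape[0]) // 2
    c0 = (img.shape[1] - shape[1]) // 2
    return img[r0:r0 + shape[0], c0:c0 + shape[1]]


def _faz_centroid_mm(angio: EnFaceAngiogram,
                     closing_radius_um: float = 30.0,
                     search_radius_mm: float = 0.8) -> tuple[float, float] | None:
    """Centroid of the avascular component at the image centre, or None."""
    img = np.asarray(angio.image, dtype=np.float64)
    finite = img[np.isfinite(img)]
    if finite.size == 0 or float(finite.max()) == float(finite.min()):
        return None
    thr = threshold_otsu(img)
    vessels = img > thr
    comp = _central_avascular_component(vessels, angio.lateral_spacing,
                                        closing_radius_um, search_radius_mm)
    if comp is None:
        return None
    idx = np.argwhere(comp)
    n0, n1 = img.shape
    cx = (idx[:, 0].mean() - (n0 - 1) / 2.0) * angio.lateral_spacing / 1000.0
    cy = (idx[:, 1].mean() - (n1 - 1) / 2.0) * angio.lateral_spacing / 1000.0
    return (float(cx), float(cy))


def _central_avascular_component(vessels: np.ndarray, spacing_um: float,
                                 closing_radius_um: float,
                                 search_radius_mm: float,
                                 center_px: tuple[float, float] | None = None,
                                 ) -> np.ndarray | None:
    """Connected avascular component containing the centre after closing the
    vessel map; None when the centre is vessel or the component leaks out of
    the search disk (no enclosing capillary ring)."""
    r_px = max(int(round(closing_radius_um / spacing_um)), 1)
    closed = _gray_closing(vessels, disk(r_px)).astype(bool)
    n0, n1 = vessels.shape
    if center_px is None:
        center_px = ((n0 - 1) / 2.0, (n1 - 1) / 2.0)
    ci, cj = int(round(center_px[0])), int(round(center_px[1]))
    if not (0 <= ci < n0 and 0 <= cj < n1) or closed[ci, cj]:
        return None
    x = (np.arange(n0) - center_px[0]) * spacing_um / 1000.0
    y = (np.arange(n1) - center_px[1]) * spacing_um / 1000.0
    search = np.hypot(x[:, None], y[None, :]) <= search_radius_mm
    avascular = ~closed & search
    labels, _ = ndimage.label(avascular)
    comp = labels == labels[ci, cj]
    # leaking through the search boundary means the FAZ is not enclosed
    boundary = np.hypot(x[:, None], y[None, :]) > (search_radius_mm
                                                   - 2 * spacing_um / 1000.0)
    if np.any(comp & boundary):
        return None
    return comp


def register_angiograms(a_sd: EnFaceAngiogram, a_ss: EnFaceAngiogram,
                        min_correlation: float = 0.2) -> CommonCircularROI:
    """Co-register paired angiograms and return the common circular ROI.

    The pitch ratio is known from the scan metadata, so only a residual
    translation is estimated, by the peak of the normalized cross-correlation
    on a common fine grid.  The circle is centred on the fovea — the FAZ
    centroid of the SS image, which has the denser grid — and is the largest
    circle contained in both fields of view.  A correlation peak below
    ``min_correlation`` raises :class:`RegistrationError`.
    """
    spacing = min(a_sd.lateral_spacing, a_ss.lateral_spacing)
    r_sd = _resample_to_spacing(a_sd, spacing)
    r_ss = _resample_to_spacing(a_ss, spacing)
    shape = (min(r_sd.shape[0], r_ss.shape[0]),
             min(r_sd.shape[1], r_ss.shape[1]))
    r_sd = _central_crop(r_sd, shape)
    r_ss = _central_crop(r_ss, shape)
    if float(r_sd.std()) == 0.0 or float(r_ss.std()) == 0.0:
        raise RegistrationError("constant image cannot be registered")
    response = match_template(r_ss, r_sd, pad_input=True)
    # only consider shifts up to a quarter of the field: tiny border overlaps
    # produce spurious correlation values
    q0, q1 = shape[0] // 4, shape[1] // 4
    central = response[q0:shape[0] - q0, q1:shape[1] - q1]
    peak = float(central.max())
    if peak < min_correlation:
        raise RegistrationError(
            f"correlation peak {peak:.3f} below floor {min_correlation}")
    pk = np.unravel_index(int(central.argmax()), central.shape)
    shift_px = (pk[0] + q0 - (shape[0] - 1) / 2.0,
                pk[1] + q1 - (shape[1] - 1) / 2.0)
    shift_mm = (shift_px[0] * spacing / 1000.0, shift_px[1] * spacing / 1000.0)

    fovea_ss = _faz_centroid_mm(a_ss)
    if fovea_ss is None:
        fovea_ss = (0.0, 0.0)
    center_ss = fovea_ss
    center_sd = (center_ss[0] - shift_mm[0], center_ss[1] - shift_mm[1])

    def max_radius(angio: EnFaceAngiogram, center: tuple[float, float]) -> float:
        half0 = angio.image.shape[0] * angio.lateral_spacing / 2000.0
        half1 = angio.image.shape[1] * angio.lateral_spacing / 2000.0
        return min(half0 - abs(center[0]), half1 - abs(center[1]))

    radius = min(max_radius(a_sd, center_sd), max_radius(a_ss, center_ss))
    radius -= spacing / 1000.0  # stay strictly inside both fields
    if radius <= 0:
        raise RegistrationError("no common circular region exists")
    return CommonCircularROI(center_sd_mm=center_sd, center_ss_mm=center_ss,
                             radius_mm=float(radius), shift_mm=shift_mm,
                             correlation=peak)


# ---------------------------------------------------------------------------
# Binarization, FAZ, density
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BinarizationConfig:
    """Method configuration recorded with every binarization for provenance."""

    method: str = "otsu"
    low_percentile: float = 1.0
    high_percentile: float = 99.0


@dataclass
class VesselBinarization:
    vessel_map: np.ndarray
    roi_mask: np.ndarray
    threshold: float
    method: str
    device: str


def binarize_vessels(angio: EnFaceAngiogram, roi: CommonCircularROI,
                     config: BinarizationConfig | None = None,
                     ) -> VesselBinarization:
    """Binarize vessels inside the ROI.

    Intensities are contrast-normalized within the ROI (robust percentile
    stretch, which makes the result invariant to affine intensity
    rescaling), then thresholded globally by the between-class-variance
    criterion.  Pixels strictly above the threshold are vessel.
    """
    cfg = config or BinarizationConfig()
    roi_mask = roi.pixel_mask(angio)
    if not roi_mask.any():
        raise ValidationError("ROI does not intersect the image")
    pix = angio.image[roi_mask]
    lo, hi = np.percentile(pix, [cfg.low_percentile, cfg.high_percentile])
    if hi <= lo:
        lo, hi = float(pix.min()), float(pix.max())
    if hi <= lo:
        raise DegenerateInputError(
            "constant image inside ROI: no threshold separates classes")
    norm = np.clip((angio.image - lo) / (hi - lo), 0.0, 1.0)
    thr = float(threshold_otsu(norm[roi_mask]))
    vessel = (norm > thr) & roi_mask
    return VesselBinarization(vessel_map=vessel, roi_mask=roi_mask,
                              threshold=thr, method=cfg.method,
                              device=angio.device)


@dataclass(frozen=True)
class FAZConfig:
    closing_radius_um: float = 30.0
    fallback_radius_mm: float = 0.25
    search_radius_mm: float = 0.8
    mode: str = "auto"  # "auto" (connected component) or "fixed" (disk)


@dataclass
class FAZMask:
    mask: np.ndarray
    area_mm2: float
    fallback_used: bool


def exclude_faz(binarization: VesselBinarization, roi: CommonCircularROI,
                angio: EnFaceAngiogram,
                config: FAZConfig | None = None) -> FAZMask:
    """Identify the foveal avascular zone to exclude from density.

    Default mode: morphologically close the vessel map, then take the
    connected avascular component containing the ROI centre.  When the
    centre is vessel after closing (or the component is not enclosed by a
    capillary ring), fall back to a fixed-radius disk and flag it.
    """
    cfg = config or FAZConfig()
    spacing = angio.lateral_spacing
    n0, n1 = binarization.vessel_map.shape
    cx, cy = roi.center_for(angio.device)
    center_px = (cx * 1000.0 / spacing + (n0 - 1) / 2.0,
                 cy * 1000.0 / spacing + (n1 - 1) / 2.0)
    comp = None
    if cfg.mode == "auto":
        comp = _central_avascular_component(
            binarization.vessel_map, spacing, cfg.closing_radius_um,
            cfg.search_radius_mm, center_px=center_px)
    fallback = comp is None
    if fallback:
        x = (np.arange(n0) - center_px[0]) * spacing / 1000.0
        y = (np.arange(n1) - center_px[1]) * spacing / 1000.0
        comp = np.hypot(x[:, None], y[None, :]) <= cfg.fallback_radius_mm
    mask = comp & ~binarization.vessel_map & binarization.roi_mask
    area = float(mask.sum()) * (spacing / 1000.0) ** 2
    return FAZMask(mask=mask, area_mm2=area,
                   fallback_used=fallback and cfg.mode == "auto")


@dataclass(frozen=True)
class VesselDensityResult:
    density_percent: float
    faz_area_mm2: float
    device: str
    pattern_name: str
    roi_radius_mm: float
    method: str
    n_pixels: int


def vessel_density(binarization: VesselBinarization, roi: CommonCircularROI,
                   faz: FAZMask, pattern_name: str = "") -> VesselDensityResult:
    """Vessel-pixel percentage of the ROI, FAZ pixels excluded from both
    numerator and denominator."""
    denom = binarization.roi_mask & ~faz.mask
    n = int(denom.sum())
    if n == 0:
        raise DegenerateInputError("ROI is entirely inside the FAZ")
    vessels = int((binarization.vessel_map & denom).sum())
    return VesselDensityResult(
        density_percent=100.0 * vessels / n,
        faz_area_mm2=faz.area_mm2, device=binarization.device,
        pattern_name=pattern_name, roi_radius_mm=roi.radius_mm,
        method=binarization.method, n_pixels=n)
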