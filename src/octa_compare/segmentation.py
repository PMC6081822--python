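"""Layer masks from boundary surfaces, and serous-fluid volumetry.

Anatomical slabs
----------------
* superficial retina: ILM to IPL,
* deep retina: IPL to OPL (the INL top is taken as the bottom of the IPL
  surface, so the slab runs from just below IPL down to OPL),
* Sattler's layer: a fixed-thickness band immediately below Bruch's
  membrane (medium choroidal vessels),
* Haller's layer: the next fixed-thickness band (large choroidal vessels).

Fixed choroidal thicknesses are used because automated choroidal sublayer
segmentation is not reproducible across devices; the defaults (100 µm
Sattler, 200 µm Haller) sit within published ranges and are configurable.

Slab convention
---------------
A voxel belongs to a slab when its centre depth ``k * axial_spacing`` lies in
the half-open interval ``(top, bottom]``; the very first slab (superficial
retina) additionally includes its top surface, so a voxel exactly on the ILM
is superficial.  Half-open intervals guarantee that adjacent slabs never
share a voxel.

The serous detachment (CSR) region is the gap between the photoreceptor
IS/OS band and the RPE wherever that gap exceeds a threshold separating
genuine detachment from normal apposition.  Central serous volume (CSV) is
the whole-voxel count of that region times the voxel volume.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datamodel import (BoundarySurfaces, CSVMeasurement, LayerMask,
                        ScanPatternConfig)
from .errors import ValidationError


@dataclass(frozen=True)
class ChoroidParams:
    """Fixed sub-Bruch's slab thicknesses in µm."""

    sattler_thickness_um: float = 100.0
    haller_thickness_um: float = 200.0


#: Default detachment threshold: IS/OS-RPE gaps at or below this are treated
#: as normal apposition (two axial samples at the default 5 µm pitch).
DEFAULT_MIN_GAP_UM = 10.0


def _depth_grid(config: ScanPatternConfig) -> np.ndarray:
    return config.depth_coords_um()[None, None, :]


def _band_mask(top: np.ndarray, bottom: np.ndarray,
               config: ScanPatternConfig, *,
               include_top: bool = False) -> tuple[np.ndarray, bool]:
    z = _depth_grid(config)
    t = top[:, :, None]
    b = bottom[:, :, None]
    mask = (z > t) & (z <= b)
    if include_top:
        mask |= np.isclose(z, t)
    clipped = bool(np.any(bottom > config.depth_um - config.axial_spacing))
    return mask, clipped


def slab_mask(boundaries: BoundarySurfaces, layer_name: str,
              config: ScanPatternConfig,
              choroid_params: ChoroidParams | None = None) -> LayerMask:
    """Boolean mask of an anatomical slab on the volume grid.

    Slabs that run past the bottom of the depth window are clipped and the
    result carries ``clipped=True``.
    """
    if boundaries.shape != (config.n_fast, config.n_slow):
        raise ValidationError(
            f"surface grid {boundaries.shape} does not match scan "
            f"({config.n_fast}, {config.n_slow})")
    cp = choroid_params or ChoroidParams()
    bm = boundaries["BM"]
    if layer_name == "superficial_retina":
        mask, clipped = _band_mask(boundaries["ILM"], boundaries["IPL"],
                                   config, include_top=True)
    elif layer_name == "deep_retina":
        mask, clipped = _band_mask(boundaries["IPL"], boundaries["OPL"], config)
    elif layer_name == "sattler":
        mask, clipped = _band_mask(bm, bm + cp.sattler_thickness_um, config)
    elif layer_name == "haller":
        mask, clipped = _band_mask(bm + cp.sattler_thickness_um,
                                   bm + cp.sattler_thickness_um
                                   + cp.haller_thickness_um, config)
    else:
        raise ValidationError(f"unknown slab layer {layer_name!r}")
    return LayerMask(mask=mask, layer_name=layer_name, clipped=clipped)


def csr_mask(boundaries: BoundarySurfaces, config: ScanPatternConfig,
             min_gap_um: float = DEFAULT_MIN_GAP_UM) -> LayerMask:
    """Serous detachment region: IS/OS-RPE gap where it exceeds ``min_gap_um``.

    Columns whose gap is at or below the threshold contribute nothing, so a
    normal eye (apposed photoreceptors) yields an empty mask.
    """
    isos = boundaries["ISOS"]
    rpe = boundaries["RPE"]
    detached = (rpe - isos) > min_gap_um
    mask, _ = _band_mask(isos, rpe, config)
    mask &= detached[:, :, None]
    return LayerMask(mask=mask, layer_name="csr_region")


def measure_csv(mask: LayerMask, config: ScanPatternConfig) -> CSVMeasurement:
    """Central serous volume in mm³ by whole-voxel counting."""
    if mask.layer_name != "csr_region":
        raise ValidationError(
            f"CSV is measured on a csr_region mask, got {mask.layer_name!r}")
    count = mask.voxel_count
    volume_mm3 = count * config.voxel_volume_um3 * 1e-9
    return CSVMeasurement(volume_mm3=volume_mm3, voxel_count=count,
                          device=config.device,
                          pattern_name=config.pattern_name,
                          truncated_by_fov=touches_lateral_boundary(mask))


def touches_lateral_boundary(mask: LayerMask) -> bool:
    """True when a mask reaches the edge of the scanned field, i.e. the
    region it segments is truncated by the field of view."""
    m = mask.mask
    if m.size == 0 or not m.any():
        return False
    return bool(m[0].any() or m[-1].any() or m[:, 0].any() or m[:, -1].any())
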