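"""Signal-strength metrics for cross-device comparison.

The incident light energy and detector sensitivity of the two instruments
differ, so raw intensities are not comparable.  Assuming negligible
absorption, the total backscattered signal of a scan is proportional to the
energy delivered to the tissue, and dividing by it puts both devices on a
common unit-energy scale:

    S_norm(x, y, z) = S_m(x, y, z) / S_sum

where ``S_sum`` sums every voxel of the scanned volume (all depths, not per
B-scan).  The per-layer signal strength is the mean normalized signal per
voxel of the layer,

    S_dev = S_layer_sum / N_layer_voxel

and the inter-device difference for a layer is ΔS = S_ss − S_sd.

All accumulation is performed in float64 with numpy's pairwise summation,
which is deterministic for a given array shape and accurate to well below
the 1e−9 conservation tolerance used by the validation suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datamodel import LayerMask, NormalizedVolume, ScanVolume
from .errors import DegenerateInputError, ValidationError


@dataclass(frozen=True)
class LayerSignalStrength:
    """Mean normalized signal per voxel within one layer for one device."""

    layer_name: str
    device: str
    value: float
    layer_sum: float
    voxel_count: int
    subject_id: str = ""
    pattern_name: str = ""


@dataclass(frozen=True)
class SignalDifference:
    """Per-layer signal-strength difference ΔS = S_ss − S_sd."""

    layer_name: str
    delta: float
    subject_id: str = ""
    pattern_name: str = ""


def normalize_volume(volume: ScanVolume) -> NormalizedVolume:
    """Divide a raw volume by its total backscattered signal.

    Raises :class:`DegenerateInputError` for an all-zero volume, where the
    unit-energy assumption is meaningless and the division undefined.
    """
    raw = np.asarray(volume.intensities, dtype=np.float64)
    total = float(raw.sum())
    if total <= 0.0:
        raise DegenerateInputError("cannot normalize an all-zero volume")
    return NormalizedVolume(values=raw / total, total_raw_signal=total,
                            config=volume.config,
                            subject_id=volume.subject_id,
                            eye_label=volume.eye_label)


def layer_signal_strength(normalized: NormalizedVolume,
                          mask: LayerMask,
                          *,
                          raw: np.ndarray | None = None,
                          ) -> LayerSignalStrength:
    """Mean normalized signal per voxel over a layer mask.

    ``raw`` switches the computation to unnormalized intensities — a
    diagnostic mode only; all cross-device comparisons use the normalized
    signal.
    """
    values = normalized.values if raw is None else np.asarray(raw, dtype=np.float64)
    if mask.mask.shape != values.shape:
        raise ValidationError(
            f"mask shape {mask.mask.shape} does not match volume {values.shape}")
    n = mask.voxel_count
    if n == 0:
        raise DegenerateInputError(f"empty mask for layer {mask.layer_name!r}")
    layer_sum = float(np.sum(values, where=mask.mask, dtype=np.float64))
    return LayerSignalStrength(layer_name=mask.layer_name,
                               device=normalized.config.device,
                               value=layer_sum / n,
                               layer_sum=layer_sum,
                               voxel_count=n,
                               subject_id=normalized.subject_id,
                               pattern_name=normalized.config.pattern_name)


def signal_strength_difference(s_ss: LayerSignalStrength,
                               s_sd: LayerSignalStrength) -> SignalDifference:
    """ΔS = S_ss − S_sd for one subject, layer and scan pattern.

    The sign is preserved: a positive ΔS means the swept-source device
    recovered more normalized signal from the layer.
    """
    if s_ss.device != "SS" or s_sd.device != "SD":
        raise ValidationError(
            f"expected (SS, SD) pairing, got ({s_ss.device}, {s_sd.device})")
    for attr in ("layer_name", "subject_id", "pattern_name"):
        a, b = getattr(s_ss, attr), getattr(s_sd, attr)
        if a != b:
            raise ValidationError(f"mismatched {attr}: {a!r} != {b!r}")
    return SignalDifference(layer_name=s_ss.layer_name,
                            delta=s_ss.value - s_sd.value,
                            subject_id=s_ss.subject_id,
                            pattern_name=s_ss.pattern_name)
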