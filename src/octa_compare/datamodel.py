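"""Core data containers and file I/O for the SD/SS OCT comparison pipeline.

Conventions
-----------
* Volumes are indexed ``(fast, slow, depth)``; the depth axis ``z`` increases
  away from the instrument (inner retina shallow, choroid deep).
* Depth sample ``k`` sits at physical depth ``k * axial_spacing`` µm measured
  from the top of the scan window.
* Lateral pixel centres are ``(i - (n - 1) / 2) * lateral_spacing`` µm so the
  origin of the en-face physical frame is the scan centre (nominally the
  fovea).
* Intensities are linear-scale arbitrary units, never dB: the total-energy
  normalization sums backscattered signal, which is only meaningful on a
  linear scale.
* Boundary surfaces are stored in µm from the top of the window.

Persistence uses multi-page grayscale TIFF (one page per slow-axis B-scan)
with a YAML sidecar for spacings and identity — standard, lossless, and
language neutral.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
import yaml

from .errors import DegenerateInputError, ValidationError

#: Boundary surface names, ordered from shallow to deep.
SURFACE_NAMES = ("ILM", "IPL", "OPL", "ISOS", "RPE", "BM")

#: Layer-mask names understood by the segmentation stage.
LAYER_NAMES = ("superficial_retina", "deep_retina", "sattler", "haller",
               "csr_region")

_FIELD_WIDTH_UM = {"3x3mm": 3000.0, "6x6mm": 6000.0}


@dataclass(frozen=True)
class ScanPatternConfig:
    """A device scan protocol: grid counts, spacings and repeat strategy.

    ``n_fast`` is the A-line count per B-scan, ``n_slow`` the number of
    B-scan locations.  ``lateral_spacing`` is the en-face pixel pitch in µm,
    ``axial_spacing`` the depth sample pitch in µm.  The depth window
    (``n_depth`` × ``axial_spacing``) is an explicit package default of
    400 × 5 µm = 2 mm, since commercial exports do not standardize it.
    """

    device: str
    pattern_name: str
    n_fast: int
    n_slow: int
    lateral_spacing: float
    repeats: int
    n_depth: int = 400
    axial_spacing: float = 5.0

    def __post_init__(self) -> None:
        if self.device not in ("SD", "SS"):
            raise ValidationError(f"unknown device {self.device!r}")
        if self.pattern_name not in _FIELD_WIDTH_UM:
            raise ValidationError(f"unknown scan pattern {self.pattern_name!r}")
        for name in ("n_fast", "n_slow", "n_depth", "repeats"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v <= 0:
                raise ValidationError(f"{name} must be a positive integer, got {v!r}")
        if self.lateral_spacing <= 0 or self.axial_spacing <= 0:
            raise ValidationError("spacings must be positive")
        # Pixel-area convention: n pixels of pitch s tile the scan width to
        # within one pitch (e.g. 245 x 12.2 µm = 2989 µm for the 3 mm scan).
        width = self.field_width_um
        if abs(self.n_fast * self.lateral_spacing - width) > self.lateral_spacing:
            raise ValidationError(
                f"{self.n_fast} pixels at {self.lateral_spacing} µm do not "
                f"tile a {width} µm field")

    @property
    def field_width_um(self) -> float:
        """Nominal physical scan width in µm (3000 or 6000)."""
        return _FIELD_WIDTH_UM[self.pattern_name]

    @property
    def depth_um(self) -> float:
        """Physical depth window in µm."""
        return self.n_depth * self.axial_spacing

    @property
    def voxel_volume_um3(self) -> float:
        return self.lateral_spacing ** 2 * self.axial_spacing

    def lateral_coords_um(self, n: int | None = None) -> np.ndarray:
        """Pixel-centre coordinates along one lateral axis, centred on 0."""
        if n is None:
            n = self.n_fast
        return (np.arange(n) - (n - 1) / 2.0) * self.lateral_spacing

    def depth_coords_um(self) -> np.ndarray:
        return np.arange(self.n_depth) * self.axial_spacing

    def key(self) -> tuple[str, str]:
        return (self.device, self.pattern_name)


def builtin_scan_configs(n_depth: int = 400,
                         axial_spacing: float = 5.0,
                         ) -> dict[tuple[str, str], ScanPatternConfig]:
    """The four commercial scan protocols compared in this study.

    SD (spectral-domain, ~840 nm): 3×3 mm at 245×245 A-lines (12.2 µm pitch,
    4 repeats) and 6×6 mm at 350×350 (17.1 µm, 2 repeats).  SS (swept-source,
    ~1050 nm): 3×3 mm at 300×300 (10 µm, 4 repeats) and 6×6 mm at 500×500
    (12 µm, 2 repeats).
    """
    specs = [
        ("SD", "3x3mm", 245, 12.2, 4),
        ("SD", "6x6mm", 350, 17.1, 2),
        ("SS", "3x3mm", 300, 10.0, 4),
        ("SS", "6x6mm", 500, 12.0, 2),
    ]
    out = {}
    for device, pattern, n, pitch, repeats in specs:
        out[(device, pattern)] = ScanPatternConfig(
            device=device, pattern_name=pattern, n_fast=n, n_slow=n,
            lateral_spacing=pitch, repeats=repeats,
            n_depth=n_depth, axial_spacing=axial_spacing)
    return out


@dataclass
class ScanVolume:
    """A raw 3-D OCT intensity volume ``S_m(x, y, z)`` with its protocol."""

    intensities: np.ndarray
    config: ScanPatternConfig
    subject_id: str = ""
    eye_label: str = ""

    def __post_init__(self) -> None:
        a = np.asarray(self.intensities)
        expected = (self.config.n_fast, self.config.n_slow, self.config.n_depth)
        if a.shape != expected:
            raise ValidationError(
                f"volume shape {a.shape} does not match config {expected}")
        if a.size and float(a.min()) < 0:
            raise ValidationError("negative intensities are not valid OCT signal")
        self.intensities = a


@dataclass
class NormalizedVolume:
    """A volume divided by its total backscattered signal; sums to one."""

    values: np.ndarray
    total_raw_signal: float
    config: ScanPatternConfig
    subject_id: str = ""
    eye_label: str = ""


@dataclass
class BoundarySurfaces:
    """Ordered retinal/choroidal boundary depth maps in µm.

    One ``(n_fast, n_slow)`` map per surface in :data:`SURFACE_NAMES`; at every
    lateral position the depths must be monotone non-decreasing from ILM to BM.
    """

    surfaces: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        missing = [s for s in SURFACE_NAMES if s not in self.surfaces]
        if missing:
            raise ValidationError(f"missing surfaces: {missing}")
        shape = self.surfaces[SURFACE_NAMES[0]].shape
        for name in SURFACE_NAMES:
            m = np.asarray(self.surfaces[name], dtype=float)
            if m.shape != shape:
                raise ValidationError(f"surface {name} shape {m.shape} != {shape}")
            self.surfaces[name] = m
        stack = self.as_array()
        if np.any(np.diff(stack, axis=0) < -1e-9):
            raise ValidationError("surfaces are not ordered ILM <= ... <= BM")
        if np.any(stack < 0):
            raise ValidationError("negative surface depth")

    def as_array(self) -> np.ndarray:
        """Stack of shape ``(6, n_fast, n_slow)`` in anatomical order."""
        return np.stack([self.surfaces[s] for s in SURFACE_NAMES])

    def __getitem__(self, name: str) -> np.ndarray:
        return self.surfaces[name]

    @property
    def shape(self) -> tuple[int, int]:
        return self.surfaces[SURFACE_NAMES[0]].shape


@dataclass
class LayerMask:
    """A named boolean 3-D region congruent with a scan volume."""

    mask: np.ndarray
    layer_name: str
    clipped: bool = False  # slab ran past the bottom of the depth window

    def __post_init__(self) -> None:
        if self.layer_name not in LAYER_NAMES:
            raise ValidationError(f"unknown layer {self.layer_name!r}")
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def voxel_count(self) -> int:
        return int(self.mask.sum())


@dataclass
class EnFaceAngiogram:
    """A 2-D en-face flow-intensity image on a device grid."""

    image: np.ndarray
    lateral_spacing: float
    device: str
    layer_name: str = "retina"

    def __post_init__(self) -> None:
        a = np.asarray(self.image, dtype=float)
        if a.ndim != 2:
            raise ValidationError("angiogram must be 2-D")
        if a.size and float(a.min()) < 0:
            raise ValidationError("negative angiogram intensities")
        self.image = a

    @property
    def field_size_um(self) -> tuple[float, float]:
        return (self.image.shape[0] * self.lateral_spacing,
                self.image.shape[1] * self.lateral_spacing)


@dataclass(frozen=True)
class CSVMeasurement:
    """Central serous volume: whole-voxel count of the fluid region."""

    volume_mm3: float
    voxel_count: int
    device: str
    pattern_name: str
    truncated_by_fov: bool = False


# ---------------------------------------------------------------------------
# Persistence
# ---------------------------------------------------------------------------

def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".yaml")


def _config_to_dict(config: ScanPatternConfig) -> dict:
    return dataclasses.asdict(config)


def write_volume(volume: ScanVolume, path: str | Path) -> None:
    """Write a volume as a multi-page TIFF (page = one B-scan, rows = depth)
    plus a YAML metadata sidecar.  Round-trips bit-exactly."""
    path = Path(path)
    pages = np.transpose(volume.intensities, (1, 2, 0))  # (slow, depth, fast)
    tifffile.imwrite(path, np.ascontiguousarray(pages))
    meta = {
        "config": _config_to_dict(volume.config),
        "subject_id": volume.subject_id,
        "eye_label": volume.eye_label,
        "dtype": str(volume.intensities.dtype),
    }
    _sidecar_path(path).write_text(yaml.safe_dump(meta))


def read_volume(path: str | Path, metadata: dict | None = None) -> ScanVolume:
    """Read a volume written by :func:`write_volume`.

    ``metadata`` overrides the sidecar (a plain dict with the same keys);
    dimension mismatches between the stack and the metadata are reported with
    both shapes, and negative pixels are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if metadata is None:
        side = _sidecar_path(path)
        if not side.exists():
            raise FileNotFoundError(f"metadata sidecar missing: {side}")
        metadata = yaml.safe_load(side.read_text())
    config = ScanPatternConfig(**metadata["config"])
    pages = tifffile.imread(path)
    if pages.ndim == 2:
        pages = pages[None]
    stack_shape = (pages.shape[2], pages.shape[0], pages.shape[1])
    expected = (config.n_fast, config.n_slow, config.n_depth)
    if stack_shape != expected:
        raise ValidationError(
            f"stack shape (fast, slow, depth) = {stack_shape} does not match "
            f"metadata {expected}")
    intensities = np.transpose(pages, (2, 0, 1))
    if intensities.size and float(intensities.min()) < 0:
        raise ValidationError("stack contains negative intensities")
    return ScanVolume(intensities=intensities, config=config,
                      subject_id=metadata.get("subject_id", ""),
                      eye_label=metadata.get("eye_label", ""))


def write_surfaces(surfaces: BoundarySurfaces, directory: str | Path) -> None:
    """One single-page float TIFF per boundary surface."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name in SURFACE_NAMES:
        tifffile.imwrite(directory / f"{name}.tif",
                         surfaces[name].astype(np.float64))


def read_surfaces(directory: str | Path) -> BoundarySurfaces:
    directory = Path(directory)
    surfaces = {}
    for name in SURFACE_NAMES:
        p = directory / f"{name}.tif"
        if not p.exists():
            raise FileNotFoundError(p)
        surfaces[name] = tifffile.imread(p)
    return BoundarySurfaces(surfaces=surfaces)


def write_angiogram(angio: EnFaceAngiogram, path: str | Path) -> None:
    path = Path(path)
    tifffile.imwrite(path, angio.image.astype(np.float64))
    meta = {"lateral_spacing": float(angio.lateral_spacing),
            "device": angio.device, "layer_name": angio.layer_name}
    _sidecar_path(path).write_text(yaml.safe_dump(meta))


def read_angiogram(path: str | Path) -> EnFaceAngiogram:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    meta = yaml.safe_load(_sidecar_path(path).read_text())
    return EnFaceAngiogram(image=tifffile.imread(path), **meta)


def write_mask(mask: LayerMask, path: str | Path) -> None:
    pages = np.transpose(mask.mask.astype(np.uint8), (1, 2, 0))
    tifffile.imwrite(Path(path), np.ascontiguousarray(pages))


def read_mask(path: str | Path, layer_name: str) -> LayerMask:
    pages = tifffile.imread(Path(path))
    if pages.ndim == 2:
        pages = pages[None]
    return LayerMask(mask=np.transpose(pages, (2, 0, 1)) > 0,
                     layer_name=layer_name)


def write_report_tables(report, directory: str | Path) -> list[Path]:
    """Write the comparison report as CSV tables (comma, header, UTF-8).

    Emits per-subject metrics, the per-layer paired-test summary, the
    regression summary (ΔS vs CSV and inter-device CSV) and the Bland-Altman
    summary.  Raises :class:`DegenerateInputError` on an empty report and
    writes nothing in that case.
    """
    tables = {
        "per_subject_metrics.csv": report.subjects,
        "paired_tests.csv": report.paired_tests,
        "regressions.csv": report.regressions,
        "bland_altman.csv": report.bland_altman,
    }
    if report.subjects is None or len(report.subjects) == 0:
        raise DegenerateInputError("report has no per-subject rows")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []
    for name, frame in tables.items():
        out = directory / name
        frame.to_csv(out, index=False)
        written.append(out)
    return written
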