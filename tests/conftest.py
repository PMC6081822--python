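"""Shared fixtures: scaled-down scan grids and tiny geometries.

The small grids keep every physical convention of the builtin protocols
(field widths, axial pitch, device identities) at a fraction of the A-line
counts, so unit tests exercise the full code paths quickly; acceptance
tests use the real grids.
"""

import numpy as np
import pytest

from octa_compare.datamodel import ScanPatternConfig
from octa_compare.synth import GeometryParams, build_geometry


def _small(device, pattern, n, pitch, repeats, n_depth=400):
    return ScanPatternConfig(device=device, pattern_name=pattern, n_fast=n,
                             n_slow=n, lateral_spacing=pitch, repeats=repeats,
                             n_depth=n_depth)


@pytest.fixture(scope="session")
def small_configs():
    """All four device × pattern combinations on reduced grids."""
    return {
        ("SD", "3x3mm"): _small("SD", "3x3mm", 75, 40.0, 4),
        ("SS", "3x3mm"): _small("SS", "3x3mm", 100, 30.0, 4),
        ("SD", "6x6mm"): _small("SD", "6x6mm", 120, 50.0, 2),
        ("SS", "6x6mm"): _small("SS", "6x6mm", 150, 40.0, 2),
    }


@pytest.fixture(scope="session")
def cfg_sd3(small_configs):
    return small_configs[("SD", "3x3mm")]


@pytest.fixture(scope="session")
def cfg_ss3(small_configs):
    return small_configs[("SS", "3x3mm")]


@pytest.fixture(scope="session")
def flat_geometry():
    """A normal (dome-free) eye with deterministic anatomy."""
    params = GeometryParams(thickness_jitter_sd_um=0.0,
                            elevation_jitter_sd_um=0.0,
                            reflectivity_jitter_sd=0.0)
    geometry, _ = build_geometry(params, seed=0)
    return geometry


@pytest.fixture(scope="session")
def dome_geometry():
    """A CSR eye with the reference half-ellipsoid dome (a=b=0.5, c=0.2)."""
    params = GeometryParams(dome_a_mm=0.5, dome_b_mm=0.5, dome_c_mm=0.2,
                            thickness_jitter_sd_um=0.0,
                            elevation_jitter_sd_um=0.0,
                            reflectivity_jitter_sd=0.0)
    geometry, _ = build_geometry(params, seed=0)
    return geometry


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
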