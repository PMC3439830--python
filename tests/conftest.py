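"""Shared fixtures: analytic phantoms and cached pipeline runs.

Expensive artifacts (full pipeline runs) are session-scoped; every test
input is generated programmatically from the phantom module.
"""

from __future__ import annotations

import numpy as np
import pytest

import c8morph as c8

# Standard study phantom: half-annulus band, r=8 mm, R=12 mm (4 mm thick,
# mid-radius 10 mm), 0.5 mm partial-volume blur, 1 mm isotropic voxels.
STD_CENTER = (0.0, 15.0)
STD_INNER, STD_OUTER = 8.0, 12.0
STD_AREA = np.pi * (STD_OUTER**2 - STD_INNER**2) / 2  # 125.664 mm^2
STD_LENGTH = np.pi * (STD_INNER + STD_OUTER) / 2      # 31.416 mm
STD_THICKNESS = STD_OUTER - STD_INNER                 # 4 mm


@pytest.fixture(scope="session")
def std_spec() -> c8.PhantomSpec:
    return c8.PhantomSpec(inner_radius_mm=STD_INNER, outer_radius_mm=STD_OUTER,
                          center_mni=STD_CENTER, blur_sigma_mm=0.5)


@pytest.fixture(scope="session")
def std_phantom(std_spec):
    return c8.make_arch_phantom(std_spec)


@pytest.fixture(scope="session")
def std_volume(std_phantom):
    return std_phantom[0]


@pytest.fixture(scope="session")
def std_truth(std_phantom):
    return std_phantom[1]


@pytest.fixture(scope="session")
def std_config() -> c8.C8Config:
    return c8.C8Config()


@pytest.fixture(scope="session")
def std_report(std_volume, std_config):
    return c8.run_c8(std_volume, std_config)


@pytest.fixture(scope="session")
def std_slice(std_volume):
    """Midsagittal slice of the standard phantom (no orientation filter)."""
    return c8.extract_parasagittal_slices(std_volume, [0.0])[0]


@pytest.fixture(scope="session")
def std_cluster(std_slice):
    return c8.extract_callosum(std_slice)


@pytest.fixture(scope="session")
def std_line(std_slice, std_cluster):
    centroid = c8.compute_centroid(std_cluster)
    fan = c8.cast_radial_rays(std_slice, std_cluster, centroid)
    return c8.build_median_line(fan, std_cluster)


def make_band_slice(z_lo=10.0, z_hi=14.0, spacing=1.0, y_span=(-20.0, 20.0),
                    z_span=(0.0, 30.0)) -> c8.WMSliceMap:
    """Binary horizontal band: p=1 for z in [z_lo, z_hi), sharp edges."""
    y_axis = np.arange(y_span[0], y_span[1] + spacing / 2, spacing)
    z_axis = np.arange(z_span[0], z_span[1] + spacing / 2, spacing)
    data = np.zeros((y_axis.size, z_axis.size))
    data[:, (z_axis >= z_lo) & (z_axis < z_hi)] = 1.0
    return c8.WMSliceMap(data=data, x_offset_mm=0.0, y_axis=y_axis, z_axis=z_axis)
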