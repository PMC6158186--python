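"""Shared fixtures: small geometries, cached transients, canned event tables.

Expensive fixtures are session-scoped; the full-resolution single-AP
reaction-diffusion solution is computed once and reused by every test that
needs a realistic Ca2+ transient.
"""

from __future__ import annotations

import numpy as np
import pytest

from simplesyn.calcium3d import (
    CalciumTransient,
    InfluxSpec,
    SimConfig,
    default_buffers,
    run_single_ap,
)
from simplesyn.geometry import GeometryConfig, build_geometry


@pytest.fixture(scope="session")
def small_geometry():
    """Degenerate one-cluster geometry on a coarse 20 nm grid."""
    return build_geometry(
        GeometryConfig(box_um=(0.3, 0.3, 0.3), voxel_nm=20.0, n_clusters=1,
                       channels_per_cluster=9)
    )


@pytest.fixture(scope="session")
def coarse_single_ap(small_geometry):
    """Fast coarse-grid single-AP transient for stepper-level tests."""
    sim = SimConfig(dt_us=0.25, t_end_ms=1.5, record_interval_us=10.0)
    return run_single_ap(small_geometry, default_buffers(), InfluxSpec(ap_times_ms=(0.3,)), sim)


@pytest.fixture(scope="session")
def reference_single_ap():
    """Full-resolution (10 nm, default geometry) single-AP transient.

    This is the study-condition Ca2+ input used by the release-model tests;
    computed once per session (a few minutes).
    """
    sim = SimConfig(dt_us=0.07, t_end_ms=3.0, record_interval_us=10.0)
    return run_single_ap(build_geometry(), default_buffers(), InfluxSpec(ap_times_ms=(0.5,)), sim)


@pytest.fixture(scope="session")
def synthetic_transient():
    """Cheap analytic stand-in for a single-AP Ca2+ transient.

    A lognormal-shaped local spike (peak ~45 uM at ~0.65 ms) over a slow
    global elevation; synthetic, used where the exact microdomain shape
    does not matter.
    """
    t = np.arange(0.0, 5.0 + 1e-9, 0.01)
    peak_t, width = 0.65, 0.28
    spike = np.exp(-0.5 * ((np.log((t + 1e-9) / peak_t)) / width) ** 2)
    local = 0.05 + 45.0 * spike
    glob = 0.05 + 0.95 * (1 - np.exp(-np.maximum(t - 0.4, 0) / 0.25)) * np.exp(
        -np.maximum(t - 0.4, 0) / 40.0
    )
    return CalciumTransient(t, local + glob - 0.05, glob)
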