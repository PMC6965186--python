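"""Shared fixtures. Expensive phantom/tracking fixtures are session-scoped."""

from __future__ import annotations

import numpy as np
import pytest

from lung4dxv.core import Volume4D
from lung4dxv.gated_recon import ReconGeometry
from lung4dxv.phantom import (
    DefectSpec,
    PhantomSpec,
    forward_project,
    simulate_breath_series,
    speckle_texture,
)
from lung4dxv.velocimetry import XVParams, track_breath


def default_tau_defect_spec() -> PhantomSpec:
    """Default breathing lung plus one pure time-constant defect.

    The defect slows expiration (tau x2) in the terminal regions whose
    endpoints fall inside a sphere covering roughly one lateral half of
    the lung; expansion is untouched (expansion_scale = 1), so
    inspiration-phase measurements are identical to the healthy lung.
    """
    base = PhantomSpec()
    c, semi = base.lung_center, base.lung_semiaxes
    defect = DefectSpec(
        center=(c[0], c[1], c[2] - 0.6 * semi[2]),
        radius=0.9 * semi[2],
        expansion_scale=1.0,
        tau_scale=2.0,
    )
    return PhantomSpec(defects=(defect,))


@pytest.fixture(scope="session")
def breath():
    """Generation-6 breathing lung at 128^3, 15 phases, with a tau defect."""
    return simulate_breath_series(default_tau_defect_spec())


@pytest.fixture(scope="session")
def tracked(breath):
    """XV tracking of the session breath (32^3 windows, 50% overlap)."""
    params = XVParams(lung_mask=breath.lung_mask)
    return track_breath(breath.volume4d, params)


@pytest.fixture(scope="session")
def speckle128():
    """Pure speckle phantom for shift-recovery oracles.

    Grain 3 voxels: the optimal feature size for 32^3 interrogation
    windows (a few voxels per speckle cell, many cells per window).
    """
    return 0.5 + 0.16 * speckle_texture((128, 128, 128), 3.0, 1)


@pytest.fixture(scope="session")
def sphere64():
    n = 64
    z, y, x = np.mgrid[0:n, 0:n, 0:n].astype(float)
    c = (n - 1) / 2.0
    return ((z - c) ** 2 + (y - c) ** 2 + (x - c) ** 2 <= 20.0**2).astype(np.float32)


@pytest.fixture(scope="session")
def sphere_projections(sphere64):
    """200 cone-beam projections of the sphere at unit effective pixel."""
    geom = ReconGeometry(r1=200.0, r2=400.0, detector_pitch=2.0, detector_shape=(80, 80))
    angles = np.arange(200) * 360.0 / 200.0
    return forward_project(sphere64, geom, angles), geom


@pytest.fixture()
def small_volume4d():
    rng = np.random.default_rng(0)
    data = rng.random((3, 24, 20, 22)).astype(np.float32)
    return Volume4D(data, voxel_size=0.5, phase_times=[0.0, 10.0, 20.0])
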