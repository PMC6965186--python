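"""Respiratory-gated cone-beam CT: projection binning and FDK reconstruction.

Acquisition model: the animal rotates continuously through 360 deg while
being ventilated; the camera is triggered by the ventilator at a fixed
frame rate, so each frame lands at a fixed time bin within the breath.
When the frame rate and respiratory rate are commensurate, every breath
contributes one frame per bin and binning the frames by phase yields a
full angular sweep per time bin (e.g. 30 fps at 120 breaths/min gives 15
bins; 6000 frames give 400 projections per bin).

Reconstruction is a Feldkamp-type (FDK) filtered backprojection on a
circular source orbit: cosine pre-weighting, row-wise ramp filtering, and
distance-weighted backprojection. Projections need not be uniformly
spaced in angle — each is weighted by its angular gap, which is what a
gated one-frame-per-breath acquisition produces.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .core import Volume4D

__all__ = [
    "ReconGeometry",
    "ProjectionSet",
    "GatingSchedule",
    "GatingError",
    "GeometryError",
    "phases_per_breath",
    "bin_projections_by_phase",
    "effective_pixel_size",
    "fdk_reconstruct",
    "reconstruct_4d",
]


class GatingError(ValueError):
    """Inconsistent gating schedule (phase bins would drift between breaths)."""


class GeometryError(ValueError):
    """Invalid cone-beam geometry."""


@dataclass(frozen=True)
class ReconGeometry:
    """Circular cone-beam geometry.

    ``r1``/``r2`` are source-to-isocenter and source-to-detector distances
    (any consistent length unit; the bench described by the acquisition
    protocol uses 0.36 m and 3.0 m), ``detector_pitch`` the physical pixel
    size, ``detector_shape`` (rows, cols) = (v, u).
    """

    r1: float
    r2: float
    detector_pitch: float
    detector_shape: tuple[int, int]

    def __post_init__(self) -> None:
        if not (0 < self.r1 < self.r2):
            raise GeometryError(f"need 0 < r1 < r2, got r1={self.r1}, r2={self.r2}")
        if self.detector_pitch <= 0:
            raise GeometryError("detector_pitch must be positive")

    @property
    def magnification(self) -> float:
        return self.r2 / self.r1


@dataclass
class ProjectionSet:
    """Stack of 2D projections with per-frame angle and breath-phase tag."""

    images: np.ndarray  # (n, v, u)
    angles: np.ndarray  # degrees in [0, 360)
    phase_tags: np.ndarray  # int time-bin index per projection

    def __post_init__(self) -> None:
        self.images = np.asarray(self.images)
        self.angles = np.asarray(self.angles, dtype=float)
        self.phase_tags = np.asarray(self.phase_tags, dtype=int)
        if self.images.ndim != 3:
            raise ValueError("images must be a (n, v, u) stack")
        n = self.images.shape[0]
        if len(self.angles) != n or len(self.phase_tags) != n:
            raise ValueError("images, angles and phase_tags must have equal length")

    def __len__(self) -> int:
        return int(self.images.shape[0])

    def select(self, idx: np.ndarray) -> "ProjectionSet":
        return ProjectionSet(self.images[idx], self.angles[idx], self.phase_tags[idx])


@dataclass(frozen=True)
class GatingSchedule:
    """Ventilator-triggered gating: camera frames per breath define the bins."""

    frame_rate: float  # frames / s
    respiratory_rate: float  # breaths / min
    n_phases: int = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.frame_rate <= 0 or self.respiratory_rate <= 0:
            raise GatingError("rates must be positive")
        derived = self.frame_rate * 60.0 / self.respiratory_rate
        if abs(derived - round(derived)) > 1e-9:
            raise GatingError(
                f"{self.frame_rate} fps at {self.respiratory_rate} breaths/min gives "
                f"{derived:.4f} frames per breath — gating would drift; rates must "
                "divide evenly"
            )
        if self.n_phases is None:
            object.__setattr__(self, "n_phases", int(round(derived)))
        elif self.n_phases != int(round(derived)):
            raise GatingError(
                f"n_phases={self.n_phases} inconsistent with "
                f"{self.frame_rate} fps / {self.respiratory_rate} bpm (= {derived:.0f})"
            )

    @property
    def breath_period_ms(self) -> float:
        return 60000.0 / self.respiratory_rate


def phases_per_breath(schedule: GatingSchedule) -> int:
    """Number of time bins per breath: frame_rate * 60 / respiratory_rate.

    30 fps at 120 breaths/min -> 15 bins.
    """
    return schedule.n_phases


def bin_projections_by_phase(
    projections: ProjectionSet, schedule: GatingSchedule
) -> list[ProjectionSet]:
    """Partition projections into one ProjectionSet per breath time bin.

    Every input projection lands in exactly one output set (counts are
    conserved); angles travel with their frames. Empty bins are an error —
    that phase could not be reconstructed.
    """
    n_phases = schedule.n_phases
    if np.any(projections.phase_tags < 0) or np.any(projections.phase_tags >= n_phases):
        raise GatingError("phase tags outside [0, n_phases)")
    sets = []
    empty = []
    for p in range(n_phases):
        idx = np.flatnonzero(projections.phase_tags == p)
        if idx.size == 0:
            empty.append(p)
        sets.append(projections.select(idx))
    if empty:
        raise GatingError(f"no projections in phase bins {empty}")
    return sets


def effective_pixel_size(geometry: ReconGeometry) -> float:
    """Detector pixel demagnified to the isocenter: pitch * r1 / r2."""
    return geometry.detector_pitch * geometry.r1 / geometry.r2


# ---------------------------------------------------------------------------
# FDK filtered backprojection
# ---------------------------------------------------------------------------


def _ramp_filter_rows(proj: np.ndarray, pitch: float, window: str = "hann") -> np.ndarray:
    """Apply a ramp filter along the detector u axis (last axis)."""
    nu = proj.shape[-1]
    npad = 1 << int(np.ceil(np.log2(2 * nu)))
    f = np.fft.rfftfreq(npad, d=pitch)
    h = np.abs(f)
    if window == "hann":
        h = h * (0.5 + 0.5 * np.cos(np.pi * f / f[-1]))
    elif window != "ramp":
        raise ValueError(f"unknown filter window {window!r}")
    spec = np.fft.rfft(proj, n=npad, axis=-1)
    out = np.fft.irfft(spec * h, n=npad, axis=-1)[..., :nu]
    return out


def _angular_weights(angles_deg: np.ndarray) -> np.ndarray:
    """Per-projection angular gap (radians) on the circle, half-gap rule."""
    a = np.deg2rad(np.mod(angles_deg, 360.0))
    order = np.argsort(a)
    sa = a[order]
    gaps = np.diff(np.concatenate([sa, sa[:1] + 2 * np.pi]))
    w = np.empty_like(sa)
    w = 0.5 * (gaps + np.roll(gaps, 1))
    out = np.empty_like(w)
    out[order] = w
    return out


def fdk_reconstruct(
    per_phase: ProjectionSet,
    geometry: ReconGeometry,
    out_shape: tuple[int, int, int],
    voxel_size: float | None = None,
    window: str = "hann",
) -> np.ndarray:
    """Feldkamp filtered backprojection of one phase bin onto a cube at isocenter.

    The reconstruction grid is centered on the isocenter with voxel size
    defaulting to the effective (demagnified) detector pixel. The result
    is linear in the projection data; projections are weighted by their
    angular gaps so non-uniform gated angle sets reconstruct correctly.
    """
    if len(per_phase) == 0:
        raise ValueError("empty projection set")
    if voxel_size is None:
        voxel_size = effective_pixel_size(geometry)
    r1 = geometry.r1 / voxel_size  # work in voxel units
    m = geometry.r1 / geometry.r2
    pitch_iso = geometry.detector_pitch * m / voxel_size
    nv, nu = per_phase.images.shape[1:]

    # cosine weighting on the virtual detector at the isocenter
    u = (np.arange(nu) - (nu - 1) / 2.0) * pitch_iso
    v = (np.arange(nv) - (nv - 1) / 2.0) * pitch_iso
    uu, vv = np.meshgrid(u, v)
    cosw = r1 / np.sqrt(r1**2 + uu**2 + vv**2)

    weights = _angular_weights(per_phase.angles)

    nz, ny, nx = out_shape
    zc = np.arange(nz) - (nz - 1) / 2.0
    yc = np.arange(ny) - (ny - 1) / 2.0
    xc = np.arange(nx) - (nx - 1) / 2.0
    Z, Y, X = np.meshgrid(zc, yc, xc, indexing="ij")
    vol = np.zeros(out_shape, dtype=np.float64)

    for img, ang, dbeta in zip(per_phase.images, per_phase.angles, weights):
        beta = np.deg2rad(ang)
        filt = _ramp_filter_rows(img.astype(np.float64) * cosw, pitch_iso, window)
        s = X * np.cos(beta) + Y * np.sin(beta)
        t = -X * np.sin(beta) + Y * np.cos(beta)
        U = r1 - s
        ui = (t * r1 / U) / pitch_iso + (nu - 1) / 2.0
        vi = (Z * r1 / U) / pitch_iso + (nv - 1) / 2.0
        samp = ndimage.map_coordinates(
            filt, [vi.ravel(), ui.ravel()], order=1, mode="constant", cval=0.0
        ).reshape(out_shape)
        vol += dbeta * (r1**2 / U**2) * samp

    return (vol / 2.0).astype(np.float32)


def reconstruct_4d(
    projections: ProjectionSet,
    schedule: GatingSchedule,
    geometry: ReconGeometry,
    out_shape: tuple[int, int, int],
    voxel_size: float | None = None,
    window: str = "hann",
) -> Volume4D:
    """Bin projections by breath phase and reconstruct one volume per bin."""
    per_phase = bin_projections_by_phase(projections, schedule)
    vols = [
        fdk_reconstruct(ps, geometry, out_shape, voxel_size=voxel_size, window=window)
        for ps in per_phase
    ]
    period = schedule.breath_period_ms
    times = np.arange(schedule.n_phases) * period / schedule.n_phases
    if voxel_size is None:
        voxel_size = effective_pixel_size(geometry)
    return Volume4D(np.stack(vols), voxel_size=voxel_size, phase_times=times)
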