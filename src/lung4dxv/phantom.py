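"""Synthetic breathing-lung phantom with known ground truth.

Builds a 4D CT-like dataset that every downstream stage (reconstruction,
airway segmentation, velocimetry, airway-tree airflow analysis) can be
validated against:

* a full binary airway tree embedded in an ellipsoidal lung envelope,
* speckled parenchyma texture (band-limited random field) emulating the
  phase-contrast lung speckle that velocimetry tracks,
* a smooth analytic displacement field — uniform dilation about the lung
  centre, modulated by spherical "defect" regions and a per-region
  expiratory time constant — whose divergence is available in closed
  form, so regional air-volume ground truth is exact,
* optional cone-beam forward projection with ventilator-trigger phase
  tags, to exercise the gated reconstruction stage.

Temporal profile of the breath: a raised-cosine rise over the
inspiratory time, then exponential decay exp(-(t - t_insp)/tau) over
expiration, so the expiratory time constant is a direct phantom
parameter and its recovery can be tested.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .core import AirwaySegment, AirwayTree, TreeError, Volume4D
from .gated_recon import GeometryError, ProjectionSet, ReconGeometry, GatingSchedule

__all__ = [
    "VentilationProtocol",
    "DefectSpec",
    "PhantomSpec",
    "DisplacementTruth",
    "BreathSeries",
    "generate_airway_tree",
    "lung_envelope_mask",
    "airway_lumen_mask",
    "render_reference_volume",
    "analytic_displacement",
    "simulate_breath_series",
    "forward_project",
]


@dataclass(frozen=True)
class VentilationProtocol:
    """Ventilator settings: pressures, inspiratory/expiratory times, rates.

    Defaults follow a small-animal protocol of 12/2 cm H2O PIP/PEEP,
    250/250 ms inspiration/expiration (hence 120 breaths/min) imaged at
    30 frames/s. The pressures are metadata only — no mechanics are
    modelled.
    """

    pip: float = 12.0  # cm H2O
    peep: float = 2.0  # cm H2O
    t_insp: float = 250.0  # ms
    t_exp: float = 250.0  # ms
    respiratory_rate: float = 120.0  # breaths / min
    frame_rate: float = 30.0  # frames / s

    def __post_init__(self) -> None:
        for name in ("pip", "peep", "t_insp", "t_exp", "respiratory_rate", "frame_rate"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if abs(self.t_insp + self.t_exp - 60000.0 / self.respiratory_rate) > 1e-6:
            raise ValueError(
                f"t_insp + t_exp = {self.t_insp + self.t_exp} ms inconsistent with "
                f"respiratory rate {self.respiratory_rate}/min "
                f"(breath period {60000.0 / self.respiratory_rate} ms)"
            )

    @classmethod
    def from_times(
        cls,
        t_insp: float,
        t_exp: float,
        pip: float = 12.0,
        peep: float = 2.0,
        frame_rate: float = 30.0,
    ) -> "VentilationProtocol":
        """Build a protocol from inspiratory/expiratory times; the
        respiratory rate follows as 60000 / (t_insp + t_exp)."""
        rate = 60000.0 / (t_insp + t_exp)
        return cls(pip=pip, peep=peep, t_insp=t_insp, t_exp=t_exp,
                   respiratory_rate=rate, frame_rate=frame_rate)

    @property
    def period_ms(self) -> float:
        return self.t_insp + self.t_exp


@dataclass(frozen=True)
class DefectSpec:
    """Spherical region of impaired function, emulating patchy obstructive
    disease: expansion is reduced by ``expansion_scale`` (<= 1) and the
    expiratory time constant slowed by ``tau_scale`` (>= 1)."""

    center: tuple[float, float, float]  # (z, y, x) voxels
    radius: float  # voxels
    expansion_scale: float = 0.5
    tau_scale: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.expansion_scale <= 1.0):
            raise ValueError("expansion_scale must lie in [0, 1] (defects reduce expansion)")
        if self.tau_scale < 1.0:
            raise ValueError("tau_scale must be >= 1 (defects slow expiration)")
        if self.radius <= 0:
            raise ValueError("radius must be positive")


@dataclass(frozen=True)
class PhantomSpec:
    """Full parameterization of the synthetic breathing lung.

    ``tidal_fraction`` is the peak volumetric strain of healthy
    parenchyma (divergence of the displacement field at end-inspiration);
    ``tau_ms`` the baseline expiratory time constant. All randomness
    derives from ``seed`` — identical specs give bit-identical output.
    """

    grid_shape: tuple[int, int, int] = (128, 128, 128)
    voxel_size: float = 1.0
    tree_generations: int = 6
    tidal_fraction: float = 0.12
    speckle_grain: float = 5.0
    noise_sigma: float = 0.0
    n_phases: int = 15
    tau_ms: float = 80.0
    defects: tuple[DefectSpec, ...] = ()
    tau_by_region: bool = True
    ventilation: VentilationProtocol = field(default_factory=VentilationProtocol)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_phases < 2:
            raise ValueError("n_phases must be >= 2")
        if self.tree_generations < 0:
            raise ValueError("tree_generations must be >= 0")
        if not (0.0 <= self.tidal_fraction < 0.5):
            raise ValueError("tidal_fraction must lie in [0, 0.5)")
        if self.tau_ms <= 0:
            raise ValueError("tau_ms must be positive")
        object.__setattr__(self, "defects", tuple(self.defects))
        object.__setattr__(self, "grid_shape", tuple(int(s) for s in self.grid_shape))

    # lung envelope: ellipsoid placed centrally, apex toward low z where
    # the trachea enters
    @property
    def lung_center(self) -> np.ndarray:
        nz, ny, nx = self.grid_shape
        return np.array([0.55 * nz, 0.5 * ny, 0.5 * nx])

    @property
    def lung_semiaxes(self) -> np.ndarray:
        nz, ny, nx = self.grid_shape
        return np.array([0.34 * nz, 0.31 * ny, 0.36 * nx])

    @property
    def phase_times(self) -> np.ndarray:
        period = self.ventilation.period_ms
        return np.arange(self.n_phases) * period / self.n_phases


# ---------------------------------------------------------------------------
# Airway tree generation
# ---------------------------------------------------------------------------


def generate_airway_tree(spec: PhantomSpec) -> AirwayTree:
    """Grow a full binary airway tree inside the lung envelope.

    Space-filling growth: a seeded point cloud fills the ellipsoidal
    envelope; each bifurcation splits its point set in two across the
    set's principal axis and sends one child toward the centroid of each
    half (terminal segments end at their half's centroid). This spreads
    the 2^g terminals evenly through the lung, with branch-angle jitter
    coming from the seeded cloud. Radii decay by 2^(-1/3) per generation
    (Murray-type) and are strictly decreasing down the tree. A tree of g
    generations has 2^(g+1)-1 segments and 2^g terminals.
    """
    rng = np.random.default_rng(spec.seed)
    nz, ny, nx = spec.grid_shape
    c, semi = spec.lung_center, spec.lung_semiaxes

    r0 = 0.040 * min(ny, nx)
    radius_decay = 2.0 ** (-1.0 / 3.0)

    # quasi-uniform target points inside the (slightly shrunk) envelope
    n_targets = max(512, 16 * 2**spec.tree_generations)
    pts: list[np.ndarray] = []
    while len(pts) < n_targets:
        cand = rng.uniform(-1.0, 1.0, size=(n_targets, 3))
        keep = cand[np.linalg.norm(cand, axis=1) <= 0.92]
        pts.extend(keep)
    targets = c + np.array(pts[:n_targets]) * semi

    segments: dict[int, AirwaySegment] = {}
    counter = [0]

    def check_bounds(p: np.ndarray, r: float, seg_id: int) -> None:
        margin = r + 1.0
        if np.any(p - margin < 0) or np.any(p + margin > np.array(spec.grid_shape) - 1):
            raise TreeError(
                f"segment {seg_id} (point {np.round(p, 1).tolist()}, radius {r:.1f}) "
                "exceeds the grid bounds; enlarge grid_shape or reduce tree_generations"
            )

    def make_segment(
        start: np.ndarray, end: np.ndarray, radius: float,
        generation: int, parent_id: int | None,
    ) -> int:
        seg_id = counter[0]
        counter[0] += 1
        check_bounds(start, radius, seg_id)
        check_bounds(end, radius, seg_id)
        length = float(np.linalg.norm(end - start))
        n_pts = max(2, int(np.ceil(length)) + 1)
        line = np.linspace(0.0, 1.0, n_pts)[:, None]
        segments[seg_id] = AirwaySegment(
            id=seg_id, parent_id=parent_id, generation=generation,
            points=start[None, :] + line * (end - start)[None, :],
            radii=np.full(n_pts, radius),
        )
        return seg_id

    def split_targets(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        center = points.mean(axis=0)
        centered = points - center
        # principal axis of the subset; fall back to widest coordinate span
        cov = centered.T @ centered
        w, v = np.linalg.eigh(cov)
        axis = v[:, -1]
        proj = centered @ axis
        order = np.argsort(proj)
        half = len(points) // 2
        return points[order[:half]], points[order[half:]]

    def grow(parent_id: int, generation: int, points: np.ndarray) -> None:
        if generation > spec.tree_generations:
            return
        parent = segments[parent_id]
        radius = r0 * radius_decay**generation
        # branches shorter than the junction blob (~2 radii) would vanish
        # in the skeleton; enforce a radius-tied floor (terminals need
        # extra length to survive tip erosion plus spur pruning)
        terminal = generation == spec.tree_generations
        min_length = (4.5 * radius + 3.0) if terminal else (3.0 * radius + 2.0)
        for sub in split_targets(points):
            centroid = sub.mean(axis=0)
            if terminal:
                end = centroid
            else:
                # advance partway toward the subset centroid
                end = parent.end + 0.45 * (centroid - parent.end)
            if np.linalg.norm(end - parent.end) < min_length:
                d = centroid - parent.end
                n = np.linalg.norm(d)
                d = d / n if n > 1e-9 else np.array([1.0, 0.0, 0.0])
                end = parent.end + min_length * d
            cid = make_segment(parent.end, end, radius, generation, parent_id)
            grow(cid, generation + 1, sub)

    start = np.array([max(0.06 * nz, r0 + 1.5), 0.5 * ny, 0.5 * nx])
    carina = np.array([c[0] - 0.75 * semi[0], 0.5 * ny, 0.5 * nx])
    root = make_segment(start, carina, r0, 0, None)
    grow(root, 1, targets)
    return AirwayTree(segments=segments, root_id=root)


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------


def lung_envelope_mask(spec: PhantomSpec) -> np.ndarray:
    """Binary ellipsoidal lung envelope."""
    nz, ny, nx = spec.grid_shape
    z, y, x = np.ogrid[0:nz, 0:ny, 0:nx]
    c, semi = spec.lung_center, spec.lung_semiaxes
    m2 = (
        ((z - c[0]) / semi[0]) ** 2
        + ((y - c[1]) / semi[1]) ** 2
        + ((x - c[2]) / semi[2]) ** 2
    )
    return m2 <= 1.0


def airway_lumen_mask(tree: AirwayTree, spec: PhantomSpec) -> np.ndarray:
    """Binary air-filled airway lumen, stamped from the tree centerlines."""
    mask = np.zeros(spec.grid_shape, dtype=bool)
    shape = np.array(spec.grid_shape)
    for seg in tree.segments.values():
        p0, p1 = seg.start, seg.end
        r = float(np.max(seg.radii))
        lo = np.maximum(np.floor(np.minimum(p0, p1) - r - 1).astype(int), 0)
        hi = np.minimum(np.ceil(np.maximum(p0, p1) + r + 1).astype(int) + 1, shape)
        if np.any(hi <= lo):
            continue
        z, y, x = np.mgrid[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
        p = np.stack([z, y, x], axis=-1).astype(float)
        d = p1 - p0
        L2 = float(np.dot(d, d))
        t = np.clip(((p - p0) @ d) / max(L2, 1e-12), 0.0, 1.0)
        closest = p0 + t[..., None] * d
        dist2 = np.sum((p - closest) ** 2, axis=-1)
        mask[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] |= dist2 <= r**2
    return mask


#: rendering intensities (arbitrary CT-like units in [0, 1])
_BACKGROUND = 0.45
_PARENCHYMA_MEAN = 0.55
_SPECKLE_AMPLITUDE = 0.16
_LUMEN = 0.08


def speckle_texture(
    shape: tuple[int, int, int], grain: float, seed: int
) -> np.ndarray:
    """Band-limited random texture with autocorrelation FWHM ~ ``grain``.

    Gaussian-smoothed white noise has autocorrelation FWHM
    2*sqrt(2 ln 2) * sigma * sqrt(2) = 3.33 sigma; the kernel width is
    chosen to match the requested grain. Zero mean, unit variance.
    """
    rng = np.random.default_rng(seed)
    texture = ndimage.gaussian_filter(rng.standard_normal(shape), grain / 3.33)
    texture -= texture.mean()
    texture /= max(texture.std(), 1e-12)
    return texture


def render_reference_volume(tree: AirwayTree, spec: PhantomSpec) -> np.ndarray:
    """Render the end-expiration reference volume.

    Parenchyma is a band-limited random texture ("speckle") whose
    autocorrelation width is set by ``speckle_grain``; airway lumens and
    non-lung background are low/flat. Deterministic for a fixed seed.
    """
    texture = speckle_texture(
        spec.grid_shape, spec.speckle_grain / spec.voxel_size, spec.seed + 1
    )

    vol = np.full(spec.grid_shape, _BACKGROUND, dtype=np.float32)
    lung = lung_envelope_mask(spec)
    vol[lung] = _PARENCHYMA_MEAN + _SPECKLE_AMPLITUDE * texture[lung]
    lumen = airway_lumen_mask(tree, spec)
    vol[lumen] = _LUMEN
    return np.clip(vol, 0.0, 1.0)


# ---------------------------------------------------------------------------
# Analytic displacement / expansion ground truth
# ---------------------------------------------------------------------------


class DisplacementTruth:
    """Closed-form breathing displacement field and its divergence.

    u(x, t) = a * phi(t; tau(x)) * g(x) * (x - c)

    with ``a = tidal_fraction / 3`` (so the healthy peak divergence is
    ``tidal_fraction``), ``g`` the defect expansion factor (1 outside
    defects, ``expansion_scale`` inside, cosine-smoothed over a 2-voxel
    shell) and phi a raised-cosine rise over inspiration followed by
    exponential decay with time constant tau(x) over expiration.

    div u = a * phi * (3 g + (x - c) . grad g) away from region-tau
    boundaries; both quantities are evaluated in closed form (no numeric
    differentiation).
    """

    def __init__(self, spec: PhantomSpec, region_labels: np.ndarray | None = None,
                 tree: AirwayTree | None = None) -> None:
        self.spec = spec
        self.center = spec.lung_center
        self.a = spec.tidal_fraction / 3.0
        nz, ny, nx = spec.grid_shape
        z, y, x = np.ogrid[0:nz, 0:ny, 0:nx]
        c = self.center

        g = np.ones(spec.grid_shape, dtype=np.float64)
        term = np.zeros(spec.grid_shape, dtype=np.float64)  # (x-c).grad g
        shell = 2.0  # voxels, smooth transition half-width
        for d in spec.defects:
            dz, dy, dx = d.center
            rho = np.sqrt((z - dz) ** 2 + (y - dy) ** 2 + (x - dx) ** 2)
            s = np.zeros_like(rho)
            s[rho <= d.radius - shell] = 1.0
            band = (rho > d.radius - shell) & (rho < d.radius + shell)
            s[band] = 0.5 * (1.0 + np.cos(np.pi * (rho[band] - (d.radius - shell)) / (2 * shell)))
            ds = np.zeros_like(rho)
            ds[band] = -np.pi / (4 * shell) * np.sin(
                np.pi * (rho[band] - (d.radius - shell)) / (2 * shell)
            )
            factor = 1.0 + (d.expansion_scale - 1.0) * s
            # (x-c).grad of this defect's factor (radial about the defect center)
            rc_dot = (z - c[0]) * (z - dz) + (y - c[1]) * (y - dy) + (x - c[2]) * (x - dx)
            with np.errstate(invalid="ignore", divide="ignore"):
                dterm = (d.expansion_scale - 1.0) * ds * np.where(rho > 0, rc_dot / rho, 0.0)
            # product rule across (assumed non-overlapping) defects
            term = term * factor + dterm * g
            g = g * factor

        self.g = g.astype(np.float32)
        self.grad_term = term.astype(np.float32)
        self.tau = self._build_tau(spec, region_labels, tree).astype(np.float32)

    @staticmethod
    def _build_tau(spec: PhantomSpec, region_labels: np.ndarray | None,
                   tree: AirwayTree | None) -> np.ndarray:
        tau = np.full(spec.grid_shape, spec.tau_ms, dtype=np.float64)
        scaled = [d for d in spec.defects if d.tau_scale > 1.0]
        if not scaled:
            return tau
        if spec.tau_by_region:
            if tree is None:
                tree = generate_airway_tree(spec)
            if region_labels is None:
                region_labels = terminal_region_labels(tree, lung_envelope_mask(spec))
            endpoints = tree.terminal_endpoints()
            for d in scaled:
                slow = [tid for tid, p in endpoints.items()
                        if np.linalg.norm(p - np.array(d.center)) <= d.radius]
                if slow:
                    tau[np.isin(region_labels, slow)] = spec.tau_ms * d.tau_scale
        else:
            nz, ny, nx = spec.grid_shape
            z, y, x = np.ogrid[0:nz, 0:ny, 0:nx]
            for d in scaled:
                dz, dy, dx = d.center
                inside = (z - dz) ** 2 + (y - dy) ** 2 + (x - dx) ** 2 <= d.radius**2
                tau[inside] = spec.tau_ms * d.tau_scale
        return tau

    # -- temporal profile --------------------------------------------------
    def _check_time(self, t: float) -> None:
        if not (0.0 <= t <= self.spec.ventilation.period_ms):
            raise ValueError(
                f"phase_time {t} ms outside breath period "
                f"[0, {self.spec.ventilation.period_ms}] ms"
            )

    def temporal(self, t: float) -> np.ndarray | float:
        """phi(t): raised-cosine rise, then exponential expiratory decay."""
        self._check_time(t)
        t_insp = self.spec.ventilation.t_insp
        if t <= t_insp:
            return 0.5 * (1.0 - np.cos(np.pi * t / t_insp))
        return np.exp(-(t - t_insp) / self.tau)

    def displacement(self, t: float) -> np.ndarray:
        """Vector field (3, z, y, x) in voxels at phase time t (ms)."""
        phi = self.temporal(t)
        nz, ny, nx = self.spec.grid_shape
        amp = self.a * phi * self.g
        c = self.center
        out = np.empty((3, nz, ny, nx), dtype=np.float32)
        out[0] = amp * (np.arange(nz, dtype=np.float32)[:, None, None] - c[0])
        out[1] = amp * (np.arange(ny, dtype=np.float32)[None, :, None] - c[1])
        out[2] = amp * (np.arange(nx, dtype=np.float32)[None, None, :] - c[2])
        return out

    def divergence(self, t: float) -> np.ndarray:
        """Volumetric strain field (z, y, x) at phase time t, closed form."""
        phi = self.temporal(t)
        return (self.a * phi * (3.0 * self.g + self.grad_term)).astype(np.float32)


def analytic_displacement(
    spec: PhantomSpec, phase_time: float, tree: AirwayTree | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Evaluate the ground-truth displacement and divergence at one time."""
    truth = DisplacementTruth(spec, tree=tree)
    return truth.displacement(phase_time), truth.divergence(phase_time)


def terminal_region_labels(tree: AirwayTree, lung_mask: np.ndarray) -> np.ndarray:
    """Assign every lung voxel to its nearest terminal-segment endpoint.

    Returns an int array (z, y, x): terminal segment id inside the mask,
    -1 outside. Distance ties break to the lowest segment id.
    """
    ids = tree.terminal_ids()
    endpoints = np.array([tree.segments[i].end for i in ids])
    labels = np.full(lung_mask.shape, -1, dtype=np.int32)
    coords = np.argwhere(lung_mask)
    if coords.size == 0:
        return labels
    kd = cKDTree(endpoints)
    if len(ids) == 1:
        labels[lung_mask] = ids[0]
        return labels
    dist, nearest = kd.query(coords, k=2)
    pick = np.asarray(nearest)[:, 0].copy()
    # deterministic tie-break: lowest id wins on exact distance ties
    ties = np.isclose(dist[:, 0], dist[:, 1])
    pick[ties] = np.minimum(nearest[ties, 0], nearest[ties, 1])
    id_arr = np.array(ids, dtype=np.int32)
    labels[tuple(coords.T)] = id_arr[pick]
    return labels


# ---------------------------------------------------------------------------
# Breath series assembly
# ---------------------------------------------------------------------------


@dataclass
class BreathSeries:
    """A simulated breath with all ground truth attached."""

    volume4d: Volume4D
    truth: DisplacementTruth
    tree: AirwayTree
    lung_mask: np.ndarray
    lumen_mask: np.ndarray
    region_labels: np.ndarray  # terminal id per lung voxel, -1 outside
    regional_volumes: dict[int, np.ndarray]  # terminal id -> series (n_phases,)
    total_volume: np.ndarray  # (n_phases,) summed air volume vs end-expiration

    @property
    def phase_times(self) -> np.ndarray:
        return self.volume4d.phase_times


def simulate_breath_series(spec: PhantomSpec) -> BreathSeries:
    """Generate the full 4D phantom: warped volumes plus exact ground truth.

    Each phase volume pulls from the end-expiration reference through the
    negated forward displacement (trilinear interpolation) — accurate to
    second order in the strain. Regional air-volume truth integrates the
    closed-form divergence over each terminal region, so the sum over
    regions equals the total lung volume change exactly.
    """
    tree = generate_airway_tree(spec)
    ref = render_reference_volume(tree, spec)
    lung = lung_envelope_mask(spec)
    lumen = airway_lumen_mask(tree, spec)
    labels = terminal_region_labels(tree, lung)
    truth = DisplacementTruth(spec, region_labels=labels, tree=tree)

    times = spec.phase_times
    nz, ny, nx = spec.grid_shape
    zz, yy, xx = np.meshgrid(
        np.arange(nz, dtype=np.float32),
        np.arange(ny, dtype=np.float32),
        np.arange(nx, dtype=np.float32),
        indexing="ij",
    )
    rng = np.random.default_rng(spec.seed + 2)
    phases = np.empty((spec.n_phases, nz, ny, nx), dtype=np.float32)
    for i, t in enumerate(times):
        if t == 0.0 or spec.tidal_fraction == 0.0:
            warped = ref.copy()
        else:
            u = truth.displacement(t)
            warped = ndimage.map_coordinates(
                ref, [zz - u[0], yy - u[1], xx - u[2]], order=1, mode="nearest"
            ).astype(np.float32)
        if spec.noise_sigma > 0:
            warped = warped + spec.noise_sigma * rng.standard_normal(
                (nz, ny, nx)
            ).astype(np.float32)
        phases[i] = warped

    vol4d = Volume4D(phases, voxel_size=spec.voxel_size, phase_times=times)

    voxel_vol = spec.voxel_size**3
    ids = tree.terminal_ids()
    flat_labels = labels[lung]
    regional = {tid: np.zeros(spec.n_phases) for tid in ids}
    total = np.zeros(spec.n_phases)
    max_id = max(ids)
    for i, t in enumerate(times):
        div = truth.divergence(t)[lung].astype(np.float64)
        sums = np.bincount(flat_labels, weights=div, minlength=max_id + 1)
        for tid in ids:
            regional[tid][i] = sums[tid] * voxel_vol
        total[i] = div.sum() * voxel_vol

    return BreathSeries(
        volume4d=vol4d, truth=truth, tree=tree, lung_mask=lung, lumen_mask=lumen,
        region_labels=labels, regional_volumes=regional, total_volume=total,
    )


# ---------------------------------------------------------------------------
# Cone-beam forward projection
# ---------------------------------------------------------------------------


def _project_one(
    volume: np.ndarray, geometry: ReconGeometry, beta_deg: float,
    voxel_size: float, step: float,
) -> np.ndarray:
    """Line-integral cone-beam projection of one volume at one angle."""
    r1 = geometry.r1 / voxel_size
    r2 = geometry.r2 / voxel_size
    pitch = geometry.detector_pitch / voxel_size
    nv, nu = geometry.detector_shape
    beta = np.deg2rad(beta_deg)

    src = np.array([0.0, r1 * np.sin(beta), r1 * np.cos(beta)])  # (Z, Y, X)
    det_c = np.array([0.0, -(r2 - r1) * np.sin(beta), -(r2 - r1) * np.cos(beta)])
    e_u = np.array([0.0, np.cos(beta), -np.sin(beta)])
    e_v = np.array([1.0, 0.0, 0.0])

    u = (np.arange(nu) - (nu - 1) / 2.0) * pitch
    v = (np.arange(nv) - (nv - 1) / 2.0) * pitch
    vv, uu = np.meshgrid(v, u, indexing="ij")
    pix = det_c[None, None, :] + uu[..., None] * e_u + vv[..., None] * e_v
    rays = pix - src
    norms = np.linalg.norm(rays, axis=-1, keepdims=True)
    rays = rays / norms

    shape = np.array(volume.shape, dtype=float)
    rmax = 0.5 * float(np.linalg.norm(shape))
    ts = np.arange(r1 - rmax, r1 + rmax + step, step)
    # sample points: (nv, nu, nsteps, 3)
    pts = src[None, None, None, :] + rays[:, :, None, :] * ts[None, None, :, None]
    center = (shape - 1) / 2.0
    idx = pts + center[None, None, None, :]
    vals = ndimage.map_coordinates(
        volume,
        [idx[..., 0].ravel(), idx[..., 1].ravel(), idx[..., 2].ravel()],
        order=1, mode="constant", cval=0.0,
    ).reshape(idx.shape[:3])
    return (vals.sum(axis=-1) * step).astype(np.float32)


def forward_project(
    volume: np.ndarray | Volume4D,
    geometry: ReconGeometry,
    angles: np.ndarray,
    schedule: GatingSchedule | None = None,
    voxel_size: float = 1.0,
    step: float = 0.7,
) -> ProjectionSet:
    """Simulate a gated cone-beam acquisition.

    For a static 3D volume every frame projects the same object (phase
    tags all 0, or cycling if a schedule is given). For a ``Volume4D``
    frame ``i`` receives phase tag ``i mod n_phases`` — the ventilator
    trigger — and projects that phase's volume, emulating continuous
    rotation during breathing.
    """
    if geometry.r1 >= geometry.r2:  # pragma: no cover - caught by ReconGeometry
        raise GeometryError("r1 must be < r2")
    angles = np.asarray(angles, dtype=float)
    n = len(angles)
    if isinstance(volume, Volume4D):
        n_phases = volume.n_phases
        if schedule is not None and schedule.n_phases != n_phases:
            raise GatingError(
                f"schedule has {schedule.n_phases} phases but volume has {n_phases}"
            )
        tags = np.arange(n) % n_phases
        vsize = volume.voxel_size
        images = np.stack([
            _project_one(volume.phase(int(tag)), geometry, ang, vsize, step)
            for ang, tag in zip(angles, tags)
        ])
    else:
        vol = np.asarray(volume, dtype=np.float32)
        tags = (np.arange(n) % schedule.n_phases) if schedule is not None else np.zeros(n, int)
        images = np.stack([
            _project_one(vol, geometry, ang, voxel_size, step) for ang in angles
        ])
    return ProjectionSet(images=images, angles=angles, phase_tags=tags)
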