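"""3D cross-correlation velocimetry (the XV core).

Lung tissue displacement between successive breath phases is measured by
windowed, normalized 3D cross-correlation: the volume is tiled with
cubic interrogation regions (default 32^3 voxels, 50% overlap), each
window pair is correlated in the frequency domain, the correlation peak
is refined to subvoxel precision with a 3-point Gaussian fit per axis,
and vectors are validated by the primary-to-secondary peak ratio.
The regional expansion rate is the divergence of the displacement field,
computed by central differences on the interrogation grid.

Before correlation the volumes are Gaussian-smoothed and bandpass
filtered to enhance speckle visibility and suppress both low-frequency
anatomy and voxel noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .core import Volume4D

__all__ = [
    "XVParams",
    "GridSpec",
    "DisplacementField",
    "ExpansionField",
    "preprocess",
    "build_grid",
    "correlate_pair",
    "displacement_field",
    "expansion",
    "track_breath",
    "BreathTracking",
]


@dataclass(frozen=True)
class XVParams:
    """Velocimetry configuration.

    ``window``: interrogation region edge length (voxels); ``overlap``:
    fraction shared by neighbouring regions; ``band_low``/``band_high``:
    radial passband in cycles/voxel for speckle enhancement;
    ``peak_quality_min``: minimum primary/secondary correlation peak
    ratio for a vector to count as valid; ``fill_invalid``: replace
    invalid interior vectors by the median of their valid neighbours.
    """

    window: int = 32
    overlap: float = 0.5
    smooth_sigma: float = 1.0
    band_low: float = 0.02
    band_high: float = 0.25
    peak_quality_min: float = 1.2
    lung_mask: np.ndarray | None = None
    fill_invalid: bool = True
    subpixel: str = "gaussian"  # or "parabolic"

    def __post_init__(self) -> None:
        if self.window < 8:
            raise ValueError("window must be >= 8 voxels")
        if not (0.0 <= self.overlap < 1.0):
            raise ValueError("overlap must lie in [0, 1)")
        if not (0.0 <= self.band_low < self.band_high):
            raise ValueError("need 0 <= band_low < band_high")
        if self.subpixel not in ("gaussian", "parabolic"):
            raise ValueError("subpixel must be 'gaussian' or 'parabolic'")

    @property
    def step(self) -> int:
        return max(1, int(round(self.window * (1.0 - self.overlap))))


@dataclass(frozen=True)
class GridSpec:
    """Interrogation grid: node centers along each axis (voxel coords)."""

    origin: tuple[float, float, float]  # center of first window per axis
    spacing: int  # voxels between nodes
    shape: tuple[int, int, int]  # nodes per axis
    window: int

    def centers(self, axis: int) -> np.ndarray:
        return self.origin[axis] + self.spacing * np.arange(self.shape[axis])

    def starts(self, axis: int) -> np.ndarray:
        return (self.centers(axis) - self.window / 2.0).astype(int)

    def node_coords(self) -> np.ndarray:
        """(nz, ny, nx, 3) array of node center coordinates."""
        zz, yy, xx = np.meshgrid(
            self.centers(0), self.centers(1), self.centers(2), indexing="ij"
        )
        return np.stack([zz, yy, xx], axis=-1)


@dataclass
class DisplacementField:
    """Displacement vectors on the interrogation grid.

    ``vectors[..., k]`` is the displacement along axis k (voxels) of the
    second volume relative to the first; ``quality`` the correlation
    peak ratio; ``valid`` marks trustworthy vectors; ``filled`` marks
    invalid nodes that were median-replaced from their neighbours.
    """

    grid: GridSpec
    vectors: np.ndarray  # (nz, ny, nx, 3)
    quality: np.ndarray  # (nz, ny, nx)
    valid: np.ndarray  # bool
    filled: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.filled is None:
            self.filled = np.zeros_like(self.valid)


@dataclass
class ExpansionField:
    """Volumetric expansion rate (divergence of displacement) per node."""

    grid: GridSpec
    values: np.ndarray  # (nz, ny, nx)
    valid: np.ndarray  # bool — full central-difference stencil of usable nodes


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------


def preprocess(volume: np.ndarray, params: XVParams) -> np.ndarray:
    """Gaussian smooth + radial frequency-domain bandpass; zero-mean output.

    The DC term falls outside any positive passband, so a constant volume
    maps to zero. Output is zero-mean within the lung mask (or globally).
    """
    volume = np.asarray(volume, dtype=np.float64)
    if params.band_high > 0.5:
        raise ValueError(f"band_high {params.band_high} exceeds the Nyquist frequency 0.5")
    sm = ndimage.gaussian_filter(volume, params.smooth_sigma) if params.smooth_sigma > 0 else volume
    freqs = [np.fft.fftfreq(n) for n in sm.shape]
    fz, fy, fx = np.meshgrid(*freqs, indexing="ij", sparse=True)
    fr = np.sqrt(fz**2 + fy**2 + fx**2)
    mask = (fr >= params.band_low) & (fr <= params.band_high)
    out = np.fft.ifftn(np.fft.fftn(sm) * mask).real
    if params.lung_mask is not None:
        out = out - out[params.lung_mask].mean()
    else:
        out = out - out.mean()
    return out


# ---------------------------------------------------------------------------
# grid
# ---------------------------------------------------------------------------


def build_grid(shape: tuple[int, int, int], params: XVParams) -> GridSpec:
    """Tile the volume with interrogation windows, all fully inside.

    Nodes sit at window centers, stepping by window*(1-overlap); the
    whole tiling is centered so leftover margin splits evenly.
    """
    w, step = params.window, params.step
    counts = []
    origins = []
    for n in shape:
        if w > n:
            raise ValueError(f"window {w} larger than volume extent {n}")
        cnt = (n - w) // step + 1
        margin = (n - (w + (cnt - 1) * step)) / 2.0
        counts.append(cnt)
        origins.append(margin + w / 2.0)
    return GridSpec(
        origin=tuple(origins), spacing=step, shape=tuple(counts), window=w
    )


# ---------------------------------------------------------------------------
# correlation
# ---------------------------------------------------------------------------


def _subvoxel_offset(cm1: float, c0: float, cp1: float, mode: str) -> float:
    """3-point peak interpolation along one axis."""
    if mode == "gaussian" and min(cm1, c0, cp1) > 0:
        lm1, l0, lp1 = np.log(cm1), np.log(c0), np.log(cp1)
        denom = 2.0 * (lm1 + lp1 - 2.0 * l0)
        if denom < 0:
            return float((lm1 - lp1) / denom)
        return 0.0
    denom = 2.0 * (cm1 + cp1 - 2.0 * c0)
    if denom < 0:
        return float((cm1 - cp1) / denom)
    return 0.0


def correlate_pair(
    window_a: np.ndarray,
    window_b: np.ndarray,
    subpixel: str = "gaussian",
    normalization: str = "circular",
) -> tuple[np.ndarray, float, bool]:
    """Displacement of ``window_b`` relative to ``window_a``.

    Normalized circular cross-correlation via FFT; the integer peak is
    refined per axis by a 3-point Gaussian (or parabolic) fit. Quality is
    the ratio of the primary peak to the highest secondary peak outside
    its 3-voxel neighbourhood. Zero-variance windows yield an invalid
    result (flag False) rather than an exception.

    ``normalization="unbiased"`` divides each lag by the fraction of the
    window that can overlap at that lag — the right choice when the two
    windows sample a moving scene (content enters/leaves), as inside
    :func:`displacement_field`; the default plain circular normalization
    is exact for genuinely periodic content.
    """
    a = np.asarray(window_a, dtype=np.float64)
    b = np.asarray(window_b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("windows must have equal shapes")
    a = a - a.mean()
    b = b - b.mean()
    sa, sb = a.std(), b.std()
    if sa < 1e-12 or sb < 1e-12:
        return np.zeros(3), 0.0, False
    corr = np.fft.ifftn(np.conj(np.fft.fftn(a)) * np.fft.fftn(b)).real
    corr /= sa * sb * a.size
    corr = np.fft.fftshift(corr)
    center = np.array([s // 2 for s in corr.shape])
    if normalization == "unbiased":
        # at lag l only a (1 - |l|/W) fraction of the window content can
        # match, which biases the 3-point fit toward zero; divide it out
        # (floored to avoid amplifying far-lag noise)
        lag_w = 1.0
        for ax, n in enumerate(corr.shape):
            l = np.abs(np.arange(n) - n // 2) / n
            shape = [1, 1, 1]
            shape[ax] = n
            lag_w = lag_w * (1.0 - l).reshape(shape)
        corr = corr / np.maximum(lag_w, 0.3)
    elif normalization != "circular":
        raise ValueError("normalization must be 'circular' or 'unbiased'")

    peak_idx = np.array(np.unravel_index(np.argmax(corr), corr.shape))
    peak = corr[tuple(peak_idx)]

    # secondary peak outside a 3-voxel neighbourhood of the primary
    masked = corr.copy()
    lo = np.maximum(peak_idx - 3, 0)
    hi = np.minimum(peak_idx + 4, corr.shape)
    masked[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = -np.inf
    second = float(masked.max())
    quality = float(peak / second) if second > 1e-12 else float(np.inf)

    offset = np.zeros(3)
    for ax in range(3):
        im1 = peak_idx.copy()
        ip1 = peak_idx.copy()
        im1[ax] = (peak_idx[ax] - 1) % corr.shape[ax]
        ip1[ax] = (peak_idx[ax] + 1) % corr.shape[ax]
        offset[ax] = _subvoxel_offset(
            corr[tuple(im1)], peak, corr[tuple(ip1)], subpixel
        )
        offset[ax] = float(np.clip(offset[ax], -1.0, 1.0))
    disp = peak_idx - center + offset
    return disp, quality, True


def _extract(volume: np.ndarray, grid: GridSpec, iz: int, iy: int, ix: int) -> np.ndarray:
    w = grid.window
    z0 = grid.starts(0)[iz]
    y0 = grid.starts(1)[iy]
    x0 = grid.starts(2)[ix]
    return volume[z0:z0 + w, y0:y0 + w, x0:x0 + w]


def displacement_field(
    vol_a: np.ndarray, vol_b: np.ndarray, params: XVParams, grid: GridSpec | None = None
) -> DisplacementField:
    """Per-node cross-correlation displacement of vol_b relative to vol_a.

    Nodes outside ``params.lung_mask``, with zero-variance windows, or
    with peak quality below ``peak_quality_min`` are flagged invalid;
    interior invalid nodes are replaced by the median of their valid
    26-neighbours (and flagged as filled). Boundary nodes stay sparse.
    """
    vol_a = np.asarray(vol_a)
    vol_b = np.asarray(vol_b)
    if vol_a.shape != vol_b.shape:
        raise ValueError("volumes must have equal shapes")
    if grid is None:
        grid = build_grid(vol_a.shape, params)
    nz, ny, nx = grid.shape
    vectors = np.zeros((nz, ny, nx, 3))
    quality = np.zeros((nz, ny, nx))
    valid = np.zeros((nz, ny, nx), dtype=bool)

    if params.lung_mask is not None:
        centers = np.round(grid.node_coords()).astype(int)
        in_mask = params.lung_mask[
            centers[..., 0], centers[..., 1], centers[..., 2]
        ]
    else:
        in_mask = np.ones((nz, ny, nx), dtype=bool)

    for iz in range(nz):
        for iy in range(ny):
            for ix in range(nx):
                if not in_mask[iz, iy, ix]:
                    continue
                d, q, ok = correlate_pair(
                    _extract(vol_a, grid, iz, iy, ix),
                    _extract(vol_b, grid, iz, iy, ix),
                    subpixel=params.subpixel,
                    normalization="unbiased",
                )
                vectors[iz, iy, ix] = d
                quality[iz, iy, ix] = q
                valid[iz, iy, ix] = ok and q >= params.peak_quality_min

    fld = DisplacementField(grid=grid, vectors=vectors, quality=quality, valid=valid)
    if params.fill_invalid:
        _fill_interior(fld, in_mask)
    return fld


def _fill_interior(fld: DisplacementField, in_mask: np.ndarray) -> None:
    """Median-replace invalid interior nodes from valid 26-neighbours."""
    nz, ny, nx = fld.valid.shape
    bad = np.argwhere(~fld.valid & in_mask)
    for iz, iy, ix in bad:
        if iz in (0, nz - 1) or iy in (0, ny - 1) or ix in (0, nx - 1):
            continue  # boundary stays sparse
        nb = fld.vectors[iz - 1:iz + 2, iy - 1:iy + 2, ix - 1:ix + 2]
        ok = fld.valid[iz - 1:iz + 2, iy - 1:iy + 2, ix - 1:ix + 2]
        if ok.sum() >= 3:
            fld.vectors[iz, iy, ix] = np.median(nb[ok], axis=0)
            fld.filled[iz, iy, ix] = True


# ---------------------------------------------------------------------------
# expansion
# ---------------------------------------------------------------------------


def expansion(fld: DisplacementField) -> ExpansionField:
    """Divergence of the displacement field by central differences.

    Defined only where a node and all six stencil neighbours carry a
    usable vector (valid or filled); everything else is flagged.
    """
    nz, ny, nx = fld.valid.shape
    if min(nz, ny, nx) < 3:
        return ExpansionField(
            grid=fld.grid,
            values=np.zeros((nz, ny, nx)),
            valid=np.zeros((nz, ny, nx), dtype=bool),
        )
    usable = fld.valid | fld.filled
    h = float(fld.grid.spacing)
    values = np.zeros((nz, ny, nx))
    ok = np.zeros((nz, ny, nx), dtype=bool)
    ok[1:-1, 1:-1, 1:-1] = (
        usable[1:-1, 1:-1, 1:-1]
        & usable[2:, 1:-1, 1:-1] & usable[:-2, 1:-1, 1:-1]
        & usable[1:-1, 2:, 1:-1] & usable[1:-1, :-2, 1:-1]
        & usable[1:-1, 1:-1, 2:] & usable[1:-1, 1:-1, :-2]
    )
    div = (
        (fld.vectors[2:, 1:-1, 1:-1, 0] - fld.vectors[:-2, 1:-1, 1:-1, 0])
        + (fld.vectors[1:-1, 2:, 1:-1, 1] - fld.vectors[1:-1, :-2, 1:-1, 1])
        + (fld.vectors[1:-1, 1:-1, 2:, 2] - fld.vectors[1:-1, 1:-1, :-2, 2])
    ) / (2.0 * h)
    values[1:-1, 1:-1, 1:-1] = div
    values[~ok] = 0.0
    return ExpansionField(grid=fld.grid, values=values, valid=ok)


# ---------------------------------------------------------------------------
# breath tracking
# ---------------------------------------------------------------------------


@dataclass
class BreathTracking:
    """XV result over a breath: one field per successive phase interval."""

    fields: list[DisplacementField]
    expansions: list[ExpansionField]
    phase_times: np.ndarray

    @property
    def n_intervals(self) -> int:
        return len(self.fields)

    def cumulative_expansion(self, upto: int | None = None) -> ExpansionField:
        """Summed incremental expansion from phase 0 through interval ``upto``
        (exclusive end phase index; default all). Small-strain summation at
        fixed nodes; valid where every summand is valid."""
        k = self.n_intervals if upto is None else upto
        grid = self.fields[0].grid
        total = np.zeros(grid.shape)
        ok = np.ones(grid.shape, dtype=bool)
        for e in self.expansions[:k]:
            total += e.values
            ok &= e.valid
        return ExpansionField(grid=grid, values=total, valid=ok)

    def cumulative_displacement(self, upto: int | None = None) -> DisplacementField:
        """Summed incremental displacement from phase 0, each increment
        sampled (linear grid resampling) at the cumulatively advected node
        position."""
        k = self.n_intervals if upto is None else upto
        grid = self.fields[0].grid
        nzyx = grid.shape
        total = np.zeros(nzyx + (3,))
        ok = np.ones(nzyx, dtype=bool)
        base = grid.node_coords()  # (..., 3) voxel coords
        for f in self.fields[:k]:
            ok &= f.valid | f.filled
            # node-index coordinates of the advected positions
            pos = base + total
            idx = [
                (pos[..., a] - grid.origin[a]) / grid.spacing for a in range(3)
            ]
            for a in range(3):
                inc = ndimage.map_coordinates(
                    f.vectors[..., a], idx, order=1, mode="nearest"
                )
                total[..., a] += inc
        return DisplacementField(
            grid=grid, vectors=total,
            quality=np.where(ok, 1.0, 0.0), valid=ok,
        )


def track_breath(volume4d: Volume4D, params: XVParams) -> BreathTracking:
    """Run XV over all successive phase pairs (t -> t+1) of a breath."""
    if volume4d.n_phases < 2:
        raise ValueError("need at least two phases to track")
    pre = [preprocess(volume4d.phase(i), params) for i in range(volume4d.n_phases)]
    grid = build_grid(volume4d.grid_shape, params)
    fields = []
    expansions = []
    for i in range(volume4d.n_phases - 1):
        f = displacement_field(pre[i], pre[i + 1], params, grid=grid)
        fields.append(f)
        expansions.append(expansion(f))
    return BreathTracking(
        fields=fields, expansions=expansions, phase_times=volume4d.phase_times
    )
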