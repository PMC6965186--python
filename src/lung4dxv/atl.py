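"""Airway Tree Link (ATL): from regional expansion to per-branch airflow.

Each lung voxel is assigned to the terminal airway segment that supplies
it (nearest terminal endpoint). Integrating the measured expansion over
a terminal's region gives the air volume passing that terminal at each
breath phase; summing recursively up the tree — flow through a parent
equals the sum of its daughters' flows, airway compression neglected —
gives the air volume that has passed every location in the airway tree,
relative to end-expiration (functional residual capacity).

The expiratory time constant of a branch is the time after the start of
expiration at which its expired volume first reaches 1 - 1/e (~63%) of
its tidal volume — an operational, fit-free definition, with linear
interpolation between phase samples. Branches that never reach the
threshold within the measured breath are flagged invalid rather than
extrapolated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .core import AirwayTree
from .phantom import VentilationProtocol, terminal_region_labels
from .velocimetry import ExpansionField

__all__ = [
    "RegionAssignment",
    "BranchFlowSeries",
    "TimeConstantMap",
    "ATLError",
    "EXPIRED_FRACTION",
    "assign_regions",
    "regional_volumes",
    "flow_sum",
    "expiratory_time_constant",
    "aeration_map",
]

#: expired-volume fraction defining one expiratory time constant
#: (1 - 1/e ~ 0.632, i.e. a 63% decrease of the tidal volume)
EXPIRED_FRACTION = 1.0 - 1.0 / np.e


class ATLError(ValueError):
    pass


@dataclass
class RegionAssignment:
    """Terminal-segment supply regions: one terminal id per lung voxel."""

    labels: np.ndarray  # (z, y, x) int, terminal id inside mask, -1 outside
    terminal_ids: tuple[int, ...]

    @property
    def mask(self) -> np.ndarray:
        return self.labels >= 0

    def region_sizes(self) -> dict[int, int]:
        ids, counts = np.unique(self.labels[self.labels >= 0], return_counts=True)
        return dict(zip(ids.tolist(), counts.tolist()))


@dataclass
class BranchFlowSeries:
    """Per-segment air volume passed (relative to end-expiration) per phase.

    ``volumes[seg_id]`` is a series over ``phase_times`` starting at 0;
    ``airflow`` is its finite difference per interval (volume/ms).
    """

    phase_times: np.ndarray  # (n_phases,) ms
    volumes: dict[int, np.ndarray]

    def __post_init__(self) -> None:
        self.phase_times = np.asarray(self.phase_times, dtype=float)
        for sid, v in self.volumes.items():
            v = np.asarray(v, dtype=float)
            if v.shape != self.phase_times.shape:
                raise ATLError(f"segment {sid}: series length mismatch")
            self.volumes[sid] = v

    def airflow(self, seg_id: int) -> np.ndarray:
        """Mean airflow per phase interval (volume / ms)."""
        return np.diff(self.volumes[seg_id]) / np.diff(self.phase_times)

    def tidal_volume(self, seg_id: int) -> float:
        """Peak of the cumulative volume series (air inhaled per breath)."""
        return float(np.max(self.volumes[seg_id]))


@dataclass
class TimeConstantMap:
    """Per-segment expiratory time constant (ms) with validity flags."""

    tau_ms: dict[int, float]
    valid: dict[int, bool]

    def to_frame(self) -> pd.DataFrame:
        ids = sorted(self.tau_ms)
        return pd.DataFrame(
            {"segment_id": ids,
             "tau_ms": [self.tau_ms[i] for i in ids],
             "valid": [self.valid[i] for i in ids]}
        )


# ---------------------------------------------------------------------------


def assign_regions(lung_mask: np.ndarray, tree: AirwayTree) -> RegionAssignment:
    """Partition the lung mask by nearest terminal-segment endpoint.

    Every masked voxel is assigned to exactly one terminal (Euclidean
    distance, ties to the lowest segment id).
    """
    lung_mask = np.asarray(lung_mask, dtype=bool)
    if not lung_mask.any():
        raise ATLError("empty lung mask")
    labels = terminal_region_labels(tree, lung_mask)
    return RegionAssignment(labels=labels, terminal_ids=tuple(tree.terminal_ids()))


def _upsample_expansion(exp: ExpansionField, shape: tuple[int, int, int]) -> np.ndarray:
    """Linear upsampling of node-grid expansion to the voxel grid.

    Invalid nodes are replaced by their nearest usable node before
    interpolation so boundary voxels get sensible values.
    """
    vals = exp.values.copy()
    if not exp.valid.all():
        if not exp.valid.any():
            raise ATLError("expansion field has no valid nodes")
        idx = ndimage.distance_transform_edt(
            ~exp.valid, return_distances=False, return_indices=True
        )
        vals = vals[tuple(idx)]
    g = exp.grid
    zi = (np.arange(shape[0]) - g.origin[0]) / g.spacing
    yi = (np.arange(shape[1]) - g.origin[1]) / g.spacing
    xi = (np.arange(shape[2]) - g.origin[2]) / g.spacing
    zz, yy, xx = np.meshgrid(zi, yi, xi, indexing="ij", sparse=False)
    return ndimage.map_coordinates(vals, [zz, yy, xx], order=1, mode="nearest")


def regional_volumes(
    expansion_series: list[ExpansionField],
    assignment: RegionAssignment,
    voxel_size: float = 1.0,
) -> dict[int, np.ndarray]:
    """Cumulative air volume per terminal region from incremental expansion.

    For each phase interval the node-grid expansion is upsampled to the
    voxel grid, summed over each terminal's assigned voxels and scaled by
    the voxel volume; the cumulative sum over intervals (prepended with 0
    at end-expiration) is each terminal's volume series.
    """
    if not expansion_series:
        raise ATLError("empty expansion series")
    mask = assignment.mask
    shape = assignment.labels.shape
    for e in expansion_series:
        gshape = e.values.shape
        if gshape != expansion_series[0].values.shape:
            raise ATLError("expansion fields have mismatched grids")
    flat_labels = assignment.labels[mask]
    max_id = max(assignment.terminal_ids)
    voxel_vol = voxel_size**3
    n_phases = len(expansion_series) + 1
    out = {tid: np.zeros(n_phases) for tid in assignment.terminal_ids}
    for i, e in enumerate(expansion_series):
        up = _upsample_expansion(e, shape)
        sums = np.bincount(flat_labels, weights=up[mask], minlength=max_id + 1)
        for tid in assignment.terminal_ids:
            out[tid][i + 1] = out[tid][i] + sums[tid] * voxel_vol
    return out


def flow_sum(tree: AirwayTree, terminal_series: dict[int, np.ndarray],
             phase_times: np.ndarray) -> BranchFlowSeries:
    """Recursive flow summation up the tree.

    Leaf series are the terminal series; every internal segment's series
    is the sum of its children's — flow through a parent equals the sum
    of the flows from its supplying daughters.
    """
    terminals = tree.terminal_ids()
    missing = [t for t in terminals if t not in terminal_series]
    if missing:
        raise ATLError(f"no volume series for terminal segments {missing}")
    phase_times = np.asarray(phase_times, dtype=float)
    volumes: dict[int, np.ndarray] = {}
    for sid in tree.postorder():
        kids = tree.children(sid)
        if not kids:
            volumes[sid] = np.asarray(terminal_series[sid], dtype=float)
        else:
            volumes[sid] = np.sum([volumes[k] for k in kids], axis=0)
    return BranchFlowSeries(phase_times=phase_times, volumes=volumes)


def expiratory_time_constant(
    series: BranchFlowSeries,
    protocol: VentilationProtocol,
    threshold: float = EXPIRED_FRACTION,
    method: str = "threshold",
) -> TimeConstantMap:
    """Expiratory time constant per branch.

    ``method="threshold"`` (default): tau is the time after the start of
    expiration (``protocol.t_insp``, ventilator-triggered acquisition
    makes protocol time authoritative) at which the branch's expired
    volume first reaches ``threshold`` (1 - 1/e) of its tidal volume,
    linearly interpolated between phase samples. ``method="expfit"``
    instead fits log(V) over the expiratory samples.

    Branches with non-positive tidal volume or which never reach the
    threshold are flagged invalid (no exception).
    """
    t0 = protocol.t_insp
    taus: dict[int, float] = {}
    valid: dict[int, bool] = {}
    times = series.phase_times
    for sid, vol in series.volumes.items():
        tidal = series.tidal_volume(sid)
        if tidal <= 0:
            taus[sid], valid[sid] = np.nan, False
            continue
        exp_sel = times >= t0
        if exp_sel.sum() < 2:
            taus[sid], valid[sid] = np.nan, False
            continue
        t_exp = times[exp_sel]
        v_exp = vol[exp_sel]
        if method == "expfit":
            pos = v_exp > 0
            if pos.sum() < 2:
                taus[sid], valid[sid] = np.nan, False
                continue
            slope = np.polyfit(t_exp[pos], np.log(v_exp[pos]), 1)[0]
            if slope >= 0:
                taus[sid], valid[sid] = np.nan, False
                continue
            taus[sid], valid[sid] = -1.0 / slope, True
            continue
        if method != "threshold":
            raise ValueError("method must be 'threshold' or 'expfit'")
        expired = (tidal - v_exp) / tidal
        above = np.flatnonzero(expired >= threshold)
        if above.size == 0:
            taus[sid], valid[sid] = np.nan, False
            continue
        k = above[0]
        if k == 0:
            t_cross = t_exp[0]
        else:
            f0, f1 = expired[k - 1], expired[k]
            frac = (threshold - f0) / (f1 - f0) if f1 > f0 else 0.0
            t_cross = t_exp[k - 1] + frac * (t_exp[k] - t_exp[k - 1])
        taus[sid] = float(t_cross - t0)
        valid[sid] = taus[sid] > 0
    return TimeConstantMap(tau_ms=taus, valid=valid)


def aeration_map(
    flow: BranchFlowSeries, tree: AirwayTree
) -> dict[int, dict[int, float]]:
    """Cumulative air volume passed each airway location, per phase.

    Returns ``{phase_index: {segment_id: volume}}`` — every centerline
    location of a segment carries its segment's cumulative volume; at
    t = 0 (functional residual capacity) everything is 0. Suitable for
    colouring tree renderings phase by phase.
    """
    out: dict[int, dict[int, float]] = {}
    for i in range(len(flow.phase_times)):
        out[i] = {sid: float(flow.volumes[sid][i]) for sid in tree.segments}
    return out
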