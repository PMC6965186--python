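"""Shared in-memory containers for the 4DxV pipeline.

Coordinate convention (used throughout the package): volumes are numpy
arrays indexed ``(z, y, x)`` with 0-based voxel indices; positions are
float voxel coordinates in the same axis order; world units are
``voxels * voxel_size``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

__all__ = ["AirwaySegment", "AirwayTree", "Volume4D", "TreeError"]


class TreeError(ValueError):
    """Raised when an airway tree violates its structural invariants."""


@dataclass
class AirwaySegment:
    """One airway branch: a centerline polyline with per-point radii.

    ``generation`` counts bifurcations from the root (trachea = 0).
    """

    id: int
    parent_id: int | None
    generation: int
    points: np.ndarray  # (n, 3) float voxel coords (z, y, x)
    radii: np.ndarray  # (n,) voxels

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        self.radii = np.broadcast_to(
            np.asarray(self.radii, dtype=float), (self.points.shape[0],)
        ).copy()

    @property
    def start(self) -> np.ndarray:
        return self.points[0]

    @property
    def end(self) -> np.ndarray:
        return self.points[-1]

    @property
    def length(self) -> float:
        if len(self.points) < 2:
            return 0.0
        return float(np.linalg.norm(np.diff(self.points, axis=0), axis=1).sum())

    @property
    def mean_radius(self) -> float:
        return float(np.mean(self.radii))


@dataclass
class AirwayTree:
    """Rooted tree of airway segments.

    Exactly one root (the trachea, generation 0); every other segment has
    one parent; the segment graph is connected and acyclic.
    """

    segments: dict[int, AirwaySegment]
    root_id: int

    def __post_init__(self) -> None:
        self.validate()

    # -- structure ---------------------------------------------------------
    def validate(self) -> None:
        if self.root_id not in self.segments:
            raise TreeError(f"root id {self.root_id} not among segments")
        roots = [s.id for s in self.segments.values() if s.parent_id is None]
        if roots != [self.root_id]:
            raise TreeError(f"expected exactly one root {self.root_id}, found {roots}")
        g = self.to_networkx()
        if g.number_of_nodes() != len(self.segments):
            raise TreeError("duplicate or missing segment ids")
        if not nx.is_tree(g.to_undirected()):
            raise TreeError("segment graph is not a connected acyclic tree")
        for seg in self.segments.values():
            if seg.parent_id is not None:
                parent = self.segments.get(seg.parent_id)
                if parent is None:
                    raise TreeError(f"segment {seg.id} references missing parent {seg.parent_id}")
                if seg.generation != parent.generation + 1:
                    raise TreeError(
                        f"segment {seg.id}: generation {seg.generation} != parent's + 1"
                    )
        if self.segments[self.root_id].generation != 0:
            raise TreeError("root generation must be 0")

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        for seg in self.segments.values():
            g.add_node(seg.id)
        for seg in self.segments.values():
            if seg.parent_id is not None:
                g.add_edge(seg.parent_id, seg.id)
        return g

    # -- queries -----------------------------------------------------------
    def children(self, seg_id: int) -> list[int]:
        return sorted(s.id for s in self.segments.values() if s.parent_id == seg_id)

    def terminal_ids(self) -> list[int]:
        has_child = {s.parent_id for s in self.segments.values() if s.parent_id is not None}
        return sorted(i for i in self.segments if i not in has_child)

    def terminal_endpoints(self) -> dict[int, np.ndarray]:
        return {i: self.segments[i].end for i in self.terminal_ids()}

    @property
    def n_segments(self) -> int:
        return len(self.segments)

    @property
    def n_bifurcations(self) -> int:
        return sum(1 for i in self.segments if len(self.children(i)) >= 2)

    @property
    def max_generation(self) -> int:
        return max(s.generation for s in self.segments.values())

    def is_binary(self) -> bool:
        return all(len(self.children(i)) in (0, 2) for i in self.segments)

    def postorder(self) -> list[int]:
        order: list[int] = []

        def visit(i: int) -> None:
            for c in self.children(i):
                visit(c)
            order.append(i)

        visit(self.root_id)
        return order


@dataclass
class Volume4D:
    """Respiratory-gated CT series: one 3D volume per breath time bin.

    ``phase_times`` are milliseconds within the breath; the first phase is
    end-expiration (t = 0), the zero reference for all volume series.
    """

    data: np.ndarray  # (n_phases, z, y, x)
    voxel_size: float = 1.0
    phase_times: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError(f"expected 4D (phase, z, y, x) array, got shape {self.data.shape}")
        if self.phase_times is None:
            self.phase_times = np.arange(self.data.shape[0], dtype=float)
        self.phase_times = np.asarray(self.phase_times, dtype=float)
        if len(self.phase_times) != self.data.shape[0]:
            raise ValueError("phase_times length must match number of phases")
        if self.phase_times[0] != 0.0:
            raise ValueError("first phase must be end-expiration (t = 0)")
        if np.any(np.diff(self.phase_times) <= 0):
            raise ValueError("phase_times must be strictly increasing")

    @property
    def n_phases(self) -> int:
        return int(self.data.shape[0])

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return tuple(self.data.shape[1:])  # type: ignore[return-value]

    def phase(self, i: int) -> np.ndarray:
        return self.data[i]

    def __iter__(self):
        return iter(self.data)
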