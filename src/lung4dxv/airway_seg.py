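"""Airway segmentation: multiscale tubularity, flood fill, skeleton-to-tree.

Airways are air-filled, hence *dark* tubes on brighter parenchyma; the
Hessian-eigenvalue vesselness filter is therefore run in dark-ridge mode
by default. Segmentation operates on the end-expiration phase (the first
of the gated volumes), where distal gas spaces hold the least air and
lumen contrast is maximal.

The flood-fill + skeletonization chain turns the binary lumen mask into
an :class:`~lung4dxv.core.AirwayTree`: 3D thinning, a 26-connected
centerline graph, rooting at the trachea seed, spur pruning, and
generation numbering by bifurcation count from the root.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy import ndimage
from skimage.filters import frangi, threshold_otsu
from skimage.morphology import skeletonize

from .core import AirwaySegment, AirwayTree, TreeError, Volume4D

__all__ = [
    "VesselnessParams",
    "TubularityVolume",
    "SegmentationError",
    "multiscale_tubularity",
    "flood_fill_segment",
    "skeletonize_to_tree",
    "segment_airways",
]


class SegmentationError(ValueError):
    pass


def _default_scales(low: float = 1.0, high: float = 30.0, n: int = 10) -> tuple[float, ...]:
    return tuple(np.geomspace(low, high, n))


@dataclass(frozen=True)
class VesselnessParams:
    """Multiscale vesselness configuration.

    ``scales`` are Gaussian kernel scales in voxels, geometrically spaced
    over 1-30 by default; ``alpha`` penalises plate-like structures,
    ``beta`` blob-like ones, and ``gamma`` sets the contrast scale of the
    background suppression (``None`` = half of the maximum Hessian norm
    per scale, the original convention). ``bright_on_dark=False`` selects
    dark tubes in bright surroundings (air-filled airways).
    """

    scales: tuple[float, ...] = _default_scales()
    alpha: float = 0.5
    beta: float = 0.5
    gamma: float | None = None
    bright_on_dark: bool = False

    def __post_init__(self) -> None:
        s = np.asarray(self.scales, dtype=float)
        if s.size == 0 or np.any(s <= 0) or np.any(np.diff(s) <= 0):
            raise ValueError("scales must be non-empty, positive and increasing")
        object.__setattr__(self, "scales", tuple(float(v) for v in s))


@dataclass
class TubularityVolume:
    """Per-voxel tubular-structure probability in [0, 1] plus winning scale."""

    response: np.ndarray
    scale: np.ndarray  # Gaussian scale (voxels) that won at each voxel

    def __post_init__(self) -> None:
        if self.response.min() < 0 or self.response.max() > 1.0 + 1e-6:
            raise ValueError("tubularity response must lie in [0, 1]")


def multiscale_tubularity(volume: np.ndarray, params: VesselnessParams) -> TubularityVolume:
    """Maximum Frangi vesselness over scales, with the winning scale.

    The response at each voxel is the max over ``params.scales`` of the
    vesselness built from scale-normalized Hessian eigenvalues
    (|l1| <= |l2| <= |l3|); invariant to adding a constant to the volume
    and monotone in contrast through the gamma weight.
    """
    volume = np.asarray(volume, dtype=np.float64)
    if volume.ndim != 3:
        raise SegmentationError("expected a 3D volume")
    if min(volume.shape) <= 2 * max(params.scales):
        raise SegmentationError(
            f"volume shape {volume.shape} smaller than the largest kernel support "
            f"(scale {max(params.scales)})"
        )
    best = np.zeros_like(volume)
    best_scale = np.full(volume.shape, params.scales[0])
    for s in params.scales:
        r = frangi(
            volume,
            sigmas=[s],
            alpha=params.alpha,
            beta=params.beta,
            gamma=params.gamma,
            black_ridges=not params.bright_on_dark,
        )
        win = r > best
        best = np.where(win, r, best)
        best_scale = np.where(win, s, best_scale)
    return TubularityVolume(response=np.clip(best, 0.0, 1.0), scale=best_scale)


def flood_fill_segment(
    tubularity: TubularityVolume | np.ndarray,
    seed: tuple[int, int, int],
    threshold: float | None = None,
) -> np.ndarray:
    """26-connected component of {response >= threshold} containing the seed.

    ``threshold=None`` picks Otsu's threshold on the response histogram.
    """
    resp = tubularity.response if isinstance(tubularity, TubularityVolume) else tubularity
    if threshold is None:
        threshold = float(threshold_otsu(resp))
    seed = tuple(int(s) for s in seed)
    if resp[seed] < threshold:
        raise SegmentationError(
            f"seed {seed} has response {resp[seed]:.4g} below threshold {threshold:.4g}"
        )
    fg = resp >= threshold
    labels, _ = ndimage.label(fg, structure=np.ones((3, 3, 3), dtype=int))
    return labels == labels[seed]


# ---------------------------------------------------------------------------
# Skeleton -> tree
# ---------------------------------------------------------------------------

_NEIGHBORS = np.array(
    [(dz, dy, dx)
     for dz in (-1, 0, 1) for dy in (-1, 0, 1) for dx in (-1, 0, 1)
     if (dz, dy, dx) != (0, 0, 0)]
)


def _skeleton_graph(skel: np.ndarray) -> tuple[nx.Graph, np.ndarray]:
    coords = np.argwhere(skel)
    index = {tuple(c): i for i, c in enumerate(coords)}
    g = nx.Graph()
    g.add_nodes_from(range(len(coords)))
    shape = skel.shape
    for i, c in enumerate(coords):
        for d in _NEIGHBORS:
            nb = tuple(c + d)
            if all(0 <= nb[k] < shape[k] for k in range(3)):
                j = index.get(nb)
                if j is not None and j > i:
                    g.add_edge(i, j)
    return g, coords


def skeletonize_to_tree(
    mask: np.ndarray,
    root_voxel: tuple[int, int, int],
    prune_factor: float = 2.0,
) -> AirwayTree:
    """Thin a binary airway mask to a rooted centerline tree.

    Radius at each centerline point is the Euclidean distance-transform
    value; terminal spurs shorter than ``prune_factor`` x the local
    radius at their branch point are removed (skeletonization artefacts),
    and pass-through chains re-merged. Generations count bifurcations
    from the root.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise SegmentationError("empty mask")
    labels, n = ndimage.label(mask, structure=np.ones((3, 3, 3), dtype=int))
    root_voxel = tuple(int(v) for v in root_voxel)
    if labels[root_voxel] == 0:
        raise SegmentationError(f"root voxel {root_voxel} not inside the mask")
    if n > 1:
        raise SegmentationError(f"mask has {n} connected components; expected 1")

    skel = skeletonize(mask)
    if not skel.any():
        raise SegmentationError("skeletonization produced an empty centerline")
    dist = ndimage.distance_transform_edt(mask)
    g, coords = _skeleton_graph(skel)

    # largest component containing (voxel nearest to) the root
    root_node = int(np.argmin(np.sum((coords - np.array(root_voxel)) ** 2, axis=1)))
    comp = nx.node_connected_component(g, root_node)
    g = g.subgraph(comp).copy()

    # BFS tree from the root resolves any junction-cluster cycles
    bfs = nx.bfs_tree(g, root_node)

    def build_segments(tree_graph: nx.DiGraph) -> dict[int, dict]:
        """Compress BFS chains into segments (lists of skeleton nodes)."""
        segs: dict[int, dict] = {}
        counter = [0]

        def walk(node: int, parent_seg: int | None, generation: int) -> None:
            seg_id = counter[0]
            counter[0] += 1
            pts = [node]
            cur = node
            while True:
                kids = list(tree_graph.successors(cur))
                if len(kids) == 1:
                    cur = kids[0]
                    pts.append(cur)
                else:
                    break
            segs[seg_id] = {"parent": parent_seg, "gen": generation, "nodes": pts}
            for k in sorted(tree_graph.successors(cur)):
                walk(k, seg_id, generation + 1)

        walk(node=root_node, parent_seg=None, generation=0)
        return segs

    segs = build_segments(bfs)

    # iteratively prune short terminal spurs, then re-merge chains
    def seg_length(s: dict) -> float:
        pts = coords[s["nodes"]].astype(float)
        return float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum()) if len(pts) > 1 else 0.0

    changed = True
    while changed:
        changed = False
        children: dict[int | None, list[int]] = {}
        for sid, s in segs.items():
            children.setdefault(s["parent"], []).append(sid)
        for sid, s in list(segs.items()):
            if s["parent"] is None or children.get(sid):
                continue  # root or internal
            branch_pt = s["nodes"][0]
            local_r = float(dist[tuple(coords[branch_pt])])
            if seg_length(s) < prune_factor * local_r:
                siblings = children[s["parent"]]
                if len(siblings) > 1:  # never prune the only continuation
                    del segs[sid]
                    changed = True
        if not changed:
            break
        # re-merge parents left with a single child
        merged = True
        while merged:
            merged = False
            children = {}
            for sid, s in segs.items():
                children.setdefault(s["parent"], []).append(sid)
            for sid, kids in list(children.items()):
                if sid is not None and sid in segs and len(kids) == 1:
                    k = kids[0]
                    segs[sid]["nodes"] = segs[sid]["nodes"] + segs[k]["nodes"]
                    for s2 in segs.values():
                        if s2["parent"] == k:
                            s2["parent"] = sid
                    del segs[k]
                    merged = True
                    break

    # renumber generations after pruning/merging and emit AirwaySegments
    out: dict[int, AirwaySegment] = {}
    id_map = {sid: i for i, sid in enumerate(sorted(segs))}
    gens: dict[int, int] = {}

    def generation_of(sid: int) -> int:
        if sid in gens:
            return gens[sid]
        p = segs[sid]["parent"]
        gens[sid] = 0 if p is None else generation_of(p) + 1
        return gens[sid]

    for sid, s in segs.items():
        pts = coords[s["nodes"]].astype(float)
        radii = np.array([dist[tuple(coords[n_])] for n_ in s["nodes"]], dtype=float)
        out[id_map[sid]] = AirwaySegment(
            id=id_map[sid],
            parent_id=None if s["parent"] is None else id_map[s["parent"]],
            generation=generation_of(sid),
            points=pts,
            radii=radii,
        )
    try:
        return AirwayTree(segments=out, root_id=id_map[min(segs)])
    except TreeError as exc:  # pragma: no cover - defensive
        raise SegmentationError(f"skeleton did not form a valid tree: {exc}") from exc


def segment_airways(
    volume4d: Volume4D,
    params: VesselnessParams,
    seed: tuple[int, int, int],
    threshold: float | None = None,
    prune_factor: float = 2.0,
) -> AirwayTree:
    """Full chain on the end-expiration phase (phase 0 only).

    Tubularity -> flood fill from the trachea seed -> skeleton tree.
    Phase 0 is used because distal air volume is minimal there, giving
    maximal lumen contrast.
    """
    if volume4d.n_phases < 1:
        raise SegmentationError("need at least one phase")
    tub = multiscale_tubularity(volume4d.phase(0), params)
    mask = flood_fill_segment(tub, seed, threshold)
    return skeletonize_to_tree(mask, seed, prune_factor=prune_factor)
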