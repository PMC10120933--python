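"""Skeletonization and skeleton-graph morphometry (pipeline stage 2B).

The binary vessel map is thinned to a 1-pixel-wide, 8-connected skeleton;
skeleton pixels are then tagged by their 8-neighbor count (1 -> endpoint,
2 -> slab, >=3 -> junction pixel), adjacent junction pixels are clustered
into single junction nodes, and the slab runs between nodes become branches
with chain-code geodesic lengths (1 px per axial step, sqrt(2) px per
diagonal step) and straight-line Euclidean lengths, both in mm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.ndimage as ndi
from skimage.measure import label as cc_label
from skimage.morphology import skeletonize as _thin

from .raster_io import ValidationError
from .vessel_filters import BinaryVesselMap

_NEIGHBOR_KERNEL = np.array([[1, 1, 1], [1, 0, 1], [1, 1, 1]])
_OFFSETS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


@dataclass(frozen=True)
class SkeletonNode:
    """A junction (>=3 skeleton neighbors) or endpoint (1 neighbor) node.

    ``pixels`` holds the member pixels of a clustered junction (a single
    pixel for endpoints); ``coord`` is the representative pixel closest to
    the cluster centroid.  An isolated skeleton pixel is reported as a
    degenerate endpoint node of degree 0.
    """

    id: int
    kind: str  # "junction" | "endpoint"
    coord: tuple[int, int]
    pixels: tuple[tuple[int, int], ...]


@dataclass(frozen=True)
class SkeletonBranch:
    """A slab run between two nodes (or a closed loop with no node).

    ``path`` is the ordered pixel chain including the touching node pixels;
    geodesic_length sums chain-code step lengths over the path, in mm.
    For a pure cycle ``nodes`` is (None, None) and euclidean_length is 0.
    """

    id: int
    nodes: tuple[int | None, int | None]
    path: tuple[tuple[int, int], ...]
    geodesic_length: float
    euclidean_length: float

    @property
    def is_loop(self) -> bool:
        return self.path[0] == self.path[-1] and len(self.path) > 1


@dataclass(frozen=True)
class SkeletonGraph:
    """Tagged skeleton: nodes, branches, the skeleton mask and its scale."""

    nodes: tuple[SkeletonNode, ...]
    branches: tuple[SkeletonBranch, ...]
    skeleton: np.ndarray
    scale: float

    @property
    def junctions(self) -> tuple[SkeletonNode, ...]:
        return tuple(n for n in self.nodes if n.kind == "junction")

    @property
    def endpoints(self) -> tuple[SkeletonNode, ...]:
        return tuple(n for n in self.nodes if n.kind == "endpoint")

    def node_by_id(self, node_id: int) -> SkeletonNode:
        return self.nodes[node_id]


@dataclass(frozen=True)
class PruneConfig:
    """Artifact-pruning parameters.

    ``min_component_pixels`` removes small disconnected skeleton flecks;
    ``prune_end_branches_shorter_than`` (mm) iteratively removes terminal
    branches shorter than the threshold (0 disables end-branch pruning).
    """

    min_component_pixels: int = 5
    prune_end_branches_shorter_than: float = 0.0

    def __post_init__(self) -> None:
        if self.min_component_pixels < 0 or self.prune_end_branches_shorter_than < 0:
            raise ValidationError("prune parameters must be non-negative")


def skeletonize(vessels: BinaryVesselMap) -> BinaryVesselMap:
    """Thin a binary vessel map to a 1-pixel-wide 8-connected skeleton.

    The skeleton is a subset of the foreground, preserves the 8-connected
    component count, and the operation is idempotent.
    """
    return BinaryVesselMap(mask=_thin(vessels.mask), scale=vessels.scale)


def _neighbor_counts(sk: np.ndarray) -> np.ndarray:
    return ndi.convolve(sk.astype(np.int8), _NEIGHBOR_KERNEL, mode="constant", cval=0)


def _check_thin(sk: np.ndarray) -> None:
    # a thin skeleton is a fixed point of the thinning algorithm; thick
    # inputs (e.g. a 3-pixel-wide bar) lose pixels under another pass
    if sk.any() and not np.array_equal(_thin(sk), sk):
        raise ValidationError("input is not a thin skeleton (thinning would remove pixels)")


def _chain_length(path: list[tuple[int, int]]) -> float:
    """Chain-code length in pixels: 1 per axial step, sqrt(2) per diagonal."""
    p = np.asarray(path, dtype=np.float64)
    if len(p) < 2:
        return 0.0
    steps = np.abs(np.diff(p, axis=0))
    return float(np.where(steps.sum(axis=1) == 2, np.sqrt(2.0), 1.0).sum())


def tag_skeleton(skeleton: BinaryVesselMap) -> SkeletonGraph:
    """Build the node/branch graph of a thin skeleton.

    Raises :class:`ValidationError` if the input is not 1 pixel wide.
    """
    sk = skeleton.mask
    _check_thin(sk)
    h, w = sk.shape
    deg = _neighbor_counts(sk)
    deg[~sk] = -1

    nodes: list[SkeletonNode] = []
    node_id_of: dict[tuple[int, int], int] = {}

    # clustered junction nodes (8-connected clumps of junction pixels)
    junction_mask = sk & (deg >= 3)
    labels, n_clusters = cc_label(junction_mask, connectivity=2, return_num=True)
    for lab in range(1, n_clusters + 1):
        pix = [tuple(p) for p in np.argwhere(labels == lab)]
        centroid = np.mean(pix, axis=0)
        rep = min(pix, key=lambda p: (p[0] - centroid[0]) ** 2 + (p[1] - centroid[1]) ** 2)
        node = SkeletonNode(id=len(nodes), kind="junction", coord=rep, pixels=tuple(pix))
        nodes.append(node)
        for p in pix:
            node_id_of[p] = node.id

    # endpoint nodes (degree 1) and isolated pixels (degree 0, degenerate)
    for p in map(tuple, np.argwhere(sk & ((deg == 1) | (deg == 0)))):
        node = SkeletonNode(id=len(nodes), kind="endpoint", coord=p, pixels=(p,))
        nodes.append(node)
        node_id_of[p] = node.id

    def neighbors(p: tuple[int, int]) -> list[tuple[int, int]]:
        r, c = p
        return [
            (r + dr, c + dc)
            for dr, dc in _OFFSETS
            if 0 <= r + dr < h and 0 <= c + dc < w and sk[r + dr, c + dc]
        ]

    branches: list[SkeletonBranch] = []
    visited_slab: set[tuple[int, int]] = set()
    direct_links: set[frozenset[tuple[int, int]]] = set()
    scale = skeleton.scale

    def add_branch(path: list[tuple[int, int]], a: int | None, b: int | None) -> None:
        geo = _chain_length(path) / scale
        eu = float(np.hypot(path[0][0] - path[-1][0], path[0][1] - path[-1][1])) / scale
        branches.append(
            SkeletonBranch(
                id=len(branches),
                nodes=(a, b),
                path=tuple(path),
                geodesic_length=geo,
                euclidean_length=eu,
            )
        )

    # trace slab runs outward from every node pixel
    for node in nodes:
        for p in node.pixels:
            for q in neighbors(p):
                if q in node_id_of:
                    other = node_id_of[q]
                    if other == node.id:
                        continue  # intra-cluster adjacency
                    link = frozenset((p, q))
                    if link not in direct_links:
                        direct_links.add(link)
                        add_branch([p, q], node.id, other)
                    continue
                if q in visited_slab:
                    continue
                path = [p, q]
                visited_slab.add(q)
                prev, cur = p, q
                while True:
                    nxt = [n for n in neighbors(cur) if n != prev]
                    # slab pixels have exactly 2 neighbors; pick the forward one
                    forward = None
                    for n in nxt:
                        if n in node_id_of or n not in visited_slab:
                            forward = n
                            break
                    if forward is None:
                        break  # dead end (should not happen on valid skeletons)
                    path.append(forward)
                    if forward in node_id_of:
                        add_branch(path, node.id, node_id_of[forward])
                        break
                    visited_slab.add(forward)
                    prev, cur = cur, forward

    # pure cycles: slab pixels never reached from any node
    remaining = {tuple(p) for p in np.argwhere(sk & (deg == 2))} - visited_slab
    while remaining:
        start = min(remaining)  # deterministic pick
        path = [start]
        visited_slab.add(start)
        remaining.discard(start)
        prev, cur = None, start
        while True:
            step = [n for n in neighbors(cur) if n != prev and n in remaining]
            if not step:
                break
            nxt = step[0]
            path.append(nxt)
            visited_slab.add(nxt)
            remaining.discard(nxt)
            prev, cur = cur, nxt
        path.append(start)  # close the loop
        add_branch(path, None, None)

    return SkeletonGraph(
        nodes=tuple(nodes), branches=tuple(branches), skeleton=sk.copy(), scale=scale
    )


def _filter_small_components(sk: np.ndarray, min_pixels: int) -> np.ndarray:
    if min_pixels <= 1 or not sk.any():
        return sk
    labels, n = cc_label(sk, connectivity=2, return_num=True)
    if n == 0:
        return sk
    sizes = np.bincount(labels.ravel())
    keep = sizes >= min_pixels
    keep[0] = False
    return keep[labels]


def prune(graph: SkeletonGraph, config: PruneConfig = PruneConfig()) -> SkeletonGraph:
    """Remove skeleton artifacts and re-tag, to a deterministic fixed point.

    Small disconnected components (< ``min_component_pixels`` skeleton
    pixels) are always removed.  If a positive end-branch threshold is set,
    terminal branches (touching an endpoint node) shorter than it are
    deleted (their slab and endpoint pixels; junction-cluster pixels stay),
    and tagging repeats until nothing changes.
    """
    sk = _filter_small_components(graph.skeleton.copy(), config.min_component_pixels)
    out = tag_skeleton(BinaryVesselMap(mask=sk, scale=graph.scale))
    if config.prune_end_branches_shorter_than <= 0:
        return out
    while True:
        junction_pixels = {p for n in out.junctions for p in n.pixels}
        removed = False
        sk = out.skeleton.copy()
        for br in out.branches:
            kinds = [
                out.node_by_id(nid).kind if nid is not None else None for nid in br.nodes
            ]
            if "endpoint" not in kinds:
                continue
            if br.geodesic_length < config.prune_end_branches_shorter_than:
                for p in br.path:
                    if p not in junction_pixels:
                        sk[p] = False
                removed = True
        if not removed:
            return out
        # kept junction pixels can become redundant once their branch is
        # gone; re-thinning (idempotent on thin parts) restores thinness
        sk = _thin(_filter_small_components(sk, config.min_component_pixels))
        out = tag_skeleton(BinaryVesselMap(mask=sk, scale=out.scale))
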