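"""Vessel graphs from binary class masks.

The image-domain stage of the pipeline: a per-class binary raster is thinned
to a 1-px skeleton, branch points (pixels with != 2 skeleton neighbours) are
clustered into graph nodes, maximal node-to-node pixel paths become ordered
centerline segments, and per-point vessel diameters are read off the
Euclidean distance transform of the original mask.

Conventions (used everywhere in this package): pixel grid is 0-based
(row, col), origin top-left, y increases downward; skeleton connectivity is
8-connectivity; angles are degrees in image coordinates.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree
from skimage.morphology import skeletonize as _sk_skeletonize

__all__ = [
    "RasterMask",
    "OpticDisc",
    "VesselSegment",
    "VesselGraph",
    "skeletonize",
    "build_graph",
    "prune_spurs",
    "consolidate_junctions",
    "smooth_segments",
    "measure_diameters",
]


@dataclass
class RasterMask:
    """Binary vessel raster for one class (artery or vein) of one image."""

    data: np.ndarray
    image_id: str = ""
    vessel_class: str = "artery"
    px_per_disc_diameter: Optional[float] = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 2:
            raise ValueError("RasterMask.data must be a 2D array")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def pixel_count(self) -> int:
        return int(self.data.sum())


@dataclass(frozen=True)
class OpticDisc:
    """Optic disc location: center (row, col) and radius, in pixels."""

    center: tuple[float, float]
    radius: float

    def __post_init__(self) -> None:
        if not self.radius > 0:
            raise ValueError("optic disc radius must be > 0")


@dataclass
class VesselSegment:
    """Ordered centerline with per-point diameters between two graph nodes."""

    vessel_class: str
    points: np.ndarray  # (n, 2) float, (row, col)
    diameters: Optional[np.ndarray] = None  # (n,) px, filled by measure_diameters
    node_ids: tuple[int, int] = (-1, -1)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[0] < 2:
            raise ValueError("a vessel segment needs >= 2 centerline points")
        if self.diameters is not None:
            self.diameters = np.asarray(self.diameters, dtype=float)

    @property
    def n_points(self) -> int:
        return int(self.points.shape[0])

    def arc_length(self) -> float:
        return float(np.sum(np.hypot(*np.diff(self.points, axis=0).T)))

    def chord_length(self) -> float:
        return float(np.hypot(*(self.points[-1] - self.points[0])))

    def is_loop(self) -> bool:
        return self.node_ids[0] == self.node_ids[1]


@dataclass
class Node:
    id: int
    position: tuple[float, float]
    kind: str = "endpoint"  # endpoint | bifurcation | crossing_candidate | through
    pixels: list = field(default_factory=list)


@dataclass
class VesselGraph:
    """Nodes plus centerline segments traced from one class skeleton."""

    nodes: dict[int, Node] = field(default_factory=dict)
    segments: list[VesselSegment] = field(default_factory=list)
    vessel_class: str = "artery"
    image_id: str = ""

    def node_degree(self, node_id: int) -> int:
        deg = 0
        for seg in self.segments:
            deg += (seg.node_ids[0] == node_id) + (seg.node_ids[1] == node_id)
        return deg

    def refresh_node_kinds(self) -> None:
        """Re-derive node kinds from segment incidence (loops count twice)."""
        degrees = {nid: 0 for nid in self.nodes}
        for seg in self.segments:
            degrees[seg.node_ids[0]] += 1
            degrees[seg.node_ids[1]] += 1
        for nid, node in self.nodes.items():
            d = degrees[nid]
            if d <= 1:
                node.kind = "endpoint"
            elif d == 2:
                node.kind = "through"
            elif d == 3:
                node.kind = "bifurcation"
            else:
                node.kind = "crossing_candidate"

    def n_bifurcations(self) -> int:
        return sum(1 for n in self.nodes.values() if n.kind == "bifurcation")

    def drop_isolated_nodes(self) -> None:
        incident = set()
        for seg in self.segments:
            incident.update(seg.node_ids)
        self.nodes = {nid: n for nid, n in self.nodes.items() if nid in incident}


# ---------------------------------------------------------------------------
# skeletonization

def skeletonize(mask: RasterMask) -> RasterMask:
    """Thin a binary mask to a 1-px-wide, topology-preserving skeleton."""
    skel = _sk_skeletonize(mask.data)
    return RasterMask(skel, image_id=mask.image_id, vessel_class=mask.vessel_class,
                      px_per_disc_diameter=mask.px_per_disc_diameter)


_NEIGH_KERNEL = np.array([[1, 1, 1], [1, 0, 1], [1, 1, 1]], dtype=np.uint8)

_OFFSETS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def _neighbour_counts(skel: np.ndarray) -> np.ndarray:
    return ndimage.convolve(skel.astype(np.uint8), _NEIGH_KERNEL,
                            mode="constant", cval=0)


# ---------------------------------------------------------------------------
# graph construction

def build_graph(skeleton: RasterMask, merge_radius: float = 2.0) -> VesselGraph:
    """Trace a 1-px skeleton into nodes and ordered centerline segments.

    Node pixels are skeleton pixels with != 2 eight-neighbours; node pixels
    within Chebyshev distance ``merge_radius`` of each other collapse into a
    single node at their centroid.  Segments are the maximal degree-2 pixel
    chains joining two node clusters (or one cluster twice, for loops).
    """
    skel = skeleton.data
    graph = VesselGraph(vessel_class=skeleton.vessel_class,
                        image_id=skeleton.image_id)
    if not skel.any():
        return graph

    nn = _neighbour_counts(skel)
    node_mask = skel & (nn != 2)
    node_px = np.argwhere(node_mask)

    # cluster node pixels (union-find over Chebyshev-close pairs)
    cluster_of: dict[tuple[int, int], int] = {}
    if len(node_px):
        parent = np.arange(len(node_px))

        def find(i: int) -> int:
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        tree = cKDTree(node_px)
        for i, j in tree.query_pairs(r=merge_radius, p=np.inf):
            ri, rj = find(i), find(j)
            if ri != rj:
                parent[ri] = rj
        roots = {}
        for i, (r, c) in enumerate(node_px):
            root = find(i)
            nid = roots.setdefault(root, len(roots))
            cluster_of[(int(r), int(c))] = nid
        members: dict[int, list] = {}
        for px, nid in cluster_of.items():
            members.setdefault(nid, []).append(px)
        for nid, pxs in members.items():
            centroid = tuple(np.mean(np.asarray(pxs, dtype=float), axis=0))
            graph.nodes[nid] = Node(id=nid, position=centroid, pixels=pxs)

    h, w = skel.shape

    def nb8(p):
        r, c = p
        for dr, dc in _OFFSETS:
            rr, cc = r + dr, c + dc
            if 0 <= rr < h and 0 <= cc < w and skel[rr, cc]:
                yield (rr, cc)

    used = np.zeros_like(skel, dtype=bool)
    seen_direct = set()  # node-pixel to node-pixel adjacencies already emitted

    def emit(path, nid_a, nid_b):
        graph.segments.append(VesselSegment(
            vessel_class=skeleton.vessel_class,
            points=np.asarray(path, dtype=float),
            node_ids=(nid_a, nid_b)))

    for (r, c), nid in cluster_of.items():
        p = (r, c)
        for q in nb8(p):
            if q in cluster_of:
                other = cluster_of[q]
                if other == nid:
                    continue
                key = frozenset((p, q))
                if key in seen_direct:
                    continue
                seen_direct.add(key)
                emit([p, q], nid, other)
                continue
            if used[q]:
                continue
            # walk the degree-2 chain starting at q
            path = [p, q]
            used[q] = True
            prev, cur = p, q
            for _ in range(skel.size):
                nxt = None
                for x in nb8(cur):
                    if x == prev:
                        continue
                    # avoid doubling back onto the start cluster via a
                    # redundant diagonal right at the junction
                    if len(path) == 2 and x in cluster_of and cluster_of[x] == nid \
                            and max(abs(x[0] - p[0]), abs(x[1] - p[1])) <= 1:
                        continue
                    nxt = x
                    break
                if nxt is None:  # dead end (shouldn't happen on valid skeletons)
                    break
                path.append(nxt)
                if nxt in cluster_of:
                    emit(path, nid, cluster_of[nxt])
                    break
                used[nxt] = True
                prev, cur = cur, nxt

    # pure cycles: degree-2 pixels never reached from any node
    remaining = skel & ~used & ~node_mask
    if remaining.any():
        lbl, nlab = ndimage.label(remaining, structure=np.ones((3, 3)))
        for k in range(1, nlab + 1):
            pxs = [tuple(p) for p in np.argwhere(lbl == k)]
            if len(pxs) < 3:
                continue
            start = pxs[0]
            nid = len(graph.nodes)
            graph.nodes[nid] = Node(id=nid, position=(float(start[0]), float(start[1])),
                                    pixels=[start])
            path = [start]
            prev, cur = None, start
            for _ in range(len(pxs) + 1):
                nxt = None
                for x in nb8(cur):
                    if x != prev and (lbl[x] == k or x == start) and (x == start or not used[x]):
                        nxt = x
                        break
                if nxt is None:
                    break
                path.append(nxt)
                if nxt == start:
                    break
                used[nxt] = True
                prev, cur = cur, nxt
            if len(path) >= 3:
                emit(path, nid, nid)

    graph.refresh_node_kinds()
    return graph


# ---------------------------------------------------------------------------
# pruning and simplification

def _dissolve_through_nodes(graph: VesselGraph) -> None:
    """Merge the two segments incident to each degree-2 node into one."""
    changed = True
    while changed:
        changed = False
        graph.refresh_node_kinds()
        incidence: dict[int, list[int]] = {}
        for i, seg in enumerate(graph.segments):
            for nid in seg.node_ids:
                incidence.setdefault(nid, []).append(i)
        for nid, node in list(graph.nodes.items()):
            segs = incidence.get(nid, [])
            if node.kind != "through" or len(segs) != 2 or segs[0] == segs[1]:
                continue
            a, b = graph.segments[segs[0]], graph.segments[segs[1]]
            pa = a.points if a.node_ids[1] == nid else a.points[::-1]
            na = a.node_ids[0] if a.node_ids[1] == nid else a.node_ids[1]
            pb = b.points if b.node_ids[0] == nid else b.points[::-1]
            nb = b.node_ids[1] if b.node_ids[0] == nid else b.node_ids[0]
            merged = VesselSegment(
                vessel_class=a.vessel_class,
                points=np.vstack([pa, pb[1:]]),
                node_ids=(na, nb))
            graph.segments = [s for i, s in enumerate(graph.segments)
                              if i not in segs]
            graph.segments.append(merged)
            del graph.nodes[nid]
            changed = True
            break
    graph.refresh_node_kinds()


def prune_spurs(graph: VesselGraph, min_spur_px: float = 10.0) -> VesselGraph:
    """Remove terminal segments shorter than ``min_spur_px``.

    Spurs are thinning artifacts: short dead-end branches hanging off a
    junction.  After removal, junctions reduced to degree 2 are dissolved
    (their two incident segments concatenated).  Idempotent.
    """
    graph = dataclasses.replace(
        graph,
        nodes={nid: dataclasses.replace(n) for nid, n in graph.nodes.items()},
        segments=list(graph.segments))
    while True:
        graph.refresh_node_kinds()
        degrees: dict[int, int] = {nid: 0 for nid in graph.nodes}
        for seg in graph.segments:
            degrees[seg.node_ids[0]] += 1
            degrees[seg.node_ids[1]] += 1
        to_drop = []
        for i, seg in enumerate(graph.segments):
            if seg.is_loop() or seg.arc_length() >= min_spur_px:
                continue
            d0, d1 = degrees[seg.node_ids[0]], degrees[seg.node_ids[1]]
            # terminal: one end is a leaf and the other is a junction --
            # never delete an isolated whole vessel (both ends leaves)
            if (d0 == 1) != (d1 == 1):
                junction = seg.node_ids[1] if d0 == 1 else seg.node_ids[0]
                if degrees[junction] >= 3:
                    to_drop.append(i)
        if not to_drop:
            break
        graph.segments = [s for i, s in enumerate(graph.segments)
                          if i not in set(to_drop)]
        graph.drop_isolated_nodes()
    _dissolve_through_nodes(graph)
    graph.drop_isolated_nodes()
    graph.refresh_node_kinds()
    return graph


def consolidate_junctions(graph: VesselGraph,
                          min_sep_px: float = 10.0) -> VesselGraph:
    """Contract short internal segments joining two junction nodes.

    Thinning a wide vessel junction often yields a small parallel-path loop
    or a pair of branch points a few pixels apart where the anatomy has a
    single bifurcation.  Any non-terminal segment shorter than ``min_sep_px``
    whose two end nodes both have degree >= 3 is contracted (the nodes
    merged); tiny loops at the merged node are dropped.  Node kinds are
    recomputed from the resulting degrees.
    """
    changed = True
    while changed:
        changed = False
        degrees: dict[int, int] = {nid: 0 for nid in graph.nodes}
        for seg in graph.segments:
            degrees[seg.node_ids[0]] += 1
            degrees[seg.node_ids[1]] += 1
        for i, seg in enumerate(graph.segments):
            u, vtx = seg.node_ids
            if u == vtx:
                if seg.arc_length() < min_sep_px:
                    graph.segments.pop(i)
                    changed = True
                    break
                continue
            if seg.arc_length() >= min_sep_px:
                continue
            if degrees[u] < 3 or degrees[vtx] < 3:
                continue
            # merge vtx into u
            pu = np.asarray(graph.nodes[u].position)
            pv = np.asarray(graph.nodes[vtx].position)
            graph.nodes[u].position = tuple((pu + pv) / 2.0)
            graph.nodes[u].pixels = (graph.nodes[u].pixels
                                     + graph.nodes[vtx].pixels)
            del graph.nodes[vtx]
            graph.segments.pop(i)
            for other in graph.segments:
                a, b = other.node_ids
                other.node_ids = (u if a == vtx else a, u if b == vtx else b)
            changed = True
            break
    _dissolve_through_nodes(graph)
    graph.drop_isolated_nodes()
    graph.refresh_node_kinds()
    return graph


# ---------------------------------------------------------------------------
# centerline smoothing and diameters

def smooth_segments(graph: VesselGraph, window: int = 3,
                    passes: int = 2) -> VesselGraph:
    """Moving-average smoothing of segment centerlines (endpoints fixed).

    Thinning yields integer pixel chains whose staircase inflates arc
    lengths; a short moving average recovers sub-pixel centerlines.  Window 3
    with two passes keeps the curve shape while removing the 1-px zigzag.
    """
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be an odd integer >= 3")
    kernel = np.ones(window) / window
    half = window // 2
    for seg in graph.segments:
        pts = seg.points
        if pts.shape[0] <= window:
            continue
        for _ in range(passes):
            sm = pts.copy()
            for axis in (0, 1):
                conv = np.convolve(pts[:, axis], kernel, mode="valid")
                sm[half:-half, axis] = conv
            sm[0], sm[-1] = pts[0], pts[-1]
            pts = sm
        seg.points = pts
    return graph


def measure_diameters(graph: VesselGraph, mask: RasterMask,
                      edge_correction_px: float = 1.0) -> VesselGraph:
    """Attach per-point diameters from the Euclidean distance transform.

    Diameter = 2 x (ridge-corrected EDT) - ``edge_correction_px``.  The EDT
    reaches from the sampling point to the first *background pixel centre*,
    i.e. about half a pixel past the true boundary; and the traced centerline
    can sit up to half a pixel off the true medial ridge (even-width
    strokes).  Sampling the EDT at the point and at +-0.5 px along the local
    normal, and taking max(EDT + |offset|), recovers the ridge value; the
    1 px correction then removes the two half-pixel boundary overshoots.
    The graph must have been traced from this mask's skeleton (every
    centerline point inside the foreground)."""
    edt = ndimage.distance_transform_edt(mask.data)
    for seg in graph.segments:
        rows = np.clip(np.rint(seg.points[:, 0]).astype(int), 0, mask.shape[0] - 1)
        cols = np.clip(np.rint(seg.points[:, 1]).astype(int), 0, mask.shape[1] - 1)
        on_fg = mask.data[rows, cols]
        if not on_fg.all():
            # smoothed sub-pixel centerlines of 1-px strokes may round onto
            # a background pixel; tolerate points within 1 px of foreground
            for i in np.flatnonzero(~on_fg):
                r0, c0 = rows[i], cols[i]
                window = mask.data[max(0, r0 - 1):r0 + 2, max(0, c0 - 1):c0 + 2]
                if not window.any():
                    raise ValueError(
                        f"centerline point outside mask foreground for image "
                        f"{mask.image_id!r} ({mask.vessel_class}): "
                        f"graph/mask mismatch")
        tangents = np.gradient(seg.points, axis=0)
        norms = np.hypot(tangents[:, 0], tangents[:, 1])
        norms[norms == 0] = 1.0
        normal = np.column_stack([-tangents[:, 1], tangents[:, 0]]) / norms[:, None]
        ridge = ndimage.map_coordinates(edt, seg.points.T, order=1,
                                        mode="nearest")
        for t in (-0.5, 0.5):
            shifted = ndimage.map_coordinates(
                edt, (seg.points + t * normal).T, order=1, mode="nearest")
            ridge = np.maximum(ridge, shifted + abs(t))
        seg.diameters = np.maximum(2.0 * ridge - edge_correction_px, 1.0)
    return graph
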