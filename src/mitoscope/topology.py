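"""One-pixel skeletonization and skeleton-graph topology.

A binary object is thinned to a one-pixel-wide, homotopy-preserving
skeleton and converted to a multigraph whose nodes are endpoints
(degree 1), junctions (degree >= 3, with mutually adjacent junction
pixels merged into a single node) or isolated pixels, and whose edges
are the traced pixel paths between nodes.  The number of independent
loops is the cyclomatic number E - V + C of that multigraph, which for
a homotopy-preserving thinning equals the number of holes in the
original region.

Pixel adjacency is 8-connected, with one standard correction: a
diagonal link between two skeleton pixels is dropped when the two
pixels already share an axial (4-connected) common neighbor, so that
staircase corners do not create spurious 3-cycles.  Geodesic edge
length sums 1 per axial step and sqrt(2) per diagonal step.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from skimage import morphology

Coord = tuple[int, int]

_SQRT2 = math.sqrt(2.0)

_NEIGHBORS8 = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


@dataclass
class SkeletonNode:
    node_id: int
    coord: tuple[float, float]  # centroid (row, col) of the pixel cluster
    pixels: list[Coord]
    kind: str  # endpoint | junction | isolated | cycle
    degree: int = 0


@dataclass
class SkeletonEdge:
    edge_id: int
    path: list[Coord]  # ordered pixel path including both terminal pixels
    length: float
    u: int
    v: int


@dataclass
class SkeletonGraph:
    """Node/edge decomposition of a one-pixel skeleton for one object."""

    label: int
    nodes: dict[int, SkeletonNode]
    edges: dict[int, SkeletonEdge]
    graph: nx.MultiGraph = field(repr=False, default_factory=nx.MultiGraph)

    @property
    def n_components(self) -> int:
        if len(self.graph) == 0:
            return 0
        return nx.number_connected_components(self.graph)


@dataclass
class TopologySummary:
    """Per-object topology census used by morphotyping and feature fusion."""

    label: int
    endpoints: int
    junctions: int
    loops: int
    branch_count: int
    mean_branch_length_px: float
    mean_branch_angle_deg: float  # NaN when the skeleton has no chords
    total_length_px: float


def skeletonize(mask: np.ndarray) -> np.ndarray:
    """Thin a binary object to a one-pixel-wide skeleton.

    Uses Guo-Hall morphological thinning (scikit-image ``thin``), which
    preserves homotopy — a simply connected blob keeps zero cycles, an
    annulus keeps exactly one — followed by a simple-point cleanup that
    erases residual 2x2 blocks where a deletion is topology-preserving.
    The only blocks that can remain are thick junctions whose four
    pixels all carry separate limbs; those are merged into a single
    junction node by the graph builder.  An empty mask yields an empty
    skeleton.
    """
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        return np.zeros_like(mask)
    return _remove_square_blocks(morphology.thin(mask))


# circular 8-neighborhood order: N, NE, E, SE, S, SW, W, NW
_CIRCLE = [(-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1)]


def _deletable(skel: np.ndarray, r: int, c: int) -> bool:
    """Simple-point test: removal keeps local connectivity and holes.

    Uses the standard crossing-number criterion (exactly one 0->1
    transition around the 8-neighborhood) plus a non-endpoint guard.
    """
    ring = []
    for dr, dc in _CIRCLE:
        rr, cc = r + dr, c + dc
        inside = 0 <= rr < skel.shape[0] and 0 <= cc < skel.shape[1]
        ring.append(bool(skel[rr, cc]) if inside else False)
    transitions = sum(
        1 for i in range(8) if not ring[i] and ring[(i + 1) % 8]
    )
    return transitions == 1 and sum(ring) >= 2


def _remove_square_blocks(skel: np.ndarray) -> np.ndarray:
    """Erase residual 2x2 blocks left by thinning, one simple pixel at a time."""
    skel = skel.copy()
    for _ in range(skel.size):
        blocks = np.argwhere(
            skel[:-1, :-1] & skel[1:, :-1] & skel[:-1, 1:] & skel[1:, 1:]
        )
        if len(blocks) == 0:
            return skel
        removed = False
        for r, c in blocks:
            for dr, dc in ((0, 0), (0, 1), (1, 0), (1, 1)):
                if skel[r + dr, c + dc] and _deletable(skel, r + dr, c + dc):
                    skel[r + dr, c + dc] = False
                    removed = True
                    break
            if removed:
                break
        if not removed:
            return skel  # leave for the graph builder's thinness check
    return skel


def _check_thin(pixels: set[Coord], degree: dict[Coord, int]) -> None:
    """Reject 2x2 foreground blocks unless they are thick junctions.

    Four mutually adjacent branch-bearing pixels (each of pruned degree
    >= 3) can be unavoidable where several limbs meet; they are merged
    into a single junction node downstream, matching the junction-pixel
    clustering convention.  Any other 2x2 block means the input is not a
    valid one-pixel skeleton.
    """
    for r, c in pixels:
        block = [(r, c), (r + 1, c), (r, c + 1), (r + 1, c + 1)]
        if all(p in pixels for p in block):
            if any(degree[p] < 3 for p in block):
                raise ValueError(
                    f"skeleton is not one pixel wide: 2x2 block at ({r}, {c})"
                )


def _adjacency(pixels: set[Coord]) -> dict[Coord, list[Coord]]:
    """8-adjacency with diagonal links pruned at staircase corners."""
    adj: dict[Coord, list[Coord]] = {}
    for r, c in pixels:
        neigh = []
        for dr, dc in _NEIGHBORS8:
            q = (r + dr, c + dc)
            if q not in pixels:
                continue
            if dr != 0 and dc != 0:
                # drop the diagonal if an axial 2-step route exists
                if (r, c + dc) in pixels or (r + dr, c) in pixels:
                    continue
            neigh.append(q)
        adj[(r, c)] = neigh
    return adj


def _step_length(a: Coord, b: Coord) -> float:
    return _SQRT2 if (a[0] != b[0] and a[1] != b[1]) else 1.0


def _path_length(path: list[Coord]) -> float:
    return sum(_step_length(a, b) for a, b in zip(path, path[1:]))


def build_skeleton_graph(skeleton: np.ndarray, label: int = 1) -> SkeletonGraph:
    """Convert a one-pixel skeleton mask into a :class:`SkeletonGraph`.

    Raises ``ValueError`` (with the offending coordinates) if the input
    contains a 2x2 foreground block, i.e. is not a valid thin skeleton.
    """
    skeleton = np.asarray(skeleton).astype(bool)
    pixels = {(int(r), int(c)) for r, c in zip(*np.nonzero(skeleton))}

    graph = SkeletonGraph(label=label, nodes={}, edges={})
    if not pixels:
        return graph
    adj = _adjacency(pixels)
    degree = {p: len(adj[p]) for p in pixels}
    _check_thin(pixels, degree)

    # --- node pixels: anything whose pixel degree differs from 2
    node_pixel: dict[Coord, int] = {}
    next_node = 0

    def _add_node(px_list: list[Coord], kind: str) -> int:
        nonlocal next_node
        nid = next_node
        next_node += 1
        rr = float(np.mean([p[0] for p in px_list]))
        cc = float(np.mean([p[1] for p in px_list]))
        graph.nodes[nid] = SkeletonNode(nid, (rr, cc), list(px_list), kind)
        for p in px_list:
            node_pixel[p] = nid
        return nid

    junction_pixels = {p for p in pixels if degree[p] >= 3}
    # merge mutually adjacent junction pixels into one node
    seen: set[Coord] = set()
    for p in sorted(junction_pixels):
        if p in seen:
            continue
        cluster = [p]
        seen.add(p)
        stack = [p]
        while stack:
            q = stack.pop()
            for w in adj[q]:
                if w in junction_pixels and w not in seen:
                    seen.add(w)
                    cluster.append(w)
                    stack.append(w)
        _add_node(sorted(cluster), "junction")
    for p in sorted(pixels):
        if degree[p] == 1:
            _add_node([p], "endpoint")
        elif degree[p] == 0:
            _add_node([p], "isolated")

    # --- trace edges between node pixels through degree-2 chains
    next_edge = 0
    used_halfedges: set[tuple[Coord, Coord]] = set()

    def _add_edge(path: list[Coord], u: int, v: int) -> None:
        nonlocal next_edge
        eid = next_edge
        next_edge += 1
        graph.edges[eid] = SkeletonEdge(eid, path, _path_length(path), u, v)
        graph.graph.add_edge(u, v, key=eid, length=_path_length(path))

    for start in sorted(node_pixel):
        u = node_pixel[start]
        for first in adj[start]:
            if (start, first) in used_halfedges:
                continue
            if first in node_pixel:
                nid = node_pixel[first]
                if nid == u and first == start:
                    continue
                if nid == u and graph.nodes[u].kind == "junction":
                    # internal cluster adjacency, not an edge
                    used_halfedges.add((start, first))
                    used_halfedges.add((first, start))
                    continue
                used_halfedges.add((start, first))
                used_halfedges.add((first, start))
                _add_edge([start, first], u, nid)
                continue
            # walk the degree-2 chain
            path = [start, first]
            used_halfedges.add((start, first))
            prev, cur = start, first
            while cur not in node_pixel:
                nxt_candidates = [w for w in adj[cur] if w != prev]
                if not nxt_candidates:
                    break  # dead end inside a chain (cannot happen on valid input)
                nxt = nxt_candidates[0]
                used_halfedges.add((cur, nxt))
                path.append(nxt)
                prev, cur = cur, nxt
            if cur in node_pixel:
                used_halfedges.add((cur, prev))
                _add_edge(path, u, node_pixel[cur])

    # --- components made only of degree-2 pixels are pure cycles
    assigned = set(node_pixel)
    for e in graph.edges.values():
        assigned.update(e.path)
    remaining = sorted(pixels - assigned)
    while remaining:
        anchor = remaining[0]
        nid = _add_node([anchor], "cycle")
        first = adj[anchor][0]
        path = [anchor, first]
        prev, cur = anchor, first
        while cur != anchor:
            nxt = [w for w in adj[cur] if w != prev][0]
            path.append(nxt)
            prev, cur = cur, nxt
        _add_edge(path, nid, nid)
        assigned.update(path)
        remaining = sorted(pixels - assigned)

    # make isolated/endpoint-only nodes visible to networkx
    for nid in graph.nodes:
        if nid not in graph.graph:
            graph.graph.add_node(nid)
    for node in graph.nodes.values():
        node.degree = sum(
            (1 if e.u == node.node_id else 0) + (1 if e.v == node.node_id else 0)
            for e in graph.edges.values()
        )
    return graph


def count_loops(graph: SkeletonGraph) -> int:
    """Cyclomatic number E - V + C of the skeleton multigraph."""
    if len(graph.graph) == 0:
        return 0
    return graph.graph.number_of_edges() - graph.graph.number_of_nodes() + graph.n_components


def _chord_angle_deg(edge: SkeletonEdge, nodes: dict[int, SkeletonNode]) -> float | None:
    """Orientation in [0, 180) of the straight chord between edge endpoints.

    Measured from the +col (x) axis with row increasing downward, so a
    horizontal path has orientation 0 and one rising to the right 45.
    Self-loops have no chord and are skipped.
    """
    a, b = edge.path[0], edge.path[-1]
    dr, dc = b[0] - a[0], b[1] - a[1]
    if dr == 0 and dc == 0:
        return None
    return math.degrees(math.atan2(-dr, dc)) % 180.0


def _circular_mean_180(angles_deg: list[float]) -> float:
    doubled = np.deg2rad(np.asarray(angles_deg) * 2.0)
    mean = math.atan2(float(np.sin(doubled).sum()), float(np.cos(doubled).sum()))
    return (math.degrees(mean) / 2.0) % 180.0


def topology_summary(graph: SkeletonGraph) -> TopologySummary:
    """Summarize a skeleton graph into the counts used downstream.

    ``branch_count`` is the number of edges incident to at least one
    junction node; a junction-free skeleton (plain rod or dot) therefore
    has branch count 0, which is what the dot/rod morphotype rules
    expect.  ``mean_branch_angle_deg`` is the circular mean (period 180)
    of edge chord orientations, NaN when no edge has a nonzero chord.
    """
    endpoints = sum(1 for n in graph.nodes.values() if n.kind == "endpoint")
    junctions = sum(1 for n in graph.nodes.values() if n.kind == "junction")
    loops = count_loops(graph)
    junction_ids = {n.node_id for n in graph.nodes.values() if n.kind == "junction"}
    branch_count = sum(
        1 for e in graph.edges.values() if e.u in junction_ids or e.v in junction_ids
    )
    lengths = [e.length for e in graph.edges.values()]
    total = float(sum(lengths))
    mean_len = float(np.mean(lengths)) if lengths else 0.0
    angles = [
        a
        for e in graph.edges.values()
        if (a := _chord_angle_deg(e, graph.nodes)) is not None
    ]
    mean_angle = _circular_mean_180(angles) if angles else float("nan")
    return TopologySummary(
        label=graph.label,
        endpoints=endpoints,
        junctions=junctions,
        loops=loops,
        branch_count=branch_count,
        mean_branch_length_px=mean_len,
        mean_branch_angle_deg=mean_angle,
        total_length_px=total,
    )


def object_topology(mask: np.ndarray, label: int = 1) -> TopologySummary:
    """Convenience: skeletonize one object mask and summarize its topology."""
    return topology_summary(build_skeleton_graph(skeletonize(mask), label))
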