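"""Shared fixtures and independent brute-force oracles.

The oracle functions here deliberately avoid the library's own code
paths: moments are accumulated pixel by pixel, skeleton cycles are
counted by fundamental-cycle search on an explicit pixel graph, AUC by
exhaustive pair counting, and dilation by scanning every offset.
"""

from __future__ import annotations

import math

import networkx as nx
import numpy as np
import pytest

from mitoscope import synthetic as syn


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


# ---------------------------------------------------------------------------
# brute-force moment / shape oracles


def brute_force_axes(mask: np.ndarray) -> tuple[float, float, float]:
    """Moment-ellipse axes via explicit eigen-decomposition of the
    pixel covariance (with the 1/12 per-pixel variance correction)."""
    rows, cols = np.nonzero(mask)
    pts = np.stack([rows, cols], axis=1).astype(float)
    pts -= pts.mean(axis=0)
    cov = pts.T @ pts / len(pts) + np.eye(2) / 12.0
    evals, evecs = np.linalg.eigh(cov)
    major = 4.0 * math.sqrt(max(evals[1], 0.0))
    minor = 4.0 * math.sqrt(max(evals[0], 0.0))
    v = evecs[:, 1]  # (row, col) direction of the major axis
    angle = math.degrees(math.atan2(-v[0], v[1])) % 180.0
    return max(major, 1.0), max(minor, 1.0), angle


def brute_force_dilate_3x3(mask: np.ndarray) -> np.ndarray:
    out = np.zeros_like(mask, dtype=bool)
    nrows, ncols = mask.shape
    for r, c in zip(*np.nonzero(mask)):
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                rr, cc = r + dr, c + dc
                if 0 <= rr < nrows and 0 <= cc < ncols:
                    out[rr, cc] = True
    return out


def brute_force_boundary(mask: np.ndarray) -> np.ndarray:
    """Foreground pixels with at least one background 4-neighbor."""
    fg = mask > 0
    out = np.zeros_like(fg)
    nrows, ncols = fg.shape
    for r, c in zip(*np.nonzero(fg)):
        for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
            rr, cc = r + dr, c + dc
            if not (0 <= rr < nrows and 0 <= cc < ncols) or not fg[rr, cc]:
                out[r, c] = True
                break
    return out


# ---------------------------------------------------------------------------
# brute-force skeleton-pixel graph oracle


def pixel_graph(skeleton: np.ndarray) -> nx.Graph:
    """8-connected pixel graph with staircase diagonals pruned."""
    pixels = {(int(r), int(c)) for r, c in zip(*np.nonzero(skeleton))}
    g = nx.Graph()
    g.add_nodes_from(pixels)
    for r, c in pixels:
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == dc == 0:
                    continue
                q = (r + dr, c + dc)
                if q not in pixels:
                    continue
                if dr != 0 and dc != 0 and ((r, c + dc) in pixels or (r + dr, c) in pixels):
                    continue
                g.add_edge((r, c), q)
    return g


def oracle_cycles(skeleton: np.ndarray) -> int:
    """Independent-cycle count by E - V + C on the contracted pixel graph.

    Mutually adjacent branch pixels (degree >= 3) are contracted to one
    junction node first — the same clustering convention the library
    documents — so a thick 2x2 junction does not read as a spurious loop.
    """
    g = pixel_graph(skeleton)
    junction_pixels = [n for n in g if g.degree(n) >= 3]
    mapping = {}
    for i, cluster in enumerate(nx.connected_components(g.subgraph(junction_pixels))):
        for n in cluster:
            mapping[n] = ("junction", i)
    mg = nx.MultiGraph()
    for n in g:
        mg.add_node(mapping.get(n, n))
    for u, v in g.edges():
        mu, mv = mapping.get(u, u), mapping.get(v, v)
        if mu == mv and isinstance(mu, tuple):
            continue  # internal junction-cluster adjacency
        mg.add_edge(mu, mv)
    return (
        mg.number_of_edges()
        - mg.number_of_nodes()
        + nx.number_connected_components(mg)
    )


def oracle_endpoint_junction_counts(skeleton: np.ndarray) -> tuple[int, int]:
    """(endpoints, junction clusters) by raw degree scan on the pixel graph."""
    g = pixel_graph(skeleton)
    endpoints = sum(1 for n in g if g.degree(n) == 1)
    junction_pixels = [n for n in g if g.degree(n) >= 3]
    sub = g.subgraph(junction_pixels)
    junctions = nx.number_connected_components(sub) if junction_pixels else 0
    return endpoints, junctions


def oracle_auc(scores, labels) -> float:
    """Pairwise concordance probability, ties counted half."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == labels.max()]
    neg = scores[labels != labels.max()]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


# ---------------------------------------------------------------------------
# shape fixtures


def shape_mask(kind: str, rng: np.random.Generator, canvas_px: int = 160) -> np.ndarray:
    """One randomly parameterized, margin-respecting shape on its own canvas."""
    spec = syn.random_shape_spec(kind, rng)
    spec.center = (canvas_px / 2, canvas_px / 2)
    return syn.make_shape(spec, (canvas_px, canvas_px))


@pytest.fixture
def small_scene():
    rng = np.random.default_rng(7)
    shapes = [syn.random_shape_spec(k, rng) for k in ["dot"] * 3 + ["rod"] * 3 + ["network"] * 3]
    return syn.render_scene(syn.SceneSpec(shapes, canvas=(400, 400), seed=7))
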