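"""Dendritic-arbor graph metrics from traced skeletons.

A 1-px-wide skeleton image plus a soma mask are converted into a graph whose
vertices are the soma, branch points (pixels with three or more skeleton
neighbors) and terminal endpoints; edges carry their pixel polylines and
physical lengths (straight steps = pixel size, diagonal steps = sqrt(2) x
pixel size, 8-connectivity).  Dendritic complexity is summarized as the
number of nodes (junctions), tips (endpoints) and total dendritic length.
Terminal twigs shorter than a threshold can be pruned away, smallest first;
the junctions and segments surviving the pruning are the "master" junctions
and segments reported as nodes.

The graph builder expects a clean single-pixel-wide skeleton (as produced by
the synthetic tree generator or by careful thinning); thick junction blobs
are not merged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx
import numpy as np

__all__ = [
    "SOMA",
    "TreeMetrics",
    "skeleton_to_graph",
    "prune_to_master",
    "prune_leaves_once",
    "tree_metrics",
    "rasterize_graph",
    "write_swc",
]

SOMA = "soma"

_SQRT2 = math.sqrt(2.0)


@dataclass
class TreeMetrics:
    """Dendritic complexity summary."""

    nodes: int
    tips: int
    total_length_um: float


def _neighbors(p: tuple[int, int], pix: set[tuple[int, int]]
               ) -> list[tuple[int, int]]:
    r, c = p
    out = []
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            if dr == 0 and dc == 0:
                continue
            q = (r + dr, c + dc)
            if q in pix:
                out.append(q)
    return out


def _polyline_length_um(polyline: list[tuple[int, int]],
                        pixel_size_um: float) -> float:
    total = 0.0
    for (r0, c0), (r1, c1) in zip(polyline, polyline[1:]):
        total += _SQRT2 if (r0 != r1 and c0 != c1) else 1.0
    return total * pixel_size_um


def skeleton_to_graph(skeleton: np.ndarray, soma_mask: np.ndarray,
                      pixel_size_um: float) -> nx.MultiGraph:
    """Build the arbor graph of a skeleton anchored on a soma mask.

    Skeleton pixels inside the soma are discarded; skeleton pixels 8-adjacent
    to the soma are attachment points and are contracted into a single
    ``soma`` vertex, so primary dendrites are the edges incident to it.
    """
    skeleton = np.asarray(skeleton, dtype=bool)
    soma_mask = np.asarray(soma_mask, dtype=bool)
    if skeleton.shape != soma_mask.shape:
        raise ValueError("skeleton and soma mask shapes differ")
    if pixel_size_um <= 0:
        raise ValueError("pixel_size_um must be > 0")
    body = skeleton & ~soma_mask
    if not body.any():
        raise ValueError("empty skeleton")

    pix = set(zip(*np.nonzero(body)))
    soma_set = set(zip(*np.nonzero(soma_mask)))
    deg = {p: len(_neighbors(p, pix)) for p in pix}
    anchors = {p for p in pix if _neighbors(p, soma_set)}
    if not anchors:
        raise ValueError("skeleton does not touch the soma mask")

    vertex_pixels = {p for p in pix if deg[p] != 2} | anchors

    g = nx.MultiGraph()
    g.add_node(SOMA, kind="soma")
    for p in vertex_pixels:
        if p not in anchors:
            g.add_node(p, kind="junction" if deg[p] >= 3 else "endpoint",
                       pixel=p)

    def node_of(p: tuple[int, int]):
        return SOMA if p in anchors else p

    used: set[tuple[tuple[int, int], tuple[int, int]]] = set()
    for v in sorted(vertex_pixels):
        for n in sorted(_neighbors(v, pix)):
            if (v, n) in used:
                continue
            polyline = [v, n]
            prev, cur = v, n
            while cur not in vertex_pixels:
                nxts = [q for q in _neighbors(cur, pix) if q != prev]
                if len(nxts) != 1:  # dead-end stub pixel; treat as endpoint
                    break
                prev, cur = cur, nxts[0]
                polyline.append(cur)
            used.add((v, n))
            used.add((cur, prev))
            u0, u1 = node_of(v), node_of(cur)
            if u0 == SOMA and u1 == SOMA and len(polyline) == 2:
                continue  # two adjacent anchor pixels: no dendrite between
            g.add_edge(u0, u1,
                       length_um=_polyline_length_um(polyline, pixel_size_um),
                       polyline=polyline)

    # isolated anchor pixel (degree 0 in the skeleton): a primary stub with
    # no extent; contributes nothing
    return g


def tree_metrics(g: nx.MultiGraph) -> TreeMetrics:
    """Count junctions and tips and sum edge lengths (soma excluded)."""
    nodes = 0
    tips = 0
    for v in g.nodes:
        if v == SOMA:
            continue
        d = g.degree(v)
        if d >= 3:
            nodes += 1
        elif d == 1:
            tips += 1
    total = sum(data["length_um"] for _, _, data in g.edges(data=True))
    return TreeMetrics(nodes=nodes, tips=tips, total_length_um=total)


def _orient_to_end_at(polyline: list[tuple[int, int]], pixel: tuple[int, int]
                      ) -> list[tuple[int, int]]:
    if polyline[-1] == pixel:
        return list(polyline)
    if polyline[0] == pixel:
        return list(reversed(polyline))
    raise ValueError("polyline does not touch the merge vertex")


def _merge_degree_two(g: nx.MultiGraph, w) -> None:
    """Replace a degree-2 non-soma vertex by a single concatenated edge."""
    edges = list(g.edges(w, keys=True, data=True))
    if len(edges) != 2:
        return
    (w0, a, k0, d0), (w1, b, k1, d1) = edges
    pa = _orient_to_end_at(d0["polyline"], g.nodes[w]["pixel"])
    pb = list(reversed(_orient_to_end_at(d1["polyline"], g.nodes[w]["pixel"])))
    merged = pa + pb[1:]
    length = d0["length_um"] + d1["length_um"]
    g.remove_node(w)
    g.add_edge(a, b, length_um=length, polyline=merged)


def prune_to_master(g: nx.MultiGraph,
                    min_branch_length_um: float) -> nx.MultiGraph:
    """Iteratively remove terminal twigs shorter than the threshold.

    The shortest qualifying terminal segment is removed first; a junction
    left with degree 2 is merged away (edge lengths summed), which can expose
    new removable twigs, so removal iterates to a fixed point.  Segments
    attached to the soma are never removed.  Threshold 0 is the identity.
    """
    if min_branch_length_um < 0:
        raise ValueError("min_branch_length_um must be >= 0")
    out = g.copy()
    while True:
        candidates = []
        for u, v, key, data in out.edges(keys=True, data=True):
            if u == SOMA or v == SOMA:
                continue
            leaf = None
            if out.degree(u) == 1:
                leaf = u
            elif out.degree(v) == 1:
                leaf = v
            if leaf is None:
                continue
            if data["length_um"] < min_branch_length_um:
                candidates.append((data["length_um"], sorted((u, v)), u, v,
                                   key, leaf))
        if not candidates:
            break
        candidates.sort(key=lambda t: (t[0], t[1]))
        _, _, u, v, key, leaf = candidates[0]
        keep = v if leaf == u else u
        out.remove_edge(u, v, key=key)
        out.remove_node(leaf)
        if keep != SOMA and out.degree(keep) == 2:
            _merge_degree_two(out, keep)
    return out


def prune_leaves_once(g: nx.MultiGraph) -> nx.MultiGraph:
    """Alternative pruning: remove every terminal segment exactly once."""
    out = g.copy()
    doomed = []
    for u, v, key in out.edges(keys=True):
        if u == SOMA or v == SOMA:
            continue
        if out.degree(u) == 1 or out.degree(v) == 1:
            doomed.append((u, v, key))
    leaves = set()
    for u, v, key in doomed:
        leaves.add(u if out.degree(u) == 1 else v)
        out.remove_edge(u, v, key=key)
    for leaf in leaves:
        if leaf in out and out.degree(leaf) == 0:
            out.remove_node(leaf)
    for w in [n for n in out.nodes if n != SOMA and out.degree(n) == 2]:
        _merge_degree_two(out, w)
    return out


def rasterize_graph(g: nx.MultiGraph, shape: tuple[int, int]) -> np.ndarray:
    """Paint every edge polyline back into a boolean skeleton image."""
    img = np.zeros(shape, dtype=bool)
    for _, _, data in g.edges(data=True):
        for p in data["polyline"]:
            img[p] = True
    return img


def write_swc(g: nx.MultiGraph, path, pixel_size_um: float,
              soma_center_px: tuple[float, float] | None = None) -> None:
    """Export the arbor as an SWC morphology file (type 3 = dendrite)."""
    lines = []
    idx = 0
    if soma_center_px is None:
        anchor_px = [data["polyline"][0]
                     for u, v, data in g.edges(data=True)
                     if SOMA in (u, v)]
        if anchor_px:
            soma_center_px = tuple(np.mean(anchor_px, axis=0))
        else:
            soma_center_px = (0.0, 0.0)
    idx += 1
    soma_idx = idx
    lines.append(f"{idx} 1 {soma_center_px[1] * pixel_size_um:.4f} "
                 f"{soma_center_px[0] * pixel_size_um:.4f} 0.0 1.0 -1")

    visited_edges = set()

    def emit(parent_idx: int, polyline: list[tuple[int, int]]) -> int:
        nonlocal idx
        last = parent_idx
        for r, c in polyline:
            idx += 1
            lines.append(f"{idx} 3 {c * pixel_size_um:.4f} "
                         f"{r * pixel_size_um:.4f} 0.0 0.2 {last}")
            last = idx
        return last

    def walk(node, parent_idx: int) -> None:
        for u, v, key, data in sorted(
            g.edges(node, keys=True, data=True),
            key=lambda e: (str(e[0]), str(e[1]), e[2]),
        ):
            ek = tuple(sorted((str(u), str(v)))) + (key,)
            if ek in visited_edges:
                continue
            visited_edges.add(ek)
            other = v if u == node else u
            poly = data["polyline"]
            if node != SOMA:
                if poly[0] != g.nodes[node].get("pixel"):
                    poly = list(reversed(poly))
            elif other != SOMA and poly[-1] != g.nodes[other].get("pixel"):
                poly = list(reversed(poly))
            last = emit(parent_idx, poly if node == SOMA else poly[1:])
            walk(other, last)

    walk(SOMA, soma_idx)
    with open(path, "w") as fh:
        fh.write("# SWC export\n")
        fh.write("\n".join(lines) + "\n")
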