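"""Skeletonization and the typed plant graph.

The binary plant mask is reduced to a one-pixel-wide skeleton, represented
as a graph P = {V, E} whose nodes are skeleton pixels of degree != 2 and
whose edges are the maximal degree-2 pixel chains between them. Short
boundary-noise branches (spurs, default threshold 10 px) are pruned and the
degree-2 nodes this leaves behind are collapsed, after which nodes are
typed:

* BASE — the bottom-most skeleton node (where the stem leaves the soil);
* TIP — remaining degree-1 nodes (free leaf ends);
* JUNCTION — degree >= 3 nodes (collars, where leaves meet the stem).

Edges with a TIP endpoint are leaves; junction-junction edges are
inter-junctions (the stem is the chain of these from the base); the edge
incident to the base is the base segment. Crossing leaves create cycles,
which classification refuses — occluded/crossed frames are reported as
unanalyzable rather than mis-measured.

Pixel geometry uses raster (row, col) coordinates; edge lengths count
diagonal steps as sqrt(2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from skimage.measure import label as sklabel
from skimage.morphology import skeletonize as _sk_skeletonize

from .errors import (
    EmptyInputError,
    InvalidArgumentError,
    UnsupportedTopologyError,
)

BASE = "BASE"
TIP = "TIP"
JUNCTION = "JUNCTION"
LEAF = "LEAF"
INTER_JUNCTION = "INTER_JUNCTION"
BASE_SEGMENT = "BASE_SEGMENT"

DEFAULT_SPUR_THRESHOLD = 10.0
_CLUSTER_TOL = 3.0  # junction-cluster consolidation scale, px

_NBRS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


@dataclass
class Skeleton:
    """One-pixel-wide skeleton raster."""

    mask: np.ndarray

    @property
    def pixels(self) -> set[tuple[int, int]]:
        return set(map(tuple, np.argwhere(self.mask)))


def _local_components(mask: np.ndarray, r: int, c: int) -> int:
    """8-connected components among the set neighbors of (r, c), excluding it."""
    nbrs = [
        (r + dr, c + dc)
        for dr, dc in _NBRS
        if 0 <= r + dr < mask.shape[0]
        and 0 <= c + dc < mask.shape[1]
        and mask[r + dr, c + dc]
    ]
    if not nbrs:
        return 0
    seen: set[tuple[int, int]] = set()
    comps = 0
    nbr_set = set(nbrs)
    for p in nbrs:
        if p in seen:
            continue
        comps += 1
        stack = [p]
        while stack:
            q = stack.pop()
            if q in seen:
                continue
            seen.add(q)
            for dr, dc in _NBRS:
                w = (q[0] + dr, q[1] + dc)
                if w in nbr_set and w not in seen:
                    stack.append(w)
    return comps


def _thin_to_unit_width(mask: np.ndarray) -> np.ndarray:
    """Remove redundant pixels so that no 2x2 block is fully set.

    A pixel inside a full 2x2 block is deleted when it is simple (its set
    neighbors stay 8-connected without it) and not an endpoint.
    """
    mask = mask.copy()
    for _ in range(64):
        full = (
            mask[:-1, :-1] & mask[:-1, 1:] & mask[1:, :-1] & mask[1:, 1:]
        )
        if not full.any():
            break
        changed = False
        for r, c in map(tuple, np.argwhere(full)):
            for dr, dc in ((0, 0), (0, 1), (1, 0), (1, 1)):
                rr, cc = r + dr, c + dc
                if not mask[rr, cc]:
                    continue
                count = sum(
                    1
                    for ddr, ddc in _NBRS
                    if 0 <= rr + ddr < mask.shape[0]
                    and 0 <= cc + ddc < mask.shape[1]
                    and mask[rr + ddr, cc + ddc]
                )
                if count > 1 and _local_components(mask, rr, cc) == 1:
                    mask[rr, cc] = False
                    changed = True
                    break
            if changed:
                break
        if not changed:
            break
    return mask


def skeletonize(mask: np.ndarray) -> Skeleton:
    """Reduce a single-component binary mask to a 1-px skeleton."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise EmptyInputError("cannot skeletonize an empty mask")
    n_comp = int(sklabel(mask, connectivity=2).max())
    if n_comp != 1:
        raise InvalidArgumentError(
            f"mask must have exactly one component, found {n_comp}"
        )
    sk = _sk_skeletonize(mask)
    sk = _thin_to_unit_width(sk)
    return Skeleton(mask=sk)


# ---------------------------------------------------------------------------
# Graph construction
# ---------------------------------------------------------------------------


class PlantGraph:
    """Typed skeleton graph P = {V, E} over pixel coordinates.

    Thin wrapper over a :class:`networkx.MultiGraph`. Node keys are
    ``(row, col)`` pixels; node attribute ``kind`` is one of BASE / TIP /
    JUNCTION once classified. Edge attributes: ``path`` (ordered pixel
    list), ``length`` (px, diagonal steps sqrt(2)) and ``kind``.
    """

    def __init__(self, g: nx.MultiGraph, typed: bool = False,
                 stroke_radius: float | None = None):
        self.g = g
        self.typed = typed
        #: median half-width (px) of the source mask along the skeleton;
        #: downstream fits use it to discount the junction mixing zone
        self.stroke_radius = stroke_radius

    # -- structural queries -------------------------------------------------

    @property
    def cyclic(self) -> bool:
        n_comp = nx.number_connected_components(self.g) if len(self.g) else 0
        return self.g.number_of_edges() > len(self.g) - n_comp

    @property
    def connected(self) -> bool:
        return len(self.g) > 0 and nx.is_connected(self.g)

    def nodes_of_kind(self, kind: str) -> list[tuple[int, int]]:
        return [n for n, d in self.g.nodes(data=True) if d.get("kind") == kind]

    def edges_of_kind(self, kind: str):
        return [
            (u, v, k, d)
            for u, v, k, d in self.g.edges(keys=True, data=True)
            if d.get("kind") == kind
        ]

    @property
    def base(self) -> tuple[int, int]:
        nodes = self.nodes_of_kind(BASE)
        if len(nodes) != 1:
            raise InvalidArgumentError("graph has no unique BASE; classify first")
        return nodes[0]

    def copy(self) -> "PlantGraph":
        return PlantGraph(self.g.copy(), typed=self.typed,
                          stroke_radius=self.stroke_radius)

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        nodes = [
            {"id": i, "position": list(map(int, n)),
             "degree": self.g.degree(n), "kind": d.get("kind")}
            for i, (n, d) in enumerate(sorted(self.g.nodes(data=True)))
        ]
        index = {tuple(n["position"]): n["id"] for n in nodes}
        edges = [
            {
                "endpoints": [index[u], index[v]],
                "length": d["length"],
                "kind": d.get("kind"),
                "leaf_rank": d.get("leaf_rank"),
                "path": [list(map(int, p)) for p in d["path"]],
            }
            for u, v, k, d in sorted(
                self.g.edges(keys=True, data=True),
                key=lambda e: (e[0], e[1], e[2]),
            )
        ]
        return {"nodes": nodes, "edges": edges}


def _step_length(a: tuple[int, int], b: tuple[int, int]) -> float:
    return math.sqrt(2.0) if (a[0] != b[0] and a[1] != b[1]) else 1.0


def _path_length(path: list[tuple[int, int]]) -> float:
    return sum(_step_length(a, b) for a, b in zip(path, path[1:]))


def _chain_neighbors(pix: set[tuple[int, int]]) -> dict:
    """8-neighborhood adjacency with redundant diagonal links dropped.

    A diagonal link between two skeleton pixels that also share a set
    4-neighbor is a shortcut across a staircase; keeping it would turn every
    staircase corner into a fake 3-cycle. Dropping it preserves
    connectivity (the 4-path through the shared neighbor remains).
    """
    nbrs = {}
    for p in pix:
        r, c = p
        out = []
        for dr, dc in _NBRS:
            q = (r + dr, c + dc)
            if q not in pix:
                continue
            if dr != 0 and dc != 0:
                if (r + dr, c) in pix or (r, c + dc) in pix:
                    continue
            out.append(q)
        nbrs[p] = out
    return nbrs


def graph_from_skeleton(skel: Skeleton) -> PlantGraph:
    """Raw pixel graph: nodes are degree != 2 pixels, edges degree-2 chains."""
    pix = skel.pixels
    if not pix:
        raise EmptyInputError("empty skeleton")
    nbrs = _chain_neighbors(pix)
    node_pixels = {p for p, ns in nbrs.items() if len(ns) != 2}
    if not node_pixels:  # closed loop: anchor one arbitrary deterministic node
        node_pixels = {min(pix)}
    g = nx.MultiGraph()
    for p in node_pixels:
        g.add_node(p, kind=None)
    visited: set[tuple[tuple[int, int], tuple[int, int]]] = set()
    for n in sorted(node_pixels):
        for q in sorted(nbrs[n]):
            if (n, q) in visited:
                continue
            path = [n, q]
            visited.add((n, q))
            visited.add((q, n))
            prev, cur = n, q
            while cur not in node_pixels:
                nxt_choices = [w for w in nbrs[cur] if w != prev]
                nxt = nxt_choices[0]
                visited.add((cur, nxt))
                visited.add((nxt, cur))
                path.append(nxt)
                prev, cur = cur, nxt
            g.add_edge(n, cur, path=path, length=_path_length(path), kind=None,
                       leaf_rank=None)
    return PlantGraph(g)


# ---------------------------------------------------------------------------
# Pruning
# ---------------------------------------------------------------------------


def _bottom_most_node(g: nx.MultiGraph) -> tuple[int, int]:
    return max(g.nodes, key=lambda n: (n[0], -n[1]))


def _oriented_path(d: dict, src, dst) -> list[tuple[int, int]]:
    path = d["path"]
    if path[0] == src and path[-1] == dst:
        return list(path)
    if path[0] == dst and path[-1] == src:
        return list(reversed(path))
    # endpoints were merged during contraction; orient by nearest end
    if _sq(path[0], src) <= _sq(path[-1], src):
        return list(path)
    return list(reversed(path))


def _sq(a, b) -> float:
    return (a[0] - b[0]) ** 2 + (a[1] - b[1]) ** 2


def prune_spurs(
    graph: PlantGraph,
    threshold: float = DEFAULT_SPUR_THRESHOLD,
    cluster_tol: float = _CLUSTER_TOL,
) -> PlantGraph:
    """Remove spurs, consolidate junction clusters, collapse degree-2 nodes.

    Iterated to fixpoint: removing one spur can expose another once the
    redundant degree-2 node it hung from is collapsed. The bottom-most node
    (the future base) is never removed as a spur endpoint.
    """
    g = graph.g.copy()
    while True:
        changed = False
        protected = _bottom_most_node(g)

        # 1. drop short tip-terminated edges
        for u, v, k, d in sorted(
            g.edges(keys=True, data=True), key=lambda e: (e[0], e[1], e[2])
        ):
            if not g.has_edge(u, v, k):
                continue
            if u == v:
                continue
            for tip_end, other in ((u, v), (v, u)):
                if (
                    g.degree(tip_end) == 1
                    and g.degree(other) > 1
                    and tip_end != protected
                    and d["length"] <= threshold
                ):
                    g.remove_edge(u, v, key=k)
                    g.remove_node(tip_end)
                    changed = True
                    break

        # 1b. dissolve pinhole loops: a tiny unresolved hole in the mask
        # makes the skeleton encircle it, which collapses to a short pair of
        # parallel edges (or a short self-loop). Keep the shorter branch.
        for u, v in sorted({(u, v) for u, v, _ in g.edges(keys=True)}):
            if not g.has_edge(u, v):
                continue
            if u == v:
                for k, d in sorted(dict(g[u][v]).items()):
                    if d["length"] <= 2 * threshold:
                        g.remove_edge(u, v, key=k)
                        changed = True
                continue
            dup = sorted(dict(g[u][v]).items(),
                         key=lambda kd: (kd[1]["length"], kd[0]))
            for k, d in dup[1:]:
                if d["length"] <= threshold:
                    g.remove_edge(u, v, key=k)
                    changed = True

        # 2. consolidate junction clusters (tiny junction-junction edges)
        for u, v, k, d in sorted(
            g.edges(keys=True, data=True), key=lambda e: (e[0], e[1], e[2])
        ):
            if not g.has_edge(u, v, k) or u == v:
                continue
            if g.degree(u) >= 3 and g.degree(v) >= 3 and d["length"] <= cluster_tol:
                keep, drop = (u, v)
                if (drop == protected) or (
                    keep != protected and (drop[0], -drop[1]) > (keep[0], -keep[1])
                ):
                    keep, drop = drop, keep
                bridge = _oriented_path(d, keep, drop)
                g.remove_edge(u, v, key=k)
                for _, w, k2, d2 in list(g.edges(drop, keys=True, data=True)):
                    tail = _oriented_path(d2, drop, w)
                    new_path = bridge + tail[1:]
                    g.add_edge(keep, w, path=new_path,
                               length=_path_length(new_path),
                               kind=None, leaf_rank=None)
                g.remove_node(drop)
                changed = True
                break  # edge view invalidated; restart pass

        # 3. collapse redundant degree-2 nodes
        for n in sorted(g.nodes):
            if n == protected or g.degree(n) != 2:
                continue
            inc = list(g.edges(n, keys=True, data=True))
            if len(inc) != 2:  # degree 2 via a self-loop: leave it
                continue
            (_, a, k1, d1), (_, b, k2, d2) = inc
            p1 = _oriented_path(d1, a, n)
            p2 = _oriented_path(d2, n, b)
            new_path = p1 + p2[1:]
            g.remove_edge(n, a, key=k1)
            g.remove_edge(n, b, key=k2)
            g.remove_node(n)
            g.add_edge(a, b, path=new_path, length=_path_length(new_path),
                       kind=None, leaf_rank=None)
            changed = True
            break

        if not changed:
            break
    return PlantGraph(g, stroke_radius=graph.stroke_radius)


# ---------------------------------------------------------------------------
# Classification and traversal
# ---------------------------------------------------------------------------


def classify(graph: PlantGraph) -> PlantGraph:
    """Assign node kinds (BASE/TIP/JUNCTION) and edge kinds.

    The base is the bottom-most node (maximal row; leftmost column on ties).
    Edges with a TIP endpoint are leaves; the base-incident edge is the base
    segment (stem) unless its far end is itself a tip (seedling case, which
    the tip rule classifies as a leaf); junction-junction edges are
    inter-junctions. Cyclic graphs (leaf crossover) are refused.
    """
    if graph.cyclic:
        raise UnsupportedTopologyError(
            "skeleton graph contains cycles (leaf crossover/self-occlusion)"
        )
    if not graph.connected:
        raise InvalidArgumentError("plant graph must be connected")
    pg = graph.copy()
    g = pg.g
    base = _bottom_most_node(g)
    for n in g.nodes:
        if n == base:
            g.nodes[n]["kind"] = BASE
        elif g.degree(n) == 1:
            g.nodes[n]["kind"] = TIP
        else:
            g.nodes[n]["kind"] = JUNCTION
    for u, v, k, d in g.edges(keys=True, data=True):
        kinds = {g.nodes[u]["kind"], g.nodes[v]["kind"]}
        if TIP in kinds:
            d["kind"] = LEAF
        elif BASE in kinds:
            d["kind"] = BASE_SEGMENT
        else:
            d["kind"] = INTER_JUNCTION
    pg.typed = True
    return pg


def count_leaves(graph: PlantGraph, seedling_counts_leaf: bool = True) -> int:
    """Number of LEAF edges.

    A pre-junction seedling is a single base-tip edge; the tip rule counts
    it as one leaf (the first visible blade), which ``seedling_counts_leaf``
    can disable.
    """
    if not graph.typed:
        raise InvalidArgumentError("classify the graph first")
    n = 0
    base = graph.base
    for u, v, k, d in graph.edges_of_kind(LEAF):
        if not seedling_counts_leaf and base in (u, v):
            continue
        n += 1
    return n


def leaf_tips(graph: PlantGraph) -> list[tuple[int, int]]:
    """(row, col) tip pixel of every LEAF edge, in :func:`leaf_edges` order."""
    return [rec["tip"] for rec in leaf_edges(graph)]


def leaf_edges(graph: PlantGraph) -> list[dict]:
    """Per-leaf records: junction/tip pixels and the junction->tip path.

    Ordered by junction row, bottom first (single-frame emergence-rank
    order). Each record: ``junction``, ``tip`` (row, col), ``path`` oriented
    junction -> tip, ``length`` and the edge ``key``.
    """
    g = graph.g
    records = []
    for u, v, k, d in graph.edges_of_kind(LEAF):
        tip = u if g.nodes[u]["kind"] == TIP else v
        junction = v if tip == u else u
        path = _oriented_path(d, junction, tip)
        records.append(
            {
                "junction": junction,
                "tip": tip,
                "path": path,
                "length": d["length"],
                "edge": (u, v, k),
                "leaf_rank": d.get("leaf_rank"),
            }
        )
    records.sort(key=lambda r: (-r["junction"][0], r["junction"][1]))
    for i, rec in enumerate(records):
        if rec["leaf_rank"] is None:
            rec["leaf_rank"] = i + 1
    return records


def extract_stem(graph: PlantGraph) -> tuple[list[tuple[int, int]], list[tuple[int, int]]]:
    """Ordered junction positions from the base upward, plus the stem path.

    Traverses BASE_SEGMENT / INTER_JUNCTION edges from the base. With no
    junctions (seedling), the stem is the base segment alone and the
    junction list is empty.
    """
    if not graph.typed:
        raise InvalidArgumentError("classify the graph first")
    g = graph.g
    base = graph.base
    stem_kinds = {BASE_SEGMENT, INTER_JUNCTION}
    junctions: list[tuple[int, int]] = []
    path: list[tuple[int, int]] = [base]
    cur = base
    prev = None
    while True:
        options = [
            (w, k, d)
            for _, w, k, d in g.edges(cur, keys=True, data=True)
            if d["kind"] in stem_kinds and w != prev
        ]
        if not options:
            break
        # stem continues upward: prefer the branch whose far node is highest
        options.sort(key=lambda o: o[0][0])
        w, k, d = options[0]
        path.extend(_oriented_path(d, cur, w)[1:])
        prev, cur = cur, w
        if g.nodes[cur]["kind"] == JUNCTION:
            junctions.append(cur)
        if g.degree(cur) == 1:
            break
    if not junctions and path == [base]:
        # seedling: the only edge is the tip-terminated base segment
        inc = list(g.edges(base, keys=True, data=True))
        if inc:
            _, w, k, d = inc[0]
            path = _oriented_path(d, base, w)
    return junctions, path


# ---------------------------------------------------------------------------
# Temporal leaf tracking
# ---------------------------------------------------------------------------


def track_emergence(
    graphs: list[tuple[int, PlantGraph]],
    radius: float = 20.0,
) -> pd.DataFrame:
    """Match leaves across a chronological per-day graph sequence.

    Leaves are matched day-to-day greedily by junction proximity (falling
    back on tip proximity, which is more stable while a leaf is still the
    topmost and its junction estimate shifts); the first day a leaf appears
    fixes its emergence rank, ties broken by lower junction first. A leaf
    absent on one day keeps its rank and is flagged missing.
    """
    known: list[dict] = []  # rank, junction, tip, first_day
    rows = []
    for day, graph in sorted(graphs, key=lambda t: t[0]):
        dets = leaf_edges(graph)
        cand = []
        for i, det in enumerate(dets):
            for j, kn in enumerate(known):
                dj = math.dist(det["junction"], kn["junction"])
                dt = math.dist(det["tip"], kn["tip"])
                cost = min(dj, dt)
                if cost <= radius:
                    # ties (two leaves sharing a junction estimate while the
                    # whorl top is unresolved) break on tip proximity
                    cand.append((cost, dt, i, j))
        cand.sort()
        det_match: dict[int, int] = {}
        used_known: set[int] = set()
        for cost, _, i, j in cand:
            if i in det_match or j in used_known:
                continue
            det_match[i] = j
            used_known.add(j)
        # new leaves, bottom-most junction first
        new_idx = [i for i in range(len(dets)) if i not in det_match]
        new_idx.sort(key=lambda i: (-dets[i]["junction"][0], dets[i]["junction"][1]))
        for i in new_idx:
            known.append(
                {
                    "rank": len(known) + 1,
                    "junction": dets[i]["junction"],
                    "tip": dets[i]["tip"],
                    "first_day": day,
                }
            )
            det_match[i] = len(known) - 1
            used_known.add(len(known) - 1)
        for i, det in enumerate(dets):
            kn = known[det_match[i]]
            kn["junction"] = det["junction"]
            kn["tip"] = det["tip"]
            det["leaf_rank"] = kn["rank"]
            rows.append(
                {
                    "day": day,
                    "leaf_rank": kn["rank"],
                    "junction_row": det["junction"][0],
                    "junction_col": det["junction"][1],
                    "tip_row": det["tip"][0],
                    "tip_col": det["tip"][1],
                    "length_px": det["length"],
                    "first_day": kn["first_day"],
                    "missing": False,
                }
            )
        for j, kn in enumerate(known):
            if j not in used_known:
                rows.append(
                    {
                        "day": day,
                        "leaf_rank": kn["rank"],
                        "junction_row": kn["junction"][0],
                        "junction_col": kn["junction"][1],
                        "tip_row": kn["tip"][0],
                        "tip_col": kn["tip"][1],
                        "length_px": np.nan,
                        "first_day": kn["first_day"],
                        "missing": True,
                    }
                )
    return pd.DataFrame(
        rows,
        columns=[
            "day", "leaf_rank", "junction_row", "junction_col",
            "tip_row", "tip_col", "length_px", "first_day", "missing",
        ],
    )


def mask_to_graph(
    mask: np.ndarray,
    spur_threshold: float = DEFAULT_SPUR_THRESHOLD,
) -> PlantGraph:
    """Convenience composition: skeletonize -> graph -> prune -> classify.

    Also estimates the mask's stroke half-width (median Euclidean distance
    transform along the skeleton) and stores it on the graph for downstream
    junction-zone handling in the leaf fits.
    """
    from scipy.ndimage import distance_transform_edt

    skel = skeletonize(mask)
    raw = graph_from_skeleton(skel)
    pruned = prune_spurs(raw, threshold=spur_threshold)
    typed = classify(pruned)
    edt = distance_transform_edt(np.asarray(mask, dtype=bool))
    typed.stroke_radius = float(np.median(edt[skel.mask]))
    return typed
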