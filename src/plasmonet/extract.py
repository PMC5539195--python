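"""Extract a region-region network from a finished simulation.

The trail (or particle occupancy) image is binarized, thinned to a
one-pixel skeleton, and converted into a graph whose nodes are region
sites (captured onto the nearest skeleton pixel) and Steiner nodes
(junction pixel clusters). Regions joined by a path whose interior runs
only through Steiner nodes count as directly connected, which yields the
per-replicate region adjacency matrix.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np
from scipy.ndimage import label as cc_label
from scipy.ndimage import uniform_filter
from skimage.morphology import skeletonize as _sk_skeletonize

from .arena import Arena, RegionSite
from .sim import SimState, occupancy

__all__ = [
    "ExtractConfig",
    "SkeletonGraph",
    "AdjacencyRecord",
    "binarize_trails",
    "smooth_occupancy",
    "skeletonize",
    "build_skeleton_graph",
    "region_adjacency",
    "extract_network",
]

_EIGHT = np.ones((3, 3), dtype=np.int64)


@dataclass(frozen=True)
class ExtractConfig:
    """Digitization choices for turning simulator output into a graph.

    ``source`` selects the binarization input: "trail" (the chemoattractant
    field; default — it is smooth, and nutrient stimuli guarantee the site
    cells sit inside the digitized material) or "occupancy" (particle
    presence smoothed with the diffusion kernel). ``tau`` is the
    binarization threshold; when None it defaults to deposit/2 for trail
    and 0.2 for occupancy. ``strict_steiner`` restricts Steiner
    transparency to a single interior junction.
    """

    source: str = "trail"
    tau: float | None = None
    smooth_kernel: int = 3
    capture_radius: float = 5.0
    strict_steiner: bool = False
    deposit: float = 5.0

    def threshold(self) -> float:
        if self.tau is not None:
            return self.tau
        return 0.2 if self.source == "occupancy" else self.deposit / 2.0


@dataclass
class SkeletonGraph:
    """Thinned trail network with region and Steiner nodes.

    ``graph`` is an undirected networkx graph; node attributes are
    ``kind`` ("region" | "steiner"), ``cell`` (row, col) and, for region
    nodes, ``region_id``; edges carry ``length`` in cells.
    """

    graph: nx.Graph

    def region_nodes(self) -> list:
        return [n for n, d in self.graph.nodes(data=True) if d["kind"] == "region"]

    def steiner_nodes(self) -> list:
        return [n for n, d in self.graph.nodes(data=True) if d["kind"] == "steiner"]

    def region_ids(self) -> list[int]:
        return sorted(self.graph.nodes[n]["region_id"] for n in self.region_nodes())

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t")
            w.writerow(["node_a", "node_b", "length_cells"])
            for a, b, d in sorted(self.graph.edges(data=True), key=lambda e: (str(e[0]), str(e[1]))):
                w.writerow([a, b, f"{d['length']:.3f}"])

    def write_graphml(self, path: str | Path) -> None:
        g = nx.Graph()
        for n, d in self.graph.nodes(data=True):
            g.add_node(str(n), kind=d["kind"], row=int(d["cell"][0]), col=int(d["cell"][1]),
                       region_id=int(d.get("region_id", -1)))
        for a, b, d in self.graph.edges(data=True):
            g.add_edge(str(a), str(b), length=float(d["length"]))
        nx.write_graphml(g, path)


@dataclass
class AdjacencyRecord:
    """Symmetric boolean region x region adjacency for one replicate."""

    replicate_id: str
    region_ids: tuple
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=bool)
        k = len(self.region_ids)
        if m.shape != (k, k):
            raise ValueError(f"matrix shape {m.shape} != ({k}, {k})")
        if not np.array_equal(m, m.T):
            raise ValueError("adjacency matrix must be symmetric")
        if m.diagonal().any():
            raise ValueError("adjacency matrix must have a zero diagonal")
        self.matrix = m
        self.region_ids = tuple(self.region_ids)

    def edges(self) -> set[frozenset]:
        out = set()
        idx = np.argwhere(np.triu(self.matrix, k=1))
        for i, j in idx:
            out.add(frozenset((self.region_ids[i], self.region_ids[j])))
        return out

    def degree(self, region) -> int:
        return int(self.matrix[self.region_ids.index(region)].sum())

    def write_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["region_id", *self.region_ids])
            for rid, row in zip(self.region_ids, self.matrix.astype(int)):
                w.writerow([rid, *row.tolist()])

    @classmethod
    def read_csv(cls, path: str | Path, replicate_id: str | None = None) -> "AdjacencyRecord":
        with open(path, newline="") as fh:
            rows = [r for r in csv.reader(fh) if r]
        header = rows[0][1:]

        def parse(x: str):
            try:
                return int(x)
            except ValueError:
                return x

        ids = tuple(parse(h) for h in header)
        mat = np.array([[int(v) for v in r[1:]] for r in rows[1:]], dtype=bool)
        return cls(replicate_id or Path(path).stem, ids, mat)


def binarize_trails(field: np.ndarray, tau: float) -> np.ndarray:
    """Cells with value strictly above ``tau``."""
    if tau < 0:
        raise ValueError(f"tau must be >= 0, got {tau}")
    return np.asarray(field) > tau


def smooth_occupancy(occ: np.ndarray, kernel: int = 3) -> np.ndarray:
    """In-bounds mean filter of a 0/1 occupancy grid (values in [0, 1])."""
    occf = np.asarray(occ, dtype=np.float64)
    sums = uniform_filter(occf, size=kernel, mode="constant") * kernel * kernel
    ones = np.ones_like(occf)
    counts = np.rint(uniform_filter(ones, size=kernel, mode="constant") * kernel * kernel)
    return sums / counts


def skeletonize(mask: np.ndarray) -> np.ndarray:
    """Thin a binary mask to a one-pixel-wide skeleton (Zhang-Suen family,
    8-connectivity); connected-component count is preserved."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return np.zeros_like(mask)
    return _sk_skeletonize(mask)


def _neighbor_counts(skel: np.ndarray) -> np.ndarray:
    from scipy.ndimage import convolve

    k = _EIGHT.copy()
    k[1, 1] = 0
    return convolve(skel.astype(np.int64), k, mode="constant")


_NBRS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def build_skeleton_graph(
    skeleton: np.ndarray,
    sites: Sequence[RegionSite],
    capture_radius: float = 5.0,
    mask: np.ndarray | None = None,
) -> SkeletonGraph:
    """Resolve a skeleton mask into region nodes, Steiner nodes and edges.

    Each site captures the nearest skeleton pixel within
    ``capture_radius`` (Euclidean); sites with none become isolated region
    nodes. When the pre-thinning binary ``mask`` is supplied, a site lying
    inside the material instead captures the nearest skeleton pixel of its
    own mask component — the thinned centerline of a wide lane can sit
    farther than any fixed radius, but it is still the lane the site is
    embedded in. Junction pixels (>= 3 skeleton neighbours) are merged by
    8-connected flood fill into Steiner nodes. Edges follow skeleton
    chains between nodes; skeleton components holding no region node are
    discarded, dangling spurs are dropped, and Steiner nodes are spliced
    or pruned until every remaining one has degree >= 3.
    """
    if capture_radius < 0:
        raise ValueError(f"capture_radius must be >= 0, got {capture_radius}")
    skel = np.asarray(skeleton, dtype=bool)
    g = nx.Graph()

    # anchor each site to its nearest skeleton pixel
    sk_pts = np.argwhere(skel)
    captured: dict[int, tuple[int, int]] = {}
    mask_lab = None
    if mask is not None:
        mask_lab, _ = cc_label(np.asarray(mask, dtype=bool), structure=_EIGHT)
    for s in sites:
        g.add_node(f"region:{s.region_id}", kind="region", region_id=s.region_id,
                   cell=(s.row, s.col), name=s.name)
        if sk_pts.size == 0:
            continue
        cand = sk_pts
        in_material = mask_lab is not None and mask_lab[s.row, s.col] > 0
        if in_material:
            same = mask_lab[sk_pts[:, 0], sk_pts[:, 1]] == mask_lab[s.row, s.col]
            if same.any():
                cand = sk_pts[same]
            else:
                in_material = False
        d2 = (cand[:, 0] - s.row) ** 2 + (cand[:, 1] - s.col) ** 2
        j = int(np.argmin(d2))
        if in_material or d2[j] <= capture_radius ** 2:
            cell = (int(cand[j, 0]), int(cand[j, 1]))
            captured[s.region_id] = cell
    if sk_pts.size == 0:
        return SkeletonGraph(g)

    # keep only skeleton components containing a region anchor
    comp, _ = cc_label(skel, structure=_EIGHT)
    keep_labels = {comp[r, c] for (r, c) in captured.values()}
    skel = skel & np.isin(comp, sorted(keep_labels))

    # node id per pixel: junction clusters and region anchors
    node_of: dict[tuple[int, int], str] = {}
    ncnt = _neighbor_counts(skel)
    junction = skel & (ncnt >= 3)
    jlab, nj = cc_label(junction, structure=_EIGHT)
    cluster_node: dict[int, str] = {}
    # region anchors take priority over (and absorb) their junction cluster
    for rid, cell in sorted(captured.items()):
        if not skel[cell]:
            continue  # component was discarded (cannot happen: kept by construction)
        nid = f"region:{rid}"
        lab = jlab[cell]
        if lab > 0 and lab not in cluster_node:
            cluster_node[lab] = nid
        node_of[cell] = nid
    for lab in range(1, nj + 1):
        pts = [tuple(p) for p in np.argwhere(jlab == lab)]
        if lab in cluster_node:
            nid = cluster_node[lab]
        else:
            nid = f"steiner:{lab}"
            centroid = np.mean(pts, axis=0)
            d2 = [(p[0] - centroid[0]) ** 2 + (p[1] - centroid[1]) ** 2 for p in pts]
            g.add_node(nid, kind="steiner", cell=pts[int(np.argmin(d2))])
        for p in pts:
            node_of.setdefault(p, nid)

    # trace chains between node pixels
    def trace(start: tuple[int, int], first: tuple[int, int]):
        length = float(np.hypot(first[0] - start[0], first[1] - start[1]))
        prev, cur = start, first
        while cur not in node_of:
            nxts = []
            for dr, dc in _NBRS:
                q = (cur[0] + dr, cur[1] + dc)
                if q == prev:
                    continue
                if 0 <= q[0] < skel.shape[0] and 0 <= q[1] < skel.shape[1] and skel[q]:
                    # avoid stepping diagonally across the pixel we came from
                    nxts.append(q)
            if not nxts:
                return None, length  # dangling spur
            # prefer 4-connected continuation to keep chains single-file
            nxts.sort(key=lambda q: (abs(q[0] - cur[0]) + abs(q[1] - cur[1])))
            nq = nxts[0]
            length += float(np.hypot(nq[0] - cur[0], nq[1] - cur[1]))
            prev, cur = cur, nq
        return node_of[cur], length

    for cell, nid in list(node_of.items()):
        for dr, dc in _NBRS:
            q = (cell[0] + dr, cell[1] + dc)
            if not (0 <= q[0] < skel.shape[0] and 0 <= q[1] < skel.shape[1]) or not skel[q]:
                continue
            if q in node_of:
                other = node_of[q]
                if other != nid:
                    L = float(np.hypot(dr, dc))
                    if not g.has_edge(nid, other) or g[nid][other]["length"] > L:
                        g.add_edge(nid, other, length=L)
                continue
            end, L = trace(cell, q)
            if end is None or end == nid:
                continue
            if not g.has_edge(nid, end) or g[nid][end]["length"] > L:
                g.add_edge(nid, end, length=L)

    _enforce_steiner_degree(g)
    return SkeletonGraph(g)


def _enforce_steiner_degree(g: nx.Graph) -> None:
    """Prune degree<=1 Steiner nodes and splice out degree-2 ones so every
    surviving Steiner node is a genuine junction (degree >= 3)."""
    changed = True
    while changed:
        changed = False
        for n in list(g.nodes):
            if g.nodes[n]["kind"] != "steiner":
                continue
            deg = g.degree(n)
            if deg <= 1:
                g.remove_node(n)
                changed = True
            elif deg == 2:
                (a, da), (b, db) = [(m, g[n][m]["length"]) for m in g.neighbors(n)]
                g.remove_node(n)
                if a != b:
                    L = da + db
                    if not g.has_edge(a, b) or g[a][b]["length"] > L:
                        g.add_edge(a, b, length=L)
                changed = True


def region_adjacency(sg: SkeletonGraph, strict: bool = False) -> AdjacencyRecord:
    """Region adjacency under Steiner transparency.

    Regions a and b are adjacent iff some path joins them whose interior
    nodes are all Steiner nodes (an intermediate region node blocks the
    connection). With ``strict=True`` at most one interior Steiner node is
    allowed, matching the single-junction reading of the rule.
    """
    g = sg.graph
    regions = sorted(sg.region_nodes(), key=lambda n: g.nodes[n]["region_id"])
    ids = tuple(g.nodes[n]["region_id"] for n in regions)
    k = len(regions)
    mat = np.zeros((k, k), dtype=bool)
    for i, rn in enumerate(regions):
        if strict:
            reach = set(g.neighbors(rn))
            for m in list(g.neighbors(rn)):
                if g.nodes[m]["kind"] == "steiner":
                    reach.update(g.neighbors(m))
        else:
            # BFS expanding only through Steiner nodes
            reach = set()
            frontier = [rn]
            seen = {rn}
            while frontier:
                nxt = []
                for u in frontier:
                    for v in g.neighbors(u):
                        if v in seen:
                            continue
                        seen.add(v)
                        reach.add(v)
                        if g.nodes[v]["kind"] == "steiner":
                            nxt.append(v)
                frontier = nxt
        for j, rm in enumerate(regions):
            if j != i and rm in reach:
                mat[i, j] = True
    mat |= mat.T
    return AdjacencyRecord("skeleton", ids, mat)


def extract_network(
    state: SimState,
    arena: Arena,
    cfg: ExtractConfig = ExtractConfig(),
) -> tuple[SkeletonGraph, AdjacencyRecord]:
    """Full pipeline: binarize -> skeletonize -> graph -> adjacency."""
    if cfg.source == "occupancy":
        field = smooth_occupancy(occupancy(state), cfg.smooth_kernel)
    elif cfg.source == "trail":
        field = state.trail
    else:
        raise ValueError(f"unknown binarization source {cfg.source!r}")
    mask = binarize_trails(field, cfg.threshold())
    skel = skeletonize(mask)
    sg = build_skeleton_graph(skel, arena.sites, cfg.capture_radius, mask=mask)
    rec = region_adjacency(sg, strict=cfg.strict_steiner)
    return sg, rec
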