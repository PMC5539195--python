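"""Weighted "Physarum graph" statistics over replicate experiments.

A Physarum graph P = (C, R, p) collects the regions C, every region-region
edge R observed in at least one replicate, and the per-edge observation
frequency p(e) = count / N over N replicates (e.g. p = 3/13 when an edge
appeared in 3 of 13 experiments). Thresholding at frequency theta keeps
T(R) = {e : p(e) >= theta}; sweeping theta reveals how the consensus
network disconnects. Edge probabilities and thresholds are exact
rationals, so p(e) >= theta never suffers float-equality hazards.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

from .extract import AdjacencyRecord

__all__ = [
    "PhysarumGraph",
    "ThresholdGraph",
    "ConnectivityReport",
    "edge_probability",
    "build_physarum_graph",
    "threshold_graph",
    "weight_sweep",
    "connectivity_report",
    "is_planar",
    "edge_count_stats",
    "mean_degree_table",
    "edge_incidence_weights",
]


def edge_probability(count: int, n_replicates: int) -> Fraction:
    """Observation frequency of an edge as an exact rational.

    ``count`` observations over ``n_replicates`` experiments give
    p = count/n_replicates (``float(p)`` for the decimal view).
    """
    if n_replicates < 1:
        raise ValueError(f"n_replicates must be >= 1, got {n_replicates}")
    if not 0 <= count <= n_replicates:
        raise ValueError(f"count {count} outside [0, {n_replicates}]")
    return Fraction(count, n_replicates)


@dataclass(frozen=True)
class PhysarumGraph:
    """P = (C, R, p): regions, observed edges, and edge frequencies."""

    regions: tuple
    counts: Mapping[frozenset, int]
    n_replicates: int

    @property
    def edges(self) -> set[frozenset]:
        return set(self.counts)

    def p(self, a, b) -> Fraction:
        return edge_probability(self.counts.get(frozenset((a, b)), 0), self.n_replicates)

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.regions)
        for e, k in self.counts.items():
            a, b = sorted(e, key=str)
            g.add_edge(a, b, count=k, p=float(Fraction(k, self.n_replicates)))
        return g


def build_physarum_graph(records: Sequence[AdjacencyRecord]) -> PhysarumGraph:
    """Aggregate replicate adjacency records into a Physarum graph.

    Every record must cover the same region set; an edge enters R iff it
    was observed at least once, with p = count / N.
    """
    if not records:
        raise ValueError("need at least one replicate record")
    region_set = set(records[0].region_ids)
    for r in records[1:]:
        if set(r.region_ids) != region_set:
            raise ValueError(
                f"replicate {r.replicate_id}: region set differs from the first record"
            )
    counts: dict[frozenset, int] = {}
    for r in records:
        for e in r.edges():
            counts[e] = counts.get(e, 0) + 1
    regions = tuple(sorted(region_set, key=str))
    return PhysarumGraph(regions, counts, len(records))


def _as_theta(theta, n_replicates: int) -> Fraction:
    """Accept theta as an exact Fraction, a "k/N" string, an integer count,
    or a float (floats are converted exactly; prefer counts or strings)."""
    if isinstance(theta, Fraction):
        return theta
    if isinstance(theta, str):
        if "/" in theta:
            num, den = theta.split("/")
            return Fraction(int(num), int(den))
        return Fraction(theta)
    if isinstance(theta, (int, np.integer)):
        return Fraction(int(theta), n_replicates)
    return Fraction(float(theta))


@dataclass(frozen=True)
class ThresholdGraph:
    """Threshold transform T(R) = {e : p(e) >= theta} of a Physarum graph."""

    parent: PhysarumGraph
    theta: Fraction
    retained: frozenset

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.parent.regions)
        for e in self.retained:
            a, b = sorted(e, key=str)
            g.add_edge(a, b, count=self.parent.counts[e])
        return g


def threshold_graph(P: PhysarumGraph, theta) -> ThresholdGraph:
    """Keep exactly the edges with p(e) >= theta (rational comparison).

    ``theta`` may be a Fraction, a "k/N" string, an integer count k
    (meaning k/N), or a float.
    """
    th = _as_theta(theta, P.n_replicates)
    kept = frozenset(
        e for e, k in P.counts.items() if Fraction(k, P.n_replicates) >= th
    )
    return ThresholdGraph(P, th, kept)


def weight_sweep(
    records: Sequence[AdjacencyRecord] | PhysarumGraph,
    weights: Iterable[int] | None = None,
) -> dict[int, ThresholdGraph]:
    """Graphs of edges observed in >= w replicates, for each integer w.

    Identical to ``threshold_graph`` at theta = w/N; defaults to the full
    sweep w = 1..N.
    """
    P = records if isinstance(records, PhysarumGraph) else build_physarum_graph(records)
    ws = list(weights) if weights is not None else list(range(1, P.n_replicates + 1))
    out: dict[int, ThresholdGraph] = {}
    for w in ws:
        if not 1 <= w <= P.n_replicates:
            raise ValueError(f"w must be in [1, {P.n_replicates}], got {w}")
        out[w] = threshold_graph(P, Fraction(w, P.n_replicates))
    return out


@dataclass(frozen=True)
class ConnectivityReport:
    """Components, isolated nodes, planarity and degrees of one graph."""

    components: tuple
    isolated: tuple
    planar: bool
    degrees: Mapping

    def to_dict(self) -> dict:
        return {
            "components": [list(c) for c in self.components],
            "isolated": list(self.isolated),
            "planar": self.planar,
            "degrees": {str(k): int(v) for k, v in self.degrees.items()},
        }


def _as_graph(G) -> nx.Graph:
    if isinstance(G, ThresholdGraph):
        return G.graph()
    if isinstance(G, PhysarumGraph):
        return G.graph()
    return G


def connectivity_report(G) -> ConnectivityReport:
    """Connected components (singletons included), isolated nodes,
    exact planarity, and per-node degree."""
    g = _as_graph(G)
    comps = tuple(
        tuple(sorted(c, key=str)) for c in sorted(
            nx.connected_components(g), key=lambda c: (-len(c), str(sorted(c, key=str)))
        )
    )
    isolated = tuple(sorted((n for n in g.nodes if g.degree(n) == 0), key=str))
    return ConnectivityReport(
        components=comps,
        isolated=isolated,
        planar=is_planar(g),
        degrees=dict(g.degree()),
    )


def is_planar(G) -> bool:
    """Exact planarity via the left-right certificate algorithm."""
    ok, _ = nx.check_planarity(_as_graph(G))
    return ok


def edge_count_stats(
    records: Sequence[AdjacencyRecord],
) -> tuple[float, float, dict[int, float]]:
    """Per-replicate edge-count mean, sample SD (n-1), and a relative-
    frequency histogram (bin masses sum to 1)."""
    if len(records) < 2:
        raise ValueError("need >= 2 replicates for a sample SD")
    counts = np.array([len(r.edges()) for r in records], dtype=np.float64)
    mean = float(counts.mean())
    sd = float(counts.std(ddof=1))
    vals, freq = np.unique(counts.astype(int), return_counts=True)
    hist = {int(v): float(f) / len(records) for v, f in zip(vals, freq)}
    return mean, sd, hist


def mean_degree_table(
    records: Sequence[AdjacencyRecord],
    names: Mapping | None = None,
):
    """Per-region mean degree over replicates, ranked descending.

    Ties break by region label (ascending). Returns a pandas DataFrame
    with columns ``region``, ``name`` (when provided) and ``mean_degree``.
    """
    import pandas as pd

    if not records:
        raise ValueError("need at least one replicate record")
    P = build_physarum_graph(records)
    rows = []
    for region in P.regions:
        md = float(np.mean([r.degree(region) for r in records]))
        rows.append({"region": region, "mean_degree": md})
    df = pd.DataFrame(rows)
    if names:
        df.insert(1, "name", df["region"].map(lambda r: names.get(r, str(r))))
    df = df.sort_values(
        ["mean_degree", "region"], ascending=[False, True],
        key=lambda s: s.map(str) if s.name == "region" else s,
    ).reset_index(drop=True)
    df.index = df.index + 1
    df.index.name = "rank"
    return df


def edge_incidence_weights(records: Sequence[AdjacencyRecord]) -> dict[frozenset, int]:
    """Per-edge observation counts (for width-proportional rendering);
    unobserved pairs are absent."""
    return dict(build_physarum_graph(records).counts)
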