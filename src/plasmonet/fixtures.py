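"""Packaged, seedable inputs for offline testing and demos.

The 13-replicate edge-observation table here is SYNTHETIC: the raw
laboratory adjacency sets behind the published threshold analysis were
never released, so this table is constructed purely from the qualitative
threshold-transition constraints that analysis reports (planarity onset,
node isolations, the three-triad split, the last-surviving edge) and is
validated against every constraint at build time. It exercises the
threshold/connectivity code path; it is not laboratory data.

The ridge and triangle arenas are scaled-down terrains for simulator
experiments: a two-site arena split by a Gaussian ridge with low
corridors around its ends, and a flat three-site arena.
"""

from __future__ import annotations

from functools import lru_cache

import networkx as nx
import numpy as np

from .arena import Arena, RegionSite, make_arena, synth_heightfield
from .extract import AdjacencyRecord

__all__ = [
    "REGIONS",
    "N_REPLICATES",
    "FixtureError",
    "synthetic_edge_counts",
    "synthetic_replicates",
    "ridge_arena",
    "triangle_arena",
]

#: The 17 urban-centre labels (region_id, name) of the Balkans use case.
REGIONS: tuple[tuple[int, str], ...] = (
    (1, "Thessaloniki"),
    (2, "Philippoi"),
    (3, "Nicopolis"),
    (4, "Scupi"),
    (5, "Traianoupolis"),
    (6, "Dyrrachium"),
    (7, "Heraclea"),
    (8, "Constantinople"),
    (9, "Marcianopolis"),
    (10, "Serdica"),
    (11, "Sirmium"),
    (12, "Doclea"),
    (13, "Remesiana"),
    (14, "Hadrianopolis"),
    (15, "Philippopolis"),
    (16, "Singidunum"),
    (17, "Tomis"),
)

N_REPLICATES = 13

# Edge observation counts (out of 13), constructed to satisfy the
# threshold-transition constraints; see synthetic_replicates docstring.
_BACKBONE: tuple[tuple[str, str, int], ...] = (
    ("Thessaloniki", "Scupi", 9),
    ("Thessaloniki", "Philippoi", 7),
    ("Doclea", "Dyrrachium", 8),
    ("Dyrrachium", "Nicopolis", 7),
    ("Remesiana", "Serdica", 8),
    ("Serdica", "Philippopolis", 7),
    ("Traianoupolis", "Hadrianopolis", 10),
    ("Philippoi", "Traianoupolis", 6),
    ("Hadrianopolis", "Constantinople", 6),
    ("Philippopolis", "Hadrianopolis", 6),
    ("Scupi", "Remesiana", 6),
    ("Marcianopolis", "Constantinople", 5),
    ("Marcianopolis", "Tomis", 3),
    ("Sirmium", "Singidunum", 5),
    ("Remesiana", "Singidunum", 3),
    ("Doclea", "Sirmium", 3),
    ("Scupi", "Heraclea", 5),
    ("Heraclea", "Dyrrachium", 5),
    ("Nicopolis", "Heraclea", 4),
)

# A K5 among once-observed edges keeps the full union graph non-planar
# until the count-1 noise edges are thresholded away.
_K5_NODES = ("Thessaloniki", "Traianoupolis", "Serdica", "Sirmium", "Tomis")

_TRIADS = (
    frozenset({"Doclea", "Dyrrachium", "Nicopolis"}),
    frozenset({"Remesiana", "Serdica", "Philippopolis"}),
    frozenset({"Scupi", "Thessaloniki", "Philippoi"}),
)


class FixtureError(AssertionError):
    """A packaged fixture failed its build-time constraint validation."""


def synthetic_edge_counts() -> dict[frozenset, int]:
    """Edge -> observation count (of 13) for the synthetic replicate table."""
    counts: dict[frozenset, int] = {}
    for a, b, k in _BACKBONE:
        counts[frozenset((a, b))] = k
    for i, a in enumerate(_K5_NODES):
        for b in _K5_NODES[i + 1:]:
            e = frozenset((a, b))
            if e not in counts:
                counts[e] = 1
    return counts


def _validate(counts: dict[frozenset, int]) -> None:
    names = [n for _, n in REGIONS]

    def graph_at(w: int) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(names)
        g.add_edges_from(tuple(e) for e, k in counts.items() if k >= w)
        return g

    # Tomis: max incident count is exactly 3
    tomis_max = max(k for e, k in counts.items() if "Tomis" in e)
    if tomis_max != 3:
        raise FixtureError(f"Tomis max incident count {tomis_max} != 3")
    # Sirmium-Singidunum cut: every edge leaving the pair has count <= 3,
    # with at least one equal to 3 (attached at theta = 3/13)
    pair = {"Sirmium", "Singidunum"}
    cut = [k for e, k in counts.items() if len(e & pair) == 1]
    if max(cut) != 3:
        raise FixtureError(f"Sirmium-Singidunum cut max {max(cut)} != 3")
    # last survivor
    top = {e for e, k in counts.items() if k >= 10}
    if top != {frozenset({"Traianoupolis", "Hadrianopolis"})}:
        raise FixtureError(f"edges with count >= 10: {top}")
    # connected at theta = 3/13, Tomis and the pair split off just above it
    if not nx.is_connected(graph_at(3)):
        raise FixtureError("union graph at count 3 is not connected")
    g4 = graph_at(4)
    comps4 = [frozenset(c) for c in nx.connected_components(g4)]
    if frozenset({"Tomis"}) not in comps4 or frozenset(pair) not in comps4:
        raise FixtureError(f"components at count 4: {comps4}")
    # three triads at theta = 7/13 (plus the surviving top pair and isolates)
    g7 = graph_at(7)
    comps7 = {frozenset(c) for c in nx.connected_components(g7) if len(c) >= 3}
    if comps7 != set(_TRIADS):
        raise FixtureError(f"size>=3 components at count 7: {comps7}")
    big7 = {frozenset(c) for c in nx.connected_components(g7) if len(c) == 2}
    if big7 != {frozenset({"Traianoupolis", "Hadrianopolis"})}:
        raise FixtureError(f"pairs at count 7: {big7}")
    # planar from count 2, non-planar with the count-1 edges included
    if not nx.check_planarity(graph_at(2))[0]:
        raise FixtureError("count>=2 graph is not planar")
    if nx.check_planarity(graph_at(1))[0]:
        raise FixtureError("count>=1 graph is unexpectedly planar")
    # the four peripheral nodes are all isolated by theta = 6/13
    g6 = graph_at(6)
    for n in ("Tomis", "Marcianopolis", "Sirmium", "Singidunum"):
        if g6.degree(n) != 0:
            raise FixtureError(f"{n} not isolated at count 6")


@lru_cache(maxsize=1)
def synthetic_replicates() -> tuple[AdjacencyRecord, ...]:
    """The packaged 13-replicate edge-observation fixture (synthetic).

    An edge with count k is assigned to k of the 13 replicates round-robin,
    which spreads per-replicate edge counts roughly evenly. The constraint
    set is validated on every build; violations raise ``FixtureError``.
    """
    counts = synthetic_edge_counts()
    _validate(counts)
    names = [n for _, n in REGIONS]
    idx = {n: i for i, n in enumerate(names)}
    mats = [np.zeros((len(names), len(names)), dtype=bool) for _ in range(N_REPLICATES)]
    ptr = 0
    for e in sorted(counts, key=lambda e: tuple(sorted(e))):
        k = counts[e]
        a, b = sorted(e)
        for j in range(k):
            m = mats[(ptr + j) % N_REPLICATES]
            m[idx[a], idx[b]] = m[idx[b], idx[a]] = True
        ptr += k
    return tuple(
        AdjacencyRecord(f"synthetic-{i + 1:02d}", tuple(names), m)
        for i, m in enumerate(mats)
    )


_RIDGE_HILLS = (
    # broad rolling hills so the arena has a meaningful median elevation
    ((40.0, 70.0), 0.0, 0.35, 22.0),
    ((62.0, 140.0), 0.0, 0.30, 20.0),
    ((148.0, 62.0), 0.0, 0.30, 24.0),
    ((160.0, 132.0), 0.0, 0.35, 20.0),
    ((30.0, 162.0), 0.0, 0.30, 18.0),
    ((172.0, 36.0), 0.0, 0.28, 18.0),
    ((96.0, 64.0), 0.0, 0.22, 14.0),
    ((104.0, 140.0), 0.0, 0.22, 14.0),
)


def ridge_arena(seed: int = 0) -> Arena:
    """200 x 200 terrain split by a Gaussian ridge (amplitude 0.9).

    The ridge runs along the rows through the middle of the arena with
    low-elevation corridors around its ends; broad rolling hills give the
    terrain a realistic spread of elevations away from the ridge. The two
    sites sit in valleys on opposite sides at elevation < 0.1.
    Deterministic per seed.
    """
    hf = synth_heightfield(
        200, 200,
        ridges=[((100.0, 100.0), 90.0, 0.9, (45.0, 10.0)), *_RIDGE_HILLS],
        seed=seed,
    )
    sites = [
        RegionSite(1, "west", 100, 30),
        RegionSite(2, "east", 100, 170),
    ]
    return make_arena(np.ones((200, 200), dtype=bool), sites, hf)


def triangle_arena() -> Arena:
    """200 x 200 flat arena with three sites in an equilateral layout."""
    sites = [
        RegionSite(1, "a", 35, 100),
        RegionSite(2, "b", 133, 44),
        RegionSite(3, "c", 133, 156),
    ]
    return make_arena(np.ones((200, 200), dtype=bool), sites, None)
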