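"""Scaled-down replicate experiment protocols.

The full-size study (a Balkans-shaped arena populated with 70,000
particles) is expensive; these protocols reproduce its qualitative
behaviour at desk scale on the packaged 200 x 200 arenas: a flat
three-site arena probes whether adaptation reliably forms a network
spanning all sites, and the ridge arena probes terrain response — whether
networks route over lower ground and pores open preferentially on high
ground. Each trial is one fully seeded simulation plus network
extraction, so success rates over a seed list are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

from .extract import ExtractConfig, binarize_trails, extract_network
from .fixtures import ridge_arena, triangle_arena
from .sim import SimConfig, occupancy, run_simulation

__all__ = [
    "TRIANGLE_PROTOCOL",
    "RIDGE_PROTOCOL",
    "RidgeTrial",
    "triangle_trial",
    "triangle_success_count",
    "ridge_trial",
    "ridge_condition_comparison",
]

#: Three-site connectivity protocol: ~6,000 particles on the flat
#: 200 x 200 triangle arena, 2,000 adaptation steps.
TRIANGLE_PROTOCOL = SimConfig(steps=2000, target_population=6000)

#: Terrain-response protocol: half-coverage inoculation of the ridge
#: arena, 2,000 adaptation steps, default terrain coupling.
RIDGE_PROTOCOL = SimConfig(steps=2000, init_density=0.5)


def triangle_trial(seed: int, cfg: SimConfig = TRIANGLE_PROTOCOL) -> bool:
    """Run one seeded triangle experiment; True if the extracted network
    connects all three sites (in one adjacency component)."""
    arena = triangle_arena()
    state = run_simulation(arena, cfg, seed=seed)
    _, rec = extract_network(state, arena, ExtractConfig(deposit=cfg.deposit))
    g = nx.Graph()
    g.add_nodes_from(rec.region_ids)
    g.add_edges_from(tuple(e) for e in rec.edges())
    return nx.is_connected(g)


def triangle_success_count(seeds: Iterable[int]) -> tuple[int, int]:
    """(successes, trials) of ``triangle_trial`` over the seed list."""
    seeds = list(seeds)
    return sum(triangle_trial(s) for s in seeds), len(seeds)


@dataclass(frozen=True)
class RidgeTrial:
    """Terrain metrics of one seeded ridge-arena run."""

    seed: int
    height_weight: float
    mean_network_elevation: float  # mean height under digitized network cells
    empty_above_median: float      # vacant fraction of above-median-height cells
    empty_below_median: float      # vacant fraction of below-median cells
    sites_connected: bool


def ridge_trial(seed: int, height_weight: float | None = None,
                cfg: SimConfig = RIDGE_PROTOCOL) -> RidgeTrial:
    """Run one seeded ridge experiment and measure terrain response."""
    if height_weight is not None:
        cfg = replace(cfg, height_weight=height_weight)
    arena = ridge_arena()
    H = arena.heightfield.values
    med = float(np.median(H))
    state = run_simulation(arena, cfg, seed=seed)
    net = binarize_trails(state.trail, cfg.deposit / 2.0)
    empty = ~occupancy(state) & arena.mask
    _, rec = extract_network(state, arena, ExtractConfig(deposit=cfg.deposit))
    return RidgeTrial(
        seed=seed,
        height_weight=cfg.height_weight,
        mean_network_elevation=float(H[net].mean()) if net.any() else float("nan"),
        empty_above_median=float(empty[H > med].mean()),
        empty_below_median=float(empty[H <= med].mean()),
        sites_connected=bool(rec.matrix[0, 1]),
    )


def ridge_condition_comparison(
    seeds: Sequence[int], height_weight: float | None = None
) -> dict:
    """Paired no-height vs height runs over ``seeds``.

    Returns counts of seeds where (a) the network's mean elevation is lower
    with terrain coupling than without, and (b) vacancy is higher above the
    median elevation than below it under terrain coupling.
    """
    seeds = list(seeds)
    flat = [ridge_trial(s, height_weight=0.0) for s in seeds]
    hilly = [ridge_trial(s, height_weight=height_weight) for s in seeds]
    elev_lower = sum(
        h.mean_network_elevation < f.mean_network_elevation
        for h, f in zip(hilly, flat)
    )
    pores_above = sum(h.empty_above_median > h.empty_below_median for h in hilly)
    return {
        "n_seeds": len(seeds),
        "elevation_lower": elev_lower,
        "pores_above_median": pores_above,
        "flat": flat,
        "hilly": hilly,
    }
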