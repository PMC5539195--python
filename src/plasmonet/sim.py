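"""Multi-agent virtual plasmodium on a lattice.

A population of mobile particles — each a hypothetical unit of gel/sol
interaction — senses and deposits chemoattractant on a diffusive trail
lattice. Nutrient stimuli are projected at region sites each step, the
population grows and shrinks by local-density rules, and terrain enters
as a subtractive penalty on sensed trail values, so particles prefer
low ground. From full-coverage inoculation the material opens pores and
collapses into a minimised transport network spanning the sites.

One seeded generator drives the whole run; per step it is consumed in a
fixed order (stimuli need none; sensory permutation, sensory tie draws,
motor permutation, motor reset draws, then growth permutation/direction/
heading draws when scheduled), so trajectories are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.ndimage import uniform_filter

from . import _kernels
from .arena import Arena, HeightField, RegionSite

__all__ = [
    "SimConfig",
    "SimState",
    "SimError",
    "inoculate_full",
    "effective_value",
    "sense_and_steer",
    "motor_step",
    "project_stimuli",
    "diffuse_decay",
    "window_counts",
    "adapt_population",
    "run_simulation",
    "occupancy",
    "DEFAULT_HEIGHT_WEIGHT",
]

NEG_INF = float("-inf")

#: Default terrain coupling (trail units per unit elevation). Calibrated on
#: the packaged ridge arena (scripts/calibrate_height_weight.py) so that
#: networks reliably route around the ridge rather than over it.
DEFAULT_HEIGHT_WEIGHT = 10.0


class SimError(ValueError):
    """Raised for invalid simulator configuration or state."""


@dataclass(frozen=True)
class SimConfig:
    """Simulation parameters.

    Angles are degrees, distances are lattice cells, the trail field is in
    arbitrary deposit units. Defaults are the canonical values of the
    three-sensor particle model family; every run-specific quantity
    (population, schedule, terrain coupling) is explicit here.
    """

    sensor_angle: float = 45.0       # SA: sensor separation from heading
    rotation_angle: float = 45.0     # RA: turn per steering decision
    sensor_offset: float = 9.0       # SO: sensor distance ahead
    step_size: float = 1.0           # SS: advance per motor step
    deposit: float = 5.0             # D: trail laid per successful move
    decay: float = 0.1               # rho: trail fraction lost per step
    diffusion_kernel: int = 3        # k: mean-filter window (odd)
    height_weight: float = DEFAULT_HEIGHT_WEIGHT  # w_h: sensing penalty per unit height
    max_height: float = 1.0          # movement blocked above this elevation (1.0 = never)
    site_stimulus: float = 255.0     # w_f: trail added at each site per step
    init_density: float = 0.5        # d0: per-cell occupancy probability at inoculation
    target_population: int | None = None  # overrides init_density when set
    growth_window: int = 9           # G
    growth_min: int = 1              # g_min (window count incl. self)
    growth_max: int = 10             # g_max
    growth_interval: int = 5         # steps between division events (0 = off)
    shrink_window: int = 5           # S
    shrink_min: int = 1              # s_min (other particles required)
    shrink_interval: int = 5         # steps between removal events (0 = off)
    steps: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.decay < 1.0:
            raise SimError(f"decay must be in [0, 1), got {self.decay}")
        for name in ("sensor_angle", "rotation_angle"):
            v = getattr(self, name)
            if not 0.0 < v < 180.0:
                raise SimError(f"{name} must be in (0, 180), got {v}")
        if self.sensor_offset < 1.0:
            raise SimError(f"sensor_offset must be >= 1, got {self.sensor_offset}")
        if self.diffusion_kernel % 2 != 1 or self.diffusion_kernel < 1:
            raise SimError(f"diffusion_kernel must be odd and >= 1, got {self.diffusion_kernel}")
        if not 0.0 < self.init_density <= 1.0:
            raise SimError(f"init_density must be in (0, 1], got {self.init_density}")
        if self.steps < 0:
            raise SimError("steps must be >= 0")


@dataclass
class SimState:
    """Dense particle arrays plus the trail lattice.

    The first ``n`` entries of each array are live particles; ``occ`` maps
    each cell to the index of its occupant (-1 when empty), enforcing the
    one-particle-per-cell exclusion rule.
    """

    pos_r: np.ndarray
    pos_c: np.ndarray
    heading: np.ndarray
    cell_r: np.ndarray
    cell_c: np.ndarray
    n: int
    occ: np.ndarray
    trail: np.ndarray
    step: int
    rng: np.random.Generator
    population_curve: list = field(default_factory=list)

    @property
    def count(self) -> int:
        return self.n

    def cells(self) -> np.ndarray:
        """(n, 2) array of occupied (row, col) cells."""
        return np.stack([self.cell_r[: self.n], self.cell_c[: self.n]], axis=1)

    def positions(self) -> np.ndarray:
        return np.stack([self.pos_r[: self.n], self.pos_c[: self.n]], axis=1)

    def headings(self) -> np.ndarray:
        return self.heading[: self.n].copy()

    def check_exclusion(self) -> None:
        cells = self.cells()
        if len(np.unique(cells[:, 0] * self.occ.shape[1] + cells[:, 1])) != self.n:
            raise AssertionError("exclusion violated: two particles share a cell")


def occupancy(state: SimState) -> np.ndarray:
    """Boolean per-cell occupancy grid."""
    return state.occ >= 0


def _heights_for(arena: Arena) -> tuple[np.ndarray, bool]:
    if arena.heightfield is None:
        return np.zeros(arena.shape, dtype=np.float64), False
    return np.ascontiguousarray(arena.heightfield.values), True


def inoculate_full(arena: Arena, cfg: SimConfig, seed: int | None = None) -> SimState:
    """Populate the habitable area as a single mass.

    Each habitable cell is independently occupied with probability d0
    (``init_density``, or ``target_population``/habitable cells when a
    target is set); headings are uniform in [0, 360). The trail starts at
    zero. Deterministic given the seed.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    d0 = cfg.init_density
    if cfg.target_population is not None:
        d0 = cfg.target_population / max(arena.n_habitable, 1)
    if d0 <= 0.0:
        raise SimError(f"initial density must be > 0, got {d0}")
    d0 = min(d0, 1.0)
    mask = arena.mask
    occupied = (rng.random(mask.shape) < d0) & mask
    rows, cols = np.nonzero(occupied)
    n = rows.size
    cap = arena.n_habitable
    pos_r = np.zeros(cap, dtype=np.float64)
    pos_c = np.zeros(cap, dtype=np.float64)
    heading = np.zeros(cap, dtype=np.float64)
    cell_r = np.zeros(cap, dtype=np.int64)
    cell_c = np.zeros(cap, dtype=np.int64)
    pos_r[:n] = rows
    pos_c[:n] = cols
    heading[:n] = rng.uniform(0.0, 360.0, n)
    cell_r[:n] = rows
    cell_c[:n] = cols
    occ = np.full(mask.shape, -1, dtype=np.int64)
    occ[rows, cols] = np.arange(n)
    trail = np.zeros(mask.shape, dtype=np.float64)
    return SimState(pos_r, pos_c, heading, cell_r, cell_c, n, occ, trail, 0, rng)


def effective_value(
    trail: np.ndarray,
    heightfield: HeightField | np.ndarray | None,
    cell: tuple[int, int],
    height_weight: float,
    mask: np.ndarray | None = None,
) -> float:
    """Sensed value at a cell: trail minus the elevation penalty.

    Out-of-grid or non-habitable cells read -inf so they are never
    preferred. With no heightfield the value is the raw trail.
    """
    r, c = cell
    if not (0 <= r < trail.shape[0] and 0 <= c < trail.shape[1]):
        return NEG_INF
    if mask is not None and not mask[r, c]:
        return NEG_INF
    if heightfield is None:
        return float(trail[r, c])
    hv = heightfield.values if isinstance(heightfield, HeightField) else heightfield
    return float(trail[r, c] - height_weight * hv[r, c])


def sense_and_steer(
    particle: tuple[tuple[float, float], float],
    trail: np.ndarray,
    arena: Arena,
    cfg: SimConfig,
    rng: np.random.Generator,
) -> float:
    """Single-particle steering decision; returns the new heading.

    ``particle`` is ((row, col), heading_deg). The front sensor keeps the
    heading whenever it is at least as good as both side sensors; otherwise
    the better side wins, and an exact side tie is broken by one draw.
    """
    (pr, pc), h = particle
    hf = arena.heightfield.values if arena.heightfield is not None else None
    w_h = cfg.height_weight if hf is not None else 0.0

    def read(angle: float) -> float:
        a = np.deg2rad(angle)
        r = int(np.rint(pr + cfg.sensor_offset * np.sin(a)))
        c = int(np.rint(pc + cfg.sensor_offset * np.cos(a)))
        return effective_value(trail, hf, (r, c), w_h, arena.mask)

    f = read(h)
    left = read(h - cfg.sensor_angle)
    right = read(h + cfg.sensor_angle)
    if f >= left and f >= right:
        return h % 360.0
    if left > right:
        return (h - cfg.rotation_angle) % 360.0
    if right > left:
        return (h + cfg.rotation_angle) % 360.0
    turn = -cfg.rotation_angle if rng.random() < 0.5 else cfg.rotation_angle
    return (h + turn) % 360.0


def _sensory_stage(state: SimState, arena: Arena, cfg: SimConfig,
                   heights: np.ndarray, w_h: float) -> None:
    order = state.rng.permutation(state.n)
    ties = state.rng.random(state.n)
    _kernels.sensory_stage(
        order, state.pos_r, state.pos_c, state.heading, state.trail, heights,
        arena.mask, w_h, cfg.sensor_angle, cfg.rotation_angle,
        cfg.sensor_offset, ties,
    )


def motor_step(state: SimState, arena: Arena, cfg: SimConfig) -> SimState:
    """Advance every particle one movement attempt (random order, in place).

    Blocked particles (destination off-mask, above ``max_height``, or
    occupied) stay put with a re-randomized heading and deposit nothing;
    movers deposit ``deposit`` at their new cell.
    """
    heights, _ = _heights_for(arena)
    order = state.rng.permutation(state.n)
    resets = state.rng.random(state.n)
    _kernels.motor_stage(
        order, state.pos_r, state.pos_c, state.heading, state.cell_r,
        state.cell_c, state.occ, state.trail, arena.mask, heights,
        cfg.step_size, cfg.deposit, cfg.max_height, resets,
    )
    return state


def project_stimuli(
    trail: np.ndarray,
    sites: Sequence[RegionSite | tuple[int, int]],
    site_stimulus: float,
) -> np.ndarray:
    """Return a copy of the trail with ``site_stimulus`` added at each site
    cell (sites sharing a cell accumulate additively)."""
    out = trail.copy()
    for s in sites:
        r, c = (s.row, s.col) if isinstance(s, RegionSite) else s
        if not (0 <= r < trail.shape[0] and 0 <= c < trail.shape[1]):
            raise SimError(f"site ({r},{c}) outside grid {trail.shape}")
        out[r, c] += site_stimulus
    return out


_count_cache: dict[tuple[tuple[int, int], int], np.ndarray] = {}


def _inbounds_counts(shape: tuple[int, int], k: int) -> np.ndarray:
    key = (shape, k)
    got = _count_cache.get(key)
    if got is None:
        ones = np.ones(shape, dtype=np.float64)
        got = np.rint(uniform_filter(ones, size=k, mode="constant") * k * k)
        _count_cache[key] = got
    return got


def diffuse_decay(
    trail: np.ndarray,
    diffusion_kernel: int | SimConfig = 3,
    decay: float = 0.1,
    toroidal: bool = False,
) -> np.ndarray:
    """Mean-filter the trail over a k x k window, then decay by (1 - rho).

    The default window averages over in-bounds cells only; ``toroidal``
    wraps the grid instead (useful because the wrap-around variant
    conserves total mass exactly, giving a mass-balance oracle).
    """
    if isinstance(diffusion_kernel, SimConfig):
        cfg = diffusion_kernel
        diffusion_kernel, decay = cfg.diffusion_kernel, cfg.decay
    k = int(diffusion_kernel)
    if k % 2 != 1 or k < 1:
        raise SimError(f"diffusion kernel must be odd and >= 1, got {k}")
    if toroidal:
        out = uniform_filter(trail, size=k, mode="wrap")
    else:
        sums = uniform_filter(trail, size=k, mode="constant") * k * k
        out = sums / _inbounds_counts(trail.shape, k)
    out *= 1.0 - decay
    return np.maximum(out, 0.0)


def window_counts(state: SimState, window: int) -> np.ndarray:
    """Per-cell count of particles in the window x window neighbourhood
    (window truncated at the boundary), including the cell itself."""
    occf = (state.occ >= 0).astype(np.float64)
    return np.rint(uniform_filter(occf, size=window, mode="constant") * window * window).astype(np.int64)


def adapt_population(state: SimState, arena: Arena, cfg: SimConfig) -> SimState:
    """Division and removal by local density, on their schedules.

    At a growth event each particle whose G x G window holds between
    ``growth_min`` and ``growth_max`` particles spawns one offspring into a
    random free 4-neighbour cell; at a shrink event each particle with
    fewer than ``shrink_min`` other particles in its S x S window is
    removed. Each event is one pass against pre-event counts.
    """
    step = state.step
    if cfg.growth_interval and step % cfg.growth_interval == 0:
        counts = window_counts(state, cfg.growth_window)
        order = state.rng.permutation(state.n)
        dirs = state.rng.integers(0, 4, state.n)
        heads = state.rng.random(state.n)
        state.n = int(_kernels.growth_pass(
            order, state.pos_r, state.pos_c, state.heading, state.cell_r,
            state.cell_c, state.occ, arena.mask, state.n, counts,
            cfg.growth_min, cfg.growth_max, dirs, heads,
        ))
    if cfg.shrink_interval and step % cfg.shrink_interval == 0:
        counts = window_counts(state, cfg.shrink_window)
        state.n = int(_kernels.shrink_pass(
            state.pos_r, state.pos_c, state.heading, state.cell_r,
            state.cell_c, state.occ, state.n, counts, cfg.shrink_min,
        ))
    return state


def run_simulation(
    arena: Arena,
    cfg: SimConfig,
    seed: int | None = None,
    snapshot_every: int | None = None,
    snapshot_cb: Callable[[SimState], None] | None = None,
    check_exclusion: bool = False,
) -> SimState:
    """Run the full adaptation loop and return the final state.

    Per step: project site stimuli -> sensory stage (shuffled) -> motor
    stage (shuffled) -> population adaptation (on schedule) -> trail
    diffusion and decay. Bit-reproducible given (arena, cfg, seed).
    """
    state = inoculate_full(arena, cfg, seed)
    heights, has_height = _heights_for(arena)
    w_h = cfg.height_weight if has_height else 0.0
    site_cells = [(s.row, s.col) for s in arena.sites]
    for t in range(1, cfg.steps + 1):
        state.step = t
        state.trail = project_stimuli(state.trail, site_cells, cfg.site_stimulus)
        _sensory_stage(state, arena, cfg, heights, w_h)
        motor_step(state, arena, cfg)
        adapt_population(state, arena, cfg)
        state.trail = diffuse_decay(state.trail, cfg.diffusion_kernel, cfg.decay)
        state.population_curve.append(state.n)
        if check_exclusion:
            state.check_exclusion()
        if snapshot_every and snapshot_cb and t % snapshot_every == 0:
            snapshot_cb(state)
    return state
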