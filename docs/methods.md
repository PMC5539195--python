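# Methods

## Model

The simulator is a multi-agent model of the *Physarum polycephalum*
plasmodium of the three-sensor particle family. The plasmodium is
conceptualised as an aggregate of identical components: each particle is
a hypothetical unit of gel/sol interaction, the particle positions
indicate the structure of the protoplasmic network, and particle movement
represents the flux of sol within it. The medium is a 2D floating-point
lattice of chemoattractant ("trail"), isomorphic to the discrete particle
lattice; particles keep continuous internal position and heading,
rounded to cells for movement and sensing.

Per step, in order:

1. **Stimuli.** Each region site adds `site_stimulus` to the trail at its
   cell (sites sharing a cell accumulate).
2. **Sensory stage** (one random permutation of the population). Each
   particle reads three sensors at distance SO ahead, at angles
   {−SA, 0, +SA} relative to its heading. The sensed quantity is the
   *effective value* `trail(c) − w_h·h(c)` with h the normalized
   elevation; cells outside the arena or mask read −∞ and are never
   preferred. If the front sensor is at least as good as both sides the
   heading is kept; otherwise the particle turns ±RA toward the strictly
   better side, and an exact side tie above the front resolves by one
   uniform draw.
3. **Motor stage** (a second permutation). Each particle attempts to
   advance SS along its heading. If the destination cell is habitable,
   below the impassable cutoff `max_height`, and unoccupied, the particle
   moves and deposits D there; a blocked particle stays, adopts a fresh
   uniform heading, and deposits nothing. The resistance of the gel
   matrix to sol flux is generated entirely by these collisions, so at
   most one particle ever occupies a cell.
4. **Adaptation** (on schedule). Every `growth_interval` steps, a
   particle whose G×G window holds between `growth_min` and `growth_max`
   particles (self included) spawns one offspring into a random free
   4-neighbour cell; every `shrink_interval` steps, a particle with fewer
   than `shrink_min` *other* particles in its S×S window is removed. Each
   event is a single pass judged against pre-event window counts, so
   fates do not depend on processing order within the event.
5. **Diffusion and decay.** The trail is replaced by its k×k in-bounds
   window mean and multiplied by (1 − ρ).

Runs start from full-coverage inoculation: every habitable cell is
independently occupied with probability d0 (or `target_population` /
habitable cells), headings uniform. From this dense material, pores open
and grow until a minimised network remains, pinned to the nutrient
sites.

### Parameters

| name | default | units | role |
|---|---|---|---|
| SA (`sensor_angle`) | 45 | deg | sensor separation |
| RA (`rotation_angle`) | 45 | deg | turn per decision |
| SO (`sensor_offset`) | 9 | cells | sensor distance; sets lane cohesion |
| SS (`step_size`) | 1 | cells | advance per step |
| D (`deposit`) | 5 | trail/step | deposition per successful move |
| ρ (`decay`) | 0.1 | 1/step | trail decay |
| k (`diffusion_kernel`) | 3 | cells | mean-filter window |
| w_f (`site_stimulus`) | 255 | trail/step | nutrient projection per site |
| w_h (`height_weight`) | 10 | trail per unit height | terrain penalty in sensing |
| `max_height` | 1.0 | — | impassable-elevation cutoff (1.0 = off) |
| d0 (`init_density`) | 0.5 | — | inoculation coverage |
| G, g_min, g_max, interval | 9, 1, 10, 5 | — | division rule |
| S, s_min, interval | 5, 1, 5 | — | removal rule |

SA/RA/SO/SS/D/ρ/k and the growth/shrink rules are the canonical values of
the reference model family. Two values are this package's own choices:

- **w_f = 255.** Nutrient stimuli must dominate lane trail concentrations
  (which equilibrate near D/ρ = 50) or minimisation detaches the network
  from the sites; projecting the full 8-bit food value per step pins the
  network at every site throughout adaptation. Weak projections (a few
  trail units per step) leave site attachment unreliable at desk scale.
- **w_h = 10.** Calibrated on the packaged ridge arena
  (`scripts/calibrate_height_weight.py`): across the sweep {5, 10, 20}
  the network's mean elevation always drops relative to an uncoupled
  control, but pore localisation on high ground saturates from w_h = 10
  while cross-ridge connectivity collapses at w_h = 20 (the terrain
  penalty then outweighs any trail gradient). w_h = 10 is the middle of
  that window.

Terrain couples through sensing only; movement is never blocked by
elevation unless `max_height` is set. This is the minimal mechanism that
yields both ridge avoidance and high-elevation pores; a hard cutoff is
available for genuinely impassable terrain.

### Determinism

One seeded `numpy` generator drives a run; each step consumes draws in a
fixed order (sensory permutation, sensory tie draws, motor permutation,
motor reset draws, then growth permutation/direction/heading draws when
scheduled). Trajectories are bitwise reproducible given (arena, config,
seed). The per-particle inner loops are numba kernels; they receive all
randomness pre-drawn, so compiled and pure-Python paths consume identical
streams.

## Network extraction

The trail field is binarized at τ (default D/2), thinned to a one-pixel
skeleton (Zhang–Suen-family thinning, 8-connectivity, component-count
preserving), and resolved into a graph. Junction pixels (≥ 3 skeleton
neighbours) are merged by 8-connected flood fill into Steiner nodes;
each region site captures the nearest skeleton pixel — within
`capture_radius` (default 5 cells) when the site lies outside the
digitized material, or within its own mask component when inside (the
centerline of a wide lane can legitimately sit beyond any small fixed
radius). Skeleton components containing no region node — trail remnants
trapped by terrain — are discarded. Dangling spurs are dropped and
Steiner nodes are spliced or pruned until each has degree ≥ 3. Regions
joined by a path whose interior nodes are all Steiner nodes count as
directly connected; transparency is unlimited-depth by default, with a
strict single-junction mode behind a flag.

The trail (not particle occupancy) is the default digitization source:
it is smooth, its value at every site provably contains the stimulus
bump (so sites sit inside the material they belong to), and τ = D/2
separates maintained lanes from decayed background. Occupancy-based
digitization is available but yields thick, blocky masks whose medial
axes wander far from site cells.

## Replicate statistics

The Physarum graph **P** = (**C**, **R**, p) holds every edge observed in
at least one replicate with p(e) = count/N as an exact `Fraction`;
thresholds are compared rationally (θ accepted as a count, a "k/N"
string, a `Fraction`, or a float), so p(e) ≥ θ has no float-equality
hazards. The transform keeps edges **at** equality — the convention
under which each listed transition happens as θ *exceeds* the stated
value. The weight sweep at integer w equals the threshold transform at
θ = w/N identically. Edge-count SD is the sample (n−1) estimator.
Planarity uses the left–right certificate algorithm; the test suite
cross-checks it against an exhaustive Kuratowski-subdivision search on
all sampled graphs with ≤ 8 nodes, where subdivision interiors are
limited to the ≤ 3 non-branch vertices. Mean-degree ranking is
descending, ties broken by region label.

## Synthetic data

Three packaged inputs make every stage testable offline:

- **13-replicate edge-observation table** (`synthetic_replicates`). The
  original laboratory adjacency sets were never published; this table is
  openly synthetic, constructed from the qualitative constraints the
  published threshold analysis states — connected at θ = 3/13; Tomis and
  the Sirmium–Singidunum pair split off above 3/13; Tomis, Marcianopolis,
  Sirmium, Singidunum all isolated by 6/13; exactly three 3-node segments
  at 7/13; a single surviving pair at 10/13; planar from 2/13 with a K5
  among once-observed edges below it. Counts are spread round-robin over
  replicates, and every constraint is re-validated at build time. It
  validates the analysis code, not the laboratory data: per-replicate
  edge counts are nearly uniform (no biological variance model), and
  matching any real network's degree statistics is out of its scope.
- **Ridge arena**: a 200×200 terrain split by a tall Gaussian ridge
  (crest ≈ 0.9) with low corridors around its ends, over broad rolling
  hills (amplitudes 0.22–0.35) that give the arena a realistic elevation
  spread — the median elevation (~0.16) separates genuine uplands from
  valleys, which is what the pore-localisation measurement needs. Two
  sites sit in valleys (< 0.1) on opposite sides.
- **Triangle arena**: 200×200, flat, all-habitable, three sites in an
  equilateral layout.

What passing the scaled-down experiments shows — and what it does not:
the protocols (200×200, ~6,000 particles for the flat run, half-coverage
for the terrain run, 2,000 steps, 20 seeds) demonstrate that network
formation spans sites reliably and that terrain coupling reroutes
networks onto low ground and opens pores on high ground. They do not
reproduce the full-size study (70,000 particles on a Balkans-shaped
arena with satellite terrain), its exact network geometries, or any
laboratory statistics.

## Numerical choices and edge cases

- Trail is clamped non-negative after diffusion (guards float rounding).
- The in-bounds window mean uses separable uniform filtering with an
  exact cell-count normalizer; a wrap-around variant conserves total
  mass to float precision and serves as the mass-balance oracle.
- Steering ties (left = right > front) consume one pre-drawn uniform per
  particle per stage whether or not a tie occurs, keeping draw streams
  aligned across implementations.
- Growth stops silently when the particle array reaches its capacity
  (the habitable-cell count), which exclusion makes the hard ceiling.
- An empty binarization mask yields a graph of isolated region nodes;
  θ > 1 yields an empty threshold graph; a single replicate makes every
  observed edge frequency 1.

## Known limitations

- The terrain mechanism is sensing-penalty only; no gravisensitive
  motility model, no humidity, no 3D voxel substrate. "3D" here means a
  heightfield-modulated planar lattice.
- Oscillatory shuttle streaming, nutrient depletion and engulfment are
  not modelled; stimuli are constant per step regardless of site
  occupancy.
- Skeleton edge lengths are pixel-path lengths (diagonal √2), not
  geodesic distances on terrain.
- The CLI's snapshot PGMs scale the trail to the per-frame maximum, so
  frames are not radiometrically comparable across steps.
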