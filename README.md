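# plasmonet

Slime-mould-inspired transport networks over terrain: an agent-based
virtual plasmodium on a 2D lattice, network extraction with Steiner-node
resolution, and weighted proximity-graph statistics over replicate
experiments.

## What it is for

The plasmodium of *Physarum polycephalum* spans scattered food sources
with a network of protoplasmic tubes that approximates efficient
human-made transport networks. `plasmonet` packages the computational
side of that paradigm for researchers who use it to study transport
network formation — for example, comparing emergent networks against
historical road systems on real terrain:

- **Simulator** (`plasmonet.sim`): a population of mobile particles —
  each a hypothetical unit of gel/sol interaction — moves on a lattice,
  depositing and sensing a diffusive chemoattractant trail. Each particle
  carries three forward sensors (offset SO, separation ±SA) and turns by
  ±RA toward the strongest reading; movement is blocked by collisions
  (one particle per cell), and the population grows and shrinks by local
  density rules. Nutrient stimuli are projected at region sites every
  step. Terrain enters through an 8-bit greyscale heightfield h ∈ [0, 1]:
  sensors read `trail(c) − w_h · h(c)`, so particles prefer low ground and
  networks route around elevations. From a full-coverage inoculation the
  virtual material opens pores — preferentially on high ground — and
  collapses into a minimised transport network spanning the sites.
- **Network extraction** (`plasmonet.extract`): binarize the trail field,
  thin it to a one-pixel skeleton, resolve region nodes and Steiner
  (junction) nodes, and read off a region×region adjacency matrix in
  which regions joined through Steiner nodes count as directly connected.
- **Replicate statistics** (`plasmonet.stats`): the weighted Physarum
  graph **P** = (**C**, **R**, p) with exact rational edge frequencies
  p(e) = count/N, the threshold transform T(**R**) = {e : p(e) ≥ θ},
  edge-weight sweeps, planarity and connectivity reports, per-replicate
  edge-count statistics, and mean-degree rankings.
- **Arenas and fixtures** (`plasmonet.arena`, `plasmonet.fixtures`):
  PGM/PNG heightfields, habitability masks, CSV site lists, seeded
  synthetic terrains, and a packaged 13-replicate edge-observation table
  (openly synthetic, constraint-built) exercising every threshold
  transition the analysis layer must reproduce.

## Worked example

An edge observed in 3 of 13 replicate experiments has frequency
p = 3/13 exactly, and thresholding keeps an edge iff p(e) ≥ θ:

```python
>>> from plasmonet import edge_probability, build_physarum_graph, threshold_graph
>>> from plasmonet.fixtures import synthetic_replicates
>>> p = edge_probability(3, 13)
>>> p, float(p)
(Fraction(3, 13), 0.23076923076923078)
>>> P = build_physarum_graph(list(synthetic_replicates()))
>>> tg = threshold_graph(P, "10/13")
>>> sorted(tuple(sorted(e)) for e in tg.retained)
[('Hadrianopolis', 'Traianoupolis')]
```

Only the strongest road (observed in 10 of 13 replicates) survives the
θ = 10/13 threshold; sweeping θ downward re-attaches regions in order of
their connection strength.

A small end-to-end run from the shell (simulate → extract → report):

```sh
plasmonet simulate --arena triangle --replicates 3 --seed 1 \
    --target-population 6000 --out runs/demo
plasmonet report runs/demo --w 2 --out runs/demo-report
```

This writes one adjacency CSV per seeded replicate plus a manifest, then
a mean-degree table, edge-incidence weights and per-threshold
connectivity reports. On the flat three-site arena every replicate's
network spans all three sites, so `degree_table.csv` ranks each region
at mean degree 2.0 and `connectivity_w_2.json` reports a single planar
component `[1, 2, 3]`.

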