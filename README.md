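# polywhorl

Quantification and modelling of **whorled organ arrangements on
cylindrical bodies**, built for hydrozoan polyp tentacles.  Many hydrozoan
polyps (e.g. *Coryne uchidai*) carry dozens of tentacles arranged in
rings around the oral–aboral axis — a 3D periodic pattern closely
analogous to whorled plant phyllotaxis.  `polywhorl` provides, in one
tested pipeline:

1. **Whorl quantification** — phyllotaxis-style measurements of tentacle
   coordinate tables: internode lengths, successive-organ angles, circular
   statistics of position-angle differences, ring detection by the
   internode-gap rule, whole-body periodicity classification by lag
   correlation, population-level symmetry tallies and the size–symmetry
   correlation.
2. **A reaction–diffusion simulator** — a three-morphogen
   (activator / mouth inhibitor / tentacle-secreted lateral inhibitor)
   model on a cylindrical cell lattice with threshold- and
   global-maximum-gated tentacle initiation, which reproduces
   size-correlated tri-/tetra-/pentaradial tentacle rings.
3. **Seeded synthetic-data generators** for whorls, spirals and
   polymorphic populations, so every analysis stage is testable without
   measured specimens.

## The statistics at the core

For a sample of angles θ_j (the differences in position angles between
angularly adjacent tentacles of a ring), the package computes the
circular mean, resultant vector length and circular standard deviation:

```
θ̄  = atan2( (1/n) Σ sin θ_j , (1/n) Σ cos θ_j )
R_v = | (1/n) Σ (sin θ_j, cos θ_j) |
S   = sqrt(−2 ln R_v)        (radians; reported in degrees)
```

Tentacles are ordered by distance from the mouth; a **ring-defining
gap** is an internode Δh_i = h_{i+1} − h_i strictly greater than twice
the mean of all internodes, Σ(h_{i+1}−h_i)/(m−1).  The runs between gaps
are rings; the most oral ring (the *primary ring*) defines the radial
symmetry type: 3 → tri, 4 → tetra, 5 → penta.  Whole-body periodicity is
the lag k ∈ {1..8} maximising the Pearson correlation R_k between the
internode sequence and itself shifted by k, accepted when
max{R_k} > 0.5 and p ≤ 0.05 (otherwise "n.s.").  The size analysis uses
the Pearson product-moment formula
r = (nΣxy − ΣxΣy)/√((nΣx²−(Σx)²)(nΣy²−(Σy)²)) with the symmetry type
encoded ordinally as {3,4,5}.

In the simulator (fields a, b, c on a W×L cylinder lattice; explicit
Euler; periodic circumference, zero-flux ends):

```
∂a/∂t = D_a Δa − k_a a + s_a·[mouth]
∂b/∂t = D_b Δb − k_b b + s_b·[mouth]
∂c/∂t = D_c Δc − k_c c + s_c·[tentacles]
```

a body cell becomes a tentacle when `a > T_a`, `b < T_i`, `c < T_ti` and
it holds the global activator maximum among eligible cells; each new
tentacle is a permanent source of the lateral inhibitor c.  With the
calibrated defaults the circumferences 54, 72 and 90 cells (a 3:4:5
ratio) select primary rings of 3, 4 and 5 tentacles — the mechanism by
which body diameter selects the symmetry type.

## Worked example

```python
from polywhorl import (PopulationSpec, RunConfig, gen_population, quantify)

polyps = gen_population(PopulationSpec(n_polyps=73, exact_proportions=True, seed=1))
result = quantify(polyps, RunConfig())
print(result.tally)
print(result.correlations)
```

prints

```
   primary_count symmetry  count  percent
0              3      tri     13    17.80
1              4    tetra     41    56.16
2              5    penta     12    16.43
3              6    other      4     5.47
4              9    other      2     2.73
5             10    other      1     1.36
                           label         r   n
0           symmetry_vs_diameter  0.901962  66
1  symmetry_vs_adjacent_distance  0.287267  66
```

i.e. tetraradial polyps dominate (56.16%), percentages are truncated to
two decimals, and polyp diameter increases strongly with the symmetry
type (r ≈ 0.9, because the generator draws class-mean diameters
increasing with the primary-ring count) while the distance between
adjacent tentacles correlates only weakly — more tentacles almost
compensate the larger circumference.

Simulating and quantifying in one step from the shell:

```
polywhorl simulate-quantify --geometries 54,72,90 --seeds 1,2,3 --out runs/
```

writes a nine-row table of primary-ring counts (3/4/5 by circumference),
primary-ring circular means (≈120°, 90°, 72°), whole-body period calls
and alternation offsets (≈60°, 45°, 36°: successive rings sit at half
the period angle, as in alternate whorled phyllotaxis).

## Layout

```
src/polywhorl/
  datamodel.py    tentacle records, arrangements, simulator snapshots
  io.py           TSV readers/writers, YAML config
  circular.py     circular mean / resultant / circular SD
  metrics.py      internodes, gap rule, ring partitions, alternation
  periodicity.py  lag correlations R_k, period call, contingency table
  population.py   symmetry tallies, Pearson r, 3D distances, size analysis
  simulator.py    reaction-diffusion model + calibration
  synth.py        whorl / spiral / population generators
  pipeline.py     quantify and simulate-then-quantify flows
  cli.py          `polywhorl` command-line interface
docs/methods.md   model description, parameter rationale, limitations
```
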