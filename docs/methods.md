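# Methods

## Scope and data model

`polywhorl` treats a polyp as a cylinder: each tentacle has an axial
distance from the mouth `h` (measured along the oral–aboral axis) and a
position angle `theta` around the body axis, with optional 3D base
coordinates.  Tentacles are kept in *mouth order* — ascending `(h,
theta)`.  The package does not rectify body curvature; `h` is accepted as
measured.  Units travel as a metadata string (`um` for measurements,
`cells` for simulator output) and are never converted implicitly.

Ties in mouth order (equal `h`) are broken by ascending `theta`; the sort
is stable, so exactly coincident records keep their input order.  This
tie rule matters only inside a whorl, where axial positions nearly
coincide, and none of the downstream statistics depend on within-whorl
order except the successive-angle series, whose whorl-internal values are
reported as-is and interpreted modulo the period angle.

## Whorl quantification

*Internodes and rings.*  The internode series is `dh_i = h_{i+1} − h_i`
(length m−1).  A ring-defining gap is an internode strictly greater than
`2 ×` the mean of **all** internodes of that polyp (not a local window).
"Strictly greater" is a deliberate reading: on an ideal whorled polyp the
within-ring internodes are ≈ 0, so the inter-ring gaps exceed any
reasonable multiple of the mean and the call is insensitive to the
boundary convention; a borderline internode exactly at 2× does not
create a ring.  The rule is scale-invariant by construction.  When no gap
is called the polyp is flagged `no_gap` (non-whorled — e.g. a spiral,
whose internodes are constant) and excluded from symmetry typing rather
than forced into a class.

*Ring angle statistics.*  Within a ring, members are sorted by position
angle and the circular gaps between angularly adjacent tentacles (which
sum to 360°) are summarised by the circular mean, resultant vector
length, and circular SD `S = sqrt(−2 ln R_v)` (computed in radians,
reported in degrees; natural logarithm, the standard circular-statistics
convention).  At `R_v = 0` the mean direction is undefined; the package
raises or flags that state explicitly instead of returning an arbitrary
angle.

*Alternation.*  For each successive ring pair, the offset of the lower
ring relative to the upper is the circular median of all pairwise angle
differences taken modulo the period angle `360 / ring size`.  The
circular median is robust to a single badly jittered tentacle; ideal
alternate whorls give half the period (60° / 45° / 36° for tri / tetra /
penta).  Ring pairs of unequal size are computed on the larger ring's
period and flagged rather than forced.

*Periodicity.*  `R_k` is the Pearson correlation between the internode
series and itself shifted by `k` for `k = 1..8`; each lag needs ≥ 3
overlapping pairs, and lags with zero variance in either subsequence are
excluded.  The period call is the argmax lag when `max R_k > 0.5` and the
correlation is significant at `p ≤ 0.05` (two-sided t-approximation with
`n − 2` degrees of freedom, `n` = overlap length at the best lag — the
overlap, not the full series, because those are the pairs the statistic
actually uses); otherwise "n.s.".  One refinement: a whorl of period `p`
correlates equally at lags `p, 2p, …`, and with realistic jitter the
sample `R_{2p}` can exceed `R_p`.  The call therefore resolves the argmax
lag to its smallest divisor that also clears the same `R > 0.5, p ≤ 0.05`
bar — the fundamental period.  Exact ties (within `tie_tolerance`,
default 0.02) also break toward the smallest lag.  Classification is
restricted by default to polyps with ≥ 20 tentacles (configurable), the
regime in which an 8-lag correlogram is informative.

*Population statistics.*  Primary-ring counts of 3/4/5 define
tri/tetra/pentaradial classes (others are "other").  Percentages are
**truncated**, not rounded, to two decimals (12/73 → 16.43), matching the
reporting convention of the observational counts this pipeline mirrors.
The size analysis correlates the class, encoded ordinally as {3,4,5},
against polyp diameter and against the mean 3D Euclidean distance between
angularly adjacent primary-ring tentacles, using the summation form of
Pearson's r; classes outside {3,4,5} are excluded.  Significance bands
for these correlations are out of scope.

## Reaction–diffusion simulator

### Model

Three fields on a `W × L` cell lattice wrapped into a cylinder (periodic
in the circumferential direction; zero-flux Neumann conditions at the
oral and aboral ends, implemented by mirrored ghost rows so that
diffusion conserves mass exactly):

| field | role | source |
|---|---|---|
| `a` | activator; permits initiation where `a > T_a` | mouth rows, rate `s_a` |
| `b` | mouth inhibitor; vetoes initiation where `b ≥ T_i` | mouth rows, rate `s_b` |
| `c` | lateral inhibitor; vetoes initiation where `c ≥ T_ti` | every tentacle cell, rate `s_c` |

Each obeys `∂f/∂t = D ∇²f − k f + s` with first-order decay, integrated
by explicit Euler at `dt = 0.8 / (4 max D + max k)` (80% of the
stability bound; the bound is validated at construction and a `dt`
override that violates it is rejected before any computation).  Initial
fields are zero plus seeded uniform noise of amplitude `noise_amp`.

A body cell (outside the `mouth_rows` oral rows) becomes a tentacle when
all three threshold conditions hold **and** it carries the global maximum
of `a` among eligible cells; at most one tentacle initiates per check,
ties break to the lowest `(row, col)`, and tentacles are permanent.  The
mouth is the first two oral rows; a tentacle occupies a single cell.

### Why the pattern forms

`a` and `b` decay aborally with lengths `sqrt(D/k)` ≈ 20 and 5 cells.
Near the mouth `b` exceeds `T_i`; far down the body `a` still exceeds
`T_a` (activation is effective throughout the body, which is what permits
multiple rings rather than the single near-mouth ring).  The first
eligible cells therefore sit in a band a few rows below the mouth, and
because `a` decreases aborally, the global-maximum rule always initiates
at the most oral eligible site: rings fill sequentially from the oral
side, exactly as in live imaging of growing polyps.

The lateral inhibitor sets the spacing.  Around an established tentacle
the steady `c` exceeds `T_ti` out to a blocking radius ρ; the calibrated
defaults put ρ ≈ 17–18 cells.  A ring fills at that spacing until it
closes, then the next ring opens ≈ 15 rows further down at the angular
midpoints of the ring above (where `c` is lowest) — which is precisely
the half-period alternation of alternate whorled phyllotaxis.  The
number of tentacles per ring is the number of blocking radii that fit
around the circumference, `floor(W/18)`: 3, 4 and 5 at `W` = 54, 72 and
90.  Body circumference selecting ring symmetry is the central
size–symmetry mechanism.

### Two timing choices

**Initiation checks run every `init_interval` steps** (default 700,
≈ 23 time units), not every Euler step.  The inhibitor needs a diffusion
time of order `ρ²/4D_c` to establish its blocking radius around a fresh
tentacle; checking faster than that lets tentacles pile up at
sub-spacing distances before the veto arrives.  The interval is chosen
so the `c` front is essentially at steady state before the next check.

**A competence delay `init_warmup`** (default 2400 steps, ≈ 80 time
units) precedes the first check, during which the mouth gradients mature
— biologically, tentacles appear hours after the hydranth bud transforms.
The delay has a second, decisive effect: diffusion damps the initial
white noise mode-by-mode (`exp(−D q² t)`), so by the first initiation
only the longest circumferential wavelength survives.  The activator
maximum is then a smooth single-peaked function of angle, and each new
tentacle lands exactly at the edge of the blocked arc nearest the
surviving noise peak.  The packing becomes deterministic up to a rigid
rotation set by the seed: replicates differ by rotation (the model's
statistical rotational symmetry) while counts, spacings and ring
structure are reproducible.  With per-step checks and raw noise the
placement within a ring would instead be uniform over the eligible arcs,
which makes the per-ring count a random-sequential-adsorption draw with
an intrinsic ±1 spread — incompatible with reproducible symmetry
selection at a 3:4:5 circumference ratio.

### Calibration

The committed defaults are a re-derived calibration, not transcribed
constants.  The tuned pair is the lateral-inhibition length
`ℓ_c = sqrt(D_c/k_c)` and the threshold `T_ti`; `calibrate_params` grid
searches them and accepts a candidate when each geometry hits its target
count in ≥ 2 of 3 seeded replicates.  The working point uses a *short*
decay length (ℓ_c = 0.5 cells) with `T_ti` deep on the inhibitor tail,
so the blocking radius — where the steady point-source kernel `K`
crosses `T_ti` — is ≈ 17–18 cells.  The steepness is not incidental: the
cell that closes a ring sits at the target spacing `s` from *two*
neighbours, so closure requires `2K(s) < T_ti < K(s−1)`, i.e. the kernel
must fall by more than a factor 2 per cell.  A long-range kernel can
never close a ring at equal spacing (the pair sum always exceeds the
single-source threshold), which manifests as rings losing one tentacle
and the pattern drifting toward quasi-spirals.  `T_ti ≈ 4.7e-16` looks
extreme but is simply `K(17.5)` for a kernel that decays ~36 e-folds
over one spacing; it is fully resolved in double precision.

Defaults (lattice units; committed in `data/calibrated_sim.yaml`):
`D_a = D_b = D_c = 3`, `k_a = 0.0075`, `k_b = 0.12`, `k_c = 12`,
`s_a = s_b = s_c = 1`, `T_a = 0.2`, `T_i = 1.1`, `T_ti = 4.71e-16`,
`L = 80`, `mouth_rows = 2`, `noise_amp = 2e-4`, `max_steps = 22000`
(≈ 730 time units, enough for 5–6 rings), `max_tentacles = 26`.

### Problem sizes

One simulation is a `W × 80` lattice stepped 22 000 times (~3–4 s on one
CPU).  The standard study condition — three geometries × three seeded
replicates — runs in well under a minute; the test suite shares one such
batch across all simulator-level checks.  At `W = 54` the body holds
~5 rings of 3 (≈ 15 tentacles), below the ≥ 20-tentacle periodicity
default; the simulate-and-quantify flow therefore classifies simulated
polyps with the restriction relaxed to the run's own tentacle count,
which is legitimate because simulated series are noise-free.

## Synthetic data generator

`gen_whorled` places ring `r` at `r × ring_spacing` with truncated
Gaussian axial jitter (cut at ±ring_spacing/4 so rings never interleave
and the generating partition stays the ground truth) and tentacle `j` at
`360 j / per_ring` plus an optional half-period offset per ring plus
wrapped-Gaussian angular jitter; 3D coordinates lie on a cylinder of the
given diameter.  `gen_spiral` uses constant rise and divergence.
`gen_population` draws each polyp's class from the observed
class-frequency weights (41/13/12/4/2/1 over 73), its tentacle total from
20–28, and its diameter from class means `30 + 60 × class` µm with
σ = 20 µm — increasing over {3,4,5}, which encodes the size–symmetry
correlation as ground truth.  `exact_proportions=True` allocates class
counts by largest remainder instead of sampling, for tests that need the
observed frequencies exactly.  All generators are deterministic given
spec + seed.

What the generator does *not* emulate: measurement error of confocal
landmarking, body curvature (rings are perfectly cylindrical), rings of
heterogeneous size within one polyp, and any axial drift of ring spacing.
Tests passing on synthetic data therefore demonstrate correctness of the
estimators under the stated noise model, not robustness to every
idiosyncrasy of real specimens.

## Numerical and degenerate-input choices

- Angles are stored in degrees in [0, 360); trigonometry is in radians.
- Resultant lengths below 1e-12 are treated as zero (undefined mean).
- `pearson_r` requires n ≥ 3 and positive variance in both variables;
  zero variance raises a typed error rather than returning NaN.
- A constant internode series (single level or perfect spiral) makes all
  lag correlations undefined and raises a classification error; the
  pipeline maps this to "n.s.".
- The Euler stepper validates the stability bound at parameter
  construction and additionally checks every field for non-finite values
  each step, naming the field and step on failure.
- Tie-breaks: tentacle initiation at equal activator → lowest (row, col);
  argmax lag ties → smallest lag.

## Known limitations

- The simulated body does not grow; domain growth (diameter increase
  over time) is out of scope, so ring-size heterogeneity seen in real
  aboral regions is not reproduced.
- Replicate variability in the simulator is a rigid rotation of the
  pattern; it does not model biological noise in tentacle placement.
- The periodicity p-value is a t-approximation on overlapping (hence
  weakly dependent) pairs; it is a screening rule, not an exact test.
- Spiral-lattice (parastichy) analysis is not implemented; the pipeline
  only distinguishes whorled from non-whorled arrangements.
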