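# Methods

## Model

Each cell of an `n_layers × rows × cols` lattice carries an activity
`a ∈ [0, 1]`.  One timestep updates all cells synchronously: the cell's
input is the arithmetic mean of its neighborhood's activities and its next
state is the activation function of that input.  Synchronous order is what
makes a spatially uniform lattice follow the single-cell map exactly — the
homogeneity property the cobweb analysis relies on.

The activation function abstracts a neuron's firing-rate-vs-input
response.  Its first-order form has three thresholds, all dimensionless in
[0, 1]: the input window `[a0, a1]` outside which the response is zero,
and the output saturation `a2`.  The second-order form replaces the linear
rise by `a2(1 − (1 − u)^b)` with `u = (a_in − a0)/(1 − a0)`; it fixes the
upper input threshold at 1 and adds the nonlinearity exponent `b ≥ 0`
(`b = 1` is exactly the linear rule; `b = 0` degenerates to the zero map).
Outputs are clipped to `[0, a2]` against floating-point overshoot so the
state-boundedness invariant is exactly testable.

### Inverted threshold pairs

The linear rule's branches ("zero below `a0`", "zero above `a1`") cover
the entire input axis whenever `a1 < a0`, so a generic inverted pair is
read as the zero map.  The boundary family `a1 = 0` with `a0 > 0` is the
exception, read as the negatively-sloped response `a2(a0 − a_in)/a0` on
`[0, a0]`: quiescence maps to `a2`, which is what makes sustained
oscillation possible.  We initially evaluated the formula on
`[min(a0,a1), max(a0,a1)]` for *all* inverted pairs; that variant
sustains genuine, size-independent period-2 oscillations also at e.g.
`(a0, a1, a2) = (0.6, 0.1, 0.7)` (amplitude ≈ 0.24, persisting at
1024×1024 for 1000 steps), which contradicts the documented phenomenology
that oscillation requires `a1 = 0` exactly.  The branch-literal reading
adopted here restores that property and is the package's convention.

### Geometry

* Toroidal: both dimensions wrap; every cell has 8 Moore neighbors
  (9 with self in outer-totalistic mode).
* Spherical: columns wrap, rows do not; each top-row cell is connected to
  every other top-row cell (the pole) plus the three cells below it
  (columns c−1, c, c+1), mirrored at the bottom.  Corner cells have no
  extra diagonal pole links beyond this rule.  Neighborhood means use the
  actual, variable neighbor count.
* Layers: with 2 layers each cell gains the co-located cell of the other
  layer; with ≥ 3, the co-located cells of the layers above and below,
  topmost and bottommost layers adjacent.

Clamped (externally driven) cells are chosen uniformly at random without
replacement, `round(ext_fraction · N)` of them; they enter their
neighbors' averages at `ext_value` (1.0 by default) and are reset after
every update.  Clamped cells count toward the lattice mean — they are part
of the population.

## Classification

The five labels are decided from the mean-activity series `⟨a⟩(t)` (101
points by default) plus one transient snapshot:

1. **Oscillatory (2)** — the last 10 differences of `⟨a⟩` strictly
   alternate in sign with every amplitude > `osc_amp` (default 1e−3).
2. **Quiescent (0)** — steady state (mean of the last 10 values)
   < `tol_zero` (default 1e−4); **0a** if `⟨a⟩` first drops below
   `tol_zero` by `t_fast` (default 10) steps, else **0b**.
3. **Spiking (1)** otherwise; **1b** if the snapshot at `t = t_fast` has
   an axis-averaged autocorrelation length > `corr_length` (default 5)
   cells — coherent fronts — else **1a**.

All cutoffs are keyword arguments.  Stochastic sweeps run 3 seeds and
report the majority label (ties resolve to the lowest seed).  The
quiescent/spiking/oscillatory distinction is a property of the dynamics
and is invariant to boundary condition, neighborhood mode and layer count
for the representative parameter sets; the 1a/1b sub-split, by contrast,
is a convention measured on a fixed-time transient and can flip where a
geometry change retards the fronts (e.g. `(0, 0.6, 0.6)` reads 1a instead
of 1b under outer-totalistic multi-layer updates).  Tests therefore
assert cross-geometry invariance at the class level.

Representative parameter sets (linear rule, chosen from the 0.1-step
phase sweep as stable interior exemplars): 0a `(0.8, 0.9, 0.3)`,
0b `(0.0, 1.0, 0.8)`, 1a `(0.1, 0.4, 0.7)`, 1b `(0.0, 0.6, 0.6)`,
2 `(0.6, 0.0, 0.6)`.

Settling times are measured as the first step from which `⟨a⟩` (or its
period-2 envelope for oscillatory runs) changes by less than 1e−3 for 10
consecutive steps.

### Critical initial fraction

`critical_fraction` initializes a *binary* state — a fraction `f` of cells
at activity 1, the rest at 0 — because "active at t = 0" denotes an active
subpopulation, not a continuum; a thresholded-uniform variant would
confound the fraction with the activity level.  The smallest `f` whose
seed-averaged steady state is nonzero is reported per parameter set.  The
quantity only exists where quiescence is absorbing: the self-exciting
`a1 = 0` family regrows from `f = 0` and is excluded from aggregate
sweeps.  Across the spiking-class region of the 0.1 grid the per-set
minima span 5–50% (thresholdless `a0 = 0` rules and steep `a0 = 0.1`
rules sustain activity from 5% binary occupancy; these survivors were
verified to persist and grow to steady states of 0.23–0.39 at 1000
steps, so they are genuine attractors, not long transients).  The
grid-wide minimum is therefore 5%, not the ≈20% sometimes quoted for
interior "stable-region" parameter sets; `scripts/acceptance.py` reports
the measured value.

## Implementation notes

The update is a sparse row-averaging matrix (CSR) applied to the
flattened state, `a_in = W a`, followed by the vectorized activation map —
one code path for every boundary/neighborhood/layer combination, verified
against naive per-cell neighbor-list averaging built independently in the
test suite.  Quiescence is absorbing for unclamped lattices, so a run
whose maximum activity falls below 1e−15 is completed with zeros.  Every
run's randomness comes from one seed, split into independent substreams
(initial values, clamp placement) via `SeedSequence.spawn`, so adding a
consumer never perturbs earlier draws.  Default lattice 128×128,
timesteps 100 (the classification is size-invariant in our checks, and
100 steps suffice for every class's settling — measured onsets ≤ 53 at
256×256).

## Hodgkin–Huxley reference

The f–I curve motivating the activation rules comes from the canonical
space-clamped squid-axon HH model (C=1 µF/cm², gNa=120, gK=36, gL=0.3
mS/cm², ENa=50, EK=−77, EL=−54.4 mV), integrated with fixed-step RK4
(default dt = 0.02 ms; halving dt changes spike counts by ≤ 1/s).
Spikes are upward 0-mV crossings separated by ≥ 2 ms; rates discard a
100 ms onset transient.  Currents are densities in µA/cm² — the published
pA ranges of patch-clamp datasets live only in the aging generator's raw
current column, and normalization makes the CA-facing curve unit-free.
With the default 0–15 µA/cm² grid the curve shows the rheobase (between 6
and 7) and a bounded plateau; the depolarization-block upper threshold
appears only at currents far beyond this range, so the normalized curve
documents its range rather than asserting an upper cutoff.

### Runtime scaling

`benchmark_scaling` fits `T = a(N − b)^c` to wall-clock times of a fixed
number of sweeps.  Protocol: single-threaded BLAS (the claim concerns the
serial operation count), interleaved measurement rounds so load drifts
hit all sizes alike, per-round subtraction of a tiny-population baseline
(the size-independent numpy dispatch cost, which otherwise masks the
scaling at small N), per-size medians, and a log-space fit with |b|
bounded by min(N) (the raw 3-parameter fit is ill-conditioned and chases
noise).  The CA path measures `N = 2¹²…2¹⁷` cells (c ≈ 1.0); the
all-to-all HH Euler network measures N = 724–2048 neurons (c ≈ 2.0),
sizes chosen non-power-of-two (stride-aliasing slowdowns appear at 4096)
and small enough that the dense coupling matrix stays within one memory
regime — mixing cache-resident and DRAM-bound sizes inflates the
exponent.  Absolute times are hardware-specific; only the exponent is a
claim.

## Aging application

The young (`a0=0.45, a2=0.38, b=1.5`) and aged (`a0=0.29, a2=1.0, b=2.2`)
profiles are the published fits to normalized rhesus-monkey prefrontal
f–I data (inputs normalized over 30–330 pA).  The synthetic generator
draws inputs uniformly on the normalized axis, evaluates the second-order
rule at a profile's parameters and adds zero-mean Gaussian noise (default
σ = 0.02, n = 30), clipped at 0; the output-axis normalization of the
original dataset is unstated, so the generator exposes it (`max_rate`,
default 1 = already-normalized).  It emulates the threshold, rise and
saturation of real f–I clouds but not their heteroscedasticity, adaptation
or cell-to-cell variability, so parameter-recovery results bound fitting
error under clean conditions only.

Fitting is bounded trust-region least squares over `a0, a2 ∈ [0, 1]`,
`b ∈ [0, 40]` with 5 random restarts — the surface is weakly identified
near the thresholds (`a0` trades off against `b`) and single-start fits
can stall in the wrong basin.  Fits within 0.1% of a bound's span are
flagged "pinned" (the aged profile's `a2 = 1` legitimately pins).
Recovery from synthetic aged-profile clouds is within ±0.05 (`a0`, `a2`)
and ±0.3 (`b`) across 20 seeds; the young profile's smaller saturation
makes its `b` noticeably noisier at the same noise level.

The Q/F/R raster discretizes a fully-recorded run: a cell is Firing when
its activity ≥ `fire_threshold` (default 0.5) and not refractory,
Refractory for `refractory_steps` (default 1) steps after each firing
regardless of activity, else Quiescent.  These defaults are package
conventions, not canonical values, and both are parameters.  The
first-order (linear) fit of f–I data — which equalizes the two
populations and serves as a negative control — is available by fitting
with `b` fixed at 1.

## Known limitations

* The 1a/1b autocorrelation criterion and its `corr_length = 5` cutoff
  are not derivable from first principles; they reproduce the
  random-vs-exploding pattern distinction at the default sizes.
* Oscillation detection looks at the final 10 steps of a 100-step run;
  slowly-decaying alternations can classify as oscillatory at this
  horizon (they resolve to spiking/quiescent at longer horizons).
* Benchmark exponents are measured on small grids and depend on the host
  memory hierarchy; they verify scaling classes, not absolute cost.
* The spherical pole rule follows the most literal reading of
  "fully-connected top row"; alternative pole constructions (e.g. extra
  diagonal links) would change pole-adjacent dynamics only.
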