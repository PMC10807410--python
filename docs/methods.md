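# Methods

This note documents the model implemented by `plastinet`, the numerical
choices behind it, and what the test suite's synthetic experiments do and
do not establish.

## Neuron model

Neurons are Izhikevich two-variable units,

```
dv/dt = 0.04 v² + 5 v + 140 − u + I(t)
du/dt = a (b v − u),        if v ≥ +30 mV:  v ← c,  u ← u + d
```

with the regular-spiking parameter set a = 0.02, b = 0.2, c = −65 mV,
d = 8 throughout.  At these values the resting state (v, u) = (−70, −14)
is a stable fixed point; the saddle sits near −50 mV (rheobase ≈ 4
current units for sustained input), so the default noise regime produces
occasional spontaneous spikes (≈ 2 Hz for an isolated neuron, more in a
recurrent network).

The input current is `I = ξ + I_syn + I_stml`:

* **ξ** — Gaussian noise with standard deviation D = 5.5, drawn
  independently per neuron per integration step and treated as a current
  in the Euler update (i.e. the per-step membrane kick is `dt·ξ`).  This
  per-step-current convention follows the original fixed-step
  implementation style of models of this family; it is *not* a
  dt-consistent SDE discretization, so changing `dt` changes the
  effective noise intensity.  `noise_sd` is configurable.
* **I_syn** — the weighted sum `Σ_j g_j w_ij y_ij` over afferent synapses,
  with g = +20 for excitatory and −20 for inhibitory presynaptic cells.
* **I_stml** — pulsed stimulation: 3 ms pulses at 10 Hz.  The only hard
  requirement on the amplitude is that it be sufficient to excite the
  target; the default of 40 units is comfortably suprathreshold (a
  noise-free resting neuron responds to every pulse, typically with a
  two-spike burst).  An
  amplitude of ~10–20 evokes exactly one spike per pulse but is too weak
  to drive the network-level reorganization experiments; 40 is kept as
  the default and is configurable.

Inhibitory neurons are supported (`inhibitory_fraction` in the planar
builder) but default to zero, matching the demonstration experiments.

## Synapse model

Each directed synapse carries a Tsodyks–Markram short-term plasticity
state: fractions x (restored), y (active), z (inactivated) with
x + y + z = 1, and a facilitating release fraction u*.  Between spikes

```
dy/dt = −y/τ_I,   dz/dt = y/τ_I − z/τ_rec,   dx/dt = z/τ_rec,
du*/dt = −u*/τ_facil
```

with τ_I = 10 ms, τ_rec = 50 ms, τ_facil = 1000 ms.  On the (delayed)
arrival of a presynaptic spike, facilitation precedes release:
u* ← u* + 0.5(1 − u*), then Δ = u*·x moves from x to y.  The continuous
u* term is a decay (a growth sign here, which occasionally appears in
print for this model family, would diverge).  Conservation of
x + y + z is exact up to round-off (drift < 1e-9 over 10⁶ steps is
asserted in the tests).

With these constants the synapse facilitates near 1 Hz (u* builds up) and
depresses under fast drive; note that at intermediate rates (~20 Hz) the
large facilitation increment initially masks depression, so the
depression test drives the synapse at 100 Hz.

**Axonal delays** are distance/velocity with conduction velocity
50 μm/ms (configurable), rounded up to a multiple of dt and never below
one step.  Delivery uses a ring buffer indexed by step; events are never
lost or duplicated, and the buffer horizon covers the substrate diagonal.

## Long-term plasticity

STDP uses local trace variables: a postsynaptic trace s_i per neuron and
a presynaptic trace s_j per synapse, each incremented by 1 on its spike
(delayed arrival for s_j) and decaying with τ = 10 ms.  Weight updates
are event-driven and multiplicative (λ = 0.001, α = 5):

* postsynaptic spike: `w ← w + λ(1−w)·s_j` (potentiation),
* presynaptic arrival: `w ← w − λαw·s_i` (depression),

clipped to [0, 1].  For uncorrelated pre/post firing the drift balances
at w* = 1/(1+α) = 1/6; under sustained uncorrelated activity the weight
distribution collapses to a unimodal cloud around w* (≈ 0.16 ± 0.04 at
11 Hz), which matters for the stabilization experiment discussed below.

### Event ordering within a step

The simulation step applies, in a fixed documented order: (1) delayed
arrivals are popped; (2) transmitter pools update, arrivals trigger
facilitation + release and STDP *depression*; (3) synaptic currents are
summed; (4) neurons advance and reset; (5) new spikes trigger STDP
*potentiation* and activity-trace increments using the presynaptic trace
values *before* this step's own increments, then traces increment and the
spikes are queued with their delays; (6) all traces decay.  Consequently,
when a presynaptic arrival and a postsynaptic spike coincide in one step,
depression is applied before potentiation.  Spike times are reported as
the nominal time of the step in which threshold was crossed, which makes
"spike at 10 ms + 2 ms delay → arrival processed at 12 ms" exact.

## Structural plasticity (rewiring)

Every `rewire_period` (1 s) all weights are checked.  A synapse whose
weight has remained below `w_min` for at least `t_w` seconds is removed;
a weight that recovers above `w_min` resets its clock.  Each removal is
replaced immediately: the postsynaptic neuron is drawn uniformly, the
presynaptic neuron with probability ∝ exp(−d²/2σ²) around it (self
excluded), and the newborn synapse gets weight `w_new`, a fresh
transmitter state, a delay from its length, and a recorded birth time.
The synapse count is therefore invariant.  In single-connection mode a
candidate that duplicates an existing pair triggers a full redraw (up to
1000 attempts, then an explicit saturation error); in multiple mode
duplicates are allowed.  Removals are processed in synapse-index order
and rebirth draws consume the RNG in that order, which is part of the
reproducibility contract.

## Vector fields

The substrate is divided into an N×N grid of *closed* rectangular cells.
Every synapse defines a connection vector of magnitude l_ij pointing from
pre to post, anchored on the segment between the somata; a cell's field
value is the sum of the vectors of all synapses whose segment intersects
the cell (full vector per crossed cell, no apportionment).  Magnitudes:
wiring l = 1, weight l = w, activity l follows
`dl/dt = s_j δ(t − t_sp_i) − l/τ_l` with τ_l = 1000 ms by default (there
is no canonical value; the comparisons in the tests are insensitive to
it).

Segment/cell intersection uses closed-interval slab clipping, so a
segment that touches a cell edge or corner counts for every adjacent
cell.  The tests verify this against shapely's exact geometric
predicates on 10⁴ random segments; a point-sampling oracle is kept only
as a subset sanity check, because any fixed sampling density can miss
corner-grazing chords.

The default grid is N = 20.  For the small demonstration circuits the
analyses use grids whose cell size is ~22–25 μm (N = 21 for the line,
N = 13 for the radial circuit), comparable to half a connection length;
much finer grids fragment the field into cells crossed by single
near-cancelling synapse pairs, and even-N grids put the stimulated
neuron exactly on a cell corner, both of which are rasterization
artifacts rather than features of the connectome.

## Similarity and the stability protocol

Fields are compared by per-cell cosine similarity, averaged into a
scalar S.  The per-cell cosine is undefined where either vector is zero;
the default `valid` policy averages over cells where both are nonzero
(reporting the count), the alternative `literal` policy counts undefined
cells as 0 and divides by N².  Identical fields give S = 1, negated
fields S = −1 under the `valid` policy (the `literal` policy cannot reach
1 when empty cells exist, which is why the limit checks use `valid`).

The stability protocol runs one simulation, records full state snapshots
every `snapshot_every` seconds (excluding t = 0), computes the chosen
field per snapshot, and reports the mean of the off-diagonal pairwise
similarities; the reference configuration (15 000 s, every 1000 s) gives
15 snapshots and 105 pairs.  A batch runner sweeps `w_new`, `t_w` and the
connection-multiplicity mode and emits one row per run for downstream
statistics.

## Determinism and resumability

Noise is generated from counter-based Philox streams keyed by
(run seed, per-neuron noise key) and indexed by the global step number;
the rewiring RNG is re-derived per sweep from (seed, sweep index).  A run
is therefore a pure function of (network, configs, seed): repeated runs
are bit-identical, relabelling neurons merely relabels the spike log, and
a run resumed from a snapshot (which includes in-flight delayed spikes)
continues exactly like an uninterrupted one.  The inner loop is a
numba-compiled kernel; a pure-Python equivalent of the same code path is
used when numba is unavailable, and the test suite checks the kernel
against a direct composition of the per-component update functions.

## Scaled experiment configurations

The test experiments run at desk scale, chosen once as follows:

* **Calibration check**: 500 neurons on 500×500 μm, 5000 connections
  drawn with the Gaussian rule (unrestricted multiplicity, since
  duplicate rejection in single mode biases lengths upward by ~2–4% at
  this density); σ calibrated by bracketed root finding on the exact
  pair-sum expectation (2% tolerance).
* **Stimulated line**: 9 neurons, 50 μm spacing, w₀ = 0.3, centre driven
  at 10 Hz; rewiring w_min = 0.05, t_w = 5 s, w_new = 0.1.
* **Stimulated radial circuit**: two rings × 16 spokes (50 μm ring
  spacing), same parameters.
* **Spontaneous stabilization**: 100 neurons at the reference density
  (224×224 μm), k_out = 10, 2000 s with snapshots every 250 s,
  w_new = 0.06, five seeds per condition.

The staged reorganization is measured on its own timescales: the weight
field after 100 s of stimulation and the wiring field after 1000 s.
Anatomical conversion is an order of magnitude slower than synaptic
conversion because a centripetal synapse must first be depressed below
`w_min`, persist there for `t_w`, and its replacement must survive
repeated prune–redraw cycles before the anatomy aligns with the spike
flow.

## Known limitations

* The synthetic experiments use pure-excitatory networks and stationary
  noise; they do not emulate inhibition, bursty culture-like population
  events ("superbursts"), or any biological heterogeneity in neuron or
  synapse parameters.  Passing tests show internal consistency of the
  model and the analysis pipeline, not correspondence to recordings.
* Under the implemented noise convention, spontaneous activity is
  asynchronous at ~10 Hz per neuron in recurrent networks.  In this
  regime sustained uncorrelated traffic keeps all weights near the STDP
  balance point w*, the weight field is then dominated by the static
  anatomy, and STDP-only runs already score a mean pairwise similarity
  of ≈ 0.95–0.99 over thousands of seconds.  Structural rewiring adds
  anatomical turnover on top of that and so tends to *lower* the
  similarity slightly at this scale, rather than raising it: the
  stabilization contrast requires a regime with strong ongoing weight
  rearrangements (differentiated, multimodal weights driven by
  correlated population events) that these desk-scale conditions do not
  produce.  The corresponding directional test documents this honestly
  rather than asserting a vacuous pass.
* The Euler/fixed-step treatment of noise means results depend on dt;
  dt = 0.5 ms is the validated operating point.
* Rasterization tie-breaking (closed cells) double-counts boundary
  touches by design; fields on grids finer than a connection length are
  dominated by single-synapse cells and should be interpreted as such.
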