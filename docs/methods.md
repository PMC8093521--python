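# Methods

## Model

A network is a directed multigraph. Nodes are *sources* (emit threshold
trains), *convergences* (where streams collide) or *sinks* (where outputs
are recorded); edges are *neurites* with a physical length (m) and a
conduction velocity (m/s), so each edge imposes a pure delay
`latency = length / velocity`. A CAP is reduced to two numbers: the time
its activation threshold passes a reference point and the duration *L* of
the absolute refractory window trailing it. Units are SI throughout
(seconds, metres, hertz); field names state their unit and no
unit-carrying types are used, because the source material mixes m/s, Hz,
ms and μs and a single internal convention prevents drift.

Collision resolution at a node sweeps the merged arrival stream in time
order while maintaining a half-open window `[t_last, t_last + L)` anchored
at the last surviving threshold:

* an arrival within the fusion tolerance ε of the surviving threshold
  **fuses** (one survivor, earliest time kept; the window is *not* moved);
* an arrival strictly inside the window beyond ε is **annulled** and
  removed entirely (its refractory does not propagate);
* an arrival at or after the window end **passes** and opens a new window.

The boundary is deliberately half-open: refractory membrane that has just
recovered has no effect, so an arrival at exactly `t_last + L` passes (a
1e-12 s guard absorbs float roundoff in sums of latencies). Whether a fused
CAP's window should instead restart at the fused time is not determined by
the source material; anchoring at the earliest (surviving) threshold is
the choice made here and is what makes the output stream an exact
dead-time thinning of the merged arrivals. Surviving CAPs are copied onto
*every* outgoing neurite (fan-out duplicates the quantum), and every node
with incoming edges is gated identically — nothing distinguishes an axon
hillock from any other convergence point in this abstraction.

### Event-driven engine

`simulate` advances thresholds edge-by-edge on a priority queue of arrival
events ordered by `(time, node id, edge id)` — there is no global clock;
all timing derives from conduction latencies, and the lexicographic
tie-break makes simultaneous arrivals deterministic (identical inputs give
bit-identical collision logs). Thresholds still in transit at the horizon
are dropped from outputs but appear in the per-edge transit log, which is
what the in-transit (λ) queries read.

### Dense-time oracle

`oracle_simulate` is an independent brute-force check: time advances in
fixed steps `dt`, each neurite is a 1-D lattice of membrane points spaced
`velocity · dt` apart, and a point fires only outside its own refractory
window. Interior lattice points have a single upstream neighbour and only
relay trains already separated by ≥ L, so their gate never closes; they
reduce *exactly* to an integer delay of `round(latency/dt)` steps, and the
loop gates at the shared node points only. This keeps the oracle an
algorithmically independent path (discrete time stepping, no priority
queue, no fusion bookkeeping — same-step deliveries simply fire once)
while running inside a test budget. Fusion and annulment both remove the
later threshold and neither moves the window, so oracle output trains must
match the event-driven engine per threshold within one `dt`; equivalence
tests generate edge lengths as integer multiples of `velocity · dt` and
snap input times to the `dt` grid so that the comparison is exact up to
float roundoff for any seed, rather than probabilistically within `dt`.

## Parameters

| parameter | default | unit | rationale |
|---|---|---|---|
| refractory `L` | 1e-3 | s | observed absolute refractory scale; network-wide with per-neurite override |
| fusion tolerance ε | 1e-5 | s | threshold activation resolves on a 1–10 μs scale; must satisfy ε < L |
| conduction velocity | 0.3 | m/s | unmyelinated CNS fibre scale (interferometric measurements); always an explicit parameter — the simulator does not arbitrate between the cited velocity scales |
| oracle `dt` | 1e-6 | s | must be ≤ ε/10 |
| receptor band | 2–100 | Hz | observed bipolar-cell discharge range |
| receptors per bipolar | 12 (≤ 25) | — | retinal convergence anatomy |
| peak delay mean | 2e-4 | s | typical threshold-to-peak interval |
| peak delay sd | 1e-4 | s | spike peaks are unreliable below ~0.1 ms; exposed, not claimed measured |

### A note on the 100 Hz ceiling

The maximum CAP frequency is set by the refractory period, `f_max = 1/L`.
The commonly quoted triple (0.3 m/s, 100 Hz, 1 ms) is internally
inconsistent — 0.003 m of refractory membrane at 0.3 m/s lasts 10 ms, and
a 1 ms dead time caps at 1000 Hz. This package keeps the dimensional
identities exact: `refractory_metrics(v, f_max) = (v/f_max, 1/f_max)`, the
output ceiling is always `1/L`, and analyses that want the 100 Hz ceiling
set `L = 10 ms` explicitly. The network default stays `L = 1 ms` (the
observed absolute refractory scale).

## Retinal mean sampling

`build_retina` realises *n* receptor sources converging on one bipolar
node relayed to an RGC sink, equal neurite lengths (default 3 mm) unless
overridden. Intensities in [0, 1] map affinely onto [f_min, f_max] — the
minimal assumption consistent with a proportional intensity→rate relation;
the map is pluggable. Receptor trains are periodic with independently
drawn uniform random phases (seeded): desynchronised arrivals are what the
mean-sampling argument requires, and no phase distribution is specified by
the source material. Receptor polarity (cones hyperpolarise) is abstracted
away — only timing matters here. No exact formula is claimed for the RGC
rate as a function of receptor rates: the simulated rate and the x→z gap
statistics (`mean_sampling_gap`, the interval from refractory end to next
threshold) are both exposed, and tests assert the qualitative properties —
ceiling at `1/L`, permutation symmetry, monotonicity in receptor
frequency — rather than a closed form.

## Worked network fixture

Only three relations pin the demonstration network: λ(a→c) = 3 at the
base frequency, route λ(a→e) = 6, and latency(a→c) = ½ · latency(b→e).
The fixture realises them as `a→c` (3 phase lengths), `a→m` (3), `b→m`
(3), `m→e` (3) and `b→d` (4, a free choice), with `m` the convergence.
The frequency-doubling experiment drives source *a* alone (a second driven
input would interfere at `m` and thin the stream, changing the clean
3→6 / 6→12 occupancy arithmetic). "Frequency of (a) to (c)" is
interpreted as the in-transit CAP count on the segment — it equals λ and
is dimensionless; sink discharge frequency is reported separately.
In-transit counts are read at `transient + period/2` (between arrival
instants) where `transient = 2 ×` the longest route latency; sink
frequencies use the renewal estimator `(n−1)/(t_n − t_1)` over the
post-transient window, which is unbiased for periodic trains regardless of
window alignment.

## Jitter experiment

`timing_error_experiment` simulates the same Poisson-driven network twice
per repetition: once with activation thresholds as the timing markers, and
once with spike peaks, i.e. thresholds plus a positive lognormal delay
(right-skewed, positive support; no distribution is prescribed by the
source material, only that peaks drift and thresholds do not). Divergence
is the fraction of positions at which the two time-ordered (node, outcome)
collision sequences differ, compared over the common prefix — a rigid time
shift (zero jitter) may truncate one sequence at the horizon but cannot
reorder or flip outcomes, so it registers exactly zero. Sweeps over the
peak-delay sd reuse one seed so the underlying normal draws are shared and
only the jitter magnitude varies, which makes the divergence-vs-sd trend a
coupled comparison rather than independent Monte-Carlo noise.

## Numerical choices and problem sizes

* Continuous (float) time in the event engine; discretisation lives only
  in the oracle.
* Window boundary guard 1e-12 s; λ counts snap to integers within 1e-9.
* Graphs may contain cycles (the engine never assumes feedforward); the
  shipped fixtures are acyclic.
* Test problem sizes: oracle-equivalence uses 20 random networks of ≤ 6
  nodes, 150 Hz Poisson drive over 50 ms at `dt` = 1 μs; the retina sweep
  uses 12 receptors over 5 s per frequency; the jitter sweep uses 20
  repetitions of 2 s at 100 Hz. These sizes give exact (count-based) or
  well-separated (rate-based) comparisons while keeping the suite fast.

## What the synthetic inputs do and do not show

Generated drives are periodic or dead-time-censored Poisson trains —
stationary, independent across sources, with stated phase distributions.
Real receptor and cortical spike trains are none of these (adaptation,
bursting, correlated noise, non-stationary stimuli), so passing tests
validate the collision calculus and its implementation, not the biological
claim that retinal coding works this way. The Lymnaea electrophysiology
that motivates the threshold-vs-peak contrast enters only as the
parametric jitter model above; no biophysics (membrane currents, soliton
mechanics, synaptic chemistry) is modelled, antidromic within-fibre
collisions are out of scope, and information accounting is combinatorial
(state counting), not Shannon entropy of stochastic trains.
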