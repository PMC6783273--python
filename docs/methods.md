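# Methods

## Model

`neurogrowth` simulates the activity-dependent development of a planar
neuronal culture with `n` neurons on a square torus of side `L` (defaults:
n = 500, L = 1000 µm, i.e. 1 mm² at realistic culture density; the torus
removes boundary effects).  Each neuron i is a soma at position S_i with a
circular *neurite field* of radius R_i standing in for its combined
axonal/dendritic arbor (no axon/dendrite distinction, excitatory units
only).

**Connectivity.**  The directed weight from presynaptic neuron k onto
postsynaptic neuron i is the field-overlap area normalized by the
presynaptic field,

    W_ki = s · |A_i ∩ A_k| / |A_k| ,      s = 0.1,

computed with minimal-image center distances and the exact circle–circle
lens formula.  The normalization makes W asymmetric but preserves the
reciprocity identity W_ki·|A_k| = W_ik·|A_i|.  Autapses are excluded (the
self-overlap ratio is identically 1 and would inject a constant bias s into
every neuron's input; a config switch restores them).

**Activity.**  A slow state variable x_i ∈ [0, 1] — a proxy for
intracellular Ca²⁺ integrated over minutes — obeys

    dx_i/dt = −x_i/τ + (1 − x_i) · Σ_k W_ki f(x_k),
    f(x) = 1 / (1 + e^{(θ−x)/a}),            τ = 1 min, θ = 0.5, a = 0.12.

The population step is synchronous: all rates are evaluated on the
pre-update state.

**Integration scheme.**  The simulation clock advances in dt = τ = 1 min
steps.  Within a step the input I_i = Σ W_ki f(x_k) is held constant, which
makes the x-equation linear; by default it is therefore solved *exactly*
over the step,

    x' = x_∞ + (x − x_∞) e^{−λ dt},   λ = 1/τ + I,   x_∞ = I/λ,

preserving the continuous dynamics' unconditionally stable fixed point
x* = I/(1+I).  A plain explicit Euler step (`integration_scheme="euler"`,
x' = (1−x)·I at dt = τ, clamped to [0, 1]) is also available.  It is not
the default because at the inputs the homeostatic target requires
(I* = x*/(1−x*) ≈ 1.22 > 1) the Euler map's fixed point is unstable: the
population falls into a spurious period-2 oscillation (x alternating
between ≈0 and ≈1, time-averaged rate locked near 0.45) in which neurite
fields are never pruned — an artifact of the discretization, not a
behavior of the model equations.

**Homeostatic growth.**  Fields grow toward a firing-rate set-point ε:

    dR_i/dt = (1 − 2/(1 + e^{(ε−f_i)/β})) · ρ_growth,
    ε = 0.6, β = 0.1, ρ_growth = 4 µm/day.

Growth is maximal for silent neurons, zero at f = ε, and turns into
pruning above it; radii are floored at 0 (a fully pruned neuron is
disconnected but can regrow).  Per-day rates are divided by 1440 to
per-minute increments.

**Migration.**  Somata move with impulse

    |dS_i| = e^{µ f_i} · ρ_migration,      µ = −15, ρ_migration ∈ [0, 300] µm/day,

so movement is strong while a neuron is inactive and negligible at the
set-point (e^{µε} ≈ 1.2·10⁻⁴).  The direction mixes a *directed* component
— the input-weighted vector sum of unit bearings toward presynaptic
neurons — with a cached random unit vector refreshed every 10 min; both
components are normalized, weighted (random weight p = 0.9 by default;
which component p weights is a genuinely open convention, so a switch
`p_weights_random` exposes the other reading) and the sum renormalized.
With zero presynaptic drive the random component alone is used.  The
sign of the directed component is likewise conventional — unit bearings
toward inputs summed positively (attraction) or negatively (repulsion);
biologically migration follows the leading neurites toward presynaptic
partners, so attraction is the default and
`migrate_toward_input=False` exposes the opposite sign.

Each neuron also jitters uniformly in a disc whose radius is the cell-body
radius (6 µm) scaled by the same e^{µf} decay, redrawn every step — this
lets somata slip past each other in 2-D.  Per step, neurons are processed
in a freshly shuffled order; a proposed position (directed move + jitter,
wrapped onto the torus) that would come closer than d_min = 12 µm to any
other soma is discarded, so the hard-core constraint established at
seeding (rejection sampling of uniform positions) is invariant throughout
development.

All randomness (seeding, shuffles, jitter, direction refreshes) is drawn
from one seeded NumPy generator in a fixed, position-independent order, so
runs are bit-reproducible and exactly translation-invariant; a
configuration with migration and jitter both zero consumes no randomness.

**Development span.**  The default run length is 56 days.  Under the
default parameters a migration-free network stays quiescent until the mean
field radius reaches the critical overlap scale (Σ_k W_ki ≈ 2.9, about
135 µm at 500 neurons/mm²), which at 4 µm/day happens around day 35;
activity then ignites, overshoots (mean radius peaks near 150 µm), and
pruning returns the population rate to ε and the mean radius to its
equilibrium near 114 µm within roughly another fifteen days.  56 days
covers the full ignition–overshoot–pruning arc with margin for
seed-to-seed variation in the ignition time (and matches the ≥45-day span
over which cultured networks are typically followed); migration
accelerates the onset by locally concentrating neighbors.

## Network read-outs

**Clustering index (CI).**  A hard-core variant of the Clark–Evans index:
the observed mean wrapped nearest-neighbor distance divided by the
expectation for *random* patterns with the same point count, domain and
minimal inter-point distance.  Because the classic Poisson expectation
1/(2√λ) ignores the exclusion radius, the null expectation is computed by
Monte-Carlo resampling of the identical hard-core seeding procedure
(default 200 repetitions; the null mean can be precomputed once and shared
when scoring many patterns).  CI < 1 indicates clustering, CI > 1
grid-like regularity; hard-core random patterns score 1 by construction.

**Giant-component robustness.**  Connectivity support is taken undirected
(any W > 0 in either direction — overlap is geometrically symmetric).  For
a removal fraction φ, round(φ·n) random nodes are deleted and the largest
connected component is measured as a fraction of the surviving nodes,
averaged over repetitions (default 1000).  Modular networks fragment
faster.

**Modularity.**  W is symmetrized to (W + Wᵀ)/2 and Louvain community
detection (networkx implementation, resolution γ = 1) is run with a
configurable number of restarts (default 10, Louvain being
order-dependent); the best weighted Newman Q is reported.  Q = 0 for one
community, 1 − 1/k for k equal disconnected modules, ≈ 0 (empirically
|Q| ≲ 0.03 at n = 200) for dense iid-weighted graphs.

## Spike analytics

Operating on per-electrode spike-time tables (seconds):

* **Bursts** — maximal runs with consecutive inter-spike intervals
  strictly below 100 ms; at least 2 spikes (a single spike is not a
  series; configurable).
* **SBEs** — periods where at least T electrodes burst simultaneously,
  T = ceil(10% of active sites) clipped to [3, 20]; an *active site* is an
  electrode with ≥ 1 spike in the session.  Coincidence is resolved by an
  exact event sweep over burst start/end times (no discretization; at a
  tie, starts are processed before ends so instantaneous overlaps count).
  Cores are padded by 25 ms on both sides for build-up and fading;
  extended events that overlap are merged, so every spike belongs to at
  most one SBE.
* **Session statistics** — AFR (total spikes / duration / active sites),
  SBE rate (events/min), SBE strength (mean spikes per SBE / active
  sites), PFR (exact sliding-maximum of the 0.2 s boxcar count of the
  merged train within the extended event, / kernel / active sites; the
  session value is the mean over its SBEs), network synchrony (mean
  pairwise Pearson correlation of 30 ms binned counts; zero-variance
  electrodes excluded).  Undefined quantities (no active sites, zero
  baseline) are NaN, never 0.
* **Treatment effects** are percent changes of a chosen statistic against
  a baseline session; **developmental pooling** averages per-recording
  statistics in DIV windows of increasing width (3–5, 6–9, 10–14, 15–20,
  21–27, 28–35, 36–44, 45+) reporting mean, SEM (ddof 1, NaN for
  singletons) and n.

## Calcium gain model

ΔF/F is computed against a running 8th-percentile baseline over a 30 s
window (robust to transients shorter than the window; percentile and
window configurable), at the 25 Hz imaging frame rate.  Per SBE, the peak
ΔF/F within 200 ms of the electrophysiologically detected onset (snapped
to the nearest frame) is paired with the event's PFR.  The gain law

    ΔF/F = e^{k·PFR} − 1

is fitted by Nelder–Mead least squares from k₀ = 0.1 (the 1-D objective is
smooth; the simplex search mirrors common practice and recovers noiseless
exponents to 1e-6).  Per-event Ca²⁺ influx is estimated as e^{k·PFR} − 1
with default k = 0.11 per Hz, and long-term influx as the sum over all
events per hour.  Because the gain is convex in PFR, few strong events
produce more influx than many weak ones at equal spike budget — the
mechanism by which long-term influx can converge across architectures with
opposite SBE-rate/PFR trends.

## Synthetic generators

* `gen_point_pattern` — hard-core random (identical to network seeding),
  square lattice, or Gaussian clumps with multinomial-uniform occupancy
  and the hard core enforced; these produce CI ≈ 1, > 1, < 1
  respectively.
* `gen_spike_recording` — independent background Poisson spiking per
  electrode plus SBEs at Poisson times; each event places a fixed number
  of spikes uniformly within its width (default 0.15 s, below the 0.2 s
  boxcar kernel so the expected detected PFR is
  sites·spikes/kernel/active-sites) on a random electrode subset.  The
  latent event list is returned for ground-truth comparisons.
* `gen_ca_pairs` — PFR uniform over a range, amplitudes from the gain law
  with multiplicative Gaussian noise (CV 0.1 by default), truncated at 0.

What the generators do *not* emulate: refractoriness and spike-sorting
artifacts, within-burst rate profiles (build-up/fading are uniform),
electrode-distance-dependent burst propagation delays, slow developmental
drift within a session, and imaging noise structure (bleaching, motion).
Passing recovery tests therefore demonstrates correctness of the detectors
and estimators under the stated statistical model, not robustness to every
failure mode of real MEA or imaging data.

## Numerical choices and degenerate inputs

* Distances use the per-axis minimal-image convention on [0, L)²;
  nearest-neighbor queries use a periodic KD-tree.
* The lens formula clips acos arguments to [−1, 1] and floors the
  triangle-area radicand at 0 against roundoff near tangency.
* Zero-radius fields have zero area: their rows of W are zeroed without
  division errors and they receive no overlap.
* Hard-core rejection sampling raises after 1000·m failed candidate draws
  (infeasible density) rather than looping forever.
* Move rejection leaves the neuron in place for that step; the shuffled
  processing order prevents index-order bias.
* The boxcar peak uses closed windows anchored at spike times — the exact
  maximum of the count process, not a grid approximation.
* Threshold rounding for SBE coincidence applies ceil before clipping.
* The gain fit guards against overflow for extreme trial exponents by
  assigning a large finite residual.

## Known limitations

* The simulator is O(n²) per step (dense overlap matrix); 500 neurons ×
  tens of simulated days is comfortable on one core, but much larger
  networks would need neighbor lists.
* CI inherits Monte-Carlo error from the null (≈ 0.5% SD at 200
  repetitions, m = 500); the closed-form hard-core expectation is left as
  an extension point.
* Louvain is a heuristic; restarts mitigate but do not eliminate the
  chance of a sub-optimal partition on adversarial graphs.
* Scaled-down runs preserve density, not absolute network size; finite-size
  fluctuations are larger, and because overlaps use the planar lens formula
  with minimal-image center distances, the true toroidal overlap is
  underestimated once field radii approach half the domain side.  On small
  domains this raises the effective ignition radius and delays activity
  onset (e.g. ignition near day 36 at 100 neurons / 447 µm but near day 47
  at 60 neurons / 346 µm); tests at reduced scale extend their simulated
  span accordingly.
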