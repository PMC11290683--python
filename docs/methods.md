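# Methods

## Model overview

`slowwave` simulates one cortical hemisphere as a triangulated sphere with a
cortical column at every vertex.  Each column contains six layers (L2, L3,
L4, L5a, L5b, L6) with one excitatory (PY) and one inhibitory (IN) map-based
neuron per layer; an optional thalamus adds core and matrix relay (TC) and
reticular (RE) Hodgkin–Huxley cells on a coarser aligned sphere.  The
network alternates between a wake state (tonic irregular firing) and a
slow-wave-sleep state (global ~0.2–0.3 Hz Up/Down alternation) through a
small set of parameter changes: the PY leak and slow-adaptation strengths
(`p_L`, `p_D`), cortical AMPA/GABA conductances, and the thalamic potassium
leak.

### Cortical neurons

PY cells are discrete-time maps advanced in 0.5 ms steps with four
variables: `x` (fast voltage, membrane potential `V = 50x − 15` mV), `y`
(slow ion-channel drive), `u` (slow hyperpolarizing-current activation) and
`k` (input sensitivity).  A spike is flagged whenever `V > 0.1` mV.  The
total input current combines synaptic input, a persistent Na⁺ current
(sigmoidal in `x`, half-activated at `x = −0.99`), a slow hyperpolarizing
current `−p_D·u·(x + 1.2)` whose activation `u` grows by `δ = 0.24` on each
spike upstroke, and a leak `−p_L(x − (σ·p_L − 1))`.  IN cells are
single-variable maps with clipped input and a two-step spike condition.

Three points where the published description of this model family is
ambiguous are resolved as follows (each is configurable):

* **Resting-potential term.**  The slow drive and the leak reversal use
  `σ·p_L`.  This puts the uncoupled resting potential near −70 mV awake and
  −82 mV asleep — sleep hyperpolarizes the cortex, as the leak increase is
  meant to do.  (The alternative reading `σ/p_L` yields resting potentials
  below −130 mV and inverts the wake/sleep ordering.)
* **Sensitivity switch.**  `k` adopts the high-sensitivity value `K1` when
  `x` crosses above −0.5 (Up state) and the low value `K0` when `x` falls
  below −1.  With the opposite orientation a cell that enters an Up state
  has spike-branch gain `K0 = 0.0025` and can never reach the firing branch
  again until hyperpolarized below `x = −1`; the network then freezes in a
  depolarized silent state.  The orientation is exposed as
  `MapParams.k_printed_form`.
* **Input floor.**  The fast-map input term `β_x·I_total` is clamped below
  at `10⁻⁴`.  The clamp is a stability guard: the map diverges under large
  negative fast input.  Hyperpolarizing currents act through the slow
  variable `y`, whose drive is not clamped.  For the same reason the
  sub-threshold map branches are capped at the plateau entry (−0.4), so
  that extreme drive cannot skip the spike upstroke where the per-spike
  adaptation increment applies; the cap is inactive in physiological
  regimes.

### Synapses

AMPA, NMDA and GABA_A conductances follow first-order schemes: per-step
decay `γ_g = 0.995`, an increment `d·G_syn·w` on each presynaptic spike, and
(for AMPA) spontaneous miniature events.  Depression multiplies `d` by 0.05
on every presynaptic spike and the deficit `1 − d` recovers at 0.005 per
step (τ ≈ 100 ms); NMDA depression holds on spikes and recovers with rate
`5·10⁻⁵`.  (The recovery is written in the slow "deficit-relaxation" form
for all receptors; a literal one-step recovery would make depression inert
and admits a pathological non-adapting ~600 Hz network attractor.)  The NMDA
conductance is additionally gated by a sigmoidal magnesium-block factor,
half-open at −25 mV.

**Normalization and compensation.**  The tabulated `G_syn` values are
per-synapse conductances.  Each synapse's effective weight is its weight
factor times the ratio of the *intact* to the *current* per-neuron
per-receptor incoming-factor sum.  In the intact model the ratio is 1 and
per-cell input grows with in-degree (structure matters); after an ablation
the surviving synapses are scaled up so that every neuron's total synaptic
budget returns exactly to its intact value.  This reproduces the
compensation used by the density and radius manipulations, and the identity
holds to machine precision (asserted in the tests).  Strength-scaling
manipulations deliberately bypass the compensation.

**Minis.**  Spontaneous AMPA events drive Down→Up nucleation.  The maximal
rate `μ̄ = 500` events/s is interpreted per target neuron per receptor, with
the rate modulated by the mean of the per-presynaptic-cell activity factor
(20 % immediately after a presynaptic spike, sigmoidal recovery with
midpoint 175 ms).  Each event adds the neuron's mean per-synapse mini
conductance, scaled by the same compensation ratio as evoked transmission,
so the total mini drive is homogeneous across cells and invariant under
ablation.  The engine aggregates the per-synapse processes into one Poisson
count per neuron per step and refreshes the modulated rate every 4 steps
(2 ms, against a 175 ms modulation timescale).

### Thalamic cells

TC and RE cells are single-compartment Hodgkin–Huxley models (fast Na⁺/K⁺
spike currents with a −50 mV kinetic shift, a low-threshold Ca²⁺ current
generating rebound bursts, a K⁺ leak set by the wake/sleep state, and for
TC cells the hyperpolarization-activated cation current), integrated with
RK4 at 0.02 ms inside each 0.5 ms map step.  The formulations follow the
standard published relay/reticular single-cell models; the slow-oscillation
results do not depend on them (the cortex sustains the oscillation with the
thalamus detached, and the scaled-down study runs detach it).

## Network generation

The cortical sheet is an icosphere: `10·4^L + 2` columns at subdivision
level `L`, scaled so the maximum geodesic distance is 226.1 mm, with an
8.49 % polar cap masked as medial wall (870 of 10,242 columns at level 5).
Geodesics are exact great-circle arcs on the built-in spheres; generic
user-supplied meshes fall back to heat-method geodesics.  A furthest-point +
Lloyd procedure partitions the active columns into spatially contiguous,
approximately equal-area parcels (default 180 at full resolution), and each
parcel receives a hierarchy index in [0, 1] — by default the normalized
projection of its centroid on a configurable gradient axis, a smooth
myelination-like surrogate; real per-parcel tables can be supplied instead.

Long-range PY→PY connectivity is generative: fiber length is a rational
map of geodesic distance, `F(x) = (295.6x − 2256)/(x + 69.4)`, floored at
the geodesic distance itself; connection probability is
`0.17·exp(−fiber/23.4 mm)` plus an optional parcel-pair residual term.
Connections are classified by the pre/post parcel hierarchy difference
(within-parcel, weak/strong feedforward/feedback, split at the median
absolute difference), originate in L3 (feedforward) or L5b (feedback), and
by default innervate all six layers of the target column (the class-by-layer
weight tables are identity-initialized configuration slots).  Conduction
delays are proportional to fiber length — 40 ms at 226.1 mm — rounded up to
0.5 ms steps.  The canonical within-column circuit couples the layers
(L4 receives within-column excitation from L6 only), inhibition is strictly
local and same-layer (own column at double weight plus first- and
second-order neighbors), the reciprocal PY→IN drive pools over the same
neighborhood, and excitatory synapses within 0.1 mm are strengthened
five-fold.

**Resolution-invariant scale-down.**  At reduced mesh resolution each
simulated column stands for `10242/n` full-resolution columns, so the number
of synapses drawn per ordered column pair is Poisson with mean
`(10242/n)·p` rather than Bernoulli(`p`).  This preserves the per-cell
in-degree statistics that the dynamics depend on (at full resolution it
reduces to the plain kernel).  Without the correction an ico3 hemisphere has
a long-range in-degree of ~3.5 — the regime in which even the full-scale
model loses slow waves — and the distance distribution of connections is
unchanged by the correction.

## Calibration

The absolute synaptic strength is a free parameter of the model family; the
published per-synapse conductance tables fix only the relative wake/sleep
and receptor ratios.  The package's default gain (`RunConfig.syn_gain`)
was calibrated once, at the default study scale (ico3, full-size geometry,
thalamus detached), to the qualitative target regime: the sleep state
produces global slow waves that sweep the hemisphere and silence it in
between, and the wake state fires tonically in the physiological range.
All quantitative results (frequencies, amplitudes, participation, response
to the manipulations) are then measured, not tuned.  Near the chosen
operating point the slow-oscillation frequency is nucleation-limited and
varies noticeably between seeds (about ±0.06 Hz around ~0.25 Hz for 60 s
runs); multi-seed averages are used wherever a frequency is reported.

## Analysis conventions

* **Global Up states:** local maxima of the layer-2 LFP (mean L2 PY voltage
  × 20) with ≥ 500 ms separation and prominence ≥ half the signal range;
  amplitude = peak minus the lowest point before the next peak; frequency =
  mean inverse inter-peak interval.
* **Per-cell states:** Up above −65 mV, Down below −68 mV; same-kind states
  closer than 100 ms are merged, then states shorter than 100 ms removed.
* **Onsets/offsets:** per event, the window spans the Down-state troughs of
  the (20 ms-smoothed) mean voltage immediately flanking the peak; per-cell
  onset is the first Up entry in the window, the offset the first Down entry
  after it, both referenced to the earliest cell; synchrony is the standard
  deviation of the pooled latencies.
* **Participation:** percent of non-medial-wall columns with an onset.
* **Propagation speed:** origin = column minimizing summed geodesic distance
  to all columns with onset < 10 ms; onset regressed on distance within
  150 mm; speed = inverse slope (reported in mm/s) when R² > 0.25.
* **Regularity:** inverse approximate entropy (m = 2, r = 0.2·SD, signals
  resampled to 100 Hz, 1/ApEn capped at 10³) of per-parcel LFPs; regime
  bands default to mixed = mean regularity 4–12.
* **Coherence:** parcel-mean voltages (all layers, PY and IN) with white
  noise at SNR 5; second-order resonator filterbank (default 0.5–20 Hz in
  0.5 Hz steps, bandwidth max(0.5 Hz, f/4)); analytic signals via Hilbert
  transform; magnitude-squared coherence from the cross-spectral matrix;
  Fisher z (atanh√MSC) for averaging; per-band OLS of log coherence on
  fiber distance over 0–100 mm gives λ = −1/slope and α = exp(intercept);
  functional connectivity thresholds the SO-band (< 2 Hz) average at 0.3
  (percent connected) and counts Louvain communities.  The adaptive epoch
  sampler accumulates random 1-minute chunks (1.5 s padding trimmed after
  filtering), rejects minutes whose CMD to the running estimate exceeds the
  running mean by 3 SD, stops when the cumulative estimate moves by less
  than 10⁻⁵ CMD, and averages ten repetitions.

## What the synthetic generators do and do not emulate

The built-in surface is a geometrically regular sphere: real cortical
sheets are folded, so their geodesic and fiber-length distributions are
broader at short range and the medial wall is not a circular cap.  The
hierarchy gradient is a single smooth axis rather than the empirical
myelination map, and no parcel-pair residual connectivity ships by default —
the generated connectome is purely distance-dependent, which concentrates
connections at shorter fiber lengths than a tractography-derived table
(about 90 % within 100 mm fiber distance at ico4, versus ~80 % with the
empirical residual term included).  Passing tests on these generators
demonstrates the mechanics of the model and analyses, not agreement with
any particular subject's anatomy; all generator inputs (mesh, parcel
table, hierarchy table, residual matrix, pair masks) accept real data.

## Problem sizes

The default study scale is an ico3 hemisphere (642 columns, 587 active,
7,704 cortical cells, ~3·10⁵ synapses) with full-size geometry, chosen
because per-neuron normalization and the resolution-invariant kernel make
the dynamics approximately scale-free; ico4/ico5 are available through the
same configuration.  The test suite runs one 60 s seed per heavy condition
and 45 s regime comparisons; `scripts/acceptance.py` runs the full
protocol (three 60–90 s seeds per condition) in roughly a quarter hour.

## Known limitations

* The slow-oscillation frequency near the operating point is sensitive both
  to the realization of the mini process and, more strongly, to the
  realization of the connectome draw: at the default 642-column scale,
  different kernel-draw seeds produce pacing anywhere from silence through
  ~0.25 Hz to ~0.8 Hz at the same parameters.  At this size the Down-state
  duration is governed by whichever local cluster happens to recover first
  (an extreme-value effect that self-averages only on much larger meshes),
  so quantitative frequencies should be read per-realization, and
  manipulations should be compared within a fixed network realization.
* IN map cells have a hard firing threshold with little dynamic range —
  they are nearly binary units — so inhibitory rates during Up states are
  biologically high.
* The bimodal voltage histogram of the sleep state has a dominant Down mode
  and a broad Up plateau; the Up-state occupancy at the scaled-down size is
  lower (≈ 10 %) than in full-scale traces.
* Small planar patches at true (ico5-equivalent) column density flicker
  between Up and Down faster than the whole hemisphere oscillates: global
  pacing requires the hemisphere-scale wave/refractory loop.
* HH thalamic cells are ~50× more expensive per cell than map cells; runs
  with the thalamus attached are practical only on small meshes or short
  durations.
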