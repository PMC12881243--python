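# Methods

`casim` simulates a brain-constrained network of twelve cortical areas —
auditory (A1, AB, PB), articulatory (M1i, PMi, PFi), visual (V1, TO, AT)
and dorsolateral motor (M1L, PML, PFL) — in which Hebbian plasticity
carves out distributed cell assemblies (CAs) during word learning.  The
areas PB, PFi, AT and PFL are multimodal connector hubs; A1, M1i, V1 and
M1L are the primary (stimulated) areas.  This note documents the model
equations, the numerical backends, the protocol defaults and their
rationale, and the known limitations of the scaled-down study
configuration the tests exercise.

## Units and dynamics

Each area is a 25×25 toroidal grid of excitatory spiking cells, a
matching grid of graded mean-field inhibitory cells, and one scalar
global-inhibition unit.  All state variables are leaky integrators,

    tau dV/dt = −V + k1 (I + k2 η),

with uniform white noise η ∈ [−0.5, 0.5].  The net current of an
excitatory cell is

    I = −k_G G_A + Σ_classes s_c Σ_edges w φ_pre(t − delay) + drive + A_noise η,

with class strengths s_EE = 500, s_IE = 1500, s_E→GI = 1, k_G = 65, and
delays of one excitatory step for E→E and half a step for all other
classes.  Excitatory output is binary with subtractive adaptation:
φ = 1 iff V − ψαω > thresh, with ψ = 0.872, thresh = 0.18 and the
adaptation trace ω a leaky integral of φ (τ_adapt).  The adaptation
gain α is not fixed by the parameter tables of this model family; it is
a configuration value with default 1.0 and enters only as the product
ψα.  Spiking membranes reset to 0 (`spike_reset`, exposed as a flag).
The membrane value used for the spike decision, for plasticity and for
recorded traces is the pre-reset value of the current step.

Inhibitory cells follow the same integrator with k1 = 1, no noise and no
adaptation; their graded output is the rectified membrane potential
(`max(V_i, 0)`), an interpretive choice documented here because the
output nonlinearity of the mean-field pool is otherwise unspecified.
The global unit integrates the area's total spike count (τ_glob) and
inhibits all 625 excitatory cells uniformly — an area-wide
winner-take-all mechanism.

## Connectivity

Excitatory-to-excitatory connections, within and between areas, are
drawn by independent pairwise Bernoulli trials with probability given by
a bivariate Gaussian of the toroidal offset, truncated to a 19×19 window
(a hard cut; the kernel is never evaluated outside the window):

* local E-E: σ = 3.2, k_C = 0.15 (expected out-degree 9.45 without
  autapses, 9.60 with; autapses are excluded by default and exposed as a
  flag, since the published mean of 9.5 lies between the two
  conventions);
* between-area, within-system: σ = 9, k_C = 0.13 (expectation 33.27);
* between-area, cross-system: σ = 9, k_C = 0.065 (expectation 16.63).

Initial E-E weights are uniform on [0, 0.1].  E→I connects the full 5×5
neighbourhood deterministically with the Gaussian kernel value
(σ = 1.42, amplitude 0.295) as the weight; the parameter tables list
0.295 both as the kernel amplitude and in the strength column, and we
read these as the same number — applying it twice would square the
amplitude.  I→E is one-to-one at identical coordinates, E↔GI all-to-one
and one-to-all with unit weights.

The inter-area link table follows the standard architecture of this
model family: next-neighbour chains within each system
(primary–secondary–hub), a jumping link from each primary to its hub,
cross-system jumping links between the secondary/hub areas of the two
perisylvian and of the two extrasylvian systems, and long-distance links
among all six hub pairs.  The table is data (editable in the
configuration file), and every link instantiates a reciprocal pair of
projections.

## Two numerical backends

* **felix mode** — forward Euler, one update per excitatory step
  (dt = 1); inhibitory and global units are updated first from the
  previous step's spikes, excitatory units then use that same-step
  inhibition.
* **delay mode** — exact (exponential) integration on a half-step grid
  (dt = 0.5) with explicit delays.  We schedule inhibitory and global
  updates on half-integer ticks and excitatory updates on integer ticks,
  with E→E transmission lagging two ticks and all other classes one
  tick.  Under this staggering, the inhibition reaching an excitatory
  cell at step t is — exactly as in felix mode — a function of the
  spikes at t − 1, so the two backends realise the same dependency
  graph and differ only in their per-step decay factors (1 − 1/τ versus
  e^(−2/τ)).  This is a deliberate design choice: it makes the
  single-neuron equivalence between the backends an exact mathematical
  statement rather than an approximate one.  `matched_delay_params()`
  returns delay-mode time constants whose exact-integration decay equals
  the Euler decay, under which the two backends produce bit-identical
  spike trains; with the published (unmatched) table constants they
  differ at second order in the step size.

Time constants are given in update units: steps for felix mode
(τ_exc/τ_inh/τ_glob/τ_adapt/τ_favg = 2.5/5/12/10/30) and half-step ticks
for delay mode (5/10/24/20/30) — the doubled values denote the same real
time.  The rate-estimate constant τ_favg is 30 in both columns of the
source tables and is kept verbatim, although it therefore denotes
different real time in the two modes.

The simulator has one reference implementation of the step
(`Network.step`, vectorised numpy) and a compiled multi-step kernel
(`Network.run`, numba) used by the training loops; the two are
bit-identical on the same noise stream, which the test suite asserts.
All randomness flows from explicit `numpy.random.Generator` objects;
per-projection wiring streams are spawned from the master seed in a
fixed order, so any single projection is reproducible in isolation.

## Plasticity

Plastic E-E synapses follow the discretised ABS rule with presynaptic
rate threshold θ_pre = 0.05 on the slow rate estimate ω_E and
postsynaptic potential thresholds θ₊ = 0.15 and θ₋ (0.14 felix column,
0.11 nest column): +Δ when pre is active and V_post ≥ θ₊, −Δ when pre is
active and θ₋ ≤ V_post < θ₊ (homosynaptic LTD), −Δ when pre is inactive
and V_post ≥ θ₊ (heterosynaptic LTD), else 0.  All thresholds are
inclusive; at the ambiguous boundary V = θ₊ the LTP branch wins
(branches evaluated in printed order).  Weights are clipped to
[0, 0.225] after every update; depression floors at zero rather than
going negative.  Plasticity is applied once per excitatory step using
the same-step ω_E and pre-reset V, stays on during the inter-trial
interval, and is frozen during evaluation.  Note that heterosynaptic
LTD requires only depolarisation (V ≥ 0.15), not spiking (V > 0.18 + ψαω)
— any neuron repeatedly pushed near threshold prunes its inactive
inputs, which is the model's main pruning force.

## Protocols

**Training.**  Twelve word patterns (six "object", six "action"), each a
triplet of 20 cells drawn uniformly without replacement per area:
A1 + M1i + V1 for object words, A1 + M1i + M1L for action words.  A
trial drives the triplet for 16 steps while the unused fourth primary
area receives a fresh uncorrelated 20-cell pattern at the same
amplitude; uniform noise reaches every excitatory cell throughout
training, relaxation and evaluation.  Trials are randomly interleaved
(block-free), 2000 per word at full scale.  Between trials the network
runs noise-only steps until the global-inhibition state of both
multimodal hubs PB and PFi falls below `stsi_epsilon` (default 0.5), with
a cap of 100 steps (a capped interval is logged, not fatal).

**Evaluation.**  Plasticity frozen.  Each word is probed three times
through the auditory port (its A1 cells) and three times through the
articulatory port (its M1i cells): 5 baseline steps, 2 stimulation
steps, 60 free propagation steps, all with noise; the 67-step raster is
recorded.  Each recorded trial is preceded by 30 unrecorded noise-only
settling steps so the probe starts from the network's noisy resting
state; starting from an artificial all-zero state produces a
synchronized noise transient whose global-inhibition after-effect
suppresses the probe.  A neuron belongs to a word's CA when it is active
(≥ 1 spike) in at least 4 of the 6 trials; the alternative reading
(≥ 4 spikes in total) is implemented and selectable.

**Stimulus amplitudes.**  The external drive and noise amplitudes enter
the current I before the k1 scaling and are not fixed by the model
tables; the defaults are drive_amplitude = 55 and noise_amplitude = 30,
chosen once on three grounds.  First, a driven cell reaches threshold
within two steps from rest (0.4 · k1 · 55 = 0.22 > 0.18), the stated
calibration contract for stimulation.  Second, 55 is in the
near-threshold regime in which a single neuron under 16 steps of
constant current fires repeatedly with adaptation-lengthened
inter-spike intervals — the single-neuron phenomenology this model
family reports; a much stronger drive fires every step and shows no ISI
structure.  Third, noise at 30 yields membrane fluctuations of
σ ≈ 0.03, far below the depression threshold θ₊ = 0.15, so spontaneous
fluctuations jitter spike timing without triggering mass heterosynaptic
LTD; much larger noise amplitudes prune the connectivity
indiscriminately, and much smaller ones leave trial-onset volleys fully
synchronized, which drives the global-inhibition response into a deep
lockout after a single volley.

## Statistics

CA counts per (network, word, area) feed a two-way repeated-measures
ANOVA with the within-subject factors WordType (action/object) and Area
(12 levels) and networks as subjects; words are averaged within category
per network first.  Each effect is tested against its own
effect-by-subject interaction; for 12 networks the degrees of freedom
are (11, 121) for Area and the interaction and (1, 11) for WordType.
No sphericity correction is applied (degrees of freedom are reported
uncorrected).  With only two WordType levels the post-hoc range test
degenerates to a paired comparison, implemented as a paired t-test per
area across networks with Bonferroni correction over the 12 areas
(critical p = 0.05/12 ≈ 0.0042).  The implementation is a direct
sums-of-squares decomposition; the tests verify it against an
independent brute-force oracle and against `pingouin`, and check that
its WordType test holds its nominal 5% type-I error rate on simulated
null tables.

## Scaled-down study configuration

The full study — 12 networks × 12 words × 2000 trials — is replaced in
the test suite by a scaled configuration: 3 networks, 2 object + 2
action words, 300 trials per word, felix preset, evaluated with the
standard 6-probe protocol.  Under the default amplitudes this
configuration reproduces, on means across the three networks, the
qualitative findings the model is known for: action words recruit more
CA neurons in M1L than in V1, object words more in V1 than in M1L, and
mean CA counts order hub ≥ secondary ≥ primary.

What the scaled run does and does not show.  Per-word assemblies in the
scaled regime overlap substantially across words (pairwise Jaccard
overlap of CA membership ≈ 0.4), i.e. word-specific circuits are only
partially separated after 300 trials, and the category effect, while
present in the mean, is not guaranteed in every single network.  The
scaled run therefore demonstrates the mechanism — correlation-driven
binding of word-form cells to their grounding modality via the hub
chain — rather than the full-scale effect sizes, and no claim is made
that the printed F statistics of the full 12-network study are
reproduced (that comparison is out of scope by design).

## Numerical choices and degenerate inputs

Float comparisons in tests use explicit tolerances (1e-9 unless stated);
the engine itself performs exact threshold comparisons as the model
defines them.  State arrays are checked for NaN/Inf after every run
segment and an error names the offending area.  Euler integration
requires dt < τ and rejects unstable combinations.  Wiring with k_C = 0
yields an empty projection; a window larger than the grid wraps
toroidally and can connect a pair twice only in principle — with the
25×25 grid and 19×19 window each ordered pair is tested at most once
(single Bernoulli trial per pair, no multi-edges).  The balanced-design
check in the ANOVA rejects incomplete tables rather than silently
dropping cells.

## Known limitations

* Inhibitory units are graded and non-plastic; conductance-based
  synapses, refractory periods and spiking interneurons are out of
  scope.
* The delay backend enforces the class delays on a half-step grid but
  does not model distance-dependent inter-area delays.
* The 1:1 excitatory:inhibitory ratio follows the source architecture,
  not cortical proportions.
* The acceptance-level wiring statistics are exact; the emergent
  learning results are stochastic and asserted at the scaled
  configuration described above.
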