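# casim

A brain-constrained spiking network simulator for studying how word
meanings become grounded in sensorimotor cortex.  Twelve cortical areas
— auditory (A1, AB, PB), articulatory (M1i, PMi, PFi), visual (V1, TO,
AT) and dorsolateral motor (M1L, PML, PFL) — are modelled as 25×25
toroidal grids of excitatory spiking neurons with graded lateral and
area-wide inhibition, wired by distance-dependent Gaussian kernels and
coupled through a neuroanatomically motivated link table.  Hebbian
plasticity of the Artola–Bröcher–Singer type (discretised LTP/LTD with
a presynaptic rate threshold and two postsynaptic potential thresholds)
lets repeated co-stimulation of word-form and grounding patterns carve
out distributed **cell assemblies** whose cortical topography is
category-specific: action words recruit the lateral motor system,
object words the visual system.

The package is for computational neuroscientists who want a compact,
fully seeded, testable implementation of this model family: the neuron
and synapse equations, the wiring statistics, the word-learning and
cell-assembly-mapping protocols, and the repeated-measures statistics
used to quantify semantic topography.

## Model in brief

Membrane dynamics (all units): `tau dV/dt = −V + k1 (I + k2 η)` with
uniform noise η ∈ [−0.5, 0.5].  Excitatory input current:
`I = −k_G G_A + Σ w·φ(t−delay) + drive`, with binary output
`φ = 1 iff V − ψαω > thresh` (ψ = 0.872, thresh = 0.18) and adaptation
`tau_a dω/dt = −ω + φ`.  A per-area scalar `tau_G dG_A/dt = −G_A + Σφ`
implements winner-take-all competition.  Connection probability between
cells at toroidal offset (x, y):

    p(x, y) = k_C · exp(−[(x−x̄)²/σx² + (y−ȳ)²/σy² + 2q(x−x̄)(y−ȳ)/(σxσy)] / (2(1−q²)))

(isotropic in practice: x̄ = ȳ = q = 0).  Plastic E-E weights change by
±Δ per step under the ABS rule and are clipped to [0, 0.225].

Two numerical backends are provided and proven equivalent at the
single-neuron level: `felix` (synchronous forward Euler, same-step
inhibition, dt = 1) and `delay` (exact integration on a half-step grid
with explicit synaptic delays).  See `docs/methods.md` for the full
account.

## Worked example

```python
import numpy as np
from casim import (preset, expected_out_degree, KernelSpec,
                   ProjectionSpec, wire_projection)
from casim.protocols import single_neuron_testbench

# 1. wiring statistics: local E-E kernel on the 25x25 torus
local = KernelSpec(sigma_x=3.2, sigma_y=3.2, k_c=0.15, half_width=9)
print(round(expected_out_degree(local, exclude_self=True), 3))
spec = ProjectionSpec("A1", "A1", "EE_local", plastic=True, kernel=local,
                      weight_init="uniform", delay=1.0)
proj = wire_projection(spec, np.random.default_rng(0))
print(round(proj.out_degree().mean(), 3))

# 2. single neuron under 16 steps of constant current (felix backend)
traces = single_neuron_testbench(preset("felix"), 150.0, duration=16)
t = np.flatnonzero(traces["spikes"])
print(t.tolist(), np.diff(t).tolist())
```

prints

```
9.446
9.462
[0, 2, 5, 9, 13] [2, 3, 4, 4]
```

The first two numbers are the analytic expectation of the local
excitatory out-degree (kernel sum over the 19×19 window, autapses
excluded) and the empirical mean of one Bernoulli-wired area — each
neuron forms about 9.5 within-area connections.  The last line shows the
spike times and inter-spike intervals of a single excitatory-inhibitory
pair under constant current: the intervals lengthen (2, 3, 4, 4 steps)
as the adaptation trace accumulates and raises the effective threshold.

A scaled word-learning study from the command line:

```bash
casim train --preset felix --words 4 --trials 300 --seed 1 --outdir run/
casim evaluate --checkpoint run/trained.h5 --outdir run/
casim analyze --ca-table run/ca_table.csv --outdir run/
```

`train` wires a fresh 12-area network (7,500 excitatory neurons), trains
2 object + 2 action words for 300 randomly interleaved trials each, and
checkpoints the result; `evaluate` probes every word through the
auditory and articulatory ports and writes per-area cell-assembly
counts; `analyze` runs the WordType × Area repeated-measures ANOVA and
Bonferroni-corrected per-area post-hoc tests.

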