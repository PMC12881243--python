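"""Stimulation protocols: word-learning training, evaluation, testbench.

A "word" is a triplet of sparse activity patterns: 20 cells in the
primary auditory area (A1, the word form), 20 in the inferior motor area
(M1i, its articulation), and 20 in either the primary visual area (V1,
object words) or the lateral motor area (M1L, action words) representing
the grounding experience.  During a learning trial the triplet's cells
are driven for 16 steps while the unused fourth primary area receives a
fresh, uncorrelated 20-cell pattern; white noise reaches every area
throughout.  After stimulation the network relaxes until the
global-inhibition state of the multimodal hubs (PB, PFi) returns below
baseline (the stimulus-to-stimulus interval) before the next trial.

Evaluation freezes plasticity, probes a word's pattern through one port
area (A1 or M1i) and records the full spike raster while activity
propagates through the learned circuits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .connectivity import AREAS, N_E
from .network import Network
from .params import ModelParameters

__all__ = [
    "StimulusPattern", "TrainingConfig", "EvaluationConfig", "TrialLog",
    "generate_patterns", "make_training_schedule", "run_training_trial",
    "train_network", "run_evaluation_trial", "evaluate_network",
    "single_neuron_testbench",
]

OBJECT_AREAS = ("A1", "M1i", "V1")
ACTION_AREAS = ("A1", "M1i", "M1L")
#: primary area receiving uncorrelated input instead of the word pattern
UNUSED_PRIMARY = {"object": "M1L", "action": "V1"}


@dataclass(frozen=True)
class StimulusPattern:
    """One word's triplet of 20-cell index sets and its semantic category."""

    word_id: int
    category: str                   # "object" or "action"
    cells: dict                     # area name -> np.ndarray of cell indices

    def __post_init__(self):
        if self.category not in ("object", "action"):
            raise ValueError(f"unknown category {self.category!r}")
        expected = OBJECT_AREAS if self.category == "object" else ACTION_AREAS
        if set(self.cells) != set(expected):
            raise ValueError(f"{self.category} pattern must cover {expected}")


@dataclass
class TrainingConfig:
    """Word-learning loop settings.

    ``drive_amplitude`` is the external current injected into targeted
    cells; its default guarantees that a driven cell fires within two
    steps of stimulus onset under the standard neuron parameters.
    ``noise_amplitude`` scales the uniform white-noise current delivered
    to every excitatory cell at every step, maintaining sparse baseline
    activity between and during stimuli.
    """

    trials_per_word: int = 2000
    stim_steps: int = 16
    stsi_epsilon: float = 0.5       # hub global-inhibition baseline threshold
    stsi_max_steps: int = 100
    stsi_areas: tuple[str, ...] = ("PB", "PFi")
    stsi_plastic: bool = True       # keep plasticity on while relaxing
    drive_amplitude: float = 55.0
    noise_amplitude: float = 30.0
    cells_per_pattern: int = 20

    def __post_init__(self):
        if self.stim_steps < 1 or self.stsi_max_steps < 1:
            raise ValueError("stim_steps and stsi_max_steps must be >= 1")


@dataclass
class EvaluationConfig:
    """Cell-assembly mapping probe: 5 baseline + 2 stimulus + 60 free steps.

    ``settle_steps`` noise-only steps precede the recorded trial so the
    probe starts from the network's noisy resting state rather than from
    an artificial all-zero state (mirroring the relaxation interval that
    separates consecutive trials during learning); they are not part of
    the 67-step raster.
    """

    baseline_steps: int = 5
    stim_steps: int = 2
    propagation_steps: int = 60
    settle_steps: int = 30
    trials_per_port: int = 3
    ports: dict = field(default_factory=lambda: {"auditory": "A1", "articulatory": "M1i"})
    drive_amplitude: float = 55.0
    noise_amplitude: float = 30.0

    @property
    def total_steps(self) -> int:
        return self.baseline_steps + self.stim_steps + self.propagation_steps


@dataclass
class TrialLog:
    """Bookkeeping for one learning trial."""

    word_id: int
    stim_steps: int
    stsi_steps: int
    stsi_capped: bool
    spikes_per_area: np.ndarray     # summed over the stimulation phase


def generate_patterns(rng: np.random.Generator, n_object: int = 6,
                      n_action: int = 6, cells_per_area: int = 20,
                      n_cells: int = N_E) -> list[StimulusPattern]:
    """Draw the word-pattern set: object words first, then action words.

    Cells are sampled uniformly without replacement within each area and
    independently across words and areas (overlap across words allowed);
    each pattern engages 20/625 = 3.2% of its primary areas.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    patterns = []
    wid = 0
    for category, count in (("object", n_object), ("action", n_action)):
        areas = OBJECT_AREAS if category == "object" else ACTION_AREAS
        for _ in range(count):
            cells = {a: np.sort(rng.choice(n_cells, size=cells_per_area,
                                           replace=False)) for a in areas}
            patterns.append(StimulusPattern(wid, category, cells))
            wid += 1
    return patterns


def make_training_schedule(patterns, trials_per_word: int,
                           rng: np.random.Generator) -> np.ndarray:
    """Randomly interleaved trial order with every word appearing
    exactly ``trials_per_word`` times."""
    if not len(patterns):
        raise ValueError("patterns must be non-empty")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    ids = np.repeat([p.word_id for p in patterns], trials_per_word)
    return rng.permutation(ids)


def _pattern_drive(net: Network, pattern: StimulusPattern,
                   cfg: TrainingConfig, rng: np.random.Generator,
                   with_fourth: bool = True) -> np.ndarray:
    drive = np.zeros(net.n_e)
    for area, cells in pattern.cells.items():
        drive[np.asarray(cells) + net.area_slice(area).start] = cfg.drive_amplitude
    if with_fourth:
        fourth = UNUSED_PRIMARY[pattern.category]
        cells = rng.choice(net.cells_per_area, size=cfg.cells_per_pattern,
                           replace=False)
        drive[cells + net.area_slice(fourth).start] = cfg.drive_amplitude
    return drive


def run_training_trial(net: Network, pattern: StimulusPattern,
                       cfg: TrainingConfig,
                       rng: np.random.Generator) -> TrialLog:
    """One learning trial: 16 driven steps, then relaxation to baseline.

    The triplet's cells are driven in their three areas while the fourth
    primary area receives an uncorrelated 20-cell pattern resampled for
    this trial; plasticity acts on every E-E synapse throughout, white
    noise on every cell.  The stimulus-to-stimulus interval then runs
    noise-only steps until the hub areas' global inhibition drops below
    ``stsi_epsilon`` (or the cap is reached, which is logged, not fatal).
    """
    drive = _pattern_drive(net, pattern, cfg, rng)
    stim = net.run(cfg.stim_steps, drive=drive,
                   noise_amplitude=cfg.noise_amplitude, plastic=True)
    relax = net.run(cfg.stsi_max_steps, noise_amplitude=cfg.noise_amplitude,
                    plastic=cfg.stsi_plastic, stop_areas=cfg.stsi_areas,
                    stop_eps=cfg.stsi_epsilon)
    hubs = [net.arch.area_index(a) for a in cfg.stsi_areas]
    capped = bool(np.any(net.G[hubs] >= cfg.stsi_epsilon))
    return TrialLog(word_id=pattern.word_id, stim_steps=stim.steps,
                    stsi_steps=relax.steps, stsi_capped=capped,
                    spikes_per_area=stim.area_counts.sum(axis=0))


def train_network(net: Network, patterns, cfg: TrainingConfig,
                  seed=None, progress=None) -> list[TrialLog]:
    """Run the full randomized training schedule; returns per-trial logs."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    by_id = {p.word_id: p for p in patterns}
    schedule = make_training_schedule(patterns, cfg.trials_per_word, rng)
    logs = []
    for i, wid in enumerate(schedule):
        logs.append(run_training_trial(net, by_id[int(wid)], cfg, rng))
        if progress is not None and (i + 1) % progress == 0:
            done = sum(l.stsi_capped for l in logs)
            print(f"trial {i + 1}/{len(schedule)} (stsi capped: {done})", flush=True)
    return logs


def run_evaluation_trial(net: Network, pattern: StimulusPattern, port: str,
                         cfg: EvaluationConfig) -> np.ndarray:
    """Probe one word through one port; returns the (67, n_e) spike raster.

    Plasticity is frozen: the trained weights are read, never written.
    """
    if port in cfg.ports:
        port_area = cfg.ports[port]
    elif port in AREAS:
        port_area = port
    else:
        raise ValueError(f"unknown evaluation port {port!r}")
    drive = np.zeros(net.n_e)
    drive[np.asarray(pattern.cells[port_area]) + net.area_slice(port_area).start] \
        = cfg.drive_amplitude
    if cfg.settle_steps:
        net.run(cfg.settle_steps, noise_amplitude=cfg.noise_amplitude,
                plastic=False)
    base = net.run(cfg.baseline_steps, noise_amplitude=cfg.noise_amplitude,
                   plastic=False, record_spikes=True)
    stim = net.run(cfg.stim_steps, drive=drive,
                   noise_amplitude=cfg.noise_amplitude, plastic=False,
                   record_spikes=True)
    prop = net.run(cfg.propagation_steps, noise_amplitude=cfg.noise_amplitude,
                   plastic=False, record_spikes=True)
    return np.concatenate([base.spikes, stim.spikes, prop.spikes], axis=0)


def evaluate_network(net: Network, patterns,
                     cfg: EvaluationConfig | None = None) -> dict:
    """Map every word through both ports.

    Returns ``{word_id: [rasters]}`` with ``trials_per_port`` auditory
    probes followed by ``trials_per_port`` articulatory probes (six
    rasters per word at the defaults).  The network state is reset before
    each trial so probes are independent.
    """
    cfg = cfg or EvaluationConfig()
    out = {}
    for pattern in patterns:
        rasters = []
        for port in cfg.ports:
            for _ in range(cfg.trials_per_port):
                net.reset_state()
                rasters.append(run_evaluation_trial(net, pattern, port, cfg))
        out[pattern.word_id] = rasters
    return out


def single_neuron_testbench(params: ModelParameters, current_amplitude: float,
                            duration: int = 16, total_steps: int = 40,
                            ei_weight: float = 0.295) -> dict:
    """Minimal one-excitatory / one-inhibitory circuit under constant current.

    The excitatory cell receives ``current_amplitude`` for ``duration``
    excitatory steps (noise off) and drives its paired inhibitory cell,
    which feeds back with the one-to-one inhibitory strength; no global
    unit and no E-E synapse exist in this circuit.  Returns the full
    traces of both backends' observables for side-by-side comparison.
    """
    params.validate()
    lam = params.decay_factors()
    ce = (1.0 - lam["exc"]) * params.k1_exc
    ci = (1.0 - lam["inh"]) * params.k1_inh
    ca = 1.0 - lam["adapt"]
    cr = 1.0 - lam["favg"]
    V_e = om_a = om_r = V_i = 0.0
    phi = 0
    traces = {k: np.zeros(total_steps) for k in
              ("V_exc", "omega_adapt", "omega_rate", "V_inh")}
    spikes = np.zeros(total_steps, dtype=np.int8)
    for t in range(total_steps):
        V_i = lam["inh"] * V_i + ci * (ei_weight * phi)
        out_inh = max(V_i, 0.0)
        I = (current_amplitude if t < duration else 0.0) - params.strength_ie * out_inh
        V_e = lam["exc"] * V_e + ce * I
        phi = 1 if V_e - params.psi * params.alpha * om_a > params.thresh else 0
        om_a = lam["adapt"] * om_a + ca * phi
        om_r = lam["favg"] * om_r + cr * phi
        traces["V_exc"][t] = V_e
        if params.spike_reset and phi:
            V_e = 0.0
        traces["omega_adapt"][t] = om_a
        traces["omega_rate"][t] = om_r
        traces["V_inh"][t] = V_i
        spikes[t] = phi
    traces["spikes"] = spikes
    return traces
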