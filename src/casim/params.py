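"""Model parameters and the two numerical-backend presets.

Every scalar that governs neuron dynamics, connectivity strengths and
Hebbian learning lives here, so the rest of the package never hard-codes
a physiological constant.  Two presets are shipped:

``felix``
    Synchronous forward-Euler updating at one excitatory step per update
    (dt = 1), with same-step local and global inhibition.  Time constants
    are expressed in excitatory steps.

``nest``
    Exact (exponential) integration on a half-step grid (dt = 0.5) with
    explicit synaptic delays: excitatory-to-excitatory transmission lags a
    full excitatory step (two ticks), all other synapse classes lag half a
    step (one tick).  Time constants are expressed in half-step ticks, so
    the doubled values denote the *same* real time as the felix column.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict, replace

__all__ = [
    "PlasticityParameters",
    "ModelParameters",
    "preset",
    "PRESETS",
    "matched_exact_tau",
]


@dataclass
class PlasticityParameters:
    """Thresholds and step size of the ABS (Artola-Broecher-Singer) rule.

    The rule discretises LTP/LTD into fixed increments of ``delta``:
    potentiation when the presynaptic rate estimate and the postsynaptic
    membrane potential are both high, homosynaptic depression when the
    postsynaptic potential sits in the intermediate band, heterosynaptic
    depression when an inactive synapse targets a strongly depolarised
    neuron.  Weights are clipped to ``[w_min, w_max]`` after every update.
    """

    theta_pre: float = 0.05   # presynaptic rate threshold
    theta_plus: float = 0.15  # upper postsynaptic potential threshold (LTP)
    theta_minus: float = 0.11 # lower postsynaptic potential threshold (LTD)
    delta: float = 0.0002     # weight increment per step
    w_max: float = 0.225      # hard ceiling on plastic E-E weights
    w_min: float = 0.0        # floor (depression never drives weights negative)

    def validate(self) -> None:
        if not (0.0 <= self.theta_minus <= self.theta_plus):
            raise ValueError("require 0 <= theta_minus <= theta_plus")
        if self.delta <= 0:
            raise ValueError("delta must be positive")
        if self.w_min >= self.w_max:
            raise ValueError("w_min must be below w_max")


@dataclass
class ModelParameters:
    """All scalars of the neuron, connection and inhibition equations.

    Time constants are in *update units*: excitatory steps in felix mode,
    half-step ticks in delay mode (where one excitatory step spans two
    ticks, so e.g. ``tau_exc=5`` ticks equals 2.5 steps of real time).
    """

    mode: str = "felix"            # "felix" (Euler, dt=1) or "delay" (exact, dt=0.5)
    dt: float = 1.0                # simulation resolution in excitatory-step units

    # input and noise gains (excitatory / inhibitory / global-inhibitory)
    k1_exc: float = 0.01
    k1_inh: float = 1.0
    k1_glob: float = 1.0
    k2_exc: float = 0.005
    k2_inh: float = 0.0
    k2_glob: float = 0.0

    # time constants, in update units of the active mode
    tau_exc: float = 2.5
    tau_inh: float = 5.0
    tau_glob: float = 12.0
    tau_adapt: float = 10.0
    tau_favg: float = 30.0

    # spiking threshold and adaptation
    thresh: float = 0.18
    psi: float = 0.872             # adaptation scaling of the spiking threshold
    alpha: float = 1.0             # adaptation gain; enters only as psi*alpha
    spike_reset: bool = True       # V -> 0 after a spike

    # synapse-class strengths (dimensionless multipliers on edge weights)
    strength_ee: float = 500.0
    strength_ei: float = 0.295     # amplitude of the Gaussian E->I weights (== kernel k_C)
    strength_ie: float = 1500.0
    strength_e_gi: float = 1.0
    strength_gi_e: float = 65.0    # == k_G, the global-inhibition gain

    # synaptic delays in excitatory-step units
    delay_ee: float = 1.0
    delay_short: float = 0.5       # E->I, I->E, E->GI, GI->E

    # initial E-E weights are uniform on [0, w_up]
    w_up: float = 0.1

    plasticity: PlasticityParameters = field(default_factory=PlasticityParameters)

    # -- derived quantities -------------------------------------------------

    @property
    def k_G(self) -> float:
        return self.strength_gi_e

    @property
    def scheme(self) -> str:
        """Integration scheme implied by the mode."""
        return "euler" if self.mode == "felix" else "exact"

    @property
    def ticks_per_step(self) -> int:
        return 1 if self.mode == "felix" else 2

    def decay(self, tau: float) -> float:
        """Per-excitatory-step decay factor of a leaky state with constant tau.

        In felix mode this is the forward-Euler factor ``1 - dt/tau`` with
        dt = 1 step.  In delay mode the state is integrated exactly over
        the two half-step ticks spanning one excitatory step, giving
        ``exp(-2/tau)`` with tau in tick units.
        """
        if tau <= 0:
            raise ValueError("time constant must be positive")
        if self.mode == "felix":
            lam = 1.0 - self.dt / tau
            if lam < 0:
                raise ValueError("Euler step unstable: dt > tau")
            return lam
        return math.exp(-self.ticks_per_step / tau)

    def decay_factors(self) -> dict:
        """Per-step decay factors for every leaky state variable."""
        return {
            "exc": self.decay(self.tau_exc),
            "inh": self.decay(self.tau_inh),
            "glob": self.decay(self.tau_glob),
            "adapt": self.decay(self.tau_adapt),
            "favg": self.decay(self.tau_favg),
        }

    def validate(self) -> None:
        if self.mode not in ("felix", "delay"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "felix" and self.dt != 1.0:
            raise ValueError("felix mode requires dt = 1")
        if self.mode == "delay" and self.dt != 0.5:
            raise ValueError("delay mode requires dt = 0.5")
        for name in ("tau_exc", "tau_inh", "tau_glob", "tau_adapt", "tau_favg"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.thresh <= 0:
            raise ValueError("thresh must be positive")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.delay_ee <= 0 or self.delay_short <= 0:
            raise ValueError("delays must be positive")
        self.plasticity.validate()

    # -- (de)serialisation --------------------------------------------------

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParameters":
        d = dict(d)
        plast = d.pop("plasticity", {})
        p = cls(**d, plasticity=PlasticityParameters(**plast))
        p.validate()
        return p


def matched_exact_tau(tau_euler: float, substeps: int = 2) -> float:
    """Exact-integration time constant matching a forward-Euler decay.

    Returns the tau (in sub-step units) for which ``substeps`` exact
    updates produce the same per-step decay as one Euler update with the
    given ``tau_euler`` (dt = 1):  ``exp(-substeps/tau) == 1 - 1/tau_euler``.

    Used when the two backends must be compared trace-for-trace: with the
    table constants the integrators differ at second order in dt, so
    equality of trajectories requires matching the per-step decay itself.
    """
    lam = 1.0 - 1.0 / tau_euler
    if lam <= 0:
        raise ValueError("tau_euler must exceed 1 step")
    return -substeps / math.log(lam)


def _felix_preset() -> ModelParameters:
    return ModelParameters(
        mode="felix", dt=1.0,
        tau_exc=2.5, tau_inh=5.0, tau_glob=12.0, tau_adapt=10.0, tau_favg=30.0,
        plasticity=PlasticityParameters(delta=0.0008, theta_minus=0.14),
    )


def _nest_preset() -> ModelParameters:
    return ModelParameters(
        mode="delay", dt=0.5,
        tau_exc=5.0, tau_inh=10.0, tau_glob=24.0, tau_adapt=20.0, tau_favg=30.0,
        plasticity=PlasticityParameters(delta=0.0002, theta_minus=0.11),
    )


PRESETS = {"felix": _felix_preset, "nest": _nest_preset}


def preset(name: str) -> ModelParameters:
    """Return a fresh parameter set for preset ``name`` ('felix' or 'nest')."""
    try:
        p = PRESETS[name]()
    except KeyError:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}") from None
    p.validate()
    return p


def matched_delay_params(base: ModelParameters | None = None) -> ModelParameters:
    """Delay-mode parameters whose per-step decays equal the felix preset's.

    Convenience for backend-equivalence runs: takes the felix(-style)
    parameters and returns a delay-mode set with exact-integration time
    constants chosen so both backends realise identical per-step maps.
    """
    if base is None:
        base = preset("felix")
    return replace(
        base,
        mode="delay", dt=0.5,
        tau_exc=matched_exact_tau(base.tau_exc),
        tau_inh=matched_exact_tau(base.tau_inh),
        tau_glob=matched_exact_tau(base.tau_glob),
        tau_adapt=matched_exact_tau(base.tau_adapt),
        tau_favg=matched_exact_tau(base.tau_favg),
    )
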