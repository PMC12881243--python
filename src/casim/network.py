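"""State updates and the compiled multi-area network.

The model's units are leaky integrators updated synchronously in
discrete time.  Excitatory cells spike (binary output, Eq.-style strict
threshold with subtractive adaptation), local inhibitory cells are
graded mean-field units, and one scalar unit per area integrates the
area's total spike count and feeds back uniform global inhibition.

Two backends share one code path and one dependency structure:

* ``felix`` - forward Euler at one excitatory step per update, with
  inhibition computed within the same step from the previous step's
  spikes;
* ``delay`` - exact (exponential) integration on a half-step grid with
  explicit delays (E-E one step, all other classes half a step).
  Inhibitory and global units are updated on half-integer ticks,
  excitatory units on integer ticks, so the inhibition reaching an
  excitatory cell at step t is again a function of the spikes at t-1.

Because the dependency graphs coincide, the backends differ only in
their per-step decay factors; matching those (``matched_delay_params``)
makes the two trajectories identical, which is the discrete-time
counterpart of the "perfect match" between a same-step and an
explicit-delay implementation of this model family.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass

import numpy as np

from .connectivity import Architecture, Projection, build_architecture
from .params import ModelParameters
from . import plasticity as _plast
from . import _engine

__all__ = [
    "integrate_state", "spike_decision", "update_adaptation", "update_rate",
    "update_global", "compute_input", "RingBuffer", "Network", "AreaState",
    "SimResult", "NumericalInstabilityError",
]


class NumericalInstabilityError(RuntimeError):
    """Raised when a state array develops NaN/Inf, naming the area."""


# ---------------------------------------------------------------------------
# primitive state updates
# ---------------------------------------------------------------------------

def integrate_state(V, I, tau, k1=1.0, k2=0.0, eta=0.0, dt=1.0, scheme="euler"):
    """One update of the leaky-integrator equation tau dV/dt = -V + k1(I + k2 eta).

    ``euler``:  V' = V + (dt/tau) * (-V + k1 (I + k2 eta))
    ``exact``:  V' = V exp(-dt/tau) + k1 (I + k2 eta) (1 - exp(-dt/tau)),
    the closed-form solution with the input held constant over the step.
    """
    if tau <= 0:
        raise ValueError("time constant must be positive")
    drive = np.multiply(k1, np.add(I, np.multiply(k2, eta)))
    if scheme == "euler":
        lam = 1.0 - dt / tau
        return lam * np.asarray(V) + (dt / tau) * drive
    if scheme == "exact":
        lam = math.exp(-dt / tau)
        return lam * np.asarray(V) + (1.0 - lam) * drive
    raise ValueError(f"unknown integration scheme {scheme!r}")


def spike_decision(V, omega_adapt, params: ModelParameters):
    """Binary output: 1 iff V - psi*alpha*omega exceeds the threshold (strict)."""
    return np.asarray(V) - params.psi * params.alpha * np.asarray(omega_adapt) > params.thresh


def update_adaptation(omega, phi, tau_adapt, dt=1.0, scheme="euler"):
    """Leaky integration of the spike train: tau_a d(omega)/dt = -omega + phi."""
    return integrate_state(omega, phi, tau_adapt, k1=1.0, dt=dt, scheme=scheme)


def update_rate(omega_E, phi, tau_favg, dt=1.0, scheme="euler"):
    """Estimated instantaneous firing rate: tau_f d(omega_E)/dt = -omega_E + phi."""
    return integrate_state(omega_E, phi, tau_favg, k1=1.0, dt=dt, scheme=scheme)


def update_global(G, total_spikes, tau_glob, dt=1.0, scheme="euler"):
    """Area-wide inhibition state: tau_g dG/dt = -G + sum(phi)."""
    return integrate_state(G, total_spikes, tau_glob, k1=1.0, dt=dt, scheme=scheme)


def compute_input(synaptic_terms=(), G=0.0, k_G=0.0, external_drive=0.0):
    """Net input current -k_G G + sum over classes of strength * w . phi + drive.

    ``synaptic_terms`` is an iterable of ``(strength, weights, pre_outputs)``
    triples, each contributing ``strength * dot(weights, pre_outputs)``
    with the presynaptic outputs taken at the class's delay (the caller's
    buffers provide the lagged values).
    """
    I = -k_G * np.asarray(G, dtype=float) + external_drive
    for strength, w, phi in synaptic_terms:
        I = I + strength * np.dot(np.asarray(w, float), np.asarray(phi, float))
    return I


class RingBuffer:
    """Fixed-lag buffer: a value pushed at tick t is read back at t + lag."""

    def __init__(self, lag: int, template: np.ndarray):
        if lag < 1:
            raise ValueError("lag must be at least one tick")
        self.lag = lag
        self._q = deque((np.zeros_like(template) for _ in range(lag)), maxlen=lag)

    def push_pop(self, value: np.ndarray) -> np.ndarray:
        """Insert the current output and return the value from ``lag`` ticks ago."""
        out = self._q.popleft()
        self._q.append(np.array(value, copy=True))
        return out

    def __len__(self) -> int:
        return self.lag


# ---------------------------------------------------------------------------
# compiled network
# ---------------------------------------------------------------------------

@dataclass
class SimResult:
    """Outcome of a multi-step run."""

    steps: int                     # steps actually executed (early stop possible)
    area_counts: np.ndarray        # (steps, n_areas) spike counts per step
    spikes: np.ndarray | None = None  # (steps, n_e) int8 raster if recorded


class AreaState:
    """Read/write view of one area's state inside a :class:`Network`."""

    def __init__(self, net: "Network", index: int):
        n = net.cells_per_area
        sl = slice(index * n, (index + 1) * n)
        self.name = net.arch.areas[index]
        self.V_exc = net.V_e[sl]
        self.omega_adapt = net.om_a[sl]
        self.omega_rate = net.om_r[sl]
        self.phi = net.phi[sl]
        self.V_inh = net.V_i[sl]
        self._net = net
        self._index = index

    @property
    def out_inh(self) -> np.ndarray:
        return np.maximum(self.V_inh, 0.0)

    @property
    def G(self) -> float:
        return float(self._net.G[self._index])


def _take_rows(indptr: np.ndarray, rows: np.ndarray) -> np.ndarray:
    """Positions of all CSR entries belonging to the given rows, row-ordered."""
    counts = indptr[rows + 1] - indptr[rows]
    total = int(counts.sum())
    if total == 0:
        return np.empty(0, dtype=np.int64)
    starts = indptr[rows]
    cum = np.concatenate(([0], np.cumsum(counts)[:-1]))
    return np.repeat(starts - cum, counts) + np.arange(total)


class Network:
    """The wired 12-area model compiled to flat arrays.

    All excitatory cells across areas are concatenated into one index
    space (area a occupies ``[a*625, (a+1)*625)``); inhibitory cells use
    the same numbering.  Plastic E-E edges (local and between-area) are
    stored once, with CSR/CSC orderings for presynaptic gathering and
    postsynaptic (heterosynaptic) plasticity.  `Projection` objects keep
    views into the shared weight storage, so training updates are visible
    through them.
    """

    def __init__(self, params: ModelParameters, arch: Architecture,
                 projections: list[Projection], seed=None):
        params.validate()
        self.params = params
        self.arch = arch
        self.projections = projections
        self.cells_per_area = arch.grid * arch.grid
        self.n_areas = arch.n_areas
        self.n_e = arch.n_excitatory
        self.area_of = np.repeat(np.arange(self.n_areas, dtype=np.int32),
                                 self.cells_per_area)
        self.rng = np.random.default_rng(seed)
        self._compile()
        self.reset_state()

    # -- construction -------------------------------------------------------

    @classmethod
    def build(cls, params: ModelParameters, seed, links=None,
              exclude_self: bool = True) -> "Network":
        """Wire a fresh network from a master seed."""
        ss = np.random.SeedSequence(seed)
        wiring_seed, noise_seed = ss.spawn(2)
        arch, projections = build_architecture(
            params, np.random.default_rng(wiring_seed), links=links,
            exclude_self=exclude_self)
        return cls(params, arch, projections, seed=noise_seed)

    def _compile(self) -> None:
        n = self.cells_per_area
        aidx = {name: i for i, name in enumerate(self.arch.areas)}
        ee_pre, ee_post, ee_w, self._ee_slices = [], [], [], []
        ei_pre, ei_post, ei_w = [], [], []
        pos = 0
        for proj in self.projections:
            cls = proj.spec.synapse_class
            src = aidx[proj.spec.source_area] * n
            dst = aidx[proj.spec.target_area] * n
            if cls in ("EE_local", "EE_between"):
                ee_pre.append(proj.pre.astype(np.int32) + src)
                ee_post.append(proj.post.astype(np.int32) + dst)
                ee_w.append(proj.weight.astype(np.float64))
                self._ee_slices.append((proj, pos, pos + len(proj)))
                pos += len(proj)
            elif cls == "EI":
                ei_pre.append(proj.pre.astype(np.int32) + src)
                ei_post.append(proj.post.astype(np.int32) + dst)
                ei_w.append(proj.weight.astype(np.float64))
            # IE, E_GI, GI_E are deterministic and realised in closed form

        self.ee_pre = np.concatenate(ee_pre) if ee_pre else np.empty(0, np.int32)
        self.ee_post = np.concatenate(ee_post) if ee_post else np.empty(0, np.int32)
        self.ee_w = np.concatenate(ee_w) if ee_w else np.empty(0, np.float64)
        # hand each plastic projection a view into the shared weight store
        for proj, s, e in self._ee_slices:
            proj.weight = self.ee_w[s:e]
        self._index_ee()

        epre = np.concatenate(ei_pre) if ei_pre else np.empty(0, np.int32)
        epost = np.concatenate(ei_post) if ei_post else np.empty(0, np.int32)
        ew = np.concatenate(ei_w) if ei_w else np.empty(0, np.float64)
        order = np.argsort(epre, kind="stable").astype(np.int64)
        self.ei_order = order
        self.ei_post = epost
        self.ei_w = ew
        self.ei_indptr = np.concatenate((
            [0], np.cumsum(np.bincount(epre, minlength=self.n_e)))).astype(np.int64)

    def _index_ee(self) -> None:
        """(Re)build CSR (by pre) and CSC (by post) orderings of the E-E edges."""
        self.ee_order = np.argsort(self.ee_pre, kind="stable").astype(np.int64)
        self.ee_indptr = np.concatenate((
            [0], np.cumsum(np.bincount(self.ee_pre, minlength=self.n_e)))).astype(np.int64)
        self.ee_corder = np.argsort(self.ee_post, kind="stable").astype(np.int64)
        self.ee_cptr = np.concatenate((
            [0], np.cumsum(np.bincount(self.ee_post, minlength=self.n_e)))).astype(np.int64)

    def reset_state(self) -> None:
        self.V_e = np.zeros(self.n_e)
        self.om_a = np.zeros(self.n_e)
        self.om_r = np.zeros(self.n_e)
        self.phi = np.zeros(self.n_e, dtype=np.int8)
        self.V_i = np.zeros(self.n_e)
        self.G = np.zeros(self.n_areas)

    def area(self, name: str) -> AreaState:
        return AreaState(self, self.arch.area_index(name))

    def area_slice(self, name: str) -> slice:
        n = self.cells_per_area
        i = self.arch.area_index(name)
        return slice(i * n, (i + 1) * n)

    # -- factors ------------------------------------------------------------

    def _factors(self) -> dict:
        p = self.params
        lam = p.decay_factors()
        return dict(
            lam_e=lam["exc"], ce=(1.0 - lam["exc"]) * p.k1_exc,
            lam_i=lam["inh"], ci=(1.0 - lam["inh"]) * p.k1_inh,
            lam_g=lam["glob"], cg=(1.0 - lam["glob"]) * p.k1_glob,
            lam_a=lam["adapt"], ca=(1.0 - lam["adapt"]),
            lam_r=lam["favg"], cr=(1.0 - lam["favg"]),
        )

    # -- reference single step ----------------------------------------------

    def step(self, drive: np.ndarray | None = None, noise_amplitude: float = 0.0,
             plastic: bool = False, noise: bool = True,
             eta: np.ndarray | None = None) -> np.ndarray:
        """Advance the network by one excitatory step (reference path).

        Update order: global and local inhibitory units integrate the
        previous step's spikes; excitatory units then integrate the fresh
        inhibition together with delayed E-E input, external drive and
        noise; spikes are decided, adaptation and rate estimates advance,
        plasticity (if enabled) applies, and spiking membranes reset.
        Returns the new binary spike vector.
        """
        p = self.params
        f = self._factors()
        phi_prev = self.phi
        spk = np.flatnonzero(phi_prev)

        inp = np.zeros(self.n_e)
        inh_in = np.zeros(self.n_e)
        if spk.size:
            sel = self.ee_order[_take_rows(self.ee_indptr, spk)]
            np.add.at(inp, self.ee_post[sel], self.ee_w[sel])
            sel_i = self.ei_order[_take_rows(self.ei_indptr, spk)]
            np.add.at(inh_in, self.ei_post[sel_i], self.ei_w[sel_i])
        g_in = np.bincount(self.area_of[spk], minlength=self.n_areas).astype(float)

        self.G = f["lam_g"] * self.G + f["cg"] * g_in
        self.V_i = f["lam_i"] * self.V_i + f["ci"] * inh_in
        out_inh = np.maximum(self.V_i, 0.0)

        if eta is None:
            eta = (self.rng.uniform(-0.5, 0.5, self.n_e) if noise
                   else np.zeros(self.n_e))
        if drive is None:
            drive = 0.0
        I = (-p.k_G * self.G[self.area_of] - p.strength_ie * out_inh
             + p.strength_ee * inp + drive + noise_amplitude * eta)
        self.V_e = f["lam_e"] * self.V_e + f["ce"] * (I + p.k2_exc * eta)

        phi_new = (self.V_e - p.psi * p.alpha * self.om_a > p.thresh)
        self.om_a = f["lam_a"] * self.om_a + f["ca"] * phi_new
        self.om_r = f["lam_r"] * self.om_r + f["cr"] * phi_new

        if plastic:
            _plast.abs_update_indexed(
                self.ee_indptr, self.ee_order, self.ee_post,
                self.ee_cptr, self.ee_corder, self.ee_pre,
                self.ee_w, self.om_r, self.V_e, p.plasticity)

        if p.spike_reset:
            self.V_e[phi_new] = 0.0
        self.phi = phi_new.astype(np.int8)

        if not np.isfinite(self.V_e).all():
            bad = int(self.area_of[~np.isfinite(self.V_e)][0])
            raise NumericalInstabilityError(
                f"non-finite membrane potential in area {self.arch.areas[bad]}")
        return self.phi.copy()

    # -- fast multi-step path (numba) ---------------------------------------

    def run(self, n_steps: int, drive: np.ndarray | None = None,
            noise_amplitude: float = 0.0, plastic: bool = False,
            noise: bool = True, record_spikes: bool = False,
            stop_areas: tuple[str, ...] = (), stop_eps: float = 0.0,
            eta: np.ndarray | None = None) -> SimResult:
        """Advance ``n_steps`` with constant drive via the compiled kernel.

        With ``stop_areas``/``stop_eps`` set, the run ends early once the
        global-inhibition state of every listed area falls below
        ``stop_eps`` (the stimulus-to-stimulus relaxation criterion).
        """
        p = self.params
        f = self._factors()
        if drive is None:
            drive = np.zeros(self.n_e)
        if eta is None:
            eta = (self.rng.uniform(-0.5, 0.5, (n_steps, self.n_e)) if noise
                   else np.zeros((n_steps, self.n_e)))
        stop_idx = np.array([self.arch.area_index(a) for a in stop_areas],
                            dtype=np.int64)
        spikes = np.zeros((n_steps if record_spikes else 1, self.n_e), dtype=np.int8)
        counts = np.zeros((n_steps, self.n_areas), dtype=np.int64)
        pl = p.plasticity
        done = _engine.run_steps(
            n_steps, self.V_e, self.om_a, self.om_r, self.phi, self.V_i, self.G,
            self.area_of,
            self.ee_indptr, self.ee_order, self.ee_post, self.ee_w,
            self.ee_cptr, self.ee_corder, self.ee_pre,
            self.ei_indptr, self.ei_order, self.ei_post, self.ei_w,
            f["lam_e"], f["ce"], f["lam_i"], f["ci"], f["lam_g"], f["cg"],
            f["lam_a"], f["ca"], f["lam_r"], f["cr"],
            p.k2_exc, p.k_G, p.strength_ee, p.strength_ie,
            p.thresh, p.psi * p.alpha, p.spike_reset,
            plastic, pl.theta_pre, pl.theta_plus, pl.theta_minus,
            pl.delta, pl.w_min, pl.w_max,
            np.ascontiguousarray(drive, dtype=np.float64),
            np.ascontiguousarray(eta, dtype=np.float64),
            float(noise_amplitude),
            stop_idx, float(stop_eps),
            spikes, record_spikes, counts)
        if not np.isfinite(self.V_e).all():
            bad = int(self.area_of[~np.isfinite(self.V_e)][0])
            raise NumericalInstabilityError(
                f"non-finite membrane potential in area {self.arch.areas[bad]}")
        return SimResult(steps=int(done), area_counts=counts[:done],
                         spikes=spikes[:done] if record_spikes else None)
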