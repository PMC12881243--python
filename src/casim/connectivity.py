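"""Wiring of the 12-area architecture on toroidal 25x25 grids.

Each cortical area is a 25x25 grid of excitatory spiking neurons, a
matching grid of graded (mean-field) inhibitory neurons, and one scalar
area-wide global-inhibition unit.  Within and between areas, excitatory
connections are drawn by independent Bernoulli trials whose probability
follows a (possibly anisotropic) bivariate Gaussian of the toroidal
offset between source and target cells, truncated to a square window.

The analytic expectation of the resulting out-degree
(:func:`expected_out_degree`) serves as the oracle against which the
stochastic wiring is tested.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

__all__ = [
    "GRID", "N_E", "AREAS", "SYSTEMS", "HUB_AREAS", "SECONDARY_AREAS",
    "PRIMARY_AREAS", "DEFAULT_LINKS", "KernelSpec", "ProjectionSpec",
    "Projection", "Architecture", "kernel_probability",
    "expected_out_degree", "wire_projection", "build_architecture",
    "toroidal_offset",
]

GRID = 25          # side length of every area's neuron grid
N_E = GRID * GRID  # 625 excitatory (and 625 inhibitory) cells per area

AREAS = ("A1", "AB", "PB", "PFi", "PMi", "M1i", "V1", "TO", "AT", "PFL", "PML", "M1L")

SYSTEMS = {
    "auditory": ("A1", "AB", "PB"),
    "articulatory": ("M1i", "PMi", "PFi"),
    "visual": ("V1", "TO", "AT"),
    "dorsolateral_motor": ("M1L", "PML", "PFL"),
}

# multimodal connector hubs, modality-specific secondary and primary areas
HUB_AREAS = ("PB", "PFi", "AT", "PFL")
SECONDARY_AREAS = ("AB", "PMi", "TO", "PML")
PRIMARY_AREAS = ("A1", "M1i", "V1", "M1L")

#: Default inter-area link table.  Every entry is an undirected pair plus
#: its class; wiring instantiates a reciprocal pair of projections.
#: Within each system: next-neighbour links along the primary-secondary-hub
#: chain plus a jumping link from primary to hub.  Across systems: jumping
#: links between the secondary/hub areas of the two perisylvian systems and
#: of the two extrasylvian systems, plus long-distance links among all six
#: hub pairs.
DEFAULT_LINKS = (
    # within-system next-neighbour chains
    ("A1", "AB", "within_system"), ("AB", "PB", "within_system"),
    ("M1i", "PMi", "within_system"), ("PMi", "PFi", "within_system"),
    ("V1", "TO", "within_system"), ("TO", "AT", "within_system"),
    ("M1L", "PML", "within_system"), ("PML", "PFL", "within_system"),
    # within-system jumping links
    ("A1", "PB", "within_system"), ("M1i", "PFi", "within_system"),
    ("V1", "AT", "within_system"), ("M1L", "PFL", "within_system"),
    # cross-system jumping links between adjacent systems
    ("AB", "PFi", "cross_system"), ("PB", "PMi", "cross_system"),
    ("TO", "PFL", "cross_system"), ("AT", "PML", "cross_system"),
    # long-distance hub-to-hub links
    ("PB", "PFi", "cross_system"), ("PB", "AT", "cross_system"),
    ("PB", "PFL", "cross_system"), ("PFi", "AT", "cross_system"),
    ("PFi", "PFL", "cross_system"), ("AT", "PFL", "cross_system"),
)

SYNAPSE_CLASSES = ("EE_local", "EE_between", "EI", "IE", "E_GI", "GI_E")


@dataclass(frozen=True)
class KernelSpec:
    """Truncated bivariate Gaussian connection kernel.

    ``sigma_x``/``sigma_y`` control the spread (grid-cell units), ``mean_x``
    / ``mean_y`` shift the centre, ``q`` tilts the principal axes
    (anisotropy, |q| < 1), ``k_c`` is the peak probability and
    ``half_width`` the radius of the square window outside which the
    kernel is not evaluated (hard cut).
    """

    sigma_x: float
    sigma_y: float
    k_c: float
    half_width: int
    mean_x: float = 0.0
    mean_y: float = 0.0
    q: float = 0.0

    def __post_init__(self):
        if self.sigma_x <= 0 or self.sigma_y <= 0:
            raise ValueError("sigma_x and sigma_y must be positive")
        if abs(self.q) >= 1:
            raise ValueError("anisotropy coefficient must satisfy |q| < 1")
        if not (0.0 <= self.k_c <= 1.0):
            raise ValueError("k_c must lie in [0, 1]")
        if self.half_width < 0:
            raise ValueError("half_width must be non-negative")


def kernel_probability(kernel: KernelSpec, dx, dy):
    """Connection probability at toroidal offset ``(dx, dy)``.

    Evaluates ``k_c * exp(-[(dx-mx)^2/sx^2 + (dy-my)^2/sy^2
    + 2q(dx-mx)(dy-my)/(sx sy)] / (2(1-q^2)))``; accepts scalars or
    arrays.  Offsets beyond the window are the caller's concern (the
    wiring code never evaluates them).
    """
    dx = np.asarray(dx, dtype=float)
    dy = np.asarray(dy, dtype=float)
    ux = dx - kernel.mean_x
    uy = dy - kernel.mean_y
    sx, sy, q = kernel.sigma_x, kernel.sigma_y, kernel.q
    expo = (ux * ux / sx**2 + uy * uy / sy**2 + 2.0 * q * ux * uy / (sx * sy))
    p = kernel.k_c * np.exp(-expo / (2.0 * (1.0 - q * q)))
    return p if p.ndim else float(p)


def _window_offsets(half_width: int) -> tuple[np.ndarray, np.ndarray]:
    r = np.arange(-half_width, half_width + 1)
    dx, dy = np.meshgrid(r, r, indexing="ij")
    return dx.ravel(), dy.ravel()


def expected_out_degree(kernel: KernelSpec, exclude_self: bool = False) -> float:
    """Analytic expected number of connections per source neuron.

    Sums the kernel over every offset of the truncation window; with
    ``exclude_self`` the centre term is dropped (no autapses).  This is
    the exact mean of the Bernoulli wiring and the oracle used by the
    wiring tests.
    """
    dx, dy = _window_offsets(kernel.half_width)
    p = kernel_probability(kernel, dx, dy)
    total = float(np.sum(p))
    if exclude_self:
        total -= float(kernel_probability(kernel, 0, 0))
    return total


def toroidal_offset(a: np.ndarray, b: np.ndarray, grid: int = GRID) -> np.ndarray:
    """Signed minimal offset b - a on a ring of length ``grid``."""
    return (np.asarray(b) - np.asarray(a) + grid // 2) % grid - grid // 2


@dataclass(frozen=True)
class ProjectionSpec:
    """Recipe for one wired connection set between two grids."""

    source_area: str
    target_area: str
    synapse_class: str
    plastic: bool = False
    kernel: KernelSpec | None = None
    strength: float = 1.0
    delay: float = 0.5           # excitatory-step units
    weight_init: str = "constant"  # "uniform" | "kernel" | "constant"
    w_up: float = 0.1            # upper bound of the uniform init
    exclude_self: bool = True    # autapses in local E-E wiring

    def __post_init__(self):
        if self.synapse_class not in SYNAPSE_CLASSES:
            raise ValueError(f"unknown synapse class {self.synapse_class!r}")
        if self.plastic and self.synapse_class not in ("EE_local", "EE_between"):
            raise ValueError("only E-E connections may be plastic")
        if self.delay <= 0:
            raise ValueError("delay must be positive")


@dataclass
class Projection:
    """A wired connection set: parallel edge arrays plus provenance."""

    spec: ProjectionSpec
    pre: np.ndarray    # source indices, local to the source grid
    post: np.ndarray   # target indices, local to the target grid
    weight: np.ndarray

    def __len__(self) -> int:
        return self.pre.shape[0]

    @property
    def plastic(self) -> bool:
        return self.spec.plastic

    def out_degree(self, n_source: int = N_E) -> np.ndarray:
        """Number of outgoing edges per source neuron."""
        return np.bincount(self.pre, minlength=n_source)


def _grid_targets(half_width: int, grid: int = GRID) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-source target indices for every window offset.

    Returns (dx, dy, targets) where targets has shape (grid*grid, n_offsets)
    and targets[s, k] is the flat index of the cell at offset k from source s
    under toroidal wrap-around.
    """
    dx, dy = _window_offsets(half_width)
    rows = np.arange(grid).repeat(grid)
    cols = np.tile(np.arange(grid), grid)
    tr = (rows[:, None] + dx[None, :]) % grid
    tc = (cols[:, None] + dy[None, :]) % grid
    return dx, dy, tr * grid + tc


def wire_projection(spec: ProjectionSpec, rng: np.random.Generator,
                    grid: int = GRID) -> Projection:
    """Instantiate one projection according to its spec.

    Kernel-based classes (``EE_local``, ``EE_between``) run an independent
    Bernoulli trial per source-target pair inside the toroidal window and
    draw weights uniformly on ``[0, w_up]``.  ``EI`` connects the full
    5x5 (more generally ``(2h+1)^2``) neighbourhood with probability one
    and sets the weight to the Gaussian kernel value at the offset.
    ``IE`` is one-to-one at identical coordinates; ``E_GI``/``GI_E``
    connect all cells to/from the single global unit.  Edge arrays are
    ordered by source index.
    """
    n = grid * grid
    cls = spec.synapse_class
    if cls in ("EE_local", "EE_between"):
        if spec.kernel is None:
            raise ValueError(f"{cls} projection requires a kernel")
        dx, dy, targets = _grid_targets(spec.kernel.half_width, grid)
        p = kernel_probability(spec.kernel, dx, dy)
        if cls == "EE_local" and spec.exclude_self:
            centre = np.flatnonzero((dx == 0) & (dy == 0))
            p = p.copy()
            p[centre] = 0.0
        mask = rng.random((n, p.size)) < p[None, :]
        pre, off = np.nonzero(mask)
        post = targets[pre, off]
        if spec.weight_init == "uniform":
            w = rng.uniform(0.0, spec.w_up, size=pre.size)
        elif spec.weight_init == "constant":
            w = np.ones(pre.size)
        else:
            raise ValueError(f"unsupported weight_init {spec.weight_init!r} for {cls}")
    elif cls == "EI":
        if spec.kernel is None:
            raise ValueError("EI projection requires a kernel")
        dx, dy, targets = _grid_targets(spec.kernel.half_width, grid)
        p = kernel_probability(spec.kernel, dx, dy)
        pre = np.repeat(np.arange(n), p.size)
        post = targets.ravel()
        w = np.tile(p, n)
    elif cls == "IE":
        pre = np.arange(n)
        post = np.arange(n)
        w = np.ones(n)
    elif cls == "E_GI":
        pre = np.arange(n)
        post = np.zeros(n, dtype=np.int64)
        w = np.ones(n)
    elif cls == "GI_E":
        pre = np.zeros(n, dtype=np.int64)
        post = np.arange(n)
        w = np.ones(n)
    else:  # pragma: no cover - guarded by ProjectionSpec
        raise ValueError(f"unknown synapse class {cls!r}")
    return Projection(spec=spec,
                      pre=np.ascontiguousarray(pre, dtype=np.int32),
                      post=np.ascontiguousarray(post, dtype=np.int32),
                      weight=np.ascontiguousarray(w, dtype=np.float64))


@dataclass
class Architecture:
    """Area names, system membership and the inter-area link table."""

    areas: tuple[str, ...] = AREAS
    systems: dict = field(default_factory=lambda: {k: tuple(v) for k, v in SYSTEMS.items()})
    links: tuple = DEFAULT_LINKS
    grid: int = GRID

    def __post_init__(self):
        if len(self.areas) != 12:
            raise ValueError("architecture requires exactly 12 areas")
        names = set(self.areas)
        for a, b, cls in self.links:
            if a not in names or b not in names:
                raise ValueError(f"link ({a}, {b}) references unknown area")
            if cls not in ("within_system", "cross_system"):
                raise ValueError(f"unknown link class {cls!r}")

    @property
    def n_areas(self) -> int:
        return len(self.areas)

    @property
    def n_excitatory(self) -> int:
        return self.n_areas * self.grid * self.grid

    def area_index(self, name: str) -> int:
        return self.areas.index(name)

    def system_of(self, name: str) -> str:
        for sys_name, members in self.systems.items():
            if name in members:
                return sys_name
        raise KeyError(name)


def default_kernels(params=None) -> dict[str, KernelSpec]:
    """The four Gaussian kernels of the standard architecture."""
    return {
        "ee_local": KernelSpec(sigma_x=3.2, sigma_y=3.2, k_c=0.15, half_width=9),
        "ee_within": KernelSpec(sigma_x=9.0, sigma_y=9.0, k_c=0.13, half_width=9),
        "ee_cross": KernelSpec(sigma_x=9.0, sigma_y=9.0, k_c=0.065, half_width=9),
        "ei": KernelSpec(sigma_x=1.42, sigma_y=1.42, k_c=0.295, half_width=2),
    }


def build_architecture(params, rng: np.random.Generator | int,
                       links: Iterable | None = None,
                       exclude_self: bool = True,
                       kernels: dict | None = None,
                       ) -> tuple[Architecture, list[Projection]]:
    """Wire the full 12-area network.

    Per area: local plastic E-E wiring, deterministic E-I / I-E lateral
    inhibition, and the two global-inhibition fan-in/fan-out projections.
    Per link-table entry: a reciprocal pair of plastic between-area E-E
    projections with the within-system or cross-system kernel.  Child
    random streams are spawned per projection in a fixed order, so any
    single projection is reproducible from the master seed alone.
    """
    arch = Architecture(links=tuple(links) if links is not None else DEFAULT_LINKS)
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    k = kernels or default_kernels()
    w_up = params.w_up
    projections: list[Projection] = []

    local_specs = []
    for area in arch.areas:
        local_specs.append(ProjectionSpec(
            area, area, "EE_local", plastic=True, kernel=k["ee_local"],
            strength=params.strength_ee, delay=params.delay_ee,
            weight_init="uniform", w_up=w_up, exclude_self=exclude_self))
        local_specs.append(ProjectionSpec(
            area, area, "EI", kernel=k["ei"],
            strength=1.0, delay=params.delay_short, weight_init="kernel"))
        local_specs.append(ProjectionSpec(
            area, area, "IE", strength=params.strength_ie, delay=params.delay_short))
        local_specs.append(ProjectionSpec(
            area, area, "E_GI", strength=params.strength_e_gi, delay=params.delay_short))
        local_specs.append(ProjectionSpec(
            area, area, "GI_E", strength=params.strength_gi_e, delay=params.delay_short))

    between_specs = []
    for a, b, cls in arch.links:
        kern = k["ee_within"] if cls == "within_system" else k["ee_cross"]
        for src, dst in ((a, b), (b, a)):
            between_specs.append(ProjectionSpec(
                src, dst, "EE_between", plastic=True, kernel=kern,
                strength=params.strength_ee, delay=params.delay_ee,
                weight_init="uniform", w_up=w_up))

    all_specs = local_specs + between_specs
    child_rngs = rng.spawn(len(all_specs))
    for spec, child in zip(all_specs, child_rngs):
        projections.append(wire_projection(spec, child, grid=arch.grid))
    return arch, projections
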