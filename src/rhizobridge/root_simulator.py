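"""Stochastic 3D root-architecture growth engine (CRootBox lineage).

Simulates adventitious root systems of stem cuttings: a configurable number
of primary axes emerge from the stem base and elongate toward an
asymptotic maximal length, steered by a best-of-N tropism scheme
(gravitropism, plagiotropism or exotropism) with a random angular change
per growth sub-segment; laterals of the next root order emerge at regularly
spaced sites along the branching zone of their parent, inserted at a drawn
polar angle and a uniform radial angle; axis radii thicken from an initial
to a maximal radius; geometry is confined to a growth container (a thin
slab mimicking a germination-paper pouch, or a cylinder mimicking a
forestry Deepot) by boundary reflection.

Every per-axis parameter is realized once at axis birth from a truncated
normal distribution, so each simulation is one stochastic draw from the
parameter set. All internal geometry is in mm with depth (z) positive
down; parameters arrive in the model's conventional cm-based units and are
converted at the boundary.

The per-sub-segment angular noise is σΔx = Δx·σ (Δx in cm, σ in the
model's cm⁻¹ convention); because σ here descends from an orientation
spread measured in degrees, the product is interpreted as degrees and
converted to radians for the draw.
"""

from __future__ import annotations

import json
import math
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .parameterization import RootTypeParameters
from .trait_extraction import RootImage

__all__ = [
    "SlabDomain",
    "CylinderDomain",
    "SimulationConfig",
    "RootAxis",
    "RootSystem",
    "sample_truncated_normal",
    "axis_target_length",
    "tropism_direction",
    "grow_step",
    "confine",
    "simulate",
    "init_system",
    "render_projection",
    "export_rsml",
    "read_rsml",
    "export_segments_csv",
    "read_segments_csv",
]

MM_PER_CM = 10.0
HOURS_PER_DAY = 24.0
TROPISM_MODES = ("gravitropism", "plagiotropism", "exotropism")
_EPS = 1e-9


# ---------------------------------------------------------------------------
# domains

@dataclass(frozen=True)
class SlabDomain:
    """Axis-aligned box: x ∈ [−W/2, W/2], y ∈ [−T/2, T/2], z ∈ [0, H] (mm)."""

    width_mm: float
    height_mm: float
    thickness_mm: float

    def __post_init__(self) -> None:
        if min(self.width_mm, self.height_mm, self.thickness_mm) <= 0:
            raise ValueError("slab dimensions must be > 0")

    @property
    def min_extent_mm(self) -> float:
        # The thin (out-of-plane) dimension is excluded: repeated boundary
        # reflection across it is what keeps quasi-2D growth planar, so a
        # pouch thinner than a growth step is legitimate.
        return min(self.width_mm, self.height_mm)

    def contains(self, p: np.ndarray) -> bool:
        return (
            abs(p[0]) <= self.width_mm / 2 + _EPS
            and abs(p[1]) <= self.thickness_mm / 2 + _EPS
            and -_EPS <= p[2] <= self.height_mm + _EPS
        )


@dataclass(frozen=True)
class CylinderDomain:
    """Vertical cylinder: sqrt(x²+y²) ≤ D/2, z ∈ [0, depth] (mm)."""

    diameter_mm: float
    depth_mm: float

    def __post_init__(self) -> None:
        if min(self.diameter_mm, self.depth_mm) <= 0:
            raise ValueError("cylinder dimensions must be > 0")

    @property
    def min_extent_mm(self) -> float:
        return min(self.diameter_mm, self.depth_mm)

    def contains(self, p: np.ndarray) -> bool:
        return (
            math.hypot(p[0], p[1]) <= self.diameter_mm / 2 + _EPS
            and -_EPS <= p[2] <= self.depth_mm + _EPS
        )


def confine(point, domain):
    """Reflect a point across any violated domain boundary; interior points
    are returned unchanged."""
    p, _ = _confine_with_heading(np.asarray(point, dtype=float), None, domain)
    return p


def _confine_with_heading(p, heading, domain, max_iter=16):
    """Mirror-reflect ``p`` into the domain, negating the matching heading
    component at each reflection. Handles corner cases by iterating."""
    p = p.copy()
    h = None if heading is None else heading.copy()
    if not np.all(np.isfinite(p)):
        raise ValueError("point must be finite")
    for _ in range(max_iter):
        moved = False
        if isinstance(domain, SlabDomain):
            half_w = domain.width_mm / 2
            half_t = domain.thickness_mm / 2
            for i, (lo, hi) in enumerate(
                ((-half_w, half_w), (-half_t, half_t), (0.0, domain.height_mm))
            ):
                if p[i] < lo - _EPS:
                    p[i] = 2 * lo - p[i]
                    if h is not None:
                        h[i] = -h[i]
                    moved = True
                elif p[i] > hi + _EPS:
                    p[i] = 2 * hi - p[i]
                    if h is not None:
                        h[i] = -h[i]
                    moved = True
        elif isinstance(domain, CylinderDomain):
            radius = domain.diameter_mm / 2
            d = math.hypot(p[0], p[1])
            if d > radius + _EPS:
                n = np.array([p[0] / d, p[1] / d, 0.0])
                p[0], p[1] = (2 * radius - d) * n[0], (2 * radius - d) * n[1]
                if h is not None:
                    h -= 2 * float(h @ n) * n
                moved = True
            if p[2] < -_EPS:
                p[2] = -p[2]
                if h is not None:
                    h[2] = -h[2]
                moved = True
            elif p[2] > domain.depth_mm + _EPS:
                p[2] = 2 * domain.depth_mm - p[2]
                if h is not None:
                    h[2] = -h[2]
                moved = True
        else:
            raise TypeError(f"unknown domain type {type(domain).__name__}")
        if not moved:
            break
    if h is not None:
        norm = np.linalg.norm(h)
        if norm > 0:
            h /= norm
    return p, h


# ---------------------------------------------------------------------------
# configuration

@dataclass
class SimulationConfig:
    total_days: float
    dt: float = 1.0
    seed: int = 0
    domain: SlabDomain | CylinderDomain = field(
        default_factory=lambda: SlabDomain(279.4, 381.0, 3.175)
    )
    n_primary_roots: int = 1
    tropism_mode: dict = field(
        default_factory=lambda: {1: "gravitropism", 2: "exotropism", 3: "exotropism"}
    )
    sd_frac: float = 0.1
    #: Deepest root order to branch into; None = every order with parameters.
    max_root_order: int | None = None

    def __post_init__(self) -> None:
        if not self.dt > 0:
            raise ValueError("dt must be > 0")
        if self.total_days < 0:
            raise ValueError("total_days must be >= 0")
        if self.n_primary_roots < 1:
            raise ValueError("n_primary_roots must be >= 1")
        if self.sd_frac < 0:
            raise ValueError("sd_frac must be >= 0")
        for order, mode in self.tropism_mode.items():
            if mode not in TROPISM_MODES:
                raise ValueError(f"unknown tropism mode {mode!r} for order {order}")

    @classmethod
    def from_json(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            doc = json.load(fh)
        dom = doc.get("domain", {})
        kind = dom.get("type", "slab")
        if kind == "slab":
            domain = SlabDomain(
                dom.get("width_mm", 279.4),
                dom.get("height_mm", 381.0),
                dom.get("thickness_mm", 3.175),
            )
        elif kind == "cylinder":
            domain = CylinderDomain(dom.get("diameter_mm", 63.5),
                                    dom.get("depth_mm", 254.0))
        else:
            raise ValueError(f"unknown domain type {kind!r}")
        tropism = {
            int(k): v for k, v in doc.get(
                "tropism_mode",
                {"1": "gravitropism", "2": "exotropism", "3": "exotropism"},
            ).items()
        }
        return cls(
            total_days=float(doc["total_days"]),
            dt=float(doc.get("dt", 1.0)),
            seed=int(doc.get("seed", 0)),
            domain=domain,
            n_primary_roots=int(doc.get("n_primary_roots", 1)),
            tropism_mode=tropism,
            sd_frac=float(doc.get("sd_frac", 0.1)),
            max_root_order=(
                int(doc["max_root_order"]) if "max_root_order" in doc else None
            ),
        )


# ---------------------------------------------------------------------------
# sampling and growth primitives

def sample_truncated_normal(mean, sd, lower, upper, rng) -> float:
    """One draw from N(mean, sd) restricted to [lower, upper] by rejection.

    sd = 0 degenerates to the mean clamped into the bounds.
    """
    if not lower < upper:
        raise ValueError(f"invalid bounds: lower {lower} must be < upper {upper}")
    if sd < 0:
        raise ValueError("sd must be >= 0")
    if sd == 0:
        return float(min(max(mean, lower), upper))
    for _ in range(10000):
        x = rng.normal(mean, sd)
        if lower <= x <= upper:
            return float(x)
    # Pathological truncation window far from the mean: fall back to clamping.
    return float(min(max(mean, lower), upper))


def axis_target_length(age, r, l_max) -> float:
    """Axis length at a given age: l(age) = l_max·(1 − exp(−r·age/l_max)).

    Initial slope r, asymptote l_max (never surpassed). Units are free as
    long as r·age and l_max agree.
    """
    if age < 0:
        raise ValueError("age must be >= 0")
    if not (r > 0 and l_max > 0):
        raise ValueError("r and l_max must be > 0")
    return float(l_max * (1.0 - math.exp(-r * age / l_max)))


def _perp_basis(h: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    ref = np.array([0.0, 0.0, 1.0]) if abs(h[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    u = np.cross(h, ref)
    u /= np.linalg.norm(u)
    return u, np.cross(h, u)


def _rotate(h: np.ndarray, polar: float, azimuth: float) -> np.ndarray:
    u, v = _perp_basis(h)
    out = (
        math.cos(polar) * h
        + math.sin(polar) * (math.cos(azimuth) * u + math.sin(azimuth) * v)
    )
    return out / np.linalg.norm(out)


def tropism_direction(
    heading, sigma_dx, N, mode, rng, initial_heading=None
) -> np.ndarray:
    """Best-of-N perturbed heading under a tropism objective.

    Each of the N candidates rotates the current heading by a polar angle
    drawn from N(0, sigma_dx) (radians) about a uniform random azimuth; the
    candidate minimizing the mode's objective is returned — angle to the
    downward vertical (gravitropism), absolute angle to the horizontal
    plane (plagiotropism), or angle to the axis's initial heading
    (exotropism). sigma_dx = 0 leaves the heading unchanged. N = 1 is a
    pure random walk.
    """
    h = np.asarray(heading, dtype=float)
    norm = np.linalg.norm(h)
    if norm == 0:
        raise ValueError("zero heading vector")
    h = h / norm
    if N < 1:
        raise ValueError("N must be >= 1")
    if mode not in TROPISM_MODES:
        raise ValueError(f"unknown tropism mode {mode!r}")
    if sigma_dx == 0:
        return h
    if mode == "exotropism":
        if initial_heading is None:
            raise ValueError("exotropism requires the axis's initial heading")
        init = np.asarray(initial_heading, dtype=float)
        init = init / np.linalg.norm(init)

    best, best_score = None, math.inf
    for _ in range(int(N)):
        polar = rng.normal(0.0, sigma_dx)
        azimuth = rng.uniform(0.0, 2.0 * math.pi)
        cand = _rotate(h, polar, azimuth)
        if mode == "gravitropism":
            score = -cand[2]  # maximize downward component
        elif mode == "plagiotropism":
            score = abs(cand[2])  # minimize vertical component
        else:
            score = -float(cand @ init)
        if score < best_score:
            best, best_score = cand, score
    return best


# ---------------------------------------------------------------------------
# axes and systems

_DRAWN_PARAMS = ("l_b", "l_a", "l_n", "l_max", "r", "a_i", "a_max", "a_r")


@dataclass
class RealizedParams:
    """One axis's realized parameter draw, converted to mm / mm·d⁻¹."""

    l_b_mm: float
    l_a_mm: float
    l_n_mm: float
    l_max_mm: float
    r_mm_per_day: float
    delta_x_mm: float
    sigma_dx_rad: float
    theta_deg: float
    N: int
    a_i_mm: float
    a_max_mm: float
    a_r_mm_per_day: float


def _realize_params(params: RootTypeParameters, sd_frac: float, rng) -> RealizedParams:
    """Draw one truncated-normal realization per parameter.

    The draw uses sd = sd_frac·mean truncated to [max(0, mean−2sd),
    mean+2sd]; the insertion angle θ instead uses the measured orientation
    spread σ as its sd. Draw order is fixed so identical seeds give
    identical axes.
    """

    def draw(mean: float) -> float:
        sd = sd_frac * abs(mean)
        if sd == 0:
            return float(mean)
        lo, hi = max(0.0, mean - 2 * sd), mean + 2 * sd
        if hi <= lo:
            # Non-positive mean (e.g. a_r when a_i ≥ a_max): no spread left
            # after flooring at zero.
            return max(float(mean), 0.0)
        return sample_truncated_normal(mean, sd, lo, hi, rng)

    vals = {name: draw(getattr(params, name)) for name in _DRAWN_PARAMS}
    theta_sd = params.sigma
    if theta_sd > 0:
        lo = max(0.0, params.theta - 2 * theta_sd)
        hi = min(180.0, params.theta + 2 * theta_sd)
        if lo < hi:
            theta = sample_truncated_normal(params.theta, theta_sd, lo, hi, rng)
        else:
            theta = params.theta
    else:
        theta = params.theta
    a_i = min(vals["a_i"], vals["a_max"])
    sigma_dx_deg = params.delta_x * params.sigma  # Δx in cm × σ in cm⁻¹
    return RealizedParams(
        l_b_mm=vals["l_b"] * MM_PER_CM,
        l_a_mm=vals["l_a"] * MM_PER_CM,
        l_n_mm=vals["l_n"] * MM_PER_CM,
        l_max_mm=vals["l_max"] * MM_PER_CM,
        r_mm_per_day=vals["r"] * MM_PER_CM,
        delta_x_mm=params.delta_x * MM_PER_CM,
        sigma_dx_rad=math.radians(sigma_dx_deg),
        theta_deg=theta,
        N=int(params.N),
        a_i_mm=a_i * MM_PER_CM,
        a_max_mm=vals["a_max"] * MM_PER_CM,
        a_r_mm_per_day=vals["a_r"] * HOURS_PER_DAY,  # mm/h → mm/d
    )


@dataclass
class RootAxis:
    axis_id: int
    order: int
    birth_day: float
    parent_id: int | None
    branch_arclength_mm: float
    realized: RealizedParams
    nodes: list = field(default_factory=list)       # np.ndarray (3,) each, mm
    node_birth: list = field(default_factory=list)  # day each node appeared
    heading: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))
    initial_heading: np.ndarray = field(
        default_factory=lambda: np.array([0.0, 0.0, 1.0])
    )
    branch_sites_mm: list = field(default_factory=list)
    next_site: int = 0
    rng: object = None

    @property
    def length_mm(self) -> float:
        if len(self.nodes) < 2:
            return 0.0
        pts = np.asarray(self.nodes)
        return float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())

    def radius_at(self, node_index: int, clock: float) -> float:
        """Node radius in mm at the current clock (a_i → a_max at rate a_r)."""
        age = max(clock - self.node_birth[node_index], 0.0)
        rp = self.realized
        return float(min(rp.a_max_mm, rp.a_i_mm + rp.a_r_mm_per_day * age))

    def position_at(self, s_mm: float) -> tuple[np.ndarray, np.ndarray]:
        """Point and unit tangent at arc length ``s_mm`` along the polyline."""
        if len(self.nodes) < 2:
            base = np.asarray(self.nodes[0] if self.nodes else (0.0, 0.0, 0.0))
            return base, self.heading.copy()
        pts = np.asarray(self.nodes)
        segs = np.diff(pts, axis=0)
        lens = np.linalg.norm(segs, axis=1)
        cum = np.concatenate([[0.0], np.cumsum(lens)])
        s = min(max(s_mm, 0.0), cum[-1])
        i = int(np.searchsorted(cum, s, side="right") - 1)
        i = min(i, len(lens) - 1)
        frac = 0.0 if lens[i] == 0 else (s - cum[i]) / lens[i]
        tangent = segs[i] / lens[i] if lens[i] > 0 else self.heading
        return pts[i] + frac * segs[i], tangent


def expected_branch_sites(l_b_mm, l_a_mm, l_max_mm, l_n_mm) -> list[float]:
    """Branch-site arc lengths: zone [l_b, l_max − l_a] at spacing l_n.

    Fencepost count: floor((l_max − l_a − l_b)/l_n) + 1 sites when the zone
    is non-degenerate. A spacing longer than the whole axis (l_n > l_max)
    disables branching entirely.
    """
    zone = l_max_mm - l_a_mm - l_b_mm
    if zone < -_EPS or l_n_mm <= 0 or l_n_mm > l_max_mm:
        return []
    n = int(math.floor(zone / l_n_mm + 1e-9)) + 1
    return [l_b_mm + i * l_n_mm for i in range(n)]


@dataclass
class RootSystem:
    axes: list = field(default_factory=list)
    clock: float = 0.0
    config: SimulationConfig | None = None
    _next_id: int = 0

    @property
    def topology(self) -> dict:
        children: dict = {}
        for ax in self.axes:
            if ax.parent_id is not None:
                children.setdefault(ax.parent_id, []).append(ax.axis_id)
        return children

    def axis(self, axis_id: int) -> RootAxis:
        for ax in self.axes:
            if ax.axis_id == axis_id:
                return ax
        raise KeyError(axis_id)

    def total_length_mm(self) -> float:
        return float(sum(ax.length_mm for ax in self.axes))

    def _new_axis(
        self, order, birth_day, parent_id, branch_arclength_mm, base_point,
        heading, params_by_order, sd_frac, seed, max_order=3,
    ) -> RootAxis:
        axis_id = self._next_id
        self._next_id += 1
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=seed, spawn_key=(axis_id,))
        )
        realized = _realize_params(params_by_order[order], sd_frac, rng)
        sites = []
        if order < max_order:
            sites = expected_branch_sites(
                realized.l_b_mm, realized.l_a_mm,
                realized.l_max_mm, realized.l_n_mm,
            )
        h = np.asarray(heading, dtype=float)
        h = h / np.linalg.norm(h)
        ax = RootAxis(
            axis_id=axis_id,
            order=order,
            birth_day=birth_day,
            parent_id=parent_id,
            branch_arclength_mm=branch_arclength_mm,
            realized=realized,
            nodes=[np.asarray(base_point, dtype=float)],
            node_birth=[birth_day],
            heading=h.copy(),
            initial_heading=h.copy(),
            branch_sites_mm=sites,
            rng=rng,
        )
        self.axes.append(ax)
        return ax


def _effective_max_order(
    params_by_order: dict[int, RootTypeParameters], config: SimulationConfig
) -> int:
    """Deepest order allowed to branch; errors if parameters are missing."""
    available = max(params_by_order)
    if config.max_root_order is None:
        return min(available, 3)
    want = config.max_root_order
    for k in range(1, want + 1):
        if k not in params_by_order:
            raise ValueError(
                f"no order-{k} parameters while branching requested "
                f"(max_root_order = {want})"
            )
    return min(want, 3)


def init_system(
    params_by_order: dict[int, RootTypeParameters], config: SimulationConfig
) -> RootSystem:
    """Create a system with ``n_primary_roots`` zero-length primaries at the
    stem base, heading straight down."""
    if 1 not in params_by_order:
        raise ValueError("primary-root (order 1) parameters are required")
    max_order = _effective_max_order(params_by_order, config)
    max_dx_mm = max(p.delta_x for p in params_by_order.values()) * MM_PER_CM
    if config.domain.min_extent_mm < 2 * max_dx_mm:
        raise ValueError(
            f"domain extent {config.domain.min_extent_mm} mm thinner than twice "
            f"the growth step {max_dx_mm} mm"
        )
    system = RootSystem(config=config)
    for _ in range(config.n_primary_roots):
        system._new_axis(
            order=1,
            birth_day=0.0,
            parent_id=None,
            branch_arclength_mm=0.0,
            base_point=(0.0, 0.0, 0.0),
            heading=(0.0, 0.0, 1.0),
            params_by_order=params_by_order,
            sd_frac=config.sd_frac,
            seed=config.seed,
            max_order=max_order,
        )
    return system


def _extend_axis(ax: RootAxis, new_clock: float, config: SimulationConfig) -> None:
    rp = ax.realized
    age = new_clock - ax.birth_day
    if age <= 0:
        return
    target = axis_target_length(age, rp.r_mm_per_day, rp.l_max_mm)
    remaining = target - ax.length_mm
    mode = config.tropism_mode.get(ax.order, "gravitropism")
    while remaining > 1e-6:
        step = min(rp.delta_x_mm, remaining)
        if rp.sigma_dx_rad > 0:
            ax.heading = tropism_direction(
                ax.heading, rp.sigma_dx_rad, rp.N, mode, ax.rng,
                initial_heading=ax.initial_heading,
            )
        tip = ax.nodes[-1]
        new_pt = tip + ax.heading * step
        new_pt, new_heading = _confine_with_heading(
            new_pt, ax.heading, config.domain
        )
        ax.heading = new_heading
        ax.nodes.append(new_pt)
        ax.node_birth.append(new_clock)
        remaining -= step
    assert ax.length_mm <= rp.l_max_mm + 1e-6, "axis exceeded realized l_max"


def grow_step(
    system: RootSystem,
    params_by_order: dict[int, RootTypeParameters],
    config: SimulationConfig,
    dt: float,
) -> RootSystem:
    """Advance the system by one time step of ``dt`` days.

    All existing axes elongate toward their target length in sub-segments
    of at most Δx, with tropism applied per sub-segment; afterwards, branch
    sites newly overtaken by their parent's tip spawn zero-length laterals
    of the next order (they start elongating on the following step), with
    insertion polar angle drawn around θ and a uniform radial angle.
    """
    if not dt > 0:
        raise ValueError("dt must be > 0")
    max_order = _effective_max_order(params_by_order, config)
    before = system.total_length_mm()
    new_clock = system.clock + dt
    for ax in list(system.axes):
        _extend_axis(ax, new_clock, config)
    for ax in list(system.axes):
        while (
            ax.next_site < len(ax.branch_sites_mm)
            and ax.branch_sites_mm[ax.next_site] <= ax.length_mm + _EPS
        ):
            s = ax.branch_sites_mm[ax.next_site]
            ax.next_site += 1
            child_order = ax.order + 1
            if child_order not in params_by_order:
                raise ValueError(
                    f"no order-{child_order} parameters while branching requested"
                )
            base, tangent = ax.position_at(s)
            child = system._new_axis(
                order=child_order,
                birth_day=new_clock,
                parent_id=ax.axis_id,
                branch_arclength_mm=s,
                base_point=base,
                heading=tangent,
                params_by_order=params_by_order,
                sd_frac=config.sd_frac,
                seed=config.seed,
                max_order=max_order,
            )
            polar = math.radians(child.realized.theta_deg)
            azimuth = child.rng.uniform(0.0, 2.0 * math.pi)
            h = _rotate(tangent / np.linalg.norm(tangent), polar, azimuth)
            child.heading = h.copy()
            child.initial_heading = h.copy()
    system.clock = new_clock
    assert system.total_length_mm() >= before - 1e-9, "total length decreased"
    return system


def simulate(
    params_by_order: dict[int, RootTypeParameters], config: SimulationConfig
) -> RootSystem:
    """Run a full simulation from day 0 to ``config.total_days``."""
    system = init_system(params_by_order, config)
    n_steps = int(round(config.total_days / config.dt))
    leftover = config.total_days - n_steps * config.dt
    for _ in range(n_steps):
        grow_step(system, params_by_order, config, config.dt)
    if leftover > 1e-12:
        grow_step(system, params_by_order, config, leftover)
    return system


# ---------------------------------------------------------------------------
# rendering and serialization

def render_projection(
    system: RootSystem,
    plane: str = "xz",
    scale_mm_per_px: float = 0.5,
    trim_radius_mm: float | None = None,
    padding_mm: float = 5.0,
) -> RootImage:
    """Orthographic projection of the system onto a vertical plane.

    Each polyline segment is stroked at its local diameter with round
    caps. ``trim_radius_mm`` removes segments whose endpoints lie farther
    than that 3D distance from the stem base, mirroring trimming of roots
    beyond a fixed radius before crown imaging. Depth (z) maps to image
    rows so row 0 is the stem end.
    """
    from PIL import Image, ImageDraw

    if not scale_mm_per_px > 0:
        raise ValueError("scale must be > 0")
    if plane not in ("xz", "yz"):
        raise ValueError("plane must be 'xz' or 'yz'")
    horiz = 0 if plane == "xz" else 1

    segs = []  # (u1, v1, u2, v2, diameter_mm)
    base = np.zeros(3)
    for ax in system.axes:
        for i in range(len(ax.nodes) - 1):
            p1, p2 = ax.nodes[i], ax.nodes[i + 1]
            if trim_radius_mm is not None:
                if (
                    np.linalg.norm(p1 - base) > trim_radius_mm
                    or np.linalg.norm(p2 - base) > trim_radius_mm
                ):
                    continue
            d = ax.radius_at(i, system.clock) + ax.radius_at(i + 1, system.clock)
            segs.append((p1[horiz], p1[2], p2[horiz], p2[2], d))

    if not segs:
        side = max(int(round(2 * padding_mm / scale_mm_per_px)), 4)
        return RootImage(
            mask=np.zeros((side, side), dtype=bool),
            scale=scale_mm_per_px,
            provenance="simulated",
        )

    arr = np.asarray([s[:4] for s in segs])
    u_min = min(arr[:, 0].min(), arr[:, 2].min()) - padding_mm
    u_max = max(arr[:, 0].max(), arr[:, 2].max()) + padding_mm
    v_min = min(arr[:, 1].min(), arr[:, 3].min()) - padding_mm
    v_max = max(arr[:, 1].max(), arr[:, 3].max()) + padding_mm
    w_px = max(int(math.ceil((u_max - u_min) / scale_mm_per_px)), 1)
    h_px = max(int(math.ceil((v_max - v_min) / scale_mm_per_px)), 1)

    img = Image.new("L", (w_px, h_px), 0)
    draw = ImageDraw.Draw(img)

    def to_px(u, v):
        # +0.5 puts coordinates at pixel centers, so thin strokes do not
        # jitter across a pixel boundary.
        return (
            (u - u_min) / scale_mm_per_px + 0.5,
            (v - v_min) / scale_mm_per_px + 0.5,
        )

    for u1, v1, u2, v2, d in segs:
        width_px = max(int(round(d / scale_mm_per_px)), 1)
        a, b = to_px(u1, v1), to_px(u2, v2)
        draw.line([a, b], fill=255, width=width_px)
        half = width_px / 2.0
        for (cu, cv) in (a, b):
            draw.ellipse(
                [cu - half, cv - half, cu + half, cv + half], fill=255
            )
    mask = np.asarray(img) > 0
    return RootImage(mask=mask, scale=scale_mm_per_px, provenance="simulated")


def export_segments_csv(system: RootSystem, path) -> None:
    """One CSV row per polyline sub-segment, deterministic for a given
    system state."""
    rows = []
    for ax in system.axes:
        for i in range(len(ax.nodes) - 1):
            p1, p2 = ax.nodes[i], ax.nodes[i + 1]
            rows.append({
                "axis_id": ax.axis_id,
                "parent_id": -1 if ax.parent_id is None else ax.parent_id,
                "order": ax.order,
                "seg_index": i,
                "birth_day": ax.node_birth[i + 1],
                "x1": p1[0], "y1": p1[1], "z1": p1[2],
                "x2": p2[0], "y2": p2[1], "z2": p2[2],
                "radius_mm": 0.5 * (
                    ax.radius_at(i, system.clock)
                    + ax.radius_at(i + 1, system.clock)
                ),
            })
    cols = ["axis_id", "parent_id", "order", "seg_index", "birth_day",
            "x1", "y1", "z1", "x2", "y2", "z2", "radius_mm"]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False, float_format="%.6f")


def read_segments_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def export_rsml(system: RootSystem, path) -> None:
    """Write the system as an RSML 1.0 document.

    Scene → plant → nested root hierarchy; polyline geometry in mm;
    per-point diameter as a point-level function; root order as an
    annotation.
    """
    rsml = ET.Element("rsml")
    meta = ET.SubElement(rsml, "metadata")
    ET.SubElement(meta, "version").text = "1"
    ET.SubElement(meta, "unit").text = "mm"
    ET.SubElement(meta, "resolution").text = "1"
    ET.SubElement(meta, "software").text = "rhizobridge"
    scene = ET.SubElement(rsml, "scene")
    plant = ET.SubElement(scene, "plant", id="1", label="cutting")

    children = system.topology

    def add_root(parent_el, ax: RootAxis):
        root_el = ET.SubElement(parent_el, "root", id=str(ax.axis_id),
                                label=f"order{ax.order}")
        props = ET.SubElement(root_el, "properties")
        ET.SubElement(props, "rulerAtOrigin").text = "0"
        geom = ET.SubElement(root_el, "geometry")
        poly = ET.SubElement(geom, "polyline")
        for p in ax.nodes:
            ET.SubElement(
                poly, "point",
                x=f"{p[0]:.6f}", y=f"{p[1]:.6f}", z=f"{p[2]:.6f}",
            )
        funcs = ET.SubElement(root_el, "functions")
        fn = ET.SubElement(funcs, "function", name="diameter", domain="polyline")
        for i in range(len(ax.nodes)):
            ET.SubElement(
                fn, "sample",
                value=f"{2 * ax.radius_at(i, system.clock):.6f}",
            )
        ann = ET.SubElement(root_el, "annotations")
        order_ann = ET.SubElement(ann, "annotation", name="order")
        ET.SubElement(order_ann, "value").text = str(ax.order)
        for child_id in children.get(ax.axis_id, []):
            add_root(root_el, system.axis(child_id))

    for ax in system.axes:
        if ax.parent_id is None:
            add_root(plant, ax)

    tree = ET.ElementTree(rsml)
    ET.indent(tree)
    tree.write(path, xml_declaration=True, encoding="unicode")


def read_rsml(path) -> list[dict]:
    """Parse an RSML document back into a flat list of root dicts.

    Each dict holds id, order, parent_id (None for top-level roots), the
    polyline as an (n, 3) array in mm, and per-point diameters.
    """
    tree = ET.parse(path)
    out = []

    def walk(root_el, parent_id):
        rid = int(root_el.get("id"))
        pts = np.asarray([
            [float(p.get("x")), float(p.get("y")), float(p.get("z"))]
            for p in root_el.findall("./geometry/polyline/point")
        ]).reshape(-1, 3)
        diam = np.asarray([
            float(s.get("value"))
            for s in root_el.findall("./functions/function[@name='diameter']/sample")
        ])
        order_txt = root_el.find("./annotations/annotation[@name='order']/value")
        out.append({
            "id": rid,
            "parent_id": parent_id,
            "order": int(order_txt.text) if order_txt is not None else None,
            "polyline": pts,
            "diameter": diam,
        })
        for sub in root_el.findall("root"):
            walk(sub, rid)

    for plant in tree.getroot().findall("./scene/plant"):
        for root_el in plant.findall("root"):
            walk(root_el, None)
    return out
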