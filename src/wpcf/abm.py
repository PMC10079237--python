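"""Off-lattice agent-based model of tumour-macrophage-vessel interactions.

The model simulates a 2D tissue region containing stromal cells, tumour
cells, necrotic cells, macrophages and fixed blood vessels, coupled to five
diffusible fields: oxygen (omega), CSF-1 (c), CXCL12 (xi), TGF-beta (g) and
EGF (epsilon).  Cell centres move by the overdamped force balance

    nu dx_i/dt = F_i,

integrated with forward Euler, where F_i sums pairwise linear spring forces
(volume exclusion and adhesion within an interaction radius R_int),
isotropic random motility (macrophages), and chemotactic forces directed up
normalised gradients: macrophages climb CSF-1 with strength chi_c_m (1 - p)
and CXCL12 with strength chi_xi_m p, tumour cells climb EGF with strength
chi_eps_T.

Macrophage phenotype p in [0, 1] starts at 0 (anti-tumour, M1) on
extravasation and ratchets towards 1 (pro-tumour, M2) at rate delta_p per
hour whenever local TGF-beta exceeds g_crit:

    dp_i/dt = H(g(x_i, t) - g_crit) H(1 - p_i) delta_p.

Macrophages extravasate from vessels with probability per hour
P_ex = P_star c / (c + c_half), and kill adjacent tumour cells with
probability per hour P_phi = P_phi_star (1 - p^10 / (p^10 + 0.5^10)) once a
cooldown t_cool has elapsed since their last kill.  Killed tumour cells
become necrotic, shrink linearly and are removed.

Stromal and tumour cells progress through an oxygen-gated cell cycle:
below the type's hypoxic threshold the clock pauses (reversibly); below the
necrosis threshold the cell dies (irreversibly).  Mechanically compressed
stromal cells also pause (contact inhibition).

Fields obey reaction-diffusion equations with point sources at cells or
vessels, e.g. EGF:

    d eps/dt = D_eps lap(eps) - lambda_eps eps + kappa_eps sum_i p_i delta(x - x_i),

integrated explicitly on a regular grid with sub-stepping inside the
diffusive stability bound.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field, replace
from pathlib import Path

import numpy as np
from scipy.ndimage import map_coordinates
from scipy.spatial import cKDTree

from .pointcloud import Domain, LabelledPointCloud

__all__ = [
    "ABMParams",
    "CellAgent",
    "DiffusibleField",
    "ABMState",
    "extravasation_probability",
    "kill_probability",
    "chemotactic_forces",
    "initial_state",
    "step",
    "run",
]

STROMAL, TUMOUR, NECROTIC, MACROPHAGE = 0, 1, 2, 3
_TYPE_TO_CATEGORY = np.array(["S", "T", "N", "M"])


@dataclass(frozen=True)
class ABMParams:
    """All model parameters, in units of cell diameters and hours.

    Forces are measured in units of nu * (cell diameter / hour), so with
    nu = 1 a force of magnitude f moves a free cell at f diameters per hour.
    """

    # mechanics
    nu: float = 1.0                  # drag coefficient
    R_int: float = 1.5               # interaction radius (diameters)
    spring_k: float = 4.0            # repulsion stiffness (force / diameter)
    adhesion_k: float = 1.0          # adhesion stiffness beyond the rest length
    cell_radius: float = 0.5
    mac_radius: float = 0.4          # macrophages are smaller and squeeze through gaps
    random_motility: float = 1.0     # macrophage random-force magnitude

    # macrophage chemotaxis / phenotype / killing
    chi_c_m: float = 1.0             # CSF-1 chemotactic strength
    chi_xi_m: float = 6.0            # CXCL12 chemotactic strength
    chi_eps_T: float = 3.5           # tumour-cell EGF chemotactic strength
    K_eps_grad: float = 0.02         # EGF-gradient half-saturation for tumour taxis
    crowding_yield: float = 2.0      # active-force resistance per unit summed overlap
    P_star: float = 0.25             # max extravasation probability / h
    c_half: float = 0.5              # CSF-1 half-saturation
    P_phi_star: float = 0.07         # max kill probability / h
    t_cool: float = 10.0             # kill cooldown (h)
    delta_p: float = 0.12            # phenotype rate (/h)
    g_crit: float = 0.8              # TGF-beta threshold

    # diffusible fields: (D, lambda) plus source/consumption rates
    D_omega: float = 10.0
    lambda_omega: float = 0.05
    s_omega: float = 3.0             # oxygen source rate per vessel
    k_omega_S: float = 0.005         # oxygen consumption per stromal cell
    k_omega_T: float = 0.08          # oxygen consumption per tumour cell
    D_c: float = 15.0
    lambda_c: float = 0.15
    kappa_c: float = 1.0             # CSF-1 production per tumour cell
    D_xi: float = 15.0
    lambda_xi: float = 0.3
    s_xi: float = 0.5                # CXCL12 source rate per vessel
    D_g: float = 2.0
    lambda_g: float = 0.6
    kappa_g: float = 0.5             # TGF-beta production per tumour cell
    D_eps: float = 15.0
    lambda_eps: float = 0.5
    kappa_eps: float = 8.0           # EGF production per unit phenotype

    # oxygen thresholds and cycle
    omega_H_tum: float = 0.3
    omega_N_tum: float = 0.1
    omega_H_str: float = 0.15
    omega_N_str: float = 0.05
    A_H_str: float = 0.85            # stromal contact-inhibition area fraction
    A_H_tum: float = 0.45            # tumour contact-inhibition area fraction
    cycle_duration: float = 16.0     # mean cell-cycle time (h)
    necrosis_clear_time: float = 30.0
    division_offset: float = 0.3

    # numerics / geometry
    dt: float = 0.05                 # timestep (h)
    max_step_displacement: float = 0.5  # per-step movement cap (diameters)
    field_spacing: float = 1.0       # PDE grid spacing (diameters)
    domain: Domain = dc_field(default_factory=lambda: Domain(0.0, 40.0, 0.0, 40.0))

    # initial condition
    n_vessels: int = 20
    vessel_min_sep: float = 4.0
    vessel_exclusion_radius: float = 12.0  # keep vessels away from the seed tumour
    n_tumour_init: int = 30
    stroma_spacing: float = 1.8
    stroma_cycle_scale: float = 10.0  # stromal cycle is this much slower than tumour

    def __post_init__(self) -> None:
        positive = (
            "nu R_int spring_k cell_radius P_star c_half P_phi_star t_cool "
            "delta_p D_omega D_c D_xi D_g D_eps cycle_duration "
            "necrosis_clear_time dt field_spacing"
        ).split()
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"parameter {name} must be positive")
        if self.dt * self.P_star > 1 or self.dt * self.P_phi_star > 1:
            raise ValueError("dt * max probability per hour exceeds 1 (rate overflow)")
        if not (self.omega_N_tum < self.omega_H_tum):
            raise ValueError("need omega_N_tum < omega_H_tum")
        if not (self.omega_N_str < self.omega_H_str):
            raise ValueError("need omega_N_str < omega_H_str")
        if not (0 < self.A_H_str < 1):
            raise ValueError("A_H_str must lie in (0, 1)")
        if self.field_spacing > self.R_int:
            raise ValueError("field grid must resolve the interaction radius")

    @classmethod
    def from_toml(cls, path: str | Path) -> "ABMParams":
        """Load parameters from a TOML file with optional [domain] table."""
        import tomllib

        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        flat: dict = {}
        for key, value in data.items():
            if key == "domain":
                flat["domain"] = Domain.from_dict(value)
            elif isinstance(value, dict):
                flat.update(value)
            else:
                flat[key] = value
        return cls(**flat)

    def with_overrides(self, **kwargs) -> "ABMParams":
        return replace(self, **kwargs)


@dataclass
class CellAgent:
    """Read-only per-cell view used for inspection and testing."""

    id: int
    position: np.ndarray
    type: str  # "stromal" | "tumour" | "necrotic" | "macrophage"
    radius: float
    cycle_state: str
    cycle_clock: float
    phenotype: float | None
    kill_timer: float | None
    necrosis_clock: float | None


class DiffusibleField:
    """One reaction-diffusion field on a regular grid over the domain.

    Explicit 5-point finite differences with automatic sub-stepping inside
    the diffusive stability bound dt <= h^2 / (4 D).  Boundary condition is
    no-flux for clipped domains and wrapping for periodic ones.
    """

    def __init__(
        self,
        name: str,
        domain: Domain,
        D: float,
        lam: float,
        spacing: float = 1.0,
        initial: float = 0.0,
    ) -> None:
        self.name = name
        self.domain = domain
        self.D = D
        self.lam = lam
        self.h = spacing
        self.nx = int(round(domain.width / spacing)) + 1
        self.ny = int(round(domain.height / spacing)) + 1
        if domain.boundary_mode == "periodic":
            # periodic grids identify x_max with x_min: one fewer node
            self.nx -= 1
            self.ny -= 1
        self.grid = np.full((self.nx, self.ny), float(initial))

    # -- geometry helpers ---------------------------------------------------

    def _index_coords(self, positions: np.ndarray) -> np.ndarray:
        p = np.asarray(positions, dtype=float).reshape(-1, 2)
        ix = (p[:, 0] - self.domain.x_min) / self.h
        iy = (p[:, 1] - self.domain.y_min) / self.h
        return np.vstack([ix, iy])

    def deposit(self, positions: np.ndarray, rates: np.ndarray) -> np.ndarray:
        """Point sources mapped to nearest grid nodes, as concentration rates.

        A point source of strength s (amount per hour) on a grid of cell
        area h^2 contributes s / h^2 to the local concentration rate.
        """
        src = np.zeros_like(self.grid)
        if len(positions) == 0:
            return src
        idx = np.rint(self._index_coords(positions)).astype(int)
        if self.domain.boundary_mode == "periodic":
            idx[0] %= self.nx
            idx[1] %= self.ny
        else:
            idx[0] = np.clip(idx[0], 0, self.nx - 1)
            idx[1] = np.clip(idx[1], 0, self.ny - 1)
        np.add.at(src, (idx[0], idx[1]), np.asarray(rates, dtype=float) / self.h**2)
        return src

    def _laplacian(self, u: np.ndarray) -> np.ndarray:
        if self.domain.boundary_mode == "periodic":
            return (
                np.roll(u, 1, 0) + np.roll(u, -1, 0) + np.roll(u, 1, 1) + np.roll(u, -1, 1) - 4 * u
            ) / self.h**2
        padded = np.pad(u, 1, mode="edge")  # zero normal derivative
        return (
            padded[:-2, 1:-1] + padded[2:, 1:-1] + padded[1:-1, :-2] + padded[1:-1, 2:] - 4 * u
        ) / self.h**2

    def stable_substep(self, dt: float) -> tuple[int, float]:
        limit = 0.9 * self.h**2 / (4.0 * self.D) if self.D > 0 else dt
        n_sub = max(1, math.ceil(dt / limit))
        return n_sub, dt / n_sub

    def step(self, dt: float, source: np.ndarray | None = None) -> None:
        """Advance the field by dt with source term ``source`` (rate grid).

        Concentrations are clamped at zero so point consumption cannot
        drive them negative.
        """
        n_sub, h_dt = self.stable_substep(dt)
        decay = math.exp(-self.lam * h_dt)
        for _ in range(n_sub):
            rhs = self.D * self._laplacian(self.grid)
            if source is not None:
                rhs = rhs + source
            # operator splitting: explicit diffusion + source, then exact
            # exponential decay (uniform fields decay as e^(-lambda t) to
            # machine precision)
            self.grid += h_dt * rhs
            self.grid *= decay
            np.maximum(self.grid, 0.0, out=self.grid)

    def value_at(self, positions: np.ndarray) -> np.ndarray:
        if len(positions) == 0:
            return np.zeros(0)
        mode = "grid-wrap" if self.domain.boundary_mode == "periodic" else "nearest"
        return map_coordinates(self.grid, self._index_coords(positions), order=1, mode=mode)

    def gradient_at(self, positions: np.ndarray) -> np.ndarray:
        """(n, 2) finite-difference gradient interpolated at positions."""
        if len(positions) == 0:
            return np.zeros((0, 2))
        gx, gy = np.gradient(self.grid, self.h)
        coords = self._index_coords(positions)
        mode = "grid-wrap" if self.domain.boundary_mode == "periodic" else "nearest"
        return np.column_stack(
            [
                map_coordinates(gx, coords, order=1, mode=mode),
                map_coordinates(gy, coords, order=1, mode=mode),
            ]
        )

    @property
    def total_mass(self) -> float:
        return float(self.grid.sum() * self.h**2)


class ABMState:
    """Complete simulation state: cells, vessels, fields, time and RNG.

    Cell attributes are stored as parallel arrays for speed; ``cells``
    materialises them as :class:`CellAgent` views.
    """

    def __init__(self, params: ABMParams, rng: np.random.Generator) -> None:
        self.params = params
        self.rng = rng
        self.time = 0.0
        self.positions = np.zeros((0, 2))
        self.types = np.zeros(0, dtype=np.int8)
        self.radii = np.zeros(0)
        self.cycle_clock = np.zeros(0)
        self.cycle_length = np.zeros(0)  # per-cell sampled division time
        self.phenotype = np.zeros(0)
        self.kill_timer = np.zeros(0)
        self.necrosis_clock = np.zeros(0)
        self.paused_hypoxic = np.zeros(0, dtype=bool)
        self.paused_contact = np.zeros(0, dtype=bool)
        self.next_id = 0
        self.ids = np.zeros(0, dtype=np.int64)
        self.vessels = np.zeros((0, 2))
        self.fields: dict[str, DiffusibleField] = {}

    # -- bookkeeping --------------------------------------------------------

    def n_of(self, cell_type: int) -> int:
        return int(np.sum(self.types == cell_type))

    def add_cells(
        self,
        positions: np.ndarray,
        cell_type: int,
        phenotype: float = 0.0,
        kill_timer: float = 0.0,
        cycle_clock: np.ndarray | None = None,
    ) -> None:
        n = len(positions)
        if n == 0:
            return
        p = self.params
        self.positions = np.vstack([self.positions, np.asarray(positions, float)])
        self.types = np.concatenate([self.types, np.full(n, cell_type, dtype=np.int8)])
        radius = p.mac_radius if cell_type == MACROPHAGE else p.cell_radius
        self.radii = np.concatenate([self.radii, np.full(n, radius)])
        clocks = np.zeros(n) if cycle_clock is None else np.asarray(cycle_clock, float)
        self.cycle_clock = np.concatenate([self.cycle_clock, clocks])
        mean_cycle = p.cycle_duration * (p.stroma_cycle_scale if cell_type == STROMAL else 1.0)
        lengths = mean_cycle * self.rng.uniform(0.75, 1.25, n)
        self.cycle_length = np.concatenate([self.cycle_length, lengths])
        self.phenotype = np.concatenate([self.phenotype, np.full(n, float(phenotype))])
        self.kill_timer = np.concatenate([self.kill_timer, np.full(n, float(kill_timer))])
        self.necrosis_clock = np.concatenate([self.necrosis_clock, np.zeros(n)])
        self.paused_hypoxic = np.concatenate([self.paused_hypoxic, np.zeros(n, dtype=bool)])
        self.paused_contact = np.concatenate([self.paused_contact, np.zeros(n, dtype=bool)])
        self.ids = np.concatenate(
            [self.ids, np.arange(self.next_id, self.next_id + n, dtype=np.int64)]
        )
        self.next_id += n

    def remove_cells(self, mask: np.ndarray) -> None:
        keep = ~mask
        for name in (
            "positions",
            "types",
            "radii",
            "cycle_clock",
            "cycle_length",
            "phenotype",
            "kill_timer",
            "necrosis_clock",
            "paused_hypoxic",
            "paused_contact",
            "ids",
        ):
            setattr(self, name, getattr(self, name)[keep])

    @property
    def cells(self) -> list[CellAgent]:
        type_names = ("stromal", "tumour", "necrotic", "macrophage")
        out = []
        for i in range(len(self.positions)):
            t = int(self.types[i])
            state = "progressing"
            if self.paused_hypoxic[i]:
                state = "paused_hypoxic"
            elif self.paused_contact[i]:
                state = "paused_contact"
            out.append(
                CellAgent(
                    id=int(self.ids[i]),
                    position=self.positions[i].copy(),
                    type=type_names[t],
                    radius=float(self.radii[i]),
                    cycle_state=state,
                    cycle_clock=float(self.cycle_clock[i]),
                    phenotype=float(self.phenotype[i]) if t == MACROPHAGE else None,
                    kill_timer=float(self.kill_timer[i]) if t == MACROPHAGE else None,
                    necrosis_clock=float(self.necrosis_clock[i]) if t == NECROTIC else None,
                )
            )
        return out

    def snapshot(self) -> LabelledPointCloud:
        """Export the state as a labelled point cloud (vessels as B)."""
        positions = np.vstack([self.vessels, self.positions])
        categories = np.concatenate(
            [np.full(len(self.vessels), "B"), _TYPE_TO_CATEGORY[self.types]]
        )
        marks = np.concatenate(
            [
                np.full(len(self.vessels), np.nan),
                np.where(self.types == MACROPHAGE, self.phenotype, np.nan),
            ]
        )
        return LabelledPointCloud(
            positions=positions,
            categories=categories,
            marks=marks,
            domain=self.params.domain,
            time=self.time,
        )


# ---------------------------------------------------------------------------
# elementary rate laws


def extravasation_probability(c_local: float, params: ABMParams) -> float:
    """P_ex = P_star c / (c + c_half): saturating in local CSF-1."""
    c = max(float(c_local), 0.0)
    if c == 0.0:
        return 0.0
    return params.P_star * c / (c + params.c_half)


def kill_probability(p: float, t_phi: float, params: ABMParams) -> float:
    """Probability per hour that a macrophage kills an adjacent tumour cell.

    Decreases steeply with phenotype (Hill exponent 10, midpoint 0.5) and is
    zero while the post-kill cooldown is running.
    """
    if t_phi < params.t_cool:
        return 0.0
    p10 = float(p) ** 10
    return params.P_phi_star * (1.0 - p10 / (p10 + 0.5**10))


def chemotactic_forces(
    phenotype: np.ndarray,
    grad_c: np.ndarray,
    grad_xi: np.ndarray,
    params: ABMParams,
) -> np.ndarray:
    """Macrophage chemotactic force chi_c (1-p) c_hat + chi_xi p xi_hat.

    Gradients are normalised to unit vectors; a vanishing gradient
    contributes no force (the 0/0 convention).
    """
    phenotype = np.atleast_1d(np.asarray(phenotype, dtype=float))
    grad_c = np.asarray(grad_c, dtype=float).reshape(len(phenotype), 2)
    grad_xi = np.asarray(grad_xi, dtype=float).reshape(len(phenotype), 2)
    out = np.zeros((len(phenotype), 2))
    for strength, grad in (
        (params.chi_c_m * (1.0 - phenotype), grad_c),
        (params.chi_xi_m * phenotype, grad_xi),
    ):
        norm = np.hypot(grad[:, 0], grad[:, 1])
        ok = norm > 1e-12
        out[ok] += strength[ok, None] * grad[ok] / norm[ok, None]
    return out


# ---------------------------------------------------------------------------
# initial condition


def _place_vessels(params: ABMParams, rng: np.random.Generator) -> np.ndarray:
    dom = params.domain
    center = np.array([(dom.x_min + dom.x_max) / 2, (dom.y_min + dom.y_max) / 2])
    vessels: list[np.ndarray] = []
    margin = 1.0
    for _ in range(20000):
        if len(vessels) == params.n_vessels:
            break
        cand = rng.uniform(
            [dom.x_min + margin, dom.y_min + margin],
            [dom.x_max - margin, dom.y_max - margin],
        )
        if np.linalg.norm(cand - center) < params.vessel_exclusion_radius:
            continue
        if vessels and min(np.linalg.norm(cand - v) for v in vessels) < params.vessel_min_sep:
            continue
        vessels.append(cand)
    if len(vessels) < params.n_vessels:
        raise RuntimeError("could not place vessels with the requested separation")
    return np.array(vessels)


def _tumour_disc(n: int, center: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Approximately close-packed disc of n cells, unit spacing."""
    pts = [center.copy()]
    ring = 1
    while len(pts) < n:
        count = 6 * ring
        angles = 2 * np.pi * (np.arange(count) + 0.5 * (ring % 2)) / count
        for a in angles:
            if len(pts) >= n:
                break
            pts.append(center + ring * np.array([np.cos(a), np.sin(a)]))
        ring += 1
    return np.array(pts) + rng.uniform(-0.05, 0.05, size=(n, 2))


def initial_state(params: ABMParams, seed: int = 0) -> ABMState:
    """Seed tumour disc at the domain centre, jittered stromal lattice
    elsewhere, vessels away from the tumour, oxygen pre-relaxed to its
    quasi-steady profile (other fields start from zero)."""
    rng = np.random.default_rng(seed)
    state = ABMState(params, rng)
    dom = params.domain
    center = np.array([(dom.x_min + dom.x_max) / 2, (dom.y_min + dom.y_max) / 2])

    state.vessels = _place_vessels(params, rng)

    tum = _tumour_disc(params.n_tumour_init, center, rng)
    state.add_cells(
        tum,
        TUMOUR,
        cycle_clock=rng.uniform(0, params.cycle_duration, len(tum)),
    )

    a = params.stroma_spacing
    xs = np.arange(dom.x_min + a / 2, dom.x_max, a)
    ys = np.arange(dom.y_min + a / 2, dom.y_max, a)
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    lattice = np.column_stack([gx.ravel(), gy.ravel()])
    lattice = lattice + rng.uniform(-0.15 * a, 0.15 * a, lattice.shape)
    lattice[:, 0] = np.clip(lattice[:, 0], dom.x_min, dom.x_max)
    lattice[:, 1] = np.clip(lattice[:, 1], dom.y_min, dom.y_max)
    tumour_clearance = math.sqrt(params.n_tumour_init / math.pi) + 1.0
    keep = np.linalg.norm(lattice - center, axis=1) > tumour_clearance
    state.add_cells(
        lattice[keep],
        STROMAL,
        cycle_clock=rng.uniform(0, params.cycle_duration, int(keep.sum())),
    )

    h = params.field_spacing
    state.fields = {
        "oxygen": DiffusibleField("oxygen", dom, params.D_omega, params.lambda_omega, h),
        "csf1": DiffusibleField("csf1", dom, params.D_c, params.lambda_c, h),
        "cxcl12": DiffusibleField("cxcl12", dom, params.D_xi, params.lambda_xi, h),
        "tgfb": DiffusibleField("tgfb", dom, params.D_g, params.lambda_g, h),
        "egf": DiffusibleField("egf", dom, params.D_eps, params.lambda_eps, h),
    }
    # relax oxygen to its vessel-supplied steady profile so cells do not
    # start in spurious anoxia
    oxy = state.fields["oxygen"]
    src = _oxygen_source(state)
    for _ in range(60):
        oxy.step(1.0, src)
    return state


# ---------------------------------------------------------------------------
# per-step operations


def _oxygen_source(state: ABMState) -> np.ndarray:
    p = state.params
    oxy = state.fields["oxygen"]
    src = oxy.deposit(state.vessels, np.full(len(state.vessels), p.s_omega))
    consumers = (state.types == STROMAL) | (state.types == TUMOUR)
    if consumers.any():
        rates = np.where(state.types[consumers] == TUMOUR, p.k_omega_T, p.k_omega_S)
        src -= oxy.deposit(state.positions[consumers], rates)
    return src


def update_fields(state: ABMState, dt: float) -> None:
    """Advance all five reaction-diffusion fields by dt."""
    p = state.params
    tum = state.positions[state.types == TUMOUR]
    mac = state.types == MACROPHAGE

    state.fields["oxygen"].step(dt, _oxygen_source(state))
    state.fields["csf1"].step(
        dt, state.fields["csf1"].deposit(tum, np.full(len(tum), p.kappa_c))
    )
    state.fields["cxcl12"].step(
        dt,
        state.fields["cxcl12"].deposit(
            state.vessels, np.full(len(state.vessels), p.s_xi)
        ),
    )
    state.fields["tgfb"].step(
        dt, state.fields["tgfb"].deposit(tum, np.full(len(tum), p.kappa_g))
    )
    state.fields["egf"].step(
        dt,
        state.fields["egf"].deposit(
            state.positions[mac], p.kappa_eps * state.phenotype[mac]
        ),
    )


def attempt_extravasation(state: ABMState, dt: float) -> None:
    """Vessels spawn M1 macrophages (p = 0) at rate P_ex per hour."""
    p = state.params
    if p.dt * p.P_star > 1:
        raise ValueError("dt * P_star exceeds 1: extravasation probability overflow")
    if len(state.vessels) == 0:
        return
    c_local = state.fields["csf1"].value_at(state.vessels)
    prob = np.array([extravasation_probability(c, p) for c in c_local]) * dt
    fire = state.rng.random(len(state.vessels)) < prob
    if not fire.any():
        return
    n_new = int(fire.sum())
    angles = state.rng.uniform(0, 2 * np.pi, n_new)
    offsets = 0.5 * np.column_stack([np.cos(angles), np.sin(angles)])
    pos = state.vessels[fire] + offsets
    dom = p.domain
    pos[:, 0] = np.clip(pos[:, 0], dom.x_min, dom.x_max)
    pos[:, 1] = np.clip(pos[:, 1], dom.y_min, dom.y_max)
    # new macrophages are kill-eligible immediately: timer starts at t_cool
    state.add_cells(pos, MACROPHAGE, phenotype=0.0, kill_timer=p.t_cool)


def update_phenotypes(state: ABMState, dt: float) -> None:
    """Ratchet phenotype towards M2 where TGF-beta exceeds g_crit."""
    p = state.params
    mac = state.types == MACROPHAGE
    if not mac.any():
        return
    g_local = state.fields["tgfb"].value_at(state.positions[mac])
    advance = (g_local > p.g_crit) & (state.phenotype[mac] < 1.0)
    pheno = state.phenotype[mac]
    pheno[advance] = np.minimum(pheno[advance] + p.delta_p * dt, 1.0)
    state.phenotype[mac] = pheno


def attempt_killing(state: ABMState, dt: float, tree: cKDTree | None = None) -> int:
    """Each eligible macrophage may kill one random tumour cell within R_int.

    Returns the number of kills this step.
    """
    p = state.params
    mac_idx = np.flatnonzero(state.types == MACROPHAGE)
    tum_idx = np.flatnonzero(state.types == TUMOUR)
    if len(mac_idx) == 0 or len(tum_idx) == 0:
        return 0
    tum_tree = cKDTree(state.positions[tum_idx])
    neighbours = tum_tree.query_ball_point(state.positions[mac_idx], p.R_int)
    kills = 0
    killed: set[int] = set()
    for m, local in zip(mac_idx, neighbours):
        candidates = [tum_idx[j] for j in local if tum_idx[j] not in killed]
        if not candidates:
            continue
        prob = kill_probability(state.phenotype[m], state.kill_timer[m], p) * dt
        if prob <= 0 or state.rng.random() >= prob:
            continue
        victim = candidates[int(state.rng.integers(len(candidates)))]
        state.types[victim] = NECROTIC
        state.necrosis_clock[victim] = 0.0
        state.kill_timer[m] = 0.0
        killed.add(victim)
        kills += 1
    return kills


def _contact_compressed(state: ABMState, tree: cKDTree) -> np.ndarray:
    """Cells whose effective area has fallen below their type's threshold.

    The effective radius is half the distance to the nearest neighbour,
    capped at the rest radius; a cell pauses its cycle when
    (r_eff / r)^2 < A_H for its type (stromal cells are the more
    sensitive; tumour cells tolerate more compression).
    """
    p = state.params
    n = len(state.positions)
    out = np.zeros(n, dtype=bool)
    cycling = np.flatnonzero((state.types == STROMAL) | (state.types == TUMOUR))
    if len(cycling) == 0 or n < 2:
        return out
    dist, _ = tree.query(state.positions[cycling], k=2)
    nearest = dist[:, 1]
    r = state.radii[cycling]
    r_eff = np.minimum(r, nearest / 2.0)
    frac = (r_eff / r) ** 2
    thresh = np.where(state.types[cycling] == TUMOUR, p.A_H_tum, p.A_H_str)
    out[cycling] = frac < thresh
    return out


def update_cell_cycle(state: ABMState, dt: float, tree: cKDTree | None = None) -> None:
    """Oxygen-gated cycle progression, division, necrosis and clearance."""
    p = state.params
    n = len(state.positions)
    if n == 0:
        return
    if tree is None:
        tree = cKDTree(state.positions)
    omega = state.fields["oxygen"].value_at(state.positions)

    # irreversible necrosis below the type's anoxic threshold
    nec_thresh = np.where(state.types == TUMOUR, p.omega_N_tum, p.omega_N_str)
    dies = ((state.types == TUMOUR) | (state.types == STROMAL)) & (omega < nec_thresh)
    if dies.any():
        state.types[dies] = NECROTIC
        state.necrosis_clock[dies] = 0.0

    # reversible hypoxic pause
    hyp_thresh = np.where(state.types == TUMOUR, p.omega_H_tum, p.omega_H_str)
    cycling = (state.types == TUMOUR) | (state.types == STROMAL)
    state.paused_hypoxic = cycling & (omega < hyp_thresh)
    state.paused_contact = _contact_compressed(state, tree)

    progress = cycling & ~state.paused_hypoxic & ~state.paused_contact
    state.cycle_clock[progress] += dt

    # division
    ready = np.flatnonzero(progress & (state.cycle_clock >= state.cycle_length))
    if len(ready):
        angles = state.rng.uniform(0, 2 * np.pi, len(ready))
        offsets = p.division_offset * np.column_stack([np.cos(angles), np.sin(angles)])
        daughters = state.positions[ready] + offsets
        dom = p.domain
        daughters[:, 0] = np.clip(daughters[:, 0], dom.x_min, dom.x_max)
        daughters[:, 1] = np.clip(daughters[:, 1], dom.y_min, dom.y_max)
        state.cycle_clock[ready] = 0.0
        mean_cycle = np.where(
            state.types[ready] == STROMAL,
            p.cycle_duration * p.stroma_cycle_scale,
            p.cycle_duration,
        )
        state.cycle_length[ready] = mean_cycle * state.rng.uniform(0.75, 1.25, len(ready))
        for idx, pos in zip(ready, daughters):
            state.add_cells(pos[None, :], int(state.types[idx]))

    # necrotic shrinkage and removal
    nec = state.types == NECROTIC
    if nec.any():
        state.necrosis_clock[nec] += dt
        frac = 1.0 - state.necrosis_clock[nec] / p.necrosis_clear_time
        state.radii[nec] = p.cell_radius * np.clip(frac, 0.0, 1.0)
        gone = nec & (state.necrosis_clock >= p.necrosis_clear_time)
        if gone.any():
            state.remove_cells(gone)


def mechanical_forces(state: ABMState, tree: cKDTree | None = None) -> np.ndarray:
    """Pairwise linear springs plus random motility and chemotaxis.

    Spring magnitude is k (s - s_rest) for centre separation s, attractive
    out to R_int, repulsive inside the rest length s_rest = r_i + r_j;
    necrotic cells interact through their shrinking radii, which also scale
    the spring strength.  Vessels exert no mechanical force.
    """
    p = state.params
    n = len(state.positions)
    forces = np.zeros((n, 2))
    if n == 0:
        return forces
    if tree is None:
        tree = cKDTree(state.positions)
    pairs = tree.query_pairs(p.R_int, output_type="ndarray")
    compression = np.zeros(n)
    if len(pairs):
        i, j = pairs[:, 0], pairs[:, 1]
        diff = state.positions[j] - state.positions[i]
        s = np.hypot(diff[:, 0], diff[:, 1])
        s = np.maximum(s, 1e-9)
        unit = diff / s[:, None]
        rest = state.radii[i] + state.radii[j]
        # repulsion-dominant spring: dense aggregates would collapse if
        # adhesion matched repulsion, since far more neighbours sit in the
        # attractive band than in contact
        k_pair = np.where(s < rest, p.spring_k, p.adhesion_k)
        # strength scales with combined radius so shrinking necrotic cells
        # exert progressively weaker forces
        k_eff = k_pair * (state.radii[i] + state.radii[j]) / (2 * p.cell_radius)
        mag = k_eff * (s - rest)  # >0 attraction, <0 repulsion
        f = mag[:, None] * unit
        np.add.at(forces, i, f)
        np.add.at(forces, j, -f)
        overlap = np.maximum(rest - s, 0.0)
        # macrophages crawl over one another freely: for the resistance
        # felt by a macrophage, only overlap with non-macrophage cells
        # counts (tissue resists them, other macrophages do not)
        mac_i = state.types[i] == MACROPHAGE
        mac_j = state.types[j] == MACROPHAGE
        both_mac = mac_i & mac_j
        np.add.at(compression, i[~both_mac], overlap[~both_mac])
        np.add.at(compression, j[~both_mac], overlap[~both_mac])

    # active (motility/chemotactic) forces meet a compression-dependent
    # resistance, like a yield stress: a cell pushing into packed tissue
    # loses crowding_yield units of force per unit of summed overlap with
    # its neighbours.  Weakly driven cells therefore cannot invade a dense
    # mass at all, while strongly driven ones still can -- which is what
    # makes chemotactic strength control infiltration depth.
    resistance = p.crowding_yield * compression

    def _resisted(active: np.ndarray, idx: np.ndarray) -> np.ndarray:
        mag = np.hypot(active[:, 0], active[:, 1])
        ok = mag > 1e-12
        scale = np.zeros_like(mag)
        scale[ok] = np.maximum(mag[ok] - resistance[idx][ok], 0.0) / mag[ok]
        return active * scale[:, None]

    mac = state.types == MACROPHAGE
    n_mac = int(mac.sum())
    if n_mac:
        angles = state.rng.uniform(0, 2 * np.pi, n_mac)
        active = p.random_motility * np.column_stack([np.cos(angles), np.sin(angles)])
        grad_c = state.fields["csf1"].gradient_at(state.positions[mac])
        grad_xi = state.fields["cxcl12"].gradient_at(state.positions[mac])
        active += chemotactic_forces(state.phenotype[mac], grad_c, grad_xi, p)
        forces[mac] += _resisted(active, mac)

    tum = state.types == TUMOUR
    if tum.any() and p.chi_eps_T > 0:
        grad_eps = state.fields["egf"].gradient_at(state.positions[tum])
        norm = np.hypot(grad_eps[:, 0], grad_eps[:, 1])
        ok = norm > 1e-12
        # saturating response: full strength only where the EGF trail is
        # steep, so distant cells are not dragged at full force and dense
        # clumps at EGF peaks stay mechanically stable
        gain = norm / (norm + p.K_eps_grad)
        f_eps = np.zeros_like(grad_eps)
        f_eps[ok] = (p.chi_eps_T * gain[ok, None]) * grad_eps[ok] / norm[ok, None]
        forces[tum] += _resisted(f_eps, tum)
    return forces


def step(state: ABMState, params: ABMParams | None = None) -> ABMState:
    """Advance the simulation one timestep dt (in place; returns the state).

    Order: fields, extravasation, phenotype, killing, cell cycle, forces,
    forward-Euler positions.  Raises if any displacement exceeds one cell
    diameter (stability guard).
    """
    p = params or state.params
    dt = p.dt
    update_fields(state, dt)
    attempt_extravasation(state, dt)
    mac = state.types == MACROPHAGE
    state.kill_timer[mac] += dt
    update_phenotypes(state, dt)
    tree = cKDTree(state.positions) if len(state.positions) else None
    attempt_killing(state, dt, tree)
    update_cell_cycle(state, dt, tree)
    tree = cKDTree(state.positions) if len(state.positions) else None
    forces = mechanical_forces(state, tree)
    disp = forces * (dt / p.nu)
    if len(disp):
        # transiently jammed clusters can produce large elastic forces; a
        # movement cap keeps the explicit integration stable there without
        # affecting ordinary motion (typical displacements are < 0.25)
        norms = np.hypot(disp[:, 0], disp[:, 1])
        cap = p.max_step_displacement
        over = norms > cap
        if over.any():
            disp[over] *= (cap / norms[over])[:, None]
        max_disp = float(norms.min(initial=0.0)) if not len(norms) else float(
            np.max(np.hypot(disp[:, 0], disp[:, 1]))
        )
        if max_disp > 1.0:
            raise RuntimeError(
                f"unstable step: displacement {max_disp:.2f} diameters exceeds 1"
            )
        state.positions = state.positions + disp
        dom = p.domain
        state.positions[:, 0] = np.clip(state.positions[:, 0], dom.x_min, dom.x_max)
        state.positions[:, 1] = np.clip(state.positions[:, 1], dom.y_min, dom.y_max)
    state.time += dt
    return state


def run(
    params: ABMParams,
    t_end: float,
    snapshot_every: float | None = None,
    seed: int = 0,
) -> list[LabelledPointCloud]:
    """Run from the standard initial condition to t_end, returning snapshots.

    Snapshots are taken at t = 0, snapshot_every, 2 snapshot_every, ... and
    always at t_end.  With snapshot_every = None only the initial and final
    clouds are returned.  Identical (params, seed) give identical output.
    """
    if snapshot_every is None:
        snapshot_every = t_end if t_end > 0 else 1.0
    n_steps = int(round(t_end / params.dt))
    every = max(1, int(round(snapshot_every / params.dt)))
    if abs(every * params.dt - snapshot_every) > 1e-9:
        raise ValueError("snapshot_every must be a multiple of dt")
    state = initial_state(params, seed)
    snaps = [state.snapshot()]
    for s in range(1, n_steps + 1):
        step(state)
        if s % every == 0 or s == n_steps:
            snaps.append(state.snapshot())
    # a final step on the snapshot cadence would otherwise appear twice
    if len(snaps) >= 2 and abs(snaps[-1].time - snaps[-2].time) < 1e-9:
        snaps.pop()
    return snaps
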