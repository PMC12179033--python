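"""First-order upwind finite-volume solver for the nonlocal conflict PDE.

The density f(t, x) of groups with cooperator fraction x on [0, 1] obeys

    df/dt = d/dx [ x(1-x) pi(x) f ] + lambda * f * (2 * int rho(x, u) f(t, u) du - 1)

Advection is discretized conservatively with upwind fluxes and the exact
edge velocity ``v(x) = -x(1-x) pi(x)`` (zero at both boundaries, so no
mass leaves [0, 1]).  The nonlocal conflict term is a midpoint-quadrature
reaction using a pre-tabulated N x N kernel matrix; complementarity of
the kernel makes it exactly mass-conserving in the discrete sense.  Time
stepping is fully explicit forward Euler on the pre-step density.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .games import GameCoefficients, pi_advantage
from .victory import VictoryKernel, kernel_from_spec

__all__ = [
    "Grid",
    "DensityState",
    "SimulationConfig",
    "Trajectory",
    "edge_velocities",
    "advection_update",
    "reaction_rates",
    "step",
    "run",
    "initial_density",
    "CFLError",
]


class CFLError(ValueError):
    """Raised when dt * max|v| / dx exceeds 1."""


@dataclass(frozen=True)
class Grid:
    """Uniform partition of [0, 1] into N half-open cells [i*dx, (i+1)*dx)."""

    N: int

    def __post_init__(self) -> None:
        if self.N < 1:
            raise ValueError("grid needs at least one cell")

    @property
    def dx(self) -> float:
        return 1.0 / self.N

    @property
    def centers(self) -> np.ndarray:
        return (np.arange(self.N) + 0.5) * self.dx

    @property
    def edges(self) -> np.ndarray:
        return np.arange(self.N + 1) * self.dx


@dataclass(frozen=True)
class DensityState:
    """Cell-averaged density values with a time stamp."""

    grid: Grid
    values: np.ndarray
    time: float = 0.0

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.shape != (self.grid.N,):
            raise ValueError("values must have one entry per grid cell")
        if np.any(values < -1e-12):
            raise ValueError("density has significantly negative entries")
        object.__setattr__(self, "values", values)

    @property
    def mass(self) -> float:
        return float(np.sum(self.values) * self.grid.dx)


@dataclass(frozen=True)
class SimulationConfig:
    """Full specification of one finite-volume run.

    ``lam`` is the relative group-conflict strength (the ratio of the
    conflict rate to the individual-level selection intensity).
    """

    game: GameCoefficients
    kernel: VictoryKernel
    lam: float
    dt: float
    n_steps: int
    N: int = 256
    initial: dict = field(default_factory=lambda: {"kind": "uniform"})
    renormalize: bool = False
    snapshot_every: int = 100

    def __post_init__(self) -> None:
        if self.lam < 0:
            raise ValueError("lambda must be >= 0")
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.n_steps < 0:
            raise ValueError("n_steps must be >= 0")
        grid = Grid(self.N)
        v = edge_velocities(grid, self.game)
        cfl = self.dt * float(np.max(np.abs(v))) / grid.dx
        if cfl > 1.0 + 1e-12:
            raise CFLError(f"CFL number {cfl:.3f} exceeds 1 (reduce dt or coarsen grid)")

    @property
    def grid(self) -> Grid:
        return Grid(self.N)

    def with_steps(self, n_steps: int) -> "SimulationConfig":
        return replace(self, n_steps=n_steps)


@dataclass(frozen=True)
class Trajectory:
    """Recorded snapshots plus per-snapshot diagnostic series."""

    config: SimulationConfig
    times: np.ndarray
    states: Sequence[DensityState]
    diagnostics: dict

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        if times.size and np.any(np.diff(times) <= 0):
            raise ValueError("snapshot times must be strictly increasing")
        object.__setattr__(self, "times", times)

    @property
    def final(self) -> DensityState:
        return self.states[-1]


def edge_velocities(grid: Grid, c: GameCoefficients) -> np.ndarray:
    """Advection velocity ``v(x) = -x(1-x) pi(x)`` at the cell edges.

    The boundary factors make v(0) = v(1) = 0 exactly.
    """
    e = grid.edges
    return -e * (1.0 - e) * pi_advantage(e, c)


def advection_update(f: DensityState, v: np.ndarray, dt: float) -> DensityState:
    """One conservative upwind step of the transport term.

    The flux through edge e is ``v_e * f_upwind`` with the donor cell
    chosen by the sign of ``v_e``; boundary fluxes are zero.  Total mass
    is unchanged up to roundoff.
    """
    grid = f.grid
    v = np.asarray(v, dtype=float)
    if v.shape != (grid.N + 1,):
        raise ValueError("need one velocity per cell edge")
    cfl = dt * float(np.max(np.abs(v))) / grid.dx
    if cfl > 1.0 + 1e-12:
        raise CFLError(f"CFL number {cfl:.3f} exceeds 1")
    vals = f.values
    flux = np.zeros(grid.N + 1)
    v_in = v[1:-1]
    # donor-cell flux: left cell for v > 0, right cell for v < 0
    flux[1:-1] = np.where(v_in > 0, v_in * vals[:-1], v_in * vals[1:])
    new_vals = vals - (dt / grid.dx) * (flux[1:] - flux[:-1])
    return DensityState(grid=grid, values=new_vals, time=f.time + dt)


def reaction_rates(f: DensityState, K: np.ndarray, lam: float) -> np.ndarray:
    """Per-cell conflict growth rates ``r_i = lam * (2 * sum_j K_ij f_j dx - m)``.

    ``K`` is the pre-tabulated kernel matrix ``K_ij = rho(x_i, x_j)`` at
    the cell centers (midpoint quadrature).  For a unit-mass density
    ``m = 1`` and this is exactly ``lam * (2 * int rho(x, u) f(u) du - 1)``.
    Writing the loss term with the discrete mass ``m`` instead of the
    constant 1 makes the complementarity identity ``sum_i f_i r_i dx = 0``
    hold for *any* f, so roundoff in the total mass is not amplified at
    rate ``exp(lam * t)`` (which destroys long runs at large lam).
    """
    return lam * (2.0 * (K @ f.values) * f.grid.dx - f.mass)


def step(
    f: DensityState,
    config: SimulationConfig,
    v: np.ndarray | None = None,
    K: np.ndarray | None = None,
) -> DensityState:
    """One forward-Euler step: upwind advection plus explicit reaction.

    The reaction is evaluated on the pre-step density.  Small negative
    values (> -1e-12) produced by roundoff are clipped to zero; larger
    negativity raises, signalling instability.
    """
    grid = f.grid
    if v is None:
        v = edge_velocities(grid, config.game)
    if K is None:
        K = config.kernel.matrix(grid.centers)
    r = reaction_rates(f, K, config.lam)
    advected = advection_update(f, v, config.dt)
    new_vals = advected.values + config.dt * f.values * r
    if np.any(new_vals < -1e-12):
        raise FloatingPointError(
            f"density went negative (min {new_vals.min():.3e}); reduce dt"
        )
    new_vals = np.clip(new_vals, 0.0, None)
    if config.renormalize:
        new_vals = new_vals / (np.sum(new_vals) * grid.dx)
    return DensityState(grid=grid, values=new_vals, time=f.time + config.dt)


def initial_density(spec: dict, grid: Grid) -> DensityState:
    """Build a cell-averaged initial density from a config mapping.

    Supported kinds:

    - ``{"kind": "uniform"}``: f = 1 on [0, 1].
    - ``{"kind": "theta", "theta": t}``: density ``t * (1-x)**(t-1)``,
      discretized from the exact cell masses
      ``(1-a)**t - (1-b)**t`` so total mass is exactly 1.
    - ``{"kind": "tabulated", "values": [...]}``: explicit cell averages,
      normalized to unit mass.
    """
    kind = spec.get("kind", "uniform")
    if kind == "uniform":
        values = np.ones(grid.N)
    elif kind == "theta":
        theta = float(spec.get("theta", 1.0))
        if theta <= 0:
            raise ValueError("theta must be > 0")
        edges = grid.edges
        survivor = (1.0 - edges) ** theta  # tail mass above each edge
        masses = survivor[:-1] - survivor[1:]
        values = masses / grid.dx
    elif kind == "tabulated":
        values = np.asarray(spec["values"], dtype=float)
        if values.shape != (grid.N,):
            raise ValueError("tabulated values must match the grid size")
        if np.any(values < 0):
            raise ValueError("tabulated density must be nonnegative")
        values = values / (np.sum(values) * grid.dx)
    else:
        raise ValueError(f"unknown initial-condition kind: {kind!r}")
    return DensityState(grid=grid, values=values, time=0.0)


def run(config: SimulationConfig, f0: DensityState | None = None) -> Trajectory:
    """Integrate ``config.n_steps`` forward-Euler steps, recording snapshots.

    Deterministic: no randomness anywhere.  Diagnostics recorded at each
    snapshot are total mass, mean cooperation, average success against the
    all-cooperator group and mean group payoff.
    """
    from .analysis import mean_cooperation, success_vs_all_cooperators

    grid = config.grid
    if f0 is None:
        f0 = initial_density(config.initial, grid)
    elif f0.grid.N != grid.N:
        raise ValueError("initial state does not match the configured grid")

    v = edge_velocities(grid, config.game)
    K = config.kernel.matrix(grid.centers)
    centers = grid.centers
    G_centers = config.game.G(centers)
    rho_vs_allC = config.kernel(centers, np.ones_like(centers))

    times, states = [], []
    diag: dict[str, list] = {
        "time": [],
        "mass": [],
        "mean_coop": [],
        "success_vs_allC": [],
        "mean_payoff": [],
    }

    def record(state: DensityState) -> None:
        times.append(state.time)
        states.append(state)
        w = state.values * grid.dx
        diag["time"].append(state.time)
        diag["mass"].append(state.mass)
        diag["mean_coop"].append(mean_cooperation(state))
        diag["success_vs_allC"].append(float(np.sum(rho_vs_allC * w)))
        diag["mean_payoff"].append(float(np.sum(G_centers * w)))

    f = f0
    record(f)
    for k in range(1, config.n_steps + 1):
        f = step(f, config, v=v, K=K)
        if k % config.snapshot_every == 0 or k == config.n_steps:
            record(f)

    return Trajectory(
        config=config,
        times=np.asarray(times),
        states=states,
        diagnostics={key: np.asarray(val) for key, val in diag.items()},
    )


def config_from_dict(raw: dict) -> SimulationConfig:
    """Build a :class:`SimulationConfig` from plain config data.

    Accepts the game either as payoffs ``{"R":..,"S":..,"T":..,"P":..}``
    or as coefficients ``{"alpha":..,"beta":..,"gamma":..,"P":..}``.
    Unknown keys raise with a key-level message.
    """
    from .games import PayoffMatrix, coefficients_from_payoffs

    raw = dict(raw)
    game_spec = dict(raw.pop("game", None) or {})
    if not game_spec:
        raise ValueError("config requires a 'game' section")
    if {"R", "S", "T"} <= set(game_spec):
        extra = set(game_spec) - {"R", "S", "T", "P"}
        if extra:
            raise ValueError(f"unknown game key(s): {sorted(extra)}")
        game = coefficients_from_payoffs(PayoffMatrix(**{k: float(v) for k, v in game_spec.items()}))
    elif {"alpha", "beta", "gamma"} <= set(game_spec):
        extra = set(game_spec) - {"alpha", "beta", "gamma", "P"}
        if extra:
            raise ValueError(f"unknown game key(s): {sorted(extra)}")
        game = GameCoefficients(**{k: float(v) for k, v in game_spec.items()})
    else:
        raise ValueError("game must give either (R,S,T,P) or (alpha,beta,gamma,P)")

    kernel_spec = raw.pop("kernel", None)
    if kernel_spec is None:
        raise ValueError("config requires a 'kernel' section")
    kernel = kernel_from_spec(kernel_spec, game=game)

    known = {
        "lam": float(raw.pop("lambda", raw.pop("lam", 0.0))),
        "dt": float(raw.pop("dt", 0.003)),
        "n_steps": int(raw.pop("n_steps", 1000)),
        "N": int(raw.pop("N", 256)),
        "initial": dict(raw.pop("initial", None) or {"kind": "uniform"}),
        "renormalize": bool(raw.pop("renormalize", False)),
        "snapshot_every": int(raw.pop("snapshot_every", 100)),
    }
    if raw:
        raise ValueError(f"unknown config key(s): {sorted(raw)}")
    return SimulationConfig(game=game, kernel=kernel, **known)
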