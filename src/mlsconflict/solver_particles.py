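"""Measure-valued oracle solver: characteristics plus Picard iteration.

Solutions of the conflict PDE admit an implicit representation: atoms of
the initial measure are transported along the within-group replicator
flow and reweighted by the exponential of their accumulated net conflict
success,

    w_k(t) = w_k(0) * exp( 2*lam * int_0^t <rho(phi_s(x_k), .), mu_s> ds - lam*t ).

Because the weights appear on both sides, the solver fixes them by
Picard iteration starting from pure transport.  Atom positions are
independent of the weights, so the characteristic trajectories (and the
per-time-step kernel matrices) are computed once up front.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .games import GameCoefficients, pi_advantage
from .solver_fv import DensityState, Grid
from .victory import VictoryKernel

__all__ = [
    "ParticleMeasure",
    "FlowIterate",
    "characteristic_flow",
    "particles_from_density",
    "picard_solve",
    "measure_distance",
    "to_density",
]


@dataclass(frozen=True)
class ParticleMeasure:
    """Probability measure represented by weighted atoms on [0, 1]."""

    positions: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        w = np.asarray(self.weights, dtype=float)
        if pos.shape != w.shape or pos.ndim != 1:
            raise ValueError("positions and weights must be matching 1-d arrays")
        if np.any(pos < -1e-12) or np.any(pos > 1 + 1e-12):
            raise ValueError("particle positions must lie in [0, 1]")
        if np.any(w < 0):
            raise ValueError("particle weights must be nonnegative")
        object.__setattr__(self, "positions", np.clip(pos, 0.0, 1.0))
        object.__setattr__(self, "weights", w)

    @property
    def total(self) -> float:
        return float(np.sum(self.weights))


@dataclass(frozen=True)
class FlowIterate:
    """Converged flow of particle measures on a uniform time mesh."""

    times: np.ndarray
    positions: np.ndarray  # shape (n_times, n_particles)
    weights: np.ndarray  # shape (n_times, n_particles)
    n_iterations: int

    def at(self, index: int) -> ParticleMeasure:
        return ParticleMeasure(self.positions[index], self.weights[index])

    @property
    def final(self) -> ParticleMeasure:
        return self.at(-1)


def characteristic_flow(x0, t: float, c: GameCoefficients, rtol: float = 1e-10, atol: float = 1e-12):
    """Flow map of the within-group replicator ODE dx/dt = -x(1-x)pi(x).

    Negative ``t`` gives the backward flow (the inverse map).  The
    endpoints 0 and 1 are exact fixed points.  Accepts a scalar or an
    array of starting points; the per-particle ODEs are decoupled, so the
    whole vector is integrated at once.
    """
    x0_arr = np.atleast_1d(np.asarray(x0, dtype=float))
    if t == 0:
        out = x0_arr.copy()
    else:

        def rhs(_t, x):
            x = np.clip(x, 0.0, 1.0)
            return -x * (1.0 - x) * pi_advantage(x, c)

        sol = solve_ivp(rhs, (0.0, t), x0_arr, method="RK45", rtol=rtol, atol=atol)
        if not sol.success:
            raise RuntimeError(f"characteristic integration failed: {sol.message}")
        out = np.clip(sol.y[:, -1], 0.0, 1.0)
        # fixed points are exact regardless of integrator roundoff
        out[x0_arr == 0.0] = 0.0
        out[x0_arr == 1.0] = 1.0
    return out if np.ndim(x0) else float(out[0])


def _flow_table(x0: np.ndarray, times: np.ndarray, c: GameCoefficients) -> np.ndarray:
    """Positions of every particle at every mesh time, shape (n_t, n_p)."""

    def rhs(_t, x):
        x = np.clip(x, 0.0, 1.0)
        return -x * (1.0 - x) * pi_advantage(x, c)

    if times[-1] == 0:
        return np.tile(x0, (len(times), 1))
    sol = solve_ivp(
        rhs, (0.0, float(times[-1])), x0, method="RK45", t_eval=times, rtol=1e-10, atol=1e-12
    )
    if not sol.success:
        raise RuntimeError(f"characteristic integration failed: {sol.message}")
    table = np.clip(sol.y.T, 0.0, 1.0)
    table[:, x0 == 0.0] = 0.0
    table[:, x0 == 1.0] = 1.0
    return table


def particles_from_density(f: DensityState) -> ParticleMeasure:
    """One atom per grid cell at the cell's mass centroid, weight = cell mass.

    Cells with zero mass contribute atoms at their centers with zero
    weight, keeping the particle count tied to the grid.
    """
    grid = f.grid
    dx = grid.dx
    edges = grid.edges
    masses = f.values * dx
    # centroid of a cell under the piecewise-constant density is its center
    centroids = 0.5 * (edges[:-1] + edges[1:])
    return ParticleMeasure(positions=centroids, weights=masses)


def picard_solve(
    mu0: ParticleMeasure,
    T: float,
    dt: float,
    kernel: VictoryKernel,
    lam: float,
    max_iter: int = 50,
    tol: float = 1e-8,
    game: GameCoefficients | None = None,
) -> FlowIterate:
    """Solve the conflict dynamics by Picard iteration on particle weights.

    The iterate map evolves positions along the characteristic flow and
    sets the weight of particle k at mesh time t to

        w_k(0) * exp( 2*lam * int_0^t sum_j rho(x_k(s), x_j(s)) w_j(s) ds - lam*t )

    with the time integral by the trapezoid rule on the dt mesh.  The
    initial guess is pure transport (weights frozen at w(0)).  Iteration
    stops when successive iterates differ by less than ``tol`` in
    Wasserstein-1 distance at every mesh time.
    """
    if T < 0 or dt <= 0:
        raise ValueError("need T >= 0 and dt > 0")
    n_t = int(round(T / dt))
    times = np.arange(n_t + 1) * dt
    if game is None:
        game = _game_of(kernel)
    positions = _flow_table(np.asarray(mu0.positions, dtype=float), times, game)
    w0 = np.asarray(mu0.weights, dtype=float)
    n_p = w0.size

    if lam == 0 or n_t == 0:
        return FlowIterate(
            times=times, positions=positions, weights=np.tile(w0, (n_t + 1, 1)), n_iterations=0
        )

    # kernel matrices rho(x_k(s), x_j(s)) are weight-independent; tabulate
    # them once unless that would exceed ~0.5 GB
    cache_matrices = (n_t + 1) * n_p * n_p * 8 < 5e8
    if cache_matrices:
        R = np.empty((n_t + 1, n_p, n_p))
        for s in range(n_t + 1):
            R[s] = kernel.matrix(positions[s])

    W = np.tile(w0, (n_t + 1, 1))
    for iteration in range(1, max_iter + 1):
        # integrand I[s, k] = sum_j rho(x_k(s), x_j(s)) * w_j(s)
        if cache_matrices:
            integrand = np.einsum("skj,sj->sk", R, W)
        else:
            integrand = np.stack(
                [kernel.matrix(positions[s]) @ W[s] for s in range(n_t + 1)]
            )
        cumulative = np.zeros_like(integrand)
        cumulative[1:] = np.cumsum(0.5 * dt * (integrand[1:] + integrand[:-1]), axis=0)
        W_new = w0[None, :] * np.exp(2.0 * lam * cumulative - lam * times[:, None])
        delta = max(
            measure_distance(
                ParticleMeasure(positions[s], W_new[s]),
                ParticleMeasure(positions[s], W[s]),
                check_normalized=False,
            )
            for s in range(n_t + 1)
        )
        W = W_new
        if delta < tol:
            return FlowIterate(times=times, positions=positions, weights=W, n_iterations=iteration)
    raise RuntimeError(
        f"Picard iteration did not converge in {max_iter} iterations (last delta {delta:.3e}); "
        "try a shorter window T"
    )


def _game_of(kernel: VictoryKernel) -> GameCoefficients:
    if kernel.game is not None:
        return kernel.game
    raise ValueError(
        "picard_solve needs game coefficients; pass a kernel built from a game "
        "or attach them via VictoryKernel(game=...)"
    )


def _as_atoms(mu) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(mu, ParticleMeasure):
        return mu.positions, mu.weights
    if isinstance(mu, DensityState):
        p = particles_from_density(mu)
        return p.positions, p.weights
    raise TypeError(f"expected ParticleMeasure or DensityState, got {type(mu).__name__}")


def measure_distance(mu, nu, check_normalized: bool = True) -> float:
    """Wasserstein-1 distance between two measures on [0, 1].

    Computed as the L1 norm of the difference of the CDFs over the merged
    set of atom positions.  Accepts :class:`ParticleMeasure` or
    :class:`DensityState` (binned to atoms at cell centers).
    """
    pos_a, w_a = _as_atoms(mu)
    pos_b, w_b = _as_atoms(nu)
    if check_normalized:
        for total in (np.sum(w_a), np.sum(w_b)):
            if abs(total - 1.0) > 1e-6:
                raise ValueError(f"measure is not normalized (total {total:.6f})")
    points = np.concatenate([pos_a, pos_b])
    signed = np.concatenate([w_a, -w_b])
    order = np.argsort(points, kind="stable")
    points = points[order]
    cdf_diff = np.cumsum(signed[order])
    gaps = np.diff(points)
    return float(np.sum(np.abs(cdf_diff[:-1]) * gaps))


def to_density(mu: ParticleMeasure, grid: Grid) -> DensityState:
    """Bin particle weights into grid cells and divide by dx.

    Mass is preserved exactly; atoms at x = 1 land in the last cell.
    """
    idx = np.minimum((mu.positions / grid.dx).astype(int), grid.N - 1)
    masses = np.bincount(idx, weights=mu.weights, minlength=grid.N)
    return DensityState(grid=grid, values=masses / grid.dx, time=0.0)
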