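"""Diagnostics, analytic thresholds and steady-state predictions.

The conflict dynamics admit sharp analytic predictions: any bounded
steady-state density with tail exponent theta near x = 1 must win
against the all-cooperator group with probability
``1/2 - theta*pi(1)/(2*lambda)``, and cooperation can only outperform
the all-defector baseline when lambda exceeds
``theta*pi(1) / (rho(1,0) - rho(0,1))`` (dominance-type games) or
``theta*pi(1) / (rho(1,x_eq) - rho(x_eq,1))`` (coexistence games).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .games import GameCoefficients, interior_equilibrium, pi_advantage
from .solver_fv import DensityState, Trajectory
from .solver_particles import ParticleMeasure
from .victory import VictoryKernel

__all__ = [
    "ThresholdReport",
    "TailEstimate",
    "mean_cooperation",
    "success_vs_all_cooperators",
    "steady_success_prediction",
    "lambda_star_pd",
    "lambda_star_hd",
    "extinction_bound_holds",
    "tail_exponent_estimate",
    "long_time_prediction",
    "tail_mass_above",
    "steady_state_residual",
    "detect_steady_state",
    "threshold_report",
]


@dataclass(frozen=True)
class ThresholdReport:
    """Analytic prediction bundle for one game/kernel pair."""

    pi1: float
    rho_10: float
    rho_01: float
    rho_1xeq: float | None
    rho_xeq1: float | None
    lambda_star_pd: float | None
    lambda_star_hd: float | None
    theta: float

    def to_dict(self) -> dict:
        return {
            "pi1": self.pi1,
            "rho_10": self.rho_10,
            "rho_01": self.rho_01,
            "rho_1xeq": self.rho_1xeq,
            "rho_xeq1": self.rho_xeq1,
            "lambda_star_pd": self.lambda_star_pd,
            "lambda_star_hd": self.lambda_star_hd,
            "theta": self.theta,
        }


@dataclass(frozen=True)
class TailEstimate:
    """Log-log regression estimate of the tail exponent near x = 1."""

    theta_hat: float
    window: tuple[float, float]
    r_squared: float
    n_points: int
    reliable: bool = True


def mean_cooperation(f: DensityState) -> float:
    """Average cooperator fraction ``int x f(x) dx`` (midpoint rule)."""
    return float(np.sum(f.grid.centers * f.values) * f.grid.dx)


def success_vs_all_cooperators(f: DensityState, kernel: VictoryKernel) -> float:
    """Average victory probability ``int rho(y, 1) f(y) dy`` against all-C."""
    centers = f.grid.centers
    rho = kernel(centers, np.ones_like(centers))
    return float(np.sum(rho * f.values) * f.grid.dx)


def steady_success_prediction(lam: float, pi1: float, theta: float = 1.0) -> float:
    """Predicted steady-state success against all-C: ``1/2 - theta*pi1/(2*lam)``."""
    if lam <= 0:
        raise ValueError("lambda must be > 0")
    return 0.5 - theta * pi1 / (2.0 * lam)


def lambda_star_pd(theta: float, pi1: float, kernel: VictoryKernel) -> float:
    """Threshold conflict strength for dominance games.

    ``theta * pi(1) / (rho(1,0) - rho(0,1))``; requires a positive
    denominator (the all-C group must beat the all-D group).
    """
    denom = float(kernel(1.0, 0.0) - kernel(0.0, 1.0))
    if denom <= 0:
        raise ValueError("rho(1,0) must exceed rho(0,1)")
    return theta * pi1 / denom


def lambda_star_hd(theta: float, pi1: float, kernel: VictoryKernel, x_eq: float) -> float:
    """Threshold conflict strength for coexistence games.

    ``theta * pi(1) / (rho(1,x_eq) - rho(x_eq,1))``; requires a positive
    denominator.
    """
    denom = float(kernel(1.0, x_eq) - kernel(x_eq, 1.0))
    if denom <= 0:
        raise ValueError("rho(1,x_eq) must exceed rho(x_eq,1)")
    return theta * pi1 / denom


def extinction_bound_holds(
    lam: float,
    theta_bar: float,
    pi1: float,
    kernel: VictoryKernel,
    n_grid: int = 201,
) -> bool:
    """Sufficient condition for defectors taking over the population.

    Estimates ``||rho||_inf`` on an ``n_grid x n_grid`` lattice and
    returns whether ``lam * (2*||rho||_inf - 1) < theta_bar * pi(1)``.
    Valid for dynamics with ``pi > 0`` on [0, 1] (dominance games).
    """
    pts = np.linspace(0.0, 1.0, n_grid)
    rho_max = float(np.max(kernel(pts[:, None], pts[None, :])))
    return lam * (2.0 * rho_max - 1.0) < theta_bar * pi1


def tail_mass_above(f: DensityState, z: float) -> float:
    """Mass of groups above cooperation level z, ``int_z^1 f(x) dx``.

    The cell straddling z contributes its prorated share.
    """
    if not 0.0 <= z <= 1.0:
        raise ValueError("z must lie in [0, 1]")
    grid = f.grid
    edges = grid.edges
    overlap = np.clip(edges[1:], z, None) - np.clip(edges[:-1], z, None)
    return float(np.sum(f.values * overlap))


def _tail_mass_function(mu) -> "callable":
    """Return m(x) = mu([1-x, 1]) for a density or particle measure."""
    if isinstance(mu, DensityState):
        return lambda x: tail_mass_above(mu, 1.0 - x)
    if isinstance(mu, ParticleMeasure):
        pos, w = mu.positions, mu.weights

        def mass(x):
            return float(np.sum(w[pos >= 1.0 - x]))

        return mass
    raise TypeError(f"expected DensityState or ParticleMeasure, got {type(mu).__name__}")


def tail_exponent_estimate(
    mu,
    window: tuple[float, float] = (0.01, 0.2),
    n_points: int = 12,
) -> TailEstimate:
    """Estimate the tail exponent theta of ``mu([1-x, 1]) ~ C * x**theta``.

    Least-squares slope of log tail-mass against log x over geometrically
    spaced x inside ``window`` (a subset of (0, 0.5]).  A tail with no
    mass in the window yields an unreliable zero estimate.
    """
    lo, hi = window
    if not (0.0 < lo < hi <= 0.5):
        raise ValueError("window must satisfy 0 < lo < hi <= 0.5")
    if n_points < 2:
        raise ValueError("need at least two fit points")
    mass = _tail_mass_function(mu)
    xs = np.geomspace(lo, hi, n_points)
    ms = np.array([mass(x) for x in xs])
    keep = ms > 0
    if np.count_nonzero(keep) < 2:
        return TailEstimate(
            theta_hat=0.0, window=window, r_squared=0.0, n_points=0, reliable=False
        )
    log_x, log_m = np.log(xs[keep]), np.log(ms[keep])
    slope, intercept = np.polyfit(log_x, log_m, 1)
    resid = log_m - (slope * log_x + intercept)
    ss_tot = float(np.sum((log_m - log_m.mean()) ** 2))
    r_squared = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    return TailEstimate(
        theta_hat=float(slope),
        window=window,
        r_squared=r_squared,
        n_points=int(np.count_nonzero(keep)),
        reliable=bool(np.all(keep)),
    )


def long_time_prediction(
    lam: float,
    game: GameCoefficients,
    kernel: VictoryKernel,
    theta: float = 1.0,
    scenario: str = "PD",
) -> float:
    """Predicted long-time success against all-C as a function of lambda.

    Below the threshold the population collapses onto the within-group
    attractor (``rho(0,1)`` for PD, ``rho(x_eq,1)`` for HD); at or above
    it, a steady-state density with success ``1/2 - theta*pi1/(2*lam)``.
    The two branches agree at the threshold.
    """
    pi1 = float(pi_advantage(1.0, game))
    if scenario == "PD":
        lam_star = lambda_star_pd(theta, pi1, kernel)
        baseline = float(kernel(0.0, 1.0))
    elif scenario == "HD":
        x_eq = interior_equilibrium(game)
        if x_eq is None:
            raise ValueError("HD scenario requires an interior equilibrium")
        lam_star = lambda_star_hd(theta, pi1, kernel, x_eq)
        baseline = float(kernel(x_eq, 1.0))
    else:
        raise ValueError(f"unknown scenario: {scenario!r}")
    if lam < lam_star:
        return baseline
    return steady_success_prediction(lam, pi1, theta)


def steady_state_residual(
    f: DensityState, game: GameCoefficients, kernel: VictoryKernel, lam: float
) -> float:
    """Discrete L1 residual of the steady-state balance.

    Computes ``|| d/dx[x(1-x)pi(x)f] + lam*f*(2*int rho f - 1) ||_L1``
    using centered differences of the flux at cell centers (one-sided at
    the boundary cells) and the solver's midpoint quadrature for the
    nonlocal term.
    """
    grid = f.grid
    centers = grid.centers
    flux = centers * (1.0 - centers) * pi_advantage(centers, game) * f.values
    dflux = np.gradient(flux, grid.dx)
    K = kernel.matrix(centers)
    reaction = lam * f.values * (2.0 * (K @ f.values) * grid.dx - 1.0)
    return float(np.sum(np.abs(dflux + reaction)) * grid.dx)


def detect_steady_state(traj: Trajectory, tol: float = 1e-4) -> tuple[bool, float | None]:
    """First snapshot time with per-unit-time L1 change below ``tol``.

    Compares consecutive snapshots: ``(int |f_{k+1} - f_k| dx) / (t_{k+1}
    - t_k) < tol``.  Returns ``(False, None)`` if never reached.
    """
    if len(traj.states) < 2:
        raise ValueError("need at least two snapshots")
    dx = traj.states[0].grid.dx
    for prev, cur in zip(traj.states[:-1], traj.states[1:]):
        rate = float(np.sum(np.abs(cur.values - prev.values)) * dx) / (cur.time - prev.time)
        if rate < tol:
            return True, cur.time
    return False, None


def threshold_report(
    game: GameCoefficients, kernel: VictoryKernel, theta: float = 1.0
) -> ThresholdReport:
    """Evaluate all analytic threshold quantities for one configuration."""
    pi1 = float(pi_advantage(1.0, game))
    rho_10 = float(kernel(1.0, 0.0))
    rho_01 = float(kernel(0.0, 1.0))
    x_eq = interior_equilibrium(game)
    rho_1xeq = rho_xeq1 = lam_hd = None
    if x_eq is not None:
        rho_1xeq = float(kernel(1.0, x_eq))
        rho_xeq1 = float(kernel(x_eq, 1.0))
        if rho_1xeq > rho_xeq1 and pi1 > 0:
            lam_hd = lambda_star_hd(theta, pi1, kernel, x_eq)
    lam_pd = None
    if rho_10 > rho_01 and pi1 > 0:
        lam_pd = lambda_star_pd(theta, pi1, kernel)
    return ThresholdReport(
        pi1=pi1,
        rho_10=rho_10,
        rho_01=rho_01,
        rho_1xeq=rho_1xeq,
        rho_xeq1=rho_xeq1,
        lambda_star_pd=lam_pd,
        lambda_star_hd=lam_hd,
        theta=theta,
    )
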