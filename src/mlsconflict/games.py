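"""Two-player two-strategy games driving selection at both levels.

A 2x2 payoff matrix (R, S, T, P) induces a within-group payoff advantage
``pi(x) = -(beta + alpha*x)`` for defectors and a group average payoff
``G(x) = P + gamma*x + alpha*x**2``, where ``alpha = R - S - T + P``,
``beta = S - P`` and ``gamma = S + T - 2P``.  Everything downstream (the
advection velocity, the victory kernels and the analytic thresholds) is
expressed in terms of these coefficients.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "PayoffMatrix",
    "GameCoefficients",
    "coefficients_from_payoffs",
    "payoffs_from_coefficients",
    "classify_game",
    "pi_advantage",
    "group_payoff",
    "interior_equilibrium",
    "optimal_cooperation",
    "payoff_matching_cooperation",
]


@dataclass(frozen=True)
class PayoffMatrix:
    """Payoffs of a symmetric 2x2 game.

    Attributes
    ----------
    R : float
        Reward for mutual cooperation.
    S : float
        Sucker payoff (cooperate against a defector).
    T : float
        Temptation payoff (defect against a cooperator).
    P : float
        Punishment for mutual defection.
    """

    R: float
    S: float
    T: float
    P: float

    def __post_init__(self) -> None:
        for name in ("R", "S", "T", "P"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"payoff {name} must be finite")


@dataclass(frozen=True)
class GameCoefficients:
    """Shorthand coefficients (alpha, beta, gamma, P) of a 2x2 game.

    ``alpha = R - S - T + P``, ``beta = S - P``, ``gamma = S + T - 2P``.
    The punishment payoff ``P`` is retained so the payoff matrix can be
    recovered exactly.
    """

    alpha: float
    beta: float
    gamma: float
    P: float

    def pi(self, x):
        """Defector payoff advantage ``pi(x) = -(beta + alpha*x)``."""
        return pi_advantage(x, self)

    def G(self, x):
        """Group average payoff ``G(x) = P + gamma*x + alpha*x**2``."""
        return group_payoff(x, self)


def coefficients_from_payoffs(m: PayoffMatrix) -> GameCoefficients:
    """Map a payoff matrix to its shorthand coefficients."""
    return GameCoefficients(
        alpha=m.R - m.S - m.T + m.P,
        beta=m.S - m.P,
        gamma=m.S + m.T - 2.0 * m.P,
        P=m.P,
    )


def payoffs_from_coefficients(c: GameCoefficients) -> PayoffMatrix:
    """Invert :func:`coefficients_from_payoffs` exactly."""
    S = c.beta + c.P
    T = c.gamma + 2.0 * c.P - S
    R = c.alpha + S + T - c.P
    return PayoffMatrix(R=R, S=S, T=T, P=c.P)


def classify_game(m: PayoffMatrix) -> str:
    """Classify a payoff matrix by its strict entry ordering.

    Returns one of ``"PD"`` (T>R>P>S), ``"HD"`` (T>R>S>P), ``"SH"``
    (R>T>P>S), ``"PDel"`` (R>T>S>P) or ``"other"`` for any tie or other
    ordering.  Comparisons are exact (no tolerance).
    """
    R, S, T, P = m.R, m.S, m.T, m.P
    if T > R > P > S:
        return "PD"
    if T > R > S > P:
        return "HD"
    if R > T > P > S:
        return "SH"
    if R > T > S > P:
        return "PDel"
    return "other"


def _check_unit_interval(x) -> None:
    import numpy as np

    arr = np.asarray(x, dtype=float)
    if np.any(arr < -1e-14) or np.any(arr > 1 + 1e-14):
        raise ValueError("cooperator fraction x must lie in [0, 1]")


def pi_advantage(x, c: GameCoefficients):
    """Defector payoff advantage ``pi(x) = -(beta + alpha*x)``.

    Equals ``pi_D(x) - pi_C(x)`` for the underlying game.  Accepts scalars
    or arrays; ``x`` must lie in [0, 1].
    """
    _check_unit_interval(x)
    return -(c.beta + c.alpha * x)


def group_payoff(x, c: GameCoefficients):
    """Group average payoff ``G(x) = P + gamma*x + alpha*x**2`` on [0, 1]."""
    _check_unit_interval(x)
    return c.P + c.gamma * x + c.alpha * x * x


def interior_equilibrium(c: GameCoefficients) -> float | None:
    """Interior root of ``pi``, ``x_eq = beta / (-alpha)``, if in (0, 1).

    Returns ``None`` when ``alpha == 0`` or the root falls outside (0, 1).
    """
    if c.alpha == 0:
        return None
    x_eq = c.beta / (-c.alpha)
    if 0.0 < x_eq < 1.0:
        return x_eq
    return None


def optimal_cooperation(c: GameCoefficients) -> float:
    """Cooperator fraction ``x*`` maximizing ``G`` on [0, 1].

    For concave ``G`` (alpha < 0): ``x* = 1`` when ``gamma + 2*alpha >= 0``,
    otherwise the vertex ``gamma / (-2*alpha)`` clipped to [0, 1].  For
    convex or affine ``G`` the maximum sits at an endpoint, picked by the
    sign of ``G(1) - G(0) = gamma + alpha``.
    """
    if c.alpha < 0:
        if c.gamma + 2.0 * c.alpha >= 0:
            return 1.0
        return min(1.0, max(0.0, c.gamma / (-2.0 * c.alpha)))
    return 1.0 if c.gamma + c.alpha >= 0 else 0.0


def payoff_matching_cooperation(c: GameCoefficients) -> float | None:
    """Non-unit root ``x_bar`` of ``G(x) = G(1)``, if it lies in (0, 1).

    ``G(x) - G(1) = (x - 1) * (alpha*(x + 1) + gamma)`` so the second root
    is ``x_bar = -gamma/alpha - 1``.  Returns ``None`` when ``alpha == 0``
    or the root falls outside (0, 1).
    """
    if c.alpha == 0:
        return None
    x_bar = -c.gamma / c.alpha - 1.0
    if 0.0 < x_bar < 1.0:
        return x_bar
    return None
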