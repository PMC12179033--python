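"""Pairwise group-level victory probability kernels rho(x, y).

Every kernel maps a pair of cooperator fractions to the probability that
the first group defeats the second in a conflict, and satisfies
``0 <= rho <= 1`` and the complementarity identity
``rho(y, x) = 1 - rho(x, y)`` (so ``rho(x, x) = 1/2``).

Degenerate denominators (constant G, both payoffs at the minimum, or
``|G(x)| + |G(y)| = 0``) all return 1/2 by convention: it is the unique
value consistent with complementarity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .games import GameCoefficients

__all__ = [
    "VictoryKernel",
    "fraction_kernel",
    "local_update_kernel",
    "fermi_kernel",
    "normalized_diff_kernel",
    "tullock_kernel",
    "separable_kernel",
    "kernel_from_spec",
    "validate_kernel",
    "KernelValidationReport",
]


@dataclass(frozen=True)
class VictoryKernel:
    """A pairwise victory-probability map.

    Attributes
    ----------
    family : str
        Family name (``fraction``, ``local_update``, ``fermi``,
        ``normalized``, ``tullock``, ``separable``).
    evaluate : callable
        Vectorized map ``(x, y) -> rho(x, y)`` into [0, 1].
    params : dict
        Sensitivity parameters (``s`` for fermi, ``a`` for tullock).
    game : GameCoefficients or None
        Coefficients of the game when the kernel is G-dependent.
    """

    family: str
    evaluate: Callable[[np.ndarray, np.ndarray], np.ndarray]
    params: dict = field(default_factory=dict)
    game: GameCoefficients | None = None

    def __call__(self, x, y):
        return self.evaluate(np.asarray(x, dtype=float), np.asarray(y, dtype=float))

    def matrix(self, centers: np.ndarray) -> np.ndarray:
        """Tabulate ``rho(x_i, x_j)`` on a set of points (rows = first arg)."""
        c = np.asarray(centers, dtype=float)
        return self(c[:, None], c[None, :])


def _g_extrema(c: GameCoefficients) -> tuple[float, float]:
    """Exact max/min of the quadratic G on [0, 1]."""
    candidates = [0.0, 1.0]
    if c.alpha != 0:
        vertex = c.gamma / (-2.0 * c.alpha)
        if 0.0 < vertex < 1.0:
            candidates.append(vertex)
    values = [c.G(x) for x in candidates]
    return max(values), min(values)


def fraction_kernel() -> VictoryKernel:
    """Victory advantage proportional to the cooperator-fraction gap."""

    def rho(x, y):
        return 0.5 + 0.5 * (x - y)

    return VictoryKernel(family="fraction", evaluate=rho)


def local_update_kernel(c: GameCoefficients) -> VictoryKernel:
    """Payoff-difference kernel normalized by the range of G (separable)."""
    g_max, g_min = _g_extrema(c)
    span = g_max - g_min

    if span == 0:

        def rho(x, y):
            return np.full_like(np.asarray(x + y, dtype=float), 0.5)

    else:

        def rho(x, y):
            return 0.5 * (1.0 + (c.G(x) - c.G(y)) / span)

    return VictoryKernel(family="local_update", evaluate=rho, game=c)


def fermi_kernel(c: GameCoefficients, s: float) -> VictoryKernel:
    """Group-level Fermi rule: ``1/2 * (1 + tanh(s * [G(x) - G(y)]))``."""
    if s < 0:
        raise ValueError("fermi sensitivity s must be >= 0")

    def rho(x, y):
        return 0.5 * (1.0 + np.tanh(s * (c.G(x) - c.G(y))))

    return VictoryKernel(family="fermi", evaluate=rho, params={"s": s}, game=c)


def normalized_diff_kernel(c: GameCoefficients) -> VictoryKernel:
    """Payoff difference normalized by the summed payoff magnitudes."""

    def rho(x, y):
        gx, gy = c.G(x), c.G(y)
        denom = np.abs(gx) + np.abs(gy)
        with np.errstate(invalid="ignore", divide="ignore"):
            out = 0.5 + 0.5 * np.where(denom > 0, (gx - gy) / np.where(denom > 0, denom, 1.0), 0.0)
        return out

    return VictoryKernel(family="normalized", evaluate=rho, game=c)


def tullock_kernel(c: GameCoefficients, a: float) -> VictoryKernel:
    """Tullock contest kernel on the shifted payoffs ``G - G_*``.

    ``rho = (G(x)-G_*)^(1/a) / [(G(x)-G_*)^(1/a) + (G(y)-G_*)^(1/a)]``.
    When both arguments sit at the minimum payoff the quotient is 0/0 and
    returns 1/2; when only one does, the other side wins outright.
    """
    if a <= 0:
        raise ValueError("tullock sensitivity a must be > 0")
    _, g_min = _g_extrema(c)
    inv_a = 1.0 / a

    def rho(x, y):
        # clip guards roundoff: G can dip ~1e-16 below the analytic minimum
        px = np.clip(c.G(x) - g_min, 0.0, None) ** inv_a
        py = np.clip(c.G(y) - g_min, 0.0, None) ** inv_a
        denom = px + py
        with np.errstate(invalid="ignore", divide="ignore"):
            out = np.where(denom > 0, px / np.where(denom > 0, denom, 1.0), 0.5)
        return out

    return VictoryKernel(family="tullock", evaluate=rho, params={"a": a}, game=c)


def separable_kernel(gcal: Callable[[np.ndarray], np.ndarray]) -> VictoryKernel:
    """Additively separable kernel ``1/2 * (1 + gcal(x) - gcal(y))``.

    ``gcal`` must map [0, 1] into [-1, 1]; this is checked on a probe grid
    at construction time so that rho stays inside [0, 1].
    """
    probe = np.linspace(0.0, 1.0, 101)
    vals = np.asarray(gcal(probe), dtype=float)
    if np.any(np.abs(vals) > 1 + 1e-12):
        raise ValueError("separable kernel requires |gcal(x)| <= 1 on [0, 1]")

    def rho(x, y):
        return 0.5 * (1.0 + gcal(x) - gcal(y))

    return VictoryKernel(family="separable", evaluate=rho)


_FAMILIES = {"fraction", "local_update", "fermi", "normalized", "tullock", "separable"}


def kernel_from_spec(spec: dict, game: GameCoefficients | None = None) -> VictoryKernel:
    """Build a kernel from a config mapping ``{"family": ..., "s"/"a": ...}``."""
    spec = dict(spec)
    family = spec.pop("family", None)
    if family not in _FAMILIES:
        raise ValueError(f"unknown kernel family: {family!r}")
    if family == "fraction":
        kernel = fraction_kernel()
    elif family == "separable":
        gcal = spec.pop("gcal", None)
        if gcal is None:
            raise ValueError("separable kernel needs an explicit 'gcal' callable")
        kernel = separable_kernel(gcal)
    else:
        if game is None:
            raise ValueError(f"kernel family {family!r} requires game coefficients")
        if family == "local_update":
            kernel = local_update_kernel(game)
        elif family == "fermi":
            kernel = fermi_kernel(game, s=float(spec.pop("s", 1.0)))
        elif family == "normalized":
            kernel = normalized_diff_kernel(game)
        else:
            kernel = tullock_kernel(game, a=float(spec.pop("a", 1.0)))
    extra = {k for k in spec if k not in ("s", "a")}
    if extra:
        raise ValueError(f"unknown kernel option(s): {sorted(extra)}")
    return kernel


@dataclass(frozen=True)
class KernelValidationReport:
    """Lattice check of the victory-kernel axioms."""

    n_grid: int
    max_range_violation: float
    max_complementarity_violation: float
    z_min: float | None = None
    dominance_ok: bool | None = None
    monotone_ok: bool | None = None

    @property
    def passed(self) -> bool:
        ok = self.max_range_violation <= 1e-12 and self.max_complementarity_violation <= 1e-12
        if self.z_min is not None:
            ok = ok and bool(self.dominance_ok) and bool(self.monotone_ok)
        return ok


def validate_kernel(
    kernel, n_grid: int = 101, z_min: float | None = None
) -> KernelValidationReport:
    """Check the kernel axioms on an ``n_grid x n_grid`` lattice.

    Reports the worst violation of ``0 <= rho <= 1`` and of
    ``rho(x, y) + rho(y, x) = 1``.  If ``z_min`` is given, additionally
    checks that groups above ``z_min`` beat groups below it
    (``rho(x, y) > rho(y, x)`` for ``x > z_min > y``) and that rho is
    monotone-dominant in its first argument above ``z_min``
    (``rho(x, y) > rho(u, y)`` whenever ``x > z_min`` and ``x > u``).

    Accepts a :class:`VictoryKernel` or any callable ``(x, y) -> rho``.
    """
    if n_grid < 2:
        raise ValueError("n_grid must be >= 2")
    evaluate = kernel if callable(kernel) and not isinstance(kernel, VictoryKernel) else kernel
    pts = np.linspace(0.0, 1.0, n_grid)
    R = np.asarray(evaluate(pts[:, None], pts[None, :]), dtype=float)
    range_violation = float(max(np.max(-R, initial=0.0), np.max(R - 1.0, initial=0.0), 0.0))
    comp_violation = float(np.max(np.abs(R + R.T - 1.0)))

    dominance_ok = monotone_ok = None
    if z_min is not None:
        above = pts > z_min
        below = pts < z_min
        sub = R[np.ix_(above, below)]
        dominance_ok = bool(np.all(sub > 1.0 - sub)) if sub.size else True
        monotone_ok = True
        idx_above = np.where(above)[0]
        if idx_above.size:
            # rho(x, y) must dominate rho(u, y) for every u < x with x > z_min
            for i in idx_above:
                if i > 0 and not np.all(R[i, :] > np.max(R[:i, :], axis=0) - 1e-15):
                    monotone_ok = False
                    break
    return KernelValidationReport(
        n_grid=n_grid,
        max_range_violation=range_violation,
        max_complementarity_violation=comp_violation,
        z_min=z_min,
        dominance_ok=dominance_ok,
        monotone_ok=monotone_ok,
    )
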