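import numpy as np
import pytest

from mlsconflict.analysis import (
    detect_steady_state,
    extinction_bound_holds,
    lambda_star_hd,
    lambda_star_pd,
    long_time_prediction,
    mean_cooperation,
    steady_state_residual,
    steady_success_prediction,
    success_vs_all_cooperators,
    tail_exponent_estimate,
    tail_mass_above,
    threshold_report,
)
from mlsconflict.games import GameCoefficients, pi_advantage
from mlsconflict.solver_fv import DensityState, Grid, SimulationConfig, initial_density, run
from mlsconflict.solver_particles import ParticleMeasure
from mlsconflict.victory import fermi_kernel, fraction_kernel, separable_kernel


def linear_density(N: int) -> DensityState:
    """Discretized f(x) = 2x via exact cell masses b^2 - a^2."""
    grid = Grid(N)
    masses = grid.edges[1:] ** 2 - grid.edges[:-1] ** 2
    return DensityState(grid=grid, values=masses / grid.dx)


def top_cell_density(N: int) -> DensityState:
    vals = np.zeros(N)
    vals[-1] = N
    return DensityState(grid=Grid(N), values=vals)


class TestBasicDiagnostics:
    def test_mean_cooperation_uniform(self):
        f = DensityState(grid=Grid(32), values=np.ones(32))
        assert mean_cooperation(f) == pytest.approx(0.5, abs=1e-14)

    def test_mean_cooperation_top_cell(self):
        assert mean_cooperation(top_cell_density(256)) == pytest.approx(1.0, abs=2e-3)

    def test_mean_cooperation_linear(self):
        # int 2x * x dx = 2/3; midpoint rule is O(dx^2)
        assert mean_cooperation(linear_density(64)) == pytest.approx(2 / 3, abs=(1 / 64) ** 2)

    def test_success_delta_at_one(self):
        f = top_cell_density(512)
        kernel = fraction_kernel()
        assert success_vs_all_cooperators(f, kernel) == pytest.approx(0.5, abs=1e-3)

    def test_success_delta_at_zero_fraction(self):
        vals = np.zeros(512)
        vals[0] = 512.0
        f = DensityState(grid=Grid(512), values=vals)
        assert success_vs_all_cooperators(f, fraction_kernel()) == pytest.approx(0.0, abs=1e-3)

    def test_success_uniform_fraction(self):
        f = DensityState(grid=Grid(64), values=np.ones(64))
        # int rho(y,1) dy = int y/2 dy = 1/4
        assert success_vs_all_cooperators(f, fraction_kernel()) == pytest.approx(0.25, abs=1e-12)


class TestTailMass:
    def test_uniform_half(self):
        f = DensityState(grid=Grid(32), values=np.ones(32))
        assert tail_mass_above(f, 0.5) == pytest.approx(0.5, abs=1e-14)

    def test_delta_counts_fully(self):
        assert tail_mass_above(top_cell_density(64), 0.3) == pytest.approx(1.0, abs=1e-14)

    def test_linear_density(self):
        # int_{1/2}^1 2x dx = 3/4, exact because cell masses are exact
        assert tail_mass_above(linear_density(64), 0.5) == pytest.approx(0.75, abs=1e-13)

    def test_partial_cell_proration(self):
        f = DensityState(grid=Grid(4), values=np.ones(4))
        assert tail_mass_above(f, 0.6) == pytest.approx(0.4, abs=1e-14)


class TestSteadyPredictions:
    def test_large_lambda_limit(self):
        lams = np.geomspace(1, 1e8, 9)
        preds = [steady_success_prediction(lam, pi1=2.0, theta=1.0) for lam in lams]
        assert np.all(np.diff(preds) > 0)  # monotone increasing in lambda
        assert preds[-1] == pytest.approx(0.5, abs=1e-7)

    def test_fig1_right_regime(self):
        assert steady_success_prediction(14.0, pi1=2.0, theta=1.0) == pytest.approx(
            0.5 - 1 / 14, abs=1e-15
        )

    def test_zero_lambda_rejected(self):
        with pytest.raises(ValueError):
            steady_success_prediction(0.0, pi1=2.0)

    def test_prediction_hits_baseline_at_threshold(self, pd_game):
        kernel = fermi_kernel(pd_game, 1.0)
        pi1 = float(pi_advantage(1.0, pd_game))
        lam_star = lambda_star_pd(1.0, pi1, kernel)
        pred = steady_success_prediction(lam_star, pi1, 1.0)
        assert pred == pytest.approx(float(kernel(0.0, 1.0)), abs=1e-12)


class TestThresholds:
    def test_lambda_star_pd_fermi(self, pd_game):
        kernel = fermi_kernel(pd_game, 1.0)
        value = lambda_star_pd(1.0, 2.0, kernel)
        assert value == pytest.approx(2.0 / np.tanh(0.5), abs=1e-12)

    def test_lambda_star_pd_separable_closed_form(self):
        gcal = lambda x: 0.8 * np.asarray(x, dtype=float) - 0.2
        kernel = separable_kernel(gcal)
        assert lambda_star_pd(1.0, 2.0, kernel) == pytest.approx(2.0 / 0.8, abs=1e-12)

    def test_lambda_star_pd_linear_in_theta(self, pd_game):
        kernel = fermi_kernel(pd_game, 1.0)
        assert lambda_star_pd(2.0, 2.0, kernel) == pytest.approx(
            2 * lambda_star_pd(1.0, 2.0, kernel), abs=1e-12
        )

    def test_lambda_star_hd_fermi(self, hd_game):
        kernel = fermi_kernel(hd_game, 1.0)
        # G(1) - G(0.5) = 2.5 - 2.25 = 0.25, pi(1) = 1
        value = lambda_star_hd(1.0, 1.0, kernel, x_eq=0.5)
        assert value == pytest.approx(1.0 / np.tanh(0.25), abs=1e-12)

    def test_lambda_star_hd_separable_closed_form(self):
        gcal = lambda x: np.asarray(x, dtype=float) ** 2
        kernel = separable_kernel(gcal)
        # gcal(1) - gcal(0.5) = 0.75
        assert lambda_star_hd(1.0, 1.0, kernel, x_eq=0.5) == pytest.approx(1 / 0.75, abs=1e-12)

    def test_bad_denominator_rejected(self, pd_game):
        backwards = separable_kernel(lambda x: -np.asarray(x, dtype=float))
        with pytest.raises(ValueError):
            lambda_star_pd(1.0, 2.0, backwards)

    def test_threshold_report_bundle(self, hd_game):
        report = threshold_report(hd_game, fermi_kernel(hd_game, 1.0))
        assert report.pi1 == 1.0
        assert report.lambda_star_hd == pytest.approx(1.0 / np.tanh(0.25), abs=1e-12)
        assert report.rho_1xeq is not None and report.rho_1xeq > 0.5


class TestExtinctionBound:
    def test_neutral_kernel_always_extinct(self, pd_game):
        neutral = separable_kernel(lambda x: np.zeros_like(np.asarray(x, dtype=float)))
        assert extinction_bound_holds(1e6, 1.0, 2.0, neutral)

    def test_weak_conflict_true(self, pd_game):
        kernel = fermi_kernel(pd_game, 1.0)
        assert extinction_bound_holds(0.01, 1.0, 2.0, kernel)

    def test_strong_conflict_false(self, pd_game):
        kernel = fermi_kernel(pd_game, 1.0)
        assert not extinction_bound_holds(14.0, 1.0, 2.0, kernel)


class TestTailExponent:
    @pytest.mark.parametrize("theta", [0.5, 1.0, 2.0])
    def test_theta_family_recovered(self, theta):
        f = initial_density({"kind": "theta", "theta": theta}, Grid(512))
        est = tail_exponent_estimate(f, window=(2 / 512, 0.2))
        assert est.theta_hat == pytest.approx(theta, rel=0.02)
        assert est.reliable

    def test_top_cell_is_flat(self):
        est = tail_exponent_estimate(top_cell_density(256), window=(2 / 256, 0.2))
        assert abs(est.theta_hat) < 0.05

    def test_empty_tail_flagged(self):
        vals = np.zeros(64)
        vals[0] = 64.0
        f = DensityState(grid=Grid(64), values=vals)
        est = tail_exponent_estimate(f, window=(0.01, 0.2))
        assert not est.reliable

    def test_particle_measure_supported(self):
        rng = np.random.default_rng(7)
        pos = 1.0 - rng.uniform(0, 1, 20000) ** 0.5  # tail mass ~ x^2
        mu = ParticleMeasure(pos, np.full(20000, 5e-5))
        est = tail_exponent_estimate(mu, window=(0.02, 0.2))
        assert est.theta_hat == pytest.approx(2.0, rel=0.1)

    def test_bad_window_rejected(self):
        f = DensityState(grid=Grid(16), values=np.ones(16))
        with pytest.raises(ValueError):
            tail_exponent_estimate(f, window=(0.1, 0.6))


class TestLongTimePrediction:
    def test_pd_below_threshold_is_baseline(self, pd_game):
        kernel = fermi_kernel(pd_game, 1.0)
        assert long_time_prediction(1e-6, pd_game, kernel, scenario="PD") == pytest.approx(
            float(kernel(0.0, 1.0)), abs=1e-15
        )

    def test_branches_agree_at_threshold(self, pd_game):
        kernel = fermi_kernel(pd_game, 1.0)
        lam_star = lambda_star_pd(1.0, 2.0, kernel)
        below = long_time_prediction(lam_star * (1 - 1e-9), pd_game, kernel, scenario="PD")
        above = long_time_prediction(lam_star, pd_game, kernel, scenario="PD")
        assert below == pytest.approx(above, abs=1e-8)

    def test_hd_strong_conflict(self, hd_game):
        kernel = fermi_kernel(hd_game, 1.0)
        assert long_time_prediction(15.0, hd_game, kernel, scenario="HD") == pytest.approx(
            0.5 - 1 / 30, abs=1e-14
        )


class TestSteadyStateResidual:
    def test_inert_dynamics_zero_residual(self):
        c = GameCoefficients(alpha=0.0, beta=0.0, gamma=0.0, P=1.0)  # pi = 0
        neutral = separable_kernel(lambda x: np.zeros_like(np.asarray(x, dtype=float)))
        f = DensityState(grid=Grid(64), values=np.ones(64))
        assert steady_state_residual(f, c, neutral, lam=3.0) == pytest.approx(0.0, abs=1e-14)

    def test_uniform_pd_flux_derivative(self):
        # lam=0, f=1: residual = int |d/dx (x(1-x)(1+x))| dx = 4/(3*sqrt(3))
        c = GameCoefficients(alpha=-1.0, beta=-1.0, gamma=0.0, P=0.0)  # pi = 1 + x
        neutral = separable_kernel(lambda x: np.zeros_like(np.asarray(x, dtype=float)))
        f = DensityState(grid=Grid(512), values=np.ones(512))
        expected = 4.0 / (3.0 * np.sqrt(3.0))
        assert steady_state_residual(f, c, neutral, lam=0.0) == pytest.approx(expected, abs=0.02)

    def test_converged_run_has_small_residual(self, pd_game):
        config = SimulationConfig(
            game=pd_game,
            kernel=fermi_kernel(pd_game, 1.0),
            lam=14.0,
            dt=0.003,
            n_steps=4000,
            N=256,
            snapshot_every=10**6,
        )
        final = run(config).final
        residual = steady_state_residual(final, pd_game, config.kernel, 14.0)
        assert residual <= 10 * (1 / 256)  # within 10x the discretization scale


class TestDetectSteadyState:
    def _traj(self, states, pd_game):
        from mlsconflict.solver_fv import Trajectory

        config = SimulationConfig(
            game=pd_game, kernel=fraction_kernel(), lam=0.0, dt=0.01, n_steps=1, N=states[0].grid.N
        )
        return Trajectory(
            config=config,
            times=np.array([s.time for s in states]),
            states=states,
            diagnostics={},
        )

    def test_constant_trajectory(self, pd_game):
        grid = Grid(16)
        states = [
            DensityState(grid=grid, values=np.ones(16), time=float(t)) for t in range(3)
        ]
        found, when = detect_steady_state(self._traj(states, pd_game), tol=1e-4)
        assert found and when == 1.0

    def test_decaying_transient_monotone_in_tol(self, pd_game):
        grid = Grid(16)
        states = [
            DensityState(
                grid=grid, values=1.0 + np.exp(-t) * np.linspace(0, 1, 16), time=float(t)
            )
            for t in range(12)
        ]
        traj = self._traj(states, pd_game)
        _, t_loose = detect_steady_state(traj, tol=1e-1)
        _, t_tight = detect_steady_state(traj, tol=1e-3)
        assert t_loose < t_tight

    def test_never_steady(self, pd_game):
        grid = Grid(8)
        states = [
            DensityState(grid=grid, values=1.0 + (t % 2) * np.ones(8) * 0.5, time=float(t))
            for t in range(4)
        ]
        found, when = detect_steady_state(self._traj(states, pd_game), tol=1e-6)
        assert not found and when is None

    def test_needs_two_snapshots(self, pd_game):
        grid = Grid(8)
        states = [DensityState(grid=grid, values=np.ones(8), time=0.0)]
        with pytest.raises(ValueError):
            detect_steady_state(self._traj(states, pd_game), tol=1e-4)
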