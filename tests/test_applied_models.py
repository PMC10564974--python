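"""Applied benchmark models: fixed points, bifurcation location, runs."""
import numpy as np
import pytest

from dtews.applied_models import (
    MODELS,
    fixed_point,
    jacobian,
    locate_bifurcation,
    make_forced_run,
    make_null_run,
    step_test_model,
)
from dtews.ews import DetrendSpec, compute_ews


class TestStep:
    def test_lotka_volterra_prey_only_fixed_point(self):
        out = step_test_model("lotka_volterra", MODELS["lotka_volterra"].default_params,
                              [1.0, 0.0], 0.8, [0.0, 0.0])
        assert np.allclose(out, [1.0, 0.0], atol=1e-12)

    def test_lorenz_origin_fixed_point(self):
        out = step_test_model("lorenz", MODELS["lorenz"].default_params,
                              [0.0, 0.0], -0.5, [0.0, 0.0])
        assert np.allclose(out, [0.0, 0.0], atol=1e-12)

    def test_ricker_carrying_capacity_without_harvest(self):
        out = step_test_model("ricker", MODELS["ricker"].default_params,
                              [10.0], 0.0, [0.0])
        assert out[0] == pytest.approx(10.0, abs=1e-12)

    @pytest.mark.parametrize("name,control", [
        ("fox", 300.0),
        ("westerhoff", 10.0),
        ("ricker", 0.5),
        ("lotka_volterra", 0.7),
        ("lorenz", -0.8),
    ])
    def test_deterministic_fixed_points_are_invariant(self, name, control):
        fp = fixed_point(name, control)
        nxt = step_test_model(name, MODELS[name].default_params, fp, control, [0.0, 0.0])
        assert np.allclose(nxt, fp, atol=1e-10)


class TestLocateBifurcation:
    def test_westerhoff_closed_form(self):
        # Y* = 2a; complex pair modulus 1 when c*Y*/4 - d = 1 => a = 24
        assert locate_bifurcation("westerhoff") == pytest.approx(24.0, abs=1e-4)

    def test_lotka_volterra_exact(self):
        assert locate_bifurcation("lotka_volterra") == pytest.approx(1.0, abs=1e-6)

    def test_lorenz_exact(self):
        assert locate_bifurcation("lorenz") == pytest.approx(0.0, abs=1e-6)

    def test_fox_eigenvalue_sweep_oracle(self):
        """Brute-force sweep (grid step 1e-3): the dominant eigenvalue of
        the (D, M) Jacobian crosses -1 at the same T as the root-finder."""
        T_star = locate_bifurcation("fox")
        params = MODELS["fox"].default_params
        grid = np.arange(T_star - 0.5, T_star + 0.5, 1e-3)
        guess = fixed_point("fox", grid[-1] + 1.0)
        conds = []
        for T in grid[::-1]:
            guess = fixed_point("fox", float(T), guess=guess)
            eig = np.linalg.eigvals(jacobian("fox", params, guess, float(T)))
            conds.append(eig.real.min() + 1.0)
        conds = np.array(conds[::-1])
        sign_change = np.nonzero(np.diff(np.sign(conds)))[0]
        assert len(sign_change) == 1
        assert abs(grid[sign_change[0]] - T_star) < 2e-3

    def test_ricker_fold_oracle_by_fixed_point_counting(self):
        """The upper and middle fixed-point branches merge (tangency) at
        the located harvesting rate: a 1e-3 sweep of F sees the number
        of fixed points above the transition threshold drop there."""
        F_star = locate_bifurcation("ricker")
        p = MODELS["ricker"].default_params
        x = np.linspace(0.45, 15.0, 20000)

        def n_roots(F):
            fx = x * np.exp(p.r * (1 - x / p.k)) - F * x**2 / (x**2 + p.h**2) - x
            return int(np.sum(np.diff(np.sign(fx)) != 0))

        grid = np.arange(F_star - 0.05, F_star + 0.05, 1e-3)
        counts = np.array([n_roots(float(F)) for F in grid])
        drop = np.nonzero(np.diff(counts) < 0)[0]
        assert len(drop) >= 1
        assert abs(grid[drop[0]] - F_star) < 5e-3

    def test_westerhoff_companion_matrix_sweep(self):
        """Independent cross-check: eigenvalue modulus of the companion
        matrix crosses 1 between a = 23.999 and 24.001."""
        p = MODELS["westerhoff"].default_params

        def modulus(a):
            ystar = a / (1 - p.b - p.c / 2)
            d11 = (p.b - p.d) + p.c / 2 + p.c * ystar / 4
            d12 = p.d - p.c * ystar / 4
            J = np.array([[0.0, 1.0], [d12, d11]])
            return np.max(np.abs(np.linalg.eigvals(J)))

        grid = np.arange(23.9, 24.1, 1e-3)
        mods = np.array([modulus(a) for a in grid])
        crossing = grid[np.nonzero(np.diff(np.sign(mods - 1.0)))[0][0]]
        assert abs(crossing - 24.0) < 2e-3


class TestRuns:
    def test_fox_forced_run_ramps_down_and_truncates_at_bifurcation(self):
        traj = make_forced_run("fox", 0.05, 500, rng_seed=1)
        assert len(traj.observable) <= 500
        assert traj.mu_schedule[0] > traj.mu_schedule[-1]
        T_star = locate_bifurcation("fox")
        assert traj.mu_schedule[-1] > T_star  # all stored points pre-bifurcation
        assert traj.mu_schedule[-1] - T_star < 1.0

    def test_forced_run_length_scales_with_requested_length(self):
        for n in (100, 300):
            traj = make_forced_run("lorenz", 0.01, n, rng_seed=2)
            assert abs(len(traj.observable) - n) <= 2

    def test_same_seed_gives_identical_runs(self):
        a = make_forced_run("ricker", 0.2, 200, rng_seed=5)
        b = make_forced_run("ricker", 0.2, 200, rng_seed=5)
        assert np.array_equal(a.observable, b.observable)

    @pytest.mark.parametrize("name,null_value", [
        ("westerhoff", 10.0),
        ("lotka_volterra", 0.5),
        ("fox", 300.0),
    ])
    def test_null_runs_hold_the_stated_control_value(self, name, null_value):
        traj = make_null_run(name, MODELS[name].base_noise, 150, rng_seed=3)
        assert np.all(traj.mu_schedule == null_value)
        assert len(traj.observable) == 150

    def test_noise_free_null_settles_to_a_constant(self):
        traj = make_null_run("lotka_volterra", 0.0, 100, rng_seed=0)
        assert np.ptp(traj.observable[10:]) < 1e-6

    def test_ricker_transition_is_population_threshold(self):
        traj = make_forced_run("ricker", 0.2, 300, rng_seed=7)
        assert np.all(traj.observable >= MODELS["ricker"].default_params.transition_threshold)

    def test_forced_fox_variance_trend_is_positive(self):
        """Critical slowing down before the period-doubling: rolling
        variance trends upward in the median over seeded runs."""
        taus = []
        for seed in range(20):
            traj = make_forced_run("fox", 0.1, 300, rng_seed=seed)
            res = compute_ews(traj.observable, DetrendSpec(), 0.5)
            taus.append(res.tau_variance)
        assert np.median(taus) > 0
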