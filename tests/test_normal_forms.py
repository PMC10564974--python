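"""Normal-form maps, transition detection and library bookkeeping."""
import numpy as np
import pytest

from dtews.normal_forms import (
    BifurcationClass,
    NormalFormModel,
    SimulationDiverged,
    build_library,
    detect_transition,
    equilibrium,
    rotation_matrix,
    sample_model,
    sample_mu0,
    simulate,
    step_normal_form,
)

B = BifurcationClass


def _bare_model(cls, mu0, sigma=0.0, cubic_sign=1, seed=0, alpha=None):
    """Model with all higher-order coefficients zero unless given."""
    if cls == B.NEIMARK_SACKER:
        return NormalFormModel(
            cls,
            alpha=np.zeros(56) if alpha is None else alpha,
            beta=np.zeros(56),
            theta=np.pi / 2,
            cubic_sign=cubic_sign,
            sigma=sigma,
            mu0=mu0,
            seed=seed,
        )
    n = 7 if cls in (B.PERIOD_DOUBLING, B.PITCHFORK) else 8
    cs = cubic_sign if cls in (B.PERIOD_DOUBLING, B.PITCHFORK) else None
    return NormalFormModel(
        cls,
        alpha=np.zeros(n) if alpha is None else alpha,
        sigma=sigma,
        mu0=mu0,
        seed=seed,
        cubic_sign=cs,
    )


def test_rotation_matrix_is_orthogonal_with_unit_determinant(rng):
    for theta in rng.uniform(-10, 10, size=1000):
        R = rotation_matrix(theta)
        assert np.allclose(R @ R.T, np.eye(2), atol=1e-12)
        assert abs(np.linalg.det(R) - 1.0) < 1e-12


class TestSampling:
    def test_seeded_model_sampling_is_deterministic(self):
        m1 = sample_model(B.PERIOD_DOUBLING, rng_seed=1)
        m2 = sample_model(B.PERIOD_DOUBLING, rng_seed=1)
        assert np.array_equal(m1.alpha, m2.alpha)
        assert m1.sigma == m2.sigma and m1.mu0 == m2.mu0 and m1.seed == m2.seed

    def test_neimark_sacker_has_theta_and_both_coefficient_sets(self):
        for seed in range(10):
            m = sample_model(B.NEIMARK_SACKER, rng_seed=seed)
            assert 0.0 <= m.theta <= np.pi
            assert len(m.alpha) == 56 and len(m.beta) == 56

    def test_fold_has_degrees_3_to_10_and_no_theta(self):
        m = sample_model(B.FOLD, rng_seed=3)
        assert list(m.degrees) == list(range(3, 11))
        assert m.theta is None and m.beta is None

    @pytest.mark.parametrize(
        "cls,lo,hi",
        [
            (B.PITCHFORK, -1.8, -0.2),
            (B.PERIOD_DOUBLING, -1.8, -0.2),
            (B.FOLD, -0.9, -0.1),
        ],
    )
    def test_mu0_sampling_intervals(self, cls, lo, hi):
        draws = [sample_mu0(cls, rng_seed=s) for s in range(200)]
        assert all(lo <= d <= hi for d in draws)

    def test_eigenvalue_bound_at_interval_edge(self):
        # period-doubling linearisation at the fixed point: lambda = -(1+mu)
        mu0 = -0.2
        assert abs(-(1 + mu0)) == pytest.approx(0.8)

    def test_null_class_is_rejected(self):
        with pytest.raises(ValueError):
            sample_model(B.NULL, rng_seed=0)
        with pytest.raises(ValueError):
            sample_mu0(B.NULL, rng_seed=0)


class TestStep:
    def test_period_doubling_direct_evaluation(self):
        m = _bare_model(B.PERIOD_DOUBLING, mu0=-0.5)
        out = step_normal_form(m, [0.1], -0.5, [0.0])
        assert out[0] == pytest.approx(-0.049, abs=1e-12)

    def test_fold_fixed_point_at_sqrt_minus_mu(self):
        m = _bare_model(B.FOLD, mu0=-0.25)
        out = step_normal_form(m, [0.5], -0.25, [0.0])
        assert out[0] == pytest.approx(0.5, abs=1e-12)

    def test_neimark_sacker_quarter_turn_cubic_term(self):
        m = _bare_model(B.NEIMARK_SACKER, mu0=-1.0)
        out = step_normal_form(m, [0.1, 0.0], -1.0, [0.0, 0.0])
        assert np.allclose(out, [0.0, 0.001], atol=1e-15)

    def test_positive_mu_is_rejected(self):
        m = _bare_model(B.FOLD, mu0=-0.25)
        with pytest.raises(ValueError):
            step_normal_form(m, [0.5], 0.1, [0.0])

    @pytest.mark.parametrize(
        "cls,mu,expected",
        [
            (B.PERIOD_DOUBLING, -0.5, -0.5),   # -(1+mu)
            (B.TRANSCRITICAL, -0.5, 0.5),      # (1+mu)
            (B.PITCHFORK, -0.3, 0.7),          # (1+mu)
            (B.FOLD, -0.16, 0.2),              # 1 - 2 sqrt(-mu)
        ],
    )
    def test_linearised_growth_factor(self, cls, mu, expected):
        m = _bare_model(cls, mu0=mu)
        eq = equilibrium(m, mu)
        delta = 1e-7
        out = step_normal_form(m, eq + delta, mu, np.zeros(2))
        growth = (out[0] - equilibrium(m, mu)[0]) / delta
        assert growth == pytest.approx(expected, abs=1e-6)

    def test_neimark_sacker_growth_modulus(self):
        mu = -0.4
        m = _bare_model(B.NEIMARK_SACKER, mu0=mu)
        delta = 1e-7
        out = step_normal_form(m, [delta, 0.0], mu, np.zeros(2))
        assert np.linalg.norm(out) / delta == pytest.approx(1 + mu, abs=1e-6)


class TestTransitionDetection:
    def test_series_at_equilibrium_gives_none(self):
        vals = np.zeros(100)
        assert detect_transition(vals, np.zeros(100), sigma=0.01) is None

    def test_first_exceedance_index(self):
        vals = np.zeros(400)
        vals[250] = 0.11
        vals[300] = 0.5
        assert detect_transition(vals, np.zeros(400), sigma=0.01) == 250

    def test_fold_deviation_uses_moving_equilibrium(self):
        # forced fold run: raw x drifts from sqrt(-mu0) toward 0, but the
        # residual against sqrt(-mu_t) stays small
        m = _bare_model(B.FOLD, mu0=-0.8, sigma=0.01, seed=5)
        rng = np.random.default_rng(5)
        n = 400
        mu_sched = -0.8 * (1 - np.arange(1, n + 1) / 600)
        state = equilibrium(m, -0.8)
        vals, eqs = [], []
        for t in range(n):
            state = step_normal_form(m, state, mu_sched[t], rng.standard_normal(1))
            vals.append(state[0])
            eqs.append(equilibrium(m, mu_sched[t])[0])
        vals, eqs = np.array(vals), np.array(eqs)
        moving = detect_transition(vals, eqs, sigma=0.01)
        fixed = detect_transition(vals, np.full(n, eqs[0]), sigma=0.01)
        assert moving is None
        assert fixed is not None  # naive fixed-equilibrium rule misfires

    def test_noise_free_rule_uses_absolute_floor(self):
        vals = np.zeros(50)
        vals[30] = 0.002
        assert detect_transition(vals, np.zeros(50), sigma=0.0) == 30


class TestSimulate:
    def test_noise_free_null_is_constant_at_equilibrium(self):
        m = _bare_model(B.TRANSCRITICAL, mu0=-0.5)
        traj = simulate(m, forced=False)
        assert len(traj.observable) == 500
        assert np.allclose(traj.observable, 0.0)
        assert np.all(traj.mu_schedule == -0.5)

    def test_noise_free_forced_transcritical_stays_at_zero(self):
        m = _bare_model(B.TRANSCRITICAL, mu0=-0.5)
        traj = simulate(m, forced=True)
        assert np.allclose(traj.observable, 0.0)
        assert traj.mu_schedule[-1] == pytest.approx(0.0)

    def test_forced_mu_schedule_is_nondecreasing(self):
        m = sample_model(B.PITCHFORK, rng_seed=2)
        traj = simulate(m, forced=True)
        assert np.all(np.diff(traj.mu_schedule) >= 0)

    def test_stored_length_and_truncation(self):
        rng = np.random.default_rng(9)
        for _ in range(30):
            cls = rng.choice([B.PERIOD_DOUBLING, B.FOLD, B.NEIMARK_SACKER])
            m = sample_model(B(cls), rng_seed=int(rng.integers(2**31)))
            try:
                traj = simulate(m, forced=True)
            except SimulationDiverged:
                continue
            assert len(traj.observable) <= 500
            if traj.transition_index is not None:
                assert len(traj.observable) == min(500, traj.transition_index)

    def test_seeded_reproducibility(self):
        m = sample_model(B.FOLD, rng_seed=42)
        t1 = simulate(m, forced=True)
        t2 = simulate(m, forced=True)
        assert np.array_equal(t1.observable, t2.observable)


class TestLibrary:
    def test_scaled_build_counts(self):
        lib = build_library(10, 10, rng_seed=3)
        assert len(lib) == 60
        counts = lib.class_counts()
        assert counts == {c: 10 for c in range(6)}

    def test_no_nulls_kept(self):
        lib = build_library(4, 0, rng_seed=3)
        assert len(lib) == 20
        assert 0 not in lib.class_counts()

    def test_too_many_nulls_rejected(self):
        with pytest.raises(ValueError):
            build_library(2, 11, rng_seed=0)

    def test_bit_identical_for_identical_seeds(self):
        l1 = build_library(5, 5, rng_seed=77)
        l2 = build_library(5, 5, rng_seed=77)
        assert len(l1) == len(l2)
        for a, b in zip(l1.series, l2.series):
            assert np.array_equal(a, b)
        assert np.array_equal(l1.labels, l2.labels)

    def test_manifest_records_every_model(self):
        lib = build_library(3, 3, rng_seed=1)
        assert len(lib.manifest) == 15
        assert all("seed" in rec and "sigma" in rec for rec in lib.manifest)
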