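"""Three-state scheme: rate law, derived constants, simulation oracles."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from hemeco.kinetics import (
    ObservedRatePoint,
    ThreeStateRates,
    derived_constants,
    equilibrium_fractions,
    kobs_hyperbolic,
    rate_matrix,
    replacement_observed_rate,
    simulate_three_state,
    slowest_relaxation_rate,
    validity_check,
)


class TestRates:
    def test_positive_finite_required(self):
        with pytest.raises(ValueError):
            ThreeStateRates(k1=-1.0, k_m1=1.0, k2=1.0, k_m2=1.0)
        with pytest.raises(ValueError):
            ThreeStateRates(k1=1.0, k_m1=0.0, k2=1.0, k_m2=1.0)
        with pytest.raises(ValueError):
            ThreeStateRates(k1=1.0, k_m1=1.0, k2=np.inf, k_m2=1.0)

    def test_json_roundtrip(self, default_rates):
        restored = ThreeStateRates.from_json(default_rates.to_json())
        assert restored == default_rates


class TestKobsHyperbolic:
    def test_zero_concentration_gives_zero(self, default_rates):
        assert kobs_hyperbolic(default_rates, 0.0) == 0.0

    def test_initial_slope_is_kco(self, default_rates):
        """d(kobs)/d[CO] at [CO]->0 equals the composite on-rate 0.27."""
        c = 1e-8
        slope = kobs_hyperbolic(default_rates, c) / c
        assert slope == pytest.approx(0.27, rel=1e-4)

    def test_half_saturation_midpoint_matches_eigenvalue(self, sink_rates):
        """At [CO] = k_m1/k2 the hyperbola gives exactly k1/2, and the
        slowest relaxation of the full system agrees in the sink regime."""
        c_mid = sink_rates.k_m1 / sink_rates.k2
        assert kobs_hyperbolic(sink_rates, c_mid) == pytest.approx(
            sink_rates.k1 / 2.0, rel=1e-12
        )
        assert slowest_relaxation_rate(sink_rates, c_mid) == pytest.approx(
            sink_rates.k1 / 2.0, rel=0.01
        )

    def test_monotone_and_bounded_by_k1(self, default_rates):
        c = np.geomspace(0.1, 1e5, 200)
        k = kobs_hyperbolic(default_rates, c)
        assert np.all(np.diff(k) > 0)
        assert np.all(k < default_rates.k1)

    def test_negative_concentration_rejected(self, default_rates):
        with pytest.raises(ValueError):
            kobs_hyperbolic(default_rates, -1.0)


class TestDerivedConstants:
    def test_paper_identity(self, default_rates):
        """k_m2/kCO with the printed constants predicts ~0.19 uM."""
        k_co, kd = derived_constants(default_rates)
        assert k_co == pytest.approx(0.27, rel=1e-12)
        assert kd == pytest.approx(0.05 / 0.27, rel=1e-12)

    def test_irreversible_limit(self):
        r = ThreeStateRates(k1=25.0, k_m1=5000.0, k2=54.0, k_m2=1e-12)
        _, kd = derived_constants(r)
        assert kd < 1e-11

    def test_equilibrium_half_saturation_oracle(self, default_rates):
        """The exact half-saturation [CO] of the equilibrium CO-bound
        fraction is Kd_kinetic * (1 + k1/k_m1); for k1 << k_m1 it reduces
        to Kd_kinetic itself."""
        r = default_rates
        f_sat = equilibrium_fractions(r, 1e12)[2]
        c_half = brentq(
            lambda c: equilibrium_fractions(r, c)[2] - f_sat / 2.0, 1e-9, 1e6
        )
        expected = r.kd_kinetic * (1.0 + r.k1 / r.k_m1)
        assert c_half == pytest.approx(expected, rel=1e-6)
        assert c_half == pytest.approx(r.kd_kinetic, rel=0.01)  # k1/k_m1 = 0.005


class TestValidityCheck:
    def test_paper_ratio(self, default_rates):
        ok, ratio = validity_check(default_rates)
        assert ratio == pytest.approx(0.05 / 0.27, rel=1e-12)
        assert not ok  # 0.185 uM exceeds the default 0.01 uM threshold
        ok_loose, _ = validity_check(default_rates, threshold=1.0)
        assert ok_loose

    def test_tiny_km2_flags_valid(self):
        r = ThreeStateRates(k1=25.0, k_m1=5000.0, k2=54.0, k_m2=1e-9)
        ok, ratio = validity_check(r)
        assert ok and ratio < 1e-8

    def test_ratio_invariant_under_k2_km1_scaling(self, default_rates):
        _, ratio = validity_check(default_rates)
        for s in (0.1, 3.0, 42.0):
            scaled = ThreeStateRates(
                k1=default_rates.k1,
                k_m1=default_rates.k_m1 * s,
                k2=default_rates.k2 * s,
                k_m2=default_rates.k_m2,
            )
            assert validity_check(scaled)[1] == pytest.approx(ratio, rel=1e-12)


class TestSimulateThreeState:
    def test_mass_conservation(self, default_rates):
        t = np.geomspace(1e-5, 10.0, 300)
        traj = simulate_three_state(default_rates, 300.0, (1.0, 0.0, 0.0), t)
        assert np.max(np.abs(traj.fractions.sum(axis=1) - 1.0)) < 1e-9
        assert np.all(traj.fractions >= 0.0) and np.all(traj.fractions <= 1.0)

    def test_unnormalized_init_rejected(self, default_rates):
        with pytest.raises(ValueError):
            simulate_three_state(default_rates, 300.0, (0.5, 0.0, 0.0), np.linspace(0, 1, 10))

    def test_decoupled_two_state_limit(self):
        """k2 ~ 0: CO-bound stays put; 6c/5c relax to the k_m1:k1 ratio."""
        r = ThreeStateRates(k1=25.0, k_m1=100.0, k2=1e-12, k_m2=1e-12)
        t = np.linspace(0.0, 5.0, 50)
        traj = simulate_three_state(r, 300.0, (0.7, 0.0, 0.3), t)
        assert traj.fractions[:, 2] == pytest.approx(0.3, abs=1e-8)
        f6, f5 = traj.fractions[-1, 0], traj.fractions[-1, 1]
        assert f6 / f5 == pytest.approx(r.k_m1 / r.k1, rel=1e-6)

    def test_long_time_limit_matches_detailed_balance(self, default_rates):
        """Closed-form equilibrium (K1, K1*K2 weights) vs long integration."""
        r, co = default_rates, 5.0
        t = np.linspace(0.0, 500.0, 100)
        traj = simulate_three_state(r, co, (1.0, 0.0, 0.0), t)
        K1 = r.k1 / r.k_m1
        K2 = r.k2 * co / r.k_m2
        expected_co = K1 * K2 / (1.0 + K1 + K1 * K2)
        assert traj.fractions[-1, 2] == pytest.approx(expected_co, rel=1e-9)
        assert traj.fractions[-1] == pytest.approx(equilibrium_fractions(r, co), rel=1e-9)

    def test_eigen_solution_matches_integrator(self, default_rates):
        """Analytic eigen-decomposition vs an explicit numerical integrator."""
        co = 300.0
        t = np.linspace(0.0, 0.5, 60)
        traj = simulate_three_state(default_rates, co, (1.0, 0.0, 0.0), t)
        M = rate_matrix(default_rates, co)
        sol = solve_ivp(
            lambda _t, y: M @ y,
            (0.0, t[-1]),
            [1.0, 0.0, 0.0],
            t_eval=t,
            method="RK45",
            rtol=1e-11,
            atol=1e-13,
        )
        assert np.max(np.abs(traj.fractions - sol.y.T)) < 1e-6

    def test_slowest_relaxation_matches_kobs_in_valid_regime(self, sink_rates):
        """Where the sink and rapid-pre-equilibrium conditions both hold the
        hyperbolic law reproduces the slowest relaxation to <1%."""
        ok, ratio = validity_check(sink_rates, threshold=1e-3)
        assert ok and ratio < 1e-3
        for co in (10.0, 100.0, 1000.0):
            assert kobs_hyperbolic(sink_rates, co) == pytest.approx(
                slowest_relaxation_rate(sink_rates, co), rel=0.01
            )

    def test_pseudo_first_order_guard_warns(self, default_rates):
        with pytest.warns(UserWarning, match="pseudo-first-order"):
            simulate_three_state(
                default_rates, 10.0, (1.0, 0.0, 0.0), np.linspace(0, 1, 10), heme_conc=2.0
            )


class TestReplacementObservedRate:
    def test_perfect_trap_returns_km2(self, default_rates):
        assert replacement_observed_rate(default_rates) == pytest.approx(0.05)

    def test_vanishing_km2(self):
        r = ThreeStateRates(k1=25.0, k_m1=5000.0, k2=54.0, k_m2=1e-15)
        assert replacement_observed_rate(r) == pytest.approx(0.0, abs=1e-14)

    def test_invalid_trap_efficiency(self, default_rates):
        with pytest.raises(ValueError):
            replacement_observed_rate(default_rates, trap_efficiency=0.0)
        with pytest.raises(ValueError):
            replacement_observed_rate(default_rates, trap_efficiency=1.5)

    @pytest.mark.parametrize("f", [0.25, 0.5, 0.75, 1.0])
    def test_partial_trap_against_four_state_oracle(self, default_rates, f):
        """Competitive rebinding oracle: 5c either rebinds CO (rate kr) or is
        captured by NO (rate kt) with capture fraction f = kt/(kt + kr).
        When capture/rebinding are fast relative to k_m2 the observable
        disappearance of the CO complex proceeds at k_m2 * f."""
        km2 = default_rates.k_m2
        k_total = 1e4  # fast partitioning of the transient 5c species
        kt, kr = f * k_total, (1.0 - f) * k_total
        # states: CO-bound, 5c, NO-trapped
        M = np.array(
            [
                [-km2, kr, 0.0],
                [km2, -(kr + kt), 0.0],
                [0.0, kt, 0.0],
            ]
        )
        evals = np.sort(np.abs(np.real(np.linalg.eigvals(M))))
        slow = evals[1]  # evals[0] ~ 0 (absorbing state)
        assert replacement_observed_rate(default_rates, trap_efficiency=f) == pytest.approx(
            slow, rel=1e-3
        )


def test_observed_rate_point_validation():
    with pytest.raises(ValueError):
        ObservedRatePoint(co_conc=-1.0, k_obs=1.0)
    with pytest.raises(ValueError):
        ObservedRatePoint(co_conc=1.0, k_obs=-0.1)


def test_trajectory_csv_roundtrip(tmp_path, default_rates):
    from hemeco.kinetics import StateTrajectory

    t = np.linspace(0.0, 1.0, 20)
    traj = simulate_three_state(default_rates, 300.0, (1.0, 0.0, 0.0), t)
    path = tmp_path / "traj.csv"
    traj.to_csv(path)
    restored = StateTrajectory.from_csv(path)
    assert np.allclose(restored.fractions, traj.fractions, atol=1e-12)
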