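"""Unit and property tests for the kinetic model core."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from xlnrdyn.kinetics import (
    InputSignal,
    KineticParameters,
    LegacyParameters,
    psi_crea,
    psi_xyl,
    rhs_legacy,
    rhs_new,
    simulate,
    steady_state,
)


class TestHillFactors:
    @pytest.mark.parametrize(
        "X, K, h, expected",
        [
            (0.7, 0.7, 1, 0.5),     # half-saturation, any steepness
            (0.7, 0.7, 4, 0.5),
            (0.0, 0.3, 2, 0.0),     # no activator, no activation
            (1.0, 0.5, 2, 0.8),     # 2x threshold, h=2 -> 4/5
        ],
    )
    def test_activation_closed_form(self, X, K, h, expected):
        assert psi_xyl(X, K, h) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize(
        "x, K, h, expected",
        [
            (0.9, 0.9, 2, 0.5),        # switching level
            (0.0, 0.4, 4, 1.0),        # CreA absent: no repression
            (2.0, 1.0, 4, 1.0 / 17),   # 2x threshold, h=4
        ],
    )
    def test_repression_closed_form(self, x, K, h, expected):
        assert psi_crea(x, K, h) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("fn", [psi_xyl, psi_crea])
    def test_domain_errors(self, fn):
        with pytest.raises(ValueError):
            fn(1.0, -0.5, 2)
        with pytest.raises(ValueError):
            fn(-1.0, 0.5, 2)

    @given(
        x=st.floats(0.0, 1e6),
        K=st.floats(1e-6, 1e3),
        h=st.integers(1, 6),
    )
    @settings(max_examples=200, deadline=None)
    def test_bounded_and_monotone(self, x, K, h):
        a = psi_xyl(x, K, h)
        r = psi_crea(x, K, h)
        assert 0.0 <= a <= 1.0 and 0.0 <= r <= 1.0
        # activation rises with X, repression falls with CreA
        assert psi_xyl(x + 1.0, K, h) >= a
        assert psi_crea(x + 1.0, K, h) <= r


class TestRightHandSides:
    def test_no_stimulus_fixed_point(self, default_params):
        u0 = InputSignal("constant", u0=0.0)
        assert rhs_new((0, 0, 0), 0.0, default_params, u0) == (0, 0, 0)
        lp = LegacyParameters()
        assert rhs_legacy((0, 0), 0.0, lp, u0) == (0, 0)

    def test_knockout_removes_repression(self, default_params):
        u = InputSignal("constant", u0=1.0)
        state = (0.2, 5.0, 1.0)
        dko = rhs_new(state, 0.0, default_params, u, knockout=True)
        p = default_params
        expected = (p.k_is_Wt * psi_xyl(0.2, p.K_i1, p.h1) - p.k_id * 1.0)
        assert dko[1] == 0.0
        assert dko[2] == pytest.approx(expected)

    def test_negative_state_rejected(self, default_params):
        u = InputSignal("constant", u0=1.0)
        with pytest.raises(ValueError):
            rhs_new((-0.1, 0, 0), 0.0, default_params, u)

    def test_legacy_strong_repression_limit(self):
        # k_i2*u >> 1 drives the repression factor to ~0: pure decay
        lp = LegacyParameters(k_i2=1e6, k_id=2.0)
        u = InputSignal("constant", u0=50.0)
        d = rhs_legacy((1.0, 3.0), 0.0, lp, u)
        assert d[1] == pytest.approx(-2.0 * 3.0, rel=1e-7)


class TestSimulation:
    def test_linear_subsystem_matches_analytic(self, default_params):
        """(X, x_CreA) are linear ODEs; under constant u their closed forms
        must be reproduced to 1e-6 relative."""
        p = default_params
        u = InputSignal("constant", u0=1.0)
        t = np.linspace(0, 1.0, 21)
        traj = simulate(p, u, t)
        X_inf = p.K_on * p.x_xlnR_const / p.K_off
        C_inf = p.k1 / p.k2
        X_exact = X_inf * (1 - np.exp(-p.K_off * t))
        C_exact = C_inf * (1 - np.exp(-p.k2 * t))
        assert np.allclose(traj["X"], X_exact, rtol=1e-6, atol=1e-9)
        assert np.allclose(traj["x_CreA"], C_exact, rtol=1e-6, atol=1e-9)

    def test_pure_decay_without_activation(self, default_params):
        # u = 0 keeps psi_xyl at 0, so the transcript decays exponentially
        u = InputSignal("constant", u0=0.0)
        t = np.linspace(0, 3, 13)
        traj = simulate(default_params, u, t, init=[0, 0, 2.0])
        assert np.allclose(traj["x_i"], 2.0 * np.exp(-default_params.k_id * t),
                           rtol=1e-6)

    def test_steady_state_agrees_with_long_integration(self, default_params):
        ss = steady_state(default_params, 1.0)
        traj = simulate(default_params, InputSignal("constant", u0=1.0),
                        [0.0, 500.0, 1000.0])
        final = traj.iloc[-1]
        assert final["X"] == pytest.approx(ss.X, rel=1e-6)
        assert final["x_CreA"] == pytest.approx(ss.x_CreA, rel=1e-6)
        assert final["x_i"] == pytest.approx(ss.x_i, rel=1e-6)

    def test_steady_state_zero_input_and_monotonicity(self, default_params):
        assert steady_state(default_params, 0.0) == (0.0, 0.0, 0.0)
        # steady x_i never increases as K_off grows (less complex formed)
        vals = [steady_state(default_params.replace(K_off=K), 1.0).x_i
                for K in (20.0, 75.0, 200.0, 800.0)]
        assert all(b <= a + 1e-12 for a, b in zip(vals, vals[1:]))

    def test_transcription_rate_bounded_by_hill_product(self, default_params):
        """dx_i/dt + k_id*x_i = k_is*psi_xyl*psi_crea must lie in [0, k_is]."""
        p = default_params
        u = InputSignal("exp", u0=50.0, decay_rate=0.05)
        traj = simulate(p, u, np.linspace(0, 5, 16))
        for _, row in traj.iterrows():
            d = rhs_new((row.X, row.x_CreA, row.x_i), row.time_h, p, u)
            synth = d[2] + p.k_id * row.x_i
            assert -1e-9 <= synth <= p.k_is_Wt + 1e-9

    def test_nonnegativity(self, default_params):
        u = InputSignal("exp", u0=1.0, decay_rate=0.64)
        traj = simulate(default_params, u, np.linspace(0, 5, 31))
        assert (traj[["X", "x_CreA", "x_i"]].to_numpy() >= 0).all()

    def test_superposition_of_linear_subsystem(self, default_params):
        """X and x_CreA respond linearly to u: the response to u_a + u_b from
        rest equals the sum of the separate responses."""
        p = default_params
        t = np.linspace(0, 2, 11)
        ua = InputSignal("constant", u0=0.6)
        ub = InputSignal("exp", u0=0.4, decay_rate=0.5)
        usum_knots = tuple(
            (float(ti), float(ua(ti) + ub(ti))) for ti in np.linspace(0, 2, 81)
        )
        usum = InputSignal("interp", u0=1.0, knots=usum_knots)
        ta = simulate(p, ua, t)
        tb = simulate(p, ub, t)
        ts = simulate(p, usum, t)
        assert np.allclose(ts["X"], ta["X"] + tb["X"], rtol=1e-4, atol=1e-7)
        assert np.allclose(ts["x_CreA"], ta["x_CreA"] + tb["x_CreA"],
                           rtol=1e-4, atol=1e-7)

    def test_legacy_steady_state(self):
        lp = LegacyParameters(b=2.0, k_d=0.5)
        u = InputSignal("constant", u0=1.5)
        traj = simulate(lp, u, [0.0, 200.0, 400.0], model="legacy")
        assert traj["x_xlnR"].iloc[-1] == pytest.approx(2.0 * 1.5 / 0.5, rel=1e-6)

    def test_bad_grid_rejected(self, default_params):
        u = InputSignal("constant", u0=1.0)
        with pytest.raises(ValueError):
            simulate(default_params, u, [0.5, 1.0])
        with pytest.raises(ValueError):
            simulate(default_params, u, [0.0, 1.0, 1.0])
        with pytest.raises(ValueError):
            simulate(default_params, u, [0.0, 1.0], init=[-1, 0, 0])


class TestParameterTypes:
    def test_serialization_roundtrip(self, default_params):
        p2 = KineticParameters.from_json(default_params.to_json())
        assert p2 == default_params
        assert set(default_params.to_dict()) == {
            "K_on", "K_off", "k1", "k2", "k_is_Wt", "k_is_Mt", "K_i1",
            "K_i2_Wt", "K_i2_Mt", "k_id", "h1", "h2", "x_xlnR_const",
        }

    def test_strain_accessor(self, default_params):
        p = default_params.replace(k_is_Wt=3.0, k_is_Mt=9.0,
                                   K_i2_Wt=20.0, K_i2_Mt=60.0)
        assert p.for_strain("Wt") == (3.0, 20.0)
        assert p.for_strain("Mt") == (9.0, 60.0)
        with pytest.raises(ValueError):
            p.for_strain("wt")

    @pytest.mark.parametrize("bad", [{"K_on": -1.0}, {"k_id": 0.0}, {"h1": 0.5}])
    def test_invalid_parameters_rejected(self, bad):
        with pytest.raises(ValueError):
            KineticParameters(**bad)


class TestInputSignal:
    def test_evaluation_bounds_and_monotonicity(self):
        for u in (
            InputSignal("exp", u0=50.0, decay_rate=0.0549),
            InputSignal("interp", u0=1.0,
                        knots=((0.0, 1.0), (2.0, 0.5), (5.0, 0.05))),
        ):
            t = np.linspace(0, 6, 61)
            vals = u(t)
            assert np.all(vals >= 0) and np.all(vals <= u.u0)
            assert np.all(np.diff(vals) <= 1e-12)
            assert u(0.0) == pytest.approx(u.u0)

    def test_invalid_signals_rejected(self):
        with pytest.raises(ValueError):
            InputSignal("interp", u0=1.0, knots=((0.0, 0.5), (1.0, 0.8)))
        with pytest.raises(ValueError):
            InputSignal("exp", u0=-1.0)
        with pytest.raises(ValueError):
            InputSignal("ramp", u0=1.0)
        u = InputSignal("constant", u0=1.0)
        with pytest.raises(ValueError):
            u(-0.5)
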