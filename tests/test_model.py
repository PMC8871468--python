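"""Unit and property tests for the membrane model and RK4 integrator."""

import numpy as np
import pytest
import sympy as sp
from hypothesis import given
from hypothesis import strategies as st

from neurorqa.model import (
    CoupledConfig,
    DivergenceError,
    EFStimulus,
    MLParams,
    b_timescale,
    coupled_derivatives,
    delta_v,
    delta_v_dot,
    integrate,
    m1_steady,
    m2_steady,
    rk4_step,
    simulate_coupled,
    simulate_single,
    single_neuron_derivatives,
)

P = MLParams()


class TestGatingFunctions:
    def test_midpoints_give_half_activation(self):
        assert m1_steady(P.u1, P) == pytest.approx(0.5)
        assert m2_steady(P.u3, P) == pytest.approx(0.5)
        assert b_timescale(P.u3, P) == pytest.approx(1.0)

    def test_closed_form_values(self):
        # one slope factor away from the midpoint: 0.5*(1 ± tanh 1)
        assert m1_steady(P.u1 + P.u2, P) == pytest.approx(0.5 * (1 + np.tanh(1)))
        assert m2_steady(P.u3 - P.u4, P) == pytest.approx(0.5 * (1 - np.tanh(1)))
        assert b_timescale(P.u3 + 2 * P.u4, P) == pytest.approx(1 / np.cosh(1))

    def test_saturation_limits(self):
        assert m1_steady(1e4, P) == pytest.approx(1.0)
        assert m2_steady(-1e4, P) == pytest.approx(0.0)

    @given(v=st.floats(-200, 200), x=st.floats(0, 100))
    def test_ranges_and_b_symmetry(self, v, x):
        assert 0.0 <= m1_steady(v, P) <= 1.0
        assert 0.0 <= m2_steady(v, P) <= 1.0
        assert 0.0 < b_timescale(v, P) <= 1.0
        assert b_timescale(P.u3 + x, P) == pytest.approx(b_timescale(P.u3 - x, P))


class TestFieldDrive:
    def test_zero_time_gives_direct_voltage(self):
        s = EFStimulus(A=0.37, omega=0.1, VE=-17.63)
        assert delta_v(0.0, s) == pytest.approx(-17.63)

    def test_quarter_period_value(self):
        s = EFStimulus(A=0.1, omega=0.286, VE=-17.63)
        t = (np.pi / 2) / 0.286
        assert delta_v(t, s) == pytest.approx(0.1 / 0.286 - 17.63, abs=1e-10)

    def test_zero_amplitude_is_constant_offset(self):
        s = EFStimulus(A=0.0, omega=0.0, VE=-3.0)  # omega unset is fine at A=0
        t = np.linspace(0, 100, 7)
        assert np.all(delta_v(t, s) == -3.0)
        assert np.all(delta_v_dot(t, s) == 0.0)

    def test_rejects_nonpositive_omega_with_field(self):
        with pytest.raises(ValueError):
            EFStimulus(A=0.1, omega=0.0)


def _sympy_single_rhs(v, w, t, p, s):
    """Independent symbolic evaluation of the forced-neuron equations."""
    vs, ws, ts = sp.symbols("v w t")
    dvv = (sp.Rational(1, 1) * s.A / s.omega) * sp.sin(s.omega * ts) + s.VE
    m1 = (1 + sp.tanh((vs - p.u1) / p.u2)) / 2
    m2 = (1 + sp.tanh((vs - p.u3) / p.u4)) / 2
    b = 1 / sp.cosh((vs - p.u3) / (2 * p.u4))
    dv = (
        p.istim
        - sp.diff(dvv, ts)
        - p.gfast * m1 * (vs + dvv - p.eNa)
        - p.gslow * ws * (vs + dvv - p.eK)
        - p.gleak * (vs + dvv - p.eleak)
    ) / p.c
    dw = p.phi * (m2 - ws) / b
    sub = {vs: v, ws: w, ts: t}
    return float(dv.subs(sub)), float(dw.subs(sub))


class TestDerivatives:
    def test_all_conductances_zero_freezes_voltage(self):
        p = MLParams(gfast=0, gslow=0, gleak=0)
        dv, dw = single_neuron_derivatives([-42.0, 0.3], 5.0, p, EFStimulus(A=0.0))
        assert dv == 0.0

    def test_w_at_steady_state_has_zero_dwdt(self):
        v = -20.0
        dv, dw = single_neuron_derivatives([v, m2_steady(v, P)], 0.0, P, EFStimulus(A=0.0))
        assert dw == pytest.approx(0.0, abs=1e-15)

    def test_matches_independent_symbolic_evaluation(self):
        s = EFStimulus(A=0.1, omega=0.05)
        got = single_neuron_derivatives([-65.0, 0.0], 0.0, P, s)
        want = _sympy_single_rhs(-65.0, 0.0, 0.0, P, s)
        assert got[0] == pytest.approx(want[0], rel=1e-12)
        assert got[1] == pytest.approx(want[1], rel=1e-12)
        # and at a second, nonzero time
        got = single_neuron_derivatives([-50.0, 0.2], 7.3, P, s)
        want = _sympy_single_rhs(-50.0, 0.2, 7.3, P, s)
        assert np.allclose(got, want, rtol=1e-12)

    def test_rejects_non_finite_state(self):
        with pytest.raises(ValueError):
            single_neuron_derivatives([np.nan, 0.0], 0.0, P, EFStimulus(A=0.0))


class TestCoupledDerivatives:
    def _cfg(self, g):
        return CoupledConfig(
            params1=MLParams(u2=18.0, u3=-12.8),
            params2=MLParams(u2=18.1, u3=-10.0),
            g=g,
            stimulus=EFStimulus(A=0.1, omega=0.286),
        )

    def test_uncoupled_equals_two_single_neurons(self):
        cfg = self._cfg(0.0)
        y = [-60.0, 0.1, -55.0, 0.2]
        got = coupled_derivatives(y, 3.0, cfg)
        d1 = single_neuron_derivatives(y[:2], 3.0, cfg.params1, cfg.stimulus)
        d2 = single_neuron_derivatives(y[2:], 3.0, cfg.params2, cfg.stimulus)
        assert np.array_equal(got, np.concatenate([d1, d2]))

    def test_identical_neurons_have_cancelling_gap_term(self):
        cfg = CoupledConfig(g=0.7, stimulus=EFStimulus(A=0.0))
        got = coupled_derivatives([-60.0, 0.1, -60.0, 0.1], 0.0, cfg)
        assert got[0] == got[2] and got[1] == got[3]

    def test_gap_current_matches_brute_force(self):
        cfg = self._cfg(0.04)
        y = [-61.0, 0.15, -48.0, 0.33]
        got = coupled_derivatives(y, 2.0, cfg)
        base = coupled_derivatives(y, 2.0, self._cfg(0.0))
        gap = 0.04 * (y[0] - y[2])
        assert got[0] == pytest.approx(base[0] - gap / cfg.params1.c)
        assert got[2] == pytest.approx(base[2] + gap / cfg.params2.c)
        assert got[1] == base[1] and got[3] == base[3]


class TestIntegrator:
    def test_single_rk4_step_on_linear_ode(self):
        h = 0.3
        y = rk4_step(lambda t, y: y, 0.0, np.array([1.0]), h)
        assert y[0] == pytest.approx(1 + h + h**2 / 2 + h**3 / 6 + h**4 / 24, rel=1e-15)

    def test_empirical_convergence_order(self):
        """Global RK4 error on the neuron itself shrinks ~16x per dt halving."""
        s = EFStimulus(A=0.1, omega=0.1)

        def run(dt):
            traj = simulate_single(P, s, dt=dt, t_total=40.0)
            return traj.v[-1]

        ref = run(0.01 / 16)
        errs = [abs(run(dt) - ref) for dt in (0.08, 0.04, 0.02)]
        orders = np.log2(np.array(errs[:-1]) / np.array(errs[1:]))
        assert np.all(orders >= 3.5)

    def test_divergence_raises_and_names_step(self):
        with pytest.raises(DivergenceError, match=r"step \d+"):
            integrate(lambda t, y: y**2, np.array([1.0]), 0.01, 200)

    def test_transient_removal_and_time_grid(self):
        t, Y = integrate(lambda t, y: -y, np.array([1.0]), 0.1, 50, transient_steps=10)
        assert len(t) == 41
        assert t[0] == pytest.approx(1.0)
        assert np.allclose(np.diff(t), 0.1)

    def test_bit_reproducible(self):
        cfg = CoupledConfig(
            params1=MLParams(u2=18.0, u3=-12.8),
            params2=MLParams(u2=18.1, u3=-10.0),
            g=0.03,
            stimulus=EFStimulus(A=0.1, omega=0.286),
        )
        a = simulate_coupled(cfg, n_steps=2000, transient_steps=500)
        b = simulate_coupled(cfg, n_steps=2000, transient_steps=500)
        assert np.array_equal(a.v1, b.v1) and np.array_equal(a.w2, b.w2)

    def test_identical_coupled_neurons_stay_exactly_synchronous(self):
        cfg = CoupledConfig(g=0.12, stimulus=EFStimulus(A=0.1, omega=0.286),
                            v1_0=-62.0, v2_0=-62.0)
        traj = simulate_coupled(cfg, n_steps=4000, transient_steps=0)
        assert np.array_equal(traj.v1, traj.v2)

    def test_conductance_free_membrane_is_constant(self):
        p = MLParams(gfast=0, gslow=0, gleak=0)
        traj = simulate_single(p, EFStimulus(A=0.0), v0=-65.0, dt=0.01, t_total=20.0)
        assert np.all(traj.v == -65.0)


class TestValidation:
    @pytest.mark.parametrize(
        "kwargs", [dict(u2=0.0), dict(u4=0.0), dict(gfast=-1.0), dict(c=0.0)]
    )
    def test_bad_membrane_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            MLParams(**kwargs)

    def test_negative_coupling_rejected(self):
        with pytest.raises(ValueError):
            CoupledConfig(g=-0.01)
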