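"""Unit and property tests of the two-mass mechanics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from twomass import (
    FoldState,
    ForcePair,
    InstabilityError,
    ModelParams,
    damping_coefficients,
    eom_rhs,
    internal_forces,
    mechanical_energy,
    step,
)
from twomass.mechanics import contact_force_from_depths


class TestDampingCoefficients:
    def test_printed_formula_values(self):
        """eta_i = zeta_i * 2 sqrt(m_i k_i) element-wise, k_ix = Q k_iy."""
        eta1, eta2 = damping_coefficients(ModelParams(Q=1.0))
        assert eta1[1] == pytest.approx(0.2 * math.sqrt(0.17e-3 * 150.0), rel=1e-12)
        assert eta1[1] == pytest.approx(0.03194, rel=1e-3)
        assert eta2[1] == pytest.approx(1.2 * math.sqrt(0.03e-3 * 40.0), rel=1e-12)
        assert eta2[1] == pytest.approx(0.04157, rel=1e-3)

    def test_quadrupling_Q_doubles_vertical_damping_only(self):
        e1a, e2a = damping_coefficients(ModelParams(Q=2.0))
        e1b, e2b = damping_coefficients(ModelParams(Q=8.0))
        assert e1b[0] == pytest.approx(2.0 * e1a[0])
        assert e2b[0] == pytest.approx(2.0 * e2a[0])
        assert e1b[1] == e1a[1] and e2b[1] == e2a[1]

    @pytest.mark.parametrize("bad", [dict(m1=-1e-3), dict(k1y=0.0), dict(Q=-2.0), dict(m2=0.0)])
    def test_rejects_nonpositive_parameters(self, bad):
        with pytest.raises(ValueError):
            ModelParams(**bad)


class TestInternalForces:
    def test_rest_state_gives_zero(self, params, rest_state):
        f = internal_forces(rest_state, params)
        assert np.all(f.F1 == 0) and np.all(f.F2 == 0)

    def test_hand_evaluated_lateral_displacement(self, params):
        """r1y = 1 mm: F1y = -(k1y + kc) * 1e-3, F2y = +kc * 1e-3."""
        s = FoldState(r1=(0.0, 1e-3))
        f = internal_forces(s, params)
        assert f.F1[1] == pytest.approx(-0.170, rel=1e-12)
        assert f.F2[1] == pytest.approx(0.020, rel=1e-12)
        assert f.F1[0] == 0.0 and f.F2[0] == 0.0

    def test_equal_displacement_removes_coupling(self, params):
        s = FoldState(r1=(0.2e-3, 0.5e-3), r2=(0.2e-3, 0.5e-3))
        f = internal_forces(s, params)
        decoupled = internal_forces(s, ModelParams(kc=0.0))
        np.testing.assert_allclose(f.F1, decoupled.F1)
        np.testing.assert_allclose(f.F2, decoupled.F2)

    @given(
        scale=st.floats(min_value=0.1, max_value=5.0),
        rx=st.floats(min_value=-1e-3, max_value=1e-3),
        ry=st.floats(min_value=-1e-3, max_value=1e-3),
        vy=st.floats(min_value=-0.5, max_value=0.5),
    )
    @settings(max_examples=50, deadline=None)
    def test_odd_under_state_negation(self, scale, rx, ry, vy):
        """internal_forces(-state) == -internal_forces(state) (linear regime)."""
        p = ModelParams()
        s = FoldState(r1=(rx, ry), r2=(scale * rx, -ry), v1=(vy, vy), v2=(0.0, -vy))
        neg = FoldState(r1=-s.r1, r2=-s.r2, v1=-s.v1, v2=-s.v2)
        f, g = internal_forces(s, p), internal_forces(neg, p)
        np.testing.assert_allclose(g.F1, -f.F1, atol=1e-15)
        np.testing.assert_allclose(g.F2, -f.F2, atol=1e-15)


class TestContactForce:
    def test_no_penetration_is_zero(self, params):
        f = contact_force_from_depths((0.0, 0.0), params)
        assert np.all(f.F1 == 0) and np.all(f.F2 == 0)

    def test_linear_penalty_law(self, params):
        d = 0.2e-3
        f = contact_force_from_depths((d, 0.0), params)
        assert f.F1[1] == pytest.approx(3.0 * 150.0 * d)
        assert f.F1[0] == 0.0 and np.all(f.F2 == 0)
        f2 = contact_force_from_depths((2 * d, 0.0), params)
        assert f2.F1[1] == pytest.approx(2.0 * f.F1[1])

    def test_scale_is_configurable(self):
        p = ModelParams(contact_stiffness_scale=5.0)
        f = contact_force_from_depths((1e-4, 1e-4), p)
        assert f.F1[1] == pytest.approx(5.0 * 150.0 * 1e-4)
        assert f.F2[1] == pytest.approx(5.0 * 40.0 * 1e-4)


class TestEquationOfMotion:
    def test_zero_everything_gives_zero_derivative(self, params, rest_state):
        d = eom_rhs(rest_state, ForcePair(), params)
        assert np.all(d == 0)

    def test_newton_second_law(self, params, rest_state):
        """F1y = m1 * 1 m/s^2 on the rest state gives a1y = 1."""
        d = eom_rhs(rest_state, ForcePair(F1=(0.0, 1.7e-4)), params)
        np.testing.assert_allclose(d[:4], 0.0)
        assert d[5] == pytest.approx(1.0)

    def test_rejects_nonfinite_force(self, params, rest_state):
        with pytest.raises(ValueError):
            eom_rhs(rest_state, ForcePair(F1=(np.nan, 0.0)), params)

    def test_free_oscillation_frequency(self, zero_forces):
        """Undamped, uncoupled single-mass release oscillates at (1/2pi)sqrt(k1y/m1)."""
        p = ModelParams(zeta1=0.0, zeta2=0.0, kc=1e-12)
        f_exact = math.sqrt(150.0 / 0.17e-3) / (2 * math.pi)
        assert f_exact == pytest.approx(149.5, abs=0.05)
        dt = 1e-5
        s = FoldState(r1=(0.0, 1e-3))
        ys, ts = [], []
        for _ in range(int(3 / f_exact / dt)):
            s = step(s, dt, zero_forces, p)
            ys.append(s.r1[1])
            ts.append(s.t)
        ys = np.array(ys)
        up = np.flatnonzero((ys[:-1] < 0) & (ys[1:] >= 0))
        period = (ts[up[-1]] - ts[up[0]]) / (len(up) - 1)
        assert 1.0 / period == pytest.approx(f_exact, rel=1e-3)


class TestIntegrator:
    def test_zero_forces_zero_velocity_is_stationary(self, params, rest_state, zero_forces):
        s = step(rest_state, 1e-5, zero_forces, params)
        np.testing.assert_array_equal(s.to_vector(), rest_state.to_vector())
        assert s.t == pytest.approx(1e-5)

    def test_energy_conserved_over_one_period(self, undamped, zero_forces):
        s = FoldState(r1=(0.3e-3, 0.5e-3), r2=(-0.2e-3, 0.4e-3))
        e0 = mechanical_energy(s, undamped)
        dt = 2e-6
        for _ in range(int(1 / 153.2 / dt)):
            s = step(s, dt, zero_forces, undamped)
        assert mechanical_energy(s, undamped) == pytest.approx(e0, rel=1e-9)

    def test_fourth_order_convergence(self, zero_forces):
        """Halving dt shrinks the trajectory sup-norm error ~16x."""
        p = ModelParams(zeta1=0.0, zeta2=0.0, kc=1e-12)
        w = math.sqrt(150.0 / 0.17e-3)
        T = 2 * math.pi / w
        errs = []
        for dt in (T / 50, T / 100):
            s = FoldState(r1=(0.0, 1e-3))
            emax = 0.0
            for _ in range(int(round(T / dt))):
                s = step(s, dt, zero_forces, p)
                emax = max(emax, abs(s.r1[1] - 1e-3 * math.cos(w * s.t)))
            errs.append(emax)
        assert 12.0 < errs[0] / errs[1] < 22.0

    def test_damped_energy_monotone_decay(self, params, zero_forces):
        s = FoldState(r1=(0.3e-3, 0.5e-3), r2=(-0.2e-3, 0.4e-3))
        energies = [mechanical_energy(s, params)]
        for _ in range(2000):
            s = step(s, 1e-5, zero_forces, params)
            energies.append(mechanical_energy(s, params))
        diffs = np.diff(energies)
        assert np.all(diffs <= 1e-18)

    def test_axes_decouple_without_contact(self, undamped, zero_forces):
        """x-only initial conditions never produce y motion, and vice versa."""
        s = FoldState(r1=(0.5e-3, 0.0), v2=(0.1, 0.0))
        for _ in range(500):
            s = step(s, 1e-5, zero_forces, undamped)
        assert s.r1[1] == 0.0 and s.r2[1] == 0.0 and s.v1[1] == 0.0
        s = FoldState(r1=(0.0, 0.5e-3), v2=(0.0, 0.1))
        for _ in range(500):
            s = step(s, 1e-5, zero_forces, undamped)
        assert s.r1[0] == 0.0 and s.r2[0] == 0.0 and s.v1[0] == 0.0

    def test_instability_detection(self, params):
        blowup = lambda state: ForcePair(F1=(0.0, 50.0), F2=(0.0, 50.0))
        s = FoldState()
        with pytest.raises(InstabilityError):
            for _ in range(10000):
                s = step(s, 1e-4, blowup, params)

    def test_rejects_nonpositive_dt(self, params, rest_state, zero_forces):
        with pytest.raises(ValueError):
            step(rest_state, 0.0, zero_forces, params)
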