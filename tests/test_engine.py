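"""Integrator correctness, RHS purity, conservation, determinism."""

import math

import numpy as np
import pytest

from cardioloop import _core
from cardioloop.engine import (initial_state, integrate_cash_karp,
                               pleural_pressure, rhs, run_to_steady_state)
from cardioloop.parameters import ScenarioConfig, load_default_parameters


@pytest.fixture(scope="module")
def params():
    return load_default_parameters()


class TestPleuralPressure:
    def test_fixed_mode(self):
        for t in (0.0, 3.3, 100.0):
            assert pleural_pressure(t, "fixed_minus5") == -5.0

    def test_sinusoid_extrema_and_period(self):
        t = np.linspace(0, 7, 7001)
        p = np.array([pleural_pressure(ti, "sinusoid") for ti in t])
        assert p.min() == pytest.approx(-6.0, abs=1e-6)
        assert p.max() == pytest.approx(-2.0, abs=1e-6)
        assert pleural_pressure(1.3, "sinusoid") == pytest.approx(
            pleural_pressure(8.3, "sinusoid"))

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            pleural_pressure(-1.0, "sinusoid")


class TestRHS:
    def test_pure_and_deterministic(self, params):
        y = initial_state(params)
        d1 = rhs(0.5, y, params, phase=0.3, period=1.0)
        d2 = rhs(0.5, y, params, phase=0.3, period=1.0)
        assert (d1 == d2).all()

    def test_total_volume_derivative_zero(self, params):
        y = initial_state(params)
        d = rhs(0.0, y, params, phase=0.2, period=1.0)
        nvol = _core.SCOMP0 + _core.NCOMP
        assert abs(d[:nvol].sum()) < 1e-9

    def test_initial_state_carries_total_blood_volume(self, params):
        y = initial_state(params)
        nvol = _core.SCOMP0 + _core.NCOMP
        assert y[:nvol].sum() == pytest.approx(params.total_blood_volume)


class TestCashKarp:
    def test_exponential_decay(self):
        res = integrate_cash_karp(lambda t, y: -y, [1.0], (0.0, 1.0),
                                  rtol=1e-8, atol=1e-10)
        assert res.y[-1, 0] == pytest.approx(math.exp(-1.0), rel=1e-7)

    def test_harmonic_oscillator_energy(self):
        def f(t, y):
            return np.array([y[1], -y[0]])
        t_end = 2 * math.pi * 100
        res = integrate_cash_karp(f, [1.0, 0.0], (0.0, t_end),
                                  rtol=1e-8, atol=1e-10, dense_dt=1.0)
        energy = res.y[:, 0] ** 2 + res.y[:, 1] ** 2
        assert abs(energy[-1] - 1.0) < 1e-4

    def test_tightening_tolerance_reduces_error(self):
        errs = []
        for rtol in (1e-4, 1e-6, 1e-8):
            res = integrate_cash_karp(lambda t, y: -y, [1.0], (0.0, 2.0),
                                      rtol=rtol, atol=1e-12, dense_dt=0.5)
            errs.append(abs(res.y[-1, 0] - math.exp(-2.0)))
        assert errs[0] > errs[1] > errs[2]

    def test_bad_span_rejected(self):
        with pytest.raises(ValueError):
            integrate_cash_karp(lambda t, y: -y, [1.0], (1.0, 0.0))

    def test_compiled_and_reference_integrators_agree(self, params):
        """The jitted production path matches the generic Cash-Karp driver."""
        p = _core.pack_parameters(params)
        y0 = initial_state(params)
        period, t_end = 1.0, 0.25

        res = integrate_cash_karp(
            lambda t, y: rhs(t, y, p, phase=t, period=period),
            y0, (0.0, t_end), rtol=1e-8, atol=1e-8)

        grid_t = np.arange(1, 251) * 1e-3
        grid_y = np.empty((250, _core.NSTATE))
        grid_out = np.empty((250, _core.NOUT))
        y = y0.copy()
        _core.integrate_segment(0.0, t_end, 0.0, period, y, p, 0.0,
                                1e-8, 1e-8, grid_t, grid_y, grid_out, 0,
                                1e-4, 1e-9)
        assert np.allclose(y, res.y[-1], rtol=1e-6, atol=1e-6)


class TestSteadyState:
    def test_control_converges_with_stable_stroke_volume(self, battery):
        traj, summary, converged = battery("CONTROL")
        assert converged
        v = traj.get("v_lv")
        svs = []
        for t0, t1, _ in traj.analysis_beats():
            m = traj.window(t0, t1)
            svs.append(v[m].max() - v[m].min())
        assert np.ptp(svs) / np.mean(svs) < 0.005

    def test_left_right_outputs_match_in_series(self, battery):
        _, summary, _ = battery("CONTROL")
        assert summary.RVSV == pytest.approx(summary.LVSV, rel=0.01)

    def test_blood_volume_conserved(self, battery, params):
        traj, _, _ = battery("CONTROL")
        nvol = _core.SCOMP0 + _core.NCOMP
        total = traj.states[:, :nvol].sum(axis=1)
        drift = np.abs(total - params.total_blood_volume).max()
        assert drift / params.total_blood_volume < 1e-6

    def test_runs_are_bit_reproducible(self, params):
        sc = ScenarioConfig(dd_type="CONTROL")
        t1, s1, _ = run_to_steady_state(params, sc, max_time=22.0)
        t2, s2, _ = run_to_steady_state(params, sc, max_time=22.0)
        assert (t1.states == t2.states).all()
        assert s1.CO == s2.CO

    def test_attractor_independent_of_initial_perturbation(self, params,
                                                           battery):
        """+-10% initial compartment volumes reach the same steady state."""
        _, ref, _ = battery("CONTROL")
        rng = np.random.default_rng(7)
        fac = rng.uniform(0.9, 1.1, _core.NCOMP)

        # rescale compartments, absorb the residual in the venous reservoir
        import cardioloop.engine as eng
        orig = eng.initial_state

        def skewed(p):
            y = orig(p)
            y[_core.SCOMP0:_core.SCOMP0 + _core.NCOMP] *= fac
            i_sv = _core.SCOMP0 + _core.COMPARTMENT_ORDER.index("SV")
            nvol = _core.SCOMP0 + _core.NCOMP
            y[i_sv] += p.total_blood_volume - y[:nvol].sum()
            return y

        eng.initial_state = skewed
        try:
            _, alt, conv = run_to_steady_state(params,
                                               ScenarioConfig(dd_type="CONTROL"))
        finally:
            eng.initial_state = orig
        assert conv
        for attr in ("CO", "LVEF", "MSAP", "HR"):
            assert getattr(alt, attr) == pytest.approx(getattr(ref, attr),
                                                       rel=0.005)

    def test_refinement_stability(self, params, battery):
        """Halving the tolerance leaves cardiac output within 0.2 %."""
        _, ref, _ = battery("CONTROL")
        _, fine, _ = run_to_steady_state(params, ScenarioConfig(dd_type="CONTROL"),
                                         rtol=5e-7, atol=5e-7)
        assert fine.CO == pytest.approx(ref.CO, rel=0.002)
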