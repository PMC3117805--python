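"""Wall laws, septal fixed point, pericardium, instantaneous elastance."""

import math

import numpy as np
import pytest

from cardioloop import _core
from cardioloop.mechanics import (atrial_pressure, end_diastolic_pressure,
                                  end_systolic_pressure, free_wall_pressure,
                                  instantaneous_elastance, pericardial_pressure,
                                  solve_septal_volume)
from cardioloop.parameters import load_default_parameters


@pytest.fixture(scope="module")
def params():
    return load_default_parameters()


class TestWallLaws:
    def test_espvr_zero_at_dead_volume(self, params):
        w = params.walls["LVF"]
        assert end_systolic_pressure(w.V_d, w) == 0.0

    def test_espvr_linear_arithmetic(self, params):
        w = params.walls["LVF"]  # E_ES=3.5, V_d=1
        assert end_systolic_pressure(100.0, w) == pytest.approx(346.5)
        assert end_systolic_pressure(100.0, w, alpha=1.2) == pytest.approx(
            1.2 * 346.5)

    def test_edpvr_zero_at_rest_volume(self, params):
        w = params.walls["LVF"]
        assert end_diastolic_pressure(w.V_0, w) == 0.0

    def test_edpvr_exponential_value(self, params):
        w = params.walls["LVF"]  # P_0=2, lam=0.025, V_0=1
        expected = 2.0 * (math.exp(0.025 * 99.0) - 1.0)
        assert end_diastolic_pressure(100.0, w) == pytest.approx(expected,
                                                                 rel=1e-12)
        assert expected == pytest.approx(21.76, abs=0.01)

    def test_edpvr_overflow_guarded(self, params):
        w = params.walls["LVF"]
        assert np.isfinite(end_diastolic_pressure(1e6, w))

    def test_stiffening_raises_edpvr_everywhere(self, params):
        import dataclasses
        w = params.walls["LVF"]
        w2 = dataclasses.replace(w, lam=2 * w.lam)
        for v in np.linspace(w.V_0 + 1, 200, 25):
            assert end_diastolic_pressure(v, w2) > end_diastolic_pressure(v, w)

    @pytest.mark.parametrize("e, expected", [(1.0, 50.0), (0.0, 10.0),
                                             (0.5, 30.0)])
    def test_weighted_blend(self, e, expected):
        assert free_wall_pressure(e, 50.0, 10.0) == expected


class TestSeptalSolve:
    def test_symmetric_state_gives_zero_bulge(self, params):
        # construct V_LV, V_RV with equal free-wall pressures at V_SPT = 0
        w_l, w_r = params.walls["LVF"], params.walls["RVF"]
        v_lv = 60.0
        p_target = end_diastolic_pressure(v_lv, w_l)
        # find v_rv with matching diastolic pressure
        v_rv = w_r.V_0 + math.log(p_target / w_r.P_0 + 1.0) / w_r.lam
        res = solve_septal_volume(v_lv, v_rv, 0.0, 0.0, 0.3, params)
        assert res.V_SPT == pytest.approx(0.0, abs=1e-5)
        assert res.P_SPT == pytest.approx(0.0, abs=1e-5)

    def test_chamber_identity_holds(self, params):
        res = solve_septal_volume(120.0, 140.0, 0.2, 0.2, 0.2, params)
        # V_LVF = V_LV - V_SPT and V_RVF = V_RV + V_SPT by construction;
        # verify the returned pressures correspond to those volumes
        w = params.walls["LVF"]
        p_lvf = free_wall_pressure(
            0.2, end_systolic_pressure(120.0 - res.V_SPT, w),
            end_diastolic_pressure(120.0 - res.V_SPT, w))
        assert res.P_LVF == pytest.approx(p_lvf, rel=1e-9)

    def test_agrees_with_bisection_oracle(self, params, rng):
        """Damped fixed point matches an independent bracketing root solve."""
        p = _core.pack_parameters(params)
        lvf = _core.PW0 + 5 * _core.WLVF
        rvf = _core.PW0 + 5 * _core.WRVF
        spt = _core.PW0 + 5 * _core.WSPT

        def residual(v, v_lv, v_rv, e_l, e_r, e_s, alpha):
            p_l = _core.wall_pressure(v_lv - v, e_l, alpha, p[lvf], p[lvf + 1],
                                      p[lvf + 2], p[lvf + 3], p[lvf + 4])
            p_r = _core.wall_pressure(v_rv + v, e_r, alpha, p[rvf], p[rvf + 1],
                                      p[rvf + 2], p[rvf + 3], p[rvf + 4])
            return v - _core.septal_inverse(p_l - p_r, e_s, alpha, p[spt],
                                            p[spt + 1], p[spt + 2],
                                            p[spt + 3], p[spt + 4])

        for _ in range(1000):
            v_lv, v_rv = rng.uniform(30, 160, 2)
            e_l, e_r, e_s = rng.uniform(0, 1, 3)
            alpha = rng.uniform(1.0, 1.3)
            lo, hi = -150.0, 200.0
            assert residual(lo, v_lv, v_rv, e_l, e_r, e_s, alpha) < 0
            assert residual(hi, v_lv, v_rv, e_l, e_r, e_s, alpha) > 0
            for _ in range(60):
                mid = 0.5 * (lo + hi)
                if residual(mid, v_lv, v_rv, e_l, e_r, e_s, alpha) > 0:
                    hi = mid
                else:
                    lo = mid
            oracle = 0.5 * (lo + hi)
            res = solve_septal_volume(v_lv, v_rv, e_l, e_r, e_s, params,
                                      alpha=alpha)
            assert res.V_SPT == pytest.approx(oracle, abs=1e-6)

    def test_warm_start_independent(self, params):
        cold = solve_septal_volume(110.0, 150.0, 0.7, 0.6, 0.8, params,
                                   V_SPT_init=0.0)
        warm = solve_septal_volume(110.0, 150.0, 0.7, 0.6, 0.8, params,
                                   V_SPT_init=40.0)
        assert abs(cold.V_SPT - warm.V_SPT) < 1e-6

    def test_converges_in_about_a_dozen_sweeps(self, params):
        res = solve_septal_volume(120.0, 150.0, 0.1, 0.1, 0.1, params,
                                  V_SPT_init=30.0)
        assert not res.used_fallback
        assert res.iterations <= 40


class TestPericardium:
    def test_rest_volume_returns_pleural(self, params):
        peri = params.pericardium
        assert pericardial_pressure(peri.V_PERI0, -5.0, peri) == pytest.approx(-5.0)

    def test_printed_exponential_value(self, params):
        peri = params.pericardium  # P0=0.5, lam=0.005, V0=200
        expected = 0.5 * (math.e - 1.0) - 5.0
        assert pericardial_pressure(400.0, -5.0, peri) == pytest.approx(
            expected, rel=1e-12)
        assert expected == pytest.approx(-4.141, abs=1e-3)

    def test_monotone_in_heart_volume(self, params):
        peri = params.pericardium
        vols = np.linspace(200, 600, 50)
        pr = [pericardial_pressure(v, -5.0, peri) for v in vols]
        assert (np.diff(pr) > 0).all()


class TestAtria:
    def test_relaxed_at_rest_volume_gives_pericardial(self, params):
        w = params.walls["LA"]
        assert atrial_pressure(w.V_0, 0.0, w, -4.0) == pytest.approx(-4.0)

    def test_full_activation_linear(self, params):
        w = params.walls["LA"]  # E_ES=2.5, V_d=7
        assert atrial_pressure(50.0, 1.0, w, 0.0) == pytest.approx(107.5)

    def test_monotone_in_volume(self, params):
        w = params.walls["RA"]
        vols = np.linspace(10, 80, 30)
        pr = [atrial_pressure(v, 0.4, w, 0.0) for v in vols]
        assert (np.diff(pr) > 0).all()


class TestElastance:
    def test_full_activation_is_es_slope(self, params):
        w = params.walls["LVF"]
        assert instantaneous_elastance(1.0, 77.0, w, alpha=1.1) == pytest.approx(
            1.1 * w.E_ES)

    def test_relaxed_at_rest_volume(self, params):
        w = params.walls["LVF"]
        assert instantaneous_elastance(0.0, w.V_0, w) == pytest.approx(
            w.lam * w.P_0)

    def test_matches_numerical_derivative(self, params, rng):
        for _ in range(200):
            wall = params.walls[rng.choice(["LVF", "RVF", "SPT"])]
            e = float(rng.uniform(0, 1))
            v = float(rng.uniform(20, 150))
            alpha = float(rng.uniform(1.0, 1.3))
            h = 1e-4
            p_hi = free_wall_pressure(e, end_systolic_pressure(v + h, wall, alpha),
                                      end_diastolic_pressure(v + h, wall))
            p_lo = free_wall_pressure(e, end_systolic_pressure(v - h, wall, alpha),
                                      end_diastolic_pressure(v - h, wall))
            fd = (p_hi - p_lo) / (2 * h)
            el = instantaneous_elastance(e, v, wall, alpha)
            assert el == pytest.approx(fd, rel=1e-6)
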