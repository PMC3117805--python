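"""Waveform index extractors verified on closed-form synthetic traces."""

import numpy as np
import pytest

from cardioloop import _core
from cardioloop.engine import SolverStats, Trajectory
from cardioloop.features import (detect_valve_events, inflow_pattern,
                                 make_fixture_trace, pv_loop,
                                 respiratory_variation, summarize,
                                 venous_ds_ratio, ventricular_indices)


@pytest.fixture(scope="module")
def fixture_trace():
    return make_fixture_trace(n_beats=6, period=1.0, E=80.0, A=60.0, DT=0.2,
                              EDV=120.0, ESV=50.0, S_level=60.0, D_level=60.0)


class TestValveEvents:
    def test_rectangular_pulse_edges(self, fixture_trace):
        ev = detect_valve_events(fixture_trace)
        open_t, close_t = ev["aortic"][1]
        t0 = fixture_trace.beat_starts[1]
        assert open_t == pytest.approx(t0 + 0.08, abs=2e-3)
        assert close_t == pytest.approx(t0 + 0.38, abs=2e-3)

    def test_inlet_interval_spans_diastole(self, fixture_trace):
        ev = detect_valve_events(fixture_trace)
        open_t, close_t = ev["mitral"][1]
        t0 = fixture_trace.beat_starts[1]
        assert open_t == pytest.approx(t0 + 0.50, abs=0.01)
        assert close_t > t0 + 0.9

    def test_zero_flow_trace_has_no_events(self, fixture_trace):
        n = fixture_trace.t.size
        empty = Trajectory(
            t=fixture_trace.t, states=np.zeros((n, _core.NSTATE)),
            outputs=np.zeros((n, _core.NOUT)),
            beat_starts=fixture_trace.beat_starts,
            beat_periods=fixture_trace.beat_periods,
            analysis_start=0.0, converged=True, stats=SolverStats())
        with pytest.warns(UserWarning):
            ev = detect_valve_events(empty)
        assert all(x is None for x in ev["mitral"])


class TestVentricularIndices:
    def test_triangle_volume_wave_recovered(self, fixture_trace):
        idx = ventricular_indices(fixture_trace, "left")
        assert idx["EDV"] == pytest.approx(120.0, abs=0.5)
        assert idx["ESV"] == pytest.approx(50.0, abs=0.5)
        assert idx["SV"] == pytest.approx(70.0, abs=1.0)
        assert idx["EF"] == pytest.approx(70.0 / 120.0, abs=0.01)
        assert idx["CO"] == pytest.approx(70.0 * 60 / 1000, abs=0.1)

    def test_ejection_time_from_outlet_valve(self, fixture_trace):
        idx = ventricular_indices(fixture_trace, "left")
        assert idx["ET"] == pytest.approx(0.30, abs=0.005)


class TestInflowPattern:
    def test_two_wave_fixture_recovered(self, fixture_trace):
        pat = inflow_pattern(fixture_trace, "mitral")
        assert pat["E"] == pytest.approx(80.0, rel=0.02)
        assert pat["A"] == pytest.approx(60.0, rel=0.02)
        assert pat["E_A"] == pytest.approx(80.0 / 60.0, abs=0.03)
        # the descending limb is exactly linear with slope E/DT
        assert pat["DT"] == pytest.approx(0.2, rel=0.02)
        assert pat["PFR"] == pytest.approx(80.0, rel=0.02)

    def test_filling_fractions_sum_to_one(self, fixture_trace):
        pat = inflow_pattern(fixture_trace, "mitral")
        assert pat["RFF"] + pat["AFF"] == pytest.approx(1.0, abs=1e-6)
        assert pat["RFF"] > pat["AFF"]

    def test_fused_inflow_reports_absent_a_wave(self):
        # no atrial wave at all: monophasic inflow
        tr = make_fixture_trace(A=0.0, E=80.0)
        pat = inflow_pattern(tr, "mitral")
        assert pat["A"] is None
        assert pat["E_A"] is None

    def test_ivrt_between_outlet_close_and_inlet_open(self, fixture_trace):
        pat = inflow_pattern(fixture_trace, "mitral")
        assert pat["IVRT"] == pytest.approx(0.12, abs=0.01)


class TestVenousDS:
    def test_equal_rectangles_give_unity(self, fixture_trace):
        ds = venous_ds_ratio(fixture_trace, "central")
        assert ds["D_S"] == pytest.approx(1.0, abs=0.12)

    def test_asymmetric_rectangles(self):
        tr = make_fixture_trace(S_level=100.0, D_level=50.0)
        ds = venous_ds_ratio(tr, "central")
        assert ds["D_S"] == pytest.approx(0.5, abs=0.08)

    def test_reversal_volume_negative(self):
        tr = make_fixture_trace(AR_level=40.0)
        ds = venous_ds_ratio(tr, "pulmonary")
        assert ds["AR"] < 0


class TestRespiratoryVariation:
    def test_constant_amplitude_is_zero(self, fixture_trace):
        assert respiratory_variation(fixture_trace, "q_ra") == pytest.approx(
            0.0, abs=1e-9)

    def test_modulated_peaks_arithmetic(self):
        tr = make_fixture_trace(n_beats=4, peak_scale=[1.0, 0.9, 0.8, 0.9])
        assert respiratory_variation(tr, "q_tc") == pytest.approx(20.0,
                                                                  abs=0.5)


class TestPVLoop:
    def test_rectangular_loop_area(self):
        t = np.arange(0, 1.0, 1e-3)
        n = t.size
        states = np.zeros((n, _core.NSTATE))
        outputs = np.zeros((n, _core.NOUT))
        # traverse a rectangle V in [50, 120], P in [10, 100]
        q = n // 4
        v = np.concatenate([np.full(q, 120.0), np.linspace(120, 50, q),
                            np.full(q, 50.0), np.linspace(50, 120, n - 3 * q)])
        p = np.concatenate([np.linspace(10, 100, q), np.full(q, 100.0),
                            np.linspace(100, 10, q), np.full(n - 3 * q, 10.0)])
        states[:, _core.SV_LV] = v
        outputs[:, _core.OUT_INDEX["p_lv"]] = p
        tr = Trajectory(t=t, states=states, outputs=outputs,
                        beat_starts=np.array([0.0]),
                        beat_periods=np.array([0.999]),
                        analysis_start=0.0, converged=True,
                        stats=SolverStats())
        loops = pv_loop(tr, "lv")
        assert loops[0]["area"] == pytest.approx(70.0 * 90.0, rel=0.02)

    def test_simulated_loop_closes(self, battery):
        traj, _, _ = battery("CONTROL")
        loops = pv_loop(traj, "lv")
        lp = loops[1]
        dv = abs(lp["V"][0] - lp["V"][-1])
        assert dv < 0.02 * (lp["V"].max() - lp["V"].min())


def test_summary_schema_complete(fixture_trace):
    s = summarize(fixture_trace)
    d = s.to_dict()
    for key in ("HR", "CO", "LVSV", "LVEF", "mitral", "venous_central"):
        assert key in d


def test_fixture_is_deterministic():
    a = make_fixture_trace()
    b = make_fixture_trace()
    assert (a.outputs == b.outputs).all()
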