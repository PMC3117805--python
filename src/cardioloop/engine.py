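"""Closed-loop simulation engine: beat loop, integration, steady state.

The full model is integrated with an adaptive embedded Cash-Karp
Runge-Kutta 4(5) scheme.  The cardiac cycle is advanced beat by beat: at
each beat onset the next period is sampled from the chronotropic map using
the current filtered efferent signals, and the state is integrated over
exactly one period.  Valve discontinuities are left to the step-size
control (the diode laws are continuous); dense output is produced on a
fixed 1 ms reporting grid by landing step endpoints on grid times.

Steady state is declared when per-beat stroke volume and mean arterial
pressure change by less than the configured tolerance across three
consecutive beats (fixed pleural mode), or when consecutive 7 s
respiratory-cycle means of arterial pressure stabilize (sinusoid mode).
The clinical summary is then computed on the final five beats (or the
final complete respiratory cycle).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _core
from .parameters import (DDType, ModelParameters, PleuralMode, ScenarioConfig,
                         apply_scenario, load_default_parameters)
from .neural import heart_period

__all__ = [
    "Trajectory",
    "SolverStats",
    "pleural_pressure",
    "rhs",
    "initial_state",
    "integrate_cash_karp",
    "run_to_steady_state",
    "run_scenario",
]

REPORT_DT = 1e-3        # s, dense-output grid
DEFAULT_RTOL = 1e-6
DEFAULT_ATOL = 1e-6
HMIN = 1e-9             # s
MIN_SETTLE = 15.0       # s before steady state may be declared
ANALYSIS_BEATS = 5
RESP_PERIOD = 7.0


@dataclass
class SolverStats:
    nsteps: int = 0
    nrejected: int = 0
    nbeats: int = 0
    status: int = 0     # 0 ok, 1 step underflow, 2 negative volume, 3 step budget


@dataclass
class Trajectory:
    """Time-stamped states plus derived pressures/flows on the 1 ms grid."""
    t: np.ndarray                   # (n,)
    states: np.ndarray              # (n, NSTATE)
    outputs: np.ndarray             # (n, NOUT)
    beat_starts: np.ndarray         # beat onset times (s)
    beat_periods: np.ndarray        # sampled periods (s)
    analysis_start: float           # start of the summary window (s)
    converged: bool
    scenario: dict = field(default_factory=dict)
    stats: SolverStats = field(default_factory=SolverStats)
    atrial_offset: float = 0.06
    la_width: float = 0.053
    ra_width: float = 0.092

    _col_cache: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        if self.t.size and np.any(np.diff(self.t) <= 0):
            raise ValueError("trajectory time grid must be strictly increasing")

    @property
    def columns(self) -> tuple[str, ...]:
        return tuple(_core.STATE_NAMES) + tuple(_core.OUTPUT_NAMES)

    def get(self, name: str) -> np.ndarray:
        """Signal column by name (state or derived output)."""
        if name in _core.STATE_NAMES:
            return self.states[:, _core.STATE_NAMES.index(name)]
        if name in _core.OUT_INDEX:
            return self.outputs[:, _core.OUT_INDEX[name]]
        raise KeyError(name)

    def to_frame(self) -> pd.DataFrame:
        data = np.hstack([self.states, self.outputs])
        return pd.DataFrame(data, index=pd.Index(self.t, name="t_s"),
                            columns=list(self.columns))

    def analysis_beats(self) -> list[tuple[float, float, float]]:
        """(onset, end, period) of the beats inside the analysis window."""
        out = []
        t_end = self.t[-1] if self.t.size else 0.0
        for t0, per in zip(self.beat_starts, self.beat_periods):
            if t0 >= self.analysis_start - 1e-9 and t0 + per <= t_end + 1e-6:
                out.append((t0, t0 + per, per))
        return out

    def window(self, t0: float, t1: float) -> np.ndarray:
        """Boolean mask of grid samples in [t0, t1]."""
        return (self.t >= t0 - 1e-12) & (self.t <= t1 + 1e-12)


def pleural_pressure(t: float, mode: PleuralMode | str) -> float:
    """Pleural pressure (mmHg): fixed -5, or a -2..-6 sinusoid of 7 s period."""
    if t < 0:
        raise ValueError("time must be non-negative")
    mode = PleuralMode(mode)
    if mode is PleuralMode.FIXED:
        return -5.0
    return -4.0 - 2.0 * math.cos(2.0 * math.pi * t / RESP_PERIOD)


def rhs(t: float, state: np.ndarray, params: ModelParameters,
        phase: float | None = None, period: float = 1.0) -> np.ndarray:
    """State derivative at (t, state); deterministic and side-effect free.

    ``phase`` is the time since beat onset (defaults to t), ``period`` the
    current beat period.
    """
    p = params if isinstance(params, np.ndarray) else _core.pack_parameters(params)
    dy = np.empty(_core.NSTATE)
    out = np.empty(_core.NOUT)
    _core.eval_model(t, t if phase is None else phase, period,
                     np.asarray(state, dtype=float), p, 0.0, dy, out)
    return dy


def initial_state(params: ModelParameters) -> np.ndarray:
    """Default initial state: control-like volume distribution.

    Compartment volumes are set near the control operating point; the
    systemic venous reservoir absorbs the remainder so the total equals
    ``params.total_blood_volume`` exactly.
    """
    y = np.zeros(_core.NSTATE)
    y[_core.SV_LV], y[_core.SV_RV] = 120.0, 130.0
    y[_core.SV_LA], y[_core.SV_RA] = 60.0, 55.0
    guesses = {
        "AO_p": 101.6, "AO_d": 95.0, "SA": 93.0, "SA_d": 60.0, "SC": 30.0,
        "SVL": 12.0, "SV": 5.5, "VC": 7.4,
        "PA_p": 18.2, "PA_d": 18.0, "PA": 17.2, "PC": 13.5, "PV": 12.9,
    }  # transmural pressures, mmHg
    for i, name in enumerate(_core.COMPARTMENT_ORDER):
        c = params.compartments[name]
        y[_core.SCOMP0 + i] = c.V_un + c.C * guesses[name]
    # systemic veins take up the remaining blood volume
    i_sv = _core.SCOMP0 + _core.COMPARTMENT_ORDER.index("SV")
    vol_wo_sv = y[:_core.SCOMP0 + _core.NCOMP].sum() - y[i_sv]
    y[i_sv] = params.total_blood_volume - vol_wo_sv
    if y[i_sv] <= 0:
        raise ValueError("total blood volume too small for the chosen "
                         "unstressed volumes")
    n = params.neural
    y[_core.SF_HRV] = 0.54
    y[_core.SF_HRS] = 0.28
    y[_core.SF_CON] = n.F_con_ref
    y[_core.SF_VASO] = n.F_vaso_ref
    y[_core.SMSAP] = 96.6
    return y


# ----------------------------------------------------------------------
# generic Cash-Karp integrator (reference implementation)
# ----------------------------------------------------------------------

_CK_A = (
    (0.2,),
    (3.0 / 40.0, 9.0 / 40.0),
    (0.3, -0.9, 1.2),
    (-11.0 / 54.0, 2.5, -70.0 / 27.0, 35.0 / 27.0),
    (1631.0 / 55296.0, 175.0 / 512.0, 575.0 / 13824.0,
     44275.0 / 110592.0, 253.0 / 4096.0),
)
_CK_C = (0.0, 0.2, 0.3, 0.6, 1.0, 0.875)
_CK_B5 = (37.0 / 378.0, 0.0, 250.0 / 621.0, 125.0 / 594.0, 0.0, 512.0 / 1771.0)
_CK_B4 = (2825.0 / 27648.0, 0.0, 18575.0 / 48384.0, 13525.0 / 55296.0,
          277.0 / 14336.0, 0.25)


@dataclass
class IntegrationResult:
    t: np.ndarray
    y: np.ndarray
    nsteps: int
    nrejected: int


def integrate_cash_karp(fun, y0, t_span, rtol: float = DEFAULT_RTOL,
                        atol: float = DEFAULT_ATOL,
                        dense_dt: float = REPORT_DT,
                        h0: float = 1e-4, hmin: float = HMIN,
                        max_steps: int = 10_000_000) -> IntegrationResult:
    """Adaptive embedded Cash-Karp RK4(5) for a generic ODE ``dy/dt = fun(t, y)``.

    Dense output is reported every ``dense_dt`` by forcing step endpoints
    onto the grid.  Raises ``RuntimeError`` on step-size underflow.
    """
    t0, t1 = map(float, t_span)
    if t1 <= t0:
        raise ValueError("t_span must be increasing")
    if rtol <= 0 or atol <= 0:
        raise ValueError("tolerances must be positive")
    y = np.asarray(y0, dtype=float).copy()
    ts = [t0]
    ys = [y.copy()]
    t = t0
    h = min(h0, t1 - t0)
    next_report = t0 + dense_dt
    nsteps = nrej = 0
    k = [None] * 6
    while t < t1 - 1e-13:
        if nsteps + nrej > max_steps:
            raise RuntimeError("integrator exceeded the step budget")
        t_target = min(t1, next_report)
        if t_target - t < 1e-12:
            # grid time reached up to roundoff: snap and report
            t = t_target
            if abs(t - next_report) < 1e-12:
                ts.append(t)
                ys.append(y.copy())
                next_report += dense_dt
            continue
        h = min(h, t_target - t)
        if h < hmin:
            raise RuntimeError(f"step size underflow at t={t:.6g}")
        k[0] = np.asarray(fun(t, y), dtype=float)
        for s in range(1, 6):
            ytmp = y + h * sum(a * k[j] for j, a in enumerate(_CK_A[s - 1]))
            k[s] = np.asarray(fun(t + _CK_C[s] * h, ytmp), dtype=float)
        y5 = y + h * sum(b * k[s] for s, b in enumerate(_CK_B5) if b)
        y4 = y + h * sum(b * k[s] for s, b in enumerate(_CK_B4) if b)
        scale = atol + rtol * np.maximum(np.abs(y), np.abs(y5))
        err = float(np.max(np.abs(y5 - y4) / scale))
        if err <= 1.0:
            nsteps += 1
            t = t + h
            y = y5
            if abs(t - next_report) < 1e-12:
                ts.append(t)
                ys.append(y.copy())
                next_report += dense_dt
            fac = 5.0 if err < 1e-10 else min(5.0, 0.9 * err ** -0.2)
        else:
            nrej += 1
            fac = max(0.1, 0.9 * err ** -0.2)
        h = max(hmin, h * fac)
    if ts[-1] < t1 - 1e-9:
        ts.append(t)
        ys.append(y.copy())
    return IntegrationResult(t=np.array(ts), y=np.array(ys),
                             nsteps=nsteps, nrejected=nrej)


# ----------------------------------------------------------------------
# beat loop and steady-state runner
# ----------------------------------------------------------------------

def _sample_period(y, params, clamp_hr_period):
    if clamp_hr_period is not None:
        return clamp_hr_period
    return heart_period(y[_core.SF_HRV], y[_core.SF_HRS], params.neural)


def run_to_steady_state(params: ModelParameters,
                        scenario: ScenarioConfig | None = None,
                        max_time: float | None = None,
                        rtol: float = DEFAULT_RTOL,
                        atol: float = DEFAULT_ATOL,
                        already_applied: bool = False):
    """Integrate a scenario to periodic steady state.

    Returns ``(Trajectory, HemodynamicSummary, converged)``.  If the run
    reaches ``max_time`` without satisfying the steady-state criterion, the
    summary is computed on the final window anyway and ``converged`` is
    False.
    """
    from .features import summarize

    scenario = scenario or ScenarioConfig()
    run_params = params if already_applied else apply_scenario(params, scenario)
    duration = float(max_time if max_time is not None else scenario.duration)
    sinusoid = scenario.pleural_mode is PleuralMode.SINUSOID
    if sinusoid:
        # whole respiratory cycles only
        duration = RESP_PERIOD * max(4, math.floor(duration / RESP_PERIOD))

    p = _core.pack_parameters(run_params)
    clamp = scenario.clamp_neural
    if clamp in ("con", "all"):
        p[_core.PCLAMP_CON] = 1.0
    clamp_hr_period = None
    if clamp in ("hr", "all"):
        clamp_hr_period = heart_period(0.54, 0.28, run_params.neural)

    y = initial_state(run_params)
    grid_t = np.arange(1, int(round(duration / REPORT_DT)) + 1) * REPORT_DT
    ngrid = grid_t.size
    grid_y = np.empty((ngrid + 1, _core.NSTATE))
    grid_out = np.empty((ngrid + 1, _core.NOUT))

    # row 0 holds the initial condition
    dy0 = np.empty(_core.NSTATE)
    out0 = np.empty(_core.NOUT)
    v_spt = _core.eval_model(0.0, 0.0, 1.0, y, p, 0.0, dy0, out0)
    grid_y[0] = y
    grid_out[0] = out0

    stats = SolverStats()
    t = 0.0
    h = 1e-4
    fill = 0
    beat_starts: list[float] = []
    beat_periods: list[float] = []
    beat_fill: list[int] = []       # grid fill index at each beat end
    sv_hist: list[float] = []
    msap_hist: list[float] = []
    tol = scenario.steady_state_tol

    converged = False
    analysis_start = None
    beats_after = 0

    i_vlv = _core.SV_LV
    i_paop = _core.OUT_INDEX["p_ao_p"]

    while t < duration - 1e-9:
        period = _sample_period(y, run_params, clamp_hr_period)
        t_end = min(t + period, duration)
        beat_starts.append(t)
        beat_periods.append(period)
        fill_before = fill
        t, h, v_spt, fill, ns, nr, status = _core.integrate_segment(
            t, t_end, beat_starts[-1], period, y, p, v_spt, rtol, atol,
            grid_t, grid_y[1:], grid_out[1:], fill, h, HMIN)
        stats.nsteps += ns
        stats.nrejected += nr
        stats.nbeats += 1
        if status != 0:
            stats.status = status
            break
        beat_fill.append(fill)

        if fill > fill_before:
            seg_v = grid_y[1 + fill_before:1 + fill, i_vlv]
            seg_p = grid_out[1 + fill_before:1 + fill, i_paop]
            sv_hist.append(float(seg_v.max() - seg_v.min()))
            msap_hist.append(float(seg_p.mean()))

        if analysis_start is not None:
            beats_after += 1
            if beats_after >= ANALYSIS_BEATS:
                break
            continue

        if sinusoid:
            continue  # run to the end of the last full respiratory cycle

        if (t >= MIN_SETTLE and len(sv_hist) >= 4
                and _stable(sv_hist, tol) and _stable(msap_hist, tol)):
            converged = True
            analysis_start = t

    n_rows = fill + 1
    tgrid = np.concatenate([[0.0], grid_t[:fill]])
    traj_t_end = tgrid[-1]

    if sinusoid:
        ncyc = math.floor(traj_t_end / RESP_PERIOD + 1e-9)
        analysis_start = max(0.0, RESP_PERIOD * (ncyc - 1))
        if len(msap_hist) >= 2:
            cyc_means = _cycle_means(tgrid, grid_out[:n_rows, i_paop],
                                     RESP_PERIOD)
            converged = (len(cyc_means) >= 3
                         and abs(cyc_means[-1] - cyc_means[-2])
                         <= tol * abs(cyc_means[-2]))
    elif analysis_start is None:
        # never converged: analyze the last ANALYSIS_BEATS complete beats
        if len(beat_starts) > ANALYSIS_BEATS:
            analysis_start = beat_starts[-ANALYSIS_BEATS]
        else:
            analysis_start = 0.0

    traj = Trajectory(
        t=tgrid,
        states=grid_y[:n_rows],
        outputs=grid_out[:n_rows],
        beat_starts=np.array(beat_starts),
        beat_periods=np.array(beat_periods),
        analysis_start=float(analysis_start),
        converged=converged,
        scenario={
            "dd_type": scenario.dd_type.value,
            "contractility": scenario.contractility,
            "pleural_mode": scenario.pleural_mode.value,
            "clamp_neural": scenario.clamp_neural,
            "rtol": rtol, "atol": atol,
        },
        stats=stats,
        atrial_offset=run_params.atrial_offset,
        la_width=run_params.la_width,
        ra_width=run_params.ra_width,
    )
    summary = summarize(traj)
    return traj, summary, converged


def _stable(hist, tol, k=3):
    ref = hist[-1]
    if ref == 0:
        return False
    return all(abs(hist[-i - 1] - ref) <= tol * abs(ref) for i in range(1, k))


def _cycle_means(t, sig, period):
    means = []
    ncyc = int(math.floor((t[-1] + 1e-9) / period))
    for c in range(ncyc):
        m = (t >= c * period) & (t < (c + 1) * period)
        if m.any():
            means.append(float(sig[m].mean()))
    return means


def run_scenario(dd_type: str | DDType = "CONTROL",
                 contractility: str = "normal",
                 pleural_mode: str | PleuralMode = PleuralMode.FIXED,
                 clamp_neural: str | None = None,
                 params: ModelParameters | None = None,
                 **kwargs):
    """Convenience wrapper: default parameters + one scenario to steady state."""
    base = params or load_default_parameters()
    sc = ScenarioConfig(dd_type=DDType(dd_type), contractility=contractility,
                        pleural_mode=PleuralMode(pleural_mode),
                        clamp_neural=clamp_neural)
    return run_to_steady_state(base, sc, **kwargs)
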