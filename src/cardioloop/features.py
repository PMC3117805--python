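"""Clinical waveform indices extracted from simulated (or synthetic) traces.

All extractors are pure functions of a :class:`~cardioloop.engine.Trajectory`
and operate on the beats of its analysis window.  Conventions:

* Valve events are threshold crossings of the valve flow at 0.1 ml/s;
  open intervals separated by less than 0.25 s are merged (the inlet valves
  stay open through diastasis even when flow is nearly zero).
* The E wave is the first inflow peak after inlet-valve opening, the A wave
  the last peak before closure; the window boundary between them is the
  inter-wave flow minimum.  The deceleration time DT extrapolates a
  least-squares line on the 70 % -> 30 %-of-peak descending limb of the E
  wave to zero flow (standard echocardiographic practice).
* Venous inflow is split into systolic (S: inlet-valve closure to opening),
  diastolic (D: opening to atrial activation onset) and atrial-reversal
  (AR: atrial onset to next closure) windows; D/S is the ratio of the
  signed flow volumes.
* "Central venous" inflow is the flow entering the right atrium;
  "pulmonary venous" inflow is the flow entering the left atrium.
* Percent respiratory variation of a signal is 100*(max-min)/max of its
  per-beat peaks across one respiratory cycle.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.signal import find_peaks

from . import _core
from .engine import Trajectory, SolverStats

__all__ = [
    "HemodynamicSummary",
    "detect_valve_events",
    "ventricular_indices",
    "inflow_pattern",
    "venous_ds_ratio",
    "respiratory_variation",
    "pv_loop",
    "make_fixture_trace",
    "summarize",
]

FLOW_THRESHOLD = 0.1     # ml/s
MERGE_GAP = 0.25         # s, gaps shorter than this stay "open"

VALVE_FLOW = {"mitral": "q_m", "tricuspid": "q_tc",
              "aortic": "q_ao_p", "pulmonic": "q_pa_p"}
INLET_FOR_SIDE = {"left": "mitral", "right": "tricuspid"}
OUTLET_FOR_SIDE = {"left": "aortic", "right": "pulmonic"}
VENOUS_SIGNAL = {"central": "q_ra", "pulmonary": "q_la"}
VENOUS_SIDE = {"central": "right", "pulmonary": "left"}

RESP_SIGNALS = ("q_tc", "q_m", "v_rv", "v_pa_p", "v_pa", "v_pa_d",
                "v_pc", "v_pv", "v_lv")


# ----------------------------------------------------------------------
# valve events
# ----------------------------------------------------------------------

def _open_intervals(t: np.ndarray, flow: np.ndarray,
                    threshold: float = FLOW_THRESHOLD,
                    merge_gap: float = MERGE_GAP) -> list[tuple[float, float]]:
    """Contiguous intervals where flow exceeds the threshold, gap-merged."""
    above = flow > threshold
    if not above.any():
        return []
    edges = np.diff(above.astype(np.int8))
    starts = list(np.nonzero(edges == 1)[0] + 1)
    ends = list(np.nonzero(edges == -1)[0] + 1)
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        ends.append(len(t) - 1)
    raw = [(t[s], t[e]) for s, e in zip(starts, ends)]
    merged = [list(raw[0])]
    for a, b in raw[1:]:
        if a - merged[-1][1] < merge_gap:
            merged[-1][1] = b
        else:
            merged.append([a, b])
    return [tuple(iv) for iv in merged]


def detect_valve_events(traj: Trajectory, threshold: float = FLOW_THRESHOLD
                        ) -> dict[str, list[tuple[float, float]]]:
    """Open/close times per valve per beat of the analysis window.

    Each entry is a list aligned with ``traj.analysis_beats()``; a beat
    without a detected open interval carries ``None`` (with a warning).
    For inlet valves the interval assigned to a beat is the diastole that
    *starts* in that beat (it ends early in the following beat).
    """
    beats = traj.analysis_beats()
    if not beats:
        raise ValueError("trajectory does not cover a complete beat")
    events: dict[str, list] = {}
    for valve, col in VALVE_FLOW.items():
        flow = traj.get(col)
        intervals = _open_intervals(traj.t, flow, threshold)
        per_beat = []
        for (t0, t1, _per) in beats:
            hit = None
            for a, b in intervals:
                if t0 <= a < t1:
                    hit = (a, b)
                    break
            if hit is None:
                warnings.warn(f"{valve}: no open interval in beat at "
                              f"t={t0:.3f}s; beat excluded")
            per_beat.append(hit)
        events[valve] = per_beat
    return events


# ----------------------------------------------------------------------
# ventricular indices
# ----------------------------------------------------------------------

def ventricular_indices(traj: Trajectory, side: str = "left",
                        events: dict | None = None) -> dict[str, float]:
    """SV, EF, EDV, ESV, CO, ejection time and EDP for one ventricle."""
    side = side.lower()
    vcol = "v_lv" if side == "left" else "v_rv"
    pcol = "p_lv" if side == "left" else "p_rv"
    beats = traj.analysis_beats()
    if not beats:
        raise ValueError("trajectory does not cover a complete beat")
    events = events or detect_valve_events(traj)
    inlet = events[INLET_FOR_SIDE[side]]
    outlet = events[OUTLET_FOR_SIDE[side]]

    v = traj.get(vcol)
    pr = traj.get(pcol)
    edv, esv, per_l, et, edp = [], [], [], [], []
    for k, (t0, t1, per) in enumerate(beats):
        m = traj.window(t0, t1)
        if not m.any():
            continue
        edv.append(float(v[m].max()))
        esv.append(float(v[m].min()))
        per_l.append(per)
        if outlet[k] is not None:
            et.append(outlet[k][1] - outlet[k][0])
        # end-diastolic pressure: the post-A-wave pressure (Z point), taken
        # as the maximum over the last 150 ms of diastole before beat onset;
        # sampling strictly before onset excludes active tension of the new
        # beat (the activation clock resets at t0)
        mw = (traj.t >= t0 - 0.15) & (traj.t < t0)
        if mw.any():
            edp.append(float(pr[mw].max()))
    edv_m, esv_m = float(np.mean(edv)), float(np.mean(esv))
    sv = edv_m - esv_m
    hr = 60.0 / float(np.mean(per_l))
    return {
        "EDV": edv_m, "ESV": esv_m, "SV": sv, "EF": sv / edv_m,
        "HR": hr, "CO": sv * hr / 1000.0,
        "ET": float(np.mean(et)) if et else float("nan"),
        "EDP": float(np.mean(edp)) if edp else float("nan"),
    }


# ----------------------------------------------------------------------
# transvalvular inflow pattern
# ----------------------------------------------------------------------

def _atrial_onset(traj: Trajectory, t0: float, period: float,
                  side: str = "left") -> float:
    """Approximate onset of atrial contraction within the beat at t0."""
    width = traj.la_width if side == "left" else traj.ra_width
    return t0 + period - traj.atrial_offset - 2.0 * width


def _descending_limb_dt(tt, ff, peak_idx, end_idx):
    """DT by least-squares extrapolation of the 70-30 % descending segment."""
    fpk = ff[peak_idx]
    lo, hi = 0.3 * fpk, 0.7 * fpk
    seg_t, seg_f = [], []
    for i in range(peak_idx, end_idx + 1):
        if ff[i] <= hi:
            seg_t.append(tt[i])
            seg_f.append(ff[i])
        if ff[i] < lo and seg_t:
            break
    if len(seg_t) < 3:
        return float("nan")
    b, a = np.polyfit(seg_t, seg_f, 1)
    if b >= 0:
        return float("nan")
    t_zero = -a / b
    return t_zero - tt[peak_idx]


def inflow_pattern(traj: Trajectory, valve: str = "mitral",
                   events: dict | None = None) -> dict[str, float | None]:
    """E, A, E/A, DT, IVRT, PFR, RFF, AFF of an AV-valve inflow.

    Fused (monophasic) inflow reports ``A`` and ``E_A`` as ``None``; the
    RFF/AFF boundary then falls back to the atrial activation onset.
    Times in the result are seconds.
    """
    valve = valve.lower()
    if valve not in ("mitral", "tricuspid"):
        raise ValueError("valve must be 'mitral' or 'tricuspid'")
    side = "left" if valve == "mitral" else "right"
    flow = traj.get(VALVE_FLOW[valve])
    beats = traj.analysis_beats()
    events = events or detect_valve_events(traj)
    inlet = events[valve]
    outlet = events[OUTLET_FOR_SIDE[side]]

    E_l, A_l, dt_l, ivrt_l, pfr_l, rff_l, aff_l = [], [], [], [], [], [], []
    fused_any = False
    for k, (t0, t1, per) in enumerate(beats):
        if inlet[k] is None:
            continue
        to, tc = inlet[k]
        m = traj.window(to, tc)
        tt, ff = traj.t[m], flow[m]
        if len(tt) < 5:
            continue
        fmax = ff.max()
        pk, _ = find_peaks(ff, height=0.10 * fmax, prominence=0.02 * fmax)
        if len(pk) == 0:
            pk = np.array([int(np.argmax(ff))])
        e_i = int(pk[0])
        a_i = int(pk[-1])
        E = float(ff[e_i])
        fused = a_i == e_i
        if not fused:
            valley = e_i + int(np.argmin(ff[e_i:a_i + 1]))
            # require a genuine trough between the waves
            if ff[valley] > 0.98 * min(E, ff[a_i]):
                fused = True
        if fused:
            fused_any = True
            A = None
            boundary_t = _atrial_onset(traj, t0, per, side)
            b_i = int(np.clip(np.searchsorted(tt, boundary_t), 1, len(tt) - 1))
            dt_end = len(tt) - 1
        else:
            A = float(ff[a_i])
            b_i = valley
            dt_end = valley
        E_l.append(E)
        if A is not None:
            A_l.append(A)
        dt = _descending_limb_dt(tt, ff, e_i, dt_end)
        if np.isfinite(dt):
            dt_l.append(dt)
        if outlet[k] is not None:
            ivrt_l.append(to - outlet[k][1])
        pfr_l.append(float(ff[:b_i + 1].max()))
        vol_e = float(np.trapezoid(ff[:b_i + 1], tt[:b_i + 1]))
        vol_a = float(np.trapezoid(ff[b_i:], tt[b_i:]))
        tot = vol_e + vol_a
        if tot > 0:
            rff_l.append(vol_e / tot)
            aff_l.append(vol_a / tot)

    if not E_l:
        raise ValueError("no usable diastole found in the analysis window")
    E = float(np.mean(E_l))
    A = float(np.mean(A_l)) if A_l and not fused_any else None
    return {
        "E": E,
        "A": A,
        "E_A": (E / A) if A else None,
        "DT": float(np.mean(dt_l)) if dt_l else float("nan"),
        "IVRT": float(np.mean(ivrt_l)) if ivrt_l else float("nan"),
        "PFR": float(np.mean(pfr_l)),
        "RFF": float(np.mean(rff_l)) if rff_l else float("nan"),
        "AFF": float(np.mean(aff_l)) if aff_l else float("nan"),
    }


# ----------------------------------------------------------------------
# venous inflow S/D/AR decomposition
# ----------------------------------------------------------------------

def venous_ds_ratio(traj: Trajectory, side: str = "central",
                    events: dict | None = None) -> dict[str, float]:
    """S, D and AR flow volumes (ml) and the D/S ratio of a venous inflow."""
    side = side.lower()
    if side not in VENOUS_SIGNAL:
        raise ValueError("side must be 'central' or 'pulmonary'")
    flow = traj.get(VENOUS_SIGNAL[side])
    inlet_valve = INLET_FOR_SIDE[VENOUS_SIDE[side]]
    beats = traj.analysis_beats()
    events = events or detect_valve_events(traj)
    inlet = events[inlet_valve]

    min_len = 3 * (traj.t[1] - traj.t[0]) if traj.t.size > 1 else 0.0
    s_l, d_l, ar_l = [], [], []
    for k, (t0, t1, per) in enumerate(beats[:-1]):
        if inlet[k] is None or inlet[k + 1] is None:
            continue
        to, tc_here = inlet[k]
        tc_prev_end = tc_here  # diastole of this beat ends in beat k+1
        t_sys0 = t0 if k == 0 or inlet[k - 1] is None else inlet[k - 1][1]
        t_atr = _atrial_onset(traj, t0, per, VENOUS_SIDE[side])
        windows = {"S": (t_sys0, to), "D": (to, t_atr),
                   "AR": (t_atr, tc_prev_end)}
        if any(b - a < min_len for a, b in windows.values()):
            warnings.warn(f"venous windows too short in beat at t={t0:.3f}s; "
                          "beat excluded")
            continue
        vols = {}
        for name, (a, b) in windows.items():
            m = traj.window(a, b)
            vols[name] = float(np.trapezoid(flow[m], traj.t[m]))
        s_l.append(vols["S"])
        d_l.append(vols["D"])
        ar_l.append(vols["AR"])
    if not s_l:
        raise ValueError("no usable beat with valve events for venous windows")
    S, D, AR = map(lambda v: float(np.mean(v)), (s_l, d_l, ar_l))
    return {"S": S, "D": D, "AR": AR, "D_S": D / S}


# ----------------------------------------------------------------------
# respiratory variation, P-V loops
# ----------------------------------------------------------------------

def respiratory_variation(traj: Trajectory, signal: str) -> float:
    """Percent variation of per-beat peaks across the analysis window.

    For the transvalvular inflows (``q_m``, ``q_tc``) the per-beat peak is
    the early-filling (E-wave) peak, taken while atrial activation is
    quiescent — the standard echocardiographic convention for respiratory
    inflow variation; the atrium-driven A wave is insensitive to breathing
    and would mask the modulation.  Other signals use the whole-beat peak.
    """
    sig = traj.get(signal)
    beats = traj.analysis_beats()
    if len(beats) < 4:
        warnings.warn("fewer than 4 beats in the respiratory window")
    e_atr = None
    if signal in ("q_m", "q_tc"):
        e_atr = traj.get("e_la" if signal == "q_m" else "e_ra")
    peaks = []
    for t0, t1, _ in beats:
        m = traj.window(t0, t1)
        if e_atr is not None:
            m = m & (e_atr < 0.02)
        if m.any():
            peaks.append(float(sig[m].max()))
    if not peaks:
        raise ValueError("no beats in the analysis window")
    mx, mn = max(peaks), min(peaks)
    if mx == 0:
        return 0.0
    return 100.0 * (mx - mn) / mx


def pv_loop(traj: Trajectory, chamber: str = "lv",
            beats: list | None = None) -> list[dict]:
    """Ordered (V, P) loop points and shoelace area per analysis beat."""
    chamber = chamber.lower()
    v = traj.get(f"v_{chamber}")
    p = traj.get(f"p_{chamber}")
    result = []
    for t0, t1, _ in (beats or traj.analysis_beats()):
        m = traj.window(t0, t1)
        vv, pp = v[m], p[m]
        area = 0.5 * abs(float(np.dot(vv, np.roll(pp, -1))
                               - np.dot(pp, np.roll(vv, -1))))
        result.append({"V": vv, "P": pp, "area": area})
    return result


# ----------------------------------------------------------------------
# synthetic fixture traces
# ----------------------------------------------------------------------

def make_fixture_trace(n_beats: int = 6, period: float = 1.0,
                       E: float = 80.0, A: float = 60.0, DT: float = 0.2,
                       EDV: float = 120.0, ESV: float = 50.0,
                       S_level: float = 60.0, D_level: float = 60.0,
                       AR_level: float = 0.0,
                       ET: float = 0.3,
                       peak_scale: list[float] | None = None,
                       dt: float = 1e-3) -> Trajectory:
    """Synthetic trajectory with known E/A, DT, EF and S/D structure.

    Builds closed-form inflow (triangular E wave whose descending limb has
    slope E/DT, triangular A wave), outlet-valve rectangles, a triangular
    chamber-volume wave between EDV and ESV, and rectangular venous S/D/AR
    waves, so every extractor can be verified against the constructed
    values.  ``peak_scale`` multiplies the inflow peaks per beat (emulating
    respiratory modulation).  Deterministic.
    """
    atrial_width, atrial_offset = 0.05, 0.10
    n = int(round(n_beats * period / dt)) + 1
    t = np.arange(n) * dt
    states = np.zeros((n, _core.NSTATE))
    outputs = np.zeros((n, _core.NOUT))

    q_in = np.zeros(n)
    q_out = np.zeros(n)
    vol = np.zeros(n)
    q_ven = np.zeros(n)

    sys0, sys1 = 0.08, 0.08 + ET          # outlet valve open window
    dia0 = sys1 + 0.12                     # inlet valve opens
    t_atr = period - atrial_offset - 2.0 * atrial_width
    dia1 = period + 0.05                   # inlet valve closes next beat
    scale = peak_scale or [1.0] * n_beats

    for b in range(n_beats + 1):
        # the extra iteration assigns the final grid sample (tb == 0)
        tb = t - b * period
        in_beat = (tb >= 0) & (tb < period)
        s = scale[b % len(scale)]
        # E wave: linear rise over 60 ms, linear fall with slope E/DT
        e_pk = dia0 + 0.06
        rise = in_beat & (tb >= dia0) & (tb < e_pk)
        q_in[rise] = s * E * (tb[rise] - dia0) / 0.06
        fall = in_beat & (tb >= e_pk) & (tb < e_pk + DT)
        q_in[fall] = s * E * (1.0 - (tb[fall] - e_pk) / DT)
        q_in[fall & (q_in < 0)] = 0.0
        # A wave: symmetric triangle of half-width 50 ms at the atrial kick
        a_c = t_atr + 2.0 * atrial_width
        aw = 0.05
        tri = in_beat & (np.abs(tb - a_c) < aw)
        q_a = s * A * (1.0 - np.abs(tb[tri] - a_c) / aw)
        q_in[tri] = np.maximum(q_in[tri], q_a)
        # outlet valve rectangle
        q_out[in_beat & (tb >= sys0) & (tb < sys1)] = 300.0
        # volume triangle: EDV at onset, ESV at end-systole, back to EDV
        down = in_beat & (tb < sys1)
        vol[down] = EDV - (EDV - ESV) * tb[down] / sys1
        up = in_beat & (tb >= sys1)
        vol[up] = ESV + (EDV - ESV) * (tb[up] - sys1) / (period - sys1)
        # venous rectangles of equal duration (0.3 s): S late in systole,
        # D in diastole before the atrial kick, AR during the kick
        q_ven[in_beat & (tb >= dia0 - 0.3) & (tb < dia0)] = S_level
        q_ven[in_beat & (tb >= t_atr - 0.3) & (tb < t_atr)] = D_level
        q_ven[in_beat & (tb >= t_atr)] = -AR_level

    for col, sig in (("q_m", q_in), ("q_tc", q_in), ("q_ao_p", q_out),
                     ("q_pa_p", q_out), ("q_ra", q_ven), ("q_la", q_ven)):
        outputs[:, _core.OUT_INDEX[col]] = sig
    states[:, _core.SV_LV] = vol
    states[:, _core.SV_RV] = vol
    outputs[:, _core.OUT_INDEX["p_lv"]] = 5.0 + 0.1 * vol
    outputs[:, _core.OUT_INDEX["p_rv"]] = 2.0 + 0.05 * vol

    return Trajectory(
        t=t, states=states, outputs=outputs,
        beat_starts=np.arange(n_beats) * period,
        beat_periods=np.full(n_beats, period),
        analysis_start=0.0, converged=True,
        scenario={"fixture": True}, stats=SolverStats(),
        atrial_offset=atrial_offset,
        la_width=atrial_width, ra_width=atrial_width,
    )


# ----------------------------------------------------------------------
# summary
# ----------------------------------------------------------------------

@dataclass
class HemodynamicSummary:
    """Per-scenario clinical indices averaged over the analysis window."""
    HR: float
    CO: float
    LVSV: float
    RVSV: float
    LVEF: float
    RVEF: float
    LVEDP: float
    MSAP: float
    CVP: float
    LVET: float
    RVET: float
    LV_EDV: float
    LV_ESV: float
    RV_EDV: float
    RV_ESV: float
    mitral: dict = field(default_factory=dict)
    tricuspid: dict = field(default_factory=dict)
    venous_central: dict = field(default_factory=dict)
    venous_pulmonary: dict = field(default_factory=dict)
    pulmonary_means: dict = field(default_factory=dict)
    neural_means: dict = field(default_factory=dict)
    respiratory_variation: dict = field(default_factory=dict)
    scenario: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)


def _mean_over(traj, col, t0, t1):
    m = traj.window(t0, t1)
    return float(traj.get(col)[m].mean())


def summarize(traj: Trajectory) -> HemodynamicSummary:
    """Compute the full clinical index set on the analysis window."""
    beats = traj.analysis_beats()
    if not beats:
        raise ValueError("analysis window contains no complete beat")
    t0, t1 = beats[0][0], beats[-1][1]
    events = detect_valve_events(traj)
    lv = ventricular_indices(traj, "left", events)
    rv = ventricular_indices(traj, "right", events)

    def _try(fn, *a, **kw):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                return fn(*a, **kw)
        except (ValueError, KeyError):
            return {}

    mitral = _try(inflow_pattern, traj, "mitral", events)
    tricuspid = _try(inflow_pattern, traj, "tricuspid", events)
    ds_c = _try(venous_ds_ratio, traj, "central", events)
    ds_p = _try(venous_ds_ratio, traj, "pulmonary", events)

    pulm = {c: _mean_over(traj, c, t0, t1)
            for c in ("p_pa_p", "p_pa_d", "p_pa", "p_pc", "p_pv",
                      "v_pa_p", "v_pa_d", "v_pa", "v_pc", "v_pv")}
    neural = {c: _mean_over(traj, c, t0, t1)
              for c in ("f_b", "f_hrv", "f_hrs", "f_con", "f_vaso", "alpha")}

    resp = {}
    if traj.scenario.get("pleural_mode") == "sinusoid":
        for sig in RESP_SIGNALS:
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    resp[sig] = respiratory_variation(traj, sig)
            except (ValueError, KeyError):
                pass

    return HemodynamicSummary(
        HR=lv["HR"], CO=lv["CO"], LVSV=lv["SV"], RVSV=rv["SV"],
        LVEF=lv["EF"], RVEF=rv["EF"], LVEDP=lv["EDP"],
        MSAP=_mean_over(traj, "p_ao_p", t0, t1),
        CVP=_mean_over(traj, "p_vc", t0, t1),
        LVET=lv["ET"], RVET=rv["ET"],
        LV_EDV=lv["EDV"], LV_ESV=lv["ESV"],
        RV_EDV=rv["EDV"], RV_ESV=rv["ESV"],
        mitral=mitral, tricuspid=tricuspid,
        venous_central=ds_c, venous_pulmonary=ds_p,
        pulmonary_means=pulm, neural_means=neural,
        respiratory_variation=resp,
        scenario=dict(traj.scenario),
    )
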