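"""Compiled numerical core: model right-hand side and adaptive integrator.

Everything here operates on flat float64 vectors so it can be jitted with
numba.  The object-level API (parameters, mechanics, engine modules) wraps
these kernels; :func:`pack_parameters` flattens a ``ModelParameters`` into
the parameter vector consumed by the kernels.

State vector layout (25 entries)::

    0..3    V_LV, V_RV, V_LA, V_RA                  chamber volumes (ml)
    4..16   vascular compartment volumes (ml), order COMPARTMENT_ORDER
    17..19  inertial flows (ml/s) on the arterial segments:
            proximal->distal aorta, distal aorta->systemic arteries,
            proximal->distal pulmonary artery
    20..23  F_HRv, F_HRs, F_con, F_vaso             filtered efferents
    24      low-pass filtered proximal aortic pressure (mmHg)

The cardiac phase and current beat period are carried by the beat loop in
the engine, not in the state vector (the period only changes at beat onset).
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

# ----------------------------------------------------------------------
# layout
# ----------------------------------------------------------------------

COMPARTMENT_ORDER = ("AO_p", "AO_d", "SA", "SA_d", "SC", "SVL", "SV", "VC",
                     "PA_p", "PA_d", "PA", "PC", "PV")
NCOMP = 13

# state indices
SV_LV, SV_RV, SV_LA, SV_RA = 0, 1, 2, 3
SCOMP0 = 4                       # compartment volumes 4..16
SQ_AOD, SQ_SA, SQ_PAD = 17, 18, 19
SF_HRV, SF_HRS, SF_CON, SF_VASO = 20, 21, 22, 23
SMSAP = 24
NSTATE = 25

# parameter vector indices
PW0 = 0            # walls: 5 x (E_ES, V_d, P_0, lam, V_0); LVF,RVF,SPT,LA,RA
PACT0 = 25         # activations LVF,RVF,SPT: 7A,7B,7C,scale (22 each)
PAT_W_LA, PAT_OFF = 91, 92       # atrial Gaussian widths, offset-from-beat-end
PPERI0 = 93        # P_PERI0, lam_PERI, V_PERI0, V_fluid
PRM, PRTC, PRAV, PRPAV = 97, 98, 99, 100
PL_AOP, PL_AOD, PL_PA = 101, 102, 103   # inertances on the arterial segments
PCOMP0 = 104       # 13 x (C, V_un, thoracic)
PR0 = 143          # 16 edge resistances, order below
PR_TAO, PR_TAOD, PR_TPA = 159, 160, 161
PNB_A, PNB_B = 162, 163          # baroreceptor affine map
PLIMB0 = 164       # 4 limbs x (slope, intercept, tau); HRv, HRs, con, vaso
PTAU_MSAP = 176
PK_ALPHA, PF_CON_REF, PK_VASO_R, PK_VASO_V, PF_VASO_REF = 177, 178, 179, 180, 181
PCLAMP_CON, PCLAMP_CON_VAL = 182, 183
PPL_MODE, PPL_FIX, PPL_MEAN, PPL_AMP, PPL_PERIOD = 184, 185, 186, 187, 188
PHR_H0, PHR_HS, PHR_HV = 189, 190, 191
PAT_AMP_LA, PAT_AMP_RA = 192, 193   # atrial activation peak amplitudes
PAT_W_RA = 194
NPARAM = 195

EDGE_RESISTANCES = ("R_AO_d", "R_SA", "R_SA_d", "R_SC", "R_SVL", "R_SV",
                    "R_VC", "R_RA", "R_PA_d", "R_PA", "R_PC", "R_PV",
                    "R_LA", "R_PS", "R_COR", "R_CRB")
(R_AOD, R_SA, R_SAD, R_SC, R_SVL, R_SV, R_VC, R_RA, R_PAD, R_PA, R_PC,
 R_PV, R_LA, R_PS, R_COR, R_CRB) = range(16)

# wall order within the wall block
WLVF, WRVF, WSPT, WLA, WRA = 0, 1, 2, 3, 4

#: derived signals computed alongside the state derivative
OUTPUT_NAMES = (
    "p_lv", "p_rv", "p_la", "p_ra", "p_peri", "v_spt",
    "p_lvf", "p_rvf", "p_spt",
    "p_ao_p", "p_ao_d", "p_sa", "p_sa_d", "p_sc", "p_svl", "p_sv", "p_vc",
    "p_pa_p", "p_pa_d", "p_pa", "p_pc", "p_pv",
    "q_m", "q_tc", "q_ao_p", "q_pa_p", "q_ao_d",
    "q_sa", "q_sa_d", "q_sc", "q_svl", "q_sv", "q_vc", "q_ra",
    "q_pa_d", "q_pa", "q_pc", "q_pv", "q_la", "q_ps", "q_cor", "q_crb",
    "e_lvf", "e_rvf", "e_spt", "e_la", "e_ra",
    "alpha", "f_b", "p_pl", "spt_iters",
)
NOUT = len(OUTPUT_NAMES)
OUT_INDEX = {n: i for i, n in enumerate(OUTPUT_NAMES)}

STATE_NAMES = (
    "v_lv", "v_rv", "v_la", "v_ra",
    "v_ao_p", "v_ao_d", "v_sa", "v_sa_d", "v_sc", "v_svl", "v_sv", "v_vc",
    "v_pa_p", "v_pa_d", "v_pa", "v_pc", "v_pv",
    "iq_ao_d", "iq_sa", "iq_pa_d",
    "f_hrv", "f_hrs", "f_con", "f_vaso", "msap_filt",
)


def pack_parameters(params) -> np.ndarray:
    """Flatten a ModelParameters into the kernel parameter vector."""
    from .parameters import PleuralMode

    p = np.zeros(NPARAM)
    for wi, wall in enumerate(("LVF", "RVF", "SPT", "LA", "RA")):
        w = params.walls[wall]
        p[PW0 + 5 * wi: PW0 + 5 * wi + 5] = (w.E_ES, w.V_d, w.P_0, w.lam, w.V_0)
    for ai, wall in enumerate(("LVF", "RVF", "SPT")):
        spec = params.activations[wall]
        base = PACT0 + 22 * ai
        for i, t in enumerate(spec.terms):
            p[base + i] = t.A
            p[base + 7 + i] = t.B
            p[base + 14 + i] = t.C
        p[base + 21] = spec.normalization_scale
    p[PAT_W_LA] = params.la_width
    p[PAT_W_RA] = params.ra_width
    p[PAT_OFF] = params.atrial_offset
    p[PAT_AMP_LA] = params.la_amplitude
    p[PAT_AMP_RA] = params.ra_amplitude
    peri = params.pericardium
    p[PPERI0:PPERI0 + 4] = (peri.P_PERI0, peri.lam_PERI, peri.V_PERI0,
                            peri.V_PERI_FLUID)
    p[PRM] = params.valves["mitral"].R_open
    p[PRTC] = params.valves["tricuspid"].R_open
    p[PRAV] = params.valves["aortic"].R_open
    p[PRPAV] = params.valves["pulmonic"].R_open
    p[PL_AOP] = params.inertances["L_AO_p"]
    p[PL_AOD] = params.inertances["L_AO_d"]
    p[PL_PA] = params.inertances["L_PA"]
    for ci, name in enumerate(COMPARTMENT_ORDER):
        c = params.compartments[name]
        base = PCOMP0 + 3 * ci
        p[base] = c.C
        p[base + 1] = c.V_un
        p[base + 2] = 1.0 if c.thoracic else 0.0
    for ri, name in enumerate(EDGE_RESISTANCES):
        p[PR0 + ri] = params.resistances[name]
    p[PR_TAO] = params.resistances["R_TAO"]
    p[PR_TAOD] = params.resistances["R_TAO_d"]
    p[PR_TPA] = params.resistances["R_TPA"]
    n = params.neural
    p[PNB_A], p[PNB_B] = n.baro_slope, n.baro_intercept
    for li, limb in enumerate(("F_HRv", "F_HRs", "F_con", "F_vaso")):
        base = PLIMB0 + 3 * li
        p[base] = n.limb_slopes[limb]
        p[base + 1] = n.limb_intercepts[limb]
        p[base + 2] = n.limb_tau[limb]
    p[PTAU_MSAP] = n.tau_msap
    p[PK_ALPHA] = n.k_alpha
    p[PF_CON_REF] = n.F_con_ref
    p[PK_VASO_R] = n.k_vaso_R
    p[PK_VASO_V] = n.k_vaso_V
    p[PF_VASO_REF] = n.F_vaso_ref
    p[PCLAMP_CON] = 0.0
    p[PCLAMP_CON_VAL] = n.F_con_ref
    p[PPL_MODE] = 1.0 if params.pleural_mode is PleuralMode.SINUSOID else 0.0
    p[PPL_FIX] = -5.0
    p[PPL_MEAN] = -4.0
    p[PPL_AMP] = 2.0
    p[PPL_PERIOD] = 7.0
    p[PHR_H0], p[PHR_HS], p[PHR_HV] = n.hr_h0, n.hr_hs, n.hr_hv
    return p


# ----------------------------------------------------------------------
# scalar physics kernels
# ----------------------------------------------------------------------

@njit(cache=True)
def _exp_capped(x):
    # overflow guard for the exponential diastolic laws
    if x > 60.0:
        x = 60.0
    return math.exp(x)


@njit(cache=True)
def es_pressure(v, e_es, v_d, alpha):
    """Linear end-systolic P-V relation, scaled by the inotropic factor."""
    return alpha * e_es * (v - v_d)


@njit(cache=True)
def ed_pressure(v, p_0, lam, v_0):
    """Exponential end-diastolic P-V relation, zero at V = V_0."""
    return p_0 * (_exp_capped(lam * (v - v_0)) - 1.0)


@njit(cache=True)
def wall_pressure(v, e, alpha, e_es, v_d, p_0, lam, v_0):
    """Activation-weighted transmural wall pressure."""
    return (e * es_pressure(v, e_es, v_d, alpha)
            + (1.0 - e) * ed_pressure(v, p_0, lam, v_0))


@njit(cache=True)
def wall_elastance(v, e, alpha, e_es, p_0, lam, v_0):
    """Instantaneous elastance dP/dV of the weighted wall law (mmHg/ml)."""
    return e * alpha * e_es + (1.0 - e) * lam * p_0 * _exp_capped(lam * (v - v_0))


@njit(cache=True)
def septal_inverse(p_spt, e_spt, alpha, e_es, v_d, p_0, lam, v_0):
    """Septal volume at trans-septal pressure p_spt (sign-mirrored branches)."""
    v_sys = v_d + p_spt / (alpha * e_es)
    if p_spt >= 0.0:
        v_dia = v_0 + math.log(1.0 + p_spt / p_0) / lam
    else:
        v_dia = v_0 - math.log(1.0 - p_spt / p_0) / lam
    return e_spt * v_sys + (1.0 - e_spt) * v_dia


@njit(cache=True)
def activation_eval(phase, p, wall_idx):
    """Normalized ventricular/septal activation at cardiac phase (s)."""
    base = PACT0 + 22 * wall_idx
    s = 0.0
    for i in range(7):
        a = p[base + i]
        b = p[base + 7 + i]
        c = p[base + 14 + i]
        u = (phase - c) / b
        s += a * math.exp(-0.5 * u * u)
    s *= p[base + 21]
    if s < 0.0:
        s = 0.0
    elif s > 1.0:
        s = 1.0
    return s


@njit(cache=True)
def atrial_eval(phase, period, width, p):
    u = (phase - (period - p[PAT_OFF])) / width
    return math.exp(-0.5 * u * u)


@njit(cache=True)
def septal_solve(v_lv, v_rv, e_lvf, e_rvf, e_spt, alpha, p, v_guess):
    """Solve the septal volume fixed point.

    Returns (v_spt, p_lvf, p_rvf, iterations).  Damped fixed-point iteration
    (factor 0.5, tolerance 1e-6 ml); falls back to bisection on the residual
    if the iteration has not converged after 100 sweeps.
    """
    lvf = PW0 + 5 * WLVF
    rvf = PW0 + 5 * WRVF
    spt = PW0 + 5 * WSPT

    v = v_guess
    it = 0
    converged = False
    for _ in range(100):
        it += 1
        p_lvf = wall_pressure(v_lv - v, e_lvf, alpha, p[lvf], p[lvf + 1],
                              p[lvf + 2], p[lvf + 3], p[lvf + 4])
        p_rvf = wall_pressure(v_rv + v, e_rvf, alpha, p[rvf], p[rvf + 1],
                              p[rvf + 2], p[rvf + 3], p[rvf + 4])
        p_spt = p_lvf - p_rvf
        v_new = septal_inverse(p_spt, e_spt, alpha, p[spt], p[spt + 1],
                               p[spt + 2], p[spt + 3], p[spt + 4])
        dv = v_new - v
        v = v + 0.5 * dv
        if abs(dv) < 1e-6:
            converged = True
            break

    if not converged:
        # bisection on g(v) = v - inverse(P_spt(v)); g is increasing in v
        lo, hi = -80.0, 100.0
        for _ in range(20):  # expand the bracket if the root lies outside
            g_lo = lo - septal_inverse(
                wall_pressure(v_lv - lo, e_lvf, alpha, p[lvf], p[lvf + 1],
                              p[lvf + 2], p[lvf + 3], p[lvf + 4])
                - wall_pressure(v_rv + lo, e_rvf, alpha, p[rvf], p[rvf + 1],
                                p[rvf + 2], p[rvf + 3], p[rvf + 4]),
                e_spt, alpha, p[spt], p[spt + 1], p[spt + 2], p[spt + 3],
                p[spt + 4])
            if g_lo < 0.0:
                break
            lo *= 2.0
        for _ in range(20):
            g_hi = hi - septal_inverse(
                wall_pressure(v_lv - hi, e_lvf, alpha, p[lvf], p[lvf + 1],
                              p[lvf + 2], p[lvf + 3], p[lvf + 4])
                - wall_pressure(v_rv + hi, e_rvf, alpha, p[rvf], p[rvf + 1],
                                p[rvf + 2], p[rvf + 3], p[rvf + 4]),
                e_spt, alpha, p[spt], p[spt + 1], p[spt + 2], p[spt + 3],
                p[spt + 4])
            if g_hi > 0.0:
                break
            hi *= 2.0
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            p_lvf = wall_pressure(v_lv - mid, e_lvf, alpha, p[lvf],
                                  p[lvf + 1], p[lvf + 2], p[lvf + 3], p[lvf + 4])
            p_rvf = wall_pressure(v_rv + mid, e_rvf, alpha, p[rvf],
                                  p[rvf + 1], p[rvf + 2], p[rvf + 3], p[rvf + 4])
            g = mid - septal_inverse(p_lvf - p_rvf, e_spt, alpha, p[spt],
                                     p[spt + 1], p[spt + 2], p[spt + 3],
                                     p[spt + 4])
            if g > 0.0:
                hi = mid
            else:
                lo = mid
            if hi - lo < 1e-9:
                break
        v = 0.5 * (lo + hi)
        it = -it  # negative count flags the fallback path

    p_lvf = wall_pressure(v_lv - v, e_lvf, alpha, p[lvf], p[lvf + 1],
                          p[lvf + 2], p[lvf + 3], p[lvf + 4])
    p_rvf = wall_pressure(v_rv + v, e_rvf, alpha, p[rvf], p[rvf + 1],
                          p[rvf + 2], p[rvf + 3], p[rvf + 4])
    return v, p_lvf, p_rvf, it


@njit(cache=True)
def pleural_pressure(t, p):
    if p[PPL_MODE] < 0.5:
        return p[PPL_FIX]
    return p[PPL_MEAN] - p[PPL_AMP] * math.cos(2.0 * math.pi * t / p[PPL_PERIOD])


# ----------------------------------------------------------------------
# full model evaluation
# ----------------------------------------------------------------------

@njit(cache=True)
def eval_model(t, phase, period, y, p, v_guess, dy, out):
    """Evaluate state derivative and derived signals in place.

    Returns the converged septal volume (to warm-start the next call).
    Pure function of (t, phase, period, y, p): v_guess only affects the
    iteration count, not the solution.
    """
    p_pl = pleural_pressure(t, p)

    # --- activations ------------------------------------------------
    e_lvf = activation_eval(phase, p, WLVF)
    e_rvf = activation_eval(phase, p, WRVF)
    e_spt = activation_eval(phase, p, WSPT)
    e_la = p[PAT_AMP_LA] * atrial_eval(phase, period, p[PAT_W_LA], p)
    e_ra = p[PAT_AMP_RA] * atrial_eval(phase, period, p[PAT_W_RA], p)

    # --- inotropic factor -------------------------------------------
    if p[PCLAMP_CON] > 0.5:
        f_con = p[PCLAMP_CON_VAL]
    else:
        f_con = y[SF_CON]
    alpha = 1.0 + p[PK_ALPHA] * (f_con - p[PF_CON_REF])
    if alpha < 1.0:
        alpha = 1.0

    # --- ventricles: septal solve, free walls, pericardium ----------
    v_spt, p_lvf, p_rvf, it = septal_solve(
        y[SV_LV], y[SV_RV], e_lvf, e_rvf, e_spt, alpha, p, v_guess)

    v_heart = y[SV_LV] + y[SV_RV] + y[SV_LA] + y[SV_RA] + p[PPERI0 + 3]
    p_peri = (p[PPERI0] * (_exp_capped(p[PPERI0 + 1] * (v_heart - p[PPERI0 + 2]))
                           - 1.0) + p_pl)

    p_lv = p_lvf + p_peri
    p_rv = p_rvf + p_peri

    la = PW0 + 5 * WLA
    ra = PW0 + 5 * WRA
    p_la = wall_pressure(y[SV_LA], e_la, 1.0, p[la], p[la + 1], p[la + 2],
                         p[la + 3], p[la + 4]) + p_peri
    p_ra = wall_pressure(y[SV_RA], e_ra, 1.0, p[ra], p[ra + 1], p[ra + 2],
                         p[ra + 3], p[ra + 4]) + p_peri

    # --- vasomotor tone ---------------------------------------------
    dvaso = y[SF_VASO] - p[PF_VASO_REF]
    r_sad = p[PR0 + R_SAD] * max(0.2, 1.0 + p[PK_VASO_R] * dvaso)
    vun_sv_shift = p[PK_VASO_V] * dvaso

    # --- vascular node pressures ------------------------------------
    pc = np.empty(NCOMP)
    for i in range(NCOMP):
        base = PCOMP0 + 3 * i
        vun = p[base + 1]
        if i == 6:  # systemic veins: vasomotor unstressed-volume shift
            vun -= vun_sv_shift
        pext = p_pl if p[base + 2] > 0.5 else 0.0
        pc[i] = (y[SCOMP0 + i] - vun) / p[base] + pext

    q_aod = y[SQ_AOD]
    q_sa = y[SQ_SA]
    q_pad = y[SQ_PAD]

    # viscoelastic (Kelvin) node corrections: node pressure rises with the
    # capacitive charging current through the series resistance.  On the
    # proximal aortic/pulmonary nodes the inflow is the (resistive diode)
    # outlet valve, whose flow depends on the node pressure, so the linear
    # node equation is solved for the open- and closed-valve branches.
    g_sh = 1.0 / p[PR0 + R_COR] + 1.0 / p[PR0 + R_CRB]
    p_vc = pc[7]

    # proximal aorta with the aortic valve
    p_aop = ((pc[0] + p[PR_TAO] * (p_lv / p[PRAV] + g_sh * p_vc - q_aod))
             / (1.0 + p[PR_TAO] * (1.0 / p[PRAV] + g_sh)))
    if p_lv > p_aop:
        q_av = (p_lv - p_aop) / p[PRAV]
    else:
        q_av = 0.0
        p_aop = ((pc[0] + p[PR_TAO] * (g_sh * p_vc - q_aod))
                 / (1.0 + p[PR_TAO] * g_sh))

    # proximal pulmonary artery with the pulmonic valve
    p_pap = ((pc[8] + p[PR_TPA] * (p_rv / p[PRPAV] - q_pad))
             / (1.0 + p[PR_TPA] / p[PRPAV]))
    if p_rv > p_pap:
        q_pav = (p_rv - p_pap) / p[PRPAV]
    else:
        q_pav = 0.0
        p_pap = pc[8] - p[PR_TPA] * q_pad

    # distal aorta (both neighbors are inertial states)
    p_aod = pc[1] + p[PR_TAOD] * (q_aod - q_sa)

    p_sa = pc[2]
    p_sad = pc[3]
    p_sc = pc[4]
    p_svl = pc[5]
    p_sv = pc[6]
    p_pad = pc[9]
    p_pa = pc[10]
    p_pc = pc[11]
    p_pv = pc[12]

    # --- flows -------------------------------------------------------
    q_m = (p_la - p_lv) / p[PRM]
    if q_m < 0.0:
        q_m = 0.0
    q_tc = (p_ra - p_rv) / p[PRTC]
    if q_tc < 0.0:
        q_tc = 0.0

    q_sad = (p_sa - p_sad) / r_sad
    q_sc = (p_sad - p_sc) / p[PR0 + R_SC]
    q_svl = (p_sc - p_svl) / p[PR0 + R_SVL]
    q_sv = (p_svl - p_sv) / p[PR0 + R_SV]
    q_vc = (p_sv - p_vc) / p[PR0 + R_VC]
    q_ra = (p_vc - p_ra) / p[PR0 + R_RA]
    q_pa = (p_pad - p_pa) / p[PR0 + R_PA]
    q_pc = (p_pa - p_pc) / p[PR0 + R_PC]
    q_pv = (p_pc - p_pv) / p[PR0 + R_PV]
    q_la = (p_pv - p_la) / p[PR0 + R_LA]
    q_ps = (p_pad - p_pv) / p[PR0 + R_PS]
    q_cor = (p_aop - p_vc) / p[PR0 + R_COR]
    q_crb = (p_aop - p_vc) / p[PR0 + R_CRB]

    # --- volume derivatives (closed loop) ----------------------------
    dy[SV_LV] = q_m - q_av
    dy[SV_RV] = q_tc - q_pav
    dy[SV_LA] = q_la - q_m
    dy[SV_RA] = q_ra - q_tc
    dy[SCOMP0 + 0] = q_av - q_aod - q_cor - q_crb
    dy[SCOMP0 + 1] = q_aod - q_sa
    dy[SCOMP0 + 2] = q_sa - q_sad
    dy[SCOMP0 + 3] = q_sad - q_sc
    dy[SCOMP0 + 4] = q_sc - q_svl
    dy[SCOMP0 + 5] = q_svl - q_sv
    dy[SCOMP0 + 6] = q_sv - q_vc
    dy[SCOMP0 + 7] = q_vc + q_cor + q_crb - q_ra
    dy[SCOMP0 + 8] = q_pav - q_pad
    dy[SCOMP0 + 9] = q_pad - q_pa - q_ps
    dy[SCOMP0 + 10] = q_pa - q_pc
    dy[SCOMP0 + 11] = q_pc - q_pv
    dy[SCOMP0 + 12] = q_pv + q_ps - q_la

    # --- inertial arterial segment flows ------------------------------
    dy[SQ_AOD] = (p_aop - p_aod - p[PR0 + R_AOD] * q_aod) / p[PL_AOP]
    dy[SQ_SA] = (p_aod - p_sa - p[PR0 + R_SA] * q_sa) / p[PL_AOD]
    dy[SQ_PAD] = (p_pap - p_pad - p[PR0 + R_PAD] * q_pad) / p[PL_PA]

    # --- baroreflex ---------------------------------------------------
    f_b = p[PNB_A] * y[SMSAP] + p[PNB_B]
    if f_b < 0.0:
        f_b = 0.0
    elif f_b > 1.0:
        f_b = 1.0
    for li in range(4):
        base = PLIMB0 + 3 * li
        target = p[base] * f_b + p[base + 1]
        if target < 0.0:
            target = 0.0
        elif target > 1.0:
            target = 1.0
        dy[SF_HRV + li] = (target - y[SF_HRV + li]) / p[base + 2]
    dy[SMSAP] = (p_aop - y[SMSAP]) / p[PTAU_MSAP]

    # --- derived signals ---------------------------------------------
    out[0] = p_lv
    out[1] = p_rv
    out[2] = p_la
    out[3] = p_ra
    out[4] = p_peri
    out[5] = v_spt
    out[6] = p_lvf
    out[7] = p_rvf
    out[8] = p_lvf - p_rvf
    out[9] = p_aop
    out[10] = p_aod
    out[11] = p_sa
    out[12] = p_sad
    out[13] = p_sc
    out[14] = p_svl
    out[15] = p_sv
    out[16] = p_vc
    out[17] = p_pap
    out[18] = p_pad
    out[19] = p_pa
    out[20] = p_pc
    out[21] = p_pv
    out[22] = q_m
    out[23] = q_tc
    out[24] = q_av
    out[25] = q_pav
    out[26] = q_aod
    out[27] = q_sa
    out[28] = q_sad
    out[29] = q_sc
    out[30] = q_svl
    out[31] = q_sv
    out[32] = q_vc
    out[33] = q_ra
    out[34] = q_pad
    out[35] = q_pa
    out[36] = q_pc
    out[37] = q_pv
    out[38] = q_la
    out[39] = q_ps
    out[40] = q_cor
    out[41] = q_crb
    out[42] = e_lvf
    out[43] = e_rvf
    out[44] = e_spt
    out[45] = e_la
    out[46] = e_ra
    out[47] = alpha
    out[48] = f_b
    out[49] = p_pl
    out[50] = float(it)
    return v_spt


# ----------------------------------------------------------------------
# Cash-Karp RK4(5) integration over one beat segment
# ----------------------------------------------------------------------

@njit(cache=True)
def integrate_segment(t0, t1, beat_start, period, y, p, v_spt, rtol, atol,
                      grid_t, grid_y, grid_out, fill, h0, hmin):
    """Advance the state from t0 to t1 with adaptive Cash-Karp steps.

    Dense output is produced by forcing step endpoints onto the reporting
    grid ``grid_t`` (strictly increasing absolute times).  ``fill`` is the
    index of the next grid entry to produce; rows of ``grid_y``/``grid_out``
    are written as grid times are reached.  Returns
    ``(t, h, v_spt, fill, nsteps, nrej, status)`` with status 0 on success,
    1 on step-size underflow, 2 if a negative volume could not be stepped
    over, 3 if the per-segment step budget is exhausted.
    """
    n = y.shape[0]
    dy = np.empty(n)
    out = np.empty(NOUT)
    k1 = np.empty(n)
    k2 = np.empty(n)
    k3 = np.empty(n)
    k4 = np.empty(n)
    k5 = np.empty(n)
    k6 = np.empty(n)
    ytmp = np.empty(n)
    ynew = np.empty(n)

    t = t0
    h = h0
    nsteps = 0
    nrej = 0
    status = 0
    ngrid = grid_t.shape[0]

    while t < t1 - 1e-12:
        if nsteps + nrej > 2_000_000:
            status = 3  # step budget exhausted (pathological stiffness)
            break
        # aim the step at the next grid time or the segment end
        t_target = t1
        if fill < ngrid and grid_t[fill] < t_target:
            t_target = grid_t[fill]
        if h > t_target - t:
            h = t_target - t
        if h < hmin:
            h = hmin

        # Cash-Karp stages
        v_spt = eval_model(t, t - beat_start, period, y, p, v_spt, dy, out)
        for i in range(n):
            k1[i] = dy[i]
        for i in range(n):
            ytmp[i] = y[i] + h * 0.2 * k1[i]
        v_spt = eval_model(t + 0.2 * h, t + 0.2 * h - beat_start, period,
                           ytmp, p, v_spt, dy, out)
        for i in range(n):
            k2[i] = dy[i]
        for i in range(n):
            ytmp[i] = y[i] + h * (0.075 * k1[i] + 0.225 * k2[i])
        v_spt = eval_model(t + 0.3 * h, t + 0.3 * h - beat_start, period,
                           ytmp, p, v_spt, dy, out)
        for i in range(n):
            k3[i] = dy[i]
        for i in range(n):
            ytmp[i] = y[i] + h * (0.3 * k1[i] - 0.9 * k2[i] + 1.2 * k3[i])
        v_spt = eval_model(t + 0.6 * h, t + 0.6 * h - beat_start, period,
                           ytmp, p, v_spt, dy, out)
        for i in range(n):
            k4[i] = dy[i]
        for i in range(n):
            ytmp[i] = y[i] + h * ((-11.0 / 54.0) * k1[i] + 2.5 * k2[i]
                                  + (-70.0 / 27.0) * k3[i]
                                  + (35.0 / 27.0) * k4[i])
        v_spt = eval_model(t + h, t + h - beat_start, period,
                           ytmp, p, v_spt, dy, out)
        for i in range(n):
            k5[i] = dy[i]
        for i in range(n):
            ytmp[i] = y[i] + h * ((1631.0 / 55296.0) * k1[i]
                                  + (175.0 / 512.0) * k2[i]
                                  + (575.0 / 13824.0) * k3[i]
                                  + (44275.0 / 110592.0) * k4[i]
                                  + (253.0 / 4096.0) * k5[i])
        v_spt = eval_model(t + 0.875 * h, t + 0.875 * h - beat_start, period,
                           ytmp, p, v_spt, dy, out)
        for i in range(n):
            k6[i] = dy[i]

        errmax = 0.0
        for i in range(n):
            y5 = y[i] + h * ((37.0 / 378.0) * k1[i]
                             + (250.0 / 621.0) * k3[i]
                             + (125.0 / 594.0) * k4[i]
                             + (512.0 / 1771.0) * k6[i])
            y4 = y[i] + h * ((2825.0 / 27648.0) * k1[i]
                             + (18575.0 / 48384.0) * k3[i]
                             + (13525.0 / 55296.0) * k4[i]
                             + (277.0 / 14336.0) * k5[i]
                             + 0.25 * k6[i])
            ynew[i] = y5
            sc = atol + rtol * max(abs(y[i]), abs(y5))
            e = abs(y5 - y4) / sc
            if e > errmax:
                errmax = e

        # reject on negative stored volumes (nonphysical excursion)
        neg = False
        for i in range(SCOMP0 + NCOMP):
            if ynew[i] < 0.0:
                neg = True
                break

        if errmax <= 1.0 and not neg:
            nsteps += 1
            t_new = t + h
            for i in range(n):
                y[i] = ynew[i]
            t = t_new
            if fill < ngrid and abs(t - grid_t[fill]) < 1e-9:
                v_spt = eval_model(t, t - beat_start, period, y, p, v_spt,
                                   dy, out)
                for i in range(n):
                    grid_y[fill, i] = y[i]
                for i in range(NOUT):
                    grid_out[fill, i] = out[i]
                fill += 1
            if errmax > 1e-10:
                fac = 0.9 * errmax ** -0.2
            else:
                fac = 5.0
            if fac > 5.0:
                fac = 5.0
            h = h * fac
        else:
            nrej += 1
            if h <= hmin * 1.0001:
                if neg:
                    status = 2
                else:
                    status = 1
                break
            if errmax > 1e-10:
                fac = 0.9 * errmax ** -0.2
            else:
                fac = 0.5
            if fac < 0.1:
                fac = 0.1
            h = h * fac
            if h < hmin:
                h = hmin

    return t, h, v_spt, fill, nsteps, nrej, status
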