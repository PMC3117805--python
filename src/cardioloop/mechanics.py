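"""Cardiac wall, chamber, septal, atrial and pericardial pressures.

Each ventricular chamber pressure is assembled from an actively contracting
free wall and the shared interventricular septum.  A wall's transmural
pressure blends a linear end-systolic P-V relation (slope ``E_ES``, scaled
by the baroreflex inotropic factor alpha) with an exponential end-diastolic
relation, weighted by the activation e(t)::

    P(V, t) = e(t) * alpha * E_ES * (V - V_d)
            + (1 - e(t)) * P_0 * (exp(lambda * (V - V_0)) - 1)

The septum is a third active pump: its displaced volume ``V_SPT`` (positive
when bulging into the RV) satisfies a fixed point in which the trans-septal
pressure ``P_SPT = P_LVF(V_LV - V_SPT) - P_RVF(V_RV + V_SPT)`` maps back to
the same volume through the activation-weighted inverse of the septal wall
law.  The pericardium wraps all four chambers with its own exponential law
referenced to pleural pressure, so absolute chamber pressures are the
transmural wall pressures plus ``P_PERI``.
"""

from __future__ import annotations

from dataclasses import dataclass

from . import _core
from .parameters import ModelParameters, PericardiumParameters, WallParameters

__all__ = [
    "VentricularPressures",
    "end_systolic_pressure",
    "end_diastolic_pressure",
    "free_wall_pressure",
    "solve_septal_volume",
    "pericardial_pressure",
    "atrial_pressure",
    "instantaneous_elastance",
]


@dataclass
class VentricularPressures:
    """Result of the coupled free-wall/septal pressure solve (all mmHg/ml)."""
    P_LVF: float
    P_RVF: float
    P_LV: float
    P_RV: float
    P_SPT: float
    V_SPT: float
    iterations: int
    used_fallback: bool


def end_systolic_pressure(V: float, wall: WallParameters,
                          alpha: float = 1.0) -> float:
    """Linear ESPVR: alpha * E_ES * (V - V_d)."""
    if alpha < 1.0:
        raise ValueError("inotropic factor alpha must be >= 1")
    return float(_core.es_pressure(V, wall.E_ES, wall.V_d, alpha))


def end_diastolic_pressure(V: float, wall: WallParameters) -> float:
    """Exponential EDPVR: P_0 * (exp(lambda*(V - V_0)) - 1); zero at V_0."""
    return float(_core.ed_pressure(V, wall.P_0, wall.lam, wall.V_0))


def free_wall_pressure(e: float, P_ES: float, P_ED: float) -> float:
    """Activation-weighted blend e*P_ES + (1-e)*P_ED."""
    if not 0.0 <= e <= 1.0:
        raise ValueError("activation weight must lie in [0, 1]")
    return e * P_ES + (1.0 - e) * P_ED


def solve_septal_volume(V_LV: float, V_RV: float, e_LVF: float, e_RVF: float,
                        e_SPT: float, params: ModelParameters,
                        V_SPT_init: float = 0.0,
                        alpha: float = 1.0,
                        P_PERI: float = 0.0) -> VentricularPressures:
    """Solve the septal fixed point for given chamber volumes and activations.

    The result is independent of ``V_SPT_init`` (which only warm-starts the
    iteration).  ``iterations`` counts fixed-point sweeps; if the damped
    iteration failed to converge, a bracketing bisection on the residual is
    used instead and ``used_fallback`` is set.
    """
    if V_LV <= 0 or V_RV <= 0:
        raise ValueError("chamber volumes must be positive")
    p = _core.pack_parameters(params)
    v_spt, p_lvf, p_rvf, it = _core.septal_solve(
        V_LV, V_RV, e_LVF, e_RVF, e_SPT, alpha, p, V_SPT_init)
    return VentricularPressures(
        P_LVF=p_lvf, P_RVF=p_rvf,
        P_LV=p_lvf + P_PERI, P_RV=p_rvf + P_PERI,
        P_SPT=p_lvf - p_rvf, V_SPT=v_spt,
        iterations=abs(it), used_fallback=it < 0)


def pericardial_pressure(V_heart: float, P_PL: float,
                         peri: PericardiumParameters) -> float:
    """Exponential pericardial law referenced to pleural pressure.

    ``V_heart`` is the total intrapericardial volume: the four chamber
    volumes plus the pericardial fluid volume.
    """
    if V_heart <= 0:
        raise ValueError("heart volume must be positive")
    return float(_core.ed_pressure(V_heart, peri.P_PERI0, peri.lam_PERI,
                                   peri.V_PERI0) + P_PL)


def atrial_pressure(V: float, e_atrium: float, wall: WallParameters,
                    P_PERI: float) -> float:
    """Absolute atrial pressure: weighted wall law plus pericardial pressure."""
    if not 0.0 <= e_atrium <= 1.0:
        raise ValueError("activation weight must lie in [0, 1]")
    return float(_core.wall_pressure(V, e_atrium, 1.0, wall.E_ES, wall.V_d,
                                     wall.P_0, wall.lam, wall.V_0) + P_PERI)


def instantaneous_elastance(e: float, V: float, wall: WallParameters,
                            alpha: float = 1.0) -> float:
    """Local dP/dV of the weighted wall law (time-varying stiffness)."""
    if not 0.0 <= e <= 1.0:
        raise ValueError("activation weight must lie in [0, 1]")
    return float(_core.wall_elastance(V, e, alpha, wall.E_ES, wall.P_0,
                                      wall.lam, wall.V_0))
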