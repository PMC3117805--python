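"""Baroreflex: arterial pressure sensing, efferent limbs, effectors.

Structure: mean systemic arterial pressure (a 2 s exponential average of
proximal aortic pressure) drives the baroreceptor discharge ``F_b`` through
a saturating affine map.  ``F_b`` sets targets for four efferent limbs —
vagal heart-rate control ``F_HRv`` (increases with pressure), and the
sympathetic limbs ``F_HRs``, ``F_con``, ``F_vaso`` (decrease with pressure)
— each first-order low-pass filtered.  Effectors: the chronotropic map
``HR = h0 + hs*F_HRs - hv*F_HRv`` (sampled at each beat onset), the
inotropic factor ``alpha(F_con) = max(1, 1 + k_alpha*(F_con - F_con_ref))``
applied to ventricular end-systolic elastances, and vasomotor tone acting on
distal arteriolar resistance and venous unstressed volume.

All affine coefficients are identified by least squares from the model's
four printed steady-state operating points (see
``parameters.NEURAL_OPERATING_POINTS``); only steady-state behavior is
calibrated, the time constants are standard sympathetic/vagal values.
"""

from __future__ import annotations

import math

from .parameters import NeuralParameters

__all__ = [
    "baroreceptor_discharge",
    "efferent_targets",
    "low_pass_update",
    "heart_period",
    "contractility_gain",
]

HR_MIN, HR_MAX = 30.0, 180.0


def _clip01(x: float) -> float:
    return 0.0 if x < 0.0 else (1.0 if x > 1.0 else x)


def baroreceptor_discharge(msap_filtered: float,
                           neural: NeuralParameters) -> float:
    """Normalized baroreceptor discharge F_b in [0, 1]."""
    if msap_filtered <= 0:
        raise ValueError("filtered arterial pressure must be positive")
    return _clip01(neural.baro_slope * msap_filtered + neural.baro_intercept)


def efferent_targets(F_b: float, neural: NeuralParameters) -> dict[str, float]:
    """Affine targets for the four efferent limbs, clipped to [0, 1]."""
    return {
        limb: _clip01(neural.limb_slopes[limb] * F_b
                      + neural.limb_intercepts[limb])
        for limb in ("F_HRv", "F_HRs", "F_con", "F_vaso")
    }


def low_pass_update(current: float, target: float, tau: float,
                    dt: float) -> float:
    """Exact first-order relaxation over a step dt."""
    if tau <= 0:
        raise ValueError("time constant must be positive")
    return current + (target - current) * (1.0 - math.exp(-dt / tau))


def heart_rate(F_HRv: float, F_HRs: float, neural: NeuralParameters) -> float:
    """Chronotropic map, beats/min, clipped to the physiologic band."""
    hr = neural.hr_h0 + neural.hr_hs * F_HRs - neural.hr_hv * F_HRv
    return min(HR_MAX, max(HR_MIN, hr))


def heart_period(F_HRv: float, F_HRs: float, neural: NeuralParameters) -> float:
    """Beat period (s) from the chronotropic map."""
    return 60.0 / heart_rate(F_HRv, F_HRs, neural)


def contractility_gain(F_con: float, neural: NeuralParameters) -> float:
    """Inotropic factor alpha >= 1 applied to ventricular elastances."""
    return max(1.0, 1.0 + neural.k_alpha * (F_con - neural.F_con_ref))
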