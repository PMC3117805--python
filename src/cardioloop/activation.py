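"""Gaussian-sum activation functions driving the time-varying wall mechanics.

Each contractile wall blends its systolic and diastolic pressure-volume law
with a dimensionless weight e(t) in [0, 1].  For the ventricular free walls
and the septum, e(t) is a sum of seven Gaussians ``A_i * exp(-((t-C_i)/B_i)^2)``
(width B is the 1/e half-width), rescaled so the maximum over one beat equals
exactly 1.  The Gaussian coefficients are fixed in absolute time from beat
onset; changes of heart period lengthen or shorten diastole only.

The atria use a single normalized Gaussian pulse placed late in the cycle
(centered ``atrial_offset`` seconds before the end of the beat), so atrial
contraction immediately precedes the next ventricular beat — this produces
the A wave of the transvalvular inflow.
"""

from __future__ import annotations

import math

import numpy as np

from .parameters import ActivationSpec

__all__ = ["activation_value", "normalize_activation", "cycle_maximum",
           "atrial_activation"]

#: grid used for peak normalization (one cycle, generous upper bound)
_NORM_TMAX = 1.2
_NORM_N = 4801


def _raw_sum(t, spec: ActivationSpec):
    """Unnormalized Gaussian sum, vectorized over t."""
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    for term in spec.terms:
        out += term.A * np.exp(-0.5 * ((t - term.C) / term.B) ** 2)
    return out


def activation_value(t_cycle, spec: ActivationSpec):
    """Evaluate e(t_cycle) in [0, 1] for time since beat onset (s)."""
    t = np.asarray(t_cycle, dtype=float)
    if np.any(t < 0):
        raise ValueError("t_cycle must be non-negative")
    val = np.clip(spec.normalization_scale * _raw_sum(t, spec), 0.0, 1.0)
    return float(val) if np.isscalar(t_cycle) else val


def cycle_maximum(spec: ActivationSpec) -> float:
    """Maximum of the (scaled) activation over one cycle, by dense search."""
    grid = np.linspace(0.0, _NORM_TMAX, _NORM_N)
    return float(spec.normalization_scale * _raw_sum(grid, spec).max())


def normalize_activation(spec: ActivationSpec) -> ActivationSpec:
    """Set the normalization scale so the cycle maximum equals 1 (idempotent)."""
    raw_peak = float(_raw_sum(np.linspace(0.0, _NORM_TMAX, _NORM_N), spec).max())
    if raw_peak <= 0.0:
        raise ValueError("cannot normalize an activation with zero amplitude")
    spec.normalization_scale = 1.0 / raw_peak
    return spec


def atrial_activation(t_cycle: float, period: float,
                      width: float = 0.05, offset: float = 0.10) -> float:
    """Single-Gaussian atrial pulse centered ``offset`` s before beat end."""
    if t_cycle < 0:
        raise ValueError("t_cycle must be non-negative")
    center = period - offset
    return math.exp(-0.5 * ((t_cycle - center) / width) ** 2)
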