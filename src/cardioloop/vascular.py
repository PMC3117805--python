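"""Vascular network primitives: compliant compartments, valves, inertances.

The systemic and pulmonary circulations are chains of linear compliant
compartments connected by resistive edges; the proximal arterial segments
(aortic and pulmonary) additionally carry inertances.  Thoracic compartments reference pleural
pressure; extrathoracic ones reference body pressure (0 mmHg).  The four
heart valves are ideal diode-resistor pairs.  Three "vasoelastic" series
resistances sit between the proximal aortic / distal aortic / proximal
pulmonary arterial nodes and their compliances (a Kelvin viscoelastic
arrangement): the node pressure carries an extra term proportional to the
capacitive charging current.

The full closed-loop right-hand side lives in the compiled core; the
functions here expose the individual constitutive laws for direct use and
testing, plus :func:`circulation_derivatives`, a thin wrapper returning the
named volume derivatives for a given state.
"""

from __future__ import annotations

import numpy as np

from . import _core
from .parameters import ModelParameters, ValveElement, VascularCompartment

__all__ = [
    "compartment_pressure",
    "valve_flow",
    "inertial_flow_derivative",
    "circulation_derivatives",
]


def compartment_pressure(V: float, comp: VascularCompartment,
                         P_ext: float = 0.0) -> float:
    """Linear compliance law P = (V - V_un)/C + P_ext."""
    if V < 0:
        raise ValueError("compartment volume must be non-negative")
    return (V - comp.V_un) / comp.C + P_ext


def valve_flow(P_up: float, P_down: float, valve: ValveElement) -> float:
    """Ideal diode-resistor valve: forward flow only."""
    return max(0.0, (P_up - P_down) / valve.R_open)


def inertial_flow_derivative(Q: float, P_up: float, P_down: float,
                             R: float, L: float) -> float:
    """dQ/dt through a resistive-inertial edge."""
    if L <= 0:
        raise ValueError("inertance must be positive")
    return (P_up - P_down - R * Q) / L


def circulation_derivatives(state: np.ndarray, params: ModelParameters,
                            t: float = 0.0, phase: float = 0.0,
                            period: float = 1.0) -> dict[str, float]:
    """Named volume/flow derivatives of the closed loop at one state.

    ``state`` uses the core layout (see ``_core.STATE_NAMES``).  The sum of
    the volume derivatives is analytically zero: blood is conserved.
    """
    p = _core.pack_parameters(params)
    dy = np.empty(_core.NSTATE)
    out = np.empty(_core.NOUT)
    _core.eval_model(t, phase, period, np.asarray(state, dtype=float), p,
                     0.0, dy, out)
    return {name: float(dy[i]) for i, name in enumerate(_core.STATE_NAMES)}
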