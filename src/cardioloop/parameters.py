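"""Model parameters, validation, and diastolic-dysfunction scenario perturbations.

The full parameter set of the closed-loop circulation is collected in
:class:`ModelParameters`: five contractile walls (LV free wall, RV free wall,
septum, left and right atrium), the pericardial sac, thirteen vascular
compartments, four valves, and the baroreflex gains.  All printed constants
live in the ``*_TABLE`` dictionaries below; :func:`load_default_parameters`
assembles the control parameter set from them and cross-checks the result.

Scenario perturbations (:func:`apply_scenario`) implement the four
diastolic-dysfunction phenotypes:

``IR``
    impaired active relaxation — the tail of the LV free-wall and septal
    activation functions is widened so relaxation is slow and incomplete.
``R``
    restrictive filling — passive diastolic stiffness of the LV free wall and
    septum is doubled.
``PN``
    pseudo-normal — both of the above.
``R_NSPT``
    restrictive filling with a normal septum (only the free wall stiffens).

Independently, systolic contractility may be augmented by 60 % (the
end-systolic elastances of the LV free wall and septum scale by 1.6),
mimicking the chronic myogenic compensation seen in HFNEF patients.
"""

from __future__ import annotations

import copy
import enum
import importlib.resources
from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

__all__ = [
    "WallId",
    "DDType",
    "PleuralMode",
    "GaussianTerm",
    "ActivationSpec",
    "WallParameters",
    "PericardiumParameters",
    "VascularCompartment",
    "ValveElement",
    "NeuralParameters",
    "ModelParameters",
    "ScenarioConfig",
    "load_default_parameters",
    "apply_scenario",
    "validate_parameters",
    "params_to_dict",
    "params_from_dict",
    "params_to_yaml",
    "params_from_yaml",
]


class WallId(str, enum.Enum):
    LVF = "LVF"
    RVF = "RVF"
    SPT = "SPT"
    LA = "LA"
    RA = "RA"


class DDType(str, enum.Enum):
    CONTROL = "CONTROL"
    IR = "IR"
    R = "R"
    PN = "PN"
    R_NSPT = "R_NSPT"


class PleuralMode(str, enum.Enum):
    #: pleural pressure held at -5 mmHg (suppresses respiratory variation)
    FIXED = "fixed_minus5"
    #: sinusoid between -2 and -6 mmHg, 7 s period (quiet breathing)
    SINUSOID = "sinusoid"


# --------------------------------------------------------------------------
# printed parameter tables (control values)
# --------------------------------------------------------------------------

#: Gaussian coefficients of the shared ventricular/septal activation function.
#: Rows: amplitude A (dimensionless), width B (s), center C (s).
VENTRICULAR_GAUSSIANS = {
    "A": (0.282, 0.075, 0.384, 0.205, 0.37, 0.516, 0.15),
    "B": (0.043, 0.03, 0.05, 0.04, 0.08, 0.06, 0.04),
    "C": (0.11, 0.165, 0.22, 0.3, 0.35, 0.395, 0.405),
}

#: Impaired-relaxation replacements (Gaussian index -> field -> value).
IR_GAUSSIAN_CHANGES = {5: {"A": 0.37}, 6: {"A": 0.249, "B": 0.35}}

#: Wall mechanics: E_ES (mmHg/ml), V_d (ml), P_0 (mmHg), lambda (1/ml), V_0 (ml)
WALL_TABLE = {
    "LVF": {"E_ES": 3.5, "V_d": 1.0, "P_0": 2.0, "lam": 0.025, "V_0": 1.0},
    "RVF": {"E_ES": 0.34, "V_d": 3.0, "P_0": 1.0, "lam": 0.01, "V_0": 3.0},
    "SPT": {"E_ES": 40.0, "V_d": 0.0, "P_0": 1.11, "lam": 0.05, "V_0": 0.0},
    "LA": {"E_ES": 2.5, "V_d": 7.0, "P_0": 2.0, "lam": 0.1, "V_0": 40.0},
    "RA": {"E_ES": 0.34, "V_d": 3.0, "P_0": 1.0, "lam": 0.1, "V_0": 30.0},
}

PERICARDIUM_TABLE = {"P_PERI0": 0.5, "lam_PERI": 0.005, "V_PERI0": 200.0,
                     "V_PERI_FLUID": 6.0}

#: Valve resistances, mmHg.s/ml
VALVE_TABLE = {"mitral": 0.007, "tricuspid": 0.0028,
               "aortic": 0.005, "pulmonic": 0.002}

#: Inter-compartment (edge) resistances, mmHg.s/ml
RESISTANCE_TABLE = {
    "R_AO_d": 0.015,    # proximal -> distal aorta
    "R_SA": 0.015,      # distal aorta -> systemic arteries
    "R_SA_d": 0.35,     # systemic arteries -> arterioles (vasomotor target)
    "R_SC": 0.4,        # arterioles -> capillaries
    "R_SVL": 0.2,       # capillaries -> venules
    "R_SV": 0.2,        # venules -> veins
    "R_VC": 0.026,      # veins -> vena cava
    "R_RA": 0.01,       # vena cava -> right atrium
    "R_PA_d": 0.002,    # proximal -> distal pulmonary artery
    "R_PA": 0.01,       # distal PA -> pulmonary arterioles
    "R_PC": 0.08,       # arterioles -> pulmonary capillaries
    "R_PV": 0.008,      # capillaries -> pulmonary veins
    "R_LA": 0.01,       # pulmonary veins -> left atrium
    "R_PS": 4.0,        # pulmonary A-V shunt (distal PA -> pulmonary veins)
    "R_COR": 35.0,      # coronary shunt (proximal aorta -> vena cava)
    "R_CRB": 16.0,      # cerebral shunt (proximal aorta -> vena cava)
    # viscoelastic (Kelvin) resistances in series with the compliances
    "R_TAO": 0.051,
    "R_TAO_d": 0.0125,
    "R_TPA": 0.035,
}

#: Compliances, ml/mmHg
COMPLIANCE_TABLE = {
    "AO_p": 2.4, "AO_d": 0.43, "SA": 0.092, "SA_d": 0.069, "SC": 0.8,
    "SVL": 0.6, "SV": 37.5, "VC": 4.0,
    "PA_p": 0.69, "PA_d": 0.64, "PA": 6.0, "PC": 2.1, "PV": 7.3,
}

#: Inertances, mmHg.s^2/ml (aortic valve, proximal->distal aorta, pulmonic valve)
INERTANCE_TABLE = {"L_AO_p": 0.0055, "L_AO_d": 0.0031, "L_PA": 0.00008}

#: Which compartments sit inside the thorax and feel pleural pressure.
THORACIC = {"AO_p", "VC", "PA_p", "PA_d", "PA", "PC", "PV"}

#: Control mean pulmonary volumes (ml) and absolute pressures (mmHg) used to
#: pin the unstressed volumes of the pulmonary compartments (the model's
#: pulmonary blood distribution is anchored to these operating values).
PULMONARY_OPERATING_POINT = {
    "PA_p": (20.4, 13.2), "PA_d": (21.1, 13.0), "PA": (201.1, 12.2),
    "PC": (94.9, 8.5), "PV": (226.9, 7.9),
}

#: Unstressed volumes (ml) of the systemic compartments.  Not printed in the
#: source tables: chosen so the control steady state carries ~5 l of blood at
#: MSAP ~ 96.6 mmHg with a physiologic venous reservoir.  The systemic venous
#: entry is the calibration reservoir for mean circulatory filling.
SYSTEMIC_UNSTRESSED = {
    "AO_p": 20.0, "AO_d": 120.0, "SA": 200.0, "SA_d": 150.0,
    "SC": 250.0, "SVL": 300.0, "SV": 2550.0, "VC": 100.0,
}

TOTAL_BLOOD_VOLUME = 5000.0  # ml

#: Steady-state operating points of the reflex loop for the four
#: normal-contractility columns (control, IR, R, PN).  The affine sensor and
#: efferent maps of the baroreflex are identified from these by least squares.
NEURAL_OPERATING_POINTS = {
    "MSAP": (96.6, 91.5, 89.0, 84.9),
    "F_b": (0.41, 0.39, 0.38, 0.36),
    "F_HRv": (0.54, 0.51, 0.50, 0.47),
    "F_HRs": (0.28, 0.33, 0.35, 0.39),
    "F_con": (0.40, 0.45, 0.49, 0.53),
    "F_vaso": (0.54, 0.62, 0.64, 0.70),
    "HR": (55.2, 60.2, 63.8, 68.2),
}


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

@dataclass
class GaussianTerm:
    """One Gaussian component of an activation function.

    ``A`` is the amplitude (dimensionless), ``B`` the 1/e half-width (s) and
    ``C`` the center offset from beat onset (s).
    """
    A: float
    B: float
    C: float


@dataclass
class ActivationSpec:
    """Sum-of-Gaussians activation e(t) for one contractile wall.

    ``normalization_scale`` rescales the raw Gaussian sum so the cycle
    maximum is exactly 1 (activation is a 0-1 weight).
    """
    wall_id: WallId
    terms: list[GaussianTerm]
    normalization_scale: float = 1.0


@dataclass
class WallParameters:
    """Static mechanics of one contractile wall.

    The end-systolic P-V relation is linear with slope ``E_ES`` (mmHg/ml) and
    zero-pressure volume ``V_d`` (ml); the end-diastolic relation is
    exponential, ``P_0 * (exp(lam*(V - V_0)) - 1)``.
    """
    E_ES: float
    V_d: float
    P_0: float
    lam: float
    V_0: float


@dataclass
class PericardiumParameters:
    P_PERI0: float      # mmHg
    lam_PERI: float     # 1/ml
    V_PERI0: float      # ml, zero-pressure pericardial volume
    V_PERI_FLUID: float  # ml of pericardial fluid added to heart volume


@dataclass
class VascularCompartment:
    """Linear compliant compartment: P = (V - V_un)/C + P_ext."""
    name: str
    C: float            # ml/mmHg
    V_un: float         # ml
    thoracic: bool      # external reference: pleural if True else body


@dataclass
class ValveElement:
    name: str
    R_open: float       # mmHg.s/ml


@dataclass
class NeuralParameters:
    """Baroreflex structure: sensor -> affine maps -> low-pass -> effectors.

    The printed steady-state operating points pin the affine coefficients;
    they are re-derived by least squares in :meth:`fit` rather than stored.
    ``k_alpha`` converts the contractility efferent into the inotropic factor
    alpha = max(1, 1 + k_alpha*(F_con - F_con_ref)) applied to ventricular
    end-systolic elastances.  ``k_vaso_R`` scales arteriolar resistance and
    ``k_vaso_V`` shifts venous unstressed volume with vasomotor tone.
    """
    baro_slope: float
    baro_intercept: float
    # per-limb affine maps F_b -> target and time constants (s)
    limb_slopes: dict[str, float]
    limb_intercepts: dict[str, float]
    limb_tau: dict[str, float]
    # chronotropic map HR = h0 + hs*F_HRs - hv*F_HRv (bpm)
    hr_h0: float
    hr_hs: float
    hr_hv: float
    tau_msap: float = 2.0
    k_alpha: float = 2.0
    F_con_ref: float = 0.40
    k_vaso_R: float = 12.0
    k_vaso_V: float = 500.0
    F_vaso_ref: float = 0.50
    K_f: float = 1.2  # documented baroreceptor constant (rate term omitted)

    @classmethod
    def fit(cls, points: dict[str, tuple[float, ...]] | None = None,
            **overrides) -> "NeuralParameters":
        """Identify the affine maps from steady-state operating points."""
        pts = points or NEURAL_OPERATING_POINTS
        msap = np.asarray(pts["MSAP"], dtype=float)
        fb = np.asarray(pts["F_b"], dtype=float)
        a_b, b_b = np.polyfit(msap, fb, 1)
        slopes, intercepts = {}, {}
        for limb in ("F_HRv", "F_HRs", "F_con", "F_vaso"):
            s, c = np.polyfit(fb, np.asarray(pts[limb], dtype=float), 1)
            slopes[limb] = float(s)
            intercepts[limb] = float(c)
        # HR = h0 + hs*F_HRs - hv*F_HRv, least squares over the four columns
        hrs = np.asarray(pts["F_HRs"], dtype=float)
        hrv = np.asarray(pts["F_HRv"], dtype=float)
        hr = np.asarray(pts["HR"], dtype=float)
        design = np.column_stack([np.ones_like(hr), hrs, -hrv])
        coef, *_ = np.linalg.lstsq(design, hr, rcond=None)
        taus = {"F_HRv": 0.5, "F_HRs": 2.0, "F_con": 2.0, "F_vaso": 2.0}
        return cls(baro_slope=float(a_b), baro_intercept=float(b_b),
                   limb_slopes=slopes, limb_intercepts=intercepts,
                   limb_tau=taus, hr_h0=float(coef[0]), hr_hs=float(coef[1]),
                   hr_hv=float(coef[2]), **overrides)


@dataclass
class ModelParameters:
    walls: dict[str, WallParameters]
    activations: dict[str, ActivationSpec]
    pericardium: PericardiumParameters
    compartments: dict[str, VascularCompartment]
    valves: dict[str, ValveElement]
    resistances: dict[str, float]
    inertances: dict[str, float]
    neural: NeuralParameters
    total_blood_volume: float = TOTAL_BLOOD_VOLUME
    pleural_mode: PleuralMode = PleuralMode.FIXED
    #: atrial activation: one Gaussian per atrium.  Widths (s), center offset
    #: before beat end (s) and peak amplitudes, calibrated so the control
    #: A waves, atrial filling fractions and venous S/D split are physiologic.
    la_width: float = 0.053
    ra_width: float = 0.092
    atrial_offset: float = 0.06
    la_amplitude: float = 1.0
    ra_amplitude: float = 1.0

    def copy(self) -> "ModelParameters":
        return copy.deepcopy(self)


@dataclass
class ScenarioConfig:
    """Which diastolic-dysfunction phenotype and run conditions to simulate."""
    dd_type: DDType = DDType.CONTROL
    contractility: str = "normal"           # or "increased"
    pleural_mode: PleuralMode = PleuralMode.FIXED
    duration: float = 60.0                  # maximum model time, s
    steady_state_tol: float = 0.005         # relative per-beat change
    clamp_neural: str | None = None         # None | 'con' | 'hr' | 'all'

    def __post_init__(self):
        self.dd_type = DDType(self.dd_type)
        self.pleural_mode = PleuralMode(self.pleural_mode)
        if self.contractility not in ("normal", "increased"):
            raise ValueError(f"unknown contractility {self.contractility!r}")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.steady_state_tol <= 0:
            raise ValueError("steady_state_tol must be positive")
        if self.clamp_neural not in (None, "con", "hr", "all"):
            raise ValueError(f"unknown clamp_neural {self.clamp_neural!r}")


# --------------------------------------------------------------------------
# construction
# --------------------------------------------------------------------------

def _ventricular_spec(wall: str) -> ActivationSpec:
    g = VENTRICULAR_GAUSSIANS
    terms = [GaussianTerm(A=g["A"][i], B=g["B"][i], C=g["C"][i])
             for i in range(7)]
    return ActivationSpec(wall_id=WallId(wall), terms=terms)


def _pulmonary_unstressed(pleural: float = -5.0) -> dict[str, float]:
    """Unstressed pulmonary volumes pinned to the control operating point."""
    out = {}
    for name, (v, p) in PULMONARY_OPERATING_POINT.items():
        out[name] = v - COMPLIANCE_TABLE[name] * (p - pleural)
    return out


def load_default_parameters() -> ModelParameters:
    """Build the control parameter set from the printed tables.

    Raises ``ValueError`` naming the offending entry if the assembled set
    fails the cross-check against the table constants.
    """
    walls = {k: WallParameters(**v) for k, v in WALL_TABLE.items()}
    activations = {w: _ventricular_spec(w) for w in ("LVF", "RVF", "SPT")}

    v_un = dict(SYSTEMIC_UNSTRESSED)
    v_un.update(_pulmonary_unstressed())
    compartments = {
        name: VascularCompartment(name=name, C=C, V_un=v_un[name],
                                  thoracic=name in THORACIC)
        for name, C in COMPLIANCE_TABLE.items()
    }
    valves = {k: ValveElement(name=k, R_open=v) for k, v in VALVE_TABLE.items()}

    params = ModelParameters(
        walls=walls,
        activations=activations,
        pericardium=PericardiumParameters(**PERICARDIUM_TABLE),
        compartments=compartments,
        valves=valves,
        resistances=dict(RESISTANCE_TABLE),
        inertances=dict(INERTANCE_TABLE),
        neural=NeuralParameters.fit(),
    )
    # normalize activations to peak 1 over one cycle
    from .activation import normalize_activation
    for w in params.activations:
        params.activations[w] = normalize_activation(params.activations[w])
    _crosscheck(params)
    return params


def _crosscheck(params: ModelParameters) -> None:
    """Verify the assembled set against the printed table constants."""
    def fail(name, got, want):
        raise ValueError(
            f"parameter table inconsistency: {name} = {got}, expected {want}")

    for wall, row in WALL_TABLE.items():
        for f, want in row.items():
            got = getattr(params.walls[wall], f)
            if got != want:
                fail(f"{wall}.{f}", got, want)
    for name, want in VALVE_TABLE.items():
        if params.valves[name].R_open != want:
            fail(f"valve {name}", params.valves[name].R_open, want)
    for name, want in RESISTANCE_TABLE.items():
        if params.resistances[name] != want:
            fail(name, params.resistances[name], want)
    for name, want in COMPLIANCE_TABLE.items():
        if params.compartments[name].C != want:
            fail(f"C_{name}", params.compartments[name].C, want)
    for i, (a, b, c) in enumerate(zip(*VENTRICULAR_GAUSSIANS.values())):
        t = params.activations["RVF"].terms[i]
        if (t.A, t.B, t.C) != (a, b, c):
            fail(f"RVF Gaussian {i + 1}", (t.A, t.B, t.C), (a, b, c))


# --------------------------------------------------------------------------
# scenarios
# --------------------------------------------------------------------------

def apply_scenario(params: ModelParameters,
                   scenario: ScenarioConfig) -> ModelParameters:
    """Return a new parameter set with the scenario perturbations applied.

    The input is never mutated.  Repeated application of the same scenario is
    idempotent, and the dd_type and contractility perturbations commute.
    """
    from .activation import normalize_activation

    out = params.copy()
    out.pleural_mode = scenario.pleural_mode
    dd = scenario.dd_type

    if dd in (DDType.IR, DDType.PN):
        for wall in ("LVF", "SPT"):
            spec = out.activations[wall]
            for idx, changes in IR_GAUSSIAN_CHANGES.items():
                for f, v in changes.items():
                    setattr(spec.terms[idx], f, v)
            out.activations[wall] = normalize_activation(spec)
    if dd in (DDType.R, DDType.PN):
        out.walls["LVF"].lam = 2.0 * WALL_TABLE["LVF"]["lam"]
        out.walls["SPT"].lam = 2.0 * WALL_TABLE["SPT"]["lam"]
    if dd is DDType.R_NSPT:
        out.walls["LVF"].lam = 2.0 * WALL_TABLE["LVF"]["lam"]
    if dd is DDType.CONTROL:
        pass

    if scenario.contractility == "increased":
        out.walls["LVF"].E_ES = 1.6 * WALL_TABLE["LVF"]["E_ES"]
        out.walls["SPT"].E_ES = 1.6 * WALL_TABLE["SPT"]["E_ES"]
    return out


# --------------------------------------------------------------------------
# validation
# --------------------------------------------------------------------------

def validate_parameters(params: ModelParameters) -> list[str]:
    """Collect invariant violations; empty list means the set is valid."""
    from .activation import activation_value, cycle_maximum

    bad: list[str] = []
    for name, w in params.walls.items():
        if not w.E_ES > 0:
            bad.append(f"wall {name}: E_ES must be > 0 (got {w.E_ES})")
        if not w.lam > 0:
            bad.append(f"wall {name}: lambda must be > 0 (got {w.lam})")
        if not w.P_0 > 0:
            bad.append(f"wall {name}: P_0 must be > 0 (got {w.P_0})")
    for name, spec in params.activations.items():
        for i, t in enumerate(spec.terms):
            if not t.B > 0:
                bad.append(f"activation {name} term {i + 1}: B must be > 0")
            if t.A < 0:
                bad.append(f"activation {name} term {i + 1}: A must be >= 0")
            if t.C < 0:
                bad.append(f"activation {name} term {i + 1}: C must be >= 0")
        if not any(bad_msg.startswith(f"activation {name}") for bad_msg in bad):
            peak = cycle_maximum(spec)
            if not (0.999 <= peak <= 1.001):
                bad.append(
                    f"activation {name}: normalized peak {peak:.4f} "
                    "outside [0.999, 1.001]")
    p = params.pericardium
    for f in ("P_PERI0", "lam_PERI", "V_PERI0"):
        if not getattr(p, f) > 0:
            bad.append(f"pericardium: {f} must be > 0")
    for name, c in params.compartments.items():
        if not c.C > 0:
            bad.append(f"compartment {name}: compliance must be > 0 (got {c.C})")
        if c.V_un < 0:
            bad.append(f"compartment {name}: V_un must be >= 0 (got {c.V_un})")
    for name, v in params.valves.items():
        if not v.R_open > 0:
            bad.append(f"valve {name}: R_open must be > 0 (got {v.R_open})")
    for name, r in params.resistances.items():
        if not r > 0:
            bad.append(f"resistance {name} must be > 0 (got {r})")
    if not params.total_blood_volume > 0:
        bad.append("total_blood_volume must be > 0")
    return bad


# --------------------------------------------------------------------------
# serialization (YAML dialect)
# --------------------------------------------------------------------------

def params_to_dict(params: ModelParameters) -> dict:
    d = {
        "walls": {k: asdict(v) for k, v in params.walls.items()},
        "activations": {
            k: {"wall_id": v.wall_id.value,
                "normalization_scale": v.normalization_scale,
                "terms": [asdict(t) for t in v.terms]}
            for k, v in params.activations.items()
        },
        "pericardium": asdict(params.pericardium),
        "compartments": {k: {"C": c.C, "V_un": c.V_un, "thoracic": c.thoracic}
                         for k, c in params.compartments.items()},
        "valves": {k: v.R_open for k, v in params.valves.items()},
        "resistances": dict(params.resistances),
        "inertances": dict(params.inertances),
        "neural": asdict(params.neural),
        "total_blood_volume": params.total_blood_volume,
        "pleural_mode": params.pleural_mode.value,
        "la_width": params.la_width,
        "ra_width": params.ra_width,
        "atrial_offset": params.atrial_offset,
        "la_amplitude": params.la_amplitude,
        "ra_amplitude": params.ra_amplitude,
    }
    return d


def params_from_dict(d: dict) -> ModelParameters:
    walls = {k: WallParameters(**v) for k, v in d["walls"].items()}
    activations = {
        k: ActivationSpec(wall_id=WallId(v["wall_id"]),
                          terms=[GaussianTerm(**t) for t in v["terms"]],
                          normalization_scale=v["normalization_scale"])
        for k, v in d["activations"].items()
    }
    compartments = {k: VascularCompartment(name=k, **v)
                    for k, v in d["compartments"].items()}
    valves = {k: ValveElement(name=k, R_open=r) for k, r in d["valves"].items()}
    return ModelParameters(
        walls=walls, activations=activations,
        pericardium=PericardiumParameters(**d["pericardium"]),
        compartments=compartments, valves=valves,
        resistances=dict(d["resistances"]), inertances=dict(d["inertances"]),
        neural=NeuralParameters(**d["neural"]),
        total_blood_volume=d["total_blood_volume"],
        pleural_mode=PleuralMode(d["pleural_mode"]),
        la_width=d["la_width"], ra_width=d["ra_width"],
        atrial_offset=d["atrial_offset"],
        la_amplitude=d["la_amplitude"], ra_amplitude=d["ra_amplitude"],
    )


def params_to_yaml(params: ModelParameters, path=None) -> str:
    text = yaml.safe_dump(params_to_dict(params), sort_keys=False)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def params_from_yaml(source) -> ModelParameters:
    if hasattr(source, "read"):
        d = yaml.safe_load(source)
    else:
        try:
            with open(source) as fh:
                d = yaml.safe_load(fh)
        except (OSError, ValueError):
            d = yaml.safe_load(source)
    return params_from_dict(d)


def default_config_text() -> str:
    """The shipped default configuration file."""
    ref = importlib.resources.files("cardioloop").joinpath("data/defaults.yaml")
    return ref.read_text()
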