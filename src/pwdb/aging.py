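"""Aging model of the virtual population.

Encodes the literature-derived per-decade means and SDs of the model input
parameters (25-75 yr), interpolates them to arbitrary ages, derives subject
configurations on the +/-1 SD grid of the six strongly PW-influencing
parameters (HR, SV, LVET, large-artery diameter, PWV, MAP), calibrates the
wall-stiffness constants to the age's target pulse wave velocities and the
outlet resistances/compliances to the age's target MAP and peripheral
compliance, and screens simulated subjects for physiologically plausible
blood pressures.

Parameter coupling rules:

* LVET covaries with HR and SV through the empirical regression
  LVET = 244 - 0.926*HR + 1.08*SV (ms), applied in deviation form about the
  age mean before LVET's own +/-1 SD offset.
* The aortic PWV target depends on the subject's MAP (stiffer effective wall
  at higher distending pressure); a linear sensitivity [m/s per mmHg] scales
  all three regional targets coherently.
* One "diameter" factor moves all age-varying diameters (aortic segments and
  carotid) together by their age-specific SDs; one "PWV" factor moves the
  aortic/arm/leg targets together (with possibly asymmetric SDs).
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
from scipy.interpolate import CubicSpline, PchipInterpolator
from scipy.optimize import brentq, least_squares

from . import units
from .errors import CalibrationError, ConfigError, DomainError, ParameterError
from .inflow import lvet_from_hr_sv
from .network import Network, wave_speed

__all__ = [
    "AgingParameterSet",
    "SubjectConfig",
    "PlausibilityReference",
    "load_aging_tables",
    "aging_parameters",
    "apply_offsets",
    "calibrate_stiffness",
    "calibrate_stiffness_for_network",
    "calibrate_resistances",
    "generate_grid",
    "plausibility_filter",
    "load_plausibility_reference",
]

AGE_MIN, AGE_MAX = 25.0, 75.0

#: fixed enumeration order of the six varied parameters
VARIED_PARAMETERS = ("HR", "SV", "LVET", "diameter", "PWV", "MAP")

#: component tables moved by the single "diameter" grid factor
DIAMETER_COMPONENTS = (
    "diameter_ascending", "diameter_desc_thoracic",
    "diameter_abdominal", "diameter_carotid",
)
PWV_COMPONENTS = ("pwv_aortic", "pwv_arm", "pwv_leg")


def _data_text(name: str) -> str:
    return resources.files("pwdb.data").joinpath(name).read_text()


def load_aging_tables(source=None) -> dict:
    """Load the per-decade anchor tables (bundled by default)."""
    if source is None:
        return json.loads(_data_text("aging_tables.json"))
    if isinstance(source, dict):
        return source
    return json.loads(Path(source).read_text())


@dataclass
class AgingParameterSet:
    """Interpolated means/SDs of every model input parameter at one age."""

    age: float
    params: dict  # name -> {"mean": x, "sd_plus": s+, "sd_minus": s-}
    varied: tuple = VARIED_PARAMETERS
    pwv_map_sensitivity: float = 0.04  # m/s per mmHg

    def mean(self, name: str) -> float:
        return self.params[name]["mean"]

    def sd(self, name: str, sign: int = 1) -> float:
        p = self.params[name]
        return p["sd_plus"] if sign >= 0 else p["sd_minus"]


@dataclass
class SubjectConfig:
    """One virtual subject: age, grid offsets, derived absolute parameters."""

    age: float
    offsets: dict = field(default_factory=dict)  # varied name -> -1 | 0 | +1
    values: dict = field(default_factory=dict)  # parameter -> absolute value

    @property
    def is_baseline(self) -> bool:
        return all(v == 0 for v in self.offsets.values())

    def label(self) -> str:
        key = "".join({-1: "m", 0: "0", 1: "p"}[self.offsets.get(p, 0)]
                      for p in VARIED_PARAMETERS)
        return f"age{int(self.age)}_{key}"


def _interpolate(ages, values, age, kind):
    ages = np.asarray(ages, dtype=float)
    values = np.asarray(values, dtype=float)
    if kind == "pchip":
        return float(PchipInterpolator(ages, values)(age))
    if kind == "cubic":
        return float(CubicSpline(ages, values)(age))
    return float(np.interp(age, ages, values))


def aging_parameters(age: float, tables: dict | None = None) -> AgingParameterSet:
    """Interpolate the per-decade anchors to ``age`` (25-75 yr).

    Decade anchors are reproduced exactly.  HR uses shape-preserving (PCHIP)
    interpolation, the MAP mean a cubic spline with linear SDs; all other
    parameters are linear.
    """
    if not AGE_MIN <= age <= AGE_MAX:
        raise DomainError(f"age {age} outside the modeled range "
                          f"[{AGE_MIN:g}, {AGE_MAX:g}] yr")
    tables = load_aging_tables(tables)
    ages = tables["ages"]
    out = {}
    for name, spec in tables["parameters"].items():
        kind_mean = spec.get("interp_mean", spec.get("interp", "linear"))
        kind_sd = spec.get("interp_sd", "linear")
        mean = _interpolate(ages, spec["mean"], age, kind_mean)
        if "sd" in spec:
            sd_p = sd_m = _interpolate(ages, spec["sd"], age, kind_sd)
        else:
            sd_p = _interpolate(ages, spec["sd_plus"], age, kind_sd)
            sd_m = _interpolate(ages, spec["sd_minus"], age, kind_sd)
        if sd_p < 0 or sd_m < 0:
            raise ConfigError(f"negative SD for parameter {name!r}")
        out[name] = {"mean": mean, "sd_plus": sd_p, "sd_minus": sd_m}
    return AgingParameterSet(
        age=float(age), params=out, varied=tuple(tables["varied"]),
        pwv_map_sensitivity=float(tables.get("pwv_map_sensitivity", 0.04)),
    )


def apply_offsets(params: AgingParameterSet, offsets: dict,
                  lvet_mode: str = "deviation") -> SubjectConfig:
    """Derive a subject's absolute parameter values from grid offsets.

    ``offsets`` maps varied-parameter names to -1/0/+1 (missing names mean
    0).  Coupling rules: the LVET mean is first shifted by the HR/SV
    regression deltas (deviation mode; ``lvet_mode="absolute"`` evaluates the
    regression directly), then LVET's own offset applies; the PWV targets
    are evaluated at the subject's MAP through the linear MAP sensitivity.
    """
    for k, v in offsets.items():
        if k not in VARIED_PARAMETERS:
            raise ParameterError(f"offsets allowed only on {VARIED_PARAMETERS}, "
                                 f"got {k!r}")
        if v not in (-1, 0, 1):
            raise ParameterError(f"offset for {k!r} must be -1, 0 or +1")
    off = {p: offsets.get(p, 0) for p in VARIED_PARAMETERS}

    def moved(name, o):
        return params.mean(name) + o * params.sd(name, o)

    vals = {}
    vals["HR"] = moved("HR", off["HR"])
    vals["SV"] = moved("SV", off["SV"])
    if lvet_mode == "deviation":
        d_hr = vals["HR"] - params.mean("HR")
        d_sv = vals["SV"] - params.mean("SV")
        lvet_mean = params.mean("LVET") - 0.926 * d_hr + 1.08 * d_sv
    elif lvet_mode == "absolute":
        lvet_mean = lvet_from_hr_sv(vals["HR"], vals["SV"])
    else:
        raise ParameterError(f"unknown lvet_mode {lvet_mode!r}")
    vals["LVET"] = lvet_mean + off["LVET"] * params.sd("LVET", off["LVET"])
    vals["MAP"] = moved("MAP", off["MAP"])
    for name in DIAMETER_COMPONENTS:
        vals[name] = moved(name, off["diameter"])
    # PWV targets at the subject's MAP: shift the aortic target linearly,
    # scale the arm/leg targets by the same ratio
    pwv_a = moved("pwv_aortic", off["PWV"])
    pwv_a_adj = pwv_a + params.pwv_map_sensitivity * (vals["MAP"] - params.mean("MAP"))
    ratio = pwv_a_adj / pwv_a
    vals["pwv_aortic"] = pwv_a_adj
    vals["pwv_arm"] = moved("pwv_arm", off["PWV"]) * ratio
    vals["pwv_leg"] = moved("pwv_leg", off["PWV"]) * ratio
    for name in ("PFT", "RFV", "DBP", "proximal_aortic_length", "pvc"):
        vals[name] = params.mean(name)
    return SubjectConfig(age=params.age, offsets=off, values=vals)


# ---------------------------------------------------------------------------
# Calibration
# ---------------------------------------------------------------------------

_K_X0 = np.array([np.log(2.0e6), -2253.0, np.log(8.65e4)])  # SI-scale start


def _cd_from_k(x, Rd):
    """Wave speed at radius Rd from fit vector x = (ln k1, k2, ln k3)."""
    k1, k2, k3 = np.exp(x[0]), x[1], np.exp(x[2])
    return np.sqrt(2.0 * (k1 * np.exp(k2 * Rd) + k3) / (3.0 * 1060.0))


def _fit_k(residual_fn) -> tuple:
    fit = least_squares(residual_fn, _K_X0, method="lm", xtol=1e-14, ftol=1e-14)
    if not fit.success:
        raise CalibrationError("stiffness calibration did not converge",
                               residuals=fit.fun)
    k1, k2, k3 = float(np.exp(fit.x[0])), float(fit.x[1]), float(np.exp(fit.x[2]))
    return (k1, k2, k3), fit.fun


def calibrate_stiffness(pwv_targets: dict, anchor_radii: dict,
                        density: float = 1060.0):
    """Fit (k1, k2, k3) of the stiffness law so the theoretical wave speed at
    each anchor radius matches its regional PWV target.

    ``pwv_targets`` and ``anchor_radii`` share keys (e.g. aortic/arm/leg).
    Note c_d depends on radius only through k1*exp(k2*Rd) + k3, so the fit is
    a three-point exponential interpolation; the residuals (m/s per anchor)
    are returned alongside the SI constants.  Deterministic for a fixed
    built-in initial guess.
    """
    keys = sorted(pwv_targets)
    if sorted(anchor_radii) != keys:
        raise ParameterError("pwv_targets and anchor_radii keys must match")
    R = np.array([anchor_radii[k] for k in keys], dtype=float)
    c = np.array([pwv_targets[k] for k in keys], dtype=float)
    if np.any(R <= 0) or np.any(c <= 0):
        raise DomainError("anchor radii and PWV targets must be > 0")
    y = 1.5 * density * c**2  # k1*exp(k2*R) + k3 target

    def resid(x):
        k1, k2, k3 = np.exp(x[0]), x[1], np.exp(x[2])
        return (k1 * np.exp(k2 * R) + k3 - y) / (3.0 * density * c)

    (k1, k2, k3), fun = _fit_k(resid)
    achieved = wave_speed(R * (k1 * np.exp(k2 * R) + k3), R, density)
    return (k1, k2, k3), dict(zip(keys, achieved - c))


def calibrate_stiffness_for_network(
        network: Network, subject_values: dict, aortic_path: list[str],
        arm_anchor_radius: float, leg_anchor_radius: float,
        density: float | None = None):
    """Fit (k1, k2, k3) so the transit-time wave speed along the aortic path
    matches the aortic PWV target, with arm/leg point anchors.

    A foot-to-foot measurement over a tapered path observes the
    harmonic-mean wave speed L / sum(dx/c_d), not c_d at any single radius,
    so the aortic target constrains that path integral over the network's
    actual geometry.  Returns the SI constants and the residual vector
    (m/s): [path PWV error, arm anchor error, leg anchor error].
    """
    rho = density if density is not None else network.blood.density
    seg_r = []
    seg_dx = []
    for sid in aortic_path:
        seg = network.segments[sid]
        r = seg.node_radii()
        rmid = 0.5 * (r[1:] + r[:-1])
        seg_r.append(rmid)
        seg_dx.append(np.full(rmid.size, seg.dx))
    rr = np.concatenate(seg_r)
    dd = np.concatenate(seg_dx)
    L = float(np.sum(dd))
    t_a = subject_values["pwv_aortic"]
    t_arm = subject_values["pwv_arm"]
    t_leg = subject_values["pwv_leg"]

    def resid(x):
        k1, k2, k3 = np.exp(x[0]), x[1], np.exp(x[2])

        def cd(R):
            return np.sqrt(2.0 * (k1 * np.exp(k2 * R) + k3) / (3.0 * rho))

        pwv_path = L / np.sum(dd / cd(rr))
        return np.array([
            pwv_path - t_a,
            cd(arm_anchor_radius) - t_arm,
            cd(leg_anchor_radius) - t_leg,
        ])

    (k1, k2, k3), fun = _fit_k(resid)
    return (k1, k2, k3), fun


def calibrate_resistances(MAP_target: float, CO: float, P_out: float,
                          network: Network, pvc_total: float,
                          beds: dict[str, list[str]] | None = None) -> Network:
    """Scale the outlet windkessels so the simulated MAP lands on target.

    ``MAP_target`` and ``P_out`` in mmHg, ``CO`` in l/min, ``pvc_total`` in
    m^3/Pa.  The required total resistance is R_T = (MAP - P_out)/CO.  Bed
    totals are scaled uniformly from their baseline proportions (a scalar
    root-find on the tree's equivalent resistance, which includes the
    Poiseuille resistance of the segments so no post-hoc iteration is
    needed); within each multi-outlet bed the total is split with per-outlet
    resistance inversely proportional to the branch's luminal area.  R1 is
    held at the terminal segment's characteristic impedance; compliances are
    distributed proportional to 1/R2 and normalized to ``pvc_total``.
    Mutates and returns ``network``.
    """
    if CO <= 0:
        raise ParameterError("cardiac output must be > 0")
    R_T = (MAP_target - P_out) * units.MMHG_PA / (CO * units.LMIN_M3S)
    if R_T <= 0:
        raise ParameterError("MAP target must exceed the outflow pressure")
    rho = network.blood.density
    p_out_pa = P_out * units.MMHG_PA

    # per-outlet baseline totals, redistributed inside beds by the 1/A rule
    base_total = {o.segment_id: o.R1 + o.R2 for o in network.outlets}
    if beds:
        for members in beds.values():
            bed_R = 1.0 / sum(1.0 / base_total[m] for m in members)
            areas = {m: np.pi * network.segments[m].outlet_radius**2
                     for m in members}
            area_sum = sum(areas.values())
            for m in members:
                # R_m proportional to 1/A_m with parallel total = bed_R
                base_total[m] = bed_R * area_sum / areas[m]
    # characteristic impedance of each terminal segment
    z_char = {}
    for o in network.outlets:
        seg = network.segments[o.segment_id]
        r_t = seg.outlet_radius
        Ad = np.pi * r_t**2
        Eh = r_t * (seg.k1 * np.exp(seg.k2 * r_t) + seg.k3)
        cd = wave_speed(Eh, r_t, rho)
        z_char[o.segment_id] = rho * cd / Ad

    def apply_scale(s):
        for o in network.outlets:
            total = s * base_total[o.segment_id]
            o.R1 = z_char[o.segment_id]
            o.R2 = max(total - o.R1, 0.05 * total)
            o.P_out = p_out_pa

    def objective(s):
        apply_scale(s)
        return network.equivalent_resistance() - R_T

    # compliances: baseline proportions rescaled so the total equals the
    # age's peripheral vascular compliance (captured before R scaling)
    c_base = np.array([o.C for o in network.outlets])
    s = brentq(objective, 1e-3, 1e3, xtol=1e-12, rtol=1e-12)
    apply_scale(s)
    c_each = pvc_total * c_base / c_base.sum()
    for o, c in zip(network.outlets, c_each):
        o.C = float(c)
    return network


def generate_grid(ages, tables: dict | None = None,
                  varied: tuple = VARIED_PARAMETERS,
                  lvet_mode: str = "deviation") -> list[SubjectConfig]:
    """Enumerate the full +/-1 SD grid: 3^len(varied) subjects per age.

    Ordering is deterministic: ages in the given order; within an age,
    offsets iterate in the fixed parameter order (HR, SV, LVET, diameter,
    PWV, MAP) with the offset of the last parameter varying fastest, each in
    the order (-1, 0, +1).  The all-zero (baseline) subject is a grid member.
    """
    try:
        ages = list(ages)
    except TypeError:
        ages = [ages]
    tables = load_aging_tables(tables)
    subjects = []
    for age in ages:
        params = aging_parameters(age, tables)
        for combo in itertools.product((-1, 0, 1), repeat=len(varied)):
            offsets = dict(zip(varied, combo))
            subjects.append(apply_offsets(params, offsets, lvet_mode=lvet_mode))
    return subjects


# ---------------------------------------------------------------------------
# Plausibility filter
# ---------------------------------------------------------------------------

FILTER_QUANTITIES = (
    "aortic_SBP", "aortic_DBP", "aortic_MAP", "aortic_PP",
    "brachial_SBP", "brachial_DBP", "brachial_MAP", "brachial_PP", "PP_amp",
)
CONFIDENCE_SD = 2.575  # 99% two-sided normal band


@dataclass
class PlausibilityReference:
    """Per-age reference BP statistics; linear interpolation between decades."""

    ages: np.ndarray
    quantities: dict  # name -> {"mean": array, "sd": array}

    @classmethod
    def bundled(cls) -> "PlausibilityReference":
        raw = json.loads(_data_text("plausibility_reference.json"))
        return cls(ages=np.asarray(raw["ages"], dtype=float),
                   quantities={k: {kk: np.asarray(vv, dtype=float)
                                   for kk, vv in v.items()}
                               for k, v in raw["quantities"].items()})

    def interval(self, quantity: str, age: float) -> tuple[float, float]:
        q = self.quantities[quantity]
        mean = float(np.interp(age, self.ages, q["mean"]))
        sd = float(np.interp(age, self.ages, q["sd"]))
        return mean - CONFIDENCE_SD * sd, mean + CONFIDENCE_SD * sd


def load_plausibility_reference(source=None) -> PlausibilityReference:
    if source is None:
        return PlausibilityReference.bundled()
    raw = json.loads(Path(source).read_text()) if not isinstance(source, dict) else source
    return PlausibilityReference(
        ages=np.asarray(raw["ages"], dtype=float),
        quantities={k: {kk: np.asarray(vv, dtype=float) for kk, vv in v.items()}
                    for k, v in raw["quantities"].items()})


def plausibility_filter(bp_summary: dict, reference: PlausibilityReference,
                        age: float) -> dict:
    """Screen one subject's BP summary against the 99% reference band.

    ``bp_summary`` must hold all nine quantities (mmHg; PP_amp a ratio).  A
    subject is plausible iff every quantity lies inside the closed interval
    [mean - 2.575 sd, mean + 2.575 sd]; boundary values are plausible.
    Returns {"plausible": bool, "violations": [names]}.
    """
    missing = [q for q in FILTER_QUANTITIES if q not in bp_summary]
    if missing:
        raise ParameterError(f"BP summary missing quantities: {missing}")
    violations = []
    for q in FILTER_QUANTITIES:
        lo, hi = reference.interval(q, age)
        if not lo <= bp_summary[q] <= hi:
            violations.append(q)
    return {"plausible": not violations, "violations": violations}
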