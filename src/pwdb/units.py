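"""Unit conversions.

All internal computation is in SI (m, s, kg, Pa). The empirical wall-law
constants from the hemodynamics literature are conventionally quoted in CGS
(g, cm, s); they are converted to SI at the configuration boundary by the
helpers below and never mixed inside the solver.
"""

MMHG_PA = 133.322
"""Pa per mmHg (fixed external reporting convention)."""

#: SI value of 1 g s^-2 cm^-1 (unit of the stiffness-law constants k1, k3).
#: 1 g s^-2 cm^-1 = 1e-3 kg s^-2 / 1e-2 m = 0.1 N/m^2.
K13_CGS_SI = 0.1

#: SI value of 1 cm^-1 (unit of the stiffness-law exponent constant k2).
K2_CGS_SI = 100.0

#: SI value of 1 g/s (unit of the wall-viscosity intercept b0 and of Gamma).
B0_CGS_SI = 1e-3

#: SI value of 1 g cm s^-1 (unit of the wall-viscosity slope b1).
B1_CGS_SI = 1e-5

ML_M3 = 1e-6
LMIN_M3S = 1e-3 / 60.0
"""m^3/s per l/min."""


def mmhg_to_pa(p: float) -> float:
    return p * MMHG_PA


def pa_to_mmhg(p: float) -> float:
    return p / MMHG_PA


def stiffness_constants_to_si(k1_cgs: float, k2_cgs: float, k3_cgs: float):
    """Convert (k1, k2, k3) of the Eh(Rd) law from CGS to SI.

    In CGS the law reads Eh[g/s^2] = Rd[cm] * (k1*exp(k2*Rd[cm]) + k3) with
    k1, k3 in g s^-2 cm^-1 and k2 in cm^-1.  The SI form uses Rd in m and
    yields Eh in N/m.
    """
    return k1_cgs * K13_CGS_SI, k2_cgs * K2_CGS_SI, k3_cgs * K13_CGS_SI


def stiffness_constants_to_cgs(k1_si: float, k2_si: float, k3_si: float):
    return k1_si / K13_CGS_SI, k2_si / K2_CGS_SI, k3_si / K13_CGS_SI


def wall_viscosity_constants_to_si(b0_cgs: float, b1_cgs: float):
    """Convert (b0 [g/s], b1 [g cm/s]) of the Gamma(Rd) law to SI (kg/s, kg m/s)."""
    return b0_cgs * B0_CGS_SI, b1_cgs * B1_CGS_SI
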