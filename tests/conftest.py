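"""Shared fixtures.

The expensive full-pipeline simulations (six baseline ages; the
single-parameter cohort of the cardiac-output study) are session-scoped so
each is run exactly once per test session.
"""

import math

import numpy as np
import pytest

from pwdb.aging import aging_parameters, apply_offsets
from pwdb.analysis import index_report
from pwdb.fixtures import reference_subject
from pwdb.network import (ArterialSegment, BloodProperties, MeasurementSite,
                          Network, WindkesselOutlet, wall_stiffness, wave_speed)
from pwdb.pipeline import simulate_virtual_subject

AGES = (25, 35, 45, 55, 65, 75)


@pytest.fixture(scope="session")
def age_sweep():
    """Baseline subject of each decade, simulated to periodicity.

    Returns {age: (subject, pulse_wave_set, network, index_row)}.
    """
    out = {}
    for age in AGES:
        subject = reference_subject(age)
        pws, net = simulate_virtual_subject(subject)
        out[age] = (subject, pws, net, index_report(pws, net))
    return out


@pytest.fixture(scope="session")
def co_study_records(age_sweep):
    """Records for the CO-monitoring study: per age, the baseline plus the
    six single-parameter subjects (HR, SV, MAP at -1/+1 SD)."""
    records = []
    for age in AGES:
        subject, pws, _, _ = age_sweep[age]
        records.append({"age": age, "group": "baseline",
                        "radial": pws["radial"]["P"],
                        "co_ref": subject.values["HR"] * subject.values["SV"] * 1e-3})
        params = aging_parameters(age)
        for p in ("HR", "SV", "MAP"):
            for o in (-1, +1):
                s = apply_offsets(params, {p: o})
                pws_o, _ = simulate_virtual_subject(s)
                records.append({
                    "age": age, "group": "CO" if p in ("HR", "SV") else "MAP",
                    "radial": pws_o["radial"]["P"],
                    "co_ref": s.values["HR"] * s.values["SV"] * 1e-3})
    return records


def single_tube_network(length=1.0, radius=0.0135, n_nodes=0, cd_target=6.0,
                        Pd=80.0 * 133.322, matched=True, C=1e-9,
                        gamma_off=True, sites=(0.1, 0.9)):
    """A uniform elastic tube with a windkessel outlet, closed-form c_d."""
    rho = 1060.0
    k3 = 1.5 * rho * cd_target**2  # Eh = Rd*k3 -> c_d = cd_target exactly
    seg = ArterialSegment(id="tube", length=length, inlet_radius=radius,
                          outlet_radius=radius, k1=0.0, k2=-1.0, k3=k3,
                          b0=0.0 if gamma_off else 0.6,
                          b1=0.0 if gamma_off else 1.5e-3, n_nodes=n_nodes)
    Ad = math.pi * radius**2
    cd = wave_speed(wall_stiffness(radius, 0.0, -1.0, k3), radius, rho)
    Zc = rho * cd / Ad
    R1 = Zc if matched else 0.2 * Zc
    outlet = WindkesselOutlet(segment_id="tube", R1=R1, R2=10 * Zc, C=C,
                              P_out=Pd)
    site_map = {f"s{i}": MeasurementSite(f"s{i}", "tube", frac)
                for i, frac in enumerate(sites)}
    net = Network(segments={"tube": seg}, junctions={}, outlets=[outlet],
                  inlet_segment="tube", sites=site_map,
                  blood=BloodProperties(), diastolic_pressure=Pd)
    return net, cd


def gaussian_pulse_inflow(T=1.0, fs=4000.0, center=0.08, width=0.02,
                          amplitude=2e-6):
    from pwdb.inflow import Waveform
    t = np.arange(int(T * fs)) / fs
    q = amplitude * np.exp(-(((t - center) / width) ** 2))
    return Waveform(t=t, y=q, kind="Q")
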