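"""End-to-end simulation of one virtual subject.

Chains the aging model, geometry construction, stiffness and resistance
calibration, inflow generation and the 1D solver into a single call.
"""

from __future__ import annotations

from . import units
from .aging import (SubjectConfig, calibrate_resistances,
                    calibrate_stiffness_for_network)
from .fixtures import (AORTIC_PATH, ARM_ANCHOR_RADIUS, BEDS, EH_SCALE,
                       LEG_ANCHOR_RADIUS, make_fixture_network)
from .inflow import InflowParams, generate_inflow
from .network import Network
from .solver import PulseWaveSet, SolverOptions, simulate_subject

__all__ = ["simulate_virtual_subject", "prepare_network", "subject_inflow"]

#: inflow waveform sampling rate handed to the solver [Hz]; finer than the
#: 500-Hz output grid so the prescribed boundary flow is smooth at solver dt
INFLOW_FS = 2000.0


def prepare_network(subject: SubjectConfig) -> Network:
    """Build and fully calibrate the reduced network for one subject."""
    net = make_fixture_network("reduced", subject=subject)
    (k1, k2, k3), _ = calibrate_stiffness_for_network(
        net, subject.values, list(AORTIC_PATH),
        ARM_ANCHOR_RADIUS, LEG_ANCHOR_RADIUS)
    for seg in net.segments.values():
        s = EH_SCALE.get(seg.id, 1.0)
        seg.k1, seg.k2, seg.k3 = s * k1, k2, s * k3
    co_lmin = subject.values["HR"] * subject.values["SV"] * 1e-3
    calibrate_resistances(
        MAP_target=subject.values["MAP"], CO=co_lmin, P_out=0.0,
        network=net, pvc_total=subject.values["pvc"] * 1e-9, beds=BEDS)
    return net


def subject_inflow(subject: SubjectConfig, fs: float = INFLOW_FS):
    v = subject.values
    params = InflowParams(HR=v["HR"], SV=v["SV"], LVET=v["LVET"],
                          PFT=v["PFT"], RFV=v["RFV"], fs=fs)
    return generate_inflow(params)


def simulate_virtual_subject(
        subject: SubjectConfig,
        options: SolverOptions | None = None) -> tuple[PulseWaveSet, Network]:
    """Simulate one virtual subject to periodicity.

    Returns the converged pulse-wave set and the calibrated network (whose
    outlet states reflect the end of the run).
    """
    net = prepare_network(subject)
    inflow = subject_inflow(subject)
    result = simulate_subject(net, inflow, options=options)
    result.meta["subject"] = {"age": subject.age, "offsets": dict(subject.offsets),
                              "values": dict(subject.values)}
    return result, net
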