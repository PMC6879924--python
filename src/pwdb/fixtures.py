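"""Deterministic anatomically shaped fixture networks.

The reduced network covers the main pulse-propagation paths of the systemic
arterial tree in ~13 segments: the aorta in four tapering pieces (ascending,
arch, descending thoracic, abdominal), a head path (common carotid to a
temporal terminal), an arm path (subclavian-brachial splitting into radial
and ulnar), a leg path (iliac-femoral to a tibial terminal), and short
splanchnic/pelvic trunks carrying the visceral beds.  Geometry is scaled per
subject: the aortic and carotid diameters and the proximal aortic length
follow the aging model; peripheral geometry is age-invariant.

Baseline vascular-bed flow fractions (used only as resistance proportions;
absolute resistances are recalibrated to the subject's MAP):
head 0.04, arm 0.06 (radial/ulnar split by luminal area), splanchnic 0.50,
pelvic 0.34, leg 0.06.  (With single head/arm/leg paths the visceral trunks
absorb the flow that anatomically passes through the contralateral and
deep branches, keeping mean velocities physiological.)
"""

from __future__ import annotations

import math

from . import units
from .aging import SubjectConfig, aging_parameters, apply_offsets
from .errors import ParameterError
from .network import (ArterialSegment, BloodProperties, MeasurementSite,
                      Network, WindkesselOutlet)

__all__ = ["make_fixture_network", "AORTIC_PATH", "BEDS",
           "ARM_ANCHOR_RADIUS", "LEG_ANCHOR_RADIUS", "reference_subject"]

#: segments traversed by the aortic-root -> iliac-bifurcation PWV path
AORTIC_PATH = ("asc_aorta", "aortic_arch", "desc_thoracic", "abdominal_aorta")

#: vascular beds (terminal segment groups) for resistance splitting
BEDS = {
    "head": ["head_temporal"],
    "arm": ["radial", "ulnar"],
    "splanchnic": ["splanchnic"],
    "pelvic": ["pelvic"],
    "leg": ["tibial"],
}

BED_FLOW_FRACTIONS = {"head": 0.04, "arm": 0.06, "splanchnic": 0.50,
                      "pelvic": 0.34, "leg": 0.06}

#: representative diastolic radii of the arm and leg PWV anchor arteries [m]
ARM_ANCHOR_RADIUS = 0.0020
LEG_ANCHOR_RADIUS = 0.0025

#: wall-stiffness scale of the equivalent-compliance visceral trunks.
#: The reduced network lumps away ~100 conduit arteries whose summed volume
#: compliance (~3e-9 m^3/Pa at 25 yr) otherwise vanishes from the model and
#: inflates central pulse pressure.  The splanchnic and pelvic trunks lie on
#: no PWV measurement path, so their walls are softened to carry the
#: compliance of the vascular territories they stand in for.
EH_SCALE = {"splanchnic": 0.10, "pelvic": 0.10}

#: baseline compliance proportions of the vascular beds.  The visceral beds
#: hold nearly all peripheral compliance; the distal limb/head beds get tiny
#: shares so their windkessel volume (the PPG source) tracks the local
#: pressure wave instead of integrating it away.
BED_COMPLIANCE_FRACTIONS = {"head": 0.0008, "arm": 0.0004, "splanchnic": 0.608,
                            "pelvic": 0.39, "leg": 0.0008}

# 25-yr baseline geometry: (length m, inlet radius m, outlet radius m,
# diameter-scaling parameter or None)
_REDUCED_GEOMETRY = {
    "asc_aorta": (0.032, 0.01835, 0.01650, "diameter_ascending"),
    "aortic_arch": (0.048, 0.01650, 0.01400, "diameter_ascending"),
    "desc_thoracic": (0.160, 0.01400, 0.01100, "diameter_desc_thoracic"),
    "abdominal_aorta": (0.140, 0.01100, 0.00725, "diameter_abdominal"),
    "carotid": (0.150, 0.00310, 0.00280, "diameter_carotid"),
    "head_temporal": (0.120, 0.00160, 0.00120, None),
    "subclavian_brachial": (0.420, 0.00450, 0.00250, None),
    "radial": (0.250, 0.00180, 0.00150, None),
    "ulnar": (0.250, 0.00180, 0.00150, None),
    "splanchnic": (0.200, 0.00500, 0.00400, None),
    "pelvic": (0.200, 0.00450, 0.00360, None),
    "iliac_femoral": (0.400, 0.00400, 0.00280, None),
    "tibial": (0.350, 0.00220, 0.00180, None),
}

_REDUCED_JUNCTIONS = {
    "asc_aorta": ["aortic_arch", "subclavian_brachial"],
    "aortic_arch": ["carotid", "desc_thoracic"],
    "carotid": ["head_temporal"],
    "subclavian_brachial": ["radial", "ulnar"],
    "desc_thoracic": ["splanchnic", "abdominal_aorta"],
    "abdominal_aorta": ["pelvic", "iliac_femoral"],
    "iliac_femoral": ["tibial"],
}

_REDUCED_SITES = [
    ("aortic_root", "asc_aorta", 0.0, None),
    ("carotid", "carotid", 0.5, None),
    ("brachial", "subclavian_brachial", 0.85, None),
    ("radial", "radial", 0.9, None),
    ("femoral", "iliac_femoral", 0.6, None),
    ("ankle", "tibial", 0.9, None),
    ("iliac_bifurcation", "abdominal_aorta", 1.0, None),
    ("finger", "radial", 1.0, "windkessel"),
    ("temporal", "head_temporal", 1.0, "windkessel"),
]

#: baseline diameter anchors at 25 yr used for subject scaling [mm]
_DIAMETER_BASELINE_25 = {
    "diameter_ascending": 36.7,
    "diameter_desc_thoracic": 24.4,
    "diameter_abdominal": 14.5,
    "diameter_carotid": 6.1,
}
_PROXIMAL_LENGTH_BASELINE_25 = 80.0  # mm


def reference_subject(age: float = 25.0, offsets: dict | None = None,
                      tables=None) -> SubjectConfig:
    """Convenience: the (baseline, by default) subject at an age."""
    return apply_offsets(aging_parameters(age, tables), offsets or {})


def _nominal_total_resistance() -> float:
    """Order-of-magnitude total peripheral resistance used for the baseline
    bed proportions (recalibrated per subject afterwards)."""
    return 90.0 * units.MMHG_PA / (5.0 * units.LMIN_M3S)


def make_fixture_network(scale: str = "reduced",
                         subject: SubjectConfig | None = None) -> Network:
    """Build a deterministic fixture network.

    ``scale="tiny"``: 3 segments, 1 junction, 2 outlets (solver unit tests).
    ``scale="reduced"``: the ~13-segment anatomical network described in the
    module docstring, with measurement sites {aortic_root, carotid,
    brachial, radial, femoral, ankle, iliac_bifurcation, finger (PPG),
    temporal (PPG)}.  When ``subject`` is given, the age-varying geometry
    (aortic/carotid diameters, proximal aortic length) and the diastolic
    reference pressure are set from its values; otherwise the 25-yr baseline
    subject is used.  Outlet windkessels carry baseline proportions only and
    should be recalibrated with :func:`pwdb.aging.calibrate_resistances`.
    """
    if scale == "tiny":
        return _make_tiny()
    if scale != "reduced":
        raise ParameterError(f"unknown fixture scale {scale!r}")
    if subject is None:
        subject = reference_subject(25.0)
    v = subject.values

    length_ratio = v["proximal_aortic_length"] / _PROXIMAL_LENGTH_BASELINE_25
    dia_ratio = {p: v[p] / b for p, b in _DIAMETER_BASELINE_25.items()}

    segments = {}
    for sid, (L, rin, rout, dia_param) in _REDUCED_GEOMETRY.items():
        if sid in ("asc_aorta", "aortic_arch"):
            L = L * length_ratio
        s = dia_ratio[dia_param] if dia_param else 1.0
        segments[sid] = ArterialSegment(
            id=sid, length=L, inlet_radius=rin * s, outlet_radius=rout * s)

    r_nom = _nominal_total_resistance()
    outlets = []
    for bed, members in BEDS.items():
        bed_total = r_nom / BED_FLOW_FRACTIONS[bed]
        areas = {m: math.pi * segments[m].outlet_radius**2 for m in members}
        area_sum = sum(areas.values())
        c_bed = 4e-8 * BED_COMPLIANCE_FRACTIONS[bed]
        for m in members:
            total = bed_total * area_sum / areas[m]
            outlets.append(WindkesselOutlet(
                segment_id=m, R1=0.05 * total, R2=0.95 * total,
                C=c_bed / len(members)))

    sites = {name: MeasurementSite(name, seg, frac, ppg)
             for name, seg, frac, ppg in _REDUCED_SITES}
    return Network(
        segments=segments,
        junctions={p: list(d) for p, d in _REDUCED_JUNCTIONS.items()},
        outlets=outlets,
        inlet_segment="asc_aorta",
        sites=sites,
        blood=BloodProperties(),
        diastolic_pressure=v["DBP"] * units.MMHG_PA,
    )


def _make_tiny() -> Network:
    segments = {
        "parent": ArterialSegment(id="parent", length=0.10, inlet_radius=0.010,
                                  outlet_radius=0.009),
        "d1": ArterialSegment(id="d1", length=0.10, inlet_radius=0.0065,
                              outlet_radius=0.0060),
        "d2": ArterialSegment(id="d2", length=0.10, inlet_radius=0.0065,
                              outlet_radius=0.0060),
    }
    r_nom = _nominal_total_resistance()
    outlets = [
        WindkesselOutlet(segment_id="d1", R1=0.1 * r_nom, R2=1.9 * r_nom, C=5e-9),
        WindkesselOutlet(segment_id="d2", R1=0.1 * r_nom, R2=1.9 * r_nom, C=5e-9),
    ]
    sites = {
        "root": MeasurementSite("root", "parent", 0.0),
        "daughter": MeasurementSite("daughter", "d1", 0.5),
    }
    return Network(segments=segments, junctions={"parent": ["d1", "d2"]},
                   outlets=outlets, inlet_segment="parent", sites=sites)
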