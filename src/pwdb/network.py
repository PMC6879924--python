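"""Arterial network representation and constitutive wall laws.

An arterial tree is a set of thin, linearly tapered viscoelastic segments
joined at junctions, rooted at a single inlet (the aortic root), with every
terminal segment closed by a three-element (RCR) windkessel representing its
downstream vascular bed.

Wall mechanics follow the standard empirical laws of 1D hemodynamics:

* stiffness   Eh(Rd) = Rd * (k1 * exp(k2 * Rd) + k3)          [N/m]
* wave speed  c_d    = sqrt(2 * Eh / (3 * rho * Rd))          [m/s]
* viscosity   Gamma(Rd) = b1 / (2 * Rd) + b0                  [g/s]

k1..k3 and b0, b1 are conventionally quoted in CGS; they are converted to SI
at the configuration boundary (see :mod:`pwdb.units`) and all computation
here is in SI.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import units
from .errors import ConfigError, DomainError, TopologyError

__all__ = [
    "ArterialSegment",
    "WindkesselOutlet",
    "BloodProperties",
    "MeasurementSite",
    "Network",
    "load_network",
    "save_network",
    "radius_at",
    "wall_stiffness",
    "wave_speed",
    "wall_viscosity",
]

#: maximum node spacing [m]; chosen so boundary-cell truncation on tapered
#: segments keeps the per-cycle mass defect well under 0.5% of stroke volume
MAX_NODE_SPACING = 0.0025
MIN_NODES = 3


@dataclass
class ArterialSegment:
    """One tapered viscoelastic vessel.

    Radii are diastolic (prescribed at the subject's diastolic pressure).
    Stiffness/viscosity constants are stored in SI; see :mod:`pwdb.units`.
    """

    id: str
    length: float  # m
    inlet_radius: float  # m
    outlet_radius: float  # m
    k1: float = 2.0e6  # N/m^2  (CGS 2e7 g s^-2 cm^-1)
    k2: float = -2253.0  # 1/m   (CGS -22.53 cm^-1)
    k3: float = 8.65e4  # N/m^2  (CGS 8.65e5 g s^-2 cm^-1)
    b0: float = 0.6  # kg/s   (CGS 600 g/s)
    b1: float = 1.5e-3  # kg m/s (CGS 150 g cm/s)
    n_nodes: int = 0  # 0 -> derived from length

    def __post_init__(self):
        if self.length <= 0:
            raise DomainError(f"segment {self.id}: length must be > 0")
        if self.inlet_radius <= 0 or self.outlet_radius <= 0:
            raise DomainError(f"segment {self.id}: radii must be > 0")
        if self.n_nodes == 0:
            self.n_nodes = max(MIN_NODES, int(math.ceil(self.length / MAX_NODE_SPACING)) + 1)
        if self.n_nodes < 2:
            raise DomainError(f"segment {self.id}: n_nodes must be >= 2")

    @property
    def dx(self) -> float:
        return self.length / (self.n_nodes - 1)

    def node_radii(self) -> np.ndarray:
        x = np.linspace(0.0, 1.0, self.n_nodes)
        return self.inlet_radius + (self.outlet_radius - self.inlet_radius) * x

    def mean_radius(self) -> float:
        return 0.5 * (self.inlet_radius + self.outlet_radius)

    def poiseuille_resistance(self, viscosity: float) -> float:
        """Steady laminar flow resistance of the tapered tube [Pa s/m^3]."""
        r = self.node_radii()
        integrand = 8.0 * viscosity / (math.pi * r**4)
        return float(np.trapezoid(integrand, dx=self.dx))


@dataclass
class WindkesselOutlet:
    """Three-element RCR vascular-bed model terminating a segment.

    R1 is the proximal (characteristic) resistance, R2 the distal bed
    resistance, C the bed compliance.  V is the stored compliant volume,
    a state variable during simulation.
    """

    segment_id: str
    R1: float  # Pa s/m^3
    R2: float  # Pa s/m^3
    C: float  # m^3/Pa
    P_out: float = 0.0  # Pa
    V: float = 0.0  # m^3

    def __post_init__(self):
        if self.R1 <= 0 or self.R2 <= 0:
            raise DomainError(f"outlet {self.segment_id}: resistances must be > 0")
        if self.C <= 0:
            raise DomainError(f"outlet {self.segment_id}: compliance must be > 0")


@dataclass
class BloodProperties:
    density: float = 1060.0  # kg/m^3
    viscosity: float = 2.5e-3  # Pa s

    def __post_init__(self):
        if self.density <= 0 or self.viscosity <= 0:
            raise DomainError("blood density and viscosity must be > 0")


@dataclass
class MeasurementSite:
    """Named sampling location: (segment, axial fraction in [0, 1]).

    ``ppg`` selects how a PPG is synthesized there: "windkessel" (stored
    volume of the terminal bed fed by this segment), "segment" (luminal
    volume integral of the segment), or None (no PPG).
    """

    name: str
    segment: str
    fraction: float
    ppg: str | None = None

    def __post_init__(self):
        if not 0.0 <= self.fraction <= 1.0:
            raise DomainError(f"site {self.name}: fraction must be in [0, 1]")
        if self.ppg not in (None, "windkessel", "segment"):
            raise ConfigError(f"site {self.name}: unknown ppg mode {self.ppg!r}")


@dataclass
class Network:
    segments: dict[str, ArterialSegment]
    junctions: dict[str, list[str]]  # parent id -> daughter ids
    outlets: list[WindkesselOutlet]
    inlet_segment: str
    sites: dict[str, MeasurementSite] = field(default_factory=dict)
    blood: BloodProperties = field(default_factory=BloodProperties)
    diastolic_pressure: float = 80.0 * units.MMHG_PA  # Pa, reference of the tube law

    def __post_init__(self):
        self.validate()

    # -- topology -------------------------------------------------------
    def validate(self) -> None:
        ids = set(self.segments)
        if self.inlet_segment not in ids:
            raise TopologyError(f"inlet segment {self.inlet_segment!r} not defined")
        parent_of: dict[str, str] = {}
        for parent, daughters in self.junctions.items():
            if parent not in ids:
                raise TopologyError(f"junction parent {parent!r} is not a segment")
            if len(daughters) < 1:
                raise TopologyError(f"junction at {parent!r} has no daughters")
            for d in daughters:
                if d not in ids:
                    raise TopologyError(f"junction daughter {d!r} is not a segment")
                if d in parent_of:
                    raise TopologyError(f"segment {d!r} has two parents")
                if d == parent:
                    raise TopologyError(f"segment {d!r} feeds itself")
                parent_of[d] = parent
        if self.inlet_segment in parent_of:
            raise TopologyError("inlet segment cannot be a junction daughter")
        # connectivity: walk from the inlet
        seen: set[str] = set()
        stack = [self.inlet_segment]
        while stack:
            s = stack.pop()
            if s in seen:
                raise TopologyError(f"cycle detected at segment {s!r}")
            seen.add(s)
            stack.extend(self.junctions.get(s, []))
        if seen != ids:
            orphans = sorted(ids - seen)
            raise TopologyError(f"segments not reachable from inlet: {orphans}")
        # outlets: exactly one per terminal segment
        terminal = {s for s in ids if s not in self.junctions}
        outlet_segs = [o.segment_id for o in self.outlets]
        if len(set(outlet_segs)) != len(outlet_segs):
            raise TopologyError("duplicate outlet definitions")
        if set(outlet_segs) != terminal:
            raise TopologyError(
                f"outlets {sorted(set(outlet_segs))} do not match terminal "
                f"segments {sorted(terminal)}"
            )
        for site in self.sites.values():
            if site.segment not in ids:
                raise ConfigError(f"site {site.name!r} references unknown segment")
            if site.ppg == "windkessel" and site.segment not in terminal:
                raise ConfigError(
                    f"site {site.name!r}: windkessel PPG requires a terminal segment"
                )

    @property
    def parent_of(self) -> dict[str, str]:
        return {d: p for p, ds in self.junctions.items() for d in ds}

    def terminal_segments(self) -> list[str]:
        return [s for s in self.segments if s not in self.junctions]

    def outlet_for(self, segment_id: str) -> WindkesselOutlet:
        for o in self.outlets:
            if o.segment_id == segment_id:
                return o
        raise KeyError(segment_id)

    def path_from_root(self, segment_id: str) -> list[str]:
        """Segment ids from the inlet down to (and including) segment_id."""
        parent = self.parent_of
        path = [segment_id]
        while path[-1] != self.inlet_segment:
            path.append(parent[path[-1]])
        return path[::-1]

    def site_distance_from_root(self, site_name: str) -> float:
        """Arc length [m] from the aortic root to a measurement site."""
        site = self.sites[site_name]
        path = self.path_from_root(site.segment)
        dist = sum(self.segments[s].length for s in path[:-1])
        return dist + site.fraction * self.segments[site.segment].length

    def path_length(self, site_a: str, site_b: str) -> float:
        """Arterial path length between two sites [m].

        For sites on one root-to-periphery line this is the difference of the
        root distances; for sites on diverging branches it is the length of
        the path through their last common segment.
        """
        sa, sb = self.sites[site_a], self.sites[site_b]
        pa = self.path_from_root(sa.segment)
        pb = self.path_from_root(sb.segment)
        da = self.site_distance_from_root(site_a)
        db = self.site_distance_from_root(site_b)
        if sa.segment in pb or sb.segment in pa:
            return abs(db - da)
        common = 0.0
        for x, y in zip(pa, pb):
            if x != y:
                break
            common += self.segments[x].length
        return (da - common) + (db - common)

    def total_peripheral_resistance(self) -> float:
        """Parallel combination of all outlet (R1 + R2) [Pa s/m^3]."""
        return 1.0 / sum(1.0 / (o.R1 + o.R2) for o in self.outlets)

    def equivalent_resistance(self) -> float:
        """Steady-flow resistance of the whole tree seen from the root,
        combining Poiseuille segment resistances in series with the outlet
        resistances, beds in parallel at each junction [Pa s/m^3]."""

        def req(seg_id: str) -> float:
            seg = self.segments[seg_id]
            r = seg.poiseuille_resistance(self.blood.viscosity)
            if seg_id in self.junctions:
                inv = sum(1.0 / req(d) for d in self.junctions[seg_id])
                return r + 1.0 / inv
            o = self.outlet_for(seg_id)
            return r + o.R1 + o.R2

        return req(self.inlet_segment)


# ---------------------------------------------------------------------------
# Constitutive laws
# ---------------------------------------------------------------------------

def radius_at(segment: ArterialSegment, x: float) -> float:
    """Diastolic radius at axial fraction ``x`` of a linearly tapered segment."""
    if not 0.0 <= x <= 1.0:
        raise DomainError(f"axial fraction {x} outside [0, 1]")
    return segment.inlet_radius + (segment.outlet_radius - segment.inlet_radius) * x


def wall_stiffness(Rd, k1: float, k2: float, k3: float):
    """Eh = Rd * (k1*exp(k2*Rd) + k3), SI inputs (m, N/m^2, 1/m, N/m^2) -> N/m."""
    Rd = np.asarray(Rd, dtype=float)
    if np.any(Rd <= 0):
        raise DomainError("diastolic radius must be > 0")
    out = Rd * (k1 * np.exp(k2 * Rd) + k3)
    return float(out) if out.ndim == 0 else out


def wave_speed(Eh, Rd, density: float = 1060.0):
    """Theoretical diastolic wave speed c_d = sqrt(2*Eh / (3*rho*Rd)) [m/s]."""
    Eh = np.asarray(Eh, dtype=float)
    Rd = np.asarray(Rd, dtype=float)
    if np.any(Eh <= 0) or np.any(Rd <= 0) or density <= 0:
        raise DomainError("Eh, Rd and density must be > 0")
    out = np.sqrt(2.0 * Eh / (3.0 * density * Rd))
    return float(out) if out.ndim == 0 else out


def wall_viscosity(Rd: float, b0: float = 600.0, b1: float = 150.0) -> float:
    """Wall viscosity Gamma = b1/(2*Rd) + b0 in the literature's CGS units.

    ``Rd`` in m (converted to cm internally), ``b0`` in g/s, ``b1`` in
    g cm/s; returns Gamma in g/s.  Use :func:`wall_viscosity_si` inside the
    solver.
    """
    if Rd <= 0:
        raise DomainError("diastolic radius must be > 0")
    return b1 / (2.0 * Rd * 100.0) + b0


def wall_viscosity_si(Rd, b0_si: float = 0.6, b1_si: float = 1.5e-3):
    """Gamma [kg/s] from SI constants (b0 in kg/s, b1 in kg m/s), Rd in m."""
    Rd = np.asarray(Rd, dtype=float)
    if np.any(Rd <= 0):
        raise DomainError("diastolic radius must be > 0")
    out = b1_si / (2.0 * Rd) + b0_si
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# Serialization (JSON schema with a units header; k/b constants in CGS)
# ---------------------------------------------------------------------------

_UNITS_HEADER = {
    "geometry": "m",
    "stiffness_constants": "cgs (k1,k3: g s^-2 cm^-1; k2: cm^-1)",
    "wall_viscosity_constants": "cgs (b0: g/s; b1: g cm/s)",
    "resistance": "Pa s m^-3",
    "compliance": "m^3/Pa",
    "pressure": "Pa",
}

_REQUIRED_SEGMENT_FIELDS = ("id", "length", "inlet_radius", "outlet_radius")


def _segment_from_config(entry: dict) -> ArterialSegment:
    for f in _REQUIRED_SEGMENT_FIELDS:
        if f not in entry:
            raise ConfigError(f"segment entry missing required field {f!r}: {entry}")
    k1, k2, k3 = units.stiffness_constants_to_si(
        entry.get("k1", 2.0e7), entry.get("k2", -22.53), entry.get("k3", 8.65e5)
    )
    b0, b1 = units.wall_viscosity_constants_to_si(
        entry.get("b0", 600.0), entry.get("b1", 150.0)
    )
    return ArterialSegment(
        id=str(entry["id"]),
        length=float(entry["length"]),
        inlet_radius=float(entry["inlet_radius"]),
        outlet_radius=float(entry["outlet_radius"]),
        k1=k1, k2=k2, k3=k3, b0=b0, b1=b1,
        n_nodes=int(entry.get("n_nodes", 0)),
    )


def load_network(config_source) -> Network:
    """Build a validated :class:`Network` from a JSON file path, JSON string,
    or an already-parsed dict following the documented schema."""
    if isinstance(config_source, dict):
        cfg = config_source
    else:
        text = Path(config_source).read_text() if Path(str(config_source)).exists() \
            else str(config_source)
        try:
            cfg = json.loads(text)
        except json.JSONDecodeError as e:
            raise ConfigError(f"network config is not valid JSON: {e}") from e
    for table in ("segments", "junctions", "outlets"):
        if table not in cfg:
            raise ConfigError(f"network config missing table {table!r}")
    segments = {}
    for entry in cfg["segments"]:
        seg = _segment_from_config(entry)
        if seg.id in segments:
            raise ConfigError(f"duplicate segment id {seg.id!r}")
        segments[seg.id] = seg
    junctions = {}
    for j in cfg["junctions"]:
        for f in ("parent", "daughters"):
            if f not in j:
                raise ConfigError(f"junction entry missing field {f!r}: {j}")
        junctions[str(j["parent"])] = [str(d) for d in j["daughters"]]
    outlets = []
    for o in cfg["outlets"]:
        for f in ("segment", "R1", "R2", "C"):
            if f not in o:
                raise ConfigError(f"outlet entry missing field {f!r}: {o}")
        outlets.append(WindkesselOutlet(
            segment_id=str(o["segment"]), R1=float(o["R1"]), R2=float(o["R2"]),
            C=float(o["C"]), P_out=float(o.get("P_out", 0.0)),
        ))
    sites = {}
    for s in cfg.get("sites", []):
        for f in ("name", "segment", "fraction"):
            if f not in s:
                raise ConfigError(f"site entry missing field {f!r}: {s}")
        sites[str(s["name"])] = MeasurementSite(
            name=str(s["name"]), segment=str(s["segment"]),
            fraction=float(s["fraction"]), ppg=s.get("ppg"),
        )
    blood_cfg = cfg.get("blood", {})
    blood = BloodProperties(
        density=float(blood_cfg.get("density", 1060.0)),
        viscosity=float(blood_cfg.get("viscosity", 2.5e-3)),
    )
    if "inlet_segment" not in cfg:
        raise ConfigError("network config missing field 'inlet_segment'")
    return Network(
        segments=segments, junctions=junctions, outlets=outlets,
        inlet_segment=str(cfg["inlet_segment"]), sites=sites, blood=blood,
        diastolic_pressure=float(cfg.get("diastolic_pressure", 80.0 * units.MMHG_PA)),
    )


def network_to_config(net: Network) -> dict:
    """Round-trip writer: emit the same schema `load_network` consumes."""
    segs = []
    for s in net.segments.values():
        k1, k2, k3 = units.stiffness_constants_to_cgs(s.k1, s.k2, s.k3)
        segs.append({
            "id": s.id, "length": s.length,
            "inlet_radius": s.inlet_radius, "outlet_radius": s.outlet_radius,
            "k1": k1, "k2": k2, "k3": k3,
            "b0": s.b0 / units.B0_CGS_SI, "b1": s.b1 / units.B1_CGS_SI,
            "n_nodes": s.n_nodes,
        })
    return {
        "units": dict(_UNITS_HEADER),
        "inlet_segment": net.inlet_segment,
        "diastolic_pressure": net.diastolic_pressure,
        "blood": {"density": net.blood.density, "viscosity": net.blood.viscosity},
        "segments": segs,
        "junctions": [{"parent": p, "daughters": d} for p, d in net.junctions.items()],
        "outlets": [
            {"segment": o.segment_id, "R1": o.R1, "R2": o.R2, "C": o.C,
             "P_out": o.P_out}
            for o in net.outlets
        ],
        "sites": [
            {"name": s.name, "segment": s.segment, "fraction": s.fraction,
             "ppg": s.ppg}
            for s in net.sites.values()
        ],
    }


def save_network(net: Network, path) -> None:
    Path(path).write_text(json.dumps(network_to_config(net), indent=1))
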