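"""1D pulse-wave propagation solver with windkessel outlets and PPG synthesis.

Public surface:

* :func:`tube_law_pressure` — Voigt viscoelastic tube law.
* :func:`windkessel_step` — one explicit step of an RCR outlet.
* :func:`junction_solve` — coupled boundary values at a bifurcation.
* :func:`synthesize_ppg` — blood-volume series to normalized PPG.
* :func:`simulate_subject` — run a network to cycle-to-cycle periodicity and
  return one converged cycle of P/U/A/Q (and PPG) at the measurement sites.

The numerical scheme (MacCormack with characteristic boundary treatment and
an operator-split viscoelastic diffusion substep) lives in :mod:`pwdb._core`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import _core
from .errors import DegenerateSignalError, DomainError, ParameterError, SolverError
from .inflow import Waveform
from .network import BloodProperties, Network, WindkesselOutlet, wall_stiffness

__all__ = [
    "SolverOptions",
    "PulseWaveSet",
    "tube_law_pressure",
    "windkessel_step",
    "junction_solve",
    "synthesize_ppg",
    "simulate_subject",
]

BETA_FACTOR = 4.0 / 3.0 * math.sqrt(math.pi)

#: friction model -> (momentum correction alpha, friction coefficient factor n
#: in f = -n*pi*mu*Q/(rho*A))
FRICTION_MODELS = {"parabolic": (4.0 / 3.0, 8.0), "flat": (1.0, 22.0)}


@dataclass
class SolverOptions:
    cfl: float = 0.7
    max_cycles: int = 20
    periodicity_tol: float = 1e-3  # relative L-inf between consecutive cycles
    output_fs: float = 500.0
    friction_model: str = "parabolic"

    def __post_init__(self):
        if not 0.0 < self.cfl <= 1.0:
            raise ParameterError("cfl must be in (0, 1]")
        if self.periodicity_tol <= 0:
            raise ParameterError("periodicity_tol must be > 0")
        if self.friction_model not in FRICTION_MODELS:
            raise ParameterError(f"unknown friction model {self.friction_model!r}")

    @property
    def alpha(self) -> float:
        return FRICTION_MODELS[self.friction_model][0]

    @property
    def friction_factor(self) -> float:
        return FRICTION_MODELS[self.friction_model][1]


@dataclass
class PulseWaveSet:
    """One converged cycle of waves per measurement site.

    ``waves[site][kind]`` is a :class:`~pwdb.inflow.Waveform`; kinds present
    are P (Pa), U (m/s), A (m^2), Q (m^3/s) and, where configured, PPG
    (dimensionless in [0, 1]).
    """

    waves: dict[str, dict[str, Waveform]]
    n_cycles_run: int = 0
    converged: bool = False
    residual_history: list = field(default_factory=list)
    mass_residual: float = 0.0  # fraction of stroke volume
    meta: dict = field(default_factory=dict)

    def __getitem__(self, site: str) -> dict[str, Waveform]:
        return self.waves[site]

    def sites(self):
        return list(self.waves)


def tube_law_pressure(A, Ad, dA_dt, Eh, Gamma_si, Pd):
    """Voigt-type viscoelastic tube law [Pa].

    P = Pd + (beta/Ad)(sqrt(A) - sqrt(Ad)) + Gamma/(Ad*sqrt(Ad)) * dA/dt
    with beta = (4/3)*sqrt(pi)*Eh, so that the linearized wave speed at
    A = Ad equals sqrt(2*Eh/(3*rho*Rd)).  ``Gamma_si`` is in kg/s.
    """
    A = np.asarray(A, dtype=float)
    if np.any(A <= 0) or Ad <= 0:
        raise SolverError("nonpositive luminal area in tube law",
                          diagnostics={"A": A, "Ad": Ad})
    beta = BETA_FACTOR * Eh
    out = (Pd + beta / Ad * (np.sqrt(A) - np.sqrt(Ad))
           + Gamma_si / (Ad * math.sqrt(Ad)) * np.asarray(dA_dt, dtype=float))
    return float(out) if out.ndim == 0 else out


def windkessel_step(outlet: WindkesselOutlet, Q_in: float, dt: float,
                    _state={}) -> tuple[float, float]:
    """Advance the RCR lumped state one step; returns (P_interface, V).

    The compliant pressure P_c (stored on the outlet via its volume,
    V = C*(P_c - P_out)) obeys C dP_c/dt = Q_in - (P_c - P_out)/R2, and the
    interface pressure is P = P_c + Q_in*R1.  At steady inflow Q0 the
    interface pressure tends to Q0*(R1+R2) + P_out.
    """
    if dt <= 0:
        raise DomainError("dt must be > 0")
    Pc = outlet.P_out + outlet.V / outlet.C
    Pc += dt / outlet.C * (Q_in - (Pc - outlet.P_out) / outlet.R2)
    outlet.V = outlet.C * (Pc - outlet.P_out)
    return Pc + Q_in * outlet.R1, outlet.V


def junction_solve(parent_state: dict, daughter_states: list[dict],
                   blood: BloodProperties, Pd: float = 0.0) -> list[dict]:
    """Solve coupled boundary values at a junction (1 parent, n daughters).

    Each state dict carries {"A", "u", "Ad", "Eh"}: current area and
    velocity plus the vessel's local diastolic area and stiffness.  Mass is
    conserved and total pressure P + rho*u^2/2 is continuous, with the
    outgoing characteristic of every attached vessel held fixed.  Returns a
    list of solved {"A", "u", "Q", "P"} dicts ordered parent-first.
    """
    states = [parent_state] + list(daughter_states)
    m = len(daughter_states)
    n = m + 1
    rho = blood.density
    ck = np.empty(n); cd = np.empty(n); beta = np.empty(n); Adv = np.empty(n)
    W = np.empty(n); c0 = np.empty(n)
    for i, st in enumerate(states):
        beta[i] = BETA_FACTOR * st["Eh"]
        Adv[i] = st["Ad"]
        ck[i] = math.sqrt(beta[i] / (2.0 * rho * Adv[i]))
        cd[i] = ck[i] * Adv[i] ** 0.25
        c = ck[i] * st["A"] ** 0.25
        c0[i] = c
        if i == 0:
            W[i] = st["u"] + 4.0 * (c - cd[i])
        else:
            W[i] = st["u"] - 4.0 * (c - cd[i])
    c_out = np.empty(n)
    ok = _core._solve_junction(m, W, ck, cd, beta, Adv, Pd, rho, c0, c_out)
    if not ok:
        raise SolverError("junction Newton iteration did not converge")
    out = []
    for i in range(n):
        A = (c_out[i] / ck[i]) ** 4
        u = (W[i] - 4.0 * (c_out[i] - cd[i]) if i == 0
             else W[i] + 4.0 * (c_out[i] - cd[i]))
        P = Pd + beta[i] / Adv[i] * (math.sqrt(A) - math.sqrt(Adv[i]))
        out.append({"A": A, "u": u, "Q": A * u, "P": P})
    return out


def synthesize_ppg(volume_series: Waveform) -> Waveform:
    """Normalize a pulsatile blood-volume series to a 0-1 PPG wave."""
    v = volume_series.y
    vmin, vmax = float(np.min(v)), float(np.max(v))
    if vmax - vmin <= 0 or not np.isfinite(vmax - vmin):
        raise DegenerateSignalError("constant volume series cannot yield a PPG")
    return Waveform(t=volume_series.t, y=(v - vmin) / (vmax - vmin),
                    site=volume_series.site, kind="PPG")


# ---------------------------------------------------------------------------
# Full-network simulation
# ---------------------------------------------------------------------------

class _FlatNetwork:
    """Flattened array layout of a network for the numba kernels."""

    def __init__(self, net: Network, alpha: float, friction_factor: float):
        rho = net.blood.density
        ids = list(net.segments)
        self.index = {sid: i for i, sid in enumerate(ids)}
        nseg = len(ids)
        seg_start = np.zeros(nseg, dtype=np.int64)
        seg_n = np.zeros(nseg, dtype=np.int64)
        seg_dx = np.zeros(nseg)
        Ad_l, beta_l, gam_l = [], [], []
        pos = 0
        for i, sid in enumerate(ids):
            seg = net.segments[sid]
            seg_start[i] = pos
            seg_n[i] = seg.n_nodes
            seg_dx[i] = seg.dx
            r = seg.node_radii()
            Eh = wall_stiffness(r, seg.k1, seg.k2, seg.k3)
            gamma = seg.b1 / (2.0 * r) + seg.b0  # kg/s
            Ad = math.pi * r**2
            Ad_l.append(Ad)
            beta_l.append(BETA_FACTOR * Eh)
            gam_l.append(gamma / (Ad * np.sqrt(Ad)))
            pos += seg.n_nodes
        self.N = pos
        self.seg_start, self.seg_n, self.seg_dx = seg_start, seg_n, seg_dx
        self.Ad = np.concatenate(Ad_l)
        self.beta = np.concatenate(beta_l)
        self.gam = np.concatenate(gam_l)
        self.ck = np.sqrt(self.beta / (2.0 * rho * self.Ad))
        self.cd = self.ck * self.Ad**0.25
        # per-node axial gradients of the wall/geometry properties, used by
        # the characteristic boundary treatment on tapered segments
        self.dkd = np.zeros(self.N)  # d(beta/Ad)/dx
        self.dsq = np.zeros(self.N)  # d(sqrt(Ad))/dx
        self.dck = np.zeros(self.N)
        self.dcd = np.zeros(self.N)
        for i in range(nseg):
            s, n = int(seg_start[i]), int(seg_n[i])
            sl = slice(s, s + n)
            dx = seg_dx[i]
            self.dkd[sl] = np.gradient(self.beta[sl] / self.Ad[sl], dx)
            self.dsq[sl] = np.gradient(np.sqrt(self.Ad[sl]), dx)
            self.dck[sl] = np.gradient(self.ck[sl], dx)
            self.dcd[sl] = np.gradient(self.cd[sl], dx)
        self.inlet_seg = self.index[net.inlet_segment]

        jn_parent = np.array([self.index[p] for p in net.junctions], dtype=np.int64)
        maxd = max((len(d) for d in net.junctions.values()), default=1)
        jn_nd = np.zeros(len(net.junctions), dtype=np.int64)
        jn_daughters = np.full((max(len(net.junctions), 1), maxd), -1, dtype=np.int64)
        for j, (p, ds) in enumerate(net.junctions.items()):
            jn_nd[j] = len(ds)
            for d, did in enumerate(ds):
                jn_daughters[j, d] = self.index[did]
        self.jn_parent, self.jn_nd, self.jn_daughters = jn_parent, jn_nd, jn_daughters

        self.out_seg = np.array([self.index[o.segment_id] for o in net.outlets],
                                dtype=np.int64)
        self.out_R1 = np.array([o.R1 for o in net.outlets])
        self.out_R2 = np.array([o.R2 for o in net.outlets])
        self.out_C = np.array([o.C for o in net.outlets])
        self.out_Pout = np.array([o.P_out for o in net.outlets])
        self.alpha = alpha
        self.Cf = friction_factor * math.pi * net.blood.viscosity / rho

    def node_of(self, seg_id: str, fraction: float) -> int:
        i = self.index[seg_id]
        n = int(self.seg_n[i])
        return int(self.seg_start[i]) + int(round(fraction * (n - 1)))


def _stable_dt(flat: _FlatNetwork, options: SolverOptions, rho: float) -> float:
    """Time step from the hyperbolic CFL condition with systolic headroom on
    the wave speed (the viscous substep is implicit and does not constrain
    dt)."""
    dt_h = np.inf
    for i in range(len(flat.seg_start)):
        s, n = int(flat.seg_start[i]), int(flat.seg_n[i])
        dx = flat.seg_dx[i]
        cmax = float(np.max(flat.cd[s:s + n])) * 1.35 + 2.0
        dt_h = min(dt_h, dx / cmax)
    return options.cfl * dt_h


def _steady_warm_start(network: Network, flat: _FlatNetwork, Q_mean: float,
                       A: np.ndarray, Q: np.ndarray, out_Pc: np.ndarray):
    """Initialize (A, Q, windkessel pressures) from the steady resistive
    solution at the mean inflow, so only the fast wave dynamics remain to
    converge.  Requires a common outflow pressure datum."""
    p_outs = {o.P_out for o in network.outlets}
    if Q_mean <= 0 or len(p_outs) != 1:
        return
    p_ref = p_outs.pop()
    mu = network.blood.viscosity
    rho = network.blood.density
    Pd = network.diastolic_pressure

    def subtree_R(seg_id):
        seg = network.segments[seg_id]
        r = seg.poiseuille_resistance(mu)
        if seg_id in network.junctions:
            return r + 1.0 / sum(1.0 / subtree_R(d)
                                 for d in network.junctions[seg_id])
        o = network.outlet_for(seg_id)
        return r + o.R1 + o.R2

    outlet_index = {o.segment_id: i for i, o in enumerate(network.outlets)}

    def fill(seg_id, P_in, Q_sub):
        seg = network.segments[seg_id]
        i = flat.index[seg_id]
        s, n = int(flat.seg_start[i]), int(flat.seg_n[i])
        rr = seg.node_radii()
        P = P_in
        for j in range(n):
            k = s + j
            sq = math.sqrt(flat.Ad[k]) + (P - Pd) * flat.Ad[k] / flat.beta[k]
            A[k] = max(sq, 0.5 * math.sqrt(flat.Ad[k])) ** 2
            Q[k] = Q_sub
            if j < n - 1:
                r_mid = 0.5 * (rr[j] + rr[j + 1])
                P -= Q_sub * 8.0 * mu * seg.dx / (math.pi * r_mid**4)
        if seg_id in network.junctions:
            ds = network.junctions[seg_id]
            conds = np.array([1.0 / subtree_R(d) for d in ds])
            for d, frac in zip(ds, conds / conds.sum()):
                fill(d, P, Q_sub * frac)
        else:
            o = network.outlet_for(seg_id)
            out_Pc[outlet_index[seg_id]] = P - Q_sub * o.R1

    P_root = p_ref + Q_mean * subtree_R(network.inlet_segment)
    fill(network.inlet_segment, P_root, Q_mean)


def simulate_subject(network: Network, inflow: Waveform,
                     blood: BloodProperties | None = None,
                     options: SolverOptions | None = None) -> PulseWaveSet:
    """Run the network to cycle-to-cycle periodicity; return the last cycle.

    Cycles are repeated until the relative L-inf change of the aortic-root
    pressure between consecutive cycles falls below ``periodicity_tol`` (or
    ``max_cycles`` is hit, in which case the result is flagged
    non-converged).  The returned waves are resampled to ``output_fs``; PPG
    waves are synthesized at sites configured for them.
    """
    if blood is not None:
        network.blood = blood
    options = options or SolverOptions()
    rho = network.blood.density
    Pd = network.diastolic_pressure
    flat = _FlatNetwork(network, options.alpha, options.friction_factor)

    T = inflow.duration
    dt = _stable_dt(flat, options, rho)
    nsteps = int(math.ceil(T / dt))
    dt = T / nsteps
    t_solver = np.arange(nsteps) * dt
    Qin = np.interp(t_solver, inflow.t - inflow.t[0], inflow.y, period=T)

    # record the inlet node plus every site node
    site_names = list(network.sites)
    rec_nodes = [flat.node_of(network.inlet_segment, 0.0)]
    for name in site_names:
        s = network.sites[name]
        rec_nodes.append(flat.node_of(s.segment, s.fraction))
    rec_nodes = np.asarray(rec_nodes, dtype=np.int64)
    seg_of_node = np.zeros(flat.N, dtype=np.int64)
    for i in range(len(flat.seg_start)):
        seg_of_node[flat.seg_start[i]: flat.seg_start[i] + flat.seg_n[i]] = i
    rec_seg_of = seg_of_node[rec_nodes]
    nrec = rec_nodes.size
    rec_P = np.zeros((nrec, nsteps)); rec_U = np.zeros((nrec, nsteps))
    rec_A = np.zeros((nrec, nsteps)); rec_Q = np.zeros((nrec, nsteps))
    nout = len(network.outlets)
    rec_Pc = np.zeros((nout, nsteps))
    rec_segvol_id = np.arange(len(network.segments), dtype=np.int64)
    rec_segvol = np.zeros((len(network.segments), nsteps))

    A = flat.Ad.copy()
    Q = np.zeros(flat.N)
    out_Pc = np.full(nout, Pd)
    _steady_warm_start(network, flat, float(np.mean(Qin)), A, Q, out_Pc)

    prev_root = None
    residuals = []
    converged = False
    n_cycles = 0
    for cycle in range(options.max_cycles):
        status = _core.run_cycle(
            A, Q, flat.Ad, flat.beta, flat.ck, flat.cd, flat.gam,
            flat.dkd, flat.dsq, flat.dck, flat.dcd,
            flat.seg_start, flat.seg_n, flat.seg_dx, flat.inlet_seg,
            flat.jn_parent, flat.jn_nd, flat.jn_daughters,
            flat.out_seg, flat.out_R1, flat.out_R2, flat.out_C, flat.out_Pout,
            out_Pc, Qin, dt, rho, Pd, flat.alpha, flat.Cf,
            rec_nodes, rec_seg_of, rec_P, rec_U, rec_A, rec_Q,
            rec_Pc, rec_segvol_id, rec_segvol,
        )
        n_cycles = cycle + 1
        if status == 1:
            raise SolverError(
                f"solver blowup in cycle {n_cycles} (negative area or NaN)",
                diagnostics={"cycle": n_cycles, "dt": dt,
                             "max_A_ratio": float(np.max(A / flat.Ad))})
        if status == 2:
            raise SolverError(f"junction Newton failure in cycle {n_cycles}")
        root = rec_P[0].copy()
        if prev_root is not None:
            res = float(np.max(np.abs(root - prev_root)) / np.max(np.abs(root)))
            residuals.append(res)
            if res < options.periodicity_tol:
                converged = True
                break
        prev_root = root

    # resample the final cycle to the output rate
    n_out = int(round(T * options.output_fs))
    t_out = np.arange(n_out) / options.output_fs

    def resample(y):
        return np.interp(t_out, t_solver, y, period=T)

    waves: dict[str, dict[str, Waveform]] = {}
    for r, name in enumerate(site_names, start=1):
        site = network.sites[name]
        w = {
            "P": Waveform(t=t_out, y=resample(rec_P[r]), site=name, kind="P"),
            "U": Waveform(t=t_out, y=resample(rec_U[r]), site=name, kind="U"),
            "A": Waveform(t=t_out, y=resample(rec_A[r]), site=name, kind="A"),
            "Q": Waveform(t=t_out, y=resample(rec_Q[r]), site=name, kind="Q"),
        }
        if site.ppg == "windkessel":
            o = [i for i, out in enumerate(network.outlets)
                 if out.segment_id == site.segment][0]
            vol = network.outlets[o].C * (rec_Pc[o] - network.outlets[o].P_out)
            w["PPG"] = synthesize_ppg(
                Waveform(t=t_out, y=resample(vol), site=name, kind="V"))
        elif site.ppg == "segment":
            s = flat.index[site.segment]
            w["PPG"] = synthesize_ppg(
                Waveform(t=t_out, y=resample(rec_segvol[s]), site=name, kind="V"))
        waves[name] = w

    # cycle-averaged mass audit: inflow volume vs outlet outflow + storage
    v_in = float(np.sum(Qin) * dt)
    v_out = float(np.sum((rec_Pc - flat.out_Pout[:, None]) / flat.out_R2[:, None]) * dt)
    dV_wk = float(np.sum(flat.out_C * (rec_Pc[:, -1] - rec_Pc[:, 0])))
    dV_seg = float(np.sum(rec_segvol[:, -1] - rec_segvol[:, 0]))
    sv = abs(v_in) if v_in else 1.0
    mass_residual = abs(v_in - v_out - dV_wk - dV_seg) / sv

    root_wave = Waveform(t=t_out, y=resample(rec_P[0]), site="inlet", kind="P")
    return PulseWaveSet(
        waves=waves, n_cycles_run=n_cycles, converged=converged,
        residual_history=residuals, mass_residual=mass_residual,
        meta={"dt": dt, "steps_per_cycle": nsteps, "T": T,
              "root_pressure": root_wave,
              "output_fs": options.output_fs},
    )
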