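"""Numba kernels for the 1D hemodynamics solver.

The nonlinear 1D equations of blood flow in compliant vessels,

    dA/dt + dQ/dx = 0
    dQ/dt + d(alpha*Q^2/A)/dx + (A/rho)*dP/dx = -Cf*Q/A,

are advanced with an explicit two-step MacCormack scheme (forward-difference
predictor, backward-difference corrector) per segment.  Characteristic
boundary conditions are applied to both the predictor and the corrector
states; applying them to the predictor state as well keeps the boundary
fluxes consistent with the interior conservation update, which matters on
strongly tapered segments.  The elastic tube law

    P(A) = Pd + (beta/Ad) * (sqrt(A) - sqrt(Ad)),  beta = (4/3)*sqrt(pi)*Eh,

gives the wave speed c = ck * A^(1/4), ck = sqrt(beta/(2*rho*Ad)), so that
c(Ad) matches sqrt(2*Eh/(3*rho*Rd)) exactly.  The Voigt viscoelastic wall
term is applied by operator splitting as an explicit diffusion substep on Q
with diffusivity A*gam/rho, gam = Gamma/(Ad*sqrt(Ad)).

Boundary coupling uses the characteristic invariants W1,2 = u +/- 4*(c - cd)
of the elastic subsystem: prescribed inflow at the root, Newton solves for
conservation of mass and total pressure at junctions, and an RCR windkessel
relation at each terminal node.

All arrays are flat over the nodes of all segments; segment i occupies
nodes seg_start[i] .. seg_start[i] + seg_n[i] - 1.
"""

import numpy as np
from numba import njit

NEWTON_TOL = 1e-11
NEWTON_MAXIT = 60


@njit(cache=True)
def _pressure(A, Ad, beta, Pd):
    return Pd + beta / Ad * (np.sqrt(A) - np.sqrt(Ad))


@njit(cache=True)
def _solve_inlet(Qin, A0, ck0, cd0, W2):
    """Newton solve for inlet area given prescribed flow and outgoing W2."""
    A = A0
    for _ in range(NEWTON_MAXIT):
        f = Qin / A - 4.0 * ck0 * A**0.25 + 4.0 * cd0 - W2
        df = -Qin / (A * A) - ck0 * A**-0.75
        dA = -f / df
        if dA < -0.5 * A:
            dA = -0.5 * A
        A += dA
        if abs(dA) < NEWTON_TOL * A0:
            break
    return A


@njit(cache=True)
def _solve_outlet(W1, A0, ck, cd, beta, Ad, Pd, R1, Pc):
    """Newton solve for terminal area coupling W1 to the windkessel."""
    A = A0
    for _ in range(NEWTON_MAXIT):
        u = W1 - 4.0 * (ck * A**0.25 - cd)
        g = _pressure(A, Ad, beta, Pd) - Pc - u * A * R1
        dg = beta / (2.0 * Ad * np.sqrt(A)) - R1 * (u - ck * A**0.25)
        dA = -g / dg
        if dA < -0.5 * A:
            dA = -0.5 * A
        A += dA
        if abs(dA) < NEWTON_TOL * A0:
            break
    u = W1 - 4.0 * (ck * A**0.25 - cd)
    return A, u * A


@njit(cache=True)
def _solve_junction(m, W, ck, cd, beta, Ad, Pd, rho, c_init, c_out):
    """Newton solve for one junction: index 0 is the parent (outgoing W1),
    1..m are daughters (outgoing W2).  Unknowns are the wave speeds c_i.
    Enforces mass conservation and continuity of total pressure.
    Returns True on convergence; solution written to c_out."""
    n = m + 1
    c = c_init.copy()
    J = np.zeros((n, n))
    R = np.zeros(n)
    ok = False
    for _ in range(NEWTON_MAXIT):
        A = (c / ck) ** 4
        u = np.empty(n)
        u[0] = W[0] - 4.0 * (c[0] - cd[0])
        for i in range(1, n):
            u[i] = W[i] + 4.0 * (c[i] - cd[i])
        P = np.empty(n)
        for i in range(n):
            P[i] = Pd + beta[i] / Ad[i] * (np.sqrt(A[i]) - np.sqrt(Ad[i]))
        R[0] = A[0] * u[0]
        for i in range(1, n):
            R[0] -= A[i] * u[i]
            R[i] = P[0] + 0.5 * rho * u[0] ** 2 - P[i] - 0.5 * rho * u[i] ** 2
        scale = abs(A[0]) * (abs(u[0]) + cd[0]) + 1e-30
        resid = abs(R[0]) / scale
        for i in range(1, n):
            resid = max(resid, abs(R[i]) / (rho * cd[0] ** 2))
        if resid < 1e-10:
            ok = True
            break
        J[:, :] = 0.0
        dAdc = 4.0 * A / c
        dPdc = np.empty(n)
        for i in range(n):
            dPdc[i] = beta[i] / Ad[i] * 2.0 * c[i] / ck[i] ** 2
        J[0, 0] = u[0] * dAdc[0] - 4.0 * A[0]
        for i in range(1, n):
            J[0, i] = -(u[i] * dAdc[i] + 4.0 * A[i])
            J[i, 0] = dPdc[0] - 4.0 * rho * u[0]
            J[i, i] = -(dPdc[i] + 4.0 * rho * u[i])
        dc = np.linalg.solve(J, -R)
        for i in range(n):
            if dc[i] < -0.4 * c[i]:
                dc[i] = -0.4 * c[i]
            elif dc[i] > 0.4 * c[i]:
                dc[i] = 0.4 * c[i]
        c += dc
    c_out[:n] = c
    return ok


def _w_at_foot(sgn):
    """Build the invariant-at-foot evaluator for W = u + sgn*4*(c - cd).

    The quasi-invariant is interpolated at the foot of the outgoing
    characteristic (|lambda|*dt inside the domain) and advanced by the
    analytic source it obeys on a tapered tube,

        dW/dt along u + sgn*c =
            -Cf*u/A  - (1/rho) dP/dx|_A
            + sgn*4*(u + sgn*c) * (c*ck'/ck - cd'),

    which vanishes identically at rest (so tapered vessels hold their
    diastolic state exactly).  Property gradients are per-node arrays."""

    def impl(A, Q, kb, ki, dx, dt, ck, cd, Ad, beta,
             dkd, dsq, dck, dcd, Cf, rho):
        ub = Q[kb] / A[kb]
        cb = ck[kb] * A[kb] ** 0.25
        f = (sgn * ub + cb) * dt / dx
        if f < 0.0:
            f = 0.0
        elif f > 1.0:
            f = 1.0
        # state interpolated at the characteristic foot
        Af = (1.0 - f) * A[kb] + f * A[ki]
        uf = (1.0 - f) * ub + f * Q[ki] / A[ki]
        ckf = (1.0 - f) * ck[kb] + f * ck[ki]
        cdf = (1.0 - f) * cd[kb] + f * cd[ki]
        cf = ckf * Af**0.25
        W_f = uf + sgn * 4.0 * (cf - cdf)
        # source terms at the foot (property gradients taken at the boundary)
        fric = -Cf * uf / Af
        G = -((np.sqrt(Af) - np.sqrt(Ad[kb])) * dkd[kb]
              - beta[kb] / Ad[kb] * dsq[kb]) / rho
        taper = sgn * 4.0 * (uf + sgn * cf) * (cf * dck[kb] / ck[kb] - dcd[kb])
        return W_f + dt * (fric + G + taper)

    return impl


_W1_at_foot = njit(cache=True)(_w_at_foot(1.0))
_W2_at_foot = njit(cache=True)(_w_at_foot(-1.0))


@njit(cache=True)
def _apply_bcs(A, Q, Qin_val,
               Ad, beta, ck, cd,
               dkd, dsq, dck, dcd, Cf,
               seg_start, seg_n, seg_dx, inlet_seg,
               jn_parent, jn_nd, jn_daughters,
               out_seg, out_R1, out_R2, out_C, out_Pout,
               out_Pc, out_Qb, Pc_buf, commit,
               dt, rho, Pd,
               Wj, ckj, cdj, betaj, Adj, cj0, cjs):
    """Apply inlet/junction/outlet boundary conditions to the state (A, Q).

    The windkessel compliant pressure is advanced from the committed state
    ``out_Pc`` using the interface flow saved at the step start (out_Qb);
    the advanced values are stored in Pc_buf and copied into out_Pc only
    when ``commit`` is True (corrector application).  Returns 0, or 2 on a
    junction Newton failure."""
    # inlet
    i0 = seg_start[inlet_seg]
    W2 = _W2_at_foot(A, Q, i0, i0 + 1, seg_dx[inlet_seg], dt, ck, cd,
                     Ad, beta, dkd, dsq, dck, dcd, Cf, rho)
    A[i0] = _solve_inlet(Qin_val, A[i0], ck[i0], cd[i0], W2)
    Q[i0] = Qin_val

    # junctions
    for jn in range(jn_parent.shape[0]):
        ps = jn_parent[jn]
        pe = seg_start[ps] + seg_n[ps] - 1
        nd = jn_nd[jn]
        Wj[0] = _W1_at_foot(A, Q, pe, pe - 1, seg_dx[ps], dt, ck, cd,
                            Ad, beta, dkd, dsq, dck, dcd, Cf, rho)
        ckj[0] = ck[pe]; cdj[0] = cd[pe]; betaj[0] = beta[pe]; Adj[0] = Ad[pe]
        cj0[0] = ck[pe] * A[pe] ** 0.25
        for d in range(nd):
            sd = jn_daughters[jn, d]
            ds = seg_start[sd]
            Wj[d + 1] = _W2_at_foot(A, Q, ds, ds + 1, seg_dx[sd], dt, ck, cd,
                                    Ad, beta, dkd, dsq, dck, dcd, Cf, rho)
            ckj[d + 1] = ck[ds]; cdj[d + 1] = cd[ds]
            betaj[d + 1] = beta[ds]; Adj[d + 1] = Ad[ds]
            cj0[d + 1] = ck[ds] * A[ds] ** 0.25
        ok = _solve_junction(nd, Wj[: nd + 1], ckj[: nd + 1], cdj[: nd + 1],
                             betaj[: nd + 1], Adj[: nd + 1], Pd, rho,
                             cj0[: nd + 1], cjs)
        if not ok:
            return 2
        Ap = (cjs[0] / ckj[0]) ** 4
        A[pe] = Ap
        Q[pe] = Ap * (Wj[0] - 4.0 * (cjs[0] - cdj[0]))
        for d in range(nd):
            ds = seg_start[jn_daughters[jn, d]]
            Adn = (cjs[d + 1] / ckj[d + 1]) ** 4
            A[ds] = Adn
            Q[ds] = Adn * (Wj[d + 1] + 4.0 * (cjs[d + 1] - cdj[d + 1]))

    # windkessel outlets
    for o in range(out_seg.shape[0]):
        ts = out_seg[o]
        te = seg_start[ts] + seg_n[ts] - 1
        W1 = _W1_at_foot(A, Q, te, te - 1, seg_dx[ts], dt, ck, cd,
                         Ad, beta, dkd, dsq, dck, dcd, Cf, rho)
        Pc_new = out_Pc[o] + dt / out_C[o] * (
            out_Qb[o] - (out_Pc[o] - out_Pout[o]) / out_R2[o])
        Pc_buf[o] = Pc_new
        Anew, Qnew = _solve_outlet(W1, A[te], ck[te], cd[te], beta[te],
                                   Ad[te], Pd, out_R1[o], Pc_new)
        A[te] = Anew
        Q[te] = Qnew
    if commit:
        for o in range(out_seg.shape[0]):
            out_Pc[o] = Pc_buf[o]
    return 0


@njit(cache=True)
def run_cycle(
    A, Q,
    Ad, beta, ck, cd, gam,
    dkd, dsq, dck, dcd,
    seg_start, seg_n, seg_dx,
    inlet_seg,
    jn_parent, jn_nd, jn_daughters,
    out_seg, out_R1, out_R2, out_C, out_Pout, out_Pc,
    Qin, dt, rho, Pd, alpha, Cf,
    rec_nodes, rec_seg_of, rec_P, rec_U, rec_A, rec_Q,
    rec_Pc, rec_segvol_id, rec_segvol,
):
    """Advance one cardiac cycle (len(Qin) steps) in place.

    Records P/U/A/Q at rec_nodes, windkessel pressures, and segment luminal
    volumes each step.  Returns 0 on success, 1 on numerical blowup (NaN or
    collapsed area), 2 on junction Newton failure.
    """
    N = A.shape[0]
    nseg = seg_start.shape[0]
    nsteps = Qin.shape[0]
    nout = out_seg.shape[0]

    As = np.empty(N)
    Qs = np.empty(N)
    Qtmp = np.empty(N)
    P = np.empty(N)
    F = np.empty(N)
    out_Qb = np.empty(nout)
    Pc_buf = np.empty(nout)

    maxd = jn_daughters.shape[1]
    Wj = np.empty(maxd + 1)
    ckj = np.empty(maxd + 1)
    cdj = np.empty(maxd + 1)
    betaj = np.empty(maxd + 1)
    Adj = np.empty(maxd + 1)
    cj0 = np.empty(maxd + 1)
    cjs = np.empty(maxd + 1)

    for step in range(nsteps):
        for o in range(nout):
            out_Qb[o] = Q[seg_start[out_seg[o]] + seg_n[out_seg[o]] - 1]

        # ---- predictor (forward differences) --------------------------
        for k in range(N):
            P[k] = _pressure(A[k], Ad[k], beta[k], Pd)
            F[k] = alpha * Q[k] * Q[k] / A[k]
        for s in range(nseg):
            i0 = seg_start[s]
            i1 = i0 + seg_n[s] - 1
            dx = seg_dx[s]
            for j in range(i0, i1):
                dQdx = (Q[j + 1] - Q[j]) / dx
                dFdx = (F[j + 1] - F[j]) / dx
                dPdx = (P[j + 1] - P[j]) / dx
                As[j] = A[j] - dt * dQdx
                Qs[j] = Q[j] - dt * (dFdx + A[j] / rho * dPdx + Cf * Q[j] / A[j])
            As[i1] = A[i1]
            Qs[i1] = Q[i1]
        st = _apply_bcs(As, Qs, Qin[step], Ad, beta, ck, cd,
                        dkd, dsq, dck, dcd, Cf,
                        seg_start, seg_n, seg_dx, inlet_seg,
                        jn_parent, jn_nd, jn_daughters,
                        out_seg, out_R1, out_R2, out_C, out_Pout,
                        out_Pc, out_Qb, Pc_buf, False, dt, rho, Pd,
                        Wj, ckj, cdj, betaj, Adj, cj0, cjs)
        if st != 0:
            return st

        # ---- corrector (backward differences) -------------------------
        for k in range(N):
            P[k] = _pressure(As[k], Ad[k], beta[k], Pd)
            F[k] = alpha * Qs[k] * Qs[k] / As[k]
        for s in range(nseg):
            i0 = seg_start[s]
            i1 = i0 + seg_n[s] - 1
            dx = seg_dx[s]
            for j in range(i1, i0, -1):
                dQdx = (Qs[j] - Qs[j - 1]) / dx
                dFdx = (F[j] - F[j - 1]) / dx
                dPdx = (P[j] - P[j - 1]) / dx
                An = 0.5 * (A[j] + As[j] - dt * dQdx)
                Qn = 0.5 * (Q[j] + Qs[j]
                            - dt * (dFdx + As[j] / rho * dPdx
                                    + Cf * Qs[j] / As[j]))
                A[j] = An
                Q[j] = Qn
            # node i0 keeps its predictor/BC value pending the BC below

        # ---- viscoelastic diffusion substep (implicit, per segment) ----
        # backward-Euler solve of dQ/dt = (A/rho) d/dx(gam dQ/dx) on the
        # interior nodes with the boundary values held (Thomas algorithm);
        # unconditionally stable, so dt is set by the CFL condition alone
        for s in range(nseg):
            i0 = seg_start[s]
            i1 = i0 + seg_n[s] - 1
            dx = seg_dx[s]
            if i1 - i0 < 2:
                continue
            cp_prev = 0.0
            dp_prev = 0.0
            for j in range(i0 + 1, i1):
                r = dt * A[j] / (rho * dx * dx)
                al = -r * 0.5 * (gam[j] + gam[j - 1])
                au = -r * 0.5 * (gam[j] + gam[j + 1])
                bd = 1.0 - al - au
                rhs = Q[j]
                if j == i0 + 1:
                    rhs -= al * Q[i0]
                    al = 0.0
                if j == i1 - 1:
                    rhs -= au * Q[i1]
                    au = 0.0
                denom = bd - al * cp_prev
                cp_prev = au / denom
                dp_prev = (rhs - al * dp_prev) / denom
                Qtmp[j] = cp_prev  # modified upper coefficient
                As[j] = dp_prev  # modified rhs (As reusable after corrector)
            Q[i1 - 1] = As[i1 - 1]
            for j in range(i1 - 2, i0, -1):
                Q[j] = As[j] - Qtmp[j] * Q[j + 1]

        st = _apply_bcs(A, Q, Qin[step], Ad, beta, ck, cd,
                        dkd, dsq, dck, dcd, Cf,
                        seg_start, seg_n, seg_dx, inlet_seg,
                        jn_parent, jn_nd, jn_daughters,
                        out_seg, out_R1, out_R2, out_C, out_Pout,
                        out_Pc, out_Qb, Pc_buf, True, dt, rho, Pd,
                        Wj, ckj, cdj, betaj, Adj, cj0, cjs)
        if st != 0:
            return st

        # ---- sanity + recording ---------------------------------------
        for k in range(N):
            if not np.isfinite(A[k]) or A[k] < 0.05 * Ad[k]:
                return 1
        for r in range(rec_nodes.shape[0]):
            k = rec_nodes[r]
            s_r = rec_seg_of[r]
            i0 = seg_start[s_r]
            i1 = i0 + seg_n[s_r] - 1
            dx = seg_dx[s_r]
            # Voigt wall: recorded pressure includes the viscous term
            # gam * dA/dt = -gam * dQ/dx (continuity)
            if i0 < k < i1:
                dQdx = (Q[k + 1] - Q[k - 1]) / (2.0 * dx)
            elif k == i0:
                dQdx = (Q[k + 1] - Q[k]) / dx
            else:
                dQdx = (Q[k] - Q[k - 1]) / dx
            rec_P[r, step] = _pressure(A[k], Ad[k], beta[k], Pd) - gam[k] * dQdx
            rec_U[r, step] = Q[k] / A[k]
            rec_A[r, step] = A[k]
            rec_Q[r, step] = Q[k]
        for o in range(nout):
            rec_Pc[o, step] = out_Pc[o]
        for r in range(rec_segvol_id.shape[0]):
            s = rec_segvol_id[r]
            i0 = seg_start[s]
            i1 = i0 + seg_n[s] - 1
            vol = 0.0
            for j in range(i0, i1):
                vol += 0.5 * (A[j] + A[j + 1]) * seg_dx[s]
            rec_segvol[r, step] = vol
    return 0
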