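"""1D solver: tube law, boundary models, propagation, conservation."""

import math

import numpy as np
import pytest

from conftest import gaussian_pulse_inflow, single_tube_network
from pwdb import units
from pwdb.errors import DegenerateSignalError, ParameterError, SolverError
from pwdb.inflow import InflowParams, Waveform, generate_inflow
from pwdb.network import (ArterialSegment, BloodProperties, MeasurementSite,
                          Network, WindkesselOutlet, wall_stiffness, wave_speed)
from pwdb.solver import (SolverOptions, junction_solve, simulate_subject,
                         synthesize_ppg, tube_law_pressure, windkessel_step)

RHO = 1060.0
PD = 80.0 * units.MMHG_PA


class TestTubeLaw:
    def test_diastolic_reference(self):
        assert tube_law_pressure(1e-4, 1e-4, 0.0, 500.0, 0.6, PD) == pytest.approx(PD)

    def test_elastic_closed_form(self):
        Ad, Eh = 2e-4, 450.0
        A = 1.21 * Ad
        beta = 4.0 / 3.0 * math.sqrt(math.pi) * Eh
        expected = PD + 0.1 * beta / math.sqrt(Ad)
        assert tube_law_pressure(A, Ad, 0.0, Eh, 0.0, PD) == pytest.approx(
            expected, rel=1e-12)

    def test_linearized_speed_matches_wave_speed(self):
        """Numeric dP/dA at Ad times Ad/rho equals c_d^2 to < 0.1%."""
        Rd = 0.008
        Ad = math.pi * Rd**2
        Eh = 600.0
        eps = 1e-9 * Ad
        dPdA = (tube_law_pressure(Ad + eps, Ad, 0, Eh, 0, PD)
                - tube_law_pressure(Ad - eps, Ad, 0, Eh, 0, PD)) / (2 * eps)
        c2 = dPdA * Ad / RHO
        assert math.sqrt(c2) == pytest.approx(
            wave_speed(Eh, Rd, RHO), rel=1e-3)

    def test_viscous_term_sign(self):
        Ad = 1e-4
        p_expand = tube_law_pressure(Ad, Ad, 1e-5, 500.0, 0.8, PD)
        p_shrink = tube_law_pressure(Ad, Ad, -1e-5, 500.0, 0.8, PD)
        assert p_expand > PD > p_shrink

    def test_nonpositive_area_raises(self):
        with pytest.raises(SolverError):
            tube_law_pressure(-1e-5, 1e-4, 0, 500.0, 0.6, PD)


class TestWindkessel:
    def test_steady_state_pressure(self):
        o = WindkesselOutlet(segment_id="t", R1=1e7, R2=1e8, C=1e-9, P_out=500.0)
        Q0 = 8e-5
        dt = 1e-4
        p = None
        for _ in range(int(10 * o.R2 * o.C / dt)):
            p, _ = windkessel_step(o, Q0, dt)
        assert p == pytest.approx(Q0 * (o.R1 + o.R2) + o.P_out, rel=1e-3)

    def test_rc_decay_constant(self):
        """Zero inflow: compliant pressure decays with tau = R2*C within 1%."""
        o = WindkesselOutlet(segment_id="t", R1=1e7, R2=2e8, C=5e-9, P_out=0.0)
        pc0 = 1e4
        o.V = o.C * pc0
        tau = o.R2 * o.C
        dt = tau / 2000.0
        n = int(round(tau / dt))
        for _ in range(n):  # integrate for exactly one time constant
            windkessel_step(o, 0.0, dt)
        pc = o.V / o.C
        assert pc == pytest.approx(pc0 * math.exp(-1.0), rel=1e-2)

    def test_diastolic_decay_constant_physiological_and_age_decreasing(
            self, age_sweep):
        """Aortic diastole decays like a windkessel discharge: the fitted
        time constant is of seconds order and falls with age (stiffer,
        less compliant systems discharge faster)."""

        def tau(age):
            w = age_sweep[age][1]["aortic_root"]["P"]
            t, p = w.t, w.y
            late = (t > 0.55 * w.duration) & (t < 0.95 * w.duration)
            # exponential toward P_out = 0: log-linear fit of late diastole
            return -1.0 / np.polyfit(t[late], np.log(p[late]), 1)[0]

        t25, t75 = tau(25), tau(75)
        assert 0.5 < t75 < t25 < 4.0


class TestJunction:
    @staticmethod
    def _state(radius, u, cd, A_factor=1.0):
        Eh = 1.5 * RHO * radius * cd**2
        Ad = math.pi * radius**2
        return {"A": A_factor * Ad, "u": u, "Ad": Ad, "Eh": Eh}

    def test_symmetric_bifurcation_splits_flow(self):
        parent = self._state(0.01, 0.5, 5.0, A_factor=1.05)
        d = self._state(0.0071, 0.0, 6.0)
        out = junction_solve(parent, [dict(d), dict(d)], BloodProperties(), PD)
        assert out[1]["Q"] == pytest.approx(out[2]["Q"], rel=1e-9)
        assert out[0]["Q"] == pytest.approx(out[1]["Q"] + out[2]["Q"], rel=1e-9)

    def test_mass_balance_residual(self):
        parent = self._state(0.01, 0.8, 5.0, A_factor=1.08)
        d1 = self._state(0.008, 0.2, 5.5, A_factor=1.02)
        d2 = self._state(0.005, 0.1, 6.5, A_factor=0.99)
        out = junction_solve(parent, [d1, d2], BloodProperties(), PD)
        resid = abs(out[0]["Q"] - out[1]["Q"] - out[2]["Q"])
        assert resid < 1e-10 * max(abs(o["Q"]) for o in out)

    def test_identical_tubes_transparent(self):
        """A 1->1 'junction' between identical tubes reflects < 1%."""
        k3 = 1.5 * RHO * 36.0
        segs = {}
        for name in ("a", "b"):
            segs[name] = ArterialSegment(
                id=name, length=0.5, inlet_radius=0.01, outlet_radius=0.01,
                k1=0.0, k2=-1.0, k3=k3, b0=0.0, b1=0.0)
        Ad = math.pi * 0.01**2
        Zc = RHO * 6.0 / Ad
        out = WindkesselOutlet(segment_id="b", R1=Zc, R2=10 * Zc, C=1e-9,
                               P_out=PD)
        net = Network(
            segments=segs, junctions={"a": ["b"]}, outlets=[out],
            inlet_segment="a",
            sites={"mid_a": MeasurementSite("mid_a", "a", 0.5)},
            blood=BloodProperties(), diastolic_pressure=PD)
        # biphasic (zero net volume) pulse: no windkessel DC charging, so any
        # signal in the echo window is genuine wave reflection
        T, fs = 1.0, 4000.0
        t = np.arange(int(T * fs)) / fs
        q = -2e-6 * np.gradient(np.exp(-(((t - 0.05) / 0.01) ** 2)), t) * 0.01
        inflow = Waveform(t=t, y=q, kind="Q")
        res = simulate_subject(net, inflow,
                               options=SolverOptions(max_cycles=1))
        p = res["mid_a"]["P"].y
        t = res["mid_a"]["P"].t
        # incident pulse passes mid_a around 0.05+0.04 s; a reflection from
        # the junction (at 0.5 m) would return around 0.05+0.125 s
        incident = np.max(np.abs(p[(t > 0.0) & (t < 0.15)] - PD))
        echo = np.max(np.abs(p[(t > 0.16) & (t < 0.3)] - PD))
        assert echo < 0.01 * incident


class TestPropagation:
    def test_small_pulse_speed_matches_theory(self):
        """Foot-tracked speed of a small pulse within 2% of Eq.-3 c_d."""
        net, cd = single_tube_network(length=1.0, n_nodes=201, cd_target=6.0)
        inflow = gaussian_pulse_inflow()
        res = simulate_subject(net, inflow, options=SolverOptions(max_cycles=1))
        t = res["s0"]["P"].t

        def arrival(y):
            yn = (y - y[0]) / (np.max(y) - y[0])
            i = int(np.argmax(yn > 0.5))
            return float(np.interp(0.5, [yn[i - 1], yn[i]], [t[i - 1], t[i]]))

        dt = arrival(res["s1"]["P"].y) - arrival(res["s0"]["P"].y)
        assert 0.8 / dt == pytest.approx(cd, rel=0.02)

    def test_zero_inflow_stays_at_equilibrium(self):
        net, _ = single_tube_network()
        T, fs = 0.5, 2000.0
        t = np.arange(int(T * fs)) / fs
        res = simulate_subject(net, Waveform(t=t, y=np.zeros(t.size), kind="Q"),
                               options=SolverOptions(max_cycles=1))
        p = res["s0"]["P"].y
        assert np.allclose(p, PD, atol=1e-6 * PD)

    def test_steady_poiseuille_gradient(self):
        """Constant inflow: the mean axial pressure gradient matches the
        parabolic-profile friction law -8*pi*mu*Q/A^2."""
        net, _ = single_tube_network(length=1.0, radius=0.004, n_nodes=101,
                                     C=1e-8, sites=(0.2, 0.5, 0.8))
        mu = net.blood.viscosity
        Q0 = 1e-5
        T, fs = 3.0, 2000.0
        t = np.arange(int(T * fs)) / fs
        ramp = np.minimum(t / 0.5, 1.0) * Q0
        res = simulate_subject(net, Waveform(t=t, y=ramp, kind="Q"),
                               options=SolverOptions(max_cycles=3,
                                                     periodicity_tol=1e-6))
        p0 = res["s0"]["P"].y[-50:].mean()
        p1 = res["s2"]["P"].y[-50:].mean()
        # the tube is distended at the operating pressure: evaluate the
        # friction law at the actual mid-tube area and flow
        A = res["s1"]["A"].y[-50:].mean()
        Q = res["s1"]["Q"].y[-50:].mean()
        expected = 8 * math.pi * mu * Q / A**2 * 0.6  # over 0.6 m
        assert p0 - p1 == pytest.approx(expected, rel=0.05)

    def test_matched_outlet_no_secondary_oscillation(self):
        """R1 = Z_c termination: diastolic decay is monotone; reflection
        ripple stays under 2% of pulse pressure."""
        net, _ = single_tube_network(length=0.5, n_nodes=101, C=5e-9)
        inflow = generate_inflow(InflowParams(HR=60, SV=40, LVET=300, fs=2000))
        res = simulate_subject(net, inflow,
                               options=SolverOptions(max_cycles=8))
        p = res["s0"]["P"].y
        t = res["s0"]["P"].t
        pp = p.max() - p.min()
        dia = (t > 0.45) & (t < 0.95)
        ripple = p[dia] - np.minimum.accumulate(p[dia])
        assert np.max(ripple) < 0.02 * pp

    def test_q_equals_u_times_a(self, age_sweep):
        _, pws, _, _ = age_sweep[25]
        for site in pws.sites():
            w = pws[site]
            assert np.allclose(w["Q"].y, w["U"].y * w["A"].y, rtol=1e-9)

    def test_mass_conservation_all_ages(self, age_sweep):
        for age, (_, pws, _, _) in age_sweep.items():
            assert pws.converged
            assert pws.mass_residual < 0.005, f"age {age}"

    def test_map_consistent_with_windkessel_balance(self, age_sweep):
        """Cycle-averaged MAP = CO * R_effective + P_out within 2%."""
        subject, pws, net, row = age_sweep[25]
        co = subject.values["HR"] * subject.values["SV"] * units.ML_M3 / 60.0
        expected = co * net.equivalent_resistance() / units.MMHG_PA
        assert row["aortic_MAP"] == pytest.approx(expected, rel=0.02)

    def test_grid_refinement_stability(self):
        """Halving node spacing changes SBP by < 0.5 mmHg on a tube."""
        sbps = []
        for n in (51, 101):
            net, _ = single_tube_network(length=0.5, n_nodes=n, C=5e-9)
            inflow = generate_inflow(InflowParams(HR=60, SV=40, LVET=300,
                                                  fs=2000))
            res = simulate_subject(net, inflow,
                                   options=SolverOptions(max_cycles=8))
            sbps.append(res["s0"]["P"].y.max() / units.MMHG_PA)
        assert abs(sbps[1] - sbps[0]) < 0.5

    def test_viscoelastic_hysteresis(self):
        """Gamma = 0 closes the P-A loop; Gamma > 0 dissipates (area > 0)."""
        areas = {}
        for gamma_off in (True, False):
            net, _ = single_tube_network(length=0.5, n_nodes=51, C=5e-9,
                                         gamma_off=gamma_off)
            inflow = generate_inflow(InflowParams(HR=60, SV=40, LVET=300,
                                                  fs=2000))
            res = simulate_subject(net, inflow,
                                   options=SolverOptions(max_cycles=10,
                                                         periodicity_tol=1e-4))
            P, A = res["s0"]["P"].y, res["s0"]["A"].y
            # signed loop area via the shoelace integral over the cycle
            areas[gamma_off] = abs(np.sum(P * np.roll(A, -1) - A * np.roll(P, -1)) / 2)
        assert areas[False] > 5 * areas[True]


class TestPPG:
    def test_normalization_exact(self):
        t = np.arange(200) / 500.0
        v = 1e-6 * (2 + np.sin(2 * np.pi * t))
        ppg = synthesize_ppg(Waveform(t=t, y=v, kind="V"))
        assert ppg.y.min() == 0.0
        assert ppg.y.max() == 1.0

    def test_affine_invariance(self):
        t = np.arange(200) / 500.0
        v = np.cos(2 * np.pi * t) + 3
        p1 = synthesize_ppg(Waveform(t=t, y=v, kind="V"))
        p2 = synthesize_ppg(Waveform(t=t, y=2.5 * v + 7.0, kind="V"))
        assert np.allclose(p1.y, p2.y, atol=1e-12)

    def test_constant_volume_degenerate(self):
        t = np.arange(100) / 500.0
        with pytest.raises(DegenerateSignalError):
            synthesize_ppg(Waveform(t=t, y=np.ones(100), kind="V"))

    def test_simulated_ppg_in_unit_range(self, age_sweep):
        _, pws, _, _ = age_sweep[25]
        ppg = pws["finger"]["PPG"].y
        assert ppg.min() == 0.0 and ppg.max() == 1.0


class TestOptions:
    def test_bad_cfl(self):
        with pytest.raises(ParameterError):
            SolverOptions(cfl=1.5)

    def test_bad_friction_model(self):
        with pytest.raises(ParameterError):
            SolverOptions(friction_model="plug")

    def test_flat_profile_option_runs(self):
        net, _ = single_tube_network(length=0.5, n_nodes=26)
        inflow = gaussian_pulse_inflow(T=0.5)
        res = simulate_subject(net, inflow,
                               options=SolverOptions(max_cycles=1,
                                                     friction_model="flat"))
        assert np.all(np.isfinite(res["s0"]["P"].y))
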