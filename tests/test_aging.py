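"""Aging model: interpolation, offsets, calibration, grid, plausibility."""

import math

import numpy as np
import pytest

from pwdb import units
from pwdb.aging import (VARIED_PARAMETERS, aging_parameters, apply_offsets,
                        calibrate_resistances, calibrate_stiffness,
                        calibrate_stiffness_for_network, generate_grid,
                        load_plausibility_reference, plausibility_filter)
from pwdb.errors import DomainError, ParameterError
from pwdb.fixtures import AORTIC_PATH, BEDS, make_fixture_network, reference_subject
from pwdb.network import wall_stiffness, wave_speed


class TestAgingParameters:
    def test_prescribed_length_anchors(self):
        assert aging_parameters(25).mean("proximal_aortic_length") == 80.0
        assert aging_parameters(75).mean("proximal_aortic_length") == 112.0

    def test_prescribed_pvc_anchors(self):
        assert aging_parameters(25).mean("pvc") == pytest.approx(40.1)
        assert aging_parameters(75).mean("pvc") == pytest.approx(17.3)

    @pytest.mark.parametrize("age", [25, 35, 45, 55, 65, 75])
    def test_decade_anchors_reproduced(self, age):
        from pwdb.aging import load_aging_tables
        tables = load_aging_tables()
        i = tables["ages"].index(age)
        p = aging_parameters(age, tables)
        for name, spec in tables["parameters"].items():
            assert p.mean(name) == pytest.approx(spec["mean"][i], rel=1e-12)

    def test_interpolation_betweenness(self):
        p25, p30, p35 = (aging_parameters(a) for a in (25, 30, 35))
        for name in ("SV", "MAP", "proximal_aortic_length", "pvc",
                     "diameter_ascending", "pwv_aortic"):
            lo, hi = sorted((p25.mean(name), p35.mean(name)))
            assert lo <= p30.mean(name) <= hi

    @pytest.mark.parametrize("age", [24.9, 75.1, -3])
    def test_age_domain(self, age):
        with pytest.raises(DomainError):
            aging_parameters(age)


class TestApplyOffsets:
    def test_zero_offsets_is_identity(self):
        p = aging_parameters(45)
        s = apply_offsets(p, {})
        assert s.is_baseline
        assert s.values["HR"] == p.mean("HR")
        assert s.values["MAP"] == p.mean("MAP")
        assert s.values["pwv_aortic"] == pytest.approx(p.mean("pwv_aortic"))

    def test_hr_offset_shifts_lvet_mean(self):
        """HR +1 SD (+11 beats/min) moves the LVET mean by -0.926*11 before
        LVET's own offset applies."""
        p = aging_parameters(25)
        s = apply_offsets(p, {"HR": +1})
        expected = p.mean("LVET") - 0.926 * 11.0
        assert s.values["LVET"] == pytest.approx(expected, rel=1e-9)

    def test_asymmetric_pwv_sd_uses_correct_side(self):
        tables = {
            "ages": [25, 75],
            "parameters": {
                "HR": {"mean": [70, 70], "sd": [10, 10]},
                "SV": {"mean": [60, 60], "sd": [10, 10]},
                "LVET": {"mean": [282, 282], "sd": [20, 20]},
                "PFT": {"mean": [79, 79], "sd": [10, 10]},
                "RFV": {"mean": [0.7, 0.7], "sd": [0.6, 0.6]},
                "MAP": {"mean": [90, 90], "sd": [7, 7]},
                "DBP": {"mean": [75, 75], "sd": [7, 7]},
                "proximal_aortic_length": {"mean": [80, 112], "sd": [0, 0]},
                "diameter_ascending": {"mean": [36, 42], "sd": [3, 3]},
                "diameter_desc_thoracic": {"mean": [24, 28], "sd": [2, 2]},
                "diameter_abdominal": {"mean": [14, 16], "sd": [1, 1]},
                "diameter_carotid": {"mean": [6, 7], "sd": [0.5, 0.5]},
                "pwv_aortic": {"mean": [6, 10], "sd_plus": [2.0, 2.0],
                               "sd_minus": [0.5, 0.5]},
                "pwv_arm": {"mean": [9, 13], "sd_plus": [1, 1], "sd_minus": [1, 1]},
                "pwv_leg": {"mean": [9, 12], "sd_plus": [1, 1], "sd_minus": [1, 1]},
                "pvc": {"mean": [40, 17], "sd": [0, 0]},
            },
            "varied": list(VARIED_PARAMETERS),
            "pwv_map_sensitivity": 0.0,
        }
        p = aging_parameters(25, tables)
        up = apply_offsets(p, {"PWV": +1})
        dn = apply_offsets(p, {"PWV": -1})
        assert up.values["pwv_aortic"] == pytest.approx(8.0)   # mean + sd_plus
        assert dn.values["pwv_aortic"] == pytest.approx(5.5)   # mean - sd_minus

    def test_map_offset_moves_pwv_target(self):
        p = aging_parameters(25)
        s = apply_offsets(p, {"MAP": +1})
        dmap = s.values["MAP"] - p.mean("MAP")
        expected = p.mean("pwv_aortic") + p.pwv_map_sensitivity * dmap
        assert s.values["pwv_aortic"] == pytest.approx(expected, rel=1e-9)

    def test_invalid_offsets_rejected(self):
        p = aging_parameters(25)
        with pytest.raises(ParameterError):
            apply_offsets(p, {"HR": 2})
        with pytest.raises(ParameterError):
            apply_offsets(p, {"PFT": 1})


class TestCalibrateStiffness:
    def test_parameter_recovery(self):
        """Targets generated from known constants are re-fit to < 0.5%."""
        k_true = (2.0e6, -2253.0, 8.65e4)
        radii = {"aortic": 0.011, "arm": 0.002, "leg": 0.0025}
        targets = {
            key: wave_speed(wall_stiffness(r, *k_true), r)
            for key, r in radii.items()}
        (k1, k2, k3), resid = calibrate_stiffness(targets, radii)
        for key, r in radii.items():
            got = wave_speed(wall_stiffness(r, k1, k2, k3), r)
            assert got == pytest.approx(targets[key], rel=5e-3)

    def test_single_anchor_closed_form(self):
        """With k1 = 0 the law inverts to k3 = 1.5*rho*c^2."""
        rho, target, rd = 1060.0, 5.9, 0.011
        k3 = 1.5 * rho * target**2
        assert wave_speed(wall_stiffness(rd, 0.0, -1.0, k3), rd, rho) == \
            pytest.approx(target, rel=1e-12)

    def test_network_path_calibration_hits_target(self):
        subject = reference_subject(25)
        net = make_fixture_network("reduced", subject=subject)
        (k1, k2, k3), resid = calibrate_stiffness_for_network(
            net, subject.values, list(AORTIC_PATH), 0.002, 0.0025)
        assert abs(resid[0]) < 5e-3  # path PWV error [m/s]
        # recompute the harmonic-mean path speed independently
        num = den = 0.0
        for sid in AORTIC_PATH:
            seg = net.segments[sid]
            r = seg.node_radii()
            rm = 0.5 * (r[1:] + r[:-1])
            cd = wave_speed(wall_stiffness(rm, k1, k2, k3), rm)
            num += seg.length
            den += float(np.sum(seg.dx / cd))
        assert num / den == pytest.approx(subject.values["pwv_aortic"], rel=1e-3)


class TestCalibrateResistances:
    def test_total_resistance_arithmetic(self):
        # MAP 93.3 mmHg, CO 5 l/min, P_out 0 -> R_T ~ 1.49e8 Pa s/m^3
        rt = 93.3 * units.MMHG_PA / (5.0 * units.LMIN_M3S)
        assert rt == pytest.approx(1.49e8, rel=0.01)

    def test_equal_area_outlets_get_equal_resistance(self):
        net = make_fixture_network("reduced", subject=reference_subject(25))
        calibrate_resistances(90.0, 5.0, 0.0, net, 40e-9, beds=BEDS)
        radial = net.outlet_for("radial")
        ulnar = net.outlet_for("ulnar")
        assert radial.R1 + radial.R2 == pytest.approx(ulnar.R1 + ulnar.R2,
                                                      rel=1e-9)

    def test_equivalent_resistance_matches_target(self):
        net = make_fixture_network("reduced", subject=reference_subject(25))
        map_t, co = 89.2, 4.876
        calibrate_resistances(map_t, co, 0.0, net, 40.1e-9, beds=BEDS)
        rt = map_t * units.MMHG_PA / (co * units.LMIN_M3S)
        assert net.equivalent_resistance() == pytest.approx(rt, rel=1e-9)
        assert sum(o.C for o in net.outlets) == pytest.approx(40.1e-9, rel=1e-12)

    def test_nonpositive_target_rejected(self):
        net = make_fixture_network("reduced", subject=reference_subject(25))
        with pytest.raises(ParameterError):
            calibrate_resistances(0.0, 5.0, 10.0, net, 40e-9)


class TestGenerateGrid:
    def test_one_age_gives_729(self):
        assert len(generate_grid([25])) == 729

    def test_six_ages_give_4374(self):
        grid = generate_grid([25, 35, 45, 55, 65, 75])
        assert len(grid) == 4374

    def test_single_parameter_mode_gives_3(self):
        grid = generate_grid([45], varied=("HR",))
        assert len(grid) == 3
        assert sorted(s.offsets["HR"] for s in grid) == [-1, 0, 1]

    def test_baseline_is_grid_member(self):
        grid = generate_grid([25], varied=("HR", "MAP"))
        assert sum(s.is_baseline for s in grid) == 1

    def test_deterministic_ordering(self):
        g1 = generate_grid([25], varied=("HR", "SV"))
        g2 = generate_grid([25], varied=("HR", "SV"))
        assert [s.label() for s in g1] == [s.label() for s in g2]

    def test_symmetric_grid_mean_recovers_parameter_mean(self):
        p = aging_parameters(25)
        grid = generate_grid([25], varied=("SV",))
        assert np.mean([s.values["SV"] for s in grid]) == pytest.approx(
            p.mean("SV"))


class TestPlausibilityFilter:
    @staticmethod
    def _summary_at_means(ref, age):
        return {q: float(np.interp(age, ref.ages, ref.quantities[q]["mean"]))
                for q in ref.quantities}

    def test_reference_means_are_plausible(self):
        ref = load_plausibility_reference()
        v = plausibility_filter(self._summary_at_means(ref, 45), ref, 45)
        assert v["plausible"] and not v["violations"]

    def test_three_sd_outlier_named(self):
        ref = load_plausibility_reference()
        s = self._summary_at_means(ref, 45)
        s["brachial_SBP"] += 3.0 * float(
            np.interp(45, ref.ages, ref.quantities["brachial_SBP"]["sd"]))
        v = plausibility_filter(s, ref, 45)
        assert not v["plausible"]
        assert v["violations"] == ["brachial_SBP"]

    def test_boundary_is_closed_interval(self):
        """A value exactly at mean + 2.575 sd is still plausible."""
        ref = load_plausibility_reference()
        s = self._summary_at_means(ref, 45)
        lo, hi = ref.interval("aortic_PP", 45)
        s["aortic_PP"] = hi
        assert plausibility_filter(s, ref, 45)["plausible"]
        s["aortic_PP"] = math.nextafter(hi, math.inf)
        assert not plausibility_filter(s, ref, 45)["plausible"]

    def test_missing_quantity_is_error(self):
        ref = load_plausibility_reference()
        s = self._summary_at_means(ref, 45)
        del s["PP_amp"]
        with pytest.raises(ParameterError):
            plausibility_filter(s, ref, 45)
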