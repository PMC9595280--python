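"""Unit and property tests for the closed-loop circulation surrogate."""

import numpy as np
import pytest
from dataclasses import replace

from s3sim import (ChamberParams, ConditionConfig, ShuntSpec, ValveSpec,
                   apply_condition, exercise_hr, reference_parameters,
                   simulate_beat, valve_flow)
from s3sim.conditions import CONDITION_SWEEPS


class TestValveFlow:
    def test_zero_gradient_gives_zero_flow(self):
        assert valve_flow(10.0, 10.0, 5.0) == 0.0

    def test_zero_area_gives_zero_flow(self):
        assert valve_flow(30.0, 10.0, 0.0) == 0.0

    def test_flow_linear_in_area(self):
        q1 = valve_flow(15.0, 10.0, 2.5)
        q2 = valve_flow(15.0, 10.0, 5.0)
        assert q2 == pytest.approx(2.0 * q1, rel=1e-12)

    def test_flow_sign_follows_gradient(self):
        assert valve_flow(15.0, 10.0, 5.0) > 0
        assert valve_flow(10.0, 15.0, 5.0) < 0

    def test_bernoulli_scaling_away_from_regularisation(self):
        # far from dp=0 the law approaches Q ~ sqrt(dp)
        q1, q4 = valve_flow(11.0, 10.0, 5.0), valve_flow(14.0, 10.0, 5.0)
        assert q4 / q1 == pytest.approx(2.0, rel=0.05)


class TestParameterTypes:
    def test_chamber_invariants_enforced(self):
        with pytest.raises(ValueError):
            ChamberParams(wall_volume=100.0, emax=0.05, eed=0.06, tau=40.0,
                          activation_onset=0.0, v0=10.0, t_rise=200.0,
                          v_scale=100.0)

    def test_valve_invariants_enforced(self):
        with pytest.raises(ValueError):
            ValveSpec(area_open=5.0, leak_fraction=1.0)
        with pytest.raises(ValueError):
            ValveSpec(area_open=-1.0)

    def test_shunt_requires_diameter(self):
        with pytest.raises(ValueError):
            ShuntSpec(location="atrial", diameter=0.0)
        assert ShuntSpec(location="atrial", diameter=10.0).area == pytest.approx(
            np.pi * 0.25, rel=1e-12)

    def test_config_rejects_out_of_protocol(self):
        with pytest.raises(ValueError):
            ConditionConfig(condition="MR", severity_index=9)
        with pytest.raises(ValueError):
            ConditionConfig(condition="nonsense")


class TestConditionProtocol:
    def test_reference_is_identity_on_structure(self):
        p = reference_parameters()
        q = apply_condition(ConditionConfig.make("reference"), p)
        assert q.mv == p.mv and q.shunt == p.shunt
        assert q.lv.eed == p.lv.eed and q.lv.tau == p.lv.tau

    @pytest.mark.parametrize("sev,leak", [(1, 0.08), (2, 0.10), (3, 0.12),
                                          (4, 0.14)])
    def test_regurgitation_leak_steps(self, sev, leak):
        p = apply_condition(ConditionConfig.make("MR", sev),
                            reference_parameters())
        assert p.mv.leak_fraction == pytest.approx(leak)

    @pytest.mark.parametrize("sev,sten", [(1, 0.5), (4, 0.8)])
    def test_stenosis_steps(self, sev, sten):
        p = apply_condition(ConditionConfig.make("TS", sev),
                            reference_parameters())
        assert p.tv.stenosis_fraction == pytest.approx(sten)

    def test_hfpef_grade_three_scalings(self):
        base = reference_parameters()
        p = apply_condition(ConditionConfig.make("HFpEF", 3), base)
        assert p.lv.eed == pytest.approx(2.30 * base.lv.eed, rel=1e-12)
        assert p.lv.tau == pytest.approx(1.80 * base.lv.tau, rel=1e-12)

    def test_aging_scales_both_ventricles(self):
        base = reference_parameters()
        p = apply_condition(ConditionConfig.make("aging", 6), base)
        for side in ("lv", "rv"):
            assert getattr(p, side).eed == pytest.approx(
                1.12 * getattr(base, side).eed, rel=1e-12)
            assert getattr(p, side).tau == pytest.approx(
                1.12 * getattr(base, side).tau, rel=1e-12)

    @pytest.mark.parametrize("sev,mm", [(1, 6.0), (4, 12.0)])
    def test_shunt_diameter_steps(self, sev, mm):
        p = apply_condition(ConditionConfig.make("VSD", sev),
                            reference_parameters())
        assert p.shunt.location == "ventricular"
        assert p.shunt.diameter == mm

    def test_exercise_hr_interpolation_endpoints(self):
        assert exercise_hr(5.0) == 70.0
        assert exercise_hr(14.0) == 130.0
        assert exercise_hr(8.0) == pytest.approx(90.0)

    def test_every_sweep_step_is_constructible(self):
        base = reference_parameters()
        for cond, sweep in CONDITION_SWEEPS.items():
            for sev in sweep:
                apply_condition(ConditionConfig.make(cond, sev), base)


class TestSimulateBeat:
    def test_blood_volume_conserved_over_cycle(self, reference):
        _, _, _, series, _ = reference
        tot = series.total_volume()
        assert (tot.max() - tot.min()) / tot.mean() < 1e-6

    def test_e_and_a_waves_present_both_sides(self, reference):
        _, _, _, series, _ = reference
        onset_a = series.meta["atrial_onset_ms"]
        for q, v in ((series.q_mv, series.v_lv), (series.q_tv, series.v_rv)):
            t_es = series.t_ms[int(np.argmin(v))]
            dias = (series.t_ms > t_es) & (series.t_ms < onset_a)
            late = series.t_ms >= onset_a
            assert q[dias].max() > 100.0   # E wave
            assert q[late].max() > 50.0    # A wave

    def test_volumes_positive_and_pressures_physiological(self, reference):
        _, _, _, s, _ = reference
        for v in (s.v_la, s.v_lv, s.v_ra, s.v_rv):
            assert np.all(v > 0)
        assert 60.0 < s.p_ao.min() < s.p_ao.max() < 140.0

    def test_closed_valve_carries_no_flow(self, reference):
        # no leak configured: AV flow is never negative during systole
        _, _, _, s, _ = reference
        assert s.q_mv.min() >= 0.0
        assert s.q_tv.min() >= 0.0

    def test_no_contraction_means_no_circulation(self):
        p = reference_parameters()
        for name in ("la", "lv", "ra", "rv"):
            c = getattr(p, name)
            setattr(p, name, replace(c, emax=c.eed * (1.0 + 1e-9)))
        # pressures are time-independent, so the loop drains toward a
        # no-flow equilibrium (slowly: the venous pools discharge over
        # tens of seconds) -- a loose periodicity tolerance suffices
        series, y = simulate_beat(p, 70.0, tol=5e-3, max_beats=150)
        assert np.abs(series.q_av).max() < 1.0  # mL/s

    def test_csv_export_schema(self, reference, tmp_path):
        _, _, _, s, _ = reference
        out = tmp_path / "hemo.csv"
        s.to_csv(out)
        header = out.read_text().splitlines()[0]
        assert header == ("t_ms,p_la,p_lv,p_ra,p_rv,p_ao,p_pu,"
                          "v_la,v_lv,v_ra,v_rv,q_mv,q_tv,q_av,q_pv,q_shunt,"
                          "a_mv,a_tv,a_av,a_pv")


class TestHomeostaticRegulation:
    def test_reference_setpoints_reached(self, reference):
        _, _, _, series, _ = reference
        assert series.mean_arterial_pressure() == pytest.approx(91.0, abs=0.5)
        assert series.cardiac_output() == pytest.approx(5.0, rel=0.01)

    def test_adapted_set_is_a_fixed_point(self, reference):
        from s3sim import homeostatic_adapt
        _, adapted, y, _, _ = reference
        p2, y2, n2 = homeostatic_adapt(adapted, 70.0, 5.0, y0=y)
        assert n2 <= 5
        assert p2.systemic.r_per == pytest.approx(adapted.systemic.r_per,
                                                  rel=0.02)
        assert p2.total_volume == pytest.approx(adapted.total_volume, rel=0.01)
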