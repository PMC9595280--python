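"""Unit and property tests for the cardiohemic vibration generator."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from s3sim import (CardiohemicParams, ImpactEvent, NoTriggerError, S3Waveform,
                   VibrationParams, combine_sides, compute_cardiohemic_mass,
                   detect_impact, effective_endocardial_area, impact_velocity,
                   inflow_mass, inflow_velocity, s3_waveform, vibration_params)
from s3sim.hemodynamics import HemoTimeSeries


def _toy_series(q_mv, q_tv=None, n=857, atrial_onset=716.0):
    """Minimal HemoTimeSeries carrying prescribed AV flows."""
    t = np.arange(n, dtype=float)
    z = np.zeros(n)
    v_lv = 120.0 - 60.0 * np.sin(np.pi * np.clip(t / 400.0, 0, 1))
    q_tv = q_mv if q_tv is None else q_tv
    return HemoTimeSeries(
        t_ms=t, p_la=z + 10, p_lv=z + 8, p_ra=z + 5, p_rv=z + 4,
        p_ao=z + 91, p_pu=z + 15,
        v_la=z + 50, v_lv=v_lv, v_ra=z + 50, v_rv=v_lv.copy(),
        q_mv=q_mv, q_tv=q_tv, q_av=z, q_pv=z, q_shunt=z,
        a_mv=z + 5.0, a_tv=z + 6.0, a_av=z + 4.0, a_pv=z + 4.5,
        v_sa=z + 500, v_sv=z + 3000, v_pa=z + 150, v_pv=z + 600,
        meta=dict(hr=70.0, atrial_onset_ms=atrial_onset,
                  lv_wall_volume=145.0, rv_wall_volume=48.0,
                  lv_eed=0.06, rv_eed=0.035),
    )


class TestCardiohemicMass:
    def test_hand_computed_masses(self):
        p = compute_cardiohemic_mass(150.0, 120.0)
        assert p.m_myo == pytest.approx(0.15825, abs=1e-12)
        assert p.m_bld == pytest.approx(0.1260, abs=1e-12)
        assert p.M_ch == pytest.approx(0.28425, abs=1e-12)

    def test_linearity_in_volumes(self):
        a = compute_cardiohemic_mass(150.0, 120.0)
        b = compute_cardiohemic_mass(300.0, 240.0)
        assert b.M_ch == pytest.approx(2.0 * a.M_ch, rel=1e-12)

    @pytest.mark.parametrize("wall,cavity", [(0.0, 120.0), (150.0, 0.0),
                                             (-1.0, 120.0)])
    def test_degenerate_geometry_rejected(self, wall, cavity):
        with pytest.raises(ValueError):
            compute_cardiohemic_mass(wall, cavity)


class TestImpactDetection:
    def test_triangular_pulse_peak_found(self):
        n = 857
        q = np.zeros(n)
        q[300:500] = np.interp(np.arange(300, 500), [300, 400, 500], [0, 400, 0])
        t_imp = detect_impact(_toy_series(q), "LV")
        assert t_imp == pytest.approx(400.0, abs=1.0)

    def test_a_wave_excluded_from_search(self):
        # a taller peak after atrial onset must not win
        n = 857
        q = np.zeros(n)
        q[350:450] = 300.0 * np.hanning(100)
        q[720:820] = 500.0 * np.hanning(100)
        t_imp = detect_impact(_toy_series(q), "LV")
        assert 350.0 < t_imp < 450.0

    def test_no_inflow_signals_no_trigger(self):
        with pytest.raises(NoTriggerError):
            detect_impact(_toy_series(np.zeros(857)), "LV")


class TestImpactQuantities:
    def test_snapshot_mass_hand_value(self):
        q = np.full(857, 500.0)
        m = inflow_mass(_toy_series(q), 400.0, "LV")
        assert m == pytest.approx(5.25e-4, rel=1e-12)

    def test_snapshot_mass_linear_in_flow(self):
        s1 = _toy_series(np.full(857, 250.0))
        s2 = _toy_series(np.full(857, 500.0))
        assert inflow_mass(s2, 400.0, "LV") == pytest.approx(
            2.0 * inflow_mass(s1, 400.0, "LV"), rel=1e-12)

    def test_velocity_hand_value(self):
        v = inflow_velocity(_toy_series(np.full(857, 500.0)), 400.0, "LV")
        assert v == pytest.approx(1.0, rel=1e-12)  # 500 mL/s through 5 cm^2

    def test_zero_flow_zero_mass_and_velocity(self):
        s = _toy_series(np.zeros(857))
        assert inflow_mass(s, 400.0, "LV") == 0.0
        assert inflow_velocity(s, 400.0, "LV") == 0.0

    def test_post_impact_velocity_hand_value(self):
        assert impact_velocity(5.25e-4, 1.0, 0.28425) == pytest.approx(
            5.25e-4 / (0.28425 + 5.25e-4), rel=1e-12)

    def test_large_mass_limit_approaches_inflow_velocity(self):
        assert impact_velocity(1e6, 0.8, 0.3) == pytest.approx(0.8, rel=1e-6)

    @given(m=st.floats(1e-8, 1e-2), v=st.floats(0.0, 3.0),
           M=st.floats(0.01, 2.0))
    @settings(max_examples=200, deadline=None)
    def test_momentum_conserved_to_machine_precision(self, m, v, M):
        va = impact_velocity(m, v, M)
        res = (M + m) * va - m * v
        assert abs(res) <= 4.0 * math.ulp(max(m * v, 1e-300))


class TestVibration:
    def _params(self, k=7800.0, zeta=0.1, mass=0.305):
        c = zeta * 2.0 * math.sqrt(k * mass)
        return vibration_params(k, c, mass)

    def test_modal_quantities_definitions(self):
        p = self._params(k=7800.0, zeta=0.0 + 1e-12, mass=0.305)
        assert p.omega_n == pytest.approx(math.sqrt(7800.0 / 0.305), rel=1e-12)
        p2 = self._params(zeta=0.1)
        assert p2.zeta == pytest.approx(0.1, rel=1e-12)
        assert p2.omega_d == pytest.approx(p2.omega_n * math.sqrt(1 - 0.01),
                                           rel=1e-12)

    def test_zero_damping_omega_d_equals_omega_n(self):
        c0 = VibrationParams(k=7800.0, c=0.0, mass=0.305)
        assert c0.omega_d == c0.omega_n

    def test_waveform_initial_conditions(self):
        ev = ImpactEvent(side="LV", t_impact=400.0, m=5.25e-4, v=1.0, M_ch=0.28425)
        p = self._params()
        w = s3_waveform(ev, p, fs=100000.0)
        assert w.samples[0] == 0.0
        v0 = (w.samples[1] - w.samples[0]) * 100000.0
        assert v0 == pytest.approx(ev.V_a, rel=1e-2)

    def test_undamped_peak_amplitude(self):
        ev = ImpactEvent(side="LV", t_impact=0.0, m=1e-3, v=1.0, M_ch=0.3)
        p = VibrationParams(k=7800.0, c=0.0, mass=0.301)
        w = s3_waveform(ev, p, duration=0.2, fs=50000.0)
        assert w.peak_amplitude == pytest.approx(ev.V_a / p.omega_n, rel=1e-4)

    def test_overdamped_rejected_unless_requested(self):
        p = VibrationParams(k=7800.0, c=1000.0, mass=0.3)
        ev = ImpactEvent(side="LV", t_impact=0.0, m=1e-3, v=1.0, M_ch=0.3)
        with pytest.raises(ValueError):
            s3_waveform(ev, p)
        # explicit request: non-oscillatory decay, x(0)=0, x'(0)=V_a, no ring
        w = s3_waveform(ev, p, fs=1e6, allow_overdamped=True)
        assert w.samples[0] == 0.0
        assert (w.samples[1] - w.samples[0]) * 1e6 == pytest.approx(
            ev.V_a, rel=1e-2)
        assert np.all(w.samples >= -1e-18)  # never crosses zero

    def test_envelope_truncation_cap(self):
        ev = ImpactEvent(side="LV", t_impact=0.0, m=1e-3, v=1.0, M_ch=0.3)
        w = s3_waveform(ev, self._params(zeta=0.01))
        assert w.duration_ms <= 200.0 + 1e-9


class TestCombine:
    def _wave(self, amp, onset, n=100, fs=1000.0, side="LV"):
        return S3Waveform(side=side, fs=fs,
                          samples=amp * np.hanning(n), t_onset=onset)

    def test_zero_partner_is_identity(self):
        a = self._wave(1e-5, 400.0)
        b = self._wave(0.0, 350.0, side="RV")
        c = combine_sides(a, b, 857.0)
        i0 = int(round(a.t_onset))
        assert np.allclose(c.samples[i0:i0 + 100], a.samples)
        assert np.allclose(np.delete(c.samples, slice(i0, i0 + 100)), 0.0)

    def test_commutative(self):
        a = self._wave(1e-5, 400.0)
        b = self._wave(2e-5, 350.0, side="RV")
        assert np.array_equal(combine_sides(a, b, 857.0).samples,
                              combine_sides(b, a, 857.0).samples)

    def test_mismatched_rates_rejected(self):
        a = self._wave(1e-5, 400.0)
        b = self._wave(1e-5, 350.0, fs=2000.0, side="RV")
        with pytest.raises(ValueError):
            combine_sides(a, b, 857.0)


class TestGeometry:
    def test_sphere_area_from_volume(self):
        # 120 mL sphere: r = (3V/4pi)^(1/3)
        r = (3 * 120e-6 / (4 * math.pi)) ** (1 / 3)
        assert effective_endocardial_area(120.0) == pytest.approx(
            4 * math.pi * r * r, rel=1e-12)
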