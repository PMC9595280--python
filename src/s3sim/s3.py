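"""Impact-triggered cardiohemic vibration: the S3 generator.

The third heart sound is modelled as the free vibration of a
one-degree-of-freedom mass-spring-dashpot system.  The vibrating mass
is the *cardiohemic* mass ``M_ch`` — ventricular free-wall myocardium
plus the blood held in the cavity.  At the early-diastolic inflow peak
(the E wave) the atrioventricular pressure gradient is momentarily
balanced, so the system is treated as free; the arriving blood
parcel of mass ``m`` and velocity ``v`` merges with ``M_ch`` in a
perfectly inelastic collision, giving the post-impact velocity

    V_a = m * v / (M_ch + m)          (momentum conservation, V_b = 0)

The subsequent displacement is the underdamped free-vibration solution

    x(t) = V_a / omega_d * exp(-zeta * omega_n * t) * sin(omega_d * t)

with  zeta   = c / (2 * sqrt(k * (M_ch + m)))
      omega_n = sqrt(k / (M_ch + m))
      omega_d = omega_n * sqrt(1 - zeta^2)

``k`` is derived from the chamber's end-diastolic elastance through a
sphere-equivalent endocardial area, ``k = kappa * eed * A_eff^2`` with
a single global scale ``kappa`` calibrated once at the reference
condition and then frozen; ``c`` is 10% of critical damping.  Both are
frozen at the impact instant.  Left and right ventricles use the same
equations with their own masses, flows and valve areas; the final S3
is the sample-wise sum of the two, each placed at its own onset.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .hemodynamics import HemoTimeSeries

__all__ = [
    "RHO_MYO", "RHO_BLD", "DAMPING_RATIO",
    "CardiohemicParams", "ImpactEvent", "VibrationParams", "S3Waveform",
    "NoTriggerError",
    "compute_cardiohemic_mass", "detect_impact", "inflow_mass",
    "inflow_velocity", "impact_velocity", "effective_endocardial_area",
    "estimate_spring_damper", "vibration_params", "calibrate_stiffness_scale",
    "s3_waveform", "combine_sides",
]

RHO_MYO = 1055.0  # myocardial density, kg/m^3
RHO_BLD = 1050.0  # blood density, kg/m^3
#: damping as a fraction of critical damping (the "10% of the spring
#: factor" rule read as 10% of critical damping, which keeps the
#: oscillator underdamped as observed)
DAMPING_RATIO = 0.10
#: conversion mmHg/mL -> Pa/m^3
_MMHG_PER_ML_SI = 133.322 / 1e-6
#: waveform ends when the envelope falls below this fraction of its peak
_ENVELOPE_FLOOR = 0.01
_MAX_DURATION_S = 0.200


class NoTriggerError(RuntimeError):
    """No diastolic E-wave inflow found: no S3 is generated for that side."""


@dataclass
class CardiohemicParams:
    """Masses of the vibrating ventricular system (kg)."""

    m_myo: float
    m_bld: float

    @property
    def M_ch(self) -> float:
        return self.m_myo + self.m_bld


@dataclass
class ImpactEvent:
    """One inelastic blood-inflow impact on a ventricle."""

    side: str            # 'LV' or 'RV'
    t_impact: float      # ms within the cycle
    m: float             # inflowing blood mass over one 1-ms snapshot (kg)
    v: float             # mean inflow velocity before impact (m/s)
    M_ch: float          # cardiohemic mass (kg)
    V_b: float = 0.0     # pre-impact cardiohemic velocity (equilibrium)

    @property
    def V_a(self) -> float:
        """Post-impact velocity from momentum conservation (m/s)."""
        return self.m * self.v / (self.M_ch + self.m)


@dataclass
class VibrationParams:
    """Spring/damper and derived modal quantities, frozen at impact."""

    k: float        # N/m
    c: float        # N*s/m
    mass: float     # M_ch + m (kg)

    @property
    def zeta(self) -> float:
        return self.c / (2.0 * math.sqrt(self.k * self.mass))

    @property
    def omega_n(self) -> float:
        return math.sqrt(self.k / self.mass)

    @property
    def omega_d(self) -> float:
        z = self.zeta
        if z >= 1.0:
            raise ValueError("overdamped system has no damped resonance frequency")
        return self.omega_n * math.sqrt(1.0 - z * z)


@dataclass
class S3Waveform:
    """Sampled displacement x(t) from the impact onward."""

    side: str            # 'LV', 'RV' or 'combined'
    fs: float            # Hz
    samples: np.ndarray  # displacement (m)
    t_onset: float       # onset within the cycle (ms)

    @property
    def duration_ms(self) -> float:
        return len(self.samples) / self.fs * 1000.0

    @property
    def peak_amplitude(self) -> float:
        return float(np.max(np.abs(self.samples))) if len(self.samples) else 0.0


def compute_cardiohemic_mass(wall_volume: float, cavity_volume: float) -> CardiohemicParams:
    """Masses from wall and cavity volumes in mL.

    m_myo = wall_volume * 1055 kg/m^3, m_bld = cavity_volume * 1050 kg/m^3.
    """
    if wall_volume <= 0.0 or cavity_volume <= 0.0:
        raise ValueError("wall and cavity volumes must be positive")
    return CardiohemicParams(m_myo=wall_volume * 1e-6 * RHO_MYO,
                             m_bld=cavity_volume * 1e-6 * RHO_BLD)


def _side_arrays(series: HemoTimeSeries, side: str):
    if side == "LV":
        return series.q_mv, series.a_mv, series.v_lv
    if side == "RV":
        return series.q_tv, series.a_tv, series.v_rv
    raise ValueError(f"side must be 'LV' or 'RV', got {side!r}")


def detect_impact(series: HemoTimeSeries, side: str,
                  min_flow: float = 5.0) -> float:
    """Time (ms) of the early-diastolic inflow peak (E wave) for one side.

    The search window opens at end systole (minimum ventricular
    volume) and closes at atrial activation onset, which excludes the
    A wave.  With the quasi-steady valve law the flow maximum is the
    instant of peak transvalvular driving gradient — the free-vibration
    trigger.

    Raises
    ------
    NoTriggerError
        if diastolic inflow never exceeds ``min_flow`` (mL/s).
    """
    q, _, vol = _side_arrays(series, side)
    t = series.t_ms
    t_es = t[int(np.argmin(vol))]
    t_a = series.meta.get("atrial_onset_ms", t[-1])
    win = (t > t_es) & (t < t_a)
    if not np.any(win) or np.max(q[win]) < min_flow:
        raise NoTriggerError(f"no E-wave inflow for {side}")
    idx = np.flatnonzero(win)
    return float(t[idx[np.argmax(q[idx])]])


def inflow_mass(series: HemoTimeSeries, t_impact: float, side: str) -> float:
    """Blood mass (kg) crossing the valve during the 1-ms impact snapshot."""
    q, _, _ = _side_arrays(series, side)
    qi = float(np.interp(t_impact, series.t_ms, q))
    if qi < 0.0:
        raise ValueError("negative inflow at the trigger instant")
    return qi * 1e-6 * 1e-3 * RHO_BLD  # mL/s -> m^3/s, over 1 ms, times rho


def inflow_velocity(series: HemoTimeSeries, t_impact: float, side: str) -> float:
    """Mean inflow velocity (m/s): flow rate over valve opening area."""
    q, a, _ = _side_arrays(series, side)
    qi = float(np.interp(t_impact, series.t_ms, q))
    ai = float(np.interp(t_impact, series.t_ms, a))
    if ai <= 0.0:
        if abs(qi) > 1e-12:
            raise ValueError("nonzero flow through zero valve area")
        return 0.0
    return (qi * 1e-6) / (ai * 1e-4)


def impact_velocity(m: float, v: float, M_ch: float) -> float:
    """Post-impact velocity V_a = m*v/(M_ch + m) of the merged mass."""
    if M_ch <= 0.0 or m < 0.0:
        raise ValueError("require M_ch > 0 and m >= 0")
    return m * v / (M_ch + m)


def effective_endocardial_area(cavity_volume: float) -> float:
    """Sphere-equivalent endocardial area (m^2) of a cavity volume in mL."""
    if cavity_volume <= 0.0:
        raise ValueError("cavity volume must be positive")
    r = (3.0 * cavity_volume * 1e-6 / (4.0 * math.pi)) ** (1.0 / 3.0)
    return 4.0 * math.pi * r * r


def tangent_stiffness(eed: float, cavity_volume: float, v0_pas: float,
                      v_scale: float) -> float:
    """Instantaneous passive stiffness dP/dV (mmHg/mL) at a cavity volume.

    The exponential end-diastolic pressure-volume relation has slope
    ``eed * exp((V - v0_pas)/v_scale)``: stiffness grows with preload,
    which is what raises the S3 frequency in volume-loaded conditions.
    """
    return eed * math.exp((cavity_volume - v0_pas) / v_scale)


def estimate_spring_damper(stiffness: float, cavity_volume: float,
                           calibration_scale: float,
                           total_mass: float) -> tuple[float, float]:
    """Spring factor k (N/m) and damping factor c (N*s/m) at impact.

    k scales the chamber's passive tangent stiffness (mmHg/mL,
    converted to Pa/m^3) by the squared sphere-equivalent endocardial
    area and the global calibration constant; c is ``DAMPING_RATIO``
    of critical.  Both are frozen at the impact instant.
    """
    if stiffness <= 0.0 or calibration_scale <= 0.0:
        raise ValueError("stiffness and calibration_scale must be positive")
    a_eff = effective_endocardial_area(cavity_volume)
    k = calibration_scale * stiffness * _MMHG_PER_ML_SI * a_eff * a_eff
    c = DAMPING_RATIO * 2.0 * math.sqrt(k * total_mass)
    return k, c


def vibration_params(k: float, c: float, total_mass: float) -> VibrationParams:
    return VibrationParams(k=k, c=c, mass=total_mass)


def calibrate_stiffness_scale(stiffness: float, cavity_volume: float,
                              total_mass: float,
                              f_target: float = 27.0,
                              zeta: float = DAMPING_RATIO) -> float:
    """Global stiffness scale kappa placing the damped frequency at ``f_target``.

    Solved once for the reference left ventricle (low-frequency S3
    band) and then held fixed across all conditions, so that
    condition-to-condition frequency changes are driven purely by
    stiffness, geometry and mass.  ``stiffness`` is the reference LV
    passive tangent stiffness (mmHg/mL) at the impact volume.
    """
    omega_d = 2.0 * math.pi * f_target
    omega_n = omega_d / math.sqrt(1.0 - zeta * zeta)
    k_needed = omega_n * omega_n * total_mass
    a_eff = effective_endocardial_area(cavity_volume)
    return k_needed / (stiffness * _MMHG_PER_ML_SI * a_eff * a_eff)


def s3_waveform(event: ImpactEvent, params: VibrationParams,
                duration: float | None = None, fs: float = 1000.0,
                allow_overdamped: bool = False) -> S3Waveform:
    """Sampled analytic free-vibration displacement after the impact.

    ``x(0) = 0`` and ``x'(0) = V_a``.  Default duration runs until the
    exponential envelope falls below 1% of its initial value, capped
    at 200 ms.

    Raises
    ------
    ValueError
        for an overdamped (zeta >= 1) configuration, which produces no
        sound-like oscillation — unless ``allow_overdamped`` is set, in
        which case the non-oscillatory closed form is returned.
    """
    z = params.zeta
    wn = params.omega_n
    if z >= 1.0:
        if not allow_overdamped:
            raise ValueError(
                f"zeta = {z:.3f} >= 1: non-oscillatory configuration")
        if duration is None:
            duration = _MAX_DURATION_S
        n = max(int(round(duration * fs)), 2)
        t = np.arange(n) / fs
        if z > 1.0:
            wb = wn * math.sqrt(z * z - 1.0)
            x = (event.V_a / (2.0 * wb)) * (np.exp((-z * wn + wb) * t)
                                            - np.exp((-z * wn - wb) * t))
        else:  # critically damped
            x = event.V_a * t * np.exp(-wn * t)
        return S3Waveform(side=event.side, fs=fs, samples=x,
                          t_onset=event.t_impact)
    wd = params.omega_d
    if duration is None:
        t99 = math.log(1.0 / _ENVELOPE_FLOOR) / (z * wn) if z > 0 else _MAX_DURATION_S
        duration = min(t99, _MAX_DURATION_S)
    n = max(int(round(duration * fs)), 2)
    t = np.arange(n) / fs
    x = (event.V_a / wd) * np.exp(-z * wn * t) * np.sin(wd * t)
    return S3Waveform(side=event.side, fs=fs, samples=x, t_onset=event.t_impact)


def combine_sides(s3_lv: S3Waveform, s3_rv: S3Waveform,
                  cycle_ms: float) -> S3Waveform:
    """Sum the two single-ventricle waveforms on the common cycle axis.

    Each waveform is placed at its own onset; no rescaling is applied.
    """
    if s3_lv.fs != s3_rv.fs:
        raise ValueError("sample rates differ: resample before combining")
    fs = s3_lv.fs
    n = int(round(cycle_ms / 1000.0 * fs)) + 1
    out = np.zeros(n)
    for w in (s3_lv, s3_rv):
        i0 = int(round(w.t_onset / 1000.0 * fs))
        seg = w.samples[: max(n - i0, 0)]
        out[i0: i0 + len(seg)] += seg
    return S3Waveform(side="combined", fs=fs, samples=out, t_onset=0.0)
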