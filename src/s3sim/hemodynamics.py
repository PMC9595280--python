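"""Closed-loop lumped-parameter (0D) circulation.

A desk-scale surrogate of a full cardiovascular mechanics model: four
time-varying-elastance chambers (LA, LV, RA, RV), quasi-steady orifice
valves, systemic and pulmonary vascular beds (arterial compliance,
peripheral resistance, venous compliance, venous return resistance),
and an optional atrial or ventricular septal shunt orifice.  The model
produces the per-millisecond pressures, volumes, valve flows and valve
areas that the S3 vibration generator consumes.

Chamber model
-------------
Pressure is the sum of a passive exponential end-diastolic
pressure-volume relation (with its own zero-pressure volume
``v0_pas``, restoring early-diastolic recoil) and an active elastance
scaled by a normalised activation waveform ``a(t)``::

    p(V, t) = eed * vs * (exp((V - v0_pas)/vs) - 1)
              + a(t) * (emax - eed) * min(V - v0, act_sat)

``a(t)`` rises as a raised cosine over ``t_rise`` and relaxes
exponentially with time constant ``tau`` (the isovolumic relaxation
knob).  ``act_sat`` is a force-length plateau: an over-distended wall
generates no additional active pressure (used for the atria).  With
``emax == eed`` the pressure is time-independent and the circulation
produces no net flow — the no-contraction degenerate case.

Valve model
-----------
Aortic/pulmonary valves and septal shunts use quasi-steady Bernoulli
orifice flow, regularised near zero gradient::

    Q = 50.393 * A * dp / sqrt(|dp| + 0.05)     [mL/s; A cm^2; dp mmHg]

The effective area switches between the forward opening area
(``area_open * (1 - stenosis_fraction)``) and the systolic leak area
(``area_open * leak_fraction``) with the sign of the gradient.

The atrioventricular (mitral, tricuspid) valves additionally carry the
inertance of the inflowing blood column, ``L = rho * l_eff / A`` with
an effective length of 2 cm: forward flow is a state accelerated by
the transvalvular gradient and braked by the Bernoulli pressure drop,

    L * dQ/dt = dp - (Q / (50.393 * A))^2 * sign(Q),

so early-diastolic inflow overshoots and peaks where the gradient
crosses zero — the E-wave morphology (and the free-vibration trigger)
seen in transmitral Doppler.  When forward flow decelerates to zero
the valve closes (flow clamped at 0); a regurgitant leak conducts
quasi-steady backflow through the leak area.

Units: mmHg, mL, cm^2, seconds internally; the public time axis is
milliseconds (1 ms sample step).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "ChamberParams",
    "ValveSpec",
    "ShuntSpec",
    "WindkesselBed",
    "CirculationParams",
    "HemoTimeSeries",
    "ConvergenceError",
    "RegulationError",
    "valve_flow",
    "reference_parameters",
    "simulate_beat",
    "homeostatic_adapt",
]

# Orifice coefficient: Q[mL/s] = C * A[cm^2] * sqrt(dp[mmHg]),
# C = sqrt(2 * 133.322 Pa/mmHg / 1050 kg/m^3) * 1e2
ORIFICE_COEF = 50.3932
# Regularisation pressure (mmHg) keeping dQ/dp finite at dp = 0.
_P_EPS = 0.05
# AV-valve blood-column effective length (m) for the inflow inertance
_L_EFF = 0.02
# inertance prefactor: L[mmHg*s^2/mL] = rho * l_eff / (A[cm^2]*1e-4) / (133.322/1e-6)
_L_COEF = 1050.0 * _L_EFF / 1e-4 / (133.322 / 1e-6)


class ConvergenceError(RuntimeError):
    """Beat-to-beat iteration failed to reach a periodic steady state."""


class RegulationError(RuntimeError):
    """Homeostatic pressure-flow controller failed to reach its setpoints."""

    def __init__(self, msg: str, last_params=None, last_state=None):
        super().__init__(msg)
        self.last_params = last_params
        self.last_state = last_state


@dataclass
class ChamberParams:
    """Time-varying elastance chamber.

    wall_volume : myocardial wall volume (mL), carries the wall mass.
    emax        : end-systolic elastance (mmHg/mL).
    eed         : end-diastolic (passive) elastance near v0 (mmHg/mL).
    tau         : isovolumic relaxation time constant (ms).
    activation_onset : activation onset within the cycle (ms).
    v0          : unstressed volume (mL).
    t_rise      : raised-cosine activation rise time (ms).
    v_scale     : volume scale of the exponential passive EDPVR (mL).
    """

    wall_volume: float
    emax: float
    eed: float
    tau: float
    activation_onset: float
    v0: float
    t_rise: float
    v_scale: float
    v0_pas: float = None  # passive EDPVR zero-pressure volume; defaults to v0
    act_sat: float = None  # active force-length plateau span (mL); None = linear

    def __post_init__(self) -> None:
        if not (self.emax > self.eed > 0.0):
            raise ValueError("require emax > eed > 0")
        if self.tau <= 0.0 or self.wall_volume <= 0.0:
            raise ValueError("tau and wall_volume must be positive")
        if self.v0_pas is None:
            self.v0_pas = self.v0


@dataclass
class ValveSpec:
    """Orifice valve: opening area with optional leak and stenosis."""

    area_open: float  # cm^2
    leak_fraction: float = 0.0
    stenosis_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.area_open <= 0.0:
            raise ValueError("area_open must be positive")
        if not (0.0 <= self.leak_fraction < 1.0):
            raise ValueError("leak_fraction must be in [0, 1)")
        if not (0.0 <= self.stenosis_fraction < 1.0):
            raise ValueError("stenosis_fraction must be in [0, 1)")

    @property
    def area_forward(self) -> float:
        return self.area_open * (1.0 - self.stenosis_fraction)

    @property
    def area_backward(self) -> float:
        return self.area_open * self.leak_fraction


@dataclass
class ShuntSpec:
    """Septal defect orifice: 'atrial' (LA-RA), 'ventricular' (LV-RV) or 'none'."""

    location: str = "none"
    diameter: float = 0.0  # mm

    def __post_init__(self) -> None:
        if self.location not in ("none", "atrial", "ventricular"):
            raise ValueError(f"unknown shunt location {self.location!r}")
        if self.diameter < 0.0:
            raise ValueError("diameter must be >= 0")
        if self.location != "none" and self.diameter <= 0.0:
            raise ValueError("shunt requires a positive diameter")

    @property
    def area(self) -> float:
        """Orifice area in cm^2 from the diameter in mm."""
        r_cm = self.diameter / 20.0
        return math.pi * r_cm * r_cm


@dataclass
class WindkesselBed:
    """Arterial compliance + peripheral resistance + venous pool."""

    c_art: float   # arterial compliance (mL/mmHg)
    v0_art: float  # arterial unstressed volume (mL)
    r_per: float   # peripheral resistance (mmHg*s/mL)
    c_ven: float   # venous compliance (mL/mmHg)
    v0_ven: float  # venous unstressed volume (mL)
    r_ven: float   # venous return resistance (mmHg*s/mL)


@dataclass
class CirculationParams:
    """Full parameter set of the closed loop."""

    la: ChamberParams
    lv: ChamberParams
    ra: ChamberParams
    rv: ChamberParams
    mv: ValveSpec
    tv: ValveSpec
    av: ValveSpec
    pv: ValveSpec
    systemic: WindkesselBed
    pulmonary: WindkesselBed
    shunt: ShuntSpec = field(default_factory=ShuntSpec)
    total_volume: float = 5000.0  # mL


#: column order of the per-millisecond export
_COLUMNS = [
    "t_ms", "p_la", "p_lv", "p_ra", "p_rv", "p_ao", "p_pu",
    "v_la", "v_lv", "v_ra", "v_rv",
    "q_mv", "q_tv", "q_av", "q_pv", "q_shunt",
    "a_mv", "a_tv", "a_av", "a_pv",
]


@dataclass
class HemoTimeSeries:
    """One steady-state beat sampled at 1 ms.

    Arrays share a common length (cycle length in ms + 1, both cycle
    endpoints included).  Pressures in mmHg, volumes in mL, flows in
    mL/s, areas in cm^2.  ``meta`` carries the heart rate and the
    atrial/ventricular activation onsets the S3 trigger needs.
    """

    t_ms: np.ndarray
    p_la: np.ndarray
    p_lv: np.ndarray
    p_ra: np.ndarray
    p_rv: np.ndarray
    p_ao: np.ndarray
    p_pu: np.ndarray
    v_la: np.ndarray
    v_lv: np.ndarray
    v_ra: np.ndarray
    v_rv: np.ndarray
    q_mv: np.ndarray
    q_tv: np.ndarray
    q_av: np.ndarray
    q_pv: np.ndarray
    q_shunt: np.ndarray
    a_mv: np.ndarray
    a_tv: np.ndarray
    a_av: np.ndarray
    a_pv: np.ndarray
    v_sa: np.ndarray
    v_sv: np.ndarray
    v_pa: np.ndarray
    v_pv: np.ndarray
    meta: dict = field(default_factory=dict)

    @property
    def cycle_ms(self) -> float:
        return float(self.t_ms[-1])

    def total_volume(self) -> np.ndarray:
        """Sum of all eight compartment volumes at each sample."""
        return (self.v_la + self.v_lv + self.v_ra + self.v_rv
                + self.v_sa + self.v_sv + self.v_pa + self.v_pv)

    def mean_arterial_pressure(self) -> float:
        return float(np.trapezoid(self.p_ao, self.t_ms) / (self.t_ms[-1] - self.t_ms[0]))

    def cardiac_output(self) -> float:
        """Systemic (aortic valve) output in L/min."""
        mean_q = np.trapezoid(self.q_av, self.t_ms) / (self.t_ms[-1] - self.t_ms[0])
        return float(mean_q * 60.0 / 1000.0)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({c: getattr(self, c) for c in _COLUMNS})

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def valve_flow(p_upstream: float, p_downstream: float, effective_area: float) -> float:
    """Quasi-steady orifice flow (mL/s) through ``effective_area`` cm^2.

    Sign follows the pressure gradient; zero area gives zero flow.  The
    square-root law is regularised near zero gradient so the
    conductance stays finite (flow is linear in dp for |dp| << 0.05
    mmHg and Bernoulli-like above).
    """
    if effective_area < 0.0:
        raise ValueError("effective_area must be >= 0")
    dp = p_upstream - p_downstream
    return ORIFICE_COEF * effective_area * dp / math.sqrt(abs(dp) + _P_EPS)


def reference_parameters(hr: float = 70.0) -> CirculationParams:
    """Baseline healthy-adult parameter set (rest, CO ~5 L/min).

    Chamber elastances, unstressed volumes and vascular-bed constants
    are generic textbook 0D values; the homeostatic controller trims
    systemic resistance and circulating volume to the exact setpoints,
    so only the orders of magnitude matter here.
    """
    t_cycle = 60000.0 / hr  # ms
    # atria fire ~16.5% of the cycle before the ventricles
    on_a = t_cycle * 0.835
    # atria: thin-walled reservoirs with near-constant passive compliance
    # (v_scale >> operating volume makes the EDPVR effectively linear)
    la = ChamberParams(wall_volume=25.0, emax=0.18, eed=0.12, tau=35.0,
                       activation_onset=on_a, v0=10.0, t_rise=0.10 * t_cycle,
                       v_scale=1e5, act_sat=70.0)
    ra = ChamberParams(wall_volume=20.0, emax=0.13, eed=0.08, tau=35.0,
                       activation_onset=on_a, v0=10.0, t_rise=0.10 * t_cycle,
                       v_scale=1e5, act_sat=70.0)
    lv = ChamberParams(wall_volume=145.0, emax=2.6, eed=0.06, tau=42.0,
                       activation_onset=0.0, v0=10.0, t_rise=0.27 * t_cycle,
                       v_scale=100.0, v0_pas=40.0)
    rv = ChamberParams(wall_volume=48.0, emax=0.62, eed=0.035, tau=42.0,
                       activation_onset=0.0, v0=10.0, t_rise=0.27 * t_cycle,
                       v_scale=120.0, v0_pas=40.0)
    return CirculationParams(
        la=la, lv=lv, ra=ra, rv=rv,
        mv=ValveSpec(5.0), tv=ValveSpec(6.0), av=ValveSpec(4.0), pv=ValveSpec(4.5),
        systemic=WindkesselBed(c_art=1.3, v0_art=430.0, r_per=1.03,
                               c_ven=65.0, v0_ven=2800.0, r_ven=0.030),
        pulmonary=WindkesselBed(c_art=4.5, v0_art=120.0, r_per=0.065,
                                c_ven=11.0, v0_ven=450.0, r_ven=0.018),
        shunt=ShuntSpec(),
        total_volume=5000.0,
    )


def rescale_timing(params: CirculationParams, hr: float) -> CirculationParams:
    """Return ``params`` with activation onsets/rise times scaled to ``hr``.

    Onsets and rise times are stored in ms and must track the cycle
    length when the heart rate changes (exercise); relaxation time
    constants stay in absolute ms.
    """
    t_cycle = 60000.0 / hr
    out = replace(params)
    out.la = replace(params.la, activation_onset=0.835 * t_cycle, t_rise=0.10 * t_cycle)
    out.ra = replace(params.ra, activation_onset=0.835 * t_cycle, t_rise=0.10 * t_cycle)
    out.lv = replace(params.lv, t_rise=0.27 * t_cycle)
    out.rv = replace(params.rv, t_rise=0.27 * t_cycle)
    return out


# ---------------------------------------------------------------------------
# integrator internals: parameters flattened to a tuple of floats for speed

def _flatten(p: CirculationParams, hr: float) -> tuple:
    T = 60.0 / hr  # s
    ch = []
    for c in (p.la, p.lv, p.ra, p.rv):
        ch.extend([c.v0, c.v_scale, c.eed, c.emax - c.eed,
                   c.t_rise * 1e-3, c.tau * 1e-3, c.activation_onset * 1e-3,
                   c.v0_pas, c.act_sat if c.act_sat is not None else 1e30])
    sh_loc = {"none": 0, "atrial": 1, "ventricular": 2}[p.shunt.location]
    return (
        T, *ch,
        p.mv.area_forward, p.mv.area_backward,
        p.tv.area_forward, p.tv.area_backward,
        p.av.area_forward, p.av.area_backward,
        p.pv.area_forward, p.pv.area_backward,
        p.systemic.c_art, p.systemic.v0_art, p.systemic.r_per,
        p.systemic.c_ven, p.systemic.v0_ven, p.systemic.r_ven,
        p.pulmonary.c_art, p.pulmonary.v0_art, p.pulmonary.r_per,
        p.pulmonary.c_ven, p.pulmonary.v0_ven, p.pulmonary.r_ven,
        sh_loc, p.shunt.area,
    )


def _initial_state(p: CirculationParams) -> list:
    """Plausible volume split of total_volume over the 8 compartments."""
    frac = np.array([0.016, 0.025, 0.016, 0.025, 0.11, 0.64, 0.035, 0.133])
    v = frac / frac.sum() * p.total_volume
    return list(v) + [0.0, 0.0]  # AV-valve flow states start closed


def _act(x: float, tr: float, tau: float) -> float:
    if x < tr:
        return 0.5 - 0.5 * math.cos(math.pi * x / tr)
    return math.exp(-(x - tr) / tau)


def _pressures(t: float, y, P):
    """Chamber and vascular pressures at time t (s within cycle)."""
    T = P[0]
    p_ch = []
    for i in range(4):
        v0, vs, eed, dE, tr, tau, on, v0p, sat = P[1 + 9 * i: 10 + 9 * i]
        v = y[i]
        x = (t - on) % T
        a = _act(x, tr, tau)
        stretch = v - v0
        if stretch > sat:  # force-length plateau (overstretched wall)
            stretch = sat
        p_ch.append(eed * vs * math.expm1((v - v0p) / vs) + a * dE * stretch)
    p_sa = (y[4] - P[46]) / P[45]
    p_sv = (y[5] - P[49]) / P[48]
    p_pa = (y[6] - P[52]) / P[51]
    p_pv = (y[7] - P[55]) / P[54]
    return p_ch[0], p_ch[1], p_ch[2], p_ch[3], p_sa, p_sv, p_pa, p_pv


def _av_valve(q_state: float, dp: float, a_fwd: float, a_back: float):
    """Inertial AV valve: flow, recorded area, and dq/dt of the state."""
    if q_state > 0.0:
        q, a = q_state, a_fwd
    elif dp < 0.0:
        if a_back > 0.0:
            q = ORIFICE_COEF * a_back * dp / math.sqrt(-dp + _P_EPS)
            a = a_back
        else:
            q, a = 0.0, 0.0
    else:
        q, a = 0.0, a_fwd
    u = q_state / (ORIFICE_COEF * a_fwd)
    dq = (dp - u * abs(u)) / (_L_COEF / a_fwd)
    return q, a, dq


def _flows(t: float, y, P):
    p_la, p_lv, p_ra, p_rv, p_sa, p_sv, p_pa, p_pv = _pressures(t, y, P)

    def q(dp, af, ab):
        a = af if dp >= 0.0 else ab
        return ORIFICE_COEF * a * dp / math.sqrt(abs(dp) + _P_EPS), a

    q_mv, a_mv, dq_mv = _av_valve(y[8], p_la - p_lv, P[37], P[38])
    q_tv, a_tv, dq_tv = _av_valve(y[9], p_ra - p_rv, P[39], P[40])
    q_av, a_av = q(p_lv - p_sa, P[41], P[42])
    q_pv, a_pv = q(p_rv - p_pa, P[43], P[44])
    q_sys = (p_sa - p_sv) / P[47]
    q_svr = (p_sv - p_ra) / P[50]
    q_pul = (p_pa - p_pv) / P[53]
    q_pvl = (p_pv - p_la) / P[56]
    loc = P[57]
    if loc == 1:
        dp = p_la - p_ra
        q_sh = ORIFICE_COEF * P[58] * dp / math.sqrt(abs(dp) + _P_EPS)
    elif loc == 2:
        dp = p_lv - p_rv
        q_sh = ORIFICE_COEF * P[58] * dp / math.sqrt(abs(dp) + _P_EPS)
    else:
        q_sh = 0.0
    return ((p_la, p_lv, p_ra, p_rv, p_sa, p_sv, p_pa, p_pv),
            (q_mv, q_tv, q_av, q_pv, q_sys, q_svr, q_pul, q_pvl, q_sh),
            (a_mv, a_tv, a_av, a_pv),
            (dq_mv, dq_tv))


def _dy(t: float, y, P):
    _, f, _, dq = _flows(t, y, P)
    q_mv, q_tv, q_av, q_pv, q_sys, q_svr, q_pul, q_pvl, q_sh = f
    loc = P[57]
    sh_a = q_sh if loc == 1 else 0.0
    sh_v = q_sh if loc == 2 else 0.0
    # flows in mL/s; volumes in mL; t in s
    return (
        q_pvl - q_mv - sh_a,        # V_la
        q_mv - q_av - sh_v,         # V_lv
        q_svr - q_tv + sh_a,        # V_ra
        q_tv - q_pv + sh_v,         # V_rv
        q_av - q_sys,               # V_sa
        q_sys - q_svr,              # V_sv
        q_pv - q_pul,               # V_pa
        q_pul - q_pvl,              # V_pv
        dq[0],                      # Q_mv (inertial state)
        dq[1],                      # Q_tv (inertial state)
    )


def _run_beat(y, P, record: bool, n_sub: int = 4):
    """Advance one cardiac cycle with fixed-step RK4 (1 ms output grid).

    Returns (y_end, map_mmHg, co_lpm, HemoTimeSeries-or-None).
    Raises ConvergenceError on a negative compartment volume.
    """
    T = P[0]
    n_ms = int(round(T * 1000.0))
    h = (T / n_ms) / n_sub
    if record:
        rec = np.empty((n_ms + 1, 20))
        vrec = np.empty((n_ms + 1, 4))
    sum_psa = 0.0
    sum_qav = 0.0
    t = 0.0
    n_state = 10
    rng = range(n_state)
    for i in range(n_ms + 1):
        pr, fl, ar, _ = _flows(t, y, P)
        sum_psa += pr[4]
        sum_qav += fl[2]
        if record:
            rec[i] = (t * 1000.0, pr[0], pr[1], pr[2], pr[3], pr[4], pr[6],
                      y[0], y[1], y[2], y[3],
                      fl[0], fl[1], fl[2], fl[3], fl[8],
                      ar[0], ar[1], ar[2], ar[3])
            vrec[i] = (y[4], y[5], y[6], y[7])
        if i == n_ms:
            break
        for _ in range(n_sub):
            k1 = _dy(t, y, P)
            y2 = [y[j] + 0.5 * h * k1[j] for j in rng]
            k2 = _dy(t + 0.5 * h, y2, P)
            y3 = [y[j] + 0.5 * h * k2[j] for j in rng]
            k3 = _dy(t + 0.5 * h, y3, P)
            y4 = [y[j] + h * k3[j] for j in rng]
            k4 = _dy(t + h, y4, P)
            y = [y[j] + (h / 6.0) * (k1[j] + 2.0 * k2[j] + 2.0 * k3[j] + k4[j])
                 for j in rng]
            # AV forward-flow states never go negative (valve closure)
            if y[8] < 0.0:
                y[8] = 0.0
            if y[9] < 0.0:
                y[9] = 0.0
            t += h
        if y[0] <= 0.0 or y[1] <= 0.0 or y[2] <= 0.0 or y[3] <= 0.0:
            raise ConvergenceError("negative chamber volume: integration failure")
    map_mmhg = sum_psa / (n_ms + 1)
    co_lpm = sum_qav / (n_ms + 1) * 0.06
    series = None
    if record:
        series = HemoTimeSeries(
            t_ms=rec[:, 0], p_la=rec[:, 1], p_lv=rec[:, 2], p_ra=rec[:, 3],
            p_rv=rec[:, 4], p_ao=rec[:, 5], p_pu=rec[:, 6],
            v_la=rec[:, 7], v_lv=rec[:, 8], v_ra=rec[:, 9], v_rv=rec[:, 10],
            q_mv=rec[:, 11], q_tv=rec[:, 12], q_av=rec[:, 13], q_pv=rec[:, 14],
            q_shunt=rec[:, 15],
            a_mv=rec[:, 16], a_tv=rec[:, 17], a_av=rec[:, 18], a_pv=rec[:, 19],
            v_sa=vrec[:, 0], v_sv=vrec[:, 1], v_pa=vrec[:, 2], v_pv=vrec[:, 3],
        )
    return y, map_mmhg, co_lpm, series


def _rel_change(y_new, y_old) -> float:
    return max(abs(a - b) / (abs(b) + 1.0) for a, b in zip(y_new, y_old))


def simulate_beat(params: CirculationParams, hr: float,
                  y0: Optional[list] = None,
                  tol: float = 1e-4, max_beats: int = 200) -> tuple:
    """Run the loop to a periodic steady state; return one recorded beat.

    Steady state: relative beat-to-beat change of every compartment
    volume below ``tol``.  Returns ``(HemoTimeSeries, y_end)`` where
    ``y_end`` is the state at the cycle start (for warm restarts).

    Raises
    ------
    ConvergenceError
        if no periodic solution is found within ``max_beats`` or a
        compartment volume goes negative.
    """
    P = _flatten(params, hr)
    y = list(y0) if y0 is not None else _initial_state(params)
    for _ in range(max_beats):
        y_new, _, _, _ = _run_beat(y, P, record=False)
        if _rel_change(y_new, y) < tol:
            y = y_new
            break
        y = y_new
    else:
        raise ConvergenceError(f"no steady state within {max_beats} beats")
    y_end, _, _, series = _run_beat(y, P, record=True)
    series.meta.update(
        hr=hr,
        atrial_onset_ms=params.la.activation_onset,
        ventricular_onset_ms=params.lv.activation_onset,
        lv_wall_volume=params.lv.wall_volume,
        rv_wall_volume=params.rv.wall_volume,
        lv_eed=params.lv.eed,
        rv_eed=params.rv.eed,
        lv_v0_pas=params.lv.v0_pas,
        rv_v0_pas=params.rv.v0_pas,
        lv_v_scale=params.lv.v_scale,
        rv_v_scale=params.rv.v_scale,
    )
    return series, y_end


def homeostatic_adapt(params: CirculationParams, hr: float,
                      co_target: float, map_target: float = 91.0,
                      y0: Optional[list] = None,
                      max_beats: int = 400) -> tuple:
    """Trim systemic resistance and circulating volume to the setpoints.

    Proportional multiplicative updates per beat: systemic peripheral
    resistance targets mean arterial pressure, total circulating
    volume (added/removed from the systemic venous pool) targets
    cardiac output.  Only those two quantities are modified.

    Returns ``(adapted_params, y_end, n_beats)``; the adapted
    parameters reproduce MAP within +-0.5 mmHg and CO within 1%
    when re-simulated to steady state.

    Raises
    ------
    RegulationError
        if the controller does not settle within ``max_beats``.
    """
    p = replace(params)
    y = list(y0) if y0 is not None else _initial_state(p)
    r_per = p.systemic.r_per
    quiet = 0
    for beat in range(max_beats):
        P = _flatten(p, hr)
        try:
            y_new, map_m, co_m, _ = _run_beat(y, P, record=False)
        except ConvergenceError as exc:
            raise RegulationError(f"integration failed during adaptation: {exc}",
                                  last_params=p, last_state=y) from exc
        err_map = map_m - map_target
        err_co = co_m - co_target
        settled = (abs(err_map) < 0.3 and abs(err_co) < 0.006 * co_target
                   and _rel_change(y_new, y) < 1e-4)
        y = y_new
        if settled:
            quiet += 1
            if quiet >= 2:
                p.systemic = replace(p.systemic, r_per=r_per)
                p.total_volume = float(sum(y[:8]))
                return p, y, beat + 1
            continue
        quiet = 0
        # correct every third beat so the loop's own transient (which
        # lags a parameter change by a couple of beats) does not alias
        # into the controller and cause oscillation
        if beat % 3 == 2 and co_m > 0.1:
            r_per *= (map_target / map_m) ** 0.5
            r_per = min(max(r_per, 0.05), 20.0)
            p.systemic = replace(p.systemic, r_per=r_per)
            dv = 50.0 * (co_target - co_m)
            dv = min(max(dv, -250.0), 250.0)
            y[5] = max(y[5] + dv, 50.0)
    raise RegulationError(f"controller did not settle within {max_beats} beats",
                          last_params=p, last_state=y)
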