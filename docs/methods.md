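# Methods

## Overview

`s3sim` simulates the third heart sound (S3) from first principles in three
stages:

1. a closed-loop zero-dimensional (0D) circulation produces one steady-state
   beat of pressures, volumes, valve flows and valve areas at 1 ms resolution;
2. a one-degree-of-freedom cardiohemic vibration model is struck by the
   early-diastolic inflow at the E-wave peak and rings down as an underdamped
   free vibration — one oscillator per ventricle, summed into the final S3;
3. an acoustics layer turns displacement waveforms into band-energy spectra,
   dominant frequencies and EBU R 128 integrated loudness, and provides the
   standard phonocardiogram preprocessing recipe for external recordings.

A protocol layer sweeps cardiac conditions (exercise, aging, valve
regurgitation and stenosis, septal shunts, HFpEF grades) and exercise levels,
with homeostatic pressure–flow regulation holding mean arterial pressure
(MAP) at 91 mmHg and cardiac output (CO) at the prescribed level in every
simulation.

## Circulation surrogate

The circulation is a four-chamber time-varying-elastance loop (LA, LV, RA,
RV) with systemic and pulmonary beds (arterial compliance, peripheral
resistance, venous compliance, venous-return resistance) and an optional
septal orifice. It is a desk-scale surrogate for a full cardiovascular
mechanics model: it reproduces the hemodynamic *variables* the vibration
model consumes, not myofiber mechanics.

Chamber pressure is passive plus active:

    p(V,t) = eed·vs·(exp((V − v0_pas)/vs) − 1) + a(t)·(emax − eed)·min(V − v0, sat)

- The passive exponential EDPVR has its own zero-pressure volume `v0_pas`
  (ventricles 40 mL, near the operating end-systolic volume). Separating it
  from the active-elastance intercept `v0` (10 mL) restores early-diastolic
  recoil: the ventricle relaxes onto a low pressure floor and can even suck
  below `v0_pas`. With a shared intercept the early-diastolic pressure floor
  tracks atrial pressure and the tall restrictive E wave cannot form.
- `a(t)` rises as a raised cosine over `t_rise = 0.27·T` and decays
  exponentially with the isovolumic relaxation constant `tau` (ventricles
  42 ms at reference). `tau` and `eed` are the knobs the aging and HFpEF
  protocols scale.
- Atria are thin-walled reservoirs: near-linear passive compliance
  (`vs = 1e5` mL makes the exponential effectively linear at slope `eed`)
  and an active force–length plateau (`sat` = 70 mL) so an over-distended
  atrium does not generate unbounded booster pressure.
- With `emax = eed` the pressure is time-independent and the loop decays to
  a no-flow equilibrium — the degenerate no-contraction case used in tests.

Aortic and pulmonary valves and septal shunts follow a quasi-steady
Bernoulli orifice law, regularised near zero gradient so the conductance
stays finite (`Q = 50.393·A·Δp/√(|Δp| + 0.05)` in mL/s, cm², mmHg). The
mitral and tricuspid valves additionally carry the inertance of the
inflowing blood column, `L = ρ·l_eff/A` with `l_eff = 2 cm`: forward flow is
a state accelerated by the transvalvular gradient and braked by the
Bernoulli drop, so early-diastolic inflow overshoots and peaks where the net
gradient vanishes. This yields the E/A transmitral morphology of Doppler
echocardiography and makes the free-vibration trigger condition (no net
driving force at the inflow peak) hold by construction. When forward flow
decelerates to zero the valve closes; a regurgitant leak conducts
quasi-steady backflow through `leak_fraction · area_open`.

Integration is fixed-step classical RK4 on the 10-dimensional state (8
compartment volumes + 2 AV flow states) with 4 substeps per 1 ms output
sample. Total blood volume is conserved to machine precision because every
flow enters one compartment's derivative positively and another's
negatively. A beat is steady when the relative beat-to-beat change of every
state is below 1e-4 (capped at 200 beats).

### Homeostatic regulation

Only two quantities are adapted, mirroring physiological pressure–flow
regulation: systemic peripheral resistance (targets MAP = 91 mmHg) and total
circulating volume (targets CO). Both are updated by damped multiplicative/
proportional corrections every third beat — the loop's own transient lags a
parameter change by a couple of beats, and correcting every beat aliases
that lag into controller oscillation. Convergence requires |MAP − 91| <
0.3 mmHg, |CO − target| < 0.6% and a periodic state, comfortably inside the
contract (±0.5 mmHg, ±1%).

### Reference parameterisation

Baseline values are generic textbook 0D numbers for a healthy adult at rest
(HR 70, CO 5 L/min): LV `emax` 2.6, `eed` 0.06 mmHg/mL, wall 145 mL; RV
0.62/0.035, wall 48 mL; valve areas 5/6/4/4.5 cm² (MV/TV/AV/PV); systemic
arterial compliance 1.3 mL/mmHg. The controller trims resistance and volume
to the exact setpoints, so only orders of magnitude matter. The resulting
beat shows aortic pressure ≈ 113/69 mmHg, LV EDV/ESV ≈ 126/54 mL, distinct
E (≈ 415 mL/s) and A waves with E/A ≈ 2 (young-adult pattern), and an
atrial filling fraction of ≈ 20%.

## S3 generation

At the E-wave flow maximum (located between end systole and atrial
activation onset, which excludes the A wave) the inflow parcel of one 1 ms
snapshot, `m = Q·Δt·ρ_blood`, moving at `v = Q/A_valve`, merges inelastically
with the cardiohemic mass `M_ch = ρ_myo·V_wall + ρ_blood·V_cavity`
(densities 1055 and 1050 kg/m³; cavity volume at the impact instant).
Momentum conservation with the cardiohemic system initially at rest gives
the post-impact velocity `V_a = m·v/(M_ch + m)` — exact by construction, and
asserted to machine precision in the tests.

The subsequent displacement is the underdamped free vibration

    x(t) = V_a/ω_d · exp(−ζ·ω_n·t) · sin(ω_d·t),      x(0) = 0, x'(0) = V_a

with `ω_n = √(k/(M_ch+m))`, `ζ = c/(2√(k(M_ch+m)))`, `ω_d = ω_n√(1−ζ²)`.
Coefficients are frozen at the impact instant; the analytic form is verified
against an independent RK4 integration of the second-order ODE to 1e-9
relative accuracy over a grid of 100 parameter combinations.

### Spring and damper

- `k = κ · (dP/dV at EDV) · A_eff²`, where the tangent stiffness of the
  passive EDPVR is taken at the end-diastolic volume (the clinical meaning
  of end-diastolic elastance; evaluating at the impact-instant volume would
  hide chronic dilation, because the impact happens early in filling) and
  `A_eff` is the sphere-equivalent endocardial area at the impact-instant
  cavity volume. The single global scale κ is calibrated once so the
  *reference* LV damped frequency is 27 Hz (the centre of the low-frequency
  S3 band) and then frozen; every condition-to-condition frequency change is
  therefore driven by stiffness, geometry and mass, never recalibrated.
- `c` is 10% of critical damping, `c = 0.1·2√(k(M_ch+m))`, i.e. ζ = 0.1.
  Reading the calibration rule "damping = 10% of the spring factor"
  literally is dimensionally inconsistent (N·s/m vs N/m) and would give an
  overdamped, non-oscillatory S3; 10% of critical is the interpretation that
  keeps the oscillator underdamped as observed.

The waveform is sampled at 1 kHz until its envelope falls below 1% of peak
or 200 ms, whichever is first. The right ventricle uses identical formulas
with RV wall mass, volumes, tricuspid flow and area. The final S3 is the
sample-wise sum of the two single-ventricle waveforms, each placed at its
own impact time on the common cycle axis, with equal weighting.

## Acoustics

- **Band-energy spectrum.** The signal is low-pass filtered at 300 Hz
  (zero-phase Butterworth), Hann-windowed, zero-padded to ≤ 0.5 Hz FFT
  spacing; each 15 Hz band's energy index is the trapezoidal area under the
  *magnitude* spectrum, normalised by the total over 0–300 Hz. The area
  under the magnitude spectrum (not the power spectrum) is what reproduces
  the reported spectral balance: for a ζ ≈ 0.1 line at 27 Hz the magnitude
  Lorentzian's slowly decaying tails put roughly a quarter of the area above
  60 Hz, whereas power-spectral area would put ≈ 99% below 60 Hz. The
  dominant frequency is the argmax of the magnitude spectrum on the fine
  FFT grid within 0–300 Hz.
- **Integrated loudness** follows ITU-R BS.1770/EBU R 128: K-weighting with
  the standardised 48 kHz biquads (signals at other rates are resampled
  internally), mean square over 400 ms blocks with 75% overlap, −0.691 dB
  offset, −70 LUFS absolute gate, then a relative gate 10 LU below the
  intermediate loudness. Silence returns −∞. The implementation is written
  in-package and anchored by the standard's compliance case (full-scale
  1 kHz sine → −3.01 LUFS ± 0.1).
- **Loudness of simulated S3.** LUFS is gain-dependent, so displacement
  waveforms are scaled by one fixed physical-to-digital gain (1e4 digital
  units per metre) applied identically across conditions, and the
  steady-state beat is tiled into a 4 s track before metering — integrated
  loudness is a programme measure, and a repeated-beat track both removes
  block-gating artefacts of sub-second snippets and correctly credits the
  higher beat rate of exercise with more S3 events per second.
- **Phonocardiogram preprocessing** for external recordings: resample to
  1 kHz, zero-phase 4th-order Butterworth band-pass 25–400 Hz, then despike
  by clamping residuals against a 20 ms moving median at 5 robust standard
  deviations (MAD-based).

## Protocol

Condition sweeps (severity steps in parentheses): exercise CO 5→14 L/min in
3 L/min steps with HR interpolated linearly 70→130 bpm; aging scales
ventricular `eed` and `tau` by 2–12% (steps of 2%); MR/TR leave 8/10/12/14%
of the valve area open in systole; MS/TS narrow the valve by 50–80% (steps
of 10%); ASD/VSD open a 6–12 mm septal orifice (steps of 2 mm); HFpEF
grades I/II/III scale LV `tau` by +80% and LV `eed` by +0/75/130%. MAP is
regulated to 91 mmHg everywhere; CO and HR stay at 5 L/min and 70 bpm
except during exercise.

`run_grid` crosses all conditions with CO levels {5, 8, 11, 14} L/min
(136 cells) and warm-starts each exercise level from the previous one,
which only shortens the adaptation transient — the converged steady state,
and hence every reported feature, is independent of the path. The full grid
completes in roughly a quarter hour on one CPU; single conditions take
seconds.

## Numerical choices

- RK4 substep 0.25 ms: the stiffest time constant (open valve against
  arterial compliance) is ≈ 0.35 ms, leaving a ≥ 4× stability margin.
- Orifice regularisation 0.05 mmHg: keeps dQ/dΔp finite at valve opening;
  the error vs the pure square-root law is < 1% above 2.5 mmHg.
- AV-valve flow states are clamped at zero after each substep (valve
  closure); the clamp error is bounded by one substep of backflow through
  an already-adverse gradient.
- Steady-state tolerance 1e-4 relative (≈ 0.01 mL on chamber volumes);
  controller tolerances 0.3 mmHg / 0.6% are set inside the contracted
  ±0.5 mmHg / ±1% so that re-simulation from the adapted state stays within
  contract.
- Impact quantities interpolate linearly on the 1 ms grid; the E-wave
  search requires ≥ 5 mL/s of inflow, below which the side reports
  "no trigger" instead of producing a spurious S3.

## What the surrogate does and does not show

The circulation is a lumped surrogate: passing the trend suite shows that
the vibration model responds correctly to hemodynamic changes *of the kind
and direction* the conditions produce (preload, inflow momentum, stiffness,
mass), not that any waveform matches a specific patient. Known limitations:

- Wall mechanics are a scalar elastance; regional function, pericardial
  constraint and ventricular interaction are absent.
- The quasi-steady/inertial valve closure approximates, but does not
  reproduce, full fluid dynamics; transvalvular gradients at high stenosis
  severity are order-of-magnitude realistic only.
- S3LV and S3RV have nearly equal damped frequencies, so their sum is
  phase-sensitive: combined-waveform loudness can wobble non-monotonically
  by ~1 LU between exercise levels when the two onsets drift through
  destructive alignment, even though each side's loudness rises
  monotonically. Real recordings, with broader-band components and thoracic
  filtering, are less phase-coherent.
- In the restrictive HFpEF grade the model reproduces the frequency, onset
  and loudness changes but under-predicts the amplitude growth: with both
  grades sharing the same prolonged relaxation constant, the achievable
  E-wave momentum gain (≈ 1.45×) stays just below the √2.3 ≈ 1.52×
  frequency gain, so simulated grade III S3LV amplitude lands ≈ 5% below
  grade I instead of above it. The missing mechanism is restrictive-stage
  atrial contractile failure (clinically often atrial fibrillation), which
  the condition protocol (LV `tau`/`eed` scaling only) does not include.
- Thoracic transmission, background noise and S1/S2 generation are out of
  scope; an S1–S2 track can be superposed but is not synthesised here.
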