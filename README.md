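# s3sim — hemodynamics-driven simulation of the third heart sound

The third heart sound (S3) is a low-frequency early-diastolic sound heard in
healthy young or exercising people and in heart failure, atrioventricular
valve regurgitation and septal shunts. `s3sim` simulates it mechanistically
for computational physiologists and cardiac-acoustics researchers: a
closed-loop lumped-parameter (0D) circulation produces per-millisecond
pressures, volumes and valve flows; the rapid early-diastolic inflow then
strikes the *cardiohemic system* — the ventricular free wall plus the blood
it contains, treated as one lumped mass M_ch on a spring k and dashpot c —
and the ring-down of that system is the S3.

At the E-wave flow peak the transvalvular driving gradient vanishes, so the
system is momentarily free. The arriving blood parcel (mass m, velocity v)
merges inelastically with M_ch; momentum conservation gives the post-impact
velocity and the displacement follows the underdamped free vibration

    V_a  = m·v / (M_ch + m)
    x(t) = (V_a/ω_d) · e^(−ζω_n t) · sin(ω_d t),   x(0) = 0, x′(0) = V_a

with ω_n = √(k/(M_ch+m)), ζ = c/(2√(k(M_ch+m))), ω_d = ω_n√(1−ζ²). Each
ventricle rings separately (its own wall mass, inflow and valve area); the
final S3 is the sum of the two. Downstream, the package computes 15 Hz
band-energy spectra (300 Hz low-pass), dominant frequencies and EBU R 128 /
ITU BS.1770 integrated loudness, and offers the standard phonocardiogram
preprocessing chain (1 kHz resample, 25–400 Hz band-pass, despiking) for
external WAV recordings. Homeostatic regulation holds mean arterial
pressure at 91 mmHg and cardiac output at the prescribed level in every
simulated condition. See `docs/methods.md` for the model details and knobs.

## Worked example

Simulate the healthy rest condition and write all artifacts:

```sh
s3sim run --condition reference --out runs/reference
```

which prints

```
reference sev 0: MAP 91.3 mmHg, CO 5.01 L/min, sides ['LV', 'RV', 'combined']
```

MAP sits on the 91 mmHg setpoint and cardiac output on 5 L/min — the
homeostatic controller has adapted systemic resistance and circulating
volume. `runs/reference/features.json` then holds the acoustic features:

```
"LV":       {"peak_amplitude_m": 7.96e-06, "dominant_frequency_hz": 26.9,
             "onset_ms": 427, "loudness_lufs": -46.0}
"RV":       {"peak_amplitude_m": 1.11e-05, "dominant_frequency_hz": 22.9,
             "onset_ms": 393, "loudness_lufs": -44.4}
"combined": {"peak_amplitude_m": 1.11e-05, "dominant_frequency_hz": 28.3,
             "onset_ms": 393, "loudness_lufs": -42.5}
```

Read this as: both ventricles generate an S3 (they always do — audibility,
not existence, is what varies); each onset coincides with its E-wave peak
(~400 ms after the QRS-equivalent cycle start, i.e. early diastole); the
left-sided component rings near 27 Hz, the right-sided one slightly lower;
and the combined sound carries about −42 LUFS at the package's fixed
displacement-to-digital gain. Disease and exercise shift exactly these
numbers — e.g. `s3sim run --condition MR --severity 2 --out runs/mr2` raises
the LV amplitude and frequency (volume overload → more inflow momentum and
a stiffer, dilated ventricle), while `--co 14` (peak exercise) raises
the S3 loudness.

Other entry points: `s3sim grid --out DIR` sweeps all conditions ×
exercise levels into one long-format CSV (~15 min); `s3sim features --wav
FILE` applies the phonocardiogram preprocessing, spectrum and loudness to an
external recording. The same pipeline is available from Python via
`s3sim.run_condition(ConditionConfig.make("MR", 2))`.

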