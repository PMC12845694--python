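# respgate

Adaptive Kalman-filter respiratory prediction and gating for image-guided
intervention, with markerless rigid registration and a quantitative
evaluation harness — all runnable on simulated respiratory motion.

## The problem

Navigation displays in respiratory-gated procedures (e.g. percutaneous lung
puncture) show the target where it *was*: the tracking and rendering chain
adds a measurement/display latency of the order of 200 ms, during which the
chest wall moves several millimetres. A clinician prompted at the detected
end-inspiration point therefore acts after the optimal window. `respgate`
addresses both problems in software:

* **state estimation and prediction** — respiratory displacement is modeled
  as a harmonic oscillator with state `x = (Xr, Vr, C)` (displacement [mm],
  velocity [mm/s], slow baseline offset [mm]), transition

  ```
  A = [[1,        dt, 0],
       [-w^2 dt,  1,  0],
       [0,        0,  1]],     w = 2*pi*f_r
  ```

  and scalar observation `z = Xr + C + v`, `v ~ N(0, R)`. The filter adapts
  on-line: the breathing frequency `f_r` from peak intervals of the filtered
  signal (20 s buffer, 0.05 Hz IIR smoothing), `R = sigma_noise^2` from
  first differences of the raw stream, and
  `Q = diag(q0, w^2, alpha * sigma_resp^2)` from the long-term respiratory
  variance. Multi-step prediction `x_{k+h|k} = A^h x_k` anticipates both the
  display latency and a configurable gating horizon.

* **anticipatory gating** — a prompt is issued when the predicted velocity
  crosses zero from + to − within the look-ahead window while the
  displacement sits near its cycle maximum; every candidate is
  double-checked against a personalized breathing template learned on-line
  (shape correlation, amplitude band, timing band), suppressing pulse
  artifacts.

* **markerless registration** — the closed-form least-squares (Umeyama/
  Kabsch) rigid transform between CT-frame and world-frame fiducials of a
  five-marker calibration plate.

* **breathing classification** — mean amplitude `Ma`, amplitude
  irregularity `Ia` (sd of extremum values) and phase irregularity `Ip`
  (sd of cycle durations), with median/quartile threshold labeling into
  regular / shallow / irregular.

* **evaluation** — target-point error `TPE(t) = ||P_true - P_displayed||`,
  gold end-inspiration annotation, prompt accuracy within a ±300 ms window,
  and signed prompt lead `dT = Tprompt - Tgold`, compared between Mode A
  (raw delayed display, instantaneous detection) and Mode B (predictive
  compensation).

A seeded synthetic-respiration module generates the study waveforms (ideal
sine, regular / shallow / irregular breathing) and the measurement-chain
corruptions (Gaussian noise, baseline drift, latency), so every result in
this repository is reproducible from a single integer seed.

## Worked example

```bash
respgate demo --seed 7 --cycles 60 --outdir demo_out
```

which prints (numbers from this exact command):

```
Mode A: TPE 1.60+-0.81 mm (RMSE 1.80), accuracy 100.0%, dT 144+-78 ms over 61 cycles
Mode B: TPE 0.14+-0.12 mm (RMSE 0.19), accuracy 100.0%, dT -112+-34 ms over 61 cycles
```

Reading: on a 10 mm / 5 s sine with 0.3 mm sensor noise and 200 ms display
latency, the uncompensated display (Mode A) is off by 1.6 mm on average and
its prompts trail the true end-inspiration by ~140 ms; predictive
compensation (Mode B) cuts the display error by ~90% and converts the
prompt delay into a ~110 ms anticipatory lead, prompting every one of the
61 cycles within the ±300 ms window. `demo_out/report.json` holds the full
report; `truth.csv` / `measured.csv` the underlying signals.

The same pipeline is scriptable: `respgate simulate | filter | gate |
classify | register | evaluate` each read and write plain CSV/JSON (see
`respgate <cmd> --help`).

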