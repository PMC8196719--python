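# radarbeat

Heartbeat extraction from continuous-wave (CW) Doppler radar baseband by
SVD-template matched filtering.

## The problem

A CW Doppler radar pointed at a person's chest reads chest-surface
displacement out of the phase of the reflected carrier, enabling
non-contact heart-rate monitoring (home care, quarantine screening,
driver monitoring). The cardiac component of that displacement is tiny
(~0.5 mm at ~1 Hz) and rides on respiration that is one to two orders of
magnitude larger (0.5–20 mm at ~0.25 Hz). Because the breathing waveform
is non-sinusoidal, its harmonics fall inside the cardiac band, so a
band-pass filter alone cannot isolate the heartbeat.

`radarbeat` implements an adaptive solution: learn a heartbeat template
from the measurement itself via singular value decomposition of its
Hankel trajectory matrix, then matched-filter the band-passed signal with
that template. The package is aimed at biomedical-signal-processing
researchers who want to study or extend the method without radar
hardware: it ships a chest-vibration and radar-baseband simulator with
exact ground-truth beat times, the full extraction pipeline, beat-interval
accuracy metrics, and a parameter-sweep harness.

## The method

Starting from the quadrature baseband pair

```
B_I(t) = A_I cos(4π(x(t)+d₀)/λ + θ + Δφ(t))
B_Q(t) = A_Q sin(4π(x(t)+d₀)/λ + θ + Δφ(t))
```

1. **Arctangent demodulation** — x(t) = (λ/4π)·unwrap(atan2(B_Q, B_I)),
   mean-removed (`ArctangentDemodulator`).
2. **Band-pass** — cardiac band 0.6–2.5 Hz, total order 20, IIR
   (Butterworth in second-order sections, causal).
3. **Template generation** — embed the raw demodulated signal as the
   Hankel trajectory matrix X (rows are length-L lagged windows,
   L = 200 samples = 2 s at 100 Hz), decompose X = Σ σᵢ uᵢ vᵢᵀ, and take
   the third right singular vector v₃ as template **h**: the two leading
   singular pairs capture the large respiratory motion, and v₃ is the
   first cardiac-dominated component.
4. **Matched filter** — x_heart[n] = x[n] ∗ h*[−n], i.e. cross-correlate
   the band-passed signal with the template (`HeartbeatEnhancer`).
5. **Beat metrics** — detect peaks (≥ 0.4 s apart), form beat-to-beat
   intervals BBIᵢ, and report HR = mean(60/BBIᵢ), SDHI = population SD of
   the BBIs, and the BBI RMSE versus a reference after both interval
   series are resampled on a shared 1 Hz grid (`BeatDetector`,
   `evaluate_beats`).

The stage classes follow scikit-learn conventions (`fit`/`transform`/
`predict`, `get_params`, fitted attributes with trailing underscores);
module-level functions (`enhance`, `detect_peaks`, …) are thin wrappers.

## Worked example

```python
import radarbeat as rb

scene = rb.simulate_scene(
    resp_p=rb.RESP_PRESETS["table1"],
    scen=rb.ScenarioParams(target_snr=-20.0, seed=7, resp_phase=0.8),
    radar=rb.RadarParams(),
)
print(f"achieved SNR: {scene.achieved_snr:.2f} dB, "
      f"respiration peak: {scene.resp.values.max()*1e3:.1f} mm")

report = rb.run_pipeline(scene)
print(f"HR {report.hr:.1f} bpm  SDHI {report.sdhi*1e3:.0f} ms  "
      f"BBI-RMSE {report.rmse*1e3:.0f} ms  beats {report.n_beats}")

baseline = rb.bpf_baseline(scene)
print(f"band-pass only: HR {baseline.hr:.1f} bpm  BBI-RMSE {baseline.rmse*1e3:.0f} ms")
```

prints

```
achieved SNR: -20.00 dB, respiration peak: 5.8 mm
HR 60.6 bpm  SDHI 75 ms  BBI-RMSE 83 ms  beats 17
band-pass only: HR 72.0 bpm  BBI-RMSE 237 ms
```

The scene buries a 0.5 mm, 60 bpm heartbeat under breathing calibrated so
the amplitude-ratio SNR is −20 dB. The SVD+MF pipeline recovers the rate
to within 0.6 bpm with an 83 ms interval RMSE against the true beat
times, while peak detection on the band-passed signal alone is pulled to
72 bpm by respiration harmonics.

The same chain is available from the shell:

```bash
radarbeat simulate --snr -20 --seed 7 --resp-preset table1 --out scene.csv
radarbeat demod    --in scene.csv --wavelength 0.0125 --out disp.csv
radarbeat enhance  --in disp.csv --lag 200 --sv-index 3 --out enhanced.csv
radarbeat beats    --in enhanced.csv --ref scene.beats.txt --out metrics.json
radarbeat sweep    --replicates 20 --base-seed 0 --out sweep.csv
radarbeat report   --in sweep.csv --out summary.md
```

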