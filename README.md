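# thetaload

Detection of cognitive mental load from narrowband low-theta (4–5 Hz) EEG,
for researchers prototyping calibration-based, training-free workload
monitors and BCI front-ends.

Instead of spectral analysis, the detector summarizes the bandpassed signal
period by period with the **normalized curve length**

    Lscn(p) = (1/n) Σ_{k=1..n} sqrt((Δ_k S / Δt)² + 1),

the per-sample Euclidean path length of the signal over one nominal period
(`n = round(Fs/4.5)` samples).  `Lscn ≥ 1`, with equality exactly on a
constant signal, and it is immune to baseline level — only amplitude and
shape move it.  A sliding mean over `w = 10` periods (~2.2 s) is compared
against a per-channel threshold `Tresh_i = max` of the window means observed
during an initial 10 s rest calibration; every strict exceedance after
calibration is an *activation*.  Relative energy about the period mean is
available as an alternative criterion, and detection quality is scored
against the task timing profile (with a 3 s accepted latency) via the usual
accuracy / precision / sensitivity / specificity ratios plus paired t-test
channel ranking across sessions.

The pipeline: per-channel normalization → subtraction of the sub-2 Hz drift
(order-45 zero-phase Butterworth) → causal order-4000 (at 8192 Hz; scaled at
other rates) FIR bandpass with group-delay-corrected timestamps →
segmentation into nominal periods → spike-artifact replacement → metrics →
sliding means → calibration → detection.  See `docs/methods.md` for the full
account.

## Worked example

Generate the intermittent-load study recording (8 channels at 1024 Hz, three
20 s task bursts on channels Fp1/AF7/AF3, 10 s initial rest) and run the
detector:

```python
from thetaload import SyntheticSpec, synthesize, CognitiveLoadDetector, evaluate_trace

spec = SyntheticSpec(seed=2025, spike_rate_per_min=0.0)
rec, profile, ann = synthesize(spec)

det = CognitiveLoadDetector(t_start_s=0.0)   # sklearn-style: fit = calibrate
trace = det.fit_predict(rec)                 # predict = threshold detection

print("activations:", dict(zip(trace.labels, trace.activation_counts)))
print(evaluate_trace(trace, profile).round(3).to_string(index=False))
```

which prints

```
activations: {'Fp1': 285, 'AF7': 246, 'AF3': 265, 'F1': 121, 'F3': 58,
              'F5': 92, 'F7': 43, 'FT7': 24}
channel  tp  fp  tn  fn  precision  sensitivity
    Fp1 272  13  53  38      0.954        0.877
    AF7 246   0  66  64      1.000        0.794
    AF3 262   3  63  48      0.989        0.845
    F1   77  44  22 233      0.636        0.248
    ...
```

The three responsive channels produce 246–285 activations tightly aligned
with the task profile (precision 0.95–1.00); the background-only channels
fire an order of magnitude less, at the chance level set by the calibration
maximum.  The same workflow is available from the shell:

```sh
thetaload simulate --seed 2025 --out rec.edf --profile tasks.csv
thetaload detect   --input rec.edf --out results/ --t-start 0
thetaload evaluate --trace results/detection_trace.csv --profile tasks.csv \
                   --latency 3 --out report.csv
thetaload report   --trace results/detection_trace.csv
```

`detect` accepts EDF and BDF recordings at any sampling rate and writes the
per-window trace, per-channel activation counts, and a manifest with the
effective configuration and input hashes.

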