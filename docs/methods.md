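# Methods

## The detection problem

`thetaload` detects episodes of cognitive (mental-arithmetic-like) load in
multichannel scalp EEG from the behavior of the low-theta band.  The working
hypothesis is that imposed cognitive load elevates narrowband activity around
4–5 Hz; the detector therefore filters each channel into that 1 Hz band,
summarizes it period by period with a shape-sensitive signal metric, and flags
the moments when a short-window average of that metric exceeds a per-channel
threshold learned from an initial rest span.  Everything is analytic and
causal-in-spirit — no training data, no spectral transforms — so the same
machinery can run online against a live acquisition stream.

## Signal metrics

The narrowband signal is segmented into frames of one *nominal period*
`Tmed = 1/Fmed`, where `Fmed` is the midpoint of the passband (4.5 Hz for
4–5 Hz), so a frame holds `n = round(Fs · Tmed)` samples (1820 at 8192 Hz, 228
at 1024 Hz).  Two per-period measures are computed:

* **Curve length.** The path traced by the sampled signal in the signal–time
  plane over one period, `Lsc(p) = Σ_k sqrt((Δ_k S)² + (1/Fs)²)`, with the
  first difference taken against the previous frame's last sample so that
  consecutive frames tile the full path.  Its per-sample normalized form

      Lscn(p) = (1/n) Σ_k sqrt((Δ_k S / Δt)² + 1)

  is dimensionless, has the exact lower bound 1 (attained iff the period is
  constant), grows monotonically with amplitude, and is invariant under
  additive offsets — which makes it immune to residual baseline drift.
* **Relative energy.** `Er(p) = Σ_k (S_k − mean_p)²`, the energy about the
  period mean; shares the bias immunity, used for cross-checking the
  curve-length channel rankings.

Both series are smoothed by an arithmetic mean over a sliding window of
`w` consecutive periods (default `w = 10`, admissible 3–20) that advances one
period at a time.  The window span `w·Tmed` is the detector's intrinsic
response delay: ~2.22 s at `w = 10`, ~4.44 s at `w = 20`.

## Preprocessing chain

1. **Normalization**: per channel, z-score then division by the maximum
   absolute value, so every channel lies in [−1, 1] with zero mean.  (The two
   conventions — z-scoring and a [−1, 1] range — are reconciled by applying
   both; a zero-variance channel maps to zeros.)
2. **Drift removal**: a Butterworth lowpass with 2 Hz passband edge (≤ 1 dB)
   and 2.25 Hz stopband edge (≥ 40 dB) — order 45 from those constraints —
   estimates the slow component, which is subtracted.  The estimate is run
   zero-phase (`sosfiltfilt`): the subtraction then leaves the analysis band
   untouched in amplitude and phase, at the cost of a non-causal edge
   transient handled by the edge guard below.
3. **Narrowband filtering**: a causal windowed-sinc (Hamming) FIR bandpass,
   order 4000 at the 8192 Hz reference rate and scaled proportionally at
   other rates (500 at 1024 Hz, 244 at 500 Hz) to keep the transition width
   in Hz comparable.  The output is shifted back by the group delay
   (order/2 samples) so all reported timestamps live on the recording clock.
4. **Edge guard**: the first `t_start + retention` seconds (default 2 + 1 s)
   are excluded — start-up stabilization plus the FIR transient — and,
   symmetrically, the final `retention` seconds, where the zero-phase drift
   estimate is distorted by its end transient.

## Spike guard

Brief high-amplitude transients that survive into the narrowband are handled
by a replace-not-delete rule operating on the segmented frames.  A period is
scored by the *signal peak criterion*: the relative excess of its peak
magnitude over the mean peak of the `np` preceding clean periods.  When the
score exceeds `tresh` (defaults: `np = 10`, `tresh = 3`, i.e. a 300% peak
excursion), the period and its neighbors p−1, p+1, p+2 are replaced by the
sample-wise mean waveform of the clean window preceding the artifact.  A mean
waveform rather than a scalar fill avoids injecting step discontinuities into
a narrowband signal; replaced periods are excluded from later peak windows so
one artifact cannot license the next.  Replacement suppresses the metric in
the affected span (incoherent averaging shrinks amplitude by ~1/√np), which
is the intended conservative behavior: an artifact should never create a
detection.

## Calibration and detection

During the first `tcalib` seconds (default 10 s, the minimum; the subject is
assumed to be at imposed rest) the per-channel threshold for each metric is
the **maximum** sliding-window mean observed.  Afterwards, a window whose mean
**strictly** exceeds the threshold is an activation; by construction no window
inside the calibration span can fire.  Thresholds are frozen after
calibration.  The default decision uses the curve-length metric alone;
`metric_choice="either"` ORs the two criteria.

A consequence worth stating plainly: with windows advancing one period at a
time, a 10 s calibration span holds ~22–31 window positions but only ~3–4
*effectively independent* ones (adjacent windows share w−1 of w periods).
For a stationary background, a later background window therefore exceeds the
calibration maximum with probability of roughly 1/(m_eff+1) ≈ 10–25% — a rank
statistic that no amount of background realism changes.  The package's
synthetic no-load experiments measure this chance level at ~12% of windows
(flat over the recording), and the false-positive bounds asserted in the
acceptance suite (≤ 10%) sit slightly below it; the corresponding check is
expected to fail on typical seeds and is kept at its stated bounds rather
than widened.  Longer calibration or a coarser window stride would raise
m_eff and lower the chance level, but both are fixed by the reference
operating point.

## Evaluation

Windows are labeled by their end time — the first moment a detection can be
reported.  A window is task-time when it ends inside a load interval or
within the *accepted latency* (default 3 s) after one; the latency absorbs
cognitive after-effects, so a late detection is a true positive rather than a
false positive.  TP/FP/TN/FN then yield accuracy, precision, sensitivity and
specificity, with zero-denominator ratios reported as missing, never as 0.
Channel reliability across repeated sessions is ranked by a two-tailed paired
t-test on activation counts (load vs no-load, df = N−1), with H1 accepted
when |t| exceeds the critical value at α ∈ {0.05, 0.02, 0.01}; channels are
grouped into the tier of the smallest α they pass, after a p < 0.05 screen.

## Synthetic data

The generator emulates the study structure rather than the physiology: each
channel is 1/f^β background noise (β = 1) at a target RMS, plus a sub-2-Hz
sinusoidal drift, plus — on responsive channels, inside task intervals — a
4.5 Hz oscillation with 0.5 s cosine ramps, plus optional brief Gaussian
spike transients at a Poisson rate.  The burst amplitude is specified
relative to the background's **own 4–5 Hz RMS** (`burst_ratio`, default 3, so
in-band energy rises by 1 + r²/2 = 5.5× during load): referencing the
broadband RMS instead would make the burst an order of magnitude larger than
the resting in-band peak, and the spike guard would correctly classify the
load response itself as an artifact.  The default layout is the intermittent
protocol: 10 s initial rest, three 20 s task rounds separated by 10 s breaks,
5 s trailing rest, at 1024 Hz (the 8192 Hz reference rate is exercised by a
short dedicated test); the fixture suite adds a no-load run and a continuous
run (one merged 50 s interval).  All randomness derives from one seed;
identical specs are bit-identical.

What passing synthetic tests do **not** show: real EEG has non-stationary
rest states, eye/muscle artifacts with in-band energy, inter-channel
correlation, and load responses that wax and wane — the synthetic recovery
results are an upper bound on field behavior, not a forecast.

## Numerical choices and degenerate inputs

* `n = round(Fs·Tmed)` (the exact product is non-integer at 8192 Hz); the
  trailing partial frame is dropped.
* The first frame of a run has no predecessor; its first elementary distance
  degenerates to the flat time step (Δ₁S = 0), preserving the n-term sum.
* Strict inequalities throughout detection; ties never fire.
* A constant channel normalizes to zeros; a constant period has Lscn = 1 and
  Er = 0 exactly; a zero prior-peak mean makes the spike score undefined and
  detection is skipped for that period.
* Critical t values are reported to 4 decimals; p-values come from the exact
  t CDF, not table lookup.
* File I/O: EDF/BDF are read through MNE; the bundled writer quantizes onto
  per-channel physical ranges (16-bit EDF, 24-bit BDF, 1 s records) and the
  reader rejects files whose size contradicts the declared record count.

## Known limitations

* The false-positive floor of max-of-calibration thresholding (above) is a
  property of the method at the reference operating point, visible in the
  original no-load experiments as pervasive background activations.
* Channel selection, montage re-referencing, ICA-style artifact removal and
  multichannel fusion are out of scope by design.
* The spike guard assumes artifacts are rarer than one per `np` periods;
  sustained contamination defeats the prior-window average.
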