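# cspcwt

Decoding six grasp-and-lift motor events — handstart (HS), grasp (GS),
lift (LT), hold (HD), replace (RP) and release (RL) — from multichannel EEG,
for researchers building non-invasive brain-computer interfaces for upper-limb
prosthetics.  The package implements the full decoding chain as a library plus
a `csp-cwt` command line tool:

1. **Band-pass filtering** of the 500 Hz signal to the 7–30 Hz µ/β band with a
   linear-phase equiripple FIR (stopbands at 5/33 Hz, 65 dB attenuation),
   removing eye-blink (<4 Hz), heartbeat (≈1.2 Hz), mains (60 Hz) and muscle
   (>30 Hz) artifacts, followed by per-channel z-scoring.
2. **Common spatial pattern (CSP) filtering**, one binary contrast per event
   against a balanced pool of the other five (one-vs-rest).  For class
   covariances R̄₁, R̄₂ (trace-normalized, averaged over epochs), the composite
   R̄₁+R̄₂ = UΔUᵀ gives the whitening map P_w = Δ^{-1/2}Uᵀ; the whitened class
   covariances share common eigenvectors V with paired spectra Δ₁+Δ₂ = I, and
   the spatial filter is W = VᵀP_w, with Z = WX and X = W⁻¹Z.  Row 0 of W
   maximizes event variance where rest variance is minimal.
3. **Morse-wavelet scalograms**: each 400-sample sliding window (step 300) is
   CSP-projected, each component row transformed with an analytic Morse
   wavelet filter bank (symmetry γ = 3, time-bandwidth P² = 60, 10 voices per
   octave, automatic scale bounds → a 69 × 400 magnitude matrix), quantized to
   8-bit grayscale, resized to 224 × 224 (bicubic), and the motor (C3, Cz, C4)
   and parietal (P3, Pz, P4) triads stacked into RGB images.
4. **CNN classification** of the RGB scalograms per contrast (pluggable
   backend; the bundled reference CNN is a compact NumPy network trained with
   SGD, batch 10, ≤30 epochs, 0.8 : 0.1 : 0.1 stratified split).
5. **Evaluation**: precision TP/(TP+FP), sensitivity TP/(TP+FN), specificity
   TN/(TN+FP), accuracy, ROC curves and AUROC per contrast, macro-averaged
   over the six events.

A synthetic EEG generator (class-specific source variances mixed into six
channels, with realistic artifact components) makes the entire pipeline
testable without any recorded dataset.

## Worked example

Run the end-to-end pipeline on the strong synthetic scenario (600 RGB
scalograms per class and contrast):

```python
from cspcwt import PipelineConfig, run_all

cfg = PipelineConfig(seed=1, n_trials=135, windows_per_class=300)
result = run_all(cfg)
print(result.report.to_frame().to_string(index=False))
```

which prints (about 9 minutes on one CPU):

```
contrast  precision  sensitivity  specificity  accuracy     auroc   n
      HS   1.000000     0.933333     1.000000  0.966667  0.983333  60
      GS   0.931034     0.900000     0.933333  0.916667  0.974444  60
      LT   0.900000     0.900000     0.900000  0.900000  0.960000  60
      HD   0.925926     0.833333     0.933333  0.883333  0.918889  60
      RP   1.000000     0.933333     1.000000  0.966667  0.986667  60
      RL   1.000000     0.966667     1.000000  0.983333  0.997778  60
   macro   0.959493     0.911111     0.961111  0.936111  0.970185 360
```

Each row is one event-vs-rest contrast evaluated on its held-out test windows
(n = 60 per contrast; two scalogram views — motor and parietal triad — are
scored by separate classifiers and fused per window).  The macro row is the
unweighted mean over the six contrasts: here the pipeline separates events
from the pooled rest class with macro AUROC 0.97 on synthetic data with a
10 : 1 planted variance contrast.

The same run is available from the shell:

```bash
csp-cwt run --seed 1 --out runs/demo
```

and the individual stages as `csp-cwt simulate / ingest / csp-fit /
scalogram`.

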