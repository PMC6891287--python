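# Methods

This note documents the models, numerical choices and limitations behind
`cspcwt`.  It is written for a reader who wants to know exactly what the code
computes and why, module by module.

## Signal model and preprocessing

The input is multichannel EEG sampled at 500 Hz with per-sample binary
annotations for six grasp-and-lift events in fixed order HS, GS, LT, HD, RP,
RL.  Six channels over motor (C3, Cz, C4) and parietal (P3, Pz, P4) cortex
carry the µ (8–13 Hz) and β (13–30 Hz) rhythms that index sensorimotor
activity; everything outside 7–30 Hz is treated as artifact (blinks < 4 Hz,
heartbeat ≈ 1.2 Hz, mains 60 Hz, muscle > 30 Hz).

The band-pass is a type-I (odd-length, symmetric) equiripple FIR: passband
7–30 Hz with ±0.5 dB ripple, stopbands below 5 Hz and above 33 Hz at 65 dB.
The order is estimated with Bellanger's formula from the ripple/attenuation
targets and the 2 Hz transition bands, rounded up to even, then the
Parks–McClellan design is *measured* against the spec (64 probes per band)
and the order grown until it passes — the returned filter therefore meets the
stated attenuation by construction, not by assumption (633 taps at the
default spec).  Filtering is causal with the (L−1)/2-sample group delay
compensated by shifting; forward–backward filtering is deliberately avoided
because it would square the magnitude response and silently double the
stopband attenuation relative to the designed 65 dB.  Each channel is then
z-scored over the whole recording (filter first, then normalize).

## Common spatial patterns

For one epoch X (channels × samples) the spatial covariance is
R = XXᵀ/trace(XXᵀ); class covariances R̄₁, R̄₂ are plain means over epochs.
Whitening diagonalizes the composite R̄₁+R̄₂ = UΔUᵀ (eigenvalues descending,
ties kept in stable order) and sets P_w = Δ^{-1/2}Uᵀ.  The whitened class
covariances Q₁, Q₂ commute, share eigenvectors V, and their eigenvalue pairs
satisfy Δ₁+Δ₂ = I, so the spatial filter W = VᵀP_w simultaneously maximizes
the variance of one class and minimizes the other's along each row; rows are
ordered by Δ₁ descending and V's column signs are fixed (largest-magnitude
entry positive) to make results deterministic.  W⁻¹'s columns are the spatial
patterns.  All six components are retained — the scalogram stage needs six
signal rows to mirror the six-electrode grouping — and component row *i* is
identified with electrode *i* of the input ordering for naming purposes.

Rank deficiency: whitening refuses to proceed when the smallest eigenvalue of
the composite covariance falls below 10⁻¹⁰ times the largest.  A shrinkage
hook R ← (1−λ)R + λ(trace(R)/N)I exists (`cspcwt.csp.shrink`) but is off by
default; CSP's known outlier sensitivity is out of scope here.

Multiclass decoding is one-vs-rest: for each event the rest pool draws an
equal number of epochs (seeded, without replacement where possible) from each
of the five other classes, balanced so no single class dominates the rest
covariance.  The five classes admit 5! = 120 orderings; the pool is one
balanced random draw, not an enumeration.

## Morse wavelet filter bank

The analytic generalized Morse wavelet has frequency response
a·ω^β·e^(−ω^γ) for ω > 0 (zero for ω ≤ 0), with symmetry γ = 3 and
time-bandwidth product P² = 60, i.e. β = P²/γ = 20; the mother wavelet peaks
at ω_p = (β/γ)^(1/γ) ≈ 1.8821 rad/sample.  Scales form a geometric grid with
10 voices per octave between bounds set by an energy-spread rule:

- s_min = ω_p/π — the smallest scale puts the wavelet's peak at Nyquist;
- s_max = n/(K·σ_t) — the largest scale keeps K wavelet time standard
  deviations σ_t (computed numerically from |ψ(t)|², ≈ 2.92 samples at unit
  scale) inside the n-sample window.

K = 1.98 is a frozen package constant, calibrated once so that the standard
analysis window (n = 400 at 500 Hz) yields exactly 69 scales — the scale
count is floor(10·log₂(s_max/s_min)) + 1.  K ≈ 2 has the natural reading
"two time-SDs must fit"; any K in roughly 1.93–2.07 gives the same count, so
the calibration is not delicate.  Lengthening the window adds scales only at
the long-scale end; existing scale values are unchanged.

The CWT is computed by frequency-domain multiplication after reflection
padding (half the window length each side, FFT length rounded up to a power
of two); magnitudes of the complex coefficients form the 69 × 400 scalogram,
row 0 = highest frequency.

## Images

Scalograms are min–max quantized to 8-bit grayscale with round-half-up.  The
default normalization shares one min/max range across the six component
scalograms of a window ("per-window"), because the information CSP extracts
*is* the between-component variance ratio: normalizing each image separately
erases it.  Per-image normalization remains selectable and every manifest row
records the mode.  Grayscale images are resized to 224 × 224 with bicubic
spline interpolation (order 3, no antialias prefilter), then the motor triad
(C3, Cz, C4) and parietal triad (P3, Pz, P4) are stacked as RGB planes, one
image per triad per window per contrast.  Stacking is lossless — each plane
is recoverable bit-exactly.

## Classifier

The classifier stage is backend-pluggable; the bundled reference backend is a
compact CNN implemented directly on NumPy (gradient-checked backprop):
a parameter-free 4 × 4 average-pool stem (224 → 56; scalograms are smooth at
that scale, and the stem cuts CPU cost ~16×), conv(3×3, 16) + ReLU +
maxpool(2), conv(3×3, 32) + ReLU + maxpool(2), global average pooling, dense
softmax.  Training is SGD with momentum 0.9 and learning rate 10⁻², batch 10,
at most 30 epochs with per-epoch validation; the parameters from the best
validation epoch are kept, and training stops early after 6 epochs without
improvement.  The rate was set where plain SGD with a global-average-pooling
head reliably fits separable image sets within the epoch budget; 10⁻³
underfits there.  All randomness (init, batch order, splits) flows from one
seed.  A large pre-trained network could be dropped in through the same
train/predict interface; none is bundled.

Each window produces two views (motor/parietal triad).  The pipeline splits
*windows* 0.8 : 0.1 : 0.1 (stratified, so both views of a window share a
partition), trains one classifier per (contrast, triad), and fuses the two
view scores per test window by their mean.  The per-triad readout matters on
synthetic data: the discriminative CSP component maps into the motor-triad
image, so pooling both views into one classifier mixes informative and
uninformative samples under the same label and collapses performance.

## Evaluation

Precision, sensitivity, specificity, accuracy from confusion counts at the
0.5 operating point; any metric with a zero denominator is reported as an
explicit `None`, never silently 0 (small test sets do hit these cases).  ROC
curves place thresholds at unique score values with ties grouped; AUROC is
the trapezoidal area, which equals the Mann–Whitney concordance probability
(tested against an independent pair-counting oracle, including ties).  Macro
averages are unweighted means over the six contrasts and the report records
the number of evaluated items.

## Synthetic data

The generator emulates the statistical structure CSP assumes: six
band-limited Gaussian sources (centers 9–25 Hz, 4th-order Butterworth
shaping — deliberately a different filter family than the analysis band-pass,
so filter tests are not circular) mixed into six channels by a fixed
well-conditioned random mixing matrix.  Event k raises source k's variance
(10 : 1 in the strong scenario, 1.5 : 1 in the weak one); since the filter
extracting source k is row k of the mixing inverse, the scenario knows the
direction a perfect CSP fit should recover (`planted_direction`).  Sources
run continuously through the recording and the class variance enters as a
per-block gain with 40 ms raised-cosine transitions — hard splices would
inject broadband power at every block boundary.  Trials are six contiguous
event blocks in HS→RL order (durations uniform 0.8–2.0 s) separated by
0.4–0.8 s event-free gaps; white sensor noise (SD 0.1 of source scale) and
additive artifacts (blink pulse bursts, 1.2 Hz heartbeat pulse train, 60 Hz
line, >30 Hz muscle noise, each with a random spatial topography) complete
the recording, scaled to ~10 µV per unit source SD.

What passing tests do and do not show: the synthetic world is stationary
within blocks, linearly mixed and Gaussian — real EEG adds nonstationarity,
inter-subject and inter-session variation, volume-conduction structure and
event-related (de)synchronization dynamics.  Success here validates the
implementation (the machinery recovers planted structure and the end-to-end
chain is learnable), not clinical-grade decoding performance on recorded
data.

## Problem sizes

The end-to-end check uses 135 trials (≈20 minutes of synthetic recording),
300 event windows per contrast (600 RGB scalograms per class counting both
triads), and the reference CNN at the training protocol above — chosen so the
whole pipeline, including six contrasts × two triads of training, completes
in under ten minutes on one CPU while leaving ≥ 50 test windows per
contrast.  Unit tests use far smaller fixtures.

## Known limitations

- No regularized/filter-bank/Riemannian CSP variants; no true multiclass
  joint diagonalization.
- The reference CNN is intentionally small; it is a stand-in for the
  classification stage's interface, not a state-of-the-art image model.
- Epochs are cut within one recording, never across files; majority labelling
  of sliding windows (strict majority, ties broken HS>GS>LT>HD>RP>RL) is a
  convention — annotation schemes with overlapping events would need a
  different rule.
- Undefined behavior under non-finite input is not guarded; inputs are
  assumed to be real recordings or generator output.
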