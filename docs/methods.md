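# Methods

This note records the models implemented in `mskrecon`, the assumptions and
parameter choices behind them, and what the synthetic experiments do and do
not establish.

## Acquisition model

Cartesian 2-D k-space, fully sampled along readout, sampled line-by-line
along phase encoding (PE). A `SamplingPattern` is the union of a regular grid
(lines congruent to `offset` mod `R`) and a contiguous ACS block centered on
the k-space center line, restricted to the retained phase-resolution band.

Conventions chosen where the field has no single standard:

* **FFT layout.** Centered, orthonormal (`norm="ortho"`), DC at index
  `n // 2`. Unitarity makes Parseval checks and noise propagation exact:
  k-space noise of std σ per component stays std σ per pixel in image space.
* **Phase-resolution truncation** removes `floor(n_pe · (1 − p))` lines split
  evenly between the two peripheries, the odd leftover from the high-index
  edge; truncated lines are zero-filled, not cropped, so one matrix size
  flows through the pipeline. (A scanner might instead truncate one-sidedly;
  symmetric truncation preserves image phase best.)
* **ACS placement**: centered on line `n_pe // 2`, starting at
  `n_pe//2 − acs//2`. A pattern whose ACS would poke outside the retained
  band is rejected rather than silently clipped.

## Synthetic study conditions

The generator defines the conditions every test and the acceptance script run
under:

* **Phantoms**: one body ellipse plus 2–6 inner ellipses with intensities in
  [−0.4, 0.5] on a 0.6–0.9 body, optional fine sinusoidal texture
  (amplitude ≤ 0.06) and a random linear phase ramp (±1.5 cycles across the
  FOV) so images are genuinely complex. The fixed `knee_like_phantom` used
  for SNR comparisons has two dark bone-like ellipses, a bright thin
  cartilage-like band and one small bright structure.
* **Coils**: 8 Gaussian-profile coils (width 0.9) on a ring of radius 1.2
  around the FOV with per-coil linear phase; maps are RSS-normalized, so
  `‖A‖ ≤ 1` holds exactly. The coil-average phase ramp is subtracted (coil
  phase is only defined relative to a reference), which also makes the
  single-coil case exactly the identity map.
* **Bias field**: `exp` of a random order-2 polynomial (amplitude 0.3),
  normalized to mean 1 — smooth, strictly positive, redrawn per item (per
  "subject"); the coil array is shared across items (one scanner).
* **Noise**: i.i.d. complex Gaussian, std 0.015 per component on sampled
  lines. Under the unitary FFT this equals the per-coil image-domain noise
  std, giving ≈ 30 dB input SNR for the ~0.65-RMS phantoms.
* **Protocol defaults**: R = 4 with a 16-line ACS block — the accelerated
  protocol the network targets.

What this emulates: multi-coil encoding, undersampling artifacts, coil-noise
propagation, intensity inhomogeneity, complex-valued images. What it does
not: TSE echo-train signal evolution (T2 blurring), fat suppression, motion,
susceptibility, realistic anatomy and contrast diversity. Passing tests
therefore establish the *mechanics* of the pipeline (operators, guarantees,
learning dynamics, statistics), not clinical image quality.

## Sensitivity estimation

Windowed low-resolution method: Hamming window along PE over the ACS,
zero-pad, inverse transform, divide by the RSS (guarded by a floor of 5% of
the max RSS, which also defines the support). The estimate inherits the
low-resolution image phase as a spatially smooth phase common to all coils;
this is irrelevant to reconstruction (the image estimate absorbs it) and
tests compare maps after per-pixel phase alignment. An eigen-decomposition
(ESPIRiT-style) estimator could replace this behind the same signature.

## Unrolled network

Chain structure and the concrete reading of "trainable extrapolation":
iterate extrapolation `z = xₖ + μₖ(xₖ − xₖ₋₁)` with trainable scalars per
cascade, initialized μ = 0, t = 0.5 (half the maximal stable step for
`‖A‖ ≤ 1`). The post-cascade is the same gradient step frozen at t = 1,
μ = 0 — with `‖A‖ ≤ 1` the acquired-line residual map is the contraction
`(I − AAᴴ)`, which is the data-consistency guarantee asserted per item in the
tests. Regularizers are residual encoder–decoders (2 levels, 8 base channels
by default, channel count doubling per level, additive skips, zero-initialized
output convolution) with per-cascade weights; a `share_weights` switch ties
them. Zero-initializing the output convolution makes a fresh network exactly
the linear data-consistency chain, which is both a stable training start and
the object the linearity/superposition tests check.

Normalization: each item is scaled by the 99th percentile of `|Aᴴy|` and
unscaled on output; with zeroed regularizers this cancels exactly, keeping
the chain linear. Bias handling: the network iterates on uncorrected data;
the field divides the output magnitude (and the training prediction) while
targets are the bias-free phantom magnitudes.

Loss: `α·mean|p − t| + β·(1 − MS-SSIM(p, t))`, α = β = 1. MS-SSIM uses
3 scales (2× mean pooling), an 11-tap Gaussian window (σ = 1.5),
k₁ = 0.01, k₂ = 0.03, uniform scale weights, the luminance term at the
coarsest scale only, and zero-padded filtering — chosen because the
zero-padding operator is self-adjoint, which keeps the hand-derived gradient
exact (it is finite-difference-verified to ~1e-7). Scale means are clamped at
1e-6 before the geometric mean.

Training: per-item Adam (lr 2e-3, default betas), batch size 1, shuffled
per epoch, all randomness under one seed; single precision by default
(structural properties are asserted in double in the tests). Divergence
(non-finite loss) aborts with a diagnostic rather than continuing. The
implementation is plain NumPy with hand-derived analytic gradients through
the entire unrolled chain — data-consistency steps, momenta, CNNs and loss —
validated against finite differences in the test suite.

Desk-scale problem sizes were chosen so the full study runs in minutes on one
CPU: 96×96 matrices, 8 coils, 200-phantom corpus (160/20/20 split), 2/4/1
cascades, 20 epochs. The clinical-scale 6/12/1 configuration is expressible
(`CascadeConfig(n_pre=6, n_main=12)`) but not exercised by default.

Adversarial training is deliberately not implemented; the post-cascade
guarantee it motivates is.

## GRAPPA baseline

Standard calibration: per missing-line offset `d ∈ 1..R−1`, a least-squares
fit of 4-source-line × 5-readout-tap all-coil kernels over the ACS, Tikhonov-
regularized with λ = 1e-5 × (trace-normalized). The λ default is small enough
that the calibration fit residual on noiseless smooth-coil phantoms stays
below 1e-3 (at λ = 1e-4 the residual is regularization-dominated) while still
stabilizing noisy calibrations. Synthesis fills every missing line inside the
retained band with zero-padded edge sources; acquired samples (including ACS
lines) pass through untouched. Coil images are combined by RSS; the bias
field can be divided out so the baseline is display-comparable to the
network output. Calibration warns below 10× equations-per-unknown and fails
when underdetermined; single-coil calibration is rejected outright (aliasing
is unresolvable).

## Pseudo-replica SNR

For reconstruction `f`: add `n` complex Gaussian noise realizations (std σ
per component, sampled lines only) to the measured k-space, reconstruct each,
and take SNR = |f(y)| / std over replicas of the magnitude stack. The
unperturbed reconstruction is the signal by default (`signal="replica_mean"`
selects the mean-of-replicas variant). Magnitude statistics mirror clinical
display but are Rician at low SNR, where the std underestimates the complex
noise — comparisons are therefore read on high-signal pixels. Replica std is
flagged infinite/capped where it is exactly zero (σ = 0).

ROI choice for homogeneity comparisons: the coefficient of variation of an
SNR map over a mixed-tissue ROI is dominated by the phantom's own intensity
steps, identically for all methods; homogeneity of the *noise* behavior is
what differs between reconstructions. The comparison ROI is therefore the
uniform-intensity body tissue (|img| ∈ (0.6, 0.8)), where any SNR variation
must come from spatially varying noise amplification (g-factor-like
structure for GRAPPA).

## Evaluation and statistics

* PSNR (peak = target max, capped at 300 dB for identical images) and NRMSE.
  Cross-method comparisons first apply a per-image least-squares amplitude
  fit so no method gains or loses dB from a global scaling — the zero-filled
  adjoint would otherwise be penalized for missing-line energy rather than
  artifacts.
* Acquisition-time savings: `100·(1 − ta_accel/ta_standard)` per protocol,
  reported rounded to integer percent; the packaged table holds the twelve
  conventional/accelerated pairs (savings 2–75%). The 2% outlier
  (ankle-sagittal, 1:47 → 1:45) is reported as computed.
* Wilcoxon signed-rank: zero differences dropped, tied |differences| get
  averaged ranks, statistic W⁺. Exact null up to 25 non-tied pairs via a
  convolution over doubled (integer) ranks — unlike generic exact routines
  this remains exact under ties, which ordinal Likert data guarantee;
  beyond 25, the tie-corrected normal approximation with continuity
  correction. All-tied input raises (the test is undefined).
* Cohen's kappa: unweighted, `(p_o − p_e)/(1 − p_e)`, with the conventional
  agreement bands (≤0.20 poor, ≤0.40 fair, ≤0.60 moderate, ≤0.80
  substantial, ≤1 (almost) perfect); `p_e = 1` (both raters constant)
  raises.

## Numerical notes and degenerate inputs

* Division guards: sensitivity floor 5% of max RSS; bias floor 1e-3;
  magnitude-phase gradient uses 0 at exactly-zero pixels.
* The phase-resolution floor adds 1e-9 before truncation to absorb binary
  fraction wobble (65 × (1 − 0.8) = 12.999…).
* Pseudo-replica std below 1e-12 × max signal is treated as zero (identical
  replicas leave only rounding residue).
* GRAPPA edge lines use zero-padded sources; lines outside the retained band
  stay zero.
* Reconstruction normalization guards a zero scale (all-zero input maps to
  all-zero output).

## Known limitations

* No TSE contrast evolution: the phantom sees a single static image, so
  echo-train blurring and its interaction with acceleration are out of scope.
* The regularizer is far smaller than clinical down-up architectures; results
  demonstrate the training mechanics and ordering of methods, not attainable
  image quality.
* GRAPPA at R = 4 with a 16-line ACS is a deliberately lean calibration
  (it warns); it represents "the standard method applied to the accelerated
  protocol", not GRAPPA at its own best operating point.
* Reader-study statistics are implemented and verified on constructed
  tables; no claim is made about any particular clinical rating dataset.
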