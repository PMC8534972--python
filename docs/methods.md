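# Methods

This note documents the models, the simulator, the numerical choices and
the known limitations of `angioflow`, in the spirit of a methods appendix.

## Measurement model

The package treats contrast transport as 1-D bulk (plug) flow of an
indicator: the bolus moves at the mean velocity `v = Q / A`, so volumetric
flow is recovered as

```
Q = Ā · d / τ · 60   [mL/min]
```

with `τ` the bolus transit time between two user-chosen ROIs, `d` the
centerline arc length between their rows, and `Ā` the mean circular
cross-sectional area. The combining formula is dimensional necessity for a
mean-velocity model; no parabolic-profile (Poiseuille) correction factor is
applied, so `Q` is the flow implied by the *mean* transport speed of the
indicator, which is the quantity an in-line ultrasonic flow sensor reports.

### Time-density curves

ROI aggregation is the unweighted spatial mean, making TDC amplitude
invariant to ROI size; transit estimation depends only on timing.
Fluoroscopic frames are negated at extraction (contrast darkens an
unsubtracted image), giving one contrast-positive convention for every fit.
Baseline correction subtracts the mean of the first `n_pre` samples;
`n_pre` defaults to `floor(1 s / Δt)`, the samples inside the injector's
1 s delay.

### Transit-time algorithms

Both algorithms run on a grid upsampled ×100 (`effective Δt = Δt/100`).
At 3–10 samples/s and sub-second transit times, temporal quantization is
otherwise the dominant error — flow is proportional to `1/τ`, so a half
frame of quantization at high flow is a tens-of-percent error. Fitted
curves are evaluated directly on the fine grid; raw curves are linearly
interpolated.

* PP takes the first maximum of each curve (deterministic tie-break).
* CC evaluates `φ(τ) = (1/N) Σ P₁(t) P₂(t+τ)` at every integer lag of the
  fine grid, zero-padding out-of-range samples (exact for baseline-zero
  curves), and reports the first maximizing non-negative lag. The positive
  sign convention means a downstream second ROI always yields `τ ≥ 0`; if
  the correlation is maximized only at negative lags the ROI order is
  reported as swapped instead of returning a nonsense delay.

### Reference-curve models

* **Gamma variate** `C(t) = Kₐ(t−AT)^α e^{−(t−AT)/β}`, zero for `t ≤ AT`;
  peak at `AT + αβ`, area `Kₐ β^{α+1} Γ(α+1)`. Evaluated in log space to
  avoid overflow at large `α`.
* **Lagged normal** — Gaussian ⊛ exponential, evaluated in the closed form
  `(A/2)·K·[1+erf(L)]` with `K = λ e^{−λt+λµ+λ²σ²/2}` and
  `L = (t−µ−λσ²)/√(2σ²)`; computed through `erfcx` with an asymptotic
  branch deep in the exponential tail so it is finite for every `λ`. Mean
  and variance are `µ + 1/λ` and `σ² + 1/λ²`; both are verified against
  dense quadrature in the tests.
* **Polynomial (degree 6)** by ordinary least squares over a configurable
  fit window (default: the whole acquisition), clamped non-negative and
  zero outside the window for downstream use.

### Fit optimization

Nonlinear parameters are found by a coarse grid followed by pattern-search
refinement; the linear scale (`Kₐ` or `A`) is solved by closed-form
non-negative least squares at every candidate, which removes one dimension
exactly. The coarse grid anchors the appearance time to the first sample
exceeding 5% of the peak and the decay scale so the model peak lands near
the observed peak. Refinement explores the full ±1-step neighborhood
(all 3³ offset combinations, so correlated valleys can be descended
diagonally), moves greedily while the RMSE improves by more than 1e-9, and
shrinks the step ×5 per round. Ten rounds are used: the (α, β, AT) valley
is strongly correlated, and fewer rounds leave the search stalled at the
percent level, while ten recover noise-free generator parameters to better
than 0.01% with RMSE below 1e-6 of the peak. RMSE ties break toward the
smaller appearance time (gamma variate) or mean (lagged normal) for
determinism. Gradient-based and stochastic global optimizers are
deliberately out of scope.

### Vessel geometry

Geometry is computed on the max-opacification image (pixelwise temporal
maximum of polarity-normalized, baseline-subtracted frames) — the most
enhanced, motion-free view of the lumen. Because the temporal maximum
pushes background noise upward (its expectation grows with the number of
frames), the image is median-filtered (3×3 by default; the median of a
monotone ramp is the ramp, so edges do not shift) and the image median —
background, as the vessel occupies a small pixel fraction — is subtracted
before thresholding.

Scan lines are image rows stepping 25 px (default) from the first ROI's
center row to the second's, both end rows always included. Edges are the
sub-pixel linear interpolations of the 12%-of-global-max threshold
crossings (the 5% initial cut-off remains available as a config option);
among multiple above-threshold runs the one nearest the previous station's
centerline wins (the widest at the first station), after discarding runs
narrower than 25% of the widest, which rejects residual noise spikes.
Width is the continuous `right − left`, not a pixel count, because area
enters flow with the square of the radius. The traversal distance is the
arc length of the centerline polyline; per-station areas assume a circular
cross-section, and their arithmetic mean is used (mean-of-areas, not
area-of-mean-diameter, to represent tapering vessels).

## Phantom simulator

The simulator emulates a benchtop flow circuit: a peristaltic carrier flow
through a silicone tube (straight, angular or loop configuration, all with
monotone image rows so row-wise scanning is well posed), a power-injected
rectangular contrast pulse — defaults 10/3 mL/s for 3 s after a 1 s delay,
i.e. exactly the 10 mL protocol volume — and 8 s acquisitions at 3, 4, 6 or
10 samples/s.

Transport: the inlet concentration is the injection diluted by the carrier,
`c₀ = Qᵢ/(Qᵢ + Q)`, advected at `v = Q/A` with Gaussian longitudinal
dispersion of variance `2Dt` (superposed analytic step responses of the 1-D
advection–dispersion equation; mass-conserving while the pulse is inside
the tube). The default `D = 15 cm²/s` is sized from the shear-induced
spreading of a plug in a 0.6 cm tube at patent-access velocities
(σ_s ≈ v·t/√12 over sub-second transits): molecular-diffusion-limited
Taylor dispersion does not apply at these time scales, and it is this
shear spreading that turns the rectangular injection into the smooth
right-skewed first-pass curves seen in practice.

Projection: each pixel's noise-free intensity is the chord length of the
circular tube at the pixel's perpendicular distance from the densely
sampled centerline times the local concentration — path-length-
proportional attenuation in arbitrary detector units. DSA frames have zero
baseline plus additive Gaussian noise with SD 5% of the peak vessel signal;
fluoroscopic frames place the darkened vessel on a bright constant
background with 15% noise (3× the DSA level, matching the clinical image-
quality ordering; the noise fraction is configurable). A delayed
low-amplitude second pass (recirculation) can be enabled to stress the
first-pass isolation of the curve fits; it is off by default. All
randomness derives from the config seed; the same seed and config render
bit-identical sequences.

Geometry defaults chosen once for the study conditions: 512×256 px frames
at 0.05 cm/px (a 25.6 cm field), tube diameter 0.6 cm (12 px), default
ROIs on the path at 20% and 80% of the arc length. With these choices the
ROI-to-ROI transit spans ≈0.24–0.81 s across 300–1000 mL/min — a genuinely
hard sub-frame regime at 3–10 samples/s, which is exactly what the
upsampled transit estimators are for.

What the simulator does *not* model: beam hardening, scatter, detector
MTF, pulsatile pump waveforms, wall compliance, motion, and a resolved
parabolic velocity profile (dispersion is the 1-D surrogate). Passing the
phantom-based tests therefore demonstrates the correctness and noise
robustness of the algorithms under the stated transport and projection
model, not clinical performance on patient fistulagrams.

## Evaluation statistics

Accuracy is the absolute percent error versus ground truth, summarized as
mean ± SEM (sample SD, n−1) with a normal 95% CI (±1.96·SEM — the normal
multiplier is used rather than a t quantile, consistent with the
limits-of-agreement convention, and documented so tabulated outputs are
comparable). Agreement is Bland–Altman bias ± 1.96·SD of paired
differences plus the Pearson correlation. Algorithm comparisons use a
two-sided paired Student t test on per-case errors, since every algorithm
measures the same acquisitions; zero within-pair variance is reported as
the degenerate case it is (t = 0, p = 1 for identical errors; p = 0 with a
flag for a constant nonzero difference) rather than an exception from the
generic routine. The benchmark harness renders each phantom once per
repetition and measures it with every scenario that shares imaging
settings, so method comparisons are paired; failed measurements are
excluded and counted, never imputed.

## Problem sizes

The test suite and the acceptance script use 50-phantom ensembles per
imaging condition (straight tube, flows uniform in 300–1000 mL/min), which
puts the Monte-Carlo error of a mean-percent-error estimate near half a
percentage point — small against the error bounds being checked — while
keeping a full run in the low minutes on one CPU.

## Known limitations

* Row-wise width measurement overestimates the diameter of obliquely
  oriented segments by `1/cos θ` (the horizontal chord of a tilted tube is
  longer than its true width), inflating the area — and hence flow — on
  the slanted legs of angular and loop configurations. The straight-tube
  case is unbiased up to the threshold bias below. A non-circular /
  orientation-aware cross-section model is future work.
* The 12% relative threshold systematically reads a chord slightly inside
  the lumen (width `2R√(1−0.12²) ≈ 0.993·2R`) and sub-pixel interpolation
  on the steep dome edge adds a fraction of a pixel outward; net area bias
  on the default 12 px tube is a few percent.
* The injection itself adds ~200 mL/min to the carrier flow in the real
  circuit during the 3 s injection; the simulator advects at the carrier
  velocity only, so this systematic is not represented.
* Plug flow plus a scalar dispersion coefficient is a deliberate 1-D
  surrogate for shear dispersion; it reproduces realistic TDC shapes but
  not their dependence on viscosity or hematocrit.
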