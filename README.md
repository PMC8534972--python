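# angioflow

Image-based blood-flow quantification for dialysis (vascular) access from
2-D angiographic image sequences — digital subtraction angiography (DSA) or
pulsed fluoroscopy — with a synthetic flow-phantom simulator for end-to-end
validation against known ground truth.

Blood flow in an arteriovenous fistula or graft is the key patency metric
(guideline thresholds sit around 400–600 mL/min), yet the angiography suite
where access-salvage procedures happen has no image-based flow measurement.
`angioflow` implements the bolus-tracking approach: a radiopaque contrast
bolus is power-injected, its passage is tracked at two regions of interest
(ROIs) on the flight path, and volumetric flow follows from the transit
time, the traversal distance and the vessel cross-section.

## Method

For each ROI the *time-density curve* (TDC) `P(t)` is the spatial-mean
contrast intensity per frame, baseline-corrected over the pre-contrast
window (fluoroscopic sequences are sign-inverted so contrast is positive).
The transit time `τ` between the ROIs comes from one of two algorithms,
optionally applied to a fitted noise-free reference curve:

* **Peak-to-peak (PP)** — `τ = t(P₂)ₘₐₓ − t(P₁)ₘₐₓ`, the difference of the
  peak-intensity times.
* **Cross-correlation (CC)** — template matching:
  `φ(τ) = (1/N) Σₜ P₁(t)·P₂(t+τ)`; the maximizing non-negative lag is the
  transit time. Both run on a ×100 upsampled grid for sub-frame resolution.

Three reference-curve models suppress noise and recirculation:

* gamma variate `C(t) = Kₐ(t−AT)^α e^{−(t−AT)/β}`,
* lagged normal — a Gaussian `N(µ, σ²)` convolved with an exponential of
  rate `λ` (an exponentially modified Gaussian),
* 6th-degree polynomial (ordinary least squares).

The nonlinear fits minimize the RMS residual by a coarse parameter grid
followed by shrinking pattern-search refinement, with the linear scale
solved in closed form at every candidate.

Vessel geometry is read off the max-opacification image: row-wise
distance–intensity profiles every 25 px between the ROIs, sub-pixel edges
at 12% of the maximum opacification, centerline midpoints, traversal
distance as the centerline arc length, and the mean circular
cross-sectional area from the per-station widths. Flow is then

```
Q [mL/min] = Ā [cm²] × d [cm] / τ [s] × 60
```

The phantom simulator reproduces the bench protocol: 10 mL of contrast at
10/3 mL/s for 3 s after a 1 s delay, 8 s acquisitions at 3/6 frames/s (DSA)
or 4/10 pulses/s (fluoroscopy), straight/angular/loop tube configurations,
plug-flow advection with longitudinal dispersion, chord-length projection,
and modality-dependent noise. Agreement statistics (absolute percent error,
mean ± SEM with 95% CI, Bland–Altman bias and limits of agreement, Pearson
r, paired t test) complete the evaluation loop.

## Worked example

```sh
python examples/03_measure_flow.py
```

```
transit time:       0.422 s   (truth 0.406 s)
traversal distance: 14.35 cm
mean cross-section: 0.3035 cm^2 (truth 0.2827)
measured flow:      619.7 mL/min (truth 600)
quantification error: 3.29%
```

A 600 mL/min phantom imaged in DSA at 6 frames/s is measured with the
cross-correlation + gamma-variate pipeline to within a few percent: the
transit time is recovered to a fraction of the 0.167 s frame interval, and
the residual error is dominated by the edge-threshold area estimate.

The other scripts in `examples/` simulate a phantom
(`01_simulate_phantom.py`), fit the three reference-curve models to a TDC
(`02_fit_time_density_curve.py`), and benchmark algorithm/fit combinations
on paired ensembles (`04_compare_methods.py` — cross-correlation with the
gamma-variate fit comes out most accurate, peak-to-peak on raw curves
worst, matching the bench comparison).

A thin CLI wraps the same library:

```sh
angioflow simulate --shape loop --flow 600 --rate 6 --modality dsa --seed 42 --out phantom.npz
angioflow measure --input phantom.npz --roi1 104,121,120,137 --roi2 391,408,120,137 \
    --algorithm cc --fit gv --out result.json
angioflow evaluate --config grid.cfg --out-csv results.csv
```

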