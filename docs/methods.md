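# Methods

## Scope and model

`natsc` implements the measurement chain of an internal-reference tissue
sodium concentration (TSC) study of the prostate at 3 T, end to end, on
synthetic data with known ground truth:

1. **Phantom** — a labelled pelvic volume (peripheral zone PZ, transition
   zone TZ, a focal lesion, bilateral femoral blood vessels, muscle
   background) with one true TSC per compartment.
2. **Signal model** — steady-state spoiled signal at 90° excitation:
   `S = TSC · (1 − e^(−TR/T1)) · decay(TE)`, with monoexponential T2\*
   decay for blood and muscle and biexponential decay
   `w_f·e^(−TE/T2f) + w_s·e^(−TE/T2s)` for prostate tissue.
3. **Acquisition** — density-adapted 3D center-out radial k-space
   sampling (8000 spokes × 384 samples, TR/TE = 120/1.2 ms, 5.1 mm
   nominal resolution), 16 smooth complex receive channels, additive
   complex white Gaussian noise.
4. **Reconstruction** — per-channel Kaiser–Bessel gridding (width 4,
   Beatty β, 2× oversampling), analytic density compensation, optional
   radial Hanning taper, zero-filling factor 2 (2.55 mm output voxels),
   deapodization by the analytic kernel transform.
5. **Adaptive coil combination (ACC)** — per-block channel covariance,
   principal-eigenvector weights, global-reference phase anchoring,
   trilinear weight interpolation, magnitude of the weighted conjugate
   sum.
6. **B1⁻ correction** — low-pass-filter method: Gaussian-smoothed image
   (σ₁ = 10 voxels, 41-voxel kernel) divided by the Gaussian-smoothed
   support mask (σ₂ = 20 voxels, 81-voxel kernel) gives the receive-bias
   map; the image is divided by the map.
7. **Quantification** — trilinear resampling to the anatomical grid,
   metric erosion of ROI masks (WP/TZ 5.2 mm, PZ 2.6 mm, lesions and
   mirrored contralateral regions none, vessel references none),
   single-point linear calibration through the origin from the pooled
   femoral-blood-vessel (FBV) ROIs assuming blood TSC = 81 mM, per-ROI
   relaxation-factor correction, per-ROI mean/SD/count plus left–right
   reference-stability metrics.
8. **Statistics** — paired two-tailed t-test, Pearson correlation,
   one-sample KS normality check, Cohen's d for paired designs, and
   noncentral-t power / sample-size machinery
   (`df = n−1`, noncentrality `d·√n`).

## Key parameters and defaults

| Parameter | Default | Why |
|---|---|---|
| TR / TE / flip | 120 ms / 1.2 ms / 90° | clinical sodium protocol |
| Spokes × samples | 8000 × 384 | protocol; 16 min at TR 120 ms |
| Nominal resolution | 5.1 mm iso | protocol; k_max = 1/(2·5.1 mm) |
| Zero-fill | 2 | 5.1 → 2.55 mm apparent voxels |
| Ramp fraction | 0.25 | density-adapted readout; exposed, not restated in the protocol |
| Blood T1/T2\* | 31.9 / 20.1 ms | in-vivo blood sodium relaxometry |
| Prostate T1, T2f, T2s | 38.8, 6.8, 14.8 ms | in-vivo prostate sodium relaxometry |
| Fast fraction w_f | 0.6 | standard tissue sodium fast fraction; not stated with the T2 values |
| Muscle T1/T2\* | 29 / 13 ms | literature-range choice for the background |
| Blood reference TSC | 81 mM | assumed reference concentration |
| Compartment TSC | PZ 40.7, TZ 37.5, lesion 32.2, muscle 20 mM | cohort means used as simulation truth |
| Erosions | WP/TZ 5.2, PZ 2.6, lesion/contra/FBV 0 mm | partial-volume control bound to ROI role |
| ACC block | 8³ voxels | method cited without parameters; covariance well-conditioned at 512 voxels/block |
| B1⁻ filters | σ₁=10/41, σ₂=20/81 voxels | protocol values |
| B1⁻ threshold | Otsu on the smoothed image | threshold value unstated; `fraction_of_max` exposed |

The phantom geometry (64³ at 2.5 mm) was fixed once, from anatomy and
measurability, before any end-to-end test existed: a 59 cm³ gland
(plausible for an elderly, PSA-elevated cohort), a posterior-crescent PZ,
a PI-RADS-5-sized lesion (18 × 14 × 12 mm) abutting the capsule — where
posterior PZ tumours typically sit, and where its two partial-volume
leak terms (from brighter PZ and darker surroundings) partially cancel —
a mirrored contralateral region, and 22 mm-calibre iliac-femoral vessels
whose 8 mm-diameter central reference ROIs sit on the flat part of the
band-limited lumen profile. The anatomy is embedded in a 76 mm-radius
muscle body (20 mM) surrounded by air: the B1⁻ method's thresholding
step reconstructs the body envelope, so a phantom without an air class
makes that stage imprint anatomy into the correction map instead of the
body shape.

## The Hanning taper and the two-pass quantification

A radial Hanning window before gridding suppresses noise and Gibbs
ringing at the cost of roughly doubling the point-spread-function
main-lobe width. Both faces matter here:

* Inside the high-contrast vessel lumen (blood 81 mM vs ~20 mM
  surroundings) the *untapered* reconstruction rings: the reference-ROI
  mean oscillates by ±8% as a function of vessel calibre. The tapered
  reconstruction is ringing-free (reference bias < 0.1% in the noiseless
  phantom).
* Across a 2.6 mm erosion margin the tapered point-spread function leaks
  ~26% of a step edge, biasing small prostate ROIs (PZ, un-eroded lesion
  and contralateral regions) by 5–10%; the untapered reconstruction
  keeps these within ~2%.

The default pipeline therefore reconstructs twice from the same k-space:
the FBV calibration is read from the tapered pass, tissue ROIs from the
untapered pass. ACC weights and the B1⁻ map are estimated once (on the
tapered pass) and applied to both, and the reconstruction's amplitude
convention makes a single calibration slope valid for both images.
`quantify.two_pass_reference: false` restores the classical single-image
pipeline with whatever taper `recon.hanning` selects.

## Numerical choices

* Forward simulation: exact non-uniform DFT when
  `n_samples × n_support ≤ 2·10⁸`, otherwise a type-2 Kaiser–Bessel NUFFT
  (relative accuracy ~10⁻³, validated against the exact transform).
  Kernel lookups use a 4096-point table; k-space indices wrap
  periodically (the spectrum of a discrete image is periodic).
* Density compensation is analytic from the radial law
  (r² dr/dt per sample, solid angle 4π/n_spokes), normalised so the
  weights sum exactly to the k-ball volume; the radial law matches value
  *and* slope at the ramp junction so the volume element is continuous.
* Deapodization divides by the analytic separable kernel transform,
  floored at 10⁻⁶ of its maximum.
* ACC eigenvector phases are anchored to one volume-wide reference
  channel (the channel with the largest total weight); a per-block
  anchor would break phase consistency between interpolated blocks.
  Zero-variance blocks fall back to uniform weights with a logged
  warning.
* `normalize_map` rescales the B1⁻ map so the corrected image preserves
  the mean intensity inside the thresholded mask.
* Erosion thresholds the exact Euclidean distance transform computed
  with the physical voxel spacing (`edt > distance`).
* Safe division in the B1⁻ map uses ε = 10⁻⁶ · max(M_LP).
* The single global seed fans out to per-stage child seeds through a
  CRC-keyed `SeedSequence`, so stages are reproducible standalone.
* Noise level for a requested interior SNR is calibrated at run time by
  reconstructing one channel of unit-variance noise and measuring the
  image-domain level inside the target mask.

## What the generator emulates — and what it does not

The phantom reproduces the acquisition geometry, relaxation weighting,
receive-field structure, thermal noise and partial-volume physics of a
pelvic sodium examination. It does **not** model B0 off-resonance, T2\*
decay during the readout, motion, intra-compartment TSC heterogeneity
(truth is piecewise constant), sub-voxel boundary mixing (labels are
rasterised at voxel centres), inter-patient anatomical variability, or
segmentation error. Passing recovery tests therefore demonstrates that
the *processing chain* is unbiased at realistic geometry and SNR; it
does not certify accuracy on patient data, where those unmodelled
effects (and the ±2 mM systematic uncertainty of the blood reference
itself) dominate the error budget.

## Statistical conventions

Power uses the noncentral t-distribution exactly; sample-size search is
the smallest integer n ≥ 2 whose power reaches the target. With the
study's printed inputs this machinery reproduces the printed
retrospective power (73.7% at d = 0.99, n = 9, within rounding), the
80%-power sample size (11), the medium-effect sample size (34) and the
>99% secondary power — but yields **13**, not "approximately 15", for
90% power at d = 0.99 (confirmed against R's `power.t.test`). The
package reports the computed value. The KS normality check defaults to
sample-estimated reference parameters (a Lilliefors-style usage; the
classical p-value is then conservative in the usual sense), with fixed
parameters available.

## Known limitations

* The gridded forward model's ~10⁻³ accuracy bounds how precisely the
  noiseless pipeline can be validated end to end; the dominant residuals
  in the recovery tests are partial-volume physics, not interpolation.
* ACC assumes identity noise covariance (true in simulation); no noise
  prewhitening from a separate scan.
* Registration supports rigid translation + resampling only.
* The reported problem sizes (64³ phantom at 2.5 mm, full 8000 × 384
  sampling for the main run; reduced spoke counts in unit tests) are the
  package's test conditions; larger grids use the same code paths via
  the gridded forward model.
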