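# Methods

`gelqa` models a Gamma Knife quality-assurance experiment in which the same
single-shot irradiation is measured three ways — polymer-gel dosimetry read
out by MRI, radiochromic film read out by a flatbed scanner, and the
treatment-planning reference — and the readouts are compared by profile
width (FWHM) and by per-isodose structural similarity. This note records
the models, their parameters, and the numerical choices, in that order.

## Reference dose field

A single shot is modelled as a radially symmetric flat top with
error-function penumbra,

    D(r) = A · ½ [erf((R − r)/(σ√2)) + erf((R + r)/(σ√2))] / f(0),

where `σ` is the penumbra scale (`penumbra_sigma`, default 1.0 mm), and the
flat-top half-width `R` is solved numerically (Brent's method) so that the
profile's FWHM equals the collimator's nominal width exactly: 6.2, 11.3 and
19.8 mm for the 4, 8 and 16 mm collimators. The amplitude `A` places
`prescription_dose / prescription_isodose` at the shot center — with the
usual Gy@50% prescription, twice the prescribed dose. Multiple shots
superpose additively. Output factors (0.814 / 0.90 / 1.00) and dose rate
(2.52 Gy/min default) enter only the beam-time bookkeeping; they do not
rescale the normalized field shape. The profile shape is an idealization:
it reproduces the flat-top-with-penumbra character of planning-system
profiles and has an analytically controllable FWHM, but it is not a
source-geometry calculation (no 192-source sector model, no tissue
attenuation term).

## Gel forward model (MRI)

Absorbed dose raises the transverse relaxation rate of the nPAG gel. The
dose response is linear-then-saturating, modelled as a saturating
exponential

    R2(D) = R2₀ + s·R2₀·D_sat·(1 − exp(−D/D_sat)),

with `R2₀ = r2_baseline` (default 10 s⁻¹, i.e. T2 = 100 ms; a free
parameter — plausible for a gelatin matrix at 1.5 T, not a measured
value), `s = sensitivity` the slope of the *normalized* response
(R2 − R2₀)/R2₀ per Gy (default 0.084 Gy⁻¹, the R2-based gel sensitivity),
and `D_sat = saturation_dose` (default 100 Gy) the dose scale of the
saturating regime. With this default the response droops ≈5% at 10 Gy —
visually near-linear over the calibration range with saturation tendencies
appearing toward its top, and a full-range linear fit recovers ≈0.95 of the
configured slope (an analytically derived property of the model, visible in
the worked examples).

The spin-echo signal is mono-exponential, `S(TE) = s0·exp(−R2(D)·TE)`
(`s0` default 1000 signal units), sampled at the two echo times of the
evaluation protocol, TE 89 and 145 ms. Magnitude noise is Rician —
independent Gaussian noise of SD `noise_sigma` on the two quadrature
channels followed by the magnitude — which is the correct noise family for
magnitude MR images and reduces to additive Gaussian at high SNR. The
generator does not model B1 inhomogeneity, slice-profile effects,
susceptibility distortion, multi-exponential relaxation, or gel aging
between irradiation and scan; passing tests therefore certify the analysis
chain, not those acquisition physics.

## Film forward model

Net optical density saturates exponentially,
`OD(D) = OD_sat·(1 − exp(−D/D_c))`, so the low-dose sensitivity is
`OD_sat/D_c`: defaults OD_sat = 1.0, D_c = 10 Gy give 0.100 Gy⁻¹ (the
RTQA2-like film); the EBT3 variant uses D_c = 1/0.101. Saturation is
visible from roughly 4 Gy upward, well before the gel's. Pixel values
follow `PV = pv0·10^(−OD)` (pv0 default 40000 of a 16-bit range) with
additive scanner noise, clipped to [0, 65535]. Scans carry 1200 dpi pixel
spacing (25.4/1200 ≈ 0.0212 mm). Post-irradiation darkening over time is
not modelled.

## Two-point R2 mapping

`R2 = ln(S(TE1)/S(TE2)) / (TE2 − TE1)`, echo times converted from ms to
seconds, evaluated per voxel. Voxels with either signal at or below the
signal floor are masked invalid (NaN) and never raise. The default floor is
3× an estimated background noise SD; the estimate uses wavelet-based noise
estimation so smooth dose structure is not mistaken for noise. Echo order
is normalized internally, so a swapped pair yields the identical map.
Normalization to `(R2 − R2_ref)/R2_ref` uses the mean over a user-supplied
zero-dose reference region and is refused on an already-normalized map.
Only the two-echo evaluation is implemented; multi-echo exponential fitting
is out of scope.

## Calibration

Sensitivity is the slope of a weighted least-squares line through
(dose, response) points with dose at or below `linear_max_dose`. Weights
are 1/SD² when every point carries a positive SD (covariance then taken
unscaled, the SDs being trusted); otherwise the fit is unweighted with
residual-variance-scaled covariance. Doses are recorded in the Gy@50%
prescription convention with the total center dose stored alongside; the
fitted slope is per Gy on that axis, which is also the axis the forward
models use.

Automatic linear-range detection walks the candidate bounds
{40, 20, 10, 8, 4} Gy from the top and keeps the largest whose data show no
significant lack of fit against a saturating-exponential alternative at
α = 0.05. With trusted SDs the comparison is a chi-square difference test
(Δχ² on 1 dof between the two weighted SSEs); without SDs it is a
nested-style F-test on residual SSEs. The Δχ² form was chosen because at
calibration-sized samples (n ≈ 6) the F-test has too little power to flag
even a many-sigma droop, while the known-variance chi-square retains its
nominal level and detects the bend reliably. If the saturating fit cannot
be computed (fewer than 4 points, or no convergence), lack of fit cannot be
demonstrated and the bound is accepted.

Inversion is `(response − intercept)/slope`; doses above the linear bound
are returned but flagged saturated, negative doses are clipped to zero and
flagged. The delivered-dose chamber correction is a single scalar factor
`(1 + δ)` applied to nominal doses (δ configurable, default 0, with the
sub-percent band of routine chamber checks in mind).

## Dose-map reconstruction and isodose rendering

Reconstruction is per-voxel curve inversion; invalid response voxels stay
invalid, geometry passes through unchanged, and the curve's response-kind
tag must match the map's (a film-OD curve cannot invert a gel R2 map).
Isodose labels assign each voxel the highest level (% of the robust
maximum) it reaches, so bands are nested by construction. The robust
maximum is the 99.5th percentile of dose *within the half-maximum core*
rather than of all voxels: a plain percentile over the whole volume
collapses for a point field surrounded by background, while the core
percentile still ignores single-voxel noise spikes and preserves the peak
of smooth fields.

## Profiles and FWHM

Profiles sample the line of voxel centers nearest the requested
stereotactic point (no transverse interpolation), optionally normalized to
a 100% peak. The half level is half the observed peak sample (ties broken
leftmost, for determinism); each crossing is linearly interpolated between
the bracketing samples moving outward from the peak, and a profile that
never falls below half maximum on a side is rejected as truncated. Against
the analytic field this estimator converges as the grid refines: errors of
about 4×10⁻³, 3×10⁻⁴ and 6×10⁻⁵ mm at 0.5, 0.25 and 0.125 mm spacing for
the 6.2 mm field.

Deviation against the reference width is `100·|ref − meas| / denom`,
reported to one decimal. The denominator convention is an explicit
parameter because published QA tables are not consistent about it — some
entries divide by the reference width, others by the measured one — and the
QA report therefore prints both. Penumbra (80–20%) widths are not
computed.

## Similarity scoring

Alignment is an exhaustive integer-pixel normalized cross-correlation
search (default radius a quarter of the image, keeping ≥25% overlap),
returning the displacement of the moving map; it is deterministic and
inverse-consistent, with ties broken toward the smaller shift. This
replaces the feature-matching style of alignment sometimes used for
phantom imagery: for rigid phantom geometry a translation search is
sufficient and has no stochastic component.

Segmentation thresholds the normalized (0–100%) map at the requested
levels into nested bands (default levels 90/80/70/60/50/30/10%) and
computes a Sobel gradient-magnitude edge image with the standard
unnormalized 3×3 kernels and reflected boundary (a unit step yields
magnitude 4).

SSIM uses the standard Gaussian-window formulation — window 11, σ = 1.5,
C1 = (0.01 L)², C2 = (0.03 L)² with L the dynamic range (100 for
normalized dose maps), population (not sample) covariance — computed as a
full local map and averaged globally and within each band. The
radiosurgical range is operationalized as the ≥50%-of-Dmax region and the
radiotherapeutic range as 10–50%; the split is a definition of this
package, not a measured quantity.

## Pipeline, determinism, and problem sizes

`run_qa_pipeline` merges a partial config over documented defaults
(unknown keys are rejected by name), draws all randomness from one seeded
generator, and emits a QAReport whose JSON/CSV payloads are byte-identical
across runs of the same config (DICOM outputs derive their UIDs from
content for the same reason). A method's pass flag requires its worst FWHM
deviation across collimators and conventions to stay within the threshold,
default 5%, the customary clinical limit.

Default problem sizes are chosen desk-scale: a 25 mm half-extent sagittal
grid (2.5 mm slices along X, 0.5 mm in plane — profiles along Z therefore
live at 0.5 mm), 3×9×9-voxel calibration cuvettes, and 200-replicate
recovery studies; a full three-collimator run completes in a few seconds.
Cuvette calibration simulates uniformly irradiated patches rather than full
shot fields, matching the broad-field irradiation of a small ROI at the
focus.

## Known limitations

- The gel and film saturation laws are single-exponential conveniences;
  real dosimeters need not follow them outside the calibrated range.
- Absolute dose above the linear range is flagged, not trusted; the
  mapping stage is a relative-distribution tool there.
- The reference field is analytic; agreement with it validates the
  analysis chain, not a planning system.
- DICOM signals are quantized to uint16 on write (≤0.05% of the default
  s0), so float round-trips are exact only for integer-valued signals.
- Alignment is integer-pixel and translation-only; rotations and sub-pixel
  shifts are outside scope.
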