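# Models and methods

This note records the models behind the simulator and the analysis
estimators, the defaults and why they were chosen, the numerical choices
that matter, and what the synthetic validation does and does not show about
real data.

## Illumination fields

Sample-plane excitation is parameterized directly, not derived from beam
optics — every downstream quantity depends only on the sample-plane field.

* Gaussian: `I(r) = I_0 exp(−r² / 2σ²)`.  The width is set by the
  *edge ratio* — the intensity at the field-of-view edge midpoint relative
  to the center — with closed form `σ = (w/2) / sqrt(2 ln(1/ratio))` for FOV
  side `w`.  Default ratio 1/3, matching the roughly three-fold center-to-edge
  drop typical of large-FOV Gaussian TIRF.
* Flat-top: super-Gaussian `I(r) = I_0 exp(−2 (r/R)^{2n})` with plateau
  radius `R` (default `0.9 w`, covering the FOV corners) and edge order
  `n = 20`.  The plateau is flat to <1% over `r ≤ 0.8 R` for `n ≥ 12` and
  approaches an ideal disk as `n → ∞`.  Equal-power comparison between the
  two profiles is done by matching the radially integrated power
  (`2π ∫ r I(r) dr`, numerically to 1e−6 relative); the resulting
  flat-top-mean-over-FOV to Gaussian-peak ratio is reported as a diagnostic.

Intensities are in arbitrary units; all photon calibration lives in the
emission model.  Evanescent-depth, polarization and aperture effects are out
of scope.

## Binding kinetics and photobleaching

Each docking site is an alternating renewal process: dark intervals
`Exp(k_on · c)`, bright intervals `min(Exp(k_off), Exp(k_b · I))` with the
bleach draw flagged.  Every event uses a fresh dye, so bleaching truncates
individual events rather than depleting sites.  Expected bright time is
`1/(k_off + k_b I)`; under Gaussian illumination this varies radially,
which is the mechanism behind bright-time broadening and species confusion.

Defaults (study conditions, chosen once): exposure 100 ms; `k_off = 2 s⁻¹`
(mean bright time 0.5 s, typical of a 9-nt docking strand);
`k_on = 2×10⁶ M⁻¹s⁻¹` at 5 nM imager (on-rate 0.01 s⁻¹, mean dark time
100 s per site); bleaching off unless a scenario enables it
(`k_b` in s⁻¹ per intensity unit).  Bright times are reported uncorrected
for frame discretization; linking consecutive frames biases the mean by up
to about half a frame, which is negligible at 5 frames per mean event.

## Emission, camera, and the fast localization path

A full frame at intensity `I` yields `Poisson(ψ · I · t_exp)` detected
photons (`ψ` defaults to 150,000 photons·s⁻¹ per intensity unit: 15,000
photons per 100 ms frame at the profile peak).  The rendered path deposits
an integrated-pixel Gaussian PSF (σ = 130 nm = 1 pixel) per active emitter,
adds excitation-proportional background, Poisson shot noise, Gaussian
readout noise, gain and baseline, and writes 16-bit frames.

The fast path skips rendering: each event contributes one localization per
overlapped frame (frames with exposure overlap < 0.3 are dropped, mimicking
detection loss on clipped events), with position error drawn isotropically
at `σ_loc = 1.4 · psf_sigma / sqrt(N)`.  The 1.4 excess factor is a
configurable stand-in for the background-dependent correction to the
photon-limited bound; the analyses validated here depend on linearity and
recovery, not on the exact constant.  Emitters active in the same frame
closer than `2.5 · psf_sigma` are merged into one localization carrying the
pooled photons at the photon-weighted centroid — reproducing what a
single-emitter fitter does — with the true emitter count kept as ground
truth.  On a common small scene the two paths agree in localization counts
(±10%) and photon means (±5%), which is the license for using the fast path
in the large benchmarks.

## Spot detection and fitting

The net gradient of pixel `p` sums, over a box (default 7 px), the
central-difference image gradients at the box pixels projected onto the
unit vectors pointing toward `p`.  Flat background cancels; a PSF-shaped
spot scores its summed inward gradient flux.  Detection takes local maxima
above a *fixed global threshold* with non-maximum suppression — fixed by
design, because the radial decay of this score under a Gaussian beam is
precisely the detection-loss mechanism being quantified.  Candidates are
fitted by Poisson maximum likelihood with an integrated-pixel 2D Gaussian
(sub-pixel x/y, photons, per-axis widths, uniform background), optimized
with L-BFGS-B on log-scaled amplitude parameters; rail-pinned or
non-converged fits are discarded, and duplicate fits within 1 px are merged
keeping the brighter.  Pixel convention: a localization at the center of
pixel `(i, j)` has `x = j + 0.5`, `y = i + 0.5`.

## Segmentation, picks, kinetics QC

Structures (not localizations) are ranked by distance from the beam center
and split into K = 5 rings of equal count (ranks `[⌊kN/K⌋, ⌊(k+1)N/K⌋)`,
ties by input order; boundaries at midpoints).  Localizations inherit their
structure's ring.  Picks assign localizations to the nearest structure
center within 143 nm.  Event linking bridges gaps of `max_dark_frames`
(default 0 — conservative, and all bright-time conclusions here are ratios
or qualitative); events touching the acquisition boundaries are censored
and excluded from distribution fits.  Temporal QC passes a pick when its
mean localization frame is within 0.2·n_frames of the midpoint and its
frame std exceeds 0.15·n_frames (a uniform arrival pattern has
std = 0.29·n_frames); both thresholds are config values.  Kinetic species
separation fits a two-component Gaussian mixture to log per-pick mean
bright times and flags non-separable outcomes by BIC against a single
component, Ashman's D < 2, or a vanishing weight.

## Photon-mixture filter

The per-frame photon histogram (Freedman–Diaconis bins) is fitted with two
Gaussians, initialized at the histogram mode and twice the mode.  A second
component is only accepted if it carries ≥1% of the first component's area
*within the histogram support* — a component pushed outside the data range
is unconstrained, not a peak.  The filter removes localizations above
`mu_1 + 2 sigma_1`, the upper abscissa where the single-emitter peak falls
to 1/e² of its height; in simulation the removals are cross-tabulated
against the true emitter count.

## NeNA

Distances between each localization and its nearest neighbor in the
following frame within the same pick follow, for the same molecule,
`p(d) = d/(2σ²) · exp(−d²/(4σ²))` (mode at `σ√2`).  The histogram is fitted
with that term plus a broad Gaussian (nearest distinct site) plus a linear
term, weights free; the same-molecule σ is the reported precision.

## Particle averaging and spacing fits

Picks are aligned to a model image of the designed site pattern by
exhaustive rotation search (1° steps over 360°/symmetry; 180° symmetry for
the rectangular grids) with translation from FFT cross-correlation of
40×-oversampled histograms (3.25 nm bins), sub-bin refined by parabolic
interpolation; the model is then rebuilt from the aligned average and the
loop repeats (≤10 iterations).  Convergence is judged on the discrete part
of the transforms — integer-bin shifts and rotation steps — because the
sub-bin refinement jitters at the noise floor of the re-histogrammed model;
near-tie rotations keep the current angle to avoid oscillation.

Spacing fits operate on the pooled aligned *localizations* (statistically
more efficient than fitting the rendered image): a two-Gaussian fit to the
coordinate histogram across the two central site columns returns the
peak-to-peak distance, per-peak σ, and the midpoint dip; "resolved" means
dip ≥ 20%.  Degenerate fits (peaks closer than 0.3 pitch, vanishing
amplitude, or R² < 0.5) raise instead of returning nonsense.

**Rod phantoms.**  Labels sit at uniform azimuth on a cylinder surface, so
the projected transverse density is the arcsine-type
`∝ 1/sqrt(R² − y²)` blurred by the localization error.  A plain
two-Gaussian fit on this geometry is structurally biased inward: the
inter-rail density pulls the least-squares optimum to ~2/3 of the rail
separation regardless of binning or weighting (the package's tests document
this).  The rod analysis therefore fits the blurred circle-projection model
itself (amplitude, radius, blur) and reports the rail separation `2R̂`,
which recovers the designed geometry without bias; the two-Gaussian result
is returned alongside for comparison.

## Validation scope and problem sizes

The benchmark scenarios use 220–260 structures on a 512-px (66.6 µm) field,
3,000–4,000 frames, via the fast path; the rendered-path tests use ≤64-px
crops.  These sizes are the smallest at which the estimators are stable —
spacing fits to ±0.1 nm, NeNA to ±0.05 nm — and keep a full run in tens of
seconds.

The generator reproduces the statistical structure the analysis assumes:
Poisson photon statistics proportional to local intensity, competing
exponential unbinding/bleaching, diffraction-limited merging of
simultaneous emitters, and uniform structure placement.  It omits drift,
sCMOS pixel-dependent noise, dipole emission, 3D PSFs, aperture-induced
peripheral resolution loss, and heterogeneous structure quality.  Passing
parameter-recovery tests therefore demonstrates that the estimators are
correct and unbiased under the modeled physics, not that real acquisitions
meet these assumptions; on real data the same pipeline requires
drift-corrected localizations and a picker in place of the ground-truth
structure assignment.
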