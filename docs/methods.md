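# Methods

This note documents the models behind `memquant`, the defaults and why they
were chosen, what the synthetic data do and do not emulate, and the numerical
decisions that matter for reproducing its outputs.

## Coordinate and unit conventions

All axial positions are nanometers, positive from the coverslip into the
sample; micrometers appear only in presentation. Images are `(row, col[,
channel])` with 0-based indices. Profile coordinates are re-indexed to start
at x = 1 at the intracellular edge of the ROI so the sigmoid argument
`(x/C)^B` is always positive; every fit records this convention. "Reported"
positions are raw stage readouts; "calibrated" positions are reported
displacements multiplied by the axial calibration factor.

## Stage model

A motorized objective stage with three error terms:

- **Axial scale factor** (default 1.17): true focal displacement per unit
  reported displacement. The generator applies it when rendering bead
  z-stacks; the calibration module estimates it back.
- **Backlash** (default 150 nm): drive-train play. The model keeps an
  engagement state in `[0, backlash]`; a move first takes up remaining play
  in its direction, so the first move after a reversal undershoots by up to
  the full backlash while repeated small same-direction corrections ratchet
  the drive back into engagement. This reproduces both the characteristic
  post-reversal undershoot and the realistic behavior of micro-corrections
  after a reversal (a fixed-undershoot model would deadlock the correction
  loop whenever corrections are smaller than the backlash). The magnitude is
  not printed anywhere; 150 nm is typical of a geared microscope focus
  drive.
- **Thermal drift**: deterministic ramp (default 200 nm/min, chosen so the
  ten-minute protocol accumulates ~2 µm uncompensated) plus a Gaussian
  random walk (default 5 nm/√s, a minor stochastic component ~6% of the
  ramp over ten minutes).

The scan protocol (five z-scans over planes at 0/0.59/2.34 µm above a
baseline, 50 s between scans) is expanded into constant-target hold
segments; holds default to 27 s so the full protocol lasts ~10 min. The
controller runs at 1 Hz with a 5 nm deadband and proportional gain 1, and
corrects during settling as well as holds; the first two updates after each
move are labeled `moving` and excluded from repeatability statistics, since
there the measured-target difference reflects motion dynamics rather than
drift. None of the loop constants are prescribed by the experiment they
emulate; they are configuration with the stated defaults.

`uncorrected_drift` is defined per constant-target run as (change in
measured position) − (change in stage readout), summed over runs: in open
loop this is the accumulated drift, in closed loop the net compensation the
controller issued. Commanded plane changes fall between runs and are
excluded.

## Bead image formation (stand-in)

The reflected-light appearance of a coverslip bead is not modeled physically
(the real contrast mechanism — partial interference of LED light — is
undocumented for this geometry). The stand-in renders a bright rim of radius

```
r(dz) = sqrt(R² − dz²)          |dz| ≤ R      (spherical cross-section)
r(dz) = 0.7 · (|dz| − R)        |dz| > R      (defocus cone)
```

at defocus dz from the bead center, as a radial Gaussian of constant
thickness (1 px) whose amplitude decays as a Lorentzian in dz. Two properties
matter and are satisfied by construction:

1. **Inside the bead** the width-versus-z curve is symmetric and unimodal
   with its maximum at the equator, and the squared width is exactly
   quadratic in z — the basis of the calibration estimators.
2. **On the defocus cone** the ring radius is strictly monotone in dz, so a
   reference library recorded on one side of the bead gives an injective
   template-to-position mapping. Tracking simulations therefore operate
   2.3–7 µm above the bead center; near the cone apex (ring radius below
   ~1 px) neighboring templates are nearly indistinguishable and estimates
   degrade, which is a property of this stand-in, not of the method.

A sub-diffraction glass-surface impurity is rendered as an isotropic
Gaussian spot whose fitted amplitude peaks when the focus is at the surface,
with defocus widening.

Default imaging constants: 250 nm pixels, peak bead amplitude 1000 counts,
background 20 counts, Poisson noise (reflected LED imaging is bright;
two-photon fluorescence detection is shot-noise dominated, so Poisson is the
default noise everywhere).

## Calibration estimators

Frame widths come from the symmetric double-Gaussian fit
`bg + a[G(x−c+d) + G(x−c−d)]` (shared amplitude and width; width = 2d),
applied to horizontal and vertical center-line profiles and averaged;
disagreement > 2 px flags the frame. Initial guesses are moment-based;
non-convergence yields a flagged NaN sample, never an exception mid-stack.

The equatorial plane is the vertex of a least-squares parabola through the
*squared* widths over the rim region (samples above half the maximum width).
For a spherical bead w² is exactly quadratic in z, so this is the
exact-model form of parabolic peak refinement; a 3-point parabola on the raw
width curve would be dominated by single-sample noise because the curve is
locally flat at the equator (curvature ~1/R). Near rim collapse the two
Gaussian lobes of the width fit overlap and bias d downward; the half-maximum
selection excludes that region, and because the rim model is symmetric the
residual bias is symmetric in z and cancels in the vertex. The glass surface
uses a windowed parabola (±10 samples) over the fitted impurity amplitudes.

Method 1: factor = R / |center − surface| (reported nm). Method 2: factor =
|R_a − R_b| / |center_a − center_b|. Both recover factors in {1.0, 1.1,
1.17, 1.3} to ≤2% (median over 10 Poisson seeds) on the default scene and
agree within 3%.

## Reference-library tracking

Templates are background-subtracted bead ROIs at uniform calibrated spacing
(nominal 23 nm over 4.68 µm → 204 templates), selected nearest-frame from a
source z-stack; the benchmark library source is commanded directly at 23 nm
calibrated spacing. The similarity metric is zero-normalized
cross-correlation (insensitive to illumination drift and offset), behind an
interface so alternatives can be swapped. The best match is refined by a
3-point parabola over the score curve, clipped to ±half a spacing; an exact
template match returns the grid position exactly. Peak score < 0.5 raises a
bead-lost error, which truncates a running trace with a flag.

Under the default conditions the closed-loop protocol yields hold-phase RMS
errors of ~16 nm (seed-to-seed 15–17 nm), dominated by per-update drift
(~6 nm), estimation noise (6–13 nm depending on plane), and the deadband.

## Cell time series

The cross-section image of each protein is built row-wise from the profile
models, with the membrane column following a parabolic bowing across rows
(quantized to whole pixels so integer re-alignment inverts it exactly — a
deliberate idealization that lets noiseless end-to-end runs recover ground
truth to numerical precision). Recruitment kinetics: a fraction
`φ(t) = φ_max (1 − e^(−t/τ))` (φ_max = 0.5, τ = 18 min) of the cytoplasmic
pool `(U0 − L)·C` transfers to the membrane Gaussian, conserving the total
by construction. The protocol default is 14 scans at 5-minute intervals with
two untreated scans (times −10 and −5 min) and agonist at t = 0.

Emission spectra are two-sided Gaussians peaked at 508 nm (mEGFP-like,
narrow blue edge, broad red tail) and 529 nm (mCitrine-like), sampled on 16
channels over 450–600 nm and normalized to unit sum. Per-pixel composites
are abundance-weighted sums with Poisson noise. The basolateral plane is a
uniform receptor field plus post-treatment puncta (a subset co-placed in the
arrestin channel) whose amplitudes grow with φ(t).

Not emulated: vesicle trafficking beyond an optional planted blob (used to
exercise the row-exclusion rule), photobleaching, cell motion, membrane
roughness beyond smooth bowing, detector gain/readout structure, and
spectral bleed beyond the linear mixing model. Passing tests therefore
demonstrate correctness of the estimators under the stated models, not
robustness to every real-data pathology.

## Profile quantification

Per-row peaks are located in the receptor channel; a row is excluded when
its peak column deviates from the rolling median (window 5) of neighboring
rows by > 3 px or its peak intensity exceeds 3× the median row peak (vesicle
signature); manual exclusions are also accepted. The aligned column µ is the
median of included peaks (ties toward the lower column). The same shifts and
exclusions are applied to the arrestin channel; vacated pixels are missing
(never wrapped) and are dropped from profiles and fits rather than imputed.

Fits use bounded trust-region least squares (tolerances 1e-12, ≤ 5000
evaluations). Receptor: `f(x)` with µ fixed, A ≥ 0, σ ∈ [0.1, W]; a fit
whose σ reaches the window scale is flagged degenerate. Arrestin: `f + g`
with µ fixed; initial values L/U from the profile tails, C from the first
crossing of the plateau midpoint, B = 8, σ = 2 px; C is fitted freely on
untreated frames, averaged, and then held fixed for the series. A fitted
U < L is flagged, not raised.

Because the aligned µ is the median peak column, the aligned-frame sigmoid
inflection is the generator's C plus the alignment offset (µ_aligned −
µ_truth); recovery tests compare in the aligned frame.

Concentrations are `Aσ√(2π) / (ε_proto · area factor)`. The dilution-series
slope Θ (a.u./µM) is converted to per-number-density units (1 µM =
0.60221 molecules/µm³) inside `epsilon_proto`, so ε carries a.u. per
molecule; since I_Gauss is in a.u.·px, the resulting concentrations are
relative (consistent across a series, absolute only if ε and the area factor
carry absolute units — no units are asserted for the final series, and all
outputs echo their unit bookkeeping). The PSF is the 3D Gaussian
`exp(−2(x²+y²)/w0² − 2z²/wz²)` with defaults w0 = 300 nm, wz = 900 nm
(plausible for a 1.2-NA water-immersion two-photon system); its squared
integrals have closed forms (volume π^{3/2}w0²wz/8, area factor πw0wz/4)
used to validate the trapezoidal quadrature (extent 5 waists, refinement by
grid halving to < 0.1%). The area factor in the concentration formula is the
2D integral over the plane through the focus.

Trend fits on the concentration series (receptor: ordinary least-squares
line; arrestin: third-order polynomial) are labeled guides to the eye, not
kinetic models.

## Problem sizes and determinism

Default simulation sizes: calibration stacks of 141 frames (20 nm reported
steps over −0.4…2.4 µm, bracketing the glass surface and both bead
equators); tracking runs of ~605 one-second updates against a 204-template
library; cell series of 14 scans at 188×128×16. All generators take explicit
seeds and are bit-reproducible; stochastic recovery statements are medians
over 10 seeds (2% for the calibration factor, 5% for profile parameters, 2%
for brightness).

## Known limitations

- The bead appearance model is a stand-in; estimation precision versus
  defocus depends on its shape gradients (weak near the cone apex and at
  extreme defocus, where pixelation limits noiseless accuracy to ~10–20 nm).
- The conserved-total diagnostic `Aσ√(2π) + (U−L)·C` treats C as the
  effective cytoplasm width; with C fixed from untreated frames the
  conservation check is exact only up to the fixed-vs-true C ratio (a ~1%
  effect at the defaults).
- Unmixing assumes exact, noise-free elementary spectra; crosstalk noise
  between the two spectrally close fluorophores amplifies per-pixel
  abundance noise (anticorrelated), which is why punctum ranking on single
  pixels is only reliable once puncta are well developed.
- The unconstrained/nonnegative unmixing choice is a config flag (default
  nonnegative); both branches are exercised in tests and recorded in output
  metadata.
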