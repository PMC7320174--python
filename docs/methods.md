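# Methods

This note records the models, conventions, parameter choices and known
limitations behind `zring`, in the order the pipeline runs.

## Synthetic ring movies

The generator renders a purely kinematic model of a treadmilling FtsZ
vortex: an annulus of radial Gaussian profile (σ_ring) whose azimuthal
intensity is cos²(π·s/p) along the arc length s, rigidly rotated at
angular speed ω = v/r. There is no filament-scale physics — no
nucleation, fragmentation or GTP hydrolysis — because the analysis being
validated measures only the ensemble pattern speed; a rotating pattern
with known v is exactly the ground truth it needs. cos² rather than cos
keeps the expectation non-negative, as a Poisson mean must be. The
period p is snapped to an integer fraction of the circumference so the
pattern closes smoothly at the 0/2π seam.

The image model is: expectation image → Gaussian PSF convolution →
photobleaching (exponential amplitude decay, ring only) and lateral
drift (applied to the center) → Poisson shot noise, optional additive
Gaussian read noise. A `noise=False` flag emits the expectation images
themselves, which the oracle tests sample directly.

Defaults, chosen once to represent the imaging conditions this kind of
reconstitution experiment runs under:

| parameter | default | rationale |
|---|---|---|
| pixel size | 65 nm/px | 6.5 µm sCMOS pixel behind a 100× objective |
| PSF σ | 110 nm | diffraction limit for 488 nm excitation at NA 1.49 |
| ring radius | 500 nm | ~1 µm vortex diameter |
| ring width σ | 100 nm | a few filaments wide, below the PSF |
| frame interval | 3 s | the faster of the two acquisition cadences used for such time-lapses (3 or 10 s) |
| frames | 120 | 6 min of imaging; ≥ 2 full 50-row analysis windows after edge trimming |
| pattern period | 600 nm → 628.3 nm | sub-resolution speckle is unrecoverable; a ~0.6 µm azimuthal texture survives the PSF with ~50 % contrast |
| speed | 35 nm/s | the wild-type chimera's mean rotational speed |
| peak / background | 200 / 20 photons | moderate-SNR TIRF; recovery degrades below ~150 |
| bleach rate | 5·10⁻⁴ s⁻¹ | ~10 % loss over the movie, typical for YFP under shuttered TIRF |
| drift | 0 nm/s | drift is exercised explicitly in the registration tests |

The simulator emulates shot noise, bleaching, drift and the PSF; it does
**not** emulate filament turnover noise, heterogeneous ring shapes,
neighbouring structures, or uneven illumination. Passing the recovery
tests therefore shows the estimator is correct and noise-robust under
the stated image model, not that segmentation-free analysis of crowded
fields of real rings would reach the same accuracy.

## Kymograph construction

* Ring definition: two user coordinates are read as the endpoints of a
  diameter (center = midpoint, radius = half distance). The two-point
  convention is ambiguous in principle; a center+edge mode is available
  behind `mode="center_edge"`.
* Angular sampling: n = round(2πr) samples, i.e. ~1 px arc length per
  column, so column units match pixel units and the "r ± 1 px"
  trajectories and 50-px windows are commensurate. Calibration is exact
  by construction: arc_step·n = 2πr·pixel_size.
* Sampling: bilinear interpolation (exact on affine images — used as a
  test oracle); the three trajectories at r − 1, r, r + 1 px are averaged,
  which suppresses noise and tolerates small circle-fit errors.
* Preprocessing: non-overlapping temporal block averaging (the 5–10
  frame "mean filter" convention; the frame interval scales by the
  window), and frame-0-referenced phase-correlation drift correction
  with sub-pixel refinement. A 3×3 spatial mean filter exists but is off
  by default.

## Fourier-phase slope estimation

Within each half-overlapping window of 50 time rows (stride 25, plus a
flush window at the end so trailing rows are analysed):

1. Per column, remove a **linear** trend over time. Mean removal alone
   leaves photobleaching decay, which concentrates spurious power in the
   lowest temporal bins of static rings; the linear detrend removes it.
2. FFT along time; the dominant temporal frequency is the argmax of the
   column-summed power over positive frequencies (ties → lowest
   frequency, preferring the fundamental).
3. The frequency is refined to sub-bin precision by direct evaluation of
   the column-summed periodogram on a fine grid spanning the two
   neighbouring bins (81 points, parabolic touch-up). Rectangular-window
   leakage is not parabolic in log-power, so interpolating the FFT bins
   is biased; the direct periodogram peaks at the true frequency and
   removes what would otherwise be a few-percent quantization error at
   the slowest speeds.
4. The per-column phase of the single-frequency DFT at f* is unwrapped
   along the cyclic column axis and fitted by least squares;
   slope = −2π f*/(dφ/dj) columns/row. The sign convention follows the
   e^{−2πi f t} transform and was validated against the simulator's
   closed-form kinematics and the brute-force search.

A window is **rejected** unless all of:

* dominant-power fraction ≥ 0.2 of total positive-frequency power;
* phase-fit R² ≥ 0.8;
* RMS phase-fit residual ≤ 0.5 rad — unwrapped noise phases form a
  random walk, which can fit a line with high R² while leaving ~1–2.5 rad
  residuals; true stripes leave ~0.1 rad, so this scale-free gate is the
  one that separates them;
* the total phase change around the ring is within 1 rad of 2πk for a
  **nonzero** integer k (a periodic ring pattern must wind an integer
  number of turns; k = 0 is what bleach trends and noise produce).

All four thresholds are configurable and reported per window. The ring
slope is the mean over accepted windows; no accepted window ⇒ "no
reliable slope", which classifies the ring static. A final |v| < 5 nm/s
gate (configurable) catches near-zero fitted slopes; in practice static
rings are caught by window rejection.

Savitzky–Golay smoothing (window 11 rows, order 2 — order is the
field's convention, window length our choice) runs per column before
CLAHE (clip 0.01, tile 16 px). The filter's half-window boundary
transient is trimmed from both ends of the time axis: those rows are
polynomial extrapolations and measurably bias the periodogram peak in
windows touching the kymograph edges (≈1 % speed bias before trimming,
<0.05 % after). CLAHE affects phase estimates only mildly because phase
is computed after detrending.

The independent cross-check, `estimate_slope_radon`, shears the
kymograph by candidate slopes (cyclic Fourier shift per row), scores the
variance of the time-averaged column profile, and refines the grid
argmax parabolically. It shares no code with the Fourier path and is
used in tests and the acceptance script as the oracle.

Measured performance under the default generator (20 seeds/speed): mean
absolute relative speed error ≲ 3 % over 15–45 nm/s, zero-speed rings
flagged static in 100 % of seeds.

## Velocity, diameter, classification

velocity = slope × arc_step / frame_interval (nm/s, sign = rotation
direction; summaries report |v|). Diameter: centroid-refined center,
angular-averaged radial profile at 0.25 px steps, argmax with parabolic
refinement, ×2×pixel_size; a profile with no interior maximum raises
(not a ring). Small rings carry a modest inward bias (~2–3 %) from PSF
blur and curvature, within the half-pixel tolerance used in tests.

## QCM-D

Sauerbrey conversion uses C = 17.7 ng cm⁻² Hz⁻¹ (5 MHz AT-cut crystal)
and divides raw overtone shifts by n (9 by default); a `normalized`
dialect flag handles exports that already store Δf/n, since instrument
software does either. The SLB check (plateau within 1 Hz of −25 Hz on
the normalized shift) finds the last rolling 30-sample window whose sd
is below 3× the baseline noise estimate, floored at 0.01 Hz so that a
noise-free exponential tail still counts as stable, and takes its
median. Binding shifts are plateau-minus-baseline medians (robust to
spikes). Fold changes are reported raw and display-rounded (integers
above 10-fold, one decimal below). No viscoelastic modelling: the
Sauerbrey relation assumes a thin rigid film, which is the convention
for protein monolayers on SLBs but underestimates soft, hydrated layers.

## GTPase assay

Standards: 1:2 serial dilution from 40 µM Pi plus a blank; OLS of
blank-subtracted absorbance on concentration. Samples: absorbance →
[Pi] through the inverted curve, initial rate by OLS over all seven
timepoints (0–120 s; no burst-phase exclusion, as none is defined for
this assay format). The stopped-well rate is multiplied by the 50/13
dilution factor (13 µL reaction quenched into 37 µL stop solution) —
exposed as a parameter since published rates do not always state whether
they correct for it. Turnover assumes 5 µM FtsZ. Negative fitted rates
are flagged, not clamped. Normalization divides by a supplied reference
rate; both raw and turnover scales are emitted.

## Statistics

Welch's t-test is the default two-sample comparison (the pooled variant
is behind a flag): with group SDs differing several-fold — 13 vs 6 nm/s
in the motivating comparison — the equal-variance assumption is not
defensible. `welch_t_from_summary` makes the test computable from
printed mean ± SD, n values; `welch_t_from_samples` is definitionally
the same test applied to sample summaries, and the two routes agree to
machine precision (property-tested). Quartiles use linear interpolation
between order statistics; notches are median ± 1.58·IQR/√n.

## Numerical choices and degenerate inputs

* All randomness flows from explicit integer seeds
  (`numpy.random.default_rng`); the pipeline derives per-stage seeds
  from one root seed by SHA-256, keeping them below 2³¹.
* Constant frames in drift correction produce zero shifts and a logged
  warning; constant kymographs preprocess to a constant (a ≤1e-9
  relative ptp is treated as constant to avoid amplifying float dust).
* Vertical manual lines (equal time rows) are rejected — the stripe
  slope is undefined.
* Trajectory samples falling outside the image raise immediately rather
  than extrapolate.
* Demo/analysis problem sizes (64×64 px, 120 frames, 20 seeds per
  condition) were chosen so the full validation battery runs in seconds
  while leaving ≥2 independent analysis windows per ring and ~5 %
  statistical resolution on detection rates.

## Known limitations

* The slope model assumes a single coherent rotation; counter-rotating
  or incoherent multi-filament rings would yield split spectral peaks
  that the dominant-frequency reading collapses to one component.
* Azimuthal sampling at 1 px arc length cannot represent patterns finer
  than ~2 px arc; with the default PSF this is not binding.
* The diameter estimator expects a single annulus in the search window;
  overlapping rings are out of scope (ROIs come from the user, matching
  the semi-manual workflow).
* Fourier-phase and brute-force estimators agree within one slope-grid
  step on noiseless stripes, but both inherit the kymograph's
  interpolation error on real images.
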