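# Methods

## Overview

platescan turns a time series of flatbed-scanner images of a 96-well
microplate into per-well bacterial growth curves and dose-response summaries.
The measurement principle: when a black-covered plate is scanned from below,
a clear well shows a crisp bright-ring/central-shadow pattern produced by
refraction at the well walls; as the culture grows and the broth becomes
turbid, scattering washes that pattern out. Image contrast is therefore a
monotone proxy for optical density, and a classifier can bin each well image
into one of L discrete *density levels* that stand in for OD620 intervals.

The default level table has six bins:

| level | OD620 interval |
|------:|----------------|
| 1 | [0, 0.06) |
| 2 | [0.06, 0.15) |
| 3 | [0.15, 0.25) |
| 4 | [0.25, 0.35) |
| 5 | [0.35, 0.60) |
| 6 | [0.60, inf) |

All bins are left-closed/right-open; OD values are used as read, without
blank subtraction. The table is a CSV (`level,lower,upper`) and fully
user-configurable; nothing in the pipeline assumes L = 6.

## Image processing

A scan is converted to 8-bit grayscale with the ITU-R 601 luminance weighting
(0.299 R + 0.587 G + 0.114 B), applied identically at training and inference
time. Frames are mirrored by the scanner, so the default preprocessing flips
each frame horizontally before cropping. An *image mask* CSV
(`label,x,y,width,height`) maps the raster to 96 labelled rectangles;
coordinates are 0-based and rectangles half-open, so crops tile without
overlap and reassemble the source exactly. A parametric default mask (grid
origin, pitch, well size) is provided because mask coordinates are
scanner-specific.

## Classification

Each well crop is reduced to seven turbidity features: mean intensity,
intensity standard deviation, radial contrast (mean over a 0.55-0.95 R
annulus minus mean over the central disk < 0.35 R), mean edge-gradient
magnitude, and the 10/50/90 % intensity quantiles. The default classifier is
a single depth-limited decision tree (scikit-learn, depth <= 12, fixed seed)
over these features. A tree was chosen deliberately: the signal is monotone
in OD, so axis-aligned thresholds placed at midpoints between neighbouring
training examples are exactly the right decision boundary estimator, and the
model is interpretable and fast on a laptop. The classifier sits behind a
small interface (`fit`/`predict` over the declared feature layout), so a CNN
or any other backend can be plugged in without touching the pipeline.
Training holds out a stratified 20 % split to report an accuracy, then
refits on all data. Models serialize to a single ZIP archive (tree tables as
JSON + levels CSV + feature spec) with a fixed archive timestamp, so
identical training runs produce byte-identical files.

Model evaluation compares model-assigned levels against levels binned from
externally measured ODs: global accuracy, per-level accuracy stratified by
the *measured* level, an L x L confusion matrix, and R² defined as the
coefficient of determination of an ordinary least-squares fit of assigned on
measured level (0 for a constant predictor). Count-weighted per-level
accuracies average exactly to the global accuracy, and the confusion-matrix
trace over the total equals it; both identities are tested.

## Growth quantification

**AUC.** With levels f(t_i) at unit-spaced timepoints, the trapezoidal rule
with the resting level subtracted gives

    AUC = sum_i [ (f(t_i) + f(t_{i+1})) / 2 - baseline ],   baseline = 1,

so a well that never grows scores exactly 0 and the maximum possible score
is (L - 1) x n_intervals. The baseline is an explicit parameter. The
timepoint index is the abscissa by default (unit spacing); interior missing
timepoints are bridged by linear interpolation, missing ends trimmed, never
extrapolated.

**Hill dose-response.** Per antibiotic, well AUCs at 46 h are fitted against
the log2-transformed concentration x with

    AUC(x) = AUC_max - E_m * (x/EC50)^k / (1 + (x/EC50)^k),

where AUC_max is the no-antibiotic AUC, E_m the maximal AUC reduction, EC50
the half-effect point on the log2 axis and k the Hill (sigmoidicity)
coefficient. Zero-concentration controls cannot enter the log2 axis; they
anchor AUC_max instead, reducing the fit to three free parameters.
Optimization is bounded trust-region least squares (E_m >= 0, EC50 > 0,
k in (0, 20]) with a deterministic multi-start grid (6 log-spaced EC50
candidates extending beyond the dose range on both sides x 5 sigmoidicities).
The amplitude bounds are deliberately loose (50x the observed maximum)
because when the half-effect point lies below the sampled dose range the
plateau AUC_max sits far above any observed AUC. The unanchored 4-parameter
fit is only well-conditioned when the sampled doses straddle the half-effect
point; with tail-only data, AUC_max and E_m are identified only jointly, so
noisy designs should anchor AUC_max to the control wells (this is also how
AUC_max is defined).

**Gompertz.** Individual curves can be fitted with the modified Gompertz
model (Zwietering parameterization): y(t) = baseline +
A exp(-exp(mu_m e / A (lambda - t) + 1)), with asymptote A (levels above
baseline), maximum growth rate mu_m (level/min) and lag lambda (min). Fits
use bounded least squares with five heuristic starts (rise-based A, max
finite-difference slope for mu_m, 10 %-rise crossing for lambda, plus
perturbations). A flat curve returns A = 0 with a degenerate-fit warning and
`converged=False`. On noiseless model-generated trajectories all three
parameters are recovered to < 1 %, and the lag survives quantization to
integer levels to within one 30-min sampling interval.

## Run orchestration

Offline runs process a directory of frames in lexicographic filename order;
each frame is flipped, sliced and classified; an unreadable frame becomes an
explicitly missing timepoint (nulls, never zeros) and the run continues. A
previously saved session can be extended when new frames appear. "Online"
acquisition is abstracted as a source contract (`next_image() -> path |
None`) with directory-watching and synthetic backends; results are identical
to the offline path over the same frames, and real scanner control is an
extension point. Sessions persist as versioned JSON (schema
`platescan-session-1`: config, timepoints, per-well level series) written
with sorted keys so equal sessions are byte-identical; loading validates
levels against the configured level count. The table export is a wide CSV
(`minutes,A1,...,H12`) that round-trips the level matrix exactly.

## Synthetic data

The generator exists so every stage is testable without hardware.

*Kinetics.* Each well follows a modified-Gompertz OD620 trajectory. Defaults
emulate a dilute E. coli inoculum in LB: od_start 0.01, plateau od_max 1.0,
mu_m 0.005 OD/min, lag 120 min, additive Gaussian read noise 0.01 OD
(clipped at 0). Antibiotic action is a saturating effect
e(c) = c^k / (EC50^k + c^k) in linear concentration that extends the lag by
up to 600 min and suppresses the plateau rise by up to 90 %; defaults EC50
2000 ug/L, k 2. The default plate layout mirrors a susceptibility sample
run: two antibiotics (k = 1 and k = 4, same EC50) x 8 two-fold doses
(250-32,000 ug/L) x 3 replicate rows, drug-free growth controls and sterile
blanks.

*Rendering.* A stylized disk with a Gaussian-profile bright ring (centre
0.75 R, sigma 0.1 R) over a central shadow on a dark background.
Ring-minus-centre contrast is base_contrast x exp(-2.5 od) — strictly
decreasing in OD, which is the only contract the classifier relies on — and
the interior brightens mildly with turbidity as a secondary cue. The smooth
radial profile matters numerically: pixel averaging over the annulus
resolves contrast well below the 8-bit quantization step, so at zero noise
the rendered contrast is effectively continuous in OD. Pixel noise is
additive Gaussian (sd 3 intensity units by default). The rendering is not a
physical optics model and does not emulate focus blur, broth colour
(Maillard browning) or scanner vignetting; pipeline closure results on
synthetic data bound what the code does, not classifier accuracy on real
scans.

*Training sets.* Per level, ODs are placed on an evenly spaced grid covering
the level's half-open interval — including the closed lower edge and
approaching the open upper edge within 1e-6 OD — so the classifier sees each
class's extremes; the unbounded top level is capped at OD 1.2 (configurable).
Grid placement rather than i.i.d. sampling guarantees coverage at every
training size.

*Closure.* With the defaults (fixed seeds, 200 images/level training, 93
frames at 30 min = 46 h), the image -> classification path reproduces the
ground-truth level of 99.7 % of the 8,928 (well, timepoint) cells, and 100 %
when both OD and pixel noise are zero and the classifier is trained at zero
noise. The full image -> AUC -> Hill path recovers the generating half-effect
point on the fitted (log2) axis to 13 % (k = 1) and 3 % (k = 4) and preserves
the steepness ordering. Recovery is judged on the log2 axis because the
generator's effect is a Hill in linear concentration while the analysis model
is a Hill in log2 concentration — different curve families whose EC50s do not
coincide on the linear axis.

## Problem sizes and numerical choices

The test suite trains on 50-200 images/level and runs 12- and 93-frame
series; these sizes were chosen as the smallest at which the statistical
contracts are comfortably exercised. Determinism: every stochastic component
(kinetics noise, pixel noise, training split, multi-start order) derives from
explicit integer seeds via numpy SeedSequence spawning; fixed seeds give
byte-identical images and model archives. Ties at level-bin edges follow the
left-closed/right-open rule. Degenerate inputs (flat curves, flat
dose-response, uniform rasters) return explicit degenerate results or
warnings rather than raising.

## Known limitations

- The shallow classifier is trained and validated on the synthetic renderer;
  accuracy numbers here say nothing about real scanner images, for which a
  user should train and evaluate a model on their own plates (the tag /
  group / evaluate workflow exists for exactly that).
- Density levels are a coarse quantization of OD; AUC and fits inherit that
  resolution floor.
- One plate per scan; no automatic plate localisation (the mask is manual).
- Hill fits with all sampled doses far above the half-effect point are
  reported honestly (converged flag, residual SSE) but are extrapolations;
  anchor AUC_max and widen the dose range where possible.
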