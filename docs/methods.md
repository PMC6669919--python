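# Methods

`nbquant` quantifies two read-outs of nuclear condensate material state
from fluorescence microscopy: exchange kinetics of molecules in a
photobleached region (FRAP), and the spatial enrichment of a protein in
segmented subnuclear bodies. Because the image analyses are usually run
inside commercial software, the package re-implements each step as an
open, tested procedure and ships a synthetic-data generator so that every
analysis can be validated against known ground truth.

## FRAP analysis

### Double normalization

Given per-frame mean intensities of a bleach ROI (`I_bleach`), the entire
cellular structure (`I_total`) and a background ROI that measures the
camera offset (`I_bg`), the normalized recovery is

```
N(t) = [(I_bleach(t) - I_bg(t)) / (I_bleach(t0) - I_bg(t0))]
     / [(I_total(t)  - I_bg(t)) / (I_total(t0)  - I_bg(t0))]
```

The t0 reference statistics are the means over all pre-bleach frames (at
least one); with a stationary pre-bleach signal this makes N = 1 before
the bleach by construction, and dividing the bleach-normalized term by
the total-normalized term cancels any global multiplicative decay such as
acquisition photobleaching exactly. Post-bleach frames whose total
denominator is nonpositive are excluded with a logged warning;
nonpositive t0 denominators are an error because no normalization exists.

### Recovery model and populations

Recovery is fitted as an immobile floor plus up to two exchanging
populations:

```
N(t) = floor + A_fast (1 - exp(-k_fast t)) + A_slow (1 - exp(-k_slow t))
```

with bounded multi-start trust-region least squares (five fixed starts
spanning recovery timescales from ~1 s to ~1000 s, rates bounded to
[1e-4, 10] s^-1). The single- vs double-exponential model is selected by
AICc; ties go to the lower residual, then to the fewer-rate model. This
is the minimal kinetic model that realizes three observable populations —
fast-exchanging, slow-exchanging and immobile — without committing to a
reaction-diffusion mechanism.

The mobile fraction is normalized for bleach depth,

```
mobile = (plateau - floor) / (1 - floor),    plateau = floor + A_fast + A_slow,
```

so comparisons between experiments do not depend on how much fluorescence
the bleach pulse destroyed. A fitted plateau above 1 is clipped to 1 with
a warning. The three populations reported are `immobile = 1 - mobile` and
the mobile part split in proportion to the fitted amplitudes
(`fast = mobile * A_fast / (A_fast + A_slow)`, analogously for `slow`).
The amplitude-based split is one defensible reading of a fast/slow
decomposition; a rate-threshold split would be another, and the fitted
rates are reported so users can apply their own boundary.

Replicate curves are averaged pointwise (mean and SD, resampling by
linear interpolation when grids differ), matching the standard
presentation of averaged FRAP data with the fitted curve overlaid.

### Drift registration

Stage drift is modeled as a rigid per-frame translation and estimated by
phase correlation with subpixel (1/50 px) refinement against one fixed
reference, avoiding the error accumulation of sequential pairwise
alignment over 120+ frames. The reference for FRAP movies is the mean of
the pre-bleach frames after aligning them to frame 0 — averaging first
would smear the reference by the drift accumulated across those frames
and bias the correlation. Trajectories estimated against a reference
image are re-baselined so frame 0 (where ROIs are defined) has zero
shift. Correction translates each frame back with bilinear interpolation;
pixels whose source left the field become NaN and are excluded from all
ROI statistics, never interpolated over.

Subpixel resampling blurs the one-pixel boundary ring of the bleached
square, so `ROISet.inset_bleach(px)` provides a measurement ROI inset
from the bleached region (1 px suffices for bilinear resampling). The
drift-pipeline validation estimates the trajectory from the noisy movie
but evaluates curve fidelity on the noiseless rendering of the same
movie: two same-seed movies with and without drift carry different noise
realizations in ROI coordinates, a difference no registration can remove,
and the check is meant to isolate the error registration controls.

## High-content assay

### Segmentation

Nuclei: Gaussian smoothing (sigma 2 px), Otsu threshold, hole filling,
removal of objects below a minimum area (default 200 px), and a
distance-transform watershed to split touching nuclei. Bodies: the
negated Laplacian-of-Gaussian response (sigma 2 px by default, matched to
the expected spot radius) is hysteresis-thresholded at 3/6 robust
(median/MAD) standard deviations above the in-nucleus median response.
Because the LoG skirt extends past the object edge, each detected blob is
refined to the pixels above the half-maximum between its interior median
and the local nucleoplasm median, which tracks the intensity edge.
Bodies are restricted to nuclear masks and assigned to the nucleus
containing their centroid; a body whose centroid falls outside every
nucleus is discarded.

### Enrichment ratio

For each body, enrichment is the mean intensity of the assayed channel
inside the body divided by the mean in a surrounding nucleoplasmic
annulus: a dilation ring of width 3 px (configurable) separated from
every body mask by a 1 px guard gap (so rim pixels missed by the
half-maximum segmentation cannot contaminate the surround), intersected
with the parent nucleus. The camera offset is subtracted from both means
by default, consistent with the background handling of the FRAP
equation; the subtraction is toggleable for a strictly literal reading of
the raw-intensity ratio. A body is called enriched above a threshold of
1.5 by default; the threshold is configurable since studies also report
enrichment at a cutoff of 2. Bodies touching the image border or whose
annulus is empty (body at the nucleus boundary) are flagged, excluded
from the enriched fraction with a logged count, and kept in counts.

### Counting and categorization

Per-nucleus foci counts are exact tallies of assigned body labels.
Counts are binned into ordered categories that must partition the
nonnegative integers; the default bins are {0}, {1–2} and {≥3}. Binnings
quoted as "0, 1–2, and > 3" leave a count of exactly 3 unassigned; this
package assigns 3 to the top bin and labels it `>=3`.
Per-category percentages sum to 100 over all nuclei. A separate
classifier calls a region positive when its mean intensity exceeds the
background mean by `c` background SDs (default c = 3), for
percentage-of-positive-cells read-outs.

## Group statistics

One-way ANOVA (classical F with (k-1, N-k) df) followed by all pairwise
two-tailed pooled-variance Student's t-tests adjusted by the
Bonferroni-Holm step-down; a pooled two-tailed Student's t-test for two
groups (Welch's correction available behind a flag); errors reported as
s.e.m. The Holm step-down is implemented directly (sort ascending,
multiply the i-th smallest of m by m-i+1, enforce monotonicity, cap at
1) and cross-checked in the test suite against statsmodels. All pairwise
comparisons are used as the post-hoc family because no restricted
comparison set is canonical.

## Synthetic-data generator

`simgen` renders what the analyses assume: disk-shaped nuclei of uniform
nucleoplasmic intensity containing disk-shaped bright bodies, a cargo
channel whose true inside/surround ratio is planted exactly, and FRAP
movies of a single nucleus whose central body contains a square bleach
ROI (2.02 × 2.02 μm by default, a typical confocal bleach-spot size for
this assay). The default FRAP acquisition is 5 pre-bleach frames plus
120 post-bleach frames at 5 s intervals (600 s of recovery);
kinetics default to fast/slow/immobile fractions (0.5, 0.3, 0.2) with
time constants 5 s and 60 s. Noise is Poisson on the scaled signal
(`poisson_scale`, `inf` disables shot noise) plus Gaussian read noise
plus a constant camera offset (default 100 counts). Where a validation
condition quotes an SNR, it is defined as the pre-bleach bleach-ROI pixel
signal above offset divided by the per-pixel noise SD, realized with read
noise only so the stated value is exact.

The bleached structure is modeled as exchanging with an effectively
unlimited unbleached nucleoplasmic reservoir: the bleach-ROI signal at
post-bleach time t is

```
offset + B(t) * I0 * [1 - depth * g(t)],
g(t) = f_imm + f_fast exp(-t/tau_fast) + f_slow exp(-t/tau_slow),
```

with `B(t) = exp(-acquisition_bleach_rate * frame)` the global
acquisition-bleaching factor, while structure pixels outside the ROI stay
at `I0 * B(t)`; the whole-structure signal therefore decays only by B(t)
plus the current bleached-fluorophore deficit. A closed-compartment
alternative (photon conservation within the structure) would multiply the
normalized curve by the constant `1/(1 - depth * S/T)` (S, T the
pre-bleach ROI and structure fluxes) and bias the recovered mobile
fraction by several percent; the reservoir model keeps that bias below
~0.006 at the default geometry (whole nucleus as the total ROI, S/T ≈
0.05). The dead time between the bleach pulse and the first recovery
frame is instrument-dependent and rarely reported, so it is an explicit
parameter (default 0).

Drift is rendered as a cumulative subpixel translation per frame with
bilinear interpolation. Determinism: every output is a pure function of
the parameter objects including their seeds. Ground truth (per-body
centroids/radii/enrichment, per-nucleus counts, the drift trajectory, the
true mobile fraction and the pre-bleach ROI/structure fluxes) is recorded
in a JSON-serializable sidecar.

What the generator does not emulate — and what passing tests therefore do
not establish for real data: diffraction (objects are hard disks, no
PSF), realistic reaction-diffusion bleach profiles and diffusion during
the bleach pulse, 3D structure and defocus, nonuniform illumination,
spectral bleed-through, cell motion other than rigid stage drift, and
photophysics (blinking, reversible photoswitching). Parameter-recovery
results bound algorithmic error, not these physical effects.

## Numerical choices and problem sizes

- Coordinates are 0-based pixel indices, x right / y down; ROIs are
  half-open pixel boxes; physical sizes are entered in μm and converted
  via the pixel size.
- The bleach event is instantaneous between the last pre-bleach and first
  post-bleach frame; t = 0 at the first post-bleach frame.
- Fit tie-breaks: lowest AICc, then lowest residual, then fewest rates;
  frames invalidated by registration are dropped, not interpolated.
- Validation problem sizes: 20 replicates per kinetic condition for
  parameter recovery, 10 fields for segmentation scoring, 10,000
  replicates for each statistical-calibration simulation; FRAP movies are
  rendered at 384 × 384 px, 0.1 μm/px, 125 frames. These sizes give
  stable medians and rate estimates while keeping the full validation in
  the low minutes on one core.

## Known limitations

- The fast/slow boundary of the population decomposition is defined by
  the two fitted exponentials, not by an absolute rate threshold; with
  closely spaced time constants the amplitude split is ill-conditioned
  even when the mobile fraction is well determined.
- Rigid translation only; rotation, scaling or elastic deformation are
  out of scope.
- Whether the "entire cellular structure" of the normalization equation
  is the whole nucleus or a single body is experiment-dependent; the
  ROI set leaves it caller-defined (the simulator uses the whole
  nucleus).
- Enrichment of bodies at the nucleus border cannot be measured (empty
  annulus) and is reported as excluded rather than guessed.
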