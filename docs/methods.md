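# Methods

`mitograph` quantifies live-cell STED images of the mitochondrial inner
membrane (IM) and confocal images of mtDNA nucleoids. Because such raw
image data is rarely shareable, the package pairs every analysis stage
with a synthetic-scene generator whose vector ground truth makes the whole
chain testable end to end. This note records the models, the parameters
that matter, and the choices made where the design was genuinely open.

## Image formation

**Depletion law.** The fluorescence remaining at depletion power *I* is

    F(I) = F0 / (1 + I / Is),

where the saturation power *Is* is defined as the power at which the
signal drops to 50%. This hyperbolic form is the unique simple law
consistent with the effective-PSF relation used throughout:

    d = d0 / sqrt(1 + I_dep / Is).

An exponential-depletion alternative was rejected because it cannot
reproduce that square-root resolution law. With the default confocal PSF
`d0 = 250 nm`, a low-saturation dye (`Is = 0.864 mW`) driven at
`I_dep = 34.7 mW` yields a 6.4-fold enhancement, i.e. a ~39 nm PSF.

**PSF.** The depletion donut is not modeled explicitly; its entire effect
is the effective FWHM above, realized as an isotropic Gaussian. Images
are formed by convolving a fluorophore-density map with this PSF, scaling
so the brightest pixel expects `photon_budget` photons, then applying
Poisson noise, a constant background and Gaussian read noise (clipped at
zero). Every random stage takes an explicit seed and is bit-reproducible.

**Photon budget.** "High SNR" in the test suite means 1000 expected
photons in the brightest pixel (background 2, read noise 1). This is the
regime where Fourier ring correlation of a cristae scene reads out the
PSF FWHM itself: at much higher budgets the FRC curve stays above the 1/7
threshold all the way to Nyquist (reported as a flagged bound, not an
estimate), and at much lower budgets the noise floor, not the optics,
sets the crossing.

**Saturation measurement.** The simulated power series mirrors the
two-pass solution-dye protocol: one pass with excitation on, one with
excitation off. The off pass contains only secondary excitation by the
depletion beam, modeled as an affine function of power and shared by both
passes; subtracting it, clipping negatives, normalizing by the zero-power
value and least-squares fitting `1/(1 + I/Is)` recovers *Is*. A monotone
interpolation of the 50% crossing is the fallback when the fit fails, and
a series whose normalized minimum stays above 0.5 is rejected as not
reaching saturation. With 12 powers spanning 0-40 mW and 2% multiplicative
noise, the median of 100 fits recovers a 0.864 mW ground truth within 1%.

## Resolution estimation

**FRC.** Two frames with independent noise are apodized (Tukey window,
alpha = 0.25), Fourier transformed and correlated in 1-pixel rings; the
curve is smoothed by a 3-ring moving average and resolution is the
inverse of the first frequency below 1/7. These constants follow common
FRC practice; none is data-tuned. Degenerate cases are explicit: a pair
whose FRC never drops below 1/7 returns the Nyquist bound flagged
`is_bound`; a pair already uncorrelated at the lowest rings (pure noise)
returns `no_correlation` and no number.

**FWHM.** Line profiles are sampled with a cubic interpolating spline
(bilinear sampling adds ~1/6 px^2 of variance, a visible widening at
PSF-scale widths) and fitted with a Gaussian plus constant offset;
FWHM = 2*sqrt(2 ln 2)*sigma. Note that a profile across a real crista
measures the structure convolved with the PSF: a 20 nm-thick crista under
a 44 nm PSF reads ~48 nm. Resolution checks therefore use deliberately
thin (8 nm) test cristae.

## Synthetic scenes

Coordinates are continuous micrometres, origin at the field corner; pixel
`(i, j)` is centred at `(x, y) = (j, i) * p` (default `p = 20 nm`, which
Nyquist-samples a 40 nm PSF; both channels share the grid).

Tubules are random-walk polylines with a curvature cap, diameters drawn
from 200-700 nm; branches are grafted at random arc positions. Cristae
are transverse segments (perpendicular to the local centreline) spaced
70 nm apart, spanning 75% of the tubule radius, painted with a Gaussian
cross-profile of 20 nm FWHM; the inner boundary membrane is painted at
0.3x the cristae amplitude. A nucleoid-sized (~0.15 um) clearance is kept
around junctions, matching the void seen where branches meet. Components
keep a 0.5 um clearance from each other so that organelles remain
individually resolvable.

**Nucleoids** are disks of 120 nm physical diameter placed on
centrelines. Each tip/branch point is occupied with probability 0.677;
unoccupied landmarks get a dedicated nucleoid at an Exponential(lambda)
arc distance along the tubule (lambda = 1.7470 /um by default, the rate
for which 65% of distances fall below 0.6 um), truncated at the tubule
end with a warning when the exponential mean exceeds every tubule.
Interior nucleoids are a Poisson line process. One consequence worth
knowing: with nonzero occupancy the observable "fraction of landmarks
with a nucleoid within one radius" slightly exceeds the occupancy,
because an exponential draw can also land that close (+~0.03 at default
radius).

**Control calibration.** The control condition's interior density,
`CONTROL_NUCLEOIDS_PER_UM = 0.55`, was calibrated once so that the full
pipeline (render, acquire, segment, detect, measure) reproduces a mean
per-mitochondrion mtDNA/mitochondrion area ratio of ~0.29, and then
frozen. The measured ratio is dominated by the confocal apparent size of
nucleoids (a 120 nm disk detects at ~0.06-0.15 um^2), so this density
should be read as "what the control condition looks like through this
pipeline", not as a biological census.

**Morphology populations.** Class mixtures are sampled by drawing a class
label from the requested mixture, rejection-sampling a lognormal length
into that class's admissible region, and drawing the cristae count as
length / 0.35 um plus noise, clipped into the class region. The 0.35 um
"effective cluster spacing" reflects that per-organelle counts in
length/cristae scatter data are far below length / 70 nm: cristae come in
clusters separated by gaps. Each sampled organelle is laid out as an
isolated, gently curved tubule with its count spread evenly along the
centreline, so the generator's truth is exactly renderable.

## Segmentation

**Cristae.** The default, fully deterministic mode computes a multiscale
tubeness (Sato) response and combines it with the smoothed intensity as
`cbrt(response * intensity^2)`; the squared intensity suppresses the
dimmer boundary membrane, which a bare ridge filter would also segment.
The map is normalized by the 99.5th percentile of its support (robust to
sparsely populated fields) and thresholded at 0.35. The threshold and the
map's functional form were calibrated against synthetic truth rasters -
the imaging protocol itself prescribes adjusting the threshold until
cristae are accurately distinguished - using cristae-mask Dice on dense
networks and count accuracy on cluster-spaced organelles; at the default
high-SNR condition Dice >= 0.83 across seeds and counts are exact. The
alternative `pixel-classifier` mode trains a random forest on a small
filter bank (Gaussians, gradient magnitude, Hessian eigenvalues) from
labeled pixels, with the same probability -> threshold -> mask contract.

Ground-truth rasters for such comparisons are drawn at the imaging
resolution (40 nm line thickness): a mask cannot be thinner than the PSF,
so comparing against the 20 nm paint width would penalize physics, not
segmentation.

**Mitochondria.** Whole organelles are recovered by closing the cristae
mask with a disk, filling holes and labeling 8-connected components. The
closing radius must exceed half the largest within-organelle cristae gap:
150 nm by default (bridging the 70 nm spacing and the junction
clearance), 350 nm for cluster-spaced populations. Components below
0.05 um^2 are discarded. Areas are pixel counts times the pixel area.

**Nucleoids.** The confocal channel is smoothed (sigma 60 nm), a
rolling-median background (2 um window, computed on an 8x-downsampled
grid for speed - the window is far larger than any nucleoid, so the
coarse estimate is smooth at full scale) is subtracted, and Otsu's
threshold (floored at 3 robust sigma) yields components filtered at
0.02 um^2. A contrast guard returns an empty set when nothing stands
6 robust sigma above background, where Otsu would otherwise split the
noise floor. Merged detections are physical at confocal resolution:
nucleoid pairs closer than ~0.5 um cannot be separated, so
precision/recall guarantees hold for resolvable nucleoids. Blob
splitting via watershed is deliberately not default.

## Morphometry

Each labeled component is median-smoothed (60 nm disk; skipped if that
would erase a thin structure) - raw skeletons meander along the
crista-end scallops of the mask boundary and over-count length by ~6% -
then thinned. The skeleton pixel graph uses 8-connectivity with
staircase-closing diagonals dropped; edge lengths are 1 or sqrt(2)
pixels. Terminal twigs shorter than 0.2 um ending at a junction are
pruned. Tips (degree 1) are extended outward to the mask boundary, since
thinning retracts rounded ends by about the tube half-width; branch
pixels (degree >= 3) within 3 px merge into single landmarks. Reported
length is total skeleton length (networks are treated as single
organelles) minus a 0.09 um halo per tip - the mask extends roughly half
the effective PSF beyond the true end. On rendered tubules of 3/4/5 um
this recovers truth within ~1%; the suite requires 5%.

Cristae are counted as connected components of the cristae mask assigned
to the label under their centroid (majority vote if the centroid falls on
background). Counting is only meaningful for resolvable (cluster-spaced)
cristae; at dense 70 nm spacing the binary masks of neighbours touch at
any threshold that preserves Dice.

**Classification.** With thresholds 2.5/5 um and 6/12 cristae:
Class III if length > 5 or count > 12; else Class II if length >= 2.5 or
count >= 6; else Class I. The disjunctive clauses overlap; III is tested
first so a short organelle with many cristae counts as a network, and
boundary values 2.5 um / 6 cristae fall to Class II, exactly as the
interval notation reads. The rule is total and exclusive on
[0, inf) x {0, 1, ...} (property-tested including boundaries).

## Spatial statistics

Landmark-to-nucleoid distances are 2D Euclidean to nucleoid *centroids*
(chosen over boundaries for stability at confocal resolution); tips,
branch points and externally supplied landmarks (e.g. fusion sites from a
CSV) are treated identically. The fraction below the 0.6 um cutoff uses
strict inequality. The exponential rate is the MLE 1/mean with a seeded
percentile bootstrap CI (1000 resamples) and a one-sample KS check.
Group comparison defaults to two-sided Mann-Whitney U - exact for
n <= 20 without ties, otherwise the tie-corrected normal approximation -
with identical constant samples flagged degenerate (p = 1); a KS
alternative is selectable. Area ratios are computed per mitochondrion
(nucleoid area over mitochondrion or cristae area), zero denominators
skipped with a warning, then averaged per group; distance histograms
default to 0.2 um bins (the source histograms' binning is not stated).

## What the generator does and does not emulate

It reproduces: the two-resolution dual-channel geometry, tubule diameters
and cristae spacing, perpendicular cristae with junction voids,
landmark-biased nucleoid placement with an exponential distance law,
Poisson + read noise, and class-structured (length, count) populations.
It does not model: 3D structure, time-lapse dynamics and cristae
remodeling, nucleoid clustering or sub-nucleoid structure, spatially
varying background or labeling heterogeneity, and optical aberrations
beyond an isotropic Gaussian PSF. Passing tests therefore validate the
measurement chain under controlled geometry; they do not certify
segmentation accuracy on real micrographs, where membrane contrast and
background vary far more.

## Problem sizes in the shipped suite

Chosen as the smallest that leave clear statistical margin: 100
replicates for saturation recovery; one 600x600 px frame pair for FRC;
~370 tips across 23 fields for the distance fraction; 300 organelles per
condition for class proportions; 30 three-component fields for the
control area ratio; 10 seeds for the Dice and precision/recall sweeps.
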