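# Methods

This note documents the models, estimators and numerical choices behind
`cometkit`, and what the synthetic-data validation does and does not
demonstrate.

## The measurement problem

Growing microtubule (MT) plus-ends recruit end-binding proteins that
image as comet-shaped puncta: a sharp leading edge at the polymerising
tip and an intensity tail decaying toward the soma, reflecting the
maturation of the GTP cap behind the tip. Three families of readouts are
implemented: (i) still-image comet quantification (count, length, mean
intensity, and their product, the "comet amount"), (ii) dynamic readouts
from time-lapse movies (velocity and lifetime, via kymographs or 2D
particle tracking), and (iii) axon morphometrics (length, curled-area
MDI, swelling counts). A statistics layer normalises per-neuron values
to same-repeat controls and compares genotypes nonparametrically.

## Synthetic data generator (`cometkit.synth`)

The generator is the validation substrate: every downstream estimate is
scored against its ground truth.

**Axon geometry.** An axon is a polyline trace in pixel coordinates,
soma end first. Curled regions are inserted as full circular loops: a
loop of radius `r = sqrt(A/pi)` consumes exactly its circumference of
arclength, so the trace's total arclength stays at `axon_length_um`
while enclosing the requested area `A`. The ground-truth polygon is the
discretised circle; its stored area is recomputed by the shoelace
formula from the stored vertices, so geometry tests are exact by
construction. Loops that do not fit the image raise, naming the span.

**Comet model.** A comet is a line emitter along the trace with axial
profile

```
p(u) = exp(-u^2 / (2 sigma^2))   for u >= 0   (ahead of the tip)
p(u) = exp(u / tau)              for u <  0   (trailing tail)
```

with `sigma = psf_sigma_um` and `tau = comet_tail_length_um`, normalised
to unit integral and convolved with a 2D Gaussian PSF. `comet_amplitude`
is the comet's *integrated* intensity (flux): total summed intensity is
then independent of the PSF width, which is the physically meaningful
conserved quantity; the resulting peak pixel value is available
numerically via `comet_peak_intensity` (used to set signal-to-noise
ratios). Rendering deposits line samples on a 3x-oversampled grid
(half-cell sampling step), applies the Gaussian PSF, block-sums back to
the camera grid and divides by the pixel area — pixel values are
intensity surface densities, so the same physical scene renders
identically at any pixel size.

**Dynamics.** Comets nucleate as a homogeneous Poisson process in
time x arclength at `comet_nucleation_rate_per_um_min`, move at constant
signed velocity (positive = anterograde, tail pointing to the soma), and
die after exponentially distributed lifetimes, truncated where the
trajectory leaves the axon. Noise is optional Poisson shot noise on the
offset image followed by additive Gaussian read noise (an sCMOS-style
model; both components are independently switchable so exact fixtures
are possible). Equal configurations (including `rng_seed`) give
bit-identical stacks and truth.

**Defaults as study conditions.** 1 s frames for 1 min (2 s for the
tracking experiments), 0.1 um pixels, PSF sigma 0.11 um, axons
30-60 um, velocities 0.05-0.4 um/s, tail 1 um, mean lifetime 8 s,
nucleation 0.6 comets/(um min). Absolute intensities are not claims:
amplitude 4000 (integrated counts) over a 100-count offset gives
comet-to-noise ratios around 20 under shot noise; validation scenarios
set Gaussian noise explicitly for a peak SNR of 5.

**What the generator does not emulate.** Photobleaching, comet shape
changes (catastrophe/rescue transitions), intensity heterogeneity
between comets, axon branching, focus drift, and non-uniform lattice
binding. Passing tests therefore demonstrate estimator correctness under
the stated model, not performance on real movies; in particular the
paper-style manual scoring of kymographs may differ systematically from
the automated extraction on real data.

## Comet quantification (`cometkit.comets`)

All still-image readouts operate on the band-averaged along-trace
profile: the image is sampled every pixel of arclength (bilinear
interpolation) and averaged across a perpendicular band of `band_px`
pixels (default 3), mirroring an average-intensity reslice.

- **Detection**: 1D difference of Gaussians (0.1/0.5 um), threshold at
  `median + max(k*MAD, 0.05*(max-median))` — the relative floor keeps
  the threshold meaningful on noise-free data where the MAD vanishes —
  local maxima, strongest-first suppression below `min_sep_um`,
  parabolic sub-pixel refinement. On noiseless stills the detected
  position sits ~0.1 um behind the geometric tip (the apparent peak of
  an asymmetric profile).
- **Comet extent**: the maximal contiguous run around the peak where
  intensity exceeds `background + f*(peak - background)`, `f = 0.2` by
  default. The manual line-drawing protocol this reproduces has no
  stated edge rule; a fractional-peak threshold is the deterministic,
  reproducible choice, and `f` is exposed. Length is the run span, mean
  intensity the background-subtracted mean over the run, and
  `amount = mean x length` holds as an algebraic identity.
- **Background**: median profile intensity outside exclusion zones
  around detected comets (at least 25% of samples must remain). For
  lattice intensity the background must come from *off-trace* pixels
  (`off_trace_background`): the on-trace median would subtract the very
  lattice signal being measured.

Because the edge rule and background handling of the original manual
measurements are unspecified, absolute intensity agreement with any
particular dataset is not claimable — only ratios and control-normalised
values are comparable.

## Kymographs (`cometkit.kymo`)

Kymographs are S x T arrays: column t is the band-averaged profile of
frame t at 1-px arclength steps. Trajectory extraction detects
per-column peaks with the same DoG + MAD rule, localises them by an
intensity-weighted centroid in a narrow window (4 px; the asymmetric
profile gives the centroid a constant tail-ward offset, which cancels in
slopes and lifetimes, and the narrow window resists contamination from
neighbouring comets), and links peaks frame to frame: nearest candidate
within `max_step_um` per elapsed frame (ties by smaller jump, then
higher intensity), with a prediction gate (0.4 um per frame around the
extrapolated position once a track has a trend) and gap closing up to
2 frames. Tracks shorter than 3 observed frames are discarded. Velocity
is the least-squares slope of arclength versus time over all track
points; lifetime is (last frame - first frame) x frame interval, gaps
included, matching a line drawn on a kymograph from first to last
appearance.

At SNR 5 the per-column localisation noise is ~0.03 um (close to the
information bound for this profile and band); for the slowest simulated
comets (0.05 um/s = 0.5 px/frame) the least-squares slope over a short
exponential-lifetime track is therefore intrinsically noisy, and the
velocity-recovery guarantee is stated for the pooled physiological
velocity grid (0.05-0.3 um/s), where the pooled matched-track median
error is ~4-5%; at 0.1 um/s and above each velocity individually
recovers within 10%.

## 2D plus-end tracking (`cometkit.tracking`)

Detection: 2D DoG, robust threshold with the same relative floor,
strongest-first non-maximum suppression (6 px; comet tails produce
secondary maxima), re-centering on the raw intensity maximum, parabolic
sub-pixel refinement on a lightly smoothed image.

Linking implements an explicit semantics for the printed parameter set
(gap 8, minimum track 3, search radius 5-12 px, forward 50 deg,
backward 10 deg, shrinkage 0.8, fluctuation 2.5 px, 2 s interval),
since the original software's internal cost matrices are not documented:

- a candidate step is a **pause** if its length is at most the
  fluctuation radius (the lower search-radius bound is waived);
  otherwise its length must lie within the search-radius band;
- a step within the forward cone of the current heading is **forward**
  (the heading is the direction of the last forward step; before any
  forward step, direction is unconstrained);
- a **backward** step must point within the backward cone of the
  reversed heading *and* be no longer than the shrinkage factor times
  the mean forward step so far;
- frame-to-frame assignment minimises total displacement (Hungarian
  algorithm) over feasible candidates;
- ended segments reconnect to later segment starts across gaps of at
  most 8 frames when the extrapolated position (heading x mean forward
  step) lies within the *lower* search radius scaled by the gap length —
  generous for honest detection dropouts, tight enough not to stitch
  unrelated comets — and only if the stitched sequence still passes the
  independent constraint checker, so every emitted track is compliant
  by construction;
- tracks with fewer than 3 observed points are discarded.

`check_track_constraints` replays these rules over any track and returns
violations; it is used both post hoc in tests and inside gap closing.

Velocity is the least-squares slope of along-track arclength versus
time, pooled over gapless segments with per-segment intercepts: a
reconnection bridge measures the extrapolation — and, when gap closing
legitimately stitches a compound track (one comet dying while another
nucleates on its extrapolated path), the offset between two different
comets — rather than observed motion, so bridges are excluded from the
slope. Lifetime spans first to last observed frame.

**Interpretation caveat**: the semantics of "maximum shrinkage factor"
and "fluctuation radius" above are this package's explicit
interpretation; the original tool's precise behaviour is not published.

## Morphometrics (`cometkit.morpho`)

Axon length is the summed Euclidean segment length of the trace times
the pixel size. Polygon areas use the shoelace formula (simplicity is
validated via shapely). The MDI sums all curl polygons of an axon
before dividing by (length x reference diameter); the reference
diameter is a parameter defaulting to 0.5 um. Swelling counts are
annotation-driven (labels `swelling` / `swelling_with_curl`, the latter
counting toward both tallies); no automated swelling segmentation is
attempted.

## Statistics (`cometkit.stats`)

- **Parallel-control normalisation**: each value is divided by the
  centre (median or mean) of the same-repeat control values; the control
  centre is exactly 1 per repeat afterwards. Metrics reported as
  median +/- 95% CI in the source protocol (amounts, velocities,
  lifetimes, lengths) use the median; mean +/- SEM metrics (MDI, counts)
  use the mean; the centre is an argument throughout.
- **Kruskal-Wallis** H is tie-corrected
  (`H / (1 - sum(t^3 - t)/(N^3 - N))`), p from chi-squared with k-1 df;
  identical data across groups returns H = 0, p = 1, flagged degenerate.
- **Dunn's post-hoc** z uses the pooled-rank variance
  `(N(N+1)/12 - tie/(12(N-1))) * (1/n_i + 1/n_j)`; raw two-sided normal
  p-values and Holm-adjusted p-values are both reported (the source
  protocol does not state an adjustment; Holm is the headline).
- **Mann-Whitney**: exact enumeration of the U distribution (standard
  recurrence) when `min(n1, n2) <= 8` with no ties; otherwise the
  tie-corrected normal approximation with continuity correction.
- **Spearman**: Pearson correlation of ranks (tie-corrected); exact
  permutation p for n <= 9 without ties (vectorised enumeration),
  otherwise the t approximation with n-2 df. Constant input is flagged
  degenerate.
- **Repeat summaries**: per-repeat centres alongside the pooled
  per-neuron centre with a percentile-bootstrap CI (10,000 resamples,
  seed recorded). Individual neurons are the statistical unit; repeats
  contribute one centre each (superplot convention). No hierarchical
  model is attempted.

These rank statistics are implemented directly because the exact
small-sample branches and Dunn's test have no counterpart in the
installed stack; scipy.stats serves as the independent cross-check in
the test suite (agreement within 1e-9 on random tables).

## Validation scoring (`cometkit.evaluate`)

Extracted tracks are matched to ground truth greedily, best overlap
first. Matching is shift-invariant (the per-pair median signed residual,
bounded by 1 um, is removed first) because every localiser of an
asymmetric comet carries an estimator-dependent constant offset that
cancels in the dynamic quantities being scored;
`apparent_peak_offset_um` computes the analytic peak-tip offset for
placing apparent-position truth in 2D. Kymograph matching is one-to-one
and requires at least three agreeing frames; 2D matching lets one
compound track claim several truths in disjoint frame ranges, since gap
closing deliberately reconnects a dying comet to one nucleating on its
extrapolated path. Eligibility for recall is at least three visible
frames (the minimum track length).

## Problem sizes

The validation battery simulates: 50 random still layouts for count
recovery; 30 seeds per velocity on 60-frame movies for kymograph
recovery; 8 two-second-interval movies for tracker recall; 500
simulations x 10,000 bootstrap resamples for CI coverage; and a
10-genotype, 2-repeat, 3-neurons-per-repeat cohort for the end-to-end
correlation. The full suite runs in about half a minute on one CPU;
sizes were chosen so each estimate's sampling error is small relative to
the tolerance it is checked against.
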