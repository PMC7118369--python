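# Methods

## The measurement problem

Intravital two-photon imaging of a fluorescent tumor yields a time series
of 2D frames in two channels: RFP marks every tumor cell, eGFP marks the
Lgr5⁺ stem-cell subset. Three quantities are extracted: (i) which cells
move, and how fast; (ii) whether movers are Lgr5⁺ or Lgr5⁻, and whether
they move alone or in contact; (iii) in liver sections, how lesion size
relates to the presence of Lgr5⁺ cells. Before (i) is meaningful the
movie must be rigidly drift-corrected, because the whole field moves with
the animal's breathing and tissue relaxation.

## Drift correction

Model: each frame differs from the first time point by an unknown
integer-pixel rigid translation; rotation, scaling and elastic
deformation are out of scope, as is Z (frames are single planes already
selected per time point).

Similarity is the Pearson correlation restricted to the jointly positive
pixel mask {a > 0 ∧ b > 0}. Two properties make this mask the right
domain: shifted-in border pixels are zero-filled, so they drop out
automatically, and detector-dark regions do not dilute the statistic.
A mask smaller than `min_overlap` (default 64 px) or with zero variance
raises a *degenerate overlap* error, deliberately distinct from a
dimension mismatch.

Optimization is greedy coordinate ascent on the integer shift lattice:
all four unit moves (left, right, up, down) are evaluated and the single
best strictly-improving one is accepted; ties are broken in the fixed
order left, right, up, down, making the result order-independent and
reproducible. Iteration stops when no move improves (`converged=True`)
or after `max_steps` (default 200, a divergence guard). The accepted
correlation sequence is strictly increasing by construction. Frames of a
movie are processed against frame 0, warm-started from the previous
frame's accepted shift — drift accumulates slowly, so the previous
optimum is adjacent to the next one. A frame failing with degenerate
overlap keeps the previous shift and is flagged, without aborting the
run.

Greedy ascent finds the global argmax only when the correlation-vs-shift
surface has a monotone path from the start to the optimum. This holds
for realistic tissue images, whose spatial autocorrelation decays
smoothly over several pixels; it provably fails on pathological inputs
such as i.i.d. noise textures, whose correlation surface is a delta
function. The test suite therefore checks greedy/exhaustive equivalence
on unimodal single-blob fixtures and on spatially correlated textures,
which is the regime the algorithm is designed for.

Validation follows the landmark rule: the correction is successful when
every tracked static landmark moves less than half a cell diameter net
over a 4-hour window of the corrected movie (strict inequality at the
boundary).

## Detection, classification, linking

Cells are detected on the background-subtracted (median pedestal) RFP
channel with Laplacian-of-Gaussian blob detection over the configured
diameter range. The blob scale radius is defined as 2σ of the detected
scale, so the reported `diameter_um = 4σ` is unbiased for cells with a
Gaussian intensity profile of σ = diameter/4 (the generator's render);
centroids are refined to sub-pixel precision by intensity-weighted
averaging, and channel means are measured in a disk of the detected
radius.

The Lgr5 call is `mean_gfp > threshold`. With the default `"otsu"` mode
the threshold is computed once per movie from the pooled detection
intensities at 4096 histogram bins (the native 12-bit resolution —
coarser binning can collapse a tight mode into one bin and return a
threshold inside it). Otsu assumes bimodality; when the split it finds
has class-mean contrast below 2× the distribution is treated as unimodal
(a movie whose cells are all dark or all bright) and an absolute floor
(default 50 counts) is used instead. The floor is an instrument-scale
constant: background-only eGFP disks average a few counts at realistic
noise, bright membrane reporters hundreds.

Linking is frame-to-frame greedy nearest-neighbor matching processed
globally in order of increasing pair distance, with pairs beyond
`max_link_um` (default 1.5× the mean detected diameter) rejected.
Distance-ordered processing makes the assignment deterministic and
input-order invariant; the test suite checks it against an optimal
(Hungarian) assignment oracle on well-separated fixtures, where the two
coincide. Track-level Lgr5 state is a majority vote over member
detections, ties called Lgr5⁺ (conservative toward the rarer class).

## Migration metrics

Metrics are computed on the first 4-hour stretch of each track (tracks
spanning less are excluded and logged). Net displacement is the
start-to-end Euclidean distance; path length, the sum of step lengths,
is reported alongside for transparency. Velocity defaults to net
displacement / 4 h; cumulative path / time is available as an option and
logged when used. A track is migratory iff net displacement strictly
exceeds half a cell diameter; the diameter comes from the track's mean
detected diameter, with a global override for parity with manual scoring.

Mode: two migratory cells are in contact in a frame when their center
distance is ≤ κ(rᵢ+rⱼ) with κ = 1.2; a track is a *cluster* when in
contact with ≥ 1 other migratory track in ≥ 75% of window frames, else
*single*. Sustained contact (rather than any-frame contact) encodes
"maintaining cell–cell contact"; 75% admits brief detection dropouts
while excluding incidental passes.

Cohort summaries use the animal as the unit of analysis: the Lgr5⁻
fraction is computed per animal over its migratory tracks, and the group
mean ± SEM is taken across those animal-level values, never pooled over
cells. Animals without migratory tracks are excluded and logged.

## Lesion scoring

Lesions in 2-channel section images are 8-connected components of
RFP above threshold with area at least one mean-diameter cell (smaller
components are single cells or debris, not lesions). Diameter is the
equivalent-circle value 2√(area/π). A lesion *contains Lgr5⁺ cells*
when ≥ 5 pixels inside its footprint exceed the GFP threshold (the
5-pixel minimum rejects shot noise). Binning is half-open [lo, hi) over
configurable edges, default {0, 20, 40, 80, 160, 320} μm with an
overflow bin; counts are conserved.

The plasticity threshold D\* is the smallest observed diameter such that
every lesion larger than D\* contains Lgr5⁺ cells — operationally the
largest Lgr5⁻-only diameter, `None` when the largest lesion itself is
Lgr5⁻-only, and the smallest observed diameter when every lesion is
positive. Under the packaged simulator rule (all-positive above
L\* = 80 μm) the estimator approaches L\* from below with a gap of order
the spacing between sub-threshold negative diameters (≈ 1 μm at
n = 500).

## Statistics

Welch's t (unpooled variances, Welch–Satterthwaite df), the paired t
(one-sample t on differences), and Mann–Whitney U with midrank ties are
computed from their defining formulas; only the t and normal
distribution functions come from scipy. Mann–Whitney p is exact by full
enumeration of rank assignments when n₁+n₂ ≤ 12 with no ties (at most
C(12,6) = 924 splits — enumeration is cheap below this size and the
normal approximation is already within 0.02 of exact at n₁ = n₂ = 6);
otherwise the normal approximation with tie and continuity correction is
used. All p values are two-sided. Zero-variance inputs return flagged
degenerate results (t = 0, p = 1 for equal means; ±∞, p = 0 otherwise)
rather than NaNs. A Shapiro–Wilk helper is provided for reporting only —
test choice is the caller's, not gated on it.

## Synthetic data: what it emulates, and what it does not

The generator renders T hourly frames (default 5, a 4-h window) of
H×W 12-bit images at 1 μm/px. Cells are isotropic 2D Gaussians
(σ = diameter/4, peak 2500 counts) with diameters ~ N(20, 2²) μm; Lgr5⁺
cells are rendered identically in the eGFP channel. The field sits on a
smooth positive background texture (level 300, ±30% at ~1.5 px
correlation length) standing in for densely labeled static tissue — it
is what gives registration its signal, as in real movies where most of
the field is non-migrating tumor. Drift is an integer random walk
(default ±2 px/frame/axis, or explicit shifts) applied rigidly to all
frame content; noise is additive N(0, 20²), then clipping to [0, 4095].
Static cells jitter < 0.1 diameter total; migratory cells move 5 μm per
frame with a persistent heading (0.1 rad jitter); a cluster event is a
co-moving pair at 0.8·(rᵢ+rⱼ) separation sharing one Lgr5 draw (one
escape event, one phenotype). Migratory events are Lgr5⁻ with
probability 0.9; static cells Lgr5⁺ with probability 0.3. Placement
rejection-samples anchors with ≥ 2 diameters + migratory excursion
separation, with margins keeping every blob in frame for all drifts;
impossible configurations raise a configuration error, and drift
exceeding half the frame logs a warning.

Lesion tables draw diameters uniformly; composition follows a step rule:
always Lgr5⁺ above L\* = 80 μm, Lgr5⁺ with p₀ = 0.4 below, always Lgr5⁻
at single-cell scale (≤ 20 μm).

Not emulated: 3D structure, elastic tissue deformation, membrane-bound
(ring-shaped) eGFP, photobleaching, second-harmonic stroma, cell division
or death, detection-confusing clutter, or sub-pixel drift. Passing tests
therefore demonstrate correctness of the algorithms under rigid drift
with separable cells — not robustness to dense tissue, occlusion or
deformation, which in the source workflow were handled by manual QC and
external elastic-correction software.

## Numerical choices and problem sizes

Correlations are accumulated in float64; r is clamped to [−1, 1] against
rounding excursions. Frames below 16×16 are rejected for registration.
Determinism: a single `numpy` Generator seeded from the configuration
drives every stochastic step, so identical configurations give
bit-identical movies and tables. Test problem sizes — 384×384 movies,
5 frames, ≤ 20 cells; cohorts of 9 animals × 3 movies; 500-lesion
tables; 2000-replicate null calibration — were chosen as the smallest
sizes at which every estimator's sampling error is well inside its
acceptance band.

## Known limitations

- The greedy climb inherits local optima on surfaces that are not
  unimodal along coordinate paths; the warm start mitigates but cannot
  eliminate this for large abrupt drifts.
- The absolute eGFP floor used in the unimodal fallback is an
  instrument-scale constant; images on other intensity scales need a
  fixed threshold instead.
- The linker handles neither division nor merging; crossing tracks
  closer than the link radius can swap identities.
- One-pixel registration residuals are possible at realistic noise; they
  are an order of magnitude below the half-diameter success criterion.
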