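# Methods

This note documents the models, procedures, numerical choices and
simulation conditions implemented in `geomrep`.

## Stimulus geometry

Eleven quadrilateral families span a gradient of geometric regularity:
square, rectangle, isosceles trapezoid, parallelogram, losange
(rhombus), kite, right kite, hinge, right hinge, plain trapezoid, and a
fully irregular family ("random"). All families are matched on the mean
pairwise distance between their four vertices (mpd) — the quantity that
standardizes deviant-corner displacements across shapes — to a relative
tolerance of 1e-6. Canonical pose places the bottom side (edge 0→1)
horizontal, vertices counterclockwise, centroid at the origin.

Two construction modes realize the matching constraints:

* **Solved families** (square, isoTrapezoid, trapezoid) keep the bottom
  side exactly at the requested length; one free parameter (the
  trapezoid height, or the left-leg length of the parallel-leg
  trapezoid) is root-found with Brent's method so that the mpd matches
  the square's. Brackets are fixed; non-convergence raises an error
  naming the family.
* **Frozen families** are fixed vertex sets rescaled uniformly to the
  target mpd, with the residual bottom-side deviation recorded on the
  shape. The rescale route is forced by geometry: a rectangle with the
  square's mpd and an equal bottom side *is* the square, a rhombus's mpd
  is strictly below the square's at equal side length, and solving a
  kite or parallelogram for mpd at a fixed bottom side collapses it
  toward the rhombus, destroying its intended feature signature.
  Since the feature predicates are similarity-invariant, uniform
  rescaling never perturbs a frozen family's features.

The frozen coordinates were tuned so that each family carries exactly
its intended feature set at the default 12.5% tolerance with at least
~30% slack on every predicate threshold, giving the regularity ranking
square 18 > rectangle 14 > losange 10 > parallelogram 6 > rightKite 5 >
isoTrapezoid 4 > kite 3 > rightHinge 2 > hinge 1 = trapezoid 1 >
random 0. The irregular family is a frozen vertex set selected by
randomized search (generator seed 7) to carry zero features with
maximal slack.

Deviants displace the bottom-right corner (canonical index 1) by
45% of the shape's mpd in one of four diagonal directions (±45°, ±135°
from the canonical x-axis; the four directions are a design choice —
only their number is constrained). A deviant that self-intersects is
rejected with an explicit error so the caller can try another direction.

## Geometric feature model

Each quadrilateral is coded by 22 boolean predicates: 4 right angles,
6 equal-angle pairs, 6 equal-side pairs, 6 parallel-side pairs, all
evaluated at a dimensionless tolerance τ (default 0.125). The
normalization of τ is a design decision: right angles are tested as
|θ − 90°| ≤ τ·90°, pairwise equalities relative to the pair mean, and
parallelism as an undirected direction difference (mod 180°) ≤ τ·90°.
These choices are scale- and rotation-invariant and reduce to exact
predicates as τ → 0; feature sets are nested in τ. Sides sharing a
vertex meet and are never counted as parallel.

Shape dissimilarity is the Hamming distance between feature vectors
("features not in common"). An alternative reading — the absolute
difference of feature counts — is available via
`feature_dissimilarity(..., metric="count-difference")`; the two
coincide whenever one feature set contains the other, which holds along
the main regularity gradient. Hamming is the default because the
count-difference reading makes two very different shapes with equal
counts spuriously identical.

## Behavioral dissimilarity

A visual-search trial records participant, reference shape, intruder
shape, accuracy and response time. The dissimilarity of an ordered pair
is mean accuracy divided by mean RT (units 1/ms): easy search — accurate
and fast — means dissimilar shapes. Ordered estimates are averaged into
the unordered cell and the 55 unordered entries are z-scored. When
pooling across participants, pooling precedes the ratio (ratio of
pooled means). RT averages include error trials by default (the ratio
is defined without exclusions; a switch restricts to correct trials).
Single-participant cells with a lone trial are 0 or 1/RT and are kept
for per-participant analyses, never z-scored per participant.

RDM regression is ordinary least squares with intercept on the
vectorized unordered entries. MDS is non-metric (ordinal), 32 seeded
random restarts, best normalized stress kept. The projection of a
per-shape property (e.g. the regularity count) onto the MDS plane is a
regression of the property on the two axes; its significance is
assessed by bootstrap over participants (resample participants with
replacement → re-estimate the RDM → re-embed → Procrustes-align to the
point-estimate configuration → re-project), two-sided. The bootstrap is
one reasonable choice among several for this quantity; no claim is made
that it matches any particular published procedure.

## Crossnobis RSA

The cross-validated Mahalanobis (crossnobis) distance between
conditions i and j is the average over independent fold pairs of
(x_i^m − x_j^m)ᵀ Σ⁻¹ (x_i^n − x_j^n) / P, with P the channel count.
Two schemes are provided: all ordered fold pairs, and leave-one-out
(each fold against the mean of the others; the default for temporal
RSA). Both are unbiased — within-condition distances have expectation
zero and estimates may be negative; negative values are never clipped.
Division by P is a normalization convention, switchable.

The noise covariance Σ is estimated from residuals by shrinkage toward
the sample diagonal with a Ledoit–Wolf-style analytic weight (λ = 1
keeps the diagonal; absent residuals give the identity, reducing
Mahalanobis to Euclidean distance). A small trace-scaled jitter
guarantees positive definiteness for inversion.

Whitened RDM comparison multiplies both RDM vectors by the matrix
square root of the empirical RDM's entry-precision estimate before
Pearson correlation; identity precision reduces to plain Pearson. The
entry precision, when requested, is a diagonal estimate from
leave-one-fold-out resampling of the crossnobis RDM — the simplest
estimator consistent with entry whitening; equivalence with any
specific toolbox estimator is not claimed. Model RDMs are compared to
the empirical series one at a time (no cross-model partialling), which
is appropriate when the model RDMs are close to orthogonal.

## Oddball decoding

Epochs span −150…+1150 ms around stimulus onset (250 Hz by default; the
simulations in the test-suite use 125 Hz to halve the cost without
changing any contract). The first six epochs of each 30-item miniblock
are discarded (they can never be oddballs, and at a block transition
they act as oddballs of the previous block's shape). Each epoch is
normalized before fitting — by default z-scored across channels at each
timepoint (a whole-window variant is provided; which normalization is
"right" is underdetermined, so both exist and the per-timepoint variant
is the default).

Cross-validation uses three fixed partitions of the 8 runs — even vs
odd, first vs second half, {1,2,5,6} vs {3,4,7,8} — each applied in
both directions, i.e. 6 train/test splits with disjoint run sets, so
slow signal autocorrelation cannot leak across folds. A logistic
regression (small fixed L2 penalty, C = 1, for stability on separable
timepoints) is trained per timepoint on all shapes pooled (or per shape
with `per_shape_training`) and tested per shape; the score is the ROC
AUC, computed by the rank-sum identity (imbalance-robust: there are 4
oddballs per 24 retained items). Test cells with a single class are
NaN and propagate as missing, never imputed as 0.5.

Decoding time courses are optionally smoothed with a centered 100 ms
uniform window (truncated at the edges). The regularity correlation is
a per-participant Pearson r between per-shape AUC and the regularity
count at each timepoint, followed by the one-tailed sign-flip cluster
test (2^13 permutations, cluster-forming p < 0.05). The latency
statistic is the first post-onset timepoint where a shape's smoothed
AUC exceeds 0.57; shapes that never cross are excluded, participants
with fewer than three defined latencies are dropped with a warning, and
the group test is a one-tailed t-test of per-participant
latency-on-regularity slopes against zero in the direction "more
regular → earlier".

## Cluster-based permutation inference

Temporal: one-sample t per timepoint across participants; clusters are
maximal runs above the cluster-forming threshold (p < 0.05 one-tailed
on t); cluster mass is the sum of t values; the null is built by
randomly flipping the sign of each participant's whole series, and the
corrected p is k/N — the count of permutation maximum masses at or
above the observed mass over the number of permutations, with the
observed statistic not re-added to the null (so 3 exceedances of
10,000 swaps give exactly 0.0003). Sign flips leave per-participant
sums of squares unchanged, so the permuted t statistics are computed in
closed form from flipped means — the permutation loop is fully
vectorized. Zero-variance timepoints have undefined t and are excluded
from clusters. An exact mode enumerates all 2^n sign patterns for
small n, matching the exhaustive randomization distribution.

Spatial: voxelwise one-sample t, cluster-forming threshold p < 0.001
(one- or two-tailed per caller; RSA maps are tested one-tailed since
negative model correlations are not interpreted), contiguity by
6-connectivity (18/26 switchable), mass = sum of t, 10,000 sign swaps
by default. t-sum mass is used for temporal clusters as well, matching
the spatial definition.

## Searchlight RSA

Spheres are built in voxel units with a strict norm inequality —
radius 3 gives exactly 93 voxels including the center (the non-strict
variant would give 123, inconsistent with that count). Centers are
in-mask voxels with strictly more than 50% of their sphere inside the
mask; out-of-volume voxels count as outside. Per sphere, a
leave-one-out crossnobis RDM across runs (identity noise covariance) is
correlated with each model RDM; the value is assigned to the center;
discarded centers and zero-variance spheres are NaN. Group maps can be
smoothed with a mask-aware Gaussian (σ = fwhm / (2√(2 ln 2)); missing
values are excluded from the kernels and the result renormalized, so a
constant map is unchanged). The subject-specific ROI estimator selects
the top 10% of ROI voxels by one run's contrast and averages responses
from the remaining runs, looping over selection runs, so selection and
estimation data are always disjoint.

The searchlight operates on volumes; surface or sensor neighborhoods
can be expressed by providing per-location pattern subsets directly to
the crossnobis functions.

## Synthetic data: what is emulated, and what is not

The generators plant a known representational structure so every
analysis stage has a recoverable ground truth.

**Designs.** Miniblocks have 30 items and 4 oddballs; oddballs never
occupy the first six positions and never occur twice in a row; valid
placements are sampled uniformly (rejection sampling). Runs present one
miniblock per shape in random order. Intruder displays place six shapes
on two half-circles (radius 120 px, shifted ±100 px) with
without-replacement scale/rotation sampling from the six-value sets;
the intruder slot never repeats across consecutive displays. The
online search task enumerates all 110 ordered shape pairs per
participant with the original ordering constraints (no repeated
reference on consecutive trials; an intruder never equals the previous
reference). The in-trial 20% size ramp of the presentation is recorded
nowhere in the signals because no analysis consumes it.

**Behavior.** One trial per ordered pair per participant.
P(correct) = logistic(1.2·d + 1.0) and RT = exp(log 1500 − 0.25·d + ε),
ε ~ N(0, 0.3²), with d the z-scored ground-truth dissimilarity. These
defaults give ~60–95% accuracy and 1–2.5 s RTs over the stimulus range,
the regime of the online task; they were chosen once, on that
plausibility argument.

**Epochs.** Condition patterns realize a model RDM via classical MDS:
RDM entries are treated as squared Euclidean distances, the
double-centered Gram matrix is eigendecomposed, and the configuration
is rotated into channel space by a random orthogonal map — exact for
Euclidean-realizable RDMs (Hamming distances of binary feature vectors
are squared Euclidean distances, so the feature model embeds exactly).
Geometry A is active in an early window (60–320 ms), geometry B in a
late window (128–400 ms), as boxcars. Oddball epochs add a deviance
component along a common random channel direction with amplitude
1 + 0.15·regularity and onset 260 − 5·regularity ms (300 ms duration):
more regular shapes yield larger and earlier deviance responses.
Channel noise is Gaussian with a random SPD spatial covariance
(condition number ≤ 10, trace-normalized); the pattern RMS amplitude
relative to unit channel noise is the SNR parameter, default 0.5 — a
moderate single-epoch pattern SNR at which participant-level window
correlations land around 0.5–0.8, the order seen in sensor RSA.

Not emulated: biophysical forward models, temporal autocorrelation of
noise, eye/cardiac artifacts, the size ramp, evoked transients. Passing
recovery tests therefore show the analysis code is correct and the
inference calibrated — not that real MEG data will show these effects.

**Beta volumes.** Two disjoint regions on a masked grid carry patterns
realizing two model RDMs (same classical-MDS construction in voxel
space, low-dimensional, so every sphere inside a region carries the
same geometry); all other voxels are noise; runs have independent
noise; subjects redraw patterns and noise. Default pattern SNR is 0.25
of the voxel noise SD — run-level beta patterns are weak, and this
value puts searchlight model correlations near 0.5 in coding regions,
the order reported in fMRI RSA. No haemodynamics, spatial noise
correlations or inter-subject anatomical variability are simulated.

## Desk-scale study conditions

The recovery suites run at a reduced scale chosen as the package's own
simulation design: 16 channels, 125 Hz, 4 runs (8 where the decoding
fold scheme requires them), cohorts of 10–20 participants, 20 cohorts
for rate estimates, 20³ voxel grids with 8³ planted regions, 10
subjects. Inference settings match the full-scale analyses (2^13
temporal permutations, 10,000 spatial swaps, thresholds as above).

## Known limitations

* The exact vertex coordinates of the original 11 shapes are not
  published as numbers; the families here satisfy the same matching
  constraints and feature signatures but are not claimed to be
  numerically identical to the originals.
* Whether the original deviant directions were diagonal or axis-aligned
  is unknown; diagonal is this package's convention.
* The entry-precision estimator for whitened correlation is a diagonal
  approximation; full covariance whitening of RDM entries is not
  implemented.
* The sign-flip null assumes per-participant distributions symmetric
  around zero under H0; calibration is verified for that case only.
* Nonmetric MDS is non-convex; determinism is guaranteed only through
  the seeded restart list.
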