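# Methods notes

## The analysis model

The pipeline treats a verbal-fluency block as a sequence of word events at
a metronome pace (default 0.75 words/s) over a fixed 12-item vocabulary,
with gaze sampled continuously (default 1000 Hz) in screen pixels, origin
top-left with y increasing downward. The only preprocessing is exclusion:
samples flagged invalid (blinks, off-screen losses) are dropped; there is
no filtering, smoothing, interpolation or detrending, because the effects
of interest are expected in raw spontaneous gaze and any correction risks
manufacturing or destroying small biases.

Each trial is summarized by the median gaze position over the valid samples
in the half-open window [onset − 500 ms, onset). The median (not the mean)
is used for robustness to residual outliers. A trial with fewer than
`min_samples` valid samples (default 10, i.e. 10 ms of data at 1 kHz) is
invalid. Transitions are formed only between trials adjacent in utterance
order within one block; if either member is invalid the transition is
dropped rather than bridged, since bridging across a lost trial would
fabricate long displacements that no saccade produced.

Per-subject inference uses Spearman rank correlations: the displacement
distributions are heavy-tailed mixtures of fixational jitter and saccades,
and rank correlation is invariant to any monotone recalibration of pixel
units. A Pearson option exists for sensitivity checks. Group inference
operates on Fisher z = atanh ρ, which is variance-stabilizing and makes the
per-subject values approximately normal; degrees of freedom are
n_subjects − 1 (one-sample) or pairs − 1 (paired).

The JZS Bayes factor is the default objective Bayes factor for a one-sample
t test: a Cauchy(0, r) prior on the standardized effect δ with r = √2⁄2,
evaluated through the inverse-gamma mixture representation
(g ~ InvGamma(1/2, r²/2)) by adaptive quadrature on (0, ∞) in log space.
It agrees with pingouin's implementation to four significant digits over
the tested range and is monotone in |t| at fixed n. Quadrature failure
(relative error above 1e−4) raises rather than returning a dubious number.

## Conceptual distance models

* **Numbers.** The change between consecutive trials is the signed integer
  difference; modes decompose it into sign-only, magnitude-only and
  combined variants. For the 2D displacement axis the conceptual change is
  used unsigned, since a non-negative Euclidean displacement cannot
  coherently pair with a signed quantity.
* **Colors.** Each subject's color space is rebuilt from their own 1–9
  similarity ratings: ratings are pooled over repetitions and both
  presentation orders, dissimilarity is 10 − mean rating (the same inverse
  transform used for external similarity matrices; the alternative 9 − s
  differs only by an additive constant, which classical MDS double-centering
  removes, so the choice is inconsequential), and classical (Torgerson)
  MDS embeds the matrix: double-center the squared dissimilarities,
  eigendecompose, keep the top two non-negative eigenvalues. Negative
  eigenvalues — non-Euclidean noise in judgments — are clipped to zero,
  the standard classical-MDS treatment. If fewer positive eigenvalues than
  requested dimensions exist, missing columns are zero-padded with a
  warning.
* **Animals.** Five interchangeable models: cosine distance between word
  embedding vectors (word2vec text format); binary cluster jumps (1 iff
  consecutive words share no semantic label; a graded shared-label variant
  is available behind a flag but binary is the default); externally rated
  similarity consumed as a labeled CSV matrix and inverted as 10 − rating
  (repeated ratings are averaged before inversion); Euclidean distance
  along the first principal component of the centered (not scaled)
  embedding matrix; and the unsigned difference in word frequency, used
  exactly as supplied with no log transform. Transition counts (how often
  the exact ordered word pair occurs across a subject's blocks) serve as a
  control covariate, correlated against unsigned displacement.

## Geometry recovery

Absolute-position analyses average per-trial medians within concept, then:
(i) regress mean horizontal position on numerical value per subject and
test the per-subject slopes against zero; (ii) compute the matrix of
pairwise Euclidean distances between concept-specific fixation points and
correlate its strictly-lower triangle with the conceptual distance matrix
(RSA; the diagonal is excluded as in standard representational-similarity
practice); (iii) reconstruct a group-level space by scaling each subject's
fixation-distance matrix to unit mean off-diagonal entry, averaging
entrywise, and embedding with classical MDS. Distances are averaged rather
than coordinates because each subject's visual frame is an arbitrary
isometry of the conceptual space — coordinate averaging without prior
alignment would cancel the structure. Procrustes disparity (optimal
translation + uniform scale + rotation/reflection, normalized residual)
quantifies shape agreement, since MDS output is defined only up to
isometry.

## Decoding

The classifier is a two-class LDA with pooled within-class covariance,
equal priors, and a ridge of 1e−6 · trace/d on the diagonal for numerical
stability; ties break toward the lexicographically smaller label so
predictions are deterministic. Cross-validation is leave-one-trial-out; in
every fold the majority class of the training set is downsampled without
replacement (seeded) to the minority size, so chance is exactly 1/2 even
with unbalanced label counts (upsampling is available behind a flag).
Significance comes from rerunning the entire procedure — fresh balancing
included — under label permutations; p = count(permuted ≥ observed)/n_perm
exactly as defined, with an optional (count+1)/(n_perm+1) estimator that
avoids zero p values. Numbers are decoded as small (1–6) vs large (7–12)
from the horizontal coordinate only; colors are decoded for every
unordered pair from both coordinates, the 12×12 matrix is explicitly
symmetrized, and the overall accuracy is the lower-triangle mean.

## The synthetic generator

`synthgaze` emulates the statistical structure the analyses rely on, not
oculomotor physiology. Words are drawn uniformly (immediate repeats
allowed; a no-repeat flag exists). Onsets are exactly metronome-spaced. In
each pre-onset window the gaze sits at an affine image of the coupling-
scaled latent coordinate plus a per-trial Gaussian offset (`noise_sd`),
with a small fixed-fraction within-window jitter; between windows the gaze
follows a Gaussian random walk (`drift_sd` per sample) anchored at the
previous fixation, clipped to the screen. `noise_sd` is deliberately a
*per-trial* scatter: purely per-sample noise would be averaged away by the
~500-sample median and make the noise dial meaningless. Blinks are
contiguous invalid runs with geometric lengths calibrated so the expected
invalid fraction equals the requested rate.

Latent geometries: numbers are the integers 1–12 on a line; colors are 12
equally spaced points on the unit circle, with a random per-subject
rotation/reflection applied through the affine map because the color wheel
is defined only up to isometry; animal words carry log-uniform (Zipf-like)
frequency values, and the embedded effect places the horizontal target at
the unsigned frequency difference from the previous word, matching the
direction of the reported effect (small transition → left, large → right).
The truth table nevertheless records the per-label frequency values, so
ground truth is exactly retained per label in every domain.

Cohort defaults are chosen to mimic the published effect sizes: coupling
6.5 px per number unit (the reported number-line slope is ≈6.5 px/unit)
with `noise_sd` = 85 px, which together give per-subject horizontal
correlations of roughly ρ ≈ 0.2 at 90 trials; the color ring spans 150 px
on screen; the animal frequency coupling is 0.1 px per frequency unit.
Similarity judgments add Gaussian noise (sd 0.8 rating points) before
rounding and clipping to 1–9.

What the generator does *not* emulate: saccade kinematics (main-sequence
velocity profiles), pupil dynamics, calibration drift, serial dependence in
word choice, or subject-specific response lags. Passing tests therefore
demonstrate that the pipeline recovers embedded geometry from data with the
right covariance structure — not that real gaze has that structure.

## Problem sizes and numerical choices

Simulation-based tests use 90-trial blocks at 1000 Hz (the experimental
pacing), cohorts of 20–30 subjects, 100 cohorts for power/false-positive
checks, 1000 permutations for decoder calibration, and 24-block subjects
for dense-sampling decoding; these sizes make all Monte-Carlo margins wide
relative to their thresholds while keeping the default suite fast.
Deterministic tolerances (Procrustes < 1e−6 on exact inputs, oracle
agreement at 1e−10–1e−12) reflect pure floating-point error. All
randomness flows through explicit integer seeds via numpy Generators; the
same configuration and seed reproduce byte-identical outputs, and the
runner writes a manifest of SHA-256 content hashes to make this checkable.

## Known limitations

* Ingest mode expects the package's own bundle layout (events.csv +
  per-block TSVs); proprietary tracker formats must be converted upstream.
* The first-order partial Spearman correlation raises on a control that is
  rank-identical to either variable (the formula is 0/0 there).
* Group-level inference is a fixed-effects t on Fisher-z values; no
  hierarchical or mixed-effects alternatives are provided.
* The LDA is strictly two-class and 1–2 dimensional by design, matching
  the analyses it serves.
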