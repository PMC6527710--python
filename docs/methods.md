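# Methods

This note documents the models, statistics and numerical choices behind
`megrwa`, in the spirit of the methods documentation that accompanies
packages such as statsmodels or mne-python.

## The analysis problem

Object vision engages several stimulus descriptions at once — low-level
spectral content, object shape, and semantic category — and these
descriptions are *collinear*: objects of one category tend to share both
silhouettes and spectral signatures.  `megrwa` asks, for every point of a
sensor-space MEG map, how the local representational geometry apportions
among three model geometries when their shared variance is accounted for.
The pipeline is:

1. build one representational dissimilarity matrix (RDM) per feature
   model over the stimulus set;
2. collapse epoched MEG trials to one pseudo-trial per stimulus and
   compute a neural RDM inside every spatiotemporal searchlight;
3. apportion each neural RDM's explained variance among the model RDMs
   with Relative Weights Analysis (RWA);
4. test the subject-level weight maps at the group level with a
   sign-flip permutation test corrected by threshold-free cluster
   enhancement (TFCE).

## Feature models

**Low-level (GIST).**  Images are converted to grayscale (ITU-R 601
luminance weights), resized to 256 × 256, and optionally local-contrast
normalized (whitening followed by divisive normalization by local
energy; on by default).  A bank of oriented log-Gabor filters — 4 scales
an octave apart (center frequencies 0.25 … 0.03125 cycles/pixel) × 8
orientations — is applied in the frequency domain; squared response
magnitudes are averaged in a 4 × 4 grid, giving 4 × 8 × 16 = 512
features.  A note on filter terminology: a literally *isotropic* filter
has no orientation preference, so an oriented bank is the only reading
under which "8 orientations" is meaningful; we implement standard
oriented log-Gabors.  Descriptors are z-scored (unit-norm available) and
compared with the correlation distance 1 − Pearson's r.  With
local-contrast normalization the descriptor is invariant to adding a
constant to the image; zero-variance descriptors get distance 1 to
everything (logged) so RDMs stay finite.

**Shape (medial axis).**  Each binary silhouette is thinned to its
medial axis with distance-transform radii.  Discrete thinning emits
hairline spurs wherever boundary pixelation creates a locally maximal
disc; we prune points whose maximal disc is contained in an
already-kept larger disc up to 0.5 px (greedy by decreasing radius).
Branch topology (endpoint/junction labeling) is taken from the raw
thinned skeleton.  Pairwise shape dissimilarity is a **skeletal
deformation-cost proxy**: the historical shock-graph edit-distance
matchers are closed external programs, so we ship our own measure with
the same intent.  Skeletons are normalized for translation (centroid)
and scale (RMS of point spread and radii) and compared by a symmetric
Chamfer distance in (x, y, radius) space, with each point's
contribution weighted by its inscribed radius — deforming a thick trunk
costs more than trimming a thin spur — plus a penalty of 0.05 × the
normalized branch-count difference.  The measure is symmetric,
non-negative, zero for identical shapes, and equivariant under 90°
rotations up to discretization.  It is *not* numerically interchangeable
with shock-graph edit distances; it is a documented stand-in that
preserves their ordinal behaviour on simple shapes (a five-pointed star
deforms a disc more than a mild ellipse does).

**Category.**  Binary: 0 for same-category pairs, 1 otherwise.

Model collinearity is summarized by Spearman rank correlation between
vectorized RDMs (constant vectors reported as missing with a warning).

## Preprocessing

4th-order Butterworth band-pass (1–80 Hz) plus 4th-order band-stop notch
(48–52 Hz; a "50 Hz notch" without a stated bandwidth), applied
forward–backward.  Zero-phase filtering is the standard choice for MEG
epochs; it doubles the effective order, which is why the 200 Hz
stop-band test expects the squared 4th-order response.  Epochs span
−0.5 to +1.0 s around onset, **half-open at the right edge**, and are
resampled to 400 Hz by polyphase anti-alias filtering: exactly 600
samples per epoch, no off-by-one ambiguity.  Interactive artifact
screening is replaced by summary statistics (range, variance, max |amp|,
max z) with a reproducible flagging rule (default: any statistic above
median + 5 MAD).  Bad sensors are rebuilt as the inverse-distance
weighted mean of their nearest good neighbours.  Trials are averaged
into one pseudo-trial per stimulus.

## Searchlight

A searchlight at (sensor, time) contains the k = 10 nearest sensors
including the center (count semantics, matching count-based neighborhood
definitions in MVPA toolboxes; the alternative center + 10 reading would
give 11) and the center sample ± 10 samples — 21 samples, 52.5 ms at
400 Hz — truncated at epoch edges rather than skipped.  Stimulus
patterns (sensor set × window, flattened) are z-scored per stimulus and
compared with the correlation distance; for 30 stimuli each searchlight
yields a 435-vector.

## Relative Weights Analysis

For standardized outcome y (a vectorized neural RDM) and standardized
predictors X (the p = 3 vectorized model RDMs), RWA computes

&nbsp;&nbsp;&nbsp;&nbsp;ε_j = Σ_k λ²_jk β²_k,

where β_k is the correlation of y with the k-th orthogonal variable and
λ_jk the correlation of predictor j with it.  The default orthogonal
counterpart is the **best-fitting orthogonal approximation** Z = P Qᵀ
from the SVD X = P Δ Qᵀ (the closer Z is to X, the more interpretable
the weights).  With this choice the λ-matrix columns have unit norm, so
the weights partition the total explained variance exactly:
Σ_j ε_j = R² of the OLS fit of y on X.  A PCA-scores orthogonalization
is selectable by config; it satisfies the same ε formula but its column
norms equal the eigenvalues of the predictor correlation matrix, so the
exact partition identity is specific to the default.  Outcome and
predictors are always standardized per searchlight (required for the
partition identity); an optional rank transform is off by default since
the RDMs are regressed directly.  Rank-deficient predictor sets raise an
error naming the collinear columns.

## Group statistics

ε is a sum of squares and therefore non-negative; a one-sample test
"against zero" would be degenerate.  Each subject's map is first
centered on a **chance baseline**: the mean ε over (default) 100 random
stimulus relabelings of the neural RDM, computed per searchlight.  A
`baseline: none` option skips this.  The group test is a one-sample
sign-flip permutation test on the centered maps using the normalized
Wilcoxon signed-rank statistic per point; when 2^n_subjects does not
exceed the requested 100,000 permutations (n ≤ 16), all sign flips are
enumerated and the test is exact (logged).  Each permuted map is
TFCE-transformed,

&nbsp;&nbsp;&nbsp;&nbsp;TFCE(v) = Σ_h e(h)^E · h^H · dh,&nbsp;&nbsp;E = 0.5, H = 2, dh = max/100,

over the (sensor-graph × time) adjacency (mutualized 4-nearest-neighbour
sensor graph; consecutive samples in time); corrected one-tailed
p-values come from the permutation distribution of the map maximum, and
z = Φ⁻¹(1 − p) clipped to the resolution of the permutation
distribution so maps stay finite.  The TFCE parameters are the canonical
defaults of the method.  For display, time is divided into 50-ms bins
and a sensor is reported for a bin only if significant at *every* sample
inside it.

TFCE is computed incrementally: thresholds are swept downward while a
union-find grows the supra-threshold clusters, so the cost is
O(steps × nodes + edges) rather than a full relabeling per threshold;
the implementation is verified against an explicit threshold-sweep
oracle.

## Synthetic data generator

The generator emulates the study conditions end to end: 30 stimuli in 6
categories of 5; each picture presented 24 times (8 runs × 3 blocks,
every picture once per block, block order randomized); multi-subject
sensor × time epochs at 400 Hz on a quasi-uniform head-disc layout
(negative y = posterior).

*Stimuli* are parametric silhouettes (blob, bar, star, cross, ring,
wedge) filled with an oriented grating texture.  Category couples to
both the silhouette family and the texture's orientation/frequency with
probability `category_strength` (default 0.5), which places the pairwise
model rank correlations in the weak regime (≈ 0.05–0.15) characteristic
of natural object photographs; colour tints are drawn per stimulus,
independent of category, so luminance carries no categorical signal.
Within-category jitter perturbs all shape and texture parameters.
`collinear=False` decouples the assignments entirely.

*Planted signal.*  For each model RDM D the similarity C = 1 − D is
eigendecomposed, negative eigenvalues clipped (D need not be Euclidean;
the clipped mass is reported as a distortion figure), and rows
renormalized, giving a factor L with L Lᵀ ≈ C.  Model RDMs are first
variance-equalized (off-diagonals rescaled to mean 1, sd 0.3) so the
planted weight vector is expressed on a common scale — without this, a
model whose raw RDM has larger dispersion would dominate the mixture
regardless of its weight.  Every planted feature (sensor-time point
inside a plant) receives, per model and subject, an independent Gaussian
loading g, contributing √w_j (L g) to the stimulus-indexed signal; the
across-stimulus correlation of the planted patterns therefore equals
Σ w_j C_j / Σ w_j in expectation, and i.i.d. Gaussian sensor noise is
added per trial.  An exact embedding on disjoint orthonormal basis rows
(`exact_mixture_patterns`) reproduces the mixture correlation to float
precision; it serves as the construction oracle in tests and, via
`PlantedSignalSpec(exact_geometry=True)`, as a deterministic planting
mode in which a searchlight that fully covers the plant recovers the
planted ranking exactly.  With the stochastic default, searchlights
that only partially overlap a plant see a random subsample of the
feature loadings, so their *individual* weight orderings carry sampling
noise even without sensor noise; ordering recovery is therefore
assessed on group-mean maps (stochastic mode) or at fully covering
searchlights (exact mode).

*What the generator does not emulate:* 1/f spectra, sensor covariance,
forward-model field spread, head movement, eye/heart artifacts, or any
behavioural/semantic structure.  Passing tests on this generator
demonstrates that the estimator and inference chain recover planted
representational structure and control false positives under white
noise — not that they would detect any particular effect in real
recordings.

## Experiment scales and expected outcomes

The recovery experiment plants w = (0.5, 0.3, 0.2) in the 10 most
posterior of 30 sensors at 100–150 ms (epochs −0.2 … 0.4 s, 8 subjects,
24 trials/stimulus, unit noise).  Because the mixture similarity enters
the RWA outcome linearly but ε is quadratic in the coefficients, the
recovered group-mean weights compress toward (w̄²) — the *ordering*, not
the magnitudes, is the planted quantity being recovered, and it is
recovered at 100% of directly planted searchlights at these settings.
False positives are counted over searchlights whose sensor set and time
window share no feature with the plant; searchlights that overlap the
plant genuinely contain planted signal and are excluded from that count.

The type-I experiment runs 200 noise-only replicates (6 subjects, 20
sensors, epochs −0.05 … 0.15 s, 4 trials/stimulus, 1000 requested
permutations → 64 exhaustive sign flips).  With exhaustive enumeration
the corrected test is exact, so the family-wise error should sit at or
below α = 0.05 up to binomial noise.

These problem sizes are the package's own experiment designs; all of
them are plain `RunConfig` settings and scale up freely.

## Numerical choices and edge cases

- Standardization uses the population convention (ddof = 0) throughout.
- Zero-variance patterns or descriptors → correlation distance 1,
  logged; constant outcome RDMs → ε = 0 with a warning.
- Orthogonalization raises on rank-deficient X, naming the collinear
  columns; PCA eigenvector signs are arbitrary (weights use squares, so
  results are unaffected).
- Epoch windows are half-open; temporal searchlight windows truncate at
  edges; 50-ms bins align to multiples of 50 ms and use only samples
  falling inside them.
- All randomness flows from one seed via `numpy.random.SeedSequence`
  spawning; thinning tie-breaks are pinned; HDF5 writes disable
  timestamp tracking — two runs with the same config and seed are
  byte-identical.

## Known limitations

- The shape dissimilarity is a proxy, not a shock-graph edit distance;
  absolute values are not comparable to historical matchers.
- The chance-centered ε is mildly right-skewed, while the sign-flip
  test assumes symmetry under the null; with the signed-rank statistic
  the residual miscalibration is small (and bounded empirically by the
  type-I experiment), but it is not exactly zero.
- The PCA orthogonalization option does not preserve the exact variance
  partition (see above).
- Searchlight temporal smoothing (±10 samples) spreads genuine effects
  up to 26 ms beyond their true extent; binned displays inherit this.
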