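# Methods

This note documents the estimators, generative models and numerical
choices implemented in `crossgen`, including the decisions made where the
underlying methodology leaves details open.

## Cross-validated distances

**Estimator.** Information within a context is the two-fold
cross-validated Mahalanobis distance: trials are split into two halves,
stratified by class, by a seeded random permutation; for each ordering of
the two folds the class-1-minus-class-2 mean difference of the training
fold is multiplied through `Σ⁻¹` with the test fold's difference, and the
two orderings are averaged. Cross-context generalization pairs the
training half of one context with the test half of the other, in both
directions; the statistic is symmetric in the two contexts. Because the
noise in train and test differences is independent, both statistics are
unbiased — zero expectation under no class difference (within-context) or
orthogonal representations (cross-context) — and can be negative. No
normalization by channel or trial count is applied anywhere.

**Noise covariance.** The methodology needs a channel covariance but does
not prescribe an estimator. We use the sample covariance of within-class
residuals (trials minus their class mean, per time point for time-resolved
data), pooled over classes — and over both contexts for cross-context
distances, since a single metric must apply to both difference vectors —
with pooled degrees of freedom `Σ_g (n_g − 1)` and diagonal-loading
shrinkage `(1−γ)·S + γ·diag(S)`. Default `γ = 0.05`, which keeps the
matrix invertible from ~10 sensors up to 272 and perturbs the metric
negligibly when `S` is well conditioned. A singular covariance raises an
error that points at the shrinkage parameter rather than failing opaquely.

## Expected generalization under identity

Two representations are *identical* when their class-difference vectors
are collinear; their lengths — and hence their information values — may
still differ. For unbiased bilinear statistics the expected cross-context
product under identity is the geometric mean `√(I_A · I_B)` of the two
within-context values. We plug in the cross-validated estimates, clamping
negative values to zero before the square root (returning 0 if either
input is ≤ 0). The clamp is the conservative choice: it preserves the
estimate's character as a lower bound on the true generalization, which is
what the one-tailed identity test needs. The identity-null logic survives
spatial mixing because mixing can only increase measured similarity:
rejecting identity at the sensor level implies non-identity at the neural
level. The converse inference (evidence *for* identity) is not available —
the estimate is a lower bound, not a calibrated null.

The bias of the estimate, `(estimated − true) / true`, is validated by
simulation (`identity_simulation_study`): two contexts share a collinear
difference vector with squared Mahalanobis lengths `(M_A, M_B)` under unit
noise covariance; fold-mean differences are sampled directly with
covariance `(8/n_trials)·I`. With identity enforced, spatial mixing acts
identically on both contexts and drops out of the bias question, so the
study runs at the measurement level with a known metric. The mean bias is
≤ 0 at every SNR, below 0.5% in magnitude at `M = 4` with 1000 trials, and
grows as `M` shrinks (the clamp engages more often); with unequal SNR
(4 vs 0.25) the conventional `min(I_A, I_B)` reference is biased by about
−75% while the geometric mean stays near zero bias.

**Non-commutativity.** The expectation is computed per replicate and only
then averaged. The reverse order (geometric mean of group-averaged
information) over-estimates whenever the `I_A/I_B` ratio varies across
replicates, inflating false positives of the identity test; the API does
not expose the commuted variant, and a regression test pins the ordering.

**Relative generalization** is `empirical / expected`, reported as NaN
whenever the expectation is not positive; group summaries are NaN-aware
and report how many cells were excluded.

## Sensor-mixing simulation

The generative model for the false-positive-rate study:

- 100 neurons; each context's class-difference weights occupy a random
  half of them, the two halves disjoint, so the neuron-level
  representations are exactly orthogonal and *every* significant
  generalization is a false positive. (Subset sizes are not prescribed by
  the methodology; the even split is the symmetric choice.)
- Selective weights have half-normal magnitudes; the sign is +1 with
  probability `(1+u)/2`, so uniformity `u = 1` makes every selective
  neuron prefer class 1 and `u = 0` makes signs symmetric.
- Across the 20 repetitions (subjects) of a run, weights are the
  variance-preserving mixture `√s·shared + √(1−s)·individual`, giving
  across-repetition weight correlation ≈ `s`, bit-identical patterns at
  `s = 1` and independent patterns at `s = 0`. Selective sets and the
  shared component are drawn once per run.
- Trials (1000 per context, balanced classes) are `±scale·pattern/2` plus
  unit Gaussian neuron noise, spatially mixed into 10 sensors by Gaussian
  kernels over the neuron index (SD 25 neurons, rows normalized to unit
  sum).
- Analysis at the sensor level: pooled shrunk covariance, two-fold
  crossnobis cross-context generalization per repetition, two-tailed
  one-sample t-test across repetitions at `p < 0.05` (two-tailed, so both
  generalization and reversals count), repeated over `n_runs` runs; the
  false-positive rate is reported with its exact (Clopper–Pearson)
  binomial 95% CI.

**SNR calibration.** Each SNR condition is defined by its average
*sensor-level* crossnobis distance (the level at which the analysis runs).
The signal scale is found by monotone bisection on Monte-Carlo estimates
with common random numbers — a probe of 400 repetitions is replayed at
every candidate scale, making the probe distance a deterministic,
monotone function of scale — to a relative tolerance of 5%.

**Implementation.** The engine samples sensor noise directly from
`N(0, Mix·Mixᵀ)` via the symmetric matrix square root — exactly the
distribution of mixed i.i.d. neuron noise — and computes fold statistics
from a fixed trial layout (valid because i.i.d. noise is exchangeable).
A test verifies the vectorised engine against the public per-TrialSet
pipeline to 1e−10 on identical draws. An identity-mixing control
(`n_sensors = n_neurons`, identity operator) restores the nominal rate at
full uniformity and stability, isolating mixing as the causal ingredient.

## Forward-model simulation

The second study replaces the abstract mixing kernel with leadfields.
Empirical gain matrices can be supplied as HDF5 containers (`gain`,
`positions`, `area_labels`, attribute `subject_id`); since no empirical
head models ship with the package, a synthetic spherical stand-in is
provided and used by the tests:

- a deterministic Fibonacci lattice of sources (default 600) on a 70 mm
  sphere, parcellated into contiguous areas by seeded k-means on source
  positions — identical across replicates, so "the same representation in
  every subject" is well defined;
- sensors (default 272) on a 110 mm sphere with per-replicate positional
  jitter (6 mm), so leadfields differ across subjects;
- gain `exp(−d²/2σ²)` of source-sensor distance (σ = 40 mm), rows
  L2-normalized. Cross-talk (cosine similarity of gain rows) is 1 for
  coincident sources, decays monotonically with separation on average,
  and never reaches zero — the property that lets spurious generalization
  survive at large distances.

Per run, 10 selective sources per context (a count the methodology leaves
open) receive positive half-normal weights — the uniform regime — in a
chosen pair of areas, disjoint even within a single area, and the same
source pattern is used for every replicate; noise is independent per
source, trial and replicate. Cortical distance is the Euclidean distance
between area centroids (geodesic distance would need a cortical mesh the
stand-in lacks).

Because source noise is i.i.d., the sensor noise covariance is known
exactly (`GᵀG`, plus the same diagonal shrinkage), and the analysis
whitens with it rather than re-estimating a 272×272 matrix per replicate
per run; covariance *estimation* is exercised by the mixing study and the
analysis pipeline. In the whitened space fold-mean differences are
`scale·q + √(8/n)·z` with `q` the whitened sensor pattern, which the
engine samples directly. Calibration is analytic here: the crossnobis
estimator is unbiased, so the expected within-context distance is
`scale²` times the mean whitened-pattern energy of the cell.

Per cell (area pair × SNR) the grid reports the raw false-positive rate of
the two-tailed group test, the mean relative generalization, and the rate
of the combined criterion — significant vs 0 AND not significantly below
the identity expectation (one-tailed paired test). On the synthetic
cohort the raw rate falls from ~1 (same area, high SNR) with distance but
stays above nominal at intermediate distances; the combined criterion
returns the rate to nominal at every nonzero distance for medium/high SNR,
with the expected same-area exception at low SNR. The published
headline numbers for this study (e.g. ~70% false positives at 50 mm)
depend on empirical MRI-based head models that are only available on
request; the synthetic stand-in reproduces the qualitative profile, not
those exact values.

## Group statistics

One-sample and paired t-tests raise on zero-variance samples rather than
returning NaN. Cluster permutation: pointwise t-values thresholded at the
t-quantile of `cluster_alpha` (default 0.05), clusters formed by adjacency
(runs in 1-D; 4-neighbour connectivity in 2-D, 8 optional), cluster mass =
sum of t, null = permutation distribution of the maximum |mass| under
random per-replicate sign flips (default 1000), `p = (1 + #{null ≥
observed}) / (n_perm + 1)` with ties counting toward the null. The
smallest attainable p is `1/(n_perm+1)`; family-wise error on null data is
verified at ~5% by simulation. Two-sided tests form positive and negative
clusters separately against the shared |max| null.

## Time-resolved pipeline and the synthetic example

The analysis model shares one fold assignment across all time points of a
replicate (so cross-temporal products compare like with like) and pools
the noise covariance over time points by default (stabilizing inversion;
a per-time covariance is a straightforward variant). The cross-temporal
matrix's diagonal equals the information time course exactly; the
stable-representation expectation `√(I(t₁)·I(t₂))` is symmetric by
construction, and the empirical-minus-expected difference map feeds the
one-tailed dynamics test.

`synth_meg_example` emulates the structure of a two-hemifield,
two-contrast MEG experiment without claiming its numbers: 19 replicates,
30 channels, 40 time points at 50 Hz (onset at sample 10), 200 trials per
context. Latent class-difference patterns occupy five disjoint,
spatially contiguous blocks of a 100-dimensional source axis — early
context-specific components in adjacent blocks, a late component pair
sharing a common block (cross-context cosine = `late_overlap`, default
0.8) — mixed into channels by Gaussian kernels (SD 4 latent units) that
are *shared across replicates*, plus i.i.d. unit channel noise. The
per-time signal scale is set so the true channel-level crossnobis distance
follows `snr_profile` (default: saturating at 4 after onset). The
adjacency of the early blocks leaks a small, replicate-consistent overlap
into the channels: exactly the mechanism that makes early generalization
group-significant while its relative value stays ≈ 0.2 and the identity
test rejects. The late representation is genuinely shared, with relative
generalization recovering the generating overlap; under
`rotation='dynamic'` the early-to-late rotation produces the
characteristic off-diagonal deficit in the cross-temporal difference map.

What the generator does **not** emulate: temporal autocorrelation of
noise, channel-correlated noise, per-replicate topography variation,
trial-count imbalance, and any preprocessing artefact (e.g. high-pass
filter ringing). Passing tests therefore demonstrate the statistical
machinery and its failure modes under the stated generative assumptions,
not performance on raw recordings.

## Problem sizes and reproducibility

Default study sizes were chosen so each component answers its scientific
question with conventional Monte-Carlo resolution: 1000 runs for baseline
false-positive calibration (binomial 95% CI ≈ ±1.4% at 5%), 200 runs per
grid cell for inflation trends, 500 simulations per bias condition, 100
runs per forward-model cell, 19 replicates matching typical cohort sizes.
All randomness flows from a single root seed through named
`SeedSequence` children, so every result — including the chunked
vectorised engines — is bit-reproducible for a given seed; CLI runs
record the seed, package version, config hash and per-file SHA-256
checksums in a manifest, and refuse to overwrite an existing manifest
without `--force`.

## Known limitations

- The identity expectation is a lower bound; the package deliberately
  offers no Bayesian evidence for identity.
- Classifier-accuracy-based cross-decoding is out of scope: its
  nonlinearity and ceiling break the expectation logic. Cross-validated
  MANOVA and Euclidean variants would slot into the same interfaces but
  are not implemented.
- The synthetic leadfield is a stand-in: spherical geometry, scalar
  (orientation-free) sources, Gaussian gain; quantitative claims about
  specific sensor arrays require supplying empirical leadfields through
  the reader.
- Area parcellation of the stand-in uses k-means on source positions;
  parcel shapes are data-independent but arbitrary.
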