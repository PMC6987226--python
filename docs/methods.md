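# Methods

## Problem and scope

`multifc` quantifies functional connectivity (FC) — the pairwise statistical
dependence between brain regions' BOLD time series — with nine measures
instead of the conventional single Pearson correlation, concatenates them
into a composite multi-metric FC vector, and evaluates the measures with
three pipelines: (1) consistency of binarized connection patterns
(Sørensen-Dice overlap, task-vs-rest and observed-vs-idealized), (2)
two-group classification from vectorized FC features with embedded feature
selection inside nested leave-one-out cross-validation, and (3) alternative
brain configurations derived by clustering each measure's group-mean FC
matrix, validated through brain-behavior regression.

The human fMRI data the design targets (resting-state BOLD, TR = 2.6 s,
~227–231 volumes after discarding equilibration frames, 68 regions in 10
canonical networks) are not publicly available, so the package ships a
synthetic cohort generator with planted ground truth; every quantitative
claim made by the test suite and the acceptance script is about recovery of
planted structure, not about real cohorts.

## The nine measures

For two region signals x, y ∈ R^t:

- **Pearson correlation** (`corr`): cov(x,y) / (σ_x σ_y), in [−1, 1].
- **Cross-correlation** (`xcorr`): both signals demeaned over the full
  record; c(m) = Σ_i x_{i+m} y_i / (‖x̃‖‖ỹ‖) evaluated for |m| ≤ `max_lag`
  (default ⌊t/4⌋). The scalar FC value is the peak magnitude; the lag is
  retained as metadata. Under this normalization c(0) equals Pearson's r
  exactly and the peak is bounded by 1 (Cauchy–Schwarz on sub-records).
- **Coherence** (`coherence`): magnitude-squared coherence
  |P_xy|²/(P_xx P_yy) by segment averaging (Hamming taper, default segment
  2^⌊log2(t/4)⌋, 50 % overlap). At least two averaging segments are
  required — a single segment makes the estimate identically 1. The scalar
  is the peak inside the 0.01–0.1 Hz BOLD band (the preprocessing
  passband); an optional flag falls back to the full band when the band
  holds no bin at the achievable resolution.
- **Wavelet coherence** (`wcoherence`): analytic Morlet transform on scales
  spanning periods 10–100 s (the reciprocal of the band, 8 voices/octave),
  smoothed in time with a scale-proportional Gaussian and across 3 adjacent
  scales with a boxcar, then |S(W_x W_y*)|² / (S(|W_x|²) S(|W_y|²)).
  Smoothing is mandatory: unsmoothed, the ratio is identically 1. Points
  inside the cone of influence (closer than √2·scale to an edge) are
  excluded; the scalar is the peak magnitude over the remaining time-scale
  plane, phase-blind by construction (wcoh(x, −x) = 1).
- **Mutual information** (`mutual_info`): plug-in estimate in nats over a
  rank-binned joint, default 8 near-equiprobable bins. Rank binning is
  monotone-invariant and stable at t ≈ 227; with t a multiple of B and
  distinct values, I(x; x) = log B exactly. A constant signal occupies one
  bin and returns 0 with a warning rather than an error.
- **Euclidean / cityblock** (`euclidean`, `cityblock`): ℓ2 / ℓ1 norms of
  the difference; scale-variant dissimilarities with zero diagonal.
- **Dynamic time warping** (`dtw`): minimum cumulative |x_i − y_j| cost
  over monotone boundary-to-boundary paths with steps (1,0), (0,1), (1,1);
  for equal lengths the diagonal path makes dtw ≤ cityblock. The O(t²)
  recurrence is JIT-compiled when numba is available, with a pure-numpy
  fallback.
- **Earth mover's distance** (`emd`): each signal becomes a distribution
  over its time indices — amplitudes shifted by the signal minimum (BOLD
  values can be negative; the shift is the minimal nonnegativity fix and is
  recorded in metadata) and normalized to unit mass — with ground distance
  |i − j| samples. On this 1-D grid the optimal-transport cost has the
  closed form Σ_i |CDF_x(i) − CDF_y(i)|, which the tests cross-check
  against a transportation linear program.

`pairwise_fc` applies one measure to every unordered pair; the diagonal
stores the self-value (1, 1, 1, 1, H(x), 0, 0, 0, 0) but no downstream step
reads it. `to_similarity` puts matrices on a common similarity scale: only
magnitudes are compared across measures, so similarity matrices take
absolute values and distances become 1 − min-max-rescaled distance, with
the min/max pooled over a subject group when group analyses follow (so
"above threshold" always means "strongly connected"). The composite vector
concatenates the nine upper-triangle vectors in the fixed order
corr | xcorr | coherence | wcoherence | mutual_info | euclidean |
cityblock | dtw | emd, length 9·n(n−1)/2.

## Consistency pipeline

Per measure and condition: subject matrices → similarity scale → cell-wise
group mean → binarize at (grand mean + 1 population SD) of the
upper-triangle values pooled across subjects, strict inequality → Dice
2|A∩B|/(|A|+|B|) over upper-triangle edges. Conventions chosen where the
procedure is underdetermined: the diagonal is excluded (including it would
inflate all overlaps identically), ties at the threshold are 0, population
rather than sample SD (the difference is at most one borderline edge), and
two empty masks count as perfectly overlapping with a warning. The
idealized reference pattern connects every within-network pair and no
between-network pair.

## Classification pipeline

Feature vectors are the n(n−1)/2 unique FC coefficients per network and
measure (magnitudes for correlation-like measures, raw scale for
distances). The nested leave-one-out design keeps everything learnable
inside the training fold: per-feature standardization statistics, NCA
feature weights, the regularization strength, and the SVM itself.

The embedded selector is neighborhood component analysis with a diagonal
metric: distance d_w(i,j) = Σ_r w_r² |x_ir − x_jr|, stochastic-neighbor
probabilities p_ij ∝ exp(−d_w), objective mean leave-one-out
same-class probability minus λ Σ w_r², maximized by L-BFGS from w = 1.
λ is chosen from {0.25, 0.5, 1, 2}/n_train by inner leave-one-out 1-NN
accuracy (ties to the smaller λ). Features with weight > 0.01·max weight
are kept, falling back to the single top feature. The classifier is a
linear-kernel SVM with unit cost — appropriate in the p ≫ n regime and
interpretable; AUC is computed from pooled signed decision values rather
than calibrated probabilities (calibration would add a fitted layer the
design does not need). A decision value of exactly 0 assigns the majority
training class with a logged warning. For the composite, per-feature
fold-wise z-scoring subsumes per-measure block scaling (raw scales differ
by orders of magnitude and would otherwise dominate the selector).

## Reconfiguration pipeline

Per restart: the group-mean similarity matrix is shuffled by one joint
row/column permutation (removing the a-priori ordering from the clustering
initialization while preserving all values), region profiles are clustered
by L1 k-means — implemented as k-medians: cityblock assignment,
per-coordinate median centroids, k-means++-style seeding under L1, empty
clusters reseeded from the farthest point, at most 300 sweeps — and the
induced idealized block pattern is scored by Dice against the thresholded
group matrix. Cluster sizes are unconstrained. The search keeps the argmax
over restarts (1000 in the full protocol; the scaled-down analyses here
use 200, which already recovers planted 10-block structure exactly); ties
resolve to the lowest restart index, and restart seeds derive
deterministically from the master seed. A verification mode injects the
a-priori partition as restart 0 so `best_dice ≥ original_dice` by
construction.

Brain-behavior validation regresses behavior on each cluster's
within-cluster mean FC with forward-backward stepwise OLS. Selection uses
adjusted R² ("maximize R²" is degenerate as a stepwise criterion — plain
R² never decreases on entry): an addition must improve adjusted R² by more
than 1e-4, and a removal is also taken when it is free within the same
threshold, which prunes redundant terms from saturated fits (a noiseless
planted outcome ends with exactly the planted term and R² = 1). The search
starts from all linear terms; with interactions enabled, all pairwise
products are candidates without a hierarchy requirement, so an interaction
may stand alone. The composite run keeps, per measure, the single
best-associated cluster's mean FC, z-scores the nine features, and repeats
the stepwise fit with interactions.

## Synthetic cohorts

Region i in network k emits
s_i = √(w−b)·u_k + √b·g + √(1−w)·e_i, where u_k is the network's latent
signal, g a global component and e_i private noise — each of them white
Gaussian noise hard-filtered to 0.01–0.1 Hz and standardized. All
components have unit variance, so the expected Pearson correlation is
exactly w within a network and b between networks; this latent-factor form
was chosen over covariance sampling precisely so the planted parameter is
analytically recoverable, while the trajectories stay band-limited and
realistic enough for the non-linear measures. Defaults mirror the target
acquisition: t = 227 (231 volumes minus 4 discarded), TR = 2.6 s, ten
networks of sizes (8,8,8,7,7,7,6,6,6,5) summing to 68 regions, within-
strength 0.6. Cohorts plant a group effect (group B gets w + δ on chosen
networks; default group sizes 29 vs 24) and a behavior score
intercept + slope·(subject's mean within-network Pearson FC) + Gaussian
noise (defaults 40 + 20·FC). Per-subject seeds come from a splitmix64 mix
of (master seed, subject index), so generation is reproducible and
parallelizable.

What the generator does **not** emulate: hemodynamic response shape, head
motion, scanner noise spectra, spatial autocorrelation, inter-subject
anatomical variability. Passing tests therefore demonstrate the pipelines'
correctness and their ability to recover planted dependence structure —
not effect sizes on real cohorts.

## Numerical choices and edge cases

- Symmetry enforced within 1e-9; wavelet coherence may exceed 1 by at most
  1e-6 numerically and is clipped.
- Zero-variance signals raise a degenerate-input error in correlation-type
  measures (never a silent 0); constant signals have zero mass for EMD and
  raise; a constant signal in MI warns and returns 0.
- Cross-correlation peak ties resolve to the first (most negative) lag;
  stepwise moves tie toward removal; k-means empty clusters reseed from the
  farthest point.
- File I/O writes floats at 17 significant digits and reads them with
  round-trip parsing, so write → read is bitwise exact.

## Problem sizes used by the shipped analyses

The test suite and the acceptance script run the pipelines at deliberately
modest scale: measure oracles on 200 random short signals, matrix
invariants on 100 random 4-region BOLD matrices, parameter recovery with
19 subjects at full length (t = 227, 68 regions), classification on a
29-vs-24 cohort with 20 label permutations, and reconfiguration with 200
restarts. These sizes were chosen as the smallest at which each claim is
sharp; the full 1000-restart protocol is a flag away (`--restarts 1000`).

## Known limitations

- k = 10 is fixed by design; no model selection over k.
- Single Lloyd runs can hit local optima on rare seeds; conclusions should
  always come from the multi-restart search.
- The NCA selector's λ grid and threshold are small and fixed; no broader
  hyperparameter search is attempted.
- Only undirected, pairwise dependence is measured — no effective
  connectivity, partial correlation, or multi-nodal statistics.
- The stepwise null behavior (what R² to expect on pure noise at n = 29,
  q = 10) is characterized in the tests; adjusted R² is a mild penalty and
  still admits moderate-looking null fits (~0.3), which is inherent to the
  criterion, not a defect of the implementation.
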