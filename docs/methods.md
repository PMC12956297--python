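# Methods

This note documents the models implemented in `eventspan`, the design
decisions behind them, and what the synthetic cohort does and does not
emulate.

## Edge time series and event detection

Nodal activity is z-scored per node over valid frames with the sample
(T−1) denominator; masked frames (the analogue of censored high-motion
frames in real data) are dropped before z-scoring. The edge time series
`e_ij(t) = z_i(t) z_j(t)` decomposes the Pearson correlation exactly:
`FC_ij = 1/(T−1) Σ_t e_ij(t)`, an identity the test suite asserts to 1e−10.
Pair indexing is everywhere the 0-based row-major upper triangle (i < j);
`matrix_to_vector` / `vector_to_matrix` enforce it.

The global co-fluctuation amplitude per frame is the root-sum-square of the
ETS column (a `root_mean_square` option divides by √n_pairs; the two differ
by a constant, so rankings and quantile-based event sets coincide — this is
why the naming ambiguity in the literature is inconsequential here). The
amplitude is computed in O(N) per frame via
`2 Σ_{i<j}(z_i z_j)² = (Σ_i z_i²)² − Σ_i z_i⁴`, which makes surrogate
generation cheap.

The circular-shift null independently rotates each node's series by a
uniform offset in [1, T−1]. A rotation is a permutation of the row, so every
marginal moment (and the autocorrelation sequence, up to wraparound) is
preserved exactly while inter-node alignment is destroyed.

Event thresholding offers three rules:

- `frame` (the `detect_events` default): threshold at the (1−α) quantile of
  the pooled null amplitudes. This is a per-frame error rate: on null data it
  flags an α fraction of frames, which is what the calibration tests assert.
- `peak`: as `frame`, keeping only each contiguous supra-threshold segment's
  argmax.
- `max` (the cohort pipeline's default): threshold at the (1−α) quantile of
  each null realization's *maximum* amplitude, i.e. familywise control per
  run. Empirical event analyses operate in a regime where events occupy well
  under 1% of frames; a per-frame 5% rule would flag ~45 noise frames per
  900-frame run against ~6 genuine events, and any downstream pooling of
  "event frames" would then be dominated by noise. The familywise rule keeps
  detection in the sub-1% regime while the per-frame rule remains available
  (and calibrated) for null-rate analyses.

## Synthetic lifespan cohort

The generator plants the statistical structure the analysis assumes, so
every downstream stage can be tested against ground truth.

- **Baseline activity**: i.i.d. frames from N(0, Σ) with
  Σ = noise_sd²·I + c·(within-system blocks), c = `modular_cov` = 0.02.
  The value 0.02 was chosen once so that baseline correlation is present but
  weak enough that the circular-shift null stays calibrated (flagged fraction
  ≈ α on event-free runs); at c = 0.05 the per-frame rule measurably
  over-flags. No temporal autocorrelation is modeled (white innovations).
- **Events**: sparse frames (Poisson count, expected 6 per 900-frame run —
  0.67% of frames; minimum separation 5 frames) where
  `x(t) = A·√N·s·w + baseline noise`, with `w` a unit-norm template
  component, `s = ±1`, and A = `event_amplitude` = 3.0. Because `w` has unit
  Euclidean norm, the √N factor expresses A in units of per-node baseline SD:
  a node carrying a typical template weight deflects ~3 SD. Without this
  scaling a "3.0" amplitude would be a 0.3-SD per-node ripple — undetectable
  and unclusterable — which would contradict the defining property of events
  as *high-amplitude* co-fluctuations.
- **Templates**: pattern 2 is a single bipartite component (+ on the
  higher-order systems — the last 3/8 of the system order — and − on the
  rest), giving a rank-1 edge pattern whose first principal component
  carries ~99% of variance. Pattern 1 is a cone of 8 components
  `u1 + 0.75(cos φ u2 + sin φ u3)` over three disjoint localized bipartite
  motifs (each contrasts a small positive node group against a large
  negative one within one third of the node order). The shared core `u1`
  makes the pattern internally cohesive — repeated k-means recovers it as
  one cluster and the cross-run similarity curve peaks at K = 2 — while the
  circular spread has no preferred split axis, so sub-clusterings are
  irreproducible. The mean edge pattern is rank 3 (leading Gram-eigenvalue
  share ≈ 0.84 < 0.9) and more modular under the uniform null
  (Q ≈ 0.61 vs. ≈ 0.50 for the near-balanced bipartite pattern 2), because
  its cross-third blocks carry zero weight and its 1:4 within-motif splits
  make positive pair mass dominate.
- **Age structure**: seven 10-year bins covering ages 6–75, ages uniform
  within bin. The probability that an event is pattern 1 interpolates
  linearly from 0.7 (youngest) to 0.2 (oldest); linearity is a deliberate
  minimal choice — only monotone trends are claimed downstream.
- **Geometry and SC**: nodes on a Fibonacci lattice of a 100 mm sphere;
  per-subject SC `exp(−d/λ)·g` with λ = 30 mm and gamma-distributed
  multiplicative noise (shape 4, mean 1), thresholded to 30% density and
  repaired to connectivity with maximum-weight spanning edges; volumes
  lognormal (median 1500 mm³, σ_log = 0.3). Systems are eight contiguous
  lattice bands named after the canonical cortical systems.
- **Phenotype**: `β·f2 + γ·age + ε` with β = 20, γ = 0.1, σ_ε = 1, where
  `f2` is the subject's true pattern-2 event fraction.
- **Determinism**: all randomness descends from one seed through
  SeedSequence spawning (geometry, then one stream per subject, then
  phenotype noise, in that fixed order); identical spec + seed reproduces
  the cohort bit-for-bit.

What the generator does **not** emulate: hemodynamics, temporal
autocorrelation, head motion, subject-specific connectivity fingerprints
(so framewise identifiability on the synthetic cohort is small and driven
only by each subject's realized pattern mix), scanner/site effects, and any
nonlinearity in lifespan trajectories. Passing tests therefore demonstrate
that the *pipeline* recovers planted structure of the assumed form, not that
real data satisfy those assumptions.

## Clustering

K-means under a similarity metric (Pearson correlation or Lin's concordance
with population 1/n moments; the concordance form additionally penalizes
mean/scale differences and satisfies |ρ_c| ≤ |r|): Lloyd iterations
assigning each frame to the argmax-similarity centroid (ties to the lowest
index), centroids recomputed as assigned means, empty clusters reseeded with
the frame least similar to its own centroid (one distinct frame per empty
cluster), best of 10 restarts by total within-cluster similarity. Labels are
aligned across repetitions by Hungarian assignment minimizing total
`1 − corr(centroid, reference centroid)`, the reference being the
best-objective run; tests verify optimality against exhaustive permutation
for K ≤ 6. The repeated sampling loop draws 20 subjects per age bin with
replacement and at most 10 cached event frames per subject per repetition;
detections are cached and only the sampling is redrawn.

## Age trends and nulls

System-block averages exclude the diagonal; singleton-system within-blocks
are recorded as missing. Age correlations (group level at bin centers, or
subject level) are tested against an age-permutation null with the +1-count
two-sided p-value and Benjamini–Hochberg adjustment (q = 0.01 default; BH
rather than BY since the elements are positively dependent at worst).
Zero-variance elements report r = 0 and p ≈ 1. Note the interplay between
permutation resolution and FDR: with n_perm permutations the smallest
achievable p is 1/(1+n_perm), so detecting anything at q = 0.01 across m
elements requires n_perm ≳ m/0.01; the defaults (5000 permutations, 36
system pairs) respect this.

Spin permutations draw a uniform random 3-D rotation (QR sign-corrected),
rotate the node coordinates, and map each node to its nearest rotated node
with greedy conflict resolution by ascending assignment distance, so every
permutation is a bijection and preserves the multiset of any nodal map. The
synthetic geometry is a single sphere; hemisphere handling for real
bihemispheric parcellations is out of scope.

## Communication measures and coupling

The registry implements seven predictors: Euclidean distance, binary
communicability `exp(A)`, weighted communicability `exp(D^{−1/2} A D^{−1/2})`
(D = strength diagonal; invariant to global weight rescaling), weighted
shortest-path lengths under the 1/w and −log(w/w_max) transforms, mean first
passage time of the unbiased random walk (via the fundamental matrix), and
search information along 1/w-shortest paths. MFPT and search information are
intrinsically asymmetric and are symmetrized as (M + Mᵀ)/2 (configurable).
Disconnected input raises before any non-finite value propagates.

Coupling is per node and per measure: R² of the simple regression of the
node's off-diagonal pattern row on its off-diagonal predictor row (squared
Pearson r — affine- and sign-invariant), not a multi-measure regression,
because the question asked of each measure is marginal. Per-node maxima
break ties by measure-name order. System-level age trends of coupling are
significant only if they beat both a spin null (nodal maps spun before
system averaging) and the magnitude of the matching nonevent trend.

## Modularity

Similarity-like matrices have no meaningful degree sequence, so the null
expectation of an edge is the mean off-diagonal weight (uniform null):
`B = W − γ·W̄`, γ = 1 by default, and
`Q = Σ_{i<j, same} B_ij / Σ_{i<j} |W_ij|`. The absolute-weight normalization
is a declared convention making Q scale-invariant; only relative comparisons
are used. Optimization is a generalized Louvain (greedy node moves with
escape-to-singleton for negatively attached nodes, then graph aggregation,
repeated until no improving move), seeded; an internal assertion checks Q
never decreases across phases, and tests verify it attains the exhaustive
optimum on ≤8-node graphs (best of 10 seeds). Consensus repeats the
algorithm (1000 runs at full scale; fewer in tests), forms the co-assignment
matrix, and re-clusters `C − τ` iteratively; τ defaults to the
permutation-null co-assignment expectation implied by the runs' module sizes
and is re-estimated each iteration. Convergence requires agreement among the
batch runs that attain the top modularity score on the current consensus
matrix — runs stuck in strictly worse local optima cannot veto convergence,
while genuine ties keep iterating (an error is raised after 50 iterations).

## Prediction

Differential identifiability uses the Pearson frame-to-frame similarity
matrix; within-subject means exclude self-pairs, subjects with one frame
contribute only between-subject terms, and `I_diff = (I_self − I_others)·100`.

CPM uses leave-one-out CV by default (10-fold available): per fold, edges
correlated with the phenotype at p < 0.01 on training subjects are split by
sign, each subject is summarized by the two set sums, and OLS on the
training sums predicts the held-out subjects; performance is the correlation
of held-out predictions with observations. Feature selection and fitting
never see test rows (a canary test plants a phenotype-valued feature visible
only in held-out rows and checks it cannot help). A caution documented by
our own permutation experiments: the null distribution of the CPM
prediction–outcome correlation is wide (sd ≈ 0.2 under LOO at n = 140,
≈ 0.13 under 10-fold, essentially independent of the number of candidate
edges), because edge selection happens on n−1 of n subjects and its
selection bias survives cross-validation. CPM significance should therefore
always be assessed by permutation, never against a parametric small-|r|
expectation.

## Problem sizes in tests and the acceptance script

Unit tests run on small cohorts (60 nodes, 400 frames, 6 subjects per bin);
the end-to-end recovery tests and the acceptance script use the generator's
default study conditions (100 nodes, 900 frames, 7 × 20 subjects) with 20
surrogate realizations per subject, 5–10 clustering repetitions, 500–1000
permutations, and best-of-5 Louvain for modularity summaries — sizes chosen
so the full pipeline remains a desk-scale computation while every recovery
margin stays wide (sensitivity 1.0, ARI 1.0, reproducibility curve margin
> 0.02 at K = 2 across probe seeds).

## Known limitations

- The uniform-null Q of weak-but-clean block structure is high once noise is
  averaged away; comparisons are meaningful only between matrices estimated
  from comparable amounts of data.
- The event detector assumes exchangeability of frames under rotation; slow
  nonstationarities (drift, arousal) in real data would violate this.
- The synthetic phenotype is linear in the pattern-2 fraction by
  construction; CPM results on the cohort demonstrate recovery, not
  real-world predictive value.
- Lifespan trends are modeled and tested as monotone/linear; quadratic or
  U-shaped trajectories require a different trend model.
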