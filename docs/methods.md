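# Methods

This note records the models, conventions and numerical choices behind
`rankcurves`, in the spirit of a statistical software appendix: enough
detail to re-derive every number the package produces.

## Synthetic data model

A dataset is defined by interaction groups (relation, p, copies), a count
of irrelevant features and an instance count.  Per instance the target
F_t is a fair coin.  Each *single* group copy draws its feature to agree
with F_t with probability p.  Each *xor* group copy draws the pair
(F_i, F_j) so that P(XOR(F_i, F_j) = F_t) = p, choosing uniformly between
the two assignments realizing the sampled parity; this keeps each member
marginally uniform and marginally independent of the target, which is
what defeats univariate relevance measures.  Irrelevant features are
independent fair coins.

**Redundant copies are conditional resamples, not duplicated columns.**
Copies of a group are independent realizations given the same target.
Duplicated columns would create exact ties everywhere and degenerate
rankings; conditional resampling yields the correlated-but-distinct
features that redundancy in real data actually looks like.

**Ground-truth relevance** is the *population* mutual information of a
group with the target, I = 1 − H_b(p) bits (the target has 1 bit of
entropy, so relevances live in [0, 1]), divided evenly among the group's
members.  The population value, not the sample estimate, is used: the
generating model is known, and sample MI would make the "ground truth"
seed-dependent and nonzero for noise features.

The three standard specifications (`single`, `pair`, `combined`) use
three copies of each group at p ∈ {0.8, 0.7, 0.6}, padded with fair-coin
features to exactly 100 features and 1,000 instances; they contain 9, 18
and 27 features of positive relevance respectively.

What the generator does *not* emulate: numeric features, class imbalance,
correlated noise, missing values, and relevance that varies continuously
across features.  Passing tests on these benchmarks therefore demonstrate
that the evaluation machinery behaves correctly where the answer is
known — not that any particular ranker is adequate for a given real
dataset.

## Rankings, ties and noise

Rankings are built by sorting scores in descending order.  Ties are
broken lexicographically by feature name by default (reproducible) or
uniformly at random (seeded); *fractional average ranks* of the scores
are carried alongside and always sum to n(n+1)/2.  All rank-correlation
work uses the fractional ranks on both sides — the standard treatment of
tied Spearman correlation — because the zero-relevance block of a
synthetic benchmark is one huge tie whose arbitrary ordering would
otherwise dominate every distance.

A noisy ranking R_θ replaces the scores of round(θ·n) distinct features
(chosen uniformly without replacement) with independent Uniform(0, 1)
draws.  Symmetric rounding makes the printed θ grid exact on n = 100.
θ = 0 is the identity; θ = 1 induces a uniformly random ranking.

**Score scale for noise mixing.**  Because the replacement scores live on
the unit interval, the ground-truth scores are rescaled before mixing so
that the strongest interaction group sits at 1 (`spec_distance` divides
by the spec's maximum group relevance; for the standard benchmarks that
is 1 − H_b(0.8) ≈ 0.278).  Rankings are scale-invariant, so this affects
only where noise inserts relative to the relevant features — without the
rescaling, almost every U(0, 1) draw would exceed every true relevance
and the distances at moderate θ would be systematically inflated.

The distance of R_θ to the ground truth is 1 − mean Spearman ρ over m
perturbation realizations (default m = 100), with the Monte-Carlo
standard error reported.  ρ is the Pearson correlation of the two
fractional-rank vectors, centered on their actual means (the textbook
(n+1)/2 when untied).

## Canberra machinery

The Canberra distance on ranks weights disagreements near the top most.
The top-i (partial) variant clamps all ranks at i + 1, so features both
rankings leave outside their top-i contribute nothing.

The stability normalizer Ca(n, i) — the expected partial Canberra
distance between two independent uniform rankings — is computed
**exactly in O(n²)**: the marginal rank of a fixed feature is uniform on
1..n and independent between the two rankings, so by linearity
Ca(n, i) = n · E|a′ − b′|/(a′ + b′) with a, b uniform and clamped.  This
matches full (n!)² enumeration to machine precision for n ≤ 5 and a
10,000-pair Monte-Carlo estimate at n = 100 within sampling error.

A closed-form approximation from the stability literature,
((i+1)(2n−i)/n)·ln 4 + i(1+i)/n + 2i − 3, is retained verbatim
(`method="approx"`, natural logarithm) together with an `auto` mode that
switches from exact to approximate at i = 8.  The approximation evaluates
far above the exact expectation (at i = n it scales like ≈ 4.39 n versus
the true ≈ n(2 ln 2 − 1) ≈ 0.386 n), so the **default normalizer
everywhere is the exact expectation**; the approximation is kept only for
comparability with that literature, and a seeded Monte-Carlo normalizer
is available as a cross-check.  With the exact normalizer the stability
curve has clean anchors: 0 for identical rankings, ≈ 1 for uniformly
random ones.

## Rankers

* **Information gain** — empirical H(F_t) − H(F_t | F_i) in bits from the
  contingency table; numeric features are discretized into equal-frequency
  10-bin codes first (the synthetic benchmarks are binary, so this choice
  is inert there).  A constant target yields all-zero scores with a
  warning.
* **ReliefF** — every instance serves as an anchor once
  (`sample_fraction = 1`); 10 nearest hits and 10 nearest misses per
  opposing class (Manhattan distance on normalized differences); miss
  contributions weighted by class priors P(c)/(1 − P(class)).  Feature
  differences use the overlap metric for discrete features and
  range-normalized absolute difference for numeric ones — the standard
  ReliefF conventions.
* **Random forest** — 100 trees, ceil(log₂ n) candidate features per
  split; impurity-decrease importance by default, permutation importance
  by configuration.
* **SVM-RFE** — linear soft-margin SVM (C = 0.1, tolerance 1e-12) refit
  after each elimination of the feature with the smallest squared weight;
  above 500 surviving features the worst 10% are dropped per round, a
  pure-speed measure.

All rankers are deterministic given data, hyperparameters and seed.

## Error curves

Subset chains follow the ranking from the top (FFA) or bottom (RFA).  The
default schedule evaluates every size up to 100 features and a thinned
schedule beyond: step 1 up to size 50, step 5 up to 500, then n // 20,
with the last step clipped so the chain ends exactly at n.  Explicit size
grids are also accepted (n is always appended).

Performance is mean accuracy under repeated stratified k-fold CV
(defaults 10×10; the error rate is available as the complementary
metric).  Three determinism rules make curves comparable:

1. fold partitions are a pure function of (cv seed, repeat index), shared
   across subsets, rankings and curve types;
2. learner seeds are a pure function of (cv seed, repeat, fold);
3. subset columns are canonicalized to dataset order before fitting — a
   feature *set*'s score must not depend on the order the chain added
   features in (tree learners are column-order sensitive; kernel,
   neighbor and naive Bayes learners are inherently order-invariant).

Consequently FFA and RFA curves of any ranking agree exactly at i = n.

Learners: Gaussian naive Bayes; CART decision tree; random forest (100
trees, log₂ feature sampling); SVM with an inhomogeneous quadratic kernel
(x·y + 1)², C = 0.1, tolerance 1e-12; kNN with k = 10.  The SVM solver is
additionally capped at 100,000 SMO iterations: on degenerate all-noise
binary subsets (many duplicate rows with conflicting labels) the solver
can cycle at the tiny tolerance, and the cap leaves accuracy at the same
chance level while bounding runtime.  On non-binary data, numeric
features are min-max scaled and multi-valued discrete features one-hot
encoded inside each training fold (with per-fold median/mode imputation
when values are missing); all-binary data passes through untouched.

The expected curve averages the curves of m whole random rankings
(default m = 100) rather than sampling random subsets per size; its
standard errors are across-ranking Monte-Carlo errors.

## Stability estimation

Rankings are resampled from CV *training folds* (repeats × folds
rankings), each fold's ranking computed on its training portion only.
The stability index at depth i is the mean pairwise partial Canberra
distance, normalized by Ca(n, i) as above; lower is more stable.

## Desk-scale evaluation settings

The behavioral test suite runs the full method at reduced but statistically
adequate sizes, chosen once: 3×3 CV instead of 10×10; 25 noise
realizations per θ ∈ {0.05, 0.2, 0.5, 1} for the curve-ordering check,
with a 10-point subset grid concentrated where the standard benchmarks'
curves carry structure (sizes 1–50); 25 random rankings for the
expected-curve identity; m = 100 realizations for the distance table; 100
random rankings of 50 features for the stability anchors.  Curve
comparisons use the unpaired combined standard errors of the two curve
estimates — the same error bars one compares overlaid curves with.

## Known limitations

* The exact normalizer assumes uniformly random rankings; rankers with
  systematic biases (e.g., alphabetical tie-breaking over many tied
  scores) can push normalized stability slightly above 1.
* The partial Canberra distance is a distance on rank vectors, not a
  calibrated probability; stability curves of different n are comparable
  only through the normalization.
* Accuracy is the only built-in curve metric (plus its complement); for
  imbalanced targets a different error measure would be needed, and the
  curve machinery is deliberately agnostic to that extension.
* ReliefF is O(n²) in instances per fold; on datasets much beyond 10⁴
  instances subsampling anchors (`sample_fraction < 1`) is advisable.
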