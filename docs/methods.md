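# Methods

## Problem setting

Two-class expression matrices with n samples and d features, n ≪ d
(tens-to-hundreds of samples, thousands-to-tens-of-thousands of genes),
with class-imbalance ratios around 1–2.2. Labels are recoded to
{+1, −1} with the minority class as +1; that single convention fixes
the positive class for every metric, the weighted-SVM penalties, and
the ROC orientation. Ties in class size are broken by assigning +1 to
the lexicographically smaller label so the encoding is deterministic.

## Mutual information and discretization

All relevance and redundancy terms are plug-in mutual-information
estimates on discretized data, in bits. Base 2 is chosen because it
gives clean closed-form test values (a balanced binary variable has
exactly 1 bit of entropy); the MI estimator sums only over observed
cells, with the 0·log 0 = 0 convention for empty ones.

Discretization default: equal-frequency, 4 bins. Equal-frequency is
rank-based — samples are stably sorted per feature and split into
near-equal chunks — rather than cut at quantile *values*. Under the
heavy ties common in expression data, value-based quantile cuts can
collapse bins entirely (a median cut on (1, 1, 1, 100) puts every
sample in one bin); the rank-based form always yields balanced
occupancies and the uniform marginals that behave best with plug-in MI.
Equal-width binning is available as an alternative. Constant features
collapse to one category (zero MI with anything) and are flagged.
Four bins is a compromise for cohorts of 60–250 samples: fewer bins
lose signal, more bins overfit the contingency tables.

## mRMR: accumulated redundancy

Greedy selection maximizes `relevance(f) − acc(f)/|S|`, where `acc(f)`
is a running per-candidate sum of MI values against the selected set,
updated after each pick with a single MI evaluation against the newly
selected feature. The first pick is the relevance argmax; ties break
toward the lowest feature index everywhere, for determinism. The
normalization by |S| (mean redundancy against the selected set) is used
for selection; the symmetric pairwise form R = (1/|X|²)·ΣΣ I(x_i; x_j),
which includes self-pairs and is the natural subset-level statistic, is
exposed separately (`subset_redundancy`) for reporting. A naive
selector recomputing the mean redundancy from scratch each step serves
as the testing oracle: both must order features identically on every
input, and a 100-instance randomized equivalence test enforces it.

## The spider optimizer

A population of N candidate solutions in a box, maximizing. Per
iteration: fitness evaluation and descending sort, elitist prey update,
then two moves.

* Exploration: per spider i and dimension j independently, draw
  α₁ ~ U(0,1) and replace the coordinate with the prey's when
  α₁ < SPF(i). SPF is the spider's share of total fitness,
  F_i / Σ F_j — this guarantees SPF ∈ [0,1], so the comparison with a
  uniform draw is meaningful. (Two alternative readings of the share,
  F_i/ΣF_j² and (F_i/ΣF_j)², are available behind `spf_mode`.)
  Fitness is shifted by its minimum when negative values occur, since
  the share needs non-negative mass; an all-zero vector falls back to
  the uniform share 1/N.
* Exploitation: per spider draw α₂, α₄, α₅ ~ U(0,1) once per
  iteration. With α₅ < 0.5 the spiral move
  x' = r + |α₂·r − x| · e^{α₃} · cos(2π·α₄) applies per dimension;
  otherwise the linear pull x' = r + α₂·(r − x). The reference point r
  is the prey (best-so-far) coordinate — the only previously defined
  reference position in the update scheme. α₃ follows the
  deterministic schedule (1 − i/i_max)², shrinking the spiral from
  amplitude e down to 1 over the run; the deterministic formula is used
  even though the surrounding prose could be read as making α₃ a
  uniform draw, because the formula is explicit. Positions leaving the
  box are clamped to the nearest bound.

Draw granularity — α₁ per (spider, dimension); α₂, α₄, α₅ per spider —
mirrors the element-wise indexing of the exploration rule and the
single branch decision per spider of the exploitation rule. Both
phases apply to all spiders in every iteration. The best-so-far is
elitist: the reported best fitness is non-decreasing by construction,
and every trace is asserted monotone.

## Binary wrapper

The binary search space is the top-M mRMR features (default M = 100;
the filter output is the wrapper's input per the hybrid design, and 100
keeps the inner cross-validation affordable at desk scale while
comfortably containing the planted signal in the synthetic regime).
The continuous box is [0,1]^M so the sigmoid midpoint 0.5 is the
natural inclusion boundary; the slope 10 makes the transfer nearly
saturated at the box edges. Bits are drawn per evaluation
(bit = 1 iff S(x) > u), and an all-zero vector is repaired by forcing
the top-ranked feature in.

Fitness: F = α·MCC(KNN) + (1−α)·(1 − N_f/N) with α = 0.9 (quality
prioritized over sparsity, the common wrapper-FS weighting), KNN with
k = 5 (odd, so no vote ties), and stratified 5-fold cross-validation on
the training split only. N is the size of the reduced space, so the
sparsity term spans [1/N, 1] over admissible subsets. MCC on a
degenerate fold (zero denominator) is defined as 0. Fold assignment is
fixed once per run, making fitness a pure function of the bit pattern,
which is also the cache key — identical subsets recur constantly and
the inner CV is the cost center.

Initialization seeds ⌈N/2⌉ members from the ranking (inclusion
probability decaying linearly from 0.9 at the top rank to 0.1 at the
bottom) and draws the rest Bernoulli(0.5); initial continuous
coordinates are placed on the matching side of 0.5.

The train/test wiring: the 80/20 stratified split is made first;
wrapper fitness uses inner CV on the training split; final reports use
the untouched 20% test split. The two evaluation phases (filter-only
vs. filter+wrapper) consume the identical partition for a fair
comparison, and an assertion enforces train/test disjointness.

## Classifiers and metrics

The weighted SVM is the standard soft-margin SVM with per-class slack
penalties; the balanced inverse-frequency rule C_class = C·n/(2·n_class)
is used because the penalty *rule* is otherwise a free choice, and this
one has the two properties that matter: C+/C− equals the imbalance
ratio, and both collapse to C on balanced data (so WSVM is
prediction-identical to SVM there — asserted on toy fixtures). The
kernelized dual with per-class box constraints is delegated to libsvm
via scikit-learn; kernel default RBF with the median-bandwidth-style
`gamma='scale'` heuristic. DT, XGBoost, AdaBoost, RF and KNN use the
established library defaults, which are recorded in each benchmark
report.

Metric panel: Acc, MCR = 100 − Acc, Pre, Rcl, Spe, F1, FNR, FPR, MCC,
reported as percentages to two decimals. Specificity is tn/(tn+fp) and
the false-positive rate fp/(fp+tn) — the standard forms under which the
complement identities Rcl+FNR = Spe+FPR = 100% hold, which the panel's
property tests check on random confusion tables. Zero-denominator
ratios are reported as 0 with a `degenerate` flag instead of NaN so
fold averaging stays numeric. ROC staircases come from thresholding
decision scores at unique values.

## Synthetic data

Class-conditional Gaussian model: informative genes are N(0,1) in the
majority class and N(effect, 1) in the minority; redundant copies are
ρ·parent + √(1−ρ²)·ε (population correlation ρ with the parent);
noise genes are N(0,1) regardless of class. This is the simplest
structure under which MI-based relevance, correlation-based redundancy
and class separation are all simultaneously well defined and
controllable. Columns are randomly permuted so planted structure
carries no positional cue. Class counts follow
n_minority = round(n/(1+imbalance)).

Default conditions: n = 100 samples, 10 informative genes at effect
1.5, 2 redundant copies each at ρ = 0.8, 470 noise genes (d = 500),
imbalance 1.8 — the scale and imbalance regime of classic two-class
microarray benchmarks, small enough to run in seconds.

What the generator does **not** emulate: probe-level noise physics,
batch effects, heavy-tailed intensity distributions, gene–gene
interaction structure beyond pairwise correlation, and multi-class
heterogeneity. Passing tests on this model therefore demonstrate the
machinery (ranking, search, weighting, bookkeeping) under a clean
signal, not performance claims on real microarray cohorts.

## A deliberate tension worth knowing about

On the default fixture the per-gene effect (1.5 SD) is strong enough
that the inner KNN reaches MCC = 1.0 with roughly five
signal-carrying features (measured: a 5-informative subset scores
F = 0.995 versus 0.990 for all ten). Once MCC saturates, the sparsity
term makes the *smallest* perfect subset the global optimum, so a
well-functioning optimizer recovers only a fraction of the planted
informative set — planted recall at these settings is ~0.3, and a
stronger optimizer drives it *lower*, not higher. Recall of the full
planted set and maximization of this fitness are simply different
objectives whenever the signal is redundant. The package reports both
(recall/noise-fraction via `recovery_score`, fitness/MCC via the
selection result) so the trade-off is visible rather than hidden.

## Numerical and reproducibility choices

* One seed drives everything: dataset generation, splits, folds, the
  optimizer stream, and classifier seeds. Reruns are byte-identical
  (sorted-key JSON, no timestamps).
* Ties: argmax everywhere takes the lowest index.
* MI is clipped at 0 against floating-point negatives.
* Problem sizes in the test suite and acceptance script (e.g., 100
  random mRMR-equivalence instances up to 60×30; 5 seeds for the
  recovery and phase studies; 10 seeds for the sphere benchmark) were
  chosen to make the statistical checks stable while keeping a full
  run in the low minutes on one core.

## Known limitations

* Binary classification only; multi-class labels are rejected.
* The MI estimator is the plug-in on discretized data; no bias
  correction or continuous (k-NN/KDE) estimators.
* No normalization or batch correction — inputs are assumed
  preprocessed.
* The wrapper's fitness variance across fold assignments is not
  averaged out (one fixed fold split per run, by design, for purity of
  the fitness function).
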