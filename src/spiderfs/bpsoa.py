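"""Binary spider optimization for wrapper feature selection.

Continuous spider positions live in [0,1]^M and are mapped to feature
inclusion bits through a steep sigmoid centred at 0.5 followed by a
stochastic threshold.  Each candidate bit vector is scored by

    F = alpha * MCC(KNN) + (1 - alpha) * (1 - Nf / N)

where MCC(KNN) is the mean Matthews correlation of a k-nearest-neighbor
classifier under stratified cross-validation on the training split
restricted to the selected features, Nf the number of selected features
and N the size of the reduced search space.  MCC replaces accuracy in
the fitness because the target datasets are class-imbalanced; the
second term rewards sparsity.

The search space is first reduced by the fast mRMR filter, and half of
the initial population is seeded from the top of the mRMR ranking so
the wrapper starts from an already-informative region.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from sklearn.neighbors import KNeighborsClassifier
from sklearn.model_selection import StratifiedKFold

from .core import ExpressionDataset
from .metrics import confusion_counts
from .mrmr import MrmrRanking, discretize, fast_mrmr_select
from .psoa import (
    ConvergenceTrace,
    PsoaParams,
    SpiderPopulation,
    exploitation_step,
    exploration_step,
)


class BpsoaError(ValueError):
    pass


@dataclass(frozen=True)
class FitnessConfig:
    """Wrapper-fitness weights and inner cross-validation settings."""

    alpha: float = 0.9
    knn_k: int = 5
    n_folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise BpsoaError("alpha must be in [0, 1]")
        if self.knn_k % 2 == 0 or self.knn_k < 1:
            raise BpsoaError("knn_k must be odd and positive (avoids vote ties)")
        if self.n_folds < 2:
            raise BpsoaError("n_folds must be >= 2")


@dataclass(frozen=True)
class SelectionResult:
    """Outcome of a hybrid selection run."""

    best_bits: np.ndarray  # over the reduced space
    selected_indices: np.ndarray  # original feature indices
    best_fitness: float
    inner_mcc: float
    trace: ConvergenceTrace
    ranking: MrmrRanking
    reduced_indices: np.ndarray  # mRMR-kept original indices, rank order


def sigmoid_transfer(x) -> np.ndarray | float:
    """Steep logistic 1 / (1 + e^{-10(x - 0.5)}) mapping [0,1] to (0,1).

    The factor 10 makes the transfer nearly saturated at the box edges
    so continuous coordinates near 0 or 1 translate to near-certain
    exclusion or inclusion; S(0.5) = 0.5 and S(x) + S(1-x) = 1.
    """
    with np.errstate(over="ignore"):  # exp overflow saturates to S=0
        return 1.0 / (1.0 + np.exp(-10.0 * (np.asarray(x, dtype=float) - 0.5)))


def binarize(position: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Stochastic threshold: bit_j = 1 iff S(x_j) > u_j, u_j ~ U(0,1)."""
    s = sigmoid_transfer(position)
    return (s > rng.random(len(position))).astype(np.int8)


def repair_empty_subset(bits: np.ndarray, ranking_top: int) -> np.ndarray:
    """Force the top-ranked feature in when no bit is set; else identity."""
    if bits.any():
        return bits
    repaired = bits.copy()
    repaired[ranking_top] = 1
    return repaired


class SubsetFitness:
    """Cached wrapper-fitness evaluator over a fixed training matrix.

    Fold assignment is drawn once at construction so fitness is a pure
    function of the bit vector for the lifetime of the evaluator; the
    cache is keyed by the bit pattern because identical subsets recur
    and the inner cross-validation dominates the cost.
    """

    def __init__(self, X: np.ndarray, y: np.ndarray, cfg: FitnessConfig):
        self.X = np.asarray(X, dtype=float)
        self.y = np.asarray(y)
        self.cfg = cfg
        self.n_space = self.X.shape[1]
        minority = int(min(np.sum(self.y == 1), np.sum(self.y == -1)))
        folds = min(cfg.n_folds, minority)
        if folds < 2:
            raise BpsoaError("need >= 2 samples per class for inner CV")
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=cfg.seed)
        self.folds = [(tr, va) for tr, va in skf.split(self.X, self.y)]
        self._cache: dict[bytes, tuple[float, float]] = {}
        self.evaluations = 0

    def mcc_and_fitness(self, bits: np.ndarray) -> tuple[float, float]:
        bits = np.asarray(bits, dtype=np.int8)
        if not bits.any():
            raise BpsoaError("empty feature subset (repair first)")
        key = bits.tobytes()
        if key in self._cache:
            return self._cache[key]
        cols = np.flatnonzero(bits)
        Xs = self.X[:, cols]
        mccs = []
        for tr, va in self.folds:
            k = min(self.cfg.knn_k, len(tr))
            model = KNeighborsClassifier(n_neighbors=k)
            model.fit(Xs[tr], self.y[tr])
            pred = model.predict(Xs[va])
            mccs.append(confusion_counts(self.y[va], pred).mcc)
        mcc = float(np.mean(mccs))
        a = self.cfg.alpha
        fitness = a * mcc + (1 - a) * (1 - len(cols) / self.n_space)
        lo = -a
        hi = a + (1 - a) * (1 - 1 / self.n_space)
        assert lo - 1e-12 <= fitness <= hi + 1e-12, "fitness out of bounds"
        self._cache[key] = (mcc, fitness)
        self.evaluations += 1
        return mcc, fitness

    def __call__(self, bits: np.ndarray) -> float:
        return self.mcc_and_fitness(bits)[1]


def hybrid_init(
    ranking_size: int,
    n_spiders: int,
    seeded_fraction: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Initial binary population mixing mRMR-seeded and uniform members.

    The reduced space is ordered by mRMR rank (column r = rank r), so
    seeded members include feature r with probability decaying linearly
    from 0.9 (top rank) to 0.1 (bottom); the remaining members are
    uniform Bernoulli(0.5).  Every member is repaired non-empty.
    """
    if not 0.0 <= seeded_fraction <= 1.0:
        raise BpsoaError("seeded_fraction must be in [0, 1]")
    m = ranking_size
    n_seeded = math.ceil(seeded_fraction * n_spiders)
    if m == 1:
        probs = np.array([0.9])
    else:
        probs = 0.9 - 0.8 * np.arange(m) / (m - 1)
    pop = np.empty((n_spiders, m), dtype=np.int8)
    for i in range(n_spiders):
        p = probs if i < n_seeded else np.full(m, 0.5)
        pop[i] = (rng.random(m) < p).astype(np.int8)
        pop[i] = repair_empty_subset(pop[i], 0)
    return pop


def bpsoa_select(
    ds: ExpressionDataset,
    m_top: int = 100,
    params: PsoaParams | None = None,
    cfg: FitnessConfig | None = None,
    n_bins: int = 4,
    seeded_fraction: float = 0.5,
) -> SelectionResult:
    """Full hybrid selection on a training dataset.

    Stages: (1) discretize and rank with fast mRMR, keeping the top
    ``m_top`` features; (2) build the seeded binary population;
    (3) run the spider loop in the continuous box [0,1]^M, binarizing
    each position at evaluation time and scoring with the wrapper
    fitness; (4) return the elitist best bit vector mapped back to
    original feature indices.  Deterministic for a fixed seed (taken
    from ``params.seed``).
    """
    params = params or PsoaParams()
    cfg = cfg or FitnessConfig(seed=params.seed)
    if m_top > ds.n_features:
        raise BpsoaError(
            f"m_top={m_top} exceeds feature count {ds.n_features}"
        )
    dm = discretize(ds.matrix, n_bins=n_bins)
    ranking = fast_mrmr_select(dm, ds.labels, k=m_top)
    reduced_idx = ranking.order  # rank order; reduced column r = rank r
    X_red = ds.matrix[:, reduced_idx]

    fitness_fn = SubsetFitness(X_red, ds.labels, cfg)
    rng = np.random.default_rng(params.seed)
    m = m_top

    bits_pop = hybrid_init(m, params.n_spiders, seeded_fraction, rng)
    # continuous positions consistent with the initial bits: coordinates
    # land on the inclusion side of the 0.5 decision boundary
    positions = np.where(
        bits_pop == 1, rng.uniform(0.5, 1.0, bits_pop.shape), rng.uniform(0.0, 0.5, bits_pop.shape)
    )

    def eval_bits(b: np.ndarray) -> tuple[np.ndarray, float]:
        b = repair_empty_subset(b, 0)
        return b, fitness_fn(b)

    fitness = np.empty(params.n_spiders)
    all_bits = []
    for i in range(params.n_spiders):
        b, f = eval_bits(bits_pop[i])
        all_bits.append(b)
        fitness[i] = f
    best_i = int(np.argmax(fitness))
    best_bits = all_bits[best_i].copy()
    best_fit = float(fitness[best_i])

    pop = SpiderPopulation(
        positions=positions,
        fitness=fitness,
        prey=positions[best_i].copy(),
        prey_fitness=best_fit,
        bounds=(0.0, 1.0),
    )
    trace = ConvergenceTrace()
    trace.record(best_fit, params.n_spiders)

    for it in range(params.max_iters):
        order = np.argsort(pop.fitness)[::-1]
        pop.positions = pop.positions[order]
        pop.fitness = pop.fitness[order]
        exploration_step(pop, rng, spf_mode=params.spf_mode)
        exploitation_step(pop, it, params.max_iters, rng)
        for i in range(params.n_spiders):
            b, f = eval_bits(binarize(pop.positions[i], rng))
            pop.fitness[i] = f
            if f > best_fit:
                best_fit = f
                best_bits = b.copy()
                pop.prey = pop.positions[i].copy()
                pop.prey_fitness = f
        trace.record(best_fit, params.n_spiders)

    inner_mcc, _ = fitness_fn.mcc_and_fitness(best_bits)
    selected = np.sort(reduced_idx[np.flatnonzero(best_bits)])
    return SelectionResult(
        best_bits=best_bits,
        selected_indices=selected,
        best_fitness=best_fit,
        inner_mcc=inner_mcc,
        trace=trace,
        ranking=ranking,
        reduced_indices=reduced_idx,
    )
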