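"""Microarray-like synthetic two-class data with planted ground truth.

Emulates the n << d regime of two-class expression studies: a handful
of informative genes whose class-conditional means differ by a
standardized effect size, correlated redundant copies of each of them,
and a large background of class-independent noise genes.  The planted
index sets give every pipeline stage an objective ground truth that
real expression data cannot provide.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import ExpressionDataset


class SyntheticSpecError(ValueError):
    pass


@dataclass(frozen=True)
class SyntheticSpec:
    """Generator configuration.

    effect_size is the standardized mean shift (in within-class SD
    units) of informative genes between classes; redundancy_rho the
    correlation of each redundant copy with its parent; imbalance the
    majority/minority sample ratio.
    """

    n_samples: int = 100
    n_informative: int = 10
    n_redundant_per_informative: int = 2
    n_noise: int = 470
    effect_size: float = 1.5
    redundancy_rho: float = 0.8
    imbalance: float = 1.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.imbalance < 1.0:
            raise SyntheticSpecError("imbalance ratio must be >= 1")
        if not 0.0 < self.redundancy_rho < 1.0:
            raise SyntheticSpecError("redundancy_rho must be in (0, 1)")
        if self.n_informative < 1 or self.n_noise < 0 or self.n_redundant_per_informative < 0:
            raise SyntheticSpecError("feature counts must be non-negative (>=1 informative)")
        if self.minority_count < 1:
            raise SyntheticSpecError("spec yields an empty minority class")

    @property
    def n_features(self) -> int:
        return self.n_informative * (1 + self.n_redundant_per_informative) + self.n_noise

    @property
    def minority_count(self) -> int:
        return int(round(self.n_samples / (1.0 + self.imbalance)))


@dataclass(frozen=True)
class PlantedTruth:
    """Post-shuffle column indices of each planted feature group."""

    informative: np.ndarray
    redundant: np.ndarray
    noise: np.ndarray
    parent_of: dict[int, int]  # redundant column -> its informative parent


def generate_synthetic_dataset(spec: SyntheticSpec) -> tuple[ExpressionDataset, PlantedTruth]:
    """Draw one dataset under ``spec``; deterministic for its seed.

    Informative genes are class-conditional Gaussians N(0,1) for the
    majority (-1) class and N(effect_size, 1) for the minority (+1).
    Each redundant copy is rho*parent + sqrt(1-rho^2)*eps with
    independent standard-normal eps, giving population correlation rho
    with its parent.  Noise genes are N(0,1) regardless of class.
    Columns are randomly permuted so planted structure carries no
    positional cue.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_samples
    n_min = spec.minority_count
    n_maj = n - n_min
    if n_maj < n_min:
        raise SyntheticSpecError("rounded class counts invert the imbalance")
    y = np.concatenate([np.ones(n_min, dtype=int), -np.ones(n_maj, dtype=int)])
    rng.shuffle(y)

    ni = spec.n_informative
    nr = spec.n_redundant_per_informative
    inform = rng.standard_normal((n, ni))
    inform[y == 1] += spec.effect_size

    rho = spec.redundancy_rho
    redundant = np.empty((n, ni * nr))
    parent_local: list[int] = []
    for p in range(ni):
        for _ in range(nr):
            eps = rng.standard_normal(n)
            redundant[:, len(parent_local)] = rho * inform[:, p] + np.sqrt(1 - rho**2) * eps
            parent_local.append(p)
    noise = rng.standard_normal((n, spec.n_noise))

    original = np.concatenate([inform, redundant, noise], axis=1)
    d = original.shape[1]
    pos = rng.permutation(d)  # original column i lands at column pos[i]
    matrix = np.empty((n, d))
    matrix[:, pos] = original

    informative_idx = np.sort(pos[:ni])
    redundant_idx = np.sort(pos[ni : ni + ni * nr])
    noise_idx = np.sort(pos[ni + ni * nr :])
    parent_of = {
        int(pos[ni + r]): int(pos[parent_local[r]]) for r in range(ni * nr)
    }

    ds = ExpressionDataset(
        matrix=matrix,
        labels=y,
        feature_names=tuple(f"g{j:05d}" for j in range(d)),
        sample_ids=tuple(f"s{i:04d}" for i in range(n)),
        label_names={1: "case", -1: "control"},
    )
    truth = PlantedTruth(
        informative=informative_idx,
        redundant=redundant_idx,
        noise=noise_idx,
        parent_of=parent_of,
    )
    return ds, truth


def recovery_score(selected, truth: PlantedTruth) -> tuple[float, float]:
    """(recall of informative features, fraction of selection that is noise)."""
    selected = set(int(i) for i in np.asarray(selected).ravel())
    n_feat = len(truth.informative) + len(truth.redundant) + len(truth.noise)
    if selected and (min(selected) < 0 or max(selected) >= n_feat):
        raise SyntheticSpecError("selected indices out of range")
    inform = set(truth.informative.tolist())
    noise = set(truth.noise.tolist())
    recall = len(selected & inform) / len(inform)
    noise_frac = len(selected & noise) / len(selected) if selected else 0.0
    return recall, noise_frac
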