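"""Portia spider optimization: a population metaheuristic maximizer.

The population of candidate solutions ("spiders") is drawn toward the
best position found so far (the "prey") through two alternating moves:

* an exploration jump, where each coordinate of a spider is replaced by
  the prey's coordinate with probability equal to the spider's
  standardized fitness share; and
* an exploitation move, which with probability 1/2 spirals around the
  prey (amplitude e^{a3} cos(2*pi*a4) of the gap |a2*r - x|) and
  otherwise moves linearly toward it by a random fraction a2 of the gap.

The spiral amplitude shrinks over the run through the schedule
a3 = (1 - i/i_max)^2, trading global search early for local refinement
late.  The best-so-far position is elitist: it is never lost, so the
reported best fitness is non-decreasing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np


class PsoaError(ValueError):
    pass


class ObjectiveError(RuntimeError):
    """Wraps an exception raised by the objective, with iteration context."""


@dataclass
class PsoaParams:
    """Configuration of the optimizer (always maximizes)."""

    n_spiders: int = 30
    max_iters: int = 100
    seed: int = 0
    bounds: tuple[float, float] = (0.0, 1.0)
    spf_mode: str = "proportion"  # see spf_scores

    def __post_init__(self) -> None:
        if self.n_spiders < 2:
            raise PsoaError("population size must be >= 2")
        if self.max_iters < 1:
            raise PsoaError("max_iters must be >= 1")
        lo, hi = self.bounds
        if not lo < hi:
            raise PsoaError("bounds must satisfy low < high")


@dataclass
class SpiderPopulation:
    """Positions, fitness and elitist best (prey) of the swarm."""

    positions: np.ndarray  # N x d
    fitness: np.ndarray  # N
    prey: np.ndarray  # d
    prey_fitness: float
    bounds: tuple[float, float]

    def clamp(self) -> None:
        np.clip(self.positions, self.bounds[0], self.bounds[1], out=self.positions)


@dataclass
class ConvergenceTrace:
    best_fitness: list[float] = field(default_factory=list)
    evaluations: int = 0

    def record(self, best: float, n_evals: int) -> None:
        self.best_fitness.append(best)
        self.evaluations += n_evals

    def to_rows(self) -> list[dict]:
        return [
            {"iteration": i, "best_fitness": f}
            for i, f in enumerate(self.best_fitness)
        ]


def spf_scores(fitness: np.ndarray, mode: str = "proportion") -> np.ndarray:
    """Standardized fitness share of each spider.

    ``proportion`` (default) is F_i / sum_j F_j, guaranteeing scores in
    [0, 1] that sum to 1 so they are comparable with uniform draws in
    the exploration step.  The alternative readings of the share —
    ``square-denominator`` F_i / sum_j F_j^2 and ``square-ratio``
    (F_i / sum_j F_j)^2 — are kept behind this switch.  Negative
    fitness must be shifted by the caller; an all-zero vector yields
    the uniform share 1/N.
    """
    f = np.asarray(fitness, dtype=float)
    if np.any(f < 0):
        raise PsoaError("spf_scores requires non-negative fitness (shift first)")
    if mode == "proportion":
        total = f.sum()
        if total == 0:
            return np.full(f.shape, 1.0 / f.size)
        return f / total
    if mode == "square-denominator":
        total = (f**2).sum()
        if total == 0:
            return np.full(f.shape, 1.0 / f.size)
        return f / total
    if mode == "square-ratio":
        total = f.sum()
        if total == 0:
            return np.full(f.shape, 1.0 / f.size)
        return (f / total) ** 2
    raise PsoaError(f"unknown spf mode {mode!r}")


def exploration_step(pop: SpiderPopulation, rng: np.random.Generator, spf_mode: str = "proportion") -> None:
    """Prey-directed jump: coordinate-wise replacement by the prey.

    For spider i and dimension j independently, draw a1 ~ U(0,1); the
    coordinate becomes the prey's t_j when a1 < SPF(S_i), else stays.
    Operates in place.
    """
    shifted = pop.fitness - min(pop.fitness.min(), 0.0)
    spf = spf_scores(shifted, mode=spf_mode)
    n, d = pop.positions.shape
    alpha1 = rng.random((n, d))
    jump = alpha1 < spf[:, None]
    pop.positions[jump] = np.broadcast_to(pop.prey, (n, d))[jump]


def alpha3_schedule(i_cur: int, i_max: int) -> float:
    """Spiral-amplitude exponent (1 - i_cur/i_max)^2, from 1 down to 0."""
    if i_max <= 0:
        raise PsoaError("i_max must be positive")
    if not 0 <= i_cur <= i_max:
        raise PsoaError("i_cur out of [0, i_max]")
    return (1.0 - i_cur / i_max) ** 2


def exploitation_step(
    pop: SpiderPopulation,
    i_cur: int,
    i_max: int,
    rng: np.random.Generator,
) -> None:
    """Spiral or linear move toward the prey, per spider, in place.

    a2, a4, a5 are drawn once per spider per iteration; a3 comes from
    the deterministic schedule.  With a5 < 0.5 the move is the spiral
    r + |a2*r - x| * e^{a3} * cos(2*pi*a4) applied per dimension with
    the prey coordinate as r; otherwise the linear pull
    r + a2*(r - x).  Positions are clamped to bounds afterwards.
    """
    n, d = pop.positions.shape
    alpha2 = rng.random(n)
    alpha4 = rng.random(n)
    alpha5 = rng.random(n)
    a3 = alpha3_schedule(i_cur, i_max)
    r = pop.prey[None, :]
    x = pop.positions
    spiral = r + np.abs(alpha2[:, None] * r - x) * np.exp(a3) * np.cos(2 * np.pi * alpha4)[:, None]
    linear = r + alpha2[:, None] * (r - x)
    pop.positions = np.where((alpha5 < 0.5)[:, None], spiral, linear)
    pop.clamp()


def _evaluate(objective, positions: np.ndarray, iteration: int) -> np.ndarray:
    try:
        return np.array([float(objective(p)) for p in positions])
    except Exception as exc:  # re-raise with loop context
        raise ObjectiveError(f"objective failed at iteration {iteration}") from exc


def psoa_optimize(
    objective: Callable[[np.ndarray], float],
    d: int,
    params: PsoaParams,
) -> tuple[np.ndarray, float, ConvergenceTrace]:
    """Maximize ``objective`` over the box ``params.bounds``^d.

    Runs the full loop: random initialization, then per iteration
    fitness evaluation and sorting, prey update (elitist best-so-far),
    exploration and exploitation.  Deterministic for a fixed seed.
    Returns the best position, its fitness and the convergence trace.
    """
    rng = np.random.default_rng(params.seed)
    lo, hi = params.bounds
    positions = rng.uniform(lo, hi, size=(params.n_spiders, d))
    fitness = _evaluate(objective, positions, 0)
    best_i = int(np.argmax(fitness))
    pop = SpiderPopulation(
        positions=positions,
        fitness=fitness,
        prey=positions[best_i].copy(),
        prey_fitness=float(fitness[best_i]),
        bounds=params.bounds,
    )
    trace = ConvergenceTrace()
    trace.record(pop.prey_fitness, params.n_spiders)
    for it in range(params.max_iters):
        order = np.argsort(pop.fitness)[::-1]
        pop.positions = pop.positions[order]
        pop.fitness = pop.fitness[order]
        exploration_step(pop, rng, spf_mode=params.spf_mode)
        exploitation_step(pop, it, params.max_iters, rng)
        pop.fitness = _evaluate(objective, pop.positions, it + 1)
        best_i = int(np.argmax(pop.fitness))
        if pop.fitness[best_i] > pop.prey_fitness:
            pop.prey = pop.positions[best_i].copy()
            pop.prey_fitness = float(pop.fitness[best_i])
        trace.record(pop.prey_fitness, params.n_spiders)
    return pop.prey, pop.prey_fitness, trace
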