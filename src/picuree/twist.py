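"""Joint evolutionary input selection and distribution-matched record splitting.

A single chromosome encodes both a feature mask over the candidate
variables and a two-way record split.  Fitness is blind predictive
performance of the MLP under the reversal protocol, penalized by the
distributional mismatch between the two halves, so the search
simultaneously minimizes the variable set and produces train/test halves
with similar empirical distributions.

The underlying search is a standard elitist genetic algorithm (tournament
selection, uniform crossover, per-bit mutation); the proprietary algorithm
it stands in for is reimplemented at contract level only.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .ann import MLPSpec, train_mlp
from .errors import ConfigurationError, DomainError

__all__ = [
    "Chromosome",
    "GAConfig",
    "SelectionResult",
    "distribution_similarity",
    "evaluate_fitness",
    "evolve",
    "run_twist",
]

NEG_INF = -np.inf

#: Maximum relative imbalance between split halves.
SPLIT_IMBALANCE_MAX = 0.10


@dataclass(frozen=True)
class Chromosome:
    feature_mask: np.ndarray  # bool per candidate variable
    split_assignment: np.ndarray  # bool per record; True = half A

    def __post_init__(self):
        object.__setattr__(self, "feature_mask", np.asarray(self.feature_mask, dtype=bool))
        object.__setattr__(
            self, "split_assignment", np.asarray(self.split_assignment, dtype=bool)
        )

    def key(self) -> bytes:
        return self.feature_mask.tobytes() + b"|" + self.split_assignment.tobytes()


@dataclass(frozen=True)
class GAConfig:
    population_size: int = 50
    generations: int = 100
    crossover_rate: float = 0.9
    mutation_rate: Optional[float] = None  # default 1/chromosome-length
    elitism_count: int = 2
    seed: int = 0
    fitness: str = "neg_mae"  # neg_mae | accuracy_rel
    distribution_penalty_weight: float = 1.0
    feature_penalty: float = 0.0  # optional explicit parsimony pressure
    tournament_size: int = 3

    def __post_init__(self):
        if not (0 <= self.crossover_rate <= 1):
            raise ConfigurationError("crossover_rate must be in [0, 1]")
        if self.mutation_rate is not None and not (0 <= self.mutation_rate <= 1):
            raise ConfigurationError("mutation_rate must be in [0, 1]")
        if self.elitism_count < 1 or self.elitism_count >= self.population_size:
            raise ConfigurationError("elitism_count must be in [1, population_size)")
        if self.fitness not in ("neg_mae", "accuracy_rel"):
            raise ConfigurationError(f"unknown fitness {self.fitness!r}")
        if self.distribution_penalty_weight < 0:
            raise ConfigurationError("distribution_penalty_weight must be nonnegative")


@dataclass
class SelectionResult:
    selected_features: list[str]
    split_plan: np.ndarray
    fitness_trajectory: list[float]
    final_fitness: float
    config: GAConfig = field(repr=False)

    def to_dict(self) -> dict:
        return {
            "selected_features": self.selected_features,
            "split_plan": [int(v) for v in self.split_plan],
            "fitness_trajectory": self.fitness_trajectory,
            "final_fitness": self.final_fitness,
        }


def _is_binary(col: np.ndarray) -> bool:
    vals = np.unique(col[~np.isnan(col)])
    return vals.size <= 2 and np.all(np.isin(vals, (0.0, 1.0)))


def distribution_similarity(data, split_assignment) -> float:
    """Mean distributional distance between split halves over all variables.

    Continuous variables contribute a two-sample Kolmogorov-Smirnov
    statistic, binary variables the absolute difference in proportions;
    0 iff the halves have identical empirical distributions.
    """
    arr = np.atleast_2d(np.asarray(data, dtype=float))
    split = np.asarray(split_assignment, dtype=bool).ravel()
    if split.all() or (~split).all():
        raise DomainError("both split halves must be nonempty")
    a, b = arr[split], arr[~split]
    parts = []
    for j in range(arr.shape[1]):
        col_a, col_b = a[:, j], b[:, j]
        if _is_binary(arr[:, j]):
            parts.append(abs(col_a.mean() - col_b.mean()))
        else:
            parts.append(stats.ks_2samp(col_a, col_b, method="asymp").statistic)
    return float(np.mean(parts))


def _split_balanced(split: np.ndarray) -> bool:
    n = split.size
    n_a = int(split.sum())
    return abs(n_a - n / 2) <= SPLIT_IMBALANCE_MAX * (n / 2) and 0 < n_a < n


def _repair(chrom: Chromosome, rng: np.random.Generator) -> Chromosome:
    """Enforce chromosome invariants: >=1 feature, near-balanced split."""
    mask = chrom.feature_mask.copy()
    split = chrom.split_assignment.copy()
    if not mask.any():
        mask[rng.integers(mask.size)] = True
    n = split.size
    lo = int(np.ceil((n / 2) * (1 - SPLIT_IMBALANCE_MAX)))
    hi = int(np.floor((n / 2) * (1 + SPLIT_IMBALANCE_MAX)))
    lo, hi = max(lo, 1), min(hi, n - 1)
    n_a = int(split.sum())
    if n_a < lo:
        idx = rng.choice(np.flatnonzero(~split), size=lo - n_a, replace=False)
        split[idx] = True
    elif n_a > hi:
        idx = rng.choice(np.flatnonzero(split), size=n_a - hi, replace=False)
        split[idx] = False
    return Chromosome(mask, split)


def evaluate_fitness(
    chromosome: Chromosome,
    X: np.ndarray,
    y: np.ndarray,
    mlp_spec: MLPSpec,
    config: GAConfig,
) -> float:
    """Blind reversal score of the masked features minus the split penalty.

    Trains on half A, scores on half B, and vice versa; the two test scores
    are averaged.  Degenerate chromosomes (no usable features, unbalanced
    split, constant features within a training half) get a -inf sentinel.
    """
    mask = chromosome.feature_mask
    split = chromosome.split_assignment
    if not mask.any() or not _split_balanced(split):
        return NEG_INF
    Xm = X[:, mask]
    scores = []
    for train_mask in (split, ~split):
        Xtr, ytr = Xm[train_mask], y[train_mask]
        usable = Xtr.std(axis=0) > 0
        if not usable.any():
            return NEG_INF
        model = train_mlp(Xtr[:, usable], ytr, mlp_spec)
        pred = model.predict(Xm[~train_mask][:, usable])
        true = y[~train_mask]
        if config.fitness == "neg_mae":
            scores.append(-float(np.abs(pred - true).mean()))
        else:
            rel = np.abs(pred - true) / np.abs(true)
            scores.append(100.0 * (1.0 - float(rel.mean())))
    fitness = float(np.mean(scores))
    if config.distribution_penalty_weight > 0:
        fitness -= config.distribution_penalty_weight * distribution_similarity(X, split)
    if config.feature_penalty > 0:
        fitness -= config.feature_penalty * int(mask.sum())
    return fitness


def _tournament(fitnesses: np.ndarray, rng: np.random.Generator, k: int) -> int:
    contenders = rng.integers(0, fitnesses.size, size=k)
    return int(contenders[np.argmax(fitnesses[contenders])])


def evolve(
    population: list[Chromosome],
    fitnesses,
    config: GAConfig,
    rng: np.random.Generator,
) -> list[Chromosome]:
    """One elitist GA generation: tournament, uniform crossover, bit-flip mutation."""
    fitnesses = np.asarray(fitnesses, dtype=float)
    if len(population) != config.population_size or fitnesses.size != len(population):
        raise ConfigurationError("population/fitness size must match config.population_size")
    n_feat = population[0].feature_mask.size
    n_rec = population[0].split_assignment.size
    length = n_feat + n_rec
    mut = config.mutation_rate if config.mutation_rate is not None else 1.0 / length
    elite_idx = np.argsort(fitnesses)[::-1][: config.elitism_count]
    nxt: list[Chromosome] = [population[i] for i in elite_idx]
    while len(nxt) < config.population_size:
        p1 = population[_tournament(fitnesses, rng, config.tournament_size)]
        p2 = population[_tournament(fitnesses, rng, config.tournament_size)]
        g1 = np.concatenate([p1.feature_mask, p1.split_assignment])
        g2 = np.concatenate([p2.feature_mask, p2.split_assignment])
        if rng.random() < config.crossover_rate:
            take = rng.random(length) < 0.5
            child = np.where(take, g1, g2)
        else:
            child = g1.copy()
        flip = rng.random(length) < mut
        child = child ^ flip
        nxt.append(
            _repair(Chromosome(child[:n_feat], child[n_feat:]), rng)
        )
    return nxt


def _random_population(
    n_feat: int, n_rec: int, config: GAConfig, rng: np.random.Generator
) -> list[Chromosome]:
    pop = []
    for _ in range(config.population_size):
        mask = rng.random(n_feat) < 0.5
        split = np.zeros(n_rec, dtype=bool)
        split[rng.permutation(n_rec)[: n_rec // 2]] = True
        pop.append(_repair(Chromosome(mask, split), rng))
    return pop


def run_twist(
    data: pd.DataFrame,
    target: str,
    candidates: list[str],
    config: GAConfig,
    mlp_spec: MLPSpec,
) -> SelectionResult:
    """Run the evolutionary search and return the best feature set + split.

    Fully reproducible for a fixed ``(data, config)``; fitness evaluations
    are memoized per chromosome so converged populations are cheap.
    """
    if len(candidates) < 2:
        if len(candidates) == 1 and len(data) >= 20:
            # degenerate case: no feature search, just pick the best split
            config = replace(config, generations=1)
        else:
            raise ConfigurationError("run_twist requires at least 2 candidate variables")
    if len(data) < 20:
        raise ConfigurationError("run_twist requires at least 20 records")
    missing = [c for c in list(candidates) + [target] if c not in data.columns]
    if missing:
        raise ConfigurationError(f"columns missing from data: {missing}")

    X = data[list(candidates)].to_numpy(dtype=float)
    y = data[target].to_numpy(dtype=float)
    rng = np.random.default_rng(config.seed)
    pop = _random_population(len(candidates), len(data), config, rng)
    if len(candidates) == 1:
        pop = [Chromosome(np.ones(1, dtype=bool), c.split_assignment) for c in pop]

    cache: dict[bytes, float] = {}

    def fit_of(chrom: Chromosome) -> float:
        k = chrom.key()
        if k not in cache:
            cache[k] = evaluate_fitness(chrom, X, y, mlp_spec, config)
        return cache[k]

    best: Optional[Chromosome] = None
    best_fit = NEG_INF
    trajectory: list[float] = []
    for gen in range(config.generations):
        fits = np.array([fit_of(c) for c in pop])
        gen_best = int(np.argmax(fits))
        if fits[gen_best] > best_fit:
            best_fit = float(fits[gen_best])
            best = pop[gen_best]
        trajectory.append(best_fit)
        if gen < config.generations - 1:
            pop = evolve(pop, fits, config, rng)
    assert best is not None
    selected = [c for c, keep in zip(candidates, best.feature_mask) if keep]
    return SelectionResult(
        selected_features=selected,
        split_plan=best.split_assignment.copy(),
        fitness_trajectory=trajectory,
        final_fitness=best_fit,
        config=config,
    )
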