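"""Genetic-algorithm wrapper feature selection.

A chromosome is a 204-bit mask over the feature vector. Its fitness is the
cost

    cost = 1 / (accuracy + 1 / NOF)

where accuracy is the classifier's 10-fold CV accuracy (a fraction in
[0, 1]) on the selected columns and NOF the number of selected features;
lower cost is better, so the GA maximizes accuracy while pressuring the
feature count down through the 1/NOF term.

Operators: tournament selection (size 3), uniform crossover (probability
0.8), per-bit flip mutation at rate 1/L, elitism of 1, empty chromosomes
repaired by switching one random bit on. Fold assignment is fixed for the
whole run so chromosome costs are comparable, and evaluations are cached by
bit pattern.
"""

from __future__ import annotations

import dataclasses
from typing import Dict, List, Optional, Tuple

import numpy as np

from .classify import ClassifierSpec, cv_accuracy, kfold_split
from .errors import ParameterError, StratificationError

POPULATION_SIZE = 100
MAX_ITERATIONS = 500
TOURNAMENT_SIZE = 3
CROSSOVER_PROB = 0.8
ELITE_COUNT = 1


def cost(accuracy: float, nof: int) -> float:
    """GA cost 1/(accuracy + 1/NOF); lower is better."""
    if nof < 1:
        raise ParameterError("cost undefined when no features are selected")
    if not 0.0 <= accuracy <= 1.0:
        raise ParameterError("accuracy must be a fraction in [0, 1]")
    return 1.0 / (accuracy + 1.0 / nof)


@dataclasses.dataclass
class Chromosome:
    bits: np.ndarray
    accuracy: Optional[float] = None
    cost: Optional[float] = None

    @property
    def nof(self) -> int:
        return int(self.bits.sum())


@dataclasses.dataclass
class GaRun:
    """Full history of one GA run (for cost curves and selection maps)."""

    best_bits: np.ndarray
    best_cost: float
    best_accuracy: float
    history_cost: List[float]
    history_bits: List[np.ndarray]
    rng_seed: int
    population_size: int
    iterations: int


class _Evaluator:
    """Caching CV evaluator with folds fixed per GA run."""

    def __init__(self, X: np.ndarray, y: np.ndarray, spec: ClassifierSpec,
                 k: int, rng_seed: int):
        self.X = np.asarray(X, dtype=float)
        self.y = np.asarray(y, dtype=int)
        if len(np.unique(self.y)) < 2:
            raise StratificationError("feature table must contain both classes")
        self.spec = spec
        self.folds = kfold_split(len(self.y), k=k, labels=self.y, rng_seed=rng_seed)
        self.rng_seed = rng_seed
        self.cache: Dict[bytes, Tuple[float, float]] = {}

    def __call__(self, bits: np.ndarray) -> Tuple[float, float]:
        key = np.packbits(bits).tobytes()
        if key not in self.cache:
            acc = cv_accuracy(self.spec, self.X[:, bits], self.y,
                              folds=self.folds, rng_seed=self.rng_seed)
            self.cache[key] = (acc, cost(acc, int(bits.sum())))
        return self.cache[key]


def evaluate_chromosome(bits: np.ndarray, X: np.ndarray, y: np.ndarray,
                        spec: ClassifierSpec, *, k: int = 10,
                        rng_seed: int = 0) -> Tuple[float, float]:
    """(accuracy, cost) of one bit mask under k-fold CV."""
    bits = np.asarray(bits, dtype=bool)
    if bits.sum() == 0:
        raise ParameterError("at least one feature must be selected")
    return _Evaluator(X, y, spec, k, rng_seed)(bits)


def _repair(bits: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    if bits.sum() == 0:
        bits = bits.copy()
        bits[rng.integers(len(bits))] = True
    return bits


def ga_select(X: np.ndarray, y: np.ndarray, spec: ClassifierSpec, *,
              population: int = POPULATION_SIZE,
              iterations: int = MAX_ITERATIONS,
              k: int = 10, rng_seed: int = 0) -> GaRun:
    """Run the GA and return the best chromosome with the full history."""
    X = np.asarray(X, dtype=float)
    n_features = X.shape[1]
    rng = np.random.default_rng(rng_seed)
    evaluate = _Evaluator(X, y, spec, k, rng_seed)
    mutation_rate = 1.0 / n_features

    pop = [_repair(rng.random(n_features) < 0.5, rng) for _ in range(population)]
    costs = np.array([evaluate(b)[1] for b in pop])

    history_cost: List[float] = []
    history_bits: List[np.ndarray] = []
    for _ in range(iterations):
        order = np.argsort(costs)
        elite = [pop[i].copy() for i in order[:ELITE_COUNT]]
        children: List[np.ndarray] = list(elite)
        while len(children) < population:
            parents = []
            for _ in range(2):
                contenders = rng.integers(0, population, TOURNAMENT_SIZE)
                parents.append(pop[min(contenders, key=lambda i: costs[i])])
            a, b = parents[0].copy(), parents[1].copy()
            if rng.random() < CROSSOVER_PROB:
                swap = rng.random(n_features) < 0.5
                a[swap], b[swap] = b[swap], a[swap].copy()
            for child in (a, b):
                flip = rng.random(n_features) < mutation_rate
                child ^= flip
                children.append(_repair(child, rng))
        pop = children[:population]
        costs = np.array([evaluate(b)[1] for b in pop])
        best = int(np.argmin(costs))
        history_cost.append(float(costs[best]))
        history_bits.append(pop[best].copy())

    best = int(np.argmin(costs))
    acc, c = evaluate(pop[best])
    return GaRun(best_bits=pop[best].copy(), best_cost=c, best_accuracy=acc,
                 history_cost=history_cost, history_bits=history_bits,
                 rng_seed=rng_seed, population_size=population,
                 iterations=iterations)


def selection_map(run: GaRun) -> np.ndarray:
    """Binary matrix (n_features x iterations): column t = best bits at t.

    Rendered as an image (white = selected) this shows which features the
    GA holds onto across generations; a solid horizontal line is a feature
    selected in every generation.
    """
    if not run.history_bits:
        raise ParameterError("run has no history")
    return np.stack(run.history_bits, axis=1).astype(np.uint8)


def write_selection_map_png(run: GaRun, path) -> None:
    from .image import write_png

    write_png(path, selection_map(run) * 255)
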