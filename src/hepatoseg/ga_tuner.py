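"""Real-coded genetic algorithm for tuning the five level-set parameters.

Each individual carries one gene per parameter ``(min_rms, G_L, G_H, beta,
gamma)``.  Fitness of an individual is ``F = 100 - S`` where ``S`` is the
total human-anchored score of the segmentations it produces against the
reference masks, aggregated over the training exams by mean or minimum;
minimising ``F`` therefore maximises agreement with the references.

The evolutionary scheme: uniform initialisation within per-gene ranges;
fitness-proportional selection with single-individual elitism; arithmetic
crossover; Gaussian-perturbation mutation clipped to the ranges; a
steady-state fraction of the population (its best part) carried over
unchanged each generation.  Crossover, mutation and steady-state rates
interpolate linearly between their initial and final values across the
generations.  Two sequenced experiments are run by default, the second
seeded with a fraction of copies of the first experiment's best individual.

Because the segmentation is expensive and the GA revisits genotypes,
fitness values are cached by the rounded gene tuple.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .eval_metrics import HumanErrorRefs, compute_metrics, total_score
from .liver_levelset import LevelSetParams, segment_liver
from .volume_io import Mask, Volume

__all__ = ["GAConfig", "Individual", "evaluate_fitness", "run_ga",
           "make_segmentation_fitness"]

log = logging.getLogger(__name__)

GENE_NAMES = ("min_rms", "G_L", "G_H", "beta", "gamma")

# Default per-gene search ranges, widened around the regimes in which the
# parameters are known to behave well (min RMS around 0.01-0.03, the
# Gaussian factors around 0.2-0.5, curvature weight up to ~1000).  beta is
# searched by magnitude; the solver's sign convention fixes its effect.
DEFAULT_RANGES: dict[str, tuple[float, float]] = {
    "min_rms": (0.005, 0.05),
    "G_L": (0.1, 0.7),
    "G_H": (0.1, 0.7),
    "beta": (0.5, 50.0),
    "gamma": (0.0, 1000.0),
}


@dataclass
class GAConfig:
    n_generations: int = 30
    population_size: int = 30
    crossover_rate_initial: float = 0.8
    crossover_rate_final: float = 0.65
    mutation_rate_initial: float = 0.1
    mutation_rate_final: float = 0.8
    steady_state_rate_initial: float = 0.8
    steady_state_rate_final: float = 0.2
    n_sequenced_experiments: int = 2
    seed_rate_between_experiments: float = 0.1
    mutation_sigma_fraction: float = 0.05  # of the gene range width
    ranges: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_RANGES)
    )
    aggregation: str = "mean"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        rates = (
            self.crossover_rate_initial, self.crossover_rate_final,
            self.mutation_rate_initial, self.mutation_rate_final,
            self.steady_state_rate_initial, self.steady_state_rate_final,
            self.seed_rate_between_experiments,
        )
        if any(not 0.0 <= r <= 1.0 for r in rates):
            raise ValueError("all rates must lie in [0, 1]")
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        if self.aggregation not in ("mean", "min"):
            raise ValueError("aggregation must be 'mean' or 'min'")
        for name, (lo, hi) in self.ranges.items():
            if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
                raise ValueError(f"invalid range for {name}: ({lo}, {hi})")

    def range_array(self) -> np.ndarray:
        return np.array([self.ranges[n] for n in GENE_NAMES], dtype=float)


@dataclass
class Individual:
    genes: np.ndarray  # (min_rms, G_L, G_H, beta, gamma)
    fitness: float | None = None  # F; smaller is better

    def params(self) -> LevelSetParams:
        g = self.genes
        return LevelSetParams(
            min_rms=float(g[0]), G_L=float(g[1]), G_H=float(g[2]),
            beta=-abs(float(g[3])), gamma=float(g[4]),
        )


TrainingCase = tuple[Volume, int, np.ndarray, Mask]  # volume, slice, init, ref


def evaluate_fitness(
    individual: Individual,
    training_set: Sequence[TrainingCase],
    refs: HumanErrorRefs,
    aggregation: str = "mean",
) -> float:
    """``F = 100 - aggregated total score`` over the training exams.

    A failed or empty segmentation contributes a score of 0 for its exam.
    """
    if not training_set:
        raise ValueError("training set is empty")
    scores = []
    for vol, k, init2d, ref in training_set:
        try:
            seg = segment_liver(vol, k, init2d, individual.params())
            m = compute_metrics(seg, ref)
            scores.append(total_score(m, refs).total_score)
        except (ValueError, RuntimeError) as exc:
            log.warning("segmentation failed during fitness evaluation: %s",
                        exc)
            scores.append(0.0)
    agg = min(scores) if aggregation == "min" else float(np.mean(scores))
    return 100.0 - agg


def make_segmentation_fitness(
    training_set: Sequence[TrainingCase],
    refs: HumanErrorRefs,
    aggregation: str = "mean",
) -> Callable[[np.ndarray], float]:
    def fn(genes: np.ndarray) -> float:
        return evaluate_fitness(Individual(genes=genes), training_set, refs,
                                aggregation)
    return fn


def _lerp(a: float, b: float, t: float) -> float:
    return a + (b - a) * t


def _select(pop: list[Individual], rng: np.random.Generator) -> Individual:
    """Fitness-proportional selection on (max_F - F)."""
    f = np.array([ind.fitness for ind in pop])
    w = f.max() - f
    if w.sum() <= 0:
        return pop[int(rng.integers(len(pop)))]
    p = w / w.sum()
    return pop[int(rng.choice(len(pop), p=p))]


def run_ga(
    cfg: GAConfig,
    training_set: Sequence[TrainingCase] | None = None,
    refs: HumanErrorRefs | None = None,
    fitness_fn: Callable[[np.ndarray], float] | None = None,
) -> tuple[Individual, list[dict]]:
    """Run the full GA (all sequenced experiments); return the best
    individual and a per-generation history of best/mean fitness.

    ``fitness_fn`` maps a gene vector to ``F`` (smaller is better); when not
    given it is built from ``training_set`` and ``refs`` via
    :func:`evaluate_fitness`.
    """
    if fitness_fn is None:
        if not training_set:
            raise ValueError("training set is empty and no fitness_fn given")
        if refs is None:
            raise ValueError("human-error references are required")
        fitness_fn = make_segmentation_fitness(training_set, refs,
                                               cfg.aggregation)

    rng = np.random.default_rng(cfg.rng_seed)
    ranges = cfg.range_array()
    lo, hi = ranges[:, 0], ranges[:, 1]
    width = hi - lo
    cache: dict[tuple, float] = {}

    def evaluate(ind: Individual) -> None:
        key = tuple(np.round(ind.genes, 6))
        if key not in cache:
            cache[key] = float(fitness_fn(ind.genes))
        ind.fitness = cache[key]

    history: list[dict] = []
    overall_best: Individual | None = None

    for exp in range(max(cfg.n_sequenced_experiments, 1)):
        pop = [
            Individual(genes=rng.uniform(lo, hi))
            for _ in range(cfg.population_size)
        ]
        if exp > 0 and overall_best is not None:
            n_seed = int(round(cfg.seed_rate_between_experiments
                               * cfg.population_size))
            for i in range(min(n_seed, cfg.population_size)):
                pop[i] = Individual(genes=overall_best.genes.copy())
        for ind in pop:
            evaluate(ind)
        pop.sort(key=lambda i: i.fitness)

        for gen in range(cfg.n_generations):
            t = gen / max(cfg.n_generations - 1, 1)
            cr = _lerp(cfg.crossover_rate_initial, cfg.crossover_rate_final, t)
            mr = _lerp(cfg.mutation_rate_initial, cfg.mutation_rate_final, t)
            ss = _lerp(cfg.steady_state_rate_initial,
                       cfg.steady_state_rate_final, t)
            n_keep = max(1, int(round(ss * cfg.population_size)))
            nxt = [Individual(genes=p.genes.copy(), fitness=p.fitness)
                   for p in pop[:n_keep]]
            while len(nxt) < cfg.population_size:
                p1 = _select(pop, rng)
                if rng.random() < cr:
                    p2 = _select(pop, rng)
                    u = rng.random(len(GENE_NAMES))
                    child = u * p1.genes + (1.0 - u) * p2.genes
                else:
                    child = p1.genes.copy()
                mutate = rng.random(len(GENE_NAMES)) < mr
                noise = rng.normal(
                    0.0, cfg.mutation_sigma_fraction * width,
                    len(GENE_NAMES),
                )
                child = np.where(mutate, child + noise, child)
                child = np.clip(child, lo, hi)
                nxt.append(Individual(genes=child))
            for ind in nxt:
                evaluate(ind)
            nxt.sort(key=lambda i: i.fitness)
            # elitism: the best of the previous generation always survives
            if nxt[0].fitness > pop[0].fitness:
                nxt[-1] = pop[0]
                nxt.sort(key=lambda i: i.fitness)
            pop = nxt
            history.append({
                "experiment": exp,
                "generation": gen,
                "best_F": pop[0].fitness,
                "mean_F": float(np.mean([i.fitness for i in pop])),
            })
        if overall_best is None or pop[0].fitness < overall_best.fitness:
            overall_best = Individual(genes=pop[0].genes.copy(),
                                      fitness=pop[0].fitness)
        log.info("experiment %d finished: best F = %.4f", exp,
                 overall_best.fitness)

    assert overall_best is not None
    return overall_best, history
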