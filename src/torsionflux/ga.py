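"""Genetic-algorithm wrapper feature selection.

Each chromosome is a binary mask over feature columns (one gene per
column).  A chromosome's fitness is the cross-validated performance of
a gradient-boosted regressor restricted to its selected columns,
scored with the combined objective

    objfit = 1 - MAE + PCC

(2 is a perfect predictor).  The population evolves by elitism,
fitness-proportional (roulette) parent selection, single-point
crossover and per-gene bit-flip mutation.  Everything is reproducible
from the config seed.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
from lightgbm import LGBMRegressor

from .evaluate import chain_level_folds, mae, pcc

__all__ = [
    "Chromosome",
    "GAConfig",
    "EMPTY_MASK_FITNESS",
    "FITNESS_MODEL_PARAMS",
    "objfit",
    "evaluate_fitness",
    "evolve",
    "select_features",
    "save_selection",
]

EMPTY_MASK_FITNESS = float("-inf")

# Boosted-tree settings for the (fast) fitness model used inside the GA;
# the final predictor uses its own tuned RegressorConfig.
FITNESS_MODEL_PARAMS = dict(
    max_depth=6,
    learning_rate=0.1,
    n_estimators=100,
    min_child_weight=5,
    subsample=0.9,
    subsample_freq=1,
    max_bin=500,
)


@dataclass
class Chromosome:
    """Binary feature mask with cached fitness."""

    mask: np.ndarray
    fitness: float = EMPTY_MASK_FITNESS

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def n_selected(self) -> int:
        return int(self.mask.sum())


@dataclass
class GAConfig:
    population_size: int = 50
    generations: int = 30
    elite_count: int = 2
    crossover_rate: float = 0.9
    mutation_rate: float | None = None  # default 1/D, set at run time
    seed: int = 0
    fitness_cv_folds: int = 3

    def __post_init__(self) -> None:
        if not 0 <= self.crossover_rate <= 1:
            raise ValueError("crossover_rate must be a probability")
        if self.mutation_rate is not None and not 0 <= self.mutation_rate <= 1:
            raise ValueError("mutation_rate must be a probability")
        if self.elite_count >= self.population_size:
            raise ValueError("elite_count must be smaller than population_size")


def objfit(mae_value: float, pcc_value: float) -> float:
    """Combined objective 1 - MAE + PCC (higher is better)."""
    return 1.0 - mae_value + pcc_value


def _fitness_model(seed: int) -> LGBMRegressor:
    return LGBMRegressor(
        **FITNESS_MODEL_PARAMS,
        random_state=seed,
        deterministic=True,
        force_row_wise=True,
        n_jobs=1,
        verbose=-1,
    )


def evaluate_fitness(c: Chromosome, X, y, chain_ids, cfg: GAConfig) -> float:
    """objfit of pooled out-of-fold predictions under chain-level CV,
    using only the chromosome's selected columns.

    An empty mask gets the -inf sentinel and is never selected.
    Deterministic for a given seed.
    """
    if c.n_selected == 0:
        return EMPTY_MASK_FITNESS
    X = np.asarray(X, dtype=float)[:, c.mask]
    y = np.asarray(y, dtype=float)
    chain_ids = np.asarray(chain_ids)
    assignment = chain_level_folds(chain_ids, k=cfg.fitness_cv_folds, seed=cfg.seed)
    folds = np.array([assignment[cid] for cid in chain_ids])
    oof = np.empty_like(y)
    for f in range(cfg.fitness_cv_folds):
        test = folds == f
        model = _fitness_model(cfg.seed)
        with warnings.catch_warnings():
            warnings.filterwarnings("ignore", message=".*feature names.*")
            model.fit(X[~test], y[~test])
            oof[test] = model.predict(X[test])
    return objfit(mae(oof, y), pcc(oof, y))


def _roulette_pick(rng: np.random.Generator, fitnesses: np.ndarray) -> int:
    finite = np.isfinite(fitnesses)
    if not finite.any():
        raise ValueError("all chromosomes carry the empty-mask sentinel")
    w = np.where(finite, fitnesses, np.nan)
    shifted = w - np.nanmin(w)
    shifted = np.where(finite, shifted + 1e-12, 0.0)
    p = shifted / shifted.sum()
    return int(rng.choice(len(fitnesses), p=p))


def evolve(pop: list[Chromosome], cfg: GAConfig, rng: np.random.Generator) -> list[Chromosome]:
    """One generation: elitism, roulette selection, single-point
    crossover, per-gene bit-flip mutation.  Population size preserved;
    returned non-elite chromosomes are unevaluated."""
    D = pop[0].mask.size
    mut = cfg.mutation_rate if cfg.mutation_rate is not None else 1.0 / D
    fitnesses = np.array([c.fitness for c in pop])
    order = np.argsort(-fitnesses, kind="stable")
    next_pop: list[Chromosome] = [
        Chromosome(pop[i].mask.copy(), pop[i].fitness) for i in order[: cfg.elite_count]
    ]
    while len(next_pop) < cfg.population_size:
        a = pop[_roulette_pick(rng, fitnesses)].mask.copy()
        b = pop[_roulette_pick(rng, fitnesses)].mask.copy()
        if D > 1 and rng.random() < cfg.crossover_rate:
            point = int(rng.integers(1, D))
            a = np.concatenate([a[:point], b[point:]])
        flips = rng.random(D) < mut
        child = np.where(flips, ~a, a)
        next_pop.append(Chromosome(child))
    return next_pop[: cfg.population_size]


def select_features(X, y, chain_ids, cfg: GAConfig):
    """Run the GA from a uniform-random population; return
    (best Chromosome ever seen, per-generation best-fitness history).

    Fully reproducible from cfg.seed.  Repeated masks are looked up in
    a cache instead of re-trained.  Degenerate inputs (e.g. all
    constant columns) complete normally -- the search then just cannot
    separate masks.
    """
    X = np.asarray(X, dtype=float)
    D = X.shape[1]
    rng = np.random.default_rng(cfg.seed)
    cache: dict[bytes, float] = {}

    def fit_of(c: Chromosome) -> float:
        key = np.packbits(c.mask).tobytes()
        if key not in cache:
            cache[key] = evaluate_fitness(c, X, y, chain_ids, cfg)
        return cache[key]

    pop = [Chromosome(rng.random(D) < 0.5) for _ in range(cfg.population_size)]
    best: Chromosome | None = None
    history: list[float] = []
    for _ in range(cfg.generations):
        for c in pop:
            c.fitness = fit_of(c)
        gen_best = max(pop, key=lambda c: c.fitness)
        if best is None or gen_best.fitness > best.fitness:
            best = Chromosome(gen_best.mask.copy(), gen_best.fitness)
        history.append(best.fitness)
        pop = evolve(pop, cfg, rng)
    return best, history


def save_selection(best: Chromosome, history: list[float], path) -> None:
    """Serialize the selected mask and fitness trace as JSON."""
    payload = {
        "mask": [int(v) for v in best.mask],
        "fitness": best.fitness,
        "n_selected": best.n_selected,
        "history": history,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
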