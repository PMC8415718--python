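"""Genetic-algorithm wrapper feature selection over synthetic variables.

Genomes are bit vectors marking which retained synthetic variables enter the
logistic model.  Fitness is the binormally smoothed AUC of the model's
predicted probabilities on a validation split (fast deterministic
maximum-likelihood fits by default; full HMC fits optionally).  Parents are
drawn by linear rank selection with selection pressure bounded by
min/n and max/n (min + max = 2); offspring undergo single-point crossover
with probability 0.8 and, with probability 0.1 per genome, a single
uniformly chosen bit flip.  The top elite fraction of each generation is
copied unchanged, which makes the per-generation maximum fitness
non-decreasing.  The initial population has a forced prefix of bits switched
on (the leading synthetic variables); later genetic operators may clear them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bayes import BayesianLogit
from .roc import smoothed_auc

__all__ = [
    "GAConfig",
    "GATrace",
    "ConfigError",
    "rank_selection_probs",
    "single_point_crossover",
    "mutate",
    "FitnessEvaluator",
    "run_ga",
]


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class GAConfig:
    """GA hyper-parameters.  Defaults are the full-scale study settings."""

    population: int = 500
    generations: int = 200
    crossover_prob: float = 0.8
    mutation_prob: float = 0.1
    elite_fraction: float = 0.05
    selection_min: float = 0.7
    selection_max: float = 1.3
    forced_prefix: int = 7
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(self.selection_min + self.selection_max - 2.0) > 1e-9:
            raise ConfigError("selection min + max must equal 2")
        for p in (self.crossover_prob, self.mutation_prob):
            if not 0.0 <= p <= 1.0:
                raise ConfigError("probabilities must lie in [0,1]")
        if self.elite_fraction * self.population < 1:
            raise ConfigError("elite fraction x population must be >= 1")

    @classmethod
    def desk_scale(cls, seed: int = 0, **overrides) -> "GAConfig":
        """A small configuration for interactive runs and tests."""
        base = dict(population=50, generations=25, seed=seed)
        base.update(overrides)
        return cls(**base)

    @property
    def n_elite(self) -> int:
        return max(1, int(np.ceil(self.elite_fraction * self.population)))


@dataclass
class GATrace:
    max_fitness: list[float] = field(default_factory=list)
    mean_fitness: list[float] = field(default_factory=list)
    median_fitness: list[float] = field(default_factory=list)
    best_genomes: list[np.ndarray] = field(default_factory=list)
    cache_hits: int = 0
    evaluations: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "generation": np.arange(1, len(self.max_fitness) + 1),
                "max": self.max_fitness,
                "mean": self.mean_fitness,
                "median": self.median_fitness,
            }
        )


def rank_selection_probs(n: int, selection_min: float = 0.7, selection_max: float = 1.3) -> np.ndarray:
    """Linear rank-selection probabilities, worst to best.

    p_i = (min + (max - min) * i / (n - 1)) / n with zero-based rank i
    (i = 0 worst, i = n-1 best), so the probabilities sum to exactly 1 and
    the worst/best individuals have probabilities min/n and max/n.
    """
    if abs(selection_min + selection_max - 2.0) > 1e-9:
        raise ConfigError("selection min + max must equal 2")
    if n < 2:
        raise ConfigError("population must have n >= 2")
    ranks = np.arange(n)
    return (selection_min + (selection_max - selection_min) * ranks / (n - 1)) / n


def single_point_crossover(
    g1: np.ndarray, g2: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Exchange suffixes after a uniform cut point in 1..m-1."""
    if len(g1) != len(g2):
        raise ValueError("genomes must have equal length")
    if len(g1) < 2:
        raise ValueError("genomes must have length >= 2")
    cut = int(rng.integers(1, len(g1)))
    c1 = np.concatenate([g1[:cut], g2[cut:]])
    c2 = np.concatenate([g2[:cut], g1[cut:]])
    return c1, c2


def mutate(genome: np.ndarray, rng: np.random.Generator, prob: float = 0.1) -> np.ndarray:
    """With probability ``prob``, flip one uniformly chosen bit."""
    if len(genome) == 0:
        raise ValueError("genome must be nonempty")
    if rng.random() < prob:
        out = genome.copy()
        j = int(rng.integers(0, len(genome)))
        out[j] = 1 - out[j]
        return out
    return genome


class FitnessEvaluator:
    """Memoized smoothed-AUC fitness of a variable subset.

    Fits a logistic model on the training columns selected by the genome and
    scores the binormally smoothed AUC of its predicted probabilities on the
    validation split.  ``mode='mle'`` (default) uses the deterministic Newton
    fit; ``mode='hmc'`` uses the full posterior's mean predicted probability.
    An empty subset scores -inf; a non-converged fit falls back to 0.5 (the
    no-signal AUC), logged in ``failures``.
    """

    def __init__(self, train_X, train_y, val_X, val_y, mode: str = "mle", hmc_kwargs=None):
        if mode not in ("mle", "hmc"):
            raise ConfigError(f"unknown fitness mode {mode!r}")
        self.train_X = np.asarray(train_X, dtype=float)
        self.train_y = np.asarray(train_y)
        self.val_X = np.asarray(val_X, dtype=float)
        self.val_y = np.asarray(val_y)
        self.mode = mode
        self.hmc_kwargs = hmc_kwargs or {}
        self.cache: dict[bytes, float] = {}
        self.cache_hits = 0
        self.fits = 0
        self.failures = 0

    def __call__(self, genome: np.ndarray) -> float:
        key = np.packbits(genome.astype(np.uint8)).tobytes()
        if key in self.cache:
            self.cache_hits += 1
            return self.cache[key]
        value = self._evaluate(genome)
        self.cache[key] = value
        return value

    def _evaluate(self, genome: np.ndarray) -> float:
        cols = np.flatnonzero(genome)
        if cols.size == 0:
            return -np.inf
        self.fits += 1
        model = BayesianLogit(self.train_y, self.train_X[:, cols])
        try:
            if self.mode == "mle":
                res = model.fit_mle()
                if not res.converged:
                    self.failures += 1
                    return 0.5
            else:
                res = model.fit(**self.hmc_kwargs)
            probs = res.predict_prob(self.val_X[:, cols])
            return smoothed_auc(probs, self.val_y)
        except Exception:  # degenerate ROC / non-convergence: no-signal fitness
            self.failures += 1
            return 0.5


def _order_population(pop: np.ndarray, fitness: np.ndarray) -> np.ndarray:
    """Indices worst-to-best; ties favour smaller subsets then lexicographic order."""
    sizes = pop.sum(axis=1)
    lex = [tuple(g) for g in pop]
    keyed = sorted(
        range(len(pop)),
        key=lambda i: (fitness[i], -sizes[i], tuple(-b for b in lex[i])),
    )
    return np.array(keyed)


def run_ga(
    config: GAConfig,
    evaluate,
    genome_length: int,
) -> tuple[np.ndarray, GATrace]:
    """Run the GA; returns the best-ever genome and the per-generation trace."""
    if genome_length < max(2, config.forced_prefix):
        raise ConfigError("genome length must cover the forced prefix")
    rng = np.random.default_rng(config.seed)
    n = config.population

    pop = (rng.random((n, genome_length)) < 0.5).astype(np.int8)
    pop[:, : config.forced_prefix] = 1

    trace = GATrace()
    best_genome: np.ndarray | None = None
    best_fitness = -np.inf

    for _gen in range(config.generations):
        fitness = np.array([evaluate(g) for g in pop])
        finite = fitness[np.isfinite(fitness)]
        trace.max_fitness.append(float(fitness.max()))
        trace.mean_fitness.append(float(finite.mean()) if finite.size else -np.inf)
        trace.median_fitness.append(float(np.median(finite)) if finite.size else -np.inf)

        order = _order_population(pop, fitness)
        gen_best = pop[order[-1]].copy()
        trace.best_genomes.append(gen_best)
        if (fitness[order[-1]] > best_fitness) or (
            fitness[order[-1]] == best_fitness
            and best_genome is not None
            and _prefer(gen_best, best_genome)
        ):
            best_fitness = float(fitness[order[-1]])
            best_genome = gen_best

        elites = pop[order[-config.n_elite :]][::-1].copy()

        probs = rank_selection_probs(n, config.selection_min, config.selection_max)
        n_children = n - config.n_elite
        children = []
        while len(children) < n_children:
            i, j = rng.choice(order, size=2, p=probs)
            p1, p2 = pop[i].copy(), pop[j].copy()
            if rng.random() < config.crossover_prob:
                p1, p2 = single_point_crossover(p1, p2, rng)
            children.append(mutate(p1, rng, config.mutation_prob))
            if len(children) < n_children:
                children.append(mutate(p2, rng, config.mutation_prob))
        pop = np.vstack([elites, np.array(children, dtype=np.int8)])

    # account the final population too, mirroring the loop's bookkeeping
    fitness = np.array([evaluate(g) for g in pop])
    order = _order_population(pop, fitness)
    if fitness[order[-1]] > best_fitness:
        best_fitness = float(fitness[order[-1]])
        best_genome = pop[order[-1]].copy()

    if hasattr(evaluate, "cache_hits"):
        trace.cache_hits = evaluate.cache_hits
    if hasattr(evaluate, "fits"):
        trace.evaluations = evaluate.fits
    assert best_genome is not None
    return best_genome, trace


def _prefer(candidate: np.ndarray, incumbent: np.ndarray) -> bool:
    """Tie-break: smaller subset first, then lexicographically smaller genome."""
    cs, is_ = candidate.sum(), incumbent.sum()
    if cs != is_:
        return cs < is_
    return tuple(candidate) < tuple(incumbent)
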