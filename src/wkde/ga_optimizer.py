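"""Genetic-algorithm optimization of per-CpG weights.

The optimizer searches real-valued weight vectors w in [-10, 10]^n that
minimize the total absolute training error

    sum_l | age_l - argmax_i sum_k w_k * K[i, DNAm_l(k), k] | ,

i.e. the summed years by which the weighted argmax predictor misses the
known donor ages.  The objective is piecewise constant in w (only the
argmax matters), so gradient-free population search is a natural fit.

Concrete operators: truncation selection (top ``keep_fraction`` survive),
arithmetic (blend) crossover with a fresh uniform coefficient per gene,
uniform-reset mutation per gene, and elitism.  Because survivors are the
generation's best and the best-ever individual is always among them, the
best-fitness trace is non-increasing by construction.  The unit vector
(1, ..., 1) is injected into the initial population, so the optimized
clock can never be worse than the unweighted clock on training data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from wkde.core_io import KernelModel, MethylationMatrix
from wkde.wkde_predictor import dnam_to_row

logger = logging.getLogger("wkde")


@dataclass(frozen=True)
class GAConfig:
    population_size: int = 150
    iterations: int = 100
    keep_fraction: float = 0.4
    mutation_rate: float = 0.1
    bounds: tuple[float, float] = (-10.0, 10.0)
    seed: int = 0
    elitism: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.keep_fraction < 1:
            raise ValueError("keep_fraction must lie in (0, 1)")
        if not 0 <= self.mutation_rate <= 1:
            raise ValueError("mutation_rate must lie in [0, 1]")
        if self.bounds[0] >= self.bounds[1]:
            raise ValueError("bounds must be ordered")
        if self.population_size < 4:
            raise ValueError("population_size must be at least 4")


class DensityCache:
    """Precomputed density rows: for sample l and CpG k, the 101-vector of
    densities the model would look up for that sample's DNAm level.

    The GA evaluates ~15,000 weight vectors; caching the row lookups makes
    each objective evaluation a single matrix product.
    """

    def __init__(self, rows: np.ndarray, ages: np.ndarray,
                 sample_ids: list[str]):
        self.rows = rows          # (n_samples, n_cpgs, n_grid)
        self.ages = ages          # (n_samples,)
        self.sample_ids = sample_ids
        # flattened view for batched evaluation: (n_cpgs, n_samples * n_grid)
        self._flat = np.ascontiguousarray(
            rows.transpose(1, 0, 2).reshape(rows.shape[1], -1))

    @property
    def n_samples(self) -> int:
        return self.rows.shape[0]

    @property
    def n_cpgs(self) -> int:
        return self.rows.shape[1]

    @classmethod
    def build(cls, model: KernelModel, matrix: MethylationMatrix,
              samples: pd.DataFrame) -> "DensityCache":
        """Cache rows for every sample with complete signature DNAm;
        incomplete samples are dropped (logged)."""
        sub = matrix.subset_cpgs(model.cpg_ids)
        values = sub.values.to_numpy(dtype=float)  # (n_cpgs, n_samples)
        complete = np.all(np.isfinite(values), axis=0)
        if not complete.all():
            logger.info("dropping %d samples with incomplete signature DNAm",
                        int((~complete).sum()))
        if not complete.any():
            raise ValueError("no sample has complete signature DNAm")
        sample_ids = [s for s, ok in zip(sub.sample_ids, complete) if ok]
        ages = (samples.set_index("sample_id").loc[sample_ids, "age"]
                .to_numpy(dtype=float))
        n_grid = model.grid.n_points
        rows = np.empty((len(sample_ids), model.n_cpgs, n_grid))
        for k, kernel in enumerate(model.kernels):
            v = values[k, complete]
            idx = np.array([dnam_to_row(model.grid, x) for x in v])
            rows[:, k, :] = kernel.density[idx]
        return cls(rows, ages, sample_ids)


def objective(weights: np.ndarray, cache: DensityCache,
              ages: np.ndarray | None = None) -> float:
    """Total absolute error (years) of the weighted argmax predictor."""
    ages = cache.ages if ages is None else np.asarray(ages, dtype=float)
    profiles = np.tensordot(cache.rows, np.asarray(weights, float),
                            axes=([1], [0]))  # (n_samples, n_grid)
    preds = np.argmax(profiles, axis=1)  # first max = youngest tied age
    return float(np.sum(np.abs(ages - preds)))


def _objective_batch(pop: np.ndarray, cache: DensityCache) -> np.ndarray:
    profiles = (pop @ cache._flat).reshape(pop.shape[0], cache.n_samples, -1)
    preds = np.argmax(profiles, axis=2)
    return np.abs(cache.ages[None, :] - preds).sum(axis=1)


def optimize_weights(model: KernelModel, matrix: MethylationMatrix,
                     samples: pd.DataFrame, cfg: GAConfig | None = None
                     ) -> tuple[np.ndarray, pd.DataFrame]:
    """Run the GA; returns (best weights, per-generation fitness trace).

    The trace DataFrame has columns generation, best, median; ``best`` is
    the best-ever objective after that generation.
    """
    cfg = cfg or GAConfig()
    if model.n_cpgs == 0:
        raise ValueError("model has no signature CpGs")
    cache = DensityCache.build(model, matrix, samples)
    rng = np.random.default_rng(cfg.seed)
    lo, hi = cfg.bounds
    n_genes = model.n_cpgs
    pop = rng.uniform(lo, hi, size=(cfg.population_size, n_genes))
    pop[0] = 1.0  # the unweighted clock always competes
    n_keep = max(2, int(round(cfg.keep_fraction * cfg.population_size)))

    best_w = pop[0].copy()
    best_f = np.inf
    trace = []
    for gen in range(cfg.iterations):
        fitness = _objective_batch(pop, cache)
        order = np.argsort(fitness, kind="stable")
        survivors = pop[order[:n_keep]]
        if fitness[order[0]] < best_f:
            best_f = float(fitness[order[0]])
            best_w = pop[order[0]].copy()
        trace.append({"generation": gen, "best": best_f,
                      "median": float(np.median(fitness))})
        n_offspring = cfg.population_size - n_keep
        parents = np.empty((n_offspring, 2), dtype=int)
        parents[:, 0] = rng.integers(0, n_keep, size=n_offspring)
        shift = rng.integers(1, n_keep, size=n_offspring)
        parents[:, 1] = (parents[:, 0] + shift) % n_keep  # distinct mates
        alpha = rng.uniform(0.0, 1.0, size=(n_offspring, n_genes))
        offspring = (alpha * survivors[parents[:, 0]]
                     + (1.0 - alpha) * survivors[parents[:, 1]])
        mutate = rng.uniform(size=offspring.shape) < cfg.mutation_rate
        offspring[mutate] = rng.uniform(lo, hi, size=int(mutate.sum()))
        pop = np.vstack([survivors, offspring])
        if cfg.elitism:
            pop[0] = best_w  # survivors[0] is the incumbent best anyway

    final = _objective_batch(pop, cache)
    i = int(np.argmin(final))
    if final[i] < best_f:
        best_f, best_w = float(final[i]), pop[i].copy()
    trace_df = pd.DataFrame(trace)
    logger.info("GA finished: best objective %.1f years over %d samples",
                best_f, cache.n_samples)
    return np.clip(best_w, lo, hi), trace_df
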