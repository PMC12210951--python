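"""Real-coded genetic algorithm for box-bounded minimization.

Configured to match a classical GA-toolbox setup: population 50, up to 300
generations, crossover probability 0.8, 5% elitism, stochastic universal
sampling selection, arithmetic blend crossover and an adaptive Gaussian
mutation whose scale decays with generation count and shrinks near the
bounds.  The run stops early when the best fitness improves by less than a
tolerance (1e-6 by default) over a 20-generation stall window.

Maximization problems are handled by negating the objective
(:func:`negate_objective`): the GA always minimizes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = ["GAConfig", "GAResult", "ga_minimize", "negate_objective", "parameter_sweep"]


@dataclass(frozen=True)
class GAConfig:
    """Operator settings and stopping rule for :func:`ga_minimize`."""

    bounds: tuple[tuple[float, float], ...]
    pop_size: int = 50
    max_generations: int = 300
    crossover_prob: float = 0.8
    elite_fraction: float = 0.05
    stall_generations: int = 20
    stall_tol: float = 1e-6
    mutation_scale: float = 0.1   # initial sd as a fraction of each variable's range
    mutation_decay: float = 50.0  # generations over which the scale halves once
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pop_size < 2:
            raise ValueError("population size must be at least 2")
        if not 0.0 <= self.crossover_prob <= 1.0:
            raise ValueError("crossover probability must lie in [0, 1]")
        if not self.bounds:
            raise ValueError("bounds are required")
        for lo, hi in self.bounds:
            if not (math.isfinite(lo) and math.isfinite(hi) and lo < hi):
                raise ValueError(f"bounds ({lo}, {hi}) must be finite with lower < upper")
        if self.elite_count < 1:
            raise ValueError("elite fraction must give at least one elite")

    @property
    def n_vars(self) -> int:
        return len(self.bounds)

    @property
    def elite_count(self) -> int:
        return math.ceil(self.elite_fraction * self.pop_size)


@dataclass(frozen=True)
class GAResult:
    """Outcome of one GA run (fitness is the minimized quantity)."""

    best_point: np.ndarray
    best_fitness: float
    generations: int
    best_history: np.ndarray
    mean_history: np.ndarray
    termination: str


def negate_objective(f: Callable[[np.ndarray], float]) -> Callable[[np.ndarray], float]:
    """Turn a maximization objective into a GA fitness (f -> -f)."""

    def fitness(x: np.ndarray) -> float:
        return -f(x)

    return fitness


def _evaluate(fitness, pop: np.ndarray) -> np.ndarray:
    vals = np.array([fitness(ind) for ind in pop], dtype=float)
    if not np.isfinite(vals).all():
        i = int(np.flatnonzero(~np.isfinite(vals))[0])
        raise ValueError(f"non-finite fitness {vals[i]} at point {pop[i].tolist()}")
    return vals


def _sus_select(fitness_vals: np.ndarray, n: int, rng: np.random.Generator) -> np.ndarray:
    """Stochastic universal sampling on rank-scaled minimization fitness."""
    # convert minimization fitness to selection weights via inverse rank
    ranks = np.empty_like(fitness_vals)
    ranks[np.argsort(fitness_vals)] = np.arange(len(fitness_vals))
    weights = 1.0 / np.sqrt(ranks + 1.0)
    cum = np.cumsum(weights)
    total = cum[-1]
    start = rng.uniform(0, total / n)
    pointers = start + (total / n) * np.arange(n)
    return np.searchsorted(cum, pointers, side="left")


def ga_minimize(fitness: Callable[[np.ndarray], float], config: GAConfig) -> GAResult:
    """Minimize a fitness function over a bounded box with a real-coded GA.

    Deterministic for a fixed config (seed included).  The best-so-far
    fitness is non-increasing across generations because elites are copied
    unchanged.
    """
    rng = np.random.default_rng(config.seed)
    lo = np.array([b[0] for b in config.bounds])
    hi = np.array([b[1] for b in config.bounds])
    span = hi - lo
    pop = rng.uniform(lo, hi, size=(config.pop_size, config.n_vars))
    vals = _evaluate(fitness, pop)
    best_hist: list[float] = []
    mean_hist: list[float] = []
    termination = "max generations"
    n_elite = config.elite_count
    gen = 0
    for gen in range(1, config.max_generations + 1):
        order = np.argsort(vals)
        pop, vals = pop[order], vals[order]
        best_hist.append(float(vals[0]))
        mean_hist.append(float(vals.mean()))
        if len(best_hist) > config.stall_generations:
            window = best_hist[-(config.stall_generations + 1):]
            if abs(window[0] - window[-1]) < config.stall_tol:
                termination = "stall"
                break
        elites = pop[:n_elite].copy()
        n_children = config.pop_size - n_elite
        parents = pop[_sus_select(vals, 2 * n_children, rng)]
        mothers, fathers = parents[:n_children], parents[n_children:]
        # arithmetic blend crossover with per-pair mixing ratio
        mix = rng.uniform(0.0, 1.0, size=(n_children, 1))
        cross = rng.uniform(size=n_children) < config.crossover_prob
        children = np.where(cross[:, None],
                            mix * mothers + (1.0 - mix) * fathers,
                            mothers)
        # adaptive Gaussian mutation: scale decays with generation and
        # shrinks with each individual's distance to the nearest bound
        scale = config.mutation_scale / (1.0 + gen / config.mutation_decay)
        dist = np.minimum(children - lo, hi - children) / span
        sd = scale * span * np.maximum(dist, 0.05)
        children = children + rng.normal(0.0, 1.0, children.shape) * sd
        clipped = np.clip(children, lo, hi)
        children = clipped
        pop = np.vstack([elites, children])
        child_vals = _evaluate(fitness, children)
        vals = np.concatenate([vals[:n_elite], child_vals])
    order = np.argsort(vals)
    pop, vals = pop[order], vals[order]
    if gen == config.max_generations and termination != "stall":
        best_hist.append(float(vals[0]))
        mean_hist.append(float(vals.mean()))
    return GAResult(
        best_point=pop[0].copy(),
        best_fitness=float(vals[0]),
        generations=len(best_hist),
        best_history=np.array(best_hist),
        mean_history=np.array(mean_hist),
        termination=termination,
    )


def parameter_sweep(fitness: Callable[[np.ndarray], float],
                    base_config: GAConfig,
                    grid: dict[str, Sequence],
                    n_replicates: int = 3,
                    seed: int = 0) -> pd.DataFrame:
    """Run the GA across a grid of config overrides with seeded replicates.

    ``grid`` maps GAConfig field names (e.g. ``pop_size``,
    ``crossover_prob``, ``max_generations``) to the values to try; the
    cartesian product of all listed values is swept.  Returns one row per
    (setting, replicate) with the best fitness and generations used.
    """
    from dataclasses import replace
    from itertools import product

    keys = list(grid)
    rows = []
    for combo in product(*(grid[k] for k in keys)):
        overrides = dict(zip(keys, combo))
        for rep in range(n_replicates):
            cfg = replace(base_config, seed=seed + rep, **overrides)
            res = ga_minimize(fitness, cfg)
            row = dict(overrides)
            row.update(replicate=rep, seed=cfg.seed,
                       best_fitness=res.best_fitness,
                       generations=res.generations,
                       termination=res.termination)
            rows.append(row)
    return pd.DataFrame(rows)
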