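"""Differential evolution with hybrid adaptive control (HDE).

Classic DE evolves a population of parameter vectors by vector-difference
mutation, binomial crossover, and greedy selection.  The hybrid variant
implemented here adds two control mechanisms on top:

* piecewise adaptation — the mutation factor F and crossover rate CR are
  reset each generation from the convergence indicator c_t (the relative
  recent improvement of the best fitness):

      F  = 0.2 + 0.5 r   if c_t <= 0.05     CR = 0.95
           0.3 + 0.5 r   if 0.05 < c_t <= 0.1    0.9
           0.5 + 0.5 r   if c_t > 0.1            0.7

  with r ~ U[0, 1];

* diversity adaptation — F and CR are shifted by Delta*(1 - D/D_max),
  where D is the mean pairwise distance of the population in
  bounds-normalized coordinates and D_max its initial value;

and a stage schedule over four mutation strategies: rand/1 while
exploring (first third of the run), current-to-best/1 in the middle
third, and best/1 alternating with best/2 for final exploitation.
The "combined" adaptation mode (default) applies the piecewise rule and
then adds the diversity adjustment; after any adaptation F and CR are
clipped to [0.05, 1].  Minimization convention throughout.

In the piecewise and combined modes the uniform draw r — whose stated
purpose is to avoid premature convergence — is taken per *individual*,
so step sizes stay heterogeneous within a generation (the same role
dither plays in classic DE); the diversity mode is deterministic and
shared across the generation.  Randomness is drawn in a fixed,
documented order so seeded runs are bit-reproducible: per individual,
one uniform r if the piecewise rule is active, then the mutation
indices (a no-replacement choice from the other indices), one crossover
index j_rand, and d uniform crossover draws; trial evaluation follows
immediately.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist

__all__ = [
    "HDEConfig",
    "Population",
    "OptimizeResult",
    "STRATEGIES",
    "adapt_piecewise",
    "adapt_diversity",
    "diversity",
    "convergence_indicator",
    "mutate",
    "crossover",
    "reflect_into_bounds",
    "optimize",
]

STRATEGIES = ("rand1", "best1", "current_to_best1", "best2")
_INDEX_DEMAND = {"rand1": 3, "best1": 2, "current_to_best1": 2, "best2": 4}
F_CLIP = (0.05, 1.0)
CR_CLIP = (0.05, 1.0)


@dataclass(frozen=True)
class HDEConfig:
    """Optimizer settings.

    adaptation: "fixed" (classic DE), "piecewise", "diversity", or
    "combined".  strategy_schedule maps a stage fraction in [0, 1) to a
    strategy; None selects the default stage schedule.  A single-element
    schedule {0.0: "rand1"} with adaptation="fixed" recovers classic
    DE/rand/1/bin.
    """

    bounds: tuple[tuple[float, float], ...]
    population_size: int = 20
    generations: int = 50
    f_base: float = 0.5
    cr_base: float = 0.9
    delta_f: float = 0.1
    delta_cr: float = 0.1
    adaptation: str = "combined"
    strategy_schedule: tuple[tuple[float, str], ...] | None = None
    convergence_window: int = 1
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.population_size < 4:
            raise ValueError("population size must be at least 4")
        if self.generations < 1:
            raise ValueError("generations must be at least 1")
        for low, high in self.bounds:
            if not (np.isfinite(low) and np.isfinite(high) and low < high):
                raise ValueError("bounds must be finite with low < high")
        if self.adaptation not in ("fixed", "piecewise", "diversity", "combined"):
            raise ValueError(f"unknown adaptation mode {self.adaptation!r}")
        if self.strategy_schedule is not None:
            for _, s in self.strategy_schedule:
                if s not in STRATEGIES:
                    raise ValueError(f"unknown strategy {s!r}")

    def strategy_at(self, generation: int) -> str:
        """Strategy for a 1-based generation index."""
        stage = (generation - 1) / self.generations
        if self.strategy_schedule is not None:
            chosen = self.strategy_schedule[0][1]
            for threshold, s in self.strategy_schedule:
                if stage >= threshold:
                    chosen = s
            return chosen
        if stage < 1 / 3:
            return "rand1"
        if stage < 2 / 3:
            return "current_to_best1"
        return "best1" if generation % 2 else "best2"


@dataclass
class Population:
    """Optimizer state at one generation (minimization convention)."""

    individuals: np.ndarray           # (NP, d)
    fitness: np.ndarray               # (NP,)
    generation: int = 0
    d_max: float = 0.0
    d_current: float = 0.0
    c_t: float = 0.0

    @property
    def best_index(self) -> int:
        return int(np.argmin(self.fitness))

    @property
    def best(self) -> np.ndarray:
        return self.individuals[self.best_index]


@dataclass
class OptimizeResult:
    x: np.ndarray
    fun: float
    history: pd.DataFrame
    n_evaluations: int


def adapt_piecewise(c_t: float, rng: np.random.Generator | None = None, r: float | None = None):
    """Piecewise (F, CR) update from the convergence indicator.

    ``r`` may be supplied directly (deterministic evaluation); otherwise
    one uniform draw is taken from ``rng``.
    """
    if c_t < 0:
        raise ValueError("convergence indicator must be non-negative")
    if r is None:
        if rng is None:
            raise ValueError("either rng or r must be given")
        r = float(rng.uniform())
    if c_t <= 0.05:
        return 0.2 + 0.5 * r, 0.95
    if c_t <= 0.1:
        return 0.3 + 0.5 * r, 0.9
    return 0.5 + 0.5 * r, 0.7


def adapt_diversity(
    f_base: float,
    cr_base: float,
    d_current: float,
    d_max: float,
    delta_f: float,
    delta_cr: float,
):
    """Diversity-driven (F, CR): base + Delta * (1 - D/D_max), clipped."""
    if d_max <= 0:
        raise ValueError("D_max must be positive")
    if d_current < 0:
        raise ValueError("D_current must be non-negative")
    shrink = 1.0 - d_current / d_max
    f = float(np.clip(f_base + delta_f * shrink, *F_CLIP))
    cr = float(np.clip(cr_base + delta_cr * shrink, *CR_CLIP))
    return f, cr


def diversity(individuals: np.ndarray, bounds) -> float:
    """Mean pairwise Euclidean distance in bounds-normalized coordinates."""
    individuals = np.atleast_2d(individuals)
    if individuals.shape[0] < 2:
        raise ValueError("diversity needs at least two individuals")
    bounds = np.asarray(bounds, dtype=float)
    span = bounds[:, 1] - bounds[:, 0]
    normalized = (individuals - bounds[:, 0]) / span
    return float(pdist(normalized).mean())


def convergence_indicator(best_history: Sequence[float], window: int = 1) -> float:
    """Relative best-fitness improvement over ``window`` generations.

    c_t = |f(t) - f(t-w)| / max(|f(t-w)|, eps); small values signal
    stagnation (near-convergence).
    """
    if len(best_history) < 2:
        raise ValueError("need at least two recorded generations")
    window = min(window, len(best_history) - 1)
    current = best_history[-1]
    past = best_history[-1 - window]
    return abs(current - past) / max(abs(past), 1e-12)


def reflect_into_bounds(v: np.ndarray, bounds) -> np.ndarray:
    """Fold out-of-bounds components back into the box by reflection."""
    bounds = np.asarray(bounds, dtype=float)
    low, high = bounds[:, 0], bounds[:, 1]
    span = high - low
    # reflect with period 2*span, exact for arbitrarily far excursions
    folded = np.mod(v - low, 2 * span)
    folded = np.where(folded > span, 2 * span - folded, folded)
    return low + folded


def _distinct_indices(rng: np.random.Generator, population_size: int, exclude: int, k: int):
    pool = np.array([j for j in range(population_size) if j != exclude])
    if len(pool) < k:
        raise ValueError(
            f"population too small: strategy needs {k} distinct other individuals"
        )
    return pool[rng.choice(len(pool), size=k, replace=False)]


def mutate(
    population: Population,
    i: int,
    strategy: str,
    f: float,
    rng: np.random.Generator,
    bounds,
) -> np.ndarray:
    """Donor vector for individual ``i`` under the selected strategy.

    rand1:             v = x_r1 + F (x_r2 - x_r3)
    best1:             v = x_best + F (x_r1 - x_r2)
    current_to_best1:  v = x_i + F (x_best - x_i) + F (x_r1 - x_r2)
    best2:             v = x_best + F (x_r1 - x_r2) + F (x_r3 - x_r4)

    Random indices are distinct from each other and from ``i``; donor
    components outside the bounds are reflected back in.
    """
    if strategy not in STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}")
    x = population.individuals
    idx = _distinct_indices(rng, x.shape[0], i, _INDEX_DEMAND[strategy])
    best = population.best
    if strategy == "rand1":
        v = x[idx[0]] + f * (x[idx[1]] - x[idx[2]])
    elif strategy == "best1":
        v = best + f * (x[idx[0]] - x[idx[1]])
    elif strategy == "current_to_best1":
        v = x[i] + f * (best - x[i]) + f * (x[idx[0]] - x[idx[1]])
    else:  # best2
        v = best + f * (x[idx[0]] - x[idx[1]]) + f * (x[idx[2]] - x[idx[3]])
    return reflect_into_bounds(v, bounds)


def crossover(
    target: np.ndarray, donor: np.ndarray, cr: float, rng: np.random.Generator
) -> np.ndarray:
    """Binomial crossover with a guaranteed donor component at j_rand."""
    if not 0 <= cr <= 1:
        raise ValueError("CR must lie in [0, 1]")
    d = target.size
    j_rand = int(rng.integers(d))
    mask = rng.random(d) < cr
    mask[j_rand] = True
    return np.where(mask, donor, target)


def optimize(
    objective: Callable[[np.ndarray], float], config: HDEConfig
) -> OptimizeResult:
    """Run the adaptive DE loop and return the best solution found.

    The objective is minimized; non-finite trial evaluations are rejected
    with a warning.  The history records, per generation, the best
    fitness and the control state (F, CR, diversity, strategy).
    """
    rng = np.random.default_rng(config.seed)
    bounds = np.asarray(config.bounds, dtype=float)
    d = bounds.shape[0]
    population_size = config.population_size

    individuals = bounds[:, 0] + rng.random((population_size, d)) * (
        bounds[:, 1] - bounds[:, 0]
    )
    fitness = np.empty(population_size)
    for i in range(population_size):
        fitness[i] = objective(individuals[i])
    n_evaluations = population_size
    if not np.all(np.isfinite(fitness)):
        raise ValueError("objective returned non-finite values on the initial population")

    pop = Population(individuals=individuals, fitness=fitness, generation=0)
    pop.d_max = diversity(individuals, bounds)
    pop.d_current = pop.d_max
    best_history = [float(fitness.min())]
    records = []

    f, cr = config.f_base, config.cr_base
    for t in range(1, config.generations + 1):
        pop.generation = t
        pop.d_current = diversity(pop.individuals, bounds)
        pop.c_t = (
            convergence_indicator(best_history, config.convergence_window)
            if len(best_history) >= 2
            else 0.0
        )
        mode = config.adaptation
        shrink = 1.0 - pop.d_current / pop.d_max
        if mode == "fixed":
            f, cr = config.f_base, config.cr_base
        elif mode == "diversity":
            f, cr = adapt_diversity(
                config.f_base, config.cr_base, pop.d_current, pop.d_max,
                config.delta_f, config.delta_cr,
            )
        f_applied, cr_applied = [], []

        strategy = config.strategy_at(t)
        for i in range(population_size):
            if mode in ("piecewise", "combined"):
                # fresh uniform draw per individual: heterogeneous step
                # sizes within the generation guard against premature
                # population collapse (the stated purpose of r)
                f, cr = adapt_piecewise(pop.c_t, rng)
                if mode == "combined":
                    f = f + config.delta_f * shrink
                    cr = cr + config.delta_cr * shrink
            f = float(np.clip(f, *F_CLIP))
            cr = float(np.clip(cr, *CR_CLIP))
            f_applied.append(f)
            cr_applied.append(cr)
            donor = mutate(pop, i, strategy, f, rng, bounds)
            trial = crossover(pop.individuals[i], donor, cr, rng)
            trial_fitness = objective(trial)
            n_evaluations += 1
            if not np.isfinite(trial_fitness):
                warnings.warn("objective returned non-finite value; trial rejected",
                              stacklevel=2)
                continue
            if trial_fitness <= pop.fitness[i]:
                pop.individuals[i] = trial
                pop.fitness[i] = trial_fitness

        best_history.append(float(pop.fitness.min()))
        records.append(
            {
                "generation": t,
                "best_f": best_history[-1],
                "F": float(np.mean(f_applied)),
                "CR": float(np.mean(cr_applied)),
                "diversity": pop.d_current,
                "strategy": strategy,
            }
        )

    history = pd.DataFrame.from_records(records)
    best = pop.best_index
    return OptimizeResult(
        x=pop.individuals[best].copy(),
        fun=float(pop.fitness[best]),
        history=history,
        n_evaluations=n_evaluations,
    )
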