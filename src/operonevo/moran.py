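"""Moran process with genome inversions and direct selection for clustering.

A fixed-size population of N bacterial genomes, all initially identical with
the pathway genes placed uniformly at random, evolves by overlapping
birth-death events.  Each elementary step:

* one individual is chosen uniformly and two inversion breakpoints drawn;
* with probability ``rho`` an inversion is attempted on the chosen genome —
  if the replichore-imbalance rule allows it the genome is replaced by its
  inverted copy; otherwise the inversion is lethal, the individual dies and
  is replaced by the offspring of a parent drawn from the remaining N − 1
  individuals with probability proportional to fitness;
* with probability ``1 − rho`` the chosen individual simply dies and is
  replaced by the offspring of a fitness-proportional parent drawn from the
  whole population.

Fitness is a non-increasing function of the minimum arc distance
(exponential or sigmoidal, see :mod:`operonevo.popgen`); one generation is
N elementary steps.  Selection uses log-fitness shifted by its maximum, so
arbitrarily steep fitness functions remain exact in floating point.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import (
    ConfigError,
    GenomeConfig,
    draw_breakpoints,
    invert_positions,
    inversion_viable,
    positions_min_arc,
    random_positions,
)
from .popgen import FitnessParams, log_fitness
from .runio import Trajectory, params_to_dict

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MoranParams:
    """Parameters of the Moran inversion model.

    ``exclude_dead_parent`` controls whether the parent replacing a
    lethally-inverted individual is drawn from the other N − 1 individuals
    (default) or from the whole population including the dead one.
    """

    pop_size: int = 100
    rho: float = 1e-2
    fitness: FitnessParams = field(default_factory=FitnessParams)
    genome: GenomeConfig = field(default_factory=GenomeConfig)
    n_generations: int = 200
    record_every: int | None = None  # steps; default one generation (N steps)
    exclude_dead_parent: bool = True

    def __post_init__(self) -> None:
        if int(self.pop_size) != self.pop_size or self.pop_size < 2:
            raise ConfigError(f"pop_size must be an integer >= 2, got {self.pop_size!r}")
        if not 0.0 <= self.rho <= 1.0:
            raise ConfigError(f"rho must be in [0, 1], got {self.rho!r}")
        if self.n_generations < 0:
            raise ConfigError(f"n_generations must be >= 0, got {self.n_generations!r}")


class Population:
    """Fixed-size collection of genomes with cached distances and log-fitness."""

    def __init__(
        self,
        positions: np.ndarray,
        genome: GenomeConfig,
        fitness: FitnessParams,
    ):
        self.genome = genome
        self.fitness_params = fitness
        self.positions = np.asarray(positions, dtype=np.int64).reshape(
            -1, genome.n_genes
        )
        self.distances = np.array(
            [positions_min_arc(row, genome.length_kb) for row in self.positions],
            dtype=np.int64,
        )
        self.logw = log_fitness(self.distances.astype(float), fitness)
        self.logw = np.atleast_1d(np.asarray(self.logw, dtype=float))

    @classmethod
    def monomorphic(
        cls, params: MoranParams, rng: np.random.Generator
    ) -> "Population":
        founder = random_positions(params.genome, rng)
        positions = np.tile(founder, (params.pop_size, 1))
        return cls(positions, params.genome, params.fitness)

    def __len__(self) -> int:
        return len(self.positions)

    def set_genome(self, i: int, new_positions: np.ndarray) -> None:
        self.positions[i] = new_positions
        self.distances[i] = positions_min_arc(new_positions, self.genome.length_kb)
        self.logw[i] = float(
            log_fitness(float(self.distances[i]), self.fitness_params)
        )

    def mean_distance(self) -> float:
        return float(self.distances.mean())

    def recompute_caches(self) -> None:
        """Rebuild distance/fitness caches from positions (contract check)."""
        fresh = Population(self.positions.copy(), self.genome, self.fitness_params)
        self.distances = fresh.distances
        self.logw = fresh.logw


def _fitness_weights(logw: np.ndarray) -> np.ndarray:
    """Relative fitness weights, exact up to a common factor."""
    return np.exp(logw - logw.max())


def _choose_parent(
    popn: Population, rng: np.random.Generator, exclude: int | None = None
) -> int:
    w = _fitness_weights(popn.logw)
    if exclude is not None:
        w = w.copy()
        w[exclude] = 0.0
    total = w.sum()
    assert total > 0, "all-zero fitness weights (unreachable for valid fitness)"
    cum = np.cumsum(w)
    return int(np.searchsorted(cum, rng.random() * total, side="right"))


def moran_step(
    popn: Population, params: MoranParams, rng: np.random.Generator
) -> Population:
    """One elementary birth-death / inversion event (in place)."""
    i = int(rng.integers(len(popn)))
    a, b = draw_breakpoints(params.genome, rng)
    if rng.random() < params.rho:
        if inversion_viable(a, b, params.genome):
            popn.set_genome(i, invert_positions(popn.positions[i], a, b))
        else:
            # lethal inversion: i dies, fitness-proportional replacement birth
            parent = _choose_parent(
                popn, rng, exclude=i if params.exclude_dead_parent else None
            )
            popn.positions[i] = popn.positions[parent]
            popn.distances[i] = popn.distances[parent]
            popn.logw[i] = popn.logw[parent]
    else:
        parent = _choose_parent(popn, rng)
        popn.positions[i] = popn.positions[parent]
        popn.distances[i] = popn.distances[parent]
        popn.logw[i] = popn.logw[parent]
    return popn


def run_moran(
    params: MoranParams,
    rng: np.random.Generator,
    seed: int | None = None,
) -> Trajectory:
    """Run the Moran process for ``n_generations`` (N steps each).

    Records the population-mean minimum arc distance every ``record_every``
    steps (default: once per generation), including the initial state.
    """
    popn = Population.monomorphic(params, rng)
    n = len(popn)
    total_steps = params.n_generations * n
    stride = params.record_every or n

    gens = [0.0]
    means = [popn.mean_distance()]
    heartbeat = max(1, total_steps // 10)

    for step in range(1, total_steps + 1):
        moran_step(popn, params, rng)
        if step % stride == 0 or step == total_steps:
            gens.append(step / n)
            means.append(popn.mean_distance())
        if step % heartbeat == 0:
            logger.info(
                "moran: step %d/%d (%.0f%%), mean distance %.1f kb",
                step, total_steps, 100 * step / total_steps, means[-1],
            )

    data = pd.DataFrame({"generation": gens, "mean_min_arc_kb": means})
    # an exact duplicate of the final row can occur when total_steps is a
    # multiple of the stride; drop it
    data = data.drop_duplicates(subset="generation", keep="first").reset_index(
        drop=True
    )
    return Trajectory(
        model="moran",
        data=data,
        status="completed",
        seed=seed,
        params=params_to_dict(params),
    )
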