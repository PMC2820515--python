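"""The selfish-operon species-pool simulation of Lawrence and Roth.

A pool of "positive" species — each monomorphic for one arrangement of the
pathway genes — evolves in discrete time steps.  Per species and step:

1. with probability ``rho`` (variant-dependent, below) the genome is
   rearranged;
2. with probability ``p_loss`` the function is destroyed and the species
   leaves the pool;
3. if the pool currently holds fewer than ``max_species`` positive species,
   horizontal transfer recruits a new species (from a limitless supply of
   negative species) carrying a copy of this species' arrangement, with
   probability ``P(d) = p_max * exp(-lambda_transfer * d)`` where d is the
   donor's minimum arc distance.  Transfer switches back on as soon as the
   pool drops below the cap.

Three rearrangement variants are provided:

* ``original_translocation`` — with probability rho, a random pathway gene
  moves to a random free position (the rearrangement always hits the genes
  in question);
* ``corrected_translocation`` — the move happens with probability
  ``rho * n / L``, accounting for the chance that a random rearrangement
  touches the n pathway genes at all.  This lowers the effective
  rearrangement probability by a few orders of magnitude;
* ``inversion`` — with probability rho an inversion is attempted: two
  breakpoints are drawn and, if the replichore-imbalance rule allows it,
  the segment is inverted; a lethal inversion leaves the species'
  arrangement unchanged at the species level.

Update semantics: species are processed in index order; losses apply
immediately to the running count, and recruits are appended after the sweep
(they are not themselves iterated within the step).  The per-species
Bernoulli draws are made as vectorized blocks in index order, which is
equivalent in distribution to the sequential loop.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import (
    Arrangement,
    ConfigError,
    GenomeConfig,
    draw_breakpoints,
    invert_positions,
    inversion_viable,
    positions_min_arc,
    random_positions,
    translocate_positions,
)
from .popgen import TransferParams, transfer_prob
from .runio import Trajectory, params_to_dict

logger = logging.getLogger(__name__)

VARIANTS = ("original_translocation", "corrected_translocation", "inversion")


@dataclass(frozen=True)
class SelfishParams:
    """Parameters of the species-pool simulation."""

    rho: float = 1e-5
    variant: str = "corrected_translocation"
    transfer: TransferParams = field(default_factory=TransferParams)
    genome: GenomeConfig = field(default_factory=GenomeConfig)
    init_species: int = 100
    max_species: int = 900
    min_species: int = 10
    n_steps: int = 50_000

    def __post_init__(self) -> None:
        if not 0.0 <= self.rho <= 1.0:
            raise ConfigError(f"rho must be in [0, 1], got {self.rho!r}")
        if self.variant not in VARIANTS:
            raise ConfigError(
                f"variant must be one of {VARIANTS}, got {self.variant!r}"
            )
        if self.init_species > self.max_species:
            raise ConfigError(
                f"init_species ({self.init_species}) must not exceed "
                f"max_species ({self.max_species})"
            )
        if self.init_species < 1 or self.n_steps < 0:
            raise ConfigError("init_species must be >= 1 and n_steps >= 0")


class SpeciesPool:
    """Ordered pool of positive species, one arrangement each.

    Internally the pool is a ``(size, n_genes)`` integer position matrix with
    a cached vector of minimum arc distances.
    """

    def __init__(self, positions: np.ndarray, config: GenomeConfig):
        self.config = config
        self.positions = np.asarray(positions, dtype=np.int64).reshape(
            -1, config.n_genes
        )
        self.distances = np.array(
            [positions_min_arc(row, config.length_kb) for row in self.positions],
            dtype=np.int64,
        )

    @classmethod
    def random(
        cls, n_species: int, config: GenomeConfig, rng: np.random.Generator
    ) -> "SpeciesPool":
        rows = [random_positions(config, rng) for _ in range(n_species)]
        return cls(np.array(rows, dtype=np.int64), config)

    def __len__(self) -> int:
        return len(self.positions)

    @property
    def arrangements(self) -> list[Arrangement]:
        return [Arrangement(row, self.config) for row in self.positions]

    def mean_distance(self) -> float:
        return float(self.distances.mean())

    def proportion_clustered(self, threshold_kb: float | None = None) -> float:
        if threshold_kb is None:
            threshold_kb = self.config.cluster_threshold_kb
        return float(np.mean(self.distances < threshold_kb))


def _rearrange_species(
    pool: SpeciesPool, params: SelfishParams, rng: np.random.Generator
) -> None:
    """Apply the variant's rearrangement process in place."""
    size = len(pool)
    L = pool.config.length_kb
    if params.variant == "corrected_translocation":
        p = params.rho * pool.config.n_genes / L
    else:
        p = params.rho
    if p <= 0.0 or size == 0:
        return
    hits = np.flatnonzero(rng.random(size) < p)
    for i in hits:
        if params.variant == "inversion":
            a, b = draw_breakpoints(pool.config, rng)
            if not inversion_viable(a, b, pool.config):
                continue  # lethal at the individual level; species unchanged
            pool.positions[i] = invert_positions(pool.positions[i], a, b)
        else:
            pool.positions[i] = translocate_positions(pool.positions[i], L, rng)
        pool.distances[i] = positions_min_arc(pool.positions[i], L)


def selfish_step(
    pool: SpeciesPool, params: SelfishParams, rng: np.random.Generator
) -> SpeciesPool:
    """Advance the pool by one time step (rearrangement, loss, recruitment)."""
    size = len(pool)
    if size == 0:
        return pool
    _rearrange_species(pool, params, rng)

    tp = params.transfer
    lost = rng.random(size) < tp.p_loss
    candidate = rng.random(size) < transfer_prob(pool.distances, tp)

    # sequential bookkeeping over the (few) species with an event this step:
    # a lost species leaves immediately and cannot donate; a recruit counts
    # against the cap from the moment it is accepted.
    count = size
    accepted: list[int] = []
    for i in np.flatnonzero(lost | candidate):
        if lost[i]:
            count -= 1
        elif count < params.max_species:
            accepted.append(i)
            count += 1

    keep = pool.positions[~lost]
    keep_d = pool.distances[~lost]
    if accepted:
        new_pos = np.concatenate([keep, pool.positions[accepted]])
        new_d = np.concatenate([keep_d, pool.distances[accepted]])
    else:
        new_pos, new_d = keep, keep_d

    out = SpeciesPool.__new__(SpeciesPool)
    out.config = pool.config
    out.positions = new_pos
    out.distances = new_d
    return out


def run_selfish(
    params: SelfishParams,
    rng: np.random.Generator,
    seed: int | None = None,
    record_every: int = 1,
) -> Trajectory:
    """Run the species-pool simulation and record summary statistics.

    The trajectory has one row per recorded step with the positive-species
    count, the pool mean minimum arc distance and the proportion of species
    clustered under 3 chromosome minutes.  If the pool goes extinct the
    trajectory is truncated and flagged ``status="extinct"``.
    """
    pool = SpeciesPool.random(params.init_species, params.genome, rng)
    threshold = params.genome.cluster_threshold_kb

    steps = [0]
    sizes = [len(pool)]
    means = [pool.mean_distance()]
    props = [pool.proportion_clustered(threshold)]
    status = "completed"
    heartbeat = max(1, params.n_steps // 10)

    for step in range(1, params.n_steps + 1):
        pool = selfish_step(pool, params, rng)
        if len(pool) == 0:
            status = "extinct"
            steps.append(step)
            sizes.append(0)
            means.append(float("nan"))
            props.append(float("nan"))
            break
        if step % record_every == 0 or step == params.n_steps:
            steps.append(step)
            sizes.append(len(pool))
            means.append(pool.mean_distance())
            props.append(pool.proportion_clustered(threshold))
        if step % heartbeat == 0:
            logger.info(
                "selfish: step %d/%d (%.0f%%), pool=%d, mean distance %.1f kb",
                step, params.n_steps, 100 * step / params.n_steps,
                len(pool), means[-1],
            )

    data = pd.DataFrame(
        {
            "step": np.array(steps, dtype=np.int64),
            "pop_size": np.array(sizes, dtype=np.int64),
            "mean_min_arc_kb": means,
            "prop_clustered": props,
        }
    )
    return Trajectory(
        model="selfish",
        data=data,
        status=status,
        seed=seed,
        params=params_to_dict(params),
    )
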