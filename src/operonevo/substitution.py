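"""Origin-fixation (rearrangement substitution) model of cluster evolution.

The population is assumed monomorphic, so only one resident arrangement is
tracked.  Time advances in generations through a sequence of proposed
inversions:

1. the waiting time to the next rearrangement arising anywhere in the
   population is geometric with parameter ``1 − (1 − rho)^N`` (≈ N·rho);
2. two inversion breakpoints are drawn; a non-viable (replichore-imbalanced)
   inversion changes nothing but still consumes the waiting interval;
3. for a viable inversion the selection coefficient
   ``s = w(d_new)/w(d_old) − 1`` is computed from the minimum arc distances
   before and after, and the proposal fixes with the diffusion-theory
   probability ``pi(s)``;
4. on fixation the resident arrangement is replaced and the clock advances
   additionally by the expected conditional fixation time; otherwise the
   resident is retained.

The run stops once the elapsed time reaches ``t_end`` generations.  The
monomorphism assumption requires ``N·rho`` to be small; a warning is issued
when it is not.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Any

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
from .popgen import (
    FitnessParams,
    PopGenParams,
    fixation_probability,
    fixation_time,
    selection_coefficient,
    waiting_time,
)
from .runio import Trajectory, params_to_dict

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SubstParams:
    """Parameters of the rearrangement substitution model."""

    rho: float = 1e-6
    popgen: PopGenParams = field(default_factory=PopGenParams)
    fitness: FitnessParams = field(default_factory=FitnessParams)
    genome: GenomeConfig = field(default_factory=GenomeConfig)
    t_end: float = 50_000.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.rho <= 1.0:
            raise ConfigError(f"rho must be in [0, 1], got {self.rho!r}")
        if self.t_end < 0:
            raise ConfigError(f"t_end must be >= 0, got {self.t_end!r}")
        if self.rho * self.popgen.pop_size > 0.1:
            warnings.warn(
                f"N*rho = {self.rho * self.popgen.pop_size:.3g} is not small; "
                "the monomorphic-population assumption is strained",
                stacklevel=2,
            )


@dataclass
class SubstState:
    """Resident arrangement plus elapsed time and the event log."""

    positions: np.ndarray
    elapsed: float = 0.0
    history: list[dict[str, Any]] = field(default_factory=list)


def _fixation_cache_key(
    d_old: int, d_new: int, fitness: FitnessParams
) -> tuple:
    # for exponential fitness s depends only on the distance change
    if fitness.shape == "exponential":
        return (d_new - d_old,)
    return (d_old, d_new)


def subst_event(
    state: SubstState,
    params: SubstParams,
    rng: np.random.Generator,
    _cache: dict | None = None,
) -> SubstState:
    """Advance the state past one proposed rearrangement (in place)."""
    L = params.genome.length_kb
    n = params.popgen.pop_size
    state.elapsed += waiting_time(params.rho, n, rng)

    a, b = draw_breakpoints(params.genome, rng)
    d_old = positions_min_arc(state.positions, L)
    if not inversion_viable(a, b, params.genome):
        state.history.append(
            {
                "time": state.elapsed,
                "distance_kb": d_old,
                "s": float("nan"),
                "fixed": False,
                "viable": False,
                "a": a,
                "b": b,
            }
        )
        return state

    new_positions = invert_positions(state.positions, a, b)
    d_new = positions_min_arc(new_positions, L)
    key = _fixation_cache_key(d_old, d_new, params.fitness)
    if _cache is not None and key in _cache:
        s, pi = _cache[key]
    else:
        s = selection_coefficient(d_old, d_new, params.fitness)
        pi = fixation_probability(s, params.popgen)
        if _cache is not None:
            _cache[key] = (s, pi)

    fixed = rng.random() < pi
    if fixed:
        tkey = ("t",) + key
        if _cache is not None and tkey in _cache:
            t_fix = _cache[tkey]
        else:
            t_fix = fixation_time(s, params.popgen)
            if _cache is not None:
                _cache[tkey] = t_fix
        state.elapsed += t_fix
        state.positions = new_positions
        d_old = d_new
    state.history.append(
        {
            "time": state.elapsed,
            "distance_kb": d_old,
            "s": s,
            "fixed": fixed,
            "viable": True,
            "a": a,
            "b": b,
        }
    )
    return state


def run_subst(
    params: SubstParams,
    rng: np.random.Generator,
    seed: int | None = None,
) -> Trajectory:
    """Run the substitution model until the clock passes ``t_end``.

    The trajectory is the event log (one row per proposed rearrangement:
    time, resident distance, selection coefficient, fixation flag) with an
    initial row at time 0 and a final row at ``t_end`` carrying the
    recorded end-of-run distance.
    """
    state = SubstState(positions=random_positions(params.genome, rng))
    L = params.genome.length_kb
    cache: dict = {}
    d0 = positions_min_arc(state.positions, L)

    heartbeat = params.t_end / 10 if params.t_end > 0 else np.inf
    next_mark = heartbeat
    while state.elapsed < params.t_end:
        subst_event(state, params, rng, _cache=cache)
        if state.elapsed >= next_mark:
            logger.info(
                "subst: t=%.0f/%.0f generations (%.0f%%), distance %d kb",
                state.elapsed, params.t_end,
                100 * min(1.0, state.elapsed / params.t_end),
                positions_min_arc(state.positions, L),
            )
            next_mark += heartbeat

    rows = [
        {"time": 0.0, "distance_kb": d0, "s": float("nan"), "fixed": False}
    ]
    rows += [
        {k: ev[k] for k in ("time", "distance_kb", "s", "fixed")}
        for ev in state.history
        if ev["time"] < params.t_end
    ]
    if params.t_end > 0:
        rows.append(
            {
                "time": float(params.t_end),
                "distance_kb": positions_min_arc(state.positions, L),
                "s": float("nan"),
                "fixed": False,
            }
        )
    data = pd.DataFrame(rows, columns=["time", "distance_kb", "s", "fixed"])
    return Trajectory(
        model="subst",
        data=data,
        status="completed",
        seed=seed,
        params=params_to_dict(params),
    )
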