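"""Parameter exploration: latin hypercube designs, sweeps, Kendall's tau.

A latin hypercube design divides each parameter's range into ``k``
equiprobable strata and places exactly one design value in each, with the
strata permuted independently per parameter ("sampling without
replacement" of the grid).  Parameters whose range spans two or more orders
of magnitude are stratified on a log scale by default.

:func:`sweep` runs any of the three simulators over a design (or an
explicit grid), with per-point/per-replicate seeds derived from a master
seed by a counter scheme so that results are reproducible and independent
of execution order.  Sensitivity direction and significance are summarised
with Kendall's tau-b rank correlation.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import qmc

from .genome import ConfigError
from .runio import Trajectory

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ParamSpec:
    """One swept parameter: a name (dotted path into the model's parameter
    dataclass, e.g. ``"fitness.lambda_fitness"`` or the shorthand ``"rho"``),
    its range, and how to sample it."""

    name: str
    lower: float
    upper: float
    log: bool | None = None  # default: log scale iff range spans >= 2 decades
    integer: bool = False

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise ConfigError(
                f"parameter {self.name!r}: lower ({self.lower}) must be "
                f"< upper ({self.upper})"
            )
        if self.use_log and self.lower <= 0:
            raise ConfigError(
                f"parameter {self.name!r}: log-scale sampling needs lower > 0"
            )

    @property
    def use_log(self) -> bool:
        if self.log is not None:
            return self.log
        return self.lower > 0 and self.upper / self.lower >= 100

    def from_unit(self, u: np.ndarray) -> np.ndarray:
        """Map unit-interval samples onto the parameter range."""
        if self.use_log:
            lo, hi = np.log10(self.lower), np.log10(self.upper)
            vals = 10 ** (lo + u * (hi - lo))
        else:
            vals = self.lower + u * (self.upper - self.lower)
        if self.integer:
            vals = np.clip(np.round(vals), self.lower, self.upper)
        return vals


@dataclass
class LHSDesign:
    """A k_points × n_params latin hypercube design."""

    parameters: list[ParamSpec]
    k_points: int
    matrix: np.ndarray  # parameter values, shape (k_points, n_params)
    unit: np.ndarray  # underlying samples in [0, 1)^d
    sims_per_point: int = 1

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, columns=[p.name for p in self.parameters])


def lhs_sample(
    parameters: Sequence[ParamSpec],
    k_points: int,
    rng: np.random.Generator,
    sims_per_point: int = 1,
) -> LHSDesign:
    """Stratified latin hypercube sample over the parameter box."""
    parameters = list(parameters)
    if k_points < 1:
        raise ConfigError(f"k_points must be >= 1, got {k_points}")
    sampler = qmc.LatinHypercube(d=len(parameters), seed=rng)
    unit = sampler.random(k_points)
    matrix = np.column_stack(
        [p.from_unit(unit[:, j]) for j, p in enumerate(parameters)]
    )
    return LHSDesign(
        parameters=parameters,
        k_points=k_points,
        matrix=matrix,
        unit=unit,
        sims_per_point=sims_per_point,
    )


def kendall_tau(x, y) -> tuple[float, float]:
    """Kendall's tau-b with tie correction and a two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if len(x) < 3:
        raise ValueError("kendall_tau needs at least 3 observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("kendall_tau is undefined for a constant input vector")
    res = stats.kendalltau(x, y)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# sweeps
# ---------------------------------------------------------------------------


def _set_nested(params: Any, path: str, value: Any) -> Any:
    """Return a copy of a (frozen, nested) parameter dataclass with one field
    replaced; ``path`` uses dots for nesting."""
    head, _, rest = path.partition(".")
    if rest:
        sub = getattr(params, head)
        return dataclasses.replace(params, **{head: _set_nested(sub, rest, value)})
    current = getattr(params, head)
    if isinstance(current, int) and not isinstance(current, bool):
        value = int(round(value))
    return dataclasses.replace(params, **{head: value})


# shorthand names accepted in designs, per model
_ALIASES: dict[str, dict[str, str]] = {
    "selfish": {
        "rho": "rho",
        "p_max": "transfer.p_max",
        "p_loss": "transfer.p_loss",
        "lambda_transfer": "transfer.lambda_transfer",
        "n_genes": "genome.n_genes",
    },
    "moran": {
        "rho": "rho",
        "pop_size": "pop_size",
        "lambda_fitness": "fitness.lambda_fitness",
        "n_genes": "genome.n_genes",
    },
    "subst": {
        "rho": "rho",
        "pop_size": "popgen.pop_size",
        "lambda_fitness": "fitness.lambda_fitness",
        "n_genes": "genome.n_genes",
    },
}


def apply_point(model: str, base_params: Any, names: Sequence[str], values) -> Any:
    """Build the parameter object for one design point."""
    params = base_params
    aliases = _ALIASES.get(model, {})
    for name, value in zip(names, values):
        params = _set_nested(params, aliases.get(name, name), value)
    return params


def _final_distance(traj: Trajectory) -> float:
    col = "mean_min_arc_kb" if "mean_min_arc_kb" in traj.data.columns else "distance_kb"
    return traj.final(col)


def _run_model(model: str, params: Any, rng: np.random.Generator) -> Trajectory:
    if model == "selfish":
        from .selfish import run_selfish

        return run_selfish(params, rng)
    if model == "moran":
        from .moran import run_moran

        return run_moran(params, rng)
    if model == "subst":
        from .substitution import run_subst

        return run_subst(params, rng)
    raise ConfigError(f"unknown model {model!r}")


def replicate_seed(master_seed: int, point: int, replicate: int) -> np.random.SeedSequence:
    """Counter-scheme seed: independent stream per (point, replicate)."""
    return np.random.SeedSequence([int(master_seed), int(point), int(replicate)])


def sweep(
    model: str,
    design: LHSDesign | pd.DataFrame,
    base_params: Any,
    master_seed: int,
    sims_per_point: int | None = None,
) -> pd.DataFrame:
    """Run a simulator over every design point.

    Returns one row per point with the parameter values, the mean and
    central-90% interval (5th/95th percentiles) of the final mean minimum
    arc distance over replicates, the number of successful replicates, and
    a status string.  A failing or extinct replicate is recorded, not
    silently dropped.
    """
    if isinstance(design, LHSDesign):
        points = design.as_frame()
        if sims_per_point is None:
            sims_per_point = design.sims_per_point
    else:
        points = design.reset_index(drop=True)
        if sims_per_point is None:
            sims_per_point = 1

    names = list(points.columns)
    records = []
    for idx, row in points.iterrows():
        finals: list[float] = []
        statuses: list[str] = []
        try:
            params = apply_point(model, base_params, names, row.to_numpy())
        except Exception as exc:  # invalid point: record and move on
            records.append(
                {
                    "point": idx,
                    **row.to_dict(),
                    "mean_final_kb": float("nan"),
                    "q5_kb": float("nan"),
                    "q95_kb": float("nan"),
                    "n_ok": 0,
                    "status": f"error: {exc}",
                }
            )
            continue
        for rep in range(sims_per_point):
            rng = np.random.default_rng(replicate_seed(master_seed, idx, rep))
            try:
                traj = _run_model(model, params, rng)
            except Exception as exc:
                statuses.append(f"error: {exc}")
                continue
            if traj.status != "completed":
                statuses.append(traj.status)
                continue
            finals.append(_final_distance(traj))
            statuses.append("ok")
        ok = np.array(finals, dtype=float)
        records.append(
            {
                "point": idx,
                **row.to_dict(),
                "mean_final_kb": float(ok.mean()) if ok.size else float("nan"),
                "q5_kb": float(np.percentile(ok, 5)) if ok.size else float("nan"),
                "q95_kb": float(np.percentile(ok, 95)) if ok.size else float("nan"),
                "n_ok": int(ok.size),
                "status": ";".join(sorted(set(statuses))),
            }
        )
        logger.info("sweep: point %d/%d done", idx + 1, len(points))
    return pd.DataFrame(records)


def sensitivity_taus(results: pd.DataFrame, names: Sequence[str]) -> pd.DataFrame:
    """Kendall tau of each parameter against the mean final distance."""
    ok = results.dropna(subset=["mean_final_kb"])
    rows = []
    for name in names:
        tau, p = kendall_tau(ok[name].to_numpy(), ok["mean_final_kb"].to_numpy())
        rows.append({"parameter": name, "tau": tau, "p_value": p})
    return pd.DataFrame(rows)
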