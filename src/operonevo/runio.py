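"""Trajectories, run manifests and configuration files.

A :class:`Trajectory` is the common result container: a tidy table of
per-sampling-time summary statistics plus run metadata (model name, seed,
completion status).  Trajectories serialize to TSV with a single ``#``
metadata line (JSON) ahead of the column header; numbers are written with 6
significant digits.

A :class:`RunManifest` records everything needed to reproduce a run
bit-for-bit: model, full parameter set, seed, package version and
timestamps.  Configuration files are YAML with one section per parameter
group; unknown sections or keys are rejected, and every value is validated
by the corresponding parameter dataclass.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from .genome import ConfigError, GenomeConfig


@dataclass
class Trajectory:
    """Time series of summary statistics from one simulation run."""

    model: str
    data: pd.DataFrame
    status: str = "completed"
    seed: int | None = None
    params: dict[str, Any] = field(default_factory=dict)

    @property
    def times(self) -> np.ndarray:
        return self.data.iloc[:, 0].to_numpy()

    def final(self, column: str) -> float:
        """Value of ``column`` at the last recorded time."""
        return float(self.data[column].iloc[-1])


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    """Write a trajectory as TSV ('.' decimal, UTF-8, 6 significant digits)."""
    path = Path(path)
    meta = {
        "model": traj.model,
        "status": traj.status,
        "seed": traj.seed,
        "params": traj.params,
    }
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# " + json.dumps(meta) + "\n")
        fh.write("\t".join(traj.data.columns) + "\n")
        for row in traj.data.itertuples(index=False):
            fh.write(
                "\t".join(
                    str(v) if isinstance(v, (int, np.integer, bool)) else f"{v:.6g}"
                    for v in row
                )
                + "\n"
            )


def read_trajectory(path: str | Path) -> Trajectory:
    """Inverse of :func:`write_trajectory` (values to 6 significant digits)."""
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        first = fh.readline()
        if not first.startswith("#"):
            raise ValueError(f"{path}:1: missing metadata line")
        meta = json.loads(first[1:])
        header = fh.readline().rstrip("\n").split("\t")
        rows = []
        for lineno, line in enumerate(fh, start=3):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(header):
                raise ValueError(
                    f"{path}:{lineno}: expected {len(header)} fields, "
                    f"got {len(parts)}"
                )
            rows.append(parts)
    data = pd.DataFrame(rows, columns=header)
    for col in data.columns:
        vals = data[col]
        if vals.isin(["True", "False"]).all():
            data[col] = vals == "True"
        elif vals.str.fullmatch(r"-?\d+").all():
            data[col] = vals.astype(np.int64)
        else:
            data[col] = vals.astype(float)  # handles 'nan' markers
    return Trajectory(
        model=meta["model"],
        data=data,
        status=meta["status"],
        seed=meta["seed"],
        params=meta.get("params", {}),
    )


@dataclass
class RunManifest:
    """Reproducibility record written next to every simulation output."""

    model: str
    params: dict[str, Any]
    seed: int
    version: str
    started: str = ""
    finished: str = ""
    outputs: list[str] = field(default_factory=list)

    def write(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(dataclasses.asdict(self), indent=2) + "\n", encoding="utf-8"
        )

    @classmethod
    def read(cls, path: str | Path) -> "RunManifest":
        return cls(**json.loads(Path(path).read_text(encoding="utf-8")))


def utcnow() -> str:
    return _dt.datetime.now(_dt.timezone.utc).isoformat(timespec="seconds")


# ---------------------------------------------------------------------------
# configuration files
# ---------------------------------------------------------------------------


def params_to_dict(obj: Any) -> Any:
    """Recursively convert parameter dataclasses to plain JSON-able dicts."""
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {
            f.name: params_to_dict(getattr(obj, f.name))
            for f in dataclasses.fields(obj)
        }
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def _build_section(cls: type, name: str, data: dict[str, Any]) -> Any:
    valid = {f.name for f in dataclasses.fields(cls) if f.init}
    unknown = set(data) - valid
    if unknown:
        raise ConfigError(
            f"unknown key(s) {sorted(unknown)} in section '{name}'; "
            f"valid keys: {sorted(valid)}"
        )
    try:
        return cls(**data)
    except ConfigError as exc:
        raise ConfigError(f"section '{name}': {exc}") from exc


def load_config(path: str | Path | None = None) -> dict[str, Any]:
    """Load and validate a YAML configuration file.

    Returns a dict with fully constructed parameter objects under the keys
    ``genome``, ``transfer``, ``fitness``, ``popgen``, ``selfish``, ``moran``
    and ``subst``; an empty (or absent) file yields the full default set.
    Shared sections (genome/transfer/fitness/popgen) are injected into the
    per-model parameter objects.
    """
    from .moran import MoranParams
    from .popgen import FitnessParams, PopGenParams, TransferParams
    from .selfish import SelfishParams
    from .substitution import SubstParams

    raw: dict[str, Any] = {}
    if path is not None:
        text = Path(path).read_text(encoding="utf-8")
        loaded = yaml.safe_load(text)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigError(f"{path}: top level must be a mapping")
        raw = loaded

    sections = {
        "genome": GenomeConfig,
        "transfer": TransferParams,
        "fitness": FitnessParams,
        "popgen": PopGenParams,
        "selfish": SelfishParams,
        "moran": MoranParams,
        "subst": SubstParams,
    }
    unknown = set(raw) - set(sections)
    if unknown:
        raise ConfigError(
            f"unknown section(s) {sorted(unknown)}; valid: {sorted(sections)}"
        )
    for name, data in raw.items():
        if not isinstance(data, dict):
            raise ConfigError(f"section '{name}' must be a mapping")

    genome = _build_section(GenomeConfig, "genome", raw.get("genome", {}))
    transfer = _build_section(TransferParams, "transfer", raw.get("transfer", {}))
    fitness = _build_section(FitnessParams, "fitness", raw.get("fitness", {}))
    popgen = _build_section(PopGenParams, "popgen", raw.get("popgen", {}))

    selfish_kw = dict(raw.get("selfish", {}))
    selfish_kw.setdefault("genome", genome)
    selfish_kw.setdefault("transfer", transfer)
    selfish = _build_section(SelfishParams, "selfish", selfish_kw)

    moran_kw = dict(raw.get("moran", {}))
    moran_kw.setdefault("genome", genome)
    moran_kw.setdefault("fitness", fitness)
    moran = _build_section(MoranParams, "moran", moran_kw)

    subst_kw = dict(raw.get("subst", {}))
    subst_kw.setdefault("genome", genome)
    subst_kw.setdefault("fitness", fitness)
    subst_kw.setdefault("popgen", popgen)
    subst = _build_section(SubstParams, "subst", subst_kw)

    return {
        "genome": genome,
        "transfer": transfer,
        "fitness": fitness,
        "popgen": popgen,
        "selfish": selfish,
        "moran": moran,
        "subst": subst,
    }


def dump_config(config: dict[str, Any], path: str | Path) -> None:
    """Write a config dict (as produced by :func:`load_config`) back to YAML."""
    out: dict[str, Any] = {}
    for name in ("genome", "transfer", "fitness", "popgen"):
        out[name] = params_to_dict(config[name])
    for name in ("selfish", "moran", "subst"):
        d = params_to_dict(config[name])
        # shared sub-objects are serialized in their own sections
        for shared in ("genome", "transfer", "fitness", "popgen"):
            d.pop(shared, None)
        out[name] = d
    Path(path).write_text(yaml.safe_dump(out, sort_keys=False), encoding="utf-8")
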