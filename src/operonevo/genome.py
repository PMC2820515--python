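"""Circular-chromosome gene arrangements and rearrangement operators.

This module carries the machinery shared by all three simulators: a circular
chromosome of ``L`` kilobases with ``n`` pathway genes occupying distinct
1-kb positions, the two rearrangement operators (translocation of a single
gene, and inversion of the segment between two breakpoints), the
replichore-imbalance viability rule for inversions, and the minimum arc
distance — the length of the shortest contiguous arc containing all pathway
genes, equivalently the genome length minus the largest gap between
neighbouring genes.

Coordinate conventions
----------------------
* Gene positions are 1-based integers in ``[1, L]``; genes are 1 kb long and
  identified with their position.  Only one gene may occupy a position.
* Inversion breakpoints fall *between* genes: two integers are drawn
  uniformly on ``{1..L}`` and offset by −0.5, so breakpoints are
  half-integers and can never coincide with a gene.
* The replication origin sits at coordinate 0 (≡ L) and the terminus at
  L/2.  An inversion whose segment is ordered (``a ≤ b``) never contains the
  origin, so viability reduces to a terminus-displacement test: the
  reflection maps the terminus to ``a + b − L/2`` and the arrangement is
  lethal when ``|a + b − L|`` exceeds the imbalance tolerance.
* One "minute" of the chromosome is ``L/100`` kb; the clustering threshold
  used for reporting is 3 minutes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np


class ConfigError(ValueError):
    """A parameter violates its documented constraint."""


# ---------------------------------------------------------------------------
# configuration and arrangement containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenomeConfig:
    """Static geometry of the circular chromosome.

    Parameters
    ----------
    length_kb:
        Chromosome length L in kilobases (default 4900).
    n_genes:
        Number of pathway genes n (default 3).
    tolerance_kb:
        Maximum tolerated displacement of the origin/terminus by an
        inversion before the arrangement is considered lethal (default 100).
    """

    length_kb: int = 4900
    n_genes: int = 3
    tolerance_kb: float = 100.0

    def __post_init__(self) -> None:
        if int(self.length_kb) != self.length_kb or self.length_kb <= 0:
            raise ConfigError(
                f"length_kb must be a positive integer, got {self.length_kb!r}"
            )
        if int(self.n_genes) != self.n_genes or not 2 <= self.n_genes <= self.length_kb:
            raise ConfigError(
                f"n_genes must be an integer in [2, length_kb={self.length_kb}], "
                f"got {self.n_genes!r}"
            )
        if self.tolerance_kb < 0:
            raise ConfigError(
                f"tolerance_kb must be non-negative, got {self.tolerance_kb!r}"
            )

    @property
    def origin_kb(self) -> float:
        return 0.0

    @property
    def terminus_kb(self) -> float:
        return self.length_kb / 2

    @property
    def minute_kb(self) -> float:
        return self.length_kb / 100

    @property
    def cluster_threshold_kb(self) -> float:
        """The 3-minute clustering threshold used for reporting."""
        return 3 * self.minute_kb


@dataclass(frozen=True)
class Arrangement:
    """Positions of the pathway genes on one circular chromosome.

    ``positions`` is a sorted integer array of ``config.n_genes`` distinct
    values in ``[1, config.length_kb]``.
    """

    positions: np.ndarray
    config: GenomeConfig = field(default_factory=GenomeConfig)

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=np.int64)
        pos = np.sort(pos)
        object.__setattr__(self, "positions", pos)
        if pos.size != self.config.n_genes:
            raise ConfigError(
                f"expected {self.config.n_genes} gene positions, got {pos.size}"
            )
        if np.unique(pos).size != pos.size:
            raise ConfigError("gene positions must be pairwise distinct")
        if pos.size and (pos[0] < 1 or pos[-1] > self.config.length_kb):
            raise ConfigError(
                f"gene positions must lie in [1, {self.config.length_kb}]"
            )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Arrangement):
            return NotImplemented
        return self.config == other.config and np.array_equal(
            self.positions, other.positions
        )

    def to_tsv(self) -> str:
        """One-line record: ``length_kb<TAB>comma-separated-positions``."""
        return f"{self.config.length_kb}\t{','.join(map(str, self.positions))}"

    @classmethod
    def from_tsv(
        cls, line: str, config: GenomeConfig | None = None
    ) -> "Arrangement":
        length_s, pos_s = line.rstrip("\n").split("\t")
        positions = np.array([int(p) for p in pos_s.split(",")], dtype=np.int64)
        if config is None:
            config = GenomeConfig(length_kb=int(length_s), n_genes=positions.size)
        elif config.length_kb != int(length_s):
            raise ConfigError(
                f"record length {length_s} does not match config "
                f"length {config.length_kb}"
            )
        return cls(positions, config)


# ---------------------------------------------------------------------------
# initialisation
# ---------------------------------------------------------------------------


def random_arrangement(config: GenomeConfig, rng: np.random.Generator) -> Arrangement:
    """Place ``n_genes`` genes uniformly at random, without replacement."""
    positions = random_positions(config, rng)
    return Arrangement(positions, config)


def random_positions(config: GenomeConfig, rng: np.random.Generator) -> np.ndarray:
    """Array form of :func:`random_arrangement` used by the hot loops."""
    return np.sort(
        rng.choice(config.length_kb, size=config.n_genes, replace=False) + 1
    ).astype(np.int64)


# ---------------------------------------------------------------------------
# the minimum arc distance statistic
# ---------------------------------------------------------------------------


def positions_min_arc(positions: np.ndarray, length_kb: int) -> int:
    """Minimum arc distance of a raw (possibly unsorted) position array.

    Returns L minus the largest circular gap between consecutive genes.
    By convention an arrangement with fewer than 2 genes has distance 0.
    """
    n = len(positions)
    if n < 2:
        return 0
    pos = np.sort(np.asarray(positions))
    gaps = np.diff(pos)
    wrap = length_kb - (pos[-1] - pos[0])
    largest = max(int(gaps.max()), int(wrap)) if n > 1 else length_kb
    return int(length_kb - largest)


def min_arc_distance(arr: Arrangement) -> int:
    """Minimum arc distance of an :class:`Arrangement`, in kb."""
    return positions_min_arc(arr.positions, arr.config.length_kb)


def proportion_clustered(
    arrs: Sequence[Arrangement] | Iterable[Arrangement],
    threshold_kb: float | None = None,
) -> float:
    """Fraction of arrangements with min-arc distance strictly below threshold.

    The default threshold is 3 chromosome minutes (``3 L / 100`` kb).
    """
    arrs = list(arrs)
    if not arrs:
        raise ValueError("proportion_clustered is undefined for an empty list")
    if threshold_kb is None:
        threshold_kb = arrs[0].config.cluster_threshold_kb
    hits = sum(1 for a in arrs if min_arc_distance(a) < threshold_kb)
    return hits / len(arrs)


# ---------------------------------------------------------------------------
# rearrangement operators
# ---------------------------------------------------------------------------


def draw_breakpoints(
    config: GenomeConfig, rng: np.random.Generator
) -> tuple[float, float]:
    """Draw an ordered pair of inversion breakpoints.

    Two integers uniform on ``{1..L}`` are offset by −0.5 so that breakpoints
    fall between genes; the pair is returned with ``a <= b``.
    """
    u, v = rng.integers(1, config.length_kb + 1, size=2)
    a, b = (u, v) if u <= v else (v, u)
    return a - 0.5, b - 0.5


def inversion_viable(a: float, b: float, config: GenomeConfig) -> bool:
    """Replichore-imbalance viability of inverting the segment (a, b).

    With the origin pinned at 0 (never interior to an ordered segment) the
    rule reduces to: the segment misses the terminus entirely, or the
    reflected terminus ``a + b − L/2`` is displaced by at most the tolerance.
    """
    if a > b:
        raise ValueError(f"breakpoints must be ordered, got a={a} > b={b}")
    half = config.length_kb / 2
    return (
        b < half
        or a > half
        or abs(a + b - config.length_kb) <= config.tolerance_kb
    )


def invert_positions(positions: np.ndarray, a: float, b: float) -> np.ndarray:
    """Reflect every gene strictly inside (a, b) to ``a + b − g``."""
    pos = np.asarray(positions)
    inside = (pos > a) & (pos < b)
    out = pos.copy()
    # a+b is an odd integer sum of two half-integers, so a+b-g stays integral
    out[inside] = np.round(a + b - pos[inside]).astype(pos.dtype)
    return np.sort(out)


def apply_inversion(arr: Arrangement, a: float, b: float) -> Arrangement:
    """Apply an (already viability-checked) inversion to an arrangement."""
    if a > b:
        raise ValueError(f"breakpoints must be ordered, got a={a} > b={b}")
    return Arrangement(invert_positions(arr.positions, a, b), arr.config)


def translocate_positions(
    positions: np.ndarray, length_kb: int, rng: np.random.Generator
) -> np.ndarray:
    """Move one uniformly chosen gene to a uniformly chosen unoccupied slot."""
    pos = np.asarray(positions, dtype=np.int64)
    i = int(rng.integers(pos.size))
    occupied = set(int(p) for p in pos)
    # rejection sampling: uniform over the L - n free slots
    while True:
        dest = int(rng.integers(1, length_kb + 1))
        if dest not in occupied:
            break
    out = pos.copy()
    out[i] = dest
    return np.sort(out)


def apply_translocation(arr: Arrangement, rng: np.random.Generator) -> Arrangement:
    """Translocation operator on an :class:`Arrangement`."""
    return Arrangement(
        translocate_positions(arr.positions, arr.config.length_kb, rng), arr.config
    )
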