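"""Rate, fitness and population-genetic functions shared by the simulators.

Three ingredients live here:

* the distance-decaying horizontal-transfer kernel
  ``P(d) = P_max * exp(-lambda_transfer * d)``, calibrated by default so that
  a 50 kb fragment is exactly 6 times more likely to transfer than a 500 kb
  one (``lambda_transfer = ln(6)/450`` per kb);
* relative fitness as a function of the minimum arc distance d, either
  exponential ``w(d) = exp(-lambda_fitness * d)`` or a logistic (sigmoidal)
  decline ``w(d) = 1 / (1 + exp(k (d - m)))``, and the derived selection
  coefficient ``s = w(d_new)/w(d_old) - 1``;
* diffusion-theory fixation quantities for a single new haploid mutant.
  Diploid results are applied to haploids through the substitution
  ``N_e = N/2``, which gives the fixation probability

      pi(s) = (1 - exp(-2 s)) / (1 - exp(-2 N s)),

  with the neutral limit ``pi(0) = 1/N``, and the Kimura–Ohta conditional
  mean fixation time, evaluated by numerical integration of the conditional
  sojourn-time density with initial frequency ``p = 1/N`` (neutral limit
  ``4 N_e = 2N`` generations).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.integrate import quad

from .genome import ConfigError

#: default transfer decay per kb: pinned so P(50)/P(500) = 6 exactly
DEFAULT_LAMBDA_TRANSFER = math.log(6) / 450.0


@dataclass(frozen=True)
class TransferParams:
    """Horizontal-transfer kernel and loss parameters (selfish-operon model).

    ``p_max`` is the transfer probability per genome per time step when the
    genes share a chromosome minute; ``p_loss`` the per-step probability of
    losing the pathway function.
    """

    p_max: float = 0.01
    lambda_transfer: float = DEFAULT_LAMBDA_TRANSFER
    p_loss: float = 0.001

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_max <= 1.0:
            raise ConfigError(f"p_max must be in [0, 1], got {self.p_max!r}")
        if self.lambda_transfer < 0:
            raise ConfigError(
                f"lambda_transfer must be >= 0, got {self.lambda_transfer!r}"
            )
        if not 0.0 <= self.p_loss <= 1.0:
            raise ConfigError(f"p_loss must be in [0, 1], got {self.p_loss!r}")


@dataclass(frozen=True)
class FitnessParams:
    """Decline of relative fitness with minimum arc distance.

    ``shape`` selects the exponential form (decay ``lambda_fitness`` per kb)
    or the sigmoidal form, a logistic with midpoint ``sig_midpoint_kb`` and
    steepness ``sig_steepness`` per kb under which fitness falls off sharply
    between roughly 5 and 20 kb at the defaults.
    """

    shape: str = "exponential"
    lambda_fitness: float = 1e-3
    sig_midpoint_kb: float = 12.5
    sig_steepness: float = 0.5

    def __post_init__(self) -> None:
        if self.shape not in ("exponential", "sigmoidal"):
            raise ConfigError(
                f"shape must be 'exponential' or 'sigmoidal', got {self.shape!r}"
            )
        if self.lambda_fitness < 0:
            raise ConfigError(
                f"lambda_fitness must be >= 0, got {self.lambda_fitness!r}"
            )
        if self.sig_steepness < 0:
            raise ConfigError(
                f"sig_steepness must be >= 0, got {self.sig_steepness!r}"
            )


@dataclass(frozen=True)
class PopGenParams:
    """Haploid population size; the diffusion formulas use N_e = N/2."""

    pop_size: int = 10_000

    def __post_init__(self) -> None:
        if int(self.pop_size) != self.pop_size or self.pop_size < 2:
            raise ConfigError(f"pop_size must be an integer >= 2, got {self.pop_size!r}")

    @property
    def effective_size(self) -> float:
        return self.pop_size / 2


# ---------------------------------------------------------------------------
# transfer and fitness kernels
# ---------------------------------------------------------------------------


def transfer_prob(d, params: TransferParams):
    """Horizontal-transfer probability at minimum arc distance ``d`` (kb)."""
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("distance must be non-negative")
    out = params.p_max * np.exp(-params.lambda_transfer * d)
    return float(out) if out.ndim == 0 else out


def log_fitness(d, params: FitnessParams):
    """log w(d); the simulators select on this to avoid underflow at large d."""
    d = np.asarray(d, dtype=float)
    if params.shape == "exponential":
        out = -params.lambda_fitness * d
    else:
        # log(1 / (1 + e^{k(d-m)})) computed stably
        out = -np.logaddexp(0.0, params.sig_steepness * (d - params.sig_midpoint_kb))
    return float(out) if out.ndim == 0 else out


def fitness(d, params: FitnessParams):
    """Relative fitness w(d) in (0, 1], non-increasing in d.

    Note that for the sigmoidal shape at distances far beyond the midpoint
    the true value is below double-precision range and the float result
    underflows to 0; the simulators therefore work with :func:`log_fitness`.
    """
    out = np.exp(log_fitness(d, params))
    return float(out) if np.ndim(out) == 0 else out


def selection_coefficient(d_old: float, d_new: float, params: FitnessParams) -> float:
    """s = w(d_new) / w(d_old) − 1, computed from log-fitness.

    Always > −1; 0 when the distances coincide; negative when the new
    arrangement spreads the genes further apart.
    """
    if d_old < 0 or d_new < 0:
        raise ValueError("distances must be non-negative")
    delta = log_fitness(d_new, params) - log_fitness(d_old, params)
    # cap to keep downstream exponentials finite; pi(s) is already 1 here
    return float(math.expm1(min(delta, 700.0)))


# ---------------------------------------------------------------------------
# diffusion-theory fixation quantities
# ---------------------------------------------------------------------------


def fixation_probability(s: float, params: PopGenParams) -> float:
    """Probability that a single new mutant with selection s fixes.

    ``pi(s) = (1 − e^{−2s}) / (1 − e^{−2Ns})`` (haploid mapping N_e = N/2),
    continuous at s = 0 with value 1/N, strictly increasing in s.
    """
    if s <= -1:
        raise ValueError(f"selection coefficient must exceed -1, got {s}")
    n = params.pop_size
    if s == 0 or abs(s) < 1e-14:
        return 1.0 / n
    u = -2.0 * s
    nu = -2.0 * n * s
    if nu > 700.0:
        # strongly deleterious: (e^u - 1)/(e^{Nu} - 1) ~ e^{u - Nu}(1 - e^{-u})
        return math.exp(u - nu) * (-math.expm1(-u))
    return math.expm1(u) / math.expm1(nu)


def _neutral_fixation_time(params: PopGenParams) -> float:
    # -4 Ne (1-p) ln(1-p) / p with Ne = N/2, p = 1/N
    n = params.pop_size
    p = 1.0 / n
    return -2.0 * n * (1.0 - p) * math.log1p(-p) / p


def fixation_time(s: float, params: PopGenParams) -> float:
    """Expected fixation time (generations) of a single new mutant, given fixation.

    Kimura–Ohta conditional sojourn-time integral for the haploid
    Wright–Fisher diffusion (drift ``s x(1−x)``, variance ``x(1−x)/N``,
    initial frequency ``p = 1/N``).  The neutral limit is ``2N`` generations.
    Negative s is handled through the Maruyama–Kimura symmetry
    ``t_fix(s) = t_fix(−s)`` for a single initial copy.
    """
    if s <= -1:
        raise ValueError(f"selection coefficient must exceed -1, got {s}")
    n = params.pop_size
    p = 1.0 / n
    s = abs(s)
    S = 2.0 * n * s  # scaled selection 4 Ne s
    if S < 1e-8:
        return _neutral_fixation_time(params)

    em1_S = -math.expm1(-S)  # 1 - e^{-S}, safe for all S >= 0

    def u_of(x: float) -> float:
        return -math.expm1(-S * x) / em1_S

    u_p = u_of(p)

    def upper(x: float) -> float:
        # conditional sojourn density for p <= x <= 1
        return 2.0 * n * u_of(x) * (-math.expm1(-S * (1.0 - x))) / (S * x * (1.0 - x))

    tail = -math.expm1(-S * (1.0 - p))  # 1 - e^{-S(1-p)}

    def lower(x: float) -> float:
        # conditional sojourn density for 0 <= x <= p
        ux = u_of(x)
        return (
            2.0 * n * math.exp(S * (x - p)) * tail * ux * ux
            / (u_p * S * x * (1.0 - x))
        )

    # the upper integrand decays on a scale 1/S near x = 1; give quad hints
    pts = sorted({x for x in (1.0 - 1.0 / S, 1.0 - 10.0 / S, 0.5) if p < x < 1.0})
    t_upper, err_u = quad(upper, p, 1.0, points=pts or None, limit=200)
    t_lower, err_l = quad(lower, 0.0, p, limit=200)
    total = t_upper + t_lower
    if not np.isfinite(total) or (err_u + err_l) > max(1e-3 * total, 1e-6):
        raise RuntimeError(
            f"fixation-time integral did not converge (s={s}, N={n}, "
            f"value={total}, abserr={err_u + err_l})"
        )
    return total


def waiting_time(rho: float, pop_size: int, rng: np.random.Generator) -> int:
    """Generations until a rearrangement arises in at least one individual.

    Geometric draw with per-generation success probability
    ``p = 1 − (1 − rho)^N`` (≈ N·rho for small rho).
    """
    if not 0.0 <= rho <= 1.0:
        raise ValueError(f"rho must be in [0, 1], got {rho}")
    if rho == 1.0:
        return 1
    p = -math.expm1(pop_size * math.log1p(-rho))
    if p <= 0.0:
        raise ValueError(
            f"no rearrangement possible: rho={rho}, N={pop_size} give p=0"
        )
    return int(rng.geometric(p))
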