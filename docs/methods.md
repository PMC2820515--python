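# Methods

This note documents the models implemented in `operonevo`, the parameter
defaults and the reasoning behind them, the numerical choices, and what
the test suite does and does not establish.

## Genome model

A genome is a circular chromosome of `L` integer kb positions carrying
`n ≥ 2` pathway genes, each 1 kb long and identified with its position;
two genes cannot share a position. The summary statistic throughout is
the minimum arc distance `d`: the shortest contiguous arc containing all
pathway genes, computed as `L` minus the largest circular gap between
consecutive sorted positions. For `n` uniform random genes
`E[d] = L(1 − H_n/n)` with `H_n` the harmonic number; for `n = 3` this is
`7L/18`, which the initialization tests use as an analytic oracle.

Coordinates: gene positions are 1-based integers; inversion breakpoints
are drawn as two uniform integers on `{1..L}` offset by −0.5, so they fall
between genes and the reflection `g → a + b − g` maps integers to
integers. The replication origin is pinned at coordinate 0 (≡ `L`) and
the terminus at `L/2`. Because an ordered segment `(a, b)` with
`0 < a ≤ b < L` can never contain the origin, the replichore-imbalance
viability rule reduces to a single landmark test: the inversion is viable
iff the segment misses the terminus (`b < L/2` or `a > L/2`) or the
reflected terminus is displaced by at most the tolerance
(`|a + b − L| ≤ T`).

Defaults and why:

| parameter | default | rationale |
| --- | --- | --- |
| `L` | 4900 kb | a typical enterobacterial chromosome; makes the random-placement mean `7L/18 ≈ 1906` kb agree with the ~1900 kb initialization statistic |
| `n` | 3 | smallest interesting pathway |
| `T` | 100 kb | a strict imbalance tolerance (~2% of `L`); configurable, and the qualitative results are insensitive to it because it only rescales the viable-proposal rate |
| clustering threshold | 3 minutes = `3L/100` kb | classical *E. coli* mapping units; 147 kb at the default `L` |

Translocation moves one uniformly chosen pathway gene to a uniformly
chosen unoccupied position (rejection sampling; the old position is
occupied until the move, so it is excluded).

## Transfer kernel, fitness, and fixation theory

Horizontal transfer decays exponentially with the distance that must be
co-transferred: `P(d) = P_max·e^{−λ_t d}` with `P_max = 0.01` and
`P_loss = 0.001` per genome per time step. The decay is pinned at
`λ_t = ln(6)/450 per kb` so that a 50-kb fragment is exactly 6 times more
likely to transfer than a 500-kb one.

Fitness under direct selection is either exponential, `w(d) = e^{−λ d}`
(default `λ = 10⁻³ per kb`, the geometric middle of the interesting range
— see the sensitivity section), or sigmoidal,
`w(d) = 1/(1 + e^{k(d−m)})` with midpoint `m = 12.5` kb and steepness
`k = 0.5 per kb`, which makes fitness collapse between roughly 5 and
20 kb. The sigmoid underflows double precision for `d ≫ m`
(`e^{−0.5·1900}` is far below the smallest double), so the simulators
never exponentiate absolute fitness: they select on log-fitness shifted
by its maximum, which preserves the exact ratios. The selection
coefficient is `s = w(d_new)/w(d_old) − 1 = e^{Δlog w} − 1`, computed in
log space and capped at `e^700 − 1` (beyond which the fixation probability
is 1 to machine precision anyway).

Fixation quantities come from diffusion theory with the haploid mapping
`N_e = N/2`, giving for a single new mutant

    π(s) = (1 − e^{−2s}) / (1 − e^{−2Ns}),    π(0) = 1/N.

For `2N|s| > 700` asymptotic branches avoid overflow. Two caveats the
tests encode explicitly:

* π is the haploid **Wright–Fisher** diffusion result. The exact Moran
  birth–death absorption probability agrees with it only in the
  weak-selection regime (the ratio is ≈ `2/(1 + e^{−Ns})`, i.e. the
  well-known factor-2 timescale difference at large `Ns`), so the
  consistency test compares the two at `|Ns| ≤ 0.15`, where 10%
  agreement is guaranteed.
* The expected conditional fixation time is evaluated by numerical
  integration (adaptive quadrature) of the Kimura–Ohta conditional
  sojourn-time density for the haploid diffusion (drift `s·x(1−x)`,
  variance `x(1−x)/N`, initial frequency `p = 1/N`), written in
  exponentially stable form. The neutral value is the closed form
  `−4N_e(1−p)ln(1−p)/p → 2N` generations, used both as a small-`s`
  branch and as a validation anchor; for `s < 0` the Maruyama–Kimura
  single-mutant symmetry `t_fix(s) = t_fix(−s)` is used, which is exact
  in the `p → 0` limit and avoids overflowing integrands. The integral
  is cross-checked against a vectorized Wright–Fisher simulation
  (`N = 50`, `s = 0.05`, >2000 fixations) allowing 3 standard errors
  plus a 2% margin for the `O(1/N)` discreteness bias of the diffusion
  approximation.

Waiting times between rearrangement proposals are geometric with
parameter `1 − (1−ρ)^N` (≈ `Nρ` for small ρ), computed via `log1p` to
stay exact for tiny ρ.

## Selfish-operon species pool

One step processes species in index order: (a) rearrangement — original
translocation with probability ρ, corrected translocation with
probability `ρ·n/L`, or attempted inversion with probability ρ (a
non-viable inversion leaves the species unchanged: the individual dying
of a lethal inversion does not change the species' fixed arrangement);
(b) loss with probability `P_loss`, applied immediately; (c) if the pool
currently holds fewer than 900 positive species, the species donates a
recruit (an identical copy) with probability `P(d)`. Recruits are
appended after the sweep and not iterated within the step. The
per-species Bernoulli draws are generated as vectorized blocks in index
order — distributionally identical to the sequential loop — and only
species with an event enter the sequential cap bookkeeping, which makes a
15,000-step run take under a second.

The 10-species floor is reported but not enforced (no intervention is
defined for it); a pool that reaches size 0 ends the run with
`status="extinct"` and a truncated trajectory.

Dynamics worth knowing when interpreting runs at the defaults: transfer
beats loss only below `d* = ln(P_max/P_loss)/λ_t ≈ 578` kb. Of 100
random founders only ~4 expected species fall below `d*`, each a barely
supercritical branching lineage, so in roughly a quarter of runs no
clustered lineage establishes and the pool dwindles (the run may even go
extinct); in the rest, the clustered lineages take over, the pool mean
distance sweeps down past 800 kb toward `d*` and below, and the pool hits
the 900 cap within a few thousand steps. Tests and the acceptance script
therefore phrase cap-reaching claims about the *typical* run (medians
over ≥ 21 replicates) rather than a single stochastic realization.

## Moran model

Classical overlapping-generations Moran dynamics plus inversion: per
elementary step one uniform individual is chosen and breakpoints drawn;
with probability ρ an inversion is attempted — viable inversions replace
the chosen genome, lethal ones kill the individual, which is replaced by
the offspring of a parent drawn fitness-proportionally from the other
`N − 1` individuals (self-exclusion is the default because the focal
genome is dead; a config switch `exclude_dead_parent=False` restores
whole-population sampling). With probability `1 − ρ` the chosen
individual dies and is replaced by the offspring of a
fitness-proportional parent from the whole population (standard Moran,
self-replacement allowed). One generation = `N` steps; the population
mean distance is recorded once per generation by default.

Distances and log-fitness are cached per individual and invalidated on
genome change; a `recompute_caches` method lets tests verify the cache
contract. Since viable inversions are permutations of the `L` sites, a
neutral run leaves the (uniform-random-subset) distribution of each
genome invariant, which is the basis of the trajectory-flatness test.

## Rearrangement substitution model

State is a single resident arrangement plus a clock in generations. Per
event: advance by a geometric waiting time; draw breakpoints; a
non-viable proposal changes nothing (but has consumed the waiting
interval); a viable one fixes with probability `π(s)`, in which case the
resident is replaced and the clock additionally advances by the expected
conditional fixation time. Fixation time for *unsuccessful* excursions is
not added — the printed algorithm only assigns a time cost on
substitution, and failed excursions are brief by comparison. The run
stops once the clock passes `t_end = 50,000` generations. Monomorphism
requires `Nρ ≪ 1`; a warning is raised above 0.1.

Defaults `ρ = 10⁻⁶`, `N = 10⁴`, `λ = 10⁻³`: about 500 proposals per run,
strong but not saturating selection — a regime where clustering clearly
emerges yet every parameter still matters. Because distances are
integers and exponential-fitness selection depends only on `Δd`, per-run
caches keyed by `Δd` (or the `(d_old, d_new)` pair for sigmoidal fitness)
make the quadrature cost negligible.

## Sensitivity analysis

Latin hypercube designs (one sample per equiprobable stratum per
parameter, strata permuted independently) are generated by
`scipy.stats.qmc.LatinHypercube` and mapped onto parameter ranges;
parameters spanning ≥ 2 decades are stratified on a log scale by default,
and integer parameters are rounded. Sweeps derive one RNG stream per
(point, replicate) from the master seed with a counter scheme, so results
are bit-reproducible and independent of execution order; failing or
extinct replicates are recorded in a status column, never dropped.
Kendall's tau-b (scipy) summarises sensitivity directions; an O(n²)
pair-counting oracle validates it in the tests.

Default ranges for the substitution-model design: `ρ ∈ [10⁻¹⁰, 10⁻⁶]`,
`N ∈ [10², 10⁶]`, `λ ∈ [10⁻⁶, 10⁻²]` (all log), `n ∈ {3..10}`. The λ
range was chosen to bracket the weak-to-strong-selection transition
observed in one-at-a-time sweeps at the default `N` and ρ (the response
flattens above λ ≈ 10⁻³); a range sitting entirely in the saturated
regime would show no marginal λ effect. With these ranges a 200-point,
40-replicate design reproduces the sensitivity directions — final
distance decreases in ρ, `N` and λ and increases in `n` — each with
p < 0.01.

## Problem sizes used in the tests

Monte-Carlo sizes were chosen so each check has ≥ 4-standard-error
resolution at a few seconds' cost: 10,000 placements for the
initialization statistic, 1200–1500 Moran fixation runs at `N = 20`,
10⁵ proposal events for the neutral acceptance rate, 100 replicates for
neutral stationarity of the substitution model, 21 replicates of
15,000-step selfish runs for the population-dynamics checks, and the
200×40 hypercube above. All tests are deterministic (fixed seeds).

## What the synthetic conditions do and do not show

The simulators *are* the object of study — there is no external data —
but the conditions remain idealisations: genes are 1-kb points, a single
pathway per genome, no within-species polymorphism in the selfish and
substitution models, no clonal interference, no gene duplication, and an
uncalibrated time step in the species-pool model (outputs are labelled
"steps"). Passing tests show the implementations reproduce the models'
analytic anchors and qualitative regimes, not that any particular
bacterial clade evolved its operons this way.

## Known limitations

* `fitness()` itself can underflow to 0 for the sigmoid at extreme
  distances; all selection paths use `log_fitness` instead, but user code
  comparing raw fitness values at `d > ~1400` kb should too.
* The fixation-time quadrature targets ~10⁻³ relative accuracy and
  raises if the integrator's error estimate exceeds it.
* The exact-Moran/diffusion factor-2 discrepancy at `Ns ≳ 1` means the
  substitution model and the Moran simulator are not numerically
  interchangeable at strong selection; they agree in the weak-selection
  limit and qualitatively elsewhere.
* Trajectory TSVs round values to 6 significant digits; byte-identical
  reproduction requires the same package version and seed.
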