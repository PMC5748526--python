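"""Closed-form expectations and regime calculators for seed-bank populations.

The central closed form is the equilibrium pairwise diversity of the active
pool in a population with a seed bank,

    E[pi] = theta * (1 + M/N),

where ``theta`` is the population-scaled mutation rate ``2 * Ne * mu`` and
``M/N`` is the relative excess of dormant individuals.  The inflation factor
``(1 + M/N)`` is exact for the engine in this package for any exchange count
``c``: following two active lineages backward through the active/dormant
state chain, the expected total active lineage time to coalescence is
``N (1 + M/N)`` generations regardless of how often lineages swap pools.

What ``theta`` is numerically depends on the update rule.  A Moran engine
performing N birth--death events per generation, with mutation at birth, has
pairwise-coalescent effective size ``Ne = N/2``, so its theta is ``N * mu``;
the Wright--Fisher convention has ``Ne = N`` and ``theta = 2 N mu``.  Use
:func:`coalescent_theta` to obtain the value appropriate to the process being
compared against.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Union

import numpy as np

from .model import ConfigurationError, SeedBankParams, init_population, seed_beneficial, step

__all__ = [
    "RegimeReport",
    "expected_pi",
    "coalescent_theta",
    "mean_residence_time",
    "classify_regime",
    "strong_seedbank_wallclock",
    "moran_fixation_probability",
    "no_seedbank_tfix_reference",
]

DAYS_PER_YEAR = 365.25


def expected_pi(theta: float, M: int, N: int) -> float:
    """Equilibrium pairwise diversity ``theta * (1 + M/N)``.

    ``theta`` is the population-scaled mutation rate of the active pool
    (see :func:`coalescent_theta`); reduces to ``theta`` without a seed bank.
    """
    if N < 1:
        raise ConfigurationError("N must be >= 1")
    if theta < 0 or M < 0:
        raise ConfigurationError("theta and M must be non-negative")
    return theta * (1.0 + M / N)


def coalescent_theta(N: int, mu: float, update: str = "moran") -> float:
    """Population-scaled mutation rate ``2 * Ne * mu`` for the update rule.

    ``update='moran'`` (this package's engine, N events per generation,
    mutation at birth): Ne = N/2, theta = N*mu.  ``update='wright-fisher'``:
    Ne = N, theta = 2*N*mu.
    """
    if update == "moran":
        return N * mu
    if update == "wright-fisher":
        return 2.0 * N * mu
    raise ConfigurationError(f"unknown update rule {update!r}")


def mean_residence_time(M: int, c: int) -> float:
    """Mean of the geometric residence-time distribution, ``M / c`` generations.

    Each dormant individual exits with probability ``c/M`` per generation.
    ``c = 0`` with a non-empty bank means dormancy is never left: returns
    ``inf`` explicitly.  An empty bank has residence 0.
    """
    if M < 0 or c < 0:
        raise ConfigurationError("M and c must be non-negative")
    if M == 0:
        return 0.0
    if c == 0:
        return math.inf
    return M / c


@dataclass(frozen=True)
class RegimeReport:
    """Weak/strong seed-bank classification for one parameterisation.

    ``regime`` is ``'strong'`` iff the mean residence time exceeds the
    number of active individuals (strictly), ``'weak'`` otherwise.
    """

    mean_residence: float
    threshold: float
    regime: str
    wallclock_years: Optional[float] = None


def classify_regime(params: SeedBankParams,
                    generations_per_day: Optional[float] = None) -> RegimeReport:
    """Classify a parameterisation as weak or strong seed bank.

    The threshold is the active pool size N; the regime is strong when the
    mean dormancy duration M/c strictly exceeds it. If ``generations_per_day``
    is given, the mean residence is also converted to wall-clock years.
    """
    mean_res = mean_residence_time(params.M, params.c)
    regime = "strong" if mean_res > params.N else "weak"
    years = None
    if generations_per_day is not None and math.isfinite(mean_res):
        years = strong_seedbank_wallclock(mean_res, generations_per_day) if mean_res > 0 else 0.0
    return RegimeReport(mean_residence=mean_res, threshold=float(params.N),
                        regime=regime, wallclock_years=years)


def strong_seedbank_wallclock(generations_dormant: float,
                              generations_per_day: float) -> float:
    """Convert a dormancy duration in generations to wall-clock years.

    E.g. 1e9 dormant generations at ~6.67 generations/day -- the scale at
    which a strong seed bank becomes possible for a large E. coli
    population -- exceeds 400,000 years.
    """
    if generations_dormant <= 0 or generations_per_day <= 0:
        raise ConfigurationError("both arguments must be positive")
    return generations_dormant / generations_per_day / DAYS_PER_YEAR


def moran_fixation_probability(N: int, s: float) -> float:
    """Fixation probability of a single mutant in the Moran model without a bank.

    ``1/N`` when neutral; ``(1 - (1+s)^-1) / (1 - (1+s)^-N)`` with relative
    fitness ``1+s``.
    """
    if N < 1:
        raise ConfigurationError("N must be >= 1")
    if s == 0:
        return 1.0 / N
    r = 1.0 + s
    return (1.0 - 1.0 / r) / (1.0 - r ** (-N))


def no_seedbank_tfix_reference(N: int, s: float, reps: int,
                               rng: Union[np.random.Generator, int],
                               max_generations: int = 10_000_000) -> float:
    """Monte-Carlo mean conditional fixation time without a seed bank.

    Simulates ``reps`` replicates of a single beneficial mutant in a Moran
    population of size N (M=0) and averages the fixation time over the
    replicates in which the allele fixed.  This is the horizontal reference
    that the active-pool quasi-fixation time approaches past the strong
    seed-bank threshold.
    """
    if s <= 0:
        raise ConfigurationError("the reference fixation time requires s > 0")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    params = SeedBankParams(N=N, M=0, c=0, s=s, mode="biallelic")
    times = []
    for _ in range(reps):
        state = seed_beneficial(init_population(params), 1)
        for _ in range(max_generations):
            step(state, params, rng)
            k = int(state.active.sum())
            if k == 0:
                break
            if k == N:
                times.append(state.generation)
                break
    if not times:
        raise RuntimeError(
            f"no fixations in {reps} replicates; increase reps for a usable reference")
    return float(np.mean(times))
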