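"""Experiment drivers: selective sweeps, mutation--drift equilibrium, and
neutral substitution rates, each over configurable residence-time grids.

Replicate ``r`` of a batch uses the seeded stream ``default_rng(base_seed + r)``
so every experiment is bit-reproducible from its base seed and replicate
count alone.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np

from . import theory
from .model import (ConfigurationError, PopulationState, SeedBankParams,
                    init_population, seed_beneficial, step)
from .stats import JC69SaturationError, jc69_distance, state_diversity

__all__ = [
    "SweepResult",
    "SweepExperimentResult",
    "EquilibriumResult",
    "SubstitutionResult",
    "FixationEstimate",
    "run_sweep_replicate",
    "sweep_experiment",
    "fixation_probability",
    "equilibrium_experiment",
    "stationary_pi",
    "substitution_experiment",
]


# ---------------------------------------------------------------------------
# selective sweeps


@dataclass
class SweepResult:
    """Fate of a single beneficial-allele replicate.

    ``t_quasi_fix_active`` is the first generation boundary at which the
    active pool is 100% beneficial (dormant wild types may persist);
    ``t_fix_total`` the first at which all N+M individuals carry the allele.
    """

    replicate_id: int
    fixed: bool
    t_quasi_fix_active: Optional[int] = None
    t_fix_total: Optional[int] = None
    trajectory: Optional[np.ndarray] = None  # columns: generation, active_freq, dormant_freq


@dataclass
class SweepExperimentResult:
    params: SeedBankParams
    base_seed: int
    results: List[SweepResult]
    n_attempts: int
    n_fixed: int
    n_lost: int
    mean_t_fix_total: Optional[float]
    mean_t_quasi_fix_active: Optional[float]


@dataclass
class FixationEstimate:
    probability: float
    n_fixed: int
    reps: int


def run_sweep_replicate(params: SeedBankParams, rng: np.random.Generator,
                        replicate_id: int = 0, record_every: Optional[int] = 1,
                        max_generations: int = 10_000_000) -> SweepResult:
    """Run one replicate from a single seeded carrier until fixation or loss."""
    state = seed_beneficial(init_population(params), 1)
    n, m = params.N, params.M
    total = n + m
    record = record_every is not None
    traj: List[Tuple[int, float, float]] = []
    if record:
        traj.append((0, 1.0 / n, 0.0 if m else math.nan))
    t_quasi: Optional[int] = None
    t_fix: Optional[int] = None
    fixed = False
    for _ in range(max_generations):
        step(state, params, rng)
        ka = int(state.active.sum())
        kd = int(state.dormant.sum()) if m else 0
        gen = state.generation
        if t_quasi is None and ka == n:
            t_quasi = gen
        done = (ka + kd == 0) or (ka + kd == total)
        if record and (gen % record_every == 0 or done):
            traj.append((gen, ka / n, kd / m if m else math.nan))
        if done:
            fixed = ka + kd == total
            if fixed:
                t_fix = gen
            break
    else:
        raise RuntimeError(f"replicate {replicate_id} not absorbed within {max_generations} generations")
    return SweepResult(
        replicate_id=replicate_id,
        fixed=fixed,
        t_quasi_fix_active=t_quasi,
        t_fix_total=t_fix,
        trajectory=np.asarray(traj, dtype=float) if record else None)


def sweep_experiment(params: SeedBankParams, reps: int, base_seed: int,
                     min_fixations: Optional[int] = None,
                     max_attempts: Optional[int] = None,
                     record_every: Optional[int] = 1,
                     max_generations: int = 10_000_000) -> SweepExperimentResult:
    """Beneficial-allele sweep over many replicates.

    Runs ``reps`` replicates, or -- when ``min_fixations`` is given -- keeps
    attempting (up to ``max_attempts``, default 200 per requested fixation)
    until that many replicates fixed, since the reported fixation times are
    conditioned on success.  Lost replicates are kept in ``results`` but
    excluded from the conditional means.
    """
    if params.mode != "biallelic":
        raise ConfigurationError("sweeps are defined in biallelic mode")
    if params.s <= 0:
        raise ConfigurationError("sweep_experiment requires s > 0 (use the drift "
                                 "experiments for neutral dynamics)")
    if min_fixations is not None and max_attempts is None:
        max_attempts = 200 * min_fixations
    results: List[SweepResult] = []
    n_fixed = 0
    attempt = 0
    while True:
        if min_fixations is None:
            if attempt >= reps:
                break
        else:
            if n_fixed >= min_fixations or attempt >= max_attempts:
                break
        rng = np.random.default_rng(base_seed + attempt)
        res = run_sweep_replicate(params, rng, replicate_id=attempt,
                                  record_every=record_every,
                                  max_generations=max_generations)
        results.append(res)
        n_fixed += res.fixed
        attempt += 1
    if min_fixations is not None and n_fixed < min_fixations:
        raise RuntimeError(
            f"only {n_fixed}/{min_fixations} fixations in {attempt} attempts")
    fixed_results = [r for r in results if r.fixed]
    mean_t_fix = float(np.mean([r.t_fix_total for r in fixed_results])) if fixed_results else None
    quasi = [r.t_quasi_fix_active for r in fixed_results if r.t_quasi_fix_active is not None]
    mean_t_quasi = float(np.mean(quasi)) if quasi else None
    return SweepExperimentResult(
        params=params, base_seed=base_seed, results=results,
        n_attempts=attempt, n_fixed=n_fixed, n_lost=attempt - n_fixed,
        mean_t_fix_total=mean_t_fix, mean_t_quasi_fix_active=mean_t_quasi)


def fixation_probability(params: SeedBankParams, reps: int, base_seed: int,
                         max_generations: int = 10_000_000) -> FixationEstimate:
    """Monte-Carlo fixation probability of a single (possibly neutral) mutant."""
    n_fixed = 0
    for r in range(reps):
        rng = np.random.default_rng(base_seed + r)
        res = run_sweep_replicate(params, rng, replicate_id=r, record_every=None,
                                  max_generations=max_generations)
        n_fixed += res.fixed
    return FixationEstimate(probability=n_fixed / reps, n_fixed=n_fixed, reps=reps)


# ---------------------------------------------------------------------------
# mutation--drift equilibrium


@dataclass
class EquilibriumResult:
    """Replicate-mean diversity trajectory and detected time to equilibrium.

    ``t_equilibrium`` is the first recorded generation from which the
    replicate-mean active-pool pi stays within ``tolerance`` of ``target_pi``
    for a full confirmation window; ``None`` if never satisfied within the
    horizon."""

    pi_series: np.ndarray  # columns: generation, replicate-mean pi
    t_equilibrium: Optional[int]
    target_pi: float
    tolerance: float
    window: int
    replicate_pi: Optional[np.ndarray] = None  # (reps, n_recorded)


def _run_pi_series(params: SeedBankParams, reps: int, horizon: int, base_seed: int,
                   record_every: int) -> Tuple[np.ndarray, np.ndarray]:
    gens = np.arange(record_every, horizon + 1, record_every)
    mat = np.empty((reps, gens.shape[0]))
    for r in range(reps):
        rng = np.random.default_rng(base_seed + r)
        state = init_population(params)
        j = 0
        for _ in range(horizon):
            step(state, params, rng)
            if j < gens.shape[0] and state.generation == gens[j]:
                mat[r, j] = state_diversity(state, pool="active").pi
                j += 1
    return gens, mat


def equilibrium_experiment(params: SeedBankParams, reps: int, horizon: int,
                           base_seed: int, record_every: Optional[int] = None,
                           tolerance: float = 0.10, window: Optional[int] = None,
                           target_pi: Optional[float] = None) -> EquilibriumResult:
    """Neutral drift run detecting the time to mutation--drift equilibrium.

    The population starts monomorphic; at each recording point the mean
    active-pool pi across replicates is computed, and equilibrium is declared
    at the first recorded generation from which the mean stays within
    ``tolerance`` (relative) of the expected equilibrium diversity for a full
    confirmation ``window`` (default N generations).  The default target is
    the engine's closed form ``theta * (1 + M/N)`` with ``theta = N * mu``
    (Moran pairwise-coalescent scaling).
    """
    if params.mode != "infinite_sites":
        raise ConfigurationError("equilibrium_experiment runs in infinite_sites mode")
    if params.s != 0 or params.mu_d != 0:
        raise ConfigurationError("equilibrium_experiment is neutral: s = mu_d = 0")
    if record_every is None:
        record_every = max(1, horizon // 1000)
    if window is None:
        window = params.N
    if target_pi is None:
        target_pi = theory.expected_pi(
            theory.coalescent_theta(params.N, params.mu, "moran"), params.M, params.N)
    gens, mat = _run_pi_series(params, reps, horizon, base_seed, record_every)
    mean = mat.mean(axis=0)
    t_eq: Optional[int] = None
    if target_pi > 0:
        in_band = np.abs(mean - target_pi) <= tolerance * target_pi
        for i, g in enumerate(gens):
            if g + window > gens[-1]:
                break
            j = int(np.searchsorted(gens, g + window, side="right"))
            if in_band[i:j].all():
                t_eq = int(g)
                break
    return EquilibriumResult(
        pi_series=np.column_stack([gens, mean]),
        t_equilibrium=t_eq, target_pi=float(target_pi),
        tolerance=tolerance, window=window, replicate_pi=mat)


def stationary_pi(params: SeedBankParams, reps: int, horizon: int, burn_in: int,
                  base_seed: int, record_every: Optional[int] = None
                  ) -> Tuple[float, float, int]:
    """Long-run mean active-pool pi (mean, between-replicate SE, reps).

    Each replicate's recorded pi values after ``burn_in`` are time-averaged;
    the returned mean and standard error are across replicates.
    """
    if record_every is None:
        record_every = max(1, horizon // 100)
    gens, mat = _run_pi_series(params, reps, horizon, base_seed, record_every)
    keep = gens >= burn_in
    if not keep.any():
        raise ConfigurationError("burn_in leaves no recorded samples")
    per_rep = mat[:, keep].mean(axis=1)
    return float(per_rep.mean()), float(per_rep.std(ddof=1) / math.sqrt(reps)), reps


# ---------------------------------------------------------------------------
# neutral substitution rates


@dataclass
class SubstitutionResult:
    """Mean JC69 distance to the ancestor for one residence-time grid point."""

    mean_residence: float
    mean_jc69_distance: float
    se: float
    n_sampled: int
    n_saturated: int
    M: int
    c: int


def substitution_experiment(params: SeedBankParams, residences: Sequence[float],
                            reps: int, horizon: int, base_seed: int,
                            sample_size: int = 30,
                            vary: str = "bank_size") -> List[SubstitutionResult]:
    """Neutral molecular-clock run across a mean-residence grid.

    After ``horizon`` generations each replicate samples ``sample_size``
    individuals uniformly from the entire population (active and dormant
    jointly) and averages their JC69-corrected distances to the ancestral
    sequence.  The residence grid is realised by scaling the bank size
    ``M = residence * c`` at fixed exchange count (default), which varies the
    dormant fraction and hence the per-lineage reproduction rate; a residence
    of 0 denotes the bank-free control.  ``vary='exchange'`` instead keeps
    ``M`` fixed and sets ``c = M / residence`` (note the mean distance is
    insensitive to ``c`` at fixed pool sizes, so this grid isolates
    higher-moment effects only).  Saturated comparisons (p >= 3/4) are
    counted and excluded from the mean, never averaged silently.
    """
    if params.mode != "sequence":
        raise ConfigurationError("substitution_experiment runs in sequence mode")
    if params.s != 0:
        raise ConfigurationError("substitution_experiment is neutral: s = 0")
    out: List[SubstitutionResult] = []
    for gi, res in enumerate(residences):
        if res == 0:
            p = replace(params, M=0, c=0)
        elif vary == "bank_size":
            m = int(round(res * params.c))
            p = replace(params, M=m, c=params.c if m else 0)
        elif vary == "exchange":
            if params.M == 0:
                raise ConfigurationError("vary='exchange' requires a fixed M > 0")
            p = replace(params, c=max(1, int(round(params.M / res))))
        else:
            raise ConfigurationError(f"unknown grid mode {vary!r}")
        rep_means = []
        n_sampled = 0
        n_saturated = 0
        for r in range(reps):
            rng = np.random.default_rng(base_seed + 1000 * gi + r)
            state = init_population(p, rng)
            for _ in range(horizon):
                step(state, p, rng)
            pool = np.concatenate([state.active, state.dormant]) if p.M else state.active
            k = min(sample_size, pool.shape[0])
            idx = rng.choice(pool.shape[0], size=k, replace=False)
            dists = []
            for i in idx:
                d = jc69_distance(pool[i], state.ancestral, on_saturation="inf")
                if math.isinf(d):
                    n_saturated += 1
                else:
                    dists.append(d)
            n_sampled += k
            if dists:
                rep_means.append(float(np.mean(dists)))
        mean = float(np.mean(rep_means))
        se = float(np.std(rep_means, ddof=1) / math.sqrt(len(rep_means))) if len(rep_means) > 1 else 0.0
        out.append(SubstitutionResult(
            mean_residence=float(theory.mean_residence_time(p.M, p.c)) if p.M else 0.0,
            mean_jc69_distance=mean, se=se, n_sampled=n_sampled,
            n_saturated=n_saturated, M=p.M, c=p.c))
    return out
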