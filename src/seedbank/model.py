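"""Domain types and the per-generation stochastic engine.

The population consists of ``N`` active individuals that reproduce under Moran
birth--death dynamics and ``M`` dormant individuals that neither reproduce nor
die.  One generation is ``N`` sequential birth--death events followed by one
exchange step in which ``c`` dormant individuals resuscitate and ``c`` active
individuals enter the seed bank (a paired swap, so pool sizes are exactly
conserved).  A dormant individual therefore exits the bank each generation with
probability ``c/M``; residence times are geometric with mean ``M/c``.

Three genotype encodings are supported:

``biallelic``
    one beneficial allele segregating against the wild type; genotypes are
    0/1 flags and the beneficial allele has relative fitness ``1+s`` whenever
    its carrier is active.
``infinite_sites``
    every mutation is new; genotypes are ids into a shared
    :class:`HaplotypeStore` forest, and the id of a haplotype doubles as the
    globally unique identifier of the mutation that created it.
``sequence``
    explicit length-``L`` nucleotide sequences over {A,C,G,T}, encoded 0..3;
    each site of a newborn substitutes to one of the three other bases with
    probability ``mu``.

Mutation happens at birth (active reproduction); dormant individuals acquire
mutations only through the optional per-generation clock ``mu_d`` (default 0,
the assumption under which the closed-form diversity expectation holds).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Optional, Union

import numpy as np

from . import _kernels

__all__ = [
    "ConfigurationError",
    "SeedBankParams",
    "HaplotypeStore",
    "PopulationState",
    "BASES",
    "init_population",
    "seed_beneficial",
    "moran_generation",
    "exchange_step",
    "mutate_offspring",
    "step",
    "run",
    "residence_spells",
    "sample_distinct",
]

BASES = "ACGT"

MODES = ("biallelic", "infinite_sites", "sequence")


class ConfigurationError(ValueError):
    """Raised when parameters or state violate a model invariant."""


@dataclass(frozen=True)
class SeedBankParams:
    """All demographic, mutational and selective parameters of one run.

    Parameters
    ----------
    N : int
        Number of active (reproducing) individuals.
    M : int
        Number of dormant individuals (the seed bank); 0 disables the bank.
    c : int
        Individuals exiting (and entering) the seed bank per generation;
        must satisfy ``0 <= c <= min(N, M)``.
    mu : float
        Mutation probability per birth: per genome in ``infinite_sites``
        mode, per site in ``sequence`` mode. Unused in ``biallelic`` mode.
    mu_d : float
        Optional per-generation mutation probability for dormant genotypes
        (same per-genome/per-site meaning as ``mu``). Default 0: dormant
        individuals do not acquire mutations.
    s : float
        Selective advantage of the beneficial allele (relative fitness
        ``1+s``); only meaningful in ``biallelic`` mode.
    L : int, optional
        Sequence length; required in ``sequence`` mode.
    mode : {"biallelic", "infinite_sites", "sequence"}
    dormant_death : float
        Optional per-generation death-with-replacement probability for
        dormant individuals (a dying dormant is replaced by the mutated
        offspring of a uniformly chosen active parent). Default 0, the
        limiting case under which the analytic expectations are derived.
    """

    N: int
    M: int = 0
    c: int = 0
    mu: float = 0.0
    mu_d: float = 0.0
    s: float = 0.0
    L: Optional[int] = None
    mode: str = "biallelic"
    dormant_death: float = 0.0

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ConfigurationError(f"unknown mode {self.mode!r}; expected one of {MODES}")
        if self.N < 1:
            raise ConfigurationError("N must be a positive integer")
        if self.M < 0:
            raise ConfigurationError("M must be non-negative")
        if not (0 <= self.c <= min(self.N, self.M) if self.M else self.c == 0):
            raise ConfigurationError(
                f"require 0 <= c <= min(N, M) (and c=0 when M=0); got c={self.c}, N={self.N}, M={self.M}")
        for name in ("mu", "mu_d", "dormant_death"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigurationError(f"{name} must lie in [0, 1]; got {v}")
        if self.s < 0:
            raise ConfigurationError(f"s must be >= 0; got {self.s}")
        if self.s > 0 and self.mode != "biallelic":
            raise ConfigurationError("selection (s > 0) is only defined in biallelic mode")
        if self.mode == "sequence":
            if self.L is None or self.L < 1:
                raise ConfigurationError("sequence mode requires a positive sequence length L")


class HaplotypeStore:
    """Forest of haplotypes for the infinite-sites model.

    Haplotype 0 is the mutation-free ancestor. Every other haplotype is its
    parent haplotype plus exactly one new mutation, and the haplotype id is
    the globally unique identifier of that mutation.
    """

    def __init__(self, capacity: int = 1024) -> None:
        capacity = max(capacity, 16)
        self.parent = np.full(capacity, -1, dtype=np.int64)
        self.depth = np.zeros(capacity, dtype=np.int64)
        self.next_id = 1  # id 0 is the ancestral haplotype

    def ensure_capacity(self, extra: int) -> None:
        need = self.next_id + extra
        if need > self.parent.shape[0]:
            new_cap = max(need, 2 * self.parent.shape[0])
            self.parent = np.concatenate(
                [self.parent, np.full(new_cap - self.parent.shape[0], -1, dtype=np.int64)])
            self.depth = np.concatenate(
                [self.depth, np.zeros(new_cap - self.depth.shape[0], dtype=np.int64)])

    def new_child(self, parent_id: int) -> int:
        """Allocate a haplotype carrying one fresh mutation on top of ``parent_id``."""
        self.ensure_capacity(1)
        hid = self.next_id
        self.parent[hid] = parent_id
        self.depth[hid] = self.depth[parent_id] + 1
        self.next_id += 1
        return hid

    def mutation_set(self, hap_id: int) -> frozenset:
        """The set of mutation identifiers carried by a haplotype."""
        out = []
        h = int(hap_id)
        while h > 0:
            out.append(h)
            h = int(self.parent[h])
        return frozenset(out)


@dataclass
class PopulationState:
    """Genotypes of the active and dormant pools plus a generation counter."""

    mode: str
    active: np.ndarray
    dormant: np.ndarray
    generation: int = 0
    store: Optional[HaplotypeStore] = None
    ancestral: Optional[np.ndarray] = None  # sequence mode reference sequence

    @property
    def N(self) -> int:
        return int(self.active.shape[0])

    @property
    def M(self) -> int:
        return int(self.dormant.shape[0])

    def check(self, params: SeedBankParams) -> None:
        if self.mode != params.mode:
            raise ConfigurationError(
                f"state mode {self.mode!r} does not match params mode {params.mode!r}")
        if self.N != params.N or self.M != params.M:
            raise ConfigurationError(
                f"state pools ({self.N}, {self.M}) do not match params (N={params.N}, M={params.M})")


def init_population(params: SeedBankParams,
                    rng: Optional[np.random.Generator] = None) -> PopulationState:
    """Monomorphic starting population.

    In sequence mode the shared ancestral sequence is drawn uniformly at
    random from ``rng`` (or all-A when no generator is given).
    """
    if params.mode == "biallelic":
        return PopulationState(
            mode=params.mode,
            active=np.zeros(params.N, dtype=np.uint8),
            dormant=np.zeros(params.M, dtype=np.uint8))
    if params.mode == "infinite_sites":
        return PopulationState(
            mode=params.mode,
            active=np.zeros(params.N, dtype=np.int64),
            dormant=np.zeros(params.M, dtype=np.int64),
            store=HaplotypeStore())
    if rng is None:
        anc = np.zeros(params.L, dtype=np.uint8)
    else:
        anc = rng.integers(0, 4, size=params.L).astype(np.uint8)
    return PopulationState(
        mode=params.mode,
        active=np.tile(anc, (params.N, 1)),
        dormant=np.tile(anc, (params.M, 1)) if params.M else np.empty((0, params.L), dtype=np.uint8),
        ancestral=anc)


def seed_beneficial(state: PopulationState, n_carriers: int = 1) -> PopulationState:
    """Seed ``n_carriers`` beneficial mutants into the active pool (biallelic)."""
    if state.mode != "biallelic":
        raise ConfigurationError("beneficial alleles are defined in biallelic mode only")
    if not (0 <= n_carriers <= state.N):
        raise ConfigurationError("number of carriers must lie in [0, N]")
    state.active[:] = 0
    state.active[:n_carriers] = 1
    state.dormant[:] = 0
    return state


def sample_distinct(rng: np.random.Generator, n: int, c: int) -> np.ndarray:
    """``c`` distinct indices uniform over ``range(n)``.

    Rejection sampling when the birthday-collision probability is small
    (roughly c^2/2n), a permutation otherwise; both are exact.
    """
    if c > n:
        raise ConfigurationError(f"cannot draw {c} distinct indices from {n}")
    if 2 * c * c >= n:
        return rng.permutation(n)[:c]
    while True:
        idx = rng.integers(0, n, size=c)
        if np.unique(idx).shape[0] == c:
            return idx


def _sequence_mutation_csr(rng: np.random.Generator, n_events: int, L: int, mu: float):
    """Pre-draw per-event substitution sites/offsets as a CSR triple.

    Site counts are Binomial(L, mu) per event; sites within an event are a
    uniform subset without replacement, so each site independently mutates
    with probability ``mu`` exactly.
    """
    counts = rng.binomial(L, mu, size=n_events) if mu > 0 else np.zeros(n_events, dtype=np.int64)
    ptr = np.zeros(n_events + 1, dtype=np.int64)
    np.cumsum(counts, out=ptr[1:])
    total = int(ptr[-1])
    sites = np.empty(total, dtype=np.int64)
    offsets = np.empty(total, dtype=np.uint8)
    if total:
        for e in np.nonzero(counts)[0]:
            lo, hi = ptr[e], ptr[e + 1]
            sites[lo:hi] = rng.choice(L, size=hi - lo, replace=False)
        offsets[:] = rng.integers(0, 3, size=total, dtype=np.uint8)
    return ptr, sites, offsets


def moran_generation(state: PopulationState, params: SeedBankParams,
                     rng: np.random.Generator) -> PopulationState:
    """Apply exactly ``N`` birth--death events (one generation of reproduction).

    Each event picks a parent from the active pool with probability
    proportional to fitness, copies it, mutates the copy at birth, and writes
    it over a uniformly chosen active individual (which may be the parent
    itself). Dormant genotypes are untouched except for the optional ``mu_d``
    mutation clock. The state is updated in place and returned; the
    generation counter increases by one.
    """
    state.check(params)
    n = params.N
    pv = rng.integers(0, n, size=2 * n)
    parents, victims = pv[:n], pv[n:]

    if params.mode == "biallelic":
        u_parent = rng.random(n)
        _kernels.biallelic_generation(state.active, params.s, u_parent, victims)
    elif params.mode == "infinite_sites":
        flags = (rng.random(n) < params.mu) if params.mu > 0 else np.zeros(n, dtype=bool)
        store = state.store
        store.ensure_capacity(n)
        store.next_id = _kernels.infinite_sites_generation(
            state.active, parents, victims, flags, store.next_id,
            store.parent, store.depth)
    else:
        ptr, sites, offsets = _sequence_mutation_csr(rng, n, params.L, params.mu)
        _kernels.sequence_generation(state.active, parents, victims, ptr, sites, offsets)

    if params.mu_d > 0 and params.M > 0:
        _dormant_mutation_clock(state, params, rng)

    state.generation += 1
    return state


def _dormant_mutation_clock(state: PopulationState, params: SeedBankParams,
                            rng: np.random.Generator) -> None:
    if params.mode == "infinite_sites":
        flags = np.nonzero(rng.random(params.M) < params.mu_d)[0]
        for i in flags:
            state.dormant[i] = state.store.new_child(int(state.dormant[i]))
    elif params.mode == "sequence":
        ptr, sites, offsets = _sequence_mutation_csr(rng, params.M, params.L, params.mu_d)
        for i in np.nonzero(np.diff(ptr))[0]:
            for j in range(ptr[i], ptr[i + 1]):
                site = sites[j]
                state.dormant[i, site] = (state.dormant[i, site] + 1 + offsets[j]) % 4
    # biallelic: no mutation after the initial beneficial mutant is seeded


def exchange_step(state: PopulationState, params: SeedBankParams,
                  rng: np.random.Generator, return_indices: bool = False):
    """Swap ``c`` uniformly chosen dormant individuals with ``c`` active ones.

    Pool sizes are exactly conserved. With ``return_indices=True`` the pair
    ``(active_idx, dormant_idx)`` of swapped positions is returned alongside
    the state (used e.g. for residence-time instrumentation).
    """
    state.check(params)
    c = params.c
    if c == 0:
        return (state, (np.empty(0, dtype=np.int64),) * 2) if return_indices else state
    idx_a = sample_distinct(rng, params.N, c)
    idx_d = sample_distinct(rng, params.M, c)
    moved_out = state.dormant[idx_d].copy()
    state.dormant[idx_d] = state.active[idx_a]
    state.active[idx_a] = moved_out
    if return_indices:
        return state, (idx_a, idx_d)
    return state


def _dormant_death_step(state: PopulationState, params: SeedBankParams,
                        rng: np.random.Generator) -> None:
    """Optional dormant mortality: dying dormants are replaced by newborn
    offspring of uniformly chosen active parents (pool sizes conserved)."""
    dying = np.nonzero(rng.random(params.M) < params.dormant_death)[0]
    for i in dying:
        parent = int(rng.integers(0, params.N))
        if params.mode == "sequence":
            child = state.active[parent].copy()
        else:
            child = state.active[parent]
        state.dormant[i] = mutate_offspring(child, params, rng, store=state.store)


def step(state: PopulationState, params: SeedBankParams,
         rng: np.random.Generator) -> PopulationState:
    """One full generation: reproduction, then exchange.

    A resuscitated individual therefore cannot reproduce in the generation it
    wakes; frequencies recorded at generation boundaries are post-exchange.
    """
    moran_generation(state, params, rng)
    exchange_step(state, params, rng)
    if params.dormant_death > 0 and params.M > 0:
        _dormant_death_step(state, params, rng)
    return state


def run(state: PopulationState, params: SeedBankParams, rng: np.random.Generator,
        n_generations: int,
        callback: Optional[Callable[[PopulationState], None]] = None) -> PopulationState:
    """Advance ``n_generations`` full generations, invoking ``callback`` after each."""
    for _ in range(n_generations):
        step(state, params, rng)
        if callback is not None:
            callback(state)
    return state


def mutate_offspring(genotype, params: SeedBankParams, rng: np.random.Generator,
                     store: Optional[HaplotypeStore] = None):
    """Mutate a single newborn genotype.

    biallelic: returned unchanged (the beneficial mutant is seeded once, not
    recurrent). infinite_sites: ``genotype`` is a haplotype id; with
    probability ``mu`` a fresh haplotype carrying one new, globally unique
    mutation is allocated in ``store``. sequence: each site substitutes to one
    of the three other bases independently with probability ``mu``; accepts a
    0..3 uint8 array or an ACGT string and returns the same type.
    """
    if params.mode == "biallelic":
        return genotype
    if params.mode == "infinite_sites":
        if store is None:
            raise ConfigurationError("infinite_sites mutation requires a HaplotypeStore")
        if params.mu > 0 and rng.random() < params.mu:
            return store.new_child(int(genotype))
        return int(genotype)
    as_str = isinstance(genotype, str)
    seq = encode_sequence(genotype) if as_str else np.array(genotype, dtype=np.uint8, copy=True)
    if params.mu > 0:
        hit = np.nonzero(rng.random(seq.shape[0]) < params.mu)[0]
        if hit.shape[0]:
            seq[hit] = (seq[hit] + 1 + rng.integers(0, 3, size=hit.shape[0], dtype=np.uint8)) % 4
    return decode_sequence(seq) if as_str else seq


def encode_sequence(seq: str) -> np.ndarray:
    """ACGT string -> 0..3 uint8 array."""
    lut = np.full(256, 255, dtype=np.uint8)
    for i, b in enumerate(BASES):
        lut[ord(b)] = i
        lut[ord(b.lower())] = i
    arr = lut[np.frombuffer(seq.encode(), dtype=np.uint8)]
    if (arr == 255).any():
        raise ConfigurationError("sequence contains characters outside ACGT")
    return arr


def decode_sequence(arr: np.ndarray) -> str:
    """0..3 array -> ACGT string."""
    return "".join(BASES[b] for b in np.asarray(arr, dtype=np.uint8))


def residence_spells(params: SeedBankParams, n_spells: int,
                     rng: np.random.Generator,
                     max_generations: int = 100_000_000) -> np.ndarray:
    """Completed dormancy spell lengths for a cohort of seed-bank entrants.

    Runs the engine's exchange step on a population, tracks the first
    ``n_spells`` individuals that *enter* the bank during the run, and keeps
    simulating until every tracked entrant has exited again, so no spell is
    truncated by the observation window.  Under the model the returned spells
    are i.i.d. geometric with success probability ``c/M`` (mean ``M/c``).
    Occupants present at generation 0 never entered and are not tracked.
    """
    if params.M == 0 or params.c == 0:
        raise ConfigurationError("residence spells require M > 0 and c > 0")
    state = init_population(replace(params, mode="biallelic", L=None, s=0.0))
    entry = np.full(params.M, -1, dtype=np.int64)  # -1: untracked occupant
    n_entered = 0
    open_spells = 0
    spells: list = []
    for t in range(1, max_generations + 1):
        _, (_, idx_d) = exchange_step(state, params, rng, return_indices=True)
        exited = entry[idx_d]
        tracked = exited >= 0
        spells.extend((t - exited[tracked]).tolist())
        open_spells -= int(tracked.sum())
        if n_entered < n_spells:
            take = min(params.c, n_spells - n_entered)
            entry[idx_d[:take]] = t
            entry[idx_d[take:]] = -1
            n_entered += take
            open_spells += take
        else:
            entry[idx_d] = -1
            if open_spells == 0:
                break
    else:
        raise RuntimeError("cohort did not fully exit within max_generations")
    return np.asarray(spells, dtype=np.int64)
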