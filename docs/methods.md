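# Methods

## Model definition

The population is haploid with a fixed number `N` of active individuals and
`M` dormant ones. Time advances in generations; one generation is

1. exactly `N` sequential Moran birth–death events among the active pool:
   each event draws a parent with probability proportional to fitness
   (relative fitness `1+s` for beneficial-allele carriers, all 1 under
   neutrality), copies it, applies mutation to the copy at birth, and
   overwrites a uniformly drawn active individual (the parent may replace
   itself); then
2. one exchange step: `c` dormant and `c` active individuals, each chosen
   uniformly without replacement, swap pools.

Events within a generation are sequential — an offspring born at event `e`
can parent event `e+1`. Exchange follows reproduction, so a resuscitated
individual cannot reproduce in the generation it wakes, and all recorded
frequencies are post-exchange generation-boundary values. Dormant
individuals neither reproduce nor die and acquire no mutations by default;
an optional per-generation dormancy mutation clock (`mu_d`) and a dormant
death-with-replacement rate (`dormant_death`) are exposed for sensitivity
runs and default to 0, the limiting case under which the closed forms below
hold.

Because `c` of `M` dormant individuals exit each generation, a dormant
individual's residence time is geometric with success probability `c/M`
(mean `M/c`, support 1, 2, …). This is a construction of the exchange step,
and the test suite verifies it empirically (KS against the geometric law on
a cohort of bank entrants followed until every member has exited, which
avoids the length-biased truncation a fixed observation window would cause).

## Genotype encodings

- `biallelic` — a 0/1 flag; used for sweeps. No recurrent mutation: the
  single beneficial mutant is seeded at generation 0.
- `infinite_sites` — every mutation is new. Genotypes are ids into a shared
  haplotype forest; a mutation allocates a child haplotype whose id doubles
  as the globally unique mutation identifier. Diversity statistics walk the
  forest and count mutation frequencies, so π over a pool costs
  O(distinct haplotypes · depth) instead of O(n²) pairwise set operations.
  `mu` is a per-genome probability per birth.
- `sequence` — explicit length-`L` arrays over {A,C,G,T}; each site of a
  newborn substitutes to one of the three other bases with per-site
  probability `mu`. Site draws use exact Binomial(L, mu) counts plus a
  uniform without-replacement site subset, so sites mutate independently
  with probability `mu` exactly.

## Diversity expectations and the θ convention

For two active lineages followed backward, the state chain is
active↔dormant with per-generation rates `c/N` (entering the bank) and
`c/M` (leaving it); mutations accrue only on active segments and
coalescence (rate `2/N` per generation) requires both lineages active.
Solving the first-step equations gives the expected total active lineage
time to coalescence as exactly `N(1 + M/N)` — independent of `c` — and
hence

    E[π] = θ (1 + M/N),

with `θ = 2·Ne·μ`. A Moran engine with `N` events per generation and
mutation at birth has pairwise-coalescent effective size `Ne = N/2` (each
lineage is renewed once per generation while pairs coalesce at rate `2/N`),
so the engine's θ is `N·μ`; the familiar Wright–Fisher convention is
`2N·μ`. `coalescent_theta(N, mu, update=...)` makes the convention explicit,
and all simulation checks in this package compare against the Moran value.
The same derivation shows the mean pair-coalescence time is
`(N/2)(1+M/N)²` generations, again independent of `c` — a useful fact twice
below.

The factor `(1+M/N)` is exact at the diffusion level for any exchange count;
discrete-generation corrections are O(1/N, c/N). At `N=100, M=1000, c=10,
μ=5·10⁻⁴` the long-run active-pool π measured over 200 replicates falls
within a few percent of the predicted 0.55.

## Equilibrium detection

The paper-level notion "time to mutation–drift equilibrium" needs an
operational rule; ours: record replicate-mean active-pool π on a fixed
cadence (default `horizon/1000` generations) and declare equilibrium at the
first recorded generation from which the mean stays within a relative
tolerance (default ±10%) of the target `θ(1+M/N)` for a full confirmation
window (default `N` generations). Both knobs are config-exposed. With a
target of exactly 0 (no mutation) detection is disabled rather than
trivially satisfied. The detected time is noisy at small replicate counts —
π has coefficient of variation near 1 at these θ values — which is why the
monotonicity check across a residence grid uses a rank correlation rather
than strict pointwise ordering: the two weak-regime grid points share the
same mean coalescence time (see above) and differ only through slow
relaxation modes, while the strong-regime point separates cleanly.

Burn-in and horizon for the stationary-diversity measurements come from the
relaxation scale `(N/2)(1+M/N)²` ≈ 6·10³ generations at the standard grid:
burn-in 15,000 ≳ 2.5τ, horizon 25,000, with per-replicate time averaging
over the tail.

## Sweeps

One beneficial carrier is seeded into the active pool. Two times are
recorded per replicate: `t_quasi_fix_active`, the first generation boundary
at which the active pool is 100% beneficial (dormant wild types may remain —
the allele can still dip below 1 afterwards as they resuscitate), and
`t_fix_total`, the first generation all `N+M` individuals carry the allele
(absorbing). Reported means condition on fixation; lost replicates are
retained in the output but excluded from means, and when a fixed number of
conditioned fixations is requested, attempts continue up to a cap. The
bank-free reference time is a seeded Monte-Carlo estimate from the same
engine at `M=0` (the external closed form it approximates is not
transcribed here); for `N=2` the engine's conditional fixation time has the
exact value 4/3 generations, which the tests use as an oracle.

## Substitution experiment

After a fixed horizon, individuals are sampled uniformly from the *entire*
population (active + dormant, default 30 per replicate) and their
JC69-corrected distances to the ancestral sequence are averaged; saturated
comparisons (`p ≥ 3/4`) are counted and reported, never silently averaged.

The residence grid is realised by scaling the bank size (`M = residence·c`
at fixed `c`), not by scaling the exchange count. The reason is structural:
at fixed `N` and `M`, a uniformly sampled individual's backward lineage is
active a fraction `N/(N+M)` of the time *regardless of c* (the stationary
occupancy of the two-state chain), so the expected number of births — and
hence substitutions — on the lineage does not depend on `c`. Varying the
dormant excess is what changes the population's realised reproduction rate
and produces the decline of substitution rate with mean residence time. A
`vary="exchange"` mode is still available; it isolates higher-moment
effects only. The bank-free control recovers the neutral clock `μ·t`
(each active lineage experiences one birth per generation in expectation).

## Numerics and reproducibility

- Per-generation inner loops are numba-jitted kernels consuming pre-drawn
  arrays of uniforms/indices; pure-Python reference implementations of the
  same loops live alongside and the tests assert bit-identical agreement.
  If numba is unavailable the reference path is used transparently.
- All stochastic drawing happens through `numpy.random.Generator`.
  Replicate `r` of a batch uses `default_rng(base_seed + r)`; batch
  components in the acceptance script use disjoint seed blocks. Identical
  seeds give bit-identical trajectories, which the tests verify.
- Uniform without-replacement index draws use rejection sampling when the
  birthday bound `2c² < n` holds and a partial permutation otherwise; both
  are exact.
- KS tests against the geometric law use the continuous-null KS statistic,
  which is conservative for discrete data (p-values biased upward); this is
  acceptable for an α=0.01 rejection check and a binned chi-square gives the
  same verdict.
- The haplotype forest is never garbage-collected within a run; at the
  default mutation rates the store stays small (fixed mutations are rare on
  the simulated horizons).

## What the generator does and does not emulate

Defaults follow the study conditions of the phenomena being reproduced:
sweeps default to `N=1000, M=10000, s=0.01` (the figure-scale
parameterisation) with desk-scale runs at `N=100, M=1000, s=0.05`;
substitution runs use `L=1000, μ=10⁻⁵`/site with a 10,000-generation
default horizon (2,000 at desk scale); equilibrium grids straddle the
strong-bank threshold `M/c = N`. Constant pool sizes, a single panmictic
deme, no recombination or HGT, no dormant mortality, and environment-free
fitness are deliberate idealisations: passing tests show the engine
reproduces the analytic seed-bank laws under those assumptions, not that
real seed banks — with fluctuating sizes, stress-dependent entry and exit,
and mutagenesis under starvation — obey them quantitatively.

## Known limitations

- Selection is single-locus and biallelic; clonal interference and multiple
  concurrent beneficial mutations are out of scope.
- The equilibrium-time statistic depends on the detection rule; only its
  monotone trend in residence time, not its absolute value, should be
  interpreted.
- Sequence mode stores dense `(N+M)×L` arrays; very long genomes at large
  `M` are better run in infinite-sites mode.
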