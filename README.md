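# seedbank

Forward-time Moran simulation of microbial populations with a **seed bank** —
a pool of dormant, non-reproducing individuals that exchanges members with the
active, reproducing pool. Many microbes (endospore-forming Firmicutes being
the canonical case) persist through bad conditions this way, and the
population-genetic consequences are large: dormancy buffers genetic drift,
inflates standing diversity, reshapes selective sweeps, and slows molecular
evolution. This package is for population geneticists and microbial ecologists
who want to simulate those effects and check them against the corresponding
closed-form expectations.

## Model

A haploid population has `N` active individuals and `M` dormant ones. One
generation consists of

1. **Reproduction** — `N` Moran birth–death events among active individuals:
   a parent is chosen with probability proportional to fitness (`1+s` for
   carriers of a beneficial allele, 1 otherwise), its offspring is mutated at
   birth and replaces a uniformly chosen active individual. Dormant
   individuals never reproduce and never die.
2. **Exchange** — `c` dormant individuals resuscitate and `c` active
   individuals enter the bank (a paired swap; pool sizes are exactly
   conserved). Each dormant individual therefore exits with probability
   `c/M` per generation: residence times are geometric with mean `M/c`.

Genotypes can be a biallelic flag (sweeps), sets of unique mutations
(infinite-sites diversity), or explicit ACGT sequences of length `L`
(substitution rates, JC69 distances). Dormant individuals acquire no
mutations unless an optional dormancy mutation clock `mu_d` is switched on.

Key quantities:

- **Equilibrium diversity** — `E[π] = θ(1 + M/N)`, with
  `θ = 2·Ne·μ` the population-scaled mutation rate. For this engine
  (Moran updates, mutation at birth) `Ne = N/2`, so `θ = Nμ`;
  `seedbank.coalescent_theta` returns the right value per convention.
- **Weak vs strong seed bank** — the regime is *strong* when the mean
  residence `M/c` exceeds the number of active individuals `N`; genealogies
  and sweep dynamics change qualitatively past that threshold.
- **JC69 distance** — `−(3/4)·ln(1 − 4p/3)` for raw site divergence `p`,
  the substitutions-per-site estimate used for the molecular-clock runs.

## Worked example

A sweep of a single beneficial mutant (`s = 0.05`) through a population of
100 active and 1,000 dormant individuals, across mean residence times
10–1,000 generations (`python examples/sweep_demo.py`):

```
no-bank reference T_fix          :      84 generations

residence  T_fix (total)  T_quasi (active)
       10           2198              1781
      100           2789              1471
     1000           9583               499
```

Total fixation time grows with residence — the bank must be flushed by
exchange before the allele occupies all `N+M` individuals. But the time for
the *active* pool to first become 100% beneficial (`T_quasi`) **falls back
toward the bank-free reference once residence exceeds `N`**: resuscitation
of wild-type individuals becomes too rare to interfere with selection among
active cells. Other capabilities, one script each, live in `examples/`:
closed-form reports (`theory_report.py`), time to mutation–drift equilibrium
(`equilibrium_demo.py`), declining substitution rates
(`substitution_demo.py`), and the geometric residence law
(`residence_law.py`).

The same machinery is scriptable from the shell:

```bash
seedbank theory -N 1000 -M 10000 -c 1 --mu 5e-6 --generations-per-day 6.67
seedbank simulate sweep -N 100 -M 1000 -c 10 -s 0.05 --reps 20 --seed 1 -o runs/sweep
seedbank simulate substitution --residences 0,1,10,100 --seed 1 -o runs/sub --fasta
seedbank stats runs/sub/final_population.fasta
```

Every run directory receives the resolved config (YAML), TSV tables and a
JSON summary; identical seeds reproduce outputs bit for bit.

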