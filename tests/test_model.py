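"""Engine-level behaviour: parameter validation, pool conservation, mutation
bookkeeping, exchange dynamics, determinism, and kernel-path agreement."""

import numpy as np
import pytest

import seedbank as sb
from seedbank import _kernels
from seedbank.model import sample_distinct


def make_params(mode, **kw):
    defaults = dict(N=10, M=20, c=3, mode=mode)
    if mode == "infinite_sites":
        defaults["mu"] = 0.1
    if mode == "sequence":
        defaults.update(mu=0.01, L=40)
    defaults.update(kw)
    return sb.SeedBankParams(**defaults)


class TestParamsValidation:
    @pytest.mark.parametrize("kw", [
        dict(N=0),
        dict(M=-1),
        dict(c=30),              # c > min(N, M)
        dict(c=11, M=100),       # c > N
        dict(M=0, c=1),          # bank absent but exchange requested
        dict(mu=1.5, mode="infinite_sites"),
        dict(mu_d=-0.1),
        dict(s=-0.01),
        dict(mode="diploid"),
    ])
    def test_invalid_parameters_rejected(self, kw):
        base = dict(N=10, M=20, c=3, mode="biallelic")
        base.update(kw)
        with pytest.raises(sb.ConfigurationError):
            sb.SeedBankParams(**base)

    def test_selection_restricted_to_biallelic(self):
        with pytest.raises(sb.ConfigurationError):
            sb.SeedBankParams(N=10, mode="infinite_sites", s=0.1)

    def test_sequence_mode_requires_length(self):
        with pytest.raises(sb.ConfigurationError):
            sb.SeedBankParams(N=10, mode="sequence")

    def test_state_params_mismatch_detected(self):
        p = make_params("biallelic")
        state = sb.init_population(p)
        other = make_params("biallelic", N=11, M=20, c=3)
        with pytest.raises(sb.ConfigurationError):
            sb.moran_generation(state, other, np.random.default_rng(0))


class TestMoranGeneration:
    def test_single_individual_self_replaces(self):
        """N=1, neutral, no mutation: only the generation counter advances."""
        p = sb.SeedBankParams(N=1, M=0, c=0, mode="infinite_sites", mu=0.0)
        state = sb.init_population(p)
        before = state.active.copy()
        sb.moran_generation(state, p, np.random.default_rng(1))
        assert state.generation == 1
        assert np.array_equal(state.active, before)

    @pytest.mark.parametrize("mode", ["biallelic", "infinite_sites", "sequence"])
    def test_pool_sizes_conserved(self, mode):
        p = make_params(mode, s=0.05 if mode == "biallelic" else 0.0)
        rng = np.random.default_rng(2)
        state = sb.init_population(p, rng)
        if mode == "biallelic":
            sb.seed_beneficial(state, 3)
        for _ in range(25):
            sb.step(state, p, rng)
        assert state.N == p.N and state.M == p.M
        assert state.generation == 25

    def test_determinism_identical_seeds(self):
        """Identical seeds must give bit-identical trajectories."""
        for mode in ("biallelic", "infinite_sites", "sequence"):
            p = make_params(mode)
            states = []
            for _ in range(2):
                rng = np.random.default_rng(42)
                st = sb.init_population(p, rng)
                for _ in range(20):
                    sb.step(st, p, rng)
                states.append(st)
            assert np.array_equal(states[0].active, states[1].active)
            assert np.array_equal(states[0].dormant, states[1].dormant)

    def test_mutation_count_matches_binomial_expectation(self):
        """1e5 births at mu=0.1 yield ~1e4 new mutations (3 sigma band)."""
        p = sb.SeedBankParams(N=1000, M=0, c=0, mu=0.1, mode="infinite_sites")
        rng = np.random.default_rng(3)
        state = sb.init_population(p)
        for _ in range(100):
            sb.moran_generation(state, p, rng)
        n_births = 1000 * 100
        n_mut = state.store.next_id - 1
        sigma = np.sqrt(n_births * 0.1 * 0.9)
        assert abs(n_mut - n_births * 0.1) < 3 * sigma

    def test_neutral_total_frequency_is_martingale(self):
        """With s=0 the expected whole-population allele frequency is constant."""
        p = sb.SeedBankParams(N=30, M=60, c=5, mode="biallelic")
        reps, gens = 1500, 30
        final = np.empty(reps)
        for r in range(reps):
            rng = np.random.default_rng(100 + r)
            state = sb.init_population(p)
            state.active[:15] = 1   # freq 0.5 in both pools
            state.dormant[:30] = 1
            for _ in range(gens):
                sb.step(state, p, rng)
            final[r] = (state.active.sum() + state.dormant.sum()) / 90
        se = final.std(ddof=1) / np.sqrt(reps)
        assert abs(final.mean() - 0.5) < 3 * se


class TestMutateOffspring:
    def test_no_mutation_leaves_genotype_unchanged(self):
        rng = np.random.default_rng(4)
        p_seq = make_params("sequence", mu=0.0)
        seq = "ACGTACGT" * 5
        assert sb.mutate_offspring(seq, p_seq, rng) == seq
        p_inf = make_params("infinite_sites", mu=0.0)
        store = sb.HaplotypeStore()
        assert sb.mutate_offspring(0, p_inf, rng, store=store) == 0

    def test_forced_substitution_always_changes_base(self):
        p = sb.SeedBankParams(N=2, M=0, c=0, mu=1.0, L=1, mode="sequence")
        rng = np.random.default_rng(5)
        for _ in range(50):
            assert sb.mutate_offspring("A", p, rng) != "A"

    def test_mutation_identifiers_globally_unique(self):
        p = make_params("infinite_sites", mu=1.0)
        rng = np.random.default_rng(6)
        store = sb.HaplotypeStore()
        ids = [sb.mutate_offspring(0, p, rng, store=store) for _ in range(200)]
        muts = [m for hid in ids for m in store.mutation_set(hid)]
        assert len(muts) == len(set(muts)) == 200


class TestExchange:
    def test_no_exchange_when_c_zero(self):
        p = sb.SeedBankParams(N=5, M=8, c=0, mode="biallelic")
        state = sb.init_population(p)
        state.dormant[:4] = 1
        before_a, before_d = state.active.copy(), state.dormant.copy()
        sb.exchange_step(state, p, np.random.default_rng(7))
        assert np.array_equal(state.active, before_a)
        assert np.array_equal(state.dormant, before_d)

    def test_full_swap_when_c_equals_pools(self):
        """c = M = N exchanges the two pools completely."""
        p = sb.SeedBankParams(N=6, M=6, c=6, mode="biallelic")
        state = sb.init_population(p)
        state.active[:] = 1
        sb.exchange_step(state, p, np.random.default_rng(8))
        assert state.active.sum() == 0
        assert state.dormant.sum() == 6

    def test_residence_spell_mean_matches_geometric(self):
        """Empirical mean dormancy of M/c = 1000 generations, within 2%."""
        p = sb.SeedBankParams(N=100, M=10000, c=10, mode="biallelic")
        spells = sb.residence_spells(p, 100_000, np.random.default_rng(9))
        assert spells.shape[0] >= 100_000
        assert abs(spells.mean() - 1000.0) / 1000.0 < 0.02

    def test_sample_distinct_is_distinct_and_in_range(self):
        rng = np.random.default_rng(10)
        for n, c in [(10, 10), (1000, 10), (50, 20), (7, 1)]:
            idx = sample_distinct(rng, n, c)
            assert len(np.unique(idx)) == c
            assert idx.min() >= 0 and idx.max() < n


class TestKernelPaths:
    """The jitted kernels must agree bit-for-bit with the pure-Python reference."""

    def test_biallelic_kernel_agreement(self):
        rng = np.random.default_rng(11)
        a1 = (rng.random(50) < 0.3).astype(np.uint8)
        a2 = a1.copy()
        u, v = rng.random(50), rng.integers(0, 50, 50)
        k1 = _kernels.biallelic_generation(a1, 0.05, u, v)
        k2 = _kernels._py_biallelic_generation(a2, 0.05, u, v)
        assert k1 == k2 and np.array_equal(a1, a2)

    def test_infinite_sites_kernel_agreement(self):
        rng = np.random.default_rng(12)
        g1 = rng.integers(0, 3, 40).astype(np.int64)
        g2 = g1.copy()
        parents = rng.integers(0, 40, 40)
        victims = rng.integers(0, 40, 40)
        flags = rng.random(40) < 0.2
        hp1, hd1 = np.full(200, -1, np.int64), np.zeros(200, np.int64)
        hp2, hd2 = hp1.copy(), hd1.copy()
        n1 = _kernels.infinite_sites_generation(g1, parents, victims, flags, 3, hp1, hd1)
        n2 = _kernels._py_infinite_sites_generation(g2, parents, victims, flags, 3, hp2, hd2)
        assert n1 == n2
        assert np.array_equal(g1, g2) and np.array_equal(hp1, hp2) and np.array_equal(hd1, hd2)

    def test_sequence_kernel_agreement(self):
        rng = np.random.default_rng(13)
        s1 = rng.integers(0, 4, (20, 30)).astype(np.uint8)
        s2 = s1.copy()
        parents = rng.integers(0, 20, 20)
        victims = rng.integers(0, 20, 20)
        counts = rng.binomial(3, 0.4, 20)
        ptr = np.zeros(21, np.int64)
        np.cumsum(counts, out=ptr[1:])
        sites = rng.integers(0, 30, int(ptr[-1]))
        offs = rng.integers(0, 3, int(ptr[-1])).astype(np.uint8)
        _kernels.sequence_generation(s1, parents, victims, ptr, sites, offs)
        _kernels._py_sequence_generation(s2, parents, victims, ptr, sites, offs)
        assert np.array_equal(s1, s2)
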