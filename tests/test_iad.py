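"""Amplification-divergence simulator: kernels, engine, and oracles."""

import math

import numpy as np
import pytest

from weaklink import iad

from oracles import agent_run_class_counts

LN2 = math.log(2.0)


def _state_from(counts_by_class, k_max):
    classes, index = iad.genotype_classes(k_max)
    counts = np.zeros(len(classes))
    for g, n in counts_by_class.items():
        counts[index[iad.ArrayGenotype(*g)]] = n
    return iad.PopulationState(counts=counts, k_max=k_max)


class TestMutationRate:
    @pytest.mark.parametrize(
        "mu_gene, k, expected",
        [(1e-6, 10, 1e-5), (1e-7, 10, 1e-6), (1e-6, 1, 1e-6)],
    )
    def test_linear_regime(self, mu_gene, k, expected):
        assert iad.per_array_mutation_rate(mu_gene, k) == pytest.approx(expected, rel=1e-9)

    def test_per_gene_rate_from_nucleotide_rate(self):
        p = iad.SimParams(mu_nt=1e-9, gene_length_nt=1000)
        assert p.mu_gene == pytest.approx(1e-6, rel=1e-12)

    def test_exact_form_for_large_rates(self):
        assert iad.per_array_mutation_rate(0.1, 10) == pytest.approx(1 - 0.9**10, rel=1e-12)


class TestFitness:
    def test_baseline_without_mutants(self):
        fm = iad.FitnessMap(mu0=0.24, s_max=0.75, cost_per_copy=0.0)
        for k in (1, 7, 20):
            assert iad.genotype_fitness((k, 0), fm) == pytest.approx(0.24)

    def test_full_sweep_benefit(self):
        fm = iad.FitnessMap(mu0=0.24, s_max=0.75, cost_per_copy=0.0)
        assert iad.genotype_fitness((7, 7), fm) == pytest.approx(1.75 * 0.24, rel=1e-12)

    def test_hand_computed_single_mutant_copy(self):
        fm = iad.FitnessMap(mu0=0.24, s_max=0.75, cost_per_copy=0.0)
        assert iad.genotype_fitness((7, 1), fm) == pytest.approx(0.2657, abs=1e-4)

    def test_copy_cost_and_clamping(self):
        fm = iad.FitnessMap(mu0=0.24, s_max=0.75, cost_per_copy=0.05)
        assert iad.genotype_fitness((7, 0), fm) == max(0.24 - 0.05 * 6, 0.0)
        heavy = iad.FitnessMap(mu0=0.1, s_max=0.0, cost_per_copy=1.0)
        assert iad.genotype_fitness((20, 0), heavy) == 0.0

    def test_saturating_mode_bounded_by_smax(self):
        fm = iad.FitnessMap(mu0=0.24, s_max=0.75, mode="saturating")
        mus = [iad.genotype_fitness((k, k), fm) for k in range(1, 21)]
        assert all(m < 0.24 * 1.75 for m in mus)
        assert mus == sorted(mus)  # more mutant activity, more benefit


class TestRecombine:
    def test_allele_identity_conserved(self, rng):
        p = iad.SimParams()
        for _ in range(200):
            g = iad.recombine((5, 0), p, rng)
            assert g.j == 0
            g = iad.recombine((5, 5), p, rng)
            assert g.j == g.k

    def test_single_copy_arrays_unchanged(self, rng):
        assert iad.recombine((1, 0), iad.SimParams(), rng) == (1, 0)

    def test_copy_number_bounds(self, rng):
        p = iad.SimParams(k_max=3)
        for _ in range(500):
            g = iad.recombine((3, 1), p, rng)
            assert 1 <= g.k <= 3 and 0 <= g.j <= g.k

    def test_hypergeometric_kernel_distribution(self, rng):
        """(k=2, j=1), no copy-number change: the duplicated pool is 2 mutant
        + 2 wild-type copies, and drawing 2 gives P(j') = {1/6, 4/6, 1/6} by
        enumeration of H(4, 2, 2)."""
        p = iad.SimParams(copy_change_probs=(0.0, 1.0, 0.0))
        draws = np.array([iad.recombine((2, 1), p, rng).j for _ in range(100_000)])
        expected = np.array([1 / 6, 4 / 6, 1 / 6])
        for val, pe in zip((0, 1, 2), expected):
            freq = float(np.mean(draws == val))
            se = math.sqrt(pe * (1 - pe) / draws.size)
            assert abs(freq - pe) < 3 * se

    def test_matrix_matches_enumeration(self):
        p = iad.SimParams(k_max=2, copy_change_probs=(0.0, 1.0, 0.0))
        classes, index = iad.genotype_classes(2)
        col = iad.recombination_matrix(p)[:, index[iad.ArrayGenotype(2, 1)]]
        assert col[index[iad.ArrayGenotype(2, 0)]] == pytest.approx(1 / 6)
        assert col[index[iad.ArrayGenotype(2, 1)]] == pytest.approx(4 / 6)
        assert col[index[iad.ArrayGenotype(2, 2)]] == pytest.approx(1 / 6)

    def test_matrix_columns_stochastic(self):
        p = iad.SimParams(k_max=6)
        mat = iad.recombination_matrix(p)
        assert np.allclose(mat.sum(axis=0), 1.0, atol=1e-12)


class TestStep:
    def test_population_size_conserved(self, rng):
        p = iad.SimParams(n_pop=1000, k_max=8)
        state = iad.founder_state(p, resident=(7, 0), founder=(7, 1), n_founders=10)
        for _ in range(20):
            state = iad.step(state, p, rng)
            assert state.n == 1000

    def test_neutral_martingale(self):
        """With no mutation, no recombination and equal fitness, class
        frequencies are a martingale: the mean over replicates is unchanged."""
        fm = iad.FitnessMap(mu0=0.3, s_max=0.0)
        p = iad.SimParams(mu_nt=0.0, rec_rate=0.0, n_pop=100, k_max=2,
                          fitness_map=fm)
        init = _state_from({(1, 0): 50, (1, 1): 50}, 2)
        classes, index = iad.genotype_classes(2)
        i11 = index[iad.ArrayGenotype(1, 1)]
        freqs = []
        for rep in range(1000):
            rng = iad.replicate_rng(99, rep)
            s = init
            for _ in range(5):
                s = iad.step(s, p, rng)
            freqs.append(s.counts[i11] / s.n)
        se = np.std(freqs, ddof=1) / math.sqrt(len(freqs))
        assert abs(np.mean(freqs) - 0.5) < 3 * se

    def test_deterministic_selection_recursion(self):
        """In the no-resampling limit a two-class system follows the haploid
        selection recursion exactly: logit(p) increases by ln(w1/w0) each
        generation."""
        fm = iad.FitnessMap(mu0=0.3, s_max=0.4)
        p = iad.SimParams(mu_nt=0.0, rec_rate=0.0, n_pop=10_000, k_max=1, fitness_map=fm)
        f0 = iad.genotype_fitness((1, 0), fm)
        f1 = iad.genotype_fitness((1, 1), fm)
        dt = LN2 / f1
        log_w_ratio = (f1 - f0) * dt  # ln(1+s) of the per-generation recursion
        state = _state_from({(1, 0): 9900, (1, 1): 100}, 1)
        classes, index = iad.genotype_classes(1)
        i1 = index[iad.ArrayGenotype(1, 1)]
        for _ in range(10):
            prev = state.counts[i1] / state.n
            state = iad.expected_step(state, p)
            cur = state.counts[i1] / state.n
            inc = math.log(cur / (1 - cur)) - math.log(prev / (1 - prev))
            assert inc == pytest.approx(log_w_ratio, abs=1e-12)

    def test_class_engine_matches_agent_oracle(self):
        """Distributional equivalence on a small instance: 100 cells, four
        occupied classes, 3 generations, compared class-by-class over 10^4
        replicates of each engine."""
        fm = iad.FitnessMap(mu0=0.3, s_max=0.5)
        p = iad.SimParams(mu_nt=5e-3, gene_length_nt=1, rec_rate=0.2, n_pop=100,
                          k_max=3, fitness_map=fm)
        init_dict = {(2, 0): 40, (2, 1): 30, (3, 1): 20, (3, 3): 10}
        init = _state_from(init_dict, 3)
        n_rep, n_gen = 10_000, 3
        classes, _ = iad.genotype_classes(3)

        engine = np.empty((n_rep, len(classes)))
        for rep in range(n_rep):
            rng = iad.replicate_rng(7, rep)
            s = init
            for _ in range(n_gen):
                s = iad.step(s, p, rng)
            engine[rep] = s.counts

        agent = np.empty((n_rep, len(classes)))
        rng = np.random.default_rng(2024)
        for rep in range(n_rep):
            agent[rep] = agent_run_class_counts(init_dict, p, n_gen, rng)

        m1, m2 = engine.mean(0), agent.mean(0)
        se = np.sqrt(engine.var(0, ddof=1) / n_rep + agent.var(0, ddof=1) / n_rep)
        occupied = (m1 + m2) > 0.5
        z = np.abs(m1 - m2)[occupied] / se[occupied]
        assert np.all(z < 3.0), f"max z = {z.max():.2f}"

    def test_extinction_raises(self):
        p = iad.SimParams(n_pop=10, k_max=1)
        empty = iad.PopulationState(np.zeros(2), k_max=1)
        with pytest.raises(RuntimeError, match="extinct"):
            iad.step(empty, p, iad.replicate_rng(0, 0))


class TestRun:
    def test_closed_system_keeps_heterozygosity(self):
        p = iad.SimParams(mu_nt=0.0, rec_rate=0.0, n_pop=500, k_max=8)
        init = _state_from({(7, 1): 500}, 8)
        (tr,) = iad.run(p, 50, 1, init=init)
        assert np.all(tr.heterozygosity == 1.0)
        assert tr.loh_generation is None

    def test_determinism_same_seed_bitwise(self):
        p = iad.SimParams(n_pop=2000, k_max=8, seed=5)
        init = iad.founder_state(p, founder=(7, 1), n_founders=20)
        a = iad.run(p, 30, 2, init=init)
        b = iad.run(p, 30, 2, init=init)
        for ta, tb in zip(a, b):
            assert np.array_equal(ta.mutant_freq_copy, tb.mutant_freq_copy)
            assert np.array_equal(ta.heterozygosity, tb.heterozygosity)

    def test_single_lineage_homogenization_matches_markov_chain(self):
        """A (2,1) array recombining at rate 0.01 per generation is a 3-state
        Markov chain on j in {0,1,2}; its mean absorption time from j=1,
        computed from the transition matrix, is matched by simulation."""
        p = iad.SimParams(rec_rate=0.01, copy_change_probs=(0.0, 1.0, 0.0), k_max=2)
        # chain oracle: event prob r, event kernel H(4,2,2) = {1/6, 4/6, 1/6}
        r = 0.01
        q_stay = (1 - r) + r * (4 / 6)
        expected_time = 1.0 / (1.0 - q_stay)  # = 300 generations
        assert expected_time == pytest.approx(300.0, rel=1e-12)
        rng = iad.replicate_rng(17, 0)
        times = [iad.single_lineage_homogenization_time((2, 1), p, rng)
                 for _ in range(2000)]
        se = np.std(times, ddof=1) / math.sqrt(len(times))
        assert abs(np.mean(times) - expected_time) < 3 * se

    def test_homogenization_beats_second_mutation_within_array(self):
        """Recombination homogenizes an amplified array long before a second,
        independent mutation arises in a different copy of the same array.

        Race within one array lineage starting at (7, 1): per generation the
        array recombines with probability 0.01 (hypergeometric kernel) while
        each of its wild-type copies mutates at 1e-6 per division.  With a
        homogenization hazard of order 1/300 per generation versus a second-
        mutation hazard of ~6e-6, homogenization wins essentially always;
        assert it wins in >= 90% of lineages that keep the mutant allele.
        """
        p = iad.SimParams()  # rec_rate 0.01, mu_gene 1e-6
        rng = iad.replicate_rng(77, 0)
        full_first, second_first = 0, 0
        for _ in range(2000):
            g = iad.ArrayGenotype(7, 1)
            for _ in range(100_000):
                if rng.random() < iad.per_array_mutation_rate(p.mu_gene, g.k - g.j):
                    second_first += 1
                    break
                if rng.random() < p.rec_rate:
                    g = iad.recombine(g, p, rng)
                if g.j == 0:
                    break  # mutant allele lost; lineage leaves the race
                if g.j == g.k:
                    full_first += 1
                    break
        decided = full_first + second_first
        assert decided > 200
        assert full_first / decided >= 0.9


class TestParams:
    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            iad.SimParams(rec_rate=1.5)
        with pytest.raises(ValueError):
            iad.SimParams(copy_change_probs=(0.5, 0.5, 0.5))
        with pytest.raises(ValueError):
            iad.FitnessMap(mu0=-1.0)

    def test_genotype_bounds_checked(self):
        with pytest.raises(ValueError):
            iad.ArrayGenotype(0, 0).validate(20)
        with pytest.raises(ValueError):
            iad.ArrayGenotype(3, 4).validate(20)
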