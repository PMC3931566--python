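"""Selection and mutation: Wright–Fisher contracts and oracles."""

import numpy as np
import pytest

from ednaratchet.core import Genome, ModelParams, Population, mutate, reproduce, step_deme
from ednaratchet.edna import EdnaPool
from ednaratchet.experiments import initial_state


class TestModelParams:
    def test_indivisible_grid_rejected(self):
        with pytest.raises(ValueError):
            ModelParams(N=1000, U=0.01, grid=(4, 4))  # 1000 % 16 != 0

    @pytest.mark.parametrize(
        "kw",
        [
            {"U": -1e-3},
            {"s": 0.0},
            {"s": 1.0},
            {"d_edna": 1.5},
            {"D_pop": -0.1},
            {"D_edna": 2.0},
            {"r": -0.5},
        ],
    )
    def test_out_of_range_rates_rejected(self, kw):
        base = dict(N=1600, U=0.01)
        base.update(kw)
        with pytest.raises(ValueError):
            ModelParams(**base)

    def test_infinite_diffusion_spelled_out(self):
        p = ModelParams(N=1600, U=0.01, D_edna="infinite", grid=(4, 4))
        assert np.isinf(p.D_edna)
        assert p.deme_size == 100


class TestPopulation:
    def test_genome_and_class_views(self):
        pop = Population.from_genomes([Genome((0, 1, 2)), Genome((0, 1, 2)), Genome((1, 0, 0))])
        assert pop.size == 3 and pop.l == 3
        assert list(pop.loads) == [3, 3, 1]
        uniq, counts = pop.genotype_classes()
        assert sorted(counts) == [1, 2]
        assert pop.load_histogram()[3] == 2

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            Population(np.zeros((0, 5)))

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            Population(np.array([[1, -1]]))


class TestReproduce:
    def test_monomorphic_invariant(self, rng):
        pop = Population.monomorphic(50, 10, [1, 2] + [0] * 8)
        out = reproduce(pop, 0.05, rng)
        assert np.array_equal(out.loci, pop.loci)

    def test_size_conserved_and_subset(self, rng):
        pop = Population(rng.integers(0, 3, (200, 5)).astype(np.int16))
        out = reproduce(pop, 0.1, rng)
        assert out.size == pop.size
        parent_set = {r.tobytes() for r in pop.loci}
        assert all(r.tobytes() in parent_set for r in out.loci)

    def test_neutral_symmetry(self, two_class_pop, rng):
        # s = 0: expected offspring frequency of each class is its parent frequency
        freqs = []
        for _ in range(3000):
            out = reproduce(two_class_pop, 0.0, rng)
            freqs.append(np.count_nonzero(out.loads == 0) / out.size)
        se = np.std(freqs) / np.sqrt(len(freqs))
        assert abs(np.mean(freqs) - 0.5) < 3 * se + 1e-12

    def test_selection_matches_wf_expectation(self, rng):
        # two classes loads 0/1 at p = 0.3: E[p'] = p / (p + (1-s)(1-p))
        s, p0, n = 0.2, 0.3, 200
        mat = np.zeros((n, 4), dtype=np.int16)
        mat[int(n * p0):, 0] = 1
        pop = Population(mat)
        expected = p0 / (p0 + (1 - s) * (1 - p0))
        freqs = [
            np.count_nonzero(reproduce(pop, s, rng).loads == 0) / n
            for _ in range(3000)
        ]
        se = np.std(freqs) / np.sqrt(len(freqs))
        assert abs(np.mean(freqs) - expected) < 3 * se

    def test_deterministic_given_seed(self, two_class_pop):
        a = reproduce(two_class_pop, 0.01, np.random.default_rng(7))
        b = reproduce(two_class_pop, 0.01, np.random.default_rng(7))
        assert np.array_equal(a.loci, b.loci)


class TestMutate:
    def test_zero_rate_identity(self, two_class_pop, rng):
        out = mutate(two_class_pop, 0.0, rng)
        assert np.array_equal(out.loci, two_class_pop.loci)

    def test_poisson_total_oracle(self, rng):
        # N*U = 500 expected new mutations, Poisson-distributed
        pop = Population.monomorphic(10**4, 20)
        totals = [int(mutate(pop, 0.05, rng).loads.sum()) for _ in range(30)]
        mean = np.mean(totals)
        assert abs(mean - 500) < 3 * np.sqrt(500 / len(totals))

    def test_uniform_locus_assignment(self, rng):
        from scipy import stats

        pop = Population.monomorphic(2000, 10)
        counts = np.zeros(10)
        for _ in range(10):
            out = mutate(pop, 0.5, rng)
            counts += out.loci.sum(axis=0)
        chi2 = ((counts - counts.mean()) ** 2 / counts.mean()).sum()
        assert chi2 < stats.chi2.ppf(0.99, df=9)

    def test_load_never_decreases(self, rng):
        pop = Population(rng.integers(0, 2, (100, 8)).astype(np.int16))
        out = mutate(pop, 0.3, rng)
        assert np.all(out.loads >= pop.loads)
        assert out.size == pop.size


class TestStepDeme:
    def test_absorbing_without_mutation_or_hgt(self, rng):
        params = ModelParams(N=100, U=0.0, r=0.0, l=10)
        pop = Population.monomorphic(100, 10)
        pool = EdnaPool.empty(10)
        for _ in range(20):
            pop, pool = step_deme(pop, pool, params, rng)
        assert np.array_equal(pop.loci, np.zeros((100, 10)))

    def test_rapid_turnover_pool_count(self, rng):
        # d_eDNA = 1: after a step the pool holds exactly N*l allele copies
        params = ModelParams(N=200, U=0.05, r=0.0, l=10, d_edna=1.0)
        pop, pool = initial_state(params, rng)
        for _ in range(5):
            pop, pool = step_deme(pop, pool, params, rng)
            assert pool.total == 200 * 10

    def test_trajectory_reproducible(self):
        params = ModelParams(N=300, U=0.05, r=0.02, l=10, d_edna=0.5, seed=9)
        results = []
        for _ in range(2):
            rng = np.random.default_rng(params.seed)
            pop, pool = initial_state(params, rng)
            for _ in range(30):
                pop, pool = step_deme(pop, pool, params, rng)
            results.append((pop.loci.copy(), pool.copies.copy()))
        assert np.array_equal(results[0][0], results[1][0])
        assert np.array_equal(results[0][1], results[1][1])

    def test_locus_relabeling_leaves_load_statistics(self):
        # permuting locus labels changes nothing load-based
        from ednaratchet import observables as obs

        rng = np.random.default_rng(0)
        mat = rng.integers(0, 3, (50, 12)).astype(np.int16)
        pop = Population(mat)
        perm = rng.permutation(12)
        permuted = Population(mat[:, perm])
        assert np.array_equal(np.sort(pop.loads), np.sort(permuted.loads))
        assert obs.fixed_mutations(pop) == obs.fixed_mutations(permuted)
        assert obs.gene_diversity(obs.llc_members(pop)) == pytest.approx(
            obs.gene_diversity(obs.llc_members(permuted))
        )
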