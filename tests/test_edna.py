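"""eDNA pool dynamics: death weights, production, decay, transformation."""

import numpy as np
import pytest

from ednaratchet.core import Population
from ednaratchet.edna import (
    EdnaPool,
    death_weights,
    decay,
    hgt,
    produce,
    sample_alleles,
)


class TestDeathWeights:
    def test_least_loaded_never_dies(self):
        pop = Population(np.array([[0, 0], [1, 0]], dtype=np.int16))
        eps = death_weights(pop, 0.01)
        assert eps[0] == 0.0
        assert eps[1] == pytest.approx(1.0)

    def test_monomorphic_uniform(self):
        pop = Population.monomorphic(8, 5, [1, 1, 0, 0, 0])
        assert np.allclose(death_weights(pop, 0.01), 1 / 8)

    def test_three_class_hand_evaluation(self):
        # loads (0, 1, 2), s = 0.01: eps ∝ (0, 0.01, 0.0199)
        pop = Population(np.array([[0, 0], [1, 0], [1, 1]], dtype=np.int16))
        eps = death_weights(pop, 0.01)
        assert eps == pytest.approx([0.0, 0.33445, 0.66555], abs=5e-6)

    def test_increasing_in_load(self, rng):
        pop = Population(rng.integers(0, 4, (100, 6)).astype(np.int16))
        eps = death_weights(pop, 0.05)
        order = np.argsort(pop.loads)
        assert np.all(np.diff(eps[order]) >= -1e-15)

    def test_weights_are_relative_to_llc(self):
        # shifting every genome by a fixed fixed-mutation background is neutral
        pop_lo = Population(np.array([[0, 0], [1, 0]], dtype=np.int16))
        pop_hi = Population(np.array([[5, 3], [6, 3]], dtype=np.int16))
        assert death_weights(pop_lo, 0.01) == pytest.approx(death_weights(pop_hi, 0.01))


class TestProduce:
    def test_increment_is_size_times_l(self, rng, two_class_pop):
        pool = EdnaPool.empty(two_class_pop.l)
        out = produce(pool, two_class_pop, 0.01, rng)
        assert out.total == two_class_pop.size * two_class_pop.l

    def test_only_loaded_class_contributes(self, rng, two_class_pop):
        # load-0 cells have eps = 0, so every dead genome carries the mutation
        out = produce(EdnaPool.empty(10), two_class_pop, 0.01, rng)
        assert out.copies[0, 1] == two_class_pop.size  # locus 0, one-mutation allele
        assert out.copies[1:, 0].sum() == two_class_pop.size * 9

    def test_single_class_composition(self, rng):
        genome = [2, 0, 1]
        pop = Population.monomorphic(40, 3, genome)
        out = produce(EdnaPool.empty(3), pop, 0.01, rng)
        for locus, allele in enumerate(genome):
            assert out.copies[locus, allele] == 40

    def test_accumulates_on_existing_pool(self, rng, two_class_pop):
        pool = EdnaPool.from_entries(10, [(0, 0, 7)])
        out = produce(pool, two_class_pop, 0.01, rng)
        assert out.total == 7 + two_class_pop.size * 10


class TestDecay:
    def test_full_turnover_empties(self, rng, uniform_pool):
        assert decay(uniform_pool, 1.0, rng).is_empty

    def test_zero_rate_identity(self, rng, uniform_pool):
        assert np.array_equal(decay(uniform_pool, 0.0, rng).copies, uniform_pool.copies)

    def test_deterministic_branch(self, rng):
        # e = 10, d = 0.3: expectation 3 > 1, deterministic decrement of 3
        pool = EdnaPool.from_entries(2, [(0, 0, 10)])
        out = decay(pool, 0.3, rng)
        assert out.copies[0, 0] == 7

    def test_stochastic_branch_mean(self, rng):
        # e = 9, d = 0.1: expectation 0.9 <= 1, Binomial(9, 0.1) losses
        pool = EdnaPool.from_entries(1, [(0, 0, 9)])
        losses = [9 - decay(pool, 0.1, rng).copies[0, 0] for _ in range(4000)]
        se = np.std(losses) / np.sqrt(len(losses))
        assert abs(np.mean(losses) - 0.9) < 3 * se

    def test_pool_accounting_over_a_generation(self, rng, two_class_pop):
        # total after decay+produce = (previous - decayed) + size*l
        pool = EdnaPool.from_entries(10, [(i, 0, 50) for i in range(10)])
        decayed = decay(pool, 0.3, rng)
        out = produce(decayed, two_class_pop, 0.01, rng)
        assert out.total == decayed.total + two_class_pop.size * 10


class TestHgt:
    def test_zero_rate_identity(self, rng, two_class_pop, uniform_pool):
        out = hgt(two_class_pop, uniform_pool, 0.0, rng)
        assert np.array_equal(out.loci, two_class_pop.loci)

    def test_empty_pool_noop(self, rng, two_class_pop):
        out = hgt(two_class_pop, EdnaPool.empty(10), 5.0, rng)
        assert np.array_equal(out.loci, two_class_pop.loci)

    def test_single_outcome_pool(self, rng):
        # all pool mass on (locus 3, 5 mutations): any event writes load 5 there
        pop = Population.monomorphic(50, 10)
        pool = EdnaPool.from_entries(10, [(3, 5, 100)])
        out = hgt(pop, pool, 30.0, rng)  # essentially every genome hit
        hit = out.loads > 0
        assert hit.mean() > 0.99
        assert np.all(out.loci[hit, 3] == 5)
        assert np.all(out.loci[:, :3] == 0) and np.all(out.loci[:, 4:] == 0)

    def test_single_event_restoration_probability(self, rng, uniform_pool):
        # recipient with one mutation; pool only mutation-free alleles:
        # a single event restores the clean genome iff it hits the mutated
        # locus, probability 1/l
        l, events = 10, 10**5
        loci_drawn, alleles = sample_alleles(uniform_pool, events, rng)
        mutated_locus = rng.integers(0, l, events)
        restored = (loci_drawn == mutated_locus) & (alleles == 0)
        p_emp = restored.mean()
        se = np.sqrt(p_emp * (1 - p_emp) / events)
        assert abs(p_emp - 1 / l) < 3 * se

    def test_pool_not_depleted(self, rng, two_class_pop, uniform_pool):
        before = uniform_pool.copies.copy()
        hgt(two_class_pop, uniform_pool, 2.0, rng)
        assert np.array_equal(uniform_pool.copies, before)

    def test_population_size_unchanged(self, rng, two_class_pop, uniform_pool):
        assert hgt(two_class_pop, uniform_pool, 1.0, rng).size == two_class_pop.size


class TestPoolContainer:
    def test_mean_load_per_genome(self):
        pool = EdnaPool.from_entries(4, [(0, 2, 10), (1, 0, 10), (2, 1, 20)])
        # total 40 copies over l=4: mean = 4 * (2*10 + 1*20) / 40 = 4
        assert pool.mean_load_per_genome() == pytest.approx(4.0)

    def test_empty_pool_mean_load_undefined(self):
        with pytest.raises(ValueError):
            EdnaPool.empty(5).mean_load_per_genome()

    def test_tidy_export_roundtrip(self):
        pool = EdnaPool.from_entries(3, [(0, 1, 5), (2, 0, 7)])
        df = pool.to_frame()
        rebuilt = EdnaPool.from_entries(3, df.itertuples(index=False))
        assert np.array_equal(rebuilt.copies[:, :2], pool.copies[:, :2])

    def test_allele_fraction_conventions(self):
        pool = EdnaPool.from_entries(2, [(0, 0, 30), (1, 1, 10)])
        whole = pool.allele_fractions()
        per_locus = pool.allele_fractions(per_locus=True)
        assert whole.sum() == pytest.approx(1.0)
        assert whole[0, 0] == pytest.approx(0.75)
        assert per_locus[0, 0] == 1.0 and per_locus[1, 1] == 1.0
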