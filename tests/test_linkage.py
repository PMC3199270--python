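import itertools
import random

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cryptosex.clones import MissingPolicy, clone_correct
from cryptosex.core import MISSING
from cryptosex.linkage import (
    _batch_permuted_vo,
    _vo,
    expected_variance,
    index_of_association,
    mismatch_distribution,
    permutation_test_ia,
)
from cryptosex.simulate import SimulationConfig, simulate_population
from conftest import brute_force_ia, make_population


class TestMismatchDistribution:
    def test_two_class_enumeration(self, two_class_pop):
        d = mismatch_distribution(two_class_pop)
        assert d.n_pairs == 6
        assert sorted(d.K_values.tolist()) == [0, 0, 2, 2, 2, 2]
        assert d.mean_K == pytest.approx(4 / 3)
        assert d.V_O == pytest.approx(8 / 9)

    def test_all_gametes_enumeration(self, all_gametes_pop):
        d = mismatch_distribution(all_gametes_pop)
        assert d.V_O == pytest.approx(2 - (4 / 3) ** 2)

    def test_identical_isolates_zero_variance(self):
        pop = make_population([("1", "2")] * 4)
        d = mismatch_distribution(pop)
        assert d.V_O == 0.0 and d.mean_K == 0.0

    def test_too_few_isolates(self):
        pop = make_population([("1", "2"), ("3", "4")])
        with pytest.raises(ValueError, match="fewer than 3"):
            mismatch_distribution(pop)


class TestExpectedVariance:
    def test_two_biallelic_loci(self, two_class_pop):
        v_e, h = expected_variance(two_class_pop)
        assert h.tolist() == [0.5, 0.5]
        assert v_e == pytest.approx(0.5)

    def test_monomorphic_locus_contributes_zero(self):
        pop = make_population([("1", "1"), ("1", "2"), ("1", "1"), ("1", "2")])
        v_e, h = expected_variance(pop)
        assert h[0] == 0.0
        assert v_e == pytest.approx(0.5 * 0.5)

    def test_all_monomorphic_makes_ia_undefined(self):
        pop = make_population([("1", "2")] * 4)
        with pytest.raises(ValueError, match="monomorphic"):
            index_of_association(pop)


class TestIndexOfAssociation:
    def test_hand_enumerated_values(self, two_class_pop, all_gametes_pop):
        assert index_of_association(two_class_pop).I_A == pytest.approx(7 / 9, abs=1e-12)
        assert index_of_association(all_gametes_pop).I_A == pytest.approx(
            -5 / 9, abs=1e-12
        )

    def test_clone_correction_invariance(self, all_gametes_pop):
        import dataclasses

        doubled = all_gametes_pop.with_isolates(
            list(all_gametes_pop.isolates)
            + [
                dataclasses.replace(iso, strain_id=iso.strain_id + "_dup")
                for iso in all_gametes_pop.isolates
            ]
        )
        corrected = clone_correct(doubled)
        assert corrected.n_isolates == all_gametes_pop.n_isolates
        assert index_of_association(corrected).I_A == pytest.approx(
            index_of_association(all_gametes_pop).I_A, abs=1e-12
        )

    def test_row_order_invariance(self):
        pop, _ = simulate_population(
            SimulationConfig(n_isolates=12, n_loci=4, alleles_per_locus=3, seed=2)
        )
        shuffled = pop.with_isolates(random.Random(1).sample(pop.isolates, 12))
        assert index_of_association(shuffled).I_A == pytest.approx(
            index_of_association(pop).I_A, abs=1e-12
        )

    def test_allele_relabeling_invariance(self):
        import dataclasses

        pop, _ = simulate_population(
            SimulationConfig(n_isolates=10, n_loci=3, alleles_per_locus=3, seed=4)
        )
        relabel = {"a0": "z", "a1": "q", "a2": "a0"}
        recoded = pop.with_isolates(
            dataclasses.replace(i, genotype=tuple(relabel[a] for a in i.genotype))
            for i in pop.isolates
        )
        assert index_of_association(recoded).I_A == pytest.approx(
            index_of_association(pop).I_A, abs=1e-12
        )

    @given(st.integers(0, 10_000))
    @settings(max_examples=30, deadline=None)
    def test_matches_brute_force_oracle_on_small_populations(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 7))
        n_loci = int(rng.integers(2, 5))
        genos = [
            tuple(str(rng.integers(0, 3)) for _ in range(n_loci)) for _ in range(n)
        ]
        pop = make_population(genos)
        v_o, v_e, ia = brute_force_ia(genos)
        if v_e == 0:
            with pytest.raises(ValueError):
                index_of_association(pop)
            return
        res = index_of_association(pop)
        assert res.V_O == pytest.approx(v_o, abs=1e-12)
        assert res.V_E == pytest.approx(v_e, abs=1e-12)
        assert res.I_A == pytest.approx(ia, abs=1e-12)

    def test_missing_data_isolates_dropped(self):
        genos = [("1", "2"), ("1", "2"), ("3", "4"), ("3", "4"), (MISSING, "4")]
        pop = make_population(genos)
        res = index_of_association(pop)
        assert res.n_mlh == 4


class TestPermutationTest:
    def test_seed_reproducibility(self):
        pop, _ = simulate_population(
            SimulationConfig(n_isolates=20, n_loci=6, seed=8)
        )
        a = permutation_test_ia(pop, n_perm=299, seed=5)
        b = permutation_test_ia(pop, n_perm=299, seed=5)
        assert a.p_perm == b.p_perm
        c = permutation_test_ia(pop, n_perm=299, seed=6)
        assert a.I_A == c.I_A  # statistic independent of seed

    def test_zero_permutations_statistic_only(self, two_class_pop):
        res = permutation_test_ia(two_class_pop, n_perm=0)
        assert res.p_perm is None and res.I_A == pytest.approx(7 / 9)

    def test_underpowered_warning(self, two_class_pop):
        with pytest.warns(UserWarning, match="underpowered"):
            permutation_test_ia(two_class_pop, n_perm=50, seed=1)

    def test_small_case_matches_exhaustive_null(self, two_class_pop):
        """For 2 loci with allele multiset {A,A,a,a} per locus, the exact
        null P(I_A_perm >= I_A_obs) is 1/3: of the 6 relative arrangements
        of the second locus, the aligned and anti-aligned ones reach the
        observed mismatch variance."""
        obs = index_of_association(two_class_pop).V_O
        exceed = total = 0
        for perm in itertools.permutations(range(4)):
            col2 = np.array([0, 0, 1, 1])[list(perm)]
            M = np.column_stack([np.array([0, 0, 1, 1]), col2])
            total += 1
            exceed += _vo(M) >= obs - 1e-12
        assert exceed / total == pytest.approx(1 / 3)
        res = permutation_test_ia(two_class_pop, n_perm=999, seed=11)
        assert res.p_perm == pytest.approx(1 / 3, abs=0.06)

    def test_batch_vo_equals_direct_computation(self):
        """The locus-pair decomposition used for permuted replicates must
        agree exactly with the direct pairwise variance."""

        class IdentityRng:
            def permuted(self, col, axis=1):
                return np.array(col)

        rng = np.random.default_rng(3)
        for _ in range(25):
            n = int(rng.integers(4, 40))
            L = int(rng.integers(2, 8))
            M = rng.integers(0, 5, size=(n, L))
            assert _batch_permuted_vo(M, 2, IdentityRng()) == pytest.approx(
                _vo(M), abs=1e-10
            )

    def test_clonal_population_detected(self):
        pop, _ = simulate_population(
            SimulationConfig(
                n_isolates=50, n_loci=10, alleles_per_locus=4,
                clonality=0.8, mutation_rate=0.05, seed=7,
            )
        )
        cc = clone_correct(pop, MissingPolicy.EXCLUDE_ISOLATE)
        res = permutation_test_ia(cc, n_perm=499, seed=9)
        assert res.I_A > 0
        assert res.p_perm < 0.05
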