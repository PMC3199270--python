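from fractions import Fraction
from math import comb

import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import binomtest

from cryptosex.core import MatingType
from cryptosex.mating import (
    Decision,
    Sided,
    TestFamily,
    exact_binomial_ratio_test,
    pool_rare_species,
    ratio_test_counts,
    run_ratio_analysis,
    summarize_ratio_tests,
)
from cryptosex.simulate import SimulationConfig, simulate_population
from conftest import make_population


def exact_tail(n1, n2):
    """Arbitrary-precision oracle: sum of C(n, k)/2^n for k <= min(n1, n2)."""
    n, k = n1 + n2, min(n1, n2)
    return Fraction(sum(comb(n, i) for i in range(k + 1)), 2**n)


class TestExactBinomial:
    def test_balanced_counts_give_p_one(self):
        assert exact_binomial_ratio_test(10, 10) == 1.0

    @pytest.mark.parametrize(
        "n1,n2,two_sided,one_sided",
        [
            # frozen from the integer-arithmetic oracle below
            (13, 5, 0.0962524, 0.0481262),
            (10, 30, 0.00222143, 0.00111072),
            (7, 0, 0.015625, 0.0078125),
        ],
    )
    def test_frozen_tail_sums(self, n1, n2, two_sided, one_sided):
        assert exact_binomial_ratio_test(n1, n2, Sided.TWO_SIDED) == pytest.approx(
            two_sided, rel=1e-5
        )
        assert exact_binomial_ratio_test(n1, n2, Sided.ONE_SIDED) == pytest.approx(
            one_sided, rel=1e-5
        )

    @given(st.integers(0, 80), st.integers(0, 80))
    @settings(max_examples=60, deadline=None)
    def test_matches_integer_oracle_and_is_symmetric(self, n1, n2):
        if n1 + n2 == 0:
            return
        oracle = float(exact_tail(n1, n2))
        assert exact_binomial_ratio_test(n1, n2, Sided.ONE_SIDED) == pytest.approx(
            oracle, abs=1e-12
        )
        assert exact_binomial_ratio_test(n1, n2) == pytest.approx(
            min(1.0, 2 * oracle), abs=1e-12
        )
        assert exact_binomial_ratio_test(n1, n2) == exact_binomial_ratio_test(n2, n1)

    def test_agrees_with_scipy_binomtest(self):
        # library cross-check at p = 1/2 (minlike two-sided == doubled tail)
        for n1, n2 in [(3, 11), (20, 9), (5, 5), (0, 12)]:
            ours = exact_binomial_ratio_test(n1, n2)
            ref = binomtest(n1, n1 + n2, 0.5).pvalue
            assert ours == pytest.approx(ref, abs=1e-12)

    def test_monotone_in_imbalance(self):
        total = 30
        ps = [exact_binomial_ratio_test(k, total - k) for k in range(total // 2 + 1)]
        assert all(a <= b for a, b in zip(ps, ps[1:]))

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            exact_binomial_ratio_test(-1, 3)


class TestPooling:
    def _collection(self, sizes):
        return [
            make_population([("1", "1")] * n, species=sp, site=site)
            for (sp, site), n in sizes.items()
        ]

    def test_rare_species_pooled_to_global(self):
        pops = self._collection(
            {("Common", "A"): 60, ("Common", "B"): 37, ("Rare", "A"): 2, ("Rare", "B"): 1}
        )
        pooled = pool_rare_species(pops, 0.03)  # Rare: 3/100 = 3% is not < 3%
        assert {p.key for p in pooled} == {
            ("Common", "A"), ("Common", "B"), ("Rare", "A"), ("Rare", "B")
        }
        pooled = pool_rare_species(pops, 0.05)
        keys = {p.key for p in pooled}
        assert ("Rare", "Global") in keys
        (rare,) = [p for p in pooled if p.species == "Rare"]
        assert rare.n_isolates == 3

    def test_abundant_species_untouched(self):
        pops = self._collection({("Common", "A"): 90, ("Other", "A"): 10})
        assert pool_rare_species(pops, 0.03) == pops

    def test_empty_collection_errors(self):
        with pytest.raises(ValueError):
            pool_rare_species([], 0.03)


class TestRatioTestPopulation:
    def test_below_min_mlh_not_tested_counts_reported(self):
        res = ratio_test_counts("Sp", "X", 24, 7, 4, 3, TestFamily(m=5))
        assert not res.tested
        assert res.decision is Decision.NOT_TESTED
        assert res.p_value is None
        assert (res.n_mat1_1, res.n_mat1_2) == (4, 3)

    def test_balanced_population_not_significant(self):
        res = ratio_test_counts("Sp", "X", 40, 40, 20, 20, TestFamily(m=1))
        assert res.tested and res.decision is Decision.NOT_SIGNIFICANT

    def test_bonferroni_scaling(self):
        res = ratio_test_counts("Sp", "X", 60, 40, 10, 30, TestFamily(m=57))
        # 57 * 0.0022214 ~ 0.1266: significant raw, not after correction
        assert res.decision is Decision.SIG_01
        assert res.p_bonferroni == pytest.approx(57 * 0.00222143, rel=1e-4)
        assert res.p_bonferroni > 0.05

    def test_one_mating_type_absent_still_testable(self):
        res = ratio_test_counts("Sp", "X", 18, 12, 12, 0, TestFamily(m=1))
        assert res.tested and res.p_value == pytest.approx(2 * 0.5**12, rel=1e-9)


class TestSummary:
    def test_fraction_over_tested_only(self):
        family = TestFamily(m=10)
        results = [
            ratio_test_counts("Sp", f"T{i}", 40, 20, 10, 10, family) for i in range(9)
        ]
        results.append(ratio_test_counts("Sp", "T9", 40, 20, 18, 2, family))
        results.append(ratio_test_counts("Sp", "U", 9, 7, 4, 3, family))  # untested
        s = summarize_ratio_tests(results)
        assert s.n_tested == 10
        assert s.n_significant_raw == 1
        assert s.fraction_nonsignificant == pytest.approx(0.9)

    def test_no_tested_populations_errors(self):
        res = ratio_test_counts("Sp", "X", 9, 7, 4, 3, TestFamily(m=1))
        with pytest.raises(ValueError):
            summarize_ratio_tests([res])


class TestNullCalibrationAndPower:
    def test_type_i_error_conservative_under_null(self):
        # mating types iid Bernoulli(1/2), n = 40 haplotypes, 1000 replicates
        rejections = 0
        n_rep = 1000
        for i in range(n_rep):
            pop, _ = simulate_population(
                SimulationConfig(n_isolates=40, n_loci=12, mat_skew=0.5, seed=70_000 + i)
            )
            counts = pop.mating_type_counts()
            p = exact_binomial_ratio_test(
                counts[MatingType.MAT1_1], counts[MatingType.MAT1_2]
            )
            rejections += p < 0.05
        assert 0.01 <= rejections / n_rep <= 0.07

    def test_power_against_skewed_mating(self):
        # skew 0.75 at n = 40: the exact test should reject most of the time
        rejections = 0
        n_rep = 500
        for i in range(n_rep):
            pop, _ = simulate_population(
                SimulationConfig(n_isolates=40, n_loci=12, mat_skew=0.75, seed=80_000 + i)
            )
            counts = pop.mating_type_counts()
            p = exact_binomial_ratio_test(
                counts[MatingType.MAT1_1], counts[MatingType.MAT1_2]
            )
            rejections += p < 0.05
        assert rejections / n_rep > 0.75


def test_run_ratio_analysis_family_is_tested_count():
    pops = [
        make_population(
            [(str(i), str(i)) for i in range(12)],
            mating_types=[MatingType.MAT1_1] * 6 + [MatingType.MAT1_2] * 6,
            species="Big", site=f"S{k}",
        )
        for k in range(3)
    ] + [
        make_population([("1", "1")] * 4, species="Small", site="S0")
    ]
    results = run_ratio_analysis(pops, pool_threshold=0.0)
    tested = [r for r in results if r.tested]
    assert len(tested) == 3
    for r in tested:
        assert r.p_bonferroni == pytest.approx(min(1.0, 3 * r.p_value))
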