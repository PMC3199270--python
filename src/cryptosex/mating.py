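"""Mating-type ratio tests.

Under random mating, frequency-dependent selection keeps the two mating
types of a heterothallic ascomycete at a 1:1 ratio, so each clone-corrected
population is tested against Binomial(n, 1/2) with the exact binomial test.
Species that are rare across the whole collection (< 3% of strains) are
pooled over sites before testing; populations with fewer than 10 distinct
haplotypes are reported without a test; Bonferroni correction is applied
over the family of tested populations.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass

from scipy.stats import binom

from .clones import MissingPolicy, clone_correct
from .core import MatingType, PopulationDataset, SiteGeometry
from .io_core import substream_seed  # noqa: F401  (re-export convenience)

logger = logging.getLogger("cryptosex")

POOLED_SITE = "Global"


class Sided(enum.Enum):
    TWO_SIDED = "two"
    ONE_SIDED = "one"


class Decision(enum.Enum):
    NOT_SIGNIFICANT = "n.s."
    SIG_05 = "*"
    SIG_01 = "**"
    NOT_TESTED = "n.a."


@dataclass(frozen=True)
class TestFamily:
    """Size of the simultaneous-test family for Bonferroni correction."""

    m: int = 1
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("family size m must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")


TestFamily.__test__ = False  # not a test case despite the name


@dataclass
class RatioTestResult:
    species: str
    site: str
    n_strains: int
    n_mlh: int
    n_mat1_1: int
    n_mat1_2: int
    tested: bool
    p_value: float | None = None
    p_bonferroni: float | None = None
    decision: Decision = Decision.NOT_TESTED

    def report_row(self) -> dict:
        return {
            "species": self.species,
            "site": self.site,
            "n": self.n_strains,
            "n_mlh": self.n_mlh,
            "n_mat1_1": self.n_mat1_1,
            "n_mat1_2": self.n_mat1_2,
            "p": self.p_value,
            "p_bonferroni": self.p_bonferroni,
            "decision": self.decision.value,
        }


def exact_binomial_ratio_test(n1: int, n2: int, sided: Sided = Sided.TWO_SIDED) -> float:
    """Exact binomial p-value against a 1:1 null.

    One-sided: P(X <= min(n1, n2)) with X ~ Binomial(n1+n2, 1/2).
    Two-sided: twice that tail, capped at 1 — at p = 1/2 this equals the
    minimum-likelihood two-sided convention by symmetry of the null.
    """
    if n1 < 0 or n2 < 0:
        raise ValueError("counts must be non-negative")
    n = n1 + n2
    if n < 1:
        raise ValueError("need at least one typed haplotype")
    tail = float(binom.cdf(min(n1, n2), n, 0.5))
    if sided is Sided.ONE_SIDED:
        return tail
    return min(1.0, 2.0 * tail)


def pool_rare_species(
    datasets: list[PopulationDataset], freq_threshold: float = 0.03
) -> list[PopulationDataset]:
    """Pool species rarer than ``freq_threshold`` over all sites.

    The input must cover the full collection so species frequencies are
    well defined.  Each rare species is merged into a single population
    with site ``"Global"``; abundant species pass through unchanged.
    """
    if not datasets:
        raise ValueError("empty collection")
    total = sum(p.n_isolates for p in datasets)
    by_species: dict[str, int] = {}
    for p in datasets:
        by_species[p.species] = by_species.get(p.species, 0) + p.n_isolates
    rare = {sp for sp, n in by_species.items() if n / total < freq_threshold}

    out: list[PopulationDataset] = []
    pooled: dict[str, list[PopulationDataset]] = {}
    for p in datasets:
        if p.species in rare:
            pooled.setdefault(p.species, []).append(p)
        else:
            out.append(p)
    for species in sorted(pooled):
        parts = pooled[species]
        isolates = [iso for p in parts for iso in p.isolates]
        max_gp = max((i.grid_point for i in isolates if i.grid_point is not None), default=0)
        merged = PopulationDataset(
            species=species,
            site=POOLED_SITE,
            geometry=SiteGeometry.custom(POOLED_SITE, max(1, max_gp + 1)),
            locus_names=parts[0].locus_names,
            isolates=isolates,
            marker_type=parts[0].marker_type,
        )
        logger.info(
            "pooled rare species %s (%d strains, %.1f%% of collection) across %d sites",
            species, merged.n_isolates, 100 * by_species[species] / total, len(parts),
        )
        out.append(merged)
    return out


def _decide(p: float, alpha: float) -> Decision:
    if p < 0.01:
        return Decision.SIG_01
    if p < alpha:
        return Decision.SIG_05
    return Decision.NOT_SIGNIFICANT


def ratio_test_counts(
    species: str,
    site: str,
    n_strains: int,
    n_mlh: int,
    n_mat1_1: int,
    n_mat1_2: int,
    family: TestFamily,
    min_mlh: int = 10,
    sided: Sided = Sided.TWO_SIDED,
    force_test: bool = False,
) -> RatioTestResult:
    """Ratio test on pre-computed clone-corrected counts.

    ``force_test=True`` bypasses the ``min_mlh`` rule (used when replaying
    published count tables whose tested/untested status is recorded).
    """
    tested = force_test or n_mlh >= min_mlh
    result = RatioTestResult(
        species=species, site=site, n_strains=n_strains, n_mlh=n_mlh,
        n_mat1_1=n_mat1_1, n_mat1_2=n_mat1_2, tested=tested,
    )
    if tested and (n_mat1_1 + n_mat1_2) >= 1:
        p = exact_binomial_ratio_test(n_mat1_1, n_mat1_2, sided)
        result.p_value = p
        result.p_bonferroni = min(1.0, family.m * p)
        result.decision = _decide(p, family.alpha)
    else:
        result.tested = False
    return result


def ratio_test_population(
    pop: PopulationDataset,
    family: TestFamily,
    min_mlh: int = 10,
    sided: Sided = Sided.TWO_SIDED,
    n_strains_raw: int | None = None,
) -> RatioTestResult:
    """Ratio test on a clone-corrected population.

    BOTH/UNKNOWN mating types are excluded from the counts (and logged);
    populations with fewer than ``min_mlh`` haplotypes report counts only.
    """
    counts = pop.mating_type_counts()
    excluded = counts[MatingType.BOTH] + counts[MatingType.UNKNOWN]
    if excluded:
        logger.info(
            "ratio test %s/%s: excluding %d isolates with BOTH/UNKNOWN mating type",
            pop.species, pop.site, excluded,
        )
    return ratio_test_counts(
        species=pop.species,
        site=pop.site,
        n_strains=pop.n_isolates if n_strains_raw is None else n_strains_raw,
        n_mlh=pop.n_isolates,
        n_mat1_1=counts[MatingType.MAT1_1],
        n_mat1_2=counts[MatingType.MAT1_2],
        family=family,
        min_mlh=min_mlh,
        sided=sided,
    )


@dataclass(frozen=True)
class RatioSummary:
    n_tested: int
    n_significant_raw: int
    n_significant_bonferroni: int
    fraction_nonsignificant: float

    def report_row(self) -> dict:
        return {
            "n_tested": self.n_tested,
            "n_significant_raw": self.n_significant_raw,
            "n_significant_bonferroni": self.n_significant_bonferroni,
            "fraction_nonsignificant": self.fraction_nonsignificant,
        }


def summarize_ratio_tests(results: list[RatioTestResult], alpha: float = 0.05) -> RatioSummary:
    """Summarize a family of ratio tests over the *tested* populations only."""
    tested = [r for r in results if r.tested and r.p_value is not None]
    if not tested:
        raise ValueError("no tested populations to summarize")
    n_sig = sum(r.p_value < alpha for r in tested)
    n_sig_bonf = sum(r.p_bonferroni < alpha for r in tested)
    return RatioSummary(
        n_tested=len(tested),
        n_significant_raw=n_sig,
        n_significant_bonferroni=n_sig_bonf,
        fraction_nonsignificant=1.0 - n_sig / len(tested),
    )


def run_ratio_analysis(
    datasets: list[PopulationDataset],
    alpha: float = 0.05,
    sided: Sided = Sided.TWO_SIDED,
    min_mlh: int = 10,
    pool_threshold: float = 0.03,
    missing_policy: MissingPolicy = MissingPolicy.EXACT_MATCH,
) -> list[RatioTestResult]:
    """Full ratio pipeline: pool rare species, clone-correct, test.

    The Bonferroni family is the number of populations that end up tested,
    determined in a first pass so every reported ``p_bonferroni`` uses the
    same family size.
    """
    pooled = pool_rare_species(datasets, pool_threshold)
    corrected = [(p.n_isolates, clone_correct(p, missing_policy)) for p in pooled]
    m = sum(cc.n_isolates >= min_mlh for _, cc in corrected)
    family = TestFamily(m=max(1, m), alpha=alpha)
    return [
        ratio_test_population(cc, family, min_mlh=min_mlh, sided=sided, n_strains_raw=raw_n)
        for raw_n, cc in corrected
    ]
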