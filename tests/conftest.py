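import pytest

from cryptosex.core import (
    IsolateRecord,
    MatingType,
    PopulationDataset,
    SiteGeometry,
)


def make_population(
    genotypes,
    mating_types=None,
    grid_points=None,
    species="Toy",
    site="ToySite",
    n_grid_points=None,
    locus_names=None,
):
    """Build a small population from plain tuples."""
    n = len(genotypes)
    n_loci = len(genotypes[0])
    mating_types = mating_types or [MatingType.MAT1_1] * n
    grid_points = grid_points if grid_points is not None else list(range(n))
    n_grid_points = n_grid_points or max(g for g in grid_points if g is not None) + 1
    locus_names = locus_names or tuple(f"L{j+1:02d}" for j in range(n_loci))
    isolates = [
        IsolateRecord(
            strain_id=f"s{i+1:03d}", species=species, site=site,
            mating_type=mating_types[i], genotype=tuple(genotypes[i]),
            grid_point=grid_points[i],
        )
        for i in range(n)
    ]
    return PopulationDataset(
        species=species, site=site,
        geometry=SiteGeometry.custom(site, n_grid_points),
        locus_names=locus_names, isolates=isolates,
    )


@pytest.fixture
def two_class_pop():
    """Two perfectly associated haplotype classes: AB, AB, ab, ab."""
    return make_population([("A", "B"), ("A", "B"), ("a", "b"), ("a", "b")])


@pytest.fixture
def all_gametes_pop():
    """All four gametic classes at two biallelic loci."""
    return make_population([("A", "B"), ("A", "b"), ("a", "B"), ("a", "b")])


def brute_force_ia(genotypes):
    """Independent I_A oracle: explicit pair enumeration and allele counts.

    Kept deliberately naive (pure-Python loops, no shared code with the
    implementation under test).
    """
    n = len(genotypes)
    n_loci = len(genotypes[0])
    ks = []
    for i in range(n):
        for j in range(i + 1, n):
            ks.append(sum(genotypes[i][l] != genotypes[j][l] for l in range(n_loci)))
    n_pairs = len(ks)
    mean = sum(ks) / n_pairs
    v_o = sum((k - mean) ** 2 for k in ks) / n_pairs
    v_e = 0.0
    for l in range(n_loci):
        freqs = {}
        for i in range(n):
            freqs[genotypes[i][l]] = freqs.get(genotypes[i][l], 0) + 1
        h = 1.0 - sum((c / n) ** 2 for c in freqs.values())
        v_e += h * (1.0 - h)
    if v_e == 0.0:
        return v_o, v_e, None
    return v_o, v_e, v_o / v_e - 1.0
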