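"""Seeded forward simulation of partially clonal haploid populations.

The generator emulates the statistical structure the analyses assume: a
population is built isolate by isolate; with probability ``clonality`` a
new isolate is a clonal copy of a uniformly chosen earlier isolate
(inheriting its mating type, mutating each locus to a novel allele with
probability ``mutation_rate`` under an infinite-alleles model, and landing
within ``patch_spread`` grid points of its source), otherwise it is an
independent recombinant: each locus drawn independently from the founder
allele frequencies (linkage equilibrium), mating type Bernoulli(mat_skew),
uniform grid placement.  Uniform choice among *prior isolates* (not
lineages) makes abundant clones ever more likely to be copied, so
epidemic clonal structure emerges without an explicit demographic model.

Bookkeeping (true lineage of every isolate, planted haplotype count, true
allele frequencies) is returned alongside the dataset so downstream
modules can be tested against ground truth.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .core import (
    MISSING,
    IsolateRecord,
    MarkerType,
    MatingType,
    PopulationDataset,
    SiteGeometry,
)
from .io_core import substream_seed, write_genotype_table


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one simulated population.

    Defaults sit inside the envelope of the real survey: tens of isolates
    per population, 12 microsatellite-like loci, grid-net sites.
    """

    n_isolates: int = 50
    n_loci: int = 12
    alleles_per_locus: int | Sequence[int] = 4
    allele_freq_model: str = "uniform"      # "uniform" or "dirichlet"
    dirichlet_alpha: float = 1.0
    clonality: float = 0.0                   # probability of a clonal copy
    mutation_rate: float = 0.0               # per locus per clonal copy
    mat_skew: float = 0.5                    # P(recombinant is MAT1-1)
    geometry: SiteGeometry = field(
        default_factory=lambda: SiteGeometry.grid_net("SimSite")
    )
    patch_spread: int = 1
    missing_rate: float = 0.0
    both_rate: float = 0.0                   # anomalous dual-amplification rate
    unknown_rate: float = 0.0
    species: str = "SimSp"
    site: str | None = None                  # defaults to geometry.site
    seed: int | None = None

    def __post_init__(self) -> None:
        for name in ("clonality", "mutation_rate", "mat_skew", "missing_rate",
                     "both_rate", "unknown_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.n_isolates < 1 or self.n_loci < 1:
            raise ValueError("n_isolates and n_loci must be >= 1")


@dataclass
class SimulationTruth:
    lineage_of: dict[str, int]
    planted_mlh_count: int
    allele_freqs: list[np.ndarray]
    mating_type_counts: dict[MatingType, int]


def _founder_freqs(cfg: SimulationConfig, rng: np.random.Generator) -> list[np.ndarray]:
    if isinstance(cfg.alleles_per_locus, int):
        ks = [cfg.alleles_per_locus] * cfg.n_loci
    else:
        ks = list(cfg.alleles_per_locus)
        if len(ks) != cfg.n_loci:
            raise ValueError("alleles_per_locus vector length != n_loci")
    freqs = []
    for k in ks:
        if cfg.allele_freq_model == "uniform":
            freqs.append(np.full(k, 1.0 / k))
        elif cfg.allele_freq_model == "dirichlet":
            freqs.append(rng.dirichlet(np.full(k, cfg.dirichlet_alpha)))
        else:
            raise ValueError(f"unknown allele_freq_model {cfg.allele_freq_model!r}")
    return freqs


def simulate_population(
    cfg: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[PopulationDataset, SimulationTruth]:
    """Generate one population and its ground truth.

    Identical seed -> identical dataset, byte for byte when written.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    site = cfg.site or cfg.geometry.site
    freqs = _founder_freqs(cfg, rng)
    cum_freqs = [np.cumsum(f) for f in freqs]
    n_points = cfg.geometry.n_grid_points

    genotypes: list[list[str]] = []
    mats: list[MatingType] = []
    grid: list[int] = []
    lineages: list[int] = []
    next_lineage = 0
    novel_counter = 0

    for i in range(cfg.n_isolates):
        if i > 0 and rng.random() < cfg.clonality:
            src = int(rng.integers(0, i))
            geno = list(genotypes[src])
            for j in range(cfg.n_loci):
                if rng.random() < cfg.mutation_rate:
                    novel_counter += 1
                    geno[j] = f"m{novel_counter}"       # infinite-alleles novelty
            mat = mats[src]
            lo = max(0, grid[src] - cfg.patch_spread)
            hi = min(n_points - 1, grid[src] + cfg.patch_spread)
            gp = int(rng.integers(lo, hi + 1))
            lineage = lineages[src]
        else:
            draws = rng.random(cfg.n_loci)
            geno = [
                f"a{int(np.searchsorted(cf, u, side='right'))}"
                for cf, u in zip(cum_freqs, draws)
            ]
            mat = MatingType.MAT1_1 if rng.random() < cfg.mat_skew else MatingType.MAT1_2
            gp = int(rng.integers(0, n_points))
            lineage = next_lineage
            next_lineage += 1
        genotypes.append(geno)
        mats.append(mat)
        grid.append(gp)
        lineages.append(lineage)

    # anomalous typing outcomes (dual amplification / failure), then masking
    for i in range(cfg.n_isolates):
        u = rng.random()
        if u < cfg.both_rate:
            mats[i] = MatingType.BOTH
        elif u < cfg.both_rate + cfg.unknown_rate:
            mats[i] = MatingType.UNKNOWN
    if cfg.missing_rate > 0:
        for i in range(cfg.n_isolates):
            for j in range(cfg.n_loci):
                if rng.random() < cfg.missing_rate:
                    genotypes[i][j] = MISSING

    width = len(str(cfg.n_isolates))
    isolates = [
        IsolateRecord(
            strain_id=f"{cfg.species}_{i + 1:0{width}d}",
            species=cfg.species,
            site=site,
            mating_type=mats[i],
            genotype=tuple(genotypes[i]),
            grid_point=grid[i],
        )
        for i in range(cfg.n_isolates)
    ]
    pop = PopulationDataset(
        species=cfg.species,
        site=site,
        geometry=cfg.geometry if cfg.site is None
        else replace(cfg.geometry, site=site),
        locus_names=tuple(f"L{j + 1:02d}" for j in range(cfg.n_loci)),
        isolates=isolates,
        marker_type=MarkerType.MICROSAT,
    )
    truth = SimulationTruth(
        lineage_of={iso.strain_id: lin for iso, lin in zip(isolates, lineages)},
        planted_mlh_count=len(set(lineages)),
        allele_freqs=freqs,
        mating_type_counts={
            m: sum(1 for x in mats if x is m) for m in MatingType
        },
    )
    return pop, truth


def zipf_abundances(n_species: int, exponent: float = 1.0) -> np.ndarray:
    """Hyperbolic (Zipf-like) relative abundances: a few dominant species,
    many rare ones — the shape of real endophyte communities."""
    ranks = np.arange(1, n_species + 1, dtype=float)
    w = ranks ** (-exponent)
    return w / w.sum()


def simulate_collection(
    site_geometries: Sequence[SiteGeometry],
    species_names: Sequence[str],
    n_per_site: int = 120,
    zipf_exponent: float = 1.0,
    base_cfg: SimulationConfig | None = None,
    seed: int = 0,
) -> list[tuple[PopulationDataset, SimulationTruth]]:
    """Simulate a multi-site, multi-species collection.

    Species abundances follow a Zipf distribution (same ranking at every
    site) so that rare-species pooling is exercised; each (site, species)
    population draws its own random substream from the global seed, making
    results independent of execution order.
    """
    if not site_geometries:
        raise ValueError("need at least one site")
    base_cfg = base_cfg or SimulationConfig()
    probs = zipf_abundances(len(species_names), zipf_exponent)
    out = []
    for geom in site_geometries:
        counts_rng = np.random.default_rng(substream_seed(f"counts|{geom.site}", seed))
        counts = counts_rng.multinomial(n_per_site, probs)
        for species, n in zip(species_names, counts):
            if n == 0:
                continue
            cfg = replace(
                base_cfg, species=species, site=geom.site, geometry=geom,
                n_isolates=int(n), seed=None,
            )
            rng = np.random.default_rng(
                substream_seed(f"{species}/{geom.site}", seed)
            )
            out.append(simulate_population(cfg, rng))
    return out


def write_fixture_suite(outdir: str | Path, seed: int = 0) -> Path:
    """Emit the standing fixture files plus a checksum manifest.

    Fixtures: a linkage-equilibrium population, a clonal population, the
    two hand-enumerable four-isolate datasets, and copies of the packaged
    survey tables.  Returns the manifest path.
    """
    from importlib import resources

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    def _toy(name: str, rows: list[tuple[str, str]]) -> PopulationDataset:
        return PopulationDataset(
            species="Toy", site=name,
            geometry=SiteGeometry.custom(name, 4),
            locus_names=("L01", "L02"),
            isolates=[
                IsolateRecord(f"t{i + 1}", "Toy", name, MatingType.MAT1_1,
                              g, grid_point=i)
                for i, g in enumerate(rows)
            ],
        )

    files: dict[str, Path] = {}

    eq_pop, _ = simulate_population(
        SimulationConfig(n_isolates=50, n_loci=10, alleles_per_locus=4,
                         species="EqSp", seed=substream_seed("equilibrium", seed))
    )
    files["equilibrium_population.tsv"] = outdir / "equilibrium_population.tsv"
    write_genotype_table([eq_pop], files["equilibrium_population.tsv"])

    cl_pop, _ = simulate_population(
        SimulationConfig(n_isolates=50, n_loci=10, alleles_per_locus=4,
                         clonality=0.8, mutation_rate=0.05, species="ClSp",
                         seed=substream_seed("clonal", seed))
    )
    files["clonal_population.tsv"] = outdir / "clonal_population.tsv"
    write_genotype_table([cl_pop], files["clonal_population.tsv"])

    files["toy_two_class.tsv"] = outdir / "toy_two_class.tsv"
    write_genotype_table(
        [_toy("TwoClass", [("A", "B"), ("A", "B"), ("a", "b"), ("a", "b")])],
        files["toy_two_class.tsv"],
    )
    files["toy_all_gametes.tsv"] = outdir / "toy_all_gametes.tsv"
    write_genotype_table(
        [_toy("AllGametes", [("A", "B"), ("A", "b"), ("a", "B"), ("a", "b")])],
        files["toy_all_gametes.tsv"],
    )

    for name in ("pac_mating_type_counts.tsv", "pac_mat_codeml_fits.tsv"):
        dest = outdir / name
        dest.write_bytes(
            (resources.files("cryptosex.data") / name).read_bytes()
        )
        files[name] = dest

    manifest = outdir / "MANIFEST.tsv"
    with open(manifest, "w") as fh:
        fh.write("file\tsha256\n")
        for name in sorted(files):
            digest = hashlib.sha256(files[name].read_bytes()).hexdigest()
            fh.write(f"{name}\t{digest}\n")
    return manifest
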