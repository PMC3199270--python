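"""Core domain types for haploid multilocus population datasets.

The unit of every analysis is a *population*: all strains of one species
collected at one study site.  Isolates are haploid, carry a mating-type
idiomorph (MAT1-1 or MAT1-2 in heterothallic ascomycetes) and a vector of
allele codes at a fixed panel of loci (microsatellites or single-copy RFLP
markers).  Sites are sampled either on grid nets (74 grid points) or on
transects (11 grid points).
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

logger = logging.getLogger("cryptosex")

#: Sentinel used for a missing allele call inside a genotype vector.
MISSING = "NA"


class MatingType(enum.Enum):
    MAT1_1 = "MAT1-1"
    MAT1_2 = "MAT1-2"
    BOTH = "both"
    UNKNOWN = "unknown"

    def __str__(self) -> str:  # stable text form for reports
        return self.value


_MAT_TOKENS = {
    "mat1-1": MatingType.MAT1_1,
    "mat1_1": MatingType.MAT1_1,
    "mat11": MatingType.MAT1_1,
    "1": MatingType.MAT1_1,
    "mat1-2": MatingType.MAT1_2,
    "mat1_2": MatingType.MAT1_2,
    "mat12": MatingType.MAT1_2,
    "2": MatingType.MAT1_2,
    "both": MatingType.BOTH,
    "mat1-1/mat1-2": MatingType.BOTH,
    "unknown": MatingType.UNKNOWN,
    "na": MatingType.UNKNOWN,
    "?": MatingType.UNKNOWN,
    "": MatingType.UNKNOWN,
}


def parse_mating_type(token: str) -> MatingType:
    """Map a mating-type token onto the enum, case-insensitively.

    Accepted dialects include ``MAT1-1``, ``mat1_1`` and bare ``1``.
    Raises :class:`ValueError` for anything else.
    """
    try:
        return _MAT_TOKENS[token.strip().lower()]
    except KeyError:
        raise ValueError(f"unknown mating-type token: {token!r}") from None


class Layout(enum.Enum):
    GRID_NET = "grid_net"    # 196 m^2 grid net, 74 grid points
    TRANSECT = "transect"    # 50 m transect, 11 grid points
    CUSTOM = "custom"


GRID_NET_POINTS = 74
TRANSECT_POINTS = 11


@dataclass(frozen=True)
class SiteGeometry:
    """Sampling geometry of a study site."""

    site: str
    layout: Layout = Layout.CUSTOM
    n_grid_points: int = 1

    def __post_init__(self) -> None:
        if self.layout is Layout.GRID_NET and self.n_grid_points != GRID_NET_POINTS:
            raise ValueError("grid-net sites have 74 grid points; use CUSTOM to override")
        if self.layout is Layout.TRANSECT and self.n_grid_points != TRANSECT_POINTS:
            raise ValueError("transect sites have 11 grid points; use CUSTOM to override")
        if self.n_grid_points < 1:
            raise ValueError("n_grid_points must be positive")

    @classmethod
    def grid_net(cls, site: str) -> "SiteGeometry":
        return cls(site, Layout.GRID_NET, GRID_NET_POINTS)

    @classmethod
    def transect(cls, site: str) -> "SiteGeometry":
        return cls(site, Layout.TRANSECT, TRANSECT_POINTS)

    @classmethod
    def custom(cls, site: str, n_grid_points: int) -> "SiteGeometry":
        return cls(site, Layout.CUSTOM, n_grid_points)


class MarkerType(enum.Enum):
    MICROSAT = "M"
    RFLP = "RFLP"


@dataclass(frozen=True)
class IsolateRecord:
    """One sampled strain."""

    strain_id: str
    species: str
    site: str
    mating_type: MatingType
    genotype: tuple[str, ...]
    grid_point: int | None = None

    @property
    def has_missing(self) -> bool:
        return MISSING in self.genotype


@dataclass
class PopulationDataset:
    """All isolates of one species at one study site.

    ``(species, site)`` uniquely identifies a population; every statistical
    test in this package operates on one :class:`PopulationDataset`.
    """

    species: str
    site: str
    geometry: SiteGeometry
    locus_names: tuple[str, ...]
    isolates: list[IsolateRecord] = field(default_factory=list)
    marker_type: MarkerType = MarkerType.MICROSAT

    def __post_init__(self) -> None:
        self.locus_names = tuple(self.locus_names)
        for iso in self.isolates:
            if len(iso.genotype) != self.n_loci:
                raise ValueError(
                    f"isolate {iso.strain_id!r}: genotype has {len(iso.genotype)} "
                    f"alleles, dataset declares {self.n_loci} loci"
                )

    @property
    def key(self) -> tuple[str, str]:
        return (self.species, self.site)

    @property
    def n_loci(self) -> int:
        return len(self.locus_names)

    @property
    def n_isolates(self) -> int:
        return len(self.isolates)

    def mating_type_counts(self) -> dict[MatingType, int]:
        counts: dict[MatingType, int] = {m: 0 for m in MatingType}
        for iso in self.isolates:
            counts[iso.mating_type] += 1
        return counts

    def with_isolates(self, isolates: Iterable[IsolateRecord]) -> "PopulationDataset":
        return replace(self, isolates=list(isolates))


def group_into_populations(
    isolates: Sequence[IsolateRecord],
    locus_names: Sequence[str],
    geometries: dict[str, SiteGeometry] | None = None,
    marker_type: MarkerType = MarkerType.MICROSAT,
) -> list[PopulationDataset]:
    """Group isolates into populations keyed by ``(species, site)``.

    Populations appear in order of first occurrence in the input, so row
    count is conserved: every isolate lands in exactly one population.
    Sites without a declared geometry get a CUSTOM geometry wide enough for
    the largest grid index observed.
    """
    geometries = geometries or {}
    grouped: dict[tuple[str, str], list[IsolateRecord]] = {}
    for iso in isolates:
        grouped.setdefault((iso.species, iso.site), []).append(iso)
    pops = []
    for (species, site), members in grouped.items():
        geom = geometries.get(site)
        if geom is None:
            max_gp = max((i.grid_point for i in members if i.grid_point is not None), default=0)
            geom = SiteGeometry.custom(site, max(1, max_gp + 1))
        pops.append(
            PopulationDataset(
                species=species,
                site=site,
                geometry=geom,
                locus_names=tuple(locus_names),
                isolates=members,
                marker_type=marker_type,
            )
        )
    return pops
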