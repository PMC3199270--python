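"""Spatial co-occurrence of compatible mating types on sampling grids.

Each grid point of a study site is classified by which mating types of a
species were isolated there: only MAT1-1, only MAT1-2, both, or neither.
Association between the two presence/absence patterns is measured with the
2x2 coefficient of association

    Q = (ad - bc) / (ad + bc),

where a = points with both types, b = only MAT1-1, c = only MAT1-2 and
d = neither, together with a Pearson chi-square test of independence on
the same table.  Q > 0 means compatible mating types co-occur more often
than chance — physical proximity being a prerequisite for mating.

This analysis runs on raw (not clone-corrected) collections: co-occurrence
concerns thalli in the ground, and the same clone occupying two points is
real spatial structure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2

from .core import MatingType, PopulationDataset

logger = logging.getLogger("cryptosex")


@dataclass(frozen=True)
class OccupancyTable:
    species: str
    site: str
    n_strains: int
    frac_single_strain_points: float
    n_points_multi: int
    n_only_mat1_1: int       # b
    n_only_mat1_2: int       # c
    n_both: int              # a
    n_neither: int           # d
    n_grid_points_total: int


@dataclass
class SpatialResult:
    occupancy: OccupancyTable
    Q: float | None
    chi2: float | None
    p_value: float | None
    significant: bool

    def report_row(self) -> dict:
        t = self.occupancy
        return {
            "species": t.species,
            "site": t.site,
            "n_strains": t.n_strains,
            "frac_single_strain_points": t.frac_single_strain_points,
            "n_points_multi": t.n_points_multi,
            "points_mat1_1": t.n_only_mat1_1,
            "points_mat1_2": t.n_only_mat1_2,
            "points_both": t.n_both,
            "Q": self.Q,
            "chi2": self.chi2,
            "p": self.p_value,
            "significant": self.significant,
        }


def occupancy_table(pop: PopulationDataset) -> OccupancyTable:
    """Classify every grid point of the site by mating-type occupancy.

    Isolates with BOTH/UNKNOWN mating type or without a grid address are
    excluded (and logged); the four occupancy classes partition the site's
    full sampled grid, so the "neither" class counts points where the
    species was not found.
    """
    total = pop.geometry.n_grid_points
    kept = []
    for iso in pop.isolates:
        if iso.mating_type not in (MatingType.MAT1_1, MatingType.MAT1_2):
            logger.info(
                "spatial %s/%s: excluding %s (mating type %s)",
                pop.species, pop.site, iso.strain_id, iso.mating_type.value,
            )
            continue
        if iso.grid_point is None:
            logger.info(
                "spatial %s/%s: excluding %s (no grid address)",
                pop.species, pop.site, iso.strain_id,
            )
            continue
        if not 0 <= iso.grid_point < total:
            raise ValueError(
                f"{pop.species}/{pop.site}: isolate {iso.strain_id} grid point "
                f"{iso.grid_point} outside 0..{total - 1}"
            )
        kept.append(iso)

    strains_per_point = np.zeros(total, dtype=int)
    has_1 = np.zeros(total, dtype=bool)
    has_2 = np.zeros(total, dtype=bool)
    for iso in kept:
        strains_per_point[iso.grid_point] += 1
        if iso.mating_type is MatingType.MAT1_1:
            has_1[iso.grid_point] = True
        else:
            has_2[iso.grid_point] = True

    occupied = strains_per_point > 0
    n_occupied = int(occupied.sum())
    return OccupancyTable(
        species=pop.species,
        site=pop.site,
        n_strains=len(kept),
        frac_single_strain_points=(
            float((strains_per_point == 1).sum() / n_occupied) if n_occupied else 0.0
        ),
        n_points_multi=int((strains_per_point > 1).sum()),
        n_only_mat1_1=int((has_1 & ~has_2).sum()),
        n_only_mat1_2=int((~has_1 & has_2).sum()),
        n_both=int((has_1 & has_2).sum()),
        n_neither=int((~has_1 & ~has_2).sum()),
        n_grid_points_total=total,
    )


def association_q(t: OccupancyTable) -> float:
    """Coefficient of association Q between the two mating types.

    Q = (ad - bc)/(ad + bc) on the presence/absence table; +1 iff the types
    never occur apart (b = c = 0), -1 iff they never co-occur (a = 0 or
    d = 0 with bc > 0).  Undefined when ad + bc = 0.
    """
    a, b, c, d = t.n_both, t.n_only_mat1_1, t.n_only_mat1_2, t.n_neither
    denom = a * d + b * c
    if denom == 0:
        raise ValueError("degenerate occupancy table: ad + bc = 0, Q undefined")
    return (a * d - b * c) / denom


def chi_square_independence(
    t: OccupancyTable, yates: bool = False
) -> tuple[float, float]:
    """Pearson chi-square test of independence of the two presence patterns.

    The 2x2 table is [[both, only MAT1-1], [only MAT1-2, neither]] over all
    grid points; 1 degree of freedom, optional Yates continuity correction.
    """
    a, b, c, d = t.n_both, t.n_only_mat1_1, t.n_only_mat1_2, t.n_neither
    n = a + b + c + d
    if min(a + b, c + d, a + c, b + d) == 0:
        raise ValueError("zero marginal in 2x2 occupancy table")
    diff = abs(a * d - b * c)
    if yates:
        diff = max(0.0, diff - n / 2)
    stat = n * diff**2 / ((a + b) * (c + d) * (a + c) * (b + d))
    return float(stat), float(chi2.sf(stat, df=1))


def spatial_report(
    pops: list[PopulationDataset],
    top_k_per_site: int = 2,
    alpha: float = 0.05,
    yates: bool = False,
) -> list[SpatialResult]:
    """Spatial association for the top-k most abundant species per site.

    Ties at the k-th abundance rank keep every tied species (logged).
    Populations with a degenerate Q table report Q as None.
    """
    by_site: dict[str, list[PopulationDataset]] = {}
    for p in pops:
        by_site.setdefault(p.site, []).append(p)
    results: list[SpatialResult] = []
    for site in by_site:
        ranked = sorted(by_site[site], key=lambda p: (-p.n_isolates, p.species))
        if len(ranked) > top_k_per_site:
            cutoff = ranked[top_k_per_site - 1].n_isolates
            selected = [p for p in ranked if p.n_isolates >= cutoff]
            if len(selected) > top_k_per_site:
                logger.info(
                    "site %s: abundance tie at rank %d, keeping %d species",
                    site, top_k_per_site, len(selected),
                )
        else:
            selected = ranked
        for pop in selected:
            t = occupancy_table(pop)
            try:
                q = association_q(t)
            except ValueError:
                q = None
            try:
                stat, p = chi_square_independence(t, yates=yates)
            except ValueError:
                stat, p = None, None
            results.append(
                SpatialResult(occupancy=t, Q=q, chi2=stat, p_value=p,
                              significant=p is not None and p < alpha)
            )
    return results
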