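"""Clone correction: collapse a population to one isolate per multilocus
haplotype (MLH).

The same fungal thallus can be sampled at several grid points, so raw
collections over-represent clones.  Every downstream test of random mating
therefore runs on clone-corrected data: one representative per distinct
multilocus genotype.  Missing alleles are handled by policy — either the
isolate is excluded up front (the rule used for gametic-disequilibrium
analysis) or missing is treated as matching nothing, keeping the isolate
as its own haplotype (appropriate for mating-type ratio counts).
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass

from .core import MISSING, PopulationDataset

logger = logging.getLogger("cryptosex")


class MissingPolicy(enum.Enum):
    EXCLUDE_ISOLATE = "exclude"
    EXACT_MATCH = "exact"


@dataclass(frozen=True)
class MlhAssignment:
    """One multilocus haplotype: its members and deterministic representative."""

    mlh_id: int
    members: tuple[str, ...]          # strain ids, sorted
    representative: str               # lexicographically smallest strain id


def assign_mlh(
    pop: PopulationDataset, missing_policy: MissingPolicy = MissingPolicy.EXACT_MATCH
) -> list[MlhAssignment]:
    """Assign every retained isolate to a multilocus haplotype.

    Haplotypes are keyed by the full allele vector.  Isolates with an
    identical genotype but different mating types cannot be one clone, so
    they are kept in separate haplotypes and a warning is logged.  MLH ids
    are dense from 1, ordered by representative strain id, hence invariant
    under permutation of the input rows.
    """
    isolates = pop.isolates
    if missing_policy is MissingPolicy.EXCLUDE_ISOLATE:
        kept = [iso for iso in isolates if not iso.has_missing]
        for iso in isolates:
            if iso.has_missing:
                logger.info(
                    "clone-correct %s/%s: excluding %s (missing allele)",
                    pop.species, pop.site, iso.strain_id,
                )
    else:
        kept = list(isolates)
    if not kept:
        raise ValueError(
            f"population {pop.species}/{pop.site}: empty after missing-data exclusion"
        )

    groups: dict[tuple, list] = {}
    for iso in kept:
        groups.setdefault(iso.genotype, []).append(iso)

    split_groups: list[list] = []
    for genotype, members in groups.items():
        by_mat: dict = {}
        for iso in members:
            by_mat.setdefault(iso.mating_type, []).append(iso)
        if len(by_mat) > 1:
            logger.warning(
                "population %s/%s: identical genotype with different mating types "
                "(%s); not merged", pop.species, pop.site,
                ", ".join(sorted(i.strain_id for i in members)),
            )
        split_groups.extend(by_mat.values())

    split_groups.sort(key=lambda ms: min(i.strain_id for i in ms))
    return [
        MlhAssignment(
            mlh_id=i,
            members=tuple(sorted(iso.strain_id for iso in members)),
            representative=min(iso.strain_id for iso in members),
        )
        for i, members in enumerate(split_groups, start=1)
    ]


def clone_correct(
    pop: PopulationDataset, missing_policy: MissingPolicy = MissingPolicy.EXACT_MATCH
) -> PopulationDataset:
    """Return the population reduced to one representative per MLH.

    Idempotent: clone-correcting an already clone-corrected population is
    the identity.
    """
    assignments = assign_mlh(pop, missing_policy)
    by_id = {iso.strain_id: iso for iso in pop.isolates}
    return pop.with_isolates(by_id[a.representative] for a in assignments)
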