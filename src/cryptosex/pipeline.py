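"""End-to-end analysis pipeline over a genotype collection.

``run_all`` chains the full workflow — rare-species pooling, clone
correction, mating-type ratio tests, index-of-association permutation
tests, spatial co-occurrence analysis and (from the packaged fit table)
the codon-model LRT layer — and writes one report per stage.  All
randomness derives from a single seed via per-population substreams, so
two runs with the same inputs and seed produce byte-identical reports.
"""

from __future__ import annotations

import logging
from pathlib import Path

from .clones import MissingPolicy, clone_correct
from .core import PopulationDataset
from .io_core import substream_seed, write_report
from .linkage import IaResult, permutation_test_ia
from .mating import Sided, run_ratio_analysis, summarize_ratio_tests
from .refdata import load_codon_model_fits
from .selection import run_lrt_suite, selection_summary
from .spatial import spatial_report

logger = logging.getLogger("cryptosex")


def run_ia_analysis(
    datasets: list[PopulationDataset],
    n_perm: int = 999,
    seed: int = 0,
    min_mlh: int = 3,
) -> list[IaResult]:
    """Clone-correct (excluding missing-data isolates) and run the I_A
    permutation test on every population large and diverse enough."""
    results = []
    for pop in datasets:
        try:
            cc = clone_correct(pop, MissingPolicy.EXCLUDE_ISOLATE)
        except ValueError as exc:
            logger.info("I_A: skipping %s/%s: %s", pop.species, pop.site, exc)
            continue
        if cc.n_isolates < min_mlh:
            logger.info(
                "I_A: skipping %s/%s: only %d haplotypes",
                pop.species, pop.site, cc.n_isolates,
            )
            continue
        sub = substream_seed(f"ia|{pop.species}/{pop.site}", seed)
        try:
            results.append(permutation_test_ia(cc, n_perm=n_perm, seed=sub))
        except ValueError as exc:
            logger.info("I_A: skipping %s/%s: %s", pop.species, pop.site, exc)
    return results


def run_all(
    datasets: list[PopulationDataset],
    outdir: str | Path,
    seed: int = 0,
    alpha: float = 0.05,
    sided: Sided = Sided.TWO_SIDED,
    n_perm: int = 999,
    min_mlh: int = 10,
    pool_threshold: float = 0.03,
    top_k_spatial: int = 2,
) -> dict[str, Path]:
    """Run every analysis stage and write one TSV report per stage.

    Returns the mapping of stage name to report path.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    reports: dict[str, Path] = {}

    ratio_results = run_ratio_analysis(
        datasets, alpha=alpha, sided=sided, min_mlh=min_mlh,
        pool_threshold=pool_threshold,
    )
    rows: list = list(ratio_results)
    try:
        rows.append(summarize_ratio_tests(ratio_results, alpha=alpha))
    except ValueError:
        logger.info("ratio summary skipped: no tested populations")
    reports["ratio"] = outdir / "ratio_report.tsv"
    write_report(rows, reports["ratio"])

    ia_results = run_ia_analysis(datasets, n_perm=n_perm, seed=seed)
    if ia_results:
        reports["ia"] = outdir / "ia_report.tsv"
        write_report(ia_results, reports["ia"])

    sp_results = spatial_report(datasets, top_k_per_site=top_k_spatial, alpha=alpha)
    if sp_results:
        reports["spatial"] = outdir / "spatial_report.tsv"
        write_report(sp_results, reports["spatial"])

    fits = load_codon_model_fits()
    lrts = run_lrt_suite(fits, alpha=alpha)
    reports["lrt"] = outdir / "lrt_report.tsv"
    write_report(lrts + [selection_summary(fits, lrts)], reports["lrt"])

    return reports
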