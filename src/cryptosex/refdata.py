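"""Packaged reference tables from the global PAC mating-type survey.

Two small tables ship with the package:

* ``pac_mating_type_counts.tsv`` — per-population clone-corrected
  MAT1-1/MAT1-2 counts (with the published significance flags) for the
  worldwide collection of Phialocephala fortinii s.l. / Acephala applanata
  populations.  The raw genotype matrices behind these counts were never
  deposited, so the counts themselves are the finest-grained public record.
* ``pac_mat_codeml_fits.tsv`` — CODEML site-model fits (log-likelihoods,
  gene-wide dN/dS, site-class mixtures) for the three MAT genes
  MAT1-1-1, MAT1-1-3 and MAT1-2-1.

These serve as inputs for replaying the published ratio-test and
likelihood-ratio-test summaries.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import pandas as pd

from .mating import (
    RatioSummary,
    RatioTestResult,
    Sided,
    TestFamily,
    exact_binomial_ratio_test,
    summarize_ratio_tests,
)
from .selection import ModelFit, read_model_fits

UNTESTED_FLAG = "n.a."


def _data_path(name: str):
    return resources.files("cryptosex.data") / name


def load_mating_type_counts() -> pd.DataFrame:
    """Per-population clone-corrected mating-type counts, one row per
    population (rare species appear pooled with site ``Global``)."""
    with resources.as_file(_data_path("pac_mating_type_counts.tsv")) as p:
        df = pd.read_csv(p, sep="\t", keep_default_na=False)
    for col in ("n_strains", "n_mlh", "n_mat1_1", "n_mat1_2"):
        df[col] = df[col].astype(int)
    return df


def load_codon_model_fits() -> list[ModelFit]:
    """Published site-model fits for the three MAT genes (18 fits)."""
    with resources.as_file(_data_path("pac_mat_codeml_fits.tsv")) as p:
        return read_model_fits(p)


@dataclass(frozen=True)
class PublishedRatioReplay:
    results: list[RatioTestResult]
    summary: RatioSummary
    percent_nonsignificant: float


def replay_published_ratio_tests(
    sided: Sided = Sided.TWO_SIDED, alpha: float = 0.05
) -> PublishedRatioReplay:
    """Re-run exact binomial ratio tests on the packaged count table.

    A population counts as tested iff its published significance column is
    not ``"n.a."`` (the survey's own record of which populations were
    tested); the Bonferroni family is the full set of tested populations.
    """
    df = load_mating_type_counts()
    tested_mask = df["significance"].str.strip() != UNTESTED_FLAG
    family = TestFamily(m=int(tested_mask.sum()), alpha=alpha)
    results = []
    for _, row in df.iterrows():
        tested = row["significance"].strip() != UNTESTED_FLAG
        n1, n2 = int(row["n_mat1_1"]), int(row["n_mat1_2"])
        res = RatioTestResult(
            species=row["species"], site=row["site"],
            n_strains=int(row["n_strains"]), n_mlh=int(row["n_mlh"]),
            n_mat1_1=n1, n_mat1_2=n2, tested=tested,
        )
        if tested:
            p = exact_binomial_ratio_test(n1, n2, sided)
            res.p_value = p
            res.p_bonferroni = min(1.0, family.m * p)
        results.append(res)
    summary = summarize_ratio_tests(results, alpha=alpha)
    return PublishedRatioReplay(
        results=results,
        summary=summary,
        percent_nonsignificant=100.0 * summary.fraction_nonsignificant,
    )
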