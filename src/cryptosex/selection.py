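"""Likelihood-ratio tests between nested codon site models of MAT genes.

This module consumes externally fitted site-model results (CODEML-style:
log-likelihood, gene-wide dN/dS = omega, site-class mixtures) and computes
the standard nested comparisons:

    M0 (one ratio)     vs M3 (discrete)            df = 4
    M1a (nearly neutral) vs M2a (positive selection) df = 2
    M7 (beta)          vs M8 (beta & omega > 1)    df = 2

with 2*delta(lnL) referred to a chi-square upper tail.  M0-vs-M3 tests for
variable selective pressure among sites; M1a-vs-M2a and M7-vs-M8 test for
sites under positive selection (omega > 1).  Fitting the codon models
themselves is out of scope — that is what CODEML/PAML is for.
"""

from __future__ import annotations

import csv
import enum
import logging
from dataclasses import dataclass, field
from pathlib import Path

from scipy.stats import chi2

logger = logging.getLogger("cryptosex")


class Model(enum.Enum):
    M0 = "M0"
    M1a = "M1a"
    M2a = "M2a"
    M3 = "M3"
    M7 = "M7"
    M8 = "M8"


#: Sanctioned nested comparisons and their degrees of freedom.
LRT_PAIRS: dict[tuple[Model, Model], int] = {
    (Model.M0, Model.M3): 4,
    (Model.M1a, Model.M2a): 2,
    (Model.M7, Model.M8): 2,
}

#: Models whose site-class mixture must sum to one (M8 prints only the
#: positive class weight alongside its beta component).
_FULL_MIXTURE = {Model.M1a, Model.M2a, Model.M3}


@dataclass
class ModelFit:
    gene: str
    model: Model
    lnL: float
    n_params: int | None = None
    omega_overall: float | None = None
    site_classes: list[tuple[float, float]] = field(default_factory=list)
    beta_params: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.model in _FULL_MIXTURE and self.site_classes:
            total = sum(p for p, _ in self.site_classes)
            if abs(total - 1.0) > 1e-3:
                raise ValueError(
                    f"{self.gene}/{self.model.value}: site-class proportions "
                    f"sum to {total:.4f}, expected 1"
                )


@dataclass
class LrtResult:
    gene: str
    null_model: Model
    alt_model: Model
    two_delta_lambda: float
    df: int
    p_value: float
    significant: bool

    def report_row(self) -> dict:
        return {
            "gene": self.gene,
            "null": self.null_model.value,
            "alt": self.alt_model.value,
            "two_delta_lambda": self.two_delta_lambda,
            "df": self.df,
            "p": self.p_value,
            "significant": self.significant,
        }


_COLUMNS = ["gene", "model", "lnL", "np", "omega",
            "p0", "p1", "p2", "w0", "w1", "w2", "beta_p", "beta_q"]


def _opt_float(value: str | None) -> float | None:
    if value is None:
        return None
    value = value.strip()
    return None if value in ("", "NA") else float(value)


def read_model_fits(path: str | Path) -> list[ModelFit]:
    """Read a site-model fit table (TSV, one row per gene x model).

    Columns: gene, model, lnL, np, omega, p0..p2, w0..w2, beta_p, beta_q;
    empty cells mean "not part of this model".  Unknown model names and
    mixture proportions not summing to one are errors.
    """
    path = Path(path)
    fits: list[ModelFit] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for rownum, row in enumerate(reader, start=2):
            try:
                model = Model(row["model"])
            except ValueError:
                raise ValueError(
                    f"{path}: row {rownum}: unknown model {row['model']!r}"
                ) from None
            if row.get("lnL") in (None, ""):
                raise ValueError(f"{path}: row {rownum}: missing lnL")
            classes = []
            for i in range(3):
                p = _opt_float(row.get(f"p{i}", ""))
                w = _opt_float(row.get(f"w{i}", ""))
                if p is not None and w is not None:
                    classes.append((p, w))
            bp, bq = _opt_float(row.get("beta_p", "")), _opt_float(row.get("beta_q", ""))
            np_ = row.get("np", "")
            fits.append(
                ModelFit(
                    gene=row["gene"],
                    model=model,
                    lnL=float(row["lnL"]),
                    n_params=int(np_) if np_ not in ("", None) else None,
                    omega_overall=_opt_float(row.get("omega", "")),
                    site_classes=classes,
                    beta_params=(bp, bq) if bp is not None and bq is not None else None,
                )
            )
    return fits


def write_model_fits(fits: list[ModelFit], path: str | Path) -> None:
    """Write fits back in the table layout ``read_model_fits`` consumes."""
    with open(Path(path), "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(_COLUMNS)
        for f in fits:
            ps = [p for p, _ in f.site_classes] + [None] * (3 - len(f.site_classes))
            ws = [wv for _, wv in f.site_classes] + [None] * (3 - len(f.site_classes))
            bp, bq = f.beta_params if f.beta_params else (None, None)
            row = [f.gene, f.model.value, repr(f.lnL),
                   "" if f.n_params is None else f.n_params,
                   "" if f.omega_overall is None else repr(f.omega_overall)]
            row += ["" if v is None else repr(v) for v in (*ps, *ws, bp, bq)]
            w.writerow(row)


def lrt(null: ModelFit, alt: ModelFit, alpha: float = 0.05) -> LrtResult:
    """Likelihood-ratio test between a sanctioned nested model pair.

    2*delta(lnL) is floored at zero (independently converged fits can give
    a slightly negative raw difference, which is logged).
    """
    if null.gene != alt.gene:
        raise ValueError(f"gene mismatch: {null.gene!r} vs {alt.gene!r}")
    pair = (null.model, alt.model)
    if pair not in LRT_PAIRS:
        raise ValueError(
            f"unsanctioned model pair {null.model.value} vs {alt.model.value}"
        )
    df = LRT_PAIRS[pair]
    raw = 2.0 * (alt.lnL - null.lnL)
    if raw < 0:
        logger.warning(
            "%s %s vs %s: negative 2*delta(lnL) = %.6f floored at 0",
            null.gene, null.model.value, alt.model.value, raw,
        )
    stat = max(0.0, raw)
    p = float(chi2.sf(stat, df=df))
    return LrtResult(
        gene=null.gene, null_model=null.model, alt_model=alt.model,
        two_delta_lambda=stat, df=df, p_value=p, significant=p < alpha,
    )


def run_lrt_suite(fits: list[ModelFit], alpha: float = 0.05) -> list[LrtResult]:
    """All sanctioned LRTs for every gene with both models present."""
    by_key = {(f.gene, f.model): f for f in fits}
    genes = sorted({f.gene for f in fits})
    results = []
    for gene in genes:
        for (null_m, alt_m) in LRT_PAIRS:
            null, alt = by_key.get((gene, null_m)), by_key.get((gene, alt_m))
            if null is not None and alt is not None:
                results.append(lrt(null, alt, alpha=alpha))
    return results


@dataclass
class SelectionSummary:
    omega_min: float
    omega_max: float
    genes_with_variable_pressure: set[str]
    genes_with_positive_selection_support: set[str]
    positive_site_classes: list[tuple[str, float, float]]  # (gene, proportion, omega)

    def report_row(self) -> dict:
        return {
            "omega_min": self.omega_min,
            "omega_max": self.omega_max,
            "variable_pressure": ";".join(sorted(self.genes_with_variable_pressure)),
            "positive_selection": ";".join(sorted(self.genes_with_positive_selection_support)),
            "positive_site_classes": ";".join(
                f"{g}:{p:.4f}@{w:.4f}" for g, p, w in self.positive_site_classes
            ),
        }


def selection_summary(fits: list[ModelFit], lrts: list[LrtResult]) -> SelectionSummary:
    """Summarize selective pressure across genes.

    The gene-wide omega range is taken over all reported per-model dN/dS
    values, rounded to two decimals.  A gene shows "variable pressure" iff
    its M0-vs-M3 LRT is significant, and "positive selection support" iff
    M1a-vs-M2a or M7-vs-M8 is significant.  Positive site classes are the
    (proportion, omega) mixture components with omega > 1 from M2a and M8.
    """
    omegas = [f.omega_overall for f in fits if f.omega_overall is not None]
    if not omegas:
        raise ValueError("no gene-wide omega values in fits")
    variable = {
        r.gene for r in lrts
        if (r.null_model, r.alt_model) == (Model.M0, Model.M3) and r.significant
    }
    positive = {
        r.gene for r in lrts
        if (r.null_model, r.alt_model) in ((Model.M1a, Model.M2a), (Model.M7, Model.M8))
        and r.significant
    }
    classes = [
        (f.gene, p, w)
        for f in fits if f.model in (Model.M2a, Model.M8)
        for p, w in f.site_classes
        if w > 1.0 and p > 0.0
    ]
    return SelectionSummary(
        omega_min=round(min(omegas), 2),
        omega_max=round(max(omegas), 2),
        genes_with_variable_pressure=variable,
        genes_with_positive_selection_support=positive,
        positive_site_classes=sorted(classes),
    )
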