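"""Delimited-text input/output for genotype tables and analysis reports.

Genotype tables are long/wide delimited text: one row per isolate, fixed
metadata columns plus one column per locus.  Reports are sectioned TSV with
a fixed numeric format (four decimals) so repeated runs are byte-identical.
"""

from __future__ import annotations

import csv
import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Sequence

from .core import (
    MISSING,
    IsolateRecord,
    MarkerType,
    MatingType,
    PopulationDataset,
    SiteGeometry,
    group_into_populations,
    parse_mating_type,
)

logger = logging.getLogger("cryptosex")


@dataclass
class TableSchema:
    """Column-name mapping for genotype tables.

    ``locus_columns=None`` means "every column not otherwise claimed, in
    file order".  A two-column ``(grid_row, grid_col)`` address is accepted
    and flattened to ``row * n_cols + col``; the flat 0-based ``grid_point``
    form is the default.
    """

    strain_id: str = "strain_id"
    species: str = "species"
    site: str = "site"
    grid_point: str = "grid_point"
    grid_row: str | None = None
    grid_col: str | None = None
    grid_n_cols: int = 1
    mating_type: str = "mating_type"
    locus_columns: Sequence[str] | None = None
    missing: str = MISSING

    def meta_columns(self) -> list[str]:
        cols = [self.strain_id, self.species, self.site, self.mating_type]
        if self.grid_row and self.grid_col:
            cols += [self.grid_row, self.grid_col]
        else:
            cols.append(self.grid_point)
        return cols


def _delimiter_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_genotype_table(
    path: str | Path,
    schema: TableSchema | None = None,
    geometries: dict[str, SiteGeometry] | None = None,
    marker_type: MarkerType = MarkerType.MICROSAT,
) -> list[PopulationDataset]:
    """Read a genotype table and group rows into populations.

    Every input row becomes exactly one isolate or raises with its row
    number; ragged rows (wrong field count) are an error, not silent
    missing data.
    """
    path = Path(path)
    schema = schema or TableSchema()
    delim = _delimiter_for(path)
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter=delim)
        try:
            header = next(reader)
        except StopIteration:
            raise ValueError(f"{path}: empty file") from None
        rows = list(reader)

    idx = {name: i for i, name in enumerate(header)}
    for col in schema.meta_columns():
        if col not in idx:
            raise ValueError(f"{path}: missing required column {col!r}")
    if schema.locus_columns is None:
        claimed = set(schema.meta_columns())
        locus_cols = [c for c in header if c not in claimed]
    else:
        locus_cols = list(schema.locus_columns)
        for col in locus_cols:
            if col not in idx:
                raise ValueError(f"{path}: missing locus column {col!r}")
    if not locus_cols:
        raise ValueError(f"{path}: no locus columns found")

    isolates: list[IsolateRecord] = []
    for rownum, row in enumerate(rows, start=2):  # 1-based incl. header
        if not row or all(f == "" for f in row):
            continue
        if len(row) != len(header):
            raise ValueError(
                f"{path}: row {rownum} has {len(row)} fields, header has {len(header)}"
            )
        try:
            mat = parse_mating_type(row[idx[schema.mating_type]])
        except ValueError as exc:
            raise ValueError(f"{path}: row {rownum}: {exc}") from None
        if schema.grid_row and schema.grid_col:
            gp: int | None = (
                int(row[idx[schema.grid_row]]) * schema.grid_n_cols
                + int(row[idx[schema.grid_col]])
            )
        else:
            raw_gp = row[idx[schema.grid_point]]
            gp = None if raw_gp in ("", schema.missing) else int(raw_gp)
        genotype = tuple(
            MISSING if row[idx[c]] in ("", schema.missing) else row[idx[c]]
            for c in locus_cols
        )
        isolates.append(
            IsolateRecord(
                strain_id=row[idx[schema.strain_id]],
                species=row[idx[schema.species]],
                site=row[idx[schema.site]],
                mating_type=mat,
                genotype=genotype,
                grid_point=gp,
            )
        )
    pops = group_into_populations(isolates, locus_cols, geometries, marker_type)
    logger.info("read %d isolates into %d populations from %s", len(isolates), len(pops), path)
    return pops


def write_genotype_table(
    pops: Iterable[PopulationDataset], path: str | Path, schema: TableSchema | None = None
) -> None:
    """Write populations back to the standard genotype-table layout."""
    path = Path(path)
    schema = schema or TableSchema()
    pops = list(pops)
    if not pops:
        raise ValueError("no populations to write")
    locus_names = pops[0].locus_names
    for p in pops:
        if p.locus_names != locus_names:
            raise ValueError("populations disagree on locus panel")
    delim = _delimiter_for(path)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter=delim, lineterminator="\n")
        w.writerow(
            [schema.strain_id, schema.species, schema.site, schema.mating_type,
             schema.grid_point, *locus_names]
        )
        for pop in pops:
            for iso in pop.isolates:
                w.writerow(
                    [iso.strain_id, iso.species, iso.site, iso.mating_type.value,
                     "" if iso.grid_point is None else iso.grid_point,
                     *(schema.missing if a == MISSING else a for a in iso.genotype)]
                )


# ---------------------------------------------------------------------------
# report writing

def _fmt(x: Any) -> str:
    if x is None:
        return "n.a."
    if isinstance(x, bool):
        return str(x).lower()
    if isinstance(x, float):
        return f"{x:.4f}"
    return str(x)


def write_report(results: Sequence[Any], path: str | Path) -> None:
    """Write a sectioned TSV report, one section per result type.

    Each result object must provide ``report_row()`` returning an ordered
    ``dict``; p-values and statistics are printed with four decimals so a
    re-read reproduces the stored numbers to printed precision.
    """
    results = list(results)
    if not results:
        raise ValueError("no results to report")
    sections: dict[str, list[Any]] = {}
    for r in results:
        sections.setdefault(type(r).__name__, []).append(r)
    with open(Path(path), "w", newline="") as fh:
        for name in sorted(sections):
            rows = [r.report_row() for r in sections[name]]
            fh.write(f"# section: {name}\n")
            cols = list(rows[0])
            fh.write("\t".join(cols) + "\n")
            for row in rows:
                fh.write("\t".join(_fmt(row[c]) for c in cols) + "\n")


def read_report(path: str | Path) -> dict[str, list[dict[str, str]]]:
    """Re-read a sectioned report into ``{section: [row dicts]}``."""
    sections: dict[str, list[dict[str, str]]] = {}
    current: str | None = None
    header: list[str] | None = None
    for line in Path(path).read_text().splitlines():
        if line.startswith("# section: "):
            current = line.removeprefix("# section: ")
            sections[current] = []
            header = None
        elif current is not None and header is None:
            header = line.split("\t")
        elif current is not None and header is not None and line:
            sections[current].append(dict(zip(header, line.split("\t"))))
    return sections


def read_config(path: str | Path) -> dict[str, str]:
    """Parse a plain ``key: value`` configuration file.

    Blank lines and ``#`` comments are ignored; later keys win.
    """
    cfg: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if ":" not in line:
            raise ValueError(f"{path}: line {lineno}: expected 'key: value'")
        key, value = line.split(":", 1)
        cfg[key.strip()] = value.strip()
    return cfg


def substream_seed(key: str, seed: int) -> int:
    """Derive a reproducible per-population seed from a global seed.

    Hashing decouples each population's random stream from execution
    order, so parallel or reordered runs give identical per-population
    results.
    """
    digest = hashlib.sha256(f"{key}|{seed}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)
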