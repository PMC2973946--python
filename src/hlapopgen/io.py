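"""Readers and writers for the delimited-text artifacts of the pipeline.

Genotype tables are TSV/CSV with a ``sample_id`` column followed by two
columns per locus (``A_1``, ``A_2``, ...).  Frequency tables are TSV with
``locus``, ``allele`` and either a full-precision ``frequency`` proportion
or a 2-decimal ``percent`` column (the convention of published HLA
frequency reports, where every value is an integer count over 2N).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from fractions import Fraction
from numbers import Rational
from pathlib import Path
from typing import Mapping

import pandas as pd

from .datatypes import FrequencyTable, Individual, PopulationSample, make_individual
from .nomenclature import parse_allele_name

__all__ = [
    "round_half_up",
    "read_genotype_table",
    "write_genotype_table",
    "read_frequency_tables",
    "write_frequency_tables",
    "reconstruct_counts",
    "CountReconstruction",
    "write_phylip_matrix",
]

MISSING = "NA"


def round_half_up(x, ndigits: int = 0) -> float:
    """Round with ties away from zero at *ndigits* decimals.

    Exact inputs (Fraction, Decimal, int) are rounded exactly; floats go
    through their shortest decimal repr so that values like ``2.405`` behave
    as printed rather than as binary doubles.
    """
    if isinstance(x, Rational) and not isinstance(x, int):
        d = Decimal(x.numerator) / Decimal(x.denominator)
    elif isinstance(x, Decimal):
        d = x
    else:
        d = Decimal(str(x))
    q = Decimal(1).scaleb(-ndigits)
    return float(d.quantize(q, rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# genotype tables


def _detect_sep(header_line: str) -> str:
    return "\t" if "\t" in header_line else ","


def read_genotype_table(path: str | Path) -> PopulationSample:
    """Read a delimited genotype table into a :class:`PopulationSample`.

    The delimiter (tab or comma) is auto-detected from the header line.
    Allele cells may carry the locus prefix (``A*0101``) or the bare
    four-digit code; ``NA`` in both columns of a locus marks that
    individual untyped there.
    """
    path = Path(path)
    with path.open() as fh:
        header_line = fh.readline()
    if not header_line.strip():
        raise ValueError(f"{path}: no individuals (empty file)")
    sep = _detect_sep(header_line)
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    if df.empty:
        raise ValueError(f"{path}: no individuals")
    cols = list(df.columns)
    if cols[0] != "sample_id":
        raise ValueError(f"{path}: first column must be 'sample_id', got {cols[0]!r}")
    allele_cols = cols[1:]
    if len(allele_cols) % 2 != 0:
        raise ValueError(f"{path}: odd number of allele columns ({len(allele_cols)})")
    loci: list[str] = []
    for i in range(0, len(allele_cols), 2):
        c1, c2 = allele_cols[i], allele_cols[i + 1]
        if not (c1.endswith("_1") and c2.endswith("_2") and c1[:-2] == c2[:-2]):
            raise ValueError(f"{path}: columns {c1!r},{c2!r} are not a <LOCUS>_1/_2 pair")
        loci.append(c1[:-2])

    individuals: list[Individual] = []
    for row_idx, row in df.iterrows():
        pairs: list[tuple[str, str] | None] = []
        for locus in loci:
            raw = (row[f"{locus}_1"].strip(), row[f"{locus}_2"].strip())
            if MISSING in raw:
                if raw != (MISSING, MISSING):
                    raise ValueError(
                        f"{path}: row {row_idx + 2}, locus {locus}: half-missing genotype"
                    )
                pairs.append(None)
                continue
            codes = []
            for col_suffix, cell in zip(("_1", "_2"), raw):
                try:
                    codes.append(parse_allele_name(cell, locus=locus).code)
                except ValueError as exc:
                    raise ValueError(
                        f"{path}: row {row_idx + 2}, column {locus}{col_suffix}: {exc}"
                    ) from exc
            pairs.append((codes[0], codes[1]))
        individuals.append(make_individual(str(row["sample_id"]), loci, pairs))
    return PopulationSample(loci=tuple(loci), individuals=individuals)


def write_genotype_table(sample: PopulationSample, path: str | Path, sep: str = "\t") -> None:
    rows = []
    for ind in sample.individuals:
        row: dict[str, str] = {"sample_id": ind.sample_id}
        for locus in sample.loci:
            g = ind.genotype(locus)
            row[f"{locus}_1"], row[f"{locus}_2"] = g if g is not None else (MISSING, MISSING)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# frequency tables


def read_frequency_tables(
    path: str | Path, tol: float = 1e-6
) -> dict[str, FrequencyTable]:
    """Read a TSV of per-locus allele frequencies, one table per locus.

    A ``frequency`` column is taken at full precision; otherwise a
    ``percent`` column is parsed exactly as a decimal and divided by 100.
    Each locus must sum to 1 within *tol* (widened to the worst-case
    rounding error for percent tables).
    """
    df = pd.read_csv(path, sep="\t", dtype={"locus": str, "allele": str})
    if df.empty:
        raise ValueError(f"{path}: empty frequency table")
    percent_mode = "frequency" not in df.columns
    if percent_mode and "percent" not in df.columns:
        raise ValueError(f"{path}: need a 'frequency' or 'percent' column")
    out: dict[str, FrequencyTable] = {}
    for locus, sub in df.groupby("locus", sort=False):
        entries: dict[str, Fraction | float] = {}
        for _, row in sub.iterrows():
            allele = parse_allele_name(str(row["allele"]), locus=str(locus)).code
            if percent_mode:
                entries[allele] = Fraction(Decimal(str(row["percent"]))) / 100
            else:
                entries[allele] = float(row["frequency"])
        # a percent printed to 2 decimals is off by at most 0.005% per entry
        eff_tol = max(tol, 5e-5 * len(entries)) if percent_mode else tol
        table = FrequencyTable(locus=str(locus), entries=entries)
        s = table.total()
        if abs(s - 1.0) > eff_tol:
            raise ValueError(f"{path}: locus {locus} frequencies sum to {s:.6f}, not 1")
        out[str(locus)] = table
    return out


def write_frequency_tables(
    tables: Mapping[str, FrequencyTable] | FrequencyTable,
    path: str | Path,
    percent: bool = False,
) -> None:
    """Write frequency tables as TSV; ``percent=True`` adds a 2-decimal
    percent column (round-half-up) alongside the full-precision proportion."""
    if isinstance(tables, FrequencyTable):
        tables = {tables.locus: tables}
    rows = []
    for locus, table in tables.items():
        for allele, f in table.entries.items():
            row = {"locus": locus, "allele": allele, "frequency": repr(float(f))}
            if percent:
                row["percent"] = f"{round_half_up(100 * Fraction(f) if isinstance(f, Rational) else 100 * f, 2):.2f}"
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# count reconstruction


@dataclass
class CountReconstruction:
    """Integer gene-copy counts recovered from a (possibly rounded) table."""

    counts: dict[str, int]
    gene_copies: int
    roundtrip_failures: list[str]

    @property
    def roundtrip_ok(self) -> bool:
        return not self.roundtrip_failures


def reconstruct_counts(
    table: FrequencyTable, gene_copies: int | None = None
) -> CountReconstruction:
    """Recover integer allele counts as round-half-up(freq x 2N).

    Published HLA frequency tables print ``count / 2N`` rounded to two
    percent decimals; multiplying back by 2N and rounding half-up recovers
    the counts.  Each count is validated by re-deriving its 2-decimal
    percent; alleles failing the round trip are reported in a warning but do
    not abort.
    """
    if gene_copies is None:
        gene_copies = table.source_gene_copies
    if gene_copies is None or gene_copies < 1:
        raise ValueError("gene_copies must be a positive integer")
    counts: dict[str, int] = {}
    failures: list[str] = []
    for allele, f in table.entries.items():
        exact = Fraction(f) if isinstance(f, Rational) else Fraction(str(f))
        c = int(round_half_up(exact * gene_copies))
        counts[allele] = c
        if round_half_up(Fraction(100 * c, gene_copies), 2) != round_half_up(100 * exact, 2):
            failures.append(allele)
    if failures:
        warnings.warn(
            f"locus {table.locus}: counts for {failures} do not round-trip to the "
            f"input frequencies",
            stacklevel=2,
        )
    return CountReconstruction(counts=counts, gene_copies=gene_copies, roundtrip_failures=failures)


# ---------------------------------------------------------------------------
# distance matrices


def write_phylip_matrix(dm, path: str | Path) -> None:
    """Write a square PHYLIP-style distance matrix."""
    lines = [f"{len(dm.labels)}"]
    for label, row in zip(dm.labels, dm.values):
        cells = " ".join(f"{v:.6f}" for v in row)
        lines.append(f"{label:<12s}{cells}")
    Path(path).write_text("\n".join(lines) + "\n")
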