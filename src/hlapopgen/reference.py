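"""Bundled published reference tables for the Uyghur study population.

Three small TSVs ship with the package, transcribed from the published
population report of 104 unrelated Uyghur individuals (Yining city,
Xinjiang) typed at HLA-A, -B and -DRB1 by sequence-based typing:

* per-locus allele frequencies (2-decimal percents, all equal to an
  integer count over 2N = 208 gene copies);
* the two-locus haplotype LD table (HF, D, Dmax, D' as printed);
* the per-locus forensic-parameter table (HO, HE, PD, PIC, PPE, HWE p).

These printed values are the deterministic inputs the package's identity
checks recompute from; the study's raw genotypes were never deposited.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import pandas as pd

from .datatypes import FrequencyTable
from .io import read_frequency_tables

__all__ = [
    "uyghur_allele_frequencies",
    "uyghur_ld_table",
    "uyghur_forensic_table",
    "UYGHUR_N",
    "UYGHUR_GENE_COPIES",
]

UYGHUR_N = 104
UYGHUR_GENE_COPIES = 2 * UYGHUR_N


def _data_path(name: str):
    return resources.files("hlapopgen").joinpath("data", name)


def uyghur_allele_frequencies() -> dict[str, FrequencyTable]:
    """Published allele-frequency tables, one per locus, exact percents."""
    with resources.as_file(_data_path("uyghur_allele_frequencies.tsv")) as p:
        return read_frequency_tables(p)


def uyghur_ld_table() -> pd.DataFrame:
    """Published two-locus LD table (percent columns as printed)."""
    with resources.as_file(_data_path("uyghur_two_locus_ld.tsv")) as p:
        return pd.read_csv(p, sep="\t", dtype={"allele1": str, "allele2": str})


def uyghur_forensic_table() -> pd.DataFrame:
    """Published forensic parameters per locus."""
    with resources.as_file(_data_path("uyghur_forensic_parameters.tsv")) as p:
        return pd.read_csv(p, sep="\t")
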