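"""Counting estimators: allele frequencies, family aggregates, heterozygosity.

Everything here is plain gene counting over the 2N' non-missing gene copies
at a locus, kept in exact rational arithmetic so that totals close exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from numbers import Rational
from typing import Iterable

from .datatypes import FrequencyTable, PopulationSample

__all__ = [
    "allele_frequencies",
    "family_frequencies",
    "cumulative_frequency",
    "heterozygosity",
    "top_alleles",
    "LocusSummary",
    "locus_summary",
]


def allele_frequencies(sample: PopulationSample, locus: str) -> FrequencyTable:
    """Counting allele frequencies: copies of each allele over 2N' copies.

    Individuals missing at *locus* are excluded from that locus only.
    """
    counts = sample.allele_counts(locus)
    if not counts:
        raise ValueError(f"no individuals typed at locus {locus!r}")
    return FrequencyTable.from_counts(locus, counts)


def family_frequencies(freq: FrequencyTable) -> dict[str, Fraction | float]:
    """Aggregate four-digit frequencies into two-digit allele families.

    Families (serological groups) partition the table, so the family values
    sum to 1 exactly like the input.
    """
    out: dict[str, Fraction | float] = {}
    for allele, f in freq.entries.items():
        fam = allele[:2]
        out[fam] = out.get(fam, 0) + f
    return dict(sorted(out.items()))


def cumulative_frequency(freq: FrequencyTable, alleles: Iterable[str]) -> Fraction | float:
    """Exact sum of the listed alleles' frequencies."""
    total: Fraction | float = 0
    for a in alleles:
        if a not in freq.entries:
            raise KeyError(f"allele {a!r} not in table for locus {freq.locus!r}")
        total = total + freq.entries[a]
    return total


def top_alleles(freq: FrequencyTable, k: int) -> list[str]:
    """The k most frequent alleles; ties broken by name for determinism."""
    return [a for a, _ in sorted(freq.entries.items(), key=lambda kv: (-kv[1], kv[0]))[:k]]


def heterozygosity(sample: PopulationSample, locus: str) -> tuple[float, float, float]:
    """(HO, HE_biased, HE_unbiased) at one locus.

    HO is the heterozygote proportion among the N' typed individuals.
    HE_biased = 1 - sum p_i^2; the unbiased variant rescales by 2N'/(2N'-1).
    """
    typed = sample.typed_individuals([locus])
    if not typed:
        raise ValueError(f"no individuals typed at locus {locus!r}")
    n = len(typed)
    het = sum(1 for ind in typed if ind.genotype(locus)[0] != ind.genotype(locus)[1])
    ho = het / n
    freq = allele_frequencies(sample, locus)
    he_biased = float(1 - sum(Fraction(f) ** 2 if isinstance(f, Rational) else f * f
                              for f in freq.entries.values()))
    two_n = 2 * n
    he_unbiased = he_biased if two_n <= 1 else two_n / (two_n - 1) * he_biased
    return ho, he_biased, he_unbiased


@dataclass
class LocusSummary:
    """Per-locus roll-up: allele count, frequencies and heterozygosity."""

    locus: str
    n_alleles: int
    freq: FrequencyTable
    ho: float
    he_biased: float
    he_unbiased: float


def locus_summary(sample: PopulationSample, locus: str) -> LocusSummary:
    freq = allele_frequencies(sample, locus)
    ho, he_b, he_u = heterozygosity(sample, locus)
    return LocusSummary(
        locus=locus,
        n_alleles=len(freq),
        freq=freq,
        ho=ho,
        he_biased=he_b,
        he_unbiased=he_u,
    )
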