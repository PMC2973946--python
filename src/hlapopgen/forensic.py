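"""Forensic informativeness statistics per locus and combined across loci.

Definitions (p_i are allele frequencies, G_g observed genotype proportions):

    PM  = sum_g G_g^2          match probability between two random people
    PD  = 1 - PM               power of discrimination
    PIC = 1 - sum p_i^2 - (sum p_i^2)^2 + sum p_i^4
                               polymorphism information content (Botstein)
    PPE = h^2 (1 - 2 h H^2),  H = 1 - h
                               probability of paternity exclusion from a
                               heterozygosity h
    CPM = prod PM;  CPD = 1 - CPM;  CPE = 1 - prod (1 - PPE)

PPE takes heterozygosity as an explicit argument because published tables
differ in whether observed or expected heterozygosity is plugged in; PM/PD
on genotype data use observed genotype frequencies.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from numbers import Rational
from typing import Sequence

from .allele_stats import allele_frequencies, heterozygosity
from .datatypes import FrequencyTable, PopulationSample

__all__ = [
    "matching_probability",
    "pic",
    "ppe",
    "combined_measures",
    "LocusForensics",
    "ForensicReport",
    "forensic_report",
]


def matching_probability(sample: PopulationSample, locus: str) -> tuple[float, float]:
    """(PM, PD) from observed genotype proportions at one locus."""
    counts = sample.genotype_counts(locus)
    n = sum(counts.values())
    if n == 0:
        raise ValueError(f"no individuals typed at locus {locus!r}")
    pm = float(sum(Fraction(c, n) ** 2 for c in counts.values()))
    return pm, 1.0 - pm


def pic(freq: FrequencyTable) -> float:
    """Polymorphism information content of a locus.

    Computed exactly when the table holds rational (count-based)
    frequencies.
    """
    freq.validate_sum(tol=5e-3)
    vals = [Fraction(f) if isinstance(f, Rational) else float(f) for f in freq.entries.values()]
    s2 = sum(v * v for v in vals)
    s4 = sum(v**4 for v in vals)
    return float(1 - s2 - s2 * s2 + s4)


def ppe(h: float) -> float:
    """Probability of paternity exclusion from heterozygosity h."""
    if not (0 <= h <= 1):
        raise ValueError(f"heterozygosity outside [0, 1]: {h}")
    big_h = 1.0 - h
    return h * h * (1.0 - 2.0 * h * big_h * big_h)


def combined_measures(
    pm_values: Sequence[float], ppe_values: Sequence[float]
) -> tuple[float, float, float]:
    """(CPM, CPD, CPE) across independent loci."""
    if not pm_values or not ppe_values:
        raise ValueError("need at least one locus")
    cpm = 1.0
    for v in pm_values:
        cpm *= v
    cpe = 1.0
    for v in ppe_values:
        cpe *= 1.0 - v
    return cpm, 1.0 - cpm, 1.0 - cpe


@dataclass
class LocusForensics:
    locus: str
    ho: float
    he_biased: float
    he_unbiased: float
    pm: float
    pd: float
    pic: float
    ppe_observed: float  # PPE with h = HO
    ppe_expected: float  # PPE with h = HE (biased)
    hwe_p: float | None = None


@dataclass
class ForensicReport:
    loci: list[LocusForensics]
    cpm: float
    cpd: float
    cpe: float


def forensic_report(
    sample: PopulationSample,
    loci: Sequence[str] | None = None,
    hwe_p: dict[str, float] | None = None,
    use_expected_h_for_cpe: bool = True,
) -> ForensicReport:
    """Full per-locus battery plus combined measures.

    Both PPE variants are reported (h = HO and h = HE) since conventions
    differ; the combined CPE uses the expected-heterozygosity variant by
    default.
    """
    loci = list(loci) if loci is not None else list(sample.loci)
    rows: list[LocusForensics] = []
    for locus in loci:
        ho, he_b, he_u = heterozygosity(sample, locus)
        pm, pd_ = matching_probability(sample, locus)
        rows.append(
            LocusForensics(
                locus=locus,
                ho=ho,
                he_biased=he_b,
                he_unbiased=he_u,
                pm=pm,
                pd=pd_,
                pic=pic(allele_frequencies(sample, locus)),
                ppe_observed=ppe(ho),
                ppe_expected=ppe(he_b),
                hwe_p=(hwe_p or {}).get(locus),
            )
        )
    ppe_vals = [r.ppe_expected if use_expected_h_for_cpe else r.ppe_observed for r in rows]
    cpm, cpd, cpe = combined_measures([r.pm for r in rows], ppe_vals)
    return ForensicReport(loci=rows, cpm=cpm, cpd=cpd, cpe=cpe)
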