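"""Two-locus linkage-disequilibrium decomposition per haplotype.

For a haplotype carrying allele A (frequency pA) at one locus and B (pB)
at the other, with haplotype frequency f_AB:

    D     = f_AB - pA * pB                       (absolute LD)
    Dmax  = min(pA (1-pB), pB (1-pA))  if D >= 0 (maximal LD given margins)
          = min(pA pB, (1-pA)(1-pB))   if D < 0
    D'    = D / Dmax                             (relative LD, in [-1, 1])

D' = 1 exactly when f_AB attains its upper bound min(pA, pB); Dmax = 0
(a fixed allele at either locus) is flagged degenerate and D' set to 0 by
convention.  Exact rational inputs give exact rational outputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from numbers import Rational

from .datatypes import FrequencyTable, HaplotypeTable

__all__ = ["LDRecord", "ld_two_locus", "ld_table"]

_CONSISTENCY_TOL = 1e-6


@dataclass
class LDRecord:
    """One haplotype's (HF, D, Dmax, D') quadruple with its margins."""

    haplotype: tuple[str, str]
    hf: float
    pa: float
    pb: float
    d: float
    dmax: float
    dprime: float
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not self.degenerate and not (-1 - 1e-12 <= self.dprime <= 1 + 1e-12):
            raise ValueError(f"D' outside [-1, 1]: {self.dprime}")


def _exactify(x) -> Fraction | float:
    return Fraction(x) if isinstance(x, Rational) else float(x)


def ld_two_locus(
    hf, pa, pb, haplotype: tuple[str, str] = ("?", "?"), tol: float = _CONSISTENCY_TOL
) -> LDRecord:
    """Decompose one haplotype's LD into (D, Dmax, D').

    Inputs may be floats or exact rationals (e.g. counts over 2N); exact
    inputs are decomposed exactly before conversion to float for storage.
    """
    hf, pa, pb = _exactify(hf), _exactify(pa), _exactify(pb)
    for name, v in (("HF", hf), ("pA", pa), ("pB", pb)):
        if not (0 <= v <= 1):
            raise ValueError(f"{name} outside [0, 1]: {v}")
    if hf > min(pa, pb) + tol:
        raise ValueError(
            f"haplotype frequency {float(hf):.6f} exceeds min(pA, pB) = "
            f"{float(min(pa, pb)):.6f}: inconsistent inputs"
        )
    d = hf - pa * pb
    if d >= 0:
        dmax = min(pa * (1 - pb), pb * (1 - pa))
    else:
        dmax = min(pa * pb, (1 - pa) * (1 - pb))
    degenerate = dmax == 0
    dprime = 0.0 if degenerate else d / dmax
    return LDRecord(
        haplotype=haplotype,
        hf=float(hf),
        pa=float(pa),
        pb=float(pb),
        d=float(d),
        dmax=float(dmax),
        dprime=float(dprime),
        degenerate=degenerate,
    )


def ld_table(
    hap_table: HaplotypeTable,
    freq1: FrequencyTable,
    freq2: FrequencyTable,
) -> list[LDRecord]:
    """LD records for every positive-frequency haplotype of a 2-locus table.

    The two frequency tables must be the marginals of the haplotype table
    (within 1e-6) — automatic when both come from the same sample.  Records
    are sorted by D' descending, then HF descending, then haplotype name.
    """
    if len(hap_table.loci) != 2:
        raise ValueError("ld_table needs a 2-locus haplotype table")
    if (freq1.locus, freq2.locus) != hap_table.loci:
        raise ValueError(
            f"frequency tables {freq1.locus, freq2.locus} do not match "
            f"haplotype loci {hap_table.loci}"
        )
    for freq, locus in ((freq1, hap_table.loci[0]), (freq2, hap_table.loci[1])):
        marg = hap_table.marginal(locus)
        for allele, f in marg.items():
            if abs(f - float(freq.entries.get(allele, 0))) > _CONSISTENCY_TOL:
                raise ValueError(
                    f"marginal of {locus}*{allele} ({f:.6f}) disagrees with the "
                    f"frequency table ({float(freq.entries.get(allele, 0)):.6f})"
                )
    records = []
    for (a, b), hf in hap_table.entries.items():
        if hf <= 0:
            continue
        records.append(
            ld_two_locus(hf, freq1.entries[a], freq2.entries[b], haplotype=(a, b))
        )
    records.sort(key=lambda r: (-r.dprime, -r.hf, r.haplotype))
    return records
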