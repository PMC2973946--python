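"""Core containers shared by every analysis stage.

All frequencies are stored as proportions in ``[0, 1]``; percent rendering
happens only at I/O edges.  Counting estimators keep exact
:class:`fractions.Fraction` values so that sums close exactly; anything
downstream may treat entries as plain numbers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction
from numbers import Rational
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "Genotype",
    "Individual",
    "PopulationSample",
    "FrequencyTable",
    "HaplotypeTable",
    "DistanceMatrix",
]

#: An unordered pair of allele codes at one locus, stored sorted.
Genotype = tuple[str, str]


def _as_genotype(pair: Iterable[str]) -> Genotype:
    a, b = pair
    return (a, b) if a <= b else (b, a)


@dataclass(frozen=True)
class Individual:
    """One sampled diploid individual: id plus unordered allele pairs.

    ``genotypes[locus]`` is ``None`` when the individual was not typed at
    that locus; such individuals are excluded from that locus only.
    """

    sample_id: str
    genotypes: Mapping[str, Genotype | None]

    def genotype(self, locus: str) -> Genotype | None:
        return self.genotypes.get(locus)

    def is_complete(self, loci: Sequence[str]) -> bool:
        return all(self.genotypes.get(l) is not None for l in loci)


@dataclass
class PopulationSample:
    """N unrelated diploid individuals typed at L loci (unphased calls).

    2N gene copies per fully typed locus is the denominator of every
    counting estimate.
    """

    loci: tuple[str, ...]
    individuals: list[Individual]

    def __post_init__(self) -> None:
        if len(self.individuals) < 1:
            raise ValueError("a population sample needs at least one individual")
        seen: set[str] = set()
        for ind in self.individuals:
            if ind.sample_id in seen:
                raise ValueError(f"duplicate sample_id {ind.sample_id!r}")
            seen.add(ind.sample_id)

    @property
    def n(self) -> int:
        return len(self.individuals)

    def typed_individuals(self, loci: Sequence[str]) -> list[Individual]:
        """Individuals complete at every locus in *loci*."""
        missing = [l for l in loci if l not in self.loci]
        if missing:
            raise KeyError(f"loci not in sample: {missing}")
        return [ind for ind in self.individuals if ind.is_complete(loci)]

    def genotype_counts(self, locus: str) -> dict[Genotype, int]:
        """Multiplicity of each observed unordered genotype at *locus*."""
        counts: dict[Genotype, int] = {}
        for ind in self.typed_individuals([locus]):
            g = ind.genotype(locus)
            assert g is not None
            counts[g] = counts.get(g, 0) + 1
        return counts

    def allele_counts(self, locus: str) -> dict[str, int]:
        """Gene-copy count of each allele at *locus* (sums to 2N')."""
        counts: dict[str, int] = {}
        for g, k in self.genotype_counts(locus).items():
            for a in g:
                counts[a] = counts.get(a, 0) + k
        return counts


@dataclass
class FrequencyTable:
    """Allele -> relative frequency at one locus.

    ``source_gene_copies`` records the 2N behind a counting estimate and
    enables exact count reconstruction for tables loaded from rounded
    percentages.
    """

    locus: str
    entries: dict[str, Fraction | float]
    source_gene_copies: int | None = None

    def __post_init__(self) -> None:
        for allele, f in self.entries.items():
            if not (0 <= f <= 1):
                raise ValueError(f"frequency of {allele!r} outside [0, 1]: {f}")

    def total(self) -> float:
        return float(sum(self.entries.values()))

    def validate_sum(self, tol: float = 1e-9) -> None:
        s = self.total()
        if abs(s - 1.0) > tol:
            raise ValueError(f"frequencies at locus {self.locus!r} sum to {s}, not 1")

    def __getitem__(self, allele: str) -> float:
        return float(self.entries[allele])

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    @property
    def is_exact(self) -> bool:
        """True when every entry is rational (counting estimate)."""
        return all(isinstance(f, Rational) for f in self.entries.values())

    @classmethod
    def from_counts(cls, locus: str, counts: Mapping[str, int]) -> "FrequencyTable":
        total = sum(counts.values())
        if total <= 0:
            raise ValueError(f"no gene copies at locus {locus!r}")
        entries = {a: Fraction(c, total) for a, c in sorted(counts.items())}
        return cls(locus=locus, entries=entries, source_gene_copies=total)


#: A multi-locus haplotype: one allele code per locus, in locus order.
Haplotype = tuple[str, ...]


@dataclass
class HaplotypeTable:
    """Haplotype-frequency estimates at a tuple of loci, with EM diagnostics."""

    loci: tuple[str, ...]
    entries: dict[Haplotype, float]
    log_likelihood: float = math.nan
    n_iterations: int = 0
    converged: bool = True
    significant: dict[Haplotype, bool] = field(default_factory=dict)
    #: observed-data log-likelihood after each E-step (non-decreasing for EM)
    loglik_history: list[float] = field(default_factory=list)

    def validate_sum(self, tol: float = 1e-9) -> None:
        s = sum(self.entries.values())
        if abs(s - 1.0) > tol:
            raise ValueError(f"haplotype frequencies sum to {s}, not 1")

    def marginal(self, locus: str) -> dict[str, float]:
        """Single-locus allele frequencies implied by the haplotype table."""
        i = self.loci.index(locus)
        out: dict[str, float] = {}
        for hap, f in self.entries.items():
            out[hap[i]] = out.get(hap[i], 0.0) + f
        return out


@dataclass
class DistanceMatrix:
    """Square symmetric matrix of pairwise population distances."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match label count")
        if not np.allclose(self.values, self.values.T, equal_nan=True):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.values), 0.0):
            raise ValueError("distance matrix diagonal is not zero")

    @property
    def finite(self) -> np.ndarray:
        """Boolean mask of finite cells (Nei distance is infinite when two
        populations share no alleles)."""
        return np.isfinite(self.values)

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i = self.labels.index(pair[0])
        j = self.labels.index(pair[1])
        return float(self.values[i, j])


def make_individual(
    sample_id: str, loci: Sequence[str], pairs: Sequence[Iterable[str] | None]
) -> Individual:
    """Convenience constructor pairing *loci* with unordered allele pairs."""
    genos = {
        locus: (None if pair is None else _as_genotype(pair))
        for locus, pair in zip(loci, pairs, strict=True)
    }
    return Individual(sample_id=sample_id, genotypes=genos)
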