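"""Synthetic diploid populations with known haplotype-frequency truth.

Each individual draws two haplotypes i.i.d. from a specified spectrum;
with probability F the second draw is replaced by a copy of the first,
which inflates homozygosity exactly like an inbreeding coefficient and
gives a controllable Hardy-Weinberg departure (F = 0 is random mating).
Phase is then discarded, producing the unphased genotype tables every
estimator in this package consumes.  Because the spectrum fixes both the
allele margins and the haplotype composition, LD and HWE truth are known
exactly and estimator recovery can be tested without any real genotypes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from .datatypes import Haplotype, Individual, PopulationSample, make_individual

__all__ = ["SimulationSpec", "simulate_population", "uyghur_like_fixture"]


@dataclass
class SimulationSpec:
    """Conditions for one simulated sample.

    spectrum maps haplotypes (one allele code per locus) to frequencies
    summing to 1; F in [0, 1] is the HWE-distortion (inbreeding-like)
    parameter.
    """

    loci: tuple[str, ...]
    spectrum: dict[Haplotype, float]
    n_individuals: int
    f_inbreeding: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_individuals < 1:
            raise ValueError("need at least one individual")
        if not (0 <= self.f_inbreeding <= 1):
            raise ValueError("F must be in [0, 1]")
        total = sum(self.spectrum.values())
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"haplotype spectrum sums to {total}, not 1")
        for hap in self.spectrum:
            if len(hap) != len(self.loci):
                raise ValueError(f"haplotype {hap} does not span loci {self.loci}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationSpec":
        doc = yaml.safe_load(Path(path).read_text())
        spectrum = {tuple(str(k).split("-")): float(v) for k, v in doc["spectrum"].items()}
        return cls(
            loci=tuple(doc["loci"]),
            spectrum=spectrum,
            n_individuals=int(doc["n_individuals"]),
            f_inbreeding=float(doc.get("f_inbreeding", 0.0)),
            seed=doc.get("seed"),
        )


def simulate_population(spec: SimulationSpec) -> PopulationSample:
    """Draw a :class:`PopulationSample` under the spec's conditions."""
    rng = np.random.default_rng(spec.seed)
    haps = list(spec.spectrum)
    probs = np.array([spec.spectrum[h] for h in haps], dtype=float)
    probs = probs / probs.sum()
    n = spec.n_individuals
    first = rng.choice(len(haps), size=n, p=probs)
    second = rng.choice(len(haps), size=n, p=probs)
    if spec.f_inbreeding > 0:
        dup = rng.random(n) < spec.f_inbreeding
        second = np.where(dup, first, second)
    individuals = []
    width = len(str(n))
    for i in range(n):
        h1, h2 = haps[first[i]], haps[second[i]]
        pairs = [(h1[k], h2[k]) for k in range(len(spec.loci))]
        individuals.append(make_individual(f"S{i + 1:0{width}d}", spec.loci, pairs))
    return PopulationSample(loci=spec.loci, individuals=individuals)


def uyghur_like_fixture() -> PopulationSample:
    """A deterministic 104-individual sample matching the published Uyghur
    per-locus allele counts.

    Per locus, the reconstructed gene-copy counts (count = percent x 208,
    rounded half-up) are expanded into 208 copies, permuted with a fixed
    seed and paired into 104 genotypes.  Marginal allele counts therefore
    equal the published ones exactly, but phase and genotype pairing are
    fabricated: the fixture is valid for frequency and count statistics,
    not as LD or HWE truth.  (Synthetic stand-in; the study's raw genotypes
    were never deposited.)
    """
    from .io import reconstruct_counts
    from .reference import uyghur_allele_frequencies

    tables = uyghur_allele_frequencies()
    loci = tuple(tables)
    rng = np.random.default_rng(104)  # fixed: fixture must be deterministic
    per_locus_pairs: dict[str, list[tuple[str, str]]] = {}
    for locus, table in tables.items():
        with warnings.catch_warnings():
            # a few published HLA-B percents sit a print-rounding ulp off
            # count/208; the counts themselves are unambiguous
            warnings.simplefilter("ignore", UserWarning)
            rec = reconstruct_counts(table, 208)
        copies = [a for a, c in sorted(rec.counts.items()) for _ in range(c)]
        assert len(copies) == 208
        order = rng.permutation(208)
        shuffled = [copies[i] for i in order]
        per_locus_pairs[locus] = [
            (shuffled[2 * i], shuffled[2 * i + 1]) for i in range(104)
        ]
    individuals = []
    for i in range(104):
        pairs = [per_locus_pairs[locus][i] for locus in loci]
        individuals.append(make_individual(f"U{i + 1:03d}", loci, pairs))
    return PopulationSample(loci=loci, individuals=individuals)
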