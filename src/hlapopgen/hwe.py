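"""Exact test of Hardy-Weinberg proportions at a multi-allelic locus.

Conditional on the observed allele counts, the probability of a genotype
array (n_ij) under random mating is the Levene distribution

    P(array) = N! * prod_a c_a! * 2^h / ((2N)! * prod_{i<=j} n_ij!)

with h the number of heterozygous individuals.  The exact p-value sums
P over all arrays no more probable than the observed one (ties included).
Small problems are solved by complete enumeration in rational arithmetic;
larger ones by Monte Carlo: shuffle the multiset of 2N gene copies, re-pair
sequentially into N genotypes (a draw from the conditional null) and count
how often the simulated array is at most as probable as the observed one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Mapping, Sequence

import numpy as np
from scipy.special import gammaln

from .datatypes import Genotype, PopulationSample

__all__ = [
    "HWETestResult",
    "EnumerationCapExceeded",
    "genotype_array_probability",
    "hwe_exact_enumeration",
    "hwe_monte_carlo",
    "hwe_test",
]

DEFAULT_MC_REPS = 170_000


class EnumerationCapExceeded(RuntimeError):
    """Too many consistent genotype arrays; use the Monte Carlo test."""


@dataclass
class HWETestResult:
    locus: str
    p_value: float
    method: str  # "enumeration" | "monte_carlo"
    reps: int | None = None
    seed: int | None = None
    se: float | None = None
    p_exact: Fraction | None = None  # rational p from enumeration

    def __post_init__(self) -> None:
        if not (0 <= self.p_value <= 1):
            raise ValueError(f"p-value outside [0, 1]: {self.p_value}")


def genotype_array_probability(
    genotype_counts: Mapping[Genotype, int],
    allele_counts: Mapping[str, int],
    n_individuals: int,
) -> Fraction:
    """Exact Levene probability of one genotype array given its margins."""
    if sum(genotype_counts.values()) != n_individuals:
        raise ValueError("genotype counts do not sum to N")
    margins: dict[str, int] = {a: 0 for a in allele_counts}
    h = 0
    for (a, b), k in genotype_counts.items():
        margins[a] = margins.get(a, 0) + k
        margins[b] = margins.get(b, 0) + k
        if a != b:
            h += k
    if margins != dict(allele_counts):
        raise ValueError(
            f"genotype array margins {margins} inconsistent with allele counts "
            f"{dict(allele_counts)}"
        )
    two_n = 2 * n_individuals
    p = Fraction(math.factorial(n_individuals), math.factorial(two_n)) * 2**h
    for c in allele_counts.values():
        p *= math.factorial(c)
    for k in genotype_counts.values():
        p /= math.factorial(k)
    return p


def _enumerate_arrays(counts: Sequence[int], cap: int):
    """Yield all symmetric genotype arrays with the given allele-count margins.

    Arrays are dicts (i, j)->n_ij over allele indices i<=j.  Enumeration is a
    backtracking walk over cells; *cap* bounds the number of arrays yielded.
    """
    k = len(counts)
    cells = [(i, j) for i in range(k) for j in range(i, k)]
    array: dict[tuple[int, int], int] = {}
    rem = list(counts)
    yielded = 0

    def rec(idx: int):
        nonlocal yielded
        if idx == len(cells):
            if all(r == 0 for r in rem):
                yielded += 1
                if yielded > cap:
                    raise EnumerationCapExceeded(
                        f"more than {cap} consistent genotype arrays"
                    )
                yield dict(array)
            return
        i, j = cells[idx]
        if i == j:
            hi = rem[i] // 2
        else:
            hi = min(rem[i], rem[j])
        # last cell touching allele i must exhaust its remaining copies
        for n in range(hi, -1, -1):
            take_i = 2 * n if i == j else n
            rem[i] -= take_i
            if i != j:
                rem[j] -= n
            # prune: once all cells of row i are placed, rem[i] must be 0
            last_for_i = j == k - 1
            if not (last_for_i and rem[i] != 0):
                if n:
                    array[(i, j)] = n
                yield from rec(idx + 1)
                array.pop((i, j), None)
            rem[i] += take_i
            if i != j:
                rem[j] += n

    yield from rec(0)


def hwe_exact_enumeration(
    sample: PopulationSample, locus: str, max_arrays: int = 500_000
) -> HWETestResult:
    """Exact p by complete enumeration of genotype arrays (small problems).

    Raises :class:`EnumerationCapExceeded` when more than *max_arrays*
    arrays are consistent with the allele counts.
    """
    geno_counts = sample.genotype_counts(locus)
    allele_counts = sample.allele_counts(locus)
    n = sum(geno_counts.values())
    alleles = sorted(allele_counts)
    index = {a: i for i, a in enumerate(alleles)}
    counts = [allele_counts[a] for a in alleles]

    obs = {(index[a], index[b]): k for (a, b), k in geno_counts.items()}
    obs = {(min(i, j), max(i, j)): k for (i, j), k in obs.items()}
    p_obs = _array_probability_indexed(obs, counts, n)

    total = Fraction(0)
    p_le = Fraction(0)
    for array in _enumerate_arrays(counts, max_arrays):
        p = _array_probability_indexed(array, counts, n)
        total += p
        if p <= p_obs:
            p_le += p
    # sanity: the conditional distribution must sum to 1
    if total != 1:
        raise AssertionError(f"enumeration mass {total} != 1 (internal error)")
    return HWETestResult(
        locus=locus, p_value=float(p_le), method="enumeration", p_exact=p_le
    )


def _array_probability_indexed(
    array: Mapping[tuple[int, int], int], counts: Sequence[int], n: int
) -> Fraction:
    h = sum(k for (i, j), k in array.items() if i != j)
    p = Fraction(math.factorial(n), math.factorial(sum(counts))) * 2**h
    for c in counts:
        p *= math.factorial(c)
    for k in array.values():
        p /= math.factorial(k)
    return p


def _log_stat(pair_counts: np.ndarray, het: int) -> float:
    """h*ln2 - sum ln(n_g!): the array-dependent part of log P."""
    return het * math.log(2.0) - float(gammaln(pair_counts + 1.0).sum())


def hwe_monte_carlo(
    sample: PopulationSample,
    locus: str,
    reps: int = DEFAULT_MC_REPS,
    seed: int | None = None,
) -> HWETestResult:
    """Monte Carlo exact test: random re-pairings of the observed gene copies.

    Returns the proportion of shuffled arrays whose conditional probability
    is <= the observed array's, with the binomial standard error
    sqrt(p(1-p)/reps).
    """
    if reps < 1000:
        raise ValueError("use at least 1000 replicates")
    geno_counts = sample.genotype_counts(locus)
    allele_counts = sample.allele_counts(locus)
    alleles = sorted(allele_counts)
    k = len(alleles)
    if k == 1:
        return HWETestResult(locus=locus, p_value=1.0, method="monte_carlo",
                             reps=reps, seed=seed, se=0.0)
    index = {a: i for i, a in enumerate(alleles)}

    obs_pairs = np.array([g_count for g_count in geno_counts.values()])
    obs_het = sum(c for (a, b), c in geno_counts.items() if a != b)
    t_obs = _log_stat(obs_pairs, obs_het)

    copies = np.repeat(
        np.array([index[a] for a in alleles]),
        np.array([allele_counts[a] for a in alleles]),
    )
    rng = np.random.default_rng(seed)
    hits = 0
    tol = 1e-9
    for _ in range(reps):
        rng.shuffle(copies)
        a = copies[0::2]
        b = copies[1::2]
        lo = np.minimum(a, b)
        hi = np.maximum(a, b)
        codes = lo * k + hi
        counts = np.bincount(codes, minlength=k * k)
        counts = counts[counts > 0]
        het = int((lo != hi).sum())
        if _log_stat(counts, het) <= t_obs + tol:
            hits += 1
    p = hits / reps
    se = math.sqrt(max(p * (1 - p), 0.0) / reps)
    return HWETestResult(
        locus=locus, p_value=p, method="monte_carlo", reps=reps, seed=seed, se=se
    )


def hwe_test(
    sample: PopulationSample,
    locus: str,
    reps: int = DEFAULT_MC_REPS,
    seed: int | None = None,
    max_arrays: int = 200_000,
) -> HWETestResult:
    """Enumerate when feasible, otherwise fall back to Monte Carlo."""
    try:
        return hwe_exact_enumeration(sample, locus, max_arrays=max_arrays)
    except EnumerationCapExceeded:
        return hwe_monte_carlo(sample, locus, reps=reps, seed=seed)
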