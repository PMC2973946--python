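"""Maximum-likelihood haplotype frequencies from unphased genotypes (EM).

An individual heterozygous at h of the L loci is compatible with
2^(h-1) unordered haplotype pairs (one when h <= 1).  The E-step weights
each pair by its probability under the current frequencies (f_i f_j for a
homozygous pair, 2 f_i f_j otherwise); the M-step sets each haplotype's
frequency to its expected copy count over 2N.  The observed-data
log-likelihood is non-decreasing across iterations, and every M-step
iterate preserves the single-locus counting allele frequencies because
each phase decomposition conserves allele counts.

Estimated haplotypes are conventionally reported as statistically
meaningful only when their frequency reaches 2/(3N) — roughly two expected
copies among the 2N sampled gene copies plus margin; with N=104 that
cutoff is 0.64%.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from itertools import product
from typing import Sequence

import numpy as np

from .datatypes import Genotype, Haplotype, HaplotypeTable, PopulationSample

__all__ = [
    "EMConfig",
    "enumerate_phase_decompositions",
    "em_haplotype_frequencies",
    "significance_threshold",
    "apply_significance_filter",
    "significant_summary",
]


@dataclass
class EMConfig:
    """EM controls.

    tolerance: stop when the largest absolute frequency change falls below
    this (default 1e-9).  init: 'product' starts from linkage equilibrium
    (the product of counting allele frequencies — deterministic and unbiased
    toward any phase), 'uniform' from equal frequencies, 'random' from a
    seeded Dirichlet draw.  restarts > 0 reruns from random starts and keeps
    the best likelihood (the likelihood can be multimodal).
    """

    tolerance: float = 1e-9
    max_iterations: int = 1000
    init: str = "product"
    seed: int | None = None
    restarts: int = 0

    def __post_init__(self) -> None:
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.init not in ("product", "uniform", "random"):
            raise ValueError(f"unknown init {self.init!r}")


def enumerate_phase_decompositions(
    genotype: Sequence[Genotype],
) -> list[tuple[Haplotype, Haplotype]]:
    """All unordered haplotype pairs compatible with one multilocus genotype.

    Returns 2^(h-1) distinct pairs, h = number of heterozygous loci; each
    pair jointly carries exactly the observed alleles.
    """
    het_loci = [i for i, (a, b) in enumerate(genotype) if a != b]
    if not het_loci:
        hap = tuple(a for a, _ in genotype)
        return [(hap, hap)]
    # fix the first heterozygous locus to kill the mirror-image duplicates
    first = het_loci[0]
    out: list[tuple[Haplotype, Haplotype]] = []
    for choice in product((0, 1), repeat=len(het_loci) - 1):
        choices = dict(zip(het_loci[1:], choice))
        h1 = []
        h2 = []
        for i, (a, b) in enumerate(genotype):
            if a == b:
                h1.append(a)
                h2.append(b)
            elif i == first:
                h1.append(a)
                h2.append(b)
            else:
                c = choices[i]
                h1.append((a, b)[c])
                h2.append((a, b)[1 - c])
        pair = (tuple(h1), tuple(h2))
        out.append(pair if pair[0] <= pair[1] else (pair[1], pair[0]))
    return out


def _initial_frequencies(
    haplotypes: list[Haplotype],
    sample: PopulationSample,
    loci: Sequence[str],
    config: EMConfig,
    rng: np.random.Generator | None,
) -> np.ndarray:
    m = len(haplotypes)
    if config.init == "uniform":
        f = np.full(m, 1.0 / m)
    elif config.init == "random":
        if rng is None:
            rng = np.random.default_rng(config.seed)
        f = rng.dirichlet(np.ones(m))
    else:  # product of counting allele frequencies, renormalized over the
        # observed-haplotype state space
        margs = []
        for locus in loci:
            counts = {}
            for ind in sample.typed_individuals(loci):
                g = ind.genotype(locus)
                for a in g:
                    counts[a] = counts.get(a, 0) + 1
            tot = sum(counts.values())
            margs.append({a: c / tot for a, c in counts.items()})
        f = np.array(
            [math.prod(margs[i][h[i]] for i in range(len(loci))) for h in haplotypes]
        )
        f = f / f.sum()
    return f


def em_haplotype_frequencies(
    sample: PopulationSample,
    loci: Sequence[str],
    config: EMConfig | None = None,
) -> HaplotypeTable:
    """EM estimate of haplotype frequencies at a 2- or 3-locus tuple.

    Individuals incomplete at the tuple are dropped (pairwise-complete
    analysis).  Haplotypes appearing in no decomposition have ML frequency 0
    and are excluded from the state space.  Returns the table with the final
    log-likelihood, the iteration count and a convergence flag.
    """
    config = config or EMConfig()
    loci = tuple(loci)
    typed = sample.typed_individuals(loci)
    if not typed:
        raise ValueError(f"no individuals complete at loci {loci}")

    decomps = [
        enumerate_phase_decompositions([ind.genotype(l) for l in loci]) for ind in typed
    ]
    hap_set: set[Haplotype] = set()
    for d in decomps:
        for h1, h2 in d:
            hap_set.add(h1)
            hap_set.add(h2)
    haplotypes = sorted(hap_set)
    idx = {h: i for i, h in enumerate(haplotypes)}

    # flat arrays over all (individual, decomposition) pairs
    i1 = np.array([idx[h1] for d in decomps for h1, _ in d])
    i2 = np.array([idx[h2] for d in decomps for _, h2 in d])
    coeff = np.where(i1 == i2, 1.0, 2.0)
    owner = np.repeat(np.arange(len(typed)), [len(d) for d in decomps])
    n_ind = len(typed)

    def run(f: np.ndarray) -> tuple[np.ndarray, float, int, bool, list[float]]:
        loglik = -np.inf
        history: list[float] = []
        for it in range(1, config.max_iterations + 1):
            pair_p = coeff * f[i1] * f[i2]
            per_ind = np.bincount(owner, weights=pair_p, minlength=n_ind)
            loglik = float(np.log(per_ind).sum())
            history.append(loglik)
            w = pair_p / per_ind[owner]
            new_f = (
                np.bincount(i1, weights=w, minlength=len(f))
                + np.bincount(i2, weights=w, minlength=len(f))
            ) / (2.0 * n_ind)
            delta = float(np.abs(new_f - f).max())
            f = new_f
            if delta < config.tolerance:
                return f, loglik, it, True, history
        return f, loglik, config.max_iterations, False, history

    rng = np.random.default_rng(config.seed) if config.seed is not None else None
    best = run(_initial_frequencies(haplotypes, sample, loci, config, rng))
    for _ in range(config.restarts):
        if rng is None:
            rng = np.random.default_rng()
        cand = run(rng.dirichlet(np.ones(len(haplotypes))))
        if cand[1] > best[1]:
            best = cand
    f, loglik, iters, converged, history = best
    return HaplotypeTable(
        loci=loci,
        entries={h: float(f[idx[h]]) for h in haplotypes},
        log_likelihood=loglik,
        n_iterations=iters,
        converged=converged,
        loglik_history=history,
    )


def significance_threshold(n_individuals: int) -> Fraction:
    """The conventional 2/(3N) reporting cutoff for EM haplotype estimates."""
    if n_individuals < 1:
        raise ValueError("N must be >= 1")
    return Fraction(2, 3 * n_individuals)


def apply_significance_filter(table: HaplotypeTable, n_individuals: int) -> HaplotypeTable:
    """Flag entries with frequency >= 2/(3N); returns the same table with
    its ``significant`` map filled in."""
    thr = float(significance_threshold(n_individuals))
    table.significant = {h: (f >= thr) for h, f in table.entries.items()}
    return table


def significant_summary(table: HaplotypeTable) -> tuple[int, float]:
    """(number of flagged haplotypes, their cumulative frequency)."""
    flagged = [h for h, s in table.significant.items() if s]
    return len(flagged), sum(table.entries[h] for h in flagged)
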