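# Methods

This note records the statistical models implemented, the numerical
choices behind them, and what the synthetic-data validation does and does
not establish.

## Data model

The universal input is a sample of N unrelated diploid individuals with an
unordered pair of four-digit allele calls (`LOCUS*FFPP`) at each typed
locus; 2N gene copies per locus is the denominator of every counting
estimate. Missing genotypes (`NA`) exclude an individual from the affected
locus only; multi-locus analyses drop individuals incomplete at the locus
tuple under analysis (pairwise-complete analysis). Frequencies are held as
proportions internally — counting estimators return exact
`fractions.Fraction` values so that totals close exactly — and percents
appear only at I/O edges, rounded half-up to two decimals, matching the
convention of published HLA reports in which every printed frequency is an
integer count over 2N.

### Count reconstruction from printed tables

Published 2-decimal percent tables are inverted by
`count = round-half-up(percent/100 × 2N)`, validated by re-deriving the
percent from the count. In the bundled Uyghur reference table this round
trip is exact for HLA-A and HLA-DRB1; four HLA-B entries are printed as
2.41% where `5/208 = 2.4038%` rounds to 2.40%, a one-ulp print-rounding
artifact of the source table. The counts are unambiguous (each locus sums
to exactly 208 copies); the discrepancy is reported as a warning, not an
error, and the affected percents are excluded from exact-identity checks.

## Exact Hardy–Weinberg test

Conditional on the observed allele counts `c_a`, a genotype array `(n_g)`
has probability `N! Π c_a! 2^h / ((2N)! Π n_g!)` (h = heterozygote count)
under random mating. The p-value is the total probability of arrays no
more probable than the observed one; ties count toward p (the standard
exact-test convention). Two engines:

- **Enumeration** — backtracking over symmetric genotype arrays with the
  observed margins, in exact rational arithmetic; the total enumerated mass
  is asserted equal to 1. Guarded by a configurable array cap (default
  2×10⁵–5×10⁵) beyond which the caller is redirected to Monte Carlo.
- **Monte Carlo** — shuffle the multiset of 2N gene copies and pair
  consecutively, an exact draw from the conditional null, rather than a
  Metropolis chain with proposal switches: simpler, unbiased and adequate
  at these problem sizes. Default 170,000 replicates; the binomial standard
  error `√(p(1−p)/reps)` is reported. Array comparisons use the
  array-dependent part of the log-probability with a 1e-9 tie tolerance.

The test is invariant to individual order, and MC agrees with enumeration
within Monte-Carlo error on all enumerable cases (asserted in tests at four
standard errors). Chain settings of the original software used for the
published p-values are unknown; the defaults here are this package's own.

## EM haplotype estimation

A genotype heterozygous at h loci admits `2^(h−1)` phase decompositions
(one if h ≤ 1), enumerated by fixing the phase of the first heterozygous
locus. The E-step weights each decomposition by `f_i f_j` (×2 for distinct
pairs) under current frequencies; the M-step divides expected copy counts
by 2N. Numerical choices:

- **Initialization**: product of counting allele frequencies (a linkage-
  equilibrium start) — deterministic and unbiased toward any phase.
  Uniform and seeded-random starts plus optional random restarts are
  available because the likelihood can be multimodal; default restarts 0.
- **Convergence**: max |Δf| < 1e-9 or 1000 iterations; non-convergence is
  flagged, not raised.
- Haplotypes appearing in no decomposition have ML frequency 0 and are
  excluded from the state space, bounding memory at the number of observed
  haplotypes rather than the product of allele counts.

Invariants asserted in tests: the observed-data log-likelihood (recorded
per iteration) is non-decreasing; frequencies sum to 1 within 1e-9 at every
iterate; single-locus marginals of the estimate equal the counting allele
frequencies within 1e-6 (decompositions conserve allele counts, so EM
cannot move the margins). Estimated haplotypes are flagged as reportable
when their frequency reaches `2/(3N)` — with N = 104, 0.64% — the
conventional cutoff of roughly two expected copies.

## LD decomposition

Per haplotype: `D = f_AB − p_A p_B`; `D_max = min(p_A(1−p_B), p_B(1−p_A))`
when `D ≥ 0` and `min(p_A p_B, (1−p_A)(1−p_B))` otherwise; `D′ = D/D_max`,
set to 0 and flagged degenerate when `D_max = 0` (a fixed allele). Exact
rational inputs give exact outputs. Over a complete haplotype table D sums
to zero, and D′ is invariant to swapping the loci. Identity checks against
the bundled published LD table use count-based inputs and only the rows
that recompute exactly under them; a few published cells are consistent
only with rounded intermediate inputs (e.g. one Dmax printed 2.34% where
counts give 2.33%, one D′ printed 0.7920 where counts give 0.7941) and are
deliberately not asserted.

## Nei distance and neighbor joining

Nei's standard distance `D = −ln(J_XY / √(J_X J_Y))` with the J terms
averaged across the locus panel before normalization (the multi-locus
convention; the bundled analyses use the single HLA-B locus, where the
mean is trivial). Identity of gene sets is not required: alleles absent
from one population are implicit zeros, and disjoint allele sets give
I = 0, reported as an infinite distance flag rather than an exception.

Neighbor joining is the classic Saitou–Nei agglomeration with
`Q(i,j) = (n−2)d(i,j) − r_i − r_j`, standard branch-length and
distance-update formulas, and a trifurcating root for the final three
clusters (the standard unrooted representation). Ties in Q are broken by
the lexicographically smallest pair of cluster labels (a cluster is
labelled by its smallest leaf), making output deterministic; negative
branch lengths are kept but flagged, as is common NJ practice. Trees are
dendropy objects, serialized as Newick. Correctness is established by
oracle properties — exact recovery of additive matrices from random 4–8
leaf trees (path lengths to 1e-9) and the 3-taxon closed form — because
reproducing the published 24-population dendrogram would require the 23
external population frequency tables, which are out of scope.

## Forensic statistics

`PM = Σ G_g²` over observed genotype proportions (so PD from real data
depends on genotype pairings, not allele counts alone);
`PIC = 1 − Σp² − (Σp²)² + Σp⁴` (Botstein), computed from unrounded
count-based frequencies; `PPE = h²(1 − 2hH²)` with `H = 1 − h`. PPE takes
heterozygosity as an explicit argument — both the h = H_O and h = H_E
variants are reported — because published tables differ in which is
plugged in, and the bundled reference values are reproduced by the
expected-heterozygosity variant. Both the biased (`1 − Σp²`) and unbiased
(`2N/(2N−1)` rescaled) H_E are computed: the bundled table's printed H_E
values are not derivable from its own allele counts by either convention
(its H_E source is unknown), so downstream identities consume the printed
H_E directly rather than guessing a formula. Combined measures:
`CPM = Π PM`, `CPD = 1 − CPM`, `CPE = 1 − Π(1 − PPE)`, permutation-
invariant in locus order.

## Synthetic populations

`simulate_population` draws two haplotypes i.i.d. per individual from a
specified spectrum; with probability F the second is a copy of the first
(an inbreeding-like HWE distortion, F = 0 meaning random mating), then
phase is discarded. This emulates exactly the sampling model the
estimators assume — unrelated individuals, no typing error, no ambiguity,
no missingness unless injected — so passing tests demonstrate estimator
correctness under the model, not robustness to the artifacts of real HLA
typing (ambiguity resolution, genotyping error, relatedness).

`uyghur_like_fixture` builds a deterministic 104-individual sample whose
per-locus allele counts equal the published Uyghur counts exactly, by
expanding the reconstructed counts into 208 copies and pairing them under
a fixed permutation. Phase and genotype pairing are fabricated (the
published haplotype data are far too sparse to constrain them), so the
fixture validates count-driven statistics (frequencies, families, PIC) but
is *not* LD or HWE truth; those estimators are validated on simulated
spectra instead.

## Validation problem sizes

Parameter-recovery tests use N = 5,000 individuals for EM spectra
(tolerance ±0.015 for haplotypes with true frequency ≥ 0.02, a ~3σ
binomial envelope), N = 10,000 for law-of-large-numbers and D′-recovery
checks (±0.01–0.02), and 200 replicate samples of N = 104 with eight
equifrequent alleles for the HWE null-uniformity check
(Kolmogorov–Smirnov at α = 0.01, Monte-Carlo p at 1,000 replicates per
sample). These sizes give comfortable statistical resolution for the
stated tolerances while keeping the whole suite fast.

## Known limitations

- Four-digit nomenclature only; no colon-delimited modern names, G/P
  ambiguity groups, or IMGT database semantics.
- EM assumes HWE within the sample for phase weighting (as all
  genotype-based haplotype estimators do) and can be multimodal; restarts
  are available but not default.
- No confidence intervals on frequency estimates, no r² or global
  multi-allelic D′ summaries, no bootstrap support on trees.
- PD printed in published reports is not reproducible from allele
  frequencies alone; this package computes it from genotype data only.
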