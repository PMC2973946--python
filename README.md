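# hlapopgen

Population-genetic analysis of highly polymorphic HLA loci (HLA-A, -B,
-DRB1), built for the standard descriptive battery of an HLA population
report: allele and haplotype frequency estimation, exact Hardy–Weinberg
testing, linkage-disequilibrium decomposition, inter-population genetic
distances with neighbor-joining trees, and forensic informativeness
statistics. It targets immunogenetics and forensic-genetics workflows where
the input is a table of unphased two-allele calls per locus for N unrelated
diploid individuals, and ships the published allele-frequency, LD and
forensic tables of a 104-individual Chinese Uyghur population sample as
reference data for validation and worked examples.

## What it computes

With `p_i` the allele frequencies at a locus (counting estimates
`count / 2N`) and `f_AB` a two-locus haplotype frequency:

- **Allele statistics** — counting frequencies, two-digit family
  (serological group) aggregates, cumulative frequencies, observed and
  expected heterozygosity `H_O`, `H_E = 1 − Σ p_i²`.
- **Exact HWE test** — conditional on allele counts, a genotype array has
  Levene probability `P = N! Π_a c_a! 2^h / ((2N)! Π_g n_g!)`; the p-value
  sums `P` over all arrays no more probable than the observed one. Complete
  enumeration (exact rational) for small problems, Monte Carlo re-pairing of
  the 2N gene copies otherwise.
- **EM haplotype frequencies** — maximum-likelihood estimation from
  unphased multi-locus genotypes (2^(h−1) phase decompositions per
  individual), with the conventional `2/(3N)` reporting filter.
- **LD decomposition** per haplotype: `D = f_AB − p_A p_B`,
  `D_max = min(p_A(1−p_B), p_B(1−p_A))` for `D ≥ 0` (mirrored for `D < 0`),
  and the relative coefficient `D′ = D / D_max ∈ [−1, 1]`.
- **Nei standard distance** `D = −ln I`, `I = J_XY / √(J_X J_Y)`, and
  neighbor-joining trees (Saitou–Nei) with Newick output.
- **Forensic battery** — match probability `PM = Σ G_g²` and power of
  discrimination `PD = 1 − PM`; polymorphism information content
  `PIC = 1 − Σp_i² − (Σp_i²)² + Σp_i⁴`; paternity-exclusion probability
  `PPE = h²(1 − 2hH²)`, `H = 1 − h`; and the combined across-locus forms
  `CPM = Π PM`, `CPD = 1 − CPM`, `CPE = 1 − Π(1 − PPE)`.

A synthetic-population generator (`hlapopgen.simulate`) draws diploid
samples from a specified haplotype spectrum with an optional inbreeding-like
HWE distortion `F`, so every estimator can be validated against known truth.

## Worked example

`examples/` holds one short script per capability. Running
`python examples/03_haplotypes_and_ld.py` simulates 2000 individuals from a
two-locus spectrum with true `D′ = 0.6`, re-estimates haplotypes by EM and
decomposes the LD:

```
EM converged in 17 iterations, logL = -3831.53
reporting threshold 2/(3N) = 0.00033

haplotype   HF      D       Dmax    D'
A2-B2       0.3105  +0.1188 0.1973  +0.6021
A1-B1       0.4287  +0.1188 0.1973  +0.6021
A2-B1       0.1823  -0.1188 0.1973  -0.6021
A1-B2       0.0785  -0.1188 0.1973  -0.6021
```

The estimated `D′ = 0.6021` sits within sampling error of the true 0.6;
with two alleles per locus all four haplotypes share one |D|, and D sums to
zero over the complete table. `python examples/01_allele_frequencies.py`
reproduces the published Uyghur roll-ups from the bundled reference table —
the five most common HLA-A alleles (A\*1101 13.46%, A\*0201 12.50%,
A\*0301 10.10%, A\*3301 9.62%, A\*2402 9.13%) accumulate 54.81%, and the
A\*02 family sums to 17.78%.

A thin CLI (`hlapop`) exposes the same operations for shell pipelines:
`hlapop report genotypes.tsv --outdir out --seed 1` writes the full set of
report tables (frequencies, HWE, haplotypes, LD, forensic) for a genotype
file.

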