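"""Allele frequencies, family aggregates and cumulative frequencies.

Uses the deterministic 104-individual sample that matches the published
Uyghur per-locus allele counts (2N = 208 gene copies per locus).
"""

from hlapopgen import allele_frequencies, cumulative_frequency, family_frequencies, top_alleles
from hlapopgen.io import round_half_up
from hlapopgen.reference import uyghur_allele_frequencies
from hlapopgen.simulate import uyghur_like_fixture

sample = uyghur_like_fixture()
print(f"N = {sample.n} individuals, loci: {', '.join(sample.loci)}")

freq_a = allele_frequencies(sample, "A")
print(f"\nHLA-A: {len(freq_a)} distinct alleles")
top5 = top_alleles(freq_a, 5)
for allele in top5:
    print(f"  A*{allele}  {round_half_up(100 * freq_a.entries[allele], 2):.2f}%")
cum = cumulative_frequency(freq_a, top5)
print(f"five most common alleles cumulative: {round_half_up(100 * cum, 2):.2f}%")
# 54.81% of all HLA-A gene copies carry one of just five alleles

# family aggregates follow the published report convention: exact sums of
# the printed 2-decimal percents (count-based sums can differ by 0.01%)
published = uyghur_allele_frequencies()
fams = family_frequencies(published["A"])
print(f"\nA*02 family (serological group): {round_half_up(100 * fams['02'], 2):.2f}%")
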