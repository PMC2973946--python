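from fractions import Fraction

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hlapopgen import (
    FrequencyTable,
    allele_frequencies,
    cumulative_frequency,
    family_frequencies,
    heterozygosity,
    locus_summary,
    top_alleles,
)
from conftest import tiny_sample


def test_counting_frequencies_tiny():
    s = tiny_sample([("0101", "0201"), ("0101", "0101")], loci=("A",))
    freq = allele_frequencies(s, "A")
    assert freq.entries["0101"] == Fraction(3, 4)
    assert freq.entries["0201"] == Fraction(1, 4)
    freq.validate_sum(tol=0)


def test_monomorphic_frequency_is_one():
    s = tiny_sample([("0101", "0101")], loci=("A",))
    assert allele_frequencies(s, "A").entries["0101"] == 1


def test_unknown_locus_errors():
    s = tiny_sample([("0101", "0101")], loci=("A",))
    with pytest.raises(KeyError):
        allele_frequencies(s, "B")


def test_published_frequencies_reproduced_from_fixture(uyghur_sample):
    freq = allele_frequencies(uyghur_sample, "A")
    assert freq.entries["1101"] == Fraction(28, 208)
    assert float(100 * freq.entries["1101"]) == pytest.approx(13.46, abs=0.005)


def test_family_aggregation_partitions_table():
    t = FrequencyTable(
        locus="A",
        entries={"0201": Fraction(1, 2), "0205": Fraction(1, 4), "1101": Fraction(1, 4)},
    )
    fams = family_frequencies(t)
    assert fams == {"02": Fraction(3, 4), "11": Fraction(1, 4)}
    assert sum(fams.values()) == 1


def test_single_allele_family_is_total():
    t = FrequencyTable(locus="A", entries={"0101": Fraction(1)})
    assert family_frequencies(t) == {"01": 1}


def test_cumulative_frequency():
    t = FrequencyTable(
        locus="A",
        entries={"0101": Fraction(1, 2), "0201": Fraction(1, 4), "0301": Fraction(1, 4)},
    )
    assert cumulative_frequency(t, ["0101", "0201"]) == Fraction(3, 4)
    assert cumulative_frequency(t, []) == 0
    with pytest.raises(KeyError, match="9901"):
        cumulative_frequency(t, ["9901"])


def test_top_alleles_deterministic_tiebreak():
    t = FrequencyTable(
        locus="A",
        entries={"0301": Fraction(1, 4), "0101": Fraction(1, 4), "0201": Fraction(1, 2)},
    )
    assert top_alleles(t, 2) == ["0201", "0101"]


def test_heterozygosity_all_het():
    s = tiny_sample([("01", "02"), ("01", "02")], loci=("L",))
    ho, he_b, he_u = heterozygosity(s, "L")
    assert ho == 1.0
    assert he_b == pytest.approx(0.5)
    assert he_u == pytest.approx(0.5 * 4 / 3)


def test_heterozygosity_monomorphic_zero():
    s = tiny_sample([("01", "01")], loci=("L",))
    ho, he_b, _ = heterozygosity(s, "L")
    assert (ho, he_b) == (0.0, 0.0)


def test_locus_summary_counts(uyghur_sample):
    s = locus_summary(uyghur_sample, "B")
    assert s.n_alleles == 51
    assert s.he_biased <= s.he_unbiased


@settings(deadline=None, max_examples=25)
@given(
    counts=st.lists(st.integers(min_value=1, max_value=10), min_size=1, max_size=5),
)
def test_he_biased_matches_pairwise_draw_oracle(counts):
    """1 - sum p^2 equals the probability that two copies drawn with
    replacement differ, by direct double sum."""
    total = sum(counts)
    p = [Fraction(c, total) for c in counts]
    he = 1 - sum(x * x for x in p)
    oracle = sum(p[i] * p[j] for i in range(len(p)) for j in range(len(p)) if i != j)
    assert he == oracle
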