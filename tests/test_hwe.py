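from fractions import Fraction

import pytest

from hlapopgen import (
    genotype_array_probability,
    hwe_exact_enumeration,
    hwe_monte_carlo,
    hwe_test,
)
from hlapopgen.hwe import EnumerationCapExceeded
from hlapopgen.simulate import SimulationSpec, simulate_population
from conftest import tiny_sample


def test_levene_probability_two_allele_hand_enumeration():
    """N=2 with allele counts {A:2, B:2}: the two consistent arrays have
    probabilities 1/3 (AA+BB) and 2/3 (AB+AB)."""
    allele_counts = {"A": 2, "B": 2}
    p1 = genotype_array_probability({("A", "A"): 1, ("B", "B"): 1}, allele_counts, 2)
    p2 = genotype_array_probability({("A", "B"): 2}, allele_counts, 2)
    assert p1 == Fraction(1, 3)
    assert p2 == Fraction(2, 3)


def test_levene_probability_single_homozygote():
    assert genotype_array_probability({("A", "A"): 1}, {"A": 2}, 1) == 1


def test_levene_probability_inconsistent_margins_rejected():
    with pytest.raises(ValueError, match="inconsistent"):
        genotype_array_probability({("A", "A"): 2}, {"A": 2, "B": 2}, 2)


def test_enumeration_p_value_toy():
    s = tiny_sample([("A", "A"), ("B", "B")])
    res = hwe_exact_enumeration(s, "L")
    assert res.p_exact == Fraction(1, 3)

    s = tiny_sample([("A", "B"), ("A", "B")])
    res = hwe_exact_enumeration(s, "L")
    assert res.p_exact == 1  # the most probable array accumulates all mass


def test_enumeration_unique_array_p_is_one():
    s = tiny_sample([("A", "A")])
    assert hwe_exact_enumeration(s, "L").p_exact == 1


def test_enumeration_invariant_under_individual_order():
    genos = [("A", "B"), ("A", "A"), ("B", "C"), ("C", "C"), ("A", "C")]
    p1 = hwe_exact_enumeration(tiny_sample(genos), "L").p_exact
    p2 = hwe_exact_enumeration(tiny_sample(list(reversed(genos))), "L").p_exact
    assert p1 == p2


def test_enumeration_cap_raises():
    spec = SimulationSpec(
        loci=("L",),
        spectrum={(f"{i:02d}",): 0.125 for i in range(8)},
        n_individuals=60,
        seed=5,
    )
    s = simulate_population(spec)
    with pytest.raises(EnumerationCapExceeded):
        hwe_exact_enumeration(s, "L", max_arrays=1000)
    assert hwe_test(s, "L", reps=1000, seed=0, max_arrays=1000).method == "monte_carlo"


def test_monte_carlo_matches_enumeration_on_toys():
    """MC p within 4 binomial standard errors of the exact rational p."""
    toys = [
        [("A", "A"), ("B", "B")],
        [("A", "B"), ("A", "B"), ("A", "A")],
        [("A", "B"), ("C", "D"), ("A", "C"), ("B", "D")],
        [("A", "A"), ("A", "B"), ("B", "C"), ("C", "C"), ("A", "C"), ("B", "B")],
    ]
    for genos in toys:
        s = tiny_sample(genos)
        exact = float(hwe_exact_enumeration(s, "L").p_exact)
        mc = hwe_monte_carlo(s, "L", reps=20_000, seed=11)
        band = 4 * max(mc.se, 1e-12)
        assert abs(mc.p_value - exact) <= band, (genos, exact, mc.p_value)


def test_monte_carlo_reproducible_and_seed_sensitive():
    s = tiny_sample([("A", "B"), ("A", "B"), ("A", "A"), ("B", "B")])
    a = hwe_monte_carlo(s, "L", reps=2000, seed=42)
    b = hwe_monte_carlo(s, "L", reps=2000, seed=42)
    assert a.p_value == b.p_value
    assert a.se == pytest.approx((a.p_value * (1 - a.p_value) / 2000) ** 0.5)


def test_monomorphic_locus_p_is_one():
    s = tiny_sample([("A", "A"), ("A", "A")])
    assert hwe_monte_carlo(s, "L", reps=1000, seed=0).p_value == 1.0
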