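import numpy as np
import pytest

from hlapopgen import (
    EMConfig,
    apply_significance_filter,
    em_haplotype_frequencies,
    enumerate_phase_decompositions,
    significance_threshold,
)
from hlapopgen.datatypes import HaplotypeTable
from hlapopgen.io import round_half_up
from hlapopgen.simulate import SimulationSpec, simulate_population
from conftest import tiny_sample


def test_decompositions_double_heterozygote():
    d = enumerate_phase_decompositions([("A1", "A2"), ("B1", "B2")])
    assert len(d) == 2
    assert {frozenset(p) for p in d} == {
        frozenset({("A1", "B1"), ("A2", "B2")}),
        frozenset({("A1", "B2"), ("A2", "B1")}),
    }


def test_decompositions_homozygote_single():
    d = enumerate_phase_decompositions([("A1", "A1"), ("B1", "B1")])
    assert d == [(("A1", "B1"), ("A1", "B1"))]


def test_decompositions_triple_heterozygote_count():
    d = enumerate_phase_decompositions([("A1", "A2"), ("B1", "B2"), ("C1", "C2")])
    assert len(d) == 4
    assert len(set(d)) == 4
    for h1, h2 in d:
        assert sorted([h1[0], h2[0]]) == ["A1", "A2"]


def test_em_all_homozygous_is_point_mass():
    s = tiny_sample([[("A1", "A1"), ("B1", "B1")]] * 2, loci=("A", "B"))
    t = em_haplotype_frequencies(s, ("A", "B"))
    assert t.entries[("A1", "B1")] == pytest.approx(1.0)
    assert t.converged


def test_em_single_double_heterozygote_symmetric_fixed_point():
    s = tiny_sample([[("A1", "A2"), ("B1", "B2")]], loci=("A", "B"))
    t = em_haplotype_frequencies(s, ("A", "B"), EMConfig(init="uniform"))
    for f in t.entries.values():
        assert f == pytest.approx(0.25)


def test_em_recovers_complete_ld_spectrum():
    spec = SimulationSpec(
        loci=("A", "B"),
        spectrum={("A1", "B1"): 0.5, ("A2", "B2"): 0.5},
        n_individuals=10_000,
        seed=7,
    )
    t = em_haplotype_frequencies(simulate_population(spec), ("A", "B"))
    for hap, truth in spec.spectrum.items():
        assert t.entries[hap] == pytest.approx(truth, abs=0.01)


def test_em_invariants_on_simulated_data():
    """Log-likelihood non-decreasing; frequencies sum to 1; marginals match
    counting allele frequencies."""
    spec = SimulationSpec(
        loci=("A", "B"),
        spectrum={
            ("A1", "B1"): 0.35,
            ("A1", "B2"): 0.15,
            ("A2", "B1"): 0.1,
            ("A2", "B2"): 0.25,
            ("A3", "B3"): 0.15,
        },
        n_individuals=300,
        seed=13,
    )
    sample = simulate_population(spec)
    t = em_haplotype_frequencies(sample, ("A", "B"))
    diffs = np.diff(t.loglik_history)
    assert (diffs >= -1e-9).all()
    t.validate_sum(tol=1e-9)
    for locus in ("A", "B"):
        marg = t.marginal(locus)
        counts = sample.allele_counts(locus)
        total = sum(counts.values())
        for allele, c in counts.items():
            assert marg[allele] == pytest.approx(c / total, abs=1e-6)


def test_em_incomplete_individuals_dropped():
    s = tiny_sample(
        [
            [("A1", "A1"), ("B1", "B1")],
            [("A2", "A2"), None],
        ],
        loci=("A", "B"),
    )
    t = em_haplotype_frequencies(s, ("A", "B"))
    assert t.entries == {("A1", "B1"): pytest.approx(1.0)}


def test_significance_threshold_value():
    thr = significance_threshold(104)
    assert round_half_up(float(100 * thr), 2) == 0.64
    assert significance_threshold(1) == pytest.approx(2 / 3)
    with pytest.raises(ValueError):
        significance_threshold(0)


def test_significance_filter_flags():
    t = HaplotypeTable(loci=("A", "B"), entries={("h1", "x"): 0.007, ("h2", "x"): 0.006})
    apply_significance_filter(t, 104)
    assert t.significant[("h1", "x")] is True  # 0.00641 cut
    assert t.significant[("h2", "x")] is False


def test_em_three_locus_recovery():
    spec = SimulationSpec(
        loci=("A", "B", "DRB1"),
        spectrum={
            ("A1", "B1", "D1"): 0.4,
            ("A2", "B2", "D2"): 0.35,
            ("A1", "B2", "D1"): 0.25,
        },
        n_individuals=2000,
        seed=21,
    )
    t = em_haplotype_frequencies(simulate_population(spec), ("A", "B", "DRB1"))
    for hap, truth in spec.spectrum.items():
        assert t.entries[hap] == pytest.approx(truth, abs=0.03)
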