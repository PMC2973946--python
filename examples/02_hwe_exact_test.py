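"""Exact Hardy-Weinberg test: enumeration on a toy, Monte Carlo at scale.

Conditional on allele counts, the p-value sums the probabilities of all
genotype arrays no more probable than the observed one.
"""

from hlapopgen import PopulationSample, hwe_exact_enumeration, hwe_monte_carlo, make_individual
from hlapopgen.simulate import SimulationSpec, simulate_population

# two individuals AA and BB: of the two arrays consistent with allele
# counts {A: 2, B: 2}, the observed one has probability 1/3, so p = 1/3
toy = PopulationSample(
    loci=("L",),
    individuals=[
        make_individual("s1", ["L"], [("A", "A")]),
        make_individual("s2", ["L"], [("B", "B")]),
    ],
)
res = hwe_exact_enumeration(toy, "L")
print(f"toy enumeration: p = {res.p_exact} (exact rational)")

# a random-mating population of 104 individuals with 8 equifrequent
# alleles: p should be unremarkable (the null holds by construction)
spec = SimulationSpec(
    loci=("L",),
    spectrum={(f"{i:02d}",): 0.125 for i in range(8)},
    n_individuals=104,
    seed=42,
)
sample = simulate_population(spec)
mc = hwe_monte_carlo(sample, "L", reps=20_000, seed=1)
print(f"simulated null sample: p = {mc.p_value:.4f} +- {mc.se:.4f} (Monte Carlo)")
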