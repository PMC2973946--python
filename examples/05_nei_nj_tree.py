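"""Nei standard genetic distances and a neighbor-joining tree.

Four synthetic populations with nested frequency perturbations: P1/P2 are
nearly identical, P3/P4 form a distant pair, so NJ must join them that way.
"""

from hlapopgen import FrequencyTable, PopulationFrequencySet, build_population_tree


def pop(name, freqs):
    return PopulationFrequencySet(
        name=name, tables={"B": FrequencyTable(locus="B", entries=freqs)}
    )


populations = [
    pop("P1", {"a": 0.50, "b": 0.50}),
    pop("P2", {"a": 0.52, "b": 0.48}),
    pop("P3", {"a": 0.05, "b": 0.05, "c": 0.90}),
    pop("P4", {"a": 0.04, "b": 0.06, "c": 0.90}),
]

dm, tree = build_population_tree(populations)
print("pairwise Nei standard distances (D = -ln I):")
for i, a in enumerate(dm.labels):
    for j in range(i + 1, len(dm.labels)):
        print(f"  D({a}, {dm.labels[j]}) = {dm.values[i, j]:.4f}")
print("\nNewick:", tree.newick())
# small D = close genetic relationship; the tree clusters P1 with P2
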