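"""Nei standard genetic distance and neighbor-joining trees.

The standard distance between populations X and Y over a locus panel is

    D = -ln I,   I = Jxy / sqrt(Jx * Jy)

where Jxy is the mean over loci of sum_a x_a y_a and Jx, Jy the analogous
mean squared-frequency sums (the normalized identity of genes).  Alleles
absent from a population are implicit zeros; populations sharing no allele
have I = 0 and infinite distance, which is flagged rather than raised.

Neighbor joining follows the classic Saitou-Nei agglomeration: at each
step join the pair minimizing Q(i,j) = (n-2) d(i,j) - r_i - r_j, with the
usual branch-length and distance-update formulas.  Ties are broken by the
lexicographically smallest pair of cluster labels (a cluster is labelled by
its smallest leaf) so output is deterministic.  Negative branch lengths are
kept but flagged, as is common NJ practice.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

from .datatypes import DistanceMatrix, FrequencyTable

__all__ = [
    "PopulationFrequencySet",
    "nei_standard_distance",
    "nei_distance_matrix",
    "PhyloTree",
    "nj_tree",
    "build_population_tree",
    "read_population_frequency_sets",
]


@dataclass
class PopulationFrequencySet:
    """One population's allele-frequency tables over a shared locus panel."""

    name: str
    tables: dict[str, FrequencyTable]

    def __post_init__(self) -> None:
        for locus, t in self.tables.items():
            t.validate_sum(tol=5e-3)  # published tables are rounded

    @property
    def loci(self) -> set[str]:
        return set(self.tables)


def nei_standard_distance(
    x: PopulationFrequencySet,
    y: PopulationFrequencySet,
    loci: Sequence[str] | None = None,
) -> float:
    """Nei (1972) standard genetic distance over the shared locus panel.

    Returns ``inf`` when the populations share no alleles (I = 0); the
    multi-locus form averages the J terms across loci before normalizing.
    """
    panel = list(loci) if loci is not None else sorted(x.loci & y.loci)
    if not panel:
        raise ValueError(f"populations {x.name!r} and {y.name!r} share no locus")
    jxy = jx = jy = 0.0
    for locus in panel:
        tx = x.tables[locus].entries
        ty = y.tables[locus].entries
        jxy += sum(float(fx) * float(ty.get(a, 0.0)) for a, fx in tx.items())
        jx += sum(float(f) ** 2 for f in tx.values())
        jy += sum(float(f) ** 2 for f in ty.values())
    n = len(panel)
    identity = (jxy / n) / math.sqrt((jx / n) * (jy / n))
    if identity <= 0:
        return math.inf
    # clip tiny floating excess above 1 for identical tables
    return max(0.0, -math.log(min(identity, 1.0)))


def nei_distance_matrix(
    populations: Sequence[PopulationFrequencySet],
    loci: Sequence[str] | None = None,
) -> DistanceMatrix:
    labels = [p.name for p in populations]
    n = len(populations)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = nei_standard_distance(populations[i], populations[j], loci)
            values[i, j] = values[j, i] = d
    return DistanceMatrix(labels=labels, values=values)


@dataclass
class PhyloTree:
    """An unrooted NJ tree (dendropy-backed) with a negative-length flag."""

    tree: dendropy.Tree
    has_negative_lengths: bool = False
    labels: list[str] = field(default_factory=list)

    def newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True).strip()

    def write_newick(self, path: str | Path) -> None:
        Path(path).write_text(self.newick() + "\n")

    def leaf_labels(self) -> set[str]:
        return {leaf.taxon.label for leaf in self.tree.leaf_node_iter()}


def nj_tree(dm: DistanceMatrix) -> PhyloTree:
    """Neighbor-joining tree from a symmetric distance matrix.

    Requires n >= 3 finite distances; the result is returned unrooted with
    a trifurcating root node, the standard NJ representation.
    """
    n = len(dm.labels)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    if not np.isfinite(dm.values).all():
        raise ValueError("distance matrix contains non-finite entries")

    taxa = dendropy.TaxonNamespace(dm.labels)
    tree = dendropy.Tree(taxon_namespace=taxa)

    # active clusters: label -> (node, {other label -> distance})
    nodes: dict[str, dendropy.Node] = {}
    for label in dm.labels:
        node = dendropy.Node(taxon=taxa.get_taxon(label))
        nodes[label] = node
    dist: dict[frozenset[str], float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            dist[frozenset((dm.labels[i], dm.labels[j]))] = float(dm.values[i, j])

    active = sorted(dm.labels)
    negative = False

    def d(a: str, b: str) -> float:
        return dist[frozenset((a, b))]

    while len(active) > 3:
        m = len(active)
        r = {a: sum(d(a, b) for b in active if b != a) for a in active}
        best: tuple[float, str, str] | None = None
        for i, a in enumerate(active):
            for b in active[i + 1 :]:
                q = (m - 2) * d(a, b) - r[a] - r[b]
                key = (q, a, b)  # lexicographic tie-break on the label pair
                if best is None or key < best:
                    best = key
        _, f, g = best
        dfg = d(f, g)
        lf = 0.5 * dfg + (r[f] - r[g]) / (2 * (m - 2))
        lg = dfg - lf
        parent = dendropy.Node()
        nodes[f].edge.length = lf
        nodes[g].edge.length = lg
        negative = negative or lf < 0 or lg < 0
        parent.add_child(nodes[f])
        parent.add_child(nodes[g])
        new_label = min(f, g)  # cluster labelled by its smallest leaf
        for k in active:
            if k in (f, g):
                continue
            duk = 0.5 * (d(f, k) + d(g, k) - dfg)
            dist[frozenset((new_label, k))] = duk
        active = sorted([k for k in active if k not in (f, g)] + [new_label])
        nodes[new_label] = parent

    a, b, c = active
    la = 0.5 * (d(a, b) + d(a, c) - d(b, c))
    lb = 0.5 * (d(a, b) + d(b, c) - d(a, c))
    lc = 0.5 * (d(a, c) + d(b, c) - d(a, b))
    negative = negative or min(la, lb, lc) < 0
    root = tree.seed_node
    for label, length in ((a, la), (b, lb), (c, lc)):
        nodes[label].edge.length = length
        root.add_child(nodes[label])
    tree.is_rooted = False
    return PhyloTree(tree=tree, has_negative_lengths=negative, labels=list(dm.labels))


def build_population_tree(
    populations: Sequence[PopulationFrequencySet],
    loci: Sequence[str] | None = None,
) -> tuple[DistanceMatrix, PhyloTree]:
    """Pairwise Nei distances then NJ; errors on any infinite distance."""
    if len(populations) < 3:
        raise ValueError("need at least 3 populations")
    dm = nei_distance_matrix(populations, loci)
    bad = [
        (dm.labels[i], dm.labels[j])
        for i in range(len(dm.labels))
        for j in range(i + 1, len(dm.labels))
        if not math.isfinite(dm.values[i, j])
    ]
    if bad:
        raise ValueError(f"infinite Nei distance (no shared alleles) for pairs: {bad}")
    return dm, nj_tree(dm)


def read_population_frequency_sets(path: str | Path) -> list[PopulationFrequencySet]:
    """Read a multi-population frequency TSV
    (columns: population, locus, allele, frequency)."""
    df = pd.read_csv(path, sep="\t", dtype={"population": str, "locus": str, "allele": str})
    out = []
    for pop, sub in df.groupby("population", sort=False):
        tables = {}
        for locus, ssub in sub.groupby("locus", sort=False):
            tables[str(locus)] = FrequencyTable(
                locus=str(locus),
                entries={str(r.allele): float(r.frequency) for r in ssub.itertuples()},
            )
        out.append(PopulationFrequencySet(name=str(pop), tables=tables))
    return out
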