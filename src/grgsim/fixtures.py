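"""Deterministic synthetic genotype fixtures.

Everything here is a pure function of a :class:`FixtureSpec` (seed
included), so tests and examples run with no external data.  Two genotype
shapes are provided: dense random matrices with a controlled allele
frequency spectrum, and random binary coalescent-topology trees whose
internal nodes carry the mutations (these exercise multi-level accumulation
paths that flat built graphs do not).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .graph import GenotypeMatrix, Grg, GrgNode, Mutation

__all__ = ["FixtureSpec", "generate_matrix", "generate_tree_grg", "figure1_fixture"]

_ALLELE_PAIRS = [("A", "T"), ("C", "G"), ("G", "A"), ("T", "C")]


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of a synthetic genotype fixture.

    ``frequency_model`` is either ``"uniform"`` (allele frequency drawn
    uniformly from ``(freq_low, freq_high)``, then carrier count =
    ``round(f * 2N)``) or ``"sfs"`` (neutral site-frequency spectrum: carrier
    count ``k`` drawn with probability proportional to ``1/k`` over
    ``1 .. 2N-1``, the standard infinite-sites expectation).
    """

    n_individuals: int
    n_mutations: int
    frequency_model: str = "uniform"
    freq_low: float = 0.05
    freq_high: float = 0.5
    seed: int = 0
    shape: str = "matrix"

    def __post_init__(self) -> None:
        if self.n_individuals < 1 or self.n_mutations < 0:
            raise ValueError("n_individuals must be >= 1 and n_mutations >= 0")
        if self.frequency_model not in ("uniform", "sfs"):
            raise ValueError(f"unknown frequency model {self.frequency_model!r}")
        if not (0.0 < self.freq_low <= self.freq_high < 1.0):
            raise ValueError("frequency bounds must satisfy 0 < low <= high < 1")


def _mutation_records(n_mutations: int) -> list[Mutation]:
    return [
        Mutation(
            m,
            position=100 * (m + 1),
            ref_allele=_ALLELE_PAIRS[m % 4][0],
            alt_allele=_ALLELE_PAIRS[m % 4][1],
        )
        for m in range(n_mutations)
    ]


def generate_matrix(spec: FixtureSpec) -> GenotypeMatrix:
    """Random phased genotype matrix with the spec's frequency spectrum.

    For each mutation a carrier count is drawn from the frequency model and
    that many haplotypes are chosen uniformly without replacement.
    """
    rng = np.random.default_rng(spec.seed)
    two_n = 2 * spec.n_individuals
    values = np.zeros((two_n, spec.n_mutations), dtype=np.int8)
    if spec.frequency_model == "uniform":
        freqs = rng.uniform(spec.freq_low, spec.freq_high, size=spec.n_mutations)
        counts = np.rint(freqs * two_n).astype(int)
    else:
        ks = np.arange(1, two_n)
        probs = (1.0 / ks) / np.sum(1.0 / ks)
        counts = rng.choice(ks, size=spec.n_mutations, p=probs)
    for m, k in enumerate(counts):
        carriers = rng.choice(two_n, size=int(k), replace=False)
        values[carriers, m] = 1
    return GenotypeMatrix(values, _mutation_records(spec.n_mutations))


def generate_tree_grg(spec: FixtureSpec) -> Grg:
    """Random binary coalescent-topology tree over ``2N`` sample leaves.

    Lineages are merged pairwise uniformly at random until a single root
    remains; each mutation is then attached to a uniformly chosen internal
    node.  The result is a valid graph whose decode is well defined.
    """
    rng = np.random.default_rng(spec.seed)
    two_n = 2 * spec.n_individuals
    children: list[list[int]] = [[] for _ in range(two_n)]
    lineages = list(range(two_n))
    while len(lineages) > 1:
        i, j = sorted(rng.choice(len(lineages), size=2, replace=False))
        a, b = lineages[i], lineages[j]
        new_id = len(children)
        children.append([a, b])
        lineages[i] = new_id
        # swap-pop keeps the merge loop O(n) at large sample sizes
        lineages[j] = lineages[-1]
        lineages.pop()
    internal = np.arange(two_n, len(children))
    node_muts: list[list[int]] = [[] for _ in range(len(children))]
    for m in range(spec.n_mutations):
        node_muts[int(rng.choice(internal))].append(m)
    nodes = [
        GrgNode(i, tuple(ch), tuple(mu))
        for i, (ch, mu) in enumerate(zip(children, node_muts))
    ]
    return Grg(two_n, nodes, _mutation_records(spec.n_mutations))


def figure1_fixture() -> Grg:
    """Small golden graph: 4 haploid samples (2 individuals), 3 mutations.

    Node 4 has children {1, 2} and carries mutation ``m2`` (so samples 1 and
    2 carry it, samples 0 and 3 do not); a root node 5 spans {0, 4} and
    carries ``m1``; sample leaf 3 carries ``m0``.  Carrier sets are
    therefore m0 -> {3}, m1 -> {0, 1, 2}, m2 -> {1, 2}.
    """
    nodes = [
        GrgNode(0),
        GrgNode(1),
        GrgNode(2),
        GrgNode(3, mutation_ids=(0,)),
        GrgNode(4, children=(1, 2), mutation_ids=(2,)),
        GrgNode(5, children=(0, 4), mutation_ids=(1,)),
    ]
    mutations = [
        Mutation(0, position=100, ref_allele="A", alt_allele="T"),
        Mutation(1, position=200, ref_allele="C", alt_allele="G"),
        Mutation(2, position=300, ref_allele="G", alt_allele="A"),
    ]
    return Grg(4, nodes, mutations)
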