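"""Genotype representation graph: structure, traversals, and dot products.

A genotype representation graph (GRG) is a directed acyclic graph that
losslessly encodes phased genotype hard calls.  Leaves (``node_id <
num_haploid_samples``) are haploid sample nodes; mutations attach to
arbitrary nodes; sample ``s_j`` carries mutation ``m_i`` iff a directed
down-path exists from the node holding ``m_i`` to ``s_j``.  The graph
therefore implicitly houses the phased genotype matrix ``G`` (``2N x M``,
entries 0/1), and two traversals compute its matrix-vector products:

* downward (parents accumulate into children): ``G u`` for any length-M ``u``
* upward (children accumulate into parents):  ``G^T v`` for any length-2N ``v``

Indexing is 0-based throughout: diploid individual ``i`` owns haploid sample
nodes ``2i`` and ``2i + 1``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import sparse

__all__ = [
    "Mutation",
    "GrgNode",
    "Grg",
    "GenotypeMatrix",
    "FrequencyVector",
    "GrgStructureError",
    "topological_order",
    "dot_product_down",
    "dot_product_up",
    "allele_frequencies",
    "build_from_matrix",
    "decode_to_matrix",
]


class GrgStructureError(ValueError):
    """Raised when a graph violates a structural invariant (e.g. a cycle)."""


@dataclass
class Mutation:
    """Variant metadata keyed by a dense 0-based ``mutation_id``.

    ``position`` follows the coordinate system of the source file (1-based
    for VCF input).  ``frequency`` is the alt/mutation allele frequency in
    [0, 1]; it is optional until :func:`allele_frequencies` populates it.
    """

    mutation_id: int
    position: int
    ref_allele: str
    alt_allele: str
    frequency: float | None = None

    def __post_init__(self) -> None:
        if self.frequency is not None and not (0.0 <= self.frequency <= 1.0):
            raise ValueError(
                f"mutation {self.mutation_id}: frequency {self.frequency} outside [0, 1]"
            )


@dataclass
class GrgNode:
    """One graph node: ordered down-edges and attached mutation ids.

    Sample nodes must have no children; no node may list the same child
    twice (the accumulation rule would double-count it).
    """

    node_id: int
    children: tuple[int, ...] = ()
    mutation_ids: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        self.children = tuple(self.children)
        self.mutation_ids = tuple(self.mutation_ids)
        if len(set(self.children)) != len(self.children):
            raise GrgStructureError(
                f"node {self.node_id} lists a duplicate child (parallel edges are forbidden)"
            )


class Grg:
    """Immutable DAG over haploid sample leaves with mutations on nodes.

    Parameters
    ----------
    num_haploid_samples
        ``2N``; must be even and positive.  Node ids ``0 .. 2N-1`` are the
        sample leaves, in individual order (individual ``i`` owns ``2i`` and
        ``2i+1``).
    nodes
        All graph nodes; ids must be dense ``0 .. n_nodes-1`` and include
        every sample node.
    mutations
        All mutations; ids must be dense ``0 .. M-1`` and each must be
        attached to exactly one node.
    individual_ids
        Optional ``N`` identifiers; defaults to ``ind0 .. ind{N-1}``.
    """

    def __init__(
        self,
        num_haploid_samples: int,
        nodes: Sequence[GrgNode],
        mutations: Sequence[Mutation],
        individual_ids: Sequence[str] | None = None,
    ) -> None:
        if num_haploid_samples <= 0 or num_haploid_samples % 2 != 0:
            raise GrgStructureError(
                f"num_haploid_samples must be positive and even, got {num_haploid_samples}"
            )
        self.num_haploid_samples = int(num_haploid_samples)
        self.nodes: list[GrgNode] = sorted(nodes, key=lambda n: n.node_id)
        self.mutations: list[Mutation] = sorted(mutations, key=lambda m: m.mutation_id)
        n = self.num_individuals
        if individual_ids is None:
            individual_ids = [f"ind{i}" for i in range(n)]
        if len(individual_ids) != n:
            raise GrgStructureError(
                f"expected {n} individual ids, got {len(individual_ids)}"
            )
        self.individual_ids: list[str] = [str(s) for s in individual_ids]
        self._validate()
        # caches built lazily
        self._child_matrix: sparse.csr_matrix | None = None
        self._parent_matrix: sparse.csr_matrix | None = None
        self._down_levels: list[np.ndarray] | None = None
        self._up_levels: list[np.ndarray] | None = None

    # -- basic accessors ---------------------------------------------------

    @property
    def num_individuals(self) -> int:
        return self.num_haploid_samples // 2

    @property
    def num_mutations(self) -> int:
        return len(self.mutations)

    @property
    def num_nodes(self) -> int:
        return len(self.nodes)

    @property
    def num_edges(self) -> int:
        return sum(len(nd.children) for nd in self.nodes)

    @property
    def mutation_node(self) -> np.ndarray:
        """Array mapping ``mutation_id -> node_id`` it is attached to."""
        return self._mutation_node

    def is_sample(self, node_id: int) -> bool:
        return node_id < self.num_haploid_samples

    # -- validation --------------------------------------------------------

    def _validate(self) -> None:
        n_nodes = len(self.nodes)
        if n_nodes < self.num_haploid_samples:
            raise GrgStructureError(
                f"{n_nodes} nodes cannot cover {self.num_haploid_samples} sample leaves"
            )
        for i, nd in enumerate(self.nodes):
            if nd.node_id != i:
                raise GrgStructureError(
                    f"node ids must be dense 0..{n_nodes - 1}; missing id {i}"
                )
            if nd.node_id < self.num_haploid_samples and nd.children:
                raise GrgStructureError(
                    f"sample node {nd.node_id} must be a leaf but has children {nd.children}"
                )
            for c in nd.children:
                if not (0 <= c < n_nodes):
                    raise GrgStructureError(
                        f"node {nd.node_id} references unknown child {c}"
                    )
        for i, mut in enumerate(self.mutations):
            if mut.mutation_id != i:
                raise GrgStructureError(
                    f"mutation ids must be dense 0..{len(self.mutations) - 1}; missing id {i}"
                )
        owner: dict[int, int] = {}
        for nd in self.nodes:
            for m in nd.mutation_ids:
                if not (0 <= m < len(self.mutations)):
                    raise GrgStructureError(f"node {nd.node_id} carries unknown mutation {m}")
                if m in owner:
                    raise GrgStructureError(
                        f"mutation {m} attached to both node {owner[m]} and node {nd.node_id}"
                    )
                owner[m] = nd.node_id
        missing = set(range(len(self.mutations))) - owner.keys()
        if missing:
            raise GrgStructureError(
                f"mutation {min(missing)} is not attached to any node"
            )
        self._mutation_node = np.array(
            [owner[m] for m in range(len(self.mutations))], dtype=np.int64
        )
        # acyclicity: computing a topological order raises on a cycle
        topological_order(self, "down")

    # -- cached adjacency and level schedules ------------------------------

    def child_matrix(self) -> sparse.csr_matrix:
        """Sparse 0/1 matrix ``C`` with ``C[parent, child] = 1``."""
        if self._child_matrix is None:
            rows, cols = [], []
            for nd in self.nodes:
                rows.extend([nd.node_id] * len(nd.children))
                cols.extend(nd.children)
            n = self.num_nodes
            self._child_matrix = sparse.csr_matrix(
                (np.ones(len(rows)), (rows, cols)), shape=(n, n)
            )
        return self._child_matrix

    def parent_matrix(self) -> sparse.csr_matrix:
        """Transpose of :meth:`child_matrix` in CSR form (cached)."""
        if self._parent_matrix is None:
            self._parent_matrix = self.child_matrix().T.tocsr()
        return self._parent_matrix

    def parents(self) -> list[list[int]]:
        """Parent lists indexed by node id (derived from down edges)."""
        par: list[list[int]] = [[] for _ in range(self.num_nodes)]
        for nd in self.nodes:
            for c in nd.children:
                par[c].append(nd.node_id)
        return par

    def _levels(self, direction: str) -> list[np.ndarray]:
        """Group node ids by longest-path depth for vectorized traversal.

        ``down``: level 0 = nodes without parents; a node sits one past its
        deepest parent.  ``up``: level 0 = leaves; one past its deepest child.
        Within a level all values depend only on earlier levels, so each
        level is a single sparse matvec slice.
        """
        cache = self._down_levels if direction == "down" else self._up_levels
        if cache is not None:
            return cache  # list of (node_ids, sliced adjacency rows) pairs
        order = topological_order(self, direction)
        depth = np.zeros(self.num_nodes, dtype=np.int64)
        if direction == "down":
            for nid in order:
                d = depth[nid] + 1
                for c in self.nodes[nid].children:
                    if depth[c] < d:
                        depth[c] = d
        else:
            for nid in order:
                ch = self.nodes[nid].children
                if ch:
                    depth[nid] = 1 + max(depth[c] for c in ch)
        adj = self.parent_matrix() if direction == "down" else self.child_matrix()
        # pre-slice the adjacency rows per level so repeated dot products pay
        # no slicing cost
        levels = [
            (idx, adj[idx])
            for d in range(1, int(depth.max()) + 1)
            if (idx := np.flatnonzero(depth == d)).size
        ]
        if direction == "down":
            self._down_levels = levels
        else:
            self._up_levels = levels
        return levels


@dataclass
class GenotypeMatrix:
    """Dense phased genotype matrix ``G`` (``2N x M``, entries 0/1)."""

    values: np.ndarray
    mutations: list[Mutation] = field(default_factory=list)
    individual_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("genotype matrix must be 2-dimensional")
        if self.values.shape[0] % 2 != 0:
            raise ValueError(
                f"haploid row count must be even, got {self.values.shape[0]}"
            )
        if self.values.size and not np.isin(self.values, (0, 1)).all():
            bad = self.values[~np.isin(self.values, (0, 1))].flat[0]
            raise ValueError(f"genotype entries must be 0/1, found {bad!r}")
        if not self.mutations:
            self.mutations = [
                Mutation(i, position=i + 1, ref_allele="A", alt_allele="T")
                for i in range(self.values.shape[1])
            ]
        if self.individual_ids is None:
            self.individual_ids = [f"ind{i}" for i in range(self.values.shape[0] // 2)]

    @property
    def num_haploid_samples(self) -> int:
        return self.values.shape[0]

    @property
    def num_mutations(self) -> int:
        return self.values.shape[1]


@dataclass
class FrequencyVector:
    """Per-mutation alt-allele frequencies ``f_i`` and derived scales.

    ``sigma_i = sqrt(2 f_i (1 - f_i))`` is the per-site standard deviation of
    a diploid genotype under Hardy-Weinberg; it is zero iff the site is
    monomorphic (``f_i`` in {0, 1}).
    """

    frequencies: np.ndarray

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        if self.frequencies.size and (
            self.frequencies.min() < 0.0 or self.frequencies.max() > 1.0
        ):
            raise ValueError("allele frequencies must lie in [0, 1]")

    @property
    def sigmas(self) -> np.ndarray:
        return np.sqrt(2.0 * self.frequencies * (1.0 - self.frequencies))

    @property
    def polymorphic(self) -> np.ndarray:
        """Boolean mask of sites with 0 < f < 1."""
        return (self.frequencies > 0.0) & (self.frequencies < 1.0)


# ---------------------------------------------------------------------------
# traversal order
# ---------------------------------------------------------------------------


def topological_order(grg: Grg, direction: str = "down") -> list[int]:
    """Topological order of the node ids along the down-edge relation.

    ``down``: every parent precedes all of its children (the order used to
    push effects from roots to sample leaves).  ``up``: every child precedes
    all of its parents.  Ties among incomparable nodes are broken by
    ascending node id, so the order is deterministic.

    Raises
    ------
    GrgStructureError
        If the edge relation contains a cycle; the message names one edge on
        the cycle.
    """
    import heapq

    if direction not in ("down", "up"):
        raise ValueError(f"direction must be 'down' or 'up', got {direction!r}")
    n = grg.num_nodes
    indeg = np.zeros(n, dtype=np.int64)
    if direction == "down":
        succ = [list(nd.children) for nd in grg.nodes]
    else:
        succ = [[] for _ in range(n)]
        for nd in grg.nodes:
            for c in nd.children:
                succ[c].append(nd.node_id)
    for lst in succ:
        for v in lst:
            indeg[v] += 1
    ready = [int(i) for i in np.flatnonzero(indeg == 0)]
    heapq.heapify(ready)
    order: list[int] = []
    while ready:
        u = heapq.heappop(ready)
        order.append(u)
        for v in succ[u]:
            indeg[v] -= 1
            if indeg[v] == 0:
                heapq.heappush(ready, v)
    if len(order) < n:
        # every blocked node has a blocked predecessor, so walking
        # predecessors inside the blocked set must close a cycle
        remaining = set(np.flatnonzero(indeg > 0).tolist())
        pred: dict[int, int] = {}
        for p in remaining:
            for v in succ[p]:
                if v in remaining:
                    pred.setdefault(v, p)
        u = min(remaining)
        seen: list[int] = []
        while u not in seen:
            seen.append(u)
            u = pred[u]
        p = pred[u]  # edge p -> u (in succ orientation) lies on the cycle
        edge = (p, u) if direction == "down" else (u, p)
        raise GrgStructureError(
            f"cycle detected involving edge {edge[0]} -> {edge[1]}"
        )
    return order


# ---------------------------------------------------------------------------
# dot products
# ---------------------------------------------------------------------------


def dot_product_down(grg: Grg, u: np.ndarray) -> np.ndarray:
    """Downward traversal computing ``G u`` for a length-M real vector.

    Each node's value is the sum of its attached entries of ``u`` plus the
    values of all its parents, accumulated in down-topological order; the
    output is the values at the sample leaves ``0 .. 2N-1``.
    """
    u = np.asarray(u, dtype=float)
    if u.shape != (grg.num_mutations,):
        raise ValueError(
            f"expected vector of length {grg.num_mutations}, got shape {u.shape}"
        )
    values = np.zeros(grg.num_nodes)
    if grg.num_mutations:
        np.add.at(values, grg.mutation_node, u)
    for idx, rows in grg._levels("down"):
        values[idx] += rows @ values
    return values[: grg.num_haploid_samples]


def dot_product_up(grg: Grg, v: np.ndarray) -> np.ndarray:
    """Upward traversal computing ``G^T v`` for a length-2N real vector.

    Sample leaves take the entries of ``v``; every internal node sums its
    children's values in up-topological order; output ``m`` is the value at
    the node carrying mutation ``m``.
    """
    v = np.asarray(v, dtype=float)
    if v.shape != (grg.num_haploid_samples,):
        raise ValueError(
            f"expected vector of length {grg.num_haploid_samples}, got shape {v.shape}"
        )
    values = np.zeros(grg.num_nodes)
    values[: grg.num_haploid_samples] = v
    for idx, rows in grg._levels("up"):
        values[idx] = rows @ values
    return values[grg.mutation_node] if grg.num_mutations else np.zeros(0)


def allele_frequencies(grg: Grg, populate: bool = True) -> FrequencyVector:
    """Alt-allele frequency per mutation: carrier count over ``2N``.

    Computed as one upward dot product with the all-ones vector.  When
    ``populate`` is true the result is also written onto each
    :class:`Mutation`'s ``frequency`` field.
    """
    counts = dot_product_up(grg, np.ones(grg.num_haploid_samples))
    freqs = counts / grg.num_haploid_samples
    fv = FrequencyVector(freqs)
    if populate:
        for mut, f in zip(grg.mutations, freqs):
            mut.frequency = float(f)
    return fv


# ---------------------------------------------------------------------------
# builder and decoder
# ---------------------------------------------------------------------------


def build_from_matrix(gm: GenotypeMatrix, compress: bool = False) -> Grg:
    """Build a lossless graph from a dense 0/1 phased genotype matrix.

    Stage 1 creates one internal node per distinct carrier set with direct
    edges to its sample leaves (mutations with identical carrier sets share
    one node).  With ``compress``, a greedy second stage repeatedly extracts
    the most frequent child pair shared by at least two parents into a new
    internal node, until no pair is shared; this never changes reachability,
    so ``decode_to_matrix(build_from_matrix(gm)) == gm`` holds either way.
    """
    two_n = gm.num_haploid_samples
    carrier_to_node: dict[tuple[int, ...], int] = {}
    node_children: list[list[int]] = [[] for _ in range(two_n)]
    node_mutations: list[list[int]] = [[] for _ in range(two_n)]
    for m in range(gm.num_mutations):
        carriers = tuple(np.flatnonzero(gm.values[:, m]).tolist())
        nid = carrier_to_node.get(carriers)
        if nid is None:
            nid = len(node_children)
            carrier_to_node[carriers] = nid
            node_children.append(list(carriers))
            node_mutations.append([])
        node_mutations[nid].append(m)

    if compress:
        _factor_shared_pairs(node_children, node_mutations, two_n)

    nodes = [
        GrgNode(i, tuple(ch), tuple(mu))
        for i, (ch, mu) in enumerate(zip(node_children, node_mutations))
    ]
    mutations = [
        Mutation(m.mutation_id, m.position, m.ref_allele, m.alt_allele, m.frequency)
        for m in gm.mutations
    ]
    return Grg(two_n, nodes, mutations, gm.individual_ids)


def _factor_shared_pairs(
    node_children: list[list[int]], node_mutations: list[list[int]], two_n: int
) -> None:
    """Greedy pass: hoist the most common shared child pair into a new node.

    Ties among equally frequent pairs break toward the lexicographically
    smallest (ascending node ids) for determinism.  Terminates because each
    extraction strictly reduces the total edge count.
    """
    from collections import Counter

    while True:
        counts: Counter[tuple[int, int]] = Counter()
        for nid in range(two_n, len(node_children)):
            ch = sorted(node_children[nid])
            for i in range(len(ch)):
                for j in range(i + 1, len(ch)):
                    counts[(ch[i], ch[j])] += 1
        if not counts:
            return
        best_count = max(counts.values())
        if best_count < 2:
            return
        pair = min(p for p, c in counts.items() if c == best_count)
        new_id = len(node_children)
        node_children.append(list(pair))
        node_mutations.append([])
        a, b = pair
        for nid in range(two_n, new_id):
            ch = node_children[nid]
            if a in ch and b in ch:
                ch.remove(a)
                ch.remove(b)
                ch.append(new_id)


def decode_to_matrix(grg: Grg) -> GenotypeMatrix:
    """Decode the graph back to the dense matrix via direct reachability.

    Entry ``(j, i)`` is 1 iff sample ``j`` is reachable from the node
    carrying mutation ``i`` along down edges.  Deliberately implemented as a
    per-node reachability closure, independent of the dot-product traversal,
    so the two routes can cross-validate each other.
    """
    two_n = grg.num_haploid_samples
    n_nodes = grg.num_nodes
    # reachable sample sets, computed leaves-first (bitsets over samples)
    reach: list[int] = [0] * n_nodes
    for j in range(two_n):
        reach[j] = 1 << j
    for nid in topological_order(grg, "up"):
        if nid >= two_n:
            acc = 0
            for c in grg.nodes[nid].children:
                acc |= reach[c]
            reach[nid] = acc
    values = np.zeros((two_n, grg.num_mutations), dtype=np.int8)
    nbytes = (two_n + 7) // 8
    for m in range(grg.num_mutations):
        bits = reach[grg.mutation_node[m]]
        raw = np.frombuffer(bits.to_bytes(nbytes, "little"), dtype=np.uint8)
        values[:, m] = np.unpackbits(raw, bitorder="little")[:two_n]
    mutations = [
        Mutation(m.mutation_id, m.position, m.ref_allele, m.alt_allele, m.frequency)
        for m in grg.mutations
    ]
    return GenotypeMatrix(values, mutations, list(grg.individual_ids))
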