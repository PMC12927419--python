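"""Shared fixtures and independent dense/recursive oracles.

The oracles here deliberately avoid the package's vectorized traversal code
paths: dense matrix algebra works on the decoded 0/1 matrix, and the
recursive accumulators walk the graph one node at a time, so the two routes
can cross-validate the production implementation.
"""

from __future__ import annotations

import sys

import numpy as np
import pytest

import grgsim
from grgsim import FixtureSpec, build_from_matrix, generate_matrix


# ---------------------------------------------------------------------------
# oracle helpers (importable via the fixtures below)
# ---------------------------------------------------------------------------


def dense_X(gm) -> np.ndarray:
    """Diploid genotype matrix: X[i, j] = G[2i, j] + G[2i+1, j]."""
    g = np.asarray(gm.values, dtype=float)
    return g[0::2] + g[1::2]


def dense_standardized_gv(gm, beta: np.ndarray) -> np.ndarray:
    """(X - U) Sigma beta computed with explicit dense matrices."""
    x = dense_X(gm)
    f = np.asarray(gm.values, dtype=float).mean(axis=0)
    sigma = np.sqrt(2.0 * f * (1.0 - f))
    causal = np.flatnonzero(beta)
    xs = (x[:, causal] - 2.0 * f[causal]) / sigma[causal]
    return xs @ beta[causal]


def recursive_down(grg, u: np.ndarray) -> np.ndarray:
    """Per-node recursive accumulation of G u (memoized, no vectorization)."""
    sys.setrecursionlimit(max(10_000, grg.num_nodes * 4))
    parents = grg.parents()
    memo: dict[int, float] = {}

    def value(n: int) -> float:
        if n not in memo:
            own = sum(u[m] for m in grg.nodes[n].mutation_ids)
            memo[n] = own + sum(value(p) for p in parents[n])
        return memo[n]

    return np.array([value(j) for j in range(grg.num_haploid_samples)])


def recursive_up(grg, v: np.ndarray) -> np.ndarray:
    """Per-node recursive accumulation of G^T v."""
    sys.setrecursionlimit(max(10_000, grg.num_nodes * 4))
    memo: dict[int, float] = {}

    def value(n: int) -> float:
        if n not in memo:
            if grg.is_sample(n):
                memo[n] = float(v[n])
            else:
                memo[n] = sum(value(c) for c in grg.nodes[n].children)
        return memo[n]

    return np.array([value(int(nid)) for nid in grg.mutation_node])


@pytest.fixture
def oracles():
    """Bundle of independent oracle callables."""
    return {
        "dense_X": dense_X,
        "dense_standardized_gv": dense_standardized_gv,
        "recursive_down": recursive_down,
        "recursive_up": recursive_up,
    }


# ---------------------------------------------------------------------------
# graph fixtures
# ---------------------------------------------------------------------------


@pytest.fixture
def fig1():
    return grgsim.figure1_fixture()


@pytest.fixture
def small_gm():
    """8 haplotypes x 6 mutations random matrix."""
    return generate_matrix(FixtureSpec(n_individuals=4, n_mutations=6, seed=11))


@pytest.fixture
def small_grg(small_gm):
    return build_from_matrix(small_gm)


@pytest.fixture
def medium_gm():
    """100 haplotypes x 40 mutations random matrix."""
    return generate_matrix(FixtureSpec(n_individuals=50, n_mutations=40, seed=23))


@pytest.fixture
def medium_grg(medium_gm):
    return build_from_matrix(medium_gm)
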