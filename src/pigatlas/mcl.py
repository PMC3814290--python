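"""Markov Cluster (MCL) algorithm on weighted correlation graphs.

MCL simulates stochastic flow on the graph: a column-stochastic transition
matrix is alternately *expanded* (matrix power, spreading flow along
paths) and *inflated* (entry-wise power followed by column renormalization,
strengthening strong currents and weakening weak ones) until the flow
converges to a set of attractor systems, which are read out as clusters.
The inflation exponent sets cluster granularity: higher inflation yields
more, smaller clusters.  Typical operating points here are 2.2 (atlas and
transcription-factor networks), 1.7 (coarser gastrointestinal pass) and 6
(sample QC).

Edge weights (Pearson r) are used directly as similarities; each node gets
a self-loop at its maximum incident weight before normalization, the
canonical guard against odd-length-path parity effects.  Small matrix
entries are pruned each iteration to keep the iteration sparse.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import scipy.sparse as sp

from .core import ClusterAssignment, name_clusters


@dataclass(frozen=True)
class MCLParams:
    """Tunable parameters of the MCL iteration.

    inflation
        Entry-wise power applied each iteration; must be > 1.
    expansion
        Matrix-power exponent (2 is the canonical choice).
    pruning_threshold
        Entries below this are zeroed after inflation (columns are then
        renormalized); keeps the iteration sparse.
    convergence_tol
        Stop when the largest absolute entry change falls below this.
    add_self_loops
        Add a self-loop per node at its maximum incident weight.
    """

    inflation: float = 2.2
    expansion: int = 2
    pruning_threshold: float = 1e-5
    max_iterations: int = 100
    convergence_tol: float = 1e-6
    add_self_loops: bool = True

    def __post_init__(self) -> None:
        if self.inflation <= 1:
            raise ValueError("inflation must be > 1")
        if self.expansion < 2:
            raise ValueError("expansion must be >= 2")
        if self.pruning_threshold < 0:
            raise ValueError("pruning_threshold must be >= 0")
        if self.convergence_tol <= 0:
            raise ValueError("convergence_tol must be > 0")


def _normalize_columns(m: sp.csc_matrix) -> sp.csc_matrix:
    sums = np.asarray(m.sum(axis=0)).ravel()
    sums[sums == 0] = 1.0
    d = sp.diags(1.0 / sums)
    return (m @ d).tocsc()


def _inflate(m: sp.csc_matrix, power: float, prune: float) -> sp.csc_matrix:
    m = m.copy()
    m.data = np.power(m.data, power)
    if prune > 0:
        m.data[m.data < prune] = 0.0
        m.eliminate_zeros()
    return _normalize_columns(m)


def mcl_matrix(
    graph: nx.Graph, params: MCLParams | None = None
) -> tuple[sp.csc_matrix, list[str], bool]:
    """Run the MCL iteration and return (converged matrix, node order, converged?).

    Nodes are processed in sorted order, so the result is invariant to the
    order in which the graph was assembled.
    """
    params = params or MCLParams()
    if graph.number_of_nodes() == 0:
        raise ValueError("MCL requires a non-empty graph")
    nodes = sorted(str(n) for n in graph.nodes)
    index = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    rows, cols, data = [], [], []
    for a, b, attrs in graph.edges(data=True):
        w = float(attrs.get("weight", 1.0))
        if w <= 0:
            raise ValueError(f"MCL requires positive edge weights; ({a},{b}) has {w}")
        i, j = index[str(a)], index[str(b)]
        rows += [i, j]
        cols += [j, i]
        data += [w, w]
    adj = sp.coo_matrix((data, (rows, cols)), shape=(n, n)).tocsc()
    if params.add_self_loops:
        incident_max = np.asarray(adj.max(axis=0).todense()).ravel()
        incident_max[incident_max == 0] = 1.0  # isolated nodes
        adj = (adj + sp.diags(incident_max)).tocsc()
    m = _normalize_columns(adj)

    converged = False
    for _ in range(params.max_iterations):
        expanded = m
        for _ in range(params.expansion - 1):
            expanded = (expanded @ m).tocsc()
        new = _inflate(expanded, params.inflation, params.pruning_threshold)
        diff = abs(new - m)
        change = diff.max() if diff.nnz else 0.0
        m = new
        if change < params.convergence_tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"MCL did not converge within {params.max_iterations} iterations",
            stacklevel=2,
        )
    return m, nodes, converged


def _interpret(m: sp.csc_matrix, nodes: list[str]) -> list[list[int]]:
    """Read clusters from a converged MCL matrix as attractor systems.

    Attractors are nodes with positive diagonal mass; each attractor row's
    support is a candidate cluster (identical supports deduplicated).  A
    node covered by several candidates goes to the one with the largest
    transition-matrix entry; remaining ties go to the candidate containing
    the smallest node id.  Uncovered nodes follow their column's largest
    entry.
    """
    csr = m.tocsr()
    diag = csr.diagonal()
    attractors = np.nonzero(diag > 0)[0]
    supports: dict[frozenset[int], list[int]] = {}
    for i in attractors:
        row = csr.getrow(i)
        members = frozenset(row.indices.tolist()) | {int(i)}
        supports.setdefault(members, []).append(int(i))
    candidates = sorted(supports.items(), key=lambda kv: min(kv[0]))

    coverage: dict[int, list[int]] = {}
    for ci, (members, _rows) in enumerate(candidates):
        for j in members:
            coverage.setdefault(j, []).append(ci)

    assign: dict[int, int] = {}
    for j, cands in coverage.items():
        if len(cands) == 1:
            assign[j] = cands[0]
            continue
        best_ci, best_key = None, None
        for ci in cands:
            members, rows = candidates[ci]
            entry = max(csr[i, j] for i in rows)
            # larger entry wins; ties -> cluster whose smallest member id
            # (node label order) is smallest
            key = (-entry, min(members))
            if best_key is None or key < best_key:
                best_key, best_ci = key, ci
        assign[j] = best_ci

    # nodes with no attractor coverage: follow the column's largest entry
    csc = m.tocsc()
    extra_clusters: list[list[int]] = []
    for j in range(len(nodes)):
        if j in assign:
            continue
        col = csc.getcol(j)
        if col.nnz:
            i = int(col.indices[np.argmax(col.data)])
            if i in assign:
                assign[j] = assign[i]
                continue
        extra_clusters.append([j])

    groups: dict[int, list[int]] = {}
    for j, ci in assign.items():
        groups.setdefault(ci, []).append(j)
    return [sorted(g) for g in groups.values()] + extra_clusters


def mcl(graph: nx.Graph, params: MCLParams | None = None) -> ClusterAssignment:
    """Cluster a weighted graph with MCL; clusters named by descending size.

    Returns a :class:`ClusterAssignment` whose ``converged`` flag is False
    if the iteration hit ``max_iterations`` (a warning is also emitted and
    the current flow interpretation is returned).
    """
    m, nodes, converged = mcl_matrix(graph, params)
    idx_groups = _interpret(m, nodes)
    groups = [[nodes[j] for j in g] for g in idx_groups]
    raw = ClusterAssignment(
        [g for g in groups if len(g) > 1],
        [g[0] for g in groups if len(g) == 1],
        converged=converged,
    )
    return name_clusters(raw)
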