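"""Thresholded Pearson coexpression graph construction.

The transcript-to-transcript network is built in three steps: optional
low-intensity filtering, all-vs-all Pearson correlation with an inclusive
threshold (r >= min_r; negative correlations are never edges), and pruning
of small connected components.  Correlation is computed in row blocks so
peak memory is O(chunk_size x n_probesets) floats; blocking is purely a
memory contract — the edge set is identical for any chunk size.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import networkx as nx
import numpy as np

from .core import EdgeList, ExpressionMatrix


def filter_low_intensity(
    matrix: ExpressionMatrix,
    samples: Sequence[str] | None = None,
    threshold: float = 50.0,
) -> ExpressionMatrix:
    """Drop probesets whose maximum over ``samples`` never exceeds ``threshold``.

    A probeset is retained iff its maximum over the given samples is
    *strictly* greater than the threshold ("never exceeded 50" removes a
    probeset whose maximum is exactly 50).  The sample set of the returned
    matrix is unchanged.  Guards against low-intensity values correlating
    by chance in small sample sets.
    """
    if samples is None:
        samples = matrix.sample_ids
    if len(samples) == 0:
        raise ValueError("empty sample subset")
    cols = matrix.column_indices(samples)
    keep = matrix.values[:, cols].max(axis=1) > threshold
    kept_ids = [p for p, k in zip(matrix.probeset_ids, keep) if k]
    if not kept_ids:
        raise ValueError(f"no probesets exceed intensity {threshold}")
    return matrix.subset_probesets(kept_ids)


def pairwise_pearson(
    matrix: ExpressionMatrix, min_r: float, chunk_size: int = 1024
) -> EdgeList:
    """All-vs-all Pearson correlation, keeping pairs with r >= ``min_r``.

    The threshold is inclusive; negative correlations are never edges.
    Zero-variance probesets yield no edges and a warning.  Requires at
    least 3 samples (with 2, |r| is 1 for every pair).
    """
    if matrix.n_samples < 3:
        raise ValueError("pairwise Pearson requires >= 3 samples")
    if not 0.0 < min_r <= 1.0:
        raise ValueError("min_r must be in (0, 1]")
    if chunk_size < 1:
        raise ValueError("chunk_size must be >= 1")

    x = matrix.values
    mu = x.mean(axis=1, keepdims=True)
    centered = x - mu
    ss = np.sqrt((centered**2).sum(axis=1))
    zero_var = ss == 0
    if zero_var.any():
        bad = [p for p, z in zip(matrix.probeset_ids, zero_var) if z]
        warnings.warn(
            f"{len(bad)} zero-variance probeset(s) excluded from correlation "
            f"(first: {bad[0]!r})",
            stacklevel=2,
        )
    z = np.zeros_like(centered)
    np.divide(centered, ss[:, None], out=z, where=~zero_var[:, None])

    ids = matrix.probeset_ids
    n = len(ids)
    pairs: list[tuple[str, str, float]] = []
    for start in range(0, n, chunk_size):
        stop = min(start + chunk_size, n)
        block = z[start:stop] @ z.T  # (stop-start) x n correlations
        np.clip(block, -1.0, 1.0, out=block)
        ii, jj = np.nonzero(block >= min_r)
        for bi, j in zip(ii, jj):
            i = start + bi
            if i < j and not zero_var[i] and not zero_var[j]:
                pairs.append((ids[i], ids[j], float(block[bi, j])))
    return EdgeList.from_pairs(pairs, threshold=min_r)


def build_graph(edges: EdgeList, min_component_size: int = 5) -> nx.Graph:
    """Build the correlation graph, keeping only components of >= ``min_component_size`` nodes.

    Nodes with no surviving edge are absent; the published atlas graphs use
    a minimum component size of five.
    """
    g = nx.Graph(r_threshold=edges.threshold, min_component_size=min_component_size)
    for a, b, r in edges.records():
        g.add_edge(a, b, weight=r)
    small = [
        c for c in nx.connected_components(g) if len(c) < min_component_size
    ]
    for comp in small:
        g.remove_nodes_from(comp)
    return g


def layout_3d(
    graph: nx.Graph, seed: int = 0, iterations: int = 50
) -> dict[str, np.ndarray]:
    """Weighted Fruchterman–Reingold force-directed layout in 3-D.

    Edge weights (correlations) act as spring strengths, so strongly
    correlated transcripts are pulled together.  Deterministic for a fixed
    seed; a single node is placed at the origin by convention.
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("cannot lay out an empty graph")
    if graph.number_of_nodes() == 1:
        return {str(next(iter(graph.nodes))): np.zeros(3)}
    pos = nx.spring_layout(
        graph, dim=3, seed=seed, iterations=iterations, weight="weight"
    )
    return {str(n): np.asarray(p, dtype=float) for n, p in pos.items()}
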