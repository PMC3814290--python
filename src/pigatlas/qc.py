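"""Sample-level quality control via a sample-sample correlation graph.

Each array sample is correlated with every other over all probesets; pairs
with r strictly above a high threshold (0.91 by default) are joined by an
edge and the resulting graph is clustered with MCL at high inflation (6),
which yields tight groups of like samples.  A sample whose cluster holds no
other sample of its tissue — while some other cluster does — likely
reflects a collection or processing error and is flagged ``mismatched``; a
sample correlated with nothing is ``isolated``.  Flags are advisory:
removal is left to the caller, since biologically distinct samples (pure
cell populations, pancreas) can legitimately sit apart.
"""

from __future__ import annotations

import warnings

import networkx as nx
import numpy as np
import pandas as pd

from .core import ExpressionMatrix, SampleMetadata
from .mcl import MCLParams, mcl


def sample_correlation_graph(
    matrix: ExpressionMatrix, r_threshold: float = 0.91
) -> nx.Graph:
    """Graph over samples with edges where sample-sample Pearson r > threshold.

    The threshold is *strict* (r must exceed it).  Every sample is a node,
    so unconnected samples appear with degree 0.  A constant (zero-
    variance) sample column gets no edges and a warning.
    """
    if matrix.n_samples < 2:
        raise ValueError("sample QC requires >= 2 samples")
    x = matrix.values.T  # samples x probesets
    sd = x.std(axis=1)
    zero_var = sd == 0
    if zero_var.any():
        bad = [s for s, z in zip(matrix.sample_ids, zero_var) if z]
        warnings.warn(f"zero-variance sample column(s): {bad}", stacklevel=2)
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(x)
    g = nx.Graph(r_threshold=r_threshold, kind="sample")
    g.add_nodes_from(matrix.sample_ids)
    n = matrix.n_samples
    for i in range(n):
        for j in range(i + 1, n):
            r = corr[i, j]
            if np.isfinite(r) and r > r_threshold:
                g.add_edge(matrix.sample_ids[i], matrix.sample_ids[j], weight=float(r))
    return g


def flag_outliers(
    graph: nx.Graph, meta: SampleMetadata, inflation: float = 6.0
) -> pd.DataFrame:
    """Flag samples that fail to group with like samples.

    Returns one row per sample with its tissue, connected-component id,
    MCL cluster id (inflation 6 by default), and a flag:

    * ``isolated`` — degree 0 (correlated with no other sample);
    * ``mismatched`` — its cluster contains no other sample of the same
      tissue while another cluster does;
    * ``ok`` — otherwise.
    """
    samples = sorted(str(n) for n in graph.nodes)
    missing = [s for s in samples if s not in meta._tissue]
    if missing:
        raise ValueError(f"metadata missing samples: {missing}")

    comp_of: dict[str, int] = {}
    comps = sorted(nx.connected_components(graph), key=lambda c: (-len(c), min(c)))
    for ci, comp in enumerate(comps, start=1):
        for s in comp:
            comp_of[str(s)] = ci

    # cluster the non-isolated part; isolated nodes are their own story
    connected = [s for s in samples if graph.degree[s] > 0]
    labels: dict[str, int] = {}
    if connected:
        sub = graph.subgraph(connected)
        assignment = mcl(sub, MCLParams(inflation=inflation))
        labels = assignment.labels()

    tissue_clusters: dict[str, set[int]] = {}
    for s in connected:
        tissue_clusters.setdefault(meta.tissue_of(s), set()).add(labels[s])

    rows = []
    for s in samples:
        tissue = meta.tissue_of(s)
        if graph.degree[s] == 0:
            rows.append((s, tissue, comp_of[s], None, "isolated"))
            continue
        cl = labels[s]
        mates = [t for t in connected if t != s and labels[t] == cl]
        same_tissue_here = any(meta.tissue_of(t) == tissue for t in mates)
        same_tissue_elsewhere = any(
            c != cl for c in tissue_clusters.get(tissue, set())
        )
        flag = (
            "mismatched"
            if (not same_tissue_here and same_tissue_elsewhere)
            else "ok"
        )
        rows.append((s, tissue, comp_of[s], cl, flag))
    return pd.DataFrame(
        rows, columns=["sample_id", "tissue", "component", "cluster", "flag"]
    )
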