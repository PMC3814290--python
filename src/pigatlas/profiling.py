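"""Cluster characterization and the composite sub-analyses.

Given a cluster assignment over the coexpression graph, this module
computes per-cluster mean expression profiles, discretized percent-of-max
block profiles (values rounded to the nearest 10%, half-up), and a
collapsed cluster-level summary graph.  It also orchestrates the two
composite analyses built from the primitive stages:

* the two-pass gastrointestinal (GI) analysis — low-intensity filter,
  network at r = 0.90, MCL at 2.2, explicit removal of reviewer-identified
  clusters, then a second network + MCL pass at inflation 1.7;
* the transcription-factor sub-network — the standard pipeline restricted
  to a supplied transcription-factor probeset list (r > 0.8, MCL 2.2).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import networkx as nx
import pandas as pd

from .core import ClusterAssignment, ExpressionMatrix, SampleMetadata
from .mcl import MCLParams, mcl
from .network import build_graph, filter_low_intensity, pairwise_pearson


@dataclass
class ClusterProfile:
    """Mean expression of a cluster's members, per sample and per tissue.

    ``discretized`` holds each tissue's mean as a percent of the maximal
    tissue, rounded half-up to a multiple of 10 (None until
    :func:`discretize_profile` is applied).
    """

    cluster: int
    sample_means: pd.Series
    group_means: pd.Series
    discretized: pd.Series | None = None


def cluster_mean_profile(
    matrix: ExpressionMatrix,
    assignment: ClusterAssignment,
    meta: SampleMetadata,
) -> dict[int, ClusterProfile]:
    """Arithmetic mean profile of each named cluster, per sample and per tissue.

    Tissue (group) means average the replicate samples of each tissue.
    """
    frame = matrix.to_frame()
    tissue_of = {s: meta.tissue_of(s) for s in matrix.sample_ids}
    profiles: dict[int, ClusterProfile] = {}
    for ci in range(1, assignment.n_clusters + 1):
        members = assignment.members(ci)
        if not members:
            raise ValueError(f"cluster {ci} is empty")
        missing = [m for m in members if m not in frame.index]
        if missing:
            raise ValueError(f"cluster {ci} members not in matrix: {missing[:5]}")
        sample_means = frame.loc[members].mean(axis=0)
        group_means = sample_means.groupby(
            sample_means.index.map(tissue_of)
        ).mean()
        # keep tissue order as first appearance in the metadata
        order = [t for t in meta.tissues if t in group_means.index]
        profiles[ci] = ClusterProfile(ci, sample_means, group_means.loc[order])
    return profiles


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def discretize_profile(profile: ClusterProfile) -> ClusterProfile:
    """Express tissue means as percent of maximum, rounded half-up to 10s.

    Each value becomes ``round_half_up(100 * v / max / 10) * 10`` — so 24%
    of maximum prints 20 and 25% prints 30.  Scale-invariant by
    construction.  All-zero profiles are rejected.
    """
    g = profile.group_means
    peak = float(g.max())
    if peak <= 0:
        raise ValueError("cannot discretize an all-zero profile")
    disc = g.map(lambda v: _round_half_up(100.0 * v / peak / 10.0) * 10)
    return ClusterProfile(profile.cluster, profile.sample_means, g, disc.astype(int))


def collapse_graph(
    graph: nx.Graph, assignment: ClusterAssignment, top_n: int = 150
) -> nx.Graph:
    """Summary graph whose nodes are the ``top_n`` largest clusters.

    Two clusters are joined when members of one share original-graph edges
    with members of the other; the edge ``weight`` is the cross-edge count
    and each node's ``size`` is its membership count.
    """
    top = list(range(1, min(top_n, assignment.n_clusters) + 1))
    member_of: dict[str, int] = {}
    for ci in top:
        for m in assignment.members(ci):
            member_of[m] = ci
    out = nx.Graph()
    for ci in top:
        out.add_node(ci, size=len(assignment.members(ci)))
    for a, b in graph.edges():
        ca, cb = member_of.get(str(a)), member_of.get(str(b))
        if ca is None or cb is None or ca == cb:
            continue
        if out.has_edge(ca, cb):
            out[ca][cb]["weight"] += 1
        else:
            out.add_edge(ca, cb, weight=1)
    return out


@dataclass
class TwoPassResult:
    """Artifacts of both passes of the GI analysis."""

    filtered: ExpressionMatrix
    pass1_graph: nx.Graph
    pass1_assignment: ClusterAssignment
    pass2_graph: nx.Graph
    pass2_assignment: ClusterAssignment


def gi_two_pass(
    matrix: ExpressionMatrix,
    gi_samples: Sequence[str],
    exclude_clusters: Sequence[int] = (),
    r: float = 0.90,
    inflation_pass2: float = 1.7,
    intensity_threshold: float = 50.0,
    inflation_pass1: float = 2.2,
    min_component_size: int = 5,
    chunk_size: int = 1024,
) -> TwoPassResult:
    """Two-pass regional analysis of a sample subset (the GI tract).

    Pass 1 restricts the matrix to ``gi_samples``, drops probesets whose
    maximum never exceeds ``intensity_threshold``, builds the network at
    correlation ``r`` and clusters at ``inflation_pass1``.  Probesets in
    ``exclude_clusters`` (pass-1 cluster ids, identified by inspection,
    e.g. contamination from surrounding tissue) are then removed and the
    remaining data re-analyzed at the same ``r`` with the coarser
    ``inflation_pass2``.  With an empty exclusion list pass 2 reproduces
    pass 1 exactly.
    """
    sub = matrix.subset_samples(list(gi_samples))
    filtered = filter_low_intensity(sub, threshold=intensity_threshold)

    edges1 = pairwise_pearson(filtered, min_r=r, chunk_size=chunk_size)
    graph1 = build_graph(edges1, min_component_size=min_component_size)
    assign1 = mcl(graph1, MCLParams(inflation=inflation_pass1))

    bad = [c for c in exclude_clusters if not 1 <= c <= assign1.n_clusters]
    if bad:
        raise ValueError(f"excluded cluster ids absent from pass 1: {bad}")
    drop: set[str] = set()
    for c in exclude_clusters:
        drop.update(assign1.members(c))
    keep = [p for p in filtered.probeset_ids if p not in drop]
    pass2_matrix = filtered.subset_probesets(keep)

    edges2 = pairwise_pearson(pass2_matrix, min_r=r, chunk_size=chunk_size)
    graph2 = build_graph(edges2, min_component_size=min_component_size)
    assign2 = mcl(graph2, MCLParams(inflation=inflation_pass2))
    return TwoPassResult(filtered, graph1, assign1, graph2, assign2)


def tf_subnetwork(
    matrix: ExpressionMatrix,
    tf_ids: Sequence[str],
    r: float = 0.8,
    inflation: float = 2.2,
    min_component_size: int = 5,
    chunk_size: int = 1024,
) -> tuple[nx.Graph, ClusterAssignment]:
    """Standard network + MCL restricted to a transcription-factor list.

    Identifiers absent from the matrix are logged with a warning, not
    fatal; an empty intersection is an error.  Degenerate inputs (a single
    transcription factor, or no edge surviving the threshold) return an
    empty graph and an empty assignment with a warning.
    """
    if not tf_ids:
        raise ValueError("empty transcription-factor list")
    present = [t for t in tf_ids if t in matrix._row_index]
    absent = [t for t in tf_ids if t not in matrix._row_index]
    if not present:
        raise ValueError("no transcription-factor ids found in the matrix")
    if absent:
        warnings.warn(
            f"{len(absent)} transcription-factor id(s) absent from the matrix "
            f"(first: {absent[0]!r})",
            stacklevel=2,
        )
    sub = matrix.subset_probesets(present)
    if sub.n_probesets < 2:
        warnings.warn("fewer than 2 transcription factors: empty network", stacklevel=2)
        return nx.Graph(r_threshold=r), ClusterAssignment([], [])
    edges = pairwise_pearson(sub, min_r=r, chunk_size=chunk_size)
    graph = build_graph(edges, min_component_size=min_component_size)
    if graph.number_of_nodes() == 0:
        warnings.warn("no component survives the size filter", stacklevel=2)
        return graph, ClusterAssignment([], [])
    return graph, mcl(graph, MCLParams(inflation=inflation))
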