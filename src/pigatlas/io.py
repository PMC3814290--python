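"""Readers and writers for the pipeline's tab-delimited file dialects.

Three dialects are supported, all plain UTF-8 TSV:

``.expression``
    Header row of sample ids; column 1 is the probeset id; trailing
    non-numeric columns are auto-detected as annotation and routed to a
    side table, never into the value grid.
``.pearson`` / edge list
    ``node_a<TAB>node_b<TAB>r`` with a header, sorted by (node_a, node_b),
    r at 6 decimal places.
``.layout``
    ``node_id<TAB>x<TAB>y<TAB>z<TAB>cluster<TAB>class`` — one record per
    graph node with precomputed 3-D coordinates.

Readers reject structural violations (duplicate ids, non-numeric cells in
the value region, missing nodes) rather than silently repairing them.
Missing values are unsupported: normalized intensity matrices are complete.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .core import ClusterAssignment, EdgeList, ExpressionMatrix, FormatError, SampleMetadata


def read_expression(path: str | Path, assume_log2: bool = False) -> ExpressionMatrix:
    """Read a ``.expression`` matrix.

    Parameters
    ----------
    path
        TSV file: first row = sample header, first column = probeset id.
    assume_log2
        If True, input values are log2 intensities and are converted to the
        linear scale (``2**v``) on load.  Off by default: absolute-intensity
        thresholds in this pipeline are defined on the linear scale.
    """
    path = Path(path)
    raw = pd.read_csv(path, sep="\t", header=0, dtype=str, keep_default_na=False)
    if raw.shape[0] == 0 or raw.shape[1] < 2:
        raise FormatError(f"{path}: empty expression matrix")
    probesets = raw.iloc[:, 0].tolist()
    body = raw.iloc[:, 1:]

    # Trailing non-numeric columns form the annotation side table.
    numeric: dict[str, np.ndarray] = {}
    cols = list(body.columns)
    n_value_cols = len(cols)
    for j in range(len(cols) - 1, -1, -1):
        converted = pd.to_numeric(body[cols[j]], errors="coerce")
        # annotation column: trailing and non-numeric throughout; a column
        # with a *mixture* of numbers and text is a corrupted value column
        if converted.isna().all() and j == n_value_cols - 1:
            n_value_cols -= 1
        elif converted.isna().any():
            i = int(converted.isna().idxmax())
            raise FormatError(
                f"{path}: non-numeric value {body[cols[j]].iloc[i]!r} at "
                f"row {probesets[i]!r}, column {cols[j]!r}"
            )
        else:
            numeric[cols[j]] = converted.to_numpy(dtype=float)
    value_cols = cols[:n_value_cols]
    if not value_cols:
        raise FormatError(f"{path}: no numeric sample columns found")
    values = np.column_stack([numeric[c] for c in value_cols])
    if assume_log2:
        values = np.power(2.0, values)
    annotations = None
    if n_value_cols < len(cols):
        annotations = body.iloc[:, n_value_cols:].copy()
        annotations.index = pd.Index(probesets)
    return ExpressionMatrix(probesets, value_cols, values, annotations)


def write_expression(matrix: ExpressionMatrix, path: str | Path) -> Path:
    """Write a ``.expression`` file; values at full float precision."""
    path = Path(path)
    frame = matrix.to_frame()
    if matrix.annotations is not None:
        frame = pd.concat([frame, matrix.annotations], axis=1)
    frame.to_csv(path, sep="\t", index_label="probeset_id", float_format="%.10g")
    return path


def write_edge_list(edges: EdgeList, path: str | Path) -> Path:
    """Write a ``.pearson``-style edge list, r at 6 decimal places."""
    path = Path(path)
    table = edges.table.copy()
    table["r"] = table["r"].map(lambda v: f"{v:.6f}")
    table.to_csv(path, sep="\t", index=False)
    return path


def read_edge_list(path: str | Path, threshold: float) -> EdgeList:
    """Read an edge list written by :func:`write_edge_list`."""
    path = Path(path)
    table = pd.read_csv(path, sep="\t", dtype={"node_a": str, "node_b": str})
    if list(table.columns[:3]) != ["node_a", "node_b", "r"]:
        raise FormatError(f"{path}: expected header node_a<TAB>node_b<TAB>r")
    return EdgeList(table, threshold)


def write_layout(
    graph: nx.Graph,
    coords: Mapping[str, Sequence[float]],
    clusters: ClusterAssignment,
    path: str | Path,
    node_class: Mapping[str, str] | None = None,
) -> Path:
    """Write a ``.layout`` file of precomputed 3-D node positions.

    ``coords`` and ``clusters`` must cover every graph node; the display
    class defaults to the cluster label when ``node_class`` is omitted.
    """
    path = Path(path)
    nodes = sorted(str(n) for n in graph.nodes)
    labels = clusters.labels()
    missing_c = [n for n in nodes if n not in coords]
    missing_k = [n for n in nodes if n not in labels]
    if missing_c or missing_k:
        raise FormatError(
            f"layout incomplete: nodes missing coordinates {missing_c[:5]}, "
            f"missing cluster {missing_k[:5]}"
        )
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["node_id", "x", "y", "z", "cluster", "class"])
        for n in nodes:
            x, y, z = (float(v) for v in coords[n])
            if not (np.isfinite(x) and np.isfinite(y) and np.isfinite(z)):
                raise FormatError(f"non-finite coordinate for node {n!r}")
            cls = node_class[n] if node_class is not None else f"Cluster {labels[n]}"
            w.writerow([n, f"{x:.6f}", f"{y:.6f}", f"{z:.6f}", labels[n], cls])
    return path


def read_layout(path: str | Path) -> pd.DataFrame:
    """Read a ``.layout`` file into a DataFrame indexed by node id."""
    path = Path(path)
    table = pd.read_csv(path, sep="\t", dtype={"node_id": str, "class": str})
    expected = ["node_id", "x", "y", "z", "cluster", "class"]
    if list(table.columns) != expected:
        raise FormatError(f"{path}: expected columns {expected}")
    if table["node_id"].duplicated().any():
        dup = table.loc[table["node_id"].duplicated(), "node_id"].iloc[0]
        raise FormatError(f"{path}: duplicate node {dup!r}")
    if not np.isfinite(table[["x", "y", "z"]].to_numpy()).all():
        raise FormatError(f"{path}: non-finite coordinates")
    return table.set_index("node_id")


def read_sample_metadata(path: str | Path) -> SampleMetadata:
    """Read a sample metadata TSV: sample_id, tissue, replicate, class."""
    table = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "tissue": str, "class": str})
    return SampleMetadata(table)


def write_sample_metadata(meta: SampleMetadata, path: str | Path) -> Path:
    path = Path(path)
    meta.table.to_csv(path, sep="\t", index=False)
    return path
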