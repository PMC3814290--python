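"""Core in-memory containers shared across the pipeline.

The pipeline's unit of analysis is the *probeset*: a set of array probes
summarized into one normalized, linear-scale intensity per sample.  An
:class:`ExpressionMatrix` holds the probeset-by-sample grid; thresholded
Pearson correlation graphs are plain :class:`networkx.Graph` objects whose
nodes are probeset (or sample) identifiers and whose edge ``weight``
attribute is the correlation coefficient; :class:`ClusterAssignment` holds
a size-ordered partition of graph nodes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd


class FormatError(ValueError):
    """A file or container violates a structural invariant."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise FormatError(f"duplicate {what} identifier: {i!r}")
        seen.add(i)


@dataclass
class ExpressionMatrix:
    """Probeset x sample grid of normalized linear-scale intensities.

    Parameters
    ----------
    probeset_ids
        Ordered, unique probeset identifiers (rows).
    sample_ids
        Ordered, unique sample identifiers (columns).
    values
        Array of shape ``(len(probeset_ids), len(sample_ids))``; all values
        finite and non-negative.  Intensities are on the *linear* scale —
        absolute-intensity filters (e.g. "maximum above 50") are only
        meaningful there.
    annotations
        Optional side table of non-numeric per-probeset columns carried
        along from the input file; never part of the value grid.
    """

    probeset_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    annotations: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.probeset_ids = [str(p) for p in self.probeset_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise FormatError("expression values must be a 2-D array")
        if self.values.size == 0:
            raise FormatError("empty expression matrix")
        _check_unique(self.probeset_ids, "probeset")
        _check_unique(self.sample_ids, "sample")
        if self.values.shape != (len(self.probeset_ids), len(self.sample_ids)):
            raise FormatError(
                f"value grid shape {self.values.shape} does not match "
                f"{len(self.probeset_ids)} probesets x {len(self.sample_ids)} samples"
            )
        if not np.all(np.isfinite(self.values)):
            raise FormatError("expression values must all be finite")
        if np.any(self.values < 0):
            raise FormatError("expression values must be non-negative")
        self._row_index = {p: i for i, p in enumerate(self.probeset_ids)}
        self._col_index = {s: j for j, s in enumerate(self.sample_ids)}

    @property
    def n_probesets(self) -> int:
        return len(self.probeset_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def row(self, probeset: str) -> np.ndarray:
        return self.values[self._row_index[probeset]]

    def column_indices(self, samples: Sequence[str]) -> np.ndarray:
        missing = [s for s in samples if s not in self._col_index]
        if missing:
            raise KeyError(f"samples not in matrix: {missing}")
        return np.array([self._col_index[s] for s in samples], dtype=int)

    def subset_samples(self, samples: Sequence[str]) -> "ExpressionMatrix":
        cols = self.column_indices(samples)
        return ExpressionMatrix(
            list(self.probeset_ids),
            [str(s) for s in samples],
            self.values[:, cols],
            self.annotations,
        )

    def subset_probesets(self, probesets: Sequence[str]) -> "ExpressionMatrix":
        missing = [p for p in probesets if p not in self._row_index]
        if missing:
            raise KeyError(f"probesets not in matrix: {missing[:10]}")
        rows = np.array([self._row_index[p] for p in probesets], dtype=int)
        ann = None
        if self.annotations is not None:
            ann = self.annotations.loc[list(probesets)]
        return ExpressionMatrix(
            [str(p) for p in probesets], list(self.sample_ids), self.values[rows], ann
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.probeset_ids, columns=self.sample_ids
        )


@dataclass
class SampleMetadata:
    """Per-sample tissue type, replicate index and display class.

    Backed by a DataFrame with columns ``sample_id``, ``tissue``,
    ``replicate``, ``class``.  Sample ordering for display ("samples ordered
    according to tissue type") is driven from here, never from file order.
    """

    table: pd.DataFrame

    REQUIRED = ("sample_id", "tissue", "replicate", "class")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise FormatError(f"sample metadata missing columns: {missing}")
        _check_unique(list(self.table["sample_id"].astype(str)), "sample")
        self.table = self.table.reset_index(drop=True)
        self._tissue = dict(
            zip(self.table["sample_id"].astype(str), self.table["tissue"].astype(str))
        )
        self._class = dict(
            zip(self.table["sample_id"].astype(str), self.table["class"].astype(str))
        )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"].astype(str))

    @property
    def tissues(self) -> list[str]:
        seen: dict[str, None] = {}
        for t in self.table["tissue"].astype(str):
            seen.setdefault(t, None)
        return list(seen)

    def tissue_of(self, sample: str) -> str:
        return self._tissue[sample]

    def class_of(self, sample: str) -> str:
        return self._class[sample]

    def samples_of_tissue(self, tissue: str) -> list[str]:
        t = self.table
        return list(t.loc[t["tissue"].astype(str) == tissue, "sample_id"].astype(str))


@dataclass
class EdgeList:
    """Thresholded correlation edges: records ``(node_a, node_b, r)``.

    Invariants: ``node_a < node_b`` under lexicographic ordering (no
    self-edges, no duplicates) and every ``r >= threshold``.  This mirrors
    the ``.pearson`` file in which all correlations at or above the storage
    threshold are kept.
    """

    table: pd.DataFrame
    threshold: float

    def __post_init__(self) -> None:
        cols = list(self.table.columns)
        if cols[:3] != ["node_a", "node_b", "r"]:
            self.table = self.table.rename(
                columns=dict(zip(cols[:3], ["node_a", "node_b", "r"]))
            )
        t = self.table
        t["node_a"] = t["node_a"].astype(str)
        t["node_b"] = t["node_b"].astype(str)
        t["r"] = t["r"].astype(float)
        if (t["node_a"] >= t["node_b"]).any():
            bad = t.loc[t["node_a"] >= t["node_b"]].iloc[0]
            raise FormatError(
                f"edge ({bad['node_a']!r}, {bad['node_b']!r}) violates node_a < node_b "
                "(self-edge or unordered pair)"
            )
        if t.duplicated(["node_a", "node_b"]).any():
            dup = t.loc[t.duplicated(["node_a", "node_b"])].iloc[0]
            raise FormatError(f"duplicate edge ({dup['node_a']!r}, {dup['node_b']!r})")
        if (t["r"] < self.threshold).any():
            bad = t.loc[t["r"] < self.threshold].iloc[0]
            raise FormatError(
                f"edge r={bad['r']} below stated threshold {self.threshold}"
            )
        self.table = t.sort_values(["node_a", "node_b"], kind="mergesort").reset_index(
            drop=True
        )

    @classmethod
    def from_pairs(
        cls, pairs: Iterable[tuple[str, str, float]], threshold: float
    ) -> "EdgeList":
        recs = []
        for a, b, r in pairs:
            a, b = str(a), str(b)
            if a > b:
                a, b = b, a
            recs.append((a, b, float(r)))
        table = pd.DataFrame(recs, columns=["node_a", "node_b", "r"])
        return cls(table, threshold)

    def __len__(self) -> int:
        return len(self.table)

    def records(self) -> list[tuple[str, str, float]]:
        return list(self.table.itertuples(index=False, name=None))


@dataclass
class ClusterAssignment:
    """Size-ordered partition of graph nodes.

    ``clusters[i]`` holds the sorted members of "Cluster i+1"; clusters are
    named by descending size, ties broken by lexicographically smallest
    member.  Single-member clusters are reported separately in
    ``singletons`` (cluster counts in the literature are quoted for n > 1).
    """

    clusters: list[list[str]]
    singletons: list[str] = field(default_factory=list)
    converged: bool = True

    def __post_init__(self) -> None:
        self.clusters = [sorted(str(m) for m in c) for c in self.clusters]
        self.singletons = sorted(str(s) for s in self.singletons)
        all_nodes: set[str] = set()
        for c in self.clusters:
            for m in c:
                if m in all_nodes:
                    raise FormatError(f"node {m!r} assigned to multiple clusters")
                all_nodes.add(m)
        for s in self.singletons:
            if s in all_nodes:
                raise FormatError(f"node {s!r} both clustered and singleton")
            all_nodes.add(s)

    @property
    def n_clusters(self) -> int:
        """Number of clusters with more than one member."""
        return len(self.clusters)

    @property
    def largest_size(self) -> int:
        return len(self.clusters[0]) if self.clusters else (1 if self.singletons else 0)

    def members(self, cluster: int) -> list[str]:
        """Members of "Cluster ``cluster``" (1-based)."""
        return list(self.clusters[cluster - 1])

    def all_nodes(self) -> set[str]:
        out: set[str] = set()
        for c in self.clusters:
            out.update(c)
        out.update(self.singletons)
        return out

    def labels(self) -> dict[str, int]:
        """Node -> cluster id; singletons get distinct ids after the named ones."""
        lab: dict[str, int] = {}
        for i, c in enumerate(self.clusters, start=1):
            for m in c:
                lab[m] = i
        k = len(self.clusters)
        for j, s in enumerate(self.singletons, start=1):
            lab[s] = k + j
        return lab

    def as_series(self) -> pd.Series:
        lab = self.labels()
        nodes = sorted(lab)
        return pd.Series([lab[n] for n in nodes], index=nodes, name="cluster")


def name_clusters(assignment: ClusterAssignment) -> ClusterAssignment:
    """Renumber clusters 1..k by descending size, the largest first.

    Ties are broken by the lexicographically smallest member identifier.
    Single-member groups are routed to ``singletons``.  Idempotent.
    """
    groups = [list(c) for c in assignment.clusters] + [
        [s] for s in assignment.singletons
    ]
    multi = [sorted(g) for g in groups if len(g) > 1]
    single = [g[0] for g in groups if len(g) == 1]
    multi.sort(key=lambda g: (-len(g), g[0]))
    return ClusterAssignment(multi, single, converged=assignment.converged)
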