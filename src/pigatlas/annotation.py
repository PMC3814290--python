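"""Array design and annotation procedures over precomputed alignment tables.

Three procedures from the design of a comprehensive expression array:

* **reference accretion** — build a non-redundant reference transcript set
  by iterating over ordered query collections; a query joins the reference
  only if its best alignment bitscore against the *current* reference is
  not in excess of the threshold (50), so later collections see earlier
  additions.  Running BLAST itself is out of scope: the module consumes
  tabular (``-m8`` / ``outfmt 6``) hit files plus a subject metadata table.
* **probe-selection-region (PSR) splitting** — tile each transcript into
  near-equal regions of ~150 nt (at most 25), within which probes are
  designed, aiming at 20-25 probes per transcript.
* **species-priority annotation** — assign each query one gene symbol by
  walking priority tiers: human HGNC symbols (e-value < 1e-9), then a
  fixed species order, then any species, then provisional 'LOC' names as a
  fallback, then anything.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

HUMAN = "Homo sapiens"

#: Species walked in order at the symbol tiers (human first).
DEFAULT_SPECIES_PRIORITY: tuple[str, ...] = (
    HUMAN,
    "Sus scrofa",
    "Bos taurus",
    "Pan troglodytes",
    "Mus musculus",
    "Canis lupus familiaris",
    "Pongo abelii",
    "Equus caballus",
    "Rattus norvegicus",
    "Macaca mulatta",
)

#: Species whose provisional LOC symbols are acceptable, in priority order.
DEFAULT_LOC_PRIORITY: tuple[str, ...] = (
    HUMAN,
    "Sus scrofa",
    "Bos taurus",
    "Pan troglodytes",
    "Mus musculus",
)


@dataclass(frozen=True)
class HitRecord:
    """One alignment hit, already joined to subject species and symbol."""

    query_id: str
    subject_id: str
    species: str
    bitscore: float
    e_value: float
    symbol: str

    def __post_init__(self) -> None:
        if self.e_value < 0:
            raise ValueError("e_value must be >= 0")

    @property
    def symbol_is_loc(self) -> bool:
        return self.symbol.upper().startswith("LOC")


@dataclass(frozen=True)
class PSR:
    """Probe selection region: 0-based half-open interval on a transcript."""

    transcript_id: str
    start: int
    end: int
    index: int

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class AnnotationRecord:
    """Annotation outcome for one query.

    ``tier`` names the class of evidence (human_hgnc, species_symbol,
    any_hit, loc_fallback, unannotated); ``rule`` records which pipeline
    step fired, distinguishing the two rules that share the any_hit tier.
    """

    query_id: str
    symbol: str
    tier: str
    species: str
    e_value: float | None
    rule: str


@dataclass(frozen=True)
class QuerySet:
    """One iteration's query collection for reference accretion.

    ``min_length`` (with ``lengths``) filters short sequences before the
    iteration, as applied to EST-derived collections; ``always_add``
    bypasses alignment entirely (used for short RNA collections that
    cannot be meaningfully aligned with BLASTN).
    """

    name: str
    ids: tuple[str, ...]
    lengths: Mapping[str, int] | None = None
    min_length: int | None = None
    always_add: bool = False

    def effective_ids(self) -> list[str]:
        if self.min_length is None:
            return list(self.ids)
        if self.lengths is None:
            raise ValueError(
                f"query set {self.name!r} has min_length but no lengths table"
            )
        return [q for q in self.ids if self.lengths[q] > self.min_length]


@dataclass
class AccretionResult:
    reference: set[str]
    added_per_iteration: list[tuple[str, int]]
    added_ids: dict[str, list[str]]


def accrete_reference(
    initial_reference: Iterable[str],
    query_sets: Sequence[QuerySet],
    hits_per_iteration: Mapping[str, Sequence[HitRecord]],
    bitscore_threshold: float = 50.0,
) -> AccretionResult:
    """Iteratively accrete queries into a non-redundant reference set.

    For each query set in order, a query is added iff its best bitscore
    against the reference *as it stands at that iteration* is <= the
    threshold (a score must be strictly "in excess of 50" to count as
    matched).  Hits against subjects not yet in the reference are ignored,
    which reproduces sequential re-alignment without re-running it.
    Additions become visible to all later iterations.
    """
    reference = {str(s) for s in initial_reference}
    added_per_iteration: list[tuple[str, int]] = []
    added_ids: dict[str, list[str]] = {}
    for qs in query_sets:
        ids = qs.effective_ids()
        known = set(qs.ids)
        eligible = set(ids)
        if qs.always_add:
            new = [q for q in ids if q not in reference]
            reference.update(new)
            added_per_iteration.append((qs.name, len(new)))
            added_ids[qs.name] = new
            continue
        best: dict[str, float] = {}
        for h in hits_per_iteration.get(qs.name, ()):
            if h.query_id not in known:
                raise ValueError(
                    f"hit for unknown query {h.query_id!r} in iteration {qs.name!r}"
                )
            if h.query_id not in eligible or h.subject_id not in reference:
                continue
            if h.bitscore > best.get(h.query_id, float("-inf")):
                best[h.query_id] = h.bitscore
        new = [
            q
            for q in ids
            if q not in reference and best.get(q, 0.0) <= bitscore_threshold
        ]
        reference.update(new)
        added_per_iteration.append((qs.name, len(new)))
        added_ids[qs.name] = new
    return AccretionResult(reference, added_per_iteration, added_ids)


def split_psrs(
    transcript_length: int,
    target_len: int = 150,
    max_psrs: int = 25,
    min_psrs_for_probes: int = 20,
    transcript_id: str = "",
) -> list[PSR]:
    """Tile a transcript into near-equal probe selection regions.

    The region count is ``clamp(round(length / target_len), 1, max_psrs)``
    (round half-up); regions tile the transcript without gaps or overlaps
    and differ in length by at most 1 nt.  ``min_psrs_for_probes`` is the
    design aim (20-25 probes per transcript) and does not alter the count.
    """
    if transcript_length < 1:
        raise ValueError("transcript_length must be >= 1")
    n = int(transcript_length / target_len + 0.5)
    n = max(1, min(n, max_psrs))
    base, rem = divmod(transcript_length, n)
    out: list[PSR] = []
    pos = 0
    for i in range(n):
        size = base + (1 if i < rem else 0)
        out.append(PSR(transcript_id, pos, pos + size, i))
        pos += size
    return out


def _best_hit(hits: Sequence[HitRecord]) -> HitRecord:
    # lowest e-value; ties by higher bitscore, then subject id
    return min(hits, key=lambda h: (h.e_value, -h.bitscore, h.subject_id))


def assign_annotation(
    hits: Iterable[HitRecord],
    species_priority: Sequence[str] = DEFAULT_SPECIES_PRIORITY,
    human_evalue_cutoff: float = 1e-9,
    apply_cutoff_all_symbol_tiers: bool = True,
    loc_priority: Sequence[str] = DEFAULT_LOC_PRIORITY,
    queries: Sequence[str] | None = None,
) -> dict[str, AnnotationRecord]:
    """Assign one symbol per query by walking the species-priority tiers.

    Per query, the best (lowest e-value) hit within each species is chosen
    first; then the tiers are walked:

    1. human symbol at e-value < ``human_evalue_cutoff`` (LOC skipped);
    2. each further species in ``species_priority`` order (LOC skipped;
       the e-value cutoff also applies here unless
       ``apply_cutoff_all_symbol_tiers`` is False);
    3. any other species, best e-value first (LOC skipped, same cutoff
       policy);
    4. LOC symbols from ``loc_priority`` species, in order (no cutoff);
    5. any remaining hit at all.

    Queries with no usable hit — or listed in ``queries`` but absent from
    the hit table — come back ``unannotated``.  Deterministic and
    independent of hit-row order.
    """
    per_query: dict[str, list[HitRecord]] = {}
    for h in hits:
        per_query.setdefault(h.query_id, []).append(h)
    all_queries = set(per_query)
    if queries is not None:
        all_queries.update(str(q) for q in queries)

    prioritized = list(species_priority)
    out: dict[str, AnnotationRecord] = {}
    for q in sorted(all_queries):
        qhits = per_query.get(q, [])
        by_species: dict[str, HitRecord] = {}
        for sp in {h.species for h in qhits}:
            by_species[sp] = _best_hit([h for h in qhits if h.species == sp])

        record = None
        # tiers 1-2: the explicit species order
        for rank, sp in enumerate(prioritized):
            h = by_species.get(sp)
            if h is None or h.symbol_is_loc or not h.symbol:
                continue
            if rank == 0 and h.e_value >= human_evalue_cutoff:
                continue
            if (
                rank > 0
                and apply_cutoff_all_symbol_tiers
                and h.e_value >= human_evalue_cutoff
            ):
                continue
            tier = "human_hgnc" if rank == 0 else "species_symbol"
            rule = "step2" if rank == 0 else "step3"
            record = AnnotationRecord(q, h.symbol, tier, sp, h.e_value, rule)
            break
        # tier 3: any other species, non-LOC
        if record is None:
            others = [
                h
                for sp, h in by_species.items()
                if sp not in prioritized and not h.symbol_is_loc and h.symbol
            ]
            if apply_cutoff_all_symbol_tiers:
                others = [h for h in others if h.e_value < human_evalue_cutoff]
            if others:
                h = _best_hit(others)
                record = AnnotationRecord(q, h.symbol, "any_hit", h.species, h.e_value, "step4")
        # tier 4: LOC fallback in stated species order
        if record is None:
            for sp in loc_priority:
                h = by_species.get(sp)
                if h is not None and h.symbol_is_loc:
                    record = AnnotationRecord(
                        q, h.symbol, "loc_fallback", sp, h.e_value, "step5"
                    )
                    break
        # tier 5: anything else with a symbol
        if record is None:
            leftover = [h for h in by_species.values() if h.symbol]
            if leftover:
                h = _best_hit(leftover)
                record = AnnotationRecord(q, h.symbol, "any_hit", h.species, h.e_value, "step6")
        if record is None:
            record = AnnotationRecord(q, "", "unannotated", "", None, "none")
        out[q] = record
    return out


# -- file plumbing -----------------------------------------------------------

BLAST_M8_COLUMNS = (
    "query_id subject_id pct_identity aln_length mismatches gap_opens "
    "q_start q_end s_start s_end e_value bitscore"
).split()


def read_blast_tabular(
    path: str | Path, subject_meta: Mapping[str, tuple[str, str]]
) -> list[HitRecord]:
    """Read a BLAST ``-m8`` / ``outfmt 6`` file into hit records.

    ``subject_meta`` maps subject id -> (species, gene symbol); subjects
    absent from the mapping are a hard error, since annotation decisions
    depend on both fields.
    """
    table = pd.read_csv(
        path, sep="\t", names=BLAST_M8_COLUMNS, dtype={"query_id": str, "subject_id": str}
    )
    records = []
    for row in table.itertuples(index=False):
        sid = str(row.subject_id)
        if sid not in subject_meta:
            raise ValueError(f"subject {sid!r} missing from subject metadata")
        species, symbol = subject_meta[sid]
        records.append(
            HitRecord(
                query_id=str(row.query_id),
                subject_id=sid,
                species=species,
                bitscore=float(row.bitscore),
                e_value=float(row.e_value),
                symbol=symbol,
            )
        )
    return records


def read_subject_metadata(path: str | Path) -> dict[str, tuple[str, str]]:
    """Read a subject metadata TSV: subject_id, species, symbol."""
    table = pd.read_csv(path, sep="\t", dtype=str)
    need = ["subject_id", "species", "symbol"]
    if list(table.columns[:3]) != need:
        raise ValueError(f"expected columns {need}")
    return {
        str(r.subject_id): (str(r.species), "" if pd.isna(r.symbol) else str(r.symbol))
        for r in table.itertuples(index=False)
    }


def write_annotation(records: Mapping[str, AnnotationRecord], path: str | Path) -> Path:
    path = Path(path)
    rows = [
        (r.query_id, r.symbol, r.tier, r.species, "" if r.e_value is None else r.e_value, r.rule)
        for r in (records[q] for q in sorted(records))
    ]
    pd.DataFrame(
        rows, columns=["query_id", "symbol", "tier", "species", "e_value", "rule"]
    ).to_csv(path, sep="\t", index=False)
    return path


def write_psrs(psrs: Sequence[PSR], path: str | Path) -> Path:
    """Write PSRs as a BED-like TSV (0-based half-open coordinates)."""
    path = Path(path)
    pd.DataFrame(
        [(p.transcript_id, p.start, p.end, p.index) for p in psrs],
        columns=["transcript_id", "start", "end", "index"],
    ).to_csv(path, sep="\t", index=False)
    return path
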