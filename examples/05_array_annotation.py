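"""Array design logic: reference accretion, PSR tiling, symbol annotation.

Walks the three design-time procedures on a toy fixture: (1) accrete a
non-redundant reference set over two query collections, where a query
joins only if no alignment against the current reference scores above
bitscore 50; (2) tile transcripts into ~150 nt probe selection regions
(at most 25 per transcript); (3) assign one gene symbol per query by
species priority, demoting provisional LOC names to a fallback tier.
"""

import pigatlas as pa

# 1. reference accretion -----------------------------------------------------
hits = {
    "mrna": [
        pa.HitRecord("q_known", "seed1", "Sus scrofa", 180.0, 1e-40, "ALB"),
        pa.HitRecord("q_novel", "seed1", "Sus scrofa", 32.0, 1e-3, "ALB"),
    ],
    "est": [
        # only alignment is against q_novel, added in the previous round
        pa.HitRecord("q_redundant", "q_novel", "Sus scrofa", 140.0, 1e-30, ""),
    ],
}
result = pa.accrete_reference(
    initial_reference={"seed1", "seed2"},
    query_sets=[
        pa.QuerySet("mrna", ("q_known", "q_novel")),
        pa.QuerySet("est", ("q_redundant", "q_new"), {"q_redundant": 800, "q_new": 700}, 500),
    ],
    hits_per_iteration=hits,
)
for name, count in result.added_per_iteration:
    print(f"iteration {name}: {count} added ({', '.join(result.added_ids[name]) or '-'})")
print(f"final reference: {len(result.reference)} sequences\n")

# 2. probe selection regions -------------------------------------------------
for length in (150, 1000, 10_000):
    psrs = pa.split_psrs(length, transcript_id=f"tx{length}")
    print(
        f"transcript of {length} nt -> {len(psrs)} PSRs of "
        f"{psrs[0].length}-{psrs[-1].length} nt"
    )
print()

# 3. species-priority annotation ----------------------------------------------
records = pa.assign_annotation(
    [
        pa.HitRecord("probe1", "h1", "Homo sapiens", 200.0, 1e-25, "CSF1R"),
        pa.HitRecord("probe2", "h2", "Homo sapiens", 150.0, 1e-30, "LOC441",),
        pa.HitRecord("probe2", "p1", "Sus scrofa", 120.0, 1e-14, "CD163"),
    ],
    queries=["probe3"],
)
for q in sorted(records):
    r = records[q]
    print(f"{q}: symbol={r.symbol or '-'} tier={r.tier} species={r.species or '-'}")
print("(human HGNC beats a pig symbol, but a human LOC name does not)")
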