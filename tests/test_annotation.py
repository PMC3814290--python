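"""Reference accretion, PSR tiling and the species-priority annotation engine."""

import pytest
from hypothesis import given, settings, strategies as st

import pigatlas as pa
from pigatlas.annotation import (
    DEFAULT_LOC_PRIORITY,
    DEFAULT_SPECIES_PRIORITY,
    HitRecord,
    QuerySet,
    accrete_reference,
    assign_annotation,
    split_psrs,
)


def hit(q, s, species="Homo sapiens", bitscore=100.0, e=1e-20, symbol="SYM"):
    return HitRecord(q, s, species, bitscore, e, symbol)


class TestAccreteReference:
    def test_empty_hit_table_adds_every_query(self):
        qs = [QuerySet("iter1", ("q1", "q2", "q3"))]
        res = accrete_reference({"ref1"}, qs, {})
        assert res.reference == {"ref1", "q1", "q2", "q3"}
        assert res.added_per_iteration == [("iter1", 3)]

    def test_bitscore_exactly_50_is_added(self):
        qs = [QuerySet("iter1", ("q1",))]
        hits = {"iter1": [hit("q1", "ref1", bitscore=50.0)]}
        res = accrete_reference({"ref1"}, qs, hits)
        assert "q1" in res.reference  # 50.0 is not "in excess of 50"

    def test_bitscore_above_50_is_matched_not_added(self):
        qs = [QuerySet("iter1", ("q1",))]
        hits = {"iter1": [hit("q1", "ref1", bitscore=50.001)]}
        res = accrete_reference({"ref1"}, qs, hits)
        assert "q1" not in res.reference

    def test_additions_visible_to_later_iterations(self):
        # q1 joins in iter1; q2's only strong hit is against q1, so q2 is
        # matched in iter2 only because q1 is now reference
        qs = [QuerySet("iter1", ("q1",)), QuerySet("iter2", ("q2",))]
        hits = {"iter2": [hit("q2", "q1", bitscore=200.0)]}
        res = accrete_reference({"ref1"}, qs, hits)
        assert "q1" in res.reference and "q2" not in res.reference

    def test_hits_against_non_reference_subjects_ignored(self):
        qs = [QuerySet("iter1", ("q1",))]
        hits = {"iter1": [hit("q1", "stranger", bitscore=500.0)]}
        res = accrete_reference({"ref1"}, qs, hits)
        assert "q1" in res.reference

    def test_min_length_filter(self):
        qs = [QuerySet("iter1", ("short", "long"), {"short": 400, "long": 900}, 500)]
        res = accrete_reference(set(), qs, {})
        assert res.reference == {"long"}

    def test_always_add_bypasses_alignment(self):
        qs = [QuerySet("mirna", ("m1", "m2"), always_add=True)]
        hits = {"mirna": [hit("m1", "ref1", bitscore=999.0)]}
        res = accrete_reference({"ref1"}, qs, hits)
        assert {"m1", "m2"} <= res.reference

    def test_unknown_query_in_hits_is_error(self):
        qs = [QuerySet("iter1", ("q1",))]
        with pytest.raises(ValueError, match="unknown query"):
            accrete_reference({"r"}, qs, {"iter1": [hit("ghost", "r")]})

    def test_three_iteration_fixture_matches_sequential_oracle(self):
        # brute-force sequential simulation with overlapping queries
        seeds = {f"s{i}" for i in range(10)}
        queries = {
            "it1": ["a1", "a2", "a3", "a4"],
            "it2": ["a2", "b1", "b2"],
            "it3": ["b2", "c1", "c2", "c3"],
        }
        # pairwise scores: query -> {subject: bitscore}
        scores = {
            "a1": {"s0": 80.0},          # matched by seed
            "a2": {"s1": 30.0},          # weak -> added in it1
            "a3": {},                     # no hit -> added
            "a4": {"s2": 50.0},          # boundary -> added
            "b1": {"a3": 120.0},         # matched by it1 addition
            "b2": {"a2": 45.0, "s3": 20.0},  # weak everywhere -> added in it2
            "c1": {"b2": 75.0},          # matched by it2 addition
            "c2": {"s9": 51.0},          # matched by seed
            "c3": {"b1": 90.0},          # b1 never added -> hit ignored -> added
        }
        # oracle: explicit sequential simulation
        ref = set(seeds)
        oracle_added = []
        for name in ["it1", "it2", "it3"]:
            new = []
            for q in queries[name]:
                if q in ref:
                    continue
                best = max(
                    (b for s, b in scores[q].items() if s in ref), default=0.0
                )
                if best <= 50.0:
                    new.append(q)
            ref.update(new)
            oracle_added.append((name, len(new)))

        qsets = [QuerySet(n, tuple(queries[n])) for n in ["it1", "it2", "it3"]]
        hits = {
            n: [
                hit(q, s, bitscore=b)
                for q in queries[n]
                for s, b in scores[q].items()
            ]
            for n in ["it1", "it2", "it3"]
        }
        res = accrete_reference(seeds, qsets, hits)
        assert res.reference == ref
        assert res.added_per_iteration == oracle_added

    def test_iteration_order_matters(self):
        # permuting iterations changes the outcome by design
        q_x = QuerySet("x", ("qx",))
        q_y = QuerySet("y", ("qy",))
        hits = {"y": [hit("qy", "qx", bitscore=300.0)]}
        forward = accrete_reference(set(), [q_x, q_y], hits)
        backward = accrete_reference(set(), [q_y, q_x], hits)
        assert "qy" not in forward.reference  # qx added first, matches qy
        assert "qy" in backward.reference  # qx not yet reference


class TestSplitPSRs:
    def test_length_150_is_one_psr(self):
        psrs = split_psrs(150)
        assert [(p.start, p.end) for p in psrs] == [(0, 150)]

    def test_length_3750_hits_the_25_cap_exactly(self):
        psrs = split_psrs(3750)
        assert len(psrs) == 25
        assert all(p.length == 150 for p in psrs)

    def test_length_10000_caps_at_25_equal_regions(self):
        psrs = split_psrs(10_000)
        assert len(psrs) == 25
        assert all(p.length == 400 for p in psrs)

    def test_round_half_up_on_region_count(self):
        assert len(split_psrs(225)) == 2  # 1.5 rounds up
        assert len(split_psrs(220)) == 1  # 1.47 rounds down

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(st.integers(min_value=1, max_value=30_000))
    def test_tiling_is_exact_and_near_equal(self, length):
        psrs = split_psrs(length)
        assert psrs[0].start == 0
        assert psrs[-1].end == length
        for a, b in zip(psrs, psrs[1:]):
            assert a.end == b.start  # no gaps, no overlap
        sizes = [p.length for p in psrs]
        assert sum(sizes) == length
        assert max(sizes) - min(sizes) <= 1
        assert len(psrs) <= 25


class TestAssignAnnotation:
    def test_ten_query_hand_traced_fixture(self):
        hits = [
            # q01: clean human hit -> HGNC tier
            hit("q01", "h1", "Homo sapiens", 200, 1e-20, "TP53"),
            # q02: human hit too weak (e >= 1e-9), pig rescues
            hit("q02", "h2", "Homo sapiens", 60, 1e-6, "BRCA1"),
            hit("q02", "p1", "Sus scrofa", 180, 1e-15, "BRCA1"),
            # q03: human LOC skipped at symbol tier, pig symbol wins
            hit("q03", "h3", "Homo sapiens", 300, 1e-30, "LOC12345"),
            hit("q03", "p2", "Sus scrofa", 150, 1e-12, "GAPDH"),
            # q04: species priority order — cow outranks mouse
            hit("q04", "b1", "Bos taurus", 150, 1e-12, "ACTB"),
            hit("q04", "m1", "Mus musculus", 250, 1e-25, "Actb"),
            # q05: only an off-list species -> any_hit (step 4)
            hit("q05", "x1", "Gallus gallus", 90, 1e-11, "MYC"),
            # q06: only LOC symbols -> loc_fallback in species order
            hit("q06", "h4", "Homo sapiens", 80, 1e-4, "LOC999"),
            hit("q06", "p3", "Sus scrofa", 150, 1e-14, "LOC777"),
            # q07: LOC from a species outside the fallback order -> step 6
            hit("q07", "x2", "Danio rerio", 70, 1e-10, "LOC555"),
            # q08: within-species best-hit by e-value before tiers
            hit("q08", "h5", "Homo sapiens", 100, 1e-10, "WEAK"),
            hit("q08", "h6", "Homo sapiens", 90, 1e-22, "STRONG"),
            # q09: e-value tie broken by higher bitscore
            hit("q09", "h7", "Homo sapiens", 120, 1e-15, "LOSER"),
            hit("q09", "h8", "Homo sapiens", 180, 1e-15, "WINNER"),
        ]
        records = assign_annotation(hits, queries=["q10"])  # q10 has no hits

        assert (records["q01"].symbol, records["q01"].tier) == ("TP53", "human_hgnc")
        assert (records["q02"].symbol, records["q02"].species) == ("BRCA1", "Sus scrofa")
        assert records["q02"].tier == "species_symbol"
        assert (records["q03"].symbol, records["q03"].tier) == ("GAPDH", "species_symbol")
        assert records["q04"].symbol == "ACTB"  # cow before mouse in priority
        assert (records["q05"].tier, records["q05"].rule) == ("any_hit", "step4")
        assert (records["q06"].symbol, records["q06"].tier) == ("LOC999", "loc_fallback")
        assert records["q06"].species == "Homo sapiens"  # human LOC outranks pig LOC
        assert (records["q07"].symbol, records["q07"].rule) == ("LOC555", "step6")
        assert records["q08"].symbol == "STRONG"
        assert records["q09"].symbol == "WINNER"
        assert (records["q10"].symbol, records["q10"].tier) == ("", "unannotated")

    def test_independent_of_hit_row_order(self):
        hits = [
            hit("q1", "h1", "Homo sapiens", 100, 1e-20, "A1"),
            hit("q1", "p1", "Sus scrofa", 300, 1e-30, "B2"),
            hit("q1", "b1", "Bos taurus", 200, 1e-25, "C3"),
        ]
        fwd = assign_annotation(hits)
        rev = assign_annotation(list(reversed(hits)))
        assert fwd == rev

    def test_cutoff_policy_changes_rule_not_symbol(self):
        # with the cutoff enforced the weak pig hit only survives via the
        # final everything-else step; without it, the symbol tier fires
        hits = [hit("q1", "p1", "Sus scrofa", 60, 1e-5, "PIGGY")]
        strict = assign_annotation(hits)
        loose = assign_annotation(hits, apply_cutoff_all_symbol_tiers=False)
        assert (strict["q1"].symbol, strict["q1"].tier, strict["q1"].rule) == (
            "PIGGY", "any_hit", "step6",
        )
        assert (loose["q1"].symbol, loose["q1"].tier, loose["q1"].rule) == (
            "PIGGY", "species_symbol", "step3",
        )

    def test_default_priority_orders(self):
        assert DEFAULT_SPECIES_PRIORITY[0] == "Homo sapiens"
        assert DEFAULT_SPECIES_PRIORITY.index("Bos taurus") < DEFAULT_SPECIES_PRIORITY.index(
            "Mus musculus"
        )
        assert list(DEFAULT_LOC_PRIORITY) == [
            "Homo sapiens", "Sus scrofa", "Bos taurus", "Pan troglodytes", "Mus musculus",
        ]
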