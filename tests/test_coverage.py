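import random

import pytest
from hypothesis import given, settings, strategies as st

from refaudit.coverage import (
    CoverageMatrix,
    FLAG_SOURCE_ERROR,
    FLAG_UNREGISTERED,
    apply_country_filter,
    apply_length_filter,
    build_coverage_matrix,
    country_tally,
    dedupe_cross_db,
    strip_version,
    summarize,
)
from refaudit.errors import SourceUnavailableError
from refaudit.model import (
    BarcodeGroup,
    FilterSpec,
    OrganismQuery,
    SourceDB,
    default_barcode_groups,
)
from refaudit.sources import Capability, SnapshotSource
from refaudit.sources.base import RecordSource
from refaudit.synth import demo_plan, generate_snapshot
from refaudit.taxonomy import Backbone, resolve_names

from conftest import make_record


def matrix_from_cells(cells_by_barcode):
    """Build a CoverageMatrix literal from {barcode: [counts per organism]}."""
    barcodes = list(cells_by_barcode)
    n = len(next(iter(cells_by_barcode.values())))
    organisms = [f"Org {i}" for i in range(n)]
    cells = {
        (o, b): cells_by_barcode[b][i]
        for i, o in enumerate(organisms)
        for b in barcodes
    }
    return CoverageMatrix(organisms=organisms, barcodes=barcodes, cells=cells)


class TestSummarize:
    def test_hand_enumerated_example(self):
        # oracle: CO1 5+0+2=7 of 10 total -> 70.0%; 16S 1+1+1=3 -> 30.0%
        cm = matrix_from_cells({"CO1": [5, 0, 2], "16S": [1, 1, 1]})
        st_ = summarize(cm)
        by = {r.barcode: r for r in st_.rows}
        assert by["CO1"].n_sequences == 7 and by["16S"].n_sequences == 3
        assert by["CO1"].pct_of_total == 70.0 and by["16S"].pct_of_total == 30.0
        assert by["CO1"].n_organisms_covered == 2 and by["16S"].n_organisms_covered == 3
        assert by["CO1"].n_organisms_missing == 1 and by["16S"].n_organisms_missing == 0
        assert st_.total_sequences == 10
        assert st_.total_organisms_detected == 3

    def test_all_zero_matrix(self):
        cm = matrix_from_cells({"CO1": [0, 0], "16S": [0, 0]})
        st_ = summarize(cm)
        for row in st_.rows:
            assert row.n_sequences == 0
            assert row.pct_of_total == 0.0
            assert row.n_organisms_missing == 2
        assert st_.total_organisms_detected == 0

    def test_single_barcode_pct_100(self):
        cm = matrix_from_cells({"CO1": [3, 4]})
        assert summarize(cm).rows[0].pct_of_total == 100.0

    def test_na_cells_excluded_not_zero(self):
        cm = matrix_from_cells({"CO1": [5, None], "16S": [1, 2]})
        st_ = summarize(cm)
        by = {r.barcode: r for r in st_.rows}
        assert by["CO1"].n_sequences == 5
        assert by["CO1"].n_organisms_covered == 1

    def test_half_up_rounding_from_raw_counts(self):
        # 1/3 -> 33.3, 2/3 -> 66.7 (never 33.4/66.6)
        cm = matrix_from_cells({"A": [1], "B": [2]})
        by = {r.barcode: r for r in summarize(cm).rows}
        assert by["A"].pct_of_total == 33.3
        assert by["B"].pct_of_total == 66.7

    @given(
        st.lists(
            st.lists(st.integers(min_value=0, max_value=50), min_size=3, max_size=3),
            min_size=1,
            max_size=5,
        )
    )
    @settings(max_examples=60, deadline=None)
    def test_identities_on_random_matrices(self, columns):
        cm = matrix_from_cells({f"B{i}": col for i, col in enumerate(columns)})
        st_ = summarize(cm)
        for row in st_.rows:
            assert row.n_organisms_covered + row.n_organisms_missing == len(cm.organisms)
            assert row.n_sequences == sum(
                cm.cells[(o, row.barcode)] for o in cm.organisms
            )
        assert st_.total_sequences == sum(r.n_sequences for r in st_.rows)
        if st_.total_sequences > 0:
            assert 99.5 <= sum(r.pct_of_total for r in st_.rows) <= 100.5


class TestBuildCoverageMatrix:
    def test_planted_counts_recovered(self):
        plan = demo_plan(seed=3)
        plan.barcode_groups = default_barcode_groups()
        src = SnapshotSource(generate_snapshot(plan))
        queries = resolve_names([o.binomial for o in plan.organisms])
        groups = [g for g in default_barcode_groups() if g.canonical in plan.barcodes]
        cm = build_coverage_matrix(src, queries, groups)
        for org in plan.organisms:
            for b in plan.barcodes:
                assert cm.cells[(org.binomial, b)] == plan.planted_counts[
                    (org.binomial, b)
                ]

    def test_empty_queries_rejected(self, xenopus_source, co1_group):
        with pytest.raises(ValueError):
            build_coverage_matrix(xenopus_source, [], [co1_group])

    def test_single_zero_cell(self, co1_group):
        from refaudit.sources import Snapshot

        src = SnapshotSource(Snapshot())
        cm = build_coverage_matrix(src, [OrganismQuery("Nobody here")], [co1_group])
        assert cm.cells[("Nobody here", "CO1")] == 0

    def test_unregistered_all_zero_flagged_no_fallback_rows(
        self, xenopus_source, xenopus_snapshot, co1_group, s16_group
    ):
        bb = Backbone.from_snapshot(xenopus_snapshot)
        cm = build_coverage_matrix(
            xenopus_source,
            [OrganismQuery("Euwallacea whitfordiodendrus")],
            [co1_group, s16_group],
            enable_fallback=True,
            backbone=bb,
        )
        assert cm.cells[("Euwallacea whitfordiodendrus", "CO1")] == 0
        assert cm.cells[("Euwallacea whitfordiodendrus", "16S")] == 0
        assert FLAG_UNREGISTERED in cm.flags["Euwallacea whitfordiodendrus"]
        assert cm.fallback_rows == []

    def test_source_error_cell_absent_not_zero(self, co1_group):
        class FailingSource(RecordSource):
            name = "broken"
            capabilities = Capability.COUNT | Capability.FETCH

            def count_matches(self, organism, group, filters=None):
                raise SourceUnavailableError("boom")

            def fetch_records(self, organism, group, filters=None, want_sequence=False):
                raise SourceUnavailableError("boom")

        cm = build_coverage_matrix(
            FailingSource(), [OrganismQuery("Xenopus laevis")], [co1_group]
        )
        assert cm.cells[("Xenopus laevis", "CO1")] is None
        assert FLAG_SOURCE_ERROR in cm.flags["Xenopus laevis"]

    def test_pooled_correction_counts(self, xenopus_source, co1_group):
        oq = OrganismQuery(
            "Xenopus laeviss", resolved_names=["Xenopus laeviss", "Xenopus laevis"]
        )
        cm = build_coverage_matrix(xenopus_source, [oq], [co1_group])
        assert cm.cells[("Xenopus laeviss", "CO1")] == 3
        assert "CORRECTED" in cm.flags["Xenopus laeviss"]

    def test_column_sum_identity_randomized(self):
        rng = random.Random(11)
        for _ in range(5):
            plan = demo_plan(seed=rng.randint(0, 10**6))
            src = SnapshotSource(generate_snapshot(plan))
            queries = resolve_names([o.binomial for o in plan.organisms])
            groups = [BarcodeGroup.singleton(b) for b in plan.barcodes]
            cm = build_coverage_matrix(src, queries, groups)
            st_ = summarize(cm)
            for row in st_.rows:
                assert row.n_sequences == sum(
                    cm.cells[(o, row.barcode)] for o in cm.organisms
                )


def random_records(rng, n=500):
    recs = []
    for i in range(n):
        length = rng.choice([None, rng.randint(50, 1200)])
        country = rng.choice([None, "Iceland", "Chile", " iceland ", "United States"])
        recs.append(
            make_record(
                f"R{i:04d}",
                organism=rng.choice(["A b", "C d", "E f"]),
                seq_length=length,
                country=country,
            )
        )
    return recs


class TestFilters:
    def test_length_filter_basic(self):
        recs = [
            make_record("A1", seq_length=100),
            make_record("A2", seq_length=500),
            make_record("A3", seq_length=900),
        ]
        kept, dropped = apply_length_filter(recs, 200, 800)
        assert [r.accession for r in kept] == ["A2"]
        assert len(dropped) == 2

    def test_no_bounds_identity(self):
        recs = [make_record("A1", seq_length=None), make_record("A2", seq_length=5)]
        kept, dropped = apply_length_filter(recs)
        assert kept == recs and dropped == []

    def test_bounds_inclusive(self):
        recs = [make_record("A1", seq_length=200), make_record("A2", seq_length=800)]
        kept, _ = apply_length_filter(recs, 200, 800)
        assert len(kept) == 2

    def test_absent_length_dropped_and_reported(self):
        recs = [make_record("A1", seq_length=None)]
        kept, dropped = apply_length_filter(recs, 100, None)
        assert kept == [] and dropped == recs

    def test_country_filter_basic(self):
        recs = [
            make_record("A1", country="Iceland"),
            make_record("A2", country="Chile"),
            make_record("A3", country=None),
        ]
        kept = apply_country_filter(recs, {"Iceland"})
        assert [r.accession for r in kept] == ["A1"]

    def test_unspecified_matches_absent_country(self):
        recs = [make_record("A1", country="Iceland"), make_record("A2", country=None)]
        kept = apply_country_filter(recs, {"Unspecified"})
        assert [r.accession for r in kept] == ["A2"]

    def test_empty_country_set_keeps_nothing(self):
        assert apply_country_filter([make_record("A1", country="Iceland")], set()) == []

    def test_country_trim_and_case(self):
        recs = [make_record("A1", country="  ICELAND ")]
        assert len(apply_country_filter(recs, {"iceland"})) == 1

    def test_oracle_equivalence_500_records(self):
        rng = random.Random(99)
        recs = random_records(rng, 500)
        lo, hi = 200, 900
        kept, dropped = apply_length_filter(recs, lo, hi)
        expected = [r for r in recs if r.seq_length is not None and lo <= r.seq_length <= hi]
        assert kept == expected
        assert dropped == [r for r in recs if r not in expected]

        wanted = {"Iceland", "Unspecified"}
        kept_c = apply_country_filter(recs, wanted)
        norm = lambda c: (c or "Unspecified").strip().casefold()
        expected_c = [r for r in recs if norm(r.country) in {w.casefold() for w in wanted}]
        assert kept_c == expected_c

    def test_filters_commute(self):
        rng = random.Random(7)
        recs = random_records(rng, 300)
        a, _ = apply_length_filter(apply_country_filter(recs, {"Iceland"}), 100, 1000)
        b = apply_country_filter(apply_length_filter(recs, 100, 1000)[0], {"Iceland"})
        assert a == b

    def test_invalid_bounds(self):
        with pytest.raises(ValueError):
            apply_length_filter([], 500, 100)


class TestDedupe:
    def test_strip_version(self):
        assert strip_version("MK123.1") == "MK123"
        assert strip_version("MK123") == "MK123"
        assert strip_version("MK.ABC") == "MK.ABC"

    def test_planted_overlap_removed(self):
        bold = [
            make_record(f"B{i}", source_db=SourceDB.BOLD,
                        genbank_xref=f"NC{i:03d}.1" if i < 4 else None)
            for i in range(10)
        ]
        ncbi_set = {f"NC{i:03d}" for i in range(4)}
        kept, removed = dedupe_cross_db(bold, ncbi_set)
        assert len(kept) == 6 and len(removed) == 4

    def test_absent_xref_always_kept(self):
        bold = [make_record("B1", source_db=SourceDB.BOLD, genbank_xref=None)]
        kept, removed = dedupe_cross_db(bold, {"B1"})
        assert kept == bold and removed == []

    def test_empty_ncbi_set_identity(self):
        bold = [make_record("B1", source_db=SourceDB.BOLD, genbank_xref="X.1")]
        kept, removed = dedupe_cross_db(bold, set())
        assert kept == bold and removed == []

    def test_partition_and_order(self):
        bold = [
            make_record(f"B{i}", source_db=SourceDB.BOLD,
                        genbank_xref="HIT" if i % 2 else None)
            for i in range(6)
        ]
        kept, removed = dedupe_cross_db(bold, {"HIT"})
        assert kept + removed != []
        assert sorted(r.accession for r in kept + removed) == sorted(
            r.accession for r in bold
        )
        assert [r.accession for r in kept] == ["B0", "B2", "B4"]

    def test_postcondition_no_residual_overlap(self):
        bold = [
            make_record(f"B{i}", source_db=SourceDB.BOLD, genbank_xref=f"X{i}.2")
            for i in range(8)
        ]
        ncbi_set = {"X1", "X5"}
        kept, _ = dedupe_cross_db(bold, ncbi_set)
        assert {
            strip_version(r.genbank_xref) for r in kept if r.genbank_xref
        } & ncbi_set == set()


class TestCountryTally:
    def test_basic(self):
        recs = [
            make_record("A1", country="Iceland"),
            make_record("A2", country="Iceland", organism="C d"),
            make_record("A3", country="Chile"),
        ]
        tally = country_tally(recs)
        assert tally[0] == ("Iceland", 2, 2)
        assert tally[1] == ("Chile", 1, 1)

    def test_empty(self):
        assert country_tally([]) == []

    def test_all_absent_single_unspecified_row(self):
        recs = [make_record(f"A{i}", country=None) for i in range(3)]
        tally = country_tally(recs)
        assert tally == [("Unspecified", 3, 1)]

    def test_record_conservation(self):
        rng = random.Random(5)
        recs = random_records(rng, 200)
        tally = country_tally(recs)
        assert sum(n for _, n, _ in tally) == len(recs)
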