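"""Screening of mined candidates: table IO, filters, triad scan, composition."""

import pytest

from pessp.curation import (
    ReferenceTableError,
    cap_identity_duplicates,
    curate,
    dedup_by_species,
    filter_identity_window,
    load_reference_table,
    scan_catalytic_triad,
    write_reference_table,
)
from pessp.datasets import table1_path
from pessp.records import CurationConfig, ProteinRecord


def rec(acc, identity=50.0, organism=None, defined="", predicted="putative nitrilase",
        residues=""):
    return ProteinRecord(
        accession=acc,
        organism=organism or f"Testus sp. {acc}",
        residues=residues,
        predicted_function=predicted,
        defined_function=defined,
        identity_to_query=identity,
    )


class TestLoadReferenceTable:
    def test_packaged_candidate_table_loads_fully(self):
        records = load_reference_table(table1_path())
        assert len(records) == 39
        assert sum(r.is_reference for r in records) == 16
        # row order preserved: the query enzyme heads the table at 100%
        assert records[0].accession == "NP_773042"
        assert records[0].identity_to_query == 100.0
        assert records[-1].identity_to_query == 30.0

    def test_header_only_file_yields_empty_list(self, tmp_path):
        p = tmp_path / "empty.tsv"
        p.write_text(
            "accession\torganism\tpredicted_function\tdefined_function\t"
            "identity_pct\tcitation\n"
        )
        assert load_reference_table(p) == []

    @pytest.mark.parametrize(
        "body,match",
        [
            ("A1\tOrg\t\tnitrilase\t50\t\nA1\tOrg\t\t\t40\t\n", "duplicate accession"),
            ("A1\tOrg\t\t\tforty\t\n", "malformed identity"),
        ],
    )
    def test_bad_rows_are_parse_errors_naming_the_row(self, tmp_path, body, match):
        p = tmp_path / "bad.tsv"
        p.write_text(
            "accession\torganism\tpredicted_function\tdefined_function\t"
            "identity_pct\tcitation\n" + body
        )
        with pytest.raises(ReferenceTableError, match=match):
            load_reference_table(p)

    def test_wrong_header_rejected(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("acc\torg\n")
        with pytest.raises(ReferenceTableError, match="header"):
            load_reference_table(p)

    def test_round_trip(self, tmp_path):
        records = load_reference_table(table1_path())
        out = tmp_path / "rt.tsv"
        write_reference_table(records, out)
        again = load_reference_table(out)
        assert [r.accession for r in again] == [r.accession for r in records]
        assert [r.identity_to_query for r in again] == [
            r.identity_to_query for r in records
        ]


class TestIdentityWindow:
    def test_too_similar_uncharacterized_removed(self):
        kept = filter_identity_window([rec("X", 95.0)], CurationConfig())
        assert kept == []

    def test_mid_window_candidate_kept(self):
        # mirrors the Burkholderia cenocepacia J2315 row at 56%
        r = rec("YP_002231697", 56.0)
        assert filter_identity_window([r], CurationConfig()) == [r]

    def test_query_itself_survives_via_defined_function_priority(self):
        query = rec("NP_773042", 100.0, defined="nitrilase", predicted="")
        assert filter_identity_window([query], CurationConfig()) == [query]

    def test_unset_identity_is_an_error_naming_accessions(self):
        bad = rec("NOID", None)
        with pytest.raises(ValueError, match="NOID"):
            filter_identity_window([rec("OK", 50.0), bad], CurationConfig())


class TestIdentityCap:
    def test_third_record_at_shared_identity_dropped(self):
        records = [rec("A", 58.0), rec("B", 58.0), rec("C", 58.0)]
        kept = cap_identity_duplicates(records, CurationConfig())
        assert [r.accession for r in kept] == ["A", "B"]

    def test_pair_at_shared_identity_survives(self):
        records = [rec("A", 58.0), rec("B", 58.0)]
        assert cap_identity_duplicates(records, CurationConfig()) == records

    def test_distinct_identities_untouched(self):
        records = [rec(f"R{i}", 30.0 + i) for i in range(10)]
        assert cap_identity_duplicates(records, CurationConfig()) == records

    def test_references_neither_count_nor_fall(self):
        records = [
            rec("REF1", 58.0, defined="nitrilase"),
            rec("A", 58.0),
            rec("B", 58.0),
            rec("REF2", 58.0, defined="nitrilase"),
        ]
        kept = cap_identity_duplicates(records, CurationConfig())
        assert [r.accession for r in kept] == ["REF1", "A", "B", "REF2"]

    def test_raising_cap_never_shrinks_survivors(self):
        records = [rec(f"R{i}", 58.0) for i in range(5)]
        sizes = [
            len(cap_identity_duplicates(records, CurationConfig(max_per_identity=k)))
            for k in (1, 2, 3, 4, 5)
        ]
        assert sizes == sorted(sizes)


class TestSpeciesDedup:
    def test_distinct_loci_from_one_strain_both_kept(self, make_triad_sequence):
        a = rec("L1", 58.0, organism="Sphingomonas wittichii RW1",
                residues=make_triad_sequence(1))
        b = rec("L2", 46.0, organism="Sphingomonas wittichii RW1",
                residues=make_triad_sequence(2))
        assert dedup_by_species([a, b]) == [a, b]

    def test_identical_sequence_from_one_organism_collapsed(self, make_triad_sequence):
        s = make_triad_sequence(3)
        a = rec("D1", 58.0, organism="Same sp.", residues=s)
        b = rec("D2", 58.0, organism="Same sp.", residues=s)
        assert dedup_by_species([a, b]) == [a]

    def test_all_distinct_organisms_pass_through(self, make_triad_sequence):
        records = [rec(f"O{i}", 50.0, residues=make_triad_sequence(i)) for i in range(4)]
        assert dedup_by_species(records) == records


class TestTriadScan:
    def test_ordered_triple_found_with_positions(self):
        assert scan_catalytic_triad("MEAKAC") == (True, (2, 4, 6))

    def test_no_cysteine_means_no_triad(self):
        assert scan_catalytic_triad("MEAKAA") == (False, None)

    def test_order_violation_rejected(self):
        assert scan_catalytic_triad("CKE") == (False, None)

    def test_empty_sequence_is_an_error(self):
        with pytest.raises(ValueError):
            scan_catalytic_triad("")

    def test_spacing_window_enforced_when_requested(self):
        found, _ = scan_catalytic_triad("MEAKAC", min_spacing=10, max_spacing=400)
        assert not found
        seq = "E" + "A" * 10 + "K" + "A" * 10 + "C"
        found, pos = scan_catalytic_triad(seq, min_spacing=10, max_spacing=400)
        assert found and pos == (1, 12, 23)

    def test_result_invariant_under_appending_after_found_cysteine(self):
        base = "MEAKAC"
        found, pos = scan_catalytic_triad(base)
        for suffix in ("", "AAAA", "EKC", "WWWWWW"):
            assert scan_catalytic_triad(base + suffix)[0] == found
            assert scan_catalytic_triad(base + suffix)[1] == pos


class TestCurate:
    @pytest.fixture
    def fixture_records(self, make_triad_sequence):
        records = load_reference_table(table1_path())
        return [r.with_residues(make_triad_sequence(i)) for i, r in enumerate(records)]

    def test_printed_table_is_not_a_fixed_point_of_the_printed_cap(self, fixture_records):
        """Four uncharacterized rows share identity 36%, so the two-per-identity
        cap (applied at the table's integer precision) removes the last two of
        them on re-screening; everything else survives."""
        curated = curate(fixture_records)
        assert len(curated) == 37
        assert curated.audit == {
            "NP_949502": "identity_cap",
            "YP_260565": "identity_cap",
        }
        assert sum(r.is_reference for r in curated.records) == 16

    def test_injected_too_similar_record_audited_to_identity_window(
        self, fixture_records, make_triad_sequence
    ):
        extra = rec("INJECTED", 95.0, residues=make_triad_sequence(99))
        curated = curate(fixture_records + [extra])
        assert curated.audit["INJECTED"] == "identity_window"
        assert "INJECTED" not in curated.accessions

    def test_unnamed_product_without_triad_removed(self, make_triad_sequence):
        no_triad = rec("NOTRIAD", 50.0, predicted="unnamed protein product",
                       residues="M" + "A" * 100)
        with_triad = rec("TRIAD", 51.0, predicted="unnamed protein product",
                         residues=make_triad_sequence(5))
        curated = curate([no_triad, with_triad])
        assert curated.accessions == ["TRIAD"]
        assert curated.audit == {"NOTRIAD": "missing_triad"}

    def test_empty_input_gives_empty_set(self):
        curated = curate([])
        assert len(curated) == 0 and curated.audit == {}

    def test_curation_is_idempotent(self, fixture_records):
        once = curate(fixture_records)
        twice = curate(once.records)
        assert twice.accessions == once.accessions
        assert twice.audit == {}

    def test_references_always_survive(self, fixture_records):
        curated = curate(fixture_records)
        expected = {r.accession for r in fixture_records if r.is_reference}
        assert expected <= set(curated.accessions)

    def test_tightening_identity_high_never_grows_survivors(self, fixture_records):
        sizes = [
            len(curate(fixture_records, CurationConfig(identity_high=h)))
            for h in (90.0, 60.0, 50.0, 40.0)
        ]
        assert sizes == sorted(sizes, reverse=True)

    def test_passthrough_config_removes_nothing(self, fixture_records):
        curated = curate(fixture_records, CurationConfig.passthrough())
        assert len(curated) == len(fixture_records) and curated.audit == {}
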