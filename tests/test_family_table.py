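import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from medfamilies import (
    FamilyRecord,
    FamilyTable,
    filter_min_size,
    read_family_table,
    substitute_missing_regional_totals,
    write_results_table,
)
from medfamilies.family_table import (
    DuplicateColumnError,
    DuplicateFamilyError,
    MedicinalExceedsTotalError,
    MissingColumnError,
    MissingFamilyError,
    NonIntegerCountError,
    UnknownRegionError,
)


def make_table(rows, stratum="NATIONAL"):
    return FamilyTable(
        records=tuple(
            FamilyRecord(family=f, total_species=t, medicinal_species=m, region=stratum)
            for f, t, m in rows
        ),
        stratum=stratum,
    )


class TestRecordValidation:
    def test_medicinal_exceeding_total_is_rejected(self):
        with pytest.raises(MedicinalExceedsTotalError):
            FamilyRecord(family="X", total_species=3, medicinal_species=5)

    @pytest.mark.parametrize("bad", [-1, 2.5, True])
    def test_counts_must_be_nonnegative_integers(self, bad):
        with pytest.raises(NonIntegerCountError):
            FamilyRecord(family="X", total_species=10, medicinal_species=bad)

    def test_unknown_region_code_rejected(self):
        with pytest.raises(UnknownRegionError):
            FamilyRecord(family="X", total_species=10, medicinal_species=1, region="XX")

    def test_unknown_total_is_distinct_from_zero(self):
        rec = FamilyRecord(family="X", total_species=None, medicinal_species=4)
        assert rec.total_species is None
        zero = FamilyRecord(family="Y", total_species=0, medicinal_species=0)
        assert zero.total_species == 0

    def test_duplicate_family_within_stratum_rejected(self):
        with pytest.raises(DuplicateFamilyError):
            make_table([("A", 10, 1), ("A", 12, 2)])

    def test_labels_are_whitespace_trimmed_not_case_folded(self):
        rec = FamilyRecord(family="  Asteraceae ", total_species=10, medicinal_species=1)
        assert rec.family == "Asteraceae"
        # case differences are distinct families
        make_table([("asteraceae", 10, 1), ("Asteraceae", 10, 1)])


class TestReadWrite:
    def test_read_two_national_rows(self, tmp_path):
        p = tmp_path / "t.tsv"
        p.write_text(
            "family\ttotal_species\tmedicinal_species\n"
            "Asteraceae\t237\t139\nOrchidaceae\t1099\t32\n"
        )
        table = read_family_table(p)
        assert len(table) == 2
        assert table["Asteraceae"].medicinal_species == 139
        assert table.stratum == "NATIONAL"

    def test_empty_data_section_is_valid(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text("family,total_species,medicinal_species\n")
        assert len(read_family_table(p, dialect="csv")) == 0

    def test_missing_column_raises(self, tmp_path):
        p = tmp_path / "t.tsv"
        p.write_text("family\ttotal_species\nA\t10\n")
        with pytest.raises(MissingColumnError):
            read_family_table(p)

    def test_duplicate_column_raises(self, tmp_path):
        p = tmp_path / "t.tsv"
        p.write_text("family\tfamily\ttotal_species\tmedicinal_species\nA\tA\t10\t1\n")
        with pytest.raises(DuplicateColumnError):
            read_family_table(p)

    def test_invariant_violation_raises(self, tmp_path):
        p = tmp_path / "t.tsv"
        p.write_text("family\ttotal_species\tmedicinal_species\nA\t3\t5\n")
        with pytest.raises(MedicinalExceedsTotalError):
            read_family_table(p)

    def test_blank_total_reads_as_unknown(self, tmp_path):
        p = tmp_path / "t.tsv"
        p.write_text(
            "family\tregion\ttotal_species\tmedicinal_species\nFam1\tN\t\t4\n"
        )
        table = read_family_table(p)
        assert table["Fam1"].total_species is None
        assert table.stratum == "N"

    def test_results_roundtrip_through_reader(self, national_result, tmp_path):
        out = tmp_path / "results.tsv"
        write_results_table(national_result, out)
        back = read_family_table(out)
        assert len(back) == 115
        for res in national_result.residuals:
            rec = back[res.family]
            assert (rec.total_species, rec.medicinal_species) == (
                res.total_species,
                res.observed,
            )

    def test_small_probability_rendered_in_scientific_notation(
        self, national_result, tmp_path
    ):
        out = tmp_path / "results.tsv"
        write_results_table(national_result, out)
        amaranthaceae = next(
            line for line in out.read_text().splitlines() if line.startswith("Amaranthaceae")
        )
        p_cell = amaranthaceae.split("\t")[7]
        assert "E-05" in p_cell


class TestFixture:
    def test_integrity(self, table1):
        assert len(table1) == 115
        assert table1.total_species_sum() == 9097
        assert all(r.total_species >= 10 for r in table1)
        assert all(r.medicinal_species <= r.total_species for r in table1)

    def test_known_rows(self, table1):
        assert table1["Asteraceae"].total_species == 237
        assert table1["Asteraceae"].medicinal_species == 139
        assert table1["Orchidaceae"].total_species == 1099


class TestFilter:
    def test_fixture_already_filtered_at_10(self, table1):
        assert filter_min_size(table1, 10).families == table1.families

    def test_k_zero_is_identity(self, table1):
        assert filter_min_size(table1, 0) == table1

    def test_toy_enumeration(self):
        table = make_table([("A", 9, 1), ("B", 10, 2), ("C", 50, 5)])
        assert filter_min_size(table, 10).families == ("B", "C")

    @given(k1=st.integers(0, 100), k2=st.integers(0, 100))
    @settings(max_examples=30, derandomize=True)
    def test_idempotent_and_monotone(self, table1, k1, k2):
        once = filter_min_size(table1, k1)
        assert filter_min_size(once, k1) == once
        lo, hi = sorted([k1, k2])
        assert set(filter_min_size(table1, hi).families) <= set(
            filter_min_size(table1, lo).families
        )


class TestSubstitution:
    national = make_table([("Fam1", 30, 5), ("Fam2", 20, 3)])

    def test_unknown_total_takes_national_value(self):
        regional = FamilyTable(
            records=(
                FamilyRecord(family="Fam1", region="N", total_species=None, medicinal_species=4),
            ),
            stratum="N",
        )
        out = substitute_missing_regional_totals(regional, self.national)
        assert out["Fam1"].total_species == 30
        assert out["Fam1"].medicinal_species == 4

    def test_no_unknowns_is_identity(self):
        regional = FamilyTable(
            records=(
                FamilyRecord(family="Fam1", region="N", total_species=12, medicinal_species=4),
            ),
            stratum="N",
        )
        assert substitute_missing_regional_totals(regional, self.national) == regional

    def test_family_absent_nationally_raises(self):
        regional = FamilyTable(
            records=(
                FamilyRecord(family="FamX", region="N", total_species=None, medicinal_species=2),
            ),
            stratum="N",
        )
        with pytest.raises(MissingFamilyError):
            substitute_missing_regional_totals(regional, self.national)

    def test_substitution_cannot_break_count_invariant(self):
        regional = FamilyTable(
            records=(
                FamilyRecord(family="Fam2", region="N", total_species=None, medicinal_species=25),
            ),
            stratum="N",
        )
        with pytest.raises(MedicinalExceedsTotalError):
            substitute_missing_regional_totals(regional, self.national)
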