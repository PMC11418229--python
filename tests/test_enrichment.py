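import io
import math

import pytest

from goenrichview import (
    AnalysisSet,
    adjusted_p,
    attach,
    combine_over_under,
    fold_change,
    is_significant,
    read_combined_table,
    read_gostats_table,
    write_combined_table,
)
from goenrichview.errors import TableFormatError, UndefinedFoldError

from conftest import D, D_ALT, make_record

HEADER = "GOBPID\tPvalue\tOddsRatio\tExpCount\tCount\tSize\tTerm"


def table(*rows, header=HEADER):
    return io.StringIO("\n".join([header, *rows]) + "\n")


class TestReadGostatsTable:
    def test_basic_row_mapping_comma_delimited(self):
        src = io.StringIO(
            "GOBPID,Pvalue,OddsRatio,ExpCount,Count,Size,Term\n"
            "GO:0000004, 0.001, 3.2, 2.5, 10, 40, D\n"
        )
        (rec,) = read_gostats_table(src, "over")
        assert rec.go_id == "GO:0000004"
        assert rec.p_value == 0.001
        assert rec.odds_ratio == 3.2
        assert rec.expected_count == 2.5
        assert rec.observed_count == 10
        assert rec.gene_set_size == 40
        assert rec.direction == "over"

    def test_header_only_is_empty(self):
        assert read_gostats_table(table(), "over") == []

    def test_inf_odds_ratio_accepted(self):
        (rec,) = read_gostats_table(
            table("GO:0000004\t0.001\tInf\t2.5\t10\t40\tD"), "over"
        )
        assert math.isinf(rec.odds_ratio)

    @pytest.mark.parametrize(
        "id_col", ["GOBPID", "GOMFID", "GOCCID", "GOID", "gobpid"]
    )
    def test_id_column_variants(self, id_col):
        header = HEADER.replace("GOBPID", id_col)
        recs = read_gostats_table(
            table("GO:0000004\t0.5\t1.0\t2.0\t2\t10\tD", header=header), "under"
        )
        assert recs[0].go_id == "GO:0000004"

    def test_missing_id_column_is_format_error(self):
        header = HEADER.replace("GOBPID", "Identifier")
        with pytest.raises(TableFormatError, match="GO id column"):
            read_gostats_table(table(header=header), "over")

    def test_missing_mandatory_column_named(self):
        header = HEADER.replace("\tOddsRatio", "")
        with pytest.raises(TableFormatError, match="OddsRatio"):
            read_gostats_table(
                table("GO:0000004\t0.5\t2.0\t2\t10\tD", header=header), "over"
            )

    def test_unparseable_numeric_cites_row(self):
        with pytest.raises(TableFormatError, match="row 2"):
            read_gostats_table(
                table(
                    "GO:0000004\t0.5\t1.0\t2.0\t2\t10\tD",
                    "GO:0000005\tnot_a_p\t1.0\t2.0\t2\t10\tE",
                ),
                "over",
            )


class TestCombineOverUnder:
    def test_id_only_in_one_direction_kept(self):
        over = [make_record(go_id="GO:0000002", direction="over")]
        combined = combine_over_under(over, [])
        assert combined["GO:0000002"].direction == "over"

    def test_min_p_wins(self):
        over = [make_record(p_value=0.001, direction="over")]
        under = [make_record(p_value=0.9, direction="under")]
        assert combine_over_under(over, under)[D].direction == "over"
        assert combine_over_under(
            [make_record(p_value=0.9, direction="over")],
            [make_record(p_value=0.001, direction="under")],
        )[D].direction == "under"

    def test_tie_goes_to_over(self):
        over = [make_record(p_value=0.01, direction="over")]
        under = [make_record(p_value=0.01, direction="under")]
        assert combine_over_under(over, under)[D].direction == "over"

    def test_size_is_union_of_ids(self):
        over = [make_record(go_id=f"GO:000000{i}") for i in (1, 2)]
        under = [
            make_record(go_id=f"GO:000000{i}", direction="under") for i in (2, 3)
        ]
        assert set(combine_over_under(over, under)) == {
            "GO:0000001",
            "GO:0000002",
            "GO:0000003",
        }

    def test_combined_file_round_trip_with_direction_column(self):
        over = [make_record(go_id="GO:0000002", direction="over")]
        under = [make_record(go_id="GO:0000003", direction="under")]
        buf = io.StringIO()
        write_combined_table(over, under, buf, policy="concat")
        buf.seek(0)
        back = read_combined_table(buf)
        assert {(r.go_id, r.direction) for r in back} == {
            ("GO:0000002", "over"),
            ("GO:0000003", "under"),
        }

    def test_combined_file_without_direction_infers_from_odds_ratio(self):
        src = table(
            "GO:0000002\t0.01\t3.0\t2.0\t6\t20\tB",
            "GO:0000003\t0.01\t0.4\t5.0\t2\t20\tC",
        )
        by_id = {r.go_id: r for r in read_combined_table(src)}
        assert by_id["GO:0000002"].direction == "over"
        assert by_id["GO:0000003"].direction == "under"


class TestFoldChange:
    @pytest.mark.parametrize(
        "obs,exp,want", [(10, 2.5, 4.0), (1, 4.0, 0.25), (0, 2.0, 0.0)]
    )
    def test_ratio(self, obs, exp, want):
        rec = make_record(observed_count=obs, expected_count=exp)
        assert fold_change(rec) == want

    def test_zero_expected_is_undefined(self):
        rec = make_record(expected_count=0.0, observed_count=0)
        with pytest.raises(UndefinedFoldError):
            fold_change(rec)

    def test_product_identity(self):
        rec = make_record(observed_count=7, expected_count=1.9)
        assert abs(fold_change(rec) * rec.expected_count - rec.observed_count) < 1e-12


class TestSignificance:
    def test_raw_below_alpha(self):
        aset = AnalysisSet(analyses=[("a", {D: make_record(p_value=0.001)})])
        assert is_significant(aset.records_for("a")[D], aset)

    def test_boundary_is_strict(self):
        aset = AnalysisSet(analyses=[("a", {D: make_record(p_value=0.05)})])
        assert not is_significant(aset.records_for("a")[D], aset)

    def test_bh_hand_example(self):
        recs = [
            make_record(go_id="GO:0000001", p_value=0.01),
            make_record(go_id="GO:0000002", p_value=0.02),
            make_record(go_id="GO:0000003", p_value=0.04),
        ]
        adj = adjusted_p(recs, "benjamini_hochberg")
        assert adj == pytest.approx(
            {"GO:0000001": 0.03, "GO:0000002": 0.03, "GO:0000003": 0.04}
        )
        aset = AnalysisSet(
            analyses=[("a", {r.go_id: r for r in recs})],
            adjust="benjamini_hochberg",
        )
        assert all(aset.significance("a").values())

    def test_bh_monotone_and_bounded(self):
        ps = [0.001, 0.2, 0.04, 0.9, 0.5, 0.0499]
        recs = [
            make_record(go_id=f"GO:00000{i:02d}", p_value=p)
            for i, p in enumerate(ps, 1)
        ]
        adj = adjusted_p(recs, "benjamini_hochberg")
        ranked = sorted(recs, key=lambda r: r.p_value)
        values = [adj[r.go_id] for r in ranked]
        assert values == sorted(values)
        assert all(0 <= v <= 1 for v in values)


class TestAttach:
    def _four_analyses(self):
        return AnalysisSet(
            analyses=[
                (f"analysis_{k}", {D: make_record()}) for k in range(1, 5)
            ]
        )

    def test_label_order_preserved(self, diamond):
        index = attach(diamond, self._four_analyses())
        assert index.labels == [f"analysis_{k}" for k in range(1, 5)]
        assert len(index.per_analysis(D)) == 4
        assert all(r is not None for r in index.per_analysis(D))

    def test_alt_id_filed_under_canonical(self, diamond):
        aset = AnalysisSet(analyses=[("a", {D_ALT: make_record(go_id=D_ALT)})])
        index = attach(diamond, aset)
        assert index.per_analysis(D)[0] is not None
        assert index.unmatched == []

    def test_absent_id_reported_not_dropped_silently(self, diamond):
        aset = AnalysisSet(
            analyses=[("a", {"GO:9999999": make_record(go_id="GO:9999999")})]
        )
        index = attach(diamond, aset)
        assert index.unmatched == [("a", "GO:9999999")]
        assert "GO:9999999" not in index.records


class TestRecordValidation:
    def test_p_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            make_record(p_value=1.5)

    def test_count_above_size_rejected(self):
        with pytest.raises(ValueError):
            make_record(observed_count=50, gene_set_size=40)

    def test_duplicate_labels_rejected(self):
        with pytest.raises(ValueError):
            AnalysisSet(analyses=[("a", {}), ("a", {})])
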