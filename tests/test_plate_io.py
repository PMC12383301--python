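import json

import numpy as np
import pandas as pd
import pytest

from stip.plate_io import (ConfluenceTrace, DeathTrace, ParseError,
                           StructuralError, ValidationError,
                           read_confluence_export, read_death_export,
                           read_metrics, read_plate_map, write_results)

POINT_CSV = """# exported traces
elapsed_h,A1,A2
0,0.0,10.0
1,0.1,12.5
2,0.4,15.0
"""

COMMA_CSV = """# exported traces
elapsed_h;A1;A2
0;0,0;10,0
1;0,1;12,5
2;0,4;15,0
"""


class TestConfluenceExport:
    def test_decimal_comma_values_parse_as_points(self, tmp_path):
        p = tmp_path / "c.csv"
        p.write_text(COMMA_CSV)
        traces = {t.well_id: t for t in read_confluence_export(p)}
        assert np.allclose(traces["A1"].values, [0.0, 0.1, 0.4])
        assert np.allclose(traces["A2"].values, [10.0, 12.5, 15.0])

    def test_dialects_yield_identical_traces(self, tmp_path):
        pa = tmp_path / "a.csv"
        pa.write_text(POINT_CSV)
        pb = tmp_path / "b.csv"
        pb.write_text(COMMA_CSV)
        ta = {t.well_id: t for t in read_confluence_export(pa)}
        tb = {t.well_id: t for t in read_confluence_export(pb)}
        for w in ta:
            assert np.array_equal(ta[w].values, tb[w].values)
            assert np.array_equal(ta[w].times, tb[w].times)

    def test_forced_point_dialect_on_comma_file_errors(self, tmp_path):
        p = tmp_path / "c.csv"
        p.write_text(COMMA_CSV)
        with pytest.raises((ParseError, ValidationError)):
            read_confluence_export(p, dialect="point")

    def test_hourly_file_gives_full_length_trace(self, tmp_path):
        rows = ["elapsed_h,B7"] + [f"{t},{min(99, t)}" for t in range(49)]
        p = tmp_path / "h.csv"
        p.write_text("\n".join(rows))
        (trace,) = read_confluence_export(p)
        assert trace.well_id == "B7"
        assert len(trace) == 49

    def test_nonnumeric_cell_names_row_and_column(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("elapsed_h,A1\n0,5\n1,oops\n")
        with pytest.raises(ParseError, match=r"row 3.*'A1'.*oops"):
            read_confluence_export(p)

    def test_out_of_range_value_lists_offender(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("elapsed_h,A1\n0,5\n1,105\n")
        with pytest.raises(ValidationError, match="105"):
            read_confluence_export(p)

    def test_non_increasing_time_column_errors(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("elapsed_h,A1\n0,5\n2,6\n1,7\n")
        with pytest.raises(ValidationError, match="increasing"):
            read_confluence_export(p)

    def test_pretreatment_rows_dropped_with_warning(self, tmp_path):
        p = tmp_path / "pre.csv"
        p.write_text("elapsed_h,A1\n-2,3\n-1,4\n0,5\n1,6\n2,7\n")
        with pytest.warns(UserWarning, match="pre-treatment"):
            (trace,) = read_confluence_export(p)
        assert trace.times[0] == 0

    def test_short_gaps_interpolated_long_gaps_error(self, tmp_path):
        p = tmp_path / "gap.csv"
        p.write_text("elapsed_h,A1\n0,0\n1,\n2,\n3,30\n4,40\n")
        (trace,) = read_confluence_export(p)
        assert np.allclose(trace.values, [0, 10, 20, 30, 40])
        p2 = tmp_path / "gap2.csv"
        p2.write_text("elapsed_h,A1\n0,0\n1,\n2,\n3,\n4,40\n5,50\n")
        with pytest.raises(ValidationError, match="consecutive missing"):
            read_confluence_export(p2)

    def test_well_ids_case_insensitive_uppercased(self, tmp_path):
        p = tmp_path / "case.csv"
        p.write_text("elapsed_h,b7\n0,1\n1,2\n")
        (trace,) = read_confluence_export(p)
        assert trace.well_id == "B7"


class TestTraceInvariants:
    def test_irregular_grid_rejected(self):
        with pytest.raises(ValidationError, match="uniform"):
            ConfluenceTrace("A1", [0, 1, 2, 10], [1, 2, 3, 4])

    def test_death_trace_rejects_decreasing_values(self, tmp_path):
        with pytest.raises(ValidationError, match="decreases"):
            DeathTrace("A1", [0, 1, 2], [1.0, 2.0, 1.0])
        # within the 0.2-point smoothing tolerance is acceptable
        DeathTrace("A1", [0, 1, 2], [1.0, 2.0, 1.85])

    def test_death_export_reader_roundtrip(self, tmp_path):
        p = tmp_path / "d.csv"
        p.write_text("elapsed_h,A1\n0,0\n1,0.5\n2,1.2\n")
        (trace,) = read_death_export(p)
        assert isinstance(trace, DeathTrace)
        assert trace.values[-1] == 1.2


class TestPlateMap:
    @staticmethod
    def _map_csv(tmp_path, rows):
        head = "well,cell_line,condition,formulation_id,production_batch,replicate"
        p = tmp_path / "map.csv"
        p.write_text("\n".join([head] + rows))
        return p

    def test_minimal_matched_pair(self, tmp_path):
        rows = [f"A{i},BEWO,treated,FV-001,B1,{i}" for i in (1, 2, 3)]
        rows += [f"A{i},BEWO,control,,B1,{i - 3}" for i in (4, 5, 6)]
        pmap = read_plate_map(self._map_csv(tmp_path, rows))
        assert len(pmap.groups()) == 2
        assert pmap.control_wells("BEWO", "B1") == ["A4", "A5", "A6"]

    def test_treated_without_control_is_structural_error(self, tmp_path):
        rows = [f"A{i},BEWO,treated,FV-001,B1,{i}" for i in (1, 2, 3)]
        with pytest.raises(StructuralError, match="no matched control"):
            read_plate_map(self._map_csv(tmp_path, rows))

    def test_duplicate_well_is_structural_error(self, tmp_path):
        rows = ["A1,BEWO,treated,FV-001,B1,1", "A1,BEWO,treated,FV-001,B1,2",
                "A4,BEWO,control,,B1,1", "A5,BEWO,control,,B1,2"]
        with pytest.raises(StructuralError, match="duplicate well"):
            read_plate_map(self._map_csv(tmp_path, rows))

    def test_full_plate_has_16_groups_8_pairs(self, tmp_path):
        lines = ["L1", "L2", "L3", "L4", "L5", "L6", "L7", "L8"]
        rows = []
        for i, line in enumerate(lines):
            row = "ABCDEFGH"[i]
            for rep in (1, 2, 3):
                rows.append(f"{row}{rep},{line},treated,FV-001,B1,{rep}")
                rows.append(f"{row}{rep + 3},{line},control,,B1,{rep}")
        pmap = read_plate_map(self._map_csv(tmp_path, rows))
        groups = pmap.groups()
        assert len(groups) == 16
        treated = [g for g in groups if g[1] == "treated"]
        assert len(treated) == 8
        for line, _, _, batch in treated:
            assert len(pmap.control_wells(line, batch)) == 3


class TestWriteResults:
    def test_empty_results_produce_valid_empty_files(self, tmp_path):
        written = write_results(tmp_path)
        assert json.loads(written["calls.json"].read_text()) == {}
        assert json.loads(written["qc.json"].read_text()) == {}
        assert read_metrics(written["metrics.csv"]).empty

    def test_single_call_payload_has_evidence(self, tmp_path):
        calls = [{"cell_line": "BEWO", "category": "stimulatory",
                  "evidence": {"magnitude_pass": True}}]
        written = write_results(tmp_path, calls=calls)
        payload = json.loads(written["calls.json"].read_text())
        assert len(payload) == 1
        assert payload[0]["evidence"]["magnitude_pass"] is True

    def test_metrics_round_trip_to_1e6(self, tmp_path):
        df = pd.DataFrame({
            "cell_line": ["BEWO", "A375"],
            "delta_relative": [1.1718213058419, -0.4784580498866],
            "auc": [2145.678901, 987.654321],
        })
        written = write_results(tmp_path, metrics=df)
        back = read_metrics(written["metrics.csv"])
        for col in ("delta_relative", "auc"):
            assert np.allclose(back[col], df[col], atol=1e-6)
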