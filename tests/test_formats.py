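"""Round-trip identity and error contracts of every reader/writer pair."""

import numpy as np
import pandas as pd
import pytest

import poolfit as pf
from poolfit import formats
from poolfit.errors import ConsistencyError, FormatError


def small_scan() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "array_id": ["day02", "day02"],
            "day": [2, 2],
            "strain_id": ["S1", "S1"],
            "tag_kind": ["UP", "DN"],
            "replicate_index": [1, 1],
            "fg_exp": [500.0, 130.0],
            "bg_exp": [100.0, 100.0],
            "fg_ctl": [400.0, 120.0],
            "bg_ctl": [100.0, 100.0],
            "flag": ["ok", "discarded"],
        }
    )


class TestScanTable:
    def test_round_trip_identity(self, tmp_path):
        path = tmp_path / "scan.tsv"
        formats.write_scan_table(small_scan(), path)
        back = formats.read_scan_table(path)
        pd.testing.assert_frame_equal(back, small_scan())

    def test_discarded_rows_retained(self, tmp_path):
        path = tmp_path / "scan.tsv"
        formats.write_scan_table(small_scan(), path)
        back = formats.read_scan_table(path)
        assert len(back) == 2
        assert (back["flag"] == "discarded").sum() == 1

    def test_missing_column_named(self, tmp_path):
        path = tmp_path / "scan.tsv"
        small_scan().drop(columns=["fg_ctl"]).to_csv(path, sep="\t", index=False)
        with pytest.raises(FormatError, match="fg_ctl"):
            formats.read_scan_table(path)

    def test_negative_intensity_reports_row(self, tmp_path):
        bad = small_scan()
        bad.loc[1, "fg_exp"] = -5.0
        path = tmp_path / "scan.tsv"
        bad.to_csv(path, sep="\t", index=False)
        with pytest.raises(FormatError, match="row 2"):
            formats.read_scan_table(path)

    def test_column_order_free(self, tmp_path):
        path = tmp_path / "scan.tsv"
        shuffled = small_scan()[list(reversed(formats.SCAN_COLUMNS))]
        shuffled.to_csv(path, sep="\t", index=False)
        back = formats.read_scan_table(path)
        pd.testing.assert_frame_equal(back, small_scan())

    def test_gpr_import_maps_channels(self, tmp_path):
        gpr = pd.DataFrame(
            {
                "Name": ["S1:UP:1", "S2:DN:1"],
                "F635 Median": [800, 90],
                "B635 Median": [100, 100],
                "F532 Median": [700, 95],
                "B532 Median": [100, 100],
                "Flags": [0, -50],
            }
        )
        path = tmp_path / "a.gpr"
        gpr.to_csv(path, sep="\t", index=False)
        scan = formats.read_gpr_table(path, array_id="day02", day=2)
        assert list(scan["fg_exp"]) == [800, 90]
        assert list(scan["flag"]) == ["ok", "discarded"]
        assert list(scan["tag_kind"]) == ["UP", "DN"]


class TestKey:
    def test_three_line_key(self, tmp_path):
        path = tmp_path / "key.tsv"
        path.write_text(
            "strain_id\tgene\tin_pool\nS1\tG1\t1\nS2\tG2\ttrue\nS3\tG3\tFalse\n"
        )
        key = formats.read_key(path)
        assert len(key) == 3
        assert list(key["in_pool"]) == [True, True, False]

    def test_duplicate_strain_rejected(self, tmp_path):
        path = tmp_path / "key.tsv"
        path.write_text("strain_id\tgene\tin_pool\nS1\tG1\t1\nS1\tG2\t0\n")
        with pytest.raises(FormatError, match="S1"):
            formats.read_key(path)

    def test_write_read_identity(self, tmp_path, small_key):
        path = tmp_path / "key.tsv"
        formats.write_key(small_key, path)
        back = formats.read_key(path)
        pd.testing.assert_frame_equal(back, small_key.reset_index(drop=True))


class TestGmt:
    def test_basic_line(self, tmp_path):
        path = tmp_path / "sets.gmt"
        path.write_text("AUTOPHAGY\tcore\tATG1\tATG8\n")
        sets = formats.read_gmt(path)
        assert sets["AUTOPHAGY"]["members"] == ["ATG1", "ATG8"]

    def test_duplicates_within_line_dropped(self, tmp_path):
        path = tmp_path / "sets.gmt"
        path.write_text("X\td\tG1\tG1\n")
        assert formats.read_gmt(path)["X"]["members"] == ["G1"]

    def test_short_line_reports_lineno(self, tmp_path):
        path = tmp_path / "sets.gmt"
        path.write_text("OK\td\tG1\nX\td\n")
        with pytest.raises(FormatError, match="line 2"):
            formats.read_gmt(path)

    def test_round_trip(self, tmp_path):
        sets = {
            "A": {"description": "first", "members": ["G1", "G2", "G3"]},
            "B": {"description": "second", "members": ["G2"]},
        }
        path = tmp_path / "sets.gmt"
        formats.write_gmt(sets, path)
        assert formats.read_gmt(path) == sets


class TestCdtGtr:
    def test_single_merge_similarity(self, tmp_path):
        matrix = pd.DataFrame([[1.0, 2.0], [1.5, 2.5]], index=["g1", "g2"])
        tree = pf.Dendrogram(n_leaves=2, merges=[(0, 1, 0.2)], leaf_order=[0, 1])
        cdt, gtr = tmp_path / "x.cdt", tmp_path / "x.gtr"
        formats.write_cdt_gtr(matrix, tree, cdt, gtr)
        line = gtr.read_text().strip()
        assert line.startswith("NODE1X\tGENE0X\tGENE1X")
        assert line.endswith("0.8")

    def test_cdt_round_trip_full_precision(self, tmp_path):
        rng = np.random.default_rng(0)
        matrix = pd.DataFrame(rng.normal(size=(5, 6)), index=[f"g{i}" for i in range(5)])
        matrix.iloc[2, 3] = np.nan
        tree = pf.average_linkage(matrix)
        cdt, gtr = tmp_path / "m.cdt", tmp_path / "m.gtr"
        formats.write_cdt_gtr(matrix, tree, cdt, gtr)
        back = formats.read_cdt(cdt)
        assert len(back) == len(matrix)
        reordered = matrix.iloc[tree.leaf_order]
        reordered.columns = back.columns
        pd.testing.assert_frame_equal(back, reordered)

    def test_leaf_mismatch_rejected(self, tmp_path):
        matrix = pd.DataFrame([[1.0], [2.0], [3.0]])
        tree = pf.Dendrogram(n_leaves=2, merges=[(0, 1, 0.1)], leaf_order=[0, 1])
        with pytest.raises(ConsistencyError):
            formats.write_cdt_gtr(matrix, tree, tmp_path / "x.cdt", tmp_path / "x.gtr")


class TestResultsTable:
    def test_empty_results_header_only(self, tmp_path):
        path = tmp_path / "r.tsv"
        formats.write_results_table(pd.DataFrame(columns=["a", "b"]), path)
        assert path.read_text() == "a\tb\n"

    def test_row_count(self, tmp_path):
        df = pd.DataFrame({"a": range(300)})
        path = tmp_path / "r.tsv"
        formats.write_results_table(df, path)
        assert len(path.read_text().splitlines()) == 301

    def test_enrichment_sorted_by_adjusted_p(self, tmp_path):
        df = pd.DataFrame({"category_id": ["x", "y"], "p_raw": [0.3, 0.001], "p_adj": [1.0, 0.459]})
        path = tmp_path / "r.tsv"
        formats.write_results_table(df, path)
        lines = path.read_text().splitlines()
        assert lines[1].startswith("y")
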