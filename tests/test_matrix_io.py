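"""Round-trips, aggregation arithmetic, and input validation."""

import numpy as np
import pandas as pd
import pytest

from falafl import (
    CellDepthTable,
    CoverageFractionMatrix,
    PatientMeta,
    SiteId,
    aggregate_cell_depths,
    read_fraction_matrix,
    write_fraction_matrix,
)
from falafl.matrix_io import MatrixParseError, read_cell_depth_table


class TestRoundTrip:
    @pytest.mark.parametrize("fmt", ["dense_tsv", "triplet"])
    def test_write_read_identity(self, small_fraction_matrix, tmp_path, fmt):
        path = tmp_path / f"m.{fmt}.tsv"
        write_fraction_matrix(small_fraction_matrix, path, format=fmt)
        back = read_fraction_matrix(path, format=fmt)
        np.testing.assert_array_equal(back.values, small_fraction_matrix.values)
        assert back.sites == small_fraction_matrix.sites
        assert back.patient_ids == small_fraction_matrix.patient_ids

    def test_dense_small_example(self, tmp_path):
        path = tmp_path / "m.tsv"
        path.write_text(
            "patient_id\tchr1:1\tchr1:2\tchr1:3\np1\t0\t0.5\t1\np2\t1\t0\t0.5\n"
        )
        m = read_fraction_matrix(path)
        assert (m.n_patients, m.n_sites) == (2, 3)
        np.testing.assert_array_equal(m.values, [[0, 0.5, 1], [1, 0, 0.5]])

    def test_triplet_missing_entries_default_zero(self, tmp_path):
        path = tmp_path / "t.tsv"
        path.write_text(
            "#dims 2 2\n#patients\tp1\tp2\n#sites\tchr1:100\tchr1:200\n"
            "p1\tchr1:100\t0.8\n"
        )
        m = read_fraction_matrix(path, format="triplet")
        np.testing.assert_array_equal(m.values, [[0.8, 0.0], [0.0, 0.0]])

    def test_triplet_omits_zeros(self, small_fraction_matrix, tmp_path):
        path = tmp_path / "t.tsv"
        write_fraction_matrix(small_fraction_matrix, path, format="triplet")
        data_rows = [
            l for l in path.read_text().splitlines() if not l.startswith("#")
        ]
        assert len(data_rows) == np.count_nonzero(small_fraction_matrix.values)

    def test_empty_site_list_rejected(self, tmp_path):
        m = CoverageFractionMatrix([PatientMeta("p1")], [], np.zeros((1, 0)))
        with pytest.raises(ValueError, match="no sites"):
            write_fraction_matrix(m, tmp_path / "x.tsv")


class TestValidation:
    def test_out_of_range_value_names_cell(self, tmp_path):
        path = tmp_path / "m.tsv"
        path.write_text("patient_id\tchr1:1\np1\t1.2\n")
        with pytest.raises(MatrixParseError, match="1.2"):
            read_fraction_matrix(path)

    def test_duplicate_site_ids_rejected(self):
        with pytest.raises(MatrixParseError, match="duplicate site"):
            CoverageFractionMatrix(
                [PatientMeta("p1")],
                [SiteId("chr1", 1), SiteId("chr1", 1)],
                np.zeros((1, 2)),
            )

    def test_bad_site_token(self):
        with pytest.raises(MatrixParseError):
            SiteId.parse("chr1-100")

    def test_position_must_be_positive(self):
        with pytest.raises(ValueError):
            SiteId("chr1", 0)


def _table(patient, depths_by_cell_site):
    rows = [
        {"cell_id": c, "chrom": "chr1", "pos": pos, "depth": d}
        for (c, pos), d in depths_by_cell_site.items()
    ]
    return CellDepthTable(patient, pd.DataFrame(rows))


class TestAggregation:
    @pytest.mark.parametrize(
        "threshold,expected",
        [(1, 3 / 4), (2, 2 / 4)],  # depths (0,1,2,3) over 4 cells
    )
    def test_threshold_counting(self, threshold, expected):
        tab = _table(
            "p1", {(f"c{i}", 100): d for i, d in enumerate((0, 1, 2, 3))}
        )
        m = aggregate_cell_depths([tab], depth_threshold=threshold)
        assert m.values[0, 0] == pytest.approx(expected)

    def test_absent_site_is_zero(self):
        t1 = _table("p1", {("c1", 100): 2, ("c2", 100): 2})
        t2 = _table("p2", {("c1", 200): 1})
        m = aggregate_cell_depths([t1, t2], depth_threshold=1)
        j100 = m.sites.index(SiteId("chr1", 100))
        j200 = m.sites.index(SiteId("chr1", 200))
        assert m.values[1, j100] == 0.0
        assert m.values[0, j200] == 0.0

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(0)
        rows = [
            {"cell_id": f"c{c}", "chrom": "chr1", "pos": p, "depth": int(d)}
            for c in range(5)
            for p, d in zip((100, 200, 300), rng.integers(0, 5, 3))
        ]
        tab = CellDepthTable("p1", pd.DataFrame(rows))
        prev = None
        for thr in (1, 2, 3, 4):
            m = aggregate_cell_depths([tab], depth_threshold=thr)
            if prev is not None:
                assert (m.values <= prev + 1e-12).all()
            prev = m.values

    def test_row_sum_equals_pair_count(self):
        tab = _table("p1", {("c1", 100): 2, ("c1", 200): 1, ("c2", 100): 3})
        meta = {"p1": PatientMeta("p1", n_cells=2)}
        m = aggregate_cell_depths([tab], depth_threshold=1, patient_meta=meta)
        assert m.values[0].sum() == pytest.approx(3 / 2)

    def test_meth_unmeth_counts_sum_to_depth(self):
        rows = pd.DataFrame(
            {
                "cell_id": ["c1"],
                "chrom": ["chr1"],
                "pos": [100],
                "meth_count": [1],
                "unmeth_count": [1],
            }
        )
        tab = CellDepthTable("p1", rows)
        m = aggregate_cell_depths([tab], depth_threshold=2)
        assert m.values[0, 0] == 1.0

    def test_bismark_reader(self, tmp_path):
        path = tmp_path / "cell.cov"
        path.write_text("chr1\t100\t100\t50.0\t1\t1\nchr2\t5\t5\t0.0\t0\t3\n")
        frag = read_cell_depth_table(path, "p1", "c1")
        assert list(frag["depth"]) == [2, 3]
        assert list(frag["pos"]) == [100, 5]
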