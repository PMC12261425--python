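"""Containers and I/O for patient-by-site coverage-fraction matrices.

The central object is the :class:`CoverageFractionMatrix`: an ``n × m``
matrix whose entry ``s_ij`` is the fraction of cells in patient ``i`` in
which CpG site ``j`` has at least ``depth_threshold`` reads.  Matrices can
be read from / written to a dense TSV or a sparse triplet TSV, or
aggregated from per-cell read-depth tables (Bismark-coverage style).

Coordinates are 1-based cytosine positions; a CpG is treated as a single
strand-collapsed site, matching the Bismark coverage convention.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SiteId",
    "PatientMeta",
    "CoverageFractionMatrix",
    "CellDepthTable",
    "read_fraction_matrix",
    "write_fraction_matrix",
    "aggregate_cell_depths",
    "read_cell_depth_table",
    "read_patient_metadata",
]


class MatrixParseError(ValueError):
    """Raised when a coverage matrix file is malformed."""


@dataclass(frozen=True, order=True)
class SiteId:
    """A CpG site: chromosome name plus 1-based cytosine coordinate."""

    chrom: str
    pos: int

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"site position must be >= 1, got {self.pos}")

    def __str__(self) -> str:
        return f"{self.chrom}:{self.pos}"

    @classmethod
    def parse(cls, token: str) -> "SiteId":
        chrom, _, pos = token.rpartition(":")
        if not chrom:
            raise MatrixParseError(f"site id {token!r} is not 'chrom:pos'")
        try:
            return cls(chrom, int(pos))
        except ValueError as exc:
            raise MatrixParseError(f"bad site id {token!r}: {exc}") from exc


@dataclass(frozen=True)
class PatientMeta:
    """Patient identifier with an optional primary-site group and cell count."""

    patient_id: str
    group: str | None = None
    n_cells: int | None = None

    def __post_init__(self) -> None:
        if self.n_cells is not None and self.n_cells < 1:
            raise ValueError(f"n_cells must be >= 1, got {self.n_cells}")


def _check_unique(items: Sequence, what: str) -> None:
    seen = set()
    for it in items:
        if it in seen:
            raise MatrixParseError(f"duplicate {what}: {it}")
        seen.add(it)


@dataclass
class CoverageFractionMatrix:
    """Patients × sites matrix of per-patient covered-cell fractions.

    Parameters
    ----------
    patients:
        Ordered patient metadata, one per row.
    sites:
        Ordered site identifiers, one per column.
    values:
        ``(n, m)`` float array with entries in ``[0, 1]``.
    depth_threshold:
        Minimum per-cell read count counted as "sufficient" when the
        matrix was aggregated from cell-level depths.  Default 1 read.
    """

    patients: list[PatientMeta]
    sites: list[SiteId]
    values: np.ndarray
    depth_threshold: int = 1

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n, m = len(self.patients), len(self.sites)
        if self.values.shape != (n, m):
            raise ValueError(
                f"values shape {self.values.shape} inconsistent with "
                f"{n} patients x {m} sites"
            )
        _check_unique([p.patient_id for p in self.patients], "patient id")
        _check_unique(self.sites, "site id")
        if self.values.size and (
            self.values.min() < 0.0 or self.values.max() > 1.0
        ):
            i, j = np.unravel_index(
                np.argmax((self.values < 0) | (self.values > 1)), self.values.shape
            )
            raise ValueError(
                f"entry ({self.patients[i].patient_id}, {self.sites[j]}) = "
                f"{self.values[i, j]} outside [0, 1]"
            )
        if self.depth_threshold < 1:
            raise ValueError("depth_threshold must be >= 1")

    @property
    def n_patients(self) -> int:
        return len(self.patients)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def patient_ids(self) -> list[str]:
        return [p.patient_id for p in self.patients]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values,
            index=self.patient_ids,
            columns=[str(s) for s in self.sites],
        )


@dataclass
class CellDepthTable:
    """Per-cell read depths for one patient.

    ``rows`` has columns ``cell_id``, ``chrom``, ``pos`` and either a
    ``depth`` column or ``meth_count``/``unmeth_count`` columns (in which
    case depth is their sum).  One row per (cell, site).
    """

    patient_id: str
    rows: pd.DataFrame

    def __post_init__(self) -> None:
        cols = set(self.rows.columns)
        if not {"cell_id", "chrom", "pos"} <= cols:
            raise ValueError("rows need cell_id, chrom, pos columns")
        if "depth" not in cols:
            if not {"meth_count", "unmeth_count"} <= cols:
                raise ValueError("rows need a depth or meth/unmeth count columns")
            self.rows = self.rows.assign(
                depth=self.rows["meth_count"] + self.rows["unmeth_count"]
            )
        if (self.rows["depth"] < 0).any():
            raise ValueError("negative read depth")

    @property
    def cell_ids(self) -> list[str]:
        return sorted(self.rows["cell_id"].unique())


# ---------------------------------------------------------------------------
# dense / triplet readers and writers
# ---------------------------------------------------------------------------

def read_fraction_matrix(path, format: str = "dense_tsv") -> CoverageFractionMatrix:
    """Read a coverage-fraction matrix from ``path``.

    ``dense_tsv``: first header field is ignored (row-label column), the
    remaining header fields are ``chrom:pos`` site ids; each following row
    is a patient id followed by its fractions.

    ``triplet``: header lines ``#dims n m``, ``#patients id...``,
    ``#sites chrom:pos ...`` followed by ``patient_id<TAB>site<TAB>value``
    rows; entries not listed are zero.
    """
    if format == "dense_tsv":
        return _read_dense(path)
    if format == "triplet":
        return _read_triplet(path)
    raise ValueError(f"unknown format {format!r}")


def _read_dense(path) -> CoverageFractionMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.columns.empty:
        raise MatrixParseError(f"{path}: no site columns in header")
    sites = [SiteId.parse(c) for c in df.columns]
    patients = [PatientMeta(str(pid)) for pid in df.index]
    values = df.to_numpy(dtype=float)
    bad = np.argwhere((values < 0) | (values > 1) | ~np.isfinite(values))
    if bad.size:
        i, j = bad[0]
        raise MatrixParseError(
            f"{path}: value {values[i, j]} at row {df.index[i]!r}, "
            f"column {df.columns[j]!r} outside [0, 1]"
        )
    return CoverageFractionMatrix(patients, sites, values)


def _read_triplet(path) -> CoverageFractionMatrix:
    dims = pats = sites_tok = None
    triplets: list[tuple[str, str, float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#dims"):
                dims = tuple(int(x) for x in line.split()[1:3])
            elif line.startswith("#patients"):
                pats = line.split("\t")[1:] or line.split()[1:]
            elif line.startswith("#sites"):
                sites_tok = line.split("\t")[1:] or line.split()[1:]
            elif line.startswith("#"):
                continue
            else:
                parts = line.split("\t")
                if len(parts) != 3:
                    raise MatrixParseError(
                        f"{path}:{lineno}: expected 3 tab-separated fields"
                    )
                triplets.append((parts[0], parts[1], float(parts[2])))
    if dims is None or pats is None or sites_tok is None:
        raise MatrixParseError(
            f"{path}: triplet file needs #dims, #patients and #sites headers"
        )
    n, m = dims
    if len(pats) != n or len(sites_tok) != m:
        raise MatrixParseError(f"{path}: #dims {dims} inconsistent with id lists")
    sites = [SiteId.parse(t) for t in sites_tok]
    _check_unique(sites, "site id")
    row_of = {p: i for i, p in enumerate(pats)}
    col_of = {str(s): j for j, s in enumerate(sites)}
    values = np.zeros((n, m))
    for pid, stok, val in triplets:
        if pid not in row_of:
            raise MatrixParseError(f"{path}: unknown patient {pid!r}")
        if stok not in col_of:
            raise MatrixParseError(f"{path}: unknown site {stok!r}")
        if not 0.0 <= val <= 1.0:
            raise MatrixParseError(
                f"{path}: value {val} at ({pid}, {stok}) outside [0, 1]"
            )
        values[row_of[pid], col_of[stok]] = val
    return CoverageFractionMatrix([PatientMeta(p) for p in pats], sites, values)


def write_fraction_matrix(
    matrix: CoverageFractionMatrix, path, format: str = "dense_tsv"
) -> None:
    """Write ``matrix`` so that :func:`read_fraction_matrix` round-trips it."""
    if matrix.n_sites == 0:
        raise ValueError("refusing to write a matrix with no sites")
    if format == "dense_tsv":
        df = matrix.to_frame()
        df.index.name = "patient_id"
        df.to_csv(path, sep="\t", float_format="%.17g")
    elif format == "triplet":
        with open(path, "w") as fh:
            fh.write(f"#dims {matrix.n_patients} {matrix.n_sites}\n")
            fh.write("#patients\t" + "\t".join(matrix.patient_ids) + "\n")
            fh.write("#sites\t" + "\t".join(str(s) for s in matrix.sites) + "\n")
            rows, cols = np.nonzero(matrix.values)
            for i, j in zip(rows, cols):
                fh.write(
                    f"{matrix.patients[i].patient_id}\t{matrix.sites[j]}\t"
                    f"{matrix.values[i, j]:.17g}\n"
                )
    else:
        raise ValueError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# aggregation from cell-level depths
# ---------------------------------------------------------------------------

def aggregate_cell_depths(
    tables: Sequence[CellDepthTable],
    depth_threshold: int = 1,
    patient_meta: dict[str, PatientMeta] | None = None,
) -> CoverageFractionMatrix:
    """Aggregate per-cell depths into a coverage-fraction matrix.

    ``s_ij`` is the fraction of patient ``i``'s cells with depth at least
    ``depth_threshold`` at site ``j``.  Sites absent from a patient's table
    get fraction 0.  Cell counts come from ``patient_meta`` when provided,
    otherwise from the distinct ``cell_id`` values in each table.
    """
    if depth_threshold < 1:
        raise ValueError("depth_threshold must be >= 1")
    if not tables:
        raise ValueError("no cell depth tables given")
    all_sites: set[SiteId] = set()
    for t in tables:
        for chrom, pos in zip(t.rows["chrom"], t.rows["pos"]):
            all_sites.add(SiteId(str(chrom), int(pos)))
    sites = sorted(all_sites)
    col_of = {s: j for j, s in enumerate(sites)}

    patients: list[PatientMeta] = []
    values = np.zeros((len(tables), len(sites)))
    for i, t in enumerate(tables):
        meta = (patient_meta or {}).get(t.patient_id, PatientMeta(t.patient_id))
        n_cells = meta.n_cells if meta.n_cells is not None else len(t.cell_ids)
        if n_cells < 1:
            raise ValueError(f"patient {t.patient_id} has no cells")
        patients.append(
            PatientMeta(t.patient_id, group=meta.group, n_cells=n_cells)
        )
        ok = t.rows[t.rows["depth"] >= depth_threshold]
        if len(ok):
            grouped = ok.groupby(["chrom", "pos"])["cell_id"].nunique()
            for (chrom, pos), count in grouped.items():
                values[i, col_of[SiteId(str(chrom), int(pos))]] = count / n_cells
    return CoverageFractionMatrix(
        patients, sites, values, depth_threshold=depth_threshold
    )


def read_cell_depth_table(path, patient_id: str, cell_id: str) -> pd.DataFrame:
    """Read one cell's Bismark-style coverage TSV into CellDepthTable rows.

    Expected columns: chrom, start (1-based), end, methylation %, methylated
    count, unmethylated count.  Returns a DataFrame fragment; concatenate
    fragments per patient and wrap in :class:`CellDepthTable`.
    """
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "pos", "end", "meth_pct", "meth_count", "unmeth_count"],
    )
    return pd.DataFrame(
        {
            "cell_id": cell_id,
            "chrom": df["chrom"].astype(str),
            "pos": df["pos"].astype(int),
            "meth_count": df["meth_count"].astype(int),
            "unmeth_count": df["unmeth_count"].astype(int),
            "depth": (df["meth_count"] + df["unmeth_count"]).astype(int),
        }
    )


def read_patient_metadata(path) -> dict[str, PatientMeta]:
    """Read a patient metadata TSV (patient_id, group, n_cells)."""
    df = pd.read_csv(path, sep="\t")
    out: dict[str, PatientMeta] = {}
    for _, row in df.iterrows():
        pid = str(row["patient_id"])
        if pid in out:
            raise MatrixParseError(f"duplicate patient id {pid}")
        out[pid] = PatientMeta(
            pid,
            group=str(row["group"]) if "group" in df.columns else None,
            n_cells=int(row["n_cells"]) if "n_cells" in df.columns else None,
        )
    return out
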