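"""Preprocessing pipeline: fraction filter, binarization, patient-count filter.

Three steps, applied in a fixed order, turn a coverage-fraction matrix into
the binary input of the selection problem:

1. delta filter — drop (or zero) entries/sites with covered-cell fraction
   below ``delta``;
2. binarize — ``s̄_ij = 1`` iff ``s_ij >= p``;
3. k filter — keep only sites with ``sum_i s̄_ij >= k``, optionally also
   requiring per-group minima (e.g. at least two left-colon patients, one
   right-colon patient and one rectum patient).

All thresholds are inclusive.  Defaults mirror the colorectal-cancer study
conditions: ``delta=0.1``, ``p=0.5``, ``k = floor(n/2)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .matrix_io import CoverageFractionMatrix, PatientMeta, SiteId

__all__ = [
    "PreprocessConfig",
    "BinaryCoverageMatrix",
    "delta_filter",
    "binarize",
    "k_filter",
    "preprocess",
    "CoveragePreprocessor",
]


@dataclass
class PreprocessConfig:
    """Thresholds for the three preprocessing steps.

    ``delta_mode='all_patients'`` drops a site when *any* patient falls
    below delta (the cohort-level reading); ``'per_patient'`` zeroes only
    the failing entries and keeps the site for the remaining patients.
    ``k=None`` means ``floor(n/2)``, resolved against the input matrix.
    """

    delta: float = 0.1
    p: float = 0.5
    k: int | None = None
    group_minima: dict[str, int] | None = None
    delta_mode: str = "all_patients"

    def __post_init__(self) -> None:
        for name, v in (("delta", self.delta), ("p", self.p)):
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.delta > self.p:
            warnings.warn(
                f"delta={self.delta} > p={self.p}: the delta filter then "
                "dominates the binarization threshold",
                stacklevel=2,
            )
        if self.k is not None and self.k < 0:
            raise ValueError("k must be >= 0")
        if self.delta_mode not in ("all_patients", "per_patient"):
            raise ValueError(f"unknown delta_mode {self.delta_mode!r}")

    def resolve_k(self, n_patients: int) -> int:
        return n_patients // 2 if self.k is None else self.k


@dataclass
class BinaryCoverageMatrix:
    """Binarized, filtered patient-by-site matrix.

    ``original_columns[j]`` maps retained column ``j`` back to its column
    index in the matrix the pipeline started from.
    """

    patients: list[PatientMeta]
    retained_sites: list[SiteId]
    values: np.ndarray
    original_columns: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("binary matrix entries must be 0 or 1")
        self.values = self.values.astype(np.uint8)
        n, m = len(self.patients), len(self.retained_sites)
        if self.values.shape != (n, m):
            raise ValueError(
                f"values shape {self.values.shape} inconsistent with "
                f"{n} patients x {m} sites"
            )
        if self.original_columns is None:
            self.original_columns = np.arange(m)
        else:
            self.original_columns = np.asarray(self.original_columns, dtype=int)
            if self.original_columns.shape != (m,):
                raise ValueError("original_columns length mismatch")

    @property
    def n_patients(self) -> int:
        return len(self.patients)

    @property
    def n_sites(self) -> int:
        return len(self.retained_sites)

    @property
    def column_patient_counts(self) -> np.ndarray:
        """Per-column number of patients with a 1 (the objective weights)."""
        return self.values.sum(axis=0).astype(int)

    def groups(self) -> list[str | None]:
        return [p.group for p in self.patients]


def delta_filter(
    matrix: CoverageFractionMatrix,
    delta: float,
    delta_mode: str = "all_patients",
) -> CoverageFractionMatrix:
    """Apply the minimum covered-cell-fraction filter.

    ``all_patients``: a site survives only if ``s_ij >= delta`` in every
    patient.  ``per_patient``: entries below delta are zeroed and sites
    with at least one surviving entry are kept.
    """
    if not 0.0 <= delta <= 1.0:
        raise ValueError("delta must be in [0, 1]")
    vals = matrix.values
    if delta_mode == "all_patients":
        keep = (vals >= delta).all(axis=0)
        new_vals = vals[:, keep]
    elif delta_mode == "per_patient":
        masked = np.where(vals >= delta, vals, 0.0)
        keep = (masked > 0).any(axis=0) | (vals >= delta).any(axis=0)
        new_vals = masked[:, keep]
    else:
        raise ValueError(f"unknown delta_mode {delta_mode!r}")
    if not keep.any():
        warnings.warn("delta filter removed every site", stacklevel=2)
    sites = [s for s, k in zip(matrix.sites, keep) if k]
    return CoverageFractionMatrix(
        matrix.patients, sites, new_vals, depth_threshold=matrix.depth_threshold
    )


def binarize(matrix: CoverageFractionMatrix, p: float) -> BinaryCoverageMatrix:
    """Binarize: ``s̄_ij = 1`` iff ``s_ij >= p`` (boundary inclusive)."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must be in [0, 1]")
    return BinaryCoverageMatrix(
        matrix.patients,
        list(matrix.sites),
        (matrix.values >= p).astype(np.uint8),
    )


def k_filter(
    binary: BinaryCoverageMatrix,
    k: int,
    group_minima: dict[str, int] | None = None,
) -> BinaryCoverageMatrix:
    """Keep columns covered in at least ``k`` patients and meeting group minima.

    Both predicates are per-column, so they are applied jointly in one
    pass; retained column order is preserved.
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    keep = binary.values.sum(axis=0) >= k
    if group_minima:
        groups = binary.groups()
        for g, minimum in group_minima.items():
            rows = [i for i, gi in enumerate(groups) if gi == g]
            if not rows:
                raise ValueError(f"group {g!r} not present among patients")
            keep &= binary.values[rows].sum(axis=0) >= minimum
    sites = [s for s, kk in zip(binary.retained_sites, keep) if kk]
    return BinaryCoverageMatrix(
        binary.patients,
        sites,
        binary.values[:, keep],
        original_columns=binary.original_columns[keep],
    )


def preprocess(
    matrix: CoverageFractionMatrix,
    config: PreprocessConfig | None = None,
    report: list | None = None,
) -> BinaryCoverageMatrix:
    """Run the fixed delta → binarize → k pipeline.

    When ``report`` is a list, (stage, sites_in, sites_out) tuples are
    appended so the preprocessing funnel can be audited.
    """
    config = config or PreprocessConfig()
    m0 = matrix.n_sites
    filtered = delta_filter(matrix, config.delta, config.delta_mode)
    if report is not None:
        report.append(("delta_filter", m0, filtered.n_sites))
    binary = binarize(filtered, config.p)
    if report is not None:
        report.append(("binarize", filtered.n_sites, binary.n_sites))
    k = config.resolve_k(matrix.n_patients)
    out = k_filter(binary, k, config.group_minima)
    if report is not None:
        report.append(("k_filter", binary.n_sites, out.n_sites))
    # re-anchor the column map to the pipeline's input, not the delta stage
    orig_of = {s: j for j, s in enumerate(matrix.sites)}
    out.original_columns = np.array(
        [orig_of[s] for s in out.retained_sites], dtype=int
    )
    return out


class CoveragePreprocessor(TransformerMixin, BaseEstimator):
    """Column filter over raw fraction arrays, scikit-learn style.

    ``X`` is an ``(n_patients, n_sites)`` array of coverage fractions;
    ``fit`` learns the retained-column mask and ``transform`` returns the
    binarized retained columns.  The estimator exists so the pipeline
    composes with scikit-learn model selection; :func:`preprocess` is the
    container-aware interface.
    """

    def __init__(
        self,
        delta: float = 0.1,
        p: float = 0.5,
        k: int | None = None,
        delta_mode: str = "all_patients",
    ):
        self.delta = delta
        self.p = p
        self.k = k
        self.delta_mode = delta_mode

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (patients x sites)")
        cfg = PreprocessConfig(
            delta=self.delta, p=self.p, k=self.k, delta_mode=self.delta_mode
        )
        if cfg.delta_mode == "all_patients":
            keep = (X >= cfg.delta).all(axis=0)
            vals = np.where(keep, X, 0.0)
        else:
            vals = np.where(X >= cfg.delta, X, 0.0)
            keep = (vals > 0).any(axis=0) | (X >= cfg.delta).any(axis=0)
        binary = (vals >= cfg.p).astype(np.uint8)
        keep &= binary.sum(axis=0) >= cfg.resolve_k(X.shape[0])
        self.n_features_in_ = X.shape[1]
        self.support_ = keep
        self.binary_ = binary[:, keep]
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError("X has a different number of sites than fit saw")
        vals = X[:, self.support_]
        if self.delta_mode == "per_patient":
            vals = np.where(vals >= self.delta, vals, 0.0)
        return (vals >= self.p).astype(np.uint8)

    def get_support(self, indices: bool = False):
        return np.flatnonzero(self.support_) if indices else self.support_
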