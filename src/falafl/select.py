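"""Fair site selection by integer linear programming.

Given a binary patient-by-site matrix ``S̄`` and a fairness fraction
``q``, choose a 0/1 vector ``r`` over sites

    maximize    sum_j r_j * (sum_i s̄_ij)
    subject to  sum_j r_j s̄_ij  >=  q * sum_j r_j      for every patient i

i.e. pick the heaviest site set such that every patient has coverage in at
least a fraction ``q`` of the chosen sites.  The decision version of this
problem is NP-hard (by reduction from Exact Cover by 3-Sets), but in
practice instances have few patients and therefore at most ``2^n`` distinct
column patterns: identical columns are merged into one integer variable
with multiplicity before handing the model to the HiGHS solver, which makes
million-site instances solve in seconds.

:func:`brute_force_select` is an exhaustive oracle for small instances and
is used to verify the solver path; it never backs the production path.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import Bounds, LinearConstraint, milp
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin

from .matrix_io import PatientMeta, SiteId
from .preprocess import BinaryCoverageMatrix

__all__ = [
    "SelectionResult",
    "select",
    "brute_force_select",
    "FalaflSelector",
    "x3c_to_falafl",
    "decision_falafl",
]

_ENUM_BOUND = 20  # max columns for exhaustive enumeration


@dataclass
class SelectionResult:
    """Outcome of one selection run.

    ``selected`` holds retained-site column indices (into the matrix the
    selection ran on); ``objective`` is the total patient count over the
    selected columns; ``per_patient_fraction[i]`` is the share of selected
    sites covered in patient ``i`` (NaN for an empty selection).
    """

    selected: np.ndarray
    objective: int
    per_patient_fraction: np.ndarray
    q: float
    solver_status: str = "optimal"

    @property
    def n_selected(self) -> int:
        return len(self.selected)

    def selected_sites(self, binary: BinaryCoverageMatrix) -> list[SiteId]:
        return [binary.retained_sites[j] for j in self.selected]


def _as_binary_array(binary) -> np.ndarray:
    if isinstance(binary, BinaryCoverageMatrix):
        return binary.values
    arr = np.asarray(binary)
    if arr.ndim != 2 or not np.isin(arr, (0, 1)).all():
        raise ValueError("input must be a 2-D 0/1 matrix")
    return arr.astype(np.uint8)


def _result_from_mask(S: np.ndarray, chosen: np.ndarray, q: float, status: str):
    chosen = np.sort(np.asarray(chosen, dtype=int))
    if chosen.size == 0:
        warnings.warn(
            "no nonempty site set satisfies the fairness constraint; "
            "returning the empty selection",
            stacklevel=3,
        )
        frac = np.full(S.shape[0], np.nan)
        return SelectionResult(chosen, 0, frac, q, status)
    sub = S[:, chosen]
    frac = sub.sum(axis=1) / chosen.size
    return SelectionResult(chosen, int(sub.sum()), frac, q, status)


def select(
    binary,
    q: float,
    time_limit: float | None = None,
    seed: int = 0,
    compress: bool = True,
) -> SelectionResult:
    """Solve the fair-selection problem to optimality with HiGHS.

    Parameters
    ----------
    binary:
        A :class:`~falafl.preprocess.BinaryCoverageMatrix` or a 0/1 array
        of shape (patients, sites).
    q:
        Minimum fraction of the selected sites each patient must cover.
    time_limit:
        Optional solver wall-clock limit in seconds; when hit, the best
        incumbent is returned with status ``feasible_nonoptimal``.
    seed:
        Recorded for provenance; HiGHS is deterministic on a single
        thread, so repeated runs return the same optimum among ties.
    compress:
        Merge identical columns into one integer variable (multiplicity
        as the upper bound).  Preserves the optimum; on re-expansion the
        lowest column indices of a pattern are taken first.
    """
    S = _as_binary_array(binary)
    n, m = S.shape
    if m < 1:
        raise ValueError("matrix has no sites")
    if not 0.0 <= q <= 1.0:
        raise ValueError(f"q must be in [0, 1], got {q}")

    if compress:
        patterns, inverse, counts = np.unique(
            S, axis=1, return_inverse=True, return_counts=True
        )
        upper = counts.astype(float)
    else:
        patterns, inverse = S, np.arange(m)
        upper = np.ones(m)
    t = patterns.shape[1]

    weights = patterns.sum(axis=0).astype(float)
    # per-patient fairness: sum_t (pattern_it - q) * c_t >= 0
    A = patterns.astype(float) - q
    constraints = LinearConstraint(A, lb=np.zeros(n), ub=np.full(n, np.inf))
    options = {"presolve": True}
    if time_limit is not None:
        options["time_limit"] = float(time_limit)
    res = milp(
        c=-weights,
        constraints=constraints,
        integrality=np.ones(t),
        bounds=Bounds(np.zeros(t), upper),
        options=options,
    )
    if res.status == 0:
        status = "optimal"
    elif res.status == 1:
        # time/iteration limit: keep the incumbent, or fall back to the
        # always-feasible empty selection if none was found
        status = "feasible_nonoptimal"
        if res.x is None:
            return _result_from_mask(S, np.array([], dtype=int), q, status)
    else:
        raise RuntimeError(f"MILP solver failed: {res.message}")

    c = np.round(res.x).astype(int)
    chosen: list[int] = []
    if compress:
        order = np.argsort(inverse.ravel(), kind="stable")
        cols_by_pattern = np.split(
            order, np.cumsum(np.bincount(inverse.ravel(), minlength=t))[:-1]
        )
        for tt in range(t):
            if c[tt] > 0:
                chosen.extend(cols_by_pattern[tt][: c[tt]])
    else:
        chosen = list(np.flatnonzero(c))
    return _result_from_mask(S, np.array(chosen, dtype=int), q, status)


def brute_force_select(binary, q: float) -> SelectionResult:
    """Exact optimum by enumerating every subset of columns.

    Verification oracle only: the column count must be at most 20.  Ties
    are broken toward the lexicographically first subset in bitmask order.
    """
    S = _as_binary_array(binary)
    n, m = S.shape
    if m > _ENUM_BOUND:
        raise ValueError(f"enumeration bound is {_ENUM_BOUND} columns, got {m}")
    if not 0.0 <= q <= 1.0:
        raise ValueError(f"q must be in [0, 1], got {q}")
    row_bits = [int(sum(1 << j for j in range(m) if S[i, j])) for i in range(n)]
    col_weight = S.sum(axis=0)
    best_mask, best_obj = 0, 0
    for mask in range(1, 1 << m):
        size = mask.bit_count()
        if any((rb & mask).bit_count() < q * size for rb in row_bits):
            continue
        obj = sum(int(col_weight[j]) for j in range(m) if mask >> j & 1)
        if obj > best_obj:
            best_mask, best_obj = mask, obj
    chosen = np.array([j for j in range(m) if best_mask >> j & 1], dtype=int)
    return _result_from_mask(S, chosen, q, "optimal")


class FalaflSelector(SelectorMixin, BaseEstimator):
    """Fair feature selection as a scikit-learn selector.

    ``fit(X)`` treats ``X`` as the binary patient-by-site matrix (rows =
    patients / samples, columns = features) and solves the fairness ILP;
    ``transform`` then keeps the selected columns.  Fitted attributes:
    ``support_mask_``, ``objective_``, ``per_patient_fraction_``,
    ``solver_status_``.
    """

    def __init__(
        self,
        q: float = 0.75,
        time_limit: float | None = None,
        seed: int = 0,
        compress: bool = True,
    ):
        self.q = q
        self.time_limit = time_limit
        self.seed = seed
        self.compress = compress

    def fit(self, X, y=None):
        X = _as_binary_array(X)
        result = select(
            X,
            q=self.q,
            time_limit=self.time_limit,
            seed=self.seed,
            compress=self.compress,
        )
        self.n_features_in_ = X.shape[1]
        mask = np.zeros(X.shape[1], dtype=bool)
        mask[result.selected] = True
        self.support_mask_ = mask
        self.objective_ = result.objective
        self.per_patient_fraction_ = result.per_patient_fraction
        self.solver_status_ = result.solver_status
        self.result_ = result
        return self

    def _get_support_mask(self):
        return self.support_mask_

    def __sklearn_tags__(self):
        tags = super().__sklearn_tags__()
        tags.target_tags.required = False
        tags.input_tags.allow_nan = False
        return tags


# ---------------------------------------------------------------------------
# NP-hardness reduction from Exact Cover by 3-Sets (used in verification)
# ---------------------------------------------------------------------------

def x3c_to_falafl(
    universe_size: int, subsets: list[frozenset | set]
) -> tuple[BinaryCoverageMatrix, int, int]:
    """Reduce an Exact-Cover-by-3-Sets instance to the decision problem.

    Builds the binary matrix ``Q`` with one row per universe element and
    one column per 3-subset (``Q[i, j] = 1`` iff element ``i+1`` is in
    subset ``j``), and returns ``(Q, k, ell)`` with ``k = universe_size/3``
    and ``ell = 1``: the universe has an exact cover iff some ``k`` columns
    of ``Q`` give every row at least one 1.
    """
    if universe_size % 3 != 0 or universe_size < 3:
        raise ValueError("universe size must be a positive multiple of 3")
    universe = set(range(1, universe_size + 1))
    Q = np.zeros((universe_size, len(subsets)), dtype=np.uint8)
    for j, sub in enumerate(subsets):
        sub = set(sub)
        if len(sub) != 3 or not sub <= universe:
            raise ValueError(
                f"subset {j} must have exactly 3 elements from 1..{universe_size}"
            )
        for x in sub:
            Q[x - 1, j] = 1
    patients = [PatientMeta(f"x{i}") for i in range(1, universe_size + 1)]
    sites = [SiteId("set", j + 1) for j in range(len(subsets))]
    binary = BinaryCoverageMatrix(patients, sites, Q)
    return binary, universe_size // 3, 1


def decision_falafl(Q, k_columns: int, ell: int = 1) -> bool:
    """Decision problem: do some exactly-``k_columns`` columns of ``Q`` give
    every row at least ``ell`` ones?  Exhaustive; test-scale only."""
    S = _as_binary_array(Q)
    n, m = S.shape
    if m > _ENUM_BOUND:
        raise ValueError(f"enumeration bound is {_ENUM_BOUND} columns, got {m}")
    if k_columns > m:
        return False
    for combo in itertools.combinations(range(m), k_columns):
        if (S[:, combo].sum(axis=1) >= ell).all():
            return True
    return False
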