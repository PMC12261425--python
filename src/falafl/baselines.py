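"""Naive selection baselines, shuffle-robustness, and balance summaries.

Three naive strategies serve as comparison points for the fair ILP
selection: keeping sites covered in at least half the patients, greedy
per-patient-pair selection, and uniform random sampling from the
unpreprocessed site universe.  The shuffle-robustness protocol reruns the
ILP on random column permutations of the same matrix and measures
pairwise Jaccard overlap of the returned site sets.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin

from .matrix_io import CoverageFractionMatrix, SiteId
from .preprocess import BinaryCoverageMatrix
from .select import SelectionResult, select

__all__ = [
    "BaselineResult",
    "naive_half",
    "NaiveCoverageSelector",
    "greedy_pairwise",
    "PairwiseSelection",
    "random_select",
    "jaccard",
    "shuffle_robustness",
    "ShuffleRobustness",
    "balance_report",
    "informativeness_correlation",
]


@dataclass
class BaselineResult:
    method: str
    selected: np.ndarray
    replicate: int | None = None


def naive_half(binary: BinaryCoverageMatrix | np.ndarray) -> BaselineResult:
    """Select columns covered in at least half (``ceil(n/2)``) of patients."""
    values = binary.values if isinstance(binary, BinaryCoverageMatrix) else np.asarray(binary)
    n = values.shape[0]
    threshold = math.ceil(n / 2)
    selected = np.flatnonzero(values.sum(axis=0) >= threshold)
    return BaselineResult("naive_half", selected)


class NaiveCoverageSelector(SelectorMixin, BaseEstimator):
    """scikit-learn selector keeping features covered in >= ceil(n/2) rows
    (or an explicit ``min_patients``)."""

    def __init__(self, min_patients: int | None = None):
        self.min_patients = min_patients

    def fit(self, X, y=None):
        X = np.asarray(X)
        thr = self.min_patients
        if thr is None:
            thr = math.ceil(X.shape[0] / 2)
        self.n_features_in_ = X.shape[1]
        self.support_mask_ = X.sum(axis=0) >= thr
        return self

    def _get_support_mask(self):
        return self.support_mask_

    def __sklearn_tags__(self):
        tags = super().__sklearn_tags__()
        tags.target_tags.required = False
        return tags


@dataclass
class PairwiseSelection:
    """Greedy per-pair selections plus their all-pairs intersection."""

    per_pair: dict[tuple[str, str], np.ndarray]
    intersection: np.ndarray
    threshold: float = 0.5


def greedy_pairwise(
    fractions: CoverageFractionMatrix, threshold: float = 0.5
) -> PairwiseSelection:
    """For each unordered patient pair, keep sites with covered-cell
    fraction at least ``threshold`` in both patients.

    Intended for fraction matrices aggregated at one read of depth (sites
    "covered by at least one read in 50% or more of the cells").
    """
    n = fractions.n_patients
    if n < 2:
        raise ValueError("greedy pairwise selection needs >= 2 patients")
    if fractions.depth_threshold != 1:
        warnings.warn(
            "greedy pairwise selection is defined on depth_threshold=1 "
            f"fraction matrices; got {fractions.depth_threshold}",
            stacklevel=2,
        )
    good = fractions.values >= threshold
    ids = fractions.patient_ids
    per_pair: dict[tuple[str, str], np.ndarray] = {}
    inter = np.ones(fractions.n_sites, dtype=bool)
    for a, b in itertools.combinations(range(n), 2):
        mask = good[a] & good[b]
        per_pair[(ids[a], ids[b])] = np.flatnonzero(mask)
        inter &= mask
    return PairwiseSelection(per_pair, np.flatnonzero(inter), threshold)


def random_select(
    universe: list[SiteId] | int,
    count: int,
    replicates: int = 5,
    seed: int = 0,
) -> list[BaselineResult]:
    """Uniform samples without replacement from the unpreprocessed universe.

    ``universe`` may be a site list or just its size; each replicate draws
    from an independent seeded stream, so a fixed seed reproduces the
    whole list of replicates.
    """
    size = universe if isinstance(universe, int) else len(universe)
    if count > size:
        raise ValueError(f"cannot sample {count} sites from universe of {size}")
    rng = np.random.default_rng(seed)
    out = []
    for rep in range(replicates):
        sel = np.sort(rng.choice(size, size=count, replace=False))
        out.append(BaselineResult("random", sel, replicate=rep))
    return out


def jaccard(a, b) -> float:
    """Jaccard index of two index sets; two empty sets count as 1.0."""
    sa, sb = set(np.asarray(a).tolist()), set(np.asarray(b).tolist())
    if not sa and not sb:
        warnings.warn("Jaccard of two empty sets, defined as 1.0", stacklevel=2)
        return 1.0
    return len(sa & sb) / len(sa | sb)


@dataclass
class ShuffleRobustness:
    pairwise_jaccard: np.ndarray
    selections: list[np.ndarray] = field(repr=False)
    objectives: list[int] = field(default_factory=list)

    @property
    def min_pairwise(self) -> float:
        n = self.pairwise_jaccard.shape[0]
        iu = np.triu_indices(n, k=1)
        return float(self.pairwise_jaccard[iu].min())


def shuffle_robustness(
    binary: BinaryCoverageMatrix | np.ndarray,
    q: float,
    n_shuffles: int = 3,
    seed: int = 0,
) -> ShuffleRobustness:
    """Rerun the ILP on random column permutations and compare outputs.

    Each run's selection is mapped back to original column indices; the
    pairwise Jaccard matrix over runs quantifies how much the solver's
    choice depends on column order.  Objectives are provably identical
    across permutations; the site sets can differ only among ties.
    """
    if n_shuffles < 2:
        raise ValueError("need at least 2 shuffles to compare")
    values = binary.values if isinstance(binary, BinaryCoverageMatrix) else np.asarray(binary)
    m = values.shape[1]
    rng = np.random.default_rng(seed)
    selections, objectives = [], []
    for _ in range(n_shuffles):
        perm = rng.permutation(m)
        res = select(values[:, perm], q)
        selections.append(np.sort(perm[res.selected]))
        objectives.append(res.objective)
    jac = np.ones((n_shuffles, n_shuffles))
    for i, j in itertools.combinations(range(n_shuffles), 2):
        jac[i, j] = jac[j, i] = jaccard(selections[i], selections[j])
    return ShuffleRobustness(jac, selections, objectives)


def balance_report(
    selected: np.ndarray, binary: BinaryCoverageMatrix | np.ndarray
) -> tuple[pd.Series, dict[int, int]]:
    """Per-patient covered-site counts and the patient-count histogram.

    Returns (series indexed by patient of #selected sites with a 1, and
    {t: #selected sites covered in exactly t patients}).
    """
    selected = np.asarray(selected, dtype=int)
    if selected.size == 0:
        raise ValueError("balance report needs a nonempty selection")
    if isinstance(binary, BinaryCoverageMatrix):
        values, index = binary.values, [p.patient_id for p in binary.patients]
    else:
        values = np.asarray(binary)
        index = [f"patient{i + 1}" for i in range(values.shape[0])]
    sub = values[:, selected]
    per_patient = pd.Series(sub.sum(axis=1).astype(int), index=index)
    col_counts = sub.sum(axis=0).astype(int)
    hist = {
        int(t): int(c)
        for t, c in zip(*np.unique(col_counts, return_counts=True))
        if t > 0
    }
    return per_patient, hist


def informativeness_correlation(js: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation of per-site informativeness between patient
    pairs (columns of ``js`` are patients, rows are sites)."""
    return js.corr(method="pearson")
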