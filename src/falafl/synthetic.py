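"""Synthetic data generators for coverage matrices and methylation counts.

These emulate the study conditions of low-coverage single-cell bisulfite
sequencing cohorts: binary coverage matrices with per-entry density around
0.66 (the empirical coverage of the real data), perturbed-cohort matrices
built by resampling patient rows and flipping entries with probability
0.1, Beta-distributed coverage-fraction matrices with patient-group
structure, and small-read-count methylation matrices on a balanced cell
tree with a planted informative clade.

Every generator is a pure function of its configuration including the
seed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import dendropy
import numpy as np

from .lineage import MethylCountMatrices, load_cell_tree
from .matrix_io import CoverageFractionMatrix, PatientMeta, SiteId
from .preprocess import BinaryCoverageMatrix

__all__ = [
    "SyntheticConfig",
    "random_binary_matrix",
    "perturbed_cohort",
    "random_fraction_matrix",
    "balanced_tree",
    "synthetic_methylation",
    "SyntheticMethylation",
]

# study-condition defaults: coverage density and perturbation rate
DEFAULT_DENSITY = 0.66
DEFAULT_FLIP_PROB = 0.1


@dataclass
class SyntheticConfig:
    """Parameters of the binary-matrix generators."""

    n_patients: int
    m_sites: int
    density: float = DEFAULT_DENSITY
    groups: dict[str, float] | None = None
    flip_prob: float = DEFAULT_FLIP_PROB
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.density <= 1.0:
            raise ValueError("density must be in [0, 1]")
        if not 0.0 <= self.flip_prob <= 1.0:
            raise ValueError("flip_prob must be in [0, 1]")
        if self.n_patients < 1 or self.m_sites < 1:
            raise ValueError("need at least one patient and one site")
        if self.groups is not None:
            total = sum(self.groups.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError("group proportions must sum to 1")


def _make_sites(m: int, spacing: int = 50) -> list[SiteId]:
    return [SiteId("chr1", spacing * j + 1) for j in range(m)]


def _make_patients(n: int, groups: dict[str, float] | None) -> list[PatientMeta]:
    if groups is None:
        return [PatientMeta(f"P{i + 1}") for i in range(n)]
    labels: list[str] = []
    names = sorted(groups)
    counts = {g: int(round(groups[g] * n)) for g in names}
    # fix rounding drift on the largest group
    drift = n - sum(counts.values())
    counts[max(names, key=lambda g: groups[g])] += drift
    for g in names:
        labels.extend([g] * counts[g])
    return [PatientMeta(f"P{i + 1}", group=labels[i]) for i in range(n)]


def random_binary_matrix(config: SyntheticConfig) -> BinaryCoverageMatrix:
    """I.i.d. Bernoulli(density) binary coverage matrix."""
    rng = np.random.default_rng(config.seed)
    values = (
        rng.random((config.n_patients, config.m_sites)) < config.density
    ).astype(np.uint8)
    return BinaryCoverageMatrix(
        _make_patients(config.n_patients, config.groups),
        _make_sites(config.m_sites),
        values,
    )


def perturbed_cohort(
    base: BinaryCoverageMatrix,
    n_target: int,
    flip_prob: float = DEFAULT_FLIP_PROB,
    seed: int = 0,
) -> BinaryCoverageMatrix:
    """Resample patient rows (with replacement) and flip entries.

    Emulates growing a small real cohort to ``n_target`` patients: each
    target row is a copy of a random source patient with every entry
    complemented independently with probability ``flip_prob``.
    """
    if base.n_sites == 0 or base.n_patients == 0:
        raise ValueError("base matrix is empty")
    if not 0.0 <= flip_prob <= 1.0:
        raise ValueError("flip_prob must be in [0, 1]")
    rng = np.random.default_rng(seed)
    rows = rng.integers(0, base.n_patients, size=n_target)
    values = base.values[rows].astype(np.uint8)
    flips = rng.random(values.shape) < flip_prob
    values = np.where(flips, 1 - values, values).astype(np.uint8)
    patients = [
        PatientMeta(f"P{i + 1}", group=base.patients[r].group)
        for i, r in enumerate(rows)
    ]
    return BinaryCoverageMatrix(patients, list(base.retained_sites), values)


def random_fraction_matrix(
    n_patients: int,
    m_sites: int,
    alpha: float = 2.0,
    beta: float = 1.0,
    groups: dict[str, float] | None = None,
    seed: int = 0,
) -> CoverageFractionMatrix:
    """Beta(alpha, beta)-distributed covered-cell fractions.

    The default Beta(2, 1) skews toward well-covered sites, mimicking a
    post-filtering fraction matrix; lower ``alpha`` produces the sparser
    heterogeneous coverage of raw data.
    """
    rng = np.random.default_rng(seed)
    values = rng.beta(alpha, beta, size=(n_patients, m_sites))
    return CoverageFractionMatrix(
        _make_patients(n_patients, groups), _make_sites(m_sites), values
    )


def balanced_tree(n_leaves: int) -> tuple[dendropy.Tree, str]:
    """Balanced binary cell tree with labeled internal nodes.

    Leaves are ``cell1..cellN``; internal nodes get labels ``n1, n2, ...``
    in construction order.  Returns (tree, label of the root's first
    child), the natural planting target for a clade effect.
    """
    if n_leaves < 4:
        raise ValueError("need at least 4 leaves for a meaningful split")
    counter = itertools.count(1)

    def build(cells: list[str]) -> tuple[str, str | None]:
        if len(cells) == 1:
            return cells[0], None
        mid = len(cells) // 2
        left, _ = build(cells[:mid])
        right, _ = build(cells[mid:])
        label = f"n{next(counter)}"
        return f"({left},{right}){label}", label

    cells = [f"cell{i + 1}" for i in range(n_leaves)]
    mid = n_leaves // 2
    left_str, left_label = build(cells[:mid])
    right_str, _ = build(cells[mid:])
    newick = f"({left_str},{right_str})root;"
    tree = load_cell_tree(newick, is_path=False)
    # single-leaf left subtree has no internal label; fall back to right
    if left_label is None:
        raise ValueError("left subtree has a single leaf; use more leaves")
    return tree, left_label


@dataclass
class SyntheticMethylation:
    tree: dendropy.Tree
    counts: MethylCountMatrices
    informative_sites: list[SiteId]
    background_sites: list[SiteId]
    clade_node: str


def synthetic_methylation(
    n_leaves: int,
    n_informative: int,
    n_background: int,
    clade: str = "auto",
    clade_effect: float = 1.0,
    noise: float = 0.0,
    max_reads: int = 5,
    seed: int = 0,
) -> SyntheticMethylation:
    """Methylation read counts on a balanced tree with a planted clade.

    Informative sites get per-cell methylation levels whose means differ
    by ``clade_effect`` between the designated clade and the rest of the
    tree (Gaussian jitter with s.d. ``noise``, clipped to [0, 1]);
    background sites draw levels uniformly.  Read totals per (cell, site)
    are uniform on 1..``max_reads`` to mimic low coverage, and methylated
    counts are binomial in the level.
    """
    if not 0.0 <= clade_effect <= 1.0:
        raise ValueError("clade_effect must be in [0, 1]")
    if noise < 0:
        raise ValueError("noise must be >= 0")
    tree, default_clade = balanced_tree(n_leaves)
    internal = {
        node.label
        for node in tree.preorder_node_iter()
        if node is not tree.seed_node and not node.is_leaf() and node.label
    }
    clade_label = default_clade if clade == "auto" else clade
    if clade_label not in internal:
        raise ValueError(f"clade {clade_label!r} is not an internal node label")
    clade_node = next(
        nd for nd in tree.preorder_node_iter() if nd.label == clade_label
    )
    in_clade_cells = {lf.taxon.label for lf in clade_node.leaf_iter()}

    rng = np.random.default_rng(seed)
    cells = [f"cell{i + 1}" for i in range(n_leaves)]
    in_mask = np.array([c in in_clade_cells for c in cells])
    m = n_informative + n_background
    sites = _make_sites(m)
    levels = np.empty((n_leaves, m))
    hi, lo = 0.5 + clade_effect / 2, 0.5 - clade_effect / 2
    for j in range(n_informative):
        mu = np.where(in_mask, hi, lo)
        levels[:, j] = np.clip(mu + rng.normal(0, noise, size=n_leaves), 0, 1)
    levels[:, n_informative:] = rng.random((n_leaves, n_background))
    totals = rng.integers(1, max_reads + 1, size=(n_leaves, m))
    N = rng.binomial(totals, levels)
    M = totals - N
    counts = MethylCountMatrices(N, M, cells, sites)
    return SyntheticMethylation(
        tree,
        counts,
        informative_sites=sites[:n_informative],
        background_sites=sites[n_informative:],
        clade_node=clade_label,
    )
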