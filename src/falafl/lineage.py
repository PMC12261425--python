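"""Lineage-informativeness of CpG sites on a fixed single-cell tree.

A site is lineage-informative when its methylation status switches once on
the tumor phylogeny and is then stably inherited: the cells inside some
clade then have a methylation-level distribution far from that of the rest
of the tree.  For each internal node (root excluded) the per-cell
methylation levels ``N/(N+M)`` of covered cells are histogrammed in-clade
vs out-of-clade and compared with the Jensen–Shannon distance (base-2
logs, so the distance is bounded by 1); the site's score is the maximum
over nodes.

The tree is supplied as Newick with leaf labels matching cell identifiers;
inferring the tree is out of scope here — any phylogeny reconstruction
method can provide it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
from scipy.spatial.distance import jensenshannon

from .matrix_io import SiteId

__all__ = [
    "MethylCountMatrices",
    "SiteInformativeness",
    "js_distance",
    "load_cell_tree",
    "site_informativeness",
    "informativeness_profile",
    "classify_universality",
]


@dataclass
class MethylCountMatrices:
    """Cells × sites methylated (``N``) and unmethylated (``M``) read counts.

    A (cell, site) with ``N + M = 0`` is uncovered and is excluded from
    every distribution (no imputation).
    """

    N: np.ndarray
    M: np.ndarray
    cell_ids: list[str]
    sites: list[SiteId]

    def __post_init__(self) -> None:
        self.N = np.asarray(self.N, dtype=float)
        self.M = np.asarray(self.M, dtype=float)
        if self.N.shape != self.M.shape:
            raise ValueError("N and M must have the same shape")
        if (self.N < 0).any() or (self.M < 0).any():
            raise ValueError("read counts must be nonnegative")
        if self.N.shape != (len(self.cell_ids), len(self.sites)):
            raise ValueError("count shape inconsistent with cell/site lists")

    def levels(self, col: int) -> tuple[np.ndarray, np.ndarray]:
        """Methylation level per covered cell at column ``col``.

        Returns (covered mask over cells, level N/(N+M) for covered cells).
        """
        tot = self.N[:, col] + self.M[:, col]
        covered = tot > 0
        lev = np.zeros_like(tot)
        lev[covered] = self.N[covered, col] / tot[covered]
        return covered, lev

    def site_column(self, site: SiteId) -> int:
        try:
            return self.sites.index(site)
        except ValueError:
            raise KeyError(f"site {site} not in count matrices") from None


@dataclass
class SiteInformativeness:
    site: SiteId
    js: float
    argmax_node: str


def js_distance(pdist, qdist) -> float:
    """Jensen–Shannon distance between two discrete distributions.

    Base-2 logs: 0 for identical distributions, 1 for disjoint supports.
    Inputs must be nonnegative and sum to 1 over the same support.
    """
    p = np.asarray(pdist, dtype=float)
    q = np.asarray(qdist, dtype=float)
    if p.shape != q.shape or p.ndim != 1:
        raise ValueError("distributions must be 1-D over the same support")
    for name, d in (("p", p), ("q", q)):
        if (d < 0).any() or abs(d.sum() - 1.0) > 1e-9:
            raise ValueError(f"{name} is not a normalized distribution")
    return float(min(jensenshannon(p, q, base=2), 1.0))


def load_cell_tree(source: str, *, is_path: bool = True) -> dendropy.Tree:
    """Load a rooted cell tree from a Newick file (or string)."""
    kwargs = {"path": source} if is_path else {"data": source}
    tree = dendropy.Tree.get(schema="newick", **kwargs)
    labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
    if len(labels) != len(set(labels)):
        raise ValueError("leaf labels must be unique")
    return tree


def _internal_nodes(tree: dendropy.Tree):
    """Internal nodes below the root, with stable identifiers and the
    row indices of the leaves in their clade."""
    nodes = []
    for idx, node in enumerate(tree.preorder_node_iter()):
        if node is tree.seed_node or node.is_leaf():
            continue
        label = node.label or f"node{idx}"
        leaves = [lf.taxon.label for lf in node.leaf_iter()]
        nodes.append((label, leaves))
    return nodes


def _histogram(levels: np.ndarray, bins: int) -> np.ndarray:
    h, _ = np.histogram(levels, bins=bins, range=(0.0, 1.0))
    return h / h.sum()


def site_informativeness(
    counts: MethylCountMatrices,
    tree: dendropy.Tree,
    site: SiteId,
    bins: int = 10,
    min_cells: int = 3,
) -> SiteInformativeness:
    """Maximum clade-vs-rest Jensen–Shannon distance for one site.

    Internal nodes where either the clade or its complement has fewer
    than ``min_cells`` covered cells are skipped: a histogram estimated
    from one or two cells is dominated by sampling noise and would let
    tiny clades inflate the maximum.  ``min_cells=1`` skips only
    empty-sided nodes.  The root is always excluded (its complement is
    empty by construction).
    """
    if bins < 2:
        raise ValueError("need at least 2 histogram bins")
    if min_cells < 1:
        raise ValueError("min_cells must be >= 1")
    col = counts.site_column(site)
    covered, lev = counts.levels(col)
    if not covered.any():
        raise ValueError(f"site {site} is uncovered in every cell")
    row_of = {cid: i for i, cid in enumerate(counts.cell_ids)}
    in_tree = np.zeros(len(counts.cell_ids), dtype=bool)
    clades = []
    for label, leaves in _internal_nodes(tree):
        rows = np.array([row_of[l] for l in leaves if l in row_of], dtype=int)
        mask = np.zeros(len(counts.cell_ids), dtype=bool)
        mask[rows] = True
        in_tree |= mask
        clades.append((label, mask))
    best: SiteInformativeness | None = None
    for label, mask in clades:
        inside = covered & mask
        outside = covered & in_tree & ~mask
        if inside.sum() < min_cells or outside.sum() < min_cells:
            continue
        js = js_distance(
            _histogram(lev[inside], bins), _histogram(lev[outside], bins)
        )
        if best is None or js > best.js:
            best = SiteInformativeness(site, js, label)
    if best is None:
        raise ValueError(
            f"site {site}: no internal node has covered cells on both sides"
        )
    return best


def informativeness_profile(
    counts: MethylCountMatrices,
    tree: dendropy.Tree,
    bins: int = 10,
    min_cells: int = 3,
    skip_invalid: bool = True,
) -> pd.DataFrame:
    """Score every site; returns a table (site, js, argmax_node).

    Sites with no valid clade split are dropped when ``skip_invalid`` is
    true, else they raise.
    """
    records = []
    for site in counts.sites:
        try:
            r = site_informativeness(counts, tree, site, bins=bins, min_cells=min_cells)
        except ValueError:
            if skip_invalid:
                continue
            raise
        records.append((str(r.site), r.js, r.argmax_node))
    return pd.DataFrame(records, columns=["site", "js", "argmax_node"])


def classify_universality(profiles: pd.DataFrame) -> pd.DataFrame:
    """Label sites universally informative / uninformative / other.

    ``profiles`` needs columns ``mean_js`` (mean JS distance across
    patients) and ``normalized_deviation``.  Thresholds are the cohort
    means of the two columns; comparisons are strict: informative =
    above-mean informativeness with below-mean deviation, uninformative =
    below-mean informativeness with below-mean deviation, everything else
    (including values exactly at a threshold) is "other".  The thresholds
    used are recorded in ``result.attrs``.
    """
    if len(profiles) < 2:
        raise ValueError("need at least 2 sites to set cohort thresholds")
    mean_js = profiles["mean_js"].to_numpy(dtype=float)
    dev = profiles["normalized_deviation"].to_numpy(dtype=float)
    if not (np.isfinite(mean_js).all() and np.isfinite(dev).all()):
        raise ValueError("profiles contain non-finite values")
    t_js = mean_js.mean()
    t_dev = dev.mean()
    label = np.where(
        (mean_js > t_js) & (dev < t_dev),
        "universally_informative",
        np.where((mean_js < t_js) & (dev < t_dev), "universally_uninformative", "other"),
    )
    if (label == "other").all():
        warnings.warn("no site cleared both cohort-mean thresholds", stacklevel=2)
    out = profiles.copy()
    out["label"] = label
    out.attrs["threshold_mean_js"] = float(t_js)
    out.attrs["threshold_deviation"] = float(t_dev)
    return out
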