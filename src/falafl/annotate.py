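"""CpG island / shore / shelf / inter-CGI annotation of sites.

CpG islands come in as BED intervals (0-based, half-open).  A site inside
an island is labeled ``island``; otherwise the gap distance to the nearest
island edge decides: within 2 kb → ``shore``, within the next 2 kb (gap ≤
4 kb) → ``shelf``, beyond → ``interCGI``.  Boundaries are inclusive and
overlapping annotations from adjacent islands resolve by the precedence
island > shore > shelf > interCGI, so each site gets exactly one label.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrix_io import SiteId

__all__ = [
    "RegionAnnotation",
    "read_cgi_bed",
    "annotate_sites",
    "region_fractions",
    "SHORE_WIDTH",
    "SHELF_WIDTH",
]

SHORE_WIDTH = 2000  # bp flanking an island on each side
SHELF_WIDTH = 2000  # bp beyond the shore

REGIONS = ("island", "shore", "shelf", "interCGI")


@dataclass(frozen=True)
class RegionAnnotation:
    site: SiteId
    region: str


def read_cgi_bed(path) -> dict[str, np.ndarray]:
    """Read CGI intervals from BED into {chrom: (k, 2) start/end array}."""
    ivals: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: BED needs >= 3 columns")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if end <= start:
                raise ValueError(f"{path}:{lineno}: empty interval")
            ivals.setdefault(chrom, []).append((start, end))
    return {
        c: np.array(sorted(v), dtype=int).reshape(-1, 2) for c, v in ivals.items()
    }


def _gap_distance(pos0: int, intervals: np.ndarray) -> int:
    """Gap distance (bp) from 0-based position to the nearest interval;
    0 means inside or adjacent."""
    starts, ends = intervals[:, 0], intervals[:, 1]
    inside = (starts <= pos0) & (pos0 < ends)
    if inside.any():
        return 0
    left = np.where(pos0 >= ends, pos0 - (ends - 1), np.iinfo(int).max)
    right = np.where(pos0 < starts, starts - pos0, np.iinfo(int).max)
    return int(min(left.min(), right.min()))


def annotate_sites(
    sites: list[SiteId], cgi: dict[str, np.ndarray]
) -> list[RegionAnnotation]:
    """Assign each site exactly one region label.

    Site coordinates are 1-based; containment and distance are computed on
    the 0-based position ``pos - 1``.  Chromosomes with no CGI interval
    annotate as interCGI with a warning.
    """
    missing: set[str] = set()
    out: list[RegionAnnotation] = []
    for site in sites:
        intervals = cgi.get(site.chrom)
        if intervals is None or len(intervals) == 0:
            missing.add(site.chrom)
            out.append(RegionAnnotation(site, "interCGI"))
            continue
        d = _gap_distance(site.pos - 1, intervals)
        if d == 0:
            region = "island"
        elif d <= SHORE_WIDTH:
            region = "shore"
        elif d <= SHORE_WIDTH + SHELF_WIDTH:
            region = "shelf"
        else:
            region = "interCGI"
        out.append(RegionAnnotation(site, region))
    if missing:
        warnings.warn(
            f"no CGI intervals for chromosome(s) {sorted(missing)}; "
            "their sites are labeled interCGI",
            stacklevel=2,
        )
    return out


def region_fractions(
    annotations: list[RegionAnnotation],
    labels: dict[SiteId, str] | None = None,
) -> pd.DataFrame:
    """Fractions of sites in each region, optionally stratified by a
    per-site label (e.g. universality class).

    Rows are label groups (a single ``all`` row when no labels are given);
    the four region fractions in each row sum to 1.  Empty groups simply
    do not appear.
    """
    if not annotations:
        return pd.DataFrame(columns=REGIONS)
    groups: dict[str, list[str]] = {}
    for ann in annotations:
        grp = "all" if labels is None else labels.get(ann.site)
        if grp is None:
            raise ValueError(f"site {ann.site} has no label")
        groups.setdefault(grp, []).append(ann.region)
    rows = {}
    for grp, regs in sorted(groups.items()):
        counts = pd.Series(regs).value_counts()
        rows[grp] = [counts.get(r, 0) / len(regs) for r in REGIONS]
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(REGIONS))
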