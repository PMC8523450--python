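"""Short-artifact read characterization and filtering.

Amplification negatives on amplicon mtDNA panels are dominated by short,
poorly mapped reads — putative micro-amplicons formed between primers of
overlapping amplicons.  This module clusters reads into a short/low-MAPQ and
a long/high-MAPQ population (k=2 k-means on standardized length x MAPQ),
derives a length cutoff from the cluster midpoints, filters reads below it,
and reports which amplicons the removed reads concentrate in.

MAPQ takes part in clustering and reporting but not in the filter predicate;
the filter is length-only (a MAPQ floor can be enabled explicitly).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from sklearn.cluster import KMeans

from .reads import AlignedReadRecord, ReadSet
from .reference import AmpliconPanel

DEFAULT_CUTOFF_BP = 80


class InsufficientData(ValueError):
    pass


class DegenerateInput(ValueError):
    pass


@dataclass
class ClusterResult:
    """Two-cluster summary of the (length, MAPQ) read cloud.

    Labels are assigned by length ordering: the cluster with the smaller mean
    length is ``short``.  Midpoints are arithmetic means of the two centroids
    in original units.
    """

    centroid_short: tuple[float, float]
    centroid_long: tuple[float, float]
    assignment: np.ndarray  # 0 = short cluster, 1 = long cluster

    @property
    def midpoint_length(self) -> float:
        return (self.centroid_short[0] + self.centroid_long[0]) / 2.0

    @property
    def midpoint_mapq(self) -> float:
        return (self.centroid_short[1] + self.centroid_long[1]) / 2.0


@dataclass
class FilterReport:
    total_mapped: int
    removed: int
    cutoff_bp: int
    per_amplicon_removed: dict[str, int] = field(default_factory=dict)

    @property
    def kept(self) -> int:
        return self.total_mapped - self.removed

    @property
    def pct_short(self) -> float:
        """Percentage of reads below the cutoff (exact, unrounded)."""
        if self.total_mapped == 0:
            return 0.0
        return 100.0 * self.removed / self.total_mapped

    @property
    def pct_short_display(self) -> float:
        return round(self.pct_short, 1)

    def to_dict(self) -> dict:
        return {
            "total_mapped": self.total_mapped,
            "removed": self.removed,
            "kept": self.kept,
            "pct_short": self.pct_short_display,
            "cutoff_bp": self.cutoff_bp,
            "per_amplicon_removed": dict(self.per_amplicon_removed),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def _length_mapq_matrix(reads) -> np.ndarray:
    if isinstance(reads, ReadSet):
        return np.column_stack([reads.lengths(), reads.mapqs()]).astype(float)
    arr = np.array([(r.aligned_length, r.mapq) for r in reads], dtype=float)
    return arr.reshape(-1, 2)


_EXACT_MAX_POINTS = 40


def _exact_two_means_labels(Z: np.ndarray) -> np.ndarray:
    """Globally optimal 2-means partition of 2-D points.

    The optimal two clusters are separated by the perpendicular bisector of
    their means, so the partition is a threshold split along some direction.
    Sweeping directions just inside every angular cell of the projection
    arrangement (perpendiculars of pairwise differences, rotated by +-eps)
    and testing every split yields the exact optimum.
    """
    n = len(Z)
    sq = (Z ** 2).sum()
    diffs = []
    for i in range(n):
        for j in range(i + 1, n):
            d = Z[j] - Z[i]
            if d @ d > 0:
                diffs.append(d)
    directions = []
    for d in diffs:
        perp = np.array([-d[1], d[0]])
        for eps in (1e-7, -1e-7):
            c, s = np.cos(eps), np.sin(eps)
            directions.append(
                np.array([c * perp[0] - s * perp[1],
                          s * perp[0] + c * perp[1]])
            )
    best_ss, best_labels = np.inf, None
    for d in directions:
        order = np.argsort(Z @ d, kind="stable")
        P = Z[order]
        csum = np.cumsum(P, axis=0)
        total = csum[-1]
        k = np.arange(1, n)
        left = csum[:-1]
        right = total - left
        ss = sq - (left ** 2).sum(axis=1) / k \
            - (right ** 2).sum(axis=1) / (n - k)
        kbest = int(np.argmin(ss))
        if ss[kbest] < best_ss - 1e-12:
            best_ss = float(ss[kbest])
            labels = np.ones(n, dtype=int)
            labels[order[: kbest + 1]] = 0
            best_labels = labels
    return best_labels


def cluster_reads_2means(reads, seed: int = 0, n_init: int = 30) -> ClusterResult:
    """Two-cluster analysis of the (aligned length, MAPQ) cloud.

    Points are z-score standardized; small inputs (<= 40 points) are solved
    to the exact minimum within-cluster sum of squares via a projection
    sweep, larger ones by k-means with ``n_init`` restarts.  Reads with
    MAPQ 0 are excluded from the fit (they carry no usable mapping signal);
    the returned assignment covers the fitted reads only.  Deterministic for
    a fixed seed; centroids are reported in original units.
    """
    X = _length_mapq_matrix(reads)
    X = X[X[:, 1] > 0] if (X[:, 1] == 0).any() and (X[:, 1] > 0).sum() >= 2 else X
    if len(X) < 2:
        raise InsufficientData("need >= 2 reads to cluster")
    if len(np.unique(X, axis=0)) < 2:
        raise DegenerateInput("all (length, MAPQ) points identical")
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (X - mu) / sd
    if len(Z) <= _EXACT_MAX_POINTS:
        raw_labels = _exact_two_means_labels(Z)
    else:
        km = KMeans(n_clusters=2, n_init=n_init, random_state=seed).fit(Z)
        raw_labels = km.labels_
    centroids = np.stack([X[raw_labels == lab].mean(axis=0) for lab in (0, 1)])
    order = np.argsort(centroids[:, 0])  # short first
    labels = np.where(raw_labels == order[0], 0, 1)
    return ClusterResult(
        centroid_short=tuple(centroids[order[0]]),
        centroid_long=tuple(centroids[order[1]]),
        assignment=labels,
    )


def derive_length_cutoff(
    cluster_results: Sequence[ClusterResult], granularity: int = 5
) -> int:
    """Length cutoff from cluster midpoints: mean midpoint rounded UP to the
    next multiple of ``granularity`` (minimum 1)."""
    if not cluster_results:
        raise InsufficientData("no cluster results")
    if granularity < 1:
        raise ValueError("granularity must be >= 1")
    mean_mid = float(np.mean([c.midpoint_length for c in cluster_results]))
    return max(1, math.ceil(mean_mid / granularity) * granularity)


def filter_reads(
    reads,
    cutoff_bp: int = DEFAULT_CUTOFF_BP,
    panel: AmpliconPanel | None = None,
):
    """Split reads at the length cutoff.

    Returns ``(kept, removed, FilterReport)``.  ``reads`` may be a ReadSet
    (kept/removed are ReadSets) or a sequence of AlignedReadRecord
    (kept/removed are lists).  Removed reads are attributed to amplicons —
    by the record's own assignment, or by maximal span overlap when a panel
    is supplied.
    """
    if cutoff_bp < 1:
        raise ValueError("cutoff_bp must be >= 1")
    if isinstance(reads, ReadSet):
        kept, removed = reads.subset_by_length(cutoff_bp)
        removed_records: Iterable[AlignedReadRecord] = removed.iter_records()
        total = reads.n_reads
        n_removed = removed.n_reads
    else:
        reads = list(reads)
        kept = [r for r in reads if r.aligned_length >= cutoff_bp]
        removed = [r for r in reads if r.aligned_length < cutoff_bp]
        removed_records = removed
        total = len(reads)
        n_removed = len(removed)
    per_amplicon: dict[str, int] = {}
    for r in removed_records:
        name = r.amplicon
        if panel is not None:
            name = panel.assign(r.start, r.start + r.aligned_length - 1)
        if name is None:
            name = "unassigned"
        per_amplicon[name] = per_amplicon.get(name, 0) + 1
    report = FilterReport(
        total_mapped=total,
        removed=n_removed,
        cutoff_bp=cutoff_bp,
        per_amplicon_removed=per_amplicon,
    )
    return kept, removed, report


def hotspot_amplicons(
    removed_reads,
    panel: AmpliconPanel,
    enrichment_factor: float = 2.0,
) -> list[str]:
    """Amplicons where removed reads concentrate.

    A hotspot's removed-read count exceeds ``enrichment_factor`` times the
    mean removed-read count across *all* panel amplicons.  Sorted by count,
    descending.  Removed reads are assigned to amplicons by maximal overlap
    of their aligned span.
    """
    if panel.count == 0:
        raise ValueError("empty amplicon panel")
    if isinstance(removed_reads, ReadSet):
        removed_reads = list(removed_reads.iter_records())
    counts = {a.name: 0 for a in panel}
    for r in removed_reads:
        name = panel.assign(r.start, r.start + r.aligned_length - 1)
        if name is not None:
            counts[name] += 1
    mean_count = sum(counts.values()) / panel.count
    hot = [
        (n, c) for n, c in counts.items() if c > enrichment_factor * mean_count
    ]
    hot.sort(key=lambda t: -t[1])
    return [n for n, _ in hot]
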