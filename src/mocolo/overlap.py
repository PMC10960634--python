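"""Reciprocal co-occurrence metrics over two motif libraries.

The test metric is the number of distinct *pivot* motifs that have at least
one qualifying overlap (overlap length >= ``min_overlap``) with the query
library, together with the number of qualifying (pivot, query) pairs. The
pair count is identical under pivot exchange; the distinct-motif counts in
general are not, which is exactly what the reciprocal test exploits when
one feature nests many motifs inside few motifs of the other.

Counting uses a sorted/searchsorted sweep per chromosome:

* a pivot ``[ps, pe)`` has a qualifying partner iff some query satisfies
  ``qs <= pe - t`` and ``qe >= ps + t`` (plus both lengths >= t), which is
  decided with a prefix maximum of query ends in query-start order;
* pair counts come from inclusion-exclusion over the two sorted coordinate
  arrays, with an exact correction for the rare regime ``t > (plen + 3) / 2``
  where the two subtracted sets intersect.

Equivalence with the all-pairs brute force is enforced by the test suite.
"""

from __future__ import annotations

import warnings
from collections.abc import Mapping, Sequence
from dataclasses import dataclass

import numpy as np

from .core import MotifLibrary

__all__ = [
    "OverlapMetrics",
    "count_overlapping",
    "coverage_profile",
    "overlapped_pivot_mask",
    "reciprocal_metrics",
    "stratified_counts",
]


@dataclass(frozen=True)
class OverlapMetrics:
    """Overlap summary for one choice of pivot feature.

    ``n_pivot_overlapped`` is the count of distinct pivot motifs with at
    least one overlap of length >= ``min_overlap``; ``n_pairs`` counts the
    qualifying (pivot, query) pairs and is symmetric in the two features.
    """

    pivot: str
    n_pivot_overlapped: int
    min_overlap: int
    n_pairs: int
    n_pivot_total: int

    def __post_init__(self) -> None:
        if not 0 <= self.n_pivot_overlapped <= self.n_pivot_total:
            raise ValueError("overlapped pivot count out of range")
        if self.n_pivot_overlapped > self.n_pairs:
            raise ValueError("n_pivot_overlapped cannot exceed n_pairs")


class _QueryIndex:
    """Per-chromosome sorted query arrays for sweep counting."""

    def __init__(self, query: MotifLibrary, min_overlap: int):
        self.t = min_overlap
        self.by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]] = {}
        keep = query.lengths >= min_overlap
        for chrom in dict.fromkeys(query.chroms.tolist()):
            m = keep & (query.chroms == chrom)
            if not m.any():
                continue
            qs = query.starts[m]
            qe = query.ends[m]
            order = np.argsort(qs, kind="stable")
            qs_sorted = qs[order]
            qe_by_qs = qe[order]
            prefix_max = np.empty(qs_sorted.size + 1, dtype=np.int64)
            prefix_max[0] = np.iinfo(np.int64).min
            np.maximum.accumulate(qe_by_qs, out=prefix_max[1:])
            np.maximum(prefix_max[1:], prefix_max[0], out=prefix_max[1:])
            qe_sorted = np.sort(qe)
            self.by_chrom[chrom] = (qs_sorted, qe_by_qs, prefix_max, qe_sorted)


def _per_pivot(
    pivot: MotifLibrary, query: MotifLibrary, min_overlap: int
) -> tuple[np.ndarray, np.ndarray]:
    """Per-pivot overlap mask and qualifying pair counts, in pivot order."""
    t = int(min_overlap)
    n = pivot.count
    mask = np.zeros(n, dtype=bool)
    pairs = np.zeros(n, dtype=np.int64)
    index = _QueryIndex(query, t)
    for chrom in dict.fromkeys(pivot.chroms.tolist()):
        entry = index.by_chrom.get(chrom)
        if entry is None:
            continue
        qs_sorted, qe_by_qs, prefix_max, qe_sorted = entry
        sel = np.nonzero(pivot.chroms == chrom)[0]
        ps = pivot.starts[sel]
        pe = pivot.ends[sel]
        plen = pe - ps
        valid = plen >= t
        hi = np.searchsorted(qs_sorted, pe - t, side="right")
        mask[sel] = valid & (prefix_max[hi] >= ps + t)
        # pairs = #{qs <= pe-t} - #{qe < ps+t} + #{qs > pe-t and qe < ps+t}
        cnt_low = np.searchsorted(qe_sorted, ps + t, side="left")
        pc = hi - cnt_low
        need = valid & (plen <= 2 * t - 3)
        for j in np.nonzero(need)[0]:
            lo = np.searchsorted(qs_sorted, pe[j] - t, side="right")
            pc[j] += int(np.count_nonzero(qe_by_qs[lo:] <= ps[j] + t - 1))
        pc[~valid] = 0
        pairs[sel] = pc
    return mask, pairs


def overlapped_pivot_mask(
    pivot: MotifLibrary, query: MotifLibrary, min_overlap: int = 1
) -> np.ndarray:
    """Boolean mask (pivot file order) of pivot motifs with a qualifying overlap."""
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    mask, _ = _per_pivot(pivot, query, min_overlap)
    return mask


def count_overlapping(
    pivot: MotifLibrary,
    query: MotifLibrary,
    min_overlap: int = 1,
    pivot_label: str = "pivot",
) -> OverlapMetrics:
    """Count pivot motifs overlapped by the query library.

    Two motifs co-localize when their overlap length is at least
    ``min_overlap`` bases (default 1: any shared base). An empty pivot
    library leaves the metric undefined and raises; an empty query library
    yields all-zero metrics with a warning.
    """
    if int(min_overlap) < 1:
        raise ValueError("min_overlap must be >= 1")
    if pivot.count == 0:
        raise ValueError("empty pivot library: overlap metric is undefined")
    if query.count == 0:
        warnings.warn(
            "empty query library: all overlap metrics are zero", stacklevel=2
        )
        return OverlapMetrics(pivot_label, 0, int(min_overlap), 0, pivot.count)
    mask, pairs = _per_pivot(pivot, query, int(min_overlap))
    return OverlapMetrics(
        pivot=pivot_label,
        n_pivot_overlapped=int(mask.sum()),
        min_overlap=int(min_overlap),
        n_pairs=int(pairs.sum()),
        n_pivot_total=pivot.count,
    )


def reciprocal_metrics(
    f1: MotifLibrary, f2: MotifLibrary, min_overlap: int = 1
) -> tuple[OverlapMetrics, OverlapMetrics]:
    """Both directional metrics: (pivot=F1 counting F1 motifs, pivot=F2).

    The pair count is the same in both directions; the distinct-motif
    counts differ whenever motifs of one feature nest inside the other.
    """
    if f1.count == 0 or f2.count == 0:
        raise ValueError("both libraries must be non-empty")
    m1 = count_overlapping(f1, f2, min_overlap, pivot_label="F1")
    m2 = count_overlapping(f2, f1, min_overlap, pivot_label="F2")
    return m1, m2


def coverage_profile(
    pivot: MotifLibrary,
    query: MotifLibrary,
    thresholds: Sequence[int],
) -> list[int]:
    """Overlapped-pivot counts at increasing minimum intersection sizes.

    ``thresholds`` must be strictly increasing; the returned sequence of
    counts is non-increasing by construction.
    """
    th = list(thresholds)
    if not th or any(b <= a for a, b in zip(th, th[1:])):
        raise ValueError("thresholds must be a non-empty strictly increasing list")
    return [
        count_overlapping(pivot, query, t, pivot_label="pivot").n_pivot_overlapped
        for t in th
    ]


def stratified_counts(
    pivot: MotifLibrary,
    query: MotifLibrary,
    annotation: MotifLibrary,
    min_overlap: int = 1,
) -> dict[str, int]:
    """Overlapped pivot motifs tallied by genomic region class.

    Each pivot motif with a qualifying query overlap is assigned to the
    class (annotation name column: exon, intron, ...) of the annotation
    interval overlapping it most; ties break by annotation file order.
    Overlapped pivots touching no annotation are tallied as "unannotated".
    """
    labels = [
        iv if iv is not None else annotation.subtypes[i]
        for i, iv in enumerate(annotation.names)
    ]
    if annotation.count == 0 or any(lab is None or lab == "" for lab in labels):
        raise ValueError("every annotation interval must carry a class label")
    mask = overlapped_pivot_mask(pivot, query, min_overlap)
    counts: dict[str, int] = {}
    ann_by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for chrom in dict.fromkeys(annotation.chroms.tolist()):
        m = annotation.chroms == chrom
        ann_by_chrom[chrom] = (
            annotation.starts[m],
            annotation.ends[m],
            np.nonzero(m)[0],
        )
    for i in np.nonzero(mask)[0]:
        chrom = pivot.chroms[i]
        entry = ann_by_chrom.get(chrom)
        label = "unannotated"
        if entry is not None:
            a_s, a_e, a_idx = entry
            ov = np.minimum(a_e, pivot.ends[i]) - np.maximum(a_s, pivot.starts[i])
            j = int(np.argmax(ov))  # first-in-file-order on ties
            if ov[j] > 0:
                label = str(labels[a_idx[j]])
        counts[label] = counts.get(label, 0) + 1
    return counts
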