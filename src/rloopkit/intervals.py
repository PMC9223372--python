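"""Exact interval arithmetic: overlap counting, nearest distance, signal means.

Overlap counting uses the pair semantics of ``bedtools intersect``: the
count is the number of (query, subject) pairs sharing at least one base
pair, so one query hitting three subjects contributes three.  The dedup
variant collapses multi-copy features (e.g. tRNA genes duplicated across
the genome) to at most one count per distinct subject name.  Strand is
ignored throughout.
"""

from __future__ import annotations

import numpy as np

from .genome import IntervalSet, SignalTrack, require_same_genome

NO_SUBJECT = -1  # nearest_distance sentinel: no subject on the query's chromosome


def _sorted_cols(iset: IntervalSet) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per-chromosome (sorted starts, sorted ends) for counting formulas."""
    out = {}
    for chrom, idx in iset.by_chrom().items():
        out[chrom] = (np.sort(iset.starts[idx]), np.sort(iset.ends[idx]))
    return out


def pair_overlap_count(
    q_starts: np.ndarray,
    q_ends: np.ndarray,
    s_starts_sorted: np.ndarray,
    s_ends_sorted: np.ndarray,
) -> np.ndarray:
    """Number of subjects overlapping each query (same chromosome assumed).

    A subject ``[s, e)`` overlaps query ``[qs, qe)`` iff ``s < qe`` and
    ``e > qs``; since every subject with ``e <= qs`` also has ``s < qe``,
    the count is ``#(s < qe) - #(e <= qs)``.
    """
    a = np.searchsorted(s_starts_sorted, q_ends, side="left")
    b = np.searchsorted(s_ends_sorted, q_starts, side="right")
    return a - b


def count_overlaps(query: IntervalSet, subject: IntervalSet) -> int:
    """Total number of overlapping (query, subject) pairs."""
    require_same_genome(query, subject)
    sub = _sorted_cols(subject)
    total = 0
    for chrom, idx in query.by_chrom().items():
        if chrom not in sub:
            continue
        ss, se = sub[chrom]
        total += int(pair_overlap_count(query.starts[idx], query.ends[idx], ss, se).sum())
    return total


def count_overlaps_dedup(query: IntervalSet, subject: IntervalSet) -> int:
    """Number of distinct subject names overlapped by at least one query.

    Used for multi-copy features counted once per unique sequence class:
    all subject intervals sharing a name contribute at most one count no
    matter how many copies or queries overlap.
    """
    require_same_genome(query, subject)
    if subject.names is None or any(n is None for n in subject.names):
        raise ValueError("count_overlaps_dedup requires names on every subject interval")
    qcols = _sorted_cols(query)
    hit: set[str] = set()
    for chrom, idx in subject.by_chrom().items():
        if chrom not in qcols:
            continue
        qs, qe = qcols[chrom]
        n = pair_overlap_count(subject.starts[idx], subject.ends[idx], qs, qe)
        for name in subject.names[idx][n > 0]:
            hit.add(name)
    return len(hit)


def nearest_distance(query: IntervalSet, subject: IntervalSet) -> np.ndarray:
    """Genomic gap from each query to the closest same-chromosome subject.

    The half-open gap between ``[a,b)`` and ``[c,d)`` is
    ``max(0, max(a,c) - min(b,d))``: overlapping or book-ended intervals
    are at distance 0.  Queries on chromosomes without any subject get the
    sentinel ``NO_SUBJECT`` (-1).
    """
    require_same_genome(query, subject)
    out = np.full(len(query), NO_SUBJECT, dtype=np.int64)
    sub = _sorted_cols(subject)
    for chrom, idx in query.by_chrom().items():
        if chrom not in sub:
            continue
        ss, se = sub[chrom]
        qs = query.starts[idx]
        qe = query.ends[idx]
        overlap = pair_overlap_count(qs, qe, ss, se) > 0
        d = np.full(len(idx), np.iinfo(np.int64).max, dtype=np.int64)
        # nearest subject entirely to the left: largest end <= q.start
        i = np.searchsorted(se, qs, side="right")
        has_left = i > 0
        d[has_left] = qs[has_left] - se[i[has_left] - 1]
        # nearest subject entirely to the right: smallest start >= q.end
        j = np.searchsorted(ss, qe, side="left")
        has_right = j < len(ss)
        d[has_right] = np.minimum(d[has_right], ss[j[has_right]] - qe[has_right])
        d[overlap] = 0
        out[idx] = d
    return out


def mean_signal_over_regions(
    track: SignalTrack, regions: IntervalSet
) -> np.ndarray:
    """Per-region length-weighted mean of overlapping track bin values.

    Partial bins are weighted by the number of covered base pairs.  A
    region on a chromosome absent from the track is an error.
    """
    out = np.empty(len(regions), dtype=float)
    for chrom, idx in regions.by_chrom().items():
        if chrom not in track.values:
            raise KeyError(f"region chromosome {chrom!r} absent from track")
        out[idx] = track.interval_means(
            chrom, regions.starts[idx].astype(float), regions.ends[idx].astype(float)
        )
    return out
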