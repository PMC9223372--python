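"""Shared fixtures and independent brute-force oracles.

The oracle functions here deliberately use naive all-pairs / per-bp /
enumeration algorithms so they share no code path with the library
implementations they check.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pytest

from rloopkit import GenomeLayout, GenomicInterval, IntervalSet, SignalTrack

IUPAC_ORACLE = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}


@pytest.fixture
def toy_genome() -> GenomeLayout:
    return GenomeLayout((("2L", 10000), ("2R", 8000), ("X", 6000)),
                        x_chroms=frozenset({"X"}))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240611)


def random_interval_set(
    rng: np.random.Generator,
    genome: GenomeLayout,
    n: int,
    max_width: int = 200,
    with_names: bool = False,
    name_pool: int = 5,
) -> IntervalSet:
    intervals = []
    names = [f"k{i}" for i in range(name_pool)]
    for i in range(n):
        chrom, length = genome.entries[rng.integers(len(genome.entries))]
        w = int(rng.integers(1, max_width + 1))
        s = int(rng.integers(0, length - w + 1))
        intervals.append(
            GenomicInterval(
                chrom, s, s + w,
                name=str(rng.choice(names)) if with_names else None,
            )
        )
    return IntervalSet.from_intervals(intervals, label="rand", genome=genome)


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def brute_count_overlaps(query: IntervalSet, subject: IntervalSet) -> int:
    """O(n*m) all-pairs overlap count."""
    total = 0
    for q in query:
        for s in subject:
            if q.chrom == s.chrom and q.start < s.end and s.start < q.end:
                total += 1
    return total


def brute_count_overlaps_dedup(query: IntervalSet, subject: IntervalSet) -> int:
    """Set of subject names with at least one overlapping query."""
    hit = set()
    for s in subject:
        for q in query:
            if q.chrom == s.chrom and q.start < s.end and s.start < q.end:
                hit.add(s.name)
                break
    return len(hit)


def brute_nearest_distance(query: IntervalSet, subject: IntervalSet) -> list[int]:
    """All-pairs minimum half-open gap, -1 when no same-chromosome subject."""
    out = []
    for q in query:
        best = None
        for s in subject:
            if s.chrom != q.chrom:
                continue
            gap = max(0, max(q.start, s.start) - min(q.end, s.end))
            best = gap if best is None else min(best, gap)
        out.append(-1 if best is None else best)
    return out


def brute_region_mean(track: SignalTrack, chrom: str, start: float, end: float) -> float:
    """Per-bp average of the piecewise-constant track over [start, end).

    Integrates bp-by-bp with fractional edge weights; bp outside the
    chromosome contribute zero signal but count toward the window length.
    """
    length = track.genome.length_of(chrom)
    vals = track.values[chrom]
    total = 0.0
    lo, hi = start, end
    # integrate over unit steps aligned to integer bp, handling fractions
    pos = lo
    while pos < hi:
        nxt = min(hi, float(int(pos) + 1) if pos != int(pos) else pos + 1.0)
        mid = (pos + nxt) / 2.0
        if 0 <= mid < length:
            total += vals[int(mid // track.bin_size)] * (nxt - pos)
        pos = nxt
    return total / (end - start)


def brute_binom_two_sided(k: int, n: int, p0: float) -> float:
    """Minimum-likelihood two-sided binomial p by direct pmf enumeration."""
    from math import comb

    pmf = [comb(n, i) * p0**i * (1 - p0) ** (n - i) for i in range(n + 1)]
    pk = pmf[k]
    return min(1.0, sum(q for q in pmf if q <= pk * (1 + 1e-12)))


def brute_ranksum_exact(a, b) -> tuple[float, float]:
    """Exact two-sided rank-sum p by enumerating all rank assignments."""
    a = list(a)
    b = list(b)
    pooled = sorted(a + b)
    assert len(set(pooled)) == len(pooled), "oracle requires tie-free data"
    ranks_a = [pooled.index(x) + 1 for x in a]
    n, m = len(a), len(b)
    u_obs = sum(ranks_a) - n * (n + 1) / 2
    le = ge = total = 0
    for comb_ in combinations(range(1, n + m + 1), n):
        u = sum(comb_) - n * (n + 1) / 2
        total += 1
        le += u <= u_obs
        ge += u >= u_obs
    return u_obs, min(1.0, 2 * min(le, ge) / total)


def brute_scan_motif(sequence: dict[str, str], consensus: str, both_strands: bool = True):
    """Sliding-window IUPAC match positions: {(chrom, start, end)}."""
    comp = {"A": "T", "C": "G", "G": "C", "T": "A",
            "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
            "B": "V", "V": "B", "D": "H", "H": "D", "N": "N"}
    patterns = [consensus.upper()]
    if both_strands:
        rc = "".join(comp[c] for c in consensus.upper())[::-1]
        if rc != consensus.upper():
            patterns.append(rc)
    hits = set()
    for chrom, seq in sequence.items():
        seq = seq.upper()
        for pat in patterns:
            w = len(pat)
            for s in range(len(seq) - w + 1):
                if all(seq[s + j] in IUPAC_ORACLE[pat[j]] for j in range(w)):
                    hits.add((chrom, s, s + w))
    return hits
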