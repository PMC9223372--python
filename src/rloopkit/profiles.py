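"""Scale-regions metagene profiles and the sequencing-depth titration.

The metagene geometry follows the common scale-regions convention:
fixed-width flanks in genomic coordinates (default 1000 bp each, 50 bp
bins, 20 bins per flank) and a gene body rescaled onto a fixed number of
bins (default 3000 bp / 50 bp = 60 bins) by length-weighted averaging.
Minus-strand rows are reversed so bin 0 is always the 5'-most position.

The depth analysis thins integer-count tracks binomially (the binned
analogue of subsampling reads) and re-calls peaks with a deliberately
simple sliding-window Poisson caller.  The caller is plumbing that exists
so depth effects on peak counts can be exercised end to end; it makes no
attempt at the local-background or fragment modelling of a production
peak caller.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
from scipy import stats

from .genome import GenomicInterval, IntervalSet, SignalTrack

logger = logging.getLogger(__name__)

RngLike = Union[int, np.random.Generator]


def _as_rng(seed: RngLike) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass
class MetageneMatrix:
    """Per-region binned signal: flank bins in genomic bp, body rescaled."""

    values: np.ndarray  # (n_regions, n_bins), 5'->3' orientation
    region_names: list[Optional[str]]
    groups: Optional[list[str]]
    n_upstream: int
    n_body: int
    n_downstream: int
    n_dropped: int = 0

    @property
    def n_bins(self) -> int:
        return self.n_upstream + self.n_body + self.n_downstream


@dataclass
class MetageneProfile:
    """Per-bin mean and standard error over a group of regions."""

    mean: np.ndarray
    sem: np.ndarray
    n_regions: int


def metagene_matrix(
    regions: IntervalSet,
    track: SignalTrack,
    upstream: int = 1000,
    downstream: int = 1000,
    body: int = 3000,
    bin_size: int = 50,
    skip_zeros: bool = True,
) -> MetageneMatrix:
    """Scale-regions matrix of ``track`` signal over stranded ``regions``.

    Flanks are sampled on fixed genomic bins of ``bin_size`` bp (clipped at
    chromosome ends, where missing sequence contributes zero signal); the
    region body is divided into ``body / bin_size`` equal-width bins whose
    boundaries may be fractional, each averaged with exact length
    weighting.  All-zero rows are dropped when ``skip_zeros``.
    """
    if upstream % bin_size or downstream % bin_size or body % bin_size:
        raise ValueError("upstream/downstream/body must be multiples of bin_size")
    n_up = upstream // bin_size
    n_down = downstream // bin_size
    n_body = body // bin_size
    n_bins = n_up + n_body + n_down

    rows = []
    names = []
    n_dropped = 0
    for i in range(len(regions)):
        chrom = regions.chroms[i]
        start = int(regions.starts[i])
        end = int(regions.ends[i])
        strand = regions.strands[i]
        if end - start < 1:
            n_dropped += 1
            continue
        if chrom not in track.values:
            raise KeyError(f"region chromosome {chrom!r} absent from track")
        # genomic-coordinate bin edges, ascending
        up_edges = start + bin_size * np.arange(-n_up, 0, dtype=float)
        body_edges = start + (end - start) * np.arange(n_body + 1, dtype=float) / n_body
        down_edges = end + bin_size * np.arange(1, n_down + 1, dtype=float)
        edges = np.concatenate([up_edges, body_edges, down_edges])
        row = track.interval_means(chrom, edges[:-1], edges[1:])
        if strand == "-":
            row = row[::-1]
        if skip_zeros and not np.any(row):
            n_dropped += 1
            continue
        rows.append(row)
        names.append(None if regions.names is None else regions.names[i])
    if n_dropped:
        logger.info("metagene_matrix: dropped %d regions", n_dropped)
    values = (
        np.vstack(rows) if rows else np.empty((0, n_bins), dtype=float)
    )
    return MetageneMatrix(values, names, None, n_up, n_body, n_down, n_dropped)


def metagene_profile(
    matrix: MetageneMatrix,
    group_by: Optional[Sequence[str]] = None,
) -> dict[str, MetageneProfile]:
    """Per-group per-bin mean and SEM (sample SD / sqrt(n)).

    ``group_by`` gives one label per retained matrix row; omit it to pool
    every row under the label ``"all"``.  A single-region group has SEM 0
    by convention.
    """
    if matrix.values.shape[0] == 0:
        raise ValueError("empty metagene matrix")
    if group_by is None:
        group_by = ["all"] * matrix.values.shape[0]
    group_by = list(group_by)
    if len(group_by) != matrix.values.shape[0]:
        raise ValueError("one group label per matrix row required")
    out: dict[str, MetageneProfile] = {}
    for label in sorted(set(group_by)):
        sel = matrix.values[[g == label for g in group_by]]
        n = sel.shape[0]
        mean = sel.mean(axis=0)
        if n == 1:
            logger.warning("metagene group %r has a single region; SEM set to 0", label)
            sem = np.zeros_like(mean)
        else:
            sem = sel.std(axis=0, ddof=1) / np.sqrt(n)
        out[label] = MetageneProfile(mean, sem, n)
    return out


# ---------------------------------------------------------------------------
# depth titration
# ---------------------------------------------------------------------------

def thin_track(
    track: SignalTrack,
    fraction: float,
    seed: RngLike,
    chroms: Optional[Sequence[str]] = None,
) -> SignalTrack:
    """Binomially thin an integer-count track to ``fraction`` of its depth.

    Every bin count ``k`` is replaced by a Binomial(k, fraction) draw, the
    binned equivalent of retaining each read independently.  ``chroms``
    restricts thinning to a subset of chromosomes (used for per-arm depth
    matching); others are copied unchanged.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError(f"fraction {fraction} outside [0, 1]")
    if not track.is_integer():
        raise ValueError("thin_track requires an integer-valued track")
    rng = _as_rng(seed)
    which = set(track.values) if chroms is None else set(chroms)
    new_vals = {}
    for chrom, v in track.values.items():
        if chrom in which:
            new_vals[chrom] = rng.binomial(v.astype(np.int64), fraction).astype(float)
        else:
            new_vals[chrom] = v.copy()
    return SignalTrack(track.bin_size, new_vals, track.genome)


def call_peaks_poisson(
    ip: SignalTrack,
    control: SignalTrack,
    p_threshold: float = 1e-3,
    window: int = 4,
) -> IntervalSet:
    """Sliding-window Poisson caller over binned IP vs. control counts.

    For each window of ``window`` consecutive bins the IP count is tested
    against a Poisson rate given by the library-size-scaled control window
    count, floored at the genome-wide average IP window count.  Windows
    with upper-tail p below ``p_threshold`` are merged (adjacent or
    book-ended) into peaks.  This is a deliberately minimal caller used to
    study how peak yield responds to sequencing depth.
    """
    if ip.bin_size != control.bin_size or ip.genome != control.genome:
        raise ValueError("ip and control tracks must share binning and genome")
    control_total = control.total()
    if control_total <= 0:
        raise ValueError("all-zero control track")
    ip_total = ip.total()
    scale = ip_total / control_total
    # genome-wide background rate for a window: mean IP count per bin x bins
    total_bins = sum(len(v) for v in ip.values.values())
    lam_floor = ip_total * window / total_bins if total_bins else 0.0

    peaks: list[GenomicInterval] = []
    k = 0
    for chrom in ip.genome.names:
        if chrom not in ip.values:
            continue
        v_ip = ip.values[chrom]
        v_ct = control.values[chrom]
        if len(v_ip) < window:
            continue
        kernel = np.ones(window)
        ip_win = np.convolve(v_ip, kernel, mode="valid")
        ct_win = np.convolve(v_ct, kernel, mode="valid")
        lam = np.maximum(ct_win * scale, lam_floor)
        with np.errstate(divide="ignore"):
            pvals = stats.poisson.sf(ip_win - 1, lam)
        sig = pvals < p_threshold
        if not sig.any():
            continue
        # significant window i spans bins [i, i+window)
        starts = np.flatnonzero(sig)
        cur_lo = cur_hi = None
        length = ip.genome.length_of(chrom)
        for s in starts:
            lo, hi = s, s + window
            if cur_lo is None:
                cur_lo, cur_hi = lo, hi
            elif lo <= cur_hi:  # overlapping or book-ended windows merge
                cur_hi = max(cur_hi, hi)
            else:
                k += 1
                peaks.append(
                    GenomicInterval(
                        chrom,
                        cur_lo * ip.bin_size,
                        min(cur_hi * ip.bin_size, length),
                        name=f"peak_{k}",
                    )
                )
                cur_lo, cur_hi = lo, hi
        k += 1
        peaks.append(
            GenomicInterval(
                chrom,
                cur_lo * ip.bin_size,
                min(cur_hi * ip.bin_size, length),
                name=f"peak_{k}",
            )
        )
    return IntervalSet.from_intervals(peaks, label="poisson_peaks", genome=ip.genome)


def depth_titration(
    ip: SignalTrack,
    control: SignalTrack,
    fractions: Sequence[float],
    seeds: Sequence[int],
    p_threshold: float = 1e-3,
    window: int = 4,
):
    """Peak counts per chromosome after thinning both tracks to each fraction.

    Returns a DataFrame with columns ``fraction, chrom, mean_peaks`` where
    the mean is over ``seeds`` independent thinning replicates (fraction
    1.0 bypasses thinning and equals a direct call on the input).
    """
    import pandas as pd

    rows = []
    for frac in fractions:
        if not 0.0 <= frac <= 1.0:
            raise ValueError(f"fraction {frac} outside [0, 1]")
        counts = {c: [] for c, _ in ip.genome.entries}
        for seed in seeds:
            if frac >= 1.0:
                ip_f, ct_f = ip, control
            else:
                ip_f = thin_track(ip, frac, seed)
                ct_f = thin_track(control, frac, seed + 1)
            try:
                peaks = call_peaks_poisson(ip_f, ct_f, p_threshold, window)
            except ValueError:
                # fully thinned-out control: no basis for calling
                for c in counts:
                    counts[c].append(0)
                continue
            by_chrom = peaks.by_chrom()
            for c in counts:
                counts[c].append(len(by_chrom.get(c, ())))
        for c in counts:
            rows.append(
                {"fraction": frac, "chrom": c, "mean_peaks": float(np.mean(counts[c]))}
            )
    return pd.DataFrame(rows)
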