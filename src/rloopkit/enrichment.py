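"""Permutation enrichment against chromosome-preserving shuffles, plus the
binomial density and rank-sum tests used by the downstream analyses.

The null model mirrors ``bedtools shuffle -chrom``: every interval keeps
its chromosome and width and gets a new start drawn uniformly from the
positions where it still fits.  Observed overlap counts are compared with
the mean over shuffled replicates; empirical p-values are two-sided
(double the smaller tail, with a +1 add-one correction so p is never 0)
and corrected across feature labels by Benjamini-Hochberg.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence, Union

import numpy as np
from scipy import stats

from .genome import GenomeLayout, IntervalSet

RngLike = Union[int, np.random.Generator]


def _as_rng(seed: RngLike) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass
class EnrichmentResult:
    """Observed vs. expected overlap for one feature label."""

    feature_label: str
    observed: int
    expected_mean: float
    log2_ratio: float  # NaN when observed or expected is 0
    p_perm: float
    q_bh: float
    n_perm: int


@dataclass
class DensityTestResult:
    """Peak density per chromosome and the X-vs-autosome binomial test."""

    per_chrom_density: dict[str, float]  # peaks per Mb
    x_count: int
    total: int
    p0: float  # X fraction of genome length (null success probability)
    p_binom: float


# ---------------------------------------------------------------------------
# shuffling
# ---------------------------------------------------------------------------

def shuffle_intervals(
    peaks: IntervalSet, genome: GenomeLayout, seed: RngLike
) -> IntervalSet:
    """Chromosome- and width-preserving shuffle of ``peaks``.

    Each interval is re-placed independently with a uniform start on
    ``[0, chrom_length - width]``; shuffled intervals may overlap one
    another.  An interval wider than its chromosome is an error.
    """
    rng = _as_rng(seed)
    new_starts = peaks.starts.copy()
    widths = peaks.widths
    for chrom in genome.names:
        idx = peaks.by_chrom().get(chrom)
        if idx is None:
            continue
        length = genome.length_of(chrom)
        w = widths[idx]
        if (w > length).any():
            raise ValueError(f"interval wider than chromosome {chrom!r}")
        new_starts[idx] = rng.integers(0, length - w + 1)
    return IntervalSet(
        chroms=peaks.chroms,
        starts=new_starts,
        ends=new_starts + widths,
        strands=peaks.strands,
        names=peaks.names,
        scores=peaks.scores,
        label=peaks.label,
        genome=genome,
    )


# ---------------------------------------------------------------------------
# permutation enrichment
# ---------------------------------------------------------------------------

def _empirical_two_sided_p(perm_counts: np.ndarray, observed: int) -> float:
    n = len(perm_counts)
    ge = int((perm_counts >= observed).sum())
    le = int((perm_counts <= observed).sum())
    return min(1.0, (1 + 2 * min(ge, le)) / (n + 1))


def permutation_enrichment(
    peaks: IntervalSet,
    features: Mapping[str, IntervalSet],
    genome: GenomeLayout,
    n_perm: int = 10000,
    seed: RngLike = 0,
    dedup_labels: Iterable[str] = (),
) -> list[EnrichmentResult]:
    """Observed/expected overlap enrichment of ``peaks`` in each feature set.

    One stream of ``n_perm`` chromosome-preserving shuffles is drawn and
    every feature label is counted against the *same* shuffled peak sets,
    so per-feature results share the null exactly as when shuffled peak
    files are intersected with every annotation in turn.  Labels in
    ``dedup_labels`` are counted once per distinct subject name (multi-copy
    features such as tRNAs); all others use pair counts.

    The shuffle stream is consumed chromosome-by-chromosome in genome
    order within each replicate block, so results are reproducible for a
    given seed regardless of feature labels requested.
    """
    from .intervals import count_overlaps, count_overlaps_dedup

    if len(peaks) == 0:
        raise ValueError("empty peak set")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    dedup_labels = set(dedup_labels)
    rng = _as_rng(seed)
    labels = list(features)

    observed: dict[str, int] = {}
    for lab in labels:
        fn = count_overlaps_dedup if lab in dedup_labels else count_overlaps
        observed[lab] = fn(peaks, features[lab])

    # per-chromosome peak geometry
    chrom_order = [c for c in genome.names if c in peaks.by_chrom()]
    widths = {c: peaks.widths[peaks.by_chrom()[c]] for c in chrom_order}
    for c in chrom_order:
        if (widths[c] > genome.length_of(c)).any():
            raise ValueError(f"interval wider than chromosome {c!r}")

    # per-label, per-chromosome feature columns
    pair_cols: dict[str, dict[str, tuple[np.ndarray, np.ndarray]]] = {}
    dedup_cols: dict[str, dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]] = {}
    dedup_nkeys: dict[str, int] = {}
    for lab in labels:
        f = features[lab]
        if lab in dedup_labels:
            if f.names is None or any(n is None for n in f.names):
                raise ValueError(f"dedup label {lab!r} requires subject names")
            uniq, codes = np.unique(f.names.astype(str), return_inverse=True)
            dedup_nkeys[lab] = len(uniq)
            cols = {}
            for c, idx in f.by_chrom().items():
                cols[c] = (f.starts[idx], f.ends[idx], codes[idx])
            dedup_cols[lab] = cols
        else:
            cols = {}
            for c, idx in f.by_chrom().items():
                cols[c] = (np.sort(f.starts[idx]), np.sort(f.ends[idx]))
            pair_cols[lab] = cols

    perm_counts = {lab: np.zeros(n_perm, dtype=np.int64) for lab in labels}
    chunk = max(1, min(n_perm, int(4_000_000 / max(1, len(peaks)))))
    done = 0
    while done < n_perm:
        size = min(chunk, n_perm - done)
        sl = slice(done, done + size)
        starts = {}
        ends = {}
        for c in chrom_order:
            length = genome.length_of(c)
            s = rng.integers(0, length - widths[c] + 1, size=(size, len(widths[c])))
            starts[c] = s
            ends[c] = s + widths[c]
        for lab in labels:
            if lab in dedup_labels:
                hit = np.zeros((size, dedup_nkeys[lab]), dtype=bool)
                for c in chrom_order:
                    if c not in dedup_cols[lab]:
                        continue
                    fs, fe, codes = dedup_cols[lab][c]
                    # (replicate, peak, subject) overlap tensor; peaks and
                    # subjects per chromosome are small at study scale
                    m = (starts[c][:, :, None] < fe[None, None, :]) & (
                        ends[c][:, :, None] > fs[None, None, :]
                    )
                    any_hit = m.any(axis=1)  # (replicate, subject)
                    for j, code in enumerate(codes):
                        hit[:, code] |= any_hit[:, j]
                perm_counts[lab][sl] += hit.sum(axis=1)
            else:
                for c in chrom_order:
                    if c not in pair_cols[lab]:
                        continue
                    fs, fe = pair_cols[lab][c]
                    a = np.searchsorted(fs, ends[c].ravel(), side="left")
                    b = np.searchsorted(fe, starts[c].ravel(), side="right")
                    perm_counts[lab][sl] += (
                        (a - b).reshape(size, -1).sum(axis=1)
                    )
        done += size

    pvals = []
    results: list[EnrichmentResult] = []
    for lab in labels:
        obs = observed[lab]
        exp = float(perm_counts[lab].mean())
        log2_ratio = math.log2(obs / exp) if obs > 0 and exp > 0 else float("nan")
        p = _empirical_two_sided_p(perm_counts[lab], obs)
        pvals.append(p)
        results.append(
            EnrichmentResult(lab, obs, exp, log2_ratio, p, float("nan"), n_perm)
        )
    qvals = bh_adjust(pvals)
    for r, q in zip(results, qvals):
        r.q_bh = q
    return results


def enrichment_frame(results: Sequence[EnrichmentResult]):
    """Tabulate :class:`EnrichmentResult` records as a DataFrame."""
    import pandas as pd

    return pd.DataFrame(
        {
            "feature": [r.feature_label for r in results],
            "observed": [r.observed for r in results],
            "expected": [r.expected_mean for r in results],
            "log2_ratio": [r.log2_ratio for r in results],
            "p": [r.p_perm for r in results],
            "q": [r.q_bh for r in results],
            "n_perm": [r.n_perm for r in results],
        }
    )


# ---------------------------------------------------------------------------
# multiple testing
# ---------------------------------------------------------------------------

def bh_adjust(pvals: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjustment, order-preserving."""
    p = np.asarray(list(pvals), dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if (p <= 0).any() or (p > 1).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in (0, 1]")
    from statsmodels.stats.multitest import multipletests

    _, q, _, _ = multipletests(p, method="fdr_bh")
    return [float(x) for x in q]


# ---------------------------------------------------------------------------
# chromosome density binomial test
# ---------------------------------------------------------------------------

def chromosome_density_test(
    peaks: IntervalSet, genome: GenomeLayout
) -> DensityTestResult:
    """Peaks per Mb by chromosome and the exact X-vs-autosome binomial test.

    Under the no-density-difference null every peak lands on the X with
    probability ``p0`` equal to the X share of genome length.  The
    two-sided p-value follows the minimum-likelihood convention of R's
    ``binom.test``: all outcomes at most as probable as the observed count
    are summed.
    """
    if len(peaks) == 0:
        raise ValueError("density test requires at least one peak")
    if not genome.x_chroms:
        raise ValueError("genome layout has no X-flagged chromosome")
    counts = {c: 0 for c in genome.names}
    for c, idx in peaks.by_chrom().items():
        counts[c] = len(idx)
    density = {
        c: counts[c] / (genome.length_of(c) / 1e6) for c in genome.names
    }
    x_count = sum(counts[c] for c in genome.x_chroms)
    total = len(peaks)
    p0 = genome.x_length / genome.total_length
    p_binom = float(stats.binomtest(x_count, total, p0).pvalue)
    return DensityTestResult(density, x_count, total, p0, p_binom)


# ---------------------------------------------------------------------------
# rank-sum test
# ---------------------------------------------------------------------------

def rank_sum_test(
    a: Sequence[float], b: Sequence[float]
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test of two independent samples.

    Returns ``(U_a, p)`` where ``U_a`` is the U statistic of the first
    sample with midrank tie handling.  Small tie-free problems
    (``n_a + n_b <= 12``) are solved by exact enumeration of all rank
    assignments (two-sided p doubles the smaller tail); larger or tied
    problems use the normal approximation with tie and continuity
    corrections.  Identical pooled values give p = 1 by convention.
    """
    a = np.asarray(list(a), dtype=float)
    b = np.asarray(list(b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    u_a = float(ranks[: a.size].sum() - a.size * (a.size + 1) / 2)
    if np.all(pooled == pooled[0]):
        return u_a, 1.0
    n, m = a.size, b.size
    has_ties = len(np.unique(pooled)) < n + m
    if n + m <= 12 and not has_ties:
        # exact null distribution of U by enumerating rank assignments
        total = 0
        le = 0
        ge = 0
        for comb in combinations(range(1, n + m + 1), n):
            u = sum(comb) - n * (n + 1) / 2
            total += 1
            if u <= u_a:
                le += 1
            if u >= u_a:
                ge += 1
        p = min(1.0, 2 * min(le, ge) / total)
        return u_a, p
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided", method="asymptotic", use_continuity=True
    )
    p = float(res.pvalue)
    if math.isnan(p):
        p = 1.0
    return u_a, p
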