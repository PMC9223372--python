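"""Sex-bias analyses over differential-enrichment (DE) peak classes.

Peaks carry one of three labels — nonDE (shared between sexes), FE
(female-enriched) or ME (male-enriched) — assigned upstream by a
differential-binding analysis; this module summarises those classes,
profiles them by chromosome, scans consensus motifs, and compares
per-gene quantities (expression, distance to dosage-compensation entry
sites, chromatin signal) across groups with rank-sum tests.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .enrichment import DensityTestResult, chromosome_density_test, rank_sum_test
from .genome import GenomeLayout, GenomicInterval, IntervalSet

logger = logging.getLogger(__name__)

PEAK_GROUPS = ("nonDE", "FE", "ME")
GENE_GROUPS = ("nonDE", "FE", "ME", "no_R_loop")

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}
_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


@dataclass(frozen=True)
class MotifModel:
    """A consensus motif over the IUPAC nucleotide alphabet."""

    consensus: str
    label: str

    def __post_init__(self) -> None:
        consensus = self.consensus.upper()
        object.__setattr__(self, "consensus", consensus)
        if not consensus:
            raise ValueError("empty motif consensus")
        bad = set(consensus) - set(IUPAC)
        if bad:
            raise ValueError(f"invalid IUPAC letter(s) {sorted(bad)} in {consensus!r}")

    @property
    def reverse_complement(self) -> str:
        return self.consensus.translate(_COMPLEMENT)[::-1]


@dataclass
class DEGroupTable:
    """Intervals (peaks or genes) with one DE-group label each.

    ``level`` is ``"peak"`` (labels in nonDE/FE/ME) or ``"gene"`` (labels
    may also be ``no_R_loop``).
    """

    intervals: IntervalSet
    labels: np.ndarray
    level: str = "peak"

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=object)
        if len(self.labels) != len(self.intervals):
            raise ValueError("one label per interval required")
        allowed = set(PEAK_GROUPS if self.level == "peak" else GENE_GROUPS)
        bad = set(self.labels) - allowed
        if bad:
            raise ValueError(f"invalid group label(s) {sorted(bad)} for level {self.level!r}")

    def counts(self) -> dict[str, int]:
        groups = PEAK_GROUPS if self.level == "peak" else GENE_GROUPS
        return {g: int((self.labels == g).sum()) for g in groups}

    def subset(self, group: str) -> IntervalSet:
        mask = np.flatnonzero(self.labels == group)
        return self.intervals.subset(mask, label=group)


@dataclass
class DebiasSummary:
    n_nonDE: int
    n_FE: int
    n_ME: int
    pct_sex_biased: float
    me_fe_ratio: float  # NaN sentinel when FE = 0


def summarize_de_counts(n_nonde: int, n_fe: int, n_me: int) -> DebiasSummary:
    """Sex-biased percentage and ME:FE ratio from raw class counts."""
    total = n_nonde + n_fe + n_me
    if total <= 0:
        raise ValueError("at least one peak required")
    pct = 100.0 * (n_fe + n_me) / total
    ratio = n_me / n_fe if n_fe > 0 else float("nan")
    return DebiasSummary(n_nonde, n_fe, n_me, pct, ratio)


def debias_summary(table: DEGroupTable) -> DebiasSummary:
    """Class sizes, percent sex-biased, and ME:FE ratio of a peak table."""
    c = table.counts()
    return summarize_de_counts(c["nonDE"], c["FE"], c["ME"])


def de_chromosome_profile(
    table: DEGroupTable, genome: GenomeLayout
) -> dict[str, dict]:
    """Per-group chromosome densities, X fraction, and binomial test.

    Groups with zero peaks are omitted with a warning.  Each entry holds
    the :class:`DensityTestResult` of the group's peaks plus the fraction
    of the group's peaks on the X.
    """
    out: dict[str, dict] = {}
    for group in PEAK_GROUPS:
        sub = table.subset(group)
        if len(sub) == 0:
            logger.warning("DE group %r has no peaks; omitted from profile", group)
            continue
        res = chromosome_density_test(sub, genome)
        out[group] = {
            "density": res,
            "x_fraction": res.x_count / res.total,
            "p_binom": res.p_binom,
        }
    return out


# ---------------------------------------------------------------------------
# motif scanning
# ---------------------------------------------------------------------------

def _iupac_regex(consensus: str) -> re.Pattern:
    # lookahead so overlapping occurrences are all reported
    body = "".join(
        c if len(IUPAC[c]) == 1 else "[" + IUPAC[c] + "]" for c in consensus
    )
    return re.compile(f"(?=({body}))")


def scan_motif(
    sequence: Mapping[str, str],
    motif: MotifModel,
    both_strands: bool = True,
) -> IntervalSet:
    """All occurrences of an IUPAC consensus in per-chromosome sequences.

    Overlapping matches are all reported.  With ``both_strands`` the
    reverse complement is also scanned (reported on the minus strand);
    a position matching on both strands — e.g. a palindromic consensus —
    is counted once, on the plus strand.
    """
    fwd = _iupac_regex(motif.consensus)
    hits: list[GenomicInterval] = []
    width = len(motif.consensus)
    for chrom, seq in sequence.items():
        seq = seq.upper()
        if width > len(seq):
            continue
        fwd_starts = {m.start() for m in fwd.finditer(seq)}
        for s in sorted(fwd_starts):
            hits.append(GenomicInterval(chrom, s, s + width, "+", motif.label))
        if both_strands:
            rev = _iupac_regex(motif.reverse_complement)
            for m in rev.finditer(seq):
                if m.start() not in fwd_starts:
                    hits.append(
                        GenomicInterval(chrom, m.start(), m.start() + width, "-", motif.label)
                    )
    return IntervalSet.from_intervals(hits, label=motif.label)


def motif_density_ratio(
    hits: IntervalSet, genome: GenomeLayout
) -> tuple[float, float]:
    """log2 X:autosome motif density (per Mb) and its binomial p-value.

    Under the null of equal density, each occurrence falls on the X with
    probability equal to the X share of genome length; the two-sided
    exact binomial test follows the minimum-likelihood convention.
    Returns ``(nan, nan)`` with a warning if either side has zero hits.
    """
    if len(hits) == 0:
        raise ValueError("no motif hits")
    x_hits = sum(
        len(idx) for c, idx in hits.by_chrom().items() if genome.is_x(c)
    )
    a_hits = len(hits) - x_hits
    if x_hits == 0 or a_hits == 0:
        logger.warning("motif %r has zero hits on one side; ratio undefined", hits.label)
        return float("nan"), float("nan")
    x_mb = genome.x_length / 1e6
    a_mb = genome.autosome_length / 1e6
    log2_ratio = math.log2((x_hits / x_mb) / (a_hits / a_mb))
    p0 = genome.x_length / genome.total_length
    p = float(stats.binomtest(x_hits, len(hits), p0).pvalue)
    return log2_ratio, p


# ---------------------------------------------------------------------------
# gene-level labels and group comparisons
# ---------------------------------------------------------------------------

def label_genes(
    genes: IntervalSet,
    table: DEGroupTable,
    precedence: Sequence[str] = ("FE", "ME", "nonDE"),
) -> DEGroupTable:
    """Assign each gene one DE-group label from its overlapping peaks.

    A gene overlapping peaks of several classes takes the first class in
    ``precedence`` (default FE > ME > nonDE, so the rarer sex-biased
    classes are not swallowed by the abundant shared class); genes with no
    overlapping peak are ``no_R_loop``.  Genes must be uniquely named.
    """
    if genes.names is None or any(n is None for n in genes.names):
        raise ValueError("genes must be named")
    if len(set(genes.names)) != len(genes):
        raise ValueError("gene names must be unique")
    if sorted(precedence) != sorted(PEAK_GROUPS):
        raise ValueError(f"precedence must order {PEAK_GROUPS}")
    from .intervals import pair_overlap_count

    labels = np.array(["no_R_loop"] * len(genes), dtype=object)
    for group in reversed(list(precedence)):
        sub = table.subset(group)
        cols = {
            c: (np.sort(sub.starts[idx]), np.sort(sub.ends[idx]))
            for c, idx in sub.by_chrom().items()
        }
        for chrom, idx in genes.by_chrom().items():
            if chrom not in cols:
                continue
            ss, se = cols[chrom]
            n = pair_overlap_count(genes.starts[idx], genes.ends[idx], ss, se)
            labels[idx[n > 0]] = group
    return DEGroupTable(genes, labels, level="gene")


def group_compare(
    values: Mapping[str, float],
    labels: DEGroupTable,
    pairs: Sequence[tuple[str, str]],
):
    """Rank-sum comparisons of a per-gene quantity between label pairs.

    ``values`` maps gene name to the quantity (expression, log2 distance,
    mean signal, ...).  Genes without a value are ignored; pairs with an
    empty group are skipped with a warning.  Returns a DataFrame with
    group sizes, medians, the U statistic and the two-sided p-value.
    """
    import pandas as pd

    if labels.level != "gene":
        raise ValueError("group_compare requires a gene-level table")
    by_group: dict[str, list[float]] = {}
    for name, lab in zip(labels.intervals.names, labels.labels):
        if name in values:
            by_group.setdefault(lab, []).append(float(values[name]))
    rows = []
    for ga, gb in pairs:
        a = by_group.get(ga, [])
        b = by_group.get(gb, [])
        if not a or not b:
            logger.warning("pair (%s, %s) skipped: empty group", ga, gb)
            continue
        u, p = rank_sum_test(a, b)
        rows.append(
            {
                "group_a": ga,
                "group_b": gb,
                "n_a": len(a),
                "n_b": len(b),
                "median_a": float(np.median(a)),
                "median_b": float(np.median(b)),
                "statistic": u,
                "p": p,
            }
        )
    return pd.DataFrame(rows)


def distance_to_ces(
    table: DEGroupTable,
    ces: IntervalSet,
    genome: GenomeLayout,
) -> dict[str, np.ndarray]:
    """log2(bp + 1) distance from X-linked peaks of each group to the
    nearest dosage-compensation entry site.

    The +1 offset admits overlapping peaks (distance 0) on the log scale.
    """
    from .intervals import NO_SUBJECT, nearest_distance

    out = {}
    for group in PEAK_GROUPS:
        sub = table.subset(group)
        on_x = np.flatnonzero([genome.is_x(c) for c in sub.chroms])
        if len(on_x) == 0:
            continue
        d = nearest_distance(sub.subset(on_x), ces)
        d = d[d != NO_SUBJECT]
        out[group] = np.log2(d + 1.0)
    return out


def presence_filter(calls, min_present: int = 2):
    """Genes detectably expressed in at least ``min_present`` of 4 arrays.

    ``calls`` is a gene x 4 binary DataFrame (one column per microarray
    replicate); returns the index of retained genes.
    """
    import pandas as pd

    calls = pd.DataFrame(calls)
    if calls.shape[1] != 4:
        raise ValueError(f"expected exactly 4 call columns, got {calls.shape[1]}")
    arr = calls.to_numpy()
    if not np.isin(arr, (0, 1)).all():
        raise ValueError("presence calls must be binary (0/1)")
    return calls.index[arr.sum(axis=1) >= min_present]
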