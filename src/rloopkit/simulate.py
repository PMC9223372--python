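"""Seeded generator of synthetic R-loop study data.

Produces a complete miniature of a sexed DRIP-seq experiment's inputs on a
five-arm genome
(2L, 2R, 3L, 3R, X): a chromatin-state partition, gene models with
5'UTR/CDS/intron/3'UTR structure, four peak samples (sex x strain) with
X-enriched density, nonDE/FE/ME differential-enrichment labels, DRIP-like
signal tracks (TSS-proximal on autosomes, gene-body-broad on X),
planted motif occurrences embedded in generated sequence, and expression
and presence-call tables in which peak-bearing genes are stochastically
more expressed.

Default chromosome lengths are the five major Drosophila melanogaster
arms scaled 1:100 (~235-321 kb each) so that full 10,000-iteration
permutation runs finish in seconds; pass
``chrom_lengths=REAL_CHROM_LENGTHS`` for full-scale coordinates.  All
randomness flows from a single seeded generator whose consumption order
is fixed by the generation stages documented in :func:`generate`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Mapping, Optional, Sequence, Union

import numpy as np

from .genome import GenomeLayout, GenomicInterval, IntervalSet, SignalTrack
from .intervals import pair_overlap_count
from .sexbias import DEGroupTable, IUPAC, MotifModel, label_genes

RngLike = Union[int, np.random.Generator]

#: dm6 major-arm lengths scaled 1:100 (bp)
DEFAULT_CHROM_LENGTHS: dict[str, int] = {
    "2L": 235137,
    "2R": 252869,
    "3L": 281102,
    "3R": 320793,
    "X": 235422,
}
#: full-scale dm6 major-arm lengths (bp)
REAL_CHROM_LENGTHS: dict[str, int] = {c: l * 100 for c, l in DEFAULT_CHROM_LENGTHS.items()}

STATE_LABELS = ("RED", "YELLOW", "BLUE", "GREEN", "BLACK")
SAMPLES = ("F379", "F732", "M379", "M732")


def _as_rng(seed: RngLike) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic study; defaults emulate the real data.

    ``x_density_multiplier`` is the expected X:autosome peak density
    ratio (fly DRIP data show roughly 2-fold X enrichment), ``frac_FE`` /
    ``frac_ME`` reproduce the reported DE class proportions
    (558 and 1282 of 15281 peaks), and ``me_on_x_fraction`` reflects that
    nearly half of male-enriched peaks sit on the X.
    """

    seed: int = 0
    chrom_lengths: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_CHROM_LENGTHS)
    )
    x_chroms: Sequence[str] = ("X",)
    n_genes: int = 500
    n_peaks: int = 1000
    peak_width_range: tuple[int, int] = (3, 15)
    x_density_multiplier: float = 2.0
    state_fractions: Mapping[str, float] = field(
        default_factory=lambda: {
            "RED": 0.10, "YELLOW": 0.15, "BLUE": 0.10, "GREEN": 0.15, "BLACK": 0.50,
        }
    )
    state_enrichment: Mapping[str, float] = field(
        default_factory=lambda: {
            "RED": 3.0, "YELLOW": 1.5, "BLUE": 1.5, "GREEN": 0.4, "BLACK": 0.3,
        }
    )
    mean_state_segment: int = 3000
    min_state_segment: int = 300
    frac_FE: float = 558 / 15281
    frac_ME: float = 1282 / 15281
    me_on_x_fraction: float = 0.45
    signal_noise_sd: float = 0.3
    depth_reads_per_mb: float = 2e5
    gene_length_range: tuple[int, int] = (800, 2500)
    expression_separation_sd: float = 1.0
    sex_expression_shift: float = 0.8
    motifs: Sequence[tuple[str, str]] = (
        ("GGCGAAGGAG", "GGCGAAGGAG"),
        ("CTC_repeat", "CTCCTCCTC"),
        ("CACA_repeat", "CACACACACA"),
        ("polyA", "AAAAAAAAAA"),
    )
    motif_density_per_mb: float = 200.0
    motif_x_multiplier: float = 1.4
    n_trna: int = 30
    n_trna_classes: int = 12
    trna_width: int = 70
    n_ces: int = 8
    ces_width: int = 10
    track_bin_size: int = 50
    samples: Sequence[str] = SAMPLES

    def __post_init__(self) -> None:
        if self.frac_FE + self.frac_ME >= 1:
            raise ValueError("frac_FE + frac_ME must be < 1")
        if self.frac_FE < 0 or self.frac_ME < 0:
            raise ValueError("DE fractions must be non-negative")
        if self.peak_width_range[0] < 1 or self.peak_width_range[0] > self.peak_width_range[1]:
            raise ValueError("invalid peak_width_range")
        if any(m < 0 for m in self.state_enrichment.values()):
            raise ValueError("state enrichment multipliers must be >= 0")
        if self.x_density_multiplier < 0:
            raise ValueError("x_density_multiplier must be >= 0")
        if self.signal_noise_sd < 0:
            raise ValueError("signal_noise_sd must be >= 0")
        if abs(sum(self.state_fractions.values()) - 1.0) > 1e-9:
            raise ValueError("state_fractions must sum to 1")

    def genome(self) -> GenomeLayout:
        return GenomeLayout(
            tuple(self.chrom_lengths.items()),
            x_chroms=frozenset(c for c in self.x_chroms if c in self.chrom_lengths),
        )


@dataclass
class SyntheticDataset:
    """Everything the analysis pipeline consumes, generated from one seed."""

    config: SyntheticConfig
    genome: GenomeLayout
    states: IntervalSet  # non-overlapping tiling, names = state labels
    genes: "object"  # DataFrame: name chrom start end strand tss
    gene_regions: IntervalSet
    features: dict[str, IntervalSet]  # gene/5UTR/CDS/intron/3UTR/upstream/tRNA
    peaks: dict[str, IntervalSet]  # per sample
    consensus_peaks: IntervalSet
    de_labels: DEGroupTable
    gene_labels: DEGroupTable
    tracks: dict[str, SignalTrack]
    control_track: SignalTrack
    motif_hits: dict[str, IntervalSet]
    sequence: dict[str, str]
    expression: "object"  # DataFrame genes x samples
    presence_calls: "object"  # DataFrame genes x 4 binary
    ces: IntervalSet

    def state_features(self) -> dict[str, IntervalSet]:
        """One IntervalSet per chromatin color, for enrichment analyses."""
        out = {}
        for label in STATE_LABELS:
            idx = np.flatnonzero(self.states.names == label)
            out[label] = self.states.subset(idx, label=label)
        return out


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _make_states(cfg: SyntheticConfig, genome: GenomeLayout, rng: np.random.Generator):
    """Tile every chromosome with labelled segments (exact partition)."""
    labels = list(cfg.state_fractions)
    probs = np.array([cfg.state_fractions[s] for s in labels])
    chroms, starts, ends, names = [], [], [], []
    lookup = {}
    for chrom, length in genome.entries:
        bounds = [0]
        while bounds[-1] < length:
            seg = cfg.min_state_segment + rng.exponential(
                max(1, cfg.mean_state_segment - cfg.min_state_segment)
            )
            bounds.append(min(length, bounds[-1] + int(round(seg))))
        seg_labels = rng.choice(labels, size=len(bounds) - 1, p=probs)
        for i in range(len(bounds) - 1):
            chroms.append(chrom)
            starts.append(bounds[i])
            ends.append(bounds[i + 1])
            names.append(seg_labels[i])
        lookup[chrom] = (np.asarray(bounds[1:], dtype=np.int64), seg_labels)
    states = IntervalSet(chroms, starts, ends, names=names, label="chromatin_states",
                         genome=genome)
    return states, lookup


def _make_genes(cfg: SyntheticConfig, genome: GenomeLayout, rng: np.random.Generator):
    """Non-overlapping gene models laid out with random inter-gene gaps."""
    import pandas as pd

    lengths = np.array([l for _, l in genome.entries], dtype=float)
    per_chrom = rng.multinomial(cfg.n_genes, lengths / lengths.sum())
    rows = []
    feature_rows = {k: [] for k in ("5UTR", "CDS", "intron", "3UTR", "upstream")}
    gid = 0
    lo_w, hi_w = cfg.gene_length_range
    for (chrom, length), n_c in zip(genome.entries, per_chrom):
        if n_c == 0:
            continue
        glens = rng.integers(lo_w, hi_w + 1, size=n_c).astype(np.int64)
        total = glens.sum()
        if total > 0.8 * length:  # keep >= 20% intergenic space
            glens = np.maximum(lo_w // 2, (glens * 0.8 * length / total)).astype(np.int64)
        gap_total = length - glens.sum()
        cuts = rng.dirichlet(np.ones(n_c + 1)) * gap_total
        pos = 0
        for j in range(n_c):
            pos += int(cuts[j])
            start = pos
            end = start + int(glens[j])
            pos = end
            strand = "+" if rng.random() < 0.5 else "-"
            name = f"gene_{gid:04d}"
            gid += 1
            L = end - start
            utr5 = int(round(L * rng.uniform(0.05, 0.15)))
            utr3 = int(round(L * rng.uniform(0.08, 0.20)))
            utr5 = max(20, utr5)
            utr3 = max(20, utr3)
            body = L - utr5 - utr3
            n_exons = int(rng.integers(1, 5))
            if n_exons > 1:
                intron_total = int(body * rng.uniform(0.2, 0.5))
            else:
                intron_total = 0
            exon_total = body - intron_total
            exon_parts = np.maximum(
                1, (rng.dirichlet(np.ones(n_exons)) * exon_total).astype(int)
            )
            exon_parts[-1] += exon_total - exon_parts.sum()
            if n_exons > 1:
                intron_parts = np.maximum(
                    1, (rng.dirichlet(np.ones(n_exons - 1)) * intron_total).astype(int)
                )
                intron_parts[-1] += intron_total - intron_parts.sum()
            else:
                intron_parts = np.array([], dtype=int)
            # forward-axis layout: 5'UTR, exon/intron alternation, 3'UTR;
            # mirrored for minus-strand genes so the 5'UTR is at the 3' end
            # of genomic coordinates
            segs = [("5UTR", utr5)]
            for e in range(n_exons):
                segs.append(("CDS", int(exon_parts[e])))
                if e < n_exons - 1:
                    segs.append(("intron", int(intron_parts[e])))
            segs.append(("3UTR", utr3))
            if strand == "-":
                segs = segs[::-1]
            cursor = start
            for kind, width in segs:
                if width <= 0:
                    continue
                feature_rows[kind].append((chrom, cursor, cursor + width, strand, name))
                cursor += width
            tss = start if strand == "+" else end
            up_lo = max(0, start - 500) if strand == "+" else end
            up_hi = start if strand == "+" else min(length, end + 500)
            if up_hi > up_lo:
                feature_rows["upstream"].append((chrom, up_lo, up_hi, strand, name))
            rows.append(
                {"name": name, "chrom": chrom, "start": start, "end": end,
                 "strand": strand, "tss": tss}
            )
    genes = pd.DataFrame(
        rows, columns=["name", "chrom", "start", "end", "strand", "tss"]
    )
    gene_regions = IntervalSet(
        genes["chrom"], genes["start"], genes["end"], genes["strand"],
        names=list(genes["name"]), label="genes",
    )
    features = {"gene": gene_regions}
    for kind, recs in feature_rows.items():
        features[kind] = IntervalSet(
            [r[0] for r in recs], [r[1] for r in recs], [r[2] for r in recs],
            [r[3] for r in recs], names=[r[4] for r in recs], label=kind,
        )
    return genes, gene_regions, features


def _make_trnas(cfg: SyntheticConfig, genome: GenomeLayout, rng: np.random.Generator):
    """Multi-copy tRNA genes: copies of one class share a name."""
    lengths = np.array([l for _, l in genome.entries], dtype=float)
    per_chrom = rng.multinomial(cfg.n_trna, lengths / lengths.sum())
    classes = [f"tRNA-{i:02d}" for i in range(cfg.n_trna_classes)]
    chroms, starts, names = [], [], []
    for (chrom, length), n_c in zip(genome.entries, per_chrom):
        s = rng.integers(0, length - cfg.trna_width, size=n_c)
        chroms += [chrom] * n_c
        starts += list(s)
        names += list(rng.choice(classes, size=n_c))
    starts = np.asarray(starts, dtype=np.int64)
    return IntervalSet(
        chroms, starts, starts + cfg.trna_width, names=names, label="tRNA",
        genome=genome,
    )


def _place_peaks(
    cfg: SyntheticConfig,
    genome: GenomeLayout,
    state_lookup,
    rng: np.random.Generator,
    n: int,
) -> IntervalSet:
    """State-biased, X-weighted placement of ``n`` peaks.

    The chromosome is chosen with probability proportional to length
    (times the X multiplier), then the start is rejection-sampled within
    the chromosome so local placement probability is proportional to the
    chromatin-state multiplier at the peak midpoint.  Rejection within
    the chromosome keeps per-chromosome counts exactly multinomial.
    """
    lo_w, hi_w = cfg.peak_width_range
    weights = np.array(
        [l * (cfg.x_density_multiplier if genome.is_x(c) else 1.0)
         for c, l in genome.entries]
    )
    if weights.sum() <= 0:
        raise ValueError("all chromosome weights are zero")
    per_chrom = rng.multinomial(n, weights / weights.sum())
    max_mult = max(cfg.state_enrichment.values()) or 1.0
    chroms, starts, ends = [], [], []
    for (chrom, length), n_c in zip(genome.entries, per_chrom):
        if hi_w > length:
            raise ValueError(f"peak width {hi_w} exceeds chromosome {chrom!r}")
        bounds, seg_labels = state_lookup[chrom]
        mults = np.array([cfg.state_enrichment[s] for s in seg_labels]) / max_mult
        if len(mults) == 0 or mults.max() == 0:
            mults = np.ones_like(mults) if len(mults) else np.ones(1)
        placed = 0
        while placed < n_c:
            batch = max(64, 2 * (n_c - placed))
            w = rng.integers(lo_w, hi_w + 1, size=batch)
            s = rng.integers(0, length - w + 1)
            mid = s + w // 2
            seg = np.searchsorted(bounds, mid, side="right")
            seg = np.minimum(seg, len(mults) - 1)
            keep = rng.random(batch) < mults[seg]
            w, s = w[keep], s[keep]
            take = min(len(s), n_c - placed)
            chroms += [chrom] * take
            starts += list(s[:take])
            ends += list((s + w)[:take])
            placed += take
    return IntervalSet(chroms, starts, ends, label="consensus_peaks", genome=genome)


def _assign_de_labels(
    cfg: SyntheticConfig, genome: GenomeLayout, peaks: IntervalSet,
    rng: np.random.Generator,
) -> DEGroupTable:
    n = len(peaks)
    n_fe = int(round(cfg.frac_FE * n))
    n_me = int(round(cfg.frac_ME * n))
    labels = np.array(["nonDE"] * n, dtype=object)
    on_x = np.array([genome.is_x(c) for c in peaks.chroms])
    x_pool = list(rng.permutation(np.flatnonzero(on_x)))
    a_pool = list(rng.permutation(np.flatnonzero(~on_x)))
    me_idx = []
    for _ in range(n_me):
        use_x = rng.random() < cfg.me_on_x_fraction
        pool = x_pool if (use_x and x_pool) or not a_pool else a_pool
        me_idx.append(pool.pop())
    labels[me_idx] = "ME"
    remaining = np.array(x_pool + a_pool)
    fe_idx = rng.choice(remaining, size=min(n_fe, len(remaining)), replace=False)
    labels[fe_idx] = "FE"
    return DEGroupTable(peaks, labels, level="peak")


def _sample_peaks(
    cfg: SyntheticConfig, de: DEGroupTable, rng: np.random.Generator
) -> dict[str, IntervalSet]:
    """Derive per-sample peak sets from the consensus set and its labels."""
    out = {}
    for sample in cfg.samples:
        female = sample.startswith("F")
        p_incl = {
            "nonDE": 0.95,
            "FE": 0.9 if female else 0.15,
            "ME": 0.15 if female else 0.9,
        }
        probs = np.array([p_incl[l] for l in de.labels])
        keep = np.flatnonzero(rng.random(len(probs)) < probs)
        out[sample] = de.intervals.subset(keep, label=sample)
    return out


def _make_tracks(
    cfg: SyntheticConfig,
    genome: GenomeLayout,
    genes,
    sample_peaks: Mapping[str, IntervalSet],
    expression,
    rng: np.random.Generator,
) -> tuple[dict[str, SignalTrack], SignalTrack]:
    """DRIP-like signal: TSS-proximal bumps on autosomes, broad on X."""
    b = cfg.track_bin_size
    gene_cols = {}
    for chrom, sub in genes.groupby("chrom"):
        gene_cols[chrom] = sub
    tracks = {}
    for sample in cfg.samples:
        peaks = sample_peaks[sample]
        pk_cols = {
            c: (np.sort(peaks.starts[idx]), np.sort(peaks.ends[idx]))
            for c, idx in peaks.by_chrom().items()
        }
        vals = {}
        for chrom, length in genome.entries:
            nb = -(-length // b)
            sig = np.abs(rng.normal(0.0, cfg.signal_noise_sd, size=nb))
            sub = gene_cols.get(chrom)
            if sub is not None and chrom in pk_cols:
                ss, se = pk_cols[chrom]
                gs = sub["start"].to_numpy()
                ge = sub["end"].to_numpy()
                n_hit = pair_overlap_count(gs, ge, ss, se)
                centers = (b * np.arange(nb) + b / 2.0)
                for row, hits in zip(sub.itertuples(), n_hit):
                    if hits == 0:
                        continue
                    expr = float(expression.loc[row.name_, sample]) if row.name_ in expression.index else 5.0
                    amp = max(0.3, 0.5 + 0.2 * (expr - 5.0))
                    L = row.end - row.start
                    if genome.is_x(chrom):
                        # broad gene-body elevation with a mild 3' shoulder
                        in_body = (centers >= row.start) & (centers < row.end)
                        sig[in_body] += amp * 0.8
                        center = row.end - 0.2 * L if row.strand == "+" else row.start + 0.2 * L
                        sig += 0.4 * amp * np.exp(-0.5 * ((centers - center) / (0.15 * L)) ** 2)
                    else:
                        # bump just downstream of the TSS
                        if row.strand == "+":
                            center = row.start + 0.15 * L
                        else:
                            center = row.end - 0.15 * L
                        sig += amp * np.exp(-0.5 * ((centers - center) / (0.12 * L)) ** 2)
            vals[chrom] = sig
        tracks[sample] = SignalTrack(b, vals, genome)
    # flat-ish integer control (input) track used by the demo caller
    per_bin = cfg.depth_reads_per_mb * b / 1e6
    control = SignalTrack(
        b,
        {c: rng.poisson(per_bin, size=-(-l // b)).astype(float)
         for c, l in genome.entries},
        genome,
    )
    return tracks, control


def _make_sequence_and_motifs(
    cfg: SyntheticConfig, genome: GenomeLayout, rng: np.random.Generator
):
    """Uniform background sequence with planted motif occurrences.

    Instances are placed without overlapping each other so every planted
    occurrence survives verbatim and motif scanning has exact ground
    truth; background collisions may add hits but never remove planted
    ones.  Placement density on the X is ``motif_x_multiplier``-fold the
    autosomal density.
    """
    seq_arrays = {
        c: rng.integers(0, 4, size=l).astype(np.int8) for c, l in genome.entries
    }
    occupied = {c: np.zeros(l, dtype=bool) for c, l in genome.entries}
    weights = np.array(
        [l * (cfg.motif_x_multiplier if genome.is_x(c) else 1.0)
         for c, l in genome.entries]
    )
    probs = weights / weights.sum()
    hits: dict[str, list[GenomicInterval]] = {}
    base_index = {b: i for i, b in enumerate("ACGT")}
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    n_total = int(round(cfg.motif_density_per_mb * genome.total_length / 1e6))
    for label, consensus in cfg.motifs:
        motif = MotifModel(consensus, label)
        width = len(consensus)
        per_chrom = rng.multinomial(n_total, probs)
        placed_hits: list[GenomicInterval] = []
        for (chrom, length), n_c in zip(genome.entries, per_chrom):
            occ = occupied[chrom]
            arr = seq_arrays[chrom]
            placed = 0
            attempts = 0
            while placed < n_c and attempts < 50 * n_c + 100:
                attempts += 1
                s = int(rng.integers(0, length - width + 1))
                if occ[s : s + width].any():
                    continue
                strand = "+" if rng.random() < 0.5 else "-"
                letters = [rng.choice(list(IUPAC[c])) for c in consensus]
                if strand == "-":
                    letters = [comp[c] for c in letters][::-1]
                arr[s : s + width] = [base_index[c] for c in letters]
                occ[s : s + width] = True
                placed_hits.append(GenomicInterval(chrom, s, s + width, strand, label))
                placed += 1
        hits[label] = placed_hits
    base_codes = np.frombuffer(b"ACGT", dtype=np.uint8)
    sequence = {
        c: base_codes[a].tobytes().decode("ascii") for c, a in seq_arrays.items()
    }
    motif_hits = {
        label: IntervalSet.from_intervals(h, label=label, genome=genome)
        for label, h in hits.items()
    }
    return sequence, motif_hits


def _make_expression(
    cfg: SyntheticConfig, gene_labels: DEGroupTable, rng: np.random.Generator
):
    """Gene x sample expression and gene x 4 binary presence calls."""
    import pandas as pd

    names = list(gene_labels.intervals.names)
    labels = gene_labels.labels
    base = rng.normal(5.0, 1.0, size=len(names))
    base = base + np.where(labels != "no_R_loop", cfg.expression_separation_sd, 0.0)
    data = {}
    for sample in cfg.samples:
        female = sample.startswith("F")
        shift = np.zeros(len(names))
        shift[labels == "FE"] = cfg.sex_expression_shift if female else -cfg.sex_expression_shift
        shift[labels == "ME"] = -cfg.sex_expression_shift if female else cfg.sex_expression_shift
        data[sample] = base + shift + rng.normal(0.0, 0.3, size=len(names))
    expression = pd.DataFrame(data, index=pd.Index(names, name="gene"))
    mean_expr = expression.mean(axis=1).to_numpy()
    p_present = 1.0 / (1.0 + np.exp(-(mean_expr - 5.0)))
    calls = rng.random((len(names), 4)) < p_present[:, None]
    presence = pd.DataFrame(
        calls.astype(int),
        index=pd.Index(names, name="gene"),
        columns=[f"array_{i+1}" for i in range(4)],
    )
    return expression, presence


def _make_ces(cfg: SyntheticConfig, genome: GenomeLayout, rng: np.random.Generator):
    x_names = [c for c in genome.names if genome.is_x(c)]
    chroms, starts = [], []
    for chrom in x_names:
        length = genome.length_of(chrom)
        s = rng.integers(0, length - cfg.ces_width, size=cfg.n_ces)
        chroms += [chrom] * cfg.n_ces
        starts += list(s)
    starts = np.asarray(starts, dtype=np.int64)
    return IntervalSet(
        chroms, starts, starts + cfg.ces_width,
        names=[f"CES_{i}" for i in range(len(starts))],
        label="CES", genome=genome,
    )


# ---------------------------------------------------------------------------
# top-level generation
# ---------------------------------------------------------------------------

def generate(config: Optional[SyntheticConfig] = None) -> SyntheticDataset:
    """Generate a full synthetic dataset, deterministically from the seed.

    Stages consume the single RNG stream in this fixed order: chromatin
    states, gene models, tRNAs, consensus peaks, DE labels, per-sample
    peak sets, sequence + motifs, CES, expression tables, signal tracks.
    """
    cfg = config or SyntheticConfig()
    genome = cfg.genome()
    rng = np.random.default_rng(cfg.seed)

    states, state_lookup = _make_states(cfg, genome, rng)
    genes, gene_regions, features = _make_genes(cfg, genome, rng)
    gene_regions.validate(genome)
    for fs in features.values():
        fs.validate(genome)
    features["tRNA"] = _make_trnas(cfg, genome, rng)
    consensus = _place_peaks(cfg, genome, state_lookup, rng, cfg.n_peaks)
    de_labels = _assign_de_labels(cfg, genome, consensus, rng)
    sample_peaks = _sample_peaks(cfg, de_labels, rng)
    sequence, motif_hits = _make_sequence_and_motifs(cfg, genome, rng)
    ces = _make_ces(cfg, genome, rng)
    gene_labels = label_genes(gene_regions, de_labels)
    expression, presence = _make_expression(cfg, gene_labels, rng)
    tracks, control = _make_tracks(cfg, genome, genes.rename(
        columns={"name": "name_"}), sample_peaks, expression, rng)
    return SyntheticDataset(
        config=cfg,
        genome=genome,
        states=states,
        genes=genes,
        gene_regions=gene_regions,
        features=features,
        peaks=sample_peaks,
        consensus_peaks=consensus,
        de_labels=de_labels,
        gene_labels=gene_labels,
        tracks=tracks,
        control_track=control,
        motif_hits=motif_hits,
        sequence=sequence,
        expression=expression,
        presence_calls=presence,
        ces=ces,
    )


def generate_null_peaks(
    genome: GenomeLayout,
    n: int,
    width_range: tuple[int, int] = (3, 15),
    seed: RngLike = 0,
) -> IntervalSet:
    """Peaks with uniform, length-proportional placement and no biases.

    The calibration null for the permutation and binomial tests: each
    peak picks a chromosome with probability proportional to its length
    and a uniform start where it fits.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = _as_rng(seed)
    lo_w, hi_w = width_range
    if n == 0:
        return IntervalSet([], [], [], label="null_peaks", genome=genome)
    lengths = np.array([l for _, l in genome.entries], dtype=float)
    per_chrom = rng.multinomial(n, lengths / lengths.sum())
    chroms, starts, ends = [], [], []
    for (chrom, length), n_c in zip(genome.entries, per_chrom):
        if hi_w > length:
            raise ValueError(f"peak width {hi_w} exceeds chromosome {chrom!r}")
        w = rng.integers(lo_w, hi_w + 1, size=n_c)
        s = rng.integers(0, length - w + 1)
        chroms += [chrom] * n_c
        starts += list(s)
        ends += list(s + w)
    return IntervalSet(chroms, starts, ends, label="null_peaks", genome=genome)


# ---------------------------------------------------------------------------
# depth-experiment tracks
# ---------------------------------------------------------------------------

def generate_depth_tracks(
    genome: GenomeLayout,
    seed: RngLike = 0,
    bin_size: int = 50,
    bg_per_bin: float = 10.0,
    site_density_per_mb: float = 100.0,
    x_site_multiplier: float = 2.0,
    site_amp_range: tuple[float, float] = (1.55, 2.2),
    site_width_bins: int = 4,
    x_depth_fraction: float = 0.5,
) -> tuple[SignalTrack, SignalTrack, IntervalSet]:
    """Integer-count IP/control pair emulating a male-like depth artifact.

    True enrichment sites are planted at ``x_site_multiplier``-fold density
    on the X, with moderate amplitudes so detection is depth-sensitive;
    X-chromosome coverage of both tracks is generated at
    ``x_depth_fraction`` of autosomal depth (the male X is present in one
    copy).  Returns ``(ip, control, true_sites)``.
    """
    rng = _as_rng(seed)
    ip_vals, ct_vals = {}, {}
    site_list: list[GenomicInterval] = []
    for chrom, length in genome.entries:
        nb = -(-length // bin_size)
        is_x = genome.is_x(chrom)
        depth = x_depth_fraction if is_x else 1.0
        dens = site_density_per_mb * (x_site_multiplier if is_x else 1.0)
        n_sites = rng.poisson(dens * length / 1e6)
        lam_ip = np.full(nb, bg_per_bin)
        taken = np.zeros(nb, dtype=bool)
        placed = attempts = 0
        while placed < n_sites and attempts < 50 * n_sites + 100:
            attempts += 1
            b0 = int(rng.integers(0, max(1, nb - site_width_bins)))
            if taken[b0 : b0 + site_width_bins].any():
                continue
            amp = rng.uniform(*site_amp_range)
            lam_ip[b0 : b0 + site_width_bins] = bg_per_bin * amp
            taken[b0 : b0 + site_width_bins] = True
            site_list.append(
                GenomicInterval(
                    chrom, b0 * bin_size,
                    min((b0 + site_width_bins) * bin_size, length),
                )
            )
            placed += 1
        ip_vals[chrom] = rng.poisson(lam_ip * depth).astype(float)
        ct_vals[chrom] = rng.poisson(np.full(nb, bg_per_bin) * depth).astype(float)
    ip = SignalTrack(bin_size, ip_vals, genome)
    ct = SignalTrack(bin_size, ct_vals, genome)
    sites = IntervalSet.from_intervals(site_list, label="true_sites", genome=genome)
    return ip, ct, sites


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def write_dataset(dataset: SyntheticDataset, outdir) -> None:
    """Write every component to standard text formats plus a manifest."""
    from pathlib import Path

    from . import io as rio

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    rio.write_chrom_sizes(dataset.genome, out / "genome.chrom.sizes")
    rio.write_bed(dataset.states, out / "chromatin_states.bed")
    rio.write_bed(dataset.ces, out / "ces.bed")
    rio.write_bed(dataset.consensus_peaks, out / "consensus_peaks.bed")
    for sample, peaks in dataset.peaks.items():
        rio.write_bed(peaks, out / f"peaks_{sample}.bed")
    feat_dir = out / "features"
    feat_dir.mkdir(exist_ok=True)
    for label, fs in dataset.features.items():
        rio.write_bed(fs, feat_dir / f"{label}.bed")
    for sample, track in dataset.tracks.items():
        rio.write_bedgraph(track, out / f"signal_{sample}.bedgraph")
    rio.write_bedgraph(dataset.control_track, out / "signal_input.bedgraph")
    rio.write_fasta(dataset.sequence, out / "genome.fa")
    with open(out / "motifs.txt", "w") as fh:
        for label, consensus in dataset.config.motifs:
            fh.write(f"{label}\t{consensus}\n")
    for label, hs in dataset.motif_hits.items():
        rio.write_bed(hs, feat_dir / f"motif_{label}.bed")
    dataset.expression.to_csv(out / "expression.tsv", sep="\t")
    dataset.presence_calls.to_csv(out / "presence_calls.tsv", sep="\t")
    de = dataset.de_labels.intervals.to_frame()
    de["group"] = dataset.de_labels.labels
    de.to_csv(out / "de_labels.tsv", sep="\t", index=False)
    cfg = asdict(dataset.config)
    cfg["chrom_lengths"] = dict(cfg["chrom_lengths"])
    cfg["motifs"] = [list(m) for m in cfg["motifs"]]
    with open(out / "manifest.json", "w") as fh:
        json.dump({"config": cfg, "seed": dataset.config.seed}, fh, indent=2, default=str)
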