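"""Readers and writers for chrom.sizes, BED3/BED6, bedGraph, FASTA and TSV.

The BED-family readers validate against a :class:`~rloopkit.genome.GenomeLayout`
and report parse errors with 1-based line numbers; unknown chromosomes are a
hard error rather than silently dropped, so genome/annotation mismatches
surface immediately.
"""

from __future__ import annotations

import os
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

from .genome import GenomeLayout, IntervalSet, SignalTrack

PathLike = Union[str, os.PathLike]


class ParseError(ValueError):
    """A malformed record in a text input, with file and line context."""

    def __init__(self, path: PathLike, lineno: int, message: str) -> None:
        super().__init__(f"{path}:{lineno}: {message}")
        self.path = str(path)
        self.lineno = lineno


def _data_lines(path: PathLike):
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            stripped = line.strip()
            if not stripped:
                continue
            if stripped.startswith(("#", "track", "browser")):
                continue
            yield lineno, line


def read_chrom_sizes(
    path: PathLike, x_chroms: Sequence[str] = ("X",)
) -> GenomeLayout:
    """Read a two-column whitespace-delimited ``name length`` table.

    ``x_chroms`` names present in the file are flagged X-linked.
    """
    entries: list[tuple[str, int]] = []
    seen: set[str] = set()
    for lineno, line in _data_lines(path):
        fields = line.split()
        if len(fields) < 2:
            raise ParseError(path, lineno, f"expected 2 columns, got {len(fields)}")
        name = fields[0]
        try:
            length = int(fields[1])
        except ValueError:
            raise ParseError(path, lineno, f"non-integer length {fields[1]!r}") from None
        if length <= 0:
            raise ParseError(path, lineno, f"non-positive length {length}")
        if name in seen:
            raise ParseError(path, lineno, f"duplicate chromosome {name!r}")
        seen.add(name)
        entries.append((name, length))
    if not entries:
        raise ParseError(path, 0, "no chromosomes")
    flagged = frozenset(c for c in x_chroms if c in seen)
    return GenomeLayout(tuple(entries), x_chroms=flagged)


def read_bed(
    path: PathLike, genome: GenomeLayout, label: Optional[str] = None
) -> IntervalSet:
    """Read BED3/BED6 into an :class:`IntervalSet` validated on ``genome``.

    Columns 4-6 (name, score, strand) are optional; strand ``.`` maps to
    unstranded.  ``track``/``browser``/comment lines are tolerated.
    """
    lengths = genome.lengths
    chroms: list[str] = []
    starts: list[int] = []
    ends: list[int] = []
    strands: list[str] = []
    names: list[Optional[str]] = []
    scores: list[float] = []
    for lineno, line in _data_lines(path):
        fields = line.split("\t") if "\t" in line else line.split()
        if len(fields) < 3:
            raise ParseError(path, lineno, f"expected >=3 columns, got {len(fields)}")
        chrom = fields[0]
        if chrom not in lengths:
            raise ParseError(path, lineno, f"unknown chromosome {chrom!r}")
        try:
            start, end = int(fields[1]), int(fields[2])
        except ValueError:
            raise ParseError(path, lineno, "non-integer coordinates") from None
        if start < 0:
            raise ParseError(path, lineno, f"negative start {start}")
        if start >= end:
            raise ParseError(path, lineno, f"start {start} >= end {end}")
        if end > lengths[chrom]:
            raise ParseError(
                path, lineno, f"end {end} beyond {chrom} length {lengths[chrom]}"
            )
        name = fields[3] if len(fields) > 3 and fields[3] != "." else None
        score = np.nan
        if len(fields) > 4 and fields[4] != ".":
            try:
                score = float(fields[4])
            except ValueError:
                raise ParseError(path, lineno, f"non-numeric score {fields[4]!r}") from None
        strand = fields[5] if len(fields) > 5 else "."
        if strand not in ("+", "-", "."):
            raise ParseError(path, lineno, f"invalid strand {strand!r}")
        chroms.append(chrom)
        starts.append(start)
        ends.append(end)
        strands.append(strand)
        names.append(name)
        scores.append(score)
    if label is None:
        label = Path(path).stem
    return IntervalSet(
        chroms,
        starts,
        ends,
        strands,
        names if any(n is not None for n in names) else None,
        np.array(scores) if any(np.isfinite(s) for s in scores) else None,
        label=label,
        genome=genome,
    )


def write_bed(intervals: IntervalSet, path: PathLike) -> None:
    """Write BED6 when any name/score/strand is set, else BED3."""
    bed6 = (
        intervals.names is not None
        or intervals.scores is not None
        or any(s != "." for s in intervals.strands)
    )
    with open(path, "w") as fh:
        for i in range(len(intervals)):
            row = [
                str(intervals.chroms[i]),
                str(int(intervals.starts[i])),
                str(int(intervals.ends[i])),
            ]
            if bed6:
                name = "." if intervals.names is None or intervals.names[i] is None \
                    else str(intervals.names[i])
                if intervals.scores is None or not np.isfinite(intervals.scores[i]):
                    score = "0"
                else:
                    s = float(intervals.scores[i])
                    score = str(int(s)) if s == int(s) else repr(s)
                row += [name, score, str(intervals.strands[i])]
            fh.write("\t".join(row) + "\n")


def read_bedgraph(
    path: PathLike, genome: GenomeLayout, bin_size: int
) -> SignalTrack:
    """Read bedGraph and rebin into a fixed-bin track.

    Each record's value is spread over the base pairs it covers and target
    bins take the length-weighted average of covering records (uncovered
    base pairs contribute zero).
    """
    lengths = genome.lengths
    acc = {c: np.zeros(-(-l // bin_size)) for c, l in genome.entries}
    for lineno, line in _data_lines(path):
        fields = line.split()
        if len(fields) < 4:
            raise ParseError(path, lineno, f"expected 4 columns, got {len(fields)}")
        chrom = fields[0]
        if chrom not in lengths:
            raise ParseError(path, lineno, f"unknown chromosome {chrom!r}")
        try:
            start, end = int(fields[1]), int(fields[2])
            value = float(fields[3])
        except ValueError:
            raise ParseError(path, lineno, "malformed record") from None
        if start < 0 or start >= end or end > lengths[chrom]:
            raise ParseError(path, lineno, f"bad interval {start}-{end}")
        first = start // bin_size
        last = (end - 1) // bin_size
        a = acc[chrom]
        for b in range(first, last + 1):
            lo = max(start, b * bin_size)
            hi = min(end, (b + 1) * bin_size)
            a[b] += value * (hi - lo) / bin_size
    return SignalTrack(bin_size, acc, genome)


def write_bedgraph(track: SignalTrack, path: PathLike) -> None:
    """Write one record per bin (runs of equal values are not merged)."""
    with open(path, "w") as fh:
        for chrom, length in track.genome.entries:
            if chrom not in track.values:
                continue
            vals = track.values[chrom]
            for b, v in enumerate(vals):
                start = b * track.bin_size
                end = min((b + 1) * track.bin_size, length)
                fh.write(f"{chrom}\t{start}\t{end}\t{v:g}\n")


def write_chrom_sizes(genome: GenomeLayout, path: PathLike) -> None:
    with open(path, "w") as fh:
        for chrom, length in genome.entries:
            fh.write(f"{chrom}\t{length}\n")


def read_fasta(path: PathLike) -> dict[str, str]:
    """Read a FASTA file into a ``{name: sequence}`` dict."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path: PathLike, width: int = 70) -> None:
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord
    from Bio import SeqIO

    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


def read_motifs(path: PathLike) -> list[tuple[str, str]]:
    """Read a two-column ``label consensus`` motif table (IUPAC consensus)."""
    motifs: list[tuple[str, str]] = []
    for lineno, line in _data_lines(path):
        fields = line.split()
        if len(fields) < 2:
            raise ParseError(path, lineno, f"expected 2 columns, got {len(fields)}")
        motifs.append((fields[0], fields[1].upper()))
    if not motifs:
        raise ParseError(path, 0, "no motifs")
    return motifs
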