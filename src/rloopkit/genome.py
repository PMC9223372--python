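"""Core genomic data model: genome layout, intervals, and binned signal tracks.

All coordinates are 0-based half-open (BED convention).  An interval
``[start, end)`` covers ``end - start`` base pairs; two intervals overlap
when they share at least one base pair, i.e. ``a.start < b.end`` and
``b.start < a.end``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Optional, Sequence

import numpy as np

STRANDS = ("+", "-", ".")


class GenomeMismatchError(ValueError):
    """Raised when two objects are bound to different genome layouts."""


@dataclass(frozen=True)
class GenomeLayout:
    """Ordered chromosome arms with lengths and an X/autosome flag.

    Parameters
    ----------
    entries
        Ordered ``(name, length_bp)`` pairs.  Names must be unique and
        lengths strictly positive.
    x_chroms
        Names flagged as X-linked; everything else is autosomal.  By
        default a chromosome literally named ``"X"`` is flagged when
        present; pass an explicit set to override.
    """

    entries: tuple[tuple[str, int], ...]
    x_chroms: Optional[frozenset[str]] = None

    def __post_init__(self) -> None:
        entries = tuple((str(c), int(l)) for c, l in self.entries)
        object.__setattr__(self, "entries", entries)
        if self.x_chroms is None:
            object.__setattr__(
                self,
                "x_chroms",
                frozenset({"X"} & {c for c, _ in entries}),
            )
        else:
            object.__setattr__(self, "x_chroms", frozenset(self.x_chroms))
        names = [c for c, _ in entries]
        if not names:
            raise ValueError("genome layout has no chromosomes")
        if len(set(names)) != len(names):
            dupes = sorted({c for c in names if names.count(c) > 1})
            raise ValueError(f"duplicate chromosome name(s): {dupes}")
        for c, l in entries:
            if l <= 0:
                raise ValueError(f"chromosome {c!r} has non-positive length {l}")
        unknown = self.x_chroms - set(names)
        if unknown:
            raise ValueError(f"X-flagged chromosomes not in layout: {sorted(unknown)}")

    # -- basic accessors ----------------------------------------------------
    @property
    def names(self) -> tuple[str, ...]:
        return tuple(c for c, _ in self.entries)

    @property
    def lengths(self) -> dict[str, int]:
        return dict(self.entries)

    def length_of(self, chrom: str) -> int:
        try:
            return self.lengths[chrom]
        except KeyError:
            raise KeyError(f"unknown chromosome {chrom!r}") from None

    @property
    def total_length(self) -> int:
        return sum(l for _, l in self.entries)

    def is_x(self, chrom: str) -> bool:
        return chrom in self.x_chroms

    @property
    def autosomes(self) -> tuple[str, ...]:
        return tuple(c for c in self.names if c not in self.x_chroms)

    @property
    def x_length(self) -> int:
        return sum(l for c, l in self.entries if c in self.x_chroms)

    @property
    def autosome_length(self) -> int:
        return self.total_length - self.x_length


@dataclass(frozen=True)
class GenomicInterval:
    """A single 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: Optional[str] = None
    score: Optional[float] = None

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start {self.start}")
        if self.start >= self.end:
            raise ValueError(
                f"empty or inverted interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def width(self) -> int:
        return self.end - self.start


class IntervalSet:
    """A labelled collection of intervals backed by column arrays.

    The column layout (one NumPy array per field) keeps overlap counting
    and shuffling vectorizable; iteration yields :class:`GenomicInterval`
    objects for convenience.  Interval order carries no meaning: every
    operation in this package is order-independent.
    """

    def __init__(
        self,
        chroms: Sequence[str],
        starts: Sequence[int],
        ends: Sequence[int],
        strands: Optional[Sequence[str]] = None,
        names: Optional[Sequence[Optional[str]]] = None,
        scores: Optional[Sequence[Optional[float]]] = None,
        label: str = "",
        genome: Optional[GenomeLayout] = None,
    ) -> None:
        n = len(chroms)
        self.chroms = np.asarray(chroms, dtype=object)
        self.starts = np.asarray(starts, dtype=np.int64)
        self.ends = np.asarray(ends, dtype=np.int64)
        if len(self.starts) != n or len(self.ends) != n:
            raise ValueError("column length mismatch")
        if strands is None:
            strands = ["."] * n
        self.strands = np.asarray(strands, dtype=object)
        self.names = None if names is None else np.asarray(names, dtype=object)
        self.scores = None if scores is None else np.asarray(scores, dtype=float)
        self.label = label
        self.genome = genome
        if n:
            if (self.starts < 0).any():
                raise ValueError("negative start coordinate")
            if (self.starts >= self.ends).any():
                i = int(np.argmax(self.starts >= self.ends))
                raise ValueError(
                    f"empty or inverted interval "
                    f"{self.chroms[i]}:{self.starts[i]}-{self.ends[i]}"
                )
        if genome is not None:
            self.validate(genome)
        self._by_chrom_cache: Optional[dict[str, np.ndarray]] = None

    # -- construction -------------------------------------------------------
    @classmethod
    def from_intervals(
        cls,
        intervals: Iterable[GenomicInterval],
        label: str = "",
        genome: Optional[GenomeLayout] = None,
    ) -> "IntervalSet":
        ivs = list(intervals)
        names = [iv.name for iv in ivs]
        scores = [iv.score for iv in ivs]
        return cls(
            chroms=[iv.chrom for iv in ivs],
            starts=[iv.start for iv in ivs],
            ends=[iv.end for iv in ivs],
            strands=[iv.strand for iv in ivs],
            names=names if any(n is not None for n in names) else None,
            scores=(
                np.array([np.nan if s is None else s for s in scores], dtype=float)
                if any(s is not None for s in scores)
                else None
            ),
            label=label,
            genome=genome,
        )

    # -- protocol -----------------------------------------------------------
    def __len__(self) -> int:
        return len(self.starts)

    def __iter__(self) -> Iterator[GenomicInterval]:
        for i in range(len(self)):
            yield GenomicInterval(
                chrom=self.chroms[i],
                start=int(self.starts[i]),
                end=int(self.ends[i]),
                strand=self.strands[i],
                name=None if self.names is None else self.names[i],
                score=(
                    None
                    if self.scores is None or np.isnan(self.scores[i])
                    else float(self.scores[i])
                ),
            )

    @property
    def widths(self) -> np.ndarray:
        return self.ends - self.starts

    def validate(self, genome: GenomeLayout) -> None:
        """Check every interval fits inside ``genome``; raise otherwise."""
        lengths = genome.lengths
        for i in range(len(self)):
            c = self.chroms[i]
            if c not in lengths:
                raise ValueError(f"interval on unknown chromosome {c!r}")
            if self.ends[i] > lengths[c]:
                raise ValueError(
                    f"interval {c}:{self.starts[i]}-{self.ends[i]} "
                    f"extends beyond chromosome end {lengths[c]}"
                )
        self.genome = genome

    def by_chrom(self) -> dict[str, np.ndarray]:
        """Map chromosome name -> index array of intervals on it (cached)."""
        if self._by_chrom_cache is None:
            out: dict[str, list[int]] = {}
            for i, c in enumerate(self.chroms):
                out.setdefault(c, []).append(i)
            self._by_chrom_cache = {
                c: np.asarray(ix, dtype=np.intp) for c, ix in out.items()
            }
        return self._by_chrom_cache

    def subset(self, index: np.ndarray, label: Optional[str] = None) -> "IntervalSet":
        return IntervalSet(
            chroms=self.chroms[index],
            starts=self.starts[index],
            ends=self.ends[index],
            strands=self.strands[index],
            names=None if self.names is None else self.names[index],
            scores=None if self.scores is None else self.scores[index],
            label=self.label if label is None else label,
            genome=self.genome,
        )

    def to_frame(self):
        import pandas as pd

        data = {
            "chrom": self.chroms,
            "start": self.starts,
            "end": self.ends,
            "strand": self.strands,
        }
        if self.names is not None:
            data["name"] = self.names
        if self.scores is not None:
            data["score"] = self.scores
        return pd.DataFrame(data)


class SignalTrack:
    """Fixed-bin per-chromosome numeric coverage.

    Bin ``i`` of a chromosome covers base pairs ``[i*bin_size,
    (i+1)*bin_size)``; the last bin may extend past the chromosome end but
    signal queries are clipped to the chromosome.
    """

    def __init__(
        self,
        bin_size: int,
        values: Mapping[str, np.ndarray],
        genome: GenomeLayout,
    ) -> None:
        if bin_size <= 0:
            raise ValueError("bin_size must be positive")
        self.bin_size = int(bin_size)
        self.genome = genome
        self.values: dict[str, np.ndarray] = {}
        for chrom, vals in values.items():
            length = genome.length_of(chrom)
            expected = -(-length // bin_size)  # ceil
            arr = np.asarray(vals, dtype=float)
            if len(arr) != expected:
                raise ValueError(
                    f"{chrom}: expected {expected} bins for length {length} "
                    f"at bin_size {bin_size}, got {len(arr)}"
                )
            if not np.isfinite(arr).all():
                raise ValueError(f"{chrom}: non-finite signal values")
            if (arr < 0).any():
                raise ValueError(f"{chrom}: negative signal values")
            self.values[chrom] = arr
        self._cumsum: dict[str, np.ndarray] = {}

    @classmethod
    def zeros(cls, genome: GenomeLayout, bin_size: int) -> "SignalTrack":
        vals = {
            c: np.zeros(-(-l // bin_size)) for c, l in genome.entries
        }
        return cls(bin_size, vals, genome)

    def n_bins(self, chrom: str) -> int:
        return len(self.values[chrom])

    def total(self) -> float:
        return float(sum(v.sum() for v in self.values.values()))

    def is_integer(self) -> bool:
        return all(np.allclose(v, np.round(v)) for v in self.values.values())

    def copy(self) -> "SignalTrack":
        return SignalTrack(
            self.bin_size, {c: v.copy() for c, v in self.values.items()}, self.genome
        )

    # -- exact piecewise-constant integration -------------------------------
    def _cum(self, chrom: str) -> np.ndarray:
        if chrom not in self._cumsum:
            v = self.values[chrom]
            self._cumsum[chrom] = np.concatenate(([0.0], np.cumsum(v)))
        return self._cumsum[chrom]

    def _integral(self, chrom: str, pos: np.ndarray) -> np.ndarray:
        """Integral of the per-bp signal from 0 to ``pos`` (float positions).

        The signal is piecewise constant per bin, so the cumulative is
        piecewise linear and exact for fractional positions.  Positions are
        clipped to the chromosome span; signal outside it contributes 0.
        """
        length = self.genome.length_of(chrom)
        pos = np.clip(np.asarray(pos, dtype=float), 0.0, float(length))
        cum = self._cum(chrom)
        v = self.values[chrom]
        idx = np.minimum((pos // self.bin_size).astype(np.int64), len(v) - 1)
        frac = pos - idx * self.bin_size
        return cum[idx] + v[idx] * frac / self.bin_size

    def interval_means(
        self, chrom: str, starts: np.ndarray, ends: np.ndarray
    ) -> np.ndarray:
        """Length-weighted mean signal over ``[start, end)`` windows.

        Windows may have fractional bounds (used by metagene body scaling)
        and may extend past the chromosome, in which case the out-of-genome
        part contributes zero signal but still counts toward the window
        length.
        """
        if chrom not in self.values:
            raise KeyError(f"chromosome {chrom!r} absent from track")
        starts = np.asarray(starts, dtype=float)
        ends = np.asarray(ends, dtype=float)
        width = ends - starts
        if (width <= 0).any():
            raise ValueError("window with non-positive width")
        # _integral is in units of (bin value x fraction of bin); one full bin
        # contributes its value once, i.e. bin_size bp at level value/1.
        area = self._integral(chrom, ends) - self._integral(chrom, starts)
        return area * self.bin_size / width


def require_same_genome(a: IntervalSet, b: IntervalSet) -> None:
    """Raise :class:`GenomeMismatchError` if both sets carry genomes that differ."""
    if a.genome is not None and b.genome is not None and a.genome != b.genome:
        raise GenomeMismatchError(
            "interval sets are bound to different genome layouts"
        )
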