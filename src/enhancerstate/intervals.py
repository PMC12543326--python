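"""Genomic interval types, BED/narrowPeak I/O and gap-tolerant interval algebra.

Coordinates are 0-based half-open everywhere (BED-native). Two intervals that
touch ([100,200) and [200,300)) have gap 0 and therefore overlap at any
``max_gap >= 0``. Strand is carried but ignored by all overlap operations:
histone-mark peaks are unstranded; strand matters only for promoter windows
(see :mod:`enhancerstate.annotation`).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

__all__ = [
    "GenomicInterval",
    "IntervalSet",
    "RegionParseError",
    "ChromosomeDialectError",
    "read_regions",
    "write_regions",
    "merge_intervals",
    "overlaps_with_gap",
    "subset_by_overlap",
    "check_chrom_dialects",
]

VALID_STRANDS = ("+", "-", ".")


class RegionParseError(ValueError):
    """A region file line could not be parsed; carries the 1-based line number."""

    def __init__(self, path, lineno: int, message: str):
        self.path = str(path)
        self.lineno = lineno
        super().__init__(f"{path}:{lineno}: {message}")


class ChromosomeDialectError(ValueError):
    """Inputs mix chromosome-name dialects (e.g. 'chr1' vs '1')."""


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval ``[start, end)``.

    ``summit_offset`` follows narrowPeak column-10 semantics: an offset from
    ``start`` to the point of maximal signal, or ``None`` when absent.
    """

    chrom: str
    start: int
    end: int
    name: str | None = None
    score: float | None = None
    strand: str = "."
    summit_offset: int | None = None

    def __post_init__(self):
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"strand must be one of {VALID_STRANDS}")
        if self.summit_offset is not None and not (
            0 <= self.summit_offset < self.end - self.start
        ):
            raise ValueError(
                f"summit_offset {self.summit_offset} outside interval of "
                f"length {self.end - self.start}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def summit(self) -> int:
        """Absolute summit position; midpoint when no summit is recorded."""
        if self.summit_offset is not None:
            return self.start + self.summit_offset
        return (self.start + self.end) // 2

    def sort_key(self):
        return (self.chrom, self.start, self.end)


class IntervalSet:
    """A coordinate-sorted collection of :class:`GenomicInterval`.

    Sorted by (chrom, start, end) on construction. ``genome`` optionally maps
    chromosome name to length; when given, every interval must fit.
    """

    __slots__ = ("intervals", "genome")

    def __init__(
        self,
        intervals: Iterable[GenomicInterval] = (),
        genome: Mapping[str, int] | None = None,
    ):
        ivs = sorted(intervals, key=GenomicInterval.sort_key)
        if genome is not None:
            genome = dict(genome)
            for iv in ivs:
                length = genome.get(iv.chrom)
                if length is None:
                    raise ValueError(f"interval on unknown chromosome {iv.chrom!r}")
                if iv.end > length:
                    raise ValueError(
                        f"interval {iv.chrom}:{iv.start}-{iv.end} exceeds "
                        f"chromosome length {length}"
                    )
        self.intervals: list[GenomicInterval] = ivs
        self.genome = genome

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def __getitem__(self, i):
        return self.intervals[i]

    def __eq__(self, other) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        return self.intervals == other.intervals

    def __repr__(self) -> str:
        return f"IntervalSet({len(self.intervals)} intervals)"

    def chroms(self) -> list[str]:
        out: list[str] = []
        for iv in self.intervals:
            if not out or out[-1] != iv.chrom:
                out.append(iv.chrom)
        return out

    def by_chrom(self) -> dict[str, list[GenomicInterval]]:
        out: dict[str, list[GenomicInterval]] = {}
        for iv in self.intervals:
            out.setdefault(iv.chrom, []).append(iv)
        return out

    def total_length(self) -> int:
        return sum(iv.length for iv in self.intervals)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_DIALECTS = ("bed3", "bed6", "narrowPeak", "tsv", "auto")
_TSV_HEADER = ["chrom", "start", "end", "name", "score", "strand", "summit_offset"]


def _parse_score(tok: str) -> float | None:
    if tok in (".", ""):
        return None
    return float(tok)


def read_regions(
    path,
    dialect: str = "auto",
    genome: Mapping[str, int] | None = None,
    chrom_aliases: Mapping[str, str] | None = None,
) -> IntervalSet:
    """Read a BED3/BED6/narrowPeak/TSV region file into a sorted IntervalSet.

    ``dialect='auto'`` infers the format per-file from the column count
    (3 -> bed3, 4-6 -> bed6, 10 -> narrowPeak) or a TSV header line.
    narrowPeak column 10 becomes ``summit_offset``; ``-1`` means no summit.
    Comment/track/browser lines are skipped. ``chrom_aliases`` optionally
    renames chromosomes at read time (e.g. {"1": "chr1"}).
    """
    path = Path(path)
    if dialect not in _DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {_DIALECTS}")
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if lineno == 1 and cols[: 3] == _TSV_HEADER[:3] and not cols[1].isdigit():
                continue  # TSV header
            d = dialect
            if d == "auto":
                if len(cols) == 10:
                    d = "narrowPeak"
                elif len(cols) == 3:
                    d = "bed3"
                elif 4 <= len(cols) <= 7:
                    d = "bed6"
                else:
                    raise RegionParseError(
                        path, lineno, f"cannot infer dialect from {len(cols)} columns"
                    )
            try:
                iv = _parse_line(cols, d)
            except RegionParseError:
                raise
            except (ValueError, IndexError) as exc:
                raise RegionParseError(path, lineno, str(exc)) from exc
            if chrom_aliases and iv.chrom in chrom_aliases:
                iv = replace(iv, chrom=chrom_aliases[iv.chrom])
            intervals.append(iv)
    return IntervalSet(intervals, genome=genome)


def _parse_line(cols: Sequence[str], dialect: str) -> GenomicInterval:
    minimum = {"bed3": 3, "bed6": 4, "narrowPeak": 10, "tsv": 3}[dialect]
    if len(cols) < minimum:
        raise ValueError(f"expected >= {minimum} columns for {dialect}, got {len(cols)}")
    chrom = cols[0]
    start, end = int(cols[1]), int(cols[2])
    if start >= end:
        raise ValueError(f"start {start} >= end {end}")
    name = score = None
    strand = "."
    summit = None
    if dialect != "bed3":
        if len(cols) > 3 and cols[3] not in (".", ""):
            name = cols[3]
        if len(cols) > 4:
            score = _parse_score(cols[4])
        if len(cols) > 5 and cols[5] in VALID_STRANDS:
            strand = cols[5]
    if dialect == "narrowPeak":
        peak = int(cols[9])
        if peak != -1:
            summit = peak
    elif dialect == "tsv" and len(cols) > 6 and cols[6] not in (".", ""):
        summit = int(cols[6])
    return GenomicInterval(chrom, start, end, name, score, strand, summit)


def write_regions(iset: IntervalSet, path, dialect: str = "bed6") -> None:
    """Write a sorted IntervalSet as BED6, narrowPeak or a headered TSV.

    Output is deterministic (sorted, LF endings). Scores round-trip exactly
    via ``repr``; missing fields are written as ``.`` (``-1`` for a missing
    narrowPeak summit).
    """
    if dialect not in ("bed6", "narrowPeak", "tsv"):
        raise ValueError(f"unsupported output dialect {dialect!r}")
    with open(path, "w", newline="\n") as fh:
        if dialect == "tsv":
            fh.write("\t".join(_TSV_HEADER) + "\n")
        for iv in iset:
            name = iv.name if iv.name is not None else "."
            score = repr(iv.score) if iv.score is not None else "."
            if dialect == "bed6":
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score}\t{iv.strand}\n"
                )
            elif dialect == "narrowPeak":
                peak = iv.summit_offset if iv.summit_offset is not None else -1
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score}\t{iv.strand}"
                    f"\t0\t-1\t-1\t{peak}\n"
                )
            else:
                summit = iv.summit_offset if iv.summit_offset is not None else "."
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score}\t{iv.strand}"
                    f"\t{summit}\n"
                )


# ---------------------------------------------------------------------------
# Algebra
# ---------------------------------------------------------------------------


def gap_between(a: GenomicInterval, b: GenomicInterval) -> int | None:
    """Gap in bp between two intervals; 0 if they touch or overlap, None if
    they lie on different chromosomes."""
    if a.chrom != b.chrom:
        return None
    return max(a.start - b.end, b.start - a.end, 0)


def overlaps_with_gap(a: GenomicInterval, b: GenomicInterval, max_gap: int = 0) -> bool:
    """True iff a and b are on the same chromosome within ``max_gap`` bp.

    Touching or overlapping intervals have gap 0; otherwise the gap is
    ``later.start - earlier.end``.
    """
    if max_gap < 0:
        raise ValueError("max_gap must be non-negative")
    g = gap_between(a, b)
    return g is not None and g <= max_gap


def merge_intervals(iset: IntervalSet, max_gap: int = 0) -> IntervalSet:
    """Merge intervals whose gap is <= ``max_gap``.

    Output intervals on each chromosome are pairwise separated by more than
    ``max_gap`` and cover the union of the input. Names/scores/summits are
    dropped (a merged region has no single summit).
    """
    if max_gap < 0:
        raise ValueError("max_gap must be non-negative")
    out: list[GenomicInterval] = []
    cur_chrom: str | None = None
    cur_start = cur_end = 0
    for iv in iset:
        if iv.chrom == cur_chrom and iv.start - cur_end <= max_gap:
            cur_end = max(cur_end, iv.end)
        else:
            if cur_chrom is not None:
                out.append(GenomicInterval(cur_chrom, cur_start, cur_end))
            cur_chrom, cur_start, cur_end = iv.chrom, iv.start, iv.end
    if cur_chrom is not None:
        out.append(GenomicInterval(cur_chrom, cur_start, cur_end))
    return IntervalSet(out, genome=iset.genome)


class _ChromIndex:
    """Per-chromosome arrays (starts sorted + prefix-max of ends) for
    searchsorted overlap queries."""

    def __init__(self, iset: IntervalSet):
        self.data: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom, ivs in iset.by_chrom().items():
            starts = np.fromiter((iv.start for iv in ivs), dtype=np.int64, count=len(ivs))
            ends = np.fromiter((iv.end for iv in ivs), dtype=np.int64, count=len(ivs))
            # ivs sorted by start already (set sorted by (chrom,start,end))
            self.data[chrom] = (starts, np.maximum.accumulate(ends))

    def any_within(self, iv: GenomicInterval, max_gap: int) -> bool:
        entry = self.data.get(iv.chrom)
        if entry is None:
            return False
        starts, endmax = entry
        # candidates: subject.start <= iv.end + max_gap
        k = int(np.searchsorted(starts, iv.end + max_gap, side="right"))
        if k == 0:
            return False
        # among them need max subject.end >= iv.start - max_gap
        return bool(endmax[k - 1] >= iv.start - max_gap)

    def min_gap(self, iv: GenomicInterval) -> int | None:
        """Smallest gap from ``iv`` to any indexed interval on its chromosome."""
        entry = self.data.get(iv.chrom)
        if entry is None:
            return None
        starts, endmax = entry
        best: int | None = None
        k = int(np.searchsorted(starts, iv.end, side="right"))
        if k > 0:
            best = max(int(iv.start - endmax[k - 1]), 0)
        if k < len(starts):
            right = int(starts[k] - iv.end)
            best = right if best is None else min(best, right)
        return best


def subset_by_overlap(
    query: IntervalSet,
    subject: IntervalSet,
    max_gap: int = 0,
    invert: bool = False,
) -> IntervalSet:
    """Query intervals having (or, with ``invert``, lacking) >= 1 subject
    interval within ``max_gap`` bp. Query intervals are returned unmodified,
    in order."""
    if max_gap < 0:
        raise ValueError("max_gap must be non-negative")
    idx = _ChromIndex(subject)
    kept = [
        iv for iv in query if idx.any_within(iv, max_gap) != invert
    ]
    return IntervalSet(kept, genome=query.genome)


def _dialect_flag(chroms: Iterable[str]) -> bool | None:
    flags = {c.lower().startswith("chr") for c in chroms}
    if len(flags) > 1:
        return None  # internally mixed
    return flags.pop() if flags else True


def check_chrom_dialects(named_sets: Mapping[str, IntervalSet]) -> None:
    """Fail fast when input files mix 'chr1'-style and '1'-style names.

    Raises :class:`ChromosomeDialectError` naming the offending files; the
    classic silent failure mode of cross-file interval work is an empty
    intersection from mismatched dialects.
    """
    flags: dict[str, bool | None] = {}
    for name, iset in named_sets.items():
        chroms = iset.chroms()
        if chroms:
            flags[name] = _dialect_flag(chroms)
    mixed = [n for n, f in flags.items() if f is None]
    if mixed:
        raise ChromosomeDialectError(
            f"chromosome naming mixed within file(s): {', '.join(sorted(mixed))}"
        )
    if len(set(flags.values())) > 1:
        detail = ", ".join(f"{n}={'chr*' if f else 'bare'}" for n, f in sorted(flags.items()))
        raise ChromosomeDialectError(
            f"chromosome-name dialects disagree across inputs: {detail}"
        )
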