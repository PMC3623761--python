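"""Genomic interval arithmetic and BED-format input/output.

All coordinates are 0-based half-open (BED convention) throughout the
package; 1-based formats must be converted at the reader boundary.
Strand is carried but ignored by all counting code (the histone-mark
reads are effectively unstranded after mapping).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np

__all__ = [
    "GenomicInterval",
    "merge_intervals",
    "read_bed",
    "write_bed",
    "ReadSet",
    "read_alignment_bed",
]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic region ``[start, end)``."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    id: str | None = None

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("interval has empty chromosome name")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


def _sort_key(iv: GenomicInterval) -> tuple[str, int, int]:
    return (iv.chrom, iv.start, iv.end)


def merge_intervals(
    intervals: Iterable[GenomicInterval],
    merge_abutting: bool = True,
) -> list[GenomicInterval]:
    """Merge overlapping intervals into a sorted, disjoint list.

    With ``merge_abutting`` (the default) intervals that touch at a shared
    half-open boundary ([a,b) and [b,c)) are also merged; this is harmless
    for read counting and keeps promoter sets disjoint.  The union of
    covered bases is preserved either way.
    """
    ivs = sorted(intervals, key=_sort_key)
    out: list[GenomicInterval] = []
    for iv in ivs:
        if out and out[-1].chrom == iv.chrom and (
            iv.start < out[-1].end
            or (merge_abutting and iv.start == out[-1].end)
        ):
            prev = out[-1]
            if iv.end > prev.end:
                out[-1] = GenomicInterval(prev.chrom, prev.start, iv.end)
        else:
            out.append(GenomicInterval(iv.chrom, iv.start, iv.end))
    return out


# ---------------------------------------------------------------------------
# BED reader / writer
# ---------------------------------------------------------------------------

_HEADER_PREFIXES = ("track", "browser", "#")


def _parse_bed_line(line: str, lineno: int) -> GenomicInterval:
    fields = line.rstrip("\n").split("\t")
    if len(fields) < 3:
        raise ValueError(f"malformed BED record at line {lineno}: {line!r}")
    try:
        start, end = int(fields[1]), int(fields[2])
    except ValueError as exc:
        raise ValueError(f"malformed BED record at line {lineno}: {line!r}") from exc
    name = fields[3] if len(fields) > 3 and fields[3] not in (".", "") else None
    strand = fields[5] if len(fields) > 5 and fields[5] in "+-" else "."
    try:
        return GenomicInterval(fields[0], start, end, strand, name)
    except ValueError as exc:
        raise ValueError(f"invalid interval at line {lineno}: {exc}") from exc


def read_bed(path) -> list[GenomicInterval]:
    """Read a BED3/BED6 file, skipping track/browser/comment lines."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(_HEADER_PREFIXES):
                continue
            out.append(_parse_bed_line(line, lineno))
    return out


def write_bed(path, intervals: Iterable[GenomicInterval], score=None) -> None:
    """Write intervals as BED6 in deterministic (chrom, start) order."""
    ivs = sorted(intervals, key=_sort_key)
    with open(path, "w") as fh:
        for iv in ivs:
            name = iv.id if iv.id is not None else "."
            sc = "0" if score is None else str(score)
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{sc}\t{iv.strand}\n")


# ---------------------------------------------------------------------------
# ReadSet: the mapped-read collection of one sample
# ---------------------------------------------------------------------------


@dataclass
class ReadSet:
    """Mapped single-end reads of one sample.

    Reads all share one mapped length (36 bp in the emulated libraries)
    and are held per chromosome as sorted arrays of start positions,
    which keeps genome-scale counting vectorized.
    """

    starts: dict[str, np.ndarray] = field(default_factory=dict)
    read_length: int = 36
    sample_id: str = ""

    def __post_init__(self) -> None:
        for chrom, arr in self.starts.items():
            a = np.asarray(arr, dtype=np.int64)
            if a.size and not np.all(a[1:] >= a[:-1]):
                a = np.sort(a)
            self.starts[chrom] = a

    @property
    def total(self) -> int:
        return int(sum(a.size for a in self.starts.values()))

    def chromosomes(self) -> list[str]:
        return sorted(self.starts)

    def intervals(self) -> Iterator[GenomicInterval]:
        L = self.read_length
        for chrom in self.chromosomes():
            for s in self.starts[chrom]:
                yield GenomicInterval(chrom, int(s), int(s) + L)

    @classmethod
    def from_intervals(
        cls, intervals: Iterable[GenomicInterval], read_length: int = 36,
        sample_id: str = "",
    ) -> "ReadSet":
        by_chrom: dict[str, list[int]] = {}
        for iv in intervals:
            by_chrom.setdefault(iv.chrom, []).append(iv.start)
        starts = {c: np.sort(np.asarray(v, dtype=np.int64)) for c, v in by_chrom.items()}
        return cls(starts=starts, read_length=read_length, sample_id=sample_id)

    def write_bed(self, path) -> None:
        L = self.read_length
        with open(path, "w") as fh:
            for chrom in self.chromosomes():
                for s in self.starts[chrom]:
                    fh.write(f"{chrom}\t{s}\t{s + L}\n")


def read_alignment_bed(path, read_length: int | None = None, sample_id: str = "") -> ReadSet:
    """Load one sample's mapped reads from BED into a :class:`ReadSet`.

    If ``read_length`` is not given it is taken from the first record;
    records of other lengths are accepted (their start is kept) with a
    warning, since counting treats each read as a fixed-length interval.
    """
    ivs = read_bed(path)
    if not ivs:
        warnings.warn(f"no reads in {path}")
        return ReadSet(starts={}, read_length=read_length or 36, sample_id=sample_id)
    if read_length is None:
        read_length = len(ivs[0])
    if any(len(iv) != read_length for iv in ivs):
        warnings.warn(f"{path}: variable read lengths; treating all as {read_length} bp")
    return ReadSet.from_intervals(ivs, read_length=read_length, sample_id=sample_id)
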