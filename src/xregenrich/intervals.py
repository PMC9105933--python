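"""Genomic interval containers, BED I/O and overlap counting.

All coordinates are 0-based, half-open (BED-native): an interval ``[start,
end)`` covers ``end - start`` bases and two intervals overlap iff they share
at least one base, i.e. ``a.start < b.end and b.start < a.end``.  Book-ended
intervals (``[100,200)`` next to ``[200,300)``) therefore do *not* overlap
for counting purposes, but are unioned by :func:`merge_intervals`, which is
the convention wanted when assembling disjoint query regions.

Any 1-based input convention (e.g. association-study SNP positions) must be
converted at its reader boundary; nothing in this module shifts coordinates.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence, Union

import numpy as np

__all__ = [
    "GenomicInterval",
    "RegionSet",
    "AnnotationTrack",
    "OverlapCount",
    "BedParseError",
    "ELEMENT_CLASSES",
    "read_bed",
    "read_bed_regions",
    "write_bed",
    "merge_intervals",
    "count_overlapping_elements",
]

#: Recognised annotation element classes.
ELEMENT_CLASSES = frozenset({"lncRNA", "circRNA", "miRNA", "superenhancer", "other"})


class BedParseError(ValueError):
    """A malformed BED line; carries the offending path and line number."""

    def __init__(self, path: str, line_no: int, message: str):
        super().__init__(f"{path}:{line_no}: {message}")
        self.path = path
        self.line_no = line_no


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic interval ``chrom:[start, end)``."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (isinstance(self.start, (int, np.integer)) and isinstance(self.end, (int, np.integer))):
            raise TypeError("start and end must be integers")
        object.__setattr__(self, "start", int(self.start))
        object.__setattr__(self, "end", int(self.end))
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(f"end must exceed start, got [{self.start}, {self.end})")

    @property
    def width(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True iff the two intervals share at least one base."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class RegionSet:
    """An ordered, named collection of genomic intervals.

    Intervals are stored sorted by ``(chrom, start, end)`` regardless of the
    order supplied; the container is immutable and iterable.
    """

    name: str
    intervals: tuple[GenomicInterval, ...] = ()

    def __post_init__(self) -> None:
        ordered = tuple(sorted(self.intervals))
        object.__setattr__(self, "intervals", ordered)

    @property
    def n(self) -> int:
        return len(self.intervals)

    @property
    def widths(self) -> tuple[int, ...]:
        return tuple(iv.width for iv in self.intervals)

    @property
    def total_width(self) -> int:
        return sum(self.widths)

    @property
    def chroms(self) -> tuple[str, ...]:
        return tuple(dict.fromkeys(iv.chrom for iv in self.intervals))

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def __getitem__(self, i):
        return self.intervals[i]


@dataclass(frozen=True)
class AnnotationTrack:
    """Identified annotation elements of one class (lncRNA, circRNA, ...).

    ``elements`` is a sequence of ``(element_id, interval)`` pairs; ids must
    be unique within the track.  Two coordinate-identical elements with
    distinct ids are distinct records (annotation databases contain them) and
    count separately in overlap statistics.
    """

    name: str
    element_class: str
    elements: tuple[tuple[str, GenomicInterval], ...] = ()

    def __post_init__(self) -> None:
        if self.element_class not in ELEMENT_CLASSES:
            raise ValueError(
                f"element_class must be one of {sorted(ELEMENT_CLASSES)}, "
                f"got {self.element_class!r}"
            )
        elems = tuple((str(eid), iv) for eid, iv in self.elements)
        ids = [eid for eid, _ in elems]
        if len(set(ids)) != len(ids):
            dupes = sorted({x for x in ids if ids.count(x) > 1})
            raise ValueError(f"duplicate element ids in track {self.name!r}: {dupes[:5]}")
        object.__setattr__(self, "elements", elems)

    @property
    def n(self) -> int:
        return len(self.elements)

    def __len__(self) -> int:
        return len(self.elements)

    def __iter__(self):
        return iter(self.elements)


@dataclass(frozen=True)
class OverlapCount:
    """Number (and identities) of track elements hitting a region set."""

    track_name: str
    count: int
    element_ids: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "element_ids", frozenset(self.element_ids))
        if self.count != len(self.element_ids):
            raise ValueError("count must equal |element_ids|")


# ---------------------------------------------------------------------------
# BED I/O
# ---------------------------------------------------------------------------

_SKIP_PREFIXES = ("#", "track", "browser")


def _iter_bed_lines(path) -> Iterator[tuple[int, list[str]]]:
    with open(path, "r", newline=None) as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.rstrip("\r\n")
            if not line.strip():
                continue
            if line.startswith(_SKIP_PREFIXES):
                continue
            yield line_no, line.split()


def _parse_bed_fields(path, line_no: int, fields: list[str]) -> tuple[GenomicInterval, str | None]:
    if len(fields) < 3:
        raise BedParseError(str(path), line_no, f"expected >= 3 columns, got {len(fields)}")
    chrom = fields[0]
    try:
        start, end = int(fields[1]), int(fields[2])
    except ValueError:
        raise BedParseError(
            str(path), line_no, f"non-integer coordinates {fields[1]!r}, {fields[2]!r}"
        ) from None
    if start < 0 or start >= end:
        raise BedParseError(str(path), line_no, f"invalid interval [{start}, {end})")
    name = fields[3] if len(fields) >= 4 else None
    return GenomicInterval(chrom, start, end), name


def read_bed(path, track_name: str, element_class: str = "other") -> AnnotationTrack:
    """Read a BED3/BED4 file into an :class:`AnnotationTrack`.

    A missing name column synthesizes the element id as ``chrom:start-end``;
    ``track``/``browser`` header lines, ``#`` comments and blank lines are
    skipped; LF and CRLF both work.  Malformed lines raise
    :class:`BedParseError` naming the line number.
    """
    elements = []
    for line_no, fields in _iter_bed_lines(path):
        iv, name = _parse_bed_fields(path, line_no, fields)
        if name is None:
            name = f"{iv.chrom}:{iv.start}-{iv.end}"
        elements.append((name, iv))
    return AnnotationTrack(track_name, element_class, tuple(elements))


def read_bed_regions(path, name: str) -> RegionSet:
    """Read a BED3/BED4 file as a :class:`RegionSet` (names ignored)."""
    intervals = []
    for line_no, fields in _iter_bed_lines(path):
        iv, _ = _parse_bed_fields(path, line_no, fields)
        intervals.append(iv)
    return RegionSet(name, tuple(intervals))


def write_bed(obj: Union[RegionSet, AnnotationTrack], path) -> None:
    """Write a region set or track as sorted, tab-separated BED4 lines.

    Region-set intervals get sequential synthetic names ``<set>_<i>``; track
    elements keep their ids.  Every line is newline-terminated.
    """
    if isinstance(obj, RegionSet):
        rows = [
            (iv.chrom, iv.start, iv.end, f"{obj.name}_{i + 1:04d}")
            for i, iv in enumerate(obj.intervals)
        ]
    elif isinstance(obj, AnnotationTrack):
        rows = sorted(
            (iv.chrom, iv.start, iv.end, eid) for eid, iv in obj.elements
        )
    else:
        raise TypeError(f"cannot write {type(obj).__name__} as BED")
    with open(path, "w") as fh:
        for chrom, start, end, name in rows:
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\n")


# ---------------------------------------------------------------------------
# Merging and overlap counting
# ---------------------------------------------------------------------------

def merge_intervals(regions: RegionSet, merge_gap: int = 0) -> RegionSet:
    """Union overlapping or book-ended intervals per chromosome.

    Intervals separated by at most ``merge_gap`` bases are bridged into one;
    the default 0 merges only on overlap or book-end (``end == start``).
    Idempotent; the covered-base count of already-disjoint input is invariant.
    """
    if merge_gap < 0:
        raise ValueError("merge_gap must be >= 0")
    merged: list[GenomicInterval] = []
    cur: GenomicInterval | None = None
    for iv in regions.intervals:  # already sorted by (chrom, start, end)
        if cur is not None and iv.chrom == cur.chrom and iv.start <= cur.end + merge_gap:
            if iv.end > cur.end:
                cur = GenomicInterval(cur.chrom, cur.start, iv.end)
            continue
        if cur is not None:
            merged.append(cur)
        cur = iv
    if cur is not None:
        merged.append(cur)
    return RegionSet(regions.name, tuple(merged))


def _overlap_mask(
    el_starts: np.ndarray,
    el_ends: np.ndarray,
    reg_starts: np.ndarray,
    reg_ends: np.ndarray,
) -> np.ndarray:
    """Boolean mask of elements sharing >= 1 base with a *disjoint, sorted*
    region array.

    A sorted-array interval index: among regions with ``start < el_end``
    (prefix found by searchsorted) the largest end is that of the last one,
    because disjoint sorted regions have increasing ends; the element hits
    iff that end exceeds its start.
    """
    idx = np.searchsorted(reg_starts, el_ends, side="left")
    prev_end = np.where(idx > 0, reg_ends[np.maximum(idx - 1, 0)], -1)
    return prev_end > el_starts


def count_overlapping_elements(track: AnnotationTrack, regions: RegionSet) -> OverlapCount:
    """Count track elements partially or totally overlapping the regions.

    An element counts if it shares at least one base with at least one query
    region, and counts once no matter how many regions it touches (ids are
    deduplicated).  Elements on chromosomes absent from the region set never
    count.
    """
    merged = merge_intervals(regions)
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom in merged.chroms:
        ivs = [iv for iv in merged if iv.chrom == chrom]
        by_chrom[chrom] = (
            np.fromiter((iv.start for iv in ivs), dtype=np.int64),
            np.fromiter((iv.end for iv in ivs), dtype=np.int64),
        )
    hit_ids: set[str] = set()
    # group elements by chromosome once, then vectorize per group
    groups: dict[str, list[tuple[str, GenomicInterval]]] = {}
    for eid, iv in track.elements:
        groups.setdefault(iv.chrom, []).append((eid, iv))
    for chrom, elems in groups.items():
        if chrom not in by_chrom:
            continue
        reg_starts, reg_ends = by_chrom[chrom]
        el_starts = np.fromiter((iv.start for _, iv in elems), dtype=np.int64)
        el_ends = np.fromiter((iv.end for _, iv in elems), dtype=np.int64)
        mask = _overlap_mask(el_starts, el_ends, reg_starts, reg_ends)
        hit_ids.update(eid for (eid, _), hit in zip(elems, mask) if hit)
    return OverlapCount(track.name, len(hit_ids), frozenset(hit_ids))
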