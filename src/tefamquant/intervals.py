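"""1-based fully-closed genomic intervals and a small overlap index.

All coordinates in this package follow the GFF3 convention (1-based,
both ends inclusive).  Conversions to/from the half-open 0-based SAM
convention happen only at alignment-file boundaries.
"""
from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from typing import Any, Iterable, Iterator

STRANDS = ("+", "-", ".")


@dataclass(frozen=True)
class GenomicInterval:
    """A 1-based, fully-closed interval on a named sequence."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 1:
            raise ValueError(f"start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValueError(f"end ({self.end}) < start ({self.start})")
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.end
            and other.start <= self.end
        )

    def contains(self, other: "GenomicInterval") -> bool:
        """Containment of spans (not necessarily proper)."""
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def intersection(self, other: "GenomicInterval") -> "GenomicInterval | None":
        if not self.overlaps(other):
            return None
        return GenomicInterval(
            self.chrom, max(self.start, other.start), min(self.end, other.end), self.strand
        )


def merge_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Merge overlapping or bookended intervals (per chromosome) into a
    sorted, disjoint list."""
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    out: list[GenomicInterval] = []
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom], key=lambda i: (i.start, i.end))
        cur_s, cur_e = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start <= cur_e + 1:
                cur_e = max(cur_e, iv.end)
            else:
                out.append(GenomicInterval(chrom, cur_s, cur_e))
                cur_s, cur_e = iv.start, iv.end
        out.append(GenomicInterval(chrom, cur_s, cur_e))
    return out


def subtract_interval(
    iv: GenomicInterval, others: Iterable[GenomicInterval]
) -> list[GenomicInterval]:
    """Return ``iv`` minus the union of ``others`` as sorted pieces."""
    pieces = [(iv.start, iv.end)]
    for o in others:
        if o.chrom != iv.chrom:
            continue
        nxt: list[tuple[int, int]] = []
        for s, e in pieces:
            if o.end < s or o.start > e:
                nxt.append((s, e))
                continue
            if o.start > s:
                nxt.append((s, o.start - 1))
            if o.end < e:
                nxt.append((o.end + 1, e))
        pieces = nxt
        if not pieces:
            break
    return [GenomicInterval(iv.chrom, s, e, iv.strand) for s, e in sorted(pieces)]


class IntervalIndex:
    """Static per-chromosome interval index answering 1-bp-overlap queries.

    Intervals are stored sorted by start with a running maximum of ends so
    that a stabbing/range query costs O(log n + hits) in the typical case.
    """

    def __init__(self) -> None:
        self._pending: dict[str, list[tuple[int, int, Any]]] = {}
        self._built: dict[str, tuple[list[int], list[tuple[int, int, Any]], list[int]]] = {}

    def add(self, iv: GenomicInterval, payload: Any) -> None:
        self._pending.setdefault(iv.chrom, []).append((iv.start, iv.end, payload))
        self._built.pop(iv.chrom, None)

    def _build(self, chrom: str) -> tuple[list[int], list[tuple[int, int, Any]], list[int]]:
        built = self._built.get(chrom)
        if built is None:
            entries = sorted(self._pending.get(chrom, ()), key=lambda t: (t[0], t[1]))
            starts = [s for s, _, _ in entries]
            maxend: list[int] = []
            running = 0
            for _, e, _ in entries:
                running = max(running, e)
                maxend.append(running)
            built = (starts, entries, maxend)
            self._built[chrom] = built
        return built

    def query(self, iv: GenomicInterval) -> list[Any]:
        """Payloads of all intervals overlapping ``iv`` by >= 1 bp."""
        starts, entries, maxend = self._build(iv.chrom)
        hi = bisect.bisect_right(starts, iv.end)
        hits = []
        i = hi - 1
        while i >= 0 and maxend[i] >= iv.start:
            s, e, payload = entries[i]
            if e >= iv.start:
                hits.append(payload)
            i -= 1
        hits.reverse()
        return hits

    def __iter__(self) -> Iterator[tuple[GenomicInterval, Any]]:
        for chrom in sorted(self._pending):
            for s, e, payload in sorted(self._pending[chrom]):
                yield GenomicInterval(chrom, s, e), payload
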