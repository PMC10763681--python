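"""Genomic interval model, BED-family readers, and a point-query (stab) index.

Regional regulatory evidence (DNase I hotspots, histone-mark broadPeaks,
TF motif hits, enhancer-contact regions, chromatin states, sgRNA regions,
gene bodies) arrives as BED3+ / ENCODE broadPeak tracks.  All interval files
follow the BED convention: 0-based, half-open ``[start, end)``.  Variant
positions are 1-based (dbSNP/VCF convention); callers test a variant at
1-based position P with a stab at ``pos0 = P - 1``.

Chromosome names are matched as exact strings.  An optional ``normalize_chr``
flag on the readers strips a leading ``"chr"`` prefix at load time; nothing
is normalized silently.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from intervaltree import IntervalTree

__all__ = ["GenomicInterval", "IntervalIndex", "read_bed", "build_index", "stab"]


class BedFormatError(ValueError):
    """A malformed line in a BED/broadPeak file (names file and line number)."""


@dataclass(frozen=True)
class GenomicInterval:
    """One feature from a BED3+/broadPeak track, half-open coordinates.

    ``extra`` keeps every column beyond the fourth verbatim so broadPeak
    payloads (score, strand, signalValue, pValue, qValue) survive a
    read/write round trip.
    """

    chrom: str
    start: int  # 0-based inclusive
    end: int    # 0-based exclusive
    name: str = ""
    source: str = ""
    extra: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must exceed start, got [{self.start}, {self.end})"
            )
        if not self.source:
            raise ValueError("source label must be non-empty")

    @property
    def sort_key(self) -> tuple[str, int, int, str]:
        return (self.source, self.start, self.end, self.name)

    def to_bed_fields(self) -> list[str]:
        fields = [self.chrom, str(self.start), str(self.end)]
        if self.name or self.extra:
            fields.append(self.name)
            fields.extend(self.extra)
        return fields


class IntervalIndex:
    """Per-chromosome stab index over :class:`GenomicInterval`.

    Query results are deterministically ordered by
    ``(source, start, end, name)`` regardless of insertion order.
    """

    def __init__(self, intervals: Iterable[GenomicInterval] = ()) -> None:
        self._trees: dict[str, IntervalTree] = {}
        self._sources: set[str] = set()
        self._n = 0
        for iv in intervals:
            self.add(iv)

    def add(self, iv: GenomicInterval) -> None:
        tree = self._trees.setdefault(iv.chrom, IntervalTree())
        # payload carries an insertion counter: identical duplicate features
        # must stay distinct tree members (no deduplication on query)
        tree.addi(iv.start, iv.end, (self._n, iv))
        self._sources.add(iv.source)
        self._n += 1

    @property
    def track_count(self) -> int:
        return len(self._sources)

    @property
    def sources(self) -> frozenset[str]:
        return frozenset(self._sources)

    def __len__(self) -> int:
        return self._n

    def __iter__(self) -> Iterator[GenomicInterval]:
        for tree in self._trees.values():
            for node in tree:
                yield node.data[1]

    @property
    def chromosomes(self) -> list[str]:
        return sorted(self._trees)

    def on_chrom(self, chrom: str) -> list[GenomicInterval]:
        """All intervals on one chromosome, deterministically ordered."""
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        return sorted((node.data[1] for node in tree), key=lambda iv: iv.sort_key)

    def stab(self, chrom: str, pos0: int) -> list[GenomicInterval]:
        """All intervals with ``start <= pos0 < end`` on ``chrom``.

        An unknown chromosome yields an empty list: absence of annotation
        is a valid, scoreable state, not an error.
        """
        if pos0 < 0:
            raise ValueError(f"pos0 must be >= 0, got {pos0}")
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        hits = [node.data for node in tree.at(pos0)]
        hits.sort(key=lambda item: (item[1].sort_key, item[0]))
        return [iv for _, iv in hits]


def _open_text(path: Path):
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


_SKIP_PREFIXES = ("track", "browser", "#")


def read_bed(
    path: str | Path,
    source_label: str | None = None,
    *,
    normalize_chr: bool = False,
) -> list[GenomicInterval]:
    """Read a BED3+ or broadPeak (BED6+3) file, plain or gzipped.

    Lines starting with ``track``, ``browser`` or ``#`` are skipped.  Each
    data line needs >= 3 tab-separated fields; column 4 becomes ``name`` and
    any further columns are preserved in ``extra``.  ``source_label``
    defaults to the file stem.  An empty file yields an empty list.

    Raises :class:`BedFormatError` naming the file and 1-based line number
    for non-integer coordinates, ``end <= start``, or too few columns.
    """
    path = Path(path)
    if source_label is None:
        source_label = path.name.removesuffix(".gz")
        source_label = Path(source_label).stem
    out: list[GenomicInterval] = []
    with _open_text(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip() or line.startswith(_SKIP_PREFIXES):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise BedFormatError(
                    f"{path}:{lineno}: expected >= 3 tab-separated fields, "
                    f"got {len(cols)}"
                )
            chrom = cols[0]
            if normalize_chr:
                chrom = chrom.removeprefix("chr")
            try:
                start, end = int(cols[1]), int(cols[2])
            except ValueError as exc:
                raise BedFormatError(
                    f"{path}:{lineno}: non-integer coordinate in {cols[1:3]!r}"
                ) from exc
            try:
                iv = GenomicInterval(
                    chrom=chrom,
                    start=start,
                    end=end,
                    name=cols[3] if len(cols) > 3 else "",
                    source=source_label,
                    extra=tuple(cols[4:]),
                )
            except ValueError as exc:
                raise BedFormatError(f"{path}:{lineno}: {exc}") from exc
            out.append(iv)
    return out


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    """Write intervals back as a tab-separated BED3+ file (plain text)."""
    with open(path, "wt") as fh:
        for iv in intervals:
            fh.write("\t".join(iv.to_bed_fields()) + "\n")


def build_index(intervals: Iterable[GenomicInterval]) -> IntervalIndex:
    """Index intervals for stab queries; empty input is allowed."""
    return IntervalIndex(intervals)


def stab(index: IntervalIndex, chrom: str, pos0: int) -> list[GenomicInterval]:
    """Functional alias for :meth:`IntervalIndex.stab`."""
    return index.stab(chrom, pos0)
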