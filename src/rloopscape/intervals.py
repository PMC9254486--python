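"""Genome coordinate model and stranded interval algebra.

All coordinates are 0-based half-open (BED convention) throughout the
package; 1-based formats are converted at the reader boundary.  Strand is
one of ``+``, ``-`` or ``.``, where ``.`` (unstranded) matches either
strand in stranded comparisons — chromatin-marker tracks are typically
unstranded while R-loop peaks are stranded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import numpy as np

STRANDS = ("+", "-", ".")


class ValidationError(ValueError):
    """An interval or annotation violates the genome layout or its own invariants."""


@dataclass
class StrandedInterval:
    """A half-open genomic interval with strand; the atom of all peak sets."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    id: str | None = None
    score: float | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end (empty intervals are forbidden)"
            )
        if self.strand not in STRANDS:
            raise ValidationError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def strand_matches(self, other: "StrandedInterval") -> bool:
        """True if strands are compatible; '.' matches either strand."""
        return "." in (self.strand, other.strand) or self.strand == other.strand


def overlap_bp(a: StrandedInterval, b: StrandedInterval, stranded: bool = False) -> int:
    """Number of base pairs shared by two intervals.

    Zero if they lie on different chromosomes, or (when ``stranded``) their
    strands are incompatible.
    """
    if a.chrom != b.chrom:
        return 0
    if stranded and not a.strand_matches(b):
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def reciprocal_overlap(a: StrandedInterval, b: StrandedInterval) -> tuple[float, float]:
    """Overlap expressed as a fraction of each interval's own length (unstranded)."""
    ovl = overlap_bp(a, b, stranded=False)
    return ovl / len(a), ovl / len(b)


class GenomeLayout:
    """Ordered map of chromosome name -> length in bp.

    Serves as the single coordinate-space authority: every interval entering
    the pipeline is validated against it at load time.
    """

    def __init__(self, sizes: Mapping[str, int]):
        self._sizes: dict[str, int] = {}
        for name, length in sizes.items():
            if name in self._sizes:
                raise ValidationError(f"duplicate chromosome name {name!r}")
            length = int(length)
            if length <= 0:
                raise ValidationError(f"chromosome {name!r} has non-positive length {length}")
            self._sizes[name] = length

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._sizes

    def __getitem__(self, chrom: str) -> int:
        try:
            return self._sizes[chrom]
        except KeyError:
            raise ValidationError(
                f"chromosome {chrom!r} not in genome layout "
                f"(known: {', '.join(self._sizes)}); pass a rename map if "
                "the naming conventions differ"
            ) from None

    def __iter__(self) -> Iterator[str]:
        return iter(self._sizes)

    def __len__(self) -> int:
        return len(self._sizes)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, GenomeLayout) and self._sizes == other._sizes

    def items(self) -> Iterable[tuple[str, int]]:
        return self._sizes.items()

    @property
    def total_size(self) -> int:
        return sum(self._sizes.values())

    def offsets(self) -> dict[str, int]:
        """Cumulative start offset per chromosome for flattened coordinates."""
        out, pos = {}, 0
        for name, length in self._sizes.items():
            out[name] = pos
            pos += length
        return out

    def validate(self, iv: StrandedInterval) -> None:
        if iv.end > self[iv.chrom]:
            raise ValidationError(
                f"interval {iv.chrom}:{iv.start}-{iv.end} exceeds chromosome "
                f"length {self[iv.chrom]}"
            )


class RegionMask:
    """Merged, sorted set of unstranded excluded regions (assembly gaps + blacklist).

    Used both to drop masked genome from "mappable" denominators and to
    constrain random shuffling.
    """

    def __init__(self, intervals: Iterable[StrandedInterval] = ()):
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for iv in intervals:
            by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
        self._starts: dict[str, np.ndarray] = {}
        self._ends: dict[str, np.ndarray] = {}
        for chrom, pairs in by_chrom.items():
            pairs.sort()
            merged: list[list[int]] = []
            for s, e in pairs:
                if merged and s <= merged[-1][1]:
                    merged[-1][1] = max(merged[-1][1], e)
                else:
                    merged.append([s, e])
            self._starts[chrom] = np.array([m[0] for m in merged], dtype=np.int64)
            self._ends[chrom] = np.array([m[1] for m in merged], dtype=np.int64)

    @property
    def chroms(self) -> list[str]:
        return list(self._starts)

    def intervals(self) -> list[StrandedInterval]:
        out = []
        for chrom in self._starts:
            for s, e in zip(self._starts[chrom], self._ends[chrom]):
                out.append(StrandedInterval(chrom, int(s), int(e), "."))
        return out

    @property
    def total_bp(self) -> int:
        return int(sum((self._ends[c] - self._starts[c]).sum() for c in self._starts))

    def coverage(self, chrom: str, start: int, end: int) -> int:
        """Masked bp within [start, end)."""
        if chrom not in self._starts:
            return 0
        s, e = self._starts[chrom], self._ends[chrom]
        lo = int(np.searchsorted(e, start, side="right"))
        hi = int(np.searchsorted(s, end, side="left"))
        if hi <= lo:
            return 0
        return int(
            (np.minimum(e[lo:hi], end) - np.maximum(s[lo:hi], start)).sum()
        )

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        return self.coverage(chrom, start, end) > 0

    def free_gaps(self, layout: GenomeLayout) -> list[tuple[str, int, int]]:
        """Maximal mask-free stretches per chromosome, in layout order."""
        gaps = []
        for chrom, length in layout.items():
            pos = 0
            if chrom in self._starts:
                for s, e in zip(self._starts[chrom], self._ends[chrom]):
                    if s > pos:
                        gaps.append((chrom, pos, int(s)))
                    pos = max(pos, int(e))
            if pos < length:
                gaps.append((chrom, pos, length))
        return gaps


@dataclass
class TranscriptModel:
    """Stranded gene model: genomic span plus exon structure and optional CDS.

    ``start``/``end`` are the genomic span (start < end regardless of
    strand); the TSS/TTS properties resolve the 5'/3' ends by strand.
    ``thick_start``/``thick_end`` delimit the CDS as in BED12; equal values
    mean a non-coding transcript (no UTRs).
    """

    transcript_id: str
    chrom: str
    start: int
    end: int
    strand: str
    exons: list[tuple[int, int]] = field(default_factory=list)
    gene_id: str | None = None
    thick_start: int | None = None
    thick_end: int | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(
                f"transcript {self.transcript_id} must be stranded (+/-), got {self.strand!r}"
            )
        if not (0 <= self.start < self.end):
            raise ValidationError(f"transcript {self.transcript_id}: invalid span")
        if not self.exons:
            self.exons = [(self.start, self.end)]
        prev_end = None
        for s, e in self.exons:
            if not (self.start <= s < e <= self.end):
                raise ValidationError(
                    f"transcript {self.transcript_id}: exon ({s},{e}) outside span"
                )
            if prev_end is not None and s < prev_end:
                raise ValidationError(
                    f"transcript {self.transcript_id}: exons overlap or unsorted"
                )
            prev_end = e
        if self.gene_id is None:
            self.gene_id = self.transcript_id

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def tss(self) -> int:
        """Transcription start site (5' end; the position just past the span on '-' )."""
        return self.start if self.strand == "+" else self.end

    @property
    def tts(self) -> int:
        return self.end if self.strand == "+" else self.start

    @property
    def introns(self) -> list[tuple[int, int]]:
        out = []
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 > e1:
                out.append((e1, s2))
        return out

    @property
    def coding(self) -> bool:
        return (
            self.thick_start is not None
            and self.thick_end is not None
            and self.thick_end > self.thick_start
        )

    def as_interval(self) -> StrandedInterval:
        return StrandedInterval(self.chrom, self.start, self.end, self.strand, self.transcript_id)


def validate_intervals(
    intervals: Iterable[StrandedInterval], layout: GenomeLayout
) -> list[StrandedInterval]:
    """Validate a batch against the layout; raises on the first offender."""
    out = list(intervals)
    for iv in out:
        layout.validate(iv)
    return out
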