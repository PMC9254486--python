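"""Strand-relative and feature-level annotation of R-loop peaks.

Two classifications, matching how stranded DRIP peaks are usually reported:

* sense / antisense / untranscribed — does the peak overlap a transcript on
  the same strand, only on the opposite strand, or none at all;
* genomic feature — upstream, 5'UTR, exon, intron, 3'UTR, downstream or
  intergenic, assigned from the peak midpoint with a fixed precedence order,
  together with the expected (mappable-genome) fraction of each category and
  the observed/expected enrichment.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .intervals import GenomeLayout, RegionMask, StrandedInterval, TranscriptModel

SENSE, ANTISENSE, UNTRANSCRIBED = "sense", "antisense", "untranscribed"

#: feature labels in decreasing precedence; a midpoint covered by several
#: annotations takes the highest-precedence label
FEATURE_PRECEDENCE = (
    "five_prime_utr",
    "three_prime_utr",
    "exon",
    "intron",
    "upstream",
    "downstream",
    "intergenic",
)
_CODE = {label: i for i, label in enumerate(FEATURE_PRECEDENCE)}
_MASKED = 255


@dataclass
class StrandClass:
    peak: StrandedInterval
    label: str
    transcript_ids: list[str]


@dataclass
class FeatureClass:
    peak: StrandedInterval
    label: str
    transcript_id: str | None


def _transcript_trees(
    transcripts: Sequence[TranscriptModel], pad: int = 0
) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for tx in transcripts:
        trees.setdefault(tx.chrom, IntervalTree()).addi(
            max(0, tx.start - pad), tx.end + pad, tx
        )
    return trees


def classify_strand(
    peaks: Sequence[StrandedInterval],
    transcripts: Sequence[TranscriptModel],
) -> tuple[list[StrandClass], dict[str, float]]:
    """Sense if the peak overlaps any same-strand transcript, else antisense
    if it overlaps any opposite-strand transcript, else untranscribed.

    Sense takes precedence for peaks spanning transcripts on both strands.
    Fractions over the total peak count sum to 1.
    """
    trees = _transcript_trees(transcripts)
    results: list[StrandClass] = []
    counts = {SENSE: 0, ANTISENSE: 0, UNTRANSCRIBED: 0}
    for pk in peaks:
        if pk.strand not in ("+", "-"):
            raise ValueError(
                f"peak {pk.chrom}:{pk.start}-{pk.end} is unstranded; "
                "strand classification requires stranded peaks"
            )
        same, opposite = [], []
        tree = trees.get(pk.chrom)
        if tree is not None:
            for hit in tree.overlap(pk.start, pk.end):
                tx: TranscriptModel = hit.data
                (same if tx.strand == pk.strand else opposite).append(tx.transcript_id)
        if same:
            label, support = SENSE, sorted(same)
        elif opposite:
            label, support = ANTISENSE, sorted(opposite)
        else:
            label, support = UNTRANSCRIBED, []
        counts[label] += 1
        results.append(StrandClass(pk, label, support))
    total = len(peaks)
    fractions = {k: (v / total if total else 0.0) for k, v in counts.items()}
    return results, fractions


def collapse_isoforms(transcripts: Sequence[TranscriptModel]) -> list[TranscriptModel]:
    """One model per gene: the isoform with the longest genomic span
    (ties broken by transcript id for determinism)."""
    best: dict[str, TranscriptModel] = {}
    for tx in transcripts:
        key = tx.gene_id or tx.transcript_id
        cur = best.get(key)
        if (
            cur is None
            or len(tx) > len(cur)
            or (len(tx) == len(cur) and tx.transcript_id < cur.transcript_id)
        ):
            best[key] = tx
    return sorted(best.values(), key=lambda t: (t.chrom, t.start, t.transcript_id))


def _feature_segments(
    tx: TranscriptModel, flank: int, chrom_len: int
) -> list[tuple[int, int, int]]:
    """(start, end, precedence code) segments for one transcript model."""
    segs: list[tuple[int, int, int]] = []
    exonic = tx.exons
    if tx.coding:
        cs, ce = tx.thick_start, tx.thick_end
        utr5, utr3 = ("five_prime_utr", "three_prime_utr")
        if tx.strand == "-":
            utr5, utr3 = utr3, utr5
        # on the genome: left UTR before CDS start, right UTR after CDS end
        for s, e in exonic:
            if s < cs:
                segs.append((s, min(e, cs), _CODE[utr5]))
            if e > ce:
                segs.append((max(s, ce), e, _CODE[utr3]))
            mid_s, mid_e = max(s, cs), min(e, ce)
            if mid_e > mid_s:
                segs.append((mid_s, mid_e, _CODE["exon"]))
    else:
        for s, e in exonic:
            segs.append((s, e, _CODE["exon"]))
    for s, e in tx.introns:
        segs.append((s, e, _CODE["intron"]))
    if tx.strand == "+":
        up = (max(0, tx.start - flank), tx.start)
        down = (tx.end, min(chrom_len, tx.end + flank))
    else:
        up = (tx.end, min(chrom_len, tx.end + flank))
        down = (max(0, tx.start - flank), tx.start)
    if up[1] > up[0]:
        segs.append((up[0], up[1], _CODE["upstream"]))
    if down[1] > down[0]:
        segs.append((down[0], down[1], _CODE["downstream"]))
    return [(s, e, c) for s, e, c in segs if e > s]


def _paint_genome(
    transcripts: Sequence[TranscriptModel],
    layout: GenomeLayout,
    flank: int,
    mask: RegionMask | None,
) -> dict[str, np.ndarray]:
    arrays = {
        chrom: np.full(length, _CODE["intergenic"], dtype=np.uint8)
        for chrom, length in layout.items()
    }
    for tx in transcripts:
        arr = arrays[tx.chrom]
        for s, e, code in _feature_segments(tx, flank, len(arr)):
            np.minimum(arr[s:e], code, out=arr[s:e])
    if mask is not None:
        for iv in mask.intervals():
            if iv.chrom in arrays:
                arrays[iv.chrom][iv.start : iv.end] = _MASKED
    return arrays


def _label_midpoint(
    pos: int,
    candidates: list[TranscriptModel],
    flank: int,
    chrom_len: int,
) -> tuple[str, str | None]:
    best_code, best_tx = _CODE["intergenic"], None
    for tx in sorted(candidates, key=lambda t: t.transcript_id):
        for s, e, code in _feature_segments(tx, flank, chrom_len):
            if s <= pos < e and code < best_code:
                best_code, best_tx = code, tx.transcript_id
    return FEATURE_PRECEDENCE[best_code], best_tx


@dataclass
class FeatureSummary:
    assignments: list[FeatureClass]
    counts: pd.Series
    observed_fraction: pd.Series
    genome_fraction: pd.Series
    enrichment: pd.Series

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "count": self.counts,
                "observed_fraction": self.observed_fraction,
                "genome_fraction": self.genome_fraction,
                "enrichment": self.enrichment,
            }
        )


def classify_feature(
    peaks: Sequence[StrandedInterval],
    transcripts: Sequence[TranscriptModel],
    layout: GenomeLayout,
    flank: int = 5000,
    mask: RegionMask | None = None,
) -> FeatureSummary:
    """Assign one genomic-feature label per peak (by midpoint, fixed
    precedence) and compare observed category fractions to the fraction of
    the mappable genome each category covers.

    Overlapping isoforms of a gene are collapsed to the longest before
    annotation so every peak gets exactly one label.  Enrichment is
    observed fraction / genome fraction (NaN where the genome fraction is
    zero).
    """
    collapsed = collapse_isoforms(transcripts)
    trees = _transcript_trees(collapsed, pad=flank)
    assignments: list[FeatureClass] = []
    for pk in peaks:
        pos = pk.midpoint
        tree = trees.get(pk.chrom)
        candidates = (
            [hit.data for hit in tree.at(pos)] if tree is not None else []
        )
        label, tx_id = _label_midpoint(pos, candidates, flank, layout[pk.chrom])
        assignments.append(FeatureClass(pk, label, tx_id))

    painted = _paint_genome(collapsed, layout, flank, mask)
    genome_counts = np.zeros(len(FEATURE_PRECEDENCE), dtype=np.int64)
    for arr in painted.values():
        bc = np.bincount(arr[arr != _MASKED], minlength=len(FEATURE_PRECEDENCE))
        genome_counts += bc[: len(FEATURE_PRECEDENCE)]
    mappable = genome_counts.sum()

    labels = list(FEATURE_PRECEDENCE)
    counts = pd.Series(0, index=labels, dtype=int)
    for fc in assignments:
        counts[fc.label] += 1
    observed = counts / max(len(peaks), 1)
    genome_frac = pd.Series(genome_counts / max(mappable, 1), index=labels)
    with np.errstate(divide="ignore", invalid="ignore"):
        enr = observed / genome_frac
    enr[genome_frac == 0] = np.nan
    return FeatureSummary(assignments, counts, observed, genome_frac, enr)
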