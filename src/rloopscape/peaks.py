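"""Peak post-processing: two-control consensus, both-strand artifact removal,
cross-sample sharing classification, and binned signal correlation.

The consensus step mirrors strand-specific DRIP-seq practice: peaks are
called independently against an input control and an RNase H1-treated
control, and only peaks supported by both calls are kept.  Peaks that appear
on both strands at (near-)identical coordinates are treated as artifacts of
incomplete strand separation and removed when their reciprocal overlap
exceeds a threshold (default 90%).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from intervaltree import IntervalTree

from .intervals import GenomeLayout, StrandedInterval, reciprocal_overlap


@dataclass
class StrandCalls:
    """Peak calls for one strand of one sample, against both controls."""

    peaks_vs_input: list[StrandedInterval]
    peaks_vs_rnaseh: list[StrandedInterval]


@dataclass
class SampleCalls:
    """Per-strand raw peak calls for one sample."""

    sample: str
    calls: dict[str, StrandCalls]  # keyed by "+" / "-"

    def __post_init__(self) -> None:
        for strand, sc in self.calls.items():
            for iv in sc.peaks_vs_input + sc.peaks_vs_rnaseh:
                if iv.strand != strand:
                    raise ValueError(
                        f"sample {self.sample}: peak {iv.chrom}:{iv.start}-{iv.end} "
                        f"has strand {iv.strand!r} stored under {strand!r}"
                    )


def _tree_by_chrom(intervals: Iterable[StrandedInterval]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for iv in intervals:
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, iv)
    return trees


def consensus_strand(
    peaks_vs_input: Sequence[StrandedInterval],
    peaks_vs_rnaseh: Sequence[StrandedInterval],
    min_overlap: int = 1,
) -> list[StrandedInterval]:
    """Keep each input-referenced peak that overlaps (>= min_overlap bp, same
    strand) at least one RNase H1-referenced peak; coordinates unchanged."""
    if not peaks_vs_input:
        warnings.warn("consensus: empty peaks_vs_input, returning empty result")
        return []
    trees = _tree_by_chrom(peaks_vs_rnaseh)
    kept = []
    for pk in peaks_vs_input:
        tree = trees.get(pk.chrom)
        if tree is None:
            continue
        for hit in tree.overlap(pk.start, pk.end):
            other: StrandedInterval = hit.data
            if not pk.strand_matches(other):
                continue
            if min(pk.end, other.end) - max(pk.start, other.start) >= min_overlap:
                kept.append(pk)
                break
    return kept


def consensus_peaks(
    calls: SampleCalls, min_overlap: int = 1
) -> dict[str, list[StrandedInterval]]:
    """Two-control consensus per strand (see :func:`consensus_strand`)."""
    return {
        strand: consensus_strand(sc.peaks_vs_input, sc.peaks_vs_rnaseh, min_overlap)
        for strand, sc in calls.calls.items()
    }


def filter_bistranded(
    plus_peaks: Sequence[StrandedInterval],
    minus_peaks: Sequence[StrandedInterval],
    threshold: float = 0.90,
) -> tuple[list[StrandedInterval], list[StrandedInterval], list[StrandedInterval]]:
    """Remove +/- peak pairs whose reciprocal overlap is >= threshold on BOTH sides.

    Removal is evaluated pairwise: any qualifying opposite-strand partner
    removes both members.  Returns (plus_kept, minus_kept, removed).
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    minus_trees = _tree_by_chrom(minus_peaks)
    drop_plus: set[int] = set()
    drop_minus: set[int] = set()
    minus_index = {id(iv): i for i, iv in enumerate(minus_peaks)}
    for i, pk in enumerate(plus_peaks):
        tree = minus_trees.get(pk.chrom)
        if tree is None:
            continue
        for hit in tree.overlap(pk.start, pk.end):
            other: StrandedInterval = hit.data
            fa, fb = reciprocal_overlap(pk, other)
            if fa >= threshold and fb >= threshold:
                drop_plus.add(i)
                drop_minus.add(minus_index[id(other)])
    plus_kept = [pk for i, pk in enumerate(plus_peaks) if i not in drop_plus]
    minus_kept = [pk for i, pk in enumerate(minus_peaks) if i not in drop_minus]
    removed = [pk for i, pk in enumerate(plus_peaks) if i in drop_plus] + [
        pk for i, pk in enumerate(minus_peaks) if i in drop_minus
    ]
    return plus_kept, minus_kept, removed


@dataclass
class PeakCluster:
    """Single-linkage cluster of same-strand overlapping peaks across samples."""

    members: list[tuple[str, StrandedInterval]]
    chrom: str
    strand: str
    span_start: int
    span_end: int
    samples_present: frozenset[str]
    category: str  # all_samples / two_plus / unique


@dataclass
class SharingResult:
    clusters: list[PeakCluster]
    fractions: dict[str, float]
    counts: dict[str, int]
    unique_by_sample: dict[str, list[StrandedInterval]]

    def summary_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "category": list(self.counts),
                "n_clusters": list(self.counts.values()),
                "fraction": [self.fractions[c] for c in self.counts],
            }
        )


def classify_sharing(
    sample_peaksets: Mapping[str, Sequence[StrandedInterval]]
) -> SharingResult:
    """Cluster same-strand overlapping peaks across samples (single linkage)
    and classify each cluster by how many samples contribute to it.

    Categories: ``all_samples`` (every sample present), ``two_plus`` (at
    least two but not all), ``unique`` (one sample).  Fractions are over the
    cluster count.  Per-sample unique peak sets (members of ``unique``
    clusters) are returned for downstream sample-specific analyses.
    """
    if len(sample_peaksets) < 2:
        raise ValueError("classify_sharing requires at least 2 samples")
    n_samples = len(sample_peaksets)
    tagged: dict[tuple[str, str], list[tuple[str, StrandedInterval]]] = {}
    for sample, peaks in sample_peaksets.items():
        for pk in peaks:
            if pk.strand not in ("+", "-"):
                raise ValueError("sharing classification requires stranded peaks")
            tagged.setdefault((pk.chrom, pk.strand), []).append((sample, pk))

    clusters: list[PeakCluster] = []
    for (chrom, strand), items in sorted(tagged.items()):
        items.sort(key=lambda t: (t[1].start, t[1].end))
        current: list[tuple[str, StrandedInterval]] = []
        cur_end = -1
        for sample, pk in items:
            if current and pk.start < cur_end:
                current.append((sample, pk))
                cur_end = max(cur_end, pk.end)
            else:
                if current:
                    clusters.append(_make_cluster(current, chrom, strand, n_samples))
                current = [(sample, pk)]
                cur_end = pk.end
        if current:
            clusters.append(_make_cluster(current, chrom, strand, n_samples))

    counts = {"all_samples": 0, "two_plus": 0, "unique": 0}
    unique_by_sample: dict[str, list[StrandedInterval]] = {
        s: [] for s in sample_peaksets
    }
    for cl in clusters:
        counts[cl.category] += 1
        if cl.category == "unique":
            (sample,) = cl.samples_present
            unique_by_sample[sample].extend(pk for _, pk in cl.members)
    total = len(clusters)
    fractions = {k: (v / total if total else 0.0) for k, v in counts.items()}
    return SharingResult(clusters, fractions, counts, unique_by_sample)


def _make_cluster(
    members: list[tuple[str, StrandedInterval]], chrom: str, strand: str, n_samples: int
) -> PeakCluster:
    samples = frozenset(s for s, _ in members)
    if len(samples) == n_samples:
        category = "all_samples"
    elif len(samples) >= 2:
        category = "two_plus"
    else:
        category = "unique"
    return PeakCluster(
        members=members,
        chrom=chrom,
        strand=strand,
        span_start=min(pk.start for _, pk in members),
        span_end=max(pk.end for _, pk in members),
        samples_present=samples,
        category=category,
    )


class ZeroVarianceError(ValueError):
    """Correlation undefined: one of the binned tracks is constant."""


Track = Sequence[tuple[str, int, int, float]]


def _binned_sums(
    track: Track | Mapping[str, np.ndarray],
    layout: GenomeLayout,
    bin_size: int,
    exclude: frozenset[str],
) -> np.ndarray:
    pieces = []
    if isinstance(track, Mapping):
        per_chrom = {c: np.asarray(v, dtype=float) for c, v in track.items()}
    else:
        per_chrom = {}
        for chrom, start, end, value in track:
            if chrom not in per_chrom:
                per_chrom[chrom] = np.zeros(layout[chrom], dtype=float)
            per_chrom[chrom][start:end] += value
    for chrom, length in layout.items():
        if chrom in exclude:
            continue
        arr = per_chrom.get(chrom)
        if arr is None:
            arr = np.zeros(length, dtype=float)
        n_bins = -(-length // bin_size)
        padded = np.zeros(n_bins * bin_size, dtype=float)
        padded[: len(arr)] = arr
        pieces.append(padded.reshape(n_bins, bin_size).sum(axis=1))
    return np.concatenate(pieces) if pieces else np.array([])


def binned_signal_correlation(
    track_a: Track | Mapping[str, np.ndarray],
    track_b: Track | Mapping[str, np.ndarray],
    layout: GenomeLayout,
    bin_size: int = 1000,
    exclude: Iterable[str] = (),
) -> float:
    """Pearson correlation of two coverage tracks over genome-wide bins.

    Tracks are bedGraph-style (chrom, start, end, value) records or per-base
    arrays keyed by chromosome.  Listed chromosomes (e.g. the mitochondrial
    genome) are excluded before binning.
    """
    excl = frozenset(exclude)
    a = _binned_sums(track_a, layout, bin_size, excl)
    b = _binned_sums(track_b, layout, bin_size, excl)
    if a.std() == 0 or b.std() == 0:
        raise ZeroVarianceError("binned track has zero variance; correlation undefined")
    return float(np.corrcoef(a, b)[0, 1])
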