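"""Windowed AT/GC skew and the metaprofile engine.

GC skew of window *i* is ``S_i = (G_i - C_i) / (G_i + C_i)`` where ``G_i``
and ``C_i`` count guanines and cytosines in the window; AT skew is the A/T
analog.  Both lie in [-1, 1] wherever the denominator is positive; windows
with a zero denominator (e.g. inside N gaps) carry a missing value, never 0,
so that masked genome cannot fabricate "no skew" signal.

Skew is strand-antisymmetric: the skew of a window's reverse complement is
the negation of the forward-strand skew.  Metaprofiles over stranded
regions therefore optionally orient by strand (reverse minus-strand
regions) and flip the sign of skew values on the minus strand.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from pyfaidx import Fasta

from .intervals import GenomeLayout, StrandedInterval, TranscriptModel

__all__ = [
    "SkewWindow",
    "MetaProfile",
    "compute_skew_track",
    "per_base_values",
    "skew_bedgraph_entries",
    "metaprofile",
    "skew_at_features",
]


@dataclass
class SkewWindow:
    """Per-window nucleotide counts and the derived skew statistics."""

    chrom: str
    start: int
    end: int
    g: int
    c: int
    a: int
    t: int

    @property
    def gc_skew(self) -> float | None:
        """(G-C)/(G+C), or None when the window has no G or C."""
        denom = self.g + self.c
        return (self.g - self.c) / denom if denom else None

    @property
    def at_skew(self) -> float | None:
        denom = self.a + self.t
        return (self.a - self.t) / denom if denom else None


def _resolve_sequences(genome) -> Mapping[str, str]:
    if isinstance(genome, (str, bytes)) or hasattr(genome, "__fspath__"):
        fa = Fasta(str(genome), as_raw=True)
        return {name: str(fa[name][:]) for name in fa.keys()}
    if isinstance(genome, Fasta):
        return {name: str(genome[name][:]) for name in genome.keys()}
    return genome


def compute_skew_track(
    genome,
    window: int = 50,
    layout: GenomeLayout | None = None,
) -> list[SkewWindow]:
    """Tile each chromosome with non-overlapping windows and count G/C/A/T.

    ``genome`` is a FASTA path, an open :class:`pyfaidx.Fasta`, or a mapping
    of chromosome name to sequence.  Counting is case-insensitive and N (or
    any other ambiguity code) falls in no category.  The final partial
    window is kept when it is at least ``window/2`` long, else dropped.
    When a layout is given, every layout chromosome must be present.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    seqs = _resolve_sequences(genome)
    if layout is not None:
        missing = [c for c in layout if c not in seqs]
        if missing:
            raise ValueError(f"chromosomes in layout absent from FASTA: {missing}")
    out: list[SkewWindow] = []
    for chrom, seq in seqs.items():
        arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
        n = len(arr)
        if n == 0:
            continue
        n_full = n // window
        tail = n - n_full * window
        edges = np.arange(0, n_full * window + 1, window)
        keep_tail = tail * 2 >= window
        counts = {}
        for base in "GCAT":
            hits = (arr == ord(base)).astype(np.int64)
            csum = np.concatenate(([0], np.cumsum(hits)))
            counts[base] = csum
        boundaries = list(zip(edges[:-1], edges[1:]))
        if keep_tail:
            boundaries.append((n_full * window, n))
        for s, e in boundaries:
            out.append(
                SkewWindow(
                    chrom,
                    int(s),
                    int(e),
                    g=int(counts["G"][e] - counts["G"][s]),
                    c=int(counts["C"][e] - counts["C"][s]),
                    a=int(counts["A"][e] - counts["A"][s]),
                    t=int(counts["T"][e] - counts["T"][s]),
                )
            )
    return out


def skew_bedgraph_entries(
    windows: Sequence[SkewWindow], which: str = "GC"
) -> list[tuple[str, int, int, float]]:
    """bedGraph records for the chosen skew; undefined windows are omitted."""
    attr = "gc_skew" if which.upper() == "GC" else "at_skew"
    out = []
    for w in windows:
        v = getattr(w, attr)
        if v is not None:
            out.append((w.chrom, w.start, w.end, v))
    return out


def per_base_values(
    windows: Sequence[SkewWindow],
    layout: GenomeLayout,
    which: str = "GC",
) -> dict[str, np.ndarray]:
    """Expand a windowed skew track to per-base arrays (NaN where undefined)."""
    attr = "gc_skew" if which.upper() == "GC" else "at_skew"
    vals = {chrom: np.full(length, np.nan) for chrom, length in layout.items()}
    for w in windows:
        v = getattr(w, attr)
        if v is not None:
            vals[w.chrom][w.start : w.end] = v
    return vals


@dataclass
class MetaProfile:
    """Per-bin mean +/- SEM of a signal across a set of regions."""

    mode: str  # scale_regions / reference_point
    bin_size: int
    flank: int
    body: int | None
    means: np.ndarray
    sems: np.ndarray
    counts: np.ndarray
    n_regions: int
    n_skipped: int = 0

    @property
    def n_bins(self) -> int:
        return len(self.means)

    def bin_labels(self) -> list[str]:
        nf = self.flank // self.bin_size
        if self.mode == "scale_regions":
            nb = self.body // self.bin_size
            labels = [f"up{(nf - i) * self.bin_size}" for i in range(nf)]
            labels += [f"body{i + 1}" for i in range(nb)]
            labels += [f"down{(i + 1) * self.bin_size}" for i in range(nf)]
        else:
            labels = [
                f"{(i - nf) * self.bin_size:+d}" for i in range(2 * nf)
            ]
        return labels

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "bin": self.bin_labels(),
                "mean": self.means,
                "sem": self.sems,
                "n": self.counts,
            }
        )


def _gather(vals: np.ndarray, start: int, end: int) -> np.ndarray:
    """Per-base values for [start, end), NaN-padded outside the chromosome."""
    n = len(vals)
    out = np.full(end - start, np.nan)
    lo, hi = max(start, 0), min(end, n)
    if hi > lo:
        out[lo - start : hi - start] = vals[lo:hi]
    return out


def _bin_means(segment: np.ndarray, bin_size: int) -> np.ndarray:
    n_bins = len(segment) // bin_size
    seg = segment[: n_bins * bin_size].reshape(n_bins, bin_size)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        return np.nanmean(seg, axis=1)


def _body_bins(segment: np.ndarray, n_bins: int) -> np.ndarray:
    """Resample a region body onto a fixed bin grid.

    Bin j averages the per-base values over the fractional slice
    [j*L/n, (j+1)*L/n) of the region, with every bin guaranteed at least
    one base.
    """
    L = len(segment)
    out = np.full(n_bins, np.nan)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        for j in range(n_bins):
            lo = (j * L) // n_bins
            hi = max(lo + 1, ((j + 1) * L) // n_bins)
            out[j] = np.nanmean(segment[lo:hi])
    return out


def metaprofile(
    values: Mapping[str, np.ndarray],
    regions: Sequence[StrandedInterval | TranscriptModel],
    mode: str = "scale_regions",
    bin_size: int = 50,
    flank: int = 500,
    body: int = 1000,
    anchor: str = "center",
    orient_by_strand: bool = True,
    flip_sign_on_minus: bool = False,
) -> MetaProfile:
    """Average a per-base signal over regions on a fixed bin grid.

    ``scale_regions`` mode rescales each region body onto ``body/bin_size``
    bins and adds ``flank/bin_size`` fixed-width bins on each side;
    ``reference_point`` mode takes ``2*flank/bin_size`` bins around the
    chosen anchor (``start``/``center``/``end``; start and end are resolved
    5'->3' when ``orient_by_strand``).  Minus-strand regions are reversed
    when ``orient_by_strand`` and their values negated when
    ``flip_sign_on_minus`` (appropriate for strand-antisymmetric signals
    such as skew).  Missing values are ignored in per-bin means; SEM is the
    per-bin standard error over contributing regions.
    """
    if not regions:
        raise ValueError("metaprofile requires at least one region")
    if mode not in ("scale_regions", "reference_point"):
        raise ValueError(f"unknown mode {mode!r}")
    if flank % bin_size or (mode == "scale_regions" and body % bin_size):
        raise ValueError("flank and body must be multiples of bin_size")
    if mode == "reference_point" and anchor not in ("start", "center", "end"):
        raise ValueError(f"unknown anchor {anchor!r}")
    nf = flank // bin_size
    rows = []
    n_skipped = 0
    for region in regions:
        chrom, start, end = region.chrom, region.start, region.end
        strand = getattr(region, "strand", ".")
        vals = values[chrom]
        if mode == "scale_regions":
            if end - start < bin_size:
                n_skipped += 1
                continue
            nb = body // bin_size
            left = _bin_means(_gather(vals, start - flank, start), bin_size)
            mid = _body_bins(_gather(vals, start, end), nb)
            right = _bin_means(_gather(vals, end, end + flank), bin_size)
            vec = np.concatenate([left, mid, right])
        else:
            a = anchor
            if orient_by_strand and strand == "-" and a in ("start", "end"):
                a = "end" if a == "start" else "start"
            if a == "start":
                p = start
            elif a == "end":
                p = end
            else:
                p = (start + end) // 2
            vec = _bin_means(_gather(vals, p - flank, p + flank), bin_size)
        if strand == "-":
            if orient_by_strand:
                vec = vec[::-1]
            if flip_sign_on_minus:
                vec = -vec
        rows.append(vec)
    if not rows:
        raise ValueError("all regions were shorter than one bin; nothing to profile")
    mat = np.vstack(rows)
    counts = np.sum(~np.isnan(mat), axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        means = np.nanmean(mat, axis=0)
        sds = np.nanstd(mat, axis=0, ddof=1)
    sems = np.where(counts > 1, sds / np.sqrt(np.maximum(counts, 1)), np.nan)
    return MetaProfile(
        mode=mode,
        bin_size=bin_size,
        flank=flank,
        body=body if mode == "scale_regions" else None,
        means=means,
        sems=sems,
        counts=counts,
        n_regions=len(rows),
        n_skipped=n_skipped,
    )


def skew_at_features(
    genome,
    regions: Sequence[StrandedInterval | TranscriptModel],
    layout: GenomeLayout,
    which: str = "GC",
    mode: str = "reference_point",
    window: int = 50,
    windows: Sequence[SkewWindow] | None = None,
    **profile_kwargs,
) -> MetaProfile:
    """Skew metaprofile over peaks (reference_point, center) or gene bodies
    (scale_regions).  Orientation and sign-flip on minus-strand regions
    default to on, matching the strand antisymmetry of skew."""
    if windows is None:
        windows = compute_skew_track(genome, window=window, layout=layout)
    vals = per_base_values(windows, layout, which=which)
    profile_kwargs.setdefault("orient_by_strand", True)
    profile_kwargs.setdefault("flip_sign_on_minus", True)
    if mode == "reference_point":
        profile_kwargs.setdefault("anchor", "center")
    return metaprofile(vals, regions, mode=mode, **profile_kwargs)
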