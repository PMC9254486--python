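"""Synthetic data with planted, analytically-known structure.

Generates every input the pipeline consumes — a small genome with
programmed base-composition (skew) regions and N-gaps, a transcriptome,
per-sample stranded R-loop peak sets (raw two-control calls plus final
peaks), chromatin-marker tracks with planted base-pair-overlap enrichment
factors, a two-regime tiling-probe map, and per-transcript expression
tables with a planted R-loop/expression coupling — so every stage of the
pipeline is testable without downloading anything.

Planted effects and their analytic expectations:

* a composition region with P(G)=g, P(C)=c has expected GC skew
  (g-c)/(g+c) in the large-window limit;
* skew-transition sites place +delta AT skew on the left half and -delta
  on the right half of a window around each site, so an oriented,
  sign-flipped metaprofile centered on the co-placed peaks crosses zero at
  the center bin;
* a marker with enrichment factor rho != 1 decomposes exactly: a planted
  subset of its peaks sits fully inside R-loop territory and the rest
  avoid it, sized so that E[observed]/E[null] = rho (see
  :func:`_generate_marker`); rho = 1 markers are placed uniformly,
  independent of the peaks;
* a gene acquires R-loops with probability rate (top expression quartile:
  odds * rate), so the expected share of R-loop genes in the top quartile
  is odds / (odds + 3);
* genes with sample-specific R-loops in sample A get ``delta_fpkm`` added
  to their sample-A FPKM, so the specificity-vs-expression median
  recovers the shift (zero by default).

Everything is a deterministic function of the seed; the ground truth is
written to a separate sidecar never read by the pipeline under test.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import io as rio
from .intervals import GenomeLayout, RegionMask, StrandedInterval, TranscriptModel
from .peaks import SampleCalls, StrandCalls
from .enrichment import FreeSpace

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SkewRegion:
    """Programmed base composition over a genomic window (probs sum to 1)."""

    chrom: str
    start: int
    end: int
    p_a: float = 0.25
    p_c: float = 0.25
    p_g: float = 0.25
    p_t: float = 0.25

    @property
    def probs(self) -> tuple[float, float, float, float]:
        return (self.p_a, self.p_c, self.p_g, self.p_t)

    def expected_gc_skew(self) -> float:
        return (self.p_g - self.p_c) / (self.p_g + self.p_c)

    def expected_at_skew(self) -> float:
        return (self.p_a - self.p_t) / (self.p_a + self.p_t)


@dataclass
class MarkerProgram:
    name: str
    rho: float = 1.0  # planted E[observed]/E[null] overlap ratio
    n_peaks: int = 300
    peak_len: int = 200

    def __post_init__(self) -> None:
        if self.rho <= 0:
            raise ValueError(f"marker {self.name}: enrichment factor must be > 0")


@dataclass
class SimulationConfig:
    """Knobs of the synthetic study; defaults are desk-scale but realistic."""

    seed: int = 0
    chrom_sizes: dict[str, int] = field(
        default_factory=lambda: {"chr2L": 1_200_000, "chr3R": 780_000, "chrM": 20_000}
    )
    mito_chrom: str = "chrM"
    gap_regions: list[tuple[str, int, int]] = field(
        default_factory=lambda: [("chr2L", 600_000, 610_000), ("chr3R", 300_000, 308_000)]
    )
    base_probs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)  # A C G T
    skew_regions: list[SkewRegion] = field(default_factory=list)

    # planted AT-skew transition sites (positive -> negative at the center)
    n_skew_sites: int = 0
    skew_site_half_width: int = 1000
    skew_site_at_delta: float = 0.4
    skew_site_gc_delta: float = 0.2

    # transcriptome
    n_transcripts: int = 350
    tx_len_median: float = 3000.0
    tx_len_sigma: float = 0.5
    intergenic_mean: float = 1200.0
    coding_fraction: float = 0.8

    # R-loop peaks
    samples: tuple[str, ...] = ("S2", "embryo_2_3h", "embryo_14_16h")
    peak_len_median: float = 500.0
    peak_len_sigma: float = 0.6
    peak_len_min: int = 150
    peak_len_max: int = 10_000
    gene_rloop_rate: float = 0.2
    count_lambda_base: float = 0.3
    count_lambda_slope: float = 0.0  # extra Poisson mean per quartile step
    n_background_peaks: int = 120
    placement_bias: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "S2": {"tss": 0.4, "body": 0.5, "tts": 0.1},
            "embryo_2_3h": {"tss": 0.4, "body": 0.5, "tts": 0.1},
            "embryo_14_16h": {"tss": 0.45, "body": 0.1, "tts": 0.45},
        }
    )
    call_noise_fraction: float = 0.15
    call_jitter: int = 60

    # expression
    fpkm_log_mean: float = 1.0
    fpkm_log_sigma: float = 1.5
    quartile_odds: float = 4.0
    delta_fpkm: float = 0.0

    # markers and ChIP-chip probes
    marker_programs: list[MarkerProgram] = field(
        default_factory=lambda: [
            MarkerProgram("bound_factor", rho=2.0),
            MarkerProgram("independent_factor", rho=1.0),
            MarkerProgram("avoided_factor", rho=0.5),
        ]
    )
    marker_target_sample: str = "S2"
    probe_dense_region: tuple[str, int, int] = ("chr2L", 0, 500_000)
    probe_dense_spacing: int = 100
    probe_sparse_spacing: int = 1000
    probe_len: int = 25
    n_chipchip_peaks: int = 500
    chipchip_len_median: float = 800.0
    chipchip_len_sigma: float = 0.25

    def validate(self) -> None:
        if self.quartile_odds * self.gene_rloop_rate > 1:
            raise ValueError(
                "infeasible coupling: quartile_odds * gene_rloop_rate must be <= 1"
            )
        regions = sorted(
            (r.chrom, r.start, r.end) for r in self.skew_regions
        )
        for (c1, s1, e1), (c2, s2, e2) in zip(regions, regions[1:]):
            if c1 == c2 and s2 < e1:
                raise ValueError(
                    f"overlapping skew-program regions {c1}:{s1}-{e1} and {c2}:{s2}-{e2}"
                )


@dataclass
class GenomeData:
    seqs: dict[str, str]
    layout: GenomeLayout
    mask: RegionMask


@dataclass
class TrackSet:
    transcripts: list[TranscriptModel]
    expression: dict[str, pd.DataFrame]
    rloops: dict[str, list[StrandedInterval]]  # final stranded peaks per sample
    raw_calls: dict[str, SampleCalls]
    site_peaks: list[StrandedInterval]  # peaks planted at skew-transition sites
    markers: dict[str, list[StrandedInterval]]
    probes: list[StrandedInterval]
    chipchip_peaks: list[StrandedInterval]
    ground_truth: dict


@dataclass
class SyntheticDataset:
    config: SimulationConfig
    genome: GenomeData
    tracks: TrackSet

    @property
    def layout(self) -> GenomeLayout:
        return self.genome.layout

    @property
    def mask(self) -> RegionMask:
        return self.genome.mask


def _rngs(seed: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(8)]


def _skew_site_regions(cfg: SimulationConfig) -> list[tuple[SkewRegion, SkewRegion, str, int]]:
    """(left region, right region, strand, center) per planted site.

    Sites are chosen once from the seed so that genome and track generation
    agree without sharing state.
    """
    if cfg.n_skew_sites == 0:
        return []
    rng = _rngs(cfg.seed)[1]
    w = cfg.skew_site_half_width
    candidates = [
        c for c in cfg.chrom_sizes if c != cfg.mito_chrom and cfg.chrom_sizes[c] > 10 * w
    ]
    gaps_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for c, s, e in cfg.gap_regions:
        gaps_by_chrom.setdefault(c, []).append((s, e))
    out = []
    taken: dict[str, list[tuple[int, int]]] = {c: [] for c in candidates}
    attempts = 0
    while len(out) < cfg.n_skew_sites and attempts < 1000 * cfg.n_skew_sites:
        attempts += 1
        chrom = candidates[int(rng.integers(len(candidates)))]
        center = int(rng.integers(2 * w, cfg.chrom_sizes[chrom] - 2 * w))
        lo, hi = center - w, center + w
        clash = any(lo < e and hi > s for s, e in gaps_by_chrom.get(chrom, []))
        clash = clash or any(lo < e and hi > s for s, e in taken[chrom])
        if clash:
            continue
        taken[chrom].append((lo, hi))
        strand = "+" if rng.random() < 0.5 else "-"
        da, dg = cfg.skew_site_at_delta, cfg.skew_site_gc_delta
        # AT skew +da then -da across the center; GC skew mirrors with -dg then +dg
        at_hi, at_lo = 0.25 * (1 + da), 0.25 * (1 - da)
        gc_hi, gc_lo = 0.25 * (1 + dg), 0.25 * (1 - dg)
        left = SkewRegion(chrom, lo, center, p_a=at_hi, p_t=at_lo, p_g=gc_lo, p_c=gc_hi)
        right = SkewRegion(chrom, center, hi, p_a=at_lo, p_t=at_hi, p_g=gc_hi, p_c=gc_lo)
        out.append((left, right, strand, center))
    return out


def generate_genome(cfg: SimulationConfig) -> GenomeData:
    """Sample the genome sequence from the composition program.

    Per-position nucleotides are drawn from the background composition,
    overridden inside programmed skew regions (explicit plus any planted
    transition sites); gap regions become N runs and form the region mask.
    """
    cfg.validate()
    rng = _rngs(cfg.seed)[0]
    layout = GenomeLayout(cfg.chrom_sizes)
    regions = list(cfg.skew_regions)
    for left, right, _, _ in _skew_site_regions(cfg):
        regions.extend([left, right])
    seqs: dict[str, str] = {}
    for chrom, length in layout.items():
        arr = BASES[rng.choice(4, size=length, p=list(cfg.base_probs))]
        for reg in [r for r in regions if r.chrom == chrom]:
            span = reg.end - reg.start
            arr[reg.start : reg.end] = BASES[rng.choice(4, size=span, p=list(reg.probs))]
        for gc, gs, ge in cfg.gap_regions:
            if gc == chrom:
                arr[gs:ge] = ord("N")
        seqs[chrom] = arr.tobytes().decode("ascii")
    mask = RegionMask(
        StrandedInterval(c, s, e, ".") for c, s, e in cfg.gap_regions
    )
    return GenomeData(seqs=seqs, layout=layout, mask=mask)


def _lognormal_int(
    rng: np.random.Generator, median: float, sigma: float, lo: int, hi: int
) -> int:
    return int(np.clip(round(rng.lognormal(np.log(median), sigma)), lo, hi))


def _generate_transcripts(cfg: SimulationConfig, layout: GenomeLayout) -> list[TranscriptModel]:
    rng = _rngs(cfg.seed)[2]
    gaps_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for c, s, e in cfg.gap_regions:
        gaps_by_chrom.setdefault(c, []).append((s, e))
    out: list[TranscriptModel] = []
    idx = 0
    chroms = [c for c in layout if c != cfg.mito_chrom]
    for chrom in chroms:
        length = layout[chrom]
        pos = int(rng.exponential(cfg.intergenic_mean)) + 200
        while idx < cfg.n_transcripts:
            L = _lognormal_int(rng, cfg.tx_len_median, cfg.tx_len_sigma, 500, 20_000)
            start, end = pos, pos + L
            if end > length - 200:
                break
            blocked = next(
                (
                    (gs, ge)
                    for gs, ge in gaps_by_chrom.get(chrom, [])
                    if start < ge and end > gs
                ),
                None,
            )
            if blocked is not None:
                pos = blocked[1] + int(rng.exponential(cfg.intergenic_mean)) + 200
                continue
            strand = "+" if rng.random() < 0.5 else "-"
            exons = _split_exons(rng, start, end)
            if rng.random() < cfg.coding_fraction and L > 600:
                trim = int(0.15 * L)
                thick_start, thick_end = start + trim, end - trim
            else:
                thick_start = thick_end = start
            idx += 1
            out.append(
                TranscriptModel(
                    transcript_id=f"tx{idx:04d}",
                    chrom=chrom,
                    start=start,
                    end=end,
                    strand=strand,
                    exons=exons,
                    gene_id=f"gene{idx:04d}",
                    thick_start=thick_start,
                    thick_end=thick_end,
                )
            )
            pos = end + int(rng.exponential(cfg.intergenic_mean)) + 200
    return out


def _split_exons(rng: np.random.Generator, start: int, end: int) -> list[tuple[int, int]]:
    L = end - start
    n_ex = int(rng.integers(1, 5))
    if n_ex == 1 or L < 800:
        return [(start, end)]
    # introns carved from the interior, leaving terminal exons intact
    cuts = np.sort(rng.integers(int(0.1 * L), int(0.9 * L), size=2 * (n_ex - 1)))
    exons: list[tuple[int, int]] = []
    prev = 0
    for k in range(n_ex - 1):
        i_s, i_e = int(cuts[2 * k]), int(cuts[2 * k + 1])
        if i_e - i_s < 30 or i_s - prev < 50:
            continue
        exons.append((start + prev, start + i_s))
        prev = i_e
    exons.append((start + prev, end))
    return exons


def _quartile_index(fpkm: np.ndarray) -> np.ndarray:
    s = np.sort(fpkm)
    first_rank = np.searchsorted(s, fpkm, side="left")
    return (4 * first_rank) // len(fpkm)


def _place_in_gene(
    rng: np.random.Generator,
    tx: TranscriptModel,
    peak_len: int,
    bias: Mapping[str, float],
    chrom_len: int,
) -> tuple[int, int]:
    modes, weights = zip(*sorted(bias.items()))
    w = np.asarray(weights, dtype=float)
    mode = modes[int(rng.choice(len(modes), p=w / w.sum()))]
    if mode == "tss":
        center = tx.tss + int(rng.integers(-200, 201))
    elif mode == "tts":
        center = tx.tts + int(rng.integers(-200, 201))
    else:
        center = int(rng.integers(tx.start, tx.end))
    start = max(0, min(center - peak_len // 2, chrom_len - peak_len))
    return start, start + peak_len


def generate_tracks(cfg: SimulationConfig, genome: GenomeData) -> TrackSet:
    """Generate transcripts, expression, stranded peaks, markers and probes
    with the planted couplings described in the module docstring."""
    cfg.validate()
    layout, mask = genome.layout, genome.mask
    rng_expr = _rngs(cfg.seed)[3]
    rng_marker = _rngs(cfg.seed)[4]
    rng_probe = _rngs(cfg.seed)[5]
    rng_calls = _rngs(cfg.seed)[6]

    transcripts = _generate_transcripts(cfg, layout)
    free = FreeSpace(layout, mask)

    # --- expression and genic R-loop peaks, coupled through quartile odds ---
    expression: dict[str, pd.DataFrame] = {}
    rloops: dict[str, list[StrandedInterval]] = {}
    true_rloop_genes: dict[str, list[str]] = {}
    for sample in cfg.samples:
        fpkm = rng_expr.lognormal(cfg.fpkm_log_mean, cfg.fpkm_log_sigma, len(transcripts))
        qidx = _quartile_index(fpkm)
        p = np.where(
            qidx == 3, cfg.quartile_odds * cfg.gene_rloop_rate, cfg.gene_rloop_rate
        )
        positive = rng_expr.random(len(transcripts)) < p
        peaks: list[StrandedInterval] = []
        bias = cfg.placement_bias.get(sample, {"tss": 0.4, "body": 0.5, "tts": 0.1})
        pos_genes = []
        for i, tx in enumerate(transcripts):
            if not positive[i]:
                continue
            pos_genes.append(tx.transcript_id)
            n_peaks = 1 + int(
                rng_expr.poisson(cfg.count_lambda_base + cfg.count_lambda_slope * qidx[i])
            )
            for k in range(n_peaks):
                L = _lognormal_int(
                    rng_expr,
                    cfg.peak_len_median,
                    cfg.peak_len_sigma,
                    cfg.peak_len_min,
                    min(cfg.peak_len_max, max(cfg.peak_len_min, len(tx))),
                )
                s, e = _place_in_gene(rng_expr, tx, L, bias, layout[tx.chrom])
                peaks.append(
                    StrandedInterval(
                        tx.chrom, s, e, tx.strand, f"{sample}_{tx.transcript_id}_pk{k}"
                    )
                )
        for k in range(cfg.n_background_peaks):
            L = _lognormal_int(
                rng_expr,
                cfg.peak_len_median,
                cfg.peak_len_sigma,
                cfg.peak_len_min,
                cfg.peak_len_max,
            )
            g = free.sample_starts(L, 1, rng_expr, label=f"{sample}_bg{k}")[0]
            chrom, s = free.to_local(int(g))
            strand = "+" if rng_expr.random() < 0.5 else "-"
            peaks.append(StrandedInterval(chrom, s, s + L, strand, f"{sample}_bg{k}"))
        expression[sample] = pd.DataFrame(
            {
                "transcript_id": [tx.transcript_id for tx in transcripts],
                "fpkm": np.round(fpkm, 6),
            }
        )
        rloops[sample] = peaks
        true_rloop_genes[sample] = pos_genes

    # planted expression shift for sample-specific R-loop genes (first two samples)
    if cfg.delta_fpkm != 0.0 and len(cfg.samples) >= 2:
        a, b = cfg.samples[0], cfg.samples[1]
        only_a = set(true_rloop_genes[a]) - set(true_rloop_genes[b])
        ea = expression[a]
        ea.loc[ea["transcript_id"].isin(only_a), "fpkm"] += cfg.delta_fpkm

    # peaks planted at skew-transition sites
    site_peaks = [
        StrandedInterval(left.chrom, center - 300, center + 300, strand, f"site{i}")
        for i, (left, right, strand, center) in enumerate(_skew_site_regions(cfg))
    ]

    # --- raw two-control calls emulating peak calling against both controls ---
    raw_calls: dict[str, SampleCalls] = {}
    for sample in cfg.samples:
        calls: dict[str, StrandCalls] = {}
        for strand in ("+", "-"):
            final = [pk for pk in rloops[sample] if pk.strand == strand]
            n_noise = max(1, int(cfg.call_noise_fraction * len(final)))
            vs_input = list(final) + _noise_peaks(
                cfg, free, rng_calls, strand, n_noise, f"{sample}_in"
            )
            jittered = []
            for pk in final:
                j = int(rng_calls.integers(-cfg.call_jitter, cfg.call_jitter + 1))
                s = max(0, min(pk.start + j, free.layout[pk.chrom] - len(pk)))
                jittered.append(
                    StrandedInterval(pk.chrom, s, s + len(pk), strand, pk.id)
                )
            vs_rnaseh = jittered + _noise_peaks(
                cfg, free, rng_calls, strand, n_noise, f"{sample}_rh"
            )
            calls[strand] = StrandCalls(vs_input, vs_rnaseh)
        raw_calls[sample] = SampleCalls(sample, calls)

    # --- markers with planted bp-overlap enrichment rho ---
    target = rloops.get(cfg.marker_target_sample) or next(iter(rloops.values()))
    markers = {
        mp.name: _generate_marker(cfg, mp, target, layout, mask, free, rng_marker)
        for mp in cfg.marker_programs
    }

    # --- two-regime probe map and ChIP-chip-like peaks from the dense regime ---
    probes = _generate_probes(cfg, layout, mask)
    chipchip = _generate_chipchip_peaks(cfg, layout, mask, rng_probe)

    ground_truth = {
        "rho": {mp.name: mp.rho for mp in cfg.marker_programs},
        "quartile_odds": cfg.quartile_odds,
        "gene_rloop_rate": cfg.gene_rloop_rate,
        "delta_fpkm": cfg.delta_fpkm,
        "true_rloop_genes": true_rloop_genes,
        "skew_sites": [
            {"chrom": l.chrom, "center": c, "strand": st}
            for l, r, st, c in _skew_site_regions(cfg)
        ],
        "skew_site_at_delta": cfg.skew_site_at_delta,
        "probe_regimes": {
            "dense": {
                "region": list(cfg.probe_dense_region),
                "spacing": cfg.probe_dense_spacing,
            },
            "sparse": {"spacing": cfg.probe_sparse_spacing},
        },
    }
    return TrackSet(
        transcripts=transcripts,
        expression=expression,
        rloops=rloops,
        raw_calls=raw_calls,
        site_peaks=site_peaks,
        markers=markers,
        probes=probes,
        chipchip_peaks=chipchip,
        ground_truth=ground_truth,
    )


def _noise_peaks(cfg, free, rng, strand, n, tag) -> list[StrandedInterval]:
    out = []
    for k in range(n):
        L = _lognormal_int(
            rng, cfg.peak_len_median, cfg.peak_len_sigma, cfg.peak_len_min, cfg.peak_len_max
        )
        g = free.sample_starts(L, 1, rng, label=f"{tag}{k}")[0]
        chrom, s = free.to_local(int(g))
        out.append(StrandedInterval(chrom, s, s + L, strand, f"{tag}{k}"))
    return out


def _expected_uniform_overlap(
    free: FreeSpace,
    merged: RegionMask,
    length: int,
    rng: np.random.Generator,
    n_draws: int = 50_000,
) -> float:
    """Mean bp a uniformly placed interval of the given length shares with
    the merged territory (accounts for edge effects near mask gaps)."""
    offsets = free.offsets
    ts, te = [], []
    for iv in merged.intervals():
        ts.append(offsets[iv.chrom] + iv.start)
        te.append(offsets[iv.chrom] + iv.end)
    order = np.argsort(ts)
    ts = np.asarray(ts, dtype=np.int64)[order]
    te = np.asarray(te, dtype=np.int64)[order]
    prefix = np.concatenate(([0], np.cumsum(te - ts)))

    def cumcov(x: np.ndarray) -> np.ndarray:
        i = np.searchsorted(ts, x, side="right")
        over = np.where(
            i > 0, np.maximum(te[np.maximum(i, 1) - 1] - x, 0), 0
        )
        return prefix[i] - over

    s = free.sample_starts(length, n_draws, rng)
    return float(np.mean(cumcov(s + length) - cumcov(s)))


def _generate_marker(
    cfg: SimulationConfig,
    mp: MarkerProgram,
    rloops: Sequence[StrandedInterval],
    layout: GenomeLayout,
    mask: RegionMask,
    free: FreeSpace,
    rng: np.random.Generator,
) -> list[StrandedInterval]:
    """Markers realizing a planted observed/null overlap ratio of rho.

    rho == 1 markers are placed uniformly over the mask-free genome,
    independent of the R-loop peaks.  For rho != 1 the track decomposes
    exactly: round(rho * n_peaks * mu / L) peaks sit fully inside R-loop
    territory (mu being the expected overlap of one uniformly placed peak)
    and the remainder avoid the territory entirely, so the expected overlap
    equals rho times the permutation-null expectation by construction.
    """
    L = mp.peak_len
    out: list[StrandedInterval] = []
    if mp.rho == 1.0:
        for k in range(mp.n_peaks):
            g = free.sample_starts(L, 1, rng, label=f"{mp.name}_{k}")[0]
            chrom, s = free.to_local(int(g))
            out.append(StrandedInterval(chrom, s, s + L, ".", f"{mp.name}_{k}"))
        return out

    merged = RegionMask(rloops)  # merged, unstranded R-loop territory
    mu = _expected_uniform_overlap(free, merged, L, rng)
    n_in = int(round(mp.rho * mp.n_peaks * mu / L))
    if n_in > mp.n_peaks:
        raise ValueError(
            f"marker {mp.name}: planted rho={mp.rho} infeasible "
            f"(would need {n_in} of {mp.n_peaks} peaks inside R-loop territory)"
        )
    hosts = [pk for pk in rloops if len(pk) >= L]
    if n_in > 0 and not hosts:
        raise ValueError(f"marker {mp.name}: no R-loop peak can host length {L}")
    host_w = np.array([len(pk) - L + 1 for pk in hosts], dtype=float)
    avoid_mask = RegionMask(mask.intervals() + list(merged.intervals()))
    free_avoid = FreeSpace(layout, avoid_mask)
    planted = set(rng.permutation(mp.n_peaks)[:n_in].tolist())
    for k in range(mp.n_peaks):
        if k in planted:
            h = hosts[int(rng.choice(len(hosts), p=host_w / host_w.sum()))]
            s = int(rng.integers(h.start, h.end - L + 1))
            out.append(StrandedInterval(h.chrom, s, s + L, ".", f"{mp.name}_{k}"))
        else:
            g = free_avoid.sample_starts(L, 1, rng, label=f"{mp.name}_{k}")[0]
            chrom, s = free_avoid.to_local(int(g))
            out.append(StrandedInterval(chrom, s, s + L, ".", f"{mp.name}_{k}"))
    return out


def _generate_probes(
    cfg: SimulationConfig, layout: GenomeLayout, mask: RegionMask
) -> list[StrandedInterval]:
    dchrom, dstart, dend = cfg.probe_dense_region
    out: list[StrandedInterval] = []
    i = 0
    for chrom, length in layout.items():
        if chrom == cfg.mito_chrom:
            continue
        pos = 0
        while pos + cfg.probe_len <= length:
            in_dense = chrom == dchrom and dstart <= pos < dend
            spacing = cfg.probe_dense_spacing if in_dense else cfg.probe_sparse_spacing
            if not mask.overlaps(chrom, pos, pos + cfg.probe_len):
                out.append(
                    StrandedInterval(chrom, pos, pos + cfg.probe_len, ".", f"probe{i}")
                )
                i += 1
            pos += spacing
    return out


def _generate_chipchip_peaks(
    cfg: SimulationConfig,
    layout: GenomeLayout,
    mask: RegionMask,
    rng: np.random.Generator,
) -> list[StrandedInterval]:
    """ChIP-chip-like peaks drawn entirely from the dense probe regime."""
    dchrom, dstart, dend = cfg.probe_dense_region
    out = []
    for k in range(cfg.n_chipchip_peaks):
        L = _lognormal_int(
            rng, cfg.chipchip_len_median, cfg.chipchip_len_sigma, 200, 5000
        )
        while True:
            s = int(rng.integers(dstart, dend - L))
            if not mask.overlaps(dchrom, s, s + L):
                break
        out.append(StrandedInterval(dchrom, s, s + L, ".", f"chip{k}"))
    return out


def generate_dataset(
    cfg: SimulationConfig | None = None,
    outdir: str | os.PathLike | None = None,
) -> SyntheticDataset:
    """Generate genome plus all tracks; optionally write every file."""
    cfg = cfg or SimulationConfig()
    genome = generate_genome(cfg)
    tracks = generate_tracks(cfg, genome)
    ds = SyntheticDataset(config=cfg, genome=genome, tracks=tracks)
    if outdir is not None:
        write_dataset(ds, outdir)
    return ds


def write_dataset(ds: SyntheticDataset, outdir: str | os.PathLike) -> None:
    """Write the full dataset as plain-text files (byte-stable given the seed).

    The ground truth goes to a separate sidecar (``ground_truth.json``)
    that no pipeline stage reads.
    """
    outdir = str(outdir)
    os.makedirs(outdir, exist_ok=True)
    for sub in ("peaks", "calls", "markers", "expression"):
        os.makedirs(os.path.join(outdir, sub), exist_ok=True)
    rio.write_fasta(ds.genome.seqs, os.path.join(outdir, "genome.fa"))
    rio.write_chrom_sizes(ds.layout, os.path.join(outdir, "chrom.sizes"))
    rio.write_bed(ds.mask.intervals(), os.path.join(outdir, "mask.bed"))
    rio.write_bed12(ds.tracks.transcripts, os.path.join(outdir, "transcripts.bed12"))
    strand_tag = {"+": "plus", "-": "minus"}
    for sample, peaks in ds.tracks.rloops.items():
        for strand, tag in strand_tag.items():
            rio.write_bed(
                [pk for pk in peaks if pk.strand == strand],
                os.path.join(outdir, "peaks", f"{sample}.{tag}.bed"),
            )
    for sample, sc in ds.tracks.raw_calls.items():
        for strand, tag in strand_tag.items():
            rio.write_bed(
                sc.calls[strand].peaks_vs_input,
                os.path.join(outdir, "calls", f"{sample}.{tag}.vs_input.bed"),
            )
            rio.write_bed(
                sc.calls[strand].peaks_vs_rnaseh,
                os.path.join(outdir, "calls", f"{sample}.{tag}.vs_rnaseh.bed"),
            )
    for sample, df in ds.tracks.expression.items():
        rio.write_expression_table(
            df, os.path.join(outdir, "expression", f"{sample}.tsv")
        )
    for name, peaks in ds.tracks.markers.items():
        rio.write_bed(peaks, os.path.join(outdir, "markers", f"{name}.bed"))
    rio.write_bed(ds.tracks.probes, os.path.join(outdir, "probes.bed"))
    rio.write_bed(ds.tracks.chipchip_peaks, os.path.join(outdir, "chipchip_peaks.bed"))
    rio.write_bed(ds.tracks.site_peaks, os.path.join(outdir, "site_peaks.bed"))
    with open(os.path.join(outdir, "ground_truth.json"), "w") as fh:
        json.dump(ds.tracks.ground_truth, fh, indent=1, sort_keys=True)
        fh.write("\n")
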