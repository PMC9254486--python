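"""Linking R-loop occupancy to nascent transcription.

Transcripts are binned into expression quartiles (Q1 lowest .. Q4 highest)
from a per-transcript FPKM table (e.g. GRO-seq), R-loop peaks are linked to
transcripts by strand-matched overlap, and three questions are asked: which
quartiles do R-loop genes come from, how many peaks per gene as a function
of expression, and is developmental-specific R-loop formation explained by
expression differences between samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .intervals import StrandedInterval, TranscriptModel

QUARTILES = ("Q1", "Q2", "Q3", "Q4")


def assign_quartiles(expr: pd.DataFrame) -> pd.DataFrame:
    """Add a ``quartile`` column splitting FPKM at the empirical
    25/50/75 percentiles.

    Ties at a boundary all go to the lower quartile, so a value never
    straddles two quartiles.  With no ties, group sizes differ by at most
    one.  All-equal input degenerates to all-Q1 with a warning.
    """
    if len(expr) < 4:
        raise ValueError("quartile assignment requires at least 4 records")
    out = expr.copy()
    f = out["fpkm"].to_numpy(dtype=float)
    s = np.sort(f)
    first_rank = np.searchsorted(s, f, side="left")
    q = (4 * first_rank) // len(f)
    out["quartile"] = [QUARTILES[int(i)] for i in q]
    if (q == 0).all():
        warnings.warn("all FPKM values identical; every transcript assigned Q1")
    return out


def link_rloops_to_genes(
    peaks: Sequence[StrandedInterval],
    transcripts: Sequence[TranscriptModel],
) -> pd.DataFrame:
    """Count strand-matched R-loop peaks per transcript.

    A peak links to a transcript iff it overlaps it and their strands
    match; a peak spanning several same-strand genes counts for each of
    them.  Returns one row per transcript with ``n_peaks`` and
    ``has_rloop``.
    """
    trees: dict[str, IntervalTree] = {}
    for tx in transcripts:
        trees.setdefault(tx.chrom, IntervalTree()).addi(tx.start, tx.end, tx)
    counts = {tx.transcript_id: 0 for tx in transcripts}
    for pk in peaks:
        if pk.strand not in ("+", "-"):
            raise ValueError(
                f"peak {pk.chrom}:{pk.start}-{pk.end} is unstranded; "
                "gene linking requires stranded peaks"
            )
        tree = trees.get(pk.chrom)
        if tree is None:
            continue
        for hit in tree.overlap(pk.start, pk.end):
            tx: TranscriptModel = hit.data
            if tx.strand == pk.strand:
                counts[tx.transcript_id] += 1
    df = pd.DataFrame(
        {
            "transcript_id": list(counts),
            "n_peaks": list(counts.values()),
        }
    )
    df["has_rloop"] = df["n_peaks"] >= 1
    return df


def quartile_occupancy(links: pd.DataFrame, expr: pd.DataFrame) -> pd.DataFrame:
    """Fraction of R-loop-positive genes falling in each expression quartile,
    against the uniform 25% expectation (binomial test, Bonferroni x4)."""
    expr = expr if "quartile" in expr.columns else assign_quartiles(expr)
    merged = links.merge(expr[["transcript_id", "quartile"]], on="transcript_id")
    pos = merged[merged["has_rloop"]]
    n = len(pos)
    rows = []
    for q in QUARTILES:
        k = int((pos["quartile"] == q).sum())
        frac = k / n if n else np.nan
        p = stats.binomtest(k, n, 0.25).pvalue if n else np.nan
        rows.append(
            {
                "quartile": q,
                "n_rloop_genes": k,
                "fraction": frac,
                "expected": 0.25,
                "p_value": p,
                "p_adjusted": min(1.0, 4 * p) if n else np.nan,
            }
        )
    return pd.DataFrame(rows)


def peaks_per_gene_by_quartile(
    links: pd.DataFrame, expr: pd.DataFrame, positive_only: bool = True
) -> pd.Series:
    """Mean peak count per gene in each quartile.

    By default the mean is over R-loop-positive genes (so it is >= 1 by
    construction); with ``positive_only=False`` it averages over every gene
    in the quartile.  Empty quartiles give NaN.
    """
    expr = expr if "quartile" in expr.columns else assign_quartiles(expr)
    merged = links.merge(expr[["transcript_id", "quartile"]], on="transcript_id")
    if positive_only:
        merged = merged[merged["has_rloop"]]
    means = merged.groupby("quartile")["n_peaks"].mean()
    return means.reindex(QUARTILES)


@dataclass
class SpecificityResult:
    """Per-gene expression differences for sample-specific R-loop genes."""

    table: pd.DataFrame  # transcript_id, specific_to, delta_fpkm
    median_delta: float
    sign_test_p: float
    n_genes: int


def specificity_vs_expression(
    links_a: pd.DataFrame,
    links_b: pd.DataFrame,
    expr_a: pd.DataFrame,
    expr_b: pd.DataFrame,
    name_a: str = "a",
    name_b: str = "b",
) -> SpecificityResult:
    """For genes with an R-loop in exactly one sample, the per-gene FPKM
    difference (sample a minus sample b), its median, and a sign test
    against median zero.

    If sample-specific R-loop formation tracked transcription, the deltas
    for a-specific genes would skew positive (and vice versa); a median
    near zero says specificity is not expression-driven.
    """
    a = links_a.set_index("transcript_id")["has_rloop"]
    b = links_b.set_index("transcript_id")["has_rloop"]
    shared = a.index.intersection(b.index)
    if not a.index.equals(b.index):
        warnings.warn("samples do not share an identical transcript universe; using intersection")
    specific = shared[(a[shared] & ~b[shared]) | (~a[shared] & b[shared])]
    if len(specific) == 0:
        warnings.warn("no sample-specific R-loop genes found")
        return SpecificityResult(
            pd.DataFrame(columns=["transcript_id", "specific_to", "delta_fpkm"]),
            np.nan,
            np.nan,
            0,
        )
    fa = expr_a.set_index("transcript_id")["fpkm"]
    fb = expr_b.set_index("transcript_id")["fpkm"]
    delta = fa[specific] - fb[specific]
    table = pd.DataFrame(
        {
            "transcript_id": specific,
            "specific_to": np.where(a[specific], name_a, name_b),
            "delta_fpkm": delta.to_numpy(),
        }
    )
    nonzero = delta[delta != 0]
    if len(nonzero):
        k = int((nonzero > 0).sum())
        p = stats.binomtest(k, len(nonzero), 0.5).pvalue
    else:
        p = 1.0
    return SpecificityResult(table, float(delta.median()), float(p), len(specific))


def expression_by_rloop_status(
    links: pd.DataFrame, expr: pd.DataFrame
) -> dict[str, float]:
    """Compare FPKM of R-loop-positive vs -negative genes (rank-sum test)."""
    merged = links.merge(expr[["transcript_id", "fpkm"]], on="transcript_id")
    pos = merged.loc[merged["has_rloop"], "fpkm"]
    neg = merged.loc[~merged["has_rloop"], "fpkm"]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both R-loop-positive and -negative genes are required")
    stat = stats.mannwhitneyu(pos, neg, alternative="two-sided")
    return {
        "median_positive": float(pos.median()),
        "median_negative": float(neg.median()),
        "n_positive": int(len(pos)),
        "n_negative": int(len(neg)),
        "p_value": float(stat.pvalue),
    }
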