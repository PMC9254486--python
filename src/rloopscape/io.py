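"""Readers and writers for the plain-text genomics formats the pipeline consumes.

BED3/BED6/BED12, two-column chrom.sizes, four-column bedGraph, FASTA (indexed
access via pyfaidx) and transcript-level expression tables.
"""

from __future__ import annotations

import os
from typing import Iterable, Mapping

import pandas as pd
from pyfaidx import Fasta

from .intervals import (
    GenomeLayout,
    StrandedInterval,
    TranscriptModel,
    ValidationError,
)


class BedParseError(ValueError):
    pass


def _fmt_score(score: float | None) -> str:
    if score is None:
        return "0"
    return f"{score:g}"


def read_chrom_sizes(path: str | os.PathLike) -> GenomeLayout:
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise BedParseError(f"{path}:{lineno}: expected 2 tab-separated columns")
            sizes[fields[0]] = int(fields[1])
    return GenomeLayout(sizes)


def write_chrom_sizes(layout: GenomeLayout, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for name, length in layout.items():
            fh.write(f"{name}\t{length}\n")


def read_bed(
    path: str | os.PathLike,
    expect_strand: bool = False,
    layout: GenomeLayout | None = None,
    rename: Mapping[str, str] | None = None,
) -> list[StrandedInterval]:
    """Read BED3 or BED6 into stranded intervals, in file order.

    With ``expect_strand`` a missing strand column is an error; otherwise
    3-column records get strand '.'.  Out-of-bounds intervals are rejected
    when a ``layout`` is bound.  Chromosome names absent from the layout are
    an error, not silently dropped; a ``rename`` map handles convention
    mismatches such as ``2L`` vs ``chr2L``.
    """
    out: list[StrandedInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedParseError(f"{path}:{lineno}: expected at least 3 columns")
            chrom = fields[0]
            if rename:
                chrom = rename.get(chrom, chrom)
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: non-integer coordinates") from exc
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            score = None
            if len(fields) > 4 and fields[4] != ".":
                try:
                    score = float(fields[4])
                except ValueError as exc:
                    raise BedParseError(f"{path}:{lineno}: non-numeric score") from exc
            if len(fields) > 5:
                strand = fields[5]
            elif expect_strand:
                raise BedParseError(f"{path}:{lineno}: strand column required but absent")
            else:
                strand = "."
            try:
                iv = StrandedInterval(chrom, start, end, strand, name, score)
                if layout is not None:
                    layout.validate(iv)
            except ValidationError as exc:
                raise BedParseError(f"{path}:{lineno}: {exc}") from exc
            out.append(iv)
    return out


def write_bed(intervals: Iterable[StrandedInterval], path: str | os.PathLike) -> None:
    """Write BED6; round-trips byte-identically with :func:`read_bed` for valid BED6."""
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.id or '.'}\t"
                f"{_fmt_score(iv.score)}\t{iv.strand}\n"
            )


def read_bed12(
    path: str | os.PathLike,
    layout: GenomeLayout | None = None,
    rename: Mapping[str, str] | None = None,
) -> list[TranscriptModel]:
    """Read BED12 gene models. The name column carries ``transcript_id`` or
    ``gene_id|transcript_id``."""
    out: list[TranscriptModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise BedParseError(f"{path}:{lineno}: expected 12 columns")
            chrom = fields[0]
            if rename:
                chrom = rename.get(chrom, chrom)
            try:
                start, end = int(fields[1]), int(fields[2])
                thick_start, thick_end = int(fields[6]), int(fields[7])
                n_blocks = int(fields[9])
                sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
                offsets = [int(x) for x in fields[11].rstrip(",").split(",")]
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: malformed numeric field") from exc
            if len(sizes) != n_blocks or len(offsets) != n_blocks:
                raise BedParseError(f"{path}:{lineno}: block count mismatch")
            name = fields[3]
            gene_id, _, tx_id = name.partition("|")
            if not tx_id:
                gene_id, tx_id = None, name
            exons = [(start + o, start + o + s) for o, s in zip(offsets, sizes)]
            try:
                tx = TranscriptModel(
                    transcript_id=tx_id,
                    chrom=chrom,
                    start=start,
                    end=end,
                    strand=fields[5],
                    exons=exons,
                    gene_id=gene_id,
                    thick_start=thick_start,
                    thick_end=thick_end,
                )
                if layout is not None:
                    layout.validate(tx.as_interval())
            except ValidationError as exc:
                raise BedParseError(f"{path}:{lineno}: {exc}") from exc
            out.append(tx)
    return out


def write_bed12(transcripts: Iterable[TranscriptModel], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for tx in transcripts:
            name = (
                tx.transcript_id
                if tx.gene_id in (None, tx.transcript_id)
                else f"{tx.gene_id}|{tx.transcript_id}"
            )
            sizes = ",".join(str(e - s) for s, e in tx.exons)
            offsets = ",".join(str(s - tx.start) for s, e in tx.exons)
            ts = tx.thick_start if tx.thick_start is not None else tx.start
            te = tx.thick_end if tx.thick_end is not None else tx.start
            fh.write(
                f"{tx.chrom}\t{tx.start}\t{tx.end}\t{name}\t0\t{tx.strand}\t"
                f"{ts}\t{te}\t0\t{len(tx.exons)}\t{sizes},\t{offsets},\n"
            )


def open_fasta(path: str | os.PathLike) -> Fasta:
    """Indexed FASTA access (builds a .fai sidecar on first use)."""
    return Fasta(str(path), as_raw=True, sequence_always_upper=False)


def write_fasta(seqs: Mapping[str, str], path: str | os.PathLike, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_bedgraph(
    entries: Iterable[tuple[str, int, int, float]], path: str | os.PathLike
) -> None:
    with open(path, "w") as fh:
        for chrom, start, end, value in entries:
            fh.write(f"{chrom}\t{start}\t{end}\t{value:g}\n")


def read_bedgraph(path: str | os.PathLike) -> list[tuple[str, int, int, float]]:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise BedParseError(f"{path}:{lineno}: expected 4 columns")
            out.append((fields[0], int(fields[1]), int(fields[2]), float(fields[3])))
    return out


def read_expression_table(path: str | os.PathLike) -> pd.DataFrame:
    """TSV with columns ``transcript_id`` and ``fpkm`` (header required)."""
    df = pd.read_csv(path, sep="\t")
    missing = {"transcript_id", "fpkm"} - set(df.columns)
    if missing:
        raise BedParseError(f"{path}: missing columns {sorted(missing)}")
    if (df["fpkm"] < 0).any():
        raise ValidationError(f"{path}: negative FPKM values")
    return df[["transcript_id", "fpkm"]].copy()


def write_expression_table(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
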