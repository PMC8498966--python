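"""Readers and writers for peak files and gene annotations.

Accepted peak dialects: BED3/BED6, ENCODE narrowPeak, and the package's
own headered TSV (``chrom start end height total_signal``). Gene
annotations: BED12, GTF-like, or a simple TSS table. All coordinates are
normalised to 0-based half-open on read; GTF starts are shifted by -1.
"""
from __future__ import annotations

import logging
import re
from pathlib import Path
from typing import Sequence

import pandas as pd

from .model import FeatureTrack, GeneModel, GenomicInterval, PEAK_COLUMNS

log = logging.getLogger(__name__)


class PeakFileError(ValueError):
    """Raised for unparseable peak or annotation records; names the line."""


def _parse_coords(fields: list[str], path: str, lineno: int) -> tuple[str, int, int]:
    try:
        chrom, start, end = fields[0], int(fields[1]), int(fields[2])
    except (IndexError, ValueError) as exc:
        raise PeakFileError(f"{path}:{lineno}: unparseable coordinates: {fields[:3]}") from exc
    if end <= start or start < 0:
        raise PeakFileError(f"{path}:{lineno}: invalid interval [{start}, {end})")
    return chrom, start, end


def _data_lines(path: Path):
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            yield lineno, line.split("\t") if "\t" in line else line.split()


def read_peaks(
    path: str | Path,
    format: str = "auto",
    feature_name: str | None = None,
    cell_type: str = "unknown",
) -> FeatureTrack:
    """Read a peak file into a :class:`FeatureTrack`.

    Parameters
    ----------
    format
        ``bed`` (3+ columns, no signal: height and total_signal fall back
        to the peak width and the track is flagged degenerate),
        ``narrowPeak`` (ENCODE 10-column; height = signalValue,
        total_signal = signalValue x width), ``table`` (this package's
        headered TSV), or ``auto`` (sniffed from header/column count).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if feature_name is None:
        feature_name = re.sub(r"\.(bed|narrowPeak|tsv|txt)$", "", path.name)

    if format == "auto":
        format = _sniff_format(path)

    if format == "table":
        df = pd.read_csv(path, sep="\t", comment="#")
        missing = set(PEAK_COLUMNS) - set(df.columns)
        if missing:
            raise PeakFileError(f"{path}: table format missing columns {sorted(missing)}")
        bad = df[(df["end"] <= df["start"]) | (df["start"] < 0)]
        if len(bad):
            raise PeakFileError(f"{path}: row {bad.index[0] + 2}: invalid interval")
        return FeatureTrack(feature_name, cell_type, df[PEAK_COLUMNS])

    rows: list[tuple] = []
    signal_is_width = False
    for lineno, fields in _data_lines(path):
        chrom, start, end = _parse_coords(fields, str(path), lineno)
        width = end - start
        if format == "narrowPeak":
            if len(fields) < 7:
                raise PeakFileError(
                    f"{path}:{lineno}: narrowPeak requires a signalValue column (7th)"
                )
            signal_value = float(fields[6])
            rows.append((chrom, start, end, signal_value, signal_value * width))
        elif format == "bed":
            rows.append((chrom, start, end, float(width), float(width)))
            signal_is_width = True
        else:
            raise ValueError(f"unknown peak format: {format!r}")
    if signal_is_width:
        log.warning(
            "%s: plain BED without signal; height and total_signal fall back to peak width",
            path,
        )
    df = pd.DataFrame(rows, columns=PEAK_COLUMNS)
    return FeatureTrack(feature_name, cell_type, df, signal_is_width=signal_is_width)


def _sniff_format(path: Path) -> str:
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("chrom\t") or first.split("\t")[:3] == ["chrom", "start", "end"]:
        return "table"
    n = len(first.rstrip("\n").split("\t") if "\t" in first else first.split())
    return "narrowPeak" if n >= 10 else "bed"


def write_track(track: FeatureTrack, path: str | Path) -> None:
    """Write a track as headered TSV; round-trips through ``read_peaks``."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# feature={track.feature_name} cell_type={track.cell_type}\n")
        track.df.to_csv(fh, sep="\t", index=False)


def write_narrowpeak(track: FeatureTrack, path: str | Path) -> None:
    df = track.df
    out = pd.DataFrame(
        {
            "chrom": df["chrom"],
            "start": df["start"],
            "end": df["end"],
            "name": [f"{track.feature_name}_{i}" for i in range(len(df))],
            "score": 0,
            "strand": ".",
            "signalValue": df["height"],
            "pValue": -1,
            "qValue": -1,
            "peak": -1,
        }
    )
    out.to_csv(path, sep="\t", index=False, header=False)


# ---------------------------------------------------------------- genes


def read_genes(path: str | Path, format: str = "auto") -> list[GeneModel]:
    """Read a gene annotation into a list of :class:`GeneModel`.

    For multi-transcript or duplicated gene ids, one representative model
    per gene id is kept: the most upstream TSS on the gene's strand, with
    the union of the records' bodies. BED12 and the TSS table are 0-based;
    GTF-like input is 1-based inclusive and is shifted on read.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "auto":
        with open(path) as fh:
            first = fh.readline().rstrip("\n")
        if first.startswith("gene_id"):
            format = "tss-table"
        elif len(first.split("\t")) >= 12:
            format = "bed12"
        else:
            format = "gtf"

    records: list[tuple[str, str, str, int, int]] = []  # gene_id, chrom, strand, start, end
    if format == "bed12":
        for lineno, fields in _data_lines(path):
            chrom, start, end = _parse_coords(fields, str(path), lineno)
            if len(fields) < 6 or fields[5] not in {"+", "-"}:
                raise PeakFileError(f"{path}:{lineno}: missing or invalid strand")
            records.append((fields[3], chrom, fields[5], start, end))
    elif format == "gtf":
        for lineno, fields in _data_lines(path):
            if len(fields) < 9:
                raise PeakFileError(f"{path}:{lineno}: GTF-like line with <9 columns")
            chrom, strand = fields[0], fields[6]
            if strand not in {"+", "-"}:
                raise PeakFileError(f"{path}:{lineno}: missing or invalid strand")
            try:
                start, end = int(fields[3]) - 1, int(fields[4])  # 1-based incl -> 0-based half-open
            except ValueError as exc:
                raise PeakFileError(f"{path}:{lineno}: unparseable coordinates") from exc
            m = re.search(r'gene_id[ =]"?([^";]+)"?', fields[8])
            if not m:
                raise PeakFileError(f"{path}:{lineno}: no gene_id attribute")
            records.append((m.group(1), chrom, strand, start, end))
    elif format == "tss-table":
        df = pd.read_csv(path, sep="\t", comment="#")
        required = {"gene_id", "chrom", "strand", "body_start", "body_end"}
        if not required <= set(df.columns):
            raise PeakFileError(f"{path}: tss-table needs columns {sorted(required)}")
        if not df["strand"].isin(["+", "-"]).all():
            raise PeakFileError(f"{path}: missing or invalid strand")
        records = list(
            df[["gene_id", "chrom", "strand", "body_start", "body_end"]].itertuples(index=False)
        )
    else:
        raise ValueError(f"unknown annotation format: {format!r}")

    by_gene: dict[str, list[tuple[str, str, int, int]]] = {}
    for gene_id, chrom, strand, start, end in records:
        by_gene.setdefault(str(gene_id), []).append((chrom, strand, start, end))

    n_dup = sum(1 for recs in by_gene.values() if len(recs) > 1)
    if n_dup:
        log.info("%s: %d gene ids with multiple records collapsed to one model each", path, n_dup)

    genes: list[GeneModel] = []
    for gene_id, recs in by_gene.items():
        chrom, strand = recs[0][0], recs[0][1]
        start = min(r[2] for r in recs)
        end = max(r[3] for r in recs)
        tss = start if strand == "+" else end  # most upstream on the gene's strand
        genes.append(GeneModel(gene_id, tss, strand, GenomicInterval(chrom, start, end, strand)))
    genes.sort(key=lambda g: g.gene_id)
    return genes


def write_genes_bed12(genes: Sequence[GeneModel], path: str | Path) -> None:
    rows = []
    for g in genes:
        b = g.body
        rows.append(
            (b.chrom, b.start, b.end, g.gene_id, 0, g.strand, b.start, b.end, "0", 1, b.width, 0)
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, header=False)
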