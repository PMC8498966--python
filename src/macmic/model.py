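"""Shared data model: genomic intervals, peaks, feature tracks, gene models.

Coordinates are 0-based half-open throughout (BED native). GTF-style
1-based inclusive inputs are shifted on read by :mod:`macmic.io`.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

VALID_STRANDS = {"+", "-", "."}

#: canonical column order of a track's peak table
PEAK_COLUMNS = ["chrom", "start", "end", "height", "total_signal"]


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open interval [start, end) on a named chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start: {self.start}")
        if self.end <= self.start:
            raise ValueError(f"empty interval: [{self.start}, {self.end})")
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"bad strand: {self.strand!r}")

    @property
    def width(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class Peak:
    """One called peak with its maximal (height) and summed (total) signal."""

    interval: GenomicInterval
    height: float
    total_signal: float

    def __post_init__(self) -> None:
        if self.height < 0 or self.total_signal < 0:
            raise ValueError("peak signal values must be >= 0")

    @property
    def width(self) -> int:
        return self.interval.width


class FeatureTrack:
    """Sorted set of peaks for one chromatin feature in one cell type.

    Peaks are stored columnar in a DataFrame (``chrom, start, end, height,
    total_signal``) sorted by (chrom, start, end); per-chromosome numpy
    views are cached for overlap arithmetic.

    ``signal_is_width`` flags tracks read from plain BED, where height and
    total_signal fell back to the peak width; information-theoretic scoring
    refuses such degenerate signals unless explicitly allowed.
    """

    def __init__(
        self,
        feature_name: str,
        cell_type: str,
        peaks: Iterable[Peak] | pd.DataFrame,
        signal_is_width: bool = False,
    ) -> None:
        if not feature_name or not cell_type:
            raise ValueError("feature_name and cell_type must be non-empty")
        if isinstance(peaks, pd.DataFrame):
            df = peaks.loc[:, PEAK_COLUMNS].copy()
        else:
            rows = [
                (p.interval.chrom, p.interval.start, p.interval.end, p.height, p.total_signal)
                for p in peaks
            ]
            df = pd.DataFrame(rows, columns=PEAK_COLUMNS)
        if len(df):
            if (df["end"] <= df["start"]).any():
                raise ValueError("track contains peaks with end <= start")
            if (df["start"] < 0).any():
                raise ValueError("track contains negative starts")
        df = df.astype(
            {"chrom": str, "start": np.int64, "end": np.int64, "height": float, "total_signal": float}
        )
        df = df.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(drop=True)
        self.feature_name = feature_name
        self.cell_type = cell_type
        self.df = df
        self.signal_is_width = signal_is_width
        self._by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] | None = None

    def __len__(self) -> int:
        return len(self.df)

    def __iter__(self) -> Iterator[Peak]:
        return iter(self.peaks)

    @property
    def peaks(self) -> list[Peak]:
        return [
            Peak(GenomicInterval(r.chrom, int(r.start), int(r.end)), r.height, r.total_signal)
            for r in self.df.itertuples(index=False)
        ]

    @property
    def widths(self) -> np.ndarray:
        return (self.df["end"] - self.df["start"]).to_numpy()

    @property
    def total_signal(self) -> float:
        return float(self.df["total_signal"].sum())

    def chromosomes(self) -> list[str]:
        return sorted(self.df["chrom"].unique())

    def chrom_arrays(self, chrom: str) -> tuple[np.ndarray, np.ndarray]:
        """(starts, ends) for one chromosome, start-sorted."""
        if self._by_chrom is None:
            self._by_chrom = {
                c: (g["start"].to_numpy(), g["end"].to_numpy())
                for c, g in self.df.groupby("chrom", sort=False)
            }
        return self._by_chrom.get(chrom, (np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)))

    def subset(self, mask: np.ndarray) -> "FeatureTrack":
        return FeatureTrack(
            self.feature_name, self.cell_type, self.df.loc[mask], self.signal_is_width
        )

    def __repr__(self) -> str:
        return (
            f"FeatureTrack({self.feature_name!r}, {self.cell_type!r}, "
            f"{len(self)} peaks on {len(self.chromosomes())} chromosomes)"
        )


@dataclass(frozen=True)
class GeneModel:
    """One gene: representative TSS, strand and gene body."""

    gene_id: str
    tss: int
    strand: str
    body: GenomicInterval

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")
        if self.tss < 0:
            raise ValueError(f"gene {self.gene_id}: negative TSS")


@dataclass
class GeneSignalVector:
    """Per-gene promoter aggregation of one feature track.

    ``table`` is indexed by gene_id with columns ``x`` (total promoter
    signal), ``w`` (total promoter peak width, bp) and ``k`` (number of
    promoter peaks). Genes without promoter peaks carry x = w = k = 0.
    """

    feature_name: str
    table: pd.DataFrame
    signal_is_width: bool = False

    def __post_init__(self) -> None:
        missing = {"x", "w", "k"} - set(self.table.columns)
        if missing:
            raise ValueError(f"signal table missing columns: {sorted(missing)}")

    @property
    def gene_ids(self) -> pd.Index:
        return self.table.index

    @property
    def x(self) -> np.ndarray:
        return self.table["x"].to_numpy(dtype=float)

    @property
    def w(self) -> np.ndarray:
        return self.table["w"].to_numpy(dtype=float)

    def __len__(self) -> int:
        return len(self.table)


def check_same_genes(a: GeneSignalVector, b: GeneSignalVector) -> None:
    if not a.gene_ids.equals(b.gene_ids):
        raise ValueError(
            "gene universes differ between signal vectors "
            f"({a.feature_name}: {len(a)} genes, {b.feature_name}: {len(b)} genes)"
        )


def genes_to_frame(genes: Sequence[GeneModel]) -> pd.DataFrame:
    """Tabular view of a gene collection (one row per gene)."""
    return pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in genes],
            "chrom": [g.body.chrom for g in genes],
            "tss": [g.tss for g in genes],
            "strand": [g.strand for g in genes],
            "body_start": [g.body.start for g in genes],
            "body_end": [g.body.end for g in genes],
        }
    )
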