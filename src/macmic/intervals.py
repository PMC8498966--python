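"""Overlap arithmetic: colocalization counting, promoter mapping, width groups.

A colocalization event is an intersecting (peak_a, peak_b) pair with at
least 1 bp of overlap; one A peak spanning two B peaks yields two events.
A merged-locus alternative (maximal regions covered by both tracks) is
available for sensitivity checks.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .model import FeatureTrack, GeneModel, GeneSignalVector, GenomicInterval

log = logging.getLogger(__name__)

#: promoter window extents around the TSS, strand-aware (bp)
PROMOTER_UPSTREAM = 3_000
PROMOTER_DOWNSTREAM = 10_000


@dataclass(frozen=True)
class PromoterWindow:
    """TSS-anchored scoring window, 3 kb upstream to 10 kb downstream."""

    gene_id: str
    window: GenomicInterval


def overlaps(a: GenomicInterval, b: GenomicInterval) -> bool:
    """True iff the intervals share a chromosome and >= 1 bp."""
    return a.chrom == b.chrom and max(a.start, b.start) < min(a.end, b.end)


def promoter_window(
    gene: GeneModel,
    upstream: int = PROMOTER_UPSTREAM,
    downstream: int = PROMOTER_DOWNSTREAM,
) -> PromoterWindow | None:
    """Strand-aware promoter window, clipped at position 0.

    Returns None (caller drops the gene, warned) if clipping empties it.
    """
    if gene.strand == "+":
        start, end = gene.tss - upstream, gene.tss + downstream
    else:
        start, end = gene.tss - downstream, gene.tss + upstream
    start = max(start, 0)
    if end <= start:
        log.warning("gene %s: promoter window empty after clipping; dropped", gene.gene_id)
        return None
    return PromoterWindow(gene.gene_id, GenomicInterval(gene.body.chrom, start, end, gene.strand))


def _count_overlapping(starts: np.ndarray, ends_sorted: np.ndarray, qs: int, qe: int) -> int:
    """Number of intervals (start-sorted starts, independently sorted ends)
    overlapping the half-open query [qs, qe)."""
    return int(np.searchsorted(starts, qe, side="left") - np.searchsorted(ends_sorted, qs, side="right"))


def count_colocalizations(track_a: FeatureTrack, track_b: FeatureTrack, mode: str = "pairs") -> int:
    """Count colocalization events between two tracks.

    ``pairs`` (default): number of intersecting (peak_a, peak_b) pairs;
    symmetric in its arguments. ``merged``: number of maximal genomic
    regions covered by at least one peak of each track.
    """
    if mode == "pairs":
        total = 0
        for chrom in track_a.chromosomes():
            a_starts, a_ends = track_a.chrom_arrays(chrom)
            b_starts, b_ends = track_b.chrom_arrays(chrom)
            if not len(b_starts):
                continue
            b_ends_sorted = np.sort(b_ends)
            # overlap iff b.start < a.end and b.end > a.start
            n_start_before_aend = np.searchsorted(b_starts, a_ends, side="left")
            n_end_at_or_before_astart = np.searchsorted(b_ends_sorted, a_starts, side="right")
            total += int((n_start_before_aend - n_end_at_or_before_astart).sum())
        return total
    if mode == "merged":
        return _count_merged_loci(track_a, track_b)
    raise ValueError(f"unknown colocalization mode: {mode!r}")


def _count_merged_loci(track_a: FeatureTrack, track_b: FeatureTrack) -> int:
    total = 0
    for chrom in sorted(set(track_a.chromosomes()) & set(track_b.chromosomes())):
        events: list[tuple[int, int, int]] = []  # position, +1/-1, track index
        for idx, track in enumerate((track_a, track_b)):
            starts, ends = track.chrom_arrays(chrom)
            events.extend((int(s), 1, idx) for s in starts)
            events.extend((int(e), -1, idx) for e in ends)
        events.sort(key=lambda t: (t[0], t[1]))  # close before open at same position
        cov = [0, 0]
        in_locus = False
        for _, delta, idx in events:
            cov[idx] += delta
            both = cov[0] > 0 and cov[1] > 0
            if both and not in_locus:
                total += 1
                in_locus = True
            elif not both:
                in_locus = False
    return total


def map_peaks_to_promoters(
    track: FeatureTrack,
    genes: Sequence[GeneModel],
    upstream: int = PROMOTER_UPSTREAM,
    downstream: int = PROMOTER_DOWNSTREAM,
) -> GeneSignalVector:
    """Aggregate a track over each gene's promoter window.

    Per gene: x = summed total_signal of overlapping peaks, w = summed
    widths, k = number of peaks. A peak overlapping two genes' promoters
    contributes fully to both.
    """
    gene_ids, xs, ws, ks = [], [], [], []
    df = track.df
    widths_all = track.widths
    sig_all = df["total_signal"].to_numpy()
    # peak row offsets per chromosome for slicing aggregates
    offsets = {c: np.flatnonzero((df["chrom"] == c).to_numpy()) for c in track.chromosomes()}
    for gene in genes:
        pw = promoter_window(gene, upstream, downstream)
        if pw is None:
            continue
        starts, ends = track.chrom_arrays(pw.window.chrom)
        if len(starts):
            hit_local = np.flatnonzero((starts < pw.window.end) & (ends > pw.window.start))
            rows = offsets[pw.window.chrom][hit_local] if len(hit_local) else hit_local
        else:
            rows = np.empty(0, dtype=int)
        gene_ids.append(gene.gene_id)
        xs.append(float(sig_all[rows].sum()))
        ws.append(float(widths_all[rows].sum()))
        ks.append(int(len(rows)))
    table = pd.DataFrame({"x": xs, "w": ws, "k": ks}, index=pd.Index(gene_ids, name="gene_id"))
    return GeneSignalVector(track.feature_name, table, signal_is_width=track.signal_is_width)


def promoter_colocalized(
    track_a: FeatureTrack,
    track_b: FeatureTrack,
    genes: Sequence[GeneModel],
    upstream: int = PROMOTER_UPSTREAM,
    downstream: int = PROMOTER_DOWNSTREAM,
) -> pd.Series:
    """Per gene: does any A peak overlap any B peak inside the promoter?

    True iff some peak_a and peak_b intersect each other and the promoter
    window by >= 1 bp (the intersection of all three is non-empty).
    """
    flags: dict[str, bool] = {}
    for gene in genes:
        pw = promoter_window(gene, upstream, downstream)
        if pw is None:
            continue
        w = pw.window
        a_starts, a_ends = track_a.chrom_arrays(w.chrom)
        b_starts, b_ends = track_b.chrom_arrays(w.chrom)
        hit = False
        if len(a_starts) and len(b_starts):
            a_sel = np.flatnonzero((a_starts < w.end) & (a_ends > w.start))
            for i in a_sel:
                # clip the A peak to the window, then test any B overlap
                qs, qe = max(int(a_starts[i]), w.start), min(int(a_ends[i]), w.end)
                if np.any((b_starts < qe) & (b_ends > qs)):
                    hit = True
                    break
        flags[gene.gene_id] = hit
    return pd.Series(flags, name="colocalized")


def width_rank_groups(track: FeatureTrack, group_size: int) -> list[pd.DataFrame]:
    """Chunk peaks into width-ranked groups of ``group_size``.

    Group 1 holds the widest peaks; width ties break by (chrom, start)
    ascending; the last group may be smaller.
    """
    if group_size < 1:
        raise ValueError("group_size must be >= 1")
    df = track.df.assign(width=track.widths)
    df = df.sort_values(
        ["width", "chrom", "start"], ascending=[False, True, True], kind="mergesort"
    ).reset_index(drop=True)
    return [df.iloc[i : i + group_size] for i in range(0, len(df), group_size)]
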