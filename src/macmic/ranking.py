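"""Width-based gene ranking, rank products, top-N groups, marker status.

Genes are ranked by the total width of a marker's peaks in the promoter
window (rank 1 = broadest). For a pair of markers the per-gene rank
product r1 * r2 ranks genes jointly broad in both, restricted to genes
where the two markers actually colocalize in the promoter.
"""
from __future__ import annotations

import logging
from typing import Iterable, Sequence

import pandas as pd

from . import intervals
from .model import FeatureTrack, GeneModel, GeneSignalVector, check_same_genes

log = logging.getLogger(__name__)


def rank_by_width(signals: GeneSignalVector) -> pd.Series:
    """Rank genes by total promoter peak width; 1 = widest.

    Ties (including the zero-width genes, which sort last) break by
    gene_id ascending, so the ranking is a deterministic permutation of
    1..n.
    """
    if len(signals) == 0:
        raise ValueError("empty signal vector")
    order = (
        signals.table.assign(_gid=signals.table.index)
        .sort_values(["w", "_gid"], ascending=[False, True], kind="mergesort")
        .index
    )
    ranks = pd.Series(range(1, len(order) + 1), index=order, name="rank")
    return ranks.reindex(signals.gene_ids)


def rank_product(
    sig_a: GeneSignalVector,
    sig_b: GeneSignalVector,
    colocalized: pd.Series,
) -> pd.DataFrame:
    """Joint-breadth table: per-gene product of the two width ranks.

    ``colocalized`` flags genes where the two markers overlap by >= 1 bp
    within the promoter window (see
    :func:`macmic.intervals.promoter_colocalized`); genes without such a
    colocalization are removed from the ranking. Sorted by rank product
    ascending (small = jointly broad), ties by gene_id.
    """
    check_same_genes(sig_a, sig_b)
    r1 = rank_by_width(sig_a)
    r2 = rank_by_width(sig_b)
    table = pd.DataFrame(
        {
            "w_a": sig_a.table["w"],
            "w_b": sig_b.table["w"],
            "rank_a": r1,
            "rank_b": r2,
            "rank_product": r1 * r2,
            "colocalized": colocalized.reindex(sig_a.gene_ids).fillna(False).astype(bool),
        }
    )
    kept = table[table["colocalized"]].drop(columns="colocalized")
    kept = kept.assign(_gid=kept.index).sort_values(
        ["rank_product", "_gid"], kind="mergesort"
    ).drop(columns="_gid")
    return kept


def top_n(table: pd.DataFrame | pd.Series, n: int = 500) -> list[str]:
    """First n gene ids of a sorted ranking table (all of them if fewer)."""
    if n < 0:
        raise ValueError("n must be >= 0")
    ids = list(table.index[:n])
    if len(ids) < n:
        log.warning("ranking holds only %d genes; top_n(%d) returns them all", len(ids), n)
    return ids


def set_overlap_stats(
    set_a: Iterable[str], set_b: Iterable[str], denominator: int
) -> tuple[int, float]:
    """|A intersect B| and its percentage of a fixed denominator.

    E.g. an intersection of 288 over denominator 500 is (288, 57.6)."""
    if denominator <= 0:
        raise ValueError("denominator must be > 0")
    count = len(set(set_a) & set(set_b))
    return count, 100.0 * count / denominator


def marker_presence(
    gene: GeneModel,
    track: FeatureTrack,
    region: str = "promoter",
    upstream: int = intervals.PROMOTER_UPSTREAM,
    downstream: int = intervals.PROMOTER_DOWNSTREAM,
) -> bool:
    """Is the marker present (>= 1 bp peak overlap) in the gene's region?"""
    if region == "promoter":
        pw = intervals.promoter_window(gene, upstream, downstream)
        if pw is None:
            return False
        target = pw.window
    elif region == "gene-body":
        target = gene.body
    else:
        raise ValueError(f"unknown region: {region!r}")
    starts, ends = track.chrom_arrays(target.chrom)
    if not len(starts):
        return False
    return bool(((starts < target.end) & (ends > target.start)).any())


def marker_status_counts(
    gene_ids: Sequence[str],
    genes: Sequence[GeneModel],
    track_1: FeatureTrack,
    track_2: FeatureTrack,
    region: str = "promoter",
) -> dict:
    """Lost-in-both / retained-in-both marker status across two cell types.

    For each gene in ``gene_ids``: "lost in both" means the marker is
    absent in both query tracks, "retained in both" means present in
    both. Returns counts and percentages at one-decimal and integer
    precision (e.g. 483/500 reports 96.6 and 97).
    """
    by_id = {g.gene_id: g for g in genes}
    missing = [g for g in gene_ids if g not in by_id]
    if missing:
        raise ValueError(f"{len(missing)} gene ids not in the annotation (first: {missing[0]})")
    n = len(gene_ids)
    lost = retained = 0
    for gid in gene_ids:
        p1 = marker_presence(by_id[gid], track_1, region)
        p2 = marker_presence(by_id[gid], track_2, region)
        if not p1 and not p2:
            lost += 1
        if p1 and p2:
            retained += 1
    return {
        "n": n,
        "lost_both": lost,
        "lost_both_pct": round(100.0 * lost / n, 1),
        "lost_both_pct_int": round(100.0 * lost / n),
        "retained_both": retained,
        "retained_both_pct": round(100.0 * retained / n, 1),
        "retained_both_pct_int": round(100.0 * retained / n),
    }
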