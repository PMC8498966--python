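"""Super-enhancer calling and CTCF-associated classification.

H3K27ac peaks within a stitching distance are merged into enhancers;
enhancers are ranked by total signal and the super/typical cutoff is the
point where the tangent slope of the min-max-scaled rank-signal curve
first reaches 1 (the hockey-stick inflection). Super-enhancers holding
at least one high-confidence CTCF peak (height above the upper quartile
of the CTCF track) are CTCF-associated super-enhancers (CSE); the rest
are other super-enhancers (OSE). A matched-enlargement simulation asks
how much of the CTCF association of super-enhancers is explained by
their sheer size.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .model import FeatureTrack, GeneModel, GenomicInterval

log = logging.getLogger(__name__)

DEFAULT_STITCH_DISTANCE = 12_500


@dataclass(frozen=True)
class EnhancerCall:
    """One stitched enhancer and its classification."""

    interval: GenomicInterval
    total_signal: float
    n_constituents: int
    is_super: bool
    ctcf_class: str = "not-super"  # CSE | OSE | not-super
    n_hc_ctcf: int = 0

    @property
    def width(self) -> int:
        return self.interval.width


def high_confidence_peaks(ctcf: FeatureTrack) -> FeatureTrack:
    """Peaks with height strictly above the track's upper quartile.

    The quartile uses linear interpolation (numpy default); "larger than"
    is strict, so a track of identical heights yields an empty result.
    """
    if len(ctcf) == 0:
        log.warning("empty CTCF track; no high-confidence peaks")
        return ctcf.subset(np.zeros(0, dtype=bool))
    if len(ctcf) < 4:
        log.warning("only %d CTCF peaks; upper-quartile threshold is unstable", len(ctcf))
    heights = ctcf.df["height"].to_numpy()
    q3 = float(np.quantile(heights, 0.75))
    return ctcf.subset(heights > q3)


def stitch_peaks(track: FeatureTrack, stitch_distance: int = DEFAULT_STITCH_DISTANCE) -> list[EnhancerCall]:
    """Merge peaks within ``stitch_distance`` bp into candidate enhancers."""
    calls: list[EnhancerCall] = []
    for chrom, grp in track.df.groupby("chrom", sort=True):
        cur_start = cur_end = None
        cur_signal = 0.0
        cur_n = 0
        for row in grp.itertuples(index=False):
            if cur_end is not None and row.start - cur_end <= stitch_distance:
                cur_end = max(cur_end, row.end)
                cur_signal += row.total_signal
                cur_n += 1
            else:
                if cur_end is not None:
                    calls.append(
                        EnhancerCall(
                            GenomicInterval(chrom, cur_start, cur_end), cur_signal, cur_n, False
                        )
                    )
                cur_start, cur_end = int(row.start), int(row.end)
                cur_signal, cur_n = float(row.total_signal), 1
        if cur_end is not None:
            calls.append(
                EnhancerCall(GenomicInterval(chrom, cur_start, cur_end), cur_signal, cur_n, False)
            )
    return calls


def superenhancer_cutoff_index(signals: np.ndarray) -> int:
    """Index (into the ascending-sorted signals) of the rank-signal
    inflection: the first point whose forward tangent slope on the
    [0,1]x[0,1]-scaled curve reaches 1. Enhancers strictly above this
    index are super."""
    n = len(signals)
    s = np.sort(np.asarray(signals, dtype=float))
    lo, hi = s[0], s[-1]
    if hi == lo:
        return n - 1  # flat curve: nothing is super
    x = np.arange(n) / (n - 1)
    y = (s - lo) / (hi - lo)
    slopes = np.diff(y) / np.diff(x)
    above = np.flatnonzero(slopes >= 1.0)
    return int(above[0]) if len(above) else n - 1


def call_superenhancers(
    h3k27ac: FeatureTrack, stitch_distance: int = DEFAULT_STITCH_DISTANCE
) -> list[EnhancerCall]:
    """Stitch, rank by total signal, and flag super-enhancers.

    With fewer than 3 stitched enhancers there is no inflection to find;
    everything is flagged typical with a warning.
    """
    calls = stitch_peaks(h3k27ac, stitch_distance)
    if len(calls) < 3:
        log.warning("only %d stitched enhancers; no super-enhancer call possible", len(calls))
        return calls
    signals = np.array([c.total_signal for c in calls])
    cut = superenhancer_cutoff_index(signals)
    threshold = np.sort(signals)[cut]
    flat = np.ptp(signals) == 0
    if flat:
        log.warning("all enhancer signals identical; no reliable inflection, none called super")
    return [
        replace(c, is_super=(not flat and c.total_signal > threshold)) for c in calls
    ]


def classify_cse_ose(
    enhancers: Sequence[EnhancerCall], hc_ctcf: FeatureTrack
) -> list[EnhancerCall]:
    """Split super-enhancers by high-confidence CTCF co-binding.

    ``hc_ctcf`` must already be thresholded (see
    :func:`high_confidence_peaks`). CSE = super with >= 1 contained or
    overlapping high-confidence CTCF peak; OSE = super with none; typical
    enhancers stay "not-super".
    """
    out: list[EnhancerCall] = []
    for call in enhancers:
        iv = call.interval
        starts, ends = hc_ctcf.chrom_arrays(iv.chrom)
        n_hit = int(((starts < iv.end) & (ends > iv.start)).sum()) if len(starts) else 0
        if call.is_super:
            cls = "CSE" if n_hit >= 1 else "OSE"
        else:
            cls = "not-super"
        out.append(replace(call, ctcf_class=cls, n_hc_ctcf=n_hit))
    return out


def assign_enhancer_genes(
    enhancers: Sequence[EnhancerCall],
    genes: Sequence[GeneModel],
    enhancer_class: str,
) -> set[str]:
    """Genes whose body overlaps (>= 1 bp) any enhancer of the class."""
    chosen = [e for e in enhancers if e.ctcf_class == enhancer_class]
    assigned: set[str] = set()
    for gene in genes:
        b = gene.body
        for e in chosen:
            iv = e.interval
            if iv.chrom == b.chrom and max(iv.start, b.start) < min(iv.end, b.end):
                assigned.add(gene.gene_id)
                break
    return assigned


def assign_cse_ose_genes(
    enhancers: Sequence[EnhancerCall], genes: Sequence[GeneModel]
) -> tuple[set[str], set[str]]:
    """CSE and OSE gene sets; a gene touching both classes counts as CSE."""
    cse = assign_enhancer_genes(enhancers, genes, "CSE")
    ose = assign_enhancer_genes(enhancers, genes, "OSE") - cse
    return cse, ose


def rank_class_genes(
    enhancers: Sequence[EnhancerCall],
    genes: Sequence[GeneModel],
    enhancer_class: str,
) -> list[str]:
    """Class genes ordered by the total signal of their strongest
    overlapping enhancer of that class (descending, ties by gene_id)."""
    chosen = [e for e in enhancers if e.ctcf_class == enhancer_class]
    best: dict[str, float] = {}
    for gene in genes:
        b = gene.body
        for e in chosen:
            iv = e.interval
            if iv.chrom == b.chrom and max(iv.start, b.start) < min(iv.end, b.end):
                best[gene.gene_id] = max(best.get(gene.gene_id, 0.0), e.total_signal)
    return sorted(best, key=lambda g: (-best[g], g))


def ctcf_association_rate(
    regions: Sequence[GenomicInterval], ctcf: FeatureTrack
) -> float:
    """Fraction of regions overlapping >= 1 CTCF peak."""
    if not regions:
        raise ValueError("no regions")
    hit = 0
    for iv in regions:
        starts, ends = ctcf.chrom_arrays(iv.chrom)
        if len(starts) and ((starts < iv.end) & (ends > iv.start)).any():
            hit += 1
    return hit / len(regions)


def enlarge_typical_enhancers(
    typical: Sequence[EnhancerCall],
    supers: Sequence[EnhancerCall],
    ctcf: FeatureTrack,
    seed: int,
) -> tuple[list[EnhancerCall], dict]:
    """Size-matched null for the CTCF association of super-enhancers.

    Each typical enhancer is randomly matched (with replacement) to a
    super-enhancer and grown symmetrically about its midpoint to the
    matched width; growth clipped at position 0 pushes the deficit onto
    the other side, so the final width always equals the match's.
    Returns the enlarged calls plus the CTCF-association rates of the
    typical, enlarged and super collections.
    """
    if not typical or not supers:
        raise ValueError("both typical and super collections must be non-empty")
    rng = np.random.default_rng(seed)
    matches = rng.integers(0, len(supers), size=len(typical))
    enlarged: list[EnhancerCall] = []
    for te, m in zip(typical, matches):
        target = supers[m].width
        mid = (te.interval.start + te.interval.end) // 2
        half = target // 2
        start = mid - half
        end = start + target
        if start < 0:
            end -= start  # deficit moved to the right
            start = 0
        enlarged.append(replace(te, interval=GenomicInterval(te.interval.chrom, start, end)))
    summary = {
        "typical_ctcf_rate": ctcf_association_rate([t.interval for t in typical], ctcf),
        "enlarged_ctcf_rate": ctcf_association_rate([t.interval for t in enlarged], ctcf),
        "super_ctcf_rate": ctcf_association_rate([s.interval for s in supers], ctcf),
    }
    return enlarged, summary


def calls_to_frame(calls: Sequence[EnhancerCall]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [c.interval.chrom for c in calls],
            "start": [c.interval.start for c in calls],
            "end": [c.interval.end for c in calls],
            "name": [c.ctcf_class if c.is_super else "typical" for c in calls],
            "total_signal": [c.total_signal for c in calls],
            "n_constituents": [c.n_constituents for c in calls],
            "is_super": [c.is_super for c in calls],
            "n_hc_ctcf": [c.n_hc_ctcf for c in calls],
        }
    )


def write_calls_bed(calls: Sequence[EnhancerCall], path) -> None:
    df = calls_to_frame(calls)
    bed = df[["chrom", "start", "end", "name", "total_signal"]].assign(strand=".")
    bed.to_csv(path, sep="\t", index=False, header=False)
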