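import numpy as np
import pandas as pd
import pytest

from macmic.model import FeatureTrack, GeneModel, GenomicInterval, GeneSignalVector, PEAK_COLUMNS


def make_track(rows, feature="F", cell_type="ct", **kwargs):
    """rows: (chrom, start, end[, height[, total_signal]])"""
    full = []
    for r in rows:
        chrom, start, end = r[:3]
        height = r[3] if len(r) > 3 else 1.0
        total = r[4] if len(r) > 4 else height * (end - start)
        full.append((chrom, start, end, height, total))
    return FeatureTrack(feature, cell_type, pd.DataFrame(full, columns=PEAK_COLUMNS), **kwargs)


def random_track(rng, n_peaks, chroms=("chr1", "chr2"), span=10_000, max_width=300, feature="F"):
    rows = []
    for _ in range(n_peaks):
        chrom = chroms[rng.integers(len(chroms))]
        start = int(rng.integers(0, span))
        width = int(rng.integers(1, max_width))
        rows.append((chrom, start, start + width, float(rng.uniform(0.5, 10))))
    return make_track(rows, feature=feature)


def make_signals(feature, gene_ids, x, w=None, k=None):
    x = np.asarray(x, dtype=float)
    table = pd.DataFrame(
        {
            "x": x,
            "w": np.asarray(w, dtype=float) if w is not None else x,
            "k": np.asarray(k) if k is not None else (x > 0).astype(int),
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )
    return GeneSignalVector(feature, table)


@pytest.fixture
def plus_gene():
    return GeneModel("gplus", 50_000, "+", GenomicInterval("chr1", 50_000, 60_000, "+"))


@pytest.fixture
def minus_gene():
    return GeneModel("gminus", 50_000, "-", GenomicInterval("chr1", 40_000, 50_000, "-"))
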