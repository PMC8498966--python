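"""Seeded synthetic genomes, annotations, and multi-feature peak panels.

The generator builds toy data in exactly the regime the score targets:
per-gene promoter signal correlation and genome-wide colocalization are
planted independently, so a pair can colocalize heavily while its
signals stay uncorrelated (the bivalent-domain situation) or vice versa.

Geometry guarantees make planted quantities exact. Promoter peaks live
on one chromosome, each feature at its own fixed offset inside the
window, so promoter peaks of different features never overlap.
Background and colocalization peaks live on a second chromosome laid
out as a lattice of 1-kb slots; peak widths and centre jitter are
bounded so that two peaks overlap if and only if they share a slot.
Each feature draws background slots from its own disjoint pool, and a
pair's planted colocalization slots are shared by exactly that pair, so
the pairwise overlap-event count equals the planted target exactly.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import write_genes_bed12, write_narrowpeak
from .model import FeatureTrack, GeneModel, GenomicInterval, PEAK_COLUMNS

log = logging.getLogger(__name__)

SLOT = 1_000  # background lattice pitch, bp
GENE_SPACING = 30_000  # keeps 13-kb promoter windows disjoint
_PROMOTER_PEAK_PITCH = 900  # per-feature offset inside the window
_PROMOTER_PEAK_MAX_WIDTH = 700


def _pair_key(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


@dataclass
class PanelSpec:
    """One cell type's synthetic panel.

    ``pair_rho`` plants the Pearson correlation of per-gene promoter
    signals for a feature pair; ``pair_coloc`` plants its genome-wide
    colocalization event count on the background chromosome;
    ``pair_promoter_overlap`` plants, for a fraction of genes, direct
    overlap of the pair's promoter peaks (these genes then pass the
    rank-product colocalization filter, and each adds one further
    genome-wide event). ``feature_dispersion`` (0..1] scales the
    spread of a feature's promoter signals around ``mean_signal`` —
    high-dispersion features carry more surprise under the Poisson
    background and hence more entropy.
    """

    features: tuple[str, ...]
    n_genes: int = 300
    pair_rho: Mapping[tuple[str, str], float] = field(default_factory=dict)
    pair_coloc: Mapping[tuple[str, str], int] = field(default_factory=dict)
    pair_promoter_overlap: Mapping[tuple[str, str], float] = field(default_factory=dict)
    feature_dispersion: Mapping[str, float] = field(default_factory=dict)
    mean_signal: float = 100.0
    n_background: int = 150
    width_dist: str = "uniform"  # uniform | heavy-tailed
    cell_type: str = "sim"
    seed: int = 0

    def correlation_matrix(self) -> np.ndarray:
        f = len(self.features)
        R = np.eye(f)
        idx = {name: i for i, name in enumerate(self.features)}
        for (a, b), rho in self.pair_rho.items():
            if abs(rho) > 1:
                raise ValueError(f"infeasible correlation {rho} for pair ({a}, {b})")
            R[idx[a], idx[b]] = R[idx[b], idx[a]] = rho
        return R

    def validate(self) -> None:
        if len(set(self.features)) < 1:
            raise ValueError("need at least one feature")
        for key, c in self.pair_coloc.items():
            if c < 0:
                raise ValueError(f"infeasible colocalization target {c} for {key}")
            if not set(key) <= set(self.features):
                raise ValueError(f"pair {key} names unknown features")
        eigvals = np.linalg.eigvalsh(self.correlation_matrix())
        if eigvals.min() < -1e-9:
            raise ValueError("infeasible pairwise correlation targets (matrix not PSD)")
        for f, d in self.feature_dispersion.items():
            if not 0 < d <= 1:
                raise ValueError(f"dispersion for {f} must be in (0, 1]")
        seen: set[str] = set()
        for key, frac in self.pair_promoter_overlap.items():
            if not 0 <= frac <= 1:
                raise ValueError(f"infeasible promoter-overlap fraction {frac} for {key}")
            if not set(key) <= set(self.features):
                raise ValueError(f"pair {key} names unknown features")
            if seen & set(key):
                raise ValueError("a feature may appear in only one promoter-overlap pair")
            seen |= set(key)


def _make_genes(n_genes: int) -> list[GeneModel]:
    genes = []
    for g in range(n_genes):
        tss = 20_000 + g * GENE_SPACING
        strand = "+" if g % 2 == 0 else "-"
        if strand == "+":
            body = GenomicInterval("chrG", tss, tss + 5_000, strand)
        else:
            body = GenomicInterval("chrG", tss - 5_000, tss, strand)
        genes.append(GeneModel(f"g{g:05d}", tss, strand, body))
    return genes


def _promoter_peak_interval(
    gene: GeneModel, feature_index: int, width: int
) -> tuple[int, int]:
    off = 500 + feature_index * _PROMOTER_PEAK_PITCH
    if gene.strand == "+":
        start = gene.tss + off
        return start, start + width
    end = gene.tss - off
    return end - width, end


def _slot_peak(rng: np.random.Generator, slot_index: int, width_dist: str) -> tuple[int, int]:
    """A peak confined to its slot: overlaps exactly its slot-mates."""
    if width_dist == "heavy-tailed":
        width = int(min(300 + rng.pareto(1.5) * 150, 700))
    else:
        width = int(rng.integers(300, 401))
    center = slot_index * SLOT + SLOT // 2 + int(rng.integers(-140, 141))
    return center - width // 2, center - width // 2 + width


def generate_panel(
    spec: PanelSpec, out_dir: str | Path | None = None
) -> tuple[dict[str, FeatureTrack], list[GeneModel]]:
    """Generate one cell type's feature tracks and gene annotation.

    Returns in-memory objects; with ``out_dir`` also writes one
    narrowPeak file per feature plus a BED12 annotation (byte-identical
    across runs for the same spec).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    genes = _make_genes(spec.n_genes)
    f = len(spec.features)

    # per-gene promoter signals with planted pairwise correlation
    L = np.linalg.cholesky(spec.correlation_matrix() + 1e-12 * np.eye(f))
    z = rng.standard_normal((spec.n_genes, f)) @ L.T
    sigma = np.array(
        [40.0 * spec.feature_dispersion.get(name, 0.5) for name in spec.features]
    )
    signals = np.clip(spec.mean_signal + z * sigma, 0.0, None)

    # slot allocation on the background chromosome
    pairs = sorted(_pair_key(a, b) for (a, b) in spec.pair_coloc)
    n_slots = f * spec.n_background + sum(spec.pair_coloc[p] for p in pairs)
    slot_order = rng.permutation(n_slots)
    cursor = 0
    bg_slots: dict[str, np.ndarray] = {}
    for name in spec.features:
        bg_slots[name] = slot_order[cursor : cursor + spec.n_background]
        cursor += spec.n_background
    coloc_slots: dict[tuple[str, str], np.ndarray] = {}
    for p in pairs:
        c = spec.pair_coloc[p]
        coloc_slots[p] = slot_order[cursor : cursor + c]
        cursor += c

    # genes where a pair's promoter peaks are forced to overlap: the
    # second feature of the pair reuses the first feature's window offset
    overlap_partner: dict[str, tuple[int, np.ndarray]] = {}
    for (a, b), frac in spec.pair_promoter_overlap.items():
        a, b = (a, b) if spec.features.index(a) < spec.features.index(b) else (b, a)
        chosen = rng.random(spec.n_genes) < frac
        overlap_partner[b] = (spec.features.index(a), chosen)

    tracks: dict[str, FeatureTrack] = {}
    for j, name in enumerate(spec.features):
        rows = []
        for g, gene in enumerate(genes):
            x = float(signals[g, j])
            if x <= 0:
                continue
            width = int(rng.integers(300, 601))
            offset_index = j
            if name in overlap_partner and overlap_partner[name][1][g]:
                offset_index = overlap_partner[name][0]
            start, end = _promoter_peak_interval(gene, offset_index, width)
            rows.append(("chrG", start, end, x / width, x))
        slots = list(bg_slots[name]) + [
            s for p in pairs if name in p for s in coloc_slots[p]
        ]
        for s in slots:
            start, end = _slot_peak(rng, int(s), spec.width_dist)
            height = float(rng.lognormal(np.log(5.0), 0.5))
            rows.append(("chrB", start, end, height, height * (end - start)))
        tracks[name] = FeatureTrack(
            name, spec.cell_type, pd.DataFrame(rows, columns=PEAK_COLUMNS)
        )

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_genes_bed12(genes, out_dir / "genes.bed12")
        for name, track in tracks.items():
            write_narrowpeak(track, out_dir / f"{spec.cell_type}.{name}.narrowPeak")
    return tracks, genes


# ------------------------------------------------------------- panel study


# Background colocalization targets follow the pair's information
# content plus Gaussian noise. Under the per-gene-sum Poisson entropy,
# a feature's entropy falls as its signal dispersion rises (a dispersed
# signal is individually improbable, and improbable observations
# contribute ~0 to a sum of -p log p), so the coupling goes through the
# generator's own expected entropy as a function of dispersion. The
# noise SD is fixed analytically so the background rank correlation
# between information and colocalization sits near the moderate
# positive coupling seen in real chromatin panels (~0.46):
# sd_noise = sd_signal * sqrt(1/0.46^2 - 1) ~ 1.932 * sd_signal.
_COLOC_BASE = 400.0
_COLOC_SIGNAL_SD = 61.0
_COLOC_NOISE_SD = _COLOC_SIGNAL_SD * 1.932
_PLANTED_COLOC = 1200
_PLANTED_DISPERSION = 0.9  # high dispersion = low information


def _expected_entropy(dispersion: float, n_genes: int, mean_signal: float) -> float:
    """Expected per-gene-sum Poisson entropy of a feature whose promoter
    signals are N(mean_signal, 40 * dispersion), under the promoter-mean
    rate. Deterministic; used only to couple colocalization targets to
    information content."""
    from scipy.stats import norm, poisson as poisson_dist

    sigma = 40.0 * dispersion
    lam = mean_signal
    k = np.arange(0, int(mean_signal + 8 * sigma) + 1)
    weight = norm.pdf(k, loc=mean_signal, scale=sigma)
    weight /= weight.sum()
    logp = poisson_dist.logpmf(k, lam)
    f = np.where(np.isneginf(logp), 0.0, -np.exp(logp) * logp)
    return float(n_genes * (weight * f).sum())


def simulate_study(
    n_cell_types: int = 15,
    n_features: int = 6,
    n_genes: int = 300,
    n_background: int = 150,
    planted: Sequence[tuple[str, str, str]] = (),
    seed: int = 0,
) -> tuple[dict[str, list[str]], dict[tuple[str, str], FeatureTrack], list[GeneModel], dict]:
    """A multi-cell-type panel in the regime the score was built for.

    Every cell type carries the same feature labels; feature dispersions
    (hence entropies) vary across cell types, and background pairs
    colocalize roughly in proportion to their information content with
    noise. Pairs listed in ``planted`` (cell_type, feature_a, feature_b)
    get low-information (high-dispersion) features but a colocalization
    count far above background — the signature the score should rank
    first.

    Returns (features_by_cell_type, tracks keyed by (cell_type, feature),
    genes, truth dict with planted pairs and per-pair targets).
    """
    features = [f"F{i + 1}" for i in range(n_features)]
    cell_types = [f"ct{i + 1:02d}" for i in range(n_cell_types)]
    planted_set = {(ct, *_pair_key(a, b)) for ct, a, b in planted}
    for ct, a, b in planted_set:
        if ct not in cell_types or a not in features or b not in features:
            raise ValueError(f"planted pair ({ct}, {a}, {b}) outside the panel")

    root = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in root.spawn(n_cell_types + 1)]
    rng = np.random.default_rng(child_seeds[-1])

    # draw dispersions first, then couple colocalization targets to the
    # pair's expected information content across the whole study
    dispersions: dict[str, dict[str, float]] = {}
    for ct in cell_types:
        disp = dict(zip(features, rng.uniform(0.15, 0.9, size=n_features)))
        for pct, a, b in planted_set:
            if pct == ct:
                disp[a] = disp[b] = _PLANTED_DISPERSION
        dispersions[ct] = disp

    h_cache = {
        round(d, 12): _expected_entropy(d, n_genes, 100.0)
        for disp in dispersions.values()
        for d in disp.values()
    }
    pair_signal: dict[tuple[str, str, str], float] = {}
    for ct in cell_types:
        disp = dispersions[ct]
        for j, a in enumerate(features):
            for b in features[j + 1 :]:
                pair_signal[(ct, a, b)] = (
                    h_cache[round(disp[a], 12)] + h_cache[round(disp[b], 12)]
                )
    background = [k for k in pair_signal if k not in planted_set]
    sig = np.array([pair_signal[k] for k in background])
    scale = _COLOC_SIGNAL_SD / sig.std() if len(sig) > 1 and sig.std() > 0 else 0.0
    center = sig.mean() if len(sig) else 0.0

    tracks: dict[tuple[str, str], FeatureTrack] = {}
    genes: list[GeneModel] = []
    targets: dict[tuple[str, str, str], int] = {}
    for i, ct in enumerate(cell_types):
        disp = dispersions[ct]
        pair_coloc: dict[tuple[str, str], int] = {}
        for j, a in enumerate(features):
            for b in features[j + 1 :]:
                if (ct, a, b) in planted_set:
                    c = _PLANTED_COLOC
                else:
                    c = int(
                        round(
                            _COLOC_BASE
                            + scale * (pair_signal[(ct, a, b)] - center)
                            + rng.normal(0.0, _COLOC_NOISE_SD)
                        )
                    )
                    c = max(c, 5)
                pair_coloc[(a, b)] = c
                targets[(ct, a, b)] = c
        spec = PanelSpec(
            features=tuple(features),
            n_genes=n_genes,
            pair_coloc=pair_coloc,
            feature_dispersion=disp,
            n_background=n_background,
            cell_type=ct,
            seed=child_seeds[i],
        )
        ct_tracks, genes = generate_panel(spec)
        for name, track in ct_tracks.items():
            tracks[(ct, name)] = track

    features_by_ct = {ct: list(features) for ct in cell_types}
    truth = {"planted": sorted(planted_set), "targets": targets}
    return features_by_ct, tracks, genes, truth


# --------------------------------------------------------- enhancer fixtures


def generate_hockey_stick_enhancers(
    n_typical: int,
    n_super: int,
    signal_ratio: float = 50.0,
    seed: int = 0,
    spacing: int = 30_000,
    cell_type: str = "sim",
) -> tuple[FeatureTrack, np.ndarray]:
    """H3K27ac track with a known super/typical ground truth.

    Enhancer-to-be peaks are spaced beyond any stitching distance, so
    each stitched enhancer is one peak. Typical peaks get narrow widths
    and unit-scale signal; supers get heavy widths and ``signal_ratio``
    times the signal. Returns the track and a boolean truth array
    aligned to the track's (coordinate-sorted) rows.
    """
    if n_super < 1:
        raise ValueError("need at least one super enhancer")
    if signal_ratio <= 1:
        log.warning("signal_ratio <= 1: typical and super signals overlap; no reliable inflection")
    rng = np.random.default_rng(seed)
    n = n_typical + n_super
    is_super = np.zeros(n, dtype=bool)
    is_super[rng.choice(n, size=n_super, replace=False)] = True
    rows = []
    for i in range(n):
        start = 10_000 + i * spacing
        if is_super[i]:
            width = int(rng.integers(5_000, 15_001))
            signal = float(signal_ratio * rng.uniform(1.0, 2.0))
        else:
            width = int(rng.integers(500, 2_001))
            signal = float(rng.uniform(0.5, 1.5))
        rows.append(("chrE", start, start + width, signal / width, signal))
    track = FeatureTrack(
        "H3K27ac", cell_type, pd.DataFrame(rows, columns=PEAK_COLUMNS)
    )
    # rows are generated in coordinate order on one chromosome, so the
    # truth array is already aligned to the sorted track
    return track, is_super


def generate_ctcf_for_enhancers(
    enhancer_track: FeatureTrack,
    seed: int = 0,
    p_min: float = 0.05,
    p_max: float = 0.9,
    bias: float = 2.0,
    intergenic_per_mb: float = 20.0,
) -> FeatureTrack:
    """CTCF track planted preferentially inside the widest enhancer peaks.

    Each enhancer peak receives a CTCF peak with probability
    p_min + (p_max - p_min) * width_percentile**bias, so CTCF
    association rises with width. Peak heights are lognormal, giving the
    spread the upper-quartile high-confidence threshold needs. Further
    CTCF peaks are scattered uniformly along the enhancer chromosome
    (density ``intergenic_per_mb``), the background a size-matched
    enlargement null picks up.
    """
    rng = np.random.default_rng(seed)
    df = enhancer_track.df
    widths = enhancer_track.widths.astype(float)
    pct = pd.Series(widths).rank(method="average").to_numpy() / len(widths)
    p_hit = p_min + (p_max - p_min) * pct**bias
    rows = []
    for i, row in enumerate(df.itertuples(index=False)):
        # wide enhancers host more candidate sites: expected count scales
        # with both the width-percentile bias and the width itself
        mean_sites = p_hit[i] * (1.0 + (row.end - row.start) / 5_000.0)
        for _ in range(rng.poisson(mean_sites)):
            pos = int(rng.integers(row.start, max(row.end - 200, row.start + 1)))
            height = float(rng.lognormal(1.0, 1.0))
            rows.append((row.chrom, pos, pos + 200, height, height * 200))
    chrom = df["chrom"].iloc[0] if len(df) else "chrE"
    chrom_end = int(df["end"].max()) + 50_000 if len(df) else 1_000_000
    n_intergenic = int(round(intergenic_per_mb * chrom_end / 1e6))
    for start in rng.integers(0, chrom_end - 200, size=n_intergenic):
        height = float(rng.lognormal(1.0, 1.0))
        rows.append((chrom, int(start), int(start) + 200, height, height * 200))
    return FeatureTrack(
        "CTCF", enhancer_track.cell_type, pd.DataFrame(rows, columns=PEAK_COLUMNS)
    )
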