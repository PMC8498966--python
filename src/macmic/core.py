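"""The colocalization-vs-information score for chromatin feature pairs.

For every feature pair in a panel we measure (i) the mutual information
of their per-gene promoter signals and (ii) the genome-wide number of
colocalization events (>= 1 bp peak overlaps). A single ordinary
least-squares regression of colocalization count on mutual information
across the whole panel gives each pair an expected count; the score is
the relative excess

    score = (C_observed - C_expected) / C_expected

so large positive values flag pairs that colocalize far more often than
their statistical dependence predicts (the bivalent-domain regime). Each
pair's residual is tested against zero with an externally studentized
residual referred to a t distribution with n - 3 degrees of freedom.
"""
from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import t as t_dist

from . import info, intervals
from .config import RunConfig
from .model import FeatureTrack, GeneModel

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PairManifest:
    """Unordered within-cell-type feature pairs, deterministically ordered."""

    entries: tuple[tuple[str, str, str], ...]  # (cell_type, feature_a, feature_b)

    def __len__(self) -> int:
        return len(self.entries)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.entries, columns=["cell_type", "feature_a", "feature_b"])


def build_manifest(features_by_cell_type: Mapping[str, Sequence[str]]) -> PairManifest:
    """All unordered feature pairs within each cell type.

    f features in a cell type yield f(f-1)/2 pairs; 6 features give 15,
    and 15 such cell types give 225 panel pairs.
    """
    entries: list[tuple[str, str, str]] = []
    for cell_type in sorted(features_by_cell_type):
        features = sorted(set(features_by_cell_type[cell_type]))
        for fa, fb in itertools.combinations(features, 2):
            entries.append((cell_type, fa, fb))
    if not entries:
        raise ValueError("no cell type has two or more features; nothing to pair")
    return PairManifest(tuple(entries))


@dataclass
class RegressionFit:
    """OLS fit of colocalization count on mutual information."""

    intercept: float
    slope: float
    resid_se: float
    n_pairs: int
    mi: np.ndarray
    c_observed: np.ndarray

    def predict(self, mi) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(mi, dtype=float)

    @property
    def residuals(self) -> np.ndarray:
        return self.c_observed - self.predict(self.mi)


def fit_colocalization_regression(pairs: Sequence[tuple[float, float]]) -> RegressionFit:
    """Least-squares fit of C_observed on I across the panel."""
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 3:
        raise ValueError("need at least 3 (I, C) pairs to fit the regression")
    mi, c = arr[:, 0], arr[:, 1]
    if np.ptp(mi) == 0:
        raise ValueError("degenerate design: all mutual information values identical")
    X = sm.add_constant(mi)
    res = sm.OLS(c, X).fit()
    return RegressionFit(
        intercept=float(res.params[0]),
        slope=float(res.params[1]),
        resid_se=float(np.sqrt(res.mse_resid)) if res.df_resid > 0 else float("nan"),
        n_pairs=len(mi),
        mi=mi,
        c_observed=c,
    )


def macmic_score(c_observed: float, c_expected: float) -> float:
    """(C_observed - C_expected) / C_expected; NaN when C_expected <= 0.

    The regression can predict a non-positive count at very low mutual
    information; the score is then undefined rather than clamped, because
    a clamped denominator fabricates extreme values.
    """
    if not np.isfinite(c_expected) or c_expected <= 0:
        log.warning(
            "expected colocalization %.3g <= 0; score undefined for C_observed=%.3g",
            c_expected,
            c_observed,
        )
        return float("nan")
    return (c_observed - c_expected) / c_expected


def residual_pvalue(fit: RegressionFit, pair: tuple[float, float]) -> tuple[float, str]:
    """Two-sided p for the pair's residual being zero, plus its direction.

    Uses the externally studentized residual: the residual divided by the
    leave-one-out error estimate times sqrt(1 - leverage), referred to a
    t distribution with n - 3 df. Needs n_pairs >= 4; returns NaN below.
    """
    mi_val, c_val = float(pair[0]), float(pair[1])
    e = c_val - float(fit.predict(mi_val))
    direction = "above" if e > 0 else ("below" if e < 0 else "on")
    n = fit.n_pairs
    if n <= 3:
        return float("nan"), direction
    mi = fit.mi
    sxx = float(((mi - mi.mean()) ** 2).sum())
    h = 1.0 / n + (mi_val - mi.mean()) ** 2 / sxx
    sse = float((fit.residuals**2).sum())
    # leave-one-out variance; e**2/(1-h) removes this point's contribution
    s2_loo = (sse - e**2 / (1.0 - h)) / (n - 3)
    if s2_loo <= 0:
        return 0.0 if e != 0 else 1.0, direction
    t_stat = e / np.sqrt(s2_loo * (1.0 - h))
    p = 2.0 * t_dist.sf(abs(t_stat), df=n - 3)
    return float(min(p, 1.0)), direction


@dataclass(frozen=True)
class PairRecord:
    """One scored feature pair (row schema of the score_panel table)."""

    cell_type: str
    feature_a: str
    feature_b: str
    mi: float
    c_observed: float
    c_expected: float
    macmic: float
    residual_p: float
    direction: str


def pair_records(table: pd.DataFrame) -> list[PairRecord]:
    """Typed view of a score_panel result."""
    fields = [f for f in PairRecord.__dataclass_fields__]
    return [PairRecord(**{f: getattr(r, f) for f in fields}) for r in table.itertuples(index=False)]


def _pair_association(
    sig_a, sig_b, track_a, track_b, genes, config: RunConfig
) -> float:
    if config.assoc == "abs-pearson":
        return info.abs_pearson(sig_a, sig_b)
    if config.assoc != "mi":
        raise ValueError(f"unknown association measure: {config.assoc!r}")
    if config.joint_mode == "empirical-binned":
        return info.mutual_information(
            sig_a, sig_b, joint_mode="empirical-binned", bins=config.bins
        ).mi
    genome_length = config.genome_length
    models = []
    for sig, track in ((sig_a, track_a), (sig_b, track_b)):
        models.append(
            info.poisson_model(
                sig,
                mode=config.lambda_mode,
                track=track,
                genes=genes,
                genome_length=genome_length,
                upstream=config.promoter_upstream,
                downstream=config.promoter_downstream,
            )
        )
    return info.mutual_information(
        sig_a, sig_b, models[0], models[1], joint_mode="product-poisson"
    ).mi


def _infer_genome_length(tracks: Mapping[tuple[str, str], FeatureTrack]) -> float:
    """Span covered by any track, per chromosome, summed; a conservative
    stand-in for an effective genome length when none is configured."""
    span: dict[str, int] = {}
    for track in tracks.values():
        for chrom, grp in track.df.groupby("chrom"):
            hi = int(grp["end"].max())
            span[chrom] = max(span.get(chrom, 0), hi)
    return float(sum(span.values()))


def score_panel(
    manifest: PairManifest,
    tracks: Mapping[tuple[str, str], FeatureTrack],
    genes: Sequence[GeneModel],
    config: RunConfig | None = None,
) -> pd.DataFrame:
    """Score every pair in the manifest; one pooled regression per panel.

    ``tracks`` maps (cell_type, feature_name) to its FeatureTrack. Pairs
    whose association or count cannot be computed are emitted as missing
    rows and excluded from the regression. The result is sorted by score
    descending (ties: C_observed descending, then pair identity).
    """
    config = config or RunConfig()
    if config.genome_length is None:
        config = RunConfig(**{**config.as_dict(), "genome_length": _infer_genome_length(tracks)})

    # aggregate promoter signal once per (cell type, feature)
    sig_cache: dict[tuple[str, str], object] = {}

    def signals(key: tuple[str, str]):
        if key not in sig_cache:
            sig_cache[key] = intervals.map_peaks_to_promoters(
                tracks[key], genes, config.promoter_upstream, config.promoter_downstream
            )
        return sig_cache[key]

    rows: list[dict] = []
    for cell_type, fa, fb in manifest.entries:
        key_a, key_b = (cell_type, fa), (cell_type, fb)
        try:
            track_a, track_b = tracks[key_a], tracks[key_b]
            mi_val = _pair_association(
                signals(key_a), signals(key_b), track_a, track_b, genes, config
            )
            c_obs = float(
                intervals.count_colocalizations(track_a, track_b, mode=config.coloc_mode)
            )
        except (KeyError, ValueError) as exc:
            log.warning("pair (%s, %s, %s) failed: %s", cell_type, fa, fb, exc)
            mi_val, c_obs = float("nan"), float("nan")
        rows.append(
            {"cell_type": cell_type, "feature_a": fa, "feature_b": fb, "mi": mi_val, "c_observed": c_obs}
        )
    df = pd.DataFrame(rows)

    ok = df[["mi", "c_observed"]].notna().all(axis=1)
    fit = fit_colocalization_regression(list(zip(df.loc[ok, "mi"], df.loc[ok, "c_observed"])))
    df["c_expected"] = np.where(ok, fit.predict(df["mi"].fillna(0.0)), np.nan)
    df["macmic"] = [
        macmic_score(r.c_observed, r.c_expected) if ok[i] else float("nan")
        for i, r in df.iterrows()
    ]
    pvals, directions = [], []
    for i, r in df.iterrows():
        if ok[i]:
            p, d = residual_pvalue(fit, (r.mi, r.c_observed))
        else:
            p, d = float("nan"), "missing"
        pvals.append(p)
        directions.append(d)
    df["residual_p"] = pvals
    df["direction"] = directions

    df = df.sort_values(
        ["macmic", "c_observed", "cell_type", "feature_a", "feature_b"],
        ascending=[False, False, True, True, True],
        kind="mergesort",
        na_position="last",
    ).reset_index(drop=True)
    df.attrs["fit"] = fit
    df.attrs["config"] = config.as_dict()
    return df


def write_pair_table(df: pd.DataFrame, path, config: RunConfig | None = None) -> None:
    with open(path, "w") as fh:
        if config is not None:
            fh.write(config.metadata_header() + "\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g")
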