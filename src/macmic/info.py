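"""Entropy and mutual information over per-gene promoter signals.

The association measure here is a per-gene-sum variant of mutual
information: marginal and joint entropies are sums over genes of
-P * log P, where P is the probability of the observed promoter signal
under a Poisson background model. I = H(X) + H(Y) - H(X,Y) by
construction. An empirical equal-occupancy-binned estimator (the textbook
plug-in histogram MI) is provided as a cross-check, and the absolute
Pearson correlation as a simpler alternative association measure.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import poisson

from .intervals import PROMOTER_DOWNSTREAM, PROMOTER_UPSTREAM, promoter_window
from .model import FeatureTrack, GeneModel, GeneSignalVector, check_same_genes

log = logging.getLogger(__name__)

LAMBDA_MODES = ("global", "promoter-mean")
JOINT_MODES = ("product-poisson", "empirical-binned")


@dataclass
class PoissonModel:
    """Per-gene expected promoter signal (Poisson rate) for one feature.

    ``rates`` is indexed by gene_id; ``mode`` records how the rates were
    estimated and is carried into all outputs.
    """

    rates: pd.Series
    mode: str

    def __post_init__(self) -> None:
        if (self.rates < 0).any():
            raise ValueError("Poisson rates must be >= 0")


def poisson_model(
    signals: GeneSignalVector,
    mode: str = "global",
    track: FeatureTrack | None = None,
    genes: Sequence[GeneModel] | None = None,
    genome_length: float | None = None,
    upstream: int = PROMOTER_UPSTREAM,
    downstream: int = PROMOTER_DOWNSTREAM,
) -> PoissonModel:
    """Estimate per-gene Poisson rates for promoter signal.

    ``global``: a uniform-background expectation, lambda_i = (track-wide
    total signal / genome length) x window width of gene i; requires the
    track, the gene models and the effective genome length. ``promoter-mean``:
    lambda_i = mean observed promoter signal across all genes.
    """
    if mode == "promoter-mean":
        lam = float(np.mean(signals.x)) if len(signals) else 0.0
        rates = pd.Series(lam, index=signals.gene_ids)
    elif mode == "global":
        if track is None or genes is None or genome_length is None:
            raise ValueError("global lambda mode needs track, genes and genome_length")
        density = track.total_signal / float(genome_length)
        widths = {}
        for g in genes:
            pw = promoter_window(g, upstream, downstream)
            if pw is not None:
                widths[g.gene_id] = pw.window.width
        rates = pd.Series(widths, dtype=float).reindex(signals.gene_ids) * density
        if rates.isna().any():
            raise ValueError("gene set mismatch between signals and gene models")
    else:
        raise ValueError(f"unknown lambda mode: {mode!r}")
    return PoissonModel(rates=rates, mode=mode)


def poisson_logprob(x, lam):
    """log P(round(x); lam), elementwise; lam = 0 gives 0 at x = 0, -inf else."""
    x = np.asarray(x, dtype=float)
    lam = np.asarray(lam, dtype=float)
    if (x < 0).any() or (lam < 0).any():
        raise ValueError("signal and rate must be >= 0")
    k = np.rint(x)
    with np.errstate(divide="ignore", invalid="ignore"):
        logp = poisson.logpmf(k, lam)
    # scipy yields nan at lam == 0; the degenerate Poisson puts mass 1 at 0
    zero = lam == 0
    logp = np.where(zero & (k == 0), 0.0, logp)
    logp = np.where(zero & (k > 0), -np.inf, logp)
    return logp


def poisson_prob(x: float, lam: float) -> float:
    """Poisson pmf at round(x); continuous signals are rounded to counts."""
    return float(np.exp(poisson_logprob(x, lam)))


def _neg_p_log_p(logp: np.ndarray) -> np.ndarray:
    """-p log p from log p, safe at p -> 0 (term -> 0)."""
    with np.errstate(invalid="ignore"):
        term = -np.exp(logp) * logp
    return np.where(np.isneginf(logp), 0.0, term)


def _check_model(signals: GeneSignalVector, model: PoissonModel) -> np.ndarray:
    if not model.rates.index.equals(signals.gene_ids):
        raise ValueError("model rates are not aligned to the signal vector's genes")
    if signals.signal_is_width:
        raise ValueError(
            "signals derive from a plain BED track without real signal "
            "(height = width fallback); refusing information-theoretic scoring"
        )
    return model.rates.to_numpy(dtype=float)


def entropy(signals: GeneSignalVector, model: PoissonModel) -> float:
    """H = -sum over genes of P(x_i) log P(x_i), natural log."""
    lam = _check_model(signals, model)
    return float(_neg_p_log_p(poisson_logprob(signals.x, lam)).sum())


def joint_entropy(
    sig_a: GeneSignalVector,
    sig_b: GeneSignalVector,
    model_a: PoissonModel,
    model_b: PoissonModel,
    joint_mode: str = "product-poisson",
    bins: int = 16,
) -> float:
    """Joint entropy of two per-gene signal vectors.

    ``product-poisson``: P(x_i, y_i) = P(x_i) P(y_i) from the two Poisson
    marginals, summed per gene as -P log P. ``empirical-binned``: plug-in
    entropy of the 2-D equal-occupancy histogram of (x, y) over genes.
    """
    check_same_genes(sig_a, sig_b)
    if joint_mode == "product-poisson":
        lam_a = _check_model(sig_a, model_a)
        lam_b = _check_model(sig_b, model_b)
        logp = poisson_logprob(sig_a.x, lam_a) + poisson_logprob(sig_b.x, lam_b)
        return float(_neg_p_log_p(logp).sum())
    if joint_mode == "empirical-binned":
        ia = _bin_assign(sig_a.x, bins)
        ib = _bin_assign(sig_b.x, bins)
        joint = pd.crosstab(ia, ib).to_numpy(dtype=float)
        p = joint.ravel() / joint.sum()
        p = p[p > 0]
        return float(-(p * np.log(p)).sum())
    raise ValueError(f"unknown joint mode: {joint_mode!r}")


def _bin_assign(x: np.ndarray, bins: int) -> np.ndarray:
    """Equal-occupancy bin index per observation; ties collapse bins."""
    edges = np.unique(np.quantile(x, np.linspace(0, 1, bins + 1)[1:-1]))
    return np.searchsorted(edges, x, side="right")


def _binned_entropy(idx: np.ndarray) -> float:
    _, counts = np.unique(idx, return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log(p)).sum())


@dataclass(frozen=True)
class PairInformation:
    """Marginal/joint entropies and mutual information for one feature pair."""

    feature_a: str
    feature_b: str
    h_a: float
    h_b: float
    h_ab: float
    joint_mode: str
    lambda_mode: str
    log_base: str = "e"

    @property
    def mi(self) -> float:
        return self.h_a + self.h_b - self.h_ab

    def in_base(self, base: float) -> "PairInformation":
        """Entropies rescaled from nats to the given log base."""
        f = 1.0 / np.log(base)
        return PairInformation(
            self.feature_a, self.feature_b, self.h_a * f, self.h_b * f, self.h_ab * f,
            self.joint_mode, self.lambda_mode, log_base=str(base),
        )


def mutual_information(
    sig_a: GeneSignalVector,
    sig_b: GeneSignalVector,
    model_a: PoissonModel | None = None,
    model_b: PoissonModel | None = None,
    joint_mode: str = "product-poisson",
    bins: int = 16,
) -> PairInformation:
    """I = H(X) + H(Y) - H(X,Y), symmetric in its inputs.

    In product-poisson mode the marginal entropies use the Poisson models;
    in empirical-binned mode all three entropies come from the same
    equal-occupancy binning, so the estimator is the standard plug-in
    histogram MI (non-negative; equals H(X) when Y = X).
    """
    check_same_genes(sig_a, sig_b)
    if joint_mode == "product-poisson":
        if model_a is None or model_b is None:
            raise ValueError("product-poisson mode requires both Poisson models")
        h_a = entropy(sig_a, model_a)
        h_b = entropy(sig_b, model_b)
        lambda_mode = model_a.mode
    elif joint_mode == "empirical-binned":
        h_a = _binned_entropy(_bin_assign(sig_a.x, bins))
        h_b = _binned_entropy(_bin_assign(sig_b.x, bins))
        lambda_mode = "none"
    else:
        raise ValueError(f"unknown joint mode: {joint_mode!r}")
    h_ab = joint_entropy(sig_a, sig_b, model_a, model_b, joint_mode=joint_mode, bins=bins)
    return PairInformation(
        feature_a=sig_a.feature_name,
        feature_b=sig_b.feature_name,
        h_a=h_a,
        h_b=h_b,
        h_ab=h_ab,
        joint_mode=joint_mode,
        lambda_mode=lambda_mode,
    )


def abs_pearson(sig_a: GeneSignalVector, sig_b: GeneSignalVector) -> float:
    """|Pearson r| of promoter signals over genes; 0 (warned) if degenerate."""
    check_same_genes(sig_a, sig_b)
    if len(sig_a) < 3:
        raise ValueError("need at least 3 genes for a correlation")
    x, y = sig_a.x, sig_b.x
    if np.std(x) == 0 or np.std(y) == 0:
        log.warning("zero-variance signal vector; |r| defined as 0")
        return 0.0
    return float(abs(np.corrcoef(x, y)[0, 1]))
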