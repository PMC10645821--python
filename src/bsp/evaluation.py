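"""Power-vs-FDR analysis, combined-probability meta-analysis, Moran's I baseline."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.stats as st
from scipy.spatial import cKDTree

from bsp.core import Dataset, minmax_normalize, rescale_coordinates

__all__ = [
    "PowerCurve",
    "power_curve",
    "average_power_curves",
    "tpr_at_fdr",
    "auroc",
    "combine_pvalues",
    "morans_i_baseline",
]

COMBINERS = ("fisher", "pearson", "tippett", "stouffer", "mudholkar_george")


@dataclass(frozen=True)
class PowerCurve:
    """Empirical (FDR, TPR) pairs over a p-value threshold grid."""

    thresholds: np.ndarray
    fdr: np.ndarray
    tpr: np.ndarray
    n_replicates: int = 1
    tpr_sd: np.ndarray | None = None


def power_curve(
    p_values: np.ndarray, labels: np.ndarray, thresholds: np.ndarray | None = None
) -> PowerCurve:
    """TPR and empirical FDR at each threshold t, with calls = {p <= t}.

    ``labels`` are ground-truth SVG indicators (bool, or "svg"/"null"
    strings).  FDR is FP / max(1, FP + TP); TPR is TP / #SVG.
    """
    p_values = np.asarray(p_values, dtype=np.float64)
    labels = np.asarray(labels)
    if labels.dtype != bool:
        labels = labels == "svg"
    if thresholds is None:
        thresholds = np.unique(np.concatenate([p_values, [0.0, 1.0]]))
    thresholds = np.sort(np.asarray(thresholds, dtype=np.float64))
    n_svg = int(labels.sum())
    if n_svg == 0:
        raise ValueError("no ground-truth SVGs in labels")
    calls = p_values[None, :] <= thresholds[:, None]
    tp = (calls & labels[None, :]).sum(axis=1)
    fp = (calls & ~labels[None, :]).sum(axis=1)
    if not calls.any():
        warnings.warn("no positives at any threshold; curve is all zeros", stacklevel=2)
    fdr = fp / np.maximum(1, fp + tp)
    tpr = tp / n_svg
    return PowerCurve(thresholds=thresholds, fdr=fdr, tpr=tpr)


def average_power_curves(curves: list[PowerCurve], thresholds: np.ndarray) -> PowerCurve:
    """Average replicate curves on a common threshold grid."""
    thresholds = np.sort(np.asarray(thresholds, dtype=np.float64))
    tprs, fdrs = [], []
    for c in curves:
        idx = np.searchsorted(c.thresholds, thresholds, side="right") - 1
        idx = np.clip(idx, 0, c.thresholds.size - 1)
        tprs.append(c.tpr[idx])
        fdrs.append(c.fdr[idx])
    tprs = np.array(tprs)
    return PowerCurve(
        thresholds=thresholds,
        fdr=np.mean(fdrs, axis=0),
        tpr=tprs.mean(axis=0),
        n_replicates=len(curves),
        tpr_sd=tprs.std(axis=0),
    )


def tpr_at_fdr(p_values: np.ndarray, labels: np.ndarray, fdr_level: float = 0.05) -> float:
    """Maximum TPR attainable at any threshold whose empirical FDR <= level."""
    curve = power_curve(p_values, labels)
    ok = curve.fdr <= fdr_level
    return float(curve.tpr[ok].max()) if ok.any() else 0.0


def auroc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the ROC curve of score-ranking SVGs above nulls.

    Mann-Whitney formulation with midrank tie handling; NaN scores rank
    lowest.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    if labels.dtype != bool:
        labels = labels == "svg"
    scores = np.where(np.isnan(scores), -np.inf, scores)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("need both positive and negative labels")
    ranks = st.rankdata(scores)
    return float((ranks[labels].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def combine_pvalues(per_slice_p: np.ndarray, method: str = "fisher") -> np.ndarray:
    """Combine per-slice p-values into one p per gene (rows = genes).

    Closed-form reference distributions: Fisher -2*sum(ln p) ~ chi2(2k);
    Pearson -2*sum(ln(1-p)) ~ chi2(2k) with a lower-tail p; Tippett
    min-p ~ Beta(1, k); Stouffer sum(z)/sqrt(k) ~ N(0,1);
    Mudholkar-George logit sum with its Student-t approximation.
    """
    p = np.atleast_2d(np.asarray(per_slice_p, dtype=np.float64))
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    if np.any(p == 0):
        warnings.warn("p == 0 mapped to the smallest positive float", stacklevel=2)
        p = np.maximum(p, np.finfo(np.float64).tiny)
    k = p.shape[1]
    if method == "fisher":
        stat = -2.0 * np.log(p).sum(axis=1)
        return st.chi2.sf(stat, 2 * k)
    if method == "pearson":
        # rejects for small p: the statistic is small when all p are small
        stat = -2.0 * np.log1p(-p).sum(axis=1)
        return st.chi2.cdf(stat, 2 * k)
    if method == "tippett":
        # Beta(1, k) CDF of the minimum, in cancellation-safe form
        return -np.expm1(k * np.log1p(-p.min(axis=1)))
    if method == "stouffer":
        z = st.norm.isf(p).sum(axis=1) / np.sqrt(k)
        return st.norm.sf(z)
    if method == "mudholkar_george":
        stat = -np.log(p / (1.0 - p)).sum(axis=1)
        nu = 5 * k + 4
        scale = np.sqrt(3.0 * nu / (k * np.pi**2 * (nu - 2)))
        return st.t.sf(stat * scale, nu)
    raise ValueError(f"unknown method {method!r}; choose one of {COMBINERS}")


def morans_i_baseline(
    dataset: Dataset,
    k_neighbors: int = 6,
    n_permutations: int = 999,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Moran's I with row-normalized kNN weights and permutation p-values.

    Returns (I, p) per gene; constant genes get I = NaN and p = 1.  The
    one-sided p is (1 + #{I_perm >= I_obs}) / (n_permutations + 1).
    """
    coords = dataset.coordinates
    if not coords.is_rescaled:
        coords = rescale_coordinates(coords)
    expr = dataset.expression
    if expr.normalization_state == "raw":
        expr = minmax_normalize(expr)
    pos = coords.positions
    m = pos.shape[0]
    tree = cKDTree(pos)
    _, nn = tree.query(pos, k=k_neighbors + 1)
    nn = nn[:, 1:]  # drop self

    x = expr.values
    z = x - x.mean(axis=1, keepdims=True)
    denom = (z**2).sum(axis=1)
    constant = denom == 0

    def moran(zc: np.ndarray) -> np.ndarray:
        # row-normalized weights: sum_i mean_{j in nn(i)} z_i z_j; S0 = m
        lag = zc[:, nn].mean(axis=2)
        return (zc * lag).sum(axis=1) * m / np.maximum(denom, 1e-300) / m

    i_obs = moran(z)
    rng = np.random.default_rng(seed)
    exceed = np.zeros(x.shape[0], dtype=np.int64)
    for _ in range(n_permutations):
        perm = rng.permutation(m)
        exceed += moran(z[:, perm]) >= i_obs
    p = (1.0 + exceed) / (n_permutations + 1.0)
    i_obs[constant] = np.nan
    p[constant] = 1.0
    return i_obs, p
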