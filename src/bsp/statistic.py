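"""The big-small patch test: patches, local means, variance ratio, p-values.

Pipeline: min-max normalize expression, density-rescale coordinates,
compute patch-local expression means at a small radius D1 and a big
radius D2, take per-gene population variances of the local means, weight
the big/small variance ratio by relative gene variance, fit the ratio
distribution (lognormal by default) across all genes, and assign each
gene the upper-tail probability of its ratio under the fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import scipy.sparse as sp
import scipy.stats as st
from scipy.spatial import cKDTree

from bsp.core import (
    Dataset,
    ExpressionMatrix,
    SpotCoordinates,
    constant_gene_mask,
    minmax_normalize,
    rescale_coordinates,
)

__all__ = [
    "PatchIndex",
    "BSPParams",
    "FitParams",
    "BSPResult",
    "build_patch_index",
    "local_means",
    "patch_variance",
    "gene_weights",
    "ratio_statistic",
    "fit_null_distribution",
    "compute_pvalues",
    "augment_null_genes",
    "run_bsp",
]


class PatchIndex:
    """Radius-neighbor query structure over rescaled spot positions.

    Membership uses the strict inequality dist < D and excludes the focal
    spot itself; duplicate positions are mutual neighbors for any D > 0.
    Results are identical to brute-force pairwise-distance enumeration.
    """

    def __init__(self, positions: np.ndarray):
        positions = np.asarray(positions, dtype=np.float64)
        if positions.shape[0] < 2:
            raise ValueError("patch index requires at least 2 spots")
        self.positions = positions
        self._tree = cKDTree(positions)

    @property
    def n_spots(self) -> int:
        return self.positions.shape[0]

    def query(self, spot: int, radius: float) -> np.ndarray:
        """Indices of spots strictly within ``radius`` of ``spot`` (spot excluded)."""
        if radius <= 0:
            return np.empty(0, dtype=np.intp)
        cand = np.asarray(self._tree.query_ball_point(self.positions[spot], radius), dtype=np.intp)
        cand = cand[cand != spot]
        if cand.size == 0:
            return cand
        d = np.linalg.norm(self.positions[cand] - self.positions[spot], axis=1)
        return np.sort(cand[d < radius])

    def membership_matrix(self, radius: float, include_center: bool = False) -> sp.csr_matrix:
        """M x M sparse row-averaging matrix: row i holds 1/|S_i| on S_i.

        Rows with an empty patch fall back to the spot's own value (a lone
        1 on the diagonal) so local means stay defined at isolated spots.
        """
        m = self.n_spots
        neighbor_lists = self._tree.query_ball_point(self.positions, radius)
        rows, cols = [], []
        for i, cand in enumerate(neighbor_lists):
            cand = np.asarray(cand, dtype=np.intp)
            cand = cand[cand != i]
            if cand.size:
                d = np.linalg.norm(self.positions[cand] - self.positions[i], axis=1)
                cand = cand[d < radius]
            if include_center:
                cand = np.concatenate([cand, [i]])
            if cand.size == 0:
                cand = np.array([i], dtype=np.intp)  # isolated-spot fallback
            rows.append(np.full(cand.size, i, dtype=np.intp))
            cols.append(cand)
        rows = np.concatenate(rows)
        cols = np.concatenate(cols)
        w = sp.csr_matrix(
            (np.ones(rows.size), (rows, cols)), shape=(m, m), dtype=np.float64
        )
        counts = np.asarray(w.sum(axis=1)).ravel()
        inv = sp.diags(1.0 / counts)
        return (inv @ w).tocsr()


def build_patch_index(coords: SpotCoordinates) -> PatchIndex:
    if not coords.is_rescaled:
        raise ValueError("coordinates must be rescaled before building the patch index")
    return PatchIndex(coords.positions)


def local_means(
    expr: ExpressionMatrix,
    index: PatchIndex,
    radius: float,
    include_center: bool = False,
) -> np.ndarray:
    """N x M matrix of patch-local expression means at the given radius."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    if expr.n_spots != index.n_spots:
        raise ValueError("expression and patch index disagree on spot count")
    w = index.membership_matrix(radius, include_center=include_center)
    return expr.values @ w.T


def patch_variance(local_mean_rows: np.ndarray) -> np.ndarray:
    """Population variance (divisor M) of local means across spots, per gene."""
    lm = np.atleast_2d(np.asarray(local_mean_rows, dtype=np.float64))
    return np.var(lm, axis=1)


def gene_weights(expr: ExpressionMatrix) -> np.ndarray:
    """Per-gene variance relative to the maximal-variance gene, w in [0, 1]."""
    if expr.normalization_state != "minmax":
        raise ValueError("weights are defined on min-max normalized expression")
    var = np.var(expr.values, axis=1)
    vmax = var.max()
    if vmax == 0:
        raise ValueError("all genes are constant: no expression signal anywhere")
    return var / vmax


def ratio_statistic(
    var_big: np.ndarray, var_small: np.ndarray, weights: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Weighted variance ratio r = w * var_big / var_small per gene.

    Returns (ratios, undefined_mask); genes with zero small-patch variance
    get NaN ratios and a True flag instead of an exception.
    """
    var_big = np.asarray(var_big, dtype=np.float64)
    var_small = np.asarray(var_small, dtype=np.float64)
    weights = np.asarray(weights, dtype=np.float64)
    undefined = var_small == 0
    safe = np.where(undefined, 1.0, var_small)
    r = weights * var_big / safe
    r[undefined] = np.nan
    return r, undefined


@dataclass(frozen=True)
class FitParams:
    """Fitted null family and parameters, plus the beta-domain map if used."""

    family: str
    params: dict
    n_fit: int

    def sf(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.float64)
        if self.family == "lognormal":
            return st.lognorm.sf(x, s=self.params["sigma"], scale=np.exp(self.params["mu"]))
        if self.family == "beta":
            scaled = x / self.params["domain_scale"]
            return st.beta.sf(scaled, self.params["a"], self.params["b"])
        raise ValueError(f"unknown family {self.family!r}")


def fit_null_distribution(
    ratios: np.ndarray, family: str = "lognormal", min_ratios: int = 50
) -> FitParams:
    """Maximum-likelihood fit of the ratio distribution.

    All supplied finite positive ratios enter the fit — SVGs included,
    under the assumption that only a small tail fraction of genes is
    spatially variable.  Undefined (NaN) and zero ratios are excluded.
    """
    ratios = np.asarray(ratios, dtype=np.float64)
    finite = ratios[np.isfinite(ratios) & (ratios > 0)]
    if finite.size < min_ratios:
        raise ValueError(
            f"only {finite.size} finite positive ratios (< {min_ratios}); "
            "enable null-gene augmentation to stabilize the fit"
        )
    if np.ptp(finite) == 0:
        raise ValueError("all ratios are identical; the fit is degenerate")
    if family == "lognormal":
        # closed-form MLE with location fixed at zero
        logs = np.log(finite)
        mu = float(np.mean(logs))
        sigma = float(np.std(logs))
        return FitParams("lognormal", {"mu": mu, "sigma": sigma}, int(finite.size))
    if family == "beta":
        # beta support is (0, 1): map ratios there by a recorded scale
        domain_scale = float(finite.max() * (1.0 + 1e-6))
        scaled = finite / domain_scale
        a, b, _, _ = st.beta.fit(scaled, floc=0, fscale=1)
        return FitParams(
            "beta",
            {"a": float(a), "b": float(b), "domain_scale": domain_scale},
            int(finite.size),
        )
    raise ValueError(f"unknown family {family!r}; choose 'lognormal' or 'beta'")


def compute_pvalues(ratios: np.ndarray, fit: FitParams) -> np.ndarray:
    """Upper-tail probability of each ratio under the fitted null.

    Undefined (NaN) ratios get p = 1 by convention.
    """
    ratios = np.asarray(ratios, dtype=np.float64)
    p = np.ones_like(ratios)
    ok = np.isfinite(ratios)
    p[ok] = np.clip(fit.sf(ratios[ok]), 0.0, 1.0)
    return p


def augment_null_genes(
    expr: ExpressionMatrix, null_total: int, rng: np.random.Generator
) -> tuple[ExpressionMatrix, np.ndarray]:
    """Append seeded spatial permutations of observed genes as null genes.

    Source genes are cycled until the matrix reaches ``null_total`` genes.
    Returns the augmented matrix and a boolean is-null flag per gene
    (False for the original genes).  Each null gene preserves the value
    multiset of its source, so per-gene variances are unchanged.
    """
    n, m = expr.n_genes, expr.n_spots
    n_add = null_total - n
    if n_add <= 0:
        return expr, np.zeros(n, dtype=bool)
    extra = np.empty((n_add, m))
    for k in range(n_add):
        src = expr.values[k % n]
        extra[k] = src[rng.permutation(m)]
    null_ids = np.array([f"__null_{k}" for k in range(n_add)], dtype=object)
    aug = ExpressionMatrix(
        gene_ids=np.concatenate([expr.gene_ids, null_ids]),
        spot_ids=expr.spot_ids,
        values=np.vstack([expr.values, extra]),
        normalization_state=expr.normalization_state,
    )
    flags = np.concatenate([np.zeros(n, dtype=bool), np.ones(n_add, dtype=bool)])
    return aug, flags


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.clip(q, 0, 1)
    return out


@dataclass(frozen=True)
class BSPParams:
    """Tuning knobs of the big-small patch test.

    D1 captures nearest neighbors on the density-rescaled coordinates
    (average spacing ~1 unit); D2 aggregates over a wider context.  When a
    panel has fewer than ``null_augment_threshold`` genes, permuted null
    genes are appended up to ``null_total`` so the ratio distribution can
    be fitted reliably.
    """

    d1: float = 1.0
    d2: float = 3.0
    family: str = "lognormal"
    alpha: float = 0.05
    include_center: bool = False
    null_augment_threshold: int = 1000
    null_total: int = 10000
    min_ratios_for_fit: int = 50
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.d1 < self.d2):
            raise ValueError("need 0 < d1 < d2")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")


@dataclass(frozen=True)
class BSPResult:
    """Per-gene output of the test, in input gene order."""

    gene_ids: np.ndarray
    ratio: np.ndarray
    weight: np.ndarray
    p_value: np.ndarray
    q_value: np.ndarray
    is_svg: np.ndarray
    fit_params: FitParams
    constant_gene: np.ndarray
    undefined_ratio: np.ndarray
    alpha: float

    @property
    def n_genes(self) -> int:
        return self.gene_ids.size

    def ranked_order(self) -> np.ndarray:
        """Gene indices sorted by increasing p (ties broken by input order)."""
        return np.argsort(self.p_value, kind="stable")


def run_bsp(dataset: Dataset, params: BSPParams | None = None) -> BSPResult:
    """Run the full big-small patch pipeline on a dataset.

    Normalizes expression and coordinates, optionally augments low-gene
    panels with permuted null genes, computes the weighted big/small
    variance ratio at (d1, d2), fits the chosen null family over all
    ratios, and reports upper-tail p-values for the original genes only.
    """
    params = params or BSPParams()
    expr = dataset.expression
    if expr.normalization_state == "raw":
        expr = minmax_normalize(expr, allow_negative=True)
    coords = dataset.coordinates
    if not coords.is_rescaled:
        coords = rescale_coordinates(coords)

    n_original = expr.n_genes
    constant = constant_gene_mask(expr)
    null_flags = np.zeros(expr.n_genes, dtype=bool)
    if expr.n_genes < params.null_augment_threshold:
        rng = np.random.default_rng(params.seed)
        expr, null_flags = augment_null_genes(expr, params.null_total, rng)

    index = build_patch_index(coords)
    lm_small = local_means(expr, index, params.d1, include_center=params.include_center)
    lm_big = local_means(expr, index, params.d2, include_center=params.include_center)
    var_small = patch_variance(lm_small)
    var_big = patch_variance(lm_big)
    weights = gene_weights(expr)
    ratios, undefined = ratio_statistic(var_big, var_small, weights)

    fit = fit_null_distribution(ratios, params.family, params.min_ratios_for_fit)
    p_all = compute_pvalues(ratios, fit)

    keep = ~null_flags
    p = p_all[keep][:n_original]
    ratio = ratios[keep][:n_original]
    weight = weights[keep][:n_original]
    undef = undefined[keep][:n_original]
    p[constant] = 1.0
    q = _benjamini_hochberg(p)
    return BSPResult(
        gene_ids=dataset.expression.gene_ids,
        ratio=ratio,
        weight=weight,
        p_value=p,
        q_value=q,
        is_svg=p < params.alpha,
        fit_params=fit,
        constant_gene=constant,
        undefined_ratio=undef,
        alpha=params.alpha,
    )
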