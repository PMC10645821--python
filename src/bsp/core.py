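"""Data model, expression normalization, and density-based coordinate rescaling.

The types here are thin, validated containers shared by the statistic,
simulation, and I/O layers.  Spots are stored 0-indexed internally;
string identifiers are preserved for reporting.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np


def _as_id_array(ids, what: str) -> np.ndarray:
    arr = np.asarray(ids, dtype=object)
    if arr.ndim != 1:
        raise ValueError(f"{what} must be one-dimensional")
    if len(set(arr.tolist())) != arr.size:
        raise ValueError(f"duplicate {what} found")
    return arr


@dataclass(frozen=True)
class SpotCoordinates:
    """Spot identifiers plus 2D or 3D positions.

    Positions are in arbitrary length units before rescaling and in
    density units (average spot-to-spot spacing close to one) afterwards.
    """

    spot_ids: np.ndarray
    positions: np.ndarray
    is_rescaled: bool = False

    def __post_init__(self):
        object.__setattr__(self, "spot_ids", _as_id_array(self.spot_ids, "spot_ids"))
        pos = np.asarray(self.positions, dtype=np.float64)
        if pos.ndim != 2 or pos.shape[1] not in (2, 3):
            raise ValueError("positions must be an (M, d) array with d in {2, 3}")
        if pos.shape[0] != self.spot_ids.size:
            raise ValueError("positions and spot_ids disagree on spot count")
        if pos.shape[0] < 2:
            raise ValueError("need at least 2 spots")
        if not np.all(np.isfinite(pos)):
            raise ValueError("positions contain non-finite values")
        object.__setattr__(self, "positions", pos)

    @property
    def n_spots(self) -> int:
        return self.positions.shape[0]

    @property
    def ndim(self) -> int:
        return self.positions.shape[1]

    def axis_ranges(self) -> np.ndarray:
        """Per-axis max - min of the bounding box."""
        return self.positions.max(axis=0) - self.positions.min(axis=0)


@dataclass(frozen=True)
class ExpressionMatrix:
    """Gene x spot non-negative expression values.

    ``normalization_state`` is ``"raw"`` or ``"minmax"``; after min-max
    normalization every entry lies in [0, 1] and each non-constant gene
    attains both endpoints.
    """

    gene_ids: np.ndarray
    spot_ids: np.ndarray
    values: np.ndarray
    normalization_state: str = "raw"

    def __post_init__(self):
        object.__setattr__(self, "gene_ids", _as_id_array(self.gene_ids, "gene_ids"))
        object.__setattr__(self, "spot_ids", _as_id_array(self.spot_ids, "spot_ids"))
        vals = np.asarray(self.values, dtype=np.float64)
        if vals.ndim != 2:
            raise ValueError("values must be a 2D gene x spot matrix")
        if vals.shape != (self.gene_ids.size, self.spot_ids.size):
            raise ValueError(
                f"values shape {vals.shape} does not match "
                f"({self.gene_ids.size} genes, {self.spot_ids.size} spots)"
            )
        if np.any(np.isnan(vals)):
            raise ValueError("expression contains NaN values")
        if self.normalization_state not in ("raw", "minmax"):
            raise ValueError("normalization_state must be 'raw' or 'minmax'")
        object.__setattr__(self, "values", vals)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_spots(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class Dataset:
    """An expression matrix paired with the coordinates of its spots."""

    expression: ExpressionMatrix
    coordinates: SpotCoordinates

    def __post_init__(self):
        if self.expression.spot_ids.size != self.coordinates.spot_ids.size or not np.all(
            self.expression.spot_ids == self.coordinates.spot_ids
        ):
            raise ValueError("expression and coordinates disagree on spot ids/order")


def minmax_normalize(expr: ExpressionMatrix, allow_negative: bool = False) -> ExpressionMatrix:
    """Scale each gene to [0, 1] via (x - min) / (max - min).

    Constant genes map to all-zeros (the range is zero, so the formula is
    undefined; they carry no signal and downstream assigns them p = 1).
    Negative entries are rejected by default: raw measured expression is
    non-negative, and a negative value indicates a corrupted input.
    ``allow_negative`` lifts the check for simulated matrices carrying
    additive Gaussian noise — the per-gene min-max map absorbs any
    location shift, so the result is unaffected.
    """
    if expr.normalization_state != "raw":
        raise ValueError("input is already normalized")
    vals = expr.values
    if not allow_negative and np.any(vals < 0):
        raise ValueError("expression contains negative values; refusing to normalize")
    lo = vals.min(axis=1, keepdims=True)
    hi = vals.max(axis=1, keepdims=True)
    rng = hi - lo
    constant = rng[:, 0] == 0
    safe_rng = np.where(rng == 0, 1.0, rng)
    out = (vals - lo) / safe_rng
    out[constant, :] = 0.0
    return ExpressionMatrix(
        gene_ids=expr.gene_ids,
        spot_ids=expr.spot_ids,
        values=out,
        normalization_state="minmax",
    )


def constant_gene_mask(expr: ExpressionMatrix) -> np.ndarray:
    """Boolean mask of genes whose value is identical across all spots."""
    return expr.values.max(axis=1) == expr.values.min(axis=1)


def rescale_coordinates(coords: SpotCoordinates) -> SpotCoordinates:
    """Rescale positions so that spot density is approximately one per unit.

    All axes are multiplied by (M / prod(axis ranges)) ** (1/d), where the
    ranges come from the axis-aligned bounding box (a rectangle in 2D, a
    cube in 3D).  After rescaling the average spot-to-spot distance is
    close to one unit, which is what makes the default patch radii
    (D1 = 1, D2 = 3) meaningful across datasets.
    """
    if coords.is_rescaled:
        raise ValueError("coordinates are already rescaled")
    ranges = coords.axis_ranges()
    if np.any(ranges <= 0):
        bad = [i for i, r in enumerate(ranges) if r <= 0]
        axes = ", ".join("xyz"[i] for i in bad)
        raise ValueError(
            f"axis ({axes}) has zero range: all spots are degenerate along it; "
            "drop the axis and analyze in the lower dimension"
        )
    d = coords.ndim
    factor = (coords.n_spots / np.prod(ranges)) ** (1.0 / d)
    return SpotCoordinates(
        spot_ids=coords.spot_ids,
        positions=coords.positions * factor,
        is_rescaled=True,
    )
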