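"""Labeled 2D simulations: pattern genes with fold-change structure plus permuted nulls.

Spatially variable genes carry a log-normal signal whose log-mean is
elevated by log(FC) inside a geometric pattern region (hotspot disc,
diagonal streak band, or annulus); null genes are seeded spatial
permutations of the pattern genes, which destroys the spatial structure
while preserving each gene's value distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from bsp.core import Dataset, ExpressionMatrix, SpotCoordinates

__all__ = [
    "Sim2DConfig",
    "SimulatedDataset",
    "generate_spots_2d",
    "make_pattern_mask_2d",
    "simulate_expression_2d",
    "simulate_dataset_2d",
]

PATTERNS_2D = ("hotspot", "streak", "annulus")


@dataclass(frozen=True)
class Sim2DConfig:
    n_spots: int = 260
    n_svg: int = 1000
    n_null: int = 9000
    fold_change: float = 3.0
    noise_sd: float = 0.5
    pattern: str = "hotspot"
    # geometry, as fractions of the domain side length
    hotspot_radius: float = 0.28
    streak_width: float = 0.25
    annulus_radii: tuple[float, float] = (0.25, 0.40)
    base_mean: float = 1.0
    domain_size: float = 10.0
    seed: int = 0

    def __post_init__(self):
        if self.n_svg < 0 or self.n_null < 0:
            raise ValueError("gene counts must be non-negative")
        if self.fold_change <= 1:
            raise ValueError("fold_change must exceed 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.pattern not in PATTERNS_2D:
            raise ValueError(f"pattern must be one of {PATTERNS_2D}")


@dataclass(frozen=True)
class SimulatedDataset:
    """Expression + coordinates + ground-truth labels from a seeded generator.

    ``labels`` holds "svg" / "null" per gene; ``mask`` marks the spots
    inside the spatial pattern.  Shared by the 2D and 3D simulators.
    """

    dataset: Dataset
    labels: np.ndarray
    mask: np.ndarray
    config: dict

    @property
    def is_svg(self) -> np.ndarray:
        return self.labels == "svg"


def generate_spots_2d(n: int, seed: int, domain_size: float = 10.0) -> SpotCoordinates:
    """Uniform random spots in a square (a homogeneous Poisson layout at fixed n)."""
    if n < 10:
        raise ValueError("need at least 10 spots")
    rng = np.random.default_rng(seed)
    pos = rng.uniform(0.0, domain_size, size=(n, 2))
    ids = np.array([f"spot_{i}" for i in range(n)], dtype=object)
    return SpotCoordinates(spot_ids=ids, positions=pos)


def make_pattern_mask_2d(coords: SpotCoordinates, config: Sim2DConfig) -> np.ndarray:
    """Boolean per-spot membership for the configured pattern geometry."""
    pos = coords.positions
    lo = pos.min(axis=0)
    hi = pos.max(axis=0)
    side = float(np.max(hi - lo))
    center = (lo + hi) / 2.0
    if config.pattern == "hotspot":
        r = config.hotspot_radius * side
        mask = np.linalg.norm(pos - center, axis=1) < r
    elif config.pattern == "streak":
        # band around the main diagonal of the bounding box
        u = pos - lo
        dist_to_diag = np.abs(u[:, 0] - u[:, 1]) / np.sqrt(2.0)
        mask = dist_to_diag < config.streak_width * side / 2.0
    else:  # annulus
        r_in, r_out = (f * side for f in config.annulus_radii)
        d = np.linalg.norm(pos - center, axis=1)
        mask = (d >= r_in) & (d < r_out)
    if not mask.any():
        raise ValueError("pattern mask is empty: enlarge the pattern geometry")
    if mask.all():
        raise ValueError("pattern mask covers every spot: shrink the pattern geometry")
    return mask


def simulate_expression_2d(
    coords: SpotCoordinates, mask: np.ndarray, config: Sim2DConfig
) -> SimulatedDataset:
    """Draw pattern genes and permuted nulls over the given spots and mask.

    Pattern genes: exp(N(log(base_mean) + log(FC) * in_pattern, sigma^2)),
    so at sigma = 0 the realized pattern/non-pattern mean ratio is exactly
    FC.  Null genes recycle the pattern genes' values under fresh spatial
    permutations.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.size != coords.n_spots:
        raise ValueError("mask length does not match spot count")
    rng = np.random.default_rng(config.seed + 1)
    m = coords.n_spots
    log_mu = np.where(mask, np.log(config.fold_change * config.base_mean), np.log(config.base_mean))
    svg = np.exp(log_mu + config.noise_sd * rng.standard_normal((config.n_svg, m)))
    null = np.empty((config.n_null, m))
    for k in range(config.n_null):
        null[k] = svg[k % config.n_svg][rng.permutation(m)]
    values = np.vstack([svg, null]) if config.n_null else svg
    gene_ids = np.array(
        [f"svg_{k}" for k in range(config.n_svg)]
        + [f"null_{k}" for k in range(config.n_null)],
        dtype=object,
    )
    expr = ExpressionMatrix(gene_ids=gene_ids, spot_ids=coords.spot_ids, values=values)
    labels = np.array(["svg"] * config.n_svg + ["null"] * config.n_null, dtype=object)
    return SimulatedDataset(
        dataset=Dataset(expression=expr, coordinates=coords),
        labels=labels,
        mask=mask,
        config=asdict(config),
    )


def simulate_dataset_2d(config: Sim2DConfig) -> SimulatedDataset:
    """Spots, mask, and expression in one seeded call."""
    coords = generate_spots_2d(config.n_spots, config.seed, config.domain_size)
    mask = make_pattern_mask_2d(coords, config)
    return simulate_expression_2d(coords, mask, config)
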