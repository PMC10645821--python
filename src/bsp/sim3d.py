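"""3D simulations: stacked slices, random-walk sphere patterns, quantile signal.

Geometry follows a stacked-section layout: each z-slice gets a fixed
number of uniformly placed spots and the slice index (optionally scaled)
becomes the z-coordinate.  Continuous spatial patterns are unions of
spheres whose centers follow a fixed-step random walk; the walk's
direction constraints control the pattern shape:

* ``curved_stick``  — monotone in z and in one of x/y
* ``thin_plate``    — monotone in z only
* ``irregular_lump`` — unconstrained

A discrete pattern places 16 jittered sphere centers on a 4x4 grid.
Marked spots (within radius r of any center) sample expression from the
upper q-quantile of a right-skewed base pool; unmarked spots sample from
the whole pool.  Nulls are spatial permutations of the pattern genes.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import scipy.stats as st
from scipy.spatial import cKDTree

from bsp.core import Dataset, ExpressionMatrix, SpotCoordinates
from bsp.sim2d import SimulatedDataset

__all__ = [
    "Sim3DConfig",
    "PatternCenters",
    "generate_spots_3d",
    "random_walk_centers",
    "discrete_pattern_centers",
    "mark_cells",
    "sample_expression_3d",
    "add_noise",
    "apply_dropout",
    "simulate_dataset_3d",
    "nominal_fold_change",
]

CONTINUOUS_PATTERNS = ("curved_stick", "thin_plate", "irregular_lump")

# Log-sd of the base expression pool.  With a standard lognormal pool the
# marked/unmarked mean ratio is Phi(s - z_q) / (1 - q); s = Phi^{-1}(0.80)
# makes the quantile thresholds {0.66, 0.80, 0.88} land on fold changes
# {1.96, 2.50, 3.08}, i.e. the nominal {2.0, 2.5, 3.0} within 3.5%.
DEFAULT_POOL_LOG_SD = float(st.norm.ppf(0.80))


def nominal_fold_change(q: float, pool_log_sd: float = DEFAULT_POOL_LOG_SD) -> float:
    """Expected marked/unmarked mean ratio for a lognormal pool at quantile q.

    Closed form: E[X | X > x_q] / E[X] = Phi(s - Phi^{-1}(q)) / (1 - q)
    for X lognormal with log-sd s.
    """
    return float(st.norm.cdf(pool_log_sd - st.norm.ppf(q)) / (1.0 - q))


@dataclass(frozen=True)
class Sim3DConfig:
    n_per_slice: int = 225
    n_slices: int = 10
    pattern: str = "irregular_lump"
    sphere_radius: float = 2.0
    quantile: float = 0.80
    noise_tau: float = 0.0
    n_svg: int = 1000
    nulls_per_svg: int = 9
    dropout_rate: float = 0.0
    step_length: float = 2.0
    n_steps: int = 20
    domain_size: float | None = None  # xy extent; defaults per pattern kind
    z_scale: float = 1.0
    fix_z_direction: bool = False  # cross one slice per step (anisotropic z)
    pool_log_mean: float = 0.0
    pool_log_sd: float = DEFAULT_POOL_LOG_SD
    # winsorization quantile of the pool: empirical count pools have
    # bounded support, and an unbounded max makes the per-gene min-max
    # range (hence the gene weight) artificially noisy
    pool_cap_quantile: float = 0.995
    seed: int = 0

    def __post_init__(self):
        if self.sphere_radius <= 0:
            raise ValueError("sphere_radius must be positive")
        if not (0 < self.quantile < 1):
            raise ValueError("quantile must lie in (0, 1)")
        if self.noise_tau < 0:
            raise ValueError("noise_tau must be non-negative")
        if self.nulls_per_svg < 0:
            raise ValueError("nulls_per_svg must be non-negative")
        if not (0 <= self.dropout_rate < 1):
            raise ValueError("dropout_rate must lie in [0, 1)")

    @property
    def xy_extent(self) -> float:
        if self.domain_size is not None:
            return self.domain_size
        return 30.0 if self.pattern == "discrete_grid" else 15.0

    @property
    def n_spots(self) -> int:
        return self.n_per_slice * self.n_slices


@dataclass(frozen=True)
class PatternCenters:
    """Ordered sphere centers defining one spatial pattern."""

    points: np.ndarray
    kind: str

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=np.float64)
        if pts.ndim != 2 or pts.shape[1] != 3:
            raise ValueError("centers must be an (n, 3) array")
        object.__setattr__(self, "points", pts)


def generate_spots_3d(config: Sim3DConfig, seed: int | None = None) -> SpotCoordinates:
    """Stacked-slice spot layout: uniform x,y per slice, z = slice index * z_scale."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    ext = config.xy_extent
    xy = rng.uniform(0.0, ext, size=(config.n_spots, 2))
    z = np.repeat(np.arange(1, config.n_slices + 1, dtype=np.float64), config.n_per_slice)
    pos = np.column_stack([xy, z * config.z_scale])
    ids = np.array([f"spot_{i}" for i in range(config.n_spots)], dtype=object)
    return SpotCoordinates(spot_ids=ids, positions=pos)


def _planned_increments(rng, n: int, span: float) -> np.ndarray:
    """n strictly positive increments whose sum fits within span."""
    raw = rng.uniform(0.7, 1.3, size=n)
    return raw / raw.sum() * span * rng.uniform(0.75, 0.95)


def random_walk_centers(
    config: Sim3DConfig, rng: np.random.Generator | None = None
) -> PatternCenters:
    """Fixed-step random walk of sphere centers with per-kind monotonicity.

    Produces ``n_steps`` centers: a start point plus n_steps - 1 steps of
    exact length ``step_length``.  Monotone axes (z for curved_stick and
    thin_plate, plus one of x/y for curved_stick) take strictly positive
    increments planned upfront to fit inside the axis span; the remaining
    direction components are drawn at random, sized so every step has the
    fixed length, and rejected-and-resampled against the domain bounds.

    With ``fix_z_direction`` the z-increment per step is pinned to
    ``z_scale`` so the walk crosses one slice per step even when the
    inter-plane spacing dwarfs the step length; the fixed step length
    then applies to the xy-component and the walk is capped at one center
    per slice.
    """
    if config.pattern not in CONTINUOUS_PATTERNS:
        raise ValueError(f"pattern must be one of {CONTINUOUS_PATTERNS}")
    rng = np.random.default_rng(config.seed) if rng is None else rng
    ext = config.xy_extent
    z_lo, z_hi = config.z_scale, config.n_slices * config.z_scale
    kind = config.pattern
    L = config.step_length
    n_centers = config.n_steps
    if config.fix_z_direction:
        n_centers = min(n_centers, config.n_slices)
    n_inc = n_centers - 1
    if n_inc < 1:
        raise ValueError("need at least 2 centers (n_steps >= 2)")

    for _ in range(200):  # restart budget
        mono_axis = int(rng.integers(0, 2))  # x or y, for curved_stick
        # planned strictly-increasing coordinates for the monotone axes
        if config.fix_z_direction:
            z_inc = np.full(n_inc, config.z_scale)
            z_start = z_lo
        elif kind in ("curved_stick", "thin_plate"):
            z_inc = _planned_increments(rng, n_inc, z_hi - z_lo)
            z_start = z_lo + rng.uniform(0.0, (z_hi - z_lo) - z_inc.sum())
        else:
            z_inc = None
            z_start = rng.uniform(z_lo, z_hi)
        if kind == "curved_stick":
            # the in-plane monotone increment must leave room for the
            # step-length constraint next to the z increment
            budget = np.sqrt(max(L**2 - (0 if z_inc is None else z_inc.max()) ** 2, 0))
            a_inc = _planned_increments(rng, n_inc, min(ext, n_inc * 0.9 * budget))
            a_start = rng.uniform(0.0, ext - a_inc.sum())
        else:
            a_inc = None
            a_start = None

        start = np.array([rng.uniform(0.0, ext), rng.uniform(0.0, ext), z_start])
        if a_inc is not None:
            start[mono_axis] = a_start
        pts = [start]
        ok = True
        for s in range(n_inc):
            step = np.empty(3)
            if config.fix_z_direction:
                step[2] = z_inc[s]
                resid_axes = [0, 1] if a_inc is None else [1 - mono_axis]
                resid_len2 = L**2
                if a_inc is not None:
                    step[mono_axis] = a_inc[s]
                    resid_len2 = L**2 - a_inc[s] ** 2
            else:
                if z_inc is not None:
                    step[2] = z_inc[s]
                    resid_len2 = L**2 - z_inc[s] ** 2
                    resid_axes = [0, 1]
                    if a_inc is not None:
                        step[mono_axis] = a_inc[s]
                        resid_len2 -= a_inc[s] ** 2
                        resid_axes = [1 - mono_axis]
                else:
                    resid_len2 = L**2
                    resid_axes = [0, 1, 2]
            if resid_len2 < 0:
                ok = False
                break
            resid_len = np.sqrt(resid_len2)
            placed = False
            for _try in range(50):
                u = rng.standard_normal(len(resid_axes))
                nrm = np.linalg.norm(u)
                if nrm == 0:
                    continue
                step[resid_axes] = u / nrm * resid_len
                nxt = pts[-1] + step
                if 0 <= nxt[0] <= ext and 0 <= nxt[1] <= ext and z_lo <= nxt[2] <= z_hi:
                    pts.append(nxt)
                    placed = True
                    break
            if not placed:
                ok = False
                break
        if ok:
            return PatternCenters(points=np.array(pts), kind=kind)
    raise ValueError(
        "could not fit the random walk inside the domain; "
        "reduce n_steps or step_length, or enlarge the domain"
    )


def discrete_pattern_centers(
    config: Sim3DConfig,
    rng: np.random.Generator | None = None,
    jitter: float = 2.0,
) -> PatternCenters:
    """16 sphere centers on a jittered 4x4 grid at mid-depth.

    Grid coordinates run 3..27 with spacing 8 in a 0..30 domain; each
    center's x and y get independent U(-jitter, jitter) displacement
    (default 2); z is fixed at 5.5.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    axis = np.arange(3.0, 28.0, 8.0)
    gx, gy = np.meshgrid(axis, axis, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel(), np.full(16, 5.5)])
    pts[:, :2] += rng.uniform(-jitter, jitter, size=(16, 2))
    return PatternCenters(points=pts, kind="discrete_grid")


def mark_cells(coords: SpotCoordinates, centers: PatternCenters, r: float) -> np.ndarray:
    """Spots within distance r (closed ball) of any pattern center."""
    if r < 0:
        raise ValueError("radius must be non-negative")
    tree = cKDTree(centers.points)
    dist, _ = tree.query(coords.positions, k=1)
    mask = dist <= r
    if not mask.any():
        import warnings

        warnings.warn("pattern missed all spots: the mask is empty", stacklevel=2)
    return mask


def sample_expression_3d(
    coords: SpotCoordinates,
    mask: np.ndarray,
    config: Sim3DConfig,
    rng: np.random.Generator | None = None,
) -> SimulatedDataset:
    """Quantile-based expression: marked spots draw from the pool's upper tail.

    The base pool is lognormal(pool_log_mean, pool_log_sd) — a stand-in
    for an empirical FISH expression distribution.  Marked spots draw
    values above the q-quantile (inverse-CDF sampling of U(q, 1));
    unmarked spots draw from the whole pool.  Each pattern gene spawns
    ``nulls_per_svg`` spatial permutations as null genes.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.size != coords.n_spots:
        raise ValueError("mask length does not match spot count")
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    m = coords.n_spots
    n_svg, q = config.n_svg, config.quantile
    scale = np.exp(config.pool_log_mean)

    u = rng.uniform(0.0, 1.0, size=(n_svg, m))
    u[:, mask] = q + (1.0 - q) * u[:, mask]  # upper-tail quantiles for marked spots
    svg = st.lognorm.ppf(u, s=config.pool_log_sd, scale=scale)
    if config.pool_cap_quantile < 1.0:
        cap = st.lognorm.ppf(config.pool_cap_quantile, s=config.pool_log_sd, scale=scale)
        np.minimum(svg, cap, out=svg)

    n_null = n_svg * config.nulls_per_svg
    null = np.empty((n_null, m))
    for k in range(n_null):
        null[k] = svg[k % n_svg][rng.permutation(m)]
    values = np.vstack([svg, null]) if n_null else svg
    gene_ids = np.array(
        [f"svg_{k}" for k in range(n_svg)] + [f"null_{k}" for k in range(n_null)],
        dtype=object,
    )
    labels = np.array(["svg"] * n_svg + ["null"] * n_null, dtype=object)
    expr = ExpressionMatrix(gene_ids=gene_ids, spot_ids=coords.spot_ids, values=values)
    return SimulatedDataset(
        dataset=Dataset(expression=expr, coordinates=coords),
        labels=labels,
        mask=mask,
        config=asdict(config),
    )


def add_noise(values: np.ndarray, tau: float, rng: np.random.Generator) -> np.ndarray:
    """Add N(0, (tau * s_bar)^2) noise, s_bar = mean per-gene SD of the clean matrix.

    Values may go negative and are left unclipped; downstream min-max
    normalization absorbs location and scale.
    """
    if tau < 0:
        raise ValueError("tau must be non-negative")
    values = np.asarray(values, dtype=np.float64)
    if tau == 0:
        return values.copy()
    s_bar = np.std(values, axis=1).mean()
    return values + rng.normal(0.0, tau * s_bar, size=values.shape)


def apply_dropout(values: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Zero out exactly floor(rate * M) spots per gene, chosen independently."""
    if not (0 <= rate < 1):
        raise ValueError("rate must lie in [0, 1)")
    values = np.asarray(values, dtype=np.float64).copy()
    if rate == 0:
        return values
    n, m = values.shape
    k = int(np.floor(rate * m))
    for j in range(n):
        idx = rng.choice(m, size=k, replace=False)
        values[j, idx] = 0.0
    return values


def simulate_dataset_3d(config: Sim3DConfig) -> SimulatedDataset:
    """Full seeded 3D simulation: spots, pattern, expression, noise, dropout.

    All randomness flows from ``config.seed``.  Noise may push values
    negative; they are left unclipped (the per-gene min-max normalization
    downstream absorbs location and scale).  Dropout zeros are applied to
    the clean expression, before measurement noise.
    """
    rng = np.random.default_rng(config.seed)
    coords = generate_spots_3d(config, seed=int(rng.integers(2**31)))
    if config.pattern == "discrete_grid":
        centers = discrete_pattern_centers(config, rng)
    else:
        centers = random_walk_centers(config, rng)
    mask = mark_cells(coords, centers, config.sphere_radius)
    sim = sample_expression_3d(coords, mask, config, rng)
    values = sim.dataset.expression.values
    if config.dropout_rate > 0:
        values = apply_dropout(values, config.dropout_rate, rng)
    if config.noise_tau > 0:
        values = add_noise(values, config.noise_tau, rng)
    expr = ExpressionMatrix(
        gene_ids=sim.dataset.expression.gene_ids,
        spot_ids=coords.spot_ids,
        values=values,
    )
    return SimulatedDataset(
        dataset=Dataset(expression=expr, coordinates=coords),
        labels=sim.labels,
        mask=mask,
        config=asdict(config),
    )
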