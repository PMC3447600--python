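"""Synthetic landscape generator with known ground truth.

Emulates the statistical structure the CA calibration assumes — spatially
clustered land-use maps at two epochs, driver covariates (distance
transforms, terrain, IDW-interpolated socio-economic surfaces), protection
masks, and a true logistic transition process with known coefficient vectors
— so the whole pipeline is testable without any external raster data.

Per-cell transition truth: a convertible cell of class c converts to target
class m (m ≠ c) with probability σ(β*₀ₘ + β*ₘ·x), competing target classes
drawn on disjoint uniform intervals so each marginal is exactly logistic;
the per-class base rate ("transition intensity") lives in the intercept.
Constraint-masked cells never convert.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .grid import ClassScheme, DEFAULT_SCHEME, DRIVER_NAMES, DriverStack, LandUseGrid, normalize_driver

__all__ = [
    "SyntheticSpec",
    "SyntheticBundle",
    "gen_drivers",
    "gen_initial_map",
    "evolve_true_model",
    "gen_masks",
    "generate_bundle",
]

MASK_NAMES = (
    "basic_farmland",
    "water",
    "core_area",
    "steep_slope",
    "key_ecoland_low_security",
    "key_ecoland_high_security",
)


def _default_beta():
    # Intercept first, then one slope per driver in DRIVER_NAMES order.
    # Slope magnitudes kept >= 1.2 so the generating signal is clearly
    # identifiable; intercepts set the per-class transition intensity so the
    # realized epoch-to-epoch trend matches the study system (construction
    # expanding strongly, ecological and cultivated land losing on net).
    return {
        "cultivated": np.array([-1.1, 1.5, -1.2, -2.0, -1.5, -1.8, 1.2, -1.4]),
        "ecological": np.array([-2.3, 1.8, 1.3, -1.5, 2.0, 1.4, -1.6, -1.9]),
        "construction": np.array([-1.5, -2.5, -1.8, 1.2, -1.6, -2.0, 1.5, 1.8]),
    }


@dataclass
class SyntheticSpec:
    """Generating parameters for one synthetic bundle.

    Class shares default to a Beijing-like 2005 composition (cultivated 25%,
    ecological 56%, construction 18%, other 1%). Mask fractions are of their
    respective carrier sets (see :func:`gen_masks`).
    """

    shape: tuple = (600, 600)
    cell_size: float = 100.0
    seed: int = 0
    n_towns: int = 100
    n_highways: int = 20
    n_rivers: int = 14
    n_dem_bumps: int = 14
    dem_smooth: int = 7
    n_idw_points: int = 35
    class_shares: dict = field(
        default_factory=lambda: {
            "cultivated": 0.25,
            "ecological": 0.56,
            "construction": 0.18,
            "other": 0.01,
        }
    )
    beta_true: dict = field(default_factory=_default_beta)
    basic_farmland_frac: float = 0.10  # of cultivated cells
    water_frac: float = 0.05  # of ecological+other cells
    core_area_frac: float = 0.08  # of ecological cells
    steep_slope_frac: float = 0.05  # of all cells
    key_low_frac: float = 0.15  # of ecological cells
    key_high_frac: float = 0.35  # of ecological cells
    scheme: ClassScheme = field(default_factory=lambda: DEFAULT_SCHEME)

    def __post_init__(self):
        for f in (
            self.basic_farmland_frac,
            self.water_frac,
            self.core_area_frac,
            self.steep_slope_frac,
            self.key_low_frac,
            self.key_high_frac,
        ):
            if not 0.0 <= f <= 1.0:
                raise ValueError("mask fractions must be in [0, 1]")
        if self.key_low_frac + self.key_high_frac > 1.0:
            raise ValueError("security-level fractions jointly infeasible")
        if abs(sum(self.class_shares.values()) - 1.0) > 1e-9:
            raise ValueError("class shares must sum to 1")
        for m, b in self.beta_true.items():
            if len(b) != len(DRIVER_NAMES) + 1:
                raise ValueError(f"beta_true[{m!r}] needs intercept + {len(DRIVER_NAMES)} slopes")


@dataclass
class SyntheticBundle:
    """Everything one simulation run needs, plus the generating truth."""

    map_t0: LandUseGrid
    map_t1: LandUseGrid
    drivers: DriverStack
    masks: dict  # name -> bool lattice
    truth: dict  # beta, transition_counts, seed
    spec: SyntheticSpec

    def constrained_union(self) -> np.ndarray:
        """Cells the generating process held fixed (union of hard masks)."""
        m = np.zeros(self.map_t0.shape, dtype=bool)
        for name in ("basic_farmland", "water", "core_area", "steep_slope"):
            m |= self.masks[name]
        return m


# ---------------------------------------------------------------------------
# Drivers


def _random_walk_line(rng, shape, n_steps=None):
    """Rasterized random-walk polyline crossing the lattice (rough river/road)."""
    nr, nc = shape
    n_steps = n_steps or (nr + nc)
    mask = np.zeros(shape, dtype=bool)
    # start on a random edge, walk with momentum
    edge = rng.integers(4)
    if edge == 0:
        r, c = 0, rng.integers(nc)
        dr, dc = 1.0, 0.0
    elif edge == 1:
        r, c = nr - 1, rng.integers(nc)
        dr, dc = -1.0, 0.0
    elif edge == 2:
        r, c = rng.integers(nr), 0
        dr, dc = 0.0, 1.0
    else:
        r, c = rng.integers(nr), nc - 1
        dr, dc = 0.0, -1.0
    fr, fc = float(r), float(c)
    for _ in range(n_steps):
        ir, ic = int(round(fr)), int(round(fc))
        if not (0 <= ir < nr and 0 <= ic < nc):
            break
        mask[ir, ic] = True
        dr += rng.normal(0, 0.4)
        dc += rng.normal(0, 0.4)
        norm = np.hypot(dr, dc)
        if norm < 1e-9:
            dr, dc = 1.0, 0.0
            norm = 1.0
        fr += dr / norm
        fc += dc / norm
    return mask


def _bumpy_dem(rng, shape, n_bumps, smooth):
    """Terrain as a sum of Gaussian hills plus mean-filtered noise.

    Hills give the elevation marginal a realistic hypsometric spread (flat
    plains, broad mid-elevations, a few peaks); the smoothed noise term adds
    local roughness. ``n_bumps == 0`` yields a flat DEM.
    """
    nr, nc = shape
    rr, cc = np.meshgrid(np.arange(nr), np.arange(nc), indexing="ij")
    dem = np.zeros(shape)
    for _ in range(n_bumps):
        r0, c0 = rng.uniform(0, nr), rng.uniform(0, nc)
        sigma = rng.uniform(0.08, 0.25) * max(nr, nc)
        height = rng.uniform(0.3, 1.0)
        dem += height * np.exp(-((rr - r0) ** 2 + (cc - c0) ** 2) / (2 * sigma**2))
    if smooth > 1:
        dem += 0.15 * ndimage.uniform_filter(rng.uniform(0, 1, shape), size=smooth, mode="nearest")
    return dem


def _distance_layer(feature_mask, cell_size):
    if not feature_mask.any():
        raise ValueError("degenerate spec: feature set is empty")
    d = ndimage.distance_transform_edt(~feature_mask, sampling=cell_size)
    return normalize_driver(d) if d.max() > 0 else np.zeros_like(d)


def _idw_layer(rng, shape, n_points, cell_size):
    """Inverse-distance-weighted (power 2) surface from random sample points.

    All points contribute (no search radius); a cell coinciding with a sample
    point takes that point's value exactly.
    """
    if n_points < 1:
        raise ValueError("degenerate spec: need at least one IDW point")
    nr, nc = shape
    pr = rng.integers(0, nr, size=n_points)
    pc = rng.integers(0, nc, size=n_points)
    # U-shaped point values: county-level socio-economic indicators are
    # strongly polarized (rich urban vs. poor rural districts), which keeps
    # the interpolated surface from collapsing onto its mean
    vals = rng.beta(0.4, 0.4, size=n_points)
    rr, cc = np.meshgrid(np.arange(nr), np.arange(nc), indexing="ij")
    num = np.zeros(shape)
    den = np.zeros(shape)
    for r0, c0, v in zip(pr, pc, vals):
        d2 = ((rr - r0) ** 2 + (cc - c0) ** 2).astype(float) * cell_size**2
        d2[d2 == 0] = np.inf  # zero weight here; exact value assigned below
        w = 1.0 / d2
        num += w * v
        den += w
    with np.errstate(invalid="ignore"):
        surf = num / den
    for r0, c0, v in zip(pr, pc, vals):
        surf[r0, c0] = v
    return surf


def gen_drivers(spec: SyntheticSpec, rng=None) -> DriverStack:
    """Generate the seven-driver stack, each layer min–max scaled to [0, 1]."""
    rng = rng or np.random.default_rng(spec.seed)
    nr, nc = spec.shape
    if spec.n_towns < 1:
        raise ValueError("degenerate spec: need at least one town")

    towns = np.zeros(spec.shape, dtype=bool)
    towns[rng.integers(0, nr, spec.n_towns), rng.integers(0, nc, spec.n_towns)] = True

    highways = np.zeros(spec.shape, dtype=bool)
    for _ in range(max(1, spec.n_highways)):
        highways |= _random_walk_line(rng, spec.shape)
    rivers = np.zeros(spec.shape, dtype=bool)
    for _ in range(max(1, spec.n_rivers)):
        rivers |= _random_walk_line(rng, spec.shape)

    dem_raw = _bumpy_dem(rng, spec.shape, spec.n_dem_bumps, spec.dem_smooth)
    dem = normalize_driver(dem_raw)
    gy, gx = np.gradient(dem_raw, spec.cell_size)
    slope_raw = np.hypot(gy, gx)
    slope = normalize_driver(slope_raw) if slope_raw.max() > 0 else slope_raw

    layers = {
        "dist_town": _distance_layer(towns, spec.cell_size),
        "dist_highway": _distance_layer(highways, spec.cell_size),
        "dist_river": _distance_layer(rivers, spec.cell_size),
        "dem": dem,
        "slope": slope,
        "gdp_pc": normalize_driver(_idw_layer(rng, spec.shape, spec.n_idw_points, spec.cell_size)),
        "pop_density": normalize_driver(_idw_layer(rng, spec.shape, spec.n_idw_points, spec.cell_size)),
    }
    return DriverStack(layers, cell_size=spec.cell_size)


# ---------------------------------------------------------------------------
# Initial map


def gen_initial_map(spec: SyntheticSpec, drivers: DriverStack, rng=None) -> LandUseGrid:
    """Spatially clustered 4-class map honoring the requested class shares.

    Class affinity scores combine drivers (construction near towns, ecological
    on high/rough terrain, cultivated on flat land away from towns) with a
    smoothed noise field; cells are allocated greedily by affinity so the
    realized shares match the requested shares exactly up to rounding.
    """
    rng = rng or np.random.default_rng(spec.seed + 1)
    noise = {
        name: ndimage.uniform_filter(rng.uniform(0, 1, spec.shape), size=9, mode="nearest")
        for name in spec.scheme.names
    }
    d = drivers
    score = {
        "construction": -2.0 * d["dist_town"] - 0.8 * d["slope"] + 0.8 * d["pop_density"] + noise["construction"],
        "ecological": 1.5 * d["dem"] + 1.0 * d["slope"] + 0.5 * d["dist_town"] + noise["ecological"],
        "cultivated": -1.0 * d["slope"] - 0.5 * d["dem"] + 0.5 * d["dist_town"] + noise["cultivated"],
        "other": 1.0 * d["dist_river"] - 0.5 * d["pop_density"] + noise["other"],
    }
    n_cells = spec.shape[0] * spec.shape[1]
    quota = {k: int(round(v * n_cells)) for k, v in spec.class_shares.items()}
    # fix rounding drift on the largest class
    drift = n_cells - sum(quota.values())
    quota[max(quota, key=quota.get)] += drift
    out = np.zeros(n_cells, dtype=np.int64)
    taken = np.zeros(n_cells, dtype=bool)
    # allocate rarest classes first so their quotas are attainable
    for name in sorted(quota, key=quota.get):
        q = quota[name]
        if q == 0:
            continue
        s = score[name].ravel().copy()
        s[taken] = -np.inf
        idx = np.argpartition(-s, q - 1)[:q]
        out[idx] = spec.scheme.code(name)
        taken[idx] = True
    values = out.reshape(spec.shape)
    return LandUseGrid(values, cell_size=spec.cell_size, epoch="t0", nodata=spec.scheme.nodata)


# ---------------------------------------------------------------------------
# Masks


def _clustered_subset(rng, carrier: np.ndarray, fraction: float, field=None) -> np.ndarray:
    """Top-``fraction`` of carrier cells by a smoothed random (or given) field."""
    n = int(round(fraction * np.count_nonzero(carrier)))
    out = np.zeros_like(carrier, dtype=bool)
    if n == 0:
        return out
    if field is None:
        field = ndimage.uniform_filter(rng.uniform(0, 1, carrier.shape), size=7, mode="nearest")
    vals = np.where(carrier, field, -np.inf).ravel()
    idx = np.argpartition(-vals, n - 1)[:n]
    flat = out.ravel()
    flat[idx] = True
    return flat.reshape(carrier.shape)


def gen_masks(spec: SyntheticSpec, map_t0: LandUseGrid, drivers: DriverStack, rng=None) -> dict:
    """Protection and security masks consistent with the t0 map.

    basic_farmland ⊂ cultivated; water ⊂ ecological∪other; core_area ⊂
    ecological; steep_slope = top slope quantile; the key-ecological-land
    security levels partition a subset of ecological cells (disjoint
    low/high).
    """
    rng = rng or np.random.default_rng(spec.seed + 2)
    sch = spec.scheme
    v = map_t0.values
    cultivated = v == sch.code("cultivated")
    ecological = v == sch.code("ecological")
    eco_or_other = ecological | (v == sch.code("other"))

    n_steep = int(round(spec.steep_slope_frac * v.size))
    steep = np.zeros(v.shape, dtype=bool)
    if n_steep:
        order = np.argsort(-drivers["slope"].ravel(), kind="stable")[:n_steep]
        steep.ravel()[order] = True

    n_eco = np.count_nonzero(ecological)
    sec_field = drivers["dem"] + ndimage.uniform_filter(
        rng.uniform(0, 1, v.shape), size=7, mode="nearest"
    )
    n_high = int(round(spec.key_high_frac * n_eco))
    n_low = int(round(spec.key_low_frac * n_eco))
    ranked = np.where(ecological, sec_field, -np.inf).ravel().argsort()[::-1]
    high = np.zeros(v.size, dtype=bool)
    low = np.zeros(v.size, dtype=bool)
    high[ranked[:n_high]] = True
    low[ranked[n_high : n_high + n_low]] = True

    return {
        "basic_farmland": _clustered_subset(rng, cultivated, spec.basic_farmland_frac),
        "water": _clustered_subset(rng, eco_or_other, spec.water_frac, field=-drivers["dist_river"]),
        "core_area": _clustered_subset(rng, ecological, spec.core_area_frac),
        "steep_slope": steep,
        "key_ecoland_low_security": low.reshape(v.shape),
        "key_ecoland_high_security": high.reshape(v.shape),
    }


# ---------------------------------------------------------------------------
# True transition process


def true_probabilities(spec: SyntheticSpec, drivers: DriverStack) -> dict:
    """Per-class true conversion probability surfaces σ(β*₀ + β*·x)."""
    x = drivers.design_matrix(DRIVER_NAMES)
    out = {}
    for name, beta in spec.beta_true.items():
        eta = beta[0] + x @ beta[1:]
        out[name] = (1.0 / (1.0 + np.exp(-eta))).reshape(spec.shape)
    return out


def evolve_true_model(
    map_t0: LandUseGrid,
    drivers: DriverStack,
    spec: SyntheticSpec,
    masks: dict | None = None,
    rng=None,
) -> tuple:
    """Advance the map one epoch under the true logistic transition process.

    Returns ``(map_t1, transition_counts)`` where the counts are the exact
    4×4 realized cell transition tally. Cells under any hard mask (basic
    farmland, water, core area, steep slope) never convert.
    """
    rng = rng or np.random.default_rng(spec.seed + 3)
    sch = spec.scheme
    probs = true_probabilities(spec, drivers)
    target_names = list(spec.beta_true.keys())
    p = np.stack([probs[m].ravel() for m in target_names])  # (k, n)
    v0 = map_t0.values.ravel()
    for j, m in enumerate(target_names):
        p[j, v0 == sch.code(m)] = 0.0  # a cell cannot convert to its own class
    if masks:
        hard = np.zeros(v0.size, dtype=bool)
        for name in ("basic_farmland", "water", "core_area", "steep_slope"):
            if name in masks:
                hard |= masks[name].ravel()
        p[:, hard] = 0.0
    total = p.sum(axis=0)
    over = total > 0.95
    if over.any():  # guard: competing probabilities must fit in the unit interval
        p[:, over] *= 0.95 / total[over]
    cum = np.cumsum(p, axis=0)
    u = rng.uniform(0, 1, size=v0.size)
    v1 = v0.copy()
    chosen = np.full(v0.size, -1)
    for j in range(len(target_names) - 1, -1, -1):
        chosen = np.where(u < cum[j], j, chosen)
    conv = chosen >= 0
    codes = np.array([sch.code(m) for m in target_names])
    v1[conv] = codes[chosen[conv]]

    k = len(sch.codes)
    idx = {c: i for i, c in enumerate(sch.codes)}
    ai = np.vectorize(idx.get)(v0)
    bi = np.vectorize(idx.get)(v1)
    counts = np.bincount(ai * k + bi, minlength=k * k).reshape(k, k)
    map_t1 = LandUseGrid(
        v1.reshape(spec.shape), cell_size=spec.cell_size, epoch="t1", nodata=sch.nodata
    )
    return map_t1, counts


def generate_bundle(spec: SyntheticSpec) -> SyntheticBundle:
    """Deterministically generate the full bundle from one spec + seed."""
    ss = np.random.SeedSequence(spec.seed)
    r_drv, r_map, r_msk, r_evo = [np.random.default_rng(s) for s in ss.spawn(4)]
    drivers = gen_drivers(spec, r_drv)
    map_t0 = gen_initial_map(spec, drivers, r_map)
    masks = gen_masks(spec, map_t0, drivers, r_msk)
    map_t1, counts = evolve_true_model(map_t0, drivers, spec, masks, r_evo)
    truth = {
        "beta": {k: np.asarray(v, dtype=float) for k, v in spec.beta_true.items()},
        "transition_counts": counts,
        "seed": spec.seed,
    }
    return SyntheticBundle(map_t0, map_t1, drivers, masks, truth, spec)
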