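"""Constrained CA micro-evolution engine.

Each iteration composes, per candidate cell, the synthesis conversion
probability

    P_T = P_global × Ω × con × R

from the Theil-normalized logistic suitability P_global, the Moore-
neighborhood share Ω of the candidate class, the scenario constraint con
(0 prohibits conversion), and the stochastic disturbance R = 1 + (−ln γ)^α
with one fresh γ ~ U(0, 1) per cell per iteration. The deterministic
product P_global × Ω × con is min–max normalized over the iteration's
candidate cells; the boost R ≥ 1 then perturbs the normalized score, which
is compared with the conversion threshold. (Normalizing after multiplying
by the heavy-tailed R would make passing the threshold an extreme-value
event — a vanishing handful of cells per iteration, so macro demands could
never be met; see the methods note.) Conversions are allocated highest
score first, capped by the macro demand of each class. Iteration stops once
every class count sits inside its closed stopping band [target−N, target+N].

Two-phase step: construction development first (construction is absorbing —
no conversions out of it), then reallocation among cultivated / ecological;
"other" land has no suitability model and only loses cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .grid import ClassScheme, DEFAULT_SCHEME, LandUseGrid
from .markov import MacroTargets, default_band_width, stop_band_check
from .suitability import SuitabilitySurfaces

__all__ = [
    "ConstraintMask",
    "ScenarioConfig",
    "SimulationResult",
    "SCENARIOS",
    "neighborhood_share",
    "neighborhood_share_map",
    "stochastic_factor",
    "build_constraints",
    "synthesis_probability",
    "iterate_step",
    "run_scenario",
]

SCENARIOS = ("natural_development", "object_orientation", "ecosystem_priority")


@dataclass
class ConstraintMask:
    """Per-cell conversion constraint con(i) ∈ [0, 1]; 0 prohibits conversion.

    ``base`` applies to every conversion out of a cell; ``to_construction``
    multiplies in only when the candidate target class is construction (the
    steep-slope rule binds construction alone).
    """

    base: np.ndarray
    to_construction: np.ndarray | None = None

    def __post_init__(self):
        self.base = np.asarray(self.base, dtype=float)
        if self.base.min() < 0 or self.base.max() > 1:
            raise ValueError("constraint values must be in [0, 1]")
        if self.to_construction is not None:
            self.to_construction = np.asarray(self.to_construction, dtype=float)

    def for_target(self, target_class: str) -> np.ndarray:
        if target_class == "construction" and self.to_construction is not None:
            return self.base * self.to_construction
        return self.base

    def hard_zero(self) -> np.ndarray:
        """Cells prohibited from any conversion."""
        return self.base == 0


@dataclass
class ScenarioConfig:
    """One policy scenario: constraints, macro-target source, CA tuning.

    ``p_threshold`` is compared with the min–max normalized synthesis
    probability; ``threshold_direction`` 'ge' converts cells at or above the
    threshold (default), 'lt' reproduces the literal below-threshold rule.
    ``alpha`` ∈ {1..10} shapes the stochastic disturbance; ``stop_fraction``
    sets the band half-width N as a fraction of each class target.
    """

    name: str
    targets_source: str = "markov"  # "markov" | "planning"
    p_threshold: float = 0.8
    alpha: int = 1
    stop_fraction: float = 0.01
    max_iterations: int = 200
    seed: int = 0
    threshold_direction: str = "ge"
    construction_increment_cap: float | None = None  # km², planning scenarios
    cultivated_decline_cap_pct: float | None = None

    def __post_init__(self):
        if self.name not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.name!r}")
        if not (0 < self.p_threshold < 1):
            raise ValueError("p_threshold must be in (0, 1)")
        if not (1 <= self.alpha <= 10 and int(self.alpha) == self.alpha):
            raise ValueError("alpha must be an integer in [1, 10]")
        if self.threshold_direction not in ("ge", "lt"):
            raise ValueError("threshold_direction must be 'ge' or 'lt'")
        if self.targets_source not in ("markov", "planning"):
            raise ValueError("targets_source must be 'markov' or 'planning'")


@dataclass
class SimulationResult:
    """Outcome of one scenario run: final map, trajectory, convergence."""

    final_grid: LandUseGrid
    trajectory: pd.DataFrame  # per-iteration per-class cell counts
    iterations: int
    converged: dict  # class -> bool
    gaps: dict  # class -> final count − target
    config: ScenarioConfig
    targets_cells: dict

    @property
    def all_converged(self) -> bool:
        return all(self.converged.values())

    def summary(self) -> pd.DataFrame:
        last = self.trajectory.iloc[-1]
        return pd.DataFrame(
            {
                "final_cells": last,
                "target_cells": pd.Series(self.targets_cells),
                "gap": pd.Series(self.gaps),
                "converged": pd.Series(self.converged),
            }
        )


# ---------------------------------------------------------------------------
# Factors


def neighborhood_share_map(values: np.ndarray, code: int, window: int = 3) -> np.ndarray:
    """Ω lattice: share of in-bounds Moore neighbors (center excluded) in
    ``code``, for every cell at once."""
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be odd and >= 3")
    ind = (values == code).astype(float)
    k = np.ones((window, window))
    like = ndimage.convolve(ind, k, mode="constant", cval=0.0) - ind
    nnb = ndimage.convolve(np.ones_like(ind), k, mode="constant", cval=0.0) - 1.0
    return like / nnb


def neighborhood_share(grid: LandUseGrid, cell: tuple, code: int, window: int = 3) -> float:
    """Ω for a single cell (edge cells use only their in-bounds neighbors)."""
    r, c = cell
    h = window // 2
    r0, r1 = max(0, r - h), min(grid.shape[0], r + h + 1)
    c0, c1 = max(0, c - h), min(grid.shape[1], c + h + 1)
    block = grid.values[r0:r1, c0:c1]
    n = block.size - 1
    like = int(np.count_nonzero(block == code)) - int(grid.values[r, c] == code)
    return like / n


def stochastic_factor(gamma, alpha: int):
    """Stochastic disturbance R = 1 + (−ln γ)^α, γ ∈ (0, 1), α ∈ {1..10}."""
    g = np.asarray(gamma, dtype=float)
    if np.any(g <= 0) or np.any(g >= 1):
        raise ValueError("gamma must lie strictly in (0, 1)")
    if not (1 <= alpha <= 10 and int(alpha) == alpha):
        raise ValueError("alpha must be an integer in [1, 10]")
    r = 1.0 + (-np.log(g)) ** alpha
    return float(r) if np.isscalar(gamma) else r


def build_constraints(
    scenario: str | ScenarioConfig,
    masks: dict,
    map_t0: LandUseGrid | None = None,
    scheme: ClassScheme = DEFAULT_SCHEME,
) -> ConstraintMask:
    """Scenario constraint recipe.

    natural_development: basic farmland may not evolve. object_orientation:
    water and basic farmland may not evolve. ecosystem_priority: the core
    protection set (basic farmland, water, first-level water sources / nature
    reserves / scenic and geological parks, here the ``core_area`` mask) may
    not evolve, steep (>25°) cells may not convert to construction, and no
    ecological cell may convert out at all.
    """
    name = scenario.name if isinstance(scenario, ScenarioConfig) else scenario
    if name not in SCENARIOS:
        raise ValueError(f"unknown scenario {name!r}")

    def need(key):
        if key not in masks:
            raise KeyError(f"scenario {name!r} requires mask {key!r}")
        return np.asarray(masks[key], dtype=bool)

    if name == "natural_development":
        zero = need("basic_farmland")
        base = np.where(zero, 0.0, 1.0)
        return ConstraintMask(base)
    if name == "object_orientation":
        zero = need("basic_farmland") | need("water")
        base = np.where(zero, 0.0, 1.0)
        return ConstraintMask(base)
    # ecosystem_priority
    zero = need("basic_farmland") | need("water") | need("core_area")
    if map_t0 is None:
        raise ValueError("ecosystem_priority needs the t0 map (ecological cells are protected)")
    zero = zero | (map_t0.values == scheme.code("ecological"))
    base = np.where(zero, 0.0, 1.0)
    to_constr = np.where(need("steep_slope"), 0.0, 1.0)
    return ConstraintMask(base, to_construction=to_constr)


def synthesis_probability(p_global, omega, con, r):
    """Raw synthesis probability P_T = P_global × Ω × con × R.

    In the iteration loop the deterministic part of this product is min–max
    normalized over the candidate cells before R perturbs it; this helper
    exposes the raw composition itself.
    """
    return np.asarray(p_global) * np.asarray(omega) * np.asarray(con) * np.asarray(r)


def _minmax_candidates(p: np.ndarray) -> np.ndarray:
    """Min–max normalize candidate probabilities onto [0, 1].

    All-zero candidates stay zero (nothing converts); a degenerate positive
    constant maps to 1.
    """
    if p.size == 0:
        return p
    lo, hi = p.min(), p.max()
    if hi <= 0:
        return np.zeros_like(p)
    if hi == lo:
        return np.ones_like(p)
    return (p - lo) / (hi - lo)


# ---------------------------------------------------------------------------
# Iteration


def _passes(p_norm: np.ndarray, cfg: ScenarioConfig) -> np.ndarray:
    if cfg.threshold_direction == "ge":
        return p_norm >= cfg.p_threshold
    return p_norm < cfg.p_threshold


def _allocate(order, sources, targets_of, in_cap, out_cap, values, codes_by_name):
    """Greedy allocation respecting per-class demand and supply caps.

    ``order`` indexes candidate cells by descending priority; conversions
    mutate ``values`` (flat view) and the cap dicts in place. Returns the
    number of conversions made.
    """
    made = 0
    for j in order:
        tgt = targets_of[j]
        src = sources[j]
        if in_cap.get(tgt, 0) <= 0:
            continue
        if out_cap.get(src, 0) <= 0:
            continue
        values[j] = codes_by_name[tgt]
        in_cap[tgt] -= 1
        out_cap[src] += -1
        made += 1
    return made


def iterate_step(
    state: np.ndarray,
    surfaces: SuitabilitySurfaces,
    constraints: ConstraintMask,
    targets_cells: dict,
    band: dict,
    cfg: ScenarioConfig,
    rng,
    scheme: ClassScheme = DEFAULT_SCHEME,
    window: int = 3,
    nodata: int | None = None,
) -> int:
    """Advance the lattice by one CA iteration in place; returns conversions made.

    Phase A develops construction on the highest-probability unconstrained
    cells up to remaining demand; phase B reallocates remaining convertible
    cells to the maximal of {cultivated, ecological} when it passes the
    threshold and that class is still below its band. A class inside its band
    is frozen (no net in-conversions); cells may leave a class only while its
    count exceeds its target.
    """
    names = list(scheme.names)
    codes = {n: scheme.code(n) for n in names}
    counts = {n: int(np.count_nonzero(state == codes[n])) for n in names}
    # a class accepts cells only up to its exact target (a met class may
    # still top up to the target so surplus classes can always shed), and
    # sheds cells only while above it — every conversion strictly reduces
    # the total absolute gap, so the band is reached monotonically
    in_cap = {n: max(0, targets_cells[n] - counts[n]) for n in names}
    out_cap = {n: max(0, counts[n] - targets_cells[n]) for n in names}

    flat = state.ravel()
    n_cells = flat.size
    gamma = rng.uniform(np.nextafter(0, 1), 1.0, size=n_cells)
    r_factor = 1.0 + (-np.log(gamma)) ** cfg.alpha

    name_of_code = {v: k for k, v in codes.items()}
    converted_total = 0

    # ---- Phase A: construction development (absorbing target)
    if in_cap["construction"] > 0:
        con_c = constraints.for_target("construction").ravel()
        omega_c = neighborhood_share_map(state, codes["construction"], window).ravel()
        pg_c = np.asarray(surfaces["construction"]).ravel()
        cand = (flat != codes["construction"]) & (con_c > 0)
        # only classes that can shed cells supply candidates
        src_ok = np.isin(flat, [codes[n] for n in names if out_cap[n] > 0])
        cand &= src_ok
        idx = np.flatnonzero(cand)
        if idx.size:
            det = pg_c[idx] * omega_c[idx] * con_c[idx]
            p_eff = _minmax_candidates(det) * r_factor[idx]
            keep = _passes(p_eff, cfg) & (det > 0)
            idx, p_eff = idx[keep], p_eff[keep]
            order = idx[np.lexsort((idx, -p_eff))]
            srcs = {j: name_of_code[int(flat[j])] for j in order}
            converted_total += _allocate(
                order,
                srcs,
                {j: "construction" for j in order},
                in_cap,
                out_cap,
                flat,
                codes,
            )

    # ---- Phase B: reallocation among cultivated / ecological
    realloc_targets = [m for m in ("cultivated", "ecological") if in_cap[m] > 0]
    if realloc_targets:
        con_b = constraints.base.ravel()
        cand = (flat != codes["construction"]) & (con_b > 0)
        src_ok = np.isin(flat, [codes[n] for n in names if out_cap[n] > 0])
        cand &= src_ok
        idx = np.flatnonzero(cand)
        if idx.size:
            best_p = np.full(idx.size, -1.0)
            best_m = np.full(idx.size, -1)
            for k, m in enumerate(realloc_targets):
                omega = neighborhood_share_map(state, codes[m], window).ravel()
                pg = np.asarray(surfaces[m]).ravel()
                det = pg[idx] * omega[idx] * con_b[idx]
                det[flat[idx] == codes[m]] = -1.0  # cannot convert to own class
                better = det > best_p
                best_p[better] = det[better]
                best_m[better] = k
            ok = best_p > 0
            idx, best_p, best_m = idx[ok], best_p[ok], best_m[ok]
            if idx.size:
                p_eff = _minmax_candidates(best_p) * r_factor[idx]
                keep = _passes(p_eff, cfg)
                idx, p_eff, best_m = idx[keep], p_eff[keep], best_m[keep]
                order_pos = np.lexsort((idx, -p_eff))
                order = idx[order_pos]
                tgt_of = {
                    j: realloc_targets[best_m[pos]] for pos, j in zip(order_pos, order)
                }
                srcs = {j: name_of_code[int(flat[j])] for j in order}
                converted_total += _allocate(
                    order, srcs, tgt_of, in_cap, out_cap, flat, codes
                )

    return converted_total


def run_scenario(
    map_t0: LandUseGrid,
    surfaces: SuitabilitySurfaces,
    constraints: ConstraintMask,
    targets: MacroTargets,
    cfg: ScenarioConfig,
    scheme: ClassScheme = DEFAULT_SCHEME,
    window: int = 3,
) -> SimulationResult:
    """Iterate the CA until every class is inside its stopping band.

    Non-convergence within ``max_iterations`` is reported through the
    per-class flags and gaps, not raised. Fully reproducible under the
    config seed.
    """
    if not surfaces.normalized:
        raise ValueError("run_scenario expects Theil-normalized surfaces")
    state = map_t0.values.copy()
    total_cells = int(np.count_nonzero(state != map_t0.nodata))
    targets_cells = targets.to_cells(map_t0.cell_area_km2, total_cells)
    band = default_band_width(targets_cells, cfg.stop_fraction)
    rng = np.random.default_rng(cfg.seed)
    names = list(scheme.names)
    codes = {n: scheme.code(n) for n in names}

    def counts_of(arr):
        return {n: int(np.count_nonzero(arr == codes[n])) for n in names}

    traj = [counts_of(state)]
    iterations = 0
    for iterations in range(1, cfg.max_iterations + 1):
        counts = counts_of(state)
        if np.asarray(list(counts.values())).sum() != total_cells:
            raise AssertionError("cell-count conservation violated")
        status = stop_band_check(counts, targets_cells, band)
        if all(s == "met" for s in status.values()):
            iterations -= 1
            break
        made = iterate_step(
            state,
            surfaces,
            constraints,
            targets_cells,
            band,
            cfg,
            rng,
            scheme,
            window,
            nodata=map_t0.nodata,
        )
        traj.append(counts_of(state))
        if made == 0:
            break  # no further conversions possible

    final_counts = counts_of(state)
    status = stop_band_check(final_counts, targets_cells, band)
    converged = {n: status[n] == "met" for n in names}
    gaps = {n: final_counts[n] - targets_cells[n] for n in names}
    final = LandUseGrid(
        state,
        cell_size=map_t0.cell_size,
        origin=map_t0.origin,
        epoch=targets.target_epoch,
        nodata=map_t0.nodata,
    )
    return SimulationResult(
        final_grid=final,
        trajectory=pd.DataFrame(traj),
        iterations=iterations,
        converged=converged,
        gaps=gaps,
        config=cfg,
        targets_cells=targets_cells,
    )
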