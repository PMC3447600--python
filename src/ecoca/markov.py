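"""Markov macro-prediction: transition matrices, area projection, targets.

The macro controller cross-tabulates two epochs into an inter-class area
transition matrix, row-normalizes it into a Markov state-transition
probability matrix, projects class areas forward (one step = one monitoring
interval, five years in the source data cadence), and supplies the stopping
band that freezes CA conversions into a class once its cell count reaches the
projected (or planning-constrained) target.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grid import ClassScheme, DEFAULT_SCHEME, LandUseGrid, area_table

__all__ = [
    "TransitionMatrix",
    "MacroTargets",
    "crosstab",
    "to_probability",
    "project",
    "stop_band_check",
    "markov_targets",
    "planning_targets",
]


@dataclass
class TransitionMatrix:
    """4×4 inter-class transition table.

    In area form, ``table[a, b]`` is the km² moving from class ``a`` (rows,
    epoch t) to class ``b`` (columns, epoch t+1); the grand total equals the
    landscape area. Row-normalizing yields the probability form P_ij.
    """

    table: pd.DataFrame
    form: str = "area"  # "area" | "probability"
    epochs: tuple = (None, None)
    step_years: float = 5.0
    empty_rows: tuple = ()

    def __post_init__(self):
        if (self.table.values < -1e-12).any():
            raise ValueError("transition matrix entries must be non-negative")

    @property
    def values(self) -> np.ndarray:
        return self.table.values

    def row_totals(self) -> pd.Series:
        return self.table.sum(axis=1)

    def col_totals(self) -> pd.Series:
        return self.table.sum(axis=0)

    def to_csv(self, path) -> None:
        self.table.to_csv(path)

    @classmethod
    def from_csv(cls, path, form="area", **kw) -> "TransitionMatrix":
        return cls(pd.read_csv(path, index_col=0), form=form, **kw)


@dataclass
class MacroTargets:
    """Per-class target areas with the iteration stopping tolerance.

    ``tolerance`` (the band half-width N) is in km²; the band is closed:
    a class is met iff |current − target| ≤ N. ``provenance`` records whether
    the targets come from the Markov projection or from planning caps.
    """

    target_epoch: str
    areas: pd.Series  # km² per class name
    tolerance: float | pd.Series
    provenance: str = "markov"
    landscape_area: float | None = None

    def __post_init__(self):
        if (self.areas < -1e-9).any():
            raise ValueError("targets must be non-negative")
        tol = self.tolerance
        if np.any(np.asarray(tol) <= 0):
            raise ValueError("stopping tolerance N must be > 0")
        if self.landscape_area is not None:
            tol_total = float(np.sum(np.asarray(tol)))
            if abs(self.areas.sum() - self.landscape_area) > tol_total:
                raise ValueError("targets do not conserve the landscape area")

    def tolerance_for(self, name: str) -> float:
        if isinstance(self.tolerance, pd.Series):
            return float(self.tolerance[name])
        return float(self.tolerance)

    def to_cells(self, cell_area_km2: float, total_cells: int) -> dict:
        """Integer cell-count targets conserving the landscape total exactly."""
        raw = self.areas / cell_area_km2
        cells = raw.round().astype(int)
        # adjust the largest class so the targets sum to the lattice total
        diff = total_cells - int(cells.sum())
        if diff != 0:
            cells[cells.idxmax()] += diff
        return {k: int(v) for k, v in cells.items()}


def default_band_width(targets_cells: dict, fraction: float = 0.01) -> dict:
    """Default N: 1% of each class target in cells (at least 1 cell)."""
    return {k: max(1, int(round(fraction * v))) for k, v in targets_cells.items()}


def crosstab(
    map_t0: LandUseGrid,
    map_t1: LandUseGrid,
    scheme: ClassScheme = DEFAULT_SCHEME,
) -> TransitionMatrix:
    """Cross-tabulate two aligned maps into an area transition matrix.

    Marginals equal the two epochs' area tables exactly (row sums = t0 areas,
    column sums = t1 areas).
    """
    if not map_t0.aligned_with(map_t1):
        raise ValueError("maps are not aligned")
    codes = np.array(scheme.codes)
    k = len(codes)
    code_to_idx = {c: i for i, c in enumerate(codes)}
    a = map_t0.values.ravel()
    b = map_t1.values.ravel()
    valid = (a != map_t0.nodata) & (b != map_t1.nodata)
    ai = np.vectorize(code_to_idx.get, otypes=[np.int64])(a[valid])
    bi = np.vectorize(code_to_idx.get, otypes=[np.int64])(b[valid])
    counts = np.bincount(ai * k + bi, minlength=k * k).reshape(k, k)
    table = pd.DataFrame(
        counts * map_t0.cell_area_km2, index=scheme.names, columns=scheme.names
    )
    return TransitionMatrix(table, form="area", epochs=(map_t0.epoch, map_t1.epoch))


def to_probability(tm: TransitionMatrix) -> TransitionMatrix:
    """Row-normalize an area transition matrix into Markov probabilities.

    Empty rows (a class absent at t0) get an identity row and are flagged in
    ``empty_rows`` rather than propagating NaN.
    """
    if tm.form == "probability":
        return tm
    vals = tm.values.astype(float)
    if (vals < 0).any():
        raise ValueError("negative entries in transition matrix")
    row_sums = vals.sum(axis=1)
    empty = row_sums == 0
    p = np.zeros_like(vals)
    p[~empty] = vals[~empty] / row_sums[~empty, None]
    for i in np.flatnonzero(empty):
        p[i, i] = 1.0
    table = pd.DataFrame(p, index=tm.table.index, columns=tm.table.columns)
    return TransitionMatrix(
        table,
        form="probability",
        epochs=tm.epochs,
        step_years=tm.step_years,
        empty_rows=tuple(tm.table.index[empty]),
    )


def project(areas: pd.Series, p: TransitionMatrix, steps: int) -> pd.Series:
    """Apply the probability matrix ``steps`` times to per-class areas.

    Total area is conserved for any row-stochastic matrix.
    """
    if steps < 0:
        raise ValueError("steps must be >= 0")
    if p.form != "probability":
        raise ValueError("project requires the probability form")
    if list(areas.index) != list(p.table.index):
        raise ValueError("class labels do not match the transition matrix")
    if (areas < 0).any():
        raise ValueError("areas must be non-negative")
    x = areas.values.astype(float)
    m = p.values
    for _ in range(steps):
        x = x @ m
    return pd.Series(x, index=areas.index)


def stop_band_check(current: dict, targets_cells: dict, band: dict) -> dict:
    """Classify each class count against its closed stopping band.

    Returns per class one of ``"met"`` (|current − target| ≤ N), ``"below"``
    or ``"above"``. The CA freezes conversions into a class once it is met.
    """
    status = {}
    for name, target in targets_cells.items():
        n = band[name]
        cur = current[name]
        if abs(cur - target) <= n:
            status[name] = "met"
        elif cur < target:
            status[name] = "below"
        else:
            status[name] = "above"
    return status


def markov_targets(
    map_t0: LandUseGrid,
    map_t1: LandUseGrid,
    steps: int,
    scheme: ClassScheme = DEFAULT_SCHEME,
    target_epoch: str = "projected",
    tolerance_fraction: float = 0.01,
) -> MacroTargets:
    """Markov macro targets: project the t1 areas ``steps`` intervals ahead
    with the probability matrix estimated from (t0, t1)."""
    tm = to_probability(crosstab(map_t0, map_t1, scheme))
    base = area_table(map_t1, scheme)["area_km2"]
    target = project(base, tm, steps)
    tol = (target * tolerance_fraction).clip(lower=map_t0.cell_area_km2)
    return MacroTargets(
        target_epoch=target_epoch,
        areas=target,
        tolerance=tol,
        provenance="markov",
        landscape_area=float(base.sum()),
    )


def planning_targets(
    base: pd.DataFrame | pd.Series,
    construction_increment_cap: float,
    cultivated_decline_cap_pct: float,
    target_epoch: str = "planned",
    tolerance_fraction: float = 0.01,
    scheme: ClassScheme = DEFAULT_SCHEME,
) -> MacroTargets:
    """Planning-constrained macro targets for the goal-driven scenarios.

    Construction grows by at most the planning increment (km²); cultivated
    land declines by the planning percentage of its base area; ecological and
    other land absorb the residual so the landscape total is conserved, split
    in their base-epoch ratio.
    """
    areas = base["area_km2"] if isinstance(base, pd.DataFrame) else base
    total = float(areas.sum())
    constr = areas["construction"] + construction_increment_cap
    cult = areas["cultivated"] * (1.0 - cultivated_decline_cap_pct / 100.0)
    if constr < 0 or cult < 0:
        raise ValueError("planning caps produce negative areas")
    residual = total - constr - cult
    if residual < 0:
        raise ValueError("planning caps exceed the landscape area")
    eco0, oth0 = areas["ecological"], areas["other"]
    ratio = eco0 / (eco0 + oth0) if (eco0 + oth0) > 0 else 1.0
    target = pd.Series(
        {
            "cultivated": cult,
            "ecological": residual * ratio,
            "construction": constr,
            "other": residual * (1.0 - ratio),
        }
    ).reindex(areas.index)
    tol = (target * tolerance_fraction).clip(lower=1e-9)
    return MacroTargets(
        target_epoch=target_epoch,
        areas=target,
        tolerance=tol,
        provenance="planning",
        landscape_area=total,
    )
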