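"""Landscape-pattern evaluation: class-level patch metrics and change accounting.

Implements the four class-level indices used to compare scenario outcomes —
largest patch index (LPI), patch cohesion (COHESION), splitting index
(SPLIT) and aggregation index (AI) — under the Fragstats conventions
(8-neighbor patch connectivity, 4-neighbor single-count adjacencies), plus
area-change summaries, overlay accuracy and key-ecological-land loss
accounting by security level.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .grid import ClassScheme, DEFAULT_SCHEME, LandUseGrid, area_table

__all__ = [
    "PatchSet",
    "PatchMetricsReport",
    "label_patches",
    "lpi",
    "cohesion",
    "split",
    "aggregation_index",
    "class_metrics",
    "area_change_summary",
    "overlay_accuracy",
    "key_ecoland_loss",
]


@dataclass
class PatchSet:
    """Patches of one class: per-patch cell counts and perimeters.

    Perimeters are in cell-edge units: the number of cell edges adjacent to
    a different class, nodata, or the landscape boundary. ``total_cells`` is
    the landscape total A (nodata excluded).
    """

    class_name: str
    areas: np.ndarray  # cells per patch
    perimeters: np.ndarray  # edge units per patch
    total_cells: int
    labels: np.ndarray | None = None

    @property
    def n_patches(self) -> int:
        return len(self.areas)

    @property
    def class_cells(self) -> int:
        return int(self.areas.sum())

    def __post_init__(self):
        # every patch perimeter is at least that of the equal-area square
        a = np.asarray(self.areas, dtype=float)
        p = np.asarray(self.perimeters, dtype=float)
        if np.any(p < 4.0 * np.sqrt(a) - 1e-9):
            raise ValueError("patch perimeter below the equal-area square bound")


def label_patches(
    grid: LandUseGrid,
    class_name: str,
    connectivity: int = 8,
    scheme: ClassScheme = DEFAULT_SCHEME,
) -> PatchSet:
    """Connected components of one class with per-patch area and perimeter."""
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    mask = grid.values == scheme.code(class_name)
    structure = np.ones((3, 3)) if connectivity == 8 else None
    labels, n = ndimage.label(mask, structure=structure)
    total = int(np.count_nonzero(grid.valid_mask()))
    if n == 0:
        return PatchSet(class_name, np.array([], dtype=int), np.array([], dtype=int), total, labels)
    areas = np.bincount(labels.ravel(), minlength=n + 1)[1:]
    # perimeter: 4-neighbor edges to anything outside the class (incl. boundary)
    padded = np.pad(mask, 1, constant_values=False)
    perims = np.zeros(n + 1, dtype=int)
    for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
        nb = padded[1 + dr : padded.shape[0] - 1 + dr, 1 + dc : padded.shape[1] - 1 + dc]
        edge = mask & ~nb
        perims += np.bincount(labels[edge].ravel(), minlength=n + 1)
    return PatchSet(class_name, areas, perims[1:], total, labels)


def lpi(patches: PatchSet) -> float:
    """Largest patch index: largest patch area as % of the landscape area."""
    if patches.n_patches == 0:
        warnings.warn(f"LPI undefined for empty class {patches.class_name!r}; reporting 0")
        return 0.0
    return 100.0 * patches.areas.max() / patches.total_cells


def cohesion(patches: PatchSet) -> float:
    """Patch cohesion index (physical connectedness of the class).

    COHESION = [1 − Σpᵢ / Σ(pᵢ√aᵢ)] · [1 − 1/√A]⁻¹ · 100, with patch areas
    aᵢ in cells, perimeters pᵢ in edge units and A the landscape cell count.
    """
    if patches.n_patches == 0:
        raise ValueError("COHESION undefined for an empty class")
    if patches.total_cells <= 1:
        raise ValueError("COHESION undefined on a single-cell landscape")
    p = patches.perimeters.astype(float)
    a = patches.areas.astype(float)
    return (1.0 - p.sum() / (p * np.sqrt(a)).sum()) / (
        1.0 - 1.0 / np.sqrt(patches.total_cells)
    ) * 100.0


def split(patches: PatchSet) -> float:
    """Splitting index SPLIT = A² / Σaᵢ² (≥ 1; larger = more fragmented)."""
    if patches.n_patches == 0:
        raise ValueError("SPLIT undefined for an empty class")
    a = patches.areas.astype(float)
    return patches.total_cells**2 / (a**2).sum()


def _max_like_adjacencies(a: int) -> int:
    """Fragstats combinatorial maximum of like adjacencies for a cells."""
    n = int(np.floor(np.sqrt(a)))
    m = a - n * n
    if m == 0:
        return 2 * n * (n - 1)
    if m <= n:
        return 2 * n * (n - 1) + 2 * m - 1
    return 2 * n * (n - 1) + 2 * m - 2


def aggregation_index(
    grid: LandUseGrid, class_name: str, scheme: ClassScheme = DEFAULT_SCHEME
) -> float:
    """Aggregation index AI = 100 · g / g_max (4-neighbor, single count).

    A one-cell class has g_max = 0 and is reported as fully aggregated (100)
    by convention.
    """
    mask = grid.values == scheme.code(class_name)
    a = int(np.count_nonzero(mask))
    if a == 0:
        raise ValueError(f"AI undefined for empty class {class_name!r}")
    g = int(np.count_nonzero(mask[:, :-1] & mask[:, 1:])) + int(
        np.count_nonzero(mask[:-1, :] & mask[1:, :])
    )
    gmax = _max_like_adjacencies(a)
    if gmax == 0:
        warnings.warn("single-cell class: AI reported as 100 by convention")
        return 100.0
    return 100.0 * g / gmax


def class_metrics(
    grid: LandUseGrid, class_name: str = "ecological", scheme: ClassScheme = DEFAULT_SCHEME
) -> dict:
    """The four class-level indices for one map."""
    patches = label_patches(grid, class_name, scheme=scheme)
    return {
        "LPI": lpi(patches),
        "COHESION": cohesion(patches),
        "SPLIT": split(patches),
        "AI": aggregation_index(grid, class_name, scheme),
    }


def area_change_summary(base: pd.DataFrame, result: pd.DataFrame) -> pd.DataFrame:
    """Per-class absolute (km²) and percent change between two area tables."""
    b = base["area_km2"]
    r = result["area_km2"].reindex(b.index)
    rel = abs(b.sum() - r.sum()) / b.sum()
    if rel > 0.01:
        raise ValueError("area tables do not share a landscape total")
    if rel > 1e-6:
        # published tables occasionally fail to conserve the total exactly;
        # flag it but still report the per-class changes
        warnings.warn(f"area tables differ in total by {rel:.4%}; changes reported anyway")
    if (b == 0).any():
        raise ValueError("zero base area: percent change undefined")
    out = pd.DataFrame(
        {
            "base_km2": b,
            "result_km2": r,
            "change_km2": r - b,
            "change_pct": 100.0 * (r - b) / b,
        }
    )
    return out


def overlay_accuracy(simulated: LandUseGrid, observed: LandUseGrid) -> float:
    """Cellwise agreement: 1 − (#mismatched valid cells / #valid cells)."""
    if not simulated.aligned_with(observed):
        raise ValueError("grids are not aligned")
    valid = simulated.valid_mask() & observed.valid_mask()
    n = int(np.count_nonzero(valid))
    if n == 0:
        raise ValueError("no valid overlapping cells")
    mismatch = int(np.count_nonzero(simulated.values[valid] != observed.values[valid]))
    return 1.0 - mismatch / n


def key_ecoland_loss(
    map_t0: LandUseGrid,
    map_t1: LandUseGrid,
    security_masks: dict,
    scheme: ClassScheme = DEFAULT_SCHEME,
) -> dict:
    """Km² of key ecological land lost between epochs, per security level.

    A masked cell counts as lost iff it is ecological at t0 and non-ecological
    at t1. Masked cells that are not ecological at t0 are excluded with a
    warning.
    """
    if not map_t0.aligned_with(map_t1):
        raise ValueError("grids are not aligned")
    eco = scheme.code("ecological")
    eco0 = map_t0.values == eco
    losses = {}
    for level, mask in security_masks.items():
        mask = np.asarray(mask, dtype=bool)
        off = mask & ~eco0
        if off.any():
            warnings.warn(
                f"{int(off.sum())} masked cells in {level!r} are not ecological at t0; excluded"
            )
        lost = mask & eco0 & (map_t1.values != eco)
        losses[level] = float(np.count_nonzero(lost)) * map_t0.cell_area_km2
    return losses


@dataclass
class PatchMetricsReport:
    """Scenario comparison report: indices, area changes, key-land losses."""

    label: str
    indices: dict  # class_name -> {LPI, COHESION, SPLIT, AI}
    area_change: pd.DataFrame | None = None
    key_land_loss: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = {}
        for cls, vals in self.indices.items():
            for k, v in vals.items():
                rows[f"{cls}_{k}"] = v
        for lvl, v in self.key_land_loss.items():
            rows[f"loss_{lvl}_km2"] = v
        return pd.DataFrame({self.label: rows})


def build_report(
    label: str,
    grid: LandUseGrid,
    base_grid: LandUseGrid | None = None,
    security_masks: dict | None = None,
    class_name: str = "ecological",
    scheme: ClassScheme = DEFAULT_SCHEME,
) -> PatchMetricsReport:
    """Assemble the per-scenario evaluation report for one simulated map."""
    report = PatchMetricsReport(label=label, indices={class_name: class_metrics(grid, class_name, scheme)})
    if base_grid is not None:
        report.area_change = area_change_summary(
            area_table(base_grid, scheme), area_table(grid, scheme)
        )
        if security_masks:
            report.key_land_loss = key_ecoland_loss(base_grid, grid, security_masks, scheme)
    return report
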