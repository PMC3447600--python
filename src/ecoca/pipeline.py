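"""End-to-end orchestration: calibrate, build scenario targets, simulate, report.

One top-level seed fans out to per-stage seeds through a fixed stage-name
hash so a single integer reproduces the whole run.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import engine, markov, metrics, suitability
from .grid import ClassScheme, DEFAULT_SCHEME, area_table
from .synth import SyntheticBundle

__all__ = [
    "derive_seed",
    "calibrate",
    "default_scenario_configs",
    "scenario_targets",
    "run_all_scenarios",
    "RunManifest",
]

#: Planning caps for the goal-driven scenarios, as fractions of the total
#: landscape area, mirroring the source planning document's structure: the
#: construction increment cap, and a cultivated decline that under ecosystem
#: priority exceeds the construction gain so ecological land gains the
#: residual, while under object orientation it does not.
PLANNING_RATIOS = {
    "object_orientation": {
        "construction_increment_landfrac": 0.018553,
        "cultivated_decline_landfrac": 0.014005,
    },
    "ecosystem_priority": {
        "construction_increment_landfrac": 0.018553,
        "cultivated_decline_landfrac": 0.020080,
    },
}


def derive_seed(master: int, stage: str) -> int:
    """Stable per-stage seed below 2**31 derived from one master seed."""
    return (int(master) * 1000003 + zlib.crc32(stage.encode())) % (2**31 - 1)


@dataclass
class RunManifest:
    """Record of one full run: seeds, stage outputs, convergence."""

    master_seed: int
    stage_seeds: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)
    convergence: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "master_seed": self.master_seed,
                    "stage_seeds": self.stage_seeds,
                    "outputs": self.outputs,
                    "convergence": self.convergence,
                },
                fh,
                indent=2,
                default=str,
            )


def calibrate(
    map_t0,
    map_t1,
    drivers,
    fraction: float = 0.2,
    seed: int | None = None,
    scheme: ClassScheme = DEFAULT_SCHEME,
    exclude=None,
):
    """Calibration stage: sample cells, fit the three logits, cross-tabulate.

    Returns ``(models, transition_matrix, design)``. ``exclude`` removes
    hard-constrained cells from the sampling frame (they cannot convert, and
    including them biases coefficients on drivers the masks correlate with).
    """
    design = suitability.sample_cells(
        map_t0, map_t1, drivers, fraction=fraction, seed=seed, scheme=scheme, exclude=exclude
    )
    models = suitability.fit_all(design, scheme)
    tm = markov.crosstab(map_t0, map_t1, scheme)
    return models, tm, design


def default_scenario_configs(seed: int, **overrides) -> dict:
    """The three scenario configurations sharing one seed."""
    cfgs = {}
    for name in engine.SCENARIOS:
        kw = dict(
            name=name,
            seed=derive_seed(seed, f"simulate:{name}"),
            targets_source="markov" if name == "natural_development" else "planning",
        )
        kw.update(overrides.get(name, {}))
        cfgs[name] = engine.ScenarioConfig(**kw)
    return cfgs


def scenario_targets(
    cfg: engine.ScenarioConfig,
    map_t0,
    map_t1,
    steps: int = 3,
    scheme: ClassScheme = DEFAULT_SCHEME,
) -> markov.MacroTargets:
    """Macro targets for one scenario from the calibration epoch pair.

    Natural development projects the estimated Markov matrix ``steps``
    intervals beyond t1; the planning scenarios cap construction growth and
    cultivated decline relative to the t1 base and allocate the residual to
    ecological/other in their base ratio.
    """
    if cfg.targets_source == "markov":
        return markov.markov_targets(
            map_t0, map_t1, steps=steps, scheme=scheme, tolerance_fraction=cfg.stop_fraction
        )
    base = area_table(map_t1, scheme)
    total = float(base["area_km2"].sum())
    cap = cfg.construction_increment_cap
    if cap is None:
        cap = PLANNING_RATIOS[cfg.name]["construction_increment_landfrac"] * total
    decline = cfg.cultivated_decline_cap_pct
    if decline is None:
        decline = (
            100.0
            * PLANNING_RATIOS[cfg.name]["cultivated_decline_landfrac"]
            * total
            / base.loc["cultivated", "area_km2"]
        )
    return markov.planning_targets(
        base, cap, decline, scheme=scheme, tolerance_fraction=cfg.stop_fraction
    )


def hindcast_accuracy(
    bundle: SyntheticBundle,
    models: dict,
    seed: int = 0,
    cfg_kwargs: dict | None = None,
) -> float:
    """Calibration-style validation: resimulate t0 → t1 and score the overlay.

    The CA starts from the earlier map with macro targets set to the later
    epoch's actual areas (the quantities a one-step Markov projection
    reproduces exactly) under natural-development constraints, and the
    simulated map is compared cell-by-cell with the actually realized one.
    """
    scheme = bundle.spec.scheme
    raw = {m: suitability.predict_surface(mod, bundle.drivers) for m, mod in models.items()}
    surfaces = suitability.theil_normalize(raw)
    target_areas = area_table(bundle.map_t1, scheme)["area_km2"]
    targets = markov.MacroTargets(
        target_epoch="t1",
        areas=target_areas,
        tolerance=(target_areas * 0.01).clip(lower=bundle.map_t0.cell_area_km2),
        provenance="markov",
        landscape_area=float(target_areas.sum()),
    )
    cfg = engine.ScenarioConfig(
        "natural_development", seed=derive_seed(seed, "hindcast"), **(cfg_kwargs or {})
    )
    constraints = engine.build_constraints(cfg, bundle.masks, bundle.map_t0, scheme)
    res = engine.run_scenario(bundle.map_t0, surfaces, constraints, targets, cfg, scheme)
    return metrics.overlay_accuracy(res.final_grid, bundle.map_t1)


def run_all_scenarios(
    bundle: SyntheticBundle,
    models: dict | None = None,
    seed: int = 0,
    steps: int = 3,
    calibration_fraction: float = 0.2,
    config_overrides: dict | None = None,
):
    """Calibrate (if needed) then simulate the three scenarios on one bundle.

    Returns ``(results, report, manifest)``: per-scenario SimulationResults,
    a comparison report (area tables, ecological-class indices, key-land
    losses), and the run manifest.
    """
    scheme = bundle.spec.scheme
    manifest = RunManifest(master_seed=seed)
    if models is None:
        cal_seed = derive_seed(seed, "calibrate")
        manifest.stage_seeds["calibrate"] = cal_seed
        models, _, _ = calibrate(
            bundle.map_t0,
            bundle.map_t1,
            bundle.drivers,
            fraction=calibration_fraction,
            seed=cal_seed,
            scheme=scheme,
            exclude=bundle.constrained_union(),
        )
    raw = {m: suitability.predict_surface(mod, bundle.drivers) for m, mod in models.items()}
    surfaces = suitability.theil_normalize(raw)

    cfgs = default_scenario_configs(seed, **(config_overrides or {}))
    results = {}
    frames = []
    base_table = area_table(bundle.map_t1, scheme)
    # key ecological land is scored against the simulation base epoch, so
    # restrict the security masks to cells still ecological at t1
    eco_t1 = bundle.map_t1.values == scheme.code("ecological")
    security = {
        "low_security": bundle.masks["key_ecoland_low_security"] & eco_t1,
        "high_security": bundle.masks["key_ecoland_high_security"] & eco_t1,
    }
    for name, cfg in cfgs.items():
        manifest.stage_seeds[f"simulate:{name}"] = cfg.seed
        targets = scenario_targets(cfg, bundle.map_t0, bundle.map_t1, steps=steps, scheme=scheme)
        constraints = engine.build_constraints(cfg, bundle.masks, bundle.map_t1, scheme)
        res = engine.run_scenario(bundle.map_t1, surfaces, constraints, targets, cfg, scheme)
        results[name] = res
        manifest.convergence[name] = {
            "converged": res.converged,
            "iterations": res.iterations,
            "gaps": res.gaps,
        }
        rep = metrics.build_report(
            name,
            res.final_grid,
            base_grid=bundle.map_t1,
            security_masks=security,
            scheme=scheme,
        )
        frame = rep.to_frame()
        for cls in scheme.names:
            frame.loc[f"area_{cls}_km2", name] = rep.area_change.loc[cls, "result_km2"]
        frames.append(frame)
    report = pd.concat(frames, axis=1)
    # status-epoch column for side-by-side comparison
    status = metrics.build_report("status_t1", bundle.map_t1, scheme=scheme)
    sf = status.to_frame()
    for cls in scheme.names:
        sf.loc[f"area_{cls}_km2", "status_t1"] = base_table.loc[cls, "area_km2"]
    report = pd.concat([sf, report], axis=1)
    return results, report, manifest
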