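"""Global conversion probability: per-class logistic suitability surfaces.

Observed conversions between two epochs are regressed on the driver stack,
one binary logit per target class (to cultivated, to ecological, to
construction), maximum likelihood via statsmodels. The separately fitted
probabilities are then made coherent per cell by Theil (ratio)
normalization, P'(i_j) = P(i_j) / Σ_k P(i_k), which preserves the per-cell
argmax; the maximal class is the one the cell could be transferred to.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .grid import ClassScheme, DEFAULT_SCHEME, DRIVER_NAMES, DriverStack, LandUseGrid

__all__ = [
    "LogitModel",
    "SuitabilitySurfaces",
    "sample_cells",
    "fit_logit",
    "predict_surface",
    "theil_normalize",
    "argmax_class",
    "fit_all",
    "models_to_json",
    "models_from_json",
]

#: Target classes with a suitability model; "other" land has none and
#: receives no modeled in-conversions.
MODELED_CLASSES = ("cultivated", "ecological", "construction")


@dataclass
class LogitModel:
    """Fitted binary logit for conversion to one target class."""

    target_class: str
    intercept: float
    coef: pd.Series  # indexed by driver layer name
    n_obs: int = 0
    converged: bool = True

    def linear_predictor(self, x: np.ndarray, names) -> np.ndarray:
        beta = self.coef.reindex(list(names))
        if beta.isna().any():
            missing = list(beta.index[beta.isna()])
            raise KeyError(f"driver layer(s) missing from model: {missing}")
        return self.intercept + x @ beta.values


@dataclass
class SuitabilitySurfaces:
    """Per-class probability lattices, optionally Theil-normalized."""

    surfaces: dict  # class name -> float lattice
    normalized: bool = False

    def __getitem__(self, name):
        return self.surfaces[name]

    @property
    def names(self):
        return tuple(self.surfaces.keys())


def sample_cells(
    map_t0: LandUseGrid,
    map_t1: LandUseGrid,
    drivers: DriverStack,
    fraction: float = 0.2,
    seed: int | None = None,
    scheme: ClassScheme = DEFAULT_SCHEME,
    exclude: np.ndarray | None = None,
) -> pd.DataFrame:
    """Uniform random sample (without replacement) of valid cells.

    Returns a design table with one row per sampled cell: binary outcomes
    ``y_<class>`` (1 iff the cell converted to that class between epochs),
    the seven driver values, the t0 class and the (row, col) index.
    ``exclude`` optionally removes cells (e.g. hard-constrained ones) from
    the sampling frame.
    """
    if not (0 < fraction <= 1):
        raise ValueError("fraction must be in (0, 1]")
    if not map_t0.aligned_with(map_t1):
        raise ValueError("maps are not aligned")
    v0 = map_t0.values.ravel()
    v1 = map_t1.values.ravel()
    valid = (v0 != map_t0.nodata) & (v1 != map_t1.nodata)
    if exclude is not None:
        valid &= ~np.asarray(exclude, dtype=bool).ravel()
    pool = np.flatnonzero(valid)
    n = int(round(fraction * pool.size))
    if n < 100:
        raise ValueError(f"sample of {n} cells is too small (< 100)")
    if n == pool.size:
        idx = pool
    else:
        rng = np.random.default_rng(seed)
        idx = np.sort(rng.choice(pool, size=n, replace=False))
    ncols = map_t0.shape[1]
    tab = {
        "row": idx // ncols,
        "col": idx % ncols,
        "class_t0": v0[idx],
    }
    for m in MODELED_CLASSES:
        code = scheme.code(m)
        tab[f"y_{m}"] = ((v1[idx] == code) & (v0[idx] != code)).astype(np.int8)
    x = drivers.design_matrix(DRIVER_NAMES)[idx]
    for j, name in enumerate(DRIVER_NAMES):
        tab[name] = x[:, j]
    return pd.DataFrame(tab)


def fit_logit(
    design: pd.DataFrame,
    target_class: str,
    scheme: ClassScheme = DEFAULT_SCHEME,
    driver_names=DRIVER_NAMES,
) -> LogitModel:
    """Maximum-likelihood binary logit of conversion-to-``target_class``.

    Observations are the convertible cells only — those not already in the
    target class at t0. Perfect separation is reported as an error, never
    silently worked around.
    """
    rows = design[design["class_t0"] != scheme.code(target_class)]
    y = rows[f"y_{target_class}"].values
    if y.min() == y.max():
        raise ValueError(
            f"cannot fit conversion to {target_class!r}: outcome has a single level"
        )
    x = sm.add_constant(rows[list(driver_names)].values)
    try:
        res = sm.Logit(y, x).fit(disp=False, maxiter=200, tol=1e-8)
    except PerfectSeparationError as e:  # pragma: no cover - data dependent
        raise ValueError(f"perfect separation fitting {target_class!r}: {e}") from e
    params = res.params
    if not np.all(np.isfinite(params)):
        raise ValueError(f"non-finite coefficients fitting {target_class!r}")
    return LogitModel(
        target_class=target_class,
        intercept=float(params[0]),
        coef=pd.Series(params[1:], index=list(driver_names)),
        n_obs=int(len(rows)),
        converged=bool(res.mle_retvals.get("converged", True)),
    )


def predict_surface(model: LogitModel, drivers: DriverStack) -> np.ndarray:
    """Cellwise inverse-logit probability lattice for one target class."""
    absent = [n for n in model.coef.index if n not in drivers.layers]
    if absent:
        raise KeyError(f"driver layer(s) missing from stack: {absent}")
    x = drivers.design_matrix(model.coef.index)
    eta = model.intercept + x @ model.coef.values
    return (1.0 / (1.0 + np.exp(-eta))).reshape(drivers.shape)


def theil_normalize(surfaces: dict) -> SuitabilitySurfaces:
    """Ratio-normalize per-class probabilities into a coherent set.

    Per cell, P'(i_j) = P(i_j) / Σ_k P(i_k); the per-cell ranking (and hence
    the argmax class) is unchanged. Cells where every class probability is 0
    are flagged by assigning the uniform distribution.
    """
    names = list(surfaces.keys())
    if len(names) < 2:
        raise ValueError("need at least two class surfaces to normalize")
    stack = np.stack([np.asarray(surfaces[n], dtype=float) for n in names])
    total = stack.sum(axis=0)
    zero = total == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        norm = stack / total
    if zero.any():
        norm[:, zero] = 1.0 / len(names)
    return SuitabilitySurfaces({n: norm[i] for i, n in enumerate(names)}, normalized=True)


def argmax_class(
    surfaces: SuitabilitySurfaces, scheme: ClassScheme = DEFAULT_SCHEME
) -> np.ndarray:
    """Per-cell candidate target class (code) with maximal probability.

    Exact ties break to the lowest class code — a fixed, reproducible rule.
    """
    if not surfaces.normalized:
        raise ValueError("argmax_class expects normalized surfaces")
    names = sorted(surfaces.names, key=scheme.code)
    stack = np.stack([surfaces[n] for n in names])
    idx = np.argmax(stack, axis=0)  # np.argmax returns the first maximum
    codes = np.array([scheme.code(n) for n in names])
    return codes[idx]


def fit_all(design: pd.DataFrame, scheme: ClassScheme = DEFAULT_SCHEME) -> dict:
    """Fit the three per-class logits from one design table."""
    return {m: fit_logit(design, m, scheme) for m in MODELED_CLASSES}


def models_to_json(models: dict, path) -> None:
    payload = {
        m: {
            "intercept": mod.intercept,
            "coef": {k: float(v) for k, v in mod.coef.items()},
            "n_obs": mod.n_obs,
            "converged": mod.converged,
        }
        for m, mod in models.items()
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)


def models_from_json(path) -> dict:
    with open(path) as fh:
        payload = json.load(fh)
    return {
        m: LogitModel(
            target_class=m,
            intercept=d["intercept"],
            coef=pd.Series(d["coef"]),
            n_obs=d.get("n_obs", 0),
            converged=d.get("converged", True),
        )
        for m, d in payload.items()
    }
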