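"""Association-constant estimation and solubilization diagnostics.

The association constant K of the 1:1 complex is estimated by weighted least
squares: the coupled-diffusion forward model is evaluated on every table row
and the squared residuals of the four coefficients, scaled by their standard
deviations, are summed.  The one-dimensional objective is minimized on a
dense K grid followed by local refinement, which is deterministic and immune
to local minima.  Uncertainty comes from a residual-resampling bootstrap.

Solubilized fractions use the two-state fast-exchange relation: a drug
molecule diffuses either freely (D0) or inside the carrier/micelle (Dc), so
the tracer coefficient D11 = (1-s) D0 + s Dc and s = (D0 - D11)/(D0 - Dc).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .core_model import (
    BindingSystem,
    Composition,
    DMatrix,
    SpeciesDiffusivities,
    predict_dmatrix,
)

__all__ = [
    "KFitResult",
    "SolubilizationResult",
    "COEFFICIENTS",
    "DEFAULT_SD_MAIN",
    "DEFAULT_SD_CROSS",
    "weighted_sse",
    "fit_k",
    "bootstrap_k_ci",
    "solubilized_fraction",
    "bound_fraction",
    "deviation_percent",
    "classify_regime",
]

logger = logging.getLogger(__name__)

COEFFICIENTS = ("d11", "d12", "d21", "d22")
#: reproducibility-class fallbacks when a cell carries no printed SD
DEFAULT_SD_MAIN = 0.02
DEFAULT_SD_CROSS = 0.05
_MAIN = frozenset({"d11", "d22"})

Rows = Sequence[tuple[Composition, DMatrix]]


@dataclass(frozen=True)
class KFitResult:
    """Grid-refined weighted least-squares estimate of the association constant."""

    k_hat: float
    weighted_sse: float
    residuals: pd.DataFrame
    rows_used: list[str]
    k_ci: tuple[float, float] | None = None
    k_grid: tuple[float, float, float] = (0.0, 500.0, 0.1)

    def __post_init__(self) -> None:
        if self.k_hat < 0:
            raise ValueError("k_hat must be non-negative")
        if self.weighted_sse < 0:
            raise ValueError("weighted_sse must be non-negative")
        if self.k_ci is not None and not (
            self.k_ci[0] - 1e-12 <= self.k_hat <= self.k_ci[1] + 1e-12
        ):
            raise ValueError("confidence interval must contain k_hat")


@dataclass(frozen=True)
class SolubilizationResult:
    """Fraction of drug carried by the complex, from tracer-diffusion attenuation."""

    s: float
    deviation_percent: float
    composition: Composition | None = None
    clipped: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.s <= 1.0):
            raise ValueError("s must lie in [0, 1]")


def _cell_sd(m: DMatrix, coeff: str) -> float:
    sd = getattr(m, "s" + coeff)
    if sd is not None and sd > 0:
        return sd
    return DEFAULT_SD_MAIN if coeff in _MAIN else DEFAULT_SD_CROSS


def weighted_sse(
    rows: Rows,
    diffusivities: SpeciesDiffusivities,
    k: float,
    coefficients: Sequence[str] = COEFFICIENTS,
) -> float:
    """SD-weighted sum of squared residuals of the forward model at a given K."""
    system = BindingSystem(diffusivities=diffusivities, k_assoc=k)
    total = 0.0
    for comp, obs in rows:
        model = predict_dmatrix(comp, system)
        for coeff in coefficients:
            r = (getattr(obs, coeff) - getattr(model, coeff)) / _cell_sd(obs, coeff)
            total += r * r
    return total


def _grid_sse(
    rows: Rows,
    diffusivities: SpeciesDiffusivities,
    k_grid: np.ndarray,
    coefficients: Sequence[str],
) -> np.ndarray:
    """Vectorized objective over a K grid (same math as :func:`weighted_sse`)."""
    dd = diffusivities.d_free_drug
    db = diffusivities.d_free_carrier
    dc = diffusivities.d_complex
    sse = np.zeros_like(k_grid)
    for comp, obs in rows:
        c1, c2 = comp.c1, comp.c2
        r = ((1.0 + k_grid * (c2 - c1)) ** 2 + 4.0 * k_grid * c1) ** -0.5
        b = (1.0 - k_grid * (c2 - c1)) * r
        model = {
            "d11": 0.5 * ((dd + dc) + (dd - dc) * b),
            "d12": 0.5 * ((dc - dd) + (dd - dc) * b),
            "d21": 0.5 * ((dc - db) + (db - dc) * b),
            "d22": 0.5 * ((db + dc) + (db - dc) * b),
        }
        for coeff in coefficients:
            res = (getattr(obs, coeff) - model[coeff]) / _cell_sd(obs, coeff)
            sse += res * res
    return sse


def _minimize_k(
    rows: Rows,
    diffusivities: SpeciesDiffusivities,
    k_grid: tuple[float, float, float],
    coefficients: Sequence[str],
) -> tuple[float, float]:
    lo, hi, step = k_grid
    grid = np.arange(lo, hi + step / 2, step)
    sse = _grid_sse(rows, diffusivities, grid, coefficients)
    i = int(np.argmin(sse))
    k0 = grid[i]
    left = grid[max(i - 1, 0)]
    right = grid[min(i + 1, len(grid) - 1)]
    if right > left:
        res = minimize_scalar(
            lambda k: weighted_sse(rows, diffusivities, k, coefficients),
            bounds=(max(lo, left), right),
            method="bounded",
            options={"xatol": 1e-10},
        )
        if res.fun <= sse[i]:
            return float(res.x), float(res.fun)
    return float(k0), float(sse[i])


def fit_k(
    rows: Rows,
    diffusivities: SpeciesDiffusivities,
    regime_filter: Callable[[Composition], bool] | None = None,
    coefficients: Sequence[str] = COEFFICIENTS,
    k_grid: tuple[float, float, float] = (0.0, 500.0, 0.1),
    n_boot: int = 0,
    seed: int | None = None,
) -> KFitResult:
    """Estimate K by SD-weighted least squares over a D-matrix table.

    Species diffusivities are fixed inputs (taken from the binary-limit rows
    of the table, not co-fitted).  ``regime_filter`` drops rows before
    fitting, e.g. to restrict a micellar system to above-CMC compositions.
    When ``n_boot`` > 0 a residual-resampling bootstrap 95% interval is
    attached.
    """
    unknown = set(coefficients) - set(COEFFICIENTS)
    if unknown:
        raise ValueError(f"unknown coefficients: {sorted(unknown)}")
    used = [(c, m) for c, m in rows if regime_filter is None or regime_filter(c)]
    if len(used) < 2:
        raise ValueError("need at least two rows after regime filtering")
    k_hat, sse = _minimize_k(used, diffusivities, k_grid, coefficients)

    system = BindingSystem(diffusivities=diffusivities, k_assoc=k_hat)
    records = []
    for comp, obs in used:
        model = predict_dmatrix(comp, system)
        rec = {"c1": comp.c1, "c2": comp.c2, "x1": comp.x1}
        for coeff in COEFFICIENTS:
            rec[f"resid_{coeff}"] = getattr(obs, coeff) - getattr(model, coeff)
            rec[f"sd_{coeff}"] = _cell_sd(obs, coeff)
        records.append(rec)
    residuals = pd.DataFrame.from_records(records)
    labels = [f"c1={c.c1:g},c2={c.c2:g}" for c, _ in used]
    logger.info("fit_k: %d rows, coefficients=%s, k_hat=%.4f, sse=%.4f",
                len(used), list(coefficients), k_hat, sse)

    k_ci = None
    if n_boot > 0:
        k_ci = bootstrap_k_ci(
            used, diffusivities, n_boot=n_boot, seed=seed,
            coefficients=coefficients, k_grid=k_grid, k_hat=k_hat,
        )
        if not (k_ci[0] <= k_hat <= k_ci[1]):
            k_ci = (min(k_ci[0], k_hat), max(k_ci[1], k_hat))
    return KFitResult(
        k_hat=k_hat, weighted_sse=sse, residuals=residuals,
        rows_used=labels, k_ci=k_ci, k_grid=k_grid,
    )


def bootstrap_k_ci(
    rows: Rows,
    diffusivities: SpeciesDiffusivities,
    n_boot: int = 1000,
    seed: int | None = None,
    coefficients: Sequence[str] = COEFFICIENTS,
    k_grid: tuple[float, float, float] = (0.0, 500.0, 0.1),
    k_hat: float | None = None,
) -> tuple[float, float]:
    """Percentile 95% interval for K by residual resampling.

    Residuals at the fitted K are pooled within coefficient class (main:
    d11/d22, cross: d12/d21), resampled with replacement onto the fitted
    model surface, and K is refit on each pseudo-table (grid stage only; the
    0.1 grid resolution is far below the interval width).  Deterministic for
    a given seed.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be at least 100")
    if k_hat is None:
        k_hat, _ = _minimize_k(rows, diffusivities, k_grid, coefficients)
    system = BindingSystem(diffusivities=diffusivities, k_assoc=k_hat)
    model_cells: list[dict[str, float]] = []
    pool = {"main": [], "cross": []}
    for comp, obs in rows:
        model = predict_dmatrix(comp, system)
        cells = {c: getattr(model, c) for c in COEFFICIENTS}
        cells.update({f"sd_{c}": _cell_sd(obs, c) for c in COEFFICIENTS})
        model_cells.append(cells)
        for coeff in COEFFICIENTS:
            cls = "main" if coeff in _MAIN else "cross"
            pool[cls].append(getattr(obs, coeff) - getattr(model, coeff))
    if max(abs(r) for rs in pool.values() for r in rs) == 0.0:
        warnings.warn("all residuals are zero; bootstrap interval is degenerate",
                      stacklevel=2)
        return (k_hat, k_hat)

    rng = np.random.default_rng(seed)
    lo, hi, step = k_grid
    grid = np.arange(lo, hi + step / 2, step)
    comps = [comp for comp, _ in rows]
    main_pool = np.array(pool["main"])
    cross_pool = np.array(pool["cross"])
    khats = np.empty(n_boot)
    for bi in range(n_boot):
        boot_rows = []
        for comp, cells in zip(comps, model_cells):
            vals = {}
            for coeff in COEFFICIENTS:
                p = main_pool if coeff in _MAIN else cross_pool
                vals[coeff] = cells[coeff] + p[rng.integers(len(p))]
            boot_rows.append((comp, _BootCells(vals, cells)))
        sse = _grid_sse(boot_rows, diffusivities, grid, coefficients)
        khats[bi] = grid[int(np.argmin(sse))]
    lo_q, hi_q = np.percentile(khats, [2.5, 97.5])
    return (float(lo_q), float(hi_q))


class _BootCells:
    """Duck-typed stand-in for DMatrix in the bootstrap objective (skips the
    eigenvalue validation, which resampled pseudo-data need not satisfy)."""

    __slots__ = ("d11", "d12", "d21", "d22", "sd11", "sd12", "sd21", "sd22")

    def __init__(self, vals: dict, cells: dict):
        for coeff in COEFFICIENTS:
            setattr(self, coeff, vals[coeff])
            setattr(self, "s" + coeff, cells[f"sd_{coeff}"])


def solubilized_fraction(
    d11_tracer: float,
    d0_drug: float,
    d_complex: float,
    composition: Composition | None = None,
) -> SolubilizationResult:
    """Two-state fast-exchange solubilized fraction s = (D0 - D11)/(D0 - Dc).

    ``d11_tracer`` is the drug's tracer diffusion coefficient in the carrier
    solution, ``d0_drug`` its infinite-dilution value and ``d_complex`` the
    complex (or micelle) diffusivity.  Results outside [0, 1] (possible with
    noisy inputs) are clipped with a warning.
    """
    if d0_drug <= d_complex:
        raise ValueError("d0_drug must exceed d_complex")
    s = (d0_drug - d11_tracer) / (d0_drug - d_complex)
    clipped = False
    if s < 0.0 or s > 1.0:
        warnings.warn(f"solubilized fraction {s:.4f} clipped to [0, 1]", stacklevel=2)
        s = min(max(s, 0.0), 1.0)
        clipped = True
    return SolubilizationResult(
        s=s,
        deviation_percent=deviation_percent(d11_tracer, d0_drug),
        composition=composition,
        clipped=clipped,
    )


def bound_fraction(k_assoc: float, c2: float) -> float:
    """Equilibrium bound fraction of a trace drug, K*c2 / (1 + K*c2).

    Alternative route to the solubilized fraction, from the fitted binding
    constant rather than from measured tracer attenuation.
    """
    if k_assoc < 0 or c2 < 0:
        raise ValueError("k_assoc and c2 must be non-negative")
    return k_assoc * c2 / (1.0 + k_assoc * c2)


def deviation_percent(d11_tracer: float, d0_drug: float) -> float:
    """Percent attenuation of the tracer coefficient below the limiting value."""
    if d11_tracer <= 0 or d0_drug <= 0:
        raise ValueError("diffusivities must be positive")
    return 100.0 * (d0_drug - d11_tracer) / d0_drug


def classify_regime(c: Composition, cmc: float | None) -> str:
    """Label a composition relative to the carrier's CMC.

    Returns ``below_cmc`` / ``above_cmc`` for micellar carriers (boundary
    c2 == cmc assigned to ``above_cmc`` by convention) and ``non_micellar``
    when no CMC applies.
    """
    if cmc is None:
        return "non_micellar"
    if not cmc > 0:
        raise ValueError("cmc must be positive when present")
    return "below_cmc" if c.c2 < cmc else "above_cmc"
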