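"""Synthetic experiments with the statistical structure the analysis assumes.

Two generators stand in for the laboratory instrument: noisy D-matrix tables
(forward model plus homoscedastic Gaussian noise per coefficient class, with
the reproducibility SDs of the real tables: 0.02e-9 m^2/s on the main
coefficients, 0.05e-9 on the cross coefficients) and raw detector traces
(two injections per composition through the virtual Taylor-dispersion
instrument).  Both are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .core_model import BindingSystem, Composition, DMatrix, predict_dmatrix
from .taylor_dispersion import (
    DispersionTrace,
    InstrumentGeometry,
    PeakFit,
    simulate_trace,
    weights_for_injection,
)

__all__ = [
    "SyntheticDesign",
    "TraceRecord",
    "generate_dtable",
    "generate_trace_set",
    "beta_cd_compositions",
    "sds_compositions",
]

#: reproducibility SDs of the tabulated coefficients, 1e-9 m^2 s^-1
NOISE_MAIN = 0.02
NOISE_CROSS = 0.05


def beta_cd_compositions() -> list[Composition]:
    """The seven-composition design of the drug + cyclodextrin study."""
    grid = [(0.000, 0.007), (0.0035, 0.0035), (0.007, 0.000), (0.000, 0.010),
            (0.012, 0.008), (0.018, 0.002), (0.020, 0.000)]
    return [Composition(c1, c2) for c1, c2 in grid]


def sds_compositions() -> list[Composition]:
    """The seven-composition design of the drug + surfactant study
    (four below the CMC of 0.0083 mol dm^-3, three above)."""
    grid = [(0.000, 0.004), (0.004, 0.000), (0.018, 0.002), (0.010, 0.000),
            (0.000, 0.020), (0.011, 0.009), (0.000, 0.050)]
    return [Composition(c1, c2) for c1, c2 in grid]


@dataclass(frozen=True)
class SyntheticDesign:
    """A virtual measurement campaign: composition grid, true system, noise."""

    compositions: Sequence[Composition] = field(default_factory=beta_cd_compositions)
    true_system: BindingSystem | None = None
    noise_main: float = NOISE_MAIN
    noise_cross: float = NOISE_CROSS
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.compositions:
            raise ValueError("compositions must be non-empty")
        if self.noise_main < 0 or self.noise_cross < 0:
            raise ValueError("noise SDs must be non-negative")
        if self.true_system is None:
            raise ValueError("a true BindingSystem is required")


def generate_dtable(design: SyntheticDesign) -> list[tuple[Composition, DMatrix]]:
    """Forward-model D-matrix table with per-class Gaussian noise.

    The SD columns of the output carry the class SDs actually used, so a
    downstream fit weights the cells exactly as the generator noised them.
    """
    rng = np.random.default_rng(design.seed)
    out = []
    for comp in design.compositions:
        m = predict_dmatrix(comp, design.true_system)
        e_main = rng.normal(0.0, design.noise_main, size=2) if design.noise_main else np.zeros(2)
        e_cross = rng.normal(0.0, design.noise_cross, size=2) if design.noise_cross else np.zeros(2)
        out.append(
            (
                comp,
                DMatrix(
                    d11=m.d11 + e_main[0],
                    d12=m.d12 + e_cross[0],
                    d21=m.d21 + e_cross[1],
                    d22=m.d22 + e_main[1],
                    sd11=design.noise_main,
                    sd12=design.noise_cross,
                    sd21=design.noise_cross,
                    sd22=design.noise_main,
                ),
            )
        )
    return out


@dataclass(frozen=True)
class TraceRecord:
    """One synthetic injection: the trace plus the ground truth behind it."""

    composition: Composition
    injection_excess: tuple[float, float]
    trace: DispersionTrace
    true_params: PeakFit
    true_dmatrix: DMatrix


def generate_trace_set(
    design: SyntheticDesign,
    geometry: InstrumentGeometry | None = None,
    sensitivity_ratio: float = 1.0,
    noise_sd: float = 0.0,
    seed: int | None = None,
    injection_excesses: tuple[tuple[float, float], tuple[float, float]] = (
        (0.002, 0.0),
        (0.0, 0.002),
    ),
) -> list[TraceRecord]:
    """Two dispersion traces per composition from the true system.

    Each composition's model D-matrix is eigendecomposed; the two injected
    excesses (linearly independent, by default one pure excess per component)
    set the mode weights a refractometer with the given sensitivity ratio
    would record.  Traces use the nominal retention time of the geometry.
    """
    u1, u2 = (np.asarray(u, float) for u in injection_excesses)
    if abs(np.linalg.det(np.column_stack([u1, u2]))) == 0.0:
        raise ValueError("injection excesses must be linearly independent")
    geometry = geometry or InstrumentGeometry()
    rng = np.random.default_rng(design.seed if seed is None else seed)
    records = []
    for comp in design.compositions:
        m = predict_dmatrix(comp, design.true_system)
        lam = m.eigenvalues()
        for u in injection_excesses:
            w1 = weights_for_injection(m, u, sensitivity_ratio)
            params = PeakFit(
                v0=0.0, v1=0.0, vmax=1.0,
                t_r=geometry.retention_time_nominal,
                w1=w1,
                d_eig1=float(lam[0]), d_eig2=float(lam[1]),
            )
            trace_seed = int(rng.integers(2**31 - 1))
            records.append(
                TraceRecord(
                    composition=comp,
                    injection_excess=tuple(u),
                    trace=simulate_trace(
                        params, geometry, noise_sd=noise_sd,
                        seed=trace_seed, injection_excess=tuple(u),
                    ),
                    true_params=params,
                    true_dmatrix=m,
                )
            )
    return records
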