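"""Equilibrium speciation and the coupled-diffusion forward model for 1:1 binding.

A drug (component 1) and a carrier (component 2, e.g. a cyclodextrin or a
surfactant micelle) form a 1:1 complex with association constant K.  Under the
fast-exchange, dilute-solution closure (the complex contributes no independent
cross-diffusion terms), the measurable 2x2 ternary mutual-diffusion matrix
D = [[D11, D12], [D21, D22]] is an explicit function of the composition, K and
the limiting diffusivities of the three species (free drug, free carrier,
complex).

Unit conventions used throughout the package, matching the tabulated data this
model is fitted to: diffusivities in 1e-9 m^2 s^-1, concentrations in
mol dm^-3, K in mol^-1 dm^3.  The math core never converts units.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import yaml

__all__ = [
    "SpeciesDiffusivities",
    "BindingSystem",
    "Composition",
    "Speciation",
    "DMatrix",
    "CountertransportResult",
    "solve_equilibrium",
    "r_factor",
    "predict_dmatrix",
    "complex_diffusivity_stokes_einstein",
    "countertransport_ratios",
    "load_binding_system",
]

#: slack used when checking physically motivated orderings of diffusivities
_D_ORDER_TOL = 1e-9


@dataclass(frozen=True)
class SpeciesDiffusivities:
    """Limiting diffusivities of the three species, in 1e-9 m^2 s^-1.

    ``d_drug_infinite_dilution`` is the literature infinite-dilution value of
    the drug (used by the solubilization estimators); it may exceed
    ``d_free_drug``, which is the binary value at the working concentration.
    """

    d_free_drug: float
    d_free_carrier: float
    d_complex: float
    d_drug_infinite_dilution: float | None = None

    def __post_init__(self) -> None:
        for name in ("d_free_drug", "d_free_carrier", "d_complex"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.d_complex > min(self.d_free_drug, self.d_free_carrier) + _D_ORDER_TOL:
            raise ValueError(
                "d_complex must not exceed the smaller free-species diffusivity "
                "(the complex is the largest, slowest species)"
            )
        if self.d_drug_infinite_dilution is not None:
            if not self.d_drug_infinite_dilution > 0:
                raise ValueError("d_drug_infinite_dilution must be positive")
            if self.d_drug_infinite_dilution < self.d_free_drug - _D_ORDER_TOL:
                raise ValueError(
                    "d_drug_infinite_dilution cannot be below d_free_drug"
                )


@dataclass(frozen=True)
class BindingSystem:
    """A 1:1 host-guest system: species diffusivities plus association constant.

    ``cmc`` (critical micelle concentration, mol dm^-3) is set for micellar
    carriers only; below the CMC the 'carrier' species of the model (the
    micelle) does not exist.
    """

    diffusivities: SpeciesDiffusivities
    k_assoc: float
    cmc: float | None = None
    stoichiometry: tuple[int, int] = (1, 1)

    def __post_init__(self) -> None:
        if self.k_assoc < 0:
            raise ValueError("k_assoc must be non-negative")
        if self.cmc is not None and not self.cmc > 0:
            raise ValueError("cmc must be positive when present")
        if tuple(self.stoichiometry) != (1, 1):
            raise ValueError("only 1:1 stoichiometry is supported")


@dataclass(frozen=True)
class Composition:
    """Total (analytical) concentrations of drug (c1) and carrier (c2)."""

    c1: float
    c2: float

    def __post_init__(self) -> None:
        if self.c1 < 0 or self.c2 < 0:
            raise ValueError("concentrations must be non-negative")
        if self.c1 + self.c2 <= 0:
            raise ValueError("at least one total concentration must be positive")

    @property
    def x1(self) -> float:
        """Drug solute mole fraction, c1 / (c1 + c2)."""
        return self.c1 / (self.c1 + self.c2)


@dataclass(frozen=True)
class Speciation:
    """Equilibrium concentrations of free drug, free carrier and complex."""

    free_drug: float
    free_carrier: float
    complex: float


@dataclass(frozen=True)
class DMatrix:
    """Ternary mutual-diffusion matrix with optional per-cell standard deviations.

    Main coefficients D11, D22 couple each component's flux to its own
    gradient; the cross coefficients D12, D21 carry the coupled flux.  A
    negative cross coefficient means counter-current coupled transport.
    """

    d11: float
    d12: float
    d21: float
    d22: float
    sd11: float | None = None
    sd12: float | None = None
    sd21: float | None = None
    sd22: float | None = None

    def __post_init__(self) -> None:
        if not (self.d11 > 0 and self.d22 > 0):
            raise ValueError("main diffusion coefficients must be positive")
        lam = self.eigenvalues()
        if np.iscomplexobj(lam) or not np.all(lam > 0):
            raise ValueError("diffusion matrix must have real positive eigenvalues")
        for name in ("sd11", "sd12", "sd21", "sd22"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be non-negative")

    def as_array(self) -> np.ndarray:
        return np.array([[self.d11, self.d12], [self.d21, self.d22]], dtype=float)

    def eigenvalues(self) -> np.ndarray:
        """Both eigenvalues, sorted descending; real when the matrix is physical."""
        a = np.array([[self.d11, self.d12], [self.d21, self.d22]], dtype=float)
        disc = (a[0, 0] - a[1, 1]) ** 2 + 4.0 * a[0, 1] * a[1, 0]
        if disc < 0:
            # complex pair -- returned as-is so validation can reject it
            return np.linalg.eigvals(a)
        s = math.sqrt(disc)
        tr = a[0, 0] + a[1, 1]
        return np.array([(tr + s) / 2.0, (tr - s) / 2.0])


def solve_equilibrium(c: Composition, k_assoc: float) -> Speciation:
    """Equilibrium speciation of the 1:1 binding equilibrium.

    Solves K (c1 - x)(c2 - x) = x for the complex concentration x, using the
    citardauq form of the quadratic root so that no subtractive cancellation
    occurs when K*c products are small (the common regime for weak binders).
    """
    if k_assoc < 0:
        raise ValueError("k_assoc must be non-negative")
    c1, c2 = c.c1, c.c2
    # K x^2 - (K(c1+c2)+1) x + K c1 c2 = 0; smaller root is the physical one.
    b = k_assoc * (c1 + c2) + 1.0
    disc = b * b - 4.0 * k_assoc * k_assoc * c1 * c2
    x = 2.0 * k_assoc * c1 * c2 / (b + math.sqrt(disc))
    return Speciation(free_drug=c1 - x, free_carrier=c2 - x, complex=x)


def r_factor(c: Composition, k_assoc: float) -> float:
    """Dimensionless equilibrium factor {[1 + K(c2-c1)]^2 + 4 K c1}^(-1/2).

    Equals 1 when K = 0 and decreases toward 0 as binding saturates; it
    controls how strongly complexation mixes the two diffusion modes.
    """
    if k_assoc < 0:
        raise ValueError("k_assoc must be non-negative")
    bracket = (1.0 + k_assoc * (c.c2 - c.c1)) ** 2 + 4.0 * k_assoc * c.c1
    return bracket ** -0.5


def predict_dmatrix(c: Composition, system: BindingSystem) -> DMatrix:
    """Forward model: composition + binding system -> ternary D-matrix.

    The closure neglects the complex's own cross terms (dilute solutions), so
    each measurable coefficient is an explicit combination of the free-drug,
    free-carrier and complex diffusivities weighted by the equilibrium factor.
    At K = 0 the matrix is exactly diagonal.
    """
    d = system.diffusivities
    dd, db, dc = d.d_free_drug, d.d_free_carrier, d.d_complex
    k = system.k_assoc
    r = r_factor(c, k)
    b = (1.0 - k * (c.c2 - c.c1)) * r
    return DMatrix(
        d11=0.5 * ((dd + dc) + (dd - dc) * b),
        d12=0.5 * ((dc - dd) + (dd - dc) * b),
        d21=0.5 * ((dc - db) + (db - dc) * b),
        d22=0.5 * ((db + dc) + (db - dc) * b),
    )


def complex_diffusivity_stokes_einstein(
    d_free_drug: float, d_free_carrier: float
) -> float:
    """Stokes-Einstein estimate of the 1:1 complex diffusivity.

    Each free species is assigned a hydrodynamic radius r_i proportional to
    1/D_i; the complex volume is taken as the sum of the partner volumes, and
    the composite radius is converted back: D = (D1^-3 + D2^-3)^(-1/3).
    Symmetric in its arguments and always below both inputs.
    """
    if d_free_drug <= 0 or d_free_carrier <= 0:
        raise ValueError("diffusivities must be strictly positive")
    return (d_free_drug ** -3 + d_free_carrier ** -3) ** (-1.0 / 3.0)


@dataclass(frozen=True)
class CountertransportResult:
    """Counter-transport diagnostics from a table of measured D-matrices.

    ``max_drug_per_carrier`` is max |D12|/D22 over rows with D12 < 0 (moles of
    drug counter-transported per mole of carrier); ``max_carrier_per_drug`` is
    max |D21|/D11 over rows with D21 < 0.  Per-row signed ratios are kept for
    both coefficients, co-current (positive) rows included.
    """

    max_drug_per_carrier: float
    max_carrier_per_drug: float
    ratios_12: list[float]
    ratios_21: list[float]


def countertransport_ratios(
    rows: Sequence[tuple[Composition, DMatrix]]
) -> CountertransportResult:
    """Maximum counter-current coupling ratios over a measured table.

    Only rows whose cross coefficient is negative (counter-current transport)
    enter the maxima; rows with positive cross terms are co-current and are
    reported in the per-row ratios only.
    """
    if not rows:
        raise ValueError("need at least one row")
    r12, r21 = [], []
    for _, m in rows:
        r12.append(m.d12 / m.d22)
        r21.append(m.d21 / m.d11)
    neg12 = [abs(r) for r in r12 if r < 0]
    neg21 = [abs(r) for r in r21 if r < 0]
    return CountertransportResult(
        max_drug_per_carrier=max(neg12) if neg12 else 0.0,
        max_carrier_per_drug=max(neg21) if neg21 else 0.0,
        ratios_12=r12,
        ratios_21=r21,
    )


def load_binding_system(path) -> BindingSystem:
    """Load a binding system from a YAML key/value file.

    Recognised keys: d_free_drug, d_free_carrier, d_complex,
    d_drug_infinite_dilution (optional), k_assoc, cmc (optional/null).
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: expected a mapping of keys to numbers")
    diff = SpeciesDiffusivities(
        d_free_drug=float(raw["d_free_drug"]),
        d_free_carrier=float(raw["d_free_carrier"]),
        d_complex=float(raw["d_complex"]),
        d_drug_infinite_dilution=(
            float(raw["d_drug_infinite_dilution"])
            if raw.get("d_drug_infinite_dilution") is not None
            else None
        ),
    )
    cmc = raw.get("cmc")
    return BindingSystem(
        diffusivities=diff,
        k_assoc=float(raw.get("k_assoc", 0.0)),
        cmc=float(cmc) if cmc is not None else None,
    )
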