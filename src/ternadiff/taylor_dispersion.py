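"""Virtual Taylor-dispersion instrument for ternary solutions.

A solute pulse injected into laminar tube flow disperses into a near-Gaussian
peak whose width encodes diffusivity.  For a ternary (two-solute) system the
detector trace is a two-mode profile

    V(t) = V0 + V1*t + Vmax*sqrt(tR/t) * [ W1*exp(-12*D1*(t-tR)^2/(r^2*t))
                                   + (1-W1)*exp(-12*D2*(t-tR)^2/(r^2*t)) ]

where D1 >= D2 are the eigenvalues of the 2x2 mutual-diffusion matrix, W1 is
the fraction of detector signal carried by the fast eigenmode, tR the mean
retention time and r the tube radius.  This module simulates such traces,
fits measured traces for the seven profile parameters, maps a D-matrix and an
injected concentration excess to the mode weight a refractometer would see,
and inverts paired injections back to the full D-matrix.

Diffusivities are in 1e-9 m^2 s^-1, tube dimensions in cm, time in s; the
unit bridge (1e-9 m^2 s^-1 = 1e-5 cm^2 s^-1) is applied inside the profile
evaluation only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import lmfit
import numpy as np

__all__ = [
    "InstrumentGeometry",
    "DispersionTrace",
    "PeakFit",
    "dispersion_profile",
    "simulate_trace",
    "fit_trace",
    "weights_for_injection",
    "assemble_dmatrix",
    "read_trace",
    "write_trace",
]

#: (1e-9 m^2 s^-1) expressed in cm^2 s^-1
_D_UNIT_CM2_S = 1.0e-5


@dataclass(frozen=True)
class InstrumentGeometry:
    """Dispersion-tube geometry and sampling of the detector.

    Defaults reproduce a typical laboratory setup: a 3048.0 cm Teflon
    capillary of internal radius 0.03220 cm, 0.063 cm^3 injections and a
    refractometer read every 5 s.
    """

    tube_length: float = 3048.0
    tube_radius: float = 0.03220
    injection_volume: float = 0.063
    sampling_interval: float = 5.0
    retention_time_nominal: float = 7000.0

    def __post_init__(self) -> None:
        for name in (
            "tube_length",
            "tube_radius",
            "injection_volume",
            "sampling_interval",
            "retention_time_nominal",
        ):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")

    @property
    def aspect_ratio(self) -> float:
        return self.tube_length / self.tube_radius


@dataclass(frozen=True)
class PeakFit:
    """Parameters of the two-mode dispersion profile (and, after fitting,
    their recovered values).

    ``w1`` is the signal weight of the mode with the larger eigenvalue
    ``d_eig1``; eigenvalues are reported sorted descending, which fixes the
    label-exchange ambiguity of the profile.  ``w1`` is not confined to
    [0, 1]: counter-current coupled transport puts a small negative amplitude
    on one eigenmode (the mode weights still sum to 1).  ``stderr`` maps
    parameter names to least-squares standard errors when the object comes
    from a fit.
    """

    v0: float = 0.0
    v1: float = 0.0
    vmax: float = 1.0
    t_r: float = 7000.0
    w1: float = 1.0
    d_eig1: float = 1.0
    d_eig2: float = 0.5
    residual_rms: float | None = None
    stderr: dict | None = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.w1):
            raise ValueError("w1 must be finite")
        if not (self.d_eig1 > 0 and self.d_eig2 > 0):
            raise ValueError("eigenvalue diffusivities must be positive")
        if not self.t_r > 0:
            raise ValueError("t_r must be positive")


@dataclass(frozen=True)
class DispersionTrace:
    """A detector record: uniform time grid, voltages, geometry, injection."""

    times: np.ndarray
    voltages: np.ndarray
    geometry: InstrumentGeometry
    injection_excess: tuple[float, float] = (0.0, 0.0)
    seed: int | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.voltages, dtype=float)
        if t.ndim != 1 or t.shape != v.shape:
            raise ValueError("times and voltages must be 1-D arrays of equal length")
        if len(t) < 2:
            raise ValueError("trace must contain at least two samples")
        dt = np.diff(t)
        if np.any(dt <= 0):
            raise ValueError("times must be strictly increasing")
        if np.max(np.abs(dt - dt[0])) > 1e-9 * max(1.0, abs(dt[0])):
            raise ValueError("times must be uniformly spaced")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "voltages", v)


def dispersion_profile(
    t: np.ndarray,
    v0: float,
    v1: float,
    vmax: float,
    t_r: float,
    w1: float,
    d_eig1: float,
    d_eig2: float,
    tube_radius: float,
) -> np.ndarray:
    """Evaluate the two-mode dispersion profile on a time grid (t > 0)."""
    t = np.asarray(t, dtype=float)
    if np.any(t <= 0):
        raise ValueError("profile is defined for t > 0 only")
    r2 = tube_radius * tube_radius
    arg = (t - t_r) ** 2 / (r2 * t)
    mode1 = np.exp(-12.0 * d_eig1 * _D_UNIT_CM2_S * arg)
    mode2 = np.exp(-12.0 * d_eig2 * _D_UNIT_CM2_S * arg)
    return v0 + v1 * t + vmax * np.sqrt(t_r / t) * (w1 * mode1 + (1.0 - w1) * mode2)


def _default_window(params: PeakFit, geometry: InstrumentGeometry) -> tuple[float, float]:
    # cover +-6 sigma of the slower (wider) mode, clipped to positive times
    d_slow = min(params.d_eig1, params.d_eig2)
    sigma = math.sqrt(
        geometry.tube_radius ** 2 * params.t_r / (24.0 * d_slow * _D_UNIT_CM2_S)
    )
    half = min(0.85 * params.t_r, 6.0 * sigma + 20.0 * geometry.sampling_interval)
    return params.t_r - half, params.t_r + half


def simulate_trace(
    fit_params: PeakFit,
    geometry: InstrumentGeometry | None = None,
    noise_sd: float = 0.0,
    seed: int | None = None,
    injection_excess: tuple[float, float] = (0.0, 0.0),
    window: tuple[float, float] | None = None,
) -> DispersionTrace:
    """Synthesize a detector trace: exact profile plus i.i.d. Gaussian noise.

    The time grid is uniform at the geometry's sampling interval, spanning
    ``window`` (default: +-6 sigma of the slower mode around the retention
    time).  The seed is stored on the returned trace.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    geometry = geometry or InstrumentGeometry()
    lo, hi = window if window is not None else _default_window(fit_params, geometry)
    if lo <= 0:
        raise ValueError("time window must be strictly positive")
    n = int(math.floor((hi - lo) / geometry.sampling_interval)) + 1
    t = lo + geometry.sampling_interval * np.arange(n)
    v = dispersion_profile(
        t,
        fit_params.v0,
        fit_params.v1,
        fit_params.vmax,
        fit_params.t_r,
        fit_params.w1,
        fit_params.d_eig1,
        fit_params.d_eig2,
        geometry.tube_radius,
    )
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        v = v + rng.normal(0.0, noise_sd, size=v.shape)
    return DispersionTrace(
        times=t,
        voltages=v,
        geometry=geometry,
        injection_excess=tuple(injection_excess),
        seed=seed,
    )


def _moment_init(trace: DispersionTrace) -> PeakFit:
    """Initial parameter guess: baseline from the trace edges, retention time
    from the peak maximum, diffusivity scale from the second moment."""
    t, v = trace.times, trace.voltages
    n_edge = max(3, len(t) // 20)
    edge_t = np.concatenate([t[:n_edge], t[-n_edge:]])
    edge_v = np.concatenate([v[:n_edge], v[-n_edge:]])
    slope, intercept = np.polyfit(edge_t, edge_v, 1)
    y = v - (intercept + slope * t)
    i_max = int(np.argmax(y))
    t_r = t[i_max]
    vmax = y[i_max]
    y_pos = np.clip(y, 0.0, None)
    area = np.trapezoid(y_pos, t)
    var = np.trapezoid((t - t_r) ** 2 * y_pos, t) / area if area > 0 else 1.0
    r2 = trace.geometry.tube_radius ** 2
    d_est = r2 * t_r / (24.0 * max(var, 1e-12)) / _D_UNIT_CM2_S
    d_est = float(np.clip(d_est, 1e-4, 1e3))
    return PeakFit(
        v0=float(intercept),
        v1=float(slope),
        vmax=float(vmax),
        t_r=float(t_r),
        w1=0.5,
        d_eig1=2.0 * d_est,
        d_eig2=0.5 * d_est,
    )


class TraceFitError(RuntimeError):
    """Raised when the dispersion-profile fit fails to converge."""


def fit_trace(
    trace: DispersionTrace,
    init: PeakFit | None = None,
    max_restarts: int = 7,
) -> PeakFit:
    """Nonlinear least-squares fit of the two-mode profile (all 7 parameters).

    W1 is kept in a generous band around [0, 1] (coupled ternary systems
    genuinely need small negative mode amplitudes) and both eigenvalues stay
    positive.  On poor
    convergence the diffusivity starting values are perturbed and the fit
    restarted (bounded multi-start).  Eigenvalues in the result are sorted
    descending, with w1 attached to the larger one.
    """
    if init is None:
        init = _moment_init(trace)
    radius = trace.geometry.tube_radius
    t, v = trace.times, trace.voltages

    def residual(params: lmfit.Parameters) -> np.ndarray:
        p = params.valuesdict()
        model = dispersion_profile(
            t, p["v0"], p["v1"], p["vmax"], p["t_r"], p["w1"],
            p["d_eig1"], p["d_eig2"], radius,
        )
        return model - v

    vscale = max(abs(init.vmax), np.ptp(v), 1e-12)
    best = None
    # (w1 start, factor on d_eig1, factor on d_eig2): the starts cover both
    # mode-dominance extremes, including small negative amplitudes from
    # counter-current coupling
    d_ref = math.sqrt(init.d_eig1 * init.d_eig2)
    starts = [
        (init.w1, init.d_eig1, init.d_eig2),
        (0.9, 1.5 * d_ref, 0.75 * d_ref),
        (0.1, 1.5 * d_ref, 0.75 * d_ref),
        (-0.05, 2.5 * d_ref, 1.0 * d_ref),
        (1.05, 1.0 * d_ref, 0.4 * d_ref),
        (-0.5, 3.0 * d_ref, 1.0 * d_ref),
        (1.5, 1.0 * d_ref, 0.3 * d_ref),
        (0.5, 4.0 * d_ref, 0.25 * d_ref),
    ][: max_restarts + 1]
    for w_init, d1_init, d2_init in starts:
        params = lmfit.Parameters()
        params.add("v0", value=init.v0)
        params.add("v1", value=init.v1)
        params.add("vmax", value=init.vmax)
        params.add("t_r", value=init.t_r, min=t[0] * 0.5, max=t[-1] * 1.5)
        params.add("w1", value=min(max(w_init, -1.9), 2.9), min=-2.0, max=3.0)
        params.add("d_eig1", value=d1_init, min=1e-6)
        params.add("d_eig2", value=d2_init, min=1e-6)
        try:
            out = lmfit.minimize(residual, params, method="leastsq",
                                 xtol=1e-12, ftol=1e-12)
        except Exception:  # noqa: BLE001 - treat solver blowups as a restart
            continue
        rms = float(np.sqrt(np.mean(out.residual ** 2)))
        if best is None or rms < best[0]:
            best = (rms, out)
        if rms < 1e-8 * vscale:
            break
    if best is None:
        raise TraceFitError("dispersion-profile fit failed on every restart")
    rms, out = best
    p = out.params.valuesdict()
    stderr = {
        name: (out.params[name].stderr if out.params[name].stderr is not None else None)
        for name in out.params
    }
    d1, d2, w1 = p["d_eig1"], p["d_eig2"], p["w1"]
    if d1 < d2:  # canonical ordering: mode 1 is the faster eigenmode
        d1, d2, w1 = d2, d1, 1.0 - w1
        stderr["d_eig1"], stderr["d_eig2"] = stderr["d_eig2"], stderr["d_eig1"]
    return PeakFit(
        v0=p["v0"], v1=p["v1"], vmax=p["vmax"], t_r=p["t_r"],
        w1=w1, d_eig1=d1, d_eig2=d2,
        residual_rms=rms, stderr=stderr,
    )


def _eigensystem(dmat) -> tuple[np.ndarray, np.ndarray]:
    """Eigenvalues (descending) and column eigenvectors of a 2x2 D-matrix."""
    a = dmat.as_array() if hasattr(dmat, "as_array") else np.asarray(dmat, float)
    lam, vecs = np.linalg.eig(a)
    if np.iscomplexobj(lam) and np.max(np.abs(lam.imag)) > 1e-12 * np.max(np.abs(lam)):
        raise ValueError("diffusion matrix has complex eigenvalues")
    lam = lam.real
    vecs = vecs.real
    order = np.argsort(lam)[::-1]
    lam, vecs = lam[order], vecs[:, order]
    if abs(lam[0] - lam[1]) <= 1e-10 * max(abs(lam[0]), 1.0):
        raise ValueError(
            "eigenvalues coincide; treat the system as binary (single-mode profile)"
        )
    if abs(np.linalg.det(vecs)) < 1e-12:
        raise ValueError("diffusion matrix is defective (not diagonalizable)")
    return lam, vecs


def weights_for_injection(
    dmat,
    injection_excess: tuple[float, float],
    sensitivity_ratio: float = 1.0,
) -> float:
    """Signal weight of the fast eigenmode for a given injected excess.

    The injected excess (dC1, dC2) is decomposed onto the eigenmodes of the
    diffusion matrix; each mode's amplitude is projected onto the detector
    sensitivity vector (1, sensitivity_ratio).  Returns the normalized weight
    of the mode with the larger eigenvalue; the two mode weights sum to 1.
    """
    lam, vecs = _eigensystem(dmat)
    u = np.asarray(injection_excess, dtype=float)
    s = np.array([1.0, sensitivity_ratio])
    total = float(s @ u)
    if abs(total) < 1e-15 * max(1.0, float(np.max(np.abs(u)))):
        raise ValueError("injected excess is invisible to the detector")
    alpha = np.linalg.solve(vecs, u)
    amp = (s @ vecs) * alpha  # detector amplitude per mode
    return float(amp[0] / total)


class AssemblyError(RuntimeError):
    """Raised when paired injections cannot be inverted to a D-matrix."""


def _pool_eigenvalues(
    fits: Sequence[PeakFit], min_weight: float = 0.02, n_sd: float = 3.0
) -> tuple[float, float, list[float]]:
    """Match eigenmodes across fits and pool their eigenvalues.

    A fit's mode labels say nothing about which *physical* eigenmode it saw:
    a trace dominated by the slow mode yields a near-single-mode fit whose
    heavy component is the slow eigenvalue.  Modes are therefore matched by
    eigenvalue proximity: significant components (weight > ``min_weight``)
    are split at the largest relative gap into a fast and a slow cluster.
    Within a cluster, estimates from different fits must agree within
    ``n_sd`` standard errors (fallback 1% relative).  Returns the pooled
    (lam_fast, lam_slow) and each fit's total weight on the fast cluster.
    """
    comps = []  # (d, weight, fit index, stderr or None)
    for i, f in enumerate(fits):
        e1 = e2 = None
        if f.stderr is not None:
            e1, e2 = f.stderr.get("d_eig1"), f.stderr.get("d_eig2")
        comps.append((f.d_eig1, f.w1, i, e1))
        comps.append((f.d_eig2, 1.0 - f.w1, i, e2))
    # prefer well-determined components; if they all sit on one eigenvalue
    # (detector nearly blind to a mode), fall back to the faint components
    sig: list = []
    gaps: list = []
    for threshold in (min_weight, 1e-9):
        sig = sorted(c for c in comps if abs(c[1]) > threshold)
        gaps = [sig[j + 1][0] / sig[j][0] for j in range(len(sig) - 1)]
        if gaps and max(gaps) >= 1.01:
            break
    if not gaps or max(gaps) < 1.01:
        raise AssemblyError(
            "only one distinct eigenvalue is visible across the two injections; "
            "treat the system as binary (single-mode profile)"
        )
    split = int(np.argmax(gaps)) + 1
    slow, fast = sig[:split], sig[split:]
    pooled = []
    for cluster in (fast, slow):
        ds = np.array([c[0] for c in cluster])
        ws = np.abs([c[1] for c in cluster])
        by_fit: dict[int, tuple[float, float]] = {}
        for d, w, i, err in cluster:
            sd = float(err) if err else 0.01 * abs(d)
            if i not in by_fit or abs(w) > by_fit[i][2]:
                by_fit[i] = (d, sd, abs(w))
        if len(by_fit) == 2:
            (da, sa, _), (db, sb, _) = by_fit.values()
            if abs(da - db) > max(n_sd * max(sa, sb), 0.01 * (abs(da) + abs(db)) / 2):
                raise AssemblyError(
                    f"inconsistent eigenvalue estimates between injections: {da} vs {db}"
                )
        pooled.append(float(np.sum(ws * ds) / np.sum(ws)))
    lam1, lam2 = pooled
    # fast-cluster weight per fit; insignificant components join the nearest cluster
    w_fast = []
    for i, f in enumerate(fits):
        total = 0.0
        for d, w, j, _ in comps:
            if j != i:
                continue
            if abs(d - lam1) <= abs(d - lam2):
                total += w
        w_fast.append(total)
    return lam1, lam2, w_fast


def assemble_dmatrix(
    fits: Sequence[PeakFit],
    injection_excesses: Sequence[tuple[float, float]],
    sensitivity_ratio: float = 1.0,
):
    """Invert two fitted injections into the unique ternary D-matrix.

    The matrix is written as D = lam2*I + (lam1-lam2)*Q with Q the rank-1
    spectral projector of the fast mode.  Each measured weight supplies one
    linear constraint s^T Q u = w1 * s^T u; the idempotency of Q closes the
    system.  With the canonical pure-component injection pair the solution is
    unique; for general independent excesses a quadratic may admit two
    projectors, and the one with the smaller off-diagonal norm is returned
    (deterministic tie-break).
    """
    from .core_model import DMatrix  # local import to avoid a cycle

    if len(fits) != 2 or len(injection_excesses) != 2:
        raise ValueError("exactly two fits and two injection excesses required")
    u1 = np.asarray(injection_excesses[0], dtype=float)
    u2 = np.asarray(injection_excesses[1], dtype=float)
    rho = sensitivity_ratio
    s = np.array([1.0, rho])

    axis1 = u1[1] == 0 and u2[1] == 0 and u1[0] != 0 and u2[0] != 0
    axis2 = u1[0] == 0 and u2[0] == 0 and u1[1] != 0 and u2[1] != 0
    if axis1 or axis2:
        # binary experiment: only one component ever injected, so the traces
        # carry no coupling information and the off-diagonals are zero by
        # construction; the detected (weighted) mode belongs to the injected
        # component, the other diagonal falls back to the residual mode
        w1s = np.abs([f.w1 for f in fits])
        d1s = np.array([f.d_eig1 for f in fits])
        d2s = np.array([f.d_eig2 for f in fits])
        seen = float(np.sum(w1s * d1s) / np.sum(w1s)) if np.sum(w1s) > 0 else float(np.mean(d1s))
        w2s = np.abs(1.0 - w1s)
        other = float(np.sum(w2s * d2s) / np.sum(w2s)) if np.sum(w2s) > 0 else float(np.mean(d2s))
        if axis1:
            return DMatrix(d11=seen, d12=0.0, d21=0.0, d22=other)
        return DMatrix(d11=other, d12=0.0, d21=0.0, d22=seen)
    lam1, lam2, w_fast = _pool_eigenvalues(fits)
    if abs(np.linalg.det(np.column_stack([u1, u2]))) < 1e-15 * max(
        1.0, float(np.max(np.abs([u1, u2])))
    ):
        raise AssemblyError("injection excesses are linearly dependent")

    w = np.array(w_fast)
    # Q = [[a, b], [c, 1-a]]; per injection: s^T Q u = w * s^T u
    #   a*u0 + b*u1 + rho*(c*u0 + (1-a)*u1) = w*(u0 + rho*u1)
    # => b*u1 + rho*c*u0 = w*(u0+rho*u1) - a*u0 - rho*(1-a)*u1  (affine in a)
    m = np.array([[u1[1], rho * u1[0]], [u2[1], rho * u2[0]]])
    if abs(np.linalg.det(m)) < 1e-15:
        raise AssemblyError(
            "degenerate detector geometry (cannot separate the off-diagonals); "
            "use pure-component injections or a nonzero sensitivity ratio"
        )
    h0 = np.array(
        [
            w[0] * (u1[0] + rho * u1[1]) - rho * u1[1],
            w[1] * (u2[0] + rho * u2[1]) - rho * u2[1],
        ]
    )
    h1 = np.array([-u1[0] + rho * u1[1], -u2[0] + rho * u2[1]])
    bc0 = np.linalg.solve(m, h0)  # (b, c) at a = 0
    bc1 = np.linalg.solve(m, h1)  # d(b, c)/da
    beta0, gamma0 = bc0
    beta1, gamma1 = bc1
    # idempotency: a - a^2 = (beta0+beta1*a)(gamma0+gamma1*a)
    qa = -1.0 - beta1 * gamma1
    qb = 1.0 - beta0 * gamma1 - beta1 * gamma0
    qc = -beta0 * gamma0
    if abs(qa) < 1e-13 * max(abs(qb), abs(qc), 1.0):
        if qb == 0:
            raise AssemblyError("no solution for the spectral projector")
        roots = [-qc / qb]
    else:
        disc = qb * qb - 4.0 * qa * qc
        if disc < 0:
            raise AssemblyError("no real solution for the spectral projector")
        sq = math.sqrt(disc)
        roots = [(-qb + sq) / (2.0 * qa), (-qb - sq) / (2.0 * qa)]
    candidates = []
    for a in roots:
        b = beta0 + beta1 * a
        cc = gamma0 + gamma1 * a
        q = np.array([[a, b], [cc, 1.0 - a]])
        d = lam2 * np.eye(2) + (lam1 - lam2) * q
        candidates.append(d)
    candidates.sort(key=lambda d: abs(d[0, 1]) + abs(d[1, 0]))
    d = candidates[0]
    return DMatrix(d11=d[0, 0], d12=d[0, 1], d21=d[1, 0], d22=d[1, 1])


# ---------------------------------------------------------------------------
# trace serialization: two-column CSV with a '#' metadata header


def write_trace(trace: DispersionTrace, path) -> None:
    """Write a trace as CSV with geometry/injection metadata in '#' comments."""
    g = trace.geometry
    lines = [
        f"# tube_length={g.tube_length}",
        f"# tube_radius={g.tube_radius}",
        f"# injection_volume={g.injection_volume}",
        f"# sampling_interval={g.sampling_interval}",
        f"# retention_time_nominal={g.retention_time_nominal}",
        f"# injection_excess_c1={trace.injection_excess[0]}",
        f"# injection_excess_c2={trace.injection_excess[1]}",
        f"# seed={'' if trace.seed is None else trace.seed}",
        "time_s,voltage",
    ]
    body = [f"{t:.10g},{v:.12g}" for t, v in zip(trace.times, trace.voltages)]
    with open(path, "w") as fh:
        fh.write("\n".join(lines + body) + "\n")


def read_trace(path) -> DispersionTrace:
    """Read a trace written by :func:`write_trace`."""
    meta: dict[str, str] = {}
    times, volts = [], []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                key, _, val = line[1:].strip().partition("=")
                meta[key.strip()] = val.strip()
            elif line.startswith("time_s"):
                continue
            else:
                a, b = line.split(",")
                times.append(float(a))
                volts.append(float(b))
    geometry = InstrumentGeometry(
        tube_length=float(meta.get("tube_length", 3048.0)),
        tube_radius=float(meta.get("tube_radius", 0.03220)),
        injection_volume=float(meta.get("injection_volume", 0.063)),
        sampling_interval=float(meta.get("sampling_interval", 5.0)),
        retention_time_nominal=float(meta.get("retention_time_nominal", 7000.0)),
    )
    seed = meta.get("seed") or None
    return DispersionTrace(
        times=np.array(times),
        voltages=np.array(volts),
        geometry=geometry,
        injection_excess=(
            float(meta.get("injection_excess_c1", 0.0)),
            float(meta.get("injection_excess_c2", 0.0)),
        ),
        seed=int(seed) if seed is not None else None,
    )
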