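"""Table serialization, run configuration and case-study reports.

D-matrix tables travel as CSV with the header
``c1,c2,x1,d11,sd11,d12,sd12,d21,sd21,d22,sd22``; the mole fraction column is
redundant and is validated against the concentrations on read.  Two packaged
fixture tables (a drug + cyclodextrin study and a drug + surfactant study,
with their species-diffusivity configs) let every stage run without any
external data.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .core_model import (
    BindingSystem,
    Composition,
    DMatrix,
    countertransport_ratios,
    load_binding_system,
)
from .inference import (
    COEFFICIENTS,
    bound_fraction,
    classify_regime,
    fit_k,
    solubilized_fraction,
)

__all__ = [
    "TABLE_COLUMNS",
    "read_dtable",
    "write_dtable",
    "packaged_path",
    "RunConfig",
    "run_case_study",
]

logger = logging.getLogger(__name__)

TABLE_COLUMNS = [
    "c1", "c2", "x1",
    "d11", "sd11", "d12", "sd12", "d21", "sd21", "d22", "sd22",
]

Rows = list[tuple[Composition, DMatrix]]


class TableParseError(ValueError):
    """Raised when a D-matrix table file is malformed."""


def packaged_path(name: str) -> Path:
    """Filesystem path of a packaged fixture file (CSV table or YAML config)."""
    return Path(resources.files("ternadiff.data") / name)


def read_dtable(path, x1_tol: float = 1e-3) -> Rows:
    """Read and validate a ternary D-matrix table.

    Every row must parse numerically, have non-negative concentrations and an
    x1 consistent with c1/(c1+c2) within ``x1_tol``; violations raise
    :class:`TableParseError` naming the offending line.
    """
    try:
        df = pd.read_csv(path, comment="#")
    except pd.errors.EmptyDataError as exc:
        raise TableParseError(f"{path}: empty table") from exc
    missing = [c for c in TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise TableParseError(f"{path}: missing columns {missing}")
    if df.empty:
        raise TableParseError(f"{path}: no data rows")
    rows: Rows = []
    for idx, rec in df.iterrows():
        line_no = idx + 2  # header is line 1
        vals = {}
        for col in TABLE_COLUMNS:
            v = pd.to_numeric(rec[col], errors="coerce")
            if pd.isna(v):
                raise TableParseError(
                    f"{path}, line {line_no}: non-numeric value in column {col!r}"
                )
            vals[col] = float(v)
        if vals["c1"] < 0 or vals["c2"] < 0:
            raise TableParseError(f"{path}, line {line_no}: negative concentration")
        try:
            comp = Composition(vals["c1"], vals["c2"])
        except ValueError as exc:
            raise TableParseError(f"{path}, line {line_no}: {exc}") from exc
        if abs(comp.x1 - vals["x1"]) > x1_tol:
            raise TableParseError(
                f"{path}, line {line_no}: x1={vals['x1']} inconsistent with "
                f"c1/(c1+c2)={comp.x1:.6f}"
            )
        try:
            mat = DMatrix(
                d11=vals["d11"], d12=vals["d12"], d21=vals["d21"], d22=vals["d22"],
                sd11=vals["sd11"], sd12=vals["sd12"],
                sd21=vals["sd21"], sd22=vals["sd22"],
            )
        except ValueError as exc:
            raise TableParseError(f"{path}, line {line_no}: {exc}") from exc
        rows.append((comp, mat))
    return rows


def write_dtable(rows: Rows, path) -> None:
    """Write rows in the canonical table format (full float precision)."""
    records = []
    for comp, m in rows:
        records.append(
            {
                "c1": comp.c1, "c2": comp.c2, "x1": comp.x1,
                "d11": m.d11, "sd11": m.sd11 if m.sd11 is not None else 0.0,
                "d12": m.d12, "sd12": m.sd12 if m.sd12 is not None else 0.0,
                "d21": m.d21, "sd21": m.sd21 if m.sd21 is not None else 0.0,
                "d22": m.d22, "sd22": m.sd22 if m.sd22 is not None else 0.0,
            }
        )
    pd.DataFrame.from_records(records, columns=TABLE_COLUMNS).to_csv(
        path, index=False, float_format="%.12g"
    )


@dataclass(frozen=True)
class RunConfig:
    """Configuration of a full case study."""

    system: str
    table: str
    species: str
    regime: str = "auto"  # auto | all | above_cmc | below_cmc
    coefficients: tuple[str, ...] = COEFFICIENTS
    k_grid: tuple[float, float, float] = (0.0, 500.0, 0.1)
    n_boot: int = 1000
    seed: int = 0
    outdir: str | None = None

    def __post_init__(self) -> None:
        lo, hi, step = self.k_grid
        if not (lo < hi and step > 0):
            raise ValueError("k_grid bounds must satisfy lo < hi with step > 0")
        if self.regime not in {"auto", "all", "above_cmc", "below_cmc"}:
            raise ValueError(f"unknown regime {self.regime!r}")
        for p, what in [(self.table, "table"), (self.species, "species")]:
            if not Path(p).exists():
                raise FileNotFoundError(f"{what} file not found: {p}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        kwargs = dict(raw)
        if "coefficients" in kwargs:
            kwargs["coefficients"] = tuple(kwargs["coefficients"])
        if "k_grid" in kwargs:
            kwargs["k_grid"] = tuple(kwargs["k_grid"])
        return cls(**kwargs)

    def digest(self) -> str:
        payload = {
            "system": self.system, "table": self.table, "species": self.species,
            "regime": self.regime, "coefficients": list(self.coefficients),
            "k_grid": list(self.k_grid), "n_boot": self.n_boot, "seed": self.seed,
        }
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:16]


def run_case_study(config: RunConfig) -> dict:
    """Full pipeline on one system: regime classification, K fit,
    counter-transport diagnostics and solubilized fractions.

    Returns the report as a dict; when ``config.outdir`` is set, writes
    ``<system>_report.json`` and ``<system>_report.md`` (byte-identical
    across runs with the same config and seed).
    """
    system = load_binding_system(config.species)
    rows = read_dtable(config.table)
    regimes = [classify_regime(c, system.cmc) for c, _ in rows]
    logger.info("case study %s: %d rows, regimes=%s", config.system, len(rows), regimes)

    if config.regime == "auto":
        fit_regime = "above_cmc" if system.cmc is not None else "all"
    else:
        fit_regime = config.regime
    if fit_regime == "all":
        regime_filter = None
    else:
        regime_filter = lambda c: classify_regime(c, system.cmc) == fit_regime  # noqa: E731

    result = fit_k(
        rows,
        system.diffusivities,
        regime_filter=regime_filter,
        coefficients=config.coefficients,
        k_grid=config.k_grid,
        n_boot=config.n_boot,
        seed=config.seed,
    )
    logger.info("case study %s: k_hat=%.3f ci=%s rows_used=%s",
                config.system, result.k_hat, result.k_ci, result.rows_used)

    ct_rows = (
        [(c, m) for (c, m), r in zip(rows, regimes) if r != "below_cmc"]
        if system.cmc is not None
        else rows
    )
    ct = countertransport_ratios(ct_rows)

    d0 = system.diffusivities.d_drug_infinite_dilution
    d0 = d0 if d0 is not None else system.diffusivities.d_free_drug
    solub = []
    for (c, m), regime in zip(rows, regimes):
        if c.c1 != 0.0 or regime == "below_cmc":
            continue  # tracer rows only; micellar carrier must exist
        res = solubilized_fraction(m.d11, d0, system.diffusivities.d_complex, c)
        solub.append(
            {
                "c2": c.c2,
                "d11_tracer": m.d11,
                "s": round(res.s, 6),
                "deviation_percent": round(res.deviation_percent, 4),
                "bound_fraction_from_k": round(bound_fraction(result.k_hat, c.c2), 6),
            }
        )

    report = {
        "package_version": __version__,
        "config_digest": config.digest(),
        "system": config.system,
        "seed": config.seed,
        "rows": len(rows),
        "regimes": regimes,
        "k_fit": {
            "k_hat": round(result.k_hat, 6),
            "k_ci95": [round(v, 6) for v in result.k_ci] if result.k_ci else None,
            "weighted_sse": round(result.weighted_sse, 6),
            "rows_used": result.rows_used,
            "coefficients": list(config.coefficients),
        },
        "countertransport": {
            "max_drug_per_carrier": round(ct.max_drug_per_carrier, 6),
            "max_carrier_per_drug": round(ct.max_carrier_per_drug, 6),
            "ratios_d12_over_d22": [round(r, 6) for r in ct.ratios_12],
            "ratios_d21_over_d11": [round(r, 6) for r in ct.ratios_21],
        },
        "solubilization": solub,
    }

    if config.outdir is not None:
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        stem = config.system.replace(" ", "_")
        with open(outdir / f"{stem}_report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
            fh.write("\n")
        (outdir / f"{stem}_report.md").write_text(_markdown_report(report))
    return report


def _markdown_report(report: dict) -> str:
    k = report["k_fit"]
    ct = report["countertransport"]
    lines = [
        f"# Case study: {report['system']}",
        "",
        f"- package version: {report['package_version']}",
        f"- config digest: {report['config_digest']}",
        f"- seed: {report['seed']}",
        f"- rows: {report['rows']} (regimes: {', '.join(report['regimes'])})",
        "",
        "## Association constant",
        "",
        f"- K = {k['k_hat']} mol^-1 dm^3"
        + (f" (95% CI {k['k_ci95'][0]} - {k['k_ci95'][1]})" if k["k_ci95"] else ""),
        f"- weighted SSE = {k['weighted_sse']} over {len(k['rows_used'])} rows",
        f"- coefficients fitted: {', '.join(k['coefficients'])}",
        "",
        "## Counter-transport maxima",
        "",
        f"- max |D12|/D22 (mol drug per mol carrier): {ct['max_drug_per_carrier']}",
        f"- max |D21|/D11 (mol carrier per mol drug): {ct['max_carrier_per_drug']}",
        "",
        "## Solubilized fractions (tracer rows)",
        "",
        "| c2 (mol dm^-3) | D11 tracer | s (fast exchange) | deviation % | K c2/(1+K c2) |",
        "|---|---|---|---|---|",
    ]
    for row in report["solubilization"]:
        lines.append(
            f"| {row['c2']} | {row['d11_tracer']} | {row['s']} "
            f"| {row['deviation_percent']} | {row['bound_fraction_from_k']} |"
        )
    return "\n".join(lines) + "\n"
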