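"""Three-way preprocessing comparison: zero order vs GS vs SBSF derivatives.

For every component and every preprocessing method the pipeline runs

    load/simulate -> trim raw regions -> average replicates
    -> first derivative (GS/SBSF only) -> method-specific interval trim
    -> mean-centered latent-variable LOOCV -> PC selection

and records RMSECV (mg/g), R^2 and the chosen latent-variable count in a
:class:`ComparisonReport` -- the same grid shape the published study reports.
Raw spectra are always trimmed to the zero-order intervals first (removing
the saturated UV end and the detector-switch spike *before* any
differentiation); the published per-method intervals are then applied to the
derivative curves as configured trims.

:func:`count_best_by_method` tallies, over a component subset, how often each
method attains the strictly lowest RMSECV; ties (exact, or within an optional
relative tolerance) are credited to no method.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .calibration import Algorithm, detect_outliers, loocv, select_pcs
from .concentrations import ConcentrationTable, load_concentration_table
from .filters import (
    FilterSpec,
    GS_DEFAULT,
    NONE_FILTER,
    SBSF_DEFAULT,
    apply_filter,
)
from .spectra import (
    GS_REGIONS,
    RegionSet,
    SBSF_REGIONS,
    SpectraSet,
    ZERO_ORDER_REGIONS,
    average_replicates,
    trim_regions,
)

__all__ = [
    "MethodSetting",
    "DEFAULT_METHODS",
    "PipelineConfig",
    "CellResult",
    "ComparisonReport",
    "BestMethodTally",
    "run_pipeline",
    "count_best_by_method",
    "export_report",
    "load_report",
    "load_reference_stats",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MethodSetting:
    """A named preprocessing variant: derivative filter + retained intervals."""

    name: str
    filter_spec: FilterSpec
    regions: RegionSet


#: The three published preprocessing variants with their printed intervals.
DEFAULT_METHODS = (
    MethodSetting("NONE", NONE_FILTER, ZERO_ORDER_REGIONS),
    MethodSetting("GS", GS_DEFAULT, GS_REGIONS),
    MethodSetting("SBSF", SBSF_DEFAULT, SBSF_REGIONS),
)


@dataclass
class PipelineConfig:
    """Everything :func:`run_pipeline` needs.

    ``spectra`` holds replicate-level measurements; ``table`` the reference
    concentrations (defaults to the packaged table). ``raw_regions`` is the
    pre-derivative trim shared by all methods.
    """

    spectra: SpectraSet
    table: ConcentrationTable | None = None
    methods: tuple[MethodSetting, ...] = DEFAULT_METHODS
    algorithm: Algorithm = "pls1"
    max_pc: int | None = None
    outlier_threshold: float = 3.5
    raw_regions: RegionSet = ZERO_ORDER_REGIONS
    components: tuple[int, ...] | None = None
    seed: int | None = None


@dataclass(frozen=True)
class CellResult:
    """One component x method entry of the comparison grid."""

    component: int
    component_name: str
    method: str
    rmsecv: float | None
    r2: float | None
    n_pc: int | None
    n_included: int | None = None
    excluded: dict[str, str] = field(default_factory=dict)
    error: str | None = None


@dataclass(frozen=True)
class ComparisonReport:
    """Component x method grid of cross-validated model statistics."""

    cells: tuple[CellResult, ...]
    metadata: dict = field(default_factory=dict)

    @property
    def methods(self) -> list[str]:
        return list(dict.fromkeys(c.method for c in self.cells))

    @property
    def components(self) -> list[int]:
        return sorted({c.component for c in self.cells})

    def cell(self, component: int, method: str) -> CellResult:
        for c in self.cells:
            if c.component == component and c.method == method:
                return c
        raise KeyError((component, method))

    def best_method(self, component: int, rel_tol: float = 0.0) -> str | None:
        """Method with strictly the lowest RMSECV, or None on a tie/no data.

        With ``rel_tol`` > 0, a runner-up within ``rel_tol`` (relative to the
        minimum) also voids the win.
        """
        scored = [
            (c.rmsecv, c.method)
            for c in self.cells
            if c.component == component and c.rmsecv is not None
        ]
        if not scored:
            return None
        scored.sort()
        if len(scored) > 1 and scored[1][0] <= scored[0][0] * (1.0 + rel_tol):
            return None
        return scored[0][1]

    def to_long_frame(self) -> pd.DataFrame:
        """Long-form table (one row per component x method)."""
        rows = [
            {
                "component": c.component,
                "component_name": c.component_name,
                "method": c.method,
                "rmsecv": c.rmsecv,
                "r2": c.r2,
                "n_pc": c.n_pc,
                "n_included": c.n_included,
                "excluded": ";".join(f"{k}:{v}" for k, v in c.excluded.items()),
                "error": c.error or "",
            }
            for c in self.cells
        ]
        return pd.DataFrame(rows)


def _preprocess(
    spectra: SpectraSet, setting: MethodSetting, raw_regions: RegionSet
) -> pd.DataFrame:
    """Sample x wavelength matrix for one preprocessing variant."""
    trimmed = SpectraSet(tuple(trim_regions(s, raw_regions) for s in spectra))
    averaged = average_replicates(trimmed)
    rows = {}
    for s in averaged:
        d = apply_filter(s, setting.filter_spec)
        d = trim_regions(d, setting.regions)
        rows[s.sample_id] = pd.Series(d.values, index=d.wavelengths_nm)
    return pd.DataFrame(rows).T


def run_pipeline(config: PipelineConfig) -> ComparisonReport:
    """Run the full comparison; one cell per component per method.

    A failure in one cell is recorded in that cell's ``error`` field and the
    remaining cells are still computed. Deterministic for fixed inputs.
    """
    table = config.table if config.table is not None else load_concentration_table()
    components = (
        tuple(config.components) if config.components is not None else tuple(table.components)
    )
    cells: list[CellResult] = []
    matrices: dict[str, pd.DataFrame | Exception] = {}
    for setting in config.methods:
        try:
            matrices[setting.name] = _preprocess(
                config.spectra, setting, config.raw_regions
            )
        except Exception as exc:  # noqa: BLE001 - reported per cell below
            logger.error("preprocessing failed for %s: %s", setting.name, exc)
            matrices[setting.name] = exc

    for comp in components:
        name = table.name_of(comp)
        y_all = table.component_series(comp)
        excluded: dict[str, str] = {
            str(s): "missing reference value" for s in y_all.index[y_all.isna()]
        }
        try:
            report = detect_outliers(table, comp, threshold=config.outlier_threshold)
            for sid in report.flagged:
                excluded[sid] = (
                    f"concentration outlier (robust score "
                    f"{report.scores[sid]:.1f} > {report.threshold})"
                )
        except ValueError as exc:
            logger.warning("component %d: outlier screening skipped: %s", comp, exc)

        for setting in config.methods:
            X = matrices[setting.name]
            if isinstance(X, Exception):
                cells.append(
                    CellResult(comp, name, setting.name, None, None, None, error=str(X))
                )
                continue
            try:
                include = [s for s in X.index if s not in excluded and s in y_all.index]
                y = y_all.loc[include].to_numpy(dtype=float)
                results = loocv(
                    X.loc[include].to_numpy(),
                    y,
                    max_pc=config.max_pc,
                    algorithm=config.algorithm,
                )
                sel = select_pcs(results)
                logger.info(
                    "component %d (%s) method %s: n=%d, n_pc=%d, RMSECV=%.4g",
                    comp, name, setting.name, len(include), sel.n_pc, sel.result.rmsecv,
                )
                cells.append(
                    CellResult(
                        component=comp,
                        component_name=name,
                        method=setting.name,
                        rmsecv=sel.result.rmsecv,
                        r2=sel.result.r2,
                        n_pc=sel.n_pc,
                        n_included=len(include),
                        excluded=excluded,
                    )
                )
            except Exception as exc:  # noqa: BLE001 - reported per cell
                logger.error("component %d method %s failed: %s", comp, setting.name, exc)
                cells.append(
                    CellResult(
                        comp, name, setting.name, None, None, None,
                        excluded=excluded, error=str(exc),
                    )
                )

    metadata = {
        "algorithm": config.algorithm,
        "max_pc": config.max_pc,
        "outlier_threshold": config.outlier_threshold,
        "raw_regions": list(config.raw_regions.intervals),
        "methods": {
            m.name: {
                "filter": dataclasses.asdict(m.filter_spec),
                "regions": list(m.regions.intervals),
            }
            for m in config.methods
        },
        "seed": config.seed,
        "n_spectra": len(config.spectra),
        "software_version": __version__,
    }
    return ComparisonReport(cells=tuple(cells), metadata=metadata)


@dataclass(frozen=True)
class BestMethodTally:
    """Per-method win counts over a component subset (strict minima)."""

    counts: dict[str, int]
    winners: dict[str, tuple[int, ...]]
    ties: tuple[int, ...]
    components: tuple[int, ...]


def count_best_by_method(
    report: ComparisonReport,
    components: tuple[int, ...] | None = None,
    rel_tol: float = 0.0,
) -> BestMethodTally:
    """Tally how many components each method wins outright.

    The default subset is components 1-13 of the report (the study's
    "monitored active components" convention, which leaves out the
    fourteenth compound); pass an explicit tuple to override. A component
    whose two best methods tie (within ``rel_tol``) is credited to neither.
    """
    if components is None:
        components = tuple(c for c in report.components if c <= 13)
    winners: dict[str, list[int]] = {m: [] for m in report.methods}
    ties: list[int] = []
    for comp in components:
        best = report.best_method(comp, rel_tol=rel_tol)
        if best is None:
            ties.append(comp)
        else:
            winners.setdefault(best, []).append(comp)
    return BestMethodTally(
        counts={m: len(v) for m, v in winners.items()},
        winners={m: tuple(v) for m, v in winners.items()},
        ties=tuple(ties),
        components=tuple(components),
    )


# ---------------------------------------------------------------------------
# Report serialization


def export_report(report: ComparisonReport, path, format: str = "json") -> Path:
    """Write the report as ``json`` (lossless), ``csv`` (long form) or
    ``markdown-table`` (component rows x method column groups)."""
    path = Path(path)
    if format == "json":
        payload = {
            "metadata": report.metadata,
            "cells": [dataclasses.asdict(c) for c in report.cells],
        }
        path.write_text(json.dumps(payload, indent=2, sort_keys=True))
    elif format == "csv":
        report.to_long_frame().to_csv(path, index=False, float_format="%.17g")
    elif format == "markdown-table":
        methods = report.methods
        header = ["No", "Component"] + [
            f"{m} {col}" for m in methods for col in ("RMSECV", "R2", "PCs")
        ]
        lines = ["| " + " | ".join(header) + " |",
                 "|" + "---|" * len(header)]
        for comp in report.components:
            row = [str(comp), report.cell(comp, methods[0]).component_name]
            for m in methods:
                c = report.cell(comp, m)
                if c.error or c.rmsecv is None:
                    row += ["skipped", "skipped", "skipped"]
                else:
                    row += [f"{c.rmsecv:.4g}", f"{c.r2:.4f}", str(c.n_pc)]
            lines.append("| " + " | ".join(row) + " |")
        path.write_text("\n".join(lines) + "\n")
    else:
        raise ValueError(f"unknown format {format!r}")
    return path


def _cell_from_record(rec: dict) -> CellResult:
    excluded = rec.get("excluded", {})
    if isinstance(excluded, str):
        excluded = dict(
            item.split(":", 1) for item in excluded.split(";") if item
        )
    err = rec.get("error") or None
    rmsecv = rec.get("rmsecv")
    n_pc = rec.get("n_pc")
    n_inc = rec.get("n_included")
    return CellResult(
        component=int(rec["component"]),
        component_name=str(rec["component_name"]),
        method=str(rec["method"]),
        rmsecv=None if rmsecv is None or (isinstance(rmsecv, float) and np.isnan(rmsecv)) else float(rmsecv),
        r2=None if rec.get("r2") is None or (isinstance(rec.get("r2"), float) and np.isnan(rec["r2"])) else float(rec["r2"]),
        n_pc=None if n_pc is None or (isinstance(n_pc, float) and np.isnan(n_pc)) else int(n_pc),
        n_included=None if n_inc is None or (isinstance(n_inc, float) and np.isnan(n_inc)) else int(n_inc),
        excluded=excluded,
        error=err,
    )


def load_report(path, format: str | None = None) -> ComparisonReport:
    """Read a report written by :func:`export_report` (json or csv)."""
    path = Path(path)
    if format is None:
        format = "csv" if path.suffix == ".csv" else "json"
    if format == "json":
        payload = json.loads(path.read_text())
        cells = tuple(_cell_from_record(r) for r in payload["cells"])
        return ComparisonReport(cells=cells, metadata=payload.get("metadata", {}))
    if format == "csv":
        df = pd.read_csv(path, dtype={"excluded": str, "error": str}, keep_default_na=True)
        df["excluded"] = df["excluded"].fillna("")
        df["error"] = df["error"].fillna("")
        cells = tuple(_cell_from_record(r) for r in df.to_dict("records"))
        return ComparisonReport(cells=cells, metadata={})
    raise ValueError(f"unknown format {format!r}")


def load_reference_stats() -> ComparisonReport:
    """The published cross-validated model statistics as a report.

    Note: this grid's component numbering differs from the concentration
    table's for components 7-14 (here 7 = luteolin-7-glucoside,
    8 = isoquercitrin, ..., as printed alongside the published statistics).
    """
    path = resources.files("spectrocal.data") / "reference_model_stats.csv"
    df = pd.read_csv(path)
    cells = tuple(
        CellResult(
            component=int(r.component_index),
            component_name=str(r.component_name),
            method=str(r.method),
            rmsecv=float(r.rmsecv),
            r2=float(r.r2),
            n_pc=int(r.n_pc),
        )
        for r in df.itertuples()
    )
    return ComparisonReport(cells=cells, metadata={"source": "published reference statistics"})
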