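"""Run the framework x classifier grid and emit the comparison report.

One *cell* is one (dataset, training framework, classifier family)
combination; for each cell the calibration curve (reported vs external FDR
over a grid) and the two headline counts — identifications at reported 1%
FDR and at external 1% FDR — are recorded. Cell failures are captured as
error records, never silent gaps. Per-cell seeds are derived from the grid
seed plus a stable hash of the cell name, so adding a cell never perturbs
the others.
"""

from __future__ import annotations

import json
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigError, TDBenchError
from .fdr import DEFAULT_GRID, CalibrationCurve, calibration_curve, ids_at_external_fdr
from .models import ClassifierSpec
from .rescore import FrameworkParams, run_framework
from .table import ScoreTable

REPORTED_LEVEL = 0.01
EXTERNAL_LEVEL = 0.01


@dataclass
class CellResult:
    dataset: str
    framework: str
    family: str
    curve: CalibrationCurve | None = None
    ids_at_reported_1pct: int | None = None
    ids_at_external_1pct: int | None = None
    runtime_s: float = 0.0  # diagnostic only, never asserted
    error: str | None = None
    seed: int = 0

    @property
    def name(self) -> str:
        return f"{self.dataset}|{self.framework}|{self.family}"


@dataclass
class BenchmarkResult:
    cells: list[CellResult] = field(default_factory=list)
    seed: int = 0
    grid: tuple[float, ...] = DEFAULT_GRID

    def to_dict(self) -> dict[str, Any]:
        return {
            "seed": self.seed,
            "grid": list(self.grid),
            "cells": [
                {
                    "dataset": c.dataset,
                    "framework": c.framework,
                    "family": c.family,
                    "points": None if c.curve is None else c.curve.points,
                    "ids_at_reported_1pct": c.ids_at_reported_1pct,
                    "ids_at_external_1pct": c.ids_at_external_1pct,
                    "runtime_s": c.runtime_s,
                    "error": c.error,
                    "seed": c.seed,
                }
                for c in self.cells
            ],
        }

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "BenchmarkResult":
        grid = tuple(d["grid"])
        cells = []
        for c in d["cells"]:
            curve = None
            if c["points"] is not None:
                curve = CalibrationCurve(
                    points=[tuple(p) for p in c["points"]], grid=grid
                )
            cells.append(
                CellResult(
                    dataset=c["dataset"],
                    framework=c["framework"],
                    family=c["family"],
                    curve=curve,
                    ids_at_reported_1pct=c["ids_at_reported_1pct"],
                    ids_at_external_1pct=c["ids_at_external_1pct"],
                    runtime_s=c["runtime_s"],
                    error=c["error"],
                    seed=c["seed"],
                )
            )
        return cls(cells=cells, seed=d["seed"], grid=grid)


def cell_seed(base_seed: int, cell_name: str) -> int:
    """Deterministic per-cell seed: base + CRC32 of the cell name."""
    return (int(base_seed) + zlib.crc32(cell_name.encode())) % (2**31)


def run_cell(
    table: ScoreTable,
    dataset: str,
    framework: str,
    classifier: str | ClassifierSpec,
    seed: int,
    grid: Sequence[float] = DEFAULT_GRID,
    params: Mapping[str, Any] | None = None,
) -> CellResult:
    family = classifier if isinstance(classifier, str) else classifier.family
    cell = CellResult(dataset=dataset, framework=framework, family=family, seed=seed)
    t0 = time.perf_counter()
    try:
        fp = FrameworkParams(framework=framework, seed=seed, **dict(params or {}))
        res = run_framework(table, classifier, fp)
        cell.curve = calibration_curve(res.qvalues, table, grid=grid)
        accepted = table.is_target & (res.qvalues <= REPORTED_LEVEL)
        cell.ids_at_reported_1pct = int((accepted & ~table.entrapment).sum())
        if table.entrapment.any():
            cell.ids_at_external_1pct = ids_at_external_fdr(
                res.scores, table, level=EXTERNAL_LEVEL
            )
    except TDBenchError as exc:
        cell.error = f"{type(exc).__name__}: {exc}"
    cell.runtime_s = time.perf_counter() - t0
    return cell


def run_grid(
    tables: Mapping[str, ScoreTable],
    frameworks: Sequence[str],
    classifiers: Sequence[str | ClassifierSpec],
    params: Mapping[str, Any] | None = None,
    seed: int = 0,
    grid: Sequence[float] = DEFAULT_GRID,
) -> BenchmarkResult:
    """Execute every dataset x framework x classifier combination.

    ``params`` holds FrameworkParams overrides shared by all cells (keys not
    applicable to a framework are dropped per cell). Cell order — and hence
    the report — is a deterministic function of the inputs and the seed.
    """
    if not tables or not frameworks or not classifiers:
        raise ConfigError("tables, frameworks and classifiers must be non-empty")
    result = BenchmarkResult(seed=seed, grid=tuple(grid))
    relevant = {
        "semi_supervised": {"n_iterations", "q_init", "q_learn", "epochs"},
        "fully_supervised": {"epochs"},
        "kfold": {"n_folds", "epochs", "decoy_scoring"},
    }
    for dname, table in tables.items():
        for fw in frameworks:
            for clf in classifiers:
                fam = clf if isinstance(clf, str) else clf.family
                name = f"{dname}|{fw}|{fam}"
                cell_params = {
                    k: v for k, v in dict(params or {}).items() if k in relevant.get(fw, set())
                }
                result.cells.append(
                    run_cell(
                        table,
                        dname,
                        fw,
                        clf,
                        seed=cell_seed(seed, name),
                        grid=grid,
                        params=cell_params,
                    )
                )
    if all(c.error is not None for c in result.cells):
        raise TDBenchError(
            "every benchmark cell failed; first error: " + str(result.cells[0].error)
        )
    return result


def result_frame(result: BenchmarkResult) -> pd.DataFrame:
    """Long-format view: one row per cell x grid point."""
    rows = []
    for c in result.cells:
        if c.curve is None:
            continue
        for reported, external, n_ids in c.curve.points:
            rows.append(
                {
                    "dataset": c.dataset,
                    "framework": c.framework,
                    "classifier": c.family,
                    "reported_fdr": reported,
                    "external_fdr": external,
                    "n_ids": n_ids,
                }
            )
    return pd.DataFrame(rows)


def write_report(
    result: BenchmarkResult, outdir: str | Path, plots: bool = False
) -> dict[str, Path]:
    """Write the long TSV, the JSON summary, and optional calibration plots."""
    if not result.cells:
        raise TDBenchError("benchmark result has no cells; nothing to report")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    tsv = outdir / "calibration.tsv"
    result_frame(result).to_csv(tsv, sep="\t", index=False)
    paths["tsv"] = tsv

    js = outdir / "benchmark.json"
    js.write_text(json.dumps(result.to_dict(), indent=2))
    paths["json"] = js

    if plots:
        paths["plots"] = _plot_calibration(result, outdir)
    return paths


def _plot_calibration(result: BenchmarkResult, outdir: Path) -> Path:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    path = outdir / "calibration.png"
    cells = [c for c in result.cells if c.curve is not None]
    ncol = max(1, min(4, len(cells)))
    nrow = int(np.ceil(len(cells) / ncol))
    fig, axes = plt.subplots(nrow, ncol, figsize=(3.2 * ncol, 3.0 * nrow), squeeze=False)
    for ax, c in zip(axes.ravel(), cells):
        df = c.curve.to_frame()
        ax.plot(df.reported_fdr, df.external_fdr, "o-", ms=3)
        lim = max(df.reported_fdr.max(), df.external_fdr.max()) * 1.05
        ax.plot([0, lim], [0, lim], "k--", lw=0.7)  # identity = perfect calibration
        ax.set_title(f"{c.dataset}\n{c.framework} / {c.family}", fontsize=7)
        ax.set_xlabel("reported FDR", fontsize=7)
        ax.set_ylabel("external FDR", fontsize=7)
    for ax in axes.ravel()[len(cells):]:
        ax.axis("off")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
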