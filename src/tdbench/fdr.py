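"""Decoy-based q-values and entrapment-based external FDR.

Two error estimates live here. The *reported* FDR is the engine's own
decoy-based estimate: at a score threshold s,

    FDR_hat(s) = #{decoys with score >= s} / max(1, #{targets with score >= s})

which is valid as-is under the 1:1 target:decoy design (no +1 pseudo-count,
no pi0 correction; a pseudo-count is available as an option, default off).
A target's q-value is the minimum FDR_hat over all thresholds that would
accept it. Rows sharing a score share a q-value: the threshold sweep runs
over distinct score values, so decoys tied with targets count against them.

The *external* (actual) FDR is the entrapment lower bound: among accepted
targets, the fraction whose peptide comes from a foreign proteome searched as
targets. It is a lower bound on the true false-discovery proportion whenever
entrapment hits behave like the other false hits; no database-size scaling is
applied by default (``scale`` option available). The gap between reported and
external FDR over a threshold grid is the under/over-fitting readout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import logging

import numpy as np
import pandas as pd

from .exceptions import (
    ConfigError,
    ContractError,
    EstimatorUndefinedError,
    UndefinedMetricError,
)
from .table import ScoreTable

logger = logging.getLogger(__name__)

#: the default reported-FDR grid: 1% to 5% in 0.5% steps
DEFAULT_GRID: tuple[float, ...] = tuple(np.round(np.arange(0.01, 0.0501, 0.005), 4))


@dataclass
class QValueVector:
    """Per-row q-values plus the descending sort permutation used."""

    qvalues: np.ndarray
    score_order: np.ndarray


def qvalues_from_scores(
    scores: np.ndarray,
    is_target: np.ndarray,
    pseudocount: float = 0.0,
) -> np.ndarray:
    """Per-row q-values from discriminant scores and target/decoy labels.

    The q-value of a row with score s is ``min over thresholds t <= s`` of
    ``FDR_hat(t)``, clipped to [0, 1]. Target rows carry the estimator
    proper; decoy rows get the same threshold mapping applied to their score,
    useful for diagnostics only.
    """
    scores = np.asarray(scores, dtype=float)
    is_target = np.asarray(is_target, dtype=bool)
    if not (~is_target).any():
        raise EstimatorUndefinedError("decoy-based FDR needs at least one decoy")
    if not is_target.any():
        raise EstimatorUndefinedError("decoy-based FDR needs at least one target")

    u = np.unique(scores)  # distinct thresholds, ascending
    t_sorted = np.sort(scores[is_target])
    d_sorted = np.sort(scores[~is_target])
    n_t_ge = t_sorted.size - np.searchsorted(t_sorted, u, side="left")
    n_d_ge = d_sorted.size - np.searchsorted(d_sorted, u, side="left")
    fdr = (n_d_ge + pseudocount) / np.maximum(1, n_t_ge)
    np.minimum(fdr, 1.0, out=fdr)
    # prefix min over ascending thresholds == min over all thresholds <= u_k
    q_at = np.minimum.accumulate(fdr)
    return q_at[np.searchsorted(u, scores)]


def compute_qvalues(
    scores: np.ndarray,
    labels: np.ndarray,
    pseudocount: float = 0.0,
) -> QValueVector:
    """Decoy-competition q-values; see :func:`qvalues_from_scores`.

    ``labels`` is the boolean target mask (True = target).
    """
    q = qvalues_from_scores(scores, labels, pseudocount=pseudocount)
    order = np.argsort(-np.asarray(scores, dtype=float), kind="stable")
    return QValueVector(qvalues=q, score_order=order)


def entrapment_fdr(accepted: np.ndarray, table: ScoreTable, scale: float = 1.0) -> float:
    """Entrapment lower bound: entrapment hits / all hits among ``accepted``.

    ``accepted`` is a boolean mask or an index array over the table's rows
    and may contain only target rows. Returns 0.0 (logged) when the accepted
    set is empty. ``scale`` optionally multiplies the ratio (database-size
    correction; default 1, the plain lower bound).
    """
    accepted = np.asarray(accepted)
    if accepted.dtype == bool:
        idx = np.flatnonzero(accepted)
    else:
        idx = accepted.astype(int)
    if np.any(~table.is_target[idx]):
        raise ContractError("accepted set contains decoy rows")
    if idx.size == 0:
        logger.info("entrapment FDR of an empty accepted set: returning 0.0")
        return 0.0
    return scale * float(table.entrapment[idx].sum()) / idx.size


@dataclass
class CalibrationCurve:
    """Paired (reported FDR, external FDR) points over a threshold grid."""

    points: list[tuple[float, float, int]] = field(default_factory=list)
    grid: tuple[float, ...] = DEFAULT_GRID

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.points, columns=["reported_fdr", "external_fdr", "n_ids"]
        )

    def at(self, reported: float) -> tuple[float, float, int]:
        """The curve point for a given grid threshold."""
        for p in self.points:
            if np.isclose(p[0], reported):
                return p
        raise KeyError(f"{reported} is not on the evaluated grid {self.grid}")


def calibration_curve(
    qvalues: np.ndarray,
    table: ScoreTable,
    grid: Sequence[float] = DEFAULT_GRID,
) -> CalibrationCurve:
    """Reported-vs-external FDR over a grid of reported-FDR thresholds.

    For each threshold t the accepted set is the targets with q <= t; the
    point records t, the entrapment FDR of that set, and the number of
    accepted non-entrapment targets (an entrapment hit is not a desired
    identification, so it is excluded from the count).
    """
    grid = tuple(grid)
    if len(grid) == 0:
        raise ConfigError("calibration grid must be non-empty")
    qvalues = np.asarray(qvalues, dtype=float)
    if len(qvalues) != len(table):
        raise ContractError("q-value vector does not align with the table rows")
    points = []
    for t in grid:
        accepted = table.is_target & (qvalues <= t)
        ext = entrapment_fdr(accepted, table)
        n_ids = int((accepted & ~table.entrapment).sum())
        points.append((float(t), ext, n_ids))
    return CalibrationCurve(points=points, grid=grid)


def ids_at_external_fdr(
    scores: np.ndarray,
    table: ScoreTable,
    level: float = 0.01,
) -> int:
    """Identifications under an external FDR bound.

    Sweeps score thresholds from high to low over the target rows and
    returns the maximum count of accepted non-entrapment targets over all
    thresholds at which the entrapment FDR of the accepted set is <= level.
    Returns 0 when no threshold satisfies the bound. Ties are handled as
    blocks: only thresholds at distinct score values are evaluated, with all
    tied rows accepted together.
    """
    if not table.entrapment.any():
        raise UndefinedMetricError(
            "external FDR needs at least one entrapment target row"
        )
    scores = np.asarray(scores, dtype=float)
    s = scores[table.is_target]
    e = table.entrapment[table.is_target]
    order = np.argsort(-s, kind="stable")
    ss, ee = s[order], e[order]
    cum_e = np.cumsum(ee)
    cum_n = np.arange(1, ss.size + 1)
    block_end = np.r_[ss[:-1] != ss[1:], True]  # last row of each tie block
    feasible = block_end & (cum_e / cum_n <= level)
    if not feasible.any():
        return 0
    return int((cum_n - cum_e)[feasible].max())
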