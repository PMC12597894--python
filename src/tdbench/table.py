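"""The score table: precursor rows x sub-score columns with target/decoy labels.

This is the central in-memory container of the package. One row is one
precursor (a peptide candidate), carrying an opaque identifier, an optional
peptide sequence, a target/decoy label, an entrapment flag (targets drawn
from a foreign proteome, used to estimate the actual error rate), and a dense
vector of numeric sub-scores produced by a search engine.

On disk the table is a plain TSV with a header row. Because search engines
disagree on column names and label vocabularies, reading goes through a
*column map* that names the id/label/sequence/entrapment columns and the two
label values; unmapped columns are treated as sub-scores.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import (
    ConfigError,
    EmptyInputError,
    InvalidTableError,
    ParseError,
)

logger = logging.getLogger(__name__)

#: strings read as "missing value" rather than a parse failure
_NA_STRINGS = {"", "na", "nan", "n/a", "null", "none"}

_TRUE_STRINGS = {"1", "true", "t", "yes", "y"}
_FALSE_STRINGS = {"0", "false", "f", "no", "n"} | _NA_STRINGS


@dataclass
class ScoreTable:
    """Validated precursor score table.

    Parameters
    ----------
    ids : array of str
        Opaque per-row identifiers.
    is_target : bool array
        True for target rows, False for decoy rows.
    entrapment : bool array
        True for entrapment targets (never true on a decoy row).
    scores : float array, shape (n_rows, n_features)
        Dense sub-score matrix.
    feature_names : list of str
        Column names of ``scores``.
    sequences : array of str, optional
        Peptide sequences (uppercase amino-acid letters).
    """

    ids: np.ndarray
    is_target: np.ndarray
    entrapment: np.ndarray
    scores: np.ndarray
    feature_names: list[str] = field(default_factory=list)
    sequences: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=object)
        self.is_target = np.asarray(self.is_target, dtype=bool)
        self.entrapment = np.asarray(self.entrapment, dtype=bool)
        self.scores = np.atleast_2d(np.asarray(self.scores, dtype=float))
        if self.sequences is not None:
            self.sequences = np.asarray(self.sequences, dtype=object)
        n = len(self.ids)
        if n < 1:
            raise EmptyInputError("a ScoreTable needs at least one row")
        for name, arr in (
            ("is_target", self.is_target),
            ("entrapment", self.entrapment),
            ("scores", self.scores),
        ):
            if len(arr) != n:
                raise InvalidTableError(
                    f"length mismatch: {name} has {len(arr)} rows, ids has {n}"
                )
        if self.sequences is not None and len(self.sequences) != n:
            raise InvalidTableError("sequences length does not match ids")
        if self.scores.shape[1] != len(self.feature_names):
            raise InvalidTableError(
                f"scores has {self.scores.shape[1]} columns but "
                f"{len(self.feature_names)} feature names were given"
            )
        if self.scores.shape[1] < 1:
            raise InvalidTableError("at least one score column is required")
        if np.any(self.entrapment & ~self.is_target):
            raise InvalidTableError("entrapment flag set on a decoy row")

    # -- convenience -------------------------------------------------------
    def __len__(self) -> int:
        return len(self.ids)

    @property
    def n_features(self) -> int:
        return self.scores.shape[1]

    @property
    def n_targets(self) -> int:
        return int(self.is_target.sum())

    @property
    def n_decoys(self) -> int:
        return int((~self.is_target).sum())

    def require_both_classes(self) -> None:
        """Raise unless at least one target and one decoy row exist."""
        if self.n_targets == 0 or self.n_decoys == 0:
            raise InvalidTableError(
                f"training needs both classes; table has {self.n_targets} "
                f"targets and {self.n_decoys} decoys"
            )

    def to_frame(self) -> pd.DataFrame:
        """Long DataFrame view in the canonical column order."""
        cols: dict[str, object] = {"id": self.ids}
        if self.sequences is not None:
            cols["sequence"] = self.sequences
        cols["label"] = np.where(self.is_target, "target", "decoy")
        cols["entrapment"] = self.entrapment.astype(int)
        df = pd.DataFrame(cols)
        for j, name in enumerate(self.feature_names):
            df[name] = self.scores[:, j]
        return df


DEFAULT_COLUMN_MAP: dict[str, object] = {
    "id": "id",
    "label": "label",
    "entrapment": "entrapment",
    "sequence": "sequence",
    "target_value": "target",
    "decoy_value": "decoy",
    "scores": None,  # None -> every unmapped column is a sub-score
}


def _parse_bool_column(raw: pd.Series, column: str) -> np.ndarray:
    out = np.zeros(len(raw), dtype=bool)
    for i, v in enumerate(raw):
        s = "" if v is None or (isinstance(v, float) and np.isnan(v)) else str(v).strip()
        low = s.lower()
        if low in _TRUE_STRINGS:
            out[i] = True
        elif low in _FALSE_STRINGS:
            out[i] = False
        else:
            raise ParseError(
                f"unparseable boolean {s!r} at row {i}, column {column!r}"
            )
    return out


def read_score_table(
    path: str | Path, column_map: Mapping[str, object] | None = None
) -> ScoreTable:
    """Read a TSV score table.

    ``column_map`` names the structural columns and the two label values;
    keys absent from the map fall back to :data:`DEFAULT_COLUMN_MAP`. The
    ``scores`` entry may list the sub-score columns explicitly; by default
    every column not claimed by a structural role is a sub-score.

    Unparseable labels or score cells raise :class:`ParseError` with row and
    column coordinates — rows are never silently dropped. Missing score
    values (empty cells, ``NA``/``nan``) become NaN and are left for
    :func:`validate_table` to impute.
    """
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        unknown = set(column_map) - set(DEFAULT_COLUMN_MAP)
        if unknown:
            raise ConfigError(f"unknown column_map keys: {sorted(unknown)}")
        cmap.update(column_map)

    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.shape[0] == 0:
        raise EmptyInputError(f"{path} contains no data rows")

    for role in ("id", "label"):
        col = cmap[role]
        if col not in df.columns:
            raise ConfigError(
                f"mapped {role!r} column {col!r} not found in {path.name} "
                f"(available: {list(df.columns)})"
            )

    structural = {cmap["id"], cmap["label"]}
    seq_col = cmap["sequence"] if cmap["sequence"] in df.columns else None
    ent_col = cmap["entrapment"] if cmap["entrapment"] in df.columns else None
    structural |= {c for c in (seq_col, ent_col) if c is not None}

    if cmap["scores"] is not None:
        score_cols = list(cmap["scores"])  # type: ignore[arg-type]
        missing = [c for c in score_cols if c not in df.columns]
        if missing:
            raise ConfigError(f"mapped score columns not found: {missing}")
    else:
        score_cols = [c for c in df.columns if c not in structural]
    if not score_cols:
        raise ConfigError("no score columns; at least one is required")

    tval, dval = str(cmap["target_value"]), str(cmap["decoy_value"])
    raw_labels = df[cmap["label"]].astype(str).str.strip()
    bad = ~raw_labels.isin([tval, dval])
    if bad.any():
        i = int(np.flatnonzero(bad.to_numpy())[0])
        raise ParseError(
            f"unparseable label {raw_labels.iloc[i]!r} at row {i}, column "
            f"{cmap['label']!r}; expected {tval!r} or {dval!r}"
        )
    is_target = (raw_labels == tval).to_numpy()

    scores = np.empty((len(df), len(score_cols)), dtype=float)
    for j, col in enumerate(score_cols):
        raw = df[col].astype(str).str.strip()
        # blank/NA-ish cells become NaN for validate_table to impute;
        # float() parsing (unlike the fast CSV parser) round-trips exactly
        cleaned = raw.where(~raw.str.lower().isin(_NA_STRINGS), "nan")
        try:
            scores[:, j] = cleaned.to_numpy(dtype=object).astype(float)
        except ValueError:
            for i, v in enumerate(cleaned):
                try:
                    float(v)
                except ValueError:
                    raise ParseError(
                        f"non-numeric score {raw.iloc[i]!r} at row {i}, "
                        f"column {col!r}"
                    ) from None
            raise

    entrapment = (
        _parse_bool_column(df[ent_col], ent_col)
        if ent_col is not None
        else np.zeros(len(df), dtype=bool)
    )
    sequences = df[seq_col].to_numpy(dtype=object) if seq_col is not None else None

    return ScoreTable(
        ids=df[cmap["id"]].to_numpy(dtype=object),
        is_target=is_target,
        entrapment=entrapment,
        scores=scores,
        feature_names=score_cols,
        sequences=sequences,
    )


@dataclass
class ValidationReport:
    n_imputed_cells: int = 0
    dropped_columns: list[str] = field(default_factory=list)


def validate_table(
    table: ScoreTable,
    impute: str = "median",
    return_report: bool = False,
) -> ScoreTable | tuple[ScoreTable, ValidationReport]:
    """Return a table whose every score cell is finite.

    Non-finite cells are replaced by the column median of the finite values
    (``impute="median"``, the default) or by zero (``impute="zero"``).
    Columns without a single finite value are dropped with a logged warning.
    A fully finite table is returned as-is (scores bit-identical).
    """
    table.require_both_classes()
    if impute not in ("median", "zero"):
        raise ConfigError(f"unknown imputation policy {impute!r}")

    finite = np.isfinite(table.scores)
    report = ValidationReport()
    if finite.all():
        return (table, report) if return_report else table

    keep = finite.any(axis=0)
    report.dropped_columns = [
        n for n, k in zip(table.feature_names, keep) if not k
    ]
    if report.dropped_columns:
        logger.warning(
            "dropping %d all-missing score column(s): %s",
            len(report.dropped_columns),
            report.dropped_columns,
        )
    scores = table.scores[:, keep].copy()
    finite = finite[:, keep]
    names = [n for n, k in zip(table.feature_names, keep) if k]
    if scores.shape[1] == 0:
        raise InvalidTableError("every score column is entirely non-finite")

    for j in range(scores.shape[1]):
        bad = ~finite[:, j]
        if bad.any():
            fill = 0.0 if impute == "zero" else float(np.median(scores[finite[:, j], j]))
            scores[bad, j] = fill
            report.n_imputed_cells += int(bad.sum())
    logger.info(
        "imputed %d cell(s), dropped %d column(s)",
        report.n_imputed_cells,
        len(report.dropped_columns),
    )
    out = replace(table, scores=scores, feature_names=names)
    return (out, report) if return_report else out


def write_score_table(table: ScoreTable, path: str | Path) -> None:
    """Write a TSV in the canonical column order.

    Column order is id, sequence (if present), label, entrapment, then the
    sub-scores in ``feature_names`` order. Floats are serialized with
    ``repr`` precision so a read-back reproduces them exactly.
    """
    df = table.to_frame()
    df.to_csv(Path(path), sep="\t", index=False)


def write_ground_truth(ids: Sequence[str], is_true: Sequence[bool], path: str | Path) -> None:
    """Write the ground-truth sidecar TSV (row id -> is_true_target)."""
    pd.DataFrame(
        {"id": list(ids), "is_true_target": np.asarray(is_true, dtype=int)}
    ).to_csv(Path(path), sep="\t", index=False)
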