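"""Reading and writing paired-measurement tables.

Accepts comma/semicolon/tab-delimited text (header row required) and the
first sheet of an XLSX workbook.  Column mapping is always explicit: the
reference technique A (x axis) is whatever ``reference_cols`` names, the
candidate B is ``candidate_cols`` — the roles are asymmetric and never
guessed from position.  Subjects with any missing or non-numeric declared
value are dropped listwise (all three tests are paired by subject) and every
drop is logged and recorded in the LoadReport.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import AgreeKitError, InsufficientDataError, SchemaError
from .model import MeasurementSet

logger = logging.getLogger(__name__)

__all__ = ["ColumnSpec", "LoadReport", "load_measurements",
           "write_measurements"]


@dataclass(frozen=True)
class ColumnSpec:
    """Explicit mapping of table columns to techniques.

    ``reference_cols`` are the (≥1) replicate columns of technique A,
    ``candidate_cols`` those of technique B; they must be disjoint.
    """

    reference_cols: tuple[str, ...]
    candidate_cols: tuple[str, ...]
    subject_id_col: str | None = None

    def __post_init__(self) -> None:
        ref = tuple(self.reference_cols)
        cand = tuple(self.candidate_cols)
        object.__setattr__(self, "reference_cols", ref)
        object.__setattr__(self, "candidate_cols", cand)
        if not ref or not cand:
            raise SchemaError("both techniques need at least one column")
        if set(ref) & set(cand):
            raise SchemaError("reference and candidate columns must be disjoint")
        if len(set(ref)) != len(ref) or len(set(cand)) != len(cand):
            raise SchemaError("duplicate column names within a technique")


@dataclass
class LoadReport:
    n_rows_read: int = 0
    n_rows_dropped: int = 0
    drop_reasons: list[tuple[int, str]] = field(default_factory=list)


def _sniff_delimiter(path: Path, decimal_comma: bool) -> str:
    # with decimal commas the field delimiter cannot itself be a comma
    candidates = ";\t" if decimal_comma else ",;\t"
    sample = path.read_text(errors="replace")[:4096]
    try:
        return csv.Sniffer().sniff(sample, delimiters=candidates).delimiter
    except csv.Error:
        return candidates[0]


def _read_table(path: Path, decimal_comma: bool) -> pd.DataFrame:
    decimal = "," if decimal_comma else "."
    try:
        if path.suffix.lower() in (".xlsx", ".xlsm"):
            return pd.read_excel(path, sheet_name=0)
        sep = _sniff_delimiter(path, decimal_comma)
        logger.info("reading %s with delimiter %r", path.name, sep)
        return pd.read_csv(path, sep=sep, decimal=decimal,
                           float_precision="round_trip")
    except FileNotFoundError:
        raise
    except (OSError, pd.errors.ParserError, ValueError) as exc:
        raise AgreeKitError(f"could not read {path}: {exc}") from exc


def load_measurements(path, spec: ColumnSpec, decimal_comma: bool = False
                      ) -> tuple[MeasurementSet, LoadReport]:
    """Load a table and return the retained subjects plus a load report.

    Raises `SchemaError` for missing declared columns and
    `InsufficientDataError` when fewer than 3 complete subjects remain.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = _read_table(path, decimal_comma)
    declared = list(spec.reference_cols) + list(spec.candidate_cols)
    missing = [c for c in declared if c not in df.columns]
    if missing:
        raise SchemaError(f"declared columns not found in {path.name}: "
                          f"{missing}; available: {list(df.columns)}")
    if spec.subject_id_col is not None and spec.subject_id_col not in df.columns:
        raise SchemaError(f"subject id column {spec.subject_id_col!r} not "
                          f"found in {path.name}")

    report = LoadReport(n_rows_read=len(df))
    numeric = df[declared].apply(pd.to_numeric, errors="coerce")
    numeric = numeric.where(np.isfinite(numeric))
    complete = numeric.notna().all(axis=1)
    for pos, ok in enumerate(complete):
        if not ok:
            bad = [c for c in declared if pd.isna(numeric.iloc[pos][c])]
            reason = f"missing or non-numeric value in {bad}"
            report.drop_reasons.append((pos, reason))
            logger.info("dropping row %d: %s", pos, reason)
    report.n_rows_dropped = int((~complete).sum())

    kept = numeric[complete]
    if len(kept) < 3:
        raise InsufficientDataError(
            f"only {len(kept)} complete subjects in {path.name}; "
            "regressions need at least 3"
        )
    if spec.subject_id_col is not None:
        ids = df.loc[complete, spec.subject_id_col].to_numpy()
    else:
        ids = df.index[complete].to_numpy()
    logger.info("loaded %d subjects from %s (%d dropped); reference=%s "
                "candidate=%s", len(kept), path.name, report.n_rows_dropped,
                list(spec.reference_cols), list(spec.candidate_cols))
    ms = MeasurementSet(
        x_reps=kept[list(spec.reference_cols)].to_numpy(dtype=float),
        y_reps=kept[list(spec.candidate_cols)].to_numpy(dtype=float),
        subject_ids=ids,
        x_names=spec.reference_cols,
        y_names=spec.candidate_cols,
    )
    return ms, report


def write_measurements(ms: MeasurementSet, path) -> Path:
    """Write a MeasurementSet to CSV such that a reload is value-identical."""
    path = Path(path)
    x_names = ms.x_names or tuple(f"A{j + 1}" for j in range(ms.r_x))
    y_names = ms.y_names or tuple(f"B{j + 1}" for j in range(ms.r_y))
    data = {"subject": ms.subject_ids}
    for j, name in enumerate(x_names):
        data[name] = ms.x_reps[:, j]
    for j, name in enumerate(y_names):
        data[name] = ms.y_reps[:, j]
    # default float formatting uses the shortest round-tripping repr
    pd.DataFrame(data).to_csv(path, index=False)
    return path
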