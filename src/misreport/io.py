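"""Schema-validated reading and writing of respondent and pregnancy tables.

Both tables travel as plain CSV.  Reading validates the header, rejects
malformed rows with their line numbers, and counts every exclusion
(nonpositive exposure, missing covariates) so that input rows always
reconcile as used + excluded — the complete-case accounting that survey
analyses report.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic import (
    OUTCOMES,
    PREGNANCY_BASE_COLUMNS,
    RESPONDENT_BASE_COLUMNS,
)

logger = logging.getLogger(__name__)


@dataclass
class ReadReport:
    """Accounting of one table read: rows in = used + rejected + excluded."""

    path: str
    n_input: int = 0
    n_used: int = 0
    rejected_lines: list[tuple[int, str]] = field(default_factory=list)
    n_nonpositive_exposure: int = 0

    @property
    def n_rejected(self) -> int:
        return len(self.rejected_lines)


def _read_rows(path: str | Path, required: list[str]) -> tuple[list[dict], list[str], ReadReport]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    report = ReadReport(path=str(path))
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ValueError(f"{path}: empty file") from None
        missing = [c for c in required if c not in header]
        if missing:
            raise ValueError(
                f"{path}: wrong header; expected columns {required}, "
                f"found {header} (missing {missing})"
            )
        rows = []
        for lineno, rec in enumerate(reader, start=2):
            if len(rec) != len(header):
                report.rejected_lines.append((lineno, "wrong field count"))
                continue
            rows.append(dict(zip(header, rec)))
        report.n_input = len(rows) + report.n_rejected
    if not rows and not report.rejected_lines:
        raise ValueError(f"{path}: no data rows")
    return rows, header, report


def read_respondents(path: str | Path) -> tuple[pd.DataFrame, ReadReport]:
    """Read and validate a respondent table; y_true is optional (real data)."""
    required = [c for c in RESPONDENT_BASE_COLUMNS if c != "y_true"]
    rows, header, report = _read_rows(path, required)
    keep = []
    for lineno, row in zip(_linenos(rows, report), rows):
        try:
            row["woman_id"] = row["woman_id"]
            row["y_reported"] = int(row["y_reported"])
            if "y_true" in row and row.get("y_true", "") != "":
                row["y_true"] = int(row["y_true"])
            row["t_exposure"] = float(row["t_exposure"])
            row["weight"] = float(row["weight"])
            if row["y_reported"] < 0 or row["weight"] <= 0:
                raise ValueError("negative count or nonpositive weight")
        except (ValueError, KeyError) as exc:
            report.rejected_lines.append((lineno, str(exc)))
            continue
        keep.append(row)
    df = pd.DataFrame(keep)
    if len(df):
        bad_t = df["t_exposure"] <= 0
        report.n_nonpositive_exposure = int(bad_t.sum())
        df = df.loc[~bad_t].reset_index(drop=True)
    report.n_used = len(df)
    _log_report(report)
    return df, report


def read_pregnancies(path: str | Path) -> tuple[pd.DataFrame, ReadReport]:
    rows, header, report = _read_rows(path, PREGNANCY_BASE_COLUMNS)
    keep = []
    for lineno, row in zip(_linenos(rows, report), rows):
        try:
            row["pregnancy_index"] = int(row["pregnancy_index"])
            if row["outcome"] not in OUTCOMES:
                raise ValueError(f"unknown outcome {row['outcome']!r}")
            if row["pregnancy_index"] < 1:
                raise ValueError("pregnancy_index must be >= 1")
        except (ValueError, KeyError) as exc:
            report.rejected_lines.append((lineno, str(exc)))
            continue
        keep.append(row)
    df = pd.DataFrame(keep)
    report.n_used = len(df)
    _log_report(report)
    return df, report


def _linenos(rows: list[dict], report: ReadReport) -> list[int]:
    # reconstruct data line numbers, skipping already-rejected physical lines
    rejected = {ln for ln, _ in report.rejected_lines}
    out, ln = [], 2
    for _ in rows:
        while ln in rejected:
            ln += 1
        out.append(ln)
        ln += 1
    return out


def _log_report(report: ReadReport) -> None:
    logger.info(
        "%s: %d rows in, %d used, %d rejected, %d with nonpositive exposure",
        report.path, report.n_input, report.n_used, report.n_rejected,
        report.n_nonpositive_exposure,
    )
    for lineno, reason in report.rejected_lines:
        logger.warning("%s line %d rejected: %s", report.path, lineno, reason)
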