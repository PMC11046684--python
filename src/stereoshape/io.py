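"""CSV table schemas and validated round-trip IO.

Three tidy tables flow through the pipeline (all plain CSV with a header
row; angles in degrees, lengths in cm, magnification in signed percent):

responses.csv
    participant_id, task {slant, shape}, axis {horizontal, vertical,
    uniform}, eye {left, right}, magnification_pct (signed), repetition,
    response (degrees for the slant task, a ratio for the shape task).
drawings.csv
    participant_id, spectacles {control, experimental}, object {phone,
    square}, left_cm, right_cm.
slant_reports.csv
    participant_id, spectacles, object, slanted {0, 1}, direction
    {left_closer, right_closer, none}; direction is none iff slanted = 0.
"""

from __future__ import annotations

from pathlib import Path
from typing import List

import numpy as np
import pandas as pd

RESPONSE_COLUMNS = [
    "participant_id", "task", "axis", "eye",
    "magnification_pct", "repetition", "response",
]
DRAWING_COLUMNS = ["participant_id", "spectacles", "object", "left_cm", "right_cm"]
REPORT_COLUMNS = ["participant_id", "spectacles", "object", "slanted", "direction"]


class SchemaError(ValueError):
    """A table violates its schema; the message lists offending rows."""


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def read_responses(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    problems = validate_responses(df)
    if problems:
        raise SchemaError("; ".join(problems))
    return df


def read_drawings(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    problems = validate_drawings(df)
    if problems:
        raise SchemaError("; ".join(problems))
    return df


def read_reports(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    problems = validate_reports(df)
    if problems:
        raise SchemaError("; ".join(problems))
    return df


def _check_columns(df: pd.DataFrame, expected: List[str]) -> List[str]:
    missing = [c for c in expected if c not in df.columns]
    return [f"missing column(s): {missing}"] if missing else []


def _rows_where(mask, message: str) -> List[str]:
    idx = list(np.nonzero(np.asarray(mask))[0][:5])
    if idx:
        return [f"{message} at row(s) {idx}"]
    return []


def validate_responses(df: pd.DataFrame) -> List[str]:
    problems = _check_columns(df, RESPONSE_COLUMNS)
    if problems:
        return problems
    problems += _rows_where(~df["task"].isin(["slant", "shape"]), "unknown task")
    problems += _rows_where(
        ~df["axis"].isin(["horizontal", "vertical", "uniform"]), "unknown axis"
    )
    problems += _rows_where(~df["eye"].isin(["left", "right"]), "unknown eye")
    problems += _rows_where(
        ~np.isfinite(df["response"].to_numpy(dtype=float)), "non-finite response"
    )
    shape = df[df["task"] == "shape"]
    if not shape.empty:
        problems += _rows_where(
            df["task"].eq("shape") & (df["response"] <= 0),
            "non-positive shape ratio",
        )
    return problems


def validate_drawings(df: pd.DataFrame) -> List[str]:
    problems = _check_columns(df, DRAWING_COLUMNS)
    if problems:
        return problems
    problems += _rows_where(
        ~df["spectacles"].isin(["control", "experimental"]), "unknown spectacles"
    )
    problems += _rows_where(
        (df["left_cm"] <= 0) | (df["right_cm"] <= 0), "non-positive side length"
    )
    return problems


def validate_reports(df: pd.DataFrame) -> List[str]:
    problems = _check_columns(df, REPORT_COLUMNS)
    if problems:
        return problems
    problems += _rows_where(~df["slanted"].isin([0, 1]), "slanted must be 0/1")
    problems += _rows_where(
        ~df["direction"].isin(["left_closer", "right_closer", "none"]),
        "unknown direction",
    )
    problems += _rows_where(
        (df["slanted"] == 0) != (df["direction"] == "none"),
        "direction must be 'none' iff slanted = 0",
    )
    return problems


def validate_tables(
    responses: str | Path | None = None,
    drawings: str | Path | None = None,
    reports: str | Path | None = None,
) -> List[str]:
    """Validate any of the three table files; returns all problems found."""
    problems: List[str] = []
    if responses is not None:
        problems += [f"responses: {p}"
                     for p in validate_responses(pd.read_csv(responses))]
    if drawings is not None:
        problems += [f"drawings: {p}"
                     for p in validate_drawings(pd.read_csv(drawings))]
    if reports is not None:
        problems += [f"reports: {p}"
                     for p in validate_reports(pd.read_csv(reports))]
    return problems
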