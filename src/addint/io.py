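"""Reading and writing the package's file formats.

Contingency tables travel as CSV with header ``group,a0b0,a1b0,a0b1,a1b1``
and rows ``cases,...`` / ``controls,...`` (or the JSON equivalent
``{"cases": [...], "controls": [...]}``).  Subject-level data is CSV with
columns ``outcome,factor_a,factor_b[,x1,x2,...]``.  Estimates are written
as JSON records (full precision) or a rounded human-readable table.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .model_fit import ContingencyTable2x4, InteractionEstimate, SubjectData

__all__ = [
    "TableFormatError",
    "read_table",
    "write_table",
    "read_subject_data",
    "write_subject_data",
    "write_estimates",
]

_HEADER = ["group", "a0b0", "a1b0", "a0b1", "a1b1"]


class TableFormatError(ValueError):
    """A data file does not match the documented format."""


def _parse_count(value: str, where: str) -> int:
    try:
        c = int(value)
    except ValueError as exc:
        raise TableFormatError(f"{where}: not an integer count: {value!r}") from exc
    if c < 0:
        raise TableFormatError(f"{where}: negative count {c}")
    return c


def read_table(path: str | Path) -> ContingencyTable2x4:
    """Read a 2x4 case-control table from CSV or JSON (by extension)."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        obj = json.loads(path.read_text())
        rows = {}
        for group in ("cases", "controls"):
            if group not in obj:
                raise TableFormatError(f"{path}: missing key {group!r}")
            vals = obj[group]
            if len(vals) != 4:
                raise TableFormatError(f"{path}: {group} must have 4 counts")
            rows[group] = tuple(
                _parse_count(str(v), f"{path}: {group}[{j}]")
                for j, v in enumerate(vals)
            )
        return ContingencyTable2x4(cases=rows["cases"], controls=rows["controls"])

    rows = {}
    with path.open(newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise TableFormatError(f"{path}: empty file") from None
        if [h.strip().lower() for h in header] != _HEADER:
            raise TableFormatError(
                f"{path}:1: expected header {','.join(_HEADER)!r}, "
                f"got {','.join(header)!r}"
            )
        for lineno, row in enumerate(reader, start=2):
            if not row or not any(cell.strip() for cell in row):
                continue
            group = row[0].strip().lower()
            if group not in ("cases", "controls"):
                raise TableFormatError(
                    f"{path}:{lineno}: group must be 'cases' or 'controls', "
                    f"got {row[0]!r}"
                )
            if len(row) != 5:
                raise TableFormatError(
                    f"{path}:{lineno}: expected 4 counts, got {len(row) - 1}"
                )
            rows[group] = tuple(
                _parse_count(v.strip(), f"{path}:{lineno}: column {_HEADER[j + 1]}")
                for j, v in enumerate(row[1:])
            )
    for group in ("cases", "controls"):
        if group not in rows:
            raise TableFormatError(f"{path}: missing row {group!r}")
    return ContingencyTable2x4(cases=rows["cases"], controls=rows["controls"])


def write_table(table: ContingencyTable2x4, path: str | Path) -> None:
    """Write a table as CSV or JSON (by extension); inverse of read_table."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        path.write_text(
            json.dumps({"cases": list(table.cases), "controls": list(table.controls)},
                       indent=1)
            + "\n"
        )
        return
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_HEADER)
        writer.writerow(["cases", *table.cases])
        writer.writerow(["controls", *table.controls])


def read_subject_data(path: str | Path) -> SubjectData:
    """Read subject-level records: outcome,factor_a,factor_b[,x1,x2,...]."""
    df = pd.read_csv(path)
    required = ["outcome", "factor_a", "factor_b"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise TableFormatError(f"{path}: missing column(s) {', '.join(missing)}")
    extra = [c for c in df.columns if c not in required]
    for col in required:
        bad = ~df[col].isin([0, 1])
        if bad.any():
            line = int(np.flatnonzero(bad)[0]) + 2  # header is line 1
            raise TableFormatError(
                f"{path}:{line}: {col} must be 0/1, got {df[col][bad].iloc[0]!r}"
            )
    return SubjectData(
        outcome=df["outcome"].to_numpy(),
        factor_a=df["factor_a"].to_numpy(),
        factor_b=df["factor_b"].to_numpy(),
        confounders=df[extra].to_numpy(dtype=float) if extra else None,
    )


def write_subject_data(data: SubjectData, path: str | Path) -> None:
    cols = {
        "outcome": data.outcome,
        "factor_a": data.factor_a,
        "factor_b": data.factor_b,
    }
    for i in range(data.n_confounders):
        cols[f"x{i + 1}"] = data.confounders[:, i]
    pd.DataFrame(cols).to_csv(path, index=False)


def write_estimates(
    estimates: list[InteractionEstimate],
    path: str | Path,
    provenance: dict | None = None,
) -> None:
    """Write estimates as a JSON document (full precision) with provenance."""
    doc = {
        "provenance": provenance or {},
        "estimates": [e.as_dict() for e in estimates],
    }
    Path(path).write_text(json.dumps(doc, indent=1, default=_json_default) + "\n")


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
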