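"""Delimited-text readers and writers with a fixed dialect.

Comma-separated, "." decimal point, header row required, UTF-8.  Numeric
columns are written with 17 significant digits so a write/read cycle is
bit-exact for float64.  Schema violations are reported with the
offending line number; locale-style decimal commas are rejected
explicitly rather than silently misparsed.
"""

from __future__ import annotations

import json
import re
from pathlib import Path

import numpy as np

from .exceptions import TableFormatError

__all__ = ["read_table", "write_table", "write_report"]

_DECIMAL_COMMA = re.compile(r"^-?\d+,\d+")


def read_table(path, columns: list[str], delimiter: str = ",") -> dict[str, np.ndarray]:
    """Read a delimited text table into arrays, validating the schema.

    Parameters
    ----------
    path : str or Path
        Input file.
    columns : list of str
        Required column names; the header must contain all of them (extra
        columns are ignored).

    Returns
    -------
    dict mapping each requested column name to a float64 array.
    """
    path = Path(path)
    with open(path, "r", encoding="utf-8") as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    lines = [ln for ln in lines if ln.strip() != ""]
    if not lines:
        raise TableFormatError(f"{path}: empty file")
    header = [h.strip() for h in lines[0].split(delimiter)]
    missing = [c for c in columns if c not in header]
    if missing:
        raise TableFormatError(f"{path}, line 1: missing required columns {missing} in header {header}")
    idx = {c: header.index(c) for c in columns}

    data: dict[str, list[float]] = {c: [] for c in columns}
    for lineno, line in enumerate(lines[1:], start=2):
        cells = [c.strip() for c in line.split(delimiter)]
        if len(cells) != len(header):
            raise TableFormatError(
                f"{path}, line {lineno}: expected {len(header)} fields, got {len(cells)}"
            )
        for col in columns:
            cell = cells[idx[col]]
            if _DECIMAL_COMMA.match(cell):
                raise TableFormatError(
                    f"{path}, line {lineno}: decimal comma in {cell!r}; use '.' as decimal separator"
                )
            try:
                data[col].append(float(cell))
            except ValueError as exc:
                raise TableFormatError(
                    f"{path}, line {lineno}: cannot parse {cell!r} in column {col!r}"
                ) from exc
    return {c: np.asarray(v, dtype=float) for c, v in data.items()}


def write_table(path, columns: dict, delimiter: str = ",") -> None:
    """Write named arrays as a delimited table at 17 significant digits."""
    path = Path(path)
    names = list(columns)
    arrays = [np.asarray(columns[n], dtype=float) for n in names]
    n = len(arrays[0])
    if any(len(a) != n for a in arrays):
        raise ValueError("all columns must have the same length")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(delimiter.join(names) + "\n")
        for i in range(n):
            fh.write(delimiter.join(f"{a[i]:.17g}" for a in arrays) + "\n")


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, slice):
        return [obj.start, obj.stop]
    return obj


def write_report(results: dict, out_dir) -> Path:
    """Write a structured JSON report plus a flat results table.

    Returns the path of ``report.json``.  Numeric leaves named
    ``value``/``error`` under each section also land in ``results.csv``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report_path = out_dir / "report.json"
    with open(report_path, "w", encoding="utf-8") as fh:
        json.dump(_jsonable(results), fh, indent=2, sort_keys=True)
        fh.write("\n")

    rows = []

    def walk(prefix, node):
        if isinstance(node, dict):
            for k, v in node.items():
                walk(f"{prefix}.{k}" if prefix else str(k), v)
        elif isinstance(node, (int, float, np.floating, np.integer)) and not isinstance(node, bool):
            rows.append((prefix, float(node)))

    walk("", results)
    with open(out_dir / "results.csv", "w", encoding="utf-8") as fh:
        fh.write("name,value\n")
        for name, value in rows:
            fh.write(f"{name},{value:.17g}\n")
    return report_path
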