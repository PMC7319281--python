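"""Delimited-file I/O for curve matrices and JSON/CSV report output."""

from __future__ import annotations

import csv
import dataclasses
import json
from pathlib import Path

import numpy as np

from .basis import CurveSet

__all__ = ["read_curve_matrix", "write_curve_matrix", "write_report"]


class CurveParseError(ValueError):
    """Raised when a curve-matrix file cannot be parsed; names the line."""


def _sniff_delimiter(path: Path) -> str:
    first = path.open().readline()
    return "\t" if ("\t" in first and "," not in first) else ","


def read_curve_matrix(path, delimiter: str | None = None,
                      header_grid: bool | None = None) -> CurveSet:
    """Read a delimited numeric matrix of curves (rows = subjects).

    The first row may optionally hold the observation grid.  With
    ``header_grid=None`` the grid row is auto-detected: a strictly increasing
    first row confined to [0, 1] is taken to be the grid; otherwise a uniform
    grid on [0, 1] is assumed.
    """
    path = Path(path)
    delimiter = delimiter or _sniff_delimiter(path)
    rows: list[list[float]] = []
    with path.open(newline="") as fh:
        for lineno, rec in enumerate(csv.reader(fh, delimiter=delimiter), start=1):
            if not rec or all(not c.strip() for c in rec):
                continue
            try:
                rows.append([float(c) for c in rec])
            except ValueError as exc:
                raise CurveParseError(
                    f"{path.name}:{lineno}: non-numeric cell ({exc})"
                ) from None
            if len(rows) > 1 and len(rows[-1]) != len(rows[0]):
                raise CurveParseError(
                    f"{path.name}:{lineno}: ragged row with {len(rows[-1])} "
                    f"cells, expected {len(rows[0])}"
                )
    if not rows:
        raise CurveParseError(f"{path.name}: empty file")
    mat = np.asarray(rows, dtype=float)
    first = mat[0]
    if header_grid is None:
        header_grid = bool(
            mat.shape[0] > 1
            and np.all(np.diff(first) > 0)
            and first.min() >= 0.0
            and first.max() <= 1.0
        )
    if header_grid:
        grid, values = mat[0], mat[1:]
    else:
        grid, values = np.linspace(0.0, 1.0, mat.shape[1]), mat
    return CurveSet(grid, values)


def write_curve_matrix(curves: CurveSet, path, delimiter: str = ",",
                       include_grid: bool = True) -> None:
    """Write a curve set as a delimited matrix, grid in the first row."""
    body = np.vstack([curves.grid, curves.values]) if include_grid else curves.values
    np.savetxt(path, body, delimiter=delimiter, fmt="%.12g")


def _to_jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer, np.bool_)):
        return obj.item()
    return obj


def write_report(result, path, extra: dict | None = None) -> None:
    """Write a test result (or any dataclass/dict) as JSON, or CSV by suffix."""
    path = Path(path)
    payload = _to_jsonable(result)
    if extra:
        payload = {**payload, **_to_jsonable(extra)}
    if path.suffix.lower() == ".csv":
        with path.open("w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(payload.keys())
            writer.writerow(payload.values())
    else:
        path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
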