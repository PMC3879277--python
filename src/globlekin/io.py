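"""Dataset I/O: the CSV dialect shared by the fitter, generators and CLI.

Dataset files are UTF-8 comma-separated tables with a header and columns

    cell_line, type, dose_Gy, dose_rate_Gy_per_h, fraction_dose_Gy, gap_h,
    surviving_fraction

``type`` is one of ``acute``, ``constant_rate`` or ``split``; columns not
used by a row's schedule type stay empty.  Numbers use a dot decimal
separator and are written with 10 significant digits.
"""

from __future__ import annotations

import math
import warnings
from pathlib import Path

import pandas as pd

from .fitting import SurvivalObservation
from .schedules import IrradiationSchedule

__all__ = ["read_dataset", "write_dataset", "DATASET_COLUMNS", "format_number"]

DATASET_COLUMNS = [
    "cell_line",
    "type",
    "dose_Gy",
    "dose_rate_Gy_per_h",
    "fraction_dose_Gy",
    "gap_h",
    "surviving_fraction",
]


def format_number(x: float) -> str:
    """Serialize a number with 10 significant digits (bit-stable outputs)."""
    return f"{x:.10g}"


def _require(row, col: str, line_no: int) -> float:
    v = row[col]
    if v is None or (isinstance(v, float) and math.isnan(v)) or v == "":
        raise ValueError(f"line {line_no}: column '{col}' is required for type '{row['type']}'")
    try:
        return float(v)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"line {line_no}: column '{col}' is not numeric: {v!r}") from exc


def read_dataset(path: str | Path) -> list[SurvivalObservation]:
    """Read and validate a survival dataset CSV.

    Rows with a non-positive surviving fraction are rejected with their line
    number (the fitter takes logarithms).  An empty data section yields an
    empty list with a warning.
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in DATASET_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns: {', '.join(missing)}")
    if df.empty:
        warnings.warn(f"{path}: dataset has a header but no rows", stacklevel=2)
        return []

    observations = []
    for idx, row in df.iterrows():
        line_no = idx + 2  # header is line 1
        kind = row["type"]
        s = _require(row, "surviving_fraction", line_no)
        if not 0.0 < s <= 1.0:
            raise ValueError(
                f"line {line_no}: surviving_fraction must lie in (0, 1], got {s}"
            )
        if kind == "acute":
            sched = IrradiationSchedule.acute(_require(row, "dose_Gy", line_no))
        elif kind == "constant_rate":
            sched = IrradiationSchedule.constant_rate(
                _require(row, "dose_Gy", line_no),
                _require(row, "dose_rate_Gy_per_h", line_no),
            )
        elif kind == "split":
            sched = IrradiationSchedule.split(
                _require(row, "fraction_dose_Gy", line_no),
                _require(row, "gap_h", line_no),
            )
        else:
            raise ValueError(f"line {line_no}: unknown schedule type {kind!r}")
        cell_line = row.get("cell_line")
        if isinstance(cell_line, float) and math.isnan(cell_line):
            cell_line = None
        observations.append(
            SurvivalObservation(sched, s, cell_line=cell_line)
        )
    return observations


def write_dataset(observations: list[SurvivalObservation], path: str | Path) -> None:
    """Write observations in the shared CSV dialect (LF line endings)."""
    rows = []
    for obs in observations:
        sched = obs.schedule
        row = {c: "" for c in DATASET_COLUMNS}
        row["cell_line"] = obs.cell_line or ""
        row["type"] = sched.kind
        if sched.kind == "acute":
            row["dose_Gy"] = format_number(sched.total_dose)
        elif sched.kind == "constant_rate":
            row["dose_Gy"] = format_number(sched.total_dose)
            row["dose_rate_Gy_per_h"] = format_number(sched.elements[0].dose_rate)
        elif sched.kind == "split":
            row["fraction_dose_Gy"] = format_number(sched.fraction_dose)
            row["gap_h"] = format_number(sched.gap)
        else:
            raise ValueError(
                f"schedule kind {sched.kind!r} has no CSV row representation"
            )
        row["surviving_fraction"] = format_number(obs.surviving_fraction)
        rows.append(row)
    pd.DataFrame(rows, columns=DATASET_COLUMNS).to_csv(
        path, index=False, lineterminator="\n"
    )
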