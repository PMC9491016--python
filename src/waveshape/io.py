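"""Delimited-text readers and writers for series, components and reports.

The interchange format is plain CSV: an optional ``#``-prefixed comment
header may carry the sampling rate (``# fs=625``); a first column that is
strictly monotonic and uniform is treated as time and used to infer the
sampling rate.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .analytic import UniformSeries
from .assess import ConditionReport
from .sift import ComponentSet

__all__ = ["read_series", "write_series", "write_components", "write_report"]

_REL_TOL_UNIFORM = 1e-6


def _header_fs(path: Path) -> float | None:
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if "fs=" in line:
                return float(line.split("fs=")[1].split()[0].rstrip(","))
    return None


def _read_table(path: Path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, comment="#")
    except pd.errors.ParserError as exc:
        raise ValueError(f"could not parse {path}: {exc}") from exc
    bad = df.columns[~df.dtypes.map(lambda d: np.issubdtype(d, np.number))]
    if len(bad):
        raise ValueError(f"non-numeric columns in {path}: {list(bad)}")
    return df


def _time_column(values: np.ndarray) -> float | None:
    """Sampling rate implied by a uniform, monotonic time column, else None."""
    dt = np.diff(values)
    if len(dt) == 0 or np.any(dt <= 0):
        return None
    if np.ptp(dt) > _REL_TOL_UNIFORM * dt.mean():
        return None
    return 1.0 / dt.mean()


def read_series(path, fs_override: float | None = None) -> UniformSeries | ComponentSet:
    """Read a CSV into a :class:`UniformSeries` or :class:`ComponentSet`.

    Column layout:

    * one column — a single channel (``fs`` from override or ``# fs=``
      header);
    * first column monotonic and uniform — time; remaining column(s) are
      the channel(s), ``fs`` inferred from it (a non-uniform time column
      is an error);
    * several data columns — a component matrix whose last column is the
      residual (as written by :func:`write_components`).
    """
    path = Path(path)
    df = _read_table(path)
    fs = fs_override or _header_fs(path)

    cols = [df[c].to_numpy(dtype=float) for c in df.columns]
    inferred = _time_column(cols[0]) if len(cols) >= 2 else None
    if inferred is not None:
        t0 = float(cols[0][0])
        fs = fs or inferred
        if abs(fs - inferred) > _REL_TOL_UNIFORM * inferred:
            raise ValueError(
                f"time column implies fs={inferred:g} Hz, conflicting with {fs:g}"
            )
        cols = cols[1:]
    elif fs is None:
        raise ValueError(
            f"{path} has no usable time column; pass fs_override or a '# fs=' header"
        )
    else:
        t0 = 0.0

    if len(cols) == 1:
        return UniformSeries(cols[0], fs, t0)
    matrix = np.column_stack(cols)
    return ComponentSet(matrix[:, :-1], matrix[:, -1], fs)


def write_series(x: UniformSeries, path) -> None:
    """Two-column CSV (time, value) with the sampling rate in a comment."""
    with open(path, "w") as fh:
        fh.write(f"# fs={x.fs:g}\n")
        pd.DataFrame({"time_s": x.times, "value": x.values}).to_csv(fh, index=False)


def write_components(c: ComponentSet, path) -> None:
    """One column per IMF plus the residual, sampling rate in a comment."""
    data = {f"imf{i}": c.components[:, i] for i in range(c.n_components)}
    data["residual"] = c.residual
    with open(path, "w") as fh:
        fh.write(f"# fs={c.fs:g}\n")
        pd.DataFrame(data).to_csv(fh, index=False)


_TABLE_COLUMNS = ("IF", "IA", "DCor", "omega", "a")


def _report_record(r: ConditionReport) -> dict:
    rec = dataclasses.asdict(r)
    rec["verdict"] = r.verdict.value
    rec["pair"] = list(r.pair)
    return rec


def _round6(obj):
    if isinstance(obj, float):
        return float(f"{obj:.6g}")
    if isinstance(obj, list):
        return [_round6(v) for v in obj]
    if isinstance(obj, dict):
        return {k: _round6(v) for k, v in obj.items()}
    return obj


def write_report(reports: list[ConditionReport], path, format: str = "json") -> None:
    """Serialise pair reports as JSON, CSV, or an aligned text table.

    Field order is deterministic and floats are limited to six significant
    digits, so repeated runs produce byte-identical files.  The table
    format mirrors the conventional per-IMF summary (frequency and
    amplitude ratios, distance correlation).
    """
    records = [_round6(_report_record(r)) for r in reports]
    if format == "json":
        with open(path, "w") as fh:
            json.dump(records, fh, indent=2, sort_keys=True)
            fh.write("\n")
    elif format == "csv":
        flat = []
        for rec in records:
            rec = dict(rec)
            rec["hf_index"], rec["base_index"] = rec.pop("pair")
            flat.append(rec)
        pd.DataFrame(flat).to_csv(path, index=False)
    elif format == "table":
        lines = ["pair      omega          a          DCor     aw     verdict"]
        for r in reports:
            lines.append(
                f"{r.pair[0]}->{r.pair[1]}   "
                f"{r.freq_ratio_mean:6.2f} ({r.freq_ratio_sd:.2f})  "
                f"{r.amp_ratio_mean:5.2f} ({r.amp_ratio_sd:.2f})  "
                f"{r.dcor:6.3f}  {r.aw_mean:5.2f}   {r.verdict.value}"
            )
        Path(path).write_text("\n".join(lines) + "\n")
    else:
        raise ValueError(f"unknown report format {format!r}")
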