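"""Readers and writers for the pipeline's text formats.

Bond-length time series travel as 4-column delimited text
(time_ps, B1, B2, B3) with a header, or in the GROMACS XVG dialect
(whitespace-separated, ``#``/``@`` comment lines, no header).  Events and
speed statistics are written as CSV; pipeline reports as JSON.  All numeric
round-trips are lossless (floats serialised at full precision).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .timeseries import BOND_NAMES, BondSeries, SeparationEvent, SpeedStats

__all__ = [
    "read_bond_series",
    "write_bond_series",
    "events_to_frame",
    "write_events",
    "read_events",
    "stats_to_frame",
    "write_speed_stats",
    "write_report",
    "read_report",
]

_COLUMNS = ["time_ps", "B1", "B2", "B3"]


def _sniff_sep(path: Path) -> str:
    """Delimiter of the first non-comment line: tab, comma or whitespace."""
    for line in path.read_text().splitlines():
        if line.strip() and not line.lstrip().startswith("#"):
            if "\t" in line:
                return "\t"
            if "," in line:
                return ","
            return r"\s+"
    return ","


def read_table(path: str | Path) -> pd.DataFrame:
    """Delimited text with lossless (correctly rounded) float parsing."""
    path = Path(path)
    sep = _sniff_sep(path)
    kwargs = {"comment": "#", "sep": sep}
    if sep != r"\s+":
        kwargs["float_precision"] = "round_trip"
    return pd.read_csv(path, **kwargs)


def read_bond_series(
    path: str | Path,
    dialect: str = "csv",
    base_pair_id: str = "G1-C1",
    force: float = 0.0,
    replica_id: str = "r0",
) -> BondSeries:
    """Read a bond-length time series (``csv`` or GROMACS-style ``xvg``)."""
    path = Path(path)
    if dialect == "csv":
        df = read_table(path)
        missing = [c for c in _COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"{path}: missing columns {missing}")
    elif dialect == "xvg":
        rows = []
        for line in path.read_text().splitlines():
            line = line.strip()
            if not line or line.startswith(("#", "@")):
                continue
            rows.append([float(x) for x in line.split()])
        arr = np.asarray(rows, dtype=float)
        if arr.ndim != 2 or arr.shape[1] < 4:
            raise ValueError(f"{path}: xvg needs 4 numeric columns (time, B1, B2, B3)")
        df = pd.DataFrame(arr[:, :4], columns=_COLUMNS)
    else:
        raise ValueError(f"unknown dialect {dialect!r}; use 'csv' or 'xvg'")
    return BondSeries(
        time=df["time_ps"].to_numpy(),
        lengths={b: df[b].to_numpy() for b in BOND_NAMES},
        base_pair_id=base_pair_id,
        force=force,
        replica_id=replica_id,
    )


def write_bond_series(series: BondSeries, path: str | Path) -> None:
    df = pd.DataFrame(
        {"time_ps": series.time, **{b: series.lengths[b] for b in BOND_NAMES}}
    )
    df.to_csv(path, index=False, float_format="%.17g")


def events_to_frame(
    events: Sequence[SeparationEvent], replica_id: str = "r0",
    base_pair_id: str = "G1-C1", force: float = 0.0,
) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "replica_id": replica_id,
                "base_pair_id": base_pair_id,
                "force": force,
                "start_index": ev.start_index,
                "end_index": ev.end_index,
                "peak_index": ev.peak_index,
                "slope": ev.slope,
                "slope_stderr": ev.slope_stderr,
                "accepted": ev.accepted,
                "reject_reason": ev.reject_reason or "",
                "partial": ev.partial,
            }
            for ev in events
        ]
    )


def write_events(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False, float_format="%.17g")


def read_events(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, keep_default_na=False, float_precision="round_trip",
                       dtype={"reject_reason": str})


def stats_to_frame(groups: Sequence[SpeedStats], pooled: SpeedStats) -> pd.DataFrame:
    rows = [vars(g) for g in groups] + [vars(pooled)]
    return pd.DataFrame(rows)


def write_speed_stats(groups, pooled, path: str | Path) -> None:
    stats_to_frame(groups, pooled).to_csv(path, index=False, float_format="%.17g")


def write_report(report: dict, path: str | Path) -> None:
    """JSON report with sorted keys; repeated runs are byte-identical."""
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")


def read_report(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
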