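"""CSV readers/writers for the table schemas and optional FCS support.

All tables are plain CSV with a header row:

* flow events: ``event_id,area,width``
* PI histograms: ``channel,count``
* colony counts: ``dose_gy,dish_id,cells_seeded,colonies``
* OD plates: ``well,row,col,condition,dose_gy,od562``
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .cellcycle import PIHistogram
from .errors import InputError

__all__ = [
    "read_events_csv",
    "write_events_csv",
    "read_histogram_csv",
    "write_histogram_csv",
    "read_colony_csv",
    "write_colony_csv",
    "read_od_csv",
    "write_od_csv",
    "read_events_fcs",
]

EVENT_COLUMNS = ("event_id", "area", "width")


def _require(path: str | Path) -> Path:
    p = Path(path)
    if not p.exists():
        raise InputError(f"input file not found: {p}")
    return p


def read_events_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(_require(path))
    missing = set(EVENT_COLUMNS) - set(df.columns)
    if missing:
        raise InputError(f"event CSV missing columns: {sorted(missing)}")
    if (df["area"] < 0).any() or (df["width"] < 0).any():
        raise InputError("event areas and widths must be >= 0")
    return df


def write_events_csv(events: pd.DataFrame, path: str | Path) -> None:
    events.loc[:, list(EVENT_COLUMNS)].to_csv(path, index=False)


def read_histogram_csv(path: str | Path) -> PIHistogram:
    return PIHistogram.from_frame(pd.read_csv(_require(path)))


def write_histogram_csv(hist: PIHistogram, path: str | Path) -> None:
    hist.to_frame().to_csv(path, index=False)


def read_colony_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(_require(path))


def write_colony_csv(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False)


def read_od_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(_require(path))
    if "dose_gy" in df.columns:
        df["dose_gy"] = pd.to_numeric(df["dose_gy"], errors="coerce")
    return df


def write_od_csv(plate: pd.DataFrame, path: str | Path) -> None:
    plate.to_csv(path, index=False)


def read_events_fcs(
    path: str | Path, area_channel: str = "FL2-A", width_channel: str = "FL2-W"
) -> pd.DataFrame:
    """Read an FCS 3.0/3.1 file into the event-table schema.

    Requires the optional ``fcsparser`` dependency; CSV input needs no
    extras.
    """
    try:
        import fcsparser  # type: ignore[import-not-found]
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise InputError(
            "FCS input requires the optional 'fcsparser' package; "
            "convert to the event CSV schema instead"
        ) from exc
    _, data = fcsparser.parse(str(_require(path)))  # pragma: no cover
    for ch in (area_channel, width_channel):  # pragma: no cover
        if ch not in data.columns:
            raise InputError(f"channel {ch!r} not present in FCS file")
    return pd.DataFrame(  # pragma: no cover
        {
            "event_id": np.arange(len(data)),
            "area": np.asarray(data[area_channel], dtype=float),
            "width": np.asarray(data[width_channel], dtype=float),
        }
    )
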