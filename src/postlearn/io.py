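"""Reading and writing posting timelines and result artifacts.

Timelines travel as CSV (columns user_id, timestamp, likes; header
required) or JSON Lines with the same fields.  Timestamps are either
numeric hours since an arbitrary epoch or ISO 8601 strings, which are
converted to hours.  Fits and traces serialize to JSON.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from postlearn.model import AgentParams, ModelTrace, PostTimeline

__all__ = [
    "read_timelines",
    "write_timelines",
    "timelines_to_frame",
    "write_json",
]

_COLUMNS = ["user_id", "timestamp", "likes"]


def _to_hours(ts: pd.Series) -> np.ndarray:
    if pd.api.types.is_numeric_dtype(ts):
        return ts.to_numpy(dtype=float)
    parsed = pd.to_datetime(ts, utc=True, format="ISO8601")
    return (parsed.astype("int64") / 3.6e12).to_numpy()  # ns -> hours


def timelines_to_frame(timelines: list[PostTimeline]) -> pd.DataFrame:
    frames = [
        pd.DataFrame(
            {"user_id": tl.user_id, "timestamp": tl.timestamps, "likes": tl.likes}
        )
        for tl in timelines
    ]
    return pd.concat(frames, ignore_index=True)


def read_timelines(path: str | Path) -> list[PostTimeline]:
    """Load timelines from a CSV or JSON Lines file (by extension)."""
    path = Path(path)
    if path.suffix.lower() in (".jsonl", ".ndjson"):
        df = pd.read_json(path, lines=True)
    else:
        df = pd.read_csv(path)
    missing = set(_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"timeline file missing columns: {sorted(missing)}")
    out = []
    for uid, g in df.groupby("user_id", sort=False):
        g = g.sort_values("timestamp", kind="stable") if pd.api.types.is_numeric_dtype(
            g["timestamp"]
        ) else g
        out.append(
            PostTimeline(
                user_id=str(uid),
                timestamps=_to_hours(g["timestamp"]),
                likes=g["likes"].to_numpy(dtype=float),
            )
        )
    return out


def write_timelines(
    timelines: list[PostTimeline], path: str | Path, fmt: str | None = None
) -> None:
    """Write timelines as CSV (default) or JSON Lines ('jsonl')."""
    path = Path(path)
    df = timelines_to_frame(timelines)
    fmt = fmt or ("jsonl" if path.suffix.lower() in (".jsonl", ".ndjson") else "csv")
    if fmt == "jsonl":
        df.to_json(path, orient="records", lines=True)
    else:
        df.to_csv(path, index=False)


class _Encoder(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, (AgentParams, ModelTrace)) or dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        if isinstance(o, pd.DataFrame):
            return o.to_dict(orient="records")
        return super().default(o)


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, cls=_Encoder, indent=2))
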