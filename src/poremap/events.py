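"""First-poration event records and their CSV schema."""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path

import pandas as pd

EVENT_COLUMNS = ["membrane_id", "system", "replica", "t_ns", "x_rel", "y_rel", "censored"]


@dataclass
class PorationEvent:
    """One first-poration observation.

    ``x_rel``/``y_rel`` are pore coordinates relative to the box dimensions
    at the poration time, in [0, 1). ``t_ns`` is the first-poration time; for
    a censored record it is the censoring time and no pore location is
    meaningful (NaN).
    """

    membrane_id: str
    system: str
    replica: int
    t_ns: float
    x_rel: float
    y_rel: float
    censored: bool = False

    def __post_init__(self) -> None:
        if not self.censored:
            if not (0.0 <= self.x_rel < 1.0 and 0.0 <= self.y_rel < 1.0):
                raise ValueError("relative pore coordinates must lie in [0, 1)")
            if self.t_ns <= 0:
                raise ValueError("poration time must be positive")


def events_to_frame(events: list[PorationEvent]) -> pd.DataFrame:
    return pd.DataFrame([asdict(e) for e in events], columns=EVENT_COLUMNS)


def write_events(events: list[PorationEvent] | pd.DataFrame, path: str | Path) -> None:
    df = events if isinstance(events, pd.DataFrame) else events_to_frame(events)
    df.to_csv(path, index=False)


def read_events(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(EVENT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"event table {path} lacks columns: {sorted(missing)}")
    df["censored"] = df["censored"].astype(bool)
    return df
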