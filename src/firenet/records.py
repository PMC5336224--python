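"""Fire-list records: one simulated ignition with its burning conditions."""

from __future__ import annotations

from dataclasses import dataclass, asdict

import pandas as pd

__all__ = ["FireRecord", "firelist_to_frame", "frame_to_firelist"]

FIRELIST_COLUMNS = [
    "fire_id", "x", "y", "year", "doy", "cause", "erc", "wind_speed",
    "wind_dir", "fm1", "fm10", "fm100", "burn_period_min", "expected_size_ha",
]


@dataclass
class FireRecord:
    fire_id: int
    x: float  # map m
    y: float
    year: int  # simulation season index
    doy: int
    cause: str  # "human" | "natural"
    erc: float
    wind_speed: float  # km/h gust
    wind_dir: float  # degrees, direction wind blows toward
    fm1: float  # 1-h dead fuel moisture, fraction
    fm10: float
    fm100: float
    burn_period_min: float
    expected_size_ha: float

    def __post_init__(self) -> None:
        if self.burn_period_min <= 0:
            raise ValueError("burn_period_min must be positive")
        if self.expected_size_ha <= 0:
            raise ValueError("expected_size_ha must be positive")


def firelist_to_frame(records: list[FireRecord]) -> pd.DataFrame:
    if not records:
        return pd.DataFrame(columns=FIRELIST_COLUMNS)
    return pd.DataFrame([asdict(r) for r in records])[FIRELIST_COLUMNS]


def frame_to_firelist(df: pd.DataFrame) -> list[FireRecord]:
    return [FireRecord(**{k: row[k] for k in FIRELIST_COLUMNS})
            for _, row in df.iterrows()]
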