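"""Fire-list generation: turning fitted models into simulation seasons.

For each simulated season a daily ERC trajectory is resampled from the
weather library (one historical-style year drawn at random). Ignitions
are drawn per cause from the occurrence model's daily intensities; each
ignition's burning conditions come from an ERC-matched historical-style
day, with wind restricted to the gust subset observed on large-fire days,
and fuel moisture from the ERC-conditional mean table. The size model
supplies an expected fire size (draws below the minimum modelled size are
discarded) and the burn-period curve converts size to spread duration.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .burnperiod import BurnPeriodCurve
from .grid import LandscapeGrid
from .occurrence import FireSizeResults, IgnitionOccurrenceResults
from .records import FireRecord

__all__ = ["generate_fire_list", "large_fire_gust_subset"]


def large_fire_gust_subset(
    weather: pd.DataFrame,
    catalogue: pd.DataFrame | None,
    large_fire_ha: float = 500.0,
    min_days: int = 10,
) -> pd.DataFrame:
    """Wind observations from days on which large fires burned.

    Falls back to the windiest tail implied by high fire danger (the top
    decile of ERC days) when the catalogue contains too few large-fire
    days to form a sample.
    """
    if catalogue is not None and len(catalogue):
        big = catalogue[catalogue["final_size"] > large_fire_ha]
        days = set(zip(big["year"], big["doy"]))
        mask = [
            (y, d) in days for y, d in zip(weather["year"], weather["doy"])
        ]
        sub = weather[np.asarray(mask)]
        if len(sub) >= min_days:
            return sub[["wind_speed", "wind_dir"]].reset_index(drop=True)
    thresh = weather["erc"].quantile(0.9)
    return weather.loc[weather["erc"] >= thresh,
                       ["wind_speed", "wind_dir"]].reset_index(drop=True)


def _erc_conditional_moisture(weather: pd.DataFrame) -> pd.DataFrame:
    """Mean fuel moisture by integer ERC, forward/back-filled."""
    tab = (
        weather.assign(erc_bin=weather["erc"].round().astype(int))
        .groupby("erc_bin")[["fm1", "fm10", "fm100"]]
        .mean()
        .reindex(range(0, 101))
        .ffill()
        .bfill()
    )
    return tab


def generate_fire_list(
    occurrence: dict[str, IgnitionOccurrenceResults],
    size: dict[str, FireSizeResults],
    curve: BurnPeriodCurve,
    weather_library: pd.DataFrame,
    grid: LandscapeGrid,
    n_seasons: int,
    seed: int = 0,
    min_size: float = 10.0,
    catalogue: pd.DataFrame | None = None,
    large_fire_ha: float = 500.0,
) -> list[FireRecord]:
    """Draw ``n_seasons`` of fires from the fitted prediction system.

    Returns FireRecords with ``year`` set to the 0-based season index.
    Fires whose sampled size falls below ``min_size`` ha are discarded
    (the prediction system models fires above the minimum size only).
    """
    if weather_library.empty:
        raise ValueError("weather library is empty")
    if n_seasons < 0:
        raise ValueError("n_seasons must be >= 0")
    rng = np.random.default_rng(seed)
    gusts = large_fire_gust_subset(weather_library, catalogue, large_fire_ha)
    fm_table = _erc_conditional_moisture(weather_library)
    years = np.sort(weather_library["year"].unique())

    # per-cause spatial sampling weights are season-independent because the
    # occurrence logit separates into spatial + daily parts
    cell_w = {}
    for cause, occ in occurrence.items():
        s = occ.cell_logits()
        w = np.exp(s - s.max())
        cell_w[cause] = w / w.sum()

    records: list[FireRecord] = []
    fire_id = 0
    x0, y0 = grid.origin
    for season in range(n_seasons):
        yr = years[rng.integers(0, len(years))]
        wx = weather_library[weather_library["year"] == yr]
        doy = wx["doy"].to_numpy()
        erc = wx["erc"].to_numpy()
        for cause, occ in occurrence.items():
            lam = occ.expected_daily_count(doy, erc)
            counts = rng.poisson(lam)
            total = int(counts.sum())
            if total == 0:
                continue
            day_idx = np.repeat(np.arange(len(doy)), counts)
            cells = rng.choice(grid.n_cells, size=total, p=cell_w[cause])
            rr, cc = np.divmod(cells, grid.n_cols)
            xs = x0 + (cc + rng.random(total)) * grid.cell_size
            ys = y0 + (rr + rng.random(total)) * grid.cell_size
            g = gusts.iloc[rng.integers(0, len(gusts), total)]
            sizes = size[cause].sample_size(xs, ys, erc[day_idx], rng)
            for i in range(total):
                if sizes[i] < min_size:
                    continue
                e = float(erc[day_idx[i]])
                fm = fm_table.loc[int(np.clip(round(e), 0, 100))]
                records.append(
                    FireRecord(
                        fire_id=fire_id,
                        x=float(xs[i]),
                        y=float(ys[i]),
                        year=season,
                        doy=int(doy[day_idx[i]]),
                        cause=cause,
                        erc=e,
                        wind_speed=float(g["wind_speed"].iloc[i]),
                        wind_dir=float(g["wind_dir"].iloc[i]),
                        fm1=float(fm["fm1"]),
                        fm10=float(fm["fm10"]),
                        fm100=float(fm["fm100"]),
                        burn_period_min=float(curve.burn_period(sizes[i])),
                        expected_size_ha=float(sizes[i]),
                    )
                )
                fire_id += 1
    return records
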