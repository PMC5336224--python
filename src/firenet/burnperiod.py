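"""Burn-period calibration: mapping expected fire size to burn duration.

The MTT simulator needs a burn period (minutes of active spread) for each
fire, but the ignition models predict a final size. The link is built
empirically, in the same spirit as calibrating a growth model against
controlled runs: fires are simulated at several fixed durations under
sampled weather, the median final size at each duration is recorded, and
a power law ``size = a * duration**b`` is fitted by log-log least
squares. Its inverse supplies the burn period for any target size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grid import LandscapeGrid
from .spread import moisture_factor, spread_arrival

__all__ = ["BurnPeriodCurve", "calibrate_burn_period", "CalibrationError"]


class CalibrationError(RuntimeError):
    pass


@dataclass
class BurnPeriodCurve:
    """Monotone power-law mapping between fire size and burn period.

    ``size_ha = a * duration_min**b`` with a, b > 0; the inverse
    ``burn_period(size) = (size / a)**(1/b)`` is strictly increasing.
    """

    a: float
    b: float
    calibration_points: pd.DataFrame | None = None  # duration_min, median_size_ha

    def __post_init__(self) -> None:
        if self.a <= 0 or self.b <= 0:
            raise ValueError("power-law coefficients must be positive")

    def size(self, duration_min) -> np.ndarray:
        return self.a * np.asarray(duration_min, float) ** self.b

    def burn_period(self, size_ha) -> np.ndarray:
        """Minutes of spread needed to reach ``size_ha``."""
        return (np.asarray(size_ha, float) / self.a) ** (1.0 / self.b)


def fit_power_law(durations, sizes) -> tuple[float, float]:
    """Least-squares fit of log(size) on log(duration)."""
    ld, ls = np.log(durations), np.log(sizes)
    b, loga = np.polyfit(ld, ls, 1)
    return float(np.exp(loga)), float(b)


def calibrate_burn_period(
    grid: LandscapeGrid,
    conditions: pd.DataFrame,
    durations: list[float],
    seed: int = 0,
    n_ignitions: int = 12,
    neighbors: int = 16,
) -> BurnPeriodCurve:
    """Build the size-duration curve from controlled spread simulations.

    Parameters
    ----------
    conditions : sample of weather days (columns erc, wind_speed,
        wind_dir, fm1) under which the controlled fires burn.
    durations : fixed burn periods (minutes), at least 3.
    n_ignitions : random burnable ignition points per duration (>= 5).
    """
    if len(durations) < 3:
        raise ValueError("need >= 3 calibration durations")
    if n_ignitions < 5:
        raise ValueError("need >= 5 ignition points")
    if conditions.empty:
        raise ValueError("empty conditions sample")
    rng = np.random.default_rng(seed)
    burnable = np.flatnonzero(grid.base_rate.ravel() > 0)
    if burnable.size == 0:
        raise CalibrationError("landscape has no burnable cells")
    cells = rng.choice(burnable, size=n_ignitions, replace=burnable.size < n_ignitions)
    days = conditions.iloc[rng.integers(0, len(conditions), n_ignitions)]

    med_sizes = []
    for T in durations:
        sizes = []
        for cell, (_, day) in zip(cells, days.iterrows()):
            burned, _, _ = spread_arrival(
                grid, int(cell), float(day["wind_speed"]), float(day["wind_dir"]),
                moisture_factor(float(day["fm1"])), float(T), neighbors,
            )
            sizes.append(burned.size * grid.cell_area_ha)
        med_sizes.append(float(np.median(sizes)))
    if max(med_sizes) <= 0:
        raise CalibrationError("all controlled simulations burned zero area")
    a, b = fit_power_law(np.asarray(durations, float), np.asarray(med_sizes))
    if b <= 0:
        raise CalibrationError(f"non-increasing size-duration relation (b={b:.3f})")
    points = pd.DataFrame({"duration_min": durations, "median_size_ha": med_sizes})
    return BurnPeriodCurve(a, b, points)
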