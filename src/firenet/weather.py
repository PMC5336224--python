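"""Daily fire-weather series: ERC, wind gusts, fuel moisture.

ERC (energy release component) is the daily fuel-dryness index that drives
both ignition probability and fire growth conditions. The generator
produces a seasonal sinusoid peaking in mid-July plus AR(1) noise, clipped
to the index's [0, 100] range. Dead fuel moisture (1-h, 10-h, 100-h size
classes) is a decreasing function of ERC; wind gust speeds are lognormal
with a uniform direction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["WeatherParams", "generate_weather", "fuel_moisture_from_erc"]

DAYS_PER_YEAR = 365
#: day-of-year at which the seasonal ERC cycle peaks (mid-July)
ERC_PEAK_DOY = 196


@dataclass
class WeatherParams:
    erc_mean: float = 45.0  # seasonal midline of the ERC cycle
    erc_amplitude: float = 30.0  # seasonal half-range
    erc_noise_sd: float = 10.0  # marginal sd of the AR(1) component
    erc_ar1: float = 0.8  # day-to-day autocorrelation
    wind_log_mean: float = np.log(18.0)  # lognormal gust speed, km/h
    wind_log_sd: float = 0.5

    def __post_init__(self) -> None:
        if not 0 <= self.erc_ar1 < 1:
            raise ValueError("erc_ar1 must be in [0, 1)")
        if self.erc_noise_sd < 0 or self.erc_amplitude < 0:
            raise ValueError("negative dispersion parameter")


def fuel_moisture_from_erc(erc) -> pd.DataFrame:
    """Mean dead fuel moisture (fraction) by size class, given ERC.

    Linear decrease with ERC, floored well above zero; the three size
    classes are offset (coarser fuels stay wetter). Non-increasing in ERC
    by construction, matching the use of ERC as a dryness index.
    """
    erc = np.asarray(erc, dtype=float)
    fm1 = np.clip(0.25 - 0.0022 * erc, 0.03, None)
    return pd.DataFrame({"fm1": fm1, "fm10": fm1 + 0.02, "fm100": fm1 + 0.04})


def generate_weather(
    n_years: int,
    seed: int = 0,
    params: WeatherParams | None = None,
) -> pd.DataFrame:
    """Simulate ``n_years`` of daily weather.

    Returns a DataFrame with columns ``year`` (0-based), ``doy`` (1-365),
    ``erc``, ``wind_speed`` (km/h gust), ``wind_dir`` (degrees, direction
    the wind blows toward), ``fm1``, ``fm10``, ``fm100`` (fractions).
    """
    if n_years < 1:
        raise ValueError("n_years must be >= 1")
    p = params or WeatherParams()
    rng = np.random.default_rng(seed)
    n = n_years * DAYS_PER_YEAR

    doy = np.tile(np.arange(1, DAYS_PER_YEAR + 1), n_years)
    year = np.repeat(np.arange(n_years), DAYS_PER_YEAR)

    seasonal = p.erc_mean + p.erc_amplitude * np.cos(
        2 * np.pi * (doy - ERC_PEAK_DOY) / DAYS_PER_YEAR
    )
    noise = np.empty(n)
    z = rng.standard_normal(n)
    noise[0] = p.erc_noise_sd * z[0]
    innov_sd = p.erc_noise_sd * np.sqrt(1 - p.erc_ar1 ** 2)
    for t in range(1, n):
        noise[t] = p.erc_ar1 * noise[t - 1] + innov_sd * z[t]
    erc = np.clip(seasonal + noise, 0.0, 100.0)

    wind_speed = rng.lognormal(p.wind_log_mean, p.wind_log_sd, n)
    wind_dir = rng.uniform(0.0, 360.0, n)

    out = pd.DataFrame(
        {"year": year, "doy": doy, "erc": erc,
         "wind_speed": wind_speed, "wind_dir": wind_dir}
    )
    return pd.concat([out, fuel_moisture_from_erc(erc)], axis=1)
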