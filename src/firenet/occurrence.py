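"""Spatiotemporal ignition occurrence and fire-size models.

The occurrence model is a logistic regression for the daily per-pixel
probability of an ignition as a function of ERC, location and day of
year: a quadratic tensor basis in normalized (x, y), a periodic harmonic
basis in day-of-year (continuous across the year boundary), and a linear
ERC term. Because fire pixel-days are extremely rare, the model is fitted
on a case/control sample — every ignition pixel-day plus a seeded random
subsample of non-fire pixel-days — with the intercept offset-corrected
back to the full pixel-day probability scale.

The size model is an ordinary least-squares regression of log final fire
size on the same ERC and spatial terms, fitted to fires above a minimum
modelled size (10 ha by default).

Both follow the statsmodels pattern: a Model is built from data and
``fit()`` returns a Results object carrying estimates, uncertainties and
a ``summary()`` table.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .grid import LandscapeGrid
from .weather import DAYS_PER_YEAR

__all__ = [
    "FitError",
    "IgnitionOccurrenceModel",
    "IgnitionOccurrenceResults",
    "FireSizeModel",
    "FireSizeResults",
]


class FitError(RuntimeError):
    """Model fitting failed (non-convergence or degenerate design)."""


def _normalize_xy(x, y, grid: LandscapeGrid):
    x0, y0 = grid.origin
    sx = 2.0 * (np.asarray(x, float) - x0) / (grid.n_cols * grid.cell_size) - 1.0
    sy = 2.0 * (np.asarray(y, float) - y0) / (grid.n_rows * grid.cell_size) - 1.0
    return sx, sy


def spatial_basis(x, y, grid: LandscapeGrid, degree: int = 2) -> pd.DataFrame:
    """Tensor polynomial basis in grid-normalized coordinates."""
    sx, sy = _normalize_xy(x, y, grid)
    cols = {"sx": sx, "sy": sy}
    if degree >= 2:
        cols.update({"sx2": sx ** 2, "sy2": sy ** 2, "sxy": sx * sy})
    return pd.DataFrame(cols)


def seasonal_basis(doy, n_harmonics: int = 2) -> pd.DataFrame:
    """Periodic harmonics of day-of-year, continuous at the year boundary."""
    d = np.asarray(doy, float)
    cols = {}
    for k in range(1, n_harmonics + 1):
        ang = 2.0 * np.pi * k * d / DAYS_PER_YEAR
        cols[f"sin{k}"] = np.sin(ang)
        cols[f"cos{k}"] = np.cos(ang)
    return pd.DataFrame(cols)


class IgnitionOccurrenceModel:
    """Case/control logistic model of daily per-pixel ignition probability.

    Parameters
    ----------
    catalogue : ignition records (columns x, y, year, doy, cause, erc).
    weather : daily series covering the catalogue years.
    grid : landscape defining the pixel universe and coordinate scaling.
    cause : "human" or "natural"; only records of this cause are cases.
    control_ratio : controls sampled per case (default 10).
    """

    def __init__(
        self,
        catalogue: pd.DataFrame,
        weather: pd.DataFrame,
        grid: LandscapeGrid,
        cause: str,
        control_ratio: int = 10,
        spatial_degree: int = 2,
        n_harmonics: int = 2,
        seed: int = 0,
        min_records: int = 100,
    ) -> None:
        cases = catalogue[catalogue["cause"] == cause]
        if len(cases) < min_records:
            raise ValueError(
                f"need >= {min_records} {cause} ignitions, got {len(cases)}"
            )
        if weather.empty:
            raise ValueError("weather series is empty")
        if not set(cases["year"]).issubset(set(weather["year"])):
            raise ValueError("weather does not cover catalogue years")
        self.cause = cause
        self.grid = grid
        self.spatial_degree = spatial_degree
        self.n_harmonics = n_harmonics

        rng = np.random.default_rng(seed)
        n_cases = len(cases)
        n_controls = control_ratio * n_cases

        # controls: uniform random pixel-days over the weather period
        ctrl_day = rng.integers(0, len(weather), n_controls)
        ctrl_cell = rng.integers(0, grid.n_cells, n_controls)
        rr, cc = np.divmod(ctrl_cell, grid.n_cols)
        cx, cy = grid.cell_center(rr, cc)
        wx = weather.iloc[ctrl_day]

        x = np.concatenate([cases["x"].to_numpy(), cx])
        y = np.concatenate([cases["y"].to_numpy(), cy])
        doy = np.concatenate([cases["doy"].to_numpy(), wx["doy"].to_numpy()])
        erc = np.concatenate([cases["erc"].to_numpy(), wx["erc"].to_numpy()])
        self._y = np.concatenate([np.ones(n_cases), np.zeros(n_controls)])
        self._X = self._design(x, y, doy, erc)
        # sampling fraction of the non-fire pixel-day universe
        n_universe = grid.n_cells * len(weather)
        self._log_sampling_fraction = float(np.log(n_controls / n_universe))

    def _design(self, x, y, doy, erc) -> pd.DataFrame:
        X = pd.concat(
            [
                spatial_basis(x, y, self.grid, self.spatial_degree),
                seasonal_basis(doy, self.n_harmonics),
                pd.DataFrame({"erc": np.asarray(erc, float)}),
            ],
            axis=1,
        )
        return sm.add_constant(X, has_constant="add")

    def fit(self, maxiter: int = 200) -> "IgnitionOccurrenceResults":
        try:
            res = sm.Logit(self._y, self._X).fit(
                method="newton", maxiter=maxiter, disp=False
            )
        except Exception as exc:  # singular design etc.
            raise FitError(f"occurrence model fit failed: {exc}") from exc
        if not res.mle_retvals.get("converged", True):
            raise FitError(
                f"occurrence model did not converge: {res.mle_retvals}"
            )
        return IgnitionOccurrenceResults(self, res)


class IgnitionOccurrenceResults:
    """Fitted occurrence model on the full pixel-day probability scale."""

    def __init__(self, model: IgnitionOccurrenceModel, smresults) -> None:
        self.model = model
        self._res = smresults
        self.params = smresults.params.copy()
        # correct the case/control intercept back to the pixel-day scale:
        # thinning controls by fraction f shifts the logit by -log(f)
        self.params["const"] += model._log_sampling_fraction
        self.bse = smresults.bse
        self.converged = True

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        ci = self._res.conf_int(alpha)
        ci.loc["const"] += self.model._log_sampling_fraction
        return ci

    def summary(self):
        return self._res.summary(title=(
            f"Ignition occurrence ({self.model.cause}), case/control logit"
        ))

    # -- prediction -----------------------------------------------------
    def predict_prob(self, x, y, doy, erc) -> np.ndarray:
        """Daily per-pixel ignition probability, in (0, 1)."""
        X = self.model._design(x, y, doy, erc)
        eta = X.to_numpy() @ self.params.to_numpy()
        return 1.0 / (1.0 + np.exp(-eta))

    def cell_logits(self) -> np.ndarray:
        """Spatial part of the logit for every grid cell (flat array)."""
        g = self.model.grid
        rr, cc = np.divmod(np.arange(g.n_cells), g.n_cols)
        x, y = g.cell_center(rr, cc)
        Xs = spatial_basis(x, y, g, self.model.spatial_degree)
        keep = [c for c in Xs.columns]
        return Xs.to_numpy() @ self.params[keep].to_numpy()

    def daily_logit_offset(self, doy, erc) -> np.ndarray:
        """Non-spatial part of the logit (const + season + ERC)."""
        Xt = seasonal_basis(doy, self.model.n_harmonics)
        cols = list(Xt.columns)
        return (
            self.params["const"]
            + Xt.to_numpy() @ self.params[cols].to_numpy()
            + self.params["erc"] * np.asarray(erc, float)
        )

    def expected_daily_count(self, doy, erc) -> np.ndarray:
        """Expected ignitions per day, summed over all grid cells."""
        s = self.cell_logits()
        d = np.atleast_1d(self.daily_logit_offset(doy, erc))
        # p = sigmoid(s + d); summed over cells for each day
        eta = s[None, :] + d[:, None]
        return (1.0 / (1.0 + np.exp(-eta))).sum(axis=1)

    def expected_season_count(self, weather: pd.DataFrame) -> float:
        """Integrated intensity over one season's daily weather."""
        return float(
            self.expected_daily_count(
                weather["doy"].to_numpy(), weather["erc"].to_numpy()
            ).sum()
        )


class FireSizeModel:
    """OLS of log final fire size on ERC and a spatial basis.

    Only fires larger than ``min_size`` ha (the minimum modelled size)
    enter the fit.
    """

    def __init__(
        self,
        catalogue: pd.DataFrame,
        cause: str,
        min_size: float = 10.0,
        spatial_degree: int = 2,
        grid: LandscapeGrid | None = None,
        min_records: int = 50,
    ) -> None:
        sub = catalogue[
            (catalogue["cause"] == cause) & (catalogue["final_size"] > min_size)
        ]
        if len(sub) < min_records:
            raise ValueError(
                f"need >= {min_records} {cause} fires above {min_size} ha, "
                f"got {len(sub)}"
            )
        self.cause = cause
        self.min_size = min_size
        self.grid = grid
        self.spatial_degree = spatial_degree
        parts = [pd.DataFrame({"erc": sub["erc"].to_numpy(float)})]
        if grid is not None:
            parts.insert(
                0, spatial_basis(sub["x"], sub["y"], grid, spatial_degree)
            )
        X = sm.add_constant(pd.concat(parts, axis=1), has_constant="add")
        self._X = X
        self._y = np.log(sub["final_size"].to_numpy(float))

    def fit(self) -> "FireSizeResults":
        res = sm.OLS(self._y, self._X).fit()
        if not np.all(np.isfinite(res.params)):
            raise FitError("size model produced non-finite coefficients")
        return FireSizeResults(self, res)


class FireSizeResults:
    def __init__(self, model: FireSizeModel, smresults) -> None:
        self.model = model
        self._res = smresults
        self.params = smresults.params
        self.bse = smresults.bse
        self.resid_scale = float(np.sqrt(smresults.scale))

    def conf_int(self, alpha: float = 0.05):
        return self._res.conf_int(alpha)

    def summary(self):
        return self._res.summary(title=f"Log fire size ({self.model.cause}), OLS")

    def predict_log_size(self, x, y, erc) -> np.ndarray:
        parts = [pd.DataFrame({"erc": np.atleast_1d(np.asarray(erc, float))})]
        if self.model.grid is not None:
            parts.insert(
                0,
                spatial_basis(
                    np.atleast_1d(x), np.atleast_1d(y),
                    self.model.grid, self.model.spatial_degree,
                ),
            )
        X = sm.add_constant(pd.concat(parts, axis=1), has_constant="add")
        return X.to_numpy() @ self.params.to_numpy()

    def sample_size(self, x, y, erc, rng: np.random.Generator) -> np.ndarray:
        """Draw fire sizes (ha) around the predicted log-size."""
        mu = self.predict_log_size(x, y, erc)
        return np.exp(mu + self.resid_scale * rng.standard_normal(mu.shape))
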