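"""Community firesheds: kriged structure-exposure surfaces and masks.

For each community, every simulated fire contributes one point at its
ignition location with a binary outcome: did the fire expose at least one
structure in that community? Ordinary (indicator) kriging of these 0/1
outcomes yields a smooth surface in [0, 1] — the predicted likelihood
that an ignition at a location would expose the community's structures.
Thresholding the surface (default 0.1, "at least a nominal chance") and
masking out areas with very low ignition density delineates the
community's fireshed, whose land-tenure composition identifies where
risk-reduction work would intercept community-bound fire.

The variogram estimator follows the Model/fit pattern: ``Variogram``
holds the empirical semivariances; ``fit()`` returns a ``VariogramModel``
with the fitted nugget, partial sill and range.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.optimize import curve_fit
from scipy.spatial import cKDTree
from scipy.spatial.distance import pdist, squareform

from .communities import CommunityLayer
from .grid import LandscapeGrid
from .records import FireRecord
from .spread import FirePerimeter
from .transmission import structures_exposed

logger = logging.getLogger(__name__)

__all__ = [
    "ExposurePointSet",
    "build_exposure_points",
    "Variogram",
    "VariogramModel",
    "fit_variogram",
    "krige_exposure_surface",
    "ignition_density",
    "Fireshed",
    "delineate_fireshed",
    "fireshed_summary",
]


# ---------------------------------------------------------------------------
# exposure points

@dataclass
class ExposurePointSet:
    """One record per simulated fire: ignition point + per-community outcome.

    ``indicator`` and ``structures`` are (n_fires x n_communities) frames
    indexed by fire_id with community ids as columns; the indicator is 1
    where the fire exposed at least one structure.
    """

    points: pd.DataFrame  # fire_id, x, y
    indicator: pd.DataFrame
    structures: pd.DataFrame

    def community_values(self, community_id: int) -> np.ndarray:
        return self.indicator[community_id].to_numpy(float)


def build_exposure_points(
    perimeters: list[FirePerimeter],
    firelist: list[FireRecord],
    communities: CommunityLayer,
) -> ExposurePointSet:
    by_id = {r.fire_id: r for r in firelist}
    if len(perimeters) != len(firelist) or any(
        p.fire_id not in by_id for p in perimeters
    ):
        raise ValueError("perimeters and fire list do not match one-to-one")
    cids = [c.community_id for c in communities.communities]
    xs, ys, fids = [], [], []
    expo = np.zeros((len(perimeters), len(cids)))
    for i, per in enumerate(perimeters):
        rec = by_id[per.fire_id]
        fids.append(per.fire_id)
        xs.append(rec.x)
        ys.append(rec.y)
        for cid, s in structures_exposed(per, communities).items():
            expo[i, cids.index(cid)] = s
    points = pd.DataFrame({"fire_id": fids, "x": xs, "y": ys})
    structures = pd.DataFrame(expo, index=fids, columns=cids)
    indicator = (structures > 0).astype(float)
    return ExposurePointSet(points, indicator, structures)


# ---------------------------------------------------------------------------
# variogram

@dataclass
class VariogramModel:
    """Fitted semivariogram: gamma(h) = nugget + psill * f(h / range).

    ``family`` is "exponential" (f = 1 - exp(-h/a)) or "spherical";
    ``range_m`` is the distance parameter a in map metres. gamma(0) = 0
    exactly (the nugget is the jump just above zero lag), which makes
    zero-nugget kriging an exact interpolator.
    """

    family: str
    nugget: float
    psill: float
    range_m: float
    empirical: pd.DataFrame | None = field(default=None, repr=False)
    degenerate: bool = False

    def __post_init__(self) -> None:
        if self.nugget < 0 or self.psill < 0 or self.range_m <= 0:
            raise ValueError("variogram parameters must be non-negative "
                             "(range strictly positive)")

    def gamma(self, h) -> np.ndarray:
        h = np.asarray(h, float)
        a = self.range_m
        if self.family == "exponential":
            struct = 1.0 - np.exp(-h / a)
        elif self.family == "spherical":
            hr = np.clip(h / a, 0.0, 1.0)
            struct = 1.5 * hr - 0.5 * hr ** 3
        else:
            raise ValueError(f"unknown family {self.family!r}")
        out = self.nugget + self.psill * struct
        return np.where(h == 0, 0.0, out)


class Variogram:
    """Empirical semivariogram of point values, ready to fit.

    Pairwise semivariances are binned by separation distance; bins are
    weighted by their pair counts in the least-squares fit. Point sets
    larger than ``max_points`` are subsampled (seeded) before the O(n^2)
    pair computation.
    """

    def __init__(
        self,
        x: np.ndarray,
        y: np.ndarray,
        values: np.ndarray,
        n_lags: int = 15,
        max_lag: float | None = None,
        max_points: int = 4000,
        seed: int = 0,
    ) -> None:
        x = np.asarray(x, float)
        y = np.asarray(y, float)
        values = np.asarray(values, float)
        if len(x) < 2:
            raise ValueError("need >= 2 points")
        if len(x) > max_points:
            idx = np.random.default_rng(seed).choice(len(x), max_points,
                                                     replace=False)
            x, y, values = x[idx], y[idx], values[idx]
        self.values = values
        xy = np.column_stack([x, y])
        d = pdist(xy)
        dv = pdist(values[:, None], metric="sqeuclidean") / 2.0  # semivariance
        if max_lag is None:
            max_lag = d.max() / 2.0
        self.max_lag = float(max_lag)
        edges = np.linspace(0.0, max_lag, n_lags + 1)
        which = np.digitize(d, edges) - 1
        ok = (which >= 0) & (which < n_lags)
        counts = np.bincount(which[ok], minlength=n_lags)
        sums = np.bincount(which[ok], weights=dv[ok], minlength=n_lags)
        keep = counts > 0
        self.lags = (0.5 * (edges[:-1] + edges[1:]))[keep]
        self.semivariance = sums[keep] / counts[keep]
        self.counts = counts[keep]

    def fit(self, family: str = "exponential") -> VariogramModel:
        emp = pd.DataFrame({"lag": self.lags, "gamma": self.semivariance,
                            "pairs": self.counts})
        var = float(self.values.var())
        if var == 0 or len(self.lags) < 3:
            warnings.warn("degenerate variogram input; returning pure nugget")
            return VariogramModel("exponential", max(var, 1e-12), 0.0,
                                  self.max_lag, emp, degenerate=True)

        def model(h, nugget, psill, rng_):
            return VariogramModel(family, nugget, psill, rng_).gamma(
                np.maximum(h, 1e-9)
            )

        p0 = [0.5 * self.semivariance[0], var, self.max_lag / 3.0]
        try:
            popt, _ = curve_fit(
                model, self.lags, self.semivariance,
                p0=p0, sigma=1.0 / np.sqrt(self.counts),
                bounds=([0.0, 0.0, 1e-6],
                        [10 * var + 1e-9, 10 * var + 1e-9, 10 * self.max_lag]),
                maxfev=20000,
            )
        except RuntimeError:
            warnings.warn("variogram fit failed to converge; pure nugget")
            return VariogramModel(family, var, 0.0, self.max_lag, emp,
                                  degenerate=True)
        return VariogramModel(family, float(popt[0]), float(popt[1]),
                              float(popt[2]), emp)


def fit_variogram(
    points: ExposurePointSet,
    community_id: int,
    n_lags: int = 15,
    max_lag: float | None = None,
    family: str = "exponential",
    min_points: int = 30,
) -> VariogramModel:
    """Fit an indicator variogram for one community's exposure outcomes."""
    z = points.community_values(community_id)
    x = points.points["x"].to_numpy()
    y = points.points["y"].to_numpy()
    n_ones = int(z.sum())
    if len(z) < min_points or n_ones == 0 or n_ones == len(z):
        if len(z) >= 2 and (n_ones == 0 or n_ones == len(z)):
            warnings.warn(
                f"community {community_id}: constant indicators, pure nugget"
            )
            return VariogramModel(family, max(float(np.var(z)), 1e-12), 0.0,
                                  1.0, degenerate=True)
        raise ValueError(
            f"community {community_id}: need >= {min_points} points with "
            "both outcomes present"
        )
    return Variogram(x, y, z, n_lags=n_lags, max_lag=max_lag).fit(family)


# ---------------------------------------------------------------------------
# kriging

def _krige_cells(
    xy: np.ndarray, z: np.ndarray, vg: VariogramModel,
    targets: np.ndarray, max_neighbors: int,
) -> np.ndarray:
    """Ordinary kriging of values z at target coordinates."""
    tree = cKDTree(xy)
    k = min(max_neighbors, len(z))
    dists, idx = tree.query(targets, k=k)
    if k == 1:
        dists = dists[:, None]
        idx = idx[:, None]
    out = np.empty(len(targets))
    # cache per unique neighbor set the factorized kriging matrix
    cache: dict[bytes, tuple[np.ndarray, np.ndarray]] = {}
    for i in range(len(targets)):
        nb = idx[i]
        key = nb.tobytes()
        if key in cache:
            K, nb_xy = cache[key]
        else:
            nb_xy = xy[nb]
            D = squareform(pdist(nb_xy))
            K = np.empty((k + 1, k + 1))
            K[:k, :k] = vg.gamma(D)
            K[k, :] = 1.0
            K[:, k] = 1.0
            K[k, k] = 0.0
            cache[key] = (K, nb_xy)
        rhs = np.empty(k + 1)
        rhs[:k] = vg.gamma(dists[i])
        rhs[k] = 1.0
        try:
            w = np.linalg.solve(K, rhs)
            out[i] = w[:k] @ z[nb]
        except np.linalg.LinAlgError:
            logger.warning("singular kriging system at target %d; IDW fallback", i)
            wi = 1.0 / np.maximum(dists[i], 1e-9) ** 2
            out[i] = (wi @ z[nb]) / wi.sum()
    return out


def krige_exposure_surface(
    points: ExposurePointSet,
    community_id: int,
    vg: VariogramModel,
    grid: LandscapeGrid,
    max_neighbors: int = 16,
) -> np.ndarray:
    """Ordinary kriging of a community's exposure indicator onto the grid.

    Returns an (n_rows, n_cols) surface clipped to [0, 1]. With a
    zero-nugget variogram the surface interpolates the data exactly at
    ignition locations.
    """
    z = points.community_values(community_id)
    if len(z) < 1:
        raise ValueError("need at least one exposure point")
    xy = points.points[["x", "y"]].to_numpy(float)
    if vg.degenerate or vg.psill == 0:
        return np.full((grid.n_rows, grid.n_cols), float(np.clip(z.mean(), 0, 1)))
    rr, cc = np.divmod(np.arange(grid.n_cells), grid.n_cols)
    tx, ty = grid.cell_center(rr, cc)
    targets = np.column_stack([tx, ty])
    pred = _krige_cells(xy, z, vg, targets, max_neighbors)
    return np.clip(pred, 0.0, 1.0).reshape(grid.n_rows, grid.n_cols)


def ignition_density(
    points: ExposurePointSet | pd.DataFrame,
    grid: LandscapeGrid,
    bandwidth_m: float,
) -> np.ndarray:
    """Gaussian kernel density of ignition points, per km^2.

    Counts per cell are smoothed with a Gaussian of the given bandwidth
    and divided by the cell area, so the surface integrates to the total
    number of ignition points.
    """
    df = points.points if isinstance(points, ExposurePointSet) else points
    rows, cols = grid.locate(df["x"].to_numpy(), df["y"].to_numpy())
    counts = np.zeros((grid.n_rows, grid.n_cols))
    np.add.at(counts, (rows, cols), 1.0)
    sigma_cells = max(bandwidth_m / grid.cell_size, 1e-9)
    smooth = ndimage.gaussian_filter(counts, sigma_cells, mode="constant")
    cell_km2 = (grid.cell_size / 1000.0) ** 2
    return smooth / cell_km2


# ---------------------------------------------------------------------------
# fireshed

@dataclass
class Fireshed:
    community_id: int
    mask: np.ndarray  # boolean (n_rows, n_cols)
    area_ha: float
    composition: dict[str, float]  # ha by tenure label

    def __post_init__(self) -> None:
        comp = sum(self.composition.values())
        if abs(comp - self.area_ha) > 1e-6 * max(self.area_ha, 1.0):
            raise ValueError("composition does not sum to fireshed area")


DEFAULT_EXPOSURE_THRESHOLD = 0.1
DEFAULT_MIN_IGNITION_DENSITY = 1.5e-4  # ignition points per km^2


def delineate_fireshed(
    surface: np.ndarray,
    tenure_map: LandscapeGrid,
    community_id: int = -1,
    threshold: float = DEFAULT_EXPOSURE_THRESHOLD,
    density: np.ndarray | None = None,
    min_density: float = DEFAULT_MIN_IGNITION_DENSITY,
) -> Fireshed:
    """Threshold the kriged surface and mask out ignition-sparse areas.

    ``mask = (surface >= threshold) & (density >= min_density)``; both
    comparisons are inclusive. Tenure composition is tallied against the
    tenure map.
    """
    if surface.shape != (tenure_map.n_rows, tenure_map.n_cols):
        raise ValueError("surface not co-registered with the tenure map")
    mask = surface >= threshold
    if density is not None:
        if density.shape != surface.shape:
            raise ValueError("density raster not co-registered with surface")
        mask = mask & (density >= min_density)
    area = float(mask.sum()) * tenure_map.cell_area_ha
    comp: dict[str, float] = {}
    codes, counts = np.unique(tenure_map.tenure_id[mask], return_counts=True)
    for code, cnt in zip(codes, counts):
        comp[tenure_map.label_of(code)] = float(cnt) * tenure_map.cell_area_ha
    return Fireshed(community_id, mask, area, comp)


def fireshed_summary(
    firesheds: list[Fireshed],
    tenure_map: LandscapeGrid,
    communities: CommunityLayer | None = None,
    structures_rate: pd.DataFrame | None = None,
) -> dict:
    """Combined-fireshed statistics across communities.

    Returns union area, the union's tenure composition, the fraction of
    the union belonging to two or more firesheds, the ratio of union area
    to the developed (community core + WUI) area, and — when a
    per-(community, tenure) table of structures exposed per year is
    supplied — the transmission efficiency in structures per year per
    1,000 ha of fireshed area in that tenure.
    """
    if not firesheds:
        raise ValueError("need >= 1 fireshed")
    stack = np.stack([fs.mask for fs in firesheds])
    cover = stack.sum(axis=0)
    union = cover > 0
    cell_ha = tenure_map.cell_area_ha
    union_area = float(union.sum()) * cell_ha
    comp: dict[str, float] = {}
    codes, counts = np.unique(tenure_map.tenure_id[union], return_counts=True)
    for code, cnt in zip(codes, counts):
        comp[tenure_map.label_of(code)] = float(cnt) * cell_ha
    overlap_frac = (
        float((cover >= 2).sum()) / float(union.sum()) if union.any() else 0.0
    )
    out = {
        "union_area_ha": union_area,
        "union_composition_ha": comp,
        "overlap_fraction": overlap_frac,
        "per_community_area_ha": {
            fs.community_id: fs.area_ha for fs in firesheds
        },
    }
    if communities is not None:
        dev_ha = communities.all_cells.size * cell_ha
        out["developed_area_ha"] = dev_ha
        out["fireshed_to_developed_ratio"] = (
            union_area / dev_ha if dev_ha > 0 else np.nan
        )
    if structures_rate is not None:
        by_fs = {fs.community_id: fs for fs in firesheds}
        rows = []
        for _, r in structures_rate.iterrows():
            fs = by_fs.get(r["community_id"])
            ten_ha = fs.composition.get(r["tenure"], 0.0) if fs else 0.0
            eff = r["structures_per_yr"] / ten_ha * 1000.0 if ten_ha > 0 else np.nan
            rows.append((r["community_id"], r["tenure"],
                         r["structures_per_yr"], ten_ha, eff))
        out["transmission_efficiency"] = pd.DataFrame(
            rows, columns=["community_id", "tenure", "structures_per_yr",
                           "fireshed_ha", "structures_per_1000ha"],
        )
    return out
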