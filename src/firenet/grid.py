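"""Gridded landscape container and synthetic tenure-map generator.

The landscape is a regular raster of square cells. Each cell carries a land
tenure code (ownership + management capability, e.g. managed national forest
vs. protected reserve vs. private industrial), a coarse fuel class, a base
fire spread rate (m/min at reference fuel moisture with no wind) and a
fireline-intensity scale (kW/m) used to derive flame lengths.

Conventions used throughout the package: row-major 0-based cell indices;
cell centers at map coordinates ``x = x0 + (col + 0.5) * cell_size``,
``y = y0 + (row + 0.5) * cell_size``; cell area ``cell_size**2 / 1e4`` ha,
so at the default 100 m resolution one cell is one hectare.
"""

from __future__ import annotations

import heapq
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import tifffile

__all__ = ["LandscapeGrid", "generate_landscape", "write_landscape", "read_landscape"]

#: fuel classes: forested tenures spread slowly but burn intensely,
#: grass/shrub tenures spread fast at low intensity.
FUEL_FOREST = 0
FUEL_GRASS = 1

# (base_rate lo, hi) m/min and (intensity lo, hi) kW/m by fuel class
_FUEL_PARAMS = {
    FUEL_FOREST: ((4.0, 10.0), (900.0, 2200.0)),
    FUEL_GRASS: ((15.0, 35.0), (120.0, 500.0)),
}

DEFAULT_TENURE_LABELS = [
    "NF-M", "NF-P", "BLM", "Native", "Private", "PrivateIndustrial", "ODF",
    "NPS", "OtherFED", "USFWS",
]

#: tenure label appended when communities are stamped onto a grid
COMMUNITY_LABEL = "Community"


@dataclass
class LandscapeGrid:
    n_rows: int
    n_cols: int
    cell_size: float  # m
    origin: tuple[float, float]  # (x0, y0) of the grid's lower-left corner, m
    tenure_id: np.ndarray  # (n_rows, n_cols) int16
    fuel_class: np.ndarray  # (n_rows, n_cols) int16
    base_rate: np.ndarray  # (n_rows, n_cols) float, m/min
    intensity_coeff: np.ndarray  # (n_rows, n_cols) float, kW/m
    tenure_labels: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        shape = (self.n_rows, self.n_cols)
        for name in ("tenure_id", "fuel_class", "base_rate", "intensity_coeff"):
            arr = getattr(self, name)
            if arr.shape != shape:
                raise ValueError(f"{name} has shape {arr.shape}, expected {shape}")
        if (self.base_rate < 0).any():
            raise ValueError("base_rate must be non-negative")
        codes = np.unique(self.tenure_id)
        missing = [int(c) for c in codes if int(c) not in self.tenure_labels]
        if missing:
            raise ValueError(f"tenure codes without labels: {missing}")

    # -- geometry -------------------------------------------------------
    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def cell_area_ha(self) -> float:
        return self.cell_size ** 2 / 1e4

    @property
    def area_ha(self) -> float:
        return self.n_cells * self.cell_area_ha

    def cell_center(self, row, col):
        """Map coordinates of cell centers (vectorized)."""
        x0, y0 = self.origin
        x = x0 + (np.asarray(col) + 0.5) * self.cell_size
        y = y0 + (np.asarray(row) + 0.5) * self.cell_size
        return x, y

    def locate(self, x, y):
        """Row/col of map coordinates; raises if outside the grid."""
        x0, y0 = self.origin
        col = np.floor((np.asarray(x) - x0) / self.cell_size).astype(int)
        row = np.floor((np.asarray(y) - y0) / self.cell_size).astype(int)
        if np.any((row < 0) | (row >= self.n_rows) | (col < 0) | (col >= self.n_cols)):
            raise ValueError("coordinates outside grid")
        return row, col

    def label_of(self, code: int) -> str:
        return self.tenure_labels[int(code)]

    def code_of(self, label: str) -> int:
        for code, lab in self.tenure_labels.items():
            if lab == label:
                return code
        raise KeyError(label)

    def copy(self) -> "LandscapeGrid":
        return replace(
            self,
            tenure_id=self.tenure_id.copy(),
            fuel_class=self.fuel_class.copy(),
            base_rate=self.base_rate.copy(),
            intensity_coeff=self.intensity_coeff.copy(),
            tenure_labels=dict(self.tenure_labels),
        )


def generate_landscape(
    n_rows: int,
    n_cols: int,
    cell_size: float = 100.0,
    n_tenures: int = 7,
    mean_parcel_cells: int = 500,
    seed: int = 0,
    origin: tuple[float, float] = (0.0, 0.0),
) -> LandscapeGrid:
    """Generate a mixed-tenure landscape of contiguous parcels.

    Parcels are grown from randomly placed seeds by multi-source region
    growing (a randomized flood fill), which yields contiguous, irregular
    ownership blocks like a real tenure map. Tenure classes alternate
    between forested (slow spread, high intensity) and grass/shrub fuels
    (fast spread, low intensity).

    Parameters
    ----------
    n_tenures : number of distinct tenure classes (>= 2).
    mean_parcel_cells : target mean parcel size in cells; the number of
        parcels is ``max(n_tenures, round(n_cells / mean_parcel_cells))``.
    """
    if n_tenures < 2:
        raise ValueError("n_tenures must be >= 2")
    if mean_parcel_cells < 1:
        raise ValueError("mean_parcel_cells must be >= 1")
    n_cells = n_rows * n_cols
    n_parcels = max(n_tenures, int(round(n_cells / mean_parcel_cells)))
    if n_parcels > n_cells:
        raise ValueError(
            f"grid too small: {n_cells} cells cannot host {n_parcels} parcels"
        )

    rng = np.random.default_rng(seed)
    seeds = rng.choice(n_cells, size=n_parcels, replace=False)

    # every tenure gets >= 1 parcel; remaining parcels drawn uniformly
    parcel_tenure = np.concatenate(
        [np.arange(n_tenures), rng.integers(0, n_tenures, n_parcels - n_tenures)]
    )
    rng.shuffle(parcel_tenure)

    parcel = np.full(n_cells, -1, dtype=np.int32)
    # claim seed cells up front so no parcel can be flooded out of existence
    parcel[seeds] = np.arange(n_parcels)
    heap: list[tuple[float, int, int]] = []
    offsets = ((-1, 0), (1, 0), (0, -1), (0, 1))
    for pid, cell in enumerate(seeds):
        r, c = divmod(int(cell), n_cols)
        for dr, dc in offsets:
            rr, cc = r + dr, c + dc
            if 0 <= rr < n_rows and 0 <= cc < n_cols:
                heapq.heappush(heap, (rng.random(), rr * n_cols + cc, pid))

    while heap:
        _, cell, pid = heapq.heappop(heap)
        if parcel[cell] >= 0:
            continue
        parcel[cell] = pid
        r, c = divmod(cell, n_cols)
        for dr, dc in offsets:
            rr, cc = r + dr, c + dc
            if 0 <= rr < n_rows and 0 <= cc < n_cols:
                nb = rr * n_cols + cc
                if parcel[nb] < 0:
                    heapq.heappush(heap, (rng.random(), nb, pid))

    tenure = parcel_tenure[parcel].astype(np.int16).reshape(n_rows, n_cols)

    fuel = np.empty((n_rows, n_cols), dtype=np.int16)
    base_rate = np.empty((n_rows, n_cols))
    intensity = np.empty((n_rows, n_cols))
    for t in range(n_tenures):
        fclass = FUEL_FOREST if t % 2 == 0 else FUEL_GRASS
        (rlo, rhi), (ilo, ihi) = _FUEL_PARAMS[fclass]
        mask = tenure == t
        n = int(mask.sum())
        fuel[mask] = fclass
        # per-tenure mean with mild within-tenure heterogeneity
        r_mean = rng.uniform(rlo, rhi)
        i_mean = rng.uniform(ilo, ihi)
        base_rate[mask] = np.clip(r_mean * rng.lognormal(0.0, 0.15, n), 0.5, None)
        intensity[mask] = np.clip(i_mean * rng.lognormal(0.0, 0.2, n), 50.0, None)

    labels = {
        t: (DEFAULT_TENURE_LABELS[t] if t < len(DEFAULT_TENURE_LABELS) else f"T{t}")
        for t in range(n_tenures)
    }
    return LandscapeGrid(
        n_rows=n_rows,
        n_cols=n_cols,
        cell_size=cell_size,
        origin=origin,
        tenure_id=tenure,
        fuel_class=fuel,
        base_rate=base_rate,
        intensity_coeff=intensity,
        tenure_labels=labels,
    )


# -- raster I/O: plain multi-band TIFF + JSON georeferencing sidecar ----

def write_landscape(grid: LandscapeGrid, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    stack = np.stack(
        [
            grid.tenure_id.astype(np.float64),
            grid.fuel_class.astype(np.float64),
            grid.base_rate,
            grid.intensity_coeff,
        ]
    )
    tifffile.imwrite(directory / "landscape.tif", stack,
                     photometric="minisblack")
    meta = {
        "n_rows": grid.n_rows,
        "n_cols": grid.n_cols,
        "cell_size_m": grid.cell_size,
        "origin": list(grid.origin),
        "bands": ["tenure_id", "fuel_class", "base_rate_m_min", "intensity_kw_m"],
        "tenure_labels": {str(k): v for k, v in grid.tenure_labels.items()},
    }
    (directory / "landscape.json").write_text(json.dumps(meta, indent=2))


def read_landscape(directory: str | Path) -> LandscapeGrid:
    directory = Path(directory)
    stack = tifffile.imread(directory / "landscape.tif")
    meta = json.loads((directory / "landscape.json").read_text())
    return LandscapeGrid(
        n_rows=meta["n_rows"],
        n_cols=meta["n_cols"],
        cell_size=meta["cell_size_m"],
        origin=tuple(meta["origin"]),
        tenure_id=stack[0].astype(np.int16),
        fuel_class=stack[1].astype(np.int16),
        base_rate=stack[2],
        intensity_coeff=stack[3],
        tenure_labels={int(k): v for k, v in meta["tenure_labels"].items()},
    )
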