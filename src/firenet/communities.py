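"""Communities: census-style core areas plus surrounding WUI rings.

A community is a compact core blob of cells (the developed town footprint)
surrounded by one to three wildland-urban-interface (WUI) rings where
structures intermix with wildland fuels. Each polygon (core or ring)
carries a structure count; exposure accounting is proportional to the
fraction of a polygon's cells burned.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from shapely import contains_xy
from shapely.geometry import box, mapping, shape
from shapely.ops import unary_union

from .grid import COMMUNITY_LABEL, LandscapeGrid

__all__ = [
    "WuiPolygon",
    "Community",
    "CommunityLayer",
    "generate_communities",
    "write_communities",
    "read_communities",
]


@dataclass
class WuiPolygon:
    cells: np.ndarray  # flat cell indices
    structure_count: int
    area_ha: float
    is_wui: bool  # False for the core polygon


@dataclass
class Community:
    community_id: int
    core: WuiPolygon
    wui: list[WuiPolygon]

    @property
    def polygons(self) -> list[WuiPolygon]:
        return [self.core, *self.wui]

    @property
    def cells(self) -> np.ndarray:
        return np.concatenate([p.cells for p in self.polygons])

    @property
    def structures(self) -> int:
        return sum(p.structure_count for p in self.polygons)


@dataclass
class CommunityLayer:
    communities: list[Community]
    grid: LandscapeGrid  # companion grid with community cells relabelled
    community_code: int  # tenure code of the Community class
    #: flat cell index -> community_id, -1 outside communities
    cell_community: np.ndarray = field(repr=False, default=None)

    def __post_init__(self) -> None:
        if self.cell_community is None:
            cc = np.full(self.grid.n_cells, -1, dtype=np.int32)
            for com in self.communities:
                cc[com.cells] = com.community_id
            self.cell_community = cc

    @property
    def total_structures(self) -> int:
        return sum(c.structures for c in self.communities)

    def polygon_index(self):
        """Flat-cell -> polygon id raster plus per-polygon metadata.

        Returns ``(cell_poly, meta)`` where ``cell_poly[cell]`` is a
        polygon id (-1 outside communities) and ``meta[pid]`` is
        ``(community_id, n_cells, structure_count)``. Cached.
        """
        if getattr(self, "_poly_index", None) is None:
            cell_poly = np.full(self.grid.n_cells, -1, dtype=np.int32)
            meta = []
            for com in self.communities:
                for poly in com.polygons:
                    if poly.cells.size == 0:
                        raise ValueError(
                            f"community {com.community_id} has an empty polygon"
                        )
                    cell_poly[poly.cells] = len(meta)
                    meta.append(
                        (com.community_id, poly.cells.size, poly.structure_count)
                    )
            self._poly_index = (cell_poly, meta)
        return self._poly_index

    @property
    def all_cells(self) -> np.ndarray:
        return np.flatnonzero(self.cell_community >= 0)


def _disk_cells(r0: int, c0: int, radius: float, n_rows: int, n_cols: int) -> set[int]:
    cells = set()
    ir = int(np.ceil(radius))
    for dr in range(-ir, ir + 1):
        for dc in range(-ir, ir + 1):
            if dr * dr + dc * dc <= radius * radius:
                rr, cc = r0 + dr, c0 + dc
                if 0 <= rr < n_rows and 0 <= cc < n_cols:
                    cells.add(rr * n_cols + cc)
    return cells


def _allocate(total: int, weights: np.ndarray) -> np.ndarray:
    """Integer allocation of `total` proportional to weights (conserving)."""
    weights = np.asarray(weights, dtype=float)
    raw = total * weights / weights.sum()
    out = np.floor(raw).astype(int)
    rem = total - out.sum()
    order = np.argsort(raw - np.floor(raw))[::-1]
    out[order[:rem]] += 1
    return out


def generate_communities(
    grid: LandscapeGrid,
    n_communities: int,
    structures_total: int,
    seed: int = 0,
    core_radius: float = 2.0,
    ring_width: float = 1.5,
    max_retries: int = 200,
) -> CommunityLayer:
    """Place compact community cores with 1-3 surrounding WUI rings.

    Cells covered by any community polygon are relabelled to the
    ``Community`` tenure class in the returned layer's companion grid.
    Structure counts are allocated across communities (random weights) and
    within each community (core-heavy) so they sum to ``structures_total``.
    """
    if n_communities < 1:
        raise ValueError("n_communities must be >= 1")
    rng = np.random.default_rng(seed)
    n_rows, n_cols = grid.n_rows, grid.n_cols

    max_radius = core_radius + 3 * ring_width
    occupied = np.zeros(grid.n_cells, dtype=bool)
    placements = []  # (center, n_rings)
    margin = int(np.ceil(max_radius))
    if n_rows <= 2 * margin or n_cols <= 2 * margin:
        raise ValueError("grid too small to place communities")
    for _ in range(n_communities):
        n_rings = int(rng.integers(1, 4))
        placed = False
        for _ in range(max_retries):
            r0 = int(rng.integers(margin, n_rows - margin))
            c0 = int(rng.integers(margin, n_cols - margin))
            footprint = _disk_cells(r0, c0, core_radius + n_rings * ring_width + 1,
                                    n_rows, n_cols)
            if not occupied[list(footprint)].any():
                occupied[list(footprint)] = True
                placements.append(((r0, c0), n_rings))
                placed = True
                break
        if not placed:
            raise ValueError(
                f"could not place {n_communities} communities on "
                f"{n_rows}x{n_cols} grid after {max_retries} retries"
            )

    com_weights = rng.dirichlet(np.full(n_communities, 4.0))
    com_structs = _allocate(structures_total, com_weights)

    communities = []
    for cid, (((r0, c0), n_rings), n_str) in enumerate(zip(placements, com_structs)):
        core_cells = np.array(sorted(_disk_cells(r0, c0, core_radius, n_rows, n_cols)))
        prev = set(core_cells.tolist())
        rings = []
        for k in range(1, n_rings + 1):
            disk = _disk_cells(r0, c0, core_radius + k * ring_width, n_rows, n_cols)
            ring = np.array(sorted(disk - prev))
            prev = disk
            if ring.size:
                rings.append(ring)
        # core takes ~60% of structures, rings share the rest (outer thinner)
        w = np.array([0.6] + [0.4 * 0.5 ** k / sum(0.5 ** j for j in range(1, len(rings) + 1))
                              for k in range(1, len(rings) + 1)]) if rings else np.array([1.0])
        counts = _allocate(int(n_str), w)
        core = WuiPolygon(core_cells, int(counts[0]),
                          core_cells.size * grid.cell_area_ha, is_wui=False)
        wui = [
            WuiPolygon(ring, int(cnt), ring.size * grid.cell_area_ha, is_wui=True)
            for ring, cnt in zip(rings, counts[1:])
        ]
        communities.append(Community(cid, core, wui))

    cgrid = grid.copy()
    code = max(cgrid.tenure_labels) + 1
    cgrid.tenure_labels[code] = COMMUNITY_LABEL
    for com in communities:
        rr, cc = np.divmod(com.cells, n_cols)
        cgrid.tenure_id[rr, cc] = code
    return CommunityLayer(communities, cgrid, code)


# -- GeoJSON I/O ------------------------------------------------------------

def _cells_to_polygon(cells: np.ndarray, grid: LandscapeGrid):
    x0, y0 = grid.origin
    cs = grid.cell_size
    boxes = []
    for cell in cells:
        r, c = divmod(int(cell), grid.n_cols)
        boxes.append(box(x0 + c * cs, y0 + r * cs, x0 + (c + 1) * cs, y0 + (r + 1) * cs))
    return unary_union(boxes)


def write_communities(layer: CommunityLayer, path: str | Path) -> None:
    features = []
    for com in layer.communities:
        for i, poly in enumerate(com.polygons):
            geom = _cells_to_polygon(poly.cells, layer.grid)
            features.append(
                {
                    "type": "Feature",
                    "geometry": mapping(geom),
                    "properties": {
                        "community_id": com.community_id,
                        "is_wui": poly.is_wui,
                        "ring": i,
                        "structures": poly.structure_count,
                        "area_ha": poly.area_ha,
                    },
                }
            )
    Path(path).write_text(
        json.dumps({"type": "FeatureCollection", "features": features})
    )


def read_communities(path: str | Path, grid: LandscapeGrid) -> CommunityLayer:
    """Rasterize a community GeoJSON back onto a grid (cells by center point)."""
    data = json.loads(Path(path).read_text())
    rows, cols = np.meshgrid(np.arange(grid.n_rows), np.arange(grid.n_cols),
                             indexing="ij")
    xs, ys = grid.cell_center(rows.ravel(), cols.ravel())
    by_community: dict[int, dict[int, WuiPolygon]] = {}
    for feat in data["features"]:
        g = shape(feat["geometry"]).buffer(0)
        inside = contains_xy(g, xs, ys)
        cells = np.flatnonzero(inside)
        props = feat["properties"]
        by_community.setdefault(props["community_id"], {})[props["ring"]] = WuiPolygon(
            cells, props["structures"], props["area_ha"], props["is_wui"]
        )
    communities = []
    for cid in sorted(by_community):
        polys = [by_community[cid][k] for k in sorted(by_community[cid])]
        core = next(p for p in polys if not p.is_wui)
        wui = [p for p in polys if p.is_wui]
        communities.append(Community(cid, core, wui))
    cgrid = grid.copy()
    code = max(cgrid.tenure_labels) + 1
    cgrid.tenure_labels[code] = COMMUNITY_LABEL
    for com in communities:
        rr, cc = np.divmod(com.cells, grid.n_cols)
        cgrid.tenure_id[rr, cc] = code
    return CommunityLayer(communities, cgrid, code)
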