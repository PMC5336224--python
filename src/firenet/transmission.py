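"""Cross-boundary fire transmission accounting.

Each simulated fire's burned cells are attributed to the land tenure (and
community) they fall in, with the fire's source being the tenure of its
ignition cell. Cross-tabulating burned area by (source, destination)
yields the transmission matrix, whose diagonal is non-transmitted fire
(NonTF) and whose off-diagonal column/row sums are the incoming (TF-IN)
and outgoing (TF-OUT) fire of each tenure. Every burned hectare is
counted once toward its destination's TF-IN (or NonTF) and once toward
its source's TF-OUT, so Total fire = NonTF + TF-IN for each tenure and
the grand totals of TF-IN and TF-OUT coincide.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .communities import CommunityLayer
from .grid import LandscapeGrid
from .spread import FirePerimeter

__all__ = [
    "AttributedFire",
    "attribute_fire",
    "TransmissionMatrix",
    "tabulate_transmission",
    "TenureExposureSummary",
    "summarize_tenure_exposure",
    "structures_exposed",
]

CAUSES = ("human", "natural")


@dataclass
class AttributedFire:
    fire_id: int
    season: int
    cause: str
    source_label: str  # tenure of the ignition cell
    source_community: int | None  # community id if ignited inside one
    area_by_tenure: dict[str, float]  # ha, aggregate tenure classes
    area_by_community: dict[int, float]  # ha burned inside each community

    @property
    def total_area(self) -> float:
        return float(sum(self.area_by_tenure.values()))


def attribute_fire(
    perimeter: FirePerimeter,
    tenure_map: LandscapeGrid,
    communities: CommunityLayer | None = None,
) -> AttributedFire:
    """Tally a fire's burned cells by tenure class and by community.

    Community cells count both toward the aggregate ``Community`` tenure
    class and toward their individual community id.
    """
    tenure = tenure_map.tenure_id.ravel()[perimeter.cells]
    codes, counts = np.unique(tenure, return_counts=True)
    area = tenure_map.cell_area_ha
    by_tenure = {
        tenure_map.label_of(code): float(cnt * area)
        for code, cnt in zip(codes, counts)
    }
    by_community: dict[int, float] = {}
    source_community = None
    if communities is not None:
        cc = communities.cell_community
        cids = cc[perimeter.cells]
        for cid in np.unique(cids[cids >= 0]):
            by_community[int(cid)] = float((cids == cid).sum() * area)
        ign = int(cc[perimeter.ignition_cell])
        source_community = ign if ign >= 0 else None
    source = tenure_map.label_of(tenure_map.tenure_id.ravel()[perimeter.ignition_cell])
    return AttributedFire(
        fire_id=perimeter.fire_id,
        season=perimeter.season,
        cause=perimeter.cause,
        source_label=source,
        source_community=source_community,
        area_by_tenure=by_tenure,
        area_by_community=by_community,
    )


@dataclass
class TransmissionMatrix:
    """Source x destination annual burned hectares.

    ``matrix`` sums both causes; ``by_cause`` holds the human/natural
    components. ``labels`` fixes node order. All entries are ha/yr
    (totals divided by ``n_seasons``).
    """

    labels: list[str]
    matrix: pd.DataFrame
    by_cause: dict[str, pd.DataFrame]
    n_seasons: int
    scale: str = "tenure"

    def non_transmitted(self) -> pd.Series:
        return pd.Series(np.diag(self.matrix), index=self.labels)

    def tf_in(self) -> pd.Series:
        return self.matrix.sum(axis=0) - np.diag(self.matrix)

    def tf_out(self) -> pd.Series:
        return self.matrix.sum(axis=1) - np.diag(self.matrix)

    def total_fire(self) -> pd.Series:
        return self.non_transmitted() + self.tf_in()

    def to_long(self) -> pd.DataFrame:
        rows = []
        for cause, m in self.by_cause.items():
            for src in self.labels:
                for dst in self.labels:
                    v = m.loc[src, dst]
                    if v > 0:
                        rows.append((src, dst, cause, v))
        return pd.DataFrame(rows, columns=["source", "destination", "cause",
                                           "ha_per_yr"])

    def to_exposure_table(self) -> pd.DataFrame:
        """Long-format NonTF/TF-IN/TF-OUT per tenure and cause."""
        rows = []
        for cause, m in self.by_cause.items():
            diag = pd.Series(np.diag(m), index=self.labels)
            tin = m.sum(axis=0) - diag
            tout = m.sum(axis=1) - diag
            for t in self.labels:
                rows.append((t, cause, diag[t], tin[t], tout[t]))
        return pd.DataFrame(
            rows, columns=["tenure", "cause", "nontf", "tf_in", "tf_out"]
        )


def tabulate_transmission(
    fires: list[AttributedFire],
    n_seasons: int,
    scale: str = "tenure",
    community_label: str = "Community",
) -> TransmissionMatrix:
    """Cross-tabulate attributed fires into a transmission matrix.

    ``scale="tenure"`` aggregates all communities into one Community
    class; ``scale="community"`` keeps the large tenures and disaggregates
    individual communities as their own nodes (named ``community:<id>``),
    excluding the aggregate class to avoid double counting.
    """
    if n_seasons < 1:
        raise ValueError("n_seasons must be >= 1")
    if scale not in ("tenure", "community"):
        raise ValueError(f"unknown scale {scale!r}")

    labels: list[str] = []

    def _node_areas(f: AttributedFire) -> tuple[str, dict[str, float]]:
        if scale == "tenure":
            return f.source_label, dict(f.area_by_tenure)
        areas = {k: v for k, v in f.area_by_tenure.items() if k != community_label}
        for cid, v in f.area_by_community.items():
            areas[f"community:{cid}"] = v
        src = (f"community:{f.source_community}"
               if f.source_community is not None else f.source_label)
        return src, areas

    cells: dict[str, dict[tuple[str, str], float]] = {c: {} for c in CAUSES}
    for f in fires:
        if f.cause not in cells:
            raise ValueError(f"unknown cause {f.cause!r}")
        src, areas = _node_areas(f)
        if src not in labels:
            labels.append(src)
        for dst, a in areas.items():
            if dst not in labels:
                labels.append(dst)
            key = (src, dst)
            cells[f.cause][key] = cells[f.cause].get(key, 0.0) + a

    labels = sorted(labels)
    by_cause = {}
    for cause in CAUSES:
        m = pd.DataFrame(0.0, index=labels, columns=labels)
        for (src, dst), a in cells[cause].items():
            m.loc[src, dst] += a / n_seasons
        by_cause[cause] = m
    total = sum(by_cause.values())
    return TransmissionMatrix(labels, total, by_cause, n_seasons, scale)


@dataclass
class TenureExposureSummary:
    """Per-tenure transmission summary plus landscape-wide statistics.

    ``table`` has one row per tenure with NonTF/TF-IN/TF-OUT by cause,
    total fire, and the incoming fraction TF-IN / Total fire (NaN where
    no fire burned).
    """

    table: pd.DataFrame
    mean_incoming_fraction: float
    min_incoming_fraction: float
    max_incoming_fraction: float
    grand_total: float  # ha/yr burned over all tenures
    grand_total_by_cause: dict[str, float]
    cross_boundary_share: float  # sum TF-IN / grand total
    _tf_in_total: float = field(repr=False, default=0.0)

    def incoming_fraction(self, tenure: str) -> float:
        return float(self.table.loc[tenure, "incoming_fraction"])

    def total_fire(self, tenure: str) -> float:
        return float(self.table.loc[tenure, "total_fire"])

    def group_incoming_fraction(self, tenures: list[str]) -> float:
        """Incoming fraction of a set of tenures pooled together."""
        sub = self.table.loc[tenures]
        return float(sub["tf_in"].sum() / sub["total_fire"].sum())

    def share_of_transmitted(self, tenures: list[str]) -> float:
        """Fraction of all transmitted fire received by these tenures."""
        return float(self.table.loc[tenures, "tf_in"].sum() / self._tf_in_total)


def summarize_tenure_exposure(
    data: TransmissionMatrix | pd.DataFrame,
) -> TenureExposureSummary:
    """Summarize transmission into per-tenure and landscape statistics.

    Accepts either a TransmissionMatrix or a long-format table with
    columns ``tenure, cause, nontf, tf_in, tf_out`` (the shape of the
    published per-tenure summaries).
    """
    table = data.to_exposure_table() if isinstance(data, TransmissionMatrix) else data
    required = {"tenure", "cause", "nontf", "tf_in", "tf_out"}
    if not required.issubset(table.columns):
        raise ValueError(f"exposure table must have columns {sorted(required)}")
    if (table[["nontf", "tf_in", "tf_out"]] < 0).any().any():
        raise ValueError("negative transmission entries")

    wide = table.pivot_table(
        index="tenure", columns="cause",
        values=["nontf", "tf_in", "tf_out"], aggfunc="sum", fill_value=0.0,
    )
    out = pd.DataFrame(index=wide.index)
    for part in ("nontf", "tf_in", "tf_out"):
        for cause in wide[part].columns:
            out[f"{part}_{cause}"] = wide[part][cause]
        out[part] = wide[part].sum(axis=1)
    out["total_fire"] = out["nontf"] + out["tf_in"]
    with np.errstate(invalid="ignore", divide="ignore"):
        out["incoming_fraction"] = np.where(
            out["total_fire"] > 0, out["tf_in"] / out["total_fire"], np.nan
        )

    frac = out["incoming_fraction"].dropna()
    grand_by_cause = {
        cause: float(wide["nontf"][cause].sum() + wide["tf_in"][cause].sum())
        for cause in wide["nontf"].columns
    }
    grand = float(out["total_fire"].sum())
    tf_in_total = float(out["tf_in"].sum())
    return TenureExposureSummary(
        table=out,
        mean_incoming_fraction=float(frac.mean()) if len(frac) else np.nan,
        min_incoming_fraction=float(frac.min()) if len(frac) else np.nan,
        max_incoming_fraction=float(frac.max()) if len(frac) else np.nan,
        grand_total=grand,
        grand_total_by_cause=grand_by_cause,
        cross_boundary_share=tf_in_total / grand if grand > 0 else np.nan,
        _tf_in_total=tf_in_total,
    )


def structures_exposed(
    perimeter: FirePerimeter, communities: CommunityLayer
) -> dict[int, float]:
    """Structures exposed per community by one fire.

    Polygon exposure = (burned cells in polygon / polygon cells) x
    structure count, summed over the community's polygons; a single fire
    can expose several communities.
    """
    cell_poly, meta = communities.polygon_index()
    pids = cell_poly[perimeter.cells]
    pids = pids[pids >= 0]
    out: dict[int, float] = {}
    if pids.size == 0:
        return out
    counts = np.bincount(pids, minlength=len(meta))
    for pid in np.flatnonzero(counts):
        cid, n_cells, structures = meta[pid]
        out[cid] = out.get(cid, 0.0) + counts[pid] / n_cells * structures
    return out
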