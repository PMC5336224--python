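"""Desk checks against the published per-tenure transmission table.

A published per-tenure transmission summary (annual NonTF / TF-IN /
TF-OUT hectares by cause for 11 land tenures on a large mixed-tenure
landscape) is shipped as a small CSV fixture, together with the study's
printed headline statistics and network node/edge counts. ``verify_printed_values`` recomputes every
derivable statistic from the printed inputs with this package's own
summarization code and compares each to its printed value.

Printed values are rounded, and the published table's row sums disagree
with its printed totals by up to ~0.5%, so the comparison tolerance is
1.5% relative.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .network import network_density
from .transmission import summarize_tenure_exposure

__all__ = [
    "load_table1",
    "load_printed_values",
    "summarize_table1",
    "verify_printed_values",
    "REL_TOL",
]

REL_TOL = 0.015


def _data_path(name: str) -> Path:
    return Path(str(resources.files("firenet").joinpath("data", name)))


def load_table1(path: str | Path | None = None) -> pd.DataFrame:
    """The published per-tenure table in long exposure format."""
    path = Path(path) if path is not None else _data_path("table1.csv")
    raw = pd.read_csv(path)
    if raw.empty:
        raise ValueError(f"empty per-tenure table: {path}")
    required = {"tenure", "nontf_human", "tfin_human", "tfout_human",
                "nontf_natural", "tfin_natural", "tfout_natural"}
    if not required.issubset(raw.columns):
        raise ValueError(f"malformed per-tenure table: {path}")
    rows = []
    for _, r in raw.iterrows():
        for cause in ("human", "natural"):
            rows.append((r["tenure"], cause, r[f"nontf_{cause}"],
                         r[f"tfin_{cause}"], r[f"tfout_{cause}"]))
    return pd.DataFrame(rows, columns=["tenure", "cause", "nontf", "tf_in",
                                       "tf_out"])


def load_printed_values(path: str | Path | None = None) -> dict:
    path = Path(path) if path is not None else _data_path("printed_values.json")
    return json.loads(path.read_text())


def summarize_table1(path: str | Path | None = None):
    return summarize_tenure_exposure(load_table1(path))


def _density(nodes: int, edges: int) -> float:
    import networkx as nx

    g = nx.empty_graph(nodes, create_using=nx.DiGraph)
    # density depends only on counts; build the count-equivalent graph
    it = ((u, v) for u in range(nodes) for v in range(nodes) if u != v)
    for _ in range(edges):
        g.add_edge(*next(it))
    return network_density(g)


def verify_printed_values(
    table1_path: str | Path | None = None,
    printed_path: str | Path | None = None,
    rel_tol: float = REL_TOL,
) -> pd.DataFrame:
    """Recompute the printed headline statistics and compare.

    Returns a DataFrame with one row per statistic: computed value,
    printed value, relative error and pass/fail at ``rel_tol``.
    """
    s = summarize_table1(table1_path)
    printed = load_printed_values(printed_path)
    res = printed["results"]
    hist = printed["historical"]

    checks: list[tuple[str, float, float]] = [
        ("community_incoming_fraction", s.incoming_fraction("Community"),
         res["community_incoming_fraction"]),
        ("mean_incoming_fraction", s.mean_incoming_fraction,
         res["mean_incoming_fraction"]),
        ("min_incoming_fraction", s.min_incoming_fraction,
         res["min_incoming_fraction"]),
        ("max_incoming_fraction", s.max_incoming_fraction,
         res["max_incoming_fraction"]),
        ("private_incoming_fraction",
         s.group_incoming_fraction(["Private", "PrivateIndustrial"]),
         res["private_incoming_fraction"]),
        ("cross_boundary_share", s.cross_boundary_share,
         res["cross_boundary_share"]),
        ("community_share_of_transmitted",
         s.share_of_transmitted(["Community"]),
         res["community_share_of_transmitted"]),
        ("community_human_total_ha",
         float(s.table.loc["Community", "nontf_human"]
               + s.table.loc["Community", "tf_in_human"]),
         res["community_human_total_ha"]),
        ("national_forest_total_ha",
         s.total_fire("NF-M") + s.total_fire("NF-P"),
         res["national_forest_total_ha"]),
        ("human_grand_total_ha", s.grand_total_by_cause["human"],
         res["human_grand_total_ha"]),
        ("natural_grand_total_ha", s.grand_total_by_cause["natural"],
         res["natural_grand_total_ha"]),
        ("ignitions_per_yr",
         hist["ignitions_total"] / hist["record_years"],
         hist["ignitions_per_yr"]),
        ("natural_mean_size_ha",
         hist["natural_area_per_yr_ha"] * hist["record_years"]
         / hist["natural_ignitions"],
         hist["natural_mean_size_ha"]),
    ]
    for net in printed["networks"]:
        checks.append(
            (f"network_density_{net['scale']}",
             _density(net["nodes"], net["edges"]), net["density"])
        )

    rows = []
    for name, computed, target in checks:
        rel = abs(computed - target) / abs(target)
        # printed values are rounded: also accept agreement to half the
        # last printed digit (e.g. 0.1443 vs a printed "14%")
        half_ulp = 0.5 * 10.0 ** np.floor(np.log10(abs(target)) - 1)
        ok = rel <= rel_tol or abs(computed - target) <= half_ulp
        rows.append((name, computed, target, rel, ok))
    return pd.DataFrame(
        rows, columns=["statistic", "computed", "printed", "rel_error", "ok"]
    )
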