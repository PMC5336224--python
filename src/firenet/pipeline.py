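"""End-to-end pipeline: synth -> ignite -> burn -> transmit -> network -> fireshed.

A PipelineConfig (loadable from TOML or YAML) fixes the landscape size,
study-condition parameters and seeds; ``run_pipeline`` executes every
stage, writes each module's outputs into a run directory and records
provenance (parameters, seeds, package version). A fixed config yields
bit-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .burnperiod import calibrate_burn_period
from .catalogue import IgnitionParams, generate_ignition_catalogue
from .communities import generate_communities, write_communities
from .fireshed import (
    build_exposure_points,
    delineate_fireshed,
    fireshed_summary,
    fit_variogram,
    ignition_density,
    krige_exposure_surface,
)
from .firelist import generate_fire_list
from .grid import generate_landscape, read_landscape, write_landscape
from .network import (
    EDGE_MIN_COMMUNITY,
    EDGE_MIN_TENURE,
    build_network,
    export_network,
    network_density,
)
from .occurrence import FireSizeModel, IgnitionOccurrenceModel
from .records import firelist_to_frame
from .spread import accumulate_burn_metrics, simulate_fire, write_perimeters
from .transmission import (
    attribute_fire,
    structures_exposed,
    summarize_tenure_exposure,
    tabulate_transmission,
)
from .weather import generate_weather

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "load_config"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    # landscape
    n_rows: int = 100
    n_cols: int = 100
    cell_size: float = 100.0
    n_tenures: int = 7
    mean_parcel_cells: int = 700
    n_communities: int = 5
    structures_total: int = 5000
    landscape_dir: str | None = None  # load instead of synthesizing
    # weather / catalogue study conditions. The default ignition rates are
    # scaled down from the historical 291/354 per year to suit a 10^4-ha
    # synthetic landscape (the full rates belong to a ~3.3 Mha study area)
    # while keeping enough records per cause to fit the occurrence models.
    weather_years: int = 18
    ignitions: IgnitionParams = field(
        default_factory=lambda: IgnitionParams(human_rate=12.0,
                                               natural_rate=15.0)
    )
    # simulation
    n_seasons: int = 200
    min_fire_size_ha: float = 10.0
    control_ratio: int = 10
    neighbors: int = 16
    calibration_durations: tuple[float, ...] = (60.0, 120.0, 240.0, 480.0, 960.0)
    # thresholds
    edge_min_tenure: float = EDGE_MIN_TENURE
    edge_min_community: float = EDGE_MIN_COMMUNITY
    fireshed_threshold: float = 0.1
    min_ignition_density: float = 1.5e-4
    max_kriged_communities: int = 8
    # reproducibility
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("min_fire_size_ha", "edge_min_tenure", "edge_min_community",
                     "fireshed_threshold", "min_ignition_density"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.landscape_dir is not None and not Path(self.landscape_dir).is_dir():
            raise ValueError(f"landscape_dir not found: {self.landscape_dir}")


def load_config(path: str | Path) -> PipelineConfig:
    path = Path(path)
    if path.suffix == ".toml":
        import tomllib

        raw = tomllib.loads(path.read_text())
    else:
        import yaml

        raw = yaml.safe_load(path.read_text())
    ign = raw.pop("ignitions", None)
    cfg = PipelineConfig(**raw)
    if ign:
        cfg.ignitions = IgnitionParams(**ign)
    return cfg


def _stage(name):
    def deco(fn):
        def wrapper(*a, **kw):
            try:
                return fn(*a, **kw)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage '{name}' failed: {exc}") from exc
        return wrapper
    return deco


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Run every stage and write all outputs under ``out_dir``.

    Returns a dict of in-memory results (grids, matrices, summaries,
    firesheds) for programmatic use; everything is also written to disk.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(config.seed)
    seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(8)]
    results: dict = {}

    # --- synth ---------------------------------------------------------
    @_stage("synth")
    def synth():
        if config.landscape_dir is not None:
            grid = read_landscape(config.landscape_dir)
        else:
            grid = generate_landscape(
                config.n_rows, config.n_cols, config.cell_size,
                config.n_tenures, config.mean_parcel_cells, seed=seeds[0],
            )
        communities = generate_communities(
            grid, config.n_communities, config.structures_total, seed=seeds[1]
        )
        weather = generate_weather(config.weather_years, seed=seeds[2])
        catalogue = generate_ignition_catalogue(
            grid, communities, weather, config.ignitions, seed=seeds[3]
        )
        write_landscape(communities.grid, out / "landscape")
        write_communities(communities, out / "communities.geojson")
        weather.to_csv(out / "weather.csv", index=False)
        catalogue.to_csv(out / "catalogue.csv", index=False)
        return grid, communities, weather, catalogue

    grid, communities, weather, catalogue = synth()
    sim_grid = communities.grid  # community cells carry the Community tenure
    results.update(grid=grid, communities=communities, weather=weather,
                   catalogue=catalogue)

    # --- ignite --------------------------------------------------------
    @_stage("ignite")
    def ignite():
        occ, size = {}, {}
        for cause in ("human", "natural"):
            occ[cause] = IgnitionOccurrenceModel(
                catalogue, weather, sim_grid, cause,
                control_ratio=config.control_ratio, seed=seeds[4],
            ).fit()
            size[cause] = FireSizeModel(
                catalogue, cause, min_size=config.min_fire_size_ha,
                grid=sim_grid,
            ).fit()
        conditions = weather.sample(
            n=min(len(weather), 40),
            random_state=np.random.RandomState(seeds[5] % (2 ** 31)),
        )
        curve = calibrate_burn_period(
            sim_grid, conditions, list(config.calibration_durations),
            seed=seeds[5], neighbors=config.neighbors,
        )
        firelist = generate_fire_list(
            occ, size, curve, weather, sim_grid, config.n_seasons,
            seed=seeds[6], min_size=config.min_fire_size_ha,
            catalogue=catalogue,
        )
        firelist_to_frame(firelist).to_csv(out / "firelist.csv", index=False)
        return occ, size, curve, firelist

    occ, size, curve, firelist = ignite()
    results.update(occurrence=occ, size=size, curve=curve, firelist=firelist)

    # --- burn ----------------------------------------------------------
    @_stage("burn")
    def burn():
        perimeters = [
            simulate_fire(sim_grid, rec, config.neighbors) for rec in firelist
        ]
        metrics = accumulate_burn_metrics(
            perimeters, len(perimeters), config.n_seasons, sim_grid
        )
        write_perimeters(perimeters, out / "perimeter_cells.csv",
                         out / "perimeter_summary.csv", sim_grid.n_cols)
        _write_metrics(metrics, sim_grid, out)
        return perimeters, metrics

    perimeters, metrics = burn()
    results.update(perimeters=perimeters, metrics=metrics)

    # --- transmit ------------------------------------------------------
    @_stage("transmit")
    def transmit():
        attributed = [
            attribute_fire(p, sim_grid, communities) for p in perimeters
        ]
        mt = tabulate_transmission(attributed, config.n_seasons, "tenure")
        mc = tabulate_transmission(attributed, config.n_seasons, "community")
        summary = summarize_tenure_exposure(mt)
        mt.to_long().to_csv(out / "transmission_tenure.csv", index=False)
        mc.to_long().to_csv(out / "transmission_community.csv", index=False)
        summary.table.to_csv(out / "tenure_exposure.csv")
        return attributed, mt, mc, summary

    attributed, matrix_tenure, matrix_community, summary = transmit()
    results.update(attributed=attributed, matrix_tenure=matrix_tenure,
                   matrix_community=matrix_community, exposure_summary=summary)

    # --- network -------------------------------------------------------
    @_stage("network")
    def network():
        nets = {}
        for name, matrix, thr in (
            ("tenure", matrix_tenure, config.edge_min_tenure),
            ("community", matrix_community, config.edge_min_community),
        ):
            full = build_network(matrix, 0.0)
            filtered = build_network(matrix, thr)
            export_network(full, out / f"network_{name}_edges.csv",
                           node_csv=out / f"network_{name}_nodes.csv")
            nets[name] = {
                "full": full,
                "filtered": filtered,
                "density": network_density(full),
            }
        return nets

    networks = network()
    results["networks"] = networks

    # --- fireshed ------------------------------------------------------
    @_stage("fireshed")
    def fireshed():
        points = build_exposure_points(perimeters, firelist, communities)
        dens = ignition_density(points, sim_grid, bandwidth_m=5 * grid.cell_size)
        exposed_counts = points.indicator.sum(axis=0).sort_values(ascending=False)
        chosen = [
            int(c) for c in exposed_counts.index[: config.max_kriged_communities]
            if points.indicator[c].nunique() > 1
        ]
        sheds = []
        for cid in chosen:
            vg = fit_variogram(points, cid)
            surface = krige_exposure_surface(points, cid, vg, sim_grid)
            sheds.append(delineate_fireshed(
                surface, sim_grid, cid, config.fireshed_threshold,
                dens, config.min_ignition_density,
            ))
        summary_fs = fireshed_summary(sheds, sim_grid, communities,
                                      _structures_rate(
                                          perimeters, attributed, communities,
                                          sim_grid, config.n_seasons))
        _write_firesheds(sheds, summary_fs, out)
        return points, sheds, summary_fs

    points, firesheds, fs_summary = fireshed()
    results.update(exposure_points=points, firesheds=firesheds,
                   fireshed_summary=fs_summary)

    provenance = {
        "firenet_version": __version__,
        "seed": config.seed,
        "derived_seeds": seeds,
        "config": _config_dict(config),
        "n_fires": len(firelist),
    }
    (out / "provenance.json").write_text(json.dumps(provenance, indent=2))
    results["provenance"] = provenance
    results["out_dir"] = out
    return results


def _config_dict(config: PipelineConfig) -> dict:
    d = dataclasses.asdict(config)
    d["calibration_durations"] = list(d["calibration_durations"])
    return d


def _write_metrics(metrics, grid, out: Path) -> None:
    import tifffile

    stack = np.concatenate(
        [
            metrics.bp.reshape(1, *metrics.shape),
            metrics.bp_per_fire.reshape(1, *metrics.shape),
            metrics.cfl.reshape(1, *metrics.shape),
            metrics.flame_bin_probs.T.reshape(-1, *metrics.shape),
        ]
    )
    tifffile.imwrite(out / "burn_metrics.tif", stack.astype(np.float32))


def _structures_rate(perimeters, attributed, communities, grid, n_seasons):
    """Structures exposed per year by (community, source tenure)."""
    acc: dict[tuple[int, str], float] = {}
    for per, att in zip(perimeters, attributed):
        for cid, s in structures_exposed(per, communities).items():
            key = (cid, att.source_label)
            acc[key] = acc.get(key, 0.0) + s / n_seasons
    return pd.DataFrame(
        [(cid, t, v) for (cid, t), v in acc.items()],
        columns=["community_id", "tenure", "structures_per_yr"],
    )


def _write_firesheds(sheds, summary, out: Path) -> None:
    import tifffile

    for fs in sheds:
        tifffile.imwrite(out / f"fireshed_{fs.community_id}.tif",
                         fs.mask.astype(np.uint8))
    flat = {
        "union_area_ha": summary["union_area_ha"],
        "overlap_fraction": summary["overlap_fraction"],
        "fireshed_to_developed_ratio": summary.get("fireshed_to_developed_ratio"),
        "union_composition_ha": summary["union_composition_ha"],
        "per_community_area_ha": summary["per_community_area_ha"],
    }
    (out / "fireshed_summary.json").write_text(json.dumps(flat, indent=2))
    eff = summary.get("transmission_efficiency")
    if eff is not None:
        eff.to_csv(out / "transmission_efficiency.csv", index=False)
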