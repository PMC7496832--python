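"""File-composing pipeline stages behind the command-line interface.

Each stage reads its inputs from / writes its outputs to an output directory
and records a :class:`~deepsea_exposure.config.RunManifest`, so a full
analysis is reproducible from the manifests alone. Stages:

simulate     -> synthetic climate cubes (NetCDF) + region polygons (GeoJSON)
hazard       -> per-driver hazard and cumulative negative hazard rasters
toe          -> per-driver and all-driver time-of-emergence rasters
summarize    -> Table-1-shaped regional min/max CSV
connectivity -> transport matrices and scenario-contrast class table (CSV)
refugia      -> refugium stack raster + per-count area summary (CSV)
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import connectivity as conn
from . import hazard as hz
from . import refugia as rf
from . import synthetic as syn
from .config import RunManifest, file_digest
from .grid import (
    DRIVERS,
    Field2D,
    Grid,
    read_climate_cube,
    read_field,
    read_regions,
    write_climate_cube,
    write_field,
    write_regions,
)

logger = logging.getLogger(__name__)


def _grid_from_cfg(cfg: dict) -> Grid:
    g = cfg["grid"]
    lat = np.linspace(g["lat_range"][0], g["lat_range"][1], g["nlat"])
    lon = np.linspace(g["lon_range"][0], g["lon_range"][1], g["nlon"])
    return Grid(lat=lat, lon=lon)


def _cube_path(out_dir: Path, driver: str, scenario: str) -> Path:
    return out_dir / f"cube_{driver}_{scenario}.nc"


def run_simulate(cfg: dict, out_dir) -> RunManifest:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    grid = _grid_from_cfg(cfg)
    years = range(cfg["years"]["start"], cfg["years"]["end"] + 1)
    sim = cfg["simulate"]
    manifest = RunManifest.create("simulate", cfg)
    for scenario, scale in sim["scenarios"].items():
        specs = syn.default_trend_specs(seed=int(cfg["seed"]),
                                        trend_magnitude=sim["trend_magnitude"] * scale,
                                        baseline_sd=sim["baseline_sd"],
                                        ar1_phi=sim["ar1_phi"])
        for driver, spec in specs.items():
            cube = syn.gen_climate_cube(spec, grid, years, scenario=scenario)
            path = _cube_path(out_dir, driver, scenario)
            write_climate_cube(cube, path)
            manifest.outputs.append(str(path))
    regions, _truth = syn.gen_regions(grid)
    rpath = out_dir / "regions.geojson"
    write_regions(regions, rpath)
    manifest.outputs.append(str(rpath))
    manifest.write(out_dir)
    return manifest


def run_hazard(cfg: dict, out_dir) -> RunManifest:
    out_dir = Path(out_dir)
    baseline_window = tuple(cfg["hazard"]["baseline_window"])
    windows = [tuple(w) for w in cfg["hazard"]["windows"]]
    manifest = RunManifest.create("hazard", cfg)
    for scenario in cfg["simulate"]["scenarios"]:
        hazards_by_window = {w: {} for w in windows}
        for driver in DRIVERS:
            path = _cube_path(out_dir, driver, scenario)
            manifest.inputs[str(path)] = file_digest(path)
            cube = read_climate_cube(path, driver)
            base = hz.baseline_stats(cube, baseline_window)
            for window in windows:
                hazards_by_window[window][driver] = hz.driver_hazard(
                    cube, base, window)
        for window, hazards in hazards_by_window.items():
            cum = hz.cumulative_negative_hazard(
                hazards, window, clamp=cfg["hazard"]["clamp_beneficial"])
            tag = f"{window[0]}_{window[1]}_{scenario}"
            for driver, hfield in hazards.items():
                p = out_dir / f"hazard_{driver}_{tag}.nc"
                write_field(hfield.as_field(), p)
                manifest.outputs.append(str(p))
            p = out_dir / f"cumulative_hazard_{tag}.nc"
            write_field(cum.as_field(), p)
            manifest.outputs.append(str(p))
    manifest.write(out_dir)
    return manifest


def run_toe(cfg: dict, out_dir) -> RunManifest:
    out_dir = Path(out_dir)
    tcfg = cfg["toe"]
    baseline_window = tuple(cfg["hazard"]["baseline_window"])
    manifest = RunManifest.create("toe", cfg)
    for scenario in cfg["simulate"]["scenarios"]:
        toes = {}
        for driver in DRIVERS:
            path = _cube_path(out_dir, driver, scenario)
            manifest.inputs[str(path)] = file_digest(path)
            cube = read_climate_cube(path, driver)
            base = hz.baseline_stats(cube, baseline_window)
            toes[driver] = hz.time_of_emergence(
                cube, base, k=tcfg["k"], rule=tcfg["rule"],
                horizon=tcfg["horizon"], two_sided=tcfg["two_sided"])
        toes["all_drivers"] = hz.toe_all_drivers(
            {d: toes[d] for d in DRIVERS})
        for name, toe in toes.items():
            p = out_dir / f"toe_{name}_{scenario}.nc"
            write_field(toe.as_field(), p)
            manifest.outputs.append(str(p))
    manifest.write(out_dir)
    return manifest


def run_summarize(cfg: dict, out_dir) -> RunManifest:
    out_dir = Path(out_dir)
    manifest = RunManifest.create("summarize", cfg)
    rpath = out_dir / "regions.geojson"
    manifest.inputs[str(rpath)] = file_digest(rpath)
    regions = read_regions(rpath)
    horizon = cfg["toe"]["horizon"]
    frames = []
    for scenario in cfg["simulate"]["scenarios"]:
        toe_path = out_dir / f"toe_all_drivers_{scenario}.nc"
        fld = read_field(toe_path, name=None)
        fld.attrs.update({"scenario": scenario, "horizon": horizon,
                          "window": f"->{horizon}"})
        fld.name = "toe_all_drivers"
        frames.append(hz.summaries_to_frame(hz.region_minmax(fld, regions)))
        for window in cfg["hazard"]["windows"]:
            tag = f"{window[0]}_{window[1]}_{scenario}"
            cpath = out_dir / f"cumulative_hazard_{tag}.nc"
            cfld = read_field(cpath, censored_as="nan")
            cfld.attrs.update({"scenario": scenario,
                               "window": f"{window[0]}-{window[1]}"})
            cfld.name = "cumulative_negative_hazard"
            frames.append(hz.summaries_to_frame(hz.region_minmax(cfld, regions)))
            manifest.inputs[str(cpath)] = file_digest(cpath)
        manifest.inputs[str(toe_path)] = file_digest(toe_path)
    table = pd.concat(frames, ignore_index=True)
    out = out_dir / "region_summary.csv"
    table.to_csv(out, index=False, float_format="%.6g")
    manifest.outputs.append(str(out))
    manifest.write(out_dir)
    return manifest


def run_connectivity(cfg: dict, out_dir) -> RunManifest:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ccfg = cfg["connectivity"]
    grid = _grid_from_cfg(cfg)
    manifest = RunManifest.create("connectivity", cfg)
    seed = int(cfg["seed"])

    sites = syn.gen_vent_sites(grid, n_sites=ccfg["n_sites"], seed=seed)
    release_times = tuple(30.0 * i for i in range(ccfg["n_releases"]))
    horizon = release_times[-1] + ccfg["duration_days"]
    times = np.arange(0.0, horizon + 30.0, 15.0)
    spec = conn.ReleaseSpec(
        particles_per_release=ccfg["particles_per_release"],
        release_times_days=release_times,
        duration_days=ccfg["duration_days"],
        dt_hours=ccfg["dt_hours"],
        diffusivity_m2s=ccfg["diffusivity_m2s"],
        capture_radius_km=ccfg["capture_radius_km"],
        seed=seed,
    )
    matrices = {}
    for label, scale in (("control", 1.0),
                         ("future", ccfg["future_amplitude_scale"])):
        flow = syn.FlowSpec(kind=ccfg["flow_kind"],
                            amplitude=ccfg["amplitude_ms"] * scale, seed=seed)
        field = syn.gen_velocity_field(flow, grid, times)
        traj = conn.advect_particles(field, sites, spec)
        matrices[label] = conn.transport_frequency(traj, sites, spec)
        p = out_dir / f"connectivity_{label}.csv"
        matrices[label].to_frame().to_csv(p, index=False, float_format="%.6g")
        manifest.outputs.append(str(p))
    delta = conn.compare_scenarios(matrices["future"], matrices["control"])
    p = out_dir / "connectivity_delta.csv"
    delta.to_frame().to_csv(p, index=False, float_format="%.6g")
    manifest.outputs.append(str(p))
    manifest.write(out_dir)
    return manifest


def run_refugia(cfg: dict, out_dir) -> RunManifest:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rcfg = cfg["refugia"]
    grid = _grid_from_cfg(cfg)
    manifest = RunManifest.create("refugia", cfg)
    species = syn.gen_suitability(rcfg["n_species"], grid, seed=int(cfg["seed"]),
                                  n_calibration=rcfg["n_calibration"])
    refugia_maps = {}
    for sp in species:
        thr = rf.mss_threshold(sp.calibration_scores, sp.calibration_labels)
        present = rf.binarize(sp.probability_present, thr)
        future = rf.binarize(sp.probability_future, thr)
        if rcfg["mode"] == "future_only":
            refugia_maps[sp.species] = future
        else:
            refugia_maps[sp.species] = rf.refugium_map(present, future)
    stack = rf.stack_refugia(refugia_maps)
    fld = Field2D(grid=grid, values=stack.counts.astype(float),
                  name="refugia_count")
    p = out_dir / "refugia_stack.nc"
    write_field(fld, p)
    manifest.outputs.append(str(p))

    areas = grid.cell_areas_km2()
    rows = [{"count": c,
             "n_cells": int((stack.counts == c).sum()),
             "area_km2": float(areas[stack.counts == c].sum())}
            for c in range(len(stack.species) + 1)]
    p = out_dir / "refugia_area_by_count.csv"
    pd.DataFrame(rows).to_csv(p, index=False, float_format="%.6g")
    manifest.outputs.append(str(p))
    manifest.write(out_dir)
    return manifest


STAGES = {
    "simulate": run_simulate,
    "hazard": run_hazard,
    "toe": run_toe,
    "summarize": run_summarize,
    "connectivity": run_connectivity,
    "refugia": run_refugia,
}
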