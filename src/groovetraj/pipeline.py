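"""Orchestration of the full analysis over one or more trajectories.

`run_analysis` executes, per simulation: helicity mask, helical-content
series and stable segments; across the replicate group: consensus segments,
RMSD series (all helices and the H1/H3/H4/H5 variant), the contact census
with per-pair persistence and the stable/unique sets, and the SASA burial
and windowed-exposure tables.  Every table is CSV with a fixed column order,
and a JSON manifest records every threshold and window used so each number
can be reproduced by calling the underlying operation directly.  A stage
failure is logged and marked in the bundle; later stages still run.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import contacts as contacts_mod
from . import helicity as helicity_mod
from . import sasa as sasa_mod
from .errors import ConfigError, GrooveTrajError, InputError
from .geometry import rmsd_series
from .structures import (RegionMap, Trajectory, default_region_map,
                         load_region_map, read_trajectory)

__all__ = ["SimulationEntry", "RunConfig", "load_run_config",
           "resolve_window", "run_analysis"]

log = logging.getLogger("groovetraj")


@dataclass
class SimulationEntry:
    label: str
    topology: str
    trajectory: str
    group: str = "cutoff"
    chain: str | None = None
    dt_ps: float | None = None


@dataclass
class RunConfig:
    simulations: list[SimulationEntry]
    out_dir: str
    region_map_path: str | None = None
    analysis_window: str = "all"
    first_window: str = "first:5ns"
    last_window: str = "last:5ns"
    cutoff_A: float = 4.0
    frac_threshold: float = 0.5
    occupancy_threshold: float = 0.8
    min_sims: int = 2
    min_len: int = 4
    min_seq_sep: int = 3
    helix_window: helicity_mod.HelixWindow = field(
        default_factory=helicity_mod.HelixWindow)
    sasa_params: sasa_mod.SasaParams = field(
        default_factory=sasa_mod.SasaParams)
    sasa_targets: list[int] = field(default_factory=list)
    sasa_mask_region: str = "LB"
    sasa_threshold_A2: float = 40.0
    rmsd_region_sets: list[list[str]] = field(default_factory=list)
    write_plots: bool = False

    def __post_init__(self):
        labels = [s.label for s in self.simulations]
        if len(labels) != len(set(labels)):
            raise ConfigError("simulation labels must be unique")

    def region_map(self) -> RegionMap:
        if self.region_map_path:
            return load_region_map(self.region_map_path)
        return default_region_map()


def load_run_config(path: str | Path) -> RunConfig:
    """Load a run configuration from YAML."""
    cfg = yaml.safe_load(Path(path).read_text())
    if not isinstance(cfg, dict):
        raise ConfigError(f"run config {path} is not a mapping")
    sims = [SimulationEntry(**entry) for entry in cfg.get("simulations", [])]
    if not sims:
        raise ConfigError("run config lists no simulations")
    windows = cfg.get("windows", {})
    thresholds = cfg.get("thresholds", {})
    hw = cfg.get("helix_window", {})
    sasa_cfg = cfg.get("sasa", {})
    return RunConfig(
        simulations=sims,
        out_dir=cfg.get("out_dir", "groovetraj_out"),
        region_map_path=cfg.get("region_map"),
        analysis_window=windows.get("analysis", "all"),
        first_window=windows.get("first", "first:5ns"),
        last_window=windows.get("last", "last:5ns"),
        cutoff_A=float(thresholds.get("cutoff_A", 4.0)),
        frac_threshold=float(thresholds.get("frac", 0.5)),
        occupancy_threshold=float(thresholds.get("occupancy", 0.8)),
        min_sims=int(thresholds.get("min_sims", 2)),
        min_len=int(thresholds.get("min_len", 4)),
        min_seq_sep=int(thresholds.get("min_seq_sep", 3)),
        helix_window=helicity_mod.HelixWindow(
            phi_min=float(hw.get("phi_min", -100.0)),
            phi_max=float(hw.get("phi_max", -30.0)),
            psi_min=float(hw.get("psi_min", -80.0)),
            psi_max=float(hw.get("psi_max", -5.0))),
        sasa_params=sasa_mod.SasaParams(
            probe_radius_A=float(sasa_cfg.get("probe_A", 1.4)),
            n_sphere_points=int(sasa_cfg.get("n_points", 960))),
        sasa_targets=[int(r) for r in sasa_cfg.get("targets", [])],
        sasa_mask_region=sasa_cfg.get("mask_region", "LB"),
        sasa_threshold_A2=float(sasa_cfg.get("threshold_A2", 40.0)),
        rmsd_region_sets=[list(s) for s in cfg.get("rmsd_region_sets", [])],
        write_plots=bool(cfg.get("write_plots", False)),
    )


def resolve_window(spec: str, traj: Trajectory) -> tuple[float, float]:
    """Resolve a window spec ("all", "last:20ns", "first:5ns", "t0:t1" in ps)
    into (t_start_ps, t_end_ps), inclusive of the boundary frame at the start
    of the window."""
    t0, t1 = float(traj.times_ps[0]), float(traj.times_ps[-1])
    spec = spec.strip()
    if spec == "all":
        return (t0, t1)
    if ":" not in spec:
        raise InputError(f"cannot parse window spec {spec!r}")
    head, tail = spec.split(":", 1)
    if head in ("last", "first"):
        if tail.endswith("ns"):
            span = float(tail[:-2]) * 1000.0
        elif tail.endswith("ps"):
            span = float(tail[:-2])
        else:
            span = float(tail)
        return (t1 - span, t1) if head == "last" else (t0, t0 + span)
    return (float(head), float(tail))


def _segments_frame(segments: Sequence[helicity_mod.Segment],
                    region_map: RegionMap) -> pd.DataFrame:
    rows = []
    for seg in segments:
        mid = (seg.start_residue + seg.end_residue) // 2
        rows.append({
            "start": seg.start_residue,
            "end": seg.end_residue,
            "length": seg.length,
            "region": region_map.region_of(mid) or "-",
        })
    return pd.DataFrame(rows, columns=["start", "end", "length", "region"])


def run_analysis(config: RunConfig) -> dict:
    """Run the full paper-style analysis; returns the report bundle.

    The bundle maps stage names to results; failed stages carry
    ``{"error": message}`` markers instead of aborting the run.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    region_map = config.region_map()
    bundle: dict = {"simulations": {}, "parameters": _manifest(config)}

    trajectories: dict[str, Trajectory] = {}
    masks: dict[str, helicity_mod.HelicityMask] = {}
    for sim in config.simulations:
        try:
            traj = read_trajectory(sim.topology, sim.trajectory,
                                   dt_ps=sim.dt_ps, chain=sim.chain)
            trajectories[sim.label] = traj
            mask = helicity_mod.helicity_mask(traj, config.helix_window)
            masks[sim.label] = mask
            content = helicity_mod.helical_content_series(
                traj, config.helix_window)
            pd.DataFrame({"time_ps": traj.times_ps,
                          "helical_content_pct": content}).to_csv(
                out / f"{sim.label}_content.csv", index=False)
            segs = helicity_mod.stable_segments(
                mask, config.occupancy_threshold, config.min_len)
            _segments_frame(segs, region_map).to_csv(
                out / f"{sim.label}_stable_segments.csv", index=False)
            helicity_mod.helicity_timeline(
                mask, csv_path=out / f"{sim.label}_timeline.csv",
                png_path=(out / f"{sim.label}_timeline.png"
                          if config.write_plots else None))
            bundle["simulations"][sim.label] = {
                "n_frames": traj.n_frames,
                "mean_content_pct": float(np.mean(content)),
                "stable_segments": [s.as_tuple() for s in segs],
            }
            log.info("simulation %s: %d frames, mean content %.1f%%",
                     sim.label, traj.n_frames, float(np.mean(content)))
        except (GrooveTrajError, OSError) as exc:
            log.error("simulation %s failed: %s", sim.label, exc)
            bundle["simulations"][sim.label] = {"error": str(exc)}

    # consensus across replicates
    good = [label for label in masks]
    if len(good) < config.min_sims:
        bundle["consensus_segments"] = {
            "error": f"insufficient replicates: {len(good)} available, "
                     f"min_sims={config.min_sims}"}
    else:
        try:
            cons = helicity_mod.consensus_segments(
                [masks[l] for l in good], config.min_sims,
                config.occupancy_threshold, config.min_len)
            _segments_frame(cons, region_map).to_csv(
                out / "consensus_segments.csv", index=False)
            bundle["consensus_segments"] = [s.as_tuple() for s in cons]
        except GrooveTrajError as exc:
            bundle["consensus_segments"] = {"error": str(exc)}

    # RMSD series per simulation, per region set
    region_sets = config.rmsd_region_sets or _default_region_sets(region_map)
    bundle["rmsd"] = {}
    for label, traj in trajectories.items():
        bundle["rmsd"][label] = {}
        for regions in region_sets:
            name = "+".join(regions)
            try:
                series = rmsd_series(traj, traj.frame(0), region_map, regions)
                pd.DataFrame({"time_ps": series.times_ps,
                              "rmsd_A": series.values_A}).to_csv(
                    out / f"{label}_rmsd_{name}.csv", index=False)
                bundle["rmsd"][label][name] = float(series.values_A[-1])
            except GrooveTrajError as exc:
                bundle["rmsd"][label][name] = {"error": str(exc)}

    # contacts
    try:
        bundle["contacts"] = _contact_stage(config, region_map, trajectories,
                                            out)
    except GrooveTrajError as exc:
        log.error("contact stage failed: %s", exc)
        bundle["contacts"] = {"error": str(exc)}

    # SASA
    if config.sasa_targets:
        try:
            bundle["sasa"] = _sasa_stage(config, region_map, trajectories, out)
        except GrooveTrajError as exc:
            log.error("SASA stage failed: %s", exc)
            bundle["sasa"] = {"error": str(exc)}
    else:
        bundle["sasa"] = {"skipped": "no sasa targets configured"}

    (out / "run_manifest.json").write_text(
        json.dumps(bundle["parameters"], indent=1))
    return bundle


def _default_region_sets(region_map: RegionMap) -> list[list[str]]:
    helices = list(region_map.helix_names)
    sets = [helices] if helices else []
    variant = [h for h in helices if h not in ("H2", "H6")]
    if variant and variant != helices:
        sets.append(variant)
    return sets


def _contact_stage(config: RunConfig, region_map: RegionMap,
                   trajectories: dict[str, Trajectory], out: Path) -> dict:
    if not trajectories:
        return {"error": "no trajectories loaded"}
    reference_structures = [t.frame(0) for t in trajectories.values()]
    pairs = contacts_mod.interacting_pairs(
        reference_structures, region_map, cutoff_A=config.cutoff_A,
        min_seq_sep=config.min_seq_sep)
    records = []
    for label, traj in trajectories.items():
        window = resolve_window(config.analysis_window, traj)
        for pair in sorted(pairs):
            records.append(contacts_mod.pair_persistence(
                traj, pair, cutoff_A=config.cutoff_A, window_ps=window,
                sim_id=label))
    stable = contacts_mod.stable_pairs(records, config.frac_threshold,
                                       config.min_sims)
    rows = []
    by_pair: dict = {}
    for rec in records:
        by_pair.setdefault(rec.pair, {})[rec.sim_id] = rec
    for pair in sorted(by_pair):
        row = {"res_a": pair.res_a, "res_b": pair.res_b,
               "region_a": pair.region_a, "region_b": pair.region_b}
        for label in trajectories:
            rec = by_pair[pair].get(label)
            row[f"{label}_mean_A"] = (round(rec.mean_min_dist_A, 2)
                                      if rec else np.nan)
            row[f"{label}_pct_below"] = (round(100 * rec.frac_below_cutoff)
                                         if rec else np.nan)
        row["stable"] = pair in stable
        rows.append(row)
    pd.DataFrame(rows).to_csv(out / "contact_persistence.csv", index=False)
    return {
        "n_pairs": len(pairs),
        "n_stable": len(stable),
        "stable_pairs": sorted((p.res_a, p.res_b) for p in stable),
    }


def _sasa_stage(config: RunConfig, region_map: RegionMap,
                trajectories: dict[str, Trajectory], out: Path) -> dict:
    result: dict = {}
    burial_rows = []
    exposure_frames = []
    for label, traj in trajectories.items():
        window = resolve_window(config.last_window, traj)
        records, total = sasa_mod.burial_by_region(
            traj, config.sasa_targets, region_map,
            mask_region=config.sasa_mask_region, window_ps=window,
            params=config.sasa_params)
        for rec in records:
            burial_rows.append({
                "simulation": label, "residue": rec.residue_number,
                "with_A2": round(rec.sasa_with_A2, 1),
                "without_A2": round(rec.sasa_without_A2, 1),
                "buried_A2": round(rec.buried_A2, 1)})
        result[label] = {"total_buried_A2": round(total, 1)}
        windows = [resolve_window(config.first_window, traj),
                   resolve_window(config.last_window, traj)]
        table = sasa_mod.windowed_exposure(
            traj, config.sasa_targets, windows, config.sasa_params,
            config.sasa_threshold_A2)
        table.insert(0, "simulation", label)
        exposure_frames.append(table)
    pd.DataFrame(burial_rows).to_csv(out / "sasa_burial.csv", index=False)
    pd.concat(exposure_frames, ignore_index=True).to_csv(
        out / "sasa_exposure.csv", index=False)
    return result


def _manifest(config: RunConfig) -> dict:
    return {
        "simulations": [{"label": s.label, "topology": s.topology,
                         "trajectory": s.trajectory, "group": s.group}
                        for s in config.simulations],
        "windows": {"analysis": config.analysis_window,
                    "first": config.first_window,
                    "last": config.last_window},
        "thresholds": {
            "cutoff_A": config.cutoff_A,
            "frac": config.frac_threshold,
            "occupancy": config.occupancy_threshold,
            "min_sims": config.min_sims,
            "min_len": config.min_len,
            "min_seq_sep": config.min_seq_sep,
        },
        "helix_window": {
            "phi_min": config.helix_window.phi_min,
            "phi_max": config.helix_window.phi_max,
            "psi_min": config.helix_window.psi_min,
            "psi_max": config.helix_window.psi_max,
        },
        "sasa": {
            "probe_A": config.sasa_params.probe_radius_A,
            "n_points": config.sasa_params.n_sphere_points,
            "radii_set": config.sasa_params.radii_set,
            "targets": config.sasa_targets,
            "mask_region": config.sasa_mask_region,
            "threshold_A2": config.sasa_threshold_A2,
        },
    }
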