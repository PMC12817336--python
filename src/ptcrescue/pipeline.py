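"""Reproducible multi-stage runs wiring generators to analysis stages.

A run is described by a plain-dict (YAML-friendly) configuration::

    stages: [simulate_flow, quantify_tr, activity, proximity, blot, scc]
    seed: 7
    out_dir: runs/demo
    flow:
      presets: {control_100pct: 1, q82x_untreated: 3}
      n_events: 20000
    proximity:
      preset: wild_type
      n_scenes: 2
    activity:
      samples: [wt_untreated, q82x_g418_max]
      reference: wt_untreated
    blot:
      preset: efficacy_dual_treatment
      mode: efficacy
    scc:
      variants: ["c.244C>T", "c.564G>A", "c.1279C>T"]

Each stochastic stage draws its own child seed from the run seed, every
numeric output is written as CSV/JSON under ``out_dir`` and echoed in the
JSON run report together with the parameters, seeds and input digests, so
re-running an identical configuration reproduces all numbers.  Warnings are
collected; only hard errors abort a run.
"""

from __future__ import annotations

import json
import logging
import platform
import time
from dataclasses import dataclass, field
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import presets
from .flow_tr import GatingConfig, PlateLayout, run_plate
from .imaging_proximity import ProximityConfig, run_proximity
from .quantification import (
    analyze_activity_plate,
    normalized_band_ratio,
    readthrough_efficacy_from_blot,
)
from .sequence_context import parse_hgvs_c, variant_report
from .synthetic_data import (
    make_synthetic_cds,
    simulate_activity_plate,
    simulate_blot,
    simulate_flow_sample,
    simulate_image_scene,
    write_fcs,
    write_scene_tiff,
)

logger = logging.getLogger(__name__)

KNOWN_STAGES = ("simulate_flow", "quantify_tr", "proximity", "activity", "blot", "scc")


class ConfigError(ValueError):
    pass


@dataclass
class RunReport:
    """Machine-readable provenance and outputs of one pipeline run."""

    config: dict
    seed: int
    stages: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)
    software: dict = field(default_factory=dict)
    wall_clock_s: float = 0.0

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2, default=_jsonable)


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, Path):
        return str(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def validate_config(config: dict) -> dict:
    if "stages" not in config or not config["stages"]:
        raise ConfigError("config must list at least one stage under 'stages'")
    unknown = [s for s in config["stages"] if s not in KNOWN_STAGES]
    if unknown:
        raise ConfigError(f"unknown stage(s) {unknown}; known: {list(KNOWN_STAGES)}")
    if "quantify_tr" in config["stages"] and "simulate_flow" not in config["stages"]:
        if "fcs_dir" not in config.get("quantify_tr", {}):
            raise ConfigError("quantify_tr without simulate_flow requires quantify_tr.fcs_dir")
    config.setdefault("seed", 0)
    config.setdefault("out_dir", "ptcrescue-run")
    return config


def _stage_simulate_flow(cfg: dict, rng: np.random.Generator, out: Path) -> dict:
    spec = cfg.get("flow", {})
    preset_reps: dict = spec.get("presets", {"control_100pct": 1, "q82x_untreated": 1})
    n_events = int(spec.get("n_events", 20_000))
    fcs_dir = out / "fcs"
    fcs_dir.mkdir(parents=True, exist_ok=True)
    wells = {}
    manifest = []
    idx = 0
    for preset, reps in preset_reps.items():
        model = presets.flow_model(preset)
        for rep in range(int(reps)):
            idx += 1
            seed = int(rng.integers(2**31))
            well = f"W{idx:02d}"
            fname = f"{preset}-r{rep + 1}.fcs"
            events = simulate_flow_sample(model, n_events, seed, sample_id=fname)
            write_fcs(events, fcs_dir / fname)
            role = "control" if preset == "control_100pct" and rep == 0 else "sample"
            wells[well] = {"file": fname, "condition": preset, "role": role}
            manifest.append(
                {"well": well, "file": fname, "preset": preset, "seed": seed,
                 "theta": presets.flow_truth(preset), "n_events": n_events, "role": role}
            )
    man = pd.DataFrame(manifest)
    man.to_csv(out / "flow_manifest.csv", index=False)
    with open(out / "plate_layout.yaml", "w") as fh:
        yaml.safe_dump({"wells": wells}, fh)
    return {"fcs_dir": str(fcs_dir), "manifest": str(out / "flow_manifest.csv"),
            "layout": str(out / "plate_layout.yaml"), "n_files": idx}


def _stage_quantify_tr(cfg: dict, out: Path, flow_outputs: dict | None) -> dict:
    spec = cfg.get("quantify_tr", {})
    if flow_outputs is not None:
        layout = PlateLayout.from_yaml(flow_outputs["layout"])
        fcs_dir = flow_outputs["fcs_dir"]
    else:
        layout = PlateLayout.from_yaml(spec["layout"])
        fcs_dir = spec["fcs_dir"]
    gating = GatingConfig(**spec.get("gating", {}))
    table, report = run_plate(
        layout,
        fcs_dir,
        config=gating,
        estimator=spec.get("estimator", "ratio-of-means"),
        background_correct=bool(spec.get("background_correct", False)),
        out_prefix=str(out / "tr_report"),
    )
    return {
        "table": str(out / "tr_report.csv"),
        "report": str(out / "tr_report.json"),
        "condition_summary": report["condition_summary"],
    }


def _stage_proximity(cfg: dict, rng: np.random.Generator, out: Path) -> dict:
    spec = cfg.get("proximity", {})
    preset = spec.get("preset", "wild_type")
    n_scenes = int(spec.get("n_scenes", 2))
    pcfg = ProximityConfig(**spec.get("config", {}))
    scenes = []
    img_dir = out / "scenes"
    img_dir.mkdir(parents=True, exist_ok=True)
    for i in range(n_scenes):
        sspec = presets.scene_spec(preset, seed=int(rng.integers(2**31)))
        image, _truth = simulate_image_scene(sspec)
        write_scene_tiff(img_dir / f"scene-{i + 1}.tif", image, sspec.pixel_size_um)
        scenes.append(image)
    _summaries, report = run_proximity(scenes, pcfg)
    with open(out / "proximity_report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=_jsonable)
    return {
        "report": str(out / "proximity_report.json"),
        "pooled_fraction_within": report["pooled_fraction_within"],
        "pooled_mean_center_to_center_um": report["pooled_mean_center_to_center_um"],
    }


def _stage_activity(cfg: dict, rng: np.random.Generator, out: Path) -> dict:
    spec = cfg.get("activity", {})
    names = spec.get("samples", ["wt_untreated", "q82x_g418_max"])
    sim = presets.activity_spec(names, read_noise_sd=float(spec.get("read_noise_sd", 0.0)))
    plate = simulate_activity_plate(sim, seed=int(rng.integers(2**31)))
    plate.to_csv(out / "activity_plate.csv", index=False)
    curve, results = analyze_activity_plate(plate)
    reference = spec.get("reference")
    if reference is not None and reference in set(results["sample_id"]):
        ref_val = float(
            results.loc[results["sample_id"] == reference, "activity_mU_per_mg"].iloc[0]
        )
        results["percent_of_reference"] = 100.0 * results["activity_mU_per_mg"] / ref_val
    results.to_csv(out / "activity_results.csv", index=False)
    return {
        "plate": str(out / "activity_plate.csv"),
        "results": str(out / "activity_results.csv"),
        "curve": {"slope": curve.slope, "intercept": curve.intercept,
                  "r_squared": curve.r_squared},
        "activities": results.to_dict(orient="records"),
    }


def _stage_blot(cfg: dict, rng: np.random.Generator, out: Path) -> dict:
    spec = cfg.get("blot", {})
    preset = spec.get("preset", "efficacy_dual_treatment")
    sim = presets.blot_spec(preset, intensity_noise_cv=float(spec.get("noise_cv", 0.0)))
    table = simulate_blot(sim, seed=int(rng.integers(2**31)))
    table.to_csv(out / "blot_bands.csv", index=False)
    mode = spec.get("mode", "efficacy" if sim.wt_reference_lane else "ratio")
    result: dict = {"bands": str(out / "blot_bands.csv"), "mode": mode}
    if mode == "efficacy":
        variant_lane = spec.get("variant_lane", sim.lanes[-1].lane)
        target = spec.get("target", next(iter(sim.lanes[-1].abundances)))
        result["efficacy_percent"] = readthrough_efficacy_from_blot(
            table, variant_lane, sim.wt_reference_lane, target
        )
    else:
        lanes = list(sim.lanes)
        result["relative_percent"] = normalized_band_ratio(
            table,
            target=spec.get("target", next(iter(lanes[-1].abundances))),
            control_target=sim.loading_control_target,
            condition=spec.get("condition", lanes[-1].condition),
            baseline_condition=spec.get("baseline_condition", lanes[0].condition),
        )
    return result


def _stage_scc(cfg: dict, out: Path) -> dict:
    spec = cfg.get("scc", {})
    seq = make_synthetic_cds(seed=int(spec.get("cds_seed", 0)))
    variants = spec.get("variants", ["c.244C>T", "c.564G>A", "c.1279C>T"])
    reports = [variant_report(seq, parse_hgvs_c(v)) for v in variants]
    pd.DataFrame(reports).to_csv(out / "scc_report.csv", index=False)
    with open(out / "scc_report.json", "w") as fh:
        json.dump(reports, fh, indent=2)
    return {"report": str(out / "scc_report.csv"), "variants": reports}


def run(config: dict) -> RunReport:
    """Execute the requested stages in dependency order and write a report."""
    t0 = time.monotonic()
    config = validate_config(dict(config))
    out = Path(config["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(int(config["seed"]))
    try:
        pkg_version = version("ptcrescue")
    except PackageNotFoundError:
        pkg_version = "unknown"
    report = RunReport(
        config=config,
        seed=int(config["seed"]),
        software={"ptcrescue": pkg_version, "python": platform.python_version()},
    )

    stages = list(config["stages"])
    ordered = [s for s in KNOWN_STAGES if s in stages]
    flow_outputs = None
    for stage in ordered:
        logger.info("running stage %s", stage)
        try:
            if stage == "simulate_flow":
                flow_outputs = _stage_simulate_flow(config, rng, out)
                report.stages[stage] = flow_outputs
            elif stage == "quantify_tr":
                report.stages[stage] = _stage_quantify_tr(config, out, flow_outputs)
            elif stage == "proximity":
                report.stages[stage] = _stage_proximity(config, rng, out)
            elif stage == "activity":
                report.stages[stage] = _stage_activity(config, rng, out)
            elif stage == "blot":
                report.stages[stage] = _stage_blot(config, rng, out)
            elif stage == "scc":
                report.stages[stage] = _stage_scc(config, out)
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    report.wall_clock_s = time.monotonic() - t0
    report.to_json(out / "run_report.json")
    return report
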