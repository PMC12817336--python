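"""Named study-condition presets for the synthetic generators.

Presets encode the experimental conditions the pipeline is validated
against (true readthrough fractions, specific activities, proximity
geometry).  They live in a versioned YAML file shipped with the package so
acceptance checks are parameter-recovery tests with transparent truth.
"""

from __future__ import annotations

import importlib.resources
from functools import lru_cache

import yaml

from .synthetic_data import (
    ActivitySample,
    AssaySimSpec,
    BlotLane,
    BlotSimSpec,
    ImageSceneSpec,
    ReporterCellModel,
)


class UnknownPresetError(KeyError):
    pass


@lru_cache(maxsize=1)
def _catalog() -> dict:
    ref = importlib.resources.files("ptcrescue").joinpath("presets.yaml")
    return yaml.safe_load(ref.read_text())


def list_presets() -> dict:
    """Full catalog: every preset with its truth parameters and description."""
    cat = _catalog()
    return {
        "version": cat["version"],
        "flow": {
            name: {**cat["flow_base"], **entry} for name, entry in cat["flow"].items()
        },
        "proximity": cat["proximity"],
        "activity": {
            name: {**cat["activity_curve"], **entry}
            for name, entry in cat["activity"].items()
        },
        "blot": cat["blot"],
    }


def _lookup(section: str, name: str) -> dict:
    cat = _catalog()
    if name not in cat[section]:
        raise UnknownPresetError(
            f"unknown {section} preset {name!r}; available: {sorted(cat[section])}"
        )
    return dict(cat[section][name])


def flow_model(name: str, **overrides) -> ReporterCellModel:
    """Reporter measurement model for a named flow condition."""
    entry = _lookup("flow", name)
    entry.pop("description", None)
    params = {**_catalog()["flow_base"], **entry, **overrides}
    return ReporterCellModel(**params)


def flow_truth(name: str) -> float:
    """True readthrough fraction theta behind a flow preset."""
    return float(_lookup("flow", name)["theta"])


def scene_spec(name: str, seed: int = 0, **overrides) -> ImageSceneSpec:
    """Image-scene specification for a named proximity condition."""
    entry = _lookup("proximity", name)
    entry.pop("description", None)
    entry["image_shape"] = tuple(entry["image_shape"])
    entry["lamp1_diameter_um"] = tuple(entry["lamp1_diameter_um"])
    entry["beyond_gap_um"] = tuple(entry["beyond_gap_um"])
    entry.update(overrides)
    return ImageSceneSpec(seed=seed, **entry)


def activity_spec(
    sample_names: list[str] | str, read_noise_sd: float = 0.0, **curve_overrides
) -> AssaySimSpec:
    """Assay plate specification holding the named activity presets."""
    if isinstance(sample_names, str):
        sample_names = [sample_names]
    samples = []
    for name in sample_names:
        entry = _lookup("activity", name)
        entry.pop("description", None)
        samples.append(ActivitySample(sample_id=name, **entry))
    curve = {**_catalog()["activity_curve"], **curve_overrides}
    return AssaySimSpec(samples=tuple(samples), read_noise_sd=read_noise_sd, **curve)


def activity_truth(name: str) -> float:
    return float(_lookup("activity", name)["true_activity_mU_per_mg"])


def blot_spec(name: str, intensity_noise_cv: float = 0.0) -> BlotSimSpec:
    """Blot simulation specification for a named densitometry scenario."""
    entry = _lookup("blot", name)
    entry.pop("description", None)
    lanes = tuple(BlotLane(**lane) for lane in entry.pop("lanes"))
    return BlotSimSpec(lanes=lanes, intensity_noise_cv=intensity_noise_cv, **entry)
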