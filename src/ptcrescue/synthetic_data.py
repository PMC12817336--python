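"""Generators for every input the readthrough-rescue pipeline consumes.

Each generator has a known ground truth so downstream stages can be tested
as parameter-recovery problems without any external data:

* :func:`simulate_flow_sample` — mixed transfected/untransfected/debris
  cytometry events from a dual-reporter measurement model with a true
  per-transcript readthrough fraction ``theta`` (``theta = 1`` is the
  stop-free fusion control).
* :func:`simulate_image_scene` — two-channel fluorescence scenes of
  sub-micrometer lysosome-like discs (target channel) and enzyme puncta
  (source channel) with a controlled nearest edge-to-edge distance mixture.
* :func:`simulate_activity_plate` — 4-MU standard curves plus lysate
  readings from true specific activities.
* :func:`simulate_blot` — band-intensity tables with loading-control
  structure and a diluted wild-type reference lane.
* :func:`make_synthetic_cds` — a stop-free coding sequence carrying the
  studied PTC positions (codons 82 / 188 / 427).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

from .fcs import DEFAULT_CHANNEL_NAMES, EventTable, write_fcs  # noqa: F401  (re-export)
from .sequence_context import STOP_CODONS, CodingSequence

__all__ = [
    "ReporterCellModel",
    "ImageSceneSpec",
    "AssaySimSpec",
    "ActivitySample",
    "BlotSimSpec",
    "BlotLane",
    "simulate_flow_sample",
    "simulate_image_scene",
    "simulate_activity_plate",
    "simulate_blot",
    "make_synthetic_cds",
    "write_scene_tiff",
    "read_scene_tiff",
    "write_fcs",
]


def _require(cond: bool, name: str, msg: str) -> None:
    if not cond:
        raise ValueError(f"invalid parameter {name!r}: {msg}")


# --------------------------------------------------------------------------
# Dual-reporter flow cytometry
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ReporterCellModel:
    """Generative parameters for one dual-reporter flow sample.

    Transfected cells express the reporter transcript at a lognormal level
    ``E``; the RFP channel reads ``rfp_gain * E`` and the GFP channel reads
    ``theta * gfp_gain * E`` (readthrough product per transcript), each with
    multiplicative lognormal measurement noise of coefficient of variation
    ``noise_cv`` (unit mean) plus additive per-channel autofluorescence.
    Untransfected cells and debris carry autofluorescence only; debris is
    drawn from a low scatter distribution that falls outside the cell gate
    with high probability.
    """

    theta: float
    transfected_fraction: float = 0.35
    expression_log_mean: float = 10.8
    expression_log_sd: float = 0.5
    rfp_gain: float = 1.0
    gfp_gain: float = 1.0
    autofluor_rfp_mean: float = 45.0
    autofluor_gfp_mean: float = 0.5
    autofluor_sd: float = 0.8
    fsc_mean: float = 49_000.0
    fsc_sd: float = 8_000.0
    ssc_mean: float = 40_000.0
    ssc_sd: float = 9_000.0
    debris_fraction: float = 0.08
    noise_cv: float = 0.15

    def __post_init__(self) -> None:
        for name in ("theta", "transfected_fraction", "debris_fraction"):
            v = getattr(self, name)
            _require(0.0 <= v <= 1.0, name, f"{v} not in [0, 1]")
        for name in ("rfp_gain", "gfp_gain", "fsc_mean", "fsc_sd", "ssc_mean", "ssc_sd"):
            _require(getattr(self, name) > 0, name, "must be strictly positive")
        for name in ("expression_log_sd", "autofluor_rfp_mean", "autofluor_gfp_mean",
                     "autofluor_sd", "noise_cv"):
            _require(getattr(self, name) >= 0, name, "must be nonnegative")


def _unit_mean_lognormal(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    """Multiplicative noise factors with exact unit mean and the given CV."""
    if cv == 0:
        return np.ones(size)
    sigma2 = math.log1p(cv * cv)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=math.sqrt(sigma2), size=size)


def simulate_flow_sample(
    model: ReporterCellModel, n_events: int, seed: int, sample_id: str | None = None
) -> EventTable:
    """Simulate one dual-reporter sample as an :class:`EventTable`.

    Events are debris with probability ``debris_fraction``; the remainder are
    transfected with probability ``transfected_fraction``.  Reproducible for
    a given seed; rows are shuffled so event order carries no class signal.
    """
    if n_events < 1:
        raise ValueError(f"n_events must be >= 1, got {n_events}")
    rng = np.random.default_rng(seed)

    u = rng.random(n_events)
    is_debris = u < model.debris_fraction
    is_transfected = (~is_debris) & (rng.random(n_events) < model.transfected_fraction)

    fsc = rng.normal(model.fsc_mean, model.fsc_sd, n_events)
    ssc = rng.normal(model.ssc_mean, model.ssc_sd, n_events)
    # debris: fixed low-scatter cloud well below the cell gate
    nd = int(is_debris.sum())
    fsc[is_debris] = rng.normal(0.15 * model.fsc_mean, model.fsc_sd, nd)
    ssc[is_debris] = rng.normal(0.15 * model.ssc_mean, model.ssc_sd, nd)

    expr = np.zeros(n_events)
    nt = int(is_transfected.sum())
    expr[is_transfected] = rng.lognormal(
        model.expression_log_mean, model.expression_log_sd, nt
    )

    af_rfp = np.clip(rng.normal(model.autofluor_rfp_mean, model.autofluor_sd, n_events), 0, None)
    af_gfp = np.clip(rng.normal(model.autofluor_gfp_mean, model.autofluor_sd, n_events), 0, None)

    noise_r = _unit_mean_lognormal(rng, model.noise_cv, n_events)
    noise_g = _unit_mean_lognormal(rng, model.noise_cv, n_events)

    rfp = model.rfp_gain * expr * noise_r + af_rfp
    gfp = model.theta * model.gfp_gain * expr * noise_g + af_gfp

    order = rng.permutation(n_events)
    data = pd.DataFrame(
        {
            "FSC": np.clip(fsc, 0, None)[order],
            "SSC": np.clip(ssc, 0, None)[order],
            "GFP": gfp[order],
            "RFP": rfp[order],
        }
    )
    return EventTable(
        data=data,
        sample_id=sample_id or f"sim-theta{model.theta:g}-seed{seed}",
    )


# --------------------------------------------------------------------------
# Two-channel proximity image scenes
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ImageSceneSpec:
    """Specification of a synthetic two-channel lysosome/puncta scene.

    Channel 0 holds lysosome-like discs (membrane marker role, the distance
    *target*); channel 1 holds enzyme puncta (the distance *source*).  The
    FUCA1-to-nearest-LAMP1 edge-to-edge distance follows a two-component
    mixture: a fraction ``fraction_within_02um`` of puncta are luminal,
    each placed inside a distinct disc at a uniform radial offset
    (center-to-center between 0.05 um and ``r_disc + r_punctum - 0.06``,
    so punctum and disc genuinely overlap and the realized edge distance
    is 0); the remainder sit at an edge gap drawn from ``beyond_gap_um``.
    The gap interval starts well above the classification radius on
    purpose: segmentation masks dilate by roughly one pixel per boundary
    at these optics, and the guard band keeps that from flipping a
    punctum's class.  Disc count and diameters default to one disc per
    luminal punctum at the small end of the sub-700-nm lysosome range, so
    that every punctum is optically resolvable at the default pixel size.
    """

    image_shape: tuple[int, int] = (512, 512)
    pixel_size_um: float = 0.1
    n_lamp1: int = 60
    lamp1_diameter_um: tuple[float, float] = (0.2, 0.3)
    n_fuca1: int = 100
    fuca1_diameter_um: float = 0.2
    fraction_within_02um: float = 0.6
    within_radius_um: float = 0.2
    beyond_gap_um: tuple[float, float] = (0.44, 0.54)
    psf_sigma_px: float = 0.8
    background_level: float = 20.0
    background_gradient: float = 10.0
    photon_noise_scale: float = 8.0
    lamp1_amplitude: float = 180.0
    fuca1_amplitude: float = 200.0
    seed: int = 0

    def __post_init__(self) -> None:
        _require(self.pixel_size_um > 0, "pixel_size_um", "must be positive")
        _require(0.0 <= self.fraction_within_02um <= 1.0, "fraction_within_02um", "not in [0,1]")
        _require(self.n_lamp1 >= 1, "n_lamp1", "need at least one target object")
        _require(self.n_fuca1 >= 0, "n_fuca1", "must be nonnegative")
        lo, hi = self.lamp1_diameter_um
        _require(0 < lo <= hi < 0.7, "lamp1_diameter_um", "range must lie in (0, 0.7) um")
        _require(
            lo / self.pixel_size_um >= 2.0,
            "lamp1_diameter_um",
            "smallest diameter is under 2 pixels",
        )
        _require(
            self.fuca1_diameter_um / self.pixel_size_um >= 2.0,
            "fuca1_diameter_um",
            "diameter is under 2 pixels",
        )
        glo, ghi = self.beyond_gap_um
        _require(
            glo > self.within_radius_um,
            "beyond_gap_um",
            "beyond-component gap must start above the within radius",
        )
        _require(ghi >= glo, "beyond_gap_um", "range reversed")
        _require(self.psf_sigma_px >= 0, "psf_sigma_px", "must be nonnegative")
        _require(self.photon_noise_scale >= 0, "photon_noise_scale", "must be nonnegative")


class PlacementError(RuntimeError):
    """Objects could not be placed inside bounds within the attempt budget."""


def _render_discs(shape, centers_px, radii_px, amplitude) -> np.ndarray:
    """Soft-edged (1 px antialiased) discs summed into an image."""
    img = np.zeros(shape, dtype=np.float64)
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    for (cy, cx), r in zip(centers_px, radii_px):
        lo_y, hi_y = max(0, int(cy - r - 3)), min(shape[0], int(cy + r + 4))
        lo_x, hi_x = max(0, int(cx - r - 3)), min(shape[1], int(cx + r + 4))
        d = np.hypot(yy[lo_y:hi_y, lo_x:hi_x] - cy, xx[lo_y:hi_y, lo_x:hi_x] - cx)
        img[lo_y:hi_y, lo_x:hi_x] += amplitude * np.clip(r + 0.5 - d, 0.0, 1.0)
    return img


def _edge_distance(c2c: float, r1: float, r2: float) -> float:
    return max(0.0, c2c - r1 - r2)


def simulate_image_scene(spec: ImageSceneSpec) -> tuple[np.ndarray, dict[str, pd.DataFrame]]:
    """Render one scene and return ``(image, ground_truth)``.

    ``image`` has shape ``(2, H, W)`` (channel 0 = lysosome discs, channel 1
    = puncta).  ``ground_truth`` holds two data frames (``"lamp1"``,
    ``"fuca1"``) with centroids and radii in micrometers; the puncta table
    additionally records the mixture component and the *realized* nearest
    edge-to-edge / center-to-center distances over all discs, which are
    exactly reproducible from the stored geometry.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_shape
    px = spec.pixel_size_um
    r_f = spec.fuca1_diameter_um / 2.0

    d_lo, d_hi = spec.lamp1_diameter_um
    g_lo, g_hi = spec.beyond_gap_um
    margin_um = d_hi / 2 + g_hi + r_f + 0.3  # keep partnered puncta in bounds
    _require(
        min(h, w) * px > 2 * margin_um + 1.0,
        "image_shape",
        "image too small for the object geometry",
    )

    # --- place lysosome discs with pairwise separation so they segment
    # apart and their luminal puncta cannot merge with a neighbor's
    lamp_xy: list[tuple[float, float]] = []
    lamp_r: list[float] = []
    min_sep_extra = 0.8
    attempts = 0
    while len(lamp_xy) < spec.n_lamp1:
        attempts += 1
        if attempts > 20_000:
            raise PlacementError(
                f"could not place {spec.n_lamp1} target discs after {attempts} attempts"
            )
        r = rng.uniform(d_lo, d_hi) / 2.0
        y = rng.uniform(margin_um, h * px - margin_um)
        x = rng.uniform(margin_um, w * px - margin_um)
        ok = all(
            np.hypot(y - oy, x - ox) >= r + orr + min_sep_extra
            for (oy, ox), orr in zip(lamp_xy, lamp_r)
        )
        if ok:
            lamp_xy.append((y, x))
            lamp_r.append(r)
    lamp_xy_arr = np.asarray(lamp_xy)
    lamp_r_arr = np.asarray(lamp_r)

    # --- place puncta according to the distance mixture
    fuca_rows = []
    fuca_xy: list[tuple[float, float]] = []
    occupied: set[int] = set()  # discs already hosting a luminal punctum
    # separation ladder: prefer well-separated puncta; the final rung is an
    # escape hatch for the rare binomial overflow of luminal puncta beyond
    # one per disc (such puncta may merge in the rendered image)
    for i in range(spec.n_fuca1):
        within = rng.random() < spec.fraction_within_02um
        placed = False
        for min_punctum_sep in (0.7, 0.6, 0.5, 0.3):
            if within:
                free = [p for p in rng.permutation(spec.n_lamp1) if p not in occupied]
                used = [p for p in rng.permutation(spec.n_lamp1) if p in occupied]
                partners = free + used
            else:
                partners = list(rng.permutation(spec.n_lamp1))
            for partner in partners:
                r_l = lamp_r_arr[partner]
                py, pxc = lamp_xy_arr[partner]
                for _ in range(100):
                    if within:
                        c2c = rng.uniform(0.05, r_l + r_f - 0.06)
                    else:
                        c2c = r_l + r_f + rng.uniform(g_lo, g_hi)
                    ang = rng.uniform(0, 2 * np.pi)
                    y = py + c2c * np.sin(ang)
                    x = pxc + c2c * np.cos(ang)
                    if not (margin_um * 0.3 < y < h * px - margin_um * 0.3):
                        continue
                    if not (margin_um * 0.3 < x < w * px - margin_um * 0.3):
                        continue
                    if any(np.hypot(y - oy, x - ox) < min_punctum_sep for oy, ox in fuca_xy):
                        continue
                    d_all = np.hypot(lamp_xy_arr[:, 0] - y, lamp_xy_arr[:, 1] - x)
                    edges = np.maximum(0.0, d_all - lamp_r_arr - r_f)
                    if within and edges.min() > spec.within_radius_um:
                        continue
                    if not within and edges.min() < g_lo:
                        continue
                    nearest = int(np.argmin(edges))
                    fuca_xy.append((y, x))
                    if within:
                        occupied.add(int(partner))
                    fuca_rows.append(
                        {
                            "label": i + 1,
                            "y_um": y,
                            "x_um": x,
                            "radius_um": r_f,
                            "component": "within" if within else "beyond",
                            "partner": partner + 1,
                            "nearest_lamp1": nearest + 1,
                            "center_to_center_um": float(d_all[nearest]),
                            "edge_to_edge_um": float(edges[nearest]),
                        }
                    )
                    placed = True
                    break
                if placed:
                    break
            if placed:
                break
        if not placed:
            raise PlacementError(f"could not place punctum {i + 1} within the attempt budget")

    truth_lamp1 = pd.DataFrame(
        {
            "label": np.arange(1, spec.n_lamp1 + 1),
            "y_um": lamp_xy_arr[:, 0],
            "x_um": lamp_xy_arr[:, 1],
            "radius_um": lamp_r_arr,
        }
    )
    truth_fuca1 = pd.DataFrame(
        fuca_rows,
        columns=[
            "label", "y_um", "x_um", "radius_um", "component", "partner",
            "nearest_lamp1", "center_to_center_um", "edge_to_edge_um",
        ],
    )

    # --- render
    ch0 = _render_discs((h, w), lamp_xy_arr / px, lamp_r_arr / px, spec.lamp1_amplitude)
    if len(fuca_xy):
        ch1 = _render_discs(
            (h, w),
            np.asarray(fuca_xy) / px,
            np.full(len(fuca_xy), r_f / px),
            spec.fuca1_amplitude,
        )
    else:
        ch1 = np.zeros((h, w))

    grad = spec.background_gradient * (np.arange(w) / max(1, w - 1))[None, :]
    img = np.stack([ch0, ch1]) + spec.background_level + grad

    if spec.psf_sigma_px > 0:
        from scipy.ndimage import gaussian_filter

        img = np.stack([gaussian_filter(c, spec.psf_sigma_px) for c in img])
    if spec.photon_noise_scale > 0:
        img = rng.poisson(np.clip(img, 0, None) * spec.photon_noise_scale) / spec.photon_noise_scale
    return img.astype(np.float32), {"lamp1": truth_lamp1, "fuca1": truth_fuca1}


def write_scene_tiff(path, image: np.ndarray, pixel_size_um: float) -> None:
    """Write a (C, H, W) scene as a multi-channel TIFF with pixel size metadata."""
    tifffile.imwrite(
        path,
        image,
        resolution=(1.0 / pixel_size_um, 1.0 / pixel_size_um),
        resolutionunit="MICROMETER",
        metadata={"axes": "CYX", "PixelSizeUm": pixel_size_um},
    )
    sidecar = str(path) + ".yaml"
    with open(sidecar, "w") as fh:
        yaml.safe_dump({"pixel_size_um": float(pixel_size_um), "axes": "CYX"}, fh)


def read_scene_tiff(path) -> tuple[np.ndarray, float]:
    """Read a scene TIFF; pixel size from sidecar YAML, else TIFF resolution."""
    image = tifffile.imread(path)
    try:
        with open(str(path) + ".yaml") as fh:
            meta = yaml.safe_load(fh)
        return image, float(meta["pixel_size_um"])
    except FileNotFoundError:
        with tifffile.TiffFile(path) as tf:
            page = tf.pages[0]
            xres = page.tags.get("XResolution")
            if xres is None:
                raise ValueError(f"{path}: no pixel size metadata found") from None
            num, den = xres.value
            return image, float(den) / float(num)


# --------------------------------------------------------------------------
# Enzyme-activity plates
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ActivitySample:
    """One lysate reaction with a known true specific activity (mU/mg)."""

    sample_id: str
    true_activity_mU_per_mg: float
    protein_mg: float = 0.02
    dilution_factor: float = 1.0
    incubation_min: float = 30.0

    def __post_init__(self) -> None:
        _require(self.true_activity_mU_per_mg >= 0, "true_activity_mU_per_mg", "negative")
        _require(self.protein_mg > 0, "protein_mg", "must be positive")
        _require(self.dilution_factor >= 1, "dilution_factor", "must be >= 1")
        _require(self.incubation_min > 0, "incubation_min", "must be positive")


@dataclass(frozen=True)
class AssaySimSpec:
    """A fluorogenic 4-MU activity plate: standards plus lysate samples."""

    curve_slope: float = 100.0  # AU per nmol 4-MU
    curve_intercept: float = 50.0  # blank AU
    standard_points: Sequence[float] = (0.0, 0.25, 0.5, 1.0, 2.5, 5.0, 7.5)
    samples: Sequence[ActivitySample] = ()
    read_noise_sd: float = 0.0

    def __post_init__(self) -> None:
        _require(self.curve_slope > 0, "curve_slope", "must be positive")
        _require(self.read_noise_sd >= 0, "read_noise_sd", "negative noise sd")
        _require(len(self.standard_points) >= 2, "standard_points", "need >= 2 points")
        _require(0.0 in [float(x) for x in self.standard_points], "standard_points",
                 "must include the 0 nmol blank")
        _require(all(x >= 0 for x in self.standard_points), "standard_points",
                 "negative 4-MU amount")


def simulate_activity_plate(spec: AssaySimSpec, seed: int) -> pd.DataFrame:
    """Simulate plate readings.

    Standards read ``slope * nmol + intercept``; each sample reads
    ``slope * (activity * protein_mg * incubation_min / dilution) +
    intercept``; Gaussian read noise is added to every well.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for nmol in spec.standard_points:
        rows.append(
            {
                "role": "standard",
                "sample_id": f"std-{nmol:g}",
                "nmol_4mu": float(nmol),
                "protein_mg": np.nan,
                "dilution_factor": np.nan,
                "incubation_min": np.nan,
                "reading": spec.curve_slope * float(nmol) + spec.curve_intercept,
            }
        )
    for s in spec.samples:
        nmol = (
            s.true_activity_mU_per_mg * s.protein_mg * s.incubation_min / s.dilution_factor
        )
        if nmol < 0:
            raise ValueError(f"sample {s.sample_id}: negative computed 4-MU amount")
        rows.append(
            {
                "role": "sample",
                "sample_id": s.sample_id,
                "nmol_4mu": nmol,
                "protein_mg": s.protein_mg,
                "dilution_factor": s.dilution_factor,
                "incubation_min": s.incubation_min,
                "reading": spec.curve_slope * nmol + spec.curve_intercept,
            }
        )
    plate = pd.DataFrame(rows)
    if spec.read_noise_sd > 0:
        plate["reading"] = plate["reading"] + rng.normal(0, spec.read_noise_sd, len(plate))
    return plate


# --------------------------------------------------------------------------
# Blot band-intensity tables
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class BlotLane:
    """One lane: a condition with per-target true relative abundances."""

    lane: str
    condition: str
    load_ug: float
    abundances: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        _require(self.load_ug > 0, "load_ug", "must be positive")
        _require(all(v >= 0 for v in self.abundances.values()), "abundances", "negative")


@dataclass(frozen=True)
class BlotSimSpec:
    """Band-intensity simulation: intensity ~ abundance x load, plus control.

    Every lane carries a loading-control band proportional to its loaded
    protein mass.  ``wt_reference_lane`` (if named) is loaded at
    ``wt_reference_load_fraction`` of the nominal load, which encodes the
    diluted wild-type reference used to express readthrough efficacy.
    """

    lanes: Sequence[BlotLane] = ()
    loading_control_target: str = "GAPDH"
    wt_reference_lane: str | None = None
    wt_reference_load_fraction: float = 0.01
    intensity_noise_cv: float = 0.0
    control_gain: float = 5.0  # loading-control AU per ug loaded

    def __post_init__(self) -> None:
        _require(len(self.lanes) >= 1, "lanes", "need at least one lane")
        _require(0 < self.wt_reference_load_fraction <= 1, "wt_reference_load_fraction",
                 "must be in (0, 1]")
        _require(self.intensity_noise_cv >= 0, "intensity_noise_cv", "negative")
        for ln in self.lanes:
            if self.loading_control_target in ln.abundances:
                raise ValueError(
                    f"lane {ln.lane}: loading control {self.loading_control_target!r} must "
                    "not appear among target abundances (exactly one control per lane)"
                )


def simulate_blot(spec: BlotSimSpec, seed: int) -> pd.DataFrame:
    """Simulate a band table (lane, condition, target, intensity, load_ug)."""
    rng = np.random.default_rng(seed)
    rows = []
    for ln in spec.lanes:
        load = ln.load_ug
        if spec.wt_reference_lane is not None and ln.lane == spec.wt_reference_lane:
            load = ln.load_ug * spec.wt_reference_load_fraction
        for target, abundance in ln.abundances.items():
            rows.append(
                {
                    "lane": ln.lane,
                    "condition": ln.condition,
                    "target": target,
                    "intensity": abundance * load,
                    "load_ug": load,
                }
            )
        rows.append(
            {
                "lane": ln.lane,
                "condition": ln.condition,
                "target": spec.loading_control_target,
                "intensity": spec.control_gain * load,
                "load_ug": load,
            }
        )
    table = pd.DataFrame(rows)
    if spec.intensity_noise_cv > 0:
        table["intensity"] = table["intensity"] * _unit_mean_lognormal(
            rng, spec.intensity_noise_cv, len(table)
        )
    return table


# --------------------------------------------------------------------------
# Synthetic coding sequence carrying the studied PTC positions
# --------------------------------------------------------------------------

_SENSE_CODONS = tuple(
    c
    for c in ("".join(t) for t in itertools.product("ACGT", repeat=3))
    if c not in STOP_CODONS
)

#: Fixed codons embedded in the synthetic CDS.  Codons 78-86 reproduce the
#: printed p.Q82X mutagenesis-primer context so the extracted 23-nt SCC is a
#: substring of that primer; codons 188 and 427 carry the wild-type codons
#: whose third/first-position substitutions create the studied PTCs.
_EMBEDDED_CODONS = {
    78: "CTG", 79: "TGG", 80: "CAC", 81: "TGG", 82: "CAG",
    83: "GGC", 84: "GAG", 85: "GGG", 86: "CTG",
    188: "TGG",
    427: "CAA",
}


def make_synthetic_cds(
    seed: int = 0,
    n_residues: int = 466,
    signal_peptide_len: int = 27,
    seq_id: str = "synthetic-fucosidase-cds",
) -> CodingSequence:
    """Build a stop-free synthetic CDS with the studied PTC anchor codons.

    The default length (466 residues = 27-residue signal peptide + 439-residue
    mature chain) matches the precursor of the lysosomal alpha-L-fucosidase.
    Codon 82 is CAG (c.244C>T -> TAG), codon 188 is TGG (c.564G>A -> TGA) and
    codon 427 is CAA (c.1279C>T -> TAA).
    """
    if n_residues < max(_EMBEDDED_CODONS) :
        raise ValueError(f"n_residues must be >= {max(_EMBEDDED_CODONS)}")
    rng = np.random.default_rng(seed)
    codons = ["ATG"]
    for k in range(2, n_residues + 1):
        codons.append(_EMBEDDED_CODONS.get(k, _SENSE_CODONS[rng.integers(len(_SENSE_CODONS))]))
    codons.append("TAA")
    seq = CodingSequence(id=seq_id, cds="".join(codons), signal_peptide_len=signal_peptide_len)
    seq.check_no_internal_stop()
    return seq
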