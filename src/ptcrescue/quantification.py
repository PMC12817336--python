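"""Calibrated enzymatic activity, blot densitometry and viability ratios.

Activity follows the fluorogenic 4-MU convention: an ordinary least-squares
standard curve (fluorescence = slope * nmol + intercept, blank included as
the 0 nmol point) converts readings to nanomoles of liberated product, and
specific activity is

    activity [mU/mg] = nmol * dilution / (incubation_min * protein_mg)

with 1 mU = 1 nmol/min.  ``protein_mg`` is the undiluted-equivalent protein
mass behind the reaction, so the dilution factor enters exactly once.

Densitometry operates on band-intensity tables: target/loading-control
ratios relative to a baseline condition, and readthrough efficacy of a
variant's full-length band against a diluted wild-type reference lane
(a variant band equal to the 1%-load reference means 1% efficacy).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class StandardCurve:
    """Fitted fluorescence <-> nmol 4-MU calibration line."""

    slope: float  # AU per nmol
    intercept: float  # AU (blank)
    residual_sd: float
    r_squared: float
    points: pd.DataFrame  # nmol, reading

    def predict(self, nmol: np.ndarray | float) -> np.ndarray | float:
        return self.slope * np.asarray(nmol) + self.intercept


@dataclass(frozen=True)
class ActivityMeasurement:
    """One lysate reading with its reaction bookkeeping."""

    fluorescence: float
    incubation_min: float
    protein_mg: float
    dilution_factor: float = 1.0
    sample_id: str = ""

    def __post_init__(self) -> None:
        if self.incubation_min <= 0:
            raise ValueError("incubation_min must be positive")
        if self.protein_mg <= 0:
            raise ValueError("protein_mg must be positive")
        if self.dilution_factor < 1:
            raise ValueError("dilution_factor must be >= 1")


@dataclass(frozen=True)
class ActivityResult:
    """Back-calculated product amount and derived specific activity."""

    nmol_4mu: float
    activity_mU_per_mg: float
    floored_negative: bool = False
    percent_of_reference: float | None = None
    sample_id: str = ""


class CalibrationError(ValueError):
    pass


def fit_standard_curve(points: Sequence[tuple[float, float]] | pd.DataFrame) -> StandardCurve:
    """OLS line through (nmol, fluorescence) standards.

    Requires >= 2 distinct nmol values and a positive fitted slope.
    """
    if isinstance(points, pd.DataFrame):
        frame = points.rename(columns={points.columns[0]: "nmol", points.columns[1]: "reading"})
    else:
        frame = pd.DataFrame(points, columns=["nmol", "reading"])
    x = frame["nmol"].to_numpy(dtype=float)
    y = frame["reading"].to_numpy(dtype=float)
    if len(np.unique(x)) < 2:
        raise CalibrationError("standard curve needs >= 2 distinct nmol values")
    fit = stats.linregress(x, y)
    if fit.slope <= 0:
        raise CalibrationError(f"non-positive fitted slope {fit.slope:g}")
    resid = y - (fit.slope * x + fit.intercept)
    dof = max(1, len(x) - 2)
    return StandardCurve(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        residual_sd=float(np.sqrt(np.sum(resid**2) / dof)),
        r_squared=float(fit.rvalue**2),
        points=frame,
    )


def fluorescence_to_nmol(curve: StandardCurve, fluorescence: float) -> tuple[float, bool]:
    """Invert the calibration; negative amounts floor to 0 with a flag."""
    nmol = (fluorescence - curve.intercept) / curve.slope
    if nmol < 0:
        return 0.0, True
    return float(nmol), False


def specific_activity(measurement: ActivityMeasurement, curve: StandardCurve) -> ActivityResult:
    """Specific activity in mU/mg from one reading and the fitted curve."""
    nmol, floored = fluorescence_to_nmol(curve, measurement.fluorescence)
    activity = (
        nmol * measurement.dilution_factor
        / (measurement.incubation_min * measurement.protein_mg)
    )
    return ActivityResult(
        nmol_4mu=nmol,
        activity_mU_per_mg=activity,
        floored_negative=floored,
        sample_id=measurement.sample_id,
    )


def percent_of_reference(sample: ActivityResult, reference: ActivityResult) -> float:
    """Sample activity as a percentage of a (positive) reference activity."""
    if reference.activity_mU_per_mg <= 0:
        raise ValueError("reference activity must be positive")
    return 100.0 * sample.activity_mU_per_mg / reference.activity_mU_per_mg


def analyze_activity_plate(plate: pd.DataFrame) -> tuple[StandardCurve, pd.DataFrame]:
    """Fit the curve from a plate table's standards and score every sample.

    ``plate`` follows the generator schema (columns role, sample_id,
    nmol_4mu, protein_mg, dilution_factor, incubation_min, reading).
    """
    std = plate[plate["role"] == "standard"]
    curve = fit_standard_curve(std[["nmol_4mu", "reading"]])
    rows = []
    for _, srow in plate[plate["role"] == "sample"].iterrows():
        m = ActivityMeasurement(
            fluorescence=float(srow["reading"]),
            incubation_min=float(srow["incubation_min"]),
            protein_mg=float(srow["protein_mg"]),
            dilution_factor=float(srow["dilution_factor"]),
            sample_id=str(srow["sample_id"]),
        )
        res = specific_activity(m, curve)
        rows.append(
            {
                "sample_id": res.sample_id,
                "nmol_4mu": res.nmol_4mu,
                "activity_mU_per_mg": res.activity_mU_per_mg,
                "floored_negative": res.floored_negative,
            }
        )
    return curve, pd.DataFrame(rows)


# --------------------------------------------------------------------------
# Blot densitometry
# --------------------------------------------------------------------------

def _band(table: pd.DataFrame, condition: str, target: str) -> float:
    sel = table[(table["condition"] == condition) & (table["target"] == target)]
    if len(sel) == 0:
        raise KeyError(f"no band for condition {condition!r}, target {target!r}")
    return float(sel["intensity"].sum())


def normalized_band_ratio(
    table: pd.DataFrame,
    target: str,
    control_target: str,
    condition: str,
    baseline_condition: str,
) -> float:
    """Target/loading-control ratio relative to a baseline condition, in %.

    ``(I_target/I_control)_condition / (I_target/I_control)_baseline * 100``.
    Invariant to any global intensity gain.
    """
    i_t = _band(table, condition, target)
    i_c = _band(table, condition, control_target)
    b_t = _band(table, baseline_condition, target)
    b_c = _band(table, baseline_condition, control_target)
    if i_c == 0 or b_c == 0:
        raise ZeroDivisionError("loading-control band intensity is zero")
    if b_t == 0:
        raise ZeroDivisionError("baseline target band intensity is zero")
    return 100.0 * (i_t / i_c) / (b_t / b_c)


def _lane_band(table: pd.DataFrame, lane: str, target: str) -> pd.Series:
    sel = table[(table["lane"] == lane) & (table["target"] == target)]
    if len(sel) == 0:
        raise KeyError(f"no band for lane {lane!r}, target {target!r}")
    return sel.iloc[0]


def readthrough_efficacy_from_blot(
    table: pd.DataFrame,
    variant_lane: str,
    wt_reference_lane: str,
    target: str,
    load_fraction: float | None = None,
) -> float:
    """Full-length recovery of a variant as % of undiluted wild type.

    The wild-type reference lane is loaded at ``load_fraction`` of the
    variant's load (0.01 encodes a 1:100-load reference); a variant band
    equal to that reference band therefore means ``100 * load_fraction`` %
    efficacy.  When ``load_fraction`` is None it is inferred from the
    tables' ``load_ug`` columns.
    """
    v = _lane_band(table, variant_lane, target)
    w = _lane_band(table, wt_reference_lane, target)
    if w["intensity"] <= 0:
        raise ZeroDivisionError("wild-type reference band intensity is zero")
    if load_fraction is None:
        if "load_ug" not in table.columns or pd.isna(w["load_ug"]) or pd.isna(v["load_ug"]):
            raise ValueError("load metadata missing; pass load_fraction explicitly")
        load_fraction = float(w["load_ug"]) / float(v["load_ug"])
    return 100.0 * (float(v["intensity"]) / float(w["intensity"])) * load_fraction


def viability_percent(absorbance_sample: float, absorbance_untreated_mean: float) -> float:
    """Well absorbance normalized to the untreated-control mean, in %."""
    if absorbance_untreated_mean <= 0:
        raise ValueError("untreated-control mean absorbance must be positive")
    return 100.0 * absorbance_sample / absorbance_untreated_mean
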