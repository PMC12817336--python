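"""Gating and translational-readthrough quantification from FCS3.0 files.

The readthrough statistic follows the dual-reporter convention: events are
first gated on forward/side scatter (intact cells), then on fluorescence
(RFP > 900 **or** GFP > 100, strict), and TR is the sample's GFP/RFP ratio
normalized to the ratio of a stop-free fusion control measured on the same
plate, expressed as a percentage::

    TR% = 100 * R(sample) / R(control),   R = mean(GFP) / mean(RFP)

Scatter bounds are inclusive ("between"), fluorescence thresholds strict
("above"); both conventions are configurable.  The default estimator is the
ratio of channel means over included events, which stays well-behaved when
per-cell GFP is near zero; a median-of-per-cell-ratios alternative is
available.  Optional background correction subtracts per-channel medians of
an untransfected sample before forming ratios (off by default: the printed
inclusion rule already removes untransfected events).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .fcs import EventTable, read_fcs  # noqa: F401  (read_fcs re-exported here)

logger = logging.getLogger(__name__)

Estimator = Literal["ratio-of-means", "median-of-ratios"]


@dataclass(frozen=True)
class GatingConfig:
    """Scatter bounds and fluorescence inclusion thresholds (instrument AU)."""

    fsc_min: float = 23_000.0
    fsc_max: float = 75_000.0
    ssc_min: float = 12_500.0
    ssc_max: float = 67_500.0
    rfp_min: float = 900.0
    gfp_min: float = 100.0
    bounds_inclusive: bool = True

    def __post_init__(self) -> None:
        if not (self.fsc_min < self.fsc_max and self.ssc_min < self.ssc_max):
            raise ValueError("scatter gate requires min < max on both axes")
        if self.rfp_min < 0 or self.gfp_min < 0:
            raise ValueError("fluorescence thresholds must be nonnegative")


@dataclass(frozen=True)
class TRResult:
    """Readthrough estimate for one sample against its plate control."""

    tr_percent: float
    n_total: int
    n_scatter_gated: int
    n_included: int
    sample_ratio: float
    control_ratio: float
    estimator: str
    background_corrected: bool
    sample_id: str = ""
    low_quality: bool = False

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def gate_scatter(events: EventTable, config: GatingConfig = GatingConfig()) -> EventTable:
    """Retain events inside the scatter rectangle; order preserved."""
    fsc = events.channel("FSC")
    ssc = events.channel("SSC")
    if config.bounds_inclusive:
        keep = (
            (fsc >= config.fsc_min) & (fsc <= config.fsc_max)
            & (ssc >= config.ssc_min) & (ssc <= config.ssc_max)
        )
    else:
        keep = (
            (fsc > config.fsc_min) & (fsc < config.fsc_max)
            & (ssc > config.ssc_min) & (ssc < config.ssc_max)
        )
    return replace_data(events, events.data.loc[keep])


def gate_fluorescence(events: EventTable, config: GatingConfig = GatingConfig()) -> EventTable:
    """Retain events with RFP above rfp_min OR GFP above gfp_min (strict)."""
    keep = (events.channel("RFP") > config.rfp_min) | (events.channel("GFP") > config.gfp_min)
    return replace_data(events, events.data.loc[keep])


def replace_data(events: EventTable, data: pd.DataFrame) -> EventTable:
    return EventTable(
        data=data.reset_index(drop=True),
        sample_id=events.sample_id,
        channel_name_map=dict(events.channel_name_map),
    )


def apply_gates(events: EventTable, config: GatingConfig = GatingConfig()) -> tuple[EventTable, int, int]:
    """Scatter gate then fluorescence gate; returns (gated, n_scatter, n_total)."""
    scatter = gate_scatter(events, config)
    included = gate_fluorescence(scatter, config)
    logger.info(
        "gating %s: total=%d scatter=%d included=%d",
        events.sample_id, len(events), len(scatter), len(included),
    )
    return included, len(scatter), len(events)


def _ratio(events: EventTable, estimator: Estimator, bg: tuple[float, float]) -> float:
    gfp = np.clip(events.channel("GFP") - bg[0], 0, None)
    rfp = np.clip(events.channel("RFP") - bg[1], 0, None)
    if estimator == "ratio-of-means":
        denom = float(np.mean(rfp))
        if denom == 0:
            raise ZeroDivisionError("mean RFP of included events is zero")
        return float(np.mean(gfp)) / denom
    if estimator == "median-of-ratios":
        ok = rfp > 0
        if not ok.any():
            raise ZeroDivisionError("no included event has positive RFP")
        return float(np.median(gfp[ok] / rfp[ok]))
    raise ValueError(f"unknown estimator {estimator!r}")


def tr_statistic(
    sample: EventTable,
    control: EventTable,
    estimator: Estimator = "ratio-of-means",
    background: EventTable | None = None,
    config: GatingConfig = GatingConfig(),
    pre_gated: bool = False,
    low_quality_threshold: int = 100,
) -> TRResult:
    """Readthrough percentage of ``sample`` normalized to ``control``.

    Unless ``pre_gated``, both tables are scatter- and fluorescence-gated
    first.  ``background`` (an untransfected sample) activates per-channel
    median subtraction before ratios, floored at zero.
    """
    if pre_gated:
        s_inc, s_scatter, s_total = sample, len(sample), len(sample)
        c_inc = control
    else:
        s_inc, s_scatter, s_total = apply_gates(sample, config)
        c_inc, _, _ = apply_gates(control, config)
    if len(s_inc) == 0:
        raise ValueError(f"sample {sample.sample_id!r}: no events included after gating")
    if len(c_inc) == 0:
        raise ValueError(f"control {control.sample_id!r}: no events included after gating")

    bg = (0.0, 0.0)
    if background is not None:
        bg_scatter = background if pre_gated else gate_scatter(background, config)
        bg = (
            float(np.median(bg_scatter.channel("GFP"))),
            float(np.median(bg_scatter.channel("RFP"))),
        )

    sample_ratio = _ratio(s_inc, estimator, bg)
    control_ratio = _ratio(c_inc, estimator, bg)
    if control_ratio == 0:
        raise ZeroDivisionError("control GFP/RFP ratio is zero; cannot normalize")
    return TRResult(
        tr_percent=100.0 * sample_ratio / control_ratio,
        n_total=s_total,
        n_scatter_gated=s_scatter,
        n_included=len(s_inc),
        sample_ratio=sample_ratio,
        control_ratio=control_ratio,
        estimator=estimator,
        background_corrected=background is not None,
        sample_id=sample.sample_id,
        low_quality=len(s_inc) < low_quality_threshold,
    )


def summarize_replicates(
    results: Sequence[TRResult], grouping: Sequence[str]
) -> pd.DataFrame:
    """Mean, sample s.d. (n-1) and n of TR% per condition.

    ``grouping`` assigns a condition label to each result.  A single
    replicate reports its mean with s.d. as NaN (not available).
    """
    if len(results) != len(grouping):
        raise ValueError("results and grouping must have equal length")
    if len(results) == 0:
        raise ValueError("no results to summarize")
    frame = pd.DataFrame(
        {"condition": list(grouping), "tr_percent": [r.tr_percent for r in results]}
    )
    out = (
        frame.groupby("condition", sort=False)["tr_percent"]
        .agg(mean="mean", sd=lambda x: x.std(ddof=1), n="count")
        .reset_index()
    )
    return out


@dataclass
class PlateLayout:
    """Well -> (file, condition, role) mapping for one measured plate.

    Exactly one well must have role ``control`` (the 100% fusion control);
    at most one well may have role ``untransfected``.
    """

    wells: dict[str, dict] = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "PlateLayout":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls(wells=doc["wells"])

    def validate(self) -> None:
        roles = [w.get("role", "sample") for w in self.wells.values()]
        if roles.count("control") != 1:
            raise ValueError(
                f"plate layout must name exactly one control well; found {roles.count('control')}"
            )
        if roles.count("untransfected") > 1:
            raise ValueError("plate layout names more than one untransfected well")
        for well, info in self.wells.items():
            if "file" not in info:
                raise ValueError(f"well {well}: no file mapped")

    def well_with_role(self, role: str) -> str | None:
        for well, info in self.wells.items():
            if info.get("role", "sample") == role:
                return well
        return None


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_plate(
    layout: PlateLayout,
    fcs_dir,
    config: GatingConfig = GatingConfig(),
    estimator: Estimator = "ratio-of-means",
    background_correct: bool = False,
    channel_map: Mapping[str, str] | None = None,
    out_prefix=None,
) -> tuple[pd.DataFrame, dict]:
    """Quantify every data well of a plate against the plate's own control.

    Returns (per-well table, provenance report).  When ``out_prefix`` is
    given, writes ``<prefix>.csv`` and ``<prefix>.json``.
    """
    layout.validate()
    fcs_dir = Path(fcs_dir)

    def _load(well: str) -> EventTable:
        path = fcs_dir / layout.wells[well]["file"]
        if not path.exists():
            raise FileNotFoundError(f"well {well}: missing FCS file {path}")
        ev = read_fcs(path, channel_map=channel_map)
        ev.sample_id = ev.sample_id or well
        return ev

    control_well = layout.well_with_role("control")
    control = _load(control_well)
    background = None
    if background_correct:
        ut_well = layout.well_with_role("untransfected")
        if ut_well is None:
            raise ValueError("background correction requested but no untransfected well")
        background = _load(ut_well)

    rows = []
    hashes = {}
    for well, info in layout.wells.items():
        role = info.get("role", "sample")
        if role == "untransfected":
            continue
        events = _load(well)
        hashes[well] = _sha256(fcs_dir / info["file"])
        result = tr_statistic(events, control, estimator, background, config)
        rows.append(
            {
                "well": well,
                "condition": info.get("condition", ""),
                "role": role,
                **result.as_dict(),
            }
        )
        if result.low_quality:
            logger.warning("well %s flagged low quality (%d included events)",
                           well, result.n_included)
    table = pd.DataFrame(rows)

    summary = (
        table[table["role"] == "sample"]
        .groupby("condition", sort=False)["tr_percent"]
        .agg(mean="mean", sd=lambda x: x.std(ddof=1), n="count")
        .reset_index()
    )
    report = {
        "gating": {k: getattr(config, k) for k in config.__dataclass_fields__},
        "estimator": estimator,
        "background_corrected": background_correct,
        "control_well": control_well,
        "file_sha256": hashes,
        "condition_summary": summary.to_dict(orient="records"),
    }
    if out_prefix is not None:
        table.to_csv(f"{out_prefix}.csv", index=False)
        with open(f"{out_prefix}.json", "w") as fh:
            json.dump(report, fh, indent=2)
    return table, report
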