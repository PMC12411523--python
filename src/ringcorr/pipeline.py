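"""End-to-end analysis: masked image -> per-grid periodicity table.

Chains grid partitioning, the oriented-profile angle sweep, the correlation
estimators, and post-processing.  Results come back as two tidy tables: one
row per grid (the selected data point) and a full per-angle audit table.

For two-channel images every reported per-grid value (amplitudes,
frequencies, shift) comes from the single jointly retained angle — the one
maximizing the mean autocorrelation amplitude of both channels — so each
row is one coherent data point.  Single-channel rows report the per-channel
maximum-amplitude selection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional

import numpy as np
import pandas as pd

from .correlation import (
    NoShiftError,
    ZeroVarianceError,
    auto_features,
    autocorrelate,
    cross_shift,
    crosscorrelate,
    normalize_profile,
)
from .postprocess import (
    AnalysisConfig,
    AngleRecord,
    GridRecord,
    apply_amplitude_threshold,
    classify_shift,
    filter_auto,
    normalize_shift,
    select_cross_angle,
)
from .preprocess import Grid, MaskedImage, partition_grids
from .profiles import sweep_angles

PER_GRID_COLUMNS = [
    "grid_index",
    "best_angle_deg",
    "amp_ch1",
    "freq_ch1_nm",
    "amp_ch2",
    "freq_ch2_nm",
    "shift_nm",
    "L_nm",
    "norm_shift_nm",
    "pattern_class",
]


@dataclass
class AnalysisResult:
    """Per-grid summary plus the per-angle audit trail."""

    per_grid: pd.DataFrame
    per_angle: pd.DataFrame
    grid_records: List[GridRecord]


def analyze_grid(grid: Grid, cfg: AnalysisConfig) -> List[AngleRecord]:
    """Angle sweep + correlation features for a single grid."""
    records: List[AngleRecord] = []
    for angle, profiles in sweep_angles(
        grid, cfg.angle_range_deg, cfg.angle_step_deg
    ):
        centred = []
        autos = []
        for prof in profiles:
            if prof is None:
                centred.append(None)
                autos.append(None)
                continue
            nprime = normalize_profile(prof)
            try:
                autos.append(auto_features(autocorrelate(nprime)))
                centred.append(nprime)
            except ZeroVarianceError:
                autos.append(None)
                centred.append(None)
        cross = None
        if len(centred) == 2 and centred[0] is not None and centred[1] is not None:
            try:
                cross = cross_shift(crosscorrelate(centred[0], centred[1]))
            except (ZeroVarianceError, NoShiftError):
                cross = None
        records.append(AngleRecord(angle_deg=angle, auto=autos, cross=cross))
    return records


def summarize_grid(
    grid_index: int, records: List[AngleRecord], cfg: AnalysisConfig, n_channels: int
) -> GridRecord:
    """Collapse a grid's per-angle records to its selected data point."""
    rec = GridRecord(grid_index=grid_index)
    if n_channels == 1:
        angle, feat = filter_auto(records, cfg, channel=0)
        rec.best_angle_deg = angle
        rec.amplitude = [feat.amplitude]
        rec.frequency_nm = [feat.frequency_nm]
        return rec

    selection = select_cross_angle(records, cfg)
    if selection is None:
        # grid excluded from cross analysis; report the degenerate
        # per-channel selections (amplitude 0 / NaN frequency)
        feats = [filter_auto(records, cfg, channel=i)[1] for i in range(2)]
        rec.amplitude = [f.amplitude for f in feats]
        rec.frequency_nm = [f.frequency_nm for f in feats]
        return rec
    angle, a1, a2, cross = selection
    rec.best_angle_deg = angle
    rec.amplitude = [a1.amplitude, a2.amplitude]
    rec.frequency_nm = [a1.frequency_nm, a2.frequency_nm]
    rec.shift_nm = cross.shift_nm
    L, s_prime = normalize_shift(cross.shift_nm, a1.frequency_nm, a2.frequency_nm)
    rec.L_nm = L
    rec.normalized_shift_nm = s_prime
    rec.pattern_class = classify_shift(s_prime, L)
    return rec


def _per_grid_frame(records: List[GridRecord]) -> pd.DataFrame:
    rows = []
    for rec in records:
        amp = rec.amplitude + [math.nan] * (2 - len(rec.amplitude))
        freq = rec.frequency_nm + [math.nan] * (2 - len(rec.frequency_nm))
        rows.append(
            {
                "grid_index": rec.grid_index,
                "best_angle_deg": rec.best_angle_deg,
                "amp_ch1": amp[0],
                "freq_ch1_nm": freq[0],
                "amp_ch2": amp[1],
                "freq_ch2_nm": freq[1],
                "shift_nm": rec.shift_nm,
                "L_nm": rec.L_nm,
                "norm_shift_nm": rec.normalized_shift_nm,
                "pattern_class": rec.pattern_class,
            }
        )
    return pd.DataFrame(rows, columns=PER_GRID_COLUMNS)


def _per_angle_frame(per_grid_records: dict) -> pd.DataFrame:
    rows = []
    for grid_index, records in per_grid_records.items():
        for rec in records:
            row = {"grid_index": grid_index, "angle_deg": rec.angle_deg}
            for ch, feat in enumerate(rec.auto, start=1):
                row[f"amp_ch{ch}"] = feat.amplitude if feat else math.nan
                row[f"freq_ch{ch}_nm"] = feat.frequency_nm if feat else math.nan
            row["shift_nm"] = rec.cross.shift_nm if rec.cross else math.nan
            rows.append(row)
    return pd.DataFrame(rows)


def analyze_image(img: MaskedImage, cfg: Optional[AnalysisConfig] = None) -> AnalysisResult:
    """Run the full pipeline on a masked image.

    The amplitude threshold (when configured) removes two-channel grids
    whose smaller channel amplitude at the selected angle falls below it.
    """
    cfg = cfg or AnalysisConfig()
    height_px = max(2, int(round(cfg.grid_height_um * img.pixels_per_um)))
    if cfg.grid_width == "image-width":
        width_px: object = "image-width"
    else:
        width_px = max(2, int(round(float(cfg.grid_width) * img.pixels_per_um)))
    grids = partition_grids(img, height_px, width_px)

    per_angle: dict = {}
    grid_records: List[GridRecord] = []
    for grid in grids:
        records = analyze_grid(grid, cfg)
        per_angle[grid.index] = records
        grid_records.append(
            summarize_grid(grid.index, records, cfg, img.n_channels)
        )

    if cfg.ac_amplitude_threshold is not None and img.n_channels == 2:
        grid_records = apply_amplitude_threshold(
            grid_records, cfg.ac_amplitude_threshold
        )

    return AnalysisResult(
        per_grid=_per_grid_frame(grid_records),
        per_angle=_per_angle_frame(per_angle),
        grid_records=grid_records,
    )
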