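"""Desk-scale validation experiments on simulated images.

Three experiment families mirror the simulation study used to validate the
analysis pipeline:

* amplitude sensitivity — per-grid autocorrelation amplitudes across
  periodic localization percentages (PLP), with pairwise two-sided
  Mann-Whitney U tests (reported raw, without multiplicity correction);
* cross-correlation accuracy — fraction of two-channel grids whose
  overlapping/alternating call matches the generated ground truth, per PLP
  combination, optionally after the 0.6 amplitude threshold and a
  minimum-data-point criterion;
* one-factor-at-a-time parameter sweeps over the simulator's kernel,
  noise, pixel-size, point-density and signal-variance settings.

All experiments derive every stream of randomness from a single seed and
are reproducible bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from itertools import combinations
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .pipeline import analyze_image
from .postprocess import AnalysisConfig, apply_amplitude_threshold
from .preprocess import MaskedImage
from .simulate import (
    SimulationConfig,
    ZoneMap,
    alternating_zone_map,
    backbone_from_mask,
    build_zone_map,
    simulate_channel,
    simulate_pair,
    synthetic_axon_mask,
)


@dataclass
class AccuracyCell:
    """Classification accuracy for one PLP combination (and pattern)."""

    plp_ch1: float
    plp_ch2: float
    pattern: str
    n_grids: int
    n_correct: int
    accuracy: float  # percent; NaN when n_grids == 0
    passed_min_datapoints: bool


def _child_seeds(seed: int, n: int) -> np.ndarray:
    """Deterministic stream of sub-seeds below 2**31."""
    return np.random.default_rng(seed).integers(0, 2**31, size=n)


def generate_masks(
    n_masks: int,
    seed: int = 0,
    length_um: float = 20.0,
    width_um: float = 0.6,
    curvature: float = 0.2,
    pixels_per_um: float = 100.0,
) -> List[np.ndarray]:
    """Reproducible batch of synthetic axon masks."""
    seeds = _child_seeds(seed, n_masks)
    return [
        synthetic_axon_mask(
            length_um=length_um,
            width_um=width_um,
            curvature=curvature,
            pixels_per_um=pixels_per_um,
            seed=int(s),
        )
        for s in seeds
    ]


def prepare_zone_maps(
    mask: np.ndarray, cfg: SimulationConfig
) -> Tuple[ZoneMap, ZoneMap]:
    """Base and half-period-shifted zone maps for one mask (computed once)."""
    backbone = backbone_from_mask(mask)
    base = build_zone_map(
        mask,
        backbone,
        spacing_nm=cfg.ring_spacing_nm,
        line_halfwidth_px=cfg.line_halfwidth_px,
        pixels_per_um=cfg.pixels_per_um,
    )
    shifted = alternating_zone_map(
        mask,
        backbone,
        spacing_nm=cfg.ring_spacing_nm,
        shift_nm=cfg.ring_spacing_nm / 2.0,
        line_halfwidth_px=cfg.line_halfwidth_px,
        pixels_per_um=cfg.pixels_per_um,
    )
    return base, shifted


def amplitude_experiment(
    plp_levels: Sequence[float],
    n_masks: int = 10,
    seed: int = 0,
    sim_cfg: Optional[SimulationConfig] = None,
    analysis_cfg: Optional[AnalysisConfig] = None,
    mask_length_um: float = 20.0,
) -> pd.DataFrame:
    """Per-grid amplitudes of single-channel simulations across PLP levels.

    Grids whose every data point was discarded by the angle/frequency
    filters contribute amplitude 0 (and NaN frequency), exactly as the
    pipeline reports them.
    """
    sim_cfg = sim_cfg or SimulationConfig()
    analysis_cfg = analysis_cfg or AnalysisConfig()
    masks = generate_masks(
        n_masks, seed=seed, length_um=mask_length_um,
        pixels_per_um=sim_cfg.pixels_per_um,
    )
    render_seeds = _child_seeds(seed + 1, n_masks * len(plp_levels))
    rows = []
    k = 0
    for mask_id, mask in enumerate(masks):
        base, _ = prepare_zone_maps(mask, sim_cfg)
        for plp in plp_levels:
            rng = np.random.default_rng(int(render_seeds[k]))
            k += 1
            channel = simulate_channel(base, replace(sim_cfg, plp=plp), rng)
            img = MaskedImage(
                channels=[channel], mask=mask, pixels_per_um=sim_cfg.pixels_per_um
            )
            result = analyze_image(img, analysis_cfg)
            for _, row in result.per_grid.iterrows():
                rows.append(
                    {
                        "plp": plp,
                        "mask_id": mask_id,
                        "grid_index": int(row["grid_index"]),
                        "amplitude": row["amp_ch1"],
                        "frequency_nm": row["freq_ch1_nm"],
                        "best_angle_deg": row["best_angle_deg"],
                    }
                )
    return pd.DataFrame(rows)


def pairwise_mannwhitney(
    df: pd.DataFrame, value: str = "amplitude", group: str = "plp"
) -> pd.DataFrame:
    """Two-sided Mann-Whitney U between every pair of group levels.

    P-values are reported raw (no multiplicity correction).
    """
    levels = sorted(df[group].unique())
    rows = []
    for a, b in combinations(levels, 2):
        x = df.loc[df[group] == a, value].to_numpy()
        y = df.loc[df[group] == b, value].to_numpy()
        stat, p = mannwhitneyu(x, y, alternative="two-sided")
        rows.append({f"{group}_a": a, f"{group}_b": b, "U": stat, "p_value": p,
                     "n_a": len(x), "n_b": len(y)})
    return pd.DataFrame(rows)


def amplitude_sensitivity_experiment(
    plp_levels: Sequence[float],
    n_masks: int = 10,
    seed: int = 0,
    sim_cfg: Optional[SimulationConfig] = None,
    analysis_cfg: Optional[AnalysisConfig] = None,
    mask_length_um: float = 20.0,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Amplitude-vs-PLP experiment plus its pairwise test matrix."""
    if len(plp_levels) < 2:
        raise ValueError("need at least 2 PLP levels")
    amplitudes = amplitude_experiment(
        plp_levels, n_masks=n_masks, seed=seed, sim_cfg=sim_cfg,
        analysis_cfg=analysis_cfg, mask_length_um=mask_length_um,
    )
    return amplitudes, pairwise_mannwhitney(amplitudes)


def cross_accuracy_experiment(
    plp_pairs: Sequence[Tuple[float, float]],
    patterns: Sequence[str] = ("overlapping", "alternating"),
    n_masks: int = 10,
    seed: int = 0,
    sim_cfg: Optional[SimulationConfig] = None,
    analysis_cfg: Optional[AnalysisConfig] = None,
    amplitude_threshold: Optional[float] = None,
    min_datapoints: int = 10,
    mask_length_um: float = 20.0,
) -> Tuple[pd.DataFrame, List[AccuracyCell]]:
    """Two-channel classification accuracy per PLP combination and pattern.

    Returns the per-grid table (one row per classified grid, with its call
    and ground truth) and the aggregated :class:`AccuracyCell` list.  When
    ``amplitude_threshold`` is given, grids below it are removed before
    accuracy is computed, reproducing the post-filtering analysis.
    """
    sim_cfg = sim_cfg or SimulationConfig()
    analysis_cfg = analysis_cfg or AnalysisConfig()
    masks = generate_masks(
        n_masks, seed=seed, length_um=mask_length_um,
        pixels_per_um=sim_cfg.pixels_per_um,
    )
    zone_maps = [prepare_zone_maps(mask, sim_cfg) for mask in masks]
    sim_seeds = _child_seeds(
        seed + 1, n_masks * len(plp_pairs) * len(patterns)
    )
    rows = []
    k = 0
    for mask_id, (mask, maps) in enumerate(zip(masks, zone_maps)):
        for plp1, plp2 in plp_pairs:
            for pattern in patterns:
                img, truth = simulate_pair(
                    mask,
                    sim_cfg,
                    pattern=pattern,
                    plp_ch1=plp1,
                    plp_ch2=plp2,
                    seed=int(sim_seeds[k]),
                    zone_maps=maps,
                )
                k += 1
                result = analyze_image(img, analysis_cfg)
                records = result.grid_records
                if amplitude_threshold is not None:
                    records = apply_amplitude_threshold(records, amplitude_threshold)
                for rec in records:
                    if rec.pattern_class is None:
                        continue
                    predicted = rec.pattern_class.lower()
                    rows.append(
                        {
                            "mask_id": mask_id,
                            "grid_index": rec.grid_index,
                            "plp_ch1": plp1,
                            "plp_ch2": plp2,
                            "pattern": pattern,
                            "predicted": predicted,
                            "correct": predicted == pattern,
                            "min_amplitude": min(rec.amplitude),
                            "norm_shift_nm": rec.normalized_shift_nm,
                            "L_nm": rec.L_nm,
                        }
                    )
    grid_df = pd.DataFrame(rows)
    cells = accuracy_cells(
        grid_df, plp_pairs, patterns, min_datapoints=min_datapoints
    )
    return grid_df, cells


def accuracy_cells(
    grid_df: pd.DataFrame,
    plp_pairs: Sequence[Tuple[float, float]],
    patterns: Sequence[str],
    min_datapoints: int = 10,
) -> List[AccuracyCell]:
    """Aggregate a per-grid classification table into accuracy cells."""
    cells = []
    for plp1, plp2 in plp_pairs:
        for pattern in patterns:
            if len(grid_df):
                sel = grid_df[
                    (grid_df["plp_ch1"] == plp1)
                    & (grid_df["plp_ch2"] == plp2)
                    & (grid_df["pattern"] == pattern)
                ]
                n = len(sel)
                n_correct = int(sel["correct"].sum()) if n else 0
            else:
                n, n_correct = 0, 0
            cells.append(
                AccuracyCell(
                    plp_ch1=plp1,
                    plp_ch2=plp2,
                    pattern=pattern,
                    n_grids=n,
                    n_correct=n_correct,
                    accuracy=100.0 * n_correct / n if n else float("nan"),
                    passed_min_datapoints=n >= min_datapoints,
                )
            )
    return cells


TABLE_PARAMETERS: Dict[str, List] = {
    "point_density": [25.0, 50.0, 100.0, 200.0, 300.0],
    "kernel": ["RED", "ORANGE"],
    "signal_variance": ["constant", "uniform"],
    "noise_pct": [0.0, 5.0, 10.0, 20.0, 30.0],
    "pixels_per_um": [50.0, 100.0],
}


def parameter_impact_sweep(
    plp_levels: Sequence[float],
    parameters: Optional[Dict[str, List]] = None,
    n_masks: int = 10,
    seed: int = 0,
    analysis_cfg: Optional[AnalysisConfig] = None,
    mask_length_um: float = 20.0,
) -> pd.DataFrame:
    """One-factor-at-a-time sweep: vary one simulator parameter, hold the
    rest at their defaults, and collect per-grid amplitudes per PLP level.

    The returned long-format table has columns ``parameter``, ``level``,
    ``plp``, ``mask_id``, ``grid_index``, ``amplitude``.  The default
    configuration appears in every parameter's sweep (shared baseline).
    """
    parameters = parameters if parameters is not None else TABLE_PARAMETERS
    frames = []
    for param_idx, (param, levels) in enumerate(parameters.items()):
        for level_idx, level in enumerate(levels):
            cfg = SimulationConfig(**{param: level})
            if param == "pixels_per_um" and level != 100.0:
                # keep the stripe footprint ~50 nm wide at any sampling pitch
                cfg = replace(
                    cfg,
                    line_halfwidth_px=max(1, int(round(2 * level / 100.0))),
                )
            # masks are shared across levels of one parameter (same seed)
            # except for pixel-size levels, which change the rasterization
            df = amplitude_experiment(
                plp_levels,
                n_masks=n_masks,
                seed=seed + 1000 * param_idx,
                sim_cfg=cfg,
                analysis_cfg=analysis_cfg,
                mask_length_um=mask_length_um,
            )
            df.insert(0, "parameter", param)
            df.insert(1, "level", level)
            frames.append(df)
    return pd.concat(frames, ignore_index=True)


def iqr_summary(sweep_df: pd.DataFrame) -> pd.DataFrame:
    """Median and interquartile range of amplitude per parameter level/PLP."""
    def _iqr(x: pd.Series) -> float:
        return float(x.quantile(0.75) - x.quantile(0.25))

    return (
        sweep_df.groupby(["parameter", "level", "plp"])["amplitude"]
        .agg(median="median", iqr=_iqr, n="count")
        .reset_index()
    )
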