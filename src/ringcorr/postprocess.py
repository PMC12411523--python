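"""Per-grid filtering, best-angle selection, shift normalization, classification.

After the angle sweep every grid holds one record per angle (per-channel
autocorrelation features, plus cross-correlation features for two-channel
images).  Post-processing discards entries outside the configured angle and
frequency ranges, keeps a single data point per grid, folds the
cross-correlation shift into half a period, and classifies the grid as
"Overlapping" or "Alternating":

    L  = (F1 + F2) / 4
    S' = L - |(S mod 2L) - L|          (floored modulo, so the sign of S
                                        and whole-period wraps are folded)
    Overlapping if S' < L/2, Alternating if S' >= L/2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple, Union

from .correlation import AutoFeatures, CrossFeatures

OVERLAPPING = "Overlapping"
ALTERNATING = "Alternating"


@dataclass
class AnalysisConfig:
    """Analysis defaults mirror the tool's reference configuration:

    1 um grid height with image-wide grids, +/-20 deg angle sweep at 1 deg
    steps, 170-230 nm frequency window (bracketing the ~190-200 nm MPS
    period), optional 0.6 autocorrelation-amplitude threshold, and a
    10-grid minimum for reporting aggregate statistics.
    """

    angle_range_deg: Tuple[float, float] = (-20.0, 20.0)
    angle_step_deg: float = 1.0
    freq_range_nm: Optional[Tuple[float, float]] = (170.0, 230.0)
    grid_height_um: float = 1.0
    grid_width: Union[float, str] = "image-width"
    ac_amplitude_threshold: Optional[float] = None
    min_datapoints: int = 10

    def __post_init__(self) -> None:
        lo, hi = self.angle_range_deg
        if lo > hi:
            raise ValueError("angle range must satisfy lo <= hi")
        if self.freq_range_nm is not None:
            flo, fhi = self.freq_range_nm
            if flo > fhi:
                raise ValueError("frequency range must satisfy lo <= hi")
        if not self.angle_step_deg > 0:
            raise ValueError("angle_step_deg must be positive")
        if not self.grid_height_um > 0:
            raise ValueError("grid_height_um must be positive")
        if self.grid_width != "image-width" and not float(self.grid_width) > 0:
            raise ValueError("grid_width must be positive or 'image-width'")
        if self.ac_amplitude_threshold is not None and not (
            0.0 <= self.ac_amplitude_threshold <= 1.0
        ):
            raise ValueError("ac_amplitude_threshold must lie in [0, 1]")
        if self.min_datapoints < 1:
            raise ValueError("min_datapoints must be positive")


@dataclass
class AngleRecord:
    """One grid's features at one angle.

    ``auto`` holds one :class:`AutoFeatures` (or ``None`` when that channel
    was skipped) per channel; ``cross`` is present only for two-channel
    analyses where both channels produced a profile.
    """

    angle_deg: float
    auto: List[Optional[AutoFeatures]]
    cross: Optional[CrossFeatures] = None


@dataclass
class GridRecord:
    """Post-selection summary of one grid (columns of the per-grid CSV)."""

    grid_index: int
    best_angle_deg: Optional[float] = None
    amplitude: List[float] = field(default_factory=list)
    frequency_nm: List[float] = field(default_factory=list)
    shift_nm: Optional[float] = None
    L_nm: Optional[float] = None
    normalized_shift_nm: Optional[float] = None
    pattern_class: Optional[str] = None


def _passes(
    angle: float, feat: Optional[AutoFeatures], cfg: AnalysisConfig
) -> bool:
    if feat is None:
        return False
    lo, hi = cfg.angle_range_deg
    if not lo <= angle <= hi:
        return False
    if cfg.freq_range_nm is not None:
        flo, fhi = cfg.freq_range_nm
        if math.isnan(feat.frequency_nm):
            return False
        if not flo <= feat.frequency_nm <= fhi:
            return False
    return True


def _tiebreak_key(angle: float):
    # prefer angle nearest 0 (the axon axis), then the smaller signed angle
    return (abs(angle), angle)


def filter_auto(
    records: Sequence[AngleRecord], cfg: AnalysisConfig, channel: int = 0
) -> Tuple[Optional[float], AutoFeatures]:
    """Best autocorrelation data point of one grid and channel.

    Entries outside the angle range, or whose frequency falls outside the
    frequency window (undefined frequencies always fail an active window),
    are discarded; the surviving entry with the highest amplitude wins.
    A grid with no survivor degrades to ``(None, AutoFeatures(nan, 0))``.
    """
    survivors = [
        (rec.angle_deg, rec.auto[channel])
        for rec in records
        if _passes(rec.angle_deg, rec.auto[channel], cfg)
    ]
    if not survivors:
        return None, AutoFeatures(frequency_nm=float("nan"), amplitude=0.0)
    best = min(
        survivors, key=lambda s: (-s[1].amplitude,) + _tiebreak_key(s[0])
    )
    return best[0], best[1]


def select_cross_angle(
    records: Sequence[AngleRecord], cfg: AnalysisConfig
) -> Optional[Tuple[float, AutoFeatures, AutoFeatures, CrossFeatures]]:
    """Retained data point for cross-correlation: the angle with the highest
    mean autocorrelation amplitude over both channels.

    An angle is eligible only if *both* channels pass the angle/frequency
    filters there and a cross-correlation result exists.  Returns ``None``
    (grid excluded from cross analysis) when no angle survives.
    """
    eligible = [
        rec
        for rec in records
        if len(rec.auto) == 2
        and rec.cross is not None
        and _passes(rec.angle_deg, rec.auto[0], cfg)
        and _passes(rec.angle_deg, rec.auto[1], cfg)
    ]
    if not eligible:
        return None
    best = min(
        eligible,
        key=lambda r: (-(r.auto[0].amplitude + r.auto[1].amplitude) / 2.0,)
        + _tiebreak_key(r.angle_deg),
    )
    return best.angle_deg, best.auto[0], best.auto[1], best.cross


def apply_amplitude_threshold(
    grid_records: Sequence[GridRecord], thr: float
) -> List[GridRecord]:
    """Keep grids whose smaller channel amplitude (at the selected angle)
    reaches ``thr``."""
    if not 0.0 <= thr <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    return [
        rec
        for rec in grid_records
        if len(rec.amplitude) == 2 and min(rec.amplitude) >= thr
    ]


def normalize_shift(s_nm: float, f1_nm: float, f2_nm: float) -> Tuple[float, float]:
    """Fold a signed cross-correlation shift into ``[0, L]``.

    ``L = (F1 + F2) / 4`` is half the mean period; the floored modulo makes
    the result independent of the sign of ``S`` and of whole-period wraps.
    Returns ``(L, S')``.
    """
    if not (f1_nm > 0 and f2_nm > 0):
        raise ValueError("frequencies must be positive")
    L = (f1_nm + f2_nm) / 4.0
    folded = s_nm % (2.0 * L)  # floored modulo: result in [0, 2L)
    s_prime = L - abs(folded - L)
    return L, s_prime


def classify_shift(s_prime_nm: float, L_nm: float) -> str:
    """Overlapping for ``S' < L/2``; the boundary itself is Alternating."""
    if not 0 <= s_prime_nm <= L_nm:
        raise ValueError("S' must lie in [0, L]")
    return OVERLAPPING if s_prime_nm < L_nm / 2.0 else ALTERNATING
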