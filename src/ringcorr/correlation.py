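"""Normalized auto-/cross-correlation of intensity profiles and feature extraction.

The estimators follow the plugin's printed definitions exactly: with a
mean-centred profile ``n'`` of length ``N``,

    A(k)      = sum_{i=1}^{N-k} n'_i n'_{i+k},          k = 0 .. N-1
    A_norm(k) = A(k) / (N * sigma^2)

where ``sigma`` is the *population* (divide-by-N) standard deviation of the
centred profile, which forces ``A_norm(0) = 1``.  No per-lag length
rescaling is applied; the resulting taper towards large lags is part of the
method (amplitudes are compared between profiles, not read as spectra).

Cross-correlation uses the analogous ``C(k) = sum n'_{1,i} n'_{2,i+k}``
normalized by ``N * sigma_1 * sigma_2``; the negative-lag branch is defined
by swapping channel roles, ``C(-k) = sum n'_{2,i} n'_{1,i+k}``, yielding a
two-sided correlogram on which the near-zero shift rule is evaluated.
Positive lag means channel 2's pattern leads channel 1's along increasing
label index (the sign is folded away downstream, so it never affects the
overlap/alternate classification).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np

from .profiles import IntensityProfile


class ZeroVarianceError(ValueError):
    """Raised for constant profiles, which carry no periodicity information."""


class NoShiftError(ValueError):
    """Raised when a cross-correlogram has no local maximum at all."""


@dataclass
class Correlogram:
    """Lag-indexed normalized correlation values.

    One-sided (lags ``0 .. N-1``) for autocorrelation, two-sided
    (``-(N-1) .. N-1``) for cross-correlation.  ``sigma`` stores the
    normalizing standard deviation(s).
    """

    lags: np.ndarray
    values: np.ndarray
    step_um: float
    sigma: tuple

    def lag_nm(self, lag: float) -> float:
        return lag * self.step_um * 1000.0


@dataclass
class AutoFeatures:
    """Detected period (nm) and autocorrelation amplitude of one profile.

    ``frequency_nm`` is NaN and ``amplitude`` 0 when the correlogram has no
    second maximum or no first minimum.
    """

    frequency_nm: float
    amplitude: float


@dataclass
class CrossFeatures:
    """Dominant near-zero cross-correlation shift, in lags and nm."""

    shift_lag: int
    shift_nm: float


def normalize_profile(p: IntensityProfile) -> IntensityProfile:
    """Centre a profile on zero mean (the profile normalization step)."""
    if p.n_points < 2:
        raise ValueError("profile must have at least 2 points")
    return IntensityProfile(
        values=p.values - p.values.mean(),
        angle_deg=p.angle_deg,
        step_um=p.step_um,
    )


def _sigma(values: np.ndarray) -> float:
    # population (divide-by-N) standard deviation of the centred profile
    return float(np.sqrt(np.mean(values**2)))


def autocorrelate(nprime: IntensityProfile) -> Correlogram:
    """Normalized autocorrelation of a centred profile (one-sided)."""
    v = nprime.values
    n = v.size
    sigma = _sigma(v)
    if sigma == 0:
        raise ZeroVarianceError("constant profile has zero variance")
    raw = np.correlate(v, v, mode="full")[n - 1 :]
    return Correlogram(
        lags=np.arange(n),
        values=raw / (n * sigma**2),
        step_um=nprime.step_um,
        sigma=(sigma,),
    )


def crosscorrelate(n1prime: IntensityProfile, n2prime: IntensityProfile) -> Correlogram:
    """Normalized two-sided cross-correlation of two centred profiles."""
    v1, v2 = n1prime.values, n2prime.values
    if v1.size != v2.size:
        raise ValueError("profiles must have equal length")
    n = v1.size
    s1, s2 = _sigma(v1), _sigma(v2)
    if s1 == 0 or s2 == 0:
        raise ZeroVarianceError("constant profile has zero variance")
    # full correlation: index (n - 1 + k) holds sum_i v1_i * v2_{i+k}
    raw = np.correlate(v2, v1, mode="full")
    return Correlogram(
        lags=np.arange(-(n - 1), n),
        values=raw / (n * s1 * s2),
        step_um=n1prime.step_um,
        sigma=(s1, s2),
    )


def find_extrema(c: Correlogram) -> Tuple[List[tuple], List[tuple]]:
    """Interior local minima and maxima of a correlogram.

    Extrema are sign changes of the first difference.  A plateau (run of
    equal values) flanked by opposite-sign differences reports its centre
    lag, rounded down.  Endpoints are never extrema.

    Returns ``(minima, maxima)`` as lists of ``(lag, value)`` ordered by lag.
    """
    values = np.asarray(c.values, dtype=float)
    lags = np.asarray(c.lags)
    if values.size < 3:
        return [], []
    diff = np.diff(values)
    signs = np.sign(diff)
    nz = np.nonzero(signs)[0]
    minima: List[tuple] = []
    maxima: List[tuple] = []
    for a, b in zip(nz[:-1], nz[1:]):
        if signs[a] == signs[b]:
            continue
        # plateau (possibly length 1) spans indices a+1 .. b; centre floor
        centre = (a + 1 + b) // 2
        entry = (int(lags[centre]), float(values[centre]))
        if signs[a] > 0:
            maxima.append(entry)
        else:
            minima.append(entry)
    return minima, maxima


def auto_features(c: Correlogram) -> AutoFeatures:
    """Frequency (lag of the second maximum, in nm) and amplitude.

    The forced maximum at lag 0 counts as the first maximum, so the second
    maximum is the first interior maximum at positive lag.  Amplitude is the
    correlation difference between the second maximum and the first minimum;
    when either does not exist the profile is aperiodic at this angle and
    the features degrade to (NaN, 0).
    """
    minima, maxima = find_extrema(c)
    second_max = next(((lag, val) for lag, val in maxima if lag > 0), None)
    first_min = minima[0] if minima else None
    if second_max is None or first_min is None:
        return AutoFeatures(frequency_nm=float("nan"), amplitude=0.0)
    return AutoFeatures(
        frequency_nm=c.lag_nm(second_max[0]),
        amplitude=float(second_max[1] - first_min[1]),
    )


def cross_shift(c: Correlogram) -> CrossFeatures:
    """Shift: lag of the larger of the two local maxima closest to lag zero.

    Among all interior local maxima of the two-sided correlogram, the
    nearest maximum at lag <= 0 and the nearest at lag >= 0 are candidates;
    the one with the larger correlation value wins.  Ties go to the smaller
    absolute lag, then to the non-negative lag.

    Raises
    ------
    NoShiftError
        If the correlogram has no local maxima at all.
    """
    _, maxima = find_extrema(c)
    if not maxima:
        raise NoShiftError("cross-correlogram has no local maxima")
    neg = [m for m in maxima if m[0] <= 0]
    pos = [m for m in maxima if m[0] >= 0]
    candidates = []
    if neg:
        candidates.append(max(neg, key=lambda m: m[0]))  # nearest to zero
    if pos:
        candidates.append(min(pos, key=lambda m: m[0]))
    # larger value first; ties -> smaller |lag|, then non-negative lag
    best = max(candidates, key=lambda m: (m[1], -abs(m[0]), m[0] >= 0))
    return CrossFeatures(shift_lag=int(best[0]), shift_nm=c.lag_nm(best[0]))


def correlogram_to_rows(c: Correlogram) -> List[dict]:
    """Flatten a correlogram for CSV export (lag_px, lag_nm, value)."""
    return [
        {"lag_px": int(lag), "lag_nm": c.lag_nm(lag), "value": float(val)}
        for lag, val in zip(c.lags, c.values)
    ]
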