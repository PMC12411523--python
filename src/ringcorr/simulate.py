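"""Synthetic STED-like images of periodic membrane-skeleton patterns.

The generator mirrors the validation design of the analysis tool: a binary
axon mask is skeletonized to a backbone, anchor points are spread along the
backbone every ``ring_spacing_nm`` (200 nm by default, the simulated ring
period), Bresenham lines perpendicular to the local backbone tangent are
drawn and dilated into "on-line" stripes, and the mask is thereby split
into on-line and off-line zones.  Fluorophore localizations are spawned in
the two zones according to a periodic localization percentage (PLP, symbol
``F``):

    P_total = round(D * (A_on + A_off) / PPM^2)
    P_on    = round(P_total * A_on * F / (A_on * F + A_off * (100 - F)))
    P_off   = P_total - P_on

so PLP 50 scatters points uniformly over the whole mask and PLP 100 puts
every point inside the periodic stripes.  The point image is convolved
with a Gaussian point-spread kernel (RED narrower than ORANGE, emulating
the two STED fluorophores) and optionally overlaid with zero-mean Gaussian
noise scaled to the kernel peak.

Two-channel images share one mask: "overlapping" pairs re-spawn points in
the same zone map, "alternating" pairs spawn channel 2 from a zone map
whose anchors are advanced 100 nm (half a period) along the backbone.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass, replace
from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy import ndimage
from scipy.signal import fftconvolve
from skimage.draw import line as bresenham_line
from skimage.morphology import skeletonize

from .preprocess import MaskedImage

KERNEL_FWHM_NM = {"RED": 60.0, "ORANGE": 90.0}  # synthetic parametric kernels

BACKGROUND, ON_LINE, OFF_LINE = 0, 1, 2


@dataclass
class SimulationConfig:
    """Image-generation parameters.

    Defaults are the reference condition of the validation study: RED
    kernel, no noise, 100 pixels/um, 100 points/um^2, constant unit signal,
    200 nm ring spacing, on-line stripes dilated to a 2 px half-width
    (a ~50 nm wide ring footprint at 100 px/um).
    """

    kernel: str = "RED"
    kernel_fwhm_nm: Optional[float] = None  # overrides the per-kind default
    noise_pct: float = 0.0
    pixels_per_um: float = 100.0
    point_density: float = 100.0  # points per um^2
    signal_variance: str = "constant"  # or "uniform" (values in [0.3, 1])
    plp: float = 100.0  # periodic localization percentage F
    ring_spacing_nm: float = 200.0
    line_halfwidth_px: int = 2

    def __post_init__(self) -> None:
        if self.kernel not in KERNEL_FWHM_NM:
            raise ValueError(f"kernel must be one of {sorted(KERNEL_FWHM_NM)}")
        if self.signal_variance not in ("constant", "uniform"):
            raise ValueError("signal_variance must be 'constant' or 'uniform'")
        if not 50.0 <= self.plp <= 100.0:
            raise ValueError("plp must lie in [50, 100]")
        if self.noise_pct < 0:
            raise ValueError("noise_pct must be >= 0")
        if not (self.pixels_per_um > 0 and self.point_density > 0):
            raise ValueError("pixels_per_um and point_density must be positive")

    @property
    def fwhm_nm(self) -> float:
        return (
            self.kernel_fwhm_nm
            if self.kernel_fwhm_nm is not None
            else KERNEL_FWHM_NM[self.kernel]
        )


@dataclass
class ZoneMap:
    """Per-pixel partition of a mask into background / on-line / off-line."""

    zones: np.ndarray
    backbone: np.ndarray  # ordered (row, col) pixel polyline
    spacing_nm: float

    @property
    def mask(self) -> np.ndarray:
        return self.zones != BACKGROUND

    @property
    def on_line(self) -> np.ndarray:
        return self.zones == ON_LINE

    @property
    def off_line(self) -> np.ndarray:
        return self.zones == OFF_LINE

    @property
    def area_on(self) -> int:
        return int(self.on_line.sum())

    @property
    def area_off(self) -> int:
        return int(self.off_line.sum())


@dataclass
class SpawnCounts:
    """Realized localization budget for one rendered channel."""

    p_total: int
    p_on: int
    p_off: int
    a_on: int
    a_off: int


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def synthetic_axon_mask(
    length_um: float = 20.0,
    width_um: float = 0.6,
    curvature: float = 0.2,
    pixels_per_um: float = 100.0,
    seed: int = 0,
) -> np.ndarray:
    """Band-shaped mask following a smoothly drifting centerline.

    ``curvature`` sets the typical centerline slope (rise over run); the
    drift is monotone with smooth low-frequency variation, so the band
    crosses successive image rows the way a gently curving axon crosses the
    field of view, while local orientations stay within roughly +/-20 deg
    of the image x axis.  ``curvature = 0`` yields a straight horizontal
    band.  Deterministic for a given seed.
    """
    if length_um < 5 or width_um < 0.3:
        raise ValueError("mask must be at least 5 um long and 0.3 um wide")
    rng = np.random.default_rng(seed)
    ncols = int(round(length_um * pixels_per_um))
    half_w = width_um * pixels_per_um / 2.0

    if curvature == 0:
        centre = np.zeros(ncols)
    else:
        direction = rng.choice([-1.0, 1.0])
        smooth = ndimage.gaussian_filter1d(
            rng.standard_normal(ncols), sigma=2.0 * pixels_per_um, mode="reflect"
        )
        sd = smooth.std()
        if sd > 0:
            smooth /= sd
        slope = direction * curvature * np.clip(1.0 + 0.4 * smooth, 0.3, 1.6)
        centre = np.cumsum(slope)
    centre = centre - centre.min() + half_w + 2.0
    nrows = int(math.ceil(centre.max() + half_w + 2.0)) + 1

    rr = np.arange(nrows)[:, None]
    mask = np.abs(rr - centre[None, :]) <= half_w
    return mask


def backbone_from_mask(mask: np.ndarray) -> np.ndarray:
    """Ordered backbone polyline: skeletonize, then keep the longest path.

    The mask is thinned with Lee's 3-D-capable method restricted to 2-D;
    the longest geodesic path between skeleton endpoints is found with two
    breadth-first searches and returned as an ordered ``(n, 2)`` array of
    ``(row, col)`` pixels.
    """
    mask = np.asarray(mask, dtype=bool)
    n_comp = ndimage.label(mask)[1]
    if n_comp != 1:
        raise ValueError(f"mask must be one connected component, found {n_comp}")
    skel = skeletonize(mask, method="lee")
    coords = np.argwhere(skel)
    if len(coords) < 2:
        raise ValueError("skeleton degenerate (fewer than 2 pixels)")
    coord_set = {tuple(p) for p in map(tuple, coords)}

    def neighbors(p: tuple) -> List[tuple]:
        r, c = p
        out = []
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == dc == 0:
                    continue
                q = (r + dr, c + dc)
                if q in coord_set:
                    out.append(q)
        return out

    def bfs(start: tuple) -> Tuple[tuple, Dict[tuple, tuple]]:
        parent = {start: start}
        queue = deque([start])
        last = start
        while queue:
            p = queue.popleft()
            last = p
            for q in neighbors(p):
                if q not in parent:
                    parent[q] = p
                    queue.append(q)
        return last, parent

    start = tuple(coords[0])
    far, _ = bfs(start)
    end, parent = bfs(far)
    path = [end]
    while path[-1] != far:
        path.append(parent[path[-1]])
    return np.array(path[::-1], dtype=float)


def _smooth_polyline(backbone: np.ndarray, sigma_px: float = 3.0) -> np.ndarray:
    """Low-pass the ordered skeleton polyline.

    Raw skeletons are pixel staircases whose step-path length overestimates
    the true curve length; measuring anchor spacing on the staircase would
    silently compress the simulated ring period.  Smoothing the coordinate
    sequence recovers the underlying smooth centerline.
    """
    if len(backbone) < 5 or sigma_px <= 0:
        return backbone
    return np.column_stack(
        [
            ndimage.gaussian_filter1d(backbone[:, i], sigma=sigma_px, mode="nearest")
            for i in range(2)
        ]
    )


def _anchor_points(
    backbone: np.ndarray, spacing_px: float, offset_px: float = 0.0
) -> np.ndarray:
    """Positions at arc-length multiples of ``spacing_px`` along a polyline."""
    seg = np.hypot(*np.diff(backbone, axis=0).T)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    total = arc[-1]
    if total < spacing_px:
        raise ValueError("backbone shorter than one ring spacing")
    targets = np.arange(offset_px % spacing_px, total + 1e-9, spacing_px)
    rows = np.interp(targets, arc, backbone[:, 0])
    cols = np.interp(targets, arc, backbone[:, 1])
    return np.column_stack([rows, cols])


def _anchor_tangents(anchors: np.ndarray, n_neighbors: int = 3) -> np.ndarray:
    """Unit tangent per anchor from up to 3 bidirectional anchor neighbors."""
    n = len(anchors)
    tangents = np.empty_like(anchors)
    for i in range(n):
        lo = max(0, i - n_neighbors)
        hi = min(n - 1, i + n_neighbors)
        d = anchors[hi] - anchors[lo]
        norm = np.hypot(*d)
        tangents[i] = d / norm if norm > 0 else (0.0, 1.0)
    return tangents


def build_zone_map(
    mask: np.ndarray,
    backbone: np.ndarray,
    spacing_nm: float = 200.0,
    line_halfwidth_px: int = 2,
    pixels_per_um: float = 100.0,
    offset_nm: float = 0.0,
) -> ZoneMap:
    """Split a mask into on-line stripes and off-line remainder.

    Anchors sit every ``spacing_nm`` of arc length along the backbone
    (optionally advanced by ``offset_nm``); at each anchor a Bresenham line
    perpendicular to the local tangent is drawn across the image, the union
    of lines is dilated by ``line_halfwidth_px`` and clipped to the mask.
    """
    mask = np.asarray(mask, dtype=bool)
    spacing_px = spacing_nm * pixels_per_um / 1000.0
    offset_px = offset_nm * pixels_per_um / 1000.0
    anchors = _anchor_points(_smooth_polyline(backbone), spacing_px, offset_px)
    if len(anchors) < 2:
        raise ValueError("fewer than 2 anchors on the backbone")
    tangents = _anchor_tangents(anchors)

    nrows, ncols = mask.shape
    half_len = int(math.ceil(math.hypot(nrows, ncols)))
    lines = np.zeros(mask.shape, dtype=bool)
    for (ar, ac), (tr, tc) in zip(anchors, tangents):
        pr, pc = -tc, tr  # perpendicular to the tangent
        r0 = int(round(ar - pr * half_len))
        c0 = int(round(ac - pc * half_len))
        r1 = int(round(ar + pr * half_len))
        c1 = int(round(ac + pc * half_len))
        rr, cc = bresenham_line(r0, c0, r1, c1)
        inside = (rr >= 0) & (rr < nrows) & (cc >= 0) & (cc < ncols)
        lines[rr[inside], cc[inside]] = True

    if line_halfwidth_px > 0:
        yy, xx = np.ogrid[
            -line_halfwidth_px : line_halfwidth_px + 1,
            -line_halfwidth_px : line_halfwidth_px + 1,
        ]
        disk = yy**2 + xx**2 <= line_halfwidth_px**2
        lines = ndimage.binary_dilation(lines, structure=disk)

    zones = np.zeros(mask.shape, dtype=np.int8)
    zones[mask] = OFF_LINE
    zones[lines & mask] = ON_LINE
    return ZoneMap(zones=zones, backbone=backbone, spacing_nm=spacing_nm)


def alternating_zone_map(
    mask: np.ndarray,
    backbone: np.ndarray,
    spacing_nm: float = 200.0,
    shift_nm: float = 100.0,
    line_halfwidth_px: int = 2,
    pixels_per_um: float = 100.0,
) -> ZoneMap:
    """Zone map with anchors advanced half a period along the backbone."""
    return build_zone_map(
        mask,
        backbone,
        spacing_nm=spacing_nm,
        line_halfwidth_px=line_halfwidth_px,
        pixels_per_um=pixels_per_um,
        offset_nm=shift_nm,
    )


def spawn_counts(zone_map: ZoneMap, cfg: SimulationConfig) -> SpawnCounts:
    """Localization budget per zone for the configured density and PLP.

    ``P_off`` is obtained by subtraction so the total is conserved exactly.
    """
    a_on, a_off = zone_map.area_on, zone_map.area_off
    ppm2 = cfg.pixels_per_um**2
    p_total = _round_half_up(cfg.point_density * (a_on + a_off) / ppm2)
    f = cfg.plp
    denom = a_on * f + a_off * (100.0 - f)
    p_on = _round_half_up(p_total * a_on * f / denom) if denom > 0 else 0
    p_on = min(max(p_on, 0), p_total, a_on)
    p_off = p_total - p_on
    if p_off > a_off:
        raise ValueError("point budget exceeds off-line zone pixel count")
    return SpawnCounts(p_total=p_total, p_on=p_on, p_off=p_off, a_on=a_on, a_off=a_off)


def make_kernel(
    kind: str = "RED",
    pixels_per_um: float = 100.0,
    fwhm_nm: Optional[float] = None,
) -> np.ndarray:
    """Unit-peak isotropic Gaussian point-spread kernel, truncated at 3 sigma.

    RED is narrower than ORANGE, emulating the higher-resolution STED
    fluorophore.
    """
    if fwhm_nm is None:
        fwhm_nm = KERNEL_FWHM_NM[kind]
    sigma_px = fwhm_nm / 1000.0 * pixels_per_um / (2.0 * math.sqrt(2.0 * math.log(2.0)))
    if sigma_px * 2.0 * math.sqrt(2.0 * math.log(2.0)) < 2.0:
        raise ValueError("kernel FWHM must be at least 2 px equivalent")
    radius = max(1, int(math.ceil(3.0 * sigma_px)))
    ax = np.arange(-radius, radius + 1)
    yy, xx = np.meshgrid(ax, ax, indexing="ij")
    return np.exp(-(yy**2 + xx**2) / (2.0 * sigma_px**2))


def render(
    zone_map: ZoneMap,
    counts: SpawnCounts,
    cfg: SimulationConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Spawn points, convolve with the kernel and overlay noise.

    Points are sampled without replacement within each zone; their value is
    1 ("constant" variance) or uniform in [0.3, 1] ("uniform").  Noise is
    zero-mean Gaussian with standard deviation ``noise_pct/100`` of the
    kernel peak, applied over the whole image and not clipped.
    """
    points = np.zeros(zone_map.zones.shape, dtype=float)
    for zone_value, n_points in ((ON_LINE, counts.p_on), (OFF_LINE, counts.p_off)):
        idx = np.flatnonzero(zone_map.zones.ravel() == zone_value)
        if n_points > idx.size:
            raise ValueError("point count exceeds zone pixel count")
        if n_points == 0:
            continue
        chosen = rng.choice(idx, size=n_points, replace=False)
        if cfg.signal_variance == "constant":
            values = np.ones(n_points)
        else:
            values = rng.uniform(0.3, 1.0, size=n_points)
        points.ravel()[chosen] = values

    kernel = make_kernel(cfg.kernel, cfg.pixels_per_um, cfg.kernel_fwhm_nm)
    image = fftconvolve(points, kernel, mode="same")
    # FFT round-off hygiene: pixels that received no kernel mass are exact 0
    image[np.abs(image) < 1e-9] = 0.0
    if cfg.noise_pct > 0:
        sigma_noise = cfg.noise_pct / 100.0 * kernel.max()
        image = image + rng.normal(0.0, sigma_noise, size=image.shape)
    return image


def simulate_channel(
    zone_map: ZoneMap, cfg: SimulationConfig, rng: np.random.Generator
) -> np.ndarray:
    """Render one channel from a zone map at the configured PLP."""
    return render(zone_map, spawn_counts(zone_map, cfg), cfg, rng)


def simulate_image(
    mask: np.ndarray, cfg: SimulationConfig, seed: int = 0
) -> Tuple[MaskedImage, ZoneMap]:
    """Single-channel simulation on a mask; returns image and zone map."""
    backbone = backbone_from_mask(mask)
    zone_map = build_zone_map(
        mask,
        backbone,
        spacing_nm=cfg.ring_spacing_nm,
        line_halfwidth_px=cfg.line_halfwidth_px,
        pixels_per_um=cfg.pixels_per_um,
    )
    rng = np.random.default_rng(seed)
    channel = simulate_channel(zone_map, cfg, rng)
    return (
        MaskedImage(channels=[channel], mask=mask, pixels_per_um=cfg.pixels_per_um),
        zone_map,
    )


def simulate_pair(
    mask: np.ndarray,
    cfg: SimulationConfig,
    pattern: str = "overlapping",
    plp_ch1: float = 100.0,
    plp_ch2: float = 100.0,
    seed: int = 0,
    zone_maps: Optional[Tuple[ZoneMap, ZoneMap]] = None,
) -> Tuple[MaskedImage, dict]:
    """Two-channel simulation with overlapping or alternating ground truth.

    Channel 1 always uses the base zone map; channel 2 re-spawns points in
    the same map ("overlapping") or in the half-period-shifted map
    ("alternating").  ``zone_maps`` may supply precomputed (base, shifted)
    maps to amortize skeletonization across conditions.
    """
    if pattern not in ("overlapping", "alternating"):
        raise ValueError("pattern must be 'overlapping' or 'alternating'")
    if zone_maps is None:
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
    else:
        base, shifted = zone_maps

    rng = np.random.default_rng(seed)
    ch1 = simulate_channel(base, replace(cfg, plp=plp_ch1), rng)
    map2 = base if pattern == "overlapping" else shifted
    ch2 = simulate_channel(map2, replace(cfg, plp=plp_ch2), rng)
    img = MaskedImage(
        channels=[ch1, ch2], mask=mask, pixels_per_um=cfg.pixels_per_um
    )
    truth = {"pattern": pattern, "plp_ch1": plp_ch1, "plp_ch2": plp_ch2, "seed": seed}
    return img, truth
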