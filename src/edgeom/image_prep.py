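"""Detector-image handling.

Covers Timepix quad expansion, per-frame gain estimation, dispersion-threshold
spot finding, elliptical distortion-map generation and application, the
pixel <-> millimetre transforms, and rotation-axis azimuth estimation.

Distortion sign convention
--------------------------
A :class:`DistortionMapPair` stores, for every *raw* pixel of a panel, the
offset ``corrected - raw`` in pixels, separately for the fast and the slow
direction. Converting pixel coordinates to millimetres therefore *reverses*
the correction first (fixed-point lookup) and multiplies the raw coordinate by
the pixel size; converting millimetres to pixels computes the raw coordinate
first and then *applies* the correction. Lookups are nearest-neighbour (no
interpolation). Worked example: with a constant fast-offset map of +2 px, a
corrected coordinate X maps to the millimetre position (X - 2) * pixel_size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import ndimage

from .geometry import (
    EdgeomError,
    InvalidArgumentError,
    OutOfRangeError,
    PanelModel,
)

__all__ = [
    "DistortionMapPair",
    "RawFrame",
    "SpotList",
    "AzimuthEstimate",
    "UndefinedGainError",
    "timepix_expand",
    "TIMEPIX_EXPANDED_GAIN",
    "estimate_gain",
    "dispersion_find_spots",
    "generate_elliptical_distortion_maps",
    "px_to_mm",
    "mm_to_px",
    "estimate_axis_azimuth",
]

#: multiplicative gain of a Timepix frame after :func:`timepix_expand`
TIMEPIX_EXPANDED_GAIN = 3.0


class UndefinedGainError(EdgeomError):
    """Gain estimation is undefined (empty or non-positive-mean ROI)."""


@dataclass
class DistortionMapPair:
    """Per-panel pixel-offset lookup arrays, shape (n_slow, n_fast), pixels.

    ``offset_fast[j, i]`` / ``offset_slow[j, i]`` give the fast/slow component
    of ``corrected - raw`` for the pixel with raw indices (fast=i, slow=j).
    """

    offset_fast: np.ndarray
    offset_slow: np.ndarray

    def __post_init__(self) -> None:
        self.offset_fast = np.asarray(self.offset_fast, dtype=float)
        self.offset_slow = np.asarray(self.offset_slow, dtype=float)
        if self.offset_fast.shape != self.offset_slow.shape:
            raise InvalidArgumentError("offset maps must share a shape")
        if not (np.all(np.isfinite(self.offset_fast)) and np.all(np.isfinite(self.offset_slow))):
            raise InvalidArgumentError("offset maps must be finite")

    def matches_panel(self, panel: PanelModel) -> bool:
        return self.offset_fast.shape == (panel.n_pixels[1], panel.n_pixels[0])


@dataclass
class RawFrame:
    """Raw detector frame: one integer count array per panel plus metadata.

    ``masks`` (optional) marks trusted pixels per panel; pixels outside every
    panel (e.g. inter-quad gaps) simply do not exist in this representation.
    """

    panels: list[np.ndarray]
    image_number: int = 1
    masks: Optional[list[np.ndarray]] = None

    def __post_init__(self) -> None:
        self.panels = [np.asarray(p) for p in self.panels]
        for p in self.panels:
            if np.any(p < 0):
                raise InvalidArgumentError("counts must be non-negative")
        if self.masks is not None:
            for m, p in zip(self.masks, self.panels):
                if m.shape != p.shape:
                    raise InvalidArgumentError("mask shape must match panel shape")


class SpotList:
    """Found spots: panel id, intensity-weighted centroid (X, Y px), totals, bbox."""

    COLUMNS = ["panel", "X", "Y", "total", "n_pixels", "x0", "x1", "y0", "y1"]

    def __init__(self, df: pd.DataFrame):
        df = df.reset_index(drop=True)
        for col in self.COLUMNS:
            if col not in df.columns:
                raise InvalidArgumentError(f"spot list missing column {col}")
        inside = (
            (df["X"] >= df["x0"]) & (df["X"] <= df["x1"]) & (df["Y"] >= df["y0"]) & (df["Y"] <= df["y1"])
        )
        if not bool(inside.all()):
            raise InvalidArgumentError("spot centroid outside its bounding box")
        self.df = df[self.COLUMNS]

    def __len__(self) -> int:
        return len(self.df)

    @classmethod
    def empty(cls) -> "SpotList":
        return cls(pd.DataFrame({c: pd.Series(dtype=float) for c in cls.COLUMNS}))


# --------------------------------------------------------------------------
# Timepix preparation
# --------------------------------------------------------------------------
def timepix_expand(raw_quad: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Expand a 512x512 Timepix quad into a gain-normalized 516x516 frame.

    The boundary pixels between abutting ASICs (1-based coordinates 256 and
    257 along each axis) are three times as wide as normal pixels; each is
    split into three pixels that *replicate* the original count. The result is
    a 516x516 frame with a six-pixel-wide cross whose pixels collect roughly
    three times the signal of the others, so all pixels *outside* the cross
    are multiplied by 3. The returned boolean mask marks the cross. After this
    operation the whole frame behaves as a Poisson detector with a
    multiplicative gain of 3.0 (:data:`TIMEPIX_EXPANDED_GAIN`).
    """
    raw_quad = np.asarray(raw_quad)
    if raw_quad.shape != (512, 512):
        raise InvalidArgumentError(f"expected a 512x512 quad, got {raw_quad.shape}")
    repeats = np.ones(512, dtype=int)
    repeats[255] = repeats[256] = 3  # 1-based coordinates 256, 257
    out = np.repeat(np.repeat(raw_quad, repeats, axis=0), repeats, axis=1)
    cross_1d = np.zeros(516, dtype=bool)
    cross_1d[255:261] = True
    cross = cross_1d[:, None] | cross_1d[None, :]
    out = np.where(cross, out, out * 3)
    return out, cross


# --------------------------------------------------------------------------
# Gain estimation
# --------------------------------------------------------------------------
def estimate_gain(frame: np.ndarray, roi: tuple[int, int, int, int]) -> float:
    """Detector gain from the index of dispersion (variance/mean) of an ROI.

    ``roi = (row0, row1, col0, col1)``, half-open slices. For a Poisson
    detector the result is the multiplicative gain; a constant ROI returns 0
    with a warning. At least ~100 pixels are recommended for a stable value.
    """
    frame = np.asarray(frame, dtype=float)
    r0, r1, c0, c1 = roi
    counts = frame[r0:r1, c0:c1]
    if counts.size == 0:
        raise UndefinedGainError("empty region of interest")
    mean = float(counts.mean())
    if mean <= 0:
        raise UndefinedGainError(f"ROI mean is {mean}; gain undefined")
    var = float(counts.var(ddof=1)) if counts.size > 1 else 0.0
    if var == 0.0:
        warnings.warn("constant ROI: zero variance, returning gain 0", stacklevel=2)
        return 0.0
    return var / mean


# --------------------------------------------------------------------------
# Spot finding (dispersion criterion)
# --------------------------------------------------------------------------
def dispersion_find_spots(
    frame: np.ndarray,
    panel: int = 0,
    gain: float = 1.0,
    sigma_b: float = 6.0,
    sigma_strong: float = 3.0,
    global_threshold: float = 0.0,
    kernel: int = 7,
    min_spot_size: int = 2,
    mask: Optional[np.ndarray] = None,
) -> SpotList:
    """Find strong spots with the local index-of-dispersion criterion.

    A pixel is *strong* iff, with local mean m and variance v over the
    ``kernel`` x ``kernel`` window of n unmasked pixels,

    * ``v / m  >  gain * (1 + sigma_b * sqrt(2 / (n - 1)))``  (background test),
    * ``count - m  >  sigma_strong * sqrt(gain * m)``          (signal test),
    * ``count > global_threshold``.

    Strong pixels are merged by 8-connectivity; components smaller than
    ``min_spot_size`` are discarded and centroids are intensity-weighted.
    ``kernel`` is the full window width; the default 7 corresponds to the
    conventional local-window half-width of 3.
    """
    if kernel < 3 or kernel % 2 == 0:
        raise InvalidArgumentError("kernel must be an odd window size >= 3")
    if gain <= 0 or sigma_b <= 0 or sigma_strong <= 0 or global_threshold < 0:
        raise InvalidArgumentError("spot-finding parameters out of range")
    frame = np.asarray(frame, dtype=float)
    valid = np.ones_like(frame, dtype=bool) if mask is None else np.asarray(mask, dtype=bool)
    if not np.any(valid):
        return SpotList.empty()

    k2 = kernel * kernel
    fv = np.where(valid, frame, 0.0)
    n = ndimage.uniform_filter(valid.astype(float), size=kernel, mode="constant") * k2
    s1 = ndimage.uniform_filter(fv, size=kernel, mode="constant") * k2
    s2 = ndimage.uniform_filter(fv * fv, size=kernel, mode="constant") * k2
    n = np.round(n)
    with np.errstate(divide="ignore", invalid="ignore"):
        m = np.where(n > 0, s1 / np.maximum(n, 1), 0.0)
        v = np.where(n > 1, (s2 - s1 * s1 / np.maximum(n, 1)) / np.maximum(n - 1, 1), 0.0)
        dispersion = np.where(m > 0, v / np.where(m > 0, m, 1.0), 0.0)
        t_disp = gain * (1.0 + sigma_b * np.sqrt(2.0 / np.maximum(n - 1, 1)))
    strong = (
        valid
        & (n > 1)
        & (m > 0)
        & (dispersion > t_disp)
        & (frame - m > sigma_strong * np.sqrt(gain * np.maximum(m, 0)))
        & (frame > global_threshold)
    )
    if not np.any(strong):
        return SpotList.empty()

    labels, n_lab = ndimage.label(strong, structure=np.ones((3, 3), dtype=int))
    idx = np.arange(1, n_lab + 1)
    sizes = ndimage.sum_labels(np.ones_like(frame), labels, idx)
    keep = idx[sizes >= min_spot_size]
    if keep.size == 0:
        return SpotList.empty()
    totals = ndimage.sum_labels(frame, labels, keep)
    coms = ndimage.center_of_mass(frame, labels, keep)  # (row, col), intensity weighted
    slices = ndimage.find_objects(labels)
    rows = []
    for lab, tot, (cy, cx) in zip(keep, totals, coms):
        sl = slices[lab - 1]
        rows.append(
            {
                "panel": panel,
                "X": cx + 0.5,
                "Y": cy + 0.5,
                "total": tot,
                "n_pixels": int(sizes[lab - 1]),
                "x0": sl[1].start,
                "x1": sl[1].stop,
                "y0": sl[0].start,
                "y1": sl[0].stop,
            }
        )
    return SpotList(pd.DataFrame(rows))


# --------------------------------------------------------------------------
# Distortion maps
# --------------------------------------------------------------------------
def generate_elliptical_distortion_maps(
    panel: PanelModel,
    centre: tuple[float, float],
    scale_major: float,
    scale_minor: float,
    axis_angle: float = 0.0,
) -> DistortionMapPair:
    """Offset maps correcting an elliptical (anisotropic-magnification) distortion.

    The recorded pattern is modelled as the true pattern scaled by
    ``scale_major`` along the direction at ``axis_angle`` deg (from the fast
    axis, towards slow) and ``scale_minor`` perpendicular to it, about
    ``centre`` (px). For each raw pixel centre p the maps store the offset
    between p and its image under the *inverse* scaling, so that applying the
    correction restores circular symmetry.
    """
    if scale_major <= 0 or scale_minor <= 0:
        raise InvalidArgumentError("ellipse scales must be positive")
    nf, ns = panel.n_pixels
    if scale_major == 1.0 and scale_minor == 1.0:
        zero = np.zeros((ns, nf))
        return DistortionMapPair(offset_fast=zero, offset_slow=zero.copy())
    X, Y = np.meshgrid(np.arange(nf) + 0.5, np.arange(ns) + 0.5)
    vx = X - float(centre[0])
    vy = Y - float(centre[1])
    t = np.radians(axis_angle)
    ct, st = np.cos(t), np.sin(t)
    # rotate into ellipse frame, scale by the inverse, rotate back
    ux = ct * vx + st * vy
    uy = -st * vx + ct * vy
    ux /= scale_major
    uy /= scale_minor
    wx = ct * ux - st * uy
    wy = st * ux + ct * uy
    return DistortionMapPair(offset_fast=wx - vx, offset_slow=wy - vy)


def _lookup(maps: DistortionMapPair, raw_x: np.ndarray, raw_y: np.ndarray):
    """Nearest-neighbour map lookup at raw pixel coordinates (clipped to the grid)."""
    ns, nf = maps.offset_fast.shape
    i = np.clip(np.floor(raw_x).astype(int), 0, nf - 1)
    j = np.clip(np.floor(raw_y).astype(int), 0, ns - 1)
    return maps.offset_fast[j, i], maps.offset_slow[j, i]


def px_to_mm(panel: PanelModel, X, Y, strict: bool = True):
    """Corrected pixel coordinates -> millimetre coordinates on the panel.

    When distortion maps are attached the reverse correction is applied first
    (fixed-point iteration on the nearest-neighbour lookup, max 5 iterations,
    tolerance 0.01 px) and the millimetre coordinate is computed from the raw
    pixel coordinate. With ``strict`` an :class:`OutOfRangeError` is raised
    for coordinates outside the panel.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if strict:
        nf, ns = panel.n_pixels
        if np.any((X < 0) | (X > nf) | (Y < 0) | (Y > ns)):
            raise OutOfRangeError("pixel coordinate outside panel bounds")
    maps = panel.distortion
    if maps is None:
        raw_x, raw_y = X, Y
    else:
        raw_x, raw_y = X.copy(), Y.copy()
        for _ in range(5):
            ox, oy = _lookup(maps, raw_x, raw_y)
            nx, ny = X - ox, Y - oy
            if np.max(np.abs(nx - raw_x)) < 0.01 and np.max(np.abs(ny - raw_y)) < 0.01:
                raw_x, raw_y = nx, ny
                break
            raw_x, raw_y = nx, ny
    return raw_x * panel.pixel_size[0], raw_y * panel.pixel_size[1]


def mm_to_px(panel: PanelModel, mm_fast, mm_slow):
    """Millimetre coordinates -> corrected pixel coordinates on the panel.

    The raw (uncorrected) pixel coordinate is computed first; the correction
    from the attached maps (if any) is then applied by nearest-neighbour
    lookup. Off-panel positions are transformed with edge-clipped lookups and
    left to the caller's bounds checks.
    """
    raw_x = np.asarray(mm_fast, dtype=float) / panel.pixel_size[0]
    raw_y = np.asarray(mm_slow, dtype=float) / panel.pixel_size[1]
    maps = panel.distortion
    if maps is None:
        return raw_x, raw_y
    ox, oy = _lookup(maps, raw_x, raw_y)
    return raw_x + ox, raw_y + oy


# --------------------------------------------------------------------------
# Rotation-axis azimuth
# --------------------------------------------------------------------------
@dataclass
class AzimuthEstimate:
    """Estimated rotation-axis azimuth with a confidence flag."""

    angle: float  # deg in [0, 180)
    low_confidence: bool = False
    message: str = ""


def estimate_axis_azimuth(
    spots: SpotList,
    beam_centre: tuple[float, float],
    n_bins: int = 36,
) -> AzimuthEstimate:
    """Estimate the in-plane azimuth of the rotation axis from found spots.

    The rotation axis projects to a line through the beam centre along which
    reflections have the widest reflecting range and few spots are found. The
    spot azimuths (mod 180 deg) are binned, smoothed with a circular 3-bin
    moving average, and the bin centre of minimum density is returned. The
    result is flagged low-confidence for sparse spot lists (< 50) or when no
    clear depletion exists (minimum within 20% of the mean density).
    """
    df = spots.df
    ang = np.degrees(np.arctan2(df["Y"] - beam_centre[1], df["X"] - beam_centre[0])) % 180.0
    hist, edges = np.histogram(ang, bins=n_bins, range=(0.0, 180.0))
    smooth = (hist + np.roll(hist, 1) + np.roll(hist, -1)) / 3.0
    imin = int(np.argmin(smooth))
    angle = 0.5 * (edges[imin] + edges[imin + 1])
    msgs = []
    low = False
    if len(df) < 50:
        low = True
        msgs.append(f"only {len(df)} spots (>= 50 recommended)")
    mean = float(smooth.mean()) if len(df) else 0.0
    if mean <= 0 or (mean - smooth[imin]) / mean < 0.2:
        low = True
        msgs.append("no clear depletion minimum in the azimuthal histogram")
    return AzimuthEstimate(angle=float(angle), low_confidence=low, message="; ".join(msgs))
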