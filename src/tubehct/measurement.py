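"""Marker-based pixel-ratio hematocrit measurement.

The measurement consumes only three horizontal marker lines placed on an
image of a vertical centrifuged capillary tube:

* ``lower`` — the interface between the top of the sealant plug and the
  packed red-cell column,
* ``buffy`` — the red-cell/plasma interface (at the maximum excursion of
  any meniscus),
* ``upper`` — the top of the plasma column.

Hematocrit is the packed-cell fraction of the whole sample column,

    Hct (%) = 100 * (lower - buffy) / (lower - upper),

so it is invariant to any uniform zoom or translation of the image.

Row coordinates are real-valued (markers may sit between pixel rows),
with row 0 at the image top and rows increasing downward; the plug sits
below the plasma, hence ``lower_row > upper_row``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from decimal import ROUND_HALF_UP, Decimal
from typing import Literal

import numpy as np
from skimage import transform as _sktransform

from .errors import ConfigError, DegenerateSampleError, MarkerOrderError, StateError

__all__ = [
    "MarkerSet",
    "HctResult",
    "Adjustment",
    "compute_hct",
    "resolution",
    "rotate_step",
    "apply_adjustment",
    "round_reported",
]

#: Reporting precision in percentage points. On-screen marker resolution is
#: 0.1-0.23 %/px on typical phone viewports, so one decimal is retained.
REPORT_PRECISION = 0.1

ROTATION_STEP_DEG = 0.5


def round_reported(value: float, decimals: int = 1) -> float:
    """Round a reported percentage, halves away from zero.

    Uses decimal arithmetic so that e.g. 56.25 reports as 56.3 regardless
    of binary floating-point representation.
    """
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class MarkerSet:
    """The three measurement lines, in image-row coordinates (px)."""

    lower_row: float
    buffy_row: float
    upper_row: float

    def __post_init__(self) -> None:
        for name in ("lower_row", "buffy_row", "upper_row"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise MarkerOrderError(f"{name} must be finite, got {v!r}")
        if self.lower_row <= self.upper_row:
            raise DegenerateSampleError(
                "lower_row must lie below upper_row (lower_row > upper_row); "
                f"got lower={self.lower_row}, upper={self.upper_row}"
            )
        if not (self.upper_row <= self.buffy_row <= self.lower_row):
            raise MarkerOrderError(
                f"buffy_row {self.buffy_row} outside "
                f"[upper={self.upper_row}, lower={self.lower_row}]"
            )


@dataclass(frozen=True)
class HctResult:
    """Hematocrit measurement derived from a :class:`MarkerSet`.

    ``hct_pct`` is the exact pixel ratio; ``reported_pct`` applies the
    0.1-point reporting precision. ``resolution_pct`` is the smallest Hct
    increment a one-pixel marker move can produce at this column height.
    """

    hct_pct: float
    blood_px: float
    total_px: float
    resolution_pct: float

    @property
    def reported_pct(self) -> float:
        return round_reported(self.hct_pct, 1)


def compute_hct(markers: MarkerSet) -> HctResult:
    """Compute hematocrit from the three marker rows.

    The packed-cell column spans ``lower -> buffy`` and the whole sample
    spans ``lower -> upper``; hematocrit is their pixel ratio times 100.
    """
    total = markers.lower_row - markers.upper_row
    blood = markers.lower_row - markers.buffy_row
    return HctResult(
        hct_pct=100.0 * blood / total,
        blood_px=blood,
        total_px=total,
        resolution_pct=100.0 / total,
    )


def resolution(viewport_px: float, occupancy: float) -> float:
    """Smallest measurable Hct increment, in percent per logical pixel.

    ``viewport_px`` is the logical (CSS/viewport) pixel height of the
    screen and ``occupancy`` the fraction of that height spanned by the
    plug-top-to-plasma-top distance after zooming. A 586-px viewport at
    75 % occupancy resolves 100/(0.75*586) = 0.23 %/px; a 932-px viewport
    resolves 0.1 %/px — versus the ~0.5 % feasible reading precision of a
    mechanical microhaematocrit reader scale.
    """
    if viewport_px < 1:
        raise ConfigError(f"viewport_px must be >= 1, got {viewport_px}")
    if not 0.0 < occupancy <= 1.0:
        raise ConfigError(f"occupancy must be in (0, 1], got {occupancy}")
    return 100.0 / (occupancy * viewport_px)


@dataclass(frozen=True)
class Adjustment:
    """On-screen image adjustment state: rotation steps and zoom."""

    rotation_deg: float = 0.0
    zoom: float = 1.0

    def __post_init__(self) -> None:
        if not math.isfinite(self.rotation_deg):
            raise ConfigError("rotation_deg must be finite")
        # rotation is only reachable through 0.5-degree button presses
        steps = self.rotation_deg / ROTATION_STEP_DEG
        if abs(steps - round(steps)) > 1e-9:
            raise ConfigError(
                f"rotation_deg must be a multiple of {ROTATION_STEP_DEG}, "
                f"got {self.rotation_deg}"
            )
        if self.zoom < 1.0:
            raise ConfigError(f"zoom must be >= 1, got {self.zoom}")


def rotate_step(adj: Adjustment, direction: Literal["left", "right"]) -> Adjustment:
    """One press of a rotation button: +/-0.5 degrees.

    ``right`` increases the angle, ``left`` decreases it. Rotation is
    disabled once the image has been zoomed, to preserve the vertical
    alignment of the tube.
    """
    if direction not in ("left", "right"):
        raise ConfigError(f"direction must be 'left' or 'right', got {direction!r}")
    if adj.zoom > 1.0:
        raise StateError("rotation is disabled while the image is zoomed")
    delta = ROTATION_STEP_DEG if direction == "right" else -ROTATION_STEP_DEG
    return replace(adj, rotation_deg=adj.rotation_deg + delta)


def apply_adjustment(image: np.ndarray, adj: Adjustment) -> np.ndarray:
    """Apply rotation then central crop-and-scale zoom to a raster.

    ``rotation_deg`` acts in the tube-axis sense of
    :func:`tubehct.detection.locate_tube_axis`: an image whose tube axis
    is tilted by +a degrees is straightened by adjusting by -a. The
    output raster has the input's shape. Combining a
    zoom > 1 with a nonzero rotation in one adjustment is rejected: the
    interface disables rotation once zoomed.
    """
    if adj.zoom > 1.0 and adj.rotation_deg != 0.0:
        raise StateError("cannot rotate a zoomed image; reset zoom first")
    out = np.asarray(image)
    orig_dtype = out.dtype
    if adj.rotation_deg != 0.0:
        # adjustment angle is in the tube-axis sense (positive = top to the
        # right), opposite to skimage's counter-clockwise convention
        out = _sktransform.rotate(
            out, angle=-adj.rotation_deg, resize=False, preserve_range=True, order=1
        )
    if adj.zoom > 1.0:
        h, w = out.shape[:2]
        ch, cw = h / adj.zoom, w / adj.zoom
        r0 = (h - ch) / 2.0
        c0 = (w - cw) / 2.0
        crop = out[int(round(r0)) : int(round(r0 + ch)), int(round(c0)) : int(round(c0 + cw))]
        out = _sktransform.resize(
            crop, (h, w) + out.shape[2:], preserve_range=True, order=1, anti_aliasing=False
        )
    if out is image:
        return image.copy()
    if np.issubdtype(orig_dtype, np.integer):
        out = np.clip(np.rint(out), np.iinfo(orig_dtype).min, np.iinfo(orig_dtype).max)
    return out.astype(orig_dtype)
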