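"""Automatic marker recovery from tube images.

Replaces the human slider placement for end-to-end testing: find the
tube (the largest non-background connected component), classify rows
into zones by nearest palette color, and place the three markers at zone
transitions. Detection is deterministic given the image bytes.

Zone classification is nearest-centroid against a known palette (the
renderer's by default; for real photographs the caller must supply one),
chosen over edge detection because the synthetic fixtures have known
colors and the convention keeps the module testable without tuning.

Sub-pixel convention: a transition between two zones is localized at the
midpoint between the last row of one zone and the first row of the next,
expressed in the continuous row coordinate where pixel row ``i`` spans
``[i, i+1)`` — matching the renderer's ground-truth rows. Marker rows are
read from a narrow central strip of the tube, so that a curved meniscus
is measured at its maximum excursion (the centre line), mirroring the
instruction to place the buffy marker at the meniscus extremum.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as _ndi
from skimage import measure as _skmeasure

from .errors import ClassificationError, DetectionError, NoTubeError, OrientationError
from .measurement import MarkerSet
from .renderer import DEFAULT_PALETTE, palette_separation

__all__ = ["DetectionResult", "TubeAxis", "locate_tube_axis", "classify_rows", "detect_markers"]

#: Rows are labelled unknown when the nearest palette color is farther
#: than this fraction of the minimum palette separation.
_DISTANCE_FRACTION = 0.5

#: Tube zones in physical bottom-to-top order (image bottom = plug end).
_ZONE_ORDER = ("plug", "rbc", "buffy", "plasma", "glass")

_MIN_COMPONENT_PX = 200


@dataclass(frozen=True)
class TubeAxis:
    """Principal axis of the detected tube region."""

    angle_deg: float  # in-plane tilt from vertical; positive = top leans right
    centroid_row: float
    centroid_col: float
    mask: np.ndarray  # boolean component mask, image-shaped


@dataclass(frozen=True)
class DetectionResult:
    markers: MarkerSet
    axis_angle_deg: float
    zone_sequence: tuple[tuple[str, int, int], ...]  # (label, row_start, row_stop)
    confidence: float


def _foreground_mask(image: np.ndarray, palette: dict) -> np.ndarray:
    """Pixels nearer (Chebyshev) to some tube color than to the background.

    Nearest-centroid against the full palette is robust to sensor noise up
    to roughly half the palette separation; a binary opening removes the
    residual speckle so the tube stays a single clean component.
    """
    names = ["background"] + list(_ZONE_ORDER)
    cents = np.array([palette[n] for n in names], dtype=np.int16)
    d = np.abs(image.astype(np.int16)[..., None, :] - cents).max(axis=-1)
    fg = np.argmin(d, axis=-1) != 0
    return _ndi.binary_opening(fg, structure=np.ones((3, 3), dtype=bool))


def locate_tube_axis(image: np.ndarray, palette: dict | None = None) -> TubeAxis:
    """Find the tube as the largest non-background connected component.

    Returns its centroid and principal-axis tilt from vertical (degrees,
    positive when the tube top leans toward larger columns). Raises
    :class:`NoTubeError` when no sufficiently large region exists and
    :class:`OrientationError` when the tilt exceeds 45 degrees — the
    caller should rotate the image and retry.
    """
    palette = palette or DEFAULT_PALETTE
    img = np.asarray(image)
    if img.ndim != 3 or img.shape[-1] != 3:
        raise ValueError(f"expected an (H, W, 3) raster, got shape {img.shape}")
    fg = _foreground_mask(img, palette)
    labels = _skmeasure.label(fg, connectivity=2)
    if labels.max() == 0:
        raise NoTubeError("no non-background region found")
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    best = int(np.argmax(sizes))
    if sizes[best] < _MIN_COMPONENT_PX:
        raise NoTubeError(
            f"largest candidate region has only {sizes[best]} px "
            f"(need >= {_MIN_COMPONENT_PX})"
        )
    mask = labels == best
    props = _skmeasure.regionprops(mask.astype(np.uint8))[0]
    # skimage orientation: angle of the major axis from the row axis,
    # counter-clockwise, in (-pi/2, pi/2]. For a near-vertical tube this
    # is small; sign flipped so positive = tube top leans to the right.
    angle = -math.degrees(props.orientation)
    if abs(angle) > 45.0:
        raise OrientationError(
            f"tube axis tilted {angle:.1f} deg from vertical; rotate the image first"
        )
    return TubeAxis(
        angle_deg=angle,
        centroid_row=float(props.centroid[0]),
        centroid_col=float(props.centroid[1]),
        mask=mask,
    )


def _nearest_zone(colors: np.ndarray, palette: dict, max_dist: float) -> list[str | None]:
    """Nearest-centroid label per color row; None when too far from all."""
    names = [z for z in _ZONE_ORDER]
    cents = np.array([palette[z] for z in names], dtype=np.float64)
    d = np.abs(colors[:, None, :] - cents[None, :, :]).max(axis=-1)
    idx = np.argmin(d, axis=1)
    best = d[np.arange(len(colors)), idx]
    return [names[i] if b <= max_dist else None for i, b in zip(idx, best)]


def classify_rows(
    image: np.ndarray, axis: TubeAxis, palette: dict | None = None
) -> tuple[list[str | None], float]:
    """Zone label per image row intersecting the tube, plus confidence.

    Each row's pixels inside the tube mask are averaged and assigned the
    nearest palette zone; rows farther than half the minimum palette
    separation from every centroid are labelled ``None`` (unknown).
    Confidence is the fraction of tube rows classified unambiguously.
    Raises :class:`ClassificationError` when more than half the rows are
    unknown.
    """
    palette = palette or DEFAULT_PALETTE
    img = np.asarray(image, dtype=np.float64)
    rows_any = axis.mask.any(axis=1)
    row_idx = np.flatnonzero(rows_any)
    if row_idx.size == 0:
        raise NoTubeError("tube mask is empty")
    counts = axis.mask[row_idx].sum(axis=1)
    sums = np.einsum("rwc,rw->rc", img[row_idx], axis.mask[row_idx].astype(np.float64))
    means = sums / counts[:, None]
    max_dist = palette_separation(palette) * _DISTANCE_FRACTION
    labels_present = _nearest_zone(means, palette, max_dist)
    labels: list[str | None] = [None] * img.shape[0]
    for i, lab in zip(row_idx, labels_present):
        labels[i] = lab
    unknown = sum(1 for lab in labels_present if lab is None)
    confidence = 1.0 - unknown / len(labels_present)
    if unknown > 0.5 * len(labels_present):
        raise ClassificationError(
            f"{unknown}/{len(labels_present)} tube rows unclassifiable"
        )
    return labels, confidence


def _mode_smooth(labels: list[str | None], width: int = 5) -> list[str | None]:
    """Sliding-window mode filter over the known labels (kills blips)."""
    half = width // 2
    out: list[str | None] = list(labels)
    n = len(labels)
    for i in range(n):
        if labels[i] is None:
            continue
        window = [l for l in labels[max(0, i - half) : i + half + 1] if l is not None]
        counts: dict[str, int] = {}
        for l in window:
            counts[l] = counts.get(l, 0) + 1
        best = max(counts.values())
        # keep the original label on ties to stay deterministic
        if counts[labels[i]] < best:
            out[i] = max(counts, key=lambda k: (counts[k], k == labels[i]))
    return out


def _runs(labels: list[str | None]) -> list[tuple[str, int, int]]:
    """Contiguous (label, start, stop_exclusive) runs of known labels."""
    runs: list[tuple[str, int, int]] = []
    for i, lab in enumerate(labels):
        if lab is None:
            continue
        if runs and runs[-1][0] == lab and runs[-1][2] == i:
            runs[-1] = (lab, runs[-1][1], i + 1)
        else:
            runs.append((lab, i, i + 1))
    return runs


def _clean_runs(runs: list[tuple[str, int, int]], min_len: int = 2) -> list[tuple[str, int, int]]:
    """Drop sub-minimal runs (noise speckle) and re-merge neighbours."""
    kept = [r for r in runs if r[2] - r[1] >= min_len]
    merged: list[tuple[str, int, int]] = []
    for lab, a, b in kept:
        if merged and merged[-1][0] == lab:
            merged[-1] = (lab, merged[-1][1], b)
        else:
            merged.append((lab, a, b))
    return merged


def _strip_labels(
    image: np.ndarray, axis: TubeAxis, palette: dict, half_width: int = 1
) -> list[str | None]:
    """Per-row labels from a narrow strip around the tube centre line.

    The strip follows the (possibly tilted) principal axis so the centre
    column is sampled at every row; this reads a curved meniscus boundary
    at its maximum-excursion point.
    """
    img = np.asarray(image, dtype=np.float64)
    h, w = img.shape[:2]
    tan = math.tan(math.radians(axis.angle_deg))
    rows = np.arange(h)
    centre = axis.centroid_col + (rows - axis.centroid_row) * tan
    max_dist = palette_separation(palette) * _DISTANCE_FRACTION
    labels: list[str | None] = [None] * h
    rows_any = axis.mask.any(axis=1)
    cols = np.clip(
        np.round(centre).astype(int)[:, None] + np.arange(-half_width, half_width + 1),
        0,
        w - 1,
    )
    means = np.take_along_axis(img, cols[:, :, None], axis=1).mean(axis=1)
    in_mask = np.take_along_axis(axis.mask, cols, axis=1).all(axis=1)
    sel = np.flatnonzero(rows_any & in_mask)
    if sel.size == 0:
        raise NoTubeError("central strip does not intersect the tube mask")
    for i, lab in zip(sel, _nearest_zone(means[sel], palette, max_dist)):
        labels[i] = lab
    return labels


def _transition_row(upper_zone_stop: int, lower_zone_start: int) -> float:
    """Continuous boundary row between two adjacent runs.

    ``upper_zone_stop`` is the exclusive stop of the run nearer the image
    top; ``lower_zone_start`` the start of the run below it. For directly
    adjacent runs this is their shared pixel edge; across an unknown gap
    it is the gap midpoint.
    """
    return (upper_zone_stop + lower_zone_start) / 2.0


def detect_markers(image: np.ndarray, palette: dict | None = None) -> DetectionResult:
    """Recover the three measurement markers from a tube image.

    lower = plug/red-cell transition, buffy = red-cell/plasma transition
    (meniscus extremum via the central strip), upper = plasma-top
    transition. Degenerate tubes are handled: with no red-cell zone the
    buffy marker collapses onto the lower marker; with no plasma zone
    onto the upper marker.
    """
    palette = palette or DEFAULT_PALETTE
    axis = locate_tube_axis(image, palette)
    row_labels, confidence = classify_rows(image, axis, palette)
    strip = _clean_runs(_runs(_mode_smooth(_strip_labels(image, axis, palette))))
    # zone sequence from the whole-row classification (reported), marker
    # rows from the central strip (meniscus extremum convention)
    seq_runs = _clean_runs(_runs(_mode_smooth(row_labels)))
    order = {z: i for i, z in enumerate(_ZONE_ORDER)}
    known = [r for r in seq_runs if r[0] in order]
    # image top -> bottom is plasma -> plug, so zone rank must decrease downward
    ranks = [order[r[0]] for r in known]
    if any(ranks[i] <= ranks[i + 1] for i in range(len(ranks) - 1)):
        raise DetectionError(f"non-monotone zone sequence: {[r[0] for r in known]}")

    strip_by_zone = {lab: (a, b) for lab, a, b in strip}
    if "plug" not in strip_by_zone:
        raise DetectionError("no sealant plug found; cannot anchor the lower marker")

    def boundary(above: str, below: str) -> float:
        a_stop = strip_by_zone[above][1]
        b_start = strip_by_zone[below][0]
        return _transition_row(a_stop, b_start)

    plug_start = strip_by_zone["plug"][0]
    has_rbc = "rbc" in strip_by_zone
    has_plasma = "plasma" in strip_by_zone

    if has_rbc:
        above_rbc = "buffy" if "buffy" in strip_by_zone else ("plasma" if has_plasma else "glass")
        if above_rbc not in strip_by_zone:
            raise DetectionError("red cells present but nothing above them")
        lower = boundary("rbc", "plug")
        buffy = boundary(above_rbc, "rbc")
    else:
        if not has_plasma:
            raise DetectionError("neither red cells nor plasma found above the plug")
        lower = boundary("plasma", "plug")
        buffy = lower  # Hct 0: no packed-cell column
    if has_plasma:
        above_plasma = "glass" if "glass" in strip_by_zone else None
        if above_plasma:
            upper = boundary("glass", "plasma")
        else:
            upper = float(strip_by_zone["plasma"][0])
    else:
        upper = buffy  # Hct 100: plasma absent, sample top = cell top
    if not has_plasma:
        buffy = upper

    markers = MarkerSet(lower_row=lower, buffy_row=buffy, upper_row=upper)
    return DetectionResult(
        markers=markers,
        axis_angle_deg=axis.angle_deg,
        zone_sequence=tuple(known),
        confidence=confidence,
    )
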