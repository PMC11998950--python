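"""Camera pose, the capture-quality gate, and the pinhole projection model.

Pose convention (documented because angle names alone are ambiguous):

* The world frame is the tube-plane frame of :mod:`tubehct.tube` (cm):
  tube along +y in the z = 0 plane, z up.
* The camera sits at ``(0, -setback_cm, height_cm)`` — directly above the
  tube centre when ``setback_cm`` is 0, displaced along the tube's long
  axis (beyond the plug end) otherwise.
* At the nadir pose (all angles zero) the camera looks straight down with
  the image-row direction along -y, so the plasma end appears at the top
  of the image and the plug at the bottom.
* ``pitch_deg`` rotates the camera about the horizontal axis
  perpendicular to the tube; positive pitch tilts the view back toward
  the tube centre, so a set-back camera re-centres the tube at
  pitch = atan(setback/height).
* ``yaw_deg`` tilts side-to-side (about the axis parallel to the tube's
  long axis); ``roll_deg`` rotates about the optical axis and tilts the
  tube image away from vertical.

Angles are always given from the nadir (camera horizontal, lens straight
down) reference; the stated capture geometry of 33 degrees pitch with a
10 cm setback at 19.5 cm height is geometrically over-determined
(atan(10/19.5) is about 27 degrees), and pitch, setback and height are
therefore treated as independent inputs, never forced to be consistent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import InvalidPoseError, ProjectionError
from .measurement import MarkerSet, compute_hct
from .tube import TubeSpec

__all__ = [
    "CameraPose",
    "CameraIntrinsics",
    "GateResult",
    "capture_gate",
    "project_point",
    "apparent_hct",
    "default_intrinsics",
]

#: Capture gate threshold: the on-screen indicator turns green only when
#: both |pitch| and |yaw| are strictly below 5 degrees.
GATE_LIMIT_DEG = 5.0

#: Default capture distance: the device is mounted 19.5 cm above the tube.
DEFAULT_HEIGHT_CM = 19.5

#: Default raster height (physical pixels of a small-phone sensor crop).
DEFAULT_RASTER_HEIGHT_PX = 1136
DEFAULT_RASTER_WIDTH_PX = 256

#: Fraction of the raster height a default 75 mm tube occupies at the
#: default height; fixes the default focal length.
DEFAULT_TUBE_OCCUPANCY = 0.75


@dataclass(frozen=True)
class CameraPose:
    pitch_deg: float = 0.0
    yaw_deg: float = 0.0
    roll_deg: float = 0.0
    height_cm: float = DEFAULT_HEIGHT_CM
    setback_cm: float = 0.0

    def __post_init__(self) -> None:
        for name in ("pitch_deg", "yaw_deg", "roll_deg", "height_cm", "setback_cm"):
            if not math.isfinite(getattr(self, name)):
                raise InvalidPoseError(f"{name} must be finite")
        if self.height_cm <= 0:
            raise InvalidPoseError(f"height_cm must be > 0, got {self.height_cm}")
        if self.setback_cm < 0:
            raise InvalidPoseError(f"setback_cm must be >= 0, got {self.setback_cm}")

    @property
    def is_nadir(self) -> bool:
        return (
            self.pitch_deg == 0.0
            and self.yaw_deg == 0.0
            and self.roll_deg == 0.0
            and self.setback_cm == 0.0
        )

    def position_cm(self) -> np.ndarray:
        """Camera centre in the tube-plane frame."""
        return np.array([0.0, -self.setback_cm, self.height_cm])

    def rotation_world_to_camera(self) -> np.ndarray:
        """3x3 rotation mapping world vectors into the camera frame.

        Camera frame: x right, y down the image, z along the optical axis
        into the scene. Built as roll о pitch о yaw applied to the nadir
        orientation (x_cam = +x, y_cam = -y, z_cam = -z).
        """
        nadir = np.array([[1.0, 0.0, 0.0], [0.0, -1.0, 0.0], [0.0, 0.0, -1.0]])
        p = math.radians(self.pitch_deg)
        w = math.radians(self.yaw_deg)
        r = math.radians(self.roll_deg)
        # positive pitch tilts the optical axis back toward the tube centre
        rx = np.array(
            [[1, 0, 0], [0, math.cos(p), math.sin(p)], [0, -math.sin(p), math.cos(p)]]
        )
        ry = np.array(
            [[math.cos(w), 0, -math.sin(w)], [0, 1, 0], [math.sin(w), 0, math.cos(w)]]
        )
        # sign chosen so positive roll tilts the tube image top to the right
        rz = np.array(
            [[math.cos(r), -math.sin(r), 0], [math.sin(r), math.cos(r), 0], [0, 0, 1]]
        )
        return rz @ rx @ ry @ nadir


@dataclass(frozen=True)
class CameraIntrinsics:
    """Pinhole intrinsics: focal length in pixels and raster geometry."""

    focal_px: float
    image_width_px: int = DEFAULT_RASTER_WIDTH_PX
    image_height_px: int = DEFAULT_RASTER_HEIGHT_PX
    principal_x_px: float | None = None
    principal_y_px: float | None = None

    def __post_init__(self) -> None:
        if self.focal_px <= 0:
            raise InvalidPoseError(f"focal_px must be > 0, got {self.focal_px}")
        if self.image_width_px < 1 or self.image_height_px < 1:
            raise InvalidPoseError("raster dimensions must be >= 1")
        cx, cy = self.principal_point()
        if not (0 <= cx <= self.image_width_px and 0 <= cy <= self.image_height_px):
            raise InvalidPoseError("principal point must lie inside the raster")

    def principal_point(self) -> tuple[float, float]:
        cx = self.principal_x_px if self.principal_x_px is not None else self.image_width_px / 2.0
        cy = self.principal_y_px if self.principal_y_px is not None else self.image_height_px / 2.0
        return cx, cy


def default_intrinsics(
    image_width_px: int = DEFAULT_RASTER_WIDTH_PX,
    image_height_px: int = DEFAULT_RASTER_HEIGHT_PX,
) -> CameraIntrinsics:
    """Intrinsics scaled so a 75 mm tube at 19.5 cm fills 75 % of the raster height."""
    tube_length_cm = 7.5
    focal = DEFAULT_TUBE_OCCUPANCY * image_height_px * DEFAULT_HEIGHT_CM / tube_length_cm
    return CameraIntrinsics(
        focal_px=focal, image_width_px=image_width_px, image_height_px=image_height_px
    )


@dataclass(frozen=True)
class GateResult:
    passed: bool
    pitch_ok: bool
    yaw_ok: bool


def capture_gate(pose: CameraPose) -> GateResult:
    """The on-screen green-light gate: strict |pitch| < 5 and |yaw| < 5.

    Roll and setback are not gated — the indicator reflects the device's
    tilt sensors only. Exactly 5 degrees fails.
    """
    pitch_ok = abs(pose.pitch_deg) < GATE_LIMIT_DEG
    yaw_ok = abs(pose.yaw_deg) < GATE_LIMIT_DEG
    return GateResult(passed=pitch_ok and yaw_ok, pitch_ok=pitch_ok, yaw_ok=yaw_ok)


_MIN_DEPTH_CM = 1e-9


def project_point(
    pose: CameraPose, intr: CameraIntrinsics, world_point: np.ndarray
) -> tuple[float, float]:
    """Project a 3D tube-plane point (cm) to pixel (column, row).

    Standard pinhole model without lens distortion: u = cx + f*x/z,
    v = cy + f*y/z in camera coordinates. Raises :class:`ProjectionError`
    if the point is at or behind the camera plane. The returned pixel may
    lie outside the raster; framing is the renderer's concern.
    """
    pt = np.asarray(world_point, dtype=float)
    if pt.shape != (3,):
        raise ValueError(f"world_point must be a 3-vector, got shape {pt.shape}")
    cam = pose.rotation_world_to_camera() @ (pt - pose.position_cm())
    if cam[2] <= _MIN_DEPTH_CM:
        raise ProjectionError(
            f"point {pt.tolist()} has non-positive depth {cam[2]:.3g} cm"
        )
    cx, cy = intr.principal_point()
    u = cx + intr.focal_px * cam[0] / cam[2]
    v = cy + intr.focal_px * cam[1] / cam[2]
    return float(u), float(v)


def apparent_hct(
    pose: CameraPose, intr: CameraIntrinsics | None = None, tube: TubeSpec | None = None
) -> float:
    """Analytic apparent (parallax-biased) hematocrit, in percent.

    Projects the tube's three physical interface points through the
    pinhole model and applies the pixel-ratio measurement to the
    projected image rows — predicting, without rendering, what a perfect
    marker placement would measure at this pose. At the nadir pose depth
    is constant along the tube, the projection is affine in y, and the
    result equals the tube's true hematocrit; off-nadir poses shear the
    row spacing and bias the ratio (parallax error). The result is
    invariant to the focal length, which cancels in the ratio.
    """
    if intr is None:
        intr = default_intrinsics()
    if tube is None:
        tube = TubeSpec()
    rows = [project_point(pose, intr, p)[1] for p in tube.interface_points_cm()]
    markers = MarkerSet(lower_row=rows[0], buffy_row=rows[1], upper_row=rows[2])
    return compute_hct(markers).hct_pct
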