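"""Seeded synthetic renderer for centrifuged capillary-tube photographs.

Rendering is done by inverse mapping: for every raster pixel a ray is
cast through the pinhole camera, intersected with the desk plane
(z = 0), and the hit point classified against the tube geometry in
physical coordinates. Zone boundaries in the raster therefore coincide
exactly with pinhole projections of the physical interfaces, with no
resampling artifacts, and the ground-truth marker rows are recorded at
sub-pixel precision from the same projection.

Because a pitched camera at the default field of view would push the
tube off the raster (in the lab one simply slides the sample back into
frame), the renderer auto-frames by shifting the virtual principal point
so the projected tube midpoint lands at the raster centre. A principal
point shift is a pure image translation: it leaves row *differences* —
and hence the measured pixel-ratio hematocrit — exactly unchanged, so
the raster path stays consistent with :func:`tubehct.geometry.apparent_hct`.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
from PIL import Image

from .errors import ConfigError, FramingError
from .geometry import CameraIntrinsics, CameraPose, default_intrinsics
from .measurement import MarkerSet
from .tube import TubeSpec

__all__ = [
    "RenderConfig",
    "RenderedSample",
    "render_tube",
    "render_cohort",
    "save_sample",
    "load_sidecar",
    "DEFAULT_PALETTE",
]

SIDECAR_SCHEMA_VERSION = 1

#: Zone palette (RGB). Chosen for a plausible bench photograph with
#: pairwise channel-separable colors: dark bench background, light glass,
#: orange sealant clay, dark red packed cells, off-white buffy coat,
#: straw-colored plasma.
DEFAULT_PALETTE: dict[str, tuple[int, int, int]] = {
    "background": (30, 30, 35),
    "glass": (190, 200, 210),
    "plug": (245, 130, 40),
    "rbc": (150, 15, 20),
    "buffy": (235, 230, 215),
    "plasma": (250, 215, 120),
}

#: Minimum acceptable pairwise Chebyshev (max-channel) distance between
#: palette colors; nearest-centroid detection needs separable zones.
MIN_COLOR_SEPARATION = 30


def palette_separation(palette: dict[str, tuple[int, int, int]]) -> int:
    """Smallest pairwise max-channel distance between palette colors."""
    names = sorted(palette)
    best = 255
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            d = max(abs(x - y) for x, y in zip(palette[a], palette[b]))
            best = min(best, d)
    return best


@dataclass(frozen=True)
class RenderConfig:
    """Raster size, palette, sensor noise and seed for one render."""

    width_px: int = 256
    height_px: int = 1136
    palette: dict[str, tuple[int, int, int]] = field(
        default_factory=lambda: dict(DEFAULT_PALETTE)
    )
    noise_sigma: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width_px < 8 or self.height_px < 8:
            raise ConfigError("raster must be at least 8x8 px")
        if self.noise_sigma < 0:
            raise ConfigError(f"noise_sigma must be >= 0, got {self.noise_sigma}")
        missing = set(DEFAULT_PALETTE) - set(self.palette)
        if missing:
            raise ConfigError(f"palette missing zones: {sorted(missing)}")
        sep = palette_separation(self.palette)
        if sep < MIN_COLOR_SEPARATION:
            raise ConfigError(
                f"palette colors too close (min separation {sep} < {MIN_COLOR_SEPARATION})"
            )


@dataclass(frozen=True)
class RenderedSample:
    """A rendered raster with its full ground truth."""

    image: np.ndarray  # (H, W, 3) uint8
    truth_markers: MarkerSet
    pose: CameraPose
    tube: TubeSpec
    config: RenderConfig
    intrinsics: CameraIntrinsics  # effective intrinsics incl. auto-frame shift
    seed: int


def _ray_plane_hits(
    pose: CameraPose, intr: CameraIntrinsics
) -> tuple[np.ndarray, np.ndarray]:
    """World (x, y) of the desk-plane hit of every pixel's camera ray.

    Pixels whose ray does not hit the plane in front of the camera map to
    NaN (they show background).
    """
    h, w = intr.image_height_px, intr.image_width_px
    cx, cy = intr.principal_point()
    u = (np.arange(w) + 0.5 - cx) / intr.focal_px
    v = (np.arange(h) + 0.5 - cy) / intr.focal_px
    uu, vv = np.meshgrid(u, v)
    d_cam = np.stack([uu, vv, np.ones_like(uu)], axis=-1)  # (H, W, 3)
    r_cw = pose.rotation_world_to_camera().T
    d_world = d_cam @ r_cw.T
    cam = pose.position_cm()
    dz = d_world[..., 2]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(dz < -1e-12, -cam[2] / dz, np.nan)
    x = cam[0] + t * d_world[..., 0]
    y = cam[1] + t * d_world[..., 1]
    return x, y


def _classify_plane(tube: TubeSpec, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Zone index map for desk-plane coordinates (vectorized).

    Indices follow ``_ZONES``; everything outside the tube silhouette is
    background. The red-cell/plasma interface and the plasma top carry
    the tube's parabolic meniscus profile.
    """
    zone = np.zeros(x.shape, dtype=np.uint8)  # background
    r = tube.bore_radius_cm
    half = tube.half_length_cm
    inside = (np.abs(x) <= r) & (y >= -half) & (y <= half) & np.isfinite(x)
    men = tube.meniscus_offset_cm(np.where(inside, x, 0.0))
    y_lower = tube.plug_top_y_cm
    y_buffy = tube.buffy_y_cm - men
    y_buffy_top = y_buffy + tube.buffy_thickness_mm / 10.0
    y_upper = tube.plasma_top_y_cm - men

    zone[inside] = _ZONES.index("glass")
    zone[inside & (y <= y_lower)] = _ZONES.index("plug")
    if tube.true_hct_pct > 0:
        zone[inside & (y > y_lower) & (y <= y_buffy)] = _ZONES.index("rbc")
    if tube.buffy_thickness_mm > 0 and tube.true_hct_pct > 0:
        zone[inside & (y > y_buffy) & (y <= y_buffy_top)] = _ZONES.index("buffy")
    if tube.true_hct_pct < 100:
        lo = np.where(
            tube.true_hct_pct > 0, np.maximum(y_buffy_top, y_lower), y_lower
        )
        zone[inside & (y > lo) & (y <= y_upper)] = _ZONES.index("plasma")
    return zone


_ZONES = ["background", "glass", "plug", "rbc", "buffy", "plasma"]


def render_tube(
    tube: TubeSpec,
    pose: CameraPose,
    cfg: RenderConfig | None = None,
    intr: CameraIntrinsics | None = None,
    auto_frame: bool = True,
) -> RenderedSample:
    """Render one tube under a camera pose; deterministic for a fixed seed.

    ``auto_frame`` re-centres the tube via a virtual principal-point
    shift (see module docstring); with it disabled, a pose that pushes
    any tube endpoint off the raster raises :class:`FramingError`.
    """
    cfg = cfg or RenderConfig()
    if intr is None:
        intr = default_intrinsics(cfg.width_px, cfg.height_px)
    from .geometry import project_point  # local to avoid cycle at import time

    rng = np.random.default_rng(cfg.seed)
    ends = np.array([[0.0, -tube.half_length_cm, 0.0], [0.0, tube.half_length_cm, 0.0]])
    if auto_frame:
        mid_u, mid_v = project_point(pose, intr, np.array([0.0, 0.0, 0.0]))
        cx, cy = intr.principal_point()
        # a real camera's pixel grid has no fixed phase relative to the
        # scene: dither the framing by a seeded sub-pixel offset so zone
        # boundaries fall at uniformly distributed sub-pixel positions
        # across a cohort (a grid-aligned boundary would otherwise give
        # every sample the same quantization error)
        ju, jv = rng.uniform(-0.5, 0.5, size=2)
        # dataclass is frozen; build the shifted virtual sensor explicitly,
        # bypassing the inside-raster check which is for user-built intrinsics
        shifted = object.__new__(CameraIntrinsics)
        object.__setattr__(shifted, "focal_px", intr.focal_px)
        object.__setattr__(shifted, "image_width_px", intr.image_width_px)
        object.__setattr__(shifted, "image_height_px", intr.image_height_px)
        object.__setattr__(shifted, "principal_x_px", cx + cfg.width_px / 2.0 - mid_u + ju)
        object.__setattr__(shifted, "principal_y_px", cy + cfg.height_px / 2.0 - mid_v + jv)
        intr = shifted
    for end in ends:
        u, v = project_point(pose, intr, end)
        if not (0 <= u < cfg.width_px and 0 <= v < cfg.height_px):
            raise FramingError(
                f"tube endpoint projects to ({u:.1f}, {v:.1f}) outside the "
                f"{cfg.width_px}x{cfg.height_px} raster at pose {pose}"
            )

    x, y = _ray_plane_hits(pose, intr)
    zone = _classify_plane(tube, x, y)
    lut = np.array([cfg.palette[z] for z in _ZONES], dtype=np.float64)
    img = lut[zone]
    if cfg.noise_sigma > 0:
        img = img + rng.normal(0.0, cfg.noise_sigma, size=img.shape)
    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)

    rows = [project_point(pose, intr, p)[1] for p in tube.interface_points_cm()]
    truth = MarkerSet(lower_row=rows[0], buffy_row=rows[1], upper_row=rows[2])
    return RenderedSample(
        image=img,
        truth_markers=truth,
        pose=pose,
        tube=tube,
        config=cfg,
        intrinsics=intr,
        seed=cfg.seed,
    )


def render_cohort(
    n: int,
    hct_range: tuple[float, float] = (38.0, 48.0),
    pose: CameraPose | None = None,
    cfg: RenderConfig | None = None,
    seed: int = 0,
    tube: TubeSpec | None = None,
) -> list[RenderedSample]:
    """Render ``n`` tubes with true Hct drawn uniformly from ``hct_range``.

    Each sample's noise seed is derived deterministically from the cohort
    seed, so the cohort is reproducible end to end. ``tube`` supplies the
    common tube geometry (dimensions, meniscus); only the hematocrit
    varies across the cohort.
    """
    if n < 1:
        raise ConfigError(f"n must be >= 1, got {n}")
    lo, hi = hct_range
    if not (0.0 <= lo <= hi <= 100.0):
        raise ConfigError(f"hct_range must be ordered within [0, 100], got {hct_range}")
    pose = pose or CameraPose()
    cfg = cfg or RenderConfig()
    base = tube or TubeSpec()
    rng = np.random.default_rng(seed)
    hcts = rng.uniform(lo, hi, size=n)
    child_seeds = rng.integers(0, 2**31 - 1, size=n)
    out = []
    for hct, child in zip(hcts, child_seeds):
        t = replace(base, true_hct_pct=float(hct))
        out.append(render_tube(t, pose, replace(cfg, seed=int(child))))
    return out


# -- persistence -----------------------------------------------------------


def save_sample(sample: RenderedSample, png_path: str | Path) -> Path:
    """Write the raster as PNG plus a JSON sidecar with the ground truth."""
    png_path = Path(png_path)
    Image.fromarray(sample.image).save(png_path)
    cx, cy = sample.intrinsics.principal_point()
    sidecar = {
        "schema_version": SIDECAR_SCHEMA_VERSION,
        "tube": asdict(sample.tube),
        "pose": asdict(sample.pose),
        "truth_markers": asdict(sample.truth_markers),
        "intrinsics": {
            "focal_px": sample.intrinsics.focal_px,
            "image_width_px": sample.intrinsics.image_width_px,
            "image_height_px": sample.intrinsics.image_height_px,
            "principal_x_px": cx,
            "principal_y_px": cy,
        },
        "seed": sample.seed,
    }
    sidecar_path = png_path.with_suffix(".json")
    sidecar_path.write_text(json.dumps(sidecar, indent=2))
    return sidecar_path


def load_sidecar(path: str | Path) -> dict:
    """Load and minimally validate a sample's JSON sidecar."""
    data = json.loads(Path(path).read_text())
    if data.get("schema_version") != SIDECAR_SCHEMA_VERSION:
        raise ConfigError(
            f"unsupported sidecar schema {data.get('schema_version')!r}"
        )
    return data
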