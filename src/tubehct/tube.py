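"""Physical description of a centrifuged microhaematocrit capillary tube.

World coordinate frame ("tube-plane frame", units cm): the tube lies in
the z = 0 plane with its long axis along +y, centred on the origin; the
sealant-plug end is at y = -L/2 and the open (plasma) end toward +y; z
points up toward the camera.

After centrifugation the filled part of the tube stacks, bottom to top:
sealant plug, packed red-cell column, buffy coat, plasma. The nominal
(design) hematocrit is the packed-cell fraction of the plug-top to
plasma-top distance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

MM_PER_CM = 10.0


@dataclass(frozen=True)
class TubeSpec:
    """Ground-truth geometry of one centrifuged tube.

    Defaults describe a standard 75 mm x 1.1 mm-bore microhaematocrit
    tube with a 10 mm sealant plug and a short finger-prick sample column
    of 25 mm (plug top to plasma top). ``meniscus_depth_mm`` is the signed
    centre-line excursion of the red-cell/plasma interface and the plasma
    top: positive = concave (centre dips toward the plug), negative =
    convex. The marker convention places truth markers at the maximum
    excursion of the meniscus, i.e. at the centre line.
    """

    true_hct_pct: float = 42.0
    tube_length_mm: float = 75.0
    inner_diameter_mm: float = 1.1
    plug_length_mm: float = 10.0
    fill_length_mm: float = 25.0
    buffy_thickness_mm: float = 0.5
    meniscus_depth_mm: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.true_hct_pct <= 100.0:
            raise ValueError(f"true_hct_pct must be in [0, 100], got {self.true_hct_pct}")
        for name in ("tube_length_mm", "inner_diameter_mm", "plug_length_mm", "fill_length_mm"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.inner_diameter_mm <= 0:
            raise ValueError("inner_diameter_mm must be > 0")
        if self.buffy_thickness_mm < 0:
            raise ValueError("buffy_thickness_mm must be >= 0")
        if self.plug_length_mm + self.fill_length_mm > self.tube_length_mm:
            raise ValueError("plug + fill exceed the tube length")
        if self.rbc_length_mm + self.buffy_thickness_mm > self.fill_length_mm + 1e-12:
            raise ValueError("packed cells plus buffy coat exceed the fill length")
        if abs(self.meniscus_depth_mm) > self.fill_length_mm:
            raise ValueError("meniscus depth exceeds the fill length")

    # -- derived geometry (cm, tube-plane frame) ---------------------------

    @property
    def rbc_length_mm(self) -> float:
        return self.true_hct_pct / 100.0 * self.fill_length_mm

    @property
    def half_length_cm(self) -> float:
        return self.tube_length_mm / MM_PER_CM / 2.0

    @property
    def bore_radius_cm(self) -> float:
        return self.inner_diameter_mm / MM_PER_CM / 2.0

    @property
    def plug_top_y_cm(self) -> float:
        """y of the plug-top/red-cell interface (the 'lower' marker)."""
        return -self.half_length_cm + self.plug_length_mm / MM_PER_CM

    @property
    def buffy_y_cm(self) -> float:
        """Nominal (edge-level) y of the red-cell/plasma interface."""
        return self.plug_top_y_cm + self.rbc_length_mm / MM_PER_CM

    @property
    def plasma_top_y_cm(self) -> float:
        """Nominal (edge-level) y of the plasma top (the 'upper' marker)."""
        return self.plug_top_y_cm + self.fill_length_mm / MM_PER_CM

    def meniscus_offset_cm(self, x_cm: np.ndarray | float) -> np.ndarray | float:
        """Signed boundary depression at lateral offset ``x_cm``.

        Parabolic meniscus profile: zero at the glass walls, maximum
        excursion ``meniscus_depth_mm`` at the centre line. Returned in
        cm; positive values displace the boundary toward the plug.
        """
        r = self.bore_radius_cm
        depth = self.meniscus_depth_mm / MM_PER_CM
        frac = 1.0 - np.square(np.clip(np.abs(x_cm) / r, 0.0, 1.0))
        return depth * frac

    def interface_points_cm(self) -> np.ndarray:
        """The three marker points (lower, buffy, upper) as 3x3 array.

        Each row is an (x, y, z) point in the tube-plane frame. The lower
        marker sits on the flat plug top; buffy and upper sit at the
        centre-line extremum of their meniscus. Degenerate tubes collapse
        the buffy point onto the neighbouring flat interface (no meniscus
        without an interface): Hct 0 -> buffy at the plug top, Hct 100 ->
        buffy at the plasma top.
        """
        depth = self.meniscus_depth_mm / MM_PER_CM
        y_lower = self.plug_top_y_cm
        if self.true_hct_pct <= 0.0:
            y_buffy = y_lower
        else:
            y_buffy = self.buffy_y_cm - depth
        y_upper = self.plasma_top_y_cm - depth
        if self.true_hct_pct >= 100.0:
            y_buffy = y_upper
        return np.array(
            [[0.0, y_lower, 0.0], [0.0, y_buffy, 0.0], [0.0, y_upper, 0.0]]
        )
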