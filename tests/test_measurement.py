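"""Pixel-ratio measurement, screen resolution model, image adjustments."""

import numpy as np
import pytest
from hypothesis import assume, given
from hypothesis import strategies as st

from tubehct import (
    Adjustment,
    CameraPose,
    MarkerSet,
    TubeSpec,
    apply_adjustment,
    compute_hct,
    resolution,
    rotate_step,
)
from tubehct.errors import (
    ConfigError,
    DegenerateSampleError,
    MarkerOrderError,
    StateError,
)
from tubehct.renderer import RenderConfig, render_tube


def markers_strategy():
    return st.tuples(
        st.floats(0, 2000), st.floats(1, 1999), st.floats(0, 1)
    ).map(
        # upper < buffy <= lower, built constructively
        lambda t: MarkerSet(
            lower_row=max(t[0], t[1]) + 1.0,
            buffy_row=min(t[0], t[1]) + t[2] * (abs(t[0] - t[1]) + 1.0),
            upper_row=min(t[0], t[1]),
        )
    )


class TestComputeHct:
    def test_worked_example(self):
        res = compute_hct(MarkerSet(lower_row=900, buffy_row=450, upper_row=100))
        assert res.hct_pct == pytest.approx(56.25)
        assert res.reported_pct == 56.3
        assert res.blood_px == 450
        assert res.total_px == 800
        assert res.resolution_pct == pytest.approx(100 / 800)

    def test_boundary_identities(self):
        lower, upper = 800.0, 100.0
        assert compute_hct(MarkerSet(lower, lower, upper)).hct_pct == 0.0
        assert compute_hct(MarkerSet(lower, upper, upper)).hct_pct == 100.0

    def test_degenerate_and_disordered_markers_rejected(self):
        with pytest.raises(DegenerateSampleError):
            MarkerSet(lower_row=100, buffy_row=100, upper_row=100)
        with pytest.raises(MarkerOrderError):
            MarkerSet(lower_row=800, buffy_row=900, upper_row=100)
        with pytest.raises(MarkerOrderError):
            MarkerSet(lower_row=800, buffy_row=50, upper_row=100)

    def test_matches_renderer_ground_truth(self, nadir_sample):
        res = compute_hct(nadir_sample.truth_markers)
        assert res.hct_pct == pytest.approx(42.0, abs=res.resolution_pct)

    @given(m=markers_strategy(), shift=st.floats(-500, 500), scale=st.floats(0.1, 10))
    def test_translation_and_zoom_invariance(self, m, shift, scale):
        base = compute_hct(m).hct_pct
        shifted = MarkerSet(
            m.lower_row + shift, m.buffy_row + shift, m.upper_row + shift
        )
        assert compute_hct(shifted).hct_pct == pytest.approx(base, abs=1e-6)
        scaled = MarkerSet(
            m.lower_row * scale, m.buffy_row * scale, m.upper_row * scale
        )
        assume(scaled.lower_row - scaled.upper_row > 1e-6)
        assert compute_hct(scaled).hct_pct == pytest.approx(base, abs=1e-6)

    def test_row_axis_inversion_preserves_value(self, rng):
        # mirror-flip: rows r -> H - r swaps lower/upper and reflects buffy
        for _ in range(1000):
            upper = rng.uniform(0, 500)
            lower = upper + rng.uniform(1, 800)
            buffy = rng.uniform(upper, lower)
            m = MarkerSet(lower, buffy, upper)
            h = compute_hct(m).hct_pct
            assert 0.0 <= h <= 100.0
            height = 2000.0
            flipped = MarkerSet(
                lower_row=height - upper,
                buffy_row=height - (upper + (buffy - upper)),
                upper_row=height - lower,
            )
            # flipping measures the plasma fraction; complement restores Hct
            assert compute_hct(flipped).hct_pct == pytest.approx(100.0 - h, abs=1e-9)


class TestResolution:
    @pytest.mark.parametrize(
        "viewport, occupancy, decimals, expected",
        [
            (586, 0.75, 2, 0.23),  # small-phone viewport
            (932, 0.75, 1, 0.1),  # large-phone viewport
            (1000, 1.0, 10, 0.1),
        ],
    )
    def test_printed_increments(self, viewport, occupancy, decimals, expected):
        assert round(resolution(viewport, occupancy), decimals) == expected

    def test_exact_values(self):
        assert resolution(1000, 1.0) == pytest.approx(0.1, abs=1e-12)
        assert resolution(586, 0.75) == pytest.approx(100 / 439.5, abs=1e-12)

    def test_strictly_decreasing_in_both_arguments(self):
        vps = [200, 400, 586, 932, 2000]
        occs = [0.2, 0.5, 0.75, 1.0]
        for occ in occs:
            vals = [resolution(v, occ) for v in vps]
            assert all(a > b for a, b in zip(vals, vals[1:]))
        for v in vps:
            vals = [resolution(v, o) for o in occs]
            assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_invalid_arguments(self):
        with pytest.raises(ConfigError):
            resolution(0, 0.75)
        with pytest.raises(ConfigError):
            resolution(586, 0.0)
        with pytest.raises(ConfigError):
            resolution(586, 1.1)


class TestRotateStep:
    def test_single_right_press(self):
        assert rotate_step(Adjustment(), "right").rotation_deg == 0.5

    def test_three_left_presses(self):
        adj = Adjustment()
        for _ in range(3):
            adj = rotate_step(adj, "left")
        assert adj.rotation_deg == -1.5

    @given(presses=st.lists(st.sampled_from(["left", "right"]), max_size=30))
    def test_any_sequence_stays_on_half_degree_grid(self, presses):
        adj = Adjustment()
        for p in presses:
            adj = rotate_step(adj, p)
        assert (adj.rotation_deg * 2) == pytest.approx(round(adj.rotation_deg * 2))

    def test_rotation_locked_after_zoom(self):
        with pytest.raises(StateError):
            rotate_step(Adjustment(zoom=1.5), "right")

    def test_off_grid_rotation_rejected(self):
        with pytest.raises(ConfigError):
            Adjustment(rotation_deg=0.3)
        with pytest.raises(ConfigError):
            Adjustment(zoom=0.8)


class TestApplyAdjustment:
    def test_identity_is_byte_identical(self, small_sample):
        out = apply_adjustment(small_sample.image, Adjustment())
        assert out.dtype == small_sample.image.dtype
        assert np.array_equal(out, small_sample.image)

    def test_rotate_and_back_near_identity(self, small_sample):
        img = small_sample.image
        once = apply_adjustment(img, Adjustment(rotation_deg=0.5))
        back = apply_adjustment(once, Adjustment(rotation_deg=-0.5))
        # interior pixels only: rotation clips corners
        h, w = img.shape[:2]
        a = img[h // 4 : -h // 4, w // 4 : -w // 4].astype(float)
        b = back[h // 4 : -h // 4, w // 4 : -w // 4].astype(float)
        assert np.mean(np.abs(a - b)) < 3.0

    def test_rotating_zoomed_image_is_an_error(self, small_sample):
        with pytest.raises(StateError):
            apply_adjustment(small_sample.image, Adjustment(rotation_deg=0.5, zoom=2.0))

    def test_zoom_preserves_shape(self, small_sample):
        out = apply_adjustment(small_sample.image, Adjustment(zoom=1.5))
        assert out.shape == small_sample.image.shape

    def test_counter_rotation_straightens_rolled_render(self):
        from tubehct.detection import locate_tube_axis

        rolled = render_tube(
            TubeSpec(true_hct_pct=42.0),
            CameraPose(roll_deg=2.0),
            RenderConfig(noise_sigma=0.0),
        )
        assert locate_tube_axis(rolled.image).angle_deg == pytest.approx(2.0, abs=0.5)
        fixed = apply_adjustment(rolled.image, Adjustment(rotation_deg=-2.0))
        assert abs(locate_tube_axis(fixed).angle_deg) < 0.5
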