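"""Geometry, symmetry and composition of the rendered stimulus batteries."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from crowdbench.stimuli import (
    BoundsError,
    ConfigError,
    FlankerConfig,
    StimulusGeometry,
    add_flankers,
    build_battery,
    mirror,
    render_vernier,
)


def ink_bbox_height(pixels: np.ndarray) -> int:
    ys = np.nonzero(pixels)[0]
    return int(ys.max() - ys.min() + 1)


class TestRenderVernier:
    def test_target_height_is_84_arcmin_at_unit_resolution(self, default_geometry):
        img = render_vernier(default_geometry, "right")
        assert ink_bbox_height(img.pixels) == 84

    def test_zero_offset_image_is_mirror_symmetric(self, small_geometry):
        img = render_vernier(small_geometry, "none")
        assert np.array_equal(img.pixels, mirror(img.pixels))

    def test_left_image_is_mirror_of_right(self, small_geometry):
        left = render_vernier(small_geometry, "left")
        right = render_vernier(small_geometry, "right")
        assert np.array_equal(mirror(left.pixels), right.pixels)

    def test_two_luminance_levels_only(self, small_geometry):
        img = render_vernier(small_geometry, "right")
        assert set(np.unique(img.pixels)) == {
            small_geometry.background_level, small_geometry.foreground_level}

    def test_out_of_bounds_target_rejected(self):
        g = StimulusGeometry(image_width_px=64, image_height_px=64, vernier_height=84)
        with pytest.raises(BoundsError):
            render_vernier(g, "right")

    @given(offset=st.integers(min_value=0, max_value=10))
    @settings(max_examples=10, deadline=None)
    def test_mirror_property_for_any_offset(self, offset):
        g = StimulusGeometry(image_width_px=256, image_height_px=256,
                             vernier_height=32, vernier_offset=float(offset))
        left = render_vernier(g, "left")
        right = render_vernier(g, "right")
        assert np.array_equal(mirror(left.pixels), right.pixels)


class TestAddFlankers:
    def test_two_equal_lines_have_vernier_height(self, default_geometry):
        base = render_vernier(default_geometry, "right")
        out = add_flankers(base, FlankerConfig("lines", 2, "equal"))
        added = (out.pixels != 0) & (base.pixels == 0)
        # each flanker column is a single vertical segment of vernier height
        assert ink_bbox_height(added.astype(float)) == 84
        cols = np.unique(np.nonzero(added)[1])
        assert len(cols) == 4  # 2 lines x 2 px line width

    def test_no_flankers_is_identity(self, small_geometry):
        base = render_vernier(small_geometry, "left")
        out = add_flankers(base, FlankerConfig("none", 0))
        assert np.array_equal(out.pixels, base.pixels)

    def test_ink_monotone_in_count(self, small_geometry):
        base = render_vernier(small_geometry, "right")
        few = add_flankers(base, FlankerConfig("lines", 2, "equal"))
        many = add_flankers(base, FlankerConfig("lines", 16, "equal"))
        assert many.ink_count() > few.ink_count()

    @pytest.mark.parametrize("kind", ["lines", "lines_with_x", "rectangles", "rectangles_with_x"])
    def test_ink_monotone_in_length(self, small_geometry, kind):
        base = render_vernier(small_geometry, "right")
        inks = [add_flankers(base, FlankerConfig(kind, 16, lc)).ink_count()
                for lc in ("short", "equal", "long")]
        assert inks[0] < inks[1] < inks[2]

    def test_target_pixels_unchanged(self, small_geometry):
        base = render_vernier(small_geometry, "right")
        out = add_flankers(base, FlankerConfig("rectangles_with_x", 16, "long"))
        assert np.all(out.pixels[base.pixels != 0] == small_geometry.foreground_level)

    def test_inconsistent_config_rejected(self):
        with pytest.raises(ConfigError):
            FlankerConfig("none", 2)
        with pytest.raises(ConfigError):
            FlankerConfig("lines", 0)
        with pytest.raises(ConfigError):
            FlankerConfig("lines", 4)

    def test_flankers_exceeding_frame_rejected(self):
        g = StimulusGeometry(image_width_px=128, image_height_px=128,
                             vernier_height=32, element_spacing=14)
        base = render_vernier(g, "right")
        with pytest.raises(BoundsError):
            add_flankers(base, FlankerConfig("lines", 16, "equal"))

    def test_equal_length_flanker_matches_vernier_exactly(self, small_geometry):
        base = render_vernier(small_geometry, "right")
        out = add_flankers(base, FlankerConfig("lines", 2, "equal"))
        added = (out.pixels != 0) & (base.pixels == 0)
        ys = np.nonzero(added)[0]
        assert ys.max() - ys.min() + 1 == small_geometry.px(small_geometry.vernier_height)


class TestBuildBattery:
    def test_fig2a_has_eleven_flanked_conditions(self):
        bat = build_battery("manassi_fig2a")
        assert len(bat.flanked_labels) == 11
        assert bat.geometry.eccentricity_deg == pytest.approx(3.88)

    def test_malania_has_length_count_crossing_plus_baseline(self):
        bat = build_battery("malania_fig2b")
        assert len(bat.labels) == 7
        counts = {cfg.count for _, cfg in bat.conditions}
        assert counts == {0, 2, 16}
        assert bat.geometry.eccentricity_deg == 0.0

    def test_unknown_battery_rejected(self):
        with pytest.raises(ValueError, match="unknown battery"):
            build_battery("nonexistent")

    @pytest.mark.parametrize("name", ["manassi_fig2a", "malania_fig2b"])
    def test_left_images_mirror_right_images(self, name):
        bat = build_battery(name)
        for label in bat.labels:
            left, right = bat.images[label]["left"], bat.images[label]["right"]
            assert np.array_equal(mirror(left.pixels), right.pixels), label

    def test_batteries_are_deterministic(self, small_geometry):
        a = build_battery("malania_fig2b", small_geometry)
        b = build_battery("malania_fig2b", small_geometry)
        for label in a.labels:
            assert np.array_equal(a.images[label]["left"].pixels,
                                  b.images[label]["left"].pixels)
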