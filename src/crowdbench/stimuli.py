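"""Vernier/flanker stimulus rendering.

All stimuli are generated programmatically as calibrated 2-D luminance maps
(values in [0, 1], origin top-left, x rightward, y downward).  Two stimulus
batteries are provided:

* ``manassi_fig2a`` — a vernier at 3.88 deg eccentricity, 84 arc min tall,
  surrounded by eleven flanker configurations built from vertical lines,
  rectangles and superimposed X shapes.
* ``malania_fig2b`` — a foveal vernier flanked by vertical lines whose length
  (shorter than / equal to / longer than the vernier) and count (0, 2 or 16)
  are crossed factorially.

Rendering is integer-pixel (no anti-aliasing) and deterministic.  Mirror
symmetry is built in: for every condition whose flankers are left/right
symmetric, the left-offset image is the exact horizontal mirror of the
right-offset image.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

__all__ = [
    "StimulusGeometry",
    "FlankerConfig",
    "StimulusImage",
    "StimulusBattery",
    "BoundsError",
    "ConfigError",
    "LENGTH_MULTIPLIERS",
    "MANASSI_FIG2A_CONDITIONS",
    "render_vernier",
    "add_flankers",
    "build_battery",
    "mirror",
]

OffsetDirection = Literal["left", "right", "none"]
FlankerKind = Literal["none", "lines", "lines_with_x", "rectangles", "rectangles_with_x"]
LengthClass = Literal["short", "equal", "long"]

#: Flanker length as a multiple of the vernier height.  The source data only
#: state "shorter than" / "equal to" / "longer than"; the multipliers are a
#: documented design choice.
LENGTH_MULTIPLIERS: dict[str, float] = {"short": 0.5, "equal": 1.0, "long": 2.0}


class BoundsError(ValueError):
    """Raised when rendered ink would fall outside the image frame."""


class ConfigError(ValueError):
    """Raised for an internally inconsistent stimulus configuration."""


@dataclass(frozen=True)
class StimulusGeometry:
    """Spatial calibration and target layout for a stimulus frame.

    All linear sizes are in arc min and are converted to pixels with
    ``pixels_per_arcmin``.  ``eccentricity_deg`` is the horizontal distance of
    the target from a nominal fixation point; it is carried as metadata only
    (rendering is fixation-independent and no acuity falloff is modelled).
    """

    pixels_per_arcmin: float = 1.0
    image_width_px: int = 512
    image_height_px: int = 512
    vernier_height: float = 84.0  # total height of both segments, arc min
    vernier_offset: float = 2.0  # horizontal offset of the lower segment, arc min
    vernier_gap: float = 4.0  # vertical gap between the segments, arc min
    line_width: float = 2.0  # arc min
    element_spacing: float = 14.0  # center-to-center flanker spacing, arc min
    eccentricity_deg: float = 0.0
    background_level: float = 0.0
    foreground_level: float = 1.0

    def __post_init__(self) -> None:
        if not (self.vernier_height > 0 and self.element_spacing > 0 and self.line_width > 0):
            raise ValueError("vernier_height, element_spacing and line_width must be > 0")
        if self.vernier_offset < 0:
            raise ValueError("vernier_offset must be >= 0")
        if self.vernier_gap < 0 or self.vernier_gap >= self.vernier_height:
            raise ValueError("vernier_gap must be in [0, vernier_height)")
        if not (0 <= self.background_level <= 1 and 0 <= self.foreground_level <= 1):
            raise ValueError("luminance levels must lie in [0, 1]")
        if self.background_level == self.foreground_level:
            raise ValueError("background and foreground levels must differ")

    # -- pixel conversions ------------------------------------------------
    def px(self, arcmin: float) -> int:
        """Convert an arc min extent to a whole number of pixels (rounded)."""
        return int(round(arcmin * self.pixels_per_arcmin))

    @property
    def degrees_per_pixel(self) -> float:
        return 1.0 / (self.pixels_per_arcmin * 60.0)


@dataclass(frozen=True)
class FlankerConfig:
    """Flanker arrangement: what is drawn next to the target and how much.

    ``count`` is the *total* number of flanker columns (0, 2 or 16, i.e. 0, 1
    or 8 per side).  Rectangles reuse the flanking-line positions as their
    vertical sides, so the very same lines become part of a larger structure;
    X variants superimpose the two diagonals of each flanker region.
    """

    kind: FlankerKind = "none"
    count: int = 0
    length_class: LengthClass = "equal"

    def __post_init__(self) -> None:
        if self.kind not in ("none", "lines", "lines_with_x", "rectangles", "rectangles_with_x"):
            raise ConfigError(f"unknown flanker kind {self.kind!r}")
        if self.count not in (0, 2, 16):
            raise ConfigError(f"flanker count must be 0, 2 or 16, got {self.count}")
        if self.kind == "none" and self.count != 0:
            raise ConfigError("kind='none' requires count=0")
        if self.kind != "none" and self.count == 0:
            raise ConfigError("count=0 requires kind='none'")
        if self.length_class not in LENGTH_MULTIPLIERS:
            raise ConfigError(f"unknown length_class {self.length_class!r}")

    @property
    def per_side(self) -> int:
        return self.count // 2


@dataclass
class StimulusImage:
    """A rendered luminance map plus its calibration and condition metadata."""

    pixels: np.ndarray
    geometry: StimulusGeometry
    label: str = ""
    offset_direction: OffsetDirection = "none"

    def ink_count(self) -> int:
        """Number of foreground pixels."""
        return int(np.count_nonzero(self.pixels != self.geometry.background_level))


@dataclass
class StimulusBattery:
    """An ordered set of flanker conditions with left/right-offset renderings."""

    name: str
    geometry: StimulusGeometry
    conditions: list[tuple[str, FlankerConfig]]
    images: dict[str, dict[str, StimulusImage]]  # label -> {"left": ..., "right": ...}
    baseline_label: str = "baseline"

    @property
    def labels(self) -> list[str]:
        return [label for label, _ in self.conditions]

    @property
    def flanked_labels(self) -> list[str]:
        return [label for label, cfg in self.conditions if cfg.kind != "none"]


def mirror(pixels: np.ndarray) -> np.ndarray:
    """Horizontal mirror about the vertical mid-line of the frame."""
    return np.fliplr(pixels)


# ---------------------------------------------------------------------------
# low-level ink helpers (operate on a boolean ink mask)
# ---------------------------------------------------------------------------

def _centered_span(extent_px: int, width_px: int) -> tuple[int, int]:
    """Start/stop of a ``width_px`` span centred on the mirror axis of ``extent_px``.

    Chosen so that the span is invariant under ``fliplr``; requires
    ``extent_px - width_px`` to be even, which holds for the default geometry.
    """
    start = (extent_px - width_px) // 2
    return start, start + width_px


def _paint_vline(ink: np.ndarray, x_center_offset: int, y0: int, y1: int, width: int) -> None:
    """Paint a vertical bar of ``width`` px whose centre is ``x_center_offset``
    px right of the frame's mirror axis (0 = on axis)."""
    h, w = ink.shape
    c0, c1 = _centered_span(w, width)
    x0, x1 = c0 + x_center_offset, c1 + x_center_offset
    if x0 < 0 or x1 > w or y0 < 0 or y1 > h:
        raise BoundsError("vertical segment exceeds image bounds")
    ink[y0:y1, x0:x1] = True


def _paint_hline(ink: np.ndarray, y_center: int, x0: int, x1: int, width: int) -> None:
    h, w = ink.shape
    r0 = y_center - width // 2
    r1 = r0 + width
    if r0 < 0 or r1 > h or x0 < 0 or x1 > w:
        raise BoundsError("horizontal segment exceeds image bounds")
    ink[r0:r1, x0:x1] = True


def _paint_diagonal(ink: np.ndarray, x0: int, y0: int, x1: int, y1: int, width: int) -> None:
    """Integer-pixel diagonal from (x0,y0) to (x1,y1), thickened horizontally."""
    h, w = ink.shape
    n = max(abs(x1 - x0), abs(y1 - y0)) + 1
    xs = np.round(np.linspace(x0, x1, n)).astype(int)
    ys = np.round(np.linspace(y0, y1, n)).astype(int)
    for dx in range(width):
        xx = xs + dx
        if xx.min() < 0 or xx.max() >= w or ys.min() < 0 or ys.max() >= h:
            raise BoundsError("diagonal segment exceeds image bounds")
        ink[ys, xx] = True


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def render_vernier(geometry: StimulusGeometry, direction: OffsetDirection = "none") -> StimulusImage:
    """Render the target vernier: two vertical segments, the lower one shifted.

    The two segments are each ``(vernier_height - vernier_gap)/2`` tall,
    separated vertically by ``vernier_gap`` and horizontally centred; the
    lower segment is displaced ``vernier_offset`` to the right
    (``direction='right'``), to the left (``'left'``) or not at all
    (``'none'``).
    """
    if direction not in ("left", "right", "none"):
        raise ValueError(f"unknown offset direction {direction!r}")
    g = geometry
    h, w = g.image_height_px, g.image_width_px
    total = g.px(g.vernier_height)
    gap = g.px(g.vernier_gap)
    seg = (total - gap) // 2
    lw = max(1, g.px(g.line_width))
    off = g.px(g.vernier_offset) if direction != "none" else 0
    if direction == "left":
        off = -off

    y_top, _ = _centered_span(h, total)
    ink = np.zeros((h, w), dtype=bool)
    _paint_vline(ink, 0, y_top, y_top + seg, lw)  # upper segment
    _paint_vline(ink, off, y_top + total - seg, y_top + total, lw)  # lower segment

    pixels = np.full((h, w), g.background_level, dtype=float)
    pixels[ink] = g.foreground_level
    return StimulusImage(pixels=pixels, geometry=g, label="vernier", offset_direction=direction)


def _flanker_geometry(g: StimulusGeometry, config: FlankerConfig):
    """Per-side flanker column offsets (px from mirror axis) and vertical span."""
    spacing = g.px(g.element_spacing)
    length = g.px(LENGTH_MULTIPLIERS[config.length_class] * g.vernier_height)
    h = g.image_height_px
    y0, _ = _centered_span(h, length)
    offsets = [k * spacing for k in range(1, config.per_side + 1)]
    return offsets, y0, y0 + length, spacing


def _rectangle_spans(offsets: list[int], spacing: int) -> list[tuple[int, int]]:
    """Pair consecutive flanker columns into rectangle (inner, outer) spans.

    An unpaired trailing column gets a rectangle extending one spacing outward,
    so its inner vertical still coincides with the flanking-line position.
    """
    spans = []
    for i in range(0, len(offsets) - 1, 2):
        spans.append((offsets[i], offsets[i + 1]))
    if len(offsets) % 2:
        spans.append((offsets[-1], offsets[-1] + spacing))
    return spans


def add_flankers(target: StimulusImage, config: FlankerConfig) -> StimulusImage:
    """Superimpose a flanker configuration on a rendered vernier.

    Flanker ink is rendered for the right side only and mirrored to the left,
    guaranteeing bit-exact left/right symmetry of the flanker pattern.  Target
    pixels are left unchanged.
    """
    g = target.geometry
    if config.kind == "none":
        return StimulusImage(
            pixels=target.pixels.copy(), geometry=g, label=target.label,
            offset_direction=target.offset_direction,
        )

    offsets, y0, y1, spacing = _flanker_geometry(g, config)
    lw = max(1, g.px(g.line_width))
    right = np.zeros_like(target.pixels, dtype=bool)

    if config.kind in ("lines", "lines_with_x"):
        for off in offsets:
            _paint_vline(right, off, y0, y1, lw)
    else:  # rectangles
        w = g.image_width_px
        c0, _ = _centered_span(w, lw)
        for inner, outer in _rectangle_spans(offsets, spacing):
            _paint_vline(right, inner, y0, y1, lw)
            _paint_vline(right, outer, y0, y1, lw)
            x_in, x_out = c0 + inner, c0 + outer + lw
            _paint_hline(right, y0 + lw // 2, x_in, x_out, lw)
            _paint_hline(right, y1 - 1 - lw // 2, x_in, x_out, lw)

    if config.kind in ("lines_with_x", "rectangles_with_x"):
        w = g.image_width_px
        c0, _ = _centered_span(w, lw)
        for inner, outer in _rectangle_spans(offsets, spacing):
            x_in, x_out = c0 + inner, c0 + outer + lw - 1
            _paint_diagonal(right, x_in, y0, x_out - lw + 1, y1 - 1, lw)
            _paint_diagonal(right, x_in, y1 - 1, x_out - lw + 1, y0, lw)

    ink = right | mirror(right)
    pixels = target.pixels.copy()
    pixels[ink] = g.foreground_level
    return StimulusImage(
        pixels=pixels, geometry=g, label=target.label,
        offset_direction=target.offset_direction,
    )


#: Reconstruction of the eleven flanked conditions of the peripheral battery.
#: The source figure shows these only graphically; this table is approximate
#: (kinds and counts named in the text, exact composition inferred).
MANASSI_FIG2A_CONDITIONS: list[tuple[str, FlankerConfig]] = [
    ("lines-2", FlankerConfig("lines", 2, "equal")),
    ("lines-16", FlankerConfig("lines", 16, "equal")),
    ("lines_x-2", FlankerConfig("lines_with_x", 2, "equal")),
    ("lines_x-16", FlankerConfig("lines_with_x", 16, "equal")),
    ("rect-2", FlankerConfig("rectangles", 2, "equal")),
    ("rect-16", FlankerConfig("rectangles", 16, "equal")),
    ("rect_x-2", FlankerConfig("rectangles_with_x", 2, "equal")),
    ("rect_x-16", FlankerConfig("rectangles_with_x", 16, "equal")),
    ("lines_short-2", FlankerConfig("lines", 2, "short")),
    ("lines_long-2", FlankerConfig("lines", 2, "long")),
    ("lines_short-16", FlankerConfig("lines", 16, "short")),
]

MALANIA_FIG2B_CONDITIONS: list[tuple[str, FlankerConfig]] = [
    ("baseline", FlankerConfig("none", 0)),
    ("short-2", FlankerConfig("lines", 2, "short")),
    ("short-16", FlankerConfig("lines", 16, "short")),
    ("equal-2", FlankerConfig("lines", 2, "equal")),
    ("equal-16", FlankerConfig("lines", 16, "equal")),
    ("long-2", FlankerConfig("lines", 2, "long")),
    ("long-16", FlankerConfig("lines", 16, "long")),
]

BATTERY_NAMES = ("manassi_fig2a", "malania_fig2b")


def build_battery(name: str, geometry: StimulusGeometry | None = None) -> StimulusBattery:
    """Build a full stimulus battery (left- and right-offset image per condition).

    ``manassi_fig2a``: eleven flanked conditions plus the unflanked baseline at
    3.88 deg eccentricity.  ``malania_fig2b``: the length x count crossing
    (count in {2, 16}) plus the count=0 baseline, centred fixation.
    """
    if name == "manassi_fig2a":
        geometry = geometry or StimulusGeometry(eccentricity_deg=3.88)
        conditions = [("baseline", FlankerConfig("none", 0))] + list(MANASSI_FIG2A_CONDITIONS)
    elif name == "malania_fig2b":
        geometry = geometry or StimulusGeometry(eccentricity_deg=0.0)
        conditions = list(MALANIA_FIG2B_CONDITIONS)
    else:
        raise ValueError(f"unknown battery {name!r}; expected one of {BATTERY_NAMES}")

    images: dict[str, dict[str, StimulusImage]] = {}
    for label, cfg in conditions:
        pair = {}
        for direction in ("left", "right"):
            img = add_flankers(render_vernier(geometry, direction), cfg)
            img.label = label
            pair[direction] = img
        images[label] = pair
    return StimulusBattery(name=name, geometry=geometry, conditions=conditions, images=images)
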