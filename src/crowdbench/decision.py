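"""Template-matching decision stage shared by all models.

A model's response map is compared with ideal renderings of the left- and
right-offset vernier (no flankers), restricted to a window centred on the
target whose width is five times the element spacing by default.  The match
difference (correct template minus incorrect template) indexes
discriminability; it is then inverted and linearly scaled to the range of a
human reference vector, turning model output into predicted threshold
elevations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .stimuli import StimulusBattery, StimulusGeometry, render_vernier

__all__ = [
    "TemplatePair",
    "DiscriminabilityScore",
    "ThresholdPrediction",
    "build_templates",
    "match",
    "discriminability",
    "battery_scores",
    "scale_to_human",
]


@dataclass
class TemplatePair:
    """Windowed left/right vernier templates.

    ``left`` and ``right`` are full-frame maps, zero outside a window of width
    ``width_factor * element_spacing`` centred on the target and mean-
    subtracted inside it; ``cols`` is the window's column slice.  The left
    template is the exact horizontal mirror of the right template.
    """

    left: np.ndarray
    right: np.ndarray
    cols: slice
    width_factor: float


@dataclass
class DiscriminabilityScore:
    """Directional match difference (correct minus incorrect template),
    averaged over the left- and right-offset renditions of a condition."""

    value: float
    condition: str = ""
    model: str = ""


@dataclass
class ThresholdPrediction:
    """Affine, sign-inverting mapping of scores to threshold-elevation units.

    prediction = a + b * (-score), with the gain b clamped to >= 0.  When all
    scores coincide b is unidentifiable; the fit degenerates to the mean of
    the human vector and is flagged.
    """

    predictions: np.ndarray
    a: float
    b: float
    ssr: float
    degenerate: bool = False


def build_templates(geometry: StimulusGeometry, width_factor: float = 5.0) -> TemplatePair:
    """Render the left/right vernier templates, windowed and mean-subtracted.

    The window width is ``width_factor`` times the element spacing (default 5,
    the convention of template-matching crowding observers), rounded to an
    even pixel count so the window is symmetric about the target axis.  The
    template offset magnitude equals the stimulus offset magnitude.
    """
    if width_factor <= 0:
        raise ValueError("width_factor must be > 0")
    w = geometry.image_width_px
    win = int(round(width_factor * geometry.element_spacing * geometry.pixels_per_arcmin))
    win -= (win - w) % 2  # match frame parity so the window centres exactly
    if win > w:
        raise ValueError(f"template window ({win} px) exceeds frame width ({w} px)")
    c0 = (w - win) // 2
    cols = slice(c0, c0 + win)

    def _windowed(direction: str) -> np.ndarray:
        t = render_vernier(geometry, direction).pixels.copy()
        t[:, : cols.start] = 0.0
        t[:, cols.stop:] = 0.0
        t[:, cols] -= t[:, cols].mean()
        return t

    right = _windowed("right")
    left = np.fliplr(right)  # exact mirror; the rendered left vernier coincides
    return TemplatePair(left=left, right=right, cols=cols, width_factor=width_factor)


def match(response: np.ndarray, template: np.ndarray, cols: slice,
          normalized: bool = True) -> float:
    """Correlation of a response map with a template at the fixed target location.

    The response is windowed to the template's columns and mean-subtracted
    there, then correlated with the (already mean-subtracted) template.  With
    ``normalized=True`` (default) the value is a normalized cross-correlation
    in [-1, 1], invariant to affine rescaling of the response; either operand
    having zero norm yields 0.  No spatial search is performed: the observer
    knows where the target is.
    """
    if response.shape != template.shape:
        raise ValueError(f"response shape {response.shape} != template shape {template.shape}")
    r = response[:, cols] - response[:, cols].mean()
    t = template[:, cols]
    num = float(np.sum(r * t))
    if not normalized:
        return num
    denom = float(np.linalg.norm(r) * np.linalg.norm(t))
    if denom == 0.0:
        return 0.0
    return num / denom


def discriminability(responses: dict[str, np.ndarray], templates: TemplatePair,
                     condition: str = "", model: str = "",
                     normalized: bool = True) -> DiscriminabilityScore:
    """Score a condition from its left- and right-offset response maps.

    For each rendition, value = match(correct template) - match(incorrect
    template); the two directional values are averaged.  Mirror-symmetric
    stimuli with zero offset necessarily score 0.
    """
    per_direction = []
    for direction, response in responses.items():
        if direction == "left":
            true_t, other_t = templates.left, templates.right
        elif direction == "right":
            true_t, other_t = templates.right, templates.left
        else:
            raise ValueError(f"true direction must be 'left' or 'right', got {direction!r}")
        per_direction.append(
            match(response, true_t, templates.cols, normalized)
            - match(response, other_t, templates.cols, normalized)
        )
    return DiscriminabilityScore(value=float(np.mean(per_direction)),
                                 condition=condition, model=model)


def battery_scores(battery: StimulusBattery, respond, templates: TemplatePair,
                   model: str = "", normalized: bool = True) -> dict[str, float]:
    """Apply a response function ``respond(StimulusImage) -> map`` to every
    condition of a battery and return per-condition discriminability values."""
    scores = {}
    for label in battery.labels:
        responses = {d: respond(battery.images[label][d]) for d in ("left", "right")}
        scores[label] = discriminability(responses, templates, label, model, normalized).value
    return scores


def scale_to_human(scores, human) -> ThresholdPrediction:
    """Least-squares affine map from inverted scores to the human range.

    Minimizes sum((a + b * (-score) - human)^2) over (a, b) with b >= 0.
    Identical scores leave b unidentifiable: the fit is flagged degenerate and
    returns b = 0, a = mean(human).
    """
    s = np.asarray(scores, dtype=float)
    h = np.asarray(human, dtype=float)
    if s.shape != h.shape or s.size < 2:
        raise ValueError("scores and human must be equal-length vectors of size >= 2")
    if not np.all(np.isfinite(h)) or not np.all(np.isfinite(s)):
        raise ValueError("scores and human values must be finite")

    x = -s
    var_x = float(np.var(x))
    degenerate = np.ptp(x) == 0.0  # all scores identical -> gain unidentifiable
    b = 0.0 if degenerate else max(0.0, float(np.cov(x, h, bias=True)[0, 1] / var_x))
    a = float(h.mean() - b * x.mean())
    pred = a + b * x
    ssr = float(np.sum((pred - h) ** 2))
    return ThresholdPrediction(predictions=pred, a=a, b=b, ssr=ssr, degenerate=degenerate)
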