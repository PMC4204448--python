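"""Feedforward global observer: Fourier analysis, radial frequency masking,
Fourier synthesis.

The stimulus is transformed to the frequency domain, a radially symmetric
mask in cycles/degree suppresses a subset of spatial frequencies (hard binary
masks by default, with an optional raised-cosine edge), and the inverse
transform reconstructs a filtered response map.  Phases of passed components
are kept untouched; no zero padding is applied, so the stimulus frame itself
is the analysis window (periodic boundary implied by the transform).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .stimuli import StimulusImage

__all__ = [
    "FilterSpec",
    "FrequencyMask",
    "FilterSpecError",
    "build_filter_mask",
    "filter_image",
]

FilterFamily = Literal["lowpass", "bandpass", "highpass"]


class FilterSpecError(ValueError):
    """Raised for an invalid spatial-frequency filter specification."""


@dataclass(frozen=True)
class FilterSpec:
    """Parametric description of a radial spatial-frequency filter.

    Frequencies are in cycles/degree of visual angle.  ``lowpass`` passes
    radial frequency f <= cutoff, ``highpass`` passes f >= cutoff and
    ``bandpass`` passes |f - center_freq| <= bandwidth / 2.  The DC component
    is therefore passed by any lowpass, blocked by any highpass with
    cutoff > 0, and passed by a bandpass exactly when its lower edge reaches 0.
    """

    family: FilterFamily
    cutoff: float | None = None
    center_freq: float | None = None
    bandwidth: float | None = None

    def __post_init__(self) -> None:
        if self.family in ("lowpass", "highpass"):
            if self.cutoff is None or self.cutoff < 0:
                raise FilterSpecError(f"{self.family} requires cutoff >= 0")
        elif self.family == "bandpass":
            if self.center_freq is None or self.bandwidth is None:
                raise FilterSpecError("bandpass requires center_freq and bandwidth")
            if self.center_freq < 0 or self.bandwidth < 0:
                raise FilterSpecError("bandpass frequencies must be >= 0")
            if self.center_freq - self.bandwidth / 2 < 0:
                raise FilterSpecError(
                    "bandpass lower edge extends below 0 cycles/degree "
                    f"(center={self.center_freq}, bandwidth={self.bandwidth})"
                )
        else:
            raise FilterSpecError(f"unknown filter family {self.family!r}")

    def short_id(self) -> str:
        if self.family == "bandpass":
            return f"bp_c{self.center_freq:g}_w{self.bandwidth:g}"
        return f"{self.family[:2]}_{self.cutoff:g}"


@dataclass
class FrequencyMask:
    """Realized 2-D frequency mask with DC at the grid centre.

    ``values`` lie in [0, 1] and depend only on radial frequency magnitude;
    they are binary for the default hard-mask dialect.  ``cyc_per_deg`` gives
    the radial frequency of every bin on the same (fftshifted) lattice.
    """

    values: np.ndarray
    cyc_per_deg: np.ndarray
    spec: FilterSpec


def radial_frequency_grid(shape: tuple[int, int], degrees_per_pixel: float) -> np.ndarray:
    """Radial spatial frequency (cycles/degree) of each bin, DC at centre."""
    h, w = shape
    fy = np.fft.fftshift(np.fft.fftfreq(h, d=degrees_per_pixel))
    fx = np.fft.fftshift(np.fft.fftfreq(w, d=degrees_per_pixel))
    return np.hypot(fy[:, None], fx[None, :])


def build_filter_mask(
    spec: FilterSpec,
    image_shape: tuple[int, int],
    degrees_per_pixel: float,
    taper: float = 0.0,
) -> FrequencyMask:
    """Realize a filter spec as a 2-D mask on the image's frequency lattice.

    ``taper`` > 0 replaces the hard edge with a raised-cosine transition of
    that width (cycles/degree) for robustness experiments; the default 0 gives
    the binary mask.
    """
    f = radial_frequency_grid(image_shape, degrees_per_pixel)
    if spec.family == "lowpass":
        dist = f - spec.cutoff  # positive outside the passband
    elif spec.family == "highpass":
        dist = spec.cutoff - f
    else:
        dist = np.abs(f - spec.center_freq) - spec.bandwidth / 2
    if taper <= 0:
        values = (dist <= 0).astype(float)
    else:
        t = np.clip(dist / taper + 0.5, 0.0, 1.0)  # 0 inside passband, 1 outside
        values = 0.5 * (1 + np.cos(np.pi * t))
    return FrequencyMask(values=values, cyc_per_deg=f, spec=spec)


def filter_image(image: StimulusImage | np.ndarray, mask: FrequencyMask) -> np.ndarray:
    """Fourier analysis -> mask -> Fourier synthesis.

    Returns the real reconstruction (the imaginary residue of the inverse
    transform is numerically negligible for the symmetric masks used here and
    is discarded).  The output is *not* re-clipped to [0, 1]; it feeds the
    template-matching stage, not a display.
    """
    pixels = image.pixels if isinstance(image, StimulusImage) else np.asarray(image, dtype=float)
    if pixels.shape != mask.values.shape:
        raise ValueError(f"image shape {pixels.shape} != mask shape {mask.values.shape}")
    spectrum = np.fft.fft2(pixels)
    filtered = spectrum * np.fft.ifftshift(mask.values)
    return np.fft.ifft2(filtered).real


def filter_spectrum(spectrum: np.ndarray, mask: FrequencyMask) -> np.ndarray:
    """As :func:`filter_image` but starting from a precomputed ``fft2`` spectrum.

    Used by the grid search to avoid recomputing forward transforms for every
    candidate filter.
    """
    if spectrum.shape != mask.values.shape:
        raise ValueError("spectrum/mask shape mismatch")
    return np.fft.ifft2(spectrum * np.fft.ifftshift(mask.values)).real
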