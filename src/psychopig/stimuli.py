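"""Luminance-matched striped targets and the uniform gray control.

The task shows a striped target of some contrast on one screen panel
against a uniform gray control of the same mean luminance on the other.
Contrast here is Michelson contrast on linear 8-bit gray levels,

    C = (L_max - L_min) / (L_max + L_min),

the standard metric for periodic gratings.  The stripe levels for a
target of contrast ``c`` around mean luminance ``m`` are ``m*(1+c)`` and
``m*(1-c)``, rounded half-up (away from zero); the same rule is applied
to the control.  Half-up keeps the two stripe levels' complementary
fractional parts symmetric (their exact sum ``2m`` is preserved to
within one level in the same direction as the control), so target and
control means agree to within half a gray level; half-to-even can round
both levels downward and open a full-level gap.

No display gamma model is applied: gray level is taken as proportional
to luminance.  Real deployments calibrate the display externally.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Literal, Optional

import numpy as np
from PIL import Image

__all__ = [
    "StimulusSpec",
    "StimulusImage",
    "michelson_contrast",
    "make_stripe_image",
    "make_control_image",
    "standard_contrast_set",
    "write_stimulus_set",
]

Orientation = Literal["vertical", "horizontal"]

#: Contrasts used in the experimental phase: 10% to 100% in 10% steps.
STANDARD_CONTRASTS: tuple[float, ...] = tuple(round(0.1 * i, 1) for i in range(1, 11))

DEFAULT_MEAN_LUMINANCE = 127.5
DEFAULT_SPATIAL_FREQUENCY = 8
DEFAULT_SIZE_PX = 512


class StimulusError(ValueError):
    """Invalid or unrenderable stimulus specification."""


@dataclass(frozen=True)
class StimulusSpec:
    """Parametric description of a striped target.

    Parameters
    ----------
    contrast
        Michelson contrast in [0, 1] (the 10%-100% scale as 0.1-1.0).
    mean_luminance
        Mean gray level in [0, 255]; shared with the control image.
    spatial_frequency
        Number of full stripe pairs across the axis perpendicular to
        the stripes.  The physical cycles/degree depend on screen size
        and viewing distance, which are not modeled.
    orientation
        ``"vertical"`` stripes vary along x; ``"horizontal"`` along y.
    """

    contrast: float
    mean_luminance: float = DEFAULT_MEAN_LUMINANCE
    spatial_frequency: int = DEFAULT_SPATIAL_FREQUENCY
    orientation: Orientation = "vertical"
    width_px: int = DEFAULT_SIZE_PX
    height_px: int = DEFAULT_SIZE_PX

    def __post_init__(self) -> None:
        if not 0.0 <= self.contrast <= 1.0:
            raise StimulusError(f"contrast must be in [0, 1], got {self.contrast}")
        if not 0.0 <= self.mean_luminance <= 255.0:
            raise StimulusError(
                f"mean_luminance must be in [0, 255], got {self.mean_luminance}"
            )
        if self.spatial_frequency < 1:
            raise StimulusError("spatial_frequency must be >= 1")
        if self.orientation not in ("vertical", "horizontal"):
            raise StimulusError(f"unknown orientation {self.orientation!r}")
        n_px = self.width_px if self.orientation == "vertical" else self.height_px
        if self.width_px < 2 or self.height_px < 2 or n_px < 2 * self.spatial_frequency:
            raise StimulusError(
                "image too small: need >= 2*spatial_frequency pixels across stripes"
            )

    @property
    def stripe_levels(self) -> tuple[int, int]:
        """(low, high) gray levels realizing the requested contrast."""
        hi = self.mean_luminance * (1.0 + self.contrast)
        lo = self.mean_luminance * (1.0 - self.contrast)
        if hi > 255.0 or lo < 0.0:
            raise StimulusError(
                f"unrenderable: levels ({lo:.1f}, {hi:.1f}) outside [0, 255]"
            )
        return _round_gray(lo), _round_gray(hi)


@dataclass(frozen=True)
class StimulusImage:
    """Rendered 8-bit grayscale image; ``spec is None`` marks the control."""

    pixels: np.ndarray
    spec: Optional[StimulusSpec]
    mean_luminance: float

    @property
    def is_control(self) -> bool:
        return self.spec is None

    def achieved_contrast(self) -> float:
        return michelson_contrast(int(self.pixels.max()), int(self.pixels.min()))

    def save_png(self, path: str | Path) -> Path:
        path = Path(path)
        Image.fromarray(self.pixels, mode="L").save(path, format="PNG")
        return path


def _round_gray(x: float) -> int:
    """Round a nonnegative gray level to the nearest integer, half-up."""
    return int(np.floor(x + 0.5))


def michelson_contrast(l_max: float, l_min: float) -> float:
    """Michelson contrast (l_max - l_min)/(l_max + l_min) of a grating.

    Raises
    ------
    StimulusError
        If both levels are zero (contrast undefined) or levels are
        out of order / out of the 8-bit range.
    """
    if not 0 <= l_min <= l_max <= 255:
        raise StimulusError(f"need 0 <= l_min <= l_max <= 255, got ({l_min}, {l_max})")
    if l_max + l_min == 0:
        raise StimulusError("contrast undefined when both levels are zero")
    return (l_max - l_min) / (l_max + l_min)


def make_stripe_image(spec: StimulusSpec) -> StimulusImage:
    """Render a square-wave (50% duty cycle) striped target.

    Deterministic: identical specs produce bit-identical images.  The
    image contains exactly ``spec.spatial_frequency`` full stripe pairs
    along the axis perpendicular to the stripe orientation, its mean
    gray level is within one level of ``spec.mean_luminance``, and the
    Michelson contrast of the two stripe levels is within the 8-bit
    quantization error of ``spec.contrast``.

    The mean-luminance match requires a 50% duty cycle, which holds
    exactly when the stripe-axis length is a multiple of
    ``2 * spatial_frequency`` (true for the 512 px / 8-pair defaults);
    otherwise stripe widths differ by one pixel and the mean can drift
    by up to ``255 * spatial_frequency / width`` gray levels.
    """
    lo, hi = spec.stripe_levels
    n = spec.width_px if spec.orientation == "vertical" else spec.height_px
    # 2*sf equal-as-possible bands across n pixels; band k has level hi
    # for even k so the pattern starts on a bright stripe.
    band = (np.arange(n) * 2 * spec.spatial_frequency) // n
    profile = np.where(band % 2 == 0, hi, lo).astype(np.uint8)
    if spec.orientation == "vertical":
        pixels = np.broadcast_to(profile, (spec.height_px, spec.width_px)).copy()
    else:
        pixels = np.broadcast_to(
            profile[:, None], (spec.height_px, spec.width_px)
        ).copy()
    return StimulusImage(pixels=pixels, spec=spec, mean_luminance=spec.mean_luminance)


def make_control_image(
    mean_luminance: float = DEFAULT_MEAN_LUMINANCE,
    width_px: int = DEFAULT_SIZE_PX,
    height_px: int = DEFAULT_SIZE_PX,
) -> StimulusImage:
    """Uniform gray control image at the given mean luminance.

    Non-integer levels are rounded half-up, the same rule used for
    stripe levels, so target and control means match.
    """
    if not 0.0 <= mean_luminance <= 255.0:
        raise StimulusError(f"mean_luminance must be in [0, 255], got {mean_luminance}")
    if width_px < 1 or height_px < 1:
        raise StimulusError("image dimensions must be positive")
    level = _round_gray(mean_luminance)
    pixels = np.full((height_px, width_px), level, dtype=np.uint8)
    return StimulusImage(pixels=pixels, spec=None, mean_luminance=mean_luminance)


def standard_contrast_set(
    mean_luminance: float = DEFAULT_MEAN_LUMINANCE,
    spatial_frequency: int = DEFAULT_SPATIAL_FREQUENCY,
    orientation: Orientation = "vertical",
    width_px: int = DEFAULT_SIZE_PX,
    height_px: int = DEFAULT_SIZE_PX,
) -> list[StimulusSpec]:
    """The 10 experimental-phase specs: contrasts 0.1, 0.2, ..., 1.0."""
    base = StimulusSpec(
        contrast=1.0,
        mean_luminance=mean_luminance,
        spatial_frequency=spatial_frequency,
        orientation=orientation,
        width_px=width_px,
        height_px=height_px,
    )
    return [replace(base, contrast=c) for c in STANDARD_CONTRASTS]


def write_stimulus_set(
    out_dir: str | Path,
    specs: Iterable[StimulusSpec] | None = None,
    mean_luminance: float = DEFAULT_MEAN_LUMINANCE,
) -> list[Path]:
    """Write one PNG per contrast level plus the control image.

    Filenames encode contrast in percent: ``stripe_c040.png`` is the
    40%-contrast target; ``control.png`` is the gray control.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if specs is None:
        specs = standard_contrast_set(mean_luminance=mean_luminance)
    specs = list(specs)
    paths = []
    for spec in specs:
        name = f"stripe_c{int(round(spec.contrast * 100)):03d}.png"
        paths.append(make_stripe_image(spec).save_png(out_dir / name))
    if specs:
        ctrl = make_control_image(
            specs[0].mean_luminance, specs[0].width_px, specs[0].height_px
        )
    else:
        ctrl = make_control_image(mean_luminance)
    paths.append(ctrl.save_png(out_dir / "control.png"))
    return paths
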