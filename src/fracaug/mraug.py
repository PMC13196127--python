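"""MR acquisition-variability augmentations.

Three intensity-only augmentations emulate scan-to-scan appearance
variation between treatment sessions: a random monotone histogram shift,
a random global intensity scale, and random Gibbs (k-space truncation)
ringing.  None of them ever alters image geometry or touches labels, and
identity configurations are exact fixed points.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .grid import ImageVolume

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MrAugConfig:
    """Parameter ranges of the three augmentations.

    ``histogram_shift_strength`` is the maximum control-point perturbation
    as a fraction of the intensity range; ``gibbs_alpha_range`` draws the
    fraction of highest spatial frequencies removed per axis.
    ``apply_probability`` gates each augmentation independently.
    """

    histogram_shift_control_points: int = 6
    histogram_shift_strength: float = 0.05
    intensity_scale_range: tuple[float, float] = (0.9, 1.1)
    gibbs_alpha_range: tuple[float, float] = (0.0, 0.4)
    apply_probability: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.histogram_shift_control_points < 2:
            raise ValidationError("need at least 2 histogram control points")
        if self.histogram_shift_strength < 0:
            raise ValidationError("histogram_shift_strength must be >= 0")
        for name in ("intensity_scale_range", "gibbs_alpha_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValidationError(f"{name} must be ordered (lo <= hi)")
        if not (0 <= self.gibbs_alpha_range[0] and self.gibbs_alpha_range[1] < 1):
            raise ValidationError("gibbs alphas must lie in [0, 1)")
        if not 0 <= self.apply_probability <= 1:
            raise ValidationError("apply_probability must lie in [0, 1]")

    @classmethod
    def identity(cls) -> "MrAugConfig":
        return cls(histogram_shift_strength=0.0, intensity_scale_range=(1.0, 1.0),
                   gibbs_alpha_range=(0.0, 0.0))


def random_histogram_shift(
    image: ImageVolume, config: MrAugConfig, rng: np.random.Generator
) -> ImageVolume:
    """Remap intensities through a random monotone piecewise-linear curve.

    Control points are evenly spaced over [min, max]; interior targets are
    perturbed within ``strength x range`` and re-sorted, endpoints stay
    pinned, so the output range equals the input range and intensity rank
    order is preserved.
    """
    k = config.histogram_shift_control_points
    # Draw even with strength 0 so downstream draws do not depend on it.
    perturb = rng.uniform(-1.0, 1.0, size=max(k - 2, 0))
    if config.histogram_shift_strength == 0:
        return image.with_values(image.values.copy())
    lo, hi = float(image.values.min()), float(image.values.max())
    if hi == lo:
        return image.with_values(image.values.copy())
    x = np.linspace(lo, hi, k)
    y = x.copy()
    y[1:-1] += perturb * config.histogram_shift_strength * (hi - lo)
    y[1:-1] = np.clip(y[1:-1], lo, hi)
    y = np.sort(y)
    return image.with_values(np.interp(image.values, x, y))


def random_intensity_scale(
    image: ImageVolume, config: MrAugConfig, rng: np.random.Generator
) -> ImageVolume:
    """Multiply every voxel by one factor drawn uniformly from the range."""
    lo, hi = config.intensity_scale_range
    factor = float(rng.uniform(lo, hi))
    return image.with_values(image.values * factor)


def random_gibbs_noise(
    image: ImageVolume, config: MrAugConfig, rng: np.random.Generator
) -> ImageVolume:
    """Truncation (Gibbs ringing) artefact via k-space low-pass filtering.

    A fraction alpha of the highest spatial frequencies per axis is zeroed
    in the centred FFT; alpha = 0 reproduces the input exactly.  The DC
    component is always retained.
    """
    lo, hi = config.gibbs_alpha_range
    alpha = float(rng.uniform(lo, hi))
    if alpha == 0:
        return image.with_values(image.values.copy())
    spectrum = np.fft.fftshift(np.fft.fftn(image.values))
    mask = np.ones(image.shape, dtype=bool)
    for axis, n in enumerate(image.shape):
        keep = max(1, int(round((1.0 - alpha) * n)))
        centre = n // 2
        start = max(0, min(centre - keep // 2, n - keep))
        axis_keep = np.zeros(n, dtype=bool)
        axis_keep[start:start + keep] = True
        shape = [1, 1, 1]
        shape[axis] = n
        mask &= axis_keep.reshape(shape)
    filtered = np.fft.ifftn(np.fft.ifftshift(spectrum * mask)).real
    return image.with_values(filtered)


_PIPELINE = (
    ("histogram_shift", random_histogram_shift),
    ("intensity_scale", random_intensity_scale),
    ("gibbs_noise", random_gibbs_noise),
)


def apply_mr_augmentations(
    image: ImageVolume, config: MrAugConfig, rng: np.random.Generator
) -> ImageVolume:
    """Apply the three augmentations in fixed order, each gated by a draw.

    Order is histogram shift, then intensity scale, then Gibbs noise; each
    step fires independently with ``config.apply_probability``.  The gate
    draw is consumed whether or not the step fires, so the sequence of
    draws (hence reproducibility) does not depend on earlier gates.
    """
    out = image
    for name, op in _PIPELINE:
        gate = float(rng.uniform())
        fired = gate < config.apply_probability or config.apply_probability == 1.0
        logger.info("mr augmentation %s: %s", name, "applied" if fired else "skipped")
        if fired:
            out = op(out, config, rng)
    return out
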