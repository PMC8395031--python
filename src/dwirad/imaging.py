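"""ADC map computation and ROI intensity normalization / quantization.

The apparent diffusion coefficient is estimated pixel-by-pixel from a
two-point mono-exponential decay, ``ADC = (ln SI_0 - ln SI) / (b - b_0)``,
where ``SI_0`` and ``SI`` are the signal intensities at the low and high
b-value (here 0 and 800 s/mm^2).  Before texture extraction, intensities
inside each ROI are clipped to the mean +/- 3 SD band of the ROI and
linearly rescaled; gray levels are then quantized to 8 bits (256 levels)
for co-occurrence counting.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

N_LEVELS = 256  # 8 bits/pixel

B_LOW_DEFAULT = 0.0
B_HIGH_DEFAULT = 800.0


@dataclass
class ImageStack:
    """Per-case 2D channels sharing one grid and pixel spacing.

    ``adc`` is derived (``compute_adc``); it is ``None`` until computed.
    """

    b0: np.ndarray
    b800: np.ndarray
    pixel_spacing_mm: float
    b_low: float = B_LOW_DEFAULT
    b_high: float = B_HIGH_DEFAULT
    adc: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.b0 = np.asarray(self.b0, dtype=float)
        self.b800 = np.asarray(self.b800, dtype=float)
        if self.b0.shape != self.b800.shape:
            raise ValueError(
                f"channel shapes differ: b0 {self.b0.shape} vs b800 {self.b800.shape}"
            )
        if self.b_high <= self.b_low:
            raise ValueError("b_high must exceed b_low")
        if self.pixel_spacing_mm <= 0:
            raise ValueError("pixel_spacing_mm must be positive")

    def with_adc(self) -> "ImageStack":
        """Return self after filling the ADC channel (idempotent)."""
        if self.adc is None:
            self.adc = compute_adc(self.b0, self.b800, self.b_low, self.b_high)
        return self

    @property
    def channels(self) -> dict[str, np.ndarray]:
        out = {"b0": self.b0, "b800": self.b800}
        if self.adc is not None:
            out["adc"] = self.adc
        return out


@dataclass
class NormalizationParams:
    """ROI normalization parameters: mean, SD and the quantization depth."""

    mu: float
    sigma: float
    n_levels: int = N_LEVELS
    degenerate: bool = False  # sigma == 0
    n_floored: int = 0  # non-positive pixels floored before log (ADC only)


def compute_adc(
    b0_image: np.ndarray,
    b800_image: np.ndarray,
    b_low: float = B_LOW_DEFAULT,
    b_high: float = B_HIGH_DEFAULT,
) -> np.ndarray:
    """Pixel-wise ADC map (mm^2/s) from the two-point decay model.

    Non-positive intensities are floored at the smallest positive value
    present in the corresponding image before taking logarithms, so that
    noisy background pixels yield large-but-finite values instead of
    infinities; the number of floored pixels is logged.
    """
    si0 = np.asarray(b0_image, dtype=float)
    si = np.asarray(b800_image, dtype=float)
    if si0.shape != si.shape:
        raise ValueError(f"shape mismatch: {si0.shape} vs {si.shape}")
    if b_high == b_low:
        raise ValueError("b_high and b_low must differ")
    if b_high < b_low:
        raise ValueError("b_high must exceed b_low")

    n_floored = 0
    floored = []
    for img in (si0, si):
        bad = img <= 0
        if bad.any():
            pos = img[img > 0]
            if pos.size == 0:
                raise ValueError("image contains no positive intensities")
            img = np.where(bad, pos.min(), img)
            n_floored += int(bad.sum())
        floored.append(img)
    si0, si = floored
    if n_floored:
        logger.warning("compute_adc: floored %d non-positive pixels", n_floored)

    return (np.log(si0) - np.log(si)) / (b_high - b_low)


def normalize_continuous(
    image: np.ndarray, mask: np.ndarray
) -> tuple[np.ndarray, NormalizationParams]:
    """Clip to the ROI's mu +/- 3 sigma band and rescale to [0, 255] (float).

    Statistics come from the masked pixels only; the affine map is applied to
    the whole image so that texture filters have valid neighborhoods, but only
    in-mask values are meaningful downstream.  A zero-variance ROI maps to 0
    everywhere with a degeneracy flag (batch runs keep going).
    """
    image = np.asarray(image, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != image.shape:
        raise ValueError("mask shape must match image shape")
    if not mask.any():
        raise ValueError("empty mask")
    vals = image[mask]
    mu = float(vals.mean())
    sigma = float(vals.std())  # population SD
    params = NormalizationParams(mu=mu, sigma=sigma)
    if sigma == 0.0:
        params.degenerate = True
        warnings.warn("zero-variance ROI: all pixels map to level 0", stacklevel=2)
        return np.zeros_like(image), params
    lo, hi = mu - 3.0 * sigma, mu + 3.0 * sigma
    clipped = np.clip(image, lo, hi)
    scaled = (clipped - lo) / (hi - lo) * (N_LEVELS - 1)
    return scaled, params


def quantize(normalized: np.ndarray, params: NormalizationParams) -> np.ndarray:
    """Map the continuous [0, 255] scale to integer levels 0..255.

    Half-open equal-width bins over [mu-3s, mu+3s]; the right edge is
    inclusive at level 255 (values at exactly the upper clip land on 255).
    """
    if params.degenerate:
        return np.zeros(normalized.shape, dtype=np.int64)
    # normalized is (x-lo)/(hi-lo)*255; bins of width (hi-lo)/256 correspond
    # to floor(normalized * 256/255), clipped so the top edge maps to 255.
    levels = np.floor(normalized * (N_LEVELS / (N_LEVELS - 1))).astype(np.int64)
    return np.clip(levels, 0, N_LEVELS - 1)


def normalize_and_quantize(
    image: np.ndarray, mask: np.ndarray
) -> tuple[np.ndarray, NormalizationParams]:
    """ROI normalization followed by 8-bit quantization (see module docs)."""
    scaled, params = normalize_continuous(image, mask)
    return quantize(scaled, params), params
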