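"""Semi-automatic lesion segmentation and peritumoral ring construction.

The intratumoral ROI follows a five-step recipe on the high-b-value image:
a rough seed region around the lesion is Otsu-thresholded, the binary
result is eroded with a 4x4 square structuring element, the largest
8-connected component is kept, and that component is dilated back with the
same element.  The peritumoral ROI is the band within 4 mm of the
intratumoral boundary (Euclidean distance transform, radius rounded to
pixels), optionally clipped to a breast-parenchyma mask.  Contours are
propagated unchanged to the co-registered b0 and ADC channels.

Conventions (pinned, see regression tests): masks are row-major boolean
arrays with 0-based indices; the even 4x4 element is anchored at the
top-left pixel of its central 2x2 block (``origin=-1`` in scipy terms,
covered by a regression test); mm-to-pixel rounding is nearest with
ties-to-even.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

logger = logging.getLogger(__name__)

RING_WIDTH_MM = 4.0

SQUARE_ELEMENT = np.ones((4, 4), dtype=bool)
EIGHT_CONNECTED = np.ones((3, 3), dtype=bool)
OTSU_BINS = 256


@dataclass
class RoiSet:
    """Intratumoral mask, peritumoral ring and optional breast mask."""

    intratumoral: np.ndarray
    peritumoral: np.ndarray
    breast_mask: np.ndarray | None = None
    ring_width_mm: float = RING_WIDTH_MM

    def __post_init__(self) -> None:
        self.intratumoral = np.asarray(self.intratumoral, dtype=bool)
        self.peritumoral = np.asarray(self.peritumoral, dtype=bool)
        if self.intratumoral.shape != self.peritumoral.shape:
            raise ValueError("intratumoral and peritumoral shapes differ")
        if (self.intratumoral & self.peritumoral).any():
            raise ValueError("intratumoral and peritumoral ROIs overlap")

    @property
    def regions(self) -> dict[str, np.ndarray]:
        return {"intra": self.intratumoral, "peri": self.peritumoral}


def otsu_threshold(values: np.ndarray) -> float:
    """Threshold maximizing between-class variance (256-bin histogram).

    Ties resolve to the lowest qualifying threshold.  Raises on constant
    input, where no two classes exist.
    """
    values = np.asarray(values, dtype=float).ravel()
    if values.size == 0:
        raise ValueError("no values")
    if np.unique(values).size < 2:
        raise ValueError("all values identical; Otsu threshold undefined")
    return float(threshold_otsu(values, nbins=OTSU_BINS))


def segment_intratumoral(
    b800_image: np.ndarray, seed_region: np.ndarray
) -> np.ndarray:
    """Five-step intratumoral segmentation within a rough seed region.

    Otsu-binarize the seed's intensities (lesion = bright class on b800),
    erode with the 4x4 square element, keep the largest 8-connected
    component, dilate with the same element.  The result is a single
    8-connected blob; an error names the failure stage otherwise.
    """
    image = np.asarray(b800_image, dtype=float)
    seed = np.asarray(seed_region, dtype=bool)
    if seed.shape != image.shape:
        raise ValueError("seed_region shape must match image")
    if not seed.any():
        raise ValueError("seed region is empty")

    try:
        t = otsu_threshold(image[seed])
    except ValueError as exc:
        raise ValueError(f"Otsu failed inside seed region: {exc}") from exc
    binary = seed & (image > t)
    if not binary.any():
        raise ValueError("no foreground pixels above Otsu threshold in seed")

    # origin=-1 anchors the even element at the top-left of its central 2x2
    eroded = ndimage.binary_erosion(binary, structure=SQUARE_ELEMENT, origin=-1)
    if not eroded.any():
        raise ValueError(
            "erosion with the 4x4 element emptied the mask; lesion too small"
        )

    labels, n = ndimage.label(eroded, structure=EIGHT_CONNECTED)
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, range(1, n + 1))
        keep = int(np.argmax(sizes)) + 1
        eroded = labels == keep

    return ndimage.binary_dilation(eroded, structure=SQUARE_ELEMENT, origin=-1)


def ring_radius_px(ring_width_mm: float, pixel_spacing_mm: float) -> int:
    """mm-to-pixel radius, rounded to nearest (ties-to-even)."""
    if pixel_spacing_mm <= 0:
        raise ValueError("pixel spacing must be positive")
    return int(np.round(ring_width_mm / pixel_spacing_mm))


def peritumoral_ring(
    intratumoral: np.ndarray,
    ring_width_mm: float = RING_WIDTH_MM,
    pixel_spacing_mm: float = 1.0,
    breast_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Band within ``ring_width_mm`` of the intratumoral boundary.

    Implemented as a Euclidean-distance-transform threshold (isotropic, unlike
    iterated square dilations), minus the intratumoral region, clipped to the
    breast mask when one is supplied.
    """
    intra = np.asarray(intratumoral, dtype=bool)
    if not intra.any():
        raise ValueError("intratumoral mask is empty")
    radius = ring_radius_px(ring_width_mm, pixel_spacing_mm)
    dist = ndimage.distance_transform_edt(~intra)
    ring = (dist <= radius) & ~intra
    if breast_mask is not None:
        ring &= np.asarray(breast_mask, dtype=bool)
        if not ring.any():
            warnings.warn(
                "peritumoral ring fully clipped by the breast mask", stacklevel=2
            )
    return ring


def propagate_rois(roi: RoiSet, stack) -> dict[str, RoiSet]:
    """Copy the ROI masks to every channel of a co-registered stack.

    The channels share one grid, so propagation is a per-channel reference
    to identical masks; a shape mismatch raises.
    """
    out: dict[str, RoiSet] = {}
    for name, channel in stack.channels.items():
        if channel.shape != roi.intratumoral.shape:
            raise ValueError(
                f"channel {name!r} shape {channel.shape} differs from ROI shape "
                f"{roi.intratumoral.shape}"
            )
        out[name] = RoiSet(
            intratumoral=roi.intratumoral.copy(),
            peritumoral=roi.peritumoral.copy(),
            breast_mask=None if roi.breast_mask is None else roi.breast_mask.copy(),
            ring_width_mm=roi.ring_width_mm,
        )
    return out
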