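"""The 2,504-feature texture bank and z-score normalization.

Per case: 14 shape descriptors of the intratumoral mask, plus — for every
channel (b0, b800, ADC) crossed with every region (intratumoral,
peritumoral) — 5 first-order statistics, 45 GLCM features (9 Haralick
descriptors pooled over a 4-direction x 5-distance co-occurrence ensemble
with 5 statistics), 125 Laws texture-energy features (25 separable 5x5
filters x 5 statistics of the absolute in-mask response), and 240 Gabor
features (6 frequencies x 8 orientations x 5 statistics of the response
magnitude): 14 + 6 x 415 = 2,504 uniquely named values.

Texture inputs: Laws and Gabor filters run on the continuous mu +/- 3 sigma
normalized values; the GLCM runs on the 8-bit quantized levels (quantization
exists only for co-occurrence counting).  Convolution uses reflect padding;
only in-mask response pixels are pooled.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, signal
from skimage.measure import regionprops

from .imaging import N_LEVELS, ImageStack, normalize_continuous, quantize
from .segmentation import RoiSet

CHANNELS = ("b0", "b800", "adc")
REGIONS = ("intra", "peri")
CATEGORIES = ("shape", "firstorder", "glcm", "laws", "gabor")
STATISTICS = ("mean", "median", "sd", "skewness", "kurtosis")

SHAPE_DESCRIPTORS = (
    "Area",
    "Perimeter",
    "Sphericity",
    "Elongation",
    "Extent",
    "Circularity",
    "Solidity",
    "Eccentricity",
    "EquivalentDiameter",
    "MajorAxisLength",
    "MinorAxisLength",
    "PerimeterAreaRatio",
    "Maximum2DDiameter",
    "SphericalDisproportion",
)

GLCM_DESCRIPTORS = (
    "Energy",
    "Contrast",
    "Correlation",
    "Variance",
    "Entropy",
    "Homogeneity",
    "InverseDifferenceMoment",
    "Imc1",
    "Imc2",
)

# Laws 1D kernels: level, edge, spot, wave, ripple.
LAWS_1D = {
    "L5": np.array([1.0, 4.0, 6.0, 4.0, 1.0]),
    "E5": np.array([-1.0, -2.0, 0.0, 2.0, 1.0]),
    "S5": np.array([-1.0, 0.0, 2.0, 0.0, -1.0]),
    "W5": np.array([-1.0, 2.0, 0.0, -2.0, -1.0]),
    "R5": np.array([1.0, -4.0, 6.0, -4.0, 1.0]),
}
LAWS_ORDER = ("L5", "E5", "S5", "W5", "R5")

GABOR_FREQUENCIES = (0, 2, 4, 8, 16, 32)  # cycles per image width
GABOR_ORIENTATIONS = (0.0, 22.5, 45.0, 67.5, 90.0, 112.5, 135.0, 167.5)
GABOR_ORIENTATIONS_UNIFORM = (0.0, 22.5, 45.0, 67.5, 90.0, 112.5, 135.0, 157.5)


@dataclass(frozen=True)
class BankConfig:
    """Configuration of the feature bank.

    ``glcm_distances``/``glcm_directions`` define the co-occurrence ensemble
    pooled by the five statistics; ``gabor_image_width`` is the reference
    width for the cycles-per-image-width frequencies; ``max_kernel_radius``
    truncates low-frequency Gabor envelopes (the f = 0 and f = 2 Gaussians
    would otherwise span the whole grid).  ``uniform_orientations`` replaces
    the 167.5 degree entry with the uniform 157.5 degree grid.
    """

    categories: tuple[str, ...] = CATEGORIES
    glcm_distances: tuple[int, ...] = (1, 2, 3, 4, 5)
    glcm_directions: tuple[float, ...] = (0.0, 45.0, 90.0, 135.0)
    gabor_frequencies: tuple[int, ...] = GABOR_FREQUENCIES
    uniform_orientations: bool = False
    gabor_bandwidth_octaves: float = 1.0
    gabor_image_width: int = 256
    max_kernel_radius: int = 32

    @property
    def gabor_orientations(self) -> tuple[float, ...]:
        return (
            GABOR_ORIENTATIONS_UNIFORM
            if self.uniform_orientations
            else GABOR_ORIENTATIONS
        )

    @property
    def glcm_offsets(self) -> list[tuple[int, int]]:
        offs = []
        for theta in self.glcm_directions:
            rad = np.deg2rad(theta)
            step = (-int(round(np.sin(rad))), int(round(np.cos(rad))))
            for d in self.glcm_distances:
                offs.append((step[0] * d, step[1] * d))
        return offs


DEFAULT_BANK = BankConfig()


# ---------------------------------------------------------------------------
# registry


def gabor_descriptor(freq: int | float, theta: float) -> str:
    return f"f{freq:g}-th{theta:g}"


def laws_descriptors() -> list[str]:
    return [a + b for a in LAWS_ORDER for b in LAWS_ORDER]


def feature_names(bank: BankConfig = DEFAULT_BANK) -> list[str]:
    """The full registry, in stable (serialization) order."""
    names: list[str] = []
    if "shape" in bank.categories:
        names += [f"shape__{d}" for d in SHAPE_DESCRIPTORS]
    per_combo: list[tuple[str, str]] = []
    if "firstorder" in bank.categories:
        per_combo += [("firstorder", s) for s in STATISTICS]
    if "glcm" in bank.categories:
        per_combo += [
            ("glcm", f"{d}__{s}") for d in GLCM_DESCRIPTORS for s in STATISTICS
        ]
    if "laws" in bank.categories:
        per_combo += [
            ("laws", f"{d}__{s}") for d in laws_descriptors() for s in STATISTICS
        ]
    if "gabor" in bank.categories:
        per_combo += [
            ("gabor", f"{gabor_descriptor(f, t)}__{s}")
            for f in bank.gabor_frequencies
            for t in bank.gabor_orientations
            for s in STATISTICS
        ]
    for channel in CHANNELS:
        for region in REGIONS:
            names += [f"{channel}__{region}__{cat}__{d}" for cat, d in per_combo]
    return names


def parse_feature_name(name: str) -> dict[str, str]:
    """Split a registry name into its provenance tags."""
    parts = name.split("__")
    if parts[0] == "shape":
        return {
            "category": "shape",
            "channel": "none",
            "region": "none",
            "descriptor": parts[1],
            "statistic": "none",
        }
    channel, region, category = parts[:3]
    if category == "firstorder":
        return {
            "category": category,
            "channel": channel,
            "region": region,
            "descriptor": "intensity",
            "statistic": parts[3],
        }
    return {
        "category": category,
        "channel": channel,
        "region": region,
        "descriptor": parts[3],
        "statistic": parts[4],
    }


# ---------------------------------------------------------------------------
# pooled statistics


def pooled_statistics(values: np.ndarray) -> dict[str, float]:
    """Mean, median, SD, skewness, kurtosis with population (n) denominators.

    Skewness is m3 / m2^1.5 and kurtosis m4 / m2^2 (Pearson, not excess);
    both are defined as 0 for zero-variance input.
    """
    v = np.asarray(values, dtype=float).ravel()
    if v.size == 0:
        raise ValueError("empty input")
    mean = float(v.mean())
    centered = v - mean
    m2 = float(np.mean(centered**2))
    sd = float(np.sqrt(m2))
    # zero-variance rule, robust to float cancellation on constant input
    if sd <= 1e-12 * max(1.0, abs(mean)):
        sd = 0.0
        skew = kurt = 0.0
    else:
        skew = float(np.mean(centered**3) / m2**1.5)
        kurt = float(np.mean(centered**4) / m2**2)
    return {
        "mean": mean,
        "median": float(np.median(v)),
        "sd": sd,
        "skewness": skew,
        "kurtosis": kurt,
    }


# ---------------------------------------------------------------------------
# shape


def shape_features(mask: np.ndarray, pixel_spacing_mm: float) -> dict[str, float]:
    """The 14 shape descriptors of a single-component mask, in mm / mm^2.

    Pinned formulas: Circularity = 4 pi A / P^2; Sphericity (2D) =
    2 sqrt(pi A) / P; SphericalDisproportion = P / (2 sqrt(pi A)) (the
    reciprocal of sphericity); Elongation = minor / major axis length;
    Maximum2DDiameter is the maximum Feret diameter.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    n_comp = ndimage.label(mask, structure=np.ones((3, 3)))[1]
    if n_comp != 1:
        raise ValueError(f"mask has {n_comp} components; expected a single lesion")

    props = regionprops(mask.astype(np.uint8))[0]
    s = pixel_spacing_mm
    area = props.area * s**2
    perimeter = props.perimeter * s
    if perimeter <= 0:
        raise ValueError("mask too small for perimeter-based shape features")
    sphericity = 2.0 * np.sqrt(np.pi * area) / perimeter
    major = props.axis_major_length * s
    minor = props.axis_minor_length * s
    return {
        "Area": float(area),
        "Perimeter": float(perimeter),
        "Sphericity": float(sphericity),
        "Elongation": float(minor / major) if major > 0 else 1.0,
        "Extent": float(props.extent),
        "Circularity": float(4.0 * np.pi * area / perimeter**2),
        "Solidity": float(props.solidity),
        "Eccentricity": float(props.eccentricity),
        "EquivalentDiameter": float(2.0 * np.sqrt(area / np.pi)),
        "MajorAxisLength": float(major),
        "MinorAxisLength": float(minor),
        "PerimeterAreaRatio": float(perimeter / area),
        "Maximum2DDiameter": float(props.feret_diameter_max * s),
        "SphericalDisproportion": float(1.0 / sphericity),
    }


# ---------------------------------------------------------------------------
# GLCM


def glcm_matrix(
    quantized: np.ndarray, mask: np.ndarray, offset: tuple[int, int]
) -> np.ndarray:
    """Symmetric, normalized co-occurrence matrix over in-mask pixel pairs.

    Only pairs with both pixels inside the mask are counted; the matrix is
    symmetrized (each pair counted in both orders) and normalized to sum 1.
    """
    q = np.asarray(quantized)
    m = np.asarray(mask, dtype=bool)
    dr, dc = offset
    h, w = q.shape
    r0, r1 = max(0, -dr), min(h, h - dr)
    c0, c1 = max(0, -dc), min(w, w - dc)
    if r0 >= r1 or c0 >= c1:
        raise ValueError(f"offset {offset} leaves no valid pixel pairs")
    a = q[r0:r1, c0:c1]
    b = q[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
    valid = m[r0:r1, c0:c1] & m[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
    if not valid.any():
        raise ValueError(f"no in-mask pixel pairs for offset {offset}")
    i = a[valid].astype(np.int64)
    j = b[valid].astype(np.int64)
    counts = np.bincount(i * N_LEVELS + j, minlength=N_LEVELS * N_LEVELS)
    glcm = counts.reshape(N_LEVELS, N_LEVELS).astype(float)
    glcm = glcm + glcm.T
    return glcm / glcm.sum()


def haralick_descriptors(glcm: np.ndarray) -> dict[str, float]:
    """Nine Haralick descriptors of one normalized symmetric GLCM.

    Entropies use log base 2 with 0 log 0 = 0.  Correlation and the
    information measures are defined as 0 when degenerate (zero marginal
    variance or zero marginal entropy).
    """
    idx_i, idx_j = np.nonzero(glcm)
    p = glcm[idx_i, idx_j]
    i = idx_i.astype(float)
    j = idx_j.astype(float)

    px = glcm.sum(axis=1)
    levels = np.arange(glcm.shape[0], dtype=float)
    mu = float((levels * px).sum())
    var = float(((levels - mu) ** 2 * px).sum())

    energy = float((p**2).sum())
    contrast = float(((i - j) ** 2 * p).sum())
    homogeneity = float((p / (1.0 + np.abs(i - j))).sum())
    idm = float((p / (1.0 + (i - j) ** 2)).sum())
    entropy = float(-(p * np.log2(p)).sum())
    correlation = (
        float((((i - mu) * (j - mu) * p).sum()) / var) if var > 0 else 0.0
    )

    # information measures of correlation over present marginal levels
    present = px > 0
    px_nz = px[present]
    hx = float(-(px_nz * np.log2(px_nz)).sum())
    pipj = px_nz[:, None] * px_nz[None, :]
    hxy2 = float(-(pipj * np.log2(pipj)).sum())
    hxy1 = float(-(p * np.log2(glcm.sum(axis=1)[idx_i] * px[idx_j])).sum())
    # symmetric GLCM: HX = HY, so max(HX, HY) = HX; IMC1 = (HXY - HXY1)/HX <= 0
    imc1 = (entropy - hxy1) / hx if hx > 0 else 0.0
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - entropy)))))

    return {
        "Energy": energy,
        "Contrast": contrast,
        "Correlation": correlation,
        "Variance": var,
        "Entropy": entropy,
        "Homogeneity": homogeneity,
        "InverseDifferenceMoment": idm,
        "Imc1": imc1,
        "Imc2": imc2,
    }


def glcm_features(
    quantized: np.ndarray, mask: np.ndarray, bank: BankConfig = DEFAULT_BANK
) -> dict[str, float]:
    """45 features: 9 descriptors pooled over the offset ensemble by 5 stats."""
    per_descriptor: dict[str, list[float]] = {d: [] for d in GLCM_DESCRIPTORS}
    for offset in bank.glcm_offsets:
        desc = haralick_descriptors(glcm_matrix(quantized, mask, offset))
        for name, value in desc.items():
            per_descriptor[name].append(value)
    out: dict[str, float] = {}
    for name, values in per_descriptor.items():
        for stat, value in pooled_statistics(np.array(values)).items():
            out[f"{name}__{stat}"] = value
    return out


# ---------------------------------------------------------------------------
# Laws


def laws_bank() -> dict[str, np.ndarray]:
    """25 5x5 filters: outer products of the 1D kernels (row x column)."""
    return {
        a + b: np.outer(LAWS_1D[a], LAWS_1D[b]) for a in LAWS_ORDER for b in LAWS_ORDER
    }


def laws_features(image: np.ndarray, mask: np.ndarray) -> dict[str, float]:
    """125 features: abs filter response pooled in-mask by the 5 statistics."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    if min(mask.shape) < 5:
        raise ValueError("mask support smaller than the 5x5 filter")
    out: dict[str, float] = {}
    # separable filters: one row pass per 1D kernel, then one column pass
    row_passes = {
        a: ndimage.correlate1d(image, LAWS_1D[a], axis=0, mode="reflect")
        for a in LAWS_ORDER
    }
    for a in LAWS_ORDER:
        for b in LAWS_ORDER:
            response = ndimage.correlate1d(
                row_passes[a], LAWS_1D[b], axis=1, mode="reflect"
            )
            stats = pooled_statistics(np.abs(response[mask]))
            for stat, value in stats.items():
                out[f"{a}{b}__{stat}"] = value
    return out


# ---------------------------------------------------------------------------
# Gabor


def gabor_kernel(
    frequency: float, theta_deg: float, bank: BankConfig = DEFAULT_BANK
) -> np.ndarray:
    """Complex Gabor kernel at a frequency in cycles per image width.

    The Gaussian envelope is isotropic with sigma set by the one-octave
    bandwidth rule sigma = (1 / (pi f_px)) sqrt(ln 2 / 2) (2^b + 1)/(2^b - 1);
    f = 0 degenerates to a plain Gaussian and borrows the sigma of the lowest
    nonzero frequency in the bank.  Support is truncated at 3 sigma, capped
    at ``max_kernel_radius`` pixels; the envelope is normalized to unit mass
    so the f = 0 filter passes constants unchanged.
    """
    b = bank.gabor_bandwidth_octaves
    factor = np.sqrt(np.log(2.0) / 2.0) * (2.0**b + 1.0) / (2.0**b - 1.0) / np.pi
    if frequency > 0:
        f_px = frequency / bank.gabor_image_width
    else:
        f_nonzero = min(f for f in bank.gabor_frequencies if f > 0)
        f_px = f_nonzero / bank.gabor_image_width
    sigma = factor / f_px
    radius = int(min(np.ceil(3.0 * sigma), bank.max_kernel_radius))
    y, x = np.mgrid[-radius : radius + 1, -radius : radius + 1].astype(float)
    envelope = np.exp(-(x**2 + y**2) / (2.0 * sigma**2))
    envelope /= envelope.sum()
    if frequency == 0:
        return envelope.astype(complex)
    theta = np.deg2rad(theta_deg)
    carrier = np.exp(2j * np.pi * (frequency / bank.gabor_image_width) * (
        x * np.cos(theta) + y * np.sin(theta)
    ))
    return envelope * carrier


def _reflect_convolve_magnitude(image: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """|image * kernel| with reflect padding, same output shape."""
    radius = kernel.shape[0] // 2
    padded = np.pad(image, radius, mode="reflect")
    response = signal.fftconvolve(padded, kernel, mode="valid")
    return np.abs(response)


def gabor_features(
    image: np.ndarray, mask: np.ndarray, bank: BankConfig = DEFAULT_BANK
) -> dict[str, float]:
    """240 features: response magnitude pooled in-mask by the 5 statistics."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    out: dict[str, float] = {}
    for f in bank.gabor_frequencies:
        for theta in bank.gabor_orientations:
            kernel = gabor_kernel(f, theta, bank)
            magnitude = _reflect_convolve_magnitude(image, kernel)
            stats = pooled_statistics(magnitude[mask])
            for stat, value in stats.items():
                out[f"{gabor_descriptor(f, theta)}__{stat}"] = value
    return out


# ---------------------------------------------------------------------------
# per-case extraction


def _crop_slices(
    masks: list[np.ndarray], shape: tuple[int, int], margin: int
) -> tuple[slice, slice]:
    union = np.zeros(shape, dtype=bool)
    for m in masks:
        union |= m
    rows = np.flatnonzero(union.any(axis=1))
    cols = np.flatnonzero(union.any(axis=0))
    r0 = max(0, rows[0] - margin)
    r1 = min(shape[0], rows[-1] + 1 + margin)
    c0 = max(0, cols[0] - margin)
    c1 = min(shape[1], cols[-1] + 1 + margin)
    return slice(r0, r1), slice(c0, c1)


def extract_features(
    stack: ImageStack, rois: RoiSet, bank: BankConfig = DEFAULT_BANK
) -> pd.Series:
    """Extract the configured bank for one case; values in registry order.

    Computation is restricted to the ROI bounding box plus a margin wide
    enough (max kernel radius + max GLCM distance) that every in-mask
    response pixel sees only real image data, so cropping is exact.
    """
    stack.with_adc()
    values: dict[str, float] = {}
    if "shape" in bank.categories:
        shape = shape_features(rois.intratumoral, stack.pixel_spacing_mm)
        for d in SHAPE_DESCRIPTORS:
            values[f"shape__{d}"] = shape[d]

    margin = 2 + 1  # Laws 5x5 half-width
    if "gabor" in bank.categories:
        margin += bank.max_kernel_radius
    if "glcm" in bank.categories:
        margin += max(bank.glcm_distances)
    rs, cs = _crop_slices(
        [rois.intratumoral, rois.peritumoral], stack.b0.shape, margin
    )

    for channel in CHANNELS:
        image = stack.channels[channel][rs, cs]
        for region in REGIONS:
            mask = rois.regions[region][rs, cs]
            if not mask.any():
                raise ValueError(f"empty {region} mask for channel {channel}")
            prefix = f"{channel}__{region}"
            try:
                continuous, params = normalize_continuous(image, mask)
                if "firstorder" in bank.categories:
                    for stat, v in pooled_statistics(continuous[mask]).items():
                        values[f"{prefix}__firstorder__{stat}"] = v
                if "glcm" in bank.categories:
                    quantized = quantize(continuous, params)
                    for name, v in glcm_features(quantized, mask, bank).items():
                        values[f"{prefix}__glcm__{name}"] = v
                if "laws" in bank.categories:
                    for name, v in laws_features(continuous, mask).items():
                        values[f"{prefix}__laws__{name}"] = v
                if "gabor" in bank.categories:
                    for name, v in gabor_features(continuous, mask, bank).items():
                        values[f"{prefix}__gabor__{name}"] = v
            except ValueError as exc:
                raise ValueError(f"[channel={channel}, region={region}] {exc}") from exc

    series = pd.Series(values).reindex(feature_names(bank))
    if series.isna().any():
        missing = series.index[series.isna()].tolist()[:5]
        raise RuntimeError(f"extraction left missing values, e.g. {missing}")
    return series


def extract_feature_vector(case, rois: RoiSet, bank: BankConfig = DEFAULT_BANK):
    """Extract the bank for one ``CaseRecord`` (uses ``case.images``)."""
    return extract_features(case.images, rois, bank)


# ---------------------------------------------------------------------------
# feature tables and z-scoring


@dataclass
class FeatureTable:
    """Cases x features matrix with its normalization state."""

    data: pd.DataFrame
    normalization_state: str = "raw"
    z_params: pd.DataFrame | None = field(default=None)

    @property
    def feature_names(self) -> list[str]:
        return list(self.data.columns)

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index_label="case_id")

    @classmethod
    def from_csv(cls, path) -> "FeatureTable":
        return cls(pd.read_csv(path, index_col="case_id"))


def zscore_fit_apply(
    train: FeatureTable, *others: FeatureTable
) -> tuple[list[FeatureTable], pd.DataFrame]:
    """Fit per-column mean/SD (population) on the training table, apply to all.

    Zero-variance columns pass through as 0 and are flagged in the returned
    parameter frame.  Column sets must agree across tables.
    """
    if train.data.empty:
        raise ValueError("empty training table")
    cols = list(train.data.columns)
    for other in others:
        if list(other.data.columns) != cols:
            raise ValueError("feature columns differ between tables")
    mean = train.data.mean(axis=0)
    sd = train.data.std(axis=0, ddof=0)
    degenerate = sd == 0.0
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} zero-variance feature columns pass through as 0",
            stacklevel=2,
        )
    safe_sd = sd.where(~degenerate, 1.0)
    z_params = pd.DataFrame({"mean": mean, "sd": sd, "degenerate": degenerate})

    out: list[FeatureTable] = []
    for table in (train, *others):
        z = (table.data - mean) / safe_sd
        z.loc[:, degenerate] = 0.0
        out.append(FeatureTable(z, normalization_state="z-scored", z_params=z_params))
    return out, z_params
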