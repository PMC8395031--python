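"""Synthetic phantom cohorts standing in for the patient population.

Each phantom case is a single mass-like lesion (random ellipse with a smooth
radial boundary perturbation) on a 256 x 256 grid with 340/256 mm pixel
spacing, rendered as a two-b-value DWI pair: the lesion is hyperintense on
b800 with a reduced apparent diffusion coefficient, embedded in a smoothly
varying fibroglandular background with Gaussian (clipped-at-zero, Rician
approximation) noise.  The class signal lives in lesion texture: a
band-limited random field whose high-frequency energy fraction is shifted in
positive cases by ``texture_effect``, with a weaker copy of the same effect
planted in a peritumoral band — so band-pass texture families (Laws, Gabor,
GLCM) carry the discrimination while lesion size and mean contrast stay
class-independent.  Clinical covariates (age stratum, ER, PR, Ki-67) are
drawn independently given the label from the study's class-conditional
marginal rates.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .imaging import ImageStack
from .segmentation import ring_radius_px

logger = logging.getLogger(__name__)

PIXEL_SPACING_DEFAULT = 340.0 / 256.0  # mm; 340-mm field of view on 256 px

# class-conditional rates of the "positive"/">=" category, (positive HER-2 2+,
# negative HER-2 2+); observed marginals of the 97/126 study population
CLINICAL_RATES_DEFAULT: dict[str, tuple[float, float]] = {
    "age_ge40": (80 / 97, 105 / 126),
    "er_positive": (58 / 97, 112 / 126),
    "pr_positive": (59 / 97, 105 / 126),
    "ki67_ge14": (80 / 97, 80 / 126),
}


@dataclass(frozen=True)
class PhantomConfig:
    """Generator parameters; defaults mirror the study conditions."""

    n_cases: int = 223
    positive_fraction: float = 97 / 223
    train_fraction: float = 167 / 223
    grid_size: int = 256
    pixel_spacing_mm: float = PIXEL_SPACING_DEFAULT
    lesion_area_range_mm2: tuple[float, float] = (195.0, 1512.0)
    lesion_area_median_mm2: float = 352.0
    texture_effect: float = 1.0
    noise_sigma: float = 10.0
    b800_contrast: float = 150.0
    peri_effect_scale: float = 0.5
    rician_exact: bool = False
    clinical_rates: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(CLINICAL_RATES_DEFAULT)
    )
    seed: int = 0

    # fixed tissue model (signal units / mm^2/s)
    background_b0: float = 600.0
    background_adc: float = 1.8e-3
    lesion_adc: float = 1.0e-3
    texture_fraction: float = 0.12  # lesion texture SD as fraction of mean b0
    ring_texture_width_mm: float = 6.0

    def validate(self) -> None:
        if self.n_cases <= 0:
            raise ValueError("n_cases must be a positive integer")
        if not 0.0 < self.positive_fraction < 1.0:
            raise ValueError("positive_fraction must lie in (0, 1)")
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must lie in (0, 1)")
        lo, hi = self.lesion_area_range_mm2
        if not (0 < lo <= hi):
            raise ValueError("lesion_area_range_mm2 must satisfy 0 < low <= high")
        if self.texture_effect < 0 or self.noise_sigma < 0:
            raise ValueError("texture_effect and noise_sigma must be nonnegative")
        for name, (p_pos, p_neg) in self.clinical_rates.items():
            for p in (p_pos, p_neg):
                if not 0.0 <= p <= 1.0:
                    raise ValueError(f"clinical rate {name} outside [0, 1]: {p}")
        # geometry: the largest lesion (with boundary wobble) plus the 4-mm
        # analysis ring must fit the grid with a safety margin
        max_r_px = np.sqrt(hi / np.pi) / self.pixel_spacing_mm * (1 + RADIAL_WOBBLE)
        ring_px = ring_radius_px(4.0, self.pixel_spacing_mm)
        if 2 * (max_r_px + ring_px + 4) > self.grid_size:
            raise ValueError(
                "grid too small: the largest lesion plus the peritumoral ring "
                "does not fit"
            )


RADIAL_WOBBLE = 0.10  # relative amplitude of the lesion boundary perturbation


@dataclass
class ClinicalFactors:
    """The four categorical covariates, with the study's category labels."""

    age_group: str  # {<40, >=40}
    er: str  # {negative, positive}
    pr: str  # {negative, positive}
    ki67: str  # {<14%, >=14%}

    def as_dict(self) -> dict[str, str]:
        return {
            "age_group": self.age_group,
            "er": self.er,
            "pr": self.pr,
            "ki67": self.ki67,
        }


@dataclass
class CaseRecord:
    """One phantom (or loaded) case."""

    case_id: str
    label: int  # 1 = positive HER-2 2+ (FISH), 0 = negative
    cohort: str  # {training, validation}
    images: ImageStack
    clinical: ClinicalFactors
    truth_mask: np.ndarray | None = None


# ---------------------------------------------------------------------------
# clinical covariates


def sample_clinical_factors(
    label: int,
    clinical_rates: dict[str, tuple[float, float]],
    rng: np.random.Generator,
) -> ClinicalFactors:
    """Draw the four covariates independently from class-conditional rates."""
    col = 0 if label == 1 else 1
    rates = {}
    for name, pair in clinical_rates.items():
        p = pair[col]
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"clinical rate {name} outside [0, 1]: {p}")
        rates[name] = rng.random() < p
    return ClinicalFactors(
        age_group=">=40" if rates["age_ge40"] else "<40",
        er="positive" if rates["er_positive"] else "negative",
        pr="positive" if rates["pr_positive"] else "negative",
        ki67=">=14%" if rates["ki67_ge14"] else "<14%",
    )


# ---------------------------------------------------------------------------
# lesion geometry and rendering


def _smooth_field(shape, rng, sigma):
    """Unit-variance Gaussian-smoothed white-noise field."""
    white = rng.standard_normal(shape)
    smooth = ndimage.gaussian_filter(white, sigma, mode="wrap")
    return smooth / smooth.std()


def _band_field(shape, rng):
    """Band-pass (difference-of-Gaussians) unit-variance field."""
    white = rng.standard_normal(shape)
    band = ndimage.gaussian_filter(white, 0.8, mode="wrap") - ndimage.gaussian_filter(
        white, 1.6, mode="wrap"
    )
    return band / band.std()


def _sample_lesion_area(config: PhantomConfig, rng) -> float:
    """Right-skewed area draw (log-normal around the study median, truncated)."""
    lo, hi = config.lesion_area_range_mm2
    median = min(max(config.lesion_area_median_mm2, lo), hi)
    for _ in range(100):
        area = median * np.exp(rng.normal(0.0, 0.55))
        if lo <= area <= hi:
            return float(area)
    return float(median)


def _lesion_mask(config: PhantomConfig, rng) -> np.ndarray:
    """Ellipse with a smooth low-harmonic radial boundary perturbation."""
    n = config.grid_size
    area_px = _sample_lesion_area(config, rng) / config.pixel_spacing_mm**2
    ratio = rng.uniform(0.6, 1.0)  # minor/major semi-axis ratio
    a = np.sqrt(area_px / (np.pi * ratio))  # major semi-axis, px
    b = a * ratio
    phi0 = rng.uniform(0.0, np.pi)
    max_extent = a * (1 + RADIAL_WOBBLE)
    margin = max_extent + ring_radius_px(4.0, config.pixel_spacing_mm) + 4
    jitter = max(0.0, n / 2 - margin)
    cy = n / 2 + rng.uniform(-jitter, jitter) * 0.3
    cx = n / 2 + rng.uniform(-jitter, jitter) * 0.3

    # radial wobble: few low harmonics with random phases
    harmonics = rng.integers(3, 7)
    amps = rng.uniform(0.0, RADIAL_WOBBLE / 2, size=harmonics)
    phases = rng.uniform(0.0, 2 * np.pi, size=harmonics)

    yy, xx = np.mgrid[0:n, 0:n].astype(float)
    dy, dx = yy - cy, xx - cx
    theta = np.arctan2(dy, dx)
    r = np.hypot(dy, dx)
    phi = theta - phi0
    r_ellipse = (a * b) / np.sqrt((b * np.cos(phi)) ** 2 + (a * np.sin(phi)) ** 2)
    wobble = np.zeros_like(theta)
    for k in range(harmonics):
        wobble += amps[k] * np.cos((k + 2) * theta + phases[k])
    boundary = r_ellipse * (1.0 + wobble)
    mask = r <= boundary
    # the wobble cannot disconnect a star-shaped region, but guard anyway
    labels, n_comp = ndimage.label(mask, structure=np.ones((3, 3)))
    if n_comp > 1:
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, range(1, n_comp + 1))
        mask = labels == (int(np.argmax(sizes)) + 1)
    return mask


def render_case(
    label: int, config: PhantomConfig, rng: np.random.Generator
) -> tuple[ImageStack, np.ndarray]:
    """Render one case's image pair and ground-truth lesion mask.

    The high-frequency energy fraction of the lesion (and, at half strength,
    peritumoral) texture field is w = 0.3 + 0.2 * texture_effect for positive
    cases and 0.3 for negative cases; total texture variance is held fixed so
    that per-ROI normalization cannot remove the class signal.
    """
    if label not in (0, 1):
        raise ValueError("label must be 0 or 1")
    config.validate()
    n = config.grid_size
    mask = _lesion_mask(config, rng)

    # spectral mixing weight (high-band energy fraction)
    w = np.clip(0.3 + 0.2 * config.texture_effect * label, 0.0, 0.9)
    low = _smooth_field((n, n), rng, 3.0)
    high = _band_field((n, n), rng)
    texture = np.sqrt(1.0 - w) * low + np.sqrt(w) * high
    adc_texture = np.sqrt(1.0 - w) * _smooth_field((n, n), rng, 3.0) + np.sqrt(
        w
    ) * _band_field((n, n), rng)

    # amplitude profile: full inside the lesion, reduced in a peritumoral band
    ring_px = ring_radius_px(config.ring_texture_width_mm, config.pixel_spacing_mm)
    near = (ndimage.distance_transform_edt(~mask) <= ring_px) & ~mask
    amp = np.zeros((n, n))
    amp[mask] = 1.0
    amp[near] = config.peri_effect_scale

    # tissue model
    b = 800.0
    bg_b800_mean = config.background_b0 * np.exp(-b * config.background_adc)
    lesion_b800_mean = bg_b800_mean + config.b800_contrast
    lesion_b0_mean = lesion_b800_mean * np.exp(b * config.lesion_adc)

    b0 = config.background_b0 * (1.0 + 0.05 * _smooth_field((n, n), rng, 8.0))
    adc = config.background_adc * (1.0 + 0.05 * _smooth_field((n, n), rng, 8.0))
    b0[mask] = lesion_b0_mean
    adc[mask] = config.lesion_adc
    b0 = b0 * (1.0 + config.texture_fraction * texture * amp)
    adc = adc * (1.0 + 0.10 * adc_texture * amp)
    adc = np.clip(adc, 1e-5, None)
    b800 = b0 * np.exp(-b * adc)

    if config.rician_exact:
        s = config.noise_sigma
        b0 = np.hypot(b0 + rng.normal(0, s, (n, n)), rng.normal(0, s, (n, n)))
        b800 = np.hypot(b800 + rng.normal(0, s, (n, n)), rng.normal(0, s, (n, n)))
    elif config.noise_sigma > 0:
        b0 = np.clip(b0 + rng.normal(0, config.noise_sigma, (n, n)), 0, None)
        b800 = np.clip(b800 + rng.normal(0, config.noise_sigma, (n, n)), 0, None)

    stack = ImageStack(b0=b0, b800=b800, pixel_spacing_mm=config.pixel_spacing_mm)
    return stack, mask


# ---------------------------------------------------------------------------
# cohort


def generate_cohort(config: PhantomConfig) -> list[CaseRecord]:
    """Generate the full phantom cohort, deterministically from the seed.

    Exactly round(n * positive_fraction) positive labels are assigned
    (sampling without replacement); cases are then split by index after a
    deterministic shuffle, the first round(n * train_fraction) forming the
    training cohort.
    """
    config.validate()
    n = config.n_cases
    n_pos = int(round(n * config.positive_fraction))
    n_train = int(round(n * config.train_fraction))

    root = np.random.SeedSequence(
        [config.seed & 0x7FFFFFFF, 0x9E3779B9]
    )
    order_rng = np.random.default_rng(root.spawn(1)[0])
    labels = np.array([1] * n_pos + [0] * (n - n_pos))
    labels = labels[order_rng.permutation(n)]

    case_seeds = root.spawn(n + 1)[1:]
    cases: list[CaseRecord] = []
    for i in range(n):
        rng = np.random.default_rng(case_seeds[i])
        stack, mask = render_case(int(labels[i]), config, rng)
        clinical = sample_clinical_factors(int(labels[i]), config.clinical_rates, rng)
        cases.append(
            CaseRecord(
                case_id=f"case{i:04d}",
                label=int(labels[i]),
                cohort="training" if i < n_train else "validation",
                images=stack,
                clinical=clinical,
                truth_mask=mask,
            )
        )
    return cases


def cohort_frame(cases: list[CaseRecord]) -> pd.DataFrame:
    """Clinical/label/cohort table (one row per case)."""
    rows = []
    for c in cases:
        row = {"case_id": c.case_id, "label": c.label, "cohort": c.cohort}
        row.update(c.clinical.as_dict())
        rows.append(row)
    return pd.DataFrame(rows).set_index("case_id")


# ---------------------------------------------------------------------------
# mask perturbation (second-reader emulation)


def perturb_mask(
    mask: np.ndarray, magnitude: float, rng: np.random.Generator
) -> np.ndarray:
    """Locally dilate/erode the boundary by up to ``magnitude`` pixels.

    A smooth random field modulates the signed distance threshold, so the
    boundary moves in and out by at most ``magnitude`` px.  Magnitudes that
    would swallow the mask are clamped (with a warning) rather than raised,
    and the largest connected component of a nonempty result is returned;
    an empty result falls back to the input.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    if magnitude == 0:
        return mask.copy()
    inside = ndimage.distance_transform_edt(mask)
    max_inside = float(inside.max())
    if magnitude >= max_inside:
        warnings.warn(
            f"perturbation magnitude {magnitude} >= mask radius {max_inside:.1f}; "
            "clamping",
            stacklevel=2,
        )
        magnitude = max(max_inside - 1.0, 0.5)
    signed = ndimage.distance_transform_edt(~mask) - inside
    eta = _smooth_field(mask.shape, rng, 4.0)
    eta = np.clip(eta / 2.0, -1.0, 1.0)  # ~2 sigma covers [-1, 1]
    out = signed <= magnitude * eta
    labels, n_comp = ndimage.label(out, structure=np.ones((3, 3)))
    if n_comp == 0:
        warnings.warn("perturbation emptied the mask; returning input", stacklevel=2)
        return mask.copy()
    if n_comp > 1:
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, range(1, n_comp + 1))
        out = labels == (int(np.argmax(sizes)) + 1)
    return out


def with_seed(config: PhantomConfig, seed: int) -> PhantomConfig:
    """Copy of the config with a different seed."""
    return replace(config, seed=seed)
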