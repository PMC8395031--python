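"""NIfTI / CSV persistence for cases, masks and tables.

Images are written as 2D NIfTI volumes whose affine encodes the in-plane
pixel spacing; masks use integer codes (0 = background, 1 = intratumoral,
2 = peritumoral on combined ROI volumes).  Coordinate convention throughout:
row-major arrays, 0-based indices.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .imaging import ImageStack
from .phantom import CaseRecord, ClinicalFactors
from .segmentation import RoiSet

CLINICAL_VOCABULARY = {
    "age_group": {"<40", ">=40"},
    "er": {"negative", "positive"},
    "pr": {"negative", "positive"},
    "ki67": {"<14%", ">=14%"},
}


def _affine(spacing_mm: float) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0] = aff[1, 1] = spacing_mm
    return aff


def write_image(path: Path, array: np.ndarray, spacing_mm: float) -> None:
    img = nib.Nifti1Image(np.asarray(array, dtype=np.float64), _affine(spacing_mm))
    nib.save(img, str(path))


def write_mask(path: Path, mask: np.ndarray, spacing_mm: float) -> None:
    img = nib.Nifti1Image(np.asarray(mask, dtype=np.int16), _affine(spacing_mm))
    nib.save(img, str(path))


def read_image(path: Path) -> tuple[np.ndarray, float]:
    """Return the array and its in-plane pixel spacing from the affine."""
    img = nib.load(str(path))
    spacing = float(img.affine[0, 0])
    if spacing <= 0:
        raise ValueError(f"{path}: missing or non-positive pixel spacing in header")
    return np.asarray(img.get_fdata(), dtype=float), spacing


def write_case(case: CaseRecord, outdir: Path, rois: RoiSet | None = None) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    s = case.images.pixel_spacing_mm
    write_image(outdir / f"{case.case_id}_b0.nii.gz", case.images.b0, s)
    write_image(outdir / f"{case.case_id}_b800.nii.gz", case.images.b800, s)
    if case.images.adc is not None:
        write_image(outdir / f"{case.case_id}_adc.nii.gz", case.images.adc, s)
    if case.truth_mask is not None:
        write_mask(outdir / f"{case.case_id}_truth.nii.gz", case.truth_mask, s)
    if rois is not None:
        combined = rois.intratumoral.astype(np.int16) + 2 * rois.peritumoral.astype(
            np.int16
        )
        write_mask(outdir / f"{case.case_id}_rois.nii.gz", combined, s)


def read_case_inputs(
    case_id: str,
    image_dir: Path,
    clinical_row: pd.Series,
    b_low: float = 0.0,
    b_high: float = 800.0,
) -> CaseRecord:
    """Load a real-images-mode case: NIfTI channels plus one clinical row."""
    image_dir = Path(image_dir)
    paths = {c: image_dir / f"{case_id}_{c}.nii.gz" for c in ("b0", "b800")}
    for channel, path in paths.items():
        if not path.exists():
            raise FileNotFoundError(f"case {case_id}: missing {channel} image {path}")
    b0, spacing0 = read_image(paths["b0"])
    b800, spacing1 = read_image(paths["b800"])
    if abs(spacing0 - spacing1) > 1e-9:
        raise ValueError(f"case {case_id}: channel pixel spacings differ")

    values = {}
    for key, vocab in CLINICAL_VOCABULARY.items():
        value = str(clinical_row[key])
        if value not in vocab:
            raise ValueError(
                f"case {case_id}: clinical value {key}={value!r} outside {sorted(vocab)}"
            )
        values[key] = value
    label = int(clinical_row["label"])
    if label not in (0, 1):
        raise ValueError(f"case {case_id}: label must be 0/1")

    truth = None
    truth_path = image_dir / f"{case_id}_truth.nii.gz"
    if truth_path.exists():
        truth = read_image(truth_path)[0] > 0.5

    return CaseRecord(
        case_id=case_id,
        label=label,
        cohort=str(clinical_row.get("cohort", "training")),
        images=ImageStack(
            b0=b0, b800=b800, pixel_spacing_mm=spacing0, b_low=b_low, b_high=b_high
        ),
        clinical=ClinicalFactors(
            age_group=values["age_group"],
            er=values["er"],
            pr=values["pr"],
            ki67=values["ki67"],
        ),
        truth_mask=truth,
    )
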