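"""Image, displacement-field, and manifest I/O.

Mammograms travel as 16-bit grayscale PNG/TIFF (optionally DICOM for
clinical inputs); displacement fields as 32-bit float two-channel TIFF;
cohort manifests as CSV.  Readers never rescale pixel data implicitly —
normalisation to [0, 1] is an explicit preprocessing step.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "MammogramImage",
    "read_mammogram",
    "write_mammogram",
    "write_difference_image",
    "read_difference_image",
    "write_field",
    "read_field",
    "read_manifest",
    "write_manifest",
]

U16_MAX = 65535


@dataclass(frozen=True)
class MammogramImage:
    """A 2-D grayscale mammogram with acquisition metadata.

    ``pixels`` is either an unsigned-integer array as stored on disk or a
    float array on the [0, 1] scale; ``laterality`` is ``"L"`` or ``"R"``.
    """

    pixels: np.ndarray
    laterality: str
    view: str = "MLO"
    pixel_pitch_um: float = 85.0
    thickness_mm: Optional[float] = None

    def __post_init__(self):
        if self.laterality not in ("L", "R"):
            raise ValueError(f"laterality must be 'L' or 'R', got {self.laterality!r}")
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValueError("pixels must be a 2-D grayscale array")
        if np.issubdtype(px.dtype, np.floating) and not np.all(np.isfinite(px)):
            raise ValueError("pixels contain non-finite values")


def read_mammogram(path, laterality: str, **metadata) -> MammogramImage:
    """Read a 16-bit PNG/TIFF (or DICOM) mammogram, preserving raw values."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"mammogram not found: {path}")
    suffix = path.suffix.lower()
    if suffix in (".dcm", ".dicom"):
        try:
            import pydicom
        except ImportError as e:  # pragma: no cover
            raise ImportError("DICOM input requires pydicom") from e
        px = pydicom.dcmread(path).pixel_array
    elif suffix in (".tif", ".tiff"):
        px = tifffile.imread(path)
    else:
        px = iio.imread(path)
    px = np.asarray(px)
    if px.ndim == 3 and px.shape[2] == 1:
        px = px[:, :, 0]
    if px.ndim != 2:
        raise ValueError(f"{path}: expected grayscale, got shape {px.shape}")
    if px.dtype not in (np.uint8, np.uint16) and not np.issubdtype(
        px.dtype, np.floating
    ):
        raise ValueError(f"{path}: unsupported bit depth {px.dtype}")
    return MammogramImage(pixels=px, laterality=laterality, **metadata)


def write_mammogram(image: MammogramImage, path) -> None:
    """Write as 16-bit PNG; float [0, 1] images are scaled by 65535."""
    px = np.asarray(image.pixels)
    if np.issubdtype(px.dtype, np.floating):
        if px.min() < 0 or px.max() > 1:
            raise ValueError("float pixels must lie in [0, 1] for 16-bit output")
        px = np.round(px * U16_MAX).astype(np.uint16)
    elif px.dtype == np.uint8:
        px = px.astype(np.uint16) * 257
    iio.imwrite(Path(path), px.astype(np.uint16))


def write_difference_image(diff: np.ndarray, path) -> None:
    """Write an absolute-difference image as 16-bit PNG.

    A fixed linear [0, 1] -> [0, 65535] scaling is used so files from
    different cases are directly comparable.
    """
    diff = np.asarray(diff)
    if not np.all(np.isfinite(diff)):
        raise ValueError("difference image contains non-finite values")
    if diff.min() < 0 or diff.max() > 1:
        raise ValueError("difference image values must lie in [0, 1]")
    iio.imwrite(Path(path), np.round(diff * U16_MAX).astype(np.uint16))


def read_difference_image(path) -> np.ndarray:
    """Invert :func:`write_difference_image`; exact to 1/65535 per pixel."""
    return iio.imread(Path(path)).astype(np.float64) / U16_MAX


def write_field(field: np.ndarray, path) -> None:
    """Persist a displacement field as 32-bit float two-channel TIFF."""
    field = np.asarray(field, dtype=np.float32)
    if field.ndim != 3 or field.shape[0] != 2:
        raise ValueError(
            f"displacement field must have shape (2, H, W), got {field.shape}"
        )
    tifffile.imwrite(Path(path), field)


def read_field(path) -> np.ndarray:
    field = tifffile.imread(Path(path))
    if field.ndim != 3 or field.shape[0] != 2:
        raise ValueError(f"{path}: not a two-channel displacement field")
    return field.astype(np.float32)


def write_mask(mask: np.ndarray, path) -> None:
    iio.imwrite(Path(path), (np.asarray(mask, dtype=bool) * 255).astype(np.uint8))


def read_mask(path) -> np.ndarray:
    return iio.imread(Path(path)) > 127


def read_manifest(path) -> pd.DataFrame:
    """Load a cohort manifest CSV and validate its contract."""
    df = pd.read_csv(path)
    required = {"case_id", "right_path", "left_path"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    if df["case_id"].duplicated().any():
        dupes = df.loc[df["case_id"].duplicated(), "case_id"].tolist()
        raise ValueError(f"duplicate case ids in manifest: {dupes}")
    if df[["right_path", "left_path"]].isna().any().any():
        raise ValueError("manifest rows must provide both image paths")
    return df


def write_manifest(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)
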