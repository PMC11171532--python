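"""Preprocessing: normalisation, skin-line mask, and the geometric chain.

Raw mammograms are normalised by the full bit-depth range (not per-image
min/max, so bilateral pairs stay on a common scale), the breast +
pectoralis region is segmented from the skin line, and each image is
padded on the nipple side to a square, resized with bicubic (4x4
neighbourhood) interpolation and centre-cropped to the registration
size.  The clinical protocol goes 2016x2816 -> pad -> 520x520 -> 512x512;
the same 520:512 ratio is kept for other working sizes (e.g. 130 -> 128
for desk-scale phantoms).

Coordinate convention: row-major, 0-based; after flipping, the chest
wall of both breasts lies at column 0 and the nipple side is the highest
column.  Padding uses the background value 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import filters, morphology, transform

from .image_io import MammogramImage

__all__ = [
    "RegistrationPair",
    "normalize_intensity",
    "detect_breast_mask",
    "preprocess_single",
    "preprocess_pair",
]


@dataclass
class RegistrationPair:
    """A registration-ready pair: fixed right breast, flipped left breast.

    All three arrays share the same square shape; intensities lie in
    [0, 1]; ``mask`` is the fixed-image breast + pectoral region, the
    support of both the training loss and the SAD evaluation.
    """

    fixed: np.ndarray
    flipped: np.ndarray
    mask: np.ndarray
    case_id: str = ""

    def __post_init__(self):
        if not (self.fixed.shape == self.flipped.shape == self.mask.shape):
            raise ValueError("fixed, flipped and mask must share one shape")


def normalize_intensity(image: MammogramImage) -> MammogramImage:
    """Scale pixels to [0, 1] by the full bit-depth range.

    uint16 divides by 65535, uint8 by 255.  Float input already in
    [0, 1] passes through unchanged; negative values are rejected.
    """
    px = np.asarray(image.pixels)
    if np.issubdtype(px.dtype, np.floating):
        if px.min() < 0:
            raise ValueError("negative intensities cannot be normalized")
        if px.max() > 1.0:
            out = px.astype(np.float32) / 65535.0
        else:
            out = px.astype(np.float32)
    elif px.dtype == np.uint16:
        out = px.astype(np.float32) / 65535.0
    elif px.dtype == np.uint8:
        out = px.astype(np.float32) / 255.0
    else:
        raise ValueError(f"unsupported dtype {px.dtype}")
    import dataclasses

    return dataclasses.replace(image, pixels=out)


def detect_breast_mask(image: MammogramImage) -> np.ndarray:
    """Segment breast + pectoralis major from the skin line.

    Otsu threshold on the intensity histogram, largest connected
    component, hole filling, and a light morphological closing.  Raises
    when no foreground brighter than the background exists.
    """
    px = np.asarray(image.pixels, dtype=np.float64)
    if px.max() <= px.min():
        raise ValueError("no breast detected: image is constant")
    # Otsu separates tissue from air; the skin line itself is much
    # fainter than the tissue mode, so relax the cut toward background
    # to keep the outer falloff inside the mask.
    thr = 0.4 * filters.threshold_otsu(px)
    fg = px > thr
    if not fg.any():
        raise ValueError("no breast detected: empty foreground")
    labels, n = ndimage.label(fg)
    if n == 0:
        raise ValueError("no breast detected: empty foreground")
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, range(1, n + 1))
    mask = labels == (1 + int(np.argmax(sizes)))
    mask = ndimage.binary_fill_holes(mask)
    # pad-replicate so closing does not erode tissue touching the frame
    pad = 3
    padded = np.pad(mask, pad, mode="edge")
    padded = ndimage.binary_closing(padded, structure=morphology.disk(2))
    mask = padded[pad:-pad, pad:-pad]
    mask = ndimage.binary_fill_holes(mask)
    # closing may merge satellites; keep the largest component only
    labels, n = ndimage.label(mask)
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, range(1, n + 1))
        mask = labels == (1 + int(np.argmax(sizes)))
    return mask


def _pad_to_square(arr: np.ndarray, nipple_side: str, value=0.0) -> np.ndarray:
    h, w = arr.shape
    if w > h:
        raise ValueError(
            f"unexpected MLO orientation: image wider ({w}) than tall ({h})"
        )
    pad = h - w
    if pad == 0:
        return arr
    if nipple_side == "right":
        return np.pad(arr, ((0, 0), (0, pad)), constant_values=value)
    return np.pad(arr, ((0, 0), (pad, 0)), constant_values=value)


def preprocess_single(
    image: np.ndarray,
    mask: np.ndarray,
    crop_to: int = 512,
    nipple_side: str = "right",
):
    """Pad (nipple side) -> bicubic resize -> centre crop; mask follows.

    ``crop_to`` is the registration size; the intermediate resize target
    keeps the clinical 520:512 ratio.  The mask travels through the same
    geometric chain with nearest-neighbour resampling and is
    re-binarised, so its pixels stay exactly 0 or 1.
    """
    resize_to = round(crop_to * 520 / 512)
    img_sq = _pad_to_square(np.asarray(image, dtype=np.float32), nipple_side)
    mask_sq = _pad_to_square(np.asarray(mask, dtype=np.float32), nipple_side)
    img_rs = transform.resize(
        img_sq, (resize_to, resize_to), order=3, anti_aliasing=False,
        preserve_range=True,
    )
    mask_rs = transform.resize(
        mask_sq, (resize_to, resize_to), order=0, anti_aliasing=False,
        preserve_range=True,
    )
    off = (resize_to - crop_to) // 2
    img_out = np.clip(img_rs[off : off + crop_to, off : off + crop_to], 0.0, 1.0)
    mask_out = mask_rs[off : off + crop_to, off : off + crop_to] > 0.5
    return img_out.astype(np.float32), mask_out


def preprocess_pair(
    right: MammogramImage,
    left: MammogramImage,
    crop_to: int = 512,
    case_id: str = "",
) -> RegistrationPair:
    """Build the fixed/flipped registration pair from a bilateral case.

    The left image is mirrored about the vertical axis so both chest
    walls land at column 0, then both sides run through the same
    normalise/segment/pad/resize/crop chain.  The pair mask is the
    fixed-image mask.
    """
    if right.laterality == left.laterality:
        raise ValueError(
            f"need opposite lateralities, got {right.laterality!r} twice"
        )
    if right.laterality != "R":
        right, left = left, right
    right_n = normalize_intensity(right)
    left_n = normalize_intensity(left)
    right_mask = detect_breast_mask(right_n)
    flipped_px = left_n.pixels[:, ::-1]
    flipped_mask = detect_breast_mask(
        MammogramImage(pixels=flipped_px, laterality="L")
    )
    fixed, mask = preprocess_single(right_n.pixels, right_mask, crop_to)
    flipped, _ = preprocess_single(flipped_px, flipped_mask, crop_to)
    return RegistrationPair(fixed=fixed, flipped=flipped, mask=mask, case_id=case_id)
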