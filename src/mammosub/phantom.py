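"""Synthetic bilateral MLO phantom generator.

Clinical bilateral mammogram pairs are not redistributable, so every
downstream stage is exercised on synthetic phantoms that reproduce the
qualitative structure of an MLO view: chest wall flush with one vertical
image edge, a semi-elliptical breast contour with a smooth skin-line
falloff, a triangular pectoral wedge in the upper posterior corner, and
scattered glandular texture of controllable coverage.  The left breast
is the mirror of the right warped by a known smooth random displacement
field, so registration accuracy can be scored against ground truth.

Covariates mirror the clinical ones: breast area as a percentage of the
image, mammary-gland content ratio (glandular coverage of the breast
area), and compressed breast thickness, which acts as a global
brightness/attenuation proxy.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import ndimage

from .image_io import MammogramImage

__all__ = [
    "PhantomSpec",
    "PhantomCase",
    "smooth_random_field",
    "generate_bilateral_case",
    "generate_cohort",
    "insert_lesion",
    "TABLE1_TEST_RANGES",
]

#: Test-cohort covariate spans of the clinical study used as sampling
#: defaults: breast area %, gland content ratio %, compressed thickness mm.
TABLE1_TEST_RANGES = {
    "breast_area_pct": (11.1, 79.8),
    "density_pct": (11.5, 85.0),
    "thickness_mm": (12.0, 84.0),
}


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic bilateral case.

    ``deform_magnitude`` is the RMS displacement (px) of the bilateral
    asymmetry field; ``deform_correlation_length`` its smoothness scale.
    ``thickness_mm`` maps monotonically to global tissue brightness.
    """

    image_height: int = 512
    image_width: int = 512
    breast_area_fraction: float = 0.35
    density_fraction: float = 0.44
    thickness_mm: float = 45.0
    deform_magnitude: float = 3.0
    deform_correlation_length: float = 256.0
    texture_blob_count: int = 60
    noise_sd: float = 0.01
    seed: int = 0

    def __post_init__(self):
        if self.image_height <= 0 or self.image_width <= 0:
            raise ValueError("image dimensions must be positive")
        for name in ("breast_area_fraction", "density_fraction"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name} must lie strictly in (0, 1), got {v}")
        if self.deform_magnitude < 0:
            raise ValueError("deform_magnitude must be >= 0")
        if self.deform_correlation_length <= 0:
            raise ValueError("deform_correlation_length must be > 0")
        if self.texture_blob_count < 0:
            raise ValueError("texture_blob_count must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class PhantomCase:
    """A bilateral pair with ground truth.

    ``true_field`` maps the flipped-left pixel grid onto the right image:
    warping the flipped left image by it reproduces the right image (up
    to interpolation and noise).
    """

    case_id: str
    right_image: MammogramImage
    left_image: MammogramImage
    true_field: np.ndarray  # (2, H, W), px
    right_mask: np.ndarray  # bool
    left_mask: np.ndarray  # bool
    breast_area_pct: float
    density_pct: float
    thickness_mm: float
    lesion_descriptor: Optional[tuple] = None


def smooth_random_field(
    shape, magnitude: float, correlation_length: float, seed: int
) -> np.ndarray:
    """Zero-mean smooth random displacement field with a target RMS norm.

    Gaussian-smoothed white noise, mean-centred per component and scaled
    so the empirical root-mean-square displacement magnitude equals
    ``magnitude`` px.  Returns a ``(2, H, W)`` float32 array.
    """
    h, w = int(shape[0]), int(shape[1])
    if h <= 0 or w <= 0:
        raise ValueError(f"field shape must be positive, got {shape}")
    if magnitude < 0:
        raise ValueError("magnitude must be >= 0")
    if correlation_length <= 0:
        raise ValueError("correlation_length must be > 0")
    if magnitude == 0:
        return np.zeros((2, h, w), dtype=np.float32)
    rng = np.random.default_rng(seed)
    field = rng.standard_normal((2, h, w))
    sigma = correlation_length / 2.0
    for k in range(2):
        field[k] = ndimage.gaussian_filter(field[k], sigma, mode="reflect")
        field[k] -= field[k].mean()
    rms = np.sqrt((field**2).sum(axis=0).mean())
    field *= magnitude / max(rms, 1e-12)
    return field.astype(np.float32)


def _warp_numpy(img: np.ndarray, field: np.ndarray) -> np.ndarray:
    """Bilinear resample of a 2-D array at grid + field, border clamp."""
    h, w = img.shape
    gr, gc = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    coords = np.stack([gr + field[0], gc + field[1]])
    return ndimage.map_coordinates(img, coords, order=1, mode="nearest").astype(
        img.dtype
    )


def _invert_field(field: np.ndarray, n_iter: int = 8) -> np.ndarray:
    """Fixed-point approximate inverse: v(y) = -u(y + v(y))."""
    v = np.zeros_like(field)
    for _ in range(n_iter):
        v = np.stack(
            [-_warp_numpy(field[0], v), -_warp_numpy(field[1], v)]
        )
    return v


def _breast_geometry(spec: PhantomSpec):
    """Solve the contour scale so mask area matches the requested fraction."""
    h, w = spec.image_height, spec.image_width
    rows = np.arange(h, dtype=np.float64)[:, None]
    cols = np.arange(w, dtype=np.float64)[None, :]
    center_row = 0.45 * h
    a0, b0 = 0.40 * h, 0.55 * w

    def mask_at(s):
        # keep the nipple-side skin line inside the frame: the vertical
        # extent may clip (tall breasts) but the horizontal may not
        a, b = s * a0, min(s * b0, 0.95 * w)
        ellipse = (cols / b) ** 2 + ((rows - center_row) / a) ** 2 <= 1.0
        wt, rb = 0.45 * b, min(0.9 * center_row + a * 0.2, 0.65 * h)
        wedge = (rows < rb) & (cols < wt * (1.0 - rows / rb))
        return ellipse | wedge

    target = spec.breast_area_fraction
    lo, hi = 0.02, 6.0
    if mask_at(hi).mean() < target:
        raise ValueError(
            f"breast_area_fraction {target} is not attainable for a "
            f"{h}x{w} image"
        )
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if mask_at(mid).mean() < target:
            lo = mid
        else:
            hi = mid
    return mask_at(hi)


def _glandular_texture(spec: PhantomSpec, mask: np.ndarray, rng) -> np.ndarray:
    """Blob texture field, normalised to [0, 1]; zero with no blobs."""
    h, w = mask.shape
    scale = min(h, w)
    tex = np.zeros((h, w), dtype=np.float64)
    if spec.texture_blob_count == 0:
        return tex
    # bias blob centres toward the interior so the gland stays scattered
    # inside the breast rather than hugging the skin line
    dist = ndimage.distance_transform_edt(mask)
    interior = np.argwhere(dist > 0.06 * scale)
    if len(interior) == 0:
        interior = np.argwhere(mask)
    rr, cc = np.mgrid[0:h, 0:w]
    for _ in range(spec.texture_blob_count):
        cy, cx = interior[rng.integers(len(interior))]
        sig = rng.uniform(0.02, 0.05) * scale
        amp = rng.uniform(0.4, 1.0)
        d2 = (rr - cy) ** 2 + (cc - cx) ** 2
        local = d2 < (4 * sig) ** 2
        tex[local] += amp * np.exp(-d2[local] / (2 * sig**2))
    tmax = tex.max()
    if tmax > 0:
        tex /= tmax
    return tex


def _compose_right(spec: PhantomSpec, mask: np.ndarray, rng):
    """Render the right-breast image; returns (image, gland_mask)."""
    h, w = mask.shape
    scale = min(h, w)
    edge_w = max(2.0, 0.012 * scale)
    dist = ndimage.distance_transform_edt(mask)
    falloff = np.clip(dist / edge_w, 0.0, 1.0)

    base = np.clip(0.30 + 0.004 * spec.thickness_mm, 0.0, 0.62)
    img = base * falloff

    # pectoral wedge: re-derive as the bright upper-posterior triangle
    rows = np.arange(h)[:, None]
    cols = np.arange(w)[None, :]
    rb = 0.55 * h
    wt = 0.30 * w
    wedge = (rows < rb) & (cols < wt * (1.0 - rows / rb)) & mask
    wedge_soft = ndimage.gaussian_filter(wedge.astype(np.float64), 0.01 * scale + 1)
    img += 0.20 * wedge_soft * falloff

    tex = _glandular_texture(spec, mask, rng)
    vals = tex[mask]
    if vals.size and vals.max() > 0:
        thr = np.quantile(vals, 1.0 - spec.density_fraction)
        gland = (tex >= thr) & mask & (tex > 0)
    else:
        gland = np.zeros_like(mask)
    img += 0.28 * tex * gland * falloff
    img = np.clip(img, 0.0, 0.98)
    return img, gland


def generate_bilateral_case(spec: PhantomSpec, case_id: str = "case") -> PhantomCase:
    """Build one bilateral pair with known asymmetry.

    The right image is constructed from contour + pectoral wedge +
    glandular blobs + skin-line falloff; the left image is its mirror
    warped by a smooth random field (plus texture perturbation and noise
    when ``noise_sd > 0``).  With ``deform_magnitude == 0`` and
    ``noise_sd == 0`` the flipped left image equals the right image
    bit-for-bit.
    """
    rng = np.random.default_rng(spec.seed)
    mask = _breast_geometry(spec)
    right, gland = _compose_right(spec, mask, rng)
    h, w = right.shape

    field_seed = int(rng.integers(0, 2**31 - 1))
    true_field = smooth_random_field(
        (h, w), spec.deform_magnitude, spec.deform_correlation_length, field_seed
    )

    if spec.deform_magnitude > 0:
        inv = _invert_field(true_field)
        left_flipped = _warp_numpy(right, inv)
        left_mask = _warp_numpy(mask.astype(np.float64), inv) > 0.5
    else:
        left_flipped = right.copy()
        left_mask = mask.copy()

    if spec.noise_sd > 0:
        # independent low-frequency texture perturbation on the left side,
        # then white noise on both sides
        pert = ndimage.gaussian_filter(
            rng.standard_normal((h, w)), 0.02 * min(h, w) + 1
        )
        pert /= max(np.abs(pert).max(), 1e-12)
        left_flipped = left_flipped + 3.0 * spec.noise_sd * pert * left_mask
        right = right + rng.normal(0.0, spec.noise_sd, (h, w))
        left_flipped = left_flipped + rng.normal(0.0, spec.noise_sd, (h, w))
        right = np.clip(right, 0.0, 1.0)
        left_flipped = np.clip(left_flipped, 0.0, 1.0)

    left = left_flipped[:, ::-1].copy()

    area_pct = 100.0 * mask.mean()
    density_pct = 100.0 * gland.sum() / max(mask.sum(), 1)
    return PhantomCase(
        case_id=case_id,
        right_image=MammogramImage(
            pixels=right.astype(np.float32), laterality="R",
            thickness_mm=spec.thickness_mm,
        ),
        left_image=MammogramImage(
            pixels=left.astype(np.float32), laterality="L",
            thickness_mm=spec.thickness_mm,
        ),
        true_field=true_field,
        right_mask=mask,
        left_mask=left_mask[:, ::-1].copy(),
        breast_area_pct=float(area_pct),
        density_pct=float(density_pct),
        thickness_mm=float(spec.thickness_mm),
    )


def generate_cohort(
    n: int,
    covariate_ranges: dict | None = None,
    seed: int = 0,
    image_size: tuple = (512, 512),
    deform_magnitude: float = 3.0,
    deform_correlation_length: float | None = None,
    noise_sd: float = 0.01,
    texture_blob_count: int = 60,
):
    """Sample ``n`` bilateral cases with covariates inside the given ranges.

    Ranges default to the clinical test-cohort spans
    (:data:`TABLE1_TEST_RANGES`).  Returns ``(cases, manifest)`` where the
    manifest has one row per case.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    ranges = dict(TABLE1_TEST_RANGES)
    if covariate_ranges:
        unknown = set(covariate_ranges) - set(ranges)
        if unknown:
            raise ValueError(f"unknown covariates: {sorted(unknown)}")
        ranges.update(covariate_ranges)
    for name, (lo, hi) in ranges.items():
        if not (hi > lo):
            raise ValueError(f"empty range for {name}: ({lo}, {hi})")
    h, w = image_size
    if deform_correlation_length is None:
        deform_correlation_length = min(h, w) / 2.0

    rng = np.random.default_rng(seed)
    cases, rows = [], []
    for i in range(n):
        area = rng.uniform(*ranges["breast_area_pct"])
        dens = rng.uniform(*ranges["density_pct"])
        thick = rng.uniform(*ranges["thickness_mm"])
        case_seed = int(rng.integers(0, 2**31 - 1))
        spec = PhantomSpec(
            image_height=h,
            image_width=w,
            breast_area_fraction=area / 100.0,
            density_fraction=dens / 100.0,
            thickness_mm=thick,
            deform_magnitude=deform_magnitude,
            deform_correlation_length=deform_correlation_length,
            texture_blob_count=texture_blob_count,
            noise_sd=noise_sd,
            seed=case_seed,
        )
        case_id = f"case_{i:04d}"
        case = generate_bilateral_case(spec, case_id=case_id)
        cases.append(case)
        rows.append(
            {
                "case_id": case_id,
                "right_path": f"{case_id}_R.png",
                "left_path": f"{case_id}_L.png",
                "thickness_mm": case.thickness_mm,
                "breast_area_pct": case.breast_area_pct,
                "density_pct": case.density_pct,
            }
        )
    return cases, pd.DataFrame(rows)


def insert_lesion(
    image: MammogramImage,
    mask: np.ndarray,
    center: tuple,
    radius: float,
    amplitude: float,
) -> MammogramImage:
    """Add a smooth bright disc (a mass-like focal density) to one image.

    The added profile is ``amplitude * cos^2(pi * r / (2 * radius))`` for
    ``r < radius`` and zero outside, so the intensity increase at the
    centre pixel is exactly ``amplitude`` and pixels outside the lesion
    support are untouched.
    """
    r0, c0 = center
    h, w = image.pixels.shape
    if not (0 <= r0 < h and 0 <= c0 < w) or not mask[int(r0), int(c0)]:
        raise ValueError(f"lesion center {center} lies outside the breast mask")
    if radius < 0:
        raise ValueError("radius must be >= 0")
    pixels = np.array(image.pixels, dtype=np.float32, copy=True)
    if radius > 0:
        rr, cc = np.mgrid[0:h, 0:w]
        r = np.sqrt((rr - r0) ** 2 + (cc - c0) ** 2)
        inside = r < radius
        pixels[inside] += amplitude * np.cos(np.pi * r[inside] / (2 * radius)) ** 2
    out = dataclasses.replace(image, pixels=pixels)
    return out
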