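"""Desk-scale analog of the clinical bilateral-registration experiment.

The clinical study trained on 1000 cases at 512x512 for 800 epochs; its
cohort is private.  This module runs the same pipeline end to end on a
synthetic cohort scaled to a single CPU: 96 bilateral phantom pairs at
128x128 (RMS asymmetry 3 px), 64/8/24 train/validation/test, 150 epochs
at batch 8 with a half-width U-Net.  It reports the same quantities the
clinical study reports — mean SAD without and with registration, mean
improvement, fraction of cases improved, the paired Wilcoxon p-value —
plus ground-truth deformation recovery, which only synthetic data can
score.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .evaluation import evaluate_case, sad
from .model import SMALL_CONFIG, predict_displacement, warp_image
from .phantom import PhantomSpec, generate_bilateral_case, generate_cohort
from .preprocess import preprocess_pair
from .training import TrainConfig, train

__all__ = ["AnalogResult", "run_scaled_analog", "degenerate_symmetric_check"]

N_CASES = 96
N_TRAIN, N_VAL, N_TEST = 64, 8, 24
IMAGE_SIZE = 128
EPOCHS = 150
BATCH = 8
DEFORM_MAGNITUDE = 3.0
DEFORM_CORRELATION = 64.0
NOISE_SD = 0.01


@dataclass
class AnalogResult:
    records: list
    curve_train: list
    curve_val: list
    endpoint_errors_px: np.ndarray  # per test case, median within mask interior
    model: object

    @property
    def mean_sad_without(self):
        return float(np.mean([r.sad_without for r in self.records]))

    @property
    def mean_sad_with(self):
        return float(np.mean([r.sad_with for r in self.records]))

    @property
    def mean_improvement(self):
        return float(np.mean([r.improvement for r in self.records]))

    @property
    def fraction_improved(self):
        return float(np.mean([r.improvement > 0 for r in self.records]))

    @property
    def paired_p(self):
        from scipy import stats

        return float(
            stats.wilcoxon(
                [r.sad_without for r in self.records],
                [r.sad_with for r in self.records],
                alternative="two-sided",
            ).pvalue
        )

    @property
    def median_endpoint_error(self):
        return float(np.median(self.endpoint_errors_px))


def _chain_transform_field(field, mask, crop_to):
    """Push a ground-truth field through the pad/resize/crop chain.

    The chain maps coordinates x -> x * s - off with s = resize/native
    and off the crop offset, so displacements scale by s and are
    resampled at the pre-image coordinates.
    """
    native = field.shape[1]
    resize_to = round(crop_to * 520 / 512)
    s = resize_to / native
    off = (resize_to - crop_to) // 2
    gr, gc = np.meshgrid(np.arange(crop_to), np.arange(crop_to), indexing="ij")
    src = np.stack([(gr + off) / s, (gc + off) / s])
    out = np.stack(
        [
            s * ndimage.map_coordinates(field[k], src, order=1, mode="nearest")
            for k in range(2)
        ]
    )
    m = ndimage.map_coordinates(
        mask.astype(np.float64), src, order=0, mode="nearest"
    ) > 0.5
    return out.astype(np.float32), m


def run_scaled_analog(seed: int = 0, verbose: bool = False) -> AnalogResult:
    """Simulate, preprocess, train and evaluate the scaled-down cohort."""
    rng = np.random.default_rng(seed)
    cases, _ = generate_cohort(
        N_CASES,
        seed=int(rng.integers(0, 2**31 - 1)),
        image_size=(IMAGE_SIZE, IMAGE_SIZE),
        deform_magnitude=DEFORM_MAGNITUDE,
        deform_correlation_length=DEFORM_CORRELATION,
        noise_sd=NOISE_SD,
    )
    pairs = [
        preprocess_pair(c.right_image, c.left_image, crop_to=IMAGE_SIZE, case_id=c.case_id)
        for c in cases
    ]
    train_pairs = pairs[:N_TRAIN]
    val_pairs = pairs[N_TRAIN : N_TRAIN + N_VAL]
    test_pairs = pairs[N_TRAIN + N_VAL :]
    test_cases = cases[N_TRAIN + N_VAL :]

    config = TrainConfig(
        epochs=EPOCHS, batch_size=BATCH, seed=int(rng.integers(0, 2**31 - 1))
    )
    model, curve = train(
        train_pairs, val_pairs, config, unet_config=SMALL_CONFIG, verbose=verbose
    )

    records, epes = [], []
    for case, pair in zip(test_cases, test_pairs):
        record, _, _, field = evaluate_case(
            model,
            pair,
            covariates={
                "breast_area_pct": case.breast_area_pct,
                "density_pct": case.density_pct,
                "thickness_mm": case.thickness_mm,
            },
        )
        records.append(record)
        gt_field, gt_mask = _chain_transform_field(
            case.true_field, case.right_mask, IMAGE_SIZE
        )
        interior = ndimage.binary_erosion(gt_mask, iterations=4)
        err = np.sqrt(((field - gt_field) ** 2).sum(axis=0))
        epes.append(float(np.median(err[interior])))
    return AnalogResult(
        records=records,
        curve_train=curve.train,
        curve_val=curve.val,
        endpoint_errors_px=np.array(epes),
        model=model,
    )


def degenerate_symmetric_check(seed: int = 0, image_size: int = 128):
    """Perfectly symmetric, noiseless phantom: SAD without registration is
    zero, and an identity-initialised model changes nothing.

    Returns ``(sad_without, improvement)``.
    """
    from .model import RegistrationUNet

    spec = PhantomSpec(
        image_height=image_size,
        image_width=image_size,
        deform_magnitude=0.0,
        noise_sd=0.0,
        seed=seed,
    )
    case = generate_bilateral_case(spec)
    pair = preprocess_pair(case.right_image, case.left_image, crop_to=image_size)
    model = RegistrationUNet(SMALL_CONFIG, seed=seed)
    field = predict_displacement(model, pair.fixed, pair.flipped)
    transformed = warp_image(pair.flipped, field)
    s0 = sad(pair.fixed, pair.flipped, pair.mask)
    s1 = sad(pair.fixed, transformed, pair.mask)
    return s0, s0 - s1
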