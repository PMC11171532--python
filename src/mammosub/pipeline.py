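"""End-to-end runs: simulate -> preprocess -> train -> evaluate.

Each stage writes its artifacts into a run directory and never mutates
another stage's outputs; the resolved configuration and package version
are persisted so a rerun with the same config and seed reproduces the
per-case SAD table.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .evaluation import compare_and_summarize, evaluate_case
from .image_io import (
    read_mammogram,
    read_manifest,
    write_difference_image,
    write_field,
    write_mammogram,
    write_manifest,
    write_mask,
    read_mask,
)
from .model import SMALL_CONFIG, UNetConfig, load_weights, save_weights
from .phantom import generate_cohort
from .preprocess import RegistrationPair, preprocess_pair
from .training import TrainConfig, train

logger = logging.getLogger("mammosub")

__all__ = ["RunConfig", "run_end_to_end", "simulate_stage", "preprocess_stage",
           "train_stage", "evaluate_stage"]


@dataclass
class RunConfig:
    """Configuration of an end-to-end run.

    Split fractions default to the clinical 1000/100/500 proportions of
    the total cohort size.
    """

    out_dir: str = "run"
    n_cases: int = 16
    image_size: int = 128
    crop_to: int = 128
    deform_magnitude: float = 3.0
    deform_correlation_length: float | None = None
    noise_sd: float = 0.01
    covariate_ranges: dict | None = None
    train_frac: float = 1000 / 1600
    val_frac: float = 100 / 1600
    epochs: int = 20
    batch_size: int = 8
    lambda_smooth: float = 1.0
    base_lr: float = 2e-4
    unet_profile: str = "small"  # "small" | "default"
    seed: int = 0

    def unet_config(self) -> UNetConfig:
        return SMALL_CONFIG if self.unet_profile == "small" else UNetConfig()


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                logger.info("stage %s started", name)
                out = fn(*args, **kwargs)
                logger.info("stage %s finished", name)
                return out
            except Exception as e:
                raise RuntimeError(f"stage '{name}' failed: {e}") from e

        return wrapped

    return deco


@_stage("simulate")
def simulate_stage(config: RunConfig, out: Path):
    out.mkdir(parents=True, exist_ok=True)
    cases, manifest = generate_cohort(
        config.n_cases,
        covariate_ranges=config.covariate_ranges,
        seed=config.seed,
        image_size=(config.image_size, config.image_size),
        deform_magnitude=config.deform_magnitude,
        deform_correlation_length=config.deform_correlation_length,
        noise_sd=config.noise_sd,
    )
    for case in cases:
        write_mammogram(case.right_image, out / f"{case.case_id}_R.png")
        write_mammogram(case.left_image, out / f"{case.case_id}_L.png")
        write_field(case.true_field, out / f"{case.case_id}_field.tif")
        write_mask(case.right_mask, out / f"{case.case_id}_mask_R.png")
        write_mask(case.left_mask, out / f"{case.case_id}_mask_L.png")
    write_manifest(manifest, out / "manifest.csv")
    return cases, manifest


@_stage("preprocess")
def preprocess_stage(manifest: pd.DataFrame, image_dir: Path, out: Path, crop_to: int):
    out.mkdir(parents=True, exist_ok=True)
    pairs = []
    for row in manifest.itertuples():
        right = read_mammogram(image_dir / row.right_path, laterality="R")
        left = read_mammogram(image_dir / row.left_path, laterality="L")
        pair = preprocess_pair(right, left, crop_to=crop_to, case_id=row.case_id)
        write_mammogram(
            dataclasses.replace(right, pixels=pair.fixed),
            out / f"{row.case_id}_fixed.png",
        )
        write_mammogram(
            dataclasses.replace(left, pixels=pair.flipped, laterality="L"),
            out / f"{row.case_id}_flipped.png",
        )
        write_mask(pair.mask, out / f"{row.case_id}_mask.png")
        pairs.append(pair)
    return pairs


def load_preprocessed(manifest: pd.DataFrame, prep_dir: Path) -> list:
    """Rehydrate RegistrationPairs written by the preprocess stage."""
    pairs = []
    for row in manifest.itertuples():
        fixed = read_mammogram(prep_dir / f"{row.case_id}_fixed.png", "R")
        flipped = read_mammogram(prep_dir / f"{row.case_id}_flipped.png", "L")
        mask = read_mask(prep_dir / f"{row.case_id}_mask.png")
        pairs.append(
            RegistrationPair(
                fixed=fixed.pixels.astype(np.float32) / 65535.0,
                flipped=flipped.pixels.astype(np.float32) / 65535.0,
                mask=mask,
                case_id=row.case_id,
            )
        )
    return pairs


@_stage("train")
def train_stage(train_pairs, val_pairs, config: RunConfig, out: Path):
    out.mkdir(parents=True, exist_ok=True)
    tc = TrainConfig(
        epochs=config.epochs,
        batch_size=config.batch_size,
        lambda_smooth=config.lambda_smooth,
        base_lr=config.base_lr,
        seed=config.seed,
    )
    model, curve = train(train_pairs, val_pairs, tc, unet_config=config.unet_config())
    save_weights(model, out / "weights.npz")
    log = pd.DataFrame(
        {
            "epoch": np.arange(1, len(curve.train) + 1),
            "train_loss": curve.train,
            "val_loss": curve.val if curve.val else np.nan,
        }
    )
    log.to_csv(out / "learning_curve.csv", index=False)
    _plot_curve(log, out / "learning_curve.png")
    return model, curve


def _plot_curve(log: pd.DataFrame, path: Path):
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.2))
    ax.plot(log["epoch"], log["train_loss"], label="train")
    if log["val_loss"].notna().any():
        ax.plot(log["epoch"], log["val_loss"], label="validation")
    ax.set_xlabel("epoch")
    ax.set_ylabel("loss")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


@_stage("evaluate")
def evaluate_stage(model, pairs, manifest: pd.DataFrame, out: Path):
    out.mkdir(parents=True, exist_ok=True)
    cov_cols = ("breast_area_pct", "density_pct", "thickness_mm")
    covs = manifest.set_index("case_id")
    records = []
    for pair in pairs:
        cov = (
            {k: covs.loc[pair.case_id, k] for k in cov_cols if k in covs.columns}
            if pair.case_id in covs.index
            else {}
        )
        record, diff0, diff1, field = evaluate_case(model, pair, cov)
        write_difference_image(diff0, out / f"{pair.case_id}_diff_without.png")
        write_difference_image(diff1, out / f"{pair.case_id}_diff_with.png")
        write_field(field, out / f"{pair.case_id}_pred_field.tif")
        records.append(record)
    table = pd.DataFrame(
        [
            {
                "case_id": r.case_id,
                "sad_without": r.sad_without,
                "sad_with": r.sad_with,
                "improvement": r.improvement,
                "breast_area_pct": r.breast_area_pct,
                "density_pct": r.density_pct,
                "thickness_mm": r.thickness_mm,
            }
            for r in records
        ]
    )
    table.to_csv(out / "case_records.csv", index=False)
    if len(records) >= 4:
        report = compare_and_summarize(records)
        report.table.to_csv(out / "subgroup_table.csv")
        report.pairwise.to_csv(out / "subgroup_pairwise.csv", index=False)
        (out / "subgroup_report.md").write_text(report.to_markdown())
        _plot_evaluation(table, out)
    return records


def _plot_evaluation(table: pd.DataFrame, out: Path):
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(8, 3.4))
    axes[0].boxplot(
        [table.sad_without, table.sad_with],
        tick_labels=["without\nregistration", "with\nregistration"],
    )
    axes[0].set_ylabel("SAD")
    axes[1].scatter(table.sad_without, table.improvement, s=12)
    axes[1].set_xlabel("SAD without registration")
    axes[1].set_ylabel("improvement")
    axes[1].axhline(0.0, color="grey", lw=0.8)
    fig.tight_layout()
    fig.savefig(out / "sad_summary.png", dpi=110)
    plt.close(fig)


def run_end_to_end(config: RunConfig) -> Path:
    """Execute simulate -> preprocess -> train -> evaluate in order."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    resolved = dataclasses.asdict(config)
    resolved["version"] = __version__
    (out / "run_config.yaml").write_text(yaml.safe_dump(resolved))

    cases, manifest = simulate_stage(config, out / "images")
    pairs = preprocess_stage(manifest, out / "images", out / "preprocessed",
                             config.crop_to)

    n = len(pairs)
    n_train = max(1, int(round(config.train_frac * n)))
    n_val = int(round(config.val_frac * n))
    train_pairs = pairs[:n_train]
    val_pairs = pairs[n_train : n_train + n_val]
    test_pairs = pairs[n_train + n_val :] or pairs
    test_ids = {p.case_id for p in test_pairs}

    model, _ = train_stage(train_pairs, val_pairs, config, out / "model")
    evaluate_stage(
        model,
        test_pairs,
        manifest[manifest.case_id.isin(test_ids)],
        out / "evaluation",
    )
    return out
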