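"""SAD evaluation, quartile subgroups, and statistical comparison.

SAD is the mean absolute intensity difference between two images over
the breast + pectoral mask on the [0, 1] scale — computed for the fixed
vs. flipped pair (without registration) and the fixed vs. transformed
pair (with registration); their difference is the per-case improvement.
Test cohorts are split into four near-equal quartile groups per
covariate (decreasing breast area, gland content ratio, and compressed
thickness; increasing baseline SAD) and compared with nonparametric
tests: paired two-sided Wilcoxon signed-rank within groups, pairwise
Mann-Whitney on the improvement between groups with Holm correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .model import RegistrationUNet, predict_displacement, warp_image
from .preprocess import RegistrationPair

__all__ = [
    "CaseRecord",
    "SubgroupReport",
    "sad",
    "evaluate_case",
    "quartile_split",
    "compare_and_summarize",
    "SORT_ORDERS",
]

#: Sorting direction per covariate when forming Groups 1-4.
SORT_ORDERS = {
    "breast_area_pct": "decreasing",
    "density_pct": "decreasing",
    "thickness_mm": "decreasing",
    "sad_without": "increasing",
}


@dataclass
class CaseRecord:
    """Per-case SAD outcome with covariates."""

    case_id: str
    sad_without: float
    sad_with: float
    breast_area_pct: float = np.nan
    density_pct: float = np.nan
    thickness_mm: float = np.nan

    @property
    def improvement(self) -> float:
        return self.sad_without - self.sad_with


@dataclass
class SubgroupReport:
    """Table-style summary: per-covariate quartile groups and statistics."""

    overall: pd.Series
    overall_p: float
    table: pd.DataFrame  # (covariate, group) x summary columns
    pairwise: pd.DataFrame  # between-group Mann-Whitney with Holm correction

    def to_markdown(self) -> str:
        lines = [
            "# Subgroup report",
            "",
            f"Overall (n={int(self.overall['n'])}): "
            f"SAD without {self.overall['sad_without_mean']:.4f} ± "
            f"{self.overall['sad_without_sd']:.4f}, "
            f"with {self.overall['sad_with_mean']:.4f} ± "
            f"{self.overall['sad_with_sd']:.4f}, "
            f"paired p = {self.overall_p:.3g}",
            "",
            self.table.round(5).to_markdown(),
            "",
            "## Pairwise group comparisons (improvement)",
            "",
            self.pairwise.round(5).to_markdown(index=False),
        ]
        return "\n".join(lines)


def sad(a: np.ndarray, b: np.ndarray, mask: np.ndarray) -> float:
    """Mean absolute difference between two images over the mask."""
    a = np.asarray(a)
    b = np.asarray(b)
    mask = np.asarray(mask, dtype=bool)
    if a.shape != b.shape or a.shape != mask.shape:
        raise ValueError("images and mask must share one shape")
    if not mask.any():
        raise ValueError("mask is empty")
    return float(np.mean(np.abs(a[mask] - b[mask])))


def evaluate_case(
    model: RegistrationUNet,
    pair: RegistrationPair,
    covariates: Optional[dict] = None,
):
    """Register one pair and score it.

    Returns ``(record, diff_without, diff_with, field)`` where the
    difference images are absolute differences on [0, 1].
    """
    field = predict_displacement(model, pair.fixed, pair.flipped)
    transformed = warp_image(pair.flipped, field)
    diff_without = np.abs(pair.fixed - pair.flipped)
    diff_with = np.abs(pair.fixed - transformed)
    cov = covariates or {}
    record = CaseRecord(
        case_id=pair.case_id,
        sad_without=sad(pair.fixed, pair.flipped, pair.mask),
        sad_with=sad(pair.fixed, transformed, pair.mask),
        breast_area_pct=cov.get("breast_area_pct", np.nan),
        density_pct=cov.get("density_pct", np.nan),
        thickness_mm=cov.get("thickness_mm", np.nan),
    )
    return record, diff_without, diff_with, field


def quartile_split(records, covariate: str, order: str | None = None) -> np.ndarray:
    """Assign Groups 1-4 by sorted covariate, near-equal contiguous blocks.

    ``order`` defaults to the study convention (:data:`SORT_ORDERS`).
    Ties break stably by case id; group sizes differ by at most one,
    larger groups first.  Returns labels aligned with the input order.
    """
    records = list(records)
    if len(records) < 4:
        raise ValueError("need at least 4 records to form quartiles")
    if order is None:
        if covariate not in SORT_ORDERS:
            raise ValueError(f"unknown covariate {covariate!r}")
        order = SORT_ORDERS[covariate]
    if order not in ("increasing", "decreasing"):
        raise ValueError(f"order must be increasing|decreasing, got {order!r}")
    try:
        values = np.array([getattr(r, covariate) for r in records], dtype=float)
    except AttributeError as e:
        raise ValueError(f"unknown covariate {covariate!r}") from e
    ids = [r.case_id for r in records]
    by_id = sorted(range(len(records)), key=lambda i: ids[i])
    key = values[by_id]
    inner = np.argsort(-key if order == "decreasing" else key, kind="stable")
    sorted_idx = [by_id[i] for i in inner]
    labels = np.empty(len(records), dtype=int)
    for g, chunk in enumerate(np.array_split(np.array(sorted_idx), 4), start=1):
        labels[chunk] = g
    return labels


def _paired_p(without, with_, parametric=False):
    d = np.asarray(without) - np.asarray(with_)
    if len(d) < 2:
        warnings.warn("group has fewer than 2 cases; statistic omitted")
        return np.nan
    if np.allclose(d, 0):
        return 1.0
    if parametric:
        return float(stats.ttest_rel(without, with_).pvalue)
    return float(stats.wilcoxon(without, with_, alternative="two-sided").pvalue)


def compare_and_summarize(
    records,
    covariates=("breast_area_pct", "density_pct", "thickness_mm", "sad_without"),
    parametric: bool = False,
) -> SubgroupReport:
    """Build the subgroup report over the standard four stratifications."""
    records = list(records)
    if not records:
        raise ValueError("no records to summarize")
    sw = np.array([r.sad_without for r in records])
    sv = np.array([r.sad_with for r in records])
    imp = sw - sv
    overall = pd.Series(
        {
            "n": len(records),
            "sad_without_mean": sw.mean(),
            "sad_without_sd": sw.std(ddof=1) if len(records) > 1 else 0.0,
            "sad_with_mean": sv.mean(),
            "sad_with_sd": sv.std(ddof=1) if len(records) > 1 else 0.0,
            "improvement_mean": imp.mean(),
            "improvement_min": imp.min(),
            "improvement_max": imp.max(),
        }
    )
    overall_p = _paired_p(sw, sv, parametric)

    rows, pair_rows = [], []
    for cov in covariates:
        labels = quartile_split(records, cov)
        groups = {}
        for g in (1, 2, 3, 4):
            sel = labels == g
            groups[g] = (sw[sel], sv[sel])
            rows.append(
                {
                    "covariate": cov,
                    "group": g,
                    "n": int(sel.sum()),
                    "sad_without_mean": sw[sel].mean(),
                    "sad_without_sd": sw[sel].std(ddof=1) if sel.sum() > 1 else np.nan,
                    "sad_with_mean": sv[sel].mean(),
                    "sad_with_sd": sv[sel].std(ddof=1) if sel.sum() > 1 else np.nan,
                    "improvement_mean": imp[sel].mean(),
                    "improvement_sd": imp[sel].std(ddof=1) if sel.sum() > 1 else np.nan,
                    "p_paired": _paired_p(sw[sel], sv[sel], parametric),
                }
            )
        raw = []
        combos = [(a, b) for a in (1, 2, 3, 4) for b in (1, 2, 3, 4) if a < b]
        for a, b in combos:
            ia, ib = labels == a, labels == b
            if ia.sum() < 2 or ib.sum() < 2:
                warnings.warn("group has fewer than 2 cases; statistic omitted")
                raw.append(np.nan)
                continue
            da, db = imp[ia], imp[ib]
            if parametric:
                p = float(stats.ttest_ind(da, db).pvalue)
            else:
                p = float(stats.mannwhitneyu(da, db, alternative="two-sided").pvalue)
            raw.append(p)
        adj = _holm(raw)
        for (a, b), p, ph in zip(combos, raw, adj):
            pair_rows.append(
                {
                    "covariate": cov,
                    "group_a": a,
                    "group_b": b,
                    "p_raw": p,
                    "p_holm": ph,
                }
            )
    table = pd.DataFrame(rows).set_index(["covariate", "group"])
    pairwise = pd.DataFrame(pair_rows)
    return SubgroupReport(
        overall=overall, overall_p=overall_p, table=table, pairwise=pairwise
    )


def _holm(pvals):
    """Holm step-down adjustment, NaN-tolerant."""
    from statsmodels.stats.multitest import multipletests

    pvals = np.asarray(pvals, dtype=float)
    out = np.full_like(pvals, np.nan)
    ok = np.isfinite(pvals)
    if ok.any():
        out[ok] = multipletests(pvals[ok], method="holm")[1]
    return out
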