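"""Intersection-over-union evaluation with per-region reporting.

IoU = |A∩B| / |A∪B| for a predicted mask A against ground truth B.  A
region the model never predicts (|A| = 0) is flagged DNP ("did not
predict") and contributes 0 to mean IoU.  Multi-class maps are compared
region-by-region by binarising: the region of interest is foreground,
everything else — other regions included — is a common background class.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "RegionIoU",
    "RegionIoUReport",
    "iou",
    "binarize_for_region",
    "region_report",
    "evaluate_segmentation",
    "improvement_count",
]


@dataclass(frozen=True)
class RegionIoU:
    region: str
    iou: float
    dnp: bool

    @property
    def effective(self) -> float:
        """IoU with DNP counted as 0 (the value that enters means)."""
        return 0.0 if self.dnp else self.iou


@dataclass(frozen=True)
class RegionIoUReport:
    regions: tuple[RegionIoU, ...]

    @property
    def mean_iou(self) -> float:
        return float(np.mean([r.effective for r in self.regions]))

    def rounded(self, decimals: int = 2) -> dict[str, float | str]:
        """Display form, rounded only at reporting time."""
        out: dict[str, float | str] = {
            r.region: ("DNP" if r.dnp else round(r.iou, decimals)) for r in self.regions
        }
        out["mean"] = round(self.mean_iou, decimals)
        return out


def iou(pred: np.ndarray, truth: np.ndarray) -> tuple[float, bool]:
    """(IoU value, DNP flag) of two binary masks of identical shape."""
    pred = np.asarray(pred, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    if not truth.any():
        raise ValueError("ground-truth mask is empty; IoU is undefined")
    inter = int(np.logical_and(pred, truth).sum())
    union = int(np.logical_or(pred, truth).sum())
    dnp = not pred.any()
    return inter / union, dnp


def binarize_for_region(label_map: np.ndarray, region_id: int) -> np.ndarray:
    """Foreground where the map equals ``region_id``; all else background."""
    return np.asarray(label_map) == region_id


def region_report(
    per_region: dict[str, tuple[float, bool]] | list[tuple[str, float, bool]],
) -> RegionIoUReport:
    """Aggregate per-region (IoU, DNP) pairs into a report.

    Accepts a mapping name → (iou, dnp) or a list of (name, iou, dnp).
    """
    if isinstance(per_region, dict):
        items = [(k, v[0], v[1]) for k, v in per_region.items()]
    else:
        items = list(per_region)
    if not items:
        raise ValueError("at least one region is required")
    return RegionIoUReport(tuple(RegionIoU(n, float(v), bool(d)) for n, v, d in items))


def evaluate_segmentation(
    pred_map: np.ndarray,
    truth_map: np.ndarray,
    region_table: dict[int, str],
) -> RegionIoUReport:
    """Per-region binarised IoU of a predicted map against a label mask."""
    rows = []
    for rid in sorted(region_table):
        value, dnp = iou(
            binarize_for_region(pred_map, rid), binarize_for_region(truth_map, rid)
        )
        rows.append((region_table[rid], value, dnp))
    return region_report(rows)


def improvement_count(
    baseline: RegionIoUReport | dict[str, tuple[float, bool]],
    finetuned: RegionIoUReport | dict[str, tuple[float, bool]],
) -> int:
    """Number of regions whose fine-tuned IoU strictly exceeds baseline.

    DNP entries count as 0 on either side.
    """
    if not isinstance(baseline, RegionIoUReport):
        baseline = region_report(baseline)
    if not isinstance(finetuned, RegionIoUReport):
        finetuned = region_report(finetuned)
    base = {r.region: r.effective for r in baseline.regions}
    fine = {r.region: r.effective for r in finetuned.regions}
    if set(base) != set(fine):
        raise ValueError("baseline and fine-tuned reports cover different regions")
    return sum(1 for name in base if fine[name] > base[name])
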