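"""Instance-segmentation scoring: IoU, threshold matching, AP and mean AP.

The metric follows the detection-AP convention used for nuclei instance
segmentation: instances of a prediction are matched one-to-one to
ground-truth instances when their IoU (Jaccard index) exceeds a threshold
``t``, precision at the threshold is

    p(t) = TP / (TP + FP + FN),

and the average precision (AP) is the mean of ``p(t)`` over a threshold
grid, by default ``0.50:0.05:0.95`` (10 thresholds). ``mAP50`` averages
``p(0.5)`` over several image/model pairs; ``mAP50:5:95`` averages the
full-grid AP.

Matching is a globally optimal one-to-one assignment maximizing the number
of matched pairs (ties broken by maximal summed IoU) — a greedy matcher can
return fewer matches on competing overlaps. Thresholding uses strict
``IoU > t`` (configurable via ``strict=False`` for ``>=``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from ._overlap import as_voxels, contingency
from .volumes import LabelVolume

__all__ = [
    "IoUTable",
    "MatchResult",
    "APReport",
    "MAPReport",
    "iou_table",
    "match_at_threshold",
    "average_precision",
    "mean_average_precision",
    "default_thresholds",
]


def default_thresholds(t1: float = 0.50, tM: float = 0.95, dt: float = 0.05) -> np.ndarray:
    """The IoU threshold grid ``t1, t1+dt, ..., tM``."""
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if t1 > tM:
        raise ValueError("t1 must be <= tM")
    n_steps = (tM - t1) / dt
    if abs(n_steps - round(n_steps)) > 1e-9:
        raise ValueError(f"(tM - t1) = {tM - t1} is not an integer multiple of dt = {dt}")
    return t1 + dt * np.arange(round(n_steps) + 1)


@dataclass
class IoUTable:
    """Sparse IoU between ground-truth and predicted instances.

    Absent pairs have zero intersection, hence IoU 0.
    """

    entries: dict[tuple[int, int], float]
    gt_sizes: dict[int, int]
    pred_sizes: dict[int, int]

    @property
    def n_gt(self) -> int:
        return len(self.gt_sizes)

    @property
    def n_pred(self) -> int:
        return len(self.pred_sizes)

    def transposed(self) -> "IoUTable":
        return IoUTable(
            {(p, g): v for (g, p), v in self.entries.items()},
            dict(self.pred_sizes),
            dict(self.gt_sizes),
        )


@dataclass
class MatchResult:
    """One-to-one matching outcome at a single IoU threshold."""

    t: float
    TP: int
    FP: int
    FN: int
    matches: list[tuple[int, int]]

    @property
    def precision(self) -> float:
        denom = self.TP + self.FP + self.FN
        return self.TP / denom if denom else 0.0


@dataclass
class APReport:
    """Per-threshold precision and its mean (the AP) for one gt/pred pair."""

    thresholds: np.ndarray
    precision_at: np.ndarray
    matches: list[MatchResult] = field(repr=False, default_factory=list)

    @property
    def AP(self) -> float:
        return float(np.mean(self.precision_at))


@dataclass
class MAPReport:
    """AP summary over N image/model pairs: mean ± sample s.d."""

    variant: str
    per_image_AP: list[float]

    @property
    def mean(self) -> float:
        return float(np.mean(self.per_image_AP))

    @property
    def sd(self) -> float:
        if len(self.per_image_AP) < 2:
            return 0.0
        return float(np.std(self.per_image_AP, ddof=1))


def _apply_foreground_mask(pred: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Drop predicted instances with no voxel inside the foreground mask."""
    mask = np.asarray(mask, bool)
    if mask.shape != pred.shape:
        raise ValueError("foreground mask shape mismatch")
    kept = np.unique(pred[mask & (pred > 0)])
    out = np.where(np.isin(pred, kept), pred, 0)
    return out


def iou_table(
    gt: LabelVolume | np.ndarray,
    pred: LabelVolume | np.ndarray,
    foreground_mask: np.ndarray | None = None,
) -> IoUTable:
    """IoU = |g∩p| / (|g| + |p| − |g∩p|) for every co-occurring instance pair.

    ``foreground_mask``, if given, removes predicted instances lying entirely
    outside the mask before scoring (for methods that oversegment the
    background).
    """
    pv = as_voxels(pred)
    if foreground_mask is not None:
        pv = _apply_foreground_mask(pv, foreground_mask)
    pairs, gt_sizes, pred_sizes = contingency(as_voxels(gt), pv)
    entries = {
        (g, p): inter / (gt_sizes[g] + pred_sizes[p] - inter)
        for (g, p), inter in pairs.items()
    }
    return IoUTable(entries, gt_sizes, pred_sizes)


def match_at_threshold(table: IoUTable, t: float, strict: bool = True) -> MatchResult:
    """Optimal one-to-one matching of instances with IoU above ``t``.

    Maximizes the number of matched pairs, breaking ties by maximal summed
    IoU (via a single linear assignment with a count-dominant weight).
    """
    if not (0 < t <= 1):
        raise ValueError(f"threshold must be in (0, 1], got {t}")
    gt_ids = sorted(table.gt_sizes)
    pred_ids = sorted(table.pred_sizes)
    n_gt, n_pred = len(gt_ids), len(pred_ids)
    matches: list[tuple[int, int]] = []
    if n_gt and n_pred:
        gi = {g: i for i, g in enumerate(gt_ids)}
        pi = {p: i for i, p in enumerate(pred_ids)}
        weight = np.zeros((n_gt, n_pred))
        big = min(n_gt, n_pred) + 1.0  # any extra match outweighs all IoU mass
        for (g, p), v in table.entries.items():
            ok = v > t if strict else v >= t
            if ok:
                weight[gi[g], pi[p]] = big + v
        rows, cols = linear_sum_assignment(weight, maximize=True)
        matches = [
            (gt_ids[r], pred_ids[c]) for r, c in zip(rows, cols) if weight[r, c] > 0
        ]
    tp = len(matches)
    return MatchResult(t=t, TP=tp, FP=n_pred - tp, FN=n_gt - tp, matches=sorted(matches))


def average_precision(
    gt: LabelVolume | np.ndarray,
    pred: LabelVolume | np.ndarray,
    t1: float = 0.50,
    tM: float = 0.95,
    dt: float = 0.05,
    strict: bool = True,
    foreground_mask: np.ndarray | None = None,
) -> APReport:
    """AP = mean of p(t) over the IoU grid ``t1:dt:tM`` for one pair."""
    table = iou_table(gt, pred, foreground_mask=foreground_mask)
    if table.n_gt == 0:
        raise ValueError("ground truth contains no instances; precision undefined")
    thresholds = default_thresholds(t1, tM, dt)
    results = [match_at_threshold(table, float(t), strict=strict) for t in thresholds]
    return APReport(
        thresholds=thresholds,
        precision_at=np.asarray([m.precision for m in results]),
        matches=results,
    )


def mean_average_precision(
    pairs: list[tuple[LabelVolume | np.ndarray, LabelVolume | np.ndarray]],
    variant: str = "mAP50:5:95",
    strict: bool = True,
) -> MAPReport:
    """Mean ± s.d. of per-pair AP over N image/model pairs.

    ``"mAP50"`` scores at the single threshold 0.5 (detection score);
    ``"mAP50:5:95"`` averages over the 10-threshold grid (instance
    segmentation score).
    """
    if not pairs:
        raise ValueError("at least one (gt, pred) pair is required")
    if variant == "mAP50":
        grid = (0.50, 0.50, 0.05)
    elif variant in ("mAP50:5:95", "mAP"):
        grid = (0.50, 0.95, 0.05)
    else:
        raise ValueError(f"unknown variant {variant!r}")
    aps = [
        average_precision(gt, pred, *grid, strict=strict).AP for gt, pred in pairs
    ]
    return MAPReport(variant=variant, per_image_AP=aps)
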