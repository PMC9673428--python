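"""Segmentation evaluation metrics.

Overlap metrics are computed from a (k+1)x(k+1) pixel confusion matrix
``p_ij`` (row = true class i, column = predicted class j):

* MIoU        mean_i  p_ii / (sum_j p_ij + sum_j p_ji - p_ii)
* MPA         mean_i  p_ii / sum_j p_ij
* mPrecision  mean_i  TP_i / (TP_i + FP_i)
* mDice       mean_i  2 TP_i / (2 TP_i + FP_i + FN_i)
* accuracy    trace / total

Means run over the classes present in truth or prediction; classes absent
from both are skipped (0/0), and a class absent from truth only contributes
zero.  ``include_background`` controls whether class 0 joins the means.

Boundary metrics operate on the sets of boundary pixels of one class
(4-neighbourhood; the image border counts as outside):

* Hausdorff95  max of the 95th percentiles of the two directed
  nearest-neighbour distance distributions (percentile=100 gives the exact
  symmetric Hausdorff distance)
* ASD          mean distance from each predicted-boundary pixel to the
  ground-truth boundary (one-directional; a symmetric variant is optional)

Distances are Euclidean on the pixel grid, scaled by ``spacing``
(default 1.0 pixel; set to a physical pixel size for mm).
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np
from scipy.spatial import cKDTree

__all__ = ["ConfusionMatrix", "BoundarySet", "MetricReport", "AbsentClassError",
           "confusion_matrix", "overlap_metrics", "extract_boundary",
           "hausdorff95", "asd", "evaluate_pair", "aggregate_reports"]


class AbsentClassError(ValueError):
    """Requested class has no pixels in the mask."""


@dataclass(frozen=True)
class ConfusionMatrix:
    counts: np.ndarray          # (k+1, k+1) ints
    k: int                      # number of foreground classes

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class BoundarySet:
    points: np.ndarray          # (n, 2) int (row, col), 0-based

    def __len__(self):
        return len(self.points)


@dataclass
class MetricReport:
    miou: float = np.nan
    mpa: float = np.nan
    mprecision: float = np.nan
    mdice: float = np.nan
    accuracy: float = np.nan
    hausdorff95: float = np.nan
    asd: float = np.nan

    def to_dict(self) -> dict:
        return {f.name: float(getattr(self, f.name)) for f in fields(self)}


def confusion_matrix(pred, truth, k: int) -> ConfusionMatrix:
    """Tabulate p_ij = #{pixels with truth i and prediction j}."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs truth {truth.shape}")
    n = k + 1
    for name, m in (("pred", pred), ("truth", truth)):
        if m.min() < 0 or m.max() > k:
            raise ValueError(f"{name} labels must lie in [0, {k}]")
    idx = truth.ravel().astype(np.int64) * n + pred.ravel().astype(np.int64)
    counts = np.bincount(idx, minlength=n * n).reshape(n, n)
    return ConfusionMatrix(counts=counts, k=k)


def _per_class(cm: ConfusionMatrix):
    c = cm.counts.astype(float)
    tp = np.diag(c)
    row = c.sum(axis=1)          # truth totals (TP + FN)
    col = c.sum(axis=0)          # prediction totals (TP + FP)
    return tp, row, col


def _safe_div(num, den):
    """Elementwise num/den with 0/0 -> 0."""
    out = np.zeros_like(num, dtype=float)
    nz = den > 0
    out[nz] = num[nz] / den[nz]
    return out


def overlap_metrics(cm: ConfusionMatrix, *,
                    include_background: bool = True) -> MetricReport:
    """MIoU, MPA, mPrecision, mDice and accuracy from a confusion matrix."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    tp, row, col = _per_class(cm)
    present = (row + col) > 0                 # in truth or prediction
    if not include_background:
        present[0] = False
    if not present.any():
        raise ValueError("no classes to average over")
    iou = _safe_div(tp, row + col - tp)
    pa = _safe_div(tp, row)
    prec = _safe_div(tp, col)
    dice = _safe_div(2 * tp, row + col)
    return MetricReport(
        miou=float(iou[present].mean()),
        mpa=float(pa[present].mean()),
        mprecision=float(prec[present].mean()),
        mdice=float(dice[present].mean()),
        accuracy=float(tp.sum() / cm.total),
    )


def extract_boundary(mask, cls: int) -> BoundarySet:
    """Pixels of `cls` with a 4-neighbour outside the class (border = outside)."""
    mask = np.asarray(mask)
    inside = mask == cls
    if not inside.any():
        raise AbsentClassError(f"class {cls} absent from mask")
    padded = np.pad(inside, 1, constant_values=False)
    core = (padded[:-2, 1:-1] & padded[2:, 1:-1]
            & padded[1:-1, :-2] & padded[1:-1, 2:])
    boundary = inside & ~core
    return BoundarySet(points=np.argwhere(boundary))


def _directed_distances(src: BoundarySet, dst: BoundarySet) -> np.ndarray:
    tree = cKDTree(dst.points)
    d, _ = tree.query(src.points, k=1)
    return d


def _check_nonempty(a: BoundarySet, b: BoundarySet):
    if len(a) == 0:
        raise ValueError("first boundary set is empty")
    if len(b) == 0:
        raise ValueError("second boundary set is empty")


def hausdorff95(a: BoundarySet, b: BoundarySet, spacing: float = 1.0, *,
                percentile: float = 95.0) -> float:
    """Symmetric percentile Hausdorff distance between two boundaries.

    percentile=100 reproduces the exact Hausdorff distance
    ``max(max_x d(x,B), max_y d(y,A))`` and is symmetric in its arguments.
    """
    _check_nonempty(a, b)
    dab = _directed_distances(a, b)
    dba = _directed_distances(b, a)
    return float(max(np.percentile(dab, percentile),
                     np.percentile(dba, percentile)) * spacing)


def asd(seg: BoundarySet, gt: BoundarySet, spacing: float = 1.0, *,
        symmetric: bool = False) -> float:
    """Average surface distance from `seg` boundary pixels to the `gt` boundary.

    One-directional by definition (and therefore asymmetric); with
    ``symmetric=True`` the two directed means are averaged.
    """
    _check_nonempty(seg, gt)
    d = _directed_distances(seg, gt).mean()
    if symmetric:
        d = 0.5 * (d + _directed_distances(gt, seg).mean())
    return float(d * spacing)


def evaluate_pair(pred, truth, k: int, *, spacing: float = 1.0,
                  include_background: bool = True) -> MetricReport:
    """All metrics for one prediction/ground-truth mask pair.

    Boundary metrics are averaged over the foreground classes present in
    both masks; if no class is present in both, they are NaN.
    """
    cm = confusion_matrix(pred, truth, k)
    report = overlap_metrics(cm, include_background=include_background)
    hds, asds = [], []
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    for cls in range(1, k + 1):
        if not ((pred == cls).any() and (truth == cls).any()):
            continue
        bp = extract_boundary(pred, cls)
        bt = extract_boundary(truth, cls)
        hds.append(hausdorff95(bp, bt, spacing))
        asds.append(asd(bp, bt, spacing))
    if hds:
        report.hausdorff95 = float(np.mean(hds))
        report.asd = float(np.mean(asds))
    return report


def aggregate_reports(reports: list[MetricReport]) -> MetricReport:
    """Dataset-level report: mean of per-image metrics (NaNs skipped)."""
    if not reports:
        raise ValueError("no reports to aggregate")
    agg = MetricReport()
    for f in fields(MetricReport):
        vals = [getattr(r, f.name) for r in reports]
        vals = [v for v in vals if np.isfinite(v)]
        if vals:
            setattr(agg, f.name, float(np.mean(vals)))
    return agg
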