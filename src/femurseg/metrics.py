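"""Evaluation suite: overlap metrics, physical-unit surface distances,
ROC/PRC curves with AUC/AP, operating-point selection and the paired
model-comparison statistics.

Overlap metrics from the voxelwise confusion counts:

    DSC         = 2TP / (FP + 2TP + FN)
    recall      = TP / (TP + FN)
    specificity = TN / (TN + FP)
    precision   = TP / (TP + FP)

Surface distances use 6-connected surface voxels (out-of-grid neighbors
count as background) and exact Euclidean nearest-neighbor distances between
voxel centers scaled by the spacing:

    ASD = (sum_{x in S} d(x, G) + sum_{x in G} d(x, S)) / (N_S + N_G)
    MSD = max{ max_{x in S} d(x, G), max_{x in G} d(x, S) }
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .core_io import LabelMask, ProbabilityMap

UNDEFINED = float("nan")


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass
class SurfaceSet:
    """Voxel indices of 6-connected boundary voxels plus the grid spacing."""

    coords: np.ndarray  # (n, 3) int indices
    spacing: Tuple[float, float, float]

    def __len__(self) -> int:
        return len(self.coords)

    @property
    def points_mm(self) -> np.ndarray:
        return self.coords * np.asarray(self.spacing)


@dataclass
class CurveResult:
    """Thresholds in descending order with per-threshold operating points."""

    thresholds: np.ndarray
    precision: np.ndarray
    recall: np.ndarray
    fpr: np.ndarray
    specificity: np.ndarray
    area: float
    kind: str  # "roc" | "prc"


@dataclass
class MetricsReport:
    subject_id: str
    dsc: float
    precision: float
    recall: float
    specificity: float
    asd_mm: float
    msd_mm: float
    ap: float = UNDEFINED


# ---------------------------------------------------------------------------
# Confusion-based metrics
# ---------------------------------------------------------------------------

def confusion(pred: LabelMask, gt: LabelMask) -> ConfusionCounts:
    if pred.shape != gt.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs gt {gt.shape}")
    p = pred.data.astype(bool)
    g = gt.data.astype(bool)
    tp = int(np.count_nonzero(p & g))
    fp = int(np.count_nonzero(p & ~g))
    fn = int(np.count_nonzero(~p & g))
    tn = int(np.count_nonzero(~p & ~g))
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)


def dsc(c: ConfusionCounts) -> float:
    denom = c.fp + 2 * c.tp + c.fn
    if denom == 0:
        warnings.warn("both masks empty; DSC defined as 1.0 by convention")
        return 1.0
    return 2.0 * c.tp / denom


def recall(c: ConfusionCounts) -> float:
    denom = c.tp + c.fn
    return c.tp / denom if denom else UNDEFINED


def specificity(c: ConfusionCounts) -> float:
    denom = c.tn + c.fp
    return c.tn / denom if denom else UNDEFINED


def precision(c: ConfusionCounts) -> float:
    denom = c.tp + c.fp
    return c.tp / denom if denom else UNDEFINED


# ---------------------------------------------------------------------------
# Surface distances
# ---------------------------------------------------------------------------

_FACE_STRUCTURE = ndimage.generate_binary_structure(3, 1)


def surface_voxels(m: LabelMask) -> SurfaceSet:
    """Foreground voxels with at least one face-adjacent background or
    out-of-grid neighbor."""
    fg = m.data.astype(bool)
    if not fg.any():
        raise ValueError("surface of an empty mask is undefined")
    interior = ndimage.binary_erosion(fg, structure=_FACE_STRUCTURE, border_value=0)
    surf = fg & ~interior
    return SurfaceSet(coords=np.argwhere(surf), spacing=m.spacing)


def _surface_distance_sums(pred: LabelMask, gt: LabelMask) -> Tuple[float, float, float, float, int, int]:
    """(sum_S, sum_G, max_S, max_G, N_S, N_G) of nearest-surface distances."""
    if pred.shape != gt.shape:
        raise ValueError("shape mismatch")
    if pred.spacing != gt.spacing:
        raise ValueError("spacing mismatch")
    s_set = surface_voxels(pred)
    g_set = surface_voxels(gt)
    spacing = pred.spacing

    def surf_grid(ss: SurfaceSet) -> np.ndarray:
        grid = np.zeros(pred.shape, dtype=bool)
        grid[tuple(ss.coords.T)] = True
        return grid

    # exact Euclidean distance of every voxel center to the nearest surface voxel
    dt_to_g = ndimage.distance_transform_edt(~surf_grid(g_set), sampling=spacing)
    dt_to_s = ndimage.distance_transform_edt(~surf_grid(s_set), sampling=spacing)
    d_s = dt_to_g[tuple(s_set.coords.T)]
    d_g = dt_to_s[tuple(g_set.coords.T)]
    return (float(d_s.sum()), float(d_g.sum()), float(d_s.max()), float(d_g.max()),
            len(s_set), len(g_set))


def asd(pred: LabelMask, gt: LabelMask) -> float:
    """Average symmetric surface distance in mm."""
    if pred.data.sum() == 0 or gt.data.sum() == 0:
        return UNDEFINED
    sum_s, sum_g, _, _, n_s, n_g = _surface_distance_sums(pred, gt)
    return (sum_s + sum_g) / (n_s + n_g)


def msd(pred: LabelMask, gt: LabelMask) -> float:
    """Maximum symmetric surface distance (symmetric Hausdorff) in mm."""
    if pred.data.sum() == 0 or gt.data.sum() == 0:
        return UNDEFINED
    _, _, max_s, max_g, _, _ = _surface_distance_sums(pred, gt)
    return max(max_s, max_g)


# ---------------------------------------------------------------------------
# Curves
# ---------------------------------------------------------------------------

def _pool(p, gt) -> Tuple[np.ndarray, np.ndarray]:
    if isinstance(p, (list, tuple)):
        scores = np.concatenate([np.asarray(x.data, dtype=np.float64).ravel() for x in p])
        labels = np.concatenate([m.data.ravel() for m in gt])
    else:
        scores = np.asarray(p.data, dtype=np.float64).ravel()
        labels = gt.data.ravel()
    return scores, labels.astype(np.int64)


def curves(p, gt) -> Tuple[CurveResult, CurveResult]:
    """ROC and PRC over all pooled voxels. Thresholds are the unique
    probability values in descending order; ROC area is trapezoidal over
    (FPR, TPR), PRC area (AP) is the step-wise sum Σ (R_k − R_{k−1}) · P_k."""
    scores, labels = _pool(p, gt)
    if scores.shape != labels.shape:
        raise ValueError("probability and ground-truth sizes differ")
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ground truth must contain both classes")

    order = np.argsort(-scores, kind="stable")
    s_sorted = scores[order]
    l_sorted = labels[order]
    tp_cum = np.cumsum(l_sorted)
    fp_cum = np.cumsum(1 - l_sorted)
    # last index of each distinct threshold
    distinct = np.r_[np.flatnonzero(np.diff(s_sorted)), s_sorted.size - 1]
    thresholds = s_sorted[distinct]
    tp = tp_cum[distinct].astype(np.float64)
    fp = fp_cum[distinct].astype(np.float64)
    tpr = tp / n_pos
    fpr = fp / n_neg
    prec = tp / np.maximum(tp + fp, 1)
    spec = 1.0 - fpr

    auc = float(np.trapezoid(np.r_[0.0, tpr], np.r_[0.0, fpr]))
    rec_steps = np.diff(np.r_[0.0, tpr])
    ap = float(np.sum(rec_steps * prec))

    roc = CurveResult(thresholds=thresholds, precision=prec, recall=tpr,
                      fpr=fpr, specificity=spec, area=auc, kind="roc")
    prc = CurveResult(thresholds=thresholds, precision=prec, recall=tpr,
                      fpr=fpr, specificity=spec, area=ap, kind="prc")
    return roc, prc


def average_precision(p, gt) -> float:
    """Step-wise area under the precision-recall curve of pooled voxels."""
    _, prc = curves(p, gt)
    return prc.area


def mean_curves(fold_probs: Sequence, fold_gts: Sequence,
                n_grid: int = 512) -> Tuple[CurveResult, CurveResult]:
    """Cross-validation mean curves (figure-style aggregation).

    Each fold's pooled ROC/PRC is interpolated onto a common abscissa grid
    (FPR for ROC, recall for PRC) and the ordinates averaged. The mean ROC
    area is the trapezoidal area of the averaged curve; the mean PRC area is
    the mean of the per-fold step-wise APs. The ``thresholds`` field of the
    returned curves holds the abscissa grid, not probability thresholds.
    """
    if len(fold_probs) != len(fold_gts) or not fold_probs:
        raise ValueError("need one (probabilities, ground truth) pair per fold")
    grid = np.linspace(0.0, 1.0, n_grid)
    tprs, precs, aps = [], [], []
    for p, g in zip(fold_probs, fold_gts):
        roc, prc = curves(p, g)
        tprs.append(np.interp(grid, np.r_[0.0, roc.fpr], np.r_[0.0, roc.recall]))
        order = np.argsort(prc.recall, kind="stable")
        precs.append(np.interp(grid, prc.recall[order], prc.precision[order]))
        aps.append(prc.area)
    tpr_mean = np.mean(tprs, axis=0)
    prec_mean = np.mean(precs, axis=0)
    roc_mean = CurveResult(thresholds=grid, precision=prec_mean, recall=tpr_mean,
                           fpr=grid, specificity=1.0 - grid,
                           area=float(np.trapezoid(tpr_mean, grid)), kind="roc")
    prc_mean = CurveResult(thresholds=grid, precision=prec_mean, recall=grid,
                           fpr=np.full_like(grid, UNDEFINED),
                           specificity=np.full_like(grid, UNDEFINED),
                           area=float(np.mean(aps)), kind="prc")
    return roc_mean, prc_mean


def optimal_threshold(prc: CurveResult) -> float:
    """Threshold of the PRC point with the smallest Euclidean distance to
    maximum precision and recall (1, 1); ties favor the lowest threshold."""
    if prc.thresholds.size == 0:
        raise ValueError("empty curve")
    d2 = (1.0 - prc.precision) ** 2 + (1.0 - prc.recall) ** 2
    best = d2.min()
    idx = np.flatnonzero(np.isclose(d2, best, rtol=0, atol=1e-12))
    # thresholds are descending, so the last tied index has the lowest threshold
    return float(prc.thresholds[idx[-1]])


# ---------------------------------------------------------------------------
# Paired model comparison
# ---------------------------------------------------------------------------

def holm_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Holm step-down adjustment: sorted ascending, adjusted
    p_(i) = max_{j <= i} (m - j + 1) * p_(j), capped at 1."""
    p = np.asarray(pvalues, dtype=np.float64)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj_sorted = np.maximum.accumulate((m - np.arange(m)) * p[order])
    adj = np.empty(m)
    adj[order] = np.minimum(adj_sorted, 1.0)
    return adj


def significance_code(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def _paired_wilcoxon(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided paired Wilcoxon signed-rank p-value: exact null for n <= 25
    without ties, normal approximation with tie and continuity correction
    otherwise; zero differences discarded."""
    d = np.asarray(a, dtype=np.float64) - np.asarray(b, dtype=np.float64)
    d = d[d != 0]
    if d.size == 0:
        warnings.warn("all paired differences are zero; p = 1")
        return 1.0
    ranks_tied = len(np.unique(np.abs(d))) < d.size
    method = "exact" if (d.size <= 25 and not ranks_tied) else "approx"
    res = stats.wilcoxon(d, zero_method="wilcox", alternative="two-sided",
                         correction=(method == "approx"), method=method)
    return float(res.pvalue)


def wilcoxon_holm(scores: pd.DataFrame) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise two-sided paired Wilcoxon signed-rank tests over the model
    columns of a subjects x models table, Holm-corrected across all pairs.

    Returns (adjusted p-value matrix, significance-code matrix).
    """
    if scores.shape[0] < 6:
        raise ValueError("need at least 6 subjects for the signed-rank test")
    models = list(scores.columns)
    if len(models) < 2:
        raise ValueError("need at least 2 models to compare")
    pairs = [(i, j) for i in range(len(models)) for j in range(i + 1, len(models))]
    raw = [_paired_wilcoxon(scores[models[i]].to_numpy(), scores[models[j]].to_numpy())
           for i, j in pairs]
    adj = holm_adjust(raw)
    pmat = pd.DataFrame(np.ones((len(models), len(models))), index=models, columns=models)
    cmat = pd.DataFrame("", index=models, columns=models)
    for (i, j), p_adj in zip(pairs, adj):
        pmat.iloc[i, j] = pmat.iloc[j, i] = p_adj
        cmat.iloc[i, j] = cmat.iloc[j, i] = significance_code(p_adj)
    for i in range(len(models)):
        cmat.iloc[i, i] = "ns"
    return pmat, cmat


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------

def subject_report(p: Optional[ProbabilityMap], pred: LabelMask, gt: LabelMask) -> MetricsReport:
    """Assemble all per-subject metrics (AP only when a probability map is
    supplied)."""
    c = confusion(pred, gt)
    ap = UNDEFINED
    if p is not None:
        try:
            ap = average_precision(p, gt)
        except ValueError:
            pass
    return MetricsReport(
        subject_id=gt.subject_id or pred.subject_id,
        dsc=dsc(c), precision=precision(c), recall=recall(c),
        specificity=specificity(c), asd_mm=asd(pred, gt), msd_mm=msd(pred, gt),
        ap=ap)


def reports_to_frame(reports: Sequence[MetricsReport]) -> pd.DataFrame:
    return pd.DataFrame([{
        "subject_id": r.subject_id, "dsc": r.dsc, "precision": r.precision,
        "recall": r.recall, "specificity": r.specificity, "asd_mm": r.asd_mm,
        "msd_mm": r.msd_mm, "ap": r.ap} for r in reports])


def aggregate_mean_sd(frame: pd.DataFrame) -> pd.DataFrame:
    """Mean ± SD per metric over subjects, excluding undefined entries
    (their count is reported)."""
    rows = []
    for col in frame.columns:
        if col == "subject_id":
            continue
        vals = frame[col].to_numpy(dtype=float)
        ok = np.isfinite(vals)
        rows.append({"metric": col, "mean": float(np.mean(vals[ok])) if ok.any() else UNDEFINED,
                     "sd": float(np.std(vals[ok], ddof=1)) if ok.sum() > 1 else UNDEFINED,
                     "n": int(ok.sum()), "n_undefined": int((~ok).sum())})
    return pd.DataFrame(rows)


def aggregate_median_iqr(values: Sequence[float]) -> Tuple[float, float]:
    """Median and interquartile range (AP-style aggregation)."""
    vals = np.asarray([v for v in values if np.isfinite(v)], dtype=float)
    if vals.size == 0:
        return UNDEFINED, UNDEFINED
    q1, med, q3 = np.percentile(vals, [25, 50, 75])
    return float(med), float(q3 - q1)
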