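"""Evaluation metrics: image similarity, lesion-wise detection, statistics.

Image similarity between a real volume y and its synthetic approximation is
measured locally by the median absolute error

    MAE(y, yhat) = median |y - yhat|        (over in-mask voxels)

and globally by the three-factor structural similarity index

    SSIM = l(y, yhat) * c(y, yhat) * s(y, yhat)

with luminance l = (2 mu_y mu_yh + c1) / (mu_y^2 + mu_yh^2 + c1),
contrast  c = (2 sd_y sd_yh + c2) / (sd_y^2 + sd_yh^2 + c2) and
structure s = (cov + c3) / (sd_y sd_yh + c3), computed once from global
in-mask statistics (not in sliding windows).

Detection is scored lesion-wise: a ground-truth component counts as a true
positive if at least one of its voxels overlaps any predicted component;
sensitivity = TP/(TP+FN), FDR = FP/(FP+TP), precision = TP/(TP+FP).
Undefined ratios (0/0) are reported as NaN and dropped pairwise from the
Wilcoxon signed-rank comparison.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage, stats

from .volumes import Volume


# ---------------------------------------------------------------------------
# image similarity


def _as_data(x) -> np.ndarray:
    return x.data if isinstance(x, Volume) else np.asarray(x)


def _resolve_mask(y, yhat, mask) -> np.ndarray:
    yd, yh = _as_data(y), _as_data(yhat)
    if yd.shape != yh.shape:
        raise ValueError("volumes must share the grid")
    if mask is None:
        if isinstance(y, Volume) and y.mask is not None:
            mask = y.mask
        else:
            mask = np.ones(yd.shape, dtype=bool)
    mask = _as_data(mask).astype(bool)
    if mask.shape != yd.shape:
        raise ValueError("mask must share the grid")
    if not mask.any():
        raise ValueError("empty mask")
    return mask


def mae(y, yhat, mask=None) -> float:
    """Median absolute voxel error over the mask (lower is more similar)."""
    m = _resolve_mask(y, yhat, mask)
    return float(np.median(np.abs(_as_data(y)[m] - _as_data(yhat)[m])))


@dataclasses.dataclass
class SsimConstants:
    """Stabilizers of the SSIM factors; defaults are the metric's universal
    (0.01 L)^2 / (0.03 L)^2 choice with dynamic range L = 1 for [0,1] images
    and c3 = c2 / 2."""

    dynamic_range: float = 1.0
    c1: float = dataclasses.field(default=None)  # type: ignore[assignment]
    c2: float = dataclasses.field(default=None)  # type: ignore[assignment]
    c3: float = dataclasses.field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        L = self.dynamic_range
        if self.c1 is None:
            self.c1 = (0.01 * L) ** 2
        if self.c2 is None:
            self.c2 = (0.03 * L) ** 2
        if self.c3 is None:
            self.c3 = self.c2 / 2.0
        if min(self.c1, self.c2, self.c3) <= 0:
            raise ValueError("SSIM stabilizers must be strictly positive")


def ssim(y, yhat, mask=None, k: Optional[SsimConstants] = None) -> float:
    """Global three-factor SSIM over in-mask voxels; 1 iff identical (up to
    the stabilizers), negative when the images are anti-correlated."""
    if k is None:
        k = SsimConstants()
    m = _resolve_mask(y, yhat, mask)
    a = _as_data(y)[m].astype(np.float64)
    b = _as_data(yhat)[m].astype(np.float64)
    mu_a, mu_b = a.mean(), b.mean()
    sd_a, sd_b = a.std(), b.std()
    cov = ((a - mu_a) * (b - mu_b)).mean()
    lum = (2 * mu_a * mu_b + k.c1) / (mu_a**2 + mu_b**2 + k.c1)
    con = (2 * sd_a * sd_b + k.c2) / (sd_a**2 + sd_b**2 + k.c2)
    stru = (cov + k.c3) / (sd_a * sd_b + k.c3)
    return float(lum * con * stru)


def ssim_windowed(y, yhat, mask=None, k: Optional[SsimConstants] = None) -> float:
    """Sliding-window SSIM variant (cross-check only; the headline metric in
    this package is the global :func:`ssim`)."""
    from skimage.metrics import structural_similarity

    if k is None:
        k = SsimConstants()
    a, b = _as_data(y), _as_data(yhat)
    full = structural_similarity(
        a.astype(np.float64),
        b.astype(np.float64),
        data_range=k.dynamic_range,
        full=True,
    )[1]
    m = _resolve_mask(y, yhat, mask)
    return float(full[m].mean())


# ---------------------------------------------------------------------------
# lesion-wise detection


def label_components(mask, connectivity: int = 26) -> np.ndarray:
    """Connected-component labeling of a binary mask (26-connectivity)."""
    structure = np.ones((3, 3, 3)) if connectivity == 26 else None
    data = _as_data(mask) > 0
    labels, _ = ndimage.label(data, structure=structure)
    return labels


def match_lesions(pred, gt) -> Tuple[int, int, int]:
    """Lesion-wise (TP, FP, FN) under the one-voxel-overlap rule.

    ``pred`` and ``gt`` are integer component-labeled masks (0 background).
    A ground-truth component overlapping >= 1 predicted voxel is TP, else FN;
    a predicted component overlapping no ground-truth voxel is FP.
    """
    p = _as_data(pred).astype(np.int64)
    g = _as_data(gt).astype(np.int64)
    if p.shape != g.shape:
        raise ValueError("grids do not match")
    gt_ids = np.unique(g[g > 0])
    pred_ids = np.unique(p[p > 0])
    overlap = (p > 0) & (g > 0)
    hit_gt = np.unique(g[overlap])
    hit_pred = np.unique(p[overlap])
    tp = len(hit_gt)
    fn = len(gt_ids) - tp
    fp = len(pred_ids) - len(hit_pred)
    return int(tp), int(fp), int(fn)


@dataclasses.dataclass
class DetectionScores:
    """Per-case lesion-wise counts with derived ratios (NaN when undefined)."""

    tp: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def sensitivity(self) -> float:
        d = self.tp + self.fn
        return self.tp / d if d > 0 else math.nan

    @property
    def fdr(self) -> float:
        d = self.tp + self.fp
        return self.fp / d if d > 0 else math.nan

    @property
    def precision(self) -> float:
        d = self.tp + self.fp
        return self.tp / d if d > 0 else math.nan

    @property
    def is_stable(self) -> bool:
        """True when the case has no ground-truth lesion."""
        return self.tp + self.fn == 0


def detection_scores(tp: int, fp: int, fn: int) -> DetectionScores:
    return DetectionScores(tp=tp, fp=fp, fn=fn)


def pooled_scores(per_case: Sequence[DetectionScores]) -> DetectionScores:
    """Counts pooled over cases (lesion-level aggregate)."""
    return DetectionScores(
        tp=sum(s.tp for s in per_case),
        fp=sum(s.fp for s in per_case),
        fn=sum(s.fn for s in per_case),
    )


def fp_case_count(per_case: Sequence[DetectionScores]) -> Tuple[int, int]:
    """(count, integer percent) of stable cases with any false positive."""
    if len(per_case) == 0:
        raise ValueError("empty score list")
    if any(not s.is_stable for s in per_case):
        raise ValueError("fp_case_count expects stable cases only (tp+fn == 0)")
    n_fp = sum(1 for s in per_case if s.fp > 0)
    return n_fp, int(round(100.0 * n_fp / len(per_case)))


# ---------------------------------------------------------------------------
# paired statistics


def compare_models(scores_a: Sequence[float], scores_b: Sequence[float]) -> float:
    """Two-sided Wilcoxon signed-rank p-value on paired per-case scores.

    NaN (undefined-metric) cases are dropped pairwise; zero differences are
    dropped; exact null distribution for n <= 25 remaining pairs, normal
    approximation with tie correction beyond. Returns 1.0 when every
    difference is zero.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired score lists must have equal length")
    keep = ~(np.isnan(a) | np.isnan(b))
    a, b = a[keep], b[keep]
    if len(a) < 6:
        raise ValueError("need >= 6 defined pairs for the signed-rank test")
    d = a - b
    d = d[d != 0.0]
    if len(d) == 0:
        return 1.0
    method = "exact" if len(d) <= 25 else "approx"
    res = stats.wilcoxon(d, alternative="two-sided", method=method)
    return float(res.pvalue)


def aggregate(values: Sequence[float], drop_undefined: bool = True) -> Tuple[float, float]:
    """Mean +/- SD over per-case values; NaNs dropped (default) or zero-filled."""
    v = np.asarray(values, dtype=float)
    if drop_undefined:
        v = v[~np.isnan(v)]
    else:
        v = np.nan_to_num(v, nan=0.0)
    if len(v) == 0:
        return math.nan, math.nan
    return float(v.mean()), float(v.std())
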