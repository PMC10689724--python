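"""Voxel- and lesion-wise segmentation evaluation.

Implements the standard MS-lesion evaluation suite: Dice-Sorensen
coefficient, Jaccard, positive predictive value, true positive rate,
absolute volume difference, lesion-wise TPR/FPR over 3D connected
components, and the ISBI-style composite challenge score on a 0-100
scale.

Empty-mask conventions: rates whose denominator is empty (TPR and VD
with an empty ground truth, PPV with an empty prediction, the lesion
rates with no lesions) are reported as NaN sentinels rather than being
silently substituted with 0 or 1, so that aggregation choices stay
explicit.
"""

from __future__ import annotations

import dataclasses
import math
from collections.abc import Sequence

import numpy as np
from scipy import ndimage

#: connected-component connectivity for 3D lesions: 6, 18 (default) or 26
DEFAULT_CONNECTIVITY = 18
_CONN_RANK = {6: 1, 18: 2, 26: 3}

#: composite challenge-score weights (DSC, PPV, LTPR, 1-LFPR, volume corr)
SCORE_WEIGHTS = {
    "dsc": 1 / 8,
    "ppv": 1 / 8,
    "ltpr": 1 / 4,
    "one_minus_lfpr": 1 / 4,
    "volume_correlation": 1 / 4,
}


@dataclasses.dataclass
class MetricsReport:
    """All evaluation quantities for one (prediction, ground-truth) pair."""

    dsc: float
    jaccard: float
    ppv: float
    tpr: float
    vd: float
    ltpr: float
    lfpr: float
    n_gt_lesions: int
    n_pred_lesions: int
    n_detected_lesions: int
    n_false_positive_lesions: int
    pred_volume: int
    gt_volume: int

    def as_dict(self) -> dict[str, float]:
        return dataclasses.asdict(self)


def _check_pair(pred: np.ndarray, gt: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    pred = np.asarray(pred)
    gt = np.asarray(gt)
    if pred.shape != gt.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {gt.shape}")
    for name, m in (("pred", pred), ("gt", gt)):
        if not np.isin(np.unique(m), (0, 1)).all():
            raise ValueError(f"{name} mask is not binary")
    return pred.astype(bool), gt.astype(bool)


def voxel_metrics(pred, gt) -> tuple[float, float, float, float, float]:
    """Return (dsc, jaccard, ppv, tpr, vd) for two binary masks.

    dsc = 2|P&G| / (|P|+|G|); jaccard = |P&G| / |P|G|union;
    ppv = |P&G|/|P|; tpr = |P&G|/|G|; vd = ||P|-|G|| / |G|.
    Undefined ratios (empty denominators) come back as NaN.
    """
    p, g = _check_pair(pred, gt)
    np_, ng = int(p.sum()), int(g.sum())
    inter = int((p & g).sum())
    union = np_ + ng - inter
    dsc = 2.0 * inter / (np_ + ng) if (np_ + ng) else math.nan
    jac = inter / union if union else math.nan
    ppv = inter / np_ if np_ else math.nan
    tpr = inter / ng if ng else math.nan
    vd = abs(np_ - ng) / ng if ng else math.nan
    return dsc, jac, ppv, tpr, vd


def lesion_components(
    mask, connectivity: int = DEFAULT_CONNECTIVITY
) -> tuple[np.ndarray, int]:
    """Label 3D connected components of a binary mask.

    Labels are stable: components are numbered by the scan-order position
    of their first voxel, starting at 1.
    """
    if connectivity not in _CONN_RANK:
        raise ValueError("connectivity must be one of 6, 18, 26")
    arr = np.asarray(mask).astype(bool)
    structure = ndimage.generate_binary_structure(3, _CONN_RANK[connectivity])
    labeled, n = ndimage.label(arr, structure=structure)
    # scipy already labels in scan order of first voxel; keep as-is
    return labeled, int(n)


def lesion_metrics(
    pred, gt, connectivity: int = DEFAULT_CONNECTIVITY
) -> tuple[float, float, dict[str, int]]:
    """Lesion-wise detection rates via connected-component overlap.

    A ground-truth lesion counts as detected when at least one of its
    voxels is predicted; a predicted lesion is false positive when none
    of its voxels overlaps the ground truth.
    """
    p, g = _check_pair(pred, gt)
    gt_lab, n_gt = lesion_components(g, connectivity)
    pr_lab, n_pr = lesion_components(p, connectivity)

    detected = 0
    for i in range(1, n_gt + 1):
        if p[gt_lab == i].any():
            detected += 1
    false_pos = 0
    for j in range(1, n_pr + 1):
        if not g[pr_lab == j].any():
            false_pos += 1

    ltpr = detected / n_gt if n_gt else math.nan
    lfpr = false_pos / n_pr if n_pr else math.nan
    counts = {
        "n_gt_lesions": n_gt,
        "n_pred_lesions": n_pr,
        "n_detected_lesions": detected,
        "n_false_positive_lesions": false_pos,
    }
    return ltpr, lfpr, counts


def evaluate_pair(
    pred, gt, connectivity: int = DEFAULT_CONNECTIVITY
) -> MetricsReport:
    """Full metric report for one (prediction, ground truth) volume pair."""
    dsc, jac, ppv, tpr, vd = voxel_metrics(pred, gt)
    ltpr, lfpr, counts = lesion_metrics(pred, gt, connectivity)
    p, g = _check_pair(pred, gt)
    return MetricsReport(
        dsc=dsc, jaccard=jac, ppv=ppv, tpr=tpr, vd=vd,
        ltpr=ltpr, lfpr=lfpr,
        pred_volume=int(p.sum()), gt_volume=int(g.sum()),
        **counts,
    )


def challenge_score(
    reports: Sequence[MetricsReport],
    weights: dict[str, float] | None = None,
) -> float:
    """ISBI-style composite score over a set of scans, on a 0-100 scale.

    The composite averages DSC and PPV at weight 1/8 each, LTPR and
    (1 - LFPR) at 1/4 each, and the Pearson correlation between predicted
    and ground-truth lesion volumes across scans at 1/4, scaled by 100.
    With a single scan the correlation term is undefined; it is dropped
    and the remaining weights renormalized.  NaN component metrics are
    averaged over the scans where they are defined.
    """
    if not reports:
        raise ValueError("challenge_score requires at least one report")
    w = dict(SCORE_WEIGHTS if weights is None else weights)

    def nanmean(vals):
        vals = [v for v in vals if not math.isnan(v)]
        return sum(vals) / len(vals) if vals else math.nan

    comps = {
        "dsc": nanmean([r.dsc for r in reports]),
        "ppv": nanmean([r.ppv for r in reports]),
        "ltpr": nanmean([r.ltpr for r in reports]),
        "one_minus_lfpr": nanmean([1.0 - r.lfpr for r in reports]),
    }
    if len(reports) >= 2:
        pv = np.array([r.pred_volume for r in reports], dtype=float)
        gv = np.array([r.gt_volume for r in reports], dtype=float)
        if pv.std() > 0 and gv.std() > 0:
            comps["volume_correlation"] = float(np.corrcoef(pv, gv)[0, 1])
        else:
            comps["volume_correlation"] = 1.0 if np.allclose(pv, gv) else 0.0
    else:
        import warnings

        warnings.warn(
            "single-scan input: volume-correlation term omitted and "
            "weights renormalized",
            stacklevel=2,
        )
        w.pop("volume_correlation", None)

    total_w = sum(w.values())
    score = sum(w[k] * comps[k] for k in w) / total_w
    return 100.0 * score


def bootstrap_ci(
    values: Sequence[float],
    n_boot: int = 2000,
    alpha: float = 0.05,
    seed: int = 0,
) -> tuple[float, float]:
    """Percentile bootstrap confidence interval for a mean metric."""
    vals = np.asarray([v for v in values if not math.isnan(v)], dtype=float)
    if vals.size == 0:
        return math.nan, math.nan
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, vals.size, size=(n_boot, vals.size))
    means = vals[idx].mean(axis=1)
    lo, hi = np.quantile(means, [alpha / 2, 1 - alpha / 2])
    return float(lo), float(hi)
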