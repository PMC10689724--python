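"""Independent brute-force oracles used by the test suite.

These deliberately avoid the library's own code paths: voxel metrics via
Python set arithmetic, connected components via flood fill over explicit
neighbourhood offsets, and checkpoint selection by materializing every
window with its variance and full preference order.
"""

import itertools
import math

import numpy as np


def oracle_voxel_metrics(pred, gt):
    p = {tuple(i) for i in np.argwhere(pred)}
    g = {tuple(i) for i in np.argwhere(gt)}
    inter = len(p & g)
    union = len(p | g)
    dsc = 2 * inter / (len(p) + len(g)) if p or g else math.nan
    jac = inter / union if union else math.nan
    ppv = inter / len(p) if p else math.nan
    tpr = inter / len(g) if g else math.nan
    vd = abs(len(p) - len(g)) / len(g) if g else math.nan
    return dsc, jac, ppv, tpr, vd


def neighbourhood_offsets(connectivity):
    offs = []
    for d in itertools.product((-1, 0, 1), repeat=3):
        if d == (0, 0, 0):
            continue
        manhattan = sum(abs(x) for x in d)
        if connectivity == 6 and manhattan > 1:
            continue
        if connectivity == 18 and manhattan > 2:
            continue
        offs.append(d)
    return offs


def oracle_components(mask, connectivity):
    offs = neighbourhood_offsets(connectivity)
    voxels = {tuple(i) for i in np.argwhere(mask)}
    comps = []
    seen = set()
    for v in sorted(voxels):
        if v in seen:
            continue
        comp = set()
        stack = [v]
        while stack:
            u = stack.pop()
            if u in comp:
                continue
            comp.add(u)
            for d in offs:
                w = tuple(a + b for a, b in zip(u, d))
                if w in voxels and w not in comp:
                    stack.append(w)
        seen |= comp
        comps.append(comp)
    return comps


def oracle_lesion_metrics(pred, gt, connectivity):
    gcomps = oracle_components(gt, connectivity)
    pcomps = oracle_components(pred, connectivity)
    pvox = {tuple(i) for i in np.argwhere(pred)}
    gvox = {tuple(i) for i in np.argwhere(gt)}
    detected = sum(1 for c in gcomps if c & pvox)
    fps = sum(1 for c in pcomps if not (c & gvox))
    ltpr = detected / len(gcomps) if gcomps else math.nan
    lfpr = fps / len(pcomps) if pcomps else math.nan
    return ltpr, lfpr, len(gcomps), len(pcomps), detected, fps


def oracle_select_checkpoint(losses, saved, window, span):
    """Materialize every window, its variance, and the preference order."""
    n = len(losses)
    start = n - span
    seg = np.asarray(losses[start:], dtype=float)
    seg_saved = np.asarray(saved[start:], dtype=bool)
    windows = []
    for i in range(span - window + 1):
        windows.append((seg[i : i + window].var(), -i, i))
    for _, _, wi in sorted(windows):
        prefs = sorted(
            (seg[wi + j], -(wi + j), wi + j) for j in range(window)
        )
        for _, _, e in prefs:
            if seg_saved[e]:
                return start + e
    raise RuntimeError("no checkpoint available in span")


def nan_eq(a, b, tol=1e-12):
    return (math.isnan(a) and math.isnan(b)) or abs(a - b) <= tol
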