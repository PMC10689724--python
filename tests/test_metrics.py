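"""Metric suite vs brute-force set/component oracles."""

import math

import numpy as np
import pytest

from mslesseg.metrics import (
    MetricsReport,
    bootstrap_ci,
    challenge_score,
    evaluate_pair,
    lesion_components,
    lesion_metrics,
    voxel_metrics,
)

from oracles import (  # noqa: E402
    oracle_lesion_metrics as _oracle_lesion,
    oracle_voxel_metrics as _oracle_voxel,
)


def _eq(a, b):
    return (math.isnan(a) and math.isnan(b)) or a == pytest.approx(b)


# ------------------------------------------------------------------ tests


def test_identical_masks_are_perfect():
    m = np.zeros((5, 5, 5), dtype=np.uint8)
    m[1:3, 1:3, 1:3] = 1
    dsc, jac, ppv, tpr, vd = voxel_metrics(m, m)
    assert (dsc, jac, ppv, tpr, vd) == (1.0, 1.0, 1.0, 1.0, 0.0)


def test_worked_overlap_example():
    """|P|=6, |G|=4, |P&G|=2 -> dsc .4, jac .25, ppv 1/3, tpr .5, vd .5."""
    p = np.zeros((3, 3, 3), dtype=np.uint8)
    g = np.zeros((3, 3, 3), dtype=np.uint8)
    p.flat[:6] = 1
    g.flat[4:8] = 1
    dsc, jac, ppv, tpr, vd = voxel_metrics(p, g)
    assert dsc == pytest.approx(0.4)
    assert jac == pytest.approx(0.25)
    assert ppv == pytest.approx(1 / 3)
    assert tpr == pytest.approx(0.5)
    assert vd == pytest.approx(0.5)


def test_disjoint_masks_zero_dice():
    p = np.zeros((4, 4, 4), dtype=np.uint8)
    g = np.zeros((4, 4, 4), dtype=np.uint8)
    p[0, 0, 0] = 1
    g[3, 3, 3] = 1
    assert voxel_metrics(p, g)[0] == 0.0


def test_empty_gt_flags_sentinels():
    p = np.ones((3, 3, 3), dtype=np.uint8)
    g = np.zeros((3, 3, 3), dtype=np.uint8)
    dsc, jac, ppv, tpr, vd = voxel_metrics(p, g)
    assert math.isnan(tpr) and math.isnan(vd)
    assert ppv == 0.0


@pytest.mark.parametrize("connectivity,expected", [(18, 2), (26, 1)])
def test_corner_touching_voxels_split_by_connectivity(connectivity, expected):
    m = np.zeros((4, 4, 4), dtype=np.uint8)
    m[0, 0, 0] = 1
    m[1, 1, 1] = 1
    _, n = lesion_components(m, connectivity)
    assert n == expected


def test_face_adjacent_voxels_single_component():
    m = np.zeros((4, 4, 4), dtype=np.uint8)
    m[0, 0, 0] = 1
    m[0, 0, 1] = 1
    for conn in (6, 18, 26):
        assert lesion_components(m, conn)[1] == 1


def test_lesion_detection_rates_worked_example():
    """Two GT lesions; prediction covers one and adds a disjoint blob."""
    g = np.zeros((10, 10, 10), dtype=np.uint8)
    g[1:3, 1:3, 1:3] = 1
    g[6:8, 6:8, 6:8] = 1
    p = np.zeros_like(g)
    p[1:3, 1:3, 1:3] = 1
    p[6:8, 1:3, 6:8] = 1  # disjoint from both GT lesions
    ltpr, lfpr, counts = lesion_metrics(p, g)
    assert ltpr == pytest.approx(0.5)
    assert lfpr == pytest.approx(0.5)
    assert counts["n_gt_lesions"] == 2
    assert counts["n_pred_lesions"] == 2


def test_merged_prediction_detects_both_gt_lesions():
    g = np.zeros((10, 6, 6), dtype=np.uint8)
    g[1:3, 1:3, 1:3] = 1
    g[6:8, 1:3, 1:3] = 1
    p = np.zeros_like(g)
    p[1:8, 1:3, 1:3] = 1  # one component spanning both
    ltpr, lfpr, _ = lesion_metrics(p, g)
    assert ltpr == 1.0
    assert lfpr == 0.0


@pytest.mark.parametrize("connectivity", [6, 18, 26])
def test_oracle_equivalence_on_random_masks(connectivity):
    """Voxel and lesion metrics match brute-force enumeration (500+ pairs)."""
    rng = np.random.default_rng(2024)
    for trial in range(180):
        shape = tuple(rng.integers(3, 13, size=3))
        density = rng.uniform(0.05, 0.5)
        pred = (rng.random(shape) < density).astype(np.uint8)
        gt = (rng.random(shape) < density).astype(np.uint8)

        got = voxel_metrics(pred, gt)
        want = _oracle_voxel(pred, gt)
        assert all(_eq(a, b) for a, b in zip(got, want))

        ltpr, lfpr, counts = lesion_metrics(pred, gt, connectivity)
        oltpr, olfpr, ng, np_, det, fps = _oracle_lesion(pred, gt, connectivity)
        assert _eq(ltpr, oltpr) and _eq(lfpr, olfpr)
        assert counts["n_gt_lesions"] == ng
        assert counts["n_pred_lesions"] == np_
        assert counts["n_detected_lesions"] == det
        assert counts["n_false_positive_lesions"] == fps


def test_symmetry_and_bounds_properties():
    rng = np.random.default_rng(7)
    for _ in range(50):
        shape = tuple(rng.integers(3, 10, size=3))
        p = (rng.random(shape) < 0.3).astype(np.uint8)
        g = (rng.random(shape) < 0.3).astype(np.uint8)
        if not p.any() or not g.any():
            continue
        dsc_pg = voxel_metrics(p, g)[0]
        dsc_gp = voxel_metrics(g, p)[0]
        assert dsc_pg == pytest.approx(dsc_gp)
        assert voxel_metrics(p, g)[2] == pytest.approx(voxel_metrics(g, p)[3])
        dsc, jac = voxel_metrics(p, g)[:2]
        assert 0 <= jac <= dsc <= 1
        assert jac == pytest.approx(dsc / (2 - dsc))


def test_ltpr_monotone_under_prediction_growth():
    rng = np.random.default_rng(11)
    g = (rng.random((8, 8, 8)) < 0.2).astype(np.uint8)
    p = np.zeros_like(g)
    prev = 0.0
    lesion_voxels = np.argwhere(g)
    for i in range(0, len(lesion_voxels), 3):
        for v in lesion_voxels[i : i + 3]:
            p[tuple(v)] = 1
        ltpr = lesion_metrics(p, g)[0]
        assert ltpr >= prev - 1e-12
        prev = ltpr


def _mk_report(dsc, ppv, ltpr, lfpr, pv, gv):
    return MetricsReport(
        dsc=dsc, jaccard=dsc / (2 - dsc), ppv=ppv, tpr=ppv, vd=0.0,
        ltpr=ltpr, lfpr=lfpr, n_gt_lesions=3, n_pred_lesions=3,
        n_detected_lesions=2, n_false_positive_lesions=1,
        pred_volume=pv, gt_volume=gv,
    )


def test_challenge_score_perfect_is_100():
    reports = [
        _mk_report(1.0, 1.0, 1.0, 0.0, 10, 10),
        _mk_report(1.0, 1.0, 1.0, 0.0, 30, 30),
        _mk_report(1.0, 1.0, 1.0, 0.0, 50, 50),
    ]
    assert challenge_score(reports) == pytest.approx(100.0)


def test_challenge_score_matches_hand_computed_weighted_sum():
    reports = [
        _mk_report(0.8, 0.9, 0.7, 0.3, 10, 20),
        _mk_report(0.6, 0.7, 0.5, 0.5, 40, 35),
        _mk_report(0.7, 0.8, 0.6, 0.4, 25, 30),
    ]
    corr = float(np.corrcoef([10, 40, 25], [20, 35, 30])[0, 1])
    expected = 100 * (
        0.7 / 8 + 0.8 / 8 + 0.6 / 4 + (1 - 0.4) / 4 + corr / 4
    )
    assert challenge_score(reports) == pytest.approx(expected)


def test_challenge_score_single_scan_renormalizes_with_warning():
    r = _mk_report(0.8, 0.9, 0.7, 0.3, 10, 20)
    with pytest.warns(UserWarning):
        score = challenge_score([r])
    expected = 100 * (0.8 / 8 + 0.9 / 8 + 0.7 / 4 + 0.7 / 4) / (3 / 4)
    assert score == pytest.approx(expected)


def test_evaluate_pair_report_consistency(small_phantom):
    _, _, mask = small_phantom
    rep = evaluate_pair(mask.data, mask.data)
    assert rep.dsc == 1.0 and rep.lfpr == 0.0 and rep.ltpr == 1.0
    assert rep.n_gt_lesions == rep.n_detected_lesions


def test_bootstrap_ci_brackets_mean():
    vals = [0.5, 0.6, 0.7, 0.8, 0.9]
    lo, hi = bootstrap_ci(vals, seed=1)
    assert lo <= float(np.mean(vals)) <= hi
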