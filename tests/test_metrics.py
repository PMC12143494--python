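"""Metric layer vs brute-force oracles, symmetry, bounds, aggregation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import retina_em as r
from retina_em.metrics import EmptyMaskError, evaluate_segmentation


# -- brute-force oracles -----------------------------------------------------

def brute_confusion(pred, gt, class_id):
    tp = fp = fn = tn = 0
    for p, g in zip(pred.ravel(), gt.ravel()):
        if p == class_id and g == class_id:
            tp += 1
        elif p == class_id:
            fp += 1
        elif g == class_id:
            fn += 1
        else:
            tn += 1
    return tp, fp, fn, tn


def brute_directed_hausdorff(a_mask, b_mask, spacing):
    a_pts = np.argwhere(a_mask)
    b_pts = np.argwhere(b_mask)
    sp = np.asarray(spacing, dtype=float)
    best = []
    for a in a_pts:
        d = np.sqrt((((b_pts - a) * sp) ** 2).sum(axis=1)).min()
        best.append(d)
    return max(best)


def brute_mean_nn_distance(a_mask, b_mask, spacing):
    a_pts = np.argwhere(a_mask)
    b_pts = np.argwhere(b_mask)
    sp = np.asarray(spacing, dtype=float)
    ds = [np.sqrt((((b_pts - a) * sp) ** 2).sum(axis=1)).min() for a in a_pts]
    return float(np.mean(ds))


def _random_masks(seed, shape=(6, 6), p=0.3):
    rng = np.random.default_rng(seed)
    pred = (rng.random(shape) < p)
    gt = (rng.random(shape) < p)
    return pred.astype(np.uint8), gt.astype(np.uint8)


# -- confusion / ratio metrics ----------------------------------------------

def test_confusion_perfect_prediction():
    gt = np.zeros((10, 10), dtype=np.uint8)
    gt[:2, :5] = 1
    assert r.confusion_counts(gt, gt, 1) == (10, 0, 0, 90)


def test_confusion_all_background_prediction():
    gt = np.zeros((4, 4), dtype=np.uint8)
    gt[0] = 1
    pred = np.zeros_like(gt)
    tp, fp, fn, tn = r.confusion_counts(pred, gt, 1)
    assert (tp, fp, fn, tn) == (0, 0, 4, 12)


def test_confusion_counts_sum_to_voxel_count():
    pred, gt = _random_masks(3)
    tp, fp, fn, tn = r.confusion_counts(pred, gt, 1)
    assert tp + fp + fn + tn == pred.size


def test_confusion_shape_mismatch():
    with pytest.raises(ValueError):
        r.confusion_counts(np.zeros((2, 2)), np.zeros((3, 3)), 1)


@pytest.mark.parametrize("seed", range(20))
def test_confusion_matches_brute_force(seed):
    pred, gt = _random_masks(seed)
    assert r.confusion_counts(pred, gt, 1) == brute_confusion(pred, gt, 1)


def test_semantic_scores_identical_masks():
    m = np.zeros((5, 5), dtype=np.uint8)
    m[1:3, 1:4] = 1
    s = r.semantic_scores(m, m, 1)
    assert all(v == 1.0 for v in s.values())


def test_semantic_scores_hand_counted_overlap():
    """4 predicted px, 4 true px, 2 overlapping on a 3x3 grid."""
    pred = np.array([[1, 1, 0], [1, 1, 0], [0, 0, 0]], dtype=np.uint8)
    gt = np.array([[0, 0, 0], [1, 1, 0], [1, 1, 0]], dtype=np.uint8)
    s = r.semantic_scores(pred, gt, 1)
    assert s["iou"] == pytest.approx(2 / 6)
    assert s["precision"] == pytest.approx(0.5)
    assert s["recall"] == pytest.approx(0.5)
    assert s["f_score"] == pytest.approx(0.5)


def test_semantic_scores_disjoint_masks_are_zero():
    pred = np.zeros((4, 4), dtype=np.uint8)
    pred[0, 0] = 1
    gt = np.zeros((4, 4), dtype=np.uint8)
    gt[3, 3] = 1
    s = r.semantic_scores(pred, gt, 1)
    assert all(v == 0.0 for v in s.values())


def test_semantic_scores_empty_empty_convention():
    z = np.zeros((3, 3), dtype=np.uint8)
    s = r.semantic_scores(z, z, 1)
    assert all(v == 1.0 for v in s.values())


def test_iou_symmetry_and_monotonicity():
    pred, gt = _random_masks(7, p=0.4)
    assert (r.semantic_scores(pred, gt, 1)["iou"] ==
            r.semantic_scores(gt, pred, 1)["iou"])
    # removing one false positive never decreases IoU
    fp_pos = np.argwhere((pred == 1) & (gt == 0))
    if len(fp_pos):
        pred2 = pred.copy()
        pred2[tuple(fp_pos[0])] = 0
        assert (r.semantic_scores(pred2, gt, 1)["iou"] >=
                r.semantic_scores(pred, gt, 1)["iou"])


# -- distance metrics --------------------------------------------------------

def test_mfd_identical_masks_is_zero():
    m = np.zeros((5, 5), dtype=np.uint8)
    m[2, 2] = 1
    assert r.mean_false_distance(m, m) == 0.0


def test_mfd_single_pixel_pair():
    pred = np.zeros((1, 5), dtype=np.uint8)
    pred[0, 0] = 1
    gt = np.zeros((1, 5), dtype=np.uint8)
    gt[0, 3] = 1
    assert r.mean_false_distance(pred, gt) == pytest.approx(3.0)


def test_mfd_empty_mask_raises():
    m = np.zeros((3, 3), dtype=np.uint8)
    full = np.ones_like(m)
    with pytest.raises(EmptyMaskError):
        r.mean_false_distance(m, full)


@pytest.mark.parametrize("seed", range(10))
def test_mfd_matches_brute_force(seed):
    rng = np.random.default_rng(seed + 100)
    pred = (rng.random((5, 5)) < 0.4).astype(np.uint8)
    gt = (rng.random((5, 5)) < 0.4).astype(np.uint8)
    if not pred.any() or not gt.any():
        pred[0, 0] = gt[4, 4] = 1
    expected = 0.5 * (brute_directed_hausdorff(pred, gt, (1, 1)) +
                      brute_directed_hausdorff(gt, pred, (1, 1)))
    assert r.mean_false_distance(pred, gt) == pytest.approx(expected, abs=1e-9)


def test_mfd_symmetric_under_swap():
    pred, gt = _random_masks(13, p=0.4)
    pred[0, 0] = gt[1, 1] = 1
    assert r.mean_false_distance(pred, gt) == pytest.approx(
        r.mean_false_distance(gt, pred))


def test_mfd_respects_anisotropic_spacing():
    pred = np.zeros((3, 1, 1), dtype=np.uint8)
    pred[0] = 1
    gt = np.zeros((3, 1, 1), dtype=np.uint8)
    gt[2] = 1
    assert r.mean_false_distance(pred, gt, spacing=(5, 1, 1)) == \
        pytest.approx(10.0)


# -- CREMI metrics -----------------------------------------------------------

def test_cremi_perfect_prediction():
    m = np.zeros((4, 4), dtype=np.uint8)
    m[1:3, 1:3] = 1
    block = r.cremi_scores(m, m)
    assert block["adgt"] == 0.0 and block["adf"] == 0.0
    assert block["cremi_score"] == 0.0
    assert block["fp"] == 0 and block["fn"] == 0
    assert block["one_minus_f"] == pytest.approx(0.0)


def test_cremi_single_pixel_pair():
    pred = np.zeros((1, 5), dtype=np.uint8)
    pred[0, 0] = 1
    gt = np.zeros((1, 5), dtype=np.uint8)
    gt[0, 4] = 1
    block = r.cremi_scores(pred, gt)
    assert block["adgt"] == pytest.approx(4.0)
    assert block["adf"] == pytest.approx(4.0)
    assert block["cremi_score"] == pytest.approx(4.0)


def test_cremi_empty_prediction_reports_missing_distances():
    gt = np.ones((3, 3), dtype=np.uint8)
    block = r.cremi_scores(np.zeros_like(gt), gt)
    assert block["adgt"] is None and block["adf"] is None
    assert block["cremi_score"] is None
    assert block["fn"] == 9


@pytest.mark.parametrize("seed", range(10))
def test_cremi_matches_brute_force(seed):
    rng = np.random.default_rng(seed + 50)
    pred = (rng.random((6, 6)) < 0.3).astype(np.uint8)
    gt = (rng.random((6, 6)) < 0.3).astype(np.uint8)
    if not pred.any() or not gt.any():
        pred[0, 0] = gt[5, 5] = 1
    block = r.cremi_scores(pred, gt)
    assert block["adgt"] == pytest.approx(
        brute_mean_nn_distance(pred, gt, (1, 1)), abs=1e-9)
    assert block["adf"] == pytest.approx(
        brute_mean_nn_distance(gt, pred, (1, 1)), abs=1e-9)


def test_cremi_adgt_is_adf_with_roles_swapped():
    pred, gt = _random_masks(31, p=0.4)
    pred[0, 0] = gt[2, 2] = 1
    assert r.cremi_scores(pred, gt)["adgt"] == pytest.approx(
        r.cremi_scores(gt, pred)["adf"])


# -- property-based oracle sweep --------------------------------------------

@settings(max_examples=100, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000))
def test_all_metrics_match_oracles_on_random_3d_masks(seed):
    rng = np.random.default_rng(seed)
    shape = (4, 8, 8)
    pred = (rng.random(shape) < 0.3).astype(np.uint8)
    gt = (rng.random(shape) < 0.3).astype(np.uint8)
    assert r.confusion_counts(pred, gt, 1) == brute_confusion(pred, gt, 1)
    s = r.semantic_scores(pred, gt, 1)
    assert 0.0 <= s["iou"] <= 1.0
    if s["precision"] + s["recall"] > 0:
        assert s["f_score"] == pytest.approx(
            2 * s["precision"] * s["recall"] / (s["precision"] + s["recall"]))
    if pred.any() and gt.any():
        sp = (2.0, 1.0, 1.0)
        expected = 0.5 * (brute_directed_hausdorff(pred, gt, sp) +
                          brute_directed_hausdorff(gt, pred, sp))
        assert r.mean_false_distance(pred, gt, sp) == \
            pytest.approx(expected, abs=1e-9)
        block = r.cremi_scores(pred, gt, sp)
        assert block["adgt"] == pytest.approx(
            brute_mean_nn_distance(pred, gt, sp), abs=1e-9)


# -- reports and aggregation -------------------------------------------------

def test_evaluate_segmentation_report_structure():
    gt = np.zeros((8, 8), dtype=np.uint8)
    gt[:4, :4] = 1
    gt[4:, 4:] = 2
    rep = evaluate_segmentation(gt, gt, n_classes=3)
    assert set(rep.per_class) == {1, 2}
    assert rep.mean_iou == 1.0
    assert rep.per_class[1]["mfd"] == 0.0
    d = rep.to_dict()
    assert d["mean_f"] == 1.0


def test_evaluate_segmentation_include_background_flag():
    gt = np.zeros((4, 4), dtype=np.uint8)
    gt[0, 0] = 1
    rep = evaluate_segmentation(gt, gt, n_classes=2, include_background=True)
    assert set(rep.per_class) == {0, 1}


def test_multitask_mean_reproduces_printed_task_average():
    """Mean of the four per-structure binary IoUs equals the task average."""
    tasks = [{"iou": 0.885}, {"iou": 0.890}, {"iou": 0.991}, {"iou": 0.910}]
    agg = r.aggregate(tasks, "mean_over_tasks")
    assert agg["iou"] == pytest.approx(0.919)


def test_aggregate_single_report_is_identity():
    rep = {"iou": 0.5, "f_score": 0.6}
    assert r.aggregate([rep], "mean_over_classes") == rep


def test_aggregate_simple_mean():
    assert r.aggregate([{"iou": 0.0}, {"iou": 1.0}],
                       "mean_over_tasks")["iou"] == 0.5


def test_aggregate_rejects_empty_and_unknown_scheme():
    with pytest.raises(ValueError):
        r.aggregate([], "mean_over_tasks")
    with pytest.raises(ValueError):
        r.aggregate([{"iou": 1.0}], "median")
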