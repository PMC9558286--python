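"""Metric formula identities, oracle equivalences, paired statistics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracles import brute_force_match, exact_signed_rank_p, flood_fill_label

from t1synth import metrics
from t1synth.metrics import (
    DetectionScores,
    SsimConstants,
    compare_models,
    detection_scores,
    fp_case_count,
    label_components,
    mae,
    match_lesions,
    ssim,
)
from t1synth.volumes import Volume


def _vol(data, mask=None):
    return Volume(np.asarray(data, np.float32), np.eye(4), mask)


# ---------------------------------------------------------------------------
# MAE


def test_mae_identities(rng):
    y = rng.random((10, 10, 10)).astype(np.float32)
    assert mae(y, y) == 0.0
    assert mae(y, np.clip(y + 0.2, None, None)) == pytest.approx(0.2, abs=1e-6)


def test_mae_equals_sort_based_median_oracle(rng):
    y = rng.random((10, 10, 10))
    yh = rng.random((10, 10, 10))
    diffs = np.sort(np.abs((y - yh).ravel()))
    n = diffs.size
    oracle = 0.5 * (diffs[n // 2 - 1] + diffs[n // 2])  # even count
    assert mae(y, yh) == pytest.approx(oracle, rel=0, abs=0)


def test_mae_empty_mask_raises(rng):
    y = rng.random((4, 4, 4))
    with pytest.raises(ValueError, match="empty mask"):
        mae(y, y, mask=np.zeros((4, 4, 4), bool))


# ---------------------------------------------------------------------------
# SSIM


def test_ssim_self_is_one(rng):
    y = rng.random((10, 10, 10))
    assert ssim(y, y) == pytest.approx(1.0, abs=1e-9)


def test_ssim_anticorrelated_negative(rng):
    y = rng.random((10, 10, 10))
    assert ssim(y, 1.0 - y) < 0


def test_ssim_symmetry_and_bound(rng):
    for _ in range(5):
        a = rng.random((8, 8, 8))
        b = rng.random((8, 8, 8))
        s_ab, s_ba = ssim(a, b), ssim(b, a)
        assert abs(s_ab - s_ba) <= 1e-12
        assert s_ab <= 1.0


def test_ssim_matches_three_factor_oracle(rng):
    """Independent recomposition of the luminance/contrast/structure
    factors from raw moments."""
    y = rng.random((10, 10, 10))
    yh = rng.random((10, 10, 10))
    k = SsimConstants()
    mu1, mu2 = y.mean(), yh.mean()
    s1, s2 = y.std(), yh.std()
    cov = np.mean((y - mu1) * (yh - mu2))
    lum = (2 * mu1 * mu2 + k.c1) / (mu1**2 + mu2**2 + k.c1)
    con = (2 * s1 * s2 + k.c2) / (s1**2 + s2**2 + k.c2)
    stru = (cov + k.c3) / (s1 * s2 + k.c3)
    assert ssim(y, yh) == pytest.approx(lum * con * stru, abs=1e-12)


def test_ssim_constants_validation():
    k = SsimConstants()
    assert k.c3 == pytest.approx(k.c2 / 2)
    with pytest.raises(ValueError):
        SsimConstants(c1=0.0)


# ---------------------------------------------------------------------------
# lesion matching


def test_match_lesions_identical_masks(rng):
    m = rng.random((12, 12, 12)) > 0.85
    lab = label_components(m)
    n = lab.max()
    assert match_lesions(lab, lab) == (n, 0, 0)


def test_one_voxel_overlap_counts_as_tp():
    gt = np.zeros((8, 8, 8), np.int32)
    gt[2:5, 2:5, 2] = 1
    pred = np.zeros((8, 8, 8), np.int32)
    pred[4:7, 4:7, 2] = 1  # touches gt at exactly (4,4,2)
    assert ((gt > 0) & (pred > 0)).sum() == 1
    assert match_lesions(pred, gt) == (1, 0, 0)


def test_match_lesions_relabeling_invariant(rng):
    pred = label_components(rng.random((10, 10, 10)) > 0.85)
    gt = label_components(rng.random((10, 10, 10)) > 0.85)
    res = match_lesions(pred, gt)
    # permute labels
    perm = np.concatenate([[0], 1 + np.random.default_rng(0).permutation(pred.max())])
    assert match_lesions(perm[pred], gt) == res


def test_match_lesions_oracle_200_random_masks():
    rng = np.random.default_rng(123)
    for trial in range(200):
        p_thresh = rng.uniform(0.7, 0.95)
        pred = label_components(rng.random((16, 16, 16)) > p_thresh)
        gt = label_components(rng.random((16, 16, 16)) > p_thresh)
        assert match_lesions(pred, gt) == brute_force_match(pred, gt)


def test_label_components_equals_flood_fill():
    rng = np.random.default_rng(7)
    for _ in range(30):
        m = rng.random((12, 12, 12)) > 0.8
        ours = label_components(m)
        oracle = flood_fill_label(m)
        # same partition up to label permutation
        assert ours.max() == oracle.max()
        pairs = set(zip(ours[m], oracle[m]))
        assert len(pairs) == ours.max()


# ---------------------------------------------------------------------------
# detection scores


def test_detection_score_formulas():
    s = detection_scores(3, 1, 1)
    assert s.sensitivity == pytest.approx(0.75)
    assert s.fdr == pytest.approx(0.25)
    assert s.precision == pytest.approx(0.75)


def test_precision_plus_fdr_identity(rng):
    for _ in range(50):
        tp, fp, fn = rng.integers(0, 6, 3)
        s = detection_scores(int(tp), int(fp), int(fn))
        if tp + fp > 0:
            assert s.precision + s.fdr == pytest.approx(1.0)


def test_stable_case_all_undefined():
    s = detection_scores(0, 0, 0)
    assert math.isnan(s.sensitivity) and math.isnan(s.fdr) and math.isnan(s.precision)
    assert s.is_stable


def test_fp_case_count_rounding_convention():
    def stable(fp):
        return DetectionScores(tp=0, fp=fp, fn=0)

    scores = [stable(1)] * 3 + [stable(0)] * 25
    assert fp_case_count(scores) == (3, 11)  # 3/28 -> 11%
    scores = [stable(2)] * 4 + [stable(0)] * 24
    assert fp_case_count(scores) == (4, 14)  # 4/28 -> 14%
    assert fp_case_count([stable(0)] * 10) == (0, 0)
    with pytest.raises(ValueError):
        fp_case_count([])
    with pytest.raises(ValueError, match="stable"):
        fp_case_count([DetectionScores(tp=1, fp=0, fn=0)])


# ---------------------------------------------------------------------------
# Wilcoxon


def test_identical_lists_give_p_one():
    a = [0.1, 0.5, 0.7, 0.2, 0.9, 0.4]
    assert compare_models(a, a) == 1.0


def test_all_positive_differences_n10():
    a = list(np.linspace(0.1, 0.9, 10))
    b = [x + 1 for x in a]
    assert compare_models(b, a) == pytest.approx(2 * (1 / 2**10), rel=1e-9)


def test_wilcoxon_matches_exhaustive_enumeration():
    rng = np.random.default_rng(99)
    for _ in range(20):
        n = int(rng.integers(8, 13))
        a = rng.random(n)
        b = rng.random(n)
        ours = compare_models(a, b)
        oracle = exact_signed_rank_p(a - b)
        assert ours == pytest.approx(oracle, rel=1e-9)


def test_nan_pairs_dropped_pairwise():
    a = [0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, math.nan]
    b = [0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.1]
    # equivalent to comparing the 7 defined pairs
    assert compare_models(a, b) == pytest.approx(
        compare_models(a[:7], b[:7]), rel=1e-12
    )


def test_too_few_pairs_raises():
    with pytest.raises(ValueError, match=">= 6"):
        compare_models([1, 2, 3], [2, 3, 4])


def test_aggregate_drop_vs_zero_fill():
    vals = [0.5, 1.0, math.nan]
    m_drop, _ = metrics.aggregate(vals, drop_undefined=True)
    m_zero, _ = metrics.aggregate(vals, drop_undefined=False)
    assert m_drop == pytest.approx(0.75)
    assert m_zero == pytest.approx(0.5)


# ---------------------------------------------------------------------------
# property tests


@settings(derandomize=True, max_examples=200, deadline=None)
@given(
    tp=st.integers(0, 50), fp=st.integers(0, 50), fn=st.integers(0, 50)
)
def test_score_ratio_invariants(tp, fp, fn):
    s = detection_scores(tp, fp, fn)
    if tp + fp > 0:
        assert s.precision + s.fdr == pytest.approx(1.0)
        assert 0.0 <= s.precision <= 1.0
    else:
        assert math.isnan(s.precision) and math.isnan(s.fdr)
    if tp + fn > 0:
        assert 0.0 <= s.sensitivity <= 1.0
    else:
        assert math.isnan(s.sensitivity)


@settings(derandomize=True, max_examples=50, deadline=None)
@given(shift=st.floats(0.0, 0.5), seed=st.integers(0, 10**6))
def test_mae_constant_shift_property(shift, seed):
    y = np.random.default_rng(seed).random((6, 6, 6))
    assert mae(y, y + shift) == pytest.approx(shift, abs=1e-12)
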