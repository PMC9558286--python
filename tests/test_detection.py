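"""Warping, registration loss, detector architecture, inference rules."""

import numpy as np
import pytest
from scipy import ndimage

from t1synth import detection, phantom
from t1synth.detection import (
    DeformationField,
    DetectionConfig,
    build_detection_model,
    postprocess,
    registration_loss,
    warp,
)
from t1synth.volumes import Volume


def _vol(data):
    return Volume(np.asarray(data, np.float32), np.eye(4))


def test_warp_zero_field_is_identity(rng):
    vol = _vol(rng.random((8, 8, 8)))
    field = DeformationField(np.zeros((3, 8, 8, 8)))
    out = warp(vol, field)
    np.testing.assert_array_equal(out.data, vol.data)


def test_warp_constant_integer_displacement(rng):
    vol = _vol(rng.random((8, 8, 8)))
    d = np.zeros((3, 8, 8, 8), np.float32)
    d[0] = 1.0
    out = warp(vol, DeformationField(d))
    np.testing.assert_allclose(out.data[:-1], vol.data[1:], atol=1e-6)


def test_warp_inverse_roundtrip_small_residual(anatomy, default_spec):
    """Warp then warp by the negated field is identity up to interpolation
    error on a smooth volume (audited bound on one phantom render)."""
    img = phantom.render_modality(anatomy, default_spec.contrast_flair, 0.0, 0.2, seed=2)
    smooth = ndimage.gaussian_filter(img.data, 2.0).astype(np.float32)
    vol = _vol(smooth)
    rng = np.random.default_rng(5)
    d = ndimage.gaussian_filter(rng.standard_normal((3, 64, 64, 64)), 6.0)
    d = (1.5 * d / np.abs(d).max()).astype(np.float32)
    fwd = warp(vol, DeformationField(d))
    back = warp(fwd, DeformationField(-d))
    core = (slice(8, -8),) * 3
    assert np.abs(back.data[core] - vol.data[core]).mean() < 0.01


def test_registration_loss_identities(rng):
    a = _vol(rng.random((8, 8, 8)))
    zero = DeformationField(np.zeros((3, 8, 8, 8)))
    assert registration_loss(a, a, zero, 1.0) == 0.0
    b = _vol(rng.random((8, 8, 8)))
    # zero field -> smoothness exactly 0 regardless of images
    loss = registration_loss(a, b, zero, smoothness_weight=1e6)
    np.testing.assert_allclose(loss, np.mean((a.data - b.data) ** 2), rtol=1e-5)


def test_registration_loss_linear_field_closed_form(rng):
    """d_c(v) = alpha * v_c adds lambda * 3 alpha^2 to the loss."""
    a = _vol(rng.random((6, 6, 6)))
    alpha, lam = 0.1, 2.0
    d = np.zeros((3, 6, 6, 6))
    for c in range(3):
        shape = [1, 1, 1]
        shape[c] = 6
        d[c] = np.broadcast_to(alpha * np.arange(6).reshape(shape), (6, 6, 6))
    base = registration_loss(a, a, DeformationField(np.zeros((3, 6, 6, 6))), lam)
    loss = registration_loss(a, a, DeformationField(d), lam)
    # appearance term of warp(a, d) vs a is not zero; isolate smoothness
    app = registration_loss(a, a, DeformationField(d), 0.0)
    assert loss - app == pytest.approx(lam * 3 * alpha**2, rel=1e-5)
    assert base == 0.0


def test_detector_channel_accounting():
    m1 = build_detection_model(DetectionConfig(modalities=("FLAIR",), base_width=2))
    assert m1.seg_net.stem.cin == 2  # warped baseline + follow-up
    m2 = build_detection_model(DetectionConfig(modalities=("FLAIR", "T1"), base_width=2))
    assert m2.seg_net.stem.cin == 4
    assert set(m2.reg_nets) == {"FLAIR", "T1"}
    for net in m2.reg_nets.values():
        assert net.head.cout == 3
    with pytest.raises(ValueError, match="FLAIR"):
        DetectionConfig(modalities=("T1",))
    with pytest.raises(ValueError, match="empty modality"):
        DetectionConfig(modalities=())


def test_softmax_probabilities_sum_to_one(default_spec):
    case = phantom.make_longitudinal_case(default_spec, 77)
    model = build_detection_model(
        DetectionConfig(modalities=("FLAIR",), base_width=2, n_steps=1)
    )
    prob = detection.predict_new_lesions(model, case)
    assert prob.shape == case.followup["FLAIR"].shape
    assert (prob.data >= 0).all() and (prob.data <= 1).all()


def test_end_to_end_gradients_reach_both_subnetworks(default_spec):
    """One training step leaves nonzero gradients in the registration and
    the segmentation sub-networks (end-to-end coupling through the warp)."""
    case = phantom.make_longitudinal_case(default_spec, 55)
    cfg = DetectionConfig(modalities=("FLAIR",), base_width=2, n_steps=1, batch_size=2)
    model = detection.train_detector([case], cfg, seed=0)
    # train_detector zeroes then accumulates; after the single step the
    # Adam state reflects the gradient
    reg_grads = [np.abs(p.grad).max() for p in model.reg_nets["FLAIR"].params()]
    seg_grads = [np.abs(p.grad).max() for p in model.seg_net.params()]
    assert max(reg_grads) > 0
    assert max(seg_grads) > 0


def test_training_deterministic_and_serializable(tmp_path, default_spec):
    case = phantom.make_longitudinal_case(default_spec, 55)
    cfg = DetectionConfig(modalities=("FLAIR",), base_width=2, n_steps=3, batch_size=2)
    m1 = detection.train_detector([case], cfg, seed=1)
    m2 = detection.train_detector([case], cfg, seed=1)
    for a, b in zip(m1.seg_net.state(), m2.seg_net.state()):
        np.testing.assert_array_equal(a, b)
    path = tmp_path / "det.npz"
    m1.save(path)
    m3 = detection.DetectionModel.load(path)
    prob1 = detection.predict_new_lesions(m1, case)
    prob3 = detection.predict_new_lesions(m3, case)
    np.testing.assert_array_equal(prob1.data, prob3.data)


def test_stable_only_training_warns(default_spec):
    spec = phantom.PhantomSpec(seed=3, n_new_lesions=(0, 0))
    case = phantom.make_longitudinal_case(spec, 8)
    cfg = DetectionConfig(modalities=("FLAIR",), base_width=2, n_steps=1, batch_size=2)
    with pytest.warns(UserWarning, match="stable cases only"):
        detection.train_detector([case], cfg, seed=0)


# ---------------------------------------------------------------------------
# postprocess rules


def test_minimum_size_rule():
    prob = np.zeros((10, 10, 10), np.float32)
    prob[1, 1, 1:3] = 0.9  # 2-voxel component: removed
    prob[5, 5, 5:8] = 0.9  # 3-voxel component: kept
    out = postprocess(_vol(prob), threshold=0.5, min_voxels=3)
    assert out.data[1, 1, 1] == 0
    assert out.data[5, 5, 5] > 0
    assert out.data.max() == 1  # single surviving component


def test_threshold_inclusive_at_half():
    prob = np.zeros((8, 8, 8), np.float32)
    prob[2, 2, 2:5] = 0.5  # exactly at threshold
    out = postprocess(_vol(prob), threshold=0.5, min_voxels=3)
    assert out.data[2, 2, 2] == 1


def test_lower_threshold_is_superset(rng):
    prob = _vol(ndimage.gaussian_filter(rng.random((16, 16, 16)), 1.5) * 0.8)
    hi = postprocess(prob, 0.5, 3)
    lo = postprocess(prob, 0.3, 3)
    assert ((hi.data > 0) & ~(lo.data > 0)).sum() == 0
    # monotonicity of raw thresholding
    assert (prob.data >= 0.3).sum() >= (prob.data >= 0.5).sum()


def test_threshold_03_keeps_peak_04_component():
    prob = np.zeros((8, 8, 8), np.float32)
    prob[3, 3, 2:6] = 0.4
    assert postprocess(_vol(prob), 0.5, 3).data.max() == 0
    assert postprocess(_vol(prob), 0.3, 3).data.max() == 1


def test_components_use_26_connectivity():
    prob = np.zeros((8, 8, 8), np.float32)
    # three voxels touching only diagonally: one 26-connected component
    prob[2, 2, 2] = prob[3, 3, 3] = prob[4, 4, 4] = 0.9
    out = postprocess(_vol(prob), 0.5, 3)
    assert out.data.max() == 1
    assert (out.data > 0).sum() == 3
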