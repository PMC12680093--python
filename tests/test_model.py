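"""Model assembly: head arithmetic, variant lattice, Grad-CAM formula."""

import numpy as np
import pytest

import neurofuse as nf
from neurofuse.model import (
    ModelConfig, ModelConfigError, TumorClassifier, gradcam3d,
    tiny_model_config, transfer_shared_weights,
)
from neurofuse.nn import Module, Tensor

RNG = np.random.default_rng(5)


def small_inputs(batch=1):
    dwi = RNG.normal(size=(batch, 3, 8, 64, 64)).astype(np.float32)
    t2 = RNG.normal(size=(batch, 1, 8, 128, 128)).astype(np.float32)
    return dwi, t2


# ------------------------------------------------------------------- head
def test_head_zero_weights_pass_bias_through():
    model = TumorClassifier(tiny_model_config("full"), seed=0).eval()
    model.classifier.weight.data[...] = 0.0
    model.classifier.bias.data = np.array([0.3, -1.0, 2.0], np.float32)
    C2 = 2 * model.config.stage_widths[-1]
    fused = Tensor(RNG.normal(size=(2, C2, 1, 2, 2)).astype(np.float32))
    logits = model.head(fused)
    np.testing.assert_allclose(logits.data,
                               [[0.3, -1.0, 2.0]] * 2, atol=1e-6)


def test_head_on_constant_channels_is_matrix_product():
    """1x1x1 conv + mean pool commute on channelwise-constant maps, so the
    logits equal W v + b computed by hand (2C = 4)."""
    config = ModelConfig(variant="concat_no_ara", stage_widths=(1, 1, 2, 2),
                         hfir_channels=4, dropout_p=0.0, norm_mode="instance")
    model = TumorClassifier(config, seed=0).eval()
    W = np.array([[1.0, 0.0, -1.0, 2.0],
                  [0.5, 0.5, 0.5, 0.5],
                  [-2.0, 1.0, 0.0, 1.0]], np.float32)
    bias = np.array([0.1, -0.2, 0.3], np.float32)
    model.classifier.weight.data = W.reshape(3, 4, 1, 1, 1)
    model.classifier.bias.data = bias
    v = np.array([2.0, -1.0, 0.5, 3.0], np.float32)
    fused = Tensor(np.broadcast_to(v.reshape(1, 4, 1, 1, 1),
                                   (1, 4, 2, 3, 3)).copy())
    np.testing.assert_allclose(model.head(fused).data[0], W @ v + bias,
                               rtol=1e-5)


def test_head_channel_mismatch_raises():
    model = TumorClassifier(tiny_model_config("full"), seed=0)
    with pytest.raises(ModelConfigError, match="head expects"):
        model.head(Tensor(np.zeros((1, 7, 1, 2, 2), np.float32)))


# ---------------------------------------------------------------- variants
@pytest.mark.parametrize("variant", nf.VARIANTS)
def test_all_variants_produce_finite_deterministic_logits(variant):
    model = TumorClassifier(tiny_model_config(variant), seed=3).eval()
    dwi, t2 = small_inputs()
    a = model.forward(dwi, t2).data
    b = model.forward(dwi, t2).data
    assert a.shape == (1, 3)
    assert np.isfinite(a).all()
    np.testing.assert_array_equal(a, b)


def test_dwi_only_needs_no_t2():
    model = TumorClassifier(tiny_model_config("dwi_only"), seed=0).eval()
    dwi, _ = small_inputs()
    assert model.forward(dwi, None).shape == (1, 3)
    with pytest.raises(ModelConfigError, match="requires"):
        model.forward(None, None)


def test_full_with_zero_gate_params_matches_scaled_concat():
    """With all gate parameters zero the attention is exactly 1.5x, so the
    full model's logits relate to concat_no_ara's (same branch weights) by
    logits_full = 1.5*(logits_concat - bias) + bias."""
    full = TumorClassifier(tiny_model_config("full", dropout_p=0.0), seed=9)
    concat = TumorClassifier(tiny_model_config("concat_no_ara", dropout_p=0.0),
                             seed=1)
    transfer_shared_weights(full, concat)
    for p in full.ara.parameters():
        p.data[...] = 0.0
    full.eval()
    concat.eval()
    dwi, t2 = small_inputs()
    lf = full.forward(dwi, t2).data
    lc = concat.forward(dwi, t2).data
    bias = full.classifier.bias.data
    np.testing.assert_allclose(lf, 1.5 * (lc - bias) + bias,
                               rtol=1e-4, atol=1e-5)


def test_token_layouts_agree():
    """Depth-major and slice-wise token flattenings are the same per-token
    arithmetic, so the logits must coincide."""
    a = TumorClassifier(tiny_model_config("full", dropout_p=0.0), seed=4).eval()
    b = TumorClassifier(tiny_model_config("full", dropout_p=0.0,
                                          tokens="hw-slicewise"), seed=4).eval()
    dwi, t2 = small_inputs()
    np.testing.assert_allclose(a.forward(dwi, t2).data,
                               b.forward(dwi, t2).data, atol=1e-5)


def test_mismatched_modality_geometry_raises():
    model = TumorClassifier(tiny_model_config("full"), seed=0).eval()
    dwi, _ = small_inputs()
    t2_bad = RNG.normal(size=(1, 1, 8, 64, 64)).astype(np.float32)
    with pytest.raises(Exception):
        model.forward(dwi, t2_bad)


def test_checkpoint_round_trip(tmp_path):
    model = TumorClassifier(tiny_model_config("full"), seed=6).eval()
    dwi, t2 = small_inputs()
    before = model.forward(dwi, t2).data
    path = tmp_path / "model.pkl"
    model.save(path)
    after = TumorClassifier.load(path).eval().forward(dwi, t2).data
    np.testing.assert_array_equal(before, after)


# ---------------------------------------------------------------- grad-cam
class _StubCamModel(Module):
    """Minimal model whose layer-4 'activation' and logit arithmetic are
    known in closed form: logit[k] = w_k * sum(A)."""

    def __init__(self, act, w):
        super().__init__()
        self.config = ModelConfig(variant="dwi_only")
        self._act = act
        self._w = w
        self.activations = {}

    def forward(self, dwi, t2):
        a = Tensor(self._act, requires_grad=True)
        self.activations = {"dwi": a}
        return a.sum(axis=(2, 3, 4)) @ Tensor(self._w)


def test_gradcam_matches_direct_formula():
    """Uniform gradient g_k over a single-channel activation A gives
    CAM = normalize(ReLU(g_k * A))."""
    act = RNG.normal(size=(1, 1, 2, 2, 2)).astype(np.float32)
    w = np.array([[2.0, 0.0, 0.0]], np.float32)  # d logit0 / dA = 2 everywhere
    model = _StubCamModel(act, w)
    cam = gradcam3d(model, np.zeros((1, 3, 2, 2, 2), np.float32), None, 0)
    expected = np.maximum(2.0 / 8.0 * act[0, 0], 0)
    expected = expected / expected.max()
    np.testing.assert_allclose(cam.cam[0], expected, rtol=1e-5)
    assert cam.cam_upsampled.shape == (1, 2, 2, 2)


def test_gradcam_zero_gradient_gives_zero_map():
    model = TumorClassifier(tiny_model_config("full", dropout_p=0.0), seed=2)
    model.classifier.weight.data[...] = 0.0  # logit detached from features
    dwi, t2 = small_inputs()
    cam = gradcam3d(model, dwi, t2, target_class=1, branch="dwi")
    assert (cam.cam == 0).all() and (cam.cam_upsampled == 0).all()


def test_gradcam_properties():
    model = TumorClassifier(tiny_model_config("full"), seed=8)
    dwi, t2 = small_inputs()
    cam = gradcam3d(model, dwi, t2, target_class=2, branch="t2")
    assert (cam.cam >= 0).all()
    if cam.cam.max() > 0:
        assert cam.cam.max() == pytest.approx(1.0)
    assert cam.cam_upsampled.shape[1:] == (8, 128, 128)  # T2 input grid
    with pytest.raises(ModelConfigError):
        gradcam3d(model, dwi, t2, target_class=7)
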