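"""Shape laws, output ranges and wiring of the counting network (tiny preset)."""

import numpy as np
import pytest

import paddycount as pc
from paddycount.network import CountingNet, InputSizeError, preprocess


@pytest.fixture(scope="module")
def net():
    return CountingNet("tiny", seed=0)


def _rand_input(rng, h, w):
    return rng.normal(size=(1, h, w, 3)).astype(np.float32)


class TestFeaturePyramid:
    def test_stride_and_channel_law(self, net, rng):
        l1, l2, l3, l4 = net.extract_features(_rand_input(rng, 64, 96))
        assert l1.shape == (1, 32, 48, 8)
        assert l2.shape == (1, 16, 24, 16)
        assert l3.shape == (1, 8, 12, 32)
        assert l4.shape == (1, 4, 6, 64)

    def test_odd_image_is_padded_to_multiple_of_16(self, rng):
        img = rng.uniform(0, 255, size=(65, 65, 3))
        x = preprocess(img)
        assert x.shape == (1, 80, 80, 3)

    def test_too_small_input_rejected(self, net, rng):
        with pytest.raises(InputSizeError):
            net.extract_features(_rand_input(rng, 16, 16))

    def test_non_multiple_of_16_rejected(self, net, rng):
        with pytest.raises(InputSizeError):
            net.extract_features(_rand_input(rng, 65, 64))


class TestOutputs:
    def test_maps_are_half_input_resolution(self, net, rng):
        out = net.forward(_rand_input(rng, 96, 64))
        for key in ("idm", "pam", "fdm"):
            assert out[key].shape == (1, 48, 32)
        assert out["d_p"].shape == (1,)

    @pytest.mark.parametrize("trial", range(10))
    def test_output_ranges(self, net, trial):
        rng = np.random.default_rng(trial)
        out = net.forward(_rand_input(rng, 32, 32))
        assert out["idm"].min() >= 0
        assert out["fdm"].min() >= 0
        assert 0 <= out["pam"].min() and out["pam"].max() <= 1
        assert out["d_p"][0] >= 0

    def test_inference_determinism(self, net, rng):
        x = _rand_input(rng, 64, 64)
        o1 = net.forward(x, train=False)
        o2 = net.forward(x, train=False)
        for key in ("idm", "pam", "fdm", "d_p"):
            assert np.array_equal(o1[key], o2[key])

    def test_zero_logits_give_uniform_half_attention(self, net):
        assert net.sigmoid.forward(np.zeros((1, 4, 4, 1)))[0, 0, 0, 0] == 0.5


class TestRefinement:
    def test_all_ones_attention_with_identity_conv_is_identity(self, net, rng):
        idm = np.abs(rng.normal(size=(8, 8))).astype(np.float32)
        fdm = net.refine(idm, np.ones_like(idm))  # init: weight 1, bias 0
        assert np.allclose(fdm, idm, atol=1e-6)

    def test_all_zero_attention_annihilates(self, net, rng):
        idm = np.abs(rng.normal(size=(8, 8))).astype(np.float32)
        assert net.refine(idm, np.zeros_like(idm)).max() == 0

    def test_matches_hand_computed_product_and_conv(self, rng):
        net = CountingNet("tiny", seed=3)
        w = float(net.refine_conv.w.value.squeeze())
        b = float(net.refine_conv.b.value.squeeze())
        idm = np.abs(rng.normal(size=(8, 8))).astype(np.float32)
        pam = rng.uniform(size=(8, 8)).astype(np.float32)
        expected = np.maximum(w * (pam * idm) + b, 0)
        assert np.allclose(net.refine(idm, pam), expected, atol=1e-6)

    def test_shape_mismatch_rejected(self, net):
        with pytest.raises(ValueError):
            net.refine(np.zeros((4, 4)), np.zeros((4, 5)))


class TestSizeHead:
    @pytest.mark.parametrize("hw", [(4, 4), (8, 6)])
    def test_scalar_for_any_l4_size(self, net, rng, hw):
        l4 = np.abs(rng.normal(size=(2, *hw, 64))).astype(np.float32)
        d_p = net.pse_forward(l4)
        assert d_p.shape == (2,)
        assert np.all(d_p >= 0)

    def test_determinism(self, net, rng):
        l4 = np.abs(rng.normal(size=(1, 4, 4, 64))).astype(np.float32)
        assert net.pse_forward(l4) == net.pse_forward(l4)


class TestCheckpoint:
    def test_save_load_round_trip(self, rng, tmp_path):
        net = CountingNet("tiny", seed=5)
        x = _rand_input(rng, 64, 64)
        before = net.forward(x)
        net.save(tmp_path / "ckpt")
        loaded = CountingNet.load(tmp_path / "ckpt")
        after = loaded.forward(x)
        for key in ("idm", "pam", "fdm", "d_p"):
            assert np.array_equal(before[key], after[key])

    def test_incompatible_preset_rejected(self, tmp_path):
        net = CountingNet("tiny", seed=0)
        net.save(tmp_path / "ckpt")
        import json
        side = tmp_path / "ckpt.json"
        meta = json.loads(side.read_text())
        meta["architecture"] = "full"
        side.write_text(json.dumps(meta))
        with pytest.raises(IOError):
            CountingNet.load(tmp_path / "ckpt")
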