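"""Shape contracts and algebraic properties of the EEG and visual branches."""

import numpy as np
import pytest

from eegemotion.eeg_network import EEGNet, EEGNetConfig
from eegemotion.nn import PeepholeLSTM, Tensor
from eegemotion.visual_network import (
    TemporalConvModule,
    VisualNet,
    VisualNetConfig,
    receptive_field,
)


@pytest.fixture(scope="module")
def eeg_net():
    return EEGNet(EEGNetConfig(), seed=0)


@pytest.fixture(scope="module")
def visual_net():
    return VisualNet(VisualNetConfig(), seed=0).eval()


class TestEEGCNN:
    def test_output_is_512_and_flatten_is_2048(self, eeg_net, rng):
        x = Tensor(rng.standard_normal((3, 4, 9, 9)))
        y = eeg_net.cnn_forward(x)
        assert y.shape == (3, 512)
        # 9x9 same-padded convs -> 4x4 after the 2x2/stride-2 pool, 128 maps
        assert eeg_net.fc.w.shape == (4 * 4 * 128, 512)

    def test_zero_input_zero_biases_gives_zero(self):
        net = EEGNet(EEGNetConfig(), seed=1)
        for conv in net.convs:
            conv.b.data[...] = 0.0
        net.fc.b.data[...] = 0.0
        y = net.cnn_forward(Tensor(np.zeros((1, 4, 9, 9))))
        np.testing.assert_allclose(y.data, 0.0)

    def test_wrong_shape_rejected(self, eeg_net):
        with pytest.raises(ValueError):
            eeg_net.cnn_forward(Tensor(np.zeros((1, 4, 8, 8))))


class TestLSTM:
    def test_output_shape_all_t(self, rng):
        lstm = PeepholeLSTM(16, 128, 2, np.random.default_rng(0))
        for t in (1, 3, 7):
            h = lstm(Tensor(rng.standard_normal((2, t, 16))))
            assert h.shape == (2, t, 128)

    def test_single_step_matches_manual_gate_equations(self, rng):
        lstm = PeepholeLSTM(5, 4, 1, np.random.default_rng(1))
        layer = lstm.layers[0]
        y = rng.standard_normal((1, 5))
        out = lstm(Tensor(y[:, None, :])).data[0, 0]

        sig = lambda v: 1.0 / (1.0 + np.exp(-v))
        h0 = np.zeros(4)
        c0 = np.zeros(4)
        i = sig(y[0] @ layer.w_yi.data + h0 @ layer.w_hi.data + c0 @ layer.w_ci.data + layer.b_i.data)
        f = sig(y[0] @ layer.w_yf.data + h0 @ layer.w_hf.data + c0 @ layer.w_cf.data + layer.b_f.data)
        c = f * c0 + i * np.tanh(y[0] @ layer.w_yc.data + h0 @ layer.w_hc.data + layer.b_c.data)
        o = sig(y[0] @ layer.w_yo.data + h0 @ layer.w_ho.data + c @ layer.w_co.data + layer.b_o.data)
        h = o * np.tanh(c)
        np.testing.assert_allclose(out, h, atol=1e-12)

    def test_all_zero_parameters_give_zero_states(self):
        lstm = PeepholeLSTM(3, 4, 2, np.random.default_rng(2))
        for p in lstm.parameters():
            p.data[...] = 0.0
        h = lstm(Tensor(np.ones((1, 5, 3))))
        np.testing.assert_allclose(h.data, 0.0)


class TestEEGBranch:
    def test_forward_contract(self, rng):
        net = EEGNet(EEGNetConfig(), seed=3)
        x = rng.standard_normal((2, 4, 4, 9, 9))
        out = net(x)
        assert out.probs.shape == (2, 2)
        assert out.features.shape == (2, 4, 128)  # the student sequence Vs
        assert out.band_weights.shape == (2, 4, 4)
        np.testing.assert_allclose(out.probs.data.sum(axis=1), 1.0, atol=1e-9)
        out2 = net(x)
        np.testing.assert_array_equal(out.probs.data, out2.probs.data)

    def test_classifier_softmax_values(self, rng):
        net = EEGNet(EEGNetConfig().small(), seed=0)
        net.head.w.data[...] = 0.0
        net.head.b.data[...] = (np.log(3.0), 0.0)
        probs, _ = net.classify(Tensor(rng.standard_normal((2, 4, net.config.lstm_hidden))))
        np.testing.assert_allclose(probs.data, [[0.75, 0.25]] * 2, atol=1e-12)

    def test_band_permutation_symmetry(self, rng):
        # permuting the band axis together with the first conv's input
        # channels leaves the logits unchanged (band gate is a shared scalar)
        net = EEGNet(EEGNetConfig().small(), seed=4)
        x = rng.standard_normal((2, 4, 4, 9, 9))
        ref = net(x).probs.data
        perm = np.array([2, 0, 3, 1])
        net.convs[0].w.data[...] = net.convs[0].w.data[:, perm]
        permuted = net(x[:, :, perm]).probs.data
        np.testing.assert_allclose(permuted, ref, atol=1e-10)

    def test_attention_free_variants_have_fewer_parameters(self):
        from dataclasses import replace

        cfg = EEGNetConfig().small()
        full = EEGNet(cfg, seed=0).n_parameters()
        no_band = EEGNet(replace(cfg, band_attention=False), seed=0).n_parameters()
        no_self = EEGNet(replace(cfg, self_attention=False), seed=0).n_parameters()
        none = EEGNet(replace(cfg, band_attention=False, self_attention=False), seed=0).n_parameters()
        assert full > no_band > none and full > no_self > none


class TestVisualBranch:
    def test_cnn_emits_512_per_frame(self, visual_net, rng):
        frames = rng.random((2, 3, 48, 48, 3))
        feats = visual_net.cnn_forward(frames)
        assert feats.shape == (2, 3, 512)

    def test_frames_processed_independently(self, visual_net, rng):
        frame = rng.random((48, 48, 3))
        clip = np.stack([frame, frame, rng.random((48, 48, 3))])[None]
        feats = visual_net.cnn_forward(clip).data
        np.testing.assert_array_equal(feats[0, 0], feats[0, 1])
        assert not np.array_equal(feats[0, 0], feats[0, 2])

    def test_zero_frames_zero_biases_give_zero_features(self):
        net = VisualNet(VisualNetConfig().small(), seed=0).eval()
        for layer in (net.conv1, net.conv2, net.fc):
            layer.b.data[...] = 0.0
        feats = net.cnn_forward(np.zeros((1, 2, 48, 48, 3)))
        np.testing.assert_allclose(feats.data, 0.0)

    def test_tcn_preserves_length_and_emits_128(self, visual_net, rng):
        for t in (1, 4, 9):
            spatial = Tensor(rng.standard_normal((1, t, 512)))
            vt = visual_net.tcn_forward(spatial)
            assert vt.shape == (1, t, 128)

    def test_receptive_field_is_eleven(self):
        assert receptive_field() == 11

    def test_temporal_modules_share_parameters(self, rng):
        net = VisualNet(VisualNetConfig().small(), seed=1).eval()
        spatial = Tensor(rng.standard_normal((1, 6, net.config.fc_dim)))
        ref = net.tcn_forward(spatial).data
        # one mutation changes both cascaded applications
        net.temporal.conv1.w.data *= 2.0
        changed = net.tcn_forward(spatial).data
        assert not np.allclose(ref, changed)
        assert len([m for m in (net.temporal,)]) == 1  # single shared instance

    def test_zeroed_branch_reduces_module_to_residual(self, rng):
        drng = np.random.default_rng(0)
        mod = TemporalConvModule(8, 0.5, np.random.default_rng(2), drng).eval()
        mod.conv3.w.data[...] = 0.0
        mod.conv3.b.data[...] = 0.0
        x = Tensor(rng.standard_normal((2, 8, 5)))
        from eegemotion.nn.functional import conv1d

        expected = conv1d(x, mod.residual.w, mod.residual.b).data
        np.testing.assert_allclose(mod(x).data, expected, atol=1e-12)

    def test_classifier_rows_are_distributions(self, visual_net, rng):
        frames = rng.random((1, 4, 48, 48, 3))
        probs, vt = visual_net(frames)
        assert probs.shape == (1, 4, 2)
        np.testing.assert_allclose(probs.data.sum(axis=-1), 1.0, atol=1e-9)

    def test_dropout_only_in_training_mode(self, rng):
        net = VisualNet(VisualNetConfig().small(), seed=5)
        frames = rng.random((1, 4, 48, 48, 3))
        net.train()
        a = net(frames)[1].data
        b = net(frames)[1].data
        assert not np.allclose(a, b)  # dropout masks differ
        net.eval()
        c = net(frames)[1].data
        d = net(frames)[1].data
        np.testing.assert_array_equal(c, d)

    def test_extract_features_is_deterministic_composition(self, rng):
        net = VisualNet(VisualNetConfig().small(), seed=6)
        frames = rng.random((1, 5, 48, 48, 3))
        f1 = net.extract_features(frames)
        f2 = net.extract_features(frames)
        np.testing.assert_array_equal(f1, f2)
        net.eval()
        direct = net.tcn_forward(net.cnn_forward(frames)).data
        np.testing.assert_allclose(f1, direct, atol=1e-12)
        assert f1.shape == (1, 5, net.config.tcn_channels)
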