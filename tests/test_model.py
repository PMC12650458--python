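import numpy as np
import pytest

import neurofuse.model as model_mod
import neurofuse.nn as nn_mod
from neurofuse.model import MFACNN, FeatureBundle, MFAModule
from neurofuse.nn import softmax, softmax_cross_entropy


def _small_model(**kw):
    defaults = dict(
        n_eeg_channels=4, n_fnirs_channels=3, window_len=32, dropout=0.0, seed=0
    )
    defaults.update(kw)
    return MFACNN(**defaults)


def _batch(rng, b=3, ne=4, nf=3, wl=32):
    return {
        "eeg": rng.standard_normal((b, 4, ne, ne)).astype("f4"),
        "fnirs": rng.standard_normal((b, 2 * nf, wl)).astype("f4"),
        "xmodal": rng.standard_normal((b, 4, nf, ne)).astype("f4"),
    }


class TestEncoders:
    def test_conv_stack_preserves_spatial_size(self, rng):
        m = _small_model()
        x = rng.standard_normal((2, 1, 4, 4)).astype("f4")
        h = x
        for c in m.enc_eeg.convs:
            h = c.forward(h)
            assert h.shape[2:] == (4, 4)
        assert h.shape[1] == 128

    def test_conv1d_preserves_length(self, rng):
        m = _small_model()
        x = rng.standard_normal((2, 6, 32)).astype("f4")
        h = x
        for c in m.enc_fnirs.convs:
            h = c.forward(h)
            assert h.shape[2] == 32

    def test_zero_input_zero_biases_zero_feature(self, rng):
        m = _small_model()
        for enc, shape in (
            (m.enc_eeg, (2, 1, 4, 4)),
            (m.enc_fnirs, (2, 6, 32)),
        ):
            for c in enc.convs:
                c.bias.value[...] = 0
            enc.fc.bias.value[...] = 0
            out = enc.forward(
                np.zeros(shape, dtype="f4"), np.random.default_rng(0), False
            )
            assert np.allclose(out, 0.0)

    def test_row_permutation_changes_output(self, rng):
        m = _small_model()
        x = rng.standard_normal((1, 1, 4, 4)).astype("f4")
        xp = x[:, :, ::-1].copy()
        a = m.enc_eeg.forward(x, np.random.default_rng(0), False)
        b = m.enc_eeg.forward(xp, np.random.default_rng(0), False)
        assert not np.allclose(a, b)

    def test_feature_dim_128_regardless_of_channels(self, rng):
        for nf in (3, 4):
            m = _small_model(n_fnirs_channels=nf)
            x = rng.standard_normal((2, 2 * nf, 32)).astype("f4")
            assert m.enc_fnirs.forward(x, np.random.default_rng(0), False).shape == (
                2,
                128,
            )

    def test_too_small_input_rejected(self):
        with pytest.raises(ValueError, match="at least 3x3"):
            _small_model(n_eeg_channels=2)


class TestAttention:
    def test_gap_equals_row_means(self, rng):
        m = _small_model()
        batch = _batch(rng)
        out = m.forward(batch, train=False)
        x = out["deep_features"]
        assert np.allclose(out["descriptor"], x.mean(axis=2), atol=1e-12)

    def test_gap_constant_rows(self, rng):
        mfa = MFAModule(np.random.default_rng(0))
        x = np.tile(np.arange(1.0, 10.0)[None, :, None], (2, 1, 128))
        s = x.mean(axis=2)
        assert np.allclose(s[0], np.arange(1.0, 10.0))
        z = mfa.forward(s.astype("f4"))
        assert z.shape == (2, 9)

    def test_zero_weights_give_half(self):
        mfa = MFAModule(np.random.default_rng(0))
        for _, p in mfa.params():
            p.value[...] = 0
        z = mfa.forward(np.random.default_rng(1).standard_normal((4, 9)).astype("f4"))
        assert np.allclose(z, 0.5)

    def test_weights_in_unit_interval(self, rng):
        mfa = MFAModule(np.random.default_rng(2))
        z = mfa.forward(rng.standard_normal((16, 9)).astype("f4") * 10)
        assert np.all(z > 0) and np.all(z < 1)

    def test_parameter_count_is_72(self):
        assert MFAModule(np.random.default_rng(0)).n_parameters() == 72

    def test_apply_attention_identity_zero_linearity(self, rng):
        m = _small_model()
        batch = _batch(rng)
        out = m.forward(batch, train=False)
        x, z = out["deep_features"], out["attention"]
        x_att = z[:, :, None] * x
        assert np.allclose(np.ones_like(z)[:, :, None] * x, x)
        assert np.allclose(np.zeros_like(z)[:, :, None] * x, 0.0)
        scaled = x.copy()
        scaled[:, 3] *= 2.5
        assert np.allclose(
            (z[:, :, None] * scaled)[:, 3], 2.5 * x_att[:, 3], rtol=1e-6
        )


class TestClassifierHeads:
    def test_probabilities_sum_to_one(self, rng):
        m = _small_model()
        probs = m.predict_proba(_batch(rng))
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_equal_logits_uniform(self):
        assert np.allclose(softmax(np.zeros((2, 4))), 0.25)

    def test_softmax_shift_invariance(self, rng):
        logits = rng.standard_normal((3, 4))
        assert np.allclose(softmax(logits), softmax(logits + 7.0), atol=1e-12)

    def test_heads_are_independent(self, rng):
        m = _small_model()
        batch = _batch(rng)
        base = m.forward(batch, train=False)["head_logits"]
        perturbed = dict(batch)
        perturbed["fnirs"] = batch["fnirs"] + 1.0
        out = m.forward(perturbed, train=False)["head_logits"]
        assert np.array_equal(base["eeg"], out["eeg"])
        assert np.array_equal(base["xmodal"], out["xmodal"])
        assert not np.array_equal(base["fnirs"], out["fnirs"])

    def test_head_outputs_uniform_at_zero_weights(self, rng):
        m = _small_model()
        m.head_eeg.weight.value[...] = 0
        m.head_eeg.bias.value[...] = 0
        out = m.forward(_batch(rng), train=False)
        assert np.allclose(softmax(out["head_logits"]["eeg"]), 0.25)


class TestParameterCounts:
    def test_mfa_scope_72(self):
        m = MFACNN(n_eeg_channels=8, n_fnirs_channels=4, window_len=600, seed=0)
        assert m.count_parameters("mfa") == 72

    def test_fc2_scope(self):
        m = MFACNN(n_eeg_channels=8, n_fnirs_channels=4, window_len=600, seed=0)
        assert m.count_parameters("fc2") == 9 * 128 * 4 + 4

    def test_whole_is_sum_of_scopes(self):
        m = MFACNN(n_eeg_channels=8, n_fnirs_channels=4, window_len=600, seed=0)
        parts = sum(
            m.count_parameters(s) for s in ("mfa", "fc2", "heads", "encoders")
        )
        assert m.count_parameters("all") == parts

    def test_backbone_differs_by_exactly_72(self):
        kw = dict(n_eeg_channels=8, n_fnirs_channels=4, window_len=600, seed=0)
        with_mfa = MFACNN(use_mfa=True, **kw).count_parameters("all")
        without = MFACNN(use_mfa=False, **kw).count_parameters("all")
        assert with_mfa - without == 72


class TestAblationIdentity:
    def test_unit_attention_equals_backbone_bitwise(self, rng):
        """Forcing z = 1 reduces the attention model to the plain backbone."""
        kw = dict(
            n_eeg_channels=4, n_fnirs_channels=3, window_len=32, dropout=0.0, seed=3
        )
        m_att = MFACNN(use_mfa=True, attention_scale=2.0, **kw)
        m_plain = MFACNN(use_mfa=False, **kw)
        # sigmoid(0) = 0.5 exactly; x2 scale makes every weight exactly 1
        m_att.mfa.w_e2.value[...] = 0
        m_att.mfa.w_f2.value[...] = 0
        m_att.mfa.w_c2.value[...] = 0
        batch = _batch(rng)
        a = m_att.forward(batch, train=False)
        b = m_plain.forward(batch, train=False)
        assert np.array_equal(a["attention"], np.ones_like(a["attention"]))
        assert np.array_equal(a["logits"], b["logits"])

    def test_same_seed_same_backbone_weights(self):
        kw = dict(n_eeg_channels=4, n_fnirs_channels=3, window_len=32, seed=5)
        m1 = MFACNN(use_mfa=True, **kw)
        m2 = MFACNN(use_mfa=False, **kw)
        names2 = dict(m2.named_params())
        for name, p in m1.named_params():
            if not name.startswith("mfa."):
                assert np.array_equal(p.value, names2[name].value)


class TestGradients:
    def test_all_72_mfa_params_reachable_by_gradient(self):
        """Descriptors spanning every sign pattern activate each hidden
        ReLU for some sample, so all 72 parameters accumulate gradient."""
        mfa = MFAModule(np.random.default_rng(7))
        s = np.vstack([np.eye(9), -np.eye(9)]).astype("f4")
        mfa.forward(s)
        mfa.backward(np.ones((18, 9), dtype="f4"))
        for name, p in mfa.params():
            assert np.count_nonzero(p.grad) == p.grad.size, name

    def test_gradient_reaches_mfa_through_full_model(self, rng):
        m = _small_model(seed=7)
        batch = _batch(rng, b=8)
        out = m.forward(batch, train=False)
        _, d = softmax_cross_entropy(out["logits"], np.array([0, 1, 2, 3] * 2))
        m.backward(d)
        for name, p in m.mfa.params():
            assert np.count_nonzero(p.grad) > 0, name

    def test_finite_difference_spot_check(self, rng, monkeypatch):
        """Analytic MFA gradients match central differences in float64."""
        monkeypatch.setattr(nn_mod, "DTYPE", np.float64)
        monkeypatch.setattr(model_mod, "DTYPE", np.float64)
        m = _small_model(seed=11)
        batch = {k: v.astype(np.float64) for k, v in _batch(rng, b=4).items()}
        labels = np.array([0, 1, 2, 3])

        def loss_value():
            out = m.forward(batch, train=False)
            val, _ = softmax_cross_entropy(out["logits"], labels)
            return val

        out = m.forward(batch, train=False)
        _, d = softmax_cross_entropy(out["logits"], labels)
        m.backward(d)
        checks = [
            ("w_e1", (0, 0)), ("w_e2", (1, 2)), ("w_f1", (3, 0)),
            ("w_f2", (0, 1)), ("w_c2", (2, 3)),
        ]
        params = dict(m.mfa.params())
        h = 1e-5
        for name, idx in checks:
            p = params[name]
            orig = p.value[idx]
            p.value[idx] = orig + h
            lp = loss_value()
            p.value[idx] = orig - h
            lm = loss_value()
            p.value[idx] = orig
            fd = (lp - lm) / (2 * h)
            scale = max(abs(fd), abs(p.grad[idx]), 1e-8)
            assert abs(fd - p.grad[idx]) / scale < 1e-4, name


class TestCapacity:
    def test_overfits_random_labels(self, rng):
        """32 random bundles with random labels are memorised quickly."""
        m = _small_model(seed=13, dropout=0.3)
        batch = _batch(rng, b=32)
        labels = rng.integers(0, 4, size=32)
        opt = m.make_optimizer(lr=0.005)
        for step in range(500):
            out = m.forward(batch, train=True)
            acc = (out["logits"].argmax(axis=1) == labels).mean()
            if acc == 1.0:
                # confirm in eval mode
                ev = m.forward(batch, train=False)
                if (ev["logits"].argmax(axis=1) == labels).mean() == 1.0:
                    break
            _, d = softmax_cross_entropy(out["logits"], labels)
            m.backward(d)
            opt.step()
            opt.zero_grad()
        ev = m.forward(batch, train=False)
        assert (ev["logits"].argmax(axis=1) == labels).mean() == 1.0


class TestCheckpoint:
    def test_save_load_round_trip(self, rng, tmp_path):
        m = _small_model(seed=17)
        path = tmp_path / "model.ckpt"
        m.save(path)
        again = MFACNN.load(path)
        batch = _batch(rng)
        assert np.array_equal(
            m.forward(batch, train=False)["logits"],
            again.forward(batch, train=False)["logits"],
        )


class TestFeatureBundle:
    def test_rejects_non_finite(self, rng):
        bad = rng.standard_normal((4, 4, 4))
        bad[0, 0, 0] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            FeatureBundle(bad, rng.standard_normal((6, 32)),
                          rng.standard_normal((4, 3, 4)), label=0)

    def test_requires_four_bands(self, rng):
        with pytest.raises(ValueError, match="per rhythm band"):
            FeatureBundle(rng.standard_normal((3, 4, 4)),
                          rng.standard_normal((6, 32)),
                          rng.standard_normal((4, 3, 4)), label=0)
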