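"""Cross-modal attention network: hand-worked attention examples, a
scalar-loop oracle, transformer-layer reference compositions, similarity
arithmetic and decision rules."""

import numpy as np
import pytest

from cmaad import autodiff as ad
from cmaad.io import DecisionWindow
from cmaad.model import (CMAAClassifier, ModelConfig, cross_modal_attention,
                         decide, forward, init_params, project_inputs,
                         sinusoidal_positions, windows_to_arrays)
from tests.conftest import make_window


def attention_oracle(Xa, Xb, Wq, Wk, Wv, d_k):
    """Scalar triple-loop evaluation of scaled dot-product cross-modal
    attention (independent of the vectorized implementation)."""
    Q = np.array([[sum(Xa[t][i] * Wq[i][j] for i in range(len(Xa[0])))
                   for j in range(len(Wq[0]))] for t in range(len(Xa))])
    K = np.array([[sum(Xb[t][i] * Wk[i][j] for i in range(len(Xb[0])))
                   for j in range(len(Wk[0]))] for t in range(len(Xb))])
    V = np.array([[sum(Xb[t][i] * Wv[i][j] for i in range(len(Xb[0])))
                   for j in range(len(Wv[0]))] for t in range(len(Xb))])
    Ta, Tb = len(Q), len(K)
    attn = np.zeros((Ta, Tb))
    for t in range(Ta):
        scores = [sum(Q[t][i] * K[u][i] for i in range(len(Q[t])))
                  / np.sqrt(d_k) for u in range(Tb)]
        e = np.exp(np.array(scores) - max(scores))
        attn[t] = e / e.sum()
    out = np.zeros((Ta, V.shape[1]))
    for t in range(Ta):
        for j in range(V.shape[1]):
            out[t, j] = sum(attn[t, u] * V[u, j] for u in range(Tb))
    return out, attn


class TestCrossModalAttention:
    def test_hand_example_uniform_attention(self):
        """Zero queries give uniform rows; the output is the mean value."""
        Xa = np.array([[0.0], [0.0]])
        Xb = np.array([[1.0], [3.0]])
        one = np.array([[1.0]])
        out, attn = cross_modal_attention(Xa, Xb, (one, one, one))
        np.testing.assert_allclose(attn, 0.5, atol=1e-7)
        np.testing.assert_allclose(out, 2.0, atol=1e-6)

    def test_constant_source_gives_uniform_rows(self, rng):
        Xa = rng.standard_normal((4, 3))
        Xb = np.ones((5, 3)) * 2.0
        W = [rng.standard_normal((3, 3)) for _ in range(3)]
        _, attn = cross_modal_attention(Xa, Xb, W)
        np.testing.assert_allclose(attn, 1.0 / 5, atol=1e-6)

    def test_matches_scalar_loop_oracle(self, rng):
        ad.set_default_dtype(np.float64)
        try:
            for _ in range(30):
                Ta, Tb = rng.integers(1, 5, size=2)
                da, db, dk, dv = rng.integers(1, 5, size=4)
                Xa = rng.standard_normal((Ta, da))
                Xb = rng.standard_normal((Tb, db))
                Wq = rng.standard_normal((da, dk))
                Wk = rng.standard_normal((db, dk))
                Wv = rng.standard_normal((db, dv))
                out, attn = cross_modal_attention(Xa, Xb, (Wq, Wk, Wv))
                oracle_out, oracle_attn = attention_oracle(
                    Xa, Xb, Wq, Wk, Wv, dk)
                np.testing.assert_allclose(out, oracle_out, atol=1e-10)
                np.testing.assert_allclose(attn, oracle_attn, atol=1e-10)
        finally:
            ad.set_default_dtype(np.float32)

    def test_rows_are_convex_combinations(self, rng):
        Xa = rng.standard_normal((3, 2))
        Xb = rng.standard_normal((6, 2))
        W = [rng.standard_normal((2, 2)) for _ in range(3)]
        out, attn = cross_modal_attention(Xa, Xb, W)
        assert out.shape == (3, 2)          # query length preserved
        np.testing.assert_allclose(attn.sum(axis=1), 1.0, atol=1e-6)
        assert attn.min() >= 0

    def test_source_permutation_invariance_of_output(self, rng):
        """Without positional encoding the attention output is invariant to
        permuting the source stream's time axis."""
        Xa = rng.standard_normal((4, 3))
        Xb = rng.standard_normal((7, 3))
        W = [rng.standard_normal((3, 3)) for _ in range(3)]
        perm = rng.permutation(7)
        out1, _ = cross_modal_attention(Xa, Xb, W)
        out2, _ = cross_modal_attention(Xa, Xb[perm], W)
        np.testing.assert_allclose(out1, out2, atol=1e-5)

    def test_shape_mismatch_raises(self, rng):
        with pytest.raises(ValueError):
            cross_modal_attention(rng.standard_normal((3, 2)),
                                  rng.standard_normal((3, 2)),
                                  [rng.standard_normal((4, 2))] * 3)


class TestTransformerLayer:
    """The layer recursion checked against a hand-composed reference:
    O_bar = CM(LN(prev), LN(src)) + LN(prev); O = FF(LN(O_bar)) + LN(O_bar).
    """

    @staticmethod
    def _reference_layer(prev, src, p, base):
        def LN(x, g, b, eps=1e-5):
            mu = x.mean(-1, keepdims=True)
            sd = np.sqrt(((x - mu) ** 2).mean(-1, keepdims=True) + eps)
            return (x - mu) / sd * g + b

        g = lambda n: p[base + n].data.astype(float)
        ln_prev = LN(prev, g("ln_prev_g"), g("ln_prev_b"))
        ln_src = LN(src, g("ln_src_g"), g("ln_src_b"))
        from tests.test_model import attention_oracle
        cm, _ = attention_oracle(ln_prev, ln_src, g("Wq"), g("Wk"),
                                 g("Wv"), g("Wq").shape[1])
        obar = cm + ln_prev
        ln_mid = LN(obar, g("ln_mid_g"), g("ln_mid_b"))
        ff = np.maximum(ln_mid @ g("ff_W1") + g("ff_b1"), 0) @ g("ff_W2") \
            + g("ff_b2")
        return ff + ln_mid

    @pytest.mark.parametrize("zero_ff", [False, True])
    def test_matches_reference_composition(self, rng, zero_ff):
        ad.set_default_dtype(np.float64)
        try:
            from cmaad.model import cm_transformer_layer
            cfg = ModelConfig(d_model=3, n_layers=1, dropout=0.0).resolved()
            p = init_params(cfg, 2, 4, rng)
            if zero_ff:
                p["EA.0.ff_W1"].data[:] = 0
                p["EA.0.ff_W2"].data[:] = 0
            prev = rng.standard_normal((1, 4, 3))
            src = rng.standard_normal((1, 4, 3))
            out, _ = cm_transformer_layer(ad.Tensor(prev), ad.Tensor(src),
                                          p, "EA.0.", cfg)
            ref = self._reference_layer(prev[0], src[0], p, "EA.0.")
            np.testing.assert_allclose(out.data[0], ref, atol=1e-8)
        finally:
            ad.set_default_dtype(np.float32)

    def test_deterministic_in_eval_mode(self, rng):
        from cmaad.model import cm_transformer_layer
        cfg = ModelConfig(d_model=4, dropout=0.5).resolved()
        p = init_params(cfg, 2, 5, rng)
        prev = ad.Tensor(rng.standard_normal((2, 5, 4)))
        src = ad.Tensor(rng.standard_normal((2, 5, 4)))
        o1, _ = cm_transformer_layer(prev, src, p, "EA.0.", cfg,
                                     training=False)
        o2, _ = cm_transformer_layer(prev, src, p, "EA.0.", cfg,
                                     training=False)
        np.testing.assert_array_equal(o1.data, o2.data)


class TestProjection:
    def test_zero_weights_with_positional_encoding(self, rng):
        """Zero projection weights leave exactly the positional code."""
        cfg = ModelConfig(d_model=6, positional_encoding=True)
        p = init_params(cfg.resolved(), 3, 10, rng)
        for k in ("proj_eeg_W", "proj_eeg_b", "proj_env_a_W",
                  "proj_env_a_b", "proj_env_b_W", "proj_env_b_b"):
            p[k].data[:] = 0
        seqs = project_inputs(rng.standard_normal((3, 10)),
                              rng.standard_normal(10),
                              rng.standard_normal(10), cfg, p)
        table = sinusoidal_positions(10, 6)
        for s in seqs:
            np.testing.assert_allclose(s, table, atol=1e-6)

    def test_constant_input_constant_output_without_encoding(self, rng):
        cfg = ModelConfig(d_model=4, positional_encoding=False)
        p = init_params(cfg.resolved(), 2, 6, rng)
        seqs = project_inputs(np.ones((2, 6)), np.ones(6), np.ones(6),
                              cfg, p)
        for s in seqs:
            np.testing.assert_allclose(s - s[0], 0.0, atol=1e-6)

    def test_length_mismatch_raises(self, rng):
        cfg = ModelConfig(d_model=4)
        p = init_params(cfg.resolved(), 2, 6, rng)
        with pytest.raises(ValueError):
            project_inputs(np.ones((2, 6)), np.ones(5), np.ones(6), cfg, p)


class TestForward:
    def test_similarity_examples(self):
        """Per-step cosine: identical vectors 1, orthogonal 0, and the
        [1,2,3] vs [4,5,6] pair from direct evaluation."""
        x = ad.Tensor(np.array([[[1.0, 2.0, 3.0]]]))
        y = ad.Tensor(np.array([[[4.0, 5.0, 6.0]]]))
        from cmaad.model import _cosine_per_step
        np.testing.assert_allclose(_cosine_per_step(x, y).data,
                                   [[0.9746318]], atol=1e-6)
        np.testing.assert_allclose(_cosine_per_step(x, x).data, 1.0,
                                   atol=1e-6)
        z = ad.Tensor(np.array([[[-2.0, 1.0, 0.0]]]))
        np.testing.assert_allclose(_cosine_per_step(x, z).data, 0.0,
                                   atol=1e-6)

    def test_forward_shapes_and_attention_rows(self, rng):
        cfg = ModelConfig(d_model=8, n_layers=5, dropout=0.1)
        T, M = 12, 4
        p = init_params(cfg.resolved(), M, T, rng)
        w = make_window(rng, M=M, T=T)
        sim_a, sim_b, logits, maps = forward(w, p, cfg)
        assert sim_a.shape == (T,) and sim_b.shape == (T,)
        assert logits.shape == (2,)
        assert np.all(np.abs(sim_a) <= 1 + 1e-6)
        assert len(maps) == 4 * 5
        for m in maps:
            np.testing.assert_allclose(m.weights.sum(axis=1), 1.0,
                                       atol=1e-6)
            assert m.weights.min() >= 0

    def test_decide_modes_and_tie(self):
        assert decide(similarities=(np.array([0.9]), np.array([0.1])),
                      mode="similarity_argmax") == "A"
        assert decide(logits=np.array([0.2, 0.8]), mode="fc_head") == "B"
        with pytest.warns(UserWarning, match="tie"):
            assert decide(logits=np.array([0.5, 0.5]),
                          mode="fc_head") == "A"
        with pytest.raises(ValueError):
            decide(logits=np.array([0.5, 0.5]), mode="nope")

    def test_weight_shared_streams_mirror_similarities(self, rng):
        """With tied stream parameters, swapping the two envelopes swaps
        the similarity sequences."""
        cfg = ModelConfig(d_model=6, n_layers=2, dropout=0.0,
                          weight_share=True)
        T, M = 10, 3
        p = init_params(cfg.resolved(), M, T, rng)
        w = make_window(rng, M=M, T=T)
        sa1, sb1, _, _ = forward(w, p, cfg)
        swapped = DecisionWindow(eeg=w.eeg, env_a=w.env_b, env_b=w.env_a,
                                 attended="B")
        sa2, sb2, _, _ = forward(swapped, p, cfg)
        np.testing.assert_allclose(sa1, sb2, atol=1e-6)
        np.testing.assert_allclose(sb1, sa2, atol=1e-6)


class TestClassifier:
    def _tiny_data(self, rng, n=24, M=3, T=10):
        windows = [make_window(rng, M=M, T=T,
                               attended="A" if i % 2 == 0 else "B")
                   for i in range(n)]
        return windows_to_arrays(windows)

    def test_fit_predict_api(self, rng):
        X, y = self._tiny_data(rng)
        clf = CMAAClassifier(d_model=4, n_layers=1, epochs=2,
                             learning_rate=1e-3, batch_size=8,
                             random_state=0)
        clf.fit(X, y)
        pred = clf.predict(X)
        assert set(pred) <= {"A", "B"}
        proba = clf.predict_proba(X)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-6)
        assert len(clf.history_["train_loss"]) == 2

    def test_fixed_seed_reproduces_first_epoch_loss(self, rng):
        X, y = self._tiny_data(rng)
        losses = []
        for _ in range(2):
            clf = CMAAClassifier(d_model=4, n_layers=1, epochs=1,
                                 random_state=7)
            clf.fit(X, y)
            losses.append(clf.history_["train_loss"][0])
        assert losses[0] == losses[1]

    def test_sklearn_param_interface(self):
        clf = CMAAClassifier(d_model=8)
        params = clf.get_params()
        assert params["d_model"] == 8
        clf.set_params(epochs=3)
        assert clf.epochs == 3

    def test_single_class_training_rejected(self, rng):
        X, _ = self._tiny_data(rng)
        with pytest.raises(ValueError):
            CMAAClassifier(epochs=1).fit(X, ["A"] * len(X))

    def test_checkpoint_round_trip(self, rng, tmp_path):
        from cmaad.model import load_model, save_model
        X, y = self._tiny_data(rng)
        clf = CMAAClassifier(d_model=4, n_layers=1, epochs=1,
                             random_state=0).fit(X, y)
        path = str(tmp_path / "model.npz")
        save_model(clf, path)
        clf2 = load_model(path)
        np.testing.assert_array_equal(clf.predict(X), clf2.predict(X))


class TestValueWidthProjection:
    def test_dv_differs_from_dmodel_composed_path(self, rng):
        """When the value width differs from the model width, an output
        projection restores the residual dimensionality; the layer still
        returns row-stochastic attention and the right shapes."""
        from cmaad.model import cm_transformer_layer

        cfg = ModelConfig(d_model=6, d_v=3, n_layers=1, dropout=0.0).resolved()
        p = init_params(cfg, 2, 5, rng)
        assert "EA.0.Wo" in p and p["EA.0.Wo"].shape == (3, 6)
        prev = ad.Tensor(rng.standard_normal((2, 5, 6)))
        src = ad.Tensor(rng.standard_normal((2, 5, 6)))
        out, attn = cm_transformer_layer(prev, src, p, "EA.0.", cfg)
        assert out.shape == (2, 5, 6)
        np.testing.assert_allclose(np.asarray(attn).sum(axis=-1), 1.0,
                                   atol=1e-6)

    def test_dv_training_smoke(self, rng):
        X, y = TestClassifier()._tiny_data(rng)
        clf = CMAAClassifier(d_model=4, d_v=2, n_layers=1, epochs=1,
                             random_state=0).fit(X, y)
        assert len(clf.history_["train_loss"]) == 1
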