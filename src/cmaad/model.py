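"""Cross-modal attention network for auditory attention decoding.

The network ingests one decision window: CSP-enhanced EEG [M x T] and the
two speech envelopes [T].  All three are projected to a shared width
``d_model`` (plus sinusoidal positional encoding) and fed to four
cross-modal transformers, one per modality pairing:

* ``EA`` / ``EB`` - EEG is the source (keys/values), audio A / B the query;
* ``AE`` / ``BE`` - audio A / B is the source, EEG the query.

Each transformer stacks N layers of scaled dot-product cross-modal attention
(O = softmax(Q K^T / sqrt(d_k)) V, queries from the evolving stream, keys and
values from the static source stream) with residual connections, layer norms
and a position-wise feed-forward block (two linear maps with ReLU between).
A per-time-step cosine similarity between the two transformers of each
speaker yields two length-T similarity sequences; a fully connected head
(2T -> T ReLU -> 2 sigmoid units) makes the binary attended-speaker decision.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from . import autodiff as ad
from .autodiff import Tensor

#: stream names: first letter = source (beta) modality, second = query (alpha)
STREAMS = ("EA", "EB", "AE", "BE")


@dataclass
class ModelConfig:
    """Architecture hyperparameters of the cross-modal attention network."""

    d_model: int = 32
    d_k: int | None = None           # defaults to d_model
    d_v: int | None = None           # defaults to d_model
    n_layers: int = 5
    ff_hidden: int | None = None     # defaults to 4 * d_model
    conv_kernel: int = 1
    positional_encoding: bool = True
    dropout: float = 0.1
    weight_share: bool = False

    def resolved(self) -> "ModelConfig":
        cfg = ModelConfig(**{**self.__dict__})
        cfg.d_k = self.d_k or self.d_model
        cfg.d_v = self.d_v or self.d_model
        cfg.ff_hidden = self.ff_hidden or 4 * self.d_model
        if cfg.n_layers < 1:
            raise ValueError("n_layers must be >= 1")
        if not 0 <= cfg.dropout < 1:
            raise ValueError("dropout must lie in [0, 1)")
        if cfg.conv_kernel < 1 or cfg.conv_kernel % 2 == 0:
            raise ValueError("conv_kernel must be a positive odd integer")
        return cfg


@dataclass
class AttentionMap:
    """Row-stochastic attention weights of one layer of one stream."""

    weights: np.ndarray   # [T_alpha x T_beta], rows sum to 1
    stream: str
    layer: int


def sinusoidal_positions(T: int, d: int) -> np.ndarray:
    """Standard sinusoidal positional-encoding table [T x d]."""
    pos = np.arange(T)[:, None]
    i = np.arange(d)[None, :]
    angle = pos / np.power(10000.0, (2 * (i // 2)) / d)
    table = np.where(i % 2 == 0, np.sin(angle), np.cos(angle))
    return table


def _stream_prefix(stream: str, share: bool) -> str:
    if not share:
        return stream
    return "E2X" if stream in ("EA", "EB") else "X2E"


def init_params(cfg: ModelConfig, n_eeg_channels: int, T: int,
                rng: np.random.Generator) -> dict:
    """Glorot-initialized parameter dictionary (name -> Tensor)."""
    cfg = cfg.resolved()
    d, dk, dv, ff = cfg.d_model, cfg.d_k, cfg.d_v, cfg.ff_hidden

    def glorot(*shape):
        fan_in, fan_out = shape[-2], shape[-1]
        s = np.sqrt(6.0 / (fan_in + fan_out))
        return Tensor(rng.uniform(-s, s, shape), requires_grad=True)

    def zeros(*shape):
        return Tensor(np.zeros(shape), requires_grad=True)

    def ones(*shape):
        return Tensor(np.ones(shape), requires_grad=True)

    p = {}
    k = cfg.conv_kernel
    p["proj_eeg_W"] = glorot(k, n_eeg_channels, d) if k > 1 \
        else glorot(n_eeg_channels, d)
    p["proj_eeg_b"] = zeros(d)
    env_streams = ("a",) if cfg.weight_share else ("a", "b")
    for s in env_streams:
        p[f"proj_env_{s}_W"] = glorot(k, 1, d) if k > 1 else glorot(1, d)
        p[f"proj_env_{s}_b"] = zeros(d)
    if cfg.weight_share:            # tie the two envelope projections
        p["proj_env_b_W"] = p["proj_env_a_W"]
        p["proj_env_b_b"] = p["proj_env_a_b"]

    prefixes = {_stream_prefix(s, cfg.weight_share) for s in STREAMS}
    for pre in sorted(prefixes):
        for i in range(cfg.n_layers):
            base = f"{pre}.{i}."
            p[base + "Wq"] = glorot(d, dk)
            p[base + "Wk"] = glorot(d, dk)
            p[base + "Wv"] = glorot(d, dv)
            if dv != d:
                p[base + "Wo"] = glorot(dv, d)
            for ln in ("ln_prev", "ln_src", "ln_mid"):
                p[base + ln + "_g"] = ones(d)
                p[base + ln + "_b"] = zeros(d)
            p[base + "ff_W1"] = glorot(d, ff)
            p[base + "ff_b1"] = zeros(ff)
            p[base + "ff_W2"] = glorot(ff, d)
            p[base + "ff_b2"] = zeros(d)

    p["head_W1"] = glorot(2 * T, T)
    p["head_b1"] = zeros(T)
    p["head_W2"] = glorot(T, 2)
    p["head_b2"] = zeros(2)
    return p


def n_parameters(params: dict) -> int:
    return int(sum(p.data.size for p in params.values()))


# ---------------------------------------------------------------------------
# forward pieces
# ---------------------------------------------------------------------------

def _project(x: Tensor, W: Tensor, b: Tensor, kernel: int) -> Tensor:
    """Per-timestep linear map (kernel 1) or temporal convolution with a
    centred odd kernel over the feature sequence [..., T, F]."""
    if kernel == 1:
        return ad.matmul(x, W) + b
    half = kernel // 2
    data = x.data
    terms = []
    for j in range(kernel):
        shift = j - half
        rolled = np.roll(data, -shift, axis=-2)
        if shift > 0:
            rolled[..., -shift:, :] = 0.0
        elif shift < 0:
            rolled[..., :-shift, :] = 0.0
        # input is a constant w.r.t. learning; only W[j] carries gradient
        terms.append(ad.matmul(Tensor(rolled), W_slice(W, j)))
    out = terms[0]
    for t in terms[1:]:
        out = out + t
    return out + b


def W_slice(W: Tensor, j: int) -> Tensor:
    return Tensor(W.data[j], (W,), lambda g: (_pad_slice(g, W.shape, j),))


def _pad_slice(g, shape, j):
    full = np.zeros(shape)
    full[j] = g
    return full


def cross_modal_attention(x_alpha, x_beta, weights, d_k=None,
                          dropout_p=0.0, rng=None, training=False):
    """Scaled dot-product attention across modalities.

    Queries come from ``x_alpha`` [..., T_a, d_a], keys and values from
    ``x_beta`` [..., T_b, d_b]; ``weights`` is the (W_Q, W_K, W_V) triple.
    Accepts Tensors or plain arrays; returns ``(output, attention)`` where
    output is [..., T_a, d_v] and attention rows sum to one.
    """
    as_numpy = not isinstance(x_alpha, Tensor)
    Xa = x_alpha if isinstance(x_alpha, Tensor) else Tensor(x_alpha)
    Xb = x_beta if isinstance(x_beta, Tensor) else Tensor(x_beta)
    Wq, Wk, Wv = [w if isinstance(w, Tensor) else Tensor(w) for w in weights]
    if Xa.shape[-1] != Wq.shape[0] or Xb.shape[-1] != Wk.shape[0]:
        raise ValueError("weight shapes do not match stream widths")
    dk = d_k if d_k is not None else Wq.shape[1]
    out, attn_weights = ad.scaled_dot_attention(Xa, Xb, Wq, Wk, Wv, dk)
    # dropout on the attention output (not the T x T map): equivalent
    # regularization role at a fraction of the memory traffic
    out = ad.dropout(out, dropout_p, rng, training)
    if as_numpy:
        return out.data, attn_weights
    return out, attn_weights


def cm_transformer_layer(prev: Tensor, source_static: Tensor, params: dict,
                         base: str, cfg: ModelConfig, rng=None,
                         training=False, keep_attention=True):
    """One cross-modal transformer layer.

    O_bar = CM(LN(prev), LN(source)) + LN(prev);
    O     = FF(LN(O_bar)) + LN(O_bar).
    Returns (O, attention) with O shaped like ``prev``.
    """
    g = lambda n: params[base + n]
    if cfg.d_v == cfg.d_model:
        # fused fast path (see autodiff.attention_sublayer)
        obar, attn = ad.attention_sublayer(
            prev, source_static, (g("ln_prev_g"), g("ln_prev_b")),
            (g("ln_src_g"), g("ln_src_b")), g("Wq"), g("Wk"), g("Wv"),
            cfg.d_k, dropout_p=cfg.dropout, rng=rng, training=training,
            keep_weights=keep_attention)
    else:
        ln_prev = ad.layer_norm(prev, g("ln_prev_g"), g("ln_prev_b"))
        ln_src = ad.layer_norm(source_static, g("ln_src_g"), g("ln_src_b"))
        cm, attn = cross_modal_attention(
            ln_prev, ln_src, (g("Wq"), g("Wk"), g("Wv")), d_k=cfg.d_k,
            dropout_p=cfg.dropout, rng=rng, training=training)
        cm = ad.matmul(cm, g("Wo"))
        obar = cm + ln_prev
    out = ad.ff_sublayer(
        obar, (g("ln_mid_g"), g("ln_mid_b")), g("ff_W1"), g("ff_b1"),
        g("ff_W2"), g("ff_b2"), dropout_p=cfg.dropout, rng=rng,
        training=training)
    if not np.all(np.isfinite(out.data)):
        raise FloatingPointError(
            f"non-finite activations in layer {base!r}")
    return out, attn


def _cosine_per_step(x: Tensor, y: Tensor, eps: float = 1e-12) -> Tensor:
    num = (x * y).sum(axis=-1)
    nx = ((x * x).sum(axis=-1) + eps).sqrt()
    ny = ((y * y).sum(axis=-1) + eps).sqrt()
    return num / (nx * ny)


def forward_batch(params: dict, cfg: ModelConfig, eeg: np.ndarray,
                  env_a: np.ndarray, env_b: np.ndarray, rng=None,
                  training=False, need_attention=False):
    """Run the network on a batch.

    ``eeg``: [B x T x M]; ``env_a``/``env_b``: [B x T].  Returns a dict with
    Tensors ``logits`` [B x 2], ``sim_a``/``sim_b`` [B x T] and (optionally)
    per-stream lists of attention arrays [B x T x T].
    """
    cfg = cfg.resolved()
    B, T, M = eeg.shape
    Xe = _project(Tensor(eeg), params["proj_eeg_W"], params["proj_eeg_b"],
                  cfg.conv_kernel)
    Xa = _project(Tensor(env_a[..., None]), params["proj_env_a_W"],
                  params["proj_env_a_b"], cfg.conv_kernel)
    Xb = _project(Tensor(env_b[..., None]), params["proj_env_b_W"],
                  params["proj_env_b_b"], cfg.conv_kernel)
    if cfg.positional_encoding:
        pos = Tensor(sinusoidal_positions(T, cfg.d_model))
        Xe, Xa, Xb = Xe + pos, Xa + pos, Xb + pos

    init_alpha = {"EA": Xa, "EB": Xb, "AE": Xe, "BE": Xe}
    source = {"EA": Xe, "EB": Xe, "AE": Xa, "BE": Xb}
    outputs, attention = {}, {s: [] for s in STREAMS}
    for s in STREAMS:
        pre = _stream_prefix(s, cfg.weight_share)
        o = init_alpha[s]
        for i in range(cfg.n_layers):
            o, attn = cm_transformer_layer(
                o, source[s], params, f"{pre}.{i}.", cfg, rng, training,
                keep_attention=need_attention)
            if need_attention:
                attention[s].append(attn)
        outputs[s] = o

    sim_a = _cosine_per_step(outputs["EA"], outputs["AE"])
    sim_b = _cosine_per_step(outputs["EB"], outputs["BE"])
    feats = ad.concat_last([sim_a, sim_b])                     # [B x 2T]
    h = ad.relu(ad.matmul(feats, params["head_W1"]) + params["head_b1"])
    h = ad.dropout(h, cfg.dropout, rng, training)
    logits = ad.matmul(h, params["head_W2"]) + params["head_b2"]
    out = {"logits": logits, "sim_a": sim_a, "sim_b": sim_b}
    if need_attention:
        out["attention"] = attention
    return out


def project_inputs(eeg: np.ndarray, env_a: np.ndarray, env_b: np.ndarray,
                   cfg: ModelConfig, params: dict):
    """Project one window's raw streams to three [T x d_model] sequences."""
    cfg = cfg.resolved()
    M, T = eeg.shape
    if len(env_a) != T or len(env_b) != T:
        raise ValueError("eeg, env_a and env_b must share length T")
    Xe = _project(Tensor(eeg.T[None]), params["proj_eeg_W"],
                  params["proj_eeg_b"], cfg.conv_kernel)
    Xa = _project(Tensor(env_a[None, :, None]), params["proj_env_a_W"],
                  params["proj_env_a_b"], cfg.conv_kernel)
    Xb = _project(Tensor(env_b[None, :, None]), params["proj_env_b_W"],
                  params["proj_env_b_b"], cfg.conv_kernel)
    seqs = [Xe.data[0], Xa.data[0], Xb.data[0]]
    if cfg.positional_encoding:
        pos = sinusoidal_positions(T, cfg.d_model)
        seqs = [s + pos for s in seqs]
    return tuple(seqs)


def forward(window, params: dict, cfg: ModelConfig):
    """Single-window forward pass (evaluation mode).

    Returns ``(similarity_a, similarity_b, logits, attention_maps)`` where
    the similarity sequences have length T, logits has two entries and
    attention_maps is a list of :class:`AttentionMap`.
    """
    eeg = np.asarray(window.eeg, dtype=float)
    env_a = np.asarray(window.env_a, dtype=float)
    env_b = np.asarray(window.env_b, dtype=float)
    out = forward_batch(params, cfg, eeg.T[None], env_a[None], env_b[None],
                        training=False, need_attention=True)
    sim_a = out["sim_a"].data[0]
    sim_b = out["sim_b"].data[0]
    maps = [AttentionMap(weights=out["attention"][s][i][0], stream=s, layer=i)
            for s in STREAMS for i in range(cfg.resolved().n_layers)]
    return sim_a, sim_b, out["logits"].data[0], maps


def decide(logits=None, similarities=None, mode="fc_head") -> str:
    """Map network outputs to an attended-speaker label.

    ``fc_head``: argmax of the two head outputs; ``similarity_argmax``:
    argmax of the mean per-speaker similarity.  Exact ties break toward A.
    """
    if mode == "fc_head":
        a, b = float(logits[0]), float(logits[1])
    elif mode == "similarity_argmax":
        sim_a, sim_b = similarities
        a, b = float(np.mean(sim_a)), float(np.mean(sim_b))
    else:
        raise ValueError(f"unknown decision mode {mode!r}")
    if a == b:
        warnings.warn("tie between speakers; defaulting to A")
        return "A"
    return "A" if a > b else "B"


# ---------------------------------------------------------------------------
# sklearn estimator
# ---------------------------------------------------------------------------

def windows_to_arrays(windows):
    """Stack decision windows into (X, y): X is [n x (M+2) x T] with the
    last two rows carrying env_a and env_b; y the attended labels."""
    X, y = [], []
    for w in windows:
        X.append(np.vstack([w.eeg, w.env_a[None], w.env_b[None]]))
        y.append(w.attended)
    return np.asarray(X, dtype=float), np.asarray(y)


class CMAAClassifier(BaseEstimator, ClassifierMixin):
    """Cross-modal attention classifier of the attended speaker.

    ``X`` is [n_windows x (M+2) x T]: the first M rows of each sample are
    the CSP-enhanced EEG, the last two the speech envelopes of speaker A and
    B.  ``y`` holds labels in {'A', 'B'} (or {0, 1}).

    Training minimizes weighted binary cross-entropy of the two sigmoid
    output units with Adam; sample weights default to the inverse label
    frequency of the training windows.  With validation data the parameters
    of the best-validation-accuracy epoch are kept.
    """

    def __init__(self, d_model=32, n_layers=5, d_k=None, d_v=None,
                 ff_hidden=None, conv_kernel=1, positional_encoding=True,
                 dropout=0.1, weight_share=False, epochs=200,
                 learning_rate=1e-4, batch_size=32, class_weight="auto",
                 decision_mode="fc_head", random_state=0):
        self.d_model = d_model
        self.n_layers = n_layers
        self.d_k = d_k
        self.d_v = d_v
        self.ff_hidden = ff_hidden
        self.conv_kernel = conv_kernel
        self.positional_encoding = positional_encoding
        self.dropout = dropout
        self.weight_share = weight_share
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.class_weight = class_weight
        self.decision_mode = decision_mode
        self.random_state = random_state

    # -- helpers ------------------------------------------------------------

    def _model_config(self) -> ModelConfig:
        return ModelConfig(
            d_model=self.d_model, d_k=self.d_k, d_v=self.d_v,
            n_layers=self.n_layers, ff_hidden=self.ff_hidden,
            conv_kernel=self.conv_kernel,
            positional_encoding=self.positional_encoding,
            dropout=self.dropout, weight_share=self.weight_share)

    def _encode_y(self, y):
        return np.array([0 if str(v) in ("A", "0") else 1 for v in y])

    def _split_X(self, X):
        X = np.asarray(X, dtype=float)
        if X.ndim != 3 or X.shape[1] < 3:
            raise ValueError("X must be [n x (M+2) x T] with M >= 1")
        eeg = np.swapaxes(X[:, :-2, :], 1, 2)   # [n x T x M]
        return eeg, X[:, -2, :], X[:, -1, :]

    # -- API ----------------------------------------------------------------

    def fit(self, X, y, X_val=None, y_val=None, verbose=False):
        eeg, env_a, env_b = self._split_X(X)
        y01 = self._encode_y(y)
        if set(np.unique(y01)) != {0, 1}:
            raise ValueError("training labels must contain both classes")
        n, T, M = eeg.shape
        self.classes_ = np.array(["A", "B"])
        self.T_ = T
        self.n_eeg_channels_ = M
        cfg = self._model_config().resolved()
        rng = np.random.default_rng(self.random_state)

        if self.class_weight == "auto":
            freq = np.bincount(y01, minlength=2) / n
            cw = np.where(freq > 0, 0.5 / np.maximum(freq, 1e-12), 0.0)
        elif self.class_weight is None:
            cw = np.ones(2)
        else:
            cw = np.asarray(self.class_weight, dtype=float)
        self.class_weights_ = cw

        params = init_params(cfg, M, T, rng)
        seen, param_list = set(), []
        for k in sorted(params):        # tied tensors enter Adam once
            if id(params[k]) not in seen:
                seen.add(id(params[k]))
                param_list.append(params[k])
        opt = ad.Adam(param_list, lr=self.learning_rate)
        onehot = np.eye(2)[y01]
        sample_w = cw[y01]

        history = {"train_loss": [], "val_accuracy": []}
        best = (-np.inf, None)
        for epoch in range(self.epochs):
            order = rng.permutation(n)
            losses = []
            for start in range(0, n, self.batch_size):
                idx = order[start:start + self.batch_size]
                out = forward_batch(params, cfg, eeg[idx], env_a[idx],
                                    env_b[idx], rng=rng, training=True)
                loss = ad.bce_with_logits(out["logits"], onehot[idx],
                                          sample_w[idx])
                if not np.isfinite(loss.data):
                    raise FloatingPointError(
                        f"training diverged at epoch {epoch}; last finite "
                        f"epoch loss: {history['train_loss'][-1:]}" )
                opt.zero_grad()
                loss.backward()
                opt.step()
                losses.append(float(loss.data))
            history["train_loss"].append(float(np.mean(losses)))
            if X_val is not None and len(y_val):
                self.params_, self.config_ = params, cfg  # for predict
                acc = float(np.mean(self.predict(X_val) ==
                                    np.where(self._encode_y(y_val) == 0,
                                             "A", "B")))
                history["val_accuracy"].append(acc)
                if acc > best[0]:
                    best = (acc, {k: v.data.copy() for k, v in params.items()})
            if verbose:
                msg = f"epoch {epoch + 1}/{self.epochs} loss=" \
                      f"{history['train_loss'][-1]:.4f}"
                if history["val_accuracy"]:
                    msg += f" val_acc={history['val_accuracy'][-1]:.3f}"
                print(msg)

        if best[1] is not None:
            for k, v in best[1].items():
                params[k].data = v
        self.params_ = params
        self.config_ = cfg
        self.history_ = history
        return self

    def _forward_eval(self, X, need_attention=False):
        eeg, env_a, env_b = self._split_X(X)
        outs = []
        for start in range(0, len(eeg), max(self.batch_size, 1)):
            sl = slice(start, start + self.batch_size)
            outs.append(forward_batch(
                self.params_, self.config_, eeg[sl], env_a[sl], env_b[sl],
                training=False, need_attention=need_attention))
        return outs

    def decision_function(self, X):
        chunks = self._forward_eval(X)
        logits = np.concatenate([c["logits"].data for c in chunks])
        sim_a = np.concatenate([c["sim_a"].data for c in chunks])
        sim_b = np.concatenate([c["sim_b"].data for c in chunks])
        if self.decision_mode == "similarity_argmax":
            return np.stack([sim_a.mean(axis=1), sim_b.mean(axis=1)], axis=1)
        return logits

    def predict_proba(self, X):
        scores = self.decision_function(X)
        if self.decision_mode == "fc_head":
            p = 1.0 / (1.0 + np.exp(-scores))
        else:
            p = np.exp(scores - scores.max(axis=1, keepdims=True))
        return p / p.sum(axis=1, keepdims=True)

    def predict(self, X):
        scores = self.decision_function(X)
        # ties break toward A (index 0): argmax takes the first maximum
        return self.classes_[np.argmax(scores, axis=1)]

    def attention_maps(self, X):
        """Final-layer attention arrays per stream for every sample in X:
        dict stream -> [n x T_alpha x T_beta]."""
        chunks = self._forward_eval(X, need_attention=True)
        return {s: np.concatenate([c["attention"][s][-1] for c in chunks])
                for s in STREAMS}


# ---------------------------------------------------------------------------
# checkpointing
# ---------------------------------------------------------------------------

CHECKPOINT_VERSION = "1.0"


def save_model(clf: CMAAClassifier, path: str) -> None:
    """Serialize a fitted classifier (parameters + config) to one .npz."""
    import json

    meta = {"version": CHECKPOINT_VERSION, "params": clf.get_params(),
            "T": clf.T_, "M": clf.n_eeg_channels_}
    arrays = {f"w::{k}": v.data for k, v in clf.params_.items()}
    np.savez(path, __meta__=np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_model(path: str) -> CMAAClassifier:
    import json

    with np.load(path) as f:
        meta = json.loads(bytes(f["__meta__"]).decode())
        if meta["version"].split(".")[0] != CHECKPOINT_VERSION.split(".")[0]:
            raise ValueError(f"incompatible checkpoint version "
                             f"{meta['version']}")
        clf = CMAAClassifier(**meta["params"])
        clf.classes_ = np.array(["A", "B"])
        clf.T_ = int(meta["T"])
        clf.n_eeg_channels_ = int(meta["M"])
        clf.config_ = clf._model_config().resolved()
        clf.params_ = {k[3:]: Tensor(f[k], requires_grad=True)
                       for k in f.files if k.startswith("w::")}
        if clf.weight_share:            # restore parameter tying
            clf.params_["proj_env_b_W"] = clf.params_["proj_env_a_W"]
            clf.params_["proj_env_b_b"] = clf.params_["proj_env_a_b"]
    clf.history_ = {"train_loss": [], "val_accuracy": []}
    return clf
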