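"""Windowing, splitting, training protocol, multi-run averaging and
attention-map export.

The protocol is subject-dependent: trials of one subject are randomly split
80/10/10 into train/validation/test *at the trial level*, and sliding
decision windows (50 % overlap) are cut after partitioning so that no
window straddles partitions.  CSP, class weights and all learned statistics
derive exclusively from the training partition; an audit hash of the
training-trial membership is stamped into every result for verification.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass

import numpy as np

from .csp import CSP
from .envelope import EnvelopeConfig, broadband_envelope, rms_equalize
from .io import DecisionWindow, ProcessedTrial
from .model import CMAAClassifier, ModelConfig, STREAMS, windows_to_arrays
from .preprocess import PreprocConfig, normalize_trial, preprocess_trial

log = logging.getLogger("cmaad")


@dataclass
class TrainConfig:
    """Training-protocol parameters (windows, splits, optimizer, runs)."""

    window_seconds: float = 2.0
    overlap_fraction: float = 0.5
    split: tuple = (0.8, 0.1, 0.1)
    epochs: int = 200
    learning_rate: float = 1e-4
    batch_size: int = 32
    n_runs: int = 10
    seed: int = 0
    class_weights: object = "auto"
    decision_mode: str = "fc_head"

    def validate(self) -> "TrainConfig":
        if abs(sum(self.split) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")
        if not 0 <= self.overlap_fraction < 1:
            raise ValueError("overlap_fraction must lie in [0, 1)")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        return self


# ---------------------------------------------------------------------------
# windows and splits
# ---------------------------------------------------------------------------

def make_windows(trial: ProcessedTrial, window_seconds: float,
                 overlap: float = 0.5):
    """Cut sliding decision windows of T = round(window_seconds * fs)
    samples with stride T * (1 - overlap); the trial label is inherited."""
    T = int(round(window_seconds * trial.fs))
    S = trial.n_samples
    if S < T:
        log.warning("trial %s shorter than window (%d < %d); skipped",
                    trial.trial_id, S, T)
        return []
    stride = max(1, int(round(T * (1.0 - overlap))))
    n_windows = (S - T) // stride + 1
    out = []
    for k in range(n_windows):
        a = k * stride
        out.append(DecisionWindow(
            eeg=trial.eeg_feat[:, a:a + T], env_a=trial.env_a[a:a + T],
            env_b=trial.env_b[a:a + T], attended=trial.attended,
            window_index=k, source_trial_id=trial.trial_id))
    return out


def count_windows(S: int, T: int, overlap: float) -> int:
    """Closed-form window count for a trial of S samples."""
    stride = max(1, int(round(T * (1.0 - overlap))))
    return 0 if S < T else (S - T) // stride + 1


def split_dataset(trials, split=(0.8, 0.1, 0.1), seed: int = 0):
    """Random trial-level train/validation/test partition, reproducible
    from ``seed``.  Logs the attended-label balance of each partition."""
    trials = list(trials)
    n = len(trials)
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_val = int(round(n * split[1]))
    n_test = int(round(n * split[2]))
    n_train = n - n_val - n_test
    if min(n_train, n_val, n_test) < 1:
        raise ValueError(
            f"split of {n} trials leaves an empty partition "
            f"({n_train}/{n_val}/{n_test}); provide more trials")
    parts = (order[:n_train], order[n_train:n_train + n_val],
             order[n_train + n_val:])
    out = tuple([trials[i] for i in p] for p in parts)
    for name, part in zip(("train", "val", "test"), out):
        labels = [t.attended for t in part]
        log.info("%s: %d trials (A=%d, B=%d)", name, len(part),
                 labels.count("A"), labels.count("B"))
    return out


def _membership_hash(trial_ids) -> str:
    h = hashlib.sha256()
    for t in sorted(str(x) for x in trial_ids):
        h.update(t.encode())
        h.update(b"\x00")
    return h.hexdigest()


# ---------------------------------------------------------------------------
# training / evaluation
# ---------------------------------------------------------------------------

def train(train_windows, val_windows, cfg: TrainConfig,
          model_cfg: ModelConfig | None = None, seed: int | None = None):
    """Train the cross-modal attention classifier on decision windows.

    Returns ``(clf, history)``; the parameters of the epoch with the best
    validation accuracy are kept when validation windows are provided.
    """
    cfg = cfg.validate()
    model_cfg = model_cfg or ModelConfig()
    if not train_windows:
        raise ValueError("empty training set")
    X, y = windows_to_arrays(train_windows)
    Xv, yv = (windows_to_arrays(val_windows) if val_windows else (None, None))
    clf = CMAAClassifier(
        d_model=model_cfg.d_model, n_layers=model_cfg.n_layers,
        d_k=model_cfg.d_k, d_v=model_cfg.d_v, ff_hidden=model_cfg.ff_hidden,
        conv_kernel=model_cfg.conv_kernel,
        positional_encoding=model_cfg.positional_encoding,
        dropout=model_cfg.dropout, weight_share=model_cfg.weight_share,
        epochs=cfg.epochs, learning_rate=cfg.learning_rate,
        batch_size=cfg.batch_size, class_weight=cfg.class_weights,
        decision_mode=cfg.decision_mode,
        random_state=cfg.seed if seed is None else seed)
    clf.fit(X, y, X_val=Xv, y_val=yv)
    return clf, clf.history_


def evaluate(clf, test_windows):
    """Decoding accuracy = fraction of correctly classified decision
    windows; returns ``(accuracy, predictions_dataframe)``."""
    import pandas as pd

    if not test_windows:
        raise ValueError("empty test set")
    X, y = windows_to_arrays(test_windows)
    pred = clf.predict(X)
    acc = float(np.mean(pred == y))
    df = pd.DataFrame({
        "source_trial_id": [w.source_trial_id for w in test_windows],
        "window_index": [w.window_index for w in test_windows],
        "attended": y, "predicted": pred, "correct": pred == y,
    })
    return acc, df


def repeated_runs(train_windows, val_windows, test_windows,
                  cfg: TrainConfig, model_cfg: ModelConfig | None = None,
                  n_runs: int | None = None):
    """Repeat training with different random initializations; report the
    mean and standard deviation of the test accuracy across runs."""
    cfg = cfg.validate()
    n_runs = cfg.n_runs if n_runs is None else n_runs
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    accs, runs = [], []
    for r in range(n_runs):
        clf, history = train(train_windows, val_windows, cfg, model_cfg,
                             seed=cfg.seed + 1000 * r)
        acc, df = evaluate(clf, test_windows)
        accs.append(acc)
        runs.append({"run": r, "accuracy": acc, "history": history,
                     "classifier": clf, "predictions": df})
        log.info("run %d/%d: accuracy %.3f", r + 1, n_runs, acc)
    accs = np.asarray(accs)
    return {"mean_accuracy": float(accs.mean()),
            "sd_accuracy": float(accs.std(ddof=0)),
            "accuracies": accs.tolist(), "runs": runs}


# ---------------------------------------------------------------------------
# end-to-end experiment on raw trials
# ---------------------------------------------------------------------------

def precompute_features(raw_trials, preproc_cfg: PreprocConfig | None = None,
                        env_cfg: EnvelopeConfig | None = None) -> dict:
    """Per-trial split-independent features: preprocessed (pre-CSP) 70 Hz
    EEG and the two broadband envelopes.  Computing these once lets several
    experiment seeds share the heavy signal-processing work."""
    env_cfg = env_cfg or EnvelopeConfig()
    feats = {}
    for tr in raw_trials:
        feats[tr.trial_id] = {
            "eeg70": preprocess_trial(tr, preproc_cfg),
            "env_a": broadband_envelope(tr.audio_a, tr.fs_audio, env_cfg),
            "env_b": broadband_envelope(tr.audio_b, tr.fs_audio, env_cfg),
        }
    return feats


def build_processed_trials(raw_trials, csp: CSP,
                           preproc_cfg: PreprocConfig | None = None,
                           env_cfg: EnvelopeConfig | None = None,
                           features: dict | None = None):
    """Apply the fitted CSP and envelope chain to raw trials, producing
    :class:`ProcessedTrial` objects (post-CSP channels re-standardized per
    trial; envelopes RMS-equalized)."""
    env_cfg = env_cfg or EnvelopeConfig()
    out = []
    for tr in raw_trials:
        f = (features or {}).get(tr.trial_id)
        eeg70 = f["eeg70"] if f else preprocess_trial(tr, preproc_cfg)
        feat = normalize_trial(csp.transform(eeg70))
        env_a = f["env_a"] if f else \
            broadband_envelope(tr.audio_a, tr.fs_audio, env_cfg)
        env_b = f["env_b"] if f else \
            broadband_envelope(tr.audio_b, tr.fs_audio, env_cfg)
        n = min(feat.shape[1], len(env_a), len(env_b))
        env_a, env_b = rms_equalize(env_a[:n], env_b[:n])
        out.append(ProcessedTrial(
            eeg_feat=feat[:, :n], env_a=env_a, env_b=env_b,
            attended=tr.attended, subject_id=tr.subject_id,
            trial_id=tr.trial_id, condition=tr.condition,
            fs=(preproc_cfg or PreprocConfig()).target_fs))
    return out


def run_experiment(raw_trials, cfg: TrainConfig,
                   model_cfg: ModelConfig | None = None,
                   preproc_cfg: PreprocConfig | None = None,
                   env_cfg: EnvelopeConfig | None = None,
                   seed: int | None = None, n_runs: int = 1,
                   features: dict | None = None):
    """Full pipeline on raw trials of one subject.

    Split at the trial level, preprocess, fit CSP on the training trials
    only, window each partition, train and evaluate.  Returns a result dict
    with accuracies, histories, the fitted objects and the leakage-audit
    hashes.
    """
    cfg = cfg.validate()
    seed = cfg.seed if seed is None else seed
    preproc_cfg = preproc_cfg or PreprocConfig()
    tr_raw, va_raw, te_raw = split_dataset(raw_trials, cfg.split, seed)

    if features is None:
        features = precompute_features(raw_trials, preproc_cfg, env_cfg)
    train_ids = [t.trial_id for t in tr_raw]
    csp = CSP().fit([features[t.trial_id]["eeg70"] for t in tr_raw],
                    [t.attended for t in tr_raw], trial_ids=train_ids)

    parts = {}
    for name, raws in (("train", tr_raw), ("val", va_raw), ("test", te_raw)):
        processed = build_processed_trials(raws, csp, preproc_cfg, env_cfg,
                                           features=features)
        windows = [w for t in processed
                   for w in make_windows(t, cfg.window_seconds,
                                         cfg.overlap_fraction)]
        parts[name] = windows

    # leakage guard: CSP must have seen exactly the training trials
    assert set(csp.fitted_on_) == set(train_ids), "CSP fitted outside train"
    audit = {"train_membership_hash": _membership_hash(train_ids),
             "csp_fitted_on_hash": _membership_hash(csp.fitted_on_)}

    run_cfg = TrainConfig(**{**cfg.__dict__, "seed": seed})
    result = repeated_runs(parts["train"], parts["val"], parts["test"],
                           run_cfg, model_cfg, n_runs=n_runs)
    result.update({
        "csp": csp, "windows": parts, "train_trial_ids": train_ids,
        "audit": audit, "seed": seed,
        "n_windows": {k: len(v) for k, v in parts.items()},
    })
    return result


def leakage_audit(result) -> bool:
    """Verify that CSP (and hence class statistics) derive from the
    training partition only, by re-hashing partition membership."""
    audit = result["audit"]
    expected = _membership_hash(result["train_trial_ids"])
    ok = (audit["train_membership_hash"] == expected ==
          audit["csp_fitted_on_hash"] ==
          _membership_hash(result["csp"].fitted_on_))
    train_sources = {w.source_trial_id for w in result["windows"]["train"]}
    ok &= train_sources <= set(result["train_trial_ids"])
    return bool(ok)


# ---------------------------------------------------------------------------
# attention-map export
# ---------------------------------------------------------------------------

def aggregate_attention(attn: np.ndarray, values: np.ndarray | None = None):
    """Aggregate a row-stochastic [T_q x T_k] map into per-source-step
    weights: mean attention received across query positions, optionally
    weighted by the norm of the source (value) content at each step."""
    received = attn.mean(axis=0)
    if values is not None:
        received = received * np.linalg.norm(values, axis=-1)
    return received


def export_attention_maps(clf: CMAAClassifier, windows, out_dir=None,
                          value_weighted: bool = True):
    """Per window, the three EEG-attention panels: uniform pre-attention
    weights, EEG weights w.r.t. speaker A (stream EA) and w.r.t. speaker B
    (stream EB), aggregated over query positions at the final layer.

    With ``value_weighted`` the attention received by each EEG time step is
    scaled by the norm of the attended EEG content there (row-stochastic
    maps all carry identical total mass, so the raw column means cannot
    differ between panels; the value-weighted form measures how much EEG
    signal the stream actually pulls through its attention).  Panels are
    max-normalized to [0, 1] for display; raw aggregates are kept alongside.
    Heatmap PNGs are written when ``out_dir`` is given.
    """
    X, y = windows_to_arrays(windows)
    maps = clf.attention_maps(X)
    pred = clf.predict(X)
    # value content of the EEG source at the final layer, per stream
    results = []
    for i, w in enumerate(windows):
        T = w.n_samples
        panels = {"uniform": np.full(T, 1.0 / T)}
        raw = {}
        for stream, key in (("EA", "E>A"), ("EB", "E>B")):
            attn = maps[stream][i]
            vals = _stream_value_content(clf, X[i:i + 1], stream) \
                if value_weighted else None
            agg = aggregate_attention(attn, vals)
            raw[key] = agg
            panels[key] = agg / (agg.max() + 1e-30)
        results.append({
            "panels": panels, "aggregates": raw, "attended": w.attended,
            "predicted": pred[i], "maps": {s: maps[s][i] for s in STREAMS},
        })
    if out_dir is not None:
        _render_panels(results, out_dir)
    return results


def _stream_value_content(clf, X1, stream):
    """Norm per source time step of the value vectors feeding ``stream`` at
    the final layer (the EEG content the attention distributes)."""
    from . import autodiff as ad
    from .model import (_project, _stream_prefix, sinusoidal_positions)

    eeg, env_a, env_b = clf._split_X(X1)
    cfg = clf.config_
    # recompute the source projection and final-layer value vectors
    pre = _stream_prefix(stream, cfg.weight_share)
    p = clf.params_
    Xe = _project(ad.Tensor(eeg), p["proj_eeg_W"], p["proj_eeg_b"],
                  cfg.conv_kernel)
    if cfg.positional_encoding:
        Xe = Xe + ad.Tensor(sinusoidal_positions(eeg.shape[1], cfg.d_model))
    base = f"{pre}.{cfg.n_layers - 1}."
    ln = ad.layer_norm(Xe, p[base + "ln_src_g"], p[base + "ln_src_b"])
    V = ad.matmul(ln, p[base + "Wv"])
    return V.data[0]


def _render_panels(results, out_dir):
    import os

    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    os.makedirs(out_dir, exist_ok=True)
    for i, r in enumerate(results):
        fig, axes = plt.subplots(3, 1, figsize=(8, 3), sharex=True)
        for ax, key in zip(axes, ("uniform", "E>A", "E>B")):
            ax.imshow(r["panels"][key][None, :], aspect="auto",
                      cmap="gray", vmin=0, vmax=1)
            ax.set_yticks([])
            ax.set_ylabel(key, rotation=0, ha="right", va="center")
        axes[-1].set_xlabel("EEG time step")
        fig.suptitle(f"sample {i}: attended={r['attended']} "
                     f"predicted={r['predicted']}")
        fig.savefig(os.path.join(out_dir, f"attention_{i:03d}.png"),
                    dpi=100)
        plt.close(fig)
    np.savez(os.path.join(out_dir, "attention_arrays.npz"),
             **{f"{i}:{k}": r["panels"][k] for i, r in enumerate(results)
                for k in r["panels"]})


def grid_sweep(train_windows, val_windows, test_windows, cfg: TrainConfig,
               learning_rates=(1e-4,), d_models=(32,)):
    """Minimal grid sweep over (learning_rate, d_model); selection by
    validation accuracy, reporting test accuracy of the winner."""
    best = None
    table = []
    for lr in learning_rates:
        for dm in d_models:
            c = TrainConfig(**{**cfg.__dict__, "learning_rate": lr})
            clf, hist = train(train_windows, val_windows, c,
                              ModelConfig(d_model=dm))
            val_acc = max(hist["val_accuracy"]) if hist["val_accuracy"] \
                else np.nan
            table.append({"learning_rate": lr, "d_model": dm,
                          "val_accuracy": val_acc})
            if best is None or val_acc > best[0]:
                best = (val_acc, clf)
    acc, _ = evaluate(best[1], test_windows)
    return {"table": table, "test_accuracy": acc, "classifier": best[1]}
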