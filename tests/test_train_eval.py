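"""Protocol machinery: windowing arithmetic, trial-level splits, training
and evaluation mechanics, multi-run reporting and the leakage audit."""

import numpy as np
import pytest

from cmaad.io import DecisionWindow
from cmaad.model import ModelConfig
from cmaad.train_eval import (TrainConfig, count_windows, evaluate,
                              export_attention_maps, leakage_audit,
                              make_windows, repeated_runs, run_experiment,
                              split_dataset, train)
from tests.conftest import make_processed_trial, make_window


class TestWindows:
    def test_counts_match_closed_form(self, rng):
        """50 s trial at 70 Hz: 49 two-second windows at 50 % overlap,
        19 five-second windows."""
        trial = make_processed_trial(rng, S=3500)
        assert len(make_windows(trial, 2.0, 0.5)) == 49
        assert len(make_windows(trial, 5.0, 0.5)) == 19

    def test_zero_overlap_exact_tiling(self, rng):
        trial = make_processed_trial(rng, S=280)   # 2 windows of 2 s
        wins = make_windows(trial, 2.0, 0.0)
        assert len(wins) == 2
        np.testing.assert_array_equal(wins[0].eeg,
                                      trial.eeg_feat[:, :140])
        np.testing.assert_array_equal(wins[1].eeg,
                                      trial.eeg_feat[:, 140:])

    def test_label_and_provenance_inherited(self, rng):
        trial = make_processed_trial(rng, S=700, attended="B",
                                     trial_id="T7")
        wins = make_windows(trial, 2.0, 0.5)
        assert all(w.attended == "B" for w in wins)
        assert all(w.source_trial_id == "T7" for w in wins)
        assert [w.window_index for w in wins] == list(range(len(wins)))

    def test_short_trial_empty_with_warning(self, rng, caplog):
        trial = make_processed_trial(rng, S=100)
        assert make_windows(trial, 2.0, 0.5) == []

    @pytest.mark.parametrize("S,T,overlap", [
        (3500, 140, 0.5), (3500, 350, 0.5), (1400, 140, 0.0),
        (999, 70, 0.25),
    ])
    def test_formula_consistency(self, rng, S, T, overlap):
        trial = make_processed_trial(rng, S=S)
        assert len(make_windows(trial, T / 70.0, overlap)) == \
            count_windows(S, T, overlap)


class TestSplit:
    def test_60_trials_split_48_6_6(self, rng):
        trials = [make_processed_trial(rng, S=10, trial_id=f"T{i}")
                  for i in range(60)]
        tr, va, te = split_dataset(trials, seed=0)
        assert (len(tr), len(va), len(te)) == (48, 6, 6)
        ids = {t.trial_id for t in tr + va + te}
        assert len(ids) == 60       # disjoint cover

    def test_reproducible_and_seed_sensitive(self, rng):
        trials = [make_processed_trial(rng, S=10, trial_id=f"T{i}")
                  for i in range(20)]
        a1 = [t.trial_id for t in split_dataset(trials, seed=4)[0]]
        a2 = [t.trial_id for t in split_dataset(trials, seed=4)[0]]
        assert a1 == a2
        others = [[t.trial_id for t in split_dataset(trials, seed=s)[0]]
                  for s in range(5)]
        assert any(o != a1 for o in others)

    def test_too_few_trials_raises(self, rng):
        with pytest.raises(ValueError, match="empty partition"):
            split_dataset([make_processed_trial(rng, S=10)], seed=0)


class _StubClassifier:
    """Deterministic decider for protocol tests."""

    def __init__(self, answer="A"):
        self.answer = answer

    def predict(self, X):
        return np.array([self.answer] * len(X))


class TestEvaluate:
    def test_all_correct(self, rng):
        wins = [make_window(rng, attended="A") for _ in range(10)]
        acc, df = evaluate(_StubClassifier("A"), wins)
        assert acc == 1.0
        assert df["correct"].all()

    def test_accuracy_counts_fraction(self, rng):
        wins = [make_window(rng, attended="A" if i < 3 else "B")
                for i in range(10)]
        acc, _ = evaluate(_StubClassifier("A"), wins)
        assert acc == 0.3

    def test_invariant_to_window_order(self, rng):
        wins = [make_window(rng, attended="A" if i % 3 else "B")
                for i in range(12)]
        acc1, _ = evaluate(_StubClassifier("B"), wins)
        acc2, _ = evaluate(_StubClassifier("B"), wins[::-1])
        assert acc1 == acc2

    def test_empty_test_set_raises(self):
        with pytest.raises(ValueError):
            evaluate(_StubClassifier(), [])


def tiny_train_setup(rng, n_trials=8, informative=True):
    """Small window sets; when ``informative`` the envelope of the attended
    speaker is copied into an EEG channel, so the task is learnable."""
    wins = {"train": [], "val": [], "test": []}
    for i in range(n_trials):
        attended = "A" if i % 2 == 0 else "B"
        for part, k in (("train", 6), ("val", 2), ("test", 2)):
            for _ in range(k):
                w = make_window(rng, M=3, T=12, attended=attended)
                if informative:
                    src = w.env_a if attended == "A" else w.env_b
                    w.eeg[0] = src + 0.1 * rng.standard_normal(len(src))
                wins[part].append(w)
    return wins


class TestTrainLoop:
    def test_loss_decreases_on_learnable_data(self, rng):
        wins = tiny_train_setup(rng)
        cfg = TrainConfig(epochs=15, learning_rate=3e-3, batch_size=16,
                          seed=0)
        clf, hist = train(wins["train"], wins["val"], cfg,
                          ModelConfig(d_model=4, n_layers=1, dropout=0.0))
        assert hist["train_loss"][-1] < hist["train_loss"][0]
        assert len(hist["val_accuracy"]) == 15

    def test_label_shuffle_is_at_chance(self, rng):
        """Shuffled labels destroy the stimulus-response association, so
        validation accuracy stays inside the chance binomial band."""
        wins = tiny_train_setup(rng, n_trials=8)
        labels = [w.attended for w in wins["train"]]
        perm = rng.permutation(len(labels))
        for w, j in zip(wins["train"], perm):
            w.attended = labels[j]
        cfg = TrainConfig(epochs=6, learning_rate=1e-3, batch_size=16,
                          seed=1)
        clf, hist = train(wins["train"], wins["val"], cfg,
                          ModelConfig(d_model=4, n_layers=1, dropout=0.0))
        n = len(wins["val"])
        half_width = 1.96 * 0.5 / np.sqrt(n)
        acc = hist["val_accuracy"][-1]
        assert 0.5 - half_width - 0.05 <= acc <= 0.5 + half_width + 0.05

    def test_empty_training_set_raises(self):
        with pytest.raises(ValueError):
            train([], [], TrainConfig())


class TestRepeatedRuns:
    def test_single_run_sd_zero(self, rng):
        wins = tiny_train_setup(rng, n_trials=4)
        cfg = TrainConfig(epochs=1, seed=0)
        res = repeated_runs(wins["train"], wins["val"], wins["test"], cfg,
                            ModelConfig(d_model=4, n_layers=1), n_runs=1)
        assert res["sd_accuracy"] == 0.0
        assert len(res["accuracies"]) == 1

    def test_mean_between_min_and_max(self, rng):
        wins = tiny_train_setup(rng, n_trials=4)
        cfg = TrainConfig(epochs=1, seed=0)
        res = repeated_runs(wins["train"], wins["val"], wins["test"], cfg,
                            ModelConfig(d_model=4, n_layers=1), n_runs=3)
        accs = res["accuracies"]
        assert min(accs) <= res["mean_accuracy"] <= max(accs)
        # runs differ only by initialization seed
        seeds = {r["classifier"].random_state for r in res["runs"]}
        assert len(seeds) == 3


class TestEndToEndProtocol:
    @pytest.fixture(scope="class")
    def small_experiment(self):
        from cmaad.synthetic import SimConfig, gen_trials

        sim = SimConfig(n_trials=10, trial_seconds=6.0, n_channels=6,
                        fs_audio=8000.0, noise_snr_db=10.0, seed=21)
        trials = gen_trials(sim)
        cfg = TrainConfig(window_seconds=2.0, epochs=2, learning_rate=1e-3,
                          batch_size=16, seed=21)
        return run_experiment(trials, cfg,
                              ModelConfig(d_model=4, n_layers=1), seed=21)

    def test_partitions_and_window_counts(self, small_experiment):
        res = small_experiment
        # 6 s at 70 Hz = 420 samples -> 5 windows of 140 at stride 70
        assert res["n_windows"]["train"] == 8 * 5
        assert res["n_windows"]["val"] == 5
        assert res["n_windows"]["test"] == 5

    def test_leakage_audit_passes(self, small_experiment):
        assert leakage_audit(small_experiment)

    def test_audit_detects_tampering(self, small_experiment):
        res = dict(small_experiment)
        res["train_trial_ids"] = list(res["train_trial_ids"])[:-1] + ["T99"]
        assert not leakage_audit(res)

    def test_csp_fitted_on_training_trials_only(self, small_experiment):
        res = small_experiment
        assert set(res["csp"].fitted_on_) == set(res["train_trial_ids"])
        test_ids = {w.source_trial_id for w in res["windows"]["test"]}
        assert test_ids.isdisjoint(res["csp"].fitted_on_)


class TestAttentionExport:
    def test_panels_shapes_and_ranges(self, rng, tmp_path):
        wins = tiny_train_setup(rng, n_trials=2)
        cfg = TrainConfig(epochs=1, seed=0)
        clf, _ = train(wins["train"], wins["val"], cfg,
                       ModelConfig(d_model=4, n_layers=1))
        out = export_attention_maps(clf, wins["test"][:3],
                                    out_dir=str(tmp_path))
        assert len(out) == 3
        for r in out:
            T = len(r["panels"]["uniform"])
            np.testing.assert_allclose(r["panels"]["uniform"], 1.0 / T)
            for key in ("E>A", "E>B"):
                p = r["panels"][key]
                assert p.min() >= 0 and p.max() <= 1 + 1e-6
            assert r["maps"]["EA"].shape == (T, T)
        assert (tmp_path / "attention_000.png").exists()
        assert (tmp_path / "attention_arrays.npz").exists()


class TestTransformersAndSweep:
    def test_eeg_preprocessor_transformer(self, rng):
        from cmaad.preprocess import EEGPreprocessor
        from tests.test_preprocess import synthetic_raw

        pre = EEGPreprocessor().fit([])
        out = pre.transform([synthetic_raw(rng, M=4, seconds=4.0)])
        assert out[0].shape == (4, 280)
        assert pre.get_params()["target_fs"] == 70.0

    def test_envelope_extractor_transformer(self, rng):
        from cmaad.envelope import EnvelopeExtractor

        ext = EnvelopeExtractor(n_bands=8).fit([])
        t = np.arange(8000 * 3) / 8000.0
        wav = np.sin(2 * np.pi * 500 * t)
        envs = ext.transform([(wav, 8000.0), (wav * 2, 8000.0)])
        assert all(len(e) == 210 for e in envs)

    def test_grid_sweep_selects_by_validation(self, rng):
        from cmaad.train_eval import grid_sweep
        from tests.conftest import make_window

        wins = [make_window(rng, M=3, T=10,
                            attended="A" if i % 2 else "B")
                for i in range(30)]
        cfg = TrainConfig(epochs=1, seed=0)
        res = grid_sweep(wins[:18], wins[18:24], wins[24:], cfg,
                         learning_rates=(1e-3, 1e-2), d_models=(4,))
        assert len(res["table"]) == 2
        assert 0.0 <= res["test_accuracy"] <= 1.0
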