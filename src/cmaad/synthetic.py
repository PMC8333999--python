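"""Forward-model simulator for auditory-attention EEG experiments.

Each synthetic trial follows the classical linear encoding assumption: the
cortex tracks the attended speech envelope through a temporal response
function (TRF).  Two speech-like audio streams are generated (noise carriers
amplitude-modulated at syllabic 2-8 Hz rates); the EEG is the sum of

* a spatial pattern times (TRF * attended envelope) at ``attended_gain``,
* a second pattern times (TRF * unattended envelope) at ``unattended_gain``,
* spatially mixed pink noise scaled to ``noise_snr_db``.

Spatial patterns and the noise mixing matrix are fixed per subject (seeded),
so spatial filters have stable structure to exploit.  Setting both gains
equal and sharing one spatial pattern produces a trial that carries no
attention information at all - the chance-level control.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, replace
from fractions import Fraction

import numpy as np
from scipy import signal

from .io import (DatasetManifest, RawTrial, write_bdf, write_manifest,
                 write_wav)


@dataclass
class SimConfig:
    """Study-shape and physics parameters of the simulator.

    Defaults mirror a single-subject listening experiment (60 trials of
    50 s), with desk-scale acquisition parameters: 16 EEG channels at
    512 Hz and 8 kHz audio (the envelope chain clamps its filterbank below
    Nyquist, so the identical code path serves 48 kHz recordings).
    """

    n_subjects: int = 1
    n_trials: int = 60
    trial_seconds: float = 50.0
    fs_eeg: float = 512.0
    fs_audio: float = 8000.0
    n_channels: int = 16
    trf_peaks_ms: tuple = (100.0, 200.0)
    trf_signs: tuple = (1.0, -1.0)
    attended_gain: float = 1.0
    unattended_gain: float = 0.3
    noise_snr_db: float = 0.0
    envelope_band: tuple = (2.0, 8.0)
    seed: int = 0
    identical_patterns: bool = False

    def validate(self) -> "SimConfig":
        if self.attended_gain < 0 or self.unattended_gain < 0:
            raise ValueError("gains must be nonnegative")
        if self.trial_seconds <= 0:
            raise ValueError("trial_seconds must be positive")
        lo, hi = self.envelope_band
        if not 0 < lo < hi < self.fs_eeg / 2:
            raise ValueError("envelope_band must lie inside (0, fs_eeg/2)")
        return self

    def undecodable(self) -> "SimConfig":
        """Symmetric construction: no class information whatsoever."""
        return replace(self, unattended_gain=self.attended_gain,
                       identical_patterns=True)


def channel_names(n_channels: int):
    """Generic montage: scalp channels plus two mastoids (last two)."""
    return [f"C{i + 1:02d}" for i in range(n_channels - 2)] + ["M1", "M2"]


# ---------------------------------------------------------------------------
# primitive generators
# ---------------------------------------------------------------------------

def _band_noise(n: int, fs: float, band, rng) -> np.ndarray:
    """Zero-mean Gaussian noise bandpassed to ``band`` (4th-order
    Butterworth, zero phase)."""
    x = rng.standard_normal(n)
    sos = signal.butter(4, band, btype="bandpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, x)


def _modulator(n: int, fs: float, band, rng) -> np.ndarray:
    """Nonnegative slow amplitude modulator with spectral mass in ``band``."""
    m = _band_noise(n, fs, band, rng)
    m = m / (m.std() + 1e-30)
    return np.maximum(m + 1.5, 0.0)   # mostly positive offset, rare clipping


def gen_speech_like_envelope(seconds: float, fs: float, band=(2.0, 8.0),
                             seed=0):
    """Speech-like waveform: broadband noise carrier amplitude-modulated at
    syllabic rates.  Returns ``(waveform, modulator)`` at rate ``fs``."""
    n = int(round(seconds * fs))
    if n == 0:
        return np.zeros(0), np.zeros(0)
    rng = np.random.default_rng(np.asarray([seed], dtype=np.uint32))
    mod = _modulator(n, fs, band, rng)
    carrier_band = (120.0, min(3900.0, 0.45 * fs))
    carrier = _band_noise(n, fs, carrier_band, rng)
    carrier /= np.abs(carrier).max() + 1e-30
    wav = carrier * mod
    peak = np.abs(wav).max()
    if peak > 0:
        wav = 0.5 * wav / peak
        mod = 0.5 * mod / peak
    return wav, mod


def gen_trf(peaks_ms=(100.0, 200.0), signs=(1.0, -1.0), fs: float = 512.0,
            width_ms: float = 25.0) -> np.ndarray:
    """Biphasic temporal response function: signed Gaussian bumps at the
    given latencies, unit peak magnitude, 0-400 ms support."""
    n = int(round(0.4 * fs))
    t = np.arange(n) / fs * 1000.0
    kern = np.zeros(n)
    for peak, sign in zip(peaks_ms, signs):
        kern += sign * np.exp(-0.5 * ((t - peak) / width_ms) ** 2)
    m = np.abs(kern).max()
    return kern / m if m > 0 else kern


def _pink_noise(shape, rng) -> np.ndarray:
    """1/f-amplitude noise along the last axis, unit variance."""
    white = rng.standard_normal(shape)
    spec = np.fft.rfft(white, axis=-1)
    f = np.fft.rfftfreq(shape[-1])
    scale = np.ones_like(f)
    scale[1:] = 1.0 / np.sqrt(f[1:])
    scale[0] = 0.0
    x = np.fft.irfft(spec * scale, n=shape[-1], axis=-1)
    return x / (x.std(axis=-1, keepdims=True) + 1e-30)


def _subject_forward_model(cfg: SimConfig, subject: int):
    """Per-subject fixed quantities: spatial patterns (zero on mastoids)
    and the noise mixing matrix."""
    rng = np.random.default_rng(
        np.asarray([cfg.seed, 7919, subject], dtype=np.uint32))
    M = cfg.n_channels
    scalp = M - 2

    def pattern():
        p = np.zeros(M)
        p[:scalp] = rng.standard_normal(scalp)
        return p / np.linalg.norm(p)

    pat_att = pattern()
    pat_un = pat_att if cfg.identical_patterns else pattern()
    mix, _ = np.linalg.qr(rng.standard_normal((M, M)))
    return {"pattern_attended": pat_att, "pattern_unattended": pat_un,
            "noise_mixing": mix}


def gen_trial(cfg: SimConfig, attended: str, seed: int,
              subject: int = 0) -> RawTrial:
    """Generate one trial; fully reproducible from ``(cfg.seed, seed)``.

    Ground-truth forward-model quantities are attached as the oracle-only
    attribute ``ground_truth`` (never consumed by the decoding pipeline).
    """
    cfg = cfg.validate()
    if attended not in ("A", "B"):
        raise ValueError("attended must be 'A' or 'B'")
    fwd = _subject_forward_model(cfg, subject)
    rng = np.random.default_rng(
        np.asarray([cfg.seed, 104729, subject, seed], dtype=np.uint32))
    S = int(round(cfg.trial_seconds * cfg.fs_eeg))

    # speech-like streams; modulators generated at EEG rate, audio upsampled
    mods, wavs = [], []
    for _ in range(2):
        sub_seed = int(rng.integers(0, 2 ** 31 - 1))
        srng = np.random.default_rng(np.asarray([sub_seed], dtype=np.uint32))
        mod = _modulator(S, cfg.fs_eeg, cfg.envelope_band, srng)
        carrier_band = (120.0, min(3900.0, 0.45 * cfg.fs_audio))
        n_audio = int(round(cfg.trial_seconds * cfg.fs_audio))
        carrier = _band_noise(n_audio, cfg.fs_audio, carrier_band, srng)
        carrier /= np.abs(carrier).max() + 1e-30
        frac = Fraction(cfg.fs_audio / cfg.fs_eeg).limit_denominator(10000)
        mod_audio = signal.resample_poly(mod, frac.numerator, frac.denominator)
        mod_audio = np.maximum(mod_audio[:n_audio], 0.0)
        if len(mod_audio) < n_audio:
            mod_audio = np.pad(mod_audio, (0, n_audio - len(mod_audio)),
                               mode="edge")
        wav = carrier * mod_audio
        peak = np.abs(wav).max() + 1e-30
        wavs.append(0.5 * wav / peak)
        mods.append(mod)

    trf = gen_trf(cfg.trf_peaks_ms, cfg.trf_signs, cfg.fs_eeg)
    resp = [np.convolve(m - m.mean(), trf)[:S] for m in mods]
    att_idx = 0 if attended == "A" else 1
    sig = (cfg.attended_gain *
           np.outer(fwd["pattern_attended"], resp[att_idx]) +
           cfg.unattended_gain *
           np.outer(fwd["pattern_unattended"], resp[1 - att_idx]))

    noise = fwd["noise_mixing"] @ _pink_noise((cfg.n_channels, S), rng)
    p_sig = float(np.mean(sig ** 2))
    p_noise = float(np.mean(noise ** 2))
    if p_sig > 0 and p_noise > 0:
        target = p_sig / (10.0 ** (cfg.noise_snr_db / 10.0))
        noise *= np.sqrt(target / p_noise)
    eeg = sig + noise
    eeg *= 20.0 / (np.sqrt(np.mean(eeg ** 2)) + 1e-30)  # ~20 uV RMS

    names = channel_names(cfg.n_channels)
    trial = RawTrial(
        eeg=eeg, fs_eeg=cfg.fs_eeg, channel_names=names,
        mastoid_indices=(cfg.n_channels - 2, cfg.n_channels - 1),
        audio_a=wavs[0], audio_b=wavs[1], fs_audio=cfg.fs_audio,
        attended=attended, condition="synthetic",
        subject_id=f"sim{subject:02d}", trial_id=f"trial{seed:04d}",
    ).validate()
    trial.ground_truth = {  # oracle-only; not part of the data contract
        "trf": trf, "modulators": mods, **fwd,
        "attended_gain": cfg.attended_gain,
        "unattended_gain": cfg.unattended_gain,
    }
    return trial


def _balanced_labels(n: int, rng) -> list:
    labels = ["A", "B"] * (n // 2) + (["A"] if n % 2 else [])
    rng.shuffle(labels)
    return labels


def gen_trials(cfg: SimConfig, subject: int = 0):
    """All trials of one subject, balanced attended-A/B (+-1 trial)."""
    cfg = cfg.validate()
    rng = np.random.default_rng(
        np.asarray([cfg.seed, 15485863, subject], dtype=np.uint32))
    labels = _balanced_labels(cfg.n_trials, rng)
    return [gen_trial(cfg, lab, k, subject=subject)
            for k, lab in enumerate(labels)]


def gen_dataset(cfg: SimConfig, out_dir: str) -> DatasetManifest:
    """Write a full dataset to disk: BDF EEG + WAV audio per trial plus a
    CSV manifest; byte-identical across runs with the same config."""
    import pandas as pd
    import warnings

    cfg = cfg.validate()
    os.makedirs(out_dir, exist_ok=True)
    rows = []
    for subject in range(cfg.n_subjects):
        for trial in gen_trials(cfg, subject=subject):
            stem = f"{trial.subject_id}_{trial.trial_id}"
            eeg_path = f"{stem}.bdf"
            wav_a, wav_b = f"{stem}_a.wav", f"{stem}_b.wav"
            write_bdf(os.path.join(out_dir, eeg_path), trial.eeg,
                      trial.fs_eeg, trial.channel_names)
            write_wav(os.path.join(out_dir, wav_a), trial.audio_a,
                      trial.fs_audio)
            write_wav(os.path.join(out_dir, wav_b), trial.audio_b,
                      trial.fs_audio)
            rows.append({
                "eeg_path": eeg_path, "audio_a_path": wav_a,
                "audio_b_path": wav_b, "subject_id": trial.subject_id,
                "trial_id": trial.trial_id, "condition": trial.condition,
                "attended": trial.attended, "offset_ms": 0.0,
            })
    if cfg.n_trials % 2:
        warnings.warn("odd n_trials: attended labels balanced only to +-1")
    manifest = DatasetManifest(entries=pd.DataFrame(rows))
    manifest.validate(base_dir=out_dir)
    write_manifest(manifest, os.path.join(out_dir, "manifest.csv"))
    return manifest
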