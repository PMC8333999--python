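"""Auditory-inspired broadband speech envelope extraction.

The chain mimics peripheral auditory processing: an ERB-spaced gammatone
filterbank (150-4000 Hz) splits the waveform into subbands, each subband's
Hilbert envelope is power-law compressed (exponent 0.6, approximating
cochlear compression), the compressed subband envelopes are summed into a
broadband envelope, which is then bandpass-filtered with the same 2-32 Hz
design used for the EEG and downsampled to the common 70 Hz rate.  Within a
trial the two competing streams' envelopes are finally equalized to the same
RMS so that level differences carry no attention information.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal
from sklearn.base import BaseEstimator, TransformerMixin

from .preprocess import bandpass_fir, resample_to


@dataclass
class EnvelopeConfig:
    filterbank_low: float = 150.0
    filterbank_high: float = 4000.0
    n_bands: int = 28
    compression_exponent: float = 0.6
    post_band: tuple = (2.0, 32.0)
    post_fir_order: int = 513
    target_fs: float = 70.0

    def validate(self) -> "EnvelopeConfig":
        if not 0 < self.filterbank_low < self.filterbank_high:
            raise ValueError("filterbank edges must satisfy 0 < low < high")
        if not 0 < self.compression_exponent <= 1:
            raise ValueError("compression exponent must lie in (0, 1]")
        if self.n_bands < 1:
            raise ValueError("n_bands must be >= 1")
        return self


def _hz_to_cam(f):
    return 21.4 * np.log10(4.37 * np.asarray(f, dtype=float) / 1000.0 + 1.0)


def _cam_to_hz(cam):
    return (10.0 ** (np.asarray(cam, dtype=float) / 21.4) - 1.0) * 1000.0 / 4.37


def erb_center_frequencies(low: float, high: float, n_bands: int) -> np.ndarray:
    """Center frequencies uniformly spaced on the ERB-number (Cam) scale."""
    if n_bands == 1:
        return np.array([_cam_to_hz((_hz_to_cam(low) + _hz_to_cam(high)) / 2.0)])
    cams = np.linspace(_hz_to_cam(low), _hz_to_cam(high), n_bands)
    return _cam_to_hz(cams)


def _effective_high(cfg: EnvelopeConfig, fs: float) -> float:
    # keep the top band comfortably below Nyquist at low audio rates
    return min(cfg.filterbank_high, 0.475 * fs)


def gammatone_filterbank(audio: np.ndarray, fs: float,
                         cfg: EnvelopeConfig | None = None) -> np.ndarray:
    """Filter a waveform into ``n_bands`` ERB-spaced gammatone subbands.

    Returns an [n_bands x len(audio)] matrix.  The upper edge is clamped just
    below Nyquist when the audio rate is low, so the same code path serves
    8 kHz simulations and 48 kHz recordings.
    """
    cfg = (cfg or EnvelopeConfig()).validate()
    high = _effective_high(cfg, fs)
    if high <= cfg.filterbank_low:
        raise ValueError(
            f"sampling rate {fs} Hz too low for filterbank starting at "
            f"{cfg.filterbank_low} Hz")
    audio = np.asarray(audio, dtype=float)
    centers = erb_center_frequencies(cfg.filterbank_low, high, cfg.n_bands)
    out = np.empty((cfg.n_bands, audio.shape[0]))
    for i, fc in enumerate(centers):
        b, a = signal.gammatone(fc, "iir", fs=fs)
        out[i] = signal.lfilter(b, a, audio)
    return out


def subband_envelope_powerlaw(subbands: np.ndarray,
                              exponent: float = 0.6) -> np.ndarray:
    """Hilbert-magnitude envelope of each subband, power-law compressed."""
    if exponent <= 0:
        raise ValueError("exponent must be positive")
    subbands = np.atleast_2d(np.asarray(subbands, dtype=float))
    env = np.abs(signal.hilbert(subbands, axis=-1))
    return env ** exponent


def broadband_envelope(audio: np.ndarray, fs: float,
                       cfg: EnvelopeConfig | None = None) -> np.ndarray:
    """Full chain: filterbank -> compressed subband envelopes -> sum ->
    2-32 Hz filter (same design as the EEG bandpass) -> resample to 70 Hz."""
    cfg = (cfg or EnvelopeConfig()).validate()
    audio = np.asarray(audio, dtype=float)
    if audio.size == 0:
        return np.zeros(0)
    sub = gammatone_filterbank(audio, fs, cfg)
    env = subband_envelope_powerlaw(sub, cfg.compression_exponent)
    broad = env.sum(axis=0)
    broad = bandpass_fir(broad, fs, cfg.post_band, cfg.post_fir_order)
    return resample_to(broad, fs, cfg.target_fs)


def rms_equalize(env_a: np.ndarray, env_b: np.ndarray):
    """Scale both envelopes to unit RMS (removes any level cue)."""
    env_a = np.asarray(env_a, dtype=float)
    env_b = np.asarray(env_b, dtype=float)
    out = []
    for name, e in (("env_a", env_a), ("env_b", env_b)):
        rms = float(np.sqrt(np.mean(e ** 2)))
        if rms <= 0 or not np.isfinite(rms):
            raise ValueError(f"{name} has zero energy; cannot RMS-equalize")
        out.append(e / rms)
    return out[0], out[1]


class EnvelopeExtractor(BaseEstimator, TransformerMixin):
    """Stateless sklearn-style wrapper around :func:`broadband_envelope`.

    ``transform`` maps a list of (waveform, fs) pairs to 70 Hz envelopes.
    """

    def __init__(self, filterbank_low=150.0, filterbank_high=4000.0,
                 n_bands=28, compression_exponent=0.6, target_fs=70.0):
        self.filterbank_low = filterbank_low
        self.filterbank_high = filterbank_high
        self.n_bands = n_bands
        self.compression_exponent = compression_exponent
        self.target_fs = target_fs

    def _config(self) -> EnvelopeConfig:
        return EnvelopeConfig(
            filterbank_low=self.filterbank_low,
            filterbank_high=self.filterbank_high, n_bands=self.n_bands,
            compression_exponent=self.compression_exponent,
            target_fs=self.target_fs)

    def fit(self, X, y=None):
        self._config().validate()
        return self

    def transform(self, X):
        cfg = self._config()
        return [broadband_envelope(wav, fs, cfg) for wav, fs in X]
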