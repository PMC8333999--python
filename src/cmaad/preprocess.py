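"""EEG preprocessing chain: line-noise suppression, mastoid re-referencing,
2-32 Hz bandpass, downsampling to 70 Hz, per-trial standardization.

All stages are linear except the final standardization, so the chain output
is invariant to positive rescaling of the raw input.  Every stage is
deterministic; identical input and config give bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import signal
from sklearn.base import BaseEstimator, TransformerMixin


class DegenerateChannelError(ValueError):
    """A channel is constant (zero variance) where variance is required."""


@dataclass
class PreprocConfig:
    """Parameters of the EEG preprocessing chain.

    ``line_freq``: mains frequency to notch out (with harmonics).
    ``bandpass``: passband edges in Hz (2-32 Hz keeps the cortical
    envelope-tracking band).  ``fir_order``: taps of the windowed-sinc FIR at
    a 512 Hz reference rate (scaled proportionally at other rates).
    ``target_fs``: common rate for EEG and envelopes.
    """

    line_freq: float = 50.0
    bandpass: tuple = (2.0, 32.0)
    fir_order: int = 513
    target_fs: float = 70.0
    normalize: bool = True
    n_harmonics: int = 3
    notch_q: float = 30.0
    artifact_hook: object = None  # callable (eeg, fs) -> eeg, or None

    def validate(self) -> "PreprocConfig":
        low, high = self.bandpass
        if not 0 < low < high:
            raise ValueError("bandpass must satisfy 0 < low < high")
        if high >= self.target_fs / 2:
            raise ValueError("bandpass high edge must sit below the "
                             "post-resampling Nyquist (target_fs / 2)")
        return self


def remove_line_noise(eeg: np.ndarray, fs: float, line_freq: float = 50.0,
                      n_harmonics: int = 3, q: float = 30.0) -> np.ndarray:
    """Suppress mains interference with a zero-phase IIR notch cascade at the
    line frequency and its harmonics below Nyquist."""
    if line_freq >= fs / 2:
        raise ValueError(f"line_freq {line_freq} must be below Nyquist {fs / 2}")
    out = np.asarray(eeg, dtype=float)
    # generous padding keeps the narrow notch's edge transients small
    padlen = min(out.shape[-1] - 1, int(4 * fs))
    for k in range(1, n_harmonics + 1):
        f0 = line_freq * k
        if f0 >= fs / 2 * 0.99:
            break
        b, a = signal.iirnotch(f0, q, fs=fs)
        out = signal.filtfilt(b, a, out, axis=-1, padlen=padlen)
    return out


def rereference_mastoid(eeg: np.ndarray, mastoid_indices) -> np.ndarray:
    """Subtract the mean of the two mastoid channels from every channel."""
    eeg = np.atleast_2d(np.asarray(eeg, dtype=float))
    i, j = mastoid_indices
    M = eeg.shape[0]
    if not (0 <= i < M and 0 <= j < M):
        raise IndexError(f"mastoid indices {mastoid_indices} out of range "
                         f"for {M} channels")
    ref = 0.5 * (eeg[i] + eeg[j])
    return eeg - ref[None, :]


def design_bandpass_fir(fs: float, band=(2.0, 32.0), taps: int = 513,
                        ref_fs: float = 512.0) -> np.ndarray:
    """Hamming windowed-sinc bandpass; taps scale with fs to keep the
    transition width in Hz constant across sampling rates."""
    low, high = band
    if not 0 < low < high < fs / 2:
        raise ValueError(f"band {band} must lie inside (0, {fs / 2})")
    n = int(round(taps * fs / ref_fs))
    n += 1 - n % 2  # odd length -> integer group delay, linear phase
    return signal.firwin(n, [low, high], pass_zero=False, window="hamming", fs=fs)


def bandpass_fir(eeg: np.ndarray, fs: float, band=(2.0, 32.0),
                 taps: int = 513) -> np.ndarray:
    """Zero-phase FIR bandpass (symmetric kernel, centred convolution)."""
    h = design_bandpass_fir(fs, band, taps)
    eeg = np.asarray(eeg, dtype=float)
    x = np.atleast_2d(eeg)
    if x.shape[1] < len(h):
        raise ValueError(
            f"signal length {x.shape[1]} shorter than FIR length {len(h)}; "
            "trial too short for the configured filter")
    y = signal.fftconvolve(x, h[None, :], mode="same", axes=-1)
    return y if eeg.ndim == 2 else y[0]


def resample_to(x: np.ndarray, fs_in: float, fs_out: float) -> np.ndarray:
    """Polyphase resampling with built-in anti-aliasing.

    Output length is ``round(len_in * fs_out / fs_in)`` (trimmed/padded from
    the polyphase result when the ratio is not exact).
    """
    if fs_out <= 0:
        raise ValueError("fs_out must be positive")
    if fs_in < fs_out:
        raise ValueError("only downsampling or identity supported")
    x = np.asarray(x, dtype=float)
    if fs_in == fs_out:
        return x.copy()
    frac = Fraction(fs_out / fs_in).limit_denominator(10000)
    y = signal.resample_poly(x, frac.numerator, frac.denominator, axis=-1)
    n_target = int(round(x.shape[-1] * fs_out / fs_in))
    if y.shape[-1] > n_target:
        y = y[..., :n_target]
    elif y.shape[-1] < n_target:
        pad = [(0, 0)] * (y.ndim - 1) + [(0, n_target - y.shape[-1])]
        y = np.pad(y, pad, mode="edge")
    return y


def normalize_trial(eeg: np.ndarray, rtol: float = 1e-12) -> np.ndarray:
    """Standardize every channel to zero mean and unit variance."""
    eeg = np.atleast_2d(np.asarray(eeg, dtype=float))
    mu = eeg.mean(axis=1, keepdims=True)
    sd = eeg.std(axis=1, keepdims=True)
    scale = np.abs(eeg).max() + 1e-300
    flat = np.nonzero(sd[:, 0] <= rtol * scale)[0]
    if flat.size:
        raise DegenerateChannelError(
            f"constant channel(s) {flat.tolist()} cannot be standardized")
    return (eeg - mu) / sd


def preprocess_trial(raw, cfg: PreprocConfig | None = None) -> np.ndarray:
    """Run the full chain on a raw trial's EEG; returns [M x S'] at
    ``cfg.target_fs``.

    Order: line-noise notch -> (artifact hook) -> mastoid re-reference ->
    bandpass FIR -> polyphase downsample -> per-trial standardization.
    """
    cfg = (cfg or PreprocConfig()).validate()
    eeg = np.asarray(raw.eeg, dtype=float)
    fs = float(raw.fs_eeg)
    out = remove_line_noise(eeg, fs, cfg.line_freq, cfg.n_harmonics, cfg.notch_q)
    if cfg.artifact_hook is not None:
        out = cfg.artifact_hook(out, fs)
    out = rereference_mastoid(out, raw.mastoid_indices)
    out = bandpass_fir(out, fs, cfg.bandpass, cfg.fir_order)
    out = resample_to(out, fs, cfg.target_fs)
    if cfg.normalize:
        out = normalize_trial(out)
    return out


class EEGPreprocessor(BaseEstimator, TransformerMixin):
    """Stateless sklearn-style wrapper around :func:`preprocess_trial`.

    ``transform`` accepts a list of :class:`~cmaad.io.RawTrial` and returns
    the list of preprocessed EEG matrices at ``target_fs``.
    """

    def __init__(self, line_freq=50.0, bandpass=(2.0, 32.0), fir_order=513,
                 target_fs=70.0, normalize=True, artifact_hook=None):
        self.line_freq = line_freq
        self.bandpass = bandpass
        self.fir_order = fir_order
        self.target_fs = target_fs
        self.normalize = normalize
        self.artifact_hook = artifact_hook

    def _config(self) -> PreprocConfig:
        return PreprocConfig(
            line_freq=self.line_freq, bandpass=tuple(self.bandpass),
            fir_order=self.fir_order, target_fs=self.target_fs,
            normalize=self.normalize, artifact_hook=self.artifact_hook)

    def fit(self, X, y=None):
        self._config().validate()
        self.n_features_in_ = 0
        return self

    def transform(self, X):
        cfg = self._config()
        return [preprocess_trial(trial, cfg) for trial in X]
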