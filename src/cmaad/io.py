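"""Data model and on-disk formats for auditory-attention-decoding experiments.

A dataset is a collection of *trials*: one multichannel EEG recording plus the
two competing single-speaker audio streams the listener heard, and a label
saying which speaker was attended.  Raw trials live in standard formats
(EDF/BDF for EEG, RIFF WAV for audio) indexed by a flat CSV manifest;
processed trials (70 Hz CSP-enhanced EEG features plus the two speech
envelopes) live in a single versioned HDF5 container per dataset, one group
per trial.
"""

from __future__ import annotations

import json
import os
import warnings
from dataclasses import dataclass, field, replace

import h5py
import numpy as np

SCHEMA_VERSION = "1.0"

#: Channel-name aliases accepted as mastoid electrodes.  BioSemi montages and
#: 10/20 caps disagree on naming, so matching is case-insensitive over this
#: list (first two hits are used, in list order).
DEFAULT_MASTOID_ALIASES = (
    "M1", "M2", "TP9", "TP10", "A1", "A2", "MASTL", "MASTR", "EXG1", "EXG2",
)

MANIFEST_COLUMNS = (
    "eeg_path", "audio_a_path", "audio_b_path",
    "subject_id", "trial_id", "condition", "attended", "offset_ms",
)

CONDITIONS = ("anechoic", "mild_reverb", "high_reverb", "synthetic")


class FormatError(ValueError):
    """A file or container violates the expected on-disk format."""


class SchemaVersionError(FormatError):
    """Container written by an incompatible schema version."""


class MastoidConfigError(ValueError):
    """No mastoid channels could be resolved from the channel names."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class RawTrial:
    """One experimental trial straight off disk (or the simulator).

    ``eeg`` is channels x samples in microvolts at ``fs_eeg``; ``audio_a`` /
    ``audio_b`` are the two competing mono speech waveforms at ``fs_audio``.
    ``attended`` says which stream the listener was instructed to follow.
    """

    eeg: np.ndarray
    fs_eeg: float
    channel_names: list
    mastoid_indices: tuple
    audio_a: np.ndarray
    audio_b: np.ndarray
    fs_audio: float
    attended: str
    condition: str = "synthetic"
    subject_id: str = "S0"
    trial_id: str = "T0"

    def validate(self) -> "RawTrial":
        eeg = np.asarray(self.eeg, dtype=float)
        if eeg.ndim != 2 or eeg.shape[0] < 2:
            raise ValueError("eeg must be a 2-D [channels x samples] matrix "
                             "with at least 2 channels")
        if self.fs_eeg <= 0 or self.fs_audio <= 0:
            raise ValueError("sampling rates must be positive")
        if self.attended not in ("A", "B"):
            raise ValueError(f"attended must be 'A' or 'B', got {self.attended!r}")
        if len(self.audio_a) != len(self.audio_b):
            raise FormatError("audio_a and audio_b must have equal length")
        i, j = self.mastoid_indices
        if not (0 <= i < eeg.shape[0] and 0 <= j < eeg.shape[0]) or i == j:
            raise ValueError("mastoid_indices must be two distinct valid indices")
        return self

    @property
    def n_channels(self) -> int:
        return self.eeg.shape[0]

    @property
    def n_samples(self) -> int:
        return self.eeg.shape[1]


@dataclass
class ProcessedTrial:
    """A trial after preprocessing: aligned 70 Hz EEG features and envelopes.

    ``eeg_feat`` is the CSP-enhanced, per-trial z-normalized EEG; ``env_a``
    and ``env_b`` the RMS-equalized broadband speech envelopes.  All three
    share the sample count S at ``fs`` (70 Hz by default).
    """

    eeg_feat: np.ndarray
    env_a: np.ndarray
    env_b: np.ndarray
    attended: str
    subject_id: str = "S0"
    trial_id: str = "T0"
    condition: str = "synthetic"
    fs: float = 70.0

    def validate(self, rtol: float = 1e-6) -> "ProcessedTrial":
        S = self.eeg_feat.shape[1]
        if len(self.env_a) != S or len(self.env_b) != S:
            raise ValueError("eeg_feat, env_a and env_b must share sample count")
        mu = self.eeg_feat.mean(axis=1)
        var = self.eeg_feat.var(axis=1)
        if np.abs(mu).max() > rtol or np.abs(var - 1.0).max() > max(rtol, 1e-4):
            raise ValueError("eeg_feat channels must be zero-mean unit-variance")
        ra = float(np.sqrt(np.mean(self.env_a ** 2)))
        rb = float(np.sqrt(np.mean(self.env_b ** 2)))
        if abs(ra - rb) > rtol * max(ra, rb, 1.0):
            raise ValueError("env_a and env_b must have equal RMS")
        return self

    @property
    def n_samples(self) -> int:
        return self.eeg_feat.shape[1]


@dataclass
class DecisionWindow:
    """A T-sample slice of a processed trial; the classifier's unit of
    prediction.  Inherits the attended label of its source trial."""

    eeg: np.ndarray
    env_a: np.ndarray
    env_b: np.ndarray
    attended: str
    window_index: int = 0
    source_trial_id: str = "T0"

    def __post_init__(self):
        T = self.eeg.shape[1]
        if len(self.env_a) != T or len(self.env_b) != T:
            raise ValueError("window arrays must share length T")

    @property
    def n_samples(self) -> int:
        return self.eeg.shape[1]


@dataclass
class DatasetManifest:
    """Flat index of a raw dataset: one row per trial (CSV on disk)."""

    entries: "object"  # pandas.DataFrame with MANIFEST_COLUMNS
    schema_version: str = SCHEMA_VERSION

    def validate(self, base_dir: str | None = None,
                 check_files: bool = True) -> "DatasetManifest":
        df = self.entries
        missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"manifest missing columns: {missing}")
        dup = df.duplicated(subset=["subject_id", "trial_id"])
        if dup.any():
            bad = df.loc[dup, ["subject_id", "trial_id"]].values.tolist()
            raise ValueError(f"duplicate (subject_id, trial_id) pairs: {bad}")
        if check_files:
            for col in ("eeg_path", "audio_a_path", "audio_b_path"):
                for p in df[col]:
                    full = os.path.join(base_dir, p) if base_dir else p
                    if not os.path.exists(full):
                        raise FileNotFoundError(f"manifest references missing "
                                                f"file: {full}")
        return self

    def __len__(self) -> int:
        return len(self.entries)


def read_manifest(path: str) -> DatasetManifest:
    import pandas as pd

    if not os.path.exists(path):
        raise FileNotFoundError(f"manifest not found: {path}")
    df = pd.read_csv(path, dtype={"subject_id": str, "trial_id": str})
    if "offset_ms" not in df.columns:
        df["offset_ms"] = 0.0
    return DatasetManifest(entries=df)


def write_manifest(manifest: DatasetManifest, path: str) -> None:
    manifest.entries.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# raw trial reading
# ---------------------------------------------------------------------------

def resolve_mastoids(channel_names, aliases=DEFAULT_MASTOID_ALIASES):
    """Return the indices of the two mastoid channels by alias matching."""
    lower = [c.strip().lower() for c in channel_names]
    hits = []
    for a in aliases:
        a = a.lower()
        if a in lower:
            idx = lower.index(a)
            if idx not in hits:
                hits.append(idx)
        if len(hits) == 2:
            return tuple(hits)
    raise MastoidConfigError(
        "could not resolve two mastoid channels; available channels: "
        f"{list(channel_names)}; accepted aliases: {list(aliases)}")


def read_wav(path: str) -> tuple[np.ndarray, float]:
    """Read a RIFF WAV as float64 mono in [-1, 1]; stereo is mixed down."""
    from scipy.io import wavfile

    if not os.path.exists(path):
        raise FileNotFoundError(f"audio file not found: {path}")
    fs, data = wavfile.read(path)
    data = np.asarray(data)
    if data.dtype == np.int16:
        data = data / 32768.0
    elif data.dtype == np.int32:
        data = data / 2147483648.0
    elif data.dtype == np.uint8:
        data = (data.astype(float) - 128.0) / 128.0
    else:
        data = data.astype(float)
    if data.ndim == 2:
        warnings.warn(f"{path}: multi-channel WAV mixed down to mono")
        data = data.mean(axis=1)
    return data, float(fs)


def read_raw_trial(eeg_path: str, audio_paths, meta,
                   mastoid_aliases=DEFAULT_MASTOID_ALIASES) -> RawTrial:
    """Assemble a :class:`RawTrial` from an EDF/BDF file, two WAVs and a
    manifest entry (dict-like with subject_id/trial_id/condition/attended)."""
    import mne

    if not os.path.exists(eeg_path):
        raise FileNotFoundError(f"EEG file not found: {eeg_path}")
    ext = os.path.splitext(eeg_path)[1].lower()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if ext == ".bdf":
            raw = mne.io.read_raw_bdf(eeg_path, preload=True, verbose="error")
        elif ext == ".edf":
            raw = mne.io.read_raw_edf(eeg_path, preload=True, verbose="error")
        else:
            raise FormatError(f"unsupported EEG format: {ext}")
    eeg = raw.get_data() * 1e6  # volts -> microvolts
    channel_names = list(raw.ch_names)
    fs_eeg = float(raw.info["sfreq"])

    path_a, path_b = audio_paths
    audio_a, fs_a = read_wav(path_a)
    audio_b, fs_b = read_wav(path_b)
    if fs_a != fs_b:
        raise FormatError(f"audio sampling rates differ: {fs_a} vs {fs_b}")
    if abs(len(audio_a) - len(audio_b)) > 1:
        raise FormatError(
            f"audio length mismatch: {len(audio_a)} vs {len(audio_b)} samples")
    n = min(len(audio_a), len(audio_b))
    audio_a, audio_b = audio_a[:n], audio_b[:n]

    mastoids = resolve_mastoids(channel_names, mastoid_aliases)
    get = meta.get if hasattr(meta, "get") else lambda k, d=None: getattr(meta, k, d)
    return RawTrial(
        eeg=eeg, fs_eeg=fs_eeg, channel_names=channel_names,
        mastoid_indices=mastoids, audio_a=audio_a, audio_b=audio_b,
        fs_audio=fs_a, attended=str(get("attended")),
        condition=str(get("condition", "anechoic")),
        subject_id=str(get("subject_id", "S0")),
        trial_id=str(get("trial_id", "T0")),
    ).validate()


# ---------------------------------------------------------------------------
# processed container (HDF5, one group per trial)
# ---------------------------------------------------------------------------

def save_processed(trials, path: str, csp=None) -> None:
    """Write processed trials (and optionally a fitted CSP) to one HDF5 file.

    Layout: root attr ``schema_version``; ``/trials/<k>`` holds datasets
    ``eeg_feat``, ``env_a``, ``env_b`` with trial metadata as group attrs;
    ``/csp`` holds the projection matrix and diagnostics when given.
    """
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        g = f.create_group("trials")
        for k, tr in enumerate(trials):
            gi = g.create_group(f"{k:06d}")
            gi.create_dataset("eeg_feat", data=np.asarray(tr.eeg_feat))
            gi.create_dataset("env_a", data=np.asarray(tr.env_a))
            gi.create_dataset("env_b", data=np.asarray(tr.env_b))
            gi.attrs.update({
                "attended": tr.attended, "subject_id": tr.subject_id,
                "trial_id": tr.trial_id, "condition": tr.condition,
                "fs": tr.fs,
            })
        if csp is not None:
            gc = f.create_group("csp")
            gc.create_dataset("W", data=csp.filters_)
            gc.create_dataset("eigvals_a", data=csp.eigvals_a_)
            gc.create_dataset("Z", data=csp.composite_eigvecs_)
            gc.create_dataset("psi", data=csp.composite_eigvals_)
            gc.attrs["n_components"] = csp.n_components_
            gc.attrs["fitted_on"] = json.dumps(list(csp.fitted_on_))


def load_processed(path: str, with_csp: bool = False):
    """Inverse of :func:`save_processed`; bit-exact array round trip."""
    if not os.path.exists(path):
        raise FileNotFoundError(f"container not found: {path}")
    try:
        f = h5py.File(path, "r")
    except OSError as e:
        raise FormatError(f"corrupted or unreadable container {path}: {e}") from e
    with f:
        ver = str(f.attrs.get("schema_version", ""))
        if ver.split(".")[0] != SCHEMA_VERSION.split(".")[0]:
            raise SchemaVersionError(
                f"container schema_version {ver!r} is incompatible with "
                f"supported {SCHEMA_VERSION!r}")
        trials = []
        for key in sorted(f["trials"].keys()):
            gi = f["trials"][key]
            trials.append(ProcessedTrial(
                eeg_feat=gi["eeg_feat"][()], env_a=gi["env_a"][()],
                env_b=gi["env_b"][()], attended=str(gi.attrs["attended"]),
                subject_id=str(gi.attrs["subject_id"]),
                trial_id=str(gi.attrs["trial_id"]),
                condition=str(gi.attrs["condition"]),
                fs=float(gi.attrs["fs"]),
            ))
        csp_blob = None
        if with_csp and "csp" in f:
            gc = f["csp"]
            csp_blob = {
                "W": gc["W"][()], "eigvals_a": gc["eigvals_a"][()],
                "Z": gc["Z"][()], "psi": gc["psi"][()],
                "n_components": int(gc.attrs["n_components"]),
                "fitted_on": json.loads(gc.attrs["fitted_on"]),
            }
    if with_csp:
        return trials, csp_blob
    return trials


# ---------------------------------------------------------------------------
# minimal BDF writer (BioSemi 24-bit) + WAV writer
# ---------------------------------------------------------------------------

def write_wav(path: str, audio: np.ndarray, fs: float) -> None:
    from scipy.io import wavfile

    wavfile.write(path, int(round(fs)), np.asarray(audio, dtype=np.float32))


def _pad_field(text: str, width: int) -> bytes:
    b = str(text).encode("ascii", "replace")[:width]
    return b + b" " * (width - len(b))


def write_bdf(path: str, eeg_uv: np.ndarray, fs: float, channel_names) -> None:
    """Write a 24-bit BioSemi BDF file (one-second data records).

    The signal is quantized to the 24-bit range spanning +-max(|x|); trials
    whose length is not a whole number of seconds are zero-padded to the next
    record boundary.
    """
    eeg_uv = np.asarray(eeg_uv, dtype=float)
    M, S = eeg_uv.shape
    fs = int(round(fs))
    if len(channel_names) != M:
        raise ValueError("channel_names length must match channel count")
    n_rec = int(np.ceil(S / fs))
    if n_rec * fs != S:
        warnings.warn("BDF trial padded with zeros to a whole data record")
        pad = np.zeros((M, n_rec * fs - S))
        eeg_uv = np.concatenate([eeg_uv, pad], axis=1)

    phys_max = float(np.max(np.abs(eeg_uv)))
    phys_max = max(phys_max, 1.0) * 1.01
    dig_max, dig_min = 8388607, -8388608
    gain = (2 * phys_max) / (dig_max - dig_min)
    digital = np.clip(np.round(eeg_uv / gain), dig_min, dig_max).astype(np.int32)

    header = b"\xffBIOSEMI"
    header += _pad_field("", 80)                       # patient
    header += _pad_field("", 80)                       # recording
    header += _pad_field("01.01.20", 8)                # start date
    header += _pad_field("00.00.00", 8)                # start time
    header += _pad_field(str((M + 1) * 256), 8)        # header bytes
    header += _pad_field("24BIT", 44)                  # reserved / version
    header += _pad_field(str(n_rec), 8)
    header += _pad_field("1", 8)                       # record duration (s)
    header += _pad_field(str(M), 4)
    for fields, width in (
        (channel_names, 16),
        (["simulated"] * M, 80),
        (["uV"] * M, 8),
        ([f"{-phys_max:.6g}"] * M, 8),
        ([f"{phys_max:.6g}"] * M, 8),
        ([str(dig_min)] * M, 8),
        ([str(dig_max)] * M, 8),
        ([""] * M, 80),
        ([str(fs)] * M, 8),
        ([""] * M, 32),
    ):
        for v in fields:
            header += _pad_field(v, width)

    # records: for each second, channels consecutively, 24-bit little-endian
    rec = digital.reshape(M, n_rec, fs).transpose(1, 0, 2)  # (rec, ch, samp)
    flat = rec.reshape(-1).astype("<i4")
    raw4 = flat.view(np.uint8).reshape(-1, 4)
    data = raw4[:, :3].tobytes()
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(data)
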