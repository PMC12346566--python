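"""Acoustic feature pipeline: audio loading, MFCC extraction, length
normalization, and label encoding for the eight diagnosis classes.

Every clip is reduced to a fixed-shape MFCC matrix of 52 coefficients by
926 frames (zero-padded or prefix-truncated), the input contract of the
diagnoser.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.io import wavfile

from pulmodx import _signal

#: The eight diagnosis classes, in codec order (lexicographic).
CLASSES = (
    "COPD",
    "LRTI",
    "URTI",
    "asthma",
    "bronchiectasis",
    "bronchiolitis",
    "healthy",
    "pneumonia",
)

DEFAULT_SAMPLE_RATE = 22_050
DEFAULT_N_MFCC = 52
DEFAULT_TARGET_FRAMES = 926


@dataclass
class AudioClip:
    """A mono waveform with its sample rate and provenance.

    ``samples`` is dimensionless amplitude; ``subject_id`` identifies the
    patient the clip was recorded from (augmented clips inherit it from
    their source so that subject-level splits stay leakage-free).
    """

    samples: np.ndarray
    sample_rate: int
    subject_id: str = ""
    label: str | None = None
    #: True for clips produced by the augmentation pipeline; such clips
    #: inherit subject_id from their source, which is what keeps
    #: subject-level splits leakage-free.
    augmented: bool = False

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ValueError("AudioClip requires a mono (1-D) waveform")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("AudioClip samples must be finite")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")

    @property
    def duration(self) -> float:
        return len(self.samples) / self.sample_rate


@dataclass
class MFCCMatrix:
    """MFCC feature matrix: ``values`` has n_mfcc rows x n_frames columns."""

    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("MFCCMatrix must be 2-D (n_mfcc, n_frames)")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("MFCCMatrix entries must be finite")

    @property
    def n_mfcc(self) -> int:
        return self.values.shape[0]

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]


def load_audio(path: str | Path, target_rate: int = DEFAULT_SAMPLE_RATE,
               subject_id: str = "", label: str | None = None) -> AudioClip:
    """Load a WAV file as a mono clip resampled to ``target_rate`` Hz.

    Integer PCM is scaled to [-1, 1]; multichannel input is average-downmixed
    to mono before resampling.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"audio file not found: {path}")
    try:
        sr, data = wavfile.read(path)
    except Exception as exc:  # noqa: BLE001 - re-raise with the path named
        raise ValueError(f"could not decode audio file {path}: {exc}") from exc
    data = np.asarray(data)
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(np.float64) / float(np.iinfo(data.dtype).max)
    else:
        data = data.astype(np.float64)
    if data.ndim == 2:
        data = data.mean(axis=1)
    y = _signal.resample(data, sr, target_rate)
    return AudioClip(samples=y, sample_rate=target_rate,
                     subject_id=subject_id, label=label)


def save_audio(clip: AudioClip, path: str | Path) -> None:
    """Write a clip as 32-bit float WAV."""
    wavfile.write(Path(path), clip.sample_rate, clip.samples.astype(np.float32))


def extract_mfcc(clip: AudioClip, n_mfcc: int = DEFAULT_N_MFCC,
                 n_mels: int = 128) -> MFCCMatrix:
    """Extract an MFCC matrix (n_mfcc rows) from a clip.

    Uses a 2048-sample Hann window with hop 512 and centered frames, so a
    clip of n samples yields ``1 + n // 512`` frames.
    """
    if len(clip.samples) == 0:
        raise ValueError("cannot extract MFCCs from an empty waveform")
    if n_mfcc < 1:
        raise ValueError("n_mfcc must be >= 1")
    values = _signal.mfcc(clip.samples, clip.sample_rate, n_mfcc=n_mfcc,
                          n_mels=n_mels)
    return MFCCMatrix(values=values)


def normalize_length(m: MFCCMatrix,
                     target_frames: int = DEFAULT_TARGET_FRAMES) -> MFCCMatrix:
    """Zero-pad (right) or prefix-truncate to exactly ``target_frames`` columns."""
    if target_frames < 1:
        raise ValueError("target_frames must be >= 1")
    v = m.values
    if v.shape[1] >= target_frames:
        out = v[:, :target_frames]
    else:
        out = np.pad(v, ((0, 0), (0, target_frames - v.shape[1])))
    return MFCCMatrix(values=out)


@dataclass
class LabelCodec:
    """Bijective mapping between the 8 class names and indices 0..7."""

    classes: tuple[str, ...] = CLASSES
    _index: dict = field(init=False, repr=False)

    def __post_init__(self):
        self.classes = tuple(self.classes)
        if len(set(self.classes)) != len(self.classes):
            raise ValueError("duplicate class names")
        self._index = {c: i for i, c in enumerate(self.classes)}

    def encode(self, label: str) -> int:
        try:
            return self._index[label]
        except KeyError:
            raise KeyError(f"unknown label: {label!r}") from None

    def decode(self, index: int) -> str:
        return self.classes[index]

    def one_hot(self, labels) -> np.ndarray:
        idx = np.array([self.encode(lb) for lb in labels])
        out = np.zeros((len(idx), len(self.classes)))
        out[np.arange(len(idx)), idx] = 1.0
        return out


def encode_labels(labels) -> tuple[LabelCodec, np.ndarray]:
    """One-hot encode diagnosis labels over the full 8-class vocabulary.

    Class order is the lexicographic sort of the 8 names, so the index map
    is deterministic regardless of which labels are present.
    """
    codec = LabelCodec()
    return codec, codec.one_hot(labels)


def featurize_clip(clip: AudioClip, n_mfcc: int = DEFAULT_N_MFCC,
                   target_frames: int = DEFAULT_TARGET_FRAMES) -> MFCCMatrix:
    """Shape-contract pipeline: MFCC extraction then length normalization.

    No per-feature standardization happens here (the canonical pipeline
    only length-normalizes); the diagnoser offers an optional z-score
    switch whose statistics are fitted on its training split.
    """
    return normalize_length(extract_mfcc(clip, n_mfcc=n_mfcc), target_frames)


def save_features(m: MFCCMatrix, path: str | Path, *, classes=CLASSES,
                  source: str = "") -> None:
    """Write a feature matrix as .npy plus a JSON sidecar with its shape,
    class order and source path."""
    path = Path(path)
    np.save(path.with_suffix(".npy"), m.values)
    sidecar = {
        "shape": list(m.values.shape),
        "classes": list(classes),
        "source": source,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_features(path: str | Path) -> MFCCMatrix:
    return MFCCMatrix(values=np.load(Path(path).with_suffix(".npy")))


def read_diagnosis_table(path: str | Path) -> dict[str, str]:
    """Read a two-column (patient_id, diagnosis) text file.

    Matches the Respiratory Sound Database layout where per-clip WAV
    filenames start with the patient id (underscore-separated) and one
    text table maps patients to diagnoses.
    """
    table = {}
    for line in Path(path).read_text().splitlines():
        parts = line.replace(",", "\t").split()
        if len(parts) >= 2:
            table[parts[0]] = parts[1]
    return table


def subject_from_filename(path: str | Path) -> str:
    """Patient id = first underscore-separated token of the file name."""
    return Path(path).stem.split("_")[0]
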