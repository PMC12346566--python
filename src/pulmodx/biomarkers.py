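"""Simulated molecular-biomarker channel and penultimate-layer fusion.

Each of the eight diagnosis classes maps to a small set of
literature-associated markers (e.g. pneumonia -> CRP/PCT/IL-6; COPD and
pneumonia share IL-6). A synthetic 20-marker intensity vector is drawn
per sample: marker intensity = baseline + sum_d posterior_d * weight(d, m)
+ Gaussian noise, clipped to [0, 1]. The posterior driving the simulation
is, by default, the *audio model's predicted* posterior — using true
labels at inference would leak the answer into the molecular channel; a
``from_labels`` mode exists for controlled experiments.

Fusion appends the molecular vector to the diagnoser's penultimate-layer
latent and retrains a softmax head on the concatenation. For a fair
audio-vs-fused comparison, the audio-only baseline head is trained the
same way on the latent alone.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import yaml
from sklearn.linear_model import LogisticRegression

from pulmodx.features import CLASSES, LabelCodec


@dataclass(frozen=True)
class BiomarkerMap:
    markers: tuple[str, ...]
    weights: dict[str, dict[str, float]]  # disease -> marker -> weight
    baseline: float = 0.1

    def __post_init__(self):
        for disease, mp in self.weights.items():
            for marker, w in mp.items():
                if marker not in self.markers:
                    raise ValueError(f"unknown marker {marker!r} for {disease}")
                if not 0.0 < w <= 1.0:
                    raise ValueError(f"weight for {disease}/{marker} not in (0,1]")

    def weight_matrix(self, classes=CLASSES) -> np.ndarray:
        """(n_diseases, n_markers) association weights in codec class order."""
        W = np.zeros((len(classes), len(self.markers)))
        midx = {m: j for j, m in enumerate(self.markers)}
        for i, disease in enumerate(classes):
            for marker, w in self.weights.get(disease, {}).items():
                W[i, midx[marker]] = w
        return W


def build_marker_map(path=None) -> BiomarkerMap:
    """Load the disease->marker knowledge file (YAML, editable)."""
    if path is None:
        text = resources.files("pulmodx").joinpath("data/biomarkers.yaml").read_text()
    else:
        from pathlib import Path

        text = Path(path).read_text()
    raw = yaml.safe_load(text)
    return BiomarkerMap(markers=tuple(raw["markers"]),
                        weights={d: dict(m or {}) for d, m in raw["diseases"].items()},
                        baseline=float(raw.get("baseline", 0.1)))


def simulate_vector(posterior: np.ndarray, noise_sd: float = 0.05,
                    seed: int = 0, marker_map: BiomarkerMap | None = None,
                    ) -> np.ndarray:
    """Draw one molecular intensity vector from an 8-class posterior."""
    marker_map = marker_map or build_marker_map()
    posterior = np.asarray(posterior, dtype=np.float64)
    if posterior.shape != (len(CLASSES),) or not np.isclose(posterior.sum(), 1.0, atol=1e-6):
        raise ValueError("posterior must be an 8-vector summing to 1")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    W = marker_map.weight_matrix()
    mean = marker_map.baseline + posterior @ W
    rng = np.random.default_rng(seed)
    return np.clip(mean + rng.normal(0.0, noise_sd, size=mean.shape), 0.0, 1.0)


def simulate_vectors(posteriors: np.ndarray, noise_sd: float = 0.05,
                     seed: int = 0, marker_map: BiomarkerMap | None = None,
                     ) -> np.ndarray:
    """Vectorized :func:`simulate_vector` over a batch of posteriors."""
    marker_map = marker_map or build_marker_map()
    posteriors = np.asarray(posteriors, dtype=np.float64)
    W = marker_map.weight_matrix()
    mean = marker_map.baseline + posteriors @ W
    rng = np.random.default_rng(seed)
    return np.clip(mean + rng.normal(0.0, noise_sd, size=mean.shape), 0.0, 1.0)


def posteriors_from_labels(labels, codec: LabelCodec | None = None) -> np.ndarray:
    """One-hot 'posteriors' for the controlled from-labels simulation mode."""
    codec = codec or LabelCodec()
    return codec.one_hot(labels)


@dataclass
class FusionHead:
    """Softmax head over [audio latent | molecular vector]."""

    clf: LogisticRegression
    n_latent: int
    n_markers: int

    def predict_proba(self, latent: np.ndarray, mol: np.ndarray) -> np.ndarray:
        X = np.concatenate([latent, mol], axis=1)
        if X.shape[1] != self.n_latent + self.n_markers:
            raise ValueError("latent/molecular dimension mismatch with head")
        return self.clf.predict_proba(X)


def train_fusion_head(latent: np.ndarray, mol: np.ndarray, labels,
                      codec: LabelCodec | None = None, seed: int = 0,
                      ) -> FusionHead:
    codec = codec or LabelCodec()
    y = np.array([codec.encode(lb) for lb in labels])
    clf = LogisticRegression(max_iter=2000, random_state=seed)
    clf.fit(np.concatenate([latent, mol], axis=1), y)
    return FusionHead(clf=clf, n_latent=latent.shape[1], n_markers=mol.shape[1])


def train_audio_head(latent: np.ndarray, labels,
                     codec: LabelCodec | None = None, seed: int = 0,
                     ) -> LogisticRegression:
    """Audio-only comparator head, trained identically to the fusion head."""
    codec = codec or LabelCodec()
    y = np.array([codec.encode(lb) for lb in labels])
    clf = LogisticRegression(max_iter=2000, random_state=seed)
    clf.fit(latent, y)
    return clf


def fuse_and_classify(audio_latent: np.ndarray, mol: np.ndarray,
                      fusion_head: FusionHead) -> np.ndarray:
    """8-class posterior from the fused representation (rows sum to 1)."""
    return fusion_head.predict_proba(np.atleast_2d(audio_latent),
                                     np.atleast_2d(mol))
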