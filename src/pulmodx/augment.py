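"""Three-stage class-balancing audio augmentation with fidelity gating.

Stage 1 routes extreme-minority classes through a 25x up-sampling pass;
stage 2 validates every candidate against its source clip with a
spectrogram cross-correlation gate (r > 0.85), discarding low-fidelity
outputs; stage 3 is the leakage guard: augmented clips inherit their
source clip's subject id, so subject-level splits automatically keep
derivatives on the correct side (and an audit utility enforces it).

Classical transforms cover pitch shift (+/-2 semitones), time stretch
(0.8x-1.2x), volume scaling, and noise injection at 5-30 dB SNR. The
generative quota (40% of candidates) is filled by a seeded parametric
surrogate: a convex time-domain mixture of two same-class clips followed
by a random classical transform, subjected to the same r > 0.85 gate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import fftconvolve

from pulmodx import _signal
from pulmodx.errors import LeakageError
from pulmodx.features import AudioClip
from pulmodx.fixtures import FixtureSet

PITCH_RANGE = (-2.0, 2.0)       # semitones
STRETCH_RANGE = (0.8, 1.2)      # speed factor
GAIN_RANGE = (-6.0, 6.0)        # dB
SNR_RANGE = (5.0, 30.0)         # dB
CORRELATION_THRESHOLD = 0.85

CLASSICAL_KINDS = ("pitch_shift", "time_stretch", "gain", "noise_inject")


@dataclass(frozen=True)
class AugmentOp:
    kind: str
    pitch: float = 0.0
    stretch: float = 1.0
    gain: float = 0.0
    snr: float = 20.0

    def __post_init__(self):
        if self.kind not in CLASSICAL_KINDS + ("surrogate_synthesis",):
            raise ValueError(f"unknown op kind {self.kind!r}")
        if self.kind == "pitch_shift" and not (PITCH_RANGE[0] <= self.pitch <= PITCH_RANGE[1]):
            raise ValueError(f"pitch {self.pitch} outside {PITCH_RANGE} semitones")
        if self.kind == "time_stretch" and not (STRETCH_RANGE[0] <= self.stretch <= STRETCH_RANGE[1]):
            raise ValueError(f"stretch {self.stretch} outside {STRETCH_RANGE}")
        if self.kind == "noise_inject" and not (SNR_RANGE[0] <= self.snr <= SNR_RANGE[1]):
            raise ValueError(f"snr {self.snr} outside {SNR_RANGE} dB")


@dataclass
class AugmentPlan:
    """Balancing targets and mix proportions.

    ``per_class_target`` may be left None, in which case each run draws a
    target uniformly from [720, 760] per class (classes already above 760
    are left unchanged), reproducing the ">= 720 samples" regime.
    """

    per_class_target: dict[str, int] | None = None
    classical_fraction: float = 0.6
    extreme_minority_factor: int = 25
    threshold: float = CORRELATION_THRESHOLD
    target_range: tuple[int, int] = (720, 760)

    def __post_init__(self):
        if not 0.0 <= self.classical_fraction <= 1.0:
            raise ValueError("classical_fraction must be in [0, 1]")


@dataclass(frozen=True)
class ValidationReport:
    r: float
    threshold: float = CORRELATION_THRESHOLD

    @property
    def accepted(self) -> bool:
        return self.r > self.threshold


def inject_noise(clip: AudioClip, snr_db: float, seed: int,
                 color: str = "white") -> AudioClip:
    """Add noise at an exact signal-to-noise ratio (within 0.1 dB).

    ``color`` selects white Gaussian or pink (1/f) noise; device-specific
    noise profiles can be emulated by passing a pre-shaped clip instead.
    """
    p_signal = float(np.mean(clip.samples**2))
    if p_signal == 0.0:
        raise ValueError("SNR undefined for an all-zero clip")
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal(len(clip.samples))
    if color == "pink":
        spec = np.fft.rfft(noise)
        f = np.fft.rfftfreq(len(noise))
        spec /= np.sqrt(np.maximum(f, f[1]))
        noise = np.fft.irfft(spec, n=len(noise))
    elif color != "white":
        raise ValueError(f"unknown noise color {color!r}")
    p_noise_target = p_signal / (10.0 ** (snr_db / 10.0))
    noise *= np.sqrt(p_noise_target / np.mean(noise**2))
    out = clip.samples + noise
    return AudioClip(out, clip.sample_rate, clip.subject_id, clip.label,
                     augmented=True)


def apply_op(clip: AudioClip, op: AugmentOp, seed: int = 0) -> AudioClip:
    """Apply one classical transform; all outputs are finite.

    Pitch shift preserves duration; time stretch scales duration by
    1/factor; gain scales amplitude.
    """
    y = clip.samples
    if op.kind == "pitch_shift":
        out = _signal.pitch_shift_signal(y, clip.sample_rate, op.pitch)
    elif op.kind == "time_stretch":
        out = _signal.time_stretch_signal(y, op.stretch)
    elif op.kind == "gain":
        out = y * (10.0 ** (op.gain / 20.0))
    elif op.kind == "noise_inject":
        return inject_noise(clip, op.snr, seed)
    else:
        raise ValueError(f"apply_op cannot run op kind {op.kind!r}")
    return AudioClip(out, clip.sample_rate, clip.subject_id, clip.label,
                     augmented=True)


def _centered_logmel(clip: AudioClip, n_mels: int = 64) -> np.ndarray:
    S = _signal.log_mel_spectrogram(clip.samples, clip.sample_rate, n_mels=n_mels)
    return S - S.mean()


def spectrogram_correlation(source: AudioClip, augmented: AudioClip,
                            source_spec: np.ndarray | None = None) -> float:
    """Peak normalized cross-correlation of mean-centered log-mel
    spectrograms over all time lags (frequency axis kept aligned)."""
    A = _centered_logmel(source) if source_spec is None else source_spec
    B = _centered_logmel(augmented)
    num = fftconvolve(A, B[:, ::-1], mode="full", axes=1).sum(axis=0)
    den = np.sqrt((A**2).sum() * (B**2).sum())
    if den == 0.0:
        return 0.0
    return float(num.max() / den)


def validate_augmented(source: AudioClip, augmented: AudioClip,
                       threshold: float = CORRELATION_THRESHOLD,
                       source_spec: np.ndarray | None = None) -> ValidationReport:
    if len(source.samples) == 0 or len(augmented.samples) == 0:
        raise ValueError("validation requires non-empty clips")
    r = spectrogram_correlation(source, augmented, source_spec=source_spec)
    return ValidationReport(r=r, threshold=threshold)


def convex_mix(a: AudioClip, b: AudioClip, weight: float) -> AudioClip:
    """Time-domain convex mixture w*a + (1-w)*b (trimmed to common length)."""
    n = min(len(a.samples), len(b.samples))
    y = weight * a.samples[:n] + (1.0 - weight) * b.samples[:n]
    parent = a if weight >= 0.5 else b
    return AudioClip(y, a.sample_rate, parent.subject_id, parent.label,
                     augmented=True)


def random_classical_op(rng: np.random.Generator) -> AugmentOp:
    kind = CLASSICAL_KINDS[rng.integers(len(CLASSICAL_KINDS))]
    return AugmentOp(
        kind=kind,
        pitch=float(rng.uniform(*PITCH_RANGE)),
        stretch=float(rng.uniform(*STRETCH_RANGE)),
        gain=float(rng.uniform(*GAIN_RANGE)),
        snr=float(rng.uniform(*SNR_RANGE)),
    )


def surrogate_generate(class_clips: list[AudioClip], seed: int,
                       ) -> tuple[AudioClip, AudioClip]:
    """Parametric surrogate for generative synthesis.

    Returns (candidate, dominant_parent). With fewer than 2 source clips it
    falls back to a classical transform of the single clip.
    """
    rng = np.random.default_rng(seed)
    op = random_classical_op(rng)
    if len(class_clips) < 2:
        parent = class_clips[0]
        return apply_op(parent, op, seed=int(rng.integers(2**31 - 1))), parent
    i, j = rng.choice(len(class_clips), size=2, replace=False)
    w = float(rng.uniform(0.3, 0.7))
    mixed = convex_mix(class_clips[i], class_clips[j], w)
    parent = class_clips[i] if w >= 0.5 else class_clips[j]
    out = apply_op(mixed, op, seed=int(rng.integers(2**31 - 1)))
    return out, parent


@dataclass
class BalanceResult:
    fixture: FixtureSet
    reports: pd.DataFrame
    targets: dict[str, int] = field(default_factory=dict)

    @property
    def min_class_count(self) -> int:
        return min(self.fixture.per_class_counts.values())


def class_distribution_kl(counts: dict[str, int]) -> float:
    """KL divergence of the class distribution from uniform."""
    c = np.array([v for v in counts.values() if v > 0], dtype=float)
    p = c / c.sum()
    return float(np.sum(p * np.log(p * len(p))))


def balance_classes(fixture: FixtureSet, plan: AugmentPlan | None = None,
                    seed: int = 0, retry_budget: int = 25,
                    keep_waveforms: bool = True) -> BalanceResult:
    """Augment every class up to its balancing target.

    Only candidates passing the r > threshold gate are retained; rejected
    candidates are regenerated with fresh parameters up to
    ``retry_budget`` attempts per needed sample. Augmented clips inherit
    their source subject id. ``keep_waveforms=False`` drops accepted
    waveforms after validation (counting runs at full corpus scale).
    """
    plan = plan or AugmentPlan()
    rng = np.random.default_rng(seed)
    by_class: dict[str, list[AudioClip]] = {}
    for clip in fixture.clips:
        by_class.setdefault(clip.label, []).append(clip)

    targets: dict[str, int] = {}
    for label, clips in sorted(by_class.items()):
        if plan.per_class_target is not None:
            if label not in plan.per_class_target:
                raise KeyError(f"plan has no target for class {label!r}")
            targets[label] = max(plan.per_class_target[label], len(clips))
        else:
            lo, hi = plan.target_range
            drawn = int(rng.integers(lo, hi + 1))
            targets[label] = len(clips) if len(clips) > hi else drawn

    new_clips: list[AudioClip] = []
    report_rows: list[dict] = []
    for label in sorted(by_class):
        sources = by_class[label]
        target = targets[label]
        count = len(sources)
        if count >= target:
            continue
        # Stage 1: extreme minorities cannot reach the target with one pass
        # of the op mix; they are routed through the 25x up-sampling stage
        # first, then the mix keeps iterating until the target is met.
        stage1_quota = 0
        if count * plan.extreme_minority_factor < target:
            stage1_quota = count * (plan.extreme_minority_factor - 1)
        spec_cache = {id(c): _centered_logmel(c) for c in sources}
        needed = target - count
        attempts_left = retry_budget * needed
        produced = 0
        while produced < needed:
            if attempts_left <= 0:
                raise RuntimeError(
                    f"retry budget exhausted balancing class {label!r} "
                    f"({count + produced}/{target} samples)")
            attempts_left -= 1
            use_classical = (produced >= stage1_quota and
                             rng.random() < plan.classical_fraction)
            cand_seed = int(rng.integers(2**31 - 1))
            if use_classical or len(sources) == 0:
                src = sources[rng.integers(len(sources))]
                op = random_classical_op(rng)
                candidate = apply_op(src, op, seed=cand_seed)
                parent = src
                kind = op.kind
            else:
                candidate, parent = surrogate_generate(sources, cand_seed)
                kind = "surrogate_synthesis"
            rep = validate_augmented(parent, candidate, plan.threshold,
                                     source_spec=spec_cache.get(id(parent)))
            report_rows.append({"label": label, "kind": kind, "r": rep.r,
                                "accepted": rep.accepted})
            if rep.accepted:
                if not keep_waveforms:
                    candidate = AudioClip(np.zeros(1), candidate.sample_rate,
                                          candidate.subject_id, candidate.label,
                                          augmented=True)
                new_clips.append(candidate)
                produced += 1

    all_clips = list(fixture.clips) + new_clips
    counts: dict[str, int] = {}
    for c in all_clips:
        counts[c.label] = counts.get(c.label, 0) + 1
    out = FixtureSet(clips=all_clips, per_class_counts=counts)
    return BalanceResult(fixture=out, reports=pd.DataFrame(report_rows),
                         targets=targets)


def audit_subject_separation(train_clips, test_subjects) -> None:
    """Hard leakage guard: no training clip (augmented or not) may carry a
    held-out subject's id."""
    test_subjects = set(test_subjects)
    for clip in train_clips:
        if clip.subject_id in test_subjects:
            raise LeakageError(
                f"clip derived from held-out subject {clip.subject_id!r} "
                "found in the training set")
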