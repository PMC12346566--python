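"""Class-conditional synthetic respiratory audio.

Real auscultation recordings carry two adventitious signatures the
diagnoser exploits: wheezes (sustained narrowband tones, horizontal
spectrogram ridges) and crackles (transient broadband clicks, vertical
spikes). The generator emulates exactly that statistical structure on top
of breath-modulated noise, with a fixed class->recipe table whose
parameterizations overlap (COPD and pneumonia share crackles, several
classes share wheeze energy) but remain separable, mimicking the clinical
confusion structure while staying learnable at desk scale.

No physiological realism is attempted beyond those spectrotemporal cues.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from pulmodx.features import CLASSES, DEFAULT_SAMPLE_RATE, AudioClip, save_audio

#: Per-class clip counts of the reference auscultation corpus.
DEFAULT_CLASS_COUNTS = {
    "COPD": 793,
    "pneumonia": 37,
    "healthy": 35,
    "URTI": 23,
    "bronchiectasis": 16,
    "bronchiolitis": 13,
    "LRTI": 2,
    "asthma": 1,
}


@dataclass(frozen=True)
class SoundRecipe:
    """Parameters of one class-conditional clip generator."""

    label: str
    wheeze_band: tuple[float, float] | None = None  # Hz
    wheeze_fraction: float = 0.0        # fraction of each breath cycle
    wheeze_amp: float = 0.6             # tone amplitude (pre-normalization)
    #: cycle window the wheeze occupies; None = [0, wheeze_fraction)
    wheeze_phase: tuple[float, float] | None = None
    crackle_rate: float = 0.0           # events / s
    crackle_width: float = 8.0          # ms
    crackle_freq: tuple[float, float] = (600.0, 1800.0)  # Hz band of clicks
    #: cycle window crackles cluster in; None = uniform over the clip
    crackle_phase: tuple[float, float] | None = None
    breath_noise_level: float = 0.3     # relative amplitude
    duration: float = 10.0              # s

    def __post_init__(self):
        if self.wheeze_band is not None:
            lo, hi = self.wheeze_band
            if not (50.0 < lo < hi < 2000.0):
                raise ValueError("wheeze_band must lie within (50, 2000) Hz")
        if self.wheeze_fraction < 0 or self.crackle_rate < 0:
            raise ValueError("rates and fractions must be >= 0")
        if self.duration <= 0:
            raise ValueError("duration must be positive")


#: Fixed class->recipe table. Bands and rates are distinct per class but
#: deliberately adjacent (COPD vs asthma wheeze bands, pneumonia vs LRTI
#: crackle rates) so classes overlap without collapsing. One pair,
#: bronchiectasis vs bronchiolitis, carries *identical* wheeze and
#: crackle content and differs only in where the events sit within the
#: breath cycle (early-phase wheeze with late crackles, or the reverse):
#: the timing of adventitious events relative to the respiratory cycle is
#: a genuine auscultatory cue, and it is invisible to time-averaged
#: spectra, so purely spectral classifiers are at chance on the pair
#: while sequence models are not.
DEFAULT_RECIPES: dict[str, SoundRecipe] = {
    "healthy": SoundRecipe("healthy"),
    "asthma": SoundRecipe("asthma", wheeze_band=(350.0, 550.0),
                          wheeze_fraction=0.55),
    "COPD": SoundRecipe("COPD", wheeze_band=(120.0, 260.0),
                        wheeze_fraction=0.45, crackle_rate=2.0,
                        crackle_width=12.0, crackle_freq=(400.0, 900.0)),
    "URTI": SoundRecipe("URTI", wheeze_band=(1300.0, 1700.0),
                        wheeze_fraction=0.35),
    "bronchiolitis": SoundRecipe("bronchiolitis", wheeze_band=(650.0, 850.0),
                                 wheeze_fraction=0.25,
                                 wheeze_phase=(0.6, 0.85),
                                 crackle_rate=6.0, crackle_width=12.0,
                                 crackle_freq=(500.0, 1200.0),
                                 crackle_phase=(0.15, 0.4)),
    "bronchiectasis": SoundRecipe("bronchiectasis", wheeze_band=(650.0, 850.0),
                                  wheeze_fraction=0.25,
                                  wheeze_phase=(0.15, 0.4),
                                  crackle_rate=6.0, crackle_width=12.0,
                                  crackle_freq=(500.0, 1200.0),
                                  crackle_phase=(0.6, 0.85)),
    "pneumonia": SoundRecipe("pneumonia", crackle_rate=10.0, crackle_width=7.0,
                             crackle_freq=(1500.0, 3000.0)),
    "LRTI": SoundRecipe("LRTI", crackle_rate=16.0, crackle_width=15.0,
                        crackle_freq=(500.0, 1100.0)),
}

BREATH_CYCLE_S = 3.0  # one inspiration+expiration (20 breaths/min)


@dataclass
class FixtureSet:
    """A bundle of synthetic clips with per-class counts and a subject map."""

    clips: list[AudioClip]
    per_class_counts: dict[str, int] = field(default_factory=dict)
    subjects: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if not self.per_class_counts:
            counts: dict[str, int] = {}
            for c in self.clips:
                counts[c.label] = counts.get(c.label, 0) + 1
            self.per_class_counts = counts
        for c in self.clips:
            if not c.subject_id:
                raise ValueError("every fixture clip needs a subject_id")
            prev = self.subjects.get(c.subject_id)
            if prev is not None and prev != c.label:
                raise ValueError(
                    f"subject {c.subject_id} mapped to two classes")
            self.subjects[c.subject_id] = c.label

    def to_manifest(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"subject_id": [c.subject_id for c in self.clips],
             "label": [c.label for c in self.clips]})

    def write(self, out_dir) -> pd.DataFrame:
        """Write WAV files plus a manifest CSV (path, subject_id, label)."""
        from pathlib import Path

        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        rows = []
        for i, clip in enumerate(self.clips):
            name = f"{clip.subject_id}_{i:05d}.wav"
            save_audio(clip, out_dir / name)
            rows.append({"path": name, "subject_id": clip.subject_id,
                         "label": clip.label})
        manifest = pd.DataFrame(rows)
        manifest.to_csv(out_dir / "manifest.csv", index=False)
        return manifest


def _crackle_burst(sr: int, width_ms: float, freq: float) -> np.ndarray:
    """A damped sinusoid transient ~= one crackle click."""
    n = max(int(sr * width_ms / 1000.0), 8)
    t = np.arange(n) / sr
    env = np.exp(-t / (width_ms / 3000.0))
    return env * np.sin(2.0 * np.pi * freq * t)


def synth_clip(recipe: SoundRecipe, seed: int,
               sample_rate: int = DEFAULT_SAMPLE_RATE,
               subject_id: str = "synthetic") -> AudioClip:
    """Deterministically synthesize one clip from a recipe and a seed."""
    rng = np.random.default_rng(seed)
    n = int(round(recipe.duration * sample_rate))
    t = np.arange(n) / sample_rate

    phase0 = rng.uniform(0.0, 1.0)
    cycle_pos = (t / BREATH_CYCLE_S + phase0) % 1.0
    breath_env = 0.4 + 0.6 * np.sin(np.pi * cycle_pos) ** 2

    y = recipe.breath_noise_level * breath_env * rng.standard_normal(n)

    if recipe.wheeze_band is not None and recipe.wheeze_fraction > 0:
        f0 = rng.uniform(*recipe.wheeze_band)
        # phase-modulated ~1% vibrato at 3 Hz
        vib_phase = (0.01 * f0 / 3.0) * np.sin(
            2.0 * np.pi * 3.0 * t + rng.uniform(0, 2 * np.pi))
        tone = np.sin(2.0 * np.pi * (f0 * t + vib_phase))
        lo, hi = recipe.wheeze_phase or (0.0, recipe.wheeze_fraction)
        gate = ((cycle_pos >= lo) & (cycle_pos < hi)).astype(float)
        # 20 ms ramps to avoid clicks at gate edges
        ramp = max(int(0.02 * sample_rate), 1)
        kernel = np.ones(ramp) / ramp
        gate = np.convolve(gate, kernel, mode="same")
        y += recipe.wheeze_amp * gate * breath_env * tone

    if recipe.crackle_rate > 0:
        n_events = max(int(round(recipe.crackle_rate * recipe.duration)), 1)
        if recipe.crackle_phase is None:
            starts = rng.uniform(0.0, recipe.duration, size=n_events)
        else:
            # cluster events inside the given breath-cycle window
            lo, hi = recipe.crackle_phase
            pos = rng.uniform(lo, hi, size=n_events)
            cycle = rng.integers(0, max(int(recipe.duration / BREATH_CYCLE_S), 1),
                                 size=n_events)
            # wrap around the clip so no edge pile-up leaks event timing
            # into amplitude statistics
            starts = ((cycle + pos - phase0) * BREATH_CYCLE_S) % (
                recipe.duration - 1e-3)
        for s in np.sort(starts):
            fc = rng.uniform(*recipe.crackle_freq)
            burst = _crackle_burst(sample_rate, recipe.crackle_width, fc)
            i0 = int(s * sample_rate)
            i1 = min(i0 + len(burst), n)
            y[i0:i1] += 1.2 * burst[: i1 - i0]

    peak = np.max(np.abs(y))
    if peak > 0:
        y = 0.9 * y / peak
    return AudioClip(samples=y, sample_rate=sample_rate,
                     subject_id=subject_id, label=recipe.label)


def synth_cohort(per_class_counts: dict[str, int] | None = None,
                 subjects_per_class: int = 5, seed: int = 0,
                 duration: float | None = None,
                 sample_rate: int = DEFAULT_SAMPLE_RATE,
                 recipes: dict[str, SoundRecipe] | None = None) -> FixtureSet:
    """Synthesize a cohort with exact per-class counts.

    Clips are assigned round-robin to ``min(count, subjects_per_class)``
    subjects per class; a subject never spans two classes.
    """
    counts = dict(DEFAULT_CLASS_COUNTS if per_class_counts is None
                  else per_class_counts)
    recipes = dict(DEFAULT_RECIPES if recipes is None else recipes)
    rng = np.random.default_rng(seed)
    clips: list[AudioClip] = []
    for label in sorted(counts):
        count = counts[label]
        if count <= 0:
            continue
        if label not in recipes:
            raise KeyError(f"no sound recipe for class {label!r}")
        if subjects_per_class < 1:
            raise ValueError("subjects_per_class must be >= 1")
        recipe = recipes[label]
        if duration is not None:
            recipe = replace(recipe, duration=duration)
        n_subj = min(count, subjects_per_class)
        for i in range(count):
            subject = f"{label}_s{i % n_subj}"
            clip_seed = int(rng.integers(0, 2**31 - 1))
            clips.append(synth_clip(recipe, clip_seed, sample_rate=sample_rate,
                                    subject_id=subject))
    return FixtureSet(clips=clips, per_class_counts={k: v for k, v in counts.items() if v > 0})


def band_energy_features(clip: AudioClip,
                         edges=(0, 150, 300, 500, 700, 950, 1200, 1500, 2000, 4000),
                         ) -> np.ndarray:
    """Cheap log band-energy descriptor used by baseline sanity checks."""
    spec = np.abs(np.fft.rfft(clip.samples)) ** 2
    freqs = np.fft.rfftfreq(len(clip.samples), 1.0 / clip.sample_rate)
    out = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        band = spec[(freqs >= lo) & (freqs < hi)]
        out.append(np.log10(band.sum() + 1e-12))
    return np.array(out)


def balanced_counts(n_per_class: int, classes=CLASSES) -> dict[str, int]:
    return {c: n_per_class for c in classes}
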