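"""Augmentation pipeline: SNR arithmetic, transform semantics, the
fidelity gate, class balancing and the leakage guard."""

import numpy as np
import pytest

from pulmodx import augment as A
from pulmodx import fixtures as X
from pulmodx.errors import LeakageError
from pulmodx.features import AudioClip

SR = 22_050


def tone_clip(freq=440.0, seconds=2.0, subject="s0", label="asthma"):
    t = np.arange(int(seconds * SR)) / SR
    return AudioClip(np.sin(2 * np.pi * freq * t), SR, subject, label)


class TestInjectNoise:
    def test_zero_db_equal_powers(self):
        clip = tone_clip()
        out = A.inject_noise(clip, 0.0, seed=1)
        p_noise = np.mean((out.samples - clip.samples) ** 2)
        assert 10 * np.log10(np.mean(clip.samples**2) / p_noise) == pytest.approx(0.0, abs=0.1)

    def test_ten_db_noise_power(self):
        # oracle: unit-power signal at 10 dB -> noise power 0.1
        clip = tone_clip()
        p_signal = np.mean(clip.samples**2)
        out = A.inject_noise(clip, 10.0, seed=2)
        p_noise = np.mean((out.samples - clip.samples) ** 2)
        assert p_noise == pytest.approx(0.1 * p_signal, rel=1e-3)

    def test_high_snr_limit_preserves_input(self):
        clip = tone_clip()
        out = A.inject_noise(clip, 80.0, seed=3)
        assert np.max(np.abs(out.samples - clip.samples)) < 1e-3

    def test_all_zero_clip_errors(self):
        with pytest.raises(ValueError):
            A.inject_noise(AudioClip(np.zeros(100), SR), 10.0, seed=0)

    def test_pink_noise_spectrum_tilts_low(self):
        clip = tone_clip()
        out = A.inject_noise(clip, 0.0, seed=4, color="pink")
        noise = out.samples - clip.samples
        spec = np.abs(np.fft.rfft(noise)) ** 2
        half = len(spec) // 2
        assert spec[1:half].sum() > spec[half:].sum()


class TestApplyOp:
    def test_zero_gain_is_identity(self):
        clip = tone_clip()
        out = A.apply_op(clip, A.AugmentOp("gain", gain=0.0))
        assert np.allclose(out.samples, clip.samples)

    def test_gain_scales_amplitude(self):
        clip = tone_clip()
        out = A.apply_op(clip, A.AugmentOp("gain", gain=6.0))
        assert np.allclose(out.samples, clip.samples * 10 ** (6 / 20))

    def test_time_stretch_duration(self):
        clip = tone_clip(seconds=2.0)
        out = A.apply_op(clip, A.AugmentOp("time_stretch", stretch=0.8))
        # oracle: duration / 0.8
        assert len(out.samples) == int(round(len(clip.samples) / 0.8))

    def test_pitch_shift_two_semitones(self):
        clip = tone_clip(440.0, seconds=2.0)
        out = A.apply_op(clip, A.AugmentOp("pitch_shift", pitch=2.0))
        assert len(out.samples) == len(clip.samples)
        freqs = np.fft.rfftfreq(len(out.samples), 1 / SR)
        peak = freqs[np.argmax(np.abs(np.fft.rfft(out.samples)))]
        # oracle: 440 * 2^(2/12) = 493.88 Hz
        assert peak == pytest.approx(440 * 2 ** (2 / 12), rel=0.01)

    @pytest.mark.parametrize("kwargs", [
        {"kind": "pitch_shift", "pitch": 3.0},
        {"kind": "time_stretch", "stretch": 0.5},
        {"kind": "noise_inject", "snr": 2.0},
        {"kind": "warp"},
    ])
    def test_out_of_range_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            A.AugmentOp(**kwargs)


class TestValidation:
    def test_self_correlation_is_one(self):
        clip = X.synth_clip(X.DEFAULT_RECIPES["COPD"], seed=0,
                            subject_id="s", sample_rate=SR)
        rep = A.validate_augmented(clip, clip)
        assert rep.r == pytest.approx(1.0, abs=1e-9)
        assert rep.accepted

    def test_tone_vs_noise_rejected(self):
        tone = tone_clip(seconds=3.0)
        noise = AudioClip(np.random.default_rng(0).standard_normal(3 * SR),
                          SR, "s", "healthy")
        rep = A.validate_augmented(tone, noise)
        assert abs(rep.r) < 0.3
        assert not rep.accepted

    def test_acceptance_iff_above_threshold(self):
        assert not A.ValidationReport(r=0.85).accepted
        assert A.ValidationReport(r=0.851).accepted

    def test_empty_clip_errors(self):
        with pytest.raises(ValueError):
            A.validate_augmented(AudioClip(np.zeros(0), SR), tone_clip())


class TestSurrogate:
    def test_convexity_endpoint(self):
        a, b = tone_clip(300.0), tone_clip(700.0)
        assert np.allclose(A.convex_mix(a, b, 1.0).samples, a.samples)

    def test_self_mix_idempotent(self):
        a = tone_clip(300.0)
        assert np.allclose(A.convex_mix(a, a, 0.5).samples, a.samples)

    def test_rms_triangle_bound(self):
        a = X.synth_clip(X.DEFAULT_RECIPES["pneumonia"], seed=1, sample_rate=SR)
        b = X.synth_clip(X.DEFAULT_RECIPES["pneumonia"], seed=2, sample_rate=SR)
        mix = A.convex_mix(a, b, 0.4)
        rms = lambda y: np.sqrt(np.mean(y**2))  # noqa: E731
        assert rms(mix.samples) <= max(rms(a.samples), rms(b.samples)) + 1e-9

    def test_single_clip_falls_back_to_classical(self):
        clip = X.synth_clip(X.DEFAULT_RECIPES["asthma"], seed=0,
                            subject_id="a_s0", sample_rate=SR)
        out, parent = A.surrogate_generate([clip], seed=0)
        assert parent is clip
        assert out.subject_id == "a_s0"


@pytest.fixture(scope="module")
def small_balance():
    fset = X.synth_cohort({"asthma": 1, "LRTI": 2, "pneumonia": 8,
                           "COPD": 30},
                          subjects_per_class=2, seed=0, duration=3.0)
    plan = A.AugmentPlan(per_class_target={"asthma": 26, "LRTI": 26,
                                           "pneumonia": 26, "COPD": 26})
    return fset, A.balance_classes(fset, plan, seed=0)


class TestBalanceClasses:

    def test_targets_met_and_untouched_branch(self, small_balance):
        fset, res = small_balance
        assert res.fixture.per_class_counts["asthma"] >= 26
        assert res.fixture.per_class_counts["LRTI"] >= 26
        # class already above target is untouched
        assert res.fixture.per_class_counts["COPD"] == 30
        assert not any(c.label == "COPD" and c.augmented
                       for c in res.fixture.clips)

    def test_extreme_minorities_compound_past_25x(self, small_balance):
        # 1 asthma clip x 25 = 25 < 26: the stages must compound until
        # the target is met, not stop at the 25x product
        _, res = small_balance
        assert res.fixture.per_class_counts["asthma"] >= 26

    def test_only_accepted_candidates_retained(self, small_balance):
        _, res = small_balance
        n_aug = sum(c.augmented for c in res.fixture.clips)
        assert (res.reports["accepted"]).sum() == n_aug
        assert np.all(res.reports.loc[res.reports.accepted, "r"] > 0.85)

    def test_augmented_clips_inherit_source_subject(self, small_balance):
        fset, res = small_balance
        original_subjects = set(fset.subjects)
        for clip in res.fixture.clips:
            assert clip.subject_id in original_subjects

    def test_kl_divergence_strictly_decreases(self, small_balance):
        fset, res = small_balance
        before = A.class_distribution_kl(fset.per_class_counts)
        after = A.class_distribution_kl(res.fixture.per_class_counts)
        assert after < before

    def test_retry_budget_exhaustion_names_class(self):
        fset = X.synth_cohort({"asthma": 2}, subjects_per_class=1, seed=0,
                              duration=2.0)
        plan = A.AugmentPlan(per_class_target={"asthma": 6}, threshold=1.5)
        with pytest.raises(RuntimeError, match="asthma"):
            A.balance_classes(fset, plan, seed=0, retry_budget=3)

    def test_missing_plan_target_errors(self):
        fset = X.synth_cohort({"asthma": 2}, subjects_per_class=1, seed=0,
                              duration=1.0)
        with pytest.raises(KeyError, match="asthma"):
            A.balance_classes(fset, A.AugmentPlan(per_class_target={"COPD": 5}),
                              seed=0)


class TestLeakageGuard:
    def test_clean_split_passes(self):
        clips = [tone_clip(subject="train_1"), tone_clip(subject="train_2")]
        A.audit_subject_separation(clips, {"held_out"})

    def test_augmented_derivative_of_test_subject_aborts(self):
        leaked = A.apply_op(tone_clip(subject="patient9"),
                            A.AugmentOp("gain", gain=3.0))
        with pytest.raises(LeakageError, match="patient9"):
            A.audit_subject_separation([tone_clip(subject="ok"), leaked],
                                       {"patient9"})


def test_default_plan_draws_targets_in_published_band():
    fset = X.synth_cohort({"asthma": 1, "LRTI": 2}, subjects_per_class=1,
                          seed=0, duration=1.0)
    plan = A.AugmentPlan()
    rng_targets = []
    res = A.balance_classes(fset, plan, seed=0, retry_budget=50)
    for label, target in res.targets.items():
        rng_targets.append(target)
        assert 720 <= target <= 760
    assert res.min_class_count >= 720
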