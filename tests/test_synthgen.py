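"""Synthetic experiment generator: determinism and ground truth."""

import numpy as np
import pytest
from scipy import stats

from gammasift.io_edf import epoch, epoch_basal
from gammasift.spectral import band_power, psd_multitaper
from gammasift.synthgen import (
    SyntheticSubjectSpec,
    draw_cohort_specs,
    make_cohort,
    make_subject,
)

FAST = dict(n_trials_per_hand=4, basal_minutes=0.2)


def band_integrated(x, fs, band=(30.0, 60.0)):
    psd = psd_multitaper(x, fs)
    df = psd.freqs[1] - psd.freqs[0]
    mask = (psd.freqs >= band[0]) & (psd.freqs <= band[1])
    return float(np.sum(psd.power[mask]) * df)


class TestMakeSubject:
    def test_same_seed_is_bit_identical(self):
        a = make_subject(SyntheticSubjectSpec(seed=42, **FAST))
        b = make_subject(SyntheticSubjectSpec(seed=42, **FAST))
        np.testing.assert_array_equal(a.basal.samples, b.basal.samples)
        np.testing.assert_array_equal(a.motor.samples, b.motor.samples)
        assert a.onsets == b.onsets

    def test_gamma_power_ratio_matches_ground_truth(self):
        # oracle: band-integrated periodogram of the noise-free gamma component
        spec = SyntheticSubjectSpec(
            background_sigma_uV=0.0,
            rhythm_components=(),
            ers_true_percent=80.0,
            seed=1,
            **FAST,
        )
        sub = make_subject(spec)
        basal = epoch_basal(sub.basal, spec.trial_s)
        motor = epoch(sub.motor, sub.onsets["right"], spec.trial_s, "motor", "right")
        pb = np.mean([band_integrated(tr, spec.fs) for tr in basal.trials])
        pm = np.mean([band_integrated(tr, spec.fs) for tr in motor.trials])
        assert pm / pb == pytest.approx(1.8, rel=0.01)

    def test_noise_free_pipeline_recovery(self):
        from gammasift.cli import RunConfig, analyze_subject

        spec = SyntheticSubjectSpec(
            background_sigma_uV=0.0, ers_true_percent=100.0, seed=2, **FAST
        )
        sub = make_subject(spec)
        cfg = RunConfig(methods=("original",), synth={})
        results, _ = analyze_subject(sub.basal, sub.motor, sub.onsets, cfg)
        for r in results:
            assert r.ers_percent == pytest.approx(100.0, abs=5.0)

    def test_background_band_power_stationary_across_conditions(self):
        # with no gamma injected, basal and motor in-band power differ
        # only by sampling error
        pb, pm = [], []
        for seed in range(10):
            spec = SyntheticSubjectSpec(gamma_basal_amp_uV=0.0, seed=seed, **FAST)
            sub = make_subject(spec)
            basal = epoch_basal(sub.basal, spec.trial_s)
            motor = epoch(sub.motor, sub.onsets["right"], spec.trial_s, "motor", "right")
            pb.append(np.mean([band_integrated(tr, spec.fs) for tr in basal.trials]))
            pm.append(np.mean([band_integrated(tr, spec.fs) for tr in motor.trials]))
        assert stats.ttest_rel(pb, pm).pvalue > 0.05

    def test_artifact_trials_receive_spikes(self):
        spec = SyntheticSubjectSpec(artifact_rate=1.0, seed=3, **FAST)
        sub = make_subject(spec)
        assert np.max(np.abs(sub.motor.samples)) > 400.0

    def test_sampling_condition_enforced(self):
        with pytest.raises(ValueError):
            SyntheticSubjectSpec(fs=128.0, gamma_freq_hz=45.0)

    def test_extreme_negative_ers_rejected(self):
        with pytest.raises(ValueError):
            SyntheticSubjectSpec(ers_true_percent=-100.0)


class TestCohort:
    def test_zero_sd_shares_ers(self):
        specs = draw_cohort_specs(5, SyntheticSubjectSpec(**FAST), between_subject_sd=0.0, seed=0)
        assert all(s.ers_true_percent == specs[0].ers_true_percent for s in specs)

    def test_same_master_seed_identical_cohort(self):
        a = make_cohort(3, SyntheticSubjectSpec(**FAST), 10.0, seed=5)
        b = make_cohort(3, SyntheticSubjectSpec(**FAST), 10.0, seed=5)
        for sa, sb in zip(a, b):
            np.testing.assert_array_equal(sa.motor.samples, sb.motor.samples)

    def test_drawn_means_concentrate_on_template(self):
        # law of large numbers over several master seeds
        template = SyntheticSubjectSpec(ers_true_percent=30.0, **FAST)
        means = [
            np.mean([s.ers_true_percent for s in draw_cohort_specs(25, template, 20.0, seed)])
            for seed in range(8)
        ]
        sem = 20.0 / np.sqrt(25)
        assert abs(np.mean(means) - 30.0) < 2 * sem / np.sqrt(8) * 3

    def test_subject_seeds_differ(self):
        specs = draw_cohort_specs(6, SyntheticSubjectSpec(**FAST), 5.0, seed=9)
        assert len({s.seed for s in specs}) == 6

    def test_single_subject_cohort_rejected(self):
        with pytest.raises(ValueError):
            draw_cohort_specs(1, SyntheticSubjectSpec(**FAST))
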