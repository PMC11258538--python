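"""Generator contracts: ITI sampling, lick trains, corruption, photometry."""

import numpy as np
import pytest
from scipy import integrate, stats

import lickcraft as lc
from lickcraft.synthetic import (
    CountDistribution,
    PhotoSimConfig,
    PoseSimConfig,
    truncated_exponential_cdf,
    truncated_exponential_mean,
)


class TestSampleIti:
    def test_draws_stay_inside_bounds(self, rng):
        cfg = lc.TaskConfig()
        draws = lc.sample_iti(cfg, rng, size=10_000)
        assert draws.min() >= cfg.iti_min
        assert draws.max() <= cfg.iti_max

    def test_degenerate_interval_returns_bound(self, rng):
        cfg = lc.TaskConfig(iti_mean=18.0, iti_min=5.0, iti_max=5.0)
        draws = lc.sample_iti(cfg, rng, size=100)
        np.testing.assert_allclose(draws, 5.0, atol=0.0)
        assert lc.sample_iti(cfg, rng) == 5.0

    def test_closed_form_mean_matches_numerical_integration(self):
        cfg = lc.TaskConfig()
        lam = 1.0 / cfg.iti_mean
        norm, _ = integrate.quad(
            lambda x: lam * np.exp(-lam * x), cfg.iti_min, cfg.iti_max
        )
        num, _ = integrate.quad(
            lambda x: x * lam * np.exp(-lam * x), cfg.iti_min, cfg.iti_max
        )
        assert truncated_exponential_mean(cfg) == pytest.approx(num / norm, abs=1e-9)
        # value derived from the closed form at the default task parameters
        assert truncated_exponential_mean(cfg) == pytest.approx(12.5083, abs=1e-3)

    def test_empirical_mean_matches_closed_form(self, rng):
        cfg = lc.TaskConfig()
        draws = lc.sample_iti(cfg, rng, size=100_000)
        assert draws.mean() == pytest.approx(truncated_exponential_mean(cfg), abs=0.07)

    def test_invalid_bounds_rejected(self):
        with pytest.raises(ValueError):
            lc.TaskConfig(iti_min=5.0, iti_max=2.0)


class TestGenerateLickTrain:
    def test_zero_duration_yields_empty_session(self, rng):
        s = lc.generate_lick_train(lc.LickTrainParams(), 0.0, rng)
        assert s.n_licks == 0
        assert s.bouts == ()

    def test_within_bout_ili_mean_near_target(self, rng):
        s = lc.generate_lick_train(lc.LickTrainParams(), 1800.0, rng)
        ilis = s.within_bout_ilis()
        assert ilis.size > 200
        assert ilis.mean() == pytest.approx(0.146, abs=0.005)

    def test_fixed_bout_size_ili_counting(self, rng):
        params = lc.LickTrainParams(licks_per_bout=CountDistribution("fixed", {"n": 10}))
        s = lc.generate_lick_train(params, 600.0, rng)
        # every complete bout of 10 licks contributes 9 within-bout intervals
        assert s.within_bout_ilis().size == s.n_licks - len(s.bouts)
        complete = [b for b in s.bouts if b[1] - b[0] + 1 == 10]
        assert len(complete) >= 5

    def test_timestamps_ordered_finite_in_range(self, rng):
        s = lc.generate_lick_train(lc.LickTrainParams(), 300.0, rng)
        onsets = s.lick_onsets()
        assert np.all(np.isfinite(onsets))
        assert onsets.min() >= 0
        assert max(l.offset for l in s.licks) <= s.duration
        assert np.all(np.diff(onsets) > 0)

    def test_inter_bout_gaps_exceed_break_threshold(self, rng):
        s = lc.generate_lick_train(lc.LickTrainParams(), 600.0, rng, bout_break=0.5)
        for (f1, l1), (f2, _) in zip(s.bouts, s.bouts[1:]):
            assert s.licks[f2].onset - s.licks[l1].onset >= 0.5

    def test_determinism_bit_for_bit(self):
        a = lc.generate_lick_train(lc.LickTrainParams(), 300.0, np.random.default_rng(7))
        b = lc.generate_lick_train(lc.LickTrainParams(), 300.0, np.random.default_rng(7))
        assert a == b


class TestSimulateTaskSession:
    def test_no_licks_means_no_rewards(self, rng):
        s = lc.simulate_task_session(
            lc.TaskConfig(session_duration=1e-6), lc.LickTrainParams(), rng
        )
        assert s.n_licks == 0
        assert s.reward_times == ()

    def test_rewards_coincide_with_bout_first_licks(self, short_session):
        firsts = set(short_session.bout_first_lick_times())
        assert len(short_session.reward_times) > 0
        for rt in short_session.reward_times:
            assert rt in firsts

    @pytest.mark.parametrize("seed", range(0, 100, 1))
    def test_rewards_separated_by_at_least_iti_min(self, seed):
        s = lc.simulate_task_session(
            lc.TaskConfig(session_duration=120.0),
            lc.LickTrainParams(),
            np.random.default_rng(seed),
        )
        if len(s.reward_times) >= 2:
            assert np.diff(np.asarray(s.reward_times)).min() >= 2.0


class TestCorruptEvents:
    def test_zero_rates_bijective_with_truth(self, short_session, rng):
        model = lc.ErrorModel(p_fn_short=0.0, p_fn_sipper=0.0, p_double=0.0, p_snout=0.0)
        res = lc.corrupt_events(short_session, model, rng)
        assert len(res.stream) == short_session.n_licks
        assert all(lbl == "true" for lbl in res.labels)
        np.testing.assert_allclose(
            res.stream.onsets(), short_session.lick_onsets(), atol=1e-12
        )

    def test_fn_fractions_converge_per_kind(self):
        model = lc.ErrorModel()
        n_short = n_sipper = fn_short = fn_sipper = 0
        seed = 0
        while n_short < 2000 or n_sipper < 2000:
            rng = np.random.default_rng(seed)
            s = lc.generate_lick_train(lc.LickTrainParams(), 1800.0, rng)
            res = lc.corrupt_events(s, model, rng)
            for lk, drop in zip(s.licks, res.dropped):
                if lk.kind == "short":
                    n_short += 1
                    fn_short += drop
                else:
                    n_sipper += 1
                    fn_sipper += drop
            seed += 1
        for count, n, p in (
            (fn_short, n_short, model.p_fn_short),
            (fn_sipper, n_sipper, model.p_fn_sipper),
        ):
            assert stats.binomtest(count, n, p).pvalue > 0.01

    def test_double_injection_rate_and_gap(self, rng):
        model = lc.ErrorModel(p_fn_short=0.0, p_fn_sipper=0.0, p_double=0.1, p_snout=0.0)
        total_true = 0
        doubles = []
        for seed in range(5):
            r = np.random.default_rng(seed)
            s = lc.generate_lick_train(lc.LickTrainParams(), 600.0, r)
            res = lc.corrupt_events(s, model, r)
            total_true += s.n_licks
            onsets = res.stream.onsets()
            for i, lbl in enumerate(res.labels):
                if lbl == "double_fp":
                    doubles.append(onsets[i] - onsets[i - 1])
        assert total_true >= 1000
        assert all(0 < g < 0.05 for g in doubles)
        assert stats.binomtest(len(doubles), total_true, 0.1).pvalue > 0.01

    def test_snout_artifacts_avoid_lick_neighborhood(self, short_session, rng):
        model = lc.ErrorModel(p_snout=0.1)
        res = lc.corrupt_events(short_session, model, rng)
        snouts = [
            res.stream.events[i] for i, lbl in enumerate(res.labels) if lbl == "snout_fp"
        ]
        assert snouts
        for ev in snouts:
            for lk in short_session.licks:
                assert ev.offset < lk.onset - 0.05 or ev.onset > lk.offset + 0.05

    def test_determinism(self, short_session):
        a = lc.corrupt_events(short_session, lc.ErrorModel(), np.random.default_rng(3))
        b = lc.corrupt_events(short_session, lc.ErrorModel(), np.random.default_rng(3))
        assert a.stream.events == b.stream.events
        assert a.labels == b.labels


class TestTruncatedItiDistribution:
    def test_ks_against_analytic_cdf(self, rng):
        cfg = lc.TaskConfig()
        draws = lc.sample_iti(cfg, rng, size=100_000)
        res = stats.kstest(draws, lambda x: truncated_exponential_cdf(x, cfg))
        assert res.pvalue > 0.01


class TestSimulatePhotometry:
    def test_silent_config_gives_constant_channels(self, short_session, rng):
        cfg = PhotoSimConfig(
            bleach_amp1=0.0, bleach_amp2=0.0, noise_sd=0.0, transient_amp=0.0, dip_amp=0.0
        )
        tr = lc.simulate_photometry(short_session, cfg, rng)
        np.testing.assert_allclose(tr.ch470, cfg.baseline, atol=1e-12)
        np.testing.assert_allclose(tr.ch415, cfg.iso_scale * cfg.baseline, atol=1e-12)

    def test_bleach_only_matches_two_exponential_curve(self, short_session, rng):
        cfg = PhotoSimConfig(noise_sd=0.0, transient_amp=0.0, dip_amp=0.0)
        tr = lc.simulate_photometry(short_session, cfg, rng)
        expected = (
            cfg.baseline
            + cfg.bleach_amp1 * np.exp(-tr.time / cfg.bleach_tau1)
            + cfg.bleach_amp2 * np.exp(-tr.time / cfg.bleach_tau2)
        )
        np.testing.assert_allclose(tr.ch470, expected, atol=1e-12)
        np.testing.assert_allclose(tr.ch415, cfg.iso_scale * expected, atol=1e-12)

    def test_isosbestic_carries_no_lick_locked_signal(self, short_session, rng):
        cfg = PhotoSimConfig(noise_sd=0.0)
        tr = lc.simulate_photometry(short_session, cfg, rng)
        # 415 channel is exactly scaled bleach: no kernel at reward times
        expected = (
            cfg.baseline
            + cfg.bleach_amp1 * np.exp(-tr.time / cfg.bleach_tau1)
            + cfg.bleach_amp2 * np.exp(-tr.time / cfg.bleach_tau2)
        )
        np.testing.assert_allclose(tr.ch415, cfg.iso_scale * expected, atol=1e-12)


class TestSynthesizePose:
    @pytest.mark.parametrize("seed", range(10))
    def test_segmentation_round_trip_count_and_kind(self, seed):
        rng = np.random.default_rng(seed)
        s = lc.simulate_task_session(
            lc.TaskConfig(session_duration=300.0), lc.LickTrainParams(), rng
        )
        pose = lc.synthesize_pose(s, PoseSimConfig(), rng)
        licks = lc.segment_video_licks(pose, lc.SegmentationConfig())
        assert len(licks) == s.n_licks
        assert [l.kind for l in licks] == [k.kind for k in s.licks]
        # bounds frame-accurate: every true onset inside its video lick
        for vl, lk in zip(licks, s.licks):
            assert abs(vl.start - lk.onset) <= 2.0 / 60.0
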