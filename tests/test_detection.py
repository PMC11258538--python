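"""Video-lick segmentation, event matching, metrics, Fisher test, filter."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import fisher_exact as scipy_fisher

import lickcraft as lc
from lickcraft.detection import ContingencyTable2x2, GroupedMetrics
from lickcraft.io import BodypartTrack
from _oracles import enumerate_fisher_p


def _track_from_y(y, likelihood=None, rate=60.0):
    y = np.asarray(y, dtype=float)
    n = y.size
    lik = np.full(n, 0.99) if likelihood is None else np.asarray(likelihood, dtype=float)
    bp = lambda yy: BodypartTrack(
        x=np.zeros(n), y=yy, likelihood=lik, missing=np.zeros(n, dtype=bool)
    )
    return lc.PoseTrack(
        frame_rate=rate,
        time=np.arange(n) / rate,
        bodyparts={"nose": bp(np.zeros(n)), "tongue_tip": bp(y)},
    )


class TestSegmentVideoLicks:
    def test_tongue_never_past_poke_line_yields_no_licks(self):
        track = _track_from_y(np.full(50, 2.0))
        assert lc.segment_video_licks(track, lc.SegmentationConfig()) == []

    def test_single_excursion_past_sipper_line_is_one_sipper_lick(self):
        y = np.zeros(30)
        y[10:14] = 15.0
        licks = lc.segment_video_licks(_track_from_y(y), lc.SegmentationConfig())
        assert len(licks) == 1
        assert licks[0].kind == "sipper"
        assert licks[0].peak_displacement == pytest.approx(15.0)

    def test_excursion_between_lines_is_short(self):
        y = np.zeros(30)
        y[10:14] = 8.0
        licks = lc.segment_video_licks(_track_from_y(y), lc.SegmentationConfig())
        assert len(licks) == 1
        assert licks[0].kind == "short"

    def test_two_excursions_beyond_gap_give_two_frame_accurate_licks(self):
        y = np.zeros(40)
        y[10:13] = 8.0
        y[18:21] = 8.0  # 5 below-threshold frames between: > max_gap_frames
        licks = lc.segment_video_licks(_track_from_y(y), lc.SegmentationConfig())
        assert len(licks) == 2
        dt = 1.0 / 60.0
        assert licks[0].start == pytest.approx(10 * dt)
        assert licks[0].end == pytest.approx(12 * dt + dt)
        assert licks[1].start == pytest.approx(18 * dt)
        assert licks[1].end == pytest.approx(20 * dt + dt)

    def test_one_frame_gap_is_bridged(self):
        y = np.zeros(40)
        y[10:13] = 8.0
        y[14:17] = 8.0  # single sub-threshold frame inside one lick
        licks = lc.segment_video_licks(_track_from_y(y), lc.SegmentationConfig())
        assert len(licks) == 1

    def test_low_likelihood_frames_are_inactive(self):
        y = np.zeros(30)
        y[10:14] = 8.0
        lik = np.full(30, 0.99)
        lik[10:14] = 0.5
        track = _track_from_y(y, likelihood=lik)
        assert lc.segment_video_licks(track, lc.SegmentationConfig()) == []

    def test_missing_tongue_tip_rejected(self):
        track = _track_from_y(np.zeros(10))
        track = lc.PoseTrack(
            frame_rate=60.0, time=track.time, bodyparts={"nose": track.bodyparts["nose"]}
        )
        with pytest.raises(ValueError, match="tongue_tip"):
            lc.segment_video_licks(track, lc.SegmentationConfig())


def _vl(start, end, kind="sipper"):
    return lc.VideoLick(start=start, end=end, kind=kind, peak_displacement=15.0)


def _stream(*onset_offset):
    return lc.EventStream(events=tuple(lc.LickEvent(a, b) for a, b in onset_offset))


class TestMatchEvents:
    def test_lick_without_event_is_false_negative(self):
        m = lc.match_events([_vl(1.0, 1.1)], _stream())
        assert m.fn == 1 and m.tp == 0 and m.fp == 0

    def test_second_event_in_same_lick_is_false_positive(self):
        m = lc.match_events([_vl(1.0, 1.1)], _stream((1.02, 1.03), (1.05, 1.06)))
        assert m.tp == 1 and m.fp == 1 and m.fn == 0

    def test_event_outside_all_licks_is_false_positive(self):
        m = lc.match_events([_vl(1.0, 1.1)], _stream((5.0, 5.05)))
        assert m.tp == 0 and m.fp == 1 and m.fn == 1

    def test_onset_rule_for_straddling_event(self):
        # onset inside the lick, offset beyond: belongs to the lick
        m = lc.match_events([_vl(1.0, 1.1)], _stream((1.08, 1.3)))
        assert m.tp == 1 and m.fp == 0

    def test_overlapping_video_licks_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            lc.match_events([_vl(1.0, 1.2), _vl(1.1, 1.4)], _stream())

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_label_partition_property(self, seed):
        rng = np.random.default_rng(seed)
        n_licks = rng.integers(0, 8)
        t = 0.0
        licks = []
        for _ in range(n_licks):
            t += rng.uniform(0.2, 1.0)
            licks.append(_vl(t, t + rng.uniform(0.05, 0.15)))
            t = licks[-1].end
        n_ev = rng.integers(0, 10)
        onsets = np.sort(rng.uniform(0, max(t, 1.0) + 1.0, size=n_ev))
        events, prev = [], -1.0
        for o in onsets:
            o = max(o, prev + 2e-3)
            events.append((o, o + 1e-3))
            prev = o
        m = lc.match_events(licks, _stream(*events))
        assert m.tp + m.fp == len(events)
        assert sum(m.lick_matched) + m.fn == len(licks)
        assert m.tp == sum(m.lick_matched)


class TestDetectionMetrics:
    def test_basic_arithmetic(self):
        m = lc.DetectionMetrics(tp=9, fp=1, fn=0)
        assert m.precision == pytest.approx(0.9)
        assert m.recall == pytest.approx(1.0)

    def test_undefined_precision_is_sentinel_not_zero(self):
        m = lc.DetectionMetrics(tp=0, fp=0, fn=3)
        assert m.precision is None
        assert m.recall == 0.0

    def test_pooled_vs_mean_of_ratios(self):
        sessions = [
            lc.DetectionMetrics(tp=9, fp=1, fn=0),
            lc.DetectionMetrics(tp=1, fp=9, fn=0),
        ]
        g = GroupedMetrics(pooled=lc.DetectionMetrics(10, 0, 10), per_session=tuple(sessions))
        assert g.pooled.precision == pytest.approx(0.5)
        assert g.precision_mean_sem[0] == pytest.approx(0.5 * (0.9 + 0.1))
        # unbalanced sessions: pooled and mean-of-ratios diverge
        g2 = GroupedMetrics(
            pooled=lc.DetectionMetrics(91, 0, 19),
            per_session=(
                lc.DetectionMetrics(tp=90, fp=10, fn=0),
                lc.DetectionMetrics(tp=1, fp=9, fn=0),
            ),
        )
        assert g2.pooled.precision == pytest.approx(91 / 110)
        assert g2.precision_mean_sem[0] == pytest.approx(0.5 * (0.9 + 0.1))
        assert g2.pooled.precision != pytest.approx(g2.precision_mean_sem[0])


class TestFisherExact:
    def test_validation_contingency_is_highly_significant(self):
        p = lc.fisher_exact_2x2(ContingencyTable2x2(10, 17, 4, 199))
        assert p < 1e-4

    def test_empty_column_gives_p_one(self):
        assert lc.fisher_exact_2x2(ContingencyTable2x2(0, 5, 0, 7)) == 1.0

    def test_diagonal_two_by_two_enumeration(self):
        assert lc.fisher_exact_2x2(ContingencyTable2x2(2, 0, 0, 2)) == pytest.approx(
            1.0 / 3.0, abs=1e-15
        )

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable2x2(-1, 2, 3, 4)

    @pytest.mark.parametrize("n", [5, 11, 18])
    def test_matches_enumeration_oracle_small_tables(self, n):
        for a in range(n + 1):
            for b in range(n + 1 - a):
                for c in range(n + 1 - a - b):
                    d = n - a - b - c
                    p = lc.fisher_exact_2x2(ContingencyTable2x2(a, b, c, d))
                    assert p == pytest.approx(enumerate_fisher_p(a, b, c, d), abs=1e-13)

    def test_agrees_with_scipy_convention(self, rng):
        for _ in range(50):
            a, b, c, d = rng.integers(0, 25, size=4)
            if (a + b) == 0 or (c + d) == 0 or (a + c) == 0 or (b + d) == 0:
                continue
            ours = lc.fisher_exact_2x2(ContingencyTable2x2(int(a), int(b), int(c), int(d)))
            theirs = scipy_fisher([[a, b], [c, d]])[1]
            assert ours == pytest.approx(theirs, rel=1e-6, abs=1e-12)


class TestPosthocFilter:
    def test_long_duration_event_removed(self):
        s = _stream((1.0, 1.25))
        out, removals = lc.apply_posthoc_filter(s, lc.FilterConfig())
        assert len(out) == 0
        assert removals[0].reason == "duration"

    def test_short_ili_second_event_removed(self):
        s = _stream((1.0, 1.02), (1.03, 1.05))
        out, removals = lc.apply_posthoc_filter(s, lc.FilterConfig())
        assert [e.onset for e in out] == [1.0]
        assert removals[0].reason == "ili"

    def test_isolated_valid_event_kept(self):
        s = _stream((1.0, 1.05))
        out, removals = lc.apply_posthoc_filter(s, lc.FilterConfig())
        assert len(out) == 1 and not removals

    def test_removed_double_does_not_shield_next_double(self):
        # onsets 0, 0.03, 0.06: second removed; third measured against FIRST
        # (0.06 gap > 0.05) and kept
        s = _stream((0.0, 0.01), (0.03, 0.04), (0.06, 0.07))
        out, removals = lc.apply_posthoc_filter(s, lc.FilterConfig())
        assert [e.onset for e in out] == [0.0, 0.06]
        assert len(removals) == 1 and removals[0].reason == "ili"

    def test_disjunctive_mode_removes_only_double_failures(self):
        # valid duration + bad ILI survives in disjunctive mode
        s = _stream((1.0, 1.02), (1.03, 1.05))
        out, _ = lc.apply_posthoc_filter(s, lc.FilterConfig(), mode="disjunctive")
        assert len(out) == 2
        # bad duration + bad ILI removed in disjunctive mode
        s2 = _stream((1.0, 1.02), (1.03, 1.33))
        out2, removals2 = lc.apply_posthoc_filter(s2, lc.FilterConfig(), mode="disjunctive")
        assert [e.onset for e in out2] == [1.0]
        assert removals2[0].reason == "duration+ili"


class TestFilterEffectOnSyntheticSessions:
    @pytest.mark.parametrize("seed", range(5))
    def test_filter_raises_precision_leaves_recall(self, seed):
        rng = np.random.default_rng(seed)
        truth = lc.simulate_task_session(
            lc.TaskConfig(session_duration=300.0), lc.LickTrainParams(), rng
        )
        res = lc.corrupt_events(truth, lc.ErrorModel(), rng)
        pose = lc.synthesize_pose(truth, lc.synthetic.PoseSimConfig(), rng)
        licks = lc.segment_video_licks(pose, lc.SegmentationConfig())
        pre = lc.detection_metrics(lc.match_events(licks, res.stream))
        filtered, _ = lc.apply_posthoc_filter(res.stream, lc.FilterConfig())
        post = lc.detection_metrics(lc.match_events(licks, filtered))
        assert post.fp < pre.fp
        assert post.precision > pre.precision
        assert post.fn == pre.fn
        assert post.recall == pre.recall


class TestPrecisionRecallRecovery:
    def test_estimates_recover_generative_error_rates(self):
        """On large synthetic sessions the measured FN rate per lick kind and
        the FP rate land inside 95% CIs of the generating error model."""
        from scipy.stats import binomtest

        model = lc.ErrorModel()
        n_short = n_sipper = fn_short = fn_sipper = 0
        n_true_events = n_doubles = 0
        seed = 100
        while n_short < 2000:
            rng = np.random.default_rng(seed)
            truth = lc.simulate_task_session(lc.TaskConfig(), lc.LickTrainParams(), rng)
            res = lc.corrupt_events(truth, model, rng)
            pose = lc.synthesize_pose(truth, lc.synthetic.PoseSimConfig(), rng)
            licks = lc.segment_video_licks(pose, lc.SegmentationConfig())
            m = lc.match_events(licks, res.stream)
            for vl, ok in zip(m.licks, m.lick_matched):
                if vl.kind == "short":
                    n_short += 1
                    fn_short += not ok
                else:
                    n_sipper += 1
                    fn_sipper += not ok
            n_true_events += sum(1 for l in res.labels if l == "true")
            n_doubles += sum(1 for l in res.labels if l == "double_fp")
            seed += 1
        assert binomtest(fn_short, n_short, model.p_fn_short).pvalue > 0.01
        assert binomtest(fn_sipper, n_sipper, model.p_fn_sipper).pvalue > 0.01
        assert binomtest(n_doubles, n_true_events, model.p_double).pvalue > 0.01
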