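"""Answer detection, response tables, bins and repeatability."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from softcalls import exchange, playback, synth
from softcalls.exchange import (
    answer_type_proportions,
    bin_call_counts,
    build_series_responses,
    detect_answers,
    first_answer_latency,
    repeatability_index,
)


def brute_force_answers(triggers, responders, window):
    """O(n^2) reference: each responder answers its nearest preceding
    trigger if within (0, window]."""
    out = []
    for j, r in enumerate(responders):
        best = None
        for i, t in enumerate(triggers):
            if 0 < r - t <= window and (best is None or t > triggers[best]):
                best = i
        if best is not None:
            out.append((best, j, r - triggers[best]))
    return out


class TestDetectAnswers:
    def test_answer_within_window(self):
        ans = detect_answers(np.array([10.0]), np.array([10.3]))
        assert len(ans) == 1
        assert ans["latency_s"].iloc[0] == pytest.approx(0.3)

    def test_answer_outside_window(self):
        assert len(detect_answers(np.array([10.0]), np.array([10.6]))) == 0

    def test_simultaneous_onset_not_an_answer(self):
        assert len(detect_answers(np.array([10.0]), np.array([10.0]))) == 0

    def test_matches_brute_force_on_random_streams(self):
        rng = np.random.default_rng(42)
        trig = np.sort(rng.uniform(0, 100, 200))
        resp = np.sort(rng.uniform(0, 100, 200))
        got = detect_answers(trig, resp, window_s=0.5)
        want = brute_force_answers(trig, resp, 0.5)
        assert len(got) == len(want)
        for (ti, ri, lat), (_, row) in zip(want, got.iterrows()):
            assert row["trigger_idx"] == ti
            assert row["responder_idx"] == ri
            assert row["latency_s"] == pytest.approx(lat)

    def test_unsorted_input_rejected(self):
        with pytest.raises(ValueError, match="sorted"):
            detect_answers(np.array([2.0, 1.0]), np.array([1.5]))

    @given(st.floats(min_value=-1e5, max_value=1e5))
    @settings(max_examples=25, deadline=None)
    def test_shift_invariance(self, shift):
        rng = np.random.default_rng(3)
        trig = np.sort(rng.uniform(0, 50, 60))
        resp = np.sort(rng.uniform(0, 50, 60))
        a = detect_answers(trig, resp)
        b = detect_answers(trig + shift, resp + shift)
        assert len(a) == len(b)
        np.testing.assert_allclose(a["latency_s"], b["latency_s"], atol=1e-6)

    def test_each_responder_answers_at_most_once(self):
        trig = np.array([0.0, 0.3])
        resp = np.array([0.4])  # within window of both triggers
        ans = detect_answers(trig, resp)
        assert len(ans) == 1
        assert ans["trigger_idx"].iloc[0] == 1  # nearest preceding


class TestFirstAnswerLatency:
    def test_earliest_answer_wins(self):
        assert first_answer_latency(10.0, np.array([10.4, 10.9])) == pytest.approx(0.4)

    def test_none_when_no_answer_in_window(self):
        assert first_answer_latency(10.0, np.array([12.0])) is None

    def test_matches_brute_force(self):
        rng = np.random.default_rng(11)
        resp = np.sort(rng.uniform(0, 100, 300))
        for em in rng.uniform(0, 100, 50):
            lats = [r - em for r in resp if 0 < r - em <= 1.5]
            want = min(lats) if lats else None
            got = first_answer_latency(em, resp)
            if want is None:
                assert got is None
            else:
                assert got == pytest.approx(want)


@pytest.fixture(scope="module")
def reduced_trial():
    sched = playback.build_schedule(
        "M", playback.default_exemplars("M"), seed=21, call_types=("stack",), emissions_per_exemplar=30
    )
    model = synth.ExchangeModel(
        answer_prob=0.5,
        answer_latency_mean={"m": 0.6, "f": 0.6, "uf": 0.6},
        subject_latency_sd=0.0,
    )
    resp = synth.generate_playback_responses(sched, model, seed=22)
    return sched, resp


class TestSeriesResponses:
    def test_male_trial_has_15_rows(self, male_schedule, default_model):
        resp = synth.generate_playback_responses(male_schedule, default_model, seed=1)
        series, _ = build_series_responses(male_schedule, resp, "s0", "A", "aud1")
        assert len(series) == 15
        assert list(series.columns) == exchange.SERIES_COLUMNS

    def test_empty_responder_stream_all_zero(self, male_schedule):
        empty = np.array([])
        series, lats = build_series_responses(male_schedule, empty, "s0", "A", "aud1")
        assert (series["n_answers"] == 0).all()
        assert len(lats) == 0

    def test_planted_answer_rate_recovered(self, reduced_trial):
        sched, resp = reduced_trial
        series, _ = build_series_responses(sched, resp, "s0", "A", "aud1")
        # every answer falls within 0.5 s with prob P(lat<=0.5); expected
        # answers per series = 90 * 0.5 * P; binomial slack
        from scipy.stats import truncnorm

        from softcalls.synth import _truncnorm_loc

        mu = _truncnorm_loc(0.6, 0.25, 0.0, 1.5)
        p_within = truncnorm.cdf(0.5, (0 - mu) / 0.25, (1.5 - mu) / 0.25, loc=mu, scale=0.25)
        expected = 90 * 0.5 * p_within
        sd = np.sqrt(90 * 0.5 * p_within * (1 - 0.5 * p_within))
        for n in series["n_answers"]:
            assert abs(n - expected) < 4 * sd

    def test_clock_mismatch_warns_and_excludes(self, male_schedule):
        resp = np.array([-50.0, 10.0])
        with pytest.warns(UserWarning, match="precede"):
            series, _ = build_series_responses(male_schedule, resp, "s0", "A", "aud1")


class TestAnswerTypeProportions:
    def test_below_threshold_excluded(self):
        answers = pd.DataFrame({"call_type": ["stack"] * 4})
        assert answer_type_proportions(answers) is None

    def test_single_type(self):
        answers = pd.DataFrame({"call_type": ["stack"] * 10})
        assert answer_type_proportions(answers) == {"stack": 1.0}

    def test_mixed_counts_sum_to_one(self):
        answers = pd.DataFrame({"call_type": ["stack"] * 6 + ["distance"] * 4})
        props = answer_type_proportions(answers)
        assert props == {"stack": 0.6, "distance": 0.4}
        assert sum(props.values()) == pytest.approx(1.0)


class TestBinCounts:
    def test_simple_two_bins(self):
        counts = bin_call_counts(np.array([10.0, 600.0]), bin_s=500, span_s=1000)
        assert counts.tolist() == [1, 1]

    def test_no_events(self):
        assert bin_call_counts(np.array([]), bin_s=500, span_s=2000).tolist() == [0, 0, 0, 0]

    def test_counts_conserve_total(self):
        rng = np.random.default_rng(5)
        ev = np.sort(rng.uniform(0, 9000, 1800))  # lambda = 0.2/s
        counts = bin_call_counts(ev, bin_s=500, span_s=9000)
        assert counts.sum() == len(ev)
        assert abs(counts.mean() - 100) < 3 * np.sqrt(100 / len(counts))

    def test_boundary_half_open(self):
        counts = bin_call_counts(np.array([499.999999, 500.0]), bin_s=500, span_s=1000)
        assert counts.tolist() == [1, 1]


class TestRepeatability:
    def test_hand_anova_oracle(self):
        # groups {1,2},{5,6},{9,10}: MSA=32, MSW=0.5, F=64, n0=2,
        # r = 31.5/32.5
        vals = [1, 2, 5, 6, 9, 10]
        grps = ["a", "a", "b", "b", "c", "c"]
        res = repeatability_index(vals, grps)
        assert res.ms_among == pytest.approx(32.0)
        assert res.ms_within == pytest.approx(0.5)
        assert res.f_ratio == pytest.approx(64.0)
        assert res.r == pytest.approx(31.5 / 32.5)

    def test_equal_group_means_r_near_zero(self):
        vals = [1, 2, 1, 2, 1, 2]
        res = repeatability_index(vals, ["a", "a", "b", "b", "c", "c"])
        assert res.r == pytest.approx(0.0, abs=1e-9)  # clamped; F <= 1

    def test_zero_within_variance_r_one(self):
        res = repeatability_index([1, 1, 5, 5, 9, 9], ["a", "a", "b", "b", "c", "c"])
        assert res.r == 1.0
        assert np.isinf(res.f_ratio)

    def test_degenerate_identical_values(self):
        with pytest.raises(ValueError, match="degenerate"):
            repeatability_index([3, 3, 3, 3], ["a", "a", "b", "b"])

    def test_monotone_in_between_group_variance(self):
        rs = []
        for spread in (1.0, 2.0, 4.0, 8.0):
            vals = np.concatenate([[0, 1], [spread, spread + 1], [2 * spread, 2 * spread + 1]])
            rs.append(repeatability_index(vals, ["a", "a", "b", "b", "c", "c"]).r)
        assert rs == sorted(rs)


class TestExchangeSummary:
    def test_proportions_in_unit_interval(self, bird_pair, default_model):
        cfg = synth.SimConfig(seed=31, session_duration_s=4000)
        a, b = synth.generate_exchange_session(bird_pair, default_model, cfg)
        summ = exchange.exchange_summary(a, b)
        assert (summ["proportion"] > 0).all()
        assert (summ["proportion"] <= 1).all()
        assert (summ["n_answers"] <= summ["n_caller_calls"]).all()
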