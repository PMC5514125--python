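"""Mixed models, posterior simulation and the secondary tests."""

import warnings

import numpy as np
import pandas as pd
import pytest

from softcalls import inference, pipeline, synth
from softcalls.inference import (
    ModelSpec,
    answer_type_composition_test,
    baseline_playback_correlation,
    compare_cells,
    fit_mixed_model,
    habituation_test,
    simulate_posterior,
    subset_robustness,
)

LAT_SPEC = ModelSpec(response="latency_s", transform="sqrt", fixed=("familiarity",), random=("subject_id",))


def make_latency_table(rng, n_subjects=5, n_per_cell=60, means=None, subject_sd=0.05, resid_sd=0.2):
    means = means or {"m": 0.55, "f": 0.67, "uf": 0.67}
    rows = []
    for s in range(n_subjects):
        off = rng.normal(0, subject_sd)
        for fam, mu in means.items():
            for _ in range(n_per_cell):
                rows.append((f"s{s}", fam, max(0.01, mu + off + rng.normal(0, resid_sd))))
    return pd.DataFrame(rows, columns=["subject_id", "familiarity", "latency_s"])


class TestCompareCells:
    def test_identical_draws_tie_rule(self):
        d = np.arange(100.0)
        assert compare_cells(d, d).p_greater == 0.5

    def test_fully_separated(self):
        res = compare_cells(np.zeros(100), np.ones(100))
        assert res.p_greater == 0.0
        assert res.significant

    def test_standard_normal_pairs_near_half(self):
        rng = np.random.default_rng(0)
        res = compare_cells(rng.normal(size=10000), rng.normal(size=10000))
        assert abs(res.p_greater - 0.5) < 0.02  # binomial SE ~ 0.005

    def test_complement_identity(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(size=500), rng.normal(size=500)
        assert compare_cells(a, b).p_greater + compare_cells(b, a).p_greater == pytest.approx(1.0)

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            compare_cells(np.zeros(3), np.zeros(4))


class TestMixedModelFit:
    def test_parameter_recovery_within_3_se(self, rng):
        table = make_latency_table(rng, n_subjects=8, n_per_cell=80)
        spec = ModelSpec(response="latency_s", transform="identity", fixed=("familiarity",), random=("subject_id",))
        fit = fit_mixed_model(table, spec)
        post = simulate_posterior(fit, n_draws=4000, seed=0)
        est = post.fitted[post.cell_index(familiarity="f")] - post.fitted[post.cell_index(familiarity="m")]
        se = np.sqrt(
            fit.fe_cov()[1, 1] * 4  # contrast variance upper bound
        )
        assert abs(est - 0.12) < 3 * se + 0.02

    def test_constant_response_zero_contrasts(self, rng):
        table = make_latency_table(rng, subject_sd=0.0, resid_sd=0.0, means={"m": 0.5, "f": 0.5, "uf": 0.5})
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = fit_mixed_model(table, LAT_SPEC)
        betas = np.asarray(fit.fe_params)[1:]
        np.testing.assert_allclose(betas, 0.0, atol=1e-8)

    def test_sqrt_transform_preserves_cell_ordering(self, rng):
        table = make_latency_table(rng, n_subjects=6, n_per_cell=100)
        order = {}
        for transform in ("sqrt", "identity"):
            spec = ModelSpec(response="latency_s", transform=transform, fixed=("familiarity",), random=("subject_id",))
            post = simulate_posterior(fit_mixed_model(table, spec), n_draws=10, seed=0)
            fitted = {fam: post.fitted[post.cell_index(familiarity=fam)] for fam in ("m", "f", "uf")}
            order[transform] = sorted(fitted, key=fitted.get)
        assert order["sqrt"] == order["identity"]

    def test_posterior_draw_mean_matches_point_estimate(self, rng):
        table = make_latency_table(rng)
        fit = fit_mixed_model(table, LAT_SPEC)
        post = simulate_posterior(fit, n_draws=8000, seed=3)
        mc_se = post.draws.std(axis=0) / np.sqrt(post.draws.shape[0])
        np.testing.assert_allclose(post.draws.mean(axis=0), post.fitted, atol=5 * mc_se.max())

    def test_fixed_seed_identical_draws(self, rng):
        table = make_latency_table(rng)
        fit = fit_mixed_model(table, LAT_SPEC)
        d1 = simulate_posterior(fit, n_draws=100, seed=9).draws
        d2 = simulate_posterior(fit, n_draws=100, seed=9).draws
        np.testing.assert_array_equal(d1, d2)

    def test_crossed_random_effects_accepted(self, rng):
        table = make_latency_table(rng, n_subjects=6, n_per_cell=30)
        table["audience_id"] = rng.choice(["a1", "a2", "a3"], len(table))
        table["playback_order"] = rng.choice([1, 2, 3], len(table))
        spec = ModelSpec(response="latency_s", transform="sqrt", fixed=("familiarity",))
        fit = fit_mixed_model(table, spec)
        assert set(fit.diagnostics["random_factors"]) == {"subject_id", "audience_id", "playback_order"}


class TestHabituation:
    def test_single_subject_constant_counts(self):
        counts = pd.DataFrame({"subject_id": ["s0"] * 10, "bin": list(range(10)), "n_calls": [20] * 10})
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out = habituation_test(counts, n_draws=2000, seed=0)
        assert abs(out["comparison"].p_greater - 0.5) < 0.35  # degenerate fit, wide slack

    def test_planted_decline_detected(self, rng):
        rows = []
        for s in range(8):
            for b in range(10):
                rows.append((f"s{s}", b, rng.poisson(100 - 8 * b)))
        counts = pd.DataFrame(rows, columns=["subject_id", "bin", "n_calls"])
        out = habituation_test(counts, n_draws=2000, seed=1)
        assert out["comparison"].p_greater > 0.95  # first bin clearly larger

    def test_stationary_counts_not_significant(self, rng):
        rows = [(f"s{s}", b, rng.poisson(100)) for s in range(8) for b in range(10)]
        out = habituation_test(pd.DataFrame(rows, columns=["subject_id", "bin", "n_calls"]), n_draws=2000, seed=2)
        assert 0.01 < out["comparison"].p_greater < 0.99

    def test_single_bin_rejected(self):
        counts = pd.DataFrame({"subject_id": ["s0"], "bin": [0], "n_calls": [5]})
        with pytest.raises(ValueError):
            habituation_test(counts)


class TestCompositionTest:
    def test_below_nonnull_threshold_skipped(self):
        res = answer_type_composition_test({"m": [0.5, 0.4], "f": [0.3, 0.2], "uf": [0.6, 0.1, 0.2]})
        assert res.skipped and "7" in res.reason

    def test_identical_groups_high_p(self):
        res = answer_type_composition_test({"m": [0.5] * 4, "f": [0.5] * 4, "uf": [0.5] * 4})
        assert not res.skipped
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_hand_ranked_oracle(self):
        # groups [1,2],[3,4],[5,6],[7,8]? use 3 groups of 2 with no ties:
        # rank sums 3, 7, 11 -> H = 12/(6*7) * (9/2+49/2+121/2) - 21 = 32/7
        res = answer_type_composition_test(
            {"m": [1, 2], "f": [3, 4], "uf": [5, 6]}, min_nonnull=6
        )
        assert res.statistic == pytest.approx(32 / 7)


class TestBaselineCorrelation:
    def test_identical_vectors_r_one(self):
        x = [0.1, 0.4, 0.3, 0.8, 0.6, 0.2]
        out = baseline_playback_correlation(x, x, n_draws=2000, seed=0)
        assert out["pearson_r"] == pytest.approx(1.0)
        assert out["slope"] == pytest.approx(1.0)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            baseline_playback_correlation([0.1, 0.2], [0.3, 0.4])

    def test_null_slope_coverage(self, rng):
        covered = 0
        reps = 120
        for _ in range(reps):
            x = rng.uniform(0, 1, 8)
            y = rng.normal(0.5, 0.1, 8)  # no relation
            out = baseline_playback_correlation(x, y, n_draws=1000, seed=int(rng.integers(2**31)))
            lo, hi = out["cri"]
            covered += lo <= 0 <= hi
        assert covered / reps > 0.85  # nominal 95%, small-n slack

    def test_planted_negative_slope_recovered(self, rng):
        estimates = []
        for _ in range(200):
            x = rng.uniform(0, 1, 6)
            y = 0.8 - 0.5 * x + rng.normal(0, 0.05, 6)
            out = baseline_playback_correlation(x, y, n_draws=200, seed=int(rng.integers(2**31)))
            estimates.append(out["slope"])
        est = np.asarray(estimates)
        assert abs(est.mean() + 0.5) < 3 * est.std(ddof=1) / np.sqrt(len(est))


@pytest.fixture(scope="module")
def trial():
    model = synth.ExchangeModel(subject_latency_sd=0.0)
    tables = []
    for s in range(4):
        out = pipeline.simulate_trial(
            "M", model, seed=50 + s, subject_id=f"s{s}",
            schedule_kwargs={"call_types": ("stack",), "emissions_per_exemplar": 30},
        )
        tables.append(out)
    lat = pd.concat([o["latencies"] for o in tables], ignore_index=True)
    return tables, lat


class TestSubsetRobustness:
    def test_subset_equal_to_full_identical(self, trial):
        _, lat = trial
        out = subset_robustness({"full": lat, "first": lat.copy()}, LAT_SPEC, n_draws=500, seed=0)
        np.testing.assert_allclose(out["effect_first"], out["effect_full"], rtol=1e-9)
        assert out["agree_first"].all()

    def test_stationary_responses_signs_agree(self, trial):
        tables, lat_full = trial
        firsts, lasts = [], []
        from softcalls.exchange import build_series_responses
        from softcalls.pipeline import subset_emissions

        for i, o in enumerate(tables):
            em = o["schedule"].emissions
            for which, dest in (("first", firsts), ("last", lasts)):
                sub = subset_emissions(em, 30, which)
                _, lats = build_series_responses(sub, o["responses"], f"s{i}", "A", "aud")
                dest.append(lats)
        tables_map = {
            "full": lat_full,
            "first": pd.concat(firsts, ignore_index=True),
            "last": pd.concat(lasts, ignore_index=True),
        }
        out = subset_robustness(tables_map, LAT_SPEC, n_draws=500, seed=1)
        # planted effect 0.12 s is strong: all datasets should agree in sign
        assert out["agree_first"].all()
        assert out["agree_last"].all()

    def test_missing_full_dataset_rejected(self, trial):
        _, lat = trial
        with pytest.raises(ValueError):
            subset_robustness({"first": lat}, LAT_SPEC)
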