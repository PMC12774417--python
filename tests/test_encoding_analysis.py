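"""Weight-regression estimator and its simulation controls."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bispeed.encoding_analysis import (
    BiSpeedCondition,
    UndefinedWeightError,
    bootstrap_compare,
    component_weights,
    estimate_weights_regression,
    log_mean_speed,
    random_weight_control,
    split_trial_regression,
)
from bispeed.synthetic_data import (
    EncodingRule,
    generate_poisson_trials,
    make_bispeed_responses,
)


class TestLogMeanSpeed:
    @pytest.mark.parametrize(
        "pair,expected",
        [((2.5, 10), 5.0), ((1.25, 5), 2.5), ((2.5, 5), 3.54), ((5, 10), 7.07),
         ((10, 20), 14.14), ((20, 40), 28.28)],
    )
    def test_printed_pairs(self, pair, expected):
        assert log_mean_speed(*pair) == pytest.approx(expected, abs=0.005)

    def test_identity_and_errors(self):
        assert log_mean_speed(7.3, 7.3) == pytest.approx(7.3)
        with pytest.raises(ValueError):
            log_mean_speed(-1.0, 5.0)

    def test_condition_properties(self):
        cond = BiSpeedCondition(v_s=5.0, v_f=20.0)
        assert cond.separation_factor == 4.0
        assert cond.log_mean_speed == pytest.approx(10.0)


class TestComponentWeights:
    def test_extremes_and_midpoint(self):
        assert component_weights(60.0, 20.0, 60.0) == pytest.approx((0.0, 1.0))
        assert component_weights(40.0, 20.0, 60.0) == pytest.approx((0.5, 0.5))
        assert component_weights(30.0, 20.0, 60.0) == pytest.approx((0.75, 0.25))

    def test_degenerate_denominator_flagged(self):
        with pytest.raises(UndefinedWeightError):
            component_weights(30.0, 25.0, 25.0)

    @given(
        r=st.floats(0, 200), r_s=st.floats(0, 200), r_f=st.floats(0, 200),
    )
    @settings(max_examples=200, deadline=None)
    def test_weights_always_sum_to_one(self, r, r_s, r_f):
        if abs(r_f - r_s) < 1e-6:
            return
        w_s, w_f = component_weights(r, r_s, r_f)
        assert w_s + w_f == pytest.approx(1.0, abs=1e-9)


class TestWeightRegression:
    def records(self, w_f, n=50, seed=0):
        rng = np.random.default_rng(seed)
        r_s = rng.uniform(5, 40, n)
        r_f = r_s + rng.uniform(1, 60, n)
        return pd.DataFrame({"R": (1 - w_f) * r_s + w_f * r_f, "R_s": r_s, "R_f": r_f})

    def test_faster_take_all_and_averaging(self):
        res = estimate_weights_regression(self.records(1.0))
        assert res.slope == pytest.approx(1.0, abs=1e-9)
        assert res.intercept == pytest.approx(0.0, abs=1e-8)
        assert res.r_squared == pytest.approx(1.0, abs=1e-12)
        res = estimate_weights_regression(self.records(0.5))
        assert res.slope == pytest.approx(0.5, abs=1e-9)

    def test_hand_computed_ols(self):
        # y = R - R_s = (5, 10, 2); x = R_f - R_s = (10, 20, 4): exactly y = x/2
        res = estimate_weights_regression([(10, 5, 15), (20, 10, 30), (12, 10, 14)])
        assert res.slope == pytest.approx(0.5, abs=1e-12)
        assert res.intercept == pytest.approx(0.0, abs=1e-12)
        assert res.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_noise_free_rule_recovery(self, population100):
        cond = BiSpeedCondition(v_s=2.5, v_f=10.0)
        for w_f in (0.2, 0.74, 0.9):
            rule = EncodingRule("fixed_weights", {"w_s": 1 - w_f, "w_f": w_f})
            df = make_bispeed_responses(population100, cond, rule)
            res = estimate_weights_regression(df)
            assert res.slope == pytest.approx(w_f, abs=1e-9)
            assert res.intercept == pytest.approx(0.0, abs=1e-7)

    def test_degenerate_predictor_rejected(self):
        df = pd.DataFrame({"R": [1, 2, 3], "R_s": [1, 1, 1], "R_f": [2, 2, 2]})
        with pytest.raises(ValueError):
            estimate_weights_regression(df)


class TestRandomWeightControl:
    def test_mean_slope_is_half(self, population100):
        cond = BiSpeedCondition(v_s=2.5, v_f=10.0)
        df = make_bispeed_responses(
            population100, cond, EncodingRule("fixed_weights", {"w_s": 0, "w_f": 1})
        )
        out = random_weight_control(df, n_reps=1000, seed=5)
        assert 0.45 < out["mean_slope"] < 0.55
        lo, hi = out["ci95_slope"]
        assert lo < 0.5 < hi
        assert len(out["slopes"]) == 1000

    def test_deterministic_given_seed(self, population100):
        cond = BiSpeedCondition(v_s=5.0, v_f=20.0)
        df = make_bispeed_responses(population100, cond, EncodingRule("average"))
        a = random_weight_control(df, n_reps=50, seed=11)
        b = random_weight_control(df, n_reps=50, seed=11)
        assert np.array_equal(a["slopes"], b["slopes"])


class TestBootstrapCompare:
    def test_order_statistics(self):
        sims = np.linspace(0.3, 0.7, 999)
        assert bootstrap_compare(0.9, sims) == pytest.approx(1 / 1000)
        assert bootstrap_compare(0.1, sims) == pytest.approx(1.0)
        assert bootstrap_compare(float(np.median(sims)), sims) == pytest.approx(0.5, abs=0.01)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_compare(0.5, [])


class TestSplitTrialRegression:
    def make_trials(self, population, w_f, n_trials, seed=0, poisson=True):
        cond = BiSpeedCondition(v_s=2.5, v_f=10.0)
        rule = EncodingRule("fixed_weights", {"w_s": 1 - w_f, "w_f": w_f})
        df = make_bispeed_responses(population, cond, rule)
        rows = []
        for cid, col in (("bi", "R"), ("slow", "R_s"), ("fast", "R_f")):
            rows.append(
                pd.DataFrame(
                    {"neuron_id": df["neuron_id"], "condition_id": cid, "rate": df[col]}
                )
            )
        rates = pd.concat(rows, ignore_index=True)
        if poisson:
            return generate_poisson_trials(rates, n_trials, duration=0.5, seed=seed)
        # noise-free "trials": identical counts in every trial
        table = rates.loc[rates.index.repeat(n_trials)].reset_index(drop=True)
        table["trial_index"] = np.tile(np.arange(n_trials), len(rates))
        table["spike_count"] = table["rate"] * 0.5
        table["duration"] = 0.5
        return table.drop(columns="rate")

    def test_equal_halves_reduce_to_plain_regression(self, population100):
        """When every slower-component trial is identical the split is a no-op."""
        trials = self.make_trials(population100, w_f=0.8, n_trials=4, poisson=False)
        out = split_trial_regression(trials, "bi", "slow", "fast", n_repeats=3, seed=0)
        assert out["mean_slope"] == pytest.approx(0.8, abs=1e-9)
        assert out["sd_slope"] == pytest.approx(0.0, abs=1e-9)

    def test_recovers_generative_weight_with_many_trials(self, population100):
        """Split-trial slope converges to the all-trials slope and to w_f."""
        from bispeed.io import trial_means

        trials = self.make_trials(population100, w_f=0.9, n_trials=1000, seed=2)
        out = split_trial_regression(trials, "bi", "slow", "fast", n_repeats=20, seed=3)
        means = trial_means(trials).pivot(index="neuron_id", columns="condition_id",
                                          values="rate")
        all_trials = estimate_weights_regression(
            pd.DataFrame({"R": means["bi"], "R_s": means["slow"], "R_f": means["fast"]})
        )
        assert out["mean_slope"] == pytest.approx(all_trials.slope, abs=0.02)
        assert out["mean_slope"] == pytest.approx(0.9, abs=0.03)

    def test_deterministic_given_seed(self, population100):
        trials = self.make_trials(population100, w_f=0.5, n_trials=10, seed=4)
        a = split_trial_regression(trials, "bi", "slow", "fast", n_repeats=5, seed=6)
        b = split_trial_regression(trials, "bi", "slow", "fast", n_repeats=5, seed=6)
        assert a == b
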