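"""RITI and LRM susceptibility classification and its building blocks."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ritisurv.cure_model import incidence_probability, latency_survival
from ritisurv.susceptibility import (
    classify_lrm,
    classify_riti_deterministic,
    classify_riti_stochastic,
    insusceptible_ratio,
    residual_event_time,
    youden_index,
)

from conftest import make_fit


def one_subject(x=1.0, t_e=3.0, delta_e=0, t_o=3.0, delta_o=1, sid=0):
    return pd.DataFrame(
        {"id": [sid], "x1": [x], "t_e": [t_e], "delta_e": [delta_e],
         "t_o": [t_o], "delta_o": [delta_o]}
    )


class TestInsusceptibleRatio:
    def test_prior_at_zero(self):
        fit = make_fit(0.4, [0.3], 0.2, 1.1, [0.5])
        x = np.array([1.0])
        pi = incidence_probability(fit.incidence, x)
        assert insusceptible_ratio(fit, x, 0.0) == pytest.approx(1.0 - pi)

    def test_certain_susceptibility_gives_zero(self):
        fit = make_fit(50.0, [0.0], 0.2, 1.0, [0.0])  # pi ~ 1
        assert insusceptible_ratio(fit, np.array([0.0]), 5.0) == pytest.approx(0.0, abs=1e-12)

    def test_limit_at_late_censoring(self):
        fit = make_fit(np.log(0.7 / 0.3), [0.0], 0.5, 1.0, [0.0])  # pi = 0.7
        assert insusceptible_ratio(fit, np.array([0.0]), 1e6) == pytest.approx(1.0)

    @settings(deadline=None, derandomize=True)
    @given(
        c1=st.floats(0.0, 12.0),
        c2=st.floats(0.0, 12.0),
        g0=st.floats(-3.0, 3.0),
    )
    def test_nondecreasing_in_censoring_time(self, c1, c2, g0):
        fit = make_fit(g0, [0.5], 0.3, 1.2, [0.4])
        x = np.array([1.0])
        lo, hi = sorted([c1, c2])
        assert insusceptible_ratio(fit, x, lo) <= insusceptible_ratio(fit, x, hi) + 1e-12


class TestResidualEventTime:
    def test_hand_inversion(self):
        # pi=1, exponential latency with rate 1, C_e=1, u=e^-1:
        # target survival u*S(C_e) = e^-2 -> total time 2 -> residual 1
        fit = make_fit(60.0, [0.0], 1.0, 1.0, [0.0])
        a = residual_event_time(fit, np.array([0.0]), 1.0, np.exp(-1.0))
        assert a == pytest.approx(1.0, abs=1e-9)

    def test_incalculable_when_draw_below_ratio(self):
        fit = make_fit(0.0, [0.0], 0.01, 1.0, [0.0])  # pi=0.5, S(C_e) ~ 1
        x = np.array([0.0])
        ratio = insusceptible_ratio(fit, x, 2.0)
        assert residual_event_time(fit, x, 2.0, ratio * 0.9) is None

    @settings(deadline=None, derandomize=True)
    @given(
        u=st.floats(0.01, 0.99),
        C_e=st.floats(0.1, 12.0),
        g0=st.floats(-2.0, 2.0),
    )
    def test_round_trip_identity(self, u, C_e, g0):
        fit = make_fit(g0, [0.3], 0.2, 1.3, [0.5])
        x = np.array([1.0])
        a = residual_event_time(fit, x, C_e, u)
        if a is None:
            assert u <= insusceptible_ratio(fit, x, C_e) + 1e-12
            return
        pi = incidence_probability(fit.incidence, x)
        num = 1 - pi + pi * latency_survival(fit.latency, C_e + a, x)
        den = 1 - pi + pi * latency_survival(fit.latency, C_e, x)
        assert num / den == pytest.approx(u, abs=1e-10)

    def test_invalid_u_rejected(self):
        fit = make_fit(0.0, [0.0], 1.0, 1.0, [0.0])
        with pytest.raises(ValueError):
            residual_event_time(fit, np.array([0.0]), 1.0, 1.5)


class TestStochasticRITI:
    def test_event_subjects_always_susceptible(self):
        fit = make_fit(-40.0, [0.0], 0.2, 1.0, [0.0])  # pi ~ 0: ratio ~ 1
        data = one_subject(delta_e=1, t_e=2.0, t_o=5.0)
        for seed in range(20):
            calls = classify_riti_stochastic(fit, data, seed)
            assert calls["label"].iloc[0] == 1
            assert calls["ratio"].iloc[0] == 0.0

    def test_certain_susceptibility_all_labelled_one(self):
        fit = make_fit(50.0, [0.0], 0.2, 1.0, [0.0])
        data = pd.concat([one_subject(sid=i) for i in range(10)], ignore_index=True)
        calls = classify_riti_stochastic(fit, data, 3)
        assert (calls["label"] == 1).all()

    def test_label_rate_matches_ratio(self):
        # Monte-Carlo identity: P(label=0) equals the insusceptible ratio
        fit = make_fit(0.5, [0.4], 0.15, 1.1, [0.6])
        data = one_subject(x=1.0, t_e=6.0)
        ratio = insusceptible_ratio(fit, np.array([1.0]), 6.0)
        n = 4000
        hits = sum(
            classify_riti_stochastic(fit, data, seed)["label"].iloc[0] == 0
            for seed in range(n)
        )
        se = np.sqrt(ratio * (1 - ratio) / n)
        assert hits / n == pytest.approx(ratio, abs=3 * se)

    def test_order_independence(self):
        fit = make_fit(0.2, [0.4], 0.15, 1.1, [0.6])
        rng = np.random.default_rng(1)
        data = pd.concat(
            [one_subject(x=float(rng.uniform(0, 2)), t_e=float(rng.uniform(1, 10)), sid=i)
             for i in range(30)],
            ignore_index=True,
        )
        shuffled = data.sample(frac=1.0, random_state=5).reset_index(drop=True)
        a = classify_riti_stochastic(fit, data, 77).set_index("id")["label"]
        b = classify_riti_stochastic(fit, shuffled, 77).set_index("id")["label"]
        assert a.sort_index().equals(b.sort_index())


class TestDeterministicRITI:
    def test_rule_and_boundaries(self):
        fit = make_fit(0.0, [0.0], 0.2, 1.0, [0.0])
        data = one_subject(x=0.0, t_e=4.0)
        ratio = insusceptible_ratio(fit, np.array([0.0]), 4.0)
        calls = classify_riti_deterministic(fit, data, cutoff=ratio - 0.01)
        assert calls["label"].iloc[0] == 0  # ratio > cutoff -> insusceptible
        calls = classify_riti_deterministic(fit, data, cutoff=ratio)
        assert calls["label"].iloc[0] == 1  # ratio == cutoff -> susceptible (strict >)

    def test_low_ratio_susceptible(self):
        # pi = 0.9 and C_e = 0 -> ratio = 0.1 -> susceptible
        fit = make_fit(np.log(9.0), [0.0], 0.2, 1.0, [0.0])
        calls = classify_riti_deterministic(fit, one_subject(x=0.0, t_e=0.0))
        assert calls["ratio"].iloc[0] == pytest.approx(0.1)
        assert calls["label"].iloc[0] == 1

    def test_agrees_with_stochastic_at_extreme_ratios(self):
        # ratio ~ 0 (pi ~ 1): both label susceptible; ratio ~ 1 (pi ~ 0,
        # u < 1 always): both label insusceptible
        sure = make_fit(50.0, [0.0], 0.2, 1.0, [0.0])
        never = make_fit(-50.0, [0.0], 0.2, 1.0, [0.0])
        data = one_subject(t_e=5.0)
        for fit, expected in [(sure, 1), (never, 0)]:
            det = classify_riti_deterministic(fit, data)["label"].iloc[0]
            sto = classify_riti_stochastic(fit, data, 123)["label"].iloc[0]
            assert det == sto == expected


class TestLRM:
    def test_extremes(self):
        data = one_subject()
        assert classify_lrm(make_fit(-50.0, [0.0], 1, 1, [0.0]), data, 0)["label"].iloc[0] == 0
        assert classify_lrm(make_fit(50.0, [0.0], 1, 1, [0.0]), data, 0)["label"].iloc[0] == 1

    def test_rate_matches_incidence(self):
        fit = make_fit(0.3, [0.0], 1.0, 1.0, [0.0])
        pi = incidence_probability(fit.incidence, np.array([0.0]))
        data = one_subject(x=0.0)
        n = 3000
        hits = sum(
            classify_lrm(fit, data, seed)["label"].iloc[0] == 1 for seed in range(n)
        )
        se = np.sqrt(pi * (1 - pi) / n)
        assert hits / n == pytest.approx(pi, abs=3 * se)


class TestYoudenIndex:
    def test_perfect_prediction(self):
        t = np.array([1, 1, 0, 0])
        assert youden_index(t, t) == 1.0

    def test_all_predicted_susceptible(self):
        assert youden_index(np.array([1, 1, 0, 0]), np.ones(4)) == 0.0

    def test_arithmetic(self):
        # sensitivity 0.8 (4/5), specificity 0.7 (7/10)
        true = np.r_[np.ones(5), np.zeros(10)].astype(int)
        pred = np.r_[np.ones(4), 0, np.ones(3), np.zeros(7)].astype(int)
        assert youden_index(true, pred) == pytest.approx(0.5)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            youden_index(np.ones(4, dtype=int), np.ones(4, dtype=int))
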