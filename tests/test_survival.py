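"""Cox screening, risk scores, Kaplan-Meier, log-rank and subtype markers."""

import numpy as np
import pytest

from _oracles import km_by_risk_sets, logrank_by_hand
from epishift.survival import (
    RiskModel,
    SurvivalRecord,
    build_signature,
    dichotomize,
    km_estimate,
    logrank,
    risk_score,
    subtype_markers,
    univariate_cox,
)


def rec(i, time, event, subtype="ALL", **expr):
    return SurvivalRecord(f"s{i}", time, event, subtype, dict(expr))


def simulate_cohort(rng, n=300, beta=1.0, censor=0.0, binary=False, subtype="ALL"):
    records = []
    for i in range(n):
        x = float(rng.integers(0, 2)) if binary else float(rng.standard_normal())
        st = subtype
        t = float(rng.exponential(np.exp(-beta * x)))
        event = 1
        if censor and rng.random() < censor:
            event, t = 0, t * float(rng.uniform(0.1, 1.0))
        records.append(rec(i, max(t, 1e-6), event, st, g=x))
    return records


class TestUnivariateCox:
    def test_planted_binary_hazard_recovered(self, rng):
        records = simulate_cohort(rng, n=300, beta=1.0, binary=True)
        res = univariate_cox(records, "g")
        assert res.ok
        assert abs(res.beta - 1.0) < 0.25

    def test_all_censored_flagged(self):
        records = [rec(i, 10.0 + i, 0, g=float(i)) for i in range(10)]
        res = univariate_cox(records, "g")
        assert not res.ok and "events" in res.reason

    def test_zero_variance_flagged(self):
        records = [rec(i, 1.0 + i, 1, g=2.0) for i in range(10)]
        res = univariate_cox(records, "g")
        assert not res.ok and "variance" in res.reason

    def test_null_wald_calibration(self):
        rng = np.random.default_rng(99)
        rejections = 0
        n_reps = 100
        for _ in range(n_reps):
            records = [
                rec(i, float(rng.exponential(1.0)) + 1e-6, 1, g=float(rng.standard_normal()))
                for i in range(200)
            ]
            res = univariate_cox(records, "g")
            rejections += res.ok and res.wald_p < 0.05
        se = np.sqrt(0.05 * 0.95 / n_reps)
        assert rejections / n_reps < 0.05 + 3 * se + 1e-12


class TestSignatureAndScore:
    def test_planted_pair_enters_with_correct_signs(self, rng):
        records = []
        for i in range(300):
            x1, x2 = rng.standard_normal(2)
            x3, x4 = rng.standard_normal(2)
            t = float(rng.exponential(np.exp(-(1.0 * x1 - 1.0 * x2))))
            records.append(
                rec(i, max(t, 1e-6), 1, risky=float(x1), protective=float(x2),
                    null1=float(x3), null2=float(x4))
            )
        model = build_signature(records, ["risky", "protective", "null1", "null2"])
        assert "risky" in model.genes and "protective" in model.genes
        beta = dict(zip(model.genes, model.beta))
        assert beta["risky"] > 0 > beta["protective"]

    def test_zero_threshold_empty_model(self, rng):
        records = simulate_cohort(rng, n=50)
        model = build_signature(records, ["g"], p_threshold=0.0)
        assert model.n == 0

    def test_duplicated_gene_deterministic(self, rng):
        records = simulate_cohort(rng, n=100)
        model = build_signature(records, ["g", "g"])
        assert model.genes == ["g", "g"]
        assert model.beta[0] == model.beta[1]

    @pytest.mark.parametrize(
        "genes, beta, expr, expected",
        [
            (["a", "b"], [0.5, -1.0], {"a": 2.0, "b": 1.0}, 0.0),
            ([], [], {"a": 5.0}, 0.0),
            (["a"], [1.0], {"a": 3.2}, 3.2),
        ],
    )
    def test_risk_score_arithmetic(self, genes, beta, expr, expected):
        assert risk_score(RiskModel(genes, beta), expr) == pytest.approx(expected)

    def test_risk_score_linearity_and_missing_gene(self, rng):
        model = RiskModel(["a", "b"], [0.7, -0.3])
        expr = {"a": 1.5, "b": 2.0}
        assert risk_score(model, {k: 3 * v for k, v in expr.items()}) == pytest.approx(
            3 * risk_score(model, expr)
        )
        with pytest.raises(KeyError, match="b"):
            risk_score(model, {"a": 1.0})


class TestDichotomize:
    def test_even_split(self):
        model = RiskModel(["g"], [1.0])
        records = [rec(i, 10.0, 1, g=float(i + 1)) for i in range(4)]
        got = dichotomize(records, model)
        assert got["cutoff"] == pytest.approx(2.5)
        assert got["high_risk"] == ["s2", "s3"]

    def test_odd_ties_to_low(self):
        model = RiskModel(["g"], [1.0])
        records = [rec(i, 10.0, 1, g=float(i + 1)) for i in range(3)]
        got = dichotomize(records, model)
        assert got["high_risk"] == ["s2"] and "s1" in got["low_risk"]

    def test_constant_scores_rejected(self):
        model = RiskModel(["g"], [1.0])
        records = [rec(i, 10.0, 1, g=1.0) for i in range(4)]
        with pytest.raises(ValueError, match="non-informative"):
            dichotomize(records, model)


class TestKaplanMeier:
    def test_two_deaths(self):
        curve = km_estimate([rec(0, 1.0, 1), rec(1, 2.0, 1)]).set_index("time")
        assert curve.loc[0.0, "survival"] == 1.0
        assert curve.loc[1.0, "survival"] == pytest.approx(0.5)
        assert curve.loc[2.0, "survival"] == pytest.approx(0.0)

    def test_censoring_freezes_curve(self):
        curve = km_estimate([rec(0, 1.0, 1), rec(1, 2.0, 0)]).set_index("time")
        assert curve.loc[2.0, "survival"] == pytest.approx(0.5)

    def test_matches_risk_set_oracle_and_is_monotone(self, rng):
        times = rng.exponential(5.0, size=40).round(1) + 0.1
        events = rng.integers(0, 2, size=40)
        records = [rec(i, float(t), int(e)) for i, (t, e) in enumerate(zip(times, events))]
        curve = km_estimate(records)
        oracle = km_by_risk_sets(times, events)
        for t, s in zip(curve["time"], curve["survival"]):
            assert s == pytest.approx(oracle[float(t)], abs=1e-9)
        assert (np.diff(curve["survival"]) <= 1e-12).all()

    def test_no_censoring_equals_empirical_survival(self, rng):
        times = rng.exponential(3.0, size=60)
        records = [rec(i, float(t), 1) for i, t in enumerate(times)]
        curve = km_estimate(records)
        for t, s in zip(curve["time"], curve["survival"]):
            if t == 0:
                continue
            assert s == pytest.approx(np.mean(times > t), abs=1e-9)


class TestLogrank:
    def test_identical_groups(self, rng):
        grp = [rec(i, float(t), 1) for i, t in enumerate(rng.exponential(2, 20))]
        res = logrank(grp, list(grp))
        assert res["statistic"] == pytest.approx(0.0, abs=1e-9)
        assert res["p"] == pytest.approx(1.0)

    def test_label_swap_invariance_and_hand_formula(self, rng):
        a = [rec(i, float(t), int(e)) for i, (t, e) in enumerate(
            zip(rng.exponential(2, 10), rng.integers(0, 2, 10)))]
        b = [rec(100 + i, float(t), int(e)) for i, (t, e) in enumerate(
            zip(rng.exponential(4, 10), np.ones(10, int)))]
        ab, ba = logrank(a, b), logrank(b, a)
        assert ab["statistic"] == pytest.approx(ba["statistic"])
        hand = logrank_by_hand(
            [r.time for r in a], [r.event for r in a],
            [r.time for r in b], [r.event for r in b],
        )
        assert ab["statistic"] == pytest.approx(hand, rel=1e-6)

    def test_no_events_rejected(self):
        with pytest.raises(ValueError, match="event"):
            logrank([rec(0, 1.0, 0)], [rec(1, 2.0, 0)])

    def test_power_against_planted_hazard_ratio(self):
        rng = np.random.default_rng(17)
        wins = 0
        for _ in range(100):
            a = [rec(i, float(rng.exponential(1.0)) + 1e-6, 1) for i in range(100)]
            b = [rec(200 + i, float(rng.exponential(3.0)) + 1e-6, 1) for i in range(100)]
            if logrank(a, b)["p"] < 0.05:
                wins += 1
        assert wins >= 90


class TestSubtypeMarkers:
    def test_classification_rule(self, rng):
        records = simulate_cohort(rng, n=200, beta=-0.8, subtype="GS")
        table = subtype_markers(records, ["g"], subtypes=("GS",))
        assert not table.empty
        assert (table["class"] == "Protective").all()

    def test_insufficient_events_skips_subtype(self, rng):
        records = [rec(i, 5.0, 0, "EBV", g=float(rng.standard_normal())) for i in range(20)]
        table = subtype_markers(records, ["g"], subtypes=("EBV",))
        assert table.empty

    def test_threshold_excludes(self, rng):
        records = simulate_cohort(rng, n=200, beta=0.8, subtype="CIN")
        table = subtype_markers(records, ["g"], subtypes=("CIN",), p_threshold=1e-300)
        assert table.empty
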