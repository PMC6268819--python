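"""Docking logistic-regression classifier: fitting, selection, ROC, domain."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats

from cypcons import dlr


def _sim_logit(rng, n, betas, intercept=-1.0):
    X = pd.DataFrame(rng.normal(size=(n, len(betas))), columns=[f"c{i}" for i in range(len(betas))])
    eta = intercept + X.to_numpy() @ np.asarray(betas)
    y = rng.random(n) < 1 / (1 + np.exp(-eta))
    return X, np.where(y, "P", "W")


class TestStandardize:
    def test_population_of_training_stats(self):
        m = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [0.0, 2.0, 4.0]})
        z, stats_ = dlr.standardize(m)
        assert np.allclose(z.mean(), 0, atol=1e-12)
        assert np.allclose(z.std(ddof=1), 1, atol=1e-12)

    def test_apply_time_reuses_training_stats(self):
        train = pd.DataFrame({"a": [1.0, 2.0, 3.0]})
        _, stats_ = dlr.standardize(train)
        z, _ = dlr.standardize(pd.DataFrame({"a": [2.0]}), stats_)
        assert z.iloc[0, 0] == pytest.approx(0.0)

    def test_constant_column_rejected_by_name(self):
        m = pd.DataFrame({"ok": [1.0, 2.0], "flat": [3.0, 3.0]})
        with pytest.raises(ValueError, match="flat"):
            dlr.standardize(m)

    def test_idempotent_on_training_matrix(self, rng):
        m = pd.DataFrame(rng.normal(2, 5, size=(50, 4)), columns=list("abcd"))
        z1, st1 = dlr.standardize(m)
        z2, _ = dlr.standardize(z1)
        assert np.allclose(z1.to_numpy(), z2.to_numpy(), atol=1e-9)


class TestFitLogistic:
    def test_symmetric_data_zero_intercept(self):
        x = pd.DataFrame({"c": [-2.0, -1.0, 1.0, 2.0] * 10})
        y = np.where(x["c"] > 0, "P", "W")
        m = dlr.fit_logistic(x, y)
        assert abs(m.intercept) < 0.5  # symmetry up to separation flattening

    def test_brute_force_likelihood_oracle(self, rng):
        # 2 columns, n=40: compare against direct NLL minimization
        X, y = _sim_logit(rng, 40, [0.8, -0.5])
        m = dlr.fit_logistic(X, y)
        yb = (np.asarray(y) == "P").astype(float)
        Xd = np.column_stack([np.ones(len(X)), X.to_numpy()])

        def nll(b):
            eta = Xd @ b
            return np.sum(np.log1p(np.exp(eta)) - yb * eta)

        res = optimize.minimize(nll, np.zeros(3), method="BFGS", options={"gtol": 1e-10})
        got = np.array([m.intercept, *m.coef.to_numpy()])
        assert np.allclose(got, res.x, atol=1e-4)

    def test_parameter_recovery_within_3se(self):
        rng = np.random.default_rng(202)
        betas = [1.2, -0.7, 0.4]
        X, y = _sim_logit(rng, 2000, betas, intercept=-0.8)
        m = dlr.fit_logistic(X, y)
        for c, b in zip(m.columns, betas):
            assert abs(m.coef[c] - b) < 3 * m.se[c]
        assert abs(m.intercept + 0.8) < 3 * m.se["intercept"]

    def test_wald_identity_on_printed_intercept(self):
        m = dlr.published_model()
        assert (m.coef["surflex.1W0F.catalytic"] / m.se["surflex.1W0F.catalytic"]) ** 2 == pytest.approx(
            float(m.wald_chi2["surflex.1W0F.catalytic"]), abs=0.05
        )
        assert (m.intercept / m.se["intercept"]) ** 2 == pytest.approx(25.88, abs=0.01)

    def test_overparameterized_warns(self, rng):
        X, y = _sim_logit(rng, 30, [0.5] * 20)
        with pytest.warns(UserWarning, match="1-in-20"):
            dlr.fit_logistic(X, y)


class TestSelection:
    def test_forward_picks_informative_column_first(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            X = pd.DataFrame(rng.normal(size=(500, 10)), columns=[f"c{i}" for i in range(10)])
            eta = -1.0 + 1.2 * X["c0"]
            y = np.where(rng.random(500) < 1 / (1 + np.exp(-eta)), "P", "W")
            m = dlr.select_stepwise(X, y, "forward")
            hits += bool(m.columns) and m.columns[0] == "c0"
        assert hits >= 19

    def test_forward_noise_type_i_rate(self):
        total = 0
        for seed in range(30):
            rng = np.random.default_rng(1000 + seed)
            X = pd.DataFrame(rng.normal(size=(300, 10)), columns=[f"c{i}" for i in range(10)])
            y = np.where(rng.random(300) < 0.3, "P", "W")
            total += len(dlr.select_stepwise(X, y, "forward").columns)
        # ~alpha false entries per column: expected ~0.5 per run
        assert total / 30 < 1.5

    def test_backward_retains_informative(self):
        rng = np.random.default_rng(7)
        X = pd.DataFrame(rng.normal(size=(500, 6)), columns=[f"c{i}" for i in range(6)])
        eta = -1.0 + 1.5 * X["c2"]
        y = np.where(rng.random(500) < 1 / (1 + np.exp(-eta)), "P", "W")
        m = dlr.select_stepwise(X, y, "backward")
        assert "c2" in m.columns

    def test_manual_keeps_significant_and_tops_up(self):
        # six modestly informative columns + one weaker: the strictly
        # significant set alone may sit under the AUC floor, and the manual
        # rule may only supplement from the relaxed band
        rng = np.random.default_rng(42)
        n = 200
        X = pd.DataFrame(rng.normal(size=(n, 10)), columns=[f"c{i}" for i in range(10)])
        eta = -1.2 + 0.55 * X[[f"c{i}" for i in range(6)]].sum(axis=1) + 0.3 * X["c6"]
        y = np.where(rng.random(n) < 1 / (1 + np.exp(-eta)), "P", "W")
        full = dlr.fit_logistic(X, y)
        sig = {c for c in X.columns if full.p_values[c] <= 0.05}
        m = dlr.select_manual(X, y)
        assert sig.issubset(set(m.columns))
        extras = set(m.columns) - sig
        assert all(0.05 < full.p_values[c] < 0.10 for c in extras)
        assert (m.auc_train is not None and m.auc_train > 0.8) or m.flags

    def test_manual_all_significant_equals_full(self):
        rng = np.random.default_rng(3)
        X = pd.DataFrame(rng.normal(size=(800, 3)), columns=list("abc"))
        eta = -0.5 + 1.0 * X["a"] + 1.0 * X["b"] - 1.0 * X["c"]
        y = np.where(rng.random(800) < 1 / (1 + np.exp(-eta)), "P", "W")
        m = dlr.select_manual(X, y)
        assert set(m.columns) == set("abc")

    def test_manual_unreachable_floor_flagged(self, rng):
        X = pd.DataFrame(rng.normal(size=(200, 5)), columns=[f"c{i}" for i in range(5)])
        y = np.where(rng.random(200) < 0.3, "P", "W")
        m = dlr.select_manual(X, y)
        assert m.flags  # floor not reached on pure noise


class TestRoc:
    def test_perfect_separation_auc_one(self):
        scores = np.r_[np.full(10, 0.9), np.full(10, 0.1)]
        labels = ["P"] * 10 + ["W"] * 10
        assert dlr.roc(scores, labels).auc == pytest.approx(1.0)

    def test_random_scores_auc_half(self):
        rng = np.random.default_rng(5)
        scores = rng.random(4000)
        labels = np.where(rng.random(4000) < 0.5, "P", "W")
        assert dlr.roc(scores, labels).auc == pytest.approx(0.5, abs=0.05)

    def test_auc_equals_mann_whitney(self, rng):
        scores = np.round(rng.random(300), 2)  # force ties
        labels = np.where(rng.random(300) < 0.3, "P", "W")
        curve = dlr.roc(scores, labels)
        pos = scores[labels == "P"]
        neg = scores[labels == "W"]
        u, _ = stats.mannwhitneyu(pos, neg, alternative="two-sided")
        assert curve.auc == pytest.approx(u / (len(pos) * len(neg)), abs=1e-12)

    def test_sensitivity_non_increasing_in_cutoff(self, rng):
        scores = rng.random(100)
        labels = np.where(rng.random(100) < 0.4, "P", "W")
        curve = dlr.roc(scores, labels)
        assert np.all(np.diff(curve.sensitivity) <= 1e-12)

    def test_named_points_manual_model_pattern(self):
        # confusion counts 14/33 potent, 88/88 weak at the max-accuracy cutoff
        scores = np.r_[np.full(14, 0.9), np.full(19, 0.2), np.full(88, 0.25)]
        labels = ["P"] * 33 + ["W"] * 88
        curve = dlr.roc(scores, labels)
        b = curve.points["B"]
        assert b["specificity"] == pytest.approx(1.00)
        assert b["sensitivity"] == pytest.approx(14 / 33, abs=0.01)
        assert b["accuracy"] == pytest.approx((14 + 88) / 121, abs=0.005)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            dlr.roc([0.1, 0.9], ["P", "P"])


class TestScoring:
    def test_printed_intercept_probability(self):
        m = dlr.published_model()
        row = pd.Series(0.0, index=m.columns)
        p, call = dlr.score_probability(m, row)
        assert p == pytest.approx(0.141, abs=0.001)
        assert call == "W"

    def test_unit_surflex_score(self):
        m = dlr.published_model()
        row = pd.Series(0.0, index=m.columns)
        row["surflex.1W0F.catalytic"] = 1.0
        p, call = dlr.score_probability(m, row)
        assert p == pytest.approx(0.977, abs=0.001)
        assert call == "P"

    def test_probability_in_open_interval(self, rng):
        m = dlr.published_model()
        row = pd.Series(rng.normal(size=len(m.columns)), index=m.columns)
        p, _ = dlr.score_probability(m, row)
        assert 0.0 < p < 1.0

    def test_missing_column_rejected(self):
        m = dlr.published_model()
        with pytest.raises(ValueError, match="lacks"):
            dlr.score_probability(m, pd.Series({"bogus": 1.0}))

    def test_model_json_round_trip(self, tmp_path):
        m = dlr.published_model()
        m.to_json(tmp_path / "m.json")
        back = dlr.LogisticModel.from_json(tmp_path / "m.json")
        assert back.columns == m.columns
        assert back.intercept == m.intercept
        assert np.allclose(back.coef.to_numpy(), m.coef.to_numpy())


class TestTruncateDomain:
    def test_training_fixture_high_band(self, training_frame):
        inside, outside = dlr.truncate_domain(training_frame["mw"])
        assert len(inside) == 39
        kept = training_frame.loc[inside]
        assert (kept["category"] == "P").sum() == 18
        assert (kept["category"] == "W").sum() == 21

    def test_propofol_excluded(self, training_frame):
        _, outside = dlr.truncate_domain(training_frame["mw"])
        assert "propofol" in outside

    def test_empty_domain_is_error(self):
        with pytest.raises(ValueError, match="empty"):
            dlr.truncate_domain(pd.Series({"a": 100.0, "b": 200.0}))
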