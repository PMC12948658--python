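"""Group-comparison models, shadow-feature selection, BC-bootstrap mediation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import emomap as em
from emomap.inference import (CONFIRMED, REJECTED, TENTATIVE,
                              _bc_interval, binomial_decisions)


def repeated_measures_frame(rng, n_per_group=30, group_shift=0.0,
                            emotion_effect=0.0, subject_sd=1.0, resid_sd=1.0):
    """Long score frame: 3 emotions x 2 groups with subject intercepts."""
    rows = []
    pid = 0
    for group in ("autistic", "non-autistic"):
        for _ in range(n_per_group):
            pid += 1
            intercept = rng.normal(0, subject_sd)
            shift = group_shift if group == "autistic" else 0.0
            age = rng.uniform(18, 60)
            sex = rng.choice(["female", "male"])
            for k, emotion in enumerate(("angry", "happy", "sad")):
                y = (10 + intercept + shift + emotion_effect * k
                     + rng.normal(0, resid_sd))
                rows.append(dict(participant=f"s{pid}", group=group,
                                 emotion=emotion, score=y, age=age, sex=sex))
    return pd.DataFrame(rows)


class TestCompareGroups:
    def test_detects_planted_within_effect(self):
        rng = np.random.default_rng(0)
        frame = repeated_measures_frame(rng, emotion_effect=1.0)
        out = em.compare_groups(frame, "score", within_factor="emotion",
                                covariates=["age", "sex"])
        within = out.set_index("term").loc["emotion"]
        assert within["p"] < 1e-6
        assert within["df_num"] == 2

    def test_interaction_df_matches_design(self):
        rng = np.random.default_rng(1)
        frame = repeated_measures_frame(rng, n_per_group=20)
        out = em.compare_groups(frame, "score", within_factor="emotion")
        inter = out.set_index("term").loc["emotion:group"]
        assert inter["df_num"] == 2
        # residual df = N*3 - N - 2 - 2 for N subjects
        assert inter["df_den"] == 40 * 3 - 40 - 2 - 2

    def test_power_for_moderate_group_shift(self):
        """A 1-within-subject-sd group shift at n=55/group is detected with
        power > 0.8."""
        hits = 0
        reps = 60
        for seed in range(reps):
            rng = np.random.default_rng(1000 + seed)
            frame = repeated_measures_frame(rng, n_per_group=55,
                                            group_shift=1.0)
            out = em.compare_groups(frame, "score", within_factor="emotion",
                                    covariates=["age", "sex"])
            hits += out.set_index("term").loc["group", "p"] < 0.05
        assert hits / reps > 0.8

    def test_constant_outcome_flagged_degenerate(self):
        rng = np.random.default_rng(2)
        frame = repeated_measures_frame(rng, n_per_group=5)
        frame["score"] = 3.0
        out = em.compare_groups(frame, "score", within_factor="emotion",
                                covariates=["age"])
        assert (out["stratum"] == "degenerate").all()
        assert (out["F"] == 0).all() and (out["p"] == 1).all()

    def test_missing_columns_and_cells_rejected(self):
        rng = np.random.default_rng(3)
        frame = repeated_measures_frame(rng, n_per_group=5)
        with pytest.raises(ValueError, match="missing columns"):
            em.compare_groups(frame, "nope")
        frame.loc[0, "score"] = np.nan
        with pytest.raises(ValueError, match="completeness"):
            em.compare_groups(frame, "score")


class TestRankRegression:
    def test_detects_monotone_predictor(self):
        rng = np.random.default_rng(4)
        n = 120
        x = rng.normal(size=n)
        frame = pd.DataFrame(dict(
            y=np.exp(x) + rng.normal(0, 0.3, n),      # monotone, non-linear
            x=x, z=rng.normal(size=n),
            g=rng.choice(["a", "b"], n)))
        out = em.rank_regression(frame, "y", ["x", "z", "g"])
        tx = out.set_index("term").loc["x"]
        assert tx["p"] < 1e-8
        assert out.set_index("term").loc["z", "p"] > 0.01


class TestBinomialDecisions:
    @pytest.mark.parametrize("hits,trials,n_tests,expected", [
        (15, 15, 1, CONFIRMED),     # p = 2*0.5^15 ~ 6.1e-5
        (0, 15, 1, REJECTED),
        (10, 15, 1, TENTATIVE),     # p ~ 0.30
        (15, 15, 200, TENTATIVE),   # Bonferroni kills it
        (19, 20, 10, CONFIRMED),    # p ~ 4.0e-5, corrected 4.0e-4 < 0.01
        (0, 0, 1, TENTATIVE),
    ])
    def test_hand_computed_table(self, hits, trials, n_tests, expected):
        assert binomial_decisions(hits, trials, 0.01, n_tests) == expected


class TestBorutaSelector:
    def test_injected_importances_follow_binomial_rule(self, monkeypatch):
        """With deterministic importances (feature 0 always above the
        shadow max, feature 1 always below), decisions match the binomial
        table exactly."""
        import emomap.inference as inf

        def fake_importance(est, X_test, y_test, rng, n_repeats):
            # >= 5 shadow columns always trail the real block, so the
            # shadow max is 0.1 regardless of the live-feature count
            imp = np.full(X_test.shape[1], 0.1)
            imp[0] = 1.0                # feature 0 beats the shadow max
            imp[1:3] = 0.0              # features 1-2 never beat it
            return imp

        monkeypatch.setattr(inf, "_oos_permutation_importance",
                            fake_importance)

        class NoFit:
            def fit(self, X, y):
                return self

            def predict(self, X):
                return np.zeros(len(X))

            def get_params(self, deep=True):
                return {}

            def set_params(self, **kw):
                return self

        rng = np.random.default_rng(0)
        X = rng.normal(size=(40, 3))
        y = rng.normal(size=40)
        sel = em.BorutaSelector(estimator=NoFit(), n_iter=30,
                                alpha=0.01, random_state=0).fit(X, y)
        assert sel.decisions_["x0"] == CONFIRMED
        assert sel.decisions_["x1"] == REJECTED
        assert sel.decisions_["x2"] == REJECTED
        # decision point: smallest t with 2 * 0.5^t * m < alpha
        # (m=2 undecided after x0 confirms alone at its own threshold)
        assert sel.hits_[0] == sel.trials_[0]
        assert sel.hits_[1] == 0

    def test_planted_linear_predictor_confirmed(self):
        rng = np.random.default_rng(11)
        n = 120
        X = rng.normal(size=(n, 6))
        y = 2.0 * X[:, 0] + rng.normal(0, 0.5, n)
        sel = em.BorutaSelector(n_iter=40, random_state=1).fit(X, y)
        assert sel.decisions_["x0"] == CONFIRMED
        rejected = [f for f, d in sel.decisions_.items() if d == REJECTED]
        assert len(rejected) >= 4
        assert sel.support_.sum() == 1

    def test_all_noise_rarely_confirms(self):
        confirmed = 0
        for seed in range(10):
            rng = np.random.default_rng(300 + seed)
            X = rng.normal(size=(80, 8))
            y = rng.normal(size=80)
            sel = em.BorutaSelector(n_iter=25, random_state=seed).fit(X, y)
            confirmed += sel.support_.sum() > 0
        assert confirmed <= 1

    def test_histories_consistent(self):
        rng = np.random.default_rng(12)
        X = rng.normal(size=(60, 4))
        y = X[:, 1] + rng.normal(0, 0.5, 60)
        sel = em.BorutaSelector(n_iter=30, random_state=2).fit(X, y)
        assert sel.importance_history_.shape == (sel.n_iter_, 4)
        assert len(sel.shadow_max_history_) == sel.n_iter_
        decisions = set(sel.decisions_.values())
        assert decisions <= {CONFIRMED, TENTATIVE, REJECTED}

    def test_argument_validation(self):
        X = np.random.default_rng(0).normal(size=(30, 3))
        with pytest.raises(ValueError, match="n_iter"):
            em.BorutaSelector(n_iter=10).fit(X, X[:, 0])
        with pytest.raises(ValueError, match="constant"):
            em.BorutaSelector(n_iter=20).fit(X, np.ones(30))
        with pytest.raises(ValueError, match="2 features"):
            em.BorutaSelector(n_iter=20).fit(X[:, :1], X[:, 0])


def mediation_dataset(rng, n=500, a=0.5, b=0.5, c_prime=0.0):
    x = rng.normal(size=n)
    m = a * x + rng.normal(size=n)
    y = b * m + c_prime * x + rng.normal(size=n)
    return pd.DataFrame(dict(x=x, m=m, y=y))


class TestMediation:
    def test_recovers_planted_indirect_effect(self):
        rng = np.random.default_rng(0)
        df = mediation_dataset(rng)
        rep = em.mediate_bc_bootstrap(df, "x", "m", "y", B=2000, seed=1)
        ind = rep.paths["indirect"]
        assert ind.estimate == pytest.approx(0.25, abs=0.05)
        assert ind.significant
        assert rep.B == 2000 and rep.n == 500

    def test_total_effect_identity(self):
        rng = np.random.default_rng(1)
        df = mediation_dataset(rng, n=200, c_prime=0.3)
        med = em.Mediation("x", "m", "y", B=10, random_state=0).fit(df)
        # in-sample OLS identity for nested linear models
        assert med.total_ == pytest.approx(med.c_prime_ + med.indirect_,
                                           abs=1e-10)

    def test_matches_statsmodels_point_estimates(self):
        import statsmodels.api as sm
        from statsmodels.stats.mediation import Mediation as SmMediation

        rng = np.random.default_rng(2)
        df = mediation_dataset(rng, n=300)
        med = em.Mediation("x", "m", "y", B=10, random_state=0).fit(df)
        outcome = sm.OLS.from_formula("y ~ m + x", df)
        mediator = sm.OLS.from_formula("m ~ x", df)
        sm_fit = SmMediation(outcome, mediator, "x", "m").fit(
            n_rep=50, method="parametric")
        sm_ind = sm_fit.ACME_avg.mean() if hasattr(sm_fit, "ACME_avg") else \
            sm_fit.summary().loc["ACME (average)", "Estimate"]
        assert med.indirect_ == pytest.approx(sm_ind, abs=0.02)

    def test_bootstrap_determinism(self):
        rng = np.random.default_rng(3)
        df = mediation_dataset(rng, n=150)
        r1 = em.mediate_bc_bootstrap(df, "x", "m", "y", B=500, seed=42)
        r2 = em.mediate_bc_bootstrap(df, "x", "m", "y", B=500, seed=42)
        for k in r1.paths:
            assert r1.paths[k].ci_low == r2.paths[k].ci_low
            assert r1.paths[k].ci_high == r2.paths[k].ci_high

    def test_covariates_enter_both_equations(self):
        rng = np.random.default_rng(4)
        n = 400
        z = rng.normal(size=n)             # confounder of x and m
        x = z + rng.normal(size=n)
        m = z + rng.normal(size=n)         # no true x -> m path
        y = m + rng.normal(size=n)
        df = pd.DataFrame(dict(x=x, m=m, y=y, z=z))
        adj = em.Mediation("x", "m", "y", covariates=["z"], B=10,
                           random_state=0).fit(df)
        unadj = em.Mediation("x", "m", "y", B=10, random_state=0).fit(df)
        assert abs(adj.a_) < 0.15 < abs(unadj.a_)

    def test_argument_validation(self):
        rng = np.random.default_rng(5)
        df = mediation_dataset(rng, n=50)
        with pytest.raises(ValueError, match="B"):
            em.Mediation("x", "m", "y", B=0).fit(df)
        bad = df.assign(m=1.0)
        with pytest.raises(ValueError, match="mediator"):
            em.Mediation("x", "m", "y", B=10).fit(bad)
        dup = df.assign(z1=df["x"], z2=df["x"])
        with pytest.raises(ValueError, match="collinear"):
            em.Mediation("x", "m", "y", covariates=["z1", "z2"],
                         B=10).fit(dup)
        with pytest.raises(ValueError, match="incomplete"):
            em.Mediation("x", "m", "y", B=10).fit(
                df.assign(x=np.where(df.index == 0, np.nan, df["x"])))

    def test_bc_interval_shifts_with_skew(self):
        rng = np.random.default_rng(6)
        boots = rng.chisquare(3, size=5000)
        point = 3.5                     # most replicates below the point
        lo, hi = _bc_interval(point, boots)
        plo, phi = np.quantile(boots, [0.025, 0.975])
        assert lo > plo and hi > phi    # BC pushes both endpoints up
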