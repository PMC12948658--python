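"""Inference layer: group comparisons, shadow-feature selection, mediation.

Three re-implemented procedures:

* :func:`compare_groups` — repeated-measures group comparison. The
  random-intercept mixed model is approximated by two fixed-effects strata:
  within-subject terms (the repeated factor and its interaction with group)
  are tested in an OLS model with subject fixed effects absorbed, and
  between-subject terms (group, covariates) are tested on subject-mean
  outcomes. For balanced designs the within-stratum F tests coincide with
  the mixed-model ANOVA.
* :class:`BorutaSelector` — all-relevant feature selection. Each iteration
  appends an independently permuted ("shadow") copy of every live feature,
  fits a random-forest regressor, and scores a *hit* for a real feature
  whose out-of-sample permutation importance exceeds the iteration's shadow
  maximum. A two-sided binomial test (Bonferroni-corrected over undecided
  features) turns accumulated hits into confirmed / rejected / tentative
  decisions; rejected features leave the live pool.
* :class:`Mediation` — product-of-coefficients mediation with
  bias-corrected (BC) bootstrap confidence intervals: a (predictor ->
  mediator), b (mediator -> outcome | predictor, covariates), direct c',
  indirect a*b; CI endpoints at percentiles Phi(2 z0 +/- 1.96) with
  z0 = Phi^{-1}(fraction of bootstrap replicates below the point estimate).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, clone
from sklearn.ensemble import RandomForestRegressor
from sklearn.feature_selection import SelectorMixin
from sklearn.metrics import r2_score
from sklearn.model_selection import train_test_split
from sklearn.utils.validation import check_is_fitted
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm


# ------------------------------------------------------------ group models

def _term(col: str, frame: pd.DataFrame) -> str:
    return f"C(Q('{col}'))" if not pd.api.types.is_numeric_dtype(frame[col]) \
        else f"Q('{col}')"


def compare_groups(frame: pd.DataFrame, outcome: str,
                   within_factor: str | None = None, covariates=(),
                   group: str = "group", subject: str = "participant"
                   ) -> pd.DataFrame:
    """F tests for group, the within factor, their interaction and covariates.

    Returns one row per term with columns ``term, stratum, F, df_num,
    df_den, p``. A constant outcome is flagged (zero F, p = 1).
    """
    covariates = list(covariates)
    required = [subject, group, outcome] + covariates \
        + ([within_factor] if within_factor else [])
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise ValueError(f"missing columns: {missing}")
    if frame[required].isna().any().any():
        raise ValueError("missing cells; run a completeness pass first")

    if np.ptp(frame[outcome].to_numpy(dtype=float)) == 0:
        terms = [group] + covariates + \
            ([within_factor, f"{within_factor}:{group}"] if within_factor else [])
        return pd.DataFrame([dict(term=t, stratum="degenerate", F=0.0,
                                  df_num=np.nan, df_den=np.nan, p=1.0)
                             for t in terms])

    rows = []
    # between-subject stratum: covariate-adjusted model on subject means
    agg = {outcome: "mean", group: "first"}
    agg.update({c: "first" for c in covariates})
    between = frame.groupby(subject, as_index=False).agg(agg)
    terms = [f"C(Q('{group}'))"] + [_term(c, between) for c in covariates]
    fit = smf.ols(f"Q('{outcome}') ~ " + " + ".join(terms), between).fit()
    tbl = anova_lm(fit, typ=2)
    labels = [group] + covariates
    for label, term in zip(labels, terms):
        r = tbl.loc[term]
        rows.append(dict(term=label, stratum="between", F=float(r["F"]),
                         df_num=float(r["df"]),
                         df_den=float(tbl.loc["Residual", "df"]),
                         p=float(r["PR(>F)"])))

    if within_factor is not None:
        w = f"C(Q('{within_factor}'))"
        g = f"C(Q('{group}'))"
        s = f"C(Q('{subject}'))"
        base = f"Q('{outcome}') ~ {s}"
        m0 = smf.ols(base, frame).fit()
        m1 = smf.ols(f"{base} + {w}", frame).fit()
        m2 = smf.ols(f"{base} + {w} + {w}:{g}", frame).fit()
        # nested-model F tests against the full model's residual; the group
        # main effect is absorbed by the subject dummies, so the added
        # interaction rank is exactly (levels-1) x (groups-1)
        mse = m2.ssr / m2.df_resid
        for label, small, big in ((within_factor, m0, m1),
                                  (f"{within_factor}:{group}", m1, m2)):
            df_num = small.df_resid - big.df_resid
            F = ((small.ssr - big.ssr) / df_num) / mse
            rows.append(dict(term=label, stratum="within", F=float(F),
                             df_num=float(df_num),
                             df_den=float(m2.df_resid),
                             p=float(stats.f.sf(F, df_num, m2.df_resid))))
    return pd.DataFrame(rows)


def rank_regression(frame: pd.DataFrame, outcome: str, predictors=()
                    ) -> pd.DataFrame:
    """Rank-transformed least squares (non-parametric regression fallback).

    The outcome and all numeric predictors are replaced by their ranks;
    non-numeric predictors are dummy-coded. Returns per-term t statistics.
    """
    df = frame[[outcome, *predictors]].copy()
    if df.isna().any().any():
        raise ValueError("missing values in regression frame")
    y = stats.rankdata(df[outcome].to_numpy(dtype=float))
    X = pd.DataFrame(index=df.index)
    for col in predictors:
        if pd.api.types.is_numeric_dtype(df[col]):
            X[col] = stats.rankdata(df[col].to_numpy(dtype=float))
        else:
            dummies = pd.get_dummies(df[col], prefix=col, drop_first=True)
            X = pd.concat([X, dummies.astype(float)], axis=1)
    fit = sm.OLS(y, sm.add_constant(X)).fit()
    out = pd.DataFrame(dict(term=fit.params.index, estimate=fit.params.values,
                            t=fit.tvalues.values, p=fit.pvalues.values,
                            df=fit.df_resid))
    return out[out["term"] != "const"].reset_index(drop=True)


def ols_anova(frame: pd.DataFrame, outcome: str, predictors=()
              ) -> pd.DataFrame:
    """Type II F tests of an ordinary least-squares model, one row per term."""
    terms = [_term(c, frame) for c in predictors]
    fit = smf.ols(f"Q('{outcome}') ~ " + " + ".join(terms), frame).fit()
    tbl = anova_lm(fit, typ=2)
    rows = []
    for label, term in zip(predictors, terms):
        r = tbl.loc[term]
        rows.append(dict(term=label, F=float(r["F"]), df_num=float(r["df"]),
                         df_den=float(tbl.loc["Residual", "df"]),
                         p=float(r["PR(>F)"])))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------- Boruta

CONFIRMED, TENTATIVE, REJECTED = "confirmed", "tentative", "rejected"


def binomial_decisions(hits: int, trials: int, alpha: float,
                       n_tests: int) -> str:
    """Two-sided binomial decision against hit probability 0.5.

    Bonferroni-corrected over ``n_tests`` simultaneously undecided features:
    significantly more hits than misses -> confirmed, significantly fewer ->
    rejected, otherwise tentative.
    """
    if trials == 0:
        return TENTATIVE
    p = stats.binomtest(hits, trials, 0.5).pvalue
    if p * n_tests < alpha:
        return CONFIRMED if hits > trials / 2 else REJECTED
    return TENTATIVE


def _oos_permutation_importance(est, X_test, y_test, rng, n_repeats):
    # single batched predict over all column permutations: per-call model
    # overhead dwarfs the arithmetic at these matrix sizes
    n, p = X_test.shape
    blocks = [X_test]
    for j in range(p):
        for _ in range(n_repeats):
            Xp = X_test.copy()
            Xp[:, j] = rng.permutation(Xp[:, j])
            blocks.append(Xp)
    preds = est.predict(np.vstack(blocks))
    base = r2_score(y_test, preds[:n])
    imp = np.empty(p)
    for j in range(p):
        start = n * (1 + j * n_repeats)
        drops = [base - r2_score(y_test, preds[start + r * n:start + (r + 1) * n])
                 for r in range(n_repeats)]
        imp[j] = np.mean(drops)
    return imp


class BorutaSelector(SelectorMixin, BaseEstimator):
    """All-relevant feature selection against shadow-feature importances.

    Parameters
    ----------
    estimator : regressor fit each iteration (default
        ``RandomForestRegressor(n_estimators=100, min_samples_leaf=10)``).
    n_iter : maximum iterations (>= 20); stops early once every feature is
        decided.
    alpha : level of the two-sided binomial decision test (Bonferroni
        corrected over undecided features).
    test_size : held-out fraction used for out-of-sample permutation
        importance.
    n_repeats : permutation repeats per column when scoring importance.
    random_state : seed controlling shadows, splits and the forest.

    Attributes
    ----------
    decisions_ : dict feature name -> confirmed | tentative | rejected.
    hits_, trials_ : per-feature hit counts and test counts.
    importance_history_ : (n_iter_, n_features) array, NaN once rejected.
    shadow_max_history_ : per-iteration shadow maximum.
    support_ : confirmed mask; ``support_weak_`` additionally tentative.
    """

    def __init__(self, estimator=None, n_iter: int = 100, alpha: float = 0.01,
                 test_size: float = 1 / 3, n_repeats: int = 3,
                 random_state: int | None = None):
        self.estimator = estimator
        self.n_iter = n_iter
        self.alpha = alpha
        self.test_size = test_size
        self.n_repeats = n_repeats
        self.random_state = random_state

    def fit(self, X, y):
        if self.n_iter < 20:
            raise ValueError("n_iter must be >= 20")
        if isinstance(X, pd.DataFrame):
            names = list(X.columns)
            X = X.to_numpy(dtype=float)
        else:
            X = np.asarray(X, dtype=float)
            names = [f"x{j}" for j in range(X.shape[1])]
        y = np.asarray(y, dtype=float)
        if X.shape[1] < 2:
            raise ValueError("need at least 2 features")
        if np.ptp(y) == 0:
            raise ValueError("constant outcome")
        n_feat = X.shape[1]
        rng = np.random.default_rng(self.random_state)
        # regularised leaves keep weak chance correlations from holding
        # features in the tentative band indefinitely at small n
        base_est = self.estimator if self.estimator is not None else \
            RandomForestRegressor(n_estimators=100, min_samples_leaf=10)

        status = np.array([TENTATIVE] * n_feat, dtype=object)
        hits = np.zeros(n_feat, dtype=int)
        trials = np.zeros(n_feat, dtype=int)
        imp_hist, shadow_hist = [], []

        for _ in range(self.n_iter):
            live = np.flatnonzero(status != REJECTED)
            X_live = X[:, live]
            # pad to >= 5 shadows so the shadow max stays a meaningful
            # null reference once most features are rejected
            n_shadow = max(len(live), 5)
            shadows = np.column_stack(
                [rng.permutation(X_live[:, j % len(live)])
                 for j in range(n_shadow)])
            X_aug = np.hstack([X_live, shadows])
            X_tr, X_te, y_tr, y_te = train_test_split(
                X_aug, y, test_size=self.test_size,
                random_state=int(rng.integers(2 ** 31)))
            est = clone(base_est)
            if "random_state" in est.get_params():
                est.set_params(random_state=int(rng.integers(2 ** 31)))
            est.fit(X_tr, y_tr)
            imp = _oos_permutation_importance(est, X_te, y_te, rng,
                                              self.n_repeats)
            real, shadow = imp[:len(live)], imp[len(live):]
            shadow_max = float(shadow.max())
            shadow_hist.append(shadow_max)
            row = np.full(n_feat, np.nan)
            row[live] = real
            imp_hist.append(row)

            undecided = status == TENTATIVE
            for k, j in enumerate(live):
                if undecided[j]:
                    trials[j] += 1
                    hits[j] += real[k] > shadow_max
            n_tests = max(1, int(undecided.sum()))
            for j in np.flatnonzero(undecided):
                status[j] = binomial_decisions(int(hits[j]), int(trials[j]),
                                               self.alpha, n_tests)
            if not (status == TENTATIVE).any():
                break

        self.feature_names_in_ = np.asarray(names, dtype=object)
        self.n_features_in_ = n_feat
        self.decisions_ = dict(zip(names, status))
        self.hits_, self.trials_ = hits, trials
        self.importance_history_ = np.vstack(imp_hist)
        self.shadow_max_history_ = np.asarray(shadow_hist)
        self.n_iter_ = len(shadow_hist)
        self.support_ = status == CONFIRMED
        self.support_weak_ = (status == CONFIRMED) | (status == TENTATIVE)
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "support_")
        return self.support_


def boruta_select(features: pd.DataFrame, outcome, n_iter: int = 100,
                  alpha: float = 0.01, seed: int | None = None
                  ) -> BorutaSelector:
    """Functional wrapper over :class:`BorutaSelector`."""
    return BorutaSelector(n_iter=n_iter, alpha=alpha,
                          random_state=seed).fit(features, outcome)


# -------------------------------------------------------------- mediation

@dataclass
class PathEstimate:
    estimate: float
    ci_low: float
    ci_high: float

    @property
    def significant(self) -> bool:
        return not (self.ci_low <= 0.0 <= self.ci_high)


@dataclass
class MediationReport:
    paths: dict = field(default_factory=dict)   # a, b, c_prime, indirect, total
    n: int = 0
    B: int = 0
    seed: int | None = None


def _bc_interval(point: float, boots: np.ndarray, level: float = 0.95
                 ) -> tuple[float, float]:
    B = len(boots)
    prop = np.clip((boots < point).mean(), 1 / (B + 1), 1 - 1 / (B + 1))
    z0 = stats.norm.ppf(prop)
    zc = stats.norm.ppf(0.5 + level / 2)
    lo, hi = stats.norm.cdf(2 * z0 - zc), stats.norm.cdf(2 * z0 + zc)
    return (float(np.quantile(boots, lo)), float(np.quantile(boots, hi)))


def _batched_ols(X: np.ndarray, y: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Coefficients for OLS refit on each bootstrap index row of ``idx``."""
    Xb, yb = X[idx], y[idx]                       # (B, n, k), (B, n)
    G = np.einsum("bni,bnj->bij", Xb, Xb)
    c = np.einsum("bni,bn->bi", Xb, yb)
    try:
        return np.linalg.solve(G, c[..., None])[..., 0]
    except np.linalg.LinAlgError:
        return np.einsum("bij,bj->bi", np.linalg.pinv(G), c)


class Mediation(BaseEstimator):
    """Product-of-coefficients mediation with BC bootstrap intervals.

    Two least-squares regressions give the path estimates
    (mediator ~ predictor + covariates; outcome ~ mediator + predictor +
    covariates); participants are resampled with replacement ``B`` times and
    bias-corrected 95% intervals are formed for a, b, c', the indirect
    effect a*b and the total effect.
    """

    def __init__(self, predictor: str, mediator: str, outcome: str,
                 covariates=(), B: int = 2000, level: float = 0.95,
                 random_state: int | None = None):
        self.predictor = predictor
        self.mediator = mediator
        self.outcome = outcome
        self.covariates = tuple(covariates)
        self.B = B
        self.level = level
        self.random_state = random_state

    def fit(self, data: pd.DataFrame, y=None):
        if self.B < 1:
            raise ValueError("B must be >= 1")
        cols = [self.predictor, self.mediator, self.outcome,
                *self.covariates]
        df = data[cols]
        if df.isna().any().any():
            raise ValueError("incomplete cases in mediation frame")
        x = df[self.predictor].to_numpy(dtype=float)
        m = df[self.mediator].to_numpy(dtype=float)
        yv = df[self.outcome].to_numpy(dtype=float)
        Z = df[list(self.covariates)].to_numpy(dtype=float) \
            if self.covariates else np.empty((len(df), 0))
        if np.ptp(m) == 0:
            raise ValueError("zero-variance mediator")
        n = len(df)
        ones = np.ones((n, 1))
        Xm = np.hstack([ones, x[:, None], Z])
        Xy = np.hstack([ones, m[:, None], x[:, None], Z])
        Xt = Xm  # total-effect design: outcome ~ predictor + covariates
        if np.linalg.matrix_rank(Xy) < Xy.shape[1]:
            raise ValueError("collinear design (covariates aliased)")

        coef_m = np.linalg.lstsq(Xm, m, rcond=None)[0]
        coef_y = np.linalg.lstsq(Xy, yv, rcond=None)[0]
        coef_t = np.linalg.lstsq(Xt, yv, rcond=None)[0]
        a, b, c_prime, total = (coef_m[1], coef_y[1], coef_y[2], coef_t[1])

        rng = np.random.default_rng(self.random_state)
        idx = rng.integers(0, n, size=(self.B, n))
        a_b = _batched_ols(Xm, m, idx)[:, 1]
        by = _batched_ols(Xy, yv, idx)
        b_b, cp_b = by[:, 1], by[:, 2]
        t_b = _batched_ols(Xt, yv, idx)[:, 1]

        points = dict(a=a, b=b, c_prime=c_prime, indirect=a * b, total=total)
        boots = dict(a=a_b, b=b_b, c_prime=cp_b, indirect=a_b * b_b,
                     total=t_b)
        paths = {k: PathEstimate(float(points[k]),
                                 *_bc_interval(points[k], boots[k],
                                               self.level))
                 for k in points}
        self.a_, self.b_, self.c_prime_ = float(a), float(b), float(c_prime)
        self.indirect_, self.total_ = float(a * b), float(total)
        self.boot_indirect_ = boots["indirect"]
        self.report_ = MediationReport(paths=paths, n=n, B=self.B,
                                       seed=self.random_state)
        return self


def mediate_bc_bootstrap(frame: pd.DataFrame, predictor: str, mediator: str,
                         outcome: str, covariates=(), B: int = 2000,
                         seed: int | None = None) -> MediationReport:
    """Functional wrapper over :class:`Mediation`."""
    med = Mediation(predictor, mediator, outcome, covariates, B=B,
                    random_state=seed).fit(frame)
    return med.report_
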