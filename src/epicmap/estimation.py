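"""Model-development battery: designs, OLS, upper-censored Tobit, two-part.

The mapping algorithms are developed by regressing observed EQ5D utilities
on EPIC scores (plus optional demographics/clinical covariates) under three
functional forms chosen for a ceiling-inflated outcome:

* **OLS** — the conventional direct-mapping baseline.
* **Tobit** — the observed utility is an upper-censored (at 1) version of a
  latent normal outcome whose mean is linear in the covariates; estimated
  by maximum likelihood with the scale parameterised as ``log(sigma)``.
  statsmodels ships no Tobit, so the censored-normal likelihood, analytic
  gradient and Wald machinery are implemented here.
* **Two-part** — a logistic model for the probability of being at the
  ceiling (full health) and an OLS model for utilities strictly below it;
  predictions recombine as ``p * ceiling + (1 - p) * yhat2``.

Estimators follow the scikit-learn protocol (``fit``/``predict``,
``get_params``, trailing-underscore fitted attributes) so they compose with
sklearn model selection; the module-level ``fit_*`` functions are thin
wrappers returning a :class:`FitResult`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.optimize
import scipy.special
import scipy.stats
import statsmodels.api as sm
from sklearn.base import BaseEstimator, RegressorMixin
from statsmodels.tools import numdiff

from .instruments import DOMAIN_COLUMNS, SUBDOMAIN_COLUMNS

__all__ = [
    "EstimationError",
    "SingularityError",
    "DesignSpec",
    "DesignData",
    "FitResult",
    "build_design_matrix",
    "OLSRegressor",
    "TobitRegressor",
    "TwoPartRegressor",
    "ForwardStepwise",
    "fit_ols",
    "fit_tobit",
    "predict_tobit",
    "fit_two_part",
    "stepwise_forward",
    "make_estimator",
    "to_mapping_model",
]

TOBIT_POLICIES = ("latent", "censored_expectation", "truncate_at_1")


class EstimationError(ValueError):
    """Raised when a model cannot be estimated on the data provided."""


class SingularityError(EstimationError):
    """Raised for rank-deficient design matrices; names the collinear columns."""


# ---------------------------------------------------------------------------
# design specification and matrix construction
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DesignSpec:
    """One model specification: which regressors enter, and how.

    ``group`` encodes the available data: odd groups use the four EPIC
    domains, even groups the ten sub-domains; groups 3-4 add age and race,
    groups 5-6 additionally Zubrod and the PSA category. ``score_powers``
    and ``age_powers`` request literal polynomial columns of the 0-100
    scores / age in years; ``interactions`` requests score x race and/or
    score x Zubrod product columns.
    """

    group: int
    score_powers: tuple[int, ...] = (1,)
    age_powers: tuple[int, ...] = (1,)
    interactions: tuple[str, ...] = ()
    label: str = ""

    def __post_init__(self):
        if self.group not in range(1, 7):
            raise ValueError(f"group must be in 1..6, got {self.group}")
        if not self.score_powers or not set(self.score_powers) <= {1, 2, 3}:
            raise ValueError("score_powers must be a non-empty subset of {1,2,3}")
        if not set(self.age_powers) <= {1, 2, 3}:
            raise ValueError("age_powers must be a subset of {1,2,3}")
        if not set(self.interactions) <= {"race", "zubrod"}:
            raise ValueError("interactions must be a subset of {'race','zubrod'}")
        if self.group <= 2 and self.interactions:
            raise ValueError("groups 1-2 admit no demographic/clinical interactions")
        if self.group <= 4 and "zubrod" in self.interactions:
            raise ValueError("zubrod interactions require group 5 or 6")

    @property
    def score_columns(self) -> tuple[str, ...]:
        return DOMAIN_COLUMNS if self.group % 2 == 1 else SUBDOMAIN_COLUMNS

    def columns(self) -> list[tuple[str, tuple[str, ...]]]:
        """Canonical (column name, variable product) list, in order:
        score powers, age powers, race, zubrod, psa, then interactions."""
        cols: list[tuple[str, tuple[str, ...]]] = []
        for power in sorted(self.score_powers):
            for score in self.score_columns:
                name = score if power == 1 else f"{score}_p{power}"
                cols.append((name, (score,) * power))
        if self.group >= 3:
            for power in sorted(self.age_powers):
                name = "age" if power == 1 else f"age_p{power}"
                cols.append((name, ("age",) * power))
            cols.append(("race_other", ("race_other",)))
        if self.group >= 5:
            cols.append(("zubrod", ("zubrod",)))
        if "race" in self.interactions:
            for score in self.score_columns:
                cols.append((f"{score}_x_race_other", (score, "race_other")))
        if "zubrod" in self.interactions:
            for score in self.score_columns:
                cols.append((f"{score}_x_zubrod", (score, "zubrod")))
        if self.group >= 5:
            cols.append(("psa_ge4", ("psa_ge4",)))
        return cols

    @property
    def required_inputs(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for _, variables in self.columns():
            for v in variables:
                seen.setdefault(v)
        return tuple(seen)


@dataclass
class DesignData:
    """A built design: regressor matrix, response, and exclusion accounting."""

    X: pd.DataFrame
    y: pd.Series | None
    n_dropped: int
    dropped_index: list
    spec: DesignSpec

    @property
    def n(self) -> int:
        return len(self.X)


def build_design_matrix(
    records: pd.DataFrame,
    spec: DesignSpec,
    response: str = "eq5d",
    require_response: bool | None = None,
) -> DesignData:
    """Build the regressor matrix and response for one specification.

    Polynomial columns are literal powers of the 0-100 scores / age in
    years (no centering); interaction columns are elementwise products.
    Records missing any required input (or the response, when present or
    required) are dropped and counted — the complete-case rule.
    """
    needed = list(spec.required_inputs)
    missing_cols = [c for c in needed if c not in records.columns]
    if missing_cols:
        raise EstimationError(
            f"input table lacks required column(s) {missing_cols} for group {spec.group}"
        )
    if require_response is None:
        require_response = response in records.columns
    if require_response and response not in records.columns:
        raise EstimationError(f"response column {response!r} absent from the table")

    check = needed + ([response] if require_response else [])
    usable = records[check].notna().all(axis=1)
    dropped_index = list(records.index[~usable])
    data = records.loc[usable]
    if len(data) == 0:
        raise EstimationError("no usable records after complete-case exclusions")

    X = pd.DataFrame(index=data.index)
    parents: dict[str, tuple[str, ...]] = {}
    for name, variables in spec.columns():
        col = np.ones(len(data))
        for v in variables:
            col = col * data[v].to_numpy(dtype=float)
        X[name] = col
        if len(variables) > 1 and len(set(variables)) > 1:
            parents[name] = tuple(dict.fromkeys(variables))
    X.attrs["variables"] = dict(spec.columns())
    X.attrs["parents"] = parents
    y = data[response].astype(float) if require_response else None
    return DesignData(X=X, y=y, n_dropped=len(dropped_index), dropped_index=dropped_index, spec=spec)


# ---------------------------------------------------------------------------
# shared helpers
# ---------------------------------------------------------------------------


def _as_frame(X) -> pd.DataFrame:
    if isinstance(X, pd.DataFrame):
        frame = X
    else:
        arr = np.atleast_2d(np.asarray(X, dtype=float))
        frame = pd.DataFrame(arr, columns=[f"x{i}" for i in range(arr.shape[1])])
    values = frame.to_numpy(dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("design matrix contains non-finite values")
    return frame


def _check_rank(X1: np.ndarray, names: Sequence[str]) -> None:
    """Raise SingularityError naming collinear columns of [const | X]."""
    rank = np.linalg.matrix_rank(X1)
    if rank >= X1.shape[1]:
        return
    _, _, pivots = scipy.linalg.qr(X1, mode="economic", pivoting=True)
    all_names = ["const", *names]
    collinear = sorted(all_names[j] for j in pivots[rank:])
    raise SingularityError(
        f"design matrix is rank deficient (rank {rank} < {X1.shape[1]}); "
        f"collinear column(s): {collinear}"
    )


def _ordered_X(frame: pd.DataFrame, feature_names: Sequence[str]) -> np.ndarray:
    missing = [c for c in feature_names if c not in frame.columns]
    if missing:
        raise KeyError(f"prediction data lacks fitted column(s) {missing}")
    return frame[list(feature_names)].to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# OLS
# ---------------------------------------------------------------------------


class OLSRegressor(RegressorMixin, BaseEstimator):
    """Ordinary least squares with an always-fitted intercept.

    Backed by statsmodels for inference (t-test p-values feed stepwise
    selection). ``sigma_`` is the maximum-likelihood residual scale
    ``sqrt(SSR / n)`` — the root-mean-square residual, not the unbiased
    variant — so the censoring-free Tobit reduction is exact.
    """

    def fit(self, X, y):
        frame = _as_frame(X)
        y = np.asarray(y, dtype=float)
        if len(frame) != len(y):
            raise ValueError("X and y lengths differ")
        if len(frame) <= frame.shape[1]:
            raise EstimationError(
                f"need more rows ({len(frame)}) than regressors+intercept ({frame.shape[1] + 1})"
            )
        X1 = sm.add_constant(frame.to_numpy(dtype=float), has_constant="add")
        _check_rank(X1, list(frame.columns))
        res = sm.OLS(y, X1).fit()
        self.feature_names_in_ = np.asarray(frame.columns, dtype=object)
        self.intercept_ = float(res.params[0])
        self.coef_ = np.asarray(res.params[1:], dtype=float)
        self.sigma_ = float(np.sqrt(res.ssr / len(y)))
        self.loglik_ = float(res.llf)
        self.pvalues_ = pd.Series(res.pvalues, index=["const", *frame.columns])
        self.bse_ = pd.Series(res.bse, index=["const", *frame.columns])
        self.n_obs_ = len(y)
        self.converged_ = True
        self.results_ = res
        return self

    def predict(self, X):
        frame = _as_frame(X)
        Xo = _ordered_X(frame, self.feature_names_in_)
        return self.intercept_ + Xo @ self.coef_


# ---------------------------------------------------------------------------
# upper-censored Tobit
# ---------------------------------------------------------------------------


def _tobit_negloglik_and_grad(theta, X1, y, cens, upper):
    beta, log_sigma = theta[:-1], theta[-1]
    sigma = np.exp(log_sigma)
    mu = X1 @ beta
    n = len(y)
    grad_mu = np.empty(n)
    ll = 0.0
    unc = ~cens
    if unc.any():
        z = (y[unc] - mu[unc]) / sigma
        ll += np.sum(-np.log(sigma) + scipy.stats.norm.logpdf(z))
        grad_mu[unc] = z / sigma
        dlog_sigma_unc = np.sum(-1.0 + z**2)
    else:
        dlog_sigma_unc = 0.0
    if cens.any():
        a = (mu[cens] - upper) / sigma  # log P(Y* >= upper) = log Phi(a)
        log_cdf = scipy.special.log_ndtr(a)
        ll += np.sum(log_cdf)
        ratio = np.exp(scipy.stats.norm.logpdf(a) - log_cdf)  # phi/Phi, stable
        grad_mu[cens] = ratio / sigma
        dlog_sigma_cens = np.sum(-ratio * a)
    else:
        dlog_sigma_cens = 0.0
    grad_beta = X1.T @ grad_mu
    grad = np.append(grad_beta, dlog_sigma_unc + dlog_sigma_cens)
    return -ll, -grad


class TobitRegressor(RegressorMixin, BaseEstimator):
    """Maximum-likelihood linear regression upper-censored at ``upper``.

    The latent outcome is normal with mean ``intercept + X @ beta`` and
    scale ``sigma``; observations recorded exactly at ``upper`` contribute
    the upper-tail probability to the likelihood, all others the normal
    density. Optimisation is over ``(beta, log sigma)`` (keeps sigma
    positive) with the analytic gradient; standard errors come from the
    numerically differentiated Hessian at the optimum.

    Prediction policies
    -------------------
    ``latent``
        the latent mean ``X @ beta``, unbounded.
    ``truncate_at_1``
        ``min(latent, upper)`` — the default, giving a hard ceiling.
    ``censored_expectation``
        ``E[min(Y*, upper)]`` in closed form under the fitted normal.
    """

    def __init__(self, upper: float = 1.0, policy: str = "truncate_at_1", max_iter: int = 500):
        self.upper = upper
        self.policy = policy
        self.max_iter = max_iter

    def fit(self, X, y):
        if self.policy not in TOBIT_POLICIES:
            raise ValueError(f"unknown policy {self.policy!r}; choose from {TOBIT_POLICIES}")
        frame = _as_frame(X)
        y = np.asarray(y, dtype=float)
        # censoring is recorded as exact equality with the bound (the tariff
        # returns exactly 1.0 only for full health)
        cens = y == self.upper
        if cens.all():
            raise EstimationError(
                "all observations are censored at the upper bound; "
                "the Tobit mean and scale are unidentified"
            )
        X1 = sm.add_constant(frame.to_numpy(dtype=float), has_constant="add")
        _check_rank(X1, list(frame.columns))
        names = ["const", *frame.columns]
        self.feature_names_in_ = np.asarray(frame.columns, dtype=object)
        self.n_censored_ = int(cens.sum())
        self.n_obs_ = len(y)

        # OLS start values (exact solution when nothing is censored)
        beta0, *_ = np.linalg.lstsq(X1, y, rcond=None)
        resid = y - X1 @ beta0
        sigma0 = float(np.sqrt(np.mean(resid**2)))
        if not cens.any():
            self.intercept_ = float(beta0[0])
            self.coef_ = np.asarray(beta0[1:], dtype=float)
            self.sigma_ = sigma0
            self.loglik_ = float(np.sum(scipy.stats.norm.logpdf(resid, scale=sigma0)))
            self.converged_ = True
            cov = None
        else:
            theta0 = np.append(beta0, np.log(max(sigma0, 1e-6)))
            result = scipy.optimize.minimize(
                _tobit_negloglik_and_grad,
                theta0,
                args=(X1, y, cens, self.upper),
                jac=True,
                method="BFGS",
                options={"maxiter": self.max_iter, "gtol": 1e-8},
            )
            # BFGS can stall on precision loss while already at the optimum;
            # accept if the gradient is small, otherwise flag and withhold.
            grad_ok = np.max(np.abs(result.jac)) < 1e-3 * max(1.0, abs(result.fun))
            self.converged_ = bool(result.success or grad_ok)
            if not self.converged_:
                self.optimizer_message_ = result.message
                return self
            theta = result.x
            self.intercept_ = float(theta[0])
            self.coef_ = np.asarray(theta[1:-1], dtype=float)
            self.sigma_ = float(np.exp(theta[-1]))
            self.loglik_ = float(-result.fun)
            hess = numdiff.approx_hess(
                theta, lambda t: _tobit_negloglik_and_grad(t, X1, y, cens, self.upper)[0]
            )
            try:
                cov = np.linalg.inv(hess)
            except np.linalg.LinAlgError:
                cov = None
        if cov is not None:
            bse = np.sqrt(np.clip(np.diag(cov)[:-1], 0, None))
        else:  # censoring-free reduction: OLS standard errors
            res = sm.OLS(y, X1).fit()
            bse = np.asarray(res.bse, dtype=float)
        self.bse_ = pd.Series(bse, index=names)
        params = np.append(self.intercept_, self.coef_)
        with np.errstate(divide="ignore", invalid="ignore"):
            zvals = params / np.where(bse > 0, bse, np.nan)
        self.pvalues_ = pd.Series(2 * scipy.stats.norm.sf(np.abs(zvals)), index=names)
        return self

    def _latent(self, X) -> np.ndarray:
        if not getattr(self, "converged_", False):
            raise EstimationError("Tobit fit did not converge; predictions withheld")
        frame = _as_frame(X)
        Xo = _ordered_X(frame, self.feature_names_in_)
        return self.intercept_ + Xo @ self.coef_

    def predict(self, X, policy: str | None = None) -> np.ndarray:
        policy = self.policy if policy is None else policy
        if policy not in TOBIT_POLICIES:
            raise ValueError(f"unknown policy {policy!r}; choose from {TOBIT_POLICIES}")
        mu = self._latent(X)
        if policy == "latent":
            return mu
        if policy == "truncate_at_1":
            return np.minimum(mu, self.upper)
        alpha = (self.upper - mu) / self.sigma_
        Phi = scipy.stats.norm.cdf(alpha)
        phi = scipy.stats.norm.pdf(alpha)
        return mu * Phi - self.sigma_ * phi + self.upper * (1.0 - Phi)


# ---------------------------------------------------------------------------
# two-part model
# ---------------------------------------------------------------------------


class TwoPartRegressor(RegressorMixin, BaseEstimator):
    """Logistic ceiling-probability part + OLS sub-ceiling part.

    Part 1 is a logistic regression on the indicator ``y == ceiling``
    (exact equality: the tariff returns exactly 1.0 only for full health);
    part 2 is OLS on the strict subset ``y < ceiling``. The combined
    prediction is the unconditional expectation
    ``p * ceiling + (1 - p) * yhat2``.

    Degenerate data with no ceiling observations is handled (``p == 0``,
    predictions equal part 2); perfectly separated part-1 data is flagged
    through ``part1_converged_`` rather than raised.
    """

    def __init__(self, ceiling: float = 1.0, max_iter: int = 200):
        self.ceiling = ceiling
        self.max_iter = max_iter

    def fit(self, X, y):
        frame = _as_frame(X)
        y = np.asarray(y, dtype=float)
        at_ceiling = y == self.ceiling
        below = y < self.ceiling
        if np.any(y > self.ceiling):
            raise EstimationError("observations above the ceiling are not representable")
        if below.sum() == 0:
            raise EstimationError(
                "part 2 (below-ceiling OLS) has no observations: all responses at the ceiling"
            )
        y2 = y[below]
        if len(np.unique(y2)) < 2:
            raise EstimationError("part 2 (below-ceiling OLS) has < 2 distinct outcome values")

        X1 = sm.add_constant(frame.to_numpy(dtype=float), has_constant="add")
        _check_rank(X1, list(frame.columns))
        names = ["const", *frame.columns]
        self.feature_names_in_ = np.asarray(frame.columns, dtype=object)

        if at_ceiling.any():
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                try:
                    logit_res = sm.Logit(at_ceiling.astype(float), X1).fit(
                        disp=0, maxiter=self.max_iter
                    )
                    self.part1_converged_ = bool(logit_res.mle_retvals.get("converged", True))
                except Exception:
                    # Newton refuses perfectly separated data; refit with
                    # BFGS for usable (if divergent) coefficients and flag
                    logit_res = sm.Logit(at_ceiling.astype(float), X1).fit(
                        disp=0, method="bfgs", maxiter=self.max_iter
                    )
                    self.part1_converged_ = False
            self.part1_params_ = pd.Series(np.asarray(logit_res.params), index=names)
            self.part1_pvalues_ = pd.Series(np.asarray(logit_res.pvalues), index=names)
            self.part1_results_ = logit_res
        else:  # p identically zero
            self.part1_params_ = None
            self.part1_pvalues_ = None
            self.part1_results_ = None
            self.part1_converged_ = True

        if below.sum() <= frame.shape[1]:
            raise EstimationError(
                "part 2 (below-ceiling OLS) has fewer rows than regressors+intercept"
            )
        ols_res = sm.OLS(y2, X1[below]).fit()
        self.part2_params_ = pd.Series(np.asarray(ols_res.params), index=names)
        self.part2_pvalues_ = pd.Series(np.asarray(ols_res.pvalues), index=names)
        self.part2_sigma_ = float(np.sqrt(ols_res.ssr / below.sum()))
        self.part2_results_ = ols_res
        # feature-wise p-value for stepwise entry: smallest across the parts
        if self.part1_pvalues_ is not None:
            self.pvalues_ = pd.concat(
                [self.part1_pvalues_, self.part2_pvalues_], axis=1
            ).min(axis=1)
        else:
            self.pvalues_ = self.part2_pvalues_.copy()
        self.converged_ = self.part1_converged_
        self.n_obs_ = len(y)
        return self

    def predict_ceiling_probability(self, X) -> np.ndarray:
        frame = _as_frame(X)
        n = len(frame)
        if self.part1_params_ is None:
            return np.zeros(n)
        X1 = np.column_stack(
            [np.ones(n), _ordered_X(frame, self.feature_names_in_)]
        )
        return scipy.special.expit(X1 @ self.part1_params_.to_numpy())

    def predict_below_ceiling(self, X) -> np.ndarray:
        frame = _as_frame(X)
        X1 = np.column_stack(
            [np.ones(len(frame)), _ordered_X(frame, self.feature_names_in_)]
        )
        return X1 @ self.part2_params_.to_numpy()

    def predict(self, X) -> np.ndarray:
        p = self.predict_ceiling_probability(X)
        return p * self.ceiling + (1.0 - p) * self.predict_below_ceiling(X)


# ---------------------------------------------------------------------------
# forward stepwise selection
# ---------------------------------------------------------------------------


def make_estimator(form: str, **kwargs):
    """Estimator factory for a functional form name."""
    if form == "ols":
        return OLSRegressor(**kwargs)
    if form == "tobit":
        return TobitRegressor(**kwargs)
    if form == "two_part":
        return TwoPartRegressor(**kwargs)
    raise ValueError(f"unknown functional form {form!r}")


class ForwardStepwise(BaseEstimator):
    """Forward stepwise regressor selection with entry/stay thresholds.

    At each step the candidate with the smallest entry p-value below
    ``sle`` joins the model; after every addition, included regressors
    whose p-values exceed ``slstay`` are removed (worst first). Entry
    p-values are the t-test (OLS) or Wald test (Tobit; for two-part, the
    smaller of the two parts' Wald/t p-values) of the candidate's
    coefficient in the enlarged model. Ties break by the candidate pool's
    canonical column order, so selection is deterministic.

    With ``hierarchy=True`` (weak hierarchy) a product column may enter
    only while both its parent columns are included, and leaves when a
    parent leaves; parentage is read from ``X.attrs['parents']`` (set by
    :func:`build_design_matrix`) or the ``parents`` argument.
    """

    def __init__(
        self,
        form: str = "ols",
        sle: float = 0.25,
        slstay: float = 0.25,
        hierarchy: bool = True,
        max_steps: int = 200,
        estimator_kwargs: dict | None = None,
    ):
        self.form = form
        self.sle = sle
        self.slstay = slstay
        self.hierarchy = hierarchy
        self.max_steps = max_steps
        self.estimator_kwargs = estimator_kwargs

    def _new_estimator(self):
        return make_estimator(self.form, **(self.estimator_kwargs or {}))

    def _pvalue(self, est, name: str) -> float:
        p = est.pvalues_.get(name, np.nan)
        return 1.0 if not np.isfinite(p) else float(p)

    def fit(self, X, y, parents: Mapping[str, tuple[str, ...]] | None = None):
        frame = _as_frame(X)
        if parents is None:
            parents = frame.attrs.get("parents", {}) if hasattr(frame, "attrs") else {}
        candidates = list(frame.columns)
        included: list[str] = []
        history: list[tuple[str, str, float]] = []

        def eligible(name: str) -> bool:
            if not self.hierarchy or name not in parents:
                return True
            return all(parent in included for parent in parents[name])

        for _ in range(self.max_steps):
            best_name, best_p = None, np.inf
            for name in candidates:
                if name in included or not eligible(name):
                    continue
                try:
                    est = self._new_estimator().fit(frame[included + [name]], y)
                except EstimationError:
                    continue
                if not getattr(est, "converged_", True):
                    continue
                p = self._pvalue(est, name)
                if p < best_p - 1e-15:  # strict improvement; ties keep earlier column
                    best_name, best_p = name, p
            if best_name is None or best_p >= self.sle:
                break
            included.append(best_name)
            history.append(("enter", best_name, best_p))
            # backward sweep at slstay
            while included:
                est = self._new_estimator().fit(frame[included], y)
                pvals = {name: self._pvalue(est, name) for name in included}
                worst = max(pvals, key=lambda k: (pvals[k], -included.index(k)))
                if pvals[worst] <= self.slstay:
                    break
                included.remove(worst)
                history.append(("remove", worst, pvals[worst]))
                # weak hierarchy: children of a removed parent leave too
                for name in list(included):
                    if self.hierarchy and name in parents and not eligible(name):
                        included.remove(name)
                        history.append(("remove", name, np.nan))

        self.selected_ = list(included)
        self.history_ = history
        if included:
            self.estimator_ = self._new_estimator().fit(frame[included], y)
        else:  # intercept-only model
            ones = pd.DataFrame(index=frame.index)
            est = self._new_estimator()
            if self.form == "ols":
                y_arr = np.asarray(y, dtype=float)
                est.feature_names_in_ = np.asarray([], dtype=object)
                est.intercept_ = float(np.mean(y_arr))
                est.coef_ = np.asarray([], dtype=float)
                est.sigma_ = float(np.std(y_arr))
                est.pvalues_ = pd.Series(dtype=float)
                est.converged_ = True
                est.n_obs_ = len(y_arr)
            else:
                est.fit(pd.DataFrame(np.empty((len(frame), 0))), y)
            self.estimator_ = est
        return self

    def predict(self, X):
        frame = _as_frame(X)
        if not self.selected_:
            return np.full(len(frame), self.estimator_.intercept_)
        return self.estimator_.predict(frame[self.selected_])


# ---------------------------------------------------------------------------
# FitResult wrappers
# ---------------------------------------------------------------------------


@dataclass
class FitResult:
    """Portable summary of one fitted functional form on one design."""

    coefficients: dict[str, float]
    scale_sigma: float | None
    loglik: float | None
    n_used: int
    converged: bool
    form: str
    part1_coefficients: dict[str, float] | None = None
    pvalues: dict[str, float] | None = None
    bse: dict[str, float] | None = None
    selected: list[str] | None = None
    n_censored: int | None = None


def _series_dict(series) -> dict[str, float] | None:
    return None if series is None else {str(k): float(v) for k, v in series.items()}


def _result_from(est, form: str) -> FitResult:
    if not getattr(est, "converged_", False) and not hasattr(est, "coef_"):
        return FitResult(
            coefficients={}, scale_sigma=None, loglik=None,
            n_used=getattr(est, "n_obs_", 0), converged=False, form=form,
        )
    if form == "two_part":
        return FitResult(
            coefficients=_series_dict(est.part2_params_),
            scale_sigma=est.part2_sigma_,
            loglik=None,
            n_used=est.n_obs_,
            converged=est.converged_,
            form=form,
            part1_coefficients=_series_dict(est.part1_params_),
            pvalues=_series_dict(est.pvalues_),
        )
    coefficients = {"const": est.intercept_}
    coefficients.update(dict(zip(est.feature_names_in_, est.coef_)))
    return FitResult(
        coefficients=coefficients,
        scale_sigma=est.sigma_,
        loglik=getattr(est, "loglik_", None),
        n_used=est.n_obs_,
        converged=est.converged_,
        form=form,
        pvalues=_series_dict(getattr(est, "pvalues_", None)),
        bse=_series_dict(getattr(est, "bse_", None)),
        n_censored=getattr(est, "n_censored_", None),
    )


def fit_ols(X, y) -> FitResult:
    """Least-squares fit; coefficients equal the normal-equation solution."""
    return _result_from(OLSRegressor().fit(X, y), "ols")


def fit_tobit(X, y, upper_censor: float = 1.0, max_iter: int = 500) -> FitResult:
    """Censored-normal MLE with upper censoring at ``upper_censor``."""
    return _result_from(TobitRegressor(upper=upper_censor, max_iter=max_iter).fit(X, y), "tobit")


def predict_tobit(fit, X, policy: str = "truncate_at_1") -> np.ndarray:
    """Predictions from a fitted Tobit (estimator or FitResult) under a policy."""
    if isinstance(fit, TobitRegressor):
        return fit.predict(X, policy=policy)
    if not fit.converged:
        raise EstimationError("Tobit fit did not converge; predictions withheld")
    if policy not in TOBIT_POLICIES:
        raise ValueError(f"unknown policy {policy!r}; choose from {TOBIT_POLICIES}")
    frame = _as_frame(X)
    names = [k for k in fit.coefficients if k != "const"]
    mu = fit.coefficients["const"] + _ordered_X(frame, names) @ np.array(
        [fit.coefficients[k] for k in names]
    )
    if policy == "latent":
        return mu
    if policy == "truncate_at_1":
        return np.minimum(mu, 1.0)
    sigma = fit.scale_sigma
    alpha = (1.0 - mu) / sigma
    Phi, phi = scipy.stats.norm.cdf(alpha), scipy.stats.norm.pdf(alpha)
    return mu * Phi - sigma * phi + 1.0 * (1.0 - Phi)


def fit_two_part(X, y, ceiling: float = 1.0) -> FitResult:
    """Logistic ceiling part + below-ceiling OLS part."""
    return _result_from(TwoPartRegressor(ceiling=ceiling).fit(X, y), "two_part")


def stepwise_forward(
    X, y, form: str = "ols", sle: float = 0.25, slstay: float = 0.25, hierarchy: bool = True
) -> tuple[FitResult, list[str]]:
    """Forward stepwise selection; returns the final fit and selected columns."""
    selector = ForwardStepwise(form=form, sle=sle, slstay=slstay, hierarchy=hierarchy).fit(X, y)
    result = _result_from(selector.estimator_, form)
    result.selected = selector.selected_
    return result, selector.selected_


def to_mapping_model(
    est_or_result,
    name: str,
    group: int,
    form: str,
    variables: Mapping[str, tuple[str, ...]],
    selected: Sequence[str] | None = None,
):
    """Convert a fitted estimator / FitResult to a portable MappingModel.

    ``variables`` maps design-column names to the variable products they
    were built from (``X.attrs['variables']``). Two-part fits carry their
    logistic part alongside the linear part.
    """
    from .mapping import MappingModel, Term

    result = est_or_result if isinstance(est_or_result, FitResult) else _result_from(est_or_result, form)
    if not result.converged and not result.coefficients:
        raise EstimationError("cannot export an unconverged fit")

    def terms_of(coefs: Mapping[str, float]) -> tuple[float, tuple]:
        intercept = float(coefs.get("const", 0.0))
        terms = tuple(
            Term(float(v), tuple(variables[k]))
            for k, v in coefs.items()
            if k != "const"
        )
        return intercept, terms

    intercept, terms = terms_of(result.coefficients)
    part1_intercept, part1_terms = (None, ())
    if form == "two_part" and result.part1_coefficients is not None:
        part1_intercept, part1_terms = terms_of(result.part1_coefficients)
    return MappingModel(
        name=name,
        group=group,
        form=form,
        intercept=intercept,
        terms=terms,
        part1_intercept=part1_intercept,
        part1_terms=part1_terms,
    )
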