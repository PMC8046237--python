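"""Synthetic trial-cohort generation.

The estimation machinery needs cohorts with the statistical signature of a
low-risk prostate-cancer trial population:

* a **ceiling-inflated, bimodal utility**: a point mass of patients in full
  health (utility exactly 1) plus a continuous component peaking near 0.8
  and bounded below by the worst observed state;
* **0-100 EPIC scores** with strong ceiling behaviour of their own and
  prescribed means/SDs per domain and sub-domain;
* prescribed **Pearson correlations** between the utility and every EPIC
  score, strongest for the hormonal scales and weakest for the sexual ones;
* trial-like demographics (age ~ 66, mostly Zubrod 0, ~80% PSA >= 4).

A Gaussian copula ties the margins together. The utility margin is a
mixture quantile map (point mass at 1 with weight ``p_ceiling``, otherwise
a Beta rescaled to ``[floor, 1)`` whose two moments are solved from the
overall utility mean/SD). Each EPIC margin is a *censored* normal on
[0, 100] — clipping puts realistic point masses at the scale ends and,
unlike a truncated normal, can reach the large SDs of the sexual scales —
with (mu, sigma) solved so the censored mean/SD hit their targets exactly
in population. Latent copula correlations are calibrated by root-finding
on a fixed quasi-reference panel so the *observed* Pearson correlations hit
their targets; score-score latent correlations are not reported anywhere
and default to 0.4 within the instrument (a documented assumption).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.stats
from scipy.special import ndtr, ndtri

__all__ = [
    "CohortParams",
    "LinearTruthParams",
    "CohortSimulator",
    "ParameterError",
    "generate_cohort",
    "generate_linear_truth",
]


class ParameterError(ValueError):
    """Raised when generator parameters are infeasible."""


#: (column, mean, sd) targets for the estimation cohort
DOMAIN_MARGINALS = (
    ("epic_urinary", 87.5, 12.1),
    ("epic_bowel", 93.4, 9.3),
    ("epic_sexual", 49.6, 26.3),
    ("epic_hormonal", 91.0, 11.0),
)
SUBDOMAIN_MARGINALS = (
    ("epic_uf", 93.3, 10.7),
    ("epic_ub", 84.0, 14.8),
    ("epic_uirr", 86.8, 12.6),
    ("epic_uinc", 91.6, 14.0),
    ("epic_bf", 93.2, 8.5),
    ("epic_bb", 94.6, 9.6),
    ("epic_sf", 43.7, 26.9),
    ("epic_sb", 64.0, 32.9),
    ("epic_hf", 88.7, 13.6),
    ("epic_hb", 93.0, 10.3),
)
#: observed-scale Pearson targets between utility and each score
CORRELATION_TARGETS = (
    ("epic_urinary", 0.38),
    ("epic_bowel", 0.34),
    ("epic_sexual", 0.18),
    ("epic_hormonal", 0.55),
    ("epic_uf", 0.31),
    ("epic_ub", 0.36),
    ("epic_uirr", 0.36),
    ("epic_uinc", 0.27),
    ("epic_bf", 0.30),
    ("epic_bb", 0.32),
    ("epic_sf", 0.17),
    ("epic_sb", 0.16),
    ("epic_hf", 0.43),
    ("epic_hb", 0.53),
)


@dataclass(frozen=True)
class CohortParams:
    """Calibration of the synthetic cohort generator.

    Defaults reproduce the estimation-cohort marginals: utility mean 0.90,
    SD 0.13, 55% at the ceiling, continuous component on [0.28, 1) with
    mode near 0.8, the printed EPIC domain/sub-domain means and SDs, and
    the published utility-score correlations.
    """

    n: int = 565
    p_ceiling: float = 0.55
    utility_mean: float = 0.90
    utility_sd: float = 0.13
    utility_floor: float = 0.28
    domain_marginals: tuple = DOMAIN_MARGINALS
    subdomain_marginals: tuple = SUBDOMAIN_MARGINALS
    target_correlations: tuple = CORRELATION_TARGETS
    within_epic_latent_corr: float = 0.4
    age_mean: float = 66.4
    age_sd: float = 7.3
    race_other_rate: float = 0.175
    zubrod1_rate: float = 0.062
    psa_ge4_rate: float = 0.797
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.p_ceiling <= 1.0:
            raise ParameterError(f"p_ceiling must be in [0,1], got {self.p_ceiling}")
        for col, mean, sd in (*self.domain_marginals, *self.subdomain_marginals):
            if sd <= 0:
                raise ParameterError(f"marginal SD for {col} must be > 0, got {sd}")
        if not 0.0 <= self.utility_floor < 1.0:
            raise ParameterError("utility_floor must lie in [0, 1)")

    @property
    def marginals(self) -> tuple:
        return (*self.domain_marginals, *self.subdomain_marginals)


def _beta_from_moments(params: CohortParams) -> tuple[float, float]:
    """Beta(a, b) for the continuous component on [floor, 1), solved so the
    overall mixture hits (utility_mean, utility_sd)."""
    p, m, s, lo = params.p_ceiling, params.utility_mean, params.utility_sd, params.utility_floor
    if p >= 1.0:
        raise ParameterError("p_ceiling = 1 leaves no continuous component")
    m_c = (m - p) / (1.0 - p)
    e2 = s**2 + m**2
    v_c = (e2 - p) / (1.0 - p) - m_c**2
    scale = 1.0 - lo
    mean_s = (m_c - lo) / scale
    var_s = v_c / scale**2
    if not 0.0 < mean_s < 1.0 or var_s <= 0 or var_s >= mean_s * (1.0 - mean_s):
        raise ParameterError(
            "utility mean/SD/ceiling targets are incompatible with a Beta "
            f"continuous component on [{lo}, 1) (scaled mean {mean_s:.3f}, "
            f"variance {var_s:.4f})"
        )
    nu = mean_s * (1.0 - mean_s) / var_s - 1.0
    return mean_s * nu, (1.0 - mean_s) * nu


def _censored_normal_moments(mu: float, sigma: float, lo: float = 0.0, hi: float = 100.0):
    a = (lo - mu) / sigma
    b = (hi - mu) / sigma
    Phi_a, Phi_b = ndtr(a), ndtr(b)
    phi_a, phi_b = scipy.stats.norm.pdf(a), scipy.stats.norm.pdf(b)
    Pm = Phi_b - Phi_a
    mean = lo * Phi_a + hi * (1.0 - Phi_b) + mu * Pm + sigma * (phi_a - phi_b)
    e2 = (
        lo**2 * Phi_a
        + hi**2 * (1.0 - Phi_b)
        + (mu**2 + sigma**2) * Pm
        + sigma * (2 * mu + sigma * a) * phi_a
        - sigma * (2 * mu + sigma * b) * phi_b
    )
    var = e2 - mean**2
    return mean, np.sqrt(max(var, 0.0))


def _solve_censored_normal(target_mean: float, target_sd: float) -> tuple[float, float]:
    """(mu, sigma) of the pre-clipping normal whose [0,100]-censored version
    has the target mean and SD."""

    def residual(theta):
        mu, log_sigma = theta
        mean, sd = _censored_normal_moments(mu, np.exp(log_sigma))
        return [mean - target_mean, sd - target_sd]

    sol = scipy.optimize.least_squares(
        residual, x0=[target_mean, np.log(target_sd)], xtol=1e-12, ftol=1e-12
    )
    mean, sd = _censored_normal_moments(sol.x[0], np.exp(sol.x[1]))
    if abs(mean - target_mean) > 1e-4 or abs(sd - target_sd) > 1e-4:
        raise ParameterError(
            f"no censored normal on [0,100] attains mean {target_mean}, SD {target_sd} "
            f"(best: {mean:.3f}, {sd:.3f})"
        )
    return float(sol.x[0]), float(np.exp(sol.x[1]))


class CohortSimulator:
    """Calibrated Gaussian-copula sampler for one :class:`CohortParams`.

    Construction performs all calibration work (Beta moments, censored
    normal parameters per score, latent correlation root-finding, copula
    Cholesky); :meth:`sample` then draws reproducibly from a seed.
    """

    #: size of the fixed standard-normal panel used for correlation calibration
    _PANEL = 20_000

    def __init__(self, params: CohortParams | None = None):
        self.params = params or CohortParams()
        self.beta_a_, self.beta_b_ = _beta_from_moments(self.params)
        self.score_columns_ = [col for col, _, _ in self.params.marginals]
        self.score_params_ = {
            col: _solve_censored_normal(mean, sd) for col, mean, sd in self.params.marginals
        }
        self._calibrate_latent_correlations()
        self._build_copula()

    # -- margins ------------------------------------------------------------

    def _utility_ppf(self, q: np.ndarray) -> np.ndarray:
        p, lo = self.params.p_ceiling, self.params.utility_floor
        q = np.asarray(q, dtype=float)
        out = np.ones_like(q)
        cont = q < 1.0 - p
        if cont.any():
            inner = np.clip(q[cont] / (1.0 - p), 0.0, 1.0 - 1e-14)
            scaled = scipy.stats.beta.ppf(inner, self.beta_a_, self.beta_b_)
            out[cont] = lo + (1.0 - lo) * np.minimum(scaled, 1.0 - 1e-12)
        return out

    def _score_ppf(self, col: str, q: np.ndarray) -> np.ndarray:
        mu, sigma = self.score_params_[col]
        return np.clip(mu + sigma * ndtri(q), 0.0, 100.0)

    # -- copula calibration --------------------------------------------------

    def _calibrate_latent_correlations(self):
        rng = np.random.default_rng(987654321)  # fixed panel: calibration machinery
        z0 = rng.standard_normal(self._PANEL)
        z1 = rng.standard_normal(self._PANEL)
        # avoid ndtr values of exactly 0/1 in the quantile maps
        u_ref = self._utility_ppf(ndtr(z0))
        targets = dict(self.params.target_correlations)
        self.latent_rho_ = {}
        for col in self.score_columns_:
            target = targets[col]
            ppf = self._score_ppf

            def gap(rho, col=col, target=target):
                z = rho * z0 + np.sqrt(1.0 - rho**2) * z1
                x = ppf(col, ndtr(z))
                return np.corrcoef(u_ref, x)[0, 1] - target

            hi = 0.999
            if gap(hi) < 0:
                raise ParameterError(
                    f"correlation target {target} for {col} is unreachable "
                    "under the Gaussian copula with these margins"
                )
            self.latent_rho_[col] = float(scipy.optimize.brentq(gap, 0.0, hi, xtol=1e-4))

    def _build_copula(self):
        cols = self.score_columns_
        d = 1 + len(cols)
        corr = np.full((d, d), self.params.within_epic_latent_corr)
        np.fill_diagonal(corr, 1.0)
        for j, col in enumerate(cols, start=1):
            corr[0, j] = corr[j, 0] = self.latent_rho_[col]
        eigvals = np.linalg.eigvalsh(corr)
        if eigvals.min() < 1e-10:
            # project to the nearest positive-definite correlation matrix
            w, V = np.linalg.eigh(corr)
            w = np.clip(w, 1e-8, None)
            fixed = V @ np.diag(w) @ V.T
            scale = np.sqrt(np.diag(fixed))
            fixed = fixed / np.outer(scale, scale)
            drift = np.max(np.abs(fixed[0, 1:] - corr[0, 1:]))
            if drift > 0.02:
                raise ParameterError(
                    "correlation targets are jointly infeasible; nearest "
                    f"positive-definite matrix moves a utility-score latent "
                    f"correlation by {drift:.3f}:\n{np.round(fixed, 3)}"
                )
            corr = fixed
        self.latent_corr_ = corr
        self._chol = np.linalg.cholesky(corr)

    # -- sampling -------------------------------------------------------------

    def sample(self, n: int | None = None, seed: int | None = None) -> pd.DataFrame:
        """Draw a patient table; fully reproducible from ``seed``."""
        p = self.params
        n = p.n if n is None else int(n)
        seed = p.seed if seed is None else seed
        rng = np.random.default_rng(seed)
        Z = rng.standard_normal((n, self.latent_corr_.shape[0])) @ self._chol.T
        U = np.clip(ndtr(Z), 1e-15, 1.0 - 1e-15)
        table = {"id": np.arange(n)}
        for j, col in enumerate(self.score_columns_, start=1):
            table[col] = self._score_ppf(col, U[:, j])
        table["age"] = np.clip(rng.normal(p.age_mean, p.age_sd, n), 40.0, 90.0)
        table["race_other"] = rng.binomial(1, p.race_other_rate, n)
        table["zubrod"] = rng.binomial(1, p.zubrod1_rate, n)
        table["psa_ge4"] = rng.binomial(1, p.psa_ge4_rate, n)
        table["eq5d"] = self._utility_ppf(U[:, 0])
        columns = ["id", *self.score_columns_, "age", "race_other", "zubrod", "psa_ge4", "eq5d"]
        return pd.DataFrame(table)[columns]


@lru_cache(maxsize=8)
def _simulator_for(params: CohortParams) -> CohortSimulator:
    return CohortSimulator(params)


def generate_cohort(
    params: CohortParams | None = None, n: int | None = None, seed: int | None = None
) -> pd.DataFrame:
    """Generate one synthetic patient table.

    Calibration is cached per parameter set, so repeated calls (e.g. over
    many seeds) pay the copula calibration once.
    """
    return _simulator_for(params or CohortParams()).sample(n=n, seed=seed)


# ---------------------------------------------------------------------------
# linear-truth harness for parameter-recovery tests
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LinearTruthParams:
    """Known linear generative model for estimator-recovery checks.

    Defaults give ``y* = 1.0 + 0.15 x1 - 0.08 x2 + 0.05 x3 + N(0, 0.1)``
    with iid standard-normal regressors; with censoring on, the latent mean
    at 1.0 puts ~50% of draws at the ceiling.
    """

    beta: tuple[float, ...] = (0.15, -0.08, 0.05)
    intercept: float = 1.0
    sigma: float = 0.1
    censor: bool = True
    ceiling: float = 1.0
    design: str = "normal"

    def __post_init__(self):
        if self.sigma < 0:
            raise ParameterError(f"sigma must be >= 0, got {self.sigma}")
        if self.design not in ("normal", "uniform"):
            raise ParameterError(f"design must be 'normal' or 'uniform', got {self.design!r}")


def generate_linear_truth(
    params: LinearTruthParams | None = None, n: int = 1000, seed: int = 0
) -> tuple[pd.DataFrame, dict]:
    """Draw ``(table, truth)`` from a known linear model.

    The table has columns ``x1..xk`` and ``y`` (censored at the ceiling
    when ``params.censor``); ``truth`` records the generative parameters
    and realised censoring fraction for recovery assertions.
    """
    params = params or LinearTruthParams()
    rng = np.random.default_rng(seed)
    k = len(params.beta)
    if params.design == "normal":
        X = rng.standard_normal((n, k))
    else:
        X = rng.uniform(-1.0, 1.0, (n, k))
    latent = params.intercept + X @ np.asarray(params.beta)
    if params.sigma > 0:
        latent = latent + rng.normal(0.0, params.sigma, n)
    y = np.minimum(latent, params.ceiling) if params.censor else latent
    table = pd.DataFrame(X, columns=[f"x{i + 1}" for i in range(k)])
    table["y"] = y
    truth = {
        "beta": tuple(params.beta),
        "intercept": params.intercept,
        "sigma": params.sigma,
        "censor": params.censor,
        "ceiling": params.ceiling,
        "censored_fraction": float(np.mean(y >= params.ceiling)) if params.censor else 0.0,
        "seed": seed,
        "n": n,
    }
    return table, truth
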