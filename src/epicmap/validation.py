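"""Performance assessment: splits, cross-validation, ranking, diagnostics.

Model development follows the usual mapping-study protocol: a seeded 70/30
estimation/validation split of the analyzable cohort; 5-fold
cross-validation inside the estimation sample, where each fold's held-out
predicted residual sum of squares (PRESS) is accumulated and

    RMSE = sqrt( sum_k PRESS_k / n ),    MAE = mean |held-out residual|

(PRESS is summed over folds before dividing by the total n, so unequal
folds are weighted by their size); external validation scores the frozen
candidate algorithm on the 30% sample with no refitting. Models are ranked
by ascending RMSE, ties broken by parsimony then label.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .estimation import (
    DesignSpec,
    EstimationError,
    build_design_matrix,
    make_estimator,
)

__all__ = [
    "SplitAssignment",
    "CvReport",
    "ExternalReport",
    "BlandAltman",
    "split_estimation_validation",
    "kfold_cross_validate",
    "external_validate",
    "rank_models",
    "bland_altman",
    "predicted_vs_observed_plot",
    "bland_altman_plot",
]


@dataclass
class SplitAssignment:
    """Exhaustive, disjoint estimation/validation partition of record ids."""

    estimation_ids: list
    validation_ids: list
    seed: int
    fraction: float

    @property
    def n_estimation(self) -> int:
        return len(self.estimation_ids)

    @property
    def n_validation(self) -> int:
        return len(self.validation_ids)

    def assignment(self) -> dict:
        out = {i: "estimation" for i in self.estimation_ids}
        out.update({i: "validation" for i in self.validation_ids})
        return out


def split_estimation_validation(records, fraction: float = 0.70, seed: int = 0) -> SplitAssignment:
    """Uniformly random, seed-reproducible estimation/validation split.

    The estimation sample takes ``ceil(fraction * n)`` records (a partial
    record always lands in the estimation sample: 1,092 records at 70%
    give 765/327); the remainder form the validation sample.
    """
    if isinstance(records, pd.DataFrame):
        ids = list(records.index)
    elif np.isscalar(records):
        ids = list(range(int(records)))
    else:
        ids = list(records)
    n = len(ids)
    if n < 10:
        raise ValueError(f"need at least 10 records to split, got {n}")
    if not 0.0 < fraction <= 1.0:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    # guard against float fuzz (0.7 * 1090 = 763.0000000000001) before ceiling
    n_est = int(math.ceil(round(fraction * n, 9)))
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    est = sorted(ids[i] for i in order[:n_est])
    val = sorted(ids[i] for i in order[n_est:])
    return SplitAssignment(estimation_ids=est, validation_ids=val, seed=seed, fraction=fraction)


@dataclass
class CvReport:
    """Cross-validation performance of one model specification."""

    label: str
    form: str
    fold_press: list[float]
    rmse: float
    mae: float
    predicted_mean: float
    predicted_sd: float
    predicted_min: float
    predicted_max: float
    n: int
    n_regressors: int
    k: int
    seed: int
    incomplete: bool = False
    failed_folds: list[int] = field(default_factory=list)
    rank: int | None = None

    def rendered_rmse(self, decimals: int = 5) -> str:
        """Table-style fixed-point rendering (5 decimals for CV RMSE)."""
        return f"{self.rmse:.{decimals}f}"


def _fold_indices(n: int, k: int, seed: int) -> list[np.ndarray]:
    """Seeded permutation sliced into k contiguous blocks; the remainder
    goes one record per fold to the first folds."""
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    base, extra = divmod(n, k)
    folds, start = [], 0
    for j in range(k):
        size = base + (1 if j < extra else 0)
        folds.append(order[start : start + size])
        start += size
    return folds


def kfold_cross_validate(
    records: pd.DataFrame,
    spec: DesignSpec,
    form: str = "ols",
    k: int = 5,
    seed: int = 0,
    label: str | None = None,
    estimator_kwargs: dict | None = None,
    selected: list[str] | None = None,
) -> CvReport:
    """K-fold cross-validation of one (specification, functional form) pair.

    Every record is predicted exactly once by a model fitted without it.
    When the table has an ``id`` column, records are ordered by it before
    the seeded fold assignment, so the report is invariant to row order.
    ``selected`` restricts the design to a column subset (reduced models).
    """
    if "id" in records.columns:
        records = records.sort_values("id")
    design = build_design_matrix(records, spec, require_response=True)
    X, y = design.X, design.y.to_numpy()
    if selected is not None:
        X = X[list(selected)]
    n = len(X)
    if k < 2 or k > n:
        raise ValueError(f"k must satisfy 2 <= k <= n (k={k}, n={n}); k = n is leave-one-out")
    folds = _fold_indices(n, k, seed)
    Xv, yv = X.reset_index(drop=True), y
    press, abs_err, preds = [], [], np.full(n, np.nan)
    failed = []
    for j, test_idx in enumerate(folds):
        train_mask = np.ones(n, dtype=bool)
        train_mask[test_idx] = False
        try:
            est = make_estimator(form, **(estimator_kwargs or {}))
            est.fit(Xv[train_mask], yv[train_mask])
            if not getattr(est, "converged_", True):
                raise EstimationError("fold fit did not converge")
            yhat = est.predict(Xv.iloc[test_idx])
        except EstimationError:
            failed.append(j)
            press.append(np.nan)
            continue
        resid = yv[test_idx] - yhat
        press.append(float(np.sum(resid**2)))
        abs_err.extend(np.abs(resid))
        preds[test_idx] = yhat
    incomplete = bool(failed)
    n_scored = int(np.isfinite(preds).sum())
    total_press = float(np.nansum(press)) if n_scored else float("nan")
    rmse = float(np.sqrt(total_press / n_scored)) if n_scored else float("nan")
    mae = float(np.mean(abs_err)) if abs_err else float("nan")
    scored = preds[np.isfinite(preds)]
    return CvReport(
        label=label or (spec.label or f"group{spec.group}-{form}"),
        form=form,
        fold_press=press,
        rmse=rmse,
        mae=mae,
        predicted_mean=float(np.mean(scored)) if n_scored else float("nan"),
        predicted_sd=float(np.std(scored, ddof=1)) if n_scored > 1 else float("nan"),
        predicted_min=float(np.min(scored)) if n_scored else float("nan"),
        predicted_max=float(np.max(scored)) if n_scored else float("nan"),
        n=n_scored,
        n_regressors=X.shape[1],
        k=k,
        seed=seed,
        incomplete=incomplete,
        failed_folds=failed,
    )


@dataclass
class ExternalReport:
    """Frozen-model performance on a validation sample (no refitting)."""

    model_name: str
    rmse: float
    mae: float
    predicted_mean: float
    predicted_sd: float
    predicted_min: float
    predicted_max: float
    n: int
    n_regressors: int
    rank: int | None = None

    def rendered_rmse(self, decimals: int = 6) -> str:
        """Table-style rendering (6 decimals for validation RMSE)."""
        return f"{self.rmse:.{decimals}f}"


def external_validate(model, records: pd.DataFrame, response: str = "eq5d") -> ExternalReport:
    """Score a frozen mapping model against observed utilities.

    RMSE uses the population (biased) mean square, so a constant model at
    the observed mean scores exactly the population SD of the outcome.
    """
    if response not in records.columns:
        raise ValueError(f"records lack the observed-utility column {response!r}")
    usable = records[records[response].notna()]
    if len(usable) == 0:
        raise ValueError("no records with observed utilities")
    y = usable[response].to_numpy(dtype=float)
    yhat = model.predict(usable)
    resid = y - yhat
    return ExternalReport(
        model_name=model.name,
        rmse=float(np.sqrt(np.mean(resid**2))),
        mae=float(np.mean(np.abs(resid))),
        predicted_mean=float(np.mean(yhat)),
        predicted_sd=float(np.std(yhat, ddof=1)) if len(yhat) > 1 else float("nan"),
        predicted_min=float(np.min(yhat)),
        predicted_max=float(np.max(yhat)),
        n=len(y),
        n_regressors=model.n_regressors,
    )


def rank_models(reports):
    """Order reports by ascending RMSE; ties break by fewer regressors,
    then label. Returns a new list with ``rank`` assigned from 1."""
    reports = list(reports)
    if not reports:
        raise ValueError("need at least one report to rank")

    def label_of(r):
        return getattr(r, "label", None) or getattr(r, "model_name", "")

    ordered = sorted(reports, key=lambda r: (r.rmse, r.n_regressors, label_of(r)))
    for position, report in enumerate(ordered, start=1):
        report.rank = position
    return ordered


@dataclass
class BlandAltman:
    """Agreement summary between observed and predicted utilities."""

    means: np.ndarray
    differences: np.ndarray  # predicted - observed
    mean_difference: float
    sd_difference: float
    limits: tuple[float, float]


def bland_altman(observed, predicted) -> BlandAltman:
    """Per-record (mean, difference) pairs with 95% limits of agreement
    ``mean difference +/- 1.96 * SD(differences)``."""
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if observed.shape != predicted.shape:
        raise ValueError(
            f"observed and predicted lengths differ: {observed.shape} vs {predicted.shape}"
        )
    diffs = predicted - observed
    means = (predicted + observed) / 2.0
    mean_diff = float(np.mean(diffs))
    sd_diff = float(np.std(diffs, ddof=0))
    limits = (mean_diff - 1.96 * sd_diff, mean_diff + 1.96 * sd_diff)
    return BlandAltman(
        means=means,
        differences=diffs,
        mean_difference=mean_diff,
        sd_difference=sd_diff,
        limits=limits,
    )


def predicted_vs_observed_plot(observed, predicted, path, title: str = "Predicted vs observed EQ5D"):
    """Scatter of predictions against observations with the identity line."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    ax.scatter(observed, predicted, s=12, alpha=0.5)
    lo = min(np.min(observed), np.min(predicted))
    hi = max(np.max(observed), np.max(predicted))
    ax.plot([lo, hi], [lo, hi], color="grey", lw=1)
    ax.set_xlabel("Observed EQ5D utility")
    ax.set_ylabel("Predicted EQ5D utility")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def bland_altman_plot(observed, predicted, path, title: str = "Bland-Altman"):
    """Difference-vs-mean plot with the mean difference and 95% limits."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ba = bland_altman(observed, predicted)
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.scatter(ba.means, ba.differences, s=12, alpha=0.5)
    ax.axhline(ba.mean_difference, color="black", lw=1)
    for limit in ba.limits:
        ax.axhline(limit, color="grey", lw=1, ls="--")
    ax.set_xlabel("Mean of predicted and observed")
    ax.set_ylabel("Predicted - observed")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
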