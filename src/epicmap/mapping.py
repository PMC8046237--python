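"""Published EPIC -> EQ5D mapping algorithms: representation, registry, evaluation.

A mapping model is an intercept plus an ordered list of linear terms. Each
term is a coefficient times a product of input variables (a variable
repeated in the product encodes a power, e.g. ``("age", "age", "age")`` is
age cubed), so polynomial and interaction regressors are evaluated
literally, exactly as the published equations print them.

Two models ship as built-ins at full printed precision:

* the reduced group-6 model (urinary/hormonal function & bother, Zubrod,
  and a urinary-function x Zubrod product), and
* the full group-6 model "6i" (all ten sub-domains, an age cubic, race,
  Zubrod, ten score x Zubrod products, and the PSA >= 4 indicator).

Predictions are **not** clipped to <= 1 by default: the published OLS
algorithms report maxima slightly above 1, so clipping is an explicit
option for downstream QALY use, not part of the algorithm.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Term",
    "MappingModel",
    "PredictionRecord",
    "ModelRegistry",
    "builtin_reduced_model_6",
    "builtin_full_model_6i",
    "default_registry",
    "predict_utility",
    "load_models",
]


@dataclass(frozen=True)
class Term:
    """One linear term: ``coefficient`` times the product of ``variables``."""

    coefficient: float
    variables: tuple[str, ...]

    @property
    def signature(self) -> tuple[str, ...]:
        """Order-free identity of the regressor (sorted variable multiset)."""
        return tuple(sorted(self.variables))

    def label(self) -> str:
        return "*".join(self.variables) if self.variables else "1"


@dataclass(frozen=True)
class PredictionRecord:
    """One scored record: the predicted utility plus an echo of the inputs."""

    predicted_utility: float
    inputs_used: dict
    model_name: str


def _logistic(z):
    return 1.0 / (1.0 + np.exp(-np.asarray(z, dtype=float)))


@dataclass(frozen=True)
class MappingModel:
    """A named EPIC -> EQ5D mapping algorithm.

    ``form`` records how the coefficients were estimated (``ols``,
    ``tobit`` or ``two_part``); evaluation is the literal linear predictor
    for ``ols``/``tobit`` and the recombined two-part expectation
    ``p * ceiling + (1 - p) * linear`` when ``part1`` (a logistic
    intercept/terms pair) is present.
    """

    name: str
    group: int
    form: str
    intercept: float
    terms: tuple[Term, ...]
    clip_predictions: bool = False
    part1_intercept: float | None = None
    part1_terms: tuple[Term, ...] = ()

    def __post_init__(self):
        if self.form not in ("ols", "tobit", "two_part"):
            raise ValueError(f"unknown model form {self.form!r}")
        signatures = [t.signature for t in self.terms]
        if len(set(signatures)) != len(signatures):
            dupes = {s for s in signatures if signatures.count(s) > 1}
            raise ValueError(f"duplicate regressor signature(s) in {self.name!r}: {dupes}")

    @property
    def required_inputs(self) -> frozenset[str]:
        names = {v for t in self.terms for v in t.variables}
        names |= {v for t in self.part1_terms for v in t.variables}
        return frozenset(names)

    @property
    def n_regressors(self) -> int:
        return len(self.terms)

    # -- evaluation ---------------------------------------------------------

    def _linear(self, data: Mapping[str, np.ndarray], intercept, terms, n: int) -> np.ndarray:
        out = np.full(n, float(intercept))
        for term in terms:
            product = np.full(n, term.coefficient)
            for var in term.variables:
                product = product * data[var]
            out = out + product
        return out

    def _gather(self, data) -> tuple[dict, int]:
        if isinstance(data, pd.DataFrame):
            getter, n = (lambda v: data[v].to_numpy(dtype=float)), len(data)
        elif isinstance(data, Mapping):
            getter, n = (lambda v: np.atleast_1d(np.asarray(data[v], dtype=float))), 1
        else:
            raise TypeError("data must be a DataFrame or a mapping of variable -> value")
        gathered = {}
        for var in sorted(self.required_inputs):
            try:
                gathered[var] = getter(var)
            except KeyError:
                raise KeyError(
                    f"model {self.name!r} requires input {var!r}, absent from the data"
                ) from None
        return gathered, n

    def predict(self, data) -> np.ndarray:
        """Predicted utilities for a DataFrame or a single variable mapping."""
        gathered, _ = self._gather(data)
        n = len(data) if isinstance(data, pd.DataFrame) else 1
        yhat = self._linear(gathered, self.intercept, self.terms, n)
        if self.form == "two_part" and self.part1_intercept is not None:
            p = _logistic(self._linear(gathered, self.part1_intercept, self.part1_terms, n))
            yhat = p * 1.0 + (1.0 - p) * yhat
        if self.clip_predictions:
            yhat = np.minimum(yhat, 1.0)
        return yhat

    def evaluate(self, **inputs) -> float:
        """Scalar evaluation at named inputs, e.g. ``evaluate(epic_uf=100, ...)``."""
        return float(self.predict(inputs)[0])

    # -- serialisation ------------------------------------------------------

    def to_dict(self) -> dict:
        doc = {
            "name": self.name,
            "group": self.group,
            "form": self.form,
            "intercept": self.intercept,
            "terms": [
                {"coefficient": t.coefficient, "variables": list(t.variables)}
                for t in self.terms
            ],
            "clip_predictions": self.clip_predictions,
        }
        if self.part1_intercept is not None:
            doc["part1"] = {
                "intercept": self.part1_intercept,
                "terms": [
                    {"coefficient": t.coefficient, "variables": list(t.variables)}
                    for t in self.part1_terms
                ],
            }
        return doc

    @classmethod
    def from_dict(cls, doc: Mapping) -> "MappingModel":
        part1 = doc.get("part1")
        return cls(
            name=doc["name"],
            group=int(doc["group"]),
            form=doc["form"],
            intercept=float(doc["intercept"]),
            terms=tuple(
                Term(float(t["coefficient"]), tuple(t["variables"])) for t in doc["terms"]
            ),
            clip_predictions=bool(doc.get("clip_predictions", False)),
            part1_intercept=None if part1 is None else float(part1["intercept"]),
            part1_terms=()
            if part1 is None
            else tuple(
                Term(float(t["coefficient"]), tuple(t["variables"]))
                for t in part1["terms"]
            ),
        )


# ---------------------------------------------------------------------------
# built-in published equations (coefficients at full printed precision)
# ---------------------------------------------------------------------------

_REDUCED_6_TERMS = (
    ("0.000748", ("epic_uf",)),
    ("0.001134", ("epic_ub",)),
    ("0.000968", ("epic_hf",)),
    ("0.004404", ("epic_hb",)),
    ("-0.376487", ("zubrod",)),
    ("0.003562", ("epic_uf", "zubrod")),
)

_FULL_6I_TERMS = (
    ("0.003627", ("epic_uf",)),
    ("0.004125", ("epic_ub",)),
    ("-0.003625", ("epic_uirr",)),
    ("-0.002242", ("epic_uinc",)),
    ("-0.0000058476", ("epic_bf",)),
    ("-0.000690", ("epic_bb",)),
    ("0.000589", ("epic_sf",)),
    ("-0.000244", ("epic_sb",)),
    ("0.000721", ("epic_hf",)),
    ("0.004691", ("epic_hb",)),
    ("-0.126445", ("age",)),
    ("0.001997", ("age", "age")),
    ("-0.000010336", ("age", "age", "age")),
    ("0.009922", ("race_other",)),
    ("-0.456669", ("zubrod",)),
    ("0.016593", ("epic_uf", "zubrod")),
    ("0.008613", ("epic_ub", "zubrod")),
    ("-0.011", ("epic_uirr", "zubrod")),
    ("-0.011342", ("epic_uinc", "zubrod")),
    ("0.000711", ("epic_bf", "zubrod")),
    ("0.003675", ("epic_bb", "zubrod")),
    ("-0.001631", ("epic_sf", "zubrod")),
    ("0.00008517", ("epic_sb", "zubrod")),
    ("-0.000201", ("epic_hf", "zubrod")),
    ("-0.002221", ("epic_hb", "zubrod")),
    ("0.000332", ("psa_ge4",)),
)


def builtin_reduced_model_6() -> MappingModel:
    """The best-performing reduced model (specification group 6).

    OLS, forward-stepwise selected: urinary function & bother, hormonal
    function & bother, Zubrod, and urinary function x Zubrod.
    """
    return MappingModel(
        name="reduced_6",
        group=6,
        form="ols",
        intercept=0.248541,
        terms=tuple(Term(float(c), v) for c, v in _REDUCED_6_TERMS),
    )


def builtin_full_model_6i() -> MappingModel:
    """The best-performing full model, specification 6i.

    OLS on all ten EPIC sub-domains, an age cubic, race, Zubrod, the ten
    sub-domain x Zubrod products, and the PSA >= 4 indicator (26 terms).
    """
    return MappingModel(
        name="full_6i",
        group=6,
        form="ols",
        intercept=2.922434,
        terms=tuple(Term(float(c), v) for c, v in _FULL_6I_TERMS),
    )


class ModelRegistry:
    """Name-keyed store of mapping models; duplicate names are rejected."""

    def __init__(self, models: Iterable[MappingModel] = ()):
        self._models: dict[str, MappingModel] = {}
        for model in models:
            self.register(model)

    def register(self, model: MappingModel) -> "ModelRegistry":
        if model.name in self._models:
            raise ValueError(f"model {model.name!r} already registered")
        self._models[model.name] = model
        return self

    def get(self, name: str) -> MappingModel:
        try:
            return self._models[name]
        except KeyError:
            raise KeyError(
                f"no model named {name!r}; registered: {sorted(self._models)}"
            ) from None

    def names(self) -> list[str]:
        return list(self._models)

    def __len__(self) -> int:
        return len(self._models)

    def __contains__(self, name: str) -> bool:
        return name in self._models

    def load(self, path) -> "ModelRegistry":
        """Register every model in a JSON document (one model or a list)."""
        with open(path) as handle:
            doc = json.load(handle)
        docs = doc if isinstance(doc, list) else [doc]
        for item in docs:
            self.register(MappingModel.from_dict(item))
        return self


def default_registry() -> ModelRegistry:
    """Registry pre-loaded with the two equations published in full."""
    return ModelRegistry([builtin_reduced_model_6(), builtin_full_model_6i()])


def load_models(path, registry: ModelRegistry | None = None) -> ModelRegistry:
    registry = default_registry() if registry is None else registry
    return registry.load(path)


def predict_utility(model: MappingModel, data, **covariates) -> PredictionRecord | list[PredictionRecord]:
    """Evaluate ``model`` on one record (mapping) or a table (DataFrame).

    Returns a :class:`PredictionRecord` per input row; the linear predictor
    is evaluated literally (products as printed), clipped to <= 1 only when
    the model's ``clip_predictions`` flag is set.
    """
    if covariates:
        data = {**(data or {}), **covariates}
    yhat = model.predict(data)
    if isinstance(data, pd.DataFrame):
        used = sorted(model.required_inputs)
        return [
            PredictionRecord(float(y), {v: row[v] for v in used}, model.name)
            for y, (_, row) in zip(yhat, data.iterrows())
        ]
    used = {v: data[v] for v in sorted(model.required_inputs)}
    return PredictionRecord(float(yhat[0]), used, model.name)
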