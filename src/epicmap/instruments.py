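"""Instrument score types and scoring engines.

Two instruments are involved in the mapping workflow:

* **EQ-5D-3L**, a generic preference-based measure. A respondent describes
  their health on five dimensions (mobility, self-care, usual activities,
  pain/discomfort, anxiety/depression), each at one of three severity
  levels, giving :math:`3^5 = 243` describable health states. A country
  *value set* (tariff) converts a state into a utility anchored at 1 for
  full health (and 0 for dead; states worse than dead are negative).
* **EPIC** (Expanded Prostate Cancer Index Composite), a prostate-cancer
  specific profile instrument. Multi-item Likert scales are linearly
  transformed to 0-100 scores (higher = better HRQoL), summarised as four
  domains (Urinary, Bowel, Sexual, Hormonal) and ten sub-domain
  function/bother scales.

This module ships the generic additive 3L tariff engine (value sets are
data, loaded from JSON), the 0-100 linear transform, and record-level
validation used to enforce complete-case inclusion per model group.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field, fields
from importlib import resources
from typing import Iterator, Mapping, Sequence

import numpy as np

__all__ = [
    "EQ5D_DIMENSIONS",
    "EPIC_DOMAINS",
    "EPIC_SUBDOMAINS",
    "DOMAIN_COLUMNS",
    "SUBDOMAIN_COLUMNS",
    "COVARIATE_COLUMNS",
    "EpicDomainScores",
    "EpicSubdomainScores",
    "Covariates",
    "Eq5dState",
    "ValueSet",
    "ValueSetError",
    "likert_to_0_100",
    "score_eq5d",
    "validate_record",
    "load_value_set",
    "packaged_value_set",
]

EQ5D_DIMENSIONS = (
    "mobility",
    "self_care",
    "usual_activities",
    "pain_discomfort",
    "anxiety_depression",
)

EPIC_DOMAINS = ("urinary", "bowel", "sexual", "hormonal")

#: canonical sub-domain order: function/bother (plus urinary irritation and
#: incontinence), instrument order urinary, bowel, sexual, hormonal
EPIC_SUBDOMAINS = (
    "urinary_function",
    "urinary_bother",
    "urinary_irritation",
    "urinary_incontinence",
    "bowel_function",
    "bowel_bother",
    "sexual_function",
    "sexual_bother",
    "hormonal_function",
    "hormonal_bother",
)

#: patient-table column names (delimited text files, header row)
DOMAIN_COLUMNS = tuple(f"epic_{d}" for d in EPIC_DOMAINS)
SUBDOMAIN_COLUMNS = (
    "epic_uf",
    "epic_ub",
    "epic_uirr",
    "epic_uinc",
    "epic_bf",
    "epic_bb",
    "epic_sf",
    "epic_sb",
    "epic_hf",
    "epic_hb",
)
COVARIATE_COLUMNS = ("age", "race_other", "zubrod", "psa_ge4")
RESPONSE_COLUMN = "eq5d"

SUBDOMAIN_TO_COLUMN = dict(zip(EPIC_SUBDOMAINS, SUBDOMAIN_COLUMNS))


class ValueSetError(ValueError):
    """Raised when a value-set configuration is malformed or incomplete."""


def likert_to_0_100(raw, min_raw, max_raw):
    """Linearly transform a raw Likert response to the 0-100 EPIC scale.

    Higher transformed scores represent better HRQoL. Endpoints map
    exactly: ``raw == min_raw -> 0`` and ``raw == max_raw -> 100``.

    Parameters
    ----------
    raw : float or array-like
        Raw response(s), each in ``[min_raw, max_raw]``.
    min_raw, max_raw : float
        Declared response range, ``min_raw < max_raw``.
    """
    if not min_raw < max_raw:
        raise ValueError(f"min_raw must be < max_raw (got {min_raw} >= {max_raw})")
    arr = np.asarray(raw, dtype=float)
    bad = (arr < min_raw) | (arr > max_raw)
    if np.any(bad):
        offending = arr[bad].flat[0] if arr.ndim else float(arr)
        raise ValueError(
            f"raw response {offending} outside declared range [{min_raw}, {max_raw}]"
        )
    out = 100.0 * (arr - min_raw) / (max_raw - min_raw)
    return out if arr.ndim else float(out)


def _check_scores_0_100(obj, names: Sequence[str]) -> list[str]:
    violations = []
    for name in names:
        value = getattr(obj, name)
        if value is None:
            continue
        if not np.isfinite(value) or not (0.0 <= value <= 100.0):
            violations.append(f"{name}={value!r} outside [0, 100]")
    return violations


@dataclass
class EpicDomainScores:
    """EPIC summary-domain scores, each 0-100; ``None`` marks a missing domain."""

    urinary: float | None = None
    bowel: float | None = None
    sexual: float | None = None
    hormonal: float | None = None

    def violations(self) -> list[str]:
        return _check_scores_0_100(self, EPIC_DOMAINS)

    def is_complete(self) -> bool:
        return all(getattr(self, d) is not None for d in EPIC_DOMAINS)


@dataclass
class EpicSubdomainScores:
    """EPIC function/bother sub-domain scores, each 0-100; ``None`` = missing."""

    urinary_function: float | None = None
    urinary_bother: float | None = None
    urinary_irritation: float | None = None
    urinary_incontinence: float | None = None
    bowel_function: float | None = None
    bowel_bother: float | None = None
    sexual_function: float | None = None
    sexual_bother: float | None = None
    hormonal_function: float | None = None
    hormonal_bother: float | None = None

    def violations(self) -> list[str]:
        return _check_scores_0_100(self, EPIC_SUBDOMAINS)

    def is_complete(self) -> bool:
        return all(getattr(self, s) is not None for s in EPIC_SUBDOMAINS)


@dataclass
class Covariates:
    """Demographic and clinical covariates used by mapping-model groups 3-6.

    ``race_other`` is 1 for non-White race, ``zubrod`` is the performance
    status indicator (only 0/1 occur in a low-risk population), and
    ``psa_ge4`` flags baseline PSA >= 4 ng/mL.
    """

    age: float | None = None
    race_other: int | None = None
    zubrod: int | None = None
    psa_ge4: int | None = None

    def violations(self) -> list[str]:
        out = []
        if self.age is not None and not (np.isfinite(self.age) and self.age > 0):
            out.append(f"age={self.age!r} must be > 0")
        for name in ("race_other", "zubrod", "psa_ge4"):
            value = getattr(self, name)
            if value is not None and value not in (0, 1):
                out.append(f"{name}={value!r} must be exactly 0 or 1")
        return out


@dataclass(frozen=True)
class Eq5dState:
    """One EQ-5D-3L descriptive response: five dimensions, levels 1-3."""

    mobility: int
    self_care: int
    usual_activities: int
    pain_discomfort: int
    anxiety_depression: int

    def __post_init__(self):
        for name in EQ5D_DIMENSIONS:
            level = getattr(self, name)
            if level not in (1, 2, 3):
                raise ValueError(f"{name} level must be 1, 2 or 3 (got {level!r})")

    @property
    def levels(self) -> tuple[int, int, int, int, int]:
        return tuple(getattr(self, name) for name in EQ5D_DIMENSIONS)

    @property
    def code(self) -> str:
        """Five-digit state code, e.g. ``'11223'``."""
        return "".join(str(level) for level in self.levels)

    @classmethod
    def from_code(cls, code: str) -> "Eq5dState":
        if len(code) != 5 or not code.isdigit():
            raise ValueError(f"state code must be five digits 1-3, got {code!r}")
        return cls(*(int(c) for c in code))

    @classmethod
    def all_states(cls) -> Iterator["Eq5dState"]:
        """Enumerate all 243 describable states in lexicographic order."""
        for levels in itertools.product((1, 2, 3), repeat=5):
            yield cls(*levels)


# derived regressors a value set may use beyond per-dimension decrements;
# every feature is 0 at full health so the anchor holds by construction
_EXTRA_FEATURES = {
    "any_dysfunction": lambda levels: float(any(l > 1 for l in levels)),
    "count_level2": lambda levels: float(sum(l == 2 for l in levels)),
    "count_level3": lambda levels: float(sum(l == 3 for l in levels)),
    "count_level2_minus_1": lambda levels: float(max(sum(l == 2 for l in levels) - 1, 0)),
    "count_level3_minus_1": lambda levels: float(max(sum(l == 3 for l in levels) - 1, 0)),
    "count_level2_or_3_minus_1": lambda levels: float(
        max(sum(l > 1 for l in levels) - 1, 0)
    ),
}


@dataclass(frozen=True)
class ExtraTerm:
    """A named derived regressor in a value set: ``coefficient * feature**power``."""

    name: str
    feature: str
    coefficient: float
    power: int = 1

    def contribution(self, levels: Sequence[int]) -> float:
        return self.coefficient * _EXTRA_FEATURES[self.feature](levels) ** self.power


@dataclass(frozen=True)
class ValueSet:
    """An additive EQ-5D-3L tariff.

    Utility = 1.0 + per-dimension level decrements + extra-term
    contributions. Level 1 contributes 0 by convention, so the full-health
    state ``11111`` scores exactly 1.0 for every well-formed value set.
    """

    name: str
    decrements: Mapping[str, Mapping[int, float]]  # dimension -> {2: d2, 3: d3}
    extra_terms: tuple[ExtraTerm, ...] = ()

    def __post_init__(self):
        for dim in EQ5D_DIMENSIONS:
            if dim not in self.decrements:
                raise ValueSetError(f"value set {self.name!r} missing dimension {dim!r}")
            for level in (2, 3):
                if level not in self.decrements[dim]:
                    raise ValueSetError(
                        f"value set {self.name!r} missing level-{level} entry for {dim!r}"
                    )
        for term in self.extra_terms:
            if term.feature not in _EXTRA_FEATURES:
                raise ValueSetError(
                    f"unknown extra-term feature {term.feature!r}; "
                    f"known: {sorted(_EXTRA_FEATURES)}"
                )

    def score(self, state: Eq5dState) -> float:
        utility = 1.0
        for dim in EQ5D_DIMENSIONS:
            level = getattr(state, dim)
            if level > 1:
                utility += self.decrements[dim][level]
        for term in self.extra_terms:
            utility += term.contribution(state.levels)
        return utility

    @classmethod
    def from_dict(cls, doc: Mapping) -> "ValueSet":
        try:
            name = doc["name"]
            raw_decs = doc["decrements"]
        except (KeyError, TypeError) as exc:
            raise ValueSetError(f"value-set document missing required key: {exc}") from exc
        decrements = {}
        for dim, block in raw_decs.items():
            if dim not in EQ5D_DIMENSIONS:
                raise ValueSetError(f"unknown EQ-5D dimension {dim!r}")
            try:
                decrements[dim] = {2: float(block["2"]), 3: float(block["3"])}
            except (KeyError, TypeError) as exc:
                raise ValueSetError(
                    f"dimension {dim!r} must provide level '2' and '3' decrements"
                ) from exc
        extra = tuple(
            ExtraTerm(
                name=t["name"],
                feature=t["feature"],
                coefficient=float(t["coefficient"]),
                power=int(t.get("power", 1)),
            )
            for t in doc.get("extra_terms", ())
        )
        return cls(name=name, decrements=decrements, extra_terms=extra)

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "decrements": {
                dim: {"2": self.decrements[dim][2], "3": self.decrements[dim][3]}
                for dim in EQ5D_DIMENSIONS
            },
            "extra_terms": [
                {
                    "name": t.name,
                    "feature": t.feature,
                    "coefficient": t.coefficient,
                    "power": t.power,
                }
                for t in self.extra_terms
            ],
        }


def score_eq5d(state: Eq5dState, value_set: ValueSet) -> float:
    """Score one descriptive state to a utility under ``value_set``.

    Deterministic and additive; full health always returns exactly 1.0.
    """
    return value_set.score(state)


def load_value_set(path) -> ValueSet:
    """Load and validate a value-set JSON document from ``path``."""
    with open(path) as handle:
        doc = json.load(handle)
    return ValueSet.from_dict(doc)


def packaged_value_set(name: str = "us3l_synthetic") -> ValueSet:
    """Load a value set shipped with the package.

    The default, ``us3l_synthetic``, is a synthetic stand-in with the
    structure of the published US 3L valuation (per-dimension level-2/3
    decrements plus any-dysfunction and extra-level-3 terms), calibrated to
    the published utility range; it is not the published tariff itself.
    """
    ref = resources.files("epicmap") / "valuesets" / f"{name}.json"
    with resources.as_file(ref) as path:
        return load_value_set(path)


def validate_record(
    scores: EpicDomainScores | EpicSubdomainScores | None = None,
    covariates: Covariates | None = None,
) -> list[str]:
    """Collect invariant violations for one patient record.

    Violations are returned, never raised: the caller decides whether a
    record with problems is dropped (complete-case rule) or repaired.
    An empty list means every *present* field is valid; missing fields are
    not violations here — completeness per model group is a separate
    question answered by :func:`complete_for_group`.
    """
    violations: list[str] = []
    if scores is not None:
        violations.extend(scores.violations())
    if covariates is not None:
        violations.extend(covariates.violations())
    return violations


def complete_for_group(record: Mapping[str, object], group: int) -> bool:
    """Whether a patient-table record (column -> value) is a complete case
    for the given model-specification group.

    Odd groups (1/3/5) use the four domain scores; even groups (2/4/6) the
    ten sub-domain scores. Groups 3-6 additionally need age and race;
    groups 5-6 also Zubrod and the PSA category.
    """
    if group not in range(1, 7):
        raise ValueError(f"group must be 1..6, got {group}")
    needed = list(DOMAIN_COLUMNS if group % 2 == 1 else SUBDOMAIN_COLUMNS)
    if group >= 3:
        needed += ["age", "race_other"]
    if group >= 5:
        needed += ["zubrod", "psa_ge4"]
    for column in needed:
        value = record.get(column)
        if value is None:
            return False
        try:
            if np.isnan(float(value)):  # type: ignore[arg-type]
                return False
        except (TypeError, ValueError):
            return False
    return True
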