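"""Patient-table and report I/O, column aliasing, and run manifests."""

from __future__ import annotations

import dataclasses
import datetime
import json
from dataclasses import dataclass, field
from importlib import metadata

import numpy as np
import pandas as pd

from .instruments import (
    COVARIATE_COLUMNS,
    DOMAIN_COLUMNS,
    RESPONSE_COLUMN,
    SUBDOMAIN_COLUMNS,
)

__all__ = [
    "FormatError",
    "ParseError",
    "ParseReport",
    "RunManifest",
    "KNOWN_COLUMNS",
    "COLUMN_ALIASES",
    "read_patient_table",
    "write_patient_table",
    "write_report",
    "read_report_json",
    "render_performance_table",
]


class FormatError(ValueError):
    """Raised when a table's header does not look like a patient table."""


class ParseError(ValueError):
    """Raised when a cell cannot be parsed; names the row and column."""


#: EQ5D descriptive-response columns accepted by the `score` subcommand
EQ5D_LEVEL_COLUMNS = ("eq5d_mo", "eq5d_sc", "eq5d_ua", "eq5d_pd", "eq5d_ad")

KNOWN_COLUMNS = (
    "id",
    *DOMAIN_COLUMNS,
    *SUBDOMAIN_COLUMNS,
    *COVARIATE_COLUMNS,
    RESPONSE_COLUMN,
    *EQ5D_LEVEL_COLUMNS,
)

#: common EPIC export headers -> canonical lower_snake_case names
COLUMN_ALIASES = {
    "urinary": "epic_urinary",
    "bowel": "epic_bowel",
    "sexual": "epic_sexual",
    "hormonal": "epic_hormonal",
    "epic_urinary_function": "epic_uf",
    "epic_urinary_bother": "epic_ub",
    "epic_urinary_irritation": "epic_uirr",
    "epic_urinary_incontinence": "epic_uinc",
    "epic_bowel_function": "epic_bf",
    "epic_bowel_bother": "epic_bb",
    "epic_sexual_function": "epic_sf",
    "epic_sexual_bother": "epic_sb",
    "epic_hormonal_function": "epic_hf",
    "epic_hormonal_bother": "epic_hb",
    "uf": "epic_uf",
    "ub": "epic_ub",
    "uirr": "epic_uirr",
    "uinc": "epic_uinc",
    "bf": "epic_bf",
    "bb": "epic_bb",
    "sf": "epic_sf",
    "sb": "epic_sb",
    "hf": "epic_hf",
    "hb": "epic_hb",
    "eq5d_index": "eq5d",
    "utility": "eq5d",
    "eq5d_utility": "eq5d",
}


@dataclass
class ParseReport:
    """Accounting from one table read."""

    n_records: int
    known_columns: list[str]
    unknown_columns: list[str]
    missing_counts: dict[str, int]


def read_patient_table(path, sep=None) -> tuple[pd.DataFrame, ParseReport]:
    """Read a delimited patient table (header row, one record per patient).

    Column names are lower-cased and passed through the alias map; unknown
    columns are preserved but ignored downstream. Known columns are parsed
    as numbers; an unparseable cell raises :class:`ParseError` with its row
    number. A table containing no known column raises :class:`FormatError`.
    """
    if sep is None:
        with open(path) as handle:
            header = handle.readline()
        counts = {cand: header.count(cand) for cand in (",", "\t", ";", "|")}
        sep = max(counts, key=counts.get) if max(counts.values()) else ","
    df = pd.read_csv(path, sep=sep)
    df.columns = [COLUMN_ALIASES.get(str(c).strip().lower(), str(c).strip().lower()) for c in df.columns]
    known = [c for c in df.columns if c in KNOWN_COLUMNS]
    unknown = [c for c in df.columns if c not in KNOWN_COLUMNS]
    if not known:
        raise FormatError(
            f"no recognised patient-table column in {list(df.columns)}; "
            f"expected names like {list(KNOWN_COLUMNS[:8])} ..."
        )
    missing_counts = {}
    for col in known:
        if col == "id":
            continue
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ParseError(
                f"column {col!r}, row {row + 2} (1-based, counting the header): "
                f"cannot parse value {df[col].iloc[row]!r} as a number"
            )
        df[col] = coerced
        missing_counts[col] = int(coerced.isna().sum())
    report = ParseReport(
        n_records=len(df),
        known_columns=known,
        unknown_columns=unknown,
        missing_counts=missing_counts,
    )
    return df, report


def write_patient_table(df: pd.DataFrame, path, sep=",") -> None:
    df.to_csv(path, sep=sep, index=False)


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj


def write_report(report, path, format: str = "json") -> None:
    """Write one report (or a list of reports) as JSON or delimited text.

    The JSON form round-trips: :func:`read_report_json` reconstructs equal
    values.
    """
    if format == "json":
        with open(path, "w") as handle:
            json.dump(_jsonable(report), handle, indent=2)
    elif format == "delimited":
        rows = report if isinstance(report, (list, tuple)) else [report]
        pd.DataFrame([_jsonable(r) for r in rows]).to_csv(path, sep="\t", index=False)
    else:
        raise ValueError(f"unknown report format {format!r}; use 'json' or 'delimited'")


def read_report_json(path):
    with open(path) as handle:
        return json.load(handle)


def render_performance_table(reports, validation_reports=None) -> str:
    """Render ranked reports in the published table style: cross-validation
    RMSE to 5 decimals, validation RMSE to 6 decimals."""
    lines = [
        f"{'Model':<24}{'Mean ± SD':<16}{'Min':>7}{'Max':>7}"
        f"{'CV RMSE':>10}{'Val RMSE':>11}{'Rank':>6}"
    ]
    validation_by_label = {}
    if validation_reports:
        for rep in validation_reports:
            validation_by_label[rep.model_name] = rep
    for rep in reports:
        label = getattr(rep, "label", None) or getattr(rep, "model_name", "?")
        val = validation_by_label.get(label)
        val_str = val.rendered_rmse(6) if val is not None else "-"
        lines.append(
            f"{label:<24}"
            f"{rep.predicted_mean:.2f} ± {rep.predicted_sd:.2f}   "
            f"{rep.predicted_min:>7.2f}{rep.predicted_max:>7.2f}"
            f"{rep.rmse:>10.5f}{val_str:>11}"
            f"{(rep.rank if rep.rank is not None else '-'):>6}"
        )
    return "\n".join(lines)


@dataclass
class RunManifest:
    """Provenance record emitted once per CLI run."""

    subcommand: str
    parameters: dict
    seed: int | None
    inputs: list[str]
    outputs: list[str]
    package_version: str = field(default_factory=lambda: _package_version())
    timestamp: str = field(
        default_factory=lambda: datetime.datetime.now(datetime.timezone.utc).isoformat()
    )

    def write(self, path) -> None:
        with open(path, "w") as handle:
            json.dump(_jsonable(self), handle, indent=2)


def _package_version() -> str:
    try:
        return metadata.version("epicmap")
    except metadata.PackageNotFoundError:
        return "unknown"
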