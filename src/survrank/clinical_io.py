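"""Reading, validating and summarising clinical survival tables.

The unit of data flow everywhere in the package is the :class:`SurvivalTable`:
an n x p numeric covariate matrix plus a survival time in months and a binary
event indicator (1 = death observed, 0 = right-censored). Construction
enforces the contract downstream code relies on — strictly positive times,
0/1 events, no missing values — so missing-data handling happens here, at
read time, under an explicit policy.

Schema presets are provided for the three public glioblastoma cohorts the
package is designed around (Lammer, n=60; Shieh, n=84; Berendsen, n=647),
with the per-feature codings used in their deposited files.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureSpec",
    "SurvivalTable",
    "LoadReport",
    "CohortSummary",
    "SchemaError",
    "read_cohort",
    "write_cohort",
    "dataset_schema",
    "summarize",
]

FEATURE_KINDS = ("numeric", "binary", "rank")


class SchemaError(ValueError):
    """A table does not match the declared schema."""


@dataclass(frozen=True)
class FeatureSpec:
    """Definition of one covariate: name, kind and (for coded kinds) coding.

    ``coding`` maps category labels to integer codes; binary features must use
    exactly the codes {0, 1} and rank features consecutive integers from 0.
    """

    name: str
    kind: str
    meaning: str = ""
    coding: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        if self.kind not in FEATURE_KINDS:
            raise ValueError(f"kind must be one of {FEATURE_KINDS}, got {self.kind!r}")
        codes = sorted(set(self.coding.values()))
        if self.kind == "binary" and self.coding and codes != [0, 1]:
            raise ValueError(f"binary feature {self.name!r} must code to {{0, 1}}")
        if self.kind == "rank" and self.coding and codes != list(range(len(codes))):
            raise ValueError(
                f"rank feature {self.name!r} must use consecutive codes from 0"
            )

    @property
    def codes(self) -> list[int]:
        if self.kind == "binary":
            return [0, 1]
        return sorted(set(self.coding.values()))


@dataclass(frozen=True)
class LoadReport:
    rows_read: int
    rows_dropped_missing: int
    rows_dropped_nonpositive_time: int
    rows_imputed: int
    missing_per_column: dict[str, int]

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2)


class SurvivalTable:
    """Covariates plus right-censored survival outcome.

    Attributes
    ----------
    features : list[FeatureSpec]
    X : pandas.DataFrame, n x p numeric covariates
    time : ndarray of strictly positive survival months
    event : ndarray of 0/1 indicators (1 = death observed)
    """

    def __init__(self, features, X, time, event, load_report: LoadReport | None = None):
        X = pd.DataFrame(X).reset_index(drop=True)
        time = np.asarray(time, dtype=float)
        event = np.asarray(event)
        names = [f.name for f in features]
        if list(X.columns) != names:
            raise SchemaError(
                f"covariate columns {list(X.columns)} do not match schema {names}"
            )
        if X.isna().any().any():
            raise ValueError("covariates contain missing values")
        if time.ndim != 1 or len(X) != time.size or time.size != event.size:
            raise ValueError("X, time and event must have equal row counts")
        if time.size == 0:
            raise ValueError("empty survival table")
        if np.any(~np.isfinite(time)) or np.any(time <= 0):
            bad = np.nonzero(~(np.isfinite(time) & (time > 0)))[0]
            raise ValueError(f"non-positive survival time at rows {bad.tolist()[:10]}")
        ev = event.astype(float)
        if np.any(~np.isin(ev, (0.0, 1.0))):
            bad = np.nonzero(~np.isin(ev, (0.0, 1.0)))[0]
            raise ValueError(
                f"event indicator must be 0 or 1; offending rows {bad.tolist()[:10]}"
            )
        self.features = list(features)
        self.X = X.astype(float)
        self.time = time
        self.event = ev.astype(int)
        self.load_report = load_report

    @property
    def n(self) -> int:
        return len(self.X)

    @property
    def feature_names(self) -> list[str]:
        return [f.name for f in self.features]

    def subset(self, idx) -> "SurvivalTable":
        idx = np.asarray(idx)
        return SurvivalTable(
            self.features, self.X.iloc[idx], self.time[idx], self.event[idx]
        )

    def drop_features(self, names) -> "SurvivalTable":
        keep = [f for f in self.features if f.name not in set(names)]
        return SurvivalTable(
            keep, self.X[[f.name for f in keep]], self.time, self.event
        )

    def __repr__(self) -> str:
        return f"SurvivalTable(n={self.n}, p={len(self.features)})"


# --------------------------------------------------------------------------
# Schema presets for the three glioblastoma cohorts
# --------------------------------------------------------------------------

_YN = {"no": 0, "yes": 1}

_LAMMER = [
    FeatureSpec("Age", "numeric", "Age of patient in years"),
    FeatureSpec(
        "CHSP70", "binary", "Cytosolic heat shock protein 70 expression",
        {"low": 0, "high": 1},
    ),
    FeatureSpec(
        "MGMT methylation status", "binary",
        "MGMT promoter methylation, cut-off at 8% methylated promoters", _YN,
    ),
    FeatureSpec("PFS", "numeric", "Progression-free survival in months"),
    FeatureSpec("Progress", "binary", "Tumor progression", _YN),
    FeatureSpec("Sex", "binary", "Patient sex", {"female": 0, "male": 1}),
]

_SHIEH = [
    FeatureSpec("Age", "numeric", "Age of patient in years"),
    FeatureSpec("Chemo", "binary", "Received chemotherapy", _YN),
    FeatureSpec("Dose", "numeric", "Radiation dose in Gy"),
    FeatureSpec("PFS", "numeric", "Progression-free survival in months"),
    FeatureSpec("Progress", "binary", "Tumor progression", _YN),
    FeatureSpec("Sex", "binary", "Patient sex", {"female": 0, "male": 1}),
    FeatureSpec("Surgery", "binary", "Received surgery", _YN),
    FeatureSpec("Volume", "numeric", "Radiation volume in mL"),
]

_BERENDSEN = [
    FeatureSpec(
        "Adjuvant treatment", "rank", "Adjuvant therapy intensity",
        {"none": 0, "monotherapy": 1, "RT + TMZ": 2},
    ),
    FeatureSpec("Age", "numeric", "Age of patient in years"),
    FeatureSpec(
        "Biopsy debulking", "binary", "Extent of surgery",
        {"biopsy": 0, "resection": 1},
    ),
    FeatureSpec(
        "KPS", "binary", "Karnofsky performance status, dichotomised at 70",
        {"KPS < 70": 0, "KPS >= 70": 1},
    ),
    FeatureSpec(
        "SVZ status", "binary", "Tumor contact with the subventricular zone",
        {"no SVZ contact": 0, "SVZ contact": 1},
    ),
]

_PRESETS = {
    "lammer": (_LAMMER, "Survival", "Survived"),
    "shieh": (_SHIEH, "Survival", "Survived"),
    "berendsen": (_BERENDSEN, "Survival", "Survived"),
}


def dataset_schema(name: str):
    """Return ``(schema, time_col, event_col)`` for one of the cohort presets.

    The event column follows the deposited coding ``Survived``: 1 = died
    (event observed), 0 = alive at last follow-up (censored).
    """
    key = name.strip().lower()
    if key not in _PRESETS:
        raise KeyError(
            f"unknown dataset {name!r}; valid presets: {sorted(_PRESETS)}"
        )
    schema, time_col, event_col = _PRESETS[key]
    return list(schema), time_col, event_col


# --------------------------------------------------------------------------
# Reading / writing
# --------------------------------------------------------------------------

def _normalise(name: str) -> str:
    return " ".join(str(name).strip().lower().split())


def _match_columns(df: pd.DataFrame, wanted: list[str], rename: dict[str, str]):
    """Case-insensitive, whitespace-stripped header matching."""
    rename_norm = {_normalise(k): v for k, v in (rename or {}).items()}
    lookup: dict[str, str] = {}
    for col in df.columns:
        key = _normalise(col)
        key = _normalise(rename_norm.get(key, key))
        lookup.setdefault(key, col)
    mapping = {}
    for name in wanted:
        key = _normalise(name)
        if key not in lookup:
            raise SchemaError(f"required column {name!r} missing from file header")
        mapping[name] = lookup[key]
    return mapping


def _decode_column(series: pd.Series, spec: FeatureSpec, col_label: str) -> pd.Series:
    """Map category labels through the coding; validate numeric codes."""
    raw = series.copy()
    if spec.coding:
        as_str = raw.astype("string").str.strip().str.lower()
        label_map = {_normalise(k): v for k, v in spec.coding.items()}
        decoded = as_str.map(label_map)
        raw = raw.where(decoded.isna(), decoded)
    numeric = pd.to_numeric(raw, errors="coerce")
    bad = numeric.isna() & raw.notna()
    if bad.any():
        rows = np.nonzero(bad.to_numpy())[0][:10].tolist()
        raise ValueError(
            f"unparseable value(s) in column {col_label!r} at row(s) {rows}"
        )
    if spec.kind in ("binary", "rank") and spec.codes:
        allowed = set(spec.codes)
        invalid = numeric.notna() & ~numeric.isin(list(allowed))
        if invalid.any():
            rows = np.nonzero(invalid.to_numpy())[0][:10].tolist()
            raise ValueError(
                f"column {col_label!r} contains codes outside {sorted(allowed)} "
                f"at row(s) {rows}"
            )
    return numeric


def read_cohort(
    path,
    schema: list[FeatureSpec],
    time_col: str,
    event_col: str,
    missing_policy: str = "drop_rows",
    rename: dict[str, str] | None = None,
    na_values=("", "na", "nan", "none", "missing", "?"),
) -> SurvivalTable:
    """Read a delimited clinical table into a validated :class:`SurvivalTable`.

    The delimiter (comma/semicolon/tab) is sniffed automatically. Header
    matching is case-insensitive and whitespace-stripped, with an optional
    ``rename`` map from file headers to schema names. Missing covariate values
    are handled per ``missing_policy`` (``drop_rows`` = complete-case analysis,
    the default; ``impute_mode`` = per-column mode imputation). Rows with
    missing or non-positive survival time are always dropped. A
    :class:`LoadReport` is logged and attached to the returned table.
    """
    if missing_policy not in ("drop_rows", "impute_mode"):
        raise ValueError("missing_policy must be 'drop_rows' or 'impute_mode'")
    df = pd.read_csv(
        path, sep=None, engine="python", na_values=list(na_values),
        keep_default_na=True, skipinitialspace=True,
    )
    rows_read = len(df)
    wanted = [f.name for f in schema] + [time_col, event_col]
    mapping = _match_columns(df, wanted, rename or {})

    cols = {}
    for spec in schema:
        cols[spec.name] = _decode_column(df[mapping[spec.name]], spec, spec.name)
    time = pd.to_numeric(df[mapping[time_col]], errors="coerce")
    event_raw = df[mapping[event_col]]
    event = pd.to_numeric(event_raw, errors="coerce")
    bad_event = event.notna() & ~event.isin([0, 1])
    if bad_event.any():
        rows = np.nonzero(bad_event.to_numpy())[0][:10].tolist()
        raise ValueError(
            f"event column {event_col!r} must contain only 0/1; offending "
            f"row(s) {rows}"
        )

    X = pd.DataFrame(cols)
    missing_per_column = {c: int(X[c].isna().sum()) for c in X.columns}
    missing_per_column[time_col] = int(time.isna().sum())
    missing_per_column[event_col] = int(event.isna().sum())

    # outcome must be present and time positive, regardless of policy
    keep = time.notna() & event.notna() & (time > 0)
    dropped_time = int(rows_read - keep.sum())

    rows_imputed = 0
    if missing_policy == "drop_rows":
        keep &= X.notna().all(axis=1)
    else:
        has_missing = X.isna().any(axis=1) & keep
        rows_imputed = int(has_missing.sum())
        for c in X.columns:
            col = X[c]
            if col.isna().any():
                mode = col.mode(dropna=True)
                if mode.empty:
                    raise ValueError(f"column {c!r} is entirely missing")
                X[c] = col.fillna(mode.iloc[0])
    dropped_missing = int(rows_read - keep.sum()) - dropped_time

    X, time, event = X[keep], time[keep], event[keep]
    report = LoadReport(
        rows_read=rows_read,
        rows_dropped_missing=dropped_missing,
        rows_dropped_nonpositive_time=dropped_time,
        rows_imputed=rows_imputed,
        missing_per_column=missing_per_column,
    )
    logger.info("load report for %s: %s", path, report.to_json())
    if len(X) == 0:
        raise ValueError(f"no usable rows remain after filtering {path}")
    return SurvivalTable(
        schema, X.reset_index(drop=True), time.to_numpy(), event.to_numpy(),
        load_report=report,
    )


def write_cohort(table: SurvivalTable, path, time_col="Survival", event_col="Survived"):
    """Write a table back to CSV (numeric codes, comma-delimited)."""
    out = table.X.copy()
    out[time_col] = table.time
    out[event_col] = table.event
    out.to_csv(path, index=False)


# --------------------------------------------------------------------------
# Summaries in the style of per-cohort characteristic tables
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortSummary:
    numeric: pd.DataFrame       # feature, median, mean, sd, min, max
    categorical: pd.DataFrame   # feature, level, code, count, percent

    def to_csv(self, numeric_path, categorical_path):
        self.numeric.to_csv(numeric_path, index=False)
        self.categorical.to_csv(categorical_path, index=False)


def summarize(table: SurvivalTable) -> CohortSummary:
    """Marginal summaries: median/mean/sd/range for numeric features, count and
    percentage per level for coded features. The survival time and event
    indicator are included alongside the covariates; percentages within each
    categorical feature sum to 100 up to rounding.
    """
    num_rows, cat_rows = [], []

    def add_numeric(name, values):
        values = np.asarray(values, dtype=float)
        num_rows.append(
            {
                "feature": name,
                "median": float(np.median(values)),
                "mean": float(np.mean(values)),
                "sd": float(np.std(values, ddof=1)) if values.size > 1 else 0.0,
                "min": float(values.min()),
                "max": float(values.max()),
            }
        )

    def add_categorical(name, values, coding):
        values = np.asarray(values)
        n = values.size
        inverse = {v: k for k, v in coding.items()}
        for code in sorted(np.unique(values)):
            count = int(np.sum(values == code))
            cat_rows.append(
                {
                    "feature": name,
                    "level": inverse.get(int(code), str(int(code))),
                    "code": int(code),
                    "count": count,
                    "percent": round(100.0 * count / n, 2),
                }
            )

    for spec in table.features:
        col = table.X[spec.name].to_numpy()
        if spec.kind == "numeric":
            add_numeric(spec.name, col)
        else:
            add_categorical(spec.name, col.astype(int), spec.coding)
    add_numeric("Survival", table.time)
    add_categorical("Survived", table.event, {"yes (alive)": 0, "no (died)": 1})

    return CohortSummary(pd.DataFrame(num_rows), pd.DataFrame(cat_rows))
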